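# forkstat

Quantification toolkit for replication-fork biology. It covers the three
measurement stacks such studies rest on:

1. **Single-molecule localization microscopy (SMLM/STORM).** From raw
   blinking movies to molecular coordinates and colocalization statistics:
   difference-of-Gaussians spot detection, multi-emitter 2D-Gaussian
   fitting by Poisson maximum likelihood, per-localization precision from
   the Cramér–Rao lower bound, skew-Gaussian precision calibration,
   blinking-event linking, three-colour channel alignment, auto/cross
   pair-correlation ("density of A at B"), nuclear focus segmentation, and
   10 nm-canvas rendering.
2. **DNA fiber restart assays.** CldU/IdU tract-length ratios (a proxy for
   fork speed after restart), stalled-fork fractions, the S1-nuclease
   digestion model for ssDNA gaps, and µm→kb conversion (1 µm = 2.59 kb).
3. **Dose-response viability.** Four-parameter logistic (variable-slope)
   EC50 fitting with confidence intervals.

Because raw microscope data for such experiments is rarely shareable, the
package ships a first-class **synthetic data generator** with known ground
truth for every stage: blinking emitters rendered as pixel-integrated
Gaussian PSFs with Poisson noise on a 65 nm pixel grid, two-colour point
patterns with controllable co-clustering, fiber tract tables with stalls
and gaps, and 4PL viability curves. Every analysis here is validated
against that ground truth or an independent oracle.

## The models in brief

*Localization.* A candidate pixel region (9×9 px) is fitted with
μ<sub>px</sub> = b + Σ<sub>k</sub> N<sub>k</sub>·G(x−x<sub>k</sub>, y−y<sub>k</sub>; σ),
where G is a pixel-integrated 2D Gaussian, by maximizing the Poisson
log-likelihood Σ(d·log μ − μ). Emitters are added greedily; an added
emitter is kept only if a likelihood-ratio test (2ΔlogL vs χ²₃) accepts
it. Precision is the CRLB: the square root of the position diagonal of the
inverse Fisher information of the same model.

*Pair correlation.* All pair-wise distances between molecules of two
colours are histogrammed; each bin is normalized by the edge-corrected
annulus area summed over reference points, so complete spatial randomness
(CSR) gives a flat profile and the scalar "density of A at B" equals the
global density of A under CSR.

*Fiber assay.* ratio = CldU/IdU tract length per fiber; a fork is stalled
when an IdU-positive tract has no CldU. S1 nuclease cuts the CldU segment
at every ssDNA gap; the junction-attached fragment is the measured
post-digestion length.

*Dose response.* response = floor + (ceiling−floor)/(1+10^(hill·(log₁₀c −
log₁₀EC50))).

## Worked example

```python
import numpy as np
import forkstat as fs
from forkstat.stats import mann_whitney

conds = [fs.FiberCondition(name="parental", cldu_median_um=8.0, stalled_fraction=0.25),
         fs.FiberCondition(name="slfn11_ko", cldu_median_um=16.0, stalled_fraction=0.10,
                           gap_rate_per_um=0.25, gap_len_mean_um=0.6)]
tracts, gaps = fs.simulate_fiber_table(conds, 180, seed=1)
for name, grp in tracts.groupby("condition"):
    r = fs.restart_ratios(grp)
    print(name, round(r.median(), 2), round(fs.stalled_fraction(grp), 2))
u, p = mann_whitney(fs.restart_ratios(tracts[tracts.condition == "parental"]),
                    fs.restart_ratios(tracts[tracts.condition == "slfn11_ko"]))
print(f"Mann-Whitney U={u:.0f} p={p:.3g}")
post = fs.apply_s1_table(tracts, gaps)
print("KO median CldU pre/post S1 (um):",
      round(tracts.query("condition=='slfn11_ko' and cldu_len_um>0").cldu_len_um.median(), 2),
      round(post.query("condition=='slfn11_ko' and cldu_len_um>0").cldu_len_um.median(), 2))
```

prints

```
parental 0.64 0.23
slfn11_ko 1.53 0.09
Mann-Whitney U=5357 p=3.55e-28
KO median CldU pre/post S1 (um): 15.49 2.94
```

— the knockout arm restarts faster (ratio 1.53 vs 0.64, overwhelmingly
significant at n = 180 fibers/arm), stalls less often (9% vs 23%), and its
long CldU tracts collapse after S1 digestion (15.5 → 2.9 µm median),
revealing that the extra synthesis is interspersed with ssDNA gaps.

The SMLM stack works the same way from Python
(`simulate_movie → localize_movie → calibrate_precision → link_events →
cross_pair_correlation`) or from the shell:

```bash
forkstat simulate-movie --n-emitters 20 --photons 3000 --seed 5 --out movie.tif
forkstat localize movie.tif --out locs.csv
forkstat link locs.csv --out events.csv
forkstat paircorr points.csv --roi 0,0,5000,5000 --out pc.csv
```

Every subcommand writes a JSON run manifest (config snapshot, input
hashes, seed, QC counters) next to its output.

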