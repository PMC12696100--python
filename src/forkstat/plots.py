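"""Small matplotlib helpers mirroring the study's panel styles.

All functions take an Axes (created if omitted) and return it; nothing here
is needed for the quantitative pipeline.
"""

from __future__ import annotations

import numpy as np

from .spatial import PairCorrResult


def _ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt
        _, ax = plt.subplots()
    return ax


def swarm_ratios(ratios_by_condition: dict, ax=None, jitter_seed: int = 0):
    """Swarm-style scatter of CldU/IdU ratios per condition with mean +/- SD."""
    ax = _ax(ax)
    rng = np.random.default_rng(jitter_seed)
    for i, (name, vals) in enumerate(ratios_by_condition.items()):
        vals = np.asarray(vals, dtype=float)
        x = i + rng.uniform(-0.18, 0.18, vals.size)
        ax.plot(x, vals, ".", ms=3, alpha=0.5)
        ax.errorbar([i], [vals.mean()], yerr=[vals.std(ddof=1)], fmt="_",
                    color="k", capsize=4, ms=18)
    ax.set_xticks(range(len(ratios_by_condition)),
                  list(ratios_by_condition), rotation=30, ha="right")
    ax.set_ylabel("CldU/IdU tract-length ratio")
    return ax


def tract_length_hist(lengths_by_condition: dict, bins=20, ax=None):
    """Overlaid CldU tract-length histograms (um)."""
    ax = _ax(ax)
    for name, vals in lengths_by_condition.items():
        ax.hist(np.asarray(vals, dtype=float), bins=bins, histtype="step",
                density=True, label=str(name))
    ax.set_xlabel("CldU tract length (um)")
    ax.set_ylabel("density")
    ax.legend()
    return ax


def pair_correlation_profile(result: PairCorrResult, ax=None):
    """Edge-corrected local-density profile versus pair distance."""
    ax = _ax(ax)
    centers = 0.5 * (result.r_bin_edges[:-1] + result.r_bin_edges[1:])
    ax.step(centers, result.density_profile_per_um2, where="mid")
    ax.axhline(result.density_at_b_per_um2, ls="--", color="grey",
               label=f"density at B (r0={result.r0_nm:g} nm)")
    ax.set_xlabel("pair distance (nm)")
    ax.set_ylabel("local density (um$^{-2}$)")
    ax.legend()
    return ax


def dose_response_curve(fit, concentrations, responses, ax=None):
    """Observed viabilities and the fitted 4PL curve on a log dose axis."""
    ax = _ax(ax)
    conc = np.asarray(concentrations, dtype=float)
    ax.semilogx(conc, responses, "o", ms=4)
    grid = np.geomspace(conc.min(), conc.max(), 200)
    ax.semilogx(grid, fit.predict(grid), "-",
                label=f"EC50 = {fit.ec50:.3g}")
    ax.set_xlabel("concentration")
    ax.set_ylabel("viability")
    ax.legend()
    return ax
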