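"""Ground-truth synthetic data for every downstream stage.

Four generators:

* blinking-emitter SMLM movies (pixel-integrated Gaussian PSFs + Poisson
  shot noise on a 65 nm pixel grid),
* two-colour point patterns with controllable co-clustering (the input to
  cross pair-correlation analysis),
* DNA-fiber tract tables for the fork-restart assay (lognormal IdU/CldU
  tract lengths, optional stalled forks and ssDNA gaps),
* four-parameter-logistic dose-response (viability) tables.

Every generator is a pure function of its configuration and seed: the same
inputs give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._psf import render_psf

__all__ = [
    "SimConfig",
    "EmitterGroundTruth",
    "CoClusterSpec",
    "FiberCondition",
    "Movie",
    "simulate_blinking",
    "simulate_movie",
    "random_emitters",
    "truth_table",
    "simulate_point_pattern",
    "simulate_fiber_table",
    "simulate_dose_response",
    "four_param_logistic",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class SimConfig:
    """Acquisition parameters for a simulated SMLM movie.

    Defaults mirror a typical STORM acquisition on a 65 nm/pixel camera with
    a PSF standard deviation of 143 nm.
    """

    field_size_px: tuple[int, int] = (64, 64)  # (rows, cols)
    pixel_size_nm: float = 65.0
    psf_sigma_nm: float = 143.0
    background_photons_per_px: float = 2.0
    n_frames: int = 200
    blink_on_rate: float = 0.02
    blink_off_rate: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0 or self.psf_sigma_nm <= 0:
            raise ValueError("pixel_size_nm and psf_sigma_nm must be positive")
        if self.n_frames <= 0:
            raise ValueError("n_frames must be positive")
        if not (0.0 <= self.blink_on_rate <= 1.0 and 0.0 <= self.blink_off_rate <= 1.0):
            raise ValueError("blink rates must lie in [0, 1]")
        if self.background_photons_per_px < 0:
            raise ValueError("background must be non-negative")

    @property
    def field_size_nm(self) -> tuple[float, float]:
        ny, nx = self.field_size_px
        return (nx * self.pixel_size_nm, ny * self.pixel_size_nm)


@dataclass
class EmitterGroundTruth:
    """One true emitter: position, channel, blinking schedule, brightness."""

    emitter_id: int
    x_nm: float
    y_nm: float
    channel: str
    on_intervals: list[tuple[int, int]] = field(default_factory=list)
    photons_per_frame: float = 1000.0

    def __post_init__(self) -> None:
        if self.photons_per_frame <= 0:
            raise ValueError("photons_per_frame must be positive")
        prev_last = -1
        for first, last in self.on_intervals:
            if first > last or first <= prev_last:
                raise ValueError("on_intervals must be ordered, disjoint, inclusive")
            prev_last = last

    def on_mask(self, n_frames: int) -> np.ndarray:
        mask = np.zeros(n_frames, dtype=bool)
        for first, last in self.on_intervals:
            mask[max(first, 0): last + 1] = True
        return mask


@dataclass
class Movie:
    """A frame-indexed photon-count stack with pixel size and channel label."""

    frames: np.ndarray  # (n_frames, ny, nx), photons
    pixel_size_nm: float
    channel: str = "ch0"

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def simulate_blinking(on_rate: float, off_rate: float, n_frames: int,
                      seed) -> list[tuple[int, int]]:
    """Sample a two-state (on/off) Markov blinking trajectory.

    The initial state is drawn from the stationary distribution
    p_on = on_rate / (on_rate + off_rate) (off when both rates are zero).
    Returns the "on" frames merged into inclusive (first, last) intervals.
    """
    if not (0.0 <= on_rate <= 1.0 and 0.0 <= off_rate <= 1.0):
        raise ValueError("rates must lie in [0, 1]")
    if n_frames <= 0:
        raise ValueError("n_frames must be positive")
    rng = _rng(seed)
    total = on_rate + off_rate
    p_on0 = on_rate / total if total > 0 else 0.0
    u = rng.random(n_frames)
    state = np.empty(n_frames, dtype=bool)
    state[0] = u[0] < p_on0
    for t in range(1, n_frames):
        if state[t - 1]:
            state[t] = not (u[t] < off_rate)
        else:
            state[t] = u[t] < on_rate
    return _mask_to_intervals(state)


def _mask_to_intervals(mask: np.ndarray) -> list[tuple[int, int]]:
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    return [(int(idx[s]), int(idx[e])) for s, e in zip(starts, ends)]


def random_emitters(config: SimConfig, n_emitters: int, seed,
                    photons_per_frame: float = 1000.0,
                    channel: str = "ch0",
                    margin_nm: float | None = None,
                    min_separation_nm: float = 0.0) -> list[EmitterGroundTruth]:
    """Place emitters uniformly in the field and give each a blinking schedule.

    ``margin_nm`` keeps emitters away from the borders (default 3 sigma, so
    none are clipped); ``min_separation_nm`` > 0 enforces a hard-core
    minimum distance between emitters (rejection sampling), which is how a
    "sparse" field with non-overlapping PSFs is generated.
    """
    rng = _rng(seed)
    w_nm, h_nm = config.field_size_nm
    if margin_nm is None:
        margin_nm = 3.0 * config.psf_sigma_nm
    if 2 * margin_nm >= min(w_nm, h_nm):
        raise ValueError("margin too large for the field")
    emitters: list[EmitterGroundTruth] = []
    attempts = 0
    while len(emitters) < n_emitters:
        if attempts > 1000 * n_emitters:
            raise ValueError("cannot place emitters at this separation/density")
        attempts += 1
        x = rng.uniform(margin_nm, w_nm - margin_nm)
        y = rng.uniform(margin_nm, h_nm - margin_nm)
        if min_separation_nm > 0 and any(
                (x - e.x_nm) ** 2 + (y - e.y_nm) ** 2 < min_separation_nm ** 2
                for e in emitters):
            continue
        intervals = simulate_blinking(config.blink_on_rate, config.blink_off_rate,
                                      config.n_frames, rng)
        emitters.append(EmitterGroundTruth(len(emitters), x, y, channel,
                                           intervals, photons_per_frame))
    return emitters


def simulate_movie(config: SimConfig, truth: list[EmitterGroundTruth],
                   noise: bool = True) -> Movie:
    """Render a movie: each "on" emitter contributes a pixel-integrated 2D
    Gaussian PSF scaled to its photon count, a uniform background is added,
    and (optionally) per-pixel Poisson shot noise is applied.
    """
    ny, nx = config.field_size_px
    w_nm, h_nm = config.field_size_nm
    for em in truth:
        if not (0.0 <= em.x_nm < w_nm and 0.0 <= em.y_nm < h_nm):
            raise ValueError(f"emitter {em.emitter_id} outside the field of view")
    frames = np.full((config.n_frames, ny, nx), float(config.background_photons_per_px))
    for em in truth:
        psf = render_psf((ny, nx), em.x_nm, em.y_nm, config.psf_sigma_nm,
                         config.pixel_size_nm, em.photons_per_frame)
        mask = em.on_mask(config.n_frames)
        frames[mask] += psf
    if noise:
        rng = _rng(config.seed)
        frames = rng.poisson(frames).astype(float)
    return Movie(frames=frames, pixel_size_nm=config.pixel_size_nm,
                 channel=truth[0].channel if truth else "ch0")


def truth_table(truth: list[EmitterGroundTruth], config: SimConfig) -> pd.DataFrame:
    """Ground truth as a table, one row per on-interval.

    ``clipped`` flags emitters within 3 sigma of a field edge, whose rendered
    PSF loses photons over the border.
    """
    w_nm, h_nm = config.field_size_nm
    m = 3.0 * config.psf_sigma_nm
    rows = []
    for em in truth:
        clipped = (em.x_nm < m or em.y_nm < m or em.x_nm > w_nm - m or em.y_nm > h_nm - m)
        for first, last in em.on_intervals:
            rows.append((em.emitter_id, em.x_nm, em.y_nm, em.channel,
                         first, last, em.photons_per_frame, clipped))
    return pd.DataFrame(rows, columns=["emitter_id", "x_nm", "y_nm", "channel",
                                       "first_frame", "last_frame", "photons",
                                       "clipped"])


@dataclass(frozen=True)
class CoClusterSpec:
    """Two-colour point pattern with a controllable co-clustered fraction.

    Channel A is homogeneous Poisson at ``density_a``; a ``coloc_fraction``
    of B points are placed at a random A point plus an isotropic Gaussian
    displacement of scale ``coloc_sigma_nm``, the rest are homogeneous
    Poisson at ``density_b``.  Densities are points per um^2; the region is
    an axis-aligned rectangle (x0, y0, x1, y1) in nm.
    """

    density_a: float = 50.0
    density_b: float = 50.0
    coloc_fraction: float = 0.0
    coloc_sigma_nm: float = 20.0
    region_nm: tuple[float, float, float, float] = (0.0, 0.0, 5000.0, 5000.0)

    def __post_init__(self) -> None:
        if self.density_a < 0 or self.density_b < 0:
            raise ValueError("densities must be non-negative")
        if not 0.0 <= self.coloc_fraction <= 1.0:
            raise ValueError("coloc_fraction must lie in [0, 1]")
        x0, y0, x1, y1 = self.region_nm
        if x1 <= x0 or y1 <= y0:
            raise ValueError("degenerate region")

    @property
    def area_um2(self) -> float:
        x0, y0, x1, y1 = self.region_nm
        return (x1 - x0) * (y1 - y0) / 1e6


def simulate_point_pattern(spec: CoClusterSpec, seed):
    """Sample the two channels.

    Returns ``(coords_a, coords_b, b_is_coloc)`` with coordinates in nm of
    shape (n, 2) and a boolean truth label per B point.  Co-clustered B
    points may land slightly outside the region (their parent plus a
    Gaussian offset); analyses restrict to an ROI themselves.
    """
    rng = _rng(seed)
    x0, y0, x1, y1 = spec.region_nm
    area = spec.area_um2
    n_a = rng.poisson(spec.density_a * area)
    coords_a = np.column_stack([rng.uniform(x0, x1, n_a), rng.uniform(y0, y1, n_a)])
    n_b = rng.poisson(spec.density_b * area)
    is_coloc = rng.random(n_b) < spec.coloc_fraction
    if n_a == 0:
        is_coloc[:] = False  # nothing to co-cluster with
    coords_b = np.column_stack([rng.uniform(x0, x1, n_b), rng.uniform(y0, y1, n_b)])
    n_c = int(is_coloc.sum())
    if n_c:
        parents = rng.integers(0, n_a, n_c)
        offsets = rng.normal(0.0, spec.coloc_sigma_nm, (n_c, 2))
        coords_b[is_coloc] = coords_a[parents] + offsets
    return coords_a, coords_b, is_coloc


@dataclass(frozen=True)
class FiberCondition:
    """Generating parameters for one fiber-assay condition.

    Tract lengths are lognormal with the given medians (um) and a common
    log-scale spread; ``stalled_fraction`` of tracts get a CldU length of 0;
    if ``gap_rate_per_um`` > 0, internal ssDNA gaps are placed along the
    CldU segment as a Poisson process with exponentially distributed gap
    lengths.
    """

    name: str = "control"
    idu_median_um: float = 10.0
    cldu_median_um: float = 10.0
    sigma_log: float = 0.35
    stalled_fraction: float = 0.0
    gap_rate_per_um: float = 0.0
    gap_len_mean_um: float = 0.5
    replicate: str = "r1"


def simulate_fiber_table(conditions, n_tracts: int, seed):
    """Sample a fiber-tract table plus a long-format gap table.

    Returns ``(tracts, gaps)`` DataFrames.  ``tracts`` has one row per fiber
    (condition, replicate, tract_id, idu_len_um, cldu_len_um); ``gaps`` one
    row per internal gap (tract_id, gap_start_um, gap_len_um), with starts
    measured from the IdU/CldU junction.  Gaps are trimmed to be
    non-overlapping and to lie inside the CldU segment.
    """
    if isinstance(conditions, FiberCondition):
        conditions = [conditions]
    rng = _rng(seed)
    tract_rows, gap_rows = [], []
    tract_id = 0
    for cond in conditions:
        mu_idu = np.log(cond.idu_median_um)
        mu_cldu = np.log(cond.cldu_median_um)
        for _ in range(n_tracts):
            idu = float(rng.lognormal(mu_idu, cond.sigma_log))
            stalled = rng.random() < cond.stalled_fraction
            cldu = 0.0 if stalled else float(rng.lognormal(mu_cldu, cond.sigma_log))
            if cond.gap_rate_per_um > 0 and cldu > 0:
                n_gaps = rng.poisson(cond.gap_rate_per_um * cldu)
                if n_gaps:
                    starts = np.sort(rng.uniform(0.0, cldu, n_gaps))
                    lens = rng.exponential(cond.gap_len_mean_um, n_gaps)
                    bounds = np.append(starts[1:], cldu)
                    lens = np.minimum(lens, bounds - starts)  # no overlap, stay inside
                    for s, ln in zip(starts, lens):
                        if ln > 0:
                            gap_rows.append((tract_id, float(s), float(ln)))
            tract_rows.append((cond.name, cond.replicate, tract_id, idu, cldu))
            tract_id += 1
    tracts = pd.DataFrame(tract_rows, columns=["condition", "replicate", "tract_id",
                                               "idu_len_um", "cldu_len_um"])
    gaps = pd.DataFrame(gap_rows, columns=["tract_id", "gap_start_um", "gap_len_um"])
    return tracts, gaps


def four_param_logistic(conc, ec50: float, hill: float, floor: float,
                        ceiling: float) -> np.ndarray:
    """4PL on log10 concentration: the "log[dose] vs response, variable
    slope" model.  Response falls from ``ceiling`` (c -> 0) to ``floor``
    (c -> inf) for hill > 0, crossing (floor+ceiling)/2 at c = ec50.
    """
    conc = np.asarray(conc, dtype=float)
    return floor + (ceiling - floor) / (1.0 + 10.0 ** (hill * (np.log10(conc) - np.log10(ec50))))


def simulate_dose_response(ec50: float, hill: float, floor: float, ceiling: float,
                           concentrations, seed, noise_sd: float = 0.0,
                           n_replicates: int = 1) -> pd.DataFrame:
    """Viability table from a 4PL curve with additive Gaussian noise."""
    rng = _rng(seed)
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive (log scale)")
    rows = []
    for rep in range(n_replicates):
        mean = four_param_logistic(conc, ec50, hill, floor, ceiling)
        vals = mean + rng.normal(0.0, noise_sd, conc.size) if noise_sd > 0 else mean
        for c, v in zip(conc, vals):
            rows.append((float(c), f"r{rep + 1}", float(v)))
    return pd.DataFrame(rows, columns=["concentration_uM", "replicate", "viability"])
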