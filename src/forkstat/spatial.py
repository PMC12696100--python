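"""Coordinate-level SMLM analysis.

Channel alignment, auto- and cross pair-correlation with edge-corrected
density estimates ("density of A at B"), density-based focus segmentation
with per-nucleus summaries, display rendering, and the percent-change
normalization used for condition comparisons.

Distances and coordinates are nm throughout; densities are reported per
um^2.  Pair-distance histograms use half-open bins (lo, hi], so exact
zero-distance pairs (self-pairs in the auto case) never contribute.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError, cKDTree
from shapely.geometry import Polygon, box
from sklearn.cluster import DBSCAN

__all__ = [
    "RectROI",
    "PolygonROI",
    "NucleusROI",
    "Focus",
    "PairCorrResult",
    "AffineTransform2D",
    "align_channels",
    "cross_pair_correlation",
    "auto_pair_correlation",
    "segment_foci",
    "per_nucleus_summary",
    "summarize_nuclei",
    "classify_pcna_positive",
    "render_image",
    "percent_change_normalized",
]

NM2_PER_UM2 = 1e6


# ---------------------------------------------------------------------------
# regions of interest


def _disc_quadrant_area(w: np.ndarray, h: np.ndarray, r: float) -> np.ndarray:
    """Area of {0<=x<=w, 0<=y<=h} inside a radius-r disc centred at the origin."""
    wc = np.clip(w, 0.0, r)
    heff = np.clip(h, 0.0, r)
    xc = np.sqrt(np.maximum(r * r - heff * heff, 0.0))

    def F(x):
        return 0.5 * (x * np.sqrt(np.maximum(r * r - x * x, 0.0))
                      + r * r * np.arcsin(np.clip(x / r, -1.0, 1.0)))

    return np.where(wc <= xc, wc * heff, heff * xc + F(wc) - F(xc))


class RectROI:
    """Axis-aligned rectangular ROI with exact disc-intersection areas."""

    def __init__(self, x0: float, y0: float, x1: float, y1: float):
        if x1 <= x0 or y1 <= y0:
            raise ValueError("degenerate rectangle")
        self.bounds = (float(x0), float(y0), float(x1), float(y1))

    @property
    def area_nm2(self) -> float:
        x0, y0, x1, y1 = self.bounds
        return (x1 - x0) * (y1 - y0)

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        x0, y0, x1, y1 = self.bounds
        return ((p[:, 0] >= x0) & (p[:, 0] <= x1)
                & (p[:, 1] >= y0) & (p[:, 1] <= y1))

    def disc_areas(self, centers: np.ndarray, r: float) -> np.ndarray:
        """Exact area of the radius-r disc around each centre inside the ROI."""
        if r <= 0:
            return np.zeros(len(np.atleast_2d(centers)))
        c = np.atleast_2d(centers)
        x0, y0, x1, y1 = self.bounds

        def Q(X, Y):
            return np.sign(X) * np.sign(Y) * _disc_quadrant_area(np.abs(X), np.abs(Y), r)

        return (Q(x1 - c[:, 0], y1 - c[:, 1]) - Q(x0 - c[:, 0], y1 - c[:, 1])
                - Q(x1 - c[:, 0], y0 - c[:, 1]) + Q(x0 - c[:, 0], y0 - c[:, 1]))

    def as_polygon(self) -> Polygon:
        x0, y0, x1, y1 = self.bounds
        return box(x0, y0, x1, y1)


class PolygonROI:
    """Arbitrary polygonal ROI; disc areas via constructive geometry."""

    def __init__(self, vertices_nm):
        self.polygon = vertices_nm if isinstance(vertices_nm, Polygon) \
            else Polygon(np.asarray(vertices_nm, dtype=float))
        if not self.polygon.is_valid or self.polygon.area <= 0:
            raise ValueError("invalid polygon ROI")

    @property
    def area_nm2(self) -> float:
        return float(self.polygon.area)

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        return shapely.contains_xy(self.polygon, p[:, 0], p[:, 1]) | \
            shapely.intersects_xy(self.polygon.exterior, p[:, 0], p[:, 1])

    def disc_areas(self, centers: np.ndarray, r: float) -> np.ndarray:
        c = np.atleast_2d(centers)
        out = np.full(len(c), np.pi * r * r)
        interior = self.polygon.buffer(-r)
        inside = shapely.contains_xy(interior, c[:, 0], c[:, 1]) if not \
            interior.is_empty else np.zeros(len(c), dtype=bool)
        for i in np.flatnonzero(~inside):
            disc = shapely.Point(c[i]).buffer(r, quad_segs=64)
            out[i] = disc.intersection(self.polygon).area
        return out

    def as_polygon(self) -> Polygon:
        return self.polygon


def _annulus_area_sums(roi, centers: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Sum over centres of the area of each annulus (edges[i], edges[i+1]]
    clipped to the ROI."""
    disc = np.stack([roi.disc_areas(centers, r) if r > 0
                     else np.zeros(len(np.atleast_2d(centers))) for r in edges])
    return np.diff(disc.sum(axis=1))


@dataclass
class NucleusROI:
    """One nucleus region with its S-phase (PCNA-positive) call."""

    roi: RectROI | PolygonROI
    label: str = "nucleus"
    pcna_positive: bool | None = None

    @property
    def area_um2(self) -> float:
        return self.roi.area_nm2 / NM2_PER_UM2


def classify_pcna_positive(nucleus: NucleusROI, pcna_events_xy: np.ndarray,
                           background_density_per_um2: float,
                           factor: float = 3.0) -> bool:
    """Call a nucleus PCNA-positive when its PCNA event density exceeds
    ``factor`` (default 3x) times the slide background density — a
    reproducible proxy for the visual S-phase call."""
    pts = np.atleast_2d(np.asarray(pcna_events_xy, dtype=float)) \
        if len(pcna_events_xy) else np.empty((0, 2))
    n = int(nucleus.roi.contains(pts).sum()) if len(pts) else 0
    density = n / nucleus.area_um2
    return bool(density > factor * background_density_per_um2)


# ---------------------------------------------------------------------------
# channel alignment


@dataclass
class AffineTransform2D:
    """2x2 linear part plus translation, mapping moving -> reference (nm)."""

    matrix: np.ndarray
    translation: np.ndarray
    rms_nm: float = float("nan")

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(2, 2)
        self.translation = np.asarray(self.translation, dtype=float).reshape(2)
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("singular linear part")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.atleast_2d(points) @ self.matrix.T + self.translation


def align_channels(reference_points: np.ndarray,
                   moving_points: np.ndarray) -> AffineTransform2D:
    """Least-squares affine transform from matched point pairs.

    Requires at least 3 non-collinear pairs; reports the residual RMS.
    """
    ref = np.atleast_2d(np.asarray(reference_points, dtype=float))
    mov = np.atleast_2d(np.asarray(moving_points, dtype=float))
    if ref.shape != mov.shape or ref.shape[0] < 3:
        raise ValueError("need >= 3 matched point pairs of equal length")
    centered = mov - mov.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise ValueError("matched points are collinear/degenerate")
    design = np.column_stack([mov, np.ones(len(mov))])
    coef, *_ = np.linalg.lstsq(design, ref, rcond=None)
    matrix = coef[:2].T
    translation = coef[2]
    resid = ref - (mov @ matrix.T + translation)
    rms = float(np.sqrt(np.mean(np.sum(resid ** 2, axis=1))))
    return AffineTransform2D(matrix=matrix, translation=translation, rms_nm=rms)


# ---------------------------------------------------------------------------
# pair correlation


@dataclass
class PairCorrResult:
    """Distance-distribution statistics between two coordinate channels.

    ``pdf`` is the edge-corrected probability density of A-B distances over
    the binned range (integrates to 1; flat under complete spatial
    randomness).  ``density_profile_per_um2`` is the local density of A at
    distance r from a B point; ``density_at_b_per_um2`` integrates it over a
    disc of radius ``r0_nm`` — the scalar "density of A at B".
    """

    r_bin_edges: np.ndarray
    pdf: np.ndarray
    counts: np.ndarray
    density_profile_per_um2: np.ndarray
    density_at_b_per_um2: float
    r0_nm: float
    n_a: int
    n_b: int
    auto: bool = False


def _prepare(coords, roi, name: str):
    pts = np.atleast_2d(np.asarray(coords, dtype=float))
    if pts.size == 0:
        raise ValueError(f"coordinate set {name} is empty")
    pts = pts[roi.contains(pts)]
    if len(pts) == 0:
        raise ValueError(f"coordinate set {name} has no points inside the ROI")
    return pts


def cross_pair_correlation(coords_a, coords_b, r_max: float, bin_width: float,
                           roi, r0_nm: float = 50.0,
                           _auto: bool = False) -> PairCorrResult:
    """Cross pair-correlation: all pair-wise A-B distances up to ``r_max``,
    histogrammed and normalized so that CSR gives a flat profile.

    Edge correction divides each bin's pair count by the summed
    (annulus intersect ROI) area over B points, turning counts into local
    densities of A; ``density_at_b_per_um2`` is the mean over B of the A
    count within ``r0_nm`` divided by the edge-corrected disc area.
    """
    if r_max <= 0 or bin_width <= 0:
        raise ValueError("r_max and bin_width must be positive")
    A = _prepare(coords_a, roi, "A")
    B = A if _auto else _prepare(coords_b, roi, "B")
    n_bins = int(np.ceil(r_max / bin_width))
    edges = np.arange(n_bins + 1, dtype=float) * bin_width

    tree_a = cKDTree(A)
    tree_b = cKDTree(B)
    cum = tree_b.count_neighbors(tree_a, edges)  # pairs with d <= edge
    counts = np.diff(cum).astype(float)  # bins (lo, hi]: self-pairs (d=0) drop out

    area_sums = _annulus_area_sums(roi, B, edges)  # nm^2, edge-corrected
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(area_sums > 0, counts / area_sums, 0.0)  # A per nm^2 at r
    widths = np.diff(edges)
    norm = float(np.sum(g * widths))
    pdf = g / norm if norm > 0 else np.zeros_like(g)

    n_within = tree_a.query_ball_point(B, r0_nm, return_length=True).astype(float)
    if _auto:
        n_within -= 1.0  # remove self
    disc_areas = roi.disc_areas(B, r0_nm)
    density_at_b = float(np.mean(n_within / disc_areas)) * NM2_PER_UM2

    return PairCorrResult(r_bin_edges=edges, pdf=pdf, counts=counts,
                          density_profile_per_um2=g * NM2_PER_UM2,
                          density_at_b_per_um2=density_at_b, r0_nm=r0_nm,
                          n_a=len(A), n_b=len(B), auto=_auto)


def auto_pair_correlation(coords, r_max: float, bin_width: float, roi,
                          r0_nm: float = 50.0) -> PairCorrResult:
    """Auto pair-correlation: as the cross form with A = B and self-pairs
    excluded.  ``counts`` are ordered pairs, so every unordered pair is
    counted twice."""
    return cross_pair_correlation(coords, None, r_max, bin_width, roi,
                                  r0_nm=r0_nm, _auto=True)


def csr_flatness_pvalue(coords, r_max: float, bin_width: float, roi) -> float:
    """Chi-square goodness-of-fit p-value of a pattern's auto-PC profile
    against the flat (CSR) expectation.

    Expected bin counts are proportional to the edge-corrected annulus
    areas summed over points; observed auto counts are halved to unordered
    pairs so the chi-square variance assumption holds (ordered counts come
    in pairs, doubling the variance).  Meaningful at densities where each
    point has few neighbours within ``r_max``; dense patterns inflate the
    statistic through pair-count correlations.
    """
    from scipy.stats import chisquare

    res = auto_pair_correlation(coords, r_max, bin_width, roi)
    pts = np.atleast_2d(np.asarray(coords, dtype=float))
    pts = pts[roi.contains(pts)]
    areas = _annulus_area_sums(roi, pts, res.r_bin_edges)
    observed = res.counts / 2.0
    expected = areas / areas.sum() * observed.sum()
    _, p = chisquare(observed, expected)
    return float(p)


# ---------------------------------------------------------------------------
# foci


@dataclass
class Focus:
    """One density-connected cluster of events."""

    member_ids: np.ndarray
    centroid_nm: tuple[float, float]
    area_um2: float
    density_per_um2: float

    @property
    def n(self) -> int:
        return len(self.member_ids)


def segment_foci(events_xy: np.ndarray, eps_nm: float, min_pts: int):
    """Density-based (DBSCAN) focus segmentation.

    A core point has at least ``min_pts`` events (itself included) within
    ``eps_nm``.  Each cluster's density is members / convex-hull area;
    clusters whose hull is degenerate (fewer than 3 non-collinear points)
    are dropped and counted in QC.  Returns ``(foci, qc)``.
    """
    pts = np.atleast_2d(np.asarray(events_xy, dtype=float))
    qc = {"degenerate_hulls": 0, "noise_points": 0}
    if len(pts) == 0:
        return [], qc
    labels = DBSCAN(eps=eps_nm, min_samples=min_pts).fit(pts).labels_
    qc["noise_points"] = int(np.sum(labels == -1))
    foci: list[Focus] = []
    for lab in np.unique(labels[labels >= 0]):
        ids = np.flatnonzero(labels == lab)
        members = pts[ids]
        try:
            hull = ConvexHull(members)
            area_nm2 = hull.volume  # 2D: "volume" is the area
        except QhullError:
            area_nm2 = 0.0
        if area_nm2 <= 0:
            qc["degenerate_hulls"] += 1
            continue
        area_um2 = area_nm2 / NM2_PER_UM2
        foci.append(Focus(member_ids=ids,
                          centroid_nm=tuple(members.mean(axis=0)),
                          area_um2=area_um2,
                          density_per_um2=len(ids) / area_um2))
    return foci, qc


def per_nucleus_summary(foci: list[Focus], nucleus: NucleusROI) -> float | None:
    """Unweighted mean focus density for one PCNA-positive nucleus.

    Returns None for PCNA-negative nuclei or nuclei without foci (both are
    skipped and counted at the table level by :func:`summarize_nuclei`).
    """
    if not nucleus.pcna_positive or not foci:
        return None
    return float(np.mean([f.density_per_um2 for f in foci]))


def summarize_nuclei(nuclei_foci):
    """Per-nucleus mean focus densities for a list of (NucleusROI, foci).

    Returns ``(table, qc)`` where the table has one row per analysed
    nucleus and QC counts skipped PCNA-negative and focus-free nuclei.
    """
    rows = []
    qc = {"skipped_pcna_negative": 0, "skipped_no_foci": 0}
    for nucleus, foci in nuclei_foci:
        if not nucleus.pcna_positive:
            qc["skipped_pcna_negative"] += 1
            continue
        if not foci:
            qc["skipped_no_foci"] += 1
            continue
        rows.append((nucleus.label, len(foci),
                     float(np.mean([f.density_per_um2 for f in foci]))))
    return pd.DataFrame(rows, columns=["nucleus", "n_foci",
                                       "mean_focus_density_per_um2"]), qc


# ---------------------------------------------------------------------------
# rendering


def render_image(events_xy: np.ndarray, extent_nm: tuple[float, float, float, float],
                 canvas_px_nm: float = 10.0,
                 blur_sigma_nm: float = 0.0) -> np.ndarray:
    """Render events to a display canvas (default 10 nm pixels).

    The unblurred 2D histogram sums to the number of in-extent events; an
    optional Gaussian blur (kernel sigma in nm) is applied for display and
    conserves total intensity away from borders.
    """
    pts = np.atleast_2d(np.asarray(events_xy, dtype=float))
    x0, y0, x1, y1 = extent_nm
    nx = int(np.ceil((x1 - x0) / canvas_px_nm))
    ny = int(np.ceil((y1 - y0) / canvas_px_nm))
    img, _, _ = np.histogram2d(pts[:, 1], pts[:, 0],
                               bins=(ny, nx),
                               range=((y0, y0 + ny * canvas_px_nm),
                                      (x0, x0 + nx * canvas_px_nm)))
    if blur_sigma_nm > 0:
        img = ndimage.gaussian_filter(img, blur_sigma_nm / canvas_px_nm,
                                      mode="constant")
    return img


# ---------------------------------------------------------------------------
# condition comparison


def percent_change_normalized(df: pd.DataFrame, value_col: str,
                              condition_col: str, replicate_col: str,
                              reference: str) -> pd.Series:
    """Percent change between replicate-averaged normalized condition means.

    Per replicate, condition means are divided by the smallest condition
    mean in that replicate; the normalized values are then averaged across
    replicates, and each condition is reported as
    100 * (value - reference) / reference against the stated reference
    condition.
    """
    means = df.groupby([replicate_col, condition_col])[value_col].mean().unstack()
    if reference not in means.columns:
        raise ValueError(f"reference condition {reference!r} not present")
    normalized = means.div(means.min(axis=1), axis=0)
    averaged = normalized.mean(axis=0)
    return 100.0 * (averaged - averaged[reference]) / averaged[reference]
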