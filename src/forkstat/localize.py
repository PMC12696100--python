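"""Single-molecule detection and sub-pixel localization.

The pipeline per frame is the classic DAOSTORM-style routine:

1. difference-of-Gaussians (DoG) band-pass filtering and strict local-maximum
   candidate detection,
2. a 9x9 pixel ROI crop around each candidate,
3. maximum-likelihood fitting of one-or-more pixel-integrated 2D Gaussian
   PSFs under a Poisson noise model (multi-fit with a likelihood-ratio gate
   on each added emitter),
4. per-localization precision from the Cramer-Rao lower bound (CRLB) of the
   same Poisson model,
5. a skew-Gaussian fit to the pooled precision distribution whose centre
   (mode) is the reported average localization precision.

All positions follow the repo-wide convention of continuous nm coordinates
with the origin at the outer corner of pixel (0, 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize, stats

from ._psf import integrated_gaussian_1d, integrated_gaussian_1d_deriv

__all__ = [
    "DetectionParams",
    "Localization",
    "PrecisionCalibration",
    "dog_detect",
    "crop_roi",
    "fit_mle",
    "crlb",
    "calibrate_precision",
    "localize_movie",
]


@dataclass(frozen=True)
class DetectionParams:
    """Detection and fitting configuration.

    The DoG kernel scales default to the PSF sigma (143 nm) and twice the
    PSF sigma (286 nm); the ROI half-width of 4 px gives the 9x9 = 81 px
    fitting window.  ``dog_threshold`` is in photon units of the band-pass
    response; the default of 2.0 sits roughly 10 shot-noise standard
    deviations above a 5 photon/px background while keeping emitters of a
    few hundred photons detectable.
    """

    sigma_small_nm: float = 143.0
    sigma_large_nm: float = 286.0
    roi_half_width_px: int = 4
    dog_threshold: float = 2.0
    max_emitters_per_roi: int = 3
    lr_alpha: float = 0.05

    def __post_init__(self) -> None:
        if not self.sigma_small_nm < self.sigma_large_nm:
            raise ValueError("sigma_small_nm must be smaller than sigma_large_nm")
        if self.roi_half_width_px < 1:
            raise ValueError("roi_half_width_px must be >= 1")


@dataclass
class Localization:
    """One fitted emitter."""

    x_nm: float
    y_nm: float
    frame: int
    photons: float
    background: float
    psf_sigma_nm: float
    crlb_x_nm: float
    crlb_y_nm: float
    channel: str = "ch0"
    roi_id: int = -1
    loglik: float = float("nan")

    @property
    def precision_nm(self) -> float:
        """Scalar per-localization precision: mean of the two axis CRLBs."""
        return 0.5 * (self.crlb_x_nm + self.crlb_y_nm)


@dataclass
class PrecisionCalibration:
    """Skew-Gaussian summary of the per-localization precision distribution.

    ``center_nm`` is the distribution mode and is the value reported as the
    average localization precision; ``xi_nm`` retains the skew-normal
    location parameter for comparison.
    """

    center_nm: float
    scale_nm: float
    shape: float
    n_fit: int
    xi_nm: float = float("nan")


# ---------------------------------------------------------------------------
# detection


def dog_detect(frame_image: np.ndarray, params: DetectionParams,
               pixel_size_nm: float) -> list[tuple[int, int]]:
    """Difference-of-Gaussians candidate detection.

    The frame is filtered with the small and the large Gaussian kernel, the
    large-kernel result is subtracted from the small, and strict local
    maxima of the band-pass image (greater than all 8 neighbours) above
    ``dog_threshold`` are returned as (row, col) pixel coordinates sorted by
    DoG response, strongest first.
    """
    frame_image = np.asarray(frame_image, dtype=float)
    win = 2 * params.roi_half_width_px + 1
    if min(frame_image.shape) < win:
        raise ValueError("frame smaller than the fitting ROI window")
    s_small = params.sigma_small_nm / pixel_size_nm
    s_large = params.sigma_large_nm / pixel_size_nm
    dog = (ndimage.gaussian_filter(frame_image, s_small, mode="nearest")
           - ndimage.gaussian_filter(frame_image, s_large, mode="nearest"))
    footprint = np.ones((3, 3), dtype=bool)
    footprint[1, 1] = False
    neighbour_max = ndimage.maximum_filter(dog, footprint=footprint, mode="constant",
                                           cval=-np.inf)
    peaks = (dog > neighbour_max) & (dog > params.dog_threshold)
    rows, cols = np.nonzero(peaks)
    order = np.argsort(dog[rows, cols])[::-1]
    return [(int(r), int(c)) for r, c in zip(rows[order], cols[order])]


def crop_roi(frame_image: np.ndarray, center_px: tuple[int, int],
             half_width: int):
    """Crop a (2h+1)x(2h+1) patch around ``center_px`` = (row, col).

    Returns ``(patch, (row0, col0))`` with the patch's global offset, or
    ``None`` when the centre is closer than ``half_width`` to any edge (such
    candidates are skipped and counted in QC).
    """
    r, c = center_px
    ny, nx = frame_image.shape
    if not (half_width <= r < ny - half_width and half_width <= c < nx - half_width):
        return None
    r0, c0 = r - half_width, c - half_width
    patch = frame_image[r0: r + half_width + 1, c0: c + half_width + 1]
    return patch, (r0, c0)


# ---------------------------------------------------------------------------
# Poisson MLE fitting (pixel units internally)


def _model(theta: np.ndarray, n_px: int, sigma_px: float):
    """Model mean and its parameter derivatives on an n_px x n_px grid.

    theta = [b, x1, y1, N1, x2, y2, N2, ...] in pixel/photon units.
    Returns (mu, derivs) with derivs a (len(theta), n, n) array.
    """
    edges = np.arange(n_px + 1, dtype=float)
    n_em = (theta.size - 1) // 3
    mu = np.full((n_px, n_px), theta[0])
    derivs = np.empty((theta.size, n_px, n_px))
    derivs[0] = 1.0
    for k in range(n_em):
        x, y, N = theta[1 + 3 * k: 4 + 3 * k]
        ex = integrated_gaussian_1d(edges, x, sigma_px)
        ey = integrated_gaussian_1d(edges, y, sigma_px)
        dex = integrated_gaussian_1d_deriv(edges, x, sigma_px)
        dey = integrated_gaussian_1d_deriv(edges, y, sigma_px)
        mu += N * np.outer(ey, ex)
        derivs[1 + 3 * k] = N * np.outer(ey, dex)
        derivs[2 + 3 * k] = N * np.outer(dey, ex)
        derivs[3 + 3 * k] = np.outer(ey, ex)
    return mu, derivs


def _loglik(data: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, 1e-12, None)
    return float(np.sum(data * np.log(mu) - mu))


def _clip_theta(theta: np.ndarray, n_px: int) -> np.ndarray:
    theta = theta.copy()
    theta[0] = max(theta[0], 1e-8)
    for k in range((theta.size - 1) // 3):
        theta[1 + 3 * k] = np.clip(theta[1 + 3 * k], -0.5, n_px + 0.5)
        theta[2 + 3 * k] = np.clip(theta[2 + 3 * k], -0.5, n_px + 0.5)
        theta[3 + 3 * k] = max(theta[3 + 3 * k], 1e-3)
    return theta


def _fisher_scoring(data: np.ndarray, theta0: np.ndarray, sigma_px: float,
                    tol_px: float = 1e-4, max_iter: int = 100):
    """Maximise the Poisson log-likelihood by damped Fisher scoring.

    Deterministic given the same data and initialization.  Returns
    (theta, loglik, fisher, converged).
    """
    n_px = data.shape[0]
    theta = _clip_theta(theta0.astype(float), n_px)
    mu, derivs = _model(theta, n_px, sigma_px)
    ll = _loglik(data, mu)
    fisher = None
    converged = False
    pos_idx = [i for i in range(1, theta.size) if (i - 1) % 3 != 2]
    for _ in range(max_iter):
        mu_c = np.clip(mu, 1e-12, None)
        grad = np.array([np.sum((data / mu_c - 1.0) * d) for d in derivs])
        flat = derivs.reshape(theta.size, -1) / np.sqrt(mu_c).ravel()
        fisher = flat @ flat.T
        try:
            step = np.linalg.solve(fisher + 1e-9 * np.eye(theta.size), grad)
        except np.linalg.LinAlgError:
            break
        scale = 1.0
        improved = False
        for _ in range(12):
            cand = _clip_theta(theta + scale * step, n_px)
            mu_new, derivs_new = _model(cand, n_px, sigma_px)
            ll_new = _loglik(data, mu_new)
            if ll_new >= ll - 1e-12:
                improved = True
                break
            scale *= 0.5
        if not improved:
            converged = True  # cannot improve: at a (numerical) optimum
            break
        max_move = np.max(np.abs(cand[pos_idx] - theta[pos_idx])) if pos_idx else \
            np.abs(cand - theta).max()
        theta, mu, derivs, ll = cand, mu_new, derivs_new, ll_new
        if max_move < tol_px:
            converged = True
            break
    if fisher is None:
        mu_c = np.clip(mu, 1e-12, None)
        flat = derivs.reshape(theta.size, -1) / np.sqrt(mu_c).ravel()
        fisher = flat @ flat.T
    return theta, ll, fisher, converged


def _initial_emitter(data: np.ndarray, mu: np.ndarray, sigma_px: float):
    resid = data - mu
    r, c = np.unravel_index(np.argmax(resid), resid.shape)
    peak_frac = integrated_gaussian_1d(np.array([-0.5, 0.5]), 0.0, sigma_px)[0] ** 2
    n0 = max(float(resid[r, c]) / peak_frac, 10.0)
    return float(c) + 0.5, float(r) + 0.5, n0


def fit_mle(roi: np.ndarray, params: DetectionParams, psf_sigma_nm: float,
            pixel_size_nm: float, origin_px: tuple[int, int] = (0, 0),
            frame: int = 0, channel: str = "ch0", roi_id: int = -1):
    """Fit one-or-more pixel-integrated 2D Gaussian PSFs to an ROI by
    Poisson maximum likelihood.

    Emitters are added greedily (each initialized at the largest positive
    residual pixel); an added emitter is kept only when the likelihood-ratio
    statistic 2*dlogL exceeds the chi-square(3 dof) critical value at
    ``params.lr_alpha``.  The PSF sigma is held fixed.  Returns a list of
    :class:`Localization` (possibly empty) and a QC dict.
    """
    data = np.asarray(roi, dtype=float)
    if data.ndim != 2 or data.shape[0] != data.shape[1]:
        raise ValueError("ROI must be a square 2D array")
    n_px = data.shape[0]
    sigma_px = psf_sigma_nm / pixel_size_nm
    lr_crit = stats.chi2.ppf(1.0 - params.lr_alpha, df=3)
    qc = {"nonconverged": 0, "outside_roi": 0}

    theta = np.array([max(data.mean(), 1e-6)])
    mu = np.full_like(data, theta[0])
    ll = _loglik(data, mu)
    best = (theta, ll, None)

    for _ in range(params.max_emitters_per_roi):
        x0, y0, n0 = _initial_emitter(data, mu, sigma_px)
        theta_try = np.concatenate([best[0], [x0, y0, n0]])
        theta_new, ll_new, fisher_new, conv = _fisher_scoring(data, theta_try, sigma_px)
        if not conv:
            qc["nonconverged"] += 1
            break
        if 2.0 * (ll_new - best[1]) <= lr_crit:
            break
        best = (theta_new, ll_new, fisher_new)
        mu, _ = _model(theta_new, n_px, sigma_px)

    theta, ll, fisher = best
    locs: list[Localization] = []
    n_em = (theta.size - 1) // 3
    if n_em == 0:
        return locs, qc
    cov = np.linalg.pinv(fisher)
    r0, c0 = origin_px
    for k in range(n_em):
        x, y, N = theta[1 + 3 * k: 4 + 3 * k]
        if not (0.0 <= x <= n_px and 0.0 <= y <= n_px):
            qc["outside_roi"] += 1
            continue
        var_x = max(cov[1 + 3 * k, 1 + 3 * k], 0.0)
        var_y = max(cov[2 + 3 * k, 2 + 3 * k], 0.0)
        locs.append(Localization(
            x_nm=(c0 + x) * pixel_size_nm,
            y_nm=(r0 + y) * pixel_size_nm,
            frame=frame,
            photons=float(N),
            background=float(theta[0]),
            psf_sigma_nm=psf_sigma_nm,
            crlb_x_nm=math.sqrt(var_x) * pixel_size_nm,
            crlb_y_nm=math.sqrt(var_y) * pixel_size_nm,
            channel=channel,
            roi_id=roi_id,
            loglik=ll,
        ))
    return locs, qc


# ---------------------------------------------------------------------------
# CRLB


def crlb(N: float, b: float, psf_sigma_nm: float, pixel_size_nm: float,
         roi_half_width_px: int | None = None,
         offset_frac: tuple[float, float] = (0.5, 0.5)) -> tuple[float, float]:
    """Cramer-Rao lower bound on the position of a single emitter.

    The Fisher information of the pixel-integrated Poisson Gaussian model
    (parameters x, y, N, b) is accumulated numerically over a square pixel
    grid and inverted; the square roots of the position diagonal are
    returned in nm.

    ``roi_half_width_px=None`` (default) sizes the grid to cover +/- 6 sigma
    so the bound is converged — in the b -> 0 limit it approaches
    sigma/sqrt(N) up to the irreducible pixelation penalty (< 1% at 65 nm
    pixels, sigma = 143 nm).  Pass the actual fitting half-width (4 for the
    9x9 window) to get the bound attainable from that ROI alone.
    """
    if N <= 0:
        raise ValueError("N must be positive")
    if b < 0:
        raise ValueError("background must be non-negative")
    if roi_half_width_px is None:
        roi_half_width_px = int(np.ceil(6.0 * psf_sigma_nm / pixel_size_nm))
    n_px = 2 * roi_half_width_px + 1
    sigma_px = psf_sigma_nm / pixel_size_nm
    x = roi_half_width_px + offset_frac[0]
    y = roi_half_width_px + offset_frac[1]
    theta = np.array([b if b > 0 else 1e-12, x, y, N])
    mu, derivs = _model(theta, n_px, sigma_px)
    mu_c = np.clip(mu, 1e-300, None)
    flat = derivs.reshape(4, -1) / np.sqrt(mu_c).ravel()
    fisher = flat @ flat.T
    cov = np.linalg.inv(fisher)
    return (float(np.sqrt(cov[1, 1])) * pixel_size_nm,
            float(np.sqrt(cov[2, 2])) * pixel_size_nm)


# ---------------------------------------------------------------------------
# precision calibration


def calibrate_precision(localizations, min_n: int = 50) -> PrecisionCalibration:
    """Fit a skew-Gaussian to the pooled per-localization precision values
    and report its mode as the average localization precision.

    Accepts a list of :class:`Localization` or a 1D array of precision
    values in nm.  All-equal inputs return that value with shape 0.
    """
    if len(localizations) and isinstance(localizations[0], Localization):
        values = np.array([loc.precision_nm for loc in localizations], dtype=float)
    else:
        values = np.asarray(localizations, dtype=float)
    if values.size < min_n:
        raise ValueError(f"need at least {min_n} localizations, got {values.size}")
    if np.ptp(values) == 0:
        v = float(values[0])
        return PrecisionCalibration(center_nm=v, scale_nm=0.0, shape=0.0,
                                    n_fit=values.size, xi_nm=v)
    a, loc, scale = stats.skewnorm.fit(values)
    res = optimize.minimize_scalar(
        lambda t: -stats.skewnorm.pdf(t, a, loc, scale),
        bounds=(loc - 4 * scale, loc + 4 * scale), method="bounded",
        options={"xatol": 1e-8})
    return PrecisionCalibration(center_nm=float(res.x), scale_nm=float(scale),
                                shape=float(a), n_fit=values.size, xi_nm=float(loc))


# ---------------------------------------------------------------------------
# whole-movie driver


def localize_movie(movie, params: DetectionParams | None = None,
                   psf_sigma_nm: float | None = None):
    """Run detection + multi-emitter MLE over every frame of a movie.

    Fitted emitters from overlapping ROIs closer than one pixel in the same
    frame are de-duplicated keeping the higher-likelihood fit.  Returns
    ``(localizations, qc)``.
    """
    params = params or DetectionParams()
    sigma = psf_sigma_nm if psf_sigma_nm is not None else params.sigma_small_nm
    px = movie.pixel_size_nm
    qc = {"candidates": 0, "dropped_boundary": 0, "nonconverged": 0,
          "outside_roi": 0, "duplicates_merged": 0}
    all_locs: list[Localization] = []
    roi_id = 0
    for f in range(movie.n_frames):
        frame_img = movie.frames[f]
        frame_locs: list[Localization] = []
        for center in dog_detect(frame_img, params, px):
            qc["candidates"] += 1
            cropped = crop_roi(frame_img, center, params.roi_half_width_px)
            if cropped is None:
                qc["dropped_boundary"] += 1
                continue
            patch, (r0, c0) = cropped
            locs, fit_qc = fit_mle(patch, params, sigma, px, origin_px=(r0, c0),
                                   frame=f, channel=movie.channel, roi_id=roi_id)
            qc["nonconverged"] += fit_qc["nonconverged"]
            qc["outside_roi"] += fit_qc["outside_roi"]
            frame_locs.extend(locs)
            roi_id += 1
        frame_locs.sort(key=lambda L: -L.loglik if np.isfinite(L.loglik) else 0.0)
        kept: list[Localization] = []
        for loc in frame_locs:
            dup = any((loc.x_nm - k.x_nm) ** 2 + (loc.y_nm - k.y_nm) ** 2 < px ** 2
                      for k in kept)
            if dup:
                qc["duplicates_merged"] += 1
            else:
                kept.append(loc)
        all_locs.extend(kept)
    return all_locs, qc
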