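"""Four-parameter logistic (4PL) dose-response fitting.

The "log[dose] vs normalized response, variable slope" model:

    response(c) = floor + (ceiling - floor) / (1 + 10^(hill * (log10 c - log10 EC50)))

fitted by least squares with the EC50 parameterized on the log10 scale; the
95% EC50 confidence interval comes from the parameter covariance at the
optimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .simulate import four_param_logistic

__all__ = ["DoseResponseFit", "fit_4pl"]


@dataclass
class DoseResponseFit:
    """Fitted 4PL parameters with EC50 uncertainty and fit diagnostics."""

    ec50: float
    hill: float
    floor: float
    ceiling: float
    ci95_ec50: tuple[float, float]
    rss: float
    n_obs: int
    converged: bool = True
    flat_data: bool = False

    def predict(self, conc) -> np.ndarray:
        return four_param_logistic(conc, self.ec50, self.hill, self.floor,
                                   self.ceiling)

    def summary(self) -> str:
        lo, hi = self.ci95_ec50
        lines = [
            "4PL dose-response fit",
            f"  n observations : {self.n_obs}",
            f"  EC50           : {self.ec50:.6g}  (95% CI {lo:.6g} – {hi:.6g})",
            f"  Hill slope     : {self.hill:.6g}",
            f"  floor / ceiling: {self.floor:.6g} / {self.ceiling:.6g}",
            f"  residual SS    : {self.rss:.6g}",
        ]
        if self.flat_data:
            lines.append("  warning: response range is flat; EC50 ill-determined")
        if not self.converged:
            lines.append("  warning: optimizer did not converge")
        return "\n".join(lines)


def _pack(theta, conc):
    floor, ceiling, log_ec50, hill = theta
    return floor + (ceiling - floor) / (1.0 + 10.0 ** (hill * (np.log10(conc) - log_ec50)))


def fit_4pl(concentrations, responses) -> DoseResponseFit:
    """Least-squares 4PL fit of response against concentration.

    Requires at least 5 distinct positive concentrations.  Monotonic-flat
    data (response range indistinguishable from noise) is flagged rather
    than rejected.
    """
    conc = np.asarray(concentrations, dtype=float)
    resp = np.asarray(responses, dtype=float)
    if conc.shape != resp.shape:
        raise ValueError("concentrations and responses must match in length")
    if np.unique(conc).size < 5:
        raise ValueError("need at least 5 distinct concentrations")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")

    lo, hi = float(resp.min()), float(resp.max())
    span = hi - lo
    flat = span < 1e-12 * max(abs(hi), 1.0)
    log_c = np.log10(conc)
    # initial EC50: concentration whose response is nearest the midpoint
    mid = 0.5 * (lo + hi)
    log_ec50_0 = float(log_c[np.argmin(np.abs(resp - mid))]) if not flat \
        else float(np.median(log_c))
    theta0 = np.array([lo, hi, log_ec50_0, 1.0])

    result = optimize.least_squares(
        lambda th: _pack(th, conc) - resp, theta0,
        method="lm" if conc.size >= 4 else "trf",
        xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=20000)
    floor, ceiling, log_ec50, hill = result.x
    if ceiling < floor:  # canonical orientation: floor < ceiling
        floor, ceiling, hill = ceiling, floor, -hill
    rss = float(np.sum(result.fun ** 2))
    dof = max(conc.size - 4, 1)
    s2 = rss / dof

    jac = result.jac
    try:
        cov = s2 * np.linalg.inv(jac.T @ jac)
        se_log_ec50 = float(np.sqrt(max(cov[2, 2], 0.0)))
    except np.linalg.LinAlgError:
        se_log_ec50 = np.nan
    tcrit = stats.t.ppf(0.975, dof)
    ec50 = 10.0 ** log_ec50
    if np.isfinite(se_log_ec50):
        ci = (10.0 ** (log_ec50 - tcrit * se_log_ec50),
              10.0 ** (log_ec50 + tcrit * se_log_ec50))
    else:
        ci = (np.nan, np.nan)
    return DoseResponseFit(ec50=float(ec50), hill=float(hill), floor=float(floor),
                           ceiling=float(ceiling), ci95_ec50=ci, rss=rss,
                           n_obs=conc.size, converged=bool(result.success),
                           flat_data=bool(flat))
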