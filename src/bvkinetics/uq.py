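"""Post-calibration identifiability diagnostics and parameter uncertainty.

Treats the calibrated parameters as asymptotically normal with the
covariance s²(JᵀJ)⁻¹ from the weighted least-squares fit: per-parameter 95%
confidence intervals use normal quantiles, the 2-D confidence region is the
χ²(2) ellipse of the restricted covariance, and parameter uncertainty is
propagated by Monte-Carlo sampling from N(P*, Σ) with physiologically
implausible draws (K_p ≤ 0, or 1+α_v ≤ 0 which the model cannot simulate)
excluded and the exclusion fraction reported.

Practical identifiability is additionally probed by sum-of-squares cost
contours over parameter pairs: a sublevel set (at a fixed small cost
inflation over the optimum) that runs off the evaluation grid along an axis
marks that parameter as practically unidentifiable — the testable version of
"the confidence region is unbounded in that direction".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .calibration import CalibrationResult, _guarded_residual, residual_floor
from .cohort import SubjectRecord

__all__ = [
    "ConfidenceSummary",
    "ContourGrid",
    "ParameterDraws",
    "confidence_summary",
    "cost_contours",
    "contour_grid_from_cost",
    "sample_parameters",
]


@dataclass(frozen=True)
class ConfidenceSummary:
    """Per-parameter intervals and the 2-D confidence ellipse.

    ``bounded[name]`` is False when the covariance is numerically
    ill-conditioned or the interval spans the divergence cap — i.e. the
    interval carries no real information about that parameter.
    """

    level: float
    intervals: dict[str, tuple[float, float]]
    ellipse_center: np.ndarray
    ellipse_cov: np.ndarray
    ellipse_radius: float  # Mahalanobis radius sqrt(χ²₂ quantile)
    bounded: dict[str, bool]


def confidence_summary(
    result: CalibrationResult,
    level: float = 0.95,
    quantile: str = "t",
    cond_cap: float = 1e10,
    divergence_cap: float = 1e3,
) -> ConfidenceSummary:
    """Confidence intervals and ellipse for a converged fit.

    Intervals are estimate ± q · sqrt(diag Σ).  The default quantile is
    Student's t with N − p degrees of freedom: calibration windows here hold
    on the order of ten points, where the normal quantile measurably
    undercovers; ``quantile="z"`` gives the large-sample normal version.
    The ellipse covers the first two free parameters at the joint χ²(2)
    level.
    """
    if result.covariance is None or not np.all(np.isfinite(result.covariance)):
        raise ValueError("calibration result carries no finite covariance")
    cov = result.covariance
    names = result.free_names
    if quantile == "t":
        dof = max(result.n_points - len(names), 1)
        z = stats.t.ppf(0.5 + level / 2, df=dof)
    elif quantile == "z":
        z = stats.norm.ppf(0.5 + level / 2)
    else:
        raise ValueError(f"unknown quantile rule {quantile!r}")
    sd = np.sqrt(np.maximum(np.diag(cov), 0.0))
    est = np.array([result.estimates[n] for n in names])
    cond = np.linalg.cond(cov)
    intervals = {}
    bounded = {}
    for i, name in enumerate(names):
        lo, hi = est[i] - z * sd[i], est[i] + z * sd[i]
        intervals[name] = (float(lo), float(hi))
        bounded[name] = bool(
            cond < cond_cap and hi - lo < 2 * divergence_cap and np.isfinite(lo) and np.isfinite(hi)
        )
    k = min(2, len(names))
    radius = float(np.sqrt(stats.chi2.ppf(level, df=2)))
    return ConfidenceSummary(
        level=level,
        intervals=intervals,
        ellipse_center=est[:k],
        ellipse_cov=cov[:k, :k],
        ellipse_radius=radius,
        bounded=bounded,
    )


@dataclass(frozen=True)
class ContourGrid:
    """Cost surface over a parameter pair with a boundedness verdict.

    ``bounded_along`` maps each axis name to whether the sublevel set at
    ``threshold`` stays off the grid boundary in that direction.
    """

    names: tuple[str, str]
    grid_x: np.ndarray
    grid_y: np.ndarray
    cost: np.ndarray  # shape (len(grid_y), len(grid_x))
    threshold: float
    bounded_along: dict[str, bool]


def contour_grid_from_cost(
    cost_fn,
    names: tuple[str, str],
    centers: tuple[float, float],
    half_spans: tuple[float, float],
    threshold: float,
    n_grid: int = 41,
    lower_limits: tuple[float, float] = (-np.inf, -np.inf),
) -> ContourGrid:
    """Evaluate ``cost_fn(x, y)`` on a rectangular grid and classify the
    sublevel set {cost ≤ threshold} as bounded/unbounded per axis by whether
    it touches the grid boundary there.  ``lower_limits`` clip the grid to
    the cost function's validity region (e.g. α > −1, K_p > 0)."""
    gx = np.linspace(max(centers[0] - half_spans[0], lower_limits[0]),
                     centers[0] + half_spans[0], n_grid)
    gy = np.linspace(max(centers[1] - half_spans[1], lower_limits[1]),
                     centers[1] + half_spans[1], n_grid)
    cost = np.empty((n_grid, n_grid))
    for j, y in enumerate(gy):
        for i, x in enumerate(gx):
            cost[j, i] = cost_fn(x, y)
    sub = cost <= threshold
    bounded_x = not (np.any(sub[:, 0]) or np.any(sub[:, -1]))
    bounded_y = not (np.any(sub[0, :]) or np.any(sub[-1, :]))
    return ContourGrid(
        names=names,
        grid_x=gx,
        grid_y=gy,
        cost=cost,
        threshold=threshold,
        bounded_along={names[0]: bounded_x, names[1]: bounded_y},
    )


def cost_contours(
    record: SubjectRecord,
    result: CalibrationResult,
    pair: tuple[str, str] = ("alpha_v", "k_p"),
    n_grid: int = 41,
    extent_sd: float = 6.0,
) -> ContourGrid:
    """Sum-of-squares cost over a parameter pair, others held at estimates.

    The grid spans ±``extent_sd`` posterior standard deviations around the
    estimate (floored at half the estimate's magnitude so flat directions
    still get a meaningful sweep); the verdict threshold is the optimal SSR
    inflated by the asymptotic 2-parameter factor 1 + 2/(N − p).
    """
    names = result.free_names
    for p_name in pair:
        if p_name not in names and not (p_name == "alpha_u" and result.fixed_alpha_u is not None):
            raise ValueError(f"parameter {p_name!r} not available in this fit")
    full = {**result.estimates}
    if result.fixed_alpha_u is not None:
        full["alpha_u"] = result.fixed_alpha_u
    floor = residual_floor(record, result.window)
    p = len(names)
    threshold = result.ssr * (1.0 + 2.0 / max(result.n_points - p, 1))

    sd = {}
    for i, n in enumerate(names):
        sd[n] = float(np.sqrt(max(result.covariance[i, i], 0.0)))
    if result.fixed_alpha_u is not None:
        sd["alpha_u"] = 0.0

    def span(name):
        s = extent_sd * sd.get(name, 0.0)
        base = max(0.5 * abs(full[name]), 0.25)
        return min(max(s, base), 50.0)  # cap keeps flat directions on a finite sweep

    def cost_fn(x, y):
        params = dict(full)
        params[pair[0]] = x
        params[pair[1]] = y
        if result.fixed_alpha_u is not None and "alpha_u" not in pair:
            fix = result.fixed_alpha_u
            free = np.array([params["alpha_v"], params["k_p"]])
        else:
            fix = None
            free = np.array([params["alpha_u"], params["alpha_v"], params["k_p"]])
        res = _guarded_residual(free, record, result.window, floor, fix)
        return float(res @ res)

    limits = {"alpha_u": -1.0 + 1e-6, "alpha_v": -1.0 + 1e-6, "k_p": 1e-6}
    return contour_grid_from_cost(
        cost_fn,
        names=pair,
        centers=(full[pair[0]], full[pair[1]]),
        half_spans=(span(pair[0]), span(pair[1])),
        threshold=threshold,
        n_grid=n_grid,
        lower_limits=(limits[pair[0]], limits[pair[1]]),
    )


@dataclass(frozen=True)
class ParameterDraws:
    """Monte-Carlo parameter sample for uncertainty propagation.

    ``draws`` holds retained full parameter triples (α_u, α_v, K_p), with the
    fixed α_u replicated when the fit held it constant.  The exclusion report
    separates the K_p ≤ 0 rule (implausible physiology) from the 1+α_v ≤ 0
    rule (unsimulable), so the former can be applied alone.
    """

    draws: np.ndarray  # (n_retained, 3)
    n_requested: int
    n_excluded_k_p: int
    n_excluded_alpha_v: int

    @property
    def exclusion_fraction(self) -> float:
        return (self.n_requested - self.draws.shape[0]) / self.n_requested


def sample_parameters(
    result: CalibrationResult,
    n: int = 10_000,
    rng: np.random.Generator | int = 0,
    apply_alpha_rule: bool = True,
) -> ParameterDraws:
    """Draw parameters from N(P*, Σ) and drop implausible draws.

    Draws with K_p ≤ 0 are excluded (no physical fluid shift); with
    ``apply_alpha_rule`` (default) draws with 1+α_v ≤ 0 are also excluded
    since the model cannot be simulated there.  A covariance that is not
    positive semidefinite is repaired to the nearest PSD matrix (eigenvalue
    clipping) with a warning.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    names = result.free_names
    mean = np.array([result.estimates[nm] for nm in names])
    cov = np.array(result.covariance, dtype=float)
    if not np.all(np.isfinite(cov)):
        raise ValueError("covariance contains non-finite entries")
    eigval = np.linalg.eigvalsh(cov)
    if eigval.min() < -1e-12 * max(eigval.max(), 1.0):
        warnings.warn("covariance not PSD; clipping negative eigenvalues")
        w, v = np.linalg.eigh(cov)
        cov = (v * np.clip(w, 0.0, None)) @ v.T
    # PSD is checked/repaired above; numpy's own validity warning only
    # re-reports round-off asymmetry
    free = rng.multivariate_normal(mean, cov, size=n, method="svd", check_valid="ignore")
    cols = {nm: free[:, i] for i, nm in enumerate(names)}
    alpha_u = cols.get("alpha_u", np.full(n, result.fixed_alpha_u))
    alpha_v = cols["alpha_v"]
    k_p = cols["k_p"]
    bad_kp = k_p <= 0
    bad_av = (1.0 + alpha_v <= 0) if apply_alpha_rule else np.zeros(n, dtype=bool)
    keep = ~(bad_kp | bad_av) & (1.0 + alpha_u > 0)
    draws = np.column_stack([alpha_u, alpha_v, k_p])[keep]
    return ParameterDraws(
        draws=draws,
        n_requested=n,
        n_excluded_k_p=int(np.count_nonzero(bad_kp)),
        n_excluded_alpha_v=int(np.count_nonzero(bad_av & ~bad_kp)),
    )
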