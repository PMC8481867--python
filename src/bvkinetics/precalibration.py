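"""Pre-calibration data-quality analysis and calibration-window selection.

The BV kinetics model can be rewritten as a linear regression by moving the
measured signals to one side:

    ΔV̈_B(t_i) − [U̇(t_i) − V̇(t_i)]
        = [K_p/(1+α_u), K_p/(1+α_v), K_p] · [U(t_i), −V(t_i), −ΔV̇_B(t_i)]ᵀ,

so the information the data carry about the transfer coefficients
θ = (K_p/(1+α_u), K_p/(1+α_v), K_p) is summarized by the singular value
decomposition of the N×3 design matrix.  A small singular value whose
principal direction aligns with one θ-axis flags that parameter as poorly
constrained by the candidate calibration window.  Profiling the singular
values over nested windows [0, T_c] guides the split of each record into a
calibration window and an independent validation window.

Derivatives of the measured ΔV_B are not observed; they are estimated with a
cubic smoothing spline (penalty chosen by generalized cross-validation) or,
as a diagnostic alternative, central finite differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline, make_smoothing_spline

from .cohort import SubjectRecord
from .model import InputProtocol

__all__ = [
    "AXES",
    "assign_axes",
    "RegressorSystem",
    "SVDProfile",
    "WindowSelection",
    "estimate_derivatives",
    "build_regressor",
    "svd_profile",
    "select_window",
]

# θ-axis labels, in design-matrix column order
AXES = ("zero_u", "zero_v", "pole")  # K_p/(1+α_u), K_p/(1+α_v), K_p


def estimate_derivatives(
    record: SubjectRecord,
    method: str = "spline",
    smoothing: float | str | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Estimate ΔV̇_B and ΔV̈_B on the measurement grid.

    ``method="spline"`` fits cubic splines *piecewise between protocol
    breakpoints* — ΔV̇_B is discontinuous wherever an input rate switches, so
    smoothing across a breakpoint would contaminate both derivatives on
    either side.  Within a stretch the trajectory is smooth (exponential
    plus affine).  ``smoothing=None`` interpolates (exact for noise-free
    data); ``smoothing="gcv"`` selects a penalty per stretch by generalized
    cross-validation; a float fixes the penalty.  Stretches with fewer than
    four interior-or-boundary samples fall back to polynomial fits of
    matching degree.  ``method="finite_difference"`` applies central
    differences twice, ignoring breakpoints (diagnostic alternative).
    """
    t = record.measurement_times
    y = record.measured_delta_vb
    if t.size < 5:
        raise ValueError("need at least 5 samples to estimate second derivatives")
    if method == "finite_difference":
        d1 = np.gradient(y, t)
        return d1, np.gradient(d1, t)
    if method != "spline":
        raise ValueError(f"unknown derivative method {method!r}")
    bp = np.unique(record.protocol.breakpoints)
    d1 = np.full_like(t, np.nan)
    d2 = np.full_like(t, np.nan)
    for a, b in zip(bp[:-1], bp[1:]):
        sel = (t >= a - 1e-9) & (t <= b + 1e-9)
        ts, ys = t[sel], y[sel]
        n = ts.size
        if n == 0:
            continue
        if n == 1:
            d1[sel], d2[sel] = 0.0, 0.0
        elif n < 4:
            coef = np.polyfit(ts, ys, n - 1)
            d1[sel] = np.polyval(np.polyder(coef, 1), ts)
            d2[sel] = np.polyval(np.polyder(coef, 2), ts) if n > 2 else 0.0
        elif smoothing is None or n == 4:
            spl = CubicSpline(ts, ys)
            d1[sel] = spl(ts, 1)
            d2[sel] = spl(ts, 2)
        else:
            lam = None if smoothing == "gcv" else float(smoothing)
            spl = make_smoothing_spline(ts, ys, lam=lam)
            d1[sel] = spl.derivative(1)(ts)
            d2[sel] = spl.derivative(2)(ts)
    return d1, d2


@dataclass(frozen=True)
class RegressorSystem:
    """Linear-regression form of the model over one candidate window.

    ``design`` rows are [U(t_i), −V(t_i), −ΔV̇_B(t_i)]; ``response`` is
    ΔV̈_B(t_i) − [U̇ − V̇](t_i); the parameter vector the system targets is
    θ = (K_p/(1+α_u), K_p/(1+α_v), K_p).  Samples lying exactly on protocol
    breakpoints are excluded (U̇ − V̇ is impulsive there); within segments
    U̇ − V̇ = 0.
    """

    times: np.ndarray
    design: np.ndarray
    response: np.ndarray

    @property
    def n(self) -> int:
        return self.design.shape[0]

    def solve(self) -> np.ndarray:
        """Least-squares θ estimate (diagnostic; calibration proper uses the
        nonlinear proportional-error fit)."""
        theta, *_ = np.linalg.lstsq(self.design, self.response, rcond=None)
        return theta


def build_regressor(
    record: SubjectRecord,
    t_c: float,
    derivatives: tuple[np.ndarray, np.ndarray] | None = None,
    breakpoint_tol: float = 1e-9,
) -> RegressorSystem:
    """Assemble the regression system from samples with 0 < t_i ≤ T_c.

    ``derivatives`` should be shared across windows (estimated once on the
    full record) so that nested windows yield nested row sets; if ``None``
    they are estimated here with the default spline method.
    """
    if t_c > record.protocol.t_final + 1e-9:
        raise ValueError(f"T_c={t_c} exceeds protocol end {record.protocol.t_final}")
    d1, d2 = derivatives if derivatives is not None else estimate_derivatives(record)
    t = record.measurement_times
    bp = record.protocol.breakpoints
    on_break = np.min(np.abs(t[:, None] - bp[None, :]), axis=1) <= breakpoint_tol
    keep = (t <= t_c + 1e-9) & ~on_break
    if not np.any(keep):
        raise ValueError(f"no usable samples in window (0, {t_c}]")
    u, v = record.protocol.rates_at(t[keep])
    design = np.column_stack([u, -v, -d1[keep]])
    response = d2[keep]  # U̇−V̇ ≡ 0 away from breakpoints
    return RegressorSystem(times=t[keep], design=design, response=response)


def assign_axes(
    vt: np.ndarray, alignment_threshold: float = 0.8
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assign each right singular vector (row of ``vt``) to a θ-axis.

    Each direction takes the axis with the largest absolute component; if
    that axis is already claimed or the component falls below
    ``alignment_threshold`` the direction is flagged mixed and takes the
    best unclaimed axis, so all three axes are always covered.  Returns
    (axis labels, alignment magnitudes, mixed flags).
    """
    axes = np.empty(3, dtype=object)
    alignment = np.zeros(3)
    mixed = np.zeros(3, dtype=bool)
    taken: set[int] = set()
    for k in range(3):
        comp = np.abs(vt[k])
        axis_idx = int(np.argmax(comp))
        alignment[k] = comp[axis_idx]
        if axis_idx in taken or comp[axis_idx] < alignment_threshold:
            mixed[k] = True
            order = np.argsort(comp)[::-1]
            axis_idx = next(int(j) for j in order if int(j) not in taken)
        taken.add(axis_idx)
        axes[k] = AXES[axis_idx]
    return axes, alignment, mixed


@dataclass(frozen=True)
class SVDProfile:
    """Singular-value profile of one subject's design matrix over a T_c grid.

    For each window, each singular value is assigned to the θ-axis on which
    its right singular vector has the largest absolute component;
    ``alignment`` records that component and ``mixed`` flags directions whose
    alignment falls below the threshold (the direction is not axis-pure).
    """

    subject_id: str
    t_c_grid: np.ndarray
    sigmas: np.ndarray  # (n_windows, 3), descending per row
    axes: np.ndarray  # (n_windows, 3) of AXES labels
    alignment: np.ndarray  # (n_windows, 3)
    mixed: np.ndarray  # (n_windows, 3) bool

    def sigma_for_axis(self, axis: str) -> np.ndarray:
        """Singular value assigned to ``axis`` at each window (NaN if that
        axis captured no direction)."""
        out = np.full(self.t_c_grid.shape, np.nan)
        for i in range(self.t_c_grid.size):
            hit = np.flatnonzero(self.axes[i] == axis)
            if hit.size:
                out[i] = self.sigmas[i, hit[0]]
        return out


def svd_profile(
    record: SubjectRecord,
    t_c_grid: np.ndarray,
    derivatives: tuple[np.ndarray, np.ndarray] | None = None,
    alignment_threshold: float = 0.8,
) -> SVDProfile:
    """SVD of the design matrix over nested candidate windows.

    Columns are not normalized: raw singular values are compared across
    windows, and nesting guarantees they are non-decreasing in T_c.
    """
    grid = np.sort(np.asarray(t_c_grid, dtype=float))
    if grid.size == 0:
        raise ValueError("empty T_c grid")
    if derivatives is None:
        derivatives = estimate_derivatives(record)
    sigmas = np.zeros((grid.size, 3))
    axes = np.empty((grid.size, 3), dtype=object)
    alignment = np.zeros((grid.size, 3))
    mixed = np.zeros((grid.size, 3), dtype=bool)
    for i, t_c in enumerate(grid):
        system = build_regressor(record, t_c, derivatives)
        _, s, vt = np.linalg.svd(system.design, full_matrices=False)
        sigmas[i] = np.pad(s, (0, 3 - s.size))
        vt = np.pad(vt, ((0, 3 - vt.shape[0]), (0, 0)))
        axes[i], alignment[i], mixed[i] = assign_axes(vt, alignment_threshold)
    return SVDProfile(
        subject_id=record.subject_id,
        t_c_grid=grid,
        sigmas=sigmas,
        axes=axes,
        alignment=alignment,
        mixed=mixed,
    )


@dataclass(frozen=True)
class WindowSelection:
    """Chosen calibration window T_c with its rationale flags."""

    t_c: float
    contains_hemorrhage: bool
    contains_infusion: bool
    singular_value_threshold_met: bool
    validation_contains_hemorrhage: bool
    warnings: tuple[str, ...] = field(default_factory=tuple)


def _events(protocol: InputProtocol, which: str) -> list[tuple[float, float]]:
    idx = 2 if which == "infusion" else 3
    events = []
    for t0, t1, *rates in protocol.segments:
        if rates[idx - 2] > 0:
            if events and events[-1][1] == t0:
                events[-1] = (events[-1][0], t1)
            else:
                events.append((t0, t1))
    return events


def select_window(
    profiles: list[SVDProfile],
    protocol: InputProtocol,
    threshold_fraction: float = 0.5,
    majority: float = 0.5,
) -> WindowSelection:
    """Select the calibration window T_c from cohort SVD profiles.

    Picks the smallest grid value such that (i) [0, T_c] overlaps at least
    one hemorrhage and one infusion event, (ii) for more than ``majority`` of
    subjects every singular value is at least ``threshold_fraction`` of its
    value at the final grid point ("relatively large"), and (iii) the
    validation window (T_c, t_final] still contains a hemorrhage event, so
    the model is validated against inputs unseen in calibration.  If no
    window satisfies all three, the largest T_c meeting (i)–(ii) is returned
    with a warning.
    """
    if not profiles:
        raise ValueError("no SVD profiles supplied")
    grid = profiles[0].t_c_grid
    for p in profiles[1:]:
        if not np.array_equal(p.t_c_grid, grid):
            raise ValueError("profiles must share a common T_c grid")
    hem = _events(protocol, "hemorrhage")
    inf = _events(protocol, "infusion")

    def overlaps(events, lo, hi):
        return any(t0 < hi and t1 > lo for t0, t1 in events)

    sig = np.stack([p.sigmas for p in profiles])  # (n_subj, n_grid, 3)
    final = sig[:, -1:, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        ok = np.all(sig >= threshold_fraction * final, axis=2)  # (n_subj, n_grid)
    frac_ok = ok.mean(axis=0)

    candidates = []
    for i, t_c in enumerate(grid):
        c1 = overlaps(hem, 0.0, t_c) and overlaps(inf, 0.0, t_c)
        c2 = frac_ok[i] > majority
        c3 = overlaps(hem, t_c, protocol.t_final)
        candidates.append((t_c, c1, c2, c3))
    if not any(c1 for _, c1, _, _ in candidates):
        raise ValueError(
            "no candidate window contains both a hemorrhage and an infusion event"
        )
    for t_c, c1, c2, c3 in candidates:
        if c1 and c2 and c3:
            return WindowSelection(
                t_c=float(t_c),
                contains_hemorrhage=True,
                contains_infusion=True,
                singular_value_threshold_met=True,
                validation_contains_hemorrhage=True,
            )
    fallback = [(t_c, c3) for t_c, c1, c2, c3 in candidates if c1 and c2]
    if fallback:
        t_c, c3 = fallback[-1]
        msg = (
            "no window meets the singular-value threshold while leaving a "
            "hemorrhage event for validation; using the largest window that "
            "meets criteria (i)-(ii)"
        )
    else:
        # not even (ii): fall back to the smallest window with both events
        t_c, c3 = next((t_c, c3) for t_c, c1, c2, c3 in candidates if c1)
        msg = (
            "no window meets the singular-value threshold; using the smallest "
            "window containing both event types"
        )
    warnings.warn(msg)
    return WindowSelection(
        t_c=float(t_c),
        contains_hemorrhage=True,
        contains_infusion=True,
        singular_value_threshold_met=bool(fallback),
        validation_contains_hemorrhage=bool(c3),
        warnings=(msg,),
    )
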