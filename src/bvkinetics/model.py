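"""Two-compartment blood-volume (BV) kinetics model.

The model describes the change in intravascular blood volume ``ΔV_B(t)`` (mL,
relative to normovolemic baseline) of a subject undergoing controlled
hemorrhage at rate ``V(t)`` and crystalloid fluid infusion at rate ``U(t)``
(both mL/min).  Infused fluid distributes between the intravascular and
interstitial compartments with gain ratio ``α_u``; lost volume is drawn from
both compartments with loss ratio ``α_v``; fluid shifts between the
compartments at rate constant ``K_p`` (1/min).  The governing equation is
second order,

    ΔV̈_B + K_p ΔV̇_B = [U̇ − V̇] + K_p U/(1+α_u) − K_p V/(1+α_v),

which this module integrates through the equivalent first-order realization

    ΔV̇_B = U(t) − V(t) − K_p [ΔV_B − x_T(t)],
    x_T(t) = (1+α_u)⁻¹ ∫₀ᵗ U − (1+α_v)⁻¹ ∫₀ᵗ V,

(differentiating the first-order form and substituting ẋ_T recovers the
second-order equation; it also fixes the initial conditions ΔV_B(0) = 0 and
ΔV̇_B(0) = U(0) − V(0)).  For piecewise-constant input rates every segment is
a linear ODE with affine forcing and is solved in closed form; a generic
adaptive integrator is provided as an independent cross-check.

The model is globally structurally identifiable: its transfer function has a
single pole ``K_p`` and input-channel gains ``K_p/(1+α_u)``, ``K_p/(1+α_v)``,
an invertible reparametrization implemented by
:func:`to_transfer_coeffs` / :func:`from_transfer_coeffs`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "ModelParams",
    "InputProtocol",
    "Trajectory",
    "TransferCoeffs",
    "simulate",
    "simulate_ensemble",
    "simulate_ivp",
    "steady_state",
    "to_transfer_coeffs",
    "from_transfer_coeffs",
    "delta_vb_from_hematocrit",
]


@dataclass(frozen=True)
class ModelParams:
    """Subject-specific parameter triple.

    alpha_u
        Ratio of volume gain between intravascular and interstitial
        compartments (dimensionless); a fraction 1/(1+α_u) of infused fluid
        is retained intravascularly at steady state.
    alpha_v
        Ratio of volume loss between the compartments (dimensionless).
    k_p
        Rate constant of fluid shift between compartments, 1/min.
    """

    alpha_u: float
    alpha_v: float
    k_p: float

    def __post_init__(self) -> None:
        if not self.k_p > 0:
            raise ValueError(f"k_p must be positive, got {self.k_p}")
        if not self.alpha_u > -1:
            raise ValueError(f"alpha_u must exceed -1, got {self.alpha_u}")
        if not self.alpha_v > -1:
            raise ValueError(f"alpha_v must exceed -1, got {self.alpha_v}")

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha_u, self.alpha_v, self.k_p])


@dataclass(frozen=True)
class TransferCoeffs:
    """Transfer-function coefficients of the model: pole ``K_p`` and the two
    input-channel zeros ``K_p/(1+α_u)``, ``K_p/(1+α_v)`` (all 1/min).

    The map from :class:`ModelParams` is a bijection for ``pole > 0``, which
    is the executable statement of the model's global structural
    identifiability.
    """

    pole: float
    zero_u: float
    zero_v: float


@dataclass(frozen=True)
class InputProtocol:
    """Piecewise-constant infusion/hemorrhage schedule on [0, t_final].

    ``segments`` is an ordered list of ``(t_start, t_end, infusion_rate,
    hemorrhage_rate)`` with times in minutes and rates in mL/min.  Segments
    must be contiguous, non-overlapping and cover ``[0, t_final]``; rates are
    non-negative, so cumulative volumes are piecewise-linear non-decreasing.
    """

    segments: tuple[tuple[float, float, float, float], ...]
    t_final: float = field(init=False)

    def __init__(self, segments: Sequence[Sequence[float]]):
        segs = tuple(tuple(float(x) for x in s) for s in segments)
        if not segs:
            raise ValueError("protocol needs at least one segment")
        if segs[0][0] != 0.0:
            raise ValueError("first segment must start at t=0")
        for (a0, a1, u, v), nxt in zip(segs, segs[1:] + (None,)):
            if not a1 > a0:
                raise ValueError(f"segment ({a0}, {a1}) has non-positive length")
            if u < 0 or v < 0:
                raise ValueError("rates must be non-negative")
            if nxt is not None and nxt[0] != a1:
                raise ValueError(
                    f"segments not contiguous: gap/overlap at t={a1} vs t={nxt[0]}"
                )
        object.__setattr__(self, "segments", segs)
        object.__setattr__(self, "t_final", segs[-1][1])

    # -- convenience constructors -------------------------------------------------

    @classmethod
    def from_schedules(
        cls,
        infusion: Sequence[tuple[float, float, float]],
        hemorrhage: Sequence[tuple[float, float, float]],
        t_final: float,
    ) -> "InputProtocol":
        """Merge separate ``(t0, t1, rate)`` infusion and hemorrhage schedules
        (zero rate outside the listed intervals) into a single protocol."""
        cuts = {0.0, float(t_final)}
        for t0, t1, _ in list(infusion) + list(hemorrhage):
            if not (0 <= t0 < t1 <= t_final):
                raise ValueError(f"schedule interval ({t0}, {t1}) outside [0, {t_final}]")
            cuts.update((float(t0), float(t1)))
        ts = sorted(cuts)

        def rate_at(schedule, t):
            for t0, t1, r in schedule:
                if t0 <= t < t1:
                    return float(r)
            return 0.0

        segs = []
        for a, b in zip(ts[:-1], ts[1:]):
            segs.append((a, b, rate_at(infusion, a), rate_at(hemorrhage, a)))
        return cls(segs)

    # -- queries ------------------------------------------------------------------

    @property
    def breakpoints(self) -> np.ndarray:
        """All segment boundary times, including 0 and t_final."""
        return np.array([s[0] for s in self.segments] + [self.t_final])

    def rates_at(self, t: np.ndarray | float) -> tuple[np.ndarray, np.ndarray]:
        """Infusion and hemorrhage rates at times ``t`` (right-continuous;
        the closing boundary takes the last segment's rates)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        starts = np.array([s[0] for s in self.segments])
        idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, len(self.segments) - 1)
        u = np.array([self.segments[i][2] for i in idx])
        v = np.array([self.segments[i][3] for i in idx])
        return u, v

    def cumulative(self, t: np.ndarray | float) -> tuple[np.ndarray, np.ndarray]:
        """Cumulative infused and hemorrhaged volumes ∫₀ᵗU, ∫₀ᵗV (mL)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        cum_u = np.zeros_like(t)
        cum_v = np.zeros_like(t)
        for t0, t1, u, v in self.segments:
            inside = np.clip(t, t0, t1) - t0
            cum_u += u * inside
            cum_v += v * inside
        return cum_u, cum_v

    @property
    def total_infused(self) -> float:
        return sum(u * (t1 - t0) for t0, t1, u, _ in self.segments)

    @property
    def total_hemorrhaged(self) -> float:
        return sum(v * (t1 - t0) for t0, t1, _, v in self.segments)


@dataclass(frozen=True)
class Trajectory:
    """A simulated or measured BV time course.

    times are strictly increasing minutes; ``delta_vb`` is the BV change from
    baseline (mL), zero at t=0 for simulated courses; ``d_delta_vb`` optionally
    carries the first derivative (mL/min).
    """

    times: np.ndarray
    delta_vb: np.ndarray
    d_delta_vb: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be 1-D strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "delta_vb", np.asarray(self.delta_vb, dtype=float))
        if self.d_delta_vb is not None:
            object.__setattr__(self, "d_delta_vb", np.asarray(self.d_delta_vb, dtype=float))


# ---------------------------------------------------------------------------
# forward simulation
# ---------------------------------------------------------------------------


def _check_times(times: np.ndarray, protocol: InputProtocol) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.size and (times.min() < 0 or times.max() > protocol.t_final + 1e-9):
        raise ValueError(
            f"times must lie within [0, {protocol.t_final}], got "
            f"[{times.min()}, {times.max()}]"
        )
    return times


def simulate_ensemble(
    params: np.ndarray, protocol: InputProtocol, times: np.ndarray
) -> np.ndarray:
    """Closed-form simulation vectorized over a set of parameter triples.

    ``params`` is an ``(n, 3)`` array of rows ``(α_u, α_v, K_p)``; returns an
    ``(n, len(times))`` array of ΔV_B trajectories.  Used for Monte-Carlo
    uncertainty propagation where n may be 10,000.
    """
    params = np.atleast_2d(np.asarray(params, dtype=float))
    times = _check_times(times, protocol)
    au, av, kp = params[:, 0], params[:, 1], params[:, 2]
    if np.any(kp <= 0) or np.any(au <= -1) or np.any(av <= -1):
        raise ValueError("invalid parameters: require k_p > 0 and 1+α > 0")
    inv_u = 1.0 / (1.0 + au)  # (n,)
    inv_v = 1.0 / (1.0 + av)

    out = np.empty((params.shape[0], times.size))
    y0 = np.zeros(params.shape[0])  # state at segment start
    cum_u = cum_v = 0.0
    for t0, t1, u, v in protocol.segments:
        # y' = -K_p y + b0 + b1 s on s = t - t0
        a0 = cum_u * inv_u - cum_v * inv_v  # fluid-shift target at segment start
        m = u * inv_u - v * inv_v
        b0 = (u - v) + kp * a0
        b1 = kp * m
        # particular affine solution y_p(s) = (b0/k - b1/k^2) + (b1/k) s
        c0 = b0 / kp - b1 / kp**2
        c1 = b1 / kp
        amp = y0 - c0
        last = t1 >= protocol.t_final
        sel = (times >= t0) & ((times <= t1) if last else (times < t1))
        if np.any(sel):
            s = times[sel] - t0
            out[:, sel] = amp[:, None] * np.exp(-kp[:, None] * s[None, :]) + c0[:, None] + c1[:, None] * s[None, :]
        s_end = t1 - t0
        y0 = amp * np.exp(-kp * s_end) + c0 + c1 * s_end
        cum_u += u * s_end
        cum_v += v * s_end
    return out


def simulate(
    params: ModelParams, protocol: InputProtocol, times: np.ndarray
) -> Trajectory:
    """Exact forward simulation of ΔV_B on ``times`` (reference solver).

    Solves the first-order realization segment by segment in closed form
    (each segment is a linear ODE with affine forcing), so the only numerical
    error is floating-point round-off.  Also returns the exact first
    derivative ΔV̇_B = U − V − K_p(ΔV_B − x_T).
    """
    times = _check_times(np.asarray(times, dtype=float), protocol)
    y = simulate_ensemble(params.as_array()[None, :], protocol, times)[0]
    u, v = protocol.rates_at(times)
    cu, cv = protocol.cumulative(times)
    x_t = cu / (1.0 + params.alpha_u) - cv / (1.0 + params.alpha_v)
    dy = u - v - params.k_p * (y - x_t)
    return Trajectory(times=times, delta_vb=y, d_delta_vb=dy)


def simulate_ivp(
    params: ModelParams,
    protocol: InputProtocol,
    times: np.ndarray,
    rtol: float = 1e-10,
    atol: float = 1e-10,
) -> Trajectory:
    """Generic adaptive-integrator simulation (cross-check path).

    Integrates the first-order realization segment by segment with
    ``scipy.integrate.solve_ivp`` so rate discontinuities fall on integration
    boundaries.  Exists to verify the closed-form solver independently; the
    closed form is the reference used everywhere else.
    """
    times = _check_times(np.asarray(times, dtype=float), protocol)
    inv_u = 1.0 / (1.0 + params.alpha_u)
    inv_v = 1.0 / (1.0 + params.alpha_v)
    kp = params.k_p
    out = np.empty_like(times)
    y0 = 0.0
    cum_u = cum_v = 0.0
    for t0, t1, u, v in protocol.segments:
        a0 = cum_u * inv_u - cum_v * inv_v
        m = u * inv_u - v * inv_v

        def rhs(s, y, u=u, v=v, a0=a0, m=m):
            return u - v - kp * (y[0] - (a0 + m * s))

        last = t1 >= protocol.t_final
        sel = (times >= t0) & ((times <= t1) if last else (times < t1))
        t_eval = times[sel] - t0
        sol = solve_ivp(
            rhs,
            (0.0, t1 - t0),
            [y0],
            t_eval=np.concatenate([t_eval, [t1 - t0]]) if (t_eval.size == 0 or t_eval[-1] < t1 - t0) else t_eval,
            rtol=rtol,
            atol=atol,
            method="RK45",
            max_step=(t1 - t0),
        )
        if not sol.success:
            raise RuntimeError(f"integration failed on segment ({t0}, {t1}): {sol.message}")
        out[sel] = sol.y[0, : t_eval.size]
        y0 = sol.y[0, -1]
        cum_u += u * (t1 - t0)
        cum_v += v * (t1 - t0)
    return Trajectory(times=times, delta_vb=out)


def steady_state(
    params: ModelParams, total_infused: float, total_hemorrhaged: float
) -> float:
    """Long-time ΔV_B limit after all inputs cease (mL).

    Once infusion and hemorrhage stop, ΔV_B relaxes exponentially (rate K_p)
    to total_infused/(1+α_u) − total_hemorrhaged/(1+α_v).
    """
    return total_infused / (1.0 + params.alpha_u) - total_hemorrhaged / (1.0 + params.alpha_v)


# ---------------------------------------------------------------------------
# structural identifiability: transfer-coefficient bijection
# ---------------------------------------------------------------------------


def to_transfer_coeffs(params: ModelParams) -> TransferCoeffs:
    """Map (α_u, α_v, K_p) to the transfer-function coefficients
    (pole, zero_u, zero_v) = (K_p, K_p/(1+α_u), K_p/(1+α_v))."""
    return TransferCoeffs(
        pole=params.k_p,
        zero_u=params.k_p / (1.0 + params.alpha_u),
        zero_v=params.k_p / (1.0 + params.alpha_v),
    )


def from_transfer_coeffs(coeffs: TransferCoeffs) -> ModelParams:
    """Invert :func:`to_transfer_coeffs`; unique for pole > 0.

    A zero equal to 0 corresponds to α = ∞ (no volume retained in the
    respective channel); the returned parameter is ``inf`` in that limit.
    Negative zeros (α < −1) are rejected.
    """
    if not coeffs.pole > 0:
        raise ValueError(f"pole must be positive, got {coeffs.pole}")
    if coeffs.zero_u < 0 or coeffs.zero_v < 0:
        raise ValueError("zeros must be non-negative")
    alpha_u = coeffs.pole / coeffs.zero_u - 1.0 if coeffs.zero_u > 0 else np.inf
    alpha_v = coeffs.pole / coeffs.zero_v - 1.0 if coeffs.zero_v > 0 else np.inf
    return ModelParams(alpha_u=alpha_u, alpha_v=alpha_v, k_p=coeffs.pole)


def delta_vb_from_hematocrit(bv0: float, hct0: float, hct_t: float) -> float:
    """BV change inferred from hematocrit under constant red-cell volume.

    With red-cell volume fixed, BV(t)·Hct(t) = BV₀·Hct₀, so
    ΔV_B(t) = BV₀·(Hct₀/Hct(t) − 1).
    """
    if not bv0 > 0:
        raise ValueError("baseline blood volume must be positive")
    for name, h in (("hct0", hct0), ("hct_t", hct_t)):
        if not 0 < h < 1:
            raise ValueError(f"{name} must lie in (0, 1), got {h}")
    return bv0 * (hct0 / hct_t - 1.0)
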