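"""Synthetic ovine cohort generator.

Builds virtual sheep with the protocol and noise structure of a controlled
hemorrhage / crystalloid-resuscitation experiment: a fixed weight-normalized
hemorrhage schedule (initial 25 mL/kg bleed over 15 min, two 5 mL/kg bleeds
at 50 and 70 min over 5 min each), subject-varying infusion schedules
starting 15 min after the initial bleed ends (t = 30 min) and running to
180 min, hematocrit-style BV-change measurements every 5–10 min, and
multiplicative (proportional) measurement noise.

Since every subject's true parameters are recorded, the cohort supports
parameter-recovery, coverage and validation studies for the downstream
calibration / UQ / validation stages.  Two "model-mismatch" perturbations can
be injected to emulate subjects whose physiology the model cannot represent
(an unmodelled compensatory refill, or a fluid-shift rate that differs
between net loss and net gain).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from .model import InputProtocol, ModelParams, simulate

__all__ = [
    "SubjectRecord",
    "CohortConfig",
    "ovine_hemorrhage_protocol",
    "sample_infusion_schedule",
    "generate_cohort",
    "inject_model_mismatch",
    "MISMATCH_KINDS",
]

STUDY_DURATION_MIN = 180.0
INFUSION_START_MIN = 30.0
HEMORRHAGE_ML_PER_KG = 35.0  # 25 + 5 + 5 mL/kg over the three bleeds


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's protocol and measured BV time series.

    ``true_params`` is known for synthetic subjects and ``None`` for real
    data.  ``mismatch_tag`` labels an injected model violation ("none" for a
    well-specified subject).  The first measurement is at t = 0 with value 0
    (baseline normovolemia).
    """

    subject_id: str
    weight_kg: float
    protocol: InputProtocol
    measurement_times: np.ndarray
    measured_delta_vb: np.ndarray
    true_params: ModelParams | None = None
    mismatch_tag: str = "none"
    mismatch_values: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.measurement_times, dtype=float)
        y = np.asarray(self.measured_delta_vb, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("measurement times/values must be matching 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("measurement times must be strictly increasing")
        if t[0] != 0.0 or y[0] != 0.0:
            raise ValueError("first measurement must be (t=0, ΔV_B=0)")
        if t[-1] > self.protocol.t_final + 1e-9:
            raise ValueError("measurements extend beyond the protocol")
        object.__setattr__(self, "measurement_times", t)
        object.__setattr__(self, "measured_delta_vb", y)

    @property
    def sampling_interval(self) -> float:
        """Median spacing between measurements (min)."""
        return float(np.median(np.diff(self.measurement_times)))


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for synthetic-cohort generation.

    Defaults emulate the animal study: 5-min sampling over 180 min,
    proportional measurement noise with sd 0.10 (calibration errors on the
    real data average ≈13%, so 10% generation noise is the realistic
    condition; the larger 0.2 constant is reserved for the experimental
    uncertainty band in validation), α_u centred on the literature nominal 3,
    and (α_v, K_p) log-uniform over the ranges spanned by calibrated sheep
    (α_v 0.35–3.20, K_p 0.07–0.27 1/min).
    """

    n_subjects: int = 20
    weight_range_kg: tuple[float, float] = (25.0, 45.0)
    alpha_u_nominal: float = 3.0
    alpha_u_log_sd: float = 0.2  # α_u = nominal · exp(N(0, sd))
    alpha_v_range: tuple[float, float] = (0.35, 3.20)
    k_p_range: tuple[float, float] = (0.07, 0.27)
    noise_sd: float = 0.10
    sampling_interval_min: float = 5.0
    sampling_jitter: bool = False  # jitter intervals uniformly over [5, 10] min
    infusion_family: str = "constant"  # constant | stepped | proportional-to-deficit
    infusion_total_ratio_range: tuple[float, float] = (0.5, 1.5)  # vs 35·w mL
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.infusion_family not in ("constant", "stepped", "proportional-to-deficit"):
            raise ValueError(f"unknown infusion family {self.infusion_family!r}")
        if not 0 < self.sampling_interval_min:
            raise ValueError("sampling interval must be positive")
        for name in ("weight_range_kg", "alpha_v_range", "k_p_range", "infusion_total_ratio_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ValueError(f"{name} must satisfy 0 < low <= high")


def ovine_hemorrhage_protocol(weight_kg: float) -> list[tuple[float, float, float]]:
    """Weight-normalized hemorrhage schedule as ``(t0, t1, rate mL/min)``.

    25 mL/kg withdrawn over [0, 15] min, then 5 mL/kg over [50, 55] and
    [70, 75] min; 35·weight mL total by t = 75.
    """
    if not weight_kg > 0:
        raise ValueError("weight must be positive")
    w = float(weight_kg)
    return [
        (0.0, 15.0, 25.0 * w / 15.0),
        (50.0, 55.0, 5.0 * w / 5.0),
        (70.0, 75.0, 5.0 * w / 5.0),
    ]


def sample_infusion_schedule(
    config: CohortConfig, weight_kg: float, rng: np.random.Generator
) -> list[tuple[float, float, float]]:
    """Draw one subject's infusion schedule as ``(t0, t1, rate mL/min)``.

    Infusion is zero before t = 30 min and piecewise-constant on
    [30, 180] min.  The total infused volume is a ratio of the 35·w mL
    hemorrhage drawn from ``infusion_total_ratio_range``, spanning under- to
    over-resuscitation.  Families:

    constant
        a single rate over the whole infusion period;
    stepped
        3–6 blocks with boundaries on multiples of the sampling interval and
        rates rescaled to the drawn total;
    proportional-to-deficit
        per-block rate proportional to the running volume deficit
        (cumulative hemorrhage − cumulative infusion), emulating
        deficit-driven resuscitation algorithms.
    """
    w = float(weight_kg)
    total = float(rng.uniform(*config.infusion_total_ratio_range)) * HEMORRHAGE_ML_PER_KG * w
    t0, t1 = INFUSION_START_MIN, STUDY_DURATION_MIN
    duration = t1 - t0
    if total <= 0:
        return []
    if config.infusion_family == "constant":
        return [(t0, t1, total / duration)]
    if config.infusion_family == "stepped":
        dt = config.sampling_interval_min
        n_edges = int(duration / dt)
        n_blocks = int(rng.integers(3, 7))
        edges = np.sort(rng.choice(np.arange(1, n_edges), size=n_blocks - 1, replace=False)) * dt + t0
        bounds = np.concatenate([[t0], edges, [t1]])
        raw = rng.uniform(0.2, 1.0, size=n_blocks)
        widths = np.diff(bounds)
        rates = raw * total / np.sum(raw * widths)
        return [(float(a), float(b), float(r)) for a, b, r in zip(bounds[:-1], bounds[1:], rates)]
    # proportional-to-deficit: per-block rate g·(cumulative hemorrhage − infused),
    # a discrete proportional controller; g spans sluggish to near-complete
    # replacement by 180 min.  Totals never exceed the hemorrhage volume.
    hem = ovine_hemorrhage_protocol(w)
    hem_protocol = InputProtocol.from_schedules([], hem, STUDY_DURATION_MIN)
    dt = config.sampling_interval_min
    bounds = np.arange(t0, t1 + 0.5 * dt, dt)
    g = float(np.exp(rng.uniform(np.log(0.005), np.log(0.05))))  # 1/min
    infused = 0.0
    segs: list[tuple[float, float, float]] = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        _, cum_v = hem_protocol.cumulative(a)
        deficit = max(float(cum_v[0]) - infused, 0.0)
        rate = g * deficit
        segs.append((float(a), float(b), rate))
        infused += rate * (b - a)
    return [s for s in segs if s[2] > 0]


def _measurement_times(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    if not config.sampling_jitter:
        return np.arange(0.0, STUDY_DURATION_MIN + 0.5 * config.sampling_interval_min,
                         config.sampling_interval_min)
    times = [0.0]
    while times[-1] < STUDY_DURATION_MIN:
        times.append(times[-1] + float(rng.uniform(5.0, 10.0)))
    times[-1] = min(times[-1], STUDY_DURATION_MIN)
    if times[-1] - times[-2] < 1.0:
        times.pop(-2)
    return np.array(times)


def _sample_params(config: CohortConfig, rng: np.random.Generator) -> ModelParams:
    alpha_u = config.alpha_u_nominal * float(np.exp(rng.normal(0.0, config.alpha_u_log_sd)))
    alpha_v = float(np.exp(rng.uniform(*np.log(config.alpha_v_range))))
    k_p = float(np.exp(rng.uniform(*np.log(config.k_p_range))))
    return ModelParams(alpha_u=alpha_u, alpha_v=alpha_v, k_p=k_p)


def _measure(
    params: ModelParams,
    protocol: InputProtocol,
    times: np.ndarray,
    noise_sd: float,
    rng: np.random.Generator,
    simulator=None,
) -> np.ndarray:
    truth = (simulator or (lambda p, pr, t: simulate(p, pr, t).delta_vb))(params, protocol, times)
    eps = rng.normal(0.0, noise_sd, size=times.shape) if noise_sd > 0 else 0.0
    measured = truth * (1.0 + eps)
    measured[0] = 0.0  # baseline reading defines the reference point
    return measured


def generate_cohort(config: CohortConfig) -> list[SubjectRecord]:
    """Generate ``config.n_subjects`` synthetic subjects.

    Deterministic given ``config`` (including its seed): each subject draws
    from an independent child of the root seed sequence, so cohorts are
    reproducible subject-by-subject.
    """
    root = np.random.SeedSequence(config.seed)
    records = []
    for i, child in enumerate(root.spawn(config.n_subjects)):
        rng = np.random.default_rng(child)
        weight = float(rng.uniform(*config.weight_range_kg))
        params = _sample_params(config, rng)
        infusion = sample_infusion_schedule(config, weight, rng)
        hemorrhage = ovine_hemorrhage_protocol(weight)
        protocol = InputProtocol.from_schedules(infusion, hemorrhage, STUDY_DURATION_MIN)
        times = _measurement_times(config, rng)
        measured = _measure(params, protocol, times, config.noise_sd, rng)
        records.append(
            SubjectRecord(
                subject_id=f"S{i + 1:03d}",
                weight_kg=weight,
                protocol=protocol,
                measurement_times=times,
                measured_delta_vb=measured,
                true_params=params,
            )
        )
    return records


# ---------------------------------------------------------------------------
# model-mismatch injection
# ---------------------------------------------------------------------------

MISMATCH_KINDS = ("none", "compensatory-gain", "asymmetric-kp")


def _simulate_mismatch(
    params: ModelParams,
    protocol: InputProtocol,
    times: np.ndarray,
    kind: str,
    values: dict,
) -> np.ndarray:
    """Numerically integrate a perturbed generator outside the model class.

    compensatory-gain adds an *unrecorded* endogenous fluid input
    u_endo = gain·max(−ΔV_B, 0) that enters the dynamics exactly like an
    infusion (including its contribution to the fluid-shift target), so the
    subject's blood volume is restored toward baseline by a mechanism absent
    from the recorded inputs.  asymmetric-kp uses an elevated shift rate
    while fluid is moving into the vasculature (ΔV_B below the shift target,
    the refill phase that dominates after each bleed) and the nominal rate
    otherwise.
    """
    inv_u = 1.0 / (1.0 + params.alpha_u)
    inv_v = 1.0 / (1.0 + params.alpha_v)

    if kind == "compensatory-gain":
        gain = values["gain"]  # 1/min of current vascular deficit

        # state: [ΔV_B, cumulative endogenous input]
        def rhs(t, state, u, v, a0, m, s0):
            y, cum_endo = state
            u_endo = gain * max(-y, 0.0)
            shift = a0 + m * (t - s0) + cum_endo * inv_u
            return [u + u_endo - v - params.k_p * (y - shift), u_endo]

        n_state = 2
    elif kind == "asymmetric-kp":
        kp_refill = values["k_p_refill"]
        kp_nominal = values["k_p_nominal"]

        def rhs(t, state, u, v, a0, m, s0):
            y = state[0]
            shift = a0 + m * (t - s0)
            kp = kp_refill if y < shift else kp_nominal
            return [u - v - kp * (y - shift)]

        n_state = 1
    else:
        raise ValueError(f"unknown mismatch kind {kind!r}")

    out = np.empty_like(times)
    state = [0.0, 0.0][:n_state]
    cum_u = cum_v = 0.0
    for t0, t1, u, v in protocol.segments:
        a0 = cum_u * inv_u - cum_v * inv_v
        m = u * inv_u - v * inv_v
        last = t1 >= protocol.t_final
        sel = (times >= t0) & ((times <= t1) if last else (times < t1))
        t_eval = times[sel]
        sol = solve_ivp(
            rhs,
            (t0, t1),
            state,
            t_eval=np.concatenate([t_eval, [t1]]) if (t_eval.size == 0 or t_eval[-1] < t1) else t_eval,
            args=(u, v, a0, m, t0),
            rtol=1e-8,
            atol=1e-8,
            max_step=1.0,
        )
        out[sel] = sol.y[0, : t_eval.size]
        state = [float(sol.y[k, -1]) for k in range(n_state)]
        cum_u += u * (t1 - t0)
        cum_v += v * (t1 - t0)
    return out


def inject_model_mismatch(
    subject: SubjectRecord,
    kind: str,
    rng: np.random.Generator,
    noise_sd: float = 0.10,
    gain: float = 0.5,
    kp_refill_factor: float = 5.0,
) -> SubjectRecord:
    """Regenerate a subject's measurements from a perturbed generator.

    compensatory-gain
        adds an unrecorded endogenous fluid input ``gain · max(−ΔV_B, 0)``
        (default 0.5 1/min of the current vascular deficit) so blood volume
        is restored toward baseline even under minimal infusion — an
        unmodelled compensatory recruitment mechanism.
    asymmetric-kp
        uses a fluid-shift rate ``kp_refill_factor`` times larger while
        fluid moves into the vasculature than while it leaves (default
        factor 5), breaking the model's symmetric-shift assumption.

    ``kind="none"`` returns the record unchanged.  Mismatch defaults are
    sized to the failure phenotypes the mechanism emulates: near-complete
    baseline restoration within the first hour despite minimal infusion,
    and an apparent shift rate several-fold above the cohort's range.
    """
    if kind == "none":
        return subject
    if kind not in MISMATCH_KINDS:
        raise ValueError(f"unknown mismatch kind {kind!r}; expected one of {MISMATCH_KINDS}")
    if subject.true_params is None:
        raise ValueError("mismatch injection requires a synthetic subject with known parameters")
    params = subject.true_params
    if kind == "compensatory-gain":
        values = {"gain": float(gain)}
    else:
        values = {
            "k_p_refill": params.k_p * float(kp_refill_factor),
            "k_p_nominal": params.k_p,
        }
    simulator = lambda p, pr, t: _simulate_mismatch(p, pr, t, kind, values)
    measured = _measure(
        params, subject.protocol, subject.measurement_times, noise_sd, rng, simulator
    )
    return replace(subject, measured_delta_vb=measured, mismatch_tag=kind,
                   mismatch_values=values)
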