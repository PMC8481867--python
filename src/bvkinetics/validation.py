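"""Uncertainty propagation and binary fluid-responsiveness validation.

Calibrated parameter uncertainty is propagated through the BV kinetics model
by simulating every Monte-Carlo parameter draw over the validation window,
yielding pointwise 95% prediction bands.  Experimental uncertainty is
modelled as a per-point normal with standard deviation proportional to the
measured BV change (proportionality constant 0.2 by default, from published
repeatability of hematocrit/dye-based BV measurement), optionally floored.

Fluid responsiveness is the binary event "blood volume rose above
normovolemia" (ΔV_B > 0).  Two validation tests score whether the model and
the experiment classify the subject identically: at the end of therapy
(180 min) and at T*, the subject-specific time when cumulative infusion
first equals cumulative hemorrhage (which may not exist).  The agreement
probability treats model and measurement uncertainty as independent:

    P_agreement = p_m · p_e + (1 − p_m)(1 − p_e),

with p_m the fraction of ensemble trajectories above zero and p_e the
normal-tail probability that the true measured value is above zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohort import SubjectRecord
from .model import InputProtocol, simulate_ensemble

__all__ = [
    "PredictionEnsemble",
    "ExperimentalUncertainty",
    "AgreementReport",
    "propagate",
    "t_star",
    "agreement_probability",
    "validate_subject",
]


@dataclass(frozen=True)
class PredictionEnsemble:
    """Monte-Carlo trajectory ensemble with pointwise percentile bands."""

    times: np.ndarray
    trajectories: np.ndarray  # (n_draws, n_times)
    lower: np.ndarray  # 2.5th percentile
    median: np.ndarray
    upper: np.ndarray  # 97.5th percentile

    @property
    def n_draws(self) -> int:
        return self.trajectories.shape[0]

    def at(self, t: float) -> np.ndarray:
        """Ensemble values at grid time ``t`` (must be on the grid)."""
        idx = np.flatnonzero(np.isclose(self.times, t))
        if idx.size == 0:
            raise ValueError(f"t={t} is not on the ensemble time grid")
        return self.trajectories[:, idx[0]]


@dataclass(frozen=True)
class ExperimentalUncertainty:
    """Proportional-error model of the BV measurement.

    Per-point sd = max(c_exp · |ΔV_B,e|, sigma_floor).  ``c_exp`` defaults to
    0.2; ``sigma_floor`` (mL) guards the degenerate certainty the pure
    proportional model implies as the measurement approaches zero — set it
    to 0 to recover the strictly proportional model.
    """

    c_exp: float = 0.2
    sigma_floor: float = 0.0

    def __post_init__(self) -> None:
        if self.c_exp < 0 or self.sigma_floor < 0:
            raise ValueError("c_exp and sigma_floor must be non-negative")

    def sd(self, measured: float | np.ndarray) -> np.ndarray:
        return np.maximum(self.c_exp * np.abs(measured), self.sigma_floor)

    @classmethod
    def for_weight(cls, weight_kg: float, c_exp: float = 0.2) -> "ExperimentalUncertainty":
        """Default floor of 1 mL per 10 kg body weight."""
        return cls(c_exp=c_exp, sigma_floor=0.1 * weight_kg)


@dataclass(frozen=True)
class AgreementReport:
    """Binary fluid-responsiveness agreement for one subject.

    ``p_agreement_tstar`` is None exactly when ``t_star`` is None (the
    subject's infusion never catches up with the hemorrhage volume).
    """

    subject_id: str
    p_agreement_180: float
    t_star: float | None
    p_agreement_tstar: float | None


def propagate(
    draws: np.ndarray, protocol: InputProtocol, times: np.ndarray
) -> PredictionEnsemble:
    """Simulate every parameter draw and form pointwise percentile bands."""
    draws = np.atleast_2d(np.asarray(draws, dtype=float))
    if draws.shape[0] == 0:
        raise ValueError("empty draw set")
    times = np.asarray(times, dtype=float)
    traj = simulate_ensemble(draws, protocol, times)
    lo, med, hi = np.percentile(traj, [2.5, 50.0, 97.5], axis=0)
    return PredictionEnsemble(times=times, trajectories=traj, lower=lo, median=med, upper=hi)


def t_star(protocol: InputProtocol) -> float | None:
    """Earliest t > 0 at which cumulative infusion equals cumulative
    hemorrhage with both positive; ``None`` if the volumes never balance.

    Cumulative volumes are piecewise-linear, so crossings are found exactly
    segment by segment.  If the cumulatives are equal (and positive) over an
    interval of positive length — infusion exactly tracking hemorrhage — the
    interval's start is returned by convention; should that interval start
    at t = 0 the function returns 0.0, meaning the volumes balance from the
    outset.
    """
    for t0, t1, u, v in protocol.segments:
        cu0, cv0 = (float(x[0]) for x in protocol.cumulative(t0))
        d0 = cu0 - cv0
        slope = u - v
        # d(t) = d0 + slope·(t−t0) on [t0, t1]
        if d0 == 0.0:
            if cu0 > 0:
                return float(t0)
            if slope == 0.0 and u > 0:
                # equal and growing from a zero start: balanced throughout
                return float(t0)
            continue
        if slope == 0.0:
            continue
        t_cross = t0 - d0 / slope
        if t0 < t_cross <= t1:
            cu, _ = protocol.cumulative(t_cross)
            if cu[0] > 0:
                return float(t_cross)
    return None


def agreement_probability(
    ensemble: PredictionEnsemble,
    measured: float,
    exp_unc: ExperimentalUncertainty,
    t: float,
) -> float:
    """Probability that model and experiment agree on the sign of ΔV_B at t.

    p_m is the ensemble fraction above zero; p_e = Φ(measured / sd) is the
    probability the true measured value is above zero under the experimental
    error model.  Independence gives p_m·p_e + (1−p_m)(1−p_e).
    """
    values = ensemble.at(t)
    p_m = float(np.mean(values > 0.0))
    sd = float(exp_unc.sd(measured))
    if sd == 0.0:
        if measured == 0.0:
            raise ValueError(
                "sign of a zero measurement with zero uncertainty is undefined; "
                "set a positive sigma_floor on ExperimentalUncertainty"
            )
        p_e = 1.0 if measured > 0 else 0.0
    else:
        p_e = float(stats.norm.cdf(measured / sd))
    return p_m * p_e + (1.0 - p_m) * (1.0 - p_e)


def _measurement_near(record: SubjectRecord, t: float) -> float:
    """Measured ΔV_B nearest to ``t``, within half the sampling interval."""
    dt = record.sampling_interval
    i = int(np.argmin(np.abs(record.measurement_times - t)))
    if abs(record.measurement_times[i] - t) > 0.5 * dt + 1e-9:
        raise ValueError(
            f"no measurement within half a sampling interval ({0.5 * dt:.1f} min) of t={t}"
        )
    return float(record.measured_delta_vb[i])


def validate_subject(
    record: SubjectRecord,
    draws: np.ndarray,
    exp_unc: ExperimentalUncertainty | None = None,
    t_end: float | None = None,
    grid_step: float = 2.5,
) -> AgreementReport:
    """Run both binary validation tests for one subject.

    Evaluates P_agreement at the end of therapy (the last measurement time
    if sampling jitter displaced the nominal 180 min) and, when T* exists,
    at T*.  ``draws`` are retained Monte-Carlo parameter triples from the
    calibration/UQ stages.
    """
    exp_unc = exp_unc or ExperimentalUncertainty.for_weight(record.weight_kg)
    if t_end is None:
        t_end = float(record.measurement_times[-1])
    ts = t_star(record.protocol)
    grid = np.unique(np.concatenate([
        np.arange(0.0, record.protocol.t_final + grid_step / 2, grid_step),
        [t_end] + ([ts] if ts is not None else []),
    ]))
    ensemble = propagate(draws, record.protocol, grid)
    p180 = agreement_probability(ensemble, _measurement_near(record, t_end), exp_unc, t_end)
    if ts is None:
        p_ts = None
    else:
        p_ts = agreement_probability(ensemble, _measurement_near(record, ts), exp_unc, ts)
    return AgreementReport(
        subject_id=record.subject_id,
        p_agreement_180=p180,
        t_star=ts,
        p_agreement_tstar=p_ts,
    )
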