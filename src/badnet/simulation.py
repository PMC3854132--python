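"""Trajectory integration and the two apoptosis readout models.

The signaling ODEs are integrated with a fixed-step 4th-order Runge-Kutta
scheme (default step 0.01 h), segment by segment over the piecewise-constant
treatment schedule.  An adaptive scipy route driven by the pure-Python RHS
is kept as an independent cross-check.  Apoptosis percentage is accumulated
on top of a signaling trajectory by one of two nested models:

* ``BAD_ONLY`` (model 1): the rate is limited only by the phosphorylated
  fraction of BAD;
* ``BAD_MCL1`` (model 2): an additional CREB-proxied Mcl-1 term lets
  stress signaling suppress apoptosis independently of BAD.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .errors import ConfigurationError, ContractViolationError, IntegrationFailureError
from .model_core import (
    AKT_PARTIAL_BASAL,
    BASELINE_STATE,
    INHIBITORS,
    N_SPECIES,
    ParameterSet,
    TreatmentCondition,
    bads112a_decay,
    effective_vmax,
    parse_treatment,
    rhs,
)

__all__ = [
    "ApoptosisModel",
    "Trajectory",
    "integrate",
    "simulate",
    "apoptosis_rate",
    "apoptosis_factor",
    "endpoint_apoptosis",
    "run_condition_panel",
    "READOUT_SPECIES",
    "DEFAULT_DT",
]

DEFAULT_DT = 0.01  # hours

_BADS112A_INDEX = INHIBITORS.index("BADS112A")

#: observable name -> species index in the state vector
READOUT_SPECIES = {
    "pEGFR": 0,
    "pERK": 2,
    "pRac": 4,
    "pPAK": 5,
    "PI3K": 6,
    "pAKT": 7,
    "pAKT_S473": 7,
    "cAMP": 8,
    "pPKA": 9,
    "pCREB": 10,
    "pS112BAD": 11,
    "pS136BAD": 12,
}


class ApoptosisModel(enum.Enum):
    """Which anti-apoptotic inputs gate the apoptosis rate."""

    BAD_ONLY = "bad_only"        # model 1: BAD phosphorylation only
    BAD_MCL1 = "bad_mcl1"        # model 2: BAD phosphorylation + CREB/Mcl-1

    @classmethod
    def coerce(cls, value) -> "ApoptosisModel":
        if isinstance(value, cls):
            return value
        try:
            return cls(value)
        except ValueError:
            raise ConfigurationError(
                f"unknown apoptosis model {value!r}; valid: {[m.value for m in cls]}"
            ) from None


@dataclass
class Trajectory:
    """A simulated time course: signaling states and, optionally, apoptosis %."""

    times: np.ndarray                 # (m,) hours, strictly increasing from 0
    states: np.ndarray                # (m, 13)
    condition: TreatmentCondition
    apoptosis: np.ndarray | None = None   # (m,) percentage in [0, 100]

    @property
    def survival(self) -> np.ndarray:
        """Cell survival percentage, the complement of apoptosis."""
        if self.apoptosis is None:
            raise ContractViolationError("trajectory has no apoptosis readout")
        return 100.0 - self.apoptosis

    def value(self, readout: str, t) -> np.ndarray | float:
        """Linearly interpolated readout value(s) at time(s) ``t``."""
        if readout in ("apoptosis_pct", "apoptosis"):
            if self.apoptosis is None:
                raise ConfigurationError("apoptosis was not simulated for this trajectory")
            y = self.apoptosis
        else:
            try:
                y = self.states[:, READOUT_SPECIES[readout]]
            except KeyError:
                raise ConfigurationError(
                    f"unknown readout {readout!r}; valid: {sorted(READOUT_SPECIES)} + ['apoptosis_pct']"
                ) from None
        out = np.interp(np.asarray(t, dtype=float), self.times, y)
        return float(out) if out.ndim == 0 else out

    def endpoint(self) -> np.ndarray:
        return self.states[-1]

    def to_frame(self, condition_id: str | None = None) -> pd.DataFrame:
        """Tidy export: (time, variable, value, condition_id)."""
        from .model_core import SPECIES

        cid = condition_id or self.condition.label()
        frames = [
            pd.DataFrame({
                "time": self.times, "variable": name,
                "value": self.states[:, i], "condition_id": cid,
            })
            for i, name in enumerate(SPECIES)
        ]
        if self.apoptosis is not None:
            frames.append(pd.DataFrame({
                "time": self.times, "variable": "apoptosis_pct",
                "value": self.apoptosis, "condition_id": cid,
            }))
        return pd.concat(frames, ignore_index=True)


def _segments(c: TreatmentCondition) -> list[tuple[float, float]]:
    bounds = [0.0, *c.onsets().tolist(), c.horizon]
    return [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1) if bounds[i + 1] > bounds[i]]


def _segment_inputs(p: ParameterSet, c: TreatmentCondition, t0: float, t1: float):
    egf, stress, doses = c.active_inputs(0.5 * (t0 + t1))
    veff = effective_vmax(p, doses)
    dvec = p.decay_full()
    if doses[_BADS112A_INDEX] > 0:
        dvec[11] = bads112a_decay(dvec[11], doses[_BADS112A_INDEX])
    return egf, stress, veff, dvec


def _stable_dt(dt: float, dvec: np.ndarray, t1: float) -> float:
    """Shrink the step if a decay rate would push RK4 out of its stability region."""
    lam = max(float(np.max(dvec[4:])), float(np.max(dvec[:4])) * t1, 1.0)
    return min(dt, 0.5 / lam)


def integrate(
    p: ParameterSet,
    c: TreatmentCondition,
    dt: float = DEFAULT_DT,
    method: str = "rk4",
) -> Trajectory:
    """Integrate the signaling network over the treatment schedule of ``c``.

    ``method="rk4"`` (default) uses the fixed-step compiled kernel;
    ``method="adaptive"`` uses scipy's RK45 at tight tolerances on the
    pure-Python RHS and serves as an independent numerical cross-check.
    Deterministic for fixed inputs.  Raises
    :class:`~badnet.errors.IntegrationFailureError` naming the first
    offending time on NaN/blow-up or a non-trivial negative excursion.
    """
    if dt <= 0:
        raise ContractViolationError(f"dt must be > 0 (got {dt})")
    if method not in ("rk4", "adaptive"):
        raise ConfigurationError(f"unknown integration method {method!r}")

    times_parts: list[np.ndarray] = []
    states_parts: list[np.ndarray] = []
    y = BASELINE_STATE.copy()
    first = True
    for t0, t1 in _segments(c):
        egf, stress, veff, dvec = _segment_inputs(p, c, t0, t1)
        dt_seg = _stable_dt(dt, dvec, t1)
        nsteps = max(1, int(round((t1 - t0) / dt_seg)))
        h = (t1 - t0) / nsteps
        grid = t0 + h * np.arange(nsteps + 1)
        if method == "rk4":
            out = np.empty((nsteps + 1, N_SPECIES))
            status, t_fail = _kernels.integrate_segment(
                y, t0, h, nsteps, veff, p.km, p.hill_n, dvec,
                AKT_PARTIAL_BASAL, egf, stress, out,
            )
            if status != _kernels.OK:
                kind = "non-finite state" if status == _kernels.NONFINITE else "negative state"
                raise IntegrationFailureError(
                    f"integration failed ({kind}) at t = {t_fail:.6g} h "
                    f"under condition {c.label()!r}", time=t_fail,
                )
            y = out[-1].copy()
        else:
            from scipy.integrate import solve_ivp

            sub = TreatmentCondition(
                egf=(egf, 0.0), stress=(stress, 0.0),
                inhibitors={
                    name: (dose, 0.0)
                    for name, dose in zip(INHIBITORS, c.active_inputs(0.5 * (t0 + t1))[2])
                    if dose > 0
                },
                horizon=c.horizon,
            )
            sol = solve_ivp(
                lambda t, yv: rhs(np.clip(yv, 0.0, None), t, p, sub),
                (t0, t1), y, t_eval=grid, method="RK45", rtol=1e-10, atol=1e-12,
            )
            if not sol.success:
                raise IntegrationFailureError(
                    f"adaptive integration failed in [{t0}, {t1}]: {sol.message}", time=t0
                )
            out = np.clip(sol.y.T, 0.0, None)
            y = out[-1].copy()
        if first:
            times_parts.append(grid)
            states_parts.append(out)
            first = False
        else:  # drop the duplicated segment boundary
            times_parts.append(grid[1:])
            states_parts.append(out[1:])
    return Trajectory(
        times=np.concatenate(times_parts),
        states=np.concatenate(states_parts),
        condition=c,
    )


# ---------------------------------------------------------------------------
# Apoptosis readout
# ---------------------------------------------------------------------------

def apoptosis_factor(
    ps112, ps136, creb, p: ParameterSet, choice: ApoptosisModel
) -> np.ndarray:
    """Combined anti-apoptotic inhibition factor in (0, 1].

    ``F_bad * F_creb`` (model 2) or ``F_bad`` alone (model 1); see
    :class:`~badnet.model_core.ApoptosisParams`.
    """
    a = p.apoptosis
    pb = (np.asarray(ps112, dtype=float) + a.w_s136 * np.asarray(ps136, dtype=float)) / a.bad_total
    kb = a.k_bad ** a.n_bad
    f = kb / (kb + pb ** a.n_bad)
    if ApoptosisModel.coerce(choice) is ApoptosisModel.BAD_MCL1:
        kc = a.k_creb ** a.n_creb
        f = f * kc / (kc + np.asarray(creb, dtype=float) ** a.n_creb)
    return f


def apoptosis_rate(
    state: np.ndarray, t: float, c_a: float, p: ParameterSet, choice: ApoptosisModel
) -> float:
    """Instantaneous apoptosis accumulation rate dC_a/dt (%/h).

    The rate carries an explicit ``t`` multiplier, vanishes at the 100 %
    cap, decreases as the phosphorylated BAD fraction rises and — under
    the BAD+Mcl-1 model — as CREB activity rises.
    """
    if not 0.0 <= c_a <= 100.0:
        raise ContractViolationError(f"C_a must lie in [0, 100] (got {c_a})")
    state = np.asarray(state, dtype=float)
    if c_a >= 100.0:
        return 0.0
    f = apoptosis_factor(state[11], state[12], state[10], p, choice)
    return float(p.apoptosis.k_a * t * (100.0 - c_a) * f)


def simulate(
    p: ParameterSet,
    c: TreatmentCondition,
    choice: ApoptosisModel | str | None = ApoptosisModel.BAD_MCL1,
    dt: float = DEFAULT_DT,
    method: str = "rk4",
) -> Trajectory:
    """Integrate signaling and, unless ``choice`` is None, apoptosis on top."""
    traj = integrate(p, c, dt=dt, method=method)
    if choice is not None:
        choice = ApoptosisModel.coerce(choice)
        g = apoptosis_factor(
            traj.states[:, 11], traj.states[:, 12], traj.states[:, 10], p, choice
        )
        traj.apoptosis = _kernels.apoptosis_integrate(
            traj.times, np.ascontiguousarray(g, dtype=float), p.apoptosis.k_a
        )
    return traj


def endpoint_apoptosis(
    p: ParameterSet,
    c: TreatmentCondition,
    choice: ApoptosisModel | str = ApoptosisModel.BAD_MCL1,
    dt: float = DEFAULT_DT,
) -> float:
    """Apoptosis percentage at the condition's horizon."""
    return float(simulate(p, c, choice=choice, dt=dt).apoptosis[-1])


def run_condition_panel(
    p: ParameterSet,
    conditions: Sequence[TreatmentCondition | str],
    choice: ApoptosisModel | str = ApoptosisModel.BAD_MCL1,
    dt: float = DEFAULT_DT,
    horizon: float | None = None,
) -> pd.DataFrame:
    """Endpoint apoptosis percentage for a list of treatment conditions.

    ``conditions`` may mix :class:`TreatmentCondition` objects and treatment
    strings (parsed with the shared horizon).  Returns one row per condition
    with columns (condition_id, treatment, apoptosis_pct); deterministic.
    """
    resolved: list[TreatmentCondition] = []
    for c in conditions:
        if isinstance(c, str):
            resolved.append(parse_treatment(c, horizon=horizon or 48.0))
        else:
            resolved.append(c)
    horizons = {c.horizon for c in resolved}
    if len(horizons) > 1:
        raise ConfigurationError(f"panel conditions must share one horizon (got {sorted(horizons)})")
    rows = []
    for c in resolved:
        rows.append({
            "condition_id": c.label(),
            "treatment": c.label(),
            "apoptosis_pct": endpoint_apoptosis(p, c, choice=choice, dt=dt),
        })
    return pd.DataFrame(rows)
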