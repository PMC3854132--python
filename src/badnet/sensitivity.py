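"""Local relative sensitivity of every model variable to every parameter.

The relative sensitivity coefficient of variable ``x_i`` to parameter
``p_j`` at time ``t`` is the percentage change of the variable per 1 %
increase of the parameter, estimated by a one-sided forward difference::

    S_ij(t) = 100 * (x_i(t; p_j (1+h)) - x_i(t; p_j)) / x_i(t; p_j) * (0.01 / h)

with perturbation fraction ``h`` (default 1 %).  Time-averaged
sensitivities take the mean absolute coefficient over the ``n``-point
equal partition of ``[0, T]`` (defaults T = 100 h, n = 10).  Derived decay
rates are re-closed for every perturbed run, so the baseline fixed point
is preserved and the coefficients measure genuine free-parameter effects.

The 14th variable is the apoptosis percentage.  Partition points where the
baseline variable is below 1e-8 are skipped (relative change is undefined
at zero); the skip counts are recorded in the matrix metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, IntegrationFailureError
from .model_core import ParameterSet, SPECIES, TreatmentCondition, parse_treatment
from .simulation import DEFAULT_DT, ApoptosisModel, simulate

__all__ = ["SensitivityMatrix", "relative_sensitivity", "time_averaged_sensitivity"]

VARIABLES = SPECIES + ("apoptosis",)
ZERO_GUARD = 1e-8


@dataclass
class SensitivityMatrix:
    """Time-averaged relative sensitivities (%) for 14 variables x parameters."""

    values: pd.DataFrame          # rows = variables, columns = parameter names
    metadata: dict = field(default_factory=dict)

    def max_entry(self) -> float:
        return float(np.nanmax(self.values.to_numpy()))

    def to_csv(self, path) -> None:
        self.values.to_csv(path, index_label="variable")


def _default_condition(T: float) -> TreatmentCondition:
    # the model's central fitted scenario: PI3K inhibition, no stress
    return parse_treatment("LY", horizon=T)


def _variable_courses(p, condition, choice, dt, times):
    traj = simulate(p, condition, choice=choice, dt=dt)
    vals = np.empty((len(VARIABLES), len(times)))
    for i in range(13):
        vals[i] = np.interp(times, traj.times, traj.states[:, i])
    vals[13] = np.interp(times, traj.times, traj.apoptosis)
    return vals


def relative_sensitivity(
    p: ParameterSet,
    variable: str,
    parameter: str,
    t: float,
    condition: TreatmentCondition | None = None,
    perturbation: float = 0.01,
    choice: ApoptosisModel | str = ApoptosisModel.BAD_MCL1,
    dt: float = DEFAULT_DT,
) -> float:
    """Single relative sensitivity coefficient at time ``t`` (see module doc).

    Returns NaN when the baseline variable is below the zero guard at ``t``.
    """
    if variable not in VARIABLES:
        raise ConfigurationError(f"unknown variable {variable!r}; valid: {VARIABLES}")
    if parameter not in ParameterSet.free_names():
        raise ConfigurationError(f"unknown free parameter {parameter!r}")
    if perturbation <= 0:
        raise ConfigurationError("perturbation fraction must be > 0")
    condition = condition or _default_condition(max(t, 1.0))
    times = np.array([t])
    base = _variable_courses(p, condition, choice, dt, times)
    pert = _variable_courses(
        p.with_values({parameter: p.get(parameter) * (1.0 + perturbation)}),
        condition, choice, dt, times,
    )
    i = VARIABLES.index(variable)
    if abs(base[i, 0]) < ZERO_GUARD:
        return float("nan")
    return float(100.0 * (pert[i, 0] - base[i, 0]) / base[i, 0] * (0.01 / perturbation))


def time_averaged_sensitivity(
    p: ParameterSet,
    parameters: list[str] | None = None,
    perturbation: float = 0.01,
    T: float = 100.0,
    n: int = 10,
    condition: TreatmentCondition | None = None,
    choice: ApoptosisModel | str = ApoptosisModel.BAD_MCL1,
    dt: float = DEFAULT_DT,
) -> SensitivityMatrix:
    """Time-averaged absolute relative sensitivities over ``[0, T]``.

    One baseline run plus one perturbed run per analyzed parameter (all 44
    free parameters by default).  Entirely deterministic; the result is
    independent of the order in which parameters are perturbed.
    """
    parameters = list(parameters) if parameters is not None else ParameterSet.free_names()
    condition = condition or _default_condition(T)
    if condition.horizon < T:
        raise ConfigurationError(
            f"condition horizon {condition.horizon} is shorter than T={T}"
        )
    times = T / n * np.arange(1, n + 1)
    base = _variable_courses(p, condition, choice, dt, times)
    usable = np.abs(base) >= ZERO_GUARD

    values = np.zeros((len(VARIABLES), len(parameters)))
    for j, name in enumerate(parameters):
        try:
            pert = _variable_courses(
                p.with_values({name: p.get(name) * (1.0 + perturbation)}),
                condition, choice, dt, times,
            )
        except IntegrationFailureError as err:
            raise IntegrationFailureError(
                f"perturbed run for parameter {name!r} failed: {err}", time=err.time
            ) from err
        with np.errstate(divide="ignore", invalid="ignore"):
            coeff = 100.0 * (pert - base) / base * (0.01 / perturbation)
        for i in range(len(VARIABLES)):
            keep = usable[i]
            values[i, j] = np.mean(np.abs(coeff[i, keep])) if keep.any() else 0.0

    frame = pd.DataFrame(values, index=list(VARIABLES), columns=parameters)
    meta = {
        "perturbation": perturbation,
        "T": T,
        "n": n,
        "condition": condition.label(),
        "apoptosis_model": ApoptosisModel.coerce(choice).value,
        "skipped_points": {
            VARIABLES[i]: int((~usable[i]).sum()) for i in range(len(VARIABLES))
            if (~usable[i]).any()
        },
    }
    return SensitivityMatrix(values=frame, metadata=meta)
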