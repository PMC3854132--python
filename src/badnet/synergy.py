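"""Drug-combination analysis: Loewe isobolograms and a response-scale
combination index over dose grids, including the stress-triggered
synergism-pattern switch.

Two complementary indices are implemented:

* **Loewe index** — ``CI = d1/D_x1 + d2/D_x2`` for a dose pair on the
  x %-apoptosis isobologram, where ``D_xk`` is the single-agent dose of
  drug k producing the same effect (dose-equivalence null model; a sham
  combination of a drug with itself scores exactly 1 for every split).
* **Combination index** — a response-scale index comparing the combination
  against each single agent *at the same total dose*::

      CI(d1, d2) = max(E1(d1+d2), E2(d1+d2)) / E12(d1, d2)

  so CI < 1 exactly when the combination outperforms both constituent
  drugs given the same total amount of inhibitor.  A sham combination
  again scores 1 for every split.

CI values within ``ADDITIVITY_TOL`` of 1 are labelled additive: at the
low-dose additivity boundary the index approaches 1 from either side at
first order in dose, so an exact-1 label would never fire numerically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, IntegrationFailureError, ParameterDomainError, UnreachableEffectError
from .model_core import INHIBITORS, ParameterSet, TreatmentCondition
from .simulation import DEFAULT_DT, ApoptosisModel, endpoint_apoptosis

__all__ = [
    "ADDITIVITY_TOL",
    "CombinationContext",
    "DoseResponse",
    "SynergyMap",
    "label_ci",
    "invert_dose_response",
    "loewe_index",
    "isobologram",
    "combination_index",
    "equal_dose_profile",
    "synergy_map",
    "resistance_surface",
    "region_counts",
]

#: width of the additivity band around CI = 1
ADDITIVITY_TOL = 0.01

#: default dose grid range of the synergy analyses
GRID_LO, GRID_HI = 0.01, 100.0


def label_ci(ci: float) -> str:
    if np.isnan(ci):
        return "failed"
    if ci < 1.0 - ADDITIVITY_TOL:
        return "synergy"
    if ci > 1.0 + ADDITIVITY_TOL:
        return "antagonism"
    return "additivity"


@dataclass
class CombinationContext:
    """Fixed background (stress level, model variant, horizon) for a drug pair.

    Endpoint apoptosis percentages are memoized per dose assignment, so the
    single-agent curves shared across a dose grid are simulated only once.
    """

    params: ParameterSet
    drug1: str = "BADS112A"
    drug2: str = "LY294002"
    choice: ApoptosisModel | str = ApoptosisModel.BAD_MCL1
    stress: float = 0.0
    stress_onset: float = 0.0
    horizon: float = 48.0
    dt: float = DEFAULT_DT
    _cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        for d in (self.drug1, self.drug2):
            if d not in INHIBITORS:
                raise ConfigurationError(f"unknown inhibitor {d!r}; valid: {list(INHIBITORS)}")
        self.choice = ApoptosisModel.coerce(self.choice)

    @staticmethod
    def _merge(doses) -> dict[str, float]:
        """Sum doses per drug; accepts a dict or an iterable of (name, dose)
        pairs — a drug combined with itself accumulates its total dose."""
        items = doses.items() if isinstance(doses, dict) else doses
        merged: dict[str, float] = {}
        for name, dose in items:
            merged[name] = merged.get(name, 0.0) + float(dose)
        return merged

    def condition(self, doses) -> TreatmentCondition:
        merged = self._merge(doses)
        return TreatmentCondition(
            stress=(self.stress, self.stress_onset),
            inhibitors={n: (d, 0.0) for n, d in merged.items() if d > 0},
            horizon=self.horizon,
        )

    def effect(self, doses) -> float:
        """Endpoint apoptosis percentage under the given inhibitor doses."""
        merged = self._merge(doses)
        key = tuple(sorted((n, round(float(d), 12)) for n, d in merged.items() if d > 0))
        if key not in self._cache:
            self._cache[key] = endpoint_apoptosis(
                self.params, self.condition(merged), choice=self.choice, dt=self.dt
            )
        return self._cache[key]

    def combined(self, d1: float, d2: float) -> float:
        return self.effect([(self.drug1, d1), (self.drug2, d2)])


class DoseResponse:
    """Monotone single-agent dose -> endpoint-apoptosis mapping on [0, dmax]."""

    def __init__(self, drug: str, ctx: CombinationContext, dmax: float = 500.0):
        if drug not in INHIBITORS:
            raise ConfigurationError(f"unknown inhibitor {drug!r}")
        self.drug = drug
        self.ctx = ctx
        self.dmax = float(dmax)

    def effect(self, dose: float) -> float:
        if dose < 0:
            raise ParameterDomainError(f"dose must be >= 0 (got {dose})")
        return self.ctx.effect({self.drug: dose})

    def invert(self, x: float, tol: float = 1e-4) -> float:
        """Smallest dose with effect ``x`` (bisection to |effect - x| < tol).

        Returns 0 for effects at or below the zero-dose response; raises
        :class:`UnreachableEffectError` when ``x`` exceeds the response at
        ``dmax`` (the plateau), which is distinct from numerical failure.
        """
        e0 = self.effect(0.0)
        if x <= e0:
            return 0.0
        etop = self.effect(self.dmax)
        if x > etop:
            raise UnreachableEffectError(
                f"{self.drug}: effect {x:g}% exceeds the response {etop:g}% at dose {self.dmax:g}"
            )
        lo, hi = 0.0, self.dmax
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if self.effect(mid) < x:
                lo = mid
            else:
                hi = mid
            if hi - lo < 1e-12 * max(1.0, hi):
                break
        if abs(self.effect(hi) - x) > tol:
            raise IntegrationFailureError(
                f"{self.drug}: bisection failed to converge to effect {x:g}% "
                f"(reached {self.effect(hi):g}% at dose {hi:g})"
            )
        return hi


def invert_dose_response(dr: DoseResponse, effect_pct: float, tol: float = 1e-4) -> float:
    """Functional alias for :meth:`DoseResponse.invert`."""
    return dr.invert(effect_pct, tol=tol)


# ---------------------------------------------------------------------------
# Loewe isobologram
# ---------------------------------------------------------------------------

def loewe_index(
    d1: float, d2: float, dr1: DoseResponse, dr2: DoseResponse,
    effect_pct: float | None = None,
) -> float:
    """Loewe combination index ``d1/D_x1 + d2/D_x2`` for a dose pair.

    ``effect_pct`` is the isobologram level; by default it is computed as
    the combined effect of (d1, d2) under the shared background, so the
    pair lies on its own isobologram by construction.
    """
    if d1 < 0 or d2 < 0:
        raise ParameterDomainError("doses must be >= 0")
    if effect_pct is None:
        effect_pct = dr1.ctx.effect([(dr1.drug, d1), (dr2.drug, d2)])
    ci = 0.0
    if d1 > 0:
        ci += d1 / dr1.invert(effect_pct)
    if d2 > 0:
        ci += d2 / dr2.invert(effect_pct)
    return float(ci)


def isobologram(
    effect_pct: float,
    dr1: DoseResponse,
    dr2: DoseResponse,
    n: int = 15,
) -> pd.DataFrame:
    """Trace the x % isobologram: for swept d1, solve d2 by bisection.

    Returns a frame with columns (effect_pct, d1, d2, loewe_ci); contour
    points where no d2 exists on the probed interval are excluded.
    """
    D1 = dr1.invert(effect_pct)
    rows = []
    for d1 in np.linspace(0.0, D1, n):
        # solve combined(d1, d2) = effect_pct for d2 on [0, dmax]
        def f(d2):
            return dr1.ctx.effect([(dr1.drug, d1), (dr2.drug, d2)]) - effect_pct

        if f(0.0) >= 0:
            d2 = 0.0
        elif f(dr2.dmax) < 0:
            continue
        else:
            lo, hi = 0.0, dr2.dmax
            for _ in range(80):
                mid = 0.5 * (lo + hi)
                if f(mid) < 0:
                    lo = mid
                else:
                    hi = mid
                if hi - lo < 1e-12 * max(1.0, hi):
                    break
            d2 = hi
        rows.append({
            "effect_pct": effect_pct, "d1": d1, "d2": d2,
            "loewe_ci": loewe_index(d1, d2, dr1, dr2, effect_pct=effect_pct),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Response-scale combination index and maps
# ---------------------------------------------------------------------------

def combination_index(d1: float, d2: float, ctx: CombinationContext) -> float:
    """Response-scale combination index at doses (d1, d2); see module doc."""
    if d1 < 0 or d2 < 0:
        raise ParameterDomainError("doses must be >= 0")
    if d1 == 0 and d2 == 0:
        raise ParameterDomainError("at least one dose must be positive")
    total = d1 + d2
    e1 = ctx.effect([(ctx.drug1, total)])
    e2 = ctx.effect([(ctx.drug2, total)])
    e12 = ctx.combined(d1, d2)
    best_single = max(e1, e2)
    if e12 <= 0:
        return float("inf") if best_single > 0 else 1.0
    return float(best_single / e12)


@dataclass
class SynergyMap:
    """Combination-index values over a 2-D log-spaced dose grid."""

    d1: np.ndarray                # (n1,) doses of drug 1
    d2: np.ndarray                # (n2,) doses of drug 2
    ci: np.ndarray                # (n1, n2)
    stress: float
    drug1: str
    drug2: str

    @property
    def labels(self) -> np.ndarray:
        return np.vectorize(label_ci)(self.ci)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.d1):
            for j, b in enumerate(self.d2):
                rows.append({
                    "d1": a, "d2": b, "ci": self.ci[i, j],
                    "label": label_ci(self.ci[i, j]), "stress": self.stress,
                })
        return pd.DataFrame(rows)


def synergy_map(
    ctx: CombinationContext,
    n: int = 20,
    lo: float = GRID_LO,
    hi: float = GRID_HI,
) -> SynergyMap:
    """Combination-index map over an ``n x n`` log-spaced dose grid.

    A cell whose simulation fails is flagged (CI = NaN, label "failed")
    and the map completes.
    """
    grid = np.logspace(np.log10(lo), np.log10(hi), n)
    ci = np.empty((n, n))
    for i, d1 in enumerate(grid):
        for j, d2 in enumerate(grid):
            try:
                ci[i, j] = combination_index(d1, d2, ctx)
            except IntegrationFailureError:
                ci[i, j] = np.nan
    return SynergyMap(d1=grid, d2=grid, ci=ci, stress=ctx.stress,
                      drug1=ctx.drug1, drug2=ctx.drug2)


def equal_dose_profile(
    ctx: CombinationContext,
    doses: np.ndarray | None = None,
) -> pd.DataFrame:
    """Combination index along the equal-dose sweep d1 = d2 = d.

    This is the one-parameter reading of the dose range [0.01, 100]: both
    inhibitor doses are increased together and the combination at (d, d)
    is compared with each single agent at total dose 2d.
    """
    if doses is None:
        doses = np.logspace(np.log10(GRID_LO), np.log10(GRID_HI), 25)
    rows = []
    for d in doses:
        ci = combination_index(d, d, ctx)
        rows.append({"dose": d, "ci": ci, "label": label_ci(ci), "stress": ctx.stress})
    return pd.DataFrame(rows)


def resistance_surface(
    params: ParameterSet,
    stress_levels=(0.0, 100.0),
    n: int = 10,
    lo: float = GRID_LO,
    hi: float = GRID_HI,
    drug1: str = "BADS112A",
    drug2: str = "LY294002",
    choice: ApoptosisModel | str = ApoptosisModel.BAD_MCL1,
    horizon: float = 48.0,
    dt: float = DEFAULT_DT,
) -> pd.DataFrame:
    """Raw endpoint apoptosis over the dose grid, one layer per stress level."""
    grid = np.logspace(np.log10(lo), np.log10(hi), n)
    rows = []
    for stress in stress_levels:
        ctx = CombinationContext(params=params, drug1=drug1, drug2=drug2,
                                 choice=choice, stress=stress, horizon=horizon, dt=dt)
        for d1 in grid:
            for d2 in grid:
                rows.append({
                    "stress": stress, "d1": d1, "d2": d2,
                    "apoptosis_pct": ctx.combined(d1, d2),
                })
    return pd.DataFrame(rows)


def region_counts(synergy_mask: np.ndarray) -> tuple[int, int]:
    """Connected-component counts of (synergistic, non-synergistic) cells.

    4-connectivity on the dose grid; used to verify the two-region structure
    of the stress-induced synergism-pattern switch.
    """
    from scipy import ndimage

    n_syn = int(ndimage.label(synergy_mask)[1])
    n_other = int(ndimage.label(~synergy_mask)[1])
    return n_syn, n_other
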