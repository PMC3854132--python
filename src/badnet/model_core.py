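"""Core model definition: species, parameters, treatments and the ODE right-hand side.

The model tracks 13 dimensionless phospho-protein / second-messenger activity
levels of the BAD-phosphorylation network in prostate cancer cells::

    index  species        baseline   driven by
    0      EGFR*          0          EGF stimulus
    1      Raf*           0          EGFR*
    2      ERK1/2*        0          Raf*
    3      KinaseX*       0          ERK1/2*
    4      Rac*           0          EGF stimulus
    5      PAK*           0          Rac*
    6      PI3K*          1          constitutive
    7      AKT*           1          PI3K*
    8      cAMP           0          stress (epinephrine / VIP)
    9      PKA*           0          cAMP
    10     CREB*          0          PKA*
    11     pS112-BAD      1          KinaseX* + PKA* + partial AKT*
    12     pS136-BAD      1          PAK* and AKT* (two additive routes)

Every activation term is a Hill function ``V x^n / (K^n + x^n)`` of the
upstream regulator.  The four EGFR-branch species (0..3) carry the
phenomenological time-dependent dephosphorylation ``d_i * t * x_i`` that
produces the transient peak-and-decline kinetics seen for pERK under EGF;
all other species decay at constant rates.  The constant decay rates of the
four species with non-zero baseline (PI3K, AKT, pS112, pS136) are never
fitted: they are closed so that the untreated baseline state is an exact
fixed point of the system (see :func:`derive_decay_rates`).

Pharmacological / dominant-negative inhibitors enter as a multiplicative
inhibition factor ``1/(1+u)`` on the maximal velocity of their target
reaction, where the dose ``u`` is normalized so that ``u = 1`` gives
half-maximal inhibition.  The phosphorylation-deficient mutant BADS112A is
the one exception: it scales the pS112-BAD dephosphorylation rate up by
``(1+u)`` instead.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError, ContractViolationError, ParameterDomainError

__all__ = [
    "SPECIES",
    "N_SPECIES",
    "BASELINE_STATE",
    "INHIBITORS",
    "INHIBITOR_TARGET_REACTION",
    "AKT_PARTIAL_BASAL",
    "REACTION_NAMES",
    "ApoptosisParams",
    "ParameterSet",
    "TreatmentCondition",
    "hill_activation",
    "drug_factor",
    "bads112a_decay",
    "derive_decay_rates",
    "rhs",
    "parse_treatment",
]

# ---------------------------------------------------------------------------
# Species and wiring constants
# ---------------------------------------------------------------------------

SPECIES = (
    "EGFR", "Raf", "ERK12", "KinaseX", "Rac", "PAK", "PI3K", "AKT",
    "cAMP", "PKA", "CREB", "pS112BAD", "pS136BAD",
)
N_SPECIES = 13

#: Untreated baseline: constitutively active PI3K/AKT and fully
#: phosphorylated BAD at both serines; everything else off.
BASELINE_STATE = np.array(
    [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 1.0, 1.0, 0.0, 0.0, 0.0, 1.0, 1.0]
)

#: Reaction labels, one per (V, K) pair.  pS136-BAD is fed by two additive
#: routes (PAK and AKT), labelled 13a / 13b.
REACTION_NAMES = (
    "V1", "V2", "V3", "V4", "V5", "V6", "V7",
    "V8", "V9", "V10", "V11", "V12", "V13a", "V13b",
)
N_REACTIONS = 14

#: Share of the pS112-BAD drive that is basal (AKT-independent).  AKT only
#: *partially* regulates Ser112, so its contribution to the summed upstream
#: drive of pS112 is ``(1 - AKT_PARTIAL_BASAL) + AKT_PARTIAL_BASAL * AKT``:
#: full PI3K/AKT inhibition halves, but never abolishes, that drive.
AKT_PARTIAL_BASAL = 0.5

#: The 8 modelled interventions, in packed-array order.
INHIBITORS = (
    "AG1478",      # EGFR tyrosine-kinase inhibitor
    "C4BRaf",      # dominant-negative Raf
    "DN-MEK1",     # dominant-negative MEK1 (blocks ERK1/2 activation)
    "N17Rac",      # dominant-negative Rac
    "DN-PAK1",     # dominant-negative PAK1
    "LY294002",    # PI3K inhibitor
    "PKI-GFP",     # PKA inhibitor
    "BADS112A",    # phosphorylation-deficient BAD mutant (acts on pS112 decay)
)

#: inhibitor -> index of the reaction whose maximal velocity it scales down.
#: BADS112A is absent: it acts on the pS112-BAD dephosphorylation rate.
INHIBITOR_TARGET_REACTION = {
    "AG1478": 0,     # EGF -> EGFR
    "C4BRaf": 1,     # EGFR -> Raf
    "DN-MEK1": 2,    # Raf -> ERK1/2
    "N17Rac": 4,     # EGF -> Rac
    "DN-PAK1": 5,    # Rac -> PAK
    "LY294002": 6,   # constitutive PI3K activation
    "PKI-GFP": 9,    # cAMP -> PKA
}

_BADS112A_INDEX = INHIBITORS.index("BADS112A")

# Decay bookkeeping: decay rate d_i belongs to species i (1-based d1..d13).
#: EGFR-branch decays, multiplied by t in the RHS (species 0..3).
DECAY_TIME_SCALED = (0, 1, 2, 3)
#: Zero-baseline species whose steady-state closure is degenerate; their
#: constant decay rates are free (fitted) parameters: d5, d6, d9, d10, d11.
DECAY_FREE_CONSTANT = (4, 5, 8, 9, 10)
#: Non-zero-baseline species whose constant decay rates are derived by
#: steady-state closure: d7 (PI3K), d8 (AKT), d12 (pS112), d13 (pS136).
DECAY_DERIVED = (6, 7, 11, 12)


# ---------------------------------------------------------------------------
# Elementary kinetic operations
# ---------------------------------------------------------------------------

def hill_activation(x, v, k, n):
    """Hill-type activation rate ``v * x^n / (k^n + x^n)``.

    Parameters
    ----------
    x : float or ndarray
        Upstream activity level, >= 0.
    v : float
        Maximal velocity (1/h), > 0.
    k : float
        Michaelis activation coefficient (dimensionless level), > 0.
    n : float
        Hill exponent, >= 1.

    The result is monotone non-decreasing in ``x`` and bounded above by ``v``.
    """
    if v <= 0 or k <= 0 or n < 1:
        raise ParameterDomainError(
            f"hill_activation requires v > 0, k > 0, n >= 1 (got v={v}, k={k}, n={n})"
        )
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ParameterDomainError("hill_activation requires x >= 0")
    xn = x ** n
    out = v * xn / (k ** n + xn)
    return float(out) if out.ndim == 0 else out


def drug_factor(u):
    """Multiplicative inhibition factor ``1/(1+u)`` on a maximal velocity.

    Doses are normalized to the half-inhibition concentration, so ``u = 1``
    halves the target reaction's velocity and no new parameters enter the
    model.
    """
    u = float(u)
    if u < 0:
        raise ParameterDomainError(f"drug dose must be >= 0 (got {u})")
    return 1.0 / (1.0 + u)


def bads112a_decay(d_base, u):
    """Effective pS112-BAD dephosphorylation rate under BADS112A dose ``u``.

    The mutant lowers the steady phospho-S112 level by scaling the
    dephosphorylation rate up: ``d_base * (1 + u)`` — the mirror image of
    the velocity inhibition factor, so ``u = 1`` halves the steady level.
    """
    d_base = float(d_base)
    u = float(u)
    if d_base <= 0:
        raise ParameterDomainError(f"d_base must be > 0 (got {d_base})")
    if u < 0:
        raise ParameterDomainError(f"BADS112A dose must be >= 0 (got {u})")
    return d_base * (1.0 + u)


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass
class ApoptosisParams:
    """The 7 free parameters of the apoptosis readout model.

    ``d C_a / dt = k_a * t * (100 - C_a) * F_bad * [F_creb]`` with

    * ``pb = (pS112 + w_s136 * pS136) / bad_total`` — phosphorylated fraction
      of total BAD, with either serine sufficient (additive) and a relative
      anti-apoptotic weight for Ser136;
    * ``F_bad = k_bad^n_bad / (k_bad^n_bad + pb^n_bad)`` — inhibitory Hill in
      phospho-BAD (apoptosis requires dephosphorylated BAD);
    * ``F_creb = k_creb^n_creb / (k_creb^n_creb + CREB^n_creb)`` — the
      Mcl-1 arm, proxied by CREB activity, present only in the
      BAD+Mcl-1 model variant (model 2).

    The explicit ``t`` multiplier captures the accelerating, time-dependent
    commitment to apoptosis seen in the percentage time courses.
    """

    k_a: float = 1.7e-3      # apoptosis rate (1/h^2; the rate carries a t factor)
    bad_total: float = 1.6   # total BAD level on the normalized scale
    k_bad: float = 0.3       # half-inhibition phospho-BAD fraction
    n_bad: float = 3.0       # Hill exponent of the phospho-BAD term
    w_s136: float = 0.6      # anti-apoptotic weight of pS136 relative to pS112
    k_creb: float = 0.5      # half-inhibition CREB level (model 2 only)
    n_creb: float = 2.0      # Hill exponent of the CREB/Mcl-1 term

    NAMES = ("k_a", "bad_total", "k_bad", "n_bad", "w_s136", "k_creb", "n_creb")

    def __post_init__(self):
        for name in self.NAMES:
            v = float(getattr(self, name))
            if not np.isfinite(v) or v <= 0:
                raise ParameterDomainError(f"apoptosis parameter {name} must be finite and > 0 (got {v})")
            setattr(self, name, v)

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in self.NAMES])


@dataclass
class ParameterSet:
    """Kinetic parameters of the signaling network plus the apoptosis block.

    Free (fitted) signaling parameters, 37 in total:

    * ``vmax`` — 14 maximal velocities V1..V12, V13a, V13b (1/h);
    * ``km`` — 14 Michaelis activation coefficients K1..K12, K13a, K13b;
    * ``decay_time_scaled`` — d1..d4, the EGFR-branch coefficients that are
      multiplied by t in the RHS (1/h^2);
    * ``decay_zero_baseline`` — d5, d6, d9, d10, d11 for Rac, PAK, cAMP,
      PKA and CREB, whose steady-state closure is degenerate (baseline 0).

    ``hill_n`` holds the 14 Hill exponents; they are fixed structural
    constants (default 2), not fitted — the 37-parameter budget is exactly
    exhausted by the velocities, Michaelis coefficients and free decays.

    The remaining decay rates d7, d8, d12, d13 are *derived*: recomputed
    deterministically from (vmax, km, hill_n) so that the baseline state is
    a fixed point (see :func:`derive_decay_rates`); they are exposed through
    :meth:`decay_full` and never count as free parameters.
    """

    vmax: np.ndarray
    km: np.ndarray
    hill_n: np.ndarray = field(default_factory=lambda: np.full(N_REACTIONS, 2.0))
    decay_time_scaled: np.ndarray = field(default_factory=lambda: np.full(4, 1.0))
    decay_zero_baseline: np.ndarray = field(default_factory=lambda: np.full(5, 1.0))
    apoptosis: ApoptosisParams = field(default_factory=ApoptosisParams)

    def __post_init__(self):
        self.vmax = np.asarray(self.vmax, dtype=float)
        self.km = np.asarray(self.km, dtype=float)
        self.hill_n = np.asarray(self.hill_n, dtype=float)
        self.decay_time_scaled = np.asarray(self.decay_time_scaled, dtype=float)
        self.decay_zero_baseline = np.asarray(self.decay_zero_baseline, dtype=float)
        shapes = {
            "vmax": (self.vmax, N_REACTIONS),
            "km": (self.km, N_REACTIONS),
            "hill_n": (self.hill_n, N_REACTIONS),
            "decay_time_scaled": (self.decay_time_scaled, 4),
            "decay_zero_baseline": (self.decay_zero_baseline, 5),
        }
        for name, (arr, length) in shapes.items():
            if arr.shape != (length,):
                raise ContractViolationError(f"{name} must have shape ({length},), got {arr.shape}")
            if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
                raise ParameterDomainError(f"{name} entries must be finite and strictly positive")
        if np.any(self.hill_n < 1):
            raise ParameterDomainError("Hill exponents must be >= 1")

    # -- derived decay rates ------------------------------------------------
    @property
    def decay_derived(self) -> np.ndarray:
        """Steady-state-closed decay rates (d7, d8, d12, d13)."""
        return derive_decay_rates(self)

    def decay_full(self) -> np.ndarray:
        """Constant-decay vector for all 13 species (d1..d4 time-scaled)."""
        d = np.empty(N_SPECIES)
        d[list(DECAY_TIME_SCALED)] = self.decay_time_scaled
        d[list(DECAY_FREE_CONSTANT)] = self.decay_zero_baseline
        d[list(DECAY_DERIVED)] = self.decay_derived
        return d

    # -- naming / flattening ------------------------------------------------
    @staticmethod
    def signaling_free_names() -> list[str]:
        names = [f"V{s}" for s in ("1 2 3 4 5 6 7 8 9 10 11 12 13a 13b".split())]
        names += [f"K{s}" for s in ("1 2 3 4 5 6 7 8 9 10 11 12 13a 13b".split())]
        names += ["d1", "d2", "d3", "d4"]
        names += ["d5", "d6", "d9", "d10", "d11"]
        return names

    @staticmethod
    def apoptosis_free_names() -> list[str]:
        return list(ApoptosisParams.NAMES)

    @staticmethod
    def free_names() -> list[str]:
        return ParameterSet.signaling_free_names() + ParameterSet.apoptosis_free_names()

    def get(self, name: str) -> float:
        return self.to_dict()[name]

    def to_dict(self, include_derived: bool = False) -> dict[str, float]:
        reac = "1 2 3 4 5 6 7 8 9 10 11 12 13a 13b".split()
        out: dict[str, float] = {}
        for i, s in enumerate(reac):
            out[f"V{s}"] = float(self.vmax[i])
        for i, s in enumerate(reac):
            out[f"K{s}"] = float(self.km[i])
        for i, s in enumerate(reac):
            out[f"n{s}"] = float(self.hill_n[i])
        for j, i in enumerate(DECAY_TIME_SCALED):
            out[f"d{i+1}"] = float(self.decay_time_scaled[j])
        for j, i in enumerate(DECAY_FREE_CONSTANT):
            out[f"d{i+1}"] = float(self.decay_zero_baseline[j])
        for n, v in zip(ApoptosisParams.NAMES, self.apoptosis.as_array()):
            out[n] = float(v)
        if include_derived:
            for j, i in enumerate(DECAY_DERIVED):
                out[f"d{i+1}"] = float(self.decay_derived[j])
        return out

    @classmethod
    def from_dict(cls, values: dict[str, float]) -> "ParameterSet":
        reac = "1 2 3 4 5 6 7 8 9 10 11 12 13a 13b".split()
        ref = cls.default()
        d = ref.to_dict()
        known = set(d) | {f"d{i+1}" for i in DECAY_DERIVED}
        unknown = set(values) - known
        if unknown:
            raise ConfigurationError(
                f"unknown parameter name(s) {sorted(unknown)}; valid names: {sorted(known)}"
            )
        d.update({k: v for k, v in values.items() if not (k.startswith("d") and int_or_none(k[1:]) in (7, 8, 12, 13))})
        return cls(
            vmax=np.array([d[f"V{s}"] for s in reac]),
            km=np.array([d[f"K{s}"] for s in reac]),
            hill_n=np.array([d[f"n{s}"] for s in reac]),
            decay_time_scaled=np.array([d[f"d{i+1}"] for i in DECAY_TIME_SCALED]),
            decay_zero_baseline=np.array([d[f"d{i+1}"] for i in DECAY_FREE_CONSTANT]),
            apoptosis=ApoptosisParams(**{n: d[n] for n in ApoptosisParams.NAMES}),
        )

    def with_values(self, values: dict[str, float]) -> "ParameterSet":
        """Copy with the named free parameters replaced (derived decays re-closed)."""
        d = self.to_dict()
        for k, v in values.items():
            if k not in d:
                raise ConfigurationError(f"unknown parameter name {k!r}")
            d[k] = v
        return ParameterSet.from_dict(d)

    def copy(self) -> "ParameterSet":
        return replace(
            self,
            vmax=self.vmax.copy(),
            km=self.km.copy(),
            hill_n=self.hill_n.copy(),
            decay_time_scaled=self.decay_time_scaled.copy(),
            decay_zero_baseline=self.decay_zero_baseline.copy(),
            apoptosis=ApoptosisParams(**{n: getattr(self.apoptosis, n) for n in ApoptosisParams.NAMES}),
        )

    @classmethod
    def default(cls) -> "ParameterSet":
        """Neutral all-ones-ish parameter set (valid, not calibrated)."""
        return cls(
            vmax=np.full(N_REACTIONS, 2.0),
            km=np.full(N_REACTIONS, 1.0),
        )


def int_or_none(s: str):
    try:
        return int(s)
    except ValueError:
        return None


def derive_decay_rates(p: ParameterSet) -> np.ndarray:
    """Close the decay rates of PI3K, AKT, pS112-BAD and pS136-BAD.

    Each rate is the baseline activation flux of its species divided by the
    baseline level (= 1 for all four), which makes the untreated baseline
    state an exact fixed point of the ODE system::

        d7  = V7  * H(1;  K7)          (constitutive PI3K drive)
        d8  = V8  * H(1;  K8)          (PI3K steady state = 1)
        d12 = V12 * H(1;  K12)         (summed pS112 drive at baseline = 1)
        d13 = V13b * H(1; K13b)        (AKT route only; PAK is off at baseline)

    Zero-baseline species (Rac, PAK, cAMP, PKA, CREB) have no baseline
    production, so their closure is degenerate; their decay rates are free
    parameters held in ``decay_zero_baseline`` and are not touched here.
    """
    v, k, n = p.vmax, p.km, p.hill_n

    def h1(i):  # Hill of a unit-level input
        return v[i] * 1.0 / (k[i] ** n[i] + 1.0)

    return np.array([h1(6), h1(7), h1(11), h1(13)])


# ---------------------------------------------------------------------------
# Treatments
# ---------------------------------------------------------------------------

_ALIASES = {
    "LY": "LY294002", "LY294002": "LY294002",
    "AG1478": "AG1478",
    "C4BRAF": "C4BRaf",
    "DNMEK1": "DN-MEK1", "DN-MEK1": "DN-MEK1",
    "N17RAC": "N17Rac",
    "DNPAK1": "DN-PAK1", "DN-PAK1": "DN-PAK1",
    "PKI": "PKI-GFP", "PKI-GFP": "PKI-GFP", "PKIGFP": "PKI-GFP",
    "BADS112A": "BADS112A",
    "EGF": "EGF",
    "STRESS": "STRESS", "EPI": "STRESS", "EPINEPHRINE": "STRESS", "VIP": "STRESS",
}

_TOKEN_RE = re.compile(
    r"^\s*(?P<name>[A-Za-z0-9\-]+)\s*(?::\s*(?P<dose>[0-9.eE+\-]+))?\s*(?:@\s*(?P<onset>[0-9.eE+\-]+))?\s*$"
)


@dataclass
class TreatmentCondition:
    """A piecewise-constant treatment schedule.

    Stimuli (EGF; epinephrine/VIP via the shared ``stress`` channel) and
    inhibitor doses switch on at their onset times and stay constant until
    ``horizon`` (hours).  Doses are dimensionless, normalized so 1 is the
    half-maximal-inhibition dose.
    """

    egf: tuple[float, float] = (0.0, 0.0)       # (level, onset h)
    stress: tuple[float, float] = (0.0, 0.0)    # (level, onset h)
    inhibitors: dict[str, tuple[float, float]] = field(default_factory=dict)
    horizon: float = 48.0

    def __post_init__(self):
        for name in self.inhibitors:
            if name not in INHIBITORS:
                raise ConfigurationError(
                    f"unknown inhibitor {name!r}; valid: {list(INHIBITORS)}"
                )
        for label, (level, onset) in self.items():
            if level < 0:
                raise ConfigurationError(f"{label} dose/level must be >= 0 (got {level})")
            if onset < 0 or onset > self.horizon:
                raise ConfigurationError(
                    f"{label} onset {onset} outside [0, horizon={self.horizon}]"
                )

    def items(self):
        yield "EGF", self.egf
        yield "STRESS", self.stress
        for name, spec in self.inhibitors.items():
            yield name, spec

    def onsets(self) -> np.ndarray:
        """Sorted unique schedule breakpoints in (0, horizon)."""
        ts = {onset for _, (level, onset) in self.items() if level > 0 and 0 < onset < self.horizon}
        return np.array(sorted(ts))

    def active_inputs(self, t: float) -> tuple[float, float, np.ndarray]:
        """(egf, stress, dose vector over INHIBITORS) active at time ``t``."""
        egf = self.egf[0] if t >= self.egf[1] else 0.0
        stress = self.stress[0] if t >= self.stress[1] else 0.0
        doses = np.zeros(len(INHIBITORS))
        for i, name in enumerate(INHIBITORS):
            if name in self.inhibitors:
                level, onset = self.inhibitors[name]
                if t >= onset:
                    doses[i] = level
        return egf, stress, doses

    # -- construction helpers ----------------------------------------------
    def with_added(self, name: str, dose: float, onset: float = 0.0) -> "TreatmentCondition":
        """Copy with one component added (doses of a repeated inhibitor sum)."""
        c = TreatmentCondition(
            egf=self.egf, stress=self.stress,
            inhibitors=dict(self.inhibitors), horizon=self.horizon,
        )
        canonical = _ALIASES.get(name.upper(), name)
        if canonical == "EGF":
            c.egf = (c.egf[0] + dose, onset if c.egf[0] == 0 else c.egf[1])
        elif canonical == "STRESS":
            c.stress = (c.stress[0] + dose, onset if c.stress[0] == 0 else c.stress[1])
        else:
            if canonical in c.inhibitors:
                old_dose, old_onset = c.inhibitors[canonical]
                c.inhibitors[canonical] = (old_dose + dose, min(old_onset, onset))
            else:
                c.inhibitors[canonical] = (dose, onset)
        return TreatmentCondition(c.egf, c.stress, c.inhibitors, c.horizon)

    def label(self) -> str:
        """Canonical, order-independent treatment string."""
        parts = []
        for name, (level, onset) in sorted(self.items()):
            if level > 0:
                parts.append(f"{name}:{level:g}@{onset:g}")
        return " + ".join(parts) if parts else "control"


def parse_treatment(text: str, horizon: float = 48.0) -> TreatmentCondition:
    """Parse a treatment string like ``"LY:1@0 + EGF:1@2"``.

    Grammar: components separated by ``+`` (or ``&``), each
    ``NAME[:dose][@onset]`` with dose defaulting to 1 and onset to 0 h.
    Recognized names are the 8 inhibitors (with common short aliases),
    ``EGF`` and the stress channel (``STRESS`` / ``EPI`` / ``VIP``).
    ``"control"`` or an empty string is the untreated condition.
    """
    cond = TreatmentCondition(horizon=horizon)
    text = text.strip()
    if text == "" or text.lower() in ("control", "none"):
        return cond
    for token in re.split(r"[+&]", text):
        m = _TOKEN_RE.match(token)
        if not m:
            raise ConfigurationError(f"cannot parse treatment component {token!r}")
        raw = m.group("name").upper()
        if raw not in _ALIASES:
            raise ConfigurationError(
                f"unknown treatment name {m.group('name')!r}; valid: {sorted(set(_ALIASES))}"
            )
        dose = float(m.group("dose")) if m.group("dose") else 1.0
        onset = float(m.group("onset")) if m.group("onset") else 0.0
        cond = cond.with_added(raw, dose, onset)
    return cond


# ---------------------------------------------------------------------------
# Right-hand side (pure-Python reference implementation)
# ---------------------------------------------------------------------------

def effective_vmax(p: ParameterSet, doses: np.ndarray) -> np.ndarray:
    """Velocities with the inhibition factor of each mapped inhibitor applied."""
    v = p.vmax.copy()
    for i, name in enumerate(INHIBITORS):
        if name == "BADS112A":
            continue
        if doses[i] > 0:
            v[INHIBITOR_TARGET_REACTION[name]] *= drug_factor(doses[i])
    return v


def rhs(state: np.ndarray, t: float, p: ParameterSet, c: TreatmentCondition) -> np.ndarray:
    """Time derivative of the 13 activity levels under condition ``c`` at time ``t``.

    This is the readable reference implementation; the integrator uses a
    numerically identical compiled kernel (cross-checked in the test suite).
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (N_SPECIES,):
        raise ContractViolationError(f"state must have shape ({N_SPECIES},), got {state.shape}")
    if np.any(state < 0):
        raise ContractViolationError("state entries must be >= 0")
    egf, stress, doses = c.active_inputs(t)
    v = effective_vmax(p, doses)
    k, n = p.km, p.hill_n
    d = p.decay_full()
    d12 = bads112a_decay(d[11], doses[_BADS112A_INDEX])

    x = state
    H = lambda i, u: hill_activation(u, v[i], k[i], n[i]) if u > 0 else 0.0

    dx = np.empty(N_SPECIES)
    # EGFR branch: time-dependent dephosphorylation d_i * t * x_i
    dx[0] = H(0, egf) - d[0] * t * x[0]
    dx[1] = H(1, x[0]) - d[1] * t * x[1]
    dx[2] = H(2, x[1]) - d[2] * t * x[2]
    dx[3] = H(3, x[2]) - d[3] * t * x[3]
    # Rac / PAK branch
    dx[4] = H(4, egf) - d[4] * x[4]
    dx[5] = H(5, x[4]) - d[5] * x[5]
    # PI3K / AKT branch (constitutive PI3K drive, unit input)
    dx[6] = H(6, 1.0) - d[6] * x[6]
    dx[7] = H(7, x[6]) - d[7] * x[7]
    # stress branch
    dx[8] = H(8, stress) - d[8] * x[8]
    dx[9] = H(9, x[8]) - d[9] * x[9]
    dx[10] = H(10, x[9]) - d[10] * x[10]
    # BAD phosphorylation
    s112_drive = x[3] + x[9] + ((1.0 - AKT_PARTIAL_BASAL) + AKT_PARTIAL_BASAL * x[7])
    dx[11] = H(11, s112_drive) - d12 * x[11]
    dx[12] = H(12, x[5]) + H(13, x[7]) - d[12] * x[12]
    return dx
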