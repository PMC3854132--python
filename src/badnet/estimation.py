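"""Parameter estimation against normalized observation tables.

The fitting objective is the mean squared error between simulated and
observed values over all table rows (apoptosis percentages are compared on
the 0–1 fraction scale so signaling and apoptosis residuals are
commensurate).  Free parameters are searched in log10 space with a small
seeded genetic algorithm (tournament selection, uniform crossover,
per-gene Gaussian mutation, elitism).  Fitting is staged: the 37 signaling
parameters are fitted to phospho-protein tables first, then the 7
apoptosis parameters with signaling frozen — which also lets the apoptosis
stage reuse cached signaling trajectories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _kernels
from .errors import ConfigurationError, ContractViolationError
from .model_core import ApoptosisParams, ParameterSet, parse_treatment
from .simulation import DEFAULT_DT, ApoptosisModel, READOUT_SPECIES, apoptosis_factor, integrate

__all__ = [
    "OBS_COLUMNS",
    "NORMALIZATIONS",
    "ObservationTable",
    "FitConfig",
    "FitResult",
    "ModelSelectionReport",
    "simulate_observations",
    "objective",
    "fit",
    "scale_apoptosis_datasets",
    "model_select",
    "default_bounds",
]

OBS_COLUMNS = ("condition_id", "treatment", "readout", "time_h", "value", "normalization")
NORMALIZATIONS = ("to_control", "to_max", "to_total")


@dataclass
class ObservationTable:
    """Tidy table of normalized measurements keyed by (condition, readout, time)."""

    df: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = set(OBS_COLUMNS) - set(self.df.columns)
        if missing:
            raise ContractViolationError(f"observation table lacks column(s) {sorted(missing)}")
        if (self.df["value"] < 0).any():
            raise ContractViolationError("normalized observation values must be >= 0")
        bad_norm = set(self.df["normalization"].unique()) - set(NORMALIZATIONS)
        if bad_norm:
            raise ContractViolationError(f"unknown normalization rule(s) {sorted(bad_norm)}")
        dup = self.df.duplicated(subset=["condition_id", "readout", "time_h"])
        if dup.any():
            rows = self.df.loc[dup, ["condition_id", "readout", "time_h"]]
            raise ContractViolationError(f"duplicate (condition, readout, time) rows:\n{rows}")

    def __len__(self):
        return len(self.df)

    @classmethod
    def from_csv(cls, path) -> "ObservationTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def concat(cls, tables: list["ObservationTable"]) -> "ObservationTable":
        return cls(pd.concat([t.df for t in tables], ignore_index=True))


# ---------------------------------------------------------------------------
# Simulation <-> observation mapping
# ---------------------------------------------------------------------------

def _condition_groups(table: ObservationTable):
    """Yield (treatment string, horizon, row index) per distinct condition."""
    for treatment, sub in table.df.groupby("treatment", sort=True):
        horizon = float(sub["time_h"].max())
        yield str(treatment), max(horizon, 1e-3), sub.index


def simulate_observations(
    p: ParameterSet,
    table: ObservationTable,
    choice: ApoptosisModel | str = ApoptosisModel.BAD_MCL1,
    dt: float = DEFAULT_DT,
) -> np.ndarray:
    """Simulated counterpart of every table row, after normalization rules.

    ``to_control`` and ``to_total`` readouts are identities on the model
    scale (state variables are already expressed relative to the untreated
    control / total protein); ``to_max`` readouts are divided by the
    maximum simulated value across all rows sharing the readout, mirroring
    how the measured series was normalized.
    """
    from .simulation import simulate as _simulate

    df = table.df
    sim = np.empty(len(df), dtype=float)
    for treatment, horizon, idx in _condition_groups(table):
        try:
            cond = parse_treatment(treatment, horizon=horizon)
        except ConfigurationError as err:
            raise ConfigurationError(f"condition {treatment!r} is not simulateable: {err}") from err
        needs_apoptosis = (df.loc[idx, "readout"] == "apoptosis_pct").any()
        traj = _simulate(p, cond, choice=choice if needs_apoptosis else None, dt=dt)
        for i in idx:
            sim[df.index.get_loc(i)] = traj.value(df.at[i, "readout"], df.at[i, "time_h"])
    # apply to_max normalization per readout group
    to_max = df["normalization"] == "to_max"
    if to_max.any():
        for readout in df.loc[to_max, "readout"].unique():
            mask = (to_max & (df["readout"] == readout)).to_numpy()
            top = sim[mask].max()
            if top > 0:
                sim[mask] = sim[mask] / top
    return sim


def objective(
    p: ParameterSet,
    data: ObservationTable,
    choice: ApoptosisModel | str = ApoptosisModel.BAD_MCL1,
    dt: float = DEFAULT_DT,
) -> float:
    """Mean squared error between simulated and observed values.

    Apoptosis rows enter on the fraction scale (percentage / 100).
    Deterministic given ``p``; invariant to row order.
    """
    sim = simulate_observations(p, data, choice=choice, dt=dt)
    obs = data.df["value"].to_numpy(dtype=float)
    scale = np.where(data.df["readout"].to_numpy() == "apoptosis_pct", 100.0, 1.0)
    resid = (sim - obs) / scale
    return float(np.mean(resid ** 2))


# ---------------------------------------------------------------------------
# Genetic algorithm
# ---------------------------------------------------------------------------

def default_bounds(name: str) -> tuple[float, float]:
    """Search bounds per parameter family.

    Signaling states are dimensionless and of order 1, so velocities and
    Michaelis coefficients span wide positive boxes.  The apoptosis-stage
    bounds are preset from the range of the normalized observables:
    phospho-BAD fractions and CREB activity stay within ~[0, 1.5], so
    half-inhibition constants or site weights far outside that range are
    unidentifiable from any fit set and are excluded from the search.
    """
    if name.startswith(("V", "K")):
        return (1e-3, 1e2)
    if name.startswith("d"):
        return (1e-3, 10.0)
    if name == "k_a":
        return (1e-4, 10.0)
    if name in ("n_bad", "n_creb"):
        return (1.0, 4.0)
    if name == "k_bad":
        return (0.05, 2.0)
    if name == "k_creb":
        # a large half-inhibition constant lets the CREB/Mcl-1 arm switch
        # off entirely, preserving the exact nesting of the BAD-only model
        return (0.05, 10.0)
    if name == "w_s136":
        return (0.1, 2.0)
    if name == "bad_total":
        return (0.5, 4.0)
    raise ConfigurationError(f"no default bounds for parameter {name!r}")


@dataclass
class FitConfig:
    """Genetic-algorithm settings and the free-parameter partition."""

    free: list[str]
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    population: int = 100
    generations: int = 200
    crossover: float = 0.8
    mutation_rate: float = 0.15
    mutation_sigma: float = 0.1     # log10-space Gaussian step
    tournament: int = 3
    elitism: int = 2
    seed: int = 0

    def __post_init__(self):
        if not self.free:
            raise ConfigurationError("FitConfig.free must name at least one parameter")
        valid = set(ParameterSet.free_names())
        unknown = set(self.free) - valid
        if unknown:
            raise ConfigurationError(f"unknown free parameter(s) {sorted(unknown)}")
        for name in self.free:
            lo, hi = self.bounds.get(name, default_bounds(name))
            if not (np.isfinite(lo) and np.isfinite(hi) and 0 < lo < hi):
                raise ConfigurationError(f"bounds for {name} must be finite, positive, lo < hi")
            self.bounds[name] = (float(lo), float(hi))

    def to_dict(self) -> dict:
        return {
            "free": list(self.free),
            "bounds": {k: list(v) for k, v in self.bounds.items()},
            "population": self.population, "generations": self.generations,
            "crossover": self.crossover, "mutation_rate": self.mutation_rate,
            "mutation_sigma": self.mutation_sigma, "tournament": self.tournament,
            "elitism": self.elitism, "seed": self.seed,
        }


@dataclass
class FitResult:
    params: ParameterSet
    mse: float
    history: np.ndarray           # best objective per generation (incl. initial)
    config: FitConfig
    n_evaluations: int

    def report(self) -> dict:
        return {
            "seed": self.config.seed,
            "config": self.config.to_dict(),
            "best_mse_per_generation": self.history.tolist(),
            "final_mse": self.mse,
            "parameters": self.params.to_dict(include_derived=True),
        }


def _ga_minimize(fun, lo: np.ndarray, hi: np.ndarray, cfg: FitConfig):
    """Minimize ``fun`` over a log10-space box with a seeded GA.

    Every individual in every generation respects the bounds.  Returns
    (best genome, best value, history, n_evaluations).
    """
    rng = np.random.default_rng(cfg.seed)
    dim = lo.size
    pop = rng.uniform(lo, hi, size=(cfg.population, dim))
    fitness = np.array([fun(x) for x in pop])
    n_eval = cfg.population
    order = np.argsort(fitness)
    pop, fitness = pop[order], fitness[order]
    history = [fitness[0]]

    for _ in range(cfg.generations):
        new = np.empty_like(pop)
        new[: cfg.elitism] = pop[: cfg.elitism]
        for i in range(cfg.elitism, cfg.population):
            # tournament selection of two parents
            idx1 = rng.integers(0, cfg.population, size=cfg.tournament).min()
            idx2 = rng.integers(0, cfg.population, size=cfg.tournament).min()
            p1, p2 = pop[idx1], pop[idx2]
            if rng.random() < cfg.crossover:
                mask = rng.random(dim) < 0.5
                child = np.where(mask, p1, p2)
            else:
                child = p1.copy()
            mut = rng.random(dim) < cfg.mutation_rate
            child = child + mut * rng.normal(0.0, cfg.mutation_sigma, size=dim) * (hi - lo)
            new[i] = np.clip(child, lo, hi)
        new_fitness = fitness.copy()
        for i in range(cfg.elitism, cfg.population):
            new_fitness[i] = fun(new[i])
        n_eval += cfg.population - cfg.elitism
        order = np.argsort(new_fitness)
        pop, fitness = new[order], new_fitness[order]
        history.append(fitness[0])
    return pop[0], float(fitness[0]), np.array(history), n_eval


_APOPTOSIS_NAMES = set(ApoptosisParams.NAMES)


def _make_objective(base: ParameterSet, data: ObservationTable, choice, dt, free: list[str]):
    """Objective closure over the log10 genome; caches signaling when possible.

    When only apoptosis parameters are free, the signaling trajectories are
    independent of the genome: they are simulated once and only the 1-D
    apoptosis accumulation is re-integrated per candidate.
    """
    choice = ApoptosisModel.coerce(choice)
    if set(free) <= _APOPTOSIS_NAMES:
        df = data.df
        cache = []
        obs = df["value"].to_numpy(dtype=float)
        scale = np.where(df["readout"].to_numpy() == "apoptosis_pct", 100.0, 1.0)
        sim_static = np.full(len(df), np.nan)
        for treatment, horizon, idx in _condition_groups(data):
            cond = parse_treatment(treatment, horizon=horizon)
            traj = integrate(base, cond, dt=dt)
            rows = [df.index.get_loc(i) for i in idx]
            times = df.loc[idx, "time_h"].to_numpy(dtype=float)
            is_apop = (df.loc[idx, "readout"] == "apoptosis_pct").to_numpy()
            for r, i in zip(rows, idx):
                if df.at[i, "readout"] != "apoptosis_pct":
                    sim_static[r] = traj.value(df.at[i, "readout"], df.at[i, "time_h"])
            cache.append((traj, np.array(rows)[is_apop], times[is_apop]))
        to_max = (df["normalization"] == "to_max").to_numpy()
        if to_max.any():
            # to_max readouts are signaling readouts; normalize the static part once
            for readout in df.loc[df["normalization"] == "to_max", "readout"].unique():
                mask = to_max & (df["readout"] == readout).to_numpy()
                top = np.nanmax(sim_static[mask]) if mask.any() else 0.0
                if np.isfinite(top) and top > 0:
                    sim_static[mask] = sim_static[mask] / top

        def fun(x):
            cand = base.with_values({n: 10.0 ** v for n, v in zip(free, x)})
            sim = sim_static.copy()
            for traj, rows, times in cache:
                if rows.size == 0:
                    continue
                g = apoptosis_factor(
                    traj.states[:, 11], traj.states[:, 12], traj.states[:, 10], cand, choice
                )
                ca = _kernels.apoptosis_integrate(
                    traj.times, np.ascontiguousarray(g, dtype=float), cand.apoptosis.k_a
                )
                sim[rows] = np.interp(times, traj.times, ca)
            resid = (sim - obs) / scale
            return float(np.mean(resid ** 2))

        return fun

    def fun(x):
        cand = base.with_values({n: 10.0 ** v for n, v in zip(free, x)})
        return objective(cand, data, choice=choice, dt=dt)

    return fun


def fit(
    data: ObservationTable,
    cfg: FitConfig,
    choice: ApoptosisModel | str = ApoptosisModel.BAD_MCL1,
    base: ParameterSet | None = None,
    dt: float = DEFAULT_DT,
) -> FitResult:
    """Fit the named free parameters to ``data`` with the genetic algorithm.

    ``base`` supplies the fixed (non-free) parameter values; derived decay
    rates are re-closed for every candidate.  Deterministic for a fixed
    ``cfg.seed``.  The returned objective never exceeds the best of the
    initial population; a run that fails to improve on it emits a warning.
    """
    if len(data) == 0:
        raise ConfigurationError("cannot fit an empty observation table")
    base = base if base is not None else ParameterSet.default()
    lo = np.array([np.log10(cfg.bounds[n][0]) for n in cfg.free])
    hi = np.array([np.log10(cfg.bounds[n][1]) for n in cfg.free])
    fun = _make_objective(base, data, choice, dt, cfg.free)
    best_x, best_f, history, n_eval = _ga_minimize(fun, lo, hi, cfg)
    if history.size > 1 and not (best_f < history[0]):
        warnings.warn(
            "genetic algorithm did not improve on the best initial individual",
            stacklevel=2,
        )
    params = base.with_values({n: 10.0 ** v for n, v in zip(cfg.free, best_x)})
    return FitResult(params=params, mse=best_f, history=history, config=cfg, n_evaluations=n_eval)


# ---------------------------------------------------------------------------
# Dataset scaling and model selection
# ---------------------------------------------------------------------------

def _default_anchors() -> tuple[str, str]:
    return (
        parse_treatment("LY").label(),
        parse_treatment("LY + EGF:1@2").label(),
    )


def scale_apoptosis_datasets(
    tables: list[ObservationTable],
    anchors: tuple[str, str] | None = None,
) -> ObservationTable:
    """Merge apoptosis tables from different assay environments onto one scale.

    The first table is the reference; each subsequent table is multiplied by
    the single factor that equalizes the mean apoptosis level of the anchor
    treatments (LY294002 alone and LY294002 + EGF by default) with the
    reference.  Idempotent; no rows are lost.
    """
    if not tables:
        raise ConfigurationError("no tables to scale")
    anchors = anchors or _default_anchors()

    def anchor_mean(t: ObservationTable) -> float:
        sub = t.df[
            t.df["condition_id"].isin(anchors) & (t.df["readout"] == "apoptosis_pct")
        ]
        if sub["condition_id"].nunique() < len(anchors):
            missing = set(anchors) - set(sub["condition_id"])
            raise ConfigurationError(f"anchor treatment(s) {sorted(missing)} missing from table")
        return float(sub["value"].mean())

    ref_level = anchor_mean(tables[0])
    scaled = [tables[0].df.copy()]
    for k, t in enumerate(tables[1:], start=2):
        factor = ref_level / anchor_mean(t)
        df = t.df.copy()
        apop = df["readout"] == "apoptosis_pct"
        df.loc[apop, "value"] = df.loc[apop, "value"] * factor
        # tag the assay environment so shared treatments keep unique keys
        df["condition_id"] = df["condition_id"].astype(str) + f" | set{k}"
        scaled.append(df)
    return ObservationTable(pd.concat(scaled, ignore_index=True))


@dataclass
class ModelSelectionReport:
    choice: ApoptosisModel
    holdout_mse: dict[str, float]
    train_mse: dict[str, float]
    fits: dict[str, FitResult]

    def to_dict(self) -> dict:
        return {
            "selected": self.choice.value,
            "holdout_mse": self.holdout_mse,
            "train_mse": self.train_mse,
        }


#: free apoptosis parameters per model variant (model 1 has no CREB term)
MODEL_FREE = {
    ApoptosisModel.BAD_ONLY: ["k_a", "bad_total", "k_bad", "n_bad", "w_s136"],
    ApoptosisModel.BAD_MCL1: list(ApoptosisParams.NAMES),
}


def model_select(
    data_train: ObservationTable,
    data_holdout: ObservationTable,
    signaling: ParameterSet,
    cfg: FitConfig | None = None,
    dt: float = DEFAULT_DT,
    tie_rel: float = 0.1,
) -> ModelSelectionReport:
    """Fit both apoptosis model variants on the training treatments and pick
    the one with lower holdout MSE; ties go to the BAD-only model.

    Because the BAD-only model is nested in the BAD+Mcl-1 model, holdout
    errors that differ by less than ``tie_rel`` (relative) are treated as a
    tie and parsimony prevails — the richer model must earn its extra arm
    with a material improvement.  Signaling parameters are frozen
    throughout (staged fitting).
    """
    if len(data_holdout) == 0:
        raise ConfigurationError("holdout set is empty")
    holdout_mse: dict[str, float] = {}
    train_mse: dict[str, float] = {}
    fits: dict[str, FitResult] = {}
    for variant in (ApoptosisModel.BAD_ONLY, ApoptosisModel.BAD_MCL1):
        vcfg = replace(
            cfg if cfg is not None else FitConfig(free=MODEL_FREE[variant]),
            free=list(MODEL_FREE[variant]), bounds={},
        )
        res = fit(data_train, vcfg, choice=variant, base=signaling, dt=dt)
        fits[variant.value] = res
        train_mse[variant.value] = res.mse
        holdout_mse[variant.value] = objective(res.params, data_holdout, choice=variant, dt=dt)
    mse1 = holdout_mse[ApoptosisModel.BAD_ONLY.value]
    mse2 = holdout_mse[ApoptosisModel.BAD_MCL1.value]
    if mse2 < (1.0 - tie_rel) * mse1:
        choice = ApoptosisModel.BAD_MCL1
    else:
        choice = ApoptosisModel.BAD_ONLY
    return ModelSelectionReport(choice=choice, holdout_mse=holdout_mse, train_mse=train_mse, fits=fits)
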