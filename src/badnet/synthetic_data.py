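"""Synthetic observation tables with the structure of the wet-lab designs.

A ground-truth parameter set drives the ODE model through the two
phospho-protein experimental designs and the apoptosis treatment panel;
the resulting noiseless readouts are exactly the simulation module's
output (there is no second model code path), normalized by the same rules
used for the measured tables, and then perturbed by a configurable noise
model:

* signaling readouts — multiplicative log-normal noise (western-blot
  densitometry scale) plus optional additive Gaussian noise, clipped at 0;
* apoptosis percentages — binomial counting noise with ``n_cells`` cells
  per field (the assays count >= 350 cells per treatment).

Designs
-------
``epi_dose_series``
    8 conditions: untreated control, LY294002 alone, and LY294002 (2 h
    pre-treatment) followed by epinephrine at 6 increasing doses for 1 h;
    readouts pS112-BAD (normalized to control) and pCREB (normalized to
    the series maximum) at the 3 h endpoint.  16 rows.
``ly_egf_timecourse``
    10 conditions covering LY294002 and EGF schedules (EGF 2 h after LY);
    readouts pAKT-S473, pERK (to total ERK), pS112-BAD, pS136-BAD.
    40 rows.
``apoptosis_panel``
    endpoint (or time-course) apoptosis percentages for a treatment list;
    the default list is the validation panel of single inhibitors and
    combinations with/without EGF and stress.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .model_core import ParameterSet, parse_treatment
from .simulation import DEFAULT_DT, ApoptosisModel, simulate
from .estimation import ObservationTable

__all__ = [
    "GeneratorConfig",
    "DESIGNS",
    "stress_from_epinephrine_nM",
    "generate",
    "make_fixture_suite",
    "apoptosis_fit_times",
    "APOPTOSIS_TRAIN_TREATMENTS",
    "APOPTOSIS_HOLDOUT_TREATMENTS",
]

DESIGNS = ("epi_dose_series", "ly_egf_timecourse", "apoptosis_panel")

#: epinephrine doses of the dose series (nM)
EPI_DOSES_NM = (0.01, 0.1, 1.0, 10.0, 100.0, 1000.0)

#: training treatments of the apoptosis fit (LY, LY&EGF, LY&VIP)
APOPTOSIS_TRAIN_TREATMENTS = ("LY", "LY + EGF:1@2", "LY + VIP:100")

#: remaining panel treatments, used for validation / model selection
#: (the validation panel probes both growth-factor and stress rescue, so the
#: holdout can discriminate the BAD-only and BAD+Mcl-1 apoptosis models)
APOPTOSIS_HOLDOUT_TREATMENTS = (
    "LY + C4BRAF",
    "LY + DNPAK1",
    "LY + DNPAK1 + C4BRAF",
    "LY + BADS112A",
    "EGF + LY + C4BRAF + DNPAK1",
    "LY + BADS112A + VIP:100",
)


def apoptosis_fit_times() -> np.ndarray:
    """9 assay time points per training treatment (27 fit rows in total)."""
    return np.linspace(6.0, 48.0, 9)


def stress_from_epinephrine_nM(conc_nm: float) -> float:
    """Map an epinephrine concentration (nM) to the dimensionless stress input.

    A saturating log transform with unit EC50 on the nM scale:
    ``log10(1 + c)``, so 0.01 nM is nearly silent and 1000 nM drives the
    stress channel deep into saturation.
    """
    if conc_nm < 0:
        raise ConfigurationError(f"epinephrine concentration must be >= 0 (got {conc_nm})")
    return float(np.log10(1.0 + conc_nm))


@dataclass
class GeneratorConfig:
    """Ground truth, design and noise model for one synthetic table."""

    params: ParameterSet
    design: str
    seed: int
    noise_lognorm_sd: float = 0.1    # sd of log-multiplicative noise
    noise_additive_sd: float = 0.0   # sd of additive noise on the normalized scale
    n_cells: int = 350               # cells counted per apoptosis measurement
    replicates: int = 1
    apoptosis_model: ApoptosisModel = ApoptosisModel.BAD_MCL1
    treatments: tuple[str, ...] | None = None    # apoptosis_panel only
    times: tuple[float, ...] = (48.0,)           # apoptosis_panel only
    dt: float = DEFAULT_DT

    def __post_init__(self):
        if self.design not in DESIGNS:
            raise ConfigurationError(f"unknown design {self.design!r}; valid: {DESIGNS}")
        if self.noise_lognorm_sd < 0 or self.noise_additive_sd < 0:
            raise ConfigurationError("noise standard deviations must be >= 0")
        if self.seed is None:
            raise ConfigurationError("a seed is mandatory")
        self.apoptosis_model = ApoptosisModel.coerce(self.apoptosis_model)


def _epi_dose_series_rows(cfg: GeneratorConfig) -> pd.DataFrame:
    horizon = 3.0  # LY at 0 h for 2 h, epinephrine for the final hour
    conditions = ["control", "LY"]
    conditions += [
        f"LY + EPI:{stress_from_epinephrine_nM(c):g}@2" for c in EPI_DOSES_NM
    ]
    rows = []
    for treatment in conditions:
        cond = parse_treatment(treatment, horizon=horizon)
        traj = simulate(cfg.params, cond, choice=None, dt=cfg.dt)
        rows.append({
            "condition_id": cond.label(), "treatment": treatment,
            "readout": "pS112BAD", "time_h": horizon,
            "value": traj.value("pS112BAD", horizon), "normalization": "to_control",
        })
        rows.append({
            "condition_id": cond.label(), "treatment": treatment,
            "readout": "pCREB", "time_h": horizon,
            "value": traj.value("pCREB", horizon), "normalization": "to_max",
        })
    df = pd.DataFrame(rows)
    top = df.loc[df["readout"] == "pCREB", "value"].max()
    if top > 0:
        df.loc[df["readout"] == "pCREB", "value"] /= top
    return df


#: the 10 (treatment, measurement time) conditions of the LY/EGF time course
_LY_EGF_CONDITIONS = (
    ("control", 0.5),
    ("LY", 0.5), ("LY", 1.0), ("LY", 2.0),
    ("LY + EGF:1@2", 2.083), ("LY + EGF:1@2", 2.25),
    ("LY + EGF:1@2", 2.5), ("LY + EGF:1@2", 3.0),
    ("EGF", 0.25), ("EGF", 1.0),
)

_LY_EGF_READOUTS = (
    ("pAKT_S473", "to_control"),
    ("pERK", "to_total"),
    ("pS112BAD", "to_control"),
    ("pS136BAD", "to_control"),
)


def _ly_egf_timecourse_rows(cfg: GeneratorConfig) -> pd.DataFrame:
    rows = []
    by_treatment: dict[str, list[float]] = {}
    for treatment, t in _LY_EGF_CONDITIONS:
        by_treatment.setdefault(treatment, []).append(t)
    for treatment, ts in by_treatment.items():
        horizon = max(ts)
        cond = parse_treatment(treatment, horizon=horizon)
        traj = simulate(cfg.params, cond, choice=None, dt=cfg.dt)
        for t in ts:
            cid = f"{cond.label()} | t={t:g}h"
            for readout, rule in _LY_EGF_READOUTS:
                rows.append({
                    "condition_id": cid, "treatment": treatment,
                    "readout": readout, "time_h": t,
                    "value": traj.value(readout, t), "normalization": rule,
                })
    return pd.DataFrame(rows)


def _apoptosis_panel_rows(cfg: GeneratorConfig) -> pd.DataFrame:
    treatments = cfg.treatments or (APOPTOSIS_TRAIN_TREATMENTS + APOPTOSIS_HOLDOUT_TREATMENTS)
    horizon = max(cfg.times)
    rows = []
    for treatment in treatments:
        cond = parse_treatment(treatment, horizon=horizon)
        traj = simulate(cfg.params, cond, choice=cfg.apoptosis_model, dt=cfg.dt)
        for t in cfg.times:
            rows.append({
                "condition_id": cond.label(), "treatment": treatment,
                "readout": "apoptosis_pct", "time_h": float(t),
                "value": traj.value("apoptosis_pct", t), "normalization": "to_control",
            })
    return pd.DataFrame(rows)


def generate(cfg: GeneratorConfig) -> ObservationTable:
    """Simulate the design under the ground truth and apply observation noise.

    With all noise parameters at 0 (and ``n_cells`` -> ``None``) the table
    equals the deterministic model output exactly.  Identical seeds give
    identical tables; negative noisy values are clipped at 0 and the clip
    count is recorded in ``meta['clipped']``.
    """
    if cfg.design == "epi_dose_series":
        df = _epi_dose_series_rows(cfg)
    elif cfg.design == "ly_egf_timecourse":
        df = _ly_egf_timecourse_rows(cfg)
    else:
        df = _apoptosis_panel_rows(cfg)

    if cfg.replicates > 1:
        reps = []
        for r in range(cfg.replicates):
            d = df.copy()
            d["condition_id"] = d["condition_id"] + f" | rep{r+1}"
            reps.append(d)
        df = pd.concat(reps, ignore_index=True)

    rng = np.random.default_rng(cfg.seed)
    clipped = 0
    values = df["value"].to_numpy(dtype=float).copy()
    is_apop = (df["readout"] == "apoptosis_pct").to_numpy()

    if cfg.n_cells and is_apop.any():
        p_dead = np.clip(values[is_apop] / 100.0, 0.0, 1.0)
        values[is_apop] = rng.binomial(cfg.n_cells, p_dead) / cfg.n_cells * 100.0

    sig = ~is_apop
    if cfg.noise_lognorm_sd > 0 and sig.any():
        values[sig] = values[sig] * np.exp(rng.normal(0.0, cfg.noise_lognorm_sd, sig.sum()))
    if cfg.noise_additive_sd > 0 and sig.any():
        values[sig] = values[sig] + rng.normal(0.0, cfg.noise_additive_sd, sig.sum())
        neg = sig & (values < 0)
        clipped = int(neg.sum())
        values[values < 0] = 0.0

    df = df.copy()
    df["value"] = values
    meta = {
        "design": cfg.design, "seed": cfg.seed,
        "noise_lognorm_sd": cfg.noise_lognorm_sd,
        "noise_additive_sd": cfg.noise_additive_sd,
        "n_cells": cfg.n_cells, "replicates": cfg.replicates,
        "apoptosis_model": cfg.apoptosis_model.value,
        "ground_truth": cfg.params.to_dict(include_derived=True),
        "clipped": clipped,
        "epinephrine_nM_to_stress": "log10(1 + c_nM)",
    }
    return ObservationTable(df, meta=meta)


def make_fixture_suite(params: ParameterSet, seed: int) -> dict[str, ObservationTable]:
    """Small bundle of tables exercising every pipeline stage.

    Contains noiseless and noisy variants of both signaling designs and of
    the apoptosis train/holdout splits under both apoptosis model variants.
    Byte-stable under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    seeds = iter(rng.integers(0, 2**31 - 1, size=16))
    out: dict[str, ObservationTable] = {}
    for design in ("epi_dose_series", "ly_egf_timecourse"):
        out[f"{design}_noiseless"] = generate(GeneratorConfig(
            params=params, design=design, seed=int(next(seeds)),
            noise_lognorm_sd=0.0, n_cells=0,
        ))
        out[f"{design}_noisy"] = generate(GeneratorConfig(
            params=params, design=design, seed=int(next(seeds)),
        ))
    fit_times = tuple(apoptosis_fit_times())
    for variant in (ApoptosisModel.BAD_ONLY, ApoptosisModel.BAD_MCL1):
        tag = variant.value
        out[f"apoptosis_train_{tag}_noiseless"] = generate(GeneratorConfig(
            params=params, design="apoptosis_panel", seed=int(next(seeds)),
            noise_lognorm_sd=0.0, n_cells=0, apoptosis_model=variant,
            treatments=APOPTOSIS_TRAIN_TREATMENTS, times=fit_times,
        ))
        out[f"apoptosis_holdout_{tag}_noiseless"] = generate(GeneratorConfig(
            params=params, design="apoptosis_panel", seed=int(next(seeds)),
            noise_lognorm_sd=0.0, n_cells=0, apoptosis_model=variant,
            treatments=APOPTOSIS_HOLDOUT_TREATMENTS, times=(48.0,),
        ))
        out[f"apoptosis_train_{tag}_noisy"] = generate(GeneratorConfig(
            params=params, design="apoptosis_panel", seed=int(next(seeds)),
            apoptosis_model=variant,
            treatments=APOPTOSIS_TRAIN_TREATMENTS, times=fit_times,
        ))
        out[f"apoptosis_holdout_{tag}_noisy"] = generate(GeneratorConfig(
            params=params, design="apoptosis_panel", seed=int(next(seeds)),
            apoptosis_model=variant,
            treatments=APOPTOSIS_HOLDOUT_TREATMENTS, times=(48.0,),
        ))
    return out
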