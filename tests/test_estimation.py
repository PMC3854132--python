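"""Objective, genetic algorithm, dataset scaling and model selection."""

import numpy as np
import pandas as pd
import pytest

from badnet.errors import ConfigurationError, ContractViolationError
from badnet.estimation import (
    FitConfig,
    ObservationTable,
    _ga_minimize,
    fit,
    model_select,
    objective,
    scale_apoptosis_datasets,
    simulate_observations,
)
from badnet.model_core import parse_treatment
from badnet.simulation import ApoptosisModel


class TestObservationTable:
    def test_schema_enforced(self):
        with pytest.raises(ContractViolationError):
            ObservationTable(pd.DataFrame({"condition_id": ["a"], "value": [1.0]}))

    def test_negative_values_rejected(self, noiseless_signaling):
        df = noiseless_signaling.df.copy()
        df.loc[df.index[0], "value"] = -0.1
        with pytest.raises(ContractViolationError):
            ObservationTable(df)

    def test_duplicate_keys_rejected(self, noiseless_signaling):
        df = pd.concat([noiseless_signaling.df, noiseless_signaling.df.iloc[[0]]],
                       ignore_index=True)
        with pytest.raises(ContractViolationError):
            ObservationTable(df)


class TestObjective:
    def test_self_fit_is_zero(self, ref_params, noiseless_signaling, noiseless_apoptosis_train):
        assert objective(ref_params, noiseless_signaling) == pytest.approx(0.0, abs=1e-16)
        assert objective(ref_params, noiseless_apoptosis_train) == pytest.approx(0.0, abs=1e-16)

    def test_constant_offset_gives_analytic_mse(self, ref_params, noiseless_signaling):
        shifted = ObservationTable(
            noiseless_signaling.df.assign(value=noiseless_signaling.df["value"] + 0.1)
        )
        assert objective(ref_params, shifted) == pytest.approx(0.01, rel=1e-9)

    def test_row_order_invariance(self, ref_params, noiseless_signaling):
        shuffled = ObservationTable(
            noiseless_signaling.df.sample(frac=1.0, random_state=0).reset_index(drop=True)
        )
        perturbed = ref_params.with_values({"K8": ref_params.get("K8") * 1.3})
        assert objective(perturbed, shuffled) == pytest.approx(
            objective(perturbed, noiseless_signaling), rel=1e-12
        )

    def test_apoptosis_residuals_on_fraction_scale(self, ref_params, noiseless_apoptosis_train):
        """A constant +10 percentage-point offset contributes (0.1)^2 = 0.01."""
        shifted = ObservationTable(
            noiseless_apoptosis_train.df.assign(
                value=noiseless_apoptosis_train.df["value"] + 10.0
            )
        )
        assert objective(ref_params, shifted) == pytest.approx(0.01, rel=1e-9)

    def test_unmappable_condition_is_named(self, ref_params, noiseless_signaling):
        df = noiseless_signaling.df.copy()
        df.loc[df.index[0], "treatment"] = "UNKNOWNDRUG:1"
        with pytest.raises(ConfigurationError, match="UNKNOWNDRUG"):
            objective(ref_params, ObservationTable(df))


class TestGeneticAlgorithm:
    def test_bounds_respected_in_every_generation(self):
        lo = np.array([-2.0, 0.0])
        hi = np.array([1.0, 3.0])
        seen = []

        def fun(x):
            seen.append(x.copy())
            return float(np.sum((x - 0.5) ** 2))

        cfg = FitConfig(free=["K8", "K12"], population=12, generations=10, seed=4)
        best, val, hist, n_eval = _ga_minimize(fun, lo, hi, cfg)
        seen = np.array(seen)
        assert np.all(seen >= lo - 1e-12) and np.all(seen <= hi + 1e-12)
        assert n_eval == len(seen)
        assert hist[-1] <= hist[0]

    def test_history_monotone_with_elitism(self):
        cfg = FitConfig(free=["K8"], population=10, generations=15, seed=1)
        _, _, hist, _ = _ga_minimize(
            lambda x: float(np.cos(3 * x[0]) + x[0] ** 2), np.array([-3.0]), np.array([3.0]), cfg
        )
        assert np.all(np.diff(hist) <= 0)

    def test_fit_determinism_under_seed(self, ref_params, noiseless_signaling):
        cfg = FitConfig(free=["K8", "K12"], population=8, generations=4, seed=7)
        a = fit(noiseless_signaling, cfg, base=ref_params)
        b = fit(noiseless_signaling, cfg, base=ref_params)
        assert a.mse == b.mse
        assert np.array_equal(a.history, b.history)
        assert a.params.to_dict() == b.params.to_dict()

    def test_invalid_configs(self):
        with pytest.raises(ConfigurationError):
            FitConfig(free=[])
        with pytest.raises(ConfigurationError):
            FitConfig(free=["not_a_param"])
        with pytest.raises(ConfigurationError):
            FitConfig(free=["K8"], bounds={"K8": (1.0, 0.1)})
        with pytest.raises(ConfigurationError):
            fit(ObservationTable(pd.DataFrame(columns=[
                "condition_id", "treatment", "readout", "time_h", "value", "normalization"
            ])), FitConfig(free=["K8"]))

    def test_recovery_of_identifiable_parameters(self, ref_params, noiseless_signaling):
        """Seeded GA on noiseless data recovers identifiable parameters from
        distorted starting values (reduced budget)."""
        free = ["d3", "d10", "K8", "K12"]
        start = ref_params.with_values(
            {n: ref_params.get(n) * f for n, f in zip(free, (3.0, 0.4, 2.0, 0.5))}
        )
        cfg = FitConfig(free=free, population=30, generations=40, seed=2)
        res = fit(noiseless_signaling, cfg, base=start)
        assert res.mse < 1e-2
        for name in free:
            assert res.params.get(name) == pytest.approx(ref_params.get(name), rel=0.25)


class TestScaling:
    def _table(self, scale=1.0):
        rows = []
        for treatment in ("LY", "LY + EGF:1@2", "LY + BADS112A"):
            cond = parse_treatment(treatment, horizon=48.0)
            rows.append({
                "condition_id": cond.label(), "treatment": treatment,
                "readout": "apoptosis_pct", "time_h": 48.0,
                "value": scale * {"LY": 40.0, "LY + EGF:1@2": 10.0, "LY + BADS112A": 70.0}[treatment],
                "normalization": "to_control",
            })
        return ObservationTable(pd.DataFrame(rows))

    def test_identical_tables_scale_factor_one(self):
        merged = scale_apoptosis_datasets([self._table(), self._table()])
        assert len(merged) == 6
        assert np.allclose(sorted(merged.df["value"]), sorted([10, 10, 40, 40, 70, 70]))

    def test_doubled_table_halved(self):
        merged = scale_apoptosis_datasets([self._table(), self._table(scale=2.0)])
        b = merged.df.iloc[3:]["value"].to_numpy()
        assert np.allclose(sorted(b), [10, 40, 70])

    def test_idempotent(self):
        once = scale_apoptosis_datasets([self._table(), self._table(scale=2.0)])
        again = scale_apoptosis_datasets([once])
        assert np.allclose(again.df["value"], once.df["value"])

    def test_missing_anchor_raises(self):
        broken = ObservationTable(self._table().df.iloc[[2]].reset_index(drop=True))
        with pytest.raises(ConfigurationError, match="anchor"):
            scale_apoptosis_datasets([self._table(), broken])


class TestModelSelection:
    def test_empty_holdout_rejected(self, ref_params, noiseless_apoptosis_train):
        empty = ObservationTable(noiseless_apoptosis_train.df.iloc[0:0])
        with pytest.raises(ConfigurationError):
            model_select(noiseless_apoptosis_train, empty, ref_params)

    def test_cached_apoptosis_objective_matches_full_path(
        self, ref_params, noiseless_apoptosis_train
    ):
        """The trajectory-caching objective used for apoptosis-stage fits is
        numerically identical to the full simulate-everything objective."""
        from badnet.estimation import _make_objective

        free = ["k_a", "k_creb"]
        fun = _make_objective(
            ref_params, noiseless_apoptosis_train, ApoptosisModel.BAD_MCL1, 0.01, free
        )
        x = np.log10([ref_params.get("k_a") * 1.7, ref_params.get("k_creb") * 0.6])
        direct = objective(
            ref_params.with_values({"k_a": 10 ** x[0], "k_creb": 10 ** x[1]}),
            noiseless_apoptosis_train,
            choice=ApoptosisModel.BAD_MCL1,
        )
        assert fun(x) == pytest.approx(direct, rel=1e-9)

    def test_simulated_observations_deterministic(self, ref_params, noiseless_signaling):
        a = simulate_observations(ref_params, noiseless_signaling)
        b = simulate_observations(ref_params, noiseless_signaling)
        assert np.array_equal(a, b)
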