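"""Unit and property tests for the domain types and the ODE right-hand side."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from badnet.errors import ConfigurationError, ContractViolationError, ParameterDomainError
from badnet.model_core import (
    BASELINE_STATE,
    INHIBITOR_TARGET_REACTION,
    INHIBITORS,
    ParameterSet,
    TreatmentCondition,
    bads112a_decay,
    derive_decay_rates,
    drug_factor,
    hill_activation,
    parse_treatment,
    rhs,
)
from badnet.simulation import integrate

from conftest import random_parameter_set


class TestHillActivation:
    @pytest.mark.parametrize(
        "x,v,k,n,expected",
        [
            (0.0, 3.0, 0.7, 2.0, 0.0),          # zero input
            (0.7, 2.0, 0.7, 1.0, 1.0),          # half-saturation identity
            (1e9, 5.0, 0.5, 2.0, 5.0),          # saturation limit
        ],
    )
    def test_known_values(self, x, v, k, n, expected):
        assert hill_activation(x, v, k, n) == pytest.approx(expected, abs=1e-6)

    def test_monotone_and_bounded(self):
        xs = np.linspace(0, 50, 200)
        ys = hill_activation(xs, 2.5, 0.8, 2.0)
        assert np.all(np.diff(ys) >= 0)
        assert np.all(ys <= 2.5)

    @pytest.mark.parametrize("bad", [dict(v=-1), dict(k=0), dict(n=0.5)])
    def test_domain_errors(self, bad):
        kw = dict(v=1.0, k=1.0, n=1.0)
        kw.update(bad)
        with pytest.raises(ParameterDomainError):
            hill_activation(1.0, **kw)


class TestDrugFactor:
    def test_half_maximal_convention(self):
        assert drug_factor(0.0) == 1.0
        assert drug_factor(1.0) == 0.5
        assert drug_factor(3.0) == 0.25

    def test_strictly_decreasing(self):
        doses = np.linspace(0, 20, 50)
        factors = [drug_factor(u) for u in doses]
        assert np.all(np.diff(factors) < 0)

    def test_negative_dose_rejected(self):
        with pytest.raises(ParameterDomainError):
            drug_factor(-0.1)


class TestBads112aDecay:
    def test_no_mutant_is_identity(self):
        assert bads112a_decay(1.3, 0.0) == 1.3

    def test_monotone_in_dose(self):
        rates = [bads112a_decay(1.3, u) for u in (0, 0.5, 1, 2, 10)]
        assert np.all(np.diff(rates) > 0)
        assert all(r >= 1.3 for r in rates)

    def test_domain_errors(self):
        with pytest.raises(ParameterDomainError):
            bads112a_decay(-1.0, 1.0)
        with pytest.raises(ParameterDomainError):
            bads112a_decay(1.0, -1.0)

    def test_steady_ps112_lower_under_mutant(self, ref_params):
        """Expressing the mutant lowers the steady phospho-S112 level."""
        base = integrate(ref_params, parse_treatment("control", horizon=24.0)).states[-1, 11]
        mutant = integrate(ref_params, parse_treatment("BADS112A", horizon=24.0)).states[-1, 11]
        assert mutant < base


class TestParameterSet:
    def test_free_parameter_counts(self):
        assert len(ParameterSet.signaling_free_names()) == 37
        assert len(ParameterSet.apoptosis_free_names()) == 7

    def test_positive_invariant_enforced(self):
        vm = np.full(14, 1.0)
        vm[3] = -0.2
        with pytest.raises(ParameterDomainError):
            ParameterSet(vmax=vm, km=np.full(14, 1.0))

    def test_unknown_name_rejected(self):
        with pytest.raises(ConfigurationError):
            ParameterSet.default().with_values({"V99": 1.0})

    def test_dict_round_trip(self, ref_params):
        clone = ParameterSet.from_dict(ref_params.to_dict())
        assert np.allclose(clone.vmax, ref_params.vmax)
        assert np.allclose(clone.decay_full(), ref_params.decay_full())


class TestDecayClosure:
    def test_akt_closure_matches_worked_case(self, ref_params):
        """AKT's derived decay is its baseline activation flux (PI3K and AKT
        steady states both 1): d8 = V8 * 1 / (K8^n + 1)."""
        p = ref_params
        d8 = derive_decay_rates(p)[1]
        expected = p.vmax[7] / (p.km[7] ** p.hill_n[7] + 1.0)
        assert d8 == pytest.approx(expected, rel=1e-12)

    def test_only_fed_decays_respond_to_vmax(self, ref_params):
        """Perturbing the AKT-equation velocity only changes decays fed by
        that flux (d8 itself and d13 is independent: it uses V13b)."""
        base = derive_decay_rates(ref_params)
        bumped = derive_decay_rates(ref_params.with_values({"V8": ref_params.get("V8") * 2}))
        assert bumped[1] == pytest.approx(base[1] * 2)
        assert bumped[[0, 2, 3]] == pytest.approx(base[[0, 2, 3]])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_baseline_fixed_point_for_random_parameters(self, seed):
        """With derived decay rates, the untreated baseline is stationary."""
        p = random_parameter_set(np.random.default_rng(seed))
        c = parse_treatment("control", horizon=10.0)
        drift = rhs(BASELINE_STATE, 0.5, p, c)
        assert np.abs(drift).max() < 1e-12

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_trajectories_stay_non_negative(self, seed):
        rng = np.random.default_rng(seed)
        p = random_parameter_set(rng)
        c = parse_treatment("EGF + STRESS:10 + LY:0.5", horizon=6.0)
        traj = integrate(p, c)
        assert traj.states.min() >= 0.0


class TestRhs:
    def test_contract_violations(self, ref_params):
        c = parse_treatment("control", horizon=1.0)
        with pytest.raises(ContractViolationError):
            rhs(np.zeros(5), 0.0, ref_params, c)
        bad = BASELINE_STATE.copy()
        bad[2] = -0.1
        with pytest.raises(ContractViolationError):
            rhs(bad, 0.0, ref_params, c)

    def test_erk_peaks_and_declines_under_egf(self, ref_params):
        """EGF drives a transient pERK peak that decays within the first hour."""
        traj = integrate(ref_params, parse_treatment("EGF", horizon=3.0))
        erk = traj.states[:, 2]
        t_peak = traj.times[np.argmax(erk)]
        assert 0.05 < t_peak < 1.2
        assert erk[-1] < 0.25 * erk.max()

    def test_ly_suppresses_steady_pakt(self, ref_params):
        base = integrate(ref_params, parse_treatment("control", horizon=12.0)).states[-1, 7]
        ly = integrate(ref_params, parse_treatment("LY", horizon=12.0)).states[-1, 7]
        assert ly < 0.7 * base

    @pytest.mark.parametrize("drug", [d for d in INHIBITORS if d != "BADS112A"])
    def test_drug_monotonicity_on_immediate_target(self, ref_params, drug):
        """Steady level of each inhibitor's target is non-increasing in dose."""
        # activate the pathway feeding the target so the response is visible
        background = "EGF + STRESS:10"
        target_species = {
            "AG1478": 0, "C4BRaf": 1, "DN-MEK1": 2, "N17Rac": 4,
            "DN-PAK1": 5, "LY294002": 6, "PKI-GFP": 9,
        }[drug]
        levels = []
        for u in (0.0, 0.5, 1.0, 2.0, 10.0):
            t = background if u == 0 else f"{background} + {drug}:{u}"
            traj = integrate(ref_params, parse_treatment(t, horizon=8.0))
            # EGFR-branch species carry a decaying transient; compare peaks there
            series = traj.states[:, target_species]
            levels.append(series.max() if target_species < 4 else series[-1])
        assert np.all(np.diff(levels) <= 1e-9)


class TestTreatmentParser:
    def test_aliases_and_defaults(self):
        c = parse_treatment("LY + EGF:1@2", horizon=10.0)
        assert c.inhibitors["LY294002"] == (1.0, 0.0)
        assert c.egf == (1.0, 2.0)

    def test_vip_and_epi_share_stress_channel(self):
        assert parse_treatment("VIP:100").stress == (100.0, 0.0)
        assert parse_treatment("EPI:100").stress == (100.0, 0.0)

    def test_repeated_inhibitor_doses_sum(self):
        c = parse_treatment("LY:0.6 + LY:0.4")
        assert c.inhibitors["LY294002"][0] == pytest.approx(1.0)

    def test_label_is_canonical_and_reparseable(self):
        c = parse_treatment("BADS112A + LY:2@1 + VIP:100")
        again = parse_treatment(c.label(), horizon=c.horizon)
        assert again.label() == c.label()

    def test_unknown_name_and_bad_onset(self):
        with pytest.raises(ConfigurationError):
            parse_treatment("WORTMANNIN:1")
        with pytest.raises(ConfigurationError):
            TreatmentCondition(inhibitors={"LY294002": (1.0, 99.0)}, horizon=10.0)

    def test_inhibitor_target_map_is_one_to_one(self):
        assert len(set(INHIBITOR_TARGET_REACTION.values())) == len(INHIBITOR_TARGET_REACTION)
        assert set(INHIBITOR_TARGET_REACTION) == set(INHIBITORS) - {"BADS112A"}
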