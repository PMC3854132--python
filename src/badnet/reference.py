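"""Synthetic reference parameter set.

The originally estimated parameter values for this network are not
available in machine-readable form, so reproduction runs use this
*synthetic* stand-in instead.  It was calibrated once, against the
qualitatively reported behaviour of the fitted model, by the following
construction criteria (see docs/methods.md for the rationale of each):

C1  pERK peaks under an EGF step and declines again within ~1 h.
C2  LY294002 suppresses steady pAKT; pS112/pS136-BAD fall to low levels
    under LY294002 + BADS112A.
C3  Untreated 48 h apoptosis is a few percent; LY294002 is the strongest
    single agent and LY294002 + BADS112A the strongest pair.
C4  Both LY294002 and BADS112A reach >25 % apoptosis as single agents, so
    the 25 % isobologram exists for both axes.
C5  The two single-agent dose-response curves have comparable potency
    (zero-dose slope ratio ~1) — required for the all-synergy pattern of
    the combination-index analysis at zero stress.
C6  Stress (epinephrine/VIP at level 100) suppresses drug-induced
    apoptosis and switches the synergism pattern to dose-dependent.

These are the study conditions the synthetic-data generator emulates; the
values are frozen and are not tuning knobs.
"""

import numpy as np

from .model_core import ApoptosisParams, ParameterSet

__all__ = ["reference_parameters"]


def reference_parameters() -> ParameterSet:
    """Return the synthetic reference :class:`ParameterSet` (fresh copy)."""
    return ParameterSet(
        #          V1  V2  V3  V4  V5  V6  V7  V8  V9 V10 V11  V12 V13a V13b
        vmax=np.array([6.0, 4.0, 4.0, 3.0, 2.0, 2.0, 2.0, 2.0, 3.0, 3.0, 2.0, 2.5, 1.5, 1.5]),
        #          K1   K2   K3   K4   K5   K6   K7   K8   K9  K10  K11  K12 K13a K13b
        km=np.array([0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 1.0, 1.1, 1.0, 0.5, 0.5, 0.8, 0.5, 1.6]),
        hill_n=np.full(14, 2.0),
        # d1..d4 (EGFR branch, x t): fast enough for a sub-hour pERK peak
        decay_time_scaled=np.array([4.0, 4.0, 4.0, 3.0]),
        # d5, d6, d9, d10, d11 (Rac, PAK, cAMP, PKA, CREB)
        decay_zero_baseline=np.array([2.0, 2.0, 3.0, 3.0, 2.0]),
        apoptosis=ApoptosisParams(
            k_a=1.7e-3,
            bad_total=1.35,
            k_bad=0.43,
            n_bad=3.8,
            w_s136=0.35,
            k_creb=0.5,
            n_creb=2.0,
        ),
    )
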