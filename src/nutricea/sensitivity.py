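"""One-way sensitivity analyses around the parity threshold.

Two published analyses are implemented, both under a 20%/20% reduction
in quarterly mortality and LTFU unless another effect is supplied:

* an ART program cost sweep ($500-$1200 per patient-year), with the
  lifetime cost per survivor rescaled proportionally to the annual cost
  and the stratum WTP re-benchmarked at each cost; and
* return to care of patients classified as LTFU at 6 months: a fraction
  of them later resumes care, generating the same lifetime costs and
  DALYs averted as 6-month survivors but no further supplementation.
  The ART-alone comparator is re-benchmarked under the same return
  assumption so parity compares like with like.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import pandas as pd

from .cohort import CohortStratumTable, QuarterTransition, RoundingMode, derive_transitions
from .markov import N_CYCLES, CohortOutcome, EconParams, run_cohort_model
from .thresholds import InterventionEffect, apply_effect

__all__ = [
    "BASE_EFFECT",
    "scaled_econ",
    "art_cost_sweep",
    "outcome_with_return",
    "ltfu_return_threshold",
]

#: Effect assumed by both published sensitivity analyses.
BASE_EFFECT = InterventionEffect(r_mort=0.2, r_ltfu=0.2)


def scaled_econ(annual_cost: float, base: EconParams = EconParams()) -> EconParams:
    """Economic parameters at a different annual ART cost.

    The lifetime cost per survivor is dominated by ART provision, so it
    is rescaled proportionally with the annual cost; DALYs averted are a
    health outcome and stay fixed.
    """
    return replace(
        base,
        annual_art_cost=annual_cost,
        lifetime_cost_per_survivor=base.lifetime_cost_per_survivor
        * annual_cost
        / base.annual_art_cost,
    )


def art_cost_sweep(
    table: CohortStratumTable,
    annual_costs: Sequence[float],
    effect: InterventionEffect = BASE_EFFECT,
    base: EconParams = EconParams(),
    rounding: RoundingMode = "percentages",
) -> pd.DataFrame:
    """S* across a range of annual ART program costs.

    Returns a frame with columns annual_cost, s_star; the stratum WTP is
    recomputed at each cost before solving for the supplement price.
    """
    from .thresholds import max_supplement_cost

    rows = [
        (c, max_supplement_cost(table, scaled_econ(c, base),
                                effect.r_mort, effect.r_ltfu, rounding))
        for c in annual_costs
    ]
    return pd.DataFrame(rows, columns=["annual_cost", "s_star"])


def outcome_with_return(
    transitions: Sequence[QuarterTransition],
    econ: EconParams,
    return_fraction: float,
) -> CohortOutcome:
    """Cohort outcome when a fraction of 6-month LTFU patients returns.

    Returned patients accrue the lifetime program cost net of the ART
    cost already accrued before exit (one quarter for Q1 exits, two for
    Q2 exits) and the full DALYs averted of a survivor; they receive no
    supplement beyond the quarters they actually entered, so supplement
    exposure is unchanged.
    """
    if not (0.0 <= return_fraction <= 1.0):
        raise ValueError("return_fraction must lie in [0, 1]")
    base = run_cohort_model(transitions, econ)
    t1, t2 = transitions[:N_CYCLES]
    ltfu_q1 = t1.p_ltfu
    ltfu_q2 = t1.p_alive * t2.p_ltfu
    q = econ.quarterly_art_cost
    extra_cost = return_fraction * (
        ltfu_q1 * (econ.lifetime_cost_per_survivor - 1 * q)
        + ltfu_q2 * (econ.lifetime_cost_per_survivor - 2 * q)
    )
    extra_dalys = return_fraction * (ltfu_q1 + ltfu_q2) * econ.dalys_per_survivor
    return CohortOutcome(
        six_month_survival=base.six_month_survival,
        quarterly_exposure=base.quarterly_exposure,
        expected_cost=base.expected_cost + extra_cost,
        expected_dalys=base.expected_dalys + extra_dalys,
        supplement_exposure=base.supplement_exposure,
    )


def ltfu_return_threshold(
    table: CohortStratumTable,
    return_fraction: float,
    effect: InterventionEffect = BASE_EFFECT,
    econ: EconParams = EconParams(),
    rounding: RoundingMode = "percentages",
) -> float:
    """Maximum supplement price when LTFU patients partially return.

    Both arms are evaluated under the same return assumption: the
    ART-alone WTP benchmark uses the historical transitions with
    returns, and the parity equation uses the intervention-adjusted
    transitions with returns.
    """
    historical = derive_transitions(table, rounding)[:N_CYCLES]
    comparator = outcome_with_return(historical, econ, return_fraction)
    wtp = comparator.expected_cost / comparator.expected_dalys

    adjusted = outcome_with_return(
        apply_effect(historical, effect), econ, return_fraction
    )
    return (
        wtp * adjusted.expected_dalys - adjusted.expected_cost
    ) / adjusted.supplement_exposure
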