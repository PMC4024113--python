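"""Willingness-to-pay benchmarks and supplement price thresholds.

The cost per DALY averted achieved by ART alone in a BMI stratum,
computed from the historical transition probabilities, defines the
willingness-to-pay (WTP) benchmark for that stratum.  A hypothetical
supplementation program multiplies the quarterly death and LTFU
probabilities by (1 - r_mort) and (1 - r_ltfu) respectively,
reallocating the difference to survival, and adds a quarterly
supplement cost for every patient entering a cycle.  The largest
supplement price S* at which the combined program's cost per DALY
averted still equals the stratum WTP solves a linear parity equation:

    (C' + S * E') / D' = WTP   =>   S* = (WTP * D' - C') / E'

where C', D' and E' are the intervention-adjusted expected ART cost,
DALYs averted, and quarter-entries per starting patient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cohort import (
    MALNOURISHED_STRATA,
    CohortStratumTable,
    QuarterTransition,
    RoundingMode,
    derive_transitions,
)
from .markov import N_CYCLES, CohortOutcome, EconParams, cost_per_daly, run_cohort_model

__all__ = [
    "InterventionEffect",
    "WtpBenchmark",
    "SCENARIOS",
    "apply_effect",
    "willingness_to_pay",
    "max_supplement_cost",
    "scenario_table",
    "retention_surface",
    "parity_frontier",
]

#: The four published effect scenarios: (r_mort, r_ltfu).
SCENARIOS = ((0.2, 0.0), (0.0, 0.2), (0.2, 0.2), (0.5, 0.5))


@dataclass(frozen=True)
class InterventionEffect:
    """Proportional reductions conferred by supplementation.

    ``r_mort`` and ``r_ltfu`` multiply the quarterly death and LTFU
    probabilities by (1 - r) over the 2-cycle supplementation period.
    """

    r_mort: float
    r_ltfu: float
    quarterly_supplement_cost: float = 0.0
    duration_cycles: int = N_CYCLES

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_mort <= 1.0 and 0.0 <= self.r_ltfu <= 1.0):
            raise ValueError("proportional reductions must lie in [0, 1]")
        if self.quarterly_supplement_cost < 0:
            raise ValueError("quarterly supplement cost must be >= 0")
        if self.duration_cycles != N_CYCLES:
            raise ValueError(f"the model supports exactly {N_CYCLES} cycles")


@dataclass(frozen=True)
class WtpBenchmark:
    """ART-alone cost per DALY averted for one stratum (USD/DALY)."""

    stratum_label: str
    wtp: float

    def __post_init__(self) -> None:
        if self.wtp <= 0:
            raise ValueError("WTP must be positive")


def apply_effect(
    transitions: Sequence[QuarterTransition], effect: InterventionEffect
) -> tuple[QuarterTransition, ...]:
    """Scale death/LTFU probabilities down and renormalize to survival."""
    out = []
    for t in transitions:
        p_dead = t.p_dead * (1.0 - effect.r_mort)
        p_ltfu = t.p_ltfu * (1.0 - effect.r_ltfu)
        out.append(QuarterTransition(1.0 - p_dead - p_ltfu, p_dead, p_ltfu))
    return tuple(out)


def willingness_to_pay(
    table: CohortStratumTable,
    econ: EconParams,
    rounding: RoundingMode = "percentages",
) -> WtpBenchmark:
    """Benchmark cost per DALY averted of ART alone in this stratum."""
    transitions = derive_transitions(table, rounding)[:N_CYCLES]
    outcome = run_cohort_model(transitions, econ)
    return WtpBenchmark(table.stratum_label, cost_per_daly(outcome))


def _adjusted_outcome(
    table: CohortStratumTable,
    effect: InterventionEffect,
    econ: EconParams,
    rounding: RoundingMode,
) -> CohortOutcome:
    transitions = apply_effect(derive_transitions(table, rounding)[:N_CYCLES], effect)
    return run_cohort_model(transitions, econ)


def max_supplement_cost(
    table: CohortStratumTable,
    econ: EconParams,
    r_mort: float,
    r_ltfu: float,
    rounding: RoundingMode = "percentages",
    wtp: float | None = None,
) -> float:
    """Maximum quarterly supplement price S* preserving parity with ART alone.

    The supplement is costed like ART: one quarter's price per patient
    entering each of the two cycles under the intervention-adjusted
    survival.  ``wtp`` overrides the benchmark (used by sensitivity
    analyses that re-benchmark the comparator); by default it is this
    stratum's own historical WTP.  A negative return means no positive
    price achieves parity; a warning is emitted.
    """
    if wtp is None:
        wtp = willingness_to_pay(table, econ, rounding).wtp
    adj = _adjusted_outcome(
        table, InterventionEffect(r_mort, r_ltfu), econ, rounding
    )
    s_star = (wtp * adj.expected_dalys - adj.expected_cost) / adj.supplement_exposure
    if s_star < 0:
        warnings.warn(
            f"stratum {table.stratum_label!r}: no positive supplement price "
            f"achieves parity (S*={s_star:.4f})",
            stacklevel=2,
        )
    return s_star


def scenario_table(
    tables: dict[str, CohortStratumTable],
    econ: EconParams,
    rounding: RoundingMode = "percentages",
    scenarios: Sequence[tuple[float, float]] = SCENARIOS,
) -> pd.DataFrame:
    """S* matrix for the published scenarios across malnourished strata.

    Rows are (r_mort, r_ltfu) scenarios; columns are the three
    malnourished BMI strata.
    """
    missing = [s for s in MALNOURISHED_STRATA if s not in tables]
    if missing:
        raise KeyError(f"missing malnourished strata: {missing}")
    records = {}
    for stratum in MALNOURISHED_STRATA:
        records[stratum] = [
            max_supplement_cost(tables[stratum], econ, rm, rl, rounding)
            for rm, rl in scenarios
        ]
    index = pd.MultiIndex.from_tuples(scenarios, names=["r_mort", "r_ltfu"])
    return pd.DataFrame(records, index=index)


def retention_surface(
    table: CohortStratumTable,
    r_mort_grid: Sequence[float],
    r_ltfu_grid: Sequence[float],
    rounding: RoundingMode = "percentages",
) -> pd.DataFrame:
    """Six-month alive/active percentage over an effect grid.

    Tidy frame with columns r_mort, r_ltfu, pct_alive; the (0, 0) cell
    equals the historical six-month retention.
    """
    base = derive_transitions(table, rounding)[:N_CYCLES]
    rows = []
    for rm in r_mort_grid:
        for rl in r_ltfu_grid:
            adj = apply_effect(base, InterventionEffect(rm, rl))
            survival = adj[0].p_alive * adj[1].p_alive
            rows.append((rm, rl, 100.0 * survival))
    return pd.DataFrame(rows, columns=["r_mort", "r_ltfu", "pct_alive"])


def parity_frontier(
    table: CohortStratumTable,
    econ: EconParams,
    supplement_cost: float,
    resolution: float = 0.005,
    rounding: RoundingMode = "percentages",
    r_tol: float = 1e-6,
) -> pd.DataFrame:
    """(r_mort, r_ltfu) combinations where S* equals the supplement price.

    For each r_mort on a [0, 1] grid, solves (bracketed root finding,
    tolerance ``r_tol`` on r) for the r_ltfu making the parity price
    equal ``supplement_cost``; effect pairs below the frontier are
    strictly more cost-effective than ART alone.  Grid points with no
    solution in [0, 1] are omitted.
    """
    if supplement_cost < 0:
        raise ValueError("supplement_cost must be >= 0")
    wtp = willingness_to_pay(table, econ, rounding).wtp

    def gap(rm: float, rl: float) -> float:
        return (
            max_supplement_cost(table, econ, rm, rl, rounding, wtp=wtp)
            - supplement_cost
        )

    rows = []
    for rm in np.arange(0.0, 1.0 + resolution / 2, resolution):
        rm = min(float(rm), 1.0)
        lo, hi = gap(rm, 0.0), gap(rm, 1.0)
        if lo == 0.0:
            rows.append((rm, 0.0))
            continue
        if lo > 0.0 or hi < 0.0:
            continue  # no r_ltfu in [0, 1] reaches parity at this r_mort
        rl = brentq(lambda r: gap(rm, r), 0.0, 1.0, xtol=r_tol)
        rows.append((rm, float(rl)))
    return pd.DataFrame(rows, columns=["r_mort", "r_ltfu"])
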