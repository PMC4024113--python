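"""BMI-stratified quarterly cohort disposition tables.

The historical inputs to the cost-effectiveness model are disposition
counts for adults starting antiretroviral therapy (ART), stratified by
WHO malnutrition category (body mass index at treatment start) and
followed in 90-day quarters.  At the end of each quarter every patient
who entered it is classified as alive/active in care, dead, or lost to
follow-up (LTFU); survivors enter the next quarter.  This module loads
and validates such tables and derives the conditional quarterly
transition probabilities that drive the Markov cohort model.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal

__all__ = [
    "STRATA",
    "MALNOURISHED_STRATA",
    "CohortValidationError",
    "QuarterDisposition",
    "QuarterTransition",
    "CohortStratumTable",
    "load_cohort_table",
    "write_cohort_table",
    "packaged_cohort_path",
    "derive_transitions",
    "cumulative_disposition",
]

#: WHO BMI categories (kg/m^2) in the reference cohort, from severe
#: malnutrition to normal-range.
STRATA = ("<16.0", "16.00-16.99", "17.00-18.49", ">18.5")

#: The three malnourished strata modelled for supplementation.
MALNOURISHED_STRATA = STRATA[:3]

RoundingMode = Literal["counts", "percentages"]


class CohortValidationError(ValueError):
    """A cohort table violates a structural invariant."""


@dataclass(frozen=True)
class QuarterDisposition:
    """Disposition counts for one 90-day quarter of one BMI stratum.

    ``n_entering`` patients are alive and active at the quarter start;
    by quarter end each is exactly one of alive, dead, or LTFU.
    """

    quarter_index: int
    n_entering: int
    n_alive: int
    n_dead: int
    n_ltfu: int

    def __post_init__(self) -> None:
        for name in ("n_entering", "n_alive", "n_dead", "n_ltfu"):
            if getattr(self, name) < 0:
                raise CohortValidationError(
                    f"quarter {self.quarter_index}: {name} is negative"
                )
        if self.n_alive + self.n_dead + self.n_ltfu != self.n_entering:
            raise CohortValidationError(
                f"quarter {self.quarter_index}: dispositions "
                f"{self.n_alive}+{self.n_dead}+{self.n_ltfu} do not sum to "
                f"n_entering={self.n_entering}"
            )


@dataclass(frozen=True)
class QuarterTransition:
    """Conditional one-quarter transition row (alive, dead, LTFU).

    Probabilities are conditional on being alive/active at the quarter
    start; dead and LTFU are absorbing states so the row fully
    determines the quarter.
    """

    p_alive: float
    p_dead: float
    p_ltfu: float

    def __post_init__(self) -> None:
        for name in ("p_alive", "p_dead", "p_ltfu"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise CohortValidationError(f"{name}={p} outside [0, 1]")
        total = self.p_alive + self.p_dead + self.p_ltfu
        if not math.isclose(total, 1.0, rel_tol=0.0, abs_tol=1e-9):
            raise CohortValidationError(
                f"transition probabilities sum to {total!r}, not 1"
            )

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.p_alive, self.p_dead, self.p_ltfu)


@dataclass(frozen=True)
class CohortStratumTable:
    """Ordered quarterly dispositions for one BMI stratum."""

    stratum_label: str
    quarters: tuple[QuarterDisposition, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.quarters:
            raise CohortValidationError(
                f"stratum {self.stratum_label!r}: no quarters"
            )
        for i, q in enumerate(self.quarters, start=1):
            if q.quarter_index != i:
                raise CohortValidationError(
                    f"stratum {self.stratum_label!r}: quarter indices not "
                    f"consecutive from 1 (found {q.quarter_index} at position {i})"
                )
        for prev, nxt in zip(self.quarters, self.quarters[1:]):
            if nxt.n_entering != prev.n_alive:
                raise CohortValidationError(
                    f"stratum {self.stratum_label!r}: quarter "
                    f"{nxt.quarter_index} enters {nxt.n_entering} patients but "
                    f"quarter {prev.quarter_index} ended with {prev.n_alive} alive"
                )

    @property
    def n_quarters(self) -> int:
        return len(self.quarters)

    @property
    def n_start(self) -> int:
        """Cohort size at the start of quarter 1."""
        return self.quarters[0].n_entering


def _coerce_int(value: str, *, context: str) -> int:
    try:
        return int(value)
    except (TypeError, ValueError):
        raise CohortValidationError(f"{context}: {value!r} is not an integer")


def load_cohort_table(source: str | Path) -> dict[str, CohortStratumTable]:
    """Read a stratified cohort disposition CSV.

    The schema is ``stratum,quarter,n_entering,n_alive,n_dead,n_ltfu``
    with one row per stratum-quarter.  Returns one validated
    :class:`CohortStratumTable` per stratum, keyed by label, preserving
    file order of strata.
    """
    path = Path(source)
    rows_by_stratum: dict[str, list[QuarterDisposition]] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"stratum", "quarter", "n_entering", "n_alive", "n_dead", "n_ltfu"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise CohortValidationError(
                f"{path}: header must contain {sorted(required)}"
            )
        for lineno, row in enumerate(reader, start=2):
            stratum = (row["stratum"] or "").strip()
            if not stratum:
                raise CohortValidationError(f"{path}:{lineno}: empty stratum label")
            ctx = f"{path}:{lineno} (stratum {stratum!r})"
            disp = QuarterDisposition(
                quarter_index=_coerce_int(row["quarter"], context=ctx),
                n_entering=_coerce_int(row["n_entering"], context=ctx),
                n_alive=_coerce_int(row["n_alive"], context=ctx),
                n_dead=_coerce_int(row["n_dead"], context=ctx),
                n_ltfu=_coerce_int(row["n_ltfu"], context=ctx),
            )
            rows_by_stratum.setdefault(stratum, []).append(disp)
    if not rows_by_stratum:
        raise CohortValidationError(f"{path}: no data rows")
    return {
        label: CohortStratumTable(
            stratum_label=label,
            quarters=tuple(sorted(quarters, key=lambda q: q.quarter_index)),
        )
        for label, quarters in rows_by_stratum.items()
    }


def write_cohort_table(
    tables: Iterable[CohortStratumTable], dest: str | Path
) -> Path:
    """Write tables back to the CSV schema; inverse of :func:`load_cohort_table`."""
    path = Path(dest)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["stratum", "quarter", "n_entering", "n_alive", "n_dead", "n_ltfu"])
        for table in tables:
            for q in table.quarters:
                writer.writerow(
                    [table.stratum_label, q.quarter_index, q.n_entering,
                     q.n_alive, q.n_dead, q.n_ltfu]
                )
    return path


def packaged_cohort_path() -> Path:
    """Path of the packaged Zambian national ART program cohort fixture.

    Quarterly dispositions for 58,380 adults starting ART in Lusaka
    district clinics (May 2004 - October 2010), stratified by baseline
    BMI; the basis of all published transition probabilities.
    """
    return Path(resources.files("nutricea.data") / "zambia_art_cohort.csv")


def _rounded_percentage_triple(q: QuarterDisposition) -> tuple[float, float, float]:
    # One-decimal percentages, as printed in the source table, then /100
    # and renormalized: the original analysis consumed rounded inputs.
    pct = tuple(
        round(100.0 * n / q.n_entering, 1)
        for n in (q.n_alive, q.n_dead, q.n_ltfu)
    )
    total = sum(pct)
    if abs(total - 100.0) > 0.1 + 1e-12:
        raise CohortValidationError(
            f"quarter {q.quarter_index}: rounded percentages sum to {total}, "
            "more than 0.1 from 100"
        )
    return tuple(p / total for p in pct)  # type: ignore[return-value]


def derive_transitions(
    table: CohortStratumTable, rounding: RoundingMode = "percentages"
) -> tuple[QuarterTransition, ...]:
    """Derive per-quarter transition rows from disposition counts.

    rounding="counts" divides the raw counts exactly; "percentages"
    (default) reproduces the one-decimal printed percentages (each count
    share rounded to 0.1%, renormalized), which is how the published
    threshold values are best reproduced.
    """
    if rounding not in ("counts", "percentages"):
        raise ValueError(f"unknown rounding mode {rounding!r}")
    out = []
    for q in table.quarters:
        if q.n_entering == 0:
            raise CohortValidationError(
                f"stratum {table.stratum_label!r}, quarter {q.quarter_index}: "
                "no patients entering; conditional probabilities undefined"
            )
        if rounding == "counts":
            triple = (
                q.n_alive / q.n_entering,
                q.n_dead / q.n_entering,
                q.n_ltfu / q.n_entering,
            )
        else:
            triple = _rounded_percentage_triple(q)
        out.append(QuarterTransition(*triple))
    return tuple(out)


def cumulative_disposition(
    table: CohortStratumTable, through_quarter: int
) -> tuple[float, float, float]:
    """Cumulative (alive, dead, LTFU) fractions of the starting cohort.

    Computed from raw counts: the dead fraction through quarter Q is the
    sum of deaths in quarters 1..Q over the quarter-1 cohort size, and
    likewise for LTFU; the alive fraction is the complement (patients
    still active at the end of quarter Q).
    """
    if not (1 <= through_quarter <= table.n_quarters):
        raise ValueError(
            f"through_quarter={through_quarter} outside 1..{table.n_quarters}"
        )
    n0 = table.n_start
    quarters = table.quarters[:through_quarter]
    dead = sum(q.n_dead for q in quarters) / n0
    ltfu = sum(q.n_ltfu for q in quarters) / n0
    alive = quarters[-1].n_alive / n0
    return (alive, dead, ltfu)
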