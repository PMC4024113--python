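"""Supplement ration masses, quarterly commodity costs, and affordability.

The modelled ration supplies a fixed daily energy target for one
90-day quarter.  The base target of 1,360 kcal/day represents half the
WFP recommended minimum adult intake of 2,100 kcal/day, raised by 30%
for the elevated resting metabolic rate of advanced HIV infection
(the derivation gives 1,365; the published costing uses 1,360).
Quarterly cost is mass times commodity price, with the mass rounded to
0.01 kg before pricing as in the published cost table.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "SupplementProduct",
    "RationSpec",
    "load_products",
    "packaged_products_path",
    "kcal_target",
    "quarterly_quantity_kg",
    "quarterly_cost",
    "affordability_report",
]


@dataclass(frozen=True)
class SupplementProduct:
    """A candidate supplement commodity (energy density and unit price)."""

    name: str
    kcal_per_100g: float
    price_per_kg: float
    protein_pct_kcal: float | None = None
    fat_pct_kcal: float | None = None

    def __post_init__(self) -> None:
        if self.kcal_per_100g <= 0:
            raise ValueError(f"{self.name}: energy density must be positive")
        if self.price_per_kg < 0:
            raise ValueError(f"{self.name}: price must be >= 0")


@dataclass(frozen=True)
class RationSpec:
    """Daily energy target (kcal) sustained for a number of days."""

    target_kcal_per_day: float = 1360.0
    duration_days: int = 90

    def __post_init__(self) -> None:
        if self.target_kcal_per_day <= 0 or self.duration_days <= 0:
            raise ValueError("ration target and duration must be positive")


def packaged_products_path() -> Path:
    """Path of the packaged commodity fixture (RUTF, CSB, maize, rice)."""
    return Path(resources.files("nutricea.data") / "supplement_products.yaml")


def load_products(source: str | Path | None = None) -> dict[str, SupplementProduct]:
    """Read commodity definitions from a YAML file (packaged set by default)."""
    path = Path(source) if source is not None else packaged_products_path()
    with path.open(encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    products = {}
    for entry in raw["products"]:
        entry = {k: v for k, v in entry.items() if k != "description"}
        product = SupplementProduct(**entry)
        products[product.name] = product
    return products


def kcal_target(
    base_intake: float = 2100.0,
    fraction: float = 0.5,
    metabolic_increase: float = 0.3,
) -> float:
    """Daily energy target: a fraction of a recommended intake, scaled up
    for the metabolic increase of advanced HIV infection."""
    if min(base_intake, fraction) <= 0 or metabolic_increase < 0:
        raise ValueError("inputs must be positive")
    return base_intake * fraction * (1.0 + metabolic_increase)


def quarterly_quantity_kg(product: SupplementProduct, ration: RationSpec) -> float:
    """Kilograms of product supplying the daily target for the ration period.

    kg/day = (kcal/day) / (kcal per 100 g) * 0.1.  Unrounded; round to
    two decimals only for presentation.
    """
    return ration.target_kcal_per_day / product.kcal_per_100g * 0.1 * ration.duration_days


def quarterly_cost(
    product: SupplementProduct,
    ration: RationSpec = RationSpec(),
    mass_decimals: int | None = 2,
) -> float:
    """Commodity cost of one quarterly ration, USD.

    The ration mass is rounded to ``mass_decimals`` (default 0.01 kg,
    matching the published costing) before multiplying by the unit
    price; pass None to price the exact mass.
    """
    kg = quarterly_quantity_kg(product, ration)
    if mass_decimals is not None:
        kg = round(kg, mass_decimals)
    return kg * product.price_per_kg


def affordability_report(
    products: dict[str, SupplementProduct],
    scenario_thresholds: pd.DataFrame,
    ration: RationSpec = RationSpec(),
) -> pd.DataFrame:
    """Cost-effectiveness verdicts: product ration cost vs parity threshold.

    ``scenario_thresholds`` is the scenario-by-stratum S* matrix
    (rows indexed by (r_mort, r_ltfu), one column per stratum).  A
    product is cost-effective for a cell when its quarterly ration cost
    does not exceed the threshold.
    """
    rows = []
    for name, product in products.items():
        cost = quarterly_cost(product, ration)
        for (rm, rl), thresholds in scenario_thresholds.iterrows():
            for stratum, s_star in thresholds.items():
                rows.append(
                    {
                        "product": name,
                        "quarterly_cost": cost,
                        "stratum": stratum,
                        "r_mort": rm,
                        "r_ltfu": rl,
                        "s_star": s_star,
                        "cost_effective": bool(cost <= s_star),
                    }
                )
    return pd.DataFrame(rows)
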