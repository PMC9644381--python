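"""Plan simulation-box compositions from target weight fractions.

Given target drug/water weight percentages and a protein count, the planner
converts mass balance into integer molecule counts and reports the *achieved*
fractions recomputed from those counts.  Integer rounding means achieved
fractions deviate from targets by at most one molecule's worth of mass; the
achieved values are what downstream modules should quote.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .model import DomainError

__all__ = [
    "MW_DRUG",
    "MW_PROTEIN",
    "MW_WATER",
    "SystemPlan",
    "plan_system",
    "describe_paper_grid",
    "DRY_GRID_FRACTIONS",
    "HUMID_GRID_FRACTIONS",
]

#: Default molar masses (daltons): indomethacin, beta-lactoglobulin, water.
MW_DRUG = 381.37
MW_PROTEIN = 18300.0
MW_WATER = 18.015

#: Dry-scheme target drug weight fractions (percent).
DRY_GRID_FRACTIONS = (13.0, 25.0, 38.0, 50.0, 62.0, 75.0, 87.0, 100.0)
#: Humid-scheme target drug weight fractions (percent); water fixed at 5 wt%.
HUMID_GRID_FRACTIONS = (12.0, 22.5, 35.0, 47.5, 60.0, 72.5, 83.0)

#: Default drug count for protein-free (100% drug) boxes, where mass balance
#: against the protein gives no scale.
DEFAULT_N_DRUG_PURE = 500


@dataclass(frozen=True)
class SystemPlan:
    """Integer molecule counts plus the achieved weight fractions (percent)."""

    drug_fraction_wt: float
    protein_fraction_wt: float
    water_fraction_wt: float
    n_protein: int
    n_drug: int
    n_water: int
    molar_masses: dict = field(
        default_factory=lambda: {"drug": MW_DRUG, "protein": MW_PROTEIN, "water": MW_WATER}
    )
    target_drug_fraction_wt: float = 0.0
    target_water_fraction_wt: float = 0.0

    def __post_init__(self) -> None:
        total = self.drug_fraction_wt + self.protein_fraction_wt + self.water_fraction_wt
        if self.n_drug + self.n_protein + self.n_water > 0 and abs(total - 100.0) > 0.5:
            raise DomainError(f"achieved fractions sum to {total}, expected 100 +/- 0.5")
        if min(self.n_protein, self.n_drug, self.n_water) < 0:
            raise DomainError("molecule counts must be non-negative")

    @property
    def total_mass(self) -> float:
        return (
            self.n_drug * self.molar_masses["drug"]
            + self.n_protein * self.molar_masses["protein"]
            + self.n_water * self.molar_masses["water"]
        )

    def to_dict(self) -> dict:
        return {
            "drug_fraction_wt": self.drug_fraction_wt,
            "protein_fraction_wt": self.protein_fraction_wt,
            "water_fraction_wt": self.water_fraction_wt,
            "n_protein": self.n_protein,
            "n_drug": self.n_drug,
            "n_water": self.n_water,
            "molar_masses": dict(self.molar_masses),
            "target_drug_fraction_wt": self.target_drug_fraction_wt,
            "target_water_fraction_wt": self.target_water_fraction_wt,
        }


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def plan_system(
    drug_fraction_wt: float,
    n_protein: int,
    water_fraction_wt: float = 0.0,
    mw_drug: float = MW_DRUG,
    mw_protein: float = MW_PROTEIN,
    mw_water: float = MW_WATER,
    n_drug_pure: int = DEFAULT_N_DRUG_PURE,
) -> SystemPlan:
    """Convert target weight fractions into integer molecule counts.

    The protein count is the anchor: ``n_drug`` and ``n_water`` are the
    rounded mass-balance solutions against ``n_protein`` protein molecules.
    For protein-free systems (protein fraction 0) the drug count defaults to
    ``n_drug_pure`` and water is balanced against the drug instead.
    Counts are rounded half-away-from-zero; achieved fractions are recomputed
    from the integer counts.
    """
    if not 0.0 <= drug_fraction_wt <= 100.0:
        raise DomainError(f"drug fraction must be in [0, 100], got {drug_fraction_wt}")
    if not 0.0 <= water_fraction_wt <= 20.0:
        raise DomainError(f"water fraction must be in [0, 20], got {water_fraction_wt}")
    if drug_fraction_wt + water_fraction_wt > 100.0:
        raise DomainError("drug + water fractions exceed 100%")
    f_protein = 100.0 - drug_fraction_wt - water_fraction_wt
    if n_protein == 0 and f_protein > 0:
        raise DomainError(
            f"protein fraction is {f_protein}% but n_protein is 0"
        )
    if n_protein > 0:
        protein_mass = n_protein * mw_protein
        n_drug = _round_half_away(drug_fraction_wt / f_protein * protein_mass / mw_drug)
        n_water = _round_half_away(water_fraction_wt / f_protein * protein_mass / mw_water)
    else:
        n_drug = n_drug_pure if drug_fraction_wt > 0 else 0
        if water_fraction_wt > 0 and drug_fraction_wt > 0:
            n_water = _round_half_away(
                water_fraction_wt / drug_fraction_wt * n_drug * mw_drug / mw_water
            )
        else:
            n_water = 0

    total = n_drug * mw_drug + n_protein * mw_protein + n_water * mw_water
    if total == 0:
        achieved = (0.0, 0.0, 0.0)
    else:
        achieved = (
            100.0 * n_drug * mw_drug / total,
            100.0 * n_protein * mw_protein / total,
            100.0 * n_water * mw_water / total,
        )
    return SystemPlan(
        drug_fraction_wt=achieved[0],
        protein_fraction_wt=achieved[1],
        water_fraction_wt=achieved[2],
        n_protein=n_protein,
        n_drug=n_drug,
        n_water=n_water,
        molar_masses={"drug": mw_drug, "protein": mw_protein, "water": mw_water},
        target_drug_fraction_wt=drug_fraction_wt,
        target_water_fraction_wt=water_fraction_wt,
    )


def _grid_n_protein(drug_fraction_wt: float) -> int:
    """Protein count scheme: 8 bodies below 40 wt% drug, 4 above, 0 at 100%."""
    if drug_fraction_wt >= 100.0:
        return 0
    return 8 if drug_fraction_wt < 40.0 else 4


def describe_paper_grid(
    mw_drug: float = MW_DRUG,
    mw_protein: float = MW_PROTEIN,
    mw_water: float = MW_WATER,
) -> list:
    """The 15 reference compositions: 8 dry plus 7 at fixed 5 wt% water."""
    plans = []
    for f in DRY_GRID_FRACTIONS:
        plans.append(
            plan_system(f, _grid_n_protein(f), 0.0, mw_drug, mw_protein, mw_water)
        )
    for f in HUMID_GRID_FRACTIONS:
        plans.append(
            plan_system(f, _grid_n_protein(f), 5.0, mw_drug, mw_protein, mw_water)
        )
    return plans
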