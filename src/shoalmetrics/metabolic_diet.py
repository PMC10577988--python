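"""Glucose-ketone index, ketosis classification, diet-mixture arithmetic
and supplement dose conversions.

The glucose-ketone index (GKI) is blood glucose over blood ketone, both in
mM; values below 9 indicate ketosis by the human criterion. Glucose meters
report mg/dL, converted with a divisor of 18.016 (glucose molar mass / 10)
by default; 18.0 is the common rounded convention and is configurable.

Diet mixing is ratio-weighted averaging of nutrient percentages and
caloric densities (e.g., a ketogenic feed made of a 3:1 human ketogenic
formula and a standard zebrafish diet at a 5:1 weight ratio). Dose
conversion assumes an agar-suspended feed density of 1 mg per uL and a
meal of 3% of body weight.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

__all__ = [
    "MetabolicPanel",
    "DietComponent",
    "DoseSpec",
    "DoseResult",
    "GLUCOSE_MG_DL_PER_MM",
    "KETOSIS_GKI_THRESHOLD",
    "gki",
    "mix_diets",
    "dose_convert",
    "round_pct",
]

#: mg/dL of glucose per mM (molar mass 180.16 g/mol over 10).
GLUCOSE_MG_DL_PER_MM = 18.016
#: GKI below this indicates ketosis (human criterion).
KETOSIS_GKI_THRESHOLD = 9.0


@dataclass(frozen=True)
class MetabolicPanel:
    """Glucose/ketone readings with derived GKI and ketosis call."""

    glucose_mM: float
    ketone_mM: float
    gki: float
    is_ketosis: bool
    glucose_input: float = float("nan")
    glucose_unit: str = "mM"
    divisor: float = GLUCOSE_MG_DL_PER_MM
    threshold: float = KETOSIS_GKI_THRESHOLD


@dataclass(frozen=True)
class DietComponent:
    """Named feed with nutrient percentages (by weight) and energy density."""

    name: str
    protein_pct: float
    lipid_pct: float
    carb_pct: float
    kcal_per_g: float

    def __post_init__(self) -> None:
        if min(self.protein_pct, self.lipid_pct, self.carb_pct) < 0:
            raise ValueError("nutrient percentages must be >= 0")
        if not self.kcal_per_g > 0:
            raise ValueError("kcal_per_g must be positive")


@dataclass(frozen=True)
class DoseSpec:
    """A supplement mixed into feed at a known concentration.

    ``diet_conc_mg_per_ml`` is the compound's concentration in the agar
    feed; ``meal_fraction`` is the meal size as a fraction of body weight
    (fish eat about 3% of their body weight per meal).
    """

    compound: str
    molar_mass: float
    diet_conc_mg_per_ml: float
    meal_fraction: float = 0.03

    def __post_init__(self) -> None:
        if not self.molar_mass > 0:
            raise ValueError("molar_mass must be positive")
        if not 0 < self.meal_fraction < 1:
            raise ValueError("meal_fraction must be in (0, 1)")
        if self.diet_conc_mg_per_ml < 0:
            raise ValueError("concentration must be >= 0")

    @property
    def conc_umol_per_ml(self) -> float:
        """Molar concentration in the feed (umol/mL)."""
        return self.diet_conc_mg_per_ml / self.molar_mass * 1000.0


@dataclass(frozen=True)
class DoseResult:
    """Per-meal intake for a fish of a given body weight."""

    body_g: float
    meal_mass_mg: float
    meal_volume_ul: float  # 1 mg feed ~ 1 uL
    intake_mg: float
    intake_umol: float
    umol_per_body_g: float
    mg_per_body_g: float


def gki(
    glucose: float,
    ketone_mM: float,
    glucose_unit: str = "mg/dL",
    divisor: float = GLUCOSE_MG_DL_PER_MM,
    threshold: float = KETOSIS_GKI_THRESHOLD,
) -> MetabolicPanel:
    """Glucose-ketone index and ketosis call.

    ``glucose`` in mg/dL (meter convention) or mM; ketone in mM. GKI is
    glucose (mM) / ketone (mM); ketosis iff GKI < ``threshold``.
    """
    if glucose < 0:
        raise ValueError("glucose must be >= 0")
    if not ketone_mM > 0:
        raise ValueError("GKI is undefined for ketone <= 0 mM")
    if glucose_unit == "mg/dL":
        glucose_mM = glucose / divisor
    elif glucose_unit == "mM":
        glucose_mM = glucose
    else:
        raise ValueError("glucose_unit must be 'mg/dL' or 'mM'")
    value = glucose_mM / ketone_mM
    return MetabolicPanel(
        glucose_mM=glucose_mM,
        ketone_mM=ketone_mM,
        gki=value,
        is_ketosis=value < threshold,
        glucose_input=glucose,
        glucose_unit=glucose_unit,
        divisor=divisor,
        threshold=threshold,
    )


def mix_diets(
    components: Sequence[DietComponent],
    weight_ratio: Sequence[float],
    name: str | None = None,
) -> DietComponent:
    """Ratio-weighted mixture of feeds (exact linear blend, unrounded).

    Nutrient percentages and kcal/g of the mixture are the weight-ratio
    weighted means of the components. Use :func:`round_pct` only at
    presentation time.
    """
    if len(components) != len(weight_ratio):
        raise ValueError("components and weight_ratio lengths differ")
    if not components:
        raise ValueError("need at least one component")
    if any(r <= 0 for r in weight_ratio):
        raise ValueError("weight ratios must be positive")
    total = float(sum(weight_ratio))

    def wmean(attr: str) -> float:
        return sum(
            getattr(c, attr) * r for c, r in zip(components, weight_ratio)
        ) / total

    mixed_name = name or " + ".join(
        f"{c.name}:{r:g}" for c, r in zip(components, weight_ratio)
    )
    return DietComponent(
        name=mixed_name,
        protein_pct=wmean("protein_pct"),
        lipid_pct=wmean("lipid_pct"),
        carb_pct=wmean("carb_pct"),
        kcal_per_g=wmean("kcal_per_g"),
    )


def round_pct(value: float, decimals: int = 1) -> float:
    """Half-up presentation rounding (47.55 -> 47.6), as nutrition tables
    print; banker's rounding would flip boundary cases."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def dose_convert(spec: DoseSpec, body_g: float) -> DoseResult:
    """Per-meal supplement intake for a fish of ``body_g`` grams.

    The meal is ``meal_fraction`` of body weight in mg of feed, taken as
    the same number of uL (agar feed density 1 mg/uL); intake follows from
    the feed concentration, with mass <-> mol via the molar mass.
    """
    if not body_g > 0:
        raise ValueError("body weight must be positive")
    meal_mass_mg = spec.meal_fraction * body_g * 1000.0
    meal_volume_ul = meal_mass_mg  # 1 mg ~ 1 uL
    intake_mg = spec.diet_conc_mg_per_ml * meal_volume_ul / 1000.0
    intake_umol = intake_mg / spec.molar_mass * 1000.0
    return DoseResult(
        body_g=body_g,
        meal_mass_mg=meal_mass_mg,
        meal_volume_ul=meal_volume_ul,
        intake_mg=intake_mg,
        intake_umol=intake_umol,
        umol_per_body_g=intake_umol / body_g,
        mg_per_body_g=intake_mg / body_g,
    )


# -- reference feed compositions (nutrition-label values) -------------------

BRINE_SHRIMP = DietComponent("brine shrimp", 58.4, 14.7, 5.2, 5.9)
ZEIGLER_DIET = DietComponent("Zeigler zebrafish standard diet", 54.0, 14.4, 11.6, 3.89)
KETOCAL_3_1 = DietComponent("KetoCal 3:1", 15.3, 67.7, 7.2, 6.99)


def control_diet() -> DietComponent:
    """Control feed: ketogenic formula and zebrafish diet at 1:5 by weight."""
    return mix_diets([KETOCAL_3_1, ZEIGLER_DIET], [1, 5], name="control diet")


def ketogenic_diet() -> DietComponent:
    """Ketogenic feed: ketogenic formula and zebrafish diet at 5:1 by weight."""
    return mix_diets([KETOCAL_3_1, ZEIGLER_DIET], [5, 1], name="ketogenic diet")
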