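"""Food composition table handling and rule-based glycemic-index assignment.

A food's glycemic (available) carbohydrate is total carbohydrate minus
dietary fiber, per 100 g edible portion. Its glycemic index (GI, glucose
reference = 100) is resolved through an explicit chain:

1. zero-GI class rules — diet/light carbonated beverages, high-alcohol
   distilled spirits, and meat/offal/sausages carry GI 0 by definition
   (negligible or no available carbohydrate); these rules override any
   conflicting table entry,
2. a direct (measured or literature) table entry,
3. a one-step "similar food in composition" substitution.

A food that exhausts the chain raises :class:`~glycoload.errors.UnresolvedGIError`
rather than being silently imputed.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from .errors import FoodTableError, InvalidCompositionError, UnresolvedGIError

logger = logging.getLogger(__name__)

#: validation ceiling for GI; glucose-reference foods can exceed 100
GI_MAX = 150.0


class GISource(str, enum.Enum):
    DIRECT = "direct"
    LITERATURE = "literature"
    SIMILAR_FOOD = "similar_food"
    RULE_ZERO = "rule_zero"
    UNRESOLVED = "unresolved"


class ZeroClass(str, enum.Enum):
    DIET_BEVERAGE = "diet_beverage"
    DISTILLED_SPIRIT = "distilled_spirit"
    MEAT_OFFAL_SAUSAGE = "meat_offal_sausage"


@dataclass
class FoodItem:
    """Composition and GI provenance for one food (per 100 g edible portion)."""

    food_id: str
    name: str
    total_carb_g: float
    fiber_g: float
    gi: Optional[float] = None
    gi_source: GISource = GISource.UNRESOLVED
    similar_food_id: Optional[str] = None
    zero_class: Optional[ZeroClass] = None
    protein_g: float = 0.0
    lipid_g: float = 0.0

    def __post_init__(self):
        if self.total_carb_g < 0 or self.fiber_g < 0:
            raise InvalidCompositionError(
                f"food {self.food_id!r}: negative composition "
                f"(carb={self.total_carb_g}, fiber={self.fiber_g})"
            )
        if self.gi is not None and not (0.0 <= self.gi <= GI_MAX):
            raise FoodTableError(
                f"food {self.food_id!r}: GI {self.gi} outside [0, {GI_MAX}]"
            )

    @property
    def glycemic_carb_per_100g(self) -> float:
        return glycemic_carb(self.total_carb_g, self.fiber_g)


def glycemic_carb(total_carb_g: float, fiber_g: float) -> float:
    """Glycemic (available) carbohydrate in grams: total carbohydrate minus fiber.

    Composition tables occasionally report fiber exceeding total carbohydrate;
    the difference is clamped to 0 (and logged) so downstream weighted means
    keep non-negative denominators.
    """
    if total_carb_g < 0 or fiber_g < 0:
        raise InvalidCompositionError(
            f"negative composition input (carb={total_carb_g}, fiber={fiber_g})"
        )
    diff = total_carb_g - fiber_g
    if diff < 0:
        logger.warning(
            "fiber (%.3g g) exceeds total carbohydrate (%.3g g); "
            "glycemic carbohydrate clamped to 0",
            fiber_g,
            total_carb_g,
        )
        return 0.0
    return diff


def assign_gi(
    food: FoodItem, gi_table: Mapping[str, float] | Mapping[str, FoodItem]
) -> tuple[float, GISource]:
    """Resolve a food's GI and record its provenance.

    Precedence: zero-class rule (overrides a conflicting table entry, with a
    logged conflict) > direct/literature table entry > one-step similar-food
    lookup. ``gi_table`` maps food_id to either a bare GI value or a
    :class:`FoodItem` whose own ``gi`` is used.
    """

    def _table_gi(fid: str) -> Optional[float]:
        entry = gi_table.get(fid)
        if entry is None:
            return None
        if isinstance(entry, FoodItem):
            return entry.gi
        return float(entry)

    own = _table_gi(food.food_id)
    if own is None and food.gi is not None:
        own = food.gi

    if food.zero_class is not None:
        if own is not None and own != 0.0:
            logger.warning(
                "food %r: zero-GI class %s overrides table GI %.3g",
                food.food_id,
                food.zero_class.value,
                own,
            )
        return 0.0, GISource.RULE_ZERO

    if own is not None:
        # keep the recorded provenance of an already-resolved entry (idempotence)
        source = (
            food.gi_source
            if food.gi_source in (GISource.DIRECT, GISource.LITERATURE, GISource.SIMILAR_FOOD)
            else GISource.DIRECT
        )
        return float(own), source

    if food.similar_food_id is not None:
        target_gi = _table_gi(food.similar_food_id)
        if target_gi is None:
            raise UnresolvedGIError(food.food_id)
        return float(target_gi), GISource.SIMILAR_FOOD

    raise UnresolvedGIError(food.food_id)


# ---------------------------------------------------------------------------
# table I/O

REQUIRED_COLUMNS = [
    "food_id",
    "name",
    "total_carb_g",
    "fiber_g",
    "gi",
    "gi_source",
    "similar_food_id",
    "zero_class",
]
OPTIONAL_COLUMNS = ["protein_g", "lipid_g"]


def _delimiter_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".txt", ".tab"} else ","


def load_food_table(path: str | Path) -> dict[str, FoodItem]:
    """Read a delimited food table into a validated ``{food_id: FoodItem}`` map.

    Comma or tab delimited (by extension), header row required, empty string
    means absent. Optional ``protein_g``/``lipid_g`` columns default to 0.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter_for(path), dtype=str, comment="#").fillna("")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FoodTableError(f"{path}: missing columns {missing}")

    foods: dict[str, FoodItem] = {}
    for row in df.itertuples(index=False):
        fid = str(row.food_id).strip()
        if not fid:
            raise FoodTableError(f"{path}: empty food_id")
        if fid in foods:
            raise FoodTableError(f"{path}: duplicate food_id {fid!r}")
        try:
            item = FoodItem(
                food_id=fid,
                name=str(row.name),
                total_carb_g=float(row.total_carb_g),
                fiber_g=float(row.fiber_g),
                gi=float(row.gi) if str(row.gi).strip() else None,
                gi_source=GISource(row.gi_source) if str(row.gi_source).strip() else GISource.UNRESOLVED,
                similar_food_id=str(row.similar_food_id).strip() or None,
                zero_class=ZeroClass(row.zero_class) if str(row.zero_class).strip() else None,
                protein_g=float(getattr(row, "protein_g", 0) or 0),
                lipid_g=float(getattr(row, "lipid_g", 0) or 0),
            )
        except ValueError as exc:
            raise FoodTableError(f"{path}: bad row for food_id {fid!r}: {exc}") from exc
        foods[fid] = item

    validate_food_table(foods)
    return foods


def validate_food_table(foods: Mapping[str, FoodItem]) -> None:
    """Structural validation: resolvability and depth-1 similar-food references."""
    for fid, food in foods.items():
        if food.similar_food_id is not None and food.gi is None and food.zero_class is None:
            target = foods.get(food.similar_food_id)
            if target is None:
                raise FoodTableError(
                    f"food {fid!r}: similar_food_id {food.similar_food_id!r} not in table"
                )
            if target.gi is None:
                # depth-1 only: the referenced food must carry its own GI
                raise FoodTableError(
                    f"food {fid!r}: chained similar-food reference via "
                    f"{food.similar_food_id!r} (referenced food has no direct GI)"
                )
        if food.gi is None and food.zero_class is None and food.similar_food_id is None:
            raise UnresolvedGIError(fid)
        if food.gi_source == GISource.RULE_ZERO and food.gi not in (None, 0.0):
            raise FoodTableError(f"food {fid!r}: gi_source rule_zero with nonzero GI {food.gi}")


def resolve_food_table(foods: Mapping[str, FoodItem]) -> dict[str, FoodItem]:
    """Return a copy of the table with every GI resolved and provenance recorded.

    Idempotent: resolving a resolved table returns identical items.
    """
    resolved: dict[str, FoodItem] = {}
    for fid, food in foods.items():
        gi, source = assign_gi(food, foods)
        resolved[fid] = replace(food, gi=gi, gi_source=source)
    return resolved


def food_table_frame(foods: Mapping[str, FoodItem]) -> pd.DataFrame:
    """Resolved table as a DataFrame keyed by food_id (for vectorized joins)."""
    resolved = resolve_food_table(foods)
    rows = [
        {
            "food_id": f.food_id,
            "name": f.name,
            "total_carb_g": f.total_carb_g,
            "fiber_g": f.fiber_g,
            "glycemic_carb_per_100g": f.glycemic_carb_per_100g,
            "gi": f.gi,
            "gi_source": f.gi_source.value,
            "protein_g": f.protein_g,
            "lipid_g": f.lipid_g,
        }
        for f in resolved.values()
    ]
    return pd.DataFrame(rows).set_index("food_id")


def write_food_table(foods: Mapping[str, FoodItem], path: str | Path) -> None:
    path = Path(path)
    rows = []
    for f in foods.values():
        rows.append(
            {
                "food_id": f.food_id,
                "name": f.name,
                "total_carb_g": f.total_carb_g,
                "fiber_g": f.fiber_g,
                "gi": "" if f.gi is None else f.gi,
                "gi_source": "" if f.gi_source == GISource.UNRESOLVED else f.gi_source.value,
                "similar_food_id": f.similar_food_id or "",
                "zero_class": f.zero_class.value if f.zero_class else "",
                "protein_g": f.protein_g,
                "lipid_g": f.lipid_g,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep=_delimiter_for(path), index=False)
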