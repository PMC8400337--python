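"""Food-diary data model and dietary diversity scoring.

Daily food diaries collected around the introduction of solid foods are
parsed into :class:`FoodDiary` objects and summarised with two bespoke
dietary diversity statistics:

* the *food diversity score*,
  ``(number of unique food items x number of food groups) / number of days``,
* the *pre-/probiotic diversity score*,
  ``((2 x unique prebiotic foods + unique probiotic foods) / number of days) x 10``
  under the default precedence (see :class:`ScoreConfig`).

Items are classified into seven food groups (fruit, vegetables, grains —
including beans and legumes — meat, dairy, confections/desserts, oils) and
flagged prebiotic/probiotic by a pattern lexicon.  Energy is derived from
macronutrient grams by the 4-4-9 rule with fiber counted at 2 kcal/g.
Breast milk and formula are excluded from all scores and energy.
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

FOOD_GROUPS = frozenset(
    {"fruit", "vegetables", "grains", "meat", "dairy", "confections_desserts", "oils"}
)

#: item-name patterns excluded from all scoring and energy computation
EXCLUDED_PATTERNS = ("breast milk", "breastmilk", "human milk", "formula")


class DiarySchemaError(ValueError):
    """Raised when a diary file violates the documented CSV schema."""


class DiaryValidationError(ValueError):
    """Raised when diary values are inconsistent (negative grams etc.)."""


def normalize_item_name(name: str) -> str:
    """Case-fold, trim and collapse internal whitespace.  No stemming."""
    return re.sub(r"\s+", " ", name.strip()).casefold()


def is_excluded_item(name: str) -> bool:
    """True for breast milk / formula, which never enter scores or energy."""
    norm = normalize_item_name(name)
    return any(pat in norm for pat in EXCLUDED_PATTERNS)


# ---------------------------------------------------------------------------
# Lexicon
# ---------------------------------------------------------------------------

def _singular(token: str) -> str:
    if len(token) > 3 and token.endswith("es"):
        return token[:-2]
    if len(token) > 2 and token.endswith("s"):
        return token[:-1]
    return token


@dataclass(frozen=True)
class LexiconEntry:
    pattern: str
    food_group: str | None
    is_prebiotic: bool
    is_probiotic: bool


class Lexicon:
    """Pattern table mapping item names to food group and pre-/probiotic flags.

    Multi-word patterns match as consecutive substrings of the normalized
    name; single-word patterns match any token, insensitive to simple
    plurals ("oats" matches "oat cereal").  The shipped default lexicon
    encodes the fixed prebiotic list (garlic, onions, bananas, oats, apples,
    pears, flaxseed, wheat bran, whole grain, cruciferous vegetables,
    legumes, honey, coconut, berries, corn products) and treats fermented
    foods (yoghurt, pickled foods, cheese, tempeh, sourdough, ...) as
    probiotic.
    """

    def __init__(self, entries: Iterable[LexiconEntry]):
        self.entries = list(entries)
        self._phrases = [e for e in self.entries if " " in e.pattern]
        # longest phrases first so "rice cereal" beats "rice"
        self._phrases.sort(key=lambda e: -len(e.pattern))
        self._tokens: dict[str, list[LexiconEntry]] = {}
        for e in self.entries:
            if " " not in e.pattern:
                self._tokens.setdefault(_singular(e.pattern.casefold()), []).append(e)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Lexicon":
        entries = []
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            required = {"pattern", "food_group", "is_prebiotic", "is_probiotic"}
            if reader.fieldnames is None or not required.issubset(reader.fieldnames):
                raise DiarySchemaError(
                    f"lexicon file {path} must have columns {sorted(required)}"
                )
            for row in reader:
                group = row["food_group"].strip() or None
                if group is not None and group not in FOOD_GROUPS:
                    raise DiarySchemaError(
                        f"unknown food_group {group!r} in lexicon for "
                        f"pattern {row['pattern']!r}"
                    )
                entries.append(
                    LexiconEntry(
                        pattern=normalize_item_name(row["pattern"]),
                        food_group=group,
                        is_prebiotic=row["is_prebiotic"].strip() in ("1", "true", "True"),
                        is_probiotic=row["is_probiotic"].strip() in ("1", "true", "True"),
                    )
                )
        return cls(entries)

    @classmethod
    def default(cls) -> "Lexicon":
        with resources.as_file(
            resources.files("weanbiome.data") / "default_lexicon.csv"
        ) as p:
            return cls.from_csv(p)

    def matches(self, item_name: str) -> list[LexiconEntry]:
        norm = normalize_item_name(item_name)
        tokens = [_singular(t) for t in norm.split()]
        hits = [e for e in self._phrases if e.pattern in norm]
        for tok in tokens:
            hits.extend(self._tokens.get(tok, []))
        return hits

    def classify(self, item_name: str) -> tuple[bool, bool]:
        """Return ``(is_prebiotic, is_probiotic)`` flags for an item name.

        A food may be both; an unmatched name is neither.
        """
        if not item_name or not item_name.strip():
            raise DiaryValidationError("empty item name")
        hits = self.matches(item_name)
        return any(e.is_prebiotic for e in hits), any(e.is_probiotic for e in hits)

    def food_group(self, item_name: str) -> str | None:
        for e in self.matches(item_name):
            if e.food_group is not None:
                return e.food_group
        return None


def classify_food(item_name: str, lexicon: Lexicon | None = None) -> tuple[bool, bool]:
    """Prebiotic/probiotic flags for one item name (module-level convenience)."""
    return (lexicon or Lexicon.default()).classify(item_name)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoodRecord:
    """One food-diary row: a food eaten by one infant on one study day.

    ``study_day`` is indexed so day 0 is the first day of solid food.
    Macronutrient grams are the row's contribution to daily intake.
    """

    participant_id: str
    study_day: int
    item_name: str
    food_group: str
    amount: float
    carb_g: float
    fat_g: float
    protein_g: float
    fiber_g: float
    is_prebiotic: bool = False
    is_probiotic: bool = False
    excluded: bool = False  # breast milk / formula
    unclassified: bool = False

    def __post_init__(self):
        if self.food_group not in FOOD_GROUPS and not self.unclassified:
            raise DiarySchemaError(f"unknown food group {self.food_group!r}")
        for name in ("amount", "carb_g", "fat_g", "protein_g", "fiber_g"):
            if getattr(self, name) < 0:
                raise DiaryValidationError(f"negative {name} for {self.item_name!r}")


@dataclass
class FoodDiary:
    """All diary records for one infant plus the day span the diary covers.

    ``diary_span`` is an inclusive ``(first_day, last_day)`` range; days in
    the span without records are valid zero-intake days and still count in
    score denominators.
    """

    participant_id: str
    records: list[FoodRecord] = field(default_factory=list)
    diary_span: tuple[int, int] = (0, 0)

    def __post_init__(self):
        lo, hi = self.diary_span
        if lo > hi:
            raise DiaryValidationError("diary_span start after end")
        for r in self.records:
            if not (lo <= r.study_day <= hi):
                raise DiaryValidationError(
                    f"record on day {r.study_day} outside diary span {self.diary_span}"
                )

    @property
    def n_days(self) -> int:
        return self.diary_span[1] - self.diary_span[0] + 1

    def records_in(self, window: tuple[int, int]) -> list[FoodRecord]:
        lo, hi = window
        return [r for r in self.records if lo <= r.study_day <= hi]


@dataclass(frozen=True)
class DietScoreSet:
    """Dietary diversity scores for one scoring window."""

    window: tuple[int, int]
    n_items: int
    n_groups: int
    n_prebiotic: int
    n_probiotic: int
    n_days: int
    food_diversity: float
    preprobiotic_diversity: float


@dataclass(frozen=True)
class DailyIntake:
    """Energy (kcal/d, by 4-4-9 with fiber at 2 kcal/g) and fiber for one day."""

    study_day: int
    energy_total: float
    energy_carb: float
    energy_fat: float
    energy_protein: float
    fiber: float


@dataclass(frozen=True)
class ScoreConfig:
    """Switches for the ambiguous pieces of the printed score formulas.

    literal_denominator
        If True, read the pre-/probiotic score as
        ``(2p + q) / (days x 10)`` instead of the default
        ``((2p + q) / days) x 10``.  The default reproduces the published
        daily maximum of 100 and cumulative means near 8.
    """

    literal_denominator: bool = False


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

DIARY_COLUMNS = (
    "participant_id",
    "study_day",
    "item_name",
    "food_group",
    "amount_g",
    "carb_g",
    "fat_g",
    "protein_g",
    "fiber_g",
)


def parse_food_diary(
    path: str | Path,
    lexicon: Lexicon | None = None,
    diary_span: tuple[int, int] | None = None,
    participant_id: str | None = None,
) -> dict[str, FoodDiary]:
    """Parse a diary CSV into one :class:`FoodDiary` per participant.

    Schema: ``participant_id,study_day,item_name,food_group,amount_g,carb_g,
    fat_g,protein_g,fiber_g[,is_prebiotic,is_probiotic]``.  When the optional
    classification columns are absent, flags come from the lexicon; items
    absent from the lexicon raise a warning and are flagged unclassified.
    Fiber above carbohydrate is clamped to the carbohydrate grams.

    If the file has no rows, ``diary_span`` and ``participant_id`` define a
    zero-intake diary.
    """
    lexicon = lexicon or Lexicon.default()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise DiarySchemaError(f"{path}: missing header")
        missing = set(DIARY_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise DiarySchemaError(f"{path}: missing columns {sorted(missing)}")
        has_flags = {"is_prebiotic", "is_probiotic"}.issubset(reader.fieldnames)
        rows = list(reader)

    per_pid: dict[str, list[FoodRecord]] = {}
    for row in rows:
        name = normalize_item_name(row["item_name"])
        group = row["food_group"].strip()
        excluded = is_excluded_item(name)
        unclassified = False
        if group not in FOOD_GROUPS:
            if group:
                raise DiarySchemaError(f"unknown food_group {group!r} for {name!r}")
            inferred = lexicon.food_group(name)
            if inferred is None and not excluded:
                warnings.warn(f"item {name!r} not in lexicon; left unclassified")
                unclassified = True
            group = inferred or ""
        if has_flags:
            pre = row["is_prebiotic"].strip() in ("1", "true", "True")
            pro = row["is_probiotic"].strip() in ("1", "true", "True")
        else:
            pre, pro = (False, False) if excluded else lexicon.classify(name)
        try:
            rec = FoodRecord(
                participant_id=row["participant_id"].strip(),
                study_day=int(row["study_day"]),
                item_name=name,
                food_group=group,
                amount=float(row["amount_g"]),
                carb_g=float(row["carb_g"]),
                fat_g=float(row["fat_g"]),
                protein_g=float(row["protein_g"]),
                fiber_g=min(float(row["fiber_g"]), float(row["carb_g"])),
                is_prebiotic=pre,
                is_probiotic=pro,
                excluded=excluded,
                unclassified=unclassified,
            )
        except ValueError as exc:
            raise DiaryValidationError(f"{path}: bad row {row}: {exc}") from exc
        per_pid.setdefault(rec.participant_id, []).append(rec)

    if not per_pid:
        if diary_span is None or participant_id is None:
            raise DiarySchemaError(
                f"{path}: empty diary needs explicit diary_span and participant_id"
            )
        return {participant_id: FoodDiary(participant_id, [], diary_span)}

    diaries = {}
    for pid, recs in per_pid.items():
        days = [r.study_day for r in recs]
        span = diary_span or (min(days), max(days))
        span = (min(span[0], min(days)), max(span[1], max(days)))
        diaries[pid] = FoodDiary(pid, recs, span)
    return diaries


# ---------------------------------------------------------------------------
# Energy
# ---------------------------------------------------------------------------

def energy_from_macros(
    carb_g: float, fat_g: float, protein_g: float, fiber_g: float
) -> tuple[float, float, float, float]:
    """4-4-9 energy with fiber at 2 kcal/g.

    Carbohydrate contributes 4 kcal/g on its non-fiber part and 2 kcal/g on
    fiber (fiber clamped to total carbohydrate); fat 9 kcal/g; protein
    4 kcal/g.  Returns ``(carb_kcal, fat_kcal, protein_kcal, total_kcal)``.
    """
    for v, name in ((carb_g, "carb_g"), (fat_g, "fat_g"),
                    (protein_g, "protein_g"), (fiber_g, "fiber_g")):
        if v < 0:
            raise DiaryValidationError(f"negative {name}")
    fiber = min(fiber_g, carb_g)
    e_carb = 4.0 * (carb_g - fiber) + 2.0 * fiber
    e_fat = 9.0 * fat_g
    e_prot = 4.0 * protein_g
    return e_carb, e_fat, e_prot, e_carb + e_fat + e_prot


def daily_intake(diary: FoodDiary, study_day: int) -> DailyIntake:
    """Total energy and fiber for one day, summing the day's records.

    Breast milk / formula records are excluded.
    """
    recs = [r for r in diary.records_in((study_day, study_day)) if not r.excluded]
    carb = sum(r.carb_g for r in recs)
    fat = sum(r.fat_g for r in recs)
    prot = sum(r.protein_g for r in recs)
    fiber = sum(r.fiber_g for r in recs)
    e_carb, e_fat, e_prot, total = energy_from_macros(carb, fat, prot, fiber)
    return DailyIntake(study_day, total, e_carb, e_fat, e_prot, fiber)


# ---------------------------------------------------------------------------
# Diversity scores
# ---------------------------------------------------------------------------

def _window_counts(diary: FoodDiary, window: tuple[int, int]):
    lo, hi = window
    slo, shi = diary.diary_span
    if hi < lo:
        raise DiaryValidationError("empty scoring window")
    if lo < slo or hi > shi:
        raise DiaryValidationError(
            f"window {window} outside diary span {diary.diary_span}"
        )
    recs = [r for r in diary.records_in(window) if not r.excluded]
    items = {r.item_name for r in recs}
    groups = {r.food_group for r in recs if not r.unclassified}
    pre = {r.item_name for r in recs if r.is_prebiotic}
    pro = {r.item_name for r in recs if r.is_probiotic}
    return items, groups, pre, pro, hi - lo + 1


def cumulative_scores(
    diary: FoodDiary,
    window: tuple[int, int] | None = None,
    config: ScoreConfig = ScoreConfig(),
) -> DietScoreSet:
    """Cumulative dietary diversity scores over a day window.

    Food diversity = (unique items x distinct groups) / days; the
    pre-/probiotic score weights unique prebiotic foods twice as heavily as
    unique probiotic foods.  Days without records still count in the
    denominator.
    """
    window = window or diary.diary_span
    items, groups, pre, pro, n_days = _window_counts(diary, window)
    food_div = len(items) * len(groups) / n_days
    weighted = 2 * len(pre) + len(pro)
    if config.literal_denominator:
        ppd = weighted / (n_days * 10)
    else:
        ppd = weighted / n_days * 10
    return DietScoreSet(
        window=window,
        n_items=len(items),
        n_groups=len(groups),
        n_prebiotic=len(pre),
        n_probiotic=len(pro),
        n_days=n_days,
        food_diversity=food_div,
        preprobiotic_diversity=ppd,
    )


def cumulative_food_diversity(
    diary: FoodDiary, window: tuple[int, int] | None = None
) -> DietScoreSet:
    return cumulative_scores(diary, window)


def cumulative_preprobiotic_diversity(
    diary: FoodDiary,
    window: tuple[int, int] | None = None,
    config: ScoreConfig = ScoreConfig(),
) -> DietScoreSet:
    return cumulative_scores(diary, window, config)


def daily_scores(
    diary: FoodDiary, study_day: int, config: ScoreConfig = ScoreConfig()
) -> DietScoreSet:
    """Daily scores: the cumulative formulas on a single-day window."""
    return cumulative_scores(diary, (study_day, study_day), config)


def daily_score_table(
    diary: FoodDiary, config: ScoreConfig = ScoreConfig()
) -> pd.DataFrame:
    """Per-day scores and intake for one diary, one row per day in span."""
    rows = []
    for day in range(diary.diary_span[0], diary.diary_span[1] + 1):
        s = daily_scores(diary, day, config)
        intake = daily_intake(diary, day)
        rows.append(
            {
                "participant_id": diary.participant_id,
                "study_day": day,
                "n_items": s.n_items,
                "n_groups": s.n_groups,
                "n_prebiotic": s.n_prebiotic,
                "n_probiotic": s.n_probiotic,
                "food_diversity": s.food_diversity,
                "preprobiotic_diversity": s.preprobiotic_diversity,
                "energy_total": intake.energy_total,
                "energy_carb": intake.energy_carb,
                "energy_fat": intake.energy_fat,
                "energy_protein": intake.energy_protein,
                "fiber": intake.fiber,
            }
        )
    return pd.DataFrame(rows)


def score_summary_table(
    diaries: Sequence[FoodDiary], config: ScoreConfig = ScoreConfig()
) -> pd.DataFrame:
    """Cumulative scores per participant, one row each."""
    rows = []
    for d in diaries:
        s = cumulative_scores(d, config=config)
        rows.append(
            {
                "participant_id": d.participant_id,
                "n_days": s.n_days,
                "n_items": s.n_items,
                "n_groups": s.n_groups,
                "n_prebiotic": s.n_prebiotic,
                "n_probiotic": s.n_probiotic,
                "food_diversity": s.food_diversity,
                "preprobiotic_diversity": s.preprobiotic_diversity,
            }
        )
    return pd.DataFrame(rows)
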