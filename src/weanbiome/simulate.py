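"""Synthetic two-cohort generator: paired food diaries and ASV tables.

Emulates the study design the analysis assumes: two cohorts (15 and 9
infants) sampled 5-12 times over ~2 weeks around the first solid food,
strong per-infant community individuality dominated by *Bifidobacterium*
or *Bacteroides*, richness accruing with age, and day-to-day community
drift whose magnitude shrinks with daily dietary diversity.

Mechanics:

* diaries accrue items by a Poisson new-item process from a per-cohort
  repertoire (cohort A spans all seven food groups; cohort B only fruit,
  vegetables and grains), so daily diversity trends upward;
* each infant's latent composition starts from a Dirichlet draw with mass
  concentrated on the dominance genus and evolves by a logistic-normal
  random walk with daily step scale ``sigma0 * exp(-gamma * D_t)`` where
  ``D_t`` is the day's food diversity rescaled to [0, 1] by the cohort's
  configured maximum — ``gamma`` is the diet-stability coupling;
* new low-abundance ASVs are injected at ``richness_slope`` per day;
* counts are multinomial at a log-normal library size.

Ground truth (dominance regimes, per-day drift scales, diet scores, all
parameters and the seed) is retained for parameter-recovery tests.  The
whole dataset regenerates byte-identically from ``(config, seed)``: each
infant draws from an independent counter-keyed substream of the global
seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .community import AsvCountTable, write_asv_table
from .diary import FoodDiary, FoodRecord, Lexicon, daily_scores

GENUS_POOL = (
    "Bifidobacterium",
    "Bacteroides",
    "Veillonella",
    "Escherichia",
    "Clostridium",
    "Streptococcus",
    "Blautia",
    "Parabacteroides",
)

GENUS_WEIGHTS = (0.28, 0.20, 0.10, 0.10, 0.10, 0.08, 0.08, 0.06)

GENUS_LINEAGE = {
    "Bifidobacterium": ("Bacteria", "Actinobacteriota", "Actinobacteria",
                        "Bifidobacteriales", "Bifidobacteriaceae"),
    "Bacteroides": ("Bacteria", "Bacteroidota", "Bacteroidia",
                    "Bacteroidales", "Bacteroidaceae"),
    "Veillonella": ("Bacteria", "Firmicutes", "Negativicutes",
                    "Veillonellales", "Veillonellaceae"),
    "Escherichia": ("Bacteria", "Proteobacteria", "Gammaproteobacteria",
                    "Enterobacterales", "Enterobacteriaceae"),
    "Clostridium": ("Bacteria", "Firmicutes", "Clostridia",
                    "Clostridiales", "Clostridiaceae"),
    "Streptococcus": ("Bacteria", "Firmicutes", "Bacilli",
                      "Lactobacillales", "Streptococcaceae"),
    "Blautia": ("Bacteria", "Firmicutes", "Clostridia",
                "Lachnospirales", "Lachnospiraceae"),
    "Parabacteroides": ("Bacteria", "Bacteroidota", "Bacteroidia",
                        "Bacteroidales", "Tannerellaceae"),
}

#: per-cohort food repertoires; item names resolve through the default lexicon
ITEM_POOL = {
    "fruit": ["banana", "apple", "pear", "avocado", "mango", "peach", "plum",
              "blueberry", "strawberry", "melon", "prune", "apricot", "kiwi"],
    "vegetables": ["carrot", "sweet potato", "squash", "broccoli", "cauliflower",
                   "green bean", "pea", "spinach", "zucchini", "pumpkin",
                   "parsnip", "cucumber", "beet"],
    "grains": ["oat cereal", "rice cereal", "baby cereal", "bread", "barley",
               "quinoa", "lentil", "chickpea", "corn", "rusk", "toast",
               "whole grain pasta"],
    "meat": ["chicken", "beef", "turkey", "salmon", "egg", "pork", "lamb"],
    "dairy": ["yoghurt", "cheese", "milk", "cream cheese", "butter"],
    "oils": ["olive oil", "canola oil", "sunflower oil"],
    "confections_desserts": ["biscuit", "pudding", "maple syrup", "cookie"],
}

# per-gram macronutrient densities (carb, fat, protein, fiber) and mean grams
GROUP_MACROS = {
    "fruit": ((0.12, 0.003, 0.006, 0.020), 30.0),
    "vegetables": ((0.07, 0.002, 0.012, 0.025), 30.0),
    "grains": ((0.50, 0.020, 0.080, 0.060), 15.0),
    "meat": ((0.00, 0.080, 0.250, 0.000), 20.0),
    "dairy": ((0.05, 0.050, 0.035, 0.000), 30.0),
    "oils": ((0.00, 1.000, 0.000, 0.000), 3.0),
    "confections_desserts": ((0.60, 0.150, 0.040, 0.010), 10.0),
}


@dataclass
class CohortSpec:
    """Per-cohort generator settings."""

    name: str
    n_infants: int
    item_rate: float  # expected new food items per day after introduction
    groups: tuple[str, ...]
    diet_scale_max: float  # daily food-diversity value mapped to 1.0
    age_at_intro_mean_days: float
    dominance_probs: dict[str, float]


@dataclass
class CohortConfig:
    """Two-cohort study configuration; defaults mirror the emulated design."""

    seed: int = 0
    span_before: int = 3  # diary/sampling days before first solids
    span_after: int = 11  # days after (inclusive span length = before+after+1)
    samples_min: int = 5
    samples_max: int = 12
    n_asvs: int = 240
    private_fraction: float = 0.66  # ASVs private to one cohort
    base_concentration: float = 0.3
    dominance_mass: float = 0.6
    drift_scale: float = 1.0  # sigma0, log-scale step SD per day
    diet_coupling: float = 1.2  # gamma >= 0
    richness_slope: float = 0.5  # expected new ASVs injected per day
    reversion: float = 0.9  # OU pull toward the infant's baseline composition
    library_log_mean: float = 9.9  # ~20k reads
    library_log_sd: float = 0.4
    eat_probability: float = 0.55
    include_late_samples: bool = False  # sparse samples out to ~1 year
    cohort_a: CohortSpec = field(default_factory=lambda: CohortSpec(
        name="A", n_infants=15, item_rate=1.3,
        groups=("fruit", "vegetables", "grains", "meat", "dairy", "oils",
                "confections_desserts"),
        diet_scale_max=55.0, age_at_intro_mean_days=168.0,
        dominance_probs={"Bifidobacterium": 0.78, "Bacteroides": 0.22},
    ))
    cohort_b: CohortSpec = field(default_factory=lambda: CohortSpec(
        name="B", n_infants=9, item_rate=0.65,
        groups=("fruit", "vegetables", "grains"),
        diet_scale_max=20.0, age_at_intro_mean_days=153.0,
        dominance_probs={"Bifidobacterium": 0.70, "Bacteroides": 0.30},
    ))

    def __post_init__(self):
        if self.drift_scale <= 0:
            raise ValueError("drift_scale must be positive")
        if self.diet_coupling < 0 or self.richness_slope < 0:
            raise ValueError("coupling and richness slope must be >= 0")
        for spec in (self.cohort_a, self.cohort_b):
            if abs(sum(spec.dominance_probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"dominance probabilities for cohort "
                                 f"{spec.name} must sum to 1")

    @property
    def diary_span(self) -> tuple[int, int]:
        return (-self.span_before, self.span_after)


@dataclass
class SyntheticTruth:
    """Ground truth retained for parameter-recovery tests."""

    config: dict
    seed: int
    dominance: dict[str, str]  # participant -> realized dominant genus
    daily_diet: dict[str, dict[int, float]]  # participant -> day -> food diversity
    daily_sigma: dict[str, dict[int, float]]  # participant -> day -> drift scale

    def to_json(self) -> str:
        def _convert(obj):
            if isinstance(obj, dict):
                return {str(k): _convert(v) for k, v in obj.items()}
            if isinstance(obj, (np.integer,)):
                return int(obj)
            if isinstance(obj, (np.floating,)):
                return float(obj)
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return json.dumps(_convert(dataclasses.asdict(self)), indent=1)


@dataclass
class SyntheticDataset:
    diaries: dict[str, FoodDiary]
    table: AsvCountTable
    truth: SyntheticTruth

    def write(self, outdir: str | Path) -> None:
        """Emit the diary CSV, counts/taxonomy/metadata TSVs and truth JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rows = []
        for pid in sorted(self.diaries):
            for r in self.diaries[pid].records:
                rows.append(
                    {
                        "participant_id": r.participant_id,
                        "study_day": r.study_day,
                        "item_name": r.item_name,
                        "food_group": r.food_group,
                        "amount_g": round(r.amount, 3),
                        "carb_g": round(r.carb_g, 4),
                        "fat_g": round(r.fat_g, 4),
                        "protein_g": round(r.protein_g, 4),
                        "fiber_g": round(r.fiber_g, 4),
                        "is_prebiotic": int(r.is_prebiotic),
                        "is_probiotic": int(r.is_probiotic),
                    }
                )
        pd.DataFrame(rows).to_csv(outdir / "diary.csv", index=False)
        write_asv_table(self.table, outdir)
        (outdir / "truth.json").write_text(self.truth.to_json())


def _infant_rng(seed: int, cohort_idx: int, infant_idx: int, stream: int):
    """Counter-keyed substream so each infant regenerates independently."""
    return np.random.default_rng(
        np.random.SeedSequence([seed, cohort_idx, infant_idx, stream])
    )


# ---------------------------------------------------------------------------
# Diaries
# ---------------------------------------------------------------------------

def generate_diary(
    config: CohortConfig, cohort: CohortSpec, infant_idx: int,
    lexicon: Lexicon | None = None,
) -> FoodDiary:
    """One infant's food diary over the sub-study span.

    Items accrue after day 0 by a Poisson new-item process from the
    cohort's repertoire, with early picks weighted toward fruit and
    vegetables; acquired items are re-eaten on later days with a fixed
    probability, so daily diversity trends upward with fluctuations.
    """
    cohort_idx = 0 if cohort.name == config.cohort_a.name else 1
    rng = _infant_rng(config.seed, cohort_idx, infant_idx, 0)
    lexicon = lexicon or Lexicon.default()
    pid = f"{cohort.name}{infant_idx + 1:02d}"

    pool = [(item, grp) for grp in cohort.groups for item in ITEM_POOL[grp]]
    early_weight = np.array(
        [3.0 if grp in ("fruit", "vegetables") else 1.0 for _, grp in pool]
    )
    acquired: list[tuple[str, str]] = []
    remaining = list(range(len(pool)))
    records: list[FoodRecord] = []
    span = config.diary_span
    for day in range(0, span[1] + 1):
        n_new = rng.poisson(cohort.item_rate)
        for _ in range(min(n_new, len(remaining))):
            w = early_weight[remaining]
            pick = rng.choice(len(remaining), p=w / w.sum())
            acquired.append(pool[remaining.pop(pick)])
        # day 0 always introduces at least one food
        if day == 0 and not acquired and remaining:
            w = early_weight[remaining]
            pick = rng.choice(len(remaining), p=w / w.sum())
            acquired.append(pool[remaining.pop(pick)])
        for item, grp in acquired:
            if rng.random() > config.eat_probability:
                continue
            (dens, mean_g) = GROUP_MACROS[grp]
            grams = float(rng.gamma(4.0, mean_g / 4.0))
            jitter = rng.normal(1.0, 0.1, size=4).clip(0.5, 1.5)
            carb = grams * dens[0] * jitter[0]
            fat = grams * dens[1] * jitter[1]
            prot = grams * dens[2] * jitter[2]
            fiber = min(grams * dens[3] * jitter[3], carb)
            pre, pro = lexicon.classify(item)
            records.append(
                FoodRecord(
                    participant_id=pid, study_day=day, item_name=item,
                    food_group=grp, amount=grams, carb_g=carb, fat_g=fat,
                    protein_g=prot, fiber_g=fiber,
                    is_prebiotic=pre, is_probiotic=pro,
                )
            )
    return FoodDiary(pid, records, span)


# ---------------------------------------------------------------------------
# ASV pool
# ---------------------------------------------------------------------------

def _build_asv_pool(config: CohortConfig):
    """Global ASV id space with genus labels and cohort availability."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 9999]))
    n = config.n_asvs
    genera = rng.choice(GENUS_POOL, size=n, p=np.array(GENUS_WEIGHTS))
    asv_ids = [f"ASV{i + 1:04d}" for i in range(n)]
    avail = rng.random(n)
    # shared / private-to-A / private-to-B, privates split 60/40 because the
    # first cohort carries more unique features
    shared_cut = 1.0 - config.private_fraction
    availability = np.where(
        avail < shared_cut, "both",
        np.where(avail < shared_cut + config.private_fraction * 0.6, "A", "B"),
    )
    taxonomy = pd.DataFrame(
        [GENUS_LINEAGE[g] + (g,) for g in genera],
        index=asv_ids,
        columns=["domain", "phylum", "class", "order", "family", "genus"],
    )
    return asv_ids, np.asarray(genera), availability, taxonomy


# ---------------------------------------------------------------------------
# Microbiome
# ---------------------------------------------------------------------------

def generate_microbiome(
    config: CohortConfig,
    cohort: CohortSpec,
    infant_idx: int,
    diary: FoodDiary,
    asv_pool,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Longitudinal counts + metadata for one infant.

    Returns ``(counts samples x ASVs, metadata, truth dict)``.
    """
    cohort_idx = 0 if cohort.name == config.cohort_a.name else 1
    rng = _infant_rng(config.seed, cohort_idx, infant_idx, 1)
    asv_ids, genera, availability, _tax = asv_pool
    pid = diary.participant_id

    ok = (availability == "both") | (availability == cohort.name)
    idx_avail = np.flatnonzero(ok)
    genera_avail = genera[idx_avail]

    # dominance regime
    regimes = list(cohort.dominance_probs)
    dom_genus = str(rng.choice(regimes, p=[cohort.dominance_probs[r] for r in regimes]))
    dom_pool = idx_avail[genera_avail == dom_genus]
    other_pool = idx_avail[genera_avail != dom_genus]

    n_dom = int(min(len(dom_pool), rng.integers(3, 7)))
    n_other = int(min(len(other_pool), rng.integers(18, 30)))
    active_dom = rng.choice(dom_pool, size=n_dom, replace=False)
    active_other = rng.choice(other_pool, size=n_other, replace=False)

    dom_mass = config.dominance_mass if n_dom else 0.0
    p_dom = rng.dirichlet(np.full(n_dom, 1.0)) if n_dom else np.empty(0)
    p_other = rng.dirichlet(np.full(n_other, config.base_concentration))
    active = np.concatenate([active_dom, active_other])
    p0 = np.concatenate([dom_mass * p_dom, (1 - dom_mass) * p_other])
    z0 = dict(zip(active.tolist(), np.log(np.maximum(p0, 1e-12))))
    inactive = [i for i in idx_avail if i not in z0]
    rng.shuffle(inactive)

    # sampling days: evenly spaced over the sub-study span, starting before
    # introduction (protocol-style sampling).  Even spacing keeps interval
    # length independent of where the interval falls in the span; with
    # irregular draws, long gaps cluster around the sparse before-period
    # where diet is lowest, and the gap-dependent magnitude of consecutive
    # change then masquerades as a diet effect even at zero coupling.
    span = config.diary_span
    n_samples = int(rng.integers(config.samples_min, config.samples_max + 1))
    ideal = np.linspace(span[0], span[1], n_samples)
    sample_days: list[int] = []
    for v in ideal:
        day = int(np.round(v))
        if sample_days and day <= sample_days[-1]:
            day = sample_days[-1] + 1
        sample_days.append(day)

    # diet signal per day (0 before solids)
    daily_diet, daily_sigma = {}, {}
    for day in range(span[0], span[1] + 1):
        d = daily_scores(diary, day).food_diversity if day >= 0 else 0.0
        scaled = min(d / cohort.diet_scale_max, 1.0)
        daily_diet[day] = d
        daily_sigma[day] = config.drift_scale * np.exp(
            -config.diet_coupling * scaled
        )

    age_at_intro = float(rng.normal(cohort.age_at_intro_mean_days, 15.0))
    library = rng.lognormal(config.library_log_mean, config.library_log_sd,
                            size=len(sample_days))

    counts_rows, meta_rows = [], []
    # mean-reverting (OU) deviations around the infant's baseline keep the
    # day-to-day change stationary: without the pull, log-abundance
    # dispersion grows with time and consecutive changes trend downward,
    # confounding any diet signal.  Deviations start at the pre-solids
    # stationary spread.
    phi = config.reversion
    sd_stat = daily_sigma[span[0]] / np.sqrt(1.0 - phi**2)
    x = {k: float(rng.normal(0.0, sd_stat)) for k in z0}
    day_cursor = span[0]
    for si, day in enumerate(sample_days):
        # advance the latent walk to this day
        while day_cursor < day:
            day_cursor += 1
            sigma = daily_sigma[day_cursor]
            keys = list(x)
            steps = rng.normal(0.0, sigma, size=len(keys))
            for k, s in zip(keys, steps):
                x[k] = phi * x[k] + s
            n_new = rng.poisson(config.richness_slope)
            for _ in range(min(n_new, len(inactive))):
                new = inactive.pop()
                zvals = np.fromiter(z0.values(), dtype=float)
                z0[new] = float(np.log(0.002) + logsumexp(zvals))
                x[new] = 0.0
        keys = np.fromiter(x.keys(), dtype=int)
        zvals = np.fromiter((z0[k] + x[k] for k in x), dtype=float)
        p = np.exp(zvals - logsumexp(zvals))
        full = np.zeros(len(asv_ids))
        full[keys] = p
        full /= full.sum()
        draw = rng.multinomial(int(library[si]), full)
        sid = f"{pid}D{day:+03d}".replace("+", "p").replace("-", "m")
        counts_rows.append(pd.Series(draw, index=asv_ids, name=sid))
        meta_rows.append(
            {
                "sample_id": sid,
                "participant_id": pid,
                "cohort": cohort.name,
                "study_day": day,
                "age_days": round(age_at_intro + day, 1),
                "age_at_intro_days": round(age_at_intro, 1),
            }
        )
    counts = pd.DataFrame(counts_rows)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    truth = {
        "dominance": dom_genus,
        "daily_diet": daily_diet,
        "daily_sigma": daily_sigma,
    }
    return counts, meta, truth


# ---------------------------------------------------------------------------
# Full dataset
# ---------------------------------------------------------------------------

def generate_cohorts(config: CohortConfig | None = None) -> SyntheticDataset:
    """Complete two-cohort dataset: diaries, ASV table and ground truth."""
    config = config or CohortConfig()
    lexicon = Lexicon.default()
    asv_pool = _build_asv_pool(config)
    _, _, _, taxonomy = asv_pool

    diaries: dict[str, FoodDiary] = {}
    counts_frames, meta_frames = [], []
    dominance, daily_diet, daily_sigma = {}, {}, {}
    for cohort in (config.cohort_a, config.cohort_b):
        for i in range(cohort.n_infants):
            diary = generate_diary(config, cohort, i, lexicon)
            diaries[diary.participant_id] = diary
            counts, meta, truth = generate_microbiome(
                config, cohort, i, diary, asv_pool
            )
            counts_frames.append(counts)
            meta_frames.append(meta)
            dominance[diary.participant_id] = truth["dominance"]
            daily_diet[diary.participant_id] = truth["daily_diet"]
            daily_sigma[diary.participant_id] = truth["daily_sigma"]

    counts = pd.concat(counts_frames).fillna(0).astype(np.int64)
    keep = counts.columns[counts.sum(axis=0) > 0]
    table = AsvCountTable(
        counts[keep], taxonomy.loc[keep], pd.concat(meta_frames)
    )
    truth = SyntheticTruth(
        config=dataclasses.asdict(config),
        seed=config.seed,
        dominance=dominance,
        daily_diet=daily_diet,
        daily_sigma=daily_sigma,
    )
    return SyntheticDataset(diaries, table, truth)
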