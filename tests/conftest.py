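"""Shared fixtures and small data builders for the test suite."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

from weanbiome.community import AsvCountTable
from weanbiome.diary import FOOD_GROUPS, FoodDiary, FoodRecord
from weanbiome.simulate import CohortConfig, CohortSpec, generate_cohorts

GROUPS = sorted(FOOD_GROUPS)
GENUS_POOL = (
    "Bifidobacterium",
    "Bacteroides",
    "Veillonella",
    "Escherichia",
    "Clostridium",
)


def make_record(
    pid: str,
    day: int,
    item: str,
    group: str = "fruit",
    pre: bool = False,
    pro: bool = False,
    carb: float = 10.0,
    fat: float = 2.0,
    protein: float = 3.0,
    fiber: float = 1.0,
) -> FoodRecord:
    return FoodRecord(
        participant_id=pid,
        study_day=day,
        item_name=item,
        food_group=group,
        amount=50.0,
        carb_g=carb,
        fat_g=fat,
        protein_g=protein,
        fiber_g=fiber,
        is_prebiotic=pre,
        is_probiotic=pro,
    )


def random_diary(rng: np.random.Generator, pid: str = "P01") -> FoodDiary:
    """A random but schema-valid diary with explicit classification flags."""
    span = (int(rng.integers(-4, 1)), int(rng.integers(1, 20)))
    items = [f"food{i}" for i in range(int(rng.integers(1, 25)))]
    records = []
    group_of = {it: GROUPS[rng.integers(0, len(GROUPS))] for it in items}
    pre_of = {it: bool(rng.random() < 0.3) for it in items}
    pro_of = {it: bool(rng.random() < 0.15) for it in items}
    for day in range(span[0], span[1] + 1):
        for it in items:
            if rng.random() < 0.25:
                records.append(
                    make_record(
                        pid,
                        day,
                        it,
                        group_of[it],
                        pre=pre_of[it],
                        pro=pro_of[it],
                        carb=float(rng.uniform(0, 20)),
                        fat=float(rng.uniform(0, 8)),
                        protein=float(rng.uniform(0, 8)),
                        fiber=float(rng.uniform(0, 3)),
                    )
                )
    return FoodDiary(pid, records, span)


def random_table(
    rng: np.random.Generator,
    n_samples: int = 12,
    n_asvs: int = 40,
    n_participants: int = 4,
) -> AsvCountTable:
    """A random but valid ASV table with taxonomy and metadata."""
    counts = rng.integers(0, 200, size=(n_samples, n_asvs))
    counts[rng.random(counts.shape) < 0.4] = 0
    counts[:, 0] += 1  # guarantee positive sample totals
    sample_ids = [f"S{i:03d}" for i in range(n_samples)]
    asv_ids = [f"ASV{i:03d}" for i in range(n_asvs)]
    taxonomy = pd.DataFrame(
        {
            "domain": "Bacteria",
            "phylum": "various",
            "class": "various",
            "order": "various",
            "family": "various",
            "genus": [GENUS_POOL[i % len(GENUS_POOL)] for i in range(n_asvs)],
        },
        index=pd.Index(asv_ids, name="asv_id"),
    )
    pids = [f"P{(i % n_participants):02d}" for i in range(n_samples)]
    days = [int(d) for d in rng.integers(-3, 12, size=n_samples)]
    days[0], days[1] = -2, 3  # guarantee both periods are represented
    metadata = pd.DataFrame(
        {
            "participant_id": pids,
            "cohort": ["A" if p < f"P{n_participants // 2:02d}" else "B" for p in pids],
            "study_day": days,
            "age_days": [170 + d for d in days],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return AsvCountTable(
        pd.DataFrame(counts, index=sample_ids, columns=asv_ids), taxonomy, metadata
    )


def small_cohort_config(seed: int = 11) -> CohortConfig:
    """Scaled-down generator settings for fast pipeline tests."""
    cfg = CohortConfig(seed=seed, n_asvs=60, samples_min=4, samples_max=6)
    cfg.cohort_a = dataclasses.replace(cfg.cohort_a, n_infants=5)
    cfg.cohort_b = dataclasses.replace(cfg.cohort_b, n_infants=4)
    return cfg


@pytest.fixture(scope="session")
def small_dataset():
    return generate_cohorts(small_cohort_config())


@pytest.fixture(scope="session")
def default_dataset():
    """One full-scale synthetic dataset shared by the slower tests."""
    return generate_cohorts(CohortConfig(seed=0))
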