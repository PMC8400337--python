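"""ASV count-table model and ecological metrics.

Holds samples x ASV count matrices with taxonomy and sample metadata, and
computes the community descriptors used around solid-food introduction:
observed richness and Shannon diversity (alpha), Bray-Curtis dissimilarity
on relative abundances (beta), PCoA ordination, UPGMA dendrograms, genus
summaries with an "Other" pool, per-infant dominance calls, cross-cohort
feature overlap, and the within-infant sample-to-sample stability series
that pairs consecutive Bray-Curtis changes with interval diet covariates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix, TreeNode

from .diary import FoodDiary, ScoreConfig, daily_intake, daily_scores

TAXONOMY_RANKS = ("domain", "phylum", "class", "order", "family", "genus")


class TableValidationError(ValueError):
    """Raised when counts / taxonomy / metadata files disagree."""


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------

@dataclass
class AsvCountTable:
    """Samples x ASVs integer counts with taxonomy and sample metadata.

    ``counts``: DataFrame indexed by sample id, columns ASV ids.
    ``taxonomy``: DataFrame indexed by ASV id with ranked lineage columns
    (missing ranks as explicit ``"unassigned"`` placeholders).
    ``metadata``: DataFrame indexed by sample id with ``participant_id``,
    ``cohort``, ``study_day``, ``age_days`` and a derived ``period``
    (``before`` for study_day < 0, ``after`` otherwise).
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self):
        self.counts = self.counts.astype(np.int64)
        if (self.counts.values < 0).any():
            raise TableValidationError("negative counts")
        totals = self.counts.sum(axis=1)
        if (totals == 0).any():
            bad = list(totals.index[totals == 0])
            raise TableValidationError(f"zero-total samples: {bad}")
        missing_tax = set(self.counts.columns) - set(self.taxonomy.index)
        if missing_tax:
            raise TableValidationError(f"ASVs missing taxonomy: {sorted(missing_tax)[:5]}")
        if set(self.counts.index) != set(self.metadata.index):
            only_counts = sorted(set(self.counts.index) - set(self.metadata.index))
            only_meta = sorted(set(self.metadata.index) - set(self.counts.index))
            raise TableValidationError(
                f"sample id mismatch; counts-only={only_counts[:5]}, "
                f"metadata-only={only_meta[:5]}"
            )
        self.metadata = self.metadata.loc[self.counts.index].copy()
        if "period" not in self.metadata.columns:
            self.metadata["period"] = np.where(
                self.metadata["study_day"] < 0, "before", "after"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.columns)

    def subset_samples(self, sample_ids) -> "AsvCountTable":
        sample_ids = list(sample_ids)
        counts = self.counts.loc[sample_ids]
        keep = counts.columns[counts.sum(axis=0) > 0]
        return AsvCountTable(
            counts[keep], self.taxonomy.loc[keep], self.metadata.loc[sample_ids]
        )

    def subset_cohort(self, cohort: str) -> "AsvCountTable":
        ids = self.metadata.index[self.metadata["cohort"] == cohort]
        return self.subset_samples(ids)

    def participant_samples(self, participant_id: str) -> pd.DataFrame:
        """This participant's metadata rows ordered by study day."""
        meta = self.metadata[self.metadata["participant_id"] == participant_id]
        return meta.sort_values("study_day")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _read_counts_tsv(path: str | Path, sample_ids: set[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    # orientation autodetect: samples can be rows or columns
    cols_are_samples = len(set(df.columns) & sample_ids) >= len(
        set(df.index) & sample_ids
    )
    if cols_are_samples:
        df = df.T
    if not np.allclose(df.values, np.round(df.values)):
        raise TableValidationError(f"{path}: non-integer counts")
    return df.round().astype(np.int64)


def _read_counts_biom_json(path: str | Path) -> pd.DataFrame:
    """Minimal reader for BIOM 1.0 JSON (dense or sparse) tables."""
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    obs_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    mat = np.zeros((len(obs_ids), len(sample_ids)))
    if doc.get("matrix_type") == "sparse":
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = v
    else:
        mat[:] = np.asarray(doc["data"], dtype=float)
    if not np.allclose(mat, np.round(mat)):
        raise TableValidationError(f"{path}: non-integer counts")
    return pd.DataFrame(
        mat.T.round().astype(np.int64), index=sample_ids, columns=obs_ids
    )


def _read_counts_biom_hdf5(path: str | Path) -> pd.DataFrame:
    """Minimal reader for BIOM 2.1 HDF5 tables (observation-major CSR)."""
    import h5py
    from scipy.sparse import csr_matrix

    with h5py.File(path, "r") as fh:
        obs_ids = [x.decode() for x in fh["observation/ids"][:]]
        sample_ids = [x.decode() for x in fh["sample/ids"][:]]
        g = fh["observation/matrix"]
        mat = csr_matrix(
            (g["data"][:], g["indices"][:], g["indptr"][:]),
            shape=(len(obs_ids), len(sample_ids)),
        ).toarray()
    return pd.DataFrame(mat.T.round().astype(np.int64), index=sample_ids, columns=obs_ids)


def load_asv_table(
    counts_path: str | Path,
    taxonomy_path: str | Path,
    metadata_path: str | Path,
) -> AsvCountTable:
    """Load and align counts (TSV or BIOM JSON/HDF5), taxonomy TSV, metadata TSV.

    Taxonomy schema: ``asv_id,domain,phylum,class,order,family,genus``;
    metadata schema: ``sample_id,participant_id,cohort,study_day,age_days``.
    Unassigned taxonomy ranks become explicit ``"unassigned"`` placeholders.
    """
    metadata = pd.read_csv(metadata_path, sep="\t", index_col="sample_id")
    counts_path = Path(counts_path)
    if counts_path.suffix == ".biom" or counts_path.suffix in (".h5", ".hdf5"):
        try:
            counts = _read_counts_biom_hdf5(counts_path)
        except OSError:
            counts = _read_counts_biom_json(counts_path)
    elif counts_path.suffix == ".json":
        counts = _read_counts_biom_json(counts_path)
    else:
        counts = _read_counts_tsv(counts_path, set(metadata.index))
    taxonomy = pd.read_csv(taxonomy_path, sep="\t", index_col="asv_id")
    for rank in TAXONOMY_RANKS:
        if rank not in taxonomy.columns:
            taxonomy[rank] = "unassigned"
    taxonomy = taxonomy[list(TAXONOMY_RANKS)].fillna("unassigned")
    return AsvCountTable(counts, taxonomy, metadata)


def write_asv_table(table: AsvCountTable, outdir: str | Path, prefix: str = "") -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table.counts.T.rename_axis("asv_id").to_csv(
        outdir / f"{prefix}counts.tsv", sep="\t"
    )
    table.taxonomy.rename_axis("asv_id").to_csv(
        outdir / f"{prefix}taxonomy.tsv", sep="\t"
    )
    cols = [c for c in ("participant_id", "cohort", "study_day", "age_days", "period")
            if c in table.metadata.columns]
    table.metadata[cols].rename_axis("sample_id").to_csv(
        outdir / f"{prefix}metadata.tsv", sep="\t"
    )


# ---------------------------------------------------------------------------
# Alpha / beta diversity
# ---------------------------------------------------------------------------

def relative_abundance(table: AsvCountTable | pd.DataFrame) -> pd.DataFrame:
    """Row-normalized proportions; every row sums to 1."""
    counts = table.counts if isinstance(table, AsvCountTable) else table
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        raise TableValidationError("zero-total sample in relative_abundance")
    return counts.div(totals, axis=0)


def observed_richness(counts) -> int | pd.Series:
    """Number of ASVs with a strictly positive count."""
    arr = np.asarray(counts)
    if arr.ndim == 1:
        return int((arr > 0).sum())
    c = counts.counts if isinstance(counts, AsvCountTable) else counts
    return (c > 0).sum(axis=1)


def shannon_diversity(counts) -> float:
    """Shannon index in nats: ``H = -sum p_i ln p_i`` over positive proportions."""
    arr = np.asarray(counts, dtype=float)
    total = arr.sum()
    if total <= 0:
        raise TableValidationError("Shannon undefined for empty sample")
    p = arr[arr > 0] / total
    return float(-(p * np.log(p)).sum())


def alpha_diversity_table(table: AsvCountTable) -> pd.DataFrame:
    """Per-sample observed richness and Shannon index with metadata."""
    rows = []
    for sid in table.sample_ids:
        v = table.counts.loc[sid].values
        rows.append(
            {
                "sample_id": sid,
                "observed_richness": observed_richness(v),
                "shannon": shannon_diversity(v),
            }
        )
    out = pd.DataFrame(rows).set_index("sample_id")
    return out.join(table.metadata)


def bray_curtis(table: AsvCountTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity on relative abundances.

    ``BC(x, y) = sum|x_i - y_i| / sum(x_i + y_i)`` which, on proportions,
    equals half the L1 distance.
    """
    rel = relative_abundance(table).values
    if rel.shape[0] < 2:
        raise TableValidationError("need at least 2 samples")
    diff = np.abs(rel[:, None, :] - rel[None, :, :]).sum(axis=2)
    dm = diff / 2.0  # rows sum to 1, so denominator is 2
    np.fill_diagonal(dm, 0.0)
    return DistanceMatrix(dm, ids=table.sample_ids)


def bray_curtis_pair(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    denom = (x + y).sum()
    if denom == 0:
        raise TableValidationError("Bray-Curtis undefined for two empty samples")
    return float(np.abs(x - y).sum() / denom)


# ---------------------------------------------------------------------------
# Stability series
# ---------------------------------------------------------------------------

@dataclass
class StabilitySeries:
    """Consecutive-sample Bray-Curtis changes for one infant.

    One interval per consecutive sample pair ordered by study day; interval
    diet covariates are means of daily diary values over the days strictly
    after the earlier sample up to and including the later sample's day.
    """

    participant_id: str
    intervals: pd.DataFrame = field(default_factory=pd.DataFrame)

    COVARIATES = (
        "food_diversity",
        "preprobiotic_diversity",
        "energy_total",
        "energy_carb",
        "energy_fat",
        "energy_protein",
        "fiber",
    )


def stability_series(
    table: AsvCountTable,
    diary: FoodDiary | None,
    participant_id: str | None = None,
    config: ScoreConfig = ScoreConfig(),
) -> StabilitySeries:
    """Within-infant sample-to-sample Bray-Curtis change series.

    Consecutive pairs only, ordered by study day.  Covariates are averaged
    over the interval ``(day_earlier, day_later]``; days outside the diary
    span leave the covariates missing.
    """
    pid = participant_id or (diary.participant_id if diary else None)
    if pid is None:
        raise ValueError("participant_id required when no diary is given")
    meta = table.participant_samples(pid)
    rel = relative_abundance(table)
    rows = []
    sids = list(meta.index)
    for earlier, later in zip(sids[:-1], sids[1:]):
        d0 = int(meta.loc[earlier, "study_day"])
        d1 = int(meta.loc[later, "study_day"])
        row = {
            "participant_id": pid,
            "sample_earlier": earlier,
            "sample_later": later,
            "day_earlier": d0,
            "day_later": d1,
            "bray_curtis_change": bray_curtis_pair(
                rel.loc[earlier].values, rel.loc[later].values
            ),
        }
        cov_days = [
            d
            for d in range(d0 + 1, d1 + 1)
            if diary is not None
            and diary.diary_span[0] <= d <= diary.diary_span[1]
        ]
        if cov_days:
            scores = [daily_scores(diary, d, config) for d in cov_days]
            intakes = [daily_intake(diary, d) for d in cov_days]
            row.update(
                food_diversity=float(np.mean([s.food_diversity for s in scores])),
                preprobiotic_diversity=float(
                    np.mean([s.preprobiotic_diversity for s in scores])
                ),
                energy_total=float(np.mean([i.energy_total for i in intakes])),
                energy_carb=float(np.mean([i.energy_carb for i in intakes])),
                energy_fat=float(np.mean([i.energy_fat for i in intakes])),
                energy_protein=float(np.mean([i.energy_protein for i in intakes])),
                fiber=float(np.mean([i.fiber for i in intakes])),
            )
        else:
            row.update({c: np.nan for c in StabilitySeries.COVARIATES})
        rows.append(row)
    return StabilitySeries(pid, pd.DataFrame(rows))


def pooled_stability_table(
    table: AsvCountTable,
    diaries: dict[str, FoodDiary],
    config: ScoreConfig = ScoreConfig(),
) -> pd.DataFrame:
    """Stack every infant's stability series into one long table."""
    frames = []
    for pid in sorted(table.metadata["participant_id"].unique()):
        s = stability_series(table, diaries.get(pid), pid, config)
        if len(s.intervals):
            frames.append(s.intervals)
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Taxonomy summaries
# ---------------------------------------------------------------------------

def genus_abundance(table: AsvCountTable) -> pd.DataFrame:
    """Samples x genera relative abundances (plain genus collapse)."""
    rel = relative_abundance(table)
    genus = table.taxonomy.loc[rel.columns, "genus"]
    return rel.T.groupby(genus).sum().T


def genus_summary(table: AsvCountTable, other_threshold: float = 0.05) -> pd.DataFrame:
    """Genus collapse with per-sample pooling of rare genera into "Other".

    In each sample, genera below ``other_threshold`` relative abundance are
    pooled; rows still sum to 1.
    """
    collapsed = genus_abundance(table)
    if other_threshold <= 0:
        return collapsed
    low = collapsed < other_threshold
    out = collapsed.where(~low, 0.0)
    out["Other"] = collapsed.where(low, 0.0).sum(axis=1)
    keep = out.columns[(out > 0).any(axis=0)]
    return out[keep]


def dominant_taxon(
    table: AsvCountTable, participant_id: str, threshold: float = 0.30
) -> str:
    """Genus with highest mean relative abundance across the infant's samples.

    Reported as dominant only if its mean is at least ``threshold``
    (default 0.30), else ``"mixed"``.
    """
    meta = table.participant_samples(participant_id)
    if meta.empty:
        raise TableValidationError(f"no samples for participant {participant_id!r}")
    genus = genus_abundance(table).loc[meta.index]
    means = genus.mean(axis=0).sort_values(ascending=False)
    return means.index[0] if means.iloc[0] >= threshold else "mixed"


def dominance_census(table: AsvCountTable, threshold: float = 0.30) -> pd.DataFrame:
    rows = []
    for pid in sorted(table.metadata["participant_id"].unique()):
        sub = table.metadata[table.metadata["participant_id"] == pid]
        rows.append(
            {
                "participant_id": pid,
                "cohort": sub["cohort"].iloc[0],
                "dominant_genus": dominant_taxon(table, pid, threshold),
            }
        )
    return pd.DataFrame(rows)


def shared_features(
    table_a: AsvCountTable, table_b: AsvCountTable, rank: str = "asv"
) -> dict:
    """Feature overlap between two cohorts at ASV or genus rank.

    Returns counts present in each and both, plus, per cohort, the fraction
    of total relative abundance carried by shared features.
    """
    if rank == "asv":
        feats_a = relative_abundance(table_a)
        feats_b = relative_abundance(table_b)
    elif rank == "genus":
        for t in (table_a, table_b):
            if "genus" not in t.taxonomy.columns:
                raise TableValidationError("taxonomy lacks genus rank")
        feats_a = genus_abundance(table_a)
        feats_b = genus_abundance(table_b)
    else:
        raise ValueError(f"unknown rank {rank!r}")
    present_a = set(feats_a.columns[(feats_a.sum(axis=0) > 0)])
    present_b = set(feats_b.columns[(feats_b.sum(axis=0) > 0)])
    shared = present_a & present_b

    def _shared_fraction(feats, shared_set):
        total = feats.sum(axis=0)
        if total.sum() == 0:
            return 0.0
        return float(total[total.index.isin(shared_set)].sum() / total.sum())

    return {
        "rank": rank,
        "n_a": len(present_a),
        "n_b": len(present_b),
        "n_shared": len(shared),
        "shared_abundance_a": _shared_fraction(feats_a, shared),
        "shared_abundance_b": _shared_fraction(feats_b, shared),
    }


# ---------------------------------------------------------------------------
# Ordination and clustering
# ---------------------------------------------------------------------------

def pcoa(dm: DistanceMatrix, k: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical scaling (principal coordinates) of a distance matrix.

    Double-centers the squared distances and eigendecomposes; coordinates
    are ordered by descending eigenvalue.  Negative eigenvalues (possible
    for non-Euclidean dissimilarities like Bray-Curtis) are reported as-is,
    with their axes given zero coordinates; no Lingoes/Cailliez correction.
    Returns (coordinates DataFrame with columns PC1..PCk, all eigenvalues).
    """
    d = dm.data
    n = d.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be < n_samples={n}")
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (d**2) @ j
    eigvals, eigvecs = np.linalg.eigh((g + g.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    coords = np.zeros((n, k))
    pos = eigvals[:k] > 0
    coords[:, pos] = eigvecs[:, :k][:, pos] * np.sqrt(eigvals[:k][pos])
    df = pd.DataFrame(
        coords, index=list(dm.ids), columns=[f"PC{i+1}" for i in range(k)]
    )
    return df, eigvals


def upgma(dm: DistanceMatrix) -> str:
    """Average-linkage (UPGMA) dendrogram as a newick string.

    Node heights are half the merge distance, so the tree is ultrametric
    with root-to-leaf path length equal to half the largest merge.  Ties are
    resolved deterministically by scipy's average-linkage ordering.
    """
    ids = list(dm.ids)
    if len(ids) < 2:
        raise TableValidationError("UPGMA needs at least 2 samples")
    z = linkage(squareform(dm.data, checks=False), method="average")
    heights = {i: 0.0 for i in range(len(ids))}
    newick = {i: ids[i] for i in range(len(ids))}
    n = len(ids)
    for step, (a, b, dist, _size) in enumerate(z):
        a, b = int(a), int(b)
        h = dist / 2.0
        la = dist / 2.0 - heights[a]
        lb = dist / 2.0 - heights[b]
        node = n + step
        newick[node] = f"({newick[a]}:{la:.10g},{newick[b]}:{lb:.10g})"
        heights[node] = h
    return newick[n + len(z) - 1] + ";"


def read_newick(source: str) -> TreeNode:
    """Parse a newick string (round-trip reader for UPGMA output)."""
    from io import StringIO

    return TreeNode.read(StringIO(source))


def is_ultrametric(tree: TreeNode, tol: float = 1e-10) -> bool:
    depths = [tip.accumulate_to_ancestor(tree) for tip in tree.tips()]
    return (max(depths) - min(depths)) <= tol
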