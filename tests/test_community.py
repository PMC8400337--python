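"""Community metrics against independent brute-force oracles."""

import json
import math

import h5py
import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix
from skbio.diversity import beta_diversity

from weanbiome.community import (
    AsvCountTable,
    TableValidationError,
    alpha_diversity_table,
    bray_curtis,
    bray_curtis_pair,
    dominance_census,
    dominant_taxon,
    genus_abundance,
    genus_summary,
    is_ultrametric,
    load_asv_table,
    observed_richness,
    pcoa,
    read_newick,
    relative_abundance,
    shannon_diversity,
    shared_features,
    stability_series,
    upgma,
    write_asv_table,
)
from weanbiome.diary import FoodDiary

from conftest import make_record, random_table


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------

def test_alpha_metrics_match_bruteforce():
    rng = np.random.default_rng(1)
    table = random_table(rng)
    alpha = alpha_diversity_table(table)
    for sid in table.sample_ids:
        row = table.counts.loc[sid].to_numpy()
        assert alpha.loc[sid, "observed_richness"] == sum(1 for v in row if v > 0)
        total = row.sum()
        h = -sum((v / total) * math.log(v / total) for v in row if v > 0)
        assert alpha.loc[sid, "shannon"] == pytest.approx(h, abs=1e-12)


def test_shannon_uniform_is_log_k():
    counts = pd.Series([10, 10, 10, 10])
    assert shannon_diversity(counts) == pytest.approx(math.log(4), abs=1e-12)
    assert observed_richness(counts) == 4


# ---------------------------------------------------------------------------
# Bray-Curtis
# ---------------------------------------------------------------------------

def test_bray_curtis_matches_skbio():
    rng = np.random.default_rng(2)
    table = random_table(rng)
    rel = relative_abundance(table)
    ours = bray_curtis(table)
    ref = beta_diversity("braycurtis", rel.to_numpy(), ids=table.sample_ids)
    assert np.allclose(ours.data, ref.data, atol=1e-12)


def test_bray_curtis_pair_definition():
    x = np.array([0.5, 0.5, 0.0])
    y = np.array([0.0, 0.5, 0.5])
    # sum|x-y| / sum(x+y) = 1.0 / 2.0
    assert bray_curtis_pair(x, y) == pytest.approx(0.5, abs=1e-15)
    assert bray_curtis_pair(x, x) == 0.0


# ---------------------------------------------------------------------------
# Genus summaries, dominance, shared features
# ---------------------------------------------------------------------------

def test_genus_summary_pools_rare_and_rows_sum_to_one():
    rng = np.random.default_rng(3)
    table = random_table(rng)
    summary = genus_summary(table, other_threshold=0.05)
    assert np.allclose(summary.sum(axis=1), 1.0, atol=1e-12)
    collapsed = genus_abundance(table)
    for sid in table.sample_ids:
        pooled = sum(v for v in collapsed.loc[sid] if v < 0.05)
        assert summary.loc[sid].get("Other", 0.0) == pytest.approx(pooled, abs=1e-12)


def test_dominant_taxon_threshold():
    rng = np.random.default_rng(4)
    table = random_table(rng)
    census = dominance_census(table, threshold=0.30)
    for _, row in census.iterrows():
        sub = table.participant_samples(row["participant_id"])
        means = genus_abundance(table).loc[sub.index].mean(axis=0)
        if means.max() >= 0.30:
            assert row["dominant_genus"] == means.idxmax()
        else:
            assert row["dominant_genus"] == "mixed"


def test_dominant_taxon_unknown_participant_raises():
    rng = np.random.default_rng(5)
    table = random_table(rng)
    with pytest.raises(TableValidationError):
        dominant_taxon(table, "nobody")


def test_shared_features_counts():
    rng = np.random.default_rng(6)
    table = random_table(rng, n_samples=16)
    a = table.subset_cohort("A")
    b = table.subset_cohort("B")
    res = shared_features(a, b, rank="asv")
    pa = {c for c in a.counts.columns if a.counts[c].sum() > 0}
    pb = {c for c in b.counts.columns if b.counts[c].sum() > 0}
    assert res["n_a"] == len(pa)
    assert res["n_b"] == len(pb)
    assert res["n_shared"] == len(pa & pb)
    assert 0 <= res["shared_abundance_a"] <= 1


# ---------------------------------------------------------------------------
# Stability series
# ---------------------------------------------------------------------------

def test_stability_series_manual_check():
    counts = pd.DataFrame(
        [[90, 10, 0], [50, 50, 0], [0, 10, 90]],
        index=["s1", "s2", "s3"],
        columns=["a1", "a2", "a3"],
    )
    taxonomy = pd.DataFrame(
        {"domain": "Bacteria", "phylum": "x", "class": "x", "order": "x",
         "family": "x", "genus": ["g1", "g2", "g3"]},
        index=["a1", "a2", "a3"],
    )
    metadata = pd.DataFrame(
        {"participant_id": "P1", "cohort": "A", "study_day": [-1, 2, 6],
         "age_days": [160, 163, 167]},
        index=["s1", "s2", "s3"],
    )
    table = AsvCountTable(counts, taxonomy, metadata)
    diary = FoodDiary("P1", [make_record("P1", 1, "rice", "grains")], (-1, 6))
    series = stability_series(table, diary)
    assert len(series.intervals) == 2
    assert series.intervals.loc[0, "bray_curtis_change"] == pytest.approx(0.4)
    assert series.intervals.loc[1, "bray_curtis_change"] == pytest.approx(0.9)
    # covariate window (d0, d1] means day 1's rice lands in the first interval
    assert series.intervals.loc[0, "food_diversity"] > 0
    assert series.intervals.loc[1, "food_diversity"] == 0


# ---------------------------------------------------------------------------
# Ordination and clustering
# ---------------------------------------------------------------------------

def test_pcoa_roundtrips_euclidean_configuration():
    rng = np.random.default_rng(7)
    pts = rng.normal(size=(9, 3))
    from scipy.spatial.distance import pdist, squareform

    dm = DistanceMatrix(squareform(pdist(pts)), [f"s{i}" for i in range(9)])
    coords, eigvals = pcoa(dm, k=8)
    rebuilt = squareform(pdist(coords.to_numpy()))
    assert np.allclose(rebuilt, dm.data, atol=1e-8)
    # only the intrinsic dimensionality carries signal
    assert (eigvals[:3] > 1e-8).all()
    assert np.abs(eigvals[3:]).max() < 1e-8


def test_pcoa_reports_negative_eigenvalues_uncorrected():
    rng = np.random.default_rng(8)
    table = random_table(rng)
    coords, eigvals = pcoa(bray_curtis(table), k=2)
    # Bray-Curtis is non-Euclidean: negative eigenvalues must be visible
    assert eigvals.min() < 0
    assert coords.shape == (len(table.sample_ids), 2)


def test_upgma_three_leaf_hand_example():
    dm = DistanceMatrix(np.array([[0, 2, 6], [2, 0, 6], [6, 6, 0]], float),
                        ["A", "B", "C"])
    newick = upgma(dm)
    tree = read_newick(newick)
    dists = tree.tip_tip_distances()
    assert dists["A", "B"] == pytest.approx(2.0)
    assert dists["A", "C"] == pytest.approx(6.0)
    assert dists["B", "C"] == pytest.approx(6.0)
    assert is_ultrametric(tree, tol=1e-10)


def test_upgma_random_tables_are_ultrametric():
    rng = np.random.default_rng(9)
    for _ in range(5):
        table = random_table(rng)
        tree = read_newick(upgma(bray_curtis(table)))
        assert is_ultrametric(tree, tol=1e-10)


# ---------------------------------------------------------------------------
# I/O and validation
# ---------------------------------------------------------------------------

def test_tsv_roundtrip(tmp_path):
    rng = np.random.default_rng(10)
    table = random_table(rng)
    write_asv_table(table, tmp_path)
    loaded = load_asv_table(
        tmp_path / "counts.tsv", tmp_path / "taxonomy.tsv", tmp_path / "metadata.tsv"
    )
    pd.testing.assert_frame_equal(loaded.counts, table.counts,
                                  check_names=False)
    assert (loaded.metadata["period"] == table.metadata["period"]).all()


def test_biom_json_reader(tmp_path):
    rng = np.random.default_rng(11)
    table = random_table(rng, n_samples=5, n_asvs=8)
    doc = {
        "rows": [{"id": a} for a in table.asv_ids],
        "columns": [{"id": s} for s in table.sample_ids],
        "matrix_type": "dense",
        "data": table.counts.T.to_numpy().tolist(),
    }
    counts_path = tmp_path / "table.json"
    counts_path.write_text(json.dumps(doc))
    write_asv_table(table, tmp_path)
    loaded = load_asv_table(counts_path, tmp_path / "taxonomy.tsv",
                            tmp_path / "metadata.tsv")
    assert np.array_equal(
        loaded.counts.loc[table.sample_ids, table.asv_ids].to_numpy(),
        table.counts.to_numpy(),
    )


def test_biom_hdf5_reader(tmp_path):
    from scipy.sparse import csr_matrix

    rng = np.random.default_rng(12)
    table = random_table(rng, n_samples=5, n_asvs=8)
    mat = csr_matrix(table.counts.T.to_numpy())
    path = tmp_path / "table.biom"
    with h5py.File(path, "w") as fh:
        fh.create_dataset("observation/ids",
                          data=[a.encode() for a in table.asv_ids])
        fh.create_dataset("sample/ids",
                          data=[s.encode() for s in table.sample_ids])
        fh.create_dataset("observation/matrix/data", data=mat.data.astype(float))
        fh.create_dataset("observation/matrix/indices", data=mat.indices)
        fh.create_dataset("observation/matrix/indptr", data=mat.indptr)
    write_asv_table(table, tmp_path)
    loaded = load_asv_table(path, tmp_path / "taxonomy.tsv",
                            tmp_path / "metadata.tsv")
    assert np.array_equal(
        loaded.counts.loc[table.sample_ids, table.asv_ids].to_numpy(),
        table.counts.to_numpy(),
    )


def test_zero_total_sample_rejected():
    counts = pd.DataFrame([[1, 2], [0, 0]], index=["s1", "s2"], columns=["a1", "a2"])
    taxonomy = pd.DataFrame(
        {"domain": "d", "phylum": "p", "class": "c", "order": "o",
         "family": "f", "genus": "g"}, index=["a1", "a2"])
    metadata = pd.DataFrame(
        {"participant_id": "P1", "cohort": "A", "study_day": [0, 1],
         "age_days": [100, 101]}, index=["s1", "s2"])
    with pytest.raises(TableValidationError):
        AsvCountTable(counts, taxonomy, metadata)


def test_metadata_mismatch_rejected():
    counts = pd.DataFrame([[1, 2]], index=["s1"], columns=["a1", "a2"])
    taxonomy = pd.DataFrame(
        {"domain": "d", "phylum": "p", "class": "c", "order": "o",
         "family": "f", "genus": "g"}, index=["a1", "a2"])
    metadata = pd.DataFrame(
        {"participant_id": "P1", "cohort": "A", "study_day": [0],
         "age_days": [100]}, index=["other"])
    with pytest.raises(TableValidationError):
        AsvCountTable(counts, taxonomy, metadata)
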