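"""End-to-end analysis pipeline and run artifacts.

Orchestrates the full workflow on real or synthetic inputs: dietary
scores, alpha/beta diversity, stability series, PERMANOVA, mixed models,
negative-binomial association matrices, candidate screens, taxonomy
summaries, ordination and clustering — with a machine-readable manifest
recording seeds, convergence flags and zero-nudge counts.  Every stage is
seeded from the run seed, so reruns produce byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import community, simulate, stats
from .diary import FoodDiary, Lexicon, ScoreConfig, daily_score_table, parse_food_diary, score_summary_table

logger = logging.getLogger("weanbiome")

#: nutritional variables entering the stability and alpha-diversity models
DIET_VARS = (
    "energy_total",
    "energy_carb",
    "energy_fat",
    "energy_protein",
    "fiber",
    "food_diversity",
    "preprobiotic_diversity",
)

#: diet variables used for the NB ASV regressions and candidate screens
NB_DIET_VARS = ("food_diversity", "preprobiotic_diversity", "fiber")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline run.

    Either the four real-input paths or ``synthetic=True`` (with an
    optional :class:`~weanbiome.simulate.CohortConfig`), never both.
    Thresholds default to the analysis conventions: p < 0.05 headline
    significance, 5% "Other" pooling, 9999 permutations, top-10 abundant
    ASVs, top-5 candidate screen.
    """

    outdir: str = "weanbiome_run"
    seed: int = 0
    synthetic: bool = True
    cohort_config: simulate.CohortConfig | None = None
    diary_path: str | None = None
    counts_path: str | None = None
    taxonomy_path: str | None = None
    metadata_path: str | None = None
    n_perm: int = 9999
    other_threshold: float = 0.05
    dominance_threshold: float = 0.30
    top_abundant: int = 10
    top_screen: int = 5
    nb_max_taxa: int = 15
    p_threshold: float = 0.05
    literal_denominator: bool = False
    log_level: str = "INFO"

    def __post_init__(self):
        real = [self.diary_path, self.counts_path, self.taxonomy_path,
                self.metadata_path]
        if self.synthetic and any(real):
            raise PipelineError("give either synthetic=True or real input paths")
        if not self.synthetic and not all(real):
            raise PipelineError("real runs need diary, counts, taxonomy and metadata paths")

    @property
    def score_config(self) -> ScoreConfig:
        return ScoreConfig(literal_denominator=self.literal_denominator)


def _sample_diet_table(table: community.AsvCountTable,
                       diaries: dict[str, FoodDiary],
                       config: ScoreConfig) -> pd.DataFrame:
    """Per-sample diet covariates: the sample day's daily scores and intake.

    Days before solid-food introduction carry zero intake by definition.
    """
    from .diary import daily_intake, daily_scores

    rows = []
    for sid, meta in table.metadata.iterrows():
        pid, day = meta["participant_id"], int(meta["study_day"])
        diary = diaries.get(pid)
        row = {"sample_id": sid, "participant_id": pid}
        if diary is not None and diary.diary_span[0] <= day <= diary.diary_span[1]:
            s = daily_scores(diary, day, config)
            i = daily_intake(diary, day)
            row.update(
                food_diversity=s.food_diversity,
                preprobiotic_diversity=s.preprobiotic_diversity,
                energy_total=i.energy_total,
                energy_carb=i.energy_carb,
                energy_fat=i.energy_fat,
                energy_protein=i.energy_protein,
                fiber=i.fiber,
            )
        else:
            row.update({v: np.nan for v in DIET_VARS})
        if "age_at_intro_days" in meta:
            row["age_at_intro_weeks"] = float(meta["age_at_intro_days"]) / 7.0
        row["age_days"] = float(meta.get("age_days", np.nan))
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")


def _alpha_models(alpha: pd.DataFrame, diet: pd.DataFrame) -> pd.DataFrame:
    """Univariable and energy/age-adjusted LMMs for both alpha metrics."""
    shared = [c for c in diet.columns if c in alpha.columns]
    data = alpha.join(diet.drop(columns=shared))
    rows = []
    for response in ("observed_richness", "shannon"):
        for var in DIET_VARS:
            d = data.dropna(subset=[var, response])
            if d[var].std() == 0 or d["participant_id"].nunique() < 2:
                continue
            uni = stats.fit_lmm(
                d, stats.ModelSpec(response, [var], "participant_id")
            )
            row = {
                "response": response,
                "term": var,
                "univariable_estimate": uni.coef(var) if uni.converged else np.nan,
                "univariable_p": uni.p(var) if uni.converged else np.nan,
            }
            if var != "energy_total":
                covs = [var, "energy_total"]
                if d["age_days"].notna().all() and d["age_days"].std() > 0:
                    covs.append("age_days")
                multi = stats.fit_lmm(
                    d.dropna(subset=covs),
                    stats.ModelSpec(response, covs, "participant_id"),
                )
                row["multivariable_estimate"] = (
                    multi.coef(var) if multi.converged else np.nan
                )
                row["multivariable_p"] = multi.p(var) if multi.converged else np.nan
            else:
                row["multivariable_estimate"] = np.nan
                row["multivariable_p"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def _nb_associations(
    table: community.AsvCountTable,
    diaries: dict[str, FoodDiary],
    diet: pd.DataFrame,
    cfg: RunConfig,
) -> tuple[dict[str, stats.AssociationMatrix], dict[str, pd.DataFrame]]:
    """Top-abundant + screened taxa, NB fits across the three tiers."""
    from .diary import daily_score_table

    taxa = stats.select_top_abundant(table, cfg.top_abundant)
    screens = {}
    pids = sorted(table.metadata["participant_id"].unique())
    per_infant = {}
    for var in NB_DIET_VARS:
        vals = {}
        for pid in pids:
            diary = diaries.get(pid)
            if diary is None:
                continue
            t = daily_score_table(diary, cfg.score_config)
            after = t[t["study_day"] >= 0]
            vals[pid] = float(after[var].mean())
        per_infant[var] = pd.Series(vals)
        try:
            screen = stats.candidate_screen(
                table, per_infant[var], var, top_n=cfg.top_screen
            )
            screens[var] = screen
            taxa.extend(a for a in screen["asv_id"] if a not in taxa)
        except stats.StatsError as exc:
            logger.warning("candidate screen for %s skipped: %s", var, exc)
    taxa = taxa[: cfg.nb_max_taxa]

    diet_data = diet.copy()
    if "age_at_intro_weeks" not in diet_data.columns:
        diet_data["age_at_intro_weeks"] = np.nan
    matrices = {}
    for tier in stats.NB_TIERS:
        fits = []
        for asv in taxa:
            for var in NB_DIET_VARS:
                cols = stats._tier_covariates(tier, var)
                d = diet_data.dropna(subset=[c for c in cols if c in diet_data])
                sub = table.subset_samples([s for s in table.sample_ids if s in d.index])
                if asv not in sub.counts.columns:
                    continue
                try:
                    fit = stats.fit_nb_asv(sub, asv, d, var, tier)
                except stats.StatsError:
                    continue
                fits.append(fit)
        if fits:
            matrices[tier] = stats.build_association_matrix(fits)
    return matrices, screens


def run_pipeline(cfg: RunConfig) -> Path:
    """Run the full analysis; returns the output directory.

    Any stage failure aborts with a stage-named :class:`PipelineError` and
    removes partial outputs.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    outdir = Path(cfg.outdir)
    fresh = not outdir.exists()
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    manifest: dict = {
        "seed": cfg.seed,
        "n_perm": cfg.n_perm,
        # the output directory is omitted so runs into different locations
        # with the same seed produce identical manifests
        "config": {
            k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
            for k, v in dataclasses.asdict(cfg).items()
            if k != "outdir"
        },
        "convergence_warnings": [],
        "nudge_counts": {},
    }
    try:
        # ---- inputs -----------------------------------------------------
        stage = "inputs"
        if cfg.synthetic:
            ccfg = cfg.cohort_config or simulate.CohortConfig(seed=cfg.seed)
            dataset = simulate.generate_cohorts(ccfg)
            dataset.write(outdir / "inputs")
            diaries, table = dataset.diaries, dataset.table
        else:
            diaries = parse_food_diary(cfg.diary_path, Lexicon.default())
            table = community.load_asv_table(
                cfg.counts_path, cfg.taxonomy_path, cfg.metadata_path
            )

        score_cfg = cfg.score_config
        cohorts = sorted(table.metadata["cohort"].unique())

        # ---- dietary scores --------------------------------------------
        stage = "scores"
        daily = pd.concat(
            [daily_score_table(diaries[p], score_cfg) for p in sorted(diaries)],
            ignore_index=True,
        )
        daily.to_csv(outdir / "scores_daily.tsv", sep="\t", index=False)
        cumulative = score_summary_table(
            [diaries[p] for p in sorted(diaries)], score_cfg
        )
        pid2cohort = (
            table.metadata.drop_duplicates("participant_id")
            .set_index("participant_id")["cohort"]
        )
        cumulative["cohort"] = cumulative["participant_id"].map(pid2cohort)
        cumulative.to_csv(outdir / "scores_cumulative.tsv", sep="\t", index=False)

        # ---- cohort comparison (Welch) ----------------------------------
        stage = "cohort_comparison"
        comp_rows = []
        daily_by_pid = daily.merge(
            pid2cohort.rename("cohort"), left_on="participant_id", right_index=True
        )
        for var in ("energy_total", "energy_carb", "energy_fat",
                    "energy_protein", "fiber", "food_diversity",
                    "preprobiotic_diversity"):
            groups = [
                daily_by_pid.loc[daily_by_pid["cohort"] == c, var].to_numpy()
                for c in cohorts
            ]
            if len(groups) == 2 and all(len(g) >= 2 for g in groups):
                try:
                    t, df, p = stats.welch_test(
                        groups[0].mean(), groups[0].std(ddof=1), len(groups[0]),
                        groups[1].mean(), groups[1].std(ddof=1), len(groups[1]),
                    )
                except stats.StatsError:
                    continue
                comp_rows.append(
                    {"variable": var,
                     f"mean_{cohorts[0]}": groups[0].mean(),
                     f"mean_{cohorts[1]}": groups[1].mean(),
                     "t": t, "welch_df": df, "p_value": p}
                )
        pd.DataFrame(comp_rows).to_csv(
            outdir / "cohort_comparison.tsv", sep="\t", index=False
        )

        # ---- alpha diversity + LMMs ------------------------------------
        stage = "alpha_diversity"
        alpha = community.alpha_diversity_table(table)
        alpha.to_csv(outdir / "alpha_diversity.tsv", sep="\t")
        diet = _sample_diet_table(table, diaries, score_cfg)
        for cohort in cohorts:
            sub_ids = table.metadata.index[table.metadata["cohort"] == cohort]
            lmm = _alpha_models(alpha.loc[sub_ids], diet.loc[sub_ids])
            lmm.to_csv(outdir / f"lmm_alpha_{cohort}.tsv", sep="\t", index=False)

        # ---- beta diversity: distances, PCoA, UPGMA, PERMANOVA ----------
        stage = "beta_diversity"
        dm = community.bray_curtis(table)
        pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
            outdir / "bray_curtis_merged.tsv", sep="\t"
        )
        coords, eigvals = community.pcoa(dm, k=2)
        coords.to_csv(outdir / "pcoa_coordinates.tsv", sep="\t")
        np.savetxt(outdir / "pcoa_eigenvalues.tsv", eigvals)
        for period in ("before", "after"):
            ids = table.metadata.index[table.metadata["period"] == period]
            if len(ids) >= 2:
                sub_dm = community.bray_curtis(table.subset_samples(ids))
                (outdir / f"upgma_{period}.nwk").write_text(
                    community.upgma(sub_dm)
                )

        stage = "permanova"
        terms = ["cohort", "participant_id", "period"] if len(cohorts) > 1 else [
            "participant_id", "period"]
        usable = [t for t in terms if table.metadata[t].nunique() > 1]
        perma = stats.permanova(
            dm, table.metadata, usable, n_perm=cfg.n_perm, seed=cfg.seed + 1
        )
        perma.table.to_csv(outdir / "permanova_merged.tsv", sep="\t")

        # per-cohort single-variable PERMANOVAs on the diet covariates
        for cohort in cohorts:
            sub = table.subset_cohort(cohort)
            sub_dm = community.bray_curtis(sub)
            rows = []
            sub_diet = diet.loc[sub.sample_ids]
            for var in DIET_VARS:
                cov = sub_diet[[var]].dropna()
                if cov[var].nunique() < 2:
                    continue
                ids = [s for s in sub.sample_ids if s in cov.index]
                res = stats.permanova(
                    community.bray_curtis(sub.subset_samples(ids)),
                    cov, [var], n_perm=cfg.n_perm, seed=cfg.seed + 2,
                )
                rows.append(
                    {"variable": var, "R2": res.r2(var),
                     "pseudo_F": res.table.loc[var, "pseudo_F"],
                     "p_value": res.p_value(var)}
                )
            pd.DataFrame(rows).to_csv(
                outdir / f"permanova_diet_{cohort}.tsv", sep="\t", index=False
            )

        # ---- stability series + gamma GLMM ------------------------------
        stage = "stability"
        for cohort in cohorts:
            sub = table.subset_cohort(cohort)
            pooled = community.pooled_stability_table(sub, diaries, score_cfg)
            pooled.to_csv(outdir / f"stability_{cohort}.tsv", sep="\t", index=False)
            if pooled.empty:
                continue
            y = pooled["bray_curtis_change"].to_numpy()
            nudged, n_nudges = stats.nudge_zeros(y)
            manifest["nudge_counts"][cohort] = n_nudges
            shape, rate, ks, ks_p = stats.gamma_gof(nudged)
            manifest[f"gamma_gof_{cohort}"] = {
                "shape": shape, "rate": rate, "ks_statistic": ks, "ks_p": ks_p
            }
            model_table = stats.stability_model_table(
                pooled, [v for v in DIET_VARS], adjust_for="energy_total"
            )
            model_table.to_csv(outdir / f"stability_model_{cohort}.tsv", sep="\t")
            for term, row in model_table.iterrows():
                if row.get("univariable_converged") is False:
                    manifest["convergence_warnings"].append(
                        f"stability {cohort} univariable {term}"
                    )

        # ---- taxonomy summaries, dominance, overlap ----------------------
        stage = "taxonomy"
        community.genus_summary(table, cfg.other_threshold).to_csv(
            outdir / "genus_summary.tsv", sep="\t"
        )
        community.dominance_census(table, cfg.dominance_threshold).to_csv(
            outdir / "dominance.tsv", sep="\t", index=False
        )
        if len(cohorts) == 2:
            ta = table.subset_cohort(cohorts[0])
            tb = table.subset_cohort(cohorts[1])
            overlap = {
                rank: community.shared_features(ta, tb, rank)
                for rank in ("asv", "genus")
            }
            (outdir / "shared_features.json").write_text(
                json.dumps(overlap, indent=1)
            )

        # ---- NB association matrices -------------------------------------
        stage = "nb_associations"
        for cohort in cohorts:
            sub = table.subset_cohort(cohort)
            sub_diaries = {
                p: d for p, d in diaries.items()
                if p in set(sub.metadata["participant_id"])
            }
            matrices, screens = _nb_associations(
                sub, sub_diaries, diet.loc[sub.sample_ids], cfg
            )
            for var, screen in screens.items():
                screen.to_csv(
                    outdir / f"candidates_{cohort}_{var}.tsv", sep="\t", index=False
                )
            assoc_json = {}
            for tier, matrix in matrices.items():
                matrix.to_frame().to_csv(
                    outdir / f"associations_{cohort}_{tier}.tsv", sep="\t"
                )
                assoc_json[tier] = matrix.to_records()
                n_missing = int((matrix.cells["p_bin"] == "missing").sum())
                if n_missing:
                    manifest["convergence_warnings"].append(
                        f"associations {cohort} {tier}: {n_missing} non-converged cells"
                    )
            (outdir / f"associations_{cohort}.json").write_text(
                json.dumps(assoc_json, indent=1, default=float)
            )

        # ---- manifest ----------------------------------------------------
        stage = "manifest"
        from . import __version__

        manifest["versions"] = {
            "weanbiome": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=1, default=str)
        )
    except Exception as exc:
        if fresh:
            shutil.rmtree(outdir, ignore_errors=True)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    return outdir


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def report_summary(outdir: str | Path, p_threshold: float = 0.05) -> str:
    """One-page markdown summary regenerated deterministically from artifacts."""
    outdir = Path(outdir)
    required = ["cohort_comparison.tsv", "dominance.tsv", "manifest.json"]
    for name in required:
        if not (outdir / name).exists():
            raise PipelineError(f"missing artifact {name}")
    manifest = json.loads((outdir / "manifest.json").read_text())
    lines = ["# Run summary", "", f"Seed: {manifest['seed']}", ""]

    comp = pd.read_csv(outdir / "cohort_comparison.tsv", sep="\t")
    lines.append("## Cohort diet comparison (Welch tests on daily values)")
    for _, row in comp.iterrows():
        flag = " *" if row["p_value"] < p_threshold else ""
        means = [c for c in comp.columns if c.startswith("mean_")]
        lines.append(
            f"- {row['variable']}: "
            + " vs ".join(f"{row[m]:.2f}" for m in means)
            + f", p = {row['p_value']:.3g}{flag}"
        )
    lines.append("")

    dom = pd.read_csv(outdir / "dominance.tsv", sep="\t")
    lines.append("## Dominance census")
    for cohort, grp in dom.groupby("cohort"):
        counts = grp["dominant_genus"].value_counts()
        desc = ", ".join(f"{g}: {n}/{len(grp)}" for g, n in counts.items())
        lines.append(f"- cohort {cohort}: {desc}")
    lines.append("")

    for path in sorted(outdir.glob("stability_model_*.tsv")):
        cohort = path.stem.split("_")[-1]
        tab = pd.read_csv(path, sep="\t", index_col=0)
        lines.append(f"## Stability model (gamma GLMM), cohort {cohort}")
        for term, row in tab.iterrows():
            est, p = row["multivariable_estimate"], row["multivariable_p"]
            if np.isnan(est):
                est, p = row["univariable_estimate"], row["univariable_p"]
                tier = "univariable"
            else:
                tier = "adjusted"
            if np.isnan(est):
                continue
            flag = " *" if p < p_threshold else ""
            lines.append(f"- {term} ({tier}): estimate {est:+.4f}, p = {p:.3g}{flag}")
        lines.append("")

    sig_cells = []
    for path in sorted(outdir.glob("associations_*.json")):
        recs = json.loads(path.read_text())
        cohort = path.stem.split("_")[-1]
        for tier, cells in recs.items():
            if tier != "multivariate_II":
                continue
            for cell in cells:
                pv = cell.get("p_value")
                if pv is not None and not (isinstance(pv, float) and np.isnan(pv)) \
                        and pv < p_threshold:
                    sig_cells.append((cohort, cell))
    lines.append("## Top taxon-diet associations (fully adjusted NB models)")
    if not sig_cells:
        lines.append(f"no associations at p < {p_threshold}")
    else:
        sig_cells.sort(key=lambda c: c[1]["p_value"])
        for cohort, cell in sig_cells[:10]:
            sign = "+" if cell["sign"] > 0 else "-"
            lines.append(
                f"- [{cohort}] {cell['taxon']} ~ {cell['diet_var']}: "
                f"{sign} (p bin {cell['p_bin']}, p = {cell['p_value']:.3g})"
            )
    lines.append("")
    text = "\n".join(lines)
    (outdir / "summary.md").write_text(text)
    return text
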