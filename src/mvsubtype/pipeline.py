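"""End-to-end orchestration of the five-experiment design: per-view raw
features, GCCA embedding, and DGCCA embedding feed the same clustering and
validation battery; every stage is seeded from one global seed and every
output is a CSV indexed by a JSON manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clinical, genetics, subtyping
from .dgcca import NetworkSpec, TrainConfig, embed, train_dgcca
from .embedding import correlation_table, select_components, variance_curve
from .gcca import fit_gcca, project_view, standardize_views
from .io import load_views
from .synthetic import (
    CLINICAL_MEASURES,
    COVARIATE_COLUMNS,
    SyntheticConfig,
    generate_clinical,
    generate_genotypes,
    generate_multiview,
    generate_survival,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]

# fixed stage order for the seed fan-out; toggling stages never reshuffles seeds
_STAGES = ("data", "gcca", "dgcca", "cluster", "independence", "clinical",
           "survival", "genetics")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: global seed advanced by the stage's
    fixed counter position."""
    return int(np.random.SeedSequence([global_seed, _STAGES.index(stage)])
               .generate_state(1)[0])


@dataclass
class PipelineConfig:
    output_dir: str = "mvsubtype_output"
    seed: int = 0
    synthetic: SyntheticConfig | None = None
    view_paths: list[str] = field(default_factory=list)
    experiments: list[str] = field(default_factory=lambda: ["views", "gcca", "dgcca"])
    gcca_k: int | None = None  # default: max usable
    gcca_ridge: float = 1e-6
    train: TrainConfig = field(default_factory=TrainConfig)
    hidden_dims: tuple[int, ...] = (96, 96)
    dropout_prob: float = 0.1
    n_clusters: int = 2
    linkage: str = "ward"
    alpha: float = 0.01
    fdr_q: float = 0.05
    n_permutations: int = 199
    run_independence: bool = False
    cox_strength: float = 0.1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            syn = dict(raw["synthetic"])
            for key in ("view_dims", "maf_range", "clinical_effect_sizes"):
                if key in syn:
                    syn[key] = tuple(syn[key])
            raw["synthetic"] = SyntheticConfig(**syn)
        if "train" in raw and raw["train"] is not None:
            raw["train"] = TrainConfig(**raw["train"])
        if "hidden_dims" in raw:
            raw["hidden_dims"] = tuple(raw["hidden_dims"])
        return cls(**raw)


class _Manifest:
    def __init__(self, outdir: Path, seed: int):
        self.outdir = outdir
        self.entries: dict[str, dict] = {}
        self.meta = {"seed": seed, "stages": {}}

    def add(self, name: str, df: pd.DataFrame) -> Path:
        path = self.outdir / name
        df.to_csv(path, index=False)
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.entries[name] = {"path": str(path), "sha256": digest, "rows": len(df)}
        return path

    def log_stage(self, stage: str, **info) -> None:
        self.meta["stages"][stage] = info

    def write(self) -> Path:
        path = self.outdir / "manifest.json"
        path.write_text(
            json.dumps({"meta": self.meta, "files": self.entries}, indent=2)
        )
        return path


def _assemble_data(config: PipelineConfig):
    if config.synthetic is not None:
        syn = config.synthetic
        dataset, truth = generate_multiview(syn)
        labels = truth.cluster_labels
        data_seed = stage_seed(config.seed, "data")
        clinical_table = generate_clinical(labels, syn, seed=data_seed + 1)
        survival_table = generate_survival(labels, syn, seed=data_seed + 2)
        genotypes, phenotype, geno_cov, _ = generate_genotypes(
            labels, syn.n_controls, syn, seed=data_seed + 3
        )
        return dataset, truth, clinical_table, survival_table, (genotypes, phenotype, geno_cov)
    if not config.view_paths:
        raise ValueError("config needs either a synthetic block or view_paths")
    dataset = load_views(config.view_paths)
    return dataset, None, None, None, None


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured experiment end to end; returns the manifest."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir, config.seed)

    dataset, truth, clinical_table, survival_table, geno = _assemble_data(config)
    std_views, _, _ = standardize_views(dataset.views)
    N = dataset.n_samples
    manifest.log_stage("data", n_samples=N, n_views=dataset.n_views,
                       synthetic=config.synthetic is not None)

    feature_sets: dict[str, np.ndarray] = {}
    if "views" in config.experiments:
        for j, X in enumerate(std_views):
            feature_sets[f"view{j + 1}"] = X

    dgcca_target = None
    if "dgcca" in config.experiments:
        seed = stage_seed(config.seed, "dgcca")
        train_cfg = TrainConfig(**{**asdict(config.train), "seed": seed})
        specs = [
            NetworkSpec(input_dim=X.shape[1], hidden_dims=config.hidden_dims,
                        dropout_prob=config.dropout_prob)
            for X in dataset.views
        ]
        model = train_dgcca(dataset.views, specs, train_cfg)
        projections, G_all = embed(model, dataset.views)
        feature_sets["dgcca"] = G_all
        curve = variance_curve(std_views, G_all)
        dgcca_target = float(curve[-1])
        manifest.add("dgcca_embedding.csv", _embedding_frame(dataset.sample_ids, G_all))
        manifest.add("dgcca_history.csv", pd.DataFrame(model.history))
        manifest.add("dgcca_correlations.csv", correlation_table(projections, "all"))
        manifest.add(
            "dgcca_variance_curve.csv",
            pd.DataFrame({"r": np.arange(1, len(curve) + 1), "fraction": curve}),
        )
        manifest.log_stage("dgcca", seed=seed, epochs_ran=model.epochs_ran,
                           k=train_cfg.k, variance_fraction=dgcca_target)

    if "gcca" in config.experiments:
        k_max = config.gcca_k or min(N, sum(X.shape[1] for X in std_views))
        fit = fit_gcca(std_views, k_max, ridge=config.gcca_ridge)
        curve = variance_curve(std_views, fit.G)
        # match the DGCCA embedding's captured variance when available
        target = dgcca_target if dgcca_target is not None else 0.7
        sel = select_components(curve, min(target, float(curve[-1])))
        feature_sets["gcca"] = fit.G[:, : sel.chosen_r]
        projections = [project_view(X, U) for X, U in zip(std_views, fit.U)]
        manifest.add("gcca_embedding.csv",
                     _embedding_frame(dataset.sample_ids, feature_sets["gcca"]))
        manifest.add("gcca_correlations.csv", correlation_table(projections, "all"))
        manifest.add(
            "gcca_variance_curve.csv",
            pd.DataFrame({"r": np.arange(1, len(curve) + 1), "fraction": curve}),
        )
        manifest.log_stage("gcca", k=k_max, chosen_r=sel.chosen_r,
                           target_fraction=target)

    if config.run_independence and dataset.n_views >= 2:
        seed = stage_seed(config.seed, "independence")
        rows = []
        for a in range(dataset.n_views):
            for b in range(a + 1, dataset.n_views):
                res = subtyping.independence_permutation_test(
                    std_views[a], std_views[b], config.n_clusters,
                    config.n_permutations, seed + a * 31 + b,
                    config.linkage, f"view{a + 1}-view{b + 1}",
                )
                rows.append({"view_pair": res.view_pair, "statistic": res.statistic,
                             "p_value": res.p_value,
                             "n_permutations": res.n_permutations})
        manifest.add("independence_tests.csv", pd.DataFrame(rows))
        manifest.log_stage("independence", seed=seed)

    # --- clustering per experiment --------------------------------------
    outcomes, metric_rows, subtype_frames = [], [], {}
    for name, feats in feature_sets.items():
        labels = subtyping.cluster_agglomerative(feats, config.n_clusters,
                                                 config.linkage)
        stage = dataset.stage_labels
        if config.n_clusters == 2:
            smap = subtyping.assign_subtype_labels(labels, stage)
        else:
            smap = {int(c): i + 1 for i, c in enumerate(np.unique(labels))}
        outcome = subtyping.ClusterOutcome(labels, smap, config.n_clusters,
                                           config.linkage, name)
        outcomes.append(outcome)
        row = {
            "experiment": name,
            "ch": subtyping.ch_score(feats, labels),
            "silhouette": subtyping.silhouette_score(feats, labels),
        }
        if stage is not None:
            row["ami_vs_stage"] = subtyping.ami_score(labels, stage)
            manifest.add(f"confusion_{name}.csv",
                         subtyping.confusion_table(outcome.subtypes, stage)
                         .reset_index())
        if truth is not None:
            row["ami_vs_truth"] = subtyping.ami_score(labels, truth.cluster_labels)
        metric_rows.append(row)
        frame = pd.DataFrame({"sample_id": dataset.sample_ids,
                              "cluster": labels, "subtype": outcome.subtypes})
        subtype_frames[name] = frame
        manifest.add(f"subtypes_{name}.csv", frame)

    manifest.add("cluster_metrics.csv", pd.DataFrame(metric_rows))
    if len(outcomes) >= 2:
        sim = subtyping.pairwise_cluster_similarity(outcomes)
        manifest.add("cluster_similarity.csv", sim.reset_index(names="experiment"))
    manifest.log_stage("cluster", seed=stage_seed(config.seed, "cluster"),
                       experiments=list(feature_sets))

    # --- validation ------------------------------------------------------
    if clinical_table is not None:
        frames = []
        for name, frame in subtype_frames.items():
            res = clinical.ranksum_battery(
                clinical_table[CLINICAL_MEASURES], frame["subtype"].to_numpy(),
                alpha=config.alpha,
            )
            res.insert(0, "experiment", name)
            frames.append(res)
        manifest.add("ranksum_battery.csv", pd.concat(frames, ignore_index=True))
        manifest.log_stage("clinical", alpha=config.alpha)
    else:
        logger.warning("no clinical table; skipping rank-sum battery")

    if survival_table is not None and clinical_table is not None:
        covs = CLINICAL_MEASURES + COVARIATE_COLUMNS
        merged = survival_table.merge(clinical_table, on="sample_id")
        fit = clinical.fit_cox(merged, covs, strength=config.cox_strength)
        rows, curve_frames = [], []
        for name, frame in subtype_frames.items():
            sub = frame["subtype"].to_numpy()
            chi2, p, nl2p = clinical.logrank_test(
                merged["time_months"], merged["event"], sub
            )
            rows.append({"experiment": name, "concordance": fit.concordance,
                         "logrank_chi2": chi2, "logrank_p": p, "neg_log2_p": nl2p})
            profiles = {
                f"{name}_subtype{s}": merged.loc[sub == s, covs].mean()
                for s in (1, 2)
            }
            curve_frames.append(clinical.conversion_curves(fit, profiles))
        manifest.add("survival_summary.csv", pd.DataFrame(rows))
        manifest.add("conversion_curves.csv",
                     pd.concat(curve_frames, ignore_index=True))
        coef = fit.coefficients.rename("beta").rename_axis("covariate").reset_index()
        manifest.add("cox_coefficients.csv", coef)
        manifest.log_stage("survival", strength=config.cox_strength)
    else:
        logger.warning("no survival table; skipping conversion analysis")

    if geno is not None:
        genotypes, phenotype, geno_cov = geno
        n_cases = int(phenotype.sum())
        results = []
        assoc_cov = geno_cov[["sample_id", "age", "gender", "education"]]
        for name, frame in subtype_frames.items():
            for s in (1, 2):
                case_ids = frame.loc[frame["subtype"] == s, "sample_id"]
                mask = (genotypes["sample_id"].isin(case_ids).to_numpy()
                        | (phenotype == 0))
                sub_pheno = np.where(
                    genotypes["sample_id"].isin(case_ids).to_numpy()[mask], 1, 0
                )
                res = genetics.case_control_assoc(
                    genotypes[mask],
                    sub_pheno,
                    assoc_cov[mask].drop(columns="sample_id")
                    .assign(sample_id=assoc_cov.loc[mask, "sample_id"])[
                        ["sample_id", "age", "gender", "education"]],
                    test_name=f"{name}_subtype{s}_vs_control",
                )
                results.append(res)
        manifest.add("association_results.csv",
                     pd.concat(results, ignore_index=True))
        summary = genetics.assoc_summary(results, q=config.fdr_q)
        if not summary.empty:
            manifest.add("association_summary.csv",
                         summary.reset_index())
        manifest.log_stage("genetics", n_cases=n_cases, q=config.fdr_q)
    else:
        logger.warning("no genotypes; skipping association analysis")

    manifest.write()
    return {"meta": manifest.meta, "files": manifest.entries}


def _embedding_frame(sample_ids, G: np.ndarray) -> pd.DataFrame:
    df = pd.DataFrame(G, columns=[f"c{i + 1}" for i in range(G.shape[1])])
    df.insert(0, "sample_id", list(sample_ids))
    return df
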