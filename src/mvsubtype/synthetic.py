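"""Synthetic multiview, clinical, survival and genotype data.

Emulates the statistical structure the analysis pipeline assumes: J feature
views sharing a latent cluster structure (optionally through elementwise
nonlinear maps), subtype-shifted clinical measures, subtype-dependent
conversion hazards with independent censoring, and additive-coded genotypes
with subtype-associated allele frequencies — so every downstream stage is
testable without restricted data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticConfig",
    "MultiviewDataset",
    "GroundTruth",
    "simplex_means",
    "generate_multiview",
    "generate_clinical",
    "generate_survival",
    "generate_genotypes",
    "write_genotypes_raw",
]

CLINICAL_MEASURES = [
    "cog_score_1",
    "cog_score_2",
    "cog_score_3",
    "cog_score_4",
    "cog_score_5",
    "vol_measure_1",
    "vol_measure_2",
    "vol_measure_3",
    "vol_measure_4",
    "vol_measure_5",
    "vol_measure_6",
]
COVARIATE_COLUMNS = ["age", "gender", "education", "e4_carrier"]


@dataclass
class SyntheticConfig:
    n_samples: int = 308
    n_views: int = 3
    view_dims: tuple[int, ...] = (116, 116, 116)
    latent_dim: int = 5
    n_clusters: int = 2
    cluster_separation: float = 4.0
    nonlinearity: str = "linear"  # linear | tanh | quadratic
    noise_sd: float = 0.5
    n_controls: int = 219
    n_snps: int = 100
    n_causal_snps: int = 5
    maf_range: tuple[float, float] = (0.05, 0.5)
    causal_af_shift: float = 0.2
    hazard_ratio: float = 2.0
    baseline_hazard: float = 0.02  # events per month in subtype 1
    censor_rate: float = 0.2
    clinical_effect_sizes: tuple[float, ...] = (1.0,) * 11
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.view_dims) != self.n_views:
            raise ValueError("view_dims must list one width per view")
        if min(self.n_samples, self.n_views, self.latent_dim, self.n_clusters) < 1:
            raise ValueError("counts must be >= 1")
        if self.latent_dim > min(self.view_dims):
            raise ValueError("latent_dim may not exceed min(view_dims)")
        if self.n_clusters > self.n_samples:
            raise ValueError("more clusters than samples")
        if self.n_clusters > self.latent_dim + 1:
            raise ValueError(
                "equidistant cluster means need n_clusters <= latent_dim + 1"
            )
        if self.nonlinearity not in ("linear", "tanh", "quadratic"):
            raise ValueError(f"unknown nonlinearity {self.nonlinearity!r}")
        if self.cluster_separation < 0 or self.noise_sd < 0:
            raise ValueError("separation and noise_sd must be nonnegative")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not 0 <= self.causal_af_shift < 0.5:
            raise ValueError("causal_af_shift must lie in [0, 0.5)")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be positive")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must lie in [0, 1)")
        if len(self.clinical_effect_sizes) != 11:
            raise ValueError("clinical_effect_sizes must have length 11")


@dataclass
class MultiviewDataset:
    """Aligned sample x feature views plus optional annotations."""

    views: list[np.ndarray]
    sample_ids: list[str]
    feature_names: list[list[str]]
    stage_labels: np.ndarray | None = None
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")
        for j, (X, names) in enumerate(zip(self.views, self.feature_names)):
            if X.shape != (n, len(names)):
                raise ValueError(f"view {j}: shape {X.shape} != ({n}, {len(names)})")
            if not np.all(np.isfinite(X)):
                raise ValueError(f"view {j}: non-finite values")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_views(self) -> int:
        return len(self.views)


@dataclass
class GroundTruth:
    latent: np.ndarray
    cluster_labels: np.ndarray  # integers in [1, n_clusters]
    causal_snp_indices: np.ndarray = field(default_factory=lambda: np.array([], int))
    true_log_hr: float = 0.0


def simplex_means(n_clusters: int, latent_dim: int, separation: float) -> np.ndarray:
    """Centered regular-simplex vertices in R^latent_dim with all pairwise
    distances equal to ``separation``."""
    if n_clusters > latent_dim + 1:
        raise ValueError("need n_clusters <= latent_dim + 1")
    # vertices of the regular simplex from scaled standard basis vectors
    V = np.eye(n_clusters)  # pairwise distance sqrt(2)
    V = V - V.mean(axis=0)
    # drop to an (n_clusters-1)-dim orthonormal basis, embed in latent_dim
    q, _ = np.linalg.qr(V.T)
    coords = V @ q[:, : max(n_clusters - 1, 1)]
    means = np.zeros((n_clusters, latent_dim))
    means[:, : coords.shape[1]] = coords * (separation / np.sqrt(2.0))
    return means


def _apply_nonlinearity(Z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "linear":
        return Z
    if kind == "tanh":
        return np.tanh(Z)
    if kind == "quadratic":
        return Z + 0.5 * Z**2
    raise ValueError(f"unknown nonlinearity {kind!r}")


def generate_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Fixed simple covariate distributions loosely matching an elderly
    study cohort."""
    return pd.DataFrame(
        {
            "age": rng.normal(72.0, 7.0, n),
            "gender": rng.integers(0, 2, n),
            "education": rng.normal(16.0, 2.6, n),
            "e4_carrier": rng.binomial(2, 0.3, n),
        }
    )


def generate_multiview(
    config: SyntheticConfig,
) -> tuple[MultiviewDataset, GroundTruth]:
    """Draw J views from a shared clustered latent space.

    Cluster labels are uniform; latents are ``Normal(mu_c, I_d)`` with the
    cluster means at regular-simplex vertices; each view is
    ``f_j(Z A_j) + eps_j`` for a fixed random mixing ``A_j`` and elementwise
    ``f_j`` chosen by ``config.nonlinearity``.
    """
    rng = np.random.Generator(np.random.PCG64(config.seed))
    n, d = config.n_samples, config.latent_dim

    labels = rng.integers(1, config.n_clusters + 1, size=n)
    means = simplex_means(config.n_clusters, d, config.cluster_separation)
    latent = means[labels - 1] + rng.normal(size=(n, d))

    views, feature_names = [], []
    for j, p in enumerate(config.view_dims):
        A = rng.normal(0.0, 1.0 / np.sqrt(d), size=(d, p))
        X = _apply_nonlinearity(latent @ A, config.nonlinearity)
        if config.noise_sd > 0:
            X = X + rng.normal(0.0, config.noise_sd, size=X.shape)
        views.append(X)
        feature_names.append([f"v{j + 1}_roi{i + 1:03d}" for i in range(p)])

    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    # stage labels: an EMCI/LMCI analog correlated with cluster membership
    flip = rng.random(n) < 0.25
    stage = np.where((labels == labels.min()) ^ flip, "early", "late")
    covariates = generate_covariates(rng, n)
    covariates.insert(0, "sample_id", sample_ids)

    dataset = MultiviewDataset(
        views=views,
        sample_ids=sample_ids,
        feature_names=feature_names,
        stage_labels=stage,
        covariates=covariates,
    )
    truth = GroundTruth(
        latent=latent,
        cluster_labels=labels,
        true_log_hr=float(np.log(config.hazard_ratio)),
    )
    return dataset, truth


def generate_clinical(
    labels: np.ndarray, config: SyntheticConfig, seed: int | None = None
) -> pd.DataFrame:
    """11 clinical measures with standardized subtype-2 mean shifts, plus
    4 covariates. Measure m is ``effect[m] * 1[label == 2] + N(0,1)``."""
    labels = np.asarray(labels)
    effects = np.asarray(config.clinical_effect_sizes, dtype=float)
    if effects.shape != (11,):
        raise ValueError("clinical_effect_sizes must have length 11")
    rng = np.random.Generator(
        np.random.PCG64(config.seed + 1 if seed is None else seed)
    )
    n = len(labels)
    shift = (labels == 2).astype(float)
    data = {
        name: effects[m] * shift + rng.normal(size=n)
        for m, name in enumerate(CLINICAL_MEASURES)
    }
    table = pd.DataFrame(data)
    table = pd.concat([table, generate_covariates(rng, n)], axis=1)
    table.insert(0, "sample_id", [f"S{i + 1:04d}" for i in range(n)])
    return table


def generate_survival(
    labels: np.ndarray, config: SyntheticConfig, seed: int | None = None
) -> pd.DataFrame:
    """Exponential conversion times with a subtype-2 hazard ratio and
    independent exponential censoring hitting ``censor_rate`` exactly in
    expectation (censor hazard mu = lambda * c / (1 - c))."""
    labels = np.asarray(labels)
    rng = np.random.Generator(
        np.random.PCG64(config.seed + 2 if seed is None else seed)
    )
    n = len(labels)
    rate = config.baseline_hazard * np.where(labels == 2, config.hazard_ratio, 1.0)
    event_time = rng.exponential(1.0 / rate)
    if config.censor_rate > 0:
        c = config.censor_rate
        censor_rate_param = rate * c / (1.0 - c)
        censor_time = rng.exponential(1.0 / censor_rate_param)
    else:
        censor_time = np.full(n, np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    return pd.DataFrame(
        {
            "sample_id": [f"S{i + 1:04d}" for i in range(n)],
            "time_months": time,
            "event": event,
            "group": labels,
        }
    )


def generate_genotypes(
    subtype_labels: np.ndarray,
    n_controls: int,
    config: SyntheticConfig,
    seed: int | None = None,
) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame, np.ndarray]:
    """Additive 0/1/2 genotypes for cases (the subtyped samples) plus a
    control cohort.

    Non-causal SNPs are Hardy-Weinberg draws at a shared minor-allele
    frequency; causal SNPs shift the allele frequency by
    ``causal_af_shift`` in subtype-2 cases.

    Returns (genotypes, phenotype, covariates, causal_indices): genotypes
    has `sample_id` then one column per SNP; phenotype is 1 for cases,
    0 for controls; causal_indices are 0-based SNP column positions.
    """
    subtype_labels = np.asarray(subtype_labels)
    rng = np.random.Generator(
        np.random.PCG64(config.seed + 3 if seed is None else seed)
    )
    n_cases = len(subtype_labels)
    n_total = n_cases + n_controls
    mafs = rng.uniform(*config.maf_range, size=config.n_snps)
    causal = rng.choice(config.n_snps, size=config.n_causal_snps, replace=False)
    causal = np.sort(causal)
    shifted = mafs[causal] + config.causal_af_shift
    if np.any(shifted >= 1.0) or np.any(shifted <= 0.0):
        raise ValueError("causal_af_shift pushes an allele frequency outside (0, 1)")

    af = np.tile(mafs, (n_total, 1))
    is_shifted_case = np.concatenate(
        [subtype_labels == 2, np.zeros(n_controls, bool)]
    )
    af[np.ix_(is_shifted_case, causal)] = shifted
    geno = rng.binomial(2, af)

    sample_ids = [f"S{i + 1:04d}" for i in range(n_cases)] + [
        f"C{i + 1:04d}" for i in range(n_controls)
    ]
    chroms = (np.arange(config.n_snps) % 22) + 1
    snp_cols = [f"chr{c}_snp{i + 1:05d}" for i, c in enumerate(chroms)]
    genotypes = pd.DataFrame(geno, columns=snp_cols)
    genotypes.insert(0, "sample_id", sample_ids)
    phenotype = np.concatenate([np.ones(n_cases, int), np.zeros(n_controls, int)])
    covariates = generate_covariates(rng, n_total)
    covariates.insert(0, "sample_id", sample_ids)
    return genotypes, phenotype, covariates, causal


def write_genotypes_raw(
    genotypes: pd.DataFrame, phenotype: np.ndarray, path: str
) -> None:
    """Write genotypes in the PLINK additive text dialect (.raw-style):
    FID IID PAT MAT SEX PHENOTYPE then one 0/1/2 column per SNP."""
    snp_cols = [c for c in genotypes.columns if c != "sample_id"]
    out = pd.DataFrame(
        {
            "FID": genotypes["sample_id"],
            "IID": genotypes["sample_id"],
            "PAT": 0,
            "MAT": 0,
            "SEX": 0,
            # PLINK convention: 2 = case, 1 = control
            "PHENOTYPE": np.asarray(phenotype) + 1,
        }
    )
    out = pd.concat([out, genotypes[snp_cols]], axis=1)
    out.to_csv(path, sep=" ", index=False)
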