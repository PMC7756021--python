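"""Bulk normalization, gene filtering, covariate encoding and sample QC.

RNA-seq cohorts are expressed in counts per million, filtered by the
10/L-CPM-in-at-least-N-samples rule (L = minimum library size in million
reads, N = smallest analysis group), log2-transformed and quantile
normalized.  Microarray cohorts enter as normalized log2 intensities and
are quantile normalized directly.  Covariates are encoded for three
dataset profiles: the RIN is dichotomized at a profile-specific cut, the
RNA-degradation slope at 5, and the disease status and neuronal proportion
are mean-centered, with their product as the interaction term for AD-like
profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from braincyto.diffexp import bh_fdr

PROFILES = {
    "ad_rnaseq": {
        "required": ["disease", "rin", "age", "sex", "neuronal_fraction"],
        "rin_cut": 8.5,
        "interaction": True,
    },
    "pd_rnaseq": {
        "required": ["disease", "rin", "age", "batch", "neuronal_fraction"],
        "rin_cut": 7.8,
        "interaction": False,
    },
    "pd_microarray": {
        "required": ["disease", "age", "degradation_slope", "neuronal_fraction"],
        "rin_cut": None,
        "interaction": False,
    },
}


@dataclass
class FilterParams:
    """Bulk gene-filter parameters: threshold CPM = 10/L in >= N samples."""

    L: float  # minimum library size in millions
    N: int  # smallest sample size across analysis groups

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ValueError("L must be positive")
        if self.N < 1:
            raise ValueError("N must be at least 1")

    @property
    def cpm_threshold(self) -> float:
        return 10.0 / self.L

    @classmethod
    def from_cohort(cls, counts: np.ndarray, groups: np.ndarray) -> "FilterParams":
        lib = np.asarray(counts).sum(axis=0)
        _, sizes = np.unique(groups, return_counts=True)
        return cls(L=float(lib.min()) / 1e6, N=int(sizes.min()))


@dataclass
class NormalizedMatrix:
    """Quantile-normalized log2 expression with provenance."""

    data: pd.DataFrame  # genes x samples
    library_sizes: np.ndarray | None
    platform: str = "rnaseq"  # "rnaseq" | "microarray"


def cpm(counts: np.ndarray | pd.DataFrame) -> np.ndarray | pd.DataFrame:
    """Counts per million: column j scaled by 1e6 / library_size_j."""
    arr = counts.to_numpy() if isinstance(counts, pd.DataFrame) else np.asarray(counts, dtype=float)
    lib = arr.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("zero library size")
    out = arr / lib * 1e6
    if isinstance(counts, pd.DataFrame):
        return pd.DataFrame(out, index=counts.index, columns=counts.columns)
    return out


def filter_genes_bulk(cpm_matrix: np.ndarray | pd.DataFrame, params: FilterParams) -> np.ndarray:
    """Indices of genes with CPM above 10/L in at least N samples."""
    arr = (
        cpm_matrix.to_numpy()
        if isinstance(cpm_matrix, pd.DataFrame)
        else np.asarray(cpm_matrix)
    )
    n_above = (arr > params.cpm_threshold).sum(axis=1)
    return np.flatnonzero(n_above >= params.N)


def quantile_normalize(
    log_matrix: np.ndarray | pd.DataFrame,
    library_sizes: np.ndarray | None = None,
    platform: str = "rnaseq",
) -> NormalizedMatrix:
    """Classic quantile normalization of a log2 expression matrix.

    Values are ranked within each sample and replaced by the cross-sample
    mean of each rank; ties receive the mean of the tied rank values.
    After normalization every sample's sorted value vector is identical,
    and the operation is idempotent.
    """
    df = (
        log_matrix
        if isinstance(log_matrix, pd.DataFrame)
        else pd.DataFrame(np.asarray(log_matrix, dtype=float))
    )
    if df.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    arr = df.to_numpy(dtype=float)
    reference = np.sort(arr, axis=0).mean(axis=1)
    n = arr.shape[0]
    out = np.empty_like(arr)
    grid = np.arange(1, n + 1, dtype=float)
    for j in range(arr.shape[1]):
        ranks = stats.rankdata(arr[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, reference)
    return NormalizedMatrix(
        data=pd.DataFrame(out, index=df.index, columns=df.columns),
        library_sizes=library_sizes,
        platform=platform,
    )


def log_cpm(counts: np.ndarray | pd.DataFrame, offset: float = 0.5) -> pd.DataFrame:
    """log2(CPM + offset); the +0.5 offset stabilizes low counts."""
    c = cpm(counts)
    arr = c.to_numpy() if isinstance(c, pd.DataFrame) else c
    out = np.log2(arr + offset)
    if isinstance(counts, pd.DataFrame):
        return pd.DataFrame(out, index=counts.index, columns=counts.columns)
    return pd.DataFrame(out)


def encode_covariates(
    metadata: pd.DataFrame,
    profile: str,
    rin_cut: float | None = None,
    degradation_cut: float = 5.0,
) -> pd.DataFrame:
    """Design-ready covariate table for one dataset profile.

    RIN is dichotomized high (1, strictly above the cut) vs low (0, at or
    below); the degradation slope likewise at ``degradation_cut``.  Disease
    and neuronal proportion are mean-centered to diminish the correlation
    between their estimated coefficients; the interaction column (AD
    profile) is the elementwise product of the two centered columns.
    ``metadata`` must carry a ``neuronal_fraction`` column (e.g. the
    deconvolution estimate).
    """
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}")
    prof = PROFILES[profile]
    for fieldname in prof["required"]:
        if fieldname not in metadata.columns:
            raise ValueError(f"metadata is missing required field {fieldname!r}")
        if metadata[fieldname].isna().any():
            raise ValueError(f"metadata field {fieldname!r} contains missing values")

    out = pd.DataFrame(index=metadata.index)
    disease = metadata["disease"].astype(float)
    neuronal = metadata["neuronal_fraction"].astype(float)
    out["disease_c"] = disease - disease.mean()
    out["neuronal_c"] = neuronal - neuronal.mean()
    out["age"] = metadata["age"].astype(float)
    if "sex" in prof["required"]:
        out["sex"] = metadata["sex"].astype(float)  # 1 male, 0 female
    if "rin" in prof["required"]:
        cut = prof["rin_cut"] if rin_cut is None else rin_cut
        out["rin_group"] = (metadata["rin"].astype(float) > cut).astype(float)
    if "batch" in prof["required"]:
        out["batch"] = metadata["batch"].astype(float)
    if "degradation_slope" in prof["required"]:
        out["degradation_group"] = (
            metadata["degradation_slope"].astype(float) > degradation_cut
        ).astype(float)
    if prof["interaction"]:
        out["interaction"] = out["disease_c"] * out["neuronal_c"]
    return out


@dataclass
class PCAReport:
    variance_explained: np.ndarray  # percent per component
    scores: pd.DataFrame  # samples x PCs
    correlations: pd.DataFrame  # PC x covariate Pearson r
    ks_tests: pd.DataFrame  # PC x (statistic, p) between arms
    outliers: list


def pca_qc(
    normalized: NormalizedMatrix,
    metadata: pd.DataFrame,
    fractions: pd.DataFrame | None = None,
    outlier_z: float = 4.0,
    n_components: int = 5,
) -> PCAReport:
    """SVD-based PCA of centered expression with composition diagnostics.

    Reports variance explained, Pearson correlations of PC1/PC2 sample
    scores with neuronal fraction, disease, age and sex, Kolmogorov-Smirnov
    tests of score distributions between arms, and robust-z outlier flags
    on PC1/PC2.
    """
    X = normalized.data.to_numpy(dtype=float)
    if X.shape[1] < 3:
        raise ValueError("PCA QC needs at least 3 samples")
    Xc = X - X.mean(axis=1, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    var_explained = var / var.sum() * 100.0
    k = min(n_components, len(s))
    scores = pd.DataFrame(
        (Vt[:k].T * s[:k]),
        index=normalized.data.columns,
        columns=[f"PC{i+1}" for i in range(k)],
    )

    covs: dict[str, np.ndarray] = {}
    if fractions is not None and "neuron" in fractions.columns:
        covs["neuronal_fraction"] = fractions["neuron"].to_numpy(dtype=float)
    elif "neuronal_fraction" in metadata.columns:
        covs["neuronal_fraction"] = metadata["neuronal_fraction"].to_numpy(dtype=float)
    for c in ("disease", "age", "sex"):
        if c in metadata.columns and not metadata[c].isna().any():
            covs[c] = metadata[c].to_numpy(dtype=float)

    rows = {}
    for pc in ("PC1", "PC2"):
        rows[pc] = {
            name: (
                stats.pearsonr(scores[pc], v)[0] if np.std(v) > 0 else np.nan
            )
            for name, v in covs.items()
        }
    correlations = pd.DataFrame(rows).T

    ks_rows = {}
    if "disease" in metadata.columns:
        arm = metadata["disease"].to_numpy() > 0
        for pc in ("PC1", "PC2"):
            if arm.any() and (~arm).any():
                st, p = stats.ks_2samp(scores[pc][arm], scores[pc][~arm])
            else:
                st, p = np.nan, np.nan
            ks_rows[pc] = {"statistic": st, "p": p}
    ks_tests = pd.DataFrame(ks_rows).T

    outliers = []
    for pc in ("PC1", "PC2"):
        v = scores[pc].to_numpy()
        med = np.median(v)
        mad = 1.4826 * np.median(np.abs(v - med))
        if mad > 0:
            flag = np.abs(v - med) / mad > outlier_z
            outliers.extend(scores.index[flag].tolist())
    return PCAReport(
        variance_explained=var_explained,
        scores=scores,
        correlations=correlations,
        ks_tests=ks_tests,
        outliers=sorted(set(outliers)),
    )


def correlation_cluster_qc(
    normalized: NormalizedMatrix, late_fraction: float = 0.1
) -> tuple[np.ndarray, list]:
    """Hierarchical clustering (average linkage) on Euclidean distances
    between rows of the sample-sample Pearson-correlation matrix; flags
    samples that are still singletons when the last merges happen."""
    X = normalized.data.to_numpy(dtype=float)
    n = X.shape[1]
    if n < 3:
        raise ValueError("clustering QC needs at least 3 samples")
    corr = np.corrcoef(X.T)
    Z = hierarchy.linkage(pdist(corr, metric="euclidean"), method="average")

    # step at which each original sample first joins any cluster
    first_merge = np.full(n, -1)
    for step, (a, b, _, _) in enumerate(Z):
        for node in (int(a), int(b)):
            if node < n and first_merge[node] == -1:
                first_merge[node] = step
    cutoff = (n - 1) - max(int(np.ceil(late_fraction * (n - 1))), 1)
    flags = normalized.data.columns[first_merge >= cutoff].tolist()
    return Z, flags


def suggest_batch_split(normalized: NormalizedMatrix) -> pd.Series:
    """Heuristic two-group split by the sign of PC1 scores, offered as a
    candidate 'unknown batch' covariate; the user decides whether to adopt it."""
    X = normalized.data.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    return pd.Series(
        (Vt[0] > 0).astype(int), index=normalized.data.columns, name="suggested_batch"
    )


def marker_checks(
    normalized: NormalizedMatrix,
    metadata: pd.DataFrame,
    marker_sets: dict[str, list[str]],
) -> pd.DataFrame:
    """Welch two-sample t-tests of marker expression, diseased vs control,
    BH-adjusted within the table; absent markers are listed as missing and
    zero-variance markers reported as NA."""
    arm = metadata["disease"].to_numpy() > 0
    rows = []
    for cell_type, markers in marker_sets.items():
        for gene in markers:
            if gene not in normalized.data.index:
                rows.append(
                    {"cell_type": cell_type, "gene": gene, "status": "missing",
                     "mean_diff": np.nan, "t": np.nan, "p": np.nan}
                )
                continue
            v = normalized.data.loc[gene].to_numpy(dtype=float)
            a, b = v[arm], v[~arm]
            if np.var(a) == 0 and np.var(b) == 0:
                rows.append(
                    {"cell_type": cell_type, "gene": gene, "status": "na",
                     "mean_diff": a.mean() - b.mean(), "t": np.nan, "p": np.nan}
                )
                continue
            t, p = stats.ttest_ind(a, b, equal_var=False)
            rows.append(
                {"cell_type": cell_type, "gene": gene, "status": "ok",
                 "mean_diff": a.mean() - b.mean(), "t": t, "p": p}
            )
    table = pd.DataFrame(rows)
    ok = table["status"] == "ok"
    table["fdr"] = np.nan
    if ok.any():
        table.loc[ok, "fdr"] = bh_fdr(table.loc[ok, "p"].to_numpy())
    return table
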