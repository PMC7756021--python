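"""Single-cell QC, gene filtering, variance decomposition and signatures.

Cells are screened on three metrics -- library size, number of expressed
genes (both on log scale) and mitochondrial read fraction -- using robust
z-scores in MAD units.  Genes are kept when their mean CPM exceeds 1
(log10 > 0) and their expression variance carries a biological component
beyond the mean-variance trend.  A nearest-shrunken-centroid classifier
flags candidate misclassified cells, and cell-type signature columns are
per-type mean CPM restricted to type-specific marker genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from braincyto.diffexp import bh_fdr
from braincyto.simulate import SingleCellDataset

MAD_SCALE = 1.4826  # consistency with the normal SD


@dataclass
class CellQCMetrics:
    """Per-cell QC metrics with robust z-scores (MAD units)."""

    table: pd.DataFrame  # library_size, n_expressed, mito_fraction, z_* columns
    zero_mad_metrics: list[str]

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class VarianceDecomposition:
    """Per-gene decomposition of log-expression variance.

    ``biological`` equals ``total - technical`` exactly; ``retain`` flags
    genes whose total variance significantly exceeds the technical trend.
    """

    table: pd.DataFrame  # mean, total, technical, biological, p, fdr, retain

    @property
    def retained(self) -> np.ndarray:
        return self.table.index[self.table["retain"]].to_numpy()


@dataclass
class SignatureMatrix:
    """Genes x cell-types reference expression (CPM scale) for deconvolution."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.data.to_numpy().sum(axis=1) == 0).any():
            raise ValueError("signature contains all-zero rows")

    @property
    def genes(self) -> np.ndarray:
        return self.data.index.to_numpy()

    @property
    def cell_types(self) -> list[str]:
        return list(self.data.columns)


def _robust_z(values: np.ndarray) -> tuple[np.ndarray, bool]:
    med = np.median(values)
    mad = MAD_SCALE * np.median(np.abs(values - med))
    if mad == 0:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(values == med, 0.0, np.sign(values - med) * np.inf)
        return z, True
    return (values - med) / mad, False


def cpm(counts: np.ndarray) -> np.ndarray:
    """Counts-per-million per column; errors on zero libraries."""
    lib = np.asarray(counts, dtype=float).sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("zero library size")
    return counts / lib * 1e6


def compute_cell_qc(sc: SingleCellDataset) -> CellQCMetrics:
    """Library size, expressed-gene count and mitochondrial fraction per cell,
    each with a robust z in MAD units (library size and gene counts on the
    log10 scale)."""
    if sc.n_cells == 0 or sc.n_genes == 0:
        raise ValueError("empty count matrix")
    lib = sc.counts.sum(axis=0).astype(float)
    n_expr = (sc.counts > 0).sum(axis=0).astype(float)
    mito = sc.counts[sc.mito_flag].sum(axis=0) / np.maximum(lib, 1.0)
    mito = np.where(lib > 0, mito, 0.0)

    zero_mad = []
    z_lib, flag = _robust_z(np.log10(np.maximum(lib, 1.0)))
    if flag:
        zero_mad.append("library_size")
    z_expr, flag = _robust_z(np.log10(np.maximum(n_expr, 1.0)))
    if flag:
        zero_mad.append("n_expressed")
    z_mito, flag = _robust_z(mito)
    if flag:
        zero_mad.append("mito_fraction")

    table = pd.DataFrame(
        {
            "library_size": lib,
            "n_expressed": n_expr,
            "mito_fraction": mito,
            "z_library": z_lib,
            "z_expressed": z_expr,
            "z_mito": z_mito,
        }
    )
    return CellQCMetrics(table=table, zero_mad_metrics=zero_mad)


def filter_cells(metrics: CellQCMetrics) -> tuple[np.ndarray, pd.DataFrame]:
    """Drop cells with library-size or expressed-gene robust z < -3, or
    mitochondrial-fraction robust z > 3.  Returns kept indices and a removal
    log with reasons."""
    t = metrics.table
    bad_lib = t["z_library"] < -3
    bad_expr = t["z_expressed"] < -3
    bad_mito = t["z_mito"] > 3
    removed = bad_lib | bad_expr | bad_mito
    reasons = []
    for i in np.flatnonzero(removed.to_numpy()):
        why = []
        if bad_lib.iloc[i]:
            why.append("low_library")
        if bad_expr.iloc[i]:
            why.append("few_genes")
        if bad_mito.iloc[i]:
            why.append("high_mito")
        reasons.append({"cell": i, "reason": "+".join(why)})
    kept = np.flatnonzero(~removed.to_numpy())
    return kept, pd.DataFrame(reasons, columns=["cell", "reason"])


def filter_genes_sc(sc: SingleCellDataset) -> np.ndarray:
    """Keep genes whose log10 mean CPM exceeds 0, i.e. mean CPM strictly > 1."""
    mean_cpm = cpm(sc.counts).mean(axis=1)
    return np.flatnonzero(mean_cpm > 1.0)


def decompose_variance(
    sc: SingleCellDataset, lowess_frac: float = 0.3, fdr_cut: float = 0.05
) -> VarianceDecomposition:
    """Split each gene's log2(CPM+1) variance into a technical component --
    the mean-variance trend, fitted by local polynomial regression --
    and a biological remainder.

    A gene is retained when its biological component is positive and the
    one-sided F-ratio of total over technical variance (conservative
    n_cells-1 numerator and denominator df) survives BH FDR < ``fdr_cut``.
    """
    if sc.n_genes < 20:
        raise ValueError("need at least 20 genes to fit the mean-variance trend")
    x = np.log2(cpm(sc.counts) + 1.0)
    mean = x.mean(axis=1)
    total = x.var(axis=1, ddof=1)
    if np.ptp(mean) == 0:
        raise ValueError("degenerate spread: all gene means identical")

    fit = lowess(total, mean, frac=lowess_frac, return_sorted=True)
    tech = np.interp(mean, fit[:, 0], fit[:, 1])
    tech = np.maximum(tech, 1e-8)
    bio = total - tech

    d = sc.n_cells - 1
    F = total / tech
    p = stats.f.sf(F, d, d)
    fdr = bh_fdr(p)
    retain = (bio > 0) & (fdr < fdr_cut)
    table = pd.DataFrame(
        {
            "mean": mean,
            "total": total,
            "technical": tech,
            "biological": bio,
            "p": p,
            "fdr": fdr,
            "retain": retain,
        },
        index=pd.Index(sc.gene_names, name="gene"),
    )
    return VarianceDecomposition(table=table)


# ---------------------------------------------------------------------------
# nearest shrunken centroids


@dataclass
class _NSCModel:
    types: list[str]
    shrunken: np.ndarray  # genes x classes
    pooled_sd: np.ndarray  # genes
    s0: float
    priors: np.ndarray


def _nsc_fit(x: np.ndarray, labels: np.ndarray, types: list[str], delta: float) -> _NSCModel:
    n = x.shape[1]
    K = len(types)
    overall = x.mean(axis=1)
    centroids = np.column_stack([x[:, labels == t].mean(axis=1) for t in types])
    nk = np.array([(labels == t).sum() for t in types])
    within_ss = np.zeros(x.shape[0])
    for j, t in enumerate(types):
        within_ss += ((x[:, labels == t] - centroids[:, [j]]) ** 2).sum(axis=1)
    s = np.sqrt(within_ss / max(n - K, 1))
    s0 = float(np.median(s))
    m = np.sqrt(np.maximum(1.0 / nk - 1.0 / n, 1e-12))
    denom = (s + s0)[:, None] * m[None, :]
    d = (centroids - overall[:, None]) / denom
    d_shrunk = np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)
    shrunken = overall[:, None] + denom * d_shrunk
    priors = np.full(K, 1.0 / K)
    return _NSCModel(types=types, shrunken=shrunken, pooled_sd=s, s0=s0, priors=priors)


def _nsc_predict(model: _NSCModel, x: np.ndarray) -> np.ndarray:
    sd2 = (model.pooled_sd + model.s0) ** 2
    scores = np.empty((x.shape[1], len(model.types)))
    for j in range(len(model.types)):
        diff = x - model.shrunken[:, [j]]
        scores[:, j] = (diff**2 / sd2[:, None]).sum(axis=0) - 2.0 * np.log(
            model.priors[j]
        )
    # np.argmin takes the first minimum: ties resolve to the fixed type order
    best = np.argmin(scores, axis=1)
    return np.array([model.types[j] for j in best])


def _log_norm(counts: np.ndarray) -> np.ndarray:
    return np.log2(cpm(counts) + 1.0)


def nsc_classify(
    train: SingleCellDataset,
    test_counts: np.ndarray,
    delta: float,
) -> np.ndarray:
    """Nearest-shrunken-centroid class assignment for test cells.

    Per-gene standardized class-centroid deviations are soft-thresholded by
    ``delta``; a cell is assigned the class with the smallest discriminant
    score (uniform priors, ties broken by the training type order).  Counts
    are log2(CPM+1)-normalized internally.
    """
    if delta < 0:
        raise ValueError("delta must be non-negative")
    types = list(train.cell_types)
    for t in types:
        if (train.cell_type == t).sum() < 2:
            raise ValueError(f"cell type {t!r} has fewer than 2 training cells")
    model = _nsc_fit(_log_norm(train.counts), train.cell_type, types, delta)
    return _nsc_predict(model, _log_norm(test_counts))


def nsc_crossval_delta(
    train: SingleCellDataset,
    deltas: np.ndarray | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> float:
    """Pick the shrinkage threshold by stratified cross-validation: the
    largest delta attaining the minimal CV error."""
    if deltas is None:
        deltas = np.linspace(0.0, 4.0, 9)
    rng = np.random.default_rng(seed)
    x = _log_norm(train.counts)
    labels = train.cell_type
    types = list(train.cell_types)
    folds = np.zeros(train.n_cells, dtype=int)
    for t in types:
        idx = np.flatnonzero(labels == t)
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % n_folds
    errors = np.zeros(len(deltas))
    for f in range(n_folds):
        tr, te = folds != f, folds == f
        if len(np.unique(labels[tr])) < len(types) or te.sum() == 0:
            continue
        for i, delta in enumerate(deltas):
            model = _nsc_fit(x[:, tr], labels[tr], types, delta)
            pred = _nsc_predict(model, x[:, te])
            errors[i] += (pred != labels[te]).sum()
    best = errors == errors.min()
    return float(np.asarray(deltas)[best][-1])


def detect_misclassified(
    sc: SingleCellDataset, delta: float | None = None, seed: int = 0
) -> pd.DataFrame:
    """Cells whose NSC assignment disagrees with their annotated label."""
    if delta is None:
        delta = nsc_crossval_delta(sc, seed=seed)
    pred = nsc_classify(sc, sc.counts, delta)
    bad = np.flatnonzero(pred != sc.cell_type)
    return pd.DataFrame(
        {"cell": bad, "annotated": sc.cell_type[bad], "predicted": pred[bad]}
    )


def build_signature(
    sc: SingleCellDataset,
    retained_genes: np.ndarray | None = None,
    specificity_ratio: float = 2.0,
) -> SignatureMatrix:
    """Cell-type signature: per-type mean CPM over that type's cells,
    restricted to retained genes whose top-type mean is at least
    ``specificity_ratio`` times the second-highest type mean.

    Emits a warning when some declared cell type ends up with no specific
    marker genes (e.g. two effectively identical types)."""
    for t in sc.cell_types:
        if not (sc.cell_type == t).any():
            raise ValueError(f"cell type {t!r} has zero cells")
    x = cpm(sc.counts)
    means = pd.DataFrame(
        {t: x[:, sc.cell_type == t].mean(axis=1) for t in sc.cell_types},
        index=pd.Index(sc.gene_names, name="gene"),
    )
    if retained_genes is not None:
        retained = np.asarray(retained_genes)
        if np.issubdtype(retained.dtype, np.integer):
            mask = np.isin(np.arange(sc.n_genes), retained)
        else:
            mask = means.index.isin(retained.tolist())
        means = means.loc[mask]
    arr = means.to_numpy()
    order = np.sort(arr, axis=1)
    top, second = order[:, -1], order[:, -2]
    specific = (top >= specificity_ratio * np.maximum(second, 1e-12)) & (top > 0)
    sig = means.loc[specific]
    top_type = sig.to_numpy().argmax(axis=1)
    missing = [
        t for j, t in enumerate(sc.cell_types) if not (top_type == j).any()
    ]
    if missing:
        warnings.warn(
            f"no specific marker genes for cell type(s): {', '.join(missing)}",
            UserWarning,
            stacklevel=2,
        )
    if sig.empty:
        raise ValueError("no genes pass the specificity criterion")
    return SignatureMatrix(data=sig)
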