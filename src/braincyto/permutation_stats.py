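"""Cross-dataset and cross-disease permutation statistics.

Cross-dataset consistency: per gene, the product of the disease-coefficient
moderated t-statistics from two independent cohorts is compared with the
products obtained under random permutations of the disease labels within
each cohort (refitting the disease coefficient with all other covariates
retained).  The per-gene proportion of null products at least as extreme as
the observed one is reported as a permutation FDR.

Combined score: S = -log10(FDR) when both t-statistics are positive,
log10(FDR) when both are negative, and 0 when the signs contradict; FDRs of
exactly zero are floored at 1e-5 before taking logarithms.

Cross-disease concordance: the product of the AD and PD combined scores per
gene is compared with a pooled null built by randomly re-pairing the two
score vectors across genes.

Extremeness is two-sided on the product magnitude by default, which makes
the permutation FDR uniformly distributed under the null (a directional
variant is available); contradictory genes are neutralized downstream by
the combined score's sign rule, not by the FDR itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from braincyto.diffexp import (
    EffectResult,
    LinearFit,
    ModelSpec,
    estimate_prior,
    fit_models,
    moderate,
    posterior_variances,
)

FDR_FLOOR = 1e-5  # substitution for exactly-zero permutation FDRs


@dataclass
class ConsistencyResult:
    """Per-gene cross-dataset consistency of the disease effect."""

    table: pd.DataFrame  # t1, t2, product, fdr, (score after combine)
    n_perm: int
    coef: str

    def with_scores(self, floor: float = FDR_FLOOR) -> "ConsistencyResult":
        t = self.table
        score = combined_score(
            t["t1"].to_numpy(), t["t2"].to_numpy(), t["fdr"].to_numpy(), floor=floor
        )
        out = t.copy()
        out["score"] = score
        return ConsistencyResult(table=out, n_perm=self.n_perm, coef=self.coef)


@dataclass
class ConcordanceResult:
    """Per-gene cross-disease concordance of combined scores."""

    table: pd.DataFrame  # score_1, score_2, product, fdr
    n_perm: int

    def with_scores(self, floor: float = FDR_FLOOR) -> "ConcordanceResult":
        """Attach the cross-disease combined score: signed log10 of the
        concordance FDR, positive for genes up in both diseases, negative
        for down in both, zero when the per-disease scores contradict."""
        t = self.table
        score = combined_score(
            t["score_1"].to_numpy(), t["score_2"].to_numpy(),
            t["fdr"].to_numpy(), floor=floor,
        )
        out = t.copy()
        out["score"] = score
        return ConcordanceResult(table=out, n_perm=self.n_perm)


def _extreme_counts(
    null: np.ndarray, obs: np.ndarray, tail: str
) -> np.ndarray:
    """Count null draws at least as extreme as each observation.

    ``null`` has shape (n_draws, n_genes) for per-gene nulls or (n_draws,)
    for a pooled null shared by all genes.
    """
    if tail == "two-sided":
        if null.ndim == 1:
            srt = np.sort(np.abs(null))
            return len(srt) - np.searchsorted(srt, np.abs(obs), side="left")
        return (np.abs(null) >= np.abs(obs)[None, :]).sum(axis=0)
    if tail == "directional":
        if null.ndim == 1:
            srt = np.sort(null)
            hi = len(srt) - np.searchsorted(srt, obs, side="left")
            lo = np.searchsorted(srt, obs, side="right")
            return np.where(obs >= 0, hi, lo)
        hi = (null >= obs[None, :]).sum(axis=0)
        lo = (null <= obs[None, :]).sum(axis=0)
        return np.where(obs >= 0, hi, lo)
    raise ValueError(f"unknown tail {tail!r}")


def _design_matrix(covariates: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, list[str]]:
    X = np.column_stack(
        [np.ones(len(covariates))]
        + [covariates[t].to_numpy(dtype=float) for t in spec.terms]
    )
    return X, ["intercept"] + list(spec.terms)


def _moderated_t_for_design(Y: np.ndarray, X: np.ndarray, j: int) -> np.ndarray:
    """Moderated t of design column ``j`` for all genes (fast path used in
    the permutation loop; mirrors fit_models + moderate)."""
    XtX_inv = np.linalg.inv(X.T @ X)
    proj = X @ XtX_inv
    beta = Y @ proj
    resid = Y - beta @ X.T
    df = X.shape[0] - X.shape[1]
    sigma2 = (resid**2).sum(axis=1) / df
    d0, s0_sq = estimate_prior(sigma2, df)
    s2_post = posterior_variances(sigma2, df, d0, s0_sq)
    u = np.sqrt(XtX_inv[j, j])
    return beta[:, j] / (np.sqrt(s2_post) * u)


def _binary_permutations(values: np.ndarray) -> np.ndarray:
    """All distinct rearrangements of a binary-coded label vector."""
    uniq = np.unique(values)
    if len(uniq) != 2:
        raise ValueError("exhaustive enumeration requires a binary label column")
    n = len(values)
    k = int((values == uniq[1]).sum())
    out = []
    for pos in combinations(range(n), k):
        v = np.full(n, uniq[0])
        v[list(pos)] = uniq[1]
        out.append(v)
    return np.array(out)


def t_product_fdr(
    cohort1: tuple[pd.DataFrame, pd.DataFrame, ModelSpec],
    cohort2: tuple[pd.DataFrame, pd.DataFrame, ModelSpec],
    n_perm: int = 5000,
    seed: int = 0,
    coef: str = "disease_c",
    tail: str = "two-sided",
    exhaustive: bool = False,
) -> ConsistencyResult:
    """Permutation FDR on the cross-dataset product of moderated t-statistics.

    Each cohort is a (normalized expression, encoded covariates, model spec)
    triple; only genes present in both cohorts are scored.  Per permutation
    the ``coef`` column is independently shuffled within each cohort and the
    coefficient refitted with all other covariates unchanged.  With
    ``exhaustive=True`` all distinct label rearrangements are enumerated in
    both cohorts and every cross-pairing contributes to the null (small
    cohorts only).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    if n_perm < 100 and not exhaustive:
        warnings.warn(
            f"n_perm={n_perm} gives a coarse FDR resolution of {1.0 / n_perm:g}",
            UserWarning,
            stacklevel=2,
        )

    (expr1, cov1, spec1), (expr2, cov2, spec2) = cohort1, cohort2
    shared = expr1.index.intersection(expr2.index)
    if len(shared) < 10:
        raise ValueError("fewer than 10 genes shared between cohorts")
    Y1 = expr1.loc[shared].to_numpy(dtype=float)
    Y2 = expr2.loc[shared].to_numpy(dtype=float)
    X1, names1 = _design_matrix(cov1, spec1)
    X2, names2 = _design_matrix(cov2, spec2)
    j1, j2 = names1.index(coef), names2.index(coef)

    t1 = _moderated_t_for_design(Y1, X1, j1)
    t2 = _moderated_t_for_design(Y2, X2, j2)
    obs = t1 * t2

    rng = np.random.default_rng(seed)
    G = len(shared)
    if exhaustive:
        perms1 = _binary_permutations(X1[:, j1])
        perms2 = _binary_permutations(X2[:, j2])
        T1 = np.empty((len(perms1), G))
        T2 = np.empty((len(perms2), G))
        for i, v in enumerate(perms1):
            Xp = X1.copy()
            Xp[:, j1] = v
            T1[i] = _moderated_t_for_design(Y1, Xp, j1)
        for i, v in enumerate(perms2):
            Xp = X2.copy()
            Xp[:, j2] = v
            T2[i] = _moderated_t_for_design(Y2, Xp, j2)
        counts = np.zeros(G, dtype=np.int64)
        for i in range(len(perms1)):
            null = T1[i][None, :] * T2  # all pairings with this cohort-1 perm
            counts += _extreme_counts(null, obs, tail)
        total = len(perms1) * len(perms2)
        fdr = counts / total
        n_used = total
    else:
        counts = np.zeros(G, dtype=np.int64)
        for _ in range(n_perm):
            Xp1 = X1.copy()
            Xp1[:, j1] = rng.permutation(X1[:, j1])
            Xp2 = X2.copy()
            Xp2[:, j2] = rng.permutation(X2[:, j2])
            null = (
                _moderated_t_for_design(Y1, Xp1, j1)
                * _moderated_t_for_design(Y2, Xp2, j2)
            )
            counts += _extreme_counts(null[None, :], obs, tail)
        fdr = counts / n_perm
        n_used = n_perm

    table = pd.DataFrame(
        {"t1": t1, "t2": t2, "product": obs, "fdr": fdr},
        index=pd.Index(shared, name="gene"),
    )
    return ConsistencyResult(table=table, n_perm=n_used, coef=coef)


def combined_score(
    t1: np.ndarray | float,
    t2: np.ndarray | float,
    fdr: np.ndarray | float,
    floor: float = FDR_FLOOR,
) -> np.ndarray | float:
    """Signed log FDR score: -log10(FDR) when both t's are positive,
    +log10(FDR) when both negative, 0 when the signs contradict.  FDRs of
    zero are floored at 1e-5, capping |S| at 5."""
    t1a, t2a, fa = np.asarray(t1, dtype=float), np.asarray(t2, dtype=float), np.asarray(fdr, dtype=float)
    if ((fa < 0) | (fa > 1)).any():
        raise ValueError("fdr must lie in [0, 1]")
    logf = np.log10(np.maximum(fa, floor))
    score = np.where(
        (t1a > 0) & (t2a > 0), -logf, np.where((t1a < 0) & (t2a < 0), logf, 0.0)
    )
    if np.isscalar(t1) and np.isscalar(t2) and np.isscalar(fdr):
        return float(score)
    return score


def cross_disease_fdr(
    scores_1: pd.Series,
    scores_2: pd.Series,
    n_perm: int = 1_000_000,
    seed: int = 0,
    tail: str = "two-sided",
    chunk: int = 200,
) -> ConcordanceResult:
    """Permutation FDR on the product of two diseases' combined scores.

    The observed product per gene is compared to a pooled null built by
    randomly re-pairing the score vectors: per permutation the second
    vector is shuffled across genes, all products recomputed and pooled
    over permutations and genes.  FDR_g is the pooled proportion at least
    as extreme as the observed product.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    shared = scores_1.index.intersection(scores_2.index)
    if len(shared) < 2:
        raise ValueError("score vectors share fewer than 2 genes")
    a = scores_1.loc[shared].to_numpy(dtype=float)
    b = scores_2.loc[shared].to_numpy(dtype=float)
    obs = a * b

    rng = np.random.default_rng(seed)
    G = len(shared)
    counts = np.zeros(G, dtype=np.int64)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        null = np.empty(m * G)
        for i in range(m):
            null[i * G:(i + 1) * G] = a * rng.permutation(b)
        counts += _extreme_counts(null, obs, tail)
        done += m
    fdr = counts / (n_perm * G)

    table = pd.DataFrame(
        {"score_1": a, "score_2": b, "product": obs, "fdr": fdr},
        index=pd.Index(shared, name="gene"),
    )
    return ConcordanceResult(table=table, n_perm=n_perm)
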