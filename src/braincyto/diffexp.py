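"""Per-gene linear models with composition covariates and moderated statistics.

Each gene's normalized expression is fitted by ordinary least squares on a
design that includes the centered disease status, the centered neuronal
proportion, technical and demographic covariates, and (for AD-like data)
the disease x neuronal-proportion interaction.  Gene-wise residual
variances are then shrunk toward a pooled prior by empirical Bayes
(moment-matching on log residual variances with trigamma inversion),
yielding moderated t-statistics, p-values on d0 + d_g degrees of freedom,
and a B statistic (log-odds of differential expression).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests


@dataclass
class ModelSpec:
    """Ordered model terms (column names of the encoded covariate table).

    The interaction term may only appear when both its parents (centered
    disease and centered neuronal proportion) do.
    """

    terms: list[str] = field(
        default_factory=lambda: [
            "disease_c", "rin_group", "neuronal_c", "age", "sex", "interaction"
        ]
    )
    fdr_threshold: float = 0.05

    def __post_init__(self) -> None:
        if "interaction" in self.terms and not (
            "disease_c" in self.terms and "neuronal_c" in self.terms
        ):
            raise ValueError("interaction requires both disease_c and neuronal_c")


AD_RNASEQ_SPEC = ModelSpec(
    ["disease_c", "rin_group", "neuronal_c", "age", "sex", "interaction"]
)
PD_RNASEQ_SPEC = ModelSpec(["disease_c", "rin_group", "neuronal_c", "age", "batch"])
PD_MICROARRAY_SPEC = ModelSpec(
    ["disease_c", "neuronal_c", "age", "degradation_group"], fdr_threshold=0.11
)


@dataclass
class LinearFit:
    """Gene-wise OLS results for one cohort."""

    coef: pd.DataFrame  # genes x terms (incl. intercept)
    stderr: pd.DataFrame  # genes x terms, ordinary standard errors
    sigma2: np.ndarray  # residual variance per gene
    df_residual: int
    unscaled_se: pd.Series  # per-term sqrt of diag((X'X)^-1)
    genes: pd.Index

    def t_ordinary(self) -> pd.DataFrame:
        return self.coef / self.stderr


@dataclass
class EffectResult:
    """Moderated per-gene, per-coefficient differential-expression statistics."""

    table: pd.DataFrame  # MultiIndex (gene, coef): estimate, t, moderated_t, ...
    d0: float
    s0_sq: float
    df_residual: int

    def for_coef(self, coef: str) -> pd.DataFrame:
        out = self.table.xs(coef, level="coef")
        return out


def fit_models(
    normalized: pd.DataFrame | np.ndarray,
    covariates: pd.DataFrame,
    spec: ModelSpec,
) -> LinearFit:
    """Ordinary least squares per gene: expression ~ intercept + spec.terms.

    ``normalized`` is genes x samples; ``covariates`` is the design-ready
    table from covariate encoding (samples x terms).  Raises on a
    rank-deficient design, naming the collinear terms.
    """
    Y = (
        normalized.to_numpy()
        if isinstance(normalized, pd.DataFrame)
        else np.asarray(normalized, dtype=float)
    )
    genes = (
        normalized.index
        if isinstance(normalized, pd.DataFrame)
        else pd.RangeIndex(Y.shape[0])
    )
    missing = [t for t in spec.terms if t not in covariates.columns]
    if missing:
        raise ValueError(f"covariate table lacks required terms: {missing}")
    X = np.column_stack(
        [np.ones(len(covariates))]
        + [covariates[t].to_numpy(dtype=float) for t in spec.terms]
    )
    names = ["intercept"] + list(spec.terms)
    if Y.shape[1] != X.shape[0]:
        raise ValueError("expression columns do not match covariate rows")

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns via near-zero R residuals in a QR pass
        _, R = np.linalg.qr(X)
        bad = [names[j] for j in range(X.shape[1]) if abs(R[j, j]) < 1e-10]
        raise ValueError(f"design matrix is rank deficient (collinear terms: {bad})")

    XtX_inv = np.linalg.inv(X.T @ X)
    beta = Y @ X @ XtX_inv  # genes x terms
    resid = Y - beta @ X.T
    df = X.shape[0] - X.shape[1]
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    sigma2 = (resid**2).sum(axis=1) / df
    u = np.sqrt(np.diag(XtX_inv))
    stderr = np.sqrt(sigma2)[:, None] * u[None, :]

    return LinearFit(
        coef=pd.DataFrame(beta, index=genes, columns=names),
        stderr=pd.DataFrame(stderr, index=genes, columns=names),
        sigma2=sigma2,
        df_residual=df,
        unscaled_se=pd.Series(u, index=names),
        genes=pd.Index(genes),
    )


def _trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def estimate_prior(sigma2: np.ndarray, df: int) -> tuple[float, float]:
    """Empirical-Bayes prior (d0, s0^2) for residual variances.

    Moment-matching on log residual variances: the excess variance of
    log(s_g^2) over trigamma(df/2) determines the prior df via trigamma
    inversion; the mean determines the prior variance.  Non-positive excess
    variance gives d0 = inf (full shrinkage).
    """
    s2 = np.asarray(sigma2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("need at least two positive residual variances")
    z = np.log(s2[ok])
    e = z - special.polygamma(0, df / 2.0) + np.log(df / 2.0)
    evar = np.var(e, ddof=1) - float(special.polygamma(1, df / 2.0))
    emean = float(np.mean(e))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = np.exp(
            emean + special.polygamma(0, d0 / 2.0) - np.log(d0 / 2.0)
        )
    else:
        d0 = np.inf
        s0_sq = np.exp(emean)
    return float(d0), float(s0_sq)


def posterior_variances(
    sigma2: np.ndarray, df: int, d0: float, s0_sq: float
) -> np.ndarray:
    """Convex combination of gene and prior variances:
    (d0*s0^2 + df*s^2) / (d0 + df); d0 = inf shrinks fully to s0^2."""
    if np.isinf(d0):
        return np.full_like(np.asarray(sigma2, dtype=float), s0_sq)
    return (d0 * s0_sq + df * np.asarray(sigma2, dtype=float)) / (d0 + df)


def moderate(
    fit: LinearFit,
    prior_proportion: float = 0.01,
    d0: float | None = None,
    s0_sq: float | None = None,
) -> EffectResult:
    """Empirical-Bayes moderation of all coefficients of a gene-wise fit.

    Residual variance is shrunk once per gene and applied to every
    coefficient.  The B statistic uses a coefficient prior variance
    estimated from the top decile of |moderated t| and a prior proportion
    of differentially expressed genes ``prior_proportion``.  ``d0`` and
    ``s0_sq`` may be forced for testing the no-shrinkage (d0 -> 0) and
    full-shrinkage (d0 = inf) limits.
    """
    if len(fit.sigma2) < 10 and d0 is None:
        raise ValueError("need at least 10 genes to estimate the variance prior")
    if d0 is None or s0_sq is None:
        est_d0, est_s0 = estimate_prior(fit.sigma2, fit.df_residual)
        d0 = est_d0 if d0 is None else d0
        s0_sq = est_s0 if s0_sq is None else s0_sq

    s2_post = posterior_variances(fit.sigma2, fit.df_residual, d0, s0_sq)
    df_total = fit.df_residual + d0
    df_eff = min(df_total, 1e9)  # d0 = inf: normal-limit t distribution

    frames = []
    terms = [c for c in fit.coef.columns if c != "intercept"]
    for term in terms:
        est = fit.coef[term].to_numpy()
        u = float(fit.unscaled_se[term])
        se_ord = fit.stderr[term].to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            t_ord = est / se_ord
        se_mod = np.sqrt(s2_post) * u
        t_mod = est / se_mod
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_eff)
        fdr = bh_fdr(p)
        frames.append(
            pd.DataFrame(
                {
                    "gene": fit.genes,
                    "coef": term,
                    "estimate": est,
                    "se": se_ord,
                    "t": t_ord,
                    "s2": fit.sigma2,
                    "s2_post": s2_post,
                    "moderated_t": t_mod,
                    "p": p,
                    "fdr": fdr,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)

    # B statistic: log-odds of differential expression
    logodds = []
    for term in terms:
        sub = table[table["coef"] == term]
        t_mod = sub["moderated_t"].to_numpy()
        u = float(fit.unscaled_se[term])
        v0 = _coef_prior_variance(t_mod, u)
        r = (u**2 + v0) / u**2
        t2 = t_mod**2
        if np.isinf(df_total):
            kernel = -0.5 * t2 * (1.0 - 1.0 / r)
        else:
            kernel = ((1.0 + df_total) / 2.0) * np.log(
                (t2 + df_total) / (t2 / r + df_total)
            )
        B = (
            np.log(prior_proportion / (1.0 - prior_proportion))
            - 0.5 * np.log(r)
            + kernel
        )
        logodds.append(pd.Series(B, index=sub.index))
    table["B"] = pd.concat(logodds)
    table = table.set_index(["gene", "coef"])
    return EffectResult(table=table, d0=d0, s0_sq=s0_sq, df_residual=fit.df_residual)


def _coef_prior_variance(t_mod: np.ndarray, u: float) -> float:
    """Coefficient prior variance from the top decile of |moderated t|:
    median excess of t^2 over 1, scaled back to the coefficient scale."""
    k = max(int(np.ceil(0.1 * len(t_mod))), 1)
    top = np.sort(np.abs(t_mod))[-k:]
    excess = np.median(np.maximum(top**2 - 1.0, 0.0))
    return float(max(excess, 1e-6) * u**2)


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment with monotonicity enforcement."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(
    result: EffectResult, threshold: float = 0.05
) -> dict[str, pd.DataFrame]:
    """Significant gene sets per coefficient at FDR strictly below
    ``threshold`` (0.05 default; 0.11 for the low-power microarray profile),
    with direction taken from the sign of the estimate."""
    out = {}
    for term in result.table.index.get_level_values("coef").unique():
        sub = result.for_coef(term)
        sig = sub[sub["fdr"] < threshold].copy()
        sig["direction"] = np.where(sig["estimate"] > 0, "up", "down")
        out[term] = sig.sort_values("fdr")
    return out
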