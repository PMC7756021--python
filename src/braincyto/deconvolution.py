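"""Cell-type fraction estimation from bulk transcriptomes.

Per sample, the bulk mixture is regressed on the signature-matrix columns
with non-negative least squares (default) or linear nu-support-vector
regression, and coefficients are normalized to sum to one.  The resulting
fractions represent each cell type's share of the total mRNA, not of the
cell count -- neurons carry roughly twice the mRNA of glia, so neuronal
mRNA shares exceed neuronal cell shares.  Per-sample significance comes
from permuting the sample's gene values and re-deconvolving; samples whose
neuronal share falls below 0.40 are flagged for exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.svm import NuSVR

from braincyto.single_cell import SignatureMatrix

MIN_SHARED_GENES = 50


@dataclass
class CompositionEstimate:
    """Per-sample cell-type fractions with goodness-of-fit diagnostics."""

    fractions: pd.DataFrame  # samples x cell-types, rows on the simplex
    fit_correlation: pd.Series  # Pearson r(observed, signature @ coefficients)
    p_values: pd.Series | None = None
    method: str = "nnls"

    def __post_init__(self) -> None:
        fr = self.fractions.to_numpy()
        if (fr < -1e-12).any():
            raise ValueError("fractions must be non-negative")
        if np.abs(fr.sum(axis=1) - 1.0).max() > 1e-8:
            raise ValueError("fraction rows must sum to 1")

    @property
    def neuronal(self) -> pd.Series:
        return self.fractions["neuron"]


def _solve_nnls(S: np.ndarray, y: np.ndarray) -> np.ndarray:
    coef, _ = optimize.nnls(S, y)
    return coef


def _solve_nusvr(S: np.ndarray, y: np.ndarray, nus=(0.25, 0.5, 0.75)) -> np.ndarray:
    """CIBERSORT-style backend: linear nu-SVR on z-scored data, nu chosen by
    reconstruction correlation, negative coefficients clipped to zero."""
    Sz = (S - S.mean(axis=0)) / np.where(S.std(axis=0) > 0, S.std(axis=0), 1.0)
    sd = y.std()
    yz = (y - y.mean()) / (sd if sd > 0 else 1.0)
    best_coef, best_r = None, -np.inf
    for nu in nus:
        model = NuSVR(kernel="linear", nu=nu, C=1.0)
        model.fit(Sz, yz)
        w = np.clip(model.coef_.ravel(), 0.0, None)
        recon = Sz @ w
        r = np.corrcoef(recon, yz)[0, 1] if recon.std() > 0 else -np.inf
        if r > best_r:
            best_r, best_coef = r, w
    return best_coef


def estimate_composition(
    bulk: pd.DataFrame,
    signature: SignatureMatrix,
    method: str = "nnls",
) -> CompositionEstimate:
    """Estimate mRNA-share fractions of every bulk sample.

    ``bulk`` is a genes x samples matrix (CPM or comparable linear scale);
    only genes shared with the signature are used and at least 50 must be
    shared.  Fractions are scale-free: multiplying a sample by a positive
    scalar leaves them unchanged.
    """
    if method not in ("nnls", "nusvr"):
        raise ValueError(f"unknown method {method!r}")
    shared = bulk.index.intersection(signature.data.index)
    if len(shared) < MIN_SHARED_GENES:
        raise ValueError(
            f"only {len(shared)} genes shared between bulk and signature "
            f"(need >= {MIN_SHARED_GENES})"
        )
    S = signature.data.loc[shared].to_numpy(dtype=float)
    B = bulk.loc[shared].to_numpy(dtype=float)
    if (B.sum(axis=0) <= 0).any():
        raise ValueError("bulk contains an all-zero sample")

    # genes enter the least-squares fit on a per-gene-scaled basis: count
    # noise is roughly multiplicative, so dividing each gene's row (and the
    # mixture) by the signature row mean makes errors comparable across
    # genes instead of letting the most-expressed genes dominate
    row_scale = S.mean(axis=1)
    row_scale[row_scale <= 0] = 1.0
    Ss = S / row_scale[:, None]

    n_types = S.shape[1]
    fracs = np.zeros((B.shape[1], n_types))
    fit_r = np.zeros(B.shape[1])
    for j in range(B.shape[1]):
        y = B[:, j]
        coef = (
            _solve_nnls(Ss, y / row_scale)
            if method == "nnls"
            else _solve_nusvr(S, y)
        )
        total = coef.sum()
        fracs[j] = coef / total if total > 0 else np.full(n_types, 1.0 / n_types)
        recon = S @ coef
        fit_r[j] = (
            np.corrcoef(y, recon)[0, 1] if recon.std() > 0 and y.std() > 0 else 0.0
        )
    fractions = pd.DataFrame(
        fracs, index=bulk.columns, columns=signature.cell_types
    )
    return CompositionEstimate(
        fractions=fractions,
        fit_correlation=pd.Series(fit_r, index=bulk.columns),
        method=method,
    )


def composition_significance(
    sample: pd.Series,
    signature: SignatureMatrix,
    n_perm: int = 100,
    method: str = "nnls",
    seed: int = 0,
) -> float:
    """Permutation p-value for one sample's deconvolution fit.

    The null randomly permutes the sample's gene values and re-deconvolves;
    p = (1 + #{null fit correlation >= observed}) / (1 + n_perm), so p is
    never exactly zero.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    frame = sample.to_frame(name="obs")
    obs = estimate_composition(frame, signature, method=method).fit_correlation.iloc[0]
    rng = np.random.default_rng(seed)
    shared = frame.index.intersection(signature.data.index)
    values = frame.loc[shared, "obs"].to_numpy()
    S = signature.data.loc[shared]
    count = 0
    for _ in range(n_perm):
        perm = pd.DataFrame(
            {"perm": rng.permutation(values)}, index=shared
        )
        r = estimate_composition(perm, SignatureMatrix(data=S), method=method)
        if r.fit_correlation.iloc[0] >= obs:
            count += 1
    return (1 + count) / (1 + n_perm)


def filter_low_neuron_samples(
    est: CompositionEstimate,
    metadata: pd.DataFrame | None = None,
    threshold: float = 0.40,
    keep: bool = False,
) -> tuple[pd.Index, pd.DataFrame]:
    """Flag samples whose neuronal mRNA share is strictly below ``threshold``.

    Default policy removes them; ``keep=True`` retains flagged samples
    (the small-cohort exception) while still logging them.
    """
    if "neuron" not in est.fractions.columns:
        raise ValueError("no neuron column in the composition estimate")
    neuronal = est.fractions["neuron"]
    flagged = neuronal < threshold
    log = pd.DataFrame(
        {
            "neuronal_fraction": neuronal[flagged],
            "action": "kept_by_override" if keep else "removed",
        }
    )
    kept = est.fractions.index if keep else est.fractions.index[~flagged]
    return kept, log


def benchmark_mixtures(
    true: pd.DataFrame, estimated: pd.DataFrame
) -> pd.DataFrame:
    """Per-type concordance between known and estimated fractions:
    Pearson r with p-value, RMSE and bias (mean estimated - true)."""
    if true.shape != estimated.shape:
        raise ValueError("true and estimated fraction matrices differ in shape")
    estimated = estimated[true.columns]
    rows = {}
    for t in true.columns:
        a = true[t].to_numpy(dtype=float)
        b = estimated[t].to_numpy(dtype=float)
        if np.std(a) > 0 and np.std(b) > 0:
            r, p = stats.pearsonr(a, b)
        else:
            r, p = np.nan, np.nan
        rows[t] = {
            "pearson_r": r,
            "p": p,
            "rmse": float(np.sqrt(np.mean((b - a) ** 2))),
            "bias": float(np.mean(b - a)),
        }
    out = pd.DataFrame(rows).T
    out.loc["overall"] = {
        "pearson_r": stats.pearsonr(
            true.to_numpy().ravel(), estimated.to_numpy().ravel()
        )[0],
        "p": np.nan,
        "rmse": float(
            np.sqrt(np.mean((estimated.to_numpy() - true.to_numpy()) ** 2))
        ),
        "bias": float(np.mean(estimated.to_numpy() - true.to_numpy())),
    }
    return out
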