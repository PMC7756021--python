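"""Signature-reversal compound screening.

Each compound-perturbation condition (compound x cell line x dose) is
scored by the Spearman correlation of its z-score profile with the
disease-effect scores across shared genes.  Correlations are averaged
dose-to-cell-line, then cell-line-to-compound.  Candidates are restricted
to launched or clinical-stage compounds, compounds whose perturbation
profiles track the neuronal-proportion scores (average absolute Spearman
correlation >= 0.05) are excluded as composition confounders, and the k
most negative and k most positive compound averages become reversal and
induction candidates respectively.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from braincyto.simulate import PerturbagenPanel

MIN_SHARED_GENES = 30
SELECTABLE_STATUSES = ("clinical", "launched")


def _spearman_vs_matrix(scores: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Spearman rho of one score vector against each column of Z
    (average ranks for ties)."""
    rs = stats.rankdata(scores)
    rz = stats.rankdata(Z, axis=0)
    rs = rs - rs.mean()
    rz = rz - rz.mean(axis=0)
    denom = np.sqrt((rs**2).sum()) * np.sqrt((rz**2).sum(axis=0))
    denom = np.where(denom > 0, denom, np.nan)
    return (rs @ rz) / denom


def compound_correlations(
    panel: PerturbagenPanel,
    disease_scores: pd.Series,
    neuronal_scores: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-condition and per-compound Spearman correlation tables.

    Per condition, rho with the disease scores over shared genes (at least
    30 required).  Compound aggregation averages conditions to cell lines
    (over doses/times) and cell lines to compounds.  Neuronal-proportion
    correlations take absolute values per condition before the same
    averaging, the stricter reading of the confound filter.
    """
    shared = panel.zscores.index.intersection(disease_scores.index)
    if len(shared) < MIN_SHARED_GENES:
        raise ValueError(
            f"only {len(shared)} genes shared between panel and scores "
            f"(need >= {MIN_SHARED_GENES})"
        )
    Z = panel.zscores.loc[shared].to_numpy(dtype=float)
    rho = _spearman_vs_matrix(disease_scores.loc[shared].to_numpy(dtype=float), Z)

    per_condition = panel.conditions.copy()
    per_condition["rho_disease"] = rho
    if neuronal_scores is not None:
        n_shared = shared.intersection(neuronal_scores.index)
        if len(n_shared) < MIN_SHARED_GENES:
            raise ValueError("too few genes shared with the neuronal scores")
        rho_n = _spearman_vs_matrix(
            neuronal_scores.loc[n_shared].to_numpy(dtype=float),
            panel.zscores.loc[n_shared].to_numpy(dtype=float),
        )
        per_condition["abs_rho_neuronal"] = np.abs(rho_n)
    else:
        per_condition["abs_rho_neuronal"] = np.nan

    by_line = per_condition.groupby(["compound", "cell_line"]).agg(
        rho_disease=("rho_disease", "mean"),
        abs_rho_neuronal=("abs_rho_neuronal", "mean"),
    )
    per_compound = by_line.groupby("compound").agg(
        avg_rho=("rho_disease", "mean"),
        avg_abs_rho_neuronal=("abs_rho_neuronal", "mean"),
    )
    status = per_condition.groupby("compound")["clinical_status"].first()
    per_compound["clinical_status"] = status
    per_compound["n_conditions"] = per_condition.groupby("compound").size()
    return per_condition, per_compound.sort_index()


def select_candidates(
    per_compound: pd.DataFrame,
    k: int = 20,
    confound_cut: float = 0.05,
    statuses: tuple[str, ...] = SELECTABLE_STATUSES,
) -> pd.DataFrame:
    """Assign a verdict to every compound.

    Launched/clinical compounds with average absolute neuronal correlation
    strictly below ``confound_cut`` are eligible; the k most negative
    disease correlations become ``reversal_candidate``, the k most positive
    ``induction_candidate``.  Compounds at or above the confound cut are
    ``excluded_confounded`` regardless of their disease correlation; the
    rest are ``not_selected``.  Ties break by compound id, so the output is
    deterministic.
    """
    out = per_compound.copy().sort_index()
    out["verdict"] = "not_selected"
    confounded = out["avg_abs_rho_neuronal"] >= confound_cut
    out.loc[confounded, "verdict"] = "excluded_confounded"

    eligible = (
        out[~confounded & out["clinical_status"].isin(statuses)]
        .reset_index()
        .sort_values(["avg_rho", "compound"])  # ties break by compound id
    )
    reversal = eligible.head(k)["compound"].tolist()
    remaining = eligible[~eligible["compound"].isin(reversal)]
    induction = (
        remaining.sort_values(["avg_rho", "compound"], ascending=[False, True])
        .head(k)["compound"]
        .tolist()
    )
    out.loc[out.index.isin(reversal), "verdict"] = "reversal_candidate"
    out.loc[out.index.isin(induction), "verdict"] = "induction_candidate"
    return out


def cross_disease_drug_map(
    table_1: pd.DataFrame,
    table_2: pd.DataFrame,
    panel: PerturbagenPanel,
    common_scores: pd.Series,
) -> pd.DataFrame:
    """Joint compound table across two diseases.

    Compounds present in both per-compound tables get their two disease
    correlations plus the correlation with the common (cross-disease)
    score vector; ranking by the latter identifies joint reversers and
    mimickers.  Compounds missing from either table are excluded and
    logged in the ``n_dropped`` attribute.
    """
    shared = table_1.index.intersection(table_2.index)
    _, common_table = compound_correlations(panel, common_scores)
    joint = pd.DataFrame(
        {
            "rho_1": table_1.loc[shared, "avg_rho"],
            "rho_2": table_2.loc[shared, "avg_rho"],
            "rho_common": common_table.loc[shared, "avg_rho"],
            "clinical_status": table_1.loc[shared, "clinical_status"],
        }
    ).sort_values(["rho_common", "rho_1"])
    joint.attrs["n_dropped"] = int(
        len(table_1.index.union(table_2.index)) - len(shared)
    )
    return joint
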