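"""Synthetic single-cell references, bulk cohorts, mixtures and perturbagen panels.

All generators are pure functions of (config, seed): identical seeds give
identical outputs.  Planted truth tables are attached to every dataset so
that each downstream stage can be scored by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from braincyto.config import (
    CohortDesign,
    ConfigurationError,
    PerturbagenSpec,
    SimulationConfig,
)

# ---------------------------------------------------------------------------
# containers


@dataclass
class SingleCellDataset:
    """Genes x cells count matrix with cell-type annotation and ground truth."""

    counts: np.ndarray  # genes x cells, non-negative ints
    cell_type: np.ndarray  # label per cell (as annotated)
    mito_flag: np.ndarray  # boolean per gene
    true_means: np.ndarray  # genes x cell-types generating rates
    gene_names: np.ndarray
    cell_types: tuple[str, ...]
    true_type: np.ndarray | None = None  # generating type (mislabel truth)
    degenerate: np.ndarray | None = None  # planted low-quality cells

    def __post_init__(self) -> None:
        n_genes, n_cells = self.counts.shape
        if len(self.cell_type) != n_cells:
            raise ValueError("cell annotation length does not match counts")
        if len(self.mito_flag) != n_genes or len(self.gene_names) != n_genes:
            raise ValueError("gene annotation length does not match counts")
        for t in self.cell_types:
            if not (self.cell_type == t).any():
                raise ValueError(f"declared cell type {t!r} has no cells")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def subset(self, genes=None, cells=None) -> "SingleCellDataset":
        g = np.arange(self.n_genes) if genes is None else np.asarray(genes)
        c = np.arange(self.n_cells) if cells is None else np.asarray(cells)
        return SingleCellDataset(
            counts=self.counts[np.ix_(g, c)],
            cell_type=self.cell_type[c],
            mito_flag=self.mito_flag[g],
            true_means=self.true_means[g],
            gene_names=self.gene_names[g],
            cell_types=self.cell_types,
            true_type=None if self.true_type is None else self.true_type[c],
            degenerate=None if self.degenerate is None else self.degenerate[c],
        )


@dataclass
class BulkCohort:
    """Genes x samples expression with metadata and planted ground truth.

    ``values`` are raw counts for RNA-seq cohorts and normalized log2
    intensities for microarray-like cohorts.  ``true_fractions`` rows live on
    the simplex; ``truth`` records every planted per-gene coefficient.
    """

    values: np.ndarray  # genes x samples
    metadata: pd.DataFrame  # one row per sample
    true_fractions: pd.DataFrame  # samples x cell-types
    truth: pd.DataFrame | None
    gene_names: np.ndarray
    platform: str = "rnaseq"
    name: str = "cohort"
    expected: np.ndarray | None = None  # noiseless expected CPM (genes x samples)

    def __post_init__(self) -> None:
        if self.metadata.shape[0] != self.values.shape[1]:
            raise ValueError("metadata rows do not align with sample columns")
        fr = self.true_fractions.to_numpy()
        if fr.shape[0] != self.values.shape[1]:
            raise ValueError("true_fractions rows do not align with samples")
        if (fr < -1e-12).any() or np.abs(fr.sum(axis=1) - 1.0).max() > 1e-12:
            raise ValueError("true_fractions rows must lie on the simplex")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_names, columns=self.metadata.index
        )


@dataclass
class PerturbagenPanel:
    """Compound perturbation z-scores with condition metadata and planted roles."""

    zscores: pd.DataFrame  # genes x conditions
    conditions: pd.DataFrame  # one row per condition (compound, cell_line, ...)
    planted_roles: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.conditions.index.equals(self.zscores.columns):
            raise ValueError("condition metadata must map 1:1 to z-score columns")


# ---------------------------------------------------------------------------
# helpers


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draw parameterized by mean and dispersion alpha
    (var = mu + alpha mu^2); alpha = 0 degenerates to Poisson."""
    mean = np.clip(mean, 0.0, None)
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, dispersion * mean)
    return rng.poisson(lam)


# ---------------------------------------------------------------------------
# operations


def simulate_reference(config: SimulationConfig, library_sigma: float = 0.3) -> SingleCellDataset:
    """Simulate a single-cell reference of the configured cell types.

    Per cell, counts are negative-binomial with mean proportional to
    ``base_rate[gene, type] * library_scale * mrna_content[type]``.  A
    configurable fraction of deliberately degenerate cells (tiny library,
    high mitochondrial fraction) and a configurable number of mislabeled
    cells are planted for QC testing.
    """
    rng = config.rng("single_cell")
    types = config.cell_types
    n_types = len(types)
    rates = config.base_rates()
    content = config.content_vector()
    n_cells = config.n_cells_per_type * n_types

    mito = np.zeros(config.n_genes, dtype=bool)
    n_mito = int(round(config.frac_mito_genes * config.n_genes))
    if n_mito:
        # mitochondrial genes are housekeeping: draw them from genes without
        # cell-type-marker structure so mito fraction is type-independent
        candidates = np.flatnonzero(config.marker_types() == "none")
        if len(candidates) < n_mito:
            candidates = np.arange(config.n_genes)
        mito[rng.choice(candidates, size=n_mito, replace=False)] = True

    labels = np.repeat(types, config.n_cells_per_type)
    true_type = labels.copy()
    if config.n_mislabeled_cells:
        if config.n_mislabeled_cells > n_cells:
            raise ConfigurationError("more mislabeled cells than cells")
        picked = rng.choice(n_cells, size=config.n_mislabeled_cells, replace=False)
        for c in picked:
            j = list(types).index(labels[c])
            true_type[c] = types[(j + 1) % n_types]

    degenerate = np.zeros(n_cells, dtype=bool)
    n_degen = int(round(config.frac_degenerate_cells * n_cells))
    if n_degen:
        degenerate[rng.choice(n_cells, size=n_degen, replace=False)] = True

    type_index = {t: j for j, t in enumerate(types)}
    lib_scale = np.exp(rng.normal(0.0, library_sigma, size=n_cells))
    counts = np.empty((config.n_genes, n_cells), dtype=np.int64)
    for c in range(n_cells):
        j = type_index[true_type[c]]
        mu = rates[:, j].astype(float).copy()
        if degenerate[c]:
            mu[mito] *= 25.0  # dying cell: mitochondrial reads dominate
        mu *= (
            config.sc_mean_library * content[j] * lib_scale[c] / mu.sum()
        )
        if degenerate[c]:
            mu *= 0.05  # tiny library
        counts[:, c] = _nb_sample(rng, mu, config.sc_dispersion)

    return SingleCellDataset(
        counts=counts,
        cell_type=labels,
        mito_flag=mito,
        true_means=rates,
        gene_names=config.gene_names(),
        cell_types=types,
        true_type=true_type,
        degenerate=degenerate,
    )


def _draw_fractions(
    rng: np.random.Generator, design: CohortDesign, config: SimulationConfig,
    diseased: bool, n: int,
) -> np.ndarray:
    mean = design.mean_fractions(config.cell_types, diseased)
    return rng.dirichlet(design.concentration * mean, size=n)


def simulate_bulk_cohort(
    config: SimulationConfig,
    reference: SingleCellDataset,
    disease_kind: str,
) -> BulkCohort:
    """Simulate one bulk cohort with known composition and planted effects.

    ``disease_kind`` names a cohort design from ``config.cohorts`` (or the
    shorthand ``"ad"``/``"pd"`` for the discovery designs).  Per sample the
    expected expression is the content-weighted mixture of the reference
    type means, multiplied by 2**(planted log2 effects); AD-like cohorts
    draw diseased neuronal fractions from a shifted distribution while
    PD-like cohorts use identical distributions in both arms.
    """
    alias = {"ad": "ad_discovery", "pd": "pd_discovery"}
    key = alias.get(disease_kind, disease_kind)
    if key not in config.cohorts:
        raise ConfigurationError(f"unknown disease_kind {disease_kind!r}")
    design = config.cohorts[key]
    rng = config.rng(f"bulk:{key}")

    types = config.cell_types
    content = config.content_vector()
    rates = reference.true_means
    n = design.n_control + design.n_disease
    disease = np.r_[np.zeros(design.n_control), np.ones(design.n_disease)]

    fr = np.empty((n, len(types)))
    fr[disease == 0] = _draw_fractions(rng, design, config, False, design.n_control)
    fr[disease == 1] = _draw_fractions(rng, design, config, True, design.n_disease)

    age = rng.normal(76.0 + 2.0 * disease, 8.0)
    sex = rng.integers(0, 2, size=n).astype(float) if design.has_sex else np.ones(n)
    rin = rng.uniform(7.0, 10.0, size=n)
    batch = rng.integers(0, 2, size=n).astype(float) if design.has_batch else np.zeros(n)
    degradation = rng.normal(4.8, 1.2, size=n)

    classes = config.gene_classes()
    signs = config.effect_signs()
    ec = config.effect_classes
    cv = config.covariate_effects

    # planted log2 effect per gene x sample
    eff = np.zeros((config.n_genes, n))
    sys_mask = classes == "systemic"
    eff[sys_mask] += np.outer(signs[sys_mask] * ec.systemic_lfc, disease)

    neuron_j = list(types).index("neuron")
    fn = fr[:, neuron_j]
    inter = (disease - disease.mean()) * (fn - fn.mean())
    int_mask = classes == "interaction"
    eff[int_mask] += np.outer(signs[int_mask] * ec.interaction_lfc, inter)

    cov_mask = classes == "covariate_only"
    rin_hi = (rin > design.rin_cut).astype(float)
    deg_hi = (degradation > 5.0).astype(float)
    cov_signal = cv.age * (age - age.mean())
    if design.platform == "microarray":
        cov_signal = cov_signal + cv.degradation * deg_hi
    else:
        cov_signal = cov_signal + cv.rin * rin_hi
    if design.has_sex:
        cov_signal = cov_signal + cv.sex * sex
    if design.has_batch:
        cov_signal = cov_signal + cv.batch * batch
    eff[cov_mask] += np.outer(signs[cov_mask], cov_signal)

    mixture = rates @ (fr * content).T  # genes x samples expected expression
    expected = mixture * 2.0 ** eff
    expected_cpm = expected / expected.sum(axis=0, keepdims=True) * 1e6

    sample_ids = np.array([f"{key}_S{i:03d}" for i in range(n)])
    if design.platform == "microarray":
        values = np.log2(expected_cpm + 1.0) + rng.normal(
            0.0, design.microarray_noise_sd, size=expected_cpm.shape
        )
    else:
        depth = np.exp(rng.normal(np.log(design.mean_depth), design.depth_sigma, size=n))
        mean_counts = expected_cpm / 1e6 * depth
        values = _nb_sample(rng, mean_counts, config.dispersion).astype(float)

    metadata = pd.DataFrame(
        {
            "disease": disease.astype(int),
            "age": age,
            "sex": sex if design.has_sex else np.nan,
            "rin": rin,
            "batch": batch.astype(int),
            "degradation_slope": degradation,
        },
        index=pd.Index(sample_ids, name="sample"),
    )
    truth = pd.DataFrame(
        {
            "effect_class": classes,
            "sign": signs,
            "disease_lfc": np.where(sys_mask, signs * ec.systemic_lfc, 0.0),
            "interaction_lfc": np.where(int_mask, signs * ec.interaction_lfc, 0.0),
            "covariate_lfc": np.where(cov_mask, signs, 0.0),
        },
        index=pd.Index(config.gene_names(), name="gene"),
    )
    fractions = pd.DataFrame(fr, index=metadata.index, columns=list(types))
    return BulkCohort(
        values=values,
        metadata=metadata,
        true_fractions=fractions,
        truth=truth,
        gene_names=config.gene_names(),
        platform=design.platform,
        name=key,
        expected=expected_cpm,
    )


def simulate_mixtures(
    reference: SingleCellDataset,
    proportions: np.ndarray,
    depth: int,
    mrna_content: dict[str, float] | None = None,
    seed: int = 0,
) -> BulkCohort:
    """Chimeric mixtures by nested multinomial read sampling.

    All reference cells of each type are pooled into a per-type count
    profile; each mixture allocates ``depth`` total counts to types
    according to its proportion row and, within a type, distributes counts
    across genes by the pooled profile -- a count-level emulation of
    sampling reads from cell-type-specific pools.

    ``proportions`` rows are interpreted as cell-level fractions.  When
    ``mrna_content`` is given, read shares are proportional to
    ``fraction * content``, so low-content types contribute fewer reads
    than their cell share (the mechanism behind mRNA-share deconvolution
    biases); by default read shares equal the proportions.
    """
    P = np.asarray(proportions, dtype=float)
    if P.ndim == 1:
        P = P[None, :]
    if P.shape[1] != len(reference.cell_types):
        raise ValueError("proportion columns must match reference cell types")
    if (P < -1e-12).any() or np.abs(P.sum(axis=1) - 1.0).max() > 1e-8:
        raise ValueError("each proportion row must be non-negative and sum to 1")
    if depth <= 0:
        raise ValueError("depth must be positive")

    rng = np.random.default_rng(seed)
    types = reference.cell_types
    pools = np.stack(
        [reference.counts[:, reference.cell_type == t].sum(axis=1) for t in types],
        axis=1,
    ).astype(float)
    pool_freq = pools / pools.sum(axis=0, keepdims=True)

    if mrna_content is not None:
        w = np.array([mrna_content[t] for t in types])
        shares = P * w
        shares /= shares.sum(axis=1, keepdims=True)
    else:
        shares = P

    n_mix = P.shape[0]
    counts = np.zeros((reference.n_genes, n_mix), dtype=np.int64)
    for i in range(n_mix):
        per_type = rng.multinomial(depth, shares[i])
        for j in range(len(types)):
            if per_type[j]:
                counts[:, i] += rng.multinomial(per_type[j], pool_freq[:, j])

    ids = pd.Index([f"mix{i:04d}" for i in range(n_mix)], name="sample")
    metadata = pd.DataFrame(
        {"disease": np.zeros(n_mix, dtype=int), "age": np.nan, "sex": np.nan,
         "rin": np.nan, "batch": 0, "degradation_slope": np.nan},
        index=ids,
    )
    fractions = pd.DataFrame(P, index=ids, columns=list(types))
    return BulkCohort(
        values=counts.astype(float),
        metadata=metadata,
        true_fractions=fractions,
        truth=None,
        gene_names=reference.gene_names,
        platform="rnaseq",
        name="mixtures",
    )


def dirichlet_proportions(
    n_mixtures: int,
    cell_types: tuple[str, ...],
    alpha: np.ndarray | float = 1.5,
    seed: int = 0,
) -> np.ndarray:
    """Diverse known mixing proportions, Dirichlet with configurable
    concentration (symmetric by default)."""
    rng = np.random.default_rng(seed)
    a = np.broadcast_to(np.asarray(alpha, dtype=float), (len(cell_types),))
    return rng.dirichlet(a, size=n_mixtures)


def simulate_perturbagens(
    config: SimulationConfig,
    disease_scores: pd.Series,
    neuronal_scores: pd.Series | None = None,
) -> PerturbagenPanel:
    """Synthetic compound panel with planted reversers, mimickers and
    neuronal confounders.

    Reverser conditions carry ``z ~ -k*score + noise``; mimickers the
    positive sign; neuronal confounders track the neuronal-proportion score
    vector; neutral compounds are independent noise.  Each compound is
    replicated across the configured cell lines and doses.
    """
    spec: PerturbagenSpec = config.perturbagens
    if len(disease_scores) < 100:
        raise ValueError("disease_scores must cover at least 100 genes")
    if spec.n_confounders and neuronal_scores is None:
        raise ConfigurationError("neuronal_scores required to plant confounders")
    rng = config.rng("perturbagens")

    genes = disease_scores.index
    s = disease_scores.to_numpy(dtype=float)
    s = (s - s.mean()) / (s.std() or 1.0)
    if neuronal_scores is not None:
        nv = neuronal_scores.reindex(genes).to_numpy(dtype=float)
        nv = (nv - np.nanmean(nv)) / (np.nanstd(nv) or 1.0)
        nv = np.nan_to_num(nv)
    else:
        nv = np.zeros_like(s)

    roles = {}
    compounds = [f"CPD{i:04d}" for i in range(spec.n_compounds)]
    for i, cpd in enumerate(compounds):
        if i < spec.n_reversers:
            roles[cpd] = "reverser"
        elif i < spec.n_reversers + spec.n_mimickers:
            roles[cpd] = "mimicker"
        elif i < spec.n_reversers + spec.n_mimickers + spec.n_confounders:
            roles[cpd] = "neuronal_confounder"
        else:
            roles[cpd] = "neutral"

    statuses = {}
    for cpd in compounds:
        if roles[cpd] != "neutral":
            statuses[cpd] = "launched"
        else:
            u = rng.random()
            statuses[cpd] = (
                "preclinical" if u < spec.frac_preclinical
                else ("clinical" if u < 0.6 else "launched")
            )

    cell_lines = [f"CL{j+1}" for j in range(spec.n_cell_lines)]
    doses = [10.0 * (j + 1) for j in range(spec.n_doses)]
    cols, rows, zcols = [], [], []
    k = spec.signal_strength
    for cpd in compounds:
        for line in cell_lines:
            for dose in doses:
                cond = f"{cpd}_{line}_{dose:g}um"
                base = {
                    "reverser": -k * s,
                    "mimicker": k * s,
                    "neuronal_confounder": k * nv,
                    "neutral": np.zeros_like(s),
                }[roles[cpd]]
                z = base + rng.normal(0.0, spec.noise_sd, size=len(s))
                cols.append(cond)
                zcols.append(z)
                rows.append(
                    {
                        "condition": cond,
                        "compound": cpd,
                        "cell_line": line,
                        "dose": dose,
                        "time_h": 24,
                        "plate_type": "CPD",
                        "clinical_status": statuses[cpd],
                    }
                )
    conditions = pd.DataFrame(rows).set_index("condition")
    zscores = pd.DataFrame(
        np.column_stack(zcols), index=genes, columns=conditions.index
    )
    return PerturbagenPanel(zscores=zscores, conditions=conditions, planted_roles=roles)
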