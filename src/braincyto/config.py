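"""Simulation configuration.

The synthetic cohorts emulate the statistical structure of post-mortem brain
transcriptomics studies of Alzheimer's (AD) and Parkinson's (PD) disease:
four major cell types with distinct expression programs and differing
per-cell mRNA content, bulk cohorts whose samples mix those cell types at
known fractions, planted gene classes (systemic disease effects,
composition-driven genes, interaction genes, covariate-only genes, nulls),
and a compound-perturbation panel with planted reversers and mimickers.

Default cohort sizes follow the four published study arms (71 AD / 32
control; 9 AD / 14 control; 15 PD / 26 control; 8 PD / 10 control, the last
being microarray).  The neuron mRNA-content scalar defaults to 2.0 against
1.0 for glia, reflecting neuronal RNA content being up to twice that of
glial cells; deconvolution estimates are therefore mRNA shares, not cell
shares.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

DEFAULT_CELL_TYPES = ("astrocyte", "microglia", "neuron", "oligodendrocyte")

#: Mean cell-type fractions (mRNA share) of a non-diseased cortical sample.
CONTROL_MEAN_FRACTIONS = {
    "astrocyte": 0.14,
    "microglia": 0.04,
    "neuron": 0.70,
    "oligodendrocyte": 0.12,
}

#: AD arms draw neuronal fractions from a shifted mean (0.60 vs 0.70).
AD_MEAN_FRACTIONS = {
    "astrocyte": 0.20,
    "microglia": 0.06,
    "neuron": 0.60,
    "oligodendrocyte": 0.14,
}


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass
class CohortDesign:
    """One bulk cohort arm-pair: sizes, platform and composition model.

    ``disease_kind`` controls the composition model: AD-like cohorts draw
    diseased neuronal fractions from a lower-mean distribution, PD-like
    cohorts use identical fraction distributions in both arms.
    """

    name: str
    disease_kind: str  # "ad" | "pd"
    platform: str = "rnaseq"  # "rnaseq" | "microarray"
    n_control: int = 32
    n_disease: int = 71
    #: Dirichlet concentration of cell-level fractions.  12 puts the
    #: neuronal mRNA share (what deconvolution reports) at SD ~0.11 with a
    #: 0.35-0.9 range, matching the wide spread seen in brain samples,
    #: including occasional samples below the 0.40 neuronal-share filter.
    concentration: float = 12.0
    mean_depth: float = 2e6
    depth_sigma: float = 0.2  # log-normal sigma of library sizes
    rin_cut: float = 8.5
    has_sex: bool = True  # PD cohorts were male-only
    has_batch: bool = False
    microarray_noise_sd: float = 0.30

    def mean_fractions(self, cell_types: Sequence[str], diseased: bool) -> np.ndarray:
        table = (
            AD_MEAN_FRACTIONS
            if (diseased and self.disease_kind == "ad")
            else CONTROL_MEAN_FRACTIONS
        )
        out = np.array([table[t] for t in cell_types], dtype=float)
        return out / out.sum()


def default_cohorts() -> dict[str, CohortDesign]:
    return {
        "ad_discovery": CohortDesign(
            "ad_discovery", "ad", n_control=32, n_disease=71, rin_cut=8.5
        ),
        "ad_validation": CohortDesign(
            "ad_validation", "ad", n_control=14, n_disease=9, rin_cut=7.3
        ),
        "pd_discovery": CohortDesign(
            "pd_discovery", "pd", n_control=26, n_disease=15,
            rin_cut=7.8, has_sex=False, has_batch=True,
        ),
        "pd_validation": CohortDesign(
            "pd_validation", "pd", platform="microarray",
            n_control=10, n_disease=8, has_sex=False,
        ),
    }


@dataclass
class EffectClasses:
    """Planted gene classes and their effect sizes (log2 units).

    Every gene belongs to exactly one class:

    - ``systemic``: multiplied by ``2**(systemic_lfc * disease)`` in every
      cell type (half up, half down) -- the intrinsic disease effect.
    - ``composition_driven``: strongly cell-type-specific baseline
      (neuron-to-glia expression ratio ``2**composition_lfc``, half
      neuron-high, half neuron-low); their bulk expression tracks the
      neuronal fraction and carries no disease coefficient.
    - ``interaction``: effect ``2**(interaction_lfc * disease_c * neuronal_c)``
      with both factors centered, mirroring the interaction model term.
    - ``covariate_only``: respond to age/sex/RIN/batch only.
    - ``null``: no planted effect.
    """

    frac_systemic: float = 0.10
    frac_composition: float = 0.15
    frac_interaction: float = 0.05
    frac_covariate: float = 0.10
    systemic_lfc: float = 1.0
    #: neuron-vs-glia log2 ratio of composition-driven genes; canonical
    #: cell-type markers are near-exclusive, so 8x is a realistic default
    composition_lfc: float = 3.0
    interaction_lfc: float = 1.0

    def validate(self) -> None:
        total = (
            self.frac_systemic + self.frac_composition
            + self.frac_interaction + self.frac_covariate
        )
        if total > 1.0 + 1e-12:
            raise ConfigurationError("effect-class fractions exceed 1")


@dataclass
class CovariateEffects:
    """log2-scale coefficients for nuisance covariates (covariate_only genes)."""

    age: float = 0.01  # per year
    sex: float = 0.25
    rin: float = 0.30  # on the high/low indicator
    batch: float = 0.50
    degradation: float = 0.40


@dataclass
class PerturbagenSpec:
    """Layout of the synthetic compound-perturbation panel."""

    n_compounds: int = 200
    n_cell_lines: int = 3
    n_doses: int = 1
    n_reversers: int = 2
    n_mimickers: int = 2
    n_confounders: int = 2
    signal_strength: float = 1.0
    noise_sd: float = 0.5
    frac_preclinical: float = 0.25

    def validate(self) -> None:
        planted = self.n_reversers + self.n_mimickers + self.n_confounders
        if planted > self.n_compounds:
            raise ConfigurationError("more planted compounds than compounds")
        for f in ("n_compounds", "n_cell_lines", "n_doses"):
            if getattr(self, f) < 1:
                raise ConfigurationError(f"{f} must be positive")


@dataclass
class SimulationConfig:
    """Master configuration for all synthetic datasets.

    ``baseline_expression`` (per-gene per-cell-type mean rates) and the gene
    class assignment are derived deterministically from ``seed`` unless
    supplied explicitly; identical configs therefore yield identical data.
    """

    n_genes: int = 2000
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    n_cells_per_type: int = 150
    mrna_content: dict[str, float] = field(
        default_factory=lambda: {
            "astrocyte": 1.0, "microglia": 1.0, "neuron": 2.0,
            "oligodendrocyte": 1.0,
        }
    )
    dispersion: float = 0.10  # bulk NB dispersion (per gene, constant default)
    sc_dispersion: float = 0.30  # single-cell NB dispersion
    sc_mean_library: float = 1e5  # Smart-seq-like coverage: ~50 reads per gene
    frac_mito_genes: float = 0.03
    frac_degenerate_cells: float = 0.0
    n_mislabeled_cells: int = 0
    effect_classes: EffectClasses = field(default_factory=EffectClasses)
    covariate_effects: CovariateEffects = field(default_factory=CovariateEffects)
    cohorts: dict[str, CohortDesign] = field(default_factory=default_cohorts)
    perturbagens: PerturbagenSpec = field(default_factory=PerturbagenSpec)
    #: fraction of null-class genes given cell-type-marker structure, and
    #: the marker log2 ratio; every type needs markers for deconvolution
    marker_frac_null: float = 0.15
    marker_lfc: float = 3.0
    baseline_expression: np.ndarray | None = None  # genes x types, optional
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_cells_per_type < 1:
            raise ConfigurationError("n_genes and n_cells_per_type must be positive")
        if len(self.cell_types) < 2:
            raise ConfigurationError("need at least two cell types")
        for t in self.cell_types:
            if self.mrna_content.get(t, 0.0) <= 0:
                raise ConfigurationError(f"mrna_content for {t} must be > 0")
        self.effect_classes.validate()
        self.perturbagens.validate()

    # -- deterministic derived quantities -------------------------------

    def rng(self, stream: str) -> np.random.Generator:
        """Named, independent random stream derived from the config seed."""
        tag = zlib.crc32(stream.encode()) % (2**31)
        ss = np.random.SeedSequence([self.seed, tag])
        return np.random.default_rng(ss)

    def content_vector(self) -> np.ndarray:
        return np.array([self.mrna_content[t] for t in self.cell_types])

    def gene_names(self) -> np.ndarray:
        width = len(str(self.n_genes))
        return np.array([f"G{i:0{width}d}" for i in range(self.n_genes)])

    def gene_classes(self) -> np.ndarray:
        """Deterministic assignment of genes to effect classes (contiguous
        blocks; gene order carries no other meaning)."""
        ec = self.effect_classes
        n = self.n_genes
        counts = [
            int(round(ec.frac_systemic * n)),
            int(round(ec.frac_composition * n)),
            int(round(ec.frac_interaction * n)),
            int(round(ec.frac_covariate * n)),
        ]
        labels = ["systemic", "composition_driven", "interaction", "covariate_only"]
        out = np.full(n, "null", dtype=object)
        start = 0
        for label, c in zip(labels, counts):
            out[start:start + c] = label
            start += c
        return out.astype(str)

    def effect_signs(self) -> np.ndarray:
        """Planted direction per gene: alternating +1/-1 within each class."""
        classes = self.gene_classes()
        signs = np.ones(self.n_genes)
        for label in np.unique(classes):
            idx = np.flatnonzero(classes == label)
            signs[idx[1::2]] = -1.0
        return signs

    def marker_types(self) -> np.ndarray:
        """Cell-type-marker assignment per gene ('none' for non-markers).

        Composition-driven genes are neuron-associated by construction
        (neuron-high or neuron-low); additionally a ``marker_frac_null``
        fraction of null-class genes is assigned round-robin as markers of
        single cell types so every type is distinguishable.
        """
        classes = self.gene_classes()
        out = np.full(self.n_genes, "none", dtype=object)
        neuron_label = "neuron" if "neuron" in self.cell_types else self.cell_types[0]
        comp = classes == "composition_driven"
        signs = self.effect_signs()
        out[comp & (signs > 0)] = neuron_label
        out[comp & (signs < 0)] = "glia"
        null_idx = np.flatnonzero(classes == "null")
        n_markers = int(round(self.marker_frac_null * len(null_idx)))
        for i, g in enumerate(null_idx[:n_markers]):
            out[g] = self.cell_types[i % len(self.cell_types)]
        return out.astype(str)

    def base_rates(self) -> np.ndarray:
        """Per-gene per-type mean expression rates (relative units).

        Baselines are log-normal across genes.  Composition-driven genes
        get a neuron-vs-glia ratio of ``2**composition_lfc`` (sign from
        :meth:`effect_signs`), marker genes a ``2**marker_lfc`` elevation
        in their type, and all genes mild independent type-to-type wobble.
        """
        if self.baseline_expression is not None:
            arr = np.asarray(self.baseline_expression, dtype=float)
            if arr.shape != (self.n_genes, len(self.cell_types)):
                raise ConfigurationError("baseline_expression has wrong shape")
            if (arr < 0).any():
                raise ConfigurationError("baseline_expression must be non-negative")
            return arr
        rng = self.rng("base_rates")
        base = np.exp(rng.normal(np.log(50.0), 1.2, size=self.n_genes))
        wobble = np.exp(rng.normal(0.0, 0.1, size=(self.n_genes, len(self.cell_types))))
        rates = base[:, None] * wobble
        classes = self.gene_classes()
        signs = self.effect_signs()
        types = list(self.cell_types)
        neuron = types.index("neuron") if "neuron" in types else 0
        comp = classes == "composition_driven"
        ratio = 2.0 ** (self.effect_classes.composition_lfc * signs[comp])
        rates[comp, :] = (base[comp] * wobble[comp].T).T
        rates[comp, neuron] = base[comp] * ratio
        markers = self.marker_types()
        for j, t in enumerate(types):
            m = (markers == t) & ~comp
            rates[m, j] = base[m] * 2.0 ** self.marker_lfc
        # markers are enriched in a type, not more abundant overall: rescale
        # marker rows so their typical bulk abundance (content-weighted
        # control mixture) stays at the gene's base level
        boosted = comp | (markers != "none")
        w0 = np.array(
            [CONTROL_MEAN_FRACTIONS.get(t, 1.0 / len(types)) for t in types]
        ) * self.content_vector()
        w0 /= w0.sum()
        bulk_mean = rates[boosted] @ w0
        rates[boosted] *= (base[boosted] / bulk_mean)[:, None]
        return rates

    def to_dict(self) -> dict:
        d = asdict(self)
        if d.get("baseline_expression") is not None:
            d["baseline_expression"] = np.asarray(d["baseline_expression"]).tolist()
        d["cell_types"] = list(self.cell_types)
        return d
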