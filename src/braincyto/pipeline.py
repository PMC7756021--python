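"""End-to-end orchestration of the synthetic digital-cytometry analysis.

Stage order mirrors the analysis the package implements: simulate ->
single-cell QC and signature -> deconvolution and composition-based sample
filters -> bulk preparation -> per-cohort differential expression ->
cross-dataset consistency per disease -> cross-disease concordance ->
gene-set enrichment -> perturbagen screen.  Every output file carries the
configuration hash and seed so that outputs of different runs cannot be
mixed unnoticed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from braincyto import bulk_prep, deconvolution, diffexp, drug_screen, io as bcio
from braincyto import permutation_stats as perm
from braincyto import single_cell
from braincyto.config import SimulationConfig
from braincyto.enrichment import GeneSetCollection, gsea
from braincyto.simulate import simulate_bulk_cohort, simulate_perturbagens, simulate_reference

ALL_STAGES = (
    "simulate", "scqc", "signature", "deconvolve", "prep", "diffexp",
    "consistency", "concordance", "gsea", "drugscreen",
)

COHORT_PROFILES = {
    "ad_discovery": "ad_rnaseq",
    "ad_validation": "ad_rnaseq",
    "pd_discovery": "pd_rnaseq",
    "pd_validation": "pd_microarray",
}
COHORT_SPECS = {
    "ad_rnaseq": diffexp.AD_RNASEQ_SPEC,
    "pd_rnaseq": diffexp.PD_RNASEQ_SPEC,
    "pd_microarray": diffexp.PD_MICROARRAY_SPEC,
}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Run-wide configuration: simulation, thresholds and permutation counts.

    Permutation counts default to desk-scale values so a full synthetic run
    finishes in minutes; they are dials, the statistical procedures do not
    change with them.
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    outdir: str = "results/pipeline"
    stages: tuple[str, ...] = ALL_STAGES
    neuronal_threshold: float = 0.40
    small_cohort_keep: int = 12  # keep-override below this size
    consistency_n_perm: int = 500
    concordance_n_perm: int = 50_000
    gsea_n_perm: int = 200
    deconv_method: str = "nnls"
    drug_k: int = 20
    confound_cut: float = 0.05

    @property
    def seed(self) -> int:
        return self.simulation.seed

    def config_hash(self) -> str:
        # stage toggles are deliberately not hashed: they select which
        # outputs exist, not what any output contains
        payload = repr(sorted(self.simulation.to_dict().items())) + repr(
            (self.neuronal_threshold, self.consistency_n_perm,
             self.concordance_n_perm, self.gsea_n_perm, self.deconv_method,
             self.drug_k, self.confound_cut)
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _tag(config: PipelineConfig) -> str:
    return f"config_hash={config.config_hash()} seed={config.seed}"


def prepare_cohort(cohort, est_fractions: pd.Series):
    """Normalize one cohort and encode its covariates.

    RNA-seq: CPM -> 10/L-in-N gene filter -> log2(CPM+0.5) -> quantile
    normalization.  Microarray: quantile normalization of the provided
    log2 intensities.  ``est_fractions`` supplies the neuronal proportion
    used as a covariate (restricted to the cohort's retained samples).
    """
    meta = cohort.metadata.loc[est_fractions.index].copy()
    meta["neuronal_fraction"] = est_fractions
    values = cohort.to_frame()[est_fractions.index]
    profile = COHORT_PROFILES.get(cohort.name, "ad_rnaseq")
    if cohort.platform == "microarray":
        norm = bulk_prep.quantile_normalize(values, platform="microarray")
    else:
        c = bulk_prep.cpm(values)
        params = bulk_prep.FilterParams.from_cohort(
            values.to_numpy(), meta["disease"].to_numpy()
        )
        kept = bulk_prep.filter_genes_bulk(c, params)
        logm = bulk_prep.log_cpm(values.iloc[kept])
        norm = bulk_prep.quantile_normalize(
            logm, library_sizes=values.to_numpy().sum(axis=0)
        )
    cov = bulk_prep.encode_covariates(meta, profile)
    return norm, cov, COHORT_SPECS[profile], meta


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the in-memory results and
    writes TSV outputs plus a run manifest under ``config.outdir``."""
    out: dict = {}
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tag = _tag(config)
    stages = set(config.stages)
    sim = config.simulation

    def _write(name: str, df: pd.DataFrame) -> None:
        bcio.write_tsv(df, str(outdir / name), header_comment=tag)

    try:
        reference = simulate_reference(sim)
        out["reference"] = reference
        if "simulate" in stages:
            _write("reference_counts.tsv", pd.DataFrame(
                reference.counts, index=reference.gene_names,
                columns=[f"cell{i:04d}" for i in range(reference.n_cells)],
            ))
    except Exception as e:  # pragma: no cover - defensive
        raise StageError("simulate", e) from e

    try:
        metrics = single_cell.compute_cell_qc(reference)
        kept_cells, removal_log = single_cell.filter_cells(metrics)
        sc = reference.subset(cells=kept_cells)
        kept_genes = single_cell.filter_genes_sc(sc)
        sc = sc.subset(genes=kept_genes)
        decomp = single_cell.decompose_variance(sc)
        out["scqc"] = {"metrics": metrics, "removed": removal_log, "decomp": decomp}
        if "scqc" in stages:
            _write("scqc_metrics.tsv", metrics.table)
            _write("scqc_removed.tsv", removal_log)
            _write("variance_decomposition.tsv", decomp.table)
    except Exception as e:
        raise StageError("scqc", e) from e

    try:
        signature = single_cell.build_signature(sc, decomp.retained)
        out["signature"] = signature
        if "signature" in stages:
            _write("signature.tsv", signature.data)
    except Exception as e:
        raise StageError("signature", e) from e

    try:
        cohorts = {
            name: simulate_bulk_cohort(sim, reference, name)
            for name in sim.cohorts
        }
        out["cohorts"] = cohorts
    except Exception as e:
        raise StageError("simulate", e) from e

    try:
        compositions, kept_samples = {}, {}
        for name, cohort in cohorts.items():
            values = cohort.to_frame()
            linear = (
                2.0 ** values - 1.0
                if cohort.platform == "microarray"
                else pd.DataFrame(
                    bulk_prep.cpm(values), index=values.index, columns=values.columns
                )
            )
            est = deconvolution.estimate_composition(
                linear, signature, method=config.deconv_method
            )
            keep_override = cohort.metadata.shape[0] < config.small_cohort_keep
            kept, log = deconvolution.filter_low_neuron_samples(
                est, cohort.metadata, threshold=config.neuronal_threshold,
                keep=keep_override,
            )
            compositions[name] = est
            kept_samples[name] = kept
            if "deconvolve" in stages:
                _write(f"composition_{name}.tsv", est.fractions)
                _write(f"low_neuron_{name}.tsv", log)
        out["compositions"] = compositions
    except Exception as e:
        raise StageError("deconvolve", e) from e

    try:
        prepared = {}
        for name, cohort in cohorts.items():
            est = compositions[name].neuronal.loc[kept_samples[name]]
            prepared[name] = prepare_cohort(cohort, est)
            if "prep" in stages:
                _write(f"normalized_{name}.tsv", prepared[name][0].data)
                _write(f"covariates_{name}.tsv", prepared[name][1])
        out["prepared"] = prepared
    except Exception as e:
        raise StageError("prep", e) from e

    try:
        effects = {}
        for name, (norm, cov, spec, _meta) in prepared.items():
            fit = diffexp.fit_models(norm.data, cov, spec)
            res = diffexp.moderate(fit)
            effects[name] = res
            if "diffexp" in stages:
                _write(f"diffexp_{name}.tsv", res.table.reset_index())
        out["effects"] = effects
    except Exception as e:
        raise StageError("diffexp", e) from e

    try:
        consistency = {}
        pairs = {
            "ad": ("ad_discovery", "ad_validation"),
            "pd": ("pd_discovery", "pd_validation"),
        }
        for disease, (a, b) in pairs.items():
            na, ca, sa, _ = prepared[a]
            nb, cb, sb, _ = prepared[b]
            res = perm.t_product_fdr(
                (na.data, ca, sa), (nb.data, cb, sb),
                n_perm=config.consistency_n_perm,
                seed=config.seed + 11,
            ).with_scores()
            res_neuro = perm.t_product_fdr(
                (na.data, ca, sa), (nb.data, cb, sb),
                n_perm=config.consistency_n_perm,
                seed=config.seed + 13,
                coef="neuronal_c",
            ).with_scores()
            consistency[disease] = {"disease": res, "neuronal": res_neuro}
            if "consistency" in stages:
                _write(f"consistency_{disease}.tsv", res.table)
                _write(f"consistency_{disease}_neuronal.tsv", res_neuro.table)
        out["consistency"] = consistency
    except Exception as e:
        raise StageError("consistency", e) from e

    try:
        s_ad = consistency["ad"]["disease"].table["score"]
        s_pd = consistency["pd"]["disease"].table["score"]
        conc = perm.cross_disease_fdr(
            s_ad, s_pd, n_perm=config.concordance_n_perm, seed=config.seed + 17
        ).with_scores()
        out["concordance"] = conc
        if "concordance" in stages:
            _write("concordance.tsv", conc.table)
    except Exception as e:
        raise StageError("concordance", e) from e

    try:
        truth = cohorts["ad_discovery"].truth
        common = conc.table.index
        classes = truth.loc[common, "effect_class"]
        signs = truth.loc[common, "sign"]
        sets = {
            "systemic_up": list(common[(classes == "systemic") & (signs > 0)]),
            "systemic_down": list(common[(classes == "systemic") & (signs < 0)]),
            "composition": list(common[classes == "composition_driven"]),
        }
        rng = np.random.default_rng(config.seed + 19)
        for i in range(3):
            sets[f"random_{i}"] = list(
                rng.choice(common, size=min(30, len(common)), replace=False)
            )
        collection = GeneSetCollection(
            sets={k: v for k, v in sets.items() if v}, source="planted"
        )
        enr = gsea(
            conc.table["score"], collection, n_perm=config.gsea_n_perm,
            seed=config.seed + 23,
        )
        out["gsea"] = enr
        out["gene_sets"] = collection
        if "gsea" in stages:
            _write("gsea.tsv", enr)
    except Exception as e:
        raise StageError("gsea", e) from e

    if "drugscreen" in stages:
        try:
            ad_scores = consistency["ad"]["disease"].table["score"]
            neuro_scores = consistency["ad"]["neuronal"].table["score"]
            panel = simulate_perturbagens(sim, ad_scores, neuro_scores)
            per_cond, per_cpd = drug_screen.compound_correlations(
                panel, ad_scores, neuro_scores
            )
            verdicts = drug_screen.select_candidates(
                per_cpd, k=config.drug_k, confound_cut=config.confound_cut
            )
            pd_scores = consistency["pd"]["disease"].table["score"]
            _, per_cpd_pd = drug_screen.compound_correlations(
                panel, pd_scores, neuro_scores
            )
            common_scores = conc.table["score"]
            joint = drug_screen.cross_disease_drug_map(
                per_cpd, per_cpd_pd, panel, common_scores
            )
            out["drugscreen"] = {
                "panel": panel, "per_condition": per_cond,
                "verdicts": verdicts, "joint": joint,
            }
            _write("drug_verdicts.tsv", verdicts)
            _write("drug_joint.tsv", joint)
        except Exception as e:
            raise StageError("drugscreen", e) from e

    manifest = pd.DataFrame(
        {
            "key": ["config_hash", "seed", "stages", "n_genes"],
            "value": [
                config.config_hash(), str(config.seed),
                ",".join(config.stages), str(sim.n_genes),
            ],
        }
    ).set_index("key")
    _write("manifest.tsv", manifest)
    out["manifest"] = manifest
    return out
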