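"""Study-level benchmark runs: each function executes one validation
experiment of the synthetic digital-cytometry analysis end to end and
returns the quantities it measures.

These are the computations behind the acceptance checks and the analysis
drivers: deconvolution identity and mixture-recovery benchmarks, the
disease/composition decoupling study, permutation-null calibrations, GSEA
calibration and the drug-screen recovery experiment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from braincyto import bulk_prep, diffexp, single_cell as scm
from braincyto.config import SimulationConfig
from braincyto.deconvolution import (
    benchmark_mixtures,
    estimate_composition,
    filter_low_neuron_samples,
)
from braincyto.drug_screen import compound_correlations, select_candidates
from braincyto.enrichment import GeneSetCollection, gsea
from braincyto.permutation_stats import cross_disease_fdr, t_product_fdr
from braincyto.pipeline import prepare_cohort
from braincyto.simulate import (
    dirichlet_proportions,
    simulate_bulk_cohort,
    simulate_mixtures,
    simulate_perturbagens,
    simulate_reference,
)

#: mixture-benchmark conditions: brain-like mean abundances with scarce
#: microglia, and a low microglial mRNA content against the 2x neuronal one
MIXTURE_ALPHA = np.array([1.6, 0.5, 4.4, 1.5])
MIXTURE_CONTENT = {
    "astrocyte": 1.0, "microglia": 0.5, "neuron": 2.0, "oligodendrocyte": 1.0
}


def study_config(seed: int) -> SimulationConfig:
    return SimulationConfig(n_genes=2000, n_cells_per_type=120, seed=seed)


def reference_and_signature(config: SimulationConfig):
    """Simulate the single-cell reference, run QC, and build the signature."""
    ref = simulate_reference(config)
    metrics = scm.compute_cell_qc(ref)
    kept, _ = scm.filter_cells(metrics)
    sc = ref.subset(cells=kept)
    sc = sc.subset(genes=scm.filter_genes_sc(sc))
    decomp = scm.decompose_variance(sc)
    signature = scm.build_signature(sc, decomp.retained)
    return ref, sc, decomp, signature


def deconvolution_identity(signature, seed: int = 0, n: int = 25) -> float:
    """Max absolute recovery error of NNLS on noiseless mixtures drawn from
    the signature's column space."""
    rng = np.random.default_rng(seed)
    W = rng.dirichlet(np.ones(len(signature.cell_types)), size=n)
    S = signature.data.to_numpy()
    bulk = pd.DataFrame(
        S @ W.T, index=signature.data.index, columns=[f"m{i}" for i in range(n)]
    )
    est = estimate_composition(bulk, signature)
    return float(np.abs(est.fractions.to_numpy() - W).max())


def mixture_benchmark(
    reference, signature, n_mixtures: int = 300, depth: int = 350_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Recovery of known cell fractions from chimeric count mixtures at the
    scaled-down sequencing depth."""
    P = dirichlet_proportions(
        n_mixtures, reference.cell_types, alpha=MIXTURE_ALPHA, seed=seed
    )
    mix = simulate_mixtures(
        reference, P, depth=depth, mrna_content=MIXTURE_CONTENT, seed=seed + 1
    )
    bulk = pd.DataFrame(
        bulk_prep.cpm(mix.values), index=mix.gene_names, columns=mix.metadata.index
    )
    est = estimate_composition(bulk, signature)
    return benchmark_mixtures(mix.true_fractions, est.fractions)


def run_cohort(config, reference, signature, cohort_name: str):
    """Simulate one cohort, deconvolve, filter, normalize and fit models."""
    cohort = simulate_bulk_cohort(config, reference, cohort_name)
    values = cohort.to_frame()
    linear = (
        2.0 ** values - 1.0
        if cohort.platform == "microarray"
        else pd.DataFrame(
            bulk_prep.cpm(values), index=values.index, columns=values.columns
        )
    )
    est = estimate_composition(linear, signature)
    keep_small = cohort.metadata.shape[0] < 12
    kept, _ = filter_low_neuron_samples(est, cohort.metadata, keep=keep_small)
    norm, cov, spec, meta = prepare_cohort(cohort, est.neuronal.loc[kept])
    fit = diffexp.fit_models(norm.data, cov, spec)
    result = diffexp.moderate(fit)
    return cohort, est, norm, cov, spec, result


def decoupling_study(config: SimulationConfig) -> dict[str, float]:
    """The core decoupling property on an AD-like cohort: power and false
    call rates of the disease and neuronal coefficients against the planted
    gene classes, at FDR < 0.05."""
    reference, _, _, signature = reference_and_signature(config)
    cohort, est, norm, cov, spec, result = run_cohort(
        config, reference, signature, "ad_discovery"
    )
    truth = cohort.truth.loc[norm.data.index]
    systemic = (truth["effect_class"] == "systemic").to_numpy()
    composition = (truth["effect_class"] == "composition_driven").to_numpy()
    dis = result.for_coef("disease_c")
    neu = result.for_coef("neuronal_c")
    return {
        "disease_power_systemic": float((dis.loc[systemic, "fdr"] < 0.05).mean()),
        "disease_fpr_composition": float((dis.loc[composition, "fdr"] < 0.05).mean()),
        "neuronal_power_composition": float((neu.loc[composition, "fdr"] < 0.05).mean()),
        "neuronal_fpr_systemic": float((neu.loc[systemic, "fdr"] < 0.05).mean()),
        "neuronal_estimate_r": float(
            np.corrcoef(est.neuronal, cohort.true_fractions["neuron"])[0, 1]
        ),
    }


def _null_cohort(n: int, n_genes: int, seed: int):
    rng = np.random.default_rng(seed)
    expr = pd.DataFrame(
        rng.normal(size=(n_genes, n)),
        index=[f"G{i:04d}" for i in range(n_genes)],
        columns=[f"s{seed}_{i}" for i in range(n)],
    )
    cov = pd.DataFrame(
        {
            "disease_c": np.r_[np.zeros(n // 2), np.ones(n - n // 2)] - 0.5,
            "age": rng.normal(75, 7, n),
        },
        index=expr.columns,
    )
    return expr, cov, diffexp.ModelSpec(["disease_c", "age"])


def tproduct_null_calibration(
    n_genes: int = 500, n_perm: int = 1000, seed: int = 0
) -> float:
    """FDR<0.05 call rate of the t-product permutation test on two fully
    null cohorts (should sit at the nominal 0.05)."""
    c1 = _null_cohort(24, n_genes, seed * 2 + 1)
    c2 = _null_cohort(20, n_genes, seed * 2 + 2)
    res = t_product_fdr(c1, c2, n_perm=n_perm, seed=seed + 7)
    return float((res.table["fdr"] < 0.05).mean())


def cross_disease_null_calibration(
    n_genes: int = 2000, n_perm: int = 100_000, seed: int = 0,
    threshold: float = 0.0005,
) -> float:
    """FDR<threshold call rate of the score-product permutation test on
    independent score vectors."""
    rng = np.random.default_rng(seed)
    idx = pd.Index([f"G{i:04d}" for i in range(n_genes)])
    a = pd.Series(rng.normal(size=n_genes), index=idx)
    b = pd.Series(rng.normal(size=n_genes), index=idx)
    res = cross_disease_fdr(a, b, n_perm=n_perm, seed=seed + 3)
    return float((res.table["fdr"] < threshold).mean())


def gsea_null_calibration(
    n_genes: int = 1000, n_sets: int = 800, set_size: int = 25,
    n_perm: int = 1000, seed: int = 0,
) -> dict[str, float]:
    """Fraction of random sets significant at p < 0.05 under a null
    statistic, per direction."""
    rng = np.random.default_rng(seed)
    stat = pd.Series(
        rng.normal(size=n_genes), index=[f"g{i}" for i in range(n_genes)]
    )
    sets = {
        f"s{i}": list(rng.choice(stat.index, size=set_size, replace=False))
        for i in range(n_sets)
    }
    table = gsea(
        stat, GeneSetCollection(sets=sets), n_perm=n_perm, seed=seed + 1,
        independent_nulls=True,
    )
    return {
        "rate_up": float((table["p_up"] < 0.05).mean()),
        "rate_down": float((table["p_down"] < 0.05).mean()),
    }


def drug_screen_recovery(seed: int = 0, n_genes: int = 600) -> dict[str, float]:
    """Planted-compound recovery in a 200-compound panel: the zero-noise
    reverser attains rho = -1 and ranks first; a strong neuronal confounder
    is excluded by the composition filter."""
    config = SimulationConfig(seed=seed)
    config.perturbagens.n_compounds = 200
    config.perturbagens.noise_sd = 0.0
    rng = np.random.default_rng(seed + 1)
    idx = pd.Index([f"G{i:04d}" for i in range(n_genes)])
    disease = pd.Series(rng.normal(size=n_genes), index=idx)
    # neuronal-proportion scores anti-correlate with the disease scores
    # (neuronal loss tracks disease), so the planted confounder also shows
    # an attractive disease correlation near -0.8 -- exactly the compound
    # the composition filter exists to reject
    z = (disease - disease.mean()) / disease.std()
    neuronal = pd.Series(
        -0.8 * z.to_numpy() + 0.6 * rng.normal(size=n_genes), index=idx
    )
    panel = simulate_perturbagens(config, disease, neuronal)
    _, per_cpd = compound_correlations(panel, disease, neuronal)
    verdicts = select_candidates(per_cpd)

    reversers = [c for c, r in panel.planted_roles.items() if r == "reverser"]
    confounders = [
        c for c, r in panel.planted_roles.items() if r == "neuronal_confounder"
    ]
    best = per_cpd["avg_rho"].idxmin()
    return {
        "reverser_rho": float(per_cpd.loc[reversers, "avg_rho"].min()),
        "reverser_ranks_first": float(best in reversers),
        "confounder_disease_rho": float(per_cpd.loc[confounders, "avg_rho"].min()),
        "confounder_neuronal_rho": float(
            per_cpd.loc[confounders, "avg_abs_rho_neuronal"].max()
        ),
        "confounder_excluded": float(
            (verdicts.loc[confounders, "verdict"] == "excluded_confounded").all()
        ),
    }
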