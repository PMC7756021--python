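#!/usr/bin/env python
"""Benchmark composition estimation: exact recovery on noiseless mixtures
from the signature's column space, then 300 chimeric count mixtures at the
scaled-down depth (3.5e5 reads) with known cell fractions.

Writes the per-type concordance report and prints the recovery summary,
including the expected underestimation of the low-mRNA-content microglia.
"""

from braincyto import io as bcio, study

SEED = 1
OUT = "results/analysis"


def main() -> None:
    config = study.study_config(SEED)
    reference, _, _, signature = study.reference_and_signature(config)

    err = study.deconvolution_identity(signature, seed=SEED + 1)
    print(f"noiseless column-space recovery: max abs error {err:.2e}")

    report = study.mixture_benchmark(reference, signature, seed=SEED + 2)
    bcio.write_tsv(report, f"{OUT}/mixture_benchmark.tsv")
    print("\n300 chimeric mixtures at depth 3.5e5 (cell-fraction truth):")
    print(report.round(3).to_string())
    print(
        "\nmicroglia bias "
        f"{report.loc['microglia', 'bias']:+.3f}: the low-content type is "
        "underestimated because deconvolution reports mRNA shares, while "
        "the high-content neurons are overestimated "
        f"({report.loc['neuron', 'bias']:+.3f})."
    )


if __name__ == "__main__":
    main()
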