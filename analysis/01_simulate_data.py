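#!/usr/bin/env python
"""Generate the synthetic study data set.

Emulates the raw material of a transcriptome-based SNP project: a unigene
reference with planted SNPs, paralogous gene copies and residual inbred
heterozygosity; tagged reads from the two mapping parents and the inbred
genotype; a 184-individual CP population with genotypes and two-channel
array intensities; cross-species alignment blocks; and assay design
scores. Everything lands in results/simdata with the planted truth in
truth.json.
"""

import pathlib
import sys

from grasspanel.simulate import SimConfig, simulate_all

OUT = pathlib.Path(__file__).resolve().parents[1] / "scratch" / "simdata"


def main(seed: int = 20120418) -> None:
    cfg = SimConfig(n_unigenes=120, seed=seed)
    truth = simulate_all(cfg, OUT)
    n_snps = sum(len(s) for s in truth.snps.values())
    n_paralog = sum(truth.paralog_flags.values())
    print(f"unigenes            : {len(truth.unigenes)}")
    print(f"planted SNPs        : {n_snps}")
    print(f"paralogous unigenes : {n_paralog}")
    print(f"markers in population: {len(truth.markers)}")
    print(f"wrote inputs to {OUT}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 20120418)
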