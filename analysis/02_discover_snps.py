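#!/usr/bin/env python
"""Call SNP candidates from the simulated alignments.

Builds per-position pileups from the SAM alignments, applies the calling
thresholds (depth >= 4, both alleles >= 2 reads, base quality >= 10,
posterior >= 0.5), writes the candidates as VCF, and screens unigenes for
inbred-genotype polymorphism (the paralogy signature used downstream).
"""

import json
import pathlib

from Bio import SeqIO

from grasspanel.discovery import (
    CallerConfig,
    build_pileups,
    call_snps,
    inbred_polymorphic_unigenes,
    write_vcf,
)

BASE = pathlib.Path(__file__).resolve().parents[1]
SCRATCH = BASE / "scratch"
RESULTS = BASE / "results"


def main() -> None:
    ref = {
        rec.id: str(rec.seq)
        for rec in SeqIO.parse(SCRATCH / "simdata" / "unigenes.fasta", "fasta")
    }
    cfg = CallerConfig()
    columns = build_pileups(str(SCRATCH / "simdata" / "reads.sam"), ref, cfg)
    candidates = call_snps(columns, cfg, ref)
    SCRATCH.mkdir(exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    write_vcf(candidates, ref, SCRATCH / "candidates.vcf")
    inbred_poly = sorted(inbred_polymorphic_unigenes(columns, cfg.min_allele_depth))
    (RESULTS / "inbred_polymorphic.json").write_text(json.dumps(inbred_poly, indent=1))
    with_snp = {c.unigene_id for c in candidates}
    print(f"pileup columns           : {len(columns)}")
    print(f"SNP candidates called    : {len(candidates)}")
    print(f"unigenes with a candidate: {len(with_snp)}")
    print(f"inbred-polymorphic unigenes (paralogy signature): {len(inbred_poly)}")


if __name__ == "__main__":
    main()
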