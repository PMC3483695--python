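#!/usr/bin/env python
"""Apply the assay-design selection cascade and account for every discard.

Filters candidates for flank/junction clearance, neighbouring
polymorphism, inbred-genotype polymorphism (paralogy), missing
cross-species hits, single-parent support and low design scores; selects
one SNP per surviving unigene; prints the funnel with recomputed
percentages.
"""

import dataclasses
import json
import pathlib

from Bio import SeqIO

from grasspanel.panel import (
    FilterConfig,
    apply_filters,
    parse_blast_tabular,
    read_design_scores,
    records_to_frame,
    select_panel,
)
from grasspanel.discovery import read_vcf

BASE = pathlib.Path(__file__).resolve().parents[1]
SCRATCH = BASE / "scratch"
RESULTS = BASE / "results"


def main() -> None:
    ref = {
        rec.id: str(rec.seq)
        for rec in SeqIO.parse(SCRATCH / "simdata" / "unigenes.fasta", "fasta")
    }
    candidates = read_vcf(SCRATCH / "candidates.vcf")
    cfg = FilterConfig()
    splice = parse_blast_tabular(SCRATCH / "simdata" / "blast_hits.tsv", cfg.evalue_max)
    scores = read_design_scores(SCRATCH / "simdata" / "design_scores.csv")
    inbred_poly = set(json.loads((RESULTS / "inbred_polymorphic.json").read_text()))
    lengths = {k: len(v) for k, v in ref.items()}
    records = apply_filters(candidates, splice, lengths, scores, cfg, inbred_poly)
    records, report = select_panel(records, cfg, splice, lengths)
    records_to_frame(records).to_csv(SCRATCH / "panel_records.tsv", sep="\t", index=False)
    (RESULTS / "accounting.json").write_text(
        json.dumps(dataclasses.asdict(report), indent=1)
    )
    print(f"unigenes with candidates : {report.input_unigenes}")
    for cat, n in report.discards.items():
        pct = 100 * n / report.input_unigenes
        print(f"  discarded {cat:<18}: {n:4d} ({pct:.0f}%)")
    print(f"unigenes passing         : {report.remaining_unigenes}")
    print(f"final panel size         : {report.panel_size}")


if __name__ == "__main__":
    main()
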