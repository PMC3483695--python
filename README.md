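# grasspanel

In-silico SNP panel design, array genotype calling and dense genetic
linkage mapping for outbreeding grasses — the full pipeline from
transcriptome reads aligned to a unigene reference to a centimorgan map
with marker-density tracks, exercised end to end on synthetic data with
planted ground truth.

## Who this is for

Building SNP resources in a species without a reference genome typically
means: align reads from the two parents of a mapping population (plus a
highly inbred reference genotype) to an assembled unigene set, call SNPs
from the pileups, filter them down to an assay-ready multiplex panel,
genotype the population on a bead array, and map the markers. Each stage
has well-known failure modes — paralogous gene copies masquerading as
heterozygous SNPs, probes straddling intron/exon junctions, overlapping
fluorescence clusters — and this package implements the whole chain with
explicit, testable rules for each of them.

## The methods at the core

* **SNP calling.** Per covered position, bases with Phred quality ≥ 10
  form a pileup column; a candidate requires total depth ≥ 4 and ≥ 2
  reads per allele. The SNP-existence statistic is a flat-prior posterior
  over the three pooled diploid genotypes with per-base error
  `e = 10^(−Q/10)`; candidates need posterior ≥ 0.5.
* **Paralog screen.** A unigene whose *inbred* genotype shows two alleles
  (each ≥ 2 reads) at any site carries co-aligned non-allelic sequence
  and is discarded — the key filter that keeps false SNPs off the panel.
* **Panel filters** (fixed precedence, mutually exclusive discard
  categories): flank/junction clearance ≥ 30 bp and no neighbouring
  polymorphism within 30 bp; a significant (E ≤ 1e−10) cross-species hit
  for junction prediction; read support from both parents with
  heterozygosity in at least one; assay design score > 0.6.
* **Genotype calling.** Intensities map to `theta = (2/π)·arctan(b/a)`,
  `R = a + b`; per marker a 1–3 component Gaussian mixture on theta is
  selected by BIC. Cluster separation is
  `min_adjacent clip((μⱼ−μᵢ−2σᵢ−2σⱼ)/(μⱼ−μᵢ), 0, 1)`; markers below 0.8
  are discarded, as are failed assays (median R near zero) and
  monomorphic markers.
* **Linkage.** CP segregation types `lmxll`/`nnxnp` (1:1) and `hkxhk`
  (1:2:1); grouping by independence LOD `G²/(2 ln 10)` at threshold 4.0
  (single linkage, with per-group override or fixed chromosome count);
  recombination fractions by maximum likelihood over parental phases;
  ordering by greedy insertion + 2-opt on a LOD-weighted regression
  objective, positions re-fitted by composite likelihood; distances via
  Haldane, `d = −50·ln(1 − 2r)` cM.
* **Reporting.** Map statistics, 3 cM / 0.3 cM sliding-window density
  tracks, funnel accounting with recomputed percentages, and Table-style
  cross-population transferability summaries.

## Worked example

The numbered scripts under `analysis/` run the whole pipeline on a
simulated 120-unigene, 184-individual data set (inputs land in
`scratch/`, tables in `results/`):

```bash
python analysis/01_simulate_data.py
python analysis/02_discover_snps.py
python analysis/03_design_panel.py
python analysis/04_call_genotypes.py
python analysis/05_build_map.py
python analysis/06_report.py
```

which prints, among other things:

```
unigenes            : 120
planted SNPs        : 1007
paralogous unigenes : 11
...
SNP candidates called    : 982
inbred-polymorphic unigenes (paralogy signature): 18
...
  discarded assembly_or_flank :   20 (17%)
  discarded no_blast_hit      :   10 (8%)
  discarded single_parent     :    2 (2%)
  discarded low_design_score  :    3 (2%)
final panel size         : 85
...
  polymorphic     :   85 (78%)
  monomorphic     :   13 (12%)
  failed          :   11 (10%)
parental duplicate concordance: 100.0%
missing-call rate among callable markers: 0.02%
...
linkage groups formed    : 7
total map length : 648.3 cM over 7 groups
mean interval    : 7.63 cM
```

Reading it: of 982 called candidates, 18 unigenes are flagged by the
inbred-polymorphism screen (11 carry planted paralogs, the rest residual
heterozygosity); the filter cascade leaves an 85-SNP panel; genotyping
classifies 78 % of assays polymorphic with perfect parental-duplicate
concordance; and the mapped markers form the seven planted linkage
groups at roughly their planted lengths.

The same steps are available as a CLI (`grasspanel simulate | discover |
design-panel | call-genotypes | map | report`).

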