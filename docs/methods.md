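# Methods

This note records the models, parameter choices and numerical decisions
behind each stage of the pipeline, what the synthetic data generator does
and does not emulate, and the known limitations.

## Synthetic data model

The generator (`grasspanel.simulate`) produces every input the pipeline
consumes, with planted truth. Its defaults are the study conditions the
package emulates throughout:

| parameter | default | meaning |
|---|---|---|
| `mean_unigene_len` | 889 bp | unigene lengths ~ Normal(mean, 0.2·mean), min 100 bp |
| `snp_rate` | 1/102 per bp | i.i.d. Bernoulli per site |
| `read_len_mean` | 377 bp | truncated Normal (sd 15 % of mean, min 50 bp, capped at the unigene) |
| `depth` | 20 | Poisson reads per unigene per genotype |
| `base_error` | 0.001 | per-base substitution; constant quality string at the implied Phred |
| `paralog_fraction` / `paralog_divergence` | 0.10 / 0.02 | whole-gene duplicate with i.i.d. point divergence; its reads co-align with the parent gene |
| `inbred_residual_het` | 0.015 | fraction of *segregating* sites at which the inbred line is still heterozygous (a per-bp rate would flag essentially every gene as paralogous) |
| `pop_size` / `n_groups` / `group_len_cM` | 184 / 7 / 107 | F2 pseudo-testcross population |
| `missing_rate` / `geno_error_rate` | 0.003 / 0.002 | applied to offspring genotype calls |
| `theta_centers` / `theta_sd` | 0.10, 0.50, 0.90 / 0.015 | Gaussian intensity clouds; R lognormal |
| `fail_fraction` / `monomorph_fraction` | 0.10 / 0.12 | failed assays (R scaled to ~2 %) and single-cluster markers |

Read depth per unigene is modelled as Poisson per genotype; nothing in
the emulated study pins the depth distribution down, so this is a
modelling choice, as is the uniform placement of SNP sites. Crossovers
are a Poisson process at rate 1 per 100 cM with uniform placement — the
Haldane no-interference model, deliberately matching the mapping function
used downstream, so that map recovery is a test of estimation rather
than of model mismatch. Each parent's phase at each marker is random.

Features of real data the generator does **not** emulate: 454-style
homopolymer indel errors, chimeric reads, expression-level variation
between genes and genotypes, partial-domain paralogy, plate/batch
effects on intensities, and crossover interference. Passing tests
therefore demonstrate correctness of the algorithms under the stated
model, not robustness to those artefacts.

The theta spread deserves a note: with cluster centres 0.4 apart, the
separation score is `(0.4 − 2σᵢ − 2σⱼ)/0.4`, so clouds with sd 0.03
score 0.70 and are *correctly* classified poor-clustering at the 0.8
threshold. The default sd 0.015 (separation ≈ 0.85) represents a
passing assay; a test pins the sd-0.03 behaviour.

## SNP discovery

The pooled-sample SNP-existence posterior is a flat-prior Bayes
computation over the three diploid genotypes {ref/ref, ref/alt, alt/alt}
of the pooled material. For an observed base `b` with error probability
`e = 10^(−Q/10)`: `P(b|t) = 1−e` if `b = t`, else `e/3`; the het
genotype mixes the two alleles equally; bases outside the tested pair
contribute equally under every genotype and cancel. `e` is capped at
0.75 (the uniform-base limit) so quality-0 observations are exactly
uninformative and the posterior falls back to the prior 1/3. This model
is our own; the original array-era tooling it stands in for is a black
box, and no claim of numerical equivalence is made. Note that at minimal
depth the posterior is deliberately conservative: four concordant Q30
reads still leave ~6 % posterior on the het hypothesis — far below the
0.5 calling threshold, but not the ~0 a deeper column would give.

Allele pair: the two most frequent qualified bases, ties alphabetical;
the reference base is reported as the ref allele when it is one of the
two. Coordinates are 1-based on the unigene. Indels are never emitted as
candidates; gap-adjacent columns supported by ≥ 2 reads carry an
`indel_adjacent` flag consumed by the panel's polymorphism-window filter.
Per-genotype counts come from read tags (synthetic reads encode them in
their names) or SAM read groups; untagged reads count toward depth but
are excluded from parent-presence logic.

## Panel design

Filter precedence is fixed — (a) assembly/flank (ends, junctions,
neighbouring polymorphism within 30 bp, inbred-genotype polymorphism
anywhere on the unigene), (b) no significant cross-species hit,
(c) single-parent support, (d) design score — so that every discarded
unigene lands in exactly one category and funnel accounting is
conservative by construction. A discarded unigene takes the category of
its furthest-advancing candidate. The flank distance is configurable
(`min_flank`, default 30 bp; 50 bp is the documented alternative
preset). The inbred-polymorphism test requires ≥ 2 reads per allele,
reusing the caller's allele-depth threshold, to avoid single-error false
flags. Junctions are the interior block boundaries after merging the
best subject's query intervals from 12-column BLAST tabular input;
distance-to-junction is what the flank rule tests. One SNP per unigene
is selected by maximising the minimal distance to any end, junction or
neighbouring polymorphism (ties: smallest position).

## Genotype calling

`theta = (2/π)·arctan(signal_b/signal_a)` (scale-invariant, endpoints 0
and 1 at the pure channels) and `R = signal_a + signal_b` (no further
normalisation — the platform's normalisation constant is unspecified and
upstream of this package). Assay failure: median R below 5 % of the
plate-median R. Mixtures are fitted with scikit-learn's EM (k-means++
initialisation, 10 restarts, fixed seed), k ∈ {1,2,3} by BIC with ties
to the smaller k. Clusters map to genotypes by ascending theta (AA, AB,
BB); for k < 3 the subset of canonical centres closest to the fitted
means is used. The separation score and the 0.8 threshold are transparent
surrogates for the platform's proprietary quality metrics and are
labelled as such; 0.9 is exposed as a stricter preset. Samples are
assigned to the nearest cluster in SD units within `max_sd = 3.5`
(missing beyond that); a 2-SD radius would misclassify ~5 % of genuinely
clustered samples as missing, which is inconsistent with the sub-0.3 %
missing rates a clean assay shows, while 3.5 SD leaves ~0.05 % expected
misses and still rejects gross outliers.

## Linkage

Two-point statistics come from an explicit CP gamete-transmission model:
each parent heterozygous at both markers transmits its two marker slots
with recombination probability r (phase flips r ↔ 1−r per parent);
parents heterozygous at one marker transmit independently. This yields
the joint class probabilities for every segregation-type combination,
and rf is estimated by bounded scalar ML, maximising over the admissible
phase configurations (up to four for hkxhk × hkxhk; exact ties report
rf 0.5). Pairs with no parent heterozygous at both markers — e.g.
lmxll × nnxnp — carry no two-point information and report rf 0.5, LOD 0;
this is a structural property of CP data, not an implementation limit.
The independence LOD is `G²/(2 ln 10)` on the joint contingency table
(empty rows/columns dropped), the JoinMap-documented construction.

Grouping is single linkage over edges with independence LOD ≥ 4.0.
Pseudo-linkage occasionally bridges two chromosomes at that threshold —
the same phenomenon that historically required raising the threshold for
specific groups — so two remedies are provided: per-group override
thresholds, and `group_markers_fixed_k`, which cuts the weakest maximum-
spanning-forest bridges until the known chromosome number is reached.

Ordering approximates regression mapping: pairs with rf ≤ 0.40 and
LOD ≥ 1.00 enter a weighted least-squares objective (weight = LOD,
distance = Haldane(rf)); the order is grown by greedy insertion from the
strongest pair and refined by 2-opt segment reversals, the goodness of
fit of an order being the attained weighted residual. Positions are then
re-fitted by *composite likelihood*: with the order fixed, the adjacent
interval lengths jointly maximise the sum of two-point log-likelihoods,
each pair's rf implied by its summed intervals through Haldane (phases
fixed at their pairwise ML values), followed by a ripple-style
adjacent-swap polish under the same objective. This replaces simple
cumulative adjacent distances, which are undefined across uninformative
adjacencies in mixed-type groups and noticeably less precise; it is
still built entirely from two-point statistics — full multipoint ML is
out of scope. Distances use Haldane throughout; co-segregating markers
collapse to exact position ties; sub-10⁻³ cM intervals are snapped to 0.
The distortion chi-square (1:1 or 1:2:1) is reported per marker but
never used to exclude markers.

## Validation experiments

`grasspanel.validation` fixes the problem sizes used by the tests and
the reproduction script: 50 unigenes for exact caller-vs-truth
equivalence; twenty 40-unigene replicates at inbred depth 12 and 2 %
divergence for the paralog screen; 100 markers × 192 samples for
cluster-mean recovery (a mean counts as recovered within three posterior
standard errors, `σ̂/√n_k`, so ~0.3 % of clusters are expected outside —
the test checks ≥ 97 % inside plus a hard cap on the worst error); and a
7-group, 184-individual population with 12 markers per group for map
recovery. The map experiment uses hkxhk markers on a 4 cM grid: markers
heterozygous in different parents cannot be ordered relative to each
other from two-point data at all, and 184 individuals resolve adjacent
intervals of a few cM, so this is the regime in which exact order
recovery is statistically identifiable. Position error is reported as
RMS after aligning each group to truth by shift and orientation (the
map's origin and direction are arbitrary). Map-length and position
accuracy degrade gracefully at wider spacings; grouping and ordering are
the first casualties of sparser or mixed-type panels.

## Known limitations

* The caller pools reads across genotypes for the existence posterior;
  it does not produce per-individual genotype likelihoods (population
  genotyping is array-style by design).
* Paralog detection presumes the paralog is expressed in the inbred
  genotype and diverged enough to place ≥ 2 reads per allele at some
  site; silent or ultra-recent duplicates escape.
* Ordering is heuristic (greedy + 2-opt + ripple); for very dense maps
  where many markers co-segregate, order within a recombination block is
  arbitrary and only the block structure is meaningful.
* The intensity model is two-channel Gaussian-on-theta; departures such
  as compression toward theta 0.5 or intensity-dependent variance are
  not modelled.
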