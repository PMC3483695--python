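"""Synthetic data generator for the full SNP-panel pipeline.

Emulates the data a transcriptome-based SNP project produces: a unigene
reference (non-redundant assembled transcripts), pyrosequencing-style reads
from two heterozygous outbred mapping parents plus one highly inbred
reference genotype, an F2 pseudo-testcross (CP) mapping population, and
two-channel array fluorescence intensities per marker.

Everything is planted with known ground truth (:class:`TruthSet`) so every
downstream stage — SNP calling, paralog filtering, cluster calling and
linkage mapping — can be tested against what was actually simulated.

Key realism choices:

* unigene lengths and read lengths are truncated normals around their means
  (the field typically reports only means);
* a configurable fraction of unigenes carries a diverged whole-gene paralog
  whose reads co-align with the parent gene, creating the false
  heterozygosity that the inbred genotype is used to detect;
* meioses place crossovers as a Poisson process along each linkage group
  (no interference), i.e. exactly the Haldane model used in mapping;
* intensity clouds are three Gaussian clusters on theta with lognormal
  total signal, plus failed assays (signal near zero) and monomorphic
  markers (one cluster).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASES = "ACGT"
GENOTYPE_TAGS = ("parent1", "parent2", "inbred")

# theta centres for the three genotype classes AA / AB / BB
DEFAULT_THETA_CENTERS = (0.10, 0.50, 0.90)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic pipeline.

    Defaults mirror the source study's setting: 889 bp mean unigene length,
    one SNP every ~102 bp, 377 bp mean read length, a 184-individual F2
    pseudo-testcross population over 7 linkage groups (mean group length
    107 cM), residual inbred heterozygosity below 1.5 %, and missing-call
    rates below 0.3 %.
    """

    n_unigenes: int = 200
    mean_unigene_len: int = 889
    snp_rate: float = 1.0 / 102.0
    paralog_fraction: float = 0.10
    paralog_divergence: float = 0.02
    read_len_mean: int = 377
    depth: float = 20.0
    base_error: float = 0.001
    inbred_residual_het: float = 0.015
    pop_size: int = 184
    n_groups: int = 7
    group_len_cM: float = 107.0
    missing_rate: float = 0.003
    geno_error_rate: float = 0.002
    seed: int = 0
    # intensity-model knobs
    theta_centers: tuple[float, float, float] = DEFAULT_THETA_CENTERS
    theta_sd: float = 0.015
    r_log_mean: float = 8.0
    r_log_sd: float = 0.25
    fail_fraction: float = 0.10
    monomorph_fraction: float = 0.12
    # proportions of segregation configurations among planted SNPs:
    # (parent1 het only, parent2 het only, both het)
    seg_type_probs: tuple[float, float, float] = (0.4, 0.4, 0.2)
    # cross-species alignment and assay-design emulation
    blast_hit_fraction: float = 0.93  # unigenes with a significant hit
    mean_junctions: float = 1.5  # Poisson mean splice junctions per unigene
    design_score_beta: tuple[float, float] = (5.0, 1.5)  # ~25% below 0.6

    def validate(self) -> None:
        rates = {
            "snp_rate": self.snp_rate,
            "paralog_fraction": self.paralog_fraction,
            "paralog_divergence": self.paralog_divergence,
            "base_error": self.base_error,
            "inbred_residual_het": self.inbred_residual_het,
            "missing_rate": self.missing_rate,
            "geno_error_rate": self.geno_error_rate,
            "fail_fraction": self.fail_fraction,
            "monomorph_fraction": self.monomorph_fraction,
        }
        for name, value in rates.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        for name in ("n_unigenes", "mean_unigene_len", "read_len_mean", "n_groups"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.depth < 0:
            raise ValueError("depth must be non-negative")
        if self.group_len_cM < 0:
            raise ValueError("group_len_cM must be non-negative")
        if abs(sum(self.seg_type_probs) - 1.0) > 1e-9:
            raise ValueError("seg_type_probs must sum to 1")


@dataclass
class SnpTruth:
    """A planted SNP: position, alleles and phased parental genotypes."""

    pos: int  # 1-based on the unigene
    ref: str
    alt: str
    # phased genotypes per tag: tuple of two alleles (haplotype 0, haplotype 1)
    genotypes: dict[str, tuple[str, str]]

    def het_in(self, tag: str) -> bool:
        a, b = self.genotypes[tag]
        return a != b


@dataclass
class MarkerTruth:
    """True map placement and segregation of one marker."""

    marker_id: str
    group: int  # 0-based group index
    cM: float
    seg_config: str  # 'p1het', 'p2het', 'bothhet'
    status: str  # 'segregating', 'failed', 'monomorphic'


@dataclass
class TruthSet:
    """Ground truth behind a simulated data set."""

    unigenes: dict[str, str] = field(default_factory=dict)
    snps: dict[str, list[SnpTruth]] = field(default_factory=dict)
    paralog_flags: dict[str, bool] = field(default_factory=dict)
    paralog_seqs: dict[str, str] = field(default_factory=dict)
    # residual heterozygous sites of the inbred genotype: uid -> [(pos, alt)]
    inbred_het_sites: dict[str, list[tuple[int, str]]] = field(default_factory=dict)
    markers: list[MarkerTruth] = field(default_factory=list)
    # individuals x markers true genotype calls ('AA'/'AB'/'BB')
    true_genotypes: "pd.DataFrame | None" = None

    def marker_order(self, group: int) -> list[str]:
        ms = [m for m in self.markers if m.group == group]
        ms.sort(key=lambda m: (m.cM, m.marker_id))
        return [m.marker_id for m in ms]

    def to_json(self) -> str:
        payload = {
            "unigenes": self.unigenes,
            "snps": {
                uid: [
                    {"pos": s.pos, "ref": s.ref, "alt": s.alt, "genotypes": s.genotypes}
                    for s in snps
                ]
                for uid, snps in self.snps.items()
            },
            "paralog_flags": self.paralog_flags,
            "inbred_het_sites": self.inbred_het_sites,
            "markers": [dataclasses.asdict(m) for m in self.markers],
        }
        return json.dumps(payload, indent=1, sort_keys=True)


@dataclass
class SimRead:
    """A simulated read with its (truth) alignment to a unigene."""

    read_id: str
    tag: str
    unigene_id: str
    start: int  # 1-based position of the first base on the unigene
    seq: str
    qual: str  # Phred+33


# ---------------------------------------------------------------------------
# reference and reads


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in BASES if b != base]
    return choices[rng.integers(0, 3)]


def simulate_reference(config: SimConfig, rng: np.random.Generator | None = None):
    """Simulate the unigene reference and plant SNPs, paralogs and the
    inbred genotype's residual heterozygosity.

    Returns ``(unigenes, truth)`` where ``unigenes`` maps unigene id to
    sequence and ``truth`` is a :class:`TruthSet`. Each planted SNP is
    heterozygous in at least one mapping parent; the inbred genotype is
    homozygous reference everywhere except at residual-heterozygosity sites
    drawn independently at rate ``inbred_residual_het``.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    truth = TruthSet()
    len_sd = 0.20 * config.mean_unigene_len
    seg_configs = ("p1het", "p2het", "bothhet")
    for i in range(config.n_unigenes):
        uid = f"UG{i + 1:05d}"
        length = max(100, int(round(rng.normal(config.mean_unigene_len, len_sd))))
        seq = _random_seq(rng, length)
        truth.unigenes[uid] = seq
        # plant SNPs
        snp_mask = rng.random(length) < config.snp_rate
        snps: list[SnpTruth] = []
        for pos0 in np.flatnonzero(snp_mask):
            ref = seq[pos0]
            alt = _other_base(rng, ref)
            cfg = seg_configs[rng.choice(3, p=np.asarray(config.seg_type_probs))]
            genotypes: dict[str, tuple[str, str]] = {}
            for tag, het in (
                ("parent1", cfg in ("p1het", "bothhet")),
                ("parent2", cfg in ("p2het", "bothhet")),
            ):
                if het:
                    phase = int(rng.integers(0, 2))
                    hap = [ref, ref]
                    hap[phase] = alt
                    genotypes[tag] = (hap[0], hap[1])
                else:
                    allele = ref if rng.random() < 0.5 else alt
                    genotypes[tag] = (allele, allele)
            # residual heterozygosity: the inbred line still segregates at a
            # small fraction of variable sites (not per bp)
            if rng.random() < config.inbred_residual_het:
                genotypes["inbred"] = (ref, alt)
                truth.inbred_het_sites.setdefault(uid, []).append((int(pos0) + 1, alt))
            else:
                genotypes["inbred"] = (ref, ref)
            snps.append(SnpTruth(pos=int(pos0) + 1, ref=ref, alt=alt, genotypes=genotypes))
        truth.snps[uid] = snps
        truth.inbred_het_sites.setdefault(uid, [])
        # paralog copy
        is_paralog = rng.random() < config.paralog_fraction
        truth.paralog_flags[uid] = bool(is_paralog)
        if is_paralog:
            div_mask = rng.random(length) < config.paralog_divergence
            par = list(seq)
            for p in np.flatnonzero(div_mask):
                par[p] = _other_base(rng, seq[p])
            truth.paralog_seqs[uid] = "".join(par)
    return truth.unigenes, truth


def _haplotypes(truth: TruthSet, uid: str, tag: str) -> tuple[str, str]:
    """Two haplotype sequences of ``tag`` at unigene ``uid``."""
    seq = truth.unigenes[uid]
    haps = [list(seq), list(seq)]
    for snp in truth.snps[uid]:
        a0, a1 = snp.genotypes[tag]
        haps[0][snp.pos - 1] = a0
        haps[1][snp.pos - 1] = a1
    return "".join(haps[0]), "".join(haps[1])


def simulate_reads(
    unigenes: dict[str, str],
    truth: TruthSet,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[SimRead]:
    """Simulate tagged reads for the three sequenced genotypes.

    Per genotype and unigene the read count is Poisson(``depth``); each read
    is drawn from one of the genotype's two haplotypes, gets per-base
    substitution errors at ``base_error``, and a constant quality string at
    the Phred value implied by ``base_error``. Unigenes flagged as
    paralogous additionally emit Poisson(``depth``) reads per genotype from
    the diverged copy, attributed to the parent gene's coordinates.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    if config.base_error > 0:
        q = int(round(-10.0 * math.log10(config.base_error)))
    else:
        q = 40
    q = max(2, min(q, 41))
    qchar = chr(q + 33)
    len_sd = 0.15 * config.read_len_mean

    reads: list[SimRead] = []
    counter = 0

    def emit(tag: str, uid: str, templates: tuple[str, str]) -> None:
        nonlocal counter
        n = int(rng.poisson(config.depth))
        length_ref = len(templates[0])
        for _ in range(n):
            hap = templates[int(rng.integers(0, 2))]
            rlen = int(round(rng.normal(config.read_len_mean, len_sd)))
            rlen = max(50, rlen)
            rlen = min(rlen, length_ref)
            start0 = int(rng.integers(0, length_ref - rlen + 1))
            bases = list(hap[start0 : start0 + rlen])
            if config.base_error > 0:
                err = rng.random(rlen) < config.base_error
                for p in np.flatnonzero(err):
                    bases[p] = _other_base(rng, bases[p])
            counter += 1
            reads.append(
                SimRead(
                    read_id=f"{tag}|{uid}|{start0 + 1}|{counter}",
                    tag=tag,
                    unigene_id=uid,
                    start=start0 + 1,
                    seq="".join(bases),
                    qual=qchar * rlen,
                )
            )

    for uid in unigenes:
        for tag in GENOTYPE_TAGS:
            emit(tag, uid, _haplotypes(truth, uid, tag))
        if truth.paralog_flags.get(uid) and uid in truth.paralog_seqs:
            par = truth.paralog_seqs[uid]
            for tag in GENOTYPE_TAGS:
                emit(tag, uid, (par, par))
    return reads


def simulate_blast_tabular(
    unigenes: dict[str, str], config: SimConfig, rng: np.random.Generator
) -> list[str]:
    """Emulate 12-column BLASTN output against a model grass genome.

    A ``blast_hit_fraction`` of unigenes gets a significant hit whose
    query coverage is split into exon-like blocks at Poisson-many interior
    junctions; the rest get either a weak (non-significant) hit or none.
    Returns the tab-separated lines.
    """
    lines: list[str] = []
    for uid, seq in unigenes.items():
        length = len(seq)
        subject = f"OsChr{int(rng.integers(1, 13))}"
        if rng.random() < config.blast_hit_fraction:
            n_junc = int(rng.poisson(config.mean_junctions))
            n_junc = min(n_junc, max(length // 120 - 1, 0))
            cuts = sorted(rng.choice(
                np.arange(60, length - 60), size=n_junc, replace=False
            )) if n_junc else []
            bounds = [1] + [int(c) + 1 for c in cuts] + [length + 1]
            sstart = int(rng.integers(1, 30_000_000))
            for k in range(len(bounds) - 1):
                qs, qe = bounds[k], bounds[k + 1] - 1
                blen = qe - qs + 1
                intron = int(rng.integers(60, 2000))
                ss = sstart + qs + k * intron
                lines.append(
                    f"{uid}\t{subject}\t97.5\t{blen}\t{max(1, blen // 80)}\t0\t"
                    f"{qs}\t{qe}\t{ss}\t{ss + blen - 1}\t1e-40\t{2 * blen}"
                )
        elif rng.random() < 0.5:
            # weak similarity only: above the significance cutoff
            qs = int(rng.integers(1, max(length - 100, 2)))
            qe = min(qs + 80, length)
            lines.append(
                f"{uid}\t{subject}\t82.0\t{qe - qs + 1}\t12\t2\t{qs}\t{qe}\t"
                f"500\t{500 + qe - qs}\t1e-5\t60"
            )
    return lines


def simulate_design_scores(
    marker_ids, config: SimConfig, rng: np.random.Generator
) -> dict[str, float]:
    """Emulated assay design scores (externally computed in practice)."""
    a, b = config.design_score_beta
    return {mid: float(np.round(rng.beta(a, b), 3)) for mid in marker_ids}


# ---------------------------------------------------------------------------
# population and intensities


def simulate_map_truth(
    marker_ids: list[str],
    config: SimConfig,
    rng: np.random.Generator,
    seg_configs=None,
    spacing_cM: float | None = None,
) -> list[MarkerTruth]:
    """Assign markers to linkage groups with uniform cM positions.

    Markers are spread round-robin over ``n_groups``; a ``fail_fraction`` of
    markers is designated as failed assays and a ``monomorph_fraction`` as
    monomorphic, mirroring array practice where not every designed assay
    converts into a segregating marker. With ``spacing_cM`` set, markers sit
    on an even grid instead of uniform random positions.
    """
    markers: list[MarkerTruth] = []
    n = len(marker_ids)
    statuses = np.array(["segregating"] * n, dtype=object)
    n_fail = int(round(config.fail_fraction * n))
    n_mono = int(round(config.monomorph_fraction * n))
    idx = rng.permutation(n)
    statuses[idx[:n_fail]] = "failed"
    statuses[idx[n_fail : n_fail + n_mono]] = "monomorphic"
    rank_in_group = [0] * config.n_groups
    for i, mid in enumerate(marker_ids):
        group = i % config.n_groups
        if spacing_cM is not None:
            cM = rank_in_group[group] * spacing_cM
            rank_in_group[group] += 1
        else:
            cM = float(rng.uniform(0.0, config.group_len_cM))
        if seg_configs is not None:
            cfg = seg_configs[i]
        else:
            cfg = ("p1het", "p2het", "bothhet")[
                rng.choice(3, p=np.asarray(config.seg_type_probs))
            ]
        markers.append(
            MarkerTruth(marker_id=mid, group=group, cM=cM, seg_config=cfg, status=str(statuses[i]))
        )
    return markers


def _gamete(
    positions: np.ndarray, group_len: float, rng: np.random.Generator
) -> np.ndarray:
    """Simulate one meiosis: haplotype index (0/1) transmitted per marker.

    Crossovers follow a Poisson process at rate 1 per 100 cM with uniform
    placement (Haldane, no interference).
    """
    n_x = rng.poisson(group_len / 100.0)
    current = int(rng.integers(0, 2))
    if n_x == 0:
        return np.full(positions.shape, current)
    xlocs = np.sort(rng.uniform(0.0, group_len, size=n_x))
    # haplotype switches at each crossover: parity of crossovers before pos
    before = np.searchsorted(xlocs, positions, side="right")
    return (current + before) % 2


def simulate_cp_genotypes(
    markers: list[MarkerTruth],
    config: SimConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate true genotypes of a CP population at the given markers.

    Returns a DataFrame indexed by sample (individuals ``I0001``.. plus the
    two parents), columns = marker ids, values 'AA'/'AB'/'BB'. Allele 'A' is
    haplotype-0's allele at heterozygous parents; homozygous parents carry a
    fixed random allele. Monomorphic markers are homozygous in everyone.
    """
    if config.pop_size < 2:
        raise ValueError("pop_size must be >= 2")
    mids = [m.marker_id for m in markers]
    n_m = len(mids)
    # phased parental alleles per marker: parent p haplotype h -> 0/1 allele
    p_alleles = np.zeros((2, 2, n_m), dtype=int)
    mono_allele = {}
    for j, m in enumerate(markers):
        if m.status == "monomorphic":
            a = int(rng.integers(0, 2))
            p_alleles[:, :, j] = a
            mono_allele[m.marker_id] = a
            continue
        for p, het_flag in ((0, m.seg_config in ("p1het", "bothhet")),
                            (1, m.seg_config in ("p2het", "bothhet"))):
            if het_flag:
                phase = int(rng.integers(0, 2))
                p_alleles[p, phase, j] = 1
            else:
                p_alleles[p, :, j] = int(rng.integers(0, 2))

    groups = sorted({m.group for m in markers})
    col_of = {mid: j for j, mid in enumerate(mids)}
    geno = np.zeros((config.pop_size, n_m), dtype=int)  # count of allele 1
    for g in groups:
        g_idx = np.array([col_of[m.marker_id] for m in markers if m.group == g])
        g_pos = np.array([m.cM for m in markers if m.group == g])
        for i in range(config.pop_size):
            for p in (0, 1):
                hap = _gamete(g_pos, config.group_len_cM, rng)
                geno[i, g_idx] += p_alleles[p, hap, g_idx]
    codes = np.array(["AA", "AB", "BB"], dtype=object)
    rows = {}
    for i in range(config.pop_size):
        rows[f"I{i + 1:04d}"] = codes[geno[i]]
    rows["P1"] = codes[p_alleles[0, 0] + p_alleles[0, 1]]
    rows["P2"] = codes[p_alleles[1, 0] + p_alleles[1, 1]]
    return pd.DataFrame.from_dict(rows, orient="index", columns=mids)


def perturb_genotypes(
    true_geno: pd.DataFrame, config: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Apply genotyping error and missingness to individuals (not parents)."""
    obs = true_geno.copy()
    codes = ["AA", "AB", "BB"]
    ind_rows = [r for r in obs.index if not str(r).startswith("P")]
    for r in ind_rows:
        vals = obs.loc[r].to_numpy(dtype=object)
        err = rng.random(len(vals)) < config.geno_error_rate
        for j in np.flatnonzero(err):
            others = [c for c in codes if c != vals[j]]
            vals[j] = others[rng.integers(0, 2)]
        miss = rng.random(len(vals)) < config.missing_rate
        vals[miss] = "--"
        obs.loc[r] = vals
    return obs


def simulate_intensities(
    true_geno: pd.DataFrame,
    markers: list[MarkerTruth],
    config: SimConfig,
    rng: np.random.Generator,
    duplicate_parents: bool = True,
) -> pd.DataFrame:
    """Two-channel intensities per sample x marker from true genotypes.

    The three genotype classes sit at distinct theta centres with Gaussian
    spread ``theta_sd``; total signal R is lognormal. Failed assays have R
    scaled to near zero; monomorphic markers cluster at their single class.
    Parents are duplicated (suffix ``_dup``) as on real genotyping plates.
    """
    centers = np.asarray(config.theta_centers)
    status_of = {m.marker_id: m.status for m in markers}
    geno_idx = {"AA": 0, "AB": 1, "BB": 2}
    samples = list(true_geno.index)
    if duplicate_parents:
        for p in ("P1", "P2"):
            if p in true_geno.index:
                samples.append(f"{p}_dup")
    recs = []
    for mid in true_geno.columns:
        st = status_of.get(mid, "segregating")
        for s in samples:
            src = s[:-4] if s.endswith("_dup") else s
            g = true_geno.at[src, mid]
            theta = float(np.clip(rng.normal(centers[geno_idx[g]], config.theta_sd), 0.0, 1.0))
            r = float(rng.lognormal(config.r_log_mean, config.r_log_sd))
            if st == "failed":
                r *= 0.02
                theta = float(rng.uniform(0.0, 1.0))
            a = r * (1.0 - theta)
            b = r * theta
            recs.append((s, mid, a, b))
    return pd.DataFrame(recs, columns=["sample_id", "marker_id", "signal_a", "signal_b"])


def simulate_population(
    truth: TruthSet,
    config: SimConfig,
    rng: np.random.Generator | None = None,
):
    """Simulate the CP population for one marker per SNP-bearing unigene.

    Fills ``truth.markers`` and ``truth.true_genotypes`` and returns
    ``(observed genotype matrix, intensity table)``. The observed matrix is
    the truth perturbed by ``geno_error_rate`` and masked at
    ``missing_rate``; intensities are generated from the unperturbed truth.
    """
    config.validate()
    if config.pop_size < 2:
        raise ValueError("pop_size must be >= 2")
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    marker_ids, seg_configs = [], []
    for uid in sorted(truth.snps):
        snps = truth.snps[uid]
        if not snps or truth.paralog_flags.get(uid):
            continue
        snp = snps[0]
        marker_ids.append(f"{uid}.S{snp.pos}")
        if snp.het_in("parent1") and snp.het_in("parent2"):
            seg_configs.append("bothhet")
        elif snp.het_in("parent1"):
            seg_configs.append("p1het")
        else:
            seg_configs.append("p2het")
    markers = simulate_map_truth(marker_ids, config, rng, seg_configs=seg_configs)
    truth.markers = markers
    true_geno = simulate_cp_genotypes(markers, config, rng)
    truth.true_genotypes = true_geno
    observed = perturb_genotypes(true_geno, config, rng)
    intensities = simulate_intensities(true_geno, markers, config, rng)
    return observed, intensities


# ---------------------------------------------------------------------------
# writers (plain-text formats only)


def write_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), 80):
                fh.write(s[i : i + 80] + "\n")


def write_fastq(reads: list[SimRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{r.qual}\n")


def write_sam(reads: list[SimRead], unigenes: dict[str, str], path) -> None:
    """Write truth-derived perfect-coordinate alignments as plain SAM."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for uid, seq in unigenes.items():
            fh.write(f"@SQ\tSN:{uid}\tLN:{len(seq)}\n")
        for tag in GENOTYPE_TAGS:
            fh.write(f"@RG\tID:{tag}\tSM:{tag}\n")
        for r in reads:
            fh.write(
                f"{r.read_id}\t0\t{r.unigene_id}\t{r.start}\t60\t{len(r.seq)}M\t*\t0\t0\t"
                f"{r.seq}\t{r.qual}\tRG:Z:{r.tag}\n"
            )


def write_pileup_tsv(reads: list[SimRead], path) -> None:
    """Write the 4-column TSV pileup dialect (unigene, pos, tag, base:qual)."""
    with open(path, "w") as fh:
        for r in reads:
            for i, base in enumerate(r.seq):
                fh.write(f"{r.unigene_id}\t{r.start + i}\t{r.tag}\t{base}:{ord(r.qual[i]) - 33}\n")


def simulate_all(config: SimConfig, outdir) -> TruthSet:
    """Run the full generator and write every pipeline input to ``outdir``."""
    import pathlib

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    unigenes, truth = simulate_reference(config)
    reads = simulate_reads(unigenes, truth, config)
    observed, intensities = simulate_population(truth, config)
    rng = np.random.default_rng(config.seed + 3)
    blast = simulate_blast_tabular(unigenes, config, rng)
    snp_ids = [
        f"{uid}.S{s.pos}" for uid in sorted(truth.snps) for s in truth.snps[uid]
    ]
    scores = simulate_design_scores(snp_ids, config, rng)
    write_fasta(unigenes, out / "unigenes.fasta")
    write_fastq(reads, out / "reads.fastq")
    write_sam(reads, unigenes, out / "reads.sam")
    observed.to_csv(out / "genotypes.csv", index_label="sample_id")
    intensities.to_csv(out / "intensities.csv", index=False)
    (out / "blast_hits.tsv").write_text("\n".join(blast) + "\n")
    pd.DataFrame(
        {"marker_id": list(scores), "score": list(scores.values())}
    ).to_csv(out / "design_scores.csv", index=False)
    (out / "truth.json").write_text(truth.to_json())
    return truth
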