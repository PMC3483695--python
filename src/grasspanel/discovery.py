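"""In-silico SNP discovery from reads aligned to a unigene reference.

Builds per-position pileups (from SAM, a simple TSV pileup dialect, or
in-memory simulated reads), computes a pooled-sample heterozygosity
posterior per column, and calls SNP candidates under coverage, base-quality
and posterior thresholds:

* at least ``min_total_depth`` (default 4) quality-passing reads at the
  position,
* at least ``min_allele_depth`` (default 2) reads supporting each of the
  two most frequent alleles,
* bases below ``min_base_quality`` (default Phred 10) excluded, and
* a SNP-existence posterior of at least ``min_posterior`` (default 0.5).

The posterior is a flat-prior Bayes factor over the three diploid pooled
genotypes (hom ref / het / hom alt) using per-base error probabilities
``10^(-Q/10)``; it is our own model standing in for the black-box caller
originally used, and is documented as such.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

KNOWN_TAGS = ("parent1", "parent2", "inbred")


@dataclass(frozen=True)
class CallerConfig:
    min_total_depth: int = 4
    min_allele_depth: int = 2
    min_base_quality: int = 10
    min_posterior: float = 0.5

    def validate(self) -> None:
        for name in ("min_total_depth", "min_allele_depth", "min_base_quality"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.min_posterior <= 1.0:
            raise ValueError("min_posterior must be in [0, 1]")


@dataclass
class PileupColumn:
    """Read evidence at one 1-based position of a unigene."""

    unigene_id: str
    pos: int
    observations: list[tuple[str, str, int]] = field(default_factory=list)  # (tag, base, qual)
    indel_adjacent_support: int = 0  # reads with a gap bordering this column

    @property
    def depth(self) -> int:
        return len(self.observations)

    def base_counts(self, tag: str | None = None) -> dict[str, int]:
        counts: dict[str, int] = {}
        for t, b, _ in self.observations:
            if tag is not None and t != tag:
                continue
            counts[b] = counts.get(b, 0) + 1
        return counts


@dataclass
class SnpCandidate:
    """A called biallelic variant on a unigene with per-genotype support."""

    unigene_id: str
    pos: int
    ref_allele: str
    alt_allele: str
    counts: dict[str, dict[str, int]]  # tag -> {ref: n, alt: n}
    posterior: float
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        total = sum(sum(c.values()) for c in self.counts.values())
        if total < 4:
            raise ValueError("candidate total depth below 4")
        ref_n = sum(c.get(self.ref_allele, 0) for c in self.counts.values())
        alt_n = sum(c.get(self.alt_allele, 0) for c in self.counts.values())
        if ref_n < 2 or alt_n < 2:
            raise ValueError("each allele of a candidate needs >= 2 reads")
        if self.posterior < 0.5:
            raise ValueError("candidate posterior below 0.5")

    def allele_depth(self, tag: str) -> tuple[int, int]:
        c = self.counts.get(tag, {})
        return c.get(self.ref_allele, 0), c.get(self.alt_allele, 0)

    @property
    def marker_id(self) -> str:
        return f"{self.unigene_id}.S{self.pos}"


# ---------------------------------------------------------------------------
# pileup construction


def pileups_from_reads(reads, min_base_quality: int = 10) -> list[PileupColumn]:
    """Pileup columns from in-memory simulated reads (ungapped alignments)."""
    columns: dict[tuple[str, int], PileupColumn] = {}
    for r in reads:
        for i, base in enumerate(r.seq):
            q = ord(r.qual[i]) - 33
            if q < min_base_quality:
                continue
            key = (r.unigene_id, r.start + i)
            col = columns.get(key)
            if col is None:
                col = columns[key] = PileupColumn(r.unigene_id, r.start + i)
            col.observations.append((r.tag, base, q))
    return [columns[k] for k in sorted(columns)]


def _tag_of_read(aln) -> str:
    try:
        return aln.get_tag("RG")
    except KeyError:
        name = aln.query_name or ""
        head = name.split("|", 1)[0]
        return head if head in KNOWN_TAGS else "pooled"


def pileups_from_sam(path, reference: dict[str, str] | None = None,
                     min_base_quality: int = 10) -> list[PileupColumn]:
    """Build pileup columns from a SAM/BAM file.

    Gap-bordering reference positions (flanking insertions and deletions)
    accumulate ``indel_adjacent_support`` for downstream flagging. Unknown
    reference names raise; unaligned or malformed records are skipped with
    a warning.
    """
    import pysam

    columns: dict[tuple[str, int], PileupColumn] = {}

    def col(uid: str, pos: int) -> PileupColumn:
        key = (uid, pos)
        c = columns.get(key)
        if c is None:
            c = columns[key] = PileupColumn(uid, pos)
        return c

    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.query_sequence is None:
                continue
            uid = aln.reference_name
            if reference is not None and uid not in reference:
                raise ValueError(f"alignment references unknown unigene {uid!r}")
            tag = _tag_of_read(aln)
            seq = aln.query_sequence
            quals = aln.query_qualities
            if quals is None:
                logger.warning("read %s has no qualities; skipped", aln.query_name)
                continue
            for qpos, rpos in aln.get_aligned_pairs(matches_only=True):
                q = quals[qpos]
                if q < min_base_quality:
                    continue
                col(uid, rpos + 1).observations.append((tag, seq[qpos], int(q)))
            # indel adjacency: reference positions flanking I/D cigar ops
            if aln.cigartuples and any(op in (1, 2) for op, _ in aln.cigartuples):
                rpos = aln.reference_start  # 0-based walk
                for op, length in aln.cigartuples:
                    if op in (0, 7, 8):  # M/=/X consume reference
                        rpos += length
                    elif op == 2:  # D
                        col(uid, rpos).indel_adjacent_support += 1  # base before gap
                        rpos += length
                        col(uid, rpos + 1).indel_adjacent_support += 1
                    elif op == 1:  # I
                        col(uid, rpos).indel_adjacent_support += 1
                        col(uid, rpos + 1).indel_adjacent_support += 1
                    elif op == 3:  # N
                        rpos += length
    return [columns[k] for k in sorted(columns)]


def pileups_from_tsv(path, reference: dict[str, str] | None = None,
                     min_base_quality: int = 10) -> list[PileupColumn]:
    """Parse the 4-column pileup dialect: unigene_id, pos, tag, base:qual."""
    columns: dict[tuple[str, int], PileupColumn] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4 or ":" not in parts[3]:
                logger.warning("malformed pileup line %d skipped: %r", lineno, line)
                continue
            uid, pos_s, tag, bq = parts
            if reference is not None and uid not in reference:
                raise ValueError(f"pileup line {lineno} references unknown unigene {uid!r}")
            base, q_s = bq.split(":", 1)
            pos, q = int(pos_s), int(q_s)
            if q < min_base_quality:
                continue
            key = (uid, pos)
            c = columns.get(key)
            if c is None:
                c = columns[key] = PileupColumn(uid, pos)
            c.observations.append((tag, base.upper(), q))
    return [columns[k] for k in sorted(columns)]


def build_pileups(source, reference: dict[str, str] | None = None,
                  config: CallerConfig | None = None) -> list[PileupColumn]:
    """Dispatch on source type: path to SAM/BAM or TSV, or a read list."""
    config = config or CallerConfig()
    config.validate()
    if isinstance(source, (list, tuple)):
        return pileups_from_reads(source, config.min_base_quality)
    s = str(source)
    if s.endswith((".sam", ".bam")):
        return pileups_from_sam(source, reference, config.min_base_quality)
    return pileups_from_tsv(source, reference, config.min_base_quality)


# ---------------------------------------------------------------------------
# posterior model and calling

# cap the per-base error probability at the uniform-base limit so that
# quality 0 observations are exactly uninformative
_MAX_ERROR = 0.75


def genotype_posterior(column: PileupColumn, allele_pair: tuple[str, str]) -> float:
    """Posterior that the pooled sample carries both alleles (is het).

    Flat prior over the three pooled diploid genotypes {ref/ref, ref/alt,
    alt/alt}. For an observed base b with error probability e,
    P(b | true base t) = 1-e if b == t else e/3; the het genotype mixes the
    two alleles equally. Bases other than the pair contribute a factor e/3
    under every genotype and cancel.
    """
    if not column.observations:
        raise ValueError("cannot compute posterior of an empty column")
    ref, alt = allele_pair
    log_l = np.zeros(3)  # hom-ref, het, hom-alt
    for _, base, q in column.observations:
        e = min(10.0 ** (-q / 10.0), _MAX_ERROR)
        p_match, p_mis = 1.0 - e, e / 3.0
        if base == ref:
            probs = (p_match, 0.5 * (p_match + p_mis), p_mis)
        elif base == alt:
            probs = (p_mis, 0.5 * (p_match + p_mis), p_match)
        else:
            continue  # equal factor under all genotypes
        log_l += np.log(probs)
    log_l -= log_l.max()
    lik = np.exp(log_l)
    return float(lik[1] / lik.sum())


def _top_two_alleles(counts: dict[str, int]) -> list[tuple[str, int]]:
    # most frequent first; ties broken alphabetically
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:2]


def call_snps(
    columns,
    config: CallerConfig | None = None,
    reference: dict[str, str] | None = None,
) -> list[SnpCandidate]:
    """Call SNP candidates from pileup columns.

    Emits exactly the columns with qualified depth >= ``min_total_depth``,
    both top alleles supported by >= ``min_allele_depth`` reads, and het
    posterior >= ``min_posterior``. A third allele at >= ``min_allele_depth``
    adds the ``multiallelic`` flag; columns bordering alignment gaps in >= 2
    reads get ``indel_adjacent``. The reference base (when a reference is
    given) is reported as the ref allele if it is one of the top two.
    """
    config = config or CallerConfig()
    config.validate()
    out: list[SnpCandidate] = []
    for col in columns:
        if col.depth < config.min_total_depth:
            continue
        counts = col.base_counts()
        top = _top_two_alleles(counts)
        if len(top) < 2 or top[1][1] < config.min_allele_depth:
            continue
        (a1, _), (a2, _) = top
        ref_base = None
        if reference is not None and col.unigene_id in reference:
            seq = reference[col.unigene_id]
            if 1 <= col.pos <= len(seq):
                ref_base = seq[col.pos - 1]
        if ref_base == a2:
            ref, alt = a2, a1
        else:
            ref, alt = a1, a2
        post = genotype_posterior(col, (ref, alt))
        if post < config.min_posterior:
            continue
        flags = set()
        if len(counts) > 2:
            third = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[2]
            if third[1] >= config.min_allele_depth:
                flags.add("multiallelic")
        if col.indel_adjacent_support >= 2:
            flags.add("indel_adjacent")
        per_tag: dict[str, dict[str, int]] = {}
        for t, b, _ in col.observations:
            bucket = t if t in KNOWN_TAGS else "pooled"
            d = per_tag.setdefault(bucket, {ref: 0, alt: 0})
            if b in (ref, alt):
                d[b] += 1
        out.append(
            SnpCandidate(
                unigene_id=col.unigene_id,
                pos=col.pos,
                ref_allele=ref,
                alt_allele=alt,
                counts=per_tag,
                posterior=post,
                flags=flags,
            )
        )
    return out


def inbred_polymorphic_unigenes(columns, min_allele_depth: int = 2) -> set[str]:
    """Unigenes where the inbred genotype's reads are biallelic anywhere.

    A site counts as inbred-polymorphic when at least two distinct bases
    each have >= ``min_allele_depth`` inbred reads — the signature of
    co-aligned paralogous copies (or residual heterozygosity) that
    disqualifies the whole unigene from panel design.
    """
    flagged: set[str] = set()
    for col in columns:
        if col.unigene_id in flagged:
            continue
        counts = col.base_counts(tag="inbred")
        strong = [b for b, n in counts.items() if n >= min_allele_depth]
        if len(strong) >= 2:
            flagged.add(col.unigene_id)
    return flagged


# ---------------------------------------------------------------------------
# VCF round-trip


def write_vcf(candidates: list[SnpCandidate], reference: dict[str, str], path) -> None:
    """Write candidates as a minimal VCF (1-based positions on unigenes)."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##source=grasspanel')
    for uid, seq in reference.items():
        header.contigs.add(uid, length=len(seq))
    header.info.add("DP", 1, "Integer", "Qualified read depth")
    header.info.add("AD1", 2, "Integer", "Parent1 ref,alt depth")
    header.info.add("AD2", 2, "Integer", "Parent2 ref,alt depth")
    header.info.add("ADI", 2, "Integer", "Inbred ref,alt depth")
    header.info.add("PP", 1, "Float", "SNP-existence posterior")
    header.info.add("MULTI", 0, "Flag", "Third allele with qualifying support")
    header.info.add("INDELADJ", 0, "Flag", "Adjacent to an alignment gap")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for c in candidates:
            rec = out.new_record(
                contig=c.unigene_id,
                start=c.pos - 1,
                stop=c.pos,
                alleles=(c.ref_allele, c.alt_allele),
            )
            rec.info["DP"] = sum(sum(d.values()) for d in c.counts.values())
            rec.info["AD1"] = c.allele_depth("parent1")
            rec.info["AD2"] = c.allele_depth("parent2")
            rec.info["ADI"] = c.allele_depth("inbred")
            rec.info["PP"] = c.posterior
            if "multiallelic" in c.flags:
                rec.info["MULTI"] = True
            if "indel_adjacent" in c.flags:
                rec.info["INDELADJ"] = True
            out.write(rec)


def read_vcf(path) -> list[SnpCandidate]:
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as fh:
        for rec in fh:
            ref, alt = rec.ref, rec.alts[0]
            counts = {}
            for tag, key in (("parent1", "AD1"), ("parent2", "AD2"), ("inbred", "ADI")):
                ad = rec.info.get(key, (0, 0))
                counts[tag] = {ref: int(ad[0]), alt: int(ad[1])}
            flags = set()
            if rec.info.get("MULTI"):
                flags.add("multiallelic")
            if rec.info.get("INDELADJ"):
                flags.add("indel_adjacent")
            out.append(
                SnpCandidate(
                    unigene_id=rec.chrom,
                    pos=rec.pos,
                    ref_allele=ref,
                    alt_allele=alt,
                    counts=counts,
                    posterior=float(rec.info["PP"]),
                    flags=flags,
                )
            )
    return out
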