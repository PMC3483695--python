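"""Assay-panel design: the SNP selection cascade and its accounting.

Candidates surviving discovery are filtered for array-assay suitability in
a fixed precedence that reproduces mutually exclusive discard categories:

a. ``assembly_or_flank`` — the SNP sits within ``min_flank`` bp of a
   sequence end or a predicted intron/exon junction, has another
   SNP/indel within ``poly_window`` bp, or its unigene shows allelic
   polymorphism in the inbred reference genotype (the paralogy signature);
b. ``no_blast_hit`` — no significant cross-species hit, so junctions
   cannot be predicted at all;
c. ``single_parent`` — read support from only one mapping parent, or
   heterozygous in neither;
d. ``low_design_score`` — externally computed assay design score <= cutoff.

One SNP per unigene (configurably more) is then selected; the accounting
report conserves counts at every stage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from .discovery import SnpCandidate

logger = logging.getLogger(__name__)

FILTER_NAMES = ("assembly_or_flank", "no_blast_hit", "single_parent", "low_design_score")


@dataclass(frozen=True)
class FilterConfig:
    min_flank: int = 30  # bp to sequence ends and splice junctions
    poly_window: int = 30  # bp window free of other SNPs/indels
    evalue_max: float = 1e-10
    design_score_min: float = 0.6
    max_snps_per_unigene: int = 1

    def validate(self) -> None:
        if min(self.min_flank, self.poly_window, self.max_snps_per_unigene) <= 0:
            raise ValueError("flank/window/max-SNP settings must be positive")
        if self.evalue_max <= 0 or self.design_score_min <= 0:
            raise ValueError("evalue_max and design_score_min must be positive")


@dataclass
class SpliceModel:
    """Predicted intron/exon structure of a unigene from cross-species hits."""

    unigene_id: str
    has_significant_hit: bool
    best_evalue: float | None
    junctions: list[int] = field(default_factory=list)  # 1-based transcript positions

    def __post_init__(self) -> None:
        self.junctions = sorted(self.junctions)
        if not self.has_significant_hit and self.junctions:
            raise ValueError("a unigene without a significant hit has no junctions")


@dataclass
class PanelRecord:
    candidate: SnpCandidate
    decisions: dict[str, bool]  # filter name -> passed
    fail_category: str  # one of FILTER_NAMES or 'none'
    selected: bool = False


@dataclass
class AccountingReport:
    """Stage counts of the selection funnel, per unigene."""

    input_unigenes: int
    discards: dict[str, int]
    remaining_unigenes: int
    panel_size: int

    def __post_init__(self) -> None:
        if self.input_unigenes - sum(self.discards.values()) != self.remaining_unigenes:
            raise ValueError("accounting does not conserve unigene counts")

    def percentages(self) -> dict[str, float]:
        return {
            k: 100.0 * v / self.input_unigenes for k, v in self.discards.items()
        }


# ---------------------------------------------------------------------------
# BLAST tabular -> splice models

_BLAST_COLS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def parse_blast_tabular(path, evalue_max: float = 1e-10) -> dict[str, SpliceModel]:
    """Infer splice junctions from 12-column BLAST tabular output.

    Per query: hits with evalue <= ``evalue_max`` qualify; the best subject
    is the one carrying the overall best hit (lowest evalue, then highest
    bitscore). Overlapping query intervals on that subject are merged;
    junctions are the interior boundaries between the resulting blocks
    (the end coordinate of each block but the last). Queries without a
    qualifying hit get ``has_significant_hit=False``.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=_BLAST_COLS, comment="#")
    except Exception as exc:  # pragma: no cover - pandas reports the line
        raise ValueError(f"malformed BLAST tabular file {path}: {exc}") from exc
    if df[["qstart", "qend", "evalue"]].isna().any().any():
        bad = int(df[["qstart", "qend", "evalue"]].isna().any(axis=1).idxmax()) + 1
        raise ValueError(f"malformed BLAST tabular line {bad} in {path}")
    models: dict[str, SpliceModel] = {}
    for qid, sub in df.groupby("qseqid", sort=False):
        qualifying = sub[sub["evalue"] <= evalue_max]
        if qualifying.empty:
            models[qid] = SpliceModel(qid, False, float(sub["evalue"].min()))
            continue
        best = qualifying.sort_values(["evalue", "bitscore"], ascending=[True, False]).iloc[0]
        hits = qualifying[qualifying["sseqid"] == best["sseqid"]]
        intervals = sorted(
            (min(int(r.qstart), int(r.qend)), max(int(r.qstart), int(r.qend)))
            for r in hits.itertuples()
        )
        merged: list[list[int]] = []
        for s, e in intervals:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        junctions = [e for s, e in merged[:-1]]
        models[qid] = SpliceModel(qid, True, float(best["evalue"]), junctions)
    return models


# ---------------------------------------------------------------------------
# the filter cascade


def _parent_support_ok(c: SnpCandidate, min_allele_depth: int) -> bool:
    d1 = c.counts.get("parent1", {})
    d2 = c.counts.get("parent2", {})
    if sum(d1.values()) == 0 or sum(d2.values()) == 0:
        return False
    het = False
    for d in (d1, d2):
        if (d.get(c.ref_allele, 0) >= min_allele_depth
                and d.get(c.alt_allele, 0) >= min_allele_depth):
            het = True
    return het


def _flank_clearance(c: SnpCandidate, length: int, splice: SpliceModel | None,
                     neighbours: list[int]) -> float:
    """Smallest distance to an end, junction or neighbouring polymorphism."""
    dists = [c.pos - 1, length - c.pos]
    if splice is not None:
        dists += [abs(c.pos - j) for j in splice.junctions]
    dists += [abs(c.pos - p) for p in neighbours if p != c.pos]
    return min(dists)


def apply_filters(
    candidates: list[SnpCandidate],
    splice: dict[str, SpliceModel],
    unigene_lengths: dict[str, int],
    design_scores: dict[str, float] | None,
    config: FilterConfig | None = None,
    inbred_polymorphic: set[str] | None = None,
    min_allele_depth: int = 2,
) -> list[PanelRecord]:
    """Evaluate the selection cascade on every candidate.

    ``inbred_polymorphic`` lists unigenes whose inbred-genotype reads are
    biallelic anywhere (see
    :func:`grasspanel.discovery.inbred_polymorphic_unigenes`); all their
    candidates fail as ``assembly_or_flank``. ``design_scores`` maps marker
    ids to externally computed scores; when ``None`` the score filter is
    skipped (and logged).
    """
    config = config or FilterConfig()
    config.validate()
    inbred_polymorphic = inbred_polymorphic or set()
    if design_scores is None:
        logger.info("no design scores supplied; design-score filter skipped")

    by_unigene: dict[str, list[SnpCandidate]] = {}
    for c in candidates:
        if c.unigene_id not in unigene_lengths:
            raise ValueError(f"no length for unigene {c.unigene_id!r}")
        by_unigene.setdefault(c.unigene_id, []).append(c)

    records: list[PanelRecord] = []
    for uid, cands in by_unigene.items():
        length = unigene_lengths[uid]
        model = splice.get(uid)
        # positions of every other polymorphism on the unigene (other
        # candidate SNPs; indel-adjacent candidates stand in for indels)
        poly_positions = [c.pos for c in cands]
        for c in cands:
            dist_end = min(c.pos - 1, length - c.pos)
            dist_junc = min((abs(c.pos - j) for j in (model.junctions if model else [])),
                            default=math.inf)
            near_poly = any(
                p != c.pos and abs(p - c.pos) <= config.poly_window for p in poly_positions
            )
            ok_a = (
                dist_end >= config.min_flank
                and dist_junc >= config.min_flank
                and not near_poly
                and uid not in inbred_polymorphic
            )
            ok_b = model is not None and model.has_significant_hit
            ok_c = _parent_support_ok(c, min_allele_depth)
            if design_scores is None:
                ok_d = True
            else:
                ok_d = design_scores.get(c.marker_id, 0.0) > config.design_score_min
            decisions = {
                "assembly_or_flank": ok_a,
                "no_blast_hit": ok_b,
                "single_parent": ok_c,
                "low_design_score": ok_d,
            }
            fail_category = "none"
            for name in FILTER_NAMES:
                if not decisions[name]:
                    fail_category = name
                    break
            records.append(
                PanelRecord(
                    candidate=c,
                    decisions=decisions,
                    fail_category=fail_category,
                    selected=False,
                )
            )
    return records


def select_panel(
    records: list[PanelRecord],
    config: FilterConfig | None = None,
    splice: dict[str, SpliceModel] | None = None,
    unigene_lengths: dict[str, int] | None = None,
):
    """Select up to ``max_snps_per_unigene`` passing SNPs per unigene.

    Tie-break: maximise the smallest distance to any sequence end, junction
    or neighbouring polymorphism; residual ties go to the smallest
    position. Returns ``(records, AccountingReport)`` with ``selected``
    set on the chosen records. Per-unigene discard categories use the
    furthest-through-the-cascade candidate, so every discarded unigene has
    exactly one category.
    """
    config = config or FilterConfig()
    splice = splice or {}
    by_unigene: dict[str, list[PanelRecord]] = {}
    for r in records:
        r.selected = False
        by_unigene.setdefault(r.candidate.unigene_id, []).append(r)

    discards = {name: 0 for name in FILTER_NAMES}
    remaining = 0
    panel_size = 0
    rank = {name: i for i, name in enumerate(FILTER_NAMES)}
    for uid, recs in by_unigene.items():
        passing = [r for r in recs if r.fail_category == "none"]
        if not passing:
            # the unigene got as far as its best candidate did
            best = max(recs, key=lambda r: rank[r.fail_category])
            discards[best.fail_category] += 1
            continue
        remaining += 1
        length = unigene_lengths.get(uid) if unigene_lengths else None
        model = splice.get(uid)
        neighbours = [r.candidate.pos for r in recs]

        def clearance(r: PanelRecord) -> float:
            if length is None:
                return math.inf
            return _flank_clearance(r.candidate, length, model, neighbours)

        passing.sort(key=lambda r: (-clearance(r), r.candidate.pos))
        for r in passing[: config.max_snps_per_unigene]:
            r.selected = True
            panel_size += 1
    report = AccountingReport(
        input_unigenes=len(by_unigene),
        discards=discards,
        remaining_unigenes=remaining,
        panel_size=panel_size,
    )
    return records, report


def snp_density(n_snps: int, n_unigenes: int, mean_len: float) -> tuple[float, int]:
    """SNP density summaries: (SNPs per unigene, bp per SNP)."""
    if n_unigenes <= 0 or mean_len <= 0:
        raise ValueError("counts and lengths must be positive")
    if n_snps <= 0:
        raise ValueError("bp per SNP is undefined with zero SNPs")
    return n_snps / n_unigenes, int(round(n_unigenes * mean_len / n_snps))


def read_design_scores(path) -> dict[str, float]:
    df = pd.read_csv(path)
    cols = list(df.columns[:2])
    return dict(zip(df[cols[0]].astype(str), df[cols[1]].astype(float)))


def records_to_frame(records: list[PanelRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        c = r.candidate
        rows.append(
            {
                "marker_id": c.marker_id,
                "unigene_id": c.unigene_id,
                "pos": c.pos,
                "ref": c.ref_allele,
                "alt": c.alt_allele,
                "posterior": c.posterior,
                "fail_category": r.fail_category,
                "selected": r.selected,
                **{f"pass_{k}": v for k, v in r.decisions.items()},
            }
        )
    return pd.DataFrame(rows)
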