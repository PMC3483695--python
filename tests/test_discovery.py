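"""SNP caller: posterior model, thresholds, and oracle equivalence."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from grasspanel.discovery import (
    CallerConfig,
    PileupColumn,
    build_pileups,
    call_snps,
    genotype_posterior,
    inbred_polymorphic_unigenes,
    pileups_from_reads,
    read_vcf,
    write_vcf,
)
from grasspanel.simulate import write_pileup_tsv, write_sam


def _column(obs):
    return PileupColumn("U1", 10, observations=list(obs))


def _oracle_posterior(bases, quals, ref, alt):
    """Independent closed-form three-genotype Bayes computation."""
    lik = [1.0, 1.0, 1.0]
    for b, q in zip(bases, quals):
        e = min(10 ** (-q / 10), 0.75)
        p_ref = [1 - e, 0.5 * (1 - e) + 0.5 * e / 3, e / 3]
        p_alt = [e / 3, 0.5 * (1 - e) + 0.5 * e / 3, 1 - e]
        if b == ref:
            lik = [l * p for l, p in zip(lik, p_ref)]
        elif b == alt:
            lik = [l * p for l, p in zip(lik, p_alt)]
    return lik[1] / sum(lik)


class TestGenotypePosterior:
    def test_balanced_evidence_is_confident_het(self):
        col = _column([("parent1", "A", 30)] * 2 + [("parent1", "G", 30)] * 2)
        post = genotype_posterior(col, ("A", "G"))
        assert post > 0.999
        assert post == pytest.approx(_oracle_posterior("AAGG", [30] * 4, "A", "G"))

    def test_monomorphic_evidence_disfavours_het(self):
        # at four reads the het hypothesis retains a few percent posterior;
        # the value matches the independent closed form and stays below the
        # 0.5 calling threshold
        col = _column([("parent1", "A", 30)] * 4)
        post = genotype_posterior(col, ("A", "G"))
        oracle = _oracle_posterior("AAAA", [30] * 4, "A", "G")
        assert post == pytest.approx(oracle)
        assert post < 0.5

    def test_quality_zero_reduces_to_prior(self):
        col = _column([("parent1", "A", 0)] * 6)
        assert genotype_posterior(col, ("A", "G")) == pytest.approx(1 / 3)

    def test_empty_column_rejected(self):
        with pytest.raises(ValueError):
            genotype_posterior(_column([]), ("A", "G"))

    @given(
        n_ref=st.integers(0, 8),
        n_alt=st.integers(0, 8),
        q=st.integers(5, 40),
    )
    def test_matches_independent_oracle(self, n_ref, n_alt, q):
        if n_ref + n_alt == 0:
            return
        col = _column(
            [("parent1", "A", q)] * n_ref + [("parent2", "G", q)] * n_alt
        )
        post = genotype_posterior(col, ("A", "G"))
        oracle = _oracle_posterior("A" * n_ref + "G" * n_alt, [q] * (n_ref + n_alt), "A", "G")
        assert post == pytest.approx(oracle, rel=1e-9)


class TestCallThresholds:
    def test_three_reads_insufficient(self):
        col = _column([("parent1", "A", 30), ("parent1", "G", 30), ("parent2", "G", 30)])
        assert call_snps([col]) == []

    def test_weak_alt_support_insufficient(self):
        col = _column([("parent1", "A", 30)] * 4 + [("parent2", "G", 30)])
        assert call_snps([col]) == []

    def test_minimal_qualifying_column_called(self):
        col = _column([("parent1", "A", 30)] * 2 + [("parent2", "G", 30)] * 2)
        (cand,) = call_snps([col])
        assert {cand.ref_allele, cand.alt_allele} == {"A", "G"}
        assert cand.posterior > 0.999

    def test_low_quality_bases_excluded_at_pileup(self):
        from grasspanel.simulate import SimRead

        reads = [
            SimRead("r1", "parent1", "U1", 10, "A", "?"),  # Q30
            SimRead("r2", "parent1", "U1", 10, "A", "?"),
            SimRead("r3", "parent2", "U1", 10, "G", "&"),  # Q5, dropped
        ]
        cols = pileups_from_reads(reads, min_base_quality=10)
        assert cols[0].depth == 2

    def test_multiallelic_flagged(self):
        col = _column(
            [("parent1", "A", 30)] * 3
            + [("parent2", "G", 30)] * 2
            + [("inbred", "T", 30)] * 2
        )
        (cand,) = call_snps([col])
        assert "multiallelic" in cand.flags

    @pytest.mark.parametrize("param", ["min_total_depth", "min_posterior"])
    def test_raising_thresholds_never_adds_candidates(self, clean_sim, param):
        _, unigenes, _, reads = clean_sim
        cols = pileups_from_reads(reads)
        loose = call_snps(cols, CallerConfig(), unigenes)
        values = {"min_total_depth": 8, "min_posterior": 0.95}
        strict = call_snps(
            cols, CallerConfig(**{param: values[param]}), unigenes
        )
        loose_keys = {(c.unigene_id, c.pos) for c in loose}
        strict_keys = {(c.unigene_id, c.pos) for c in strict}
        assert strict_keys <= loose_keys


def _brute_force_calls(reads, unigenes, cfg: CallerConfig):
    """Exhaustive per-position re-implementation used as oracle."""
    found = set()
    by_pos = {}
    for r in reads:
        for i, base in enumerate(r.seq):
            q = ord(r.qual[i]) - 33
            if q < cfg.min_base_quality:
                continue
            by_pos.setdefault((r.unigene_id, r.start + i), []).append((base, q))
    for (uid, pos), obs in by_pos.items():
        if len(obs) < cfg.min_total_depth:
            continue
        counts = {}
        for b, _ in obs:
            counts[b] = counts.get(b, 0) + 1
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        if len(ranked) < 2 or ranked[1][1] < cfg.min_allele_depth:
            continue
        a1, a2 = ranked[0][0], ranked[1][0]
        post = _oracle_posterior(
            [b for b, _ in obs], [q for _, q in obs], a1, a2
        )
        if post >= cfg.min_posterior:
            found.add((uid, pos))
    return found


def test_caller_matches_brute_force_and_truth(clean_sim):
    """On clean data the called set equals both the brute-force oracle and
    the planted truth restricted to qualifying coverage."""
    cfg_sim, unigenes, truth, reads = clean_sim
    caller_cfg = CallerConfig()
    cols = pileups_from_reads(reads, caller_cfg.min_base_quality)
    called = {(c.unigene_id, c.pos) for c in call_snps(cols, caller_cfg, unigenes)}
    brute = _brute_force_calls(reads, unigenes, caller_cfg)
    assert called == brute
    # truth oracle: planted SNPs with enough qualifying coverage per allele
    depth_ok = set()
    for col in cols:
        counts = col.base_counts()
        ranked = sorted(counts.values(), reverse=True)
        if col.depth >= 4 and len(ranked) >= 2 and ranked[1] >= 2:
            depth_ok.add((col.unigene_id, col.pos))
    planted = {(uid, s.pos) for uid, snps in truth.snps.items() for s in snps}
    assert called == (planted & depth_ok)
    # nothing called off the planted set on error-free, paralog-free data
    assert called <= planted


def test_sam_tsv_and_memory_pileups_agree(tmp_path, clean_sim):
    _, unigenes, _, reads = clean_sim
    subset = reads[:120]
    sam = tmp_path / "r.sam"
    tsv = tmp_path / "r.tsv"
    write_sam(subset, unigenes, sam)
    write_pileup_tsv(subset, tsv)

    def key(cols):
        return {
            (c.unigene_id, c.pos): sorted(c.observations) for c in cols if c.observations
        }

    mem = key(build_pileups(subset, unigenes))
    assert key(build_pileups(str(sam), unigenes)) == mem
    assert key(build_pileups(str(tsv), unigenes)) == mem


def test_unknown_reference_rejected(tmp_path):
    tsv = tmp_path / "r.tsv"
    tsv.write_text("UGX\t5\tparent1\tA:30\n")
    with pytest.raises(ValueError):
        build_pileups(str(tsv), {"U1": "ACGT"})


def test_vcf_round_trip(tmp_path, clean_sim):
    _, unigenes, _, reads = clean_sim
    cands = call_snps(pileups_from_reads(reads), CallerConfig(), unigenes)
    path = tmp_path / "c.vcf"
    write_vcf(cands, unigenes, path)
    back = read_vcf(path)
    assert [(c.unigene_id, c.pos, c.ref_allele, c.alt_allele) for c in back] == [
        (c.unigene_id, c.pos, c.ref_allele, c.alt_allele) for c in cands
    ]
    for a, b in zip(back, cands):
        assert a.posterior == pytest.approx(b.posterior, abs=1e-4)
        for tag in ("parent1", "parent2", "inbred"):
            assert a.allele_depth(tag) == b.allele_depth(tag)


def test_inbred_polymorphism_screen():
    cols = [
        PileupColumn("U1", 5, [("inbred", "A", 30)] * 3 + [("inbred", "G", 30)] * 2),
        PileupColumn("U2", 5, [("inbred", "A", 30)] * 5 + [("inbred", "G", 30)]),
        PileupColumn("U3", 5, [("parent1", "A", 30)] * 3 + [("parent1", "G", 30)] * 3),
    ]
    assert inbred_polymorphic_unigenes(cols) == {"U1"}
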