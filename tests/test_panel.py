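"""Selection cascade, BLAST-based splice inference, and panel accounting."""

import numpy as np
import pytest

from grasspanel.discovery import SnpCandidate
from grasspanel.panel import (
    FilterConfig,
    apply_filters,
    parse_blast_tabular,
    select_panel,
    snp_density,
)

BLAST_ROW = "{q}\t{s}\t98.0\t{ln}\t2\t0\t{qs}\t{qe}\t100\t500\t{ev}\t{bs}\n"


def _cand(uid="U1", pos=200, counts=None, posterior=0.999):
    counts = counts or {
        "parent1": {"A": 5, "G": 5},
        "parent2": {"A": 8, "G": 0},
        "inbred": {"A": 9, "G": 0},
    }
    return SnpCandidate(uid, pos, "A", "G", counts, posterior)


class TestBlastParsing:
    def test_single_full_length_hit_has_no_junctions(self, tmp_path):
        f = tmp_path / "b.tsv"
        f.write_text(BLAST_ROW.format(q="U1", s="chr1", ln=889, qs=1, qe=889,
                                      ev="1e-50", bs=900))
        models = parse_blast_tabular(f)
        assert models["U1"].has_significant_hit
        assert models["U1"].junctions == []

    def test_two_blocks_yield_interior_boundary(self, tmp_path):
        f = tmp_path / "b.tsv"
        f.write_text(
            BLAST_ROW.format(q="U1", s="chr1", ln=300, qs=1, qe=300, ev="1e-50", bs=500)
            + BLAST_ROW.format(q="U1", s="chr1", ln=400, qs=301, qe=700, ev="1e-40", bs=400)
        )
        assert parse_blast_tabular(f)["U1"].junctions == [300]

    def test_weak_evalue_means_no_significant_hit(self, tmp_path):
        f = tmp_path / "b.tsv"
        f.write_text(BLAST_ROW.format(q="U1", s="chr1", ln=200, qs=1, qe=200,
                                      ev="1e-5", bs=100))
        model = parse_blast_tabular(f)["U1"]
        assert not model.has_significant_hit
        assert model.junctions == []

    def test_overlapping_blocks_merge(self, tmp_path):
        f = tmp_path / "b.tsv"
        f.write_text(
            BLAST_ROW.format(q="U1", s="chr1", ln=300, qs=1, qe=300, ev="1e-50", bs=500)
            + BLAST_ROW.format(q="U1", s="chr1", ln=300, qs=250, qe=550, ev="1e-45", bs=450)
        )
        assert parse_blast_tabular(f)["U1"].junctions == []

    def test_malformed_line_raises(self, tmp_path):
        f = tmp_path / "b.tsv"
        f.write_text("U1\tchr1\tnot-a-number\n")
        with pytest.raises(ValueError):
            parse_blast_tabular(f)


class TestFilterCascade:
    LENGTHS = {"U1": 500}

    def _run(self, cands, splice=None, scores=None, inbred_poly=None, **kw):
        from grasspanel.panel import SpliceModel

        splice = splice if splice is not None else {
            "U1": SpliceModel("U1", True, 1e-50)
        }
        return apply_filters(
            cands, splice, self.LENGTHS, scores,
            FilterConfig(**kw), inbred_poly or set(),
        )

    def test_snp_near_sequence_end_fails_flank(self):
        (rec,) = self._run([_cand(pos=25)])
        assert rec.fail_category == "assembly_or_flank"

    def test_junction_proximity_fails_flank(self):
        from grasspanel.panel import SpliceModel

        splice = {"U1": SpliceModel("U1", True, 1e-50, junctions=[210])}
        (rec,) = self._run([_cand(pos=200)], splice=splice)
        assert rec.fail_category == "assembly_or_flank"

    def test_neighbouring_polymorphism_fails_flank(self):
        recs = self._run([_cand(pos=200), _cand(pos=215)])
        assert all(r.fail_category == "assembly_or_flank" for r in recs)

    def test_inbred_polymorphic_unigene_fails_all_candidates(self):
        (rec,) = self._run([_cand()], inbred_poly={"U1"})
        assert rec.fail_category == "assembly_or_flank"

    def test_missing_blast_hit_category(self):
        (rec,) = self._run([_cand()], splice={})
        assert rec.fail_category == "no_blast_hit"

    def test_single_parent_category(self):
        counts = {
            "parent1": {"A": 5, "G": 5},
            "parent2": {"A": 0, "G": 0},
            "inbred": {"A": 9, "G": 0},
        }
        (rec,) = self._run([_cand(counts=counts)])
        assert rec.fail_category == "single_parent"

    def test_design_score_cutoff(self):
        (rec,) = self._run([_cand()], scores={"U1.S200": 0.55})
        assert rec.fail_category == "low_design_score"
        (rec,) = self._run([_cand()], scores={"U1.S200": 0.85})
        assert rec.fail_category == "none"

    def test_passing_candidate(self):
        (rec,) = self._run([_cand()])
        assert rec.fail_category == "none"
        assert all(rec.decisions.values())

    def test_each_failing_record_has_one_category(self):
        recs = self._run([_cand(pos=25)], splice={})  # fails (a) and (b)
        assert recs[0].fail_category == "assembly_or_flank"

    def test_filters_are_idempotent(self):
        recs1 = self._run([_cand(), _cand(pos=400)])
        recs2 = self._run([r.candidate for r in recs1])
        assert [(r.candidate.pos, r.fail_category, r.decisions) for r in recs1] == [
            (r.candidate.pos, r.fail_category, r.decisions) for r in recs2
        ]

    def test_unknown_unigene_raises(self):
        with pytest.raises(ValueError):
            self._run([_cand(uid="UX")])


class TestSelection:
    def test_no_passing_candidates_selects_none(self):
        recs = TestFilterCascade()._run([_cand(pos=25)])
        recs, report = select_panel(recs)
        assert report.panel_size == 0
        assert report.discards["assembly_or_flank"] == 1

    def test_tiebreak_prefers_central_snp(self):
        from grasspanel.panel import SpliceModel

        lengths = {"U1": 900}
        splice = {"U1": SpliceModel("U1", True, 1e-50)}
        cands = [_cand(pos=100), _cand(pos=450)]
        recs = apply_filters(cands, splice, lengths, None, FilterConfig())
        recs, report = select_panel(recs, FilterConfig(), splice, lengths)
        selected = [r.candidate.pos for r in recs if r.selected]
        assert selected == [450]
        assert report.panel_size == 1

    def test_accounting_conserves_counts(self):
        from grasspanel.panel import SpliceModel

        lengths = {f"U{i}": 500 for i in range(1, 6)}
        splice = {f"U{i}": SpliceModel(f"U{i}", True, 1e-50) for i in range(1, 6)}
        cands = [_cand(uid=f"U{i}", pos=250) for i in range(1, 4)] + [
            _cand(uid="U4", pos=10),  # flank fail
            _cand(uid="U5", pos=250, counts={
                "parent1": {"A": 5, "G": 5},
                "parent2": {"A": 0, "G": 0},
                "inbred": {"A": 9, "G": 0},
            }),  # single parent
        ]
        recs = apply_filters(cands, splice, lengths, None, FilterConfig())
        recs, report = select_panel(recs, FilterConfig(), splice, lengths)
        assert report.input_unigenes == 5
        assert report.input_unigenes - sum(report.discards.values()) == report.remaining_unigenes
        assert report.remaining_unigenes == 3
        assert report.panel_size == 3


class TestSnpDensity:
    def test_study_scale_arithmetic(self):
        per_unigene, bp_per_snp = snp_density(15_433, 1_778, 889)
        assert bp_per_snp == 102
        assert round(per_unigene) == 9

    @pytest.mark.parametrize(
        "n_snps,n_unigenes,mean_len,expected",
        [(1, 1, 100, (1.0, 100)), (200, 100, 500, (2.0, 250))],
    )
    def test_direct_arithmetic(self, n_snps, n_unigenes, mean_len, expected):
        assert snp_density(n_snps, n_unigenes, mean_len) == expected

    def test_zero_snps_signalled(self):
        with pytest.raises(ValueError):
            snp_density(0, 10, 100)


def test_paralog_screen_end_to_end():
    """Unigenes carrying a diverged duplicate are discarded via the
    inbred-polymorphism criterion with high sensitivity."""
    from grasspanel.discovery import (
        CallerConfig,
        call_snps,
        inbred_polymorphic_unigenes,
        pileups_from_reads,
    )
    from grasspanel.simulate import SimConfig, simulate_reads, simulate_reference

    cfg = SimConfig(
        n_unigenes=40, mean_unigene_len=500, depth=12, paralog_fraction=0.3,
        paralog_divergence=0.02, inbred_residual_het=0.015, base_error=0.001,
        seed=97,
    )
    unigenes, truth = simulate_reference(cfg)
    reads = simulate_reads(unigenes, truth, cfg)
    cols = pileups_from_reads(reads)
    flagged = inbred_polymorphic_unigenes(cols)
    paralogs = {u for u, f in truth.paralog_flags.items() if f}
    assert paralogs, "fixture must plant paralogs"
    sensitivity = len(flagged & paralogs) / len(paralogs)
    assert sensitivity >= 0.95
    false_rate = len(flagged - paralogs) / (len(unigenes) - len(paralogs))
    # false discards stem from residual inbred heterozygosity:
    # ~1.5% of planted SNP sites per unigene (~5 SNPs each)
    assert false_rate <= 0.25
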