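"""Truth-recovery experiments on synthetic data.

Each function simulates a data set under the study conditions the package
emulates, runs the corresponding pipeline stage, and measures how well the
planted ground truth is recovered. They are used both by the test suite
and by the reproduction script, so the numbers those report are always
computed the same way.

Problem sizes are scaled to what the recovery questions need: 50 unigenes
for exact caller equivalence, 40-unigene replicates for the paralog
screen, 100 markers x 192 samples for cluster recovery, and a 7-group,
184-individual CP population with 12 fully informative markers per group
at 4 cM spacing for map recovery. Two-point data cannot order markers
heterozygous in different parents relative to each other, and 184
individuals resolve adjacent intervals of a few cM, which is why the map
experiment uses hkxhk markers on a 4 cM grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import discovery, genotyping, linkage
from .simulate import (
    SimConfig,
    simulate_cp_genotypes,
    simulate_map_truth,
    simulate_reads,
    simulate_reference,
    perturb_genotypes,
)


def _submix(seed: int, salt: int) -> int:
    # keep derived seeds well below 2**31
    return (seed * 1_000_003 + salt) % 2_000_000_011


# ---------------------------------------------------------------------------
# caller equivalence


def caller_oracle_check(seed: int, n_unigenes: int = 50) -> dict:
    """Error-free, paralog-free data: the caller must equal both a
    brute-force per-position reimplementation and the planted truth
    restricted to qualifying coverage."""
    cfg = SimConfig(
        n_unigenes=n_unigenes,
        mean_unigene_len=500,
        depth=20,
        base_error=0.0,
        paralog_fraction=0.0,
        inbred_residual_het=0.0,
        seed=_submix(seed, 1),
    )
    unigenes, truth = simulate_reference(cfg)
    reads = simulate_reads(unigenes, truth, cfg)
    caller_cfg = discovery.CallerConfig()
    cols = discovery.pileups_from_reads(reads, caller_cfg.min_base_quality)
    called = {
        (c.unigene_id, c.pos)
        for c in discovery.call_snps(cols, caller_cfg, unigenes)
    }
    planted = {(uid, s.pos) for uid, snps in truth.snps.items() for s in snps}

    def oracle_posterior(obs, a1, a2):
        # independent flat-prior three-genotype computation
        lik = [1.0, 1.0, 1.0]
        for _, base, q in obs:
            e = min(10.0 ** (-q / 10.0), 0.75)
            if base == a1:
                p = (1 - e, 0.5 * (1 - e) + 0.5 * e / 3, e / 3)
            elif base == a2:
                p = (e / 3, 0.5 * (1 - e) + 0.5 * e / 3, 1 - e)
            else:
                continue
            lik = [l * x for l, x in zip(lik, p)]
        return lik[1] / sum(lik)

    qualified = set()
    for col in cols:
        ranked = sorted(
            col.base_counts().items(), key=lambda kv: (-kv[1], kv[0])
        )
        if col.depth < caller_cfg.min_total_depth or len(ranked) < 2:
            continue
        if ranked[1][1] < caller_cfg.min_allele_depth:
            continue
        post = oracle_posterior(col.observations, ranked[0][0], ranked[1][0])
        if post >= caller_cfg.min_posterior:
            qualified.add((col.unigene_id, col.pos))
    expected = planted & qualified
    union = called | expected
    agreement = 100.0 * len(called & expected) / len(union) if union else 100.0
    return {
        "n_called": len(called),
        "n_expected": len(expected),
        "exact_match": called == expected,
        "agreement_pct": agreement,
        "false_positives": len(called - planted),
    }


# ---------------------------------------------------------------------------
# paralog screen


def paralog_recovery(seed: int, n_seeds: int = 20) -> dict:
    """Sensitivity of the inbred-polymorphism screen for planted paralogs
    (inbred read depth >= 10, copy divergence 2 %), pooled over replicate
    simulations, with the false-discard rate on clean unigenes."""
    tp = fn = fp = tn = 0
    for k in range(n_seeds):
        cfg = SimConfig(
            n_unigenes=40,
            mean_unigene_len=500,
            depth=12,
            paralog_fraction=0.3,
            paralog_divergence=0.02,
            inbred_residual_het=0.015,
            base_error=0.001,
            seed=_submix(seed, 100 + k),
        )
        unigenes, truth = simulate_reference(cfg)
        reads = simulate_reads(unigenes, truth, cfg)
        cols = discovery.pileups_from_reads(reads)
        flagged = discovery.inbred_polymorphic_unigenes(cols)
        paralogs = {u for u, f in truth.paralog_flags.items() if f}
        tp += len(flagged & paralogs)
        fn += len(paralogs - flagged)
        fp += len(flagged - paralogs)
        tn += len(set(unigenes) - paralogs - flagged)
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "false_discard_rate": fp / (fp + tn) if fp + tn else float("nan"),
        "n_paralogs": tp + fn,
    }


# ---------------------------------------------------------------------------
# cluster recovery


def cluster_recovery(seed: int, n_markers: int = 100, n_samples: int = 192) -> dict:
    """Gaussian-mixture recovery of theta cluster means on clean clouds,
    plus duplicate-call concordance.

    A cluster mean is counted as recovered when it lies within three
    posterior standard errors (fitted sd / sqrt(cluster n)) of its true
    centre; with hundreds of clusters a ~0.3 % exceedance rate is the
    expected behaviour of a well-calibrated fit.
    """
    rng = np.random.default_rng(_submix(seed, 2))
    centers = np.array([0.1, 0.5, 0.9])
    sd = 0.015
    within = total = 0
    max_err = 0.0
    concordances = []
    for m in range(n_markers):
        truth = rng.integers(0, 3, n_samples)
        thetas = np.clip(rng.normal(centers[truth], sd), 0, 1)
        model = genotyping.fit_marker(thetas, np.full(n_samples, 3000.0),
                                      marker_id=f"M{m}")
        if model.k != 3:
            continue
        counts = np.bincount(truth, minlength=3)
        for c in range(3):
            se = max(model.sds[c], 1e-4) / math.sqrt(max(counts[c], 1))
            err = abs(model.means[c] - centers[c])
            max_err = max(max_err, err)
            within += err <= 3 * se
            total += 1
        # duplicated samples: identical thetas must give identical calls
        dup_thetas = np.concatenate([thetas, thetas[:4]])
        ids = [f"S{i}" for i in range(n_samples)] + [f"S{i}_dup" for i in range(4)]
        _, conc = genotyping.call_genotypes(
            model, dup_thetas, ids,
            duplicates=[(f"S{i}", f"S{i}_dup") for i in range(4)],
        )
        if conc is not None:
            concordances.append(conc)
    return {
        "n_clusters": total,
        "fraction_within_3se": within / total if total else float("nan"),
        "max_mean_error": max_err,
        "duplicate_concordance": float(np.mean(concordances)),
    }


# ---------------------------------------------------------------------------
# linkage recovery


@dataclass
class MapRecovery:
    grouping_exact: bool
    n_groups_found: int
    orders_correct: int
    n_groups_truth: int
    position_rms_cM: float
    n_unmapped: int


def linkage_recovery(
    seed: int,
    n_groups: int = 7,
    markers_per_group: int = 12,
    spacing_cM: float = 4.0,
    pop_size: int = 184,
) -> MapRecovery:
    """Recover a CP map from simulated genotypes and score it against
    truth: grouping partition, within-group order (up to reversal), and
    position RMS after aligning each group by shift and orientation."""
    rng = np.random.default_rng(_submix(seed, 3))
    cfg = SimConfig(
        pop_size=pop_size,
        n_groups=n_groups,
        group_len_cM=(markers_per_group - 1) * spacing_cM,
        fail_fraction=0.0,
        monomorph_fraction=0.0,
        seg_type_probs=(0.0, 0.0, 1.0),
        seed=_submix(seed, 4),
    )
    mids = [f"M{i:03d}" for i in range(n_groups * markers_per_group)]
    markers = simulate_map_truth(mids, cfg, rng, spacing_cM=spacing_cM)
    true_geno = simulate_cp_genotypes(markers, cfg, rng)
    observed = perturb_genotypes(true_geno, cfg, rng)
    segs = linkage.classify_all(observed)
    gmap = linkage.build_map(segs, n_groups=n_groups)

    truth_groups: dict[int, set] = {}
    truth_pos = {m.marker_id: m.cM for m in markers}
    for m in markers:
        truth_groups.setdefault(m.group, set()).add(m.marker_id)
    found = [set(ms) for _, ms, _ in gmap.groups]
    grouping_exact = sorted(map(sorted, truth_groups.values())) == sorted(
        map(sorted, found)
    )
    orders_correct = 0
    errors: list[float] = []
    for _, ms, pos in gmap.groups:
        t = np.array([truth_pos[m] for m in ms], float)
        if np.all(np.diff(t) >= 0) or np.all(np.diff(t) <= 0):
            orders_correct += 1
        if t[0] > t[-1]:
            t = t.max() - t
        t -= t.min()
        e = np.asarray(pos) - t
        errors.extend((e - e.mean()).tolist())
    return MapRecovery(
        grouping_exact=grouping_exact,
        n_groups_found=len(gmap.groups),
        orders_correct=orders_correct,
        n_groups_truth=len(truth_groups),
        position_rms_cM=float(np.sqrt(np.mean(np.square(errors)))),
        n_unmapped=len(gmap.unmapped),
    )


def rf_recovery(seed: int, rf_true: float = 0.2, pop_size: int = 10_000) -> dict:
    """ML recovery of a planted recombination fraction from a large
    two-marker CP population; the tolerance scale is the binomial SE."""
    from .simulate import MarkerTruth

    rng = np.random.default_rng(_submix(seed, 5))
    d = linkage.haldane_cM(rf_true)
    cfg = SimConfig(
        pop_size=pop_size,
        n_groups=1,
        group_len_cM=d,
        missing_rate=0.0,
        geno_error_rate=0.0,
        fail_fraction=0.0,
        monomorph_fraction=0.0,
        seed=_submix(seed, 6),
    )
    markers = [
        MarkerTruth("A", 0, 0.0, "p1het", "segregating"),
        MarkerTruth("B", 0, d, "p1het", "segregating"),
    ]
    geno = simulate_cp_genotypes(markers, cfg, rng)
    segs = linkage.classify_all(geno)
    link = linkage.pairwise_linkage(segs["A"], segs["B"])
    se = math.sqrt(rf_true * (1 - rf_true) / pop_size)
    return {
        "rf_estimate": link.rf,
        "rf_true": rf_true,
        "binomial_se": se,
        "within_3se": abs(link.rf - rf_true) < 3 * se,
    }
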