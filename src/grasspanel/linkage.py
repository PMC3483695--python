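"""Two-point linkage analysis and map construction for CP populations.

A CP (pseudo-testcross) population descends from two outbred, heterozygous
parents; every marker segregates according to which parents are
heterozygous:

* ``lmxll`` — first parent heterozygous, offspring ``lm``/``ll`` (1:1);
* ``nnxnp`` — second parent heterozygous, offspring ``nn``/``np`` (1:1);
* ``hkxhk`` — both heterozygous, offspring ``hh``/``hk``/``kk`` (1:2:1).

Marker pairs are scored with two statistics. The independence LOD,
``G^2 / (2 ln 10)`` on the joint genotype-class contingency table, drives
linkage-group formation (single-linkage components above a LOD threshold,
with optional per-group elevated re-split thresholds). The recombination
fraction is estimated by maximum likelihood under an explicit gamete
transmission model, maximising over the admissible parental phase
configurations; the linkage LOD is ``log10 L(rf) - log10 L(0.5)``.

Within a group, ordering approximates regression mapping: markers are
inserted greedily starting from the strongest pair, each at the position
minimising the LOD-weighted squared disagreement between map-implied and
observed Haldane distances, then polished by 2-opt segment reversals.
Positions come from LOD-weighted least squares over all informative pairs
(rf <= 0.40, LOD >= 1.00), anchored at the first marker. Map distances use
the Haldane function ``d = -50 ln(1 - 2 rf)`` (cM), consistent with the
no-interference crossover model.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import chisquare

logger = logging.getLogger(__name__)

MISSING = "--"

SEG_CODES = {
    "lmxll": ("ll", "lm"),
    "nnxnp": ("nn", "np"),
    "hkxhk": ("hh", "hk", "kk"),
}
SEG_RATIOS = {
    "lmxll": (1, 1),
    "nnxnp": (1, 1),
    "hkxhk": (1, 2, 1),
}
_HET = {"lmxll": (True, False), "nnxnp": (False, True), "hkxhk": (True, True)}


@dataclass
class MarkerSegregation:
    marker_id: str
    seg_type: str  # lmxll | nnxnp | hkxhk | uninformative
    codes: list[str]  # per individual, in input order; MISSING allowed
    chi2: float = float("nan")
    df: int = 0
    n_impossible: int = 0

    def counts(self) -> dict[str, int]:
        out = {c: 0 for c in SEG_CODES.get(self.seg_type, ())}
        for c in self.codes:
            if c != MISSING:
                out[c] += 1
        return out


@dataclass
class PairwiseLinkage:
    marker_a: str
    marker_b: str
    rf: float
    lod: float
    ind_lod: float
    phase: tuple[bool, bool] | None  # per-parent repulsion flags; None if uninformative
    n: int


@dataclass
class GeneticMap:
    groups: list[tuple[str, list[str], list[float]]]  # (group_id, markers, cM)
    unmapped: list[str] = field(default_factory=list)

    def all_markers(self) -> list[str]:
        out = []
        for _, ms, _ in self.groups:
            out.extend(ms)
        return out + list(self.unmapped)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"marker_id": m, "group": gid, "position_cM": p}
            for gid, ms, ps in self.groups
            for m, p in zip(ms, ps)
        ]
        return pd.DataFrame(rows, columns=["marker_id", "group", "position_cM"])


# ---------------------------------------------------------------------------
# segregation typing and distortion


def classify_segregation(
    marker_id: str,
    parent_calls: tuple[str, str],
    offspring_calls,
) -> MarkerSegregation:
    """Derive the CP segregation type and recode offspring.

    Parent calls are biallelic genotypes 'AA'/'AB'/'BB'. het x hom gives
    ``lmxll`` (first parent het) or ``nnxnp``; het x het gives ``hkxhk``;
    hom x hom is uninformative. Offspring calls impossible under the cross
    (e.g. 'BB' from AB x AA) become missing and are counted.
    """
    p1, p2 = parent_calls
    for p in (p1, p2):
        if p not in ("AA", "AB", "BB"):
            raise ValueError(f"parent call {p!r} missing or invalid for {marker_id}")
    het1, het2 = p1 == "AB", p2 == "AB"
    if het1 and het2:
        seg = "hkxhk"
        recode = {"AA": "hh", "AB": "hk", "BB": "kk"}
    elif het1 or het2:
        seg = "lmxll" if het1 else "nnxnp"
        hom = p2 if het1 else p1
        het_code, hom_code = ("lm", "ll") if het1 else ("np", "nn")
        # offspring are het or hom-like-the-homozygous-parent
        recode = {"AB": het_code, hom: hom_code}
    else:
        seg = "uninformative"
        recode = {}
    codes, n_imp = [], 0
    for c in offspring_calls:
        if c == MISSING or seg == "uninformative":
            codes.append(MISSING)
            continue
        if c in recode:
            codes.append(recode[c])
        else:
            codes.append(MISSING)
            n_imp += 1
    seg_obj = MarkerSegregation(marker_id, seg, codes, n_impossible=n_imp)
    if seg != "uninformative":
        seg_obj.chi2, seg_obj.df = distortion_test(seg_obj)
    return seg_obj


def distortion_test(seg: MarkerSegregation) -> tuple[float, int]:
    """Chi-square against the Mendelian ratio (1:1 or 1:2:1)."""
    if seg.seg_type not in SEG_RATIOS:
        raise ValueError(f"no distortion test for {seg.seg_type} markers")
    counts = seg.counts()
    obs = np.array([counts[c] for c in SEG_CODES[seg.seg_type]], dtype=float)
    n = obs.sum()
    if n == 0:
        raise ValueError("all calls missing; distortion test undefined")
    ratio = np.array(SEG_RATIOS[seg.seg_type], dtype=float)
    stat, _ = chisquare(obs, f_exp=n * ratio / ratio.sum())
    return float(stat), len(obs) - 1


# ---------------------------------------------------------------------------
# two-point statistics


def _g2(table: np.ndarray) -> float:
    """Likelihood-ratio statistic of independence; empty rows/cols dropped."""
    t = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if t.size == 0 or min(t.shape) < 2:
        return 0.0
    n = t.sum()
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(t > 0, t * np.log(t / expected), 0.0)
    return float(2.0 * terms.sum())


def _code_fn(seg_type: str):
    if seg_type == "lmxll":
        return lambda s1, s2: "lm" if s1 else "ll"
    if seg_type == "nnxnp":
        return lambda s1, s2: "np" if s2 else "nn"
    if seg_type == "hkxhk":
        return lambda s1, s2: ("hh", "hk", "kk")[s1 + s2]
    raise ValueError(seg_type)


def _joint_class_probs(
    type_a: str, type_b: str, r: float, swap: tuple[bool, bool]
) -> dict[tuple[str, str], float]:
    """P(code_a, code_b) under the CP gamete transmission model.

    ``swap[p]`` flips parent p's phase between the two markers (repulsion);
    a parent heterozygous at only one marker transmits independently.
    """
    het_a, het_b = _HET[type_a], _HET[type_b]
    code_a, code_b = _code_fn(type_a), _code_fn(type_b)
    probs: dict[tuple[str, str], float] = {}
    for sa1, sb1, sa2, sb2 in itertools.product((0, 1), repeat=4):
        p = 1.0
        for parent, (sa, sb) in enumerate(((sa1, sb1), (sa2, sb2))):
            if het_a[parent] and het_b[parent]:
                same = sa == (sb ^ int(swap[parent]))
                p *= 0.5 * ((1.0 - r) if same else r)
            else:
                p *= 0.25
        key = (code_a(sa1, sa2), code_b(sb1, sb2))
        probs[key] = probs.get(key, 0.0) + p
    return probs


def pairwise_linkage(
    a: MarkerSegregation, b: MarkerSegregation, min_shared: int = 20
) -> PairwiseLinkage:
    """Two-point linkage between two informative markers.

    Requires >= ``min_shared`` individuals scored at both markers. The
    independence LOD comes from the G^2 statistic of the joint class
    table. rf is the ML estimate under the transmission model, maximised
    over admissible phases; pairs with no parent heterozygous at both
    markers carry no two-point information and return rf 0.5, LOD 0.
    """
    if a.seg_type not in _HET or b.seg_type not in _HET:
        raise ValueError("both markers must be informative")
    pairs = [
        (ca, cb) for ca, cb in zip(a.codes, b.codes) if ca != MISSING and cb != MISSING
    ]
    n = len(pairs)
    if n < min_shared:
        raise ValueError(f"only {n} shared individuals (< {min_shared})")
    classes_a, classes_b = SEG_CODES[a.seg_type], SEG_CODES[b.seg_type]
    table = np.zeros((len(classes_a), len(classes_b)))
    ia = {c: i for i, c in enumerate(classes_a)}
    ib = {c: i for i, c in enumerate(classes_b)}
    for ca, cb in pairs:
        table[ia[ca], ib[cb]] += 1
    ind_lod = max(_g2(table) / (2.0 * math.log(10.0)), 0.0)

    het_a, het_b = _HET[a.seg_type], _HET[b.seg_type]
    linked_parents = [p for p in (0, 1) if het_a[p] and het_b[p]]
    if not linked_parents:
        return PairwiseLinkage(a.marker_id, b.marker_id, 0.5, 0.0, ind_lod, None, n)

    counts = {k: int(v) for k, v in np.ndenumerate(table) if v > 0}

    def neg_ll(r: float, swap: tuple[bool, bool]) -> float:
        probs = _joint_class_probs(a.seg_type, b.seg_type, r, swap)
        ll = 0.0
        for (i, j), c in counts.items():
            p = probs.get((classes_a[i], classes_b[j]), 0.0)
            ll += c * math.log(max(p, 1e-300))
        return -ll

    swap_space = [
        (s1, s2)
        for s1 in ((False, True) if 0 in linked_parents else (False,))
        for s2 in ((False, True) if 1 in linked_parents else (False,))
    ]
    best = None  # (ll, rf, swap)
    for swap in swap_space:
        res = minimize_scalar(
            lambda r: neg_ll(r, swap), bounds=(1e-9, 0.5), method="bounded",
            options={"xatol": 1e-7},
        )
        cand = (-res.fun, float(res.x), swap)
        if best is None or cand[0] > best[0] + 1e-9:
            best = cand
    ll_best, rf, swap = best
    ll_null = -neg_ll(0.5, swap)
    lod = max((ll_best - ll_null) / math.log(10.0), 0.0)
    rf = min(max(rf, 0.0), 0.5)
    if lod < 1e-9:
        rf, swap = 0.5, None
    return PairwiseLinkage(a.marker_id, b.marker_id, rf, lod, ind_lod, swap, n)


def all_pairwise(
    markers: dict[str, MarkerSegregation], min_shared: int = 20
) -> list[PairwiseLinkage]:
    """Two-point statistics for every informative marker pair."""
    mids = [m for m in markers if markers[m].seg_type in _HET]
    out = []
    for i, ma in enumerate(mids):
        for mb in mids[i + 1 :]:
            try:
                out.append(pairwise_linkage(markers[ma], markers[mb], min_shared))
            except ValueError:
                logger.warning("pair (%s, %s) skipped: too few shared calls", ma, mb)
    return out


# ---------------------------------------------------------------------------
# grouping


def group_markers(
    marker_ids,
    links: list[PairwiseLinkage],
    lod_threshold: float = 4.0,
    overrides: dict[str, float] | None = None,
):
    """Partition markers into linkage groups by single linkage.

    Components of the graph with edges ``ind_lod >= lod_threshold``;
    markers with no qualifying edge are unmapped. Components are named
    ``LG1``.. by decreasing size (ties: smallest member id). ``overrides``
    maps a group name to an elevated threshold at which that component is
    re-split — the manual intervention sometimes needed to separate
    pseudo-linked groups. Returns ``(groups, unmapped)`` with groups as
    ``{name: [marker ids]}``.
    """
    marker_ids = list(marker_ids)
    graph = nx.Graph()
    graph.add_nodes_from(marker_ids)
    for l in links:
        if l.ind_lod >= lod_threshold:
            graph.add_edge(l.marker_a, l.marker_b, ind_lod=l.ind_lod)
    components = [sorted(c) for c in nx.connected_components(graph)]
    grouped = [c for c in components if len(c) >= 2]
    unmapped = sorted(m for c in components if len(c) < 2 for m in c)
    grouped.sort(key=lambda c: (-len(c), c[0]))
    named = {f"LG{i + 1}": c for i, c in enumerate(grouped)}
    if overrides:
        final = []
        for name, members in named.items():
            if name in overrides:
                sub = graph.subgraph(members).copy()
                sub.remove_edges_from(
                    [
                        (u, v)
                        for u, v, d in sub.edges(data=True)
                        if d["ind_lod"] < overrides[name]
                    ]
                )
                for comp in nx.connected_components(sub):
                    comp = sorted(comp)
                    if len(comp) >= 2:
                        final.append(comp)
                    else:
                        unmapped.extend(comp)
            else:
                final.append(members)
        final.sort(key=lambda c: (-len(c), c[0]))
        named = {f"LG{i + 1}": c for i, c in enumerate(final)}
        unmapped = sorted(unmapped)
    return named, unmapped


def group_markers_fixed_k(
    marker_ids,
    links: list[PairwiseLinkage],
    n_groups: int,
    lod_threshold: float = 4.0,
):
    """Single-linkage grouping cut at a known number of linkage groups.

    When the chromosome number of the species is known a priori (as it is
    for any established mapping population), pseudo-linkage between groups
    can be resolved the way mapping software does interactively: keep
    raising the effective threshold for the offending clusters until the
    expected group count is reached. Equivalently, this removes the
    weakest inter-cluster bridges from the maximum spanning forest of the
    ``ind_lod >= lod_threshold`` graph until ``n_groups`` components of
    size >= 2 remain. Markers with no qualifying edge stay unmapped.
    Returns ``(groups, unmapped)`` like :func:`group_markers`.
    """
    marker_ids = list(marker_ids)
    graph = nx.Graph()
    graph.add_nodes_from(marker_ids)
    for l in links:
        if l.ind_lod >= lod_threshold:
            graph.add_edge(l.marker_a, l.marker_b, ind_lod=l.ind_lod)
    forest = nx.Graph()
    forest.add_nodes_from(graph.nodes)
    forest.add_edges_from(
        nx.maximum_spanning_edges(graph, weight="ind_lod", data=True)
    )
    def n_real_groups() -> int:
        return sum(1 for c in nx.connected_components(forest) if len(c) >= 2)
    bridges = sorted(forest.edges(data=True), key=lambda e: e[2]["ind_lod"])
    for u, v, _ in bridges:
        if n_real_groups() >= n_groups:
            break
        forest.remove_edge(u, v)
        if n_real_groups() > n_groups or min(
            len(nx.node_connected_component(forest, u)),
            len(nx.node_connected_component(forest, v)),
        ) < 2:
            forest.add_edge(u, v)  # the cut would strand a marker or overshoot
    components = [sorted(c) for c in nx.connected_components(forest)]
    grouped = [c for c in components if len(c) >= 2]
    unmapped = sorted(m for c in components if len(c) < 2 for m in c)
    grouped.sort(key=lambda c: (-len(c), c[0]))
    return {f"LG{i + 1}": c for i, c in enumerate(grouped)}, unmapped


# ---------------------------------------------------------------------------
# Haldane mapping function


def haldane_cM(rf: float) -> float:
    """Map distance d = -50 ln(1 - 2 rf) in cM; rf >= 0.5 is infinite."""
    if rf < 0:
        raise ValueError("rf must be >= 0")
    if rf >= 0.5:
        return math.inf
    return -50.0 * math.log1p(-2.0 * rf)


def haldane_rf(d_cM: float) -> float:
    """Inverse Haldane: rf = (1 - exp(-d/50)) / 2."""
    if d_cM < 0:
        raise ValueError("distance must be >= 0")
    return 0.5 * (1.0 - math.exp(-d_cM / 50.0))


# ---------------------------------------------------------------------------
# ordering and positioning


def _ls_fit(order: list[str], pairs: dict, lod_floor: float = 1e-6):
    """LOD-weighted least-squares fit of map positions to a fixed order.

    Solves min sum w (p_b - p_a - d_ab)^2 over informative pairs, with the
    sign convention that b follows a in the order; the attained residual
    sum is the regression-mapping goodness of fit of that order. Returns
    ``(positions, residual)`` with positions anchored at the first marker.
    """
    idx = {m: i for i, m in enumerate(order)}
    n = len(order)
    if n == 1:
        return np.array([0.0]), 0.0
    rows, rhs, weights = [], [], []
    for (ma, mb), (d, w) in pairs.items():
        if ma not in idx or mb not in idx:
            continue
        i, j = idx[ma], idx[mb]
        if i == j:
            continue
        if i > j:
            i, j = j, i
        row = np.zeros(n)
        row[j], row[i] = 1.0, -1.0
        rows.append(row)
        rhs.append(d)
        weights.append(max(w, lod_floor))
    if not rows:
        return np.zeros(n), 0.0
    a = np.asarray(rows)
    b = np.asarray(rhs)
    w = np.sqrt(np.asarray(weights))
    anchor = np.zeros(n)
    anchor[0] = 1.0
    aw = np.vstack([a * w[:, None], anchor])
    bw = np.concatenate([b * w, [0.0]])
    sol, *_ = np.linalg.lstsq(aw, bw, rcond=None)
    residual = float(np.sum((a @ sol - b) ** 2 * w**2))
    return sol - sol[0], residual


def _objective(order: list[str], pairs: dict) -> float:
    return _ls_fit(order, pairs)[1]


def _refine_positions(
    order: list[str],
    segregations: dict[str, MarkerSegregation],
    links: list[PairwiseLinkage],
    init_positions: np.ndarray,
    rf_max: float = 0.40,
    lod_min: float = 1.00,
) -> np.ndarray:
    """Composite-likelihood re-fit of adjacent interval lengths.

    Given a fixed order, the adjacent map intervals are estimated jointly
    by maximising the sum of two-point log-likelihoods over all qualifying
    pairs, with each pair's recombination fraction implied by the summed
    intervals through the Haldane function (phases fixed at their pairwise
    ML values). This pools long- and short-range information with its
    exact likelihood weight and is noticeably more precise than plugging
    point estimates into least squares.
    """
    pairs = _cl_pairs(segregations, links, set(order), rf_max, lod_min)
    if not pairs:
        return np.asarray(init_positions, float), 0.0
    return _cl_fit(order, pairs, init_positions)


def _cl_pairs(segregations, links, members: set, rf_max: float, lod_min: float):
    """Per-pair count cells and ML phases for the composite likelihood."""
    pairs = []
    for l in links:
        if l.marker_a not in members or l.marker_b not in members:
            continue
        if l.phase is None or l.rf > rf_max or l.lod < lod_min:
            continue
        a, b = segregations[l.marker_a], segregations[l.marker_b]
        ca, cb = SEG_CODES[a.seg_type], SEG_CODES[b.seg_type]
        counts: dict[tuple[str, str], int] = {}
        for x, y in zip(a.codes, b.codes):
            if x != MISSING and y != MISSING:
                counts[(x, y)] = counts.get((x, y), 0) + 1
        # swap flags are per parent, hence symmetric under marker exchange
        pairs.append((l.marker_a, l.marker_b, a.seg_type, b.seg_type, l.phase,
                      list(counts.items())))
    return pairs


def _cl_negll(idx: dict[str, int], cum: np.ndarray, pairs) -> float:
    s = 0.0
    for ma, mb, ta, tb, phase, cells in pairs:
        r = min(max(haldane_rf(abs(cum[idx[mb]] - cum[idx[ma]])), 1e-9), 0.499999)
        probs = _joint_class_probs(ta, tb, r, phase)
        for xy, c in cells:
            s -= c * math.log(max(probs.get(xy, 0.0), 1e-300))
    return s


def _cl_fit(order: list[str], pairs, init_positions):
    """Maximise the composite likelihood over adjacent interval lengths."""
    from scipy.optimize import minimize

    idx = {m: i for i, m in enumerate(order)}

    def negll(log_d: np.ndarray) -> float:
        cum = np.concatenate([[0.0], np.cumsum(np.exp(log_d))])
        return _cl_negll(idx, cum, pairs)

    d0 = np.clip(np.diff(init_positions), 0.25, 150.0)
    bounds = [(math.log(1e-3), math.log(200.0))] * d0.size
    res = minimize(negll, np.log(d0), method="L-BFGS-B", bounds=bounds)
    d = np.exp(res.x)
    d[d < 1e-3] = 0.0  # co-segregating markers collapse to ties
    return np.concatenate([[0.0], np.cumsum(d)]), float(res.fun)


def _cl_polish(
    order: list[str],
    segregations: dict[str, MarkerSegregation],
    links: list[PairwiseLinkage],
    positions: np.ndarray,
    rf_max: float,
    lod_min: float,
):
    """Adjacent-transposition polish under the composite likelihood.

    The least-squares ordering objective can leave neighbouring markers
    swapped when their point rf estimates are noisy; re-evaluating swaps
    under the exact pair likelihoods (a ripple pass) resolves most of
    them. Candidate swaps are screened at fixed interval geometry; an
    accepted swap triggers a full interval re-fit.
    """
    pairs = _cl_pairs(segregations, links, set(order), rf_max, lod_min)
    if not pairs:
        return order, positions
    positions, best = _cl_fit(order, pairs, positions)
    for _ in range(5):
        improved = False
        for i in range(len(order) - 1):
            trial = order[:i] + [order[i + 1], order[i]] + order[i + 2 :]
            idx = {m: k for k, m in enumerate(trial)}
            screen = _cl_negll(idx, positions, pairs)
            if screen < best - 1e-6:
                pos_t, val = _cl_fit(trial, pairs, positions)
                if val < best - 1e-6:
                    order, positions, best = trial, pos_t, val
                    improved = True
        if not improved:
            break
    return order, positions


def order_and_position(
    markers: list[str],
    links: list[PairwiseLinkage],
    rf_max: float = 0.40,
    lod_min: float = 1.00,
    segregations: dict[str, MarkerSegregation] | None = None,
):
    """Order one linkage group and assign cM positions.

    Only pairs with rf <= ``rf_max`` and linkage LOD >= ``lod_min`` enter
    the weighted objective (weight = LOD, distance = Haldane(rf)). The
    order is built by greedy insertion from the strongest pair and refined
    by 2-opt reversals; positions are LOD-weighted least-squares estimates
    along the final order, origin at the first marker, re-fitted by
    composite likelihood when ``segregations`` is supplied.
    """
    markers = list(markers)
    if len(markers) == 1:
        return markers, [0.0]
    member = set(markers)
    pairs: dict[tuple[str, str], tuple[float, float]] = {}
    for l in links:
        if l.marker_a in member and l.marker_b in member:
            if l.rf <= rf_max and l.lod >= lod_min:
                pairs[(l.marker_a, l.marker_b)] = (haldane_cM(l.rf), l.lod)
    if not pairs:
        return markers, [0.0] * len(markers)
    # seed with the strongest pair
    (seed_a, seed_b), _ = max(pairs.items(), key=lambda kv: kv[1][1])
    order = [seed_a, seed_b]
    placed = {seed_a, seed_b}
    strength = {
        m: sum(w for (a_, b_), (_, w) in pairs.items() if m in (a_, b_))
        for m in markers
    }
    remaining = sorted(
        (m for m in markers if m not in placed),
        key=lambda m: (-strength.get(m, 0.0), m),
    )
    for m in remaining:
        best_order, best_val = None, math.inf
        for pos_i in range(len(order) + 1):
            trial = order[:pos_i] + [m] + order[pos_i:]
            val = _objective(trial, pairs)
            if val < best_val - 1e-12:
                best_order, best_val = trial, val
        order = best_order
        placed.add(m)
    # 2-opt refinement: segment reversals
    improved = True
    current = _objective(order, pairs)
    passes = 0
    while improved and passes < 10:
        improved = False
        passes += 1
        for i in range(len(order) - 1):
            for j in range(i + 2, len(order) + 1):
                trial = order[:i] + order[i:j][::-1] + order[j:]
                val = _objective(trial, pairs)
                if val < current - 1e-9:
                    order, current = trial, val
                    improved = True
    positions, _ = _ls_fit(order, pairs)
    # present non-decreasing positions; co-segregating markers may tie
    positions = np.maximum.accumulate(positions)
    positions -= positions[0]
    if segregations is not None and len(order) > 2:
        order, positions = _cl_polish(
            order, segregations, links, positions, rf_max, lod_min
        )
    steps = np.diff(positions)
    steps[steps < 1e-6] = 0.0  # snap numerical noise to exact co-segregation ties
    positions = np.concatenate([[0.0], np.cumsum(steps)])
    return order, [float(p) for p in positions]


def build_map(
    segregations: dict[str, MarkerSegregation],
    lod_threshold: float = 4.0,
    overrides: dict[str, float] | None = None,
    min_shared: int = 20,
    rf_max: float = 0.40,
    lod_min: float = 1.00,
    n_groups: int | None = None,
) -> GeneticMap:
    """Full two-point pipeline: pairwise -> group -> order -> positions.

    ``n_groups`` fixes the expected linkage-group count (the chromosome
    number) and resolves pseudo-linkage via
    :func:`group_markers_fixed_k`; otherwise grouping is purely
    threshold-driven with optional per-group ``overrides``.
    """
    informative = [m for m, s in segregations.items() if s.seg_type in _HET]
    links = all_pairwise(segregations, min_shared=min_shared)
    if n_groups is not None:
        groups, unmapped = group_markers_fixed_k(informative, links, n_groups, lod_threshold)
    else:
        groups, unmapped = group_markers(informative, links, lod_threshold, overrides)
    out_groups = []
    for name in sorted(groups, key=lambda g: int(g[2:])):
        order, pos = order_and_position(groups[name], links, rf_max, lod_min, segregations)
        out_groups.append((name, order, pos))
    uninformative = sorted(m for m, s in segregations.items() if s.seg_type not in _HET)
    return GeneticMap(groups=out_groups, unmapped=sorted(unmapped) + uninformative)


# ---------------------------------------------------------------------------
# calls -> segregations, and the JoinMap-style CP .loc dialect


def classify_all(
    calls: pd.DataFrame, parent1: str = "P1", parent2: str = "P2"
) -> dict[str, MarkerSegregation]:
    """Classify every marker of a wide calls table (samples x markers).

    Parents (and their ``_dup`` duplicates, when present) are checked for
    concordance; markers with discordant parental duplicates are excluded
    with a warning.
    """
    out: dict[str, MarkerSegregation] = {}
    offspring_rows = [
        r
        for r in calls.index
        if r not in (parent1, parent2) and not str(r).endswith("_dup")
    ]
    for mid in calls.columns:
        p_calls = []
        discordant = False
        for p in (parent1, parent2):
            c = calls.at[p, mid] if p in calls.index else MISSING
            dup = f"{p}_dup"
            if dup in calls.index:
                cd = calls.at[dup, mid]
                if MISSING not in (c, cd) and c != cd:
                    discordant = True
                if c == MISSING:
                    c = cd
            p_calls.append(c)
        if discordant:
            logger.warning("marker %s excluded: discordant parental duplicates", mid)
            continue
        if MISSING in p_calls:
            logger.warning("marker %s excluded: missing parental call", mid)
            continue
        out[mid] = classify_segregation(
            mid, (p_calls[0], p_calls[1]), list(calls.loc[offspring_rows, mid])
        )
    return out


def write_loc(segregations: dict[str, MarkerSegregation], path, name: str = "pop") -> None:
    """Write informative markers in the JoinMap-style CP .loc dialect."""
    informative = {m: s for m, s in segregations.items() if s.seg_type in _HET}
    n_ind = max((len(s.codes) for s in informative.values()), default=0)
    with open(path, "w") as fh:
        fh.write(f"name = {name}\npopt = CP\nnloc = {len(informative)}\nnind = {n_ind}\n\n")
        for mid, s in informative.items():
            codes = " ".join(c if c != MISSING else "--" for c in s.codes)
            fh.write(f"{mid} <{s.seg_type}>\n {codes}\n")


def read_loc(path) -> dict[str, MarkerSegregation]:
    """Parse the CP .loc dialect written by :func:`write_loc`."""
    header: dict[str, str] = {}
    segs: dict[str, MarkerSegregation] = {}
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh]
    i = 0
    while i < len(lines) and "=" in lines[i]:
        key, _, val = lines[i].partition("=")
        header[key.strip().lower()] = val.strip()
        i += 1
    if header.get("popt", "CP").upper() != "CP":
        raise ValueError("only CP population .loc files are supported")
    n_ind = int(header.get("nind", 0))
    current: tuple[str, str] | None = None
    codes: list[str] = []

    def flush() -> None:
        nonlocal current, codes
        if current is not None:
            mid, seg = current
            if n_ind and len(codes) != n_ind:
                raise ValueError(f"marker {mid}: expected {n_ind} codes, got {len(codes)}")
            s = MarkerSegregation(mid, seg, codes)
            s.chi2, s.df = distortion_test(s)
            segs[mid] = s
        current, codes = None, []

    for line in lines[i:]:
        if not line.strip():
            continue
        if "<" in line and ">" in line:
            flush()
            mid, rest = line.split("<", 1)
            seg = rest.split(">", 1)[0].strip()
            if seg not in _HET:
                raise ValueError(f"unknown segregation type {seg!r}")
            current = (mid.strip(), seg)
            tail = rest.split(">", 1)[1].strip()
            if tail:
                codes.extend(tail.split())
        elif current is not None:
            codes.extend(line.split())
    flush()
    return segs
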