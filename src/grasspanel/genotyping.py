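"""Array genotype calling from two-channel fluorescence intensities.

The two channel intensities (Cy3/Cy5 roles) are transformed to polar
coordinates: ``theta = (2/pi)*arctan(signal_b/signal_a)`` in [0, 1]
(0 = pure channel 1, 1 = pure channel 2) and ``r = signal_a + signal_b``.
Per marker a 1-3 component Gaussian mixture on theta is fitted (EM with
k-means initialisation, 10 restarts, BIC model selection, ties to the
smaller k) and the marker is classified:

* ``failed`` — median r below ``r_min`` (default 5 % of the plate median);
* ``monomorphic`` — one component;
* ``poor_clustering`` — cluster separation score below ``sep_min``;
* ``polymorphic`` — otherwise.

The separation score is the worst adjacent-pair margin
``clip((mu_j - mu_i - 2*sd_i - 2*sd_j) / (mu_j - mu_i), 0, 1)`` — a
transparent surrogate for the proprietary array-software metric, and
labelled as such in outputs. Samples are assigned to the cluster whose
mean they fall nearest in SD units, up to ``max_sd``; beyond that the
call is missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

GENOTYPES = ("AA", "AB", "BB")
MISSING = "--"


@dataclass(frozen=True)
class ClusterConfig:
    sep_min: float = 0.8  # alternative stricter preset: 0.9
    r_min_fraction: float = 0.05  # of the plate-median r
    max_sd: float = 3.5  # assignment radius in cluster SDs
    min_samples: int = 10
    theta_centers: tuple[float, float, float] = (0.10, 0.50, 0.90)
    random_state: int = 0


@dataclass
class PolarPoint:
    theta: float
    r: float

    @property
    def measurable(self) -> bool:
        return not math.isnan(self.theta)


@dataclass
class ClusterModel:
    marker_id: str
    k: int
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    separation: float | None
    status: str  # failed | poor_clustering | monomorphic | polymorphic
    genotypes: list[str] = field(default_factory=list)  # per cluster, ascending theta

    def __post_init__(self) -> None:
        if self.k >= 2 and not np.all(np.diff(self.means) > 0):
            raise ValueError("cluster means must be strictly increasing")
        if self.k and abs(float(np.sum(self.weights)) - 1.0) > 1e-6:
            raise ValueError("cluster weights must sum to 1")


def to_polar(signal_a: float, signal_b: float) -> PolarPoint:
    """Polar transform of one intensity pair.

    Both-zero input has no direction and is marked unmeasurable
    (theta = NaN, r = 0).
    """
    if signal_a < 0 or signal_b < 0:
        raise ValueError("intensities must be non-negative")
    r = signal_a + signal_b
    if r == 0:
        return PolarPoint(float("nan"), 0.0)
    theta = (2.0 / math.pi) * math.atan2(signal_b, signal_a)
    return PolarPoint(theta, r)


def separation_score(means, sds) -> float:
    """Worst adjacent-pair cluster separation on theta, clipped to [0, 1]."""
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if means.size < 2:
        raise ValueError("separation is undefined for a single cluster")
    scores = []
    for i in range(means.size - 1):
        gap = means[i + 1] - means[i]
        scores.append(np.clip((gap - 2 * sds[i] - 2 * sds[i + 1]) / gap, 0.0, 1.0))
    return float(min(scores))


def _assign_genotypes(means: np.ndarray, centers) -> list[str]:
    """Label clusters (ascending theta) with genotype classes.

    k=3 maps directly to AA/AB/BB. For k<3 the subset of canonical classes
    whose theta centres best match the cluster means is chosen, preserving
    order.
    """
    k = means.size
    if k == 3:
        return list(GENOTYPES)
    from itertools import combinations

    centers = np.asarray(centers, dtype=float)
    best, best_cost = None, math.inf
    for combo in combinations(range(3), k):
        cost = float(np.abs(means - centers[list(combo)]).sum())
        if cost < best_cost:
            best, best_cost = combo, cost
    return [GENOTYPES[i] for i in best]


def fit_marker(
    thetas,
    rs,
    marker_id: str = "",
    config: ClusterConfig | None = None,
    r_min: float | None = None,
) -> ClusterModel:
    """Fit the per-marker cluster model and classify assay status.

    ``r_min`` is the absolute failure threshold on median total signal;
    when omitted it defaults to ``r_min_fraction`` of this marker's median
    r (callers genotyping a whole plate should pass the plate-level value
    from :func:`plate_r_min`).
    """
    config = config or ClusterConfig()
    thetas = np.asarray(thetas, dtype=float)
    rs = np.asarray(rs, dtype=float)
    ok = ~np.isnan(thetas)
    thetas, rs = thetas[ok], rs[ok]
    if thetas.size < config.min_samples:
        raise ValueError(f"need >= {config.min_samples} samples to fit a marker")
    if r_min is not None and float(np.median(rs)) < r_min:
        return ClusterModel(marker_id, 0, np.array([]), np.array([]), np.array([]),
                            None, "failed", [])
    x = thetas.reshape(-1, 1)
    best_k, best_bic, best_gm = 1, math.inf, None
    for k in (1, 2, 3):
        if np.unique(thetas).size < k:
            continue
        gm = GaussianMixture(
            n_components=k,
            n_init=10,
            init_params="k-means++",
            random_state=config.random_state,
            reg_covar=1e-6,
        ).fit(x)
        bic = gm.bic(x)
        if bic < best_bic - 1e-9:  # ties favour smaller k
            best_k, best_bic, best_gm = k, bic, gm
    order = np.argsort(best_gm.means_.ravel())
    means = best_gm.means_.ravel()[order]
    sds = np.sqrt(best_gm.covariances_.ravel()[order])
    weights = best_gm.weights_[order]
    if best_k == 1:
        sep, status = None, "monomorphic"
    else:
        sep = separation_score(means, sds)
        status = "polymorphic" if sep >= config.sep_min else "poor_clustering"
    return ClusterModel(
        marker_id, best_k, means, sds, weights, sep, status,
        _assign_genotypes(means, config.theta_centers),
    )


def call_genotypes(
    model: ClusterModel,
    thetas,
    sample_ids,
    config: ClusterConfig | None = None,
    duplicates: list[tuple[str, str]] | None = None,
):
    """Assign samples to clusters; report duplicate concordance.

    A sample is called when its theta lies within ``max_sd`` standard
    deviations of some cluster mean (nearest such cluster wins); otherwise
    the call is missing. Returns ``(calls, concordance)`` where ``calls``
    maps sample id to genotype and ``concordance`` is the fraction of
    declared duplicate pairs with identical non-missing calls (None when
    no duplicates are declared).
    """
    config = config or ClusterConfig()
    if model.status not in ("polymorphic", "monomorphic"):
        raise ValueError(f"cannot call genotypes on a {model.status} marker")
    thetas = np.asarray(thetas, dtype=float)
    sds = np.maximum(model.sds, 1e-4)
    z = np.abs(thetas[:, None] - model.means[None, :]) / sds[None, :]
    nearest = np.argmin(z, axis=1)
    zmin = z[np.arange(z.shape[0]), nearest]
    calls: dict[str, str] = {}
    for sid, cl, zz, th in zip(sample_ids, nearest, zmin, thetas):
        if math.isnan(th) or zz > config.max_sd:
            calls[sid] = MISSING
        else:
            calls[sid] = model.genotypes[cl]
    concordance = None
    if duplicates:
        agreements = []
        for s1, s2 in duplicates:
            c1, c2 = calls.get(s1, MISSING), calls.get(s2, MISSING)
            if MISSING in (c1, c2):
                continue
            agreements.append(c1 == c2)
        concordance = float(np.mean(agreements)) if agreements else None
    return calls, concordance


def plate_r_min(intensities: pd.DataFrame, config: ClusterConfig | None = None) -> float:
    """Failure threshold: ``r_min_fraction`` of the plate-wide median r."""
    config = config or ClusterConfig()
    r = intensities["signal_a"].to_numpy(float) + intensities["signal_b"].to_numpy(float)
    return config.r_min_fraction * float(np.median(r))


def call_plate(
    intensities: pd.DataFrame,
    config: ClusterConfig | None = None,
    duplicates: list[tuple[str, str]] | None = None,
):
    """Fit and call every marker of an intensity table.

    ``intensities`` columns: sample_id, marker_id, signal_a, signal_b.
    Returns ``(calls wide DataFrame, {marker: ClusterModel},
    {marker: duplicate concordance})``. Failed and poorly clustering
    markers are absent from the calls table.
    """
    config = config or ClusterConfig()
    r_min = plate_r_min(intensities, config)
    models: dict[str, ClusterModel] = {}
    concordances: dict[str, float | None] = {}
    call_rows: dict[str, dict[str, str]] = {}
    for mid, sub in intensities.groupby("marker_id", sort=True):
        pts = [to_polar(a, b) for a, b in zip(sub["signal_a"], sub["signal_b"])]
        thetas = np.array([p.theta for p in pts])
        rs = np.array([p.r for p in pts])
        model = fit_marker(thetas, rs, marker_id=mid, config=config, r_min=r_min)
        models[mid] = model
        if model.status in ("polymorphic", "monomorphic"):
            calls, conc = call_genotypes(
                model, thetas, list(sub["sample_id"]), config, duplicates
            )
            concordances[mid] = conc
            call_rows[mid] = calls
    calls_df = pd.DataFrame(call_rows).fillna(MISSING)
    calls_df.index.name = "sample_id"
    return calls_df, models, concordances


def status_table(models: dict[str, ClusterModel]) -> pd.DataFrame:
    rows = [
        {
            "marker_id": mid,
            "status": m.status,
            "k": m.k,
            "separation": m.separation if m.separation is not None else float("nan"),
        }
        for mid, m in models.items()
    ]
    return pd.DataFrame(rows).set_index("marker_id").sort_index()
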