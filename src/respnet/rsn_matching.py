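"""Matching responsive networks against resting-state-network masks and against
the long-range connectivity structure.

Spatial patterns (eigenvectors over nodes) are coarse-grained to area-level
weight vectors, compared to three-level RSN masks with the Bhattacharyya
coefficient, and assessed with a permutation test (p = (n+1)/(N+1)) under
Bonferroni-Holm correction.  Graph metrics of the heterogeneous connectivity
provide a structural comparison, and two-sample tests contrast cortical
versus subcortical contributions.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import EmptyResultError, InvalidArgumentError
from .response_decomposition import ResponseEigenspace
from .synthetic_brain import HeterogeneousSC, Parcellation

__all__ = [
    "RSN_NAMES",
    "RSNMask",
    "MatchResult",
    "coarse_grain",
    "candidate_patterns",
    "bhattacharyya_coefficient",
    "permutation_test",
    "holm_correct",
    "match_candidates",
    "select_optimal_parameters",
    "graph_metrics",
    "cortical_subcortical_tests",
    "build_stimulation_map",
    "generate_synthetic_masks",
    "read_masks",
    "write_masks",
]

log = logging.getLogger(__name__)

RSN_NAMES = (
    "default mode",
    "visual",
    "auditory-phonological",
    "somatomotor",
    "memory",
    "ventral stream",
    "dorsal attention",
    "working memory",
)

LEVELS = {"none": 0, "medium": 1, "high": 2}
LEVEL_NAMES = {v: k for k, v in LEVELS.items()}

DEFAULT_N_PERM = 10_000
FULL_N_PERM = 2_000_000  # full-replication setting
SIGNIFICANCE = 0.05


@dataclass
class RSNMask:
    """Three-level area mask of one resting-state network."""

    name: str
    levels: np.ndarray  # (n_areas,) ints in {0, 1, 2}

    def __post_init__(self):
        self.levels = np.asarray(self.levels, dtype=int)
        if not np.isin(self.levels, (0, 1, 2)).all():
            raise InvalidArgumentError("mask levels must be 0 (none), 1 or 2")
        if not (self.levels > 0).any():
            raise InvalidArgumentError(f"mask {self.name!r} has no contributing area")

    @property
    def weights(self) -> np.ndarray:
        """Level scores normalized to a unit-sum weight vector."""
        w = self.levels.astype(float)
        return w / w.sum()


@dataclass
class MatchResult:
    """One pattern-vs-mask comparison with its permutation statistics."""

    rsn: str
    candidate: int  # candidate pattern id (single eigenvector or combination)
    bc: float
    n_exceed: int
    n_perm: int
    p: float
    p_corrected: float = np.nan
    significant: bool = False
    extra: dict = field(default_factory=dict)  # site, alpha, sigma, metric, ...


# ------------------------------------------------------------- coarse graining


def coarse_grain(
    eigenvector: np.ndarray,
    parcellation: Parcellation,
    metric: str = "square",
    norm: str = "sum",
) -> np.ndarray:
    """Collapse a node-level pattern to a non-negative area weight vector.

    ``metric='square'`` sums squared elements per area, ``'absolute'`` sums
    absolute values.  The result is normalized to unit sum by default (so
    Bhattacharyya overlap is well defined) or to unit Euclidean length with
    ``norm='l2'``.
    """
    if metric not in ("square", "absolute"):
        raise InvalidArgumentError(f"unknown coarse-graining metric {metric!r}")
    v = np.asarray(eigenvector, dtype=float)
    contrib = v**2 if metric == "square" else np.abs(v)
    out = np.zeros(parcellation.n_areas)
    np.add.at(out, parcellation.node_area, contrib)
    return _normalize(out, norm)


def _normalize(w: np.ndarray, norm: str = "sum") -> np.ndarray:
    if norm == "sum":
        s = w.sum()
    elif norm == "l2":
        s = np.linalg.norm(w)
    else:
        raise InvalidArgumentError(f"unknown normalization {norm!r}")
    return w / s if s > 0 else w


def candidate_patterns(
    eigenspace: ResponseEigenspace | np.ndarray,
    parcellation: Parcellation,
    metric: str = "square",
    norm: str = "sum",
) -> list[np.ndarray]:
    """Coarse-grained eigenvectors plus every combination sum, renormalized.

    For three eigenvectors this yields seven candidates: the three singles and
    the four combinations {1+2, 1+3, 2+3, 1+2+3}; for k eigenvectors, all
    2^k - 1 non-empty subsets in that order (singles first, then pairs, ...).
    """
    vecs = (
        eigenspace.eigenvectors
        if isinstance(eigenspace, ResponseEigenspace)
        else np.asarray(eigenspace)
    )
    singles = [coarse_grain(vecs[:, i], parcellation, metric, norm) for i in range(vecs.shape[1])]
    out = []
    for r in range(1, len(singles) + 1):
        for combo in itertools.combinations(range(len(singles)), r):
            out.append(_normalize(sum(singles[i] for i in combo), norm))
    return out


# --------------------------------------------------------------------- overlap


def bhattacharyya_coefficient(p: np.ndarray, q: np.ndarray) -> float:
    """Overlap of two unit-sum non-negative weight vectors: sum of sqrt(p*q)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if (p < 0).any() or (q < 0).any():
        raise InvalidArgumentError("Bhattacharyya inputs must be non-negative")
    if p.shape != q.shape:
        raise InvalidArgumentError("weight vectors differ in length")
    return float(np.sqrt(p * q).sum())


def permutation_test(
    candidate: np.ndarray,
    mask: RSNMask,
    N: int = DEFAULT_N_PERM,
    seed: int = 0,
    chunk: int = 50_000,
) -> MatchResult:
    """Permutation null for the Bhattacharyya overlap of candidate and mask.

    The mask's area weights are permuted (without replacement) N times; the
    p-value is (n+1)/(N+1) where n counts permuted coefficients strictly
    greater than the observed one.
    """
    if N < 1:
        raise InvalidArgumentError("N must be >= 1")
    q = mask.weights
    bc = bhattacharyya_coefficient(candidate, q)
    rng = np.random.default_rng(seed)
    sqrt_p = np.sqrt(np.asarray(candidate, dtype=float))
    sqrt_q = np.sqrt(q)  # permuting q commutes with the elementwise sqrt
    n_exceed = 0
    done = 0
    while done < N:
        b = min(chunk, N - done)
        perms = rng.permuted(np.tile(sqrt_q, (b, 1)), axis=1)
        n_exceed += int((perms @ sqrt_p > bc).sum())
        done += b
    p = (n_exceed + 1) / (N + 1)
    return MatchResult(rsn=mask.name, candidate=-1, bc=bc, n_exceed=n_exceed,
                       n_perm=N, p=p)


def holm_correct(p_values, m: int | None = None) -> np.ndarray:
    """Step-down Bonferroni-Holm adjustment with monotonicity enforcement.

    ``m`` is the size of the comparison family and may exceed the number of
    supplied p-values (defaults to their count).
    """
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise InvalidArgumentError("p-values must lie in [0, 1]")
    k = p.size
    m = k if m is None else int(m)
    if m < k:
        raise InvalidArgumentError("family size m must be >= number of p-values")
    order = np.argsort(p, kind="stable")
    adj = np.empty(k)
    running = 0.0
    for rank, idx in enumerate(order):
        val = min(1.0, (m - rank) * p[idx])
        running = max(running, val)
        adj[idx] = running
    return adj


def match_candidates(
    eigenspace: ResponseEigenspace | np.ndarray,
    parcellation: Parcellation,
    masks: list[RSNMask],
    metric: str = "square",
    norm: str = "sum",
    N: int = DEFAULT_N_PERM,
    seed: int = 0,
    family_size: int | None = None,
    alpha_level: float = SIGNIFICANCE,
    extra: dict | None = None,
) -> list[MatchResult]:
    """Compare every candidate pattern of one eigenspace against every mask.

    Holm correction is applied over the family of all (mask, candidate)
    comparisons for this stimulation site; pass ``family_size`` to use a fixed
    family (e.g., 24 = 8 masks x 3 eigenvectors) instead.
    """
    cands = candidate_patterns(eigenspace, parcellation, metric, norm)
    results: list[MatchResult] = []
    for ci, cand in enumerate(cands):
        for mi, mask in enumerate(masks):
            r = permutation_test(cand, mask, N=N, seed=seed + 1009 * ci + mi)
            r.candidate = ci
            r.extra = dict(extra or {})
            r.extra["metric"] = metric
            results.append(r)
    fam = family_size if family_size is not None else len(results)
    adj = holm_correct([r.p for r in results], m=fam)
    for r, pc in zip(results, adj):
        r.p_corrected = float(pc)
        r.significant = bool(pc < alpha_level)
    return results


# ---------------------------------------------------------- parameter selection


def results_table(results: list[MatchResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            dict(
                rsn=r.rsn, candidate=r.candidate, bc=r.bc, p=r.p,
                p_corrected=r.p_corrected, significant=r.significant, **r.extra,
            )
        )
    return pd.DataFrame(rows)


def select_optimal_parameters(
    table: pd.DataFrame,
    n_rsn: int = len(RSN_NAMES),
    group_column: str | None = "group",
) -> dict[str, tuple]:
    """Parameter triple maximizing the mean best significant overlap per RSN.

    For each (metric, alpha, sigma) triple, the per-RSN maximum significant
    Bhattacharyya coefficient is averaged over all ``n_rsn`` networks (missing
    networks contribute 0); the argmax triple is returned, separately per site
    group when ``group_column`` is present.
    """
    sig = table[table["significant"]]
    if sig.empty:
        raise EmptyResultError("no significant matches anywhere in the table")
    groups = (
        sorted(sig[group_column].unique())
        if group_column and group_column in sig.columns
        else ["all"]
    )
    out: dict[str, tuple] = {}
    for g in groups:
        sub = sig if g == "all" else sig[sig[group_column] == g]
        if sub.empty:
            continue
        best_score, best_triple = -1.0, None
        for triple, block in sub.groupby(["metric", "alpha", "sigma"], sort=True):
            score = block.groupby("rsn")["bc"].max().sum() / n_rsn
            if score > best_score + 1e-15:
                best_score, best_triple = score, triple
        out[g] = (*best_triple, best_score)
    return out


# ----------------------------------------------------------------- graph metrics

GRAPH_METRIC_NAMES = (
    "in_degree", "out_degree", "total_degree",
    "in_strength", "out_strength", "total_strength",
    "clustering",
)


def graph_metrics(het: HeterogeneousSC, normalize: bool = True) -> dict[str, np.ndarray]:
    """Seven per-area graph measures of the directed weighted connectivity.

    Degrees count incoming/outgoing/all ties; strengths sum their weights; the
    clustering coefficient is the weighted directed generalization built from
    cube-rooted weights (Fagiolo-style), with the bilateral-edge correction in
    the denominator.  Each vector is normalized to unit sum for overlap
    comparisons unless ``normalize=False``.
    """
    w = het.weights  # w[i, j]: j -> i
    a = (w > 0).astype(float)
    in_deg = a.sum(axis=1)
    out_deg = a.sum(axis=0)
    in_str = w.sum(axis=1)
    out_str = w.sum(axis=0)

    mx = w.max()
    wn = (w / mx) if mx > 0 else w
    # adjacency/weights in source->target orientation for the triangle count
    at = a.T
    wt_cube = np.cbrt(wn.T)
    s = wt_cube + wt_cube.T
    triangles = np.diagonal(s @ s @ s) / 2.0
    d_tot = in_deg + out_deg
    d_bi = np.diagonal(at @ at)
    denom = d_tot * (d_tot - 1) - 2 * d_bi
    clustering = np.where(denom > 0, triangles / np.where(denom > 0, denom, 1.0), 0.0)

    metrics = {
        "in_degree": in_deg,
        "out_degree": out_deg,
        "total_degree": in_deg + out_deg,
        "in_strength": in_str,
        "out_strength": out_str,
        "total_strength": in_str + out_str,
        "clustering": clustering,
    }
    if normalize:
        metrics = {k: _normalize(v.astype(float), "sum") for k, v in metrics.items()}
    return metrics


# ------------------------------------------------------- distribution contrasts


def cortical_subcortical_tests(
    area_weights: np.ndarray,
    parcellation: Parcellation,
    alpha_level: float = 0.01,
) -> dict:
    """KS and Wilcoxon rank-sum tests on cortical vs subcortical contributions."""
    cort = np.asarray(area_weights)[parcellation.cortical_area_ids()]
    sub = np.asarray(area_weights)[parcellation.subcortical_area_ids()]
    if cort.size < 2 or sub.size < 2:
        raise InvalidArgumentError("need at least 2 areas in each group")
    ks = stats.ks_2samp(cort, sub)
    rs = stats.ranksums(cort, sub)
    return {
        "ks_p": float(ks.pvalue),
        "ranksum_p": float(rs.pvalue),
        "ks_significant": bool(ks.pvalue < alpha_level),
        "ranksum_significant": bool(rs.pvalue < alpha_level),
    }


# -------------------------------------------------------------- stimulation map


def build_stimulation_map(results: list[MatchResult]) -> pd.DataFrame:
    """Best significant match per (site, RSN): the stimulation lookup table.

    Ties on the coefficient between candidate patterns keep the lowest
    candidate index.  Columns: site, group, network, bc, p_corrected,
    eigenvector (candidate id), alpha, sigma_mm.
    """
    rows = []
    for r in results:
        if not r.significant:
            continue
        rows.append(
            dict(
                site=r.extra.get("site"),
                group=r.extra.get("group", ""),
                network=r.rsn,
                bc=r.bc,
                p_corrected=r.p_corrected,
                eigenvector=r.candidate,
                alpha=r.extra.get("alpha"),
                sigma_mm=r.extra.get("sigma"),
            )
        )
    cols = ["site", "group", "network", "bc", "p_corrected", "eigenvector",
            "alpha", "sigma_mm"]
    if not rows:
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame(rows, columns=cols)
    df = df.sort_values(["site", "network", "bc", "eigenvector"],
                        ascending=[True, True, False, True], kind="stable")
    return df.groupby(["site", "network"], as_index=False).first()[cols]


# -------------------------------------------------------------------- mask IO


def generate_synthetic_masks(
    parcellation: Parcellation,
    seed: int = 0,
    names: tuple[str, ...] = RSN_NAMES,
    high_fraction: float = 0.15,
    medium_fraction: float = 0.2,
    include_subcortical: bool = True,
) -> list[RSNMask]:
    """Random three-level masks over the eligible areas, one per RSN name.

    Eligible areas are the non-callosal cortical areas plus (optionally) the
    subcortical areas; each mask marks a random subset as medium or high.
    """
    rng = np.random.default_rng(seed)
    eligible = list(parcellation.cortical_area_ids())
    if include_subcortical:
        eligible += list(parcellation.subcortical_area_ids())
    eligible = np.asarray(eligible)
    masks = []
    for name in names:
        n_high = max(1, int(round(high_fraction * eligible.size)))
        n_med = max(1, int(round(medium_fraction * eligible.size)))
        chosen = rng.choice(eligible, size=min(n_high + n_med, eligible.size),
                            replace=False)
        levels = np.zeros(parcellation.n_areas, dtype=int)
        levels[chosen[:n_high]] = 2
        levels[chosen[n_high:]] = 1
        masks.append(RSNMask(name=name, levels=levels))
    return masks


def write_masks(masks: list[RSNMask], parcellation: Parcellation, path) -> None:
    """Write masks as TSV rows of (area_label, network_name, level)."""
    labels = list(parcellation.areas["name"])
    rows = []
    for mask in masks:
        for aid, lev in enumerate(mask.levels):
            rows.append((labels[aid], mask.name, LEVEL_NAMES[int(lev)]))
    pd.DataFrame(rows, columns=["area_label", "network_name", "level"]).to_csv(
        path, sep="\t", index=False
    )


def read_masks(path, parcellation: Parcellation) -> list[RSNMask]:
    df = pd.read_csv(path, sep="\t")
    for col in ("area_label", "network_name", "level"):
        if col not in df.columns:
            raise InvalidArgumentError(f"mask file missing column {col!r}")
    label_to_id = {n: i for i, n in enumerate(parcellation.areas["name"])}
    masks = []
    for name, block in df.groupby("network_name", sort=False):
        levels = np.zeros(parcellation.n_areas, dtype=int)
        for _, row in block.iterrows():
            if row["area_label"] not in label_to_id:
                raise InvalidArgumentError(f"unknown area label {row['area_label']!r}")
            levels[label_to_id[row["area_label"]]] = LEVELS[row["level"]]
        masks.append(RSNMask(name=name, levels=levels))
    return masks
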