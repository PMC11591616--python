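"""Spatio-temporal segmentation of condition grand averages.

The four condition grand averages are concatenated and every
average-referenced, GFP-normalized time-point topography in the analysis
window enters an atomize–agglomerate hierarchical cluster analysis
(AAHC).  AAHC starts from singleton clusters and repeatedly dissolves
the cluster contributing least global explained variance (GEV),
reassigning each freed map to the cluster whose centroid it correlates
with best (signed correlation — evoked polarity is meaningful).  One
solution is recorded per cluster count k = k_max…1.

The optimal k is chosen by the convergence of several criteria that
trade explained variance against cluster count (cross-validation
criterion, Krzanowski–Lai index, a dispersion ratio, and a
silhouette index on spatial correlations): each criterion ranks the
candidate k's and the k with the best median rank wins, ties going to
the smaller k.

Finally segments shorter than a physiological minimum duration (10 ms)
are dissolved into their temporal neighbours.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .topography import EvokedERP, TemplateMap, average_reference

__all__ = [
    "SegmentationParams",
    "ClusterSolution",
    "SegmentationResult",
    "FrameSet",
    "build_frames",
    "aahc_cluster",
    "compute_gev",
    "apply_temporal_constraint",
    "meta_criterion_select",
    "segment_grand_averages",
    "match_templates",
]

logger = logging.getLogger(__name__)

DEFAULT_CRITERIA = ("cv", "kl", "w_ratio", "silhouette")


@dataclass(frozen=True)
class SegmentationParams:
    k_max: int = 20
    min_segment_ms: float = 10.0
    analysis_window_ms: tuple[float, float] = (0.0, 700.0)
    criteria: tuple[str, ...] = DEFAULT_CRITERIA

    def __post_init__(self) -> None:
        if self.k_max < 1:
            raise ValueError("k_max must be ≥ 1")
        if self.min_segment_ms < 0:
            raise ValueError("min_segment_ms must be ≥ 0")
        unknown = set(self.criteria) - set(DEFAULT_CRITERIA)
        if unknown:
            raise ValueError(f"unknown k-selection criteria: {sorted(unknown)}")


@dataclass(frozen=True)
class ClusterSolution:
    """One k-solution: templates, per-frame labels, total GEV."""

    k: int
    templates: tuple[TemplateMap, ...]
    labels: np.ndarray  # per concatenated frame; −1 = excluded (zero GFP)
    gev_total: float
    gev_per_map: np.ndarray

    def __post_init__(self) -> None:
        if len(self.templates) != self.k:
            raise ValueError("len(templates) must equal k")
        lab = np.asarray(self.labels)
        if lab.size and lab.max(initial=-1) >= self.k:
            raise ValueError("label out of range")


@dataclass(frozen=True)
class FrameSet:
    """Concatenated analysis-window topographies with bookkeeping.

    ``unit`` holds unit-L2-norm, zero-mean maps column-wise (so the dot
    product of two columns is their spatial correlation); ``gfp`` the
    per-frame field strength; ``condition`` / ``time_ms`` locate each
    frame in its source grand average.
    """

    unit: np.ndarray  # n_channels × n_frames
    gfp: np.ndarray
    condition: np.ndarray  # condition index per frame
    time_ms: np.ndarray
    sfreq: float
    cells: tuple[tuple[str, str], ...]
    n_excluded: int = 0

    @property
    def n_frames(self) -> int:
        return self.unit.shape[1]

    @property
    def gfp2_total(self) -> float:
        return float(np.sum(self.gfp**2))


def _unit_maps(data: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center columns, return (unit maps, gfp, keep mask for nonzero GFP)."""
    centered = data - data.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(centered, axis=0)
    gfp = norms / np.sqrt(data.shape[0])
    keep = gfp > 1e-12
    unit = np.zeros_like(centered)
    unit[:, keep] = centered[:, keep] / norms[keep]
    return unit, gfp, keep


def build_frames(
    grand_averages: list[EvokedERP], params: SegmentationParams
) -> FrameSet:
    """Concatenate the analysis-window maps of the condition grand averages."""
    if not grand_averages:
        raise ValueError("no grand averages")
    first = grand_averages[0]
    units, gfps, conds, times = [], [], [], []
    n_excluded = 0
    for ci, ga in enumerate(grand_averages):
        if ga.data.shape[0] != first.data.shape[0] or ga.sfreq != first.sfreq:
            raise ValueError("grand averages must share montage and sfreq")
        ga = average_reference(ga)
        t = ga.times_ms
        lo, hi = params.analysis_window_ms
        sel = (t >= lo) & (t < hi)
        if not sel.any():
            raise ValueError("analysis window contains no samples")
        unit, gfp, keep = _unit_maps(ga.data[:, sel])
        n_excluded += int((~keep).sum())
        units.append(unit[:, keep])
        gfps.append(gfp[keep])
        conds.append(np.full(keep.sum(), ci))
        times.append(t[sel][keep])
    if n_excluded:
        logger.info("excluded %d zero-GFP frames from clustering", n_excluded)
    return FrameSet(
        unit=np.concatenate(units, axis=1),
        gfp=np.concatenate(gfps),
        condition=np.concatenate(conds),
        time_ms=np.concatenate(times),
        sfreq=first.sfreq,
        cells=tuple(ga.cell for ga in grand_averages),
        n_excluded=n_excluded,
    )


def _centroid(unit: np.ndarray, members: np.ndarray) -> np.ndarray:
    """Unit-norm mean of member maps (polarity-sensitive)."""
    c = unit[:, members].sum(axis=1)
    n = np.linalg.norm(c)
    if n == 0:  # perfectly cancelling members; keep first map's direction
        return unit[:, members[0]].copy()
    return c / n


def _gev_of_labeling(
    unit: np.ndarray, gfp: np.ndarray, labels: np.ndarray, k: int, gfp2_total: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-map GEV and unit-norm centroids for a labeling (NaN centroid
    for a cluster that won no frame)."""
    gev = np.zeros(k)
    cents = np.full((k, unit.shape[0]), np.nan)
    for m in range(k):
        sel = labels == m
        if not sel.any():
            continue
        c = _centroid(unit, np.flatnonzero(sel))
        cents[m] = c
        gev[m] = float(np.sum((gfp[sel] * (c @ unit[:, sel])) ** 2) / gfp2_total)
    return gev, cents


def _polish_labels(
    unit: np.ndarray,
    gfp: np.ndarray,
    labels: np.ndarray,
    k: int,
    gfp2_total: float,
    max_iter: int = 20,
) -> np.ndarray:
    """Winner-take-all refinement of a recorded solution.

    Alternates assignment (each frame to the centroid of highest signed
    spatial correlation) and centroid update, keeping the labeling with
    the highest total GEV seen; stops if an update would empty a
    cluster.  Deterministic and never worse than the input labeling.
    """
    best_labels = labels.copy()
    best_gev, cents = _gev_of_labeling(unit, gfp, labels, k, gfp2_total)
    best_total = best_gev.sum()
    current = labels
    for _ in range(max_iter):
        corr = np.where(np.isnan(cents @ unit), -np.inf, cents @ unit)
        new = np.argmax(corr, axis=0).astype(int)
        if np.array_equal(new, current) or len(np.unique(new)) < k:
            break
        current = new
        gev, cents = _gev_of_labeling(unit, gfp, current, k, gfp2_total)
        if gev.sum() > best_total:
            best_total = gev.sum()
            best_labels = current.copy()
    return best_labels


def _split_candidates(
    unit: np.ndarray, gfp: np.ndarray, labels: np.ndarray, k_from: int
) -> list[np.ndarray]:
    """Labelings with k_from+1 clusters obtained by splitting off the
    worst-fitting frame of each multi-member cluster."""
    _, cents = _gev_of_labeling(unit, gfp, labels, k_from, gfp2_total=1.0)
    out = []
    for m in range(k_from):
        members = np.flatnonzero(labels == m)
        if members.size < 2 or np.isnan(cents[m]).any():
            continue
        corr = cents[m] @ unit[:, members]
        worst = members[int(np.argmin(corr))]
        cand = labels.copy()
        cand[worst] = k_from
        out.append(cand)
    return out


def _canonical_solution(
    unit: np.ndarray,
    gfp: np.ndarray,
    labels: np.ndarray,
    k: int,
    gfp2_total: float,
    n_frames_full: int,
    frame_index: np.ndarray,
) -> ClusterSolution:
    """Relabel clusters by earliest member frame and package a solution."""
    order = sorted(range(k), key=lambda m: int(np.flatnonzero(labels == m).min()))
    remap = {old: new for new, old in enumerate(order)}
    relabeled = np.array([remap[v] for v in labels], dtype=int)
    gev_per_map, cents = _gev_of_labeling(unit, gfp, relabeled, k, gfp2_total)
    full = np.full(n_frames_full, -1, dtype=int)
    full[frame_index] = relabeled
    templates = tuple(
        TemplateMap(map_id=m, vector=cents[m] * np.sqrt(unit.shape[0]))
        for m in range(k)
    )
    return ClusterSolution(
        k=k,
        templates=templates,
        labels=full,
        gev_total=float(gev_per_map.sum()),
        gev_per_map=gev_per_map,
    )


def aahc_cluster(frames: FrameSet, params: SegmentationParams) -> dict[int, ClusterSolution]:
    """AAHC sweep: one ClusterSolution per k = min(k_max, n_frames)…1.

    Starts from singleton clusters.  At each step the cluster with the
    smallest GEV contribution is atomized and each freed map joins the
    cluster whose centroid it best matches by signed spatial
    correlation; receiving centroids (unit-norm means of member maps)
    and their members' GEV contributions are then updated.
    """
    unit, gfp = frames.unit, frames.gfp
    T = frames.n_frames
    if T == 0:
        raise ValueError("no frames to cluster")
    D = frames.gfp2_total
    k_max = min(params.k_max, T)

    member_lists: list[np.ndarray] = [np.array([t]) for t in range(T)]
    centroids: list[np.ndarray] = [unit[:, t].copy() for t in range(T)]
    cluster_gev = [float(gfp[t] ** 2) for t in range(T)]  # un-normalized
    alive = list(range(T))
    frame_index = np.arange(T)

    raw_labelings: dict[int, np.ndarray] = {}
    while True:
        k = len(alive)
        if k <= k_max:
            raw = np.empty(T, dtype=int)
            for new_id, ci in enumerate(alive):
                raw[member_lists[ci]] = new_id
            raw_labelings[k] = raw
        if k == 1:
            break
        # atomize the cluster contributing least GEV (tie → lowest index)
        worst_pos = int(np.argmin([cluster_gev[ci] for ci in alive]))
        worst = alive.pop(worst_pos)
        freed = member_lists[worst]
        cent_mat = np.stack([centroids[ci] for ci in alive])  # (k−1) × C
        corr = cent_mat @ unit[:, freed]  # (k−1) × m
        best = np.argmax(corr, axis=0)  # tie → lowest cluster position
        receivers: dict[int, list[int]] = {}
        for pos, fr in zip(best, freed):
            receivers.setdefault(alive[int(pos)], []).append(int(fr))
        for ci, new_members in receivers.items():
            member_lists[ci] = np.concatenate([member_lists[ci], np.array(new_members)])
            centroids[ci] = _centroid(unit, member_lists[ci])
            c = centroids[ci] @ unit[:, member_lists[ci]]
            cluster_gev[ci] = float(np.sum((gfp[member_lists[ci]] * c) ** 2))

    # finalize ascending in k: polish each raw solution, and repair any
    # monotonicity break (a k-solution should never explain less than
    # the (k−1)-solution) by splitting the previous solution instead
    solutions: dict[int, ClusterSolution] = {}
    prev_labels: np.ndarray | None = None
    prev_gev = -np.inf
    for k in sorted(raw_labelings):
        best_labels = _polish_labels(unit, gfp, raw_labelings[k], k, D)
        best_gev = float(_gev_of_labeling(unit, gfp, best_labels, k, D)[0].sum())
        if prev_labels is not None and best_gev < prev_gev:
            for cand in _split_candidates(unit, gfp, prev_labels, k - 1):
                polished = _polish_labels(unit, gfp, cand, k, D)
                total = float(_gev_of_labeling(unit, gfp, polished, k, D)[0].sum())
                if total > best_gev:
                    best_labels, best_gev = polished, total
                if best_gev >= prev_gev:
                    break
        solutions[k] = _canonical_solution(unit, gfp, best_labels, k, D, T, frame_index)
        prev_labels, prev_gev = best_labels, best_gev
    return solutions


def compute_gev(
    data: EvokedERP | np.ndarray,
    templates: tuple[TemplateMap, ...] | list[TemplateMap],
    labels: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Per-map and total global explained variance.

    GEV_m = Σ_{t: label(t)=m} (GFP_t · C(u_t, T_m))² / Σ_t GFP_t², with C
    the signed spatial correlation; the denominator runs over *all*
    samples, so Σ_m GEV_m ≤ 1 with equality iff every sample is labeled
    and perfectly fit.
    """
    arr = data.data if isinstance(data, EvokedERP) else np.asarray(data, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if labels.shape[0] != arr.shape[1]:
        raise ValueError("labels must align with data samples")
    unit, gfp, keep = _unit_maps(arr)
    denom = float(np.sum(gfp**2))
    if denom <= 0:
        raise ValueError("zero total GFP")
    k = len(templates)
    tmat = np.stack([t.vector for t in templates]) / np.sqrt(arr.shape[0])  # unit L2
    per_map = np.zeros(k)
    for m in range(k):
        sel = (labels == m) & keep
        if not sel.any():
            continue
        corr = tmat[m] @ unit[:, sel]
        per_map[m] = float(np.sum((gfp[sel] * corr) ** 2) / denom)
    return per_map, float(per_map.sum())


def _runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs of equal label: list of (label, start, stop) half-open."""
    runs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append((int(labels[start]), start, i))
            start = i
    return runs


def apply_temporal_constraint(
    labels: np.ndarray,
    min_segment_ms: float,
    sfreq: float,
    data: np.ndarray,
    templates: tuple[TemplateMap, ...] | list[TemplateMap],
    max_iter: int = 500,
) -> np.ndarray:
    """Dissolve segments shorter than the physiological minimum duration.

    Works on one condition's label sequence (conditions are never merged
    across the concatenation boundary).  The shortest offending run is
    dissolved first: each of its samples is reassigned to the better of
    the two flanking runs' maps by signed spatial correlation; this
    repeats until no labeled run is shorter than ``min_segment_ms``.  If
    per-sample reassignment oscillates, the remaining short runs are
    dissolved by an optimal contiguous split between the two flanking
    maps, which guarantees termination.  A labeling made up entirely of
    short runs collapses to the single globally best map.
    """
    labels = np.asarray(labels, dtype=int).copy()
    if min_segment_ms <= 0:
        return labels
    unit, gfp, keep = _unit_maps(np.asarray(data, dtype=float))
    tmat = np.stack([t.vector for t in templates]) / np.sqrt(data.shape[0])

    def run_ms(start: int, stop: int) -> float:
        return (stop - start) * 1000.0 / sfreq

    def short_runs(runs):
        return [
            (lab, a, b)
            for lab, a, b in runs
            if lab >= 0 and run_ms(a, b) < min_segment_ms
        ]

    for it in range(max_iter):
        runs = _runs(labels)
        shorts = short_runs(runs)
        if not shorts:
            return labels
        labeled = [r for r in runs if r[0] >= 0]
        if len(shorts) == len(labeled):
            # degenerate: everything is short — single best map overall
            corr_all = tmat @ unit
            scores = np.sum((gfp[None, :] * corr_all) ** 2 * keep[None, :], axis=1)
            best = int(np.argmax(scores))
            out = np.where(labels >= 0, best, labels)
            logger.warning("all runs short; collapsed to map %d", best)
            return out
        # dissolve the shortest run first (tie → earliest)
        shorts.sort(key=lambda r: (r[2] - r[1], r[1]))
        target = None
        for lab, a, b in shorts:
            idx = runs.index((lab, a, b))
            left = runs[idx - 1][0] if idx > 0 else None
            right = runs[idx + 1][0] if idx < len(runs) - 1 else None
            cands = [c for c in (left, right) if c is not None and c >= 0 and c != lab]
            if cands:
                target = (a, b, cands)
                break
        if target is None:
            logger.warning("short runs without labeled neighbours left untouched")
            return labels
        a, b, cands = target
        contiguous = it > max_iter // 2  # force convergence late in the loop
        if len(cands) == 1 or (b - a) == 1:
            labels[a:b] = _best_per_sample(unit[:, a:b], tmat, cands)
        elif contiguous:
            labels[a:b] = _best_contiguous_split(unit[:, a:b], tmat, cands)
        else:
            labels[a:b] = _best_per_sample(unit[:, a:b], tmat, cands)
    return labels


def _best_per_sample(unit_seg: np.ndarray, tmat: np.ndarray, cands: list[int]) -> np.ndarray:
    corr = tmat[cands] @ unit_seg
    return np.asarray(cands, dtype=int)[np.argmax(corr, axis=0)]


def _best_contiguous_split(
    unit_seg: np.ndarray, tmat: np.ndarray, cands: list[int]
) -> np.ndarray:
    """Left map before the split point, right map after; best split wins."""
    left, right = cands[0], cands[-1]
    cl = tmat[left] @ unit_seg
    cr = tmat[right] @ unit_seg
    n = unit_seg.shape[1]
    cum_l = np.concatenate([[0.0], np.cumsum(cl)])
    cum_r = np.concatenate([[0.0], np.cumsum(cr)])
    scores = [cum_l[s] + (cum_r[n] - cum_r[s]) for s in range(n + 1)]
    s = int(np.argmax(scores))
    out = np.empty(n, dtype=int)
    out[:s] = left
    out[s:] = right
    return out


# ---------------------------------------------------------------------------
# k-selection criteria
# ---------------------------------------------------------------------------


def _dispersion(frames: FrameSet, sol: ClusterSolution) -> float:
    """GFP²-weighted unexplained variance W_k = (1 − GEV_k) · Σ GFP²."""
    return (1.0 - sol.gev_total) * frames.gfp2_total


def _criterion_cv(frames: FrameSet, solutions: dict[int, ClusterSolution], ks) -> dict[int, float]:
    """Predictive-residual criterion: residual variance inflated by a
    degrees-of-freedom penalty ((C−1)/(C−1−k))²; smaller is better."""
    C = frames.unit.shape[0]
    T = frames.n_frames
    out = {}
    for k in ks:
        w = _dispersion(frames, solutions[k])
        sigma2 = C * w / (T * (C - 1))
        pen = ((C - 1) / (C - 1 - k)) ** 2 if k < C - 1 else np.inf
        out[k] = sigma2 * pen
    return out


def _criterion_kl(frames: FrameSet, solutions: dict[int, ClusterSolution], ks) -> dict[int, float]:
    """Krzanowski–Lai index on the dispersion curve; larger is better.

    The denominator is floored at 1% of the mean per-step dispersion
    decline so that vanishing successive differences beyond the true k
    (numerical wiggles) cannot blow the index up."""
    C = frames.unit.shape[0]
    d = {k: k ** (2.0 / C) * _dispersion(frames, solutions[k]) for k in solutions}
    kk = sorted(d)
    floor = 0.01 * max((d[kk[0]] - d[kk[-1]]) / max(len(kk) - 1, 1), 1e-300)
    out = {}
    for k in ks:
        if k - 1 not in d or k + 1 not in d:
            continue
        diff_k = d[k - 1] - d[k]
        diff_next = d[k] - d[k + 1]
        out[k] = abs(diff_k) / max(abs(diff_next), floor)
    return out


def _criterion_w_ratio(frames: FrameSet, solutions: dict[int, ClusterSolution], ks) -> dict[int, float]:
    """Dispersion ratio W_{k−1}/W_k: the relative drop achieved by the
    k-th cluster; largest at the true cluster count, and largest at
    small k for structureless data."""
    w = {k: _dispersion(frames, solutions[k]) for k in solutions}
    out = {}
    for k in ks:
        if k - 1 not in w:
            continue
        out[k] = w[k - 1] / max(w[k], 1e-300)
    return out


def _criterion_silhouette(frames: FrameSet, solutions: dict[int, ClusterSolution], ks) -> dict[int, float]:
    """GFP²-weighted simplified silhouette on spatial correlations.

    Per frame: a = distance (1 − signed correlation) to the assigned
    template, b = distance to the closest other template; silhouette
    (b − a)/max(a, b).  The centroid-based form penalizes splitting a
    quasi-stable topography into sub-clusters (the sibling centroid sits
    at distance ≈ 0), and the GFP² weighting matches the GEV objective
    so low-field noise frames carry little weight."""
    w = frames.gfp**2
    out = {}
    for k in ks:
        if k < 2:
            continue
        sol = solutions[k]
        labels = sol.labels
        valid = labels >= 0
        tmat = np.stack([t.vector for t in sol.templates]) / np.sqrt(
            frames.unit.shape[0]
        )
        dist = 1.0 - np.clip(tmat @ frames.unit, -1.0, 1.0)  # k × T
        a = dist[labels[valid], np.nonzero(valid)[0]]
        masked = dist[:, valid].copy()
        masked[labels[valid], np.arange(valid.sum())] = np.inf
        b = masked.min(axis=0)
        denom = np.maximum(np.maximum(a, b), 1e-12)
        sil = (b - a) / denom
        out[k] = float(np.sum(w[valid] * sil) / np.sum(w[valid]))
    return out


_CRITERIA = {
    "cv": (_criterion_cv, "min"),
    "kl": (_criterion_kl, "max"),
    "w_ratio": (_criterion_w_ratio, "max"),
    "silhouette": (_criterion_silhouette, "max"),
}


#: A k-th cluster must add at least this fraction of total explained
#: variance to stay in the candidate set (parsimony: clusters that add
#: less explain noise, not structure).
MIN_GEV_GAIN = 0.01


def meta_criterion_select(
    frames: FrameSet,
    solutions: dict[int, ClusterSolution],
    criteria: tuple[str, ...] = DEFAULT_CRITERIA,
) -> tuple[int, dict[str, dict[int, float]]]:
    """Pick k by the convergence of the enabled criteria.

    Candidate k's are those whose k-th cluster still adds a non-trivial
    share of explained variance (GEV gain ≥ 1%), within 2 ≤ k ≤
    k_max − 1 so the Krzanowski–Lai differences exist; each criterion
    ranks the candidates, and the k with the best median rank is
    selected, ties resolved toward the smaller k.
    """
    kk = sorted(solutions)
    if len(kk) == 1:
        logger.warning("single-k sweep; returning k=%d", kk[0])
        return kk[0], {}
    ks = [k for k in kk if 2 <= k <= max(kk) - 1] or kk
    gains = {
        k: solutions[k].gev_total - solutions[k - 1].gev_total
        for k in kk
        if k - 1 in solutions
    }
    informative: list[int] = []
    for k in ks:  # contiguous prefix: stop once the gains dry up
        if gains.get(k, 1.0) < MIN_GEV_GAIN:
            break
        informative.append(k)
    ks = informative or ks[:1]
    scores: dict[str, dict[int, float]] = {}
    ranks: dict[int, list[float]] = {k: [] for k in ks}
    for name in criteria:
        fn, direction = _CRITERIA[name]
        vals = fn(frames, solutions, ks)
        scores[name] = vals
        if not vals:
            continue
        items = sorted(
            vals.items(),
            key=lambda kv: (kv[1] if direction == "min" else -kv[1], kv[0]),
        )
        for rank, (k, _) in enumerate(items, start=1):
            ranks[k].append(rank)
        worst = len(items) + 1
        for k in ks:
            if k not in vals:
                ranks[k].append(worst)
    med = {k: float(np.median(r)) if r else np.inf for k, r in ranks.items()}
    selected = min(ks, key=lambda k: (med[k], k))
    return selected, scores


@dataclass(frozen=True)
class SegmentationResult:
    solutions: dict[int, ClusterSolution]
    criterion_scores: dict[str, dict[int, float]]
    selected_k: int
    labels: np.ndarray  # after temporal constraint, per concatenated frame
    frames: FrameSet
    map_windows: dict[tuple[str, str], dict[int, list[tuple[float, float]]]] = field(
        default_factory=dict
    )

    @property
    def templates(self) -> tuple[TemplateMap, ...]:
        return self.solutions[self.selected_k].templates

    @property
    def gev_total_constrained(self) -> float:
        per_map, total = compute_gev_frames(self.frames, self.templates, self.labels)
        return total


def compute_gev_frames(
    frames: FrameSet, templates, labels: np.ndarray
) -> tuple[np.ndarray, float]:
    """GEV over a FrameSet (denominator = all frames' GFP²)."""
    labels = np.asarray(labels, dtype=int)
    tmat = np.stack([t.vector for t in templates]) / np.sqrt(frames.unit.shape[0])
    denom = frames.gfp2_total
    per_map = np.zeros(len(templates))
    for m in range(len(templates)):
        sel = labels == m
        if not sel.any():
            continue
        corr = tmat[m] @ frames.unit[:, sel]
        per_map[m] = float(np.sum((frames.gfp[sel] * corr) ** 2) / denom)
    return per_map, float(per_map.sum())


def _windows_from_labels(
    labels: np.ndarray, time_ms: np.ndarray, sfreq: float
) -> dict[int, list[tuple[float, float]]]:
    dt = 1000.0 / sfreq
    out: dict[int, list[tuple[float, float]]] = {}
    for lab, a, b in _runs(labels):
        if lab < 0:
            continue
        out.setdefault(lab, []).append((float(time_ms[a]), float(time_ms[b - 1] + dt)))
    return out


def segment_grand_averages(
    grand_averages: list[EvokedERP], params: SegmentationParams | None = None
) -> SegmentationResult:
    """Full segmentation: AAHC sweep → k selection → temporal constraint.

    Map windows (ms, half-open [start, end)) are derived per condition
    from the constrained labels of the selected solution.
    """
    params = params or SegmentationParams()
    frames = build_frames(grand_averages, params)
    solutions = aahc_cluster(frames, params)
    selected_k, scores = meta_criterion_select(frames, solutions, params.criteria)
    sol = solutions[selected_k]
    labels = sol.labels.copy()
    for ci in range(len(grand_averages)):
        sel = frames.condition == ci
        seg_data = frames.unit[:, sel] * (frames.gfp[sel] * np.sqrt(frames.unit.shape[0]))
        labels[sel] = apply_temporal_constraint(
            labels[sel], params.min_segment_ms, frames.sfreq, seg_data, sol.templates
        )
    map_windows = {}
    for ci, cell in enumerate(frames.cells):
        sel = frames.condition == ci
        map_windows[cell] = _windows_from_labels(
            labels[sel], frames.time_ms[sel], frames.sfreq
        )
    return SegmentationResult(
        solutions=solutions,
        criterion_scores=scores,
        selected_k=selected_k,
        labels=labels,
        frames=frames,
        map_windows=map_windows,
    )


def match_templates(
    recovered: tuple[TemplateMap, ...], reference: tuple[TemplateMap, ...]
) -> dict[int, int]:
    """Best one-to-one assignment reference map → recovered map.

    Maximizes the summed signed spatial correlation via the Hungarian
    algorithm; used to compare recovered templates with planted ground
    truth or across runs.
    """
    from scipy.optimize import linear_sum_assignment

    corr = np.array(
        [
            [float(r.vector @ t.vector) / r.vector.size for t in recovered]
            for r in reference
        ]
    )
    rows, cols = linear_sum_assignment(-corr)
    return {reference[i].map_id: recovered[j].map_id for i, j in zip(rows, cols)}
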