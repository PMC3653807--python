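"""Model-fit and geographic-consistency evaluation.

Covers: AUC (Mann–Whitney form), the theoretical AUC ceiling under
background testing, threshold selection where sensitivity ≈ specificity,
binarization, the strict-majority consensus ensemble, and pairwise
agreement between binary maps at three spatial scales:

* cell scale — Cohen's Kappa;
* neighborhood scale — fuzzy Kappa with a distance-decay membership over
  a 4-cell radius (chance-corrected by a Monte-Carlo independence null);
* whole-map scale — fuzzy global matching (mean per-cell two-way fuzzy
  similarity).

The fuzzy statistics give partial credit to near-miss agreement: a cell
of one category partially "matches" cells of the same category nearby in
the other map, with membership decaying as ``2**(-d / halving_distance)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("sdmeval")

#: Common categorical-map-comparison defaults for the neighborhood
#: statistics: 4-cell radius, membership halving every 2 cells.
DEFAULT_RADIUS_CELLS = 4.0
DEFAULT_HALVING_CELLS = 2.0

SCALES = ("cell", "neighborhood", "global")


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class BinaryMap:
    """A presence/absence map with provenance."""

    grid: np.ndarray  # 2-D of {0,1}; NaN-free; mask handled separately
    species_id: str = ""
    algorithm_id: str = ""
    replicate: int = -1
    threshold: float = float("nan")
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        g = np.asarray(self.grid)
        vals = np.unique(g[self.mask])
        if not set(vals.tolist()) <= {0, 1}:
            raise ValueError("binary map values must be 0 or 1")
        self.grid = g.astype(np.int8)

    @property
    def mask(self) -> np.ndarray:
        if self.valid_mask is None:
            return np.ones(np.asarray(self.grid).shape, dtype=bool)
        return np.asarray(self.valid_mask, dtype=bool)


@dataclass
class SimilarityRecord:
    species_id: str
    algorithm_id: str
    pair: tuple[int, int]
    scale: str
    statistic_value: float


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

def compute_auc(scores_presence: Sequence[float],
                scores_absence: Sequence[float]) -> float:
    """Mann–Whitney AUC: P(presence score > absence score), ties 0.5."""
    sp = np.asarray(scores_presence, dtype=float)
    sa = np.asarray(scores_absence, dtype=float)
    if len(sp) == 0 or len(sa) == 0:
        raise ValueError("both score sets must be non-empty")
    # rank-based formulation: O((n+m) log(n+m)), exact tie handling
    from scipy.stats import rankdata

    ranks = rankdata(np.concatenate([sp, sa]))
    r_pres = ranks[: len(sp)].sum()
    u = r_pres - len(sp) * (len(sp) + 1) / 2.0
    return float(u / (len(sp) * len(sa)))


def theoretical_max_auc(prevalence_a: float) -> float:
    """Ceiling on AUC when test absences are background cells.

    With a fraction ``a`` of cells truly occupied, an omniscient scorer
    still ties with the occupied fraction of the background, capping AUC
    at ``1 - a/2``.  This is the mechanism behind declining AUC with
    increasing occupancy.
    """
    if not (0.0 <= prevalence_a <= 1.0):
        raise ValueError("prevalence must lie in [0, 1]")
    return 1.0 - prevalence_a / 2.0


# ---------------------------------------------------------------------------
# Threshold selection and binarization
# ---------------------------------------------------------------------------

def select_threshold(scores: Sequence[float],
                     labels: Sequence[int]) -> tuple[float, float, float]:
    """Threshold minimizing |sensitivity - specificity|.

    Candidates are midpoints between adjacent distinct scores (plus the
    extremes); ties are broken by the lower threshold.  Returns
    ``(threshold, sensitivity, specificity)`` at the chosen cut, where a
    cell counts as predicted presence when its score >= threshold.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("labels must contain both classes")
    distinct = np.unique(s)
    if len(distinct) < 2:
        raise ValueError("degenerate scores: all values identical")
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    candidates = np.concatenate([[distinct[0] - 1.0], mids,
                                 [distinct[-1] + 1.0]])
    n_pos = (y == 1).sum()
    n_neg = (y == 0).sum()
    best = None
    for t in candidates:
        pred = s >= t
        se = (pred & (y == 1)).sum() / n_pos
        sp = (~pred & (y == 0)).sum() / n_neg
        gap = abs(se - sp)
        if best is None or gap < best[0] - 1e-12:
            best = (gap, t, se, sp)
    assert best is not None
    return best[1], best[2], best[3]


def binarize(suitability_map: np.ndarray, threshold: float,
             valid_mask: np.ndarray | None = None, **provenance) -> BinaryMap:
    """Presence where suitability >= threshold."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    arr = np.asarray(suitability_map, dtype=float)
    grid = np.where(np.isnan(arr), 0.0, arr) >= threshold
    return BinaryMap(grid=grid.astype(np.int8), threshold=float(threshold),
                     valid_mask=valid_mask, **provenance)


def consensus_map(member_binary_maps: Sequence[BinaryMap],
                  **provenance) -> BinaryMap:
    """Strict-majority vote: presence iff > half of members predict it.

    An exact half vote is an absence, per the strict "more than half"
    rule.
    """
    if len(member_binary_maps) < 2:
        raise ValueError("consensus needs at least two member maps")
    shapes = {m.grid.shape for m in member_binary_maps}
    if len(shapes) != 1:
        raise ValueError(f"member maps have mismatched shapes: {shapes}")
    votes = np.sum([m.grid for m in member_binary_maps], axis=0)
    grid = (votes * 2 > len(member_binary_maps)).astype(np.int8)
    return BinaryMap(grid=grid, valid_mask=member_binary_maps[0].valid_mask,
                     **provenance)


def consensus_vote_fraction(member_binary_maps: Sequence[BinaryMap]) -> np.ndarray:
    """Per-cell fraction of members voting presence (consensus score map)."""
    if len(member_binary_maps) < 2:
        raise ValueError("consensus needs at least two member maps")
    return np.mean([m.grid for m in member_binary_maps], axis=0)


# ---------------------------------------------------------------------------
# Cell-scale agreement: Cohen's Kappa
# ---------------------------------------------------------------------------

def _check_comparable(a: BinaryMap, b: BinaryMap) -> np.ndarray:
    if a.grid.shape != b.grid.shape:
        raise ValueError("maps must share one shape")
    mask = a.mask & b.mask
    if not mask.any():
        raise ValueError("maps share no valid cells")
    return mask


def cohens_kappa(map_a: BinaryMap, map_b: BinaryMap) -> float:
    """Chance-corrected cell-by-cell agreement of two binary maps."""
    mask = _check_comparable(map_a, map_b)
    a = map_a.grid[mask]
    b = map_b.grid[mask]
    n = a.size
    po = float((a == b).mean())
    pa1, pb1 = a.mean(), b.mean()
    pe = pa1 * pb1 + (1 - pa1) * (1 - pb1)
    if pe >= 1.0 - 1e-15:
        if po >= 1.0 - 1e-15:
            return 1.0
        raise ValueError("degenerate margins: chance agreement is 1")
    return float((po - pe) / (1 - pe))


# ---------------------------------------------------------------------------
# Fuzzy neighborhood machinery
# ---------------------------------------------------------------------------

def _neighborhood_offsets(radius: float, halving: float) -> list[tuple[int, int, float]]:
    """Integer offsets within Euclidean ``radius`` with decay weights."""
    r = int(np.floor(radius))
    offsets = []
    for dr in range(-r, r + 1):
        for dc in range(-r, r + 1):
            d = float(np.hypot(dr, dc))
            if d <= radius + 1e-12:
                w = 2.0 ** (-d / halving) if halving > 0 else (1.0 if d == 0 else 0.0)
                offsets.append((dr, dc, w))
    # descending weight, so the first hit is already maximal (not relied on,
    # but cheap and keeps the max-reduction stable)
    offsets.sort(key=lambda t: -t[2])
    return offsets


def _shift_max(binary: np.ndarray, offsets, out: np.ndarray) -> np.ndarray:
    """out[i] = max over offsets of weight * binary at the shifted cell.

    ``binary`` may carry a leading batch dimension.  Cells shifted past
    the edge contribute nothing.
    """
    out.fill(0.0)
    nr, nc = binary.shape[-2:]
    for dr, dc, w in offsets:
        src_r = slice(max(0, dr), min(nr, nr + dr))
        src_c = slice(max(0, dc), min(nc, nc + dc))
        dst_r = slice(max(0, -dr), min(nr, nr - dr))
        dst_c = slice(max(0, -dc), min(nc, nc - dc))
        np.maximum(out[..., dst_r, dst_c],
                   w * binary[..., src_r, src_c],
                   out=out[..., dst_r, dst_c])
    return out


def fuzzy_membership(binary_map: BinaryMap | np.ndarray,
                     radius_cells: float = DEFAULT_RADIUS_CELLS,
                     halving_distance_cells: float = DEFAULT_HALVING_CELLS,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell fuzzy membership of (presence, absence).

    Membership of category c at cell i is the maximum over cells j of
    category c within ``radius_cells`` (Euclidean) of
    ``2**(-d(i,j)/halving)``; a cell's own category always has membership
    1 (d = 0).  Cells outside the valid mask contribute nothing.
    """
    if radius_cells < 0:
        raise ValueError("radius must be >= 0")
    if isinstance(binary_map, BinaryMap):
        grid = binary_map.grid.astype(float)
        mask = binary_map.mask
    else:
        grid = np.asarray(binary_map, dtype=float)
        mask = np.ones(grid.shape, dtype=bool)
    offsets = _neighborhood_offsets(radius_cells, halving_distance_cells)
    pres = (grid == 1) & mask
    absn = (grid == 0) & mask
    m_pres = _shift_max(pres.astype(float), offsets, np.empty(grid.shape))
    m_abs = _shift_max(absn.astype(float), offsets, np.empty(grid.shape))
    return m_pres, m_abs


def fuzzy_global_matching(map_a: BinaryMap, map_b: BinaryMap,
                          radius_cells: float = DEFAULT_RADIUS_CELLS,
                          halving_distance_cells: float = DEFAULT_HALVING_CELLS,
                          ) -> float:
    """Mean per-cell two-way fuzzy similarity of two binary maps.

    At each cell the similarity is the minimum of (a) the membership, in
    map B's neighborhood, of map A's category there, and (b) vice versa;
    the statistic is the mean over valid cells.  Equals 1 iff the maps
    are identical; crisp (radius 0) limit is the raw agreement fraction.
    """
    mask = _check_comparable(map_a, map_b)
    sim = _two_way_similarity(
        map_a.grid[None].astype(float), map_b.grid[None].astype(float),
        radius_cells, halving_distance_cells, mask)
    return float(sim[0])


def _two_way_similarity(a_batch: np.ndarray, b_batch: np.ndarray,
                        radius: float, halving: float,
                        mask: np.ndarray) -> np.ndarray:
    """Batched FGM: arrays of shape (k, nr, nc) -> (k,) means."""
    offsets = _neighborhood_offsets(radius, halving)
    shape = a_batch.shape
    buf = np.empty(shape)
    pres_b = _shift_max((b_batch == 1).astype(float), offsets, buf).copy()
    abs_b = _shift_max((b_batch == 0).astype(float), offsets, buf).copy()
    pres_a = _shift_max((a_batch == 1).astype(float), offsets, buf).copy()
    abs_a = _shift_max((a_batch == 0).astype(float), offsets, buf).copy()
    # membership in B of A's category at i, and vice versa
    s_ab = np.where(a_batch == 1, pres_b, abs_b)
    s_ba = np.where(b_batch == 1, pres_a, abs_a)
    sim = np.minimum(s_ab, s_ba)
    return sim[..., mask].mean(axis=-1)


def fuzzy_kappa(map_a: BinaryMap, map_b: BinaryMap,
                radius_cells: float = DEFAULT_RADIUS_CELLS,
                halving_distance_cells: float = DEFAULT_HALVING_CELLS,
                n_null: int = 2000, seed: int = 0,
                batch_size: int = 200) -> float:
    """Chance-corrected fuzzy agreement (neighborhood-scale statistic).

    ``Kf = (P - E) / (1 - E)`` where P is the fuzzy global matching of
    the two maps and E its expectation under an independence null that
    randomly relabels the cells of both maps while preserving each map's
    presence count (Monte-Carlo with ``n_null`` seeded draws).  Identical
    maps score exactly 1; at radius 0 the null expectation converges to
    Cohen's chance agreement, recovering Cohen's Kappa.
    """
    mask = _check_comparable(map_a, map_b)
    if np.array_equal(map_a.grid[mask], map_b.grid[mask]):
        return 1.0
    p = fuzzy_global_matching(map_a, map_b, radius_cells,
                              halving_distance_cells)
    rng = np.random.default_rng(seed)
    vals_a = map_a.grid[mask].astype(float)
    vals_b = map_b.grid[mask].astype(float)
    n_cells = vals_a.size
    sims = []
    done = 0
    while done < n_null:
        k = min(batch_size, n_null - done)
        ra = np.empty((k,) + map_a.grid.shape)
        rb = np.empty((k,) + map_a.grid.shape)
        for i in range(k):
            pa = rng.permutation(n_cells)
            pb = rng.permutation(n_cells)
            ga = np.zeros(map_a.grid.shape)
            gb = np.zeros(map_a.grid.shape)
            ga[mask] = vals_a[pa]
            gb[mask] = vals_b[pb]
            ra[i] = ga
            rb[i] = gb
        sims.append(_two_way_similarity(ra, rb, radius_cells,
                                        halving_distance_cells, mask))
        done += k
    e = float(np.concatenate(sims).mean())
    if e >= 1.0 - 1e-12:
        raise ValueError("degenerate null: expected similarity is 1")
    return float((p - e) / (1 - e))


# ---------------------------------------------------------------------------
# Pairwise comparison of replicate maps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScaleSettings:
    """Settings for the three-scale pairwise map comparison."""

    radius_cells: float = DEFAULT_RADIUS_CELLS
    halving_distance_cells: float = DEFAULT_HALVING_CELLS
    n_null: int = 2000
    seed: int = 0


def pairwise_similarity(binary_maps: Sequence[BinaryMap],
                        scale_settings: ScaleSettings | None = None,
                        ) -> list[SimilarityRecord]:
    """All unordered pairs of replicate maps at all three scales.

    ``k`` maps give ``k(k-1)/2`` records per scale (10 replicate maps
    give 45 comparisons).
    """
    if len(binary_maps) < 2:
        raise ValueError("need at least two maps to compare")
    st = scale_settings or ScaleSettings()
    records: list[SimilarityRecord] = []
    for i, j in combinations(range(len(binary_maps)), 2):
        a, b = binary_maps[i], binary_maps[j]
        meta = dict(species_id=a.species_id, algorithm_id=a.algorithm_id,
                    pair=(i, j))
        records.append(SimilarityRecord(
            scale="cell", statistic_value=cohens_kappa(a, b), **meta))
        records.append(SimilarityRecord(
            scale="neighborhood",
            statistic_value=fuzzy_kappa(
                a, b, st.radius_cells, st.halving_distance_cells,
                n_null=st.n_null, seed=st.seed + 1000 * i + j),
            **meta))
        records.append(SimilarityRecord(
            scale="global",
            statistic_value=fuzzy_global_matching(
                a, b, st.radius_cells, st.halving_distance_cells),
            **meta))
    return records


def similarity_to_frame(records: Sequence[SimilarityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "species_id": [r.species_id for r in records],
            "algorithm_id": [r.algorithm_id for r in records],
            "pair_i": [r.pair[0] for r in records],
            "pair_j": [r.pair[1] for r in records],
            "scale": [r.scale for r in records],
            "value": [r.statistic_value for r in records],
        }
    )
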