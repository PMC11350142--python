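"""Cluster the twelve months of one location into named seasons.

The months of a year are points in a small zone-specific feature space
(z-scored columns, scaled by the square root of their weight so that a weight
``w`` multiplies the variable's squared-distance contribution by ``w``).
K-means with a fixed number of centers splits them into seasons: four in the
temperate zone (winter/spring/summer/autumn), two elsewhere (arctic
winter/summer, desert cooler/hotter, tropical wet/dry).

Outside the tropics a season must occupy a single circularly contiguous run of
months — once it ends it cannot reappear within the annual cycle — so raw
k-means labels are projected onto the nearest contiguous partition.  Tropical
calendars are exempt: the ITCZ can legitimately produce two wet seasons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import IntEnum
from functools import lru_cache
from itertools import combinations

import numpy as np
from scipy.optimize import linear_sum_assignment

from .climate import ClimateStack, PixelClimate, extract_pixel, znormalize
from .params import Params, WeightSet
from .zones import Zone, classify_zone, zone_map

__all__ = [
    "SeasonLabel",
    "SeasonCalendar",
    "SeasonRaster",
    "build_feature_matrix",
    "kmeans_months",
    "contiguous_partition_oracle",
    "enforce_contiguity",
    "name_seasons",
    "classify_pixel",
    "classify_raster",
    "partition_sse",
]

MONTHS = 12


class SeasonLabel(IntEnum):
    """Season names with stable raster codes (0 reserved for nodata)."""

    WINTER = 1
    SPRING = 2
    SUMMER = 3
    AUTUMN = 4
    WET = 5
    DRY = 6
    COOLER = 7
    HOTTER = 8


#: seasons each climate zone may use
ZONE_SEASONS: dict[Zone, frozenset] = {
    Zone.TEMPERATE: frozenset(
        {SeasonLabel.WINTER, SeasonLabel.SPRING, SeasonLabel.SUMMER, SeasonLabel.AUTUMN}
    ),
    Zone.ARCTIC_MONTANE: frozenset({SeasonLabel.WINTER, SeasonLabel.SUMMER}),
    Zone.TROPICAL: frozenset({SeasonLabel.WET, SeasonLabel.DRY}),
    Zone.DESERT: frozenset({SeasonLabel.COOLER, SeasonLabel.HOTTER}),
}

#: number of k-means centers per zone
ZONE_K: dict[Zone, int] = {
    Zone.TEMPERATE: 4,
    Zone.ARCTIC_MONTANE: 2,
    Zone.TROPICAL: 2,
    Zone.DESERT: 2,
}


def n_circular_runs(labels) -> int:
    """Number of maximal circular runs of equal values in a 12-vector."""
    labels = np.asarray(labels)
    changes = int((labels != np.roll(labels, 1)).sum())
    return max(changes, 1)


@dataclass
class SeasonCalendar:
    """A zone plus its ordered January..December season assignment."""

    zone: Zone
    labels: np.ndarray  # 12 SeasonLabel codes

    def __post_init__(self) -> None:
        self.zone = Zone(self.zone)
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.shape != (MONTHS,):
            raise ValueError("a season calendar needs exactly 12 monthly labels")
        allowed = {int(s) for s in ZONE_SEASONS[self.zone]}
        present = set(self.labels.tolist())
        if not present <= allowed:
            raise ValueError(f"labels {present - allowed} not allowed in zone {self.zone.name}")
        if self.zone != Zone.TROPICAL and n_circular_runs(self.labels) > len(present):
            raise ValueError("non-tropical seasons must each form one contiguous run")

    def names(self) -> list[str]:
        """Lowercase canonical season name per month."""
        return [SeasonLabel(c).name.lower() for c in self.labels]


@dataclass
class SeasonRaster:
    """12-band categorical season grid plus the zone grid it derives from."""

    codes: np.ndarray   # (12, h, w) uint8 SeasonLabel codes, 0 = nodata
    zones: np.ndarray   # (h, w) uint8 Zone codes, 0 = nodata
    mask: np.ndarray    # (h, w) bool, True on valid cells
    transform: tuple = (1.0, 0.0, 0.0, 0.0, -1.0, 0.0)
    crs: str = "EPSG:4326"

    def __post_init__(self) -> None:
        h, w = self.mask.shape
        if self.codes.shape != (MONTHS, h, w) or self.zones.shape != (h, w):
            raise ValueError("season raster shapes disagree")


# ---------------------------------------------------------------------------
# feature construction

def build_feature_matrix(
    pixel: PixelClimate,
    zone: Zone,
    weights: WeightSet | None = None,
    *,
    precip_level: bool = False,
    linear_weights: bool = False,
) -> np.ndarray:
    """12 x d matrix of z-scored, weight-scaled features for one pixel.

    Zone feature sets: arctic (tmid, srad), desert (tmid, aridity) —
    unweighted; temperate (tmid, precip lag, tmid lag, NDVI lag); tropical
    (tmid, precip lag, NDVI lag).  The temperature lag is excluded in the
    tropics, where month-to-month temperature change is not smooth.
    ``precip_level=True`` substitutes the precipitation level for its lag;
    ``linear_weights=True`` scales columns by ``w`` instead of ``sqrt(w)``.
    """
    w = weights or WeightSet()
    precip_feat = pixel.precip if precip_level else pixel.lag_precip
    if zone == Zone.ARCTIC_MONTANE:
        cols, wts = [pixel.tmid, pixel.srad], [1.0, 1.0]
    elif zone == Zone.DESERT:
        cols, wts = [pixel.tmid, pixel.aridity], [1.0, 1.0]
    elif zone == Zone.TEMPERATE:
        cols = [pixel.tmid, precip_feat, pixel.lag_tmid, pixel.lag_ndvi]
        wts = [w.temperate_temperature, w.temperate_precip_lag,
               w.temperate_temp_lag, w.temperate_ndvi_lag]
    elif zone == Zone.TROPICAL:
        cols = [pixel.tmid, precip_feat, pixel.lag_ndvi]
        wts = [w.tropical_temperature, w.tropical_precip_lag, w.tropical_ndvi_lag]
    else:
        raise ValueError(f"unknown zone {zone!r}")
    scale = np.asarray(wts) if linear_weights else np.sqrt(wts)
    return np.column_stack([znormalize(c) for c in cols]) * scale


# ---------------------------------------------------------------------------
# k-means over the 12 months

def _kmeanspp_init(X: np.ndarray, k: int, restarts: int, rng: np.random.Generator) -> np.ndarray:
    """Initial centers per restart: one deterministic farthest-point start,
    the rest k-means++ probabilistic seeding."""
    n, d = X.shape
    centers = np.empty((restarts, k, d))
    sq = lambda a, b: ((a[:, None, :] - b[None, :, :]) ** 2).sum(-1)
    for r in range(restarts):
        if r == 0:
            first = int(np.argmax(((X - X.mean(0)) ** 2).sum(1)))
        else:
            first = int(rng.integers(n))
        idx = [first]
        for _ in range(1, k):
            d2 = sq(X, X[idx]).min(axis=1)
            total = d2.sum()
            if r == 0 or total <= 0:
                nxt = int(np.argmax(d2))
            else:
                nxt = int(rng.choice(n, p=d2 / total))
            idx.append(nxt)
        centers[r] = X[idx]
    return centers


def kmeans_months(X, k: int, seed: int = 0, restarts: int = 50) -> np.ndarray:
    """Best-of-restarts k-means labels for the 12 month points.

    Lloyd iterations from farthest-point / k-means++ style starts, all
    restarts run vectorized; the labeling with the lowest within-cluster sum
    of squared distances wins (ties to the first restart found).  Deterministic
    for a given seed.  A degenerate matrix whose rows are all identical
    collapses to a single flagged cluster.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != MONTHS:
        raise ValueError(f"expected a {MONTHS}xd matrix, got {X.shape}")
    n_distinct = len(np.unique(X, axis=0))
    if k <= 1 or n_distinct == 1:
        if n_distinct == 1 and k > 1:
            warnings.warn("all months identical in feature space: single-cluster fallback")
        return np.zeros(MONTHS, dtype=int)
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct month points")

    rng = np.random.default_rng(seed)
    centers = _kmeanspp_init(X, k, restarts, rng)
    R, n = restarts, MONTHS
    labels = np.full((R, n), -1, dtype=int)
    for _ in range(100):
        dist = ((X[None, :, None, :] - centers[:, None, :, :]) ** 2).sum(-1)  # (R, n, k)
        new_labels = dist.argmin(-1)
        # re-seed empty clusters with the worst-fit point
        onehot = new_labels[:, :, None] == np.arange(k)[None, None, :]
        counts = onehot.sum(1)  # (R, k)
        for r, j in zip(*np.nonzero(counts == 0)):
            worst = int(np.argmax(dist[r, np.arange(n), new_labels[r]]))
            new_labels[r, worst] = j
            onehot[r] = new_labels[r][:, None] == np.arange(k)
            counts[r] = onehot[r].sum(0)
        if (new_labels == labels).all():
            break
        labels = new_labels
        centers = np.einsum("rnk,nd->rkd", onehot.astype(float), X) / counts[:, :, None]
    dist = ((X[None, :, None, :] - centers[:, None, :, :]) ** 2).sum(-1)
    sse = dist[np.arange(R)[:, None], np.arange(n)[None, :], labels].sum(1)
    return labels[int(np.argmin(sse))].copy()


# ---------------------------------------------------------------------------
# circularly contiguous partitions

@lru_cache(maxsize=None)
def _contiguous_partitions(k: int) -> tuple[np.ndarray, tuple]:
    """All circular k-arc partitions of 12 months, in lexicographic cut order.

    A partition is identified by its cut-set: the k month indices that start a
    new arc.  There are C(12, k) of them (66 for k=2, 495 for k=4).  Returns
    the (P, 12) arc-index matrix and the matching tuple of cut-sets.
    """
    cut_sets = list(combinations(range(MONTHS), k))
    parts = np.empty((len(cut_sets), MONTHS), dtype=int)
    for p, cuts in enumerate(cut_sets):
        arc = np.empty(MONTHS, dtype=int)
        for j, start in enumerate(cuts):
            end = cuts[j + 1] if j + 1 < k else cuts[0] + MONTHS
            for m in range(start, end):
                arc[m % MONTHS] = j
        parts[p] = arc
    return parts, tuple(cut_sets)


def partition_sse(X: np.ndarray, labels) -> float:
    """Within-cluster sum of squared distances to cluster means."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    sse = 0.0
    for lab in np.unique(labels):
        pts = X[labels == lab]
        sse += float(((pts - pts.mean(0)) ** 2).sum())
    return sse


def _all_partition_sse(X: np.ndarray, parts: np.ndarray, k: int) -> np.ndarray:
    """Vectorized within-cluster SSE for every partition in ``parts``."""
    onehot = (parts[:, :, None] == np.arange(k)).astype(float)  # (P, 12, k)
    counts = onehot.sum(1)  # (P, k)
    sums = np.einsum("pnk,nd->pkd", onehot, X)
    means = sums / counts[:, :, None]
    # SSE = sum ||x||^2 - sum_k n_k ||mean_k||^2
    total = float((X ** 2).sum())
    return total - (counts * (means ** 2).sum(-1)).sum(1)


def contiguous_partition_oracle(X, k: int) -> np.ndarray:
    """Exhaustive SSE-optimal circularly contiguous k-arc partition.

    Enumerates every cut-set and returns the arc labeling with the lowest
    within-cluster SSE; ties break to the lexicographically smallest cut-set.
    This is the exact solver the heuristic pipeline is measured against.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != MONTHS:
        raise ValueError(f"expected a {MONTHS}xd matrix, got {X.shape}")
    parts, _ = _contiguous_partitions(k)
    sse = _all_partition_sse(X, parts, k)
    return parts[int(np.argmin(sse))].copy()  # argmin keeps the lexicographically first tie


def enforce_contiguity(labels, X) -> np.ndarray:
    """Project k-means labels onto the nearest circularly contiguous partition.

    Among all contiguous k-arc partitions, picks the one disagreeing with the
    input labeling in the fewest months (arcs matched to input clusters by
    optimal assignment); ties resolve to the lower within-cluster SSE on
    ``X``, then to the lexicographically smallest cut-set.  Already-contiguous
    input is returned unchanged; output reuses the input's label values.
    """
    labels = np.asarray(labels)
    X = np.asarray(X, dtype=float)
    uniq = np.unique(labels)
    k = len(uniq)
    if n_circular_runs(labels) <= k:
        return labels.copy()
    parts, _ = _contiguous_partitions(k)
    sse = _all_partition_sse(X, parts, k)
    best = None  # (hamming, sse, p, perm)
    for p in range(parts.shape[0]):
        arcs = parts[p]
        agree = np.zeros((k, k))
        for j in range(k):
            for i, lab in enumerate(uniq):
                agree[j, i] = np.sum((arcs == j) & (labels == lab))
        rows, cols = linear_sum_assignment(-agree)
        hamming = MONTHS - int(agree[rows, cols].sum())
        key = (hamming, sse[p])
        if best is None or key < best[:2]:
            best = (hamming, sse[p], p, cols)
    _, _, p, perm = best
    out = np.empty(MONTHS, dtype=labels.dtype)
    for j in range(k):
        out[parts[p] == j] = uniq[perm[j]]
    return out


# ---------------------------------------------------------------------------
# naming and the per-pixel pipeline

def _arcs_in_circular_order(labels: np.ndarray) -> list[np.ndarray]:
    """Split a contiguous labeling into its arcs, ordered circularly from the
    arc containing January's run start."""
    labels = np.asarray(labels)
    starts = np.nonzero(labels != np.roll(labels, 1))[0]
    if len(starts) == 0:
        return [np.arange(MONTHS)]
    arcs = []
    for j, s in enumerate(sorted(starts)):
        e = sorted(starts)[j + 1] if j + 1 < len(starts) else sorted(starts)[0] + MONTHS
        arcs.append(np.arange(s, e) % MONTHS)
    return arcs


def name_seasons(labels, pixel: PixelClimate, zone: Zone) -> SeasonCalendar:
    """Turn anonymous cluster indices into the zone's named seasons.

    Two-season zones are named by contrast: the warmer cluster is summer
    (arctic) or hotter (desert), the rainier one wet (tropical).  Temperate
    arcs are anchored on the extreme months: the arc containing the coldest
    month is winter and the arc containing the warmest month is summer
    (anchoring on midwinter/midsummer is robust to arcs of unequal length,
    where a long cold arc's mean is dragged up by its shoulder months); the
    arc running forward from winter to summer is spring and the remaining arc
    autumn.  If the extremes fall in one arc, arc means decide instead, and
    if winter and summer end up adjacent the two transitional arcs are told
    apart by their mean temperature tendency (warming = spring).
    """
    labels = np.asarray(labels)
    out = np.zeros(MONTHS, dtype=np.uint8)

    if zone in (Zone.ARCTIC_MONTANE, Zone.DESERT, Zone.TROPICAL):
        uniq = list(np.unique(labels))
        if zone == Zone.TROPICAL:
            hi, lo = SeasonLabel.WET, SeasonLabel.DRY
            contrast = pixel.precip
        else:
            hi = SeasonLabel.SUMMER if zone == Zone.ARCTIC_MONTANE else SeasonLabel.HOTTER
            lo = SeasonLabel.WINTER if zone == Zone.ARCTIC_MONTANE else SeasonLabel.COOLER
            contrast = pixel.tmid
        if len(uniq) == 1:
            # degenerate single cluster: pick the label the annual mean suggests
            if zone == Zone.TROPICAL:
                out[:] = hi if float(pixel.aridity.mean()) >= 1.0 else lo
            else:
                out[:] = hi if float(pixel.tmid.mean()) >= 0.0 else lo
            return SeasonCalendar(zone=zone, labels=out)
        means = {lab: float(contrast[labels == lab].mean()) for lab in uniq}
        warm = max(uniq, key=lambda lab: (means[lab], -lab))
        out[labels == warm] = hi
        out[labels != warm] = lo
        return SeasonCalendar(zone=zone, labels=out)

    if zone != Zone.TEMPERATE:
        raise ValueError(f"unknown zone {zone!r}")
    arcs = _arcs_in_circular_order(labels)
    if len(arcs) != 4:
        raise ValueError(f"temperate naming needs 4 contiguous arcs, got {len(arcs)}")
    arc_of_month = np.empty(MONTHS, dtype=int)
    for j, a in enumerate(arcs):
        arc_of_month[a] = j
    wi = int(arc_of_month[int(np.argmin(pixel.tmid))])
    su = int(arc_of_month[int(np.argmax(pixel.tmid))])
    if wi == su:  # extremes in one arc (near-flat climate): fall back to arc means
        tmeans = [float(pixel.tmid[a].mean()) for a in arcs]
        wi = int(np.argmin(tmeans))
        su = int(np.argmax(tmeans))
        if wi == su:
            su = (wi + 2) % 4
    order = [(wi + j) % 4 for j in range(4)]  # circular order starting at winter
    pos_su = order.index(su)
    between = [order[j] for j in range(1, pos_su)]          # winter -> summer
    after = [order[j] for j in range(pos_su + 1, 4)]        # summer -> winter
    if len(between) == 1 and len(after) == 1:
        spring, autumn = between[0], after[0]
    else:
        # degenerate adjacency: the warming transitional arc is spring
        rest = between + after
        tend = [float(pixel.lag_tmid[arcs[j]].mean()) for j in rest]
        spring = rest[int(np.argmax(tend))]
        autumn = rest[1 - int(np.argmax(tend))]
    season_of_arc = {wi: SeasonLabel.WINTER, su: SeasonLabel.SUMMER,
                     spring: SeasonLabel.SPRING, autumn: SeasonLabel.AUTUMN}
    for j, a in enumerate(arcs):
        out[a] = season_of_arc[j]
    return SeasonCalendar(zone=Zone.TEMPERATE, labels=out)


def classify_pixel(
    pixel: PixelClimate,
    params: Params | None = None,
    *,
    seed: int = 0,
    restarts: int = 50,
) -> SeasonCalendar:
    """Full per-pixel pipeline: zone, features, clustering, contiguity, names.

    Deterministic for a given seed.  Temperate pixels that cannot support four
    distinct clusters (near-constant climate) fall back to the exhaustive
    contiguous-partition solver, which always yields four nonempty arcs.
    """
    params = params or Params()
    zone = classify_zone(pixel, params.thresholds)
    X = build_feature_matrix(pixel, zone, params.weights)
    k = ZONE_K[zone]
    n_distinct = len(np.unique(X, axis=0))
    if zone == Zone.TROPICAL:
        if n_distinct < k:
            labels = np.zeros(MONTHS, dtype=int)
        else:
            labels = kmeans_months(X, k, seed=seed, restarts=restarts)
    else:
        if n_distinct < k:
            labels = contiguous_partition_oracle(X, k)
        else:
            labels = kmeans_months(X, k, seed=seed, restarts=restarts)
            labels = enforce_contiguity(labels, X)
    return name_seasons(labels, pixel, zone)


def classify_raster(
    stack: ClimateStack,
    params: Params | None = None,
    *,
    seed: int = 0,
    restarts: int = 50,
) -> SeasonRaster:
    """Apply :func:`classify_pixel` to every valid cell of a stack."""
    params = params or Params()
    zones = zone_map(stack, params.thresholds)
    h, w = stack.shape
    codes = np.zeros((MONTHS, h, w), dtype=np.uint8)
    for row, col in zip(*np.nonzero(stack.mask)):
        cal = classify_pixel(
            extract_pixel(stack, int(col), int(row)), params, seed=seed, restarts=restarts
        )
        codes[:, row, col] = cal.labels
    return SeasonRaster(
        codes=codes, zones=zones, mask=stack.mask.copy(),
        transform=stack.transform, crs=stack.crs,
    )
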