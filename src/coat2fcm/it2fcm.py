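"""Interval type-2 intuitionistic fuzzy c-means clustering.

Classic fuzzy c-means (FCM) assigns each pattern x_i a membership

    u_ij = [ sum_k (d_ij / d_ik)^(2/(m-1)) ]^(-1)

to cluster j, controlled by one fuzzifier m > 1.  The interval type-2
variant uses a *pair* of fuzzifiers (m1, m2): evaluating the FCM
membership under each exponent yields two values whose min and max bound
an interval [u_lower, u_upper] — a footprint of uncertainty per (i, j).

Cluster centers then become intervals [v_left, v_right]: the extreme
weighted averages attainable when each pattern's weight may sit at
either end of its membership interval (raised to the effective fuzzifier
m = (m1 + m2) / 2).  The Karnik–Mendel construction finds those extremes
exactly; here they are computed by enumerating the switch points of the
sorted pattern values with prefix sums, which reaches the same fixed
point as the classic iterative scheme but in a single vectorized pass.

Type reduction and defuzzification are midpoints (of the centroid
interval and of the left/right memberships), after which the update
loop looks exactly like FCM — and collapses to FCM when m1 = m2.

The optional *intuitionistic* step widens hesitancy: each membership
bound u is replaced by u + pi(u) with the Yager-class hesitation degree
pi(u) = 1 - u - (1 - u^alpha)^(1/alpha), which vanishes at u = 0, u = 1
and for alpha = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    DegenerateClusterError,
    DegenerateInputError,
    InvalidArgumentError,
)

__all__ = [
    "FuzzifierPair",
    "MembershipInterval",
    "LeftRightMembership",
    "CentroidInterval",
    "ClusterModel",
    "membership_bounds",
    "apply_hesitation",
    "karnik_mendel",
    "type_reduce",
    "defuzzify_membership",
    "objective",
    "it2fcm_fit",
    "fcm_fit",
]


@dataclass(frozen=True)
class FuzzifierPair:
    """The two fuzzifier exponents; stored so m1 <= m2, both > 1."""

    m1: float
    m2: float

    def __post_init__(self) -> None:
        if self.m1 <= 1 or self.m2 <= 1:
            raise InvalidArgumentError("fuzzifiers must both be > 1")
        if self.m1 > self.m2:
            lo, hi = self.m2, self.m1
            object.__setattr__(self, "m1", lo)
            object.__setattr__(self, "m2", hi)

    @property
    def effective(self) -> float:
        """Single exponent used for Karnik–Mendel weights and the objective."""
        return 0.5 * (self.m1 + self.m2)


@dataclass(frozen=True)
class MembershipInterval:
    """Lower/upper membership grids over patterns x clusters."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        if self.lower.shape != self.upper.shape:
            raise InvalidArgumentError("lower/upper shapes differ")
        if (self.lower > self.upper + 1e-12).any():
            raise InvalidArgumentError("lower membership exceeds upper")


@dataclass(frozen=True)
class LeftRightMembership:
    """Per-(pattern, cluster) memberships chosen by the left/right extremes."""

    left: np.ndarray
    right: np.ndarray


@dataclass(frozen=True)
class CentroidInterval:
    """Per-cluster, per-feature centroid interval [v_left, v_right]."""

    v_left: np.ndarray
    v_right: np.ndarray

    def __post_init__(self) -> None:
        if (self.v_left > self.v_right + 1e-12).any():
            raise InvalidArgumentError("v_left exceeds v_right")


@dataclass(frozen=True)
class ClusterModel:
    """Result of a fit: crisp centroids/memberships and the objective value."""

    centroids: np.ndarray  # (C, M)
    memberships: np.ndarray  # (N, C), rows sum to 1
    fuzzifiers: FuzzifierPair
    objective: float
    iterations_run: int

    def labels(self) -> np.ndarray:
        """Hard labels by maximum membership; ties go to the lower index."""
        return np.argmax(self.memberships, axis=1)


def _as_matrix(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.ndim != 2 or x.size == 0 or not np.isfinite(x).all():
        raise InvalidArgumentError("feature matrix must be finite, 2-D, non-empty")
    return x


def _sq_distances(x: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances, (N, C)."""
    diff = x[:, None, :] - v[None, :, :]
    return np.einsum("ncm,ncm->nc", diff, diff)


def _fcm_membership(d2: np.ndarray, m: float) -> np.ndarray:
    """Classic FCM membership from squared distances; crisp at d = 0."""
    n, c = d2.shape
    u = np.zeros((n, c))
    zero_rows = (d2 <= 0.0).any(axis=1)
    if zero_rows.any():
        hit = d2[zero_rows] <= 0.0
        # crisp assignment to the first coincident cluster
        first = np.argmax(hit, axis=1)
        u[np.flatnonzero(zero_rows), first] = 1.0
    ok = ~zero_rows
    if ok.any():
        ratio = d2[ok][:, :, None] / d2[ok][:, None, :]  # (n_ok, C, C)
        u[ok] = 1.0 / np.power(ratio, 1.0 / (m - 1.0)).sum(axis=2)
    return u


def membership_bounds(
    x: np.ndarray, v: np.ndarray, f: FuzzifierPair
) -> MembershipInterval:
    """Lower/upper membership bounds from the two fuzzifiers.

    Each fuzzifier gives an ordinary FCM membership matrix; the upper
    bound is the elementwise max of the two and the lower bound the min.
    A pattern coinciding with a centroid is crisply assigned there.
    """
    x = _as_matrix(x)
    v = np.asarray(v, dtype=float)
    if v.ndim == 1:
        v = v[:, None]
    if not np.isfinite(v).all():
        raise InvalidArgumentError("centroids must be finite")
    d2 = _sq_distances(x, v)
    u1 = _fcm_membership(d2, f.m1)
    u2 = _fcm_membership(d2, f.m2)
    return MembershipInterval(lower=np.minimum(u1, u2), upper=np.maximum(u1, u2))


def apply_hesitation(mi: MembershipInterval, alpha: float) -> MembershipInterval:
    """Add the Yager-class hesitation degree to both membership bounds.

    u -> u + pi(u) with pi(u) = 1 - u - (1 - u^alpha)^(1/alpha), i.e. the
    Yager complement of the non-membership.  The map is monotone in u, so
    lower <= upper is preserved; results are clipped to [0, 1].
    """
    if alpha <= 0:
        raise InvalidArgumentError("hesitation alpha must be > 0")

    def _shift(u: np.ndarray) -> np.ndarray:
        u = np.clip(u, 0.0, 1.0)
        return np.clip(1.0 - (1.0 - u**alpha) ** (1.0 / alpha), 0.0, 1.0)

    return MembershipInterval(lower=_shift(mi.lower), upper=_shift(mi.upper))


def _km_extreme(
    xcol: np.ndarray,
    w_low: np.ndarray,
    w_up: np.ndarray,
    order: np.ndarray,
    side: str,
) -> tuple[float, np.ndarray]:
    """Extreme weighted average over interval weights, plus the bound choice.

    For the left (minimum) endpoint the optimum puts the upper weight on
    patterns below a switch point of the sorted values and the lower
    weight above it; for the right endpoint the roles swap.  All N + 1
    switch points are scored with prefix sums and the extreme taken,
    which equals the Karnik–Mendel fixed point.

    Returns the extreme value and a boolean vector (original pattern
    order) that is True where the *upper* bound was used.
    """
    xs = xcol[order]
    lo = w_low[order]
    up = w_up[order]
    if side == "left":
        head, tail = up, lo  # big weights on small values pull the mean down
    else:
        head, tail = lo, up
    num_head = np.concatenate(([0.0], np.cumsum(head * xs)))
    den_head = np.concatenate(([0.0], np.cumsum(head)))
    num_tail = np.concatenate(([0.0], np.cumsum((tail * xs)[::-1])))[::-1]
    den_tail = np.concatenate(([0.0], np.cumsum(tail[::-1])))[::-1]
    num = num_head + num_tail
    den = den_head + den_tail
    valid = den > 0
    if not valid.any():
        raise DegenerateClusterError("all membership weights are zero for a cluster")
    vals = np.where(valid, num / np.where(valid, den, 1.0), np.nan)
    if side == "left":
        k = int(np.nanargmin(vals))
    else:
        k = int(np.nanargmax(vals))
    used_upper_sorted = np.zeros(xs.shape[0], dtype=bool)
    if side == "left":
        used_upper_sorted[:k] = True
    else:
        used_upper_sorted[k:] = True
    used_upper = np.empty_like(used_upper_sorted)
    used_upper[order] = used_upper_sorted
    return float(vals[k]), used_upper


def karnik_mendel(
    x: np.ndarray,
    mi: MembershipInterval,
    f: FuzzifierPair,
    j: int,
    order: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, LeftRightMembership]:
    """Karnik–Mendel type reduction for cluster ``j``.

    Per feature, finds the minimum (v_left) and maximum (v_right)
    weighted average of the pattern values when each pattern's weight
    ranges over [lower_ij^m, upper_ij^m] with m the effective fuzzifier.
    Also reports, per pattern, the membership bound (lower or upper) the
    extremes selected, averaged over features — the left/right
    memberships used later for defuzzification.

    ``order`` may carry precomputed per-feature argsorts (M, N) to avoid
    re-sorting in inner loops.
    """
    x = _as_matrix(x)
    n, m_feat = x.shape
    w_low = mi.lower[:, j] ** f.effective
    w_up = mi.upper[:, j] ** f.effective
    v_left = np.empty(m_feat)
    v_right = np.empty(m_feat)
    left_u = np.empty((n, m_feat))
    right_u = np.empty((n, m_feat))
    for l in range(m_feat):
        ordr = np.argsort(x[:, l], kind="stable") if order is None else order[l]
        v_left[l], up_l = _km_extreme(x[:, l], w_low, w_up, ordr, "left")
        v_right[l], up_r = _km_extreme(x[:, l], w_low, w_up, ordr, "right")
        left_u[:, l] = np.where(up_l, mi.upper[:, j], mi.lower[:, j])
        right_u[:, l] = np.where(up_r, mi.upper[:, j], mi.lower[:, j])
    lr = LeftRightMembership(left=left_u.mean(axis=1), right=right_u.mean(axis=1))
    return v_left, v_right, lr


def type_reduce(ci: CentroidInterval) -> np.ndarray:
    """Crisp centroids: the elementwise midpoint (v_left + v_right) / 2."""
    return 0.5 * (ci.v_left + ci.v_right)


def defuzzify_membership(lr: LeftRightMembership) -> np.ndarray:
    """Crisp memberships: midpoint of left/right, rows renormalized to 1."""
    u = 0.5 * (np.asarray(lr.left, dtype=float) + np.asarray(lr.right, dtype=float))
    rows = u.sum(axis=1)
    if (rows <= 0).any():
        raise DegenerateInputError("a pattern has zero total membership")
    return u / rows[:, None]


def objective(
    x: np.ndarray, u: np.ndarray, v: np.ndarray, f: FuzzifierPair
) -> float:
    """Weighted within-cluster scatter J = sum_ij u_ij^m ||x_i - v_j||^2."""
    x = _as_matrix(x)
    v = np.asarray(v, dtype=float)
    if v.ndim == 1:
        v = v[:, None]
    d2 = _sq_distances(x, v)
    return float((np.asarray(u, dtype=float) ** f.effective * d2).sum())


def _full_iteration(
    x: np.ndarray,
    v: np.ndarray,
    f: FuzzifierPair,
    hesitation_alpha: float | None,
    order: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray]:
    """One membership -> KM -> type-reduction pass; returns (new v, crisp u)."""
    mi = membership_bounds(x, v, f)
    if hesitation_alpha is not None:
        mi = apply_hesitation(mi, hesitation_alpha)
    c = v.shape[0]
    n, m_feat = x.shape
    v_left = np.empty((c, m_feat))
    v_right = np.empty((c, m_feat))
    left = np.empty((n, c))
    right = np.empty((n, c))
    for j in range(c):
        v_left[j], v_right[j], lr = karnik_mendel(x, mi, f, j, order=order)
        left[:, j] = lr.left
        right[:, j] = lr.right
    new_v = type_reduce(CentroidInterval(v_left=v_left, v_right=v_right))
    u = defuzzify_membership(LeftRightMembership(left=left, right=right))
    return new_v, u


def _init_centroids(
    x: np.ndarray, c: int, seed: int, init_centroids: np.ndarray | None
) -> np.ndarray:
    if init_centroids is not None:
        v = np.asarray(init_centroids, dtype=float)
        if v.ndim == 1:
            v = v[:, None]
        if v.shape != (c, x.shape[1]):
            raise InvalidArgumentError("init_centroids shape must be (c, n_features)")
        return v.copy()
    # seeded sampling of c distinct patterns
    uniq = np.unique(x, axis=0)
    if uniq.shape[0] < c:
        raise InvalidArgumentError("fewer distinct patterns than clusters")
    rng = np.random.default_rng(seed)
    idx = rng.choice(uniq.shape[0], size=c, replace=False)
    return uniq[idx].astype(float)


def it2fcm_fit(
    x: np.ndarray,
    c: int,
    f: FuzzifierPair,
    init_centroids: np.ndarray | None = None,
    tol: float = 1e-5,
    max_iter: int = 100,
    hesitation_alpha: float | None = None,
    seed: int = 0,
) -> ClusterModel:
    """Fit interval type-2 (intuitionistic) fuzzy c-means.

    Alternates membership bounds, optional hesitation widening,
    Karnik–Mendel reduction per cluster, and midpoint defuzzification
    until the largest centroid displacement drops below ``tol`` or
    ``max_iter`` is reached.

    Parameters
    ----------
    x : array (N, M) or (N,)
        Feature matrix.
    c : int
        Number of clusters, 1 <= c <= N.
    f : FuzzifierPair
        The fuzzifier pair (m1, m2); m1 = m2 recovers classic FCM.
    init_centroids : array (c, M), optional
        Starting centroids; by default c distinct patterns sampled with
        the given seed.
    hesitation_alpha : float, optional
        Enables the intuitionistic hesitation step with this alpha;
        ``None`` (default) disables it.
    """
    x = _as_matrix(x)
    if c < 1 or c > x.shape[0]:
        raise InvalidArgumentError("need 1 <= c <= number of patterns")
    if tol <= 0 or max_iter < 1:
        raise InvalidArgumentError("tol must be > 0 and max_iter >= 1")
    v = _init_centroids(x, c, seed, init_centroids)
    order = np.vstack(
        [np.argsort(x[:, l], kind="stable") for l in range(x.shape[1])]
    )
    u = np.full((x.shape[0], c), 1.0 / c)
    it = 0
    for it in range(1, max_iter + 1):
        new_v, u = _full_iteration(x, v, f, hesitation_alpha, order)
        shift = np.abs(new_v - v).max()
        v = new_v
        if shift < tol:
            break
    return ClusterModel(
        centroids=v,
        memberships=u,
        fuzzifiers=f,
        objective=objective(x, u, v, f),
        iterations_run=it,
    )


def fcm_fit(
    x: np.ndarray,
    c: int,
    m: float = 2.0,
    init_centroids: np.ndarray | None = None,
    tol: float = 1e-5,
    max_iter: int = 100,
    seed: int = 0,
) -> ClusterModel:
    """Classic fuzzy c-means (single fuzzifier), the conventional baseline.

    Uses the standard alternating updates u_ij from inverse-distance
    ratios and v_j as the u^m-weighted mean.  Serves both as a baseline
    segmenter and as the degenerate reference for m1 = m2 type-2 runs.
    """
    if m <= 1:
        raise InvalidArgumentError("fuzzifier must be > 1")
    x = _as_matrix(x)
    if c < 1 or c > x.shape[0]:
        raise InvalidArgumentError("need 1 <= c <= number of patterns")
    v = _init_centroids(x, c, seed, init_centroids)
    u = np.full((x.shape[0], c), 1.0 / c)
    it = 0
    for it in range(1, max_iter + 1):
        u = _fcm_membership(_sq_distances(x, v), m)
        w = u**m
        den = w.sum(axis=0)
        if (den <= 0).any():
            raise DegenerateClusterError("a cluster lost all membership mass")
        new_v = (w.T @ x) / den[:, None]
        shift = np.abs(new_v - v).max()
        v = new_v
        if shift < tol:
            break
    pair = FuzzifierPair(m, m)
    return ClusterModel(
        centroids=v,
        memberships=u,
        fuzzifiers=pair,
        objective=objective(x, u, v, pair),
        iterations_run=it,
    )
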