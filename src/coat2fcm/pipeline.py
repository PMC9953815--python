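"""COA-T2FCM segmentation pipeline and the FCM / k-means baselines.

A candidate solution for the chimp optimizer is the flat vector

    [ v_11 .. v_1M, ..., v_C1 .. v_CM, m1, m2 ]

— C cluster centers (bounded by the per-feature data range) followed by
the fuzzifier pair (bounded to [1.1, 5.0]).  Its fitness is the
interval type-2 fuzzy c-means objective after a single cheap inner
membership/type-reduction pass, so the swarm searches jointly over
centers *and* fuzzifiers.  The best vector then seeds a short full
IT2FCM refinement, pixels are labelled by maximum crisp membership, and
the lesion mask is the cluster with the brightest (highest-intensity)
centroid — lesions are hyperintense on mammograms.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from . import it2fcm as t2
from .choa import ChoaParams, choa_optimize
from .errors import DegenerateClusterError, InvalidArgumentError
from .it2fcm import ClusterModel, FuzzifierPair
from .preprocess import INTENSITY_RANGE

__all__ = [
    "FUZZIFIER_BOUNDS",
    "LesionRule",
    "SolutionEncoding",
    "SegmentationResult",
    "image_to_features",
    "features_to_labels_grid",
    "fitness_from_encoding",
    "coa_t2fcm_segment",
    "fcm_segment",
    "kmeans_segment",
]

FUZZIFIER_BOUNDS = (1.1, 5.0)
_SPATIAL_WEIGHT = 0.25  # spatial channels scaled to w * INTENSITY_RANGE


class LesionRule(enum.Enum):
    BRIGHTEST_CENTROID = "brightest_centroid"
    LARGEST_MEAN_MEMBERSHIP = "largest_mean_membership"


@dataclass(frozen=True)
class SolutionEncoding:
    """Flat search vector layout for (centroids, fuzzifiers)."""

    c: int
    m: int  # features per pattern
    bounds: np.ndarray  # (c*m + 2, 2)

    @classmethod
    def for_features(cls, x: np.ndarray, c: int) -> "SolutionEncoding":
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        m = x.shape[1]
        lo = np.repeat(x.min(axis=0)[None, :], c, axis=0).ravel()
        hi = np.repeat(x.max(axis=0)[None, :], c, axis=0).ravel()
        bounds = np.empty((c * m + 2, 2))
        bounds[: c * m, 0] = lo
        bounds[: c * m, 1] = hi
        bounds[c * m :] = FUZZIFIER_BOUNDS
        return cls(c=c, m=m, bounds=bounds)

    def decode(self, vector: np.ndarray) -> tuple[np.ndarray, FuzzifierPair]:
        vector = np.asarray(vector, dtype=float)
        if vector.shape != (self.c * self.m + 2,):
            raise InvalidArgumentError(
                f"encoding expects length {self.c * self.m + 2}, got {vector.shape}"
            )
        centroids = vector[: self.c * self.m].reshape(self.c, self.m)
        m_lo, m_hi = sorted(vector[self.c * self.m :])
        return centroids, FuzzifierPair(m_lo, m_hi)

    def encode(self, centroids: np.ndarray, f: FuzzifierPair) -> np.ndarray:
        return np.concatenate([np.ravel(centroids), [f.m1, f.m2]])


@dataclass(frozen=True)
class SegmentationResult:
    """Label map, lesion mask and the model that produced them."""

    labels: np.ndarray  # (H, W) ints in [0, c)
    lesion_mask: np.ndarray  # (H, W) in {0, 1}
    centroids: np.ndarray
    fuzzifiers: FuzzifierPair
    objective: float
    lesion_cluster: int
    provenance: dict[str, Any] = field(default_factory=dict)


def image_to_features(
    image: np.ndarray, use_spatial: bool = False
) -> tuple[np.ndarray, tuple[int, int]]:
    """Flatten an image into a pattern matrix, row-major.

    Default: one intensity feature per pixel.  With ``use_spatial`` two
    extra channels (row/H, col/W scaled to ``_SPATIAL_WEIGHT`` times the
    intensity range) let spatially coherent clusters form.  Returns the
    feature matrix and the image shape needed to map labels back.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise InvalidArgumentError("expected a 2-D grayscale image")
    h, w = image.shape
    intens = image.reshape(-1, 1)
    if not use_spatial:
        return intens, (h, w)
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    scale = _SPATIAL_WEIGHT * INTENSITY_RANGE
    feats = np.column_stack(
        [intens[:, 0], (yy / h).ravel() * scale, (xx / w).ravel() * scale]
    )
    return feats, (h, w)


def features_to_labels_grid(labels: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Inverse of the row-major flattening for per-pattern labels."""
    return np.asarray(labels).reshape(shape)


#: Reference exponent used to *score* candidates during the swarm search.
#: The raw objective sum u^m d^2 is monotone decreasing in the fuzzifier
#: (u < 1), so scoring each candidate with its own exponent would reward
#: large fuzzifiers regardless of clustering quality; evaluating every
#: candidate's state under one fixed exponent puts them on a common scale.
SCORE_FUZZIFIER = FuzzifierPair(2.0, 2.0)


def fitness_from_encoding(
    vector: np.ndarray,
    x: np.ndarray,
    enc: SolutionEncoding,
    hesitation_alpha: float | None = None,
    km_refine_iters: int = 1,
    order: np.ndarray | None = None,
    score_fuzzifier: FuzzifierPair | None = SCORE_FUZZIFIER,
) -> float:
    """Clustering objective of a decoded candidate after a few inner passes.

    The candidate's own fuzzifier pair drives the membership bounds and
    type reduction; the resulting state is then scored with the
    objective under ``score_fuzzifier`` (pass ``None`` to score under
    the candidate's own pair).  One inner pass (default) keeps each
    swarm evaluation cheap; the final polish happens once, after the
    search.  Deterministic in its inputs, and invariant to permuting
    the centroid blocks.
    """
    centroids, f = enc.decode(vector)
    v = centroids
    u = None
    for _ in range(km_refine_iters):
        try:
            v, u = t2._full_iteration(x, v, f, hesitation_alpha, order)
        except DegenerateClusterError:
            return float(np.inf)  # caller treats unusable candidates as worst
    if u is None:
        mi = t2.membership_bounds(x, v, f)
        if hesitation_alpha is not None:
            mi = t2.apply_hesitation(mi, hesitation_alpha)
        u = t2.defuzzify_membership(
            t2.LeftRightMembership(left=mi.lower, right=mi.upper)
        )
    return t2.objective(x, u, v, score_fuzzifier if score_fuzzifier is not None else f)


def _labels_and_mask(
    model: ClusterModel,
    shape: tuple[int, int],
    rule: LesionRule,
) -> tuple[np.ndarray, np.ndarray, int]:
    labels = features_to_labels_grid(model.labels(), shape)
    if rule is LesionRule.BRIGHTEST_CENTROID:
        lesion = int(np.argmax(model.centroids[:, 0]))  # feature 0 = intensity
    else:
        lesion = int(np.argmax(model.memberships.mean(axis=0)))
    mask = (labels == lesion).astype(np.uint8)
    return labels, mask, lesion


def _check_c(image: np.ndarray, c: int) -> None:
    if c < 1:
        raise InvalidArgumentError("need at least one cluster")
    n_distinct = np.unique(np.asarray(image, dtype=float)).size
    if c > n_distinct:
        raise InvalidArgumentError(
            f"c={c} exceeds the {n_distinct} distinct pixel values"
        )


def coa_t2fcm_segment(
    image: np.ndarray,
    c: int = 3,
    choa_params: ChoaParams | None = None,
    final_refine_iters: int = 10,
    lesion_rule: LesionRule = LesionRule.BRIGHTEST_CENTROID,
    hesitation_alpha: float | None = 2.0,
    use_spatial: bool = False,
    seed: int = 0,
) -> SegmentationResult:
    """Segment an image with chimp-optimized IT2FCM.

    The chimp swarm minimizes the clustering objective over cluster
    centers and the fuzzifier pair; the winning solution is refined by
    ``final_refine_iters`` full IT2FCM iterations before labelling.

    ``hesitation_alpha`` enables the intuitionistic hesitation widening
    (default alpha = 2; pass ``None`` for plain interval type-2).
    ``choa_params`` defaults to a 12-chimp, 30-iteration search over the
    data box, seeded by ``seed``.
    """
    if c < 2:
        raise InvalidArgumentError("segmentation needs c >= 2")
    _check_c(image, c)
    x, shape = image_to_features(image, use_spatial)
    enc = SolutionEncoding.for_features(x, c)
    if choa_params is None:
        choa_params = ChoaParams(bounds=enc.bounds, pop_size=12, iterations=30, seed=seed)
    else:
        choa_params = ChoaParams(
            bounds=enc.bounds,
            pop_size=choa_params.pop_size,
            iterations=choa_params.iterations,
            f_start=choa_params.f_start,
            f_end=choa_params.f_end,
            mu_threshold=choa_params.mu_threshold,
            chaotic_map=choa_params.chaotic_map,
            chaos_init=choa_params.chaos_init,
            seed=choa_params.seed,
            opposition_init=choa_params.opposition_init,
        )
    order = np.vstack([np.argsort(x[:, l], kind="stable") for l in range(x.shape[1])])

    def fitness(vec: np.ndarray) -> float:
        val = fitness_from_encoding(
            vec, x, enc, hesitation_alpha=hesitation_alpha, order=order
        )
        return val if np.isfinite(val) else 1e300

    best_vec, _, trace = choa_optimize(fitness, choa_params)
    centroids, f = enc.decode(best_vec)
    model = t2.it2fcm_fit(
        x,
        c,
        f,
        init_centroids=centroids,
        tol=1e-6,
        max_iter=final_refine_iters,
        hesitation_alpha=hesitation_alpha,
        seed=seed,
    )
    labels, mask, lesion = _labels_and_mask(model, shape, lesion_rule)
    return SegmentationResult(
        labels=labels,
        lesion_mask=mask,
        centroids=model.centroids,
        fuzzifiers=model.fuzzifiers,
        objective=model.objective,
        lesion_cluster=lesion,
        provenance={
            "method": "coa-t2fcm",
            "c": c,
            "seed": seed,
            "hesitation_alpha": hesitation_alpha,
            "use_spatial": use_spatial,
            "choa": {
                "pop_size": choa_params.pop_size,
                "iterations": choa_params.iterations,
                "seed": choa_params.seed,
            },
            "trace": [float(t) for t in trace],
            "final_fuzzifiers": [model.fuzzifiers.m1, model.fuzzifiers.m2],
            "iterations_run": model.iterations_run,
        },
    )


def fcm_segment(
    image: np.ndarray,
    c: int = 3,
    m: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 100,
    lesion_rule: LesionRule = LesionRule.BRIGHTEST_CENTROID,
    use_spatial: bool = False,
    seed: int = 0,
) -> SegmentationResult:
    """Classic fuzzy c-means baseline with the same labelling rule."""
    if c < 2:
        raise InvalidArgumentError("segmentation needs c >= 2")
    _check_c(image, c)
    x, shape = image_to_features(image, use_spatial)
    model = t2.fcm_fit(x, c, m=m, tol=tol, max_iter=max_iter, seed=seed)
    labels, mask, lesion = _labels_and_mask(model, shape, lesion_rule)
    return SegmentationResult(
        labels=labels,
        lesion_mask=mask,
        centroids=model.centroids,
        fuzzifiers=model.fuzzifiers,
        objective=model.objective,
        lesion_cluster=lesion,
        provenance={"method": "fcm", "c": c, "m": m, "seed": seed,
                    "iterations_run": model.iterations_run},
    )


def _kmeans_fit(
    x: np.ndarray, c: int, tol: float, max_iter: int, seed: int
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Lloyd's algorithm with seeded distinct-pattern initialization.

    Returns (centroids, labels, per-iteration SSE trace).  Kept in-house
    (rather than delegating) so the trace and the exact seeded
    initialization match the other segmenters; cross-checked against
    scikit-learn in the test suite.
    """
    uniq = np.unique(x, axis=0)
    if uniq.shape[0] < c:
        raise InvalidArgumentError("fewer distinct patterns than clusters")
    rng = np.random.default_rng(seed)
    v = uniq[rng.choice(uniq.shape[0], size=c, replace=False)].astype(float)
    sse_trace: list[float] = []
    labels = np.zeros(x.shape[0], dtype=int)
    for _ in range(max_iter):
        d2 = ((x[:, None, :] - v[None, :, :]) ** 2).sum(axis=2)
        labels = np.argmin(d2, axis=1)
        sse_trace.append(float(d2[np.arange(x.shape[0]), labels].sum()))
        new_v = v.copy()
        for j in range(c):
            sel = labels == j
            if sel.any():
                new_v[j] = x[sel].mean(axis=0)
        if np.abs(new_v - v).max() < tol:
            v = new_v
            break
        v = new_v
    return v, labels, sse_trace


def kmeans_segment(
    image: np.ndarray,
    c: int = 3,
    tol: float = 1e-5,
    max_iter: int = 100,
    lesion_rule: LesionRule = LesionRule.BRIGHTEST_CENTROID,
    use_spatial: bool = False,
    seed: int = 0,
) -> SegmentationResult:
    """Hard k-means baseline (Lloyd's algorithm)."""
    if c < 1:
        raise InvalidArgumentError("need at least one cluster")
    _check_c(image, c)
    x, shape = image_to_features(image, use_spatial)
    v, flat_labels, sse_trace = _kmeans_fit(x, c, tol, max_iter, seed)
    labels = features_to_labels_grid(flat_labels, shape)
    if lesion_rule is LesionRule.BRIGHTEST_CENTROID:
        lesion = int(np.argmax(v[:, 0]))
    else:
        counts = np.bincount(flat_labels, minlength=c)
        lesion = int(np.argmax(counts))
    mask = (labels == lesion).astype(np.uint8)
    return SegmentationResult(
        labels=labels,
        lesion_mask=mask,
        centroids=v,
        fuzzifiers=FuzzifierPair(1.0 + 1e-9, 1.0 + 1e-9),
        objective=sse_trace[-1],
        lesion_cluster=lesion,
        provenance={"method": "kmeans", "c": c, "seed": seed, "sse_trace": sse_trace},
    )
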