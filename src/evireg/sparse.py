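"""Sparse (feature-based) candidate registration.

Pipeline: keypoint detection + description (pluggable detector families
behind a uniform adapter), nearest-neighbour matching with Lowe's ratio
test, robust mismatch removal by RANSAC or MSAC over 4-point minimal
samples, and a final least-squares projective fit on the consensus inliers.

Registered detector families (scikit-image implementations): ``sift``,
``orb`` and ``censure-brief`` (CENSURE keypoints with BRIEF descriptors).
Adapters normalise keypoint coordinates to this package's (v, w) =
(column, row) convention; binary descriptors are compared with the Hamming
metric, float descriptors with the Euclidean metric.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Callable

import numpy as np
from scipy.spatial.distance import cdist
from skimage import feature as skf

from .geometry import (
    DegenerateConfigurationError,
    GeometryError,
    ProjectiveTransform,
    estimate_projective_exact,
    estimate_projective_ls,
    reprojection_errors,
)
from .image import as_image

__all__ = [
    "KeypointSet",
    "MatchSet",
    "SparseConfig",
    "SparseRegistrationError",
    "detect_features",
    "match_features",
    "remove_mismatches",
    "register_sparse",
    "DETECTORS",
]


class SparseRegistrationError(RuntimeError):
    """A sparse-pipeline stage failed; the message is stage-labelled."""


@dataclasses.dataclass
class KeypointSet:
    detector: str
    coords: np.ndarray  # (n, 2) as (v, w) = (column, row)
    descriptors: np.ndarray  # (n, d); bool for binary families
    metric: str  # "hamming" | "euclidean"

    def __len__(self) -> int:
        return len(self.coords)


@dataclasses.dataclass
class MatchSet:
    ref_idx: np.ndarray
    sen_idx: np.ndarray
    distance: np.ndarray
    inlier: np.ndarray | None = None  # set by remove_mismatches

    def __len__(self) -> int:
        return len(self.ref_idx)


def _adapt(detector_name: str, keypoints_rc: np.ndarray, descriptors) -> KeypointSet:
    desc = np.asarray(descriptors)
    metric = "hamming" if desc.dtype == bool else "euclidean"
    coords = keypoints_rc[:, ::-1].astype(np.float64)  # (row, col) -> (v, w)
    return KeypointSet(detector_name, coords, desc, metric)


def _detect_sift(img: np.ndarray, **params) -> KeypointSet:
    det = skf.SIFT(**params)
    det.detect_and_extract(img)
    return _adapt("sift", det.keypoints, det.descriptors.astype(np.float64))


def _detect_orb(
    img: np.ndarray, n_keypoints: int = 2000, fast_threshold: float = 0.01, **params
) -> KeypointSet:
    # FAST threshold lowered from the library's 0.08: low-contrast textures
    # yield too few corners otherwise, starving the consensus stage
    det = skf.ORB(n_keypoints=n_keypoints, fast_threshold=fast_threshold, **params)
    det.detect_and_extract(img)
    return _adapt("orb", det.keypoints, det.descriptors)


def _detect_censure_brief(
    img: np.ndarray, non_max_threshold: float = 0.02, **params
) -> KeypointSet:
    # default response threshold lowered from the library's 0.15: the
    # box-filter response on low-contrast textures rarely clears it
    det = skf.CENSURE(non_max_threshold=non_max_threshold, **params)
    det.detect(img)
    extractor = skf.BRIEF(patch_size=25)
    extractor.extract(img, det.keypoints)
    kept = det.keypoints[extractor.mask]
    return _adapt("censure-brief", kept, extractor.descriptors)


DETECTORS: dict[str, Callable[..., KeypointSet]] = {
    "sift": _detect_sift,
    "orb": _detect_orb,
    "censure-brief": _detect_censure_brief,
}


def detect_features(img, detector: str, **params) -> KeypointSet:
    """Run a registered detector family; deterministic for fixed input/params."""
    img = as_image(img, check_size=True)
    try:
        fn = DETECTORS[detector]
    except KeyError:
        raise SparseRegistrationError(
            f"detect: unknown detector {detector!r}; registered: {sorted(DETECTORS)}"
        ) from None
    try:
        return fn(img, **params)
    except RuntimeError:
        # scikit-image raises when nothing is detected; empty set, caller decides
        return KeypointSet(detector, np.empty((0, 2)), np.empty((0, 0), bool), "hamming")


def match_features(ref: KeypointSet, sen: KeypointSet, ratio: float = 0.8) -> MatchSet:
    """Nearest-neighbour matching with Lowe's ratio test, one-to-one resolved.

    A reference keypoint matches its nearest sensed keypoint iff
    nearest / second-nearest distance <= ratio (equidistant pair: rejected
    for any ratio < 1).  The final set is made one-to-one greedily by
    ascending distance.  With a single sensed keypoint the ratio test
    degenerates to accepting the nearest (a warning is emitted).
    """
    if not 0.0 < ratio <= 1.0:
        raise SparseRegistrationError("match: ratio must be in (0, 1]")
    if len(ref) == 0 or len(sen) == 0:
        raise SparseRegistrationError("match: empty keypoint set")
    if ref.metric != sen.metric or ref.descriptors.shape[1] != sen.descriptors.shape[1]:
        raise SparseRegistrationError("match: descriptor types are incompatible")
    d = cdist(
        np.asarray(ref.descriptors, float), np.asarray(sen.descriptors, float),
        metric=ref.metric,
    )
    candidates = []
    if len(sen) < 2:
        warnings.warn("single sensed keypoint: ratio test degenerates", stacklevel=2)
        for i in range(len(ref)):
            candidates.append((d[i, 0], i, 0))
    else:
        order = np.argsort(d, axis=1, kind="stable")
        for i in range(len(ref)):
            j1, j2 = order[i, 0], order[i, 1]
            d1, d2 = d[i, j1], d[i, j2]
            if d2 == 0.0:  # both exact: ambiguous
                continue
            if d1 / d2 <= ratio:
                candidates.append((d1, i, int(j1)))
    # greedy best-distance-first one-to-one resolution
    candidates.sort(key=lambda t: (t[0], t[2]))
    used_ref: set[int] = set()
    used_sen: set[int] = set()
    ref_idx, sen_idx, dist = [], [], []
    for dd, i, j in candidates:
        if i in used_ref or j in used_sen:
            continue
        used_ref.add(i)
        used_sen.add(j)
        ref_idx.append(i)
        sen_idx.append(j)
        dist.append(dd)
    return MatchSet(np.array(ref_idx, int), np.array(sen_idx, int), np.array(dist))


def remove_mismatches(
    matches: MatchSet,
    ref: KeypointSet,
    sen: KeypointSet,
    method: str = "msac",
    threshold_px: float = 2.0,
    max_iter: int = 2000,
    seed: int = 0,
) -> tuple[MatchSet, ProjectiveTransform]:
    """Robust consensus over 4-point minimal samples (RANSAC or MSAC).

    RANSAC scores a hypothesis by its inlier count, MSAC by the truncated
    squared reprojection loss.  The winning inlier set gets a final
    least-squares re-fit.  Deterministic given the seed.
    """
    if len(matches) < 4:
        raise SparseRegistrationError("consensus: need at least 4 matches")
    if method not in ("ransac", "msac"):
        raise SparseRegistrationError(f"consensus: unknown method {method!r}")
    p_ref = ref.coords[matches.ref_idx]
    p_sen = sen.coords[matches.sen_idx]
    rng = np.random.default_rng(seed)
    n = len(matches)
    thr2 = threshold_px**2
    best_score = -np.inf
    best_inliers: np.ndarray | None = None
    for _ in range(max_iter):
        pick = rng.choice(n, size=4, replace=False)
        try:
            T = estimate_projective_exact(p_ref[pick], p_sen[pick])
        except (DegenerateConfigurationError, GeometryError):
            continue
        err2 = reprojection_errors(T, p_ref, p_sen) ** 2
        err2 = np.nan_to_num(err2, nan=np.inf)
        inliers = err2 <= thr2
        if method == "ransac":
            score = float(inliers.sum())
        else:
            score = -float(np.minimum(err2, thr2).sum())
        if score > best_score:
            best_score = score
            best_inliers = inliers
    if best_inliers is None or best_inliers.sum() < 4:
        raise SparseRegistrationError("consensus: no model with >= 4 inliers found")
    T_fit = estimate_projective_ls(p_ref[best_inliers], p_sen[best_inliers])
    # consensus set of the refit model
    err2 = np.nan_to_num(reprojection_errors(T_fit, p_ref, p_sen) ** 2, nan=np.inf)
    final_inliers = err2 <= thr2
    if final_inliers.sum() >= 4:
        T_fit = estimate_projective_ls(p_ref[final_inliers], p_sen[final_inliers])
    else:
        final_inliers = best_inliers
    out = MatchSet(
        matches.ref_idx.copy(), matches.sen_idx.copy(), matches.distance.copy(),
        inlier=final_inliers,
    )
    return out, T_fit


@dataclasses.dataclass
class SparseConfig:
    """Sparse-pipeline knobs (paper-unspecified; declared defaults)."""

    ratio: float = 0.8
    method: str = "msac"
    threshold_px: float = 2.0
    max_iter: int = 2000
    seed: int = 0
    # a projective fit on fewer inliers than this is treated as a stage
    # failure: 4 inliers determine any hypothesis exactly, so consensus
    # only means something with redundancy
    min_inliers: int = 6
    detector_params: dict = dataclasses.field(default_factory=dict)


def register_sparse(
    R,
    S,
    detector: str,
    config: SparseConfig | None = None,
) -> tuple[ProjectiveTransform, dict]:
    """Full sparse chain: detect -> match -> consensus -> LS fit.

    Returns the transform mapping reference coordinates to sensed
    coordinates, plus stage diagnostics (keypoint / match / inlier counts).
    """
    cfg = config or SparseConfig()
    R = as_image(R, check_size=True)
    S = as_image(S, check_size=True)
    kp_ref = detect_features(R, detector, **cfg.detector_params)
    kp_sen = detect_features(S, detector, **cfg.detector_params)
    if len(kp_ref) < 4 or len(kp_sen) < 4:
        raise SparseRegistrationError(
            f"detect[{detector}]: too few keypoints ({len(kp_ref)} ref, {len(kp_sen)} sen)"
        )
    matches = match_features(kp_ref, kp_sen, ratio=cfg.ratio)
    if len(matches) < 4:
        raise SparseRegistrationError(
            f"match[{detector}]: only {len(matches)} ratio-test survivors"
        )
    inliers, T = remove_mismatches(
        matches, kp_ref, kp_sen,
        method=cfg.method, threshold_px=cfg.threshold_px,
        max_iter=cfg.max_iter, seed=cfg.seed,
    )
    n_inl = int(inliers.inlier.sum())
    if n_inl < cfg.min_inliers:
        raise SparseRegistrationError(
            f"consensus[{detector}]: only {n_inl} inliers (< {cfg.min_inliers})"
        )
    diag = {
        "detector": detector,
        "keypoints_ref": len(kp_ref),
        "keypoints_sen": len(kp_sen),
        "matches": len(matches),
        "inliers": int(inliers.inlier.sum()),
    }
    return T, diag
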