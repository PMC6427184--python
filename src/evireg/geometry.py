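"""Projective-transform algebra, image warping and transform estimation.

Coordinate convention (used everywhere in this package): a point is
``(v, w) = (column index, row index)``, 0-based, with pixel centers at
integer coordinates.  Transforms act on ROW homogeneous vectors by
right-multiplication::

    [g  h  1] ~ [v  w  1] @ T

so composition "apply T1 then T2" is the matrix product ``T1 @ T2``.
Third-party routines that use the column-vector convention (e.g.
scikit-image, where ``x' = H x``) relate to this one by transposition;
any such conversion happens at a single adapter boundary.

The rigid (3-DOF) model is parameterised by an anticlockwise rotation
angle in degrees and two translations, with matrix::

    [ cos t   sin t   0 ]
    [-sin t   cos t   0 ]
    [  tv      th     1 ]

Estimation from point correspondences offers the exact 4-point solver
(Cramer-style 8x8 linear system) and least squares for n >= 4 via the
Hartley-normalised direct linear transform, optionally refined by
Levenberg-Marquardt on the geometric reprojection cost.
"""

from __future__ import annotations

import dataclasses
import json
import math
from typing import Sequence

import numpy as np
from scipy import ndimage, optimize

from .image import as_image

__all__ = [
    "ProjectiveTransform",
    "RigidParams",
    "GeometryError",
    "DegenerateConfigurationError",
    "rigid_to_matrix",
    "matrix_to_rigid",
    "translation",
    "identity",
    "warp_image",
    "estimate_projective_exact",
    "estimate_projective_ls",
]

_DET_TOL = 1e-12


class GeometryError(ValueError):
    pass


class DegenerateConfigurationError(GeometryError):
    """Point configuration cannot determine a projective transform."""


@dataclasses.dataclass(frozen=True)
class ProjectiveTransform:
    """3x3 projective transform acting on row homogeneous coordinates."""

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.shape != (3, 3):
            raise GeometryError(f"expected a 3x3 matrix, got {m.shape}")
        if not np.all(np.isfinite(m)):
            raise GeometryError("matrix has non-finite entries")
        if m[2, 2] != 0.0:
            m = m / m[2, 2]  # canonical gauge t33 = 1
        if abs(np.linalg.det(m)) <= _DET_TOL:
            raise GeometryError("matrix is singular")
        m.flags.writeable = False
        object.__setattr__(self, "matrix", m)

    # -- algebra ---------------------------------------------------------
    def apply(self, points) -> np.ndarray:
        """Map (n, 2) points (v, w) -> (g, h); rows on the line at infinity give nan."""
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        hom = np.hstack([pts, np.ones((len(pts), 1))]) @ self.matrix
        s = hom[:, 2]
        bad = np.abs(s) < 1e-12
        with np.errstate(divide="ignore", invalid="ignore"):
            out = hom[:, :2] / s[:, None]
        out[bad] = np.nan
        return out

    def inverse(self) -> "ProjectiveTransform":
        return ProjectiveTransform(np.linalg.inv(self.matrix))

    def compose(self, other: "ProjectiveTransform") -> "ProjectiveTransform":
        """Apply self first, then ``other``."""
        return ProjectiveTransform(self.matrix @ other.matrix)

    # -- structure -------------------------------------------------------
    def is_affine(self, tol: float = 1e-10) -> bool:
        return abs(self.matrix[0, 2]) <= tol and abs(self.matrix[1, 2]) <= tol

    def is_similarity(self, tol: float = 1e-10) -> bool:
        m = self.matrix
        return (
            self.is_affine(tol)
            and abs(m[0, 0] - m[1, 1]) <= tol
            and abs(m[0, 1] + m[1, 0]) <= tol
        )

    def almost_equals(self, other: "ProjectiveTransform", tol: float = 1e-9) -> bool:
        return bool(np.allclose(self.matrix, other.matrix, atol=tol))

    # -- serialization ---------------------------------------------------
    def to_json_dict(self) -> dict:
        return {
            "convention": "row-vector",
            "matrix": [float(x) for x in self.matrix.ravel()],
        }

    @classmethod
    def from_json_dict(cls, d) -> "ProjectiveTransform":
        if d.get("convention") != "row-vector":
            raise GeometryError(
                "refusing transform without a 'convention': 'row-vector' tag"
            )
        return cls(np.asarray(d["matrix"], dtype=np.float64).reshape(3, 3))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "ProjectiveTransform":
        with open(path) as fh:
            return cls.from_json_dict(json.load(fh))


def identity() -> ProjectiveTransform:
    return ProjectiveTransform(np.eye(3))


def translation(a: float, b: float) -> ProjectiveTransform:
    """Pure translation (v, w) -> (v + a, w + b)."""
    m = np.eye(3)
    m[2, 0] = a
    m[2, 1] = b
    return ProjectiveTransform(m)


@dataclasses.dataclass(frozen=True)
class RigidParams:
    """Rigid motion: anticlockwise rotation ``theta`` (degrees) then translation."""

    theta: float
    tv: float
    th: float

    def __post_init__(self):
        if not -180.0 < self.theta <= 180.0:
            raise GeometryError("theta must lie in (-180, 180] degrees")

    def as_array(self) -> np.ndarray:
        return np.array([self.theta, self.tv, self.th])


def rigid_to_matrix(
    p: RigidParams, center: tuple[float, float] = (0.0, 0.0)
) -> ProjectiveTransform:
    """Rigid matrix: rotate by theta about ``center``, then translate by (tv, th).

    With the default origin center this is the plain similarity form with
    unit scale; rotating about the image center instead keeps simulated
    pairs mostly in-frame, matching how simulated sensed images are usually
    produced.  The parameter triple is unchanged either way.
    """
    t = math.radians(p.theta)
    c, s = math.cos(t), math.sin(t)
    cv, cw = center
    # translation making `center` the fixed point of the rotation part
    tv = p.tv + cv - (cv * c - cw * s)
    th = p.th + cw - (cv * s + cw * c)
    return ProjectiveTransform(
        np.array([[c, s, 0.0], [-s, c, 0.0], [tv, th, 1.0]])
    )


def matrix_to_rigid(
    T: ProjectiveTransform,
    center: tuple[float, float] = (0.0, 0.0),
    tol: float = 1e-9,
) -> RigidParams:
    m = T.matrix
    if not T.is_similarity(tol):
        raise GeometryError("transform is not a similarity")
    scale = math.hypot(m[0, 0], m[0, 1])
    if abs(scale - 1.0) > 1e-6:
        raise GeometryError(f"similarity has scale {scale}, not rigid")
    theta = math.degrees(math.atan2(m[0, 1], m[0, 0]))
    if theta <= -180.0:
        theta += 360.0
    c, s = m[0, 0], m[0, 1]
    cv, cw = center
    tv = float(m[2, 0]) - cv + (cv * c - cw * s)
    th = float(m[2, 1]) - cw + (cv * s + cw * c)
    return RigidParams(theta=theta, tv=tv, th=th)


def image_center(shape: tuple[int, int]) -> tuple[float, float]:
    """(v, w) center of an (M, N) image: ((N-1)/2, (M-1)/2)."""
    return ((shape[1] - 1) / 2.0, (shape[0] - 1) / 2.0)


def warp_image(
    S,
    T: ProjectiveTransform,
    out_shape: tuple[int, int] | None = None,
    interpolation: str = "bilinear",
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse-mapping warp: output pixel p samples S at T(p).

    For each output pixel (v', w') the source location (g, h) = T((v', w'))
    is resampled from S; sources falling outside S fill with 0 and mask 0.
    Returns ``(warped, mask)`` with mask 1 where the source was in-bounds.
    """
    S = as_image(S)
    M, N = out_shape if out_shape is not None else S.shape
    order = {"nearest": 0, "bilinear": 1}.get(interpolation)
    if order is None:
        raise GeometryError(f"unknown interpolation {interpolation!r}")
    ww, vv = np.mgrid[0:M, 0:N]  # w = row, v = column
    pts = np.column_stack([vv.ravel(), ww.ravel()]).astype(np.float64)
    src = T.apply(pts)  # (g, h) per output pixel
    g = src[:, 0].reshape(M, N)
    h = src[:, 1].reshape(M, N)
    eps = 1e-9  # tolerate fp residue at the frame boundary (e.g. T o T^-1)
    valid = (
        np.isfinite(g)
        & np.isfinite(h)
        & (g >= -eps)
        & (g <= S.shape[1] - 1 + eps)
        & (h >= -eps)
        & (h <= S.shape[0] - 1 + eps)
    )
    g = np.clip(np.nan_to_num(g), 0, S.shape[1] - 1)
    h = np.clip(np.nan_to_num(h), 0, S.shape[0] - 1)
    coords = np.stack([h, g])  # (row, col) order
    warped = ndimage.map_coordinates(S, coords, order=order, mode="constant", cval=0.0)
    warped = np.where(valid, warped, 0.0)
    return np.clip(warped, 0.0, 1.0), valid.astype(np.float64)


# ---------------------------------------------------------------------------
# estimation from correspondences


def _check_correspondences(ref, sen, min_pairs: int):
    ref = np.atleast_2d(np.asarray(ref, dtype=np.float64))
    sen = np.atleast_2d(np.asarray(sen, dtype=np.float64))
    if ref.shape != sen.shape or ref.shape[1] != 2:
        raise GeometryError("correspondence arrays must both be (n, 2)")
    if len(ref) < min_pairs:
        raise GeometryError(f"need at least {min_pairs} correspondences, got {len(ref)}")
    return ref, sen


def _has_collinear_triple(pts: np.ndarray, tol: float = 1e-8) -> bool:
    n = len(pts)
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(j + 1, n):
                a, b, c = pts[i], pts[j], pts[k]
                area = abs(
                    (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
                )
                if area < tol:
                    return True
    return False


def estimate_projective_exact(ref, sen) -> ProjectiveTransform:
    """Unique projective transform through exactly 4 correspondences.

    Solves the 8-equation linear system for t11..t32 with t33 = 1; no three
    reference points may be collinear.
    """
    ref, sen = _check_correspondences(ref, sen, 4)
    if len(ref) != 4:
        raise GeometryError("the exact solver takes exactly 4 pairs")
    if _has_collinear_triple(ref):
        raise DegenerateConfigurationError("three reference points are collinear")
    A = np.zeros((8, 8))
    b = np.zeros(8)
    for i, ((v, w), (g, h)) in enumerate(zip(ref, sen)):
        # unknowns: t11 t21 t31 t12 t22 t32 t13 t23  (t33 = 1)
        A[2 * i] = [v, w, 1, 0, 0, 0, -g * v, -g * w]
        b[2 * i] = g
        A[2 * i + 1] = [0, 0, 0, v, w, 1, -h * v, -h * w]
        b[2 * i + 1] = h
    try:
        x = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise DegenerateConfigurationError(str(exc)) from exc
    m = np.array(
        [[x[0], x[3], x[6]], [x[1], x[4], x[7]], [x[2], x[5], 1.0]]
    )
    return ProjectiveTransform(m)


def _hartley_normalizer(pts: np.ndarray) -> np.ndarray:
    """Row-vector similarity taking the points to zero centroid, mean norm sqrt(2)."""
    centroid = pts.mean(axis=0)
    d = np.sqrt(((pts - centroid) ** 2).sum(axis=1)).mean()
    s = math.sqrt(2.0) / d if d > 0 else 1.0
    return np.array(
        [[s, 0, 0], [0, s, 0], [-s * centroid[0], -s * centroid[1], 1.0]]
    )


def _dlt(ref: np.ndarray, sen: np.ndarray) -> ProjectiveTransform:
    nr = _hartley_normalizer(ref)
    ns = _hartley_normalizer(sen)
    rn = np.hstack([ref, np.ones((len(ref), 1))]) @ nr
    sn = np.hstack([sen, np.ones((len(sen), 1))]) @ ns
    A = np.zeros((2 * len(ref), 9))
    for i, ((v, w, _), (g, h, _)) in enumerate(zip(rn, sn)):
        # unknown order: t11 t12 t13 t21 t22 t23 t31 t32 t33 (row-major T)
        A[2 * i] = [v, 0, -g * v, w, 0, -g * w, 1, 0, -g]
        A[2 * i + 1] = [0, v, -h * v, 0, w, -h * w, 0, 1, -h]
    _, sv, vt = np.linalg.svd(A)
    if sv[-2] < 1e-12:
        raise DegenerateConfigurationError("rank-deficient correspondence system")
    t_norm = vt[-1].reshape(3, 3)
    m = nr @ t_norm @ np.linalg.inv(ns)
    if abs(m[2, 2]) < 1e-12:
        raise DegenerateConfigurationError("estimated transform has t33 ~ 0")
    return ProjectiveTransform(m)


def estimate_projective_ls(
    ref,
    sen,
    refine: bool = True,
    cost: str = "squared",
    max_iter: int = 100,
) -> ProjectiveTransform:
    """Least-squares projective estimate from n >= 4 correspondences.

    Hartley-normalised DLT seed, then (by default) Levenberg-Marquardt
    refinement of the sum of squared reprojection distances; pass
    ``cost='absolute'`` for the literal sum of (non-squared) Euclidean
    distances, minimised via a smooth soft-L1 loss.  Noise-free consistent
    input is recovered exactly (to numerical precision) by the DLT alone.
    """
    ref, sen = _check_correspondences(ref, sen, 4)
    T0 = _dlt(ref, sen)
    if not refine:
        return T0

    def residuals(x):
        m = np.append(x, 1.0).reshape(3, 3)
        hom = np.hstack([ref, np.ones((len(ref), 1))]) @ m
        proj = hom[:, :2] / hom[:, 2:3]
        return (proj - sen).ravel()

    x0 = T0.matrix.ravel()[:8]
    loss = "linear" if cost == "squared" else "soft_l1"
    try:
        sol = optimize.least_squares(
            residuals, x0, method="lm" if loss == "linear" else "trf",
            loss=loss, max_nfev=max_iter * 9,
        )
        m = np.append(sol.x, 1.0).reshape(3, 3)
        return ProjectiveTransform(m)
    except (GeometryError, np.linalg.LinAlgError):
        return T0  # refinement failed; fall back to the DLT seed


def reprojection_errors(T: ProjectiveTransform, ref, sen) -> np.ndarray:
    """Per-pair Euclidean distance between T(ref) and sen."""
    ref, sen = _check_correspondences(ref, sen, 1)
    proj = T.apply(ref)
    return np.sqrt(((proj - sen) ** 2).sum(axis=1))
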