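"""Dense (intensity-based) candidate registration over the rigid parameter space.

The rigid model has three parameters (rotation angle about the reference
image center by default, plus two translations); the optimum of a chosen
similarity measure (MI, NCC or PSNR) is located by a deterministic
two-stage search:

1. an exhaustive coarse grid evaluated on a block-averaged pyramid level
   (min dimension ~64 px).  Per rotation angle the sensed image is warped
   once and the translation sweep runs as integer pixel shifts of that
   rotated image (a pre-rotation translation grid, converted back to the
   standard post-rotation parameters), which makes the full grid tractable;
2. Nelder-Mead simplex refinement of the full-resolution objective from
   the best coarse nodes; refinement never returns less than the
   full-resolution objective at the best coarse node.

The full projective dense search is deliberately out of scope: its
high-dimensional objective is intractable for direct search, which is
exactly the regime where the sparse route applies.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import optimize
from skimage.transform import downscale_local_mean

from .geometry import (
    ProjectiveTransform,
    RigidParams,
    image_center,
    matrix_to_rigid,
    rigid_to_matrix,
    warp_image,
)
from .image import as_image
from .similarity import MEASURES, _mi_codes, mse, ncc, quantize

__all__ = ["SearchConfig", "register_dense", "register_dense_multi"]


@dataclasses.dataclass
class SearchConfig:
    """Rigid-search bounds and steps (degrees / pixels, full-resolution scale)."""

    theta_bounds: tuple[float, float] = (-30.0, 30.0)
    trans_bounds: tuple[float, float] = (-30.0, 30.0)
    theta_step: float = 1.0
    trans_step: float = 2.0
    coarse_min_dim: int = 64  # pyramid level target for the coarse stage
    refine: bool = True
    refine_starts: int = 3  # distinct coarse nodes used as simplex seeds
    interpolation: str = "bilinear"
    # rotation center for the rigid model; None = reference-image center
    center: tuple[float, float] | None = None
    # evaluate the objective over the valid warp region only (recommended:
    # the out-of-frame fill value otherwise biases the optimum); False
    # gives the literal full-frame fill-0 objective
    masked: bool = True
    # reject hypotheses with less valid coverage; the default bounds keep
    # the true motion above ~0.55 coverage, so 0.5 excludes only the
    # small-overlap regime where sample-starved MI estimates inflate
    min_overlap: float = 0.5
    # MI binning for the coarse stage only: the pyramid level has few
    # pixels per overlap, so the full 256-bin joint histogram is sample
    # starved and its bias grows as overlap shrinks
    coarse_mi_bins: int = 32


def _coarse_level(shape: tuple[int, int], min_dim: int) -> int:
    ds = 1
    while min(shape) // (ds * 2) >= min_dim:
        ds *= 2
    return ds


def _shift_fill0(img: np.ndarray, a: int, b: int) -> np.ndarray:
    """out[w, v] = img[w + b, v + a] with zero fill (a: column, b: row)."""
    M, N = img.shape
    out = np.zeros_like(img)
    r0, r1 = max(0, b), min(M, M + b)
    c0, c1 = max(0, a), min(N, N + a)
    out[r0 - b:r1 - b, c0 - a:c1 - a] = img[r0:r1, c0:c1]
    return out


def _objective(R, S, measure_fns, params: np.ndarray, cfg: "SearchConfig", center):
    T = rigid_to_matrix(RigidParams(*params), center=center)
    warped, mask = warp_image(S, T, out_shape=R.shape, interpolation=cfg.interpolation)
    if not cfg.masked:
        return {name: fn(R, warped) for name, fn in measure_fns.items()}
    sel = mask > 0
    if sel.mean() < cfg.min_overlap:
        return {name: -np.inf for name in measure_fns}
    return {name: fn(R, warped, mask=sel) for name, fn in measure_fns.items()}


def register_dense_multi(
    R,
    S,
    measures: tuple[str, ...] = ("mi", "ncc", "psnr"),
    search: SearchConfig | None = None,
) -> dict[str, tuple[RigidParams, float, dict]]:
    """Run the rigid search for several measures at once, sharing every warp.

    Returns ``{measure: (params, value, diagnostics)}``; diagnostics carry
    the coarse-stage winner and its full-resolution objective value, so the
    no-regression contract (refined >= coarse start) is auditable.
    """
    cfg = search or SearchConfig()
    R = as_image(R, check_size=True)
    S = as_image(S, check_size=True)
    if np.ptp(R) == 0.0 or np.ptp(S) == 0.0:
        raise ValueError("dense registration is undefined for constant images")
    unknown = set(measures) - set(MEASURES)
    if unknown:
        raise ValueError(f"unknown measures: {sorted(unknown)}")
    if "psnr" in measures and abs(float(R.mean()) - float(S.mean())) > 0.25:
        warnings.warn(
            "PSNR with a large illumination offset is unreliable for registration",
            stacklevel=2,
        )
    measure_fns = {m: MEASURES[m] for m in measures}
    center = cfg.center if cfg.center is not None else image_center(R.shape)

    ds = _coarse_level(R.shape, cfg.coarse_min_dim)
    if ds > 1:
        Rc = np.clip(downscale_local_mean(R, (ds, ds)), 0.0, 1.0)
        Sc = np.clip(downscale_local_mean(S, (ds, ds)), 0.0, 1.0)
    else:
        Rc, Sc = R, S
    center_c = (center[0] / ds, center[1] / ds)

    thetas = np.arange(cfg.theta_bounds[0], cfg.theta_bounds[1] + 1e-9, cfg.theta_step)
    # translation sweep as integer shifts at the coarse level
    shift_step = max(1, round(cfg.trans_step / ds))
    smax = int(np.floor(cfg.trans_bounds[1] / ds))
    smin = int(np.ceil(cfg.trans_bounds[0] / ds))
    shifts = list(range(smin, smax + 1, shift_step))

    bins = cfg.coarse_mi_bins
    q_ref = quantize(Rc, bins) if "mi" in measures else None
    node_params: list[np.ndarray] = []
    values: dict[str, list[float]] = {m: [] for m in measures}
    for th in thetas:
        M0_full = rigid_to_matrix(RigidParams(float(th), 0.0, 0.0), center=center)
        M0_c = rigid_to_matrix(RigidParams(float(th), 0.0, 0.0), center=center_c)
        W0, mask0 = warp_image(Sc, M0_c, out_shape=Rc.shape,
                               interpolation=cfg.interpolation)
        for a in shifts:
            for b in shifts:
                shifted = _shift_fill0(W0, a, b)
                # full-resolution params equivalent to this coarse node
                pre = np.eye(3)
                pre[2, 0], pre[2, 1] = a * ds, b * ds
                node = matrix_to_rigid(
                    ProjectiveTransform(pre @ M0_full.matrix), center=center
                )
                node_params.append(node.as_array())
                if cfg.masked:
                    sel = _shift_fill0(mask0, a, b) > 0
                    if sel.mean() < cfg.min_overlap:
                        for m in measures:
                            values[m].append(-np.inf)
                        continue
                    rv, wv = Rc[sel], shifted[sel]
                else:
                    rv, wv = Rc.ravel(), shifted.ravel()
                for m in measures:
                    if m == "ncc":
                        values[m].append(ncc(rv[None, :], wv[None, :]))
                    elif m == "psnr":
                        d = rv - wv
                        e = float(np.mean(d * d))
                        values[m].append(
                            float("inf") if e == 0.0 else 10.0 * float(np.log10(1.0 / e))
                        )
                    else:  # mi
                        qa = q_ref[sel] if cfg.masked else q_ref.ravel()
                        values[m].append(_mi_codes(qa, quantize(wv, bins), bins))
    node_params = np.array(node_params)

    results = {}
    for m in measures:
        vals = np.array(values[m])
        order = np.argsort(vals)[::-1]
        starts = node_params[order[: max(1, cfg.refine_starts)]]
        best_params = starts[0]
        best_val = _objective(R, S, {m: measure_fns[m]}, starts[0], cfg, center)[m]
        coarse_start = (tuple(float(x) for x in starts[0]), best_val)
        if cfg.refine and np.isfinite(best_val):
            neg = lambda p: -_objective(  # noqa: E731
                R, S, {m: measure_fns[m]}, p, cfg, center
            )[m]
            for s in starts:
                init = np.asarray(s, float)
                sol = optimize.minimize(
                    neg, init, method="Nelder-Mead",
                    options={
                        "initial_simplex": init
                        + np.vstack([np.zeros(3), np.diag(
                            [cfg.theta_step, cfg.trans_step, cfg.trans_step]
                        )]),
                        "xatol": 0.01, "fatol": 1e-7, "maxiter": 300,
                    },
                )
                if np.isfinite(sol.fun) and -sol.fun > best_val:
                    best_val = -sol.fun
                    best_params = sol.x
        p = RigidParams(float(best_params[0]), float(best_params[1]), float(best_params[2]))
        results[m] = (p, float(best_val), {
            "coarse_level": ds,
            "coarse_start": coarse_start,
            "n_coarse_nodes": len(node_params),
            "center": tuple(center),
        })
    return results


def register_dense(
    R,
    S,
    measure: str = "ncc",
    search: SearchConfig | None = None,
) -> RigidParams:
    """Rigid parameters maximising one similarity measure (argmax of the search)."""
    return register_dense_multi(R, S, (measure,), search)[measure][0]
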