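"""Evidence construction and fusion for candidate transformations.

Each candidate transform T_i registers the sensed image into the reference
frame; the similarity between the reference and the registered image is
measured by NCC on three information channels (gray, Canny edge map,
phase-angle reconstruction).  Per channel, the NCCs are clamped to [0, 1],
contrast-stretched with y = e^x - 1, and normalised into a Bayesian BBA
over the candidate frame.  The three channel BBAs are fused (Dempster or
n-source PCR6) into a combined BBA m_c, and the combined transform is
formed in inverse space as the mass-weighted matrix average

    T_c^{-1} = sum_i m_c(T_i) * T_i^{-1}

with every inverse held in the canonical t33 = 1 gauge before averaging
(the average is gauge-sensitive; the choice is recorded in results).
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Sequence

import numpy as np

from .belief import (
    BBA,
    FrameOfDiscernment,
    combine_dempster,
    combine_pcr6,
    make_bba,
)
from .geometry import GeometryError, ProjectiveTransform, warp_image
from .image import as_image
from .similarity import ChannelKind, edge_channel, ncc, phase_channel

__all__ = [
    "ChannelSimilarities",
    "FusionError",
    "candidate_similarities",
    "build_channel_bbas",
    "fuse_bbas",
    "combined_transform",
]

CHANNEL_ORDER = (ChannelKind.GRAY, ChannelKind.EDGE, ChannelKind.PHASE)


class FusionError(RuntimeError):
    pass


@dataclasses.dataclass
class ChannelSimilarities:
    """Per-candidate NCC values on the three information channels."""

    labels: tuple[str, ...]
    ncc_gray: np.ndarray
    ncc_edge: np.ndarray
    ncc_phase: np.ndarray

    def __post_init__(self):
        q = len(self.labels)
        for arr in (self.ncc_gray, self.ncc_edge, self.ncc_phase):
            if len(arr) != q:
                raise FusionError("channel arrays must match the candidate count")
            if not np.all(np.isfinite(arr)):
                raise FusionError("non-finite channel similarity")
        if q < 2:
            raise FusionError("need at least two candidates")

    def channel(self, kind: ChannelKind) -> np.ndarray:
        return {
            ChannelKind.GRAY: self.ncc_gray,
            ChannelKind.EDGE: self.ncc_edge,
            ChannelKind.PHASE: self.ncc_phase,
        }[kind]

    def as_table(self) -> list[dict]:
        return [
            {
                "candidate": lab,
                "ncc_gray": float(self.ncc_gray[i]),
                "ncc_edge": float(self.ncc_edge[i]),
                "ncc_phase": float(self.ncc_phase[i]),
            }
            for i, lab in enumerate(self.labels)
        ]


def candidate_similarities(
    R,
    S,
    transforms: Sequence[ProjectiveTransform],
    labels: Sequence[str] | None = None,
    interpolation: str = "bilinear",
) -> tuple[ChannelSimilarities, list[ProjectiveTransform]]:
    """Warp S by each candidate and score the three channels against R.

    Channels are extracted independently from R and from each registered
    image; each channel NCC is evaluated over the candidate's valid warp
    region (pixels with no sensed-image source say nothing about how well
    the overlapping content aligns, and would otherwise reward overlap size
    over alignment quality).  Candidates whose warp fails, or covers almost
    none of the reference frame, are dropped with a warning; fewer than two
    survivors is an error.  Returns the similarities together with the
    surviving transforms (ordered as the labels).
    """
    R = as_image(R, check_size=True)
    S = as_image(S, check_size=True)
    transforms = list(transforms)
    if labels is None:
        labels = [f"T{i + 1}" for i in range(len(transforms))]
    labels = list(labels)
    if len(labels) != len(transforms):
        raise FusionError("labels and transforms must align")

    r_edge = edge_channel(R)
    r_phase = phase_channel(R)
    kept, g, e, p = [], [], [], []
    for lab, T in zip(labels, transforms):
        try:
            warped, mask = warp_image(
                S, T, out_shape=R.shape, interpolation=interpolation
            )
        except GeometryError as exc:
            warnings.warn(f"candidate {lab} dropped: warp failed ({exc})", stacklevel=2)
            continue
        sel = mask > 0
        if sel.mean() < 0.05:
            warnings.warn(
                f"candidate {lab} dropped: warp covers {sel.mean():.0%} of the frame",
                stacklevel=2,
            )
            continue
        kept.append((lab, T))
        g.append(ncc(R, warped, mask=sel))
        e.append(ncc(r_edge, edge_channel(warped), mask=sel))
        p.append(ncc(r_phase, phase_channel(warped), mask=sel))
    if len(kept) < 2:
        raise FusionError("fewer than two candidates survived warping")
    cs = ChannelSimilarities(
        tuple(lab for lab, _ in kept), np.array(g), np.array(e), np.array(p)
    )
    return cs, [T for _, T in kept]


def _stretch(x: np.ndarray) -> np.ndarray:
    """Clamp to [0, 1] then apply the e^x - 1 contrast stretch."""
    return np.expm1(np.clip(x, 0.0, 1.0))


def build_channel_bbas(cs: ChannelSimilarities) -> tuple[BBA, BBA, BBA]:
    """Bayesian BBAs (gray, edge, phase) from the per-channel NCC values.

    Negative NCCs carry no positive evidence and are clamped to zero before
    the stretch; a channel whose stretched values all vanish carries no
    evidence and falls back to the uniform Bayesian BBA (with a warning).
    """
    fod = FrameOfDiscernment(cs.labels)
    out = []
    for kind in CHANNEL_ORDER:
        y = _stretch(cs.channel(kind))
        total = float(y.sum())
        if total <= 0.0:
            warnings.warn(
                f"{kind.value} channel carries no evidence; uniform fallback",
                stacklevel=2,
            )
            masses = {(lab,): 1.0 / len(cs.labels) for lab in cs.labels}
        else:
            masses = {(lab,): float(v) / total for lab, v in zip(cs.labels, y)}
        out.append(make_bba(fod, masses))
    return tuple(out)


def fuse_bbas(m_g: BBA, m_e: BBA, m_p: BBA, rule: str = "pcr6") -> BBA:
    """Combine the three channel BBAs into m_c with the chosen rule."""
    if rule == "dempster":
        return combine_dempster(combine_dempster(m_g, m_e), m_p)
    if rule == "pcr6":
        return combine_pcr6([m_g, m_e, m_p])
    raise FusionError(f"unknown combination rule {rule!r}")


def combined_transform(
    m_c: BBA,
    transforms: Sequence[ProjectiveTransform],
    labels: Sequence[str] | None = None,
) -> ProjectiveTransform:
    """Mass-weighted inverse-matrix average of the candidates.

    Requires a Bayesian m_c (the average is defined over singletons); the
    inverses are t33-normalised before the weighted sum, and the sum is
    inverted and renormalised to give T_c.
    """
    if not m_c.is_bayesian():
        raise FusionError("combined transform needs a Bayesian combined BBA")
    transforms = list(transforms)
    if labels is None:
        labels = [f"T{i + 1}" for i in range(len(transforms))]
    acc = np.zeros((3, 3))
    total = 0.0
    for lab, T in zip(labels, transforms):
        w = m_c.mass((lab,))
        acc += w * T.inverse().matrix
        total += w
    if abs(total - 1.0) > 1e-6:
        raise FusionError("combined BBA does not cover the given candidates")
    try:
        inv = ProjectiveTransform(acc)
    except GeometryError as exc:
        raise FusionError(f"weighted inverse average is singular: {exc}") from exc
    return inv.inverse()
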