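"""Model/Results surface tying the candidate generators to the fusion chain.

``EvidentialRegistration`` is constructed from an image pair plus a mode
(sparse: one candidate per keypoint detector; dense: one candidate per
similarity measure; candidates: caller-supplied transforms) and a
combination rule.  ``fit`` runs the full chain — candidate generation,
three-channel NCC evidence, BBA construction, fusion, combined transform,
final warp — and returns a ``RegistrationResults`` carrying every
intermediate for audit, with a ``summary()`` table and ground-truth
evaluation helpers.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np

from . import __version__ as _pkg_version
from .belief import BBA
from .dense import SearchConfig, register_dense_multi
from .evaluation import EvaluationReport, evaluate_registration
from .fusion import (
    ChannelSimilarities,
    FusionError,
    build_channel_bbas,
    candidate_similarities,
    combined_transform,
    fuse_bbas,
)
from .geometry import ProjectiveTransform, rigid_to_matrix, warp_image
from .image import as_image
from .sparse import SparseConfig, SparseRegistrationError, register_sparse

__all__ = ["EvidentialRegistration", "RegistrationResults", "register_fused"]

DEFAULT_DETECTORS = ("sift", "orb", "censure-brief")
DEFAULT_MEASURES = ("mi", "psnr", "ncc")


@dataclasses.dataclass
class RegistrationResults:
    """Fitted registration: candidates, evidence, combined transform, diagnostics."""

    mode: str
    rule: str
    labels: tuple[str, ...]
    transforms: tuple[ProjectiveTransform, ...]
    channel_similarities: ChannelSimilarities
    bba_gray: BBA
    bba_edge: BBA
    bba_phase: BBA
    bba_combined: BBA
    transform: ProjectiveTransform  # T_c
    registered: np.ndarray  # S'_c in the reference frame
    mask: np.ndarray
    diagnostics: dict

    @property
    def combined_masses(self) -> dict[str, float]:
        return {lab: self.bba_combined.mass((lab,)) for lab in self.labels}

    def with_rule(self, rule: str, sen=None) -> "RegistrationResults":
        """Re-fuse the already-built channel BBAs under another rule.

        Candidate generation and channel evidence are shared; only the
        combination, the combined transform and (when the sensed image is
        given) the registered image are recomputed.
        """
        m_c = fuse_bbas(self.bba_gray, self.bba_edge, self.bba_phase, rule=rule)
        T_c = combined_transform(m_c, self.transforms, self.labels)
        if sen is not None:
            registered, mask = warp_image(sen, T_c, out_shape=self.registered.shape)
        else:
            registered, mask = self.registered, self.mask
        return dataclasses.replace(
            self, rule=rule, bba_combined=m_c, transform=T_c,
            registered=registered, mask=mask,
        )

    def evaluate(
        self,
        R,
        T_true: ProjectiveTransform,
        grid: tuple[int, int] = (5, 5),
        interpolation: str = "bilinear",
    ) -> EvaluationReport:
        """AAID report of the combined transform against the known truth."""
        return evaluate_registration(R, T_true, self.transform, grid, interpolation)

    def candidate_reports(
        self, R, T_true: ProjectiveTransform
    ) -> dict[str, EvaluationReport]:
        """Per-candidate AAID reports (single-generator baselines)."""
        return {
            lab: evaluate_registration(R, T_true, T)
            for lab, T in zip(self.labels, self.transforms)
        }

    def summary(self) -> str:
        cs = self.channel_similarities
        lines = [
            "Evidential registration results",
            "=" * 64,
            f"mode: {self.mode}    rule: {self.rule}    candidates: {len(self.labels)}",
            "",
            f"{'candidate':>14} {'NCC(G)':>8} {'NCC(E)':>8} {'NCC(P)':>8} {'m_c':>8}",
            "-" * 52,
        ]
        for i, lab in enumerate(self.labels):
            lines.append(
                f"{lab:>14} {cs.ncc_gray[i]:8.4f} {cs.ncc_edge[i]:8.4f}"
                f" {cs.ncc_phase[i]:8.4f} {self.combined_masses[lab]:8.4f}"
            )
        lines += ["", "combined transform T_c (row-vector convention):"]
        for row in self.transform.matrix:
            lines.append("   [" + "  ".join(f"{x:11.6f}" for x in row) + "]")
        return "\n".join(lines)

    def to_json_dict(self) -> dict:
        return {
            "package_version": _pkg_version,
            "mode": self.mode,
            "rule": self.rule,
            "candidates": {
                lab: T.to_json_dict() for lab, T in zip(self.labels, self.transforms)
            },
            "channel_ncc": self.channel_similarities.as_table(),
            "bbas": {
                "gray": self.bba_gray.to_json_dict(),
                "edge": self.bba_edge.to_json_dict(),
                "phase": self.bba_phase.to_json_dict(),
                "combined": self.bba_combined.to_json_dict(),
            },
            "transform": self.transform.to_json_dict(),
            "inverse_average_gauge": "t33=1",
            "diagnostics": self.diagnostics,
        }


class EvidentialRegistration:
    """Evidential-reasoning registration model for one image pair.

    Parameters
    ----------
    ref, sen : array-like
        Reference and sensed grayscale images with intensities in [0, 1].
    mode : {"sparse", "dense", "candidates"}
        Candidate-generation route: keypoint detectors, similarity-measure
        searches, or caller-supplied transforms.
    rule : {"pcr6", "dempster"}
        Combination rule for the three channel BBAs.
    detectors, measures : sequence of str
        Generator families for the respective mode.
    transforms, labels
        Pre-computed candidates for ``mode="candidates"``.
    """

    def __init__(
        self,
        ref,
        sen,
        mode: str = "sparse",
        rule: str = "pcr6",
        detectors: Sequence[str] = DEFAULT_DETECTORS,
        measures: Sequence[str] = DEFAULT_MEASURES,
        transforms: Sequence[ProjectiveTransform] | None = None,
        labels: Sequence[str] | None = None,
        sparse_config: SparseConfig | None = None,
        search_config: SearchConfig | None = None,
    ):
        self.ref = as_image(ref, check_size=True)
        self.sen = as_image(sen, check_size=True)
        if mode not in ("sparse", "dense", "candidates"):
            raise ValueError(f"unknown mode {mode!r}")
        if rule not in ("pcr6", "dempster"):
            raise ValueError(f"unknown rule {rule!r}")
        self.mode = mode
        self.rule = rule
        self.detectors = tuple(detectors)
        self.measures = tuple(measures)
        self.supplied_transforms = list(transforms) if transforms else None
        self.supplied_labels = list(labels) if labels else None
        self.sparse_config = sparse_config
        self.search_config = search_config

    # -- candidate generation -------------------------------------------
    def _candidates(self, seed: int) -> tuple[list[str], list[ProjectiveTransform], dict]:
        diag: dict = {}
        if self.mode == "candidates":
            if not self.supplied_transforms or len(self.supplied_transforms) < 2:
                raise FusionError("mode='candidates' needs >= 2 supplied transforms")
            labels = self.supplied_labels or [
                f"T{i + 1}" for i in range(len(self.supplied_transforms))
            ]
            return list(labels), list(self.supplied_transforms), diag
        if self.mode == "sparse":
            cfg = self.sparse_config or SparseConfig(seed=seed)
            labels, transforms = [], []
            for det in self.detectors:
                try:
                    T, d = register_sparse(self.ref, self.sen, det, cfg)
                except SparseRegistrationError as exc:
                    warnings.warn(f"candidate {det} dropped: {exc}", stacklevel=2)
                    diag[det] = {"status": "failed", "reason": str(exc)}
                    continue
                labels.append(det)
                transforms.append(T)
                diag[det] = {"status": "ok", **d}
            if len(transforms) < 2:
                raise FusionError(
                    "sparse: fewer than two detector candidates survived"
                )
            return labels, transforms, diag
        # dense
        multi = register_dense_multi(
            self.ref, self.sen, self.measures, self.search_config
        )
        labels, transforms = [], []
        for m in self.measures:
            params, value, d = multi[m]
            labels.append(m)
            transforms.append(rigid_to_matrix(params, center=d["center"]))
            diag[m] = {
                "status": "ok",
                "params": list(params.as_array()),
                "objective": value,
                **d,
            }
        return labels, transforms, diag

    # -- fit -------------------------------------------------------------
    def fit(self, seed: int = 0) -> RegistrationResults:
        """Run the full evidential chain and return the results object."""
        labels, transforms, gen_diag = self._candidates(seed)
        cs, kept = candidate_similarities(self.ref, self.sen, transforms, labels)
        m_g, m_e, m_p = build_channel_bbas(cs)
        m_c = fuse_bbas(m_g, m_e, m_p, rule=self.rule)
        T_c = combined_transform(m_c, kept, cs.labels)
        registered, mask = warp_image(self.sen, T_c, out_shape=self.ref.shape)
        return RegistrationResults(
            mode=self.mode,
            rule=self.rule,
            labels=cs.labels,
            transforms=tuple(kept),
            channel_similarities=cs,
            bba_gray=m_g,
            bba_edge=m_e,
            bba_phase=m_p,
            bba_combined=m_c,
            transform=T_c,
            registered=registered,
            mask=mask,
            diagnostics={"generation": gen_diag, "seed": seed},
        )


def register_fused(R, S, mode: str = "sparse", rule: str = "pcr6", seed: int = 0, **kwargs) -> RegistrationResults:
    """One-call fused registration (model construction + fit)."""
    return EvidentialRegistration(R, S, mode=mode, rule=rule, **kwargs).fit(seed=seed)
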