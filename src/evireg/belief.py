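"""Belief-function core: frames of discernment, mass functions and combination rules.

The frame of discernment (FOD) collects the mutually exclusive hypotheses —
in this package, candidate image transformations.  A basic belief assignment
(BBA, or mass function) distributes unit mass over non-empty subsets of the
frame.  Combination machinery covers the conjunctive rule, Dempster's rule
(conjunctive + renormalisation by the conflict), and the n-source PCR6 rule,
which redistributes each fully conflicting mass product back to its
contributors proportionally to their masses.  The pignistic transform is
provided for probabilistic read-out.

Subsets are encoded internally as bitmasks over the frame's fixed element
ordering, which gives exact set semantics and O(1) intersection.
"""

from __future__ import annotations

import itertools
import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from typing import Any

__all__ = [
    "FrameOfDiscernment",
    "BBA",
    "UnnormalizedBBA",
    "BeliefError",
    "TotalConflictError",
    "make_bba",
    "vacuous_bba",
    "belief",
    "plausibility",
    "combine_conjunctive",
    "combine_dempster",
    "combine_pcr6",
    "pignistic",
]

MASS_TOL = 1e-9
_CONFLICT_GUARD = 1e-12


class BeliefError(ValueError):
    """Invalid mass function or incompatible combination operands."""


class TotalConflictError(BeliefError):
    """Dempster's rule is undefined: the sources are in (near-)total conflict."""


@dataclass(frozen=True)
class FrameOfDiscernment:
    """Ordered frame of discernment Theta = {T1, ..., TQ}.

    Elements are opaque hashable labels; the ordering fixed at construction
    defines the canonical bitmask encoding of subsets.
    """

    elements: tuple[Any, ...]
    _index: dict[Any, int] = field(init=False, repr=False, compare=False)

    def __init__(self, elements: Iterable[Any]):
        elems = tuple(elements)
        if len(elems) < 2:
            raise BeliefError("frame needs at least two elements")
        if len(set(elems)) != len(elems):
            raise BeliefError("frame elements must be pairwise distinct")
        object.__setattr__(self, "elements", elems)
        object.__setattr__(self, "_index", {e: i for i, e in enumerate(elems)})

    def __len__(self) -> int:
        return len(self.elements)

    @property
    def full_mask(self) -> int:
        return (1 << len(self.elements)) - 1

    def mask(self, subset: Iterable[Any]) -> int:
        """Canonical bitmask of a subset given as an iterable of labels."""
        m = 0
        for e in subset:
            try:
                m |= 1 << self._index[e]
            except KeyError:
                raise BeliefError(f"{e!r} is not an element of the frame") from None
        return m

    def unmask(self, mask: int) -> frozenset:
        return frozenset(e for i, e in enumerate(self.elements) if mask >> i & 1)

    def subset_label(self, mask: int) -> str:
        return "|".join(str(e) for i, e in enumerate(self.elements) if mask >> i & 1)


def _as_mask(fod: FrameOfDiscernment, subset: int | Iterable[Any]) -> int:
    if isinstance(subset, int):
        if subset < 0 or subset > fod.full_mask:
            raise BeliefError("bitmask outside the frame")
        return subset
    return fod.mask(subset)


@dataclass(frozen=True)
class BBA:
    """Basic belief assignment: non-negative masses over non-empty subsets, summing to 1."""

    fod: FrameOfDiscernment
    masses: Mapping[int, float]  # bitmask -> mass, zero-mass entries omitted

    def __post_init__(self):
        object.__setattr__(
            self, "masses", {m: v for m, v in self.masses.items() if v != 0.0}
        )

    @property
    def focal_elements(self) -> list[int]:
        return sorted(self.masses)

    def mass(self, subset: int | Iterable[Any]) -> float:
        return self.masses.get(_as_mask(self.fod, subset), 0.0)

    def is_bayesian(self) -> bool:
        """True when every focal element is a singleton."""
        return all(m & (m - 1) == 0 for m in self.masses)

    # -- serialization ---------------------------------------------------
    def to_json_dict(self) -> dict:
        return {
            "fod": [str(e) for e in self.fod.elements],
            "masses": {
                self.fod.subset_label(m): v for m, v in sorted(self.masses.items())
            },
        }

    @classmethod
    def from_json_dict(cls, d: Mapping[str, Any]) -> "BBA":
        fod = FrameOfDiscernment(d["fod"])
        assignments = {
            tuple(key.split("|")): float(v) for key, v in d["masses"].items()
        }
        return make_bba(fod, assignments)


@dataclass(frozen=True)
class UnnormalizedBBA:
    """Conjunctive-combination intermediate: the empty set may carry the conflict mass."""

    fod: FrameOfDiscernment
    masses: Mapping[int, float]

    @property
    def conflict(self) -> float:
        """Total conflict K: the mass of the empty set."""
        return self.masses.get(0, 0.0)

    def mass(self, subset: int | Iterable[Any]) -> float:
        return self.masses.get(_as_mask(self.fod, subset), 0.0)


def make_bba(
    fod: FrameOfDiscernment,
    assignments: Mapping[Any, float],
) -> BBA:
    """Validate and build a BBA from a subset -> mass mapping.

    Subset keys may be bitmask ints or iterables of frame labels.  Masses are
    stored exactly as given: no silent renormalisation, so a sum differing
    from 1 beyond ``MASS_TOL`` raises.
    """
    masses: dict[int, float] = {}
    for key, value in assignments.items():
        mask = _as_mask(fod, key)
        if value < 0:
            raise BeliefError(f"negative mass {value} for subset {key!r}")
        if mask == 0 and value != 0:
            raise BeliefError("the empty set cannot carry mass")
        if mask in masses:
            raise BeliefError(f"duplicate subset key {key!r}")
        masses[mask] = float(value)
    total = math.fsum(masses.values())
    if abs(total - 1.0) > MASS_TOL:
        raise BeliefError(f"masses sum to {total!r}, expected 1 within {MASS_TOL}")
    return BBA(fod, masses)


def vacuous_bba(fod: FrameOfDiscernment) -> BBA:
    """The totally ignorant BBA: all mass on the full frame."""
    return BBA(fod, {fod.full_mask: 1.0})


def belief(bba: BBA, subset: int | Iterable[Any]) -> float:
    """Bel(A) = sum of masses of subsets of A."""
    a = _as_mask(bba.fod, subset)
    return math.fsum(v for m, v in bba.masses.items() if m & ~a == 0 and m != 0)


def plausibility(bba: BBA, subset: int | Iterable[Any]) -> float:
    """Pl(A) = sum of masses of focal elements intersecting A."""
    a = _as_mask(bba.fod, subset)
    return math.fsum(v for m, v in bba.masses.items() if m & a)


def _check_shared_fod(sources: Sequence[BBA]) -> FrameOfDiscernment:
    fod = sources[0].fod
    for s in sources[1:]:
        if s.fod.elements != fod.elements:
            raise BeliefError("sources must share the same frame of discernment")
    return fod


def combine_conjunctive(m1: BBA, m2: BBA) -> UnnormalizedBBA:
    """Conjunctive rule: m(A) = sum over B∩C=A of m1(B)·m2(C); conflict lands on ∅."""
    fod = _check_shared_fod([m1, m2])
    out: dict[int, float] = {}
    for b, vb in m1.masses.items():
        for c, vc in m2.masses.items():
            out[b & c] = out.get(b & c, 0.0) + vb * vc
    return UnnormalizedBBA(fod, out)


def combine_dempster(m1: BBA, m2: BBA) -> BBA:
    """Dempster's rule: conjunctive combination renormalised by 1/(1-K)."""
    conj = combine_conjunctive(m1, m2)
    k = conj.conflict
    if k > 1.0 - _CONFLICT_GUARD:
        raise TotalConflictError(f"total conflict K={k!r}; Dempster's rule undefined")
    scale = 1.0 / (1.0 - k)
    masses = {m: v * scale for m, v in conj.masses.items() if m != 0}
    return BBA(conj.fod, masses)


def combine_pcr6(sources: Sequence[BBA]) -> BBA:
    """n-source PCR6 combination.

    The conjunctive part keeps every n-tuple of focal elements with a
    non-empty common intersection; each fully conflicting tuple's product is
    redistributed to the tuple's members proportionally to the mass each
    source committed.  Total rule: defined even under total conflict.
    """
    sources = list(sources)
    if len(sources) < 2:
        raise BeliefError("PCR6 needs at least two sources")
    fod = _check_shared_fod(sources)
    out: dict[int, float] = {}
    focal_lists = [list(s.masses.items()) for s in sources]
    for combo in itertools.product(*focal_lists):
        inter = fod.full_mask
        product = 1.0
        for mask, v in combo:
            inter &= mask
            product *= v
        if inter:
            out[inter] = out.get(inter, 0.0) + product
        else:
            denom = math.fsum(v for _, v in combo)
            if denom == 0.0:
                continue
            for mask, v in combo:
                out[mask] = out.get(mask, 0.0) + product * v / denom
    total = math.fsum(out.values())
    if abs(total - 1.0) > 1e-6:
        raise BeliefError(f"PCR6 lost mass: total {total!r}")
    # compensate fp accumulation so downstream validation at MASS_TOL holds
    return BBA(fod, {m: v / total for m, v in out.items()})


def combine_pcr6_sequential(sources: Sequence[BBA]) -> BBA:
    """Pairwise left-fold of the two-source PCR6 rule.

    PCR6 is not associative, so this generally differs from the n-source
    form; provided as a configurable fallback.
    """
    sources = list(sources)
    if len(sources) < 2:
        raise BeliefError("PCR6 needs at least two sources")
    acc = sources[0]
    for s in sources[1:]:
        acc = combine_pcr6([acc, s])
    return acc


def pignistic(bba: BBA) -> dict[Any, float]:
    """Pignistic transform BetP: split each mass equally among its subset's elements."""
    out = {e: 0.0 for e in bba.fod.elements}
    for mask, v in bba.masses.items():
        members = [e for i, e in enumerate(bba.fod.elements) if mask >> i & 1]
        share = v / len(members)
        for e in members:
            out[e] += share
    return out
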