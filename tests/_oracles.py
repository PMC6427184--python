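"""Brute-force reference implementations for belief-function combination.

These operate on plain ``{frozenset: mass}`` dictionaries, independently of
the package's bitmask encoding, so they can serve as oracles for the fast
implementations.
"""

import itertools
from math import fsum


def bba_to_dict(bba):
    return {bba.fod.unmask(m): v for m, v in bba.masses.items()}


def oracle_conjunctive(d1: dict, d2: dict) -> dict:
    out = {}
    for b, vb in d1.items():
        for c, vc in d2.items():
            key = b & c
            out[key] = out.get(key, 0.0) + vb * vc
    return out


def oracle_dempster(d1: dict, d2: dict) -> dict:
    conj = oracle_conjunctive(d1, d2)
    k = conj.pop(frozenset(), 0.0)
    return {a: v / (1.0 - k) for a, v in conj.items()}


def oracle_pcr6(sources: list) -> dict:
    """n-source PCR6 by direct enumeration of all focal-element tuples."""
    out = {}
    for combo in itertools.product(*(list(d.items()) for d in sources)):
        inter = frozenset.intersection(*(a for a, _ in combo))
        product = 1.0
        for _, v in combo:
            product *= v
        if inter:
            out[inter] = out.get(inter, 0.0) + product
        else:
            denom = fsum(v for _, v in combo)
            if denom == 0.0:
                continue
            for a, v in combo:
                out[a] = out.get(a, 0.0) + product * v / denom
    return out


def oracle_pignistic(d: dict) -> dict:
    out = {}
    for subset, v in d.items():
        for e in subset:
            out[e] = out.get(e, 0.0) + v / len(subset)
    return out


def random_bba_dict(rng, elements, max_focals=4, compound=True):
    """Random BBA as a frozenset dict; Bayesian when compound=False."""
    elements = list(elements)
    if compound:
        pool = [
            frozenset(c)
            for r in range(1, len(elements) + 1)
            for c in itertools.combinations(elements, r)
        ]
    else:
        pool = [frozenset([e]) for e in elements]
    k = int(rng.integers(1, min(max_focals, len(pool)) + 1))
    idx = rng.choice(len(pool), size=k, replace=False)
    w = rng.dirichlet([1.0] * k)
    return {pool[i]: float(wi) for i, wi in zip(idx, w)}
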