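"""Decoding-time measure (DTM) and synonymous-variant design.

The DTM scores how far an ORF sits from its fastest synonymous recoding:

    eta = sum_i (tau_i - psi(i)) * w_i / K

where ``psi(i)`` is the minimum decoding time within codon i's synonymous
group and ``w_i > 0`` are positional weights.  ``eta = 0`` iff every codon is
already the fastest synonym.  Unit weights give the homogeneous DTM ``eta``;
a monotone-increasing ramp (``eta~``) expresses the hypothesis that slow
codons near the 3' end pile up ribosomes behind them ("traffic jams").

Variant rules recode a protein region-by-region with fast / median / slow
synonyms to shape steady-state ribosome density and translation rate:

* ``HIGH_RD`` — fast first half, slow second half: a downstream jam, high density.
* ``LOW_RD``  — slow first half, fast second half: throttled inflow, low density.
* ``MDN_RD``  — slow / median / fast thirds.
* ``SPD_TR``  — all fast: maximal translation rate (eta = 0).
* ``SLW_TR``  — all slow: minimal translation rate, maximal eta.

For a 239-codon ORF the built-in region boundaries are codons 1-119 / 120-239
(halves) and 1-79 / 80-159 / 160-239 (thirds); other lengths generalize
proportionally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic_genome import CodonDecodingTable

__all__ = ["DTMWeights", "VariantRule", "VARIANT_NAMES", "dtm", "default_weights", "design_variant"]

VARIANT_NAMES = ("HIGH_RD", "LOW_RD", "MDN_RD", "SPD_TR", "SLW_TR")


@dataclass(frozen=True)
class DTMWeights:
    w: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "w", np.asarray(self.w, dtype=float))
        if self.w.ndim != 1 or np.any(self.w <= 0):
            raise ValueError("weights must be a vector of positive reals")


@dataclass(frozen=True)
class VariantRule:
    """Region map: 1-based inclusive codon intervals -> speed class."""

    name: str
    region_map: tuple[tuple[tuple[int, int], str], ...]

    def __post_init__(self) -> None:
        covered = []
        for (a, b), cls in self.region_map:
            if cls not in ("fast", "median", "slow"):
                raise ValueError(f"unknown speed class {cls!r}")
            covered.extend(range(a, b + 1))
        K = max(covered)
        if sorted(covered) != list(range(1, K + 1)):
            raise ValueError("intervals must partition 1..K")

    @property
    def K(self) -> int:
        return self.region_map[-1][0][1]

    @classmethod
    def built_in(cls, name: str, K: int) -> "VariantRule":
        """The five standard rules at length K (half/third splits)."""
        if name not in VARIANT_NAMES:
            raise ValueError(f"unknown variant {name!r}; choose from {VARIANT_NAMES}")
        half = int(np.ceil(K / 2))  # second region starts here (120 for K=239)
        b1, b2 = K // 3, (2 * K) // 3  # third boundaries (79, 159 for K=239)
        regions = {
            "HIGH_RD": (((1, half - 1), "fast"), ((half, K), "slow")),
            "LOW_RD": (((1, half - 1), "slow"), ((half, K), "fast")),
            "MDN_RD": (((1, b1), "slow"), ((b1 + 1, b2), "median"), ((b2 + 1, K), "fast")),
            "SPD_TR": (((1, K), "fast"),),
            "SLW_TR": (((1, K), "slow"),),
        }[name]
        return cls(name=name, region_map=regions)


def dtm(orf: list[str], table: CodonDecodingTable, weights: DTMWeights) -> float:
    """Weighted mean excess decoding time over the fastest synonyms (eta)."""
    K = len(orf)
    if weights.w.size != K:
        raise ValueError(f"got {weights.w.size} weights for {K} codons")
    excess = np.array([table.tau(c) - min(table.tau(s) for s in table.synonyms(c)) for c in orf])
    return float(np.dot(excess, weights.w) / K)


def default_weights(K: int, kind: str = "homogeneous") -> DTMWeights:
    """Unit weights, or a linear ramp w_i = 2i/(K+1) with mean exactly 1."""
    if K < 1:
        raise ValueError("K must be >= 1")
    if kind == "homogeneous":
        return DTMWeights(np.ones(K))
    if kind == "increasing":
        return DTMWeights(2.0 * np.arange(1, K + 1) / (K + 1))
    raise ValueError(f"unknown weight kind {kind!r}")


def _pick(table: CodonDecodingTable, codon: str, speed: str) -> str:
    """The synonym of ``codon`` in the requested speed class.

    Ties and the median of an even-sized group resolve deterministically to
    the synonym with the lower decoding time (then lexicographically).
    """
    group = sorted(table.synonyms(codon), key=lambda c: (table.tau(c), c))
    if speed == "fast":
        return group[0]
    if speed == "slow":
        return group[-1]
    return group[(len(group) - 1) // 2]  # median, lower-middle for even groups


def design_variant(orf: list[str], table: CodonDecodingTable, rule: VariantRule) -> list[str]:
    """Recode an ORF per the rule's region map; the protein is unchanged."""
    if rule.K != len(orf):
        raise ValueError(f"rule covers {rule.K} codons, ORF has {len(orf)}")
    speed_of = np.empty(len(orf), dtype=object)
    for (a, b), cls in rule.region_map:
        speed_of[a - 1: b] = cls
    return [_pick(table, c, s) for c, s in zip(orf, speed_of)]
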