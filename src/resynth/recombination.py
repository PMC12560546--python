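"""Recombination-event counting on phased, map-ordered genotypes.

With phased data an ABH sequence along a chromosome traces the parental
origin of both haplotypes; the minimum number of haplotype-origin switches
compatible with the observed calls estimates the crossover load.  Between
consecutive non-missing calls the per-transition cost is: same class 0,
homozygote<->heterozygote 1, A<->B 2 (both haplotypes must switch).
Heterozygote runs are assumed phase-preserving (H->H costs 0), giving the
minimal count.  Missing calls are skipped and chromosome boundaries reset
the scan, so no transition is ever charged across chromosomes.

Counts are per-haplotype events: a pair's total is the plain sum of its two
members' counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import MarkerMap
from .scoring import A, B, H, MISSING, encode_calls

# Transition cost between consecutive non-missing calls (rows/cols A,B,H).
_COST = np.zeros((3, 3), dtype=np.int64)
_COST[A, B] = _COST[B, A] = 2
_COST[A, H] = _COST[H, A] = 1
_COST[B, H] = _COST[H, B] = 1


def _count_block(codes: np.ndarray) -> int:
    """Minimal haplotype switches within one chromosome block."""
    called = codes[codes != MISSING]
    if called.size < 2:
        return 0
    return int(_COST[called[:-1], called[1:]].sum())


def count_recombinations(geno: Sequence[str] | np.ndarray, mm: MarkerMap) -> int:
    """Total recombination events of one phased individual over all chromosomes."""
    codes = encode_calls(geno)
    if len(codes) != len(mm.entries):
        raise ValueError(
            f"genotype length {len(codes)} does not match map size {len(mm.entries)}"
        )
    return sum(_count_block(codes[start:stop]) for _, start, stop in mm.blocks())


@dataclass(frozen=True)
class RecombinationCount:
    """Per-member and summed recombination events for one pair."""

    r1: int
    r2: int
    total: int


def pair_recombination(
    geno1: Sequence[str] | np.ndarray,
    geno2: Sequence[str] | np.ndarray,
    mm: MarkerMap,
) -> RecombinationCount:
    """Recombination counts of both members and their sum."""
    r1 = count_recombinations(geno1, mm)
    r2 = count_recombinations(geno2, mm)
    return RecombinationCount(r1, r2, r1 + r2)
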