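"""Individual- and pair-level filters with annotated rejections.

Selection proceeds in three stages: (1) individuals whose heterozygosity
rate exceeds ``max_het`` are dropped — in an ideal F2 a 0.5 cut removes
about half the population; (2) pairs whose final score falls below
``min_score_fraction`` of the ideal score are discarded early; (3) pairs
with too large a fraction of invariable (A/A or B/B) loci are discarded.
Every rejection carries the subject, the reason code, the observed value
and the threshold it violated.  All boundaries accept equality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .io import GenotypeMatrix, het_fraction
from .scoring import PairScore, encode_calls

HET_RATE = "HET_RATE"
LOW_SCORE = "LOW_SCORE"
INVARIABLE_EXCESS = "INVARIABLE_EXCESS"


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the three filtering stages.

    max_het
        Maximum heterozygosity rate an individual may have (inclusive).
    max_invariable_fraction
        Maximum fraction of invariable loci a pair may have (inclusive);
        typical values range from 0 (no invariable locus tolerated) to 0.1.
    min_score_fraction
        Minimum final score as a fraction of the ideal score (inclusive).
    het_denominator
        'nonmissing' (default) divides the H count by the non-missing call
        count; 'all' divides by the full panel size.
    """

    max_het: float = 0.5
    max_invariable_fraction: float = 0.1
    min_score_fraction: float = 0.8
    het_denominator: str = "nonmissing"

    def __post_init__(self) -> None:
        for name in ("max_het", "max_invariable_fraction", "min_score_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.het_denominator not in ("nonmissing", "all"):
            raise ValueError("het_denominator must be 'nonmissing' or 'all'")


@dataclass(frozen=True)
class RejectionRecord:
    """One discarded individual or pair, annotated with the violated filter."""

    subject: Union[str, tuple[str, str]]
    reason: str  # HET_RATE | LOW_SCORE | INVARIABLE_EXCESS
    observed_value: float
    threshold: float


def het_rate(geno: Sequence[str] | np.ndarray, denominator: str = "nonmissing") -> float:
    """Heterozygosity rate of one individual's call sequence.

    By default the denominator is the number of non-missing calls, so the
    rate is comparable between individuals with different missing-data
    loads; ``denominator='all'`` uses the full marker count instead.  All
    calls missing is an error (the rate is undefined).
    """
    return het_fraction(encode_calls(geno), denominator)


def filter_individuals(
    gm: GenotypeMatrix, cfg: FilterConfig
) -> tuple[list[str], list[RejectionRecord]]:
    """Split individuals into (kept ids, HET_RATE rejections).

    Kept are those with ``het_rate <= cfg.max_het``; order is preserved.
    """
    kept: list[str] = []
    rejected: list[RejectionRecord] = []
    for i, ind in enumerate(gm.individual_ids):
        rate = het_fraction(gm.codes[i], cfg.het_denominator)
        if rate <= cfg.max_het:
            kept.append(ind)
        else:
            rejected.append(RejectionRecord(ind, HET_RATE, rate, cfg.max_het))
    return kept, rejected


def evaluate_pair(
    ps: PairScore,
    cfg: FilterConfig,
    ideal: float,
    subject: Optional[tuple[str, str]] = None,
) -> Optional[RejectionRecord]:
    """Apply the pair-level filters; return None on acceptance.

    The score filter is checked first (it enables early discard); pairs
    passing it are then checked for invariable-locus excess.
    """
    sub = subject if subject is not None else ("?", "?")
    if ps.final_score < cfg.min_score_fraction * ideal:
        return RejectionRecord(sub, LOW_SCORE, ps.final_score,
                               cfg.min_score_fraction * ideal)
    inv_fraction = ps.n_invariable / ps.n_markers
    if inv_fraction > cfg.max_invariable_fraction:
        return RejectionRecord(sub, INVARIABLE_EXCESS, inv_fraction,
                               cfg.max_invariable_fraction)
    return None
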