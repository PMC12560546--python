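"""All-pairs enumeration, scoring, filtering and deterministic ranking.

For k retained individuals all k(k-1)/2 unidirectional pairs are scored.
The pair index space is split into contiguous chunks which are evaluated
independently (optionally in parallel via joblib); because every pair is
computed identically and the final ranking is a global sort, the output is
byte-identical for any worker count and any chunking.

Ranking: final score descending, then total recombination count ascending
(phased runs only), then (id1, id2) lexicographic with id1 < id2 canonical
within each pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from joblib import Parallel, delayed

from .filters import (FilterConfig, INVARIABLE_EXCESS, LOW_SCORE,
                      RejectionRecord, filter_individuals)
from .io import GenotypeMatrix, MarkerMap, het_fraction
from .recombination import count_recombinations
from .scoring import (CLASS_LUT, HET_UNION_CLASSES, INVARIABLE_CLASSES,
                      ScoreTable, SimilarityRange, ideal_score,
                      similarity_range)

#: Above this many pairs, LOW_SCORE rejections are aggregated into a count
#: instead of being enumerated one record per pair.
DEFAULT_LOW_SCORE_CAP = 10**6


def n_comparisons(k: int) -> int:
    """Number of unidirectional pairwise comparisons, k(k-1)/2."""
    if k < 0:
        raise ValueError("k must be >= 0")
    return k * (k - 1) // 2


@dataclass(frozen=True)
class PairResult:
    """One accepted candidate pair and its selection statistics."""

    id1: str
    id2: str
    final_score: float
    n_invariable: int
    het1: float
    het2: float
    similarity: SimilarityRange
    rec1: Optional[int] = None
    rec2: Optional[int] = None
    rec_total: Optional[int] = None


@dataclass
class SelectionResult:
    """Full outcome of a selection run."""

    accepted: list[PairResult]
    rejected: list[RejectionRecord]
    stats: dict


def _eval_chunk(
    codes: np.ndarray,
    i_idx: np.ndarray,
    j_idx: np.ndarray,
    score_vec: np.ndarray,
    min_score: float,
    max_inv_frac: float,
    enumerate_low_score: bool,
):
    """Score one contiguous chunk of pairs; apply the pair filters.

    Returns (accepted rows, low-score count, low-score rows, invariable rows)
    where rows reference pair positions within this chunk.
    """
    classes = CLASS_LUT[codes[i_idx], codes[j_idx]]
    scores = score_vec[classes].sum(axis=1)
    n_inv = np.isin(classes, INVARIABLE_CLASSES).sum(axis=1)
    n_het = np.isin(classes, HET_UNION_CLASSES).sum(axis=1)
    n_markers = codes.shape[1]

    low = scores < min_score
    inv_excess = ~low & (n_inv / n_markers > max_inv_frac)
    ok = ~low & ~inv_excess
    low_rows = np.flatnonzero(low) if enumerate_low_score else np.empty(0, int)
    return (
        np.flatnonzero(ok), scores, n_inv, n_het,
        int(low.sum()), low_rows, np.flatnonzero(inv_excess),
    )


def run_selection(
    gm: GenotypeMatrix,
    mm: MarkerMap,
    table: ScoreTable,
    cfg: FilterConfig,
    phased: bool = False,
    workers: int = 1,
    low_score_cap: int = DEFAULT_LOW_SCORE_CAP,
) -> SelectionResult:
    """Run the full selection pipeline on a validated matrix/map pair."""
    if workers < 1:
        raise ValueError("workers must be >= 1")

    kept_ids, ind_rejected = filter_individuals(gm, cfg)
    k = len(kept_ids)
    sub = gm.subset(kept_ids)
    total_pairs = n_comparisons(k)
    ideal = ideal_score(gm.n_markers, table)
    min_score = cfg.min_score_fraction * ideal

    het = np.array([het_fraction(sub.codes[i], cfg.het_denominator)
                    for i in range(k)])
    rec = (np.array([count_recombinations(sub.codes[i], mm) for i in range(k)])
           if phased else None)

    enumerate_low = total_pairs <= low_score_cap
    accepted: list[PairResult] = []
    rejected: list[RejectionRecord] = list(ind_rejected)
    n_low = 0
    n_inv_excess = 0

    if total_pairs:
        i_all, j_all = np.triu_indices(k, 1)
        chunk_size = max(1, math.ceil(total_pairs / (8 * workers)))
        bounds = range(0, total_pairs, chunk_size)
        results = Parallel(n_jobs=workers)(
            delayed(_eval_chunk)(
                sub.codes, i_all[lo:lo + chunk_size], j_all[lo:lo + chunk_size],
                table.as_vector(), min_score, cfg.max_invariable_fraction,
                enumerate_low,
            )
            for lo in bounds
        )
        for lo, (ok_rows, scores, n_inv, n_het, low_count, low_rows,
                 inv_rows) in zip(bounds, results):
            i_chunk = i_all[lo:lo + chunk_size]
            j_chunk = j_all[lo:lo + chunk_size]
            n_low += low_count
            n_inv_excess += len(inv_rows)
            # emit rejections in pair order so output is chunking-invariant
            low_set = set(low_rows.tolist())
            for r in sorted(low_set | set(inv_rows.tolist())):
                subject = _canonical(kept_ids[i_chunk[r]], kept_ids[j_chunk[r]])
                if r in low_set:
                    rejected.append(RejectionRecord(
                        subject, LOW_SCORE, float(scores[r]), min_score))
                else:
                    rejected.append(RejectionRecord(
                        subject, INVARIABLE_EXCESS,
                        float(n_inv[r] / gm.n_markers),
                        cfg.max_invariable_fraction))
            for r in ok_rows:
                ii, jj = int(i_chunk[r]), int(j_chunk[r])
                if kept_ids[ii] > kept_ids[jj]:
                    ii, jj = jj, ii
                sim = similarity_range(gm.n_markers, int(n_inv[r]),
                                       int(n_het[r]))
                accepted.append(PairResult(
                    id1=kept_ids[ii], id2=kept_ids[jj],
                    final_score=float(scores[r]),
                    n_invariable=int(n_inv[r]),
                    het1=float(het[ii]), het2=float(het[jj]),
                    similarity=sim,
                    rec1=int(rec[ii]) if phased else None,
                    rec2=int(rec[jj]) if phased else None,
                    rec_total=int(rec[ii] + rec[jj]) if phased else None,
                ))

    accepted.sort(key=lambda p: (-p.final_score,
                                 p.rec_total if phased else 0,
                                 p.id1, p.id2))
    stats = {
        "n_individuals_input": gm.n_individuals,
        "n_individuals_rejected_het": len(ind_rejected),
        "n_individuals_retained": k,
        "n_pairs_evaluated": total_pairs,
        "n_rejected_low_score": n_low,
        "n_rejected_invariable_excess": n_inv_excess,
        "n_accepted": len(accepted),
        "ideal_score": ideal,
        "low_score_enumerated": enumerate_low,
        "low_score_cap": low_score_cap,
    }
    return SelectionResult(accepted, rejected, stats)


def _canonical(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)
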