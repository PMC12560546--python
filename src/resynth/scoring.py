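"""Per-locus combination scoring for complementary-pair selection.

Two individuals drawn from a selfing population are compared marker by
marker.  Each (unordered) combination of ABH-coded calls falls into one of
ten classes; a score table maps every class to a value in [0, 1], where 1
rewards the fully complementary homozygous combination A/B and 0 marks
combinations that fix the wrong state (A/A, B/B).  The sum over the marker
panel is the pair's *final score*; a fully complementary pair reaches the
*ideal score*, ``n_markers * score[A/B]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

# ---------------------------------------------------------------------------
# Call alphabet.  Internally calls are uint8 codes; '-' is missing data.

CALL_ALPHABET = ("A", "B", "H", "-")
A, B, H, MISSING = 0, 1, 2, 3
CALL_TO_CODE = {c: i for i, c in enumerate(CALL_ALPHABET)}
CODE_TO_CALL = np.array(CALL_ALPHABET)

#: The ten unordered call-combination classes, in conventional order.
COMBO_CLASSES = (
    "A/A", "B/B", "H/H", "-/-", "H/-", "A/-", "B/-", "A/H", "B/H", "A/B",
)
_CLASS_INDEX = {c: i for i, c in enumerate(COMBO_CLASSES)}

# 4x4 ordered-pair -> class-index lookup; symmetric by construction.
CLASS_LUT = np.empty((4, 4), dtype=np.uint8)
for _x, _cx in enumerate(CALL_ALPHABET):
    for _y, _cy in enumerate(CALL_ALPHABET):
        _lab = f"{_cx}/{_cy}" if f"{_cx}/{_cy}" in _CLASS_INDEX else f"{_cy}/{_cx}"
        CLASS_LUT[_x, _y] = _CLASS_INDEX[_lab]

# Class indices used by downstream counters.
INVARIABLE_CLASSES = (_CLASS_INDEX["A/A"], _CLASS_INDEX["B/B"])
HET_UNION_CLASSES = tuple(
    _CLASS_INDEX[c] for c in COMBO_CLASSES if "H" in c
)  # H/H, H/-, A/H, B/H


def encode_calls(calls: Sequence[str] | np.ndarray) -> np.ndarray:
    """Map a sequence of 'A'/'B'/'H'/'-' symbols to uint8 codes."""
    if isinstance(calls, np.ndarray) and calls.dtype == np.uint8:
        return calls
    out = np.empty(len(calls), dtype=np.uint8)
    for i, c in enumerate(calls):
        try:
            out[i] = CALL_TO_CODE[c]
        except KeyError:
            raise ValueError(
                f"invalid genotype call {c!r} at position {i}; "
                f"expected one of {CALL_ALPHABET}"
            ) from None
    return out


def classify_locus(call1: str, call2: str) -> str:
    """Return the unordered combination class of two calls, e.g. 'A/B'.

    Classification is symmetric: ``classify_locus(x, y) == classify_locus(y, x)``.
    """
    for c in (call1, call2):
        if c not in CALL_TO_CODE:
            raise ValueError(
                f"invalid genotype call {c!r}; expected one of {CALL_ALPHABET}"
            )
    return COMBO_CLASSES[CLASS_LUT[CALL_TO_CODE[call1], CALL_TO_CODE[call2]]]


# ---------------------------------------------------------------------------
# Score tables

#: Built-in score sets.  SET1 is intolerant to missing data, SET2 favours
#: homozygous A/B combinations over heterozygotes, SET3 (the default) is
#: tolerant to both missing data and heterozygosity.
_BUILTIN_TABLES: dict[str, dict[str, float]] = {
    "SET1": {"A/A": 0.0, "B/B": 0.0, "H/H": 0.5, "-/-": 0.0, "H/-": 0.5,
             "A/-": 0.0, "B/-": 0.0, "A/H": 0.75, "B/H": 0.75, "A/B": 1.0},
    "SET2": {"A/A": 0.0, "B/B": 0.0, "H/H": 0.25, "-/-": 0.0, "H/-": 0.25,
             "A/-": 0.5, "B/-": 0.5, "A/H": 0.5, "B/H": 0.5, "A/B": 1.0},
    "SET3": {"A/A": 0.0, "B/B": 0.0, "H/H": 0.5, "-/-": 0.5, "H/-": 0.625,
             "A/-": 0.75, "B/-": 0.75, "A/H": 0.75, "B/H": 0.75, "A/B": 1.0},
}

DEFAULT_TABLE_NAME = "SET3"


@dataclass(frozen=True)
class ScoreTable:
    """Map from the ten combination classes to per-locus scores in [0, 1]."""

    name: str
    scores: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = set(COMBO_CLASSES) - set(self.scores)
        extra = set(self.scores) - set(COMBO_CLASSES)
        if missing or extra:
            raise ValueError(
                f"score table {self.name!r} must define exactly the classes "
                f"{COMBO_CLASSES}; missing={sorted(missing)} extra={sorted(extra)}"
            )
        for cls, v in self.scores.items():
            if not (0.0 <= float(v) <= 1.0):
                raise ValueError(
                    f"score table {self.name!r}: value {v} for class {cls} "
                    "is outside [0, 1]"
                )

    def __getitem__(self, combo_class: str) -> float:
        return float(self.scores[combo_class])

    def as_vector(self) -> np.ndarray:
        """Scores indexed by class index (order of :data:`COMBO_CLASSES`)."""
        return np.array([self.scores[c] for c in COMBO_CLASSES], dtype=float)


def builtin_score_table(name: str) -> ScoreTable:
    """Return one of the built-in tables SET1, SET2 or SET3."""
    key = name.upper()
    if key not in _BUILTIN_TABLES:
        raise ValueError(
            f"unknown score table {name!r}; valid names: "
            + ", ".join(sorted(_BUILTIN_TABLES))
        )
    return ScoreTable(key, dict(_BUILTIN_TABLES[key]))


def read_score_table(path: str | Path, name: str | None = None) -> ScoreTable:
    """Read a user score table: two tab-separated columns (class, value).

    All ten classes are required, values are validated to [0, 1].  Class
    labels use '-' for missing data, e.g. ``H/-``.
    """
    path = Path(path)
    scores: dict[str, float] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 2:
            raise ValueError(
                f"{path}:{lineno}: expected 2 tab-separated columns, got {len(fields)}"
            )
        cls, value = fields[0].strip(), fields[1].strip()
        if cls in scores:
            raise ValueError(f"{path}:{lineno}: duplicate class {cls!r}")
        try:
            scores[cls] = float(value)
        except ValueError:
            raise ValueError(f"{path}:{lineno}: non-numeric score {value!r}") from None
    return ScoreTable(name or path.stem, scores)


# ---------------------------------------------------------------------------
# Pair scores and similarity

@dataclass(frozen=True)
class PairScore:
    """Summary of one pairwise genotype comparison over a marker panel.

    final_score
        Sum of per-locus scores.
    n_invariable
        Loci where both individuals carry the same homozygote (A/A or B/B);
        these remain fixed in all progeny of the cross.
    n_het_union
        Loci where at least one member is heterozygous (counted once even
        when both are H).
    """

    final_score: float
    n_invariable: int
    n_het_union: int
    n_markers: int


def pair_score(
    geno1: Sequence[str] | np.ndarray,
    geno2: Sequence[str] | np.ndarray,
    table: ScoreTable,
) -> PairScore:
    """Score one pair of equal-length call sequences with *table*."""
    g1, g2 = encode_calls(geno1), encode_calls(geno2)
    if len(g1) != len(g2):
        raise ValueError(f"genotype length mismatch: {len(g1)} vs {len(g2)}")
    if len(g1) == 0:
        raise ValueError("empty genotype sequences")
    classes = CLASS_LUT[g1, g2]
    final = float(table.as_vector()[classes].sum())
    n_inv = int(np.isin(classes, INVARIABLE_CLASSES).sum())
    n_het = int(np.isin(classes, HET_UNION_CLASSES).sum())
    return PairScore(final, n_inv, n_het, len(g1))


def ideal_score(n_markers: int, table: ScoreTable) -> float:
    """Score of a completely complementary pair: ``n_markers * score[A/B]``."""
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    return n_markers * table["A/B"]


@dataclass(frozen=True)
class SimilarityRange:
    """Percentage interval of attainable similarity to the original hybrid.

    The upper end removes only the invariable markers; the lower end also
    removes loci where at least one member of the pair is heterozygous.
    """

    lower_pct: float
    upper_pct: float


def similarity_range(
    n_markers: int, n_invariable: int, n_het_union: int
) -> SimilarityRange:
    """Similarity range of a pair's resynthesised progeny to the hybrid.

    upper = (n_markers - n_invariable) * 100 / n_markers
    lower = (n_markers - n_invariable - n_het_union) * 100 / n_markers
    """
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    if n_invariable < 0 or n_het_union < 0:
        raise ValueError("counts must be non-negative")
    if n_invariable + n_het_union > n_markers:
        raise ValueError(
            f"n_invariable ({n_invariable}) + n_het_union ({n_het_union}) "
            f"exceeds n_markers ({n_markers})"
        )
    upper = (n_markers - n_invariable) * 100.0 / n_markers
    lower = (n_markers - n_invariable - n_het_union) * 100.0 / n_markers
    return SimilarityRange(lower_pct=lower, upper_pct=upper)
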