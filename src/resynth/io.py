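"""Input parsing and validation for genotype and marker-map tables.

Two tab-separated files drive a run: a genotype table (individuals in rows,
markers in columns, calls in {A, B, H, -}) and a marker map (two columns:
chromosome, marker) whose marker order must match the genotype table
exactly.  Parsing is strict: unknown symbols, duplicate labels, ragged rows
and split chromosome blocks all raise with the offending location.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .scoring import CALL_ALPHABET, CALL_TO_CODE, CODE_TO_CALL, H, MISSING

_HEADER_CHROM_NAMES = {"chr", "chrom", "chromosome", "lg", "linkage_group"}


@dataclass
class GenotypeMatrix:
    """Individuals x ordered markers, calls encoded as uint8 (A,B,H,-)=(0..3).

    Marker order is positional and never re-sorted; it defines chromosome
    assignment via the companion :class:`MarkerMap`.
    """

    individual_ids: list[str]
    marker_ids: list[str]
    codes: np.ndarray  # shape (n_individuals, n_markers), dtype uint8

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.uint8)
        n, m = self.codes.shape
        if len(self.individual_ids) != n or len(self.marker_ids) != m:
            raise ValueError("id lists do not match matrix shape")
        if len(set(self.individual_ids)) != n:
            raise ValueError("duplicate individual ids")
        if len(set(self.marker_ids)) != m:
            raise ValueError("duplicate marker ids")
        if self.codes.size and self.codes.max() > MISSING:
            raise ValueError("genotype codes out of range")

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.codes.shape[1]

    def calls(self) -> np.ndarray:
        """The matrix as 'A'/'B'/'H'/'-' strings."""
        return CODE_TO_CALL[self.codes]

    def row(self, individual_id: str) -> np.ndarray:
        return self.codes[self.individual_ids.index(individual_id)]

    def subset(self, individual_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.individual_ids.index(i) for i in individual_ids]
        return GenotypeMatrix(list(individual_ids), list(self.marker_ids),
                              self.codes[idx])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.calls(), index=self.individual_ids,
                            columns=self.marker_ids)


@dataclass
class MarkerMap:
    """Ordered (chromosome, marker) entries defining contiguous blocks."""

    entries: list[tuple[str, str]]

    def __post_init__(self) -> None:
        markers = [m for _, m in self.entries]
        if len(set(markers)) != len(markers):
            dupes = sorted({m for m in markers if markers.count(m) > 1})
            raise ValueError(f"duplicate marker ids in map: {dupes}")
        seen: list[str] = []
        for chrom, _ in self.entries:
            if seen and chrom != seen[-1]:
                if chrom in seen:
                    raise ValueError(
                        f"chromosome {chrom!r} occurs in non-contiguous blocks; "
                        "markers of one chromosome must be consecutive"
                    )
                seen.append(chrom)
            elif not seen:
                seen.append(chrom)

    @property
    def marker_ids(self) -> list[str]:
        return [m for _, m in self.entries]

    @property
    def chromosomes(self) -> list[str]:
        out: list[str] = []
        for chrom, _ in self.entries:
            if not out or out[-1] != chrom:
                out.append(chrom)
        return out

    def blocks(self) -> list[tuple[str, int, int]]:
        """Per-chromosome (name, start, stop) half-open index ranges."""
        out: list[tuple[str, int, int]] = []
        start = 0
        for i, (chrom, _) in enumerate(self.entries):
            if i and chrom != self.entries[i - 1][0]:
                out.append((self.entries[i - 1][0], start, i))
                start = i
        if self.entries:
            out.append((self.entries[-1][0], start, len(self.entries)))
        return out


@dataclass(frozen=True)
class PopulationSummary:
    """Population-level statistics from a validated genotype/map pair."""

    n_individuals: int
    n_markers: int
    missing_fraction: float
    het_fraction_per_individual: dict[str, float]


def read_genotype_table(path: str | Path) -> GenotypeMatrix:
    """Parse a TSV genotype table (header = marker names, column 1 = id).

    Every cell must be one of {A, B, H, -} (case-sensitive); violations are
    reported with row, column and the offending token.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0].split("\t")
    marker_ids = [f.strip() for f in header[1:]]
    if not marker_ids:
        raise ValueError(f"{path}: header defines no markers")
    individual_ids: list[str] = []
    rows: list[list[int]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(marker_ids) + 1:
            raise ValueError(
                f"{path}:{lineno}: ragged row for {fields[0]!r}: "
                f"{len(fields) - 1} calls, expected {len(marker_ids)}"
            )
        ind = fields[0].strip()
        row: list[int] = []
        for col, tok in enumerate(fields[1:]):
            tok = tok.strip()
            if tok not in CALL_TO_CODE:
                raise ValueError(
                    f"{path}:{lineno}: invalid call {tok!r} for individual "
                    f"{ind!r} at marker {marker_ids[col]!r}; expected one of "
                    f"{CALL_ALPHABET}"
                )
            row.append(CALL_TO_CODE[tok])
        individual_ids.append(ind)
        rows.append(row)
    if not rows:
        raise ValueError(f"{path}: no individuals")
    return GenotypeMatrix(individual_ids, marker_ids,
                          np.array(rows, dtype=np.uint8))


def write_genotype_table(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a genotype matrix in the same TSV dialect read_genotype_table accepts."""
    gm.to_dataframe().to_csv(path, sep="\t", index_label="id")


def read_marker_map(path: str | Path) -> MarkerMap:
    """Parse the two-column (chromosome, marker) map.

    An optional single header line is tolerated when its first field looks
    like a column title (e.g. 'chromosome'); data rows are otherwise taken
    verbatim, in file order.
    """
    path = Path(path)
    entries: list[tuple[str, str]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = [f.strip() for f in line.split("\t")]
        if len(fields) != 2:
            raise ValueError(
                f"{path}:{lineno}: expected 2 tab-separated columns, got {len(fields)}"
            )
        if lineno == 1 and fields[0].lower() in _HEADER_CHROM_NAMES:
            continue
        entries.append((fields[0], fields[1]))
    if not entries:
        raise ValueError(f"{path}: no marker entries")
    return MarkerMap(entries)


def write_marker_map(mm: MarkerMap, path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{chrom}\t{marker}\n" for chrom, marker in mm.entries)
    )


def het_fraction(codes: np.ndarray, denominator: str = "nonmissing") -> float:
    """Heterozygous fraction of one call-code sequence.

    denominator='nonmissing' divides by the non-missing call count (default);
    'all' divides by the full marker count.
    """
    codes = np.asarray(codes, dtype=np.uint8)
    if codes.size == 0:
        raise ValueError("empty genotype sequence")
    n_het = int((codes == H).sum())
    if denominator == "all":
        return n_het / codes.size
    if denominator != "nonmissing":
        raise ValueError("denominator must be 'nonmissing' or 'all'")
    n_called = int((codes != MISSING).sum())
    if n_called == 0:
        raise ValueError("heterozygosity undefined: all calls missing")
    return n_het / n_called


def validate_consistency(
    gm: GenotypeMatrix, mm: MarkerMap, het_denominator: str = "nonmissing"
) -> PopulationSummary:
    """Check marker order agreement between matrix and map; summarise.

    Raises on the first discordant marker position; marker identity is
    checked by name and position.
    """
    if gm.n_individuals == 0:
        raise ValueError("no individuals in genotype matrix")
    map_markers = mm.marker_ids
    if len(map_markers) != gm.n_markers:
        raise ValueError(
            f"marker count mismatch: genotype table has {gm.n_markers}, "
            f"map has {len(map_markers)}"
        )
    for i, (a, b) in enumerate(zip(gm.marker_ids, map_markers)):
        if a != b:
            raise ValueError(
                f"marker order mismatch at position {i}: genotype table has "
                f"{a!r}, map has {b!r}"
            )
    missing = float((gm.codes == MISSING).mean())
    het = {
        ind: het_fraction(gm.codes[i], het_denominator)
        for i, ind in enumerate(gm.individual_ids)
    }
    return PopulationSummary(gm.n_individuals, gm.n_markers, missing, het)
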