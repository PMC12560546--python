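"""Serialisation of the four run products and the run log.

A selection run emits: (1) the accepted-pairs table, (2) the annotated
discards table, (3) a human-readable run log with every applied argument
and per-stage statistics, and (4) a genotype-profile figure of the top ten
pairs (.png and .pdf).  All paths derive from a single output prefix:
``prefix.pairs.tsv``, ``prefix.discarded.tsv``, ``prefix.log`` and
``prefix.top10.{png,pdf}``.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
import numpy as np

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.colors import ListedColormap
from matplotlib.patches import Patch

from .filters import LOW_SCORE
from .io import GenotypeMatrix, MarkerMap
from .pairs import PairResult, SelectionResult

PAIR_COLUMNS = ("id1", "id2", "final_score", "n_invariable", "het1", "het2",
                "similarity_lower_pct", "similarity_upper_pct")
PAIR_COLUMNS_PHASED = PAIR_COLUMNS + ("rec1", "rec2", "rec_total")

# Fixed colour map, call order A, B, H, '-' (missing).
_CALL_COLORS = ("#d95f02", "#1b9e77", "#e6c200", "#bdbdbd")


@dataclass
class RunLog:
    """Arguments as applied (defaults included) plus per-stage statistics."""

    arguments: dict
    stage_stats: dict
    started: str = field(default_factory=lambda: _dt.datetime.now().isoformat(timespec="seconds"))
    finished: str = ""


def _fmt_pair_row(p: PairResult, phased: bool) -> str:
    cells = [p.id1, p.id2, f"{p.final_score:.2f}", str(p.n_invariable),
             f"{p.het1:.4f}", f"{p.het2:.4f}",
             f"{p.similarity.lower_pct:.2f}", f"{p.similarity.upper_pct:.2f}"]
    if phased:
        cells += [str(p.rec1), str(p.rec2), str(p.rec_total)]
    return "\t".join(cells)


def write_accepted_pairs(result: SelectionResult, phased: bool,
                         path: str | Path) -> None:
    """Write the ranked accepted-pairs TSV (8 columns, 11 when phased)."""
    cols = PAIR_COLUMNS_PHASED if phased else PAIR_COLUMNS
    lines = ["\t".join(cols)]
    lines += [_fmt_pair_row(p, phased) for p in result.accepted]
    Path(path).write_text("\n".join(lines) + "\n")


def write_discarded(result: SelectionResult, path: str | Path) -> None:
    """Write every rejection: subject(s), reason, observed value, threshold.

    When LOW_SCORE rejections were aggregated (pair count above the cap),
    a single summary row carries the count instead of per-pair rows.
    """
    lines = ["subject\treason\tobserved_value\tthreshold"]
    for rec in result.rejected:
        subject = (rec.subject if isinstance(rec.subject, str)
                   else "|".join(rec.subject))
        lines.append(f"{subject}\t{rec.reason}\t{rec.observed_value:.6g}"
                     f"\t{rec.threshold:.6g}")
    stats = result.stats
    if not stats.get("low_score_enumerated", True):
        # Summary row: per-pair enumeration was capped.
        lines.append(
            f"<{stats['n_rejected_low_score']} pairs, aggregated: count "
            f"exceeds enumeration cap {stats['low_score_cap']}>\t"
            f"{LOW_SCORE}\t{stats['n_rejected_low_score']}\t-"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_log(log: RunLog, path: str | Path) -> None:
    """Write the human-readable run log; every applied default is printed."""
    lines = ["# resynth run log", f"started: {log.started}"]
    if log.finished:
        lines.append(f"finished: {log.finished}")
    lines.append("")
    lines.append("## arguments (as applied, defaults included)")
    for key in sorted(log.arguments):
        lines.append(f"{key}: {log.arguments[key]}")
    lines.append("")
    lines.append("## filtering statistics")
    for key, value in log.stage_stats.items():
        lines.append(f"{key}: {value}")
    Path(path).write_text("\n".join(lines) + "\n")


def plot_top_pairs(
    gm: GenotypeMatrix,
    mm: MarkerMap,
    result: SelectionResult,
    path_prefix: str | Path,
    n_pairs: int = 10,
) -> list[Path]:
    """Render genotype profiles of the top pairs to PNG and PDF.

    Rows are the individuals of the up-to-``n_pairs`` best pairs, grouped
    by pair; columns are markers grouped under chromosome headers; cells
    are colour-coded by call (A, B, H, missing).  Returns the written
    paths; with zero accepted pairs nothing is written.
    """
    top = result.accepted[:n_pairs]
    if not top:
        return []
    ids: list[str] = []
    for p in top:
        ids += [p.id1, p.id2]
    idx = [gm.individual_ids.index(i) for i in ids]
    grid = gm.codes[idx].astype(int)

    n_rows, n_cols = grid.shape
    fig_w = max(6.0, min(18.0, 0.12 * n_cols + 2.0))
    fig_h = max(3.0, 0.3 * n_rows + 1.2)
    fig, ax = plt.subplots(figsize=(fig_w, fig_h))
    ax.imshow(grid, cmap=ListedColormap(_CALL_COLORS), vmin=0, vmax=3,
              aspect="auto", interpolation="nearest")
    ax.set_yticks(range(n_rows), ids, fontsize=7)
    ax.set_xticks([])
    for chrom, start, stop in mm.blocks():
        ax.text((start + stop - 1) / 2, -0.8, chrom, ha="center", va="bottom",
                fontsize=8)
        if start:
            ax.axvline(start - 0.5, color="white", lw=1.5)
    for r in range(2, n_rows, 2):  # separate consecutive pairs
        ax.axhline(r - 0.5, color="black", lw=0.8)
    ax.legend(handles=[Patch(color=c, label=l) for c, l in
                       zip(_CALL_COLORS, ("A", "B", "H", "missing"))],
              loc="upper left", bbox_to_anchor=(1.01, 1), fontsize=8,
              frameon=False)
    ax.set_title(f"Genotype profiles of the top {len(top)} pairs", fontsize=10)
    fig.tight_layout()
    paths = [Path(f"{path_prefix}.png"), Path(f"{path_prefix}.pdf")]
    for p in paths:
        fig.savefig(p, dpi=150)
    plt.close(fig)
    return paths


def write_all(
    gm: GenotypeMatrix,
    mm: MarkerMap,
    result: SelectionResult,
    arguments: dict,
    phased: bool,
    prefix: str | Path,
) -> dict[str, Path]:
    """Write the four run products under a common path prefix."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    log = RunLog(arguments=arguments, stage_stats=result.stats)
    out = {
        "pairs": Path(f"{prefix}.pairs.tsv"),
        "discarded": Path(f"{prefix}.discarded.tsv"),
        "log": Path(f"{prefix}.log"),
    }
    write_accepted_pairs(result, phased, out["pairs"])
    write_discarded(result, out["discarded"])
    figures = plot_top_pairs(gm, mm, result, f"{prefix}.top10")
    if figures:
        out["figure_png"], out["figure_pdf"] = figures
    log.finished = _dt.datetime.now().isoformat(timespec="seconds")
    write_log(log, out["log"])
    return out
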