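"""Ranked-report writing and parsing.

The report is a tab-separated text file with a header and seven columns:
name, sequence, length, GC, Tm, Overlap_Tm, K.  Each tetrad occupies four
rows in the order gene_5, overlap_3, overlap_5, gene_3; the duplex Tm and
the integer K score appear once per tetrad, on its gene_5 row.  Identical
inputs and configuration always produce a byte-identical file.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence

from .design import PrimerCombination
from .errors import SoePrimerError

logger = logging.getLogger(__name__)

HEADER = ("name", "sequence", "length", "GC", "Tm", "Overlap_Tm", "K")


def default_report_name(name1: str, name2: str) -> str:
    """Output-file convention: ``<first>_<second>_ligation_primers.txt``."""
    return f"{name1}_{name2}_ligation_primers.txt"


def format_rows(combo: PrimerCombination) -> list[tuple[str, ...]]:
    """The four report rows of one tetrad."""
    rows = []
    for idx, primer in enumerate(combo.primers):
        first = idx == 0
        rows.append((
            primer.role,
            primer.sequence,
            str(primer.length),
            f"{primer.gc:.1f}",
            f"{primer.tm:.1f}",
            f"{combo.overlap_tm:.1f}" if first else "",
            str(combo.k_display) if first else "",
        ))
    return rows


def write_report(combinations: Sequence[PrimerCombination], out_path: str | Path,
                 top: Optional[int] = None) -> Path:
    """Write the ranked tetrads (truncated to ``top`` if given) as TSV."""
    out_path = Path(out_path)
    chosen = combinations if top is None else combinations[:top]
    if not chosen:
        logger.warning("writing header-only report to %s (no tetrads selected)", out_path)
    lines = ["\t".join(HEADER)]
    for combo in chosen:
        for row in format_rows(combo):
            lines.append("\t".join(row))
    out_path.write_text("\n".join(lines) + "\n")
    return out_path


def read_report(path: str | Path) -> list[dict]:
    """Parse a written report back into per-tetrad dicts (round-trip aid).

    Each dict holds ``sequences`` (role -> sequence, in rank order of the
    file), ``overlap_tm`` and integer ``k``.
    """
    lines = Path(path).read_text().splitlines()
    if not lines or tuple(lines[0].split("\t")) != HEADER:
        raise SoePrimerError(f"{path} is not a soeprimer report")
    body = [ln.split("\t") for ln in lines[1:] if ln]
    if len(body) % 4:
        raise SoePrimerError(f"{path}: row count {len(body)} is not a multiple of 4")
    tetrads = []
    for base in range(0, len(body), 4):
        block = body[base: base + 4]
        tetrads.append({
            "sequences": {row[0]: row[1] for row in block},
            "overlap_tm": float(block[0][5]),
            "k": int(block[0][6]),
        })
    return tetrads
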