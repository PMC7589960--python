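"""Synthetic all-vs-all similarity tables in BLAST outfmt-6 layout.

Instead of running an actual similarity search on the simulated proteins,
hits are drawn from an explicit E-value model: within-family ordered pairs
are always reported with log10(E) uniform on a low support, between-family
pairs are suppressed by default. A "hard mode" adds between-family noise
hits on a higher (still disjoint by default) support to exercise the
cutoff scan. Both directions of a pair are drawn independently, as a real
search would produce.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from Bio.SeqRecord import SeqRecord

from .families import TruthFamilies

OUTFMT6_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]


@dataclass(frozen=True)
class SimilarityModel:
    """E-value model for the synthetic similarity search.

    ``within_log10e`` and ``between_log10e`` are (low, high) supports for
    log10(E). With the defaults the supports do not overlap, so every
    within-family E-value is below every between-family one and the true
    family partition is recoverable exactly. ``between_hit_prob`` is the
    probability that a between-family ordered pair is reported at all
    (0 by default; set > 0 for the hard mode)."""

    within_log10e: tuple[float, float] = (-120.0, -20.0)
    between_log10e: tuple[float, float] = (-8.0, -3.0)
    between_hit_prob: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.between_hit_prob <= 1.0:
            raise ValueError("between_hit_prob must lie in [0, 1]")
        for lo, hi in (self.within_log10e, self.between_log10e):
            if lo > hi:
                raise ValueError("log10(E) support must have low <= high")

    @property
    def overlapping(self) -> bool:
        return (
            self.between_hit_prob > 0.0
            and self.between_log10e[0] < self.within_log10e[1]
        )


def _bitscore(log10e: float) -> float:
    # monotone decreasing proxy so that better E-values get larger scores
    return round(40.0 - 2.0 * log10e, 1)


def simulate_similarity(
    proteomes: dict[str, list[SeqRecord]],
    truth: TruthFamilies,
    model: Optional[SimilarityModel] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw an all-vs-all similarity table for the generated proteins.

    Returns a DataFrame in 12-column outfmt-6 layout. No self hits; both
    directions of a reportable pair appear with independently drawn
    E-values. Only qseqid, sseqid, evalue and bitscore carry meaning; the
    remaining columns are filled consistently with the planted identity.
    """
    model = model or SimilarityModel()
    rng = np.random.default_rng(seed)
    records = [rec for sp in sorted(proteomes) for rec in proteomes[sp]]
    ids = [r.id for r in records]
    lengths = {r.id: len(r.seq) for r in records}
    family = truth.partition()

    rows = []
    for qid in ids:
        for sid in ids:
            if qid == sid:
                continue
            same_family = family[qid] == family[sid]
            if same_family:
                lo, hi = model.within_log10e
            else:
                if rng.random() >= model.between_hit_prob:
                    continue
                lo, hi = model.between_log10e
            log10e = rng.uniform(lo, hi)
            aln_len = min(lengths[qid], lengths[sid])
            pident = 90.0 if same_family else 30.0
            rows.append(
                {
                    "qseqid": qid,
                    "sseqid": sid,
                    "pident": pident,
                    "length": aln_len,
                    "mismatch": int(round(aln_len * (1.0 - pident / 100.0))),
                    "gapopen": 0,
                    "qstart": 1,
                    "qend": aln_len,
                    "sstart": 1,
                    "send": aln_len,
                    "evalue": 10.0 ** log10e,
                    "bitscore": _bitscore(log10e),
                }
            )
    return pd.DataFrame(rows, columns=OUTFMT6_COLUMNS)


def write_similarity(table: pd.DataFrame, path) -> None:
    """Write an outfmt-6 TSV (no header, as produced by search tools)."""
    table.to_csv(path, sep="\t", header=False, index=False)
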