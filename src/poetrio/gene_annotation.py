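"""Gene spans, SNP-to-gene assignment, region exclusion, set overlap.

A gene span runs from the start of the first exon to the end of the last
exon of any transcript (1-based, closed interval); a SNP belongs to a
gene iff it lies on the same chromosome within that interval. A SNP may
belong to several overlapping genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

#: Default MHC exclusion interval (chr6), configurable by callers.
MHC_REGION = (6, 25_000_000, 34_000_000)

IMPRINT_STATUSES = ("maternal-expressed", "paternal-expressed", "predicted", "unknown")

#: ricopili "daner"-style summary-statistic headers.
RICOPILI_COLUMNS = {
    "SNP": "snp",
    "CHR": "chrom",
    "BP": "pos",
    "A1": "a1",
    "A2": "a2",
    "OR": "odds_ratio",
    "P": "p",
}


@dataclass(frozen=True)
class GeneSpan:
    symbol: str
    chrom: int
    start: int
    end: int
    imprint_status: str | None = None

    def __post_init__(self) -> None:
        if not (1 <= int(self.chrom) <= 22):
            raise ValueError(f"gene {self.symbol}: chrom {self.chrom} is not an autosome")
        if self.start > self.end:
            raise ValueError(f"gene {self.symbol}: start > end")
        if self.imprint_status is not None and self.imprint_status not in IMPRINT_STATUSES:
            raise ValueError(f"gene {self.symbol}: unknown imprint status")


class SummaryStatSet:
    """Genome-ordered GWAS summary statistics with optional gene index.

    Wraps a DataFrame with columns (snp, chrom, pos, a1, a2, odds_ratio, p),
    sorted by (chrom, pos). ``gene_index`` maps gene symbol -> row indices.
    """

    def __init__(self, df: pd.DataFrame, gene_index: dict[str, np.ndarray] | None = None):
        required = ["snp", "chrom", "pos", "a1", "a2", "odds_ratio", "p"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"summary statistics missing columns {missing}")
        df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        p = df["p"].to_numpy(float)
        if not ((p > 0) & (p <= 1)).all():
            raise ValueError("p-values must lie in (0, 1]")
        if not (df["odds_ratio"].to_numpy(float) > 0).all():
            raise ValueError("odds ratios must be positive")
        self.df = df
        self.gene_index = gene_index

    @classmethod
    def read_table(cls, path, sep=None, column_map: dict[str, str] | None = None):
        column_map = column_map or RICOPILI_COLUMNS
        raw = pd.read_csv(path, sep=sep, engine="python")
        return cls(raw.rename(columns=column_map))

    def __len__(self) -> int:
        return len(self.df)

    @property
    def p(self) -> np.ndarray:
        return self.df["p"].to_numpy(float)

    def chrom_blocks(self) -> list[tuple[int, int, int]]:
        """Contiguous row ranges per chromosome: (chrom, start, stop)."""
        chroms = self.df["chrom"].to_numpy()
        blocks = []
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                blocks.append((int(chroms[start]), start, i))
                start = i
        return blocks


def read_gene_spans(
    path,
    sep=None,
    columns: dict[str, str] | None = None,
) -> list[GeneSpan]:
    """Read gene spans from BED-like/refFlat-like delimited text.

    ``columns`` maps file headers onto (symbol, chrom, start, end[,
    imprint_status]); identity mapping by default.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    if columns:
        df = df.rename(columns=columns)
    has_status = "imprint_status" in df.columns
    genes = []
    for row in df.itertuples(index=False):
        genes.append(
            GeneSpan(
                symbol=str(row.symbol),
                chrom=int(row.chrom),
                start=int(row.start),
                end=int(row.end),
                imprint_status=getattr(row, "imprint_status", None) if has_status else None,
            )
        )
    return genes


def read_gene_list(path) -> list[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]


def assign_snps_to_genes(
    stats: SummaryStatSet, genes: list[GeneSpan]
) -> dict[str, np.ndarray]:
    """Map each gene to the indices of SNPs inside its span (closed interval)."""
    df = stats.df
    known_chroms = set(df["chrom"].unique())
    by_chrom: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, start, stop in stats.chrom_blocks():
        by_chrom[chrom] = (df["pos"].to_numpy()[start:stop], np.arange(start, stop))
    index: dict[str, np.ndarray] = {}
    for g in genes:
        if g.chrom not in known_chroms:
            log.warning("gene %s on chromosome %s absent from data, skipped", g.symbol, g.chrom)
            continue
        pos, rows = by_chrom[g.chrom]
        lo = np.searchsorted(pos, g.start, side="left")
        hi = np.searchsorted(pos, g.end, side="right")
        index[g.symbol] = rows[lo:hi]
    return index


def exclude_region(items, chrom: int, start: int, end: int):
    """Remove genes (any overlap) or SNPs (containment) in a region.

    Returns ``(filtered_items, n_removed)``. Gene lists are filtered by
    the any-overlap rule; a :class:`SummaryStatSet` by position
    containment (closed interval).
    """
    if start > end:
        raise ValueError("invalid region interval")
    if isinstance(items, SummaryStatSet):
        df = items.df
        inside = (df["chrom"] == chrom) & (df["pos"] >= start) & (df["pos"] <= end)
        return SummaryStatSet(df.loc[~inside]), int(inside.sum())
    kept = [
        g for g in items
        if not (g.chrom == chrom and g.start <= end and g.end >= start)
    ]
    return kept, len(items) - len(kept)


def gene_overlap_fisher(
    set_a_size: int, set_b_size: int, overlap: int, universe_size: int
) -> float:
    """Two-sided Fisher exact p for the overlap of two gene sets."""
    if overlap < 0 or overlap > min(set_a_size, set_b_size):
        raise ValueError("overlap exceeds a set size")
    if max(set_a_size, set_b_size) > universe_size:
        raise ValueError("set larger than universe")
    a_only = set_a_size - overlap
    b_only = set_b_size - overlap
    neither = universe_size - set_a_size - set_b_size + overlap
    if neither < 0:
        raise ValueError("inconsistent counts: sets exceed universe")
    table = [[overlap, a_only], [b_only, neither]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])
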