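"""Gene-set enrichment of GWAS summary p-values.

Two complementary tests:

* an exact binomial test for over-representation of nominally significant
  POE p-values among a pre-defined set of independent markers, and
* a SNP-count-matched bootstrap: for each gene in the set, a contiguous
  window of the same number of genome-ordered SNPs is drawn uniformly at
  random (never crossing a chromosome boundary), and the count of
  significant SNPs in the real gene set is compared with the replicate
  distribution. The same machinery yields an empirical experiment-wide
  significance threshold (the mean k-th smallest p across replicates,
  k = ceil(alpha * M)) and an empirical p for a single best marker.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .gene_annotation import SummaryStatSet


@dataclass
class BootstrapConfig:
    """Replication settings for the matched-window bootstrap."""

    n_replicates: int = 1000
    thresholds: tuple[float, ...] = (0.001, 0.01, 0.05)
    seed: int | None = None
    match_unit: str = "contiguous-window"
    #: "proportion" -> r/B (can return 0); "add-one" -> (r+1)/(B+1).
    empirical_mode: str = "proportion"
    #: If set, redraw windows overlapping the observed gene-set SNPs.
    exclude_observed: bool = False

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not all(0.0 < t < 1.0 for t in self.thresholds):
            raise ValueError("thresholds must lie in (0, 1)")
        if self.match_unit != "contiguous-window":
            raise ValueError("only contiguous-window matching is implemented")
        if self.empirical_mode not in ("proportion", "add-one"):
            raise ValueError("empirical_mode must be 'proportion' or 'add-one'")


@dataclass
class BootstrapResult:
    thresholds: tuple[float, ...]
    observed: np.ndarray
    expected_mean: np.ndarray
    expected_sd: np.ndarray
    empirical_p: np.ndarray
    replicate_counts: np.ndarray = field(repr=False)


@dataclass
class ThresholdResult:
    k: int
    m_total: int
    threshold: float
    per_replicate: np.ndarray = field(repr=False)


@dataclass
class MinPResult:
    p_value: float
    observed_min_p: float
    replicate_minima: np.ndarray = field(repr=False)


def binomial_enrichment(n_significant: int, n_tested: int, alpha: float = 0.05) -> float:
    """One-sided upper-tail exact binomial p: P(X >= n_significant),
    X ~ Binomial(n_tested, alpha)."""
    if not (0 <= n_significant <= n_tested):
        raise ValueError("need 0 <= n_significant <= n_tested")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if n_significant == 0:
        return 1.0
    return float(stats.binom.sf(n_significant - 1, n_tested, alpha))


def _counts_list(gene_snp_counts) -> tuple[list[str], np.ndarray]:
    if hasattr(gene_snp_counts, "items"):
        names = [str(k) for k in gene_snp_counts.keys()]
        counts = np.asarray(list(gene_snp_counts.values()), dtype=int)
    else:
        counts = np.asarray(list(gene_snp_counts), dtype=int)
        names = [f"region{i}" for i in range(len(counts))]
    if (counts < 1).any():
        raise ValueError("every matched-region SNP count must be >= 1")
    return names, counts


def sample_matched_regions(
    stats_set: SummaryStatSet,
    gene_snp_counts,
    rng: np.random.Generator,
    exclude: np.ndarray | None = None,
    max_redraws: int = 1000,
) -> list[tuple[int, int]]:
    """Draw one uniformly random contiguous SNP window per gene count.

    Each window of length n is drawn uniformly over every genome-ordered
    start position where n consecutive SNPs fit without crossing a
    chromosome boundary; windows are drawn independently and may overlap.
    Returns (start_index, length) pairs into the sorted SNP table.
    """
    names, counts = _counts_list(gene_snp_counts)
    blocks = stats_set.chrom_blocks()
    block_starts = np.array([b[1] for b in blocks])
    block_sizes = np.array([b[2] - b[1] for b in blocks])
    excluded = None
    if exclude is not None:
        excluded = np.zeros(len(stats_set), dtype=bool)
        excluded[np.asarray(exclude)] = True

    windows: list[tuple[int, int]] = []
    for name, n in zip(names, counts):
        feas = np.maximum(block_sizes - n + 1, 0)
        total = int(feas.sum())
        if total == 0:
            raise ValueError(
                f"{name}: no chromosome holds {n} consecutive SNPs"
            )
        cum = np.cumsum(feas)
        for _ in range(max_redraws):
            u = int(rng.integers(total))
            b = int(np.searchsorted(cum, u, side="right"))
            start = int(block_starts[b] + (u - (cum[b - 1] if b else 0)))
            if excluded is None or not excluded[start : start + n].any():
                break
        else:
            raise ValueError(f"{name}: could not place a window avoiding the gene set")
        windows.append((start, int(n)))
    return windows


def _window_counts(csum: np.ndarray, windows: list[tuple[int, int]]) -> np.ndarray:
    """Significant-SNP count per window from a prefix-sum of indicators."""
    s = np.array([w[0] for w in windows])
    e = s + np.array([w[1] for w in windows])
    return csum[e] - csum[s]


def bootstrap_gene_set_enrichment(
    stats_set: SummaryStatSet,
    gene_index: dict[str, np.ndarray],
    config: BootstrapConfig,
) -> BootstrapResult:
    """Matched-window bootstrap test of significant-SNP over-representation.

    The observed statistic at each threshold is the number of *distinct*
    gene-set SNPs with p <= threshold; each replicate redraws one
    SNP-count-matched window per gene and counts significant SNPs summed
    over windows. The empirical p is the proportion of replicates with a
    count >= observed.
    """
    if not gene_index:
        raise ValueError("gene_index is empty")
    p = stats_set.p
    union = np.unique(np.concatenate([np.asarray(v) for v in gene_index.values()]))
    thresholds = tuple(config.thresholds)
    observed = np.array([(p[union] <= t).sum() for t in thresholds])

    counts = {g: len(v) for g, v in gene_index.items() if len(v) > 0}
    rng = np.random.default_rng(config.seed)
    csums = [np.concatenate([[0], np.cumsum(p <= t)]) for t in thresholds]
    B = config.n_replicates
    rep = np.zeros((B, len(thresholds)), dtype=int)
    if config.exclude_observed:
        for b in range(B):
            windows = sample_matched_regions(stats_set, counts, rng, exclude=union)
            for j, csum in enumerate(csums):
                rep[b, j] = _window_counts(csum, windows).sum()
    else:
        # independent windows: draw all replicates of each gene's window at once
        names, cnts = _counts_list(counts)
        blocks = stats_set.chrom_blocks()
        block_starts = np.array([b[1] for b in blocks])
        block_sizes = np.array([b[2] - b[1] for b in blocks])
        for name, n_i in zip(names, cnts):
            feas = np.maximum(block_sizes - n_i + 1, 0)
            total = int(feas.sum())
            if total == 0:
                raise ValueError(f"{name}: no chromosome holds {n_i} consecutive SNPs")
            cum = np.cumsum(feas)
            u = rng.integers(total, size=B)
            blk = np.searchsorted(cum, u, side="right")
            prev = np.where(blk > 0, cum[blk - 1], 0)
            starts = block_starts[blk] + (u - prev)
            for j, csum in enumerate(csums):
                rep[:, j] += csum[starts + n_i] - csum[starts]

    if config.empirical_mode == "add-one":
        emp = ((rep >= observed).sum(0) + 1) / (B + 1)
    else:
        emp = (rep >= observed).sum(0) / B
    return BootstrapResult(
        thresholds=thresholds,
        observed=observed,
        expected_mean=rep.mean(0),
        expected_sd=rep.std(0, ddof=1) if B > 1 else np.zeros(len(thresholds)),
        empirical_p=emp,
        replicate_counts=rep,
    )


def order_statistic_index(m_total: int, alpha: float) -> int:
    """k = ceil(alpha * M), the rank of the recorded order statistic."""
    if m_total < 1:
        raise ValueError("need at least one SNP")
    scaled = round(alpha * m_total, 9)
    if scaled < 1.0:
        raise ValueError("alpha * M < 1: the order-statistic rank would be 0")
    return math.ceil(scaled)


def experimentwide_threshold(
    stats_set: SummaryStatSet,
    gene_snp_counts,
    alpha: float = 0.05,
    config: BootstrapConfig | None = None,
) -> ThresholdResult:
    """Empirical experiment-wide significance threshold.

    Per replicate, the p-values of all matched windows (M = sum of gene
    SNP counts) are pooled and the k-th smallest recorded, k =
    ceil(alpha * M); the threshold is the mean over replicates.
    """
    config = config or BootstrapConfig()
    _, counts = _counts_list(gene_snp_counts)
    m_total = int(counts.sum())
    k = order_statistic_index(m_total, alpha)
    p = stats_set.p
    rng = np.random.default_rng(config.seed)
    per_rep = np.empty(config.n_replicates)
    for b in range(config.n_replicates):
        windows = sample_matched_regions(stats_set, counts, rng)
        pool = np.concatenate([p[s : s + n] for s, n in windows])
        per_rep[b] = np.partition(pool, k - 1)[k - 1]
    return ThresholdResult(k=k, m_total=m_total, threshold=float(per_rep.mean()),
                           per_replicate=per_rep)


def empirical_min_p(
    observed_min_p: float,
    stats_set: SummaryStatSet,
    gene_snp_counts,
    config: BootstrapConfig | None = None,
) -> MinPResult:
    """Empirical significance of the single best marker in a gene set.

    Per replicate the minimum p over all matched windows is recorded; the
    returned p is the proportion of replicates whose minimum is <= the
    observed minimum.
    """
    if not (0.0 < observed_min_p <= 1.0):
        raise ValueError("observed_min_p must lie in (0, 1]")
    config = config or BootstrapConfig()
    _, counts = _counts_list(gene_snp_counts)
    p = stats_set.p
    rng = np.random.default_rng(config.seed)
    minima = np.empty(config.n_replicates)
    for b in range(config.n_replicates):
        windows = sample_matched_regions(stats_set, counts, rng)
        minima[b] = min(p[s : s + n].min() for s, n in windows)
    return MinPResult(
        p_value=float((minima <= observed_min_p).mean()),
        observed_min_p=observed_min_p,
        replicate_minima=minima,
    )
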