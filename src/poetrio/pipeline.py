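"""End-to-end orchestration of the two-step parent-of-origin design.

Step 1 screens GWAS summary statistics within a candidate gene set
against an empirical experiment-wide threshold (matched-window
bootstrap); surviving SNPs are LD-pruned within each gene. Step 2 finds
the best trio proxy for each retained SNP and runs the stratified POE
likelihood-ratio test on it, with a multiplicity correction over the
number of retained independent SNPs.

A separate scan applies the POE test directly to a list of pre-defined
independent index markers (or their proxies) and summarises nominal
significance with the exact binomial test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import enrichment, ld, poe_model
from .gene_annotation import SummaryStatSet
from .trio_io import TrioCohort

log = logging.getLogger(__name__)


@dataclass
class IndexScanReport:
    """Per-index-marker POE results plus the binomial enrichment summary."""

    table: pd.DataFrame
    n_resolved: int
    n_unresolved: int
    n_significant: int
    alpha: float
    binomial_p: float | None


def index_marker_poe_scan(
    index_list: pd.DataFrame,
    cohort: TrioCohort,
    alpha: float = 0.05,
    window_bp: int = 500_000,
    r2_min: float = 0.8,
    ld_table: dict[tuple[str, str], float] | None = None,
) -> IndexScanReport:
    """POE-test each index marker (or its best proxy) and test enrichment.

    ``index_list`` needs columns (snp, chrom, pos). Unresolved indices
    (no genotyped marker or adequate proxy) are reported but excluded
    from the binomial test's denominator.
    """
    rows = []
    for row in index_list.itertuples(index=False):
        proxy = ld.find_best_proxy(
            str(row.snp), int(row.chrom), int(row.pos), cohort,
            window_bp=window_bp, r2_min=r2_min, ld_table=ld_table,
        )
        rec = {
            "snp": row.snp, "chrom": row.chrom, "pos": row.pos,
            "proxy": proxy.proxy_id, "r2": proxy.r2, "reason": proxy.reason,
            "poe_or": np.nan, "p_poe": np.nan, "p_assoc": np.nan,
        }
        if proxy.found:
            tally = poe_model.tally_transmissions(cohort, proxy.proxy_id)
            res = poe_model.poe_test(tally)
            rec.update(poe_or=res.poe_or, p_poe=res.p_value, p_assoc=res.assoc_p)
        rows.append(rec)
    table = pd.DataFrame(rows)
    resolved = table["proxy"].notna()
    n_resolved = int(resolved.sum())
    n_sig = int((table.loc[resolved, "p_poe"] <= alpha).sum())
    binom_p = (
        enrichment.binomial_enrichment(n_sig, n_resolved, alpha)
        if n_resolved > 0
        else None
    )
    return IndexScanReport(
        table=table,
        n_resolved=n_resolved,
        n_unresolved=int((~resolved).sum()),
        n_significant=n_sig,
        alpha=alpha,
        binomial_p=binom_p,
    )


@dataclass
class TwoStepConfig:
    seed: int
    alpha: float = 0.05
    n_replicates: int = 1000
    r2_prune: float = 0.5
    window_bp: int = 500_000
    r2_strong: float = 0.8
    #: "bonferroni" or "sidak"
    correction: str = "bonferroni"

    def __post_init__(self) -> None:
        if self.correction not in ("bonferroni", "sidak"):
            raise ValueError("correction must be 'bonferroni' or 'sidak'")


@dataclass
class TwoStepReport:
    """Outputs of the two-step scan (thresholding, pruning, POE tests)."""

    threshold: enrichment.ThresholdResult
    step1: pd.DataFrame
    pruned: pd.DataFrame
    step2: pd.DataFrame
    n_retained: int


def _cohort_r2_lookup(cohort: TrioCohort):
    cache: dict[tuple[str, str], float | None] = {}

    def get(a: str, b: str):
        key = (a, b) if a <= b else (b, a)
        if key not in cache:
            if a in cohort and b in cohort:
                try:
                    cache[key] = ld.pairwise_r2(cohort, a, b).r2
                except ld.MonomorphicMarkerError:
                    cache[key] = None
            else:
                cache[key] = None
        return cache[key]

    return get


def two_step_poe_scan(
    stats: SummaryStatSet,
    gene_index: dict[str, np.ndarray],
    cohort: TrioCohort,
    config: TwoStepConfig,
    ld_table: dict[tuple[str, str], float] | None = None,
) -> TwoStepReport:
    """Run the full two-step design.

    (1) empirical experiment-wide threshold from the matched-window
    bootstrap; (2) gene-set SNPs at or below it; (3) greedy LD pruning
    (r² > ``r2_prune``) within each gene, most significant first; (4) best
    trio proxy per retained SNP within ``window_bp`` (proxies below
    ``r2_strong`` are flagged weak but still tested); (5) stratified POE
    test per proxy; (6) multiplicity correction over the retained
    independent SNPs.
    """
    counts = {g: len(v) for g, v in gene_index.items() if len(v) > 0}
    boot_cfg = enrichment.BootstrapConfig(
        n_replicates=config.n_replicates, seed=config.seed
    )
    thr = enrichment.experimentwide_threshold(
        stats, counts, alpha=config.alpha, config=boot_cfg
    )

    df = stats.df
    step1_rows = []
    for gene, idx in gene_index.items():
        sub = df.iloc[np.asarray(idx)]
        hits = sub[sub["p"] <= thr.threshold]
        for r in hits.itertuples(index=False):
            step1_rows.append(
                {"gene": gene, "snp": r.snp, "chrom": r.chrom, "pos": r.pos, "p": r.p}
            )
    step1 = pd.DataFrame(step1_rows, columns=["gene", "snp", "chrom", "pos", "p"])

    r2_get = _cohort_r2_lookup(cohort)
    pruned_rows = []
    for gene, grp in step1.groupby("gene", sort=True):
        frame = grp.rename(columns={"snp": "id"})[["id", "chrom", "pos", "p"]]
        kept = ld.ld_prune(frame, r2_get, r2_max=config.r2_prune, warn_missing=False)
        pruned_rows.append(grp[grp["snp"].isin(kept)])
    pruned = (
        pd.concat(pruned_rows, ignore_index=True)
        if pruned_rows
        else step1.iloc[0:0].copy()
    )

    step2_rows = []
    for row in pruned.itertuples(index=False):
        proxy = ld.find_best_proxy(
            str(row.snp), int(row.chrom), int(row.pos), cohort,
            window_bp=config.window_bp, r2_min=0.0, ld_table=ld_table,
        )
        rec = {
            "gene": row.gene, "snp": row.snp, "chrom": row.chrom, "pos": row.pos,
            "p_gwas": row.p, "proxy": None, "proxy_pos": np.nan, "r2": np.nan,
            "weak_proxy": np.nan, "r_m": np.nan, "r_p": np.nan,
            "poe_or": np.nan, "p_poe": np.nan,
        }
        if proxy.best_id is not None:
            tally = poe_model.tally_transmissions(cohort, proxy.best_id)
            res = poe_model.poe_test(tally)
            rec.update(
                proxy=proxy.best_id,
                proxy_pos=cohort.marker(proxy.best_id).pos,
                r2=proxy.best_r2,
                weak_proxy=proxy.best_r2 < config.r2_strong,
                r_m=res.r_m, r_p=res.r_p, poe_or=res.poe_or, p_poe=res.p_value,
            )
        step2_rows.append(rec)
    step2 = pd.DataFrame(
        step2_rows,
        columns=["gene", "snp", "chrom", "pos", "p_gwas", "proxy", "proxy_pos",
                 "r2", "weak_proxy", "r_m", "r_p", "poe_or", "p_poe"],
    )

    n_retained = len(step2)
    if n_retained:
        raw = step2["p_poe"].to_numpy(float)
        if config.correction == "sidak":
            corrected = 1.0 - (1.0 - raw) ** n_retained
        else:
            corrected = np.minimum(1.0, raw * n_retained)
        step2["p_corrected"] = corrected
    else:
        step2["p_corrected"] = pd.Series(dtype=float)
    return TwoStepReport(
        threshold=thr, step1=step1, pruned=pruned, step2=step2, n_retained=n_retained
    )
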