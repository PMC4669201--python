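"""Synthetic inputs for the parent-of-origin pipeline.

Three generators, all fully reproducible from (config, seed) and all
paired with a ledger recording the generating truth:

* trio cohorts: parents drawn under Hardy-Weinberg, children drawn from
  the same conditional transmission model the analysis fits (per-parent
  transmission of the risk allele with odds multiplied by r_p or r_m),
  with optional Mendelian-error injection and missingness;
* founder genotype pairs from explicit two-locus haplotype frequencies,
  with the generating r² returned in closed form;
* genome-ordered GWAS p-value pools with genes carved as contiguous SNP
  spans whose per-gene SNP counts are strongly right-skewed
  (median well below the mean, as real gene annotations are).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .gene_annotation import GeneSpan, SummaryStatSet
from .trio_io import CHILD, FATHER, MENDEL_COMPAT, MISSING, MOTHER, Marker, TrioCohort

log = logging.getLogger(__name__)

#: Default per-gene SNP-count distribution: log-normal with median 73 and
#: mean ~ 303 (sigma solves exp(mu + sigma^2/2) = mean with mu = ln median).
_GENE_COUNT_MEDIAN = 73.0
_GENE_COUNT_MEAN = 303.0
_GENE_COUNT_SIGMA = math.sqrt(2.0 * math.log(_GENE_COUNT_MEAN / _GENE_COUNT_MEDIAN))


@dataclass
class TrioSimConfig:
    """Generating conditions for a simulated trio cohort.

    ``mafs``, ``r_m`` and ``r_p`` may be scalars (shared by all markers)
    or per-marker arrays; ``mafs`` are founder risk-allele frequencies.
    ``mendel_error_rate`` is the fraction of complete trio-marker cells
    whose child call is corrupted to a Mendelian-impossible genotype;
    ``missing_rate`` the fraction of trio-marker cells with one member
    call set missing.
    """

    seed: int
    n_trios: int = 695
    mafs: float | Sequence[float] = 0.3
    r_m: float | Sequence[float] = 1.0
    r_p: float | Sequence[float] = 1.0
    n_markers: int | None = None
    mendel_error_rate: float = 0.0
    missing_rate: float = 0.0
    chroms: Sequence[int] | None = None
    positions: Sequence[int] | None = None
    marker_ids: Sequence[str] | None = None

    def __post_init__(self) -> None:
        if self.n_trios < 1:
            raise ValueError("n_trios must be >= 1")
        for rate in (self.mendel_error_rate, self.missing_rate):
            if not (0.0 <= rate < 1.0):
                raise ValueError("rates must lie in [0, 1)")
        n = self.n_markers
        for name in ("mafs", "r_m", "r_p"):
            v = getattr(self, name)
            if np.ndim(v) > 0:
                n = len(v) if n is None else n
                if len(v) != n:
                    raise ValueError("per-marker arrays must share one length")
        self.n_markers = 1 if n is None else n
        mafs = np.broadcast_to(np.asarray(self.mafs, float), (self.n_markers,))
        if not ((mafs > 0) & (mafs <= 0.5)).all():
            raise ValueError("mafs must lie in (0, 0.5]")
        for name in ("r_m", "r_p"):
            v = np.broadcast_to(np.asarray(getattr(self, name), float), (self.n_markers,))
            if not (v > 0).all():
                raise ValueError(f"{name} must be positive")


@dataclass
class TrioSimLedger:
    """Generating truth for a simulated cohort.

    ``a_p`` / ``a_m`` record the paternally / maternally transmitted
    risk-allele count per trio-marker cell *before* error injection;
    ``error_cells`` and ``missing_cells`` list every corrupted cell.
    """

    a_p: np.ndarray
    a_m: np.ndarray
    error_cells: pd.DataFrame
    missing_cells: pd.DataFrame
    mafs: np.ndarray
    r_m: np.ndarray
    r_p: np.ndarray


def simulate_trio_cohort(config: TrioSimConfig) -> tuple[TrioCohort, TrioSimLedger]:
    """Simulate a cohort of complete trios under the transmission model.

    Parent genotypes are Binomial(2, maf) (Hardy-Weinberg); each parent
    transmits the risk allele with probability 1 (hom-risk), 0 (hom-ref)
    or r/(1+r) (het), with r = r_p for fathers and r_m for mothers — the
    exact conditional model the analysis likelihood fits.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_trios, config.n_markers
    mafs = np.broadcast_to(np.asarray(config.mafs, float), (m,))
    r_m = np.broadcast_to(np.asarray(config.r_m, float), (m,))
    r_p = np.broadcast_to(np.asarray(config.r_p, float), (m,))

    father = rng.binomial(2, mafs, size=(n, m))
    mother = rng.binomial(2, mafs, size=(n, m))
    p_pat = np.where(father == 1, r_p / (1 + r_p), father / 2.0)
    p_mat = np.where(mother == 1, r_m / (1 + r_m), mother / 2.0)
    a_p = (rng.random((n, m)) < p_pat).astype(np.int8)
    a_m = (rng.random((n, m)) < p_mat).astype(np.int8)
    child = a_p + a_m

    geno = np.empty((n, m, 3), dtype=np.int8)
    geno[:, :, FATHER] = father
    geno[:, :, MOTHER] = mother
    geno[:, :, CHILD] = child

    # Mendelian-error injection: the corrupted-cell count is Binomial(cells,
    # rate) and cells are drawn among corruptible strata (everything except
    # het x het, where every child genotype is Mendelian-consistent).
    error_rows = []
    if config.mendel_error_rate > 0:
        n_cells = n * m
        n_err = rng.binomial(n_cells, config.mendel_error_rate)
        eligible = np.flatnonzero(~((father == 1) & (mother == 1)).ravel())
        if n_err > eligible.size:
            raise ValueError("error rate too high for the available corruptible cells")
        chosen = rng.choice(eligible, size=n_err, replace=False)
        for flat in chosen:
            i, j = divmod(int(flat), m)
            f, mo = int(father[i, j]), int(mother[i, j])
            bad = np.flatnonzero(~MENDEL_COMPAT[f, mo])
            new_child = int(rng.choice(bad))
            error_rows.append(
                {"trio": i, "marker": j, "old_child": int(child[i, j]), "new_child": new_child}
            )
            geno[i, j, CHILD] = new_child
    error_cells = pd.DataFrame(error_rows, columns=["trio", "marker", "old_child", "new_child"])

    missing_rows = []
    if config.missing_rate > 0:
        n_miss = rng.binomial(n * m, config.missing_rate)
        cells = rng.choice(n * m, size=n_miss, replace=False)
        members = rng.integers(0, 3, size=n_miss)
        for flat, member in zip(cells, members):
            i, j = divmod(int(flat), m)
            geno[i, j, member] = MISSING
            missing_rows.append({"trio": i, "marker": j, "member": int(member)})
    missing_cells = pd.DataFrame(missing_rows, columns=["trio", "marker", "member"])

    if config.marker_ids is not None:
        ids = list(config.marker_ids)
    else:
        ids = [f"snp{j + 1}" for j in range(m)]
    chroms = list(config.chroms) if config.chroms is not None else [1] * m
    positions = (
        list(config.positions)
        if config.positions is not None
        else [10_000 * (j + 1) for j in range(m)]
    )
    markers = [
        Marker(id=ids[j], chrom=chroms[j], pos=positions[j], allele_a="A", allele_b="B",
               risk_allele="B")
        for j in range(m)
    ]
    trios = pd.DataFrame(
        {
            "fid": [f"fam{i + 1}" for i in range(n)],
            "father": [f"fam{i + 1}-f" for i in range(n)],
            "mother": [f"fam{i + 1}-m" for i in range(n)],
            "child": [f"fam{i + 1}-c" for i in range(n)],
        }
    )
    cohort = TrioCohort(trios=trios, markers=markers, genotypes=geno)
    ledger = TrioSimLedger(
        a_p=a_p,
        a_m=a_m,
        error_cells=error_cells,
        missing_cells=missing_cells,
        mafs=np.array(mafs),
        r_m=np.array(r_m),
        r_p=np.array(r_p),
    )
    return cohort, ledger


def write_ped_map(cohort: TrioCohort, ped_path, map_path) -> None:
    """Write a cohort as PLINK-style PED/MAP text."""
    with open(map_path, "w") as fh:
        for mk in cohort.markers:
            fh.write(f"{mk.chrom}\t{mk.id}\t0\t{mk.pos}\n")
    with open(ped_path, "w") as fh:
        for i, row in cohort.trios.iterrows():
            members = [
                (row["father"], "0", "0", "1", FATHER),
                (row["mother"], "0", "0", "2", MOTHER),
                (row["child"], row["father"], row["mother"], "0", CHILD),
            ]
            for iid, pat, mat, sex, member in members:
                pheno = "2" if member == CHILD else "1"
                fields = [row["fid"], iid, pat, mat, sex, pheno]
                for j, mk in enumerate(cohort.markers):
                    d = cohort.genotypes[i, j, member]
                    if d < 0:
                        fields += ["0", "0"]
                    else:
                        fields += [mk.allele_b] * d + [mk.allele_a] * (2 - d)
                fh.write(" ".join(map(str, fields)) + "\n")


# ---------------------------------------------------------------------------
# LD founders


@dataclass
class LdFounderSim:
    g1: np.ndarray
    g2: np.ndarray
    hap_freqs: np.ndarray
    d: float
    r2: float


def haplotype_r2(hap_freqs) -> tuple[float, float]:
    """Closed-form (D, r²) from (f_AB, f_Ab, f_aB, f_ab)."""
    f = np.asarray(hap_freqs, float)
    if f.shape != (4,) or (f < 0).any() or abs(f.sum() - 1.0) > 1e-9:
        raise ValueError("need four non-negative haplotype frequencies summing to 1")
    pa = f[0] + f[1]
    pb = f[0] + f[2]
    denom = pa * (1 - pa) * pb * (1 - pb)
    if denom == 0:
        raise ValueError("monomorphic haplotype frequencies: r2 undefined")
    d = float(f[0] - pa * pb)
    return d, float(d * d / denom)


def simulate_ld_founders(hap_freqs, n_founders: int, seed: int) -> LdFounderSim:
    """Founder genotype pairs from explicit two-locus haplotype frequencies.

    Each founder is two independent haplotype draws; the generating D and
    r² are returned in closed form alongside the genotypes.
    """
    d, r2 = haplotype_r2(hap_freqs)
    f = np.asarray(hap_freqs, float)
    rng = np.random.default_rng(seed)
    draws = rng.choice(4, size=(n_founders, 2), p=f / f.sum())
    # haplotype index -> (allele at marker 1, allele at marker 2)
    allele1 = np.array([1, 1, 0, 0])
    allele2 = np.array([1, 0, 1, 0])
    g1 = allele1[draws].sum(axis=1)
    g2 = allele2[draws].sum(axis=1)
    return LdFounderSim(g1=g1, g2=g2, hap_freqs=f, d=d, r2=r2)


# ---------------------------------------------------------------------------
# GWAS p-value pools


def default_gene_count_sampler(rng: np.random.Generator, n: int) -> np.ndarray:
    """Right-skewed per-gene SNP counts (log-normal; median 73, mean ~303)."""
    counts = rng.lognormal(math.log(_GENE_COUNT_MEDIAN), _GENE_COUNT_SIGMA, size=n)
    return np.maximum(np.rint(counts).astype(int), 1)


def default_effect_model(rng: np.random.Generator, n: int) -> np.ndarray:
    """Sub-uniform p-values for associated SNPs: p = 10**(-U(4, 12))."""
    return 10.0 ** (-rng.uniform(4.0, 12.0, size=n))


@dataclass
class PoolSimConfig:
    """Generating conditions for an annotated genome-ordered p-value pool."""

    seed: int
    n_snps: int = 150_000
    n_genes: int = 225
    n_chroms: int = 22
    pi0: float = 1.0
    gene_count_sampler: Callable[[np.random.Generator, int], np.ndarray] = field(
        default=default_gene_count_sampler
    )
    gene_counts: Sequence[int] | None = None
    effect_model: Callable[[np.random.Generator, int], np.ndarray] = field(
        default=default_effect_model
    )
    #: "anywhere" or "outside-genes": where non-null SNPs may land.
    effect_placement: str = "anywhere"
    planted_gene: int | None = None
    planted_p: float = 1e-13
    max_gap_snps: int = 20

    def __post_init__(self) -> None:
        if not (0.0 <= self.pi0 <= 1.0):
            raise ValueError("pi0 must lie in [0, 1]")
        if self.effect_placement not in ("anywhere", "outside-genes"):
            raise ValueError("effect_placement must be 'anywhere' or 'outside-genes'")
        if not (0.0 < self.planted_p <= 1.0):
            raise ValueError("planted_p must lie in (0, 1]")


@dataclass
class PoolSim:
    stats: SummaryStatSet
    genes: list[GeneSpan]
    gene_index: dict[str, np.ndarray]
    gene_counts: np.ndarray
    nonnull_idx: np.ndarray


def simulate_pool(config: PoolSimConfig) -> PoolSim:
    """Simulate a genome-ordered p-value pool with contiguous gene spans.

    SNPs are laid out in order across ``n_chroms`` synthetic autosomes;
    genes occupy consecutive runs of SNPs separated by random gaps; null
    p-values are Uniform(0, 1) and non-null ones come from
    ``effect_model``. A planted gene (optional) has all its SNPs set to
    jittered multiples of ``planted_p``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_snps
    n_chr = config.n_chroms

    base, extra = divmod(n, n_chr)
    chrom_sizes = np.full(n_chr, base)
    chrom_sizes[:extra] += 1
    chroms = np.repeat(np.arange(1, n_chr + 1), chrom_sizes)
    positions = np.concatenate(
        [np.cumsum(rng.integers(500, 10_000, size=sz)) for sz in chrom_sizes]
    )

    if config.gene_counts is not None:
        counts = np.asarray(list(config.gene_counts), dtype=int)
        if len(counts) != config.n_genes:
            raise ValueError("gene_counts length must equal n_genes")
    else:
        counts = config.gene_count_sampler(rng, config.n_genes)
        # the log-normal tail can exceed a scaled-down chromosome; clip
        # drawn counts to half a chromosome so the greedy layout stays feasible
        cap = int(chrom_sizes.min()) // 2
        if (counts > cap).any():
            log.warning("clipped %d gene SNP counts to %d", int((counts > cap).sum()), cap)
            counts = np.minimum(counts, cap)
    if (counts < 1).any():
        raise ValueError("gene SNP counts must be >= 1")

    # Carve genes chromosome by chromosome, separated by random gaps.
    chrom_bounds = np.concatenate([[0], np.cumsum(chrom_sizes)])
    gene_rows: list[tuple[int, int]] = []  # (start index, count)
    chrom_of_gene: list[int] = []
    c = 0
    cursor = int(chrom_bounds[0])
    for g, cnt in enumerate(counts):
        placed = False
        while c < n_chr:
            gap = int(rng.integers(1, config.max_gap_snps + 1))
            start = cursor + gap
            if start + cnt <= chrom_bounds[c + 1]:
                gene_rows.append((start, int(cnt)))
                chrom_of_gene.append(c + 1)
                cursor = start + cnt
                placed = True
                break
            c += 1
            cursor = int(chrom_bounds[c]) if c < n_chr else cursor
        if not placed:
            raise ValueError(
                f"gene {g}: pool of {n} SNPs cannot hold {config.n_genes} genes "
                f"with the drawn SNP counts"
            )

    in_gene = np.zeros(n, dtype=bool)
    for start, cnt in gene_rows:
        in_gene[start : start + cnt] = True

    p = rng.uniform(0.0, 1.0, size=n)
    p = np.maximum(p, 1e-300)
    n_nonnull = int(round((1.0 - config.pi0) * n))
    if n_nonnull > 0:
        pool_idx = np.flatnonzero(~in_gene) if config.effect_placement == "outside-genes" else np.arange(n)
        if n_nonnull > pool_idx.size:
            raise ValueError("too many non-null SNPs for the chosen placement")
        nonnull_idx = np.sort(rng.choice(pool_idx, size=n_nonnull, replace=False))
        p[nonnull_idx] = config.effect_model(rng, n_nonnull)
    else:
        nonnull_idx = np.array([], dtype=int)

    genes: list[GeneSpan] = []
    gene_index: dict[str, np.ndarray] = {}
    for g, ((start, cnt), chrom) in enumerate(zip(gene_rows, chrom_of_gene)):
        symbol = f"gene{g + 1:03d}"
        idx = np.arange(start, start + cnt)
        gene_index[symbol] = idx
        genes.append(
            GeneSpan(symbol=symbol, chrom=chrom, start=int(positions[start]),
                     end=int(positions[start + cnt - 1]))
        )
        if config.planted_gene is not None and g == config.planted_gene:
            p[idx] = config.planted_p * rng.uniform(0.2, 1.0, size=cnt)

    snp_ids = [f"rs{i + 1}" for i in range(n)]
    df = pd.DataFrame(
        {
            "snp": snp_ids,
            "chrom": chroms,
            "pos": positions,
            "a1": "A",
            "a2": "B",
            "odds_ratio": np.exp(rng.normal(0.0, 0.05, size=n)),
            "p": p,
        }
    )
    stats = SummaryStatSet(df, gene_index=gene_index)
    return PoolSim(stats=stats, genes=genes, gene_index=gene_index,
                   gene_counts=counts, nonnull_idx=nonnull_idx)


# ---------------------------------------------------------------------------
# End-to-end planted-signal scenario


@dataclass
class TwoStepScenario:
    """A pool with one planted gene plus matching trios carrying a POE there."""

    pool: PoolSim
    cohort: TrioCohort
    planted_gene: str
    true_poe_or: float


def simulate_two_step_scenario(
    seed: int,
    n_trios: int = 695,
    n_snps: int = 30_000,
    n_genes: int = 30,
    planted_gene: int = 12,
    planted_snps: int = 8,
    true_r_p: float = 3.16,
    n_background_markers: int = 12,
    pi0: float = 0.94,
    max_gene_snps: int = 1000,
) -> TwoStepScenario:
    """GWAS pool with one planted significant gene and trios genotyped there.

    Background association signals (driving the experiment-wide threshold
    down, as in a well-powered GWAS) lie outside the candidate gene set;
    every SNP of the planted gene carries an ultra-significant p-value and
    is genotyped in the trios with a paternal transmission distortion of
    ``true_r_p``. A handful of null gene-set SNPs are genotyped too.
    """
    ss = np.random.SeedSequence(seed)
    s_pool, s_counts, s_trio, s_pick = (int(c.generate_state(1)[0] % 2**31)
                                        for c in ss.spawn(4))
    rng = np.random.default_rng(s_counts)
    # cap the log-normal tail so every gene fits on one scaled-down chromosome
    cap = min(max_gene_snps, n_snps // 44)
    counts = np.minimum(default_gene_count_sampler(rng, n_genes), cap)
    counts[planted_gene] = planted_snps
    pool = simulate_pool(
        PoolSimConfig(
            seed=s_pool,
            n_snps=n_snps,
            n_genes=n_genes,
            gene_counts=counts,
            pi0=pi0,
            effect_placement="outside-genes",
            planted_gene=planted_gene,
        )
    )
    planted_symbol = pool.genes[planted_gene].symbol
    planted_idx = pool.gene_index[planted_symbol]

    other_idx = np.concatenate(
        [v for k, v in pool.gene_index.items() if k != planted_symbol]
    )
    background = np.random.default_rng(s_pick).choice(
        other_idx, size=n_background_markers, replace=False
    )
    marker_idx = np.concatenate([planted_idx, np.sort(background)])
    df = pool.stats.df
    r_p = np.where(np.isin(marker_idx, planted_idx), true_r_p, 1.0)
    cohort, _ = simulate_trio_cohort(
        TrioSimConfig(
            seed=s_trio,
            n_trios=n_trios,
            mafs=np.full(marker_idx.size, 0.3),
            r_p=r_p,
            marker_ids=[df.loc[i, "snp"] for i in marker_idx],
            chroms=[int(df.loc[i, "chrom"]) for i in marker_idx],
            positions=[int(df.loc[i, "pos"]) for i in marker_idx],
        )
    )
    return TwoStepScenario(
        pool=pool, cohort=cohort, planted_gene=planted_symbol, true_poe_or=true_r_p
    )
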