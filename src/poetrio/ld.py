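"""Pairwise LD (r²) from unphased founder genotypes, proxy search, pruning.

r² is estimated by the classic two-locus haplotype-frequency EM: the only
phase ambiguity in biallelic data is the double heterozygote, which is
split between the cis and trans configurations in proportion to the
current haplotype-frequency products. LD is computed in founders
(the parents) only, since offspring chromosomes duplicate parental ones.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trio_io import TrioCohort

log = logging.getLogger(__name__)


class MonomorphicMarkerError(ValueError):
    """r² is undefined (not zero) when either marker is monomorphic."""


@dataclass
class LdEstimate:
    """EM haplotype-frequency estimate for one marker pair.

    ``hap_freqs`` is (f_AB, f_Ab, f_aB, f_ab) where A/B denote the
    dosage-counted alleles of the two markers; ``d`` is the
    disequilibrium coefficient D = f_AB - p_A p_B and
    ``r2 = D² / (p_A p_a p_B p_b)``.
    """

    hap_freqs: np.ndarray
    d: float
    r2: float
    n_founders: int
    em_iters: int
    converged: bool
    loglik_trace: tuple[float, ...] = field(default=(), repr=False)


def _cell_probs(f: np.ndarray) -> np.ndarray:
    """Genotype-cell probabilities P(g1, g2) implied by haplotype freqs."""
    f11, f10, f01, f00 = f
    p = np.empty((3, 3))
    p[2, 2] = f11 ** 2
    p[2, 1] = 2 * f11 * f10
    p[2, 0] = f10 ** 2
    p[1, 2] = 2 * f11 * f01
    p[1, 1] = 2 * (f11 * f00 + f10 * f01)
    p[1, 0] = 2 * f10 * f00
    p[0, 2] = f01 ** 2
    p[0, 1] = 2 * f01 * f00
    p[0, 0] = f00 ** 2
    return p


def r2_unphased(
    g1: np.ndarray,
    g2: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> LdEstimate:
    """EM estimate of r² from two unphased genotype dosage vectors.

    Missing calls (negative dosages) in either vector exclude the
    individual. Initialised at linkage equilibrium; converged when the
    largest haplotype-frequency change drops below ``tol``.
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    ok = (g1 >= 0) & (g2 >= 0)
    g1, g2 = g1[ok], g2[ok]
    n_ind = g1.size
    if n_ind < 2:
        raise ValueError("need at least two founders with complete genotypes")
    n = np.zeros((3, 3))
    np.add.at(n, (g1, g2), 1.0)

    p1 = g1.sum() / (2 * n_ind)
    p2 = g2.sum() / (2 * n_ind)
    if p1 in (0.0, 1.0) or p2 in (0.0, 1.0):
        raise MonomorphicMarkerError("r2 undefined for a monomorphic marker")

    f = np.array([p1 * p2, p1 * (1 - p2), (1 - p1) * p2, (1 - p1) * (1 - p2)])
    n_dh = n[1, 1]
    # Haplotype counts fully determined outside the double-het cell:
    base = np.array(
        [
            2 * n[2, 2] + n[2, 1] + n[1, 2],
            2 * n[2, 0] + n[2, 1] + n[1, 0],
            2 * n[0, 2] + n[0, 1] + n[1, 2],
            2 * n[0, 0] + n[0, 1] + n[1, 0],
        ]
    )
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        with np.errstate(divide="ignore"):
            logp = np.where(n > 0, np.log(np.maximum(_cell_probs(f), 1e-300)), 0.0)
        trace.append(float((n * logp).sum()))
        cis = f[0] * f[3]
        trans = f[1] * f[2]
        p_cis = cis / (cis + trans) if cis + trans > 0 else 0.5
        c = base + n_dh * np.array([p_cis, 1 - p_cis, 1 - p_cis, p_cis])
        f_new = c / (2 * n_ind)
        delta = float(np.abs(f_new - f).max())
        f = f_new
        if delta < tol:
            converged = True
            break

    pa = f[0] + f[1]
    pb = f[0] + f[2]
    d = float(f[0] - pa * pb)
    denom = pa * (1 - pa) * pb * (1 - pb)
    r2 = float(d * d / denom) if denom > 0 else float("nan")
    return LdEstimate(
        hap_freqs=f,
        d=d,
        r2=min(max(r2, 0.0), 1.0),
        n_founders=n_ind,
        em_iters=it,
        converged=converged,
        loglik_trace=tuple(trace),
    )


def pairwise_r2(cohort: TrioCohort, marker1: str, marker2: str, **kwargs) -> LdEstimate:
    """r² between two cohort markers, computed in the founders (parents)."""
    g1 = cohort.founder_dosages(marker1)
    g2 = cohort.founder_dosages(marker2)
    return r2_unphased(g1, g2, **kwargs)


# ---------------------------------------------------------------------------
# Proxy search and pruning


@dataclass
class ProxyResult:
    """Outcome of a best-proxy search for an index marker."""

    index_id: str
    found: bool
    proxy_id: str | None = None
    r2: float | None = None
    distance: int | None = None
    reason: str = ""
    best_id: str | None = None
    best_r2: float | None = None


def load_ld_table(source) -> dict[tuple[str, str], float]:
    """Normalise an external LD table (path/DataFrame) to a symmetric dict.

    Expects columns snp_a, snp_b, r2 (any delimiter for files).
    """
    if isinstance(source, dict):
        items = [(a, b, r) for (a, b), r in source.items()]
    else:
        df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source, sep=None, engine="python")
        items = list(zip(df["snp_a"], df["snp_b"], df["r2"]))
    table: dict[tuple[str, str], float] = {}
    for a, b, r in items:
        table[(str(a), str(b))] = float(r)
        table[(str(b), str(a))] = float(r)
    return table


def find_best_proxy(
    index_id: str,
    chrom: int,
    pos: int,
    cohort: TrioCohort,
    window_bp: int = 500_000,
    r2_min: float = 0.8,
    ld_table: dict[tuple[str, str], float] | None = None,
) -> ProxyResult:
    """Best genotyped surrogate for an index marker within a window.

    A genotyped index is its own perfect proxy (r² = 1). Otherwise the
    cohort marker with the highest r² to the index wins, with ties broken
    by distance then marker id; r² to an ungenotyped index must come from
    an external LD table. ``found`` requires best r² >= ``r2_min``.
    """
    if index_id in cohort:
        m = cohort.marker(index_id)
        return ProxyResult(index_id, True, index_id, 1.0, abs(m.pos - pos),
                           reason="genotyped", best_id=index_id, best_r2=1.0)

    candidates = [
        m for m in cohort.markers if m.chrom == chrom and abs(m.pos - pos) <= window_bp
    ]
    if not candidates:
        return ProxyResult(index_id, False, reason="no-markers-in-window")
    if ld_table is None:
        return ProxyResult(index_id, False, reason="index-not-genotyped-no-ld-table")

    scored = []
    for m in candidates:
        r2 = ld_table.get((index_id, m.id))
        if r2 is not None:
            scored.append((m, float(r2)))
    if not scored:
        return ProxyResult(index_id, False, reason="no-ld-information-in-window")
    best, best_r2 = min(scored, key=lambda t: (-t[1], abs(t[0].pos - pos), t[0].id))
    found = best_r2 >= r2_min
    return ProxyResult(
        index_id,
        found,
        proxy_id=best.id if found else None,
        r2=best_r2 if found else None,
        distance=abs(best.pos - pos) if found else None,
        reason="proxy" if found else "best-r2-below-threshold",
        best_id=best.id,
        best_r2=best_r2,
    )


def ld_prune(
    markers_with_p: pd.DataFrame,
    r2_lookup,
    r2_max: float = 0.5,
    warn_missing: bool = True,
) -> list[str]:
    """Greedy LD pruning: keep the most significant, drop correlated others.

    ``markers_with_p`` needs columns (id, chrom, pos, p). ``r2_lookup`` is
    either a symmetric dict keyed by id pairs or a callable
    ``(id_a, id_b) -> r2 or None``; an unknown pair is treated as r² = 0
    (with a warning). Ties on p break by position, then id.
    """
    if callable(r2_lookup):
        get = r2_lookup
    else:
        table = r2_lookup
        get = lambda a, b: table.get((a, b))  # noqa: E731

    df = markers_with_p.sort_values(
        ["p", "chrom", "pos", "id"], kind="mergesort"
    ).reset_index(drop=True)
    retained: list[str] = []
    missing_warned = False
    dropped: set[str] = set()
    for row in df.itertuples(index=False):
        if row.id in dropped:
            continue
        ok = True
        for kept in retained:
            r2 = get(kept, row.id)
            if r2 is None:
                r2 = 0.0
                if warn_missing and not missing_warned:
                    warnings.warn(
                        "missing LD for at least one marker pair; treating as r2=0",
                        stacklevel=2,
                    )
                    missing_warned = True
            if r2 > r2_max:
                ok = False
                break
        if ok:
            retained.append(row.id)
        else:
            dropped.add(row.id)
    return retained
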