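"""Trio genotype I/O and quality control.

Reads complete father-mother-affected-child trios from PLINK-style PED/MAP
text (or VCF plus a pedigree file), detects Mendelian inconsistencies, and
applies the standard trio QC cascade: family-level Mendelian-error
filtering first, then marker-level filters on Mendelian-error rate,
founder minor allele frequency, and founder Hardy-Weinberg equilibrium.

Genotypes are stored as risk-unoriented dosages of ``allele_b``
(0, 1, 2 copies; ``MISSING`` = -1) in an ``(n_trios, n_markers, 3)``
array whose last axis is (father, mother, child). Only biallelic
autosomal markers are retained.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

log = logging.getLogger(__name__)

MISSING = -1
FATHER, MOTHER, CHILD = 0, 1, 2


class TrioFormatError(ValueError):
    """Malformed pedigree/genotype input."""


class UndefinedValueError(ValueError):
    """A statistic is undefined for the given data (e.g. all-missing marker)."""


class EmptyCohortError(ValueError):
    """QC removed every family or every marker."""


def _mendel_compat_table() -> np.ndarray:
    """27-cell truth table: is child dosage possible given parental dosages?"""
    gametes = {0: (0,), 1: (0, 1), 2: (1,)}
    table = np.zeros((3, 3, 3), dtype=bool)
    for f in range(3):
        for m in range(3):
            for a_p in gametes[f]:
                for a_m in gametes[m]:
                    table[f, m, a_p + a_m] = True
    return table


#: MENDEL_COMPAT[f, m, c] is True iff child dosage c is compatible with
#: parental dosages (f, m) under biallelic Mendelian inheritance.
MENDEL_COMPAT = _mendel_compat_table()


@dataclass(frozen=True)
class Marker:
    """A biallelic autosomal marker.

    ``allele_a``/``allele_b`` are the two observed alleles; genotype
    dosages count copies of ``allele_b``. ``risk_allele`` (optional) names
    the allele tested for over-transmission downstream.
    """

    id: str
    chrom: int
    pos: int
    allele_a: str
    allele_b: str
    risk_allele: str | None = None

    def __post_init__(self) -> None:
        if not (1 <= int(self.chrom) <= 22):
            raise ValueError(f"marker {self.id}: chrom {self.chrom} is not an autosome")
        if self.pos < 1:
            raise ValueError(f"marker {self.id}: position must be >= 1")
        if self.allele_a == self.allele_b:
            raise ValueError(f"marker {self.id}: alleles must differ")
        if self.risk_allele is not None and self.risk_allele not in (
            self.allele_a,
            self.allele_b,
        ):
            raise ValueError(f"marker {self.id}: risk allele not among its alleles")


@dataclass
class TrioCohort:
    """Complete trios x markers genotype container.

    trios : DataFrame with columns (fid, father, mother, child).
    markers : ordered list of :class:`Marker`.
    genotypes : int8 array (n_trios, n_markers, 3); last axis is
        (father, mother, child); values in {0, 1, 2, MISSING}.
    """

    trios: pd.DataFrame
    markers: list[Marker]
    genotypes: np.ndarray
    _marker_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        expected = (len(self.trios), len(self.markers), 3)
        if self.genotypes.shape != expected:
            raise ValueError(
                f"genotype array shape {self.genotypes.shape} != {expected}"
            )
        self._marker_index = {m.id: j for j, m in enumerate(self.markers)}
        if len(self._marker_index) != len(self.markers):
            raise ValueError("duplicate marker ids")

    @property
    def n_trios(self) -> int:
        return len(self.trios)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def marker_column(self, marker_id: str) -> int:
        try:
            return self._marker_index[marker_id]
        except KeyError:
            raise KeyError(f"marker {marker_id!r} not in cohort") from None

    def marker(self, marker_id: str) -> Marker:
        return self.markers[self.marker_column(marker_id)]

    def __contains__(self, marker_id: str) -> bool:
        return marker_id in self._marker_index

    def founder_dosages(self, marker_id: str) -> np.ndarray:
        """Parental dosages at a marker, fathers then mothers (2*n_trios,)."""
        j = self.marker_column(marker_id)
        g = self.genotypes[:, j, :]
        return np.concatenate([g[:, FATHER], g[:, MOTHER]])

    def subset(
        self,
        trio_mask: np.ndarray | None = None,
        marker_mask: np.ndarray | None = None,
    ) -> "TrioCohort":
        trio_mask = (
            np.ones(self.n_trios, bool) if trio_mask is None else np.asarray(trio_mask)
        )
        marker_mask = (
            np.ones(self.n_markers, bool)
            if marker_mask is None
            else np.asarray(marker_mask)
        )
        markers = [m for m, keep in zip(self.markers, marker_mask) if keep]
        return TrioCohort(
            trios=self.trios.loc[trio_mask].reset_index(drop=True),
            markers=markers,
            genotypes=self.genotypes[trio_mask][:, marker_mask].copy(),
        )


@dataclass
class QcReport:
    """Per-family and per-marker QC statistics plus exclusion decisions.

    Rates are fractions in [0, 1]; every exclusion carries exactly one
    primary reason ("mendel", "maf", or "hwe").
    """

    per_family_mendel_rate: pd.Series
    per_marker_mendel_rate: pd.Series
    maf: pd.Series | None = None
    hwe_p: pd.Series | None = None
    excluded_families: list[tuple[str, str]] = field(default_factory=list)
    excluded_markers: list[tuple[str, str]] = field(default_factory=list)
    error_mask: np.ndarray | None = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        """Marker-level QC table (for the tab-delimited report)."""
        df = pd.DataFrame({"mendel_rate": self.per_marker_mendel_rate})
        if self.maf is not None:
            df["maf"] = self.maf
        if self.hwe_p is not None:
            df["hwe_p"] = self.hwe_p
        reasons = dict(self.excluded_markers)
        df["excluded"] = [reasons.get(mid, "") for mid in df.index]
        return df


# ---------------------------------------------------------------------------
# Reading


def _parse_map(map_path) -> tuple[list[dict], list[bool], int]:
    """Parse a PLINK MAP file; returns (rows, autosomal mask, n dropped)."""
    rows: list[dict] = []
    autosomal: list[bool] = []
    n_dropped = 0
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) == 4:
                chrom_s, mid, _cm, pos_s = fields
            elif len(fields) == 3:
                chrom_s, mid, pos_s = fields
            else:
                raise TrioFormatError(
                    f"{map_path}: line {lineno}: expected 3 or 4 fields, got {len(fields)}"
                )
            try:
                pos = int(pos_s)
            except ValueError:
                raise TrioFormatError(
                    f"{map_path}: line {lineno}: bad position {pos_s!r}"
                ) from None
            try:
                chrom = int(chrom_s)
                is_auto = 1 <= chrom <= 22
            except ValueError:
                chrom, is_auto = 0, False
            rows.append({"id": mid, "chrom": chrom, "pos": pos})
            autosomal.append(is_auto)
            if not is_auto:
                n_dropped += 1
    if n_dropped:
        log.warning("dropped %d non-autosomal markers", n_dropped)
    return rows, autosomal, n_dropped


def read_trios(ped_path, map_path) -> TrioCohort:
    """Read a PED/MAP pair, returning only complete father-mother-child trios.

    Incomplete families are dropped with a warning; non-autosomal and
    multi-allelic markers are dropped with a warning. Of multiple complete
    children in a family, the first affected (phenotype "2") child in file
    order is kept as the trio proband.
    """
    map_rows, autosomal, _ = _parse_map(map_path)
    n_all = len(map_rows)

    people: dict[tuple[str, str], dict] = {}
    order: list[tuple[str, str]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_all:
                raise TrioFormatError(
                    f"{ped_path}: line {lineno}: expected {6 + 2 * n_all} fields "
                    f"({n_all} markers), got {len(fields)}"
                )
            fid, iid, pat, mat, _sex, pheno = fields[:6]
            key = (fid, iid)
            if key in people:
                raise TrioFormatError(
                    f"{ped_path}: line {lineno}: duplicate individual {fid}:{iid}"
                )
            alleles = fields[6:]
            people[key] = {
                "fid": fid,
                "iid": iid,
                "pat": pat,
                "mat": mat,
                "pheno": pheno,
                "a1": alleles[0::2],
                "a2": alleles[1::2],
                "line": lineno,
            }
            order.append(key)

    # Allele inventory per autosomal marker.
    keep_cols = [j for j in range(n_all) if autosomal[j]]
    allele_sets: list[set[str]] = [set() for _ in keep_cols]
    for key in order:
        p = people[key]
        for k, j in enumerate(keep_cols):
            for a in (p["a1"][j], p["a2"][j]):
                if a != "0":
                    allele_sets[k].add(a)

    markers: list[Marker] = []
    final_cols: list[int] = []
    n_multi = 0
    for k, j in enumerate(keep_cols):
        obs = sorted(allele_sets[k])
        if len(obs) > 2:
            n_multi += 1
            continue
        if len(obs) == 2:
            a, b = obs
        elif len(obs) == 1:
            a, b = obs[0], "N" if obs[0] != "N" else "?"
        else:  # never genotyped: placeholder alleles, will fail MAF QC
            a, b = "N", "?"
        row = map_rows[j]
        markers.append(
            Marker(id=row["id"], chrom=row["chrom"], pos=row["pos"], allele_a=a, allele_b=b)
        )
        final_cols.append(j)
    if n_multi:
        log.warning("dropped %d multi-allelic markers", n_multi)

    # Trio assembly: a complete trio needs child + both named parents on file.
    fams: dict[str, list[tuple[str, str]]] = {}
    for fid, iid in order:
        fams.setdefault(fid, []).append((fid, iid))
    trio_rows = []
    for fid, members in fams.items():
        present = {iid for _, iid in members}
        candidates = []
        for _, iid in members:
            p = people[(fid, iid)]
            if p["pat"] != "0" and p["mat"] != "0" and p["pat"] in present and p["mat"] in present:
                candidates.append(p)
        if not candidates:
            log.warning("family %s: no complete trio, dropped", fid)
            continue
        candidates.sort(key=lambda p: (p["pheno"] != "2", p["line"]))
        child = candidates[0]
        if len(candidates) > 1:
            log.warning(
                "family %s: %d complete children, keeping %s",
                fid,
                len(candidates),
                child["iid"],
            )
        trio_rows.append(
            {"fid": fid, "father": child["pat"], "mother": child["mat"], "child": child["iid"]}
        )
    trios = pd.DataFrame(trio_rows, columns=["fid", "father", "mother", "child"])

    geno = np.full((len(trios), len(markers), 3), MISSING, dtype=np.int8)
    for i, row in trios.iterrows():
        for member_idx, iid in enumerate((row["father"], row["mother"], row["child"])):
            p = people[(row["fid"], iid)]
            for k, j in enumerate(final_cols):
                a1, a2 = p["a1"][j], p["a2"][j]
                if a1 == "0" or a2 == "0":
                    continue
                m = markers[k]
                try:
                    geno[i, k, member_idx] = (a1 == m.allele_b) + (a2 == m.allele_b)
                except Exception:  # pragma: no cover - defensive
                    raise TrioFormatError(
                        f"{ped_path}: line {p['line']}: bad genotype token at marker {m.id}"
                    )
    return TrioCohort(trios=trios, markers=markers, genotypes=geno)


def read_trios_vcf(vcf_path, pedigree_path) -> TrioCohort:
    """Read trios from a VCF plus a pedigree file.

    The pedigree file is whitespace-delimited with three columns
    (father, mother, child sample names) or four (family id first).
    Only biallelic autosomal SNVs are used.
    """
    from cyvcf2 import VCF

    trio_rows = []
    with open(pedigree_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields or fields[0].startswith("#"):
                continue
            if len(fields) == 3:
                fid, (fa, mo, ch) = f"fam{lineno}", fields
            elif len(fields) == 4:
                fid, fa, mo, ch = fields
            else:
                raise TrioFormatError(
                    f"{pedigree_path}: line {lineno}: expected 3 or 4 fields"
                )
            trio_rows.append({"fid": fid, "father": fa, "mother": mo, "child": ch})

    vcf = VCF(str(vcf_path))
    sample_idx = {s: i for i, s in enumerate(vcf.samples)}
    complete, dropped = [], 0
    for row in trio_rows:
        if all(row[k] in sample_idx for k in ("father", "mother", "child")):
            complete.append(row)
        else:
            dropped += 1
    if dropped:
        log.warning("dropped %d pedigree rows with samples absent from VCF", dropped)
    trios = pd.DataFrame(complete, columns=["fid", "father", "mother", "child"])
    cols = np.array(
        [[sample_idx[r["father"]], sample_idx[r["mother"]], sample_idx[r["child"]]] for r in complete]
    )

    markers, geno_cols = [], []
    for var in vcf:
        chrom_s = var.CHROM.removeprefix("chr")
        try:
            chrom = int(chrom_s)
        except ValueError:
            continue
        if not (1 <= chrom <= 22) or len(var.ALT) != 1 or var.ALT[0] in (".", ""):
            continue
        markers.append(
            Marker(id=var.ID or f"{chrom}:{var.POS}", chrom=chrom, pos=var.POS,
                   allele_a=var.REF, allele_b=var.ALT[0])
        )
        gt = np.asarray(var.gt_types)  # 0 hom-ref, 1 het, 3 hom-alt, 2 unknown
        dose = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING)
        geno_cols.append(dose[cols].astype(np.int8))
    geno = (
        np.stack(geno_cols, axis=1)
        if geno_cols
        else np.empty((len(trios), 0, 3), dtype=np.int8)
    )
    return TrioCohort(trios=trios, markers=markers, genotypes=geno)


# ---------------------------------------------------------------------------
# QC statistics


def _error_and_complete(cohort: TrioCohort) -> tuple[np.ndarray, np.ndarray]:
    g = cohort.genotypes
    complete = (g >= 0).all(axis=2)
    gc = np.clip(g, 0, 2)
    err = complete & ~MENDEL_COMPAT[gc[..., FATHER], gc[..., MOTHER], gc[..., CHILD]]
    return err, complete


def mendelian_check(cohort: TrioCohort) -> QcReport:
    """Per-family and per-marker Mendelian-inconsistency rates.

    A trio-marker cell is an error iff the child dosage is impossible given
    the parental dosages; cells with any missing member genotype enter
    neither numerator nor denominator.
    """
    if cohort.n_trios == 0 or cohort.n_markers == 0:
        raise ValueError("empty cohort")
    err, complete = _error_and_complete(cohort)
    with np.errstate(invalid="ignore", divide="ignore"):
        fam_rate = np.where(
            complete.sum(1) > 0, err.sum(1) / np.maximum(complete.sum(1), 1), 0.0
        )
        mk_rate = np.where(
            complete.sum(0) > 0, err.sum(0) / np.maximum(complete.sum(0), 1), 0.0
        )
    return QcReport(
        per_family_mendel_rate=pd.Series(fam_rate, index=cohort.trios["fid"].to_numpy()),
        per_marker_mendel_rate=pd.Series(mk_rate, index=[m.id for m in cohort.markers]),
        error_mask=err,
    )


def _founder_allele_counts(cohort: TrioCohort) -> tuple[np.ndarray, np.ndarray]:
    """(count of allele_b, count of called alleles) in parents, per marker."""
    g = cohort.genotypes[:, :, (FATHER, MOTHER)]
    called = g >= 0
    nb = np.where(called, g, 0).sum(axis=(0, 2))
    n_alleles = 2 * called.sum(axis=(0, 2))
    return nb, n_alleles


def founder_maf(cohort: TrioCohort, marker_id: str) -> float:
    """Minor allele frequency among the parents (founders) at one marker."""
    j = cohort.marker_column(marker_id)
    nb, n_alleles = _founder_allele_counts(cohort.subset(marker_mask=np.arange(cohort.n_markers) == j))
    if n_alleles[0] == 0:
        raise UndefinedValueError(f"marker {marker_id}: no called parental genotype")
    f = nb[0] / n_alleles[0]
    return float(min(f, 1.0 - f))


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact conditional Hardy-Weinberg test.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote count whose conditional probability does not exceed
    that of the observed count. Returns p in (0, 1].
    """
    for v in (n_aa, n_ab, n_bb):
        if v < 0 or v != int(v):
            raise ValueError("genotype counts must be non-negative integers")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("at least one genotype required")
    nb = 2 * n_bb + n_ab
    rare = min(nb, 2 * n - nb)
    if rare == 0:
        return 1.0
    hets = np.arange(rare % 2, rare + 1, 2)
    # Unnormalised log P(n_ab = h | allele counts): h*ln2 - sum of genotype factorials
    n_rr = (rare - hets) // 2
    n_cc = n - n_rr - hets
    logw = hets * math.log(2.0) - gammaln(n_rr + 1) - gammaln(hets + 1) - gammaln(n_cc + 1)
    logp = logw - logsumexp(logw)
    obs = np.searchsorted(hets, min(n_ab, rare))
    if hets[obs] != n_ab:
        raise ValueError("observed heterozygote count inconsistent with allele counts")
    p = float(np.exp(logp)[np.exp(logp) <= np.exp(logp[obs]) * (1 + 1e-12)].sum())
    return min(p, 1.0)


def apply_qc(
    cohort: TrioCohort,
    family_mendel_max: float = 0.03,
    marker_mendel_max: float = 0.01,
    maf_min: float = 0.01,
    hwe_min: float = 1e-6,
) -> tuple[TrioCohort, QcReport]:
    """Apply the trio QC cascade.

    Order: (1) drop families whose Mendelian-error rate over all tested
    markers exceeds ``family_mendel_max``; (2) recompute marker statistics
    on the retained families; (3) drop markers failing the marker-level
    Mendelian, founder-MAF or founder-HWE thresholds; (4) set residual
    Mendelian-inconsistent trio-marker cells to missing.
    """
    for t in (family_mendel_max, marker_mendel_max, maf_min, hwe_min):
        if not 0.0 <= t <= 1.0:
            raise ValueError("thresholds must lie in [0, 1]")

    fam_rep = mendelian_check(cohort)
    fam_keep = fam_rep.per_family_mendel_rate.to_numpy() <= family_mendel_max
    excluded_families = [
        (str(fid), "mendel")
        for fid, keep in zip(fam_rep.per_family_mendel_rate.index, fam_keep)
        if not keep
    ]
    cohort2 = cohort.subset(trio_mask=fam_keep)
    if cohort2.n_trios == 0:
        raise EmptyCohortError("no families survive the Mendelian-error filter")

    rep2 = mendelian_check(cohort2)
    mk_rate = rep2.per_marker_mendel_rate.to_numpy()

    nb, n_alleles = _founder_allele_counts(cohort2)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_alleles > 0, nb / np.maximum(n_alleles, 1), np.nan)
    maf = np.minimum(freq, 1.0 - freq)

    g = cohort2.genotypes[:, :, (FATHER, MOTHER)]
    hwe = np.ones(cohort2.n_markers)
    for j in range(cohort2.n_markers):
        col = g[:, j, :].ravel()
        col = col[col >= 0]
        if col.size == 0:
            continue
        counts = np.bincount(col, minlength=3)
        hwe[j] = hwe_exact_test(int(counts[0]), int(counts[1]), int(counts[2]))

    excluded_markers: list[tuple[str, str]] = []
    mk_keep = np.ones(cohort2.n_markers, bool)
    for j, m in enumerate(cohort2.markers):
        if mk_rate[j] > marker_mendel_max:
            excluded_markers.append((m.id, "mendel"))
        elif not (maf[j] >= maf_min):  # catches NaN (all-missing) too
            excluded_markers.append((m.id, "maf"))
        elif hwe[j] < hwe_min:
            excluded_markers.append((m.id, "hwe"))
        else:
            continue
        mk_keep[j] = False

    cohort3 = cohort2.subset(marker_mask=mk_keep)
    if cohort3.n_markers == 0:
        raise EmptyCohortError("no markers survive QC")

    # Residual Mendelian-inconsistent cells at retained markers -> missing,
    # so downstream transmission tallies never see impossible configurations.
    residual = rep2.error_mask[:, mk_keep]
    cohort3.genotypes[residual] = MISSING

    marker_ids = [m.id for m in cohort2.markers]
    report = QcReport(
        per_family_mendel_rate=fam_rep.per_family_mendel_rate,
        per_marker_mendel_rate=pd.Series(mk_rate, index=marker_ids),
        maf=pd.Series(maf, index=marker_ids),
        hwe_p=pd.Series(hwe, index=marker_ids),
        excluded_families=excluded_families,
        excluded_markers=excluded_markers,
    )
    return cohort3, report


def write_qc_report(report: QcReport, path) -> None:
    """Write the marker-level QC table as tab-delimited text."""
    report.to_frame().to_csv(path, sep="\t", index_label="marker")
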