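"""Parent-of-origin transmission models for affected-offspring trios.

The child genotype is modelled conditionally on the ordered parental
mating type (father genotype, mother genotype), which absorbs all
population-stratification nuisance parameters:

    P(child | F, M)  proportional to  T(a_p | F) T(a_m | M) r_p^{a_p} r_m^{a_m}

where a_p / a_m are the paternally / maternally transmitted risk-allele
counts, T is the Mendelian gamete probability, and r_p / r_m are the
multiplicative per-allele relative risks of a paternally / maternally
transmitted risk allele. Normalisation is within each (F, M) stratum; in
the triple-heterozygote cell the two unresolvable origin configurations
are summed, giving weight (r_p + r_m)/4.

Three nested models are fitted by maximum likelihood:

* ``null``         r_m = r_p = 1            (no transmission distortion)
* ``association``  r_m = r_p = r            (allelic association, no POE)
* ``poe``          r_m, r_p free            (parent-of-origin effect)

The POE test is the 1-df likelihood-ratio contrast poe vs association;
the association test is association vs null. The POE odds ratio is
reported as r_p / r_m (paternal relative to maternal transmission).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .trio_io import CHILD, FATHER, MENDEL_COMPAT, MOTHER, TrioCohort

MAX_LOG_RR = math.log(20.0)
MODELS = ("null", "association", "poe")

# Enumerate every (father, mother, a_p, a_m) gamete combination once;
# the likelihood is then a 16-term weighted sum aggregated into 27 cells.
_GAMETES = {0: ((0, 1.0),), 1: ((0, 0.5), (1, 0.5)), 2: ((1, 1.0),)}
_terms = []
for _f in range(3):
    for _m in range(3):
        for _ap, _wp in _GAMETES[_f]:
            for _am, _wm in _GAMETES[_m]:
                _terms.append((_f, _m, _ap + _am, _ap, _am, _wp * _wm))
_TF, _TM, _TC, _AP, _AM, _W0 = (np.array(x, dtype=float) for x in zip(*_terms))
_CELL = (_TF * 9 + _TM * 3 + _TC).astype(int)
_STRATUM_OF_CELL = np.repeat(np.arange(9), 3)


@dataclass
class TransmissionTally:
    """Trio genotype counts stratified by ordered parental mating type.

    counts[f, m, c] is the number of trios with father dosage f, mother
    dosage m, child dosage c (risk-allele dosages 0/1/2). The
    double-heterozygote cell (1, 1, 1), where the parental origin of the
    child's risk allele is unresolvable, is ``ambiguous_count``.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (3, 3, 3):
            raise ValueError("counts must be a 3x3x3 array")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_informative(self) -> int:
        """Trios with at least one heterozygous parent."""
        return int(self.counts[1, :, :].sum() + self.counts[:, 1, :].sum()
                   - self.counts[1, 1, :].sum())

    @property
    def ambiguous_count(self) -> int:
        return int(self.counts[1, 1, 1])

    def swapped_parents(self) -> "TransmissionTally":
        return TransmissionTally(self.counts.swapaxes(0, 1).copy())

    def flipped_allele(self) -> "TransmissionTally":
        return TransmissionTally(self.counts[::-1, ::-1, ::-1].copy())


def tally_transmissions(
    cohort: TrioCohort, marker_id: str, risk_allele: str | None = None
) -> TransmissionTally:
    """Count trio genotype configurations at a marker as risk-allele dosages.

    Every trio with all three genotypes non-missing lands in exactly one
    of the 27 cells. ``risk_allele`` defaults to the marker's allele_b.
    """
    marker = cohort.marker(marker_id)
    j = cohort.marker_column(marker_id)
    risk = risk_allele if risk_allele is not None else marker.allele_b
    if risk == marker.allele_b:
        flip = False
    elif risk == marker.allele_a:
        flip = True
    else:
        raise ValueError(
            f"risk allele {risk!r} is not an allele of marker {marker_id}"
        )
    g = cohort.genotypes[:, j, :]
    complete = (g >= 0).all(axis=1)
    g = g[complete]
    if flip:
        g = 2 - g
    idx = g[:, FATHER] * 9 + g[:, MOTHER] * 3 + g[:, CHILD]
    return TransmissionTally(np.bincount(idx, minlength=27).reshape(3, 3, 3))


# ---------------------------------------------------------------------------
# Likelihood


def _nll_grad(counts_flat: np.ndarray, x: np.ndarray) -> tuple[float, np.ndarray]:
    log_rm, log_rp = x
    tw = _W0 * np.exp(_AP * log_rp + _AM * log_rm)
    w = np.bincount(_CELL, weights=tw, minlength=27)
    wp = np.bincount(_CELL, weights=tw * _AP, minlength=27)
    wm = np.bincount(_CELL, weights=tw * _AM, minlength=27)
    s = w.reshape(9, 3).sum(1)
    sp = wp.reshape(9, 3).sum(1)
    sm = wm.reshape(9, 3).sum(1)
    valid = (counts_flat > 0) & (w > 0)
    n = counts_flat[valid]
    str_idx = _STRATUM_OF_CELL[valid]
    ll = float(np.sum(n * (np.log(w[valid]) - np.log(s[str_idx]))))
    gp = float(np.sum(n * (wp[valid] / w[valid] - sp[str_idx] / s[str_idx])))
    gm = float(np.sum(n * (wm[valid] / w[valid] - sm[str_idx] / s[str_idx])))
    return -ll, np.array([-gm, -gp])


def loglik(tally: TransmissionTally, r_m: float, r_p: float) -> float:
    """Stratified conditional log-likelihood at the given relative risks."""
    if r_m <= 0 or r_p <= 0:
        raise ValueError("relative risks must be positive")
    nll, _ = _nll_grad(tally.counts.astype(float).ravel(),
                       np.array([math.log(r_m), math.log(r_p)]))
    return -nll


@dataclass
class ModelFit:
    model: str
    params: dict[str, float]
    loglik: float
    converged: bool
    flags: tuple[str, ...] = ()


def _resolved_counts(counts: np.ndarray) -> tuple[float, float, float, float]:
    """Origin-resolved transmitted/untransmitted totals (Bp, Cp, Bm, Cm).

    Includes single-het matings and the origin-resolvable double-het cells
    with a homozygous child; valid as sufficient statistics only when the
    ambiguous (1,1,1) cell is empty, in which case the likelihood
    factorises into two independent Bernoulli series.
    """
    n = counts
    b_p = n[1, 0, 1] + n[1, 2, 2] + n[1, 1, 2]
    c_p = n[1, 0, 0] + n[1, 2, 1] + n[1, 1, 0]
    b_m = n[0, 1, 1] + n[2, 1, 2] + n[1, 1, 2]
    c_m = n[0, 1, 0] + n[2, 1, 1] + n[1, 1, 0]
    return float(b_p), float(c_p), float(b_m), float(c_m)


def _clip_log_ratio(b: float, c: float) -> tuple[float, bool]:
    """log(b/c) clipped to the optimisation box; boundary flag."""
    if b == 0 and c == 0:
        return 0.0, False
    if c == 0:
        return MAX_LOG_RR, True
    if b == 0:
        return -MAX_LOG_RR, True
    t = math.log(b / c)
    if abs(t) >= MAX_LOG_RR:
        return math.copysign(MAX_LOG_RR, t), True
    return t, False


def fit_transmission_model(tally: TransmissionTally, model: str) -> ModelFit:
    """Maximum-likelihood fit of one of the three nested transmission models.

    Optimisation is in log relative risks, started at (0, 0), boxed to
    |log r| <= log 20; when the ambiguous double-het cell is empty the MLE
    is available in closed form and used directly.
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    counts = tally.counts.astype(float)
    flat = counts.ravel()
    flags: list[str] = []
    if (counts[~MENDEL_COMPAT] > 0).any():
        flags.append("mendel-incompatible-cells-ignored")

    if tally.n_informative == 0:
        params = {} if model == "null" else (
            {"r": 1.0} if model == "association" else {"r_m": 1.0, "r_p": 1.0}
        )
        nll, _ = _nll_grad(flat, np.zeros(2))
        flags.append("uninformative")
        return ModelFit(model, params, -nll, True, tuple(flags))

    if model == "null":
        nll, _ = _nll_grad(flat, np.zeros(2))
        return ModelFit(model, {}, -nll, True, tuple(flags))

    if tally.ambiguous_count == 0:
        b_p, c_p, b_m, c_m = _resolved_counts(tally.counts)
        if model == "association":
            t, boundary = _clip_log_ratio(b_p + b_m, c_p + c_m)
            x = np.array([t, t])
            params = {"r": math.exp(t)}
        else:
            tp, bp_ = _clip_log_ratio(b_p, c_p)
            tm, bm_ = _clip_log_ratio(b_m, c_m)
            boundary = bp_ or bm_
            x = np.array([tm, tp])
            params = {"r_m": math.exp(tm), "r_p": math.exp(tp)}
        if boundary:
            flags.append("boundary")
        nll, _ = _nll_grad(flat, x)
        return ModelFit(model, params, -nll, True, tuple(flags))

    if model == "association":
        res = optimize.minimize_scalar(
            lambda t: _nll_grad(flat, np.array([t, t]))[0],
            bounds=(-MAX_LOG_RR, MAX_LOG_RR),
            method="bounded",
            options={"xatol": 1e-10},
        )
        t = float(res.x)
        if abs(t) > MAX_LOG_RR - 1e-6:
            flags.append("boundary")
        return ModelFit(model, {"r": math.exp(t)}, -float(res.fun),
                        bool(res.success), tuple(flags))

    res = optimize.minimize(
        lambda x: _nll_grad(flat, x),
        x0=np.zeros(2),
        jac=True,
        method="L-BFGS-B",
        bounds=[(-MAX_LOG_RR, MAX_LOG_RR)] * 2,
        options={"ftol": 1e-13, "gtol": 1e-9, "maxiter": 500},
    )
    tm, tp = res.x
    if max(abs(tm), abs(tp)) > MAX_LOG_RR - 1e-6:
        flags.append("boundary")
    if not res.success:
        flags.append("non-convergence")
    return ModelFit(
        "poe",
        {"r_m": math.exp(tm), "r_p": math.exp(tp)},
        -float(res.fun),
        bool(res.success),
        tuple(flags),
    )


@dataclass
class PoeResult:
    """Fitted relative risks and the 1-df likelihood-ratio tests.

    ``poe_or = r_p / r_m`` (paternal relative to maternal transmission);
    ``lrt_stat``/``p_value`` contrast the POE model against the
    equal-effects association model; ``assoc_lrt_stat``/``assoc_p``
    contrast association against the null.
    """

    r_m: float
    r_p: float
    poe_or: float
    lrt_stat: float
    df: int
    p_value: float
    assoc_r: float
    assoc_lrt_stat: float
    assoc_p: float
    converged: bool
    flags: tuple[str, ...] = ()


def poe_test(tally: TransmissionTally) -> PoeResult:
    """Likelihood-ratio test for a parent-of-origin transmission effect."""
    fit0 = fit_transmission_model(tally, "null")
    fita = fit_transmission_model(tally, "association")
    fitp = fit_transmission_model(tally, "poe")
    lrt = max(0.0, 2.0 * (fitp.loglik - fita.loglik))
    assoc_lrt = max(0.0, 2.0 * (fita.loglik - fit0.loglik))
    return PoeResult(
        r_m=fitp.params["r_m"],
        r_p=fitp.params["r_p"],
        poe_or=fitp.params["r_p"] / fitp.params["r_m"],
        lrt_stat=lrt,
        df=1,
        p_value=float(stats.chi2.sf(lrt, 1)) if lrt > 0 else 1.0,
        assoc_r=fita.params["r"],
        assoc_lrt_stat=assoc_lrt,
        assoc_p=float(stats.chi2.sf(assoc_lrt, 1)) if assoc_lrt > 0 else 1.0,
        converged=fit0.converged and fita.converged and fitp.converged,
        flags=tuple(sorted(set(fit0.flags + fita.flags + fitp.flags))),
    )


@dataclass
class TdtResult:
    b: float
    c: float
    statistic: float
    p_value: float


def tdt(tally: TransmissionTally) -> TdtResult:
    """Transmission disequilibrium test on the tally.

    b / c are transmissions / non-transmissions of the risk allele from
    heterozygous parents. Double-het matings contribute per parent where
    resolvable; with a heterozygous child they contribute one transmission
    and one non-transmission to the aggregate.
    """
    n = tally.counts
    b = (n[1, 0, 1] + n[1, 2, 2]) + (n[0, 1, 1] + n[2, 1, 2]) \
        + 2 * n[1, 1, 2] + n[1, 1, 1]
    c = (n[1, 0, 0] + n[1, 2, 1]) + (n[0, 1, 0] + n[2, 1, 1]) \
        + 2 * n[1, 1, 0] + n[1, 1, 1]
    b, c = float(b), float(c)
    if b + c == 0:
        return TdtResult(b, c, 0.0, 1.0)
    stat = (b - c) ** 2 / (b + c)
    return TdtResult(b, c, stat, float(stats.chi2.sf(stat, 1)))


def parental_transmission_counts(
    tally: TransmissionTally,
) -> tuple[int, int, int, int]:
    """(b_m, c_m, b_p, c_p) from single-heterozygous-parent matings only.

    Double-het matings are excluded entirely; the counts serve as
    diagnostics and as inputs to closed-form cross-checks of the fit.
    """
    n = tally.counts
    b_m = int(n[0, 1, 1] + n[2, 1, 2])
    c_m = int(n[0, 1, 0] + n[2, 1, 1])
    b_p = int(n[1, 0, 1] + n[1, 2, 2])
    c_p = int(n[1, 0, 0] + n[1, 2, 1])
    return b_m, c_m, b_p, c_p
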