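"""Transmission tallies, the stratified likelihood, and the POE/TDT tests."""

import numpy as np
import pytest

from poetrio import poe_model as pm
from poetrio.synthetic_data import TrioSimConfig, simulate_trio_cohort

from conftest import random_tally


def grid_search_loglik(tally, n_grid=41, n_zoom=3):
    """Brute-force zooming grid search over (log r_m, log r_p)."""
    lo = np.array([-pm.MAX_LOG_RR, -pm.MAX_LOG_RR])
    hi = np.array([pm.MAX_LOG_RR, pm.MAX_LOG_RR])
    best = None
    for _ in range(n_zoom + 1):
        gm = np.linspace(lo[0], hi[0], n_grid)
        gp = np.linspace(lo[1], hi[1], n_grid)
        vals = np.array(
            [[pm.loglik(tally, np.exp(a), np.exp(b)) for b in gp] for a in gm]
        )
        i, j = np.unravel_index(np.argmax(vals), vals.shape)
        best = vals[i, j], gm[i], gp[j]
        span_m = (hi[0] - lo[0]) / (n_grid - 1)
        span_p = (hi[1] - lo[1]) / (n_grid - 1)
        lo = np.array([max(-pm.MAX_LOG_RR, gm[i] - span_m), max(-pm.MAX_LOG_RR, gp[j] - span_p)])
        hi = np.array([min(pm.MAX_LOG_RR, gm[i] + span_m), min(pm.MAX_LOG_RR, gp[j] + span_p)])
    return best[0]


def make_tally(**cells):
    """Tally from cells named like f1m0c1."""
    counts = np.zeros((3, 3, 3), int)
    for key, v in cells.items():
        f, m, c = int(key[1]), int(key[3]), int(key[5])
        counts[f, m, c] = v
    return pm.TransmissionTally(counts)


class TestTally:
    def test_basic_cells_and_ambiguity(self):
        cohort, _ = simulate_trio_cohort(TrioSimConfig(seed=1, n_trios=2, mafs=0.3))
        cohort.genotypes[0, 0, :] = [1, 0, 1]
        cohort.genotypes[1, 0, :] = [1, 1, 1]
        t = pm.tally_transmissions(cohort, "snp1")
        assert t.counts[1, 0, 1] == 1 and t.counts[1, 1, 1] == 1
        assert t.n_informative == 2 and t.ambiguous_count == 1

    def test_risk_allele_flip_reverses_dosage(self):
        cohort, _ = simulate_trio_cohort(TrioSimConfig(seed=2, n_trios=50, mafs=0.3))
        t_b = pm.tally_transmissions(cohort, "snp1", risk_allele="B")
        t_a = pm.tally_transmissions(cohort, "snp1", risk_allele="A")
        assert (t_a.counts == t_b.counts[::-1, ::-1, ::-1]).all()
        with pytest.raises(ValueError):
            pm.tally_transmissions(cohort, "snp1", risk_allele="T")

    def test_totals_conserved_against_ledger(self):
        cohort, _ = simulate_trio_cohort(
            TrioSimConfig(seed=3, n_trios=300, mafs=0.25, missing_rate=0.05)
        )
        t = pm.tally_transmissions(cohort, "snp1")
        complete = (cohort.genotypes[:, 0, :] >= 0).all(axis=1)
        assert t.n_total == complete.sum()


class TestFit:
    def test_no_information_all_models_agree(self):
        t = make_tally(f0m0c0=10, f2m2c2=5, f0m2c1=3)
        lls = [pm.fit_transmission_model(t, m).loglik for m in pm.MODELS]
        assert max(lls) - min(lls) < 1e-12
        fit = pm.fit_transmission_model(t, "poe")
        assert fit.params == {"r_m": 1.0, "r_p": 1.0}
        assert "uninformative" in fit.flags

    def test_closed_form_single_het_parent_ratios(self):
        # maternal transmitted:untransmitted 15:15, paternal 30:10
        t = make_tally(f0m1c1=15, f0m1c0=15, f1m0c1=30, f1m0c0=10)
        assert pm.fit_transmission_model(t, "association").params["r"] == pytest.approx(1.8)
        fit = pm.fit_transmission_model(t, "poe")
        assert fit.params["r_m"] == pytest.approx(1.0)
        assert fit.params["r_p"] == pytest.approx(3.0)
        # grid oracle confirms the maximum
        assert fit.loglik == pytest.approx(grid_search_loglik(t), abs=1e-4)

    def test_fit_matches_grid_oracle_on_random_tallies(self, rng):
        for _ in range(15):
            t = random_tally(rng, n_trios=50)
            ll = pm.fit_transmission_model(t, "poe").loglik
            assert ll == pytest.approx(grid_search_loglik(t), abs=1e-4)

    def test_association_at_unit_risk_reproduces_null(self, rng):
        for _ in range(10):
            t = random_tally(rng, n_trios=40)
            ll_null = pm.fit_transmission_model(t, "null").loglik
            assert pm.loglik(t, 1.0, 1.0) == pytest.approx(ll_null, abs=1e-12)

    def test_label_symmetry(self, rng):
        """Swapping parents swaps the fitted maternal/paternal risks."""
        for _ in range(10):
            t = random_tally(rng, n_trios=40)
            a = pm.fit_transmission_model(t, "poe")
            b = pm.fit_transmission_model(t.swapped_parents(), "poe")
            assert a.params["r_m"] == pytest.approx(b.params["r_p"], rel=1e-4, abs=1e-6)
            assert a.params["r_p"] == pytest.approx(b.params["r_m"], rel=1e-4, abs=1e-6)


class TestPoeTest:
    def test_symmetric_tally_gives_null_result(self):
        t = make_tally(f0m1c1=12, f0m1c0=8, f1m0c1=12, f1m0c0=8)
        res = pm.poe_test(t)
        assert res.lrt_stat == pytest.approx(0.0, abs=1e-8)
        assert res.p_value == pytest.approx(1.0, abs=1e-6)
        assert res.poe_or == pytest.approx(1.0, rel=1e-6)

    def test_asymmetric_example_matches_grid_oracle(self):
        from scipy.stats import chi2

        t = make_tally(f0m1c1=15, f0m1c0=15, f1m0c1=30, f1m0c0=10)
        res = pm.poe_test(t)
        assert res.poe_or == pytest.approx(3.0, rel=1e-6)
        ll_poe = grid_search_loglik(t)
        ll_assoc = pm.fit_transmission_model(t, "association").loglik
        assert res.p_value == pytest.approx(
            float(chi2.sf(2 * (ll_poe - ll_assoc), 1)), rel=1e-3
        )

    def test_allele_flip_invariance(self, rng):
        """The LRT statistic is invariant to which allele is called risk."""
        for _ in range(10):
            t = random_tally(rng, n_trios=40)
            a, b = pm.poe_test(t), pm.poe_test(t.flipped_allele())
            assert a.lrt_stat == pytest.approx(b.lrt_stat, abs=1e-6)
            assert a.assoc_lrt_stat == pytest.approx(b.assoc_lrt_stat, abs=1e-6)

    def test_ambiguity_free_or_equals_count_ratio(self, rng):
        """Without double-het matings, the fitted POE OR is the exact
        cross-ratio of per-parent transmitted:untransmitted counts."""
        for _ in range(20):
            t = random_tally(rng, n_trios=60, allow_ambiguous=False)
            t.counts[1, 1, :] = 0
            b_m, c_m, b_p, c_p = pm.parental_transmission_counts(t)
            if min(b_m, c_m, b_p, c_p) == 0:
                continue
            res = pm.poe_test(t)
            assert res.poe_or == pytest.approx((b_p / c_p) / (b_m / c_m), rel=1e-9)

    def test_parameter_recovery_median(self):
        cohort, _ = simulate_trio_cohort(
            TrioSimConfig(seed=5, n_trios=695, mafs=0.2, r_m=1.0, r_p=3.16, n_markers=100)
        )
        ors = [
            pm.poe_test(pm.tally_transmissions(cohort, mk.id)).poe_or
            for mk in cohort.markers
        ]
        assert abs(np.median(ors) - 3.16) / 3.16 < 0.15


class TestTdt:
    def test_balanced_and_closed_form(self):
        t = make_tally(f1m0c1=10, f1m0c0=10)
        res = pm.tdt(t)
        assert res.statistic == 0.0 and res.p_value == 1.0
        t = make_tally(f1m0c1=30, f1m0c0=10)
        assert pm.tdt(t).statistic == pytest.approx(10.0)

    def test_double_het_accounting(self):
        # het x het with het child: one transmitted, one untransmitted
        t = make_tally(f1m1c1=7)
        res = pm.tdt(t)
        assert (res.b, res.c) == (7.0, 7.0)
        # homozygous children resolve both parents
        t = make_tally(f1m1c2=4, f1m1c0=3)
        res = pm.tdt(t)
        assert (res.b, res.c) == (8.0, 6.0)

    def test_empty_tally(self):
        t = make_tally(f0m0c0=5)
        res = pm.tdt(t)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_null_calibration(self):
        cohort, _ = simulate_trio_cohort(
            TrioSimConfig(seed=6, n_trios=300, mafs=0.3, n_markers=2000)
        )
        rej = np.mean(
            [
                pm.tdt(pm.tally_transmissions(cohort, mk.id)).p_value <= 0.05
                for mk in cohort.markers
            ]
        )
        assert 0.03 <= rej <= 0.07


class TestParentalCounts:
    def test_directional_cells(self):
        assert pm.parental_transmission_counts(make_tally(f0m1c1=4)) == (4, 0, 0, 0)
        assert pm.parental_transmission_counts(make_tally(f1m0c0=7)) == (0, 0, 0, 7)

    def test_ledger_agreement(self):
        cohort, ledger = simulate_trio_cohort(
            TrioSimConfig(seed=7, n_trios=500, mafs=0.3, r_p=2.0)
        )
        t = pm.tally_transmissions(cohort, "snp1")
        b_m, c_m, b_p, c_p = pm.parental_transmission_counts(t)
        f = cohort.genotypes[:, 0, 0]
        m = cohort.genotypes[:, 0, 1]
        sel_p = (f == 1) & (m != 1)
        sel_m = (m == 1) & (f != 1)
        assert b_p == ledger.a_p[sel_p, 0].sum()
        assert c_p == (sel_p.sum() - ledger.a_p[sel_p, 0].sum())
        assert b_m == ledger.a_m[sel_m, 0].sum()
        assert c_m == (sel_m.sum() - ledger.a_m[sel_m, 0].sum())
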