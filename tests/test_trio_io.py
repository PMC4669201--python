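"""Trio reading, Mendelian checking, founder statistics, and the QC cascade."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poetrio.synthetic_data import TrioSimConfig, simulate_trio_cohort, write_ped_map
from poetrio.trio_io import (
    MENDEL_COMPAT,
    MISSING,
    EmptyCohortError,
    TrioFormatError,
    UndefinedValueError,
    apply_qc,
    founder_maf,
    hwe_exact_test,
    mendelian_check,
    read_trios,
)

from conftest import write_ped_map_text

MAP2 = "1 snp1 0 1000\n1 snp2 0 2000\n"
TRIO_PED = (
    "f1 dad 0 0 1 1 A A G G\n"
    "f1 mum 0 0 2 1 A C G T\n"
    "f1 kid dad mum 0 2 A C G T\n"
)


class TestReadTrios:
    def test_minimal_complete_trio(self, tmp_path):
        ped, mp = write_ped_map_text(tmp_path, TRIO_PED, MAP2)
        cohort = read_trios(ped, mp)
        assert cohort.n_trios == 1 and cohort.n_markers == 2
        # dosages of the lexicographically larger allele
        m1 = cohort.marker("snp1")
        assert (m1.allele_a, m1.allele_b) == ("A", "C")
        assert cohort.genotypes[0, 0].tolist() == [0, 1, 1]

    def test_family_with_absent_father_dropped(self, tmp_path):
        extra = "f2 mum2 0 0 2 1 A A G G\nf2 kid2 dad2 mum2 0 2 A A G G\n"
        ped, mp = write_ped_map_text(tmp_path, TRIO_PED + extra, MAP2)
        cohort = read_trios(ped, mp)
        assert cohort.n_trios == 1
        assert cohort.trios["fid"].tolist() == ["f1"]

    def test_non_autosomal_marker_excluded(self, tmp_path):
        ped, mp = write_ped_map_text(
            tmp_path,
            "f1 dad 0 0 1 1 A A G G\nf1 mum 0 0 2 1 A A G G\nf1 kid dad mum 0 2 A A G G\n",
            "1 snp1 0 1000\nX snpx 0 2000\n",
        )
        cohort = read_trios(ped, mp)
        assert [m.id for m in cohort.markers] == ["snp1"]

    def test_duplicate_individual_rejected(self, tmp_path):
        ped, mp = write_ped_map_text(tmp_path, TRIO_PED + TRIO_PED.splitlines()[0] + "\n", MAP2)
        with pytest.raises(TrioFormatError, match="duplicate"):
            read_trios(ped, mp)

    def test_malformed_line_names_location(self, tmp_path):
        ped, mp = write_ped_map_text(tmp_path, "f1 dad 0 0 1 1 A A G\n", MAP2)
        with pytest.raises(TrioFormatError, match="line 1"):
            read_trios(ped, mp)

    def test_ped_map_round_trip(self, tmp_path):
        cohort, _ = simulate_trio_cohort(
            TrioSimConfig(seed=1, n_trios=20, mafs=[0.3, 0.4, 0.2], missing_rate=0.05)
        )
        write_ped_map(cohort, tmp_path / "c.ped", tmp_path / "c.map")
        back = read_trios(tmp_path / "c.ped", tmp_path / "c.map")
        assert back.n_trios == cohort.n_trios and back.n_markers == cohort.n_markers
        for j, (ma, mb) in enumerate(zip(cohort.markers, back.markers)):
            assert ma.id == mb.id and ma.pos == mb.pos
            a = cohort.genotypes[:, j, :]
            b = back.genotypes[:, j, :]
            if mb.allele_b != ma.allele_b:  # dosage orientation may flip
                b = np.where(b >= 0, 2 - b, b)
            assert (a == b).all()


class TestMendelianCheck:
    def test_truth_table_matches_brute_force(self):
        """Error detection equals exhaustive gamete enumeration on all 27 cells."""
        for f in range(3):
            for m in range(3):
                possible = {
                    ap + am
                    for ap in ((0,), (0, 1), (1,))[f]
                    for am in ((0,), (0, 1), (1,))[m]
                }
                for c in range(3):
                    assert MENDEL_COMPAT[f, m, c] == (c in possible)

    def test_impossible_and_compatible_examples(self):
        # father AA, mother AA, child AB -> error; AB x AB -> anything goes
        g = np.array([[[0, 0, 1]], [[1, 1, 0]], [[1, 1, 1]], [[1, 1, 2]]], dtype=np.int8)
        from poetrio.trio_io import TrioCohort, Marker
        import pandas as pd

        cohort = TrioCohort(
            trios=pd.DataFrame(
                {"fid": list("abcd"), "father": list("aaaa"),
                 "mother": list("bbbb"), "child": list("cccc")}
            ),
            markers=[Marker("s", 1, 1, "A", "B")],
            genotypes=g,
        )
        rep = mendelian_check(cohort)
        assert rep.per_family_mendel_rate.tolist() == [1.0, 0.0, 0.0, 0.0]

    def test_injected_rates_recovered_exactly(self):
        cohort, ledger = simulate_trio_cohort(
            TrioSimConfig(seed=3, n_trios=10, mafs=[0.3] * 100, mendel_error_rate=0.05)
        )
        rep = mendelian_check(cohort)
        err, complete = rep.error_mask, (cohort.genotypes >= 0).all(axis=2)
        assert err.sum() == len(ledger.error_cells)
        injected = set(map(tuple, ledger.error_cells[["trio", "marker"]].to_numpy()))
        assert set(map(tuple, np.argwhere(err))) == injected

    def test_missing_cells_excluded_from_both_sides(self):
        cohort, _ = simulate_trio_cohort(TrioSimConfig(seed=4, n_trios=50, mafs=0.3))
        cohort.genotypes[0, 0, 2] = MISSING
        rep = mendelian_check(cohort)
        assert rep.per_family_mendel_rate.iloc[0] == 0.0


class TestFounderMaf:
    def test_monomorphic_and_balanced(self):
        cohort, _ = simulate_trio_cohort(TrioSimConfig(seed=5, n_trios=2, mafs=0.3))
        cohort.genotypes[:, 0, :2] = 0
        assert founder_maf(cohort, "snp1") == 0.0
        cohort.genotypes[0, 0, 0] = 0
        cohort.genotypes[0, 0, 1] = 1
        cohort.genotypes[1, 0, 0] = 1
        cohort.genotypes[1, 0, 1] = 2
        assert founder_maf(cohort, "snp1") == pytest.approx(0.5)

    def test_all_missing_is_undefined(self):
        cohort, _ = simulate_trio_cohort(TrioSimConfig(seed=6, n_trios=3, mafs=0.3))
        cohort.genotypes[:, 0, :2] = MISSING
        with pytest.raises(UndefinedValueError):
            founder_maf(cohort, "snp1")

    def test_estimates_generating_frequency(self):
        cohort, _ = simulate_trio_cohort(TrioSimConfig(seed=7, n_trios=1000, mafs=0.3))
        se = math.sqrt(0.3 * 0.7 / 4000)
        assert abs(founder_maf(cohort, "snp1") - 0.3) < 3 * se


def hwe_enumeration_oracle(n_aa, n_ab, n_bb):
    """Exact-rational enumeration of the conditional heterozygote distribution."""
    n = n_aa + n_ab + n_bb
    nb = 2 * n_bb + n_ab
    rare = min(nb, 2 * n - nb)
    weights = {}
    for h in range(rare % 2, rare + 1, 2):
        n_rr = (rare - h) // 2
        n_cc = n - n_rr - h
        weights[h] = Fraction(2 ** h * math.comb(n, n_rr) * math.comb(n - n_rr, h), 1)
    total = sum(weights.values())
    obs = weights[n_ab]
    return float(sum(w for w in weights.values() if w <= obs) / total)


class TestHweExact:
    @pytest.mark.parametrize(
        "counts,expected",
        [((100, 0, 0), 1.0), ((25, 50, 25), 1.0)],
    )
    def test_reference_configurations(self, counts, expected):
        assert hwe_exact_test(*counts) == pytest.approx(expected, abs=1e-9)

    def test_total_heterozygosity_fails_strict_filter(self):
        assert hwe_exact_test(0, 100, 0) < 1e-6

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        n_aa=st.integers(0, 70), n_ab=st.integers(0, 70), n_bb=st.integers(0, 70)
    )
    def test_agrees_with_exact_enumeration(self, n_aa, n_ab, n_bb):
        if n_aa + n_ab + n_bb == 0:
            return
        assert hwe_exact_test(n_aa, n_ab, n_bb) == pytest.approx(
            hwe_enumeration_oracle(n_aa, n_ab, n_bb), abs=1e-12
        )


class TestApplyQc:
    def test_clean_cohort_untouched(self):
        cohort, _ = simulate_trio_cohort(
            TrioSimConfig(seed=8, n_trios=200, mafs=[0.2, 0.3, 0.4])
        )
        out, rep = apply_qc(cohort)
        assert out.n_trios == 200 and out.n_markers == 3
        assert not rep.excluded_families and not rep.excluded_markers
        assert (rep.per_marker_mendel_rate == 0).all()

    def test_bad_family_removed(self):
        cohort, _ = simulate_trio_cohort(TrioSimConfig(seed=9, n_trios=30, mafs=[0.3] * 100))
        # corrupt 5% of the first family's cells with an impossible child
        cohort.genotypes[0, :5, :] = np.array([0, 0, 2], dtype=np.int8)
        out, rep = apply_qc(cohort)
        assert ("fam1", "mendel") in rep.excluded_families
        assert out.n_trios == 29

    def test_low_maf_marker_removed_with_reason(self):
        cohort, _ = simulate_trio_cohort(TrioSimConfig(seed=10, n_trios=300, mafs=[0.3, 0.3]))
        cohort.genotypes[:, 1, :] = 0
        cohort.genotypes[0, 1, :] = np.array([1, 0, 0])  # founder MAF 1/1200
        out, rep = apply_qc(cohort)
        assert ("snp2", "maf") in rep.excluded_markers
        assert [m.id for m in out.markers] == ["snp1"]

    def test_hwe_failure_removed(self):
        cohort, _ = simulate_trio_cohort(TrioSimConfig(seed=11, n_trios=300, mafs=[0.3, 0.3]))
        cohort.genotypes[:, 1, :] = 1  # every founder heterozygous
        out, rep = apply_qc(cohort)
        assert ("snp2", "hwe") in rep.excluded_markers

    def test_residual_errors_masked_and_idempotent(self):
        cohort, _ = simulate_trio_cohort(
            TrioSimConfig(seed=12, n_trios=400, mafs=[0.3] * 20, mendel_error_rate=0.002)
        )
        out1, _ = apply_qc(cohort)
        assert mendelian_check(out1).error_mask.sum() == 0
        out2, rep2 = apply_qc(out1)
        assert (out1.genotypes == out2.genotypes).all()
        assert not rep2.excluded_families and not rep2.excluded_markers

    def test_empty_result_is_signalled(self):
        cohort, _ = simulate_trio_cohort(TrioSimConfig(seed=13, n_trios=50, mafs=0.3))
        cohort.genotypes[:, 0, :] = 0  # monomorphic -> MAF filter removes all markers
        with pytest.raises(EmptyCohortError):
            apply_qc(cohort)
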