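"""2x2 odds-ratio statistics and feature tabulation."""

import numpy as np
import pytest
from statsmodels.stats.contingency_tables import Table2x2

from dlakit.association_stats import (
    Counts2x2,
    UndefinedTableError,
    associate,
    association_report,
    odds_ratio,
    tabulate_alleles,
    tabulate_haplotypes,
    tabulate_homozygosity,
    wald_p,
    woolf_ci,
)
from dlakit.haplotype_inference import infer_haplotypes

from conftest import make_call
from test_haplotype_inference import dog_calls


class TestOddsRatio:
    def test_plain_cross_product(self):
        orv, corrected = odds_ratio(Counts2x2(14, 54, 8, 124))
        assert orv == pytest.approx(4.0185, abs=1e-4)
        assert not corrected

    def test_zero_cell_gets_continuity_correction(self):
        orv, corrected = odds_ratio(Counts2x2(1, 67, 0, 132))
        assert orv == pytest.approx(5.8889, abs=1e-4)
        assert corrected

    def test_symmetric_table_is_unity(self):
        orv, _ = odds_ratio(Counts2x2(5, 5, 5, 5))
        assert orv == 1.0
        assert wald_p(Counts2x2(5, 5, 5, 5)) == 1.0

    def test_zero_margin_is_undefined(self):
        with pytest.raises(UndefinedTableError):
            odds_ratio(Counts2x2(0, 0, 5, 5))

    def test_correction_applied_only_with_a_zero_cell(self):
        assert not odds_ratio(Counts2x2(1, 1, 1, 1))[1]
        assert odds_ratio(Counts2x2(0, 2, 1, 1))[1]

    def test_monotone_in_carrier_count(self):
        values = [odds_ratio(Counts2x2(a, 60, 10, 60))[0] for a in (5, 10, 20)]
        assert values == sorted(values)
        assert values[0] < values[-1]


class TestAgainstIndependentOracle:
    """Cross-check OR, CI and P against statsmodels' log-OR machinery."""

    @pytest.mark.parametrize(
        "cells",
        [(14, 54, 8, 124), (8, 60, 38, 94), (10, 24, 8, 58), (3, 7, 11, 2),
         (21, 47, 25, 107), (1, 67, 1, 131)],
    )
    def test_nonzero_tables(self, cells):
        t = Counts2x2(*cells)
        oracle = Table2x2(np.array(cells).reshape(2, 2), shift_zeros=False)
        assert odds_ratio(t)[0] == pytest.approx(oracle.oddsratio, rel=1e-12)
        lo, hi = woolf_ci(t)
        olo, ohi = oracle.oddsratio_confint()
        # statsmodels uses the full-precision quantile where the reporting
        # convention here is 1.96; bounds agree to that quantile difference.
        assert (lo, hi) == pytest.approx((olo, ohi), rel=2e-4)
        assert wald_p(t) == pytest.approx(oracle.log_oddsratio_pvalue(), rel=1e-9)

    @pytest.mark.parametrize("cells", [(1, 67, 0, 132), (0, 68, 1, 131), (3, 65, 0, 132)])
    def test_zero_cell_tables_match_oracle_on_corrected_cells(self, cells):
        t = Counts2x2(*cells)
        shifted = np.array(cells, dtype=float).reshape(2, 2) + 0.5
        oracle = Table2x2(shifted, shift_zeros=False)
        assert odds_ratio(t)[0] == pytest.approx(oracle.oddsratio, rel=1e-12)
        assert woolf_ci(t) == pytest.approx(oracle.oddsratio_confint(), rel=2e-4)


class TestSymmetries:
    @pytest.mark.parametrize("cells", [(14, 54, 8, 124), (1, 9, 5, 5), (2, 2, 3, 7)])
    def test_cohort_swap_inverts_or_and_keeps_p(self, cells):
        a, b, c, d = cells
        t, swapped = Counts2x2(a, b, c, d), Counts2x2(c, d, a, b)
        assert odds_ratio(swapped)[0] == pytest.approx(1 / odds_ratio(t)[0])
        assert wald_p(swapped) == pytest.approx(wald_p(t))
        lo, hi = woolf_ci(t)
        slo, shi = woolf_ci(swapped)
        assert (slo, shi) == pytest.approx((1 / hi, 1 / lo))

    @pytest.mark.parametrize("cells", [(14, 54, 8, 124), (1, 9, 5, 5)])
    def test_feature_complement_inverts_or(self, cells):
        a, b, c, d = cells
        assert odds_ratio(Counts2x2(b, a, d, c))[0] == pytest.approx(
            1 / odds_ratio(Counts2x2(a, b, c, d))[0]
        )


class TestTabulation:
    def test_single_homozygous_dog_contributes_two_copies(self):
        calls = [make_call("d1", "DRB1", "X", "X")]
        features = tabulate_alleles(calls + [make_call("d2", "DRB1", "Y", "Z")],
                                    {"d1": "affected", "d2": "control"})
        by_label = dict(features)
        assert by_label["DRB1*X"].cells == (2, 0, 0, 2)
        assert by_label["DRB1*Y"].cells == (0, 2, 1, 1)

    def test_uncalled_dogs_leave_locus_denominator(self):
        from dlakit.allele_typing import GenotypeCall

        calls = [
            make_call("d1", "DRB1", "X", "X"),
            GenotypeCall("d2", "DRB1", "ambiguous"),
            make_call("d3", "DRB1", "X", "Y"),
        ]
        statuses = {"d1": "affected", "d2": "affected", "d3": "control"}
        by_label = dict(tabulate_alleles(calls, statuses))
        assert by_label["DRB1*X"].cells == (2, 0, 1, 1)

    def test_homozygosity_unit_is_dogs(self):
        flat = list(dog_calls("d1", ("a", "a"), ("b", "b"), ("c", "c")).values())
        flat += list(dog_calls("d2", ("a", "x"), ("b", "b"), ("c", "c")).values())
        label, t = tabulate_homozygosity(
            flat, {"d1": "affected", "d2": "control"}
        )
        assert label == "homozygous_all_loci"
        assert t.cells == (1, 0, 0, 1)

    def test_haplotype_copies_and_unidentified_denominators(self):
        cohort = {
            "dog1": dog_calls("dog1", ("a1", "a1"), ("b1", "b1"), ("c1", "c1")),
            "dog2": dog_calls("dog2", ("a1", "a2"), ("b1", "b2"), ("c1", "c2")),
            "dog3": dog_calls("dog3", ("a3", "a4"), ("b3", "b4"), ("c3", "c4")),
        }
        statuses = {"dog1": "affected", "dog2": "control", "dog3": "control"}
        features = tabulate_haplotypes(infer_haplotypes(cohort), statuses)
        by_label = dict(features)
        assert "Unidentified" not in by_label
        # dog3 unidentified copies stay in the control denominator (4 copies).
        assert by_label["a1/b1/c1"].cells == (2, 0, 1, 3)

    def test_unknown_status_label_rejected(self):
        with pytest.raises(ValueError, match="status"):
            tabulate_alleles(
                [make_call("d1", "DRB1", "X", "X")], {"d1": "case"}
            )


class TestReport:
    def test_rows_sorted_by_total_count_then_label(self):
        features = [
            ("rare", Counts2x2(1, 9, 0, 10)),
            ("common", Counts2x2(6, 4, 5, 5)),
            ("also_common", Counts2x2(5, 5, 6, 4)),
        ]
        report = association_report(features)
        assert list(report["feature"]) == ["also_common", "common", "rare"]

    def test_label_swap_inverts_every_or(self):
        features = [("f", Counts2x2(6, 4, 3, 7)), ("g", Counts2x2(2, 8, 5, 5))]
        swapped = [(lab, Counts2x2(t.c, t.d, t.a, t.b)) for lab, t in features]
        fwd = association_report(features).set_index("feature")
        rev = association_report(swapped).set_index("feature")
        for lab in ("f", "g"):
            assert rev.loc[lab, "or_value"] == pytest.approx(
                1 / fwd.loc[lab, "or_value"]
            )
            assert rev.loc[lab, "p_value"] == pytest.approx(fwd.loc[lab, "p_value"])

    def test_result_invariants(self):
        res = associate("f", Counts2x2(14, 54, 8, 124))
        assert res.ci_low <= res.or_value <= res.ci_high
        assert 0 < res.p_value <= 1
        assert res.freq_affected == pytest.approx(14 / 68)
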