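"""Panel selection: heterozygosity degree, HWE testing, and the filter chain."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from niph.core import CohortGenotypes, SNVSite
from niph.panel import (
    PanelStatus,
    heterozygosity_degree,
    hwe_test,
    maf_filter,
    select_panel,
    status_counts,
)
from conftest import make_site


def chi2_pvalue_oracle(n0, n1, n2):
    """HWE chi-square p-value via math.erfc only (1 df), independent of scipy."""
    n = n0 + n1 + n2
    p = (2 * n0 + n1) / (2 * n)
    exp = [n * p * p, 2 * n * p * (1 - p), n * (1 - p) ** 2]
    stat = sum((o - e) ** 2 / e for o, e in zip((n0, n1, n2), exp))
    return math.erfc(math.sqrt(stat / 2))


class TestHeterozygosityDegree:
    def test_half_het(self):
        calls = np.array([1] * 48 + [0] * 24 + [2] * 24)
        assert heterozygosity_degree(calls) == 50.0

    def test_no_het(self):
        assert heterozygosity_degree(np.zeros(96, dtype=int)) == 0.0

    def test_missing_excluded_from_denominator(self):
        calls = np.array([1, 1, 0, -1, -1])
        assert heterozygosity_degree(calls) == pytest.approx(100 * 2 / 3)

    def test_all_missing_errors(self):
        with pytest.raises(ValueError):
            heterozygosity_degree(np.full(5, -1))

    def test_binomial_sampling_at_hwe(self):
        # 96 diploids at allele frequency 0.5: het count ~ Binomial(96, 0.5)
        rng = np.random.default_rng(42)
        g = rng.choice(3, size=96, p=[0.25, 0.5, 0.25])
        degree = heterozygosity_degree(g)
        sd = 100 * math.sqrt(0.5 * 0.5 / 96)
        assert abs(degree - 50.0) < 3 * sd


class TestHWETest:
    def test_exact_proportions_give_p_one(self):
        assert hwe_test(25, 50, 25) == pytest.approx(1.0)

    def test_total_het_deficit_is_rejected(self):
        # no heterozygotes at frequency 1/2: chi-square statistic equals n
        assert hwe_test(50, 0, 50) < 1e-6

    @pytest.mark.parametrize(
        "counts", [(30, 40, 26), (5, 20, 5), (90, 5, 1), (1, 1, 1), (10, 0, 1)]
    )
    def test_matches_independent_chi2_oracle(self, counts):
        assert hwe_test(*counts) == pytest.approx(chi2_pvalue_oracle(*counts), abs=1e-9)

    @given(
        st.tuples(
            st.integers(0, 60), st.integers(0, 60), st.integers(0, 60)
        ).filter(lambda c: sum(c) > 0)
    )
    def test_symmetric_under_allele_swap(self, counts):
        n0, n1, n2 = counts
        for method in ("chi2", "exact"):
            assert hwe_test(n0, n1, n2, method) == pytest.approx(
                hwe_test(n2, n1, n0, method), abs=1e-12
            )

    def test_monomorphic_site_p_one(self):
        assert hwe_test(96, 0, 0) == 1.0
        assert hwe_test(0, 0, 96, method="exact") == 1.0

    def test_exact_test_is_valid_probability_and_tracks_chi2(self):
        p_exact = hwe_test(30, 40, 26, method="exact")
        assert 0 < p_exact <= 1
        # both tests must agree on a gross violation
        assert hwe_test(50, 0, 50, method="exact") < 1e-6

    def test_negative_counts_error(self):
        with pytest.raises(ValueError):
            hwe_test(-1, 2, 3)


def cohort_from_count_rows(rows):
    """Build a cohort whose site i has genotype counts rows[i]=(n0, n1, n2)."""
    sites = [make_site(pos=100 + i) for i in range(len(rows))]
    calls = np.array(
        [[0] * n0 + [1] * n1 + [2] * n2 for n0, n1, n2 in rows], dtype=np.int8
    )
    inds = [f"I{j}" for j in range(calls.shape[1])]
    return CohortGenotypes(sites=sites, individuals=inds, calls=calls)


class TestSelectPanel:
    def test_status_assignment_per_rule(self):
        cohort = cohort_from_count_rows(
            [
                (96, 0, 0),     # common: 100% hom ref
                (93, 3, 0),     # common: 96.9% hom ref
                (2, 92, 2),     # high het: 95.8%
                (24, 48, 24),   # in window, HWE-conforming -> selected
                (38, 20, 38),   # in window, het deficit -> HWE excluded
                (0, 5, 91),     # low het, mostly hom alt -> excluded_low_het
            ]
        )
        statuses = [v.status for v in select_panel(cohort)]
        assert statuses == [
            PanelStatus.COMMON,
            PanelStatus.COMMON,
            PanelStatus.EXCLUDED_HIGH_HET,
            PanelStatus.SELECTED,
            PanelStatus.EXCLUDED_HWE,
            PanelStatus.EXCLUDED_LOW_HET,
        ]

    def test_het_window_boundaries_inclusive(self):
        # degree exactly 10% and exactly 90% both stay inside the window
        n = 100
        lo = (81, 10, 9)
        hi = (5, 90, 5)
        cohort = cohort_from_count_rows([lo, hi])
        out = select_panel(cohort)
        assert out[0].status in (PanelStatus.SELECTED, PanelStatus.EXCLUDED_HWE)
        assert out[1].status in (PanelStatus.SELECTED, PanelStatus.EXCLUDED_HWE)

    def test_common_requires_strictly_above_frac(self):
        # 95% hom-ref exactly is NOT common
        cohort = cohort_from_count_rows([(95, 5, 0)])
        assert select_panel(cohort)[0].status is not PanelStatus.COMMON

    def test_statuses_partition_sites(self):
        rng = np.random.default_rng(7)
        rows = []
        for _ in range(50):
            n1 = int(rng.integers(0, 97))
            n2 = int(rng.integers(0, 97 - n1))
            rows.append((96 - n1 - n2, n1, n2))
        variants = select_panel(cohort_from_count_rows(rows))
        assert sum(status_counts(variants).values()) == 50

    def test_order_independent(self):
        rows = [(96, 0, 0), (24, 48, 24), (38, 20, 38), (2, 92, 2)]
        fwd = select_panel(cohort_from_count_rows(rows))
        rev = select_panel(cohort_from_count_rows(rows[::-1]))
        assert [v.status for v in fwd] == [v.status for v in rev][::-1]

    def test_empty_cohort_errors(self):
        with pytest.raises(ValueError):
            select_panel(
                CohortGenotypes(sites=[], individuals=["a"], calls=np.empty((0, 1)))
            )


class TestMafFilter:
    def test_thresholding(self):
        freqs = {"keep": 0.5, "drop": 0.005, "sym": 0.995}
        assert maf_filter(freqs) == ["keep"]

    def test_boundary_is_strict(self):
        assert maf_filter({"edge": 0.01}) == []

    def test_fixture_counts(self):
        # 307 candidate sites of which 20 sit below the 1% MAF threshold
        freqs = {f"s{i}": 0.2 for i in range(287)}
        freqs.update({f"low{i}": 0.004 for i in range(20)})
        assert len(maf_filter(freqs)) == 287

    def test_invalid_frequency_errors(self):
        with pytest.raises(ValueError):
            maf_filter({"bad": 1.2})
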