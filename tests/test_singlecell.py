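import math

import numpy as np
import pytest

from sipcell.isotope import IonCountPair
from sipcell.singlecell import (
    CellROI,
    c_assim_from_n,
    cell_enrichment,
    cell_rates,
    combine_substrates,
    compare_enrichment_groups,
    growth_rate_from_enrichment,
    n_assimilation_rate,
)


def _roi(n_minor, n_major, planes=1, **kw):
    counts = [IonCountPair(n_minor // planes, n_major // planes, p) for p in range(planes)]
    return CellROI(cell_id="c1", taxon="target_NOB", roi_area_um2=0.2, n_counts=counts, **kw)


class TestCellEnrichment:
    def test_natural_abundance_cell(self):
        roi = _roi(3700, 996300)  # exactly 0.37 at%, ample counts
        enr = cell_enrichment(roi)
        assert enr.n15_excess == pytest.approx(0.0, abs=1e-9)
        assert enr.passed_filter_n

    def test_natural_abundance_cell_insufficient_counts(self):
        # same ratio but too few ions: sqrt(1/370 + 1/99630) > 5%
        enr = cell_enrichment(_roi(370, 99630))
        assert enr.n15_excess == pytest.approx(0.0, abs=1e-9)
        assert not enr.passed_filter_n

    def test_enriched_worked_example(self):
        enr = cell_enrichment(_roi(500, 9500))
        assert enr.n15_excess == pytest.approx(4.63, abs=1e-9)
        assert enr.poisson_error_n == pytest.approx(math.sqrt(1 / 500 + 1 / 9500), rel=1e-12)

    def test_low_counts_fail_filter(self):
        enr = cell_enrichment(_roi(10, 9990))
        assert not enr.passed_filter_n
        assert enr.poisson_error_n == pytest.approx(0.3164, abs=1e-3)
        assert enr.filter_reason

    def test_carbon_channel_independent(self):
        roi = CellROI(
            "c2",
            "target_AOA",
            0.1,
            n_counts=[IonCountPair(5000, 95000)],
            c_counts=[IonCountPair(10, 9990)],
        )
        enr = cell_enrichment(roi)
        assert enr.passed_filter_n
        assert enr.passed_filter_c is False
        assert not enr.passed_filter

    def test_no_carbon_counts(self):
        enr = cell_enrichment(_roi(5000, 95000))
        assert enr.c13_excess is None and enr.passed_filter_c is None
        assert enr.passed_filter == enr.passed_filter_n

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            CellROI("x", "other", 0.1, n_counts=[])


class TestNAssimilationRate:
    def test_full_turnover(self):
        fg, fmol = n_assimilation_rate(92.7, 92.7, 14.0, 1.0)
        assert fg == pytest.approx(14.0)
        assert fmol == pytest.approx(1.0)

    def test_zero_enrichment(self):
        assert n_assimilation_rate(0.0, 92.7, 15.0, 1.0) == (0.0, 0.0)

    def test_worked_example(self):
        fg, fmol = n_assimilation_rate(5.0, 92.7, 15.1, 1.0)
        assert fg == pytest.approx(0.8144, abs=5e-4)
        assert fmol == pytest.approx(0.05817, abs=5e-5)

    def test_mass_molar_identity(self):
        fg, fmol = n_assimilation_rate(3.7, 92.7, 15.1, 0.5)
        assert fmol * 14.0 == pytest.approx(fg, rel=1e-12)

    def test_negative_excess_contributes_zero(self):
        fg, fmol = n_assimilation_rate(-0.2, 92.7, 15.1, 1.0)
        assert fg == 0.0 and fmol == 0.0

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            n_assimilation_rate(5.0, 0.0, 15.0, 1.0)
        with pytest.raises(ValueError):
            n_assimilation_rate(5.0, 90.0, 15.0, 0.0)
        with pytest.raises(ValueError):
            n_assimilation_rate(5.0, 90.0, -1.0, 1.0)


class TestGrowthRate:
    def test_zero(self):
        assert growth_rate_from_enrichment(0.0, 92.7, 1.0) == 0.0

    def test_linear_in_situ_value(self):
        gr = growth_rate_from_enrichment(0.53 * 92.7, 92.7, 1.0, model="linear")
        assert gr == pytest.approx(0.53)

    def test_exponential_half_replacement(self):
        gr = growth_rate_from_enrichment(50.0, 100.0, 1.0, model="exponential")
        assert gr == pytest.approx(math.log(2))

    def test_exponential_full_replacement_rejected(self):
        with pytest.raises(ValueError):
            growth_rate_from_enrichment(100.0, 100.0, 1.0, model="exponential")

    def test_linear_equals_assim_over_quota(self):
        # algebraic identity when the same cellular N content is used
        excess, label, fg_n, t = 7.3, 92.7, 15.094, 1.0
        gr = growth_rate_from_enrichment(excess, label, t, "linear")
        fg_rate, _ = n_assimilation_rate(excess, label, fg_n, t)
        assert gr == pytest.approx(fg_rate / fg_n, rel=1e-12)


class TestCAssimFromN:
    def test_combined_nob_rate(self):
        assert c_assim_from_n(0.91) == pytest.approx(6.03, abs=0.01)

    def test_zero(self):
        assert c_assim_from_n(0.0) == 0.0

    def test_aoa_rate_within_tolerance(self):
        assert c_assim_from_n(0.12) == pytest.approx(0.795, rel=0.001)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            c_assim_from_n(-0.1)


class TestCombineSubstrates:
    def test_nob_substrates(self):
        combined = combine_substrates(
            {"ammonium": 0.42, "urea": 0.43, "cyanate": 0.05, "nitrite": 0.003}
        )
        assert combined == pytest.approx(0.903)
        assert combined == pytest.approx(0.91, rel=0.01)

    def test_aoa_substrates(self):
        combined = combine_substrates({"ammonium": 0.11, "urea": 0.005, "cyanate": 0.004})
        assert combined == pytest.approx(0.119)
        assert combined == pytest.approx(0.12, rel=0.01)

    def test_single_substrate_identity(self):
        assert combine_substrates({"urea": 0.2}) == 0.2

    def test_missing_substrate_warns(self):
        with pytest.warns(UserWarning, match="nitrite"):
            combined = combine_substrates({"ammonium": 0.4}, expected=["ammonium", "nitrite"])
        assert combined == 0.4


class TestCompareEnrichmentGroups:
    def test_disjoint_groups_extreme(self):
        a = [10 + i * 0.1 for i in range(10)]
        b = [1 + i * 0.1 for i in range(10)]
        stat, p = compare_enrichment_groups(a, b, alternative="greater", method="exact")
        assert stat == 100.0
        # oracle: only 1 of C(20,10) rank arrangements is this extreme
        assert p == pytest.approx(1 / math.comb(20, 10), rel=1e-6)

    def test_identical_groups(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 30).tolist()
        _, p = compare_enrichment_groups(a, list(a), alternative="greater")
        assert 0.4 < p < 0.6

    def test_permutation_within_group_invariant(self):
        rng = np.random.default_rng(1)
        a = rng.normal(1, 1, 15).tolist()
        b = rng.normal(0, 1, 15).tolist()
        stat1, p1 = compare_enrichment_groups(a, b)
        stat2, p2 = compare_enrichment_groups(sorted(a), b[::-1])
        assert stat1 == stat2 and p1 == p2

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_enrichment_groups([], [1.0])


def test_cell_rates_record():
    roi = _roi(5000, 95000, planes=4)
    rec = cell_rates(roi, label_excess=92.7, fg_n_cell=15.094, t_days=1.0)
    assert rec.n_assim_fmol * 14 == pytest.approx(rec.n_assim_fg, rel=1e-12)
    assert rec.c_assim_fmol == pytest.approx(rec.n_assim_fmol * 6.625, rel=1e-12)
    assert rec.growth_rate_n == pytest.approx(rec.n_assim_fg / 15.094, rel=1e-12)
    assert rec.passed_filter
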