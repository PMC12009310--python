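"""Phenotype quantifications: docking, trafficking, SMO, Gabor, morphometry."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ciliascreen.errors import ConfigurationError, UnclassifiableProfileError
from ciliascreen.phenotypes import (
    GaborParams,
    cyst_count,
    docking_classify,
    docking_rate,
    dose_response_table,
    gabor_fibre_score,
    luciferase_normalize,
    rab8a_ciliary_intensity,
    smo_occupancy,
    tubule_area,
)
from ciliascreen.simulate import ZProfilePair, simulate_fibre_image, simulate_zprofiles


def _pair(peak_a, peak_b, n=9):
    a = [0.0] * n
    b = [0.0] * n
    a[peak_a] = 1.0
    b[peak_b] = 1.0
    return ZProfilePair(tuple(a), tuple(b))


class TestDocking:
    @pytest.mark.parametrize("pa,pb,label", [
        (5, 6, "docked"),      # offset 1
        (2, 5, "undocked"),    # offset 3
        (4, 6, "docked"),      # boundary offset 2
        (4, 7, "undocked"),    # boundary offset 3
    ])
    def test_two_slice_tolerance(self, pa, pb, label):
        assert docking_classify(_pair(pa, pb)) == label

    @given(st.integers(0, 8), st.integers(0, 8))
    def test_symmetric_in_channel_order(self, pa, pb):
        flipped = ZProfilePair(_pair(pa, pb).intensity_b, _pair(pa, pb).intensity_a)
        assert docking_classify(_pair(pa, pb)) == docking_classify(flipped)

    def test_zero_tolerance_is_exact_coincidence(self):
        assert docking_classify(_pair(4, 4), tolerance_slices=0) == "docked"
        assert docking_classify(_pair(4, 5), tolerance_slices=0) == "undocked"

    def test_all_zero_channel_unclassifiable(self):
        with pytest.raises(UnclassifiableProfileError):
            docking_classify(ZProfilePair((0.0,) * 9, (1.0,) + (0.0,) * 8))

    def test_rate_3_of_4(self):
        pairs = [_pair(4, 4), _pair(4, 5), _pair(4, 6), _pair(0, 8)]
        out = docking_rate(pairs)
        assert out["pct_docked"] == 75.0

    def test_rate_with_ciliation_flags(self):
        pairs = [_pair(4, 4), _pair(4, 5), _pair(0, 8)]
        out = docking_rate(pairs, ciliated=[True, False, False])
        assert out["pct_docked_no_axoneme"] == pytest.approx(100 / 3)

    def test_all_unclassifiable_errors_with_count(self):
        bad = ZProfilePair((0.0,) * 9, (0.0,) * 9)
        with pytest.raises(UnclassifiableProfileError, match="2"):
            docking_rate([bad, bad])

    def test_rate_recovers_generator_labels_exactly(self):
        pairs, labels = simulate_zprofiles(1000, 0.5, seed=3)
        out = docking_rate(pairs)
        assert out["pct_docked"] == 100.0 * labels.mean() == 50.0


class TestRab8a:
    def test_per_roi_max_then_image_mean(self):
        out = rab8a_ciliary_intensity([[1, 5, 3], [2, 7, 1]])
        assert out["roi_maxima"] == [5.0, 7.0]
        assert out["mean_of_maxima"] == 6.0

    def test_single_slice_rois_are_identity(self):
        out = rab8a_ciliary_intensity([[4.0], [9.0]])
        assert out["roi_maxima"] == [4.0, 9.0]


class TestSmoOccupancy:
    @pytest.mark.parametrize("area,n,expected", [(120, 40, 3.0), (0, 40, 0.0)])
    def test_ratio(self, area, n, expected):
        assert smo_occupancy(area, n) == expected

    def test_no_cilia_flagged_nan(self):
        assert np.isnan(smo_occupancy(10.0, 0))

    def test_invariant_under_field_splitting(self):
        # pooling two half-fields' areas and counts gives the same ratio
        whole = smo_occupancy(120.0, 40)
        pooled = smo_occupancy(70.0 + 50.0, 25 + 15)
        assert pooled == whole


class TestGaborScore:
    def test_constant_image_scores_exactly_zero(self):
        assert gabor_fibre_score(np.full((64, 64), 0.7)) == 0.0

    def test_grating_scores_far_above_uniform(self):
        grating = simulate_fibre_image(64, "grating", contrast=1.0)
        uniform = simulate_fibre_image(64, "uniform")
        assert uniform.mean() == pytest.approx(grating.mean(), abs=1e-6)
        assert gabor_fibre_score(grating) > 10 * max(gabor_fibre_score(uniform), 1e-9)

    def test_rotation_to_any_bank_angle_within_5_percent(self):
        scores = [
            gabor_fibre_score(simulate_fibre_image(
                64, "grating", angle_deg=180.0 * k / 8, contrast=1.0))
            for k in range(8)]
        scores = np.array(scores)
        assert (scores.max() - scores.min()) / scores.mean() <= 0.05

    def test_unnormalized_response_offset_invariant(self):
        img = simulate_fibre_image(64, "grating", angle_deg=30, contrast=0.5)
        p = GaborParams(normalization="none")
        assert gabor_fibre_score(img + 1.3, params=p) == pytest.approx(
            gabor_fibre_score(img, params=p), rel=1e-12)

    def test_response_scales_linearly_with_contrast(self):
        p = GaborParams(normalization="none")
        s_half = gabor_fibre_score(
            simulate_fibre_image(64, "grating", contrast=0.5), params=p)
        s_full = gabor_fibre_score(
            simulate_fibre_image(64, "grating", contrast=1.0), params=p)
        assert s_full == pytest.approx(2 * s_half, rel=1e-9)

    def test_empty_mask_rejected(self):
        with pytest.raises(ConfigurationError):
            gabor_fibre_score(np.ones((64, 64)), mask=np.zeros((64, 64), bool))

    def test_nyquist_wavelength_enforced(self):
        with pytest.raises(ConfigurationError):
            GaborParams(wavelength=1.5)


class TestTubuleArea:
    def test_unit_circle(self):
        assert tubule_area(1, 1) == pytest.approx(np.pi)

    def test_printed_formula_pi_a_b(self):
        assert tubule_area(4, 2) == pytest.approx(8 * np.pi)

    @given(st.floats(0.1, 100), st.floats(0.1, 100))
    def test_doubling_axes_quadruples_area(self, a, b):
        a, b = max(a, b), min(a, b)
        assert tubule_area(2 * a, 2 * b) == pytest.approx(4 * tubule_area(a, b))

    def test_axes_order_enforced(self):
        with pytest.raises(ConfigurationError):
            tubule_area(2, 4)


class TestCystCount:
    def test_stage_2_and_3_count_as_cysts(self):
        grades = pd.DataFrame(dict(organoid=list("aabcd"), stage=[0, 1, 2, 3, 1]))
        assert cyst_count(grades)["n_cysts"] == 2

    def test_all_normal_counts_zero(self):
        grades = pd.DataFrame(dict(organoid=list("abc"), stage=[0, 0, 0]))
        assert cyst_count(grades)["n_cysts"] == 0

    def test_mean_cysts_per_organoid(self):
        # 13 organoids carrying 24 stage>=2 anomalies in total
        rows = []
        for i in range(13):
            rows.append(dict(organoid=f"o{i}", stage=0))
        for k in range(24):
            rows.append(dict(organoid=f"o{k % 13}", stage=2 + k % 2))
        out = cyst_count(pd.DataFrame(rows))
        assert out["n_cysts"] == 24 and out["n_organoids"] == 13
        assert out["mean_cysts_per_organoid"] == pytest.approx(1.846, abs=5e-4)

    def test_invalid_stage_rejected(self):
        with pytest.raises(ConfigurationError):
            cyst_count(pd.DataFrame(dict(organoid=["a"], stage=[4])))


class TestLuciferase:
    def test_reference_wells_normalize_to_one(self):
        out = luciferase_normalize([100, 100], [50, 50], reference_ratio=2.0)
        assert out.tolist() == [1.0, 1.0]

    def test_simple_ratio(self):
        assert luciferase_normalize([200], [100], 1.0)[0] == 2.0

    @given(st.floats(0.1, 100))
    def test_common_scaling_cancels(self, c):
        base = luciferase_normalize([120, 80], [60, 50], reference_ratio=1.6)
        scaled = luciferase_normalize([120 * c, 80 * c], [60, 50],
                                      reference_ratio=1.6 * c)
        np.testing.assert_allclose(scaled, base, rtol=1e-9)

    def test_zero_renilla_names_the_well(self):
        with pytest.raises(ConfigurationError, match="1"):
            luciferase_normalize([1, 1], [2, 0], 1.0)


class TestDoseResponse:
    def _wells(self, groups):
        cells_cycle = [900, 1000, 1100, 1200, 1300]
        rows = []
        for (compound, dose), incidences in groups.items():
            for i, inc in enumerate(incidences):
                cells = cells_cycle[i % len(cells_cycle)]
                rows.append(dict(genotype="wt", compound=compound, dose=dose,
                                 cell_count=cells,
                                 ciliated_count=round(inc / 100 * cells)))
        return pd.DataFrame(rows)

    def test_group_identical_to_vehicle_scores_zero(self):
        # symmetric vehicle population: mean == median, so mean z is exactly 0
        veh = [38, 39, 40, 41, 42]
        df = self._wells({("DMSO", 0): veh, ("drug", 1): veh})
        out = dose_response_table(df)
        assert out.z_cilia[0] == pytest.approx(0.0, abs=1e-12)
        assert out.fold_change_incidence[0] == pytest.approx(1.0)

    def test_fold_change_is_mean_ratio(self):
        df = self._wells({("DMSO", 0): [40, 40, 40, 40], ("drug", 1): [60, 60]})
        with pytest.raises(Exception):
            # degenerate vehicle spread propagates the robust-z error
            dose_response_table(df)
        df = self._wells({("DMSO", 0): [38, 39, 41, 42], ("drug", 1): [60, 60]})
        out = dose_response_table(df)
        assert out.fold_change_incidence[0] == pytest.approx(1.5)

    def test_monotone_planted_ladder_gives_monotone_fold_changes(self, rng):
        groups = {("DMSO", 0): rng.normal(40, 1, 12).tolist()}
        for i, delta in enumerate([0, 5, 10, 15]):
            groups[("drug", i + 1)] = rng.normal(40 + delta, 1, 6).tolist()
        out = dose_response_table(self._wells(groups)).sort_values("dose")
        assert out.fold_change_incidence.is_monotonic_increasing
        assert out.z_cilia.is_monotonic_increasing
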