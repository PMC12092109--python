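"""Synthetic-series generator: determinism, planted crossings, ground truth."""

import pytest

from caudawhip.errors import ValidationError
from caudawhip.mass import TissueModel, tail_mass
from caudawhip.segmentation import find_transition_point, segment
from caudawhip.series import impute_missing, read_measurements, total_length, \
    write_measurements
from caudawhip.synthetic import SyntheticSeriesSpec, generate_series, ground_truth


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_vertebrae": 2},
            {"height_taper": 1.0},
            {"height_taper": 0.0},
            {"tp_true": 1},
            {"tp_true": 43},
            {"ca1_length_cm": 30.0},  # longer than tall at Ca1
            {"noise_sd_cm": -0.1},
            {"missing_positions": (1,)},
            {"missing_positions": (43,)},
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            SyntheticSeriesSpec(**{"n_vertebrae": 43, "tp_true": 25, **kwargs})


class TestGenerateSeries:
    def test_deterministic_for_fixed_seed(self):
        spec = SyntheticSeriesSpec(n_vertebrae=30, tp_true=12, noise_sd_cm=0.4, seed=11)
        assert generate_series(spec) == generate_series(spec)

    def test_different_seed_differs(self):
        a = SyntheticSeriesSpec(n_vertebrae=30, tp_true=12, noise_sd_cm=0.4, seed=11)
        b = SyntheticSeriesSpec(n_vertebrae=30, tp_true=12, noise_sd_cm=0.4, seed=12)
        assert generate_series(a) != generate_series(b)

    def test_noiseless_crossing_at_planted_position(self):
        spec = SyntheticSeriesSpec(n_vertebrae=30, tp_true=10)
        s = generate_series(spec)
        ratios = {r.position: r.centrum_length_cm / r.total_height_cm for r in s}
        assert ratios[9] < 1 < ratios[10]
        assert find_transition_point(s) == 10

    def test_measurements_stay_positive_under_noise(self):
        # sd comparable to the smallest heights: truncation must keep values > 0
        spec = SyntheticSeriesSpec(n_vertebrae=40, tp_true=20, noise_sd_cm=1.0, seed=5)
        for r in generate_series(spec):
            assert r.centrum_length_cm > 0 and r.total_height_cm > 0

    def test_missing_positions_removed_and_listed(self):
        spec = SyntheticSeriesSpec(n_vertebrae=20, tp_true=10, missing_positions=(4, 9))
        s = generate_series(spec)
        assert s.missing_positions == (4, 9)
        assert all(r.position not in (4, 9) for r in s)

    def test_generated_file_parses_losslessly(self, tmp_path):
        spec = SyntheticSeriesSpec(n_vertebrae=25, tp_true=12, noise_sd_cm=0.2, seed=3)
        s = generate_series(spec)
        path = write_measurements(s, tmp_path / "synthetic.csv")
        back = read_measurements(path, specimen_id=s.specimen_id, taxon=s.taxon)
        assert [r.position for r in back] == [r.position for r in s]
        for a, b in zip(s, back):
            assert a.centrum_length_cm == b.centrum_length_cm
            assert a.total_height_cm == b.total_height_cm


class TestGroundTruth:
    def test_pipeline_matches_closed_form(self, vienna_like_spec):
        gt = ground_truth(vienna_like_spec, tissue=TissueModel())
        s = generate_series(vienna_like_spec)
        assert total_length(s) == pytest.approx(gt.total_length_cm, rel=1e-9)
        tp = find_transition_point(s)
        assert tp == gt.tp_position
        seg = segment(s, tp)
        assert seg.whip_length_cm == pytest.approx(gt.whip_length_cm, rel=1e-9)
        assert seg.whip_fraction == pytest.approx(gt.whip_fraction, rel=1e-9)
        whole, whip = tail_mass(s, segmentation=seg, tissue=TissueModel())
        assert whole.mass_kg == pytest.approx(gt.whole_soft_mass_kg, rel=1e-9)
        assert whip.mass_kg == pytest.approx(gt.whip_soft_mass_kg, rel=1e-9)

    def test_energies_match_closed_form(self, vienna_like_spec):
        gt = ground_truth(
            vienna_like_spec,
            whole_tail_velocity_m_s=2.0,
            whiplash_velocity_m_s=2.0,
            transfer_efficiency=0.85,
        )
        assert gt.energies_j["whole_tail"] == pytest.approx(
            0.5 * gt.whole_bone_mass_kg * 4.0
        )
        assert gt.energies_j["whip_transferred"] == pytest.approx(
            gt.energies_j["whole_tail"] * 0.85
        )

    def test_soft_to_bone_ratio_is_factor_squared(self, vienna_like_spec):
        t = TissueModel(0.3, 0.1)
        gt = ground_truth(vienna_like_spec, tissue=t)
        assert gt.whole_soft_mass_kg / gt.whole_bone_mass_kg == pytest.approx(
            t.factor**2, rel=1e-12
        )

    def test_single_gap_imputation_error_bounded_by_second_difference(self):
        # noiseless geometric decay is convex: linear imputation overestimates
        # by at most the local second difference of the length profile
        spec = SyntheticSeriesSpec(
            n_vertebrae=30, tp_true=15, missing_positions=(8,), seed=0
        )
        s = impute_missing(generate_series(spec))
        truth = spec.noiseless_length(8)
        err = s.require(8).centrum_length_cm - truth
        second_diff = abs(
            spec.noiseless_length(7) - 2 * truth + spec.noiseless_length(9)
        )
        assert 0 <= err <= second_diff
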