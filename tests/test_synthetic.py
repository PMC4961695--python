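"""Planted-truth generator: determinism, construction identities, artifacts."""

import numpy as np
import pytest

from moltimetable.core import DetectionConfig, detect_oscillating
from moltimetable.io import zscore_rows
from moltimetable.synthetic import (SyntheticParams, apply_light_artifact,
                                    generate_timecourse)


class TestGenerate:
    def test_equal_seeds_are_bit_identical(self, design_ll):
        p = SyntheticParams(n_contigs=200, seed=42)
        em1, truth1 = generate_timecourse(p, design_ll)
        em2, truth2 = generate_timecourse(p, design_ll)
        assert np.array_equal(em1.values, em2.values)
        assert truth1.table.equals(truth2.table)
        em3, _ = generate_timecourse(SyntheticParams(n_contigs=200, seed=43),
                                     design_ll)
        assert not np.array_equal(em1.values, em3.values)

    def test_exact_oscillator_count(self, design_ll):
        p = SyntheticParams(n_contigs=1000, frac_oscillating=0.3, seed=1)
        _, truth = generate_timecourse(p, design_ll)
        assert truth.n_oscillators == 300
        t = truth.table
        # peak/amplitude recorded iff oscillator
        assert t.loc[t.is_oscillator, "true_peak_time"].notna().all()
        assert t.loc[~t.is_oscillator, "true_peak_time"].isna().all()

    def test_noise_free_row_matches_cosine_formula(self, design_ll,
                                                   cosine_row):
        p = SyntheticParams(n_contigs=5, frac_oscillating=1.0, noise_cv=0.0,
                            seed=3)
        em, truth = generate_timecourse(p, design_ll)
        t = truth.table
        for _, rec in t.iterrows():
            expected = cosine_row(design_ll.times,
                                  baseline=rec.baseline_mean,
                                  a=rec.true_relative_amplitude,
                                  peak=rec.true_peak_time)
            np.testing.assert_allclose(em.row(rec.contig_id), expected,
                                       rtol=1e-12)

    def test_noise_free_rows_znormalise_to_unit_cosine(self, design_ll):
        p = SyntheticParams(n_contigs=8, frac_oscillating=1.0, noise_cv=0.0,
                            seed=6)
        em, truth = generate_timecourse(p, design_ll)
        nm, _ = zscore_rows(em)
        for cid, peak in zip(truth.table.contig_id,
                             truth.table.true_peak_time):
            i = list(nm.contig_ids).index(cid)
            expected = np.sqrt(2.0) * np.cos(
                2 * np.pi * (design_ll.times - peak) / 24.0)
            np.testing.assert_allclose(nm.z_values[i], expected, atol=1e-9)

    def test_null_matrix_yields_no_detections(self, design_ll):
        p = SyntheticParams(n_contigs=400, frac_oscillating=0.0,
                            noise_cv=0.05, seed=2)
        em, truth = generate_timecourse(p, design_ll)
        assert truth.n_oscillators == 0
        res = detect_oscillating(em)
        assert res.n_detected == 0

    @pytest.mark.parametrize("kwargs, field", [
        (dict(n_contigs=0), "n_contigs"),
        (dict(frac_oscillating=1.5), "frac_oscillating"),
        (dict(noise_cv=-0.1), "noise_cv"),
        (dict(ld_artifact_magnitude=-1.0), "ld_artifact_magnitude"),
        (dict(relative_amplitude_range=(0.5, 0.1)),
         "relative_amplitude_range"),
    ])
    def test_invalid_params_name_the_field(self, kwargs, field):
        with pytest.raises(ValueError, match=field):
            SyntheticParams(**kwargs)

    def test_truth_round_trip(self, tmp_path, design_ll):
        from moltimetable.synthetic import SyntheticTruth
        _, truth = generate_timecourse(SyntheticParams(n_contigs=50, seed=8),
                                       design_ll)
        path = tmp_path / "truth.tsv"
        truth.write(path)
        back = SyntheticTruth.read(path)
        assert back.oscillator_ids == truth.oscillator_ids

    def test_params_yaml_round_trip(self, tmp_path):
        p = SyntheticParams(n_contigs=77, frac_oscillating=0.4, seed=5,
                            relative_amplitude_range=(0.2, 0.5))
        path = tmp_path / "params.yaml"
        p.to_yaml(path)
        assert SyntheticParams.from_yaml(path) == p


class TestLightArtifact:
    def _matrix(self, design, seed=7, noise_cv=0.05):
        p = SyntheticParams(n_contigs=300, frac_oscillating=0.5,
                            relative_amplitude_range=(0.2, 0.5),
                            noise_cv=noise_cv, seed=seed)
        return generate_timecourse(p, design)

    def test_zero_magnitude_is_identity(self, design_ld):
        em, _ = self._matrix(design_ld)
        out = apply_light_artifact(em, design_ld, 0.0, 2.0, seed=1)
        assert np.array_equal(out.values, em.values)

    def test_ll_design_is_noop(self, design_ll):
        em, _ = self._matrix(design_ll)
        out = apply_light_artifact(em, design_ll, 0.7, 2.0, seed=1)
        assert np.array_equal(out.values, em.values)

    def test_artifacts_degrade_detection(self, design_ld):
        """Square-wave transients must strictly reduce the number of planted
        oscillators recovered at the default cutoffs."""
        em, truth = self._matrix(design_ld)
        osc = truth.oscillator_ids
        bumped = apply_light_artifact(em, design_ld, 0.5, 2.0, seed=99)
        clean_hits = detect_oscillating(em).passing_ids() & osc
        noisy_hits = detect_oscillating(bumped).passing_ids() & osc
        assert len(noisy_hits) < len(clean_hits)

    def test_degradation_is_monotone_over_magnitude_ladder(self, design_ld):
        em, truth = self._matrix(design_ld)
        osc = truth.oscillator_ids
        hits = []
        for mag in [0.0, 0.2, 0.5, 1.0]:
            bumped = apply_light_artifact(em, design_ld, mag, 2.0, seed=123)
            hits.append(len(detect_oscillating(bumped).passing_ids() & osc))
        assert all(b <= a for a, b in zip(hits, hits[1:]))

    def test_generator_applies_artifacts_only_under_ld(self, design_ld,
                                                       design_ll):
        p = SyntheticParams(n_contigs=100, frac_oscillating=0.5,
                            noise_cv=0.0, ld_artifact_magnitude=0.5, seed=4)
        em_ld, _ = generate_timecourse(p, design_ld)
        em_ll, _ = generate_timecourse(p, design_ll)
        assert not np.array_equal(em_ld.values, em_ll.values)
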