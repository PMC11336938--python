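"""Cohort simulation: forward model, class contrast, seeding, round trips."""

import numpy as np
import pytest

from hepatoscope.circuits import ElectrodeSkinModel, TissueDispersion, frequency_grid
from hepatoscope.cohort import (
    GeneratorConfig,
    SubjectParams,
    generate_cohort,
    load_cohort,
    save_cohort,
    simulate_matrix,
)
from hepatoscope.geometry import default_geometry


def make_subject(label="healthy", noise_sigma=0.0):
    cfg = GeneratorConfig()
    liver = cfg.nafld_liver if label == "nafld" else cfg.healthy_liver
    return SubjectParams(
        label=label,
        liver=liver,
        background=cfg.background,
        contacts=(cfg.contact,) * 6,
        noise_sigma=noise_sigma,
    )


class TestSimulateMatrix:
    def test_default_shape_is_15_by_30(self):
        m = simulate_matrix(make_subject())
        assert m.shape == (15, 30)

    def test_noise_free_is_seed_independent(self):
        a = simulate_matrix(make_subject(), rng_seed=1)
        b = simulate_matrix(make_subject(), rng_seed=999)
        np.testing.assert_array_equal(a.magnitudes, b.magnitudes)

    def test_noise_is_seed_deterministic(self):
        a = simulate_matrix(make_subject(noise_sigma=0.05), rng_seed=3)
        b = simulate_matrix(make_subject(noise_sigma=0.05), rng_seed=3)
        c = simulate_matrix(make_subject(noise_sigma=0.05), rng_seed=4)
        np.testing.assert_array_equal(a.magnitudes, b.magnitudes)
        assert not np.array_equal(a.magnitudes, c.magnitudes)

    def test_noise_free_rows_non_increasing_in_frequency(self):
        m = simulate_matrix(make_subject()).magnitudes
        assert np.all(np.diff(m, axis=1) <= 1e-9)

    def test_default_nafld_exceeds_healthy_at_low_frequency(self):
        h = simulate_matrix(make_subject("healthy")).magnitudes
        n = simulate_matrix(make_subject("nafld")).magnitudes
        assert n[:, :5].mean() > h[:, :5].mean()

    def test_contact_count_mismatch_raises(self):
        s = make_subject()
        bad = SubjectParams(
            label=s.label, liver=s.liver, background=s.background, contacts=s.contacts[:5]
        )
        with pytest.raises(ValueError):
            simulate_matrix(bad)

    def test_matrix_cell_is_the_lumped_circuit_magnitude(self):
        # one cell recomputed from scratch with plain complex arithmetic
        from hepatoscope.circuits import electrode_skin_impedance, tissue_path_impedance

        subject = make_subject()
        geo, grid = default_geometry(), frequency_grid()
        m = simulate_matrix(subject, geo, grid)
        p, k = 7, 13
        (e1, e2), w = geo.pairs[p], geo.liver_weight[p]
        f = grid.frequencies[k]
        z = (
            electrode_skin_impedance(subject.contacts[e1], f)
            + electrode_skin_impedance(subject.contacts[e2], f)
            + w * tissue_path_impedance(subject.liver, f)
            + (1 - w) * tissue_path_impedance(subject.background, f)
        )
        assert m.magnitudes[p, k] == pytest.approx(abs(z), rel=1e-12)


class TestGenerateCohort:
    def test_default_cohort_is_40_matrices_20_per_label(self):
        c = generate_cohort(seed=0)
        assert len(c) == 40
        assert (c.labels == "healthy").sum() == 20
        assert (c.labels == "nafld").sum() == 20
        assert c.stack().shape == (40, 15, 30)

    def test_empty_cohort(self):
        assert len(generate_cohort(0, 0, seed=0)) == 0

    def test_negative_counts_raise(self):
        with pytest.raises(ValueError):
            generate_cohort(-1, 5, seed=0)

    def test_seed_contract(self):
        a, b, c = generate_cohort(seed=5), generate_cohort(seed=5), generate_cohort(seed=6)
        np.testing.assert_array_equal(a.stack(), b.stack())
        assert not np.array_equal(a.stack(), c.stack())

    def test_between_subject_variability_present(self):
        c = generate_cohort(seed=0)
        healthy = c.stack()[c.y == 0]
        assert not np.array_equal(healthy[0], healthy[1])


class TestCohortIO:
    def test_round_trip_is_lossless(self, tmp_path, small_cohort):
        save_cohort(small_cohort, tmp_path / "cohort")
        loaded = load_cohort(tmp_path / "cohort")
        np.testing.assert_array_equal(loaded.stack(), small_cohort.stack())
        assert list(loaded.labels) == list(small_cohort.labels)
        assert list(loaded.subject_ids) == list(small_cohort.subject_ids)
        assert loaded.seed == small_cohort.seed

    def test_metadata_rows_match_matrix_count(self, tmp_path, small_cohort):
        import pandas as pd

        save_cohort(small_cohort, tmp_path / "cohort")
        table = pd.read_csv(tmp_path / "cohort" / "metadata.csv")
        assert len(table) == len(small_cohort)

    def test_truncated_file_raises_not_silently_loads(self, tmp_path, small_cohort):
        save_cohort(small_cohort, tmp_path / "cohort")
        table_path = tmp_path / "cohort" / "metadata.csv"
        lines = table_path.read_text().splitlines()
        table_path.write_text("\n".join(lines[:-2]))
        with pytest.raises(ValueError, match="corrupt"):
            load_cohort(tmp_path / "cohort")

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_cohort(tmp_path / "nope")
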