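import numpy as np
import pytest

from nirstew.spectra_io import (
    BandSpec,
    GridMismatchError,
    ReferenceTable,
    SpectraFormatError,
    SpectraSet,
    SpectraValidationError,
    average_replicates,
    read_reference_csv,
    read_spectra_csv,
    to_absorbance,
    trim_noise_bands,
    write_reference_csv,
    write_spectra_csv,
)

from conftest import make_spectra


class TestReadSpectraCSV:
    def test_minimal_well_formed_file(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("id,650.0,650.35,650.7\na,1,2,3\nb,4,5,6\n")
        s = read_spectra_csv(p, "VNIR")
        assert s.n_samples == 2 and s.n_wavelengths == 3
        assert s.sample_ids == ["a", "b"]
        np.testing.assert_allclose(s.wavelengths_nm, [650.0, 650.35, 650.7])

    def test_columns_sorted_ascending(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("id,700,650\na,1,2\n")
        s = read_spectra_csv(p, "VNIR")
        np.testing.assert_allclose(s.wavelengths_nm, [650.0, 700.0])
        np.testing.assert_allclose(s.values, [[2.0, 1.0]])

    def test_empty_cell_names_offending_sample(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("id,650,700\na,1,2\nbad,3,\n")
        with pytest.raises(SpectraValidationError, match="bad"):
            read_spectra_csv(p, "VNIR")

    def test_non_numeric_header_rejected(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("id,650,notanm\na,1,2\n")
        with pytest.raises(SpectraFormatError):
            read_spectra_csv(p, "VNIR")

    def test_duplicate_sample_id_rejected(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("id,650,700\na,1,2\na,3,4\n")
        with pytest.raises(SpectraValidationError):
            read_spectra_csv(p, "VNIR")

    def test_round_trip_preserves_values(self, tmp_path, rng):
        s = make_spectra(rng.standard_normal((4, 9)), 600 + np.arange(9) * 0.35)
        write_spectra_csv(s, tmp_path / "rt.csv")
        back = read_spectra_csv(tmp_path / "rt.csv", s.band_label)
        np.testing.assert_allclose(back.values, s.values, rtol=1e-12)
        np.testing.assert_allclose(back.wavelengths_nm, s.wavelengths_nm, rtol=1e-12)


class TestValidation:
    def test_non_increasing_grid_rejected(self):
        with pytest.raises(SpectraValidationError):
            make_spectra([[1.0, 2.0]], wavelengths=[700.0, 650.0])

    def test_non_finite_value_names_sample_and_wavelength(self):
        with pytest.raises(SpectraValidationError, match="s1.*700"):
            make_spectra([[1.0, 2.0], [3.0, np.nan]], wavelengths=[650.0, 700.0])

    def test_reference_table_rejects_negative_and_ragged(self):
        with pytest.raises(SpectraValidationError):
            ReferenceTable(["a", "b"], {"fat": np.array([1.0, -2.0])})
        with pytest.raises(SpectraValidationError):
            ReferenceTable(["a", "b"], {"fat": np.array([1.0])})

    def test_reference_round_trip(self, tmp_path, rng):
        refs = ReferenceTable(
            ["a", "b", "c"],
            {t: rng.uniform(1, 100, 3) for t in ("fat", "protein", "collagen", "ash", "Na")},
        )
        write_reference_csv(refs, tmp_path / "r.csv")
        back = read_reference_csv(tmp_path / "r.csv")
        for t in refs.traits:
            np.testing.assert_allclose(back.traits[t], refs.traits[t], rtol=1e-12)


class TestTrimNoiseBands:
    def test_closed_boundary_inclusion(self):
        s = make_spectra([[1, 2, 3, 4, 5]], wavelengths=[640, 650, 700, 950, 955])
        out = trim_noise_bands(s, BandSpec([(650, 950)], "keep"))
        np.testing.assert_allclose(out.wavelengths_nm, [650, 700, 950])

    @pytest.mark.parametrize(
        "start, pitch, stop, keep, lo_expect, hi_expect",
        [
            # VNIR instrument range 399.8-949.8 nm trimmed to the usable band
            (399.8, 0.35, 949.8, (650.0, 950.0), 650.0, 949.8),
            # NIR instrument range 942.7-1698.3 nm trimmed to 960-1650 nm
            (942.7, 3.6, 1698.3, (960.0, 1650.0), 960.0, 1650.0),
        ],
    )
    def test_instrument_ranges(self, start, pitch, stop, keep, lo_expect, hi_expect):
        grid = np.arange(start, stop + pitch / 2, pitch)
        s = make_spectra(np.ones((1, grid.size)), grid)
        out = trim_noise_bands(s, BandSpec([keep], "keep"))
        assert out.wavelengths_nm[0] >= lo_expect
        assert out.wavelengths_nm[-1] <= hi_expect
        # nothing inside the keep interval was dropped
        inside = (grid >= keep[0]) & (grid <= keep[1])
        assert out.n_wavelengths == inside.sum()

    def test_idempotent(self, rng):
        s = make_spectra(rng.standard_normal((3, 50)), 900 + np.arange(50) * 3.6)
        spec = BandSpec([(960, 1000)], "keep")
        once = trim_noise_bands(s, spec)
        twice = trim_noise_bands(once, spec)
        np.testing.assert_array_equal(once.values, twice.values)

    def test_empty_result_is_error(self):
        s = make_spectra([[1.0, 2.0]], wavelengths=[650.0, 700.0])
        with pytest.raises(SpectraValidationError):
            trim_noise_bands(s, BandSpec([(1000, 1100)], "keep"))

    def test_overlapping_keep_intervals_rejected(self):
        with pytest.raises(SpectraValidationError):
            BandSpec([(650, 950), (900, 1000)], "bad")


class TestAverageReplicates:
    def test_identical_sets_idempotent(self, rng):
        s = make_spectra(rng.standard_normal((2, 5)))
        out = average_replicates([s, s, s])
        np.testing.assert_allclose(out.values, s.values, rtol=1e-14)

    def test_elementwise_mean(self):
        a = make_spectra(np.zeros((1, 3)))
        b = make_spectra(np.full((1, 3), 2.0))
        np.testing.assert_allclose(average_replicates([a, b]).values, 1.0)

    def test_hierarchical_equals_joint_nine_replicates(self, rng):
        # 3 positions x 3 repeats: averaging position-means of repeat-means
        # equals one joint mean over all 9 (associativity of the mean)
        sets = [make_spectra(rng.standard_normal((4, 5))) for _ in range(9)]
        joint = average_replicates(sets)
        hierarchical = average_replicates(
            [average_replicates(sets[i : i + 3]) for i in range(0, 9, 3)]
        )
        np.testing.assert_allclose(joint.values, hierarchical.values, rtol=1e-12)

    def test_permutation_invariant(self, rng):
        sets = [make_spectra(rng.standard_normal((2, 4))) for _ in range(4)]
        a = average_replicates(sets)
        b = average_replicates(sets[::-1])
        np.testing.assert_allclose(a.values, b.values, rtol=1e-12)

    def test_mismatched_grid_and_ids(self, rng):
        a = make_spectra(rng.standard_normal((2, 4)))
        b = make_spectra(rng.standard_normal((2, 4)), wavelengths=[0, 1, 2, 4])
        with pytest.raises(GridMismatchError):
            average_replicates([a, b])
        c = make_spectra(rng.standard_normal((2, 4)), ids=["x", "y"])
        with pytest.raises(SpectraValidationError):
            average_replicates([a, c])


def test_absorbance_transform_is_log10_reciprocal():
    s = make_spectra([[0.1, 1.0, 10.0]])
    np.testing.assert_allclose(to_absorbance(s).values, [[1.0, 0.0, -1.0]], atol=1e-12)
    with pytest.raises(SpectraValidationError):
        to_absorbance(make_spectra([[0.0, 1.0]]))
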