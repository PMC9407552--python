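"""Data containers, CSV I/O, trimming, replicate averaging, SCC formula."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pearscc import (ReferenceSet, SccMeasurement, SpectraSet,
                     anova_two_groups, average_replicates, compute_scc,
                     read_reference, read_spectra, replicate_groups,
                     summarize_reference, trim_to_effective_range,
                     write_reference, write_spectra)
from pearscc.datasets import ParseError
from scipy import stats


def make_set(matrix, wl=None, ids=None):
    matrix = np.asarray(matrix, dtype=float)
    if wl is None:
        wl = 500.0 + 10.0 * np.arange(matrix.shape[1])
    if ids is None:
        ids = tuple(f"P{i:03d}" for i in range(matrix.shape[0]))
    return SpectraSet(wl, matrix, ids)


class TestSpectraSetInvariants:
    def test_rejects_nonincreasing_wavelengths(self):
        with pytest.raises(ValueError, match="increasing"):
            SpectraSet([500, 400, 600], np.ones((1, 3)), ("a",))

    def test_rejects_duplicate_ids(self):
        with pytest.raises(ValueError, match="P001"):
            SpectraSet([500, 600], np.ones((2, 2)), ("P001", "P001"))

    def test_rejects_shape_mismatch(self):
        with pytest.raises(ValueError, match="columns"):
            SpectraSet([500, 600, 700], np.ones((2, 2)), ("a", "b"))


class TestCsvRoundTrip:
    def test_spectra_round_trip_is_exact(self, tmp_path, small_spectra):
        path = tmp_path / "s.csv"
        write_spectra(small_spectra, path)
        back = read_spectra(path)
        assert back.sample_ids == small_spectra.sample_ids
        np.testing.assert_array_equal(back.wavelengths,
                                      small_spectra.wavelengths)
        np.testing.assert_array_equal(back.reflectance,
                                      small_spectra.reflectance)

    def test_duplicate_id_named_in_error(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text("id,500.0,600.0\nP001,1,2\nP001,3,4\n")
        with pytest.raises(ParseError, match="P001"):
            read_spectra(path)

    def test_ragged_row_and_bad_cell_errors_name_position(self, tmp_path):
        path = tmp_path / "ragged.csv"
        path.write_text("id,500.0,600.0\nP001,1\n")
        with pytest.raises(ParseError, match="row 2"):
            read_spectra(path)
        path.write_text("id,500.0,600.0\nP001,1,oops\n")
        with pytest.raises(ParseError, match="row 2, column 3"):
            read_spectra(path)

    def test_reference_round_trip(self, tmp_path):
        ref = ReferenceSet(("a", "b"), [0.3, 0.5])
        path = tmp_path / "r.csv"
        write_reference(ref, path)
        back = read_reference(path)
        assert back.sample_ids == ref.sample_ids
        np.testing.assert_array_equal(back.scc, ref.scc)

    def test_synthetic_table_dimensions(self, tmp_path, paper_like):
        spectra, _, _ = paper_like
        averaged = average_replicates(spectra,
                                      replicate_groups(spectra.sample_ids))
        path = tmp_path / "paper.csv"
        write_spectra(averaged, path)
        back = read_spectra(path)
        assert back.n_samples == 120
        assert back.n_channels == 1045


class TestTrim:
    def test_closed_interval_retained(self, paper_like):
        spectra, _, _ = paper_like
        trimmed = trim_to_effective_range(spectra, 498.0, 1020.0)
        assert trimmed.wavelengths.min() >= 498.0
        assert trimmed.wavelengths.max() <= 1020.0

    def test_full_range_is_identity(self, small_spectra):
        s = trim_to_effective_range(small_spectra,
                                    small_spectra.wavelengths[0],
                                    small_spectra.wavelengths[-1])
        np.testing.assert_array_equal(s.reflectance,
                                      small_spectra.reflectance)

    def test_channel_count_matches_enumeration(self):
        wl = 498.0 + 0.5 * np.arange(1045)
        s = make_set(np.ones((2, wl.size)), wl=wl)
        trimmed = trim_to_effective_range(s, 600.0, 700.0)
        expected = sum(1 for w in wl if 600.0 <= w <= 700.0)
        assert trimmed.n_channels == expected

    def test_idempotent(self, small_spectra):
        once = trim_to_effective_range(small_spectra, 550.0, 800.0)
        twice = trim_to_effective_range(once, 550.0, 800.0)
        np.testing.assert_array_equal(once.reflectance, twice.reflectance)

    def test_empty_range_errors(self, small_spectra):
        with pytest.raises(ValueError, match="no channel"):
            trim_to_effective_range(small_spectra, 100.0, 200.0)


class TestAverageReplicates:
    def test_identical_replicates_preserved(self):
        s = make_set([[1, 2], [1, 2], [1, 2]], ids=("a_r1", "a_r2", "a_r3"))
        out = average_replicates(s, replicate_groups(s.sample_ids))
        assert out.sample_ids == ("a",)
        np.testing.assert_array_equal(out.reflectance, [[1, 2]])

    def test_forced_mean(self):
        s = make_set([[1, 1], [3, 3]], ids=("a_r1", "a_r2"))
        out = average_replicates(s, {"a_r1": "a", "a_r2": "a"})
        np.testing.assert_array_equal(out.reflectance, [[2, 2]])

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(0)
        matrix = rng.uniform(size=(9, 4))
        ids = tuple(f"g{i % 3}_r{i // 3}" for i in range(9))
        s = make_set(matrix, ids=ids)
        gm = {sid: sid.split("_")[0] for sid in ids}
        out = average_replicates(s, gm)
        for gi, gid in enumerate(out.sample_ids):
            rows = [i for i, sid in enumerate(ids) if gm[sid] == gid]
            expected = sum(matrix[i] for i in rows) / len(rows)
            np.testing.assert_allclose(out.reflectance[gi], expected)

    def test_singleton_groups_identity(self, small_spectra):
        out = average_replicates(small_spectra,
                                 {s: s for s in small_spectra.sample_ids})
        np.testing.assert_array_equal(out.reflectance,
                                      small_spectra.reflectance)

    def test_unmapped_replicate_errors(self, small_spectra):
        with pytest.raises(ValueError, match="without a group"):
            average_replicates(small_spectra, {})


class TestComputeScc:
    def test_zero_stone_mass(self):
        assert compute_scc(SccMeasurement(1.0, 1.0, 50.0)) == 0.0

    def test_forced_arithmetic(self):
        assert compute_scc(SccMeasurement(1.5, 1.0, 100.0)) == pytest.approx(0.5)

    def test_negative_stone_mass_rejected(self):
        with pytest.raises(ValueError, match="negative stone mass"):
            SccMeasurement(0.9, 1.0, 50.0)

    def test_random_triples_match_formula(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            mf = rng.uniform(0.5, 2.0)
            mt = mf + rng.uniform(0.0, 1.0)
            mp = rng.uniform(10.0, 200.0)
            expected = (mt - mf) / mp * 100.0
            assert compute_scc(SccMeasurement(mt, mf, mp)) == pytest.approx(
                expected, abs=1e-12)

    @given(st.floats(0.5, 2.0), st.floats(0.0, 1.0), st.floats(10.0, 200.0),
           st.floats(0.1, 10.0))
    @settings(max_examples=50, deadline=None)
    def test_homogeneous_in_masses(self, mf, stone, mp, scale):
        base = compute_scc(SccMeasurement(mf + stone, mf, mp))
        scaled = compute_scc(
            SccMeasurement(scale * (mf + stone), scale * mf, scale * mp))
        assert scaled == pytest.approx(base, rel=1e-9, abs=1e-9)


class TestSummarize:
    def test_forced_statistics(self):
        s = summarize_reference(np.array([0.4, 0.5, 0.6]))
        assert (s.n, s.min, s.max) == (3, 0.4, 0.6)
        assert s.mean == pytest.approx(0.5)
        assert s.sd == pytest.approx(0.1)

    def test_single_value_flags_degenerate_sd(self):
        with pytest.warns(UserWarning, match="SD"):
            s = summarize_reference(np.array([0.5]))
        assert s.sd == 0.0 and s.sd_degenerate

    def test_matches_numpy(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0.2, 0.7, size=90)
        s = summarize_reference(x)
        assert s.mean == pytest.approx(np.mean(x))
        assert s.sd == pytest.approx(np.std(x, ddof=1))


class TestAnova:
    def test_identical_groups(self):
        res = anova_two_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res["F"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)

    def test_f_equals_t_squared(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=12), rng.normal(0.5, size=8)
        res = anova_two_groups(a, b)
        t, _ = stats.ttest_ind(a, b)
        assert res["F"] == pytest.approx(t ** 2, rel=1e-10)

    def test_p_matches_f_cdf(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=90), rng.normal(0.2, size=30)
        res = anova_two_groups(a, b)
        expected = stats.f.sf(res["F"], 1, 118)
        assert res["p"] == pytest.approx(expected, abs=1e-8)

    def test_symmetric_in_group_order(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=10), rng.normal(size=15)
        r1, r2 = anova_two_groups(a, b), anova_two_groups(b, a)
        assert r1["F"] == pytest.approx(r2["F"])
        assert 0.0 <= r1["p"] <= 1.0

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            anova_two_groups([1.0], [1.0, 2.0])
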