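"""Spectrum I/O, peak matching, cosine similarity, collision-energy merging."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from molconf import (
    Peak,
    Spectrum,
    cosine_score,
    match_peaks,
    merge_spectra,
    read_mgf,
    write_mgf,
)
from conftest import random_spectrum


class TestSpectrumModel:
    def test_peaks_sorted_and_validated(self):
        s = Spectrum(id="x", peaks=[Peak(200.0, 1.0), Peak(100.0, 2.0)])
        assert [p.mz for p in s.peaks] == [100.0, 200.0]
        with pytest.raises(ValueError):
            Peak(-5.0, 1.0)
        with pytest.raises(ValueError):
            Peak(100.0, -1.0)
        with pytest.raises(ValueError):
            Spectrum(id="y", peaks=[Peak(100.0, float("nan"))])


class TestMgfRoundTrip:
    def test_empty_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "empty.mgf"
        path.write_text("")
        assert read_mgf(path) == []

    def test_single_block(self, tmp_path):
        path = tmp_path / "one.mgf"
        path.write_text(
            "BEGIN IONS\nTITLE=demo\nPEPMASS=301.1")
        path.write_text(
            "BEGIN IONS\n"
            "TITLE=demo\n"
            "PEPMASS=301.1\n"
            "CHARGE=1+\n"
            "COLLISION_ENERGY=20\n"
            "100.1 10\n150.2 20\n200.3 5\n"
            "END IONS\n"
        )
        spectra = read_mgf(path)
        assert len(spectra) == 1
        s = spectra[0]
        assert len(s) == 3
        assert s.precursor_mz == pytest.approx(301.1)
        assert s.collision_energy == 20.0
        assert s.id == "demo"

    def test_round_trip_50_random_spectra(self, tmp_path, rng):
        spectra = [
            random_spectrum(rng, n_peaks=int(rng.integers(2, 30)), spectrum_id=f"s{i}")
            for i in range(50)
        ]
        path = tmp_path / "round.mgf"
        write_mgf(spectra, path)
        back = read_mgf(path)
        assert len(back) == 50
        for orig, rt in zip(spectra, back):
            assert rt.id == orig.id
            np.testing.assert_allclose(rt.mz, orig.mz, atol=1e-6)
            np.testing.assert_allclose(
                rt.intensity / rt.max_intensity,
                orig.intensity / orig.max_intensity,
                rtol=1e-6,
            )
            assert rt.precursor_mz == pytest.approx(orig.precursor_mz, abs=1e-6)
            assert rt.collision_energy == orig.collision_energy


def brute_force_max_matching(a: Spectrum, b: Spectrum, tol_ppm: float) -> int:
    """Maximum-cardinality one-to-one matching by exhaustive search."""
    pairs = [
        (i, j)
        for i in range(len(a))
        for j in range(len(b))
        if abs(a.peaks[i].mz - b.peaks[j].mz)
        <= tol_ppm * 1e-6 * max(a.peaks[i].mz, b.peaks[j].mz)
    ]
    best = 0
    for r in range(len(pairs), 0, -1):
        for combo in itertools.combinations(pairs, r):
            ia = [i for i, _ in combo]
            jb = [j for _, j in combo]
            if len(set(ia)) == r and len(set(jb)) == r:
                return r
    return best


class TestMatchPeaks:
    def test_identical_spectra_fully_matched(self, rng):
        s = random_spectrum(rng)
        pairs = match_peaks(s, s, tol_ppm=7)
        assert pairs == [(i, i) for i in range(len(s))]

    def test_just_outside_seven_ppm_window(self):
        a = Spectrum(id="a", peaks=[Peak(100.000, 1.0)])
        b = Spectrum(id="b", peaks=[Peak(100.001, 1.0)])
        # window is +-0.0007 Da at 100 Da, the 0.001 Da offset is outside
        assert match_peaks(a, b, tol_ppm=7) == []

    def test_matching_is_one_to_one(self):
        a = Spectrum(id="a", peaks=[Peak(100.0000, 1.0), Peak(100.0004, 1.0)])
        b = Spectrum(id="b", peaks=[Peak(100.0002, 1.0)])
        pairs = match_peaks(a, b, tol_ppm=7)
        assert len(pairs) == 1

    @pytest.mark.parametrize("trial", range(20))
    def test_cardinality_equals_brute_force(self, trial):
        rng = np.random.default_rng(1000 + trial)
        a = random_spectrum(rng, n_peaks=5, mz_range=(50, 500), spectrum_id="a")
        b = random_spectrum(rng, n_peaks=5, mz_range=(50, 500), spectrum_id="b")
        got = len(match_peaks(a, b, tol_ppm=2000))  # wide window forces conflicts
        assert got == brute_force_max_matching(a, b, tol_ppm=2000)


class TestCosine:
    def test_self_similarity_is_one(self, rng):
        s = random_spectrum(rng)
        assert cosine_score(s, s) == pytest.approx(1.0)

    def test_disjoint_masses_give_zero(self):
        a = Spectrum.from_arrays([100.0, 200.0], [1.0, 1.0], id="a", precursor_mz=900.0)
        b = Spectrum.from_arrays([150.0, 250.0], [1.0, 1.0], id="b", precursor_mz=900.0)
        assert cosine_score(a, b) == 0.0

    def test_hand_computed_three_peak_value(self):
        a = Spectrum.from_arrays([100.0, 200.0, 300.0], [3.0, 4.0, 0.0001],
                                 id="a", precursor_mz=900.0)
        b = Spectrum.from_arrays([100.0, 200.0, 400.0], [4.0, 3.0, 0.0001],
                                 id="b", precursor_mz=900.0)
        # matches at 100 and 200; intensities L2-normalized per spectrum:
        # (3*4 + 4*3) / (5 * 5) = 24/25
        assert cosine_score(a, b) == pytest.approx(24 / 25, abs=1e-6)

    def test_precursor_peak_excluded(self):
        a = Spectrum.from_arrays([100.0, 500.0], [1.0, 100.0], id="a", precursor_mz=500.0)
        b = Spectrum.from_arrays([100.0, 500.0], [1.0, 100.0], id="b", precursor_mz=500.0)
        with_precursor = cosine_score(a, b, exclude_precursor=False)
        without = cosine_score(a, b, exclude_precursor=True)
        assert with_precursor == pytest.approx(1.0)
        assert without == pytest.approx(1.0)  # only the 100 Da peak remains
        c = Spectrum.from_arrays([110.0, 500.0], [1.0, 100.0], id="c", precursor_mz=500.0)
        assert cosine_score(a, c) == 0.0  # fragment peaks disjoint
        assert cosine_score(a, c, exclude_precursor=False) > 0.9

    def test_both_empty_after_exclusion_raises(self):
        a = Spectrum.from_arrays([500.0], [1.0], id="a", precursor_mz=500.0)
        with pytest.raises(ValueError):
            cosine_score(a, a)

    def test_symmetric_and_bounded_property(self):
        """Symmetry and [0,1] bounds over 1,000 random spectrum pairs."""
        rng = np.random.default_rng(7)
        for _ in range(1000):
            a = random_spectrum(rng, n_peaks=int(rng.integers(1, 12)))
            b = random_spectrum(rng, n_peaks=int(rng.integers(1, 12)))
            sqrt_i = bool(rng.integers(0, 2))
            sab = cosine_score(a, b, sqrt_intensities=sqrt_i)
            sba = cosine_score(b, a, sqrt_intensities=sqrt_i)
            assert 0.0 <= sab <= 1.0
            assert sab == pytest.approx(sba, abs=1e-12)


class TestMerge:
    def test_merge_single_spectrum_keeps_peaks(self, rng):
        s = random_spectrum(rng)
        merged = merge_spectra([s])
        assert merged.collision_energy == "merged"
        assert len(merged) == len(s)
        np.testing.assert_allclose(merged.mz, s.mz, rtol=1e-9)

    def test_identical_masses_combine_intensities(self):
        a = Spectrum.from_arrays([100.0, 200.0], [1.0, 2.0], id="a", precursor_mz=300.0)
        b = Spectrum.from_arrays([100.0, 200.0], [2.0, 4.0], id="b", precursor_mz=300.0)
        merged = merge_spectra([a, b])
        assert len(merged) == 2
        # per-spectrum normalization to max 1, then summed per cluster
        np.testing.assert_allclose(merged.intensity, [1.0, 2.0])

    def test_every_output_peak_traceable(self, rng):
        spectra = [
            random_spectrum(rng, n_peaks=8, spectrum_id=f"e{i}") for i in range(3)
        ]
        merged = merge_spectra(spectra)
        all_input_mz = np.concatenate([s.mz for s in spectra])
        for p in merged.peaks:
            assert np.any(np.abs(all_input_mz - p.mz) <= 7e-6 * all_input_mz.max())

    def test_empty_input_and_precursor_mismatch(self, rng):
        with pytest.raises(ValueError):
            merge_spectra([])
        a = random_spectrum(rng, spectrum_id="a")
        b = Spectrum.from_arrays([100.0], [1.0], id="b", precursor_mz=2 * a.precursor_mz)
        with pytest.raises(ValueError):
            merge_spectra([a, b])
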