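"""Spectrum I/O, fragment generation, annotation, summing and SNR."""

import numpy as np
import pytest

from ivoryid.massdigest import (
    MONOISOTOPIC_RESIDUE_MASSES,
    PROTON,
    Peptidoform,
    WATER,
    monoisotopic_mass,
    parse_modform,
)
from ivoryid.spectra import (
    NH3,
    Run,
    Spectrum,
    ToleranceConfig,
    annotate,
    average_spectra,
    read_mgf,
    read_mzml,
    snr,
    sum_spectra,
    theoretical_fragments,
    write_mgf,
    write_mzml,
)


def make_spectrum(mz, intensity, **kw):
    return Spectrum(np.asarray(mz, float), np.asarray(intensity, float), **kw)


class TestSpectrumInvariants:
    def test_peaks_sorted_and_merged(self):
        s = make_spectrum([300.0, 100.0, 100.0], [1.0, 2.0, 3.0])
        assert list(s.mz) == [100.0, 300.0]
        assert list(s.intensity) == [5.0, 1.0]
        assert np.all(np.diff(s.mz) > 0)

    def test_ms2_requires_precursor(self):
        with pytest.raises(ValueError):
            make_spectrum([100.0], [1.0], ms_level=2)

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            make_spectrum([100.0], [-1.0])


class TestFileRoundTrips:
    def make_run(self):
        spectra = [
            make_spectrum([400.1, 500.2, 600.3], [10.0, 20.0, 5.0], rt=12.0, native_id="s1"),
            make_spectrum(
                [150.0, 250.0], [3.0, 7.0],
                ms_level=2, rt=13.0, precursor_mz=500.2, precursor_charge=2, native_id="s2",
            ),
            make_spectrum(
                [120.0], [4.0],
                ms_level=3, rt=14.0, precursor_mz=250.0, precursor_charge=1, native_id="s3",
            ),
        ]
        return Run(spectra, "roundtrip")

    def test_mgf_round_trip_preserves_everything(self, tmp_path):
        run = self.make_run()
        path = tmp_path / "run.mgf"
        write_mgf(run, path)
        back = read_mgf(path)
        assert len(back) == len(run)
        for a, b in zip(run.spectra, back.spectra):
            assert np.allclose(a.mz, b.mz, atol=1e-5)
            assert np.allclose(a.intensity, b.intensity, rtol=1e-6)
            assert a.ms_level == b.ms_level
            assert a.rt == pytest.approx(b.rt)
            if a.ms_level >= 2:
                assert b.precursor_mz == pytest.approx(a.precursor_mz)

    def test_mzml_round_trip(self, tmp_path):
        run = self.make_run()
        path = tmp_path / "run.mzML"
        write_mzml(run, path)
        back = read_mzml(path)
        assert len(back) == 3
        for a, b in zip(run.spectra, back.spectra):
            assert np.allclose(a.mz, b.mz)
            assert a.ms_level == b.ms_level
            assert b.rt == pytest.approx(a.rt)
        assert back.spectra[1].precursor_mz == pytest.approx(500.2)
        assert back.spectra[1].precursor_charge == 2

    def test_empty_mgf_gives_empty_run(self, tmp_path):
        path = tmp_path / "empty.mgf"
        path.write_text("")
        assert len(read_mgf(path)) == 0

    def test_synthetic_run_rt_nondecreasing(self, tmp_path, toy_db, toy_config):
        from ivoryid.synth import simulate_run

        db, truth = toy_db
        run, _ = simulate_run(db, truth, toy_config)
        rts = [s.rt for s in run.spectra]
        assert rts == sorted(rts)
        path = tmp_path / "synth.mgf"
        write_mgf(run, path)
        assert len(read_mgf(path)) == len(run)


class TestTheoreticalFragments:
    def test_b1_of_gk_is_glycine_plus_proton(self):
        frags = {
            (f.series, f.index): f.theoretical_mz
            for f in theoretical_fragments(Peptidoform("GK"), ("b", "y"))
        }
        assert frags[("b", 1)] == pytest.approx(57.021464 + PROTON, abs=1e-4)

    def test_b_y_complementarity(self):
        pf = Peptidoform("GPAGPK")
        n = len(pf.sequence)
        mh = monoisotopic_mass(pf) + PROTON
        frags = {
            (f.series, f.index): f.theoretical_mz
            for f in theoretical_fragments(pf, ("b", "y"))
        }
        for i in range(1, n):
            assert frags[("b", i)] + frags[("y", n - i)] == pytest.approx(
                mh + PROTON, abs=1e-9
            )

    def test_c_z_radical_complementarity(self):
        pf = Peptidoform("GPAGPK")
        n = len(pf.sequence)
        frags = {
            (f.series, f.index): f.theoretical_mz
            for f in theoretical_fragments(pf, ("c", "z_radical"))
        }
        neutral = monoisotopic_mass(pf)
        for i in range(1, n):
            total = frags[("c", i)] + frags[("z_radical", n - i)]
            assert total == pytest.approx(neutral + 1.007825 + 2 * PROTON, abs=1e-9)

    def test_modifications_shift_containing_fragments_only(self):
        plain = theoretical_fragments(Peptidoform("GPAGK"), ("b",))
        modded = theoretical_fragments(Peptidoform("GPAGK", ((2, "oxidation"),)), ("b",))
        deltas = [m.theoretical_mz - p.theoretical_mz for p, m in zip(plain, modded)]
        assert deltas[0] == pytest.approx(0.0, abs=1e-9)  # b1 excludes position 2
        assert all(d == pytest.approx(15.994915, abs=1e-6) for d in deltas[1:])

    def test_fragments_fit_acquisition_range(self):
        pf = parse_modform("GPP(+15.99)GESGAAGPTGAIGNR")
        for f in theoretical_fragments(pf, ("b", "y"), max_charge=2):
            assert f.theoretical_mz <= 2000.0
            if f.charge == 1:
                assert f.theoretical_mz >= 50.0

    def test_unsupported_series_rejected(self):
        with pytest.raises(ValueError):
            theoretical_fragments(Peptidoform("GK"), ("a",))


class TestAnnotate:
    def spectrum_with_ions(self, pf, series=("b", "y"), subset=None, noise=()):
        frags = theoretical_fragments(pf, series)
        if subset is not None:
            frags = [f for f in frags if (f.series, f.index) in subset]
        mzs = [f.theoretical_mz for f in frags] + list(noise)
        return make_spectrum(
            mzs, np.full(len(mzs), 100.0),
            ms_level=2, precursor_mz=1.0 + monoisotopic_mass(pf) / 2, precursor_charge=2,
        )

    def test_complete_ion_series_gives_full_coverage(self):
        pf = Peptidoform("GPAGPKGR")
        ann = annotate(self.spectrum_with_ions(pf), pf)
        assert ann.backbone_coverage == pytest.approx(1.0)

    def test_empty_spectrum_gives_zero_coverage(self):
        pf = Peptidoform("GPAGPKGR")
        s = make_spectrum([1500.0], [5.0], ms_level=2, precursor_mz=400.0)
        assert annotate(s, pf).backbone_coverage == 0.0

    def test_half_y_series_coverage_fraction(self):
        pf = Peptidoform("GPAGPKGR")
        n = len(pf.sequence)
        half = {("y", j) for j in range(1, n // 2 + 1)}
        ann = annotate(self.spectrum_with_ions(pf, subset=half), pf)
        assert ann.backbone_coverage == pytest.approx((n // 2) / (n - 1))

    def test_coverage_monotone_in_tolerance(self):
        pf = Peptidoform("GPAGPKGR")
        frags = theoretical_fragments(pf, ("b", "y"))
        shifted = [f.theoretical_mz + 0.015 for f in frags]
        s = make_spectrum(
            shifted, np.full(len(shifted), 10.0), ms_level=2, precursor_mz=500.0
        )
        loose = annotate(s, pf, ToleranceConfig(fragment_da=0.02)).backbone_coverage
        tight = annotate(s, pf, ToleranceConfig(fragment_da=0.005)).backbone_coverage
        assert tight <= loose
        assert loose == pytest.approx(1.0)

    def test_precursor_mismatch_sets_warning_not_failure(self):
        pf = Peptidoform("GPAGPKGR", charge=2)
        s = self.spectrum_with_ions(pf)
        s.precursor_mz += 1.0  # way off
        ann = annotate(s, pf)
        assert ann.precursor_warning
        assert ann.backbone_coverage > 0


class TestSumming:
    def test_triplicate_sum_preserves_mz_and_triples_intensity(self):
        s = make_spectrum([100.0, 200.0, 300.0], [1.0, 2.0, 3.0])
        summed = sum_spectra([s, s, s])
        assert np.allclose(summed.mz, s.mz)
        assert np.allclose(summed.intensity, 3 * s.intensity)

    def test_single_spectrum_identity(self):
        s = make_spectrum([100.0, 200.0], [1.0, 2.0])
        summed = sum_spectra([s])
        assert np.allclose(summed.mz, s.mz) and np.allclose(summed.intensity, s.intensity)

    def test_total_ion_current_conserved(self, rng):
        spectra = [
            make_spectrum(np.sort(rng.uniform(100, 1000, 50)), rng.uniform(1, 100, 50))
            for _ in range(5)
        ]
        summed = sum_spectra(spectra)
        assert summed.total_ion_current == pytest.approx(
            sum(s.total_ion_current for s in spectra), rel=1e-12
        )

    def test_mixed_ms_levels_rejected(self):
        s1 = make_spectrum([100.0], [1.0])
        s2 = make_spectrum([100.0], [1.0], ms_level=2, precursor_mz=400.0)
        with pytest.raises(ValueError):
            sum_spectra([s1, s2])

    def test_snr_grows_like_sqrt_n(self, rng):
        """Summing n replicates: planted peak adds coherently (x n) while
        the noise floor median grows slower, so SNR improves ~ sqrt(n)."""
        target = 500.0

        def replicate():
            noise_mz = rng.uniform(target - 10, target + 10, 200)
            noise_int = np.abs(rng.normal(0, 10, 200))
            return make_spectrum(
                np.append(noise_mz, target), np.append(noise_int, 40.0)
            )

        ratios = []
        for _ in range(10):
            one = replicate()
            many = sum_spectra([replicate() for _ in range(9)], bin_tolerance=0.01)
            ratios.append(snr(many, target, 0.01) / max(snr(one, target, 0.01), 1e-9))
        # expected gain ~ sqrt(9) = 3; accept a broad band around it
        assert 1.5 < np.median(ratios)

    def test_averaging_is_identity_on_replicates(self):
        s = make_spectrum([100.0, 200.0], [4.0, 8.0])
        avg = average_spectra([s, s, s, s])
        assert np.allclose(avg.mz, s.mz) and np.allclose(avg.intensity, s.intensity)


class TestSnr:
    def test_peak_over_flank_median(self):
        s = make_spectrum([499.0, 499.5, 500.0, 500.5, 501.0], [10.0, 10.0, 100.0, 10.0, 10.0])
        assert snr(s, 500.0, 0.02) == pytest.approx(10.0)

    def test_lone_peak_uses_noise_floor(self):
        s = make_spectrum([500.0], [42.0])
        assert snr(s, 500.0, 0.02) == pytest.approx(42.0)

    def test_absent_peak_gives_zero(self):
        s = make_spectrum([490.0], [10.0])
        assert snr(s, 500.0, 0.02) == 0.0
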