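"""MS3 diagnostic-loss Leu/Ile discrimination."""

import numpy as np
import pytest

from ivoryid.ilcall import (
    ILE_LOSS,
    LEU_LOSS,
    ZIonTarget,
    average_ms3,
    call_il,
    z_target_for_residue,
)
from ivoryid.massdigest import Peptidoform
from ivoryid.spectra import Spectrum, theoretical_fragments


def make_ms3(target, losses, rng=None, noise_peaks=0, noise_scale=10.0, intensities=None):
    """Synthetic MS3 spectrum: residual precursor + requested loss peaks
    (+ optional uniform noise)."""
    mzs = [target.theoretical_z_mz]
    ints = [500.0]
    for i, (loss, intensity) in enumerate(losses):
        mzs.append(target.theoretical_z_mz - loss / target.z_charge)
        ints.append(intensity)
    if noise_peaks and rng is not None:
        diagnostic = np.array(
            [target.theoretical_z_mz - ILE_LOSS / target.z_charge,
             target.theoretical_z_mz - LEU_LOSS / target.z_charge]
        )
        candidates = rng.uniform(
            target.theoretical_z_mz - 60, target.theoretical_z_mz - 1, noise_peaks
        )
        heights = np.abs(rng.normal(0, noise_scale, noise_peaks))
        # keep noise out of both diagnostic windows so planted-loss truth
        # stays the only signal there
        clear = np.all(np.abs(candidates[:, None] - diagnostic[None, :]) > 0.1, axis=1)
        mzs += list(candidates[clear])
        ints += list(heights[clear])
    return Spectrum(
        np.array(mzs), np.array(ints), ms_level=3,
        precursor_mz=target.theoretical_z_mz, precursor_charge=target.z_charge,
    )


class TestZTarget:
    def test_terminal_residue_gives_z1(self):
        pf = Peptidoform("GPAGAI")
        target = z_target_for_residue(pf, 6)
        assert target.z_index == 1

    @pytest.mark.parametrize("pos", [2, 4, 5])
    def test_index_is_length_minus_position_plus_one(self, pos):
        pf = Peptidoform("GIAILK")
        assert z_target_for_residue(pf, pos).z_index == len(pf.sequence) - pos + 1

    def test_co_sequence_peptidoforms_share_z_index(self):
        """Peptidoforms of one sequence differing only in modifications
        interrogate the same residue through the same z index."""
        base = "GPNGPIGPR"
        forms = [
            Peptidoform(base),
            Peptidoform(base, ((2, "oxidation"),)),
            Peptidoform(base, ((2, "oxidation"), (3, "deamidation"))),
        ]
        pos = 6  # the Ile
        targets = [z_target_for_residue(pf, pos) for pf in forms]
        assert {t.z_index for t in targets} == {len(base) - pos + 1}

    def test_z_mz_matches_fragment_table(self):
        pf = Peptidoform("GPAGAIGPK")
        target = z_target_for_residue(pf, 6, charge=1)
        table = {
            (f.index, f.charge): f.theoretical_mz
            for f in theoretical_fragments(pf, ("z_radical",))
        }
        assert target.theoretical_z_mz == pytest.approx(table[(target.z_index, 1)])

    def test_non_il_residue_rejected(self):
        with pytest.raises(ValueError):
            z_target_for_residue(Peptidoform("GPAGK"), 2)


class TestAveraging:
    def test_replicate_average_is_identity(self):
        pf = Peptidoform("GPAGAI")
        target = z_target_for_residue(pf, 6)
        s = make_ms3(target, [(ILE_LOSS, 100.0)])
        avg = average_ms3([s] * 5)
        assert np.allclose(avg.mz, s.mz) and np.allclose(avg.intensity, s.intensity)

    def test_single_spectrum_identity(self):
        pf = Peptidoform("GPAGAI")
        target = z_target_for_residue(pf, 6)
        s = make_ms3(target, [(ILE_LOSS, 100.0)])
        avg = average_ms3([s])
        assert np.allclose(avg.intensity, s.intensity)

    def test_noise_shrinks_like_inverse_sqrt_n(self, rng):
        """Peak-height scatter of averaged iid replicates shrinks ~1/sqrt(5)."""
        base_mz = np.arange(300.0, 310.0, 1.0)

        def noisy():
            return Spectrum(
                base_mz, 100.0 + rng.normal(0, 20.0, base_mz.size),
                ms_level=3, precursor_mz=400.0,
            )

        single_sd = np.std([noisy().intensity[0] for _ in range(200)])
        avg_sd = np.std(
            [average_ms3([noisy() for _ in range(5)]).intensity[0] for _ in range(200)]
        )
        assert avg_sd == pytest.approx(single_sd / np.sqrt(5), rel=0.35)

    def test_inconsistent_precursors_rejected(self):
        a = Spectrum(np.array([100.0]), np.array([1.0]), ms_level=3, precursor_mz=400.0)
        b = Spectrum(np.array([100.0]), np.array([1.0]), ms_level=3, precursor_mz=405.0)
        with pytest.raises(ValueError):
            average_ms3([a, b])


class TestCallIl:
    def target(self):
        return z_target_for_residue(Peptidoform("GPAGAIGPK"), 6)

    def test_planted_29_loss_called_isoleucine(self, rng):
        s = make_ms3(self.target(), [(ILE_LOSS, 200.0)], rng, noise_peaks=20)
        assert call_il(s, self.target()).call == "Ile"

    def test_planted_43_loss_called_leucine(self, rng):
        s = make_ms3(self.target(), [(LEU_LOSS, 200.0)], rng, noise_peaks=20)
        assert call_il(s, self.target()).call == "Leu"

    def test_equal_losses_ambiguous(self):
        s = make_ms3(self.target(), [(ILE_LOSS, 100.0), (LEU_LOSS, 100.0)])
        assert call_il(s, self.target()).call == "ambiguous"

    def test_no_loss_peaks_is_no_signal(self):
        s = make_ms3(self.target(), [])
        assert call_il(s, self.target()).call == "no_signal"

    def test_weak_dominance_is_ambiguous(self):
        s = make_ms3(self.target(), [(ILE_LOSS, 120.0), (LEU_LOSS, 100.0)])
        result = call_il(s, self.target())
        assert result.call == "ambiguous" and result.score == pytest.approx(1.2)

    def test_relabeling_losses_flips_calls_with_identical_scores(self, rng):
        """Perfect Ile<->Leu symmetry under 29<->43 relabeling."""
        target = self.target()
        for _ in range(20):
            intensity = float(rng.uniform(150, 400))
            seed = int(rng.integers(0, 2**31))
            r1 = np.random.default_rng(seed)
            r2 = np.random.default_rng(seed)
            as_ile = call_il(
                make_ms3(target, [(ILE_LOSS, intensity)], r1, noise_peaks=15), target
            )
            as_leu = call_il(
                make_ms3(target, [(LEU_LOSS, intensity)], r2, noise_peaks=15), target
            )
            assert {as_ile.call, as_leu.call} <= {"Ile", "Leu", "ambiguous"}
            if as_ile.call == "Ile":
                assert as_leu.call == "Leu"
                assert as_leu.score == pytest.approx(as_ile.score)

    def test_ms2_spectrum_rejected(self):
        s = Spectrum(np.array([100.0]), np.array([1.0]), ms_level=2, precursor_mz=400.0)
        with pytest.raises(ValueError):
            call_il(s, self.target())

    def test_averaging_cannot_invent_signal(self):
        target = self.target()
        empties = [make_ms3(target, []) for _ in range(5)]
        assert all(call_il(s, target).call == "no_signal" for s in empties)
        assert call_il(average_ms3(empties), target).call == "no_signal"
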