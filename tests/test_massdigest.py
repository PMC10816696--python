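"""Digestion and mass arithmetic against independent oracles.

The digest is checked against a brute-force substring enumeration; the
mass arithmetic is cross-checked against pyteomics, an implementation
we do not share code with.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pyteomics import mass as pyteomics_mass

from ivoryid.massdigest import (
    CleavageRule,
    DEAMIDATION,
    MONOISOTOPIC_RESIDUE_MASSES,
    OXIDATION,
    PROTON,
    Peptidoform,
    WATER,
    digest,
    enumerate_peptidoforms,
    format_modform,
    monoisotopic_mass,
    mz,
    parse_modform,
    ppm_error,
)


def brute_force_digest(sequence, rule, min_length=1, max_length=None):
    """Independent oracle: test every substring against the terminus and
    missed-cleavage predicates directly."""
    n = len(sequence)
    sites = {
        i
        for i in range(n - 1)
        if sequence[i] in rule.cut_after and sequence[i + 1] not in rule.blocked_before
    }

    def enzymatic_start(s):
        return s == 0 or (s - 1) in sites

    def enzymatic_end(e):
        return e == n or (e - 1) in sites

    out = {}
    for s in range(n):
        for e in range(s + 1, n + 1):
            if e - s < min_length or (max_length is not None and e - s > max_length):
                continue
            missed = sum(1 for i in range(s, e - 1) if i in sites)
            if missed > rule.max_missed:
                continue
            n_enz = enzymatic_start(s) + enzymatic_end(e)
            if rule.specificity == "full" and n_enz == 2:
                out[(s, e)] = missed
            elif rule.specificity == "semi" and n_enz >= 1:
                out[(s, e)] = missed
    return out


class TestDigest:
    def test_tryptic_cuts_with_proline_block(self):
        rule = CleavageRule(specificity="full", max_missed=0)
        peptides = {p.sequence for p in digest("GPKGPRGAAG", rule)}
        assert peptides == {"GPK", "GPR", "GAAG"}

    def test_missed_cleavages_add_joined_peptides(self):
        rule = CleavageRule(specificity="full", max_missed=1)
        peptides = {p.sequence for p in digest("GPKGPRGAAG", rule)}
        assert peptides == {"GPK", "GPR", "GAAG", "GPKGPR", "GPRGAAG"}

    def test_long_collagen_peptide_has_one_missed_cleavage(self):
        # R followed by G is a tryptic site; the internal R before G makes
        # this marker a 1-missed-cleavage product of its chain
        seq = "GAPGAIGAPGPAGANGDRGEAGPAGPAGPAGPR"
        chain = "K" + seq + "G"  # embed with enzymatic boundaries
        rule = CleavageRule(specificity="semi", max_missed=3)
        hits = [p for p in digest(chain, rule) if p.sequence == seq]
        assert hits and hits[0].missed_cleavages == 1

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            digest("", CleavageRule())

    @pytest.mark.parametrize("specificity", ["full", "semi"])
    @pytest.mark.parametrize("max_missed", [0, 2])
    def test_matches_brute_force_on_random_sequences(self, specificity, max_missed, rng):
        residues = np.array(list(MONOISOTOPIC_RESIDUE_MASSES))
        rule = CleavageRule(specificity=specificity, max_missed=max_missed)
        for _ in range(25):
            n = int(rng.integers(1, 120))
            seq = "".join(rng.choice(residues, size=n))
            expected = brute_force_digest(seq, rule)
            got = {(p.start, p.end): p.missed_cleavages for p in digest(seq, rule)}
            assert got == expected

    def test_zero_missed_full_peptides_tile_the_sequence(self, rng):
        residues = np.array(list(MONOISOTOPIC_RESIDUE_MASSES))
        rule = CleavageRule(specificity="full", max_missed=0)
        seq = "".join(rng.choice(residues, size=80))
        peptides = sorted(digest(seq, rule), key=lambda p: p.start)
        assert "".join(p.sequence for p in peptides) == seq

    def test_length_bounds_respected(self):
        rule = CleavageRule(specificity="semi", max_missed=3)
        for p in digest("GPKGPRGAAGQRGPAGPK" * 3, rule, min_length=6, max_length=10):
            assert 6 <= len(p.sequence) <= 10


class TestPeptidoformEnumeration:
    def test_one_oxidation_and_one_deamidation_site(self):
        forms = enumerate_peptidoforms("GPNGK", (OXIDATION, DEAMIDATION), 5)
        mods = {f.mods for f in forms}
        assert mods == {
            (),
            ((2, "oxidation"),),
            ((3, "deamidation"),),
            ((2, "oxidation"), (3, "deamidation")),
        }

    def test_unmodifiable_peptide_yields_base_form_only(self):
        forms = enumerate_peptidoforms("GAVGK", (OXIDATION, DEAMIDATION), 5)
        assert len(forms) == 1 and forms[0].mods == ()

    def test_variable_cap_limits_combinations(self):
        forms = enumerate_peptidoforms("GPPGK", (OXIDATION,), 1)
        assert {f.mods for f in forms} == {(), ((2, "oxidation"),), ((3, "oxidation"),)}

    @pytest.mark.parametrize("seq,cap", [("GPPNQK", 2), ("GMPNK", 3), ("GAVGK", 5)])
    def test_count_matches_closed_form(self, seq, cap):
        sites = [
            (i, m.name)
            for m in (OXIDATION, DEAMIDATION)
            for i, r in enumerate(seq, 1)
            if r in m.targets
        ]
        expected = sum(
            1
            for k in range(min(cap, len(sites)) + 1)
            for combo in itertools.combinations(sites, k)
            if len({p for p, _ in combo}) == len(combo)
        )
        assert len(enumerate_peptidoforms(seq, (OXIDATION, DEAMIDATION), cap)) == expected

    def test_mod_on_wrong_residue_rejected(self):
        with pytest.raises(ValueError):
            Peptidoform("GAVGK", ((2, "oxidation"),))


class TestMassArithmetic:
    def test_single_glycine_mz(self):
        assert mz("G", 1) == pytest.approx(57.021464 + WATER + PROTON, abs=1e-4)

    def test_mass_additivity_over_any_split(self, rng):
        residues = np.array(list(MONOISOTOPIC_RESIDUE_MASSES))
        seq = "".join(rng.choice(residues, size=30))
        for cut in (1, 10, 29):
            left, right = seq[:cut], seq[cut:]
            assert monoisotopic_mass(seq) == pytest.approx(
                monoisotopic_mass(left) + monoisotopic_mass(right) - WATER, abs=1e-9
            )

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        st.text(alphabet=sorted(MONOISOTOPIC_RESIDUE_MASSES), min_size=1, max_size=40),
        st.integers(min_value=1, max_value=6),
    )
    def test_agrees_with_pyteomics(self, seq, z):
        ours = monoisotopic_mass(seq)
        theirs = pyteomics_mass.fast_mass(seq)
        assert ours == pytest.approx(theirs, abs=5e-4)
        assert mz(Peptidoform(seq), z) == pytest.approx(
            (theirs + z * PROTON) / z, abs=5e-4
        )

    def test_mz_strictly_decreasing_in_charge(self):
        pf = Peptidoform("GPAGPAGPAGPR")
        values = [mz(pf, z) for z in range(1, 6)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_mz_mass_round_trip(self):
        pf = Peptidoform("GPAGPAGPAGPR")
        m = monoisotopic_mass(pf)
        for z in (1, 2, 3):
            assert mz(pf, z) * z - z * PROTON == pytest.approx(m, abs=1e-9)

    def test_ppm_error_sign_and_scale(self):
        assert ppm_error(1000.001, 1000.0) == pytest.approx(1.0)
        assert ppm_error(999.999, 1000.0) == pytest.approx(-1.0)


class TestModformNotation:
    def test_parse_positions_and_names(self):
        pf = parse_modform("GAP(+15.99)GAN(+0.98)GDR")
        assert pf.sequence == "GAPGANGDR"
        assert pf.mods == ((3, "oxidation"), (6, "deamidation"))

    def test_round_trip(self):
        s = "GAP(+15.99)GAIGAP(+15.99)GPAGAN(+0.98)GDRGEAGPAGPAGPAGPR"
        assert format_modform(parse_modform(s)) == s

    def test_unknown_shift_rejected(self):
        with pytest.raises(ValueError):
            parse_modform("GAP(+12.34)GK")
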