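"""In-silico proteolysis and peptide mass arithmetic.

Monoisotopic residue masses, tryptic digestion (full and semi-specific,
with missed cleavages), enumeration of modified peptidoforms, and the
m/z and ppm arithmetic every downstream module relies on.

Mass conventions: monoisotopic masses throughout; peptides are charged
by proton attachment (1.0072765 Da per charge), not hydrogen atoms.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

__all__ = [
    "MONOISOTOPIC_RESIDUE_MASSES",
    "WATER",
    "PROTON",
    "ISOTOPE_SPACING",
    "ModificationSpec",
    "CARBAMIDOMETHYL",
    "OXIDATION",
    "DEAMIDATION",
    "DEFAULT_MODIFICATIONS",
    "CleavageRule",
    "TRYPSIN_SEMI",
    "Peptide",
    "Peptidoform",
    "digest",
    "enumerate_peptidoforms",
    "monoisotopic_mass",
    "mz",
    "ppm_error",
    "parse_modform",
    "format_modform",
]

#: Monoisotopic masses of the 20 canonical amino-acid residues (Da),
#: i.e. the mass contributed inside a peptide chain (free amino acid
#: minus water).
MONOISOTOPIC_RESIDUE_MASSES: dict[str, float] = {
    "G": 57.021464,
    "A": 71.037114,
    "S": 87.032028,
    "P": 97.052764,
    "V": 99.068414,
    "T": 101.047678,
    "C": 103.009185,
    "L": 113.084064,
    "I": 113.084064,
    "N": 114.042927,
    "D": 115.026943,
    "Q": 128.058578,
    "K": 128.094963,
    "E": 129.042593,
    "M": 131.040485,
    "H": 137.058912,
    "F": 147.068414,
    "R": 156.101111,
    "Y": 163.063329,
    "W": 186.079313,
}

WATER = 18.010565
PROTON = 1.0072765
#: Average mass spacing of the C isotope envelope per charge unit.
ISOTOPE_SPACING = 1.00335


@dataclass(frozen=True)
class ModificationSpec:
    """A named mass shift applicable to a set of target residues."""

    name: str
    targets: frozenset[str]
    delta: float
    kind: str = "variable"  # "fixed" | "variable"

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError(f"modification {self.name!r} has no target residues")
        if self.kind not in ("fixed", "variable"):
            raise ValueError(f"unknown modification kind {self.kind!r}")


CARBAMIDOMETHYL = ModificationSpec("carbamidomethyl", frozenset("C"), 57.021464, "fixed")
OXIDATION = ModificationSpec("oxidation", frozenset("MP"), 15.994915, "variable")
DEAMIDATION = ModificationSpec("deamidation", frozenset("NQ"), 0.984016, "variable")

#: The default search space: fixed carbamidomethylation of cysteine,
#: variable oxidation/hydroxylation of Met and Pro (hydroxyproline is
#: mass-equivalent to oxidized proline) and variable deamidation of
#: Asn and Gln.
DEFAULT_MODIFICATIONS: tuple[ModificationSpec, ...] = (
    CARBAMIDOMETHYL,
    OXIDATION,
    DEAMIDATION,
)

MOD_BY_NAME: dict[str, ModificationSpec] = {m.name: m for m in DEFAULT_MODIFICATIONS}


@dataclass(frozen=True)
class CleavageRule:
    """Protease specificity.

    ``cut_after``/``blocked_before`` encode the classic trypsin rule
    (cleave C-terminal to K/R except before P); ``specificity`` is
    "full" or "semi" (exactly one terminus may be non-enzymatic);
    ``max_missed`` caps uncut internal sites.
    """

    cut_after: frozenset[str] = frozenset("KR")
    blocked_before: frozenset[str] = frozenset("P")
    specificity: str = "full"
    max_missed: int = 0

    def __post_init__(self) -> None:
        if self.max_missed < 0:
            raise ValueError("max_missed must be >= 0")
        if self.specificity not in ("full", "semi"):
            raise ValueError(f"unknown specificity {self.specificity!r}")

    def cut_sites(self, sequence: str) -> list[int]:
        """0-based positions i such that the bond after residue i is cleavable."""
        sites = []
        for i in range(len(sequence) - 1):
            if sequence[i] in self.cut_after and sequence[i + 1] not in self.blocked_before:
                sites.append(i)
        return sites


#: The search configuration used throughout: semi-specific trypsin with
#: up to three missed cleavages.
TRYPSIN_SEMI = CleavageRule(specificity="semi", max_missed=3)

#: Tryptic collagen markers of interest span roughly 16-33 residues;
#: these bounds keep digests to plausible, identifiable peptides.
DEFAULT_MIN_LENGTH = 6
DEFAULT_MAX_LENGTH = 45


@dataclass(frozen=True)
class Peptide:
    """A digestion product located in its parent sequence (0-based, half-open)."""

    sequence: str
    start: int
    end: int
    missed_cleavages: int
    specificity: str  # "full" | "semi"


def digest(
    sequence: str,
    rule: CleavageRule = TRYPSIN_SEMI,
    min_length: int = 1,
    max_length: int | None = None,
) -> list[Peptide]:
    """Digest ``sequence`` under ``rule``, returning peptides deduplicated
    by (start, end).

    Full-specific peptides run between allowed cut sites (or sequence
    termini) with at most ``rule.max_missed`` internal cleavable bonds.
    Semi-specific digestion additionally yields peptides with exactly
    one non-enzymatic terminus.
    """
    if not sequence:
        raise ValueError("cannot digest an empty sequence")
    n = len(sequence)
    sites = rule.cut_sites(sequence)
    site_set = set(sites)
    # Enzymatic boundaries: peptide start s is enzymatic if s == 0 or the
    # bond before it is cleavable; end e (exclusive) if e == n or the bond
    # after residue e-1 is cleavable.
    starts = [0] + [i + 1 for i in sites]
    ends = [i + 1 for i in sites] + [n]

    out: dict[tuple[int, int], Peptide] = {}

    def missed(s: int, e: int) -> int:
        return sum(1 for i in range(s, e - 1) if i in site_set)

    def keep(s: int, e: int) -> bool:
        length = e - s
        return length >= min_length and (max_length is None or length <= max_length)

    for ai, s in enumerate(starts):
        for e in ends:
            if e <= s:
                continue
            m = missed(s, e)
            if m > rule.max_missed:
                break  # ends are ascending, later ones only add misses
            if keep(s, e):
                out[(s, e)] = Peptide(sequence[s:e], s, e, m, "full")

    if rule.specificity == "semi":
        # one non-enzymatic terminus: enzymatic start with ragged end ...
        enz_starts = set(starts)
        enz_ends = set(ends)
        for s in starts:
            for e in range(s + 1, n + 1):
                if e in enz_ends:
                    continue
                m = missed(s, e)
                if m > rule.max_missed:
                    break
                if keep(s, e):
                    out.setdefault((s, e), Peptide(sequence[s:e], s, e, m, "semi"))
        # ... or ragged start with enzymatic end
        for e in ends:
            for s in range(e - 1, -1, -1):
                if s in enz_starts:
                    continue
                m = missed(s, e)
                if m > rule.max_missed:
                    break
                if keep(s, e):
                    out.setdefault((s, e), Peptide(sequence[s:e], s, e, m, "semi"))

    return sorted(out.values(), key=lambda p: (p.start, p.end))


@dataclass(frozen=True)
class Peptidoform:
    """A peptide sequence with positioned modifications and optional charge.

    ``mods`` is a tuple of (1-based position, modification name) pairs,
    sorted by position. Provenance, when known, records
    (accession, start, end, missed_cleavages) in the source chain.
    """

    sequence: str
    mods: tuple[tuple[int, str], ...] = ()
    charge: int | None = None
    provenance: tuple[str, int, int, int] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "mods", tuple(sorted(self.mods)))
        for pos, name in self.mods:
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(f"mod position {pos} outside peptide of length {len(self.sequence)}")
            spec = MOD_BY_NAME.get(name)
            if spec is not None and self.sequence[pos - 1] not in spec.targets:
                raise ValueError(
                    f"{name} cannot modify {self.sequence[pos - 1]!r} at position {pos}"
                )
        if self.charge is not None and self.charge < 1:
            raise ValueError("charge must be >= 1")

    @property
    def n_variable_mods(self) -> int:
        return sum(1 for _, name in self.mods if MOD_BY_NAME[name].kind == "variable")

    def with_charge(self, z: int) -> "Peptidoform":
        return replace(self, charge=z)


def enumerate_peptidoforms(
    peptide: str | Peptide,
    modifications: Sequence[ModificationSpec] = DEFAULT_MODIFICATIONS,
    max_variable: int = 5,
) -> list[Peptidoform]:
    """All peptidoforms of ``peptide``: fixed mods at every target site,
    variable mods in every combination of at most ``max_variable`` sites."""
    if max_variable < 0:
        raise ValueError("max_variable must be >= 0")
    if isinstance(peptide, Peptide):
        seq = peptide.sequence
        prov = None
    else:
        seq, prov = peptide, None

    fixed: list[tuple[int, str]] = []
    var_sites: list[tuple[int, str]] = []
    for spec in modifications:
        for i, res in enumerate(seq, start=1):
            if res in spec.targets:
                (fixed if spec.kind == "fixed" else var_sites).append((i, spec.name))

    forms = []
    for k in range(min(max_variable, len(var_sites)) + 1):
        for combo in itertools.combinations(var_sites, k):
            # at most one variable mod per site
            if len({pos for pos, _ in combo}) < len(combo):
                continue
            forms.append(Peptidoform(seq, tuple(fixed) + combo, provenance=prov))
    return forms


def monoisotopic_mass(
    pf: Peptidoform | str,
    mod_specs: dict[str, ModificationSpec] | None = None,
) -> float:
    """Neutral monoisotopic mass: residue masses + water + modification deltas."""
    if isinstance(pf, str):
        pf = Peptidoform(pf)
    specs = mod_specs or MOD_BY_NAME
    try:
        mass = sum(MONOISOTOPIC_RESIDUE_MASSES[r] for r in pf.sequence)
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r} in {pf.sequence!r}") from None
    for _, name in pf.mods:
        if name not in specs:
            raise ValueError(f"unknown modification {name!r}")
        mass += specs[name].delta
    return mass + WATER


def mz(pf: Peptidoform | str, z: int | None = None) -> float:
    """m/z of ``pf`` at charge ``z`` (defaults to the peptidoform's charge)."""
    if isinstance(pf, str):
        pf = Peptidoform(pf)
    if z is None:
        z = pf.charge
    if z is None or z < 1:
        raise ValueError("a positive charge is required")
    return (monoisotopic_mass(pf) + z * PROTON) / z


def neutral_mass_from_mz(observed_mz: float, z: int) -> float:
    return observed_mz * z - z * PROTON


def ppm_error(observed: float, theoretical: float) -> float:
    """Relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical mass must be positive")
    return 1e6 * (observed - theoretical) / theoretical


_MODFORM_RE = re.compile(r"([A-Z])(?:\(([+-]\d+(?:\.\d+)?)\))?")


def parse_modform(modform: str) -> Peptidoform:
    """Parse the compact "GAP(+15.99)GAN(+0.98)GDR" notation.

    Each parenthesized delta is resolved to the known modification whose
    mass shift is nearest (oxidation +15.99, deamidation +0.98,
    carbamidomethyl +57.02).
    """
    if not re.fullmatch(f"(?:{_MODFORM_RE.pattern})+", modform):
        raise ValueError(f"malformed peptidoform string: {modform!r}")
    seq_chars: list[str] = []
    mods: list[tuple[int, str]] = []
    for match in _MODFORM_RE.finditer(modform):
        residue, delta = match.group(1), match.group(2)
        seq_chars.append(residue)
        if delta is not None:
            value = float(delta)
            name = min(MOD_BY_NAME, key=lambda n: abs(MOD_BY_NAME[n].delta - value))
            if abs(MOD_BY_NAME[name].delta - value) > 0.05:
                raise ValueError(f"unrecognized mass shift {delta} in {modform!r}")
            mods.append((len(seq_chars), name))
    return Peptidoform("".join(seq_chars), tuple(mods))


def format_modform(pf: Peptidoform, precision: int = 2) -> str:
    """Inverse of :func:`parse_modform` at reporting precision."""
    by_pos = dict(pf.mods)
    parts = []
    for i, res in enumerate(pf.sequence, start=1):
        parts.append(res)
        if i in by_pos:
            delta = MOD_BY_NAME[by_pos[i]].delta
            parts.append(f"({delta:+.{precision}f})")
    return "".join(parts)


def modified_positions(pf: Peptidoform, name: str) -> tuple[int, ...]:
    """1-based positions in ``pf`` carrying the named modification."""
    return tuple(pos for pos, n in pf.mods if n == name)
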