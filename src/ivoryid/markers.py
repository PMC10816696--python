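"""Taxon-specific marker discovery with isobaric-ambiguity controls.

A peptide is a candidate marker for a taxon when it occurs in that
taxon's collagen chains and in no other taxon's. Because collagen is
highly conserved and I/L are isobaric (and deamidated N/Q are
mass-identical to D/E), every candidate is re-searched under relaxed
equivalence schemes; only peptides that stay specific under those
controls are accepted as valid markers.

Matching is exact substring containment over the local database:
tryptic peptides are literal subsequences of their source chain, so no
alignment is needed for the question being asked.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .massdigest import (
    CleavageRule,
    DEFAULT_MAX_LENGTH,
    DEFAULT_MIN_LENGTH,
    Peptidoform,
    TRYPSIN_SEMI,
    digest,
    modified_positions,
)
from .refdb import (
    EXACT,
    FULL_EXPANSION,
    EquivalenceScheme,
    ReferenceDatabase,
    Taxonomy,
)

__all__ = [
    "MarkerAssignment",
    "find_taxa",
    "classify_marker",
    "diff_markers",
    "marker_table",
]


def _match_pattern(
    sequence: str,
    scheme: EquivalenceScheme,
    deamidated_positions: Sequence[int] = (),
) -> re.Pattern:
    """Regex implementing substring matching under an equivalence scheme.

    I/L collapse applies at every position when enabled; the D/E
    expansion applies only at positions actually carrying a deamidation
    in the query peptidoform, mirroring the control of substituting the
    deamidated residue before re-searching.
    """
    deam = set(deamidated_positions)
    parts = []
    for i, res in enumerate(sequence, start=1):
        alternatives = {res}
        if scheme.il_equivalent and res in "IL":
            alternatives.update("IL")
        if scheme.deamidated_n_equals_d and res == "N" and i in deam:
            alternatives.add("D")
        if scheme.deamidated_q_equals_e and res == "Q" and i in deam:
            alternatives.add("E")
        if len(alternatives) == 1:
            parts.append(res)
        else:
            parts.append("[" + "".join(sorted(alternatives)) + "]")
    return re.compile("".join(parts))


def find_taxa(
    peptide: str | Peptidoform,
    db: ReferenceDatabase,
    scheme: EquivalenceScheme = EXACT,
) -> set[str]:
    """Taxa whose records contain ``peptide`` as a substring under ``scheme``."""
    if isinstance(peptide, Peptidoform):
        sequence = peptide.sequence
        deam = modified_positions(peptide, "deamidation")
    else:
        sequence, deam = peptide, ()
    pattern = _match_pattern(sequence, scheme, deam)
    return {rec.taxon for rec in db.records if pattern.search(rec.sequence)}


@dataclass
class MarkerAssignment:
    """Outcome of marker validation for one peptidoform."""

    peptidoform: Peptidoform
    matched_taxa_exact: set[str]
    matched_taxa_expanded: dict[EquivalenceScheme, set[str]]
    specificity_rank: str | None
    lca_taxon: str | None
    valid_marker: bool
    shared_with: list[str] = field(default_factory=list)

    @property
    def all_matched(self) -> set[str]:
        out = set(self.matched_taxa_exact)
        for taxa in self.matched_taxa_expanded.values():
            out |= taxa
        return out


#: The control schemes applied to every candidate marker: the I/L
#: isobaric collapse and the deamidated-N/D, deamidated-Q/E expansions.
DEFAULT_SCHEMES: tuple[EquivalenceScheme, ...] = (
    EquivalenceScheme(il_equivalent=True),
    EquivalenceScheme(deamidated_n_equals_d=True, deamidated_q_equals_e=True),
    FULL_EXPANSION,
)


def classify_marker(
    peptidoform: Peptidoform | str,
    db: ReferenceDatabase,
    claimed_rank: str = "species",
    schemes: Sequence[EquivalenceScheme] = DEFAULT_SCHEMES,
) -> MarkerAssignment:
    """Validate a candidate marker against the database and taxonomy.

    The peptide is searched exactly and under every control scheme; its
    specificity rank is the rank of the lowest common ancestor of the
    union of all matches. ``valid_marker`` is true when that ancestor is
    at or below ``claimed_rank`` — i.e. the candidate survives every
    isobaric control at the claimed specificity.
    """
    if isinstance(peptidoform, str):
        peptidoform = Peptidoform(peptidoform)
    exact = find_taxa(peptidoform, db, EXACT)
    expanded = {scheme: find_taxa(peptidoform, db, scheme) for scheme in schemes}
    union = set(exact)
    for taxa in expanded.values():
        union |= taxa
    if not union:
        return MarkerAssignment(peptidoform, exact, expanded, None, None, False)
    lca = db.taxonomy.lca(union)
    from .refdb import RANKS

    valid = RANKS.index(lca.rank) <= RANKS.index(claimed_rank)
    shared = sorted(union - exact) if exact else sorted(union)
    return MarkerAssignment(peptidoform, exact, expanded, lca.rank, lca.id, valid, shared)


def diff_markers(
    taxon_a: str,
    taxon_b: str,
    db: ReferenceDatabase,
    rule: CleavageRule = TRYPSIN_SEMI,
    min_length: int = DEFAULT_MIN_LENGTH,
    max_length: int = DEFAULT_MAX_LENGTH,
) -> pd.DataFrame:
    """Tryptic peptides of ``taxon_a`` absent from ``taxon_b``.

    Each row carries ``il_only``: whether the distinguishing difference
    vanishes when I and L are treated as equivalent — the hallmark of a
    marker that cannot be trusted without I/L discrimination.
    """
    records_a = db.by_taxon(taxon_a)
    records_b = db.by_taxon(taxon_b)
    if not records_a:
        raise ValueError(f"taxon {taxon_a!r} has no records")
    if not records_b:
        raise ValueError(f"taxon {taxon_b!r} has no records")
    il = EquivalenceScheme(il_equivalent=True)
    rows = []
    seen: set[str] = set()
    for rec in records_a:
        for pep in digest(rec.sequence, rule, min_length, max_length):
            if pep.sequence in seen:
                continue
            seen.add(pep.sequence)
            pattern_exact = _match_pattern(pep.sequence, EXACT)
            if any(pattern_exact.search(rb.sequence) for rb in records_b):
                continue
            pattern_il = _match_pattern(pep.sequence, il)
            il_only = any(pattern_il.search(rb.sequence) for rb in records_b)
            rows.append(
                {
                    "sequence": pep.sequence,
                    "accession": rec.accession,
                    "start": pep.start + 1,
                    "end": pep.end,
                    "missed_cleavages": pep.missed_cleavages,
                    "specificity": pep.specificity,
                    "il_only": il_only,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "sequence",
            "accession",
            "start",
            "end",
            "missed_cleavages",
            "specificity",
            "il_only",
        ],
    )


def marker_table(
    db: ReferenceDatabase,
    taxa: Iterable[str] | None = None,
    rule: CleavageRule = TRYPSIN_SEMI,
    min_length: int = DEFAULT_MIN_LENGTH,
    max_length: int = DEFAULT_MAX_LENGTH,
    claimed_rank: str = "species",
) -> pd.DataFrame:
    """Exhaustive scan for valid markers of each taxon in ``taxa``.

    Digests every record of each taxon and keeps peptides whose
    validated match set (under all control schemes) has its LCA at or
    below ``claimed_rank`` and includes the taxon. Distinct base
    sequences are reported once per taxon.
    """
    taxa = list(taxa) if taxa is not None else sorted({r.taxon for r in db.records})
    rows = []
    for taxon in taxa:
        seen: set[str] = set()
        for rec in db.by_taxon(taxon):
            for pep in digest(rec.sequence, rule, min_length, max_length):
                if pep.sequence in seen:
                    continue
                seen.add(pep.sequence)
                assignment = classify_marker(pep.sequence, db, claimed_rank)
                if not assignment.valid_marker or taxon not in assignment.all_matched:
                    continue
                rows.append(
                    {
                        "taxon": taxon,
                        "sequence": pep.sequence,
                        "accession": rec.accession,
                        "start": pep.start + 1,
                        "end": pep.end,
                        "missed_cleavages": pep.missed_cleavages,
                        "specificity": pep.specificity,
                        "rank": assignment.specificity_rank,
                        "lca": assignment.lca_taxon,
                        "shared_with": ",".join(assignment.shared_with),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "taxon",
            "sequence",
            "accession",
            "start",
            "end",
            "missed_cleavages",
            "specificity",
            "rank",
            "lca",
            "shared_with",
        ],
    )
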