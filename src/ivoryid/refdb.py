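"""Reference database: collagen sequences bound to a taxonomy.

Sequences come from user-supplied FASTA; the taxonomy and the
accession-to-taxon mapping come from an explicit TSV table (no remote
service is ever queried). Evidence-based variant edits — e.g. a P->A
substitution confirmed from exemplar specimens — are applied as
auditable, position-checked patches.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "RANKS",
    "TaxonNode",
    "Taxonomy",
    "SequenceRecord",
    "VariantEdit",
    "EquivalenceScheme",
    "ReferenceDatabase",
    "load_fasta",
    "load_taxonomy_table",
    "load_variant_table",
    "apply_variants",
    "write_fasta",
]

#: Taxonomic ranks from most to least specific, as used in reporting
#: (species / genus / family columns) and in targeted databases at
#: intermediate ranks (parvorder, infraorder).
RANKS: tuple[str, ...] = (
    "species",
    "genus",
    "subfamily",
    "family",
    "parvorder",
    "infraorder",
    "order",
    "clade",
)

CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class TaxonNode:
    id: str
    name: str
    rank: str
    parent: str | None = None

    def __post_init__(self) -> None:
        if self.rank not in RANKS:
            raise ValueError(f"unknown rank {self.rank!r} for taxon {self.id!r}")


class Taxonomy:
    """A rooted taxonomy tree with rank-coarsening validation."""

    def __init__(self, nodes: Iterable[TaxonNode]):
        self.nodes: dict[str, TaxonNode] = {}
        for node in nodes:
            if node.id in self.nodes:
                raise ValueError(f"duplicate taxon id {node.id!r}")
            self.nodes[node.id] = node
        roots = [n for n in self.nodes.values() if n.parent is None]
        if len(roots) != 1:
            raise ValueError(f"taxonomy must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        for node in self.nodes.values():
            self._validate_chain(node)

    def _validate_chain(self, node: TaxonNode) -> None:
        seen = {node.id}
        current = node
        while current.parent is not None:
            parent = self.nodes.get(current.parent)
            if parent is None:
                raise KeyError(f"taxon {current.id!r} has unknown parent {current.parent!r}")
            if parent.id in seen:
                raise ValueError(f"cycle in taxonomy at {parent.id!r}")
            if RANKS.index(parent.rank) <= RANKS.index(current.rank):
                raise ValueError(
                    f"rank must coarsen towards the root: {current.id} ({current.rank}) "
                    f"-> {parent.id} ({parent.rank})"
                )
            seen.add(parent.id)
            current = parent

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self.nodes

    def __getitem__(self, taxon_id: str) -> TaxonNode:
        try:
            return self.nodes[taxon_id]
        except KeyError:
            raise KeyError(f"unknown taxon id {taxon_id!r}") from None

    def lineage(self, taxon_id: str) -> list[TaxonNode]:
        """Ancestor chain ordered root -> the named taxon."""
        chain = [self[taxon_id]]
        while chain[-1].parent is not None:
            chain.append(self[chain[-1].parent])
        return chain[::-1]

    def lca(self, taxa: Iterable[str]) -> TaxonNode:
        """Lowest (deepest) common ancestor of a non-empty set of taxa."""
        taxa = list(taxa)
        if not taxa:
            raise ValueError("lca of an empty taxon set is undefined")
        common: list[TaxonNode] | None = None
        for tid in taxa:
            lineage = self.lineage(tid)
            if common is None:
                common = lineage
            else:
                shared = []
                for a, b in zip(common, lineage):
                    if a.id != b.id:
                        break
                    shared.append(a)
                common = shared
        assert common  # all lineages share the root
        return common[-1]

    def leaves(self) -> list[TaxonNode]:
        parents = {n.parent for n in self.nodes.values() if n.parent}
        return [n for n in self.nodes.values() if n.id not in parents]


@dataclass(frozen=True)
class SequenceRecord:
    """A collagen chain sequence bound to a taxon."""

    accession: str
    chain: str  # "COL1A1" | "COL1A2" | "other"
    taxon: str
    sequence: str
    source: str = ""
    edits: tuple[str, ...] = ()  # audit log of applied variant edits

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.accession!r} has an empty sequence")
        bad = set(self.sequence) - CANONICAL_RESIDUES
        if bad:
            raise ValueError(
                f"record {self.accession!r} contains non-canonical residue(s) "
                f"{''.join(sorted(bad))}"
            )
        if self.chain not in ("COL1A1", "COL1A2", "other"):
            raise ValueError(f"unknown chain {self.chain!r}")


@dataclass(frozen=True)
class VariantEdit:
    """A single evidence-backed residue substitution.

    ``position`` is a 1-based index into the stored record sequence;
    the coordinate frame of the evidence (e.g. mature chain vs
    precursor) is recorded in ``evidence``, not inferred.
    """

    accession: str
    position: int
    ref: str
    alt: str
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position is 1-based and must be >= 1")


@dataclass(frozen=True)
class EquivalenceScheme:
    """Which residue identities are collapsed when matching peptides.

    The all-false scheme is exact matching. ``il_equivalent`` treats the
    isobaric pair I/L as one letter; the deamidation flags let D (E)
    match a deamidated N (Q) at the deamidated position only.
    """

    il_equivalent: bool = False
    deamidated_n_equals_d: bool = False
    deamidated_q_equals_e: bool = False

    @property
    def is_exact(self) -> bool:
        return not (self.il_equivalent or self.deamidated_n_equals_d or self.deamidated_q_equals_e)


EXACT = EquivalenceScheme()
FULL_EXPANSION = EquivalenceScheme(True, True, True)


@dataclass
class ReferenceDatabase:
    """Validated sequence records plus the taxonomy they map into."""

    records: list[SequenceRecord]
    taxonomy: Taxonomy
    rejects: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.accession in seen:
                raise ValueError(f"duplicate accession {rec.accession!r}")
            seen.add(rec.accession)
            if rec.taxon not in self.taxonomy:
                raise KeyError(f"record {rec.accession!r} maps to unknown taxon {rec.taxon!r}")

    def by_taxon(self, taxon_id: str) -> list[SequenceRecord]:
        return [r for r in self.records if r.taxon == taxon_id]

    def __len__(self) -> int:
        return len(self.records)


def load_taxonomy_table(path: str | Path) -> tuple[Taxonomy, pd.DataFrame]:
    """Read the taxonomy TSV (accession, taxon_id, taxon_name, rank,
    parent_id, chain) into a tree plus the accession mapping."""
    table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"accession", "taxon_id", "taxon_name", "rank", "parent_id", "chain"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"taxonomy table missing column(s): {sorted(missing)}")
    nodes: dict[str, TaxonNode] = {}
    for _, row in table.iterrows():
        node = TaxonNode(
            row["taxon_id"], row["taxon_name"], row["rank"], row["parent_id"] or None
        )
        existing = nodes.get(node.id)
        if existing is not None and existing != node:
            raise ValueError(f"conflicting definitions for taxon {node.id!r}")
        nodes[node.id] = node
        # rows with an empty accession define internal nodes only
    # walk up adding implied parents must already be present in table
    return Taxonomy(nodes.values()), table[table["accession"] != ""]


def load_fasta(
    fasta_path: str | Path,
    taxonomy_path: str | Path,
) -> ReferenceDatabase:
    """Load a FASTA and its taxonomy mapping into a validated database.

    Records whose accession is unmapped or whose sequence fails
    validation are not silently dropped: they are listed in
    ``db.rejects`` with a reason.
    """
    taxonomy, mapping = load_taxonomy_table(taxonomy_path)
    by_accession = {row["accession"]: row for _, row in mapping.iterrows()}

    records: list[SequenceRecord] = []
    rejects: list[dict] = []
    for bio_rec in SeqIO.parse(str(fasta_path), "fasta"):
        accession = bio_rec.id
        row = by_accession.get(accession)
        if row is None:
            rejects.append({"accession": accession, "reason": "unmapped accession"})
            continue
        try:
            records.append(
                SequenceRecord(
                    accession=accession,
                    chain=row["chain"] or "other",
                    taxon=row["taxon_id"],
                    sequence=str(bio_rec.seq).upper(),
                    source=bio_rec.description,
                )
            )
        except ValueError as exc:
            reason = "non-canonical residue" if "non-canonical" in str(exc) else str(exc)
            rejects.append({"accession": accession, "reason": reason})
    return ReferenceDatabase(records, taxonomy, rejects)


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio_records = [
        _BioSeqRecord(Seq(rec.sequence), id=rec.accession, description=rec.source or rec.chain)
        for rec in records
    ]
    SeqIO.write(bio_records, str(path), "fasta")


def load_variant_table(path: str | Path) -> list[VariantEdit]:
    """Read the variant TSV (accession, position, ref, alt, evidence)."""
    table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"accession", "position", "ref", "alt"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"variant table missing column(s): {sorted(missing)}")
    return [
        VariantEdit(
            row["accession"],
            int(row["position"]),
            row["ref"],
            row["alt"],
            row.get("evidence", ""),
        )
        for _, row in table.iterrows()
    ]


def apply_variants(record: SequenceRecord, edits: Sequence[VariantEdit]) -> SequenceRecord:
    """Return an edited copy of ``record`` with every edit applied.

    Each edit's reference residue is checked against the stored sequence
    before substitution, so re-applying an already-applied edit fails
    loudly instead of silently corrupting the sequence. The result is
    independent of edit order (edits address fixed positions).
    """
    seq = list(record.sequence)
    log = list(record.edits)
    for edit in edits:
        if edit.accession != record.accession:
            raise ValueError(
                f"edit targets {edit.accession!r}, record is {record.accession!r}"
            )
        if edit.position > len(seq):
            raise ValueError(
                f"position {edit.position} beyond sequence of length {len(seq)}"
            )
        found = seq[edit.position - 1]
        if found != edit.ref:
            raise ValueError(
                f"reference mismatch at position {edit.position}: "
                f"expected {edit.ref!r}, found {found!r}"
            )
        seq[edit.position - 1] = edit.alt
        log.append(f"{edit.ref}{edit.position}{edit.alt}")
    return dataclasses.replace(record, sequence="".join(seq), edits=tuple(log))
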