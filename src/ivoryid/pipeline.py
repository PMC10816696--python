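"""Three-tier identification ladder and reporting.

Tier 1 (ms2_markers): marker peptides confirmed by well-fragmented MS2
spectra (backbone coverage above a threshold). Tier 2 (summed_ms2): for
markers that failed tier 1, replicate MS2 spectra of the targeted
precursor are summed to lift weak fragments above noise; a precursor
within tolerance plus a few fragment ions suffices. Tier 3 (lcms_pmf):
precursor-only evidence — m/z, charge state and retention time against
a same-batch reference. Escalation happens only when the previous tier
fails its threshold; a report (possibly "none") is always produced.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .massdigest import Peptidoform, ppm_error
from .pmfmap import MarkerQuery, PMFReport, pmf_assign
from .refdb import ReferenceDatabase
from .spectra import (
    DEFAULT_TOLERANCES,
    Run,
    Spectrum,
    ToleranceConfig,
    annotate,
    sum_spectra,
)

__all__ = [
    "IdentificationConfig",
    "IdentificationReport",
    "identify",
    "report_render",
    "report_from_json",
]

#: Minimum distinct marker sequences required to call a taxon at a rank.
#: Species calls need several independent sequence regions; family-level
#: calls on poorly represented clades rest on fewer distinct regions.
DEFAULT_MIN_MARKERS: dict[str, int] = {"species": 5, "genus": 3, "family": 2}


@dataclass
class IdentificationConfig:
    tolerances: ToleranceConfig = field(default_factory=ToleranceConfig)
    min_markers: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_MIN_MARKERS))
    margin: int = 2
    coverage_min: float = 0.5  # tier-1 backbone coverage threshold
    min_fragments_summed: int = 3  # tier-2 "a few fragment ions"
    sum_bin_da: float = 0.01
    rt_offset: float = 0.0

    def snapshot(self) -> dict:
        return {
            "precursor_ppm": self.tolerances.precursor_ppm,
            "fragment_da": self.tolerances.fragment_da,
            "rt_window_s": self.tolerances.rt_window_s,
            "min_markers": dict(self.min_markers),
            "margin": self.margin,
            "coverage_min": self.coverage_min,
            "min_fragments_summed": self.min_fragments_summed,
            "sum_bin_da": self.sum_bin_da,
            "rt_offset": self.rt_offset,
        }


@dataclass
class MarkerEvidence:
    sequence: str
    modform: str
    taxon: str
    charge: int
    tier: str
    backbone_coverage: float | None
    n_fragments: int
    precursor_ppm: float | None
    rt: float | None


@dataclass
class IdentificationReport:
    sample_id: str
    tier: str | None  # "ms2_markers" | "summed_ms2" | "lcms_pmf" | None
    assigned_taxon: str | None
    assigned_rank: str | None
    counts_sequences: dict[str, int]
    counts_peptidoforms: dict[str, int]
    evidence: list[MarkerEvidence]
    config: dict

    def evidence_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(e) for e in self.evidence])


def _spectra_for_query(
    run: Run, query: MarkerQuery, tol: ToleranceConfig
) -> list[Spectrum]:
    """MS2 spectra whose precursor lies within tolerance of the query."""
    out = []
    for s in run.ms_level(2):
        if s.precursor_mz is None:
            continue
        if abs(ppm_error(s.precursor_mz, query.theoretical_mz)) <= tol.precursor_ppm:
            if s.precursor_charge in (None, query.charge):
                out.append(s)
    return out


def _tally(evidence: list[MarkerEvidence]) -> tuple[dict[str, int], dict[str, int]]:
    seqs: dict[str, set] = {}
    forms: dict[str, set] = {}
    for e in evidence:
        seqs.setdefault(e.taxon, set()).add(e.sequence)
        forms.setdefault(e.taxon, set()).add(e.modform)
    return {t: len(v) for t, v in seqs.items()}, {t: len(v) for t, v in forms.items()}


def _decide(
    counts: dict[str, int],
    db: ReferenceDatabase,
    config: IdentificationConfig,
) -> tuple[str | None, str | None]:
    """Assign the leading taxon if it clears the species threshold with
    margin; otherwise fall back to the LCA of all evidenced taxa when
    that coarser rank clears its own (smaller) threshold."""
    positive = {t: c for t, c in counts.items() if c > 0}
    if not positive:
        return None, None
    ranked = sorted(positive.items(), key=lambda kv: (-kv[1], kv[0]))
    best_taxon, best_count = ranked[0]
    runner_up = ranked[1][1] if len(ranked) > 1 else 0
    need = config.min_markers.get("species", 5)
    if best_count >= need and best_count - runner_up >= config.margin:
        return best_taxon, db.taxonomy[best_taxon].rank
    # conflicting or thin species evidence: coarsen to the common ancestor
    lca = db.taxonomy.lca(positive.keys())
    total = sum(positive.values())
    need_lca = config.min_markers.get(lca.rank, need)
    if lca.rank != "species" and total >= need_lca:
        return lca.id, lca.rank
    return None, None


def identify(
    run: Run,
    queries: Sequence[MarkerQuery],
    db: ReferenceDatabase,
    config: IdentificationConfig | None = None,
    sample_id: str = "",
) -> IdentificationReport:
    """Run the identification ladder for one sample.

    ``queries`` carry the marker peptidoforms of every candidate taxon
    (with charges and same-batch reference RTs). The first tier whose
    evidence clears its threshold supplies the assignment; later tiers
    are not consulted for it.
    """
    config = config or IdentificationConfig()
    tol = config.tolerances

    # ---- tier 1: fully fragmented MS2 evidence
    tier1: list[MarkerEvidence] = []
    unconfirmed: list[MarkerQuery] = []
    for q in queries:
        best = None
        for s in _spectra_for_query(run, q, tol):
            ann = annotate(s, q.peptidoform.with_charge(q.charge), tol)
            if best is None or ann.backbone_coverage > best[0].backbone_coverage:
                best = (ann, s)
        if best is not None and best[0].backbone_coverage >= config.coverage_min:
            ann, s = best
            tier1.append(
                MarkerEvidence(
                    q.peptidoform.sequence,
                    _modform(q.peptidoform),
                    q.taxon,
                    q.charge,
                    "ms2_markers",
                    ann.backbone_coverage,
                    ann.n_matched,
                    ppm_error(s.precursor_mz, q.theoretical_mz),
                    s.rt,
                )
            )
        else:
            unconfirmed.append(q)

    counts_seq, counts_form = _tally(tier1)
    taxon, rank = _decide(counts_seq, db, config)
    if taxon is not None:
        return IdentificationReport(
            sample_id, "ms2_markers", taxon, rank, counts_seq, counts_form, tier1,
            config.snapshot(),
        )

    # ---- tier 2: summed MS2 spectra of still-unconfirmed markers
    tier2: list[MarkerEvidence] = list(tier1)
    still: list[MarkerQuery] = []
    for q in unconfirmed:
        replicates = _spectra_for_query(run, q, tol)
        if not replicates:
            still.append(q)
            continue
        summed = sum_spectra(replicates, config.sum_bin_da)
        ann = annotate(summed, q.peptidoform.with_charge(q.charge), tol)
        prec_ppm = ppm_error(summed.precursor_mz, q.theoretical_mz)
        if abs(prec_ppm) <= tol.precursor_ppm and ann.n_matched >= config.min_fragments_summed:
            tier2.append(
                MarkerEvidence(
                    q.peptidoform.sequence,
                    _modform(q.peptidoform),
                    q.taxon,
                    q.charge,
                    "summed_ms2",
                    ann.backbone_coverage,
                    ann.n_matched,
                    prec_ppm,
                    summed.rt,
                )
            )
        else:
            still.append(q)

    counts_seq, counts_form = _tally(tier2)
    taxon, rank = _decide(counts_seq, db, config)
    if taxon is not None:
        return IdentificationReport(
            sample_id, "summed_ms2", taxon, rank, counts_seq, counts_form, tier2,
            config.snapshot(),
        )

    # ---- tier 3: LC-MS PMF on precursor evidence alone
    pmf: PMFReport = pmf_assign(
        run,
        list(queries),
        tol,
        min_markers=config.min_markers.get("species", 5),
        margin=config.margin,
        rt_offset=config.rt_offset,
    )
    evidence = list(tier2)
    for m in pmf.evidence:
        if m.matched:
            evidence.append(
                MarkerEvidence(
                    m.query.peptidoform.sequence,
                    _modform(m.query.peptidoform),
                    m.query.taxon,
                    m.query.charge,
                    "lcms_pmf",
                    None,
                    0,
                    m.ppm_error,
                    m.apex_rt,
                )
            )
    counts_seq, counts_form = _tally(evidence)
    taxon, rank = (
        (pmf.assignment, db.taxonomy[pmf.assignment].rank)
        if pmf.assignment
        else _decide(counts_seq, db, config)
    )
    return IdentificationReport(
        sample_id,
        "lcms_pmf" if taxon is not None else None,
        taxon,
        rank,
        counts_seq,
        counts_form,
        evidence,
        config.snapshot(),
    )


def _modform(pf: Peptidoform) -> str:
    from .massdigest import format_modform

    return format_modform(pf)


def report_render(report: IdentificationReport, out_prefix: str | Path | None = None) -> dict:
    """Serialize a report deterministically to JSON/TSV/plain text.

    Returns {"json": str, "tsv": str, "text": str}; when ``out_prefix``
    is given the three files are written as <prefix>.json/.tsv/.txt.
    """
    payload = {
        "sample_id": report.sample_id,
        "tier": report.tier,
        "assigned_taxon": report.assigned_taxon,
        "assigned_rank": report.assigned_rank,
        "counts_sequences": dict(sorted(report.counts_sequences.items())),
        "counts_peptidoforms": dict(sorted(report.counts_peptidoforms.items())),
        "evidence": [asdict(e) for e in report.evidence],
        "config": report.config,
    }
    as_json = json.dumps(payload, indent=2, sort_keys=True)
    tsv = report.evidence_frame().to_csv(sep="\t", index=False)

    lines = [f"Sample: {report.sample_id or '(unnamed)'}"]
    if report.assigned_taxon:
        lines.append(
            f"Assignment: {report.assigned_taxon} (rank {report.assigned_rank}, "
            f"tier {report.tier})"
        )
    else:
        lines.append("Assignment: none")
    for taxon in sorted(report.counts_sequences):
        lines.append(
            f"  {taxon}: {report.counts_sequences[taxon]} marker sequence(s), "
            f"{report.counts_peptidoforms.get(taxon, 0)} peptidoform(s)"
        )
    text = "\n".join(lines) + "\n"

    if out_prefix is not None:
        prefix = Path(out_prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        prefix.with_suffix(".json").write_text(as_json)
        prefix.with_suffix(".tsv").write_text(tsv)
        prefix.with_suffix(".txt").write_text(text)
    return {"json": as_json, "tsv": tsv, "text": text}


def report_from_json(payload: str) -> IdentificationReport:
    data = json.loads(payload)
    evidence = [MarkerEvidence(**e) for e in data["evidence"]]
    return IdentificationReport(
        data["sample_id"],
        data["tier"],
        data["assigned_taxon"],
        data["assigned_rank"],
        data["counts_sequences"],
        data["counts_peptidoforms"],
        evidence,
        data["config"],
    )
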