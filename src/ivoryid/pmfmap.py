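"""LC-MS peptide-mass-fingerprint mapping for degraded samples.

When fragmentation spectra are too weak to sequence, taxon markers can
still be confirmed from precursor evidence alone: accurate m/z (ppm
tolerance), charge state (verified by the isotope companion spacing)
and retention-time agreement with a reference run acquired in the same
batch. Counting matched marker peptides per taxon then supports a
fingerprint-style assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .massdigest import ISOTOPE_SPACING, Peptidoform, mz as compute_mz, ppm_error
from .spectra import DEFAULT_TOLERANCES, Run, Spectrum, ToleranceConfig

__all__ = [
    "MarkerQuery",
    "EICTrace",
    "PMFMatch",
    "PMFReport",
    "extract_eic",
    "match_marker",
    "pmf_assign",
]

#: Charge states considered plausible for tryptic collagen precursors,
#: matching a data-dependent acquisition charge filter of 2-7.
DEFAULT_CHARGE_RANGE = (2, 7)


@dataclass(frozen=True)
class MarkerQuery:
    """A marker peptidoform to look for in a degraded run."""

    peptidoform: Peptidoform
    taxon: str
    rank: str
    charge: int
    reference_rt: float
    reference_run_id: str = ""
    theoretical_mz: float = field(default=0.0)

    def __post_init__(self) -> None:
        lo, hi = DEFAULT_CHARGE_RANGE
        if not lo <= self.charge <= hi:
            raise ValueError(f"charge {self.charge} outside plausible range {lo}-{hi}")
        if self.theoretical_mz == 0.0:
            object.__setattr__(
                self, "theoretical_mz", compute_mz(self.peptidoform, self.charge)
            )


@dataclass
class EICTrace:
    """Extracted ion chromatogram for one m/z window."""

    query_mz: float
    tolerance_ppm: float
    rt: np.ndarray
    intensity: np.ndarray

    @property
    def n_peaks(self) -> int:
        """Number of chromatographic peaks: contiguous nonzero segments."""
        nonzero = self.intensity > 0
        return int(np.sum(nonzero[1:] & ~nonzero[:-1]) + (1 if nonzero.size and nonzero[0] else 0))


@dataclass
class PMFMatch:
    query: MarkerQuery
    matched: bool
    apex_rt: float | None
    apex_intensity: float
    ppm_error: float | None
    n_eic_peaks: int
    charge_confirmed: bool = False


@dataclass
class PMFReport:
    """Per-taxon matched-marker tallies and the resulting assignment."""

    counts_sequences: dict[str, int]
    counts_peptidoforms: dict[str, int]
    assignment: str | None
    evidence: list[PMFMatch]

    def to_frame(self) -> pd.DataFrame:
        taxa = sorted(self.counts_sequences)
        return pd.DataFrame(
            {
                "taxon": taxa,
                "matched_sequences": [self.counts_sequences[t] for t in taxa],
                "matched_peptidoforms": [self.counts_peptidoforms[t] for t in taxa],
                "assigned": [t == self.assignment for t in taxa],
            }
        )


def extract_eic(run: Run, mz: float, ppm_tol: float = 10.0) -> EICTrace:
    """Per-MS1-spectrum summed intensity within +/- ppm_tol of ``mz``."""
    ms1 = run.ms_level(1)
    if not ms1:
        raise ValueError("run contains no MS1 spectra")
    half = mz * ppm_tol * 1e-6
    rt = np.array([s.rt for s in ms1])
    intensity = np.empty(len(ms1))
    for i, s in enumerate(ms1):
        lo = np.searchsorted(s.mz, mz - half, side="left")
        hi = np.searchsorted(s.mz, mz + half, side="right")
        intensity[i] = s.intensity[lo:hi].sum()
    order = np.argsort(rt, kind="stable")
    return EICTrace(mz, ppm_tol, rt[order], intensity[order])


def _charge_confirmed(
    spectrum: Spectrum, mz: float, charge: int, tol: ToleranceConfig
) -> tuple[bool, float | None]:
    """Check the isotope companion at +1.00335/z next to the mono peak.

    Returns (confirmed, ppm error of the monoisotopic peak)."""
    half = mz * tol.precursor_ppm * 1e-6
    d = np.abs(spectrum.mz - mz)
    in_win = d <= half
    if not np.any(in_win):
        return False, None
    candidates = np.flatnonzero(in_win)
    mono = candidates[np.argmax(spectrum.intensity[candidates])]
    mono_mz = spectrum.mz[mono]
    companion = mono_mz + ISOTOPE_SPACING / charge
    has_companion = bool(np.any(np.abs(spectrum.mz - companion) <= tol.fragment_da))
    return has_companion, ppm_error(mono_mz, mz)


def match_marker(
    run: Run,
    query: MarkerQuery,
    tol: ToleranceConfig = DEFAULT_TOLERANCES,
    rt_offset: float = 0.0,
) -> PMFMatch:
    """Confirm one marker by m/z, charge state and retention time.

    The marker matches when its EIC has an apex within the RT window of
    the (offset-corrected) reference RT and the apex MS1 spectrum shows
    the expected charge via the isotope companion spacing.
    """
    trace = extract_eic(run, query.theoretical_mz, tol.precursor_ppm)
    expected_rt = query.reference_rt + rt_offset
    in_window = np.abs(trace.rt - expected_rt) <= tol.rt_window_s
    if not np.any(in_window) or trace.intensity[in_window].max() <= 0:
        return PMFMatch(query, False, None, 0.0, None, trace.n_peaks)
    local = np.flatnonzero(in_window)
    apex = local[np.argmax(trace.intensity[local])]
    apex_rt = float(trace.rt[apex])
    apex_intensity = float(trace.intensity[apex])

    ms1 = sorted(run.ms_level(1), key=lambda s: s.rt)
    apex_spectrum = min(ms1, key=lambda s: abs(s.rt - apex_rt))
    confirmed, err = _charge_confirmed(apex_spectrum, query.theoretical_mz, query.charge, tol)
    return PMFMatch(query, confirmed, apex_rt, apex_intensity, err, trace.n_peaks, confirmed)


def estimate_rt_offset(
    run: Run,
    queries: Sequence[MarkerQuery],
    tol: ToleranceConfig = DEFAULT_TOLERANCES,
) -> float:
    """Median apex-vs-reference RT shift over queries that match with no
    offset; a single scalar alignment between same-batch runs."""
    deltas = []
    for q in queries:
        m = match_marker(run, q, tol)
        if m.matched and m.apex_rt is not None:
            deltas.append(m.apex_rt - q.reference_rt)
    return float(np.median(deltas)) if deltas else 0.0


def pmf_assign(
    run: Run,
    queries: Sequence[MarkerQuery],
    tol: ToleranceConfig = DEFAULT_TOLERANCES,
    min_markers: int = 5,
    margin: int = 2,
    rt_offset: float = 0.0,
) -> PMFReport:
    """Score taxa by matched markers and assign when evidence is decisive.

    Counts distinct base sequences per taxon (so one heavily modified
    peptide cannot dominate); assigns the top taxon when its count is at
    least ``min_markers`` and leads the runner-up by at least
    ``margin``. Ties or thin evidence yield no assignment, with counts
    reported either way.
    """
    evidence = [match_marker(run, q, tol, rt_offset) for q in queries]
    seqs: dict[str, set[str]] = {}
    forms: dict[str, set[tuple]] = {}
    for m in evidence:
        taxon = m.query.taxon
        seqs.setdefault(taxon, set())
        forms.setdefault(taxon, set())
        if m.matched:
            seqs[taxon].add(m.query.peptidoform.sequence)
            forms[taxon].add((m.query.peptidoform.sequence, m.query.peptidoform.mods))
    counts_seq = {t: len(s) for t, s in seqs.items()}
    counts_form = {t: len(s) for t, s in forms.items()}

    assignment = None
    if counts_seq:
        ranked = sorted(counts_seq.items(), key=lambda kv: (-kv[1], kv[0]))
        best_taxon, best_count = ranked[0]
        runner_up = ranked[1][1] if len(ranked) > 1 else 0
        if best_count >= min_markers and best_count - runner_up >= margin:
            assignment = best_taxon
    return PMFReport(counts_seq, counts_form, assignment, evidence)
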