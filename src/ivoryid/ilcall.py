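"""Leucine/isoleucine discrimination from MS3 spectra of z-radical ions.

ETD MS2 produces c/z-radical fragments; low-energy HCD MS3 of a z
radical whose N-terminal residue is Leu or Ile ejects part of the side
chain, forming a w ion. The lost radical differs: an ethyl radical
(29.0391 Da, nominal 29) for isoleucine, a propyl radical (43.0548 Da,
nominal 43) for leucine. Finding which loss dominates below the z-ion
precursor therefore reads out the residue identity that ordinary mass
measurement cannot, since I and L are isobaric.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .massdigest import PROTON, Peptidoform
from .spectra import (
    DEFAULT_TOLERANCES,
    Spectrum,
    ToleranceConfig,
    average_spectra,
    theoretical_fragments,
)

__all__ = [
    "ILE_LOSS",
    "LEU_LOSS",
    "ZIonTarget",
    "ILCall",
    "z_target_for_residue",
    "average_ms3",
    "call_il",
]

#: Monoisotopic mass of the ethyl radical (C2H5) lost from the Ile side chain.
ILE_LOSS = 29.039125
#: Monoisotopic mass of the propyl radical (C3H7) lost from the Leu side chain.
LEU_LOSS = 43.054775


@dataclass(frozen=True)
class ZIonTarget:
    """A z-radical ion whose most N-terminal residue is the interrogated I/L."""

    peptidoform: Peptidoform
    residue_position: int  # 1-based position of the I/L in the peptide
    z_index: int
    z_charge: int
    theoretical_z_mz: float


def z_target_for_residue(
    pf: Peptidoform,
    residue_position: int,
    charge: int = 1,
) -> ZIonTarget:
    """Build the z-ion target interrogating the I/L at ``residue_position``.

    The z fragment whose N-terminal residue is position p of a length-n
    peptide is z_(n-p+1): the C-terminal fragment starting at that
    residue.
    """
    n = len(pf.sequence)
    if not 1 <= residue_position <= n:
        raise ValueError(f"position {residue_position} outside peptide of length {n}")
    residue = pf.sequence[residue_position - 1]
    if residue not in "IL":
        raise ValueError(
            f"residue at position {residue_position} is {residue!r}, not I or L"
        )
    if charge < 1:
        raise ValueError("charge must be >= 1")
    z_index = n - residue_position + 1
    for ion in theoretical_fragments(pf, ("z_radical",), max_charge=charge):
        if ion.index == z_index and ion.charge == charge:
            return ZIonTarget(pf, residue_position, z_index, charge, ion.theoretical_mz)
    raise ValueError(
        f"no z_{z_index} fragment exists for a peptide of length {n} "
        "(the full-length z ion is the charge-reduced precursor, not a fragment)"
    )


@dataclass
class ILCall:
    """Outcome of one diagnostic-loss interrogation."""

    target: ZIonTarget
    loss29_intensity: float
    loss43_intensity: float
    loss29_snr: float
    loss43_snr: float
    call: str  # "Ile" | "Leu" | "ambiguous" | "no_signal"
    score: float  # dominant/competing intensity ratio (inf if no competitor)
    n_spectra_averaged: int = 1


def average_ms3(
    spectra: Sequence[Spectrum],
    bin_tolerance: float = 0.01,
    precursor_tol_mz: float = 0.05,
) -> Spectrum:
    """Average replicate MS3 spectra of one z-ion precursor.

    All spectra must reference the same precursor within
    ``precursor_tol_mz``; cluster intensities are means, so averaging n
    replicates of one spectrum returns that spectrum.
    """
    if not spectra:
        raise ValueError("need at least one spectrum to average")
    ref = spectra[0].precursor_mz
    offenders = [
        s.native_id or str(i)
        for i, s in enumerate(spectra)
        if (s.precursor_mz is None) != (ref is None)
        or (ref is not None and abs(s.precursor_mz - ref) > precursor_tol_mz)
    ]
    if offenders:
        raise ValueError(
            "spectra reference different precursors: " + ", ".join(offenders)
        )
    return average_spectra(spectra, bin_tolerance)


def call_il(
    ms3: Spectrum,
    target: ZIonTarget,
    tol: ToleranceConfig = DEFAULT_TOLERANCES,
    snr_min: float = 3.0,
    r_min: float = 3.0,
    n_spectra_averaged: int = 1,
) -> ILCall:
    """Call Ile vs Leu from the diagnostic side-chain losses.

    Looks for w-ion peaks at (z-ion m/z - 29.0391/z) and (- 43.0548/z)
    within the fragment tolerance. The dominant loss is called when its
    SNR is at least ``snr_min`` and it exceeds the competing loss by a
    factor of at least ``r_min``; otherwise the spectrum is ambiguous.
    No peak at either loss is reported as no_signal — a result, not an
    error, as expected from degraded material.
    """
    if ms3.ms_level != 3:
        raise ValueError("I/L calling expects an MS3 spectrum")
    z = target.z_charge
    mz29 = target.theoretical_z_mz - ILE_LOSS / z
    mz43 = target.theoretical_z_mz - LEU_LOSS / z

    def peak_intensity(mz_query: float) -> float:
        d = np.abs(ms3.mz - mz_query)
        hit = d <= tol.fragment_da
        return float(ms3.intensity[hit].max()) if np.any(hit) else 0.0

    i29 = peak_intensity(mz29)
    i43 = peak_intensity(mz43)
    # one shared noise floor over both diagnostic regions (excluding the
    # two tolerance windows) keeps the decision symmetric under a 29<->43
    # relabeling of the planted loss
    d29 = np.abs(ms3.mz - mz29)
    d43 = np.abs(ms3.mz - mz43)
    flank = ms3.intensity[
        ((d29 <= 2.0) | (d43 <= 2.0))
        & (d29 > tol.fragment_da)
        & (d43 > tol.fragment_da)
    ]
    floor = max(float(np.median(flank)) if flank.size else 0.0, 1.0)
    s29 = i29 / floor
    s43 = i43 / floor

    if i29 == 0.0 and i43 == 0.0:
        call, score = "no_signal", 0.0
    elif i29 == i43:
        call, score = "ambiguous", 1.0
    else:
        (dom_i, dom_s, dom_call), (comp_i, _, _) = sorted(
            [(i29, s29, "Ile"), (i43, s43, "Leu")], reverse=True
        )
        score = dom_i / comp_i if comp_i > 0 else float("inf")
        if dom_s >= snr_min and score >= r_min:
            call = dom_call
        else:
            call = "ambiguous"
    return ILCall(target, i29, i43, s29, s43, call, score, n_spectra_averaged)
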