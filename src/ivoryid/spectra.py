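"""Centroided spectra: I/O, theoretical fragments, annotation, summing.

Runs are read from mzML or MGF (via pyteomics). MGF is also the native
output format for synthetic runs; MS level and retention time travel in
the standard MSLEVEL/RTINSECONDS parameters so that a single MGF file
can hold a full MS1/MS2/MS3 run. A minimal mzML writer is provided for
interoperability (index-free, 64-bit uncompressed arrays).
"""

from __future__ import annotations

import base64
import struct
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from lxml import etree
from pyteomics import mgf as _mgf

from .massdigest import (
    MONOISOTOPIC_RESIDUE_MASSES,
    MOD_BY_NAME,
    PROTON,
    Peptidoform,
    WATER,
    monoisotopic_mass,
)

__all__ = [
    "Spectrum",
    "Run",
    "ToleranceConfig",
    "FragmentIon",
    "AnnotatedSpectrum",
    "read_mzml",
    "read_mgf",
    "write_mgf",
    "write_mzml",
    "theoretical_fragments",
    "annotate",
    "sum_spectra",
    "average_spectra",
    "snr",
]

#: Mass of NH3, used for the b/c and y/z fragment inter-conversions.
NH3 = 17.026549
#: Hydrogen atom; a z-radical ion is one H heavier than the even-electron z.
HYDROGEN = 1.007825


@dataclass(frozen=True)
class ToleranceConfig:
    """Matching tolerances: 10 ppm precursor, 0.02 Da fragment, 60 s RT."""

    precursor_ppm: float = 10.0
    fragment_da: float = 0.02
    rt_window_s: float = 60.0

    def __post_init__(self) -> None:
        if min(self.precursor_ppm, self.fragment_da, self.rt_window_s) <= 0:
            raise ValueError("all tolerances must be positive")


DEFAULT_TOLERANCES = ToleranceConfig()


@dataclass
class Spectrum:
    """A centroided peak list with acquisition metadata."""

    mz: np.ndarray
    intensity: np.ndarray
    ms_level: int = 1
    rt: float = 0.0
    precursor_mz: float | None = None
    precursor_charge: int | None = None
    native_id: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("m/z and intensity arrays must have equal length")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]
        if self.mz.size > 1 and np.any(np.diff(self.mz) <= 0):
            # merge coincident centroids so m/z stays strictly ascending
            keep_mz: list[float] = []
            keep_int: list[float] = []
            for m, i in zip(self.mz, self.intensity):
                if keep_mz and m == keep_mz[-1]:
                    keep_int[-1] += i
                else:
                    keep_mz.append(m)
                    keep_int.append(i)
            self.mz = np.array(keep_mz)
            self.intensity = np.array(keep_int)
        if self.ms_level >= 2 and self.precursor_mz is None:
            raise ValueError("MS>=2 spectra require a precursor m/z")

    def __len__(self) -> int:
        return int(self.mz.size)

    @property
    def total_ion_current(self) -> float:
        return float(self.intensity.sum())


@dataclass
class Run:
    """An ordered collection of spectra from one acquisition."""

    spectra: list[Spectrum]
    run_id: str = ""

    def ms_level(self, level: int) -> list[Spectrum]:
        return [s for s in self.spectra if s.ms_level == level]

    def __len__(self) -> int:
        return len(self.spectra)


@dataclass(frozen=True)
class FragmentIon:
    """A theoretical backbone fragment.

    series: b/y (HCD), c/z_radical (ETD), or w (side-chain loss from a
    z radical). ``index`` counts residues from the series' own terminus.
    """

    series: str
    index: int
    charge: int
    theoretical_mz: float


SUPPORTED_SERIES = ("b", "y", "c", "z_radical")


def theoretical_fragments(
    pf: Peptidoform,
    series: Sequence[str] = ("b", "y"),
    max_charge: int = 1,
) -> list[FragmentIon]:
    """Theoretical fragment m/z values of ``pf`` for the requested series.

    Positioned modifications are carried with the fragment containing
    the modified residue. z fragments use the radical (z + H relative to
    the even-electron Biemann z) convention produced by ETD.
    """
    for s in series:
        if s not in SUPPORTED_SERIES:
            raise ValueError(f"unsupported fragment series {s!r}")
    n = len(pf.sequence)
    residue = [MONOISOTOPIC_RESIDUE_MASSES[r] for r in pf.sequence]
    for pos, name in pf.mods:
        residue[pos - 1] += MOD_BY_NAME[name].delta
    prefix = np.cumsum(residue)  # prefix[i-1] = mass of residues 1..i

    out: list[FragmentIon] = []
    total = prefix[-1]
    for i in range(1, n):  # fragments never span the whole peptide
        b_neutral = prefix[i - 1]
        y_neutral = total - prefix[i - 1] + WATER
        neutrals = {
            "b": b_neutral,
            "y": y_neutral,
            "c": b_neutral + NH3,
            "z_radical": y_neutral - NH3 + HYDROGEN,
        }
        for s in series:
            idx = i if s in ("b", "c") else n - i
            for z in range(1, max_charge + 1):
                out.append(FragmentIon(s, idx, z, (neutrals[s] + z * PROTON) / z))
    return out


@dataclass
class AnnotatedSpectrum:
    """An MS2 spectrum with fragment matches and backbone coverage."""

    spectrum: Spectrum
    peptidoform: Peptidoform
    matches: list[tuple[FragmentIon, int, float]]  # (ion, peak index, error Da)
    backbone_coverage: float
    precursor_warning: bool = False

    @property
    def n_matched(self) -> int:
        return len(self.matches)


def _bond_index(ion: FragmentIon, length: int) -> int:
    """The inter-residue bond (1..length-1) an ion's presence supports."""
    if ion.series in ("b", "c"):
        return ion.index
    return length - ion.index


def annotate(
    spectrum: Spectrum,
    pf: Peptidoform,
    tol: ToleranceConfig = DEFAULT_TOLERANCES,
    series: Sequence[str] = ("b", "y"),
    max_charge: int | None = None,
) -> AnnotatedSpectrum:
    """Match theoretical fragments of ``pf`` to peaks within the fragment
    tolerance (nearest peak per ion; ties broken by smaller |error| then
    higher intensity). Backbone coverage is the fraction of the
    length-1 inter-residue bonds supported by at least one matched ion.
    """
    if spectrum.ms_level < 2:
        raise ValueError("annotation requires an MS2 (or higher) spectrum")
    if max_charge is None:
        max_charge = max(1, (pf.charge or 2) - 1)
    warning = False
    if spectrum.precursor_mz is not None and pf.charge is not None:
        theo = (monoisotopic_mass(pf) + pf.charge * PROTON) / pf.charge
        if abs(1e6 * (spectrum.precursor_mz - theo) / theo) > tol.precursor_ppm:
            warning = True

    matches: list[tuple[FragmentIon, int, float]] = []
    if len(spectrum):
        for ion in theoretical_fragments(pf, series, max_charge):
            idx = int(np.searchsorted(spectrum.mz, ion.theoretical_mz))
            best: tuple[float, float, int] | None = None  # (|err|, -intensity, peak)
            for j in (idx - 1, idx):
                if 0 <= j < len(spectrum):
                    err = spectrum.mz[j] - ion.theoretical_mz
                    if abs(err) <= tol.fragment_da:
                        key = (abs(err), -spectrum.intensity[j], j)
                        if best is None or key < best:
                            best = key
            if best is not None:
                matches.append((ion, best[2], spectrum.mz[best[2]] - ion.theoretical_mz))

    n = len(pf.sequence)
    bonds = {_bond_index(ion, n) for ion, _, _ in matches}
    coverage = len(bonds) / (n - 1) if n > 1 else 0.0
    return AnnotatedSpectrum(spectrum, pf, matches, coverage, warning)


def _cluster_peaks(
    spectra: Sequence[Spectrum], bin_tolerance: float
) -> tuple[np.ndarray, np.ndarray]:
    """Single-linkage clustering of pooled peaks: a new cluster starts
    wherever the gap to the previous (sorted) peak exceeds the bin
    tolerance. Returns intensity-weighted cluster m/z and summed
    intensity."""
    all_mz = np.concatenate([s.mz for s in spectra])
    all_int = np.concatenate([s.intensity for s in spectra])
    if all_mz.size == 0:
        return np.array([]), np.array([])
    order = np.argsort(all_mz)
    all_mz, all_int = all_mz[order], all_int[order]
    breaks = np.flatnonzero(np.diff(all_mz) > bin_tolerance) + 1
    groups = np.split(np.arange(all_mz.size), breaks)
    mz_out = np.empty(len(groups))
    int_out = np.empty(len(groups))
    for k, g in enumerate(groups):
        w = all_int[g]
        total = w.sum()
        mz_out[k] = float(np.average(all_mz[g], weights=w)) if total > 0 else float(all_mz[g].mean())
        int_out[k] = total
    return mz_out, int_out


def sum_spectra(
    spectra: Sequence[Spectrum],
    bin_tolerance: float = 0.01,
) -> Spectrum:
    """Sum spectra of one targeted precursor to boost signal-to-noise.

    Peaks are pooled and clustered by single-linkage within
    ``bin_tolerance``; each cluster reports intensity-weighted mean m/z
    and summed intensity, conserving total ion current exactly.
    """
    if not spectra:
        raise ValueError("need at least one spectrum to sum")
    levels = {s.ms_level for s in spectra}
    if len(levels) > 1:
        raise ValueError(f"cannot sum spectra with mixed MS levels {sorted(levels)}")
    mz_out, int_out = _cluster_peaks(spectra, bin_tolerance)
    first = spectra[0]
    return Spectrum(
        mz_out,
        int_out,
        ms_level=first.ms_level,
        rt=float(np.mean([s.rt for s in spectra])),
        precursor_mz=first.precursor_mz,
        precursor_charge=first.precursor_charge,
        native_id=f"summed[{len(spectra)}]",
    )


def average_spectra(
    spectra: Sequence[Spectrum],
    bin_tolerance: float = 0.01,
) -> Spectrum:
    """Like :func:`sum_spectra` but cluster intensity is divided by the
    number of spectra averaged (mean, not sum)."""
    summed = sum_spectra(spectra, bin_tolerance)
    return replace(
        summed,
        intensity=summed.intensity / len(spectra),
        native_id=f"averaged[{len(spectra)}]",
    )


def snr(
    spectrum: Spectrum,
    target_mz: float,
    tol_da: float = 0.02,
    flank_da: float = 2.0,
) -> float:
    """Signal-to-noise of the peak at ``target_mz``: its intensity over
    the median intensity of flanking peaks within +/- ``flank_da``
    (excluding the tolerance window), with a noise floor of 1.0. Returns
    0.0 when no peak lies within tolerance."""
    if len(spectrum) == 0:
        return 0.0
    d = np.abs(spectrum.mz - target_mz)
    in_tol = d <= tol_da
    if not np.any(in_tol):
        return 0.0
    signal = float(spectrum.intensity[in_tol].max())
    flank = spectrum.intensity[(d <= flank_da) & ~in_tol]
    noise = float(np.median(flank)) if flank.size else 0.0
    return signal / max(noise, 1.0)


# ---------------------------------------------------------------------------
# File I/O


def read_mgf(path: str | Path) -> Run:
    """Read an MGF file into a Run.

    MS level defaults to 2 (the MGF convention) but is overridden by an
    MSLEVEL parameter when present, so full synthetic runs round-trip.
    """
    spectra: list[Spectrum] = []
    with _mgf.MGF(str(path)) as reader:
        for entry in reader:
            params = entry["params"]
            level = int(params.get("mslevel", 2))
            pepmass = params.get("pepmass", (None,))
            precursor = pepmass[0] if level >= 2 else None
            charge = params.get("charge")
            if charge:
                charge = int(charge[0])
            else:
                charge = None
            spectra.append(
                Spectrum(
                    entry["m/z array"],
                    entry["intensity array"],
                    ms_level=level,
                    rt=float(params.get("rtinseconds", 0.0)),
                    precursor_mz=precursor,
                    precursor_charge=charge if level >= 2 else None,
                    native_id=str(params.get("title", "")),
                )
            )
    return Run(spectra, run_id=str(Path(path).stem))


def write_mgf(run: Run, path: str | Path) -> None:
    entries = []
    for i, s in enumerate(run.spectra):
        params: dict = {
            "title": s.native_id or f"spectrum={i}",
            "mslevel": s.ms_level,
            "rtinseconds": s.rt,
        }
        if s.ms_level >= 2:
            params["pepmass"] = s.precursor_mz
            if s.precursor_charge:
                params["charge"] = s.precursor_charge
        entries.append(
            {"m/z array": s.mz, "intensity array": s.intensity, "params": params}
        )
    _mgf.write(entries, str(path), file_mode="w")


_MZML_NS = "http://psi.hupo.org/ms/mzml"


def _decode_binary_array(array_elem) -> np.ndarray:
    """Decode one <binaryDataArray>: 32/64-bit floats, zlib or none."""
    import zlib

    accessions = {
        cv.get("accession") for cv in array_elem.iter(f"{{{_MZML_NS}}}cvParam")
    } | {cv.get("accession") for cv in array_elem.iter("cvParam")}
    binary = array_elem.findtext(f"{{{_MZML_NS}}}binary") or array_elem.findtext("binary") or ""
    raw = base64.b64decode(binary)
    if "MS:1000574" in accessions:  # zlib compression
        raw = zlib.decompress(raw)
    dtype = "<f4" if "MS:1000521" in accessions else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml(path: str | Path) -> Run:
    """Read centroided spectra from an mzML file.

    A direct streaming parser over the mzML schema (lxml iterparse):
    handles ms level, scan start time (minute or second units),
    precursor selected ion / charge state, and 32/64-bit float peak
    arrays with optional zlib compression.
    """
    spectra: list[Spectrum] = []
    tag = f"{{{_MZML_NS}}}spectrum"
    for _, elem in etree.iterparse(str(path), events=("end",), tag=(tag, "spectrum")):
        try:
            spectra.append(_parse_spectrum_elem(elem))
        except ValueError as exc:
            raise ValueError(
                f"malformed spectrum {elem.get('id', '?')!r} in {path}: {exc}"
            ) from exc
        elem.clear(keep_tail=True)
    return Run(spectra, run_id=str(Path(path).stem))


def _parse_spectrum_elem(elem) -> Spectrum:
    def cv_params(node):
        out = {}
        for cv in node.iter(f"{{{_MZML_NS}}}cvParam"):
            out[cv.get("accession")] = cv
        for cv in node.iter("cvParam"):
            out.setdefault(cv.get("accession"), cv)
        return out

    params = cv_params(elem)
    level = int(params["MS:1000511"].get("value")) if "MS:1000511" in params else 1

    rt = 0.0
    if "MS:1000016" in params:
        cv = params["MS:1000016"]
        rt = float(cv.get("value"))
        if cv.get("unitName", "").startswith("minute"):
            rt *= 60.0

    precursor_mz = params.get("MS:1000744")
    precursor_mz = float(precursor_mz.get("value")) if precursor_mz is not None else None
    charge = params.get("MS:1000041")
    charge = int(charge.get("value")) if charge is not None else None

    arrays: dict[str, np.ndarray] = {}
    for bda in list(elem.iter(f"{{{_MZML_NS}}}binaryDataArray")) + list(elem.iter("binaryDataArray")):
        bda_params = cv_params(bda)
        data = _decode_binary_array(bda)
        if "MS:1000514" in bda_params:
            arrays["mz"] = data
        elif "MS:1000515" in bda_params:
            arrays["intensity"] = data
    if "mz" not in arrays or "intensity" not in arrays:
        raise ValueError("missing m/z or intensity array")
    return Spectrum(
        arrays["mz"],
        arrays["intensity"],
        ms_level=level,
        rt=rt,
        precursor_mz=precursor_mz,
        precursor_charge=charge if level >= 2 else None,
        native_id=str(elem.get("id", "")),
    )


def _b64(array: np.ndarray) -> str:
    return base64.b64encode(struct.pack(f"<{array.size}d", *array)).decode()


def write_mzml(run: Run, path: str | Path) -> None:
    """Write a minimal index-free mzML (64-bit little-endian arrays,
    no compression) sufficient for standard readers."""
    lines = [
        '<?xml version="1.0" encoding="utf-8"?>',
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">',
        "  <cvList count=\"1\">",
        '    <cv id="MS" fullName="PSI-MS" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>',
        "  </cvList>",
        '  <run id="%s">' % (run.run_id or "run"),
        '    <spectrumList count="%d">' % len(run.spectra),
    ]
    for i, s in enumerate(run.spectra):
        sid = s.native_id or f"scan={i + 1}"
        lines.append(
            f'      <spectrum index="{i}" id="{sid}" defaultArrayLength="{len(s)}">'
        )
        lines.append(
            f'        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{s.ms_level}"/>'
        )
        lines.append(
            '        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>'
        )
        lines.append("        <scanList count=\"1\"><scan>")
        lines.append(
            f'          <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{s.rt}" unitName="second" unitCvRef="UO" unitAccession="UO:0000010"/>'
        )
        lines.append("        </scan></scanList>")
        if s.ms_level >= 2 and s.precursor_mz is not None:
            lines.append('        <precursorList count="1"><precursor>')
            lines.append('          <selectedIonList count="1"><selectedIon>')
            lines.append(
                f'            <cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="{s.precursor_mz}"/>'
            )
            if s.precursor_charge:
                lines.append(
                    f'            <cvParam cvRef="MS" accession="MS:1000041" name="charge state" value="{s.precursor_charge}"/>'
                )
            lines.append("          </selectedIon></selectedIonList>")
            lines.append("        </precursor></precursorList>")
        lines.append('        <binaryDataArrayList count="2">')
        for accession, name, arr in (
            ("MS:1000514", "m/z array", s.mz),
            ("MS:1000515", "intensity array", s.intensity),
        ):
            encoded = _b64(arr)
            lines.append(f'          <binaryDataArray encodedLength="{len(encoded)}">')
            lines.append(
                '            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>'
            )
            lines.append(
                '            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>'
            )
            lines.append(
                f'            <cvParam cvRef="MS" accession="{accession}" name="{name}" value=""/>'
            )
            lines.append(f"            <binary>{encoded}</binary>")
            lines.append("          </binaryDataArray>")
        lines.append("        </binaryDataArrayList>")
        lines.append("      </spectrum>")
    lines += ["    </spectrumList>", "  </run>", "</mzML>", ""]
    Path(path).write_text("\n".join(lines))
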