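"""Synthetic collagen databases and LC-MS runs with known ground truth.

Toy sequences are Gly-X-Y repeats (GPP/GPA-style motifs) with K/R
placed so that tryptic products mostly fall in the 6-45-residue range,
i.e. digest statistics resemble real collagen chains. Sibling species
differ by point substitutions at a configurable rate, including a
deliberate I/L-only difference between one sibling pair and one P->A
site mirroring the kind of single-residue variant that separates
underrepresented species from their database entries.

Simulated runs contain MS1 features (Gaussian elution, isotope
companion at +1.00335/z), b/y MS2 spectra with noise, MS3 z-radical
spectra with planted diagnostic side-chain losses, and decoy noise
features that never collide with any marker m/z — so recall and
false-positive rates of every downstream module are measurable exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ilcall import ILE_LOSS, LEU_LOSS, z_target_for_residue
from .markers import marker_table
from .massdigest import (
    ISOTOPE_SPACING,
    PROTON,
    Peptidoform,
    format_modform,
    mz as compute_mz,
)
from .refdb import ReferenceDatabase, SequenceRecord, TaxonNode, Taxonomy, write_fasta
from .spectra import Run, Spectrum, theoretical_fragments

__all__ = ["SyntheticRunConfig", "make_toy_db", "simulate_run", "simulate_psms"]

_XY_RESIDUES = list("PASVETDQNLIFH")
_XY_WEIGHTS = np.array([0.30, 0.18, 0.06, 0.06, 0.08, 0.05, 0.05, 0.05, 0.05, 0.04, 0.03, 0.03, 0.02])
_SUB_TARGETS = list("ASVETDQNLIFH")  # never G/K/R/P: digestion sites stay fixed


@dataclass
class SyntheticRunConfig:
    """Everything that defines one synthetic study, keyed by one seed."""

    seed: int = 0
    # taxonomy: 2 families -> 3 genera -> 6 species
    n_families: int = 2
    n_genera: int = 3
    n_species: int = 6
    chain_triplets: int = 100  # ~300 residues per chain
    substitution_rate: float = 0.02
    planted_taxon: str = "sp1"
    n_markers: int = 10
    charges: tuple[int, ...] = (2, 3)
    rt_range: tuple[float, float] = (120.0, 1080.0)
    scan_interval_s: float = 5.0
    elution_sigma_s: float = 6.0
    marker_intensity: float = 1000.0
    isotope_ratio: float = 0.6
    deamidation_fraction: float = 0.3
    decoy_features: int = 200
    intensity_sigma: float = 0.5  # lognormal sigma of feature intensities
    mz_jitter_ppm: float = 2.0
    rt_jitter_s: float = 5.0
    n_ms2_per_marker: int = 3
    ms2_noise_peaks: int = 30
    ms3_diagnostic_snr: float = 8.0
    degradation: float = 0.0  # fraction of markers with suppressed MS2

    def __post_init__(self) -> None:
        if not 0.0 < self.substitution_rate <= 0.1:
            raise ValueError("substitution_rate must lie in (0, 0.1]")
        if not 0.0 <= self.degradation <= 1.0:
            raise ValueError("degradation must lie in [0, 1]")
        if not 0.0 <= self.deamidation_fraction <= 1.0:
            raise ValueError("deamidation_fraction must lie in [0, 1]")


def _root_chain(rng: np.random.Generator, n_triplets: int) -> str:
    """A collagen-like Gly-X-Y chain with tryptic sites every 3-12 triplets."""
    triplets: list[str] = []
    next_cut = int(rng.integers(3, 9))
    for i in range(n_triplets):
        x = rng.choice(_XY_RESIDUES, p=_XY_WEIGHTS / _XY_WEIGHTS.sum())
        if i == next_cut:
            y = "R" if rng.random() < 0.6 else "K"
            next_cut += int(rng.integers(3, 13))
        else:
            y = rng.choice(_XY_RESIDUES, p=_XY_WEIGHTS / _XY_WEIGHTS.sum())
        triplets.append("G" + str(x) + str(y))
    # end on a basic residue so the C-terminal peptide is tryptic
    last = triplets[-1]
    triplets[-1] = last[:2] + "R"
    return "".join(triplets)


def _mutate(rng: np.random.Generator, sequence: str, rate: float) -> str:
    """Point-substitute non-structural residues (never G/K/R/P) at ``rate``."""
    seq = list(sequence)
    mutable = [i for i, r in enumerate(seq) if r not in "GKRP"]
    n_subs = rng.binomial(len(mutable), rate)
    for i in rng.choice(mutable, size=min(n_subs, len(mutable)), replace=False):
        choices = [r for r in _SUB_TARGETS if r != seq[i]]
        seq[i] = str(rng.choice(choices))
    return "".join(seq)


def _toy_taxonomy(n_species: int = 6) -> Taxonomy:
    """2 families / 3 genera / ``n_species`` species under one root clade."""
    nodes = [TaxonNode("root", "Eutheria", "clade", None)]
    nodes += [
        TaxonNode("fam1", "FamilyA", "family", "root"),
        TaxonNode("fam2", "FamilyB", "family", "root"),
        TaxonNode("gen1", "GenusA", "genus", "fam1"),
        TaxonNode("gen2", "GenusB", "genus", "fam1"),
        TaxonNode("gen3", "GenusC", "genus", "fam2"),
    ]
    genera = ["gen1", "gen1", "gen2", "gen2", "gen3", "gen3"]
    for i in range(n_species):
        nodes.append(
            TaxonNode(f"sp{i + 1}", f"Species{i + 1}", "species", genera[i % 6])
        )
    return Taxonomy(nodes)


def make_toy_db(
    config: SyntheticRunConfig,
    out_dir: str | Path | None = None,
) -> tuple[ReferenceDatabase, pd.DataFrame]:
    """Generate the toy database and its by-construction marker truth table.

    Species evolve from per-genus ancestors which evolve from per-family
    ancestors; two chains (COL1A1/COL1A2) per species. sp1/sp2 carry a
    guaranteed I/L-only difference; sp5's COL1A2 carries a P->A variant
    relative to its sibling. The truth table is the exhaustive
    species-rank marker scan of the generated database.

    When ``out_dir`` is given, FASTA, taxonomy TSV and the truth table
    are written there.
    """
    rng = np.random.default_rng(config.seed)
    taxonomy = _toy_taxonomy(config.n_species)

    family_of = {"gen1": "fam1", "gen2": "fam1", "gen3": "fam2"}
    records: list[SequenceRecord] = []
    for chain in ("COL1A1", "COL1A2"):
        root_seq = _root_chain(rng, config.chain_triplets)
        fam_seq = {
            fam: _mutate(rng, root_seq, config.substitution_rate)
            for fam in ("fam1", "fam2")
        }
        gen_seq = {
            gen: _mutate(rng, fam_seq[family_of[gen]], config.substitution_rate)
            for gen in ("gen1", "gen2", "gen3")
        }
        species_seq: dict[str, str] = {}
        for leaf in sorted(taxonomy.leaves(), key=lambda n: n.id):
            species_seq[leaf.id] = _mutate(
                rng, gen_seq[leaf.parent], config.substitution_rate
            )
        if chain == "COL1A1":
            # plant an I/L-only contrast between siblings sp1 and sp2
            il_pos = _plant_il_pair(rng, species_seq)
        if chain == "COL1A2" and "sp5" in species_seq:
            # plant a single P->A variant in sp5 (sibling sp6 keeps P)
            seq = species_seq["sp5"]
            p_sites = [i for i, r in enumerate(seq) if r == "P" and 30 < i < len(seq) - 30]
            if p_sites:
                i = int(rng.choice(p_sites))
                species_seq["sp5"] = seq[:i] + "A" + seq[i + 1 :]
        for sid, seq in species_seq.items():
            records.append(
                SequenceRecord(
                    accession=f"{sid}_{chain}",
                    chain=chain,
                    taxon=sid,
                    sequence=seq,
                    source=f"synthetic {chain} of {taxonomy[sid].name}",
                )
            )

    db = ReferenceDatabase(records, taxonomy)
    truth = marker_table(db)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(db.records, out / "toy_db.fasta")
        _write_taxonomy_tsv(db, out / "toy_taxonomy.tsv")
        truth.to_csv(out / "truth_markers.tsv", sep="\t", index=False)
    return db, truth


def _plant_il_pair(rng: np.random.Generator, species_seq: dict[str, str]) -> int:
    """Force sp1/sp2 to agree everywhere except one I-vs-L residue."""
    if not {"sp1", "sp2"} <= species_seq.keys():
        return -1
    base = species_seq["sp1"]
    mutable = [i for i, r in enumerate(base) if r not in "GKRP" and 10 < i < len(base) - 10]
    pos = int(rng.choice(mutable))
    species_seq["sp1"] = base[:pos] + "I" + base[pos + 1 :]
    species_seq["sp2"] = base[:pos] + "L" + base[pos + 1 :]
    return pos


def _write_taxonomy_tsv(db: ReferenceDatabase, path: Path) -> None:
    rows = []
    for rec in db.records:
        node = db.taxonomy[rec.taxon]
        rows.append(
            {
                "accession": rec.accession,
                "taxon_id": node.id,
                "taxon_name": node.name,
                "rank": node.rank,
                "parent_id": node.parent or "",
                "chain": rec.chain,
            }
        )
    for node in db.taxonomy.nodes.values():
        if node.rank != "species":
            rows.append(
                {
                    "accession": "",
                    "taxon_id": node.id,
                    "taxon_name": node.name,
                    "rank": node.rank,
                    "parent_id": node.parent or "",
                    "chain": "",
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _select_markers(
    truth: pd.DataFrame, config: SyntheticRunConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Pick the planted markers: distinct mid-length species-rank
    sequences of the planted taxon, preferring fully tryptic peptides
    and topping up with semi-tryptic ones."""
    pool = truth[
        (truth["taxon"] == config.planted_taxon)
        & (truth["rank"] == "species")
        & (truth["sequence"].str.len().between(8, 32))
    ].drop_duplicates("sequence")
    if len(pool) == 0:
        raise ValueError(
            f"no species-rank markers available for {config.planted_taxon!r}"
        )
    full = pool[pool["specificity"] == "full"]
    semi = pool[pool["specificity"] != "full"]
    picked = []
    for segment in (full, semi):
        remaining = config.n_markers - len(picked)
        if remaining <= 0:
            break
        n = min(remaining, len(segment))
        if n:
            idx = rng.choice(len(segment), size=n, replace=False)
            picked.append(segment.iloc[sorted(idx)])
    return pd.concat(picked).reset_index(drop=True)


def simulate_run(
    db: ReferenceDatabase,
    truth: pd.DataFrame,
    config: SyntheticRunConfig,
) -> tuple[Run, dict[str, pd.DataFrame]]:
    """Simulate one LC-MS run of the planted taxon over the toy database.

    Returns the run plus truth tables: ``features`` (one row per planted
    marker: modform, charge, m/z, RT, intensity, MS2 suppression),
    ``ms3_targets`` (interrogated I/L positions with the planted loss)
    and ``decoys``.
    """
    if config.planted_taxon not in db.taxonomy:
        raise KeyError(f"planted taxon {config.planted_taxon!r} not in database")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    markers = _select_markers(truth, config, rng)

    lo_rt, hi_rt = config.rt_range
    n_suppressed = int(round(config.degradation * len(markers)))
    suppressed_idx = set(
        rng.choice(len(markers), size=n_suppressed, replace=False).tolist()
    )

    feature_rows = []
    for i, row in markers.iterrows():
        pf = Peptidoform(row["sequence"])
        charge = int(rng.choice(list(config.charges)))
        theo = compute_mz(pf, charge)
        jitter = theo * config.mz_jitter_ppm * 1e-6
        feature_rows.append(
            {
                "sequence": row["sequence"],
                "modform": format_modform(pf),
                "taxon": config.planted_taxon,
                "charge": charge,
                "theoretical_mz": theo,
                "observed_mz": theo + rng.normal(0.0, jitter / 2),
                "rt": float(rng.uniform(lo_rt + 60, hi_rt - 60)),
                "intensity": float(
                    config.marker_intensity * rng.lognormal(0.0, config.intensity_sigma)
                ),
                "ms2_suppressed": i in suppressed_idx,
            }
        )
    features = pd.DataFrame(feature_rows)

    # decoy features: avoid every marker-query m/z in the whole database
    # within twice the matching tolerance, so false positives are real
    forbidden = _forbidden_mz(db, truth, config)
    decoy_rows = []
    while len(decoy_rows) < config.decoy_features:
        m = float(rng.uniform(400.0, 1500.0))
        if np.any(np.abs(forbidden - m) < forbidden * 40e-6):
            continue
        decoy_rows.append(
            {
                "observed_mz": m,
                "rt": float(rng.uniform(lo_rt, hi_rt)),
                "intensity": float(200.0 * rng.lognormal(0.0, config.intensity_sigma)),
                "charge": int(rng.integers(1, 5)),
                "has_isotope": bool(rng.random() < 0.5),
            }
        )
    decoys = pd.DataFrame(decoy_rows)

    spectra: list[Spectrum] = []
    scan_times = np.arange(lo_rt, hi_rt, config.scan_interval_s)
    sig = config.elution_sigma_s
    for t in scan_times:
        mzs: list[float] = []
        ints: list[float] = []
        for row in features.itertuples(index=False):
            frac = np.exp(-0.5 * ((t - row.rt) / sig) ** 2)
            if frac < 0.01:
                continue
            height = row.intensity * frac
            mzs += [row.observed_mz, row.observed_mz + ISOTOPE_SPACING / row.charge]
            ints += [height, height * config.isotope_ratio]
        for row in decoys.itertuples(index=False):
            frac = np.exp(-0.5 * ((t - row.rt) / sig) ** 2)
            if frac < 0.01:
                continue
            mzs.append(row.observed_mz)
            ints.append(row.intensity * frac)
            if row.has_isotope:
                mzs.append(row.observed_mz + ISOTOPE_SPACING / row.charge)
                ints.append(row.intensity * frac * config.isotope_ratio)
        spectra.append(
            Spectrum(np.array(mzs), np.array(ints), ms_level=1, rt=float(t),
                     native_id=f"ms1_rt{t:.0f}")
        )

    # MS2: b/y spectra near each unsuppressed marker apex
    ms3_rows = []
    for k, row in enumerate(features.itertuples(index=False)):
        pf = Peptidoform(row.sequence, charge=row.charge)
        if not row.ms2_suppressed:
            frags = theoretical_fragments(pf, ("b", "y"), max_charge=1)
            for j in range(config.n_ms2_per_marker):
                frag_mz = np.array([f.theoretical_mz for f in frags])
                frag_int = 500.0 * rng.lognormal(0.0, 0.3, size=frag_mz.size)
                noise_mz = rng.uniform(50.0, 2000.0, size=config.ms2_noise_peaks)
                noise_int = 20.0 * rng.lognormal(0.0, 0.5, size=config.ms2_noise_peaks)
                spectra.append(
                    Spectrum(
                        np.concatenate([frag_mz, noise_mz]),
                        np.concatenate([frag_int, noise_int]),
                        ms_level=2,
                        rt=row.rt + rng.normal(0.0, 2.0),
                        precursor_mz=row.observed_mz,
                        precursor_charge=row.charge,
                        native_id=f"ms2_{k}_{j}",
                    )
                )
        il_positions = [
            p for p, r in enumerate(row.sequence, start=1) if r in "IL" and p > 1
        ]
        if il_positions:
            pos = int(rng.choice(il_positions))
            residue = row.sequence[pos - 1]
            target = z_target_for_residue(pf, pos, charge=1)
            loss = ILE_LOSS if residue == "I" else LEU_LOSS
            base_noise = 50.0
            diag = base_noise * config.ms3_diagnostic_snr
            noise_mz = rng.uniform(
                max(50.0, target.theoretical_z_mz - 60),
                target.theoretical_z_mz + 10,
                size=20,
            )
            noise_int = base_noise * rng.lognormal(0.0, 0.3, size=20)
            spectra.append(
                Spectrum(
                    np.concatenate(
                        [noise_mz, [target.theoretical_z_mz, target.theoretical_z_mz - loss]]
                    ),
                    np.concatenate([noise_int, [diag * 2, diag]]),
                    ms_level=3,
                    rt=row.rt + rng.normal(0.0, 2.0),
                    precursor_mz=target.theoretical_z_mz,
                    precursor_charge=1,
                    native_id=f"ms3_{k}",
                )
            )
            ms3_rows.append(
                {
                    "native_id": f"ms3_{k}",
                    "sequence": row.sequence,
                    "position": pos,
                    "residue": residue,
                    "z_index": target.z_index,
                    "z_mz": target.theoretical_z_mz,
                }
            )

    spectra.sort(key=lambda s: (s.rt, s.ms_level, s.native_id))
    run = Run(spectra, run_id=f"synthetic_seed{config.seed}")
    return run, {"features": features, "decoys": decoys, "ms3_targets": pd.DataFrame(ms3_rows)}


def _forbidden_mz(
    db: ReferenceDatabase, truth: pd.DataFrame, config: SyntheticRunConfig
) -> np.ndarray:
    """m/z values decoys must avoid: every species-rank marker sequence of
    every taxon at every configured charge."""
    out = []
    for seq in truth["sequence"].unique():
        for z in config.charges:
            out.append(compute_mz(Peptidoform(seq), z))
    return np.array(sorted(out)) if out else np.array([])


def simulate_psms(
    true_fraction: float,
    n_psms: int = 100,
    seed: int = 0,
    protein: str = "sp1_COL1A1",
    intensity_sigma: float = 1.0,
) -> pd.DataFrame:
    """Simulate a PSM table for deamidation-profile recovery tests.

    Each PSM covers one of a handful of Q-containing peptides; each Q
    site is deamidated independently with probability ``true_fraction``;
    intensities are lognormal.
    """
    rng = np.random.default_rng(seed)
    peptides = [
        ("GPQGAAGVR", 101),
        ("GAQGPPGATGFPGAAGR", 201),
        ("GPSGPQGPSGAPGPK", 301),
        ("GEQGPAGSPGFQGLPGPAGPPGEAGK", 401),
        ("GAAGQPGAKGER", 501),
        ("GLQGLPGTGGPPGENGKPGEPGPK", 601),
        ("GDAGAQGAPGSQGAPGLQGMPGER", 701),
        ("GFSGLQGPPGPPGSPGEQGPSGASGPAGPR", 801),
    ]
    rows = []
    for _ in range(n_psms):
        seq, start = peptides[int(rng.integers(0, len(peptides)))]
        mods = []
        for i, r in enumerate(seq, start=1):
            if r == "Q" and rng.random() < true_fraction:
                mods.append((i, "deamidation"))
        pf = Peptidoform(seq, tuple(mods))
        rows.append(
            {
                "peptidoform": format_modform(pf),
                "protein": protein,
                "start": start,
                "intensity": float(rng.lognormal(10.0, intensity_sigma)),
            }
        )
    return pd.DataFrame(rows)
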