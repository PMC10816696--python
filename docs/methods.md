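# Methods

## The identification problem

Collagen type I makes up ~90% of the organic fraction of dentin and
bone. Its Gly-X-Y triple-helical repeat is strongly conserved, so two
species typically differ at only a few residues per chain; tryptic
peptides covering those residues are the taxonomic markers. Three
complications shape the design of this package:

1. **Isobaric ambiguity.** Ile and Leu have identical mass, and a
   deamidated Asn (Gln) is mass-identical to Asp (Glu). A peptide that
   looks species-specific can collapse onto another species under these
   equivalences, so marker validation must search under them explicitly.
2. **Heterogeneous modification.** Collagen is heavily hydroxylated at
   proline (mass-equivalent to oxidation, +15.994915 Da) and ancient
   collagen accumulates deamidation (+0.984016 Da); one marker region is
   usually observed as many peptidoforms with missed and semi-tryptic
   cleavages.
3. **Degradation.** Old or poorly preserved objects yield weak MS2
   spectra, or none; identification must degrade gracefully from
   sequence-level evidence to precursor-only evidence.

## Mass arithmetic

Monoisotopic residue masses throughout; peptide neutral mass is the
residue sum plus water (18.010565 Da); ions are protonated
(m/z = (M + z·1.0072765)/z). The modification search space defaults to
fixed carbamidomethyl-C and variable oxidation (M, P) and deamidation
(N, Q), at most five variable modifications per peptide. These defaults
mirror standard search settings for ancient collagen. Matching
tolerances default to 10 ppm (precursor) and 0.02 Da (fragment).

Digestion follows the classic trypsin rule (cleave after K/R, not
before P; the proline block can be disabled since search engines differ
in dialect). Semi-specific digestion admits exactly one non-enzymatic
terminus. Digest correctness is tested against a brute-force substring
enumeration of the terminus/missed-cleavage predicates. Marker-level
scans bound peptide length to 6–45 residues; identified collagen
markers in practice span roughly 16–33.

## Marker validation

Matching is substring containment, not alignment: a tryptic peptide is
an exact subsequence of its source chain, so containment answers the
in-scope question exactly and replaces a manual BLAST check. The
deamidation equivalence (N≍D, Q≍E) is applied only at positions that
actually carry a deamidation in the query peptidoform — matching the
control of substituting the observed deamidated residue before
re-searching — never globally. Specificity is the rank of the LCA of
every taxon matched under the exact scheme and all control schemes; a
marker is valid for a claimed rank only if that LCA is at or below it.
Two monotonicity properties are enforced by tests: growing the database
never shrinks a match set, and enabling an equivalence never shrinks
one (hence the set of valid species markers never grows).

Reports tally both distinct base sequences and distinct peptidoforms:
modification and cleavage variants inflate peptide counts, so
assignments are driven by distinct sequences.

## MS2 annotation and summing

Theoretical b/y (HCD) and c/z• (ETD) series carry positioned
modifications; the z series uses the radical convention (one hydrogen
heavier than the even-electron z ion). Annotation greedily matches each
theoretical ion to the nearest peak within the fragment tolerance (ties:
smaller |error|, then higher intensity). Backbone coverage is the
fraction of the n−1 inter-residue bonds supported by at least one
matched ion; "fully fragmented" corresponds to coverage 1.0.

Spectral summing pools the peaks of replicate spectra of one targeted
precursor and clusters them by single-linkage with a 0.01 Da bin
tolerance; a cluster reports the intensity-weighted mean m/z and the
summed intensity, conserving total ion current exactly. The binning
constant is a declared choice (summing is sometimes done ad hoc in
plotting software; no standard exists). SNR is the target peak intensity
over the median intensity of peaks within ±2 Da (excluding the
tolerance window), with a floor of 1.0 against empty flanks.

## MS3 Leu/Ile calling

For an I/L at position p of an n-residue peptide, the interrogated
fragment is z•(n−p+1) — the C-terminal radical fragment whose N-terminal
residue is the one in question. (Position 1 cannot be interrogated: the
full-length "fragment" is the charge-reduced precursor.) HCD of that
radical ejects part of the side chain; the lost radical is ethyl
(•C₂H₅, 29.039125 Da) for Ile and propyl (•C₃H₇, 43.054775 Da) for Leu,
the nominal 29/43 Da losses. Replicate MS3 spectra of one z• precursor
are averaged (cluster intensity = mean, so averaging replicates of one
spectrum is the identity); averaging centroided peaks is a declared
choice.

The caller searches the two loss positions (divided by the precursor
charge for multiply charged species) within the fragment tolerance and
computes both peaks' SNR against a single shared noise floor — the
median intensity over both ±2 Da diagnostic regions excluding both
tolerance windows. A shared floor makes the decision rule exactly
symmetric under relabeling the planted loss, which per-peak flanks are
not. The dominant loss is called when its SNR ≥ 3 and it exceeds the
competing loss ≥ 3-fold; otherwise `ambiguous`; no peak at either
position is `no_signal` (a result, not an error — expected from degraded
material). Both thresholds are exposed on the CLI; they are design
defaults, since manual expert reading has no published threshold.

## LC-MS PMF

An extracted ion chromatogram sums, per MS1 spectrum, the intensity
within ±10 ppm of the query m/z. A marker matches when (i) the EIC has
an apex within the RT window (default 60 s, a declared default) of the
reference RT from a same-batch exemplar run, and (ii) the apex MS1
spectrum shows the expected charge via an isotope companion at
+1.00335/z within the fragment tolerance. A single scalar RT offset
(median shift of confidently matched markers) can align runs; full RT
warping is out of scope. EICs may legitimately contain several peaks
(positional isomers of one modified peptide), so the peak count is
reported. A taxon is assigned when its distinct matched sequences reach
the minimum (default 5) and lead the runner-up by the margin (default
2); ties yield no assignment. Matching is monotone in both tolerances.

## The identification ladder

Tier 1 accepts markers confirmed by an MS2 spectrum with backbone
coverage ≥ 0.5; tier 2 retries failed markers on summed replicate MS2
spectra, requiring the precursor within 10 ppm plus ≥ 3 matched
fragment ions; tier 3 is PMF. The first tier that clears its threshold
supplies the assignment. Species calls need 5 distinct sequences
(margin 2); when species evidence is thin or conflicting, the
assignment falls back to the LCA of the evidenced taxa, which needs
only 3 (genus) or 2 (family) distinct sequences — coarser calls rest on
fewer distinct regions in practice. All thresholds are configurable and
embedded in the report for provenance. A completed analysis always
exits 0; "none" is a reported outcome.

## Q-deamidation profile

Per protein site, modified and unmodified intensities are accumulated
over every PSM covering that Q; the site fraction is
modified/(modified+unmodified), undefined (flagged) at zero total. The
sample summary is the intensity-weighted mean — equivalently total
modified over total intensity — with a count-weighted mode for
sensitivity analysis. Asn deamidation is tracked for mass math but
excluded from the profile: the age-correlated signal in collagen is
glutamine-specific. Uncertainty comes from a site-level percentile
bootstrap (default 1000 replicates, seeded). The profile orders samples
relatively; it is not an absolute dating model.

## Synthetic data: what it emulates, and what it does not

The generator builds Gly-X-Y repeat chains (~300 residues, X/Y drawn
with proline-rich weights, K/R spaced to give mostly 6–45-residue
tryptic products), evolves them down a fixed 2-family / 3-genus /
6-species taxonomy at a 2% per-branch substitution rate (substitutions
never touch G/K/R/P, so cleavage structure is constant), and plants two
deliberate contrasts: an I/L-only difference between siblings sp1/sp2
(so their COL1A1 yields no valid species markers once I≍L) and a single
P→A variant in sp5's COL1A2 — the kind of single-residue database
correction that exemplar specimens provide for underrepresented
species.

Simulated runs contain: MS1 scans every 5 s over a 120–1080 s window
with Gaussian elution (σ = 6 s), each planted marker with its
+1.00335/z isotope companion; 200 decoy features whose m/z avoids every
species-marker query m/z in the database by at least twice the matching
tolerance (so false-positive counts are interpretable); complete b/y
MS2 spectra with 30 uniform noise peaks, suppressed for a configurable
fraction of markers (the degradation level); and MS3 z• spectra with
the correct 29/43 Da loss planted at SNR 8 over a 20-peak noise floor.
One seed fixes all randomness end to end.

Not emulated: chromatographic peak shape beyond a Gaussian, isotope
envelopes beyond the first companion, charge-state coexistence,
co-isolation/chimeric MS2, systematic RT drift, and real cross-species
collagen homology structure. Passing the synthetic end-to-end tests
therefore demonstrates the correctness of the decision logic and the
tolerance handling, not the empirical error rate on real degraded
samples.

Problem sizes used by the test suite (toy chains of ~300 residues, 10
planted markers, 200 decoys, 20-seed false-positive sweeps, 25-seed
deamidation recovery at 100 PSMs) were chosen as the smallest scales at
which the planted effects are unambiguous.

## Numerical and degenerate-input choices

- Peptide positions are 1-based in all user-facing tables; record
  coordinates are local to the stored FASTA sequence (public-database
  coordinate frames are inconsistent, so variant edits carry their
  frame in the evidence field and check the reference residue before
  applying).
- Non-canonical residues (B, J, O, U, X, Z) are rejected at load with a
  per-record reject report, never silently dropped: marker logic needs
  exact residue identity.
- Coincident centroids within one spectrum are merged on construction
  so m/z stays strictly ascending.
- The mzML reader is a direct streaming parser over the schema
  (64/32-bit float arrays, optional zlib); the mzML writer emits
  index-free 64-bit uncompressed documents.
- `sum_spectra` of one spectrum is the identity; `average_ms3` of n
  replicates of one spectrum is that spectrum.

## Known limitations

- No statistical scoring of markers (no FDR, no E-values): validation
  is exact set logic over a user-supplied database, and is only as good
  as that database's coverage.
- PMF matching trusts the reference RT; between-batch comparisons need
  the scalar offset at minimum and may still be wrong under nonlinear
  drift.
- The I/L caller assumes the diagnostic loss chemistry proceeds; some
  sequence contexts fragment poorly and will legitimately return
  `no_signal` or `ambiguous`.
- Observed caption-style ppm values from vendor software are not
  reproducible in general because the software's theoretical reference
  is not stated; this package reports its own theoretical values and
  checks observed agreement at the 10 ppm parent tolerance.
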