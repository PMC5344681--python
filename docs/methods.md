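# Methods

## Mass model

All masses derive from a single pinned table of monoisotopic atomic masses
(NIST/CODATA, ≥5 decimals: H 1.00782503, C 12, N 14.00307400, O
15.99491462, P 30.97376163, S 31.97207100; proton 1.00727647). Residue
masses are computed from elemental compositions, never transcribed.
Comparisons against printed ion values are made at 4 decimal places.

The ADP-ribose modification is C₁₅H₂₁N₅O₁₃P₂ (+541.06111 Da). Its five
collisional neutral losses — adenine, adenosine − H₂O, AMP, ADP and the
complete ADP-ribose — are stored as compositions; the corresponding
printed reporter values are the protonated masses of the lost species
(printed − 1.00728 is the neutral loss applied to a fragment). Two
phosphoribose species are provided: the gas-phase AMP-loss remainder
(+193.99802 Da, C₅H₇O₆P) and the Nudix-hydrolysis product (+212.00859 Da,
C₅H₉O₇P — hydrolysis adds water). Which of the two a variable-modification
search uses is a config choice (`species:`); the gas-phase remainder is
what HCD fragments of an intact ADPr peptide exhibit, the Nudix mass is
for solution-phase-converted samples.

Fragment conventions: b/y for HCD, c/z for ETD; c = b + NH₃ (17.02655),
z = y − NH₂ (16.01872, the z-dot radical convention), singly protonated
baseline with higher charges as (M + zH⁺)/z. ETD emits
modification-spanning fragments exclusively in the intact state (the
electron-transfer reaction does not mobilize the ester linkage); HCD emits
three states per spanning fragment — intact, phosphoribose remainder and
full loss — plus the standalone adenine diagnostic ion. a/x ions, internal
fragments and poly-ADP-ribose chains are out of scope.

SILAC Lys8 is computed, not hard-coded: 6·(¹³C−¹²C) + 2·(¹⁵N−¹⁴N) =
8.01420 Da.

## Digestion

Trypsin cleaves after K/R; the proline rule (suppression before P) is a
flag because the two search styles differ on it: the site-localization
digest uses up to 5 missed cleavages, minimum length 6, proline rule on
(long multi-missed-cleavage peptides emulate a brief partial-FASP digest);
the localization-free digest uses 3 missed cleavages and no proline rule.
Coordinates are 1-based, closed intervals; the initiator methionine is not
clipped by default (configurable); I and L are distinct throughout.

## Synthetic spectra

The generator produces the statistical structure the analysis assumes and
nothing more. Base fragment intensities follow a smooth deterministic arch
over the ladder (mid-sequence ions strongest); no instrument intensity
model is claimed. Noise is four orthogonal, individually seeded effects:
Bernoulli fragment dropout, Gaussian multiplicative m/z jitter (ppm),
Gaussian intensity variation (CV), and uniform chemical-noise peaks that
are rejected within 25 ppm of any true fragment position so that noise
never impersonates signal. A zero-noise model reproduces the exact
theoretical peak list, which is what makes the generator usable as an
oracle in round-trip tests. Diagnostic adenine ions are placed at 1.2× the
strongest fragment, operationalizing "among the strongest signals" as
top-decile placement. MS1 SILAC clusters are simplified to three
isotopologue peaks with fixed 1.0/0.5/0.2 envelope; ratio arithmetic sums
the cluster, so envelope realism is irrelevant to what is tested. Real
acquisitions differ in ways the generator does not model — co-isolation,
charge-reduced ETD precursor survival, elution profiles, detector
saturation — so passing tests demonstrate correctness of the computation,
not instrument-level performance.

Single-channel SILAC cases are generated with ratio 0 (light-only) or ∞
(heavy-only), emulating peptides whose modification vanishes entirely in a
knockout background.

## Searching

Spectra are first reduced to the top 20 peaks per 100 Da window (windows
anchored at the lowest m/z). The PSM score is the Morpheus convention —
matched-product count plus matched-intensity fraction — chosen because it
is deterministic, monotone in matched peaks, and trivially auditable;
absolute values are engine-specific, so nothing downstream interprets the
scale, only rankings and thresholds calibrated on the synthetic suite.
Peak assignment is one-to-one: each theoretical ion takes at most the
nearest unused peak within tolerance, ascending m/z order, which makes
scores reproducible to the bit.

Localization-free mode implements the labile C-terminal modifier: the tag
adds to the precursor mass while the fragment hypothesis is that of the
stripped peptide (plus the diagnostic ion for HCD), so each candidate
peptide contributes exactly two hypotheses — the property that makes this
mode nearly as cheap as an unmodified search. A counter on the result
object verifies the 2-per-candidate contract.

Variable-modification mode enumerates placements on DEKRSTCYNQHM up to a
per-peptide cap (default 1 modification, 5000 hypotheses; over-cap
peptides are skipped with a warning). Precursor matching allows the
isotopic assignment to be off by up to 3 × 1.00336 (configurable);
residual ppm error is reported after offset correction. Ties break by
|ppm|, then modification count, then sequence. Defaults: 4.5 ppm
precursor / 20 ppm fragment (localization searches), 10/10 ppm
(localization-free), maximum charge 7. No target-decoy FDR machinery is
included: confidence is threshold-based by design.

## Localization probability

Every candidate placement is rescored against the spectrum using only
admissible evidence: all c/z ions for ETD; for HCD only fragments still
carrying the intact ADP-ribose or its phosphoribose remainder, because a
peak at unmodified fragment mass cannot distinguish an original lack of
modification from complete loss during fragmentation and is therefore
disregarded.

For placement *i* with *k* of *n* admissible ions matched, the match score
is −log₁₀ P(X ≥ k), X ~ Binomial(n, p), with p the probability that a
random peak lands within the fragment tolerance (estimated from the
spectrum's peak density, clipped to [10⁻⁵, 0.3]). The tail is evaluated
term-by-term in log space (a complete ladder of a long peptide sits
hundreds of orders of magnitude below the survival function's floating
point range). Site probabilities are the normalized likelihood weights
10^score. This construction was chosen over a raw score ratio because
candidate placements share most backbone ions: a plain ratio of Morpheus
scores saturates near 1/k even for a complete unambiguous ladder, whereas
the binomial weight concentrates on the placement the discriminating ions
support, is exactly uniform when no discriminating evidence exists
(including full-loss-only spectra), and is monotone in matched evidence.
It is intentionally a probability in the PTM-score family, not a
re-implementation of any specific engine's score.

Site-determining ions are counted pairwise: modification-carrying ions
(intact or phosphoribose state) whose theoretical m/z differs between two
placements and which match a peak. A candidate's reported support is the
*minimum* over all pairwise competitors — a site is pinpointed only if it
is distinguished from every alternative.

Serine validation passes when (a) at least one matched
intact/phosphoribose ion pinpoints the serine, (b) at least 2 such ions
have ≥5% of base-peak intensity ("multiple high-intensity ions", both
configurable), and (c) localization probability ≥ 0.9. Confidence
filtering keeps PSM score ≥ 10 (calibrated on the synthetic suite so that
all zero-noise true identifications pass and shuffled-sequence matches
fail; engine score cutoffs do not transfer across engines), |Δppm| < 3 and
probability > 0.9.

## SILAC quantification

Channel intensities are summed over the three-peak cluster; H/L ratio and
log₂ ratio are computed only when both channels are positive. Silent
channels propagate a sentinel state (`heavy_only` / `light_only` /
`neither`) through the ratio-versus-intensity table — single-channel rows
are flagged, never dropped and never assigned an arbitrary capped ratio.
A `max labeled residues = 7` filter on lysine count is available.

## Enrichment statistics

The N-terminal comparison tallies the first residue of each unique peptide
in the modified and unmodified sets, normalizes within set, and reports
(freq_mod + pc)/(freq_unmod + pc) with pseudocount 1/20 applied on the
frequency scale so empty classes stay finite and the ratio is invariant
under duplicating both sets. The motif summary flags sites whose preceding
protein residue is K or R (position 1 has no predecessor and is False).
No p-values are computed — the outputs are descriptive ratios; GO
enrichment is delegated to external tools that consume the emitted
gene/site lists.

## Problem sizes and determinism

Default test and demo problem sizes are deliberately desk-scale: a
four-protein demo database, eight simulated spectra per pipeline run, 200
spectra for the noisy-recovery property (20% dropout, 5 ppm jitter; the
observed recovery is 100%), 100 seeds for SILAC ratio recovery. All
randomness flows through explicit integer seeds; identical seed + config
yield byte-identical MGF/TSV outputs, which the test suite asserts with
file comparison.

## Known limitations

Single mobile modification per localization (multiple simultaneous ADPr
sites are searched but not jointly localized); no FDR estimation; no mzML
or vendor raw input (MGF only); MS1 feature detection/XIC tracing is out
of scope — SILAC quantification starts from channel intensities; the
localization probability is package-specific and should not be compared
numerically against other engines' localization scores.
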