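# Methods

This note documents the models behind each module, the defaults and why
they were chosen, the numerical choices, and what the synthetic
benchmarks do and do not demonstrate.

## Physicochemical features

Charge follows the Henderson–Hasselbalch model per titratable group with
the EMBOSS pKa set (N-terminus 8.6, C-terminus 3.6, K 10.8, R 12.5,
H 6.5, D 3.9, E 4.1, C 8.5, Y 10.1).  A basic group contributes
`+1/(1+10^(pH−pKa))`, an acidic group `−1/(1+10^(pKa−pH))`.  Because the
free termini always supply one acid and one base, the net charge is
strictly decreasing in pH and the isoelectric point is the unique root
on [0, 14]; it is found by bisection to a fixed 10⁻⁶ pH resolution,
which also guarantees `|net_charge(pI)| < 10⁻³`.  Cysteine and tyrosine
are titratable for pI purposes but are not counted as electrostatic (ζ)
residues.  Hydropathy is the Kyte–Doolittle scale; GRAVY is its plain
mean.  The hydrophobic class Φ is {A,V,L,I,M,F,W,Y} and the charged
class ζ is {D,E,K,R}; histidine sits in neither by default (it is only
~10% protonated at pH 7) but can be added to ζ via configuration.
Unknown residues (X) are invisible to charge and hydropathy but count
toward length — a declared convention, not an approximation claim.

## Tandem-repeat detection

The detector targets substitution-diverged tandem repeats with unit
length 20–120 residues, the spacing compatible with cross-linking
adjacent Rubisco holoenzymes (~2–8 nm).  The model is substitution-only:
repeat units are assumed near-equal in length (true of the known linker
families), so no within-unit indel alignment is attempted.

**Scoring.**  A candidate decomposition is (start, period p, c full
copies, optional trailing partial of length r ≥ p/2).  Its consensus is
the column-wise majority over the full copies, ties resolved to the
alphabetically first residue for determinism.  The score is the integer
number of consensus-matching residues, which equals
`copies × period × identity` where identity is the length-weighted mean
per-copy match fraction.  Validity requires ≥ 3 total copies (the
minimum valence for condensate cross-linking), boundary copies and the
partial each ≥ 0.7 identity, overall identity ≥ 0.7, and a consensus
with ≥ 5 distinct residues.  The last guard rejects low-complexity
repeats, including short-period repeats (period < 20) that would
otherwise surface inside the band at harmonic lags.

**Search.**  For each period p the lag-p self-match profile
(`m[i] = [seq[i] = seq[i+p]]`) is scanned with p-wide windows.  A window
qualifies at threshold `2·min_identity − 1 = 0.4` — the pairwise
agreement guaranteed between two adjacent copies that each match a
common consensus at 0.7 — so any repeat the scorer accepts through
adjacent-copy agreement can seed.  Qualifying runs separated by at most
one period are merged (one mutated column depresses up to p consecutive
windows), and merged runs must cover `(min_copies − 1)·p` profile
positions.  Within each seeded region (±2p before, +5p after, admitting
one junk interior copy on either flank) every decomposition is scored
exactly, with a branch-and-bound cut: a start is abandoned when the
remaining region length cannot beat the best score found.  Ties break
toward smaller period, then tighter span, then earlier start; the
tighter-span rule keeps phase rotations of the same repeat from being
selected by flank noise.

**Harmonics and overlaps.**  A hit whose period is a multiple (± jitter
of 2) of a hit covering ≥ 80% of its span with identity no more than
0.05 worse is suppressed — a clean fundamental explains its padded
harmonic even when flank junk makes the harmonic score a few residues
higher.  Remaining overlaps are resolved greedily by the same key.

**Verification and limits.**  On short 4-letter strings carrying planted
repeats (0–10% substitutions, random flanks; band [3,10] so exhaustive
enumeration is feasible), the detector's top hit reproduces the global
optimum of a brute-force enumeration under identical scoring/suppression
rules in 200/200 seeded test cases (599/600 in a wider sweep).  The
characterized failure mode is a decomposition whose *interior* copy is
junk (good–junk–good patterns): adjacent-copy agreement never rises
above the seeding threshold, so no region is seeded.  Such patterns are
chance artefacts of short random strings, not linker-like repeats.
Pure-random strings can also contain weak chance decompositions below
the seeding density; every hit the detector does report is sound (a
valid decomposition under the stated rules), which is tested separately.

## Disorder

The built-in predictor is the classic charge–hydropathy unfoldability
index `I = 2.785·⟨H⟩ − |⟨R⟩| − 1.151`, computed in a 51-residue window
truncated at the termini, with ⟨H⟩ the mean Kyte–Doolittle hydropathy
rescaled to [0,1] and ⟨R⟩ the mean integer charge (K,R → +1, D,E → −1,
H → 0 by default).  Residues with `I < 0` are called disordered.  This
self-contained index was chosen because published disorder predictors
are interchangeable for this screen (the thresholded quantity is only
the disordered *fraction*), and a dependency-free default keeps the
whole pipeline runnable offline.  Per-residue probability tables from
any external predictor can be supplied instead (call = score ≥ 0.5);
proteins missing from such a table are reported missing and can never
silently pass the disorder stage.  The pipeline's default threshold —
at least half the residues disordered — operationalizes "largely
disordered" and is a configuration key.

## Pipeline and calibration

Stages run strictly in the order physicochemistry → repeat presence →
sticker content → disorder, each protein's flags evaluated up to its
first failure.  Stage-1 thresholds are calibrated from a reference
linker: pI ± 2, length in [0.3×, 3×], Φ/ζ fractions ≥ 0.5× the
reference's.  The sticker requirement — ≥ 1 Φ and ≥ 2 ζ residues in the
best hit's consensus — operationalizes "repeats containing interacting
residues"; both counts are configuration keys.  Transit peptides are
handled by a manual N-terminal trim (`mature_trim`) rather than a
predictor.  Candidates are ranked by
`copies × identity × fraction_disordered`, a transparent surrogate for
the manual structure inspection a real campaign would add; it is not
claimed to be equivalent.  Enrichment-table triage uses strict
inequalities (log₂FC > 4, −log₁₀ adj. P > 4), matching the convention
that points on a dashed significance threshold are excluded.

## Synthetic data

A linker is leader + n near-identical units (amphipathic 10-residue
sticker: 3 hydrophobic, 3 basic, 1 acidic, 3 neutral; plus a spacer
biased to S,P,G,E,K,T,A) + short tail, units independently mutated at 5%
per residue.  Two generator choices deserve note:

* **Fixed-count composition.**  Spacers and leaders are shuffled
  multisets with largest-remainder rounded composition, not i.i.d.
  draws.  A unit is drawn once and replicated across copies, so i.i.d.
  composition noise would be amplified by the copy number; near-balanced
  acid/base content then makes the pI unstable across several pH units.
  The composition carries a lysine excess (16% K vs 10% E), making every
  linker stably basic — as the natural linker family is.
* **Coupled period/copy draw.**  The period is uniform on [20,120] and
  the copy number uniform on the subset of [3,8] keeping the repeat
  region in 160–720 residues (short units get more copies, long units
  fewer, as in the natural family).  Independent draws would span a
  13.6× total-length range that no single [0.3×, 3×] calibrated length
  window can bracket.

Linkers are verified post-generation to clear the built-in disorder
threshold (resampled up to 10×, then an error).  Decoy classes are
verified to fail where designed: globular (hydrophobic-rich composition)
→ predicted ordered; disordered-non-repetitive (spacer composition,
i.i.d.) → no repeat hit; low-complexity (3–10-residue unit over
{G,P,S,Q}) → rejected by the band and the distinct-residue guard.  In
the pipeline itself, globular decoys usually exit at stage 1 (low
charged-residue content), which is consistent: the class property is
what is guaranteed, not the first failing stage.  Record order is
shuffled and ids reassigned afterwards, so ids encode nothing.

The default benchmark (10 linkers + 3×200 decoys, ~1 s to generate and
~1 s to screen) exercises architecture recognition under composition
overlap — the disordered decoys share the linkers' residue composition
exactly.  It does not emulate real proteome properties: no transit
peptides, no domain mosaics, no repeat families with indel divergence,
no annotation noise.  Passing it shows the stages discriminate the
architecture they define; real-proteome candidate counts will depend on
annotation and predictor versions.

## Curve fits

All fits are nonlinear least squares (trust-region, bounds keeping rates
and affinities positive; relative convergence tolerances ≤ 10⁻⁸).
Initialization: Hill `B₀ = max y`, `K_D₀ = x` nearest half-max; FRAP
`A₀ = last y`, `k₀ = 1/t` at half-plateau.  The fitted RSS never exceeds
the RSS at initialization, and both fits are scale-equivariant
(tested).  The Hill coefficient is fixed at 1, matching the hyperbolic
binding form used for the SPR and gel-shift occupancy data.  FRAP
normalization order is background subtraction → photobleach correction
(divide by the unbleached reference) → full-scale normalization by the
mean pre-bleach corrected value; the order is configurable in principle
but this sequence is the declared default, and the pre-bleach mean of
the output is exactly 1.  Fitting consumes post-bleach points only, with
t = 0 at the first post-bleach frame.  Uncertainties come from a seeded
residual-resampling bootstrap (default 1,000 replicates, percentile 95%
intervals), standardizing what fitting packages usually do in
unspecified ways.  The calibration module fits an ordinary
least-squares line through (amount, intensity) standards and converts
interpolated amounts to copies per cell and compartment molarity;
samples outside the standards' intensity range are flagged and, by
default, refused.

## Problem sizes

The bundled benchmarks use sizes that keep the full test suite under a
minute of compute for the screen and a few tens of seconds for the fit
simulations: 610-protein proteomes, 200-case oracle sweeps on ≤60-residue
strings, 200-replicate noise simulations at 30 (FRAP) and 12 (Hill)
points, and bootstrap sizes of 50–199 in tests (1,000 by default in the
API).

## Known limitations

* No indel tolerance inside repeat units; linkers whose units diverge by
  insertions would need the band's jitter (±2) or would be missed.
* The detector's seeding can miss decompositions whose interior copies
  are junk or whose adjacent-copy agreement is below 0.4 — irrelevant
  for linker-like repeats, documented for completeness.
* Alignment identity depends on the denominator; the default counts
  post-trim alignment columns (internal gaps included, terminal
  overhangs excluded) and is configurable to shorter/longer sequence
  length.  Reported identities should always name the convention.
* The charge model ignores post-translational modification and local
  electrostatic environment; pI values are the standard sequence-based
  estimate.
* The rank score is a triage heuristic, not a validated predictor of
  linker function.
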