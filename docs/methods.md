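# Methods

## Model

The package implements absolute quantification of genome-wide DNA
double-strand breaks (DSBs) by calibration against restriction-digestion
standards.  The measurement chain it models is ligation-mediated qPCR:
every blunt double-strand end in a sample can ligate a universal linker
and be amplified, so the cycle threshold Ct is linear in the log of the
number of ligatable ends,

    Ct = a + b * lg10(N_DSBs),   b < 0.

Standards pin the line because their break numbers are known exactly: a
blunt-end restriction enzyme with `n` sites per genome, acting on `c`
genome copies, produces `c * n` breaks.  The genome copy number follows
from the DNA mass and the genome size,

    c = mass_ug * 6.023e23 / (genome_bp * 1e6 * 650),

with 650 g/mol the average molar mass of a base pair.  The Avogadro
constant is deliberately the rounded 6.023e23 so the bundled organism
coefficients are reproduced exactly; it is a parameter of
`CopyNumberParams` for anyone preferring the CODATA value.

Two refinements connect the pure site count to what qPCR actually sees:

1. **Size threshold.**  Amplification is efficient only for fragments
   shorter than ~2000 bp, so the count entering a standard's N_DSBs is
   the number of digestion fragments strictly below `max_fragment_bp`
   (default 2000), not the raw site count.  The raw count remains
   available (`theoretical_ndsb` takes whichever count the caller
   passes) for sensitivity analysis.
2. **Methylation exclusion.**  EheI (GGC^GCC) is blocked by CpG
   methylation in mammals, so its standard under-reports breaks there;
   `build_standard_table` flags EheI points excluded whenever the
   organism profile is mammalian.  Non-mammalian curves use all seven
   enzymes.

Per-organism coefficients ship as constants (human 1.477, mouse 1.773,
Arabidopsis 38.88, S. cerevisiae 761.7, E. coli 1782 breaks per site):
they fold the per-reaction DNA mass into a single multiplier and are
treated as authoritative rather than recomputed, because the mass they
imply is not independently specified.

## Site scanning and digestion

Sites are located with the Sunday exact string-matching algorithm: after
each window the shift is looked up from the text character one past the
window (full pattern length + 1 when that character is absent from the
pattern).  A naive sliding-window matcher is kept in the public API as
the independent oracle; a property suite asserts equivalence on
randomized texts.

All seven supported enzymes are blunt cutters with palindromic
recognition sites, so forward-strand scanning finds every double-strand
site exactly once; non-palindromic sites raise rather than silently
halving the count.  Ambiguity codes are masked to N on input and a
window containing N never matches — conservative, and guaranteed not to
invent sites in masked regions.  Overlapping occurrences are all counted
as sites (the site count is a pure string statistic), but cut
coordinates are de-duplicated before fragmenting, since two recognition
events at one coordinate are one break.

Topology is declared per record (FASTA carries none; default linear).
Linear records with `k` distinct cuts yield `k + 1` fragments; circular
records yield `k` fragments (one full-length fragment when uncut), and
sites spanning the origin are found by scanning the sequence extended
with its first `len(site) - 1` residues.  Fragment lengths always sum to
the assembly size — asserted as a hard invariant in the tests.
Coordinates are 0-based half-open internally; report files are 1-based.

## Calibration

`fit_standard_curve` is ordinary least squares of Ct on lg10(N_DSBs)
over included points — Ct is the response because measurement error
lives in Ct while the standards' break numbers are exact.  No weighting
is applied across dilution levels.  R² is the squared Pearson
correlation (identical to the OLS coefficient of determination in simple
regression).  At least 3 included points with non-degenerate lgN are
required.

Amplification efficiency is E = 10^(1/|b|) − 1 (E = 100% at
|b| = 1/lg10(2) ≈ 3.32, perfect doubling).  Unknowns are inverted
through the line, N̂ = 10^((a − Ct)/|b|), with replicate Cts combined by
arithmetic mean (the qPCR convention) and non-amplifying replicates
(recorded as "none") dropped with a warning; a sample whose replicates
all fail to amplify is flagged "below detection", not an error.

Validity gates, each a configurable flag with these defaults: R² > 0.95;
|b| within [3.0, 3.65]; every no-template/no-ligase control either Ct >
33 or non-amplifying.  The reportable range 10–10⁸ breaks is a flag on
results, not a hard error, since it is a property of the method rather
than of any one sample.

## Quality control

CVs (100 × sample sd / mean, n−1 denominator) are computed on the Ct
scale: replicate spread there is roughly constant, whereas
back-transforming to break numbers would inflate it ~8-fold through the
10^(x/3.5) map.  Intra-assay CV is the mean of per-(condition, run)
replicate CVs; inter-assay CV is the mean over conditions of the CV of
per-run means.

The limit of detection uses a one-sided 95% limit of blank: LOD Ct =
mean(blank Ct) − 1.645·sd (lower Ct = more template), inverted through
the curve.  The 1.645·sd rule is this package's choice of a standard
blank-based criterion; at least 3 numeric blanks are required, and
non-amplifying blanks are excluded with a warning.

## Synthetic data

`simulate` provides the test bed: i.i.d. random genomes at a given GC
content (P(G) = P(C) = gc/2), genomes with exactly `k` planted sites
(background scrubbed of accidental occurrences by rejection resampling,
sites written in at jittered evenly-spaced positions, result
post-verified by exhaustive search — failure after 1000 attempts is an
explicit error), and simulated Ct tables drawn from a known line with
i.i.d. Gaussian noise.  All generators take one explicit seed and are
bit-reproducible; there is no hidden global random state.

What the simulations do *not* emulate: ligation chemistry and its
efficiency, fragment-length-dependent amplification bias, chromatin
accessibility, partial digestion, and the non-uniform site distribution
of real genomes.  Passing tests therefore demonstrate the correctness of
the counting, calibration and QC arithmetic under the stated noise
model, not the wet-lab performance of the assay on real samples.

## Numerical and design choices

- Default Ct noise in simulated tables is sd 0.2 cycles over 7 decades
  of break numbers with triplicate measurements — the repeatability
  regime a well-run qPCR shows (replicate CVs of a few percent on Ct
  near 20).
- Parameter recovery under that model: the mean fitted slope over 1000
  seeded replicates is within 0.01 of truth.  With 7 standards the
  parameter errors divided by their standard errors are t-distributed
  with 5 degrees of freedom, so a ±3·SE interval covers ~97% per
  parameter (not the Gaussian 99.7%); the test asserts ≥95% joint
  coverage accordingly.
- The size threshold is strict (`< 2000`, not `≤`); thresholds, gates
  and the reportable range are all flags with the defaults above.
- Sub-threshold counts of zero make lg(N) undefined; such standards are
  flagged excluded with a warning rather than raising.
- Bundled enzyme table: AluI AG^CT, BsuRI GG^CC, DraI TTT^AAA, SspI
  AAT^ATT, StuI AGG^CCT, EcoRV GAT^ATC, EheI GGC^GCC (methylation
  sensitive); cut offsets follow the blunt-center rule.

## Problem sizes

The test suite runs entirely on synthetic genomes of 2–100 kb (large
enough that every enzyme cuts many times, small enough for exhaustive
oracles), 500 randomized matcher-equivalence cases, and 1000-replicate
Monte-Carlo loops for recovery properties; the whole suite completes in
a few seconds on one CPU.

## Known limitations

- Degenerate (IUPAC) recognition sites, nicking and sticky-end enzymes,
  star activity and partial digestion are out of scope; only blunt
  palindromic cutters are supported.
- Sites longer than a circular molecule (pathological) are not wrapped
  more than once.
- The bundled reference curves for the two mammals inherit whatever
  methylation, assembly-version and filtering choices produced their
  published inputs; they are reproduced as given, and two of the five
  printed slope/organism pairings are internally inconsistent with the
  bundled inputs (the fits, not the printed labels, are what the package
  reports).
- No confidence intervals on quantified unknowns beyond the reportable
  range and validity flags.
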