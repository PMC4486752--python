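# Methods

`melosem` asks whether short piano improvisations carry information about the
word that prompted them. The study design it implements is a 2×2
within-subject factorial: 32 stimulus words crossing *valence*
(positive/negative) with *semantic category* (morality/logic), 8 words per
cell, improvised on by 19 pianists, one piece of at most 20 s per
pianist × word (608 pieces). Three analysis stages sit on top of a symbolic
corpus model: feature extraction, an ANOVA screen, and pianist-disjoint
classification. A calibrated corpus generator makes the whole pipeline
executable and testable without any recordings.

## Score model

A piece is an ordered list of note events `(onset, offset, pitch, velocity)`
in seconds and MIDI units. Every note occupies the half-open interval
`[onset, offset)`; a pitch *sounds* at time `t` iff `onset ≤ t < offset`.
Onsets within 30 ms of a cluster's first attack count as one simultaneity
(chords are never played perfectly together; the threshold is configurable).
Standard MIDI Files are read (format 0/1, tempo map applied, note-on with
velocity 0 treated as note-off, unterminated notes closed at end of track
with a warning) and written (format 0, 480 ticks per quarter at 120 BPM, so
round trips are exact to within one tick ≈ 1.04 ms).

## The 12 musical dimensions

**Compositional.** *Ambitus* (max − min pitch, semitones); *lowest note*;
*mean note duration*; *mean velocity*; *articulation* — for each successive
pair of onset clusters, the sounding fraction of the inter-onset interval
capped at 1, averaged: 1 is legato (no gaps), 0 the staccato limit;
*harmonic dissonance* — over 50 ms frames with ≥ 2 sounding pitches, the
mean of an interval-class rank table (0 = unison/octave … 11 = tritone,
classical consonance ordering) over all sounding pairs, pooled across
frames; pieces with no simultaneities score 0. The rank table is an
editable, declared stand-in for a published dissonance measure whose exact
table is not reprinted here; conclusions should rest on contrasts, not
absolute values. *Gradus* — Euler's gradus suavitatis Γ of the
just-intonation ratio assigned to each successive melodic interval
(reduced mod 12 above the octave; Γ(p₁^k₁·…·pₙ^kₙ) = 1 + Σ kᵢ(pᵢ − 1)),
averaged along the melody.

**Melody (skyline).** The melodic line is the highest pitch of each onset
cluster — the standard skyline heuristic for polyphonic symbolic music.

**Information complexity.** *Pitch entropy* — Shannon entropy (bits) of the
pitch-class histogram of notes whose onset falls in a sliding window of 7 s
advancing by 5 s (7 s ≈ auditory sensory-memory span; the stated 2 s
overlap gives the 5 s hop), averaged over windows containing at least one
note. Counts are note counts, not durations (the weighting is not specified
upstream; note counts are the simpler convention and the one the limit
cases pin down: a single repeated pitch gives 0, uniform pitch classes give
log₂12 ≈ 3.585). *Melodic entropy* — the same computation on the skyline.

**Acoustical (spectrum-model proxies).** The original acoustical features
were measured on rendered audio. Here each sounding pitch is expanded into
a harmonic spectrum model — 6 partials at integer multiples of the
equal-tempered fundamental (A4 = 440 Hz), amplitude 1/k — and:
*roughness* is the Plomp–Levelt sensory dissonance in the Sethares
parameterization, `a₁a₂·(e^{−3.5sd} − e^{−5.75sd})` with
`s = 0.24/(0.021·f_min + 19)` and `d` the frequency difference, summed over
all distinct partial pairs per 50 ms frame and averaged over frames (0 for
a lone pure tone); *brightness* is the frame-averaged fraction of spectral
energy (amplitude²) above 1500 Hz; *attack time* is an explicit velocity
map, `a_max − (velocity/127)(a_max − a_min)` with defaults 50 ms → 5 ms
(louder keystrokes reach peak intensity sooner). Attack time is the weakest
proxy of the three and the first candidate for replacement via the external
feature override (`--features-csv`), which lets audio-derived values for
any subset of the 12 columns take precedence over the symbolic ones.

Because the spectrum model is not the rendered piano, roughness and
brightness have package-specific scales; within-corpus contrasts and ratios
are the quantities that transfer, not absolute values.

## ANOVA screen

Each dimension is screened with a two-way repeated-measures ANOVA: each
pianist × cell is collapsed to the mean over its 8 words (missing values —
e.g. articulation of a single-attack piece — are imputed with the pianist's
cell mean and logged), giving one observation per pianist per cell,
numerator df = 1 for both main effects and the interaction, and denominator
df = n_pianists − 1. Sums of squares are computed explicitly for the
balanced design; each effect is tested against its own effect-by-subject
interaction. The family of 12 tests is Bonferroni-corrected: significance
means p < 0.05/12 ≈ 0.0041. A one-factor variant screens valence within a
single category. Post-hoc contrasts are paired t-tests on word-level means
(8 words per cell, averaged over pianists, paired by position in the word
list; df = 7); two-sided p throughout. A degenerate pairing with zero
difference variance reports a signed infinite t rather than an error.

The word-level (rather than improvisation-level) aggregation is the choice
that reproduces the design's degrees of freedom; an improvisation-level
variant is deliberately not offered.

## Classification

Gaussian Naive Bayes on Z-scored features, cross-validated
pianist-disjointly: all C(19,4) = 3876 ways of holding out 4 pianists are
enumerable (a seeded uniform subsample is available for quick runs); each
fold trains on 480 improvisations and tests on 128 (240/64 for
within-category valence tasks). Z-score statistics are fit on the training
pianists only — fitting on all data would leak test information. Variances
are floored at 10⁻⁹; prediction ties break deterministically toward the
first class in sorted order. Performance is the macro-averaged F1 over both
classes; the harmonic mean of precision and recall is the default, with the
geometric mean available behind a flag (the study's verbal definition says
geometric; the standard F1 is harmonic; both are provided). Folds with no
predicted positives report precision 0 with a warning. Synergy — whether
the joint 12-feature model beats the best single feature — is a paired
t-test on fold-wise F1 differences over identical fold assignments.

## Synthetic corpus generator

The generator is calibrated on what the extractors recover, not on any
claim about pianists' cognition. Per design cell it draws, for each piece:
a register floor and range (melody pitches live in `[lowest, lowest+ambitus]`);
pitch classes from a profile that decays along the circle of fifths from a
random tonic at a cell-specific concentration (with per-piece tonal-focus
jitter); lognormal inter-onset intervals whose scale is set to
`duration_target / E[legato]` so that mean note duration and articulation
are *independent* dimensions; per-note sounding fractions around a
per-piece legato center (clipped to (0.05, 1]; the cell means are chosen so
the *extracted* articulation lands on the reported cell values
0.961/0.903/0.902/0.868); velocities around a per-piece loudness center;
and simultaneities on ~35% of attacks (with per-piece density jitter) drawn
from a four-way mix:

* **semitone clusters** of cell-specific size — the roughness carrier:
  cluster size scales beating roughness steeply at nearly constant rank
  dissonance;
* **whole-tone clusters** (notes at −2, −4) — rough but mid-rank material;
* **tritone-family dyads** (−6/−10/−11) — the rank-dissonance carrier with
  mild roughness;
* **weighted consonant dyads** (octave/fifth-heavy) — background texture.

Two further devices keep the screen's category contrast confined to
articulation, as reported: chord tones never sink below the register floor
(the melody note is raised by whole octaves instead, preserving its pitch
class and hence the skyline statistics), and the positive-morality cell
uses *anti-tonal consonant voicing* — consonant chord partners drawn by a
small tournament favoring off-profile pitch classes — which equalizes
pitch-class pollution of the entropy histogram across categories without
touching the melodic line, roughness, or the rank table.

Pianist individuality is modeled as Gaussian per-pianist offsets on cell
parameters (sd ≈ ¼ of the corresponding cell contrast). Offsets are shared
across cells, so they act as the subject blocking factor: they cancel in
the within-subject ANOVA but make pianist-disjoint classification
genuinely harder, keeping single-feature F1 scores away from 1.

The default preset injects: valence effects (positive = higher register,
narrower range, more concentrated pitch classes, softer/slower-developing
attacks, longer notes, fewer tritone-family simultaneities) and a
morality-only roughness contrast. The calibrated negative/positive morality
roughness ratio is ~6–7× on the package's roughness scale (the study
reports ~8× on its audio-based scale); the consonant-texture floor of the
spectrum proxy bounds the positive-morality cell from below, and pushing
the ratio further destabilized the category balance of the screen, so ~7×
was frozen. The ratio's direction, the interaction, and the near-equality
of the logic cells are the reproduced pattern. A `null` preset with four
identical cells supports type-I-error checks.

### What the generator does and does not emulate

It reproduces the *statistical* structure the analyses consume: cell
contrasts with pianist and piece heterogeneity, realistic note counts and
piece lengths, and feature distributions with the reported sign pattern. It
does not model meter, phrase structure, voice leading, hand constraints or
expressive timing. Passing tests therefore certify the pipeline —
extraction, screening, cross-validation — not any claim that real
improvisations would yield these exact scores; classification on this
corpus is an easier task than on human data (effect magnitudes were chosen
for reliable recovery at the corrected threshold, which makes the
within-subject F statistics larger than those printed for the human
corpus).

## Numerical choices and scale

Frame step 50 ms for all frame-based features; entropy window 7 s / hop 5 s;
onset-cluster threshold 30 ms; spectrum model 6 partials, 1/k amplitudes,
A4 = 440 Hz; brightness cutoff 1500 Hz; attack map 5–50 ms; GNB variance
floor 10⁻⁹ — all configurable. Frame-based extractors cache per unique
sounding set, so a 608-piece corpus extracts in a few seconds. The default
test suite and the acceptance script subsample pianist folds (100–200 of
the 3876) for cross-validation sweeps; fold enumeration itself is checked
exhaustively. Replicate counts in stochastic tests (20 corpus replicates
for pattern recovery; 400 direct-simulation nulls for type-I control) were
chosen as the smallest sizes at which the checked proportions are stable.

## Known limitations

* Roughness/brightness/attack-time are symbolic proxies; absolute scales do
  not transfer to audio-based measurements (use the feature override to
  import audio-derived values).
* The dissonance rank table and the just-intonation gradus table are
  declared replacements for measures whose exact definitions are published
  elsewhere, not reconstructions.
* The entropy windowing weights notes, not sounding durations; with heavy
  pedal or very long chords the two conventions can diverge.
* Same-pitch overlapping notes are matched first-on/first-off when reading
  SMF; their true pairing is unrecoverable from a MIDI stream.
* The post-hoc roughness contrast in the source study prints t = 3.74 with
  p = 0.072 at df = 7, which is internally inconsistent; the package
  reports both statistics and takes no side.
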