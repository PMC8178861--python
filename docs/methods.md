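# Methods

## Data model and conventions

A sample is one picture-description recording: a `Transcript` of utterances
of timed, POS-tagged tokens (times in seconds, half-open `[onset, offset)`
intervals), optionally a mono waveform, and optionally a bracketed
constituency parse per utterance. Hesitation markers (um/uh) are tokens with
`is_filler=True`: they are excluded from every lexical, syntactic, semantic,
and graph count, but participate in pause logic. Psycholinguistic-norm and
embedding lookups are case-folded; a word absent from a norms table is
*missing*, never zero — imputing 0 for age of acquisition or valence would
bias per-transcript means, so norm averages are taken over covered tokens
and the coverage fraction is reported as its own feature.

The CHAT reader supports a deliberately minimal dialect — participant main
tiers, continuation lines, bracketed-code/fragment/terminator stripping,
`&-um`/`&-uh` retained as fillers — sufficient for TalkBank-style transcripts;
full CLAN semantics (dependent tiers, overlap marking) are out of scope.

## Acoustic variables

Pauses come from the timing annotation, not waveform energy: a gap between
consecutive non-filler words of at least `unfilled_min` (default 0.25 s) is
an unfilled pause, split at `long_min` (default 1.0 s) into short vs long;
a gap overlapped by a filler token is a filled pause and excluded. The
thresholds are conventional for connected-speech work, not canonical —
both are config parameters. Speech rate divides the non-filler word count
by *elapsed* time (pauses included), which is what makes it co-vary
negatively with pausing; word duration averages `offset − onset` over
non-filler words.

Framewise statistics use 25 ms windows with a 10 ms hop. Zero-crossing
counts treat zero samples as positive, so they are exactly invariant to
amplitude scaling. MFCCs follow the standard chain (Hamming window, power
spectrum at the next power-of-two FFT length, 26 triangular HTK-mel
filters, log, orthonormal DCT-II), keeping c1..c13 — indexing is 1-based,
so "the 4th MFCC" is c4 — and replacing c0 with a separate log-energy
channel (natural log of per-frame power, computed pre-window). First and
second derivatives are ±2-frame regression deltas with replicated edges.
Each channel is summarised by framewise mean, variance, skewness and
kurtosis in the Pearson moment convention (kurtosis non-excess: a normal
channel scores 3); a zero-variance channel reports missing skew/kurtosis
rather than 0/0 noise. Pre-emphasis is off by default (the synthetic
waveforms are already band-limited); all framing/filterbank/delta
parameters are config.

## Linguistic variables

"Use of X" variables are normalised per 100 words, since raw counts scale
with verbosity. Nouns are NN/NNS/NNP/NNPS; past tense is VBD/VBN;
demonstratives are this/that/these/those tagged DT; the subordinate-to-
coordinate ratio counts IN-tagged lexical subordinators over CC tokens
(missing when no CC occurs). Vocabulary richness uses lemmas: TTR, MATTR
with window 10 (a sliding-window statistic, hence deliberately
order-dependent), Brunet's W = N^(V^−0.165), and Honoré's
R = 100·log N / (1 − V1/V), undefined when every type is a hapax.

Syntactic rates are counted on the bracketed parses by exact tree matching:
NP whose children are exactly DT NN; VP with children exactly VBD NP; VP
with both a VBZ and a PP child; VP dominating an SBAR anywhere below;
coordinate phrases (a CC child flanked by same-category siblings); ADJP
count; VP with a CC child; and coordinate phrases per clause (S/SBAR
nodes). Rates are per 100 words of *parsed* utterances only. The counts are
verified against an independent brute-force enumerator on random toy trees.

Utterance repetitiveness is cosine distance between bag-of-lemma count
vectors over all unordered utterance pairs (consecutive-only is available;
all-pairs is the default because perseverative returns to earlier content
need not be adjacent). Low mean distance = repetitive speech. Lemma-level
bags keep inflection from masquerading as novelty. Picture similarity
embeds each utterance as the mean vector of covered lemmas and takes its
minimum cosine distance to any picture key word; the reported value is the
maximum over utterances — the most off-picture utterance. Aggregation
choices (min over key words, max over utterances) are one reasonable
reading of "max cosine distance to the picture content"; they are isolated
in one function and easily swapped. The Cookie-Theft content lexicon
(subjects boy/girl/mother with synonyms, objects, place, actions) ships as
a replaceable TSV. The speech graph is the directed multigraph of
consecutive-lemma transitions within utterances; reported metrics are node/
edge counts, repeated transitions, self-loops, largest weakly-connected
component, and distinct-edge density.

## Ratings

Consensus is the per-item modal rating; a multimodal tie resolves to the
mode nearest the item mean, then to the lower severity (ties are absent in
practice with 5 raters; the rule just makes the operation total and
deterministic). Items with rating range ≥ 2 are flagged, and a second-round
panel can replace exactly the flagged items before recomputation —
mirroring a re-rating protocol. ICC is the two-way random-effects
absolute-agreement model; both ICC(2,1) and ICC(2,k) are always reported
(guidance on ICC reporting is precisely that the form must be stated, and a
consumer may care about either single- or averaged-rater reliability), with
ICC(2,1) as the headline and the F = MS_R/MS_E test with (n−1), (n−1)(k−1)
df. Band edges 0.5/0.75/0.9 are half-open upward (exactly 0.9 is
"excellent"). The implementation is cross-checked against pingouin to 1e−6
in the test suite.

## Association screen and odds ratios

The screen is deliberately liberal: per-feature Spearman ρ against the
consensus rating with the t approximation, unadjusted α = 0.05, because its
role is to feed a factor analysis, not to confirm individual hypotheses;
an optional Benjamini–Hochberg mode exists but is off by default. Features
with fewer than 4 complete pairs or no variation are skipped with a
warning. Type-I calibration (empirical selection rate 0.05 under the null)
and agreement of the t-approximate p with the exact permutation p at small
n are both asserted in the acceptance tests; exact enumeration uses n = 9,
the smallest size at which the t approximation stays within 0.02 of the
exact p.

Group contrasts dichotomise the consensus at ≥ 1 ("any impairment" vs
"absent/normal"; threshold configurable), form the 2×2 group × impaired
table, apply the Haldane–Anscombe +0.5 to all cells iff any cell is zero,
and report the cross-product OR with Woolf log-scale CIs. With n = 10 per
group these intervals are necessarily enormous; the method is a transparent
stand-in where a model-based estimate is not identifiable.

## Exploratory factor analysis

Retention is Horn's parallel analysis in its original full-correlation
form: observed eigenvalues of the Pearson correlation matrix versus the
per-position 95th percentile of eigenvalues from 100 iid standard-normal
datasets of the same n × p; k is the initial run of observed > threshold.
The Monte Carlo percentile is estimated with the ceiling order statistic
(the 96th of 100 ordered values) rather than interpolation: a retention
threshold estimated from a finite draw should err upward, in keeping with
the anti-over-extraction purpose of using a high percentile at all. Note a
structural fact about this rule: under the null the first observed
eigenvalue is exchangeable with the surrogate eigenvalues, so the
per-dataset probability of spuriously retaining a factor is ~5/101 ≈ 5% *by
construction* — no implementation can push the null retention rate
meaningfully above 95%.

Extraction is iterated principal-axis factoring: initial communalities are
squared multiple correlations 1 − 1/diag(R⁻¹), computed via pseudoinverse
when R is singular — which happens routinely here, since a characteristic
can select more variables than there are samples (p > n) — with per-row
max |off-diagonal| as the fallback where SMCs misbehave; communalities are
clamped at 0.995 against Heywood cases; convergence is max |Δh²| < 1e−4
within 200 sweeps (non-convergence flags the result, not fatal). Rotation
is direct oblimin with γ = 0 (quartimin) by gradient projection, 30 seeded
random starts keeping the lowest criterion; factors are sign-normalised
(largest |loading| positive) and ordered by explained variance. Assignment
gives each variable to its largest-|pattern-loading| factor among those
clearing the 0.6 cutoff, none otherwise; exact ties go to the lower factor
index. Per-factor variance is Σ pattern² / p — with oblique factors these
shares need not sum to the common variance and are reported as descriptive
percentages. Missing feature cells are mean-imputed just before EFA (the
screen guarantees the columns themselves are informative); everything up to
that point propagates missingness explicitly.

## Synthetic cohort generator

The generator emulates a 30-sample, three-group study with five raters. Per
sample, a latent severity in [0, 3] per characteristic is drawn from its
group's normal distribution (clipped); defaults place HC/MCI/AD at
0.2/1.5/2.6 (word-finding), 0.2/1.3/2.3 (incoherence), 0.1/0.6/2.1
(perseveration), 0.2/0.8/2.0 (speech errors) with SDs 0.45–0.55 — group
separations chosen so the simulated panels reproduce the good-to-excellent
inter-rater reliability and the AD-driven impairment odds that motivate the
analysis, with perseveration and speech errors predominantly AD phenomena.
Severity maps are affine with sign-validated slopes:

* word-finding → mean inter-word gap 0.06 + 0.10·s (exponential draws),
  median word duration 0.22 + 0.06·s s (lognormal, σ = 0.15), generic-noun
  substitution ("thing") with probability 0.04 + 0.10·s, filler insertion
  0.01 + 0.03·s — producing more/longer pauses, slower speech, and more
  frequent, earlier-acquired words;
* incoherence → probability 0.05 + 0.22·s of an off-picture, past-tense
  template built from late-acquired, negative-valence vocabulary;
* perseveration → probability 0.05 + 0.10·s of repeating an earlier
  utterance verbatim, and a template pool shrinking by 2 per severity unit
  (reduced diversity);
* speech errors → probability 0.03 + 0.15·s of a subordinate-clause
  fragment construction.

Transcripts draw 70–110 words from ~20 hand-built sentence templates with
POS tags and constituency parses; the closed vocabulary carries synthetic
norms (scene words early-acquired/neutral-positive/frequent, off-topic
words late-acquired/negative/rare) and random unit-vector embeddings, so
the lookup code paths run without shipping licensed norm datasets. Rater
panels are clip(round(severity + N(0, rater_sd)), 0, 3) per rater (default
5 raters, rater_sd 0.35, optional per-rater bias). Waveforms are 16 kHz
band-passed (300–3000 Hz) noise bursts inside token intervals with
raised-cosine edges and exact zeros elsewhere — sufficient for pause,
energy, and ZCR properties; MFCC values are exercised but validated only
against a reference implementation, not against real speech. All
generators are pure functions of (config, seed).

What passing tests therefore show: the statistical machinery is correct
(oracle equivalence, calibration, generative recovery), and the extraction
recovers the directions the generator plants (pauses up, rate down with
word-finding severity, the signs reported for real cohorts). What they do
not show: real-speech acoustics, real lexical distributions, or the
particular factor structure of any clinical dataset. In particular, because
the synthetic severities share the diagnostic-group structure, most
screened variables load on one dominant factor — a property of the
generator, not of the method, and the planted-structure EFA tests exist
precisely to show the method resolves multiple factors when they are there.

## Reproducibility and sizes

Every stochastic routine takes a seed or Generator; the pipeline's
`summary.json` is byte-identical across reruns with the same inputs and
seed (timestamps are confined to the log). Intermediates are plain
CSV/JSON/TSV. Default problem sizes — 30-sample cohorts, 10,000-feature
null screens, 100-replicate retention experiments, n = 500 factor-recovery
draws — keep the complete test suite and the acceptance script each under
a minute of compute on a single CPU while leaving the Monte Carlo
assertions well-powered.

## Known limitations

No automatic speech recognition or forced alignment: timing must be
supplied or simulated. Pause detection is annotation-based; an
energy-based fallback is out of scope. The CHAT dialect is minimal. The
odds-ratio method and several aggregation choices (picture-similarity
aggregation, "per 100 words" normalisation, the PA percentile estimator)
are documented stand-ins where the underlying protocol admits several
readings. EFA on p ≫ n panels rests on pseudoinverse SMCs and should be
read as descriptive; parallel analysis with highly correlated severities
tends to one global factor.
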