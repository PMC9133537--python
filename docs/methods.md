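# Methods

`speechdev` implements two simulation models of speech production around a
shared articulatory-phonology substrate: (1) a developmental model in which
growing self-organizing maps (G-SOMs) acquire a mental syllabary through
babbling and imitation, and (2) an adult dual-route production model in
which a missing motor program is constructed by adapting the program of a
phonologically similar syllable. This note documents the models, their
assumptions, the tunable parameters, and what the synthetic data can and
cannot show.

## Gesture scores

A syllable's motor plan is a *raw gesture score*: discrete gestures on four
articulatory tiers (vocal-tract/labial shaping; constriction forming;
velopharyngeal; glottal), derived per phoneme from a fixed phoneme-to-
gesture table (vowels: tract shaping + labial shaping + velic closing +
phonation; plosives: full closing + velic tight closing + phonation or
glottal opening; nasals: full closing + velic opening + phonation;
laterals: lateral constriction + velic closing + phonation; glottal stop:
glottal tight closing + velic closing). Adjacent identical gestures on a
tier assimilate into one spanning gesture; tight velic closing and plain
velic closing are distinct types and never assimilate.

A motor program (*fully specified gesture score*) adds four time points per
gesture (activation onset, target-phase start/end, activation offset), a
quantitative target value and a stiffness parameter, on a 640 ms score with
a 10 ms frame grid (64 frames, matching the state-map width). The temporal
layout is a deterministic policy, not a measured one: onset-consonant
closure target phase 80–180 ms, a cluster's second consonant 200–280 ms,
the vowel target from (last onset release + 40 ms) to 560 ms with
activation from the score's start, codas 440–560 ms, movement (attack)
60 ms before and release 60 ms after each target phase, velic and glottal
gestures aligned to their host segment's phase. Every number is a named
`TimingPolicy` field. The layout is ordering-correct (closure before vowel
target, cluster C2 between C1 release and the vowel, coda late); absolute
milliseconds are a stand-in since no quantitative timing is published for
this substrate.

**Adaptation.** To program an unlearned syllable, the donor program's time
points are copied verbatim and only gestures whose identity or target
differs from the target plan are substituted. Compatibility is checked on
the per-position (unmerged) tier coverage rather than merged gesture
counts, because a voicing substitution legitimately splits or merges the
phonation gesture. When a substitution changes the assimilation pattern,
each output gesture takes the time points of the donor gesture covering its
first segment position — a deliberately rough "first version" of the new
program. Substitution counting treats the two vocalic sub-gestures (tract
shaping and lip shaping) as one vocalic substitution; consonant-affecting
mismatches are counted per gesture.

## The articulatory-acoustic proxy

The proxy stands in for a full articulatory synthesizer; it is synthetic by
design and is labeled as such. Articulator channels (lips aperture, tongue
tip, tongue body, jaw) follow critically damped second-order target
tracking: with constant target `T`, stiffness `w` and state `(y0, v0)`,
`y(t) = T + (a + b t) exp(-w t)`, `a = y0 - T`, `b = v0 + w a`. Integration
composes this closed form exactly over the frame grid, so the trajectory
equals the analytic solution to machine precision. Gesture targets override
the neutral posture during their activation; consonantal constrictions take
priority over vocalic shaping on a shared channel. Default stiffness is
100/s so targets are effectively reached within a 60 ms movement phase.

The auditory state is a 24-channel bark-scaled formant pattern: per voiced
open-tract frame, F1–F3 are interpolated between a consonant locus and the
vowel's formant targets in proportion to the constriction state, and each
formant paints a ridge split across the two bark channels straddling its
exact critical-band position (keeping sub-channel contrasts visible).
Voiced closures paint a 120 Hz voice bar, plus murmur resonances when the
velic port is open; voiceless open frames carry aspiration-excited formants
at reduced amplitude; voiceless or glottalized closures are silent. Vowel
formant targets (e.g. /a/ 730/1090/2440 Hz) and loci (labial lowers F2,
apical raises F2, dorsal converges F2/F3) are plausibility stand-ins, not
measurements. The neuromuscular (motor-program) state maps each gesture to
one of 10 muscle groups with an agonist drive monotone in the target value
over the movement-plus-target interval and an antagonist braking drive over
the release. Optional zero-mean Gaussian sensory noise (sigma 0.02,
seeded) produces distinct renditions of one syllable.

What this emulates: pairwise-distinct, topology-friendly sensory patterns
whose similarity structure follows phonetics (vowel identity dominates;
place/voicing/nasality are visible in transitions, closures and murmur).
What it does not: real acoustics, bursts/frication spectra, aerodynamics,
speaker variability. Results on these patterns demonstrate the learning
and control machinery, not performance on real speech.

## Growing self-organizing maps

The phonetic map is a G-SOM on an integer grid (start: 2x2), with one
weight vector per attached state map (auditory 24x64, somatosensory 4x64,
motor program 2x64x10, motor plan 100). The BMU is found by Euclidean
distance on the flattened auditory pattern; the update moves the BMU
neighborhood toward the item on *all* maps, which is what associates
sensory and motor states. Growth has two regimes:

* while the neighborhood is wide (coarse ordering), a node whose cumulative
  quantization error exceeds `gt` (3000) recruits its free grid neighbors
  with interpolated weights;
* once the radius has shrunk below `recruit_radius` (0.6), a stimulus whose
  BMU distance exceeds the novelty threshold `gt_novelty` (1.7, squared
  auditory distance) recruits a fresh node of its own, placed at the
  nearest free grid position.

`gt_novelty` sits between the sensory noise floor and the smallest
between-syllable pattern gaps. Syllable pairs closer than the threshold
(in this corpus, the closest voiceless place pairs such as /te/–/ke/)
therefore share a node; these shared nodes are the model's natural source
of word-learning collisions, while babbling recall of the prototypes stays
essentially error-free. Babbling presentations add fresh sensory noise
(babbling explores; no two productions are identical); imitation presents
210 fixed noisy renditions (70 syllables x 3), restarts with a narrower
neighborhood (0.8 -> 0.3) and a lower rate (0.15 -> 0.05) because the map
is already organized, and trains a second G-SOM on 470-dimensional binary
semantic vectors (content synthetic, 25 active bits per word) with its own
novelty threshold. Hebbian co-activation updates build the word–syllable
link matrix; links decay by 10% per cycle so early-training associations
fade in favor of the settled topology.

Word production follows semantic BMU -> strongest link -> phonetic node; a
word counts as learned when that node carries exactly its syllable and no
other word resolves to it. Babbling recall error is the fraction of items
whose recalled motor state is nearest to another item's motor program.

## Feature-region analysis

Occupied nodes are labeled with 19 analysis features in five groups
(vocalic front/back/low; glottal voiced/voiceless/glottal-stop/
voiceless-then-voiced; manner plosive/lateral/nasal/plosive-lateral; place
labial/alveolar/velar/glottal/labial-alveolar/velar-alveolar; syllable
type CV/CCV). For one feature, subregions are 8-connected components of
occupied carrier nodes; two subregions merge when a pathway of free nodes
connects them that contains fewer than 10 free nodes (nearness), crosses
at most one region of a competing value in the same group (coherence) and
contains no occupied node (neutrality); merging is closed transitively and
single-node subregions are excluded as outliers. A free node counts as
crossing a competing region only when at least two of its 8-neighbors
belong to that region: touching a single node skirts the region rather
than crossing it (with single-neighbor attribution, virtually every free
node on a realistically dense map is attributed to several regions and no
merge is ever possible). The search runs shortest-first over
(node, crossed-region) states, so a longer pathway with an admissible
crossing pattern is still found; an exhaustive path-enumeration oracle
confirms equivalence on small grids. Reports give per-feature counts per
model instance with medians per feature and per group.

## Vector-symbolic phonological similarity

Every layer value of the four-layer structure description (syllable type;
score type; segment types; segment features) is an atom: a seeded random
unit vector in D = 16384 dimensions, namespaced by layer. A syllable is
encoded as the normalized weighted bundle (sum) of its atoms (all layer
weights 1); similarity is the cosine. Stored syllabary entries are encoded
with their full structure; the *knowledge level* restricts only the
query-side encoding of the target. This asymmetry is what makes the
segment-feature layer critical: without it the query retains too little of
the stored form's content to clear the retrieval threshold, while dropping
the score or segment-type layer costs little.

Retrieval is thresholded and noisy. The threshold grows with the stored
set, `theta = 0.47 + 0.048 ln(n_programs)` — the usual capacity argument
that an associative memory must raise its acceptance criterion as it fills
to keep false activations in check. Trial-to-trial variability is one
shared Gaussian perturbation of the query per trial, giving per-candidate
similarity jitter `0.0153 sqrt(n_programs)` that is *correlated* across
similar candidates (similar stored forms receive similar interference), so
weak candidates do not get independent lucky spikes. A production attempt
succeeds when the ranked candidate is above threshold, its gesture
skeleton is compatible, and adaptation needs at most two consonantal
substitutions; the attempt budget is two.

The four free constants (D, theta intercept/slope, noise base) were
calibrated once on a grid, scoring against the published knowledge-level
production percentages over 25–40 master seeds, and then frozen. The
calibration prioritized: 100% success under full knowledge, the
minus-segments and minus-features values (98.1% and 5.6% of 54 trials)
within one trial-count, and the CCV-stage full-knowledge first-attempt
rate (91.7% of 36). Under the frozen defaults the CV-stage middle levels
land above their published values (minus_scores ≈ 97.5 vs 92.6,
minus_scores_and_segments ≈ 87 vs 75.9) although the published ordering
holds at every seed tested; the CCV-stage percentages other than the
full-knowledge level are not reproduced (the published inversion that
removes layers *helps* at the CCV stage does not emerge from this
similarity model). Both are known limitations of the functional
re-implementation.

## Experiment protocols and problem sizes

* Learning experiment: 10 virtual learners (independent seeds derived from
  a master seed by a counter scheme). Each babbles the 70-item
  proto-syllable corpus for 10 cycles (7 presentations per item per
  cycle), then imitates 210 renditions for 50 cycles x 1470 steps. One
  full run takes a few minutes on one CPU core.
* Production experiments: CV stage (9 learned CV/a syllables; 5 levels x 3
  trials x 27 CV targets = 405 trials) and CCV stage (all 27 CV plus 6
  CCV/a learned; 5 x 3 x 18 = 270 trials). Per-trial seeds derive from the
  master seed; learned targets must route directly, unlearned ones through
  adaptation. Success percentages are reported over the unlearned trials
  at the first production attempt, split by stratum (vowel-only vs up to
  two consonantal substitutions).

Degenerate inputs are contracts, not crashes: an all-zero auditory or
semantic probe returns a flagged low-confidence recall; a missing motor
plan or incompatible skeleton fails the attempt and is recorded in the
trace; an unknown word raises a lexicon error.

## Known limitations

* The assembling route (building a program for a new syllable *type* from
  sub-syllabic parts) is not implemented; incompatible skeletons fail.
* Single-run production percentages over 36–54 trials carry binomial
  spread of a few points; pooled runs sharpen them.
* The proxy's acoustic constants are synthetic; region counts and error
  bands demonstrate the mechanism on this corpus, not on real audio.
* Spiking-neuron dynamics are replaced by deterministic functional
  equivalents (buffers, utility argmax, vector-symbolic similarity).
* Pseudowords, multi-syllabic utterances, stress and allophony are out of
  scope.
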