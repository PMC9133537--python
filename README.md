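# speechdev

A computational model of how speech production develops and operates:
how a child's babbling and imitation build a *mental syllabary* whose
topology encodes phonological features, and how an adult speaker produces
a syllable she has never practiced by adapting the motor program of a
phonologically similar one.

The package is for researchers in speech motor control, phonological
development and cognitive modeling who want a fully seeded, testable
re-implementation of this two-model architecture without external
articulatory-synthesizer dependencies.

## What is inside

**Model 1 — babbling and imitation (growing self-organizing maps).**
Speech items are represented by their sensory and motor states: a
bark-scaled auditory pattern (24 x 64), a somatosensory pattern (4 x 64),
an agonist/antagonist neuromuscular pattern (2 x 64 x 10) and a motor-plan
vector. A growing SOM (start: 4 nodes) finds the best-matching unit by
auditory distance and co-trains all attached maps, associating what a
syllable sounds like with how it is produced; nodes are recruited as the
item set outgrows the map. Imitation adds a semantic map and Hebbian
word–syllable links. Analysis labels occupied nodes with 19 phonological
features and counts *feature regions* (connected components, merged
through short free-node pathways, singleton outliers excluded).

**Model 2 — dual-route adult production (gesture scores).**
A syllable's motor plan is a raw gesture score: discrete gestures on four
articulatory tiers. If a motor program (fully specified score: all
activation/target time points and quantitative targets) is stored, it is
executed directly (`DIRECT_CALL_MOTOR`). Otherwise (`ADAPT_MOTOR`) the
model retrieves a phonologically similar learned syllable and copies its
temporal specification, substituting only the differing gesture targets —
e.g. donor /da/ gives /du/ its complete timing and only the vocalic target
changes. Similarity is computed in a vector-symbolic layer over the
four-layer phonological structure description (syllable type, gesture-score
type, segment types, segment features); *knowledge levels* remove layers
from the computation to measure which phonological knowledge the adaptation
route depends on.

See `docs/methods.md` for the models' assumptions, parameters and
limitations.

## Worked example

Produce an unlearned syllable at the CV learning stage (only CV syllables
with /a/ have stored motor programs):

```
$ speechdev produce du --stage cv --seed 3
du: route=adapting success=True donor=da substitutions=1 stratum=vowel_only
```

The model has no program for /du/, retrieves /da/ as the most similar
learned syllable, and builds the /du/ program from /da/'s timing with a
single substitution — the vocalic gesture target (stratum `vowel_only`).

Run the CV-stage knowledge-level grid (405 trials: 5 levels x 3 trials x
27 syllables; percentages are over the 54 unlearned-syllable trials per
level):

```
$ speechdev exp2 --stage cv --seed 1 --out out/exp2a
                           n_unlearned_trials  n_success  n_first_attempt  pct_success  pct_first_attempt  pct_first_vowel_only
level
all                                        54         54               54   100.000000         100.000000            100.000000
minus_scores                               54         53               53    98.148148          98.148148             98.148148
minus_segments                             54         54               54   100.000000         100.000000            100.000000
minus_features                             54          6                6    11.111111          11.111111             11.111111
minus_scores_and_segments                  54         51               51    94.444444          94.444444             94.444444
```

With full phonological knowledge every unlearned CV syllable finds an
adaptable donor at the first attempt; removing the segment-feature layer
collapses retrieval almost completely, while removing the score or
segment-type layers costs little — the segment features carry the
information that makes a donor's gesture score reusable.

Train ten virtual learners through babbling and imitation and analyze the
resulting maps:

```
$ speechdev exp1 --learners 10 --seed 1 --out out/exp1
babbling error (mean) 0.14% | learned words (mean) 66.5/70 | word error rate (mean) 5.00% | max region median 2.0
```

After babbling, auditory-to-motor recall is nearly error-free; after 50
imitation cycles about 66 of 70 words have a unique, correct syllable
association (the rest collide on shared map nodes, mostly acoustically
close voiceless syllables), and the median number of feature regions per
phonological feature across learners stays low — the map's topology has
organized itself by phonological features.

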