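# affecteeg

EEG-based comparison of emotional reactions to photographic versus
illustrated surgical images, as a fully reproducible pipeline.

Surgical photographs (blood, flesh, internal anatomy) provoke strong
negative affect that hinders communication with patients and students.
One proposed remedy is professionally illustrated versions of the same
images.  This package implements the quantitative side of that question:
it scores emotional reactions on Russell's circumplex — valence
(unpleasant → pleasant) and arousal (calm → activated), both on (−1, 1) —
from two sources, a CNN voting ensemble applied to EEG recordings and a
nine-point self-assessment questionnaire, and then asks two statistical
questions about a two-group experiment (20 participants viewing
photographs, 20 viewing illustrations):

* **H0** — photographic and illustrated images evoke the same emotional
  response (tested per score column with a pooled two-sample Student
  t-test, df = n₁+n₂−2);
* **H1** — EEG-estimated and self-reported scores agree (tested within
  each group after rescaling questionnaire marks u ∈ {1..9} to the common
  scale via (u−5)/4).

Effect sizes are Cohen's d = (E[X] − E[Y]) / SD_pooled with the total-n
pooled SD, SD_pooled = √((SSx + SSy)/(nx + ny)).

Because the benchmark EEG corpus the recognizer is normally trained on is
gated and the original cohort recordings are not public, the package ships:

* a **synthetic corpus generator** (`affecteeg.synthetic`) producing
  benchmark-shaped recordings (32 subjects × 40 trials, 40 channels,
  60 s at 128 Hz, continuous 1–9 valence/arousal labels) in which affect
  enters through EEG band power — valence modulates alpha (8–13 Hz) on
  anterior channels, arousal modulates beta (13–30 Hz) on posterior
  channels — so labels are recoverable by construction;
* the **preprocessing chain** (`affecteeg.preprocess`): downsampling to
  128 Hz, zero-phase 4–45 Hz Butterworth band-pass, selection of the 32
  scalp channels, and non-overlapping 32-sample windows giving 32×32
  model inputs (240 per 60 s trial);
* the **five-column voting ensemble** (`affecteeg.ensemble` /
  `affecteeg.nnet`): five independently seeded convolutional columns,
  each with valence and arousal heads; per trial each column takes a
  majority over window decisions and the ensemble takes a majority over
  the five column votes, with a continuous score in [−1, 1] from the
  fraction of high-voted windows;
* the **packaged per-participant results table** of the original
  40-participant experiment (`affecteeg.synthetic.load_table2`), and the
  **statistics stage** (`affecteeg.stats`) that regenerates the analysis
  tables from it.

## Worked example

The packaged experiment table is analyzed straight from the CLI:

```
affecteeg analyze --out report/
```

which writes CSV analogues of the four analysis tables plus
`report/report.json`, and prints:

```
between-group (t, p, |d|):
  eeg_valence            t =  -12.816   p = 2.27e-15   |d| = 4.16
  eeg_arousal            t =   14.845   p = 2.11e-17   |d| = 4.82
  user_valence           t =   -3.661   p = 0.00076    |d| = 1.19
  user_arousal           t =    6.302   p = 2.2e-07    |d| = 2.04
between-method (p, |d|):
  valence/photographic   p = 0.72       |d| = 0.12
  valence/illustrated    p = 0.844      |d| = 0.06
  arousal/photographic   p = 0.942      |d| = 0.02
  arousal/illustrated    p = 0.00536    |d| = 0.96
H0 (groups differ?) verdicts at alpha=0.05: eeg_valence=reject,
  eeg_arousal=reject, user_valence=reject, user_arousal=reject
H1 (methods agree?) verdicts at alpha=0.05: valence/photographic=fail-to-reject,
  valence/illustrated=fail-to-reject, arousal/photographic=fail-to-reject,
  arousal/illustrated=reject
```

Reading: every between-group test rejects H0 — illustrated images shift
valence up and arousal down, with very large effects (|d| > 0.8).  The
between-method comparisons fail to reject H1 for valence in both groups
(p > 0.7, |d| ≤ 0.12): the EEG ensemble and the questionnaire agree on
pleasantness.  The one disagreement is arousal in the illustrated group.

A full synthetic run — generate a corpus, train the ensemble, simulate a
cohort, score it per 10 s stimulus epoch, and analyze — is:

```
affecteeg run-all --out run/ --seed 7
```

or, skipping training (statistics-only observation model):

```
affecteeg run-all --out run/ --seed 7 --stats-only
```

Individual stages (`simulate-deap`, `simulate-cohort`, `preprocess`,
`train`, `evaluate`, `score`, `analyze`, `report`) are available as
subcommands; every artifact carries the configuration hash it was
produced under.

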