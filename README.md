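# meowdag

Automatic classification of the **emission context of cat vocalizations**:
given a short recording of a single meow, decide whether it was produced
while *waiting for food*, during *isolation in an unfamiliar environment*,
or while being *brushed*. Context recognition from meows is a building
block for welfare monitoring and for studying cat–human acoustic
communication; the recording conditions assumed here are deliberately
modest (a collar-mounted Bluetooth headset: 8 kHz sampling, a-law
companding, a usable band of 0–4 kHz).

## Method

Clips are first stripped of silence with a statistical voice-activity
detector (per-bin Gaussian likelihood-ratio test with hangover). Two
frame-level feature streams describe the remaining sound event on a
30 ms / 10 ms Hamming grid:

* **MFCC**: 23-filter mel bank, DCT-II, coefficients 1–12 + log energy,
  with Δ, ΔΔ and ΔΔΔ appended (52 dims);
* **temporal modulation**: Fourier energies of slow subband-envelope
  fluctuations (8 cochlear-style subbands × 6 modulation bands up to
  32 Hz), exploiting the redundancy of modulation patterns across the
  subbands of a harmonic call.

The classifier is a **DAG-HMM**: a Cm-class problem is decomposed into
Cm(Cm−1)/2 binary tasks, one node per class pair, each solved by a pair of
Gaussian-mixture HMMs (states S ∈ {3..6}, mixtures g ∈ {2..256}, k-means
init + Baum–Welch) whose (S, g) is searched per task. Task order is
learned: each pair task is rated on a held-out validation split of the
training fold and tasks are arranged in a rooted acyclic graph with the
highest-rate (easiest) tasks nearest the root, so classes likely to cause
confusions are eliminated early. A test clip walks the graph along the
larger Viterbi log-likelihood; after Cm−1 nodes one label remains.

Four reference systems — class-specific HMMs, a universal
(background-model) HMM with MAP-adapted means, an RBF-SVM on mean++sd
pooled clip vectors, and an echo state network — run on identical ten-fold
cross-validation splits for comparison.

The original recordings are not publicly released, so the package ships a
**synthetic corpus generator** that reproduces their documented
statistics (448 clips: 93/220/135 by context, 196 Maine Coon / 252
European Shorthair, 1.82 s mean length, 0.5 s noise pads, a-law
transport) with controllable class separation. See `docs/methods.md` for
the full model description and design rationale.

## Worked example

```python
from meowdag import CorpusSpec, generate_corpus, run_benchmark

clips, manifest = generate_corpus(CorpusSpec(seed=1))
print(len(manifest), round(manifest.duration_s.mean(), 2))

reports = run_benchmark(seed=1, classifiers=("dag", "svm"))
print(round(reports["dag"].recognition_rate, 2))
print(reports["dag"].confusion_matrix().round(1))
print(round(reports["svm"].recognition_rate, 2))
```

prints, on corpus seed 1:

```
448 1.82
91.96
           brushing   food  isolation
brushing       89.6    0.0       10.4
food            0.0  100.0        0.0
isolation       9.1    0.9       90.0
86.61
```

448 clips averaging 1.82 s; a DAG-HMM ten-fold recognition rate of
91.96 % whose row-percent confusion matrix recognizes *waiting for food*
perfectly and confuses only *isolation* and *brushing* — the documented qualitative
confusion pattern — while the pooled-vector SVM lands five
points lower. `reports["dag"].text_table()` adds per-class
precision/recall/F1.

The command line mirrors the library:

```bash
meowdag synth --seed 1 --out corpus/
meowdag evaluate --manifest corpus/manifest.csv --classifier dag --out dag.json
meowdag train --manifest corpus/manifest.csv --out model.json --dot graph.dot
```

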