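# coughdnn

Hybrid DNN-HMM classification of isolated cough / noncough sound samples,
with the GMM-HMM baseline it builds on and a fully deterministic synthetic
corpus generator.

Counting coughs objectively is a long-standing need in respiratory
medicine: severity scores from questionnaires are subjective, and ambulatory
audio monitors produce far more candidate sound events than human annotators
can label. The classifier at the heart of such a monitor must decide, for
each short isolated sound sample, *cough* or *not cough*. This package
implements that classifier the way hybrid speech recognizers are built:

* a 39-D **MFCC front end** (13 cepstra with sinusoidal liftering, Δ, ΔΔ;
  25 ms Hamming window, 10 ms shift);
* four left-to-right **HMMs** — three cough models with 4/6/8 emitting
  states and one 3-state noncough model — decoded in a free loop, with the
  decision rule "cough iff a cough model appears in the best-path
  transcription";
* a **GMM-HMM baseline** (diagonal-covariance mixtures, segmental Viterbi
  training) that both classifies on its own and provides forced-alignment
  state targets;
* **RBM / DBN pretraining** (CD-1; Gaussian-Bernoulli bottom layer, binary
  upper layers, unroll initialization W_k = W_{k−1}ᵀ) and backpropagation
  **fine-tuning** of a softmax-over-states DNN;
* **hybrid decoding** with scaled log likelihoods
  log p(s|x) − κ·log p(s) in place of GMM densities;
* the five evaluation criteria: sensitivity, specificity, cough-class F1,
  macro average (mean of the two recalls) and micro average (accuracy).

Clinical cough corpora are rarely shareable, so the `synth_corpus` module
generates a labeled stand-in — explosive band-limited cough bursts against
voiced, transient and stationary noncough sounds at 44.1 kHz, pink
background noise, patients assigned round-robin — deterministic down to the
WAV bytes given a spec.

## Worked example: the metric arithmetic

The five criteria are fully determined by the confusion counts. Given a
test set of 3119 cough and 18862 noncough samples on which a classifier
achieves recalls of 0.945 (cough) and 0.767 (noncough):

```python
>>> from coughdnn.metrics import counts_from_recalls, five_metrics, round3
>>> c = counts_from_recalls(0.945, 0.767, n_pos=3119, n_neg=18862)
>>> c
ConfusionCounts(tp=2947, fp=4395, tn=14467, fn=172)
>>> {k: round3(v) for k, v in five_metrics(c)._asdict().items()}
{'sensitivity': 0.945, 'specificity': 0.767, 'f1': 0.563,
 'macro_avg': 0.856, 'micro_avg': 0.792}
```

The low F1 despite high sensitivity is the signature of an imbalanced
screening task: 4395 false alarms against 2947 true coughs give precision
0.401, and the micro average (accuracy, 0.792) sits far below the macro
average (0.856) because the majority class dominates it.

## Worked example: training on the synthetic corpus

```python
from coughdnn import mfcc, generate_corpus, CorpusSpec, classify
from coughdnn.gmm_hmm import flat_start, viterbi_train, decode
from coughdnn.metrics import confusion, five_metrics

spec = CorpusSpec(n_cough=30, n_noncough=60, seed=42)
clips, anns = generate_corpus(spec)
labels = {a.clip_id: a.label for a in anns}
feats = {c.id: mfcc(c) for c in clips}

ids = list(feats)
modelset = flat_start([feats[i] for i in ids], [labels[i] for i in ids], seed=0)
modelset, history = viterbi_train(modelset, [(feats[i], labels[i]) for i in ids], iters=5)
print("aligned log-likelihood per iteration:", [round(h) for h in history])

preds = [classify(decode(modelset, feats[i])) for i in ids]
m = five_metrics(confusion(preds, [labels[i] for i in ids]))
print(f"sensitivity={m.sensitivity:.3f} specificity={m.specificity:.3f} "
      f"f1={m.f1:.3f} macro={m.macro_avg:.3f} micro={m.micro_avg:.3f}")
```

prints

```
aligned log-likelihood per iteration: [-784222, -740962, -736265, -735677, -735528]
sensitivity=1.000 specificity=1.000 f1=1.000 macro=1.000 micro=1.000
```

— the aligned likelihood (summed over every model/clip alignment) rises
monotonically across segmental-training iterations, and on this
(train = test) sanity check the baseline separates the two classes
perfectly. `decode` returns the full transcription, e.g.
`[('cough3', 0, 60)]`: one cough model spanning all 60 frames.

## Command line

Every stage is also a CLI subcommand over plain artifacts (WAV + TSV
manifest, `.npz` feature archives, JSON model files):

```sh
coughdnn synth      --spec spec.yaml --out corpus/
coughdnn features   --manifest corpus/manifest.tsv --out feats.npz
coughdnn train-gmm  --features feats.npz --manifest corpus/manifest.tsv --out model.json
coughdnn align      --model model.json --features feats.npz \
                    --manifest corpus/manifest.tsv --out align.tsv
coughdnn pretrain   --features feats.npz --align align.tsv --out dbn.npz
coughdnn finetune   --dbn dbn.npz --features feats.npz --align align.tsv \
                    --model model.json --out dnn.npz
coughdnn decode-dnn --model model.json --dnn dnn.npz --features feats.npz --out trans.tsv
coughdnn evaluate   --trans trans.tsv --manifest corpus/manifest.tsv
```

`coughdnn run --config exp.yaml --out rundir/` executes the whole
experiment — corpus, patient-dependent and patient-independent splits, 2:1
noncough subsampling, baseline, alignment, the pretraining grid, both
decoders, and the five-criteria report — deterministically for a given
config, with artifacts cached in the run directory. The YAML config mirrors
`coughdnn.pipeline.ExperimentConfig` (its docstring lists every field and
default); `docs/methods.md` explains the choices behind the defaults.

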