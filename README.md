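# orfvec

Coding-potential prediction for transcript sequences: given spliced
transcripts in FASTA, `orfvec` decides whether each is an mRNA (coding) or
an ncRNA/lncRNA (noncoding).

Distinguishing lncRNAs from mRNAs is hard: both are polyadenylated, spliced
and of similar length; lncRNAs may carry short ORFs encoding micropeptides;
and assembly indels break reading frames.  `orfvec` combines the classic
sequence statistics of the CPAT/CPC2/CPPred lineage with a distributed
representation of the translated protein:

* **ORF group** — longest forward-strand ORF length, coverage, integrity,
  and the in-frame **hexamer score**
  s = (1/m) Σᵢ log[f_c(hᵢ)/f_n(hᵢ)], with hexamers h₁…hₘ read from
  position 0 of the longest ORF in steps of 3 (the presumed coding frame)
  and f_c, f_n per-class hexamer frequencies learned from training data;
* **protein group** — length, isoelectric point, GRAVY, instability index
  of the protein translated from the longest ORF;
* **RNA group** — Fickett TESTCODE statistic and GC content (30 CTD
  features available behind a switch);
* **embedding group** — a 100-dimensional PV-DM paragraph vector of the
  protein split into non-overlapping 3-mers
  (`MNFLLSWVHWSLALLLYL → MNF LLS WVH WSL ALL LYL`), trained with seeded,
  bitwise-reproducible SGD with negative sampling (context half-length
  k = 2, i.e. context length 2k = 4).

The 110 features are min–max scaled to [−1, 1] and classified by an
RBF-kernel SVM (C = 300, γ = 0.4) with Platt-calibrated coding
probabilities.  Evaluation reports SN, SP, PRE, ACC, F-score, MCC (square-
rooted denominator) and trapezoidal ROC AUC.

Because the real mRNA/ncRNA benchmark corpora require external downloads,
the package ships a synthetic generator with the same statistical structure
(codon-biased planted ORFs in coding transcripts; composition-matched
noncoding sequences with bounded ORFs and optional planted sORFs / indel
corruption) so that the whole pipeline is testable offline.

## Worked example

```python
from orfvec import CodingPotentialClassifier, evaluate_predictions
from orfvec.synthetic import SyntheticConfig, simulate_dataset

coding, noncoding, _ = simulate_dataset(
    SyntheticConfig(n_coding=650, n_noncoding=650, seed=42))
train = coding[:500] + noncoding[:500]
y_train = ["coding"] * 500 + ["noncoding"] * 500
test = coding[500:] + noncoding[500:]
y_test = ["coding"] * 150 + ["noncoding"] * 150

clf = CodingPotentialClassifier(random_state=42)
clf.fit(train, y_train, unlabeled=test)      # transductive embedding
m = evaluate_predictions(y_test, clf.predict(test),
                         clf.coding_probability(test))
print(f"MCC {m.MCC:.3f}  AUC {m.AUC:.3f}  ACC {m.ACC:.3f}")
print(clf.predict(test[:3]), clf.coding_probability(test[:3]).round(3))
```

prints

```
MCC 0.907  AUC 0.985  ACC 0.953
['noncoding' 'coding' 'coding'] [0.232 0.97  0.996]
```

i.e. on 300 held-out synthetic transcripts the full model recovers the
labels with Matthews correlation 0.91.  The three transcripts shown are all
truly coding; the model is confident about the second and third and
misjudges the first (coding probability 0.23) — at this reduced training
size (500 per class) a few percent of held-out calls are wrong, and the
larger benchmark below does better.

The same flow is available from the shell:

```bash
orfvec --seed 42 simulate --out data --n-coding 500 --n-noncoding 500
orfvec --seed 42 train data/coding.fa data/noncoding.fa --out model
orfvec predict data/coding.fa --model model --out predictions.tsv
orfvec evaluate predictions.tsv data/labels.tsv
```

`predictions.tsv` has one `id  label  coding_prob` row per transcript;
`evaluate` prints the metric bundle as JSON.

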