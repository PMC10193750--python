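# Methods

## The problem and the model

`orfvec` classifies transcript sequences as coding (mRNA) or noncoding
(ncRNA/lncRNA).  Distinguishing the two is hard because lncRNAs share
poly(A) tails, splicing and length distributions with mRNAs, may carry short
ORFs encoding micropeptides, and real assemblies contain indel errors that
break reading frames.

The classifier combines four information sources computed per transcript:

1. **ORF features** — the longest forward-strand ORF (ATG through the first
   in-frame stop, stop included; three frames, no reverse complement, since
   inputs are spliced single-stranded transcripts): its length in nt, its
   coverage (length / transcript length), its integrity (+1 when both start
   and stop are present, −1 otherwise), and the **in-frame hexamer score** —
   the mean over hexamers *h₁…hₘ*, read from position 0 of the ORF in steps
   of 3, of log(f_coding(h)/f_noncoding(h)), where the two frequency tables
   are estimated from labeled training data (coding ORFs vs noncoding
   sequences, both read in steps of 3).  Reading the hexamers from the first
   reading frame of the longest ORF — rather than from the raw transcript —
   is deliberate: the ORF frame is the presumed coding frame, so in-frame
   dicodon statistics are far more informative than frame-agnostic ones.
   Zero-frequency fallbacks are bounded (both zero → 0, coding-only zero →
   −1, noncoding-only zero → +1), with no pseudocounts.
2. **Protein features** of the protein translated from the longest ORF:
   length, isoelectric point (bisection on the Henderson–Hasselbalch net
   charge with the packaged EMBOSS pKa set, to |charge| < 1e-4), GRAVY
   (mean Kyte–Doolittle hydropathy, X excluded) and the Guruprasad
   instability index ((10/L)·Σ DIWV over dipeptides; X-dipeptides weigh 0).
3. **RNA features** of the whole transcript: the Fickett TESTCODE statistic
   (published position/content probability tables and weights, packaged as
   data files; position parameter max/(min+1) over the three codon-position
   counts) and GC content.
4. **A 100-dimensional paragraph-vector (PV-DM) embedding** of the protein,
   described below.

An optional CTD group (4 composition + 6 transition + 20 distribution
features of the nucleotide sequence) is available behind a config switch and
off by default, giving 10 classic features (40 with CTD).

All features are scaled per feature to [−1, 1] with min/max taken from the
training split only, and fed to an RBF-kernel SVM with C = 300 and
γ = 0.4 (the published tuning).  Coding probabilities come from Platt-style
calibration (libsvm's `-b 1` behaviour, via scikit-learn); the decision
threshold is 0.5.  C/γ only make sense on a bounded feature scale, which is
why symmetric min–max scaling is the default; both the scaling and the
threshold are config values because the original description is silent on
them.

## The distributed representation

The protein translated from the longest ORF is split into non-overlapping
words of length 3 (`MNFLLSWVHWSLALLLYL → MNF LLS WVH WSL ALL LYL`; a
trailing remainder shorter than 3 is dropped).  Each split protein is a
document; the corpus is embedded with the distributed-memory paragraph
vector model (PV-DM): the document's paragraph vector is concatenated with
the vectors of the 2k context words around a central word, and the
concatenation predicts the central word.  The context half-length is k = 2
(context length 2k = 4), vector dimension 100, word length 3.

The trainer is written in-repo (numpy + a numba SGD kernel): stochastic
gradient descent with negative sampling (5 noise words per positive, noise
distribution ∝ unigram^0.75), learning rate decaying linearly from 0.025 to
1e-4 over all epochs, 20 epochs, min_count 1 (the trigram vocabulary is at
most ~21³ words, so no pruning is needed).  Context slots that fall outside
the document are filled by a trainable pad vector.  Training is
single-threaded and seeded — an inlined xorshift64* RNG drives negative
sampling — so runs are bitwise reproducible; this is the tested
configuration, and no multi-threaded path exists.

Two application modes: **stored** (the default protocol) embeds training
and evaluation documents jointly and returns the trained paragraph vectors —
a transductive protocol, faithful to the original method; **infer** freezes
the word and softmax matrices and optimizes a fresh, zero-initialized
paragraph vector for an unseen document with the same seeded SGD, giving a
leakage-free deployment path.  The end-to-end classifier uses stored vectors
for every transcript the embedder has seen and falls back to inference
otherwise.

Epochs, min_count, negative-sampling settings and whether vectors are
normalized are not specified by the original description; the defaults above
are the standard word2vec/doc2vec choices, and vectors enter the SVM
unnormalized (the symmetric min–max scaler handles the range; L2
normalization discards the vector-norm component, which carries document-
length information that is genuinely discriminative here).

## Evaluation metrics

SN = TP/(TP+FN), SP = TN/(FP+TN), PRE = TP/(TP+FP), ACC, F-score =
2·PRE·SN/(PRE+SN), and MCC with the square root over the four-factor
denominator (without the radical the quantity is unbounded; the square-
rooted form is the standard Matthews coefficient in [−1, 1]).  AUC is the
trapezoidal area under the ROC curve over descending score thresholds; tied
scores collapse into one ROC point, making the result identical to the
Mann–Whitney rank-sum formulation with ties counted half.  Degenerate
denominators return 0 with a warning.

## The synthetic data generator

Real benchmark corpora (RefSeq/Ensembl-derived mRNA/ncRNA sets) require
external downloads, so the package ships a generator that emulates the
statistical structure the classifier exploits:

* **Coding transcripts**: random 5'UTR + planted ORF (ATG + codons drawn
  from a dataset-level codon-usage distribution + stop) + random 3'UTR.
  The codon usage is drawn once per dataset from a symmetric Dirichlet with
  concentration 0.7 over the 61 sense codons — a skew comparable to real
  codon-usage bias — rather than copied from a real codon table, keeping the
  generator data-free and the difficulty tunable.  UTRs are resampled until
  the planted ORF is exactly the longest ORF found, so planted coordinates
  are recoverable ground truth.
* **Noncoding transcripts**: i.i.d. sequence matched to the mononucleotide
  composition implied by the coding codon usage (so GC content alone cannot
  separate the classes), rejection-sampled until the longest ORF is ≤ 300 nt.
  With probability 0.25 a short ORF (30–150 nt) built from the *coding*
  codon distribution is planted, emulating micropeptide-bearing ncRNAs as
  hard positives-lookalikes.  An optional indel mode (off by default)
  corrupts a coding-like template with per-nt indels to create frame-broken
  hard negatives.

Defaults: transcript lengths uniform on 200–1500 nt, 5'UTR 10–150 nt, 3'UTR
20–300 nt, planted ORFs ≥ 90 nt, 1000 transcripts per class.  The benchmark
harness (`orfvec.evaluation.run_synthetic_benchmark`) uses 2000+2000
training and 500+500 held-out transcripts per class — sizes at which the
embedding corpus (~5000 documents) trains in well under a minute on one
core while leaving a measurable gap between feature groups.

What the generator does **not** emulate: real protein sequence structure
(domains, motifs, conserved trigram usage across genes), splice isoforms,
expression-weighted length distributions, and real codon-usage tables.
Consequently the embedding features carry *less* class signal here than on
real data, where protein regularities are much richer: on the synthetic
corpus a supervised classifier over the full bag-of-trigram counts tops out
around MCC 0.81–0.83, so the embedding-only model's ≈0.82 is close to the
information ceiling of the protein documents, and passing the synthetic
benchmark demonstrates the machinery works end to end — not that real-data
accuracies transfer.

## Numerical and degenerate-input choices

* Ingest normalization: uppercase, U→T, every other IUPAC ambiguity code →
  N; anything else is a validation error naming the record.
* Translation: standard genetic code from position 0; any codon containing
  N → X (even when redundancy would resolve it, e.g. GGN); stops end the
  protein; trailing partial codons are dropped.
* No-complete-ORF fallback ladder: longest stop-free ATG-to-end stretch
  (trimmed to whole codons, has_stop=False); else the whole sequence in
  frame 0 (has_start=False).  Every transcript therefore yields features,
  and the flags feed ORF integrity.  For the full-sequence fallback the
  protein may be shorter than length/3 when an internal stop exists.
* ORF ties break on smaller start, then smaller frame; coordinates are
  0-based half-open throughout.
* Hexamers containing N are skipped; an ORF shorter than 6 nt scores 0.
* Empty or all-X proteins: pI, GRAVY and instability are defined as 0 with
  a warning (such transcripts are overwhelmingly noncoding fallbacks).
* Metric divisions by zero return 0 with a warning.

## Known limitations

* The transductive embedding protocol leaks unlabeled test *inputs* (not
  labels) into representation learning; the infer mode exists for settings
  where that is unacceptable, at a small accuracy cost.
* The SVM with Platt calibration refits on internal cross-validation folds;
  probabilities are smooth but not perfectly consistent with the decision
  boundary near 0.5.
* Hexamer tables require labeled training data per domain; cross-species
  transfer reuses the training tables unchanged.
* The PV-DM trainer is deliberately single-threaded for reproducibility;
  embedding 10⁵-document corpora would need a parallel variant.
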