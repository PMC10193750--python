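"""Synthetic labeled transcript datasets.

Emulates the statistical structure separating mRNAs from ncRNAs that the
classifier exploits, without any external downloads:

* coding transcripts = random 5'UTR + a planted ORF (ATG + codons drawn from
  a dataset-level skewed codon-usage distribution + stop) + random 3'UTR,
  rejection-sampled so the planted ORF is exactly the longest ORF found;
* noncoding transcripts = random sequence matched to the mononucleotide
  composition of the coding batch (so GC content alone cannot separate the
  classes), rejection-sampled to keep the longest ORF short; optionally a
  short ORF (sORF, 30-150 nt, coding-style codons) is planted to emulate
  micropeptide-bearing ncRNAs, and optionally a coding-like template is
  corrupted with indels to create frame-broken hard negatives.

Every draw is driven by one numpy Generator, so a fixed seed reproduces the
dataset byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .seqio_orf import STOP_CODONS, TranscriptRecord, find_longest_orf

_BASES = np.array(list("ACGT"))
SENSE_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                if a + b + c not in STOP_CODONS]  # 61 codons
_STOPS = sorted(STOP_CODONS)

_MAX_ATTEMPTS = 10_000


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator knobs; defaults are the package's study conditions."""

    n_coding: int = 1000
    n_noncoding: int = 1000
    len_range: tuple = (200, 1500)
    utr5_range: tuple = (10, 150)
    utr3_range: tuple = (20, 300)
    codon_bias_concentration: float = 0.7
    max_nc_orf: int = 300
    sorf_prob: float = 0.25
    indel_rate: float = 0.0
    seed: int = 42

    def __post_init__(self):
        if self.n_coding < 0 or self.n_noncoding < 0:
            raise ValueError("sample counts must be non-negative")
        if not (0 <= self.sorf_prob <= 1 and 0 <= self.indel_rate <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.len_range[0] < 60:
            raise ValueError("minimum transcript length must be >= 60 nt")
        if self.len_range[0] < self.utr5_range[0] + self.utr3_range[0] + 90:
            raise ValueError(
                "len_range cannot accommodate minimal UTRs plus a 90-nt ORF"
            )


@dataclass(frozen=True)
class DatasetContext:
    """Per-dataset draws shared by all sequences: codon usage + composition."""

    codon_probs: np.ndarray      # over SENSE_CODONS
    base_probs: np.ndarray       # mononucleotide composition for UTRs/noncoding

    @classmethod
    def draw(cls, config: SyntheticConfig, rng: np.random.Generator):
        alpha = np.full(len(SENSE_CODONS), config.codon_bias_concentration)
        codon_probs = rng.dirichlet(alpha)
        base_probs = _codon_base_composition(codon_probs)
        return cls(codon_probs, base_probs)


def _codon_base_composition(codon_probs: np.ndarray) -> np.ndarray:
    comp = np.zeros(4)
    index = {b: i for i, b in enumerate("ACGT")}
    for codon, p in zip(SENSE_CODONS, codon_probs):
        for ch in codon:
            comp[index[ch]] += p / 3.0
    return comp / comp.sum()


def _random_seq(n: int, base_probs: np.ndarray, rng) -> str:
    if n <= 0:
        return ""
    return "".join(rng.choice(_BASES, size=n, p=base_probs))


def _orf_seq(n_nt: int, ctx: DatasetContext, rng) -> str:
    """ATG + (n_nt/3 - 2) biased sense codons + one stop codon."""
    n_codons = n_nt // 3 - 2
    codons = rng.choice(len(SENSE_CODONS), size=n_codons, p=ctx.codon_probs)
    stop = _STOPS[rng.integers(len(_STOPS))]
    return "ATG" + "".join(SENSE_CODONS[i] for i in codons) + stop


def simulate_coding(config: SyntheticConfig, rng, ctx: DatasetContext,
                    ident: str = "coding_0") -> tuple[TranscriptRecord, tuple]:
    """One coding transcript; returns (record, planted ORF span).

    UTRs are resampled until the planted ORF is exactly the longest ORF of
    the transcript (so no upstream ATG extends or outranks it).
    """
    lo, hi = config.len_range
    total = int(rng.integers(lo, hi + 1))
    u5_lo, u5_hi = config.utr5_range
    u3_lo, u3_hi = config.utr3_range
    u5_hi = min(u5_hi, total - 90 - u3_lo)
    u5 = int(rng.integers(u5_lo, u5_hi + 1))
    u3_hi_eff = min(u3_hi, total - 90 - u5)
    u3 = int(rng.integers(u3_lo, u3_hi_eff + 1))
    orf_len = ((total - u5 - u3) // 3) * 3
    u3 = total - u5 - orf_len
    orf = _orf_seq(orf_len, ctx, rng)
    for _ in range(_MAX_ATTEMPTS):
        seq = _random_seq(u5, ctx.base_probs, rng) + orf \
            + _random_seq(u3, ctx.base_probs, rng)
        found = find_longest_orf(seq)
        if found.start == u5 and found.end == u5 + orf_len:
            return TranscriptRecord(ident, seq), (u5, u5 + orf_len)
    raise RuntimeError("could not place an unambiguous longest ORF; "
                       "check UTR/length configuration")


def simulate_noncoding(config: SyntheticConfig, rng, ctx: DatasetContext,
                       ident: str = "noncoding_0") -> TranscriptRecord:
    """One noncoding transcript with longest ORF <= max_nc_orf."""
    lo, hi = config.len_range
    for _ in range(_MAX_ATTEMPTS):
        total = int(rng.integers(lo, hi + 1))
        if config.indel_rate > 0:
            seq = _indel_corrupted_template(config, rng, ctx, total)
        else:
            seq = _random_seq(total, ctx.base_probs, rng)
            if rng.random() < config.sorf_prob:
                sorf_len = 3 * int(rng.integers(10, 51))  # 30..150 nt
                sorf = _orf_seq(sorf_len, ctx, rng)
                pos = int(rng.integers(0, len(seq) - sorf_len + 1))
                seq = seq[:pos] + sorf + seq[pos + sorf_len:]
        if find_longest_orf(seq).length <= config.max_nc_orf:
            return TranscriptRecord(ident, seq)
    raise RuntimeError(
        "rejection sampling failed after 10,000 attempts; "
        "consider a larger max_nc_orf"
    )


def _indel_corrupted_template(config, rng, ctx, total) -> str:
    """Coding-like template corrupted by per-nt indels (hard negatives)."""
    rec, _ = simulate_coding(replace(config, indel_rate=0.0), rng, ctx,
                             ident="template")
    chars = list(rec.seq)
    out = []
    for ch in chars:
        r = rng.random()
        if r < config.indel_rate / 2:
            continue  # deletion
        out.append(ch)
        if r > 1 - config.indel_rate / 2:
            out.append(str(rng.choice(_BASES)))  # insertion
    seq = "".join(out)
    if len(seq) > total:
        seq = seq[:total]
    return seq if seq else rec.seq[:total]


def simulate_dataset(config: SyntheticConfig):
    """(coding records, noncoding records, labels) for a full dataset.

    Labels are (id, label) pairs, label in {"coding", "noncoding"}; ids
    encode class and index.  Same seed => byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    ctx = DatasetContext.draw(config, rng)
    width = max(4, len(str(max(config.n_coding, config.n_noncoding))))
    coding = []
    for i in range(config.n_coding):
        rec, _ = simulate_coding(config, rng, ctx, f"coding_{i:0{width}d}")
        coding.append(rec)
    noncoding = [
        simulate_noncoding(config, rng, ctx, f"noncoding_{i:0{width}d}")
        for i in range(config.n_noncoding)
    ]
    labels = [(r.id, "coding") for r in coding] \
        + [(r.id, "noncoding") for r in noncoding]
    return coding, noncoding, labels


def write_labels(labels, path) -> None:
    """Labels TSV: id<TAB>label, one row per record."""
    with open(path, "w") as out:
        for ident, label in labels:
            out.write(f"{ident}\t{label}\n")
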