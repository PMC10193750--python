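"""In-frame hexamer usage tables and the hexamer log-likelihood score.

The hexamer score is the classic coding statistic of the CPAT lineage: the
mean log-ratio of coding versus noncoding frequencies of 6-mers.  Here the
score is computed on the first reading frame of the longest ORF — hexamers
are read from position 0 of the ORF in steps of 3, so each 6-mer spans two
consecutive codons in the presumed coding frame.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_POWERS = 4 ** np.arange(5, -1, -1)
N_HEXAMERS = 4096

_ALPHABET = "ACGT"


def hexamer_string(code: int) -> str:
    """Decode a 0..4095 hexamer index back to its 6-mer string."""
    chars = []
    for p in range(5, -1, -1):
        chars.append(_ALPHABET[(code >> (2 * p)) & 3])
    return "".join(chars)


def _encode(seq: str) -> np.ndarray:
    """Map a normalized sequence to base indices; N (or any other) -> -1."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int64)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def _inframe_codes(seq: str) -> np.ndarray:
    """Hexamer indices read from position 0 in steps of 3; N-containing skipped."""
    n = len(seq)
    if n < 6:
        return np.empty(0, dtype=np.int64)
    enc = _encode(seq)
    starts = np.arange(0, n - 5, 3)
    windows = enc[starts[:, None] + np.arange(6)]
    valid = (windows >= 0).all(axis=1)
    return windows[valid] @ _POWERS


class HexamerTable:
    """Per-class frequency tables over the 4096 DNA hexamers.

    Coding counts come from in-frame hexamers of coding ORFs; noncoding
    counts from noncoding sequences read the same way (position 0, step 3).
    Absent hexamers are stored with frequency 0.
    """

    def __init__(self, coding: np.ndarray, noncoding: np.ndarray):
        coding = np.asarray(coding, dtype=float)
        noncoding = np.asarray(noncoding, dtype=float)
        if coding.shape != (N_HEXAMERS,) or noncoding.shape != (N_HEXAMERS,):
            raise ValueError("frequency tables must have length 4096")
        self.coding = coding
        self.noncoding = noncoding
        self._ratio: np.ndarray | None = None

    # -- construction ------------------------------------------------------
    @classmethod
    def from_sequences(cls, coding_orfs, noncoding_seqs) -> "HexamerTable":
        if not coding_orfs or not noncoding_seqs:
            raise ValueError(
                "building a hexamer table requires at least one coding ORF "
                "and one noncoding sequence"
            )
        tables = []
        for group in (coding_orfs, noncoding_seqs):
            counts = np.zeros(N_HEXAMERS, dtype=float)
            for seq in group:
                codes = _inframe_codes(seq)
                if codes.size:
                    counts += np.bincount(codes, minlength=N_HEXAMERS)
            total = counts.sum()
            if total > 0:
                counts /= total
            tables.append(counts)
        return cls(*tables)

    # -- mapping-style access ---------------------------------------------
    def coding_freq(self, hexamer: str) -> float:
        return float(self.coding[int(_encode(hexamer) @ _POWERS)])

    def noncoding_freq(self, hexamer: str) -> float:
        return float(self.noncoding[int(_encode(hexamer) @ _POWERS)])

    # -- scoring -----------------------------------------------------------
    @property
    def log_ratios(self) -> np.ndarray:
        """Per-hexamer log(coding/noncoding) with bounded zero-frequency fallbacks.

        Both frequencies zero -> 0; coding zero only -> -1; noncoding zero
        only -> +1 (the CPAT convention, no pseudocounts).
        """
        if self._ratio is None:
            c, n = self.coding, self.noncoding
            r = np.zeros(N_HEXAMERS)
            both = (c > 0) & (n > 0)
            with np.errstate(divide="ignore"):
                r[both] = np.log(c[both] / n[both])
            r[(c == 0) & (n > 0)] = -1.0
            r[(c > 0) & (n == 0)] = 1.0
            self._ratio = r
        return self._ratio

    def score(self, orf_nt_seq: str) -> float:
        """Mean per-hexamer log-ratio over in-frame hexamers; 0 when none."""
        codes = _inframe_codes(orf_nt_seq)
        if codes.size == 0:
            return 0.0
        return float(self.log_ratios[codes].mean())

    # -- serialization -----------------------------------------------------
    def to_tsv(self, path) -> None:
        with Path(path).open("w") as out:
            out.write("hexamer\tcoding_freq\tnoncoding_freq\n")
            for code in range(N_HEXAMERS):
                out.write(
                    f"{hexamer_string(code)}\t{self.coding[code]:.12g}"
                    f"\t{self.noncoding[code]:.12g}\n"
                )

    @classmethod
    def from_tsv(cls, path) -> "HexamerTable":
        coding = np.zeros(N_HEXAMERS)
        noncoding = np.zeros(N_HEXAMERS)
        with Path(path).open() as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header != ["hexamer", "coding_freq", "noncoding_freq"]:
                raise ValueError(f"unrecognized hexamer table header: {header}")
            for line in fh:
                hx, c, n = line.rstrip("\n").split("\t")
                code = int(_encode(hx) @ _POWERS)
                coding[code] = float(c)
                noncoding[code] = float(n)
        return cls(coding, noncoding)


def build_hexamer_table(coding_orfs, noncoding_seqs) -> HexamerTable:
    """Count in-frame hexamers per class and normalize to frequencies."""
    return HexamerTable.from_sequences(coding_orfs, noncoding_seqs)


def hexamer_score(orf, table: HexamerTable) -> float:
    """Hexamer score of an ORF (or raw nucleotide string) under a table."""
    nt = orf if isinstance(orf, str) else orf.nt_seq
    return table.score(nt)
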