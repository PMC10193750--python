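"""Classic (non-embedding) coding-potential features.

Three feature groups over the transcript, its longest ORF, and the protein
translated from that ORF:

* ``orf``     — ORF length / coverage / integrity and the in-frame hexamer score
* ``protein`` — protein length, isoelectric point, GRAVY, instability index
* ``rna``     — Fickett TESTCODE score and GC content

plus an optional ``ctd`` group (30 composition/transition/distribution
features of the nucleotide sequence).  All operations are pure functions;
the ``ClassicFeatureExtractor`` estimator wraps them, fitting the hexamer
table from labeled training transcripts.
"""

from __future__ import annotations

import logging
import math
from importlib import resources
from itertools import combinations

import numpy as np
from Bio.SeqUtils.ProtParamData import DIWV, kd
from sklearn.base import BaseEstimator, TransformerMixin

from .hexamer import HexamerTable, build_hexamer_table, hexamer_score
from .seqio_orf import OrfResult, as_records, find_longest_orf

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_QUANTILES = (0.0, 0.25, 0.5, 0.75, 1.0)

CTD_NAMES = (
    [f"ctd_comp_{b}" for b in _BASES]
    + [f"ctd_trans_{a}{b}" for a, b in combinations(_BASES, 2)]
    + [f"ctd_dist_{b}_q{int(q * 100)}" for b in _BASES for q in _QUANTILES]
)

GROUP_FEATURES = {
    "orf": ["orf_length", "orf_coverage", "orf_integrity", "hexamer_score"],
    "protein": ["protein_length", "isoelectric_point", "gravy", "instability_index"],
    "rna": ["fickett_score", "gc_content"],
    "ctd": CTD_NAMES,
}
GROUP_ORDER = ("orf", "protein", "rna", "ctd")


# ---------------------------------------------------------------------------
# packaged lookup tables
# ---------------------------------------------------------------------------

def _load_fickett():
    tables: dict[str, dict] = {
        "position_prob": {}, "content_prob": {},
        "position_weight": {}, "content_weight": {},
    }
    thresholds: dict[str, list[float]] = {}
    text = resources.files("orfvec.data").joinpath("fickett_testcode.tsv").read_text()
    for line in text.splitlines():
        if not line or line.startswith("#") or line.startswith("kind\t"):
            continue
        kind, base, *vals = line.split("\t")
        vals = [float(v) for v in vals]
        if kind.endswith("_threshold"):
            thresholds[kind.split("_")[0]] = vals
        elif kind.endswith("_weight"):
            tables[kind][base] = vals[0]
        else:
            tables[kind][base] = vals
    return tables, thresholds


_FICKETT_TABLES, _FICKETT_THRESHOLDS = _load_fickett()


def _load_pka():
    pka: dict[str, tuple[float, int]] = {}
    text = resources.files("orfvec.data").joinpath("pka_set.tsv").read_text()
    for line in text.splitlines():
        if not line or line.startswith("#") or line.startswith("group\t"):
            continue
        group, value, sign = line.split("\t")
        pka[group] = (float(value), int(sign))
    return pka


PKA_SET = _load_pka()


# ---------------------------------------------------------------------------
# nucleotide-sequence features
# ---------------------------------------------------------------------------

def _lookup(param: float, thresholds, probs) -> float:
    for t, p in zip(thresholds, probs):
        if param >= t:
            return p
    return probs[-1]


def fickett_score(seq: str) -> float:
    """Fickett TESTCODE statistic of a nucleotide sequence.

    Per base: the position parameter is max/(min+1) of the base's counts in
    the three codon positions, the content parameter is the base's fraction
    of the sequence; both are mapped through the published probability
    tables and combined with the published weights.  N counts toward no base.
    """
    n = len(seq)
    if n == 0:
        raise ValueError("fickett_score of an empty sequence is undefined")
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    score = 0.0
    for base in _BASES:
        mask = arr == ord(base)
        counts = [int(mask[offset::3].sum()) for offset in range(3)]
        position = max(counts) / (min(counts) + 1.0)
        content = int(mask.sum()) / n
        score += _lookup(position, _FICKETT_THRESHOLDS["position"],
                         _FICKETT_TABLES["position_prob"][base]) \
            * _FICKETT_TABLES["position_weight"][base]
        score += _lookup(content, _FICKETT_THRESHOLDS["content"],
                         _FICKETT_TABLES["content_prob"][base]) \
            * _FICKETT_TABLES["content_weight"][base]
    return score


def gc_content(seq: str) -> float:
    """(G + C) / length; N excluded from the numerator only."""
    if not seq:
        raise ValueError("gc_content of an empty sequence is undefined")
    return (seq.count("G") + seq.count("C")) / len(seq)


def ctd_features(seq: str) -> np.ndarray:
    """Composition/transition/distribution features (30 values, CTD_NAMES order).

    Composition: per-base fraction of length.  Transition: for each unordered
    base pair, the fraction of adjacent positions carrying that (unequal)
    pair.  Distribution: for each base, the 1-based position of its 1st /
    25% / 50% / 75% / last occurrence (occurrence index ceil(q*count),
    floored at 1) divided by length; all 5 are 0 for an absent base.
    """
    n = len(seq)
    if n == 0:
        raise ValueError("ctd_features of an empty sequence is undefined")
    values = []
    for b in _BASES:
        values.append(seq.count(b) / n)
    pairs = {frozenset(p): 0 for p in combinations(_BASES, 2)}
    for a, b in zip(seq, seq[1:]):
        key = frozenset((a, b))
        if len(key) == 2 and key in pairs:
            pairs[key] += 1
    denom = max(n - 1, 1)
    for a, b in combinations(_BASES, 2):
        values.append(pairs[frozenset((a, b))] / denom)
    for b in _BASES:
        positions = [i + 1 for i, c in enumerate(seq) if c == b]
        if not positions:
            values.extend([0.0] * len(_QUANTILES))
            continue
        count = len(positions)
        for q in _QUANTILES:
            idx = max(1, math.ceil(q * count))
            values.append(positions[idx - 1] / n)
    return np.array(values)


# ---------------------------------------------------------------------------
# protein features
# ---------------------------------------------------------------------------

def gravy(protein: str) -> float:
    """Grand average of Kyte-Doolittle hydropathy; X residues excluded."""
    vals = [kd[aa] for aa in protein if aa != "X"]
    if not vals:
        logger.warning("gravy of an empty/all-X protein defined as 0")
        return 0.0
    return sum(vals) / len(vals)


def net_charge(protein: str, ph: float) -> float:
    """Henderson-Hasselbalch net charge at a given pH (termini + side chains)."""
    groups = [("Nterm", 1), ("Cterm", 1)]
    groups += [(aa, protein.count(aa)) for aa in "CDEHKRY"]
    charge = 0.0
    for name, count in groups:
        if count == 0:
            continue
        pka, sign = PKA_SET[name]
        if sign > 0:
            charge += count * 10 ** pka / (10 ** ph + 10 ** pka)
        else:
            charge -= count * 10 ** ph / (10 ** ph + 10 ** pka)
    return charge


def isoelectric_point(protein: str, tol: float = 1e-4) -> float:
    """pH in [0, 14] where the net charge vanishes, found by bisection."""
    if not protein:
        logger.warning("isoelectric point of an empty protein defined as 0")
        return 0.0
    lo, hi = 0.0, 14.0
    ph = 7.0
    for _ in range(200):
        ph = (lo + hi) / 2.0
        q = net_charge(protein, ph)
        if abs(q) < tol:
            break
        if q > 0:
            lo = ph
        else:
            hi = ph
    return ph


def instability_index(protein: str) -> float:
    """Guruprasad dipeptide-weight instability index, (10/L) * sum of DIWV.

    Dipeptides containing X contribute the table's default weight (0).
    """
    L = len(protein)
    if L < 2:
        logger.warning("instability index of a <2-residue protein defined as 0")
        return 0.0
    total = 0.0
    for a, b in zip(protein, protein[1:]):
        total += DIWV.get(a, {}).get(b, 0.0)
    return 10.0 / L * total


# ---------------------------------------------------------------------------
# ORF features
# ---------------------------------------------------------------------------

def orf_basic_features(orf: OrfResult, transcript_len: int):
    """(orf_length, orf_coverage, orf_integrity) of a located ORF."""
    if transcript_len == 0:
        raise ValueError("transcript length must be positive")
    length = orf.end - orf.start
    coverage = length / transcript_len
    integrity = 1.0 if (orf.has_start and orf.has_stop) else -1.0
    return length, coverage, integrity


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class ClassicFeatureExtractor(BaseEstimator, TransformerMixin):
    """Compute classic coding-potential features for transcripts.

    Parameters
    ----------
    groups : tuple of str
        Which feature groups to emit, drawn from {"orf", "protein", "rna",
        "ctd"}; emitted in canonical order.  Default is the 10-feature
        configuration (orf + protein + rna); adding "ctd" yields 40.

    Fitting estimates the per-class in-frame hexamer table from labeled
    transcripts (coding ORFs vs noncoding full sequences); it is only
    required when the "orf" group is enabled.
    """

    def __init__(self, groups=("orf", "protein", "rna")):
        self.groups = groups

    # y: labels in {"coding", "noncoding"} (or 1/0)
    def fit(self, X, y=None):
        groups = self._check_groups()
        records = as_records(X)
        if "orf" in groups:
            if y is None:
                raise ValueError("fitting the hexamer table requires labels")
            labels = _canonical_labels(y)
            coding_orfs = [
                find_longest_orf(r.seq).nt_seq
                for r, lab in zip(records, labels) if lab == "coding"
            ]
            noncoding = [r.seq for r, lab in zip(records, labels)
                         if lab == "noncoding"]
            self.hexamer_table_ = build_hexamer_table(coding_orfs, noncoding)
        self.feature_names_ = [
            name for g in GROUP_ORDER if g in groups for name in GROUP_FEATURES[g]
        ]
        return self

    def transform(self, X, orfs=None) -> np.ndarray:
        groups = self._check_groups()
        records = as_records(X)
        if orfs is None:
            orfs = [find_longest_orf(r.seq) for r in records]
        rows = []
        for rec, orf in zip(records, orfs):
            row: list[float] = []
            if "orf" in groups:
                length, cov, integ = orf_basic_features(orf, rec.length)
                row += [length, cov, integ,
                        hexamer_score(orf, self.hexamer_table_)]
            if "protein" in groups:
                p = orf.protein
                row += [len(p), isoelectric_point(p), gravy(p),
                        instability_index(p)]
            if "rna" in groups:
                row += [fickett_score(rec.seq), gc_content(rec.seq)]
            if "ctd" in groups:
                row += list(ctd_features(rec.seq))
            rows.append(row)
        return np.array(rows, dtype=float).reshape(len(records), -1)

    def get_feature_names_out(self, input_features=None):
        return np.array(self.feature_names_)

    def _check_groups(self):
        groups = set(self.groups)
        unknown = groups - set(GROUP_ORDER)
        if unknown:
            raise ValueError(f"unknown feature groups: {sorted(unknown)}")
        return groups


def _canonical_labels(y) -> list[str]:
    out = []
    for lab in y:
        if lab in ("coding", "noncoding"):
            out.append(lab)
        elif lab in (1, True):
            out.append("coding")
        elif lab in (0, False):
            out.append("noncoding")
        else:
            raise ValueError(f"unrecognized label: {lab!r}")
    return out
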