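import numpy as np
import pytest

from orfvec.seqio_orf import STOP_CODONS


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_dna(rng, length, bases="ACGT"):
    return "".join(rng.choice(list(bases), size=length))


def brute_force_longest_orf(seq):
    """Independent oracle: enumerate every ATG..stop span in all 3 frames.

    Returns (start, end, frame, has_start, has_stop) under the same
    tie-break (longest, then smallest start, then smallest frame) and
    fallback ladder as the production finder.
    """
    complete = []
    for frame in range(3):
        for s in range(frame, len(seq) - 2, 3):
            if seq[s:s + 3] != "ATG":
                continue
            for e in range(s + 3, len(seq) - 2 + 1, 3):
                if seq[e:e + 3] in STOP_CODONS:
                    complete.append((s, e + 3, frame))
                    break
    key = lambda t: (-(t[1] - t[0]), t[0], t[2])
    if complete:
        s, e, f = min(complete, key=key)
        return (s, e, f, True, True)
    open_spans = []
    for frame in range(3):
        for s in range(frame, len(seq) - 2, 3):
            if seq[s:s + 3] == "ATG":
                stop_free = all(seq[e:e + 3] not in STOP_CODONS
                                for e in range(s, len(seq) - 2, 3))
                if stop_free:
                    end = s + 3 * ((len(seq) - s) // 3)
                    open_spans.append((s, end, frame))
                break  # only the first ATG of the frame can be longest
    if open_spans:
        s, e, f = min(open_spans, key=key)
        return (s, e, f, True, False)
    return (0, len(seq), 0, False, False)
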