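"""Shared fixtures and independent mini-oracles used across the suite."""

import numpy as np
import pytest

from guidescout.guide_finder import get_nuclease
from guidescout.offtarget import ScoreTables


@pytest.fixture
def spcas9():
    return get_nuclease("spcas9")


@pytest.fixture
def sacas9():
    return get_nuclease("sacas9")


@pytest.fixture
def cpf1():
    return get_nuclease("cpf1")


@pytest.fixture
def uniform_tables():
    """Synthetic tables with all weights/penalties strictly inside (0, 1)."""
    return ScoreTables.uniform(20)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


@pytest.fixture
def dna_factory():
    return random_dna


# ---------------------------------------------------------------------------
# Independent microhomology oracle: a different traversal (substring
# dictionary join) than the implementation's nested position scan.
# ---------------------------------------------------------------------------

def mh_patterns_oracle(context: str, cut: int, window: int = 30, min_len: int = 2):
    lo, hi = max(0, cut - window), min(len(context), cut + window)
    left_index: dict[str, list[int]] = {}
    for l in range(lo, cut):
        for e in range(l + min_len, cut + 1):
            left_index.setdefault(context[l:e], []).append(l)
    raw = []
    for r in range(cut, hi):
        for e in range(r + min_len, hi + 1):
            sub = context[r:e]
            for l in left_index.get(sub, []):
                if r >= l + len(sub):
                    raw.append((l, r, len(sub), r - l, sub))
    kept = []
    for p in raw:
        contained = any(
            q[3] == p[3]
            and q[2] > p[2]
            and q[0] <= p[0]
            and p[0] + p[2] <= q[0] + q[2]
            for q in raw
        )
        if not contained:
            kept.append(p)
    kept.sort(key=lambda p: (p[3], p[0], p[2]))
    return kept


def oof_oracle(context: str, cut: int, window: int = 30, min_len: int = 2):
    import math

    patterns = mh_patterns_oracle(context, cut, window, min_len)
    if not patterns:
        return None
    weights = []
    for _l, _r, _length, dlen, seq in patterns:
        gc = sum(b in "GC" for b in seq)
        at = len(seq) - gc
        weights.append((dlen, 100.0 * round(math.exp(-dlen / 20.0), 3) * (2 * gc + at)))
    total = sum(w for _d, w in weights)
    if total == 0:
        return None
    return 100.0 * sum(w for d, w in weights if d % 3 != 0) / total


@pytest.fixture
def mh_oracle():
    return mh_patterns_oracle


@pytest.fixture
def oof_oracle_fn():
    return oof_oracle
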