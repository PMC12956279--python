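"""Shared fixtures and the independent brute-force folding oracle."""

from __future__ import annotations

from functools import lru_cache

import pytest

from rtdna.structure import DEFAULT_WEIGHTS, DnaSequence


def brute_force_best_score(
    seq: DnaSequence,
    min_loop: int = 3,
    weights=None,
) -> float:
    """Best non-crossing structure score by exhaustive right-to-left recursion.

    Independent of the production engine: it conditions on the partner of
    the *rightmost* residue of each interval, carries no traceback and no
    tie-breaking, and relies on memoized plain recursion rather than a
    bottom-up table.  Usable up to ~length 25.
    """
    wmap = dict(DEFAULT_WEIGHTS) if weights is None else {
        frozenset(k): v for k, v in weights.items()
    }
    s = seq.residues

    def w(i: int, j: int) -> float:
        if seq.masked(i) or seq.masked(j):
            return 0.0
        return wmap.get(frozenset((s[i], s[j])), 0.0)

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> float:
        if j - i < min_loop + 1:
            return 0.0
        score = best(i, j - 1)  # j unpaired
        for k in range(i, j - min_loop):
            wk = w(k, j)
            if wk > 0.0:
                left = best(i, k - 1) if k - 1 >= i else 0.0
                inner = best(k + 1, j - 1)
                score = max(score, wk + left + inner)
        return score

    return best(0, len(s) - 1)


@pytest.fixture
def hairpin():
    """The canonical toy hairpin: three G·C pairs around an AAA loop."""
    return DnaSequence("hairpin", "GGGAAACCC")
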