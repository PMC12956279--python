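"""Secondary-structure prediction and cargo-insertion design for retron msd scaffolds.

Retrons produce an abundant single-stranded DNA (the msd-derived RT-DNA) in
vivo, and the msd can carry a functional cargo sequence — here a fluorogenic
DNA aptamer — provided the insertion does not disrupt the native scaffold
fold.  This module predicts a non-crossing base-pair structure for a DNA
sequence, classifies each position by its structural context, proposes
insertion gaps inside unpaired runs, builds scaffold+cargo fusions, and
scores how much of the scaffold's pairing survives refolding of the fusion.

The default folding engine is a weighted base-pair-maximization dynamic
program (Nussinov-style) with DNA pair weights G·C = 3, A·T = 2, G·T = 1 and
a minimum hairpin loop of 3 unpaired residues.  It is a score surrogate, not
a nearest-neighbor free-energy model; any external thermodynamic folder can
be plugged in through the ``engine`` callable accepted by the design helpers
(an engine is any callable ``(DnaSequence) -> FoldResult``).

Coordinates are 0-based throughout.  Insertion sites use gap-index
semantics: the cargo is inserted *before* the residue at ``position``, so
valid positions run from 0 (prepend) to ``len(scaffold)`` (append).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

__all__ = [
    "DNA_ALPHABET",
    "DEFAULT_WEIGHTS",
    "DEFAULT_MIN_LOOP",
    "DnaSequence",
    "FoldResult",
    "PositionAnnotation",
    "InsertionSite",
    "FusionConstruct",
    "StemAnnotation",
    "fold_mfe",
    "parse_dotbracket",
    "pairs_to_dotbracket",
    "classify_positions",
    "propose_insertion_sites",
    "build_fusion",
    "fold_preservation",
    "truncate_stem",
]

DNA_ALPHABET = frozenset("ACGT")

#: Pair weights for the default engine: canonical G·C and A·T plus the G·T
#: wobble, which is stable enough in DNA hairpins to be worth one unit.
DEFAULT_WEIGHTS: dict[frozenset[str], float] = {
    frozenset("GC"): 3.0,
    frozenset("AT"): 2.0,
    frozenset("GT"): 1.0,
}

#: Minimum number of unpaired residues enclosed by a pair (hairpin loop size).
DEFAULT_MIN_LOOP = 3


@dataclass(frozen=True)
class DnaSequence:
    """A labelled DNA sequence with an optional pairing-exclusion mask.

    The mask is a closed interval ``(start, end)`` of positions forbidden
    from base pairing.  Its intended use is the msr-overlapping region of a
    retron ncRNA, which is sequestered in an RNA/DNA duplex in vivo and must
    not be folded intramolecularly.
    """

    id: str
    residues: str
    mask: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("sequence must be non-empty")
        bad = set(self.residues) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"non-alphabet characters in sequence {self.id!r}: {sorted(bad)}"
            )
        if self.mask is not None:
            lo, hi = self.mask
            if not (0 <= lo <= hi < len(self.residues)):
                raise ValueError(
                    f"mask {self.mask} outside sequence bounds [0, {len(self.residues)})"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def masked(self, index: int) -> bool:
        return self.mask is not None and self.mask[0] <= index <= self.mask[1]

    def trim_mask(self) -> "DnaSequence":
        """Return the sequence with the masked region removed (trim mode).

        Coordinates of the result no longer align with the original; the
        default mask mode preserves them and is preferred for design.
        """
        if self.mask is None:
            return self
        lo, hi = self.mask
        return DnaSequence(self.id, self.residues[:lo] + self.residues[hi + 1 :])


@dataclass(frozen=True)
class FoldResult:
    """A sequence together with a predicted non-crossing base-pair set."""

    sequence: DnaSequence
    pairs: frozenset[tuple[int, int]]
    score: float

    def __post_init__(self) -> None:
        n = len(self.sequence)
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (0 <= i < j < n):
                raise ValueError(f"pair {(i, j)} outside sequence bounds")
            if i in seen or j in seen:
                raise ValueError(f"index reused by pair {(i, j)}")
            seen |= {i, j}
        sp = sorted(self.pairs)
        for a, (i, j) in enumerate(sp):
            for k, l in sp[a + 1 :]:
                if k >= j:
                    break
                if i < k < j < l:
                    raise ValueError(f"crossing pairs {(i, j)} and {(k, l)}")

    @property
    def dotbracket(self) -> str:
        return pairs_to_dotbracket(self.pairs, len(self.sequence))


@dataclass(frozen=True)
class PositionAnnotation:
    """Structural class of one residue: paired, hairpin_loop, internal_or_bulge, exterior."""

    index: int
    cls: str


@dataclass(frozen=True)
class InsertionSite:
    """A candidate cargo insertion gap inside an unpaired run."""

    position: int
    run_length: int
    cls: str
    rank: int


@dataclass(frozen=True)
class FusionConstruct:
    scaffold_id: str
    cargo_id: str
    site: InsertionSite
    residues: str


@dataclass(frozen=True)
class StemAnnotation:
    """An ordered, nested, contiguous helix — outermost pair first.

    Models a terminal stem such as the aptamer's P1, which tolerates
    shortening from its full length down to a few base pairs.
    """

    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("stem must contain at least one pair")
        for (i0, j0), (i1, j1) in zip(self.pairs, self.pairs[1:]):
            if not (i1 == i0 + 1 and j1 == j0 - 1):
                raise ValueError("stem pairs must be nested and contiguous, outermost first")


def _normalize_weights(
    weights: Mapping | None,
) -> dict[frozenset[str], float]:
    if weights is None:
        return dict(DEFAULT_WEIGHTS)
    out: dict[frozenset[str], float] = {}
    for key, w in weights.items():
        out[frozenset(key)] = float(w)
    return out


def _pair_weight(a: str, b: str, weights: Mapping[frozenset[str], float]) -> float:
    return weights.get(frozenset((a, b)), 0.0)


def fold_mfe(
    seq: DnaSequence,
    min_loop: int = DEFAULT_MIN_LOOP,
    weights: Mapping | None = None,
) -> FoldResult:
    """Predict a maximum-score non-crossing structure by dynamic programming.

    Fills the classic interval table ``N[i][j]`` (best score on residues
    ``i..j``) where residue ``i`` is either unpaired or paired with some
    ``k`` such that ``k - i - 1 >= min_loop``, and traces back
    deterministically: whenever pairing the leftmost residue achieves the
    optimum, it is paired with its smallest admissible partner.  Masked
    positions never pair.

    Parameters
    ----------
    seq:
        Input sequence; its ``mask``, if set, is enforced as a hard pairing
        exclusion.
    min_loop:
        Minimum unpaired residues enclosed by any pair (default 3).
    weights:
        Mapping of pair type (e.g. ``"GC"``) to score; unlisted pairs are
        disallowed.  Defaults to GC=3, AT=2, GT=1.
    """
    if min_loop < 0:
        raise ValueError("min_loop must be >= 0")
    wmap = _normalize_weights(weights)
    s = seq.residues
    n = len(s)

    def pairable(i: int, k: int) -> float:
        if seq.masked(i) or seq.masked(k):
            return 0.0
        return _pair_weight(s[i], s[k], wmap)

    # N[i][j]: best score on closed interval [i, j]; empty/singleton = 0.
    N = [[0.0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = N[i + 1][j]  # i unpaired
            for k in range(i + min_loop + 1, j + 1):
                w = pairable(i, k)
                if w <= 0.0:
                    continue
                inner = N[i + 1][k - 1] if k - 1 >= i + 1 else 0.0
                outer = N[k + 1][j] if k + 1 <= j else 0.0
                cand = w + inner + outer
                if cand > best:
                    best = cand
            N[i][j] = best

    # Traceback, preferring to pair the smallest i with the smallest k.
    pairs: set[tuple[int, int]] = set()
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j:
            continue
        target = N[i][j]
        if target == 0.0:
            continue
        chosen = None
        for k in range(i + min_loop + 1, j + 1):
            w = pairable(i, k)
            if w <= 0.0:
                continue
            inner = N[i + 1][k - 1] if k - 1 >= i + 1 else 0.0
            outer = N[k + 1][j] if k + 1 <= j else 0.0
            if w + inner + outer == target:
                chosen = k
                break
        if chosen is None:
            stack.append((i + 1, j))
        else:
            pairs.add((i, chosen))
            stack.append((i + 1, chosen - 1))
            stack.append((chosen + 1, j))

    return FoldResult(sequence=seq, pairs=frozenset(pairs), score=N[0][n - 1] if n > 1 else 0.0)


def parse_dotbracket(s: str) -> frozenset[tuple[int, int]]:
    """Parse a dot-bracket string into a set of (i, j) pairs, i < j."""
    pairs = set()
    stack: list[int] = []
    for idx, ch in enumerate(s):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at index {idx}")
            pairs.add((stack.pop(), idx))
        elif ch != ".":
            raise ValueError(f"invalid character {ch!r} at index {idx}")
    if stack:
        raise ValueError(f"unbalanced '(' at index {stack[-1]}")
    return frozenset(pairs)


def pairs_to_dotbracket(pairs: Iterable[tuple[int, int]], length: int) -> str:
    chars = ["."] * length
    for i, j in pairs:
        if not (0 <= i < j < length):
            raise ValueError(f"pair {(i, j)} outside sequence of length {length}")
        if chars[i] != "." or chars[j] != ".":
            raise ValueError(f"index reused by pair {(i, j)}")
        chars[i], chars[j] = "(", ")"
    return "".join(chars)


def classify_positions(fold: FoldResult) -> list[PositionAnnotation]:
    """Assign each residue to paired / hairpin_loop / internal_or_bulge / exterior.

    An unpaired residue takes the class of its innermost enclosing pair:
    hairpin loop if that pair encloses no other pair, internal loop or bulge
    otherwise, exterior if no pair encloses it.
    """
    n = len(fold.sequence)
    paired = {i for p in fold.pairs for i in p}
    sorted_pairs = sorted(fold.pairs)
    out = []
    for idx in range(n):
        if idx in paired:
            out.append(PositionAnnotation(idx, "paired"))
            continue
        enclosing = None
        for i, j in sorted_pairs:
            if i < idx < j and (enclosing is None or i > enclosing[0]):
                enclosing = (i, j)
        if enclosing is None:
            out.append(PositionAnnotation(idx, "exterior"))
            continue
        i, j = enclosing
        has_inner = any(i < a and b < j for a, b in fold.pairs)
        cls = "internal_or_bulge" if has_inner else "hairpin_loop"
        out.append(PositionAnnotation(idx, cls))
    return out


_CLS_PRIORITY = {"hairpin_loop": 0, "exterior": 1, "internal_or_bulge": 2}


def propose_insertion_sites(
    fold: FoldResult, min_run: int = 3, k: int | None = None
) -> list[InsertionSite]:
    """Rank candidate cargo-insertion gaps inside unpaired runs.

    One site per maximal unpaired run of length >= ``min_run``, placed at
    the run midpoint.  Runs are ranked longest first, then by class
    (hairpin loop > exterior > internal loop/bulge), then leftmost.  The
    ranking is a reported heuristic, not a biological assertion: loops and
    single-stranded stretches are where a cargo is least likely to disturb
    the scaffold fold.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    annos = classify_positions(fold)
    runs: list[tuple[int, int, str]] = []  # (start, length, cls)
    i = 0
    n = len(annos)
    while i < n:
        if annos[i].cls == "paired":
            i += 1
            continue
        j = i
        while j < n and annos[j].cls != "paired":
            j += 1
        runs.append((i, j - i, annos[i].cls))
        i = j
    candidates = [r for r in runs if r[1] >= min_run]
    candidates.sort(key=lambda r: (-r[1], _CLS_PRIORITY[r[2]], r[0]))
    if k is not None:
        candidates = candidates[:k]
    return [
        InsertionSite(position=start + length // 2, run_length=length, cls=cls, rank=rank)
        for rank, (start, length, cls) in enumerate(candidates, start=1)
    ]


def build_fusion(
    scaffold: DnaSequence, cargo: DnaSequence, site: InsertionSite
) -> FusionConstruct:
    """Insert the cargo before scaffold residue ``site.position``."""
    pos = site.position
    if not (0 <= pos <= len(scaffold)):
        raise IndexError(
            f"insertion position {pos} outside scaffold bounds [0, {len(scaffold)}]"
        )
    residues = scaffold.residues[:pos] + cargo.residues + scaffold.residues[pos:]
    return FusionConstruct(
        scaffold_id=scaffold.id, cargo_id=cargo.id, site=site, residues=residues
    )


def fold_preservation(
    scaffold_fold: FoldResult, fusion_fold: FoldResult, site: InsertionSite
) -> float:
    """Fraction of scaffold base pairs retained in the refolded fusion.

    Scaffold pair indices at or beyond the insertion gap are shifted by the
    cargo length before comparison.  A pairless scaffold is vacuously
    preserved (returns 1.0).
    """
    shift = len(fusion_fold.sequence) - len(scaffold_fold.sequence)
    if shift < 0:
        raise ValueError("fusion shorter than scaffold: inconsistent inputs")
    if not scaffold_fold.pairs:
        return 1.0
    pos = site.position

    def shifted(idx: int) -> int:
        return idx + shift if idx >= pos else idx

    kept = sum(
        1
        for i, j in scaffold_fold.pairs
        if (shifted(i), shifted(j)) in fusion_fold.pairs
    )
    return kept / len(scaffold_fold.pairs)


def truncate_stem(cargo: DnaSequence, stem: StemAnnotation, keep: int) -> DnaSequence:
    """Shorten a terminal stem to ``keep`` base pairs.

    Removes the residues of the outermost ``len(stem) - keep`` pairs from
    both strands, leaving everything interior untouched — the in-silico
    analogue of trimming an aptamer's P1 stem.
    """
    n_pairs = len(stem.pairs)
    if not (1 <= keep <= n_pairs):
        raise ValueError(f"keep must be in [1, {n_pairs}], got {keep}")
    drop = {idx for pair in stem.pairs[: n_pairs - keep] for idx in pair}
    residues = "".join(c for i, c in enumerate(cargo.residues) if i not in drop)
    return DnaSequence(id=f"{cargo.id}_stem{keep}", residues=residues)


#: Type alias for pluggable folding engines.
FoldingEngine = Callable[[DnaSequence], FoldResult]
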