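"""RNA secondary structures with pseudoknots, and pair-score-matrix decoding.

Structures are plain pair sets over 0-based coordinates; crossing pairs
(pseudoknots) are first-class.  Dot-bracket I/O supports up to 30 bracket
levels (``()``, ``[]``, ``{}``, ``<>``, then ``Aa``..``Zz``), the convention
used by pseudoknot-capable folding tools.  Pair-score (base-pair probability)
matrices can be decoded into structures either by maximum-weight linear
assignment with unpaired diagonal weights ("Hungarian" decoding) or by the
mutual-row-maximum rule (ThreshKnot).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "SecondaryStructure",
    "PairScoreMatrix",
    "DotBracketError",
    "parse_dotbracket",
    "write_dotbracket",
    "crossed_pairs",
    "hungarian_decode",
    "threshknot_decode",
    "window_sequence",
    "read_ct",
    "write_ct",
]

# Bracket alphabets by level: 4 ASCII bracket pairs, then letter pairs.
_OPENERS = "([{<" + "".join(chr(ord("A") + k) for k in range(26))
_CLOSERS = ")]}>" + "".join(chr(ord("a") + k) for k in range(26))
MAX_LEVELS = len(_OPENERS)  # 30


class DotBracketError(ValueError):
    """Malformed dot-bracket text; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (position {position})")
        self.position = position


@dataclass(frozen=True)
class SecondaryStructure:
    """A set of base pairs over a sequence of given length.

    Pairs are 0-based ``(i, j)`` tuples with ``i < j``; each index occurs in
    at most one pair.  Crossing pairs are allowed.
    """

    length: int
    pairs: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("length must be positive")
        seen = set()
        norm = set()
        for p in self.pairs:
            i, j = (p[0], p[1]) if p[0] < p[1] else (p[1], p[0])
            if i < 0 or j >= self.length:
                raise ValueError(f"pair {p} out of range for length {self.length}")
            if i == j:
                raise ValueError(f"self-pair at index {i}")
            if i in seen or j in seen:
                raise ValueError(f"index in more than one pair: {p}")
            seen.update((i, j))
            norm.add((i, j))
        object.__setattr__(self, "pairs", frozenset(norm))

    @property
    def paired_positions(self) -> frozenset:
        return frozenset(i for p in self.pairs for i in p)

    def partner(self, i: int):
        """Pairing partner of position i, or None if unpaired."""
        for a, b in self.pairs:
            if a == i:
                return b
            if b == i:
                return a
        return None

    def pair_matrix(self) -> np.ndarray:
        """Symmetric 0/1 connectivity matrix M with M[i, j] = 1 iff i pairs j."""
        m = np.zeros((self.length, self.length))
        for i, j in self.pairs:
            m[i, j] = m[j, i] = 1.0
        return m


@dataclass
class PairScoreMatrix:
    """Symmetric per-pair score/probability matrix with optional diagonal
    unpaired weights."""

    scores: np.ndarray
    unpaired_weight: np.ndarray | None = None

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[0] != self.scores.shape[1]:
            raise ValueError("scores must be a square matrix")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")
        if not np.allclose(self.scores, self.scores.T, atol=1e-8):
            # symmetrize silently-asymmetric inputs from upstream predictors
            self.scores = 0.5 * (self.scores + self.scores.T)
        if self.unpaired_weight is not None:
            self.unpaired_weight = np.asarray(self.unpaired_weight, dtype=float)
            if self.unpaired_weight.shape != (self.scores.shape[0],):
                raise ValueError("unpaired_weight length mismatch")

    @property
    def length(self) -> int:
        return self.scores.shape[0]

    def diagonal_weights(self) -> np.ndarray:
        """Unpaired weights: supplied values, else 1 - row max clipped to [0, 1]."""
        if self.unpaired_weight is not None:
            return self.unpaired_weight
        off = self.scores - np.diag(np.diag(self.scores))
        return np.clip(1.0 - off.max(axis=1), 0.0, 1.0)


def parse_dotbracket(text: str) -> SecondaryStructure:
    """Parse multi-level dot-bracket notation into a structure.

    Each bracket level is an independent stack, so crossing levels encode
    pseudoknots.  Raises :class:`DotBracketError` naming the first offending
    position for unbalanced input.
    """
    text = text.strip()
    if not text:
        raise DotBracketError("empty dot-bracket string", 0)
    stacks: dict[int, list[int]] = {}
    pairs = set()
    for pos, ch in enumerate(text):
        if ch == ".":
            continue
        lvl = _OPENERS.find(ch)
        if lvl >= 0:
            stacks.setdefault(lvl, []).append(pos)
            continue
        lvl = _CLOSERS.find(ch)
        if lvl >= 0:
            stack = stacks.get(lvl, [])
            if not stack:
                raise DotBracketError(f"unmatched '{ch}'", pos)
            pairs.add((stack.pop(), pos))
            continue
        raise DotBracketError(f"invalid character {ch!r}", pos)
    for lvl, stack in stacks.items():
        if stack:
            raise DotBracketError(f"unmatched '{_OPENERS[lvl]}'", stack[0])
    return SecondaryStructure(length=len(text), pairs=frozenset(pairs))


def _crosses(p, q) -> bool:
    i, j = p
    m, n = q
    return (i < m < j < n) or (m < i < n < j)


def write_dotbracket(structure: SecondaryStructure) -> str:
    """Render a (possibly pseudoknotted) structure as dot-bracket text.

    Pairs are assigned greedily to the first bracket level on which they do
    not cross any pair already placed at that level.
    """
    levels: list[list[tuple]] = []
    chars = ["."] * structure.length
    for pair in sorted(structure.pairs):
        placed = False
        for lvl, members in enumerate(levels):
            if not any(_crosses(pair, q) for q in members):
                members.append(pair)
                chars[pair[0]] = _OPENERS[lvl]
                chars[pair[1]] = _CLOSERS[lvl]
                placed = True
                break
        if not placed:
            if len(levels) >= MAX_LEVELS:
                raise ValueError(f"structure requires more than {MAX_LEVELS} bracket levels")
            levels.append([pair])
            chars[pair[0]] = _OPENERS[len(levels) - 1]
            chars[pair[1]] = _CLOSERS[len(levels) - 1]
    return "".join(chars)


def crossed_pairs(structure: SecondaryStructure) -> frozenset:
    """Pairs involved in at least one crossing (pseudoknot) relation.

    Pairs (i, j) and (m, n) cross when i < m < j < n (checked both ways).
    """
    pairs = sorted(structure.pairs)
    crossed = set()
    for a in range(len(pairs)):
        for b in range(a + 1, len(pairs)):
            if _crosses(pairs[a], pairs[b]):
                crossed.add(pairs[a])
                crossed.add(pairs[b])
    return frozenset(crossed)


def hungarian_decode(
    matrix: PairScoreMatrix, threshold: float = 0.5, min_sep: int = 4
) -> SecondaryStructure:
    """Decode a pair-score matrix by maximum-weight linear assignment.

    The diagonal holds unpaired weights (defaulting to ``1 - row max``), so
    the assignment trades pairing a nucleotide against leaving it unpaired.
    A pair (i, j) is kept iff the assignment is mutual, ``scores[i, j] >=
    threshold``, and ``|i - j| >= min_sep`` (short separations correspond to
    sterically impossible hairpin loops of length < 3).  Lone pairs (singlet
    stems) are retained.
    """
    L = matrix.length
    cost = matrix.scores.copy()
    np.fill_diagonal(cost, matrix.diagonal_weights())
    _, assign = linear_sum_assignment(cost, maximize=True)
    pairs = set()
    for i in range(L):
        j = int(assign[i])
        if j <= i:
            continue
        if int(assign[j]) != i:
            continue
        if matrix.scores[i, j] < threshold:
            continue
        if j - i < min_sep:
            continue
        pairs.add((i, j))
    return SecondaryStructure(length=L, pairs=frozenset(pairs))


def threshknot_decode(matrix: PairScoreMatrix, threshold: float = 0.3) -> SecondaryStructure:
    """ThreshKnot decoding: keep pairs that are mutual row maxima above a
    threshold; conflicts resolved by descending score (ties: smaller i, then
    smaller j); minimum separation 4 enforced."""
    L = matrix.length
    s = matrix.scores - np.diag(np.diag(matrix.scores))
    rowmax = s.max(axis=1)
    candidates = []
    for i in range(L):
        for j in range(i + 1, L):
            if j - i < 4:
                continue
            v = s[i, j]
            if v >= threshold and v >= rowmax[i] - 1e-12 and v >= rowmax[j] - 1e-12:
                candidates.append((v, i, j))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    used = set()
    pairs = set()
    for v, i, j in candidates:
        if i in used or j in used:
            continue
        pairs.add((i, j))
        used.update((i, j))
    return SecondaryStructure(length=L, pairs=frozenset(pairs))


def window_sequence(seq: str, window: int, stride: int = 10) -> list[tuple[int, str]]:
    """Tile a sequence with fixed-size windows at a given stride.

    The final window is end-anchored so the full sequence is covered; a
    sequence shorter than the window is returned as a single window (padding
    to length is the library-design step's job).
    """
    if window <= 0 or stride <= 0:
        raise ValueError("window and stride must be positive")
    L = len(seq)
    if L <= window:
        return [(0, seq)]
    starts = list(range(0, L - window + 1, stride))
    if starts[-1] + window < L:
        starts.append(L - window)
    return [(s, seq[s : s + window]) for s in starts]


def read_ct(text: str) -> tuple[str, SecondaryStructure]:
    """Read a CT-format record (1-based indices) into (sequence, structure)."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split()
    n = int(header[0])
    seq = []
    pairs = set()
    for ln in lines[1 : n + 1]:
        f = ln.split()
        idx = int(f[0]) - 1
        seq.append(f[1])
        partner = int(f[4])
        if partner > 0 and partner - 1 > idx:
            pairs.add((idx, partner - 1))
    return "".join(seq), SecondaryStructure(length=n, pairs=frozenset(pairs))


def write_ct(seq: str, structure: SecondaryStructure, title: str = "") -> str:
    """Write a CT-format record (1-based, per the format's convention)."""
    if len(seq) != structure.length:
        raise ValueError("sequence/structure length mismatch")
    partner = [0] * structure.length
    for i, j in structure.pairs:
        partner[i] = j + 1
        partner[j] = i + 1
    out = [f"{structure.length} {title}".rstrip()]
    for i, base in enumerate(seq):
        nxt = i + 2 if i + 1 < structure.length else 0
        out.append(f"{i + 1} {base} {i} {nxt} {partner[i]} {i + 1}")
    return "\n".join(out) + "\n"
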