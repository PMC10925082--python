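"""Oligo-library construct assembly: barcodes, pads, and constant flanks.

Synthesized probing libraries require every construct to share one length.
Each region of interest is padded to the target length, tagged with a unique
stem-loop barcode on its 3' side, and flanked by constant priming sequences:
a 5' GAGUA-capped hairpin and a 3' A/C-rich tail.  Barcodes are stem-loop
hairpins closed by a 5'-UUCG-3' tetraloop, kept at a minimum mutual edit
distance so sequencing reads demultiplex unambiguously.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np

__all__ = [
    "FLANK5",
    "FLANK3",
    "ConstructLayout",
    "BarcodeSet",
    "edit_distance",
    "design_barcode_set",
    "design_pad",
    "assemble_construct",
    "default_pairing_oracle",
    "reverse_complement",
    "to_dna",
    "to_rna",
]

FLANK5 = "GGGAACGACUCGAGUAGAGUCGAAAA"  # constant 5' priming hairpin (GAGUA cap)
FLANK3 = "AAAAGAAACAACAACAACAAC"       # constant 3' priming tail

TETRALOOP = "UUCG"
_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
_BASES = np.array(list("ACGU"))


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def to_dna(seq: str) -> str:
    """Transliterate RNA to DNA (U -> T) for oligo ordering."""
    return seq.replace("U", "T")


def to_rna(seq: str) -> str:
    return seq.replace("T", "U")


@dataclass
class ConstructLayout:
    """One synthesizable construct: flank5 + insert + pad + barcode + flank3."""

    insert: str
    pad: str
    barcode: str
    flank5: str = FLANK5
    flank3: str = FLANK3

    @property
    def full(self) -> str:
        return self.flank5 + self.insert + self.pad + self.barcode + self.flank3


@dataclass
class BarcodeSet:
    barcodes: list[str]
    stem_length: int
    min_edit_distance: int


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance (unit-cost substitution/insertion/deletion)."""
    return edlib.align(a, b)["editDistance"]


def design_barcode_set(
    n: int, stem_length: int, min_dist: int = 2, seed: int = 0, max_attempts_per_barcode: int = 500
) -> BarcodeSet:
    """Sample n stem-loop barcodes at mutual edit distance >= min_dist.

    Each barcode is stem + UUCG + reverse-complement(stem) (Watson-Crick
    A-U/G-C), drawn by seeded rejection sampling against the already-placed
    set.  Raises if the compliant space is exhausted, reporting how many
    barcodes were placed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    placed: list[str] = []
    attempts_left = n * max_attempts_per_barcode
    while len(placed) < n:
        if attempts_left <= 0:
            raise RuntimeError(
                f"barcode space exhausted: placed {len(placed)} of {n} "
                f"(stem {stem_length}, min distance {min_dist})"
            )
        attempts_left -= 1
        stem = "".join(rng.choice(_BASES, size=stem_length))
        candidate = stem + TETRALOOP + reverse_complement(stem)
        if all(edit_distance(candidate, b) >= min_dist for b in placed):
            placed.append(candidate)
    return BarcodeSet(barcodes=placed, stem_length=stem_length, min_edit_distance=min_dist)


def default_pairing_oracle(context: str, pad: str, min_match: int = 6) -> float:
    """Crude pairing-propensity score between a pad and its sequence context:
    the number of length->=min_match substrings of the pad whose reverse
    complement occurs in the context.  Pluggable; any callable with the same
    signature (e.g. one backed by an ensemble base-pair-probability model)
    can replace it."""
    hits = 0
    for k in range(len(pad) - min_match + 1):
        if reverse_complement(pad[k : k + min_match]) in context:
            hits += 1
    return float(hits)


def _random_unstructured(length: int, rng) -> str:
    # A/C-rich: A and C cannot Watson-Crick pair with each other
    return "".join(rng.choice(np.array(list("AC")), size=length, p=[0.6, 0.4]))


def _single_stemloop(length: int, rng) -> str:
    """A hairpin filling `length` nt: unpaired A-spacer + stem-UUCG-stem."""
    stem = max((length - len(TETRALOOP)) // 2, 2)
    spacer = length - (2 * stem + len(TETRALOOP))
    while spacer < 0:
        stem -= 1
        spacer = length - (2 * stem + len(TETRALOOP))
    half = "".join(rng.choice(_BASES, size=stem))
    return "A" * spacer + half + TETRALOOP + reverse_complement(half)


def design_pad(
    length: int,
    context: str,
    oracle=default_pairing_oracle,
    n_candidates: int = 16,
    seed: int = 0,
) -> str:
    """Design a pad of exactly `length` nt that minimizes predicted
    interaction with the context.

    Short pads (< 8 nt) are unstructured A/C-rich stretches; 8-30 nt pads
    fold as one stem-loop; longer pads as a chain of stem-loops.  Among
    seeded random candidates the one with the lowest oracle score wins.
    """
    if length < 0:
        raise ValueError("length must be nonnegative")
    if length == 0:
        return ""
    rng = np.random.default_rng(seed)

    def make() -> str:
        if length < 8:
            return _random_unstructured(length, rng)
        if length <= 30:
            return _single_stemloop(length, rng)
        parts = []
        remaining = length
        while remaining > 30:
            parts.append(_single_stemloop(24, rng))
            remaining -= 24
        if remaining >= 8:
            parts.append(_single_stemloop(remaining, rng))
        elif remaining > 0:
            parts.append(_random_unstructured(remaining, rng))
        return "".join(parts)

    candidates = [make() for _ in range(max(n_candidates, 1))]
    scores = [oracle(context, c) for c in candidates]
    return candidates[int(np.argmin(scores))]


def assemble_construct(
    insert: str,
    target_length: int,
    barcode: str,
    seed: int = 0,
    oracle=default_pairing_oracle,
) -> ConstructLayout:
    """Pad an insert to the target length, append its barcode, and add the
    constant flanks.  The pad sits between insert and barcode."""
    pad_len = target_length - len(insert) - len(barcode)
    if pad_len < 0:
        raise ValueError(
            f"insert ({len(insert)} nt) + barcode ({len(barcode)} nt) exceed "
            f"target length {target_length}"
        )
    pad = design_pad(pad_len, insert, oracle=oracle, seed=seed)
    return ConstructLayout(insert=insert, pad=pad, barcode=barcode)
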