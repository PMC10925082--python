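"""Reactivity pipeline: per-position event counts -> normalized profiles.

Mutational-profiling (MaP) experiments read out chemical adducts as mutation
and deletion events during reverse transcription.  This module turns raw
per-position counts into background-subtracted, percentile-normalized
reactivity profiles with propagated counting-statistics errors, a profile
signal-to-noise estimate, and a boolean quality flag, plus utilities for
mutate-and-map (M2) reactivity matrices.

Missing values are encoded as NaN throughout; a position is missing when its
coverage is zero or when either the modified or control channel is missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "Chemistry",
    "CountsTrack",
    "ReactivityProfile",
    "M2Matrix",
    "redistribute_deletions",
    "compute_rates",
    "background_subtract",
    "normalize_profiles",
    "estimate_snr",
    "apply_sn_filter",
    "m2_zscore",
    "mutant_row_average",
    "profile_from_counts",
]

SNR_THRESHOLD = 1.00   # profile passes only with signal-to-noise strictly above this
READS_THRESHOLD = 100  # ... and strictly more reads than this


class Chemistry(str, Enum):
    """Probing chemistry: 2A3 (SHAPE-like, all nucleotides) or DMS (A/C)."""

    SHAPE_2A3 = "2A3"
    DMS = "DMS"


@dataclass
class CountsTrack:
    """Per-position modification/deletion/coverage counts for one sequence
    in one channel (modified or no-modification control).

    ``del_events`` may be fractional after deletion redistribution.
    """

    sequence: str
    mod_events: np.ndarray
    del_events: np.ndarray
    coverage: np.ndarray
    total_reads: int = 0

    def __post_init__(self):
        self.mod_events = np.asarray(self.mod_events, dtype=float)
        self.del_events = np.asarray(self.del_events, dtype=float)
        self.coverage = np.asarray(self.coverage, dtype=float)
        L = len(self.sequence)
        for name in ("mod_events", "del_events", "coverage"):
            arr = getattr(self, name)
            if arr.shape != (L,):
                raise ValueError(f"{name} length {arr.shape} != sequence length {L}")
            if np.any(arr < 0):
                raise ValueError(f"{name} has negative entries")
        if np.any(self.mod_events > self.coverage + 1e-9) or np.any(
            self.del_events > self.coverage + 1e-9
        ):
            raise ValueError("event counts exceed coverage")
        if self.total_reads < 0:
            raise ValueError("total_reads must be nonnegative")


@dataclass
class ReactivityProfile:
    """Normalized reactivity with errors and profile-level quality metrics."""

    sequence_id: str
    sequence: str
    chemistry: Chemistry
    reactivity: np.ndarray
    error: np.ndarray
    reads: int = 0
    snr: float = 0.0
    sn_filter: bool = False

    def __post_init__(self):
        self.reactivity = np.asarray(self.reactivity, dtype=float)
        self.error = np.asarray(self.error, dtype=float)
        if self.reactivity.shape != self.error.shape:
            raise ValueError("reactivity/error shape mismatch")
        r_missing = np.isnan(self.reactivity)
        e_missing = np.isnan(self.error)
        if not np.array_equal(r_missing, e_missing):
            raise ValueError("reactivity and error must share the same missing mask")
        if np.any(self.error[~e_missing] <= 0):
            raise ValueError("errors must be positive where present")

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where a value is present."""
        return ~np.isnan(self.reactivity)


@dataclass
class M2Matrix:
    """Mutate-and-map matrix: row 0 = wild type, row k = mutant at position
    k - 1; columns are probed positions."""

    values: np.ndarray
    sequence: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("M2 matrix must be 2-D")


def _runs(sequence: str):
    """Maximal runs of identical nucleotides as (start, end) half-open spans."""
    i = 0
    while i < len(sequence):
        j = i + 1
        while j < len(sequence) and sequence[j] == sequence[i]:
            j += 1
        yield i, j
        i = j


def redistribute_deletions(track: CountsTrack) -> CountsTrack:
    """Reallocate ambiguous deletions within same-nucleotide stretches.

    A deletion inside a homopolymer run cannot be localized; within each
    maximal run of identical nucleotides the run's deletion total is
    redistributed in proportion to the (unambiguous) mutation signal at each
    position.  If the run carries no mutation signal, the total is split
    uniformly.  Positions outside runs of length >= 2, mutation counts and
    coverage are untouched; per-run deletion totals are conserved.
    """
    dels = track.del_events.copy()
    for start, end in _runs(track.sequence):
        if end - start < 2:
            continue
        total = dels[start:end].sum()
        if total == 0:
            continue
        weights = track.mod_events[start:end].astype(float)
        wsum = weights.sum()
        if wsum > 0:
            dels[start:end] = total * weights / wsum
        else:
            dels[start:end] = total / (end - start)
    return CountsTrack(
        sequence=track.sequence,
        mod_events=track.mod_events.copy(),
        del_events=dels,
        coverage=track.coverage.copy(),
        total_reads=track.total_reads,
    )


def compute_rates(track: CountsTrack) -> tuple[np.ndarray, np.ndarray]:
    """Event rate and counting-statistics error per position.

    rate = (mutations + deletions) / coverage; error = sqrt(events + 1) /
    coverage.  The +1 pseudocount keeps the error positive at zero-event
    positions.  Zero-coverage positions are missing (NaN), not an error.
    """
    events = track.mod_events + track.del_events
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(track.coverage > 0, events / track.coverage, np.nan)
        error = np.where(track.coverage > 0, np.sqrt(events + 1.0) / track.coverage, np.nan)
    return rate, error


def background_subtract(
    mod: tuple[np.ndarray, np.ndarray], ctrl: tuple[np.ndarray, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Subtract the no-modification control rate, propagating errors in
    quadrature.  Results may be negative; missing in either input is missing
    in the output."""
    r_mod, e_mod = (np.asarray(a, dtype=float) for a in mod)
    r_ctrl, e_ctrl = (np.asarray(a, dtype=float) for a in ctrl)
    if r_mod.shape != r_ctrl.shape:
        raise ValueError("modified/control length mismatch")
    r = r_mod - r_ctrl
    e = np.sqrt(e_mod**2 + e_ctrl**2)
    missing = np.isnan(r_mod) | np.isnan(r_ctrl)
    r[missing] = np.nan
    e[missing] = np.nan
    return r, e


def normalize_profiles(
    rates: list[np.ndarray],
    errors: list[np.ndarray],
    mask: list[np.ndarray] | None = None,
) -> tuple[list[np.ndarray], list[np.ndarray], float]:
    """Scale a collection so the pooled 90th-percentile reactivity is 1.0.

    One scale factor is computed over all non-missing values in the
    collection (after applying the optional exclusion ``mask``, True =
    exclude, used e.g. for 3' barcode hairpins) and divides both
    reactivities and errors.  Returns (rates, errors, scale).
    """
    if mask is not None:
        pooled = np.concatenate(
            [r[~m.astype(bool)] for r, m in zip(rates, mask, strict=True)]
        )
    else:
        pooled = np.concatenate([np.asarray(r, dtype=float) for r in rates])
    pooled = pooled[~np.isnan(pooled)]
    if pooled.size == 0:
        raise ValueError("cannot normalize an all-missing collection")
    scale = float(np.percentile(pooled, 90))  # linear interpolation convention
    if scale <= 0:
        raise ValueError(f"nonpositive 90th percentile reactivity ({scale}); cannot normalize")
    out_r = []
    out_e = []
    for k, (r, e) in enumerate(zip(rates, errors, strict=True)):
        r = np.asarray(r, dtype=float) / scale
        e = np.asarray(e, dtype=float) / scale
        if mask is not None:
            excl = mask[k].astype(bool)
            r = r.copy()
            e = e.copy()
            r[excl] = np.nan
            e[excl] = np.nan
        out_r.append(r)
        out_e.append(e)
    return out_r, out_e, scale


def estimate_snr(reactivity: np.ndarray, error: np.ndarray) -> float:
    """Profile signal-to-noise: mean reactivity over mean error at positions
    with nonzero reactivity, trimming the first and last such positions when
    at least 4 are available.  No nonzero positions -> 0; floored at 0."""
    r = np.asarray(reactivity, dtype=float)
    e = np.asarray(error, dtype=float)
    idx = np.flatnonzero(~np.isnan(r) & (r != 0))
    if idx.size == 0:
        return 0.0
    if idx.size >= 4:
        idx = idx[1:-1]
    snr = float(np.mean(r[idx]) / np.mean(e[idx]))
    return max(snr, 0.0)


def apply_sn_filter(snr: float, reads: int) -> bool:
    """Quality flag: True iff signal-to-noise > 1.00 and reads > 100 (both
    strict)."""
    return snr > SNR_THRESHOLD and reads > READS_THRESHOLD


def profile_from_counts(
    mod: CountsTrack,
    ctrl: CountsTrack,
    sequence_id: str = "",
    chemistry: Chemistry = Chemistry.SHAPE_2A3,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Single-sequence pipeline up to (unnormalized) subtracted rates.

    Redistributes deletions in both channels, computes rates and errors, and
    background-subtracts.  Returns (rate, error, reads); normalization is a
    collection-level step (see :func:`normalize_profiles`).
    """
    if mod.sequence != ctrl.sequence:
        raise ValueError("modified/control sequence mismatch")
    r, e = background_subtract(
        compute_rates(redistribute_deletions(mod)),
        compute_rates(redistribute_deletions(ctrl)),
    )
    return r, e, mod.total_reads


def finalize_profile(
    sequence_id: str,
    sequence: str,
    chemistry: Chemistry,
    reactivity: np.ndarray,
    error: np.ndarray,
    reads: int,
) -> ReactivityProfile:
    """Attach SNR and the SN quality flag to a normalized profile."""
    snr = estimate_snr(reactivity, error)
    return ReactivityProfile(
        sequence_id=sequence_id,
        sequence=sequence,
        chemistry=chemistry,
        reactivity=np.asarray(reactivity, dtype=float),
        error=np.asarray(error, dtype=float),
        reads=int(reads),
        snr=snr,
        sn_filter=apply_sn_filter(snr, int(reads)),
    )


def m2_zscore(matrix: M2Matrix) -> M2Matrix:
    """Column-wise Z-scores of an M2 matrix (population standard deviation).

    Missing entries are excluded from the column statistics and stay
    missing; zero-variance columns map to all zeros.
    """
    v = matrix.values.copy()
    for c in range(v.shape[1]):
        col = v[:, c]
        present = ~np.isnan(col)
        if present.sum() < 2:
            continue
        mu = col[present].mean()
        sd = col[present].std()  # ddof=0
        if sd == 0:
            v[present, c] = 0.0
        else:
            v[present, c] = (col[present] - mu) / sd
    return M2Matrix(values=v, sequence=matrix.sequence)


def mutant_row_average(
    profiles: list[tuple[int | None, np.ndarray]], length: int
) -> M2Matrix:
    """Average profiles sharing a mutated position into one M2 row each.

    ``profiles`` holds (mutated_position, reactivity) with position ``None``
    for wild type (row 0); row k + 1 averages all profiles mutated at
    position k, element-wise ignoring missing values.  Rows with no profiles
    are all-missing.
    """
    rows = np.full((length + 1, length), np.nan)
    groups: dict[int, list[np.ndarray]] = {}
    for pos, r in profiles:
        key = -1 if pos is None else int(pos)
        groups.setdefault(key, []).append(np.asarray(r, dtype=float))
    for key, members in groups.items():
        stacked = np.vstack(members)
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(stacked, axis=0)
        rows[key + 1] = mean
    return M2Matrix(values=rows)
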