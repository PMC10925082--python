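"""Baseline models of sequencing-read dropout.

Some library members return far fewer reads than others; synthesis failures
on homopolymer repeats and reverse-transcription blocks at long, stable
hairpins are the usual suspects.  This module provides those two heuristic
features, read-count scaling to a fixed per-sequence mean, the log-reads MSE
loss, and shrinkage ("empirical Bayes") bin estimators mapping a feature
value to expected log reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure import SecondaryStructure

__all__ = [
    "LOG_EPSILON",
    "DropoutRecord",
    "BinEstimator",
    "longest_repeat",
    "longest_repeated_substring",
    "longest_hairpin",
    "scale_reads",
    "log_reads",
    "log_reads_mse",
    "fit_bayes_bin",
]

LOG_EPSILON = 1.0  # added inside logs so dropped-out (zero-read) sequences stay finite
TARGET_MEAN_READS = 1000.0


@dataclass
class DropoutRecord:
    sequence_id: str
    sequence: str
    longest_repeat: int
    longest_hairpin: int
    reads: float
    scaled_reads: float
    log_reads: float


def longest_repeat(seq: str) -> int:
    """Length of the longest homopolymer run."""
    if not seq:
        raise ValueError("empty sequence")
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def longest_repeated_substring(seq: str) -> int:
    """Length of the longest substring occurring at least twice (may
    overlap); alternative reading of the repeat feature."""
    if not seq:
        raise ValueError("empty sequence")
    lo, hi = 0, len(seq) - 1
    while lo < hi:  # binary search on answer length
        mid = (lo + hi + 1) // 2
        seen = set()
        found = False
        for k in range(len(seq) - mid + 1):
            sub = seq[k : k + mid]
            if sub in seen:
                found = True
                break
            seen.add(sub)
        if found:
            lo = mid
        else:
            hi = mid - 1
    return lo


def longest_hairpin(structure: SecondaryStructure) -> int:
    """Length in base pairs of the longest helix (maximal run of stacked
    pairs (i,j), (i+1,j-1), ...).  Empty structure -> 0."""
    pairs = set(structure.pairs)
    best = 0
    for i, j in pairs:
        if (i - 1, j + 1) in pairs:
            continue  # not a helix start
        run = 1
        a, b = i + 1, j - 1
        while (a, b) in pairs:
            run += 1
            a += 1
            b -= 1
        best = max(best, run)
    return best


def scale_reads(reads, target_mean: float = TARGET_MEAN_READS) -> np.ndarray:
    """Proportionally rescale read counts so the per-sequence mean equals
    target_mean (the experiments' nominal average read budget)."""
    r = np.asarray(reads, dtype=float)
    mean = r.mean()
    if mean <= 0:
        raise ValueError("cannot scale an all-zero read vector")
    return r * (target_mean / mean)


def log_reads(reads) -> np.ndarray:
    """Natural log of reads with the epsilon stabilizer."""
    return np.log(np.asarray(reads, dtype=float) + LOG_EPSILON)


def log_reads_mse(pred, obs) -> float:
    """MSE of log-reads, the dropout training/validation loss.  Both inputs
    should already be scaled to a common mean."""
    p = np.asarray(pred, dtype=float)
    o = np.asarray(obs, dtype=float)
    if p.shape != o.shape:
        raise ValueError("length mismatch")
    return float(np.mean((log_reads(p) - log_reads(o)) ** 2))


@dataclass
class BinEstimator:
    """Shrinkage estimator: predicted log-reads per integer feature bin.

    Each bin's prediction is pulled toward the global mean with pseudo-count
    strength k: (n * bin_mean + k * global_mean) / (n + k).  Unseen bins
    fall back to the global mean.
    """

    bins: dict = field(default_factory=dict)  # value -> (n, mean log_reads)
    global_mean: float = 0.0
    k: float = 10.0

    def predict_one(self, value: int) -> float:
        if value not in self.bins:
            return self.global_mean
        n, mean = self.bins[value]
        return (n * mean + self.k * self.global_mean) / (n + self.k)

    def predict(self, values) -> np.ndarray:
        return np.array([self.predict_one(int(v)) for v in values])


def fit_bayes_bin(feature_values, log_read_values, k: float = 10.0) -> BinEstimator:
    """Fit a per-bin shrinkage estimator of log-reads on an integer feature
    (e.g. longest repeat or longest hairpin length)."""
    f = np.asarray(feature_values)
    y = np.asarray(log_read_values, dtype=float)
    if f.size == 0:
        raise ValueError("empty training data")
    if f.shape != y.shape:
        raise ValueError("feature/target length mismatch")
    bins = {}
    for value in np.unique(f):
        sel = f == value
        bins[int(value)] = (int(sel.sum()), float(y[sel].mean()))
    return BinEstimator(bins=bins, global_mean=float(y.mean()), k=float(k))
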