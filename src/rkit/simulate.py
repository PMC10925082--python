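"""Synthetic fixtures emulating the statistics of large-scale chemical
mapping experiments.

The generator produces random (optionally pseudoknotted) secondary
structures, reactivity profiles in which unpaired positions are markedly
more reactive than paired ones, binomial mutation/deletion count tracks for
modified and no-modification control channels, mutate-and-map matrices with
partner-position perturbations, and log-normally distributed read counts
depressed by homopolymer repeats and long hairpins.

Defaults reflect MaP-scale experiments: background mutation rate ~0.5%, a
reactivity-to-mutation-rate gain of 5% per reactivity unit, mean paired
reactivity ~0.1 versus ~0.7 unpaired, and a nominal average of 1000 reads
per sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reactivity import CountsTrack
from .structure import SecondaryStructure, crossed_pairs

__all__ = [
    "SimConfig",
    "simulate_structure",
    "simulate_sequence",
    "simulate_reactivity",
    "simulate_counts",
    "simulate_m2",
    "simulate_reads",
    "recover_profile",
]

MIN_SEP = 4  # minimum |i - j| for any simulated pair


@dataclass
class SimConfig:
    """Generation parameters; defaults define the study conditions."""

    seed: int = 0
    n_sequences: int = 100
    length_min: int = 40
    length_max: int = 80
    paired_mean: float = 0.1     # mean reactivity at paired positions
    paired_shape: float = 2.0    # gamma shape for paired reactivities
    unpaired_mean: float = 0.7   # mean reactivity at unpaired positions
    unpaired_shape: float = 4.0
    base_rate: float = 0.005     # background mutation rate (control channel)
    alpha: float = 0.05          # mutation-rate gain per reactivity unit
    del_fraction: float = 0.2    # fraction of modification events read as deletions
    pk_prob: float = 0.3         # probability a structure carries a pseudoknot
    log_reads_mu: float = np.log(1000.0)   # log-normal read model
    log_reads_sigma: float = 0.8
    beta_repeat: float = 0.15    # log-reads drop per unit longest repeat
    beta_hairpin: float = 0.05   # log-reads drop per unit longest hairpin
    m2_effect: float = 0.5       # reactivity boost at mutated site and partner

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _place_stems(lo: int, hi: int, rng, pairs: list, depth: int = 0):
    """Recursively drop nested helices into [lo, hi).

    Every helix keeps a hairpin loop of >= 3 unpaired nucleotides, so the
    innermost pair has |i - j| >= 4.
    """
    span = hi - lo
    if span < 12 or depth > 6:
        return
    helix = min(int(rng.integers(3, 7)), (span - 4) // 2)
    if helix < 2:
        return
    max_d5 = span - (2 * helix + 3) - 1
    d5 = int(rng.integers(0, max_d5 + 1)) if max_d5 > 0 else 0
    i0 = lo + d5
    j0_min = i0 + 2 * helix + 3  # innermost loop >= 3
    j0_max = hi - 1
    j0 = j0_max - int(rng.integers(0, j0_max - j0_min + 1)) if j0_max > j0_min else j0_min
    for t in range(helix):
        pairs.append((i0 + t, j0 - t))
    inner_lo, inner_hi = i0 + helix, j0 - helix + 1
    if inner_hi - inner_lo >= 12 and rng.random() < 0.7:
        if inner_hi - inner_lo >= 26 and rng.random() < 0.4:
            mid = (inner_lo + inner_hi) // 2
            _place_stems(inner_lo, mid, rng, pairs, depth + 1)
            _place_stems(mid, inner_hi, rng, pairs, depth + 1)
        else:
            _place_stems(inner_lo, inner_hi, rng, pairs, depth + 1)
    if hi - (j0 + 1) >= 12 and rng.random() < 0.5:
        _place_stems(j0 + 1, hi, rng, pairs, depth + 1)


def _try_add_pseudoknot(length: int, pairs: list, rng) -> bool:
    """Pair part of a hairpin loop with a downstream unpaired run, creating
    crossings with the enclosing helix."""
    used = {k for p in pairs for k in p}
    unpaired = [k for k in range(length) if k not in used]
    for i, j in sorted(pairs, key=lambda p: -(p[1] - p[0])):
        loop = [k for k in unpaired if i < k < j]
        tail = [k for k in unpaired if k > j]
        if len(loop) < 2 or len(tail) < 2:
            continue
        m = min(len(loop), len(tail), 4)
        if m < 2:
            continue
        # antiparallel pairing: 5' loop positions to 3' tail positions
        new = []
        for t in range(m):
            a, b = loop[t], tail[m - 1 - t]
            if b - a >= MIN_SEP:
                new.append((a, b))
        if len(new) >= 2:
            pairs.extend(new)
            return True
    return False


def simulate_structure(length: int, pk_prob: float, rng) -> SecondaryStructure:
    """Random nested structure; with probability pk_prob a hairpin loop is
    paired with a downstream region, creating crossed pairs.  All pairs obey
    the minimum separation of 4."""
    if length < 12:
        raise ValueError("length must be >= 12")
    want_pk = rng.random() < pk_prob
    for _ in range(50):
        pairs: list = []
        _place_stems(0, length, rng, pairs)
        pairs = _dedupe(pairs)
        if want_pk:
            if not _try_add_pseudoknot(length, pairs, rng):
                continue
        s = SecondaryStructure(length=length, pairs=frozenset(pairs))
        if want_pk and not crossed_pairs(s):
            continue
        return s
    # deterministic fallback: a hairpin, H-type pseudoknotted when requested
    pairs = [(0, 7), (1, 6)]
    if want_pk:
        pairs += [(2, length - 1), (3, length - 2)]
    return SecondaryStructure(length=length, pairs=frozenset(pairs))


def _dedupe(pairs: list) -> list:
    used = set()
    out = []
    for i, j in pairs:
        if i in used or j in used or j - i < MIN_SEP:
            continue
        used.update((i, j))
        out.append((i, j))
    return out


def simulate_sequence(structure: SecondaryStructure, rng) -> str:
    """Random sequence compatible with the structure (Watson-Crick pairs)."""
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
    bases = list("ACGU")
    seq = [bases[int(rng.integers(4))] for _ in range(structure.length)]
    for i, j in structure.pairs:
        seq[j] = comp[seq[i]]
    return "".join(seq)


def simulate_reactivity(
    structure: SecondaryStructure, config: SimConfig, rng
) -> np.ndarray:
    """Per-position reactivity: low gamma draws at paired positions, high at
    unpaired ones (chemical probes mark nucleotides not sequestered into
    base pairs)."""
    paired = np.zeros(structure.length, dtype=bool)
    for i, j in structure.pairs:
        paired[i] = paired[j] = True
    lo = rng.gamma(config.paired_shape, config.paired_mean / config.paired_shape,
                   size=structure.length)
    hi = rng.gamma(config.unpaired_shape, config.unpaired_mean / config.unpaired_shape,
                   size=structure.length)
    return np.where(paired, lo, hi)


def simulate_counts(
    sequence: str,
    reactivity: np.ndarray,
    reads: int,
    config: SimConfig,
    rng,
) -> tuple[CountsTrack, CountsTrack]:
    """Binomial count tracks for the modified and control channels.

    Modified events occur at rate base_rate + alpha * reactivity, control
    events at base_rate (shared, so subtraction is unbiased).  A fixed
    fraction of events is recorded as deletions.
    """
    if reads < 0:
        raise ValueError("reads must be nonnegative")
    L = len(sequence)
    r = np.asarray(reactivity, dtype=float)
    p_mod = np.clip(config.base_rate + config.alpha * r, 0.0, 0.999)
    cov = np.full(L, reads)
    ev_mod = rng.binomial(reads, p_mod) if reads > 0 else np.zeros(L, dtype=int)
    ev_ctl = (
        rng.binomial(reads, config.base_rate, size=L) if reads > 0 else np.zeros(L, dtype=int)
    )
    dm = rng.binomial(ev_mod, config.del_fraction)
    dc = rng.binomial(ev_ctl, config.del_fraction)
    mod = CountsTrack(sequence=sequence, mod_events=ev_mod - dm, del_events=dm,
                      coverage=cov, total_reads=reads)
    ctl = CountsTrack(sequence=sequence, mod_events=ev_ctl - dc, del_events=dc,
                      coverage=cov, total_reads=reads)
    return mod, ctl


def recover_profile(mod: CountsTrack, ctrl: CountsTrack) -> tuple[np.ndarray, np.ndarray]:
    """Convenience: counts -> subtracted rate/error, rescaled so the probe
    gain cancels is left to normalization; used by tests and demos."""
    from .reactivity import profile_from_counts

    r, e, _ = profile_from_counts(mod, ctrl)
    return r, e


def simulate_m2(
    sequence: str,
    structure: SecondaryStructure,
    config: SimConfig,
    rng,
) -> np.ndarray:
    """Mutate-and-map matrix: row 0 is wild type; row k+1 simulates the
    mutant at position k, which frees its pairing partner (reactivity boost
    at both the mutated site and its partner)."""
    L = structure.length
    partner = {}
    for i, j in structure.pairs:
        partner[i] = j
        partner[j] = i
    rows = np.zeros((L + 1, L))
    rows[0] = simulate_reactivity(structure, config, rng)
    for k in range(L):
        r = simulate_reactivity(structure, config, rng)
        r[k] += config.m2_effect
        if k in partner:
            r[partner[k]] += config.m2_effect
        rows[k + 1] = r
    return rows


def simulate_reads(
    longest_repeats: np.ndarray,
    longest_hairpins: np.ndarray,
    config: SimConfig,
    rng,
) -> np.ndarray:
    """Log-normal read counts depressed by repeat and hairpin features:
    log reads = mu - beta1 * repeat - beta2 * hairpin + noise."""
    rep = np.asarray(longest_repeats, dtype=float)
    hp = np.asarray(longest_hairpins, dtype=float)
    logr = (
        config.log_reads_mu
        - config.beta_repeat * rep
        - config.beta_hairpin * hp
        + rng.normal(0.0, config.log_reads_sigma, size=rep.shape)
    )
    return np.round(np.exp(logr)).astype(int)
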