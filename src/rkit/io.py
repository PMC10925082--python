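"""File I/O: counts TSV, profile CSV (competition training layout),
dot-bracket and CT files, dense pair-score matrices, FASTA, and library
manifests.

The profile CSV matches the public training-data layout: one row per
profile with ``sequence_id, sequence, experiment_type, reactivity_0001...,
reactivity_error_0001..., reads, signal_to_noise, SN_filter``; empty cells
mark unprobed positions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .reactivity import Chemistry, CountsTrack, ReactivityProfile
from .structure import PairScoreMatrix, SecondaryStructure, parse_dotbracket, write_dotbracket

__all__ = [
    "read_counts_tsv",
    "write_counts_tsv",
    "read_profiles_csv",
    "write_profiles_csv",
    "read_dotbracket_file",
    "write_dotbracket_file",
    "read_matrix_file",
    "write_matrix_file",
    "read_fasta",
    "write_fasta",
]

_EXPERIMENT_TYPE = {Chemistry.SHAPE_2A3: "2A3_MaP", Chemistry.DMS: "DMS_MaP"}
_CHEMISTRY = {v: k for k, v in _EXPERIMENT_TYPE.items()}


def read_counts_tsv(path) -> dict[str, CountsTrack]:
    """Read per-position counts (columns: sequence_id, position 0-based,
    base, mod_events, del_events, coverage) into tracks keyed by id."""
    df = pd.read_csv(path, sep="\t")
    tracks = {}
    for sid, group in df.groupby("sequence_id", sort=False):
        group = group.sort_values("position")
        if not np.array_equal(group["position"].to_numpy(), np.arange(len(group))):
            raise ValueError(f"{sid}: positions must be contiguous from 0")
        tracks[sid] = CountsTrack(
            sequence="".join(group["base"]),
            mod_events=group["mod_events"].to_numpy(),
            del_events=group["del_events"].to_numpy(),
            coverage=group["coverage"].to_numpy(),
            total_reads=int(group["coverage"].max()),
        )
    return tracks


def write_counts_tsv(path, tracks: dict[str, CountsTrack]) -> None:
    rows = []
    for sid, t in tracks.items():
        for k, base in enumerate(t.sequence):
            rows.append(
                (sid, k, base, t.mod_events[k], t.del_events[k], int(t.coverage[k]))
            )
    pd.DataFrame(
        rows,
        columns=["sequence_id", "position", "base", "mod_events", "del_events", "coverage"],
    ).to_csv(path, sep="\t", index=False)


def write_profiles_csv(path, profiles: list[ReactivityProfile]) -> None:
    if not profiles:
        raise ValueError("no profiles to write")
    width = max(len(p.reactivity) for p in profiles)
    rows = []
    for p in profiles:
        row = {
            "sequence_id": p.sequence_id,
            "sequence": p.sequence,
            "experiment_type": _EXPERIMENT_TYPE[p.chemistry],
        }
        for k in range(width):
            r = p.reactivity[k] if k < len(p.reactivity) else np.nan
            e = p.error[k] if k < len(p.error) else np.nan
            row[f"reactivity_{k + 1:04d}"] = r
            row[f"reactivity_error_{k + 1:04d}"] = e
        row["reads"] = p.reads
        row["signal_to_noise"] = p.snr
        row["SN_filter"] = int(p.sn_filter)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_profiles_csv(path) -> list[ReactivityProfile]:
    df = pd.read_csv(path)
    r_cols = sorted(c for c in df.columns if c.startswith("reactivity_") and "error" not in c)
    e_cols = sorted(c for c in df.columns if c.startswith("reactivity_error_"))
    profiles = []
    for _, row in df.iterrows():
        seq = row["sequence"]
        L = len(seq)
        r = row[r_cols].to_numpy(dtype=float)[:L]
        e = row[e_cols].to_numpy(dtype=float)[:L]
        # enforce the shared missing mask on round trip
        missing = np.isnan(r) | np.isnan(e)
        r[missing] = np.nan
        e[missing] = np.nan
        profiles.append(
            ReactivityProfile(
                sequence_id=str(row["sequence_id"]),
                sequence=seq,
                chemistry=_CHEMISTRY[row["experiment_type"]],
                reactivity=r,
                error=e,
                reads=int(row["reads"]),
                snr=float(row["signal_to_noise"]),
                sn_filter=bool(row["SN_filter"]),
            )
        )
    return profiles


def read_dotbracket_file(path) -> dict[str, SecondaryStructure]:
    """One structure per line; optional preceding '>id' headers."""
    structures = {}
    name = None
    count = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].strip()
                continue
            key = name if name is not None else f"structure_{count}"
            structures[key] = parse_dotbracket(line)
            name = None
            count += 1
    return structures


def write_dotbracket_file(path, structures: dict[str, SecondaryStructure]) -> None:
    with open(path, "w") as fh:
        for name, s in structures.items():
            fh.write(f">{name}\n{write_dotbracket(s)}\n")


def read_matrix_file(path) -> PairScoreMatrix:
    """Whitespace-delimited dense square matrix, one per file."""
    return PairScoreMatrix(scores=np.loadtxt(path))


def write_matrix_file(path, matrix: PairScoreMatrix) -> None:
    np.savetxt(path, matrix.scores, fmt="%.6g")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper().replace("T", "U") for rec in SeqIO.parse(path, "fasta")}


def write_fasta(path, sequences: dict[str, str]) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, path, "fasta")
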