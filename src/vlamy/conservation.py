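"""Per-column conservation profiles of a multiple sequence alignment.

For every alignment column the profile records the Shannon entropy of the
residue distribution (gaps excluded; low entropy = high conservation), the
occupancy (fraction of non-gap symbols; low occupancy = gappy column) and
the consensus residue (modal non-gap residue, alphabetical on ties).
Profiles can be computed per group (e.g. amyloidogenic vs non-amyloidogenic,
or kappa vs lambda) to compare conservation between datasets.  Alignment
construction is out of scope: an aligned FASTA is consumed as-is.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .scales import STANDARD_AA

GAP_CHARS = frozenset("-.")


@dataclass
class MSAProfile:
    """Column-wise conservation statistics for one sequence group."""

    group_label: str
    n_sequences: int
    columns: pd.DataFrame  # index = 1-based column; entropy, occupancy, consensus
    counts: list[dict[str, int]]

    def __len__(self) -> int:
        return len(self.columns)

    def mean_entropy(self, start: int = 1, end: int | None = None) -> float:
        """Mean entropy over alignment columns [start, end], 1-based inclusive,
        skipping all-gap columns (whose entropy is undefined/NaN)."""
        end = end if end is not None else len(self.columns)
        return float(self.columns.loc[start:end, "entropy"].mean(skipna=True))


def column_entropy(counts: Mapping[str, int], base: float = 2.0) -> float:
    """Shannon entropy of one column's residue distribution.

    Gaps are excluded from the distribution (occupancy reports them
    separately); an all-gap column has no distribution and raises.
    """
    total = sum(v for aa, v in counts.items() if aa in set(STANDARD_AA) and v > 0)
    if total == 0:
        raise ValueError("all-gap column: entropy undefined")
    h = 0.0
    for aa, v in counts.items():
        if aa in set(STANDARD_AA) and v > 0:
            p = v / total
            h -= p * math.log(p, base)
    return h


def _column_stats(column: Sequence[str], base: float) -> tuple[float, float, str, dict]:
    counts: dict[str, int] = {}
    n = len(column)
    gaps = 0
    for c in column:
        if c in GAP_CHARS:
            gaps += 1
        else:
            counts[c] = counts.get(c, 0) + 1
    occupancy = (n - gaps) / n
    if not counts:
        return math.nan, 0.0, "-", {}
    consensus = min(counts, key=lambda aa: (-counts[aa], aa))
    return column_entropy(counts, base), occupancy, consensus, counts


def read_alignment(fasta_path: str | Path) -> dict[str, str]:
    """Read an aligned FASTA; all sequences must have equal length."""
    seqs = {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    if not seqs:
        raise ValueError(f"no sequences in {fasta_path}")
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment in {fasta_path}: lengths {sorted(lengths)}")
    return seqs


def profile_group(
    sequences: Sequence[str], group_label: str = "", base: float = 2.0
) -> MSAProfile:
    """Column statistics for one set of equal-length aligned sequences."""
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ValueError("sequences are not aligned (unequal lengths)")
    (width,) = lengths
    rows = []
    all_counts = []
    for j in range(width):
        column = [s[j] for s in sequences]
        entropy, occupancy, consensus, counts = _column_stats(column, base)
        rows.append(
            {"entropy": entropy, "occupancy": occupancy, "consensus": consensus}
        )
        all_counts.append(counts)
    df = pd.DataFrame(rows, index=pd.RangeIndex(1, width + 1, name="position"))
    return MSAProfile(
        group_label=group_label,
        n_sequences=len(sequences),
        columns=df,
        counts=all_counts,
    )


def profile_msa(
    aligned_fasta: str | Path,
    group_assignments: Mapping[str, str] | None = None,
    base: float = 2.0,
) -> dict[str, MSAProfile]:
    """Per-group conservation profiles from an aligned FASTA.

    ``group_assignments`` maps sequence id to group label and must cover ids
    present in the alignment only; with no assignment, a single group
    ``"all"`` containing every sequence is profiled.
    """
    seqs = read_alignment(aligned_fasta)
    if group_assignments is None:
        group_assignments = {seq_id: "all" for seq_id in seqs}
    unknown = sorted(set(group_assignments) - set(seqs))
    if unknown:
        raise KeyError(f"group assignments for ids absent from alignment: {unknown}")
    groups: dict[str, list[str]] = {}
    for seq_id, group in group_assignments.items():
        groups.setdefault(group, []).append(seqs[seq_id])
    return {
        group: profile_group(members, group_label=group, base=base)
        for group, members in groups.items()
    }


def consensus_sequence(profile: MSAProfile, occupancy_floor: float = 0.0) -> str:
    """Concatenated per-column consensus; gap where occupancy <= floor.

    With the default floor of 0 only all-gap columns yield a gap symbol.
    """
    out = []
    for _, row in profile.columns.iterrows():
        if row["occupancy"] <= occupancy_floor:
            out.append("-")
        else:
            out.append(row["consensus"])
    return "".join(out)


def write_profiles(profiles: Mapping[str, MSAProfile], path: str | Path) -> None:
    """Per-column TSV: position, group, entropy, occupancy, consensus."""
    with open(path, "w") as fh:
        fh.write("position\tgroup\tentropy\toccupancy\tconsensus\n")
        for group in sorted(profiles):
            prof = profiles[group]
            for pos, row in prof.columns.iterrows():
                ent = "NA" if math.isnan(row["entropy"]) else f"{row['entropy']:.4f}"
                fh.write(
                    f"{pos}\t{group}\t{ent}\t{row['occupancy']:.4f}\t{row['consensus']}\n"
                )
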