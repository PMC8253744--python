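"""Per-residue intrinsic-disorder profiles.

Two providers are available.  The built-in provider smooths a disorder
propensity scale (TOP-IDP by default) over a sliding window — a simple,
dependency-free stand-in whose output is a propensity profile, not an
energy-based disorder probability.  Profiles computed by an external
predictor can instead be imported from a TSV (``id  position  score``,
1-based positions) and are used verbatim; this is the route to reproduce
results that were derived from a specific external disorder predictor.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import AnnotatedVL, MASK_CHAR
from .scales import PropertyScale, get_scale

#: A disorder provider maps a record to one score per residue.
DisorderProvider = Callable[[AnnotatedVL], "DisorderProfile"]

DEFAULT_WINDOW = 11


@dataclass(frozen=True)
class DisorderProfile:
    id: str
    scores: tuple[float, ...]
    provider: str  # "builtin_window" or "imported"

    def __len__(self) -> int:
        return len(self.scores)


def builtin_disorder(
    seq: str,
    scale: PropertyScale | None = None,
    window: int = DEFAULT_WINDOW,
    seq_id: str = "",
) -> DisorderProfile:
    """Sliding-window mean of a disorder-propensity scale.

    The window is centred on each residue and truncated at the termini
    (shorter effective window near the ends), so smoothed values never leave
    the range of the raw scale.  Masked residues (``X``) are excluded from
    each window's mean.
    """
    if scale is None:
        scale = get_scale("TOPIDP")
    n = len(seq)
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    if window > n:
        raise ValueError(f"window {window} exceeds sequence length {n}")
    raw = np.array(
        [scale.values[c] if c != MASK_CHAR else np.nan for c in seq], dtype=float
    )
    half = window // 2
    scores = []
    for i in range(n):
        win = raw[max(0, i - half) : min(n, i + half + 1)]
        win = win[~np.isnan(win)]
        if win.size == 0:
            raise ValueError(f"window at position {i + 1} contains only masked residues")
        scores.append(float(win.mean()))
    return DisorderProfile(id=seq_id, scores=tuple(scores), provider="builtin_window")


def window_provider(
    scale: PropertyScale | None = None, window: int = DEFAULT_WINDOW
) -> DisorderProvider:
    """Build a provider computing :func:`builtin_disorder` on each record."""

    def provider(record: AnnotatedVL) -> DisorderProfile:
        return builtin_disorder(record.sequence, scale, window, seq_id=record.id)

    return provider


def import_disorder(tsv_path: str | Path) -> dict[str, DisorderProfile]:
    """Read externally computed per-residue scores from a TSV.

    Columns ``id``, ``position`` (1-based) and ``score``; each id's positions
    must form 1..N with no gap or duplicate.
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype={"id": str})
    required = {"id", "position", "score"}
    if not required <= set(df.columns):
        raise ValueError(f"disorder TSV must have columns {sorted(required)}")
    profiles: dict[str, DisorderProfile] = {}
    for seq_id, grp in df.groupby("id", sort=False):
        positions = grp["position"].to_numpy()
        if len(set(positions)) != len(positions):
            dup = int(pd.Series(positions).loc[pd.Series(positions).duplicated()].iloc[0])
            raise ValueError(f"duplicate position {dup} for id {seq_id!r}")
        expected = set(range(1, len(positions) + 1))
        missing = sorted(expected - set(int(p) for p in positions))
        if missing:
            raise ValueError(f"missing position {missing[0]} for id {seq_id!r}")
        ordered = grp.sort_values("position")["score"].astype(float)
        profiles[seq_id] = DisorderProfile(
            id=str(seq_id), scores=tuple(ordered), provider="imported"
        )
    return profiles


def export_disorder(
    profiles: Mapping[str, DisorderProfile], tsv_path: str | Path
) -> None:
    """Write profiles in the import TSV dialect (round-trips)."""
    with open(tsv_path, "w") as fh:
        fh.write("id\tposition\tscore\n")
        for seq_id, prof in profiles.items():
            for pos, score in enumerate(prof.scores, start=1):
                fh.write(f"{seq_id}\t{pos}\t{score:g}\n")


def imported_provider(profiles: Mapping[str, DisorderProfile]) -> DisorderProvider:
    """Build a provider serving pre-computed profiles, checked for length."""

    def provider(record: AnnotatedVL) -> DisorderProfile:
        try:
            prof = profiles[record.id]
        except KeyError:
            raise KeyError(f"no imported disorder profile for {record.id!r}") from None
        if len(prof) != len(record.sequence):
            raise ValueError(
                f"{record.id}: disorder profile length {len(prof)} != "
                f"sequence length {len(record.sequence)}"
            )
        return prof

    return provider
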