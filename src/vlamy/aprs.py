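"""Gatekeeper analysis of aggregation-prone regions (APRs).

APR intervals come from any external predictor as a BED-like TSV
(``seq_id  start  end  source  score``, 1-based inclusive coordinates);
no aggregation-propensity algorithm is run here.  For each APR the module
counts gatekeeper residues (D, E, R, K, P) in the +/-k flanking windows
(default k = 3, truncated at the sequence termini) — an APR with no
gatekeeper in either flank is "unprotected" — and maps each APR onto the
FR/CDR segments it overlaps.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .io import AnnotatedVL, REGION_ORDER
from .scales import GATEKEEPERS


@dataclass(frozen=True)
class APRInterval:
    """One predicted aggregation-prone stretch, 1-based inclusive."""

    seq_id: str
    start: int
    end: int
    source: str = ""
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(
                f"invalid APR interval {self.start}..{self.end} for {self.seq_id}"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1


def read_aprs(tsv_path: str | Path) -> dict[str, list[APRInterval]]:
    """Read APR intervals grouped by sequence id, preserving file order."""
    df = pd.read_csv(tsv_path, sep="\t", dtype={"seq_id": str})
    required = {"seq_id", "start", "end"}
    if not required <= set(df.columns):
        raise ValueError(f"APR table must have columns {sorted(required)}")
    out: dict[str, list[APRInterval]] = {}
    for _, row in df.iterrows():
        apr = APRInterval(
            seq_id=str(row["seq_id"]),
            start=int(row["start"]),
            end=int(row["end"]),
            source=str(row["source"]) if "source" in df.columns and pd.notna(row.get("source")) else "",
            score=float(row["score"]) if "score" in df.columns and pd.notna(row.get("score")) else None,
        )
        out.setdefault(apr.seq_id, []).append(apr)
    return out


def flank_gatekeepers(
    record: AnnotatedVL, apr: APRInterval, k: int = 3
) -> dict[str, object]:
    """Count gatekeepers in the +/-k flanks of an APR.

    Flanks are ``[start-k, start-1]`` and ``[end+1, end+k]``, truncated at
    the sequence boundaries; the APR is "protected" when at least one
    gatekeeper occurs in the union of the two flanks.
    """
    if k < 0:
        raise ValueError("flank width k must be >= 0")
    n = len(record.sequence)
    if apr.end > n:
        raise ValueError(
            f"APR {apr.start}..{apr.end} outside sequence {record.id} (length {n})"
        )
    left = record.sequence[max(0, apr.start - 1 - k) : apr.start - 1]
    right = record.sequence[apr.end : min(n, apr.end + k)]
    n_gk_left = sum(c in GATEKEEPERS.members for c in left)
    n_gk_right = sum(c in GATEKEEPERS.members for c in right)
    return {
        "n_gk_left": n_gk_left,
        "n_gk_right": n_gk_right,
        "protected": (n_gk_left + n_gk_right) >= 1,
    }


def apr_region_map(
    record: AnnotatedVL, aprs: Sequence[APRInterval]
) -> pd.DataFrame:
    """Overlap of each APR with the seven V_L segments.

    One row per (APR, overlapped region) with the residue overlap length;
    the per-APR overlap lengths sum to the APR length.
    """
    rows = []
    for apr in aprs:
        if apr.end > len(record.sequence):
            raise ValueError(
                f"APR {apr.start}..{apr.end} outside sequence {record.id}"
            )
        for region in REGION_ORDER:
            r_start, r_end = record.regions[region]
            overlap = min(apr.end, r_end) - max(apr.start, r_start) + 1
            if overlap > 0:
                rows.append(
                    {
                        "seq_id": record.id,
                        "apr_start": apr.start,
                        "apr_end": apr.end,
                        "source": apr.source,
                        "region": region,
                        "overlap": overlap,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["seq_id", "apr_start", "apr_end", "source", "region", "overlap"],
    )


def flank_summary(
    records: Sequence[AnnotatedVL],
    aprs_by_id: Mapping[str, Sequence[APRInterval]],
    k: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dataset-level APR analysis.

    Returns ``(per_apr, summary)``: one row per APR with flank gatekeeper
    counts and overlapped regions, and a per-region summary with APR counts
    (an APR counts toward every region it overlaps) plus the overall
    fraction of APRs left unprotected.
    """
    by_id = {r.id: r for r in records}
    apr_rows = []
    region_counts = {region: 0 for region in REGION_ORDER}
    n_aprs = 0
    n_unprotected = 0
    for seq_id, aprs in aprs_by_id.items():
        if seq_id not in by_id:
            raise KeyError(f"APR table references unknown sequence {seq_id!r}")
        record = by_id[seq_id]
        for apr in aprs:
            flank = flank_gatekeepers(record, apr, k)
            overlaps = apr_region_map(record, [apr])
            for region in overlaps["region"]:
                region_counts[region] += 1
            n_aprs += 1
            if not flank["protected"]:
                n_unprotected += 1
            apr_rows.append(
                {
                    "seq_id": seq_id,
                    "start": apr.start,
                    "end": apr.end,
                    "source": apr.source,
                    "regions": "+".join(overlaps["region"]),
                    "n_gk_left": flank["n_gk_left"],
                    "n_gk_right": flank["n_gk_right"],
                    "protected": flank["protected"],
                }
            )
    per_apr = pd.DataFrame(
        apr_rows,
        columns=[
            "seq_id", "start", "end", "source", "regions",
            "n_gk_left", "n_gk_right", "protected",
        ],
    )
    summary = pd.DataFrame(
        {
            "region": list(REGION_ORDER),
            "n_aprs": [region_counts[r] for r in REGION_ORDER],
        }
    )
    summary.attrs["n_aprs_total"] = n_aprs
    summary.attrs["fraction_unprotected"] = (
        n_unprotected / n_aprs if n_aprs else 0.0
    )
    return per_apr, summary
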