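"""Reading, validating and writing segmented light-chain variable domains.

An antibody light-chain variable domain (V_L, ~105-115 residues) is built
from four framework regions and three CDR loops laid end to end:
FR1-CDR1-FR2-CDR2-FR3-CDR3-FR4.  This module assembles ``AnnotatedVL``
records from an unaligned FASTA file plus a region-annotation table that
gives the seven segment boundaries per sequence (IMGT-style segmentation,
supplied by the data source — region annotation is never computed here).

All file coordinates are 1-based and inclusive on both ends.  Records whose
regions do not tile the sequence, or that contain nonstandard residues
under the strict policy, are excluded with a logged reason — mirroring the
curation of the source database, which drops sequences with missing or
unmatched FRs/CDRs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .scales import STANDARD_AA

logger = logging.getLogger(__name__)

#: The seven V_L segments in N-to-C order.
REGION_ORDER: tuple[str, ...] = ("FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "FR4")
CDR_REGIONS: tuple[str, ...] = ("CDR1", "CDR2", "CDR3")
FR_REGIONS: tuple[str, ...] = ("FR1", "FR2", "FR3", "FR4")

ISOTYPES = ("kappa", "lambda", "unknown")
LABELS = ("amyloid", "non_amyloid", "unlabeled")

#: Character used for masked (nonstandard) residues under the "mask" policy.
MASK_CHAR = "X"


class ValidationError(ValueError):
    """A record failed structural validation."""


@dataclass(frozen=True)
class AnnotatedVL:
    """One V_L sequence with its seven region boundaries and metadata.

    ``regions`` maps region name to (start, end), 1-based inclusive, and must
    tile ``sequence`` exactly in the canonical order.
    """

    id: str
    sequence: str
    regions: dict[str, tuple[int, int]]
    isotype: str = "unknown"
    label: str = "unlabeled"

    def region_seq(self, region: str) -> str:
        start, end = self.regions[region]
        return self.sequence[start - 1 : end]

    def __len__(self) -> int:
        return len(self.sequence)


def validate(record: AnnotatedVL, allow_mask: bool = False) -> None:
    """Raise :class:`ValidationError` if the record violates any invariant."""
    if record.isotype not in ISOTYPES:
        raise ValidationError(f"{record.id}: unknown isotype {record.isotype!r}")
    if record.label not in LABELS:
        raise ValidationError(f"{record.id}: unknown label {record.label!r}")
    if set(record.regions) != set(REGION_ORDER):
        raise ValidationError(
            f"{record.id}: regions must be exactly {REGION_ORDER}"
        )
    allowed = set(STANDARD_AA) | ({MASK_CHAR} if allow_mask else set())
    bad = sorted(set(record.sequence) - allowed)
    if bad:
        raise ValidationError(f"{record.id}: nonstandard residue(s) {bad}")
    pos = 1
    for name in REGION_ORDER:
        start, end = record.regions[name]
        if end < start:
            raise ValidationError(f"{record.id}: {name} has end < start")
        if start != pos:
            raise ValidationError(
                f"{record.id}: {name} starts at {start}, expected {pos} "
                "(regions must tile the sequence with no gap or overlap)"
            )
        pos = end + 1
    if pos - 1 != len(record.sequence):
        raise ValidationError(
            f"{record.id}: regions cover 1..{pos - 1} but sequence has "
            f"length {len(record.sequence)}"
        )


def segment(record: AnnotatedVL, region_set: str) -> str:
    """Return the residues of a region or pooled region set.

    ``region_set`` is ``"VL"`` (whole domain), ``"CDR_all"`` (CDR1+CDR2+CDR3),
    ``"FR_all"`` (FR1+FR2+FR3+FR4) or one of the seven region names.
    """
    if region_set == "VL":
        return record.sequence
    if region_set == "CDR_all":
        return "".join(record.region_seq(r) for r in CDR_REGIONS)
    if region_set == "FR_all":
        return "".join(record.region_seq(r) for r in FR_REGIONS)
    if region_set in REGION_ORDER:
        return record.region_seq(region_set)
    raise KeyError(
        f"unknown region set {region_set!r}; expected VL, CDR_all, FR_all "
        f"or one of {REGION_ORDER}"
    )


# ---------------------------------------------------------------------------
# Region-table dialect
# ---------------------------------------------------------------------------

def _region_columns() -> list[str]:
    cols = []
    for name in REGION_ORDER:
        cols.append(f"{name.lower()}_start")
        cols.append(f"{name.lower()}_end")
    return cols


REGION_TABLE_COLUMNS = ["id", *_region_columns(), "isotype"]


def read_annotated_dataset(
    fasta_path: str | Path,
    regions_path: str | Path,
    labels_path: str | Path | None = None,
    policy: Literal["strict", "mask"] = "strict",
    return_skipped: bool = False,
):
    """Assemble validated :class:`AnnotatedVL` records from FASTA + TSV.

    The regions table is TSV with columns ``id``, ``fr1_start`` ... ``fr4_end``
    (1-based inclusive), optional ``isotype`` and optional ``label``; labels
    may instead (or additionally) come from a two-column ``id<TAB>label`` file,
    which takes precedence.  Records failing validation are excluded and
    logged with the reason; input order is preserved.

    Under ``policy="mask"`` nonstandard residues are replaced by ``X`` and the
    record is kept (downstream averages skip masked positions); under the
    default strict policy such records are dropped.
    """
    fasta_path, regions_path = Path(fasta_path), Path(regions_path)
    for p in (fasta_path, regions_path):
        if not p.exists():
            raise FileNotFoundError(p)
    seqs: dict[str, str] = {}
    order: list[str] = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {fasta_path}")
        seqs[rec.id] = str(rec.seq).upper()
        order.append(rec.id)

    table = pd.read_csv(regions_path, sep="\t", dtype={"id": str})
    missing_cols = [c for c in ("id", *_region_columns()) if c not in table.columns]
    if missing_cols:
        raise ValueError(f"regions table missing columns: {missing_cols}")
    if table["id"].duplicated().any():
        dups = table.loc[table["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate ids in regions table: {dups}")
    rows = table.set_index("id")

    labels: dict[str, str] = {}
    if "label" in table.columns:
        labels.update(
            {i: str(v) for i, v in rows["label"].items() if pd.notna(v)}
        )
    if labels_path is not None:
        lab = pd.read_csv(labels_path, sep="\t", dtype=str)
        if not {"id", "label"} <= set(lab.columns):
            raise ValueError("labels file must have columns id, label")
        labels.update(dict(zip(lab["id"], lab["label"])))

    records: list[AnnotatedVL] = []
    skipped: list[tuple[str, str]] = []

    def skip(seq_id: str, reason: str) -> None:
        logger.warning("skipping %s: %s", seq_id, reason)
        skipped.append((seq_id, reason))

    for seq_id in rows.index:
        if seq_id not in seqs:
            skip(seq_id, "region row without matching FASTA sequence")

    for seq_id in order:
        if seq_id not in rows.index:
            skip(seq_id, "no region annotation")
            continue
        sequence = seqs[seq_id]
        nonstandard = sorted(set(sequence) - set(STANDARD_AA))
        if nonstandard:
            if policy == "strict":
                skip(seq_id, f"nonstandard residue(s) {nonstandard}")
                continue
            sequence = "".join(
                c if c in STANDARD_AA else MASK_CHAR for c in sequence
            )
        row = rows.loc[seq_id]
        try:
            regions = {
                name: (int(row[f"{name.lower()}_start"]), int(row[f"{name.lower()}_end"]))
                for name in REGION_ORDER
            }
        except (TypeError, ValueError):
            skip(seq_id, "non-integer region boundary")
            continue
        isotype = str(row.get("isotype", "unknown"))
        if pd.isna(row.get("isotype", "unknown")):
            isotype = "unknown"
        record = AnnotatedVL(
            id=seq_id,
            sequence=sequence,
            regions=regions,
            isotype=isotype,
            label=labels.get(seq_id, "unlabeled"),
        )
        try:
            validate(record, allow_mask=(policy == "mask"))
        except ValidationError as exc:
            skip(seq_id, str(exc))
            continue
        records.append(record)

    if return_skipped:
        return records, skipped
    return records


def write_dataset(
    records: Sequence[AnnotatedVL],
    fasta_path: str | Path,
    regions_path: str | Path,
) -> None:
    """Write records back to the FASTA + regions-TSV dialect (round-trips)."""
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records),
        str(fasta_path),
        "fasta",
    )
    data = []
    for r in records:
        row: dict[str, object] = {"id": r.id}
        for name in REGION_ORDER:
            start, end = r.regions[name]
            row[f"{name.lower()}_start"] = start
            row[f"{name.lower()}_end"] = end
        row["isotype"] = r.isotype
        row["label"] = r.label
        data.append(row)
    pd.DataFrame(data, columns=[*REGION_TABLE_COLUMNS, "label"]).to_csv(
        regions_path, sep="\t", index=False
    )


def write_predictions(
    records: Sequence[AnnotatedVL],
    probabilities: Sequence[float],
    calls: Sequence[str],
    out_path: str | Path,
    threshold: float = 0.15,
) -> None:
    """Write a per-sequence prediction table (TSV, input order, 6-decimal P)."""
    if not (len(records) == len(probabilities) == len(calls)):
        raise ValueError(
            f"length mismatch: {len(records)} records, "
            f"{len(probabilities)} probabilities, {len(calls)} calls"
        )
    with open(out_path, "w") as fh:
        fh.write("id\tisotype\tP_amyloid\tcall\tthreshold\n")
        for rec, p, call in zip(records, probabilities, calls):
            fh.write(f"{rec.id}\t{rec.isotype}\t{p:.6f}\t{call}\t{threshold:g}\n")
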