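"""Per-residue property scales and residue category sets.

A :class:`PropertyScale` maps each of the 20 standard amino acids to a real
value (hydrophobicity, disorder propensity, transfer free energy, ...).
Scales can be loaded from AAIndex1 flat files or taken from the bundled
registry, which ships the handful of published scales the final prediction
model needs:

``HNC``
    Normalized consensus hydrophobicity (Eisenberg et al.).
``CHAM830107``
    Charge-transfer capability indicator: 1 for the residues with a
    charge-transfer accepting group (D, E, N, Q), 0 otherwise.
``BULH740101``
    Transfer free energy to surface (Bull & Breese), kcal/mol.
``CHOP780202``
    Chou-Fasman beta-sheet conformational parameter.
``TOPIDP``
    TOP-IDP intrinsic disorder propensity (Campen et al.).

Residue categories (gatekeeper, non-polar, ...) are fixed membership sets
used for composition fractions rather than averaged scales.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

#: The 20 standard amino acids, alphabetical by one-letter code.
STANDARD_AA: str = "ACDEFGHIKLMNPQRSTVWY"

#: Residue order of the two rows of an AAIndex1 ``I`` block.
_AAINDEX_ROW1 = "ARNDCQEGHI"
_AAINDEX_ROW2 = "LKMFPSTWYV"
AAINDEX_ORDER: str = _AAINDEX_ROW1 + _AAINDEX_ROW2


@dataclass(frozen=True)
class PropertyScale:
    """A named map from the 20 standard amino acids to real values."""

    scale_id: str
    values: Mapping[str, float]
    description: str = ""
    source: str = "user"

    def __post_init__(self) -> None:
        keys = set(self.values)
        if keys != set(STANDARD_AA):
            missing = sorted(set(STANDARD_AA) - keys)
            extra = sorted(keys - set(STANDARD_AA))
            raise ValueError(
                f"scale {self.scale_id!r} must cover exactly the 20 standard "
                f"residues (missing {missing}, unexpected {extra})"
            )
        if not all(math.isfinite(v) for v in self.values.values()):
            raise ValueError(f"scale {self.scale_id!r} contains non-finite values")

    def __getitem__(self, residue: str) -> float:
        return self.values[residue]

    def as_dict(self) -> dict[str, float]:
        return {aa: float(self.values[aa]) for aa in STANDARD_AA}


@dataclass(frozen=True)
class ResidueCategory:
    """A named subset of the 20 standard residues."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not set(self.members) <= set(STANDARD_AA):
            raise ValueError(f"category {self.name!r} has nonstandard members")

    def __contains__(self, residue: str) -> bool:
        return residue in self.members


def _cat(name: str, members: str) -> ResidueCategory:
    return ResidueCategory(name, frozenset(members))


#: Charged / beta-breaker residues that suppress aggregation when flanking an APR.
GATEKEEPERS = _cat("gatekeeper", "DERKP")

#: Built-in residue categories. ``polar`` means uncharged polar side chains;
#: histidine is excluded from both ``charged`` and ``aromatic`` by default.
CATEGORIES: dict[str, ResidueCategory] = {
    c.name: c
    for c in (
        GATEKEEPERS,
        _cat("nonpolar", "AGILMPV"),
        _cat("polar", "CHNQSTY"),
        _cat("charged", "DEKR"),
        _cat("aromatic", "FWY"),
        _cat("charge_transfer_acceptor", "DENQ"),
    )
}


def get_category(name: str) -> ResidueCategory:
    try:
        return CATEGORIES[name]
    except KeyError:
        raise KeyError(
            f"unknown residue category {name!r}; known: {sorted(CATEGORIES)}"
        ) from None


# ---------------------------------------------------------------------------
# AAIndex1 flat-file I/O
# ---------------------------------------------------------------------------

class AAIndexFormatError(ValueError):
    pass


def _parse_entry(block: str) -> PropertyScale | None:
    """Parse one AAIndex1 entry; return None for scales with NA values."""
    accession = None
    description_lines: list[str] = []
    numbers: list[str] = []
    lines = block.splitlines()
    i = 0
    mode = None
    while i < len(lines):
        line = lines[i]
        tag = line[:1]
        if tag == "H":
            accession = line[1:].strip()
            mode = None
        elif tag == "D":
            description_lines.append(line[1:].strip())
            mode = "D"
        elif tag == "I":
            mode = "I"
        elif tag == " " and mode in ("D", "I"):
            if mode == "D":
                description_lines.append(line.strip())
            else:
                numbers.extend(line.split())
        elif tag and tag not in " ":
            mode = None
        i += 1
    if accession is None:
        raise AAIndexFormatError("entry without an H (accession) record")
    if len(numbers) != 20:
        raise AAIndexFormatError(
            f"entry {accession}: expected 20 values in the I block, got {len(numbers)}"
        )
    if any(tok.upper() == "NA" for tok in numbers):
        return None
    values = {aa: float(tok) for aa, tok in zip(AAINDEX_ORDER, numbers)}
    return PropertyScale(
        scale_id=accession,
        values=values,
        description=" ".join(description_lines),
        source="aaindex_file",
    )


def load_aaindex(
    path: str | Path, accessions: Iterable[str] | None = None
) -> list[PropertyScale]:
    """Read property scales from an AAIndex1 flat file.

    Parameters
    ----------
    path
        AAIndex1-format file (entries with H/D/I records, terminated by ``//``).
    accessions
        If given, return exactly these entries in the requested order and
        raise if any is absent or was rejected for ``NA`` values.
    """
    text = Path(path).read_text()
    scales: dict[str, PropertyScale] = {}
    rejected: list[str] = []
    for block in re.split(r"^//\s*$", text, flags=re.M):
        if not block.strip():
            continue
        parsed = _parse_entry(block)
        if parsed is None:
            m = re.search(r"^H\s+(\S+)", block, flags=re.M)
            rejected.append(m.group(1) if m else "<unknown>")
            continue
        scales[parsed.scale_id] = parsed
    if rejected:
        import warnings

        warnings.warn(
            f"AAIndex entries with NA values rejected: {rejected}", stacklevel=2
        )
    if accessions is None:
        return list(scales.values())
    missing = [a for a in accessions if a not in scales]
    if missing:
        raise KeyError(f"accessions not found in {path}: {missing}")
    return [scales[a] for a in accessions]


def write_aaindex(scales: Iterable[PropertyScale], path: str | Path) -> None:
    """Write scales back to AAIndex1 format (round-trips with load_aaindex)."""
    chunks = []
    for scale in scales:
        vals = [scale.values[aa] for aa in AAINDEX_ORDER]
        row1 = "".join(f"{v:8.3f}" for v in vals[:10])
        row2 = "".join(f"{v:8.3f}" for v in vals[10:])
        desc = scale.description or scale.scale_id
        chunks.append(
            f"H {scale.scale_id}\nD {desc}\n"
            "I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T"
            "     G/W     H/Y     I/V\n"
            f"{row1}\n{row2}\n//\n"
        )
    Path(path).write_text("".join(chunks))


# ---------------------------------------------------------------------------
# Bundled registry
# ---------------------------------------------------------------------------

#: Convenience aliases accepted by :func:`get_scale`.
ALIASES: dict[str, str] = {
    "hydrophobicity": "HNC",
    "charge_transfer": "CHAM830107",
    "transfer_free_energy": "BULH740101",
    "beta_propensity": "CHOP780202",
    "disorder_propensity": "TOPIDP",
}

_registry: dict[str, PropertyScale] | None = None


def _load_registry() -> dict[str, PropertyScale]:
    global _registry
    if _registry is None:
        data = resources.files("vlamy.data").joinpath("bundled_scales.aaindex")
        with resources.as_file(data) as path:
            scales = load_aaindex(path)
        _registry = {
            s.scale_id: PropertyScale(s.scale_id, s.values, s.description, "bundled")
            for s in scales
        }
    return _registry


def get_scale(scale_id: str) -> PropertyScale:
    """Return a bundled or registered scale by id or alias."""
    reg = _load_registry()
    key = ALIASES.get(scale_id, scale_id)
    try:
        return reg[key]
    except KeyError:
        known = sorted(reg) + sorted(ALIASES)
        raise KeyError(f"unknown scale {scale_id!r}; known ids: {known}") from None


def register_scale(scale: PropertyScale, overwrite: bool = False) -> None:
    """Add a scale to the process-wide registry (e.g. from a user AAIndex file)."""
    reg = _load_registry()
    if scale.scale_id in reg and not overwrite:
        raise ValueError(f"scale {scale.scale_id!r} already registered")
    reg[scale.scale_id] = scale


def list_scales() -> list[str]:
    return sorted(_load_registry())


def normalize_scale(scale: PropertyScale, mode: str = "zscore") -> PropertyScale:
    """Rescale values to mean 0 / sd 1 (``zscore``) or to [0, 1] (``minmax``)."""
    vals = [scale.values[aa] for aa in STANDARD_AA]
    lo, hi = min(vals), max(vals)
    if hi == lo:
        raise ValueError(f"cannot normalize constant scale {scale.scale_id!r}")
    if mode == "minmax":
        new = {aa: (scale.values[aa] - lo) / (hi - lo) for aa in STANDARD_AA}
    elif mode == "zscore":
        n = len(vals)
        mean = sum(vals) / n
        sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / n)
        new = {aa: (scale.values[aa] - mean) / sd for aa in STANDARD_AA}
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return PropertyScale(
        scale_id=f"{scale.scale_id}_{mode}",
        values=new,
        description=f"{scale.description} ({mode} normalized)",
        source=scale.source,
    )
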