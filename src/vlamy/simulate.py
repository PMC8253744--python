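"""Synthetic labeled V_L datasets with planted, tunable class effects.

Sequences follow the seven-segment V_L architecture with IMGT-like segment
length ranges.  Residues are drawn per position from region-specific
categorical distributions; for the positive (amyloidogenic) class the
distribution is exponentially tilted along the property axes the real
classes differ on:

* ``delta_hyd``  — CDR residue usage tilted toward high normalized-consensus
  hydrophobicity (positives get greasier CDR loops);
* ``delta_gk``   — gatekeeper residues (D,E,R,K,P) depleted in positive
  framework regions by the factor ``exp(-delta_gk)``;
* ``delta_dis``  — residue usage across the whole domain tilted toward high
  TOP-IDP disorder propensity for positives.

Tilt weights are ``base(a) * exp(delta * scale[a])``, renormalized, so an
all-zero delta configuration makes the two classes exchangeable (a null
model).  The base composition is uniform over the 20 residues in CDRs and,
in FRs, puts 0.25 total mass on the five gatekeepers (0.05 each) with the
remainder spread evenly — documented generator constants, not biological
claims.  Everything is deterministic given the seed.

Isotype labels are metadata only: 75% of positives are assigned lambda
(echoing the strong lambda skew of real amyloidogenic light chains) and
45% of negatives, purely to exercise group-wise reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import AnnotatedVL, REGION_ORDER, validate, write_dataset
from .scales import GATEKEEPERS, STANDARD_AA, get_scale

#: Per-region (min, max) segment lengths, approximating IMGT V_L geometry.
DEFAULT_REGION_LENGTHS: dict[str, tuple[int, int]] = {
    "FR1": (23, 26),
    "CDR1": (5, 12),
    "FR2": (17, 17),
    "CDR2": (3, 3),
    "FR3": (36, 39),
    "CDR3": (8, 13),
    "FR4": (10, 11),
}

#: Fraction of positives / negatives assigned the lambda isotype.
LAMBDA_FRACTION_POS = 0.75
LAMBDA_FRACTION_NEG = 0.45


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; the defaults are the strong planted-effect
    condition used throughout the test suite (all-zero deltas give the null)."""

    n_pos: int = 300
    n_neg: int = 300
    region_lengths: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_REGION_LENGTHS)
    )
    delta_hyd: float = 1.5
    delta_gk: float = 0.5
    delta_dis: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("delta_hyd", "delta_gk", "delta_dis"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("n_pos and n_neg must be non-negative")
        if set(self.region_lengths) != set(REGION_ORDER):
            raise ValueError(f"region_lengths must cover exactly {REGION_ORDER}")
        for region, (lo, hi) in self.region_lengths.items():
            if not 1 <= lo <= hi:
                raise ValueError(f"bad length range for {region}: ({lo}, {hi})")


def _base_distribution(region: str) -> np.ndarray:
    """Generator base residue frequencies for one region."""
    aas = list(STANDARD_AA)
    if region.startswith("CDR"):
        return np.full(20, 1 / 20)
    p = np.empty(20)
    n_gk = len(GATEKEEPERS.members)
    for i, aa in enumerate(aas):
        p[i] = 0.25 / n_gk if aa in GATEKEEPERS.members else 0.75 / (20 - n_gk)
    return p


def _tilted_distribution(region: str, config: SimConfig) -> np.ndarray:
    """Positive-class residue distribution for one region.

    CDR positions are tilted freely by hydrophobicity and disorder
    propensity.  FR positions keep the gatekeeper/non-gatekeeper split
    explicit: the total gatekeeper mass is the base mass times
    ``exp(-delta_gk)`` and the disorder tilt only redistributes residues
    *within* each of the two groups.  This keeps the planted effects
    orthogonal — the disorder tilt favors charged residues and proline,
    which are themselves gatekeepers, and would otherwise cancel the
    planted gatekeeper depletion.
    """
    hnc = get_scale("HNC")
    topidp = get_scale("TOPIDP")
    base = _base_distribution(region)
    weights = base.copy()
    for i, aa in enumerate(STANDARD_AA):
        tilt = config.delta_dis * topidp.values[aa]
        if region.startswith("CDR"):
            tilt += config.delta_hyd * hnc.values[aa]
        weights[i] *= math.exp(tilt)
    if not (math.isfinite(weights.sum()) and weights.sum() > 0):
        raise ValueError("tilted residue distribution degenerated; check deltas")
    if region.startswith("CDR"):
        return weights / weights.sum()
    gk_mask = np.array([aa in GATEKEEPERS.members for aa in STANDARD_AA])
    gk_mass = base[gk_mask].sum() * math.exp(-config.delta_gk)
    p = np.empty(20)
    p[gk_mask] = gk_mass * weights[gk_mask] / weights[gk_mask].sum()
    p[~gk_mask] = (1.0 - gk_mass) * weights[~gk_mask] / weights[~gk_mask].sum()
    return p


def _draw_record(
    rng: np.random.Generator,
    seq_id: str,
    label: str,
    isotype: str,
    dists: dict[str, np.ndarray],
    config: SimConfig,
) -> AnnotatedVL:
    aas = np.array(list(STANDARD_AA))
    parts = []
    regions = {}
    pos = 1
    for region in REGION_ORDER:
        lo, hi = config.region_lengths[region]
        length = int(rng.integers(lo, hi + 1))
        parts.append("".join(aas[rng.choice(20, size=length, p=dists[region])]))
        regions[region] = (pos, pos + length - 1)
        pos += length
    record = AnnotatedVL(
        id=seq_id,
        sequence="".join(parts),
        regions=regions,
        isotype=isotype,
        label=label,
    )
    validate(record)
    return record


def simulate(config: SimConfig) -> list[AnnotatedVL]:
    """Draw a labeled dataset (positives first, then negatives)."""
    rng = np.random.default_rng(config.seed)
    base = {region: _base_distribution(region) for region in REGION_ORDER}
    tilted = {region: _tilted_distribution(region, config) for region in REGION_ORDER}
    records = []
    for i in range(config.n_pos):
        isotype = "lambda" if rng.random() < LAMBDA_FRACTION_POS else "kappa"
        records.append(
            _draw_record(rng, f"pos_{i:04d}", "amyloid", isotype, tilted, config)
        )
    for i in range(config.n_neg):
        isotype = "lambda" if rng.random() < LAMBDA_FRACTION_NEG else "kappa"
        records.append(
            _draw_record(rng, f"neg_{i:04d}", "non_amyloid", isotype, base, config)
        )
    return records


def simulate_class_imbalance(
    n_total: int, pos_fraction: float = 0.19, config: SimConfig = SimConfig()
) -> list[AnnotatedVL]:
    """Dataset with a fixed class mix (default 19% positives, the prevalence
    of amyloidogenic sequences in the curated real dataset), positives
    rounded to the nearest integer."""
    if n_total < 2:
        raise ValueError("n_total must be >= 2")
    if not 0.0 < pos_fraction < 1.0:
        raise ValueError("pos_fraction must be in (0, 1)")
    n_pos = int(round(n_total * pos_fraction))
    n_pos = min(max(n_pos, 1), n_total - 1)
    return simulate(replace(config, n_pos=n_pos, n_neg=n_total - n_pos))


def simulate_to_files(
    config: SimConfig, out_dir: str | Path
) -> dict[str, Path]:
    """Emit FASTA + regions TSV + labels TSV in the dialect the readers
    consume; byte-identical across runs with the same config and seed."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = simulate(config)
    paths = {
        "fasta": out_dir / "sequences.fasta",
        "regions": out_dir / "regions.tsv",
        "labels": out_dir / "labels.tsv",
    }
    write_dataset(records, paths["fasta"], paths["regions"])
    with open(paths["labels"], "w") as fh:
        fh.write("id\tlabel\n")
        for r in records:
            fh.write(f"{r.id}\t{r.label}\n")
    return paths
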