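"""Region-averaged physicochemical features for V_L domains.

Every feature is a composition statistic of one region set of the domain:
either the arithmetic mean of a per-residue property scale over the region
(``F_avg = (1/N) * sum_i F_i``) or the fraction of residues belonging to a
category.  The seven features of the final classification model are:

=============  =====================================================
``f_hyd_cdr``  mean normalized-consensus hydrophobicity, pooled CDRs
``f_gk_fr``    gatekeeper (D,E,R,K,P) fraction, pooled FRs
``f_dis_vl``   mean per-residue disorder score, whole V_L
``f_beta_vl``  mean beta-sheet propensity, whole V_L
``f_np_vl``    non-polar (A,G,I,L,M,P,V) fraction, whole V_L
``f_ct_cdr``   mean charge-transfer capability (CHAM830107), pooled CDRs
``f_tfe_fr``   mean transfer free energy to surface (BULH740101), pooled FRs
=============  =====================================================

Fractions are stored in [0, 1]; reports render the gatekeeper feature as a
percentage.  "Pooled" means all CDR (or FR) residues are concatenated before
averaging, i.e. longer loops weigh more; a mean-of-per-region-means variant
is available via configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .disorder import DisorderProvider, window_provider
from .io import AnnotatedVL, CDR_REGIONS, FR_REGIONS, MASK_CHAR, segment
from .scales import (
    CATEGORIES,
    PropertyScale,
    ResidueCategory,
    get_category,
    get_scale,
    list_scales,
)

FINAL7: tuple[str, ...] = (
    "f_hyd_cdr",
    "f_gk_fr",
    "f_dis_vl",
    "f_beta_vl",
    "f_np_vl",
    "f_ct_cdr",
    "f_tfe_fr",
)

REGION_SETS = ("VL", "CDR_all", "FR_all")


def _clean(seq: str) -> str:
    """Drop masked positions before computing composition statistics."""
    return seq.replace(MASK_CHAR, "")


def region_average(seq: str, scale: PropertyScale) -> float:
    """Mean property value over a region: ``(1/N) * sum_i F_i``."""
    seq = _clean(seq)
    if not seq:
        raise ValueError("cannot average over an empty region")
    try:
        return sum(scale.values[c] for c in seq) / len(seq)
    except KeyError as exc:
        raise KeyError(
            f"residue {exc.args[0]!r} missing from scale {scale.scale_id!r}"
        ) from None


def category_fraction(seq: str, category: ResidueCategory | str) -> float:
    """Fraction of residues in ``seq`` that belong to the category."""
    if isinstance(category, str):
        category = get_category(category)
    seq = _clean(seq)
    if not seq:
        raise ValueError("cannot compute a fraction over an empty region")
    return sum(c in category.members for c in seq) / len(seq)


def aromaticity(seq: str) -> float:
    """Fraction of aromatic residues (F, W, Y)."""
    return category_fraction(seq, "aromatic")


def symmetric_charge(seq: str) -> float:
    """Squared normalized net charge, ``(n_pos - n_neg)^2 / len^2``.

    ``n_pos`` counts K and R, ``n_neg`` counts D and E.  This is a local
    convention for the net-charge-style feature; it is isolated here so an
    alternative definition can be swapped in.
    """
    seq = _clean(seq)
    if not seq:
        raise ValueError("cannot compute symmetric charge of an empty region")
    n_pos = sum(c in "KR" for c in seq)
    n_neg = sum(c in "DE" for c in seq)
    return (n_pos - n_neg) ** 2 / len(seq) ** 2


@dataclass(frozen=True)
class FeatureConfig:
    """Knobs of the feature engine.

    ``cdr_pooling`` selects between pooling all CDR residues before averaging
    (``"pooled"``, default, length-weighted) and averaging the three per-CDR
    means (``"mean_of_means"``).  ``beta_scale`` names the beta-sheet
    propensity scale used for ``f_beta_vl``.
    """

    panel: str = "final7"  # or "extended"
    cdr_pooling: str = "pooled"  # or "mean_of_means"
    beta_scale: str = "CHOP780202"
    hydrophobicity_scale: str = "HNC"

    def __post_init__(self) -> None:
        if self.panel not in ("final7", "extended"):
            raise ValueError(f"unknown panel {self.panel!r}")
        if self.cdr_pooling not in ("pooled", "mean_of_means"):
            raise ValueError(f"unknown cdr_pooling {self.cdr_pooling!r}")


def _cdr_average(record: AnnotatedVL, scale: PropertyScale, config: FeatureConfig) -> float:
    if config.cdr_pooling == "pooled":
        return region_average(segment(record, "CDR_all"), scale)
    return float(
        np.mean([region_average(record.region_seq(r), scale) for r in CDR_REGIONS])
    )


def extract_features(
    record: AnnotatedVL,
    disorder_provider: Optional[DisorderProvider] = None,
    config: FeatureConfig = FeatureConfig(),
) -> dict[str, float]:
    """Compute the final-model feature vector for one record."""
    if disorder_provider is None:
        disorder_provider = window_provider()
    profile = disorder_provider(record)
    if len(profile) != len(record.sequence):
        raise ValueError(
            f"{record.id}: disorder profile length {len(profile)} != "
            f"sequence length {len(record.sequence)}"
        )
    vl = segment(record, "VL")
    fr = segment(record, "FR_all")
    return {
        "f_hyd_cdr": _cdr_average(record, get_scale(config.hydrophobicity_scale), config),
        "f_gk_fr": category_fraction(fr, "gatekeeper"),
        "f_dis_vl": float(np.mean(profile.scores)),
        "f_beta_vl": region_average(vl, get_scale(config.beta_scale)),
        "f_np_vl": category_fraction(vl, "nonpolar"),
        "f_ct_cdr": _cdr_average(record, get_scale("CHAM830107"), config),
        "f_tfe_fr": region_average(fr, get_scale("BULH740101")),
    }


def _extended_features(record: AnnotatedVL, config: FeatureConfig) -> dict[str, float]:
    """Every registered scale and category per region set, plus the
    composition-style extras (symmetric charge, aromaticity, beta propensity)."""
    out: dict[str, float] = {}
    segs = {rs: segment(record, rs) for rs in REGION_SETS}
    for scale_id in list_scales():
        scale = get_scale(scale_id)
        for rs, seq in segs.items():
            out[f"{scale_id}_{rs}"] = region_average(seq, scale)
    for cat in CATEGORIES:
        for rs, seq in segs.items():
            out[f"frac_{cat}_{rs}"] = category_fraction(seq, cat)
    for rs, seq in segs.items():
        out[f"symmetric_charge_{rs}"] = symmetric_charge(seq)
        out[f"aromaticity_{rs}"] = aromaticity(seq)
    return out


@dataclass
class FeatureMatrix:
    """Per-record feature rows plus optional labels, row order = input order."""

    features: pd.DataFrame
    labels: Optional[pd.Series] = None

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    @property
    def X(self) -> np.ndarray:
        return self.features.to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        if self.labels is None:
            raise ValueError("feature matrix has no labels")
        return (self.labels == "amyloid").to_numpy(dtype=int)

    def __len__(self) -> int:
        return len(self.features)


def extract_matrix(
    records: Sequence[AnnotatedVL],
    disorder_provider: Optional[DisorderProvider] = None,
    config: FeatureConfig = FeatureConfig(),
) -> FeatureMatrix:
    """Feature matrix for a dataset (``final7`` or ``extended`` panel)."""
    if disorder_provider is None:
        disorder_provider = window_provider()
    rows = []
    for record in records:
        row = extract_features(record, disorder_provider, config)
        if config.panel == "extended":
            row.update(_extended_features(record, config))
        rows.append(row)
    columns = list(FINAL7) if config.panel == "final7" else None
    features = pd.DataFrame(rows, index=[r.id for r in records], columns=columns)
    labels = pd.Series(
        [r.label for r in records], index=features.index, name="label"
    )
    if (labels == "unlabeled").all():
        labels = None
    return FeatureMatrix(features=features, labels=labels)


def write_matrix(matrix: FeatureMatrix, path) -> None:
    df = matrix.features.copy()
    if matrix.labels is not None:
        df["label"] = matrix.labels
    df.to_csv(path, sep="\t", index_label="id")
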