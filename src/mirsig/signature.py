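"""Build a disease-associated miRNA signature from differential-expression tables.

A feature is retained under a contrast when its linear fold change is at least
``fold_change_min`` in either direction (|log2FC| >= log2(fold_change_min)) and
its FDR is at most ``fdr_max``; the defaults (fold change >= 2, FDR <= 0.05)
are the conventional small-RNA-seq thresholds this pipeline was designed
around.  The signature is the union of retained features across the disease
contrasts, after removing any feature that also passes the thresholds in the
mock (sham-induction) contrast paired with its disease contrast — such a
feature reflects a non-specific effect of the induction procedure, not of the
disease, and is excluded on identity alone (direction is not compared).

A member significant in several contrasts keeps one annotation per contrast
(direction can differ between contrasts and is reported per contrast).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataio import validate_de_table
from .errors import ConfigurationError, ValidationError


@dataclass(frozen=True)
class Thresholds:
    """Retention thresholds: minimum linear fold change and maximum FDR."""

    fold_change_min: float = 2.0
    fdr_max: float = 0.05

    def __post_init__(self):
        if self.fold_change_min < 1:
            raise ValidationError("fold_change_min must be >= 1 (linear scale)")
        if not (0 < self.fdr_max <= 1):
            raise ValidationError("fdr_max must lie in (0, 1]")

    @property
    def log2fc_min(self) -> float:
        return math.log2(self.fold_change_min)


def bh_fdr(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted values, in the input order.

    adj_i = min over ranks j >= rank(i) of p_(j) * n / j, capped at 1; the
    output is monotone non-decreasing in the p-value ranks.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        raise ValidationError("bh_fdr requires a non-empty list")
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n, dtype=float)
    out[order] = np.minimum(adjusted, 1.0)
    return out.tolist()


def filter_de_table(table: pd.DataFrame, thresholds: Thresholds) -> pd.DataFrame:
    """Retain rows passing both thresholds, preserving row order (idempotent)."""
    validate_de_table(table)
    mask = (table["log2fc"].abs() >= thresholds.log2fc_min) & \
           (table["fdr"] <= thresholds.fdr_max)
    return table[mask].reset_index(drop=True)


@dataclass(frozen=True)
class SignatureMember:
    """One signature miRNA with its per-contrast log2 fold changes."""

    name: str
    log2fc: Mapping[str, float] = field(default_factory=dict)

    @property
    def contrasts(self) -> tuple[str, ...]:
        return tuple(self.log2fc)

    def direction(self, contrast: str) -> str:
        return "up" if self.log2fc[contrast] > 0 else "down"

    @property
    def directions(self) -> dict[str, str]:
        return {c: self.direction(c) for c in self.log2fc}


@dataclass(frozen=True)
class Signature:
    """The retained differentially-expressed miRNAs, unique by name."""

    members: tuple[SignatureMember, ...] = ()

    def __post_init__(self):
        names = [m.name for m in self.members]
        if len(names) != len(set(names)):
            raise ValidationError("signature member names must be unique")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.members)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def upregulated_in(self, contrast: str) -> tuple[str, ...]:
        return tuple(m.name for m in self.members
                     if contrast in m.log2fc and m.log2fc[contrast] > 0)

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: one row per (member, contrast)."""
        rows = [(m.name, c, m.log2fc[c], m.direction(c))
                for m in self.members for c in m.contrasts]
        return pd.DataFrame(rows, columns=["mirna", "contrast", "log2fc", "direction"])


def build_signature(disease_tables: Mapping[str, pd.DataFrame],
                    mock_tables: Mapping[str, pd.DataFrame] | None = None,
                    pairing: Mapping[str, str] | None = None,
                    thresholds: Thresholds = Thresholds()) -> Signature:
    """Assemble the signature from per-contrast DE tables.

    ``pairing`` maps a disease contrast to the mock contrast run over the same
    time points; a feature passing the thresholds in both members of a pair is
    treated as an induction artefact and dropped from that contrast.  Features
    retained in any disease contrast are unioned into unique members, each
    carrying its per-contrast log2 fold change.
    """
    mock_tables = dict(mock_tables or {})
    pairing = dict(pairing or {})
    for disease_c, mock_c in pairing.items():
        if disease_c not in disease_tables:
            raise ConfigurationError(f"pairing references unknown disease contrast {disease_c!r}")
        if mock_c not in mock_tables:
            raise ConfigurationError(f"pairing references unknown mock contrast {mock_c!r}")

    members: dict[str, dict[str, float]] = {}
    for contrast, table in disease_tables.items():
        kept = filter_de_table(table.drop_duplicates().reset_index(drop=True), thresholds)
        if contrast in pairing:
            mock = mock_tables[pairing[contrast]]
            nonspecific = set(
                filter_de_table(mock.drop_duplicates().reset_index(drop=True),
                                thresholds)["feature_id"])
            kept = kept[~kept["feature_id"].isin(nonspecific)]
        for _, row in kept.iterrows():
            members.setdefault(row["feature_id"], {})[contrast] = float(row["log2fc"])

    return Signature(tuple(SignatureMember(name, fc) for name, fc in members.items()))
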