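"""Post-enrichment atlas intersection and small-lab statistics.

* :func:`fraction_expressed` — how many of a miRNA's risk-gene targets appear
  in a cell-type expression atlas set (e.g. genes expressed in
  oligodendrocytes).
* :func:`ddct_fold_change` — relative qPCR quantification by the 2^-ddCt
  method: technical replicates are averaged to a per-group mean dCt
  (target Ct minus reference Ct, e.g. U6 snRNA or Gapdh) before differencing.
* :func:`fisher_exact_2x2` — Fisher's exact test on a 2x2 table
  (marker-positive/negative cells by condition).  Computed with exact integer
  arithmetic over the hypergeometric distribution of the top-left cell so tie
  handling in the two-sided test is exact; the two-sided p uses the
  minimum-likelihood convention (sum of the probabilities of all tables with
  fixed margins whose point probability does not exceed the observed one).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb
from typing import Sequence

from .dataio import GeneSet, normalize_gene_symbol
from .errors import ValidationError


def fraction_expressed(overlap_genes: Sequence[str], atlas: GeneSet) -> tuple[int, int]:
    """Return ``(k, n)``: of ``n`` overlap genes, ``k`` are in the atlas set."""
    genes = {normalize_gene_symbol(g) for g in overlap_genes}
    return len(genes & atlas.genes), len(genes)


@dataclass(frozen=True)
class QpcrMeasurement:
    """One qPCR well: cycle thresholds of the target and the reference assay."""

    sample_id: str
    condition: str
    ct_target: float
    ct_reference: float

    def __post_init__(self):
        if self.ct_target <= 0 or self.ct_reference <= 0:
            raise ValidationError("Ct values must be positive")

    @property
    def dct(self) -> float:
        return self.ct_target - self.ct_reference


def ddct_fold_change(cond: Sequence[QpcrMeasurement],
                     baseline: Sequence[QpcrMeasurement]) -> float:
    """Fold change of ``cond`` over ``baseline`` by the 2^-ddCt method."""
    if not cond or not baseline:
        raise ValidationError("both qPCR groups must be non-empty")
    dct_cond = sum(m.dct for m in cond) / len(cond)
    dct_base = sum(m.dct for m in baseline) / len(baseline)
    return 2.0 ** (-(dct_cond - dct_base))


@dataclass(frozen=True)
class Contingency2x2:
    """Counts ``[[a, b], [c, d]]``; rows = marker status, columns = condition."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("cell counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValidationError("contingency table total must be positive")


def _as_cells(table) -> tuple[int, int, int, int]:
    if not isinstance(table, Contingency2x2):
        (a, b), (c, d) = table
        table = Contingency2x2(int(a), int(b), int(c), int(d))
    return table.a, table.b, table.c, table.d


def fisher_exact_2x2(table, sided: str = "two") -> float:
    """Exact hypergeometric tail probability of a 2x2 table.

    ``sided`` is ``"two"`` (minimum-likelihood convention), ``"greater"`` or
    ``"less"`` (one-sided tails in the top-left cell).  The computation uses
    integer binomial weights and a single exact rational division, so results
    carry no accumulation error and probability ties are resolved exactly.
    """
    a, b, c, d = _as_cells(table)
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = {x: comb(r1, x) * comb(r2, c1 - x) for x in range(lo, hi + 1)}
    total = sum(weights.values())  # == comb(r1 + r2, c1) by Vandermonde
    observed = weights[a]
    if sided == "two":
        numerator = sum(w for w in weights.values() if w <= observed)
    elif sided == "greater":
        numerator = sum(weights[x] for x in range(a, hi + 1))
    elif sided == "less":
        numerator = sum(weights[x] for x in range(lo, a + 1))
    else:
        raise ValidationError(f"sided must be 'two', 'greater' or 'less'; got {sided!r}")
    return float(Fraction(numerator, total))
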