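"""Per-miRNA risk-gene target enrichment with a permutation null over miRNAs.

For a miRNA family with ``m`` predicted targets in a database of ``N`` genes
that contains ``K`` risk genes, the expected risk-gene overlap under uniform
target draws is ``E = (K / N) * m`` (the hypergeometric mean), and the
enrichment score is

    S = log2(O / E)

where ``O`` is the observed overlap between the family's targets and the risk
set.  ``O = 0`` leaves the score undefined; it is encoded as ``-inf`` so it
orders below every finite score, and such a family is never significant.

Significance is calibrated against random miRNA draws: ``B`` times, ``n``
families are sampled uniformly without replacement from the database and
scored; the permutation p-value is the fraction of permuted scores that exceed
the true score.  Two null poolings are available — ``pooled`` (default; all
``B * n`` per-family scores form the null) and ``per-replicate`` (one score
per replicate, the replicate mean) — together with two tie conventions:
``strict-greater`` (p = #{null > S} / size, which can return exactly 0) and
the conservative ``greater-or-equal-plus-one`` ((#{null >= S} + 1)/(size + 1)).
A family is called significant when its score strictly exceeds ``score_min``
and its permutation p is at most ``p_max``.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .dataio import GeneSet, TargetDatabase
from .errors import ConfigurationError, ValidationError

#: sentinel for the undefined score (observed overlap of zero)
UNDEFINED = float("-inf")

TIE_MODES = ("strict-greater", "greater-or-equal-plus-one")
NULL_POOLS = ("pooled", "per-replicate")


@dataclass(frozen=True)
class PermutationConfig:
    """Settings of the random-miRNA permutation null."""

    n_perm: int = 1000
    draw_size: int | None = None  # defaults to the signature size
    seed: int = 0
    tie_mode: str = "strict-greater"
    null_pool: str = "pooled"

    def __post_init__(self):
        if self.n_perm < 1:
            raise ValidationError("n_perm must be >= 1")
        if self.draw_size is not None and self.draw_size < 1:
            raise ValidationError("draw_size must be >= 1")
        if self.tie_mode not in TIE_MODES:
            raise ValidationError(f"tie_mode must be one of {TIE_MODES}")
        if self.null_pool not in NULL_POOLS:
            raise ValidationError(f"null_pool must be one of {NULL_POOLS}")


@dataclass(frozen=True)
class SignificanceRule:
    """Call rule: finite score strictly above ``score_min`` and p <= ``p_max``."""

    score_min: float = 1.0
    p_max: float = 0.05

    def __post_init__(self):
        if not (0 < self.p_max <= 1):
            raise ValidationError("p_max must lie in (0, 1]")


@dataclass(frozen=True)
class EnrichmentRecord:
    mirna: str
    observed: int
    expected: float
    score: float  # -inf when observed == 0
    perm_p: float
    significant: bool
    overlap_genes: tuple[str, ...] = ()


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-family records plus the union of risk genes covered by any family."""

    records: tuple[EnrichmentRecord, ...]
    union_risk_genes: tuple[str, ...]

    @property
    def n_union_risk_genes(self) -> int:
        return len(self.union_risk_genes)

    @property
    def significant(self) -> tuple[str, ...]:
        return tuple(r.mirna for r in self.records if r.significant)


def observed_overlap(db: TargetDatabase, mirna: str, risk: GeneSet) -> tuple[int, list[str]]:
    """Observed overlap of a family's targets with the in-universe risk genes."""
    if mirna not in db.targets:
        raise KeyError(f"unknown miRNA family: {mirna!r}")
    usable_risk = risk.genes & db.genes
    genes = sorted(db.targets[mirna] & usable_risk)
    return len(genes), genes


def expected_count(m: int, K: int, N: int) -> float:
    """Expected overlap (K / N) * m — the hypergeometric mean under uniform draws."""
    if N <= 0:
        raise ValidationError("N must be positive")
    if not (0 <= K <= N):
        raise ValidationError("K must satisfy 0 <= K <= N")
    if not (0 <= m <= N):
        raise ValidationError("m must satisfy 0 <= m <= N")
    return (K / N) * m


def enrichment_score(observed: int, expected: float) -> float:
    """log2(observed / expected); ``-inf`` (undefined) when observed == 0."""
    if observed < 0 or expected < 0:
        raise ValidationError("observed and expected must be non-negative")
    if observed == 0:
        return UNDEFINED
    if expected == 0:
        raise ValidationError("expected == 0 with a positive observed count")
    return math.log2(observed / expected)


def _family_scores(db: TargetDatabase, risk: GeneSet) -> dict[str, float]:
    usable_risk = risk.genes & db.genes
    K, N = len(usable_risk), db.n_genes
    scores = {}
    for family in db.families:
        targets = db.targets[family]
        obs = len(targets & usable_risk)
        scores[family] = enrichment_score(obs, expected_count(len(targets), K, N))
    return scores


def _null_scores(db: TargetDatabase, risk: GeneSet, cfg: PermutationConfig,
                 draw_size: int) -> np.ndarray:
    families = db.families  # sorted -> deterministic indexing
    if draw_size > len(families):
        raise ConfigurationError(
            f"draw_size {draw_size} exceeds the {len(families)} database families")
    per_family = _family_scores(db, risk)
    scores = np.array([per_family[f] for f in families], dtype=float)
    rng = np.random.default_rng(cfg.seed)
    # row b = one replicate: draw_size families without replacement
    draws = np.argsort(rng.random((cfg.n_perm, len(families))), axis=1)[:, :draw_size]
    return scores[draws]


def permutation_pvalue(db: TargetDatabase, risk: GeneSet, true_score: float,
                       cfg: PermutationConfig) -> tuple[float, np.ndarray]:
    """Monte-Carlo permutation p-value of a true score against random draws.

    Returns ``(p, null)`` where ``null`` is the pooled score array (shape
    ``(B, n)``) or the per-replicate means (length ``B``), depending on
    ``cfg.null_pool``.  Undefined (``-inf``) null scores are never counted as
    higher than the true score.  Deterministic given ``cfg.seed``.
    """
    if cfg.draw_size is None:
        raise ConfigurationError("draw_size must be set for permutation_pvalue")
    null = _null_scores(db, risk, cfg, cfg.draw_size)
    if cfg.null_pool == "per-replicate":
        null = null.mean(axis=1)
    flat = null.ravel()
    if cfg.tie_mode == "strict-greater":
        p = float(np.count_nonzero(flat > true_score)) / flat.size
    else:
        p = (float(np.count_nonzero(flat >= true_score)) + 1.0) / (flat.size + 1.0)
    return p, null


def call_significance(record: EnrichmentRecord, rule: SignificanceRule) -> bool:
    """True iff the score is finite, exceeds ``score_min``, and p <= ``p_max``."""
    return (math.isfinite(record.score)
            and record.score > rule.score_min
            and record.perm_p <= rule.p_max)


def _family_seed(seed: int, family: str) -> int:
    # stable per-family substream: adding a family never perturbs the others
    return int(np.random.SeedSequence([seed, zlib.crc32(family.encode())])
               .generate_state(1)[0] % (2 ** 31))


def enrich_signature(db: TargetDatabase, risk: GeneSet,
                     mapped_signature: Sequence[str],
                     cfg: PermutationConfig = PermutationConfig(),
                     rule: SignificanceRule = SignificanceRule()) -> EnrichmentResult:
    """Score every signature family and calibrate each against the permutation null.

    ``draw_size`` defaults to the number of distinct signature families.  The
    permutation stream of each family is derived from ``cfg.seed`` and the
    family name, so records are reproducible and independent of the order or
    composition of the signature list.  Records are sorted by descending score
    (undefined scores last, ties broken by name).
    """
    families = list(dict.fromkeys(mapped_signature))
    if not families:
        raise ConfigurationError("mapped signature is empty")
    unknown = [f for f in families if f not in db.targets]
    if unknown:
        raise ConfigurationError(f"signature families missing from the database: {unknown}")
    if cfg.draw_size is None:
        cfg = replace(cfg, draw_size=len(families))

    usable_risk = risk.genes & db.genes
    K, N = len(usable_risk), db.n_genes

    records = []
    union: set[str] = set()
    for family in families:
        obs, genes = observed_overlap(db, family, risk)
        union.update(genes)
        expected = expected_count(db.target_count(family), K, N)
        score = enrichment_score(obs, expected)
        fam_cfg = replace(cfg, seed=_family_seed(cfg.seed, family))
        perm_p, _ = permutation_pvalue(db, risk, score, fam_cfg)
        record = EnrichmentRecord(mirna=family, observed=obs, expected=expected,
                                  score=score, perm_p=perm_p, significant=False,
                                  overlap_genes=tuple(genes))
        records.append(replace(record, significant=call_significance(record, rule)))

    records.sort(key=lambda r: (-r.score, r.mirna))
    return EnrichmentResult(records=tuple(records), union_risk_genes=tuple(sorted(union)))
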