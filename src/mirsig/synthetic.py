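"""Synthetic target databases and DE tables with planted, analytically known truth.

The generators emulate the statistical structure the enrichment analysis
assumes, so every downstream stage can be exercised without any external
download.

``simulate_target_db`` plants a controllable fold enrichment ``f`` for each
miRNA: each of its ``m`` targets is assigned to the risk class with
probability ``f * K / N`` (then a gene is drawn uniformly without replacement
within the class), so the expected risk overlap is exactly ``f * (K / N) * m``
— the enrichment score is therefore an asymptotically unbiased estimator of
``log2 f`` as ``m`` grows, which makes planted-fold recovery an analytic test
target.  Binomially drawn class counts are clamped to the feasible range
``[max(0, m - (N - K)), min(m, K)]``; at the regimes used here the clamp has
negligible probability of binding.

``simulate_de_tables`` plants log2 fold changes with small Gaussian noise and
stochastically small p-values for effect features (a scaled Beta(0.01, 1)
draw), uniform p-values and near-zero log2FC for null features; the FDR column
is the Benjamini-Hochberg adjustment of the p column.  The expression-count
machinery that would produce such tables is out of scope here — only the
table structure matters downstream — but a negative-binomial count emitter is
provided for realism-oriented experiments.

All generators are pure functions of their spec: the master seed expands into
per-miRNA / per-contrast substreams by stable hashing of the name, so adding
an entry never perturbs the draws of the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataio import DE_COLUMNS, GeneSet, TargetDatabase
from .errors import ValidationError
from .signature import bh_fdr


def _substream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(name.encode())]))


# ---------------------------------------------------------------------------
# target databases
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MirnaSpec:
    """One simulated miRNA family: name, target count, planted fold enrichment."""

    name: str
    m: int
    fold: float = 1.0


@dataclass(frozen=True)
class SyntheticDbSpec:
    """Database layout: N genes of which K are risk genes, plus the families."""

    n_genes: int
    n_risk: int
    mirnas: tuple[MirnaSpec, ...]
    seed: int = 0
    risk_name: str = "RISK"

    def __post_init__(self):
        object.__setattr__(self, "mirnas", tuple(self.mirnas))
        if self.n_genes <= 0:
            raise ValidationError("n_genes must be positive")
        if not (0 < self.n_risk <= self.n_genes):
            raise ValidationError("n_risk must satisfy 0 < K <= N")
        names = [m.name for m in self.mirnas]
        if len(names) != len(set(names)):
            raise ValidationError("miRNA names must be unique")
        for spec in self.mirnas:
            if not (0 <= spec.m <= self.n_genes):
                raise ValidationError(f"{spec.name}: m={spec.m} exceeds N={self.n_genes}")
            if spec.fold <= 0:
                raise ValidationError(f"{spec.name}: planted fold must be positive")
            if spec.fold * self.n_risk / self.n_genes > 1:
                raise ValidationError(
                    f"{spec.name}: fold * K / N = "
                    f"{spec.fold * self.n_risk / self.n_genes:.3f} > 1 is not a probability")


@dataclass(frozen=True)
class SyntheticDb:
    """A simulated database with its risk set and the planted truth."""

    db: TargetDatabase
    risk: GeneSet
    truth: pd.DataFrame  # columns: mirna, m, fold


def simulate_target_db(spec: SyntheticDbSpec) -> SyntheticDb:
    """Draw a target database with the planted per-family risk enrichment."""
    N, K = spec.n_genes, spec.n_risk
    genes = np.array([f"G{i:06d}" for i in range(N)])
    risk = GeneSet.from_symbols(spec.risk_name, genes[:K],
                                description="simulated risk genes")

    targets: dict[str, frozenset[str]] = {}
    for mirna in spec.mirnas:
        rng = _substream(spec.seed, mirna.name)
        p_risk = mirna.fold * K / N
        r = int(rng.binomial(mirna.m, p_risk))
        r = min(max(r, mirna.m - (N - K)), min(mirna.m, K))
        risk_idx = rng.choice(K, size=r, replace=False) if r else np.empty(0, dtype=int)
        rest = mirna.m - r
        other_idx = (K + rng.choice(N - K, size=rest, replace=False)
                     if rest else np.empty(0, dtype=int))
        targets[mirna.name] = frozenset(genes[np.concatenate([risk_idx, other_idx]).astype(int)])

    truth = pd.DataFrame([(m.name, m.m, m.fold) for m in spec.mirnas],
                         columns=["mirna", "m", "fold"])
    return SyntheticDb(db=TargetDatabase(genes=frozenset(genes), targets=targets),
                       risk=risk, truth=truth)


# ---------------------------------------------------------------------------
# DE tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticDeSpec:
    """Layout of simulated DE tables with planted effects.

    ``planted`` maps a contrast label to (feature, true log2FC) pairs; all
    remaining features are null under that contrast.  Effect p-values are
    ``effect_p_max * Beta(effect_p_beta_a, 1)`` draws (strongly concentrated
    near zero), null p-values are uniform on [0, 1].
    """

    n_features: int
    contrasts: tuple[str, ...]
    planted: Mapping[str, tuple[tuple[str, float], ...]] = field(default_factory=dict)
    seed: int = 0
    features: tuple[str, ...] | None = None
    null_log2fc_sd: float = 0.25
    effect_log2fc_sd: float = 0.15
    effect_p_beta_a: float = 0.01
    effect_p_max: float = 1e-3

    def __post_init__(self):
        object.__setattr__(self, "contrasts", tuple(self.contrasts))
        object.__setattr__(
            self, "planted",
            {c: tuple((f, float(x)) for f, x in pairs)
             for c, pairs in dict(self.planted).items()})
        if self.n_features <= 0:
            raise ValidationError("n_features must be positive")
        feats = self.feature_names()
        if len(feats) != self.n_features:
            raise ValidationError("features list length must equal n_features")
        known = set(feats)
        for contrast, pairs in self.planted.items():
            if contrast not in self.contrasts:
                raise ValidationError(f"planted contrast {contrast!r} not in contrasts")
            for feat, _ in pairs:
                if feat not in known:
                    raise ValidationError(f"planted feature {feat!r} not in feature list")

    def feature_names(self) -> tuple[str, ...]:
        if self.features is not None:
            return tuple(self.features)
        return tuple(f"miR-sim-{i + 1}" for i in range(self.n_features))


@dataclass(frozen=True)
class SyntheticDe:
    tables: Mapping[str, pd.DataFrame]
    truth: pd.DataFrame  # columns: contrast, feature_id, true_log2fc, planted


def simulate_de_tables(spec: SyntheticDeSpec) -> SyntheticDe:
    """Draw one DE table per contrast, plus a truth table of planted effects."""
    feats = list(spec.feature_names())
    tables: dict[str, pd.DataFrame] = {}
    truth_rows = []
    for contrast in spec.contrasts:
        rng = _substream(spec.seed, contrast)
        log2fc = rng.normal(0.0, spec.null_log2fc_sd, size=len(feats))
        pvals = rng.uniform(0.0, 1.0, size=len(feats))
        planted = dict(spec.planted.get(contrast, ()))
        for i, feat in enumerate(feats):
            if feat in planted:
                log2fc[i] = planted[feat] + rng.normal(0.0, spec.effect_log2fc_sd)
                pvals[i] = spec.effect_p_max * rng.beta(spec.effect_p_beta_a, 1.0)
            truth_rows.append((contrast, feat, planted.get(feat, 0.0), feat in planted))
        tables[contrast] = pd.DataFrame({
            "feature_id": feats,
            "log2fc": log2fc,
            "pvalue": pvals,
            "fdr": bh_fdr(pvals),
            "contrast": contrast,
        })[list(DE_COLUMNS)]
    truth = pd.DataFrame(truth_rows,
                         columns=["contrast", "feature_id", "true_log2fc", "planted"])
    return SyntheticDe(tables=tables, truth=truth)


def simulate_nb_counts(n_features: int, group_sizes: Mapping[str, int],
                       mean: float = 100.0, dispersion: float = 0.1,
                       seed: int = 0) -> pd.DataFrame:
    """Negative-binomial count matrix (features x samples), for realism studies.

    Counts follow NB with the given mean and dispersion (variance
    ``mean + dispersion * mean**2``); sample columns are named
    ``<group>_<replicate>``.  Not consumed by any pipeline stage.
    """
    if dispersion <= 0 or mean <= 0:
        raise ValidationError("mean and dispersion must be positive")
    rng = np.random.default_rng(seed)
    size = 1.0 / dispersion
    prob = size / (size + mean)
    data = {}
    for group, n in group_sizes.items():
        for rep in range(n):
            data[f"{group}_{rep + 1}"] = rng.negative_binomial(size, prob, size=n_features)
    index = [f"miR-sim-{i + 1}" for i in range(n_features)]
    return pd.DataFrame(data, index=index)
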