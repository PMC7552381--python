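"""Readers and writers for the tabular formats the pipeline touches.

Three external dialects are supported, all UTF-8 tab-delimited text with a
header row:

* TargetScan predicted-targets flat files (a miRNA-family column plus a
  gene-symbol column, optionally a species column) -> :class:`TargetDatabase`;
* GMT gene-set files (name TAB description TAB gene...) -> :class:`GeneSet`;
* differential-expression result tables (feature, log2 fold change, p, FDR)
  -> a validated :class:`pandas.DataFrame` with canonical column names.

Readers reject malformed rows instead of coercing them: a missing required
column raises :class:`~mirsig.errors.FormatError` naming the column, numeric
fields that fail to parse raise with the offending row, and p/FDR values
outside [0, 1] raise :class:`~mirsig.errors.ValidationError`.

Gene symbols are uppercase-folded and whitespace-stripped before any set
operation, because target databases and risk-gene lists mix capitalisation
conventions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import FormatError, InputError, ValidationError

#: canonical column order of a differential-expression table
DE_COLUMNS = ("feature_id", "log2fc", "pvalue", "fdr", "contrast")

_FAMILY_CANDIDATES = ("miR family", "miR Family", "mir_family", "family")
_GENE_CANDIDATES = ("Gene Symbol", "gene_symbol", "gene", "symbol")
_SPECIES_CANDIDATES = ("Species ID", "species_id", "species", "taxon_id")

_FEATURE_CANDIDATES = ("feature_id", "feature", "mirna", "miRNA", "name", "id")
_LOG2FC_CANDIDATES = ("log2fc", "log2FC", "log2(FC)", "logFC", "log2_fold_change")
_PVALUE_CANDIDATES = ("pvalue", "p_value", "PValue", "P value", "p")
_FDR_CANDIDATES = ("fdr", "FDR", "padj", "qvalue")


def normalize_gene_symbol(symbol: str) -> str:
    """Uppercase-fold and strip a gene symbol so set operations are case-safe."""
    return str(symbol).strip().upper()


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols (risk list, expression-atlas set...)."""

    name: str
    genes: frozenset[str]
    description: str = ""

    def __post_init__(self):
        if not self.name:
            raise ValidationError("gene set name must be non-empty")
        for g in self.genes:
            if not g or not g.strip():
                raise ValidationError(f"gene set {self.name!r} contains an empty symbol")

    @classmethod
    def from_symbols(cls, name: str, symbols: Iterable[str], description: str = "") -> "GeneSet":
        """Build a set from raw symbols, normalising case and dropping duplicates."""
        genes = frozenset(normalize_gene_symbol(s) for s in symbols if str(s).strip())
        return cls(name=name, genes=genes, description=description)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return normalize_gene_symbol(symbol) in self.genes


@dataclass(frozen=True)
class TargetDatabase:
    """A miRNA-family -> predicted-target-gene database over a gene universe.

    ``genes`` is the universe (size ``N``); ``targets`` maps each family to its
    predicted target set (size ``m_i``).  Every target gene must belong to the
    universe, which the constructor enforces.
    """

    genes: frozenset[str]
    targets: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self):
        if not self.genes:
            raise ValidationError("target database universe is empty")
        for family, tset in self.targets.items():
            if not family or not str(family).strip():
                raise ValidationError("target database contains an empty family name")
            stray = tset - self.genes
            if stray:
                raise ValidationError(
                    f"family {family!r} has targets outside the universe: "
                    f"{sorted(stray)[:5]}"
                )

    @property
    def families(self) -> tuple[str, ...]:
        """Family names in sorted order (deterministic iteration)."""
        return tuple(sorted(self.targets))

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def target_count(self, family: str) -> int:
        try:
            return len(self.targets[family])
        except KeyError:
            raise KeyError(f"unknown miRNA family: {family!r}") from None


# ---------------------------------------------------------------------------
# TargetScan flat files
# ---------------------------------------------------------------------------


def _resolve_column(df: pd.DataFrame, explicit: str | None, candidates: Sequence[str],
                    what: str, required: bool = True) -> str | None:
    if explicit is not None:
        if explicit not in df.columns:
            raise FormatError(
                f"missing required column {explicit!r} ({what}); "
                f"available: {list(df.columns)}"
            )
        return explicit
    for cand in candidates:
        if cand in df.columns:
            return cand
    if required:
        raise FormatError(
            f"no {what} column found (tried {list(candidates)}); "
            f"available: {list(df.columns)}"
        )
    return None


def _read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise InputError(f"empty file: {path}") from None


def read_targetscan(path, species_filter: str | int | None = None, *,
                    family_col: str | None = None, gene_col: str | None = None,
                    species_col: str | None = None,
                    universe: Iterable[str] | None = None) -> TargetDatabase:
    """Read a TargetScan predicted-targets flat file into a :class:`TargetDatabase`.

    Both conserved and nonconserved predicted-target files are accepted; no
    context++ score filtering is applied.  When ``species_filter`` is given the
    file must carry a species column and only matching rows are retained.  The
    gene universe defaults to the distinct gene symbols of the retained rows; an
    external ``universe`` may be supplied instead (it must cover all targets).

    The result is independent of the row order of the input file.
    """
    df = _read_tsv(path)
    fam = _resolve_column(df, family_col, _FAMILY_CANDIDATES, "miRNA-family")
    gene = _resolve_column(df, gene_col, _GENE_CANDIDATES, "gene-symbol")
    spc = _resolve_column(df, species_col, _SPECIES_CANDIDATES, "species",
                          required=species_filter is not None)

    bad = df.index[df[fam].isna() | df[gene].isna()]
    if len(bad):
        raise FormatError(f"row {bad[0] + 2}: missing family or gene symbol")

    if species_filter is not None:
        df = df[df[spc].astype(str).str.strip() == str(species_filter)]
    if df.empty:
        raise InputError(f"zero retained rows in {path}")

    targets: dict[str, set[str]] = {}
    for family, symbol in zip(df[fam], df[gene]):
        targets.setdefault(family.strip(), set()).add(normalize_gene_symbol(symbol))

    if universe is not None:
        genes = frozenset(normalize_gene_symbol(g) for g in universe)
    else:
        genes = frozenset().union(*targets.values())
    return TargetDatabase(genes=genes,
                          targets={f: frozenset(t) for f, t in targets.items()})


def write_targetscan(db: TargetDatabase, path) -> None:
    """Write a database in the minimal TargetScan dialect (family, gene symbol).

    Genes of the universe without any predicting family are not representable
    in this dialect and are dropped; round-trips are exact for databases whose
    universe equals the union of target sets.
    """
    rows = [(fam, g) for fam in db.families for g in sorted(db.targets[fam])]
    pd.DataFrame(rows, columns=["miR family", "Gene Symbol"]).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gmt(path) -> list[GeneSet]:
    """Read a GMT file: one gene set per line, ``name TAB description TAB gene...``."""
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3")
            sets.append(GeneSet.from_symbols(fields[0], fields[2:], description=fields[1]))
    return sets


def write_gmt(sets: Sequence[GeneSet], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.genes)]) + "\n")


def select_gene_set(sets: Sequence[GeneSet], name: str | None) -> GeneSet:
    """Pick a set by name from a GMT, or the only set when ``name`` is None."""
    if name is None:
        if len(sets) != 1:
            raise InputError(
                f"GMT holds {len(sets)} sets; a set name is required to pick one")
        return sets[0]
    for gs in sets:
        if gs.name == name:
            return gs
    raise InputError(f"gene set {name!r} not found (available: {[s.name for s in sets]})")


# ---------------------------------------------------------------------------
# differential-expression tables
# ---------------------------------------------------------------------------


def _parse_float(raw: str, row: int, col: str) -> float:
    # tolerate the unicode minus and stray spaces found in published tables
    cleaned = str(raw).replace("−", "-").replace(" ", "")
    try:
        return float(cleaned)
    except ValueError:
        raise FormatError(f"row {row}: cannot parse {col}={raw!r} as a number") from None


def validate_de_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check the invariants of a canonical DE table and return it unchanged."""
    missing = [c for c in DE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"DE table missing columns: {missing}")
    if (df["feature_id"].astype(str).str.strip() == "").any():
        raise ValidationError("DE table contains an empty feature id")
    for col in ("pvalue", "fdr"):
        bad = df.index[(df[col] < 0) | (df[col] > 1) | df[col].isna()]
        if len(bad):
            raise ValidationError(
                f"row {bad[0]}: {col}={df.loc[bad[0], col]} outside [0, 1]")
    dup = df.duplicated(subset=["feature_id", "contrast"], keep=False)
    if dup.any() and df[dup].duplicated(keep=False).sum() != dup.sum():
        raise ValidationError("conflicting duplicate (feature, contrast) rows")
    return df


def read_de_table(path, contrast: str, *, feature_col: str | None = None,
                  log2fc_col: str | None = None, pvalue_col: str | None = None,
                  fdr_col: str | None = None) -> pd.DataFrame:
    """Read a differential-expression result table under a named contrast.

    Column names are configurable; common spellings (``log2(FC)``, ``PValue``,
    ``FDR``...) are recognised automatically and scientific notation such as
    ``1.65E-05`` is parsed.  If the file carries a ``contrast`` column, only
    rows matching ``contrast`` are retained (an empty selection is valid and
    yields an empty table); otherwise every row is labelled with ``contrast``.
    """
    df = _read_tsv(path)
    feat = _resolve_column(df, feature_col, _FEATURE_CANDIDATES, "feature")
    lfc = _resolve_column(df, log2fc_col, _LOG2FC_CANDIDATES, "log2 fold-change")
    pv = _resolve_column(df, pvalue_col, _PVALUE_CANDIDATES, "p-value")
    fdr = _resolve_column(df, fdr_col, _FDR_CANDIDATES, "FDR")

    if "contrast" in df.columns:
        df = df[df["contrast"].astype(str) == contrast]

    out = pd.DataFrame({
        "feature_id": [str(v).strip() for v in df[feat]],
        "log2fc": [_parse_float(v, i, lfc) for i, v in zip(df.index, df[lfc])],
        "pvalue": [_parse_float(v, i, pv) for i, v in zip(df.index, df[pv])],
        "fdr": [_parse_float(v, i, fdr) for i, v in zip(df.index, df[fdr])],
        "contrast": contrast,
    }).reset_index(drop=True)
    out = out.drop_duplicates().reset_index(drop=True)
    return validate_de_table(out)


def empty_de_table(contrast: str) -> pd.DataFrame:
    """An empty canonical DE table under a named contrast."""
    return pd.DataFrame({
        "feature_id": pd.Series(dtype=str),
        "log2fc": pd.Series(dtype=float),
        "pvalue": pd.Series(dtype=float),
        "fdr": pd.Series(dtype=float),
        "contrast": pd.Series(dtype=str),
    }).assign(contrast=contrast)[list(DE_COLUMNS)]


def write_de_table(df: pd.DataFrame, path) -> None:
    validate_de_table(df).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# result records
# ---------------------------------------------------------------------------

_RESULT_COLUMNS = ("mirna", "observed", "expected", "score", "perm_p",
                   "significant", "overlap_genes")


def write_results(records: Sequence, path, format: str = "tsv") -> None:
    """Write enrichment records to TSV or JSON.

    An undefined score (observed overlap of zero, stored as ``-inf``) is
    written as ``-inf`` in TSV and as ``null`` in JSON; both round-trip through
    :func:`read_results`.
    """
    rows = []
    for r in records:
        rows.append({
            "mirna": r.mirna,
            "observed": int(r.observed),
            "expected": float(r.expected),
            "score": float(r.score),
            "perm_p": float(r.perm_p),
            "significant": bool(r.significant),
            "overlap_genes": ",".join(r.overlap_genes),
        })
    if format == "tsv":
        df = pd.DataFrame(rows, columns=_RESULT_COLUMNS)
        # str(float) round-trips exactly in Python 3
        for col in ("expected", "score", "perm_p"):
            df[col] = df[col].map(str)
        df.to_csv(path, sep="\t", index=False)
    elif format == "json":
        for row in rows:
            if not math.isfinite(row["score"]):
                row["score"] = None
            row["overlap_genes"] = row["overlap_genes"].split(",") if row["overlap_genes"] else []
        Path(path).write_text(json.dumps(rows, indent=2) + "\n", encoding="utf-8")
    else:
        raise ValidationError(f"unknown result format: {format!r}")


def read_results(path, format: str = "tsv") -> list:
    """Read enrichment records written by :func:`write_results`."""
    from .enrichment import EnrichmentRecord  # local import avoids a cycle

    records = []
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        for _, row in df.iterrows():
            genes = tuple(g for g in row["overlap_genes"].split(",") if g)
            records.append(EnrichmentRecord(
                mirna=row["mirna"], observed=int(row["observed"]),
                expected=float(row["expected"]), score=float(row["score"]),
                perm_p=float(row["perm_p"]),
                significant=row["significant"] in ("True", "true", "1"),
                overlap_genes=genes))
    elif format == "json":
        for row in json.loads(Path(path).read_text(encoding="utf-8")):
            score = float("-inf") if row["score"] is None else float(row["score"])
            records.append(EnrichmentRecord(
                mirna=row["mirna"], observed=int(row["observed"]),
                expected=float(row["expected"]), score=score,
                perm_p=float(row["perm_p"]), significant=bool(row["significant"]),
                overlap_genes=tuple(row["overlap_genes"])))
    else:
        raise ValidationError(f"unknown result format: {format!r}")
    return records
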