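"""End-to-end orchestration: signature -> orthologs -> enrichment -> atlas.

A single TOML config names every input, the thresholds, the permutation
settings and the output directory; all randomness flows from one master seed
recorded in the run report.  Outputs are per-stage TSVs plus a JSON report
(stage counts, seed, package version); two runs with the same config produce
byte-identical files.  Logging goes to standard error and never into result
files.
"""

from __future__ import annotations

import json
import logging
import sys
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .dataio import read_de_table, read_gmt, read_targetscan, select_gene_set, write_results
from .downstream import fraction_expressed
from .enrichment import PermutationConfig, SignificanceRule, enrich_signature
from .errors import ConfigurationError, PipelineError
from .ortholog import map_mouse_to_human, read_overrides
from .signature import Thresholds, build_signature

log = logging.getLogger("mirsig")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one run needs; defaults mirror the analysis conventions
    (fold change >= 2, FDR <= 0.05, B = 1000 permutations, score > 1, p <= 0.05)."""

    target_db: Path
    risk_gmt: Path
    disease_tables: dict[str, Path]
    mock_tables: dict[str, Path] = field(default_factory=dict)
    pairing: dict[str, str] = field(default_factory=dict)
    risk_set: str | None = None
    overrides: Path | None = None
    atlas_gmt: Path | None = None
    atlas_set: str | None = None
    thresholds: Thresholds = Thresholds()
    permutation: PermutationConfig = PermutationConfig()
    rule: SignificanceRule = SignificanceRule()
    species_filter: str | None = None
    seed: int = 0
    out_dir: Path = Path("mirsig-out")

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        raw = tomllib.loads(Path(path).read_text(encoding="utf-8"))
        base = Path(path).parent

        def _path(value):
            p = Path(value)
            return p if p.is_absolute() else base / p

        inputs = raw.get("inputs", {})
        contrasts = raw.get("contrasts", {})
        try:
            cfg = cls(
                target_db=_path(inputs["target_db"]),
                risk_gmt=_path(inputs["risk_gmt"]),
                risk_set=inputs.get("risk_set"),
                overrides=_path(inputs["overrides"]) if "overrides" in inputs else None,
                atlas_gmt=_path(inputs["atlas_gmt"]) if "atlas_gmt" in inputs else None,
                atlas_set=inputs.get("atlas_set"),
                species_filter=inputs.get("species_filter"),
                disease_tables={k: _path(v) for k, v in contrasts.get("disease", {}).items()},
                mock_tables={k: _path(v) for k, v in contrasts.get("mock", {}).items()},
                pairing=dict(contrasts.get("pairing", {})),
                thresholds=Thresholds(**raw.get("thresholds", {})),
                permutation=PermutationConfig(seed=int(raw.get("seed", 0)),
                                              **raw.get("permutation", {})),
                rule=SignificanceRule(**raw.get("significance", {})),
                seed=int(raw.get("seed", 0)),
                out_dir=_path(raw.get("out_dir", "mirsig-out")),
            )
        except KeyError as exc:
            raise ConfigurationError(f"config is missing required key: {exc}") from None
        return cfg

    def validate_paths(self) -> None:
        paths = {"target_db": self.target_db, "risk_gmt": self.risk_gmt,
                 **{f"disease:{k}": v for k, v in self.disease_tables.items()},
                 **{f"mock:{k}": v for k, v in self.mock_tables.items()}}
        if self.overrides is not None:
            paths["overrides"] = self.overrides
        if self.atlas_gmt is not None:
            paths["atlas_gmt"] = self.atlas_gmt
        missing = [f"{name} ({p})" for name, p in paths.items() if not Path(p).is_file()]
        if missing:
            raise ConfigurationError(f"missing input files: {missing}")
        if not self.disease_tables:
            raise ConfigurationError("no disease contrasts configured")


class _Stage:
    """Context manager that re-raises any failure annotated with the stage name."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        log.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and not isinstance(exc, PipelineError):
            raise PipelineError(self.name, str(exc)) from exc
        log.info("stage %s: done", self.name)
        return False


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the JSON-serialisable run report."""
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    with _Stage("load_inputs"):
        db = read_targetscan(config.target_db, species_filter=config.species_filter)
        risk = select_gene_set(read_gmt(config.risk_gmt), config.risk_set)
        disease = {c: read_de_table(p, c) for c, p in config.disease_tables.items()}
        mock = {c: read_de_table(p, c) for c, p in config.mock_tables.items()}
        overrides = read_overrides(config.overrides) if config.overrides else {}
        atlas = None
        if config.atlas_gmt is not None:
            atlas = select_gene_set(read_gmt(config.atlas_gmt), config.atlas_set)

    with _Stage("build_signature"):
        signature = build_signature(disease, mock, config.pairing, config.thresholds)
        signature.to_frame().to_csv(out / "signature.tsv", sep="\t", index=False)

    with _Stage("map_orthologs"):
        omap = map_mouse_to_human(signature.names, db, overrides)
        omap.to_frame().to_csv(out / "ortholog_map.tsv", sep="\t", index=False)

    with _Stage("enrich_signature"):
        cfg = PermutationConfig(
            n_perm=config.permutation.n_perm,
            draw_size=config.permutation.draw_size,
            seed=config.seed,
            tie_mode=config.permutation.tie_mode,
            null_pool=config.permutation.null_pool)
        result = enrich_signature(db, risk, omap.mapped_families, cfg, config.rule)
        write_results(result.records, out / "enrichment.tsv", format="tsv")

    atlas_rows = []
    if atlas is not None:
        with _Stage("atlas_intersect"):
            for record in result.records:
                k, n = fraction_expressed(record.overlap_genes, atlas)
                atlas_rows.append({"mirna": record.mirna, "expressed": k, "total": n})
            import pandas as pd
            pd.DataFrame(atlas_rows, columns=["mirna", "expressed", "total"]).to_csv(
                out / "atlas_fractions.tsv", sep="\t", index=False)

    report = {
        "version": __version__,
        "seed": config.seed,
        "counts": {
            "signature_size": len(signature),
            "mapped": omap.n_mapped,
            "unmapped": omap.n_unmapped,
            "mapped_families": len(omap.mapped_families),
            "records": len(result.records),
            "union_risk_genes": result.n_union_risk_genes,
            "significant": len(result.significant),
        },
        "significant": list(result.significant),
        "provenance": omap.provenance_counts(),
        "outputs": sorted(p.name for p in out.iterdir() if p.suffix == ".tsv"),
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n",
                                     encoding="utf-8")
    return report


def configure_logging(verbose: bool = False) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(logging.DEBUG if verbose else logging.WARNING)
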