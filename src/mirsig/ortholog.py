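"""Map mouse miRNA names to human TargetScan family names.

Mouse and human mature miRNA names differ in species prefix and, frequently,
in the paralog letter attached to the numeric core (mouse ``miR-10b-5p``
versus the human family ``miR-10-5p``).  The mapper resolves each name in a
fixed order and records the provenance of every decision:

1. an explicit override table (for correspondences no heuristic should invent,
   such as cross-arm renamings);
2. exact match of the normalised name against the database's family names;
3. paralog-letter collapse (drop a single trailing letter from the numeric
   core, keeping the arm suffix) followed by exact match;
4. otherwise the name is reported as unmapped — never silently dropped.

Seed-sequence matching is deliberately not attempted: without the seed table
it cannot be verified, and name-level mapping with explicit overrides keeps
every decision auditable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .dataio import TargetDatabase
from .errors import FormatError, ValidationError

#: provenance labels, in resolution order
PROVENANCES = ("override", "exact", "paralog-collapse", "unmapped")

_SPECIES_PREFIX = re.compile(r"^[a-z]{3,4}-(?=(miR|mir|let)\b|miR-|mir-|let-)")
_PARALOG = re.compile(r"^(miR-\d+)([a-z])(-[35]p)?$")


def normalize_mirna_name(name: str) -> str:
    """Canonicalise a mature miRNA name: strip species prefix, fix miR casing.

    ``mmu-miR-155-5p`` -> ``miR-155-5p``; ``hsa-mir-210-3p`` -> ``miR-210-3p``;
    the arm suffix (-3p/-5p), paralog letters and ``let-`` names are preserved.
    """
    if not name or not str(name).strip():
        raise ValidationError("miRNA name must be non-empty")
    out = str(name).strip()
    out = _SPECIES_PREFIX.sub("", out)
    if out.lower().startswith("mir-") or out.lower() == "mir":
        out = "miR" + out[3:]
    return out


def collapse_paralog(name: str) -> str | None:
    """Drop a trailing paralog letter from the numeric core, or None if absent.

    ``miR-142a-5p`` -> ``miR-142-5p``; ``miR-8114`` (no letter) -> None.
    """
    match = _PARALOG.match(name)
    if match is None or not match.group(2):
        return None
    return match.group(1) + (match.group(3) or "")


@dataclass(frozen=True)
class MappingEntry:
    mouse: str
    human: str | None  # None == unmapped
    provenance: str


@dataclass(frozen=True)
class OrthologMap:
    """Total mapping over an input list, with per-entry provenance."""

    entries: tuple[MappingEntry, ...] = ()

    @property
    def mapped_families(self) -> tuple[str, ...]:
        """Distinct human families, in first-seen order."""
        seen: dict[str, None] = {}
        for e in self.entries:
            if e.human is not None:
                seen.setdefault(e.human)
        return tuple(seen)

    @property
    def n_mapped(self) -> int:
        return sum(1 for e in self.entries if e.human is not None)

    @property
    def n_unmapped(self) -> int:
        return sum(1 for e in self.entries if e.human is None)

    def provenance_counts(self) -> dict[str, int]:
        counts = {p: 0 for p in PROVENANCES}
        for e in self.entries:
            counts[e.provenance] += 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.mouse, e.human if e.human is not None else "UNMAPPED", e.provenance)
             for e in self.entries],
            columns=["mouse", "human", "provenance"])


def map_mouse_to_human(names: Sequence[str], human_db: TargetDatabase,
                       overrides: Mapping[str, str] | None = None) -> OrthologMap:
    """Resolve each mouse miRNA name to a human family of ``human_db``.

    Overrides are keyed by either the raw or the normalised mouse name and win
    over the heuristic; unresolved names appear with provenance ``unmapped``.
    The mapping is deterministic and idempotent.
    """
    overrides = dict(overrides or {})
    norm_overrides = {normalize_mirna_name(k): v for k, v in overrides.items()}
    families = set(human_db.families)

    entries = []
    for raw in names:
        norm = normalize_mirna_name(raw)
        target = overrides.get(raw, norm_overrides.get(norm))
        if target is not None:
            entries.append(MappingEntry(raw, target, "override"))
            continue
        if norm in families:
            entries.append(MappingEntry(raw, norm, "exact"))
            continue
        collapsed = collapse_paralog(norm)
        if collapsed is not None and collapsed in families:
            entries.append(MappingEntry(raw, collapsed, "paralog-collapse"))
            continue
        entries.append(MappingEntry(raw, None, "unmapped"))
    return OrthologMap(tuple(entries))


def read_overrides(path) -> dict[str, str]:
    """Read a two-column override TSV (mouse name, human family).

    A header line ``mouse<TAB>human`` is accepted and skipped; ``#`` comments
    and blank lines are ignored.
    """
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated fields")
            if lineno == 1 and fields == ["mouse", "human"]:
                continue
            out[fields[0].strip()] = fields[1].strip()
    return out
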