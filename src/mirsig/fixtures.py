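"""Packaged EAE miRNA differential-expression fixtures and related constants.

The package ships the differentially expressed OL miRNAs of a longitudinal
EAE (experimental autoimmune encephalomyelitis) profiling study as two small
TSV tables: cross-sectional contrasts (EAE vs mock-injected controls at each
time point) and longitudinal contrasts (within-arm comparisons across time
points; BL = baseline, 10/20 = days post-immunization).  These tables are the
canonical worked example of the signature and ortholog stages and anchor the
regression tests.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .dataio import empty_de_table, read_de_table
from .ortholog import read_overrides

#: disease contrasts in analysis order (cross-sectional first)
DISEASE_CONTRASTS = ("EAE10-vs-Mock10", "EAE20-vs-Mock20",
                     "EAE10-vs-BL", "EAE20-vs-EAE10")
#: mock (sham-induction) contrasts
MOCK_CONTRASTS = ("Mock10-vs-BL", "Mock20-vs-Mock10")
#: disease contrast -> matched mock contrast over the same time points
PAIRING = {"EAE10-vs-BL": "Mock10-vs-BL", "EAE20-vs-EAE10": "Mock20-vs-Mock10"}

#: human TargetScan family names of the conserved signature miRNAs
HUMAN_CONSERVED_FAMILIES = (
    "miR-10-5p", "miR-1249-3p", "miR-142-5p", "miR-146-5p", "miR-155-5p",
    "miR-190-5p", "miR-203a-5p", "miR-210-3p", "miR-221-3p", "miR-28-3p",
    "miR-342-3p",
)

_CONTRAST_FILES = {
    "EAE10-vs-Mock10": "de_cross_sectional.tsv",
    "EAE20-vs-Mock20": "de_cross_sectional.tsv",
    "EAE10-vs-BL": "de_longitudinal.tsv",
    "EAE20-vs-EAE10": "de_longitudinal.tsv",
    "Mock10-vs-BL": "de_longitudinal.tsv",
    "Mock20-vs-Mock10": "de_longitudinal.tsv",
}


def fixture_path(name: str):
    """Filesystem path of a packaged fixture file."""
    return resources.files("mirsig.data") / name


def load_de_fixture(contrast: str) -> pd.DataFrame:
    """The packaged DE table of one contrast (empty for null contrasts)."""
    if contrast not in _CONTRAST_FILES:
        raise KeyError(f"unknown fixture contrast: {contrast!r}")
    with resources.as_file(fixture_path(_CONTRAST_FILES[contrast])) as path:
        table = read_de_table(path, contrast)
    return table if len(table) else empty_de_table(contrast)


def signature_inputs() -> tuple[dict[str, pd.DataFrame], dict[str, pd.DataFrame], dict[str, str]]:
    """(disease tables, mock tables, pairing) ready for ``build_signature``."""
    disease = {c: load_de_fixture(c) for c in DISEASE_CONTRASTS}
    mock = {c: load_de_fixture(c) for c in MOCK_CONTRASTS}
    return disease, mock, dict(PAIRING)


def ortholog_overrides() -> dict[str, str]:
    """The packaged mouse -> human override table (cross-arm renamings)."""
    with resources.as_file(fixture_path("ortholog_overrides.tsv")) as path:
        return read_overrides(path)
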