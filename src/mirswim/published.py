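"""Published two-library study tables bundled as reference inputs.

These are the printed summary tables of the rat-brain swimming-training
small-RNA study this pipeline models: library-level read totals, the twenty
most abundant known miRNAs with raw read counts, and the 34 significantly
differentially expressed miRNAs with their normalized expression (TPM),
log2 fold change, p-value and direction.  They serve as fixed inputs for
re-deriving the study's normalization and classification arithmetic; they
are never fitted to.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd


def _data(name: str):
    return resources.files("mirswim.data").joinpath(name)


def library_totals() -> dict[str, dict[str, int]]:
    """Per-library sequencing totals (raw, clean, unique, mapped)."""
    with _data("published_library_totals.json").open() as fh:
        return json.load(fh)


def top_known() -> pd.DataFrame:
    """The twenty most abundant known miRNAs with per-library raw counts."""
    with _data("published_top_known.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def de_table() -> pd.DataFrame:
    """The 34 significantly differentially expressed miRNAs.

    Columns: name, hist_std / nc_std (normalized expression, TPM, printed to
    2 decimals), log2fc, p_value, sig ('*'/'**'), mark (Up/Down).
    """
    with _data("published_de_table.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
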