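"""Bundled reference tables of the screen outcome.

Two small TSV transcriptions ship with the package: the 88 Class A modifiers
(gene, functional class, molecular function) and the 9 core proteostasis
modifiers with their temperature-sensitive rescue tallies (x of 4 strains).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_table1_fixture", "load_table2_fixture"]


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("wormtriage.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def load_table1_fixture() -> pd.DataFrame:
    """The 88 Class A aggregation modifiers with functional annotations."""
    return _read("table1.tsv")


def load_table2_fixture() -> pd.DataFrame:
    """The 9 core modifiers with TS rescue tallies (``ts_rescued``/``ts_tested``)."""
    return _read("table2.tsv")
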