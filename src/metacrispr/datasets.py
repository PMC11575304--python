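"""Bundled reference tables from the *Streptococcus* CRISPR typing study.

Three small tables ship with the package:

* ``copy_table`` — qPCR spacer copy numbers (copies/uL) for both CRISPR loci
  across 22 skin swabs, 11 saliva samples and 4 keyboard (object) swabs,
  with bacterial/human DNA concentrations. ``ND`` marks no amplification;
  a trailing ``*`` marks values below the 100 copies/uL LOQ.
* ``neat_comparison`` — per-sample Bray-Curtis distances to the reference
  saliva (both loci) and correct STR locus counts (of 21) for the eight
  neat skin swabs.
* ``diluted_comparison`` — the same for the eight 1:10 diluted skin swabs.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io_core import CopyTable, SampleMetadata, read_metadata

__all__ = ["load_copy_table", "load_neat_comparison", "load_diluted_comparison"]


def _data_path(name: str):
    return resources.files("metacrispr.data").joinpath(name)


def load_copy_table() -> tuple[list[SampleMetadata], CopyTable]:
    """Sample metadata and spacer copy-number table (skin/saliva/object)."""
    with resources.as_file(_data_path("copy_table.tsv")) as path:
        return read_metadata(path)


def load_neat_comparison() -> pd.DataFrame:
    """Typing-vs-STR comparison for neat skin swabs (distances + loci)."""
    with resources.as_file(_data_path("neat_comparison.tsv")) as path:
        return pd.read_csv(path, sep="\t", dtype={"sample_id": str})


def load_diluted_comparison() -> pd.DataFrame:
    """Typing-vs-STR comparison for 1:10 diluted skin swabs."""
    with resources.as_file(_data_path("diluted_comparison.tsv")) as path:
        return pd.read_csv(path, sep="\t", dtype={"sample_id": str})
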