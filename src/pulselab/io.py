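"""Table import/export in MaxQuant-flavored column layouts.

The simulator and pipeline exchange a long-format table (one row per protein
and sample).  Real MaxQuant output is wide — ``iBAQ L <sample>``,
``iBAQ H <sample>``, ``Ratio H/L <sample>`` — so converters in both
directions are provided, plus TSV round-trips.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "to_maxquant_style",
    "from_maxquant_style",
    "write_tsv",
    "read_quant_table",
]

_LONG_COLUMNS = [
    "protein_id", "sample", "time_min", "intensity_L", "intensity_H", "ratio_HL",
]


def to_maxquant_style(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long quantification table into MaxQuant-style wide columns."""
    missing = [c for c in _LONG_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"long table lacks columns: {missing}")
    samples = table[["sample", "time_min"]].drop_duplicates().sort_values(
        ["time_min", "sample"]
    )["sample"]
    wide = pd.DataFrame(
        {"Protein IDs": sorted(table["protein_id"].unique())}
    ).set_index("Protein IDs")
    for kind, prefix in (
        ("intensity_L", "iBAQ L "),
        ("intensity_H", "iBAQ H "),
        ("ratio_HL", "Ratio H/L "),
    ):
        pivot = table.pivot_table(
            index="protein_id", columns="sample", values=kind,
            aggfunc="first", dropna=False,
        )
        for s in samples:
            wide[prefix + s] = pivot[s]
    return wide.reset_index()


def from_maxquant_style(
    wide: pd.DataFrame,
    sample_times: Mapping[str, float],
    *,
    id_column: str = "Protein IDs",
) -> pd.DataFrame:
    """Melt MaxQuant-style wide columns back into the long pipeline format.

    ``sample_times`` maps each sample name to its minutes post-shift
    (0 for the unlabeled t0 replicates).  Intensities of 0 are treated as
    missing, as in MaxQuant output.
    """
    if id_column not in wide.columns:
        raise ValueError(f"missing id column {id_column!r}")
    frames = []
    for sample, t_min in sample_times.items():
        cols = {
            "intensity_L": f"iBAQ L {sample}",
            "intensity_H": f"iBAQ H {sample}",
            "ratio_HL": f"Ratio H/L {sample}",
        }
        missing = [c for c in cols.values() if c not in wide.columns]
        if missing:
            raise ValueError(f"wide table lacks columns: {missing}")
        chunk = pd.DataFrame(
            {
                "protein_id": wide[id_column],
                "sample": sample,
                "time_min": float(t_min),
            }
        )
        for out_col, in_col in cols.items():
            vals = wide[in_col].astype(float).to_numpy()
            vals[vals == 0] = np.nan
            chunk[out_col] = vals
        frames.append(chunk)
    return pd.concat(frames, ignore_index=True)


def write_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_quant_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format quantification TSV written by :func:`write_tsv`."""
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in _LONG_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: not a quantification table, lacks {missing}")
    return table
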