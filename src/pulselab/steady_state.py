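"""Steady-state (long-term adaptation) differential proteome analysis.

Works on MaxQuant-style protein-groups tables: per-sample LFQ and iBAQ
intensities plus the usual bookkeeping columns.  The workflow is the classic
Perseus one — acceptance filtering, log10 transform, down-shifted-normal
imputation of missing values, fold-change calls — plus proteome-allocation
profiles: summed relative iBAQ of a protein class per sample, correlated
with growth rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "read_protein_groups",
    "acceptance_filter",
    "log10_transform",
    "impute_missing",
    "fold_change_de",
    "relative_ibaq",
    "class_growth_correlation",
    "ClassCorrelation",
]

# Perseus-default imputation: per-sample normal, down-shifted 1.8 SD, width 0.3 SD
IMPUTE_DOWNSHIFT = 1.8
IMPUTE_WIDTH = 0.3


def read_protein_groups(path: str | Path) -> pd.DataFrame:
    """Read a MaxQuant proteinGroups.txt-style TSV."""
    return pd.read_csv(path, sep="\t")


def _require_columns(table: pd.DataFrame, columns: Sequence[str]) -> None:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise ValueError(f"protein-groups table lacks required columns: {missing}")


def acceptance_filter(
    table: pd.DataFrame,
    condition_map: Mapping[str, str],
    *,
    intensity_prefix: str = "LFQ intensity ",
    min_replicates: int = 2,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop protein groups that fail the standard acceptance criteria.

    A row survives when it is not a reverse-database hit, not identified
    only by a modification site, has more than one peptide of which at
    least one is unique, and is quantified (intensity > 0) in at least
    ``min_replicates`` replicates of at least one condition.
    ``condition_map`` maps sample names (suffixes of the intensity columns)
    to condition labels.  Returns the filtered table and per-reason drop
    counts.
    """
    _require_columns(
        table, ["Reverse", "Only identified by site", "Peptides", "Unique peptides"]
    )
    sample_cols = {s: intensity_prefix + s for s in condition_map}
    _require_columns(table, list(sample_cols.values()))

    reverse = table["Reverse"].fillna("").astype(str).str.strip() == "+"
    by_site = (
        table["Only identified by site"].fillna("").astype(str).str.strip() == "+"
    )
    few_peptides = ~(
        (table["Peptides"] > 1) & (table["Unique peptides"] >= 1)
    )

    conditions = sorted(set(condition_map.values()))
    enough = np.zeros(len(table), dtype=bool)
    for cond in conditions:
        cols = [col for s, col in sample_cols.items() if condition_map[s] == cond]
        quantified = (table[cols] > 0).sum(axis=1)
        enough |= (quantified >= min_replicates).to_numpy()
    under_replicated = ~enough

    drops = {
        "reverse": int(reverse.sum()),
        "only_identified_by_site": int((by_site & ~reverse).sum()),
        "insufficient_peptides": int((few_peptides & ~reverse & ~by_site).sum()),
        "under_replicated": int(
            (under_replicated & ~few_peptides & ~reverse & ~by_site).sum()
        ),
    }
    keep = ~(reverse | by_site | few_peptides | under_replicated)
    return table.loc[keep].reset_index(drop=True), drops


def log10_transform(
    table: pd.DataFrame,
    sample_columns: Sequence[str],
) -> pd.DataFrame:
    """log10 of the intensity columns with zeros treated as missing."""
    out = table[list(sample_columns)].astype(float).copy()
    out[out <= 0] = np.nan
    return np.log10(out)


def impute_missing(
    log_table: pd.DataFrame, seed: int | None = None
) -> pd.DataFrame:
    """Impute missing log10 intensities from a down-shifted normal.

    Per sample column, missing entries are drawn from
    ``N(mean - 1.8 SD, (0.3 SD)^2)`` of that column's observed values —
    the Perseus convention that places imputed values near the detection
    limit.  Observed values are never altered.  A column with fewer than
    two observed values has no defined spread and is an error.
    """
    rng = np.random.default_rng(seed)
    out = log_table.copy()
    for col in out.columns:
        observed = out[col].dropna()
        missing = out[col].isna()
        if not missing.any():
            continue
        if len(observed) < 2:
            raise ValueError(
                f"sample {col!r} has {len(observed)} observed values; "
                "cannot estimate an imputation distribution"
            )
        m, s = float(observed.mean()), float(observed.std(ddof=1))
        out.loc[missing, col] = rng.normal(
            m - IMPUTE_DOWNSHIFT * s, IMPUTE_WIDTH * s, size=int(missing.sum())
        )
    return out


def fold_change_de(
    log_table: pd.DataFrame,
    condition_map: Mapping[str, str],
    condition_a: str,
    condition_b: str,
    *,
    cutoff: float = 5.0,
    protein_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Fold-change differential-expression calls between two conditions.

    ``FC = 10^(mean log10 A - mean log10 B)``; a protein is differential
    when FC >= ``cutoff`` or FC <= 1/``cutoff``.  ``log_table`` columns are
    sample names (after imputation); at least two replicates per condition
    are required.
    """
    cols_a = [s for s in log_table.columns if condition_map.get(s) == condition_a]
    cols_b = [s for s in log_table.columns if condition_map.get(s) == condition_b]
    if not cols_a or not cols_b:
        unknown = condition_a if not cols_a else condition_b
        raise ValueError(f"condition {unknown!r} has no samples in the table")
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need >= 2 replicates per condition")
    mean_a = log_table[cols_a].mean(axis=1)
    mean_b = log_table[cols_b].mean(axis=1)
    fc = 10.0 ** (mean_a - mean_b)
    out = pd.DataFrame(
        {
            "mean_log10_a": mean_a,
            "mean_log10_b": mean_b,
            "fold_change": fc,
            "is_differential": (fc >= cutoff) | (fc <= 1.0 / cutoff),
        }
    )
    if protein_ids is not None:
        out.insert(0, "protein_id", list(protein_ids))
    return out.reset_index(drop=True)


def relative_ibaq(
    table: pd.DataFrame, sample_columns: Sequence[str]
) -> pd.DataFrame:
    """Each iBAQ divided by its sample's summed iBAQ (proteome fractions).

    Zeros/missing contribute nothing; each returned column sums to 1.
    """
    out = table[list(sample_columns)].astype(float).copy()
    out[out < 0] = np.nan
    totals = out.sum(axis=0, skipna=True)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"samples with no iBAQ signal: {bad}")
    return out / totals


@dataclass(frozen=True)
class ClassCorrelation:
    class_label: str
    pearson_r: float | None
    p_value: float | None
    n_samples: int


def class_growth_correlation(
    rel_ibaq: pd.DataFrame,
    class_map: Mapping[str, str],
    growth_rates: Mapping[str, float],
    protein_ids: Sequence[str],
) -> tuple[pd.DataFrame, list[ClassCorrelation]]:
    """Summed proteome fraction per class vs growth rate.

    ``rel_ibaq`` is the output of :func:`relative_ibaq` (samples as columns),
    ``class_map`` maps protein ids to class labels (subset coverage fine),
    ``growth_rates`` maps sample names to measured rates.  Returns the
    class x sample fraction profile and one Pearson correlation per class
    (``None`` with < 3 samples or a zero-variance profile).
    """
    samples = [s for s in rel_ibaq.columns if s in growth_rates]
    if not samples:
        raise ValueError("no overlap between rel_ibaq columns and growth_rates")
    ids = pd.Index(protein_ids)
    labels = pd.Series([class_map.get(p) for p in ids], index=rel_ibaq.index)
    grouped = rel_ibaq[samples].groupby(labels).sum()
    rates = np.array([growth_rates[s] for s in samples], dtype=float)

    correlations = []
    for cls in grouped.index:
        fractions = grouped.loc[cls].to_numpy(dtype=float)
        spread = np.ptp(fractions) > 1e-9 * (abs(fractions.mean()) + 1e-30)
        if len(samples) < 3 or not spread or np.ptp(rates) == 0:
            correlations.append(ClassCorrelation(cls, None, None, len(samples)))
            continue
        r, p = stats.pearsonr(fractions, rates)
        correlations.append(ClassCorrelation(cls, float(r), float(p), len(samples)))
    profile = grouped.reset_index().rename(columns={"index": "class"})
    profile = profile.rename(columns={profile.columns[0]: "class"})
    return profile, correlations
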