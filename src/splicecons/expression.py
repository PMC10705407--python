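"""Junction read support per intron conservation category.

Consumes a per-intron, per-tissue junction read-count table (one row per
donor-acceptor junction, one column per tissue), integrates tissues by the
maximum count, and summarises the max-coverage distribution per 4-way intron
conservation category.  Junction matching is exact on (contig, intron start,
intron end, strand); near-misses are never fuzzy-merged.

The on-disk table stores 1-based inclusive intron coordinates; they are
normalised to the internal 0-based half-open convention on load.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_KEY_COLUMNS = ["contig", "start", "end", "strand"]


def load_junction_table(path) -> pd.DataFrame:
    """Parse a junction coverage TSV.

    Expected columns: ``contig``, ``start``, ``end`` (1-based inclusive
    intron coordinates), ``strand``, then one integer column per tissue.
    Malformed rows are skipped with a warning count.  Adds ``max_coverage``
    (the per-row maximum over tissue columns) and converts coordinates to
    0-based half-open.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _KEY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"junction table lacks required columns: {missing}")
    tissue_cols = [c for c in df.columns if c not in _KEY_COLUMNS]
    if not tissue_cols:
        raise ValueError("junction table has no tissue columns")
    n_before = len(df)
    for col in tissue_cols + ["start", "end"]:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df = df.dropna(subset=tissue_cols + ["start", "end"])
    n_skipped = n_before - len(df)
    if n_skipped:
        logger.warning("skipped %d malformed junction rows", n_skipped)
    df = df.astype({c: int for c in tissue_cols + ["start", "end"]})
    df["start"] = df["start"] - 1  # 1-based inclusive -> 0-based half-open
    df["max_coverage"] = df[tissue_cols].max(axis=1)
    df.attrs["tissue_columns"] = tissue_cols
    return df.reset_index(drop=True)


def write_junction_table(df: pd.DataFrame, path, tissue_columns: list[str]) -> None:
    """Inverse of :func:`load_junction_table` (re-emits 1-based coordinates)."""
    out = df[_KEY_COLUMNS + tissue_columns].copy()
    out["start"] = out["start"] + 1
    out.to_csv(path, sep="\t", index=False)


def coverage_by_category(
    junctions: pd.DataFrame,
    categories: dict[tuple, int],
    gene_types: dict[tuple, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Box-plot style summaries of max coverage per intron category.

    ``categories`` maps intron keys ``(contig, start, end, strand)`` to their
    4-way category.  Returns (summary, unmatched) where the summary has
    median, IQR and +-1.5 IQR whisker bounds per category (and per gene type
    when provided) and ``unmatched`` holds junctions without a category.
    """
    keys = list(zip(junctions["contig"], junctions["start"], junctions["end"], junctions["strand"]))
    cat = pd.Series([categories.get(k) for k in keys], index=junctions.index, dtype="Int64")
    matched = junctions[cat.notna()].copy()
    matched["category"] = cat.dropna().astype(int)
    if gene_types is not None:
        matched["gene_type"] = [
            gene_types.get(k, "unknown")
            for k in np.array(keys, dtype=object)[cat.notna().to_numpy()]
        ]
        group_cols = ["gene_type", "category"]
    else:
        group_cols = ["category"]
    unmatched = junctions[cat.isna()].copy()
    rows = []
    for group, sub in matched.groupby(group_cols):
        values = sub["max_coverage"].to_numpy()
        q1, med, q3 = np.percentile(values, [25, 50, 75])
        iqr = q3 - q1
        in_whisker = values[(values >= q1 - 1.5 * iqr) & (values <= q3 + 1.5 * iqr)]
        row = dict(zip(group_cols, group if isinstance(group, tuple) else (group,)))
        row.update(
            {
                "n": len(values),
                "median": float(med),
                "q1": float(q1),
                "q3": float(q3),
                "iqr": float(iqr),
                "whisker_low": float(in_whisker.min()),
                "whisker_high": float(in_whisker.max()),
            }
        )
        rows.append(row)
    return pd.DataFrame(rows), unmatched
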