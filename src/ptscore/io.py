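"""TSV readers/writers for the pipeline's tabular formats.

On disk, segment files follow the SEG convention of 1-based inclusive
coordinates; in memory everything is 0-based half-open.  The readers
convert on load and the writers convert back, so a write/read round
trip is the identity.
"""

from __future__ import annotations

import pandas as pd

from .cna import SEGMENT_COLUMNS, validate_segments
from .variants import MAF_COLUMNS

__all__ = [
    "read_segments",
    "write_segments",
    "read_variants",
    "write_variants",
    "read_clinical",
]


def read_segments(path) -> pd.DataFrame:
    """Read a SEG-like TSV (1-based inclusive) into 0-based half-open form."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    df["start"] = df["start"].astype(int) - 1
    df["end"] = df["end"].astype(int)
    df["major_cn"] = df["major_cn"].astype(int)
    df["minor_cn"] = df["minor_cn"].astype(int)
    return validate_segments(df[SEGMENT_COLUMNS])


def write_segments(segments: pd.DataFrame, path) -> None:
    out = segments[SEGMENT_COLUMNS].copy()
    out["start"] = out["start"].astype(int) + 1  # back to 1-based inclusive
    out.to_csv(path, sep="\t", index=False)


def read_variants(path) -> pd.DataFrame:
    """Read a MAF-like TSV with the package's column dictionary."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(MAF_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")
    df["germline_pathogenic"] = (
        df["germline_pathogenic"].fillna(False).astype(bool)
    )
    df["in_cosmic"] = df["in_cosmic"].fillna(False).astype(bool)
    return df[MAF_COLUMNS]


def write_variants(variants: pd.DataFrame, path) -> None:
    variants[MAF_COLUMNS].to_csv(path, sep="\t", index=False)


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "sample" not in df.columns or "pt_sensitive" not in df.columns:
        raise ValueError("clinical table needs 'sample' and 'pt_sensitive' columns")
    return df
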