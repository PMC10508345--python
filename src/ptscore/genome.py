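"""Reduced genome model: chromosome arms, centromeres and gene anchors.

The package ships a desk-scale 22-autosome arm table with simplified
coordinates (arm lengths rounded to the nearest megabase, a uniform 3-Mb
centromere gap between the p and q arms).  Scar statistics and arm-level
loss calls only need arm boundaries, centromere extent and telomere
positions, so this reduced model supports the full feature pipeline
without any reference download.  Real centromere tables in the same
four-column TSV layout (chrom, arm, start, end) can be loaded with
:meth:`GenomeArms.from_tsv`.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd

__all__ = ["GenomeArms", "toy_genome", "toy_genes", "MB"]

MB = 1_000_000

_ARM_COLUMNS = ["chrom", "arm", "start", "end"]


class GenomeArms:
    """Arm table with chromosome bounds and centromere intervals.

    Parameters
    ----------
    arms : pandas.DataFrame
        Columns ``chrom`` (str), ``arm`` ("p" or "q"), ``start``, ``end``
        (0-based half-open base-pair coordinates).  Within a chromosome
        the p arm must precede the q arm and arms must be disjoint.
    """

    def __init__(self, arms: pd.DataFrame):
        missing = set(_ARM_COLUMNS) - set(arms.columns)
        if missing:
            raise ValueError(f"arm table missing columns: {sorted(missing)}")
        arms = arms[_ARM_COLUMNS].copy()
        arms["chrom"] = arms["chrom"].astype(str)
        if (arms["end"] <= arms["start"]).any():
            raise ValueError("zero- or negative-length arm in table")
        for chrom, grp in arms.groupby("chrom"):
            grp = grp.sort_values("start")
            if list(grp["arm"]) not in (["p", "q"], ["p"], ["q"]):
                raise ValueError(f"chromosome {chrom}: p arm must precede q arm")
            if (grp["start"].values[1:] < grp["end"].values[:-1]).any():
                raise ValueError(f"chromosome {chrom}: overlapping arms")
        self.arms = arms.sort_values(["chrom", "start"], key=_chrom_sort_key).reset_index(drop=True)
        # precomputed lookups (these are consulted once per segment group
        # in the scar scorers, so dict access matters)
        self._rows: dict[tuple[str, str], pd.Series] = {
            (row["chrom"], row["arm"]): row for _, row in self.arms.iterrows()
        }
        self._bounds: dict[str, tuple[int, int]] = {}
        self._cen: dict[str, tuple[int, int]] = {}
        for chrom, grp in self.arms.groupby("chrom"):
            grp = grp.sort_values("start")
            self._bounds[chrom] = (int(grp["start"].min()), int(grp["end"].max()))
            if len(grp) >= 2:
                self._cen[chrom] = (int(grp.iloc[0]["end"]), int(grp.iloc[1]["start"]))
            else:
                row = grp.iloc[0]
                pos = int(row["start"]) if row["arm"] == "q" else int(row["end"])
                self._cen[chrom] = (pos, pos)

    @classmethod
    def from_tsv(cls, path) -> "GenomeArms":
        return cls(pd.read_csv(path, sep="\t"))

    def arm_row(self, chrom: str, arm: str) -> pd.Series:
        try:
            return self._rows[(str(chrom), arm)]
        except KeyError:
            raise KeyError(f"no arm {chrom}{arm} in genome table") from None

    def arm_length(self, chrom: str, arm: str) -> int:
        row = self.arm_row(chrom, arm)
        return int(row["end"] - row["start"])

    def chrom_bounds(self, chrom: str) -> tuple[int, int]:
        """(start, end) of the modeled chromosome = union extent of its arms."""
        try:
            return self._bounds[str(chrom)]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom}") from None

    def centromere(self, chrom: str) -> tuple[int, int]:
        """Centromere interval = gap between the p and q arms.

        Single-arm chromosomes get a zero-width centromere at the arm
        edge facing the missing arm.
        """
        try:
            return self._cen[str(chrom)]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom}") from None

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.arms["chrom"]))

    def __iter__(self):
        return (row for _, row in self.arms.iterrows())

    def __len__(self) -> int:
        return len(self.arms)


def _chrom_sort_key(col: pd.Series) -> pd.Series:
    if col.name != "chrom":
        return col
    return col.map(lambda c: int(c) if str(c).isdigit() else 100)


@lru_cache(maxsize=1)
def toy_genome() -> GenomeArms:
    """The bundled reduced 22-autosome arm model."""
    with resources.files("ptscore.data").joinpath("toy_arms.tsv").open() as fh:
        return GenomeArms.from_tsv(fh)


@lru_cache(maxsize=1)
def toy_genes() -> pd.DataFrame:
    """Gene anchor points (gene, chrom, pos) on the toy genome.

    Positions are simplified single-point anchors used to place planted
    variants and to test variant/segment overlap; they are not real gene
    coordinates.
    """
    with resources.files("ptscore.data").joinpath("toy_genes.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"chrom": str})
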