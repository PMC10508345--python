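"""Allelic copy-number features: arm-level loss calls and genomic-scar scores.

Input segments are allele-specific copy-number intervals (one row per
constant-state interval) with integer major/minor allele copy numbers,
as produced by purity/ploidy callers such as ABSOLUTE.  Coordinates are
0-based half-open throughout this package; 1-based inclusive SEG input
is converted on read (see :mod:`ptscore.io`).

Three scar statistics are computed per sample:

* **LOH score** — number of loss-of-heterozygosity regions (minor copy
  number 0, total copy number > 0) longer than ``loh_min_mb`` after
  merging contiguous LOH segments, excluding regions spanning an entire
  chromosome.
* **TAI score** — number of allelic-imbalance regions (major != minor)
  that reach a telomere, do not cross the centromere, and exceed
  ``tai_min_mb``.
* **LST score** — number of copy-state breakpoints between adjacent
  segments each at least ``lst_flank_mb`` long and separated by less
  than ``lst_gap_mb``, computed per arm after smoothing away segments
  shorter than ``lst_smooth_mb`` (flanking segments of equal state are
  re-joined across the removed piece; pre-existing uncovered gaps are
  never bridged and count as gap distance).

The unweighted HRD score is the sum of the three counts.  Thresholds
follow the conventions of the allelic-imbalance scar literature and are
exposed as parameters so alternative dialects can be evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .genome import MB, GenomeArms, toy_genome

__all__ = [
    "SEGMENT_COLUMNS",
    "ARM_LOSS_CATEGORIES",
    "ScarParams",
    "arm_coverage",
    "classify_arm_loss",
    "arm_loss_calls",
    "score_loh",
    "score_tai",
    "score_lst",
    "scar_scores",
    "hrd_sum",
]

SEGMENT_COLUMNS = ["sample", "chrom", "start", "end", "major_cn", "minor_cn"]

# (category name, predicate over (major, minor) arrays); evaluated in listed order
ARM_LOSS_CATEGORIES = [
    ("homozygous_loss", lambda maj, mnr: (maj == 0) & (mnr == 0)),
    ("loh", lambda maj, mnr: (maj == 1) & (mnr == 0)),
    ("cnloh", lambda maj, mnr: (maj == 2) & (mnr == 0)),
    ("loh_high_ploidy", lambda maj, mnr: (maj > 2) & (mnr == 0)),
]


@dataclass(frozen=True)
class ScarParams:
    """Size thresholds (megabases) for the three scar statistics."""

    loh_min_mb: float = 15.0
    tai_min_mb: float = 11.0
    lst_smooth_mb: float = 3.0
    lst_flank_mb: float = 10.0
    lst_gap_mb: float = 3.0


def validate_segments(segments: pd.DataFrame) -> pd.DataFrame:
    missing = set(SEGMENT_COLUMNS) - set(segments.columns)
    if missing:
        raise ValueError(f"segment table missing columns: {sorted(missing)}")
    if len(segments):
        if (segments["end"] <= segments["start"]).any():
            raise ValueError("segment with end <= start")
        if (segments["minor_cn"] > segments["major_cn"]).any():
            raise ValueError("segment with minor_cn > major_cn")
        if (segments[["major_cn", "minor_cn"]] < 0).any().any():
            raise ValueError("negative copy number")
    return segments


def _chrom_arrays(segments: pd.DataFrame) -> dict[str, tuple[np.ndarray, ...]]:
    """Per-chromosome (start, end, major, minor) arrays sorted by start."""
    out: dict[str, tuple[np.ndarray, ...]] = {}
    if not len(segments):
        return out
    chroms = segments["chrom"].astype(str).to_numpy()
    start = segments["start"].to_numpy(dtype=np.int64)
    end = segments["end"].to_numpy(dtype=np.int64)
    maj = segments["major_cn"].to_numpy(dtype=np.int64)
    mnr = segments["minor_cn"].to_numpy(dtype=np.int64)
    for chrom in np.unique(chroms):
        sel = chroms == chrom
        order = np.argsort(start[sel], kind="stable")
        out[chrom] = (start[sel][order], end[sel][order], maj[sel][order], mnr[sel][order])
    return out


def _union_length(starts: np.ndarray, ends: np.ndarray) -> int:
    if len(starts) == 0:
        return 0
    order = np.argsort(starts)
    total = 0
    cur_s = cur_e = None
    for s, e in zip(starts[order], ends[order]):
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    total += cur_e - cur_s
    return int(total)


def _coverage_arrays(
    arrs: tuple[np.ndarray, ...] | None,
    arm_start: int,
    arm_end: int,
    pred: Callable[[np.ndarray, np.ndarray], np.ndarray],
) -> float:
    arm_len = arm_end - arm_start
    if arm_len <= 0:
        raise ValueError("zero-length arm")
    if arrs is None:
        return 0.0
    start, end, maj, mnr = arrs
    keep = np.asarray(pred(maj, mnr), dtype=bool)
    s = np.maximum(start[keep], arm_start)
    e = np.minimum(end[keep], arm_end)
    ok = s < e
    return _union_length(s[ok], e[ok]) / arm_len


def arm_coverage(
    segments: pd.DataFrame,
    arm: pd.Series,
    predicate: Callable[[np.ndarray, np.ndarray], np.ndarray],
) -> float:
    """Fraction of an arm covered by segments satisfying ``predicate``.

    The fraction is the length of the union of (segment ∩ arm) over
    predicate-satisfying segments, divided by arm length.  Overlapping
    segments are unioned, not double-counted.
    """
    arrs = _chrom_arrays(segments).get(str(arm["chrom"]))
    return _coverage_arrays(arrs, int(arm["start"]), int(arm["end"]), predicate)


def classify_arm_loss(
    segments: pd.DataFrame, arm: pd.Series, min_coverage: float = 0.9
) -> dict | None:
    """Call arm-level copy-number loss for one sample on one arm.

    The four loss categories (homozygous loss; classic LOH 1/0;
    copy-neutral LOH 2/0; LOH at high ploidy, major > 2 with minor 0)
    are evaluated in listed order and the first whose coverage of the
    arm reaches ``min_coverage`` is emitted; ``None`` when no category
    qualifies.
    """
    arrs = _chrom_arrays(segments).get(str(arm["chrom"]))
    return _classify_arm_arrays(
        arrs, str(arm["chrom"]), arm["arm"], int(arm["start"]), int(arm["end"]), min_coverage
    )


def _classify_arm_arrays(
    arrs, chrom: str, arm_label: str, start: int, end: int, min_coverage: float
) -> dict | None:
    for category, pred in ARM_LOSS_CATEGORIES:
        frac = _coverage_arrays(arrs, start, end, pred)
        if frac >= min_coverage:
            return {
                "arm": f"{chrom}{arm_label}",
                "category": category,
                "covered_fraction": frac,
            }
    return None


def arm_loss_calls(
    segments: pd.DataFrame,
    arms: GenomeArms | None = None,
    min_coverage: float = 0.9,
) -> pd.DataFrame:
    """Arm-loss calls for every sample × arm; long-format table."""
    arms = arms or toy_genome()
    validate_segments(segments)
    arm_rows = [
        (str(a.chrom), a.arm, int(a.start), int(a.end))
        for a in arms.arms.itertuples(index=False)
    ]
    records = []
    for sample, seg in segments.groupby("sample", sort=True):
        arrs_by_chrom = _chrom_arrays(seg)
        for chrom, arm_label, start, end in arm_rows:
            call = _classify_arm_arrays(
                arrs_by_chrom.get(chrom), chrom, arm_label, start, end, min_coverage
            )
            if call is not None:
                records.append({"sample": sample, **call})
    return pd.DataFrame(records, columns=["sample", "arm", "category", "covered_fraction"])


# ---------------------------------------------------------------------------
# scar scores


def _predicate_regions(arrs, pred) -> list[tuple[int, int]]:
    """Maximal runs of contiguous predicate-true segments (one chromosome).

    Segments must be non-overlapping; uncovered gaps break runs (the
    gap state is unknown).
    """
    start, end, maj, mnr = arrs
    ok = np.asarray(pred(maj, mnr), dtype=bool)
    regions = []
    run_s = run_e = None
    for i in range(len(start)):
        if ok[i] and run_e is not None and start[i] == run_e:
            run_e = end[i]
        elif ok[i]:
            if run_e is not None:
                regions.append((run_s, run_e))
            run_s, run_e = start[i], end[i]
        else:
            if run_e is not None:
                regions.append((run_s, run_e))
            run_s = run_e = None
    if run_e is not None:
        regions.append((run_s, run_e))
    return [(int(s), int(e)) for s, e in regions]


def score_loh(
    segments: pd.DataFrame,
    arms: GenomeArms | None = None,
    min_mb: float = 15.0,
) -> int:
    """LOH scar count for one sample's segments."""
    return _score_loh_arrays(_chrom_arrays(segments), arms or toy_genome(), min_mb)


def _score_loh_arrays(arrs_by_chrom, arms: GenomeArms, min_mb: float) -> int:
    count = 0
    for chrom, arrs in arrs_by_chrom.items():
        cs, ce = arms.chrom_bounds(chrom)
        for s, e in _predicate_regions(arrs, lambda maj, mnr: (mnr == 0) & (maj > 0)):
            if e - s <= min_mb * MB:
                continue
            if s <= cs and e >= ce:  # whole-chromosome LOH is excluded
                continue
            count += 1
    return count


def score_tai(
    segments: pd.DataFrame,
    arms: GenomeArms | None = None,
    min_mb: float = 11.0,
) -> int:
    """Telomeric allelic-imbalance count for one sample's segments."""
    return _score_tai_arrays(_chrom_arrays(segments), arms or toy_genome(), min_mb)


def _score_tai_arrays(arrs_by_chrom, arms: GenomeArms, min_mb: float) -> int:
    count = 0
    for chrom, arrs in arrs_by_chrom.items():
        cs, ce = arms.chrom_bounds(chrom)
        cen_s, cen_e = arms.centromere(chrom)
        for s, e in _predicate_regions(arrs, lambda maj, mnr: maj != mnr):
            if e - s <= min_mb * MB:
                continue
            reaches_telomere = s <= cs or e >= ce
            crosses_centromere = s < cen_s and e > cen_e
            if reaches_telomere and not crosses_centromere:
                count += 1
    return count


def _merge_abutting(pieces: list[list]) -> list[list]:
    out: list[list] = []
    for p in pieces:
        if out and out[-1][2:] == p[2:] and out[-1][1] == p[0]:
            out[-1][1] = p[1]
        else:
            out.append(list(p))
    return out


def _smooth_arm_pieces(pieces: list[list], smooth_bp: float) -> list[list]:
    """Iteratively drop sub-threshold pieces, re-joining equal-state flanks.

    ``pieces`` are [start, end, major, minor] sorted by start.  When the
    removed piece abutted both neighbours and they share a copy state,
    the neighbours are merged across the removed span; pre-existing
    uncovered gaps are never bridged.  Smallest piece first; ties to
    the leftmost.
    """
    pieces = _merge_abutting(pieces)
    while True:
        short = [(p[1] - p[0], i) for i, p in enumerate(pieces) if p[1] - p[0] < smooth_bp]
        if not short:
            return pieces
        _, i = min(short)
        removed = pieces.pop(i)
        if 0 < i <= len(pieces) - 1:
            left, right = pieces[i - 1], pieces[i]
            if left[2:] == right[2:] and left[1] == removed[0] and removed[1] == right[0]:
                left[1] = right[1]
                pieces.pop(i)


def score_lst(
    segments: pd.DataFrame,
    arms: GenomeArms | None = None,
    smooth_mb: float = 3.0,
    flank_mb: float = 10.0,
    gap_mb: float = 3.0,
) -> int:
    """Large-scale transition count for one sample's segments."""
    return _score_lst_arrays(
        _chrom_arrays(segments), arms or toy_genome(), smooth_mb, flank_mb, gap_mb
    )


def _score_lst_arrays(
    arrs_by_chrom, arms: GenomeArms, smooth_mb: float, flank_mb: float, gap_mb: float
) -> int:
    count = 0
    for arm in arms.arms.itertuples(index=False):
        arrs = arrs_by_chrom.get(str(arm.chrom))
        if arrs is None:
            continue
        start, end, maj, mnr = arrs
        s = np.maximum(start, int(arm.start))
        e = np.minimum(end, int(arm.end))
        ok = s < e
        pieces = [
            [int(a), int(b), int(m1), int(m2)]
            for a, b, m1, m2 in zip(s[ok], e[ok], maj[ok], mnr[ok])
        ]
        if len(pieces) < 2:
            continue
        pieces = _smooth_arm_pieces(pieces, smooth_mb * MB)
        for left, right in zip(pieces, pieces[1:]):
            if left[2:] == right[2:]:
                continue
            if (
                left[1] - left[0] >= flank_mb * MB
                and right[1] - right[0] >= flank_mb * MB
                and right[0] - left[1] < gap_mb * MB
            ):
                count += 1
    return count


def scar_scores(
    segments: pd.DataFrame,
    arms: GenomeArms | None = None,
    params: ScarParams = ScarParams(),
    samples: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-sample LOH/TAI/LST counts and the unweighted HRD score.

    Parameters
    ----------
    samples
        Optional full sample list; samples without segments get zeros.
    """
    arms = arms or toy_genome()
    validate_segments(segments)
    rows = {}
    for sample, seg in segments.groupby("sample", sort=True):
        arrs = _chrom_arrays(seg)
        rows[sample] = {
            "n_loh": _score_loh_arrays(arrs, arms, params.loh_min_mb),
            "n_tai": _score_tai_arrays(arrs, arms, params.tai_min_mb),
            "n_lst": _score_lst_arrays(
                arrs, arms, params.lst_smooth_mb, params.lst_flank_mb, params.lst_gap_mb
            ),
        }
    if samples is not None:
        for s in samples:
            rows.setdefault(s, {"n_loh": 0, "n_tai": 0, "n_lst": 0})
    if not rows:
        out = pd.DataFrame(columns=["n_loh", "n_tai", "n_lst", "hrd_score"], dtype=int)
        out.index.name = "sample"
        return out
    out = pd.DataFrame.from_dict(rows, orient="index").astype(int)
    out.index.name = "sample"
    out["hrd_score"] = out["n_loh"] + out["n_tai"] + out["n_lst"]
    return out.sort_index()


def hrd_sum(scores: pd.DataFrame | pd.Series) -> pd.Series | int:
    """Unweighted HRD score: n_loh + n_tai + n_lst."""
    if isinstance(scores, pd.Series):
        return int(scores["n_loh"] + scores["n_tai"] + scores["n_lst"])
    return scores["n_loh"] + scores["n_tai"] + scores["n_lst"]
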