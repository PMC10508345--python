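"""SBS-96 / ID-83 mutation catalogs and non-negative signature refitting.

Catalogs count somatic SNVs by pyrimidine-centred trinucleotide channel
(96 channels) and indels by the standard 83-channel indel taxonomy.
Exposures are fitted per sample by non-negative least squares against a
reference signature matrix (columns sum to one), i.e. the linear
combination decomposition used by refitting tools such as YAPSA, with
no sparsity penalty or signature pre-selection.

The bundled reference profiles under ``ptscore/data`` are *synthetic*
stand-ins with the canonical channel layout and labels (SBS1/3/5/39,
ID1/2/6/8); real COSMIC-format TSVs load through the same
:class:`SignatureSet` interface.

Cohort-level retention keeps a signature when its pooled absolute
exposure accounts for strictly more than ``min_share`` (default 1%) of
all attributed mutations.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd
from scipy.optimize import nnls

__all__ = [
    "SBS96_CHANNELS",
    "ID83_CHANNELS",
    "SignatureSet",
    "normalize_snv_context",
    "build_sbs_catalog",
    "build_indel_catalog",
    "fit_exposures",
    "retain_signatures",
    "synthetic_sbs_reference",
    "synthetic_id_reference",
]

_SUBS = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
_BASES = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")

#: canonical 96-channel order: substitution-major, then 5' and 3' context
SBS96_CHANNELS = [
    f"{five}[{sub}]{three}" for sub in _SUBS for five in _BASES for three in _BASES
]


def _id83_channels() -> list[str]:
    ch = []
    for alt in ("Del", "Ins"):
        for base in ("C", "T"):
            ch += [f"1:{alt}:{base}:{k}" for k in range(6)]
    for alt in ("Del", "Ins"):
        for size in range(2, 6):
            ch += [f"{size}:{alt}:R:{k}" for k in range(6)]
    for size, max_mh in ((2, 1), (3, 2), (4, 3), (5, 5)):
        ch += [f"{size}:Del:M:{k}" for k in range(1, max_mh + 1)]
    assert len(ch) == 83
    return ch


#: canonical 83-channel indel taxonomy order
ID83_CHANNELS = _id83_channels()


class SignatureSet:
    """Reference signature matrix (channels × signatures).

    Columns must be L1-normalised (sum to 1 within 1e-6).
    """

    def __init__(self, matrix: pd.DataFrame):
        arr = matrix.to_numpy(dtype=float)
        if (arr < 0).any():
            raise ValueError("negative entries in signature matrix")
        sums = arr.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            bad = matrix.columns[np.abs(sums - 1.0) > 1e-6]
            raise ValueError(f"signature columns do not sum to 1: {list(bad)}")
        self.matrix = matrix.copy()

    @property
    def channels(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def labels(self) -> list[str]:
        return list(self.matrix.columns)

    @classmethod
    def from_tsv(cls, path) -> "SignatureSet":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path) -> None:
        self.matrix.to_csv(path, sep="\t")


def normalize_snv_context(context: str) -> str:
    """Canonicalise a trinucleotide context string to the pyrimidine strand.

    ``"A[G>T]C"`` (purine reference) becomes ``"G[C>A]T"``.  Raises
    ``ValueError`` for malformed strings.
    """
    c = str(context).strip().upper()
    if len(c) != 7 or c[1] != "[" or c[3] != ">" or c[5] != "]":
        raise ValueError(f"malformed SNV context {context!r}")
    five, ref, alt, three = c[0], c[2], c[4], c[6]
    if any(b not in _BASES for b in (five, ref, alt, three)) or ref == alt:
        raise ValueError(f"malformed SNV context {context!r}")
    if ref in "AG":  # purine-centred: reverse complement the whole context
        five, ref, alt, three = (
            three.translate(_COMP),
            ref.translate(_COMP),
            alt.translate(_COMP),
            five.translate(_COMP),
        )
    channel = f"{five}[{ref}>{alt}]{three}"
    if channel not in _SBS_INDEX:
        raise ValueError(f"context {context!r} maps to unknown channel {channel}")
    return channel


_SBS_INDEX = {c: i for i, c in enumerate(SBS96_CHANNELS)}
_ID_INDEX = {c: i for i, c in enumerate(ID83_CHANNELS)}


def _build_catalog(
    labels: pd.Series,
    samples: pd.Series,
    channel_index: dict[str, int],
    channels: list[str],
    normalizer=None,
) -> tuple[pd.DataFrame, int]:
    counts: dict[str, np.ndarray] = {}
    skipped = 0
    for sample, label in zip(samples, labels):
        try:
            key = normalizer(label) if normalizer else str(label)
            idx = channel_index[key]
        except (ValueError, KeyError):
            skipped += 1
            continue
        vec = counts.setdefault(sample, np.zeros(len(channels), dtype=int))
        vec[idx] += 1
    cat = pd.DataFrame(counts, index=channels).astype(int)
    cat.index.name = "channel"
    return cat, skipped


def build_sbs_catalog(
    snvs: pd.DataFrame, samples=None
) -> tuple[pd.DataFrame, int]:
    """96-channel catalog (channels × samples) from somatic SNV records.

    Purine-centred contexts are reverse-complemented before binning.
    Returns ``(catalog, n_skipped)`` where skipped records had malformed
    context strings.  ``samples`` optionally forces the column set (with
    zero columns for sample ids that contributed no SNV).
    """
    if len(snvs):
        cat, skipped = _build_catalog(
            snvs["snv_context"], snvs["sample"], _SBS_INDEX, SBS96_CHANNELS,
            normalizer=normalize_snv_context,
        )
    else:
        cat, skipped = pd.DataFrame(index=pd.Index(SBS96_CHANNELS, name="channel")), 0
    if samples is not None:
        cat = cat.reindex(columns=sorted(set(samples)), fill_value=0).astype(int)
    return cat, skipped


def build_indel_catalog(
    indels: pd.DataFrame, samples=None
) -> tuple[pd.DataFrame, int]:
    """83-channel catalog from indel records carrying an ``indel_class``."""
    if len(indels):
        cat, skipped = _build_catalog(
            indels["indel_class"], indels["sample"], _ID_INDEX, ID83_CHANNELS
        )
    else:
        cat, skipped = pd.DataFrame(index=pd.Index(ID83_CHANNELS, name="channel")), 0
    if samples is not None:
        cat = cat.reindex(columns=sorted(set(samples)), fill_value=0).astype(int)
    return cat, skipped


def fit_exposures(catalog: pd.DataFrame, reference: SignatureSet) -> pd.DataFrame:
    """Per-sample non-negative least-squares signature exposures.

    Solves ``min ||catalog_s - R e||_2`` s.t. ``e >= 0`` for each sample
    column, where R is the reference matrix.  Returns a tidy frame
    indexed by sample with one ``<label>_abs`` and one ``<label>_rel``
    column per signature; relative exposures are the absolute vector
    normalised to sum 1 (zero when nothing is attributed).
    """
    if list(catalog.index) != reference.channels:
        raise ValueError("catalog channels do not match reference channels")
    R = reference.matrix.to_numpy(dtype=float)
    rows = {}
    for sample in catalog.columns:
        y = catalog[sample].to_numpy(dtype=float)
        e, _ = nnls(R, y)
        total = e.sum()
        rel = e / total if total > 0 else np.zeros_like(e)
        rows[sample] = np.concatenate([e, rel])
    cols = [f"{s}_abs" for s in reference.labels] + [f"{s}_rel" for s in reference.labels]
    out = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    out.index.name = "sample"
    return out.sort_index()


def retain_signatures(
    exposures: pd.DataFrame,
    labels: list[str] | None = None,
    min_share: float = 0.01,
    per_sample: bool = False,
) -> list[str]:
    """Signatures whose contribution exceeds ``min_share`` (strict).

    Default mode pools absolute exposures over the cohort: signature s is
    kept iff sum_samples(abs_s) / total attributed > min_share.  With
    ``per_sample=True`` a signature is kept when it exceeds the share in
    at least one sample.  Returns an empty list when nothing is
    attributed.
    """
    if labels is None:
        labels = [c[:-4] for c in exposures.columns if c.endswith("_abs")]
    abs_cols = exposures[[f"{s}_abs" for s in labels]]
    if per_sample:
        totals = abs_cols.sum(axis=1)
        ok = totals > 0
        if not ok.any():
            return []
        shares = abs_cols[ok].div(totals[ok], axis=0)
        keep = (shares > min_share).any(axis=0)
    else:
        pooled = abs_cols.sum(axis=0)
        total = pooled.sum()
        if total <= 0:
            return []
        keep = pooled / total > min_share
    return [s for s, k in zip(labels, keep) if k]


@lru_cache(maxsize=1)
def synthetic_sbs_reference() -> SignatureSet:
    """Bundled synthetic 96-channel reference (labels SBS1, SBS3, SBS5, SBS39)."""
    with resources.files("ptscore.data").joinpath("sbs96_reference_synthetic.tsv").open() as fh:
        return SignatureSet.from_tsv(fh)


@lru_cache(maxsize=1)
def synthetic_id_reference() -> SignatureSet:
    """Bundled synthetic 83-channel indel reference (labels ID1, ID2, ID6, ID8)."""
    with resources.files("ptscore.data").joinpath("id83_reference_synthetic.tsv").open() as fh:
        return SignatureSet.from_tsv(fh)
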