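"""Per-fragment 4C signal: normalization, smoothing, contact-frequency ratios.

A 4C experiment profiles the contacts of one restriction fragment (the
viewpoint) with the rest of the locus.  Raw per-fragment read counts are

* combined across replicate libraries by summation,
* normalized to reads per million (RPM) and smoothed with a centred running
  mean over seven fragments for track visualisation,
* summarised as contact-frequency ratios: reads in a region divided by reads
  in the whole locus, excluding the viewpoint fragment plus a 10 kb flank on
  each side where self-ligation and undigested artifacts dominate.

Ratios are always computed on raw counts — smoothing would leak signal
across interval boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataValidationError, NumericError
from .fragmap import FragmentMap, GenomicInterval

DEFAULT_EXCLUSION_FLANK = 10_000
DEFAULT_SMOOTH_WINDOW = 7


@dataclass(frozen=True)
class Viewpoint:
    """The fragment whose contacts an experiment profiles."""

    name: str
    fragment_index: int
    position: GenomicInterval
    exclusion_flank: int = DEFAULT_EXCLUSION_FLANK

    def __post_init__(self) -> None:
        if self.exclusion_flank < 0:
            raise DataValidationError("exclusion_flank must be >= 0")

    @property
    def exclusion_zone(self) -> GenomicInterval:
        """Viewpoint fragment extended by the exclusion flank on each side."""
        return GenomicInterval(
            self.position.chrom,
            max(0, self.position.start - self.exclusion_flank),
            self.position.end + self.exclusion_flank,
        )

    @classmethod
    def at(
        cls,
        fmap: FragmentMap,
        pos: int,
        name: str = "VP",
        exclusion_flank: int = DEFAULT_EXCLUSION_FLANK,
    ) -> "Viewpoint":
        """Viewpoint on the fragment containing genomic position ``pos``."""
        idx = fmap.locate(pos)
        return cls(name, idx, fmap.fragments[idx].interval, exclusion_flank)


@dataclass(frozen=True)
class FragmentCounts:
    """Raw 4C read counts per fragment for one viewpoint-sample."""

    fragment_map: FragmentMap
    viewpoint: Viewpoint
    sample: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 1 or len(counts) != len(self.fragment_map):
            raise DataValidationError(
                f"sample {self.sample!r}: counts length {counts.shape} does not "
                f"match fragment map ({len(self.fragment_map)} fragments)"
            )
        if (counts < 0).any():
            raise DataValidationError(f"sample {self.sample!r}: negative counts")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class FragmentProfile:
    """RPM-normalized and smoothed signal derived from raw counts."""

    base: FragmentCounts
    rpm: np.ndarray
    smoothed: np.ndarray
    window_w: int

    @classmethod
    def from_counts(
        cls, base: FragmentCounts, w: int = DEFAULT_SMOOTH_WINDOW, stat: str = "mean"
    ) -> "FragmentProfile":
        rpm = normalize_rpm(base)
        return cls(base, rpm, smooth_profile(rpm, w, stat=stat), w)


@dataclass(frozen=True)
class ContactFrequency:
    """Viewpoint-excluded read-ratio of an interval within the locus."""

    interval: GenomicInterval
    ratio: float
    numerator_reads: int
    denominator_reads: int
    excluded: GenomicInterval


def combine_replicates(replicates: Sequence[FragmentCounts]) -> FragmentCounts:
    """Element-wise sum of replicate counts from the same viewpoint."""
    if not replicates:
        raise DataValidationError("no replicates given")
    first = replicates[0]
    for rep in replicates[1:]:
        if (
            rep.fragment_map.locus != first.fragment_map.locus
            or len(rep.fragment_map) != len(first.fragment_map)
        ):
            raise DataValidationError(
                f"replicate {rep.sample!r} uses a different fragment map"
            )
        if rep.viewpoint.fragment_index != first.viewpoint.fragment_index:
            raise DataValidationError(
                f"replicate {rep.sample!r} uses a different viewpoint"
            )
    combined = np.sum([rep.counts for rep in replicates], axis=0)
    return FragmentCounts(
        first.fragment_map,
        first.viewpoint,
        "+".join(rep.sample for rep in replicates),
        combined,
    )


def normalize_rpm(c: FragmentCounts | np.ndarray) -> np.ndarray:
    """Reads per million: counts * 1e6 / total."""
    counts = c.counts if isinstance(c, FragmentCounts) else np.asarray(c)
    total = counts.sum()
    if total <= 0:
        raise NumericError("empty profile: total read count is zero")
    return counts * (1e6 / total)


def smooth_profile(values: np.ndarray, w: int = DEFAULT_SMOOTH_WINDOW, stat: str = "mean") -> np.ndarray:
    """Centred running mean (or median) over a window of ``w`` fragments.

    Near the edges the window is truncated to the available fragments —
    zero-padding would fabricate signal decay at the locus boundaries.
    """
    if w < 1 or w % 2 == 0:
        raise DataValidationError(f"window must be odd and >= 1, got {w}")
    if stat not in ("mean", "median"):
        raise DataValidationError(f"unknown smoothing stat {stat!r}")
    x = np.asarray(values, dtype=float)
    if stat == "median":
        roll = pd.Series(x).rolling(window=w, center=True, min_periods=1)
        return roll.median().to_numpy()
    # direct convolution: each window summed independently (no running-sum
    # roundoff), divided by the truncated window size at the edges
    kernel = np.ones(w)
    half = w // 2
    sums = np.convolve(x, kernel, mode="full")[half : half + len(x)]
    sizes = np.convolve(np.ones_like(x), kernel, mode="full")[half : half + len(x)]
    return sums / sizes


def excluded_fragment_mask(c: FragmentCounts) -> np.ndarray:
    """Fragments whose midpoint lies in the viewpoint exclusion zone."""
    mids = c.fragment_map.midpoints
    zone = c.viewpoint.exclusion_zone
    return (mids >= zone.start) & (mids < zone.end)


def contact_frequency(
    c: FragmentCounts,
    interval: GenomicInterval,
    locus: GenomicInterval | None = None,
) -> ContactFrequency:
    """Read ratio of ``interval`` within ``locus``, viewpoint excluded.

    Fragment membership is by midpoint; fragments whose midpoint falls in the
    exclusion zone are removed from numerator and denominator alike, so
    ratios of disjoint intervals add exactly.
    """
    locus = locus or c.fragment_map.locus
    if not locus.contains_interval(interval):
        raise DataValidationError(f"interval {interval} not within locus {locus}")
    mids = c.fragment_map.midpoints
    excluded = excluded_fragment_mask(c)
    keep = (~excluded) & (mids >= locus.start) & (mids < locus.end)
    denominator = int(c.counts[keep].sum())
    if denominator == 0:
        raise NumericError(
            f"no informative reads for sample {c.sample!r} in locus {locus}"
        )
    in_interval = keep & (mids >= interval.start) & (mids < interval.end)
    numerator = int(c.counts[in_interval].sum())
    return ContactFrequency(
        interval,
        numerator / denominator,
        numerator,
        denominator,
        c.viewpoint.exclusion_zone,
    )


# ---------------------------------------------------------------------------
# Track and table I/O


def write_bedgraph(
    values: np.ndarray,
    fmap: FragmentMap,
    path: str | Path,
    header: Sequence[str] = (),
) -> None:
    """One BedGraph line per fragment (0-based half-open coordinates)."""
    values = np.asarray(values, dtype=float)
    if len(values) != len(fmap):
        raise DataValidationError("values length does not match fragment map")
    if not np.isfinite(values).all():
        raise DataValidationError("non-finite values cannot be written to BedGraph")
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"#{line}\n")
        for frag, val in zip(fmap.fragments, values):
            iv = frag.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{float(val)!r}\n")


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    """Read a BedGraph into a DataFrame (chrom, start, end, value)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start, end, value = line.split()[:4]
            rows.append((chrom, int(start), int(end), float(value)))
    if not rows:
        raise DataValidationError(f"no data lines in BedGraph {path}")
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def write_counts_table(c: FragmentCounts, path: str | Path, header: Sequence[str] = ()) -> None:
    """Write counts as 4-column TSV (chrom, start, end, count)."""
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"#{line}\n")
        fh.write("chrom\tstart\tend\tcount\n")
        for frag, n in zip(c.fragment_map.fragments, c.counts):
            iv = frag.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{int(n)}\n")


def read_counts_table(
    path: str | Path,
    fmap: FragmentMap,
    viewpoint: Viewpoint,
    sample: str | None = None,
) -> FragmentCounts:
    """Read a 4-column TSV of per-fragment counts, validated against the map."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"chrom", "start", "end", "count"}
    if not required.issubset(df.columns):
        raise DataValidationError(
            f"{path}: expected columns {sorted(required)}, got {list(df.columns)}"
        )
    if len(df) != len(fmap):
        raise DataValidationError(
            f"{path}: {len(df)} rows but fragment map has {len(fmap)} fragments"
        )
    if not (
        (df["start"].to_numpy() == fmap.starts).all()
        and (df["end"].to_numpy() == fmap.ends).all()
    ):
        raise DataValidationError(f"{path}: fragment coordinates do not match map")
    name = sample if sample is not None else Path(path).stem
    return FragmentCounts(fmap, viewpoint, name, df["count"].to_numpy())
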