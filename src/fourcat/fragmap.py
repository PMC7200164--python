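"""Restriction-fragment maps and fixed-width bin grids.

4C-seq resolves chromatin contacts at the level of restriction fragments:
the genomic intervals between consecutive recognition sites of the primary
enzyme (here NlaIII, motif CATG, with DpnII/GATC as the secondary cutter).
This module builds the fragment map of a locus from its sequence by in
silico digestion, tiles regions into fixed-width bins (30 kb or 10 kb in
typical analyses), and assigns fragments to bins by their midpoints.

Conventions, applied throughout the package:

* coordinates are 0-based, half-open;
* a cut is placed at the start offset of each motif occurrence, so fragments
  end immediately before a CATG.  All downstream statistics are invariant to
  this constant <=4 bp choice;
* N bases never match a motif (conservative for masked sequence);
* a trailing partial bin is retained so bins always tile the whole region.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import DataValidationError

_VALID_MOTIF = re.compile(r"^[ACGT]+$")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise DataValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def contains(self, pos: int) -> bool:
        """Whether a point position lies inside the half-open interval."""
        return self.start <= pos < self.end

    def contains_interval(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def shifted(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, self.start + offset, self.end + offset)

    @classmethod
    def from_string(cls, text: str) -> "GenomicInterval":
        """Parse a ``chrom:start-end`` region string (commas tolerated)."""
        try:
            chrom, span = text.rsplit(":", 1)
            lo, hi = span.replace(",", "").split("-")
            return cls(chrom, int(lo), int(hi))
        except (ValueError, TypeError) as exc:
            raise DataValidationError(f"cannot parse region string {text!r}") from exc

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class RestrictionFragment:
    """One fragment of a digested locus.

    ``has_second_site`` records whether the fragment contains at least one
    occurrence of the secondary cutter; fragments without one ("blind"
    fragments) cannot re-ligate in the second digestion round and can be
    filtered downstream if desired.
    """

    interval: GenomicInterval
    index: int
    has_second_site: bool


@dataclass(frozen=True)
class FragmentMap:
    """Ordered restriction fragments tiling a locus.

    The coordinate backbone for all counting: every per-fragment signal
    vector in the package is indexed identically to ``fragments``.
    """

    locus: GenomicInterval
    first_cutter: str
    second_cutter: str
    fragments: tuple[RestrictionFragment, ...]

    def __post_init__(self) -> None:
        pos = self.locus.start
        for i, frag in enumerate(self.fragments):
            if frag.index != i or frag.interval.start != pos:
                raise DataValidationError(
                    f"fragments do not tile the locus at index {i}"
                )
            pos = frag.interval.end
        if pos != self.locus.end:
            raise DataValidationError("fragments do not reach the locus end")

    def __len__(self) -> int:
        return len(self.fragments)

    @property
    def midpoints(self) -> np.ndarray:
        """Integer midpoint of every fragment, in locus coordinates."""
        return np.array([f.interval.midpoint for f in self.fragments], dtype=np.int64)

    @property
    def starts(self) -> np.ndarray:
        return np.array([f.interval.start for f in self.fragments], dtype=np.int64)

    @property
    def ends(self) -> np.ndarray:
        return np.array([f.interval.end for f in self.fragments], dtype=np.int64)

    def locate(self, pos: int) -> int:
        """Index of the fragment containing a position."""
        if not self.locus.contains(pos):
            raise DataValidationError(f"position {pos} outside locus {self.locus}")
        idx = int(np.searchsorted(self.starts, pos, side="right") - 1)
        return idx

    def to_bed(self, path: str | Path, header: Sequence[str] = ()) -> None:
        """Write the map as BED: name = fragment index, score = has_second_site."""
        with open(path, "w") as fh:
            for line in header:
                fh.write(f"#{line}\n")
            for frag in self.fragments:
                iv = frag.interval
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{frag.index}\t"
                    f"{int(frag.has_second_site)}\n"
                )

    @classmethod
    def from_bed(
        cls, path: str | Path, first_cutter: str = "CATG", second_cutter: str = "GATC"
    ) -> "FragmentMap":
        """Rebuild a map from the BED produced by :meth:`to_bed`.

        Cutter motifs are not stored in BED; pass them explicitly (defaults
        match the NlaIII/DpnII protocol).
        """
        fragments: list[RestrictionFragment] = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                chrom, start, end, name, score = line.split()[:5]
                fragments.append(
                    RestrictionFragment(
                        GenomicInterval(chrom, int(start), int(end)),
                        int(name),
                        bool(int(score)),
                    )
                )
        if not fragments:
            raise DataValidationError(f"no fragments found in {path}")
        locus = GenomicInterval(
            fragments[0].interval.chrom,
            fragments[0].interval.start,
            fragments[-1].interval.end,
        )
        return cls(locus, first_cutter, second_cutter, tuple(fragments))


@dataclass(frozen=True)
class BinGrid:
    """Fixed-width bins tiling a region; the last bin may be partial."""

    region: GenomicInterval
    bin_size: int
    bins: tuple[GenomicInterval, ...] = field(default=())

    def __len__(self) -> int:
        return len(self.bins)

    @property
    def starts(self) -> np.ndarray:
        return np.array([b.start for b in self.bins], dtype=np.int64)

    def to_bed(self, path: str | Path, header: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header:
                fh.write(f"#{line}\n")
            for j, b in enumerate(self.bins):
                fh.write(f"{b.chrom}\t{b.start}\t{b.end}\tbin_{j}\n")


def find_motif_occurrences(seq: str, motif: str) -> list[int]:
    """All (possibly overlapping) start offsets of ``motif`` in ``seq``.

    Matching is case-insensitive; N in the sequence never matches.
    """
    if not motif:
        raise DataValidationError("empty motif")
    motif = motif.upper()
    if not _VALID_MOTIF.match(motif):
        raise DataValidationError(f"motif must be over ACGT, got {motif!r}")
    seq = seq.upper()
    out: list[int] = []
    pos = seq.find(motif)
    while pos != -1:
        out.append(pos)
        pos = seq.find(motif, pos + 1)
    return out


def digest(
    seq: str,
    locus: GenomicInterval,
    first_cutter: str,
    second_cutter: str,
) -> FragmentMap:
    """In silico digestion of a locus sequence into a :class:`FragmentMap`.

    Cuts are placed at the start offset of each primary-cutter occurrence; an
    occurrence at offset 0 coincides with the locus start and creates no
    fragment.  Each fragment's ``has_second_site`` flag is true iff its own
    subsequence contains the secondary cutter (occurrences straddling a cut
    belong to neither neighbour).
    """
    if len(seq) != locus.length:
        raise DataValidationError(
            f"sequence length {len(seq)} != locus length {locus.length}"
        )
    cuts = [off for off in find_motif_occurrences(seq, first_cutter) if off > 0]
    edges = [0, *cuts, locus.length]
    fragments = []
    for i, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
        sub = seq[lo:hi]
        fragments.append(
            RestrictionFragment(
                GenomicInterval(locus.chrom, locus.start + lo, locus.start + hi),
                i,
                bool(find_motif_occurrences(sub, second_cutter)),
            )
        )
    return FragmentMap(locus, first_cutter.upper(), second_cutter.upper(), tuple(fragments))


def uniform_fragment_map(
    locus: GenomicInterval,
    n_fragments: int,
    first_cutter: str = "CATG",
    second_cutter: str = "GATC",
) -> FragmentMap:
    """A fragment map with (near-)uniform fragment lengths, no sequence needed.

    Used by the synthetic-data generator to decouple tests from fragment-size
    confounds.  Fragment boundaries are the rounded n-quantiles of the locus.
    """
    if n_fragments < 1:
        raise DataValidationError("n_fragments must be >= 1")
    edges = np.linspace(locus.start, locus.end, n_fragments + 1).round().astype(int)
    fragments = tuple(
        RestrictionFragment(GenomicInterval(locus.chrom, int(lo), int(hi)), i, True)
        for i, (lo, hi) in enumerate(zip(edges[:-1], edges[1:]))
    )
    return FragmentMap(locus, first_cutter, second_cutter, fragments)


def make_bins(region: GenomicInterval, bin_size: int) -> BinGrid:
    """Left-anchored fixed-width tiling of a region; partial last bin kept."""
    if bin_size < 1:
        raise DataValidationError(f"bin_size must be >= 1, got {bin_size}")
    starts = range(region.start, region.end, bin_size)
    bins = tuple(
        GenomicInterval(region.chrom, s, min(s + bin_size, region.end)) for s in starts
    )
    return BinGrid(region, bin_size, bins)


def assign_fragments_to_bins(fmap: FragmentMap, grid: BinGrid) -> np.ndarray:
    """Map each fragment to the bin containing its midpoint.

    Returns an int array over fragments: the bin index, or -1 for fragments
    whose midpoint lies outside the grid region (midpoint assignment avoids
    double-counting fragments that straddle a bin boundary).
    """
    mids = fmap.midpoints
    assigned = np.full(len(fmap), -1, dtype=np.int64)
    if grid.region.chrom != fmap.locus.chrom or len(grid) == 0:
        return assigned
    inside = (mids >= grid.region.start) & (mids < grid.region.end)
    # bins tile the region contiguously, so searchsorted on starts suffices
    idx = np.searchsorted(grid.starts, mids[inside], side="right") - 1
    assigned[inside] = idx
    return assigned


def read_fasta_locus(path: str | Path, region: str | GenomicInterval) -> tuple[str, GenomicInterval]:
    """Extract a locus sequence from a FASTA file.

    ``region`` is either a record name (whole record) or a
    ``chrom:start-end`` string / :class:`GenomicInterval` selecting a slice.
    Returns ``(sequence, interval)``.
    """
    from Bio import SeqIO

    if isinstance(region, GenomicInterval):
        iv: GenomicInterval | None = region
        name = region.chrom
    elif ":" in str(region):
        iv = GenomicInterval.from_string(str(region))
        name = iv.chrom
    else:
        iv, name = None, str(region)

    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id == name:
            if iv is None:
                iv = GenomicInterval(name, 0, len(rec.seq))
            if iv.end > len(rec.seq):
                raise DataValidationError(
                    f"region {iv} exceeds record {name} length {len(rec.seq)}"
                )
            return str(rec.seq[iv.start : iv.end]).upper(), iv
    raise DataValidationError(f"record {name!r} not found in {path}")
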