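"""Binned contact-profile PCA with component-loading genome tracks.

Contact profiles of several alleles/conditions are compared by counting
reads in fixed-width bins (30 kb typically), converting each sample's bin
counts into ratios within a region of interest, and running a principal
component analysis on the resulting samples x bins matrix.  Per-bin
component loadings — eigenvector entries times the square root of the
eigenvalue — are plotted back along the genome to localize where the contact
pattern differs between sample groups; the changepoint of the first loading
track recovers insulator positions without supervision.

PCA conventions: columns (bins) are mean-centred but not variance-scaled
(ratio bins share a scale, and scaling would inflate empty-bin noise);
covariance divisor n - 1; eigenvector signs fixed so the largest-magnitude
entry of each component is positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataValidationError, NumericError
from .fragmap import BinGrid, GenomicInterval, assign_fragments_to_bins
from .profiles import FragmentCounts, excluded_fragment_mask, write_bedgraph


@dataclass(frozen=True)
class BinMatrix:
    """Samples x bins matrix of within-region read ratios."""

    grid: BinGrid
    bins: tuple[GenomicInterval, ...]  # bins retained after exclusion/empty drop
    samples: tuple[str, ...]
    X: np.ndarray
    normalized: bool


@dataclass(frozen=True)
class PCAResult:
    """Eigendecomposition of the bin-ratio covariance.

    ``components`` holds eigenvectors as rows (k x bins); ``scores`` the
    sample coordinates (samples x k); ``mean`` the per-bin centring means.
    """

    eigenvalues: np.ndarray
    components: np.ndarray
    scores: np.ndarray
    mean: np.ndarray
    samples: tuple[str, ...]
    bins: tuple[GenomicInterval, ...]

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


@dataclass(frozen=True)
class LoadingTrack:
    """Per-bin loadings of one component: v_jk * sqrt(lambda_k)."""

    component: int  # 1-based
    loadings: np.ndarray
    bins: tuple[GenomicInterval, ...]

    def to_bedgraph(self, path: str | Path, header: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header:
                fh.write(f"#{line}\n")
            for b, val in zip(self.bins, self.loadings):
                fh.write(f"{b.chrom}\t{b.start}\t{b.end}\t{float(val)!r}\n")


def build_bin_matrix(
    profiles: Sequence[FragmentCounts],
    grid: BinGrid,
    region: GenomicInterval | None = None,
    drop_empty: bool = True,
) -> BinMatrix:
    """Bin read counts per sample and normalize to within-region ratios.

    Replicates should already be combined per allele.  Bins whose midpoint
    lies in the viewpoint exclusion zone are dropped before normalization;
    bins empty across all samples are dropped with a warning.  Each row is
    divided by its total so rows sum to one.
    """
    if not profiles:
        raise DataValidationError("no profiles given")
    region = region or grid.region
    first = profiles[0]
    for p in profiles[1:]:
        if len(p.fragment_map) != len(first.fragment_map):
            raise DataValidationError(f"sample {p.sample!r}: fragment map mismatch")
        if p.viewpoint.exclusion_zone != first.viewpoint.exclusion_zone:
            raise DataValidationError(f"sample {p.sample!r}: viewpoint mismatch")

    assignment = assign_fragments_to_bins(first.fragment_map, grid)
    # restrict to the region of interest
    bin_mids = np.array([b.midpoint for b in grid.bins])
    in_region = (bin_mids >= region.start) & (bin_mids < region.end)
    zone = first.viewpoint.exclusion_zone
    not_excluded = ~((bin_mids >= zone.start) & (bin_mids < zone.end))
    keep_bins = np.flatnonzero(in_region & not_excluded)

    raw = np.zeros((len(profiles), len(grid)), dtype=np.int64)
    valid = assignment >= 0
    for r, p in enumerate(profiles):
        np.add.at(raw[r], assignment[valid], p.counts[valid])
    raw = raw[:, keep_bins]

    if drop_empty:
        nonempty = raw.sum(axis=0) > 0
        if not nonempty.all():
            warnings.warn(
                f"dropping {int((~nonempty).sum())} bins with zero reads in all samples",
                stacklevel=2,
            )
            keep_bins = keep_bins[nonempty]
            raw = raw[:, nonempty]

    totals = raw.sum(axis=1)
    for r, p in enumerate(profiles):
        if totals[r] == 0:
            raise NumericError(f"sample {p.sample!r} has zero reads in the region")
    X = raw / totals[:, None]
    bins = tuple(grid.bins[j] for j in keep_bins)
    return BinMatrix(grid, bins, tuple(p.sample for p in profiles), X, True)


def run_pca(M: BinMatrix) -> PCAResult:
    """PCA of the bin matrix via SVD of the column-centred data.

    Eigenvalues are singular values squared over n - 1 (the sample-covariance
    eigenvalues), ordered descending; the number of components returned is
    min(n_samples, n_bins).
    """
    X = np.asarray(M.X, dtype=float)
    n, p = X.shape
    if n < 2:
        raise DataValidationError(f"PCA needs >= 2 samples, got {n}")
    if p < 2:
        raise DataValidationError(f"PCA needs >= 2 bins, got {p}")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    # deterministic sign: largest-|entry| of each eigenvector positive
    for k in range(Vt.shape[0]):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    scores = U * s
    return PCAResult(eigenvalues, Vt, scores, mean, M.samples, M.bins)


def component_loadings(res: PCAResult, k: int) -> LoadingTrack:
    """Loading track of component ``k`` (1-based): eigenvector * sqrt(eigenvalue)."""
    if not 1 <= k <= res.n_components:
        raise DataValidationError(
            f"component {k} out of range 1..{res.n_components}"
        )
    lam = res.eigenvalues[k - 1]
    return LoadingTrack(k, res.components[k - 1] * np.sqrt(lam), res.bins)


def loading_changepoint(track: LoadingTrack) -> int:
    """Genomic coordinate of the strongest step in a loading track.

    Scans every boundary between consecutive bins and returns the one
    maximizing |mean(left) - mean(right)|; ties break toward the leftmost
    split.  A constant track has no changepoint and raises.
    """
    values = np.asarray(track.loadings, dtype=float)
    n = len(values)
    if n < 3:
        raise DataValidationError("changepoint needs >= 3 bins")
    if np.allclose(values, values[0]):
        raise NumericError("no changepoint: loading track is constant")
    csum = np.cumsum(values)
    total = csum[-1]
    splits = np.arange(1, n)
    left_mean = csum[:-1] / splits
    right_mean = (total - csum[:-1]) / (n - splits)
    gaps = np.abs(left_mean - right_mean)
    s = int(np.argmax(gaps))  # argmax returns the first (leftmost) maximum
    return track.bins[s + 1].start


def scores_table(res: PCAResult) -> pd.DataFrame:
    """Sample scores and eigenvalues as a tidy table."""
    cols = {f"PC{k + 1}": res.scores[:, k] for k in range(res.n_components)}
    df = pd.DataFrame({"sample": list(res.samples), **cols})
    return df
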