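"""Synthetic 4C locus generator with known ground truth.

Emulates an engineered allelic series at a locally haploid ~3 Mb locus: a
single viewpoint (a gene promoter), a CTCF-site barrier inserted a fixed
distance away, and an enhancer region beyond the barrier.  The generative
model is deliberately a one-parameter barrier, not a polymer simulation —
its purpose is to exercise every statistic in the pipeline with known truth:

* contacts decay with genomic distance d as d^-alpha;
* an allele's barrier retains a fraction beta (permeability) of
  cross-barrier contact: beta = 1 for alleles without bound CTCF, smaller
  the more CTCF sites the allele carries;
* the enhancer region escalates preferentially: its cross-barrier weight is
  beta^delta with delta >= 1, so the enhancer-vs-neutral contact exponent
  equals delta by construction;
* reads are a multinomial draw over the expected contact vector;
* expression follows a power law of enhancer contact, E = c * f^gamma, with
  lognormal noise.

Default beta values for the named alleles are documented constants chosen
only to satisfy the ordering implied by the number of directly bound CTCF
sites; they are not estimates of any real allele.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataValidationError, NumericError
from .fragmap import FragmentMap, GenomicInterval, uniform_fragment_map
from .profiles import (
    DEFAULT_EXCLUSION_FLANK,
    FragmentCounts,
    Viewpoint,
    write_counts_table,
)

DEFAULT_CHROM = "chrSim"


@functools.lru_cache(maxsize=32)
def _uniform_map_cached(chrom: str, length: int, n_fragments: int) -> FragmentMap:
    return uniform_fragment_map(GenomicInterval(chrom, 0, length), n_fragments)

#: Permeabilities of the default nine-allele panel.  Ordering contract:
#: no-CTCF alleles have beta = 1; beta decreases with the number of directly
#: bound CTCF sites; the full divergent array (and its inversion) is lowest.
DEFAULT_PANEL: tuple[tuple[str, float], ...] = (
    ("Hap", 1.00),
    ("STITCH", 0.25),
    ("delL", 0.45),
    ("delR", 0.42),
    ("invR", 0.48),
    ("del(L2-R2)", 0.60),
    ("del(L1-R2)", 0.80),
    ("del(L1-R3)", 1.00),
    ("inv(L1-R3)", 0.25),
)


@dataclass(frozen=True)
class LocusModel:
    """Generative parameters of the synthetic locus.

    Distances are base pairs.  The defaults place the viewpoint at the locus
    centre with the barrier 30 kb to its right and the enhancer region
    330-440 kb to the right, mirroring a promoter / inserted-insulator /
    distal-super-enhancer arrangement.
    """

    locus_length: int = 3_000_000
    n_fragments: int = 3_000
    viewpoint_pos: int = 1_500_000
    barrier_pos: int = 1_530_000
    decay_alpha: float = 1.0
    enhancer_region: GenomicInterval = field(
        default_factory=lambda: GenomicInterval(DEFAULT_CHROM, 1_830_000, 1_940_000)
    )
    enhancer_affinity_delta: float = 1.15
    expression_scale: float = 1.0e7
    expression_exponent: float = 4.0
    noise_sigma: float = 0.05
    chrom: str = DEFAULT_CHROM
    exclusion_flank: int = DEFAULT_EXCLUSION_FLANK

    def __post_init__(self) -> None:
        if self.decay_alpha <= 0:
            raise DataValidationError("decay_alpha must be > 0")
        if self.enhancer_affinity_delta < 1:
            raise DataValidationError("enhancer_affinity_delta must be >= 1")
        if self.barrier_pos == self.viewpoint_pos:
            raise DataValidationError("barrier must not coincide with the viewpoint")
        if self.noise_sigma < 0:
            raise DataValidationError("noise_sigma must be >= 0")
        if not (0 < self.viewpoint_pos < self.locus_length):
            raise DataValidationError("viewpoint_pos outside locus")

    @property
    def locus(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, 0, self.locus_length)

    @property
    def neutral_region(self) -> GenomicInterval:
        """A cross-barrier comparison region with no enhancer bonus.

        Same width as the enhancer region, shifted a further 300 kb from the
        viewpoint (clipped to the locus).
        """
        shift = 300_000 if self.barrier_pos > self.viewpoint_pos else -300_000
        lo, hi = self.enhancer_region.start + shift, self.enhancer_region.end + shift
        if lo < 0 or hi > self.locus_length:
            raise DataValidationError("neutral region falls outside the locus")
        return GenomicInterval(self.chrom, lo, hi)

    def fragment_map(self) -> FragmentMap:
        # FragmentMap is immutable, so sharing one instance across calls is safe
        return _uniform_map_cached(self.chrom, self.locus_length, self.n_fragments)

    def viewpoint(self, fmap: FragmentMap | None = None) -> Viewpoint:
        fmap = fmap or self.fragment_map()
        return Viewpoint.at(
            fmap, self.viewpoint_pos, name="VP-sim", exclusion_flank=self.exclusion_flank
        )


@dataclass(frozen=True)
class AlleleConfig:
    """A named allele with barrier permeability beta in (0, 1]."""

    name: str
    permeability_beta: float

    def __post_init__(self) -> None:
        if not (0 < self.permeability_beta <= 1):
            raise DataValidationError(
                f"allele {self.name!r}: beta must be in (0, 1], "
                f"got {self.permeability_beta}"
            )


def expected_contact_vector(m: LocusModel, a: AlleleConfig) -> np.ndarray:
    """Expected per-fragment contact probabilities for one allele.

    p_i is proportional to d_i^-alpha times a barrier weight: 1 on the
    viewpoint side of the barrier, beta for cross-barrier fragments, and
    beta^delta for cross-barrier fragments inside the enhancer region.  The
    viewpoint fragment itself gets probability zero.
    """
    fmap = m.fragment_map()
    vp = m.viewpoint(fmap)
    mids = fmap.midpoints.astype(float)
    vp_mid = fmap.fragments[vp.fragment_index].interval.midpoint

    d = np.abs(mids - vp_mid)
    d[vp.fragment_index] = 1.0  # placeholder; zeroed below
    weights = d ** (-m.decay_alpha)

    vp_side = np.sign(vp_mid - m.barrier_pos)
    cross = np.sign(mids - m.barrier_pos) != vp_side
    beta = a.permeability_beta
    w = np.ones_like(weights)
    w[cross] = beta
    in_enh = (mids >= m.enhancer_region.start) & (mids < m.enhancer_region.end)
    w[cross & in_enh] = beta**m.enhancer_affinity_delta

    p = weights * w
    p[vp.fragment_index] = 0.0
    total = p.sum()
    if total <= 0:
        raise NumericError("all contact weights are zero")
    return p / total


def expected_contact_frequency(
    m: LocusModel, a: AlleleConfig, region: GenomicInterval
) -> float:
    """Noise-free viewpoint-excluded contact frequency of a region.

    The expectation of the measured statistic: probability mass in the region
    over mass in the whole locus, both with fragments whose midpoint lies in
    the viewpoint exclusion zone removed (midpoint rule throughout).
    """
    fmap = m.fragment_map()
    vp = m.viewpoint(fmap)
    p = expected_contact_vector(m, a)
    mids = fmap.midpoints
    zone = vp.exclusion_zone
    keep = ~((mids >= zone.start) & (mids < zone.end))
    denom = p[keep].sum()
    if denom <= 0:
        raise NumericError("no contact mass outside the exclusion zone")
    num = p[keep & (mids >= region.start) & (mids < region.end)].sum()
    return float(num / denom)


def simulate_counts(
    m: LocusModel,
    a: AlleleConfig,
    depth: int,
    seed: int | np.random.Generator,
) -> FragmentCounts:
    """Multinomial draw of ``depth`` reads over the expected contact vector."""
    if depth < 1:
        raise DataValidationError(f"depth must be >= 1, got {depth}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = expected_contact_vector(m, a)
    counts = rng.multinomial(depth, p)
    fmap = m.fragment_map()
    return FragmentCounts(fmap, m.viewpoint(fmap), a.name, counts)


def simulate_expression(
    f_enh: float, m: LocusModel, seed: int | np.random.Generator
) -> float:
    """Expression linked to enhancer contact: c * f^gamma * exp(N(0, sigma^2))."""
    if f_enh <= 0:
        raise DataValidationError(f"enhancer contact must be > 0, got {f_enh}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eps = rng.normal(0.0, m.noise_sigma) if m.noise_sigma > 0 else 0.0
    return float(m.expression_scale * f_enh**m.expression_exponent * math.exp(eps))


@dataclass(frozen=True)
class AllelePanel:
    """Simulated counts, expression and ground truth for an allelic series."""

    model: LocusModel
    alleles: tuple[AlleleConfig, ...]
    counts: tuple[FragmentCounts, ...]
    expression: pd.DataFrame  # columns: sample, expression, true_contact

    def truth(self) -> dict[str, float | int | str]:
        t: dict[str, float | int | str] = {
            "locus_length": self.model.locus_length,
            "n_fragments": self.model.n_fragments,
            "viewpoint_pos": self.model.viewpoint_pos,
            "barrier_pos": self.model.barrier_pos,
            "decay_alpha": self.model.decay_alpha,
            "enhancer_region": str(self.model.enhancer_region),
            "enhancer_affinity_delta": self.model.enhancer_affinity_delta,
            "expression_scale": self.model.expression_scale,
            "expression_exponent": self.model.expression_exponent,
            "noise_sigma": self.model.noise_sigma,
        }
        for a in self.alleles:
            t[f"beta[{a.name}]"] = a.permeability_beta
        return t


def make_allele_panel(
    allele_spec: Sequence[tuple[str, float]] = DEFAULT_PANEL,
    m: LocusModel | None = None,
    depth: int = 1_000_000,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> AllelePanel:
    """Simulate a full allelic series; optionally write it to disk.

    One counts table and one expression value per allele.  Expression is
    linked to the allele's *expected* (noise-free) enhancer contact
    frequency, so the generative exponent is exactly the model's gamma.
    When ``out_dir`` is given, writes per-allele counts TSVs, an expression
    TSV and a flat key=value truth file.
    """
    m = m or LocusModel()
    names = [name for name, _ in allele_spec]
    if len(set(names)) != len(names):
        raise DataValidationError("duplicate allele names in panel spec")
    alleles = tuple(AlleleConfig(name, beta) for name, beta in allele_spec)

    rng = np.random.default_rng(seed)
    counts = tuple(simulate_counts(m, a, depth, rng) for a in alleles)
    rows = []
    for a in alleles:
        f_true = expected_contact_frequency(m, a, m.enhancer_region)
        rows.append((a.name, simulate_expression(f_true, m, rng), f_true))
    expression = pd.DataFrame(rows, columns=["sample", "expression", "true_contact"])
    panel = AllelePanel(m, alleles, counts, expression)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for c in counts:
            write_counts_table(c, out / f"counts_{_slug(c.sample)}.tsv")
        expression.to_csv(out / "expression.tsv", sep="\t", index=False)
        with open(out / "truth.txt", "w") as fh:
            fh.write(f"seed={seed}\ndepth={depth}\n")
            for key, val in panel.truth().items():
                fh.write(f"{key}={val}\n")
    return panel


def _slug(name: str) -> str:
    return "".join(ch if ch.isalnum() or ch in "+-_" else "_" for ch in name)
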