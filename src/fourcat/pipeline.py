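"""End-to-end pipeline: simulate -> profile -> directionality -> PCA -> scaling.

Runs the whole analysis on a synthetic allelic series (or on pre-simulated
counts) and writes a reproducible report bundle: per-sample BedGraph tracks,
interval-ratio and directionality tables, PCA scores with loading tracks and
the changepoint report, scaling fits, and a manifest with the config hash,
seed and a checksum of every output file.  Identical config + seed yields
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .directionality import directionality_table
from .errors import DataValidationError, NumericError
from .fragmap import GenomicInterval, make_bins
from .pca import (
    build_bin_matrix,
    component_loadings,
    loading_changepoint,
    run_pca,
    scores_table,
)
from .profiles import FragmentProfile, contact_frequency, write_bedgraph, write_counts_table
from .scaling import contact_contact_scaling, fit_power_law
from .simulate import DEFAULT_PANEL, AllelePanel, LocusModel, make_allele_panel

log = logging.getLogger("fourcat")

DEFAULT_DISTANCES = (100_000, 500_000, 1_000_000)


@dataclass(frozen=True)
class RunConfig:
    """Reproducible configuration of a pipeline run."""

    seed: int = 0
    depth: int = 1_000_000
    bin_size: int = 30_000
    exclusion_flank: int = 10_000
    smooth_window: int = 7
    distances: tuple[int, ...] = DEFAULT_DISTANCES
    panel: tuple[tuple[str, float], ...] = DEFAULT_PANEL
    output_dir: str = "fourcat_run"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["distances"] = list(self.distances)
        d["panel"] = [[name, beta] for name, beta in self.panel]
        return d

    @property
    def config_hash(self) -> str:
        # output_dir is deployment detail, not scientific config: two runs of
        # the same analysis into different directories hash identically
        d = {k: v for k, v in self.to_dict().items() if k != "output_dir"}
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = dict(d)
        if "distances" in kwargs:
            kwargs["distances"] = tuple(int(x) for x in kwargs["distances"])
        if "panel" in kwargs:
            kwargs["panel"] = tuple((str(n), float(b)) for n, b in kwargs["panel"])
        return cls(**kwargs)


def _header(cfg: RunConfig) -> list[str]:
    return [f"fourcat {__version__} config={cfg.config_hash} seed={cfg.seed}"]


def _write_tsv(df: pd.DataFrame, path: Path, cfg: RunConfig, floatfmt: str = "%.10g") -> None:
    with open(path, "w") as fh:
        for line in _header(cfg):
            fh.write(f"#{line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=floatfmt)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    cfg: RunConfig, panel: AllelePanel | None = None
) -> dict:
    """Execute every stage and return the manifest (also written to disk)."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = _header(cfg)

    stage = "simulate"
    try:
        if panel is None:
            model = LocusModel(exclusion_flank=cfg.exclusion_flank)
            panel = make_allele_panel(cfg.panel, model, depth=cfg.depth, seed=cfg.seed)
        model = panel.model
        log.info("simulated panel of %d alleles at depth %d", len(panel.alleles), cfg.depth)
        for c in panel.counts:
            write_counts_table(c, out / f"counts_{_slug(c.sample)}.tsv", header=header)
        _write_tsv(panel.expression, out / "expression.tsv", cfg)
        with open(out / "truth.txt", "w") as fh:
            for line in header:
                fh.write(f"#{line}\n")
            fh.write(f"seed={cfg.seed}\ndepth={cfg.depth}\n")
            for key, val in panel.truth().items():
                fh.write(f"{key}={val}\n")

        stage = "profile"
        for c in panel.counts:
            prof = FragmentProfile.from_counts(c, w=cfg.smooth_window)
            write_bedgraph(
                prof.smoothed, c.fragment_map,
                out / f"track_{_slug(c.sample)}.bedgraph", header=header,
            )
        regions = {
            "enhancer": model.enhancer_region,
            "neutral": model.neutral_region,
        }
        ratio_rows = []
        for c in panel.counts:
            for rname, region in regions.items():
                cf = contact_frequency(c, region)
                ratio_rows.append(
                    (c.sample, rname, str(region), cf.numerator_reads,
                     cf.denominator_reads, cf.ratio)
                )
        ratios = pd.DataFrame(
            ratio_rows,
            columns=["sample", "region", "interval", "reads", "total_reads", "ratio"],
        )
        _write_tsv(ratios, out / "ratios.tsv", cfg)
        log.info("wrote contact-frequency ratios for %d regions", len(regions))

        stage = "directionality"
        dtab = directionality_table(panel.counts, cfg.distances)
        _write_tsv(dtab, out / "directionality.tsv", cfg)

        stage = "pca"
        grid = make_bins(model.locus, cfg.bin_size)
        M = build_bin_matrix(panel.counts, grid)
        res = run_pca(M)
        _write_tsv(scores_table(res), out / "pca_scores.tsv", cfg)
        _write_tsv(
            pd.DataFrame(
                {"component": [f"PC{k+1}" for k in range(res.n_components)],
                 "eigenvalue": res.eigenvalues}
            ),
            out / "pca_eigenvalues.tsv", cfg,
        )
        track = component_loadings(res, 1)
        track.to_bedgraph(out / "pca_loading_PC1.bedgraph", header=header)
        change = loading_changepoint(track)
        with open(out / "pca_changepoint.txt", "w") as fh:
            for line in header:
                fh.write(f"#{line}\n")
            fh.write(f"component=PC1\nchangepoint={change}\n"
                     f"barrier_truth={model.barrier_pos}\n")
        log.info("PC1 loading changepoint at %d (truth %d)", change, model.barrier_pos)

        stage = "scaling"
        wide = ratios.pivot(index="sample", columns="region", values="ratio")
        wide = wide.loc[[c.sample for c in panel.counts]]
        expr = panel.expression.set_index("sample").loc[wide.index]
        table = pd.DataFrame(
            {"sample": wide.index, "expression": expr["expression"].to_numpy(),
             "contact": wide["enhancer"].to_numpy()}
        )
        fit_e = fit_power_law(table)
        fit_cc = contact_contact_scaling(
            wide["neutral"].to_numpy(), wide["enhancer"].to_numpy()
        )
        fits = pd.DataFrame(
            [
                ("expression_vs_enhancer_contact", fit_e.exponent, fit_e.intercept,
                 fit_e.spearman, fit_e.n),
                ("enhancer_vs_neutral_contact", fit_cc.exponent, fit_cc.intercept,
                 fit_cc.spearman, fit_cc.n),
            ],
            columns=["fit", "exponent", "intercept_log10", "spearman_rho", "n"],
        )
        _write_tsv(fits, out / "scaling_fits.tsv", cfg)
        log.info(
            "scaling exponents: expression~contact %.3f, enhancer~neutral %.3f",
            fit_e.exponent, fit_cc.exponent,
        )
    except (DataValidationError, NumericError) as exc:
        raise type(exc)(f"stage {stage!r}: {exc}") from exc

    manifest = {
        "fourcat_version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash,
        "config": cfg.to_dict(),
        "files": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _slug(name: str) -> str:
    return "".join(ch if ch.isalnum() or ch in "+-_" else "_" for ch in name)
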