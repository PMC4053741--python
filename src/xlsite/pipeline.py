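"""End-to-end orchestration: ingest -> sites -> mixture -> profiles -> clusters.

The pipeline is configured by a :class:`PipelineConfig` (constructible from a
YAML file), runs each stage with the study's default parameters (25-nt
deletion window, YCAY motif, 100 background randomizations, +/-50 background
window, 41-nt score window) and writes a manifest recording the seed, the
config hash and every output file, so a run is reproducible byte-for-byte
from its manifest.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass
from typing import Optional, Tuple

import pandas as pd

from . import __version__
from ._seq import as_genome
from .clusters import assign_counts, correlate, find_clusters, score_track
from .ingest import (MIN_LIBRARY_SIZE, collapse_auto, collapse_barcoded,
                     deletion_sites, join_no_barcode, truncation_sites)
from .io import (ensure_dir, read_cdna_sam, read_cdna_tsv, read_segments_bed,
                 write_bedgraph, write_cdna_tsv, write_sites_bed)
from .mixture import LibraryDeletionStats, MixtureEstimate
from .profiles import (closest_motif, enrichment, motif_occurrence,
                       motif_variant_proportions, nucleotide_composition,
                       randomized_background)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Inputs, mode flags and parameters of a pipeline run."""

    cdnas: str = ""
    genome: str = ""
    segments: str = ""
    outdir: str = "xlsite_out"
    input_format: str = "tsv"            # tsv | sam
    barcoded: bool = True
    window_nt: int = 25
    motif: str = "YCAY"
    background_n: int = 100
    background_window: int = 50
    profile_window: int = 30
    score_flank: int = 20                # 41-nt sliding window
    min_library_size: int = MIN_LIBRARY_SIZE
    sites_source: str = "truncation"     # truncation | deletion
    region: str = ""                     # "chrom:start-end"; default: chrom 1
    reference_clip: str = ""             # read-through reference library (TSV)
    background_library: str = ""         # mRNA-Seq background library (TSV)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _read_library(path: str, fmt: str):
    if fmt == "sam":
        return read_cdna_sam(path)
    return read_cdna_tsv(path)


def _parse_region(region: str, genome) -> Tuple[str, int, int]:
    if not region:
        chrom = sorted(genome)[0]
        return chrom, 0, len(genome[chrom])
    chrom, span = region.rsplit(":", 1)
    lo, hi = span.replace(",", "").split("-")
    return chrom, int(lo), int(hi)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every applicable stage; returns the manifest dict."""
    out = ensure_dir(config.outdir)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "outputs": [],
        "log": {},
    }

    def emit(name: str) -> str:
        path = os.path.join(out, name)
        manifest["outputs"].append(name)
        return path

    # -- ingest ------------------------------------------------------------
    try:
        raw = _read_library(config.cdnas, config.input_format)
        unique = (collapse_barcoded if config.barcoded else join_no_barcode)(raw)
        stats = LibraryDeletionStats.from_records(
            unique, config.window_nt, config.min_library_size
        )
    except Exception as exc:  # noqa: BLE001 - stage context for the user
        raise PipelineError("ingest", str(exc)) from exc
    write_cdna_tsv(unique, emit("unique_cdnas.tsv"))
    manifest["log"]["n_raw"] = len(raw)
    manifest["log"]["n_unique"] = len(unique)

    trunc = truncation_sites(unique)
    dels = deletion_sites(unique)
    write_sites_bed(trunc, emit("truncation_sites.bed"))
    write_sites_bed(dels, emit("deletion_sites.bed"))
    pd.DataFrame(
        [{
            "total_unique_cdnas": stats.total_unique_cdnas,
            "cdnas_with_any_deletion": stats.cdnas_with_any_deletion,
            "cdnas_with_deletion_in_window": stats.cdnas_with_deletion_in_window,
            "window_nt": stats.window_nt,
            "windowed_proportion": float(stats.windowed_proportion),
            "printed": stats.windowed_percent_printed,
        }]
    ).to_csv(emit("library_stats.tsv"), sep="\t", index=False)

    # -- re-definition -----------------------------------------------------
    genome = as_genome(config.genome)
    try:
        from .redefine import redefine_sites

        dels_redefined = redefine_sites(dels, genome)
    except Exception as exc:
        raise PipelineError("redefine", str(exc)) from exc
    write_sites_bed(dels_redefined, emit("deletion_sites_redefined.bed"))

    # -- mixture -----------------------------------------------------------
    if config.reference_clip and config.background_library:
        try:
            ref = collapse_auto(_read_library(config.reference_clip, "tsv"))
            bg = collapse_auto(_read_library(config.background_library, "tsv"))
            est = MixtureEstimate.from_stats(
                stats,
                LibraryDeletionStats.from_records(ref, config.window_nt,
                                                  config.min_library_size),
                LibraryDeletionStats.from_records(bg, config.window_nt,
                                                  config.min_library_size),
            )
        except Exception as exc:
            raise PipelineError("mixture", str(exc)) from exc
        pd.DataFrame([dataclasses.asdict(est)]).to_csv(
            emit("mixture_report.tsv"), sep="\t", index=False, float_format="%.6f"
        )
        manifest["log"]["mixture"] = dataclasses.asdict(est)
    else:
        logger.info("mixture stage skipped (no reference/background library)")
        manifest["log"]["mixture"] = "skipped"

    # -- profiles ----------------------------------------------------------
    sites = dels_redefined if config.sites_source == "deletion" else trunc
    segments = read_segments_bed(config.segments)
    try:
        occ = motif_occurrence(sites, config.motif, genome, config.profile_window)
        clo = closest_motif(sites, config.motif, genome, config.profile_window)
        bg_model = randomized_background(
            sites, segments, config.motif, genome,
            n=config.background_n, window=config.background_window,
            seed=config.seed,
        )
        occ_bg = motif_occurrence(sites, config.motif, genome,
                                  config.background_window)
        enr = enrichment(occ_bg, bg_model)
        comp = nucleotide_composition(sites, genome, config.profile_window)
        variants = motif_variant_proportions(sites, genome)
    except Exception as exc:
        raise PipelineError("profile", str(exc)) from exc
    occ.to_frame().to_csv(emit("motif_occurrence.tsv"), sep="\t", index=False)
    clo.to_frame().to_csv(emit("closest_motif.tsv"), sep="\t", index=False)
    pd.DataFrame({"offset": bg_model.offsets, "mean": bg_model.mean}).to_csv(
        emit("background_occurrence.tsv"), sep="\t", index=False, float_format="%.6f"
    )
    pd.DataFrame({"offset": enr.offsets, "ratio": enr.ratio,
                  "smoothed": enr.smoothed}).to_csv(
        emit("enrichment.tsv"), sep="\t", index=False, float_format="%.6f"
    )
    comp.to_frame().to_csv(emit("nucleotide_composition.tsv"), sep="\t",
                           index=False, float_format="%.6f")
    variants.to_csv(emit("motif_variants.tsv"), sep="\t", float_format="%.6f")
    region2 = enr.threshold_region(2.0)
    manifest["log"]["twofold_region"] = list(region2) if region2 else None

    # -- clusters ----------------------------------------------------------
    try:
        chrom, lo, hi = _parse_region(config.region, genome)
        track = score_track(genome, chrom, lo, hi, config.motif,
                            config.score_flank)
        clus = assign_counts(find_clusters(track), sites)
        try:
            corr = correlate(clus)
            manifest["log"]["spearman"] = {
                "rho": corr.rho, "pvalue": corr.pvalue, "n": corr.n_clusters,
            }
        except Exception as exc:  # too few qualifying clusters is a report, not a crash
            manifest["log"]["spearman"] = str(exc)
            corr = None
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("clusters", str(exc)) from exc
    write_bedgraph(chrom, lo, track.scores, emit("ycay_score.bedgraph"))
    pd.DataFrame(
        [(c.chrom, c.start, c.end, c.cluster_score, c.n_sites,
          c.max_cdna_count if c.max_cdna_count is not None else 0)
         for c in clus],
        columns=["chrom", "start", "end", "cluster_score", "n_sites",
                 "max_cdna_count"],
    ).to_csv(emit("clusters.tsv"), sep="\t", index=False)
    if corr is not None:
        pd.DataFrame([{"rho": corr.rho, "pvalue": corr.pvalue,
                       "n_clusters": corr.n_clusters}]).to_csv(
            emit("correlation.tsv"), sep="\t", index=False, float_format="%.6g"
        )

    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
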