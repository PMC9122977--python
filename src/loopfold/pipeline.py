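"""End-to-end image -> model pipeline and ensemble analysis.

Stage order for a single image: read localizations -> permissive 30 nm
uncertainty pre-filter (any axis) -> strict 15 nm filter (all axes) ->
group peaks -> image QC (abort if below probe coverage) -> TSP ordering ->
local-search optimization -> longest-edge opening -> spline interpolation
to the region's bead count -> genomic annotation.  Every run writes its
effective configuration and per-stage counts next to its outputs so it can
be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import localization as loc
from .genome import GenomicRegion, TARGET_MODEL_REGION, TARGET_N_OLIGOS, n_beads_for
from .interpolate import spline_interpolate
from .metrics import (
    DEFAULT_CONTACT_QUANTILE,
    average_distance_map,
    distance_map,
    pairwise_imj,
    save_heatmap,
)
from .model import PDB_SCALE, PolymerModel, anchor_distance, map_genome, read_pdb, write_pdb
from .tsp import reconstruct_path

log = logging.getLogger(__name__)


class QCFailure(RuntimeError):
    """An image failed probe-coverage QC; the QC report was still written."""


@dataclass
class PipelineConfig:
    """All stage parameters of the image pipeline; fully serializable."""

    # uncertainty filters (nm)
    prefilter_sigma: float = 30.0
    strict_sigma: float = 15.0
    # grouping
    group_radius: float = 50.0
    min_events: int = 2
    # QC
    n_designed_oligos: int = TARGET_N_OLIGOS
    min_fraction: float = 0.30
    # genomic annotation
    chrom: str = TARGET_MODEL_REGION.chrom
    region_start: int = TARGET_MODEL_REGION.start
    region_end: int = TARGET_MODEL_REGION.end
    anchors: tuple[int, ...] = TARGET_MODEL_REGION.anchors
    origin_bp: int | None = None  # default: region start
    bp_per_bead: int = 10
    # TSP
    max_sweeps: int = 1000
    # IMJ
    imj_variant: str = "contact"
    imj_quantile: float = DEFAULT_CONTACT_QUANTILE
    # output
    pdb_scale: float = PDB_SCALE
    seed: int = 0

    @property
    def region(self) -> GenomicRegion:
        return GenomicRegion(self.chrom, self.region_start, self.region_end, tuple(self.anchors))

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["anchors"] = list(d["anchors"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "anchors" in d:
            d["anchors"] = tuple(d["anchors"])
        return cls(**d)


def run_image_pipeline(
    localization_file, config: PipelineConfig | None = None, outdir=None,
    dialect: loc.ColumnDialect = loc.DEFAULT_DIALECT,
) -> dict:
    """Reconstruct one localization image into an annotated polymer model.

    Returns a dict with the model, distance map, QC report, ordering and
    anchor report; writes PDB/heatmap/JSON/config artifacts when ``outdir``
    is given.  Raises :class:`QCFailure` (after writing the QC report) when
    the image covers too few designed oligos.
    """
    cfg = config or PipelineConfig()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        cfg.to_yaml(out / "config.yaml")

    table = loc.read_localizations(localization_file, dialect=dialect)
    n_raw = len(table)
    table = loc.filter_by_uncertainty(table, cfg.prefilter_sigma, mode="any_axis")
    table = loc.filter_by_uncertainty(table, cfg.strict_sigma, mode="all_axes")
    n_filtered = len(table)
    groups = loc.group_peaks(table, radius=cfg.group_radius, min_events=cfg.min_events)
    report = loc.image_qc(
        groups, cfg.n_designed_oligos, cfg.min_fraction,
        n_localizations=n_raw, n_filtered=n_filtered,
    )
    log.info(
        "%s: %d raw -> %d filtered -> %d groups (QC %s)",
        table.source_id, n_raw, n_filtered, report.n_groups,
        "pass" if report.passed else "FAIL",
    )
    if out is not None:
        report.to_json(out / "qc.json")
    if not report.passed:
        raise QCFailure(
            f"{table.source_id}: {report.n_groups} group peaks cover less than "
            f"{cfg.min_fraction:.0%} of {cfg.n_designed_oligos} designed oligos"
        )

    points = groups.positions
    ordering = reconstruct_path(points, max_sweeps=cfg.max_sweeps)
    region = cfg.region
    n_beads = n_beads_for(region, cfg.bp_per_bead)
    beads = spline_interpolate(points[ordering.order], n_beads)
    model = map_genome(beads, region, cfg.bp_per_bead, origin_bp=cfg.origin_bp)
    dmap = distance_map(model)

    anchor_report = {
        "anchors_bp": list(region.anchors),
        "anchor_beads": list(model.anchor_beads),
        "anchor_distance_nm": (
            anchor_distance(model) if len(model.anchor_beads) == 2 else None
        ),
    }
    if out is not None:
        write_pdb(model, out / "model.pdb", scale=cfg.pdb_scale)
        np.savetxt(out / "distance_map.txt", dmap.matrix, fmt="%.3f")
        save_heatmap(dmap, out / "distance_map.png", title=str(region))
        (out / "anchors.json").write_text(json.dumps(anchor_report, indent=2) + "\n")
    return {
        "model": model,
        "distance_map": dmap,
        "qc": report,
        "ordering": ordering,
        "anchors": anchor_report,
        "groups": groups,
    }


def run_ensemble(models, config: PipelineConfig | None = None, outdir=None) -> dict:
    """Ensemble analysis: average map, pairwise IMJ, anchor distances.

    ``models`` is a directory of PDB files, a list of PDB paths, or a list
    of :class:`PolymerModel`.  Bead counts must match across models.
    """
    cfg = config or PipelineConfig()
    if isinstance(models, (str, Path)):
        paths = sorted(Path(models).glob("*.pdb"))
        models = paths
    loaded: list[PolymerModel] = []
    names = []
    for i, m in enumerate(models):
        if isinstance(m, PolymerModel):
            loaded.append(m)
            names.append(f"model_{i}")
        else:
            mod = read_pdb(m, scale=cfg.pdb_scale)
            loaded.append(mod)
            names.append(Path(m).stem)
    if len(loaded) < 2:
        raise ValueError("need at least 2 models for ensemble analysis")
    counts = {m.n_beads for m in loaded}
    if len(counts) > 1:
        bad = {nm: m.n_beads for nm, m in zip(names, loaded)}
        raise ValueError(f"mismatched bead counts across models: {bad}")

    maps = [distance_map(m) for m in loaded]
    avg = average_distance_map(maps)
    sim, mean_imj = pairwise_imj(
        maps, variant=cfg.imj_variant, threshold_quantile=cfg.imj_quantile
    )
    region = cfg.region
    anchor_rows = []
    for nm, m in zip(names, loaded):
        if not m.anchor_beads:
            try:
                m = map_genome(m.beads, region, cfg.bp_per_bead, origin_bp=cfg.origin_bp)
            except ValueError:
                m = None
        if m is not None and len(m.anchor_beads) == 2:
            anchor_rows.append((nm, anchor_distance(m)))
    anchors = pd.DataFrame(anchor_rows, columns=["model", "anchor_distance_nm"])

    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        cfg.to_yaml(out / "config.yaml")
        np.savetxt(out / "average_distance_map.txt", avg.matrix, fmt="%.3f")
        save_heatmap(avg, out / "average_distance_map.png", title="ensemble average")
        pd.DataFrame(sim, index=names, columns=names).to_csv(out / "pairwise_imj.csv")
        anchors.to_csv(out / "anchor_distances.csv", index=False)
        (out / "summary.json").write_text(
            json.dumps({"n_models": len(loaded), "mean_imj": mean_imj}, indent=2) + "\n"
        )
    return {
        "average_map": avg,
        "pairwise_imj": sim,
        "mean_imj": mean_imj,
        "anchor_distances": anchors,
        "names": names,
    }
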