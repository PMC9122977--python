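"""Simulation studies validating the TSP reconstruction pipeline.

Two sweeps probe how reconstruction quality degrades with incomplete
staining:

* the *efficiency sweep* keeps a random fraction of a truth model's beads
  (5%..95%, emulating per-probe attachment probability), reconstructs the
  depleted cloud with the TSP pipeline, interpolates back to the truth bead
  count and scores distance-map similarity (IMJ), order recovery (Spearman)
  and post-alignment RMSD;
* the *gap sweep* removes one contiguous run of beads (an unstained
  sub-region) and scores IMJ per gap size; per-gap-size medians summarize
  robustness.

A *random baseline* — IMJ between pairs of independent self-avoiding walks
— anchors the similarity scale: scores at or below it carry no structural
signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .interpolate import spline_interpolate
from .metrics import distance_map, imj, imj_orientation_free, kabsch_align, order_recovery
from .model import PolymerModel
from .simulate import SAWConfig, saw_ensemble, subsample_beads
from .tsp import reconstruct_path

log = logging.getLogger(__name__)


def reconstruct_from_points(points, n_beads: int) -> tuple[np.ndarray, np.ndarray]:
    """Order a depleted point cloud and interpolate to ``n_beads`` beads.

    Returns ``(beads, order)`` where ``order`` indexes the input points in
    inferred path order.  When the point count already equals ``n_beads``
    the ordered points are returned as-is: with nothing missing there is
    nothing to re-space, and resampling would only shift knots slightly
    (spline arc length exceeds chord length between knots).
    """
    ordering = reconstruct_path(points)
    ordered = np.asarray(points, dtype=float)[ordering.order]
    if len(ordered) == n_beads:
        return ordered, ordering.order
    beads = spline_interpolate(ordered, n_beads)
    return beads, ordering.order


def _score_cell(truth: PolymerModel, points, survivors, rng, with_alignment=True, **imj_kw):
    """Reconstruct one depleted point set and score it against its truth."""
    # shuffle so reconstruction cannot inherit the input order
    perm = rng.permutation(len(points))
    beads, order = reconstruct_from_points(np.asarray(points)[perm], truth.n_beads)
    # path orientation is unidentifiable: score the better map orientation
    score = imj_orientation_free(distance_map(beads), distance_map(truth), **imj_kw)
    inferred = survivors[perm[order]]
    rec = order_recovery(survivors, inferred)
    rmsd = np.nan
    if with_alignment:
        _, r_fwd = kabsch_align(truth.beads, beads)
        _, r_rev = kabsch_align(truth.beads, beads[::-1])
        rmsd = min(r_fwd, r_rev)
    return score, rec, rmsd


@dataclass
class EfficiencySweepResult:
    """Tidy per-(efficiency, structure, replicate) scores plus medians."""

    table: pd.DataFrame

    @property
    def medians(self) -> pd.Series:
        return self.table.groupby("efficiency")["imj"].median()


@dataclass
class GapSweepResult:
    """Tidy per-(gap, structure, replicate) scores plus per-gap medians."""

    table: pd.DataFrame

    @property
    def medians(self) -> pd.Series:
        return self.table.groupby("gap")["imj"].median()


def run_efficiency_sweep(
    truth_models,
    efficiencies,
    replicates: int = 10,
    seed: int = 0,
    **imj_kw,
) -> EfficiencySweepResult:
    """Staining-efficiency sweep over an ensemble of truth models.

    For each (truth model, efficiency, replicate): subsample a random bead
    fraction, reconstruct with the TSP pipeline, interpolate to the truth
    bead count, then score IMJ, order recovery and best-orientation RMSD.
    """
    efficiencies = list(efficiencies)
    if any(not (0 < e <= 1) for e in efficiencies):
        raise ValueError("efficiencies must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for si, truth in enumerate(truth_models):
        for eff in efficiencies:
            for rep in range(replicates):
                pts, surv = subsample_beads(truth, "random_fraction", eff, rng)
                score, rec, rmsd = _score_cell(truth, pts, surv, rng, **imj_kw)
                rows.append((eff, si, rep, score, rec.rho, rec.p_value, rmsd))
    table = pd.DataFrame(
        rows,
        columns=["efficiency", "structure", "replicate", "imj", "rho", "p_value", "rmsd"],
    )
    return EfficiencySweepResult(table)


def run_gap_sweep(
    truth_models,
    gap_sizes,
    replicates: int = 10,
    seed: int = 0,
    **imj_kw,
) -> GapSweepResult:
    """Contiguous-gap robustness sweep.

    For each (truth model, gap size, replicate): remove one random
    contiguous bead run, reconstruct, interpolate back, and score IMJ
    against the truth distance map.
    """
    gap_sizes = [int(g) for g in gap_sizes]
    rng = np.random.default_rng(seed)
    rows = []
    for si, truth in enumerate(truth_models):
        for gap in gap_sizes:
            for rep in range(replicates):
                pts, surv = subsample_beads(truth, "contiguous_gap", gap, rng)
                score, _, _ = _score_cell(
                    truth, pts, surv, rng, with_alignment=False, **imj_kw
                )
                rows.append((gap, si, rep, score))
        log.info("gap sweep: structure %d/%d done", si + 1, len(truth_models))
    table = pd.DataFrame(rows, columns=["gap", "structure", "replicate", "imj"])
    return GapSweepResult(table)


def evaluate_order_recovery(traces, alpha: float = 0.05, seed: int = 0) -> dict:
    """Order-recovery evaluation on ordered 3D traces (chromatin-tracing style).

    Each trace is an ordered (m, 3) array of segment coordinates; rows with
    non-finite entries (undetected segments) are dropped.  The points are
    shuffled, reconstructed by the TSP pipeline, and the inferred order is
    rank-correlated with the true one.  Traces with fewer than 3 valid
    points are skipped.
    """
    rng = np.random.default_rng(seed)
    rhos, pvals = [], []
    skipped = 0
    for trace in traces:
        pts = np.asarray(trace, dtype=float)
        valid = np.isfinite(pts).all(axis=1)
        pts = pts[valid]
        if len(pts) < 3:
            skipped += 1
            log.info("order recovery: skipping trace with <3 valid points")
            continue
        true_idx = np.arange(len(pts))
        perm = rng.permutation(len(pts))
        ordering = reconstruct_path(pts[perm])
        rec = order_recovery(true_idx, perm[ordering.order], alpha=alpha)
        rhos.append(rec.rho)
        pvals.append(rec.p_value)
    pvals_arr = np.array(pvals)
    n = len(pvals)
    return {
        "n_traces": n,
        "n_skipped": skipped,
        "fraction_significant": float(np.mean(pvals_arr < alpha)) if n else np.nan,
        "fraction_p_below_1e-5": float(np.mean(pvals_arr < 1e-5)) if n else np.nan,
        "rho": rhos,
        "p_values": pvals,
    }


def random_baseline(
    n_pairs: int,
    structure_config: SAWConfig | None = None,
    seed: int = 0,
    **imj_kw,
) -> dict:
    """IMJ between disjoint pairs of independent SAW conformations.

    The mean of this distribution is the no-signal similarity floor used to
    calibrate the IMJ variant and threshold.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    cfg = structure_config or SAWConfig(seed=seed)
    if cfg.seed != seed:
        cfg = SAWConfig(
            n_beads=cfg.n_beads, step=cfg.step,
            excluded_radius=cfg.excluded_radius, seed=seed,
            max_attempts=cfg.max_attempts,
        )
    models = saw_ensemble(2 * n_pairs, cfg)
    scores = np.array(
        [
            imj(distance_map(models[2 * i]), distance_map(models[2 * i + 1]), **imj_kw)
            for i in range(n_pairs)
        ]
    )
    return {
        "mean": float(scores.mean()),
        "std": float(scores.std(ddof=1)) if n_pairs > 1 else 0.0,
        "sem": float(scores.std(ddof=1) / np.sqrt(n_pairs)) if n_pairs > 1 else 0.0,
        "scores": scores,
    }
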