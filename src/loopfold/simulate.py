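"""Ground-truth structure and synthetic-image generators.

Three generators provide the controlled study conditions for validating the
reconstruction pipeline:

* self-avoiding random walks (SAW): fixed-bond-length off-lattice chains
  with an excluded-volume radius, the null/control polymer ensemble;
* MDS embeddings: 3D chains derived from a genomic contact matrix by
  interpreting it as a graph, computing all-pairs graph distances and
  embedding them with metric multidimensional scaling (one model per random
  initialization);
* synthetic localization images: oligo probe targets placed at regular
  genomic spacing along a truth polymer, thinned by a staining-efficiency
  probability, each retained oligo emitting a Poisson number of blinking
  events with per-axis Gaussian position noise.

All generators are reproducible bit-for-bit from their seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path
from sklearn.manifold import MDS

from .genome import GenomicRegion
from .interpolate import arc_length, spline_interpolate
from .localization import FIELDS, LocalizationTable
from .model import PolymerModel


class GenerationError(RuntimeError):
    """A generator could not satisfy its geometric constraints."""


@dataclass(frozen=True)
class SAWConfig:
    """Self-avoiding random-walk parameters.

    ``step`` is the fixed bond length (nm); non-adjacent beads must stay at
    least ``excluded_radius`` apart.  The default excluded radius equals the
    bond length (a chain of touching hard spheres): this guarantees that no
    non-adjacent bead is ever closer than a chain neighbor, the geometric
    regime in which a shortest-path ordering can follow the fiber.  Radii up
    to just below ``2 * step`` remain generable (larger radii force the
    chain toward a straight line and generation stalls).
    """

    n_beads: int = 340
    step: float = 30.0
    excluded_radius: float | None = None
    seed: int = 0
    max_attempts: int = 200_000

    def __post_init__(self) -> None:
        if self.n_beads < 2:
            raise ValueError("n_beads must be >= 2")
        if self.step <= 0:
            raise ValueError("step must be positive")
        r = self.resolved_excluded_radius
        if r >= 2.0 * self.step:
            raise ValueError(
                "excluded_radius must be smaller than twice the bond length "
                "(the walk cannot place any bent bead otherwise)"
            )

    @property
    def resolved_excluded_radius(self) -> float:
        return self.step if self.excluded_radius is None else self.excluded_radius


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def saw_generate(config: SAWConfig, rng: np.random.Generator | None = None) -> PolymerModel:
    """Grow one self-avoiding chain by random unit steps with backtracking.

    Each new bead is placed at bond length ``step`` in a uniformly random
    direction; a placement is accepted only if it stays at least
    ``excluded_radius`` away from every non-adjacent bead.  After repeated
    local failures the walk backtracks one bead.  Raises
    :class:`GenerationError` when ``max_attempts`` placements are exhausted.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n, step, rad = config.n_beads, config.step, config.resolved_excluded_radius
    beads = np.zeros((n, 3))
    beads[1] = _random_unit(rng) * step
    i = 2
    attempts = 0
    tries_here = 0
    while i < n:
        if attempts >= config.max_attempts:
            raise GenerationError(
                f"self-avoiding walk stuck after {attempts} attempts; "
                "reduce excluded_radius or n_beads"
            )
        cand = beads[i - 1] + _random_unit(rng) * step
        attempts += 1
        d = np.linalg.norm(beads[: i - 1] - cand, axis=1)
        if (d >= rad).all():
            beads[i] = cand
            i += 1
            tries_here = 0
        else:
            tries_here += 1
            if tries_here > 50 and i > 2:
                i -= 1  # backtrack one bead
                tries_here = 0
    return PolymerModel(beads=beads)


def saw_ensemble(n_models: int, config: SAWConfig) -> list[PolymerModel]:
    """Independent seeded SAW models, reproducible from ``config.seed``."""
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    children = np.random.SeedSequence(config.seed).spawn(n_models)
    return [saw_generate(config, rng=np.random.default_rng(ss)) for ss in children]


@dataclass
class ContactMatrix:
    """Dense symmetric genomic interaction-frequency matrix."""

    matrix: np.ndarray
    bin_bp: int | None = None
    region: GenomicRegion | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("contact matrix must be square")
        if not np.allclose(m, m.T):
            raise ValueError("contact matrix must be symmetric")
        if (m < 0).any():
            raise ValueError("contact frequencies must be nonnegative")

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]


def mds_models_from_contacts(
    contacts: ContactMatrix,
    n_models: int,
    threshold: float = 0.0,
    weight: str = "hop",
    seed: int = 0,
    max_iter: int = 300,
) -> list[PolymerModel]:
    """Embed a contact matrix into an ensemble of 3D bead chains.

    Bins with contact frequency above ``threshold`` become graph edges
    (``weight="hop"``: unit edges; ``"inverse_frequency"``: 1/frequency).
    All-pairs shortest-path distances over this graph are embedded in 3D by
    metric MDS; each model uses a distinct random initialization, which is
    how one matrix yields an ensemble of distinct conformations.  Every bin
    becomes one bead.
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    m = contacts.matrix.copy()
    np.fill_diagonal(m, 0.0)
    adj = m > threshold
    if weight == "hop":
        w = adj.astype(float)
    elif weight == "inverse_frequency":
        w = np.where(adj, 1.0 / np.where(adj, m, 1.0), 0.0)
    else:
        raise ValueError(f"unknown edge weight rule {weight!r}")
    graph = csr_matrix(w)
    n_comp, labels = connected_components(graph, directed=False)
    if n_comp > 1:
        counts = np.bincount(labels)
        isolated = np.flatnonzero(labels != counts.argmax())
        raise ValueError(
            f"contact graph is disconnected; isolated bins: {isolated.tolist()}"
        )
    D = shortest_path(graph, directed=False, unweighted=(weight == "hop"))
    seeds = np.random.SeedSequence(seed).spawn(n_models)
    models = []
    for ss in seeds:
        rs = int(ss.generate_state(1)[0] % (2**31 - 1))
        mds = MDS(
            n_components=3,
            metric="precomputed",
            init="random",
            n_init=1,
            max_iter=max_iter,
            random_state=rs,
            normalized_stress=False,
        )
        coords = mds.fit_transform(D)
        models.append(PolymerModel(beads=coords))
    return models


def rescale_to_volume(model: PolymerModel, reference_extent) -> PolymerModel:
    """Uniformly rescale a model so its bounding box fits a reference size.

    ``reference_extent`` is a scalar or 3-vector of nm extents; the model's
    largest bounding-box axis is matched to the largest reference extent
    (aspect ratio preserved) and the bounding-box corner moved to the
    origin.  Idempotent for an already-fitting model.
    """
    ref = np.atleast_1d(np.asarray(reference_extent, dtype=float))
    lo = model.beads.min(axis=0)
    extent = model.beads.max(axis=0) - lo
    if extent.max() <= 0:
        raise ValueError("cannot rescale a zero-extent model")
    s = ref.max() / extent.max()
    return replace(model, beads=(model.beads - lo) * s)


@dataclass(frozen=True)
class SynthImageConfig:
    """Synthetic localization-image parameters.

    Defaults emulate the target-loop staining design: 336 oligos over the
    33,312 bp modelled region (~99 bp spacing), partial staining efficiency,
    Poisson blinking counts, and per-axis Gaussian localization noise in the
    2-22 nm precision range.
    """

    oligo_spacing_bp: float = 99.0
    efficiency: float = 1.0
    events_per_oligo: float = 10.0
    sigma_xyz: tuple[float, float, float] = (8.0, 8.0, 6.0)
    photons_mean: float = 1500.0
    seed: int = 0
    poisson_events: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.efficiency <= 1):
            raise ValueError("efficiency must be in (0, 1]")
        if any(s < 0 for s in self.sigma_xyz):
            raise ValueError("sigmas must be nonnegative")
        if self.oligo_spacing_bp <= 0:
            raise ValueError("oligo_spacing_bp must be positive")


def synth_localizations(
    truth: PolymerModel, config: SynthImageConfig
) -> tuple[LocalizationTable, pd.DataFrame]:
    """Simulate a localization image of a truth polymer.

    Oligo targets are placed at equal genomic spacing along the fiber
    (positions linearly interpolated along the bead polyline by arc
    length), retained independently with probability ``efficiency``, and
    each retained oligo emits blinking events at its position plus per-axis
    Gaussian noise.  Returns the localization table and a ground-truth
    oligo table (genomic bp, 3D position, retained flag).
    """
    if truth.n_beads < 2:
        raise ValueError("truth model needs at least 2 beads")
    rng = np.random.default_rng(config.seed)
    if truth.region is not None and truth.bp_per_bead is not None:
        length_bp = truth.region.length_bp
        origin = truth.origin_bp if truth.origin_bp is not None else truth.region.start
    else:
        length_bp = truth.n_beads * (truth.bp_per_bead or 1.0)
        origin = 0
    n_oligos = int(length_bp // config.oligo_spacing_bp)
    # oligo k sits at the midpoint of its genomic tile
    frac = (np.arange(n_oligos) + 0.5) * config.oligo_spacing_bp / length_bp
    bp = origin + frac * length_bp

    # arc-length positions along the bead polyline
    seg = np.linalg.norm(np.diff(truth.beads, axis=0), axis=1)
    s = np.concatenate(([0.0], np.cumsum(seg)))
    s_target = frac * s[-1]
    oligo_pos = np.column_stack(
        [np.interp(s_target, s, truth.beads[:, k]) for k in range(3)]
    )

    retained = rng.random(n_oligos) < config.efficiency
    rows = []
    frame = 0
    sig = np.asarray(config.sigma_xyz, dtype=float)
    for k in np.flatnonzero(retained):
        if config.poisson_events:
            n_ev = int(rng.poisson(config.events_per_oligo))
        else:
            n_ev = int(round(config.events_per_oligo))
        for _ in range(n_ev):
            noise = rng.normal(0.0, 1.0, size=3) * sig
            photons = float(rng.gamma(2.0, config.photons_mean / 2.0))
            rows.append(
                (*(oligo_pos[k] + noise), *sig, photons, frame)
            )
            frame += 1
    df = pd.DataFrame(rows, columns=list(FIELDS))
    truth_df = pd.DataFrame(
        {
            "oligo_id": np.arange(n_oligos),
            "bp": bp,
            "x": oligo_pos[:, 0],
            "y": oligo_pos[:, 1],
            "z": oligo_pos[:, 2],
            "retained": retained,
        }
    )
    return LocalizationTable(df, source_id=f"synth-{config.seed}"), truth_df


def subsample_beads(
    model: PolymerModel,
    mode: str,
    amount,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Deplete a model's beads, emulating imperfect staining.

    ``mode="random_fraction"`` keeps ``round(fraction * n)`` beads uniformly
    without replacement; ``mode="contiguous_gap"`` removes one uniformly
    positioned run of ``amount`` consecutive beads.  Returns the surviving
    points and their original indices (ascending), which define the true
    order for order-recovery scoring.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = model.n_beads
    if mode == "random_fraction":
        f = float(amount)
        if not (0 < f <= 1):
            raise ValueError("fraction must be in (0, 1]")
        k = int(round(f * n))
        k = max(k, 2)
        survivors = np.sort(rng.choice(n, size=k, replace=False))
    elif mode == "contiguous_gap":
        gap = int(amount)
        if gap >= n:
            raise ValueError(f"gap size {gap} must be smaller than bead count {n}")
        if gap < 0:
            raise ValueError("gap size must be nonnegative")
        start = int(rng.integers(0, n - gap + 1))
        mask = np.ones(n, dtype=bool)
        mask[start : start + gap] = False
        survivors = np.flatnonzero(mask)
    else:
        raise ValueError(f"unknown subsampling mode {mode!r}")
    return model.beads[survivors].copy(), survivors
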