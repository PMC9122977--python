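"""Distance maps, Modified Jaccard Index, rigid alignment, order recovery.

Distance maps (pairwise Euclidean bead-bead distances, nm) are the
alignment- and orientation-free representation used for all quantitative
structure comparison.  The Modified Jaccard Index (IMJ) compares two maps as
a percentage similarity; two variants are provided:

``weighted``
    After normalizing each map by its mean off-diagonal entry,
    ``100 * sum(min(a, b)) / sum(max(a, b))`` over the upper triangle.
``contact`` (default)
    Each normalized map is binarized at a distance threshold (by default the
    10th percentile of the pooled off-diagonal normalized distances) and the
    plain Jaccard index of the two contact sets is returned.  The default
    threshold quantile was calibrated (``scripts/calibrate_imj.py``) so that
    pairs of independent self-avoiding random-walk conformations score about
    30%, the accepted cell-to-cell variability baseline for this statistic.

Mean-off-diagonal normalization makes both variants invariant to uniform
scaling, so image-derived models (nm) and contact-matrix embeddings
(arbitrary units) are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr

#: Default contact-threshold quantile for the ``contact`` IMJ variant.
DEFAULT_CONTACT_QUANTILE = 0.10


@dataclass
class DistanceMap:
    """Square symmetric matrix of pairwise bead distances (nm)."""

    matrix: np.ndarray
    labels: np.ndarray | None = None
    bin_bp: int | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("distance map must be square")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def _as_matrix(m) -> np.ndarray:
    if isinstance(m, DistanceMap):
        return m.matrix
    return np.asarray(m, dtype=float)


def distance_map(model) -> DistanceMap:
    """Pairwise Euclidean distance map of a bead model (or (n,3) array)."""
    beads = getattr(model, "beads", model)
    beads = np.asarray(beads, dtype=float)
    if len(beads) < 2:
        raise ValueError("need at least 2 beads for a distance map")
    return DistanceMap(squareform(pdist(beads)))


def average_distance_map(maps) -> DistanceMap:
    """Element-wise mean of a collection of same-sized distance maps."""
    mats = [_as_matrix(m) for m in maps]
    if not mats:
        raise ValueError("need at least one map")
    shape = mats[0].shape
    for m in mats:
        if m.shape != shape:
            raise ValueError(f"dimension mismatch: {m.shape} vs {shape}")
    return DistanceMap(np.mean(mats, axis=0))


def _offdiag(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def imj(
    map_a,
    map_b,
    variant: str = "contact",
    threshold_quantile: float = DEFAULT_CONTACT_QUANTILE,
    threshold: float | None = None,
    normalize: bool = True,
) -> float:
    """Modified Jaccard Index between two distance maps, in percent [0, 100].

    Parameters
    ----------
    map_a, map_b : DistanceMap or ndarray
        Same-dimension square distance matrices.
    variant : {"contact", "weighted"}
        See module docstring.
    threshold_quantile : float
        Contact variant: quantile of the pooled off-diagonal (normalized)
        distances below which a pair counts as a contact.
    threshold : float, optional
        Contact variant: absolute distance threshold overriding the
        quantile rule (interpreted on the normalized scale when
        ``normalize`` is on).
    normalize : bool
        Divide each map by its mean off-diagonal entry first (makes the
        score scale-invariant).
    """
    a = _as_matrix(map_a)
    b = _as_matrix(map_b)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    va, vb = _offdiag(a), _offdiag(b)
    za, zb = not va.any(), not vb.any()
    if za and zb:
        return 100.0
    if za or zb:
        return 0.0
    if normalize:
        va = va / va.mean()
        vb = vb / vb.mean()
    if variant == "weighted":
        return float(100.0 * np.minimum(va, vb).sum() / np.maximum(va, vb).sum())
    if variant == "contact":
        t = threshold if threshold is not None else float(
            np.quantile(np.concatenate([va, vb]), threshold_quantile)
        )
        ca, cb = va <= t, vb <= t
        union = int(np.sum(ca | cb))
        if union == 0:
            return 100.0
        return float(100.0 * np.sum(ca & cb) / union)
    raise ValueError(f"unknown IMJ variant {variant!r}")


def imj_orientation_free(map_a, map_b, **imj_kwargs) -> float:
    """IMJ maximized over the global path-orientation ambiguity.

    Reversing a chain's bead order flips its distance map about the
    anti-diagonal; since single-color imaging cannot orient a path, two
    structures are compared in whichever relative orientation matches
    better.
    """
    a = _as_matrix(map_a)
    flipped = a[::-1, ::-1]
    return max(imj(a, map_b, **imj_kwargs), imj(flipped, map_b, **imj_kwargs))


def pairwise_imj(models, **imj_kwargs) -> tuple[np.ndarray, float]:
    """All-pairs IMJ between models (or distance maps).

    Returns the symmetric similarity matrix (100 on the diagonal) and the
    mean of the off-diagonal pair scores.
    """
    maps = []
    for m in models:
        if isinstance(m, (DistanceMap, np.ndarray)):
            maps.append(_as_matrix(m))
        else:
            maps.append(distance_map(m).matrix)
    k = len(maps)
    if k < 2:
        raise ValueError("need at least 2 models")
    n = maps[0].shape[0]
    for m in maps:
        if m.shape[0] != n:
            raise ValueError(f"mismatched bead counts: {m.shape[0]} vs {n}")
    sim = np.full((k, k), 100.0)
    scores = []
    for i in range(k):
        for j in range(i + 1, k):
            s = imj(maps[i], maps[j], **imj_kwargs)
            sim[i, j] = sim[j, i] = s
            scores.append(s)
    return sim, float(np.mean(scores))


def kabsch_align(model_a, model_b, allow_reflection: bool = False):
    """Optimal rigid superposition of ``model_b`` onto ``model_a``.

    Returns ``(aligned_b_coords, rmsd_nm)``.  Reflection is excluded by
    default so chirality is preserved.
    """
    A = np.asarray(getattr(model_a, "beads", model_a), dtype=float)
    B = np.asarray(getattr(model_b, "beads", model_b), dtype=float)
    if A.shape != B.shape:
        raise ValueError("models must have equal bead counts")
    if len(A) < 3:
        raise ValueError("need at least 3 beads for alignment")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    P, Q = B - cb, A - ca
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d if not allow_reflection else 1.0])
    if allow_reflection:
        R = Vt.T @ U.T
    else:
        R = Vt.T @ D @ U.T
    aligned = P @ R.T + ca
    rmsd = float(np.sqrt(np.mean(np.sum((aligned - A) ** 2, axis=1))))
    return aligned, rmsd


@dataclass
class OrderRecoveryResult:
    """Spearman comparison of a true vs an inferred bead visiting order.

    ``rho`` is the absolute correlation after resolving the global
    orientation ambiguity (a reversed path is an equally valid
    reconstruction); ``orientation`` records which orientation matched.
    """

    rho: float
    p_value: float
    significant: bool
    orientation: str


def order_recovery(true_order, inferred_order, alpha: float = 0.05) -> OrderRecoveryResult:
    """Spearman rank correlation between two visiting orders of one label set.

    Both arguments are sequences of the same labels; positions of each label
    in the two orders are rank-correlated with a two-sided test.  Since a
    reversed path is geometrically equivalent, the absolute correlation is
    reported (reversal flips the sign but not the p-value).
    """
    t = np.asarray(true_order)
    f = np.asarray(inferred_order)
    if t.shape != f.shape:
        raise ValueError("orders must have equal length")
    if len(t) < 3:
        raise ValueError("need at least 3 elements")
    if set(t.tolist()) != set(f.tolist()):
        raise ValueError("orders must be permutations of the same labels")
    pos_t = {lab: i for i, lab in enumerate(t.tolist())}
    ranks_true = np.array([pos_t[lab] for lab in f.tolist()])
    rho, p = spearmanr(ranks_true, np.arange(len(f)))
    rho = float(rho)
    p = float(p)
    return OrderRecoveryResult(
        rho=abs(rho),
        p_value=p,
        significant=bool(p < alpha),
        orientation="forward" if rho >= 0 else "reversed",
    )


def bin_distance_map(dmap, bead_bp: float, bin_bp: int = 100) -> DistanceMap:
    """Coarsen a distance map to a common genomic bin size.

    Beads are grouped into consecutive bins of ``bin_bp / bead_bp`` beads and
    entries averaged per bin pair; lets maps of models with different bead
    counts be compared at a shared resolution.
    """
    m = _as_matrix(dmap)
    per = max(1, int(round(bin_bp / bead_bp)))
    n = m.shape[0]
    nb = n // per
    if nb < 2:
        raise ValueError("bin size too coarse for this map")
    trimmed = m[: nb * per, : nb * per]
    binned = trimmed.reshape(nb, per, nb, per).mean(axis=(1, 3))
    np.fill_diagonal(binned, 0.0)
    return DistanceMap(binned, bin_bp=bin_bp)


def save_heatmap(dmap, path, title: str | None = None, cmap: str = "RdBu") -> None:
    """Render a distance map as a PNG heatmap (red = near, blue = far)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    m = _as_matrix(dmap)
    fig, ax = plt.subplots(figsize=(5, 4.2))
    im = ax.imshow(m, cmap=cmap, origin="upper")
    fig.colorbar(im, ax=ax, label="distance [nm]")
    ax.set_xlabel("bead")
    ax.set_ylabel("bead")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
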