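"""Ordering unlabeled 3D probe positions into a polymer path.

Single-color imaging gives an unordered cloud of oligo positions; because
probes tile the fiber contiguously, the genomic order is recovered as a
shortest visiting path.  The solver is the classic greedy path-merging
heuristic: every point starts as a singleton path and the two closest
joinable path endpoints are repeatedly connected until a single Hamiltonian
path remains.  Greedy solutions are then improved by local search (2-opt
segment reversals plus single-point relocations), and finally the path is
closed into a tour and the longest tour edge is deleted, which leaves an
open path between the two mutually most distant endpoints.

All steps are deterministic given the input point order: candidate edges are
processed in (distance, i, j) lexicographic order and local search applies
the single best improving move per scan.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import pdist, squareform


@dataclass
class PathOrdering:
    """A visiting order over a fixed point set.

    Attributes
    ----------
    order : ndarray of int
        Permutation of ``0..n-1``; ``points[order]`` walks the path.
    total_length : float
        Sum of consecutive Euclidean edge lengths under ``order`` (nm).
    opened_at : int or None
        Index (into the pre-opening cyclic order) of the removed longest
        edge, if the path has been opened; ``None`` otherwise.
    """

    order: np.ndarray
    total_length: float
    opened_at: int | None = None


def path_length(points: np.ndarray, order: np.ndarray) -> float:
    """Total Euclidean length of the open path ``points[order]``."""
    walk = np.asarray(points, dtype=float)[np.asarray(order)]
    return float(np.linalg.norm(np.diff(walk, axis=0), axis=1).sum())


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"expected an (n, 3) point array, got shape {pts.shape}")
    if not np.isfinite(pts).all():
        raise ValueError("points must be finite")
    return pts


def greedy_tsp_path(points) -> PathOrdering:
    """Build a Hamiltonian path by greedy path merging.

    Candidate edges are sorted by (length, i, j); an edge is accepted when
    both endpoints still have degree < 2 and lie in different path
    fragments.  This realizes "repeatedly connect the two closest
    disconnected paths" with a deterministic tie-break.
    """
    pts = _as_points(points)
    n = len(pts)
    if n < 2:
        raise ValueError("need at least 2 points to build a path")
    if n == 2:
        order = np.array([0, 1])
        return PathOrdering(order, path_length(pts, order))

    dist = pdist(pts)
    ii, jj = np.triu_indices(n, k=1)
    # lexsort keys: last key is primary
    edge_rank = np.lexsort((jj, ii, dist))

    parent = np.arange(n)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    degree = np.zeros(n, dtype=int)
    neighbors: list[list[int]] = [[] for _ in range(n)]
    accepted = 0
    for k in edge_rank:
        a, b = int(ii[k]), int(jj[k])
        if degree[a] >= 2 or degree[b] >= 2:
            continue
        ra, rb = find(a), find(b)
        if ra == rb:
            continue
        parent[ra] = rb
        degree[a] += 1
        degree[b] += 1
        neighbors[a].append(b)
        neighbors[b].append(a)
        accepted += 1
        if accepted == n - 1:
            break

    # walk from the smallest-index endpoint
    endpoints = np.flatnonzero(degree == 1)
    start = int(endpoints.min())
    order = np.empty(n, dtype=int)
    order[0] = start
    prev, cur = -1, start
    for pos in range(1, n):
        nxt = neighbors[cur][0] if neighbors[cur][0] != prev else neighbors[cur][1]
        order[pos] = nxt
        prev, cur = cur, nxt
    return PathOrdering(order, path_length(pts, order))


def _best_two_opt(Dp: np.ndarray, e: np.ndarray):
    """Best 2-opt style reversal on an open path.

    Returns ``(delta, i, j)`` for reversing positions ``i..j`` inclusive, or
    ``None`` if no improving reversal exists.  Prefix (i=0) and suffix
    (j=n-1) reversals only replace one edge and are handled separately.
    """
    n = len(e) + 1
    best = (0.0, -1, -1)
    if n >= 4:
        idx = np.arange(1, n - 1)
        gain_new = Dp[idx - 1][:, idx] + Dp[np.ix_(idx, idx + 1)]
        gain_old = e[idx - 1][:, None] + e[idx][None, :]
        delta = gain_new - gain_old
        delta[np.tril_indices(len(idx), k=-1)] = np.inf
        k = int(np.argmin(delta))
        r, c = divmod(k, len(idx))
        if delta[r, c] < best[0]:
            best = (float(delta[r, c]), int(idx[r]), int(idx[c]))
    # prefix reversal p[0..j]: replaces edge (j, j+1) by (old p[0], p[j+1])
    j = np.arange(0, n - 1)
    d_pref = Dp[0, j + 1] - e[j]
    k = int(np.argmin(d_pref))
    if d_pref[k] < best[0]:
        best = (float(d_pref[k]), 0, int(j[k]))
    # suffix reversal p[i..n-1]: replaces edge (i-1, i) by (p[i-1], old p[n-1])
    i = np.arange(1, n)
    d_suf = Dp[n - 1, i - 1] - e[i - 1]
    k = int(np.argmin(d_suf))
    if d_suf[k] < best[0]:
        best = (float(d_suf[k]), int(i[k]), n - 1)
    return best if best[1] >= 0 else None


def _best_relocation(Dp: np.ndarray, e: np.ndarray):
    """Best single-point relocation; returns ``(delta, k, insert_pos)`` or None.

    ``insert_pos`` is the position (in the path with point k removed) before
    which point k is reinserted.
    """
    n = len(e) + 1
    if n < 4:
        return None
    gain = np.empty(n)
    gain[0] = e[0]
    gain[-1] = e[-1]
    mid = np.arange(1, n - 1)
    gain[mid] = e[mid - 1] + e[mid] - Dp[mid - 1, mid + 1]

    # insertion into edge (i, i+1): cost D(k,i) + D(k,i+1) - e[i]
    cost = Dp[:, :-1] + Dp[:, 1:] - e[None, :]
    kk = np.arange(n)
    for off in (-1, 0):  # edges adjacent to k are not valid targets
        cols = kk + off
        ok = (cols >= 0) & (cols <= n - 2)
        cost[kk[ok], cols[ok]] = np.inf
    delta = cost - gain[:, None]
    best = (0.0, -1, -1)
    idx = int(np.argmin(delta))
    r, c = divmod(idx, n - 1)
    if delta[r, c] < best[0]:
        # removing k shifts edge positions: insertion before position c+1
        insert = c + 1 if c + 1 <= r else c + 1
        best = (float(delta[r, c]), r, insert)
    # insertion at the front / back of the path
    front = Dp[:, 0] - gain
    front[0] = front[1] = np.inf
    k = int(np.argmin(front))
    if front[k] < best[0]:
        best = (float(front[k]), k, 0)
    back = Dp[:, n - 1] - gain
    back[n - 1] = back[n - 2] = np.inf
    k = int(np.argmin(back))
    if back[k] < best[0]:
        best = (float(back[k]), k, n)
    return best if best[1] >= 0 else None


def optimize_path(ordering: PathOrdering, points, max_sweeps: int = 1000) -> PathOrdering:
    """Improve a path by local search; total length never increases.

    Each sweep applies the single best improving move among all 2-opt
    reversals and single-point relocations, until convergence or
    ``max_sweeps`` moves.
    """
    pts = _as_points(points)
    n = len(pts)
    p = np.array(ordering.order, dtype=int).copy()
    if n < 3:
        return PathOrdering(p, path_length(pts, p), ordering.opened_at)
    D = squareform(pdist(pts))
    eps = 1e-12
    for _ in range(max_sweeps):
        Dp = D[np.ix_(p, p)]
        e = Dp[np.arange(n - 1), np.arange(1, n)]
        rev = _best_two_opt(Dp, e)
        rel = _best_relocation(Dp, e)
        d_rev = rev[0] if rev else 0.0
        d_rel = rel[0] if rel else 0.0
        if min(d_rev, d_rel) >= -eps:
            break
        if d_rev <= d_rel:
            _, i, j = rev
            p[i : j + 1] = p[i : j + 1][::-1]
        else:
            _, k, ins = rel
            moved = p[k]
            q = np.delete(p, k)
            ins_adj = ins if ins <= k else ins - 1
            p = np.insert(q, ins_adj, moved)
    return PathOrdering(p, path_length(pts, p), ordering.opened_at)


def open_path_by_longest_edge(
    ordering: PathOrdering, points, treat_as_cycle: bool = True
) -> PathOrdering:
    """Delete the longest connection so the path ends at its most distant pair.

    With ``treat_as_cycle`` (default), the path is closed into a tour and the
    single longest tour edge removed; the resulting open path starts just
    after the removed edge.  The first-encountered maximum is removed when
    tied.  With ``treat_as_cycle=False`` the longest interior edge is only
    recorded in ``opened_at`` (diagnostic), the order is unchanged.
    """
    pts = _as_points(points)
    p = np.array(ordering.order, dtype=int)
    n = len(p)
    walk = pts[p]
    interior = np.linalg.norm(np.diff(walk, axis=0), axis=1)
    if not treat_as_cycle:
        k = int(np.argmax(interior)) if n > 1 else None
        return PathOrdering(p, path_length(pts, p), opened_at=k)
    closing = float(np.linalg.norm(walk[-1] - walk[0]))
    cycle_edges = np.append(interior, closing)
    k = int(np.argmax(cycle_edges))
    new_order = np.roll(p, -(k + 1))
    return PathOrdering(new_order, path_length(pts, new_order), opened_at=k)


def reconstruct_path(points, max_sweeps: int = 1000) -> PathOrdering:
    """Full ordering pipeline: greedy merge, local search, longest-edge opening."""
    ordering = greedy_tsp_path(points)
    ordering = optimize_path(ordering, points, max_sweeps=max_sweeps)
    return open_path_by_longest_edge(ordering, points, treat_as_cycle=True)
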