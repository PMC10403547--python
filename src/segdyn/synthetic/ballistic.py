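"""Ballistic cluster merging: a minimal model of coherent collective motion.

Cells are equal disks in a periodic 2D box.  Cells sharing a cluster move
rigidly with one velocity vector of common speed v and persistent random
direction; when disks of two clusters touch, the clusters merge, keep
their member positions, and draw a fresh direction.  Aggregation only
merges, never splits, so the cluster count is non-increasing and the mean
cluster linear size (√ of the mean cluster area) grows — for
mass-independent speed the kinetic theory of coherently moving clusters
gives linear growth, L ~ t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree


@dataclass
class BallisticState:
    """Snapshot of the disk population and its cluster partition."""

    positions: np.ndarray  # (n, 2) µm
    radii: np.ndarray  # (n,) µm
    cluster_ids: np.ndarray  # (n,) int, contiguous relabelling not required
    types: np.ndarray  # (n,) int cell-type labels
    velocities: dict[int, np.ndarray]  # cluster id -> (2,) µm/h
    box: float  # µm, periodic square
    time: float  # h
    seed: int

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.cluster_ids))

    def cluster_sizes(self) -> np.ndarray:
        """Member counts per cluster."""
        _, counts = np.unique(self.cluster_ids, return_counts=True)
        return counts


def mean_cluster_size(state: BallisticState) -> float:
    """Mean cluster linear size: √(mean cluster area) in µm.

    The cluster area is its total disk area, so the mean area is total
    area over the number of clusters.  Members can overlap by at most one
    step of relative approach (2·speed·dt = radius), so the summed disk
    area overstates the geometric footprint by a bounded, size-independent
    factor that cancels in log–log growth slopes.
    """
    total_area = float(np.pi * (state.radii**2).sum())
    return float(np.sqrt(total_area / state.n_clusters))


class _UnionFind:
    def __init__(self, n: int):
        self.parent = np.arange(n)

    def find(self, i: int) -> int:
        p = self.parent
        while p[i] != i:
            p[i] = p[p[i]]
            i = p[i]
        return i

    def union(self, i: int, j: int) -> bool:
        ri, rj = self.find(i), self.find(j)
        if ri == rj:
            return False
        self.parent[rj] = ri
        return True


def _place_disks(
    n_cells: int, radius: float, box: float, rng: np.random.Generator, retry_cap: int
) -> np.ndarray:
    """Random sequential placement of non-overlapping disks."""
    pos = np.empty((n_cells, 2))
    placed = 0
    tries = 0
    while placed < n_cells:
        cand = rng.uniform(0.0, box, size=2)
        if placed:
            d = np.abs(pos[:placed] - cand)
            d = np.minimum(d, box - d)  # periodic minimum image
            if np.any((d**2).sum(axis=1) < (2 * radius) ** 2):
                tries += 1
                if tries > retry_cap:
                    raise RuntimeError(
                        "could not place non-overlapping disks; lower the "
                        "packing fraction"
                    )
                continue
        pos[placed] = cand
        placed += 1
    return pos


def simulate_ballistic_segregation(
    n_cells: int,
    cell_radius: float,
    speed: float,
    box: float,
    snapshot_times: tuple[float, ...],
    seed: int,
    n_types: int = 1,
    retry_cap: int = 100_000,
) -> list[BallisticState]:
    """Simulate ballistic motion with merge-on-contact, 2D periodic box.

    Disks advance on a fixed time grid (step = radius / 2 of travel) so a
    trajectory is a pure function of the seed, independent of the
    snapshot schedule; each requested time yields the state at the first
    grid step reaching it.  Merged clusters move rigidly; the merged
    velocity direction is redrawn uniformly.  With ``n_types > 1`` cells
    get round-robin type labels and only same-type clusters merge.
    """
    packing = n_cells * np.pi * cell_radius**2 / box**2
    if packing > 0.3:
        raise ValueError(f"initial packing fraction {packing:.2f} exceeds 0.3")
    if speed < 0 or cell_radius <= 0 or box <= 0:
        raise ValueError("speed, radius and box must be positive")
    snaps = sorted(float(t) for t in snapshot_times)
    if snaps and snaps[0] < 0:
        raise ValueError("snapshot times must be non-negative")

    ss = np.random.SeedSequence(seed).spawn(2)
    rng_init = np.random.default_rng(ss[0])
    rng_dir = np.random.default_rng(ss[1])

    pos = _place_disks(n_cells, cell_radius, box, rng_init, retry_cap)
    radii = np.full(n_cells, float(cell_radius))
    types = np.arange(n_cells) % n_types + 1
    cluster_ids = np.arange(n_cells)
    angles = rng_dir.uniform(0, 2 * np.pi, size=n_cells)
    # Per-cell velocity; cells of one cluster always hold identical rows.
    vcell = speed * np.column_stack([np.cos(angles), np.sin(angles)])

    dt = cell_radius / (2.0 * speed) if speed > 0 else np.inf
    contact = 2.0 * cell_radius

    def snapshot(t: float) -> BallisticState:
        vel = {
            int(c): vcell[np.flatnonzero(cluster_ids == c)[0]].copy()
            for c in np.unique(cluster_ids)
        }
        return BallisticState(
            positions=pos.copy(),
            radii=radii.copy(),
            cluster_ids=cluster_ids.copy(),
            types=types.copy(),
            velocities=vel,
            box=box,
            time=t,
            seed=seed,
        )

    out: list[BallisticState] = []
    t = 0.0
    si = 0
    while si < len(snaps) and snaps[si] <= t:
        out.append(snapshot(t))
        si += 1
    while si < len(snaps):
        if np.isinf(dt):  # zero speed: nothing moves or merges
            out.append(snapshot(snaps[si]))
            si += 1
            continue
        pos = (pos + vcell * dt) % box
        t += dt
        tree = cKDTree(pos, boxsize=box)
        pairs = tree.query_pairs(contact - 1e-9, output_type="ndarray")
        if len(pairs):
            keep = (cluster_ids[pairs[:, 0]] != cluster_ids[pairs[:, 1]]) & (
                types[pairs[:, 0]] == types[pairs[:, 1]]
            )
            pairs = pairs[keep]
        if len(pairs):
            # Union-find over cluster labels, not cells.
            old_unique, inv = np.unique(cluster_ids, return_inverse=True)
            uf = _UnionFind(len(old_unique))
            for i, j in pairs:
                uf.union(int(inv[i]), int(inv[j]))
            roots = np.array([uf.find(k) for k in range(len(old_unique))])
            cluster_ids = old_unique[roots][inv]
            # Redraw one direction per newly merged cluster, in ascending
            # root order for determinism.
            root_vals, root_counts = np.unique(roots, return_counts=True)
            for rv, rc in zip(root_vals, root_counts):
                if rc > 1:
                    a = rng_dir.uniform(0, 2 * np.pi)
                    v_new = speed * np.array([np.cos(a), np.sin(a)])
                    vcell[cluster_ids == old_unique[rv]] = v_new
        while si < len(snaps) and snaps[si] <= t:
            out.append(snapshot(t))
            si += 1
    return out
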