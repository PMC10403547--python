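"""Conserved lattice exchange dynamics (Kawasaki-type demixing).

A minimal statistical-physics embodiment of diffusive cell segregation: a
2D or 3D grid of labels (0 = medium, 1 = type A, 2 = type B) evolves by
Metropolis exchange of nearest-neighbour unlike pairs, which conserves the
composition exactly.  The energy is a sum of symmetric pairwise contact
energies J(s, t) over nearest-neighbour bonds, with J(s, s) = 0; the
J(cell, medium) entries play the role of cell–medium cortical tensions
and J(A, B) of the heterotypic interfacial tension, so differential
values reproduce demixing and envelopment.  Below the ordering
temperature a symmetric two-species mixture coarsens diffusively, with
homotypic domain size growing as L ~ t^{1/3}.

One sweep is (number of sites) attempted exchanges.  All randomness is
drawn from a single seeded stream consumed at a fixed rate of three
variates per attempt, so the snapshot schedule never alters a trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit


@dataclass
class LatticeState:
    """Snapshot of the label grid with its dynamical parameters."""

    labels: np.ndarray
    energy_table: np.ndarray
    temperature: float
    sweep_count: int
    seed: int
    periodic: bool = True

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.energy_table = np.asarray(self.energy_table, dtype=np.float64)
        _validate_energy_table(self.energy_table)
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape

    @property
    def composition(self) -> dict[int, int]:
        vals, counts = np.unique(self.labels, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, counts)}


@dataclass
class LatticeConfig:
    """Parameters of one exchange-dynamics run.

    ``composition`` maps label → site count and must sum to the grid
    size.  ``snapshot_sweeps`` are the sweep counts at which states are
    returned.  ``init`` is ``random`` (uniform shuffle) or ``aggregate``
    (cells packed in a central ball, medium outside — the configuration
    of an aggregate suspended in medium).
    """

    shape: tuple[int, ...]
    composition: dict[int, int]
    energy_table: np.ndarray
    temperature: float
    snapshot_sweeps: tuple[int, ...]
    seed: int
    include_medium: bool = False
    periodic: bool = True
    init: str = "random"


def _validate_energy_table(J: np.ndarray) -> None:
    if J.shape != (3, 3):
        raise ValueError("energy_table must be 3x3 (medium, type A, type B)")
    if not np.allclose(J, J.T):
        raise ValueError("energy_table must be symmetric")
    if not np.allclose(np.diag(J), 0):
        raise ValueError("energy_table must have zero diagonal")


def _neighbor_table(shape: tuple[int, ...], periodic: bool) -> np.ndarray:
    """(n_sites, 2*ndim) flat neighbour indices; -1 marks a missing
    neighbour at a non-periodic boundary."""
    ndim = len(shape)
    n = int(np.prod(shape))
    idx = np.arange(n).reshape(shape)
    cols = []
    for axis in range(ndim):
        for shift in (1, -1):
            rolled = np.roll(idx, shift, axis=axis)
            if not periodic:
                rolled = rolled.copy()
                edge = [slice(None)] * ndim
                edge[axis] = 0 if shift == 1 else -1
                rolled[tuple(edge)] = -1
            cols.append(rolled.ravel())
    return np.ascontiguousarray(np.stack(cols, axis=1).astype(np.int64))


@njit(cache=True)
def _exchange_kernel(labels, nbrs, J, T, sites, dirs, us):  # pragma: no cover
    n_nbrs = nbrs.shape[1]
    for a in range(sites.shape[0]):
        i = sites[a]
        j = nbrs[i, dirs[a]]
        if j < 0:
            continue
        si = labels[i]
        sj = labels[j]
        if si == sj:
            continue
        dE = 0.0
        for k in range(n_nbrs):
            m = nbrs[i, k]
            if m >= 0 and m != j:
                dE += J[sj, labels[m]] - J[si, labels[m]]
            m = nbrs[j, k]
            if m >= 0 and m != i:
                dE += J[si, labels[m]] - J[sj, labels[m]]
        if dE <= 0.0 or us[a] < np.exp(-dE / T):
            labels[i] = sj
            labels[j] = si


def _initial_labels(config: LatticeConfig, rng: np.random.Generator) -> np.ndarray:
    n = int(np.prod(config.shape))
    total = sum(config.composition.values())
    if total != n:
        raise ValueError(f"composition sums to {total}, grid has {n} sites")
    if any(v not in (0, 1, 2) for v in config.composition):
        raise ValueError("labels must be 0 (medium), 1 (type A) or 2 (type B)")
    pool = np.concatenate(
        [np.full(c, lab, dtype=np.int8) for lab, c in sorted(config.composition.items())]
    )
    if config.init == "random":
        rng.shuffle(pool)
        return pool.reshape(config.shape)
    if config.init == "aggregate":
        # Cells occupy the sites closest to the grid centre, medium outside;
        # cell types are shuffled within the aggregate ball.
        center = (np.asarray(config.shape) - 1) / 2.0
        grids = np.meshgrid(*[np.arange(s) for s in config.shape], indexing="ij")
        dist2 = sum((g - c) ** 2 for g, c in zip(grids, center)).ravel()
        order = np.argsort(dist2, kind="stable")
        cells = np.concatenate(
            [
                np.full(c, lab, dtype=np.int8)
                for lab, c in sorted(config.composition.items())
                if lab > 0
            ]
        )
        rng.shuffle(cells)
        labels = np.zeros(int(np.prod(config.shape)), dtype=np.int8)
        labels[order[: len(cells)]] = cells
        return labels.reshape(config.shape)
    raise ValueError(f"unknown init {config.init!r}")


def simulate_lattice_segregation(config: LatticeConfig) -> list[LatticeState]:
    """Run Metropolis exchange dynamics, returning the requested snapshots.

    At each attempt a random site and a random neighbour direction are
    drawn; if the two labels differ they are swapped with probability
    min(1, exp(−ΔE/T)).  Composition is conserved exactly, so every
    snapshot has identical per-label counts.
    """
    _validate_energy_table(np.asarray(config.energy_table, dtype=np.float64))
    if config.temperature <= 0:
        raise ValueError("temperature must be > 0")
    snaps = sorted(int(s) for s in config.snapshot_sweeps)
    if any(s < 0 for s in snaps):
        raise ValueError("snapshot sweeps must be non-negative")
    # Independent child streams: initialisation, site, direction and
    # uniform draws.  Each stream's state depends only on how many attempts
    # have been simulated, never on the snapshot schedule or chunking.
    ss = np.random.SeedSequence(config.seed).spawn(4)
    rng_init = np.random.default_rng(ss[0])
    rng_site = np.random.default_rng(ss[1])
    rng_dir = np.random.default_rng(ss[2])
    rng_u = np.random.default_rng(ss[3])
    labels = _initial_labels(config, rng_init).ravel()
    nbrs = _neighbor_table(config.shape, config.periodic)
    J = np.ascontiguousarray(config.energy_table, dtype=np.float64)
    n_sites = labels.size
    n_dirs = nbrs.shape[1]

    out: list[LatticeState] = []
    done = 0
    chunk_attempts = 1 << 20
    for target in snaps:
        remaining = (target - done) * n_sites
        while remaining > 0:
            m = min(remaining, chunk_attempts)
            sites = rng_site.integers(0, n_sites, size=m)
            dirs = rng_dir.integers(0, n_dirs, size=m)
            us = rng_u.random(size=m)
            _exchange_kernel(labels, nbrs, J, config.temperature, sites, dirs, us)
            remaining -= m
        done = target
        out.append(
            LatticeState(
                labels=labels.reshape(config.shape).copy(),
                energy_table=J,
                temperature=config.temperature,
                sweep_count=target,
                seed=config.seed,
                periodic=config.periodic,
            )
        )
    return out


def make_aggregate_config(
    shape: tuple[int, ...] = (48, 48),
    cell_fraction: float = 0.4,
    J_A_medium: float = 1.6,
    J_B_medium: float = 0.8,
    J_AB: float = 0.5,
    temperature: float = 0.5,
    snapshot_sweeps: tuple[int, ...] = (3000,),
    seed: int = 0,
) -> LatticeConfig:
    """Convenience config for envelopment runs: a mixed A+B aggregate in
    medium, fixed (non-periodic) frame, equal A/B counts.

    With J(A, medium) > J(B, medium) + J(A, B) the A phase avoids the
    medium and ends up engulfed by B (lower effective surface tension
    envelops), mirroring the ordering of tissue surface tensions.
    """
    n = int(np.prod(shape))
    n_cells = int(round(cell_fraction * n))
    n_a = n_cells // 2
    n_b = n_cells - n_a
    J = np.array(
        [
            [0.0, J_A_medium, J_B_medium],
            [J_A_medium, 0.0, J_AB],
            [J_B_medium, J_AB, 0.0],
        ]
    )
    return LatticeConfig(
        shape=shape,
        composition={0: n - n_cells, 1: n_a, 2: n_b},
        energy_table=J,
        temperature=temperature,
        snapshot_sweeps=snapshot_sweeps,
        seed=seed,
        include_medium=True,
        periodic=False,
        init="aggregate",
    )
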