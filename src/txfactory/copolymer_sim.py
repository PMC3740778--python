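"""Toy lattice model of chromatin as a rod-coil multi-block copolymer.

Chromatin carrying collinear active transcription units is modelled as a
single self-avoiding chain on the simple cubic lattice, one bead per Kb.
Stiff hyperacetylated blocks ("rods", 15 beads by default, 8 per cluster,
separated by 30-bead coils, with 670-bead inter-cluster coil spacers giving a
12% rod fraction) attract each other through a non-bonded contact energy
``-epsilon_rr`` per rod-rod lattice contact, and pay a bending penalty
``kappa_rod`` for every non-collinear bond pair centred on a rod bead.
Metropolis Monte Carlo at kT = 1 with corner-flip, crankshaft and
end-rotation moves (optionally reptation) drives microphase separation of the
rod blocks into compact microdomains, the computational analogue of H4K16ac
transcription-factory foci.  Treatments map onto the contact energy:
formamide (a solvent for the self-assembled phase) sets epsilon to zero,
while DRB, heat shock and NaCl extraction leave it unchanged.

All conclusions drawn from this model are qualitative analogues of the
microscopy observations, not quantitative predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

__all__ = [
    "BlockSpec",
    "SimParams",
    "Conformation",
    "DomainMetrics",
    "MCResult",
    "default_block_spec",
    "build_chain",
    "energy",
    "run_mc",
    "domain_metrics",
    "apply_treatment",
    "TREATMENTS",
]


@dataclass(frozen=True)
class BlockSpec:
    """Ordered rod/coil block composition of the chain."""

    blocks: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("at least one block is required")
        for kind, n in self.blocks:
            if kind not in ("rod", "coil"):
                raise ValueError(f"unknown block kind {kind!r}")
            if n < 1:
                raise ValueError("block sizes must be positive integers")

    @property
    def n_beads(self) -> int:
        return sum(n for _, n in self.blocks)

    @property
    def rod_fraction(self) -> float:
        rod = sum(n for kind, n in self.blocks if kind == "rod")
        return rod / self.n_beads

    def labels(self) -> np.ndarray:
        """Per-bead rod flag (True = rod)."""
        out = np.empty(self.n_beads, dtype=np.bool_)
        i = 0
        for kind, n in self.blocks:
            out[i : i + n] = kind == "rod"
            i += n
        return out


def default_block_spec(
    n_clusters: int = 1,
    rod_beads: int = 15,
    intra_coil_beads: int = 30,
    rods_per_cluster: int = 8,
    spacer_coil_beads: int = 670,
) -> BlockSpec:
    """The calibrated composition: 15-bead rods (1 bead = 1 Kb), 30-bead
    intra-cluster coils, 8 rods per cluster and a 670-bead spacer after each
    cluster, giving a rod fraction of 0.12."""
    blocks: list[tuple[str, int]] = []
    for _ in range(n_clusters):
        for r in range(rods_per_cluster):
            blocks.append(("rod", rod_beads))
            if r < rods_per_cluster - 1:
                blocks.append(("coil", intra_coil_beads))
        blocks.append(("coil", spacer_coil_beads))
    return BlockSpec(blocks=tuple(blocks))


@dataclass(frozen=True)
class SimParams:
    """Monte-Carlo settings.  Energies are in units of kT (temperature 1)."""

    lattice_size: tuple[int, int, int] | None = None  # None -> sized from the chain
    epsilon_rr: float = 3.0
    kappa_rod: float = 2.0
    n_steps: int = 1_000_000
    move_set: tuple[str, ...] = ("local_crankshaft", "end_rotation")
    record_interval: int = 10_000
    snapshot_interval: int = 0  # 0 -> keep only the final conformation
    seed: int | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.epsilon_rr < 0 or self.kappa_rod < 0:
            raise ValueError("epsilon_rr and kappa_rod must be non-negative")
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        for m in self.move_set:
            if m not in ("local_crankshaft", "end_rotation", "reptation"):
                raise ValueError(f"unknown move {m!r}")
        if not self.move_set:
            raise ValueError("the move set must not be empty")
        if self.seed is None:
            raise ValueError("a seed is required")
        if self.record_interval < 1:
            raise ValueError("record_interval must be >= 1")


@dataclass
class Conformation:
    """Self-avoiding chain on the cubic lattice with per-bead rod labels."""

    coords: np.ndarray  # (n, 3) integer lattice positions
    labels: np.ndarray  # (n,) bool, True = rod
    lattice_size: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.int64)
        self.labels = np.asarray(self.labels, dtype=np.bool_)
        if self.coords.shape != (self.labels.size, 3):
            raise ValueError("coords must be (n_beads, 3)")
        self.validate()

    def validate(self) -> None:
        if len({tuple(p) for p in self.coords}) != len(self.coords):
            raise ValueError("conformation is not self-avoiding")
        d = np.abs(np.diff(self.coords, axis=0)).sum(axis=1)
        if np.any(d != 1):
            raise ValueError("consecutive beads must be lattice-adjacent")
        lo = self.coords.min(axis=0)
        hi = self.coords.max(axis=0)
        if np.any(lo < 0) or np.any(hi >= np.asarray(self.lattice_size)):
            raise ValueError("chain leaves the lattice")


def build_chain(spec: BlockSpec, lattice_size: tuple[int, int, int] | None = None) -> Conformation:
    """Extended serpentine (zig-zag) initial configuration.

    The default lattice is a cube with at least eight sites per bead, so the
    chain has room to relax.
    """
    n = spec.n_beads
    if lattice_size is None:
        side = max(10, int(np.ceil((8 * n) ** (1 / 3))))
        lattice_size = (side, side, side)
    lx, ly, lz = lattice_size
    if n > lx * ly * lz:
        raise ValueError(f"chain of {n} beads cannot fit a {lattice_size} lattice")
    # boustrophedon fill: x direction alternates per row, y direction per layer
    coords = np.empty((n, 3), dtype=np.int64)
    i = 0
    row = 0
    for z in range(lz):
        ys = range(ly) if z % 2 == 0 else range(ly - 1, -1, -1)
        for y in ys:
            xs = range(lx) if row % 2 == 0 else range(lx - 1, -1, -1)
            row += 1
            for x in xs:
                if i == n:
                    break
                coords[i] = (x, y, z)
                i += 1
            if i == n:
                break
        if i == n:
            break
    return Conformation(coords=coords, labels=spec.labels(), lattice_size=lattice_size)


# ---------------------------------------------------------------------------
# energy and Monte-Carlo kernel (numba)
# ---------------------------------------------------------------------------

_NEIGH = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
    dtype=np.int64,
)


@njit(cache=True)
def _total_energy(coords, labels, grid, eps, kappa):
    n = coords.shape[0]
    e = 0.0
    # non-bonded rod-rod contacts, each pair counted once (positive axis scan)
    for i in range(n):
        if not labels[i]:
            continue
        x, y, z = coords[i, 0], coords[i, 1], coords[i, 2]
        for k in range(6):
            nx = x + _NEIGH[k, 0]
            ny = y + _NEIGH[k, 1]
            nz = z + _NEIGH[k, 2]
            if nx < 0 or ny < 0 or nz < 0 or nx >= grid.shape[0] or ny >= grid.shape[1] or nz >= grid.shape[2]:
                continue
            j = grid[nx, ny, nz]
            if j > i and labels[j] and j != i + 1:
                e -= eps
    # bending penalty at rod-centred bond pairs
    for c in range(1, n - 1):
        if not labels[c]:
            continue
        b1x = coords[c, 0] - coords[c - 1, 0]
        b1y = coords[c, 1] - coords[c - 1, 1]
        b1z = coords[c, 2] - coords[c - 1, 2]
        b2x = coords[c + 1, 0] - coords[c, 0]
        b2y = coords[c + 1, 1] - coords[c, 1]
        b2z = coords[c + 1, 2] - coords[c, 2]
        if b1x != b2x or b1y != b2y or b1z != b2z:
            e += kappa
    return e


@njit(cache=True, inline="always")
def _contact_e(i, x, y, z, labels, grid, eps, skip_a, skip_b):
    """Contact energy of rod bead i at site (x,y,z), skipping bonded partners."""
    if not labels[i]:
        return 0.0
    e = 0.0
    for k in range(6):
        nx = x + _NEIGH[k, 0]
        ny = y + _NEIGH[k, 1]
        nz = z + _NEIGH[k, 2]
        if nx < 0 or ny < 0 or nz < 0 or nx >= grid.shape[0] or ny >= grid.shape[1] or nz >= grid.shape[2]:
            continue
        j = grid[nx, ny, nz]
        if j >= 0 and j != i and j != skip_a and j != skip_b and labels[j]:
            e -= eps
    return e


@njit(cache=True, inline="always")
def _bend_e(coords, labels, c, kappa):
    """Bending energy at centre bead c (0 outside the valid range)."""
    n = coords.shape[0]
    if c < 1 or c > n - 2 or not labels[c]:
        return 0.0
    if (
        coords[c, 0] - coords[c - 1, 0] != coords[c + 1, 0] - coords[c, 0]
        or coords[c, 1] - coords[c - 1, 1] != coords[c + 1, 1] - coords[c, 1]
        or coords[c, 2] - coords[c - 1, 2] != coords[c + 1, 2] - coords[c, 2]
    ):
        return kappa
    return 0.0


@njit(cache=True)
def _mc_kernel(coords, labels, grid, eps, kappa, n_steps, use_local, use_end, use_rept,
               record_interval, snapshot_interval, seed):
    np.random.seed(seed)
    n = coords.shape[0]
    e = _total_energy(coords, labels, grid, eps, kappa)
    n_rec = n_steps // record_interval + 1
    energies = np.empty(n_rec)
    energies[0] = e
    rec = 1
    n_snap = n_steps // snapshot_interval if snapshot_interval > 0 else 0
    snapshots = np.empty((n_snap, n, 3), dtype=np.int64)
    snap = 0
    accepted = 0

    # move-type cumulative probabilities over the enabled moves
    w_local = 0.8 if use_local else 0.0
    w_end = 0.15 if use_end else 0.0
    w_rept = 0.05 if use_rept else 0.0
    wsum = w_local + w_end + w_rept
    p_local = w_local / wsum
    p_end = p_local + w_end / wsum

    for step in range(n_steps):
        u = np.random.random()
        if u < p_local:
            if n < 3:
                pass
            # corner flip or crankshaft, 50/50
            elif np.random.random() < 0.5:
                # ---- corner flip at internal bead i
                i = 1 + np.random.randint(n - 2)
                b1x = coords[i, 0] - coords[i - 1, 0]
                b1y = coords[i, 1] - coords[i - 1, 1]
                b1z = coords[i, 2] - coords[i - 1, 2]
                b2x = coords[i + 1, 0] - coords[i, 0]
                b2y = coords[i + 1, 1] - coords[i, 1]
                b2z = coords[i + 1, 2] - coords[i, 2]
                if b1x == b2x and b1y == b2y and b1z == b2z:
                    pass  # collinear: no corner to flip
                else:
                    cx = coords[i - 1, 0] + coords[i + 1, 0] - coords[i, 0]
                    cy = coords[i - 1, 1] + coords[i + 1, 1] - coords[i, 1]
                    cz = coords[i - 1, 2] + coords[i + 1, 2] - coords[i, 2]
                    if (
                        0 <= cx < grid.shape[0] and 0 <= cy < grid.shape[1]
                        and 0 <= cz < grid.shape[2] and grid[cx, cy, cz] < 0
                    ):
                        ox, oy, oz = coords[i, 0], coords[i, 1], coords[i, 2]
                        de = -_contact_e(i, ox, oy, oz, labels, grid, eps, i - 1, i + 1)
                        for c in range(i - 1, i + 2):
                            de -= _bend_e(coords, labels, c, kappa)
                        grid[ox, oy, oz] = -1
                        grid[cx, cy, cz] = i
                        coords[i, 0], coords[i, 1], coords[i, 2] = cx, cy, cz
                        de += _contact_e(i, cx, cy, cz, labels, grid, eps, i - 1, i + 1)
                        for c in range(i - 1, i + 2):
                            de += _bend_e(coords, labels, c, kappa)
                        if de <= 0 or np.random.random() < np.exp(-de):
                            e += de
                            accepted += 1
                        else:
                            grid[cx, cy, cz] = -1
                            grid[ox, oy, oz] = i
                            coords[i, 0], coords[i, 1], coords[i, 2] = ox, oy, oz
            elif n >= 4:
                # ---- crankshaft of beads i, i+1 about the i-1 -> i+2 axis
                i = 1 + np.random.randint(n - 3)
                vx = coords[i, 0] - coords[i - 1, 0]
                vy = coords[i, 1] - coords[i - 1, 1]
                vz = coords[i, 2] - coords[i - 1, 2]
                wx = coords[i + 1, 0] - coords[i + 2, 0]
                wy = coords[i + 1, 1] - coords[i + 2, 1]
                wz = coords[i + 1, 2] - coords[i + 2, 2]
                if vx == wx and vy == wy and vz == wz:
                    # U-shaped: rotate the offset v to one of the 4 directions
                    # perpendicular to the axis bond b2
                    b2x = coords[i + 1, 0] - coords[i, 0]
                    b2y = coords[i + 1, 1] - coords[i, 1]
                    b2z = coords[i + 1, 2] - coords[i, 2]
                    pick = np.random.randint(4)
                    m = -1
                    kk = 0
                    nvx = nvy = nvz = 0
                    while kk < 6:
                        dx, dy, dz = _NEIGH[kk, 0], _NEIGH[kk, 1], _NEIGH[kk, 2]
                        if dx * b2x + dy * b2y + dz * b2z == 0:
                            m += 1
                            if m == pick:
                                nvx, nvy, nvz = dx, dy, dz
                                break
                        kk += 1
                    ax, ay, az = coords[i - 1, 0] + nvx, coords[i - 1, 1] + nvy, coords[i - 1, 2] + nvz
                    bx, by, bz = coords[i + 2, 0] + nvx, coords[i + 2, 1] + nvy, coords[i + 2, 2] + nvz
                    same = nvx == vx and nvy == vy and nvz == vz
                    if same:
                        accepted += 1  # null rotation
                    elif (
                        0 <= ax < grid.shape[0] and 0 <= ay < grid.shape[1] and 0 <= az < grid.shape[2]
                        and 0 <= bx < grid.shape[0] and 0 <= by < grid.shape[1] and 0 <= bz < grid.shape[2]
                        and grid[ax, ay, az] < 0 and grid[bx, by, bz] < 0
                    ):
                        o1x, o1y, o1z = coords[i, 0], coords[i, 1], coords[i, 2]
                        o2x, o2y, o2z = coords[i + 1, 0], coords[i + 1, 1], coords[i + 1, 2]
                        de = 0.0
                        de -= _contact_e(i, o1x, o1y, o1z, labels, grid, eps, i - 1, i + 1)
                        de -= _contact_e(i + 1, o2x, o2y, o2z, labels, grid, eps, i, i + 2)
                        for c in range(i - 1, i + 3):
                            de -= _bend_e(coords, labels, c, kappa)
                        grid[o1x, o1y, o1z] = -1
                        grid[o2x, o2y, o2z] = -1
                        grid[ax, ay, az] = i
                        grid[bx, by, bz] = i + 1
                        coords[i, 0], coords[i, 1], coords[i, 2] = ax, ay, az
                        coords[i + 1, 0], coords[i + 1, 1], coords[i + 1, 2] = bx, by, bz
                        de += _contact_e(i, ax, ay, az, labels, grid, eps, i - 1, i + 1)
                        de += _contact_e(i + 1, bx, by, bz, labels, grid, eps, i, i + 2)
                        for c in range(i - 1, i + 3):
                            de += _bend_e(coords, labels, c, kappa)
                        if de <= 0 or np.random.random() < np.exp(-de):
                            e += de
                            accepted += 1
                        else:
                            grid[ax, ay, az] = -1
                            grid[bx, by, bz] = -1
                            grid[o1x, o1y, o1z] = i
                            grid[o2x, o2y, o2z] = i + 1
                            coords[i, 0], coords[i, 1], coords[i, 2] = o1x, o1y, o1z
                            coords[i + 1, 0], coords[i + 1, 1], coords[i + 1, 2] = o2x, o2y, o2z
        elif u < p_end:
            # ---- end rotation: move a terminal bead to a neighbour of its anchor
            if np.random.random() < 0.5:
                i, a = 0, 1
            else:
                i, a = n - 1, n - 2
            k = np.random.randint(6)
            cx = coords[a, 0] + _NEIGH[k, 0]
            cy = coords[a, 1] + _NEIGH[k, 1]
            cz = coords[a, 2] + _NEIGH[k, 2]
            if n < 2:
                pass
            elif cx == coords[i, 0] and cy == coords[i, 1] and cz == coords[i, 2]:
                accepted += 1  # null move
            elif (
                0 <= cx < grid.shape[0] and 0 <= cy < grid.shape[1]
                and 0 <= cz < grid.shape[2] and grid[cx, cy, cz] < 0
            ):
                ox, oy, oz = coords[i, 0], coords[i, 1], coords[i, 2]
                ctr = a  # the only affected bend centre
                de = -_contact_e(i, ox, oy, oz, labels, grid, eps, a, a)
                de -= _bend_e(coords, labels, ctr, kappa)
                grid[ox, oy, oz] = -1
                grid[cx, cy, cz] = i
                coords[i, 0], coords[i, 1], coords[i, 2] = cx, cy, cz
                de += _contact_e(i, cx, cy, cz, labels, grid, eps, a, a)
                de += _bend_e(coords, labels, ctr, kappa)
                if de <= 0 or np.random.random() < np.exp(-de):
                    e += de
                    accepted += 1
                else:
                    grid[cx, cy, cz] = -1
                    grid[ox, oy, oz] = i
                    coords[i, 0], coords[i, 1], coords[i, 2] = ox, oy, oz
        else:
            # ---- reptation (slither); O(n) per attempt, full energy recompute
            if np.random.random() < 0.5:
                head, tail = n - 1, 0
            else:
                head, tail = 0, n - 1
            k = np.random.randint(6)
            cx = coords[head, 0] + _NEIGH[k, 0]
            cy = coords[head, 1] + _NEIGH[k, 1]
            cz = coords[head, 2] + _NEIGH[k, 2]
            if (
                0 <= cx < grid.shape[0] and 0 <= cy < grid.shape[1]
                and 0 <= cz < grid.shape[2]
                and (grid[cx, cy, cz] < 0 or grid[cx, cy, cz] == tail)
            ):
                old = coords.copy()
                tx, ty, tz = coords[tail, 0], coords[tail, 1], coords[tail, 2]
                if head == n - 1:
                    for b in range(n - 1):
                        coords[b, 0] = coords[b + 1, 0]
                        coords[b, 1] = coords[b + 1, 1]
                        coords[b, 2] = coords[b + 1, 2]
                    coords[n - 1, 0], coords[n - 1, 1], coords[n - 1, 2] = cx, cy, cz
                else:
                    for b in range(n - 1, 0, -1):
                        coords[b, 0] = coords[b - 1, 0]
                        coords[b, 1] = coords[b - 1, 1]
                        coords[b, 2] = coords[b - 1, 2]
                    coords[0, 0], coords[0, 1], coords[0, 2] = cx, cy, cz
                grid[tx, ty, tz] = -1
                for b in range(n):
                    grid[coords[b, 0], coords[b, 1], coords[b, 2]] = b
                enew = _total_energy(coords, labels, grid, eps, kappa)
                de = enew - e
                if de <= 0 or np.random.random() < np.exp(-de):
                    e = enew
                    accepted += 1
                else:
                    grid[cx, cy, cz] = -1
                    for b in range(n):
                        coords[b, 0] = old[b, 0]
                        coords[b, 1] = old[b, 1]
                        coords[b, 2] = old[b, 2]
                        grid[coords[b, 0], coords[b, 1], coords[b, 2]] = b

        if (step + 1) % record_interval == 0:
            energies[rec] = e
            rec += 1
        if snapshot_interval > 0 and (step + 1) % snapshot_interval == 0:
            snapshots[snap] = coords
            snap += 1

    return energies[:rec], snapshots[:snap], accepted


def _make_grid(conf: Conformation) -> np.ndarray:
    grid = np.full(conf.lattice_size, -1, dtype=np.int64)
    for b, (x, y, z) in enumerate(conf.coords):
        grid[x, y, z] = b
    return grid


def energy(conf: Conformation, params: SimParams) -> float:
    """Total energy in kT: -epsilon_rr per non-bonded rod-rod contact plus
    kappa_rod per non-collinear bond pair centred on a rod bead."""
    return float(
        _total_energy(conf.coords, conf.labels, _make_grid(conf), params.epsilon_rr, params.kappa_rod)
    )


@dataclass
class MCResult:
    conformation: Conformation
    energies: np.ndarray  # recorded every record_interval steps, index 0 = start
    snapshots: list[Conformation]
    acceptance_rate: float
    params: SimParams


def run_mc(conf: Conformation, params: SimParams) -> MCResult:
    """Metropolis Monte Carlo at temperature 1 kT over the configured moves.

    Self-avoidance and lattice walls are enforced by proposal rejection.  The
    input conformation is not modified.  Deterministic given ``params.seed``.
    """
    conf.validate()
    coords = conf.coords.copy()
    labels = conf.labels.copy()
    grid = np.full(conf.lattice_size, -1, dtype=np.int64)
    for b, (x, y, z) in enumerate(coords):
        grid[x, y, z] = b
    use_local = "local_crankshaft" in params.move_set
    use_end = "end_rotation" in params.move_set
    use_rept = "reptation" in params.move_set
    energies, snaps, accepted = _mc_kernel(
        coords, labels, grid,
        float(params.epsilon_rr), float(params.kappa_rod), int(params.n_steps),
        use_local, use_end, use_rept,
        int(params.record_interval), int(params.snapshot_interval),
        int(params.seed) % (2**31 - 1),
    )
    rate = accepted / params.n_steps if params.n_steps else 0.0
    if params.n_steps >= len(coords) and accepted == 0:
        warnings.warn("no accepted moves over the whole run: the system appears frozen")
    final = Conformation(coords=coords, labels=labels, lattice_size=conf.lattice_size)
    snapshots = [
        Conformation(coords=s.copy(), labels=labels, lattice_size=conf.lattice_size) for s in snaps
    ]
    return MCResult(conformation=final, energies=np.asarray(energies), snapshots=snapshots,
                    acceptance_rate=rate, params=params)


# ---------------------------------------------------------------------------
# domain analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DomainMetrics:
    """Connected rod domains under lattice adjacency."""

    n_domains: int
    largest_domain_fraction: float
    mean_domain_size: float
    domain_asphericity: float  # size-weighted mean; 0 = sphere, 1 = line


def _asphericity(points: np.ndarray) -> float:
    """Relative shape anisotropy from the gyration tensor: 0 for isotropic
    (spherical) domains, 1 for collinear points.  Single points give 0."""
    if len(points) < 2:
        return 0.0
    centred = points - points.mean(axis=0)
    gyr = centred.T @ centred / len(points)
    lam = np.linalg.eigvalsh(gyr)
    tr = lam.sum()
    if tr == 0:
        return 0.0
    num = (lam[2] - lam[1]) ** 2 + (lam[2] - lam[0]) ** 2 + (lam[1] - lam[0]) ** 2
    return float(num / (2.0 * tr**2))


def domain_metrics(conf: Conformation) -> DomainMetrics:
    """Cluster rod beads into domains (6-connectivity on the lattice) and
    summarise their number, sizes and shape."""
    rods = conf.coords[conf.labels]
    if len(rods) == 0:
        raise ValueError("the chain has no rod beads")
    index = {tuple(p): i for i, p in enumerate(rods)}
    seen = np.zeros(len(rods), dtype=bool)
    domains: list[np.ndarray] = []
    for start in range(len(rods)):
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        members = []
        while stack:
            i = stack.pop()
            members.append(i)
            x, y, z = rods[i]
            for dx, dy, dz in _NEIGH:
                j = index.get((x + dx, y + dy, z + dz))
                if j is not None and not seen[j]:
                    seen[j] = True
                    stack.append(j)
        domains.append(rods[np.array(members)])
    sizes = np.array([len(d) for d in domains])
    asph = np.array([_asphericity(d.astype(float)) for d in domains])
    return DomainMetrics(
        n_domains=len(domains),
        largest_domain_fraction=float(sizes.max() / len(rods)),
        mean_domain_size=float(sizes.mean()),
        domain_asphericity=float(np.average(asph, weights=sizes)),
    )


# ---------------------------------------------------------------------------
# treatments
# ---------------------------------------------------------------------------

#: Treatment analogues: formamide dissolves the electrostatically
#: self-assembled phase (contact attraction removed); DRB, heat shock and
#: NaCl extraction strip polymerases or labile protein but leave the
#: acetylation-driven rod-rod interaction intact.
TREATMENTS = {
    "formamide": "solvent for the self-assembled phase: epsilon_rr -> 0",
    "DRB": "transcription-elongation inhibitor: interaction unchanged",
    "heat_shock": "releases RNA pol II: interaction unchanged",
    "NaCl": "2 M salt extraction: interaction unchanged",
}


def apply_treatment(params: SimParams, treatment: str) -> SimParams:
    """Return new simulation parameters under the given treatment analogue."""
    if treatment not in TREATMENTS:
        raise ValueError(
            f"unknown treatment {treatment!r}; valid treatments: {sorted(TREATMENTS)}"
        )
    note = f"{treatment}: {TREATMENTS[treatment]}"
    if treatment == "formamide":
        return replace(params, epsilon_rr=0.0, provenance=note)
    return replace(params, provenance=note)
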