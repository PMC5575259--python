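"""Domain types for the coarse-grained cysteine-rich chain.

The model is one bead per residue at the Cα position; cysteine beads
double as the position of their sulfur atom, so all sulfur-sulfur
distances and attack angles are measured between beads.  A chain carries
at most one disulfide cross-link at a time; every cysteine outside the
cross-link is a free thiol.  The I27*-like fixture is an 89-residue
chain with cysteines at residues 24, 32, 47, 55 and 63 and the native
disulfide between 24 and 55, which leaves 32, 47 and 63 reduced.

Residue indices are 1-based everywhere in the public API; coordinate
arrays are 0-based numpy arrays of shape ``(n_residues, 3)`` in nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import numpy as np

__all__ = [
    "ChainTopology",
    "Frame",
    "Trajectory",
    "SwapEvent",
    "TopologyError",
    "build_i27_star",
    "apply_swap",
    "I27_N_RESIDUES",
    "I27_CYSTEINES",
    "I27_DISULFIDE",
]

#: Number of residues of the I27-like domain.
I27_N_RESIDUES = 89
#: Cysteine residues of the five-cysteine mutant (1-based).
I27_CYSTEINES = frozenset({24, 32, 47, 55, 63})
#: The native engineered disulfide.
I27_DISULFIDE = frozenset({24, 55})

#: Bead class labels.
BEAD_GENERIC = "generic"
BEAD_CYS = "cysteine-S"


class TopologyError(ValueError):
    """Raised when a topology or a swap request is inconsistent."""


@dataclass(frozen=True)
class ChainTopology:
    """Connectivity and chemical state of the chain.

    Parameters
    ----------
    n_residues:
        Chain length (number of beads).
    cysteines:
        1-based residue indices of the cysteines.
    disulfide:
        Unordered pair of cysteine indices currently cross-linked, or
        ``None`` for a fully reduced chain.
    """

    n_residues: int
    cysteines: frozenset[int]
    disulfide: frozenset[int] | None = None

    def __post_init__(self) -> None:
        cys = frozenset(int(i) for i in self.cysteines)
        object.__setattr__(self, "cysteines", cys)
        if any(i < 1 or i > self.n_residues for i in cys):
            raise TopologyError("cysteine index outside 1..n_residues")
        if self.disulfide is not None:
            ss = frozenset(int(i) for i in self.disulfide)
            object.__setattr__(self, "disulfide", ss)
            if len(ss) != 2:
                raise TopologyError("disulfide must name exactly two residues")
            if not ss <= cys:
                raise TopologyError("disulfide pair must be a subset of the cysteines")

    @property
    def free_thiols(self) -> frozenset[int]:
        """Cysteines not engaged in the disulfide (reduced thiols)."""
        if self.disulfide is None:
            return self.cysteines
        return self.cysteines - self.disulfide

    @property
    def bead_classes(self) -> tuple[str, ...]:
        """Per-residue bead class label (1-based residue i at position i-1)."""
        return tuple(
            BEAD_CYS if i in self.cysteines else BEAD_GENERIC
            for i in range(1, self.n_residues + 1)
        )

    def disulfide_pair(self) -> tuple[int, int]:
        """The disulfide as a sorted (low, high) tuple; raises if absent."""
        if self.disulfide is None:
            raise TopologyError("chain has no disulfide")
        a, b = sorted(self.disulfide)
        return a, b


@dataclass(frozen=True)
class Frame:
    """A single time-stamped conformation.

    ``coords`` has one row per residue, in nm; cysteine rows are sulfur
    positions.  The array is copied and made read-only on construction.
    """

    time: float
    coords: np.ndarray

    def __post_init__(self) -> None:
        c = np.array(self.coords, dtype=float, copy=True)
        if c.ndim != 2 or c.shape[1] != 3:
            raise ValueError("coords must have shape (n_residues, 3)")
        if not np.all(np.isfinite(c)):
            raise ValueError("coords contain non-finite values")
        c.setflags(write=False)
        object.__setattr__(self, "coords", c)

    @property
    def n_residues(self) -> int:
        return self.coords.shape[0]

    def position(self, residue: int) -> np.ndarray:
        """Coordinates of a 1-based residue index."""
        return self.coords[residue - 1]


@dataclass
class Trajectory:
    """A time-ordered sequence of frames sharing one topology.

    A topology swap terminates a segment; trajectories produced by the
    hybrid scheme therefore carry the topology that was in force while
    their frames were generated (the final topology after an accepted
    swap is reported separately by the runner).
    """

    frames: list[Frame]
    topology: ChainTopology
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = [f.time for f in self.frames]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")
        for f in self.frames:
            if f.n_residues != self.topology.n_residues:
                raise ValueError("frame size does not match topology")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    def coords_array(self) -> np.ndarray:
        """All coordinates as an array of shape (n_frames, n_residues, 3)."""
        return np.array([f.coords for f in self.frames])


@dataclass(frozen=True)
class SwapEvent:
    """A first-passage attack geometry and its verdict.

    ``attacker`` is the free thiol, ``target`` the disulfide sulfur being
    attacked (it ends up bonded to the attacker), ``leaving`` the other
    disulfide member (released as a new free thiol).  ``d_ss`` is the
    attacker-target sulfur distance in nm, ``angle`` the
    S(attacker)-S(target)-S(leaving) angle in degrees.  ``dE`` is the
    product-minus-reactant locally minimized energy (kJ/mol) when the
    Metropolis criterion was applied, else ``None``.  ``n_rejected``
    counts Metropolis rejections before the recorded verdict.
    """

    time: float
    attacker: int
    target: int
    leaving: int
    d_ss: float
    angle: float
    verdict: str  # "detected" | "accepted" | "rejected"
    dE: float | None = None
    n_rejected: int = 0

    def __post_init__(self) -> None:
        if self.verdict not in ("detected", "accepted", "rejected"):
            raise ValueError(f"unknown verdict {self.verdict!r}")
        if not (0.0 <= self.angle <= 180.0):
            raise ValueError("angle must lie in [0, 180] degrees")
        if len({self.attacker, self.target, self.leaving}) != 3:
            raise ValueError("attacker, target and leaving must be distinct")


def apply_swap(topology: ChainTopology, event: SwapEvent) -> ChainTopology:
    """Rewire the disulfide according to an accepted exchange event.

    The attacker thiol bonds to the target sulfur; the leaving sulfur
    becomes a free thiol (the thiol proton moves to the leaving group as
    pure bookkeeping at this resolution).  The input topology is not
    modified.
    """
    if topology.disulfide is None:
        raise TopologyError("cannot swap: chain has no disulfide")
    if frozenset({event.target, event.leaving}) != topology.disulfide:
        raise TopologyError(
            f"event names disulfide {{{event.target}, {event.leaving}}} but "
            f"topology has {set(topology.disulfide)}"
        )
    if event.attacker not in topology.free_thiols:
        raise TopologyError(
            f"attacker {event.attacker} is not a free thiol "
            f"(free thiols: {sorted(topology.free_thiols)})"
        )
    return replace(topology, disulfide=frozenset({event.attacker, event.target}))


def _grow_compact_chain(
    n: int,
    bond_length: float,
    rng: np.random.Generator,
    min_sep: float,
) -> np.ndarray:
    """Grow a compact self-avoiding bead chain.

    Beads are appended at fixed bond length; each step draws candidate
    directions with a bias toward the running centroid (collapse) and
    keeps the first candidate at least ``min_sep`` away from every
    non-adjacent bead already placed.  If no candidate fits, the
    separation requirement is progressively relaxed, which keeps the
    construction total while remaining self-avoiding in practice.
    """
    coords = np.zeros((n, 3))
    for i in range(1, n):
        centroid = coords[:i].mean(axis=0)
        placed = False
        sep = min_sep
        while not placed:
            for _ in range(300):
                pull = centroid - coords[i - 1]
                norm = np.linalg.norm(pull)
                bias = pull / norm if norm > 1e-12 else np.zeros(3)
                d = rng.standard_normal(3) + 1.1 * bias * min(norm, 1.5)
                d /= np.linalg.norm(d)
                cand = coords[i - 1] + bond_length * d
                if i >= 2:
                    dists = np.linalg.norm(coords[: i - 1] - cand, axis=1)
                    if np.min(dists) < sep:
                        continue
                coords[i] = cand
                placed = True
                break
            sep *= 0.95  # relax if the pocket is too crowded
    return coords


def build_i27_star(bond_length: float = 0.38, seed: int = 0) -> tuple[ChainTopology, Frame]:
    """Build the five-cysteine I27*-like fixture chain.

    Returns an 89-bead chain with cysteines {24, 32, 47, 55, 63}, the
    native disulfide {24, 55} and free thiols {32, 47, 63}, together
    with a compact, self-avoiding starting conformation standing in for
    the folded state.  The conformation is reproducible from ``seed``.

    Parameters
    ----------
    bond_length:
        Cα-Cα virtual bond length in nm (default 0.38).
    seed:
        Seed for the conformation generator.
    """
    if bond_length <= 0:
        raise ValueError("bond_length must be positive")
    rng = np.random.default_rng(seed)
    coords = _grow_compact_chain(I27_N_RESIDUES, bond_length, rng, min_sep=0.42)
    topology = ChainTopology(
        n_residues=I27_N_RESIDUES,
        cysteines=I27_CYSTEINES,
        disulfide=I27_DISULFIDE,
    )
    # Close the 24-55 disulfide by a deterministic staged minimization:
    # the cross-link spring is ramped from soft to its production
    # stiffness, dragging the two sulfurs together through the globule.
    # Ramped closure treats the two halves of the enclosed loop
    # identically (no directional growth bias), and the final stage
    # doubles as a clash relaxation so dynamics can start at any
    # timestep without an initial force spike.
    from .potentials import PotentialParams, minimize

    full = PotentialParams(bond_r0=bond_length)
    for k_stage in (50.0, 500.0, 5000.0, full.crosslink_k):
        # hard-wall S-S (tiny softcore crossover) during closure so the
        # collapsing spring cannot fuse sulfur beads in the flat core
        params = PotentialParams(
            bond_r0=bond_length, crosslink_k=k_stage, crossover=0.01
        )
        coords, _, _ = minimize(
            coords, topology, params, tol=500.0, max_steps=300, initial_step=0.005
        )
    coords, _, _ = minimize(
        coords, topology, full, tol=500.0, max_steps=200, initial_step=0.005
    )
    coords = coords - coords.mean(axis=0)
    return topology, Frame(time=0.0, coords=coords)
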