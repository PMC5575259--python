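"""Overdamped Langevin force-clamp dynamics of the coarse-grained chain.

One terminus is held fixed at its initial position and a constant force
pulls the other along the pulling axis (the force-clamp protocol).  The
equation of motion is the Euler-Maruyama discretization of Brownian
dynamics,

    x(t+dt) = x(t) + (dt/gamma) F(x) + sqrt(2 kT dt / gamma) xi,

with gamma the friction (kJ/mol ps/nm^2) and xi unit normal deviates.
Solvent is implicit; time is a nominal "CG picosecond" whose mapping to
physical time is not calibrated — only the ordering and relative scale
of conformational events matter to the downstream exchange statistics.

The hot loop is compiled with numba; a trajectory of 10^6 steps of the
89-bead chain takes seconds.  The swap criterion of the hybrid scheme is
evaluated *inside* the integration loop every step (``watch`` pairs with
early exit), which is strictly more accurate than scanning sparsely
saved frames.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numba
import numpy as np

from .constants import kt, pn_to_internal
from .model import ChainTopology, Frame, Trajectory
from .potentials import PotentialParams

__all__ = [
    "SimulationConfig",
    "SimulationDiverged",
    "ForceClampIntegrator",
    "run_force_clamp",
    "end_to_end",
    "end_to_end_distance",
    "pairwise_rmsd",
    "select_starting_conformations",
]


class SimulationDiverged(RuntimeError):
    """Raised when coordinates become non-finite; carries the step index."""

    def __init__(self, step: int):
        super().__init__(f"simulation diverged (non-finite coordinates) at step {step}")
        self.step = step


@dataclass(frozen=True)
class SimulationConfig:
    """Force-clamp run settings.

    ``force_pn`` is the clamp force in pN (480 by default), applied to
    ``pulled_residue`` (the last bead when ``None``) along
    ``pulling_axis`` while ``fixed_residue`` is frozen at its initial
    position.  ``friction`` is in kJ/mol ps/nm^2, ``timestep`` in ps.
    """

    force_pn: float = 480.0
    temperature: float = 300.0
    friction: float = 50.0
    timestep: float = 0.001
    n_steps: int = 1_500_000
    output_stride: int = 1000
    seed: int = 0
    fixed_residue: int | None = 1
    pulled_residue: int | None = None
    pulling_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.output_stride < 1:
            raise ValueError("output_stride must be >= 1")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.friction <= 0:
            raise ValueError("friction must be positive")
        if self.fixed_residue is None and self.force_pn != 0.0:
            raise ValueError("a nonzero clamp force requires a fixed residue")

    def resolve_pulled(self, n_residues: int) -> int:
        return self.pulled_residue if self.pulled_residue is not None else n_residues

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pulling_axis"] = list(d["pulling_axis"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "pulling_axis" in d:
            d["pulling_axis"] = tuple(d["pulling_axis"])
        return cls(**d)


@numba.njit(cache=False, fastmath=True)
def _chunk(
    x, noise, mob, fixed_pos,
    is_s, xl_a, xl_b,
    bond_k, bond_r0, ang_k, ang_t0, xl_k, xl_r0,
    sig2, eps, sig2_ss, eps_ss, sc_a, sc_c, rc2, cut2,
    f_ext, i_fix, i_pull,
    watch_i, watch_j, watch_cut2,
    f,
):  # pragma: no cover - exercised via python wrappers
    """Integrate len(noise) Euler-Maruyama steps in place.

    Returns (steps_done, hit) where hit >= 0 is the index into the watch
    pair list whose distance fell below the watch cutoff after the final
    executed step (early exit), and -1 otherwise.
    mob = dt/gamma; noise is pre-scaled by sqrt(2 kT dt / gamma).
    """
    n = x.shape[0]
    nsteps = noise.shape[0]
    for s in range(nsteps):
        for i in range(n):
            f[i, 0] = 0.0
            f[i, 1] = 0.0
            f[i, 2] = 0.0
        # bonds
        for i in range(n - 1):
            dx = x[i + 1, 0] - x[i, 0]
            dy = x[i + 1, 1] - x[i, 1]
            dz = x[i + 1, 2] - x[i, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            w = -bond_k * (r - bond_r0) / r
            f[i + 1, 0] += w * dx
            f[i + 1, 1] += w * dy
            f[i + 1, 2] += w * dz
            f[i, 0] -= w * dx
            f[i, 1] -= w * dy
            f[i, 2] -= w * dz
        # bends
        if ang_k > 0.0:
            for i in range(1, n - 1):
                ux = x[i - 1, 0] - x[i, 0]
                uy = x[i - 1, 1] - x[i, 1]
                uz = x[i - 1, 2] - x[i, 2]
                vx = x[i + 1, 0] - x[i, 0]
                vy = x[i + 1, 1] - x[i, 1]
                vz = x[i + 1, 2] - x[i, 2]
                lu = np.sqrt(ux * ux + uy * uy + uz * uz)
                lv = np.sqrt(vx * vx + vy * vy + vz * vz)
                ux /= lu; uy /= lu; uz /= lu
                vx /= lv; vy /= lv; vz /= lv
                cth = ux * vx + uy * vy + uz * vz
                if cth > 1.0:
                    cth = 1.0
                elif cth < -1.0:
                    cth = -1.0
                th = np.arccos(cth)
                s2 = 1.0 - cth * cth
                if s2 < 1e-12:
                    s2 = 1e-12
                coef = ang_k * (th - ang_t0) / np.sqrt(s2)
                g0x = coef / lu * (cth * ux - vx)
                g0y = coef / lu * (cth * uy - vy)
                g0z = coef / lu * (cth * uz - vz)
                g2x = coef / lv * (cth * vx - ux)
                g2y = coef / lv * (cth * vy - uy)
                g2z = coef / lv * (cth * vz - uz)
                f[i - 1, 0] -= g0x
                f[i - 1, 1] -= g0y
                f[i - 1, 2] -= g0z
                f[i + 1, 0] -= g2x
                f[i + 1, 1] -= g2y
                f[i + 1, 2] -= g2z
                f[i, 0] += g0x + g2x
                f[i, 1] += g0y + g2y
                f[i, 2] += g0z + g2z
        # cross-link
        if xl_a >= 0:
            dx = x[xl_b, 0] - x[xl_a, 0]
            dy = x[xl_b, 1] - x[xl_a, 1]
            dz = x[xl_b, 2] - x[xl_a, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            w = -xl_k * (r - xl_r0) / r
            f[xl_b, 0] += w * dx
            f[xl_b, 1] += w * dy
            f[xl_b, 2] += w * dz
            f[xl_a, 0] -= w * dx
            f[xl_a, 1] -= w * dy
            f[xl_a, 2] -= w * dz
        # nonbonded (|i-j| >= 3, skip cross-linked pair)
        for i in range(n):
            for j in range(i + 3, n):
                if i == xl_a and j == xl_b:
                    continue
                dx = x[i, 0] - x[j, 0]
                dy = x[i, 1] - x[j, 1]
                dz = x[i, 2] - x[j, 2]
                r2 = dx * dx + dy * dy + dz * dz
                if r2 >= cut2:
                    continue
                if is_s[i] and is_s[j]:
                    if r2 < rc2:
                        w = -2.0 * sc_c  # force/r of quadratic core
                    else:
                        inv2 = sig2_ss / r2
                        s6 = inv2 * inv2 * inv2
                        w = 24.0 * eps_ss * (2.0 * s6 * s6 - s6) / r2
                else:
                    inv2 = sig2 / r2
                    s6 = inv2 * inv2 * inv2
                    w = 24.0 * eps * (2.0 * s6 * s6 - s6) / r2
                f[i, 0] += w * dx
                f[i, 1] += w * dy
                f[i, 2] += w * dz
                f[j, 0] -= w * dx
                f[j, 1] -= w * dy
                f[j, 2] -= w * dz
        # pulling force on the clamped bead
        f[i_pull, 0] += f_ext[0]
        f[i_pull, 1] += f_ext[1]
        f[i_pull, 2] += f_ext[2]
        # Euler-Maruyama update
        for i in range(n):
            x[i, 0] += mob * f[i, 0] + noise[s, i, 0]
            x[i, 1] += mob * f[i, 1] + noise[s, i, 1]
            x[i, 2] += mob * f[i, 2] + noise[s, i, 2]
        # frozen terminus
        if i_fix >= 0:
            x[i_fix, 0] = fixed_pos[0]
            x[i_fix, 1] = fixed_pos[1]
            x[i_fix, 2] = fixed_pos[2]
        # first-passage watch
        if watch_cut2 > 0.0:
            for k in range(watch_i.shape[0]):
                a = watch_i[k]
                b = watch_j[k]
                dx = x[a, 0] - x[b, 0]
                dy = x[a, 1] - x[b, 1]
                dz = x[a, 2] - x[b, 2]
                if dx * dx + dy * dy + dz * dz < watch_cut2:
                    return s + 1, k
    return nsteps, -1


class ForceClampIntegrator:
    """Stateful Brownian force-clamp propagator.

    Drives the numba kernel in chunks while drawing noise from a single
    seeded stream, so trajectories are bit-reproducible from
    ``(start, config.seed)`` regardless of how ``advance`` calls are
    interleaved (the property the hybrid scheme relies on when it
    interrupts the dynamics at swap events).
    """

    _NOISE_CHUNK = 2048

    def __init__(
        self,
        start: Frame,
        topology: ChainTopology,
        params: PotentialParams,
        config: SimulationConfig,
    ) -> None:
        n = topology.n_residues
        if start.n_residues != n:
            raise ValueError("start frame does not match topology")
        self.topology = topology
        self.params = params
        self.config = config
        self.x = np.array(start.coords, dtype=float, copy=True)
        self.step_count = 0
        self._f = np.zeros_like(self.x)
        self._rng = np.random.default_rng(config.seed)
        self._noise: np.ndarray | None = None
        self._noise_pos = 0
        self._noise_scale = float(
            np.sqrt(2.0 * kt(config.temperature) * config.timestep / config.friction)
        )
        self._mob = config.timestep / config.friction
        self.i_fix = -1 if config.fixed_residue is None else config.fixed_residue - 1
        self.i_pull = config.resolve_pulled(n) - 1
        if self.i_fix == self.i_pull and config.force_pn != 0.0:
            raise ValueError("fixed and pulled residues must differ")
        self._fixed_pos = (
            self.x[self.i_fix].copy() if self.i_fix >= 0 else np.zeros(3)
        )
        axis = np.asarray(config.pulling_axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        self.axis = axis
        self._f_ext = pn_to_internal(config.force_pn) * axis
        self._set_topology_arrays(topology)

    def _set_topology_arrays(self, topology: ChainTopology) -> None:
        n = topology.n_residues
        self._is_s = np.zeros(n, dtype=np.bool_)
        for i in topology.cysteines:
            self._is_s[i - 1] = True
        if topology.disulfide is not None:
            a, b = topology.disulfide_pair()
            self._xl = (a - 1, b - 1)
        else:
            self._xl = (-1, -1)

    def rewire(self, topology: ChainTopology) -> None:
        """Swap in a new topology (after an accepted exchange)."""
        if topology.n_residues != self.topology.n_residues:
            raise ValueError("cannot rewire to a different chain length")
        self.topology = topology
        self._set_topology_arrays(topology)

    @property
    def time(self) -> float:
        return self.step_count * self.config.timestep

    def frame(self) -> Frame:
        return Frame(time=self.time, coords=self.x)

    def _next_noise(self, max_steps: int) -> np.ndarray:
        if self._noise is None or self._noise_pos >= self._noise.shape[0]:
            n = self.topology.n_residues
            self._noise = self._noise_scale * self._rng.standard_normal(
                (self._NOISE_CHUNK, n, 3)
            )
            self._noise_pos = 0
        end = min(self._noise_pos + max_steps, self._noise.shape[0])
        return self._noise[self._noise_pos:end]

    def advance(
        self,
        n_steps: int,
        watch_pairs: Sequence[tuple[int, int]] | None = None,
        watch_cutoff: float | None = None,
    ) -> tuple[int, tuple[int, int] | None]:
        """Integrate up to ``n_steps`` steps.

        With ``watch_pairs`` (1-based residue pairs) and a cutoff, the
        integration stops after the first step whose updated coordinates
        bring any watched pair closer than the cutoff.  Returns the
        number of steps actually executed and the triggering pair (or
        ``None``).
        """
        if watch_pairs is not None and watch_cutoff is not None and len(watch_pairs):
            wi = np.array([a - 1 for a, _ in watch_pairs], dtype=np.int64)
            wj = np.array([b - 1 for _, b in watch_pairs], dtype=np.int64)
            wcut2 = float(watch_cutoff) ** 2
        else:
            wi = np.empty(0, dtype=np.int64)
            wj = np.empty(0, dtype=np.int64)
            wcut2 = -1.0
        p = self.params
        sc_a, sc_c = p.softcore_coefficients()
        done = 0
        hit_pair: tuple[int, int] | None = None
        while done < n_steps:
            noise = self._next_noise(n_steps - done)
            try:
                steps, hit = _chunk(
                    self.x, noise, self._mob, self._fixed_pos,
                    self._is_s, self._xl[0], self._xl[1],
                    p.bond_k, p.bond_r0, p.angle_k, p.angle_theta0,
                    p.crosslink_k, p.crosslink_r0,
                    p.sigma**2, p.epsilon, p.sigma_ss**2, p.epsilon_ss,
                    sc_a, sc_c, p.crossover**2, p.lj_cutoff**2,
                    self._f_ext, self.i_fix, self.i_pull,
                    wi, wj, wcut2,
                    self._f,
                )
            except ZeroDivisionError as exc:
                # a bond length hit exactly zero: the chain has exploded
                raise SimulationDiverged(self.step_count) from exc
            done += steps
            self._noise_pos += steps
            self.step_count += steps
            if not np.all(np.isfinite(self.x)):
                raise SimulationDiverged(self.step_count)
            if hit >= 0:
                hit_pair = (int(wi[hit]) + 1, int(wj[hit]) + 1)
                break
        return done, hit_pair


def run_force_clamp(
    start: Frame,
    topology: ChainTopology,
    params: PotentialParams,
    config: SimulationConfig,
) -> Trajectory:
    """Run a plain force-clamp trajectory (no swapping).

    Frames are emitted at ``config.output_stride`` steps (plus the start
    frame and the final partial stride); the run is bit-reproducible
    from ``(start, config)``.
    """
    integ = ForceClampIntegrator(start, topology, params, config)
    frames = [Frame(time=0.0, coords=integ.x)]
    remaining = config.n_steps
    while remaining > 0:
        block = min(config.output_stride, remaining)
        integ.advance(block)
        remaining -= block
        frames.append(integ.frame())
    meta = {"config": config.to_dict(), "params": params.to_dict()}
    return Trajectory(frames=frames, topology=topology, metadata=meta)


def end_to_end_distance(
    frame: Frame, fixed_residue: int = 1, pulled_residue: int | None = None
) -> float:
    """Distance in nm between the clamped termini of one frame."""
    pulled = pulled_residue if pulled_residue is not None else frame.n_residues
    return float(np.linalg.norm(frame.position(pulled) - frame.position(fixed_residue)))


def end_to_end(trajectory: Trajectory) -> np.ndarray:
    """Per-frame end-to-end (fixed-to-pulled bead) distance series, nm."""
    if len(trajectory) == 0:
        raise ValueError("empty trajectory")
    cfg = trajectory.metadata.get("config", {})
    fixed = cfg.get("fixed_residue") or 1
    pulled = cfg.get("pulled_residue") or trajectory.topology.n_residues
    coords = trajectory.coords_array()
    return np.linalg.norm(coords[:, pulled - 1] - coords[:, fixed - 1], axis=1)


def _superposed_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum RMSD (nm) between two conformations after optimal
    translation and rotation (Kabsch superposition)."""
    from scipy.spatial.transform import Rotation

    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)
    _, rssd = Rotation.align_vectors(a0, b0)
    return float(rssd / np.sqrt(a.shape[0]))


def pairwise_rmsd(coords: np.ndarray) -> np.ndarray:
    """Symmetric matrix of superposed RMSDs for frames (m, n, 3)."""
    m = coords.shape[0]
    out = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            out[i, j] = out[j, i] = _superposed_rmsd(coords[i], coords[j])
    return out


def select_starting_conformations(
    trajectory: Trajectory, rmsd_cutoff: float = 0.1, k: int = 20
) -> list[Frame]:
    """Cluster frames and return one representative per cluster.

    Greedy leader clustering: frames are visited in time order and
    assigned to the first existing cluster whose leader lies within
    ``rmsd_cutoff`` (superposed RMSD); otherwise they found a new
    cluster.  The representative of each cluster is its medoid.  At most
    ``k`` representatives are returned, largest clusters first.
    """
    if rmsd_cutoff <= 0:
        raise ValueError("rmsd_cutoff must be positive")
    if len(trajectory) == 0:
        raise ValueError("empty trajectory")
    coords = trajectory.coords_array()
    leaders: list[int] = []
    members: list[list[int]] = []
    for idx in range(coords.shape[0]):
        for li, lead in enumerate(leaders):
            if _superposed_rmsd(coords[idx], coords[lead]) < rmsd_cutoff:
                members[li].append(idx)
                break
        else:
            leaders.append(idx)
            members.append([idx])
    order = np.argsort([-len(m) for m in members], kind="stable")
    reps: list[Frame] = []
    for ci in order[:k]:
        idxs = members[ci]
        if len(idxs) == 1:
            reps.append(trajectory.frames[idxs[0]])
            continue
        sub = coords[idxs]
        d = pairwise_rmsd(sub)
        med = idxs[int(np.argmin(d.sum(axis=1)))]
        reps.append(trajectory.frames[med])
    return reps
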