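"""The hybrid Monte Carlo step: first-passage detection, topology swap,
frozen-environment minimization and Metropolis acceptance.

A thiol-disulfide exchange is proposed whenever the sulfur of a free
cysteine first comes within a cutoff distance (0.5 nm by default) of a
sulfur of the disulfide bond.  Only the first such approach matters:
under tension the reaction is effectively irreversible, so one exchange
event at most is counted per trajectory.  Two criteria are available:

``distance``
    proximity alone decides; every detected first passage is accepted.

``metropolis``
    the proposed product topology is built, both reactant and product
    conformations are relaxed by steepest descent with only the residues
    within a radius of the three reactive cysteines mobile (everything
    else frozen), and the swap is accepted with probability
    min(1, exp(-dE/kT)) on the minimized energy difference.  On
    rejection the dynamics continue and the criterion is re-tested at
    subsequent steps until accepted (or the run ends).

Because the coarse-grained folded state is a generic compact globule
rather than the native fold, sub-cutoff contacts sampled before the
chain has unfolded are artifacts of the stand-in; the runner therefore
arms the detector only once the end-to-end distance exceeds an arming
threshold (the same 20 nm that defines the unfolded state downstream).
Set ``arm_end_to_end=None`` to detect from the first step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Iterable

import numpy as np

from .constants import kt
from .model import ChainTopology, Frame, SwapEvent, Trajectory, apply_swap
from .potentials import PotentialParams, minimize
from .simulator import ForceClampIntegrator, SimulationConfig

__all__ = [
    "SwapCriterion",
    "attack_angle",
    "detect_first_passage",
    "metropolis_accept",
    "metropolis_swap",
    "run_hybrid",
    "HybridResult",
]


@dataclass(frozen=True)
class SwapCriterion:
    """Settings of the exchange criterion.

    ``mode`` is ``"distance"`` or ``"metropolis"``; ``d_cutoff`` is the
    first-passage sulfur-sulfur threshold in nm; ``angle_min`` (degrees)
    optionally requires a minimum attack angle at detection (off by
    default — angle filtering is a post-hoc analysis, not part of the
    headline protocol).  ``relax_radius`` bounds the mobile region of
    the frozen-environment minimization; ``kT`` is the Metropolis
    temperature in kJ/mol.  ``arm_end_to_end`` gates detection on the
    unfolded state (see module docstring); ``None`` disables the gate.
    """

    mode: str = "distance"
    d_cutoff: float = 0.5
    angle_min: float | None = None
    relax_radius: float = 0.5
    kT: float = kt(300.0)
    minimizer_tol: float = 10.0
    minimizer_max_steps: int = 500
    arm_end_to_end: float | None = 20.0

    def __post_init__(self) -> None:
        if self.mode not in ("distance", "metropolis"):
            raise ValueError("mode must be 'distance' or 'metropolis'")
        if self.d_cutoff < 0:
            raise ValueError("d_cutoff must be non-negative")
        if self.angle_min is not None and not (0 <= self.angle_min <= 180):
            raise ValueError("angle_min must lie in [0, 180]")
        if self.kT <= 0:
            raise ValueError("kT must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SwapCriterion":
        return cls(**d)


def attack_angle(frame: Frame, attacker: int, target: int, leaving: int) -> float:
    """S(attacker)-S(target)-S(leaving) angle in degrees.

    The interior angle at the attacked sulfur between the directions to
    the attacking and the leaving sulfur; the ideal in-line S_N2
    geometry is 180 degrees.
    """
    if len({attacker, target, leaving}) != 3:
        raise ValueError("attacker, target and leaving must be distinct residues")
    u = frame.position(attacker) - frame.position(target)
    v = frame.position(leaving) - frame.position(target)
    lu = np.linalg.norm(u)
    lv = np.linalg.norm(v)
    if lu < 1e-9 or lv < 1e-9:
        raise ValueError("coincident sulfur positions: attack angle undefined")
    c = float(np.dot(u, v) / (lu * lv))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _candidate_event(
    frame: Frame, topology: ChainTopology, attacker: int, criterion: SwapCriterion
) -> SwapEvent | None:
    """Build the detected event for one attacker in one frame, or None.

    When both disulfide sulfurs are within the cutoff the nearer one is
    the target (proximity tie-break).
    """
    a, b = topology.disulfide_pair()
    da = float(np.linalg.norm(frame.position(attacker) - frame.position(a)))
    db = float(np.linalg.norm(frame.position(attacker) - frame.position(b)))
    d = min(da, db)
    if d >= criterion.d_cutoff:
        return None
    target, leaving = (a, b) if da <= db else (b, a)
    angle = attack_angle(frame, attacker, target, leaving)
    if criterion.angle_min is not None and angle < criterion.angle_min:
        return None
    return SwapEvent(
        time=frame.time, attacker=attacker, target=target, leaving=leaving,
        d_ss=d, angle=angle, verdict="detected",
    )


def detect_first_passage(
    frames: "Trajectory | Iterable[Frame]",
    topology: ChainTopology,
    criterion: SwapCriterion,
    all_pairs: bool = False,
) -> list[SwapEvent]:
    """Scan frames for first-passage attack geometries.

    By default returns at most one event — the earliest sub-cutoff
    approach across all (free thiol, disulfide sulfur) pairs — because
    tension makes the first reaction irreversible.  With
    ``all_pairs=True`` the truncation is lifted and the first passage of
    *each* attacker is reported (at most one event per attacker, in time
    order), which is the quantity cutoff-monotonicity statements refer
    to.  An empty list is a valid result.
    """
    if topology.disulfide is None:
        raise ValueError("topology has no disulfide to attack")
    events: dict[int, SwapEvent] = {}
    attackers = sorted(topology.free_thiols)
    for frame in frames:
        for attacker in attackers:
            if attacker in events:
                continue
            ev = _candidate_event(frame, topology, attacker, criterion)
            if ev is not None:
                events[attacker] = ev
        if events and not all_pairs:
            break
        if len(events) == len(attackers):
            break
    ordered = sorted(events.values(), key=lambda e: (e.time, e.d_ss))
    return ordered if all_pairs else ordered[:1]


def metropolis_accept(dE: float, kT: float, rng: np.random.Generator) -> bool:
    """The Metropolis rule: accept with probability min(1, exp(-dE/kT))."""
    if dE <= 0:
        return True
    return float(rng.random()) < math.exp(-dE / kT)


def _mobile_region(
    frame: Frame, topology: ChainTopology, event: SwapEvent, radius: float
) -> list[int]:
    """Residues within ``radius`` of any of the three reactive sulfurs
    (the reactive cysteines themselves always included)."""
    centers = np.array([
        frame.position(event.attacker),
        frame.position(event.target),
        frame.position(event.leaving),
    ])
    d = np.linalg.norm(frame.coords[:, None, :] - centers[None, :, :], axis=2)
    mobile = np.nonzero(np.min(d, axis=1) <= radius)[0] + 1
    return [int(i) for i in mobile]


def metropolis_swap(
    frame: Frame,
    topology: ChainTopology,
    event: SwapEvent,
    params: PotentialParams,
    criterion: SwapCriterion,
    rng: np.random.Generator,
) -> tuple[str, float, Frame | None]:
    """Decide a detected event by the energy-based Metropolis criterion.

    Both the reactant (current topology) and the product (swapped
    disulfide) conformations are relaxed by steepest descent with only
    the residues within ``criterion.relax_radius`` of the three reactive
    sulfurs mobile; all other coordinates stay bit-identical.  dE is the
    product-minus-reactant energy of the mobile subsystem (frozen-frozen
    terms are constants and cancel).  Returns ``(verdict, dE,
    product_frame)`` where ``product_frame`` is the relaxed product
    conformation on acceptance and ``None`` otherwise.  A minimization
    that fails to converge rejects the event.
    """
    if event.d_ss >= criterion.d_cutoff:
        raise ValueError("event distance is not below the criterion cutoff")
    product_topology = apply_swap(
        topology, SwapEvent(
            time=event.time, attacker=event.attacker, target=event.target,
            leaving=event.leaving, d_ss=event.d_ss, angle=event.angle,
            verdict="accepted",
        )
    )
    mobile = _mobile_region(frame, topology, event, criterion.relax_radius)
    kwargs = dict(
        mobile=mobile, tol=criterion.minimizer_tol,
        max_steps=criterion.minimizer_max_steps,
    )
    x_react, e_react, ok_r = minimize(frame.coords, topology, params, **kwargs)
    x_prod, e_prod, ok_p = minimize(frame.coords, product_topology, params, **kwargs)
    dE = e_prod - e_react
    if not (ok_r and ok_p):
        return "rejected", dE, None
    if metropolis_accept(dE, criterion.kT, rng):
        return "accepted", dE, Frame(time=frame.time, coords=x_prod)
    return "rejected", dE, None


@dataclass
class HybridResult:
    """Outcome of one hybrid MC/MD run."""

    trajectory: Trajectory
    events: list[SwapEvent]
    final_topology: ChainTopology


def run_hybrid(
    start: Frame,
    topology: ChainTopology,
    params: PotentialParams,
    sim_config: SimulationConfig,
    criterion: SwapCriterion,
    stop_after_swap: bool = False,
    rewire: bool = True,
) -> HybridResult:
    """Interleave Langevin propagation with per-step swap checks.

    The sulfur-sulfur watch runs inside the integration kernel every
    step.  On a detected first passage the criterion is applied; an
    accepted swap rewires the cross-link to the new pair (and, under the
    Metropolis mode, continues from the locally relaxed product
    conformation).  At most one accepted exchange is counted per run;
    afterwards the dynamics either stop (``stop_after_swap``) or
    continue without further checks.  With ``d_cutoff == 0`` the run is
    bit-identical to plain :func:`dsxchange.simulator.run_force_clamp`.

    With ``rewire=False`` the exchange is *virtual*: the accepted event
    is recorded (and still terminates detection) but the dynamics
    continue on the unmodified topology — the post-hoc counting
    protocol, which keeps the whole trajectory sampling the native
    disulfide's conformational ensemble for the downstream analyses.

    Returns the trajectory, the event log (the accepted event carries
    the number of preceding Metropolis rejections; a run whose detected
    approaches were all rejected logs the first detection as
    ``rejected``), and the final topology.
    """
    integ = ForceClampIntegrator(start, topology, params, sim_config)
    frames = [Frame(time=0.0, coords=integ.x)]
    events: list[SwapEvent] = []
    mc_rng = np.random.default_rng(np.random.SeedSequence([sim_config.seed, 0x5A9]))
    n_rejected = 0
    first_rejection: SwapEvent | None = None
    swapped = False
    armed = criterion.arm_end_to_end is None
    watch_enabled = criterion.d_cutoff > 0

    def watch_pairs() -> list[tuple[int, int]]:
        a, b = integ.topology.disulfide_pair()
        return [(t, s) for t in sorted(integ.topology.free_thiols) for s in (a, b)]

    next_output = sim_config.output_stride
    while integ.step_count < sim_config.n_steps:
        block = min(next_output, sim_config.n_steps) - integ.step_count
        if not armed:
            # advance without watching; arm once the chain is unfolded
            integ.advance(block)
            ee = float(np.linalg.norm(integ.x[integ.i_pull] - integ.x[integ.i_fix]))
            armed = ee >= criterion.arm_end_to_end
        elif watch_enabled and not swapped:
            done, hit = integ.advance(
                block, watch_pairs=watch_pairs(), watch_cutoff=criterion.d_cutoff
            )
            if hit is not None:
                frame = integ.frame()
                ev = _candidate_event(
                    frame, integ.topology, hit[0], criterion
                )
                if ev is None:
                    # angle filter refused this geometry; keep propagating
                    pass
                elif criterion.mode == "distance":
                    accepted = SwapEvent(
                        time=ev.time, attacker=ev.attacker, target=ev.target,
                        leaving=ev.leaving, d_ss=ev.d_ss, angle=ev.angle,
                        verdict="accepted",
                    )
                    events.append(accepted)
                    if rewire:
                        integ.rewire(apply_swap(integ.topology, accepted))
                    swapped = True
                else:
                    verdict, dE, product = metropolis_swap(
                        frame, integ.topology, ev, params, criterion, mc_rng
                    )
                    if verdict == "accepted":
                        accepted = SwapEvent(
                            time=ev.time, attacker=ev.attacker, target=ev.target,
                            leaving=ev.leaving, d_ss=ev.d_ss, angle=ev.angle,
                            verdict="accepted", dE=dE, n_rejected=n_rejected,
                        )
                        events.append(accepted)
                        if rewire:
                            integ.rewire(apply_swap(integ.topology, accepted))
                            integ.x[:] = product.coords
                        swapped = True
                    else:
                        n_rejected += 1
                        if first_rejection is None:
                            first_rejection = SwapEvent(
                                time=ev.time, attacker=ev.attacker,
                                target=ev.target, leaving=ev.leaving,
                                d_ss=ev.d_ss, angle=ev.angle,
                                verdict="rejected", dE=dE,
                            )
                if swapped and stop_after_swap:
                    frames.append(integ.frame())
                    break
        else:
            integ.advance(block)
        if integ.step_count >= next_output:
            frames.append(integ.frame())
            next_output += sim_config.output_stride
    if frames[-1].time < integ.time:
        frames.append(integ.frame())
    if not any(e.verdict == "accepted" for e in events) and first_rejection is not None:
        events.append(
            SwapEvent(
                time=first_rejection.time, attacker=first_rejection.attacker,
                target=first_rejection.target, leaving=first_rejection.leaving,
                d_ss=first_rejection.d_ss, angle=first_rejection.angle,
                verdict="rejected", dE=first_rejection.dE, n_rejected=n_rejected,
            )
        )
    meta = {
        "config": sim_config.to_dict(),
        "params": params.to_dict(),
        "criterion": criterion.to_dict(),
    }
    traj = Trajectory(frames=frames, topology=topology, metadata=meta)
    return HybridResult(trajectory=traj, events=events, final_topology=integ.topology)
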