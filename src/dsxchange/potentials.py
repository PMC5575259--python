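"""Energy and force terms of the coarse-grained chain model.

The chain Hamiltonian is

    V = sum_bonds  1/2 k_b (r - r0)^2
      + sum_bends  1/2 k_a (theta - theta0)^2
      + 1/2 k_x (r_SS - r_x0)^2                    (disulfide cross-link)
      + sum_nonbonded  V_LJ(r)  or  V_soft(r)      (|i-j| >= 3, r < cutoff)
      - F * (x_pulled - x_fixed) . axis            (constant pulling force)

Nonbonded pairs where both beads carry a sulfur (cysteine beads) use a
softcore Lennard-Jones interaction: identical to the plain 12-6 form at
and beyond a crossover distance (0.35 nm by default), and a bounded
quadratic core below it that matches the LJ value and slope at the
crossover.  This keeps energy and force finite down to r = 0, so the
chain can sample the very short sulfur-sulfur approaches that precede a
thiol-disulfide exchange instead of being repelled by a diverging r^-12
wall.  The (alpha, lambda, p) softcore parameters of the all-atom
convention are recorded on the parameter object for provenance; the
functional form here is the piecewise C^1 construction, which is what
the stated physical contract (finite core, exact LJ beyond the
crossover) pins down.

All energies are kJ/mol, distances nm, angles radians internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np

from .constants import pn_to_internal

if TYPE_CHECKING:  # pragma: no cover
    from .model import ChainTopology, Frame

__all__ = [
    "PotentialParams",
    "lj",
    "lj_force",
    "softcore_lj",
    "softcore_force",
    "energy_and_forces",
    "total_energy",
    "minimize",
    "softcore_table",
]


@dataclass(frozen=True)
class PotentialParams:
    """Force-field parameters of the coarse-grained model.

    Defaults follow common one-bead-per-residue conventions: 0.38 nm
    Cα-Cα bonds, sigma = 0.47 nm excluded-volume beads with a weak
    (1 kJ/mol) well.  Sulfur-sulfur pairs use Amber-style sulfur
    parameters (sigma 0.356 nm, epsilon 1.046 kJ/mol) under the softcore
    form with a 0.35 nm crossover, which sits on the repulsive flank
    just below the S-S well minimum.  The disulfide cross-link is a
    stiff harmonic spring at 0.39 nm.
    """

    # nonbonded
    sigma: float = 0.47          # nm, generic and mixed bead pairs
    epsilon: float = 1.0         # kJ/mol
    sigma_ss: float = 0.356      # nm, sulfur-sulfur pairs
    epsilon_ss: float = 1.046    # kJ/mol
    lj_cutoff: float = 1.0       # nm, plain truncation
    # softcore bookkeeping + crossover
    softcore_alpha: float = 0.3
    softcore_lambda: float = 0.9
    softcore_power: int = 1
    crossover: float = 0.35      # nm; softcore == LJ at and beyond this
    # bonded
    bond_k: float = 15000.0      # kJ/mol/nm^2
    bond_r0: float = 0.38        # nm
    angle_k: float = 2.0         # kJ/mol/rad^2
    angle_theta0: float = 2.12   # rad (~121 deg pseudo-bond angle)
    crosslink_k: float = 15000.0  # kJ/mol/nm^2
    crosslink_r0: float = 0.39   # nm

    def __post_init__(self) -> None:
        for name in ("bond_k", "angle_k", "crosslink_k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.softcore_lambda < 1.0):
            raise ValueError("softcore_lambda must lie in (0, 1)")
        if not (0.0 < self.crossover < self.lj_cutoff):
            raise ValueError("crossover must lie in (0, lj_cutoff)")

    # --- softcore quadratic-core coefficients -------------------------
    def softcore_coefficients(self) -> tuple[float, float]:
        """(A, C) of the core V(r) = A + C r^2 for r < crossover.

        Chosen so that value and first derivative match the plain LJ
        curve at the crossover; the core force -dV/dr = -2Cr then decays
        linearly to zero at r = 0.
        """
        rc = self.crossover
        v = _lj_raw(rc, self.sigma_ss, self.epsilon_ss)
        dv = _lj_raw_deriv(rc, self.sigma_ss, self.epsilon_ss)
        c = dv / (2.0 * rc)
        a = v - c * rc**2
        return a, c

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PotentialParams":
        return cls(**d)


def _lj_raw(r, sigma, epsilon):
    s6 = (sigma / r) ** 6
    return 4.0 * epsilon * (s6 * s6 - s6)


def _lj_raw_deriv(r, sigma, epsilon):
    s6 = (sigma / r) ** 6
    return 4.0 * epsilon * (-12.0 * s6 * s6 + 6.0 * s6) / r


def lj(r, sigma: float, epsilon: float, cutoff: float | None = None):
    """Truncated 12-6 Lennard-Jones potential, kJ/mol.

    Zero at r = sigma, minimum -epsilon at 2^(1/6) sigma, zero at and
    beyond the cutoff (plain truncation, no shift).  ``r`` may be a
    scalar or array; r <= 0 raises.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("lj requires r > 0")
    v = _lj_raw(r, sigma, epsilon)
    if cutoff is not None:
        v = np.where(r >= cutoff, 0.0, v)
    return v if v.ndim else float(v)


def lj_force(r, sigma: float, epsilon: float, cutoff: float | None = None):
    """Radial force -dV/dr of the truncated LJ potential, kJ/mol/nm."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("lj_force requires r > 0")
    f = -_lj_raw_deriv(r, sigma, epsilon)
    if cutoff is not None:
        f = np.where(r >= cutoff, 0.0, f)
    return f if f.ndim else float(f)


def softcore_lj(r, params: PotentialParams):
    """Softcore sulfur-sulfur potential, kJ/mol.

    Exactly the plain truncated LJ curve for r >= params.crossover;
    a bounded quadratic core below it (finite at r = 0), continuous and
    once differentiable everywhere.  Accepts r >= 0.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("softcore_lj requires r >= 0")
    a, c = params.softcore_coefficients()
    core = a + c * r**2
    # evaluate LJ only where safe (r > 0); core branch covers the rest
    safe = np.where(r >= params.crossover, r, params.crossover)
    outer = np.where(
        safe >= params.lj_cutoff,
        0.0,
        _lj_raw(safe, params.sigma_ss, params.epsilon_ss),
    )
    v = np.where(r >= params.crossover, outer, core)
    return v if v.ndim else float(v)


def softcore_force(r, params: PotentialParams):
    """Radial force -dV/dr of the softcore potential, kJ/mol/nm.

    Finite for all r >= 0 (zero at r = 0); equals the plain LJ force at
    and beyond the crossover.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("softcore_force requires r >= 0")
    _, c = params.softcore_coefficients()
    core = -2.0 * c * r
    safe = np.where(r >= params.crossover, r, params.crossover)
    outer = np.where(
        safe >= params.lj_cutoff,
        0.0,
        -_lj_raw_deriv(safe, params.sigma_ss, params.epsilon_ss),
    )
    f = np.where(r >= params.crossover, outer, core)
    return f if f.ndim else float(f)


def softcore_table(params: PotentialParams, r_max: float | None = None,
                   dr: float = 0.001) -> np.ndarray:
    """Tabulated softcore curve: columns (r, V, -dV/dr).

    Mirrors the tabulated-potential mechanism of molecular dynamics
    engines; useful for inspection and plotting.
    """
    r_max = params.lj_cutoff if r_max is None else r_max
    r = np.arange(0.0, r_max + 0.5 * dr, dr)
    return np.column_stack([r, softcore_lj(r, params), softcore_force(r, params)])


# ----------------------------------------------------------------------
# full-chain energy and forces (numpy reference implementation)
# ----------------------------------------------------------------------

def _mask_array(topology: "ChainTopology", moving_mask) -> np.ndarray | None:
    if moving_mask is None:
        return None
    m = np.zeros(topology.n_residues, dtype=bool)
    for i in moving_mask:
        if not (1 <= int(i) <= topology.n_residues):
            raise ValueError(f"mask residue {i} outside chain")
        m[int(i) - 1] = True
    return m


def energy_and_forces(
    coords: np.ndarray,
    topology: "ChainTopology",
    params: PotentialParams,
    *,
    force_pn: float = 0.0,
    pulling_axis: Sequence[float] = (1.0, 0.0, 0.0),
    fixed_residue: int = 1,
    pulled_residue: int | None = None,
    moving_mask: Iterable[int] | None = None,
) -> tuple[float, np.ndarray]:
    """Potential energy and forces (negative gradient) of a conformation.

    With ``moving_mask`` (an iterable of 1-based residue indices), only
    terms involving at least one masked residue contribute — the energy
    of the mobile subsystem used by the frozen-environment minimization.
    Forces are returned for every bead (including frozen ones, from the
    included terms); callers freeze beads by ignoring their forces.

    The pulling term is -F * (x_pulled - x_fixed)·axis with F converted
    from pN; it participates in the mask through its two end residues.
    """
    x = np.asarray(coords, dtype=float)
    n = topology.n_residues
    if x.shape != (n, 3):
        raise ValueError(f"coords shape {x.shape} does not match chain of {n}")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite coordinates")
    mask = _mask_array(topology, moving_mask)
    f = np.zeros_like(x)
    e = 0.0

    def _pair_weight(idx_a: np.ndarray, idx_b: np.ndarray) -> np.ndarray:
        if mask is None:
            return np.ones(len(idx_a), dtype=bool)
        return mask[idx_a] | mask[idx_b]

    # bonds ------------------------------------------------------------
    ia = np.arange(n - 1)
    ib = ia + 1
    sel = _pair_weight(ia, ib)
    if np.any(sel):
        d = x[ib[sel]] - x[ia[sel]]
        r = np.linalg.norm(d, axis=1)
        dr = r - params.bond_r0
        e += 0.5 * params.bond_k * float(np.sum(dr**2))
        fr = (-params.bond_k * dr / r)[:, None] * d  # force on ib
        np.add.at(f, ib[sel], fr)
        np.add.at(f, ia[sel], -fr)

    # bends ------------------------------------------------------------
    if n >= 3 and params.angle_k > 0:
        i0 = np.arange(n - 2)
        i1 = i0 + 1
        i2 = i0 + 2
        selang = (
            np.ones(n - 2, dtype=bool) if mask is None
            else mask[i0] | mask[i1] | mask[i2]
        )
        if np.any(selang):
            a0, a1, a2 = i0[selang], i1[selang], i2[selang]
            u = x[a0] - x[a1]
            v = x[a2] - x[a1]
            lu = np.linalg.norm(u, axis=1)
            lv = np.linalg.norm(v, axis=1)
            uh = u / lu[:, None]
            vh = v / lv[:, None]
            cth = np.clip(np.einsum("ij,ij->i", uh, vh), -1.0, 1.0)
            th = np.arccos(cth)
            dth = th - params.angle_theta0
            e += 0.5 * params.angle_k * float(np.sum(dth**2))
            sth = np.sqrt(np.maximum(1.0 - cth**2, 1e-12))
            coef = params.angle_k * dth / sth  # dV/dtheta / sin(theta)
            # dtheta/dx0 = (cth*uh - vh) / (lu*sth); analogous for x2
            g0 = (coef / lu)[:, None] * (cth[:, None] * uh - vh)
            g2 = (coef / lv)[:, None] * (cth[:, None] * vh - uh)
            np.add.at(f, a0, -g0)
            np.add.at(f, a2, -g2)
            np.add.at(f, a1, g0 + g2)

    # disulfide cross-link ---------------------------------------------
    xl = None
    if topology.disulfide is not None:
        a, b = topology.disulfide_pair()
        xl = (a - 1, b - 1)
        if mask is None or mask[xl[0]] or mask[xl[1]]:
            d = x[xl[1]] - x[xl[0]]
            r = float(np.linalg.norm(d))
            dr = r - params.crosslink_r0
            e += 0.5 * params.crosslink_k * dr**2
            fr = -params.crosslink_k * dr / r * d  # force on xl[1]
            f[xl[1]] += fr
            f[xl[0]] -= fr

    # nonbonded pairs: |i-j| >= 3, excluding the cross-linked pair -----
    is_s = np.zeros(n, dtype=bool)
    for i in topology.cysteines:
        is_s[i - 1] = True
    ii, jj = np.triu_indices(n, k=3)
    if xl is not None:
        keep = ~((ii == xl[0]) & (jj == xl[1]))
        ii, jj = ii[keep], jj[keep]
    sel = _pair_weight(ii, jj)
    ii, jj = ii[sel], jj[sel]
    if len(ii):
        d = x[jj] - x[ii]
        r = np.linalg.norm(d, axis=1)
        within = r < params.lj_cutoff
        ii, jj, d, r = ii[within], jj[within], d[within], r[within]
    if len(ii):
        ss_pair = is_s[ii] & is_s[jj]
        v = np.empty(len(ii))
        fr = np.empty(len(ii))  # radial force -dV/dr
        if np.any(~ss_pair):
            rr = r[~ss_pair]
            v[~ss_pair] = _lj_raw(rr, params.sigma, params.epsilon)
            fr[~ss_pair] = -_lj_raw_deriv(rr, params.sigma, params.epsilon)
        if np.any(ss_pair):
            rr = r[ss_pair]
            v[ss_pair] = softcore_lj(rr, params)
            fr[ss_pair] = softcore_force(rr, params)
        e += float(np.sum(v))
        fv = (fr / r)[:, None] * d  # force on jj along +d
        np.add.at(f, jj, fv)
        np.add.at(f, ii, -fv)

    # constant pulling force -------------------------------------------
    if force_pn != 0.0:
        if pulled_residue is None:
            pulled_residue = n
        axis = np.asarray(pulling_axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        fi, pi = fixed_residue - 1, pulled_residue - 1
        if mask is None or mask[fi] or mask[pi]:
            fmag = pn_to_internal(force_pn)
            e -= fmag * float(np.dot(x[pi] - x[fi], axis))
            f[pi] += fmag * axis
            f[fi] -= fmag * axis

    return e, f


def total_energy(
    frame: "Frame | np.ndarray",
    topology: "ChainTopology",
    params: PotentialParams,
    *,
    force_pn: float = 0.0,
    pulling_axis: Sequence[float] = (1.0, 0.0, 0.0),
    fixed_residue: int = 1,
    pulled_residue: int | None = None,
    moving_mask: Iterable[int] | None = None,
) -> float:
    """Potential energy of a conformation (see :func:`energy_and_forces`)."""
    coords = frame.coords if hasattr(frame, "coords") else frame
    e, _ = energy_and_forces(
        coords, topology, params,
        force_pn=force_pn, pulling_axis=pulling_axis,
        fixed_residue=fixed_residue, pulled_residue=pulled_residue,
        moving_mask=moving_mask,
    )
    return e


def minimize(
    coords: np.ndarray,
    topology: "ChainTopology",
    params: PotentialParams,
    *,
    mobile: Iterable[int] | None = None,
    force_pn: float = 0.0,
    pulling_axis: Sequence[float] = (1.0, 0.0, 0.0),
    fixed_residue: int = 1,
    pulled_residue: int | None = None,
    tol: float = 10.0,
    max_steps: int = 500,
    initial_step: float = 0.01,
) -> tuple[np.ndarray, float, bool]:
    """Steepest-descent energy minimization with an optional frozen environment.

    Only residues in ``mobile`` (1-based; all residues when ``None``)
    are displaced; coordinates of every other bead are bit-identical on
    return.  The energy being minimized is the mobile-subsystem energy
    (terms touching at least one mobile residue).  The step length is
    adapted: the maximum per-bead displacement starts at
    ``initial_step`` nm, grows by 1.2x after a downhill step and shrinks
    by 0.5x after an uphill one (which is rejected).

    Returns ``(coords, energy, converged)`` where ``converged`` means
    the largest mobile force dropped below ``tol`` (kJ/mol/nm).
    """
    x = np.array(coords, dtype=float, copy=True)
    n = topology.n_residues
    if mobile is None:
        mobile_idx = np.arange(n)
        mask_arg = None
    else:
        mobile_idx = np.array(sorted({int(i) - 1 for i in mobile}), dtype=int)
        if len(mobile_idx) == 0:
            e = total_energy(
                x, topology, params, force_pn=force_pn,
                pulling_axis=pulling_axis, fixed_residue=fixed_residue,
                pulled_residue=pulled_residue, moving_mask=[],
            )
            return x, e, True
        mask_arg = [int(i) + 1 for i in mobile_idx]

    def eval_at(xc):
        return energy_and_forces(
            xc, topology, params, force_pn=force_pn,
            pulling_axis=pulling_axis, fixed_residue=fixed_residue,
            pulled_residue=pulled_residue, moving_mask=mask_arg,
        )

    e, f = eval_at(x)
    h = initial_step
    converged = False
    for _ in range(max_steps):
        fm = f[mobile_idx]
        fmax = float(np.max(np.abs(fm))) if len(fm) else 0.0
        if fmax < tol:
            converged = True
            break
        trial = x.copy()
        trial[mobile_idx] = x[mobile_idx] + h * fm / fmax
        et, ft = eval_at(trial)
        if et < e:
            x, e, f = trial, et, ft
            h = min(h * 1.2, 0.1)
        else:
            h *= 0.5
            if h < 1e-8:
                break
    return x, e, converged
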