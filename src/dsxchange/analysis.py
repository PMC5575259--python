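"""Statistics of the exchange simulations.

Covers the full downstream analysis of a force-clamp campaign:
sulfur-sulfur distance distributions per (free thiol, disulfide sulfur)
pair, regioselectivity counts with a bootstrap standard error, attack
angle survival curves, unfolding statistics, principal component
analysis of the loop enclosed by the disulfide, and solvent-accessible
surface area (SASA) comparisons between reactive conformational groups
with a Kolmogorov-Smirnov test on decorrelated samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.transform import Rotation

from .model import ChainTopology, SwapEvent, Trajectory
from .simulator import end_to_end

__all__ = [
    "RegioselectivityResult",
    "PCAResult",
    "SASAResult",
    "UnfoldingResult",
    "ss_distances",
    "ss_distance_distributions",
    "regioselectivity",
    "angle_probability",
    "unfolding_statistics",
    "loop_pca",
    "sasa",
    "sphere_points",
    "autocorrelation_stride",
    "compare_sasa_groups",
]


# ----------------------------------------------------------------------
# distance distributions
# ----------------------------------------------------------------------

def ss_distances(
    trajectories: "Trajectory | Iterable[Trajectory]",
    topology: ChainTopology,
) -> pd.DataFrame:
    """Per-frame sulfur-sulfur distances for every (thiol, disulfide) pair.

    Returns a DataFrame with columns ``time`` and ``d{thiol}_{sulfur}``
    (nm), frames from all trajectories concatenated.
    """
    if isinstance(trajectories, Trajectory):
        trajectories = [trajectories]
    a, b = topology.disulfide_pair()
    thiols = sorted(topology.free_thiols)
    rows = {f"d{t}_{s}": [] for t in thiols for s in (a, b)}
    times = []
    for traj in trajectories:
        coords = traj.coords_array()
        times.append(traj.times)
        for t in thiols:
            for s in (a, b):
                rows[f"d{t}_{s}"].append(
                    np.linalg.norm(coords[:, t - 1] - coords[:, s - 1], axis=1)
                )
    data = {k: np.concatenate(v) for k, v in rows.items()}
    data["time"] = np.concatenate(times)
    return pd.DataFrame(data)


def ss_distance_distributions(
    trajectories: "Trajectory | Iterable[Trajectory]",
    topology: ChainTopology,
    bins: int = 80,
    d_max: float = 4.0,
    close_cutoff: float = 0.5,
) -> dict[tuple[int, int], dict]:
    """Normalized distance histograms for the six thiol/disulfide pairs.

    For each (free thiol, disulfide sulfur) pair returns a density
    histogram over [0, d_max] plus a close-up below ``close_cutoff``
    (the region relevant for the exchange reaction).
    """
    df = ss_distances(trajectories, topology)
    a, b = topology.disulfide_pair()
    out: dict[tuple[int, int], dict] = {}
    for t in sorted(topology.free_thiols):
        for s in (a, b):
            d = df[f"d{t}_{s}"].to_numpy()
            dens, edges = np.histogram(d, bins=bins, range=(0.0, d_max), density=True)
            nclose = int(np.sum(d < close_cutoff))
            if nclose:
                cdens, cedges = np.histogram(
                    d[d < close_cutoff], bins=20, range=(0.0, close_cutoff),
                    density=True,
                )
            else:
                cdens, cedges = np.zeros(20), np.linspace(0, close_cutoff, 21)
            out[(t, s)] = {
                "density": dens,
                "edges": edges,
                "close_density": cdens,
                "close_edges": cedges,
                "n_close": nclose,
                "n": len(d),
            }
    return out


# ----------------------------------------------------------------------
# regioselectivity
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class RegioselectivityResult:
    """Counts of exchange events per attacked sulfur and their ratio.

    ``n_target_a / n_target_b`` is the regioselectivity (55Cys over
    24Cys for the fixture).  The standard error comes from resampling
    trajectories (one counted event each) with replacement; resamples
    with an empty denominator are redrawn, and how often that happened
    is reported.
    """

    target_a: int
    target_b: int
    n_a: int
    n_b: int
    ratio: float
    infinite: bool
    bootstrap_se: float
    n_bootstrap: int
    n_redrawn: int
    cutoff: float | None = None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        r = "inf" if self.infinite else f"{self.ratio:.3g}"
        return (
            f"N{self.target_a}={self.n_a}, N{self.target_b}={self.n_b}, "
            f"ratio={r} +/- {self.bootstrap_se:.3g}"
        )


def regioselectivity(
    events: Sequence[SwapEvent],
    n_bootstrap: int = 10_000,
    rng: np.random.Generator | None = None,
    target_a: int = 55,
    target_b: int = 24,
    attacker: int | None = None,
    cutoff: float | None = None,
) -> RegioselectivityResult:
    """Regioselectivity ratio N_a/N_b with a bootstrap standard error.

    ``events`` is the per-trajectory list of counted (accepted) events;
    events attacking other residues than the two targets are ignored for
    the ratio but participate in the resampling (the bootstrap unit is
    the trajectory).  ``attacker`` optionally restricts the counting to
    one attacking cysteine.  The ratio for a zero denominator is
    reported as ``inf`` with the ``infinite`` flag set.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    kept = [
        e for e in events
        if e.verdict == "accepted" or e.verdict == "detected"
    ]
    if attacker is not None:
        kept = [e for e in kept if e.attacker == attacker]
    targets = np.array([e.target for e in kept], dtype=int)
    n_a = int(np.sum(targets == target_a))
    n_b = int(np.sum(targets == target_b))
    infinite = n_b == 0
    ratio = float("inf") if infinite else n_a / n_b
    se = float("nan")
    n_redrawn = 0
    m = len(targets)
    if m and not infinite and n_bootstrap > 0:
        ratios = np.empty(n_bootstrap)
        filled = 0
        while filled < n_bootstrap:
            todo = n_bootstrap - filled
            idx = rng.integers(0, m, size=(todo, m))
            t = targets[idx]
            ka = np.sum(t == target_a, axis=1)
            kb = np.sum(t == target_b, axis=1)
            ok = kb > 0
            n_redrawn += int(np.sum(~ok))
            good = (ka[ok] / kb[ok])[: todo]
            ratios[filled:filled + len(good)] = good
            filled += len(good)
        se = float(np.std(ratios))
    return RegioselectivityResult(
        target_a=target_a, target_b=target_b, n_a=n_a, n_b=n_b,
        ratio=ratio, infinite=infinite, bootstrap_se=se,
        n_bootstrap=n_bootstrap, n_redrawn=n_redrawn, cutoff=cutoff,
    )


# ----------------------------------------------------------------------
# attack angles
# ----------------------------------------------------------------------

def angle_probability(
    angles_by_target: dict[int, Sequence[float]],
    theta_grid: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Survival curves P(angle > theta) per attacked sulfur.

    ``angles_by_target`` maps a target residue to the attack angles (in
    degrees) of its reactive conformations.  Returns a DataFrame with
    the grid, one survival column per target, and the ratio of the first
    two targets' curves where defined.  Empty angle sets yield NaN
    columns (flagged with a warning).
    """
    if theta_grid is None:
        theta_grid = np.arange(0.0, 181.0, 5.0)
    theta = np.asarray(theta_grid, dtype=float)
    out = {"theta": theta}
    for tgt, angles in angles_by_target.items():
        arr = np.asarray(list(angles), dtype=float)
        if arr.size == 0:
            warnings.warn(f"no reactive conformations for target {tgt}")
            out[f"p_gt_{tgt}"] = np.full_like(theta, np.nan)
        else:
            out[f"p_gt_{tgt}"] = np.array(
                [np.mean(arr > th) for th in theta]
            )
    df = pd.DataFrame(out)
    targets = list(angles_by_target)
    if len(targets) >= 2:
        pa = df[f"p_gt_{targets[0]}"]
        pb = df[f"p_gt_{targets[1]}"]
        with np.errstate(divide="ignore", invalid="ignore"):
            df["ratio"] = pa / pb
    return df


# ----------------------------------------------------------------------
# unfolding statistics
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class UnfoldingResult:
    """First-crossing unfolding times and the cumulative frequency curve."""

    threshold: float
    n_trajectories: int
    unfolding_times: np.ndarray  # sorted first-crossing times (ps)
    fraction_unfolded: float

    def cumulative_curve(self) -> tuple[np.ndarray, np.ndarray]:
        """(times, cumulative fraction of all trajectories unfolded)."""
        t = np.sort(self.unfolding_times)
        frac = np.arange(1, len(t) + 1) / self.n_trajectories
        return t, frac


def unfolding_statistics(
    trajectories: Iterable[Trajectory], threshold: float = 20.0
) -> UnfoldingResult:
    """Unfolding times: first crossing of the end-to-end threshold.

    A chain counts as unfolded once its end-to-end distance exceeds
    ``threshold`` (20 nm by default, the boundary between the folded
    stand-in and the stretched, disulfide-bonded state).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    times = []
    n = 0
    for traj in trajectories:
        n += 1
        ee = end_to_end(traj)
        above = np.nonzero(ee > threshold)[0]
        if len(above):
            times.append(traj.times[above[0]])
    times = np.sort(np.array(times))
    frac = len(times) / n if n else 0.0
    return UnfoldingResult(
        threshold=threshold, n_trajectories=n,
        unfolding_times=times, fraction_unfolded=frac,
    )


# ----------------------------------------------------------------------
# loop PCA
# ----------------------------------------------------------------------

@dataclass
class PCAResult:
    """Principal components of the loop's positional fluctuations.

    ``eigenvectors`` has one orthonormal column per mode (length 3L for
    L loop beads), eigenvalues are variances in nm^2 in non-increasing
    order, ``projections`` holds per-frame scores on every mode, and
    ``aligned`` the superposed loop coordinates the decomposition was
    computed from.
    """

    mean_structure: np.ndarray          # (L, 3)
    eigenvectors: np.ndarray            # (3L, n_modes)
    eigenvalues: np.ndarray             # (n_modes,)
    projections: np.ndarray             # (n_frames, n_modes)
    aligned: np.ndarray                 # (n_frames, L, 3)
    variance_fraction_12: float
    rank_deficient: bool = False

    def reconstruct(self, i: int, n_modes: int | None = None) -> np.ndarray:
        """Rebuild aligned frame ``i`` from the mean plus mode scores."""
        k = self.projections.shape[1] if n_modes is None else n_modes
        flat = self.mean_structure.ravel() + self.eigenvectors[:, :k] @ self.projections[i, :k]
        return flat.reshape(self.mean_structure.shape)


def _superpose_onto(ref: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Optimally rotate/translate each frame of (m, L, 3) onto ``ref``."""
    ref0 = ref - ref.mean(axis=0)
    out = np.empty_like(coords)
    for i, c in enumerate(coords):
        c0 = c - c.mean(axis=0)
        rot, _ = Rotation.align_vectors(ref0, c0)
        out[i] = rot.apply(c0)
    return out


def loop_pca(
    trajectories: "Trajectory | Iterable[Trajectory]",
    loop_range: tuple[int, int] = (24, 55),
    unfolded_only: bool = True,
    threshold: float = 20.0,
    max_iter: int = 30,
    tol: float = 1e-10,
    max_frames: int | None = 4000,
    superpose: bool = True,
) -> PCAResult:
    """PCA of the loop enclosed by the disulfide.

    Frames are restricted to the unfolded part of each trajectory when
    ``unfolded_only`` (end-to-end above ``threshold``; the folded prefix
    is discarded).  Conformations are iteratively superposed onto their
    running mean (rotate/translate, recompute mean, repeat to
    convergence) before the covariance eigendecomposition, removing the
    ambiguous rigid-body motion of the highly flexible loop
    (``superpose=False`` analyzes pre-aligned coordinates as-is, apart
    from centroid removal).  ``max_frames`` caps the ensemble by
    striding.
    """
    if isinstance(trajectories, Trajectory):
        trajectories = [trajectories]
    lo, hi = loop_range
    chunks = []
    for traj in trajectories:
        coords = traj.coords_array()[:, lo - 1:hi, :]
        if unfolded_only:
            keep = end_to_end(traj) > threshold
            coords = coords[keep]
        if len(coords):
            chunks.append(coords)
    if not chunks:
        raise ValueError("no frames to analyze (nothing unfolded?)")
    coords = np.concatenate(chunks)
    if max_frames is not None and coords.shape[0] > max_frames:
        stride = int(np.ceil(coords.shape[0] / max_frames))
        coords = coords[::stride]
    m, L, _ = coords.shape
    if m < 3 * L:
        warnings.warn(
            f"fewer frames ({m}) than loop coordinates ({3 * L}): "
            "covariance is rank deficient, spectrum truncated"
        )
    aligned = coords - coords.mean(axis=1, keepdims=True)
    if superpose:
        ref = aligned[0]
        for _ in range(max_iter):
            aligned = _superpose_onto(ref, aligned)
            new_ref = aligned.mean(axis=0)
            shift = float(np.max(np.abs(new_ref - ref)))
            ref = new_ref
            if shift < tol:
                break
    flat = aligned.reshape(m, 3 * L)
    mean_flat = flat.mean(axis=0)
    centered = flat - mean_flat
    cov = centered.T @ centered / m
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    projections = centered @ evecs
    total = float(np.sum(evals))
    vf12 = float(np.sum(evals[:2]) / total) if total > 0 else 0.0
    return PCAResult(
        mean_structure=mean_flat.reshape(L, 3),
        eigenvectors=evecs,
        eigenvalues=evals,
        projections=projections,
        aligned=aligned,
        variance_fraction_12=vf12,
        rank_deficient=m < 3 * L,
    )


# ----------------------------------------------------------------------
# solvent accessible surface area (Shrake-Rupley)
# ----------------------------------------------------------------------

def sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (Fibonacci lattice)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa(
    coords: np.ndarray,
    radii: "float | np.ndarray",
    probe: float = 0.14,
    n_points: int = 960,
) -> float:
    """Solvent-accessible surface area by the Shrake-Rupley method, nm^2.

    Each bead is covered with ``n_points`` quasi-uniform test points on
    its probe-expanded sphere of radius r_i + probe; points falling
    inside any neighbor's expanded sphere are buried.  The exposed
    fraction times 4 pi (r_i + probe)^2, summed over beads, is the SASA.
    """
    x = np.asarray(coords, dtype=float)
    n = x.shape[0]
    r = np.broadcast_to(np.asarray(radii, dtype=float), (n,)).copy()
    if np.any(r <= 0) or probe < 0:
        raise ValueError("radii must be positive and probe non-negative")
    expanded = r + probe
    unit = sphere_points(n_points)
    total = 0.0
    for i in range(n):
        pts = x[i] + expanded[i] * unit
        exposed = np.ones(n_points, dtype=bool)
        d = np.linalg.norm(x - x[i], axis=1)
        neighbors = np.nonzero(
            (d < expanded + expanded[i]) & (np.arange(n) != i)
        )[0]
        for j in neighbors:
            d2 = np.sum((pts - x[j]) ** 2, axis=1)
            e2 = expanded[j] ** 2
            # strictly-inside points are buried; points on the neighbor's
            # surface (within fp tolerance) are broken lexicographically
            # so coincident identical beads contribute their shared
            # surface once, not 0 or 2x
            boundary = np.abs(d2 - e2) <= 1e-12 * e2
            exposed &= ((d2 > e2) & ~boundary) | (boundary & (j > i))
            if not exposed.any():
                break
        total += exposed.mean() * 4.0 * np.pi * expanded[i] ** 2
    return float(total)


def autocorrelation_stride(series: Sequence[float]) -> int:
    """Frames until the normalized autocorrelation first touches zero.

    Used to pick a subsampling stride at which consecutive samples are
    decorrelated (the paper's analogue sampled every 2 ns for the same
    reason).  Returns at least 1.
    """
    x = np.asarray(series, dtype=float)
    x = x - x.mean()
    if len(x) < 2 or np.allclose(x, 0):
        return 1
    acf = np.correlate(x, x, mode="full")[len(x) - 1:]
    acf = acf / acf[0]
    below = np.nonzero(acf <= 0)[0]
    return int(below[0]) if len(below) else max(1, len(x) // 2)


@dataclass(frozen=True)
class SASAResult:
    """Two-sample KS comparison of SASA distributions of reactive groups."""

    mean_a: float
    mean_b: float
    label_a: str
    label_b: str
    n_a: int
    n_b: int
    stride_a: int
    stride_b: int
    ks_statistic: float
    p_value: float
    more_compact: str   # label of the group with the smaller mean SASA
    skipped: bool = False


def compare_sasa_groups(
    sasa_a: Sequence[float],
    sasa_b: Sequence[float],
    label_a: str = "32->24",
    label_b: str = "32->55",
    stride_a: int | None = None,
    stride_b: int | None = None,
) -> SASAResult:
    """KS test between two groups of per-frame SASA values.

    Each group is subsampled at its autocorrelation-zero stride (unless
    an explicit stride is given) so only approximately independent
    samples enter the exact two-sample Kolmogorov-Smirnov test.  Groups
    with fewer than two independent samples skip the test with a
    warning.
    """
    a = np.asarray(list(sasa_a), dtype=float)
    b = np.asarray(list(sasa_b), dtype=float)
    sa = autocorrelation_stride(a) if stride_a is None else max(1, stride_a)
    sb = autocorrelation_stride(b) if stride_b is None else max(1, stride_b)
    a_sub = a[::sa]
    b_sub = b[::sb]
    mean_a = float(a.mean()) if len(a) else float("nan")
    mean_b = float(b.mean()) if len(b) else float("nan")
    if len(a_sub) < 2 or len(b_sub) < 2:
        warnings.warn("fewer than 2 independent samples in a group; KS test skipped")
        return SASAResult(
            mean_a=mean_a, mean_b=mean_b, label_a=label_a, label_b=label_b,
            n_a=len(a_sub), n_b=len(b_sub), stride_a=sa, stride_b=sb,
            ks_statistic=float("nan"), p_value=float("nan"),
            more_compact=label_a if mean_a <= mean_b else label_b,
            skipped=True,
        )
    res = sps.ks_2samp(a_sub, b_sub, method="auto")
    return SASAResult(
        mean_a=mean_a, mean_b=mean_b, label_a=label_a, label_b=label_b,
        n_a=len(a_sub), n_b=len(b_sub), stride_a=sa, stride_b=sb,
        ks_statistic=float(res.statistic), p_value=float(res.pvalue),
        more_compact=label_a if mean_a <= mean_b else label_b,
    )
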