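"""The end-to-end campaign: replicate hybrid runs plus full analysis.

A campaign runs ``replicates`` seeded hybrid force-clamp simulations of
the five-cysteine fixture chain, collects the per-trajectory exchange
events (at most one counted event each), and derives every downstream
statistic: unfolding curve, sulfur-sulfur distance distributions,
regioselectivity with bootstrap error, attack-angle survival curves,
loop PCA, and the SASA comparison between reactive conformational
groups.  Everything is deterministic given the master seed; per-replicate
outputs are written as plain-text TSV and can be resumed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .analysis import (
    PCAResult,
    RegioselectivityResult,
    SASAResult,
    UnfoldingResult,
    angle_probability,
    compare_sasa_groups,
    loop_pca,
    regioselectivity,
    sasa,
    ss_distance_distributions,
    unfolding_statistics,
)
from .io import RunConfig, dump_run_config, read_trajectory_tsv, write_trajectory_tsv
from .model import SwapEvent, Trajectory, build_i27_star
from .simulator import end_to_end
from .swap_engine import run_hybrid

logger = logging.getLogger("dsxchange")

__all__ = ["CampaignReport", "campaign", "replicate_seed", "events_to_frame"]


def replicate_seed(master_seed: int, replicate: int, stream: int = 0) -> int:
    """Derived sub-seed (< 2^31) for one replicate and stream."""
    ss = np.random.SeedSequence([int(master_seed), int(replicate), int(stream)])
    return int(ss.generate_state(1)[0] % (2**31))


def events_to_frame(events: list[tuple[int, SwapEvent]]) -> pd.DataFrame:
    """Tabulate (replicate, event) pairs."""
    rows = [
        {
            "replicate": rep,
            "time": e.time,
            "attacker": e.attacker,
            "target": e.target,
            "leaving": e.leaving,
            "d_ss": e.d_ss,
            "angle": e.angle,
            "verdict": e.verdict,
            "dE": e.dE,
            "n_rejected": e.n_rejected,
        }
        for rep, e in events
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "replicate", "time", "attacker", "target", "leaving",
            "d_ss", "angle", "verdict", "dE", "n_rejected",
        ],
    )


@dataclass
class CampaignReport:
    """Aggregated results of a campaign."""

    config: RunConfig
    n_replicates: int
    events: pd.DataFrame
    unfolding: Optional[UnfoldingResult]
    regioselectivity: Optional[RegioselectivityResult]
    regioselectivity_by_attacker: dict[int, RegioselectivityResult]
    attacker_counts: dict[int, int]
    distance_histograms: Optional[dict]
    pca: Optional[PCAResult]
    sasa_comparison: Optional[SASAResult]
    angle_survival: Optional[pd.DataFrame]

    def summary_dict(self) -> dict:
        """JSON-friendly headline numbers."""
        out: dict = {
            "n_replicates": self.n_replicates,
            "n_events": int((self.events["verdict"] == "accepted").sum())
            if len(self.events) else 0,
            "attacker_counts": {str(k): v for k, v in self.attacker_counts.items()},
        }
        if self.unfolding is not None:
            out["fraction_unfolded"] = self.unfolding.fraction_unfolded
            out["median_unfolding_time"] = (
                float(np.median(self.unfolding.unfolding_times))
                if len(self.unfolding.unfolding_times) else None
            )
        if self.regioselectivity is not None:
            r = self.regioselectivity
            out["regioselectivity"] = {
                f"N{r.target_a}": r.n_a,
                f"N{r.target_b}": r.n_b,
                "ratio": None if r.infinite else r.ratio,
                "infinite": r.infinite,
                "bootstrap_se": None if np.isnan(r.bootstrap_se) else r.bootstrap_se,
            }
        if self.pca is not None:
            out["pca_variance_fraction_12"] = self.pca.variance_fraction_12
        if self.sasa_comparison is not None and not self.sasa_comparison.skipped:
            s = self.sasa_comparison
            out["sasa"] = {
                s.label_a: s.mean_a, s.label_b: s.mean_b,
                "ks_statistic": s.ks_statistic, "p_value": s.p_value,
                "more_compact": s.more_compact,
            }
        return out


def _run_one(config: RunConfig, replicate: int, outdir: Path | None):
    """Run (or resume) one replicate; returns (trajectory, events)."""
    if outdir is not None:
        tsv = outdir / f"replicate_{replicate:04d}.tsv"
        ev_path = outdir / f"replicate_{replicate:04d}.events.json"
        if tsv.exists() and ev_path.exists():
            traj = read_trajectory_tsv(tsv)
            with open(ev_path) as fh:
                events = [SwapEvent(**d) for d in json.load(fh)]
            logger.info("replicate %d: resumed from %s", replicate, tsv)
            return traj, events
    build_seed = replicate_seed(config.master_seed, replicate, stream=1)
    sim_seed = replicate_seed(config.master_seed, replicate, stream=0)
    topo, start = build_i27_star(bond_length=config.bond_length, seed=build_seed)
    sim_cfg = config.simulation.to_dataclass(seed=sim_seed)
    criterion = config.criterion.to_dataclass()
    result = run_hybrid(
        start, topo, config.potentials.to_dataclass(), sim_cfg, criterion,
        rewire=not config.virtual_swaps,
    )
    for e in result.events:
        logger.info(
            "replicate %d t=%.1f ps: %d -> %d (leaving %d) d=%.3f nm %s",
            replicate, e.time, e.attacker, e.target, e.leaving, e.d_ss, e.verdict,
        )
    if outdir is not None:
        write_trajectory_tsv(result.trajectory, tsv)
        with open(ev_path, "w") as fh:
            json.dump([vars(e) for e in result.events], fh, indent=1)
    return result.trajectory, result.events


def campaign(config: RunConfig, outdir: str | Path | None = None) -> CampaignReport:
    """Run the full campaign described by ``config``.

    Per-replicate failures are logged and skipped; the aggregate
    analysis uses whatever completed.  With ``outdir``, the exact
    configuration, per-replicate trajectories/events and the aggregate
    report are written there and finished replicates are not rerun.
    """
    out = None
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        dump_run_config(config, out / "config.yaml")
    trajectories: list[Trajectory] = []
    all_events: list[tuple[int, SwapEvent]] = []
    for rep in range(config.replicates):
        try:
            traj, events = _run_one(config, rep, out)
        except Exception:
            logger.exception("replicate %d failed; continuing", rep)
            continue
        trajectories.append(traj)
        all_events.extend((rep, e) for e in events)
    events_df = events_to_frame(all_events)
    report = _analyze(config, trajectories, all_events, events_df)
    if out is not None:
        events_df.to_csv(out / "events.tsv", sep="\t", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(report.summary_dict(), fh, indent=1)
    return report


def _reactive_groups(
    config: RunConfig, trajectories: list[Trajectory]
) -> tuple[list[float], list[float], list[float]]:
    """Loop SASA of conformations reactive toward each disulfide sulfur.

    A frame belongs to group a/b when the attacking thiol (32 in the
    fixture) is within ``close_cutoff`` of that sulfur; the "all" group
    is a subsample of every unfolded frame.  SASA is computed over the
    loop beads with radius sigma/2 and the configured probe.
    """
    topo = trajectories[0].topology
    a, b = topo.disulfide_pair()
    attacker = 32 if 32 in topo.free_thiols else sorted(topo.free_thiols)[0]
    lo, hi = sorted((a, b))
    radius = config.potentials.sigma / 2.0
    group_a, group_b, group_all = [], [], []
    for traj in trajectories:
        coords = traj.coords_array()
        keep = end_to_end(traj) > config.unfold_threshold
        coords = coords[keep]
        if not len(coords):
            continue
        d_a = np.linalg.norm(coords[:, attacker - 1] - coords[:, a - 1], axis=1)
        d_b = np.linalg.norm(coords[:, attacker - 1] - coords[:, b - 1], axis=1)
        loop = coords[:, lo - 1:hi, :]
        for i in range(len(coords)):
            area = None
            if d_a[i] < config.close_cutoff:
                area = sasa(loop[i], radius, config.sasa_probe, config.sasa_points)
                group_a.append(area)
            if d_b[i] < config.close_cutoff:
                if area is None:
                    area = sasa(loop[i], radius, config.sasa_probe, config.sasa_points)
                group_b.append(area)
        # strided subsample for the background distribution
        for i in range(0, len(coords), max(1, len(coords) // 20)):
            group_all.append(sasa(loop[i], radius, config.sasa_probe, config.sasa_points))
    return group_a, group_b, group_all


def _analyze(
    config: RunConfig,
    trajectories: list[Trajectory],
    all_events: list[tuple[int, SwapEvent]],
    events_df: pd.DataFrame,
) -> CampaignReport:
    if not trajectories:
        return CampaignReport(
            config=config, n_replicates=0, events=events_df,
            unfolding=None, regioselectivity=None,
            regioselectivity_by_attacker={}, attacker_counts={},
            distance_histograms=None, pca=None, sasa_comparison=None,
            angle_survival=None,
        )
    topo = trajectories[0].topology
    a, b = topo.disulfide_pair()
    accepted = [e for _, e in all_events if e.verdict == "accepted"]
    rng = np.random.default_rng(
        np.random.SeedSequence([config.master_seed, 0xB007])
    )
    regio = regioselectivity(
        accepted, n_bootstrap=config.n_bootstrap, rng=rng,
        target_a=b, target_b=a, cutoff=config.criterion.d_cutoff,
    ) if accepted else None
    by_attacker = {}
    counts: dict[int, int] = {}
    for e in accepted:
        counts[e.attacker] = counts.get(e.attacker, 0) + 1
    for att in sorted(counts):
        by_attacker[att] = regioselectivity(
            accepted, n_bootstrap=0, target_a=b, target_b=a, attacker=att,
        )
    unfold = unfolding_statistics(trajectories, config.unfold_threshold)
    hists = ss_distance_distributions(
        trajectories, topo, close_cutoff=config.criterion.d_cutoff or 0.5
    )
    angles = {
        tgt: [e.angle for e in accepted if e.target == tgt] for tgt in (b, a)
    }
    angle_df = angle_probability(angles) if accepted else None
    pca = None
    if unfold.fraction_unfolded > 0:
        pca = loop_pca(
            trajectories, loop_range=(min(a, b), max(a, b)),
            unfolded_only=True, threshold=config.unfold_threshold,
        )
    sasa_cmp = None
    if unfold.fraction_unfolded > 0:
        ga, gb, _ = _reactive_groups(config, trajectories)
        labels = (f"32->{a}", f"32->{b}")
        if len(ga) >= 2 and len(gb) >= 2:
            sasa_cmp = compare_sasa_groups(ga, gb, label_a=labels[0], label_b=labels[1])
    return CampaignReport(
        config=config,
        n_replicates=len(trajectories),
        events=events_df,
        unfolding=unfold,
        regioselectivity=regio,
        regioselectivity_by_attacker=by_attacker,
        attacker_counts=counts,
        distance_histograms=hists,
        pca=pca,
        sasa_comparison=sasa_cmp,
        angle_survival=angle_df,
    )
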