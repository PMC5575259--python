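"""Run configuration, structure and trajectory file formats.

Configuration is YAML validated by pydantic models (unknown keys are
errors — a silently misspelled cutoff would corrupt the science).
Structures travel as standard PDB (Cα records, coordinates in Å on
disk, nm in memory; SSBOND records carry the disulfide) or as a plain
TSV trajectory format with a JSON metadata sidecar:

    time\tresidue\tx\ty\tz

one row per bead per frame, residue 1-based, coordinates in nm.  The
sidecar records the topology, the simulation config, the potential
parameters and the seed — enough to reproduce the run bit for bit.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import gemmi
import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .model import ChainTopology, Frame, Trajectory, TopologyError
from .potentials import PotentialParams
from .simulator import SimulationConfig
from .swap_engine import SwapCriterion

__all__ = [
    "FormatError",
    "RunConfig",
    "load_run_config",
    "dump_run_config",
    "read_topology_sidecar",
    "write_topology_sidecar",
    "write_trajectory_tsv",
    "read_trajectory_tsv",
    "write_pdb",
    "read_structure",
]


class FormatError(ValueError):
    """Malformed structure/trajectory input, with file context."""


# ----------------------------------------------------------------------
# run configuration
# ----------------------------------------------------------------------

class SimulationSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    force_pn: float = 480.0
    temperature: float = 300.0
    friction: float = 50.0
    timestep: float = 0.001
    n_steps: int = 1_500_000
    output_stride: int = 1000
    fixed_residue: int = 1
    pulled_residue: Optional[int] = None
    pulling_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)

    def to_dataclass(self, seed: int) -> SimulationConfig:
        return SimulationConfig(seed=seed, **self.model_dump())


class PotentialSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    sigma: float = 0.47
    epsilon: float = 1.0
    sigma_ss: float = 0.356
    epsilon_ss: float = 1.046
    lj_cutoff: float = 1.0
    softcore_alpha: float = 0.3
    softcore_lambda: float = 0.9
    softcore_power: int = 1
    crossover: float = 0.35
    bond_k: float = 15000.0
    bond_r0: float = 0.38
    angle_k: float = 2.0
    angle_theta0: float = 2.12
    crosslink_k: float = 15000.0
    crosslink_r0: float = 0.39

    def to_dataclass(self) -> PotentialParams:
        return PotentialParams(**self.model_dump())


class CriterionSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    mode: str = "distance"
    d_cutoff: float = 0.5
    angle_min: Optional[float] = None
    relax_radius: float = 0.5
    kT: float = 2.4943387854
    minimizer_tol: float = 10.0
    minimizer_max_steps: int = 500
    arm_end_to_end: Optional[float] = 20.0

    def to_dataclass(self) -> SwapCriterion:
        return SwapCriterion(**self.model_dump())


class TopologySettings(BaseModel):
    """Topology sidecar: chain length, cysteines, disulfide pair."""

    model_config = ConfigDict(extra="forbid")
    n_residues: int = 89
    cysteines: list[int] = Field(default_factory=lambda: [24, 32, 47, 55, 63])
    disulfide: Optional[list[int]] = Field(default_factory=lambda: [24, 55])

    @field_validator("disulfide")
    @classmethod
    def _pair(cls, v):
        if v is not None and len(v) != 2:
            raise ValueError("disulfide must list exactly two residues")
        return v

    def to_dataclass(self) -> ChainTopology:
        return ChainTopology(
            n_residues=self.n_residues,
            cysteines=frozenset(self.cysteines),
            disulfide=None if self.disulfide is None else frozenset(self.disulfide),
        )


class RunConfig(BaseModel):
    """Top-level campaign configuration (YAML serializable)."""

    model_config = ConfigDict(extra="forbid")
    simulation: SimulationSettings = Field(default_factory=SimulationSettings)
    potentials: PotentialSettings = Field(default_factory=PotentialSettings)
    criterion: CriterionSettings = Field(default_factory=CriterionSettings)
    topology: TopologySettings = Field(default_factory=TopologySettings)
    replicates: int = 100
    master_seed: int = 0
    virtual_swaps: bool = True   # count exchanges post-hoc, keep the native topology
    bond_length: float = 0.38
    unfold_threshold: float = 20.0
    close_cutoff: float = 0.6   # "reactive conformation" distance for SASA/PCA maps
    sasa_probe: float = 0.14
    sasa_points: int = 960
    n_bootstrap: int = 10_000


def load_run_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)


def dump_run_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=False)


def read_topology_sidecar(path: str | Path) -> ChainTopology:
    """Read a YAML topology sidecar (n_residues, cysteines, disulfide)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    try:
        return TopologySettings(**data).to_dataclass()
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_topology_sidecar(topology: ChainTopology, path: str | Path) -> None:
    data = {
        "n_residues": topology.n_residues,
        "cysteines": sorted(topology.cysteines),
        "disulfide": sorted(topology.disulfide) if topology.disulfide else None,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


# ----------------------------------------------------------------------
# TSV trajectory format
# ----------------------------------------------------------------------

def _topology_dict(topology: ChainTopology) -> dict:
    return {
        "n_residues": topology.n_residues,
        "cysteines": sorted(topology.cysteines),
        "disulfide": sorted(topology.disulfide) if topology.disulfide else None,
    }


def write_trajectory_tsv(trajectory: Trajectory, path: str | Path) -> None:
    """Write frames as TSV (time, residue, x, y, z) + JSON sidecar."""
    path = Path(path)
    n = trajectory.topology.n_residues
    rows = []
    for fr in trajectory:
        block = np.empty((n, 5))
        block[:, 0] = fr.time
        block[:, 1] = np.arange(1, n + 1)
        block[:, 2:] = fr.coords
        rows.append(block)
    df = pd.DataFrame(
        np.concatenate(rows), columns=["time", "residue", "x", "y", "z"]
    )
    df["residue"] = df["residue"].astype(int)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    meta = dict(trajectory.metadata)
    meta["topology"] = _topology_dict(trajectory.topology)
    with open(path.with_suffix(path.suffix + ".meta.json"), "w") as fh:
        json.dump(meta, fh, indent=1)


def read_trajectory_tsv(path: str | Path) -> Trajectory:
    """Read a TSV trajectory written by :func:`write_trajectory_tsv`."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse TSV ({exc})") from exc
    required = {"time", "residue", "x", "y", "z"}
    if not required <= set(df.columns):
        raise FormatError(
            f"{path}: missing columns {sorted(required - set(df.columns))}"
        )
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = json.load(fh)
        topo = TopologySettings(**meta.pop("topology")).to_dataclass()
    else:
        n = int(df["residue"].max())
        topo = ChainTopology(n_residues=n, cysteines=frozenset())
        meta = {}
    frames = []
    for t, group in df.groupby("time", sort=True):
        group = group.sort_values("residue")
        res = group["residue"].to_numpy()
        if len(res) != topo.n_residues or not np.array_equal(
            res, np.arange(1, topo.n_residues + 1)
        ):
            raise FormatError(
                f"{path}: frame at t={t} does not list every residue exactly once"
            )
        frames.append(Frame(time=float(t), coords=group[["x", "y", "z"]].to_numpy()))
    return Trajectory(frames=frames, topology=topo, metadata=meta)


# ----------------------------------------------------------------------
# PDB structures (via gemmi)
# ----------------------------------------------------------------------

_NM_TO_A = 10.0


def write_pdb(
    frames: "Frame | list[Frame]",
    topology: ChainTopology,
    path: str | Path,
) -> None:
    """Write one or more frames as a (multi-model) Cα-trace PDB.

    Cysteine beads are written as CYS/SG-bearing residues (the bead is
    the sulfur position at this resolution, but the atom record is CA
    for uniformity); the disulfide becomes an SSBOND record.
    """
    if isinstance(frames, Frame):
        frames = [frames]
    st = gemmi.Structure()
    st.name = "dsxchange CG chain"
    for mi, fr in enumerate(frames, start=1):
        model = gemmi.Model(str(mi))
        chain = gemmi.Chain("A")
        for i in range(topology.n_residues):
            res = gemmi.Residue()
            res.name = "CYS" if (i + 1) in topology.cysteines else "GLY"
            res.seqid = gemmi.SeqId(i + 1, " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            x, y, z = fr.coords[i] * _NM_TO_A
            atom.pos = gemmi.Position(x, y, z)
            res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
        st.add_model(model)
    if topology.disulfide is not None:
        a, b = topology.disulfide_pair()
        chain = st[0][0]
        con = gemmi.Connection()
        con.type = gemmi.ConnectionType.Disulf
        con.partner1 = gemmi.make_address(chain, chain[a - 1], chain[a - 1][0])
        con.partner2 = gemmi.make_address(chain, chain[b - 1], chain[b - 1][0])
        st.connections.append(con)
    st.setup_entities()
    with open(path, "w") as fh:
        fh.write(st.make_pdb_string())


def read_structure(
    path: str | Path,
    sidecar: str | Path | None = None,
) -> tuple[ChainTopology, Frame]:
    """Read a single-model PDB into a one-bead-per-residue chain.

    Cα coordinates are extracted (Å on disk, nm in memory) with the
    file's 1-based residue numbering.  Cysteines are taken from CYS
    residue names, the disulfide from SSBOND records; a YAML sidecar
    (see :func:`read_topology_sidecar`) overrides both.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse PDB ({exc})") from exc
    if len(st) == 0 or len(st[0]) == 0:
        raise FormatError(f"{path}: no model/chain found")
    if len(st) > 1:
        raise FormatError(f"{path}: expected a single model, found {len(st)}")
    chain = st[0][0]
    coords = []
    numbers = []
    cys = set()
    for res in chain:
        cas = [a for a in res if a.name == "CA"]
        if not cas:
            raise FormatError(
                f"{path}: residue {res.seqid.num} {res.name} has no CA atom"
            )
        ca = cas[0]
        num = res.seqid.num
        if num in numbers or len(cas) > 1:
            raise FormatError(f"{path}: duplicate residue number {num}")
        numbers.append(num)
        coords.append([ca.pos.x, ca.pos.y, ca.pos.z])
        if res.name == "CYS":
            cys.add(num)
    if not numbers:
        raise FormatError(f"{path}: empty chain")
    if numbers != list(range(1, len(numbers) + 1)):
        raise FormatError(
            f"{path}: residues must be numbered 1..n without gaps "
            f"(found {numbers[0]}..{numbers[-1]}, n={len(numbers)})"
        )
    disulfide = None
    for con in st.connections:
        if con.type == gemmi.ConnectionType.Disulf:
            a = con.partner1.res_id.seqid.num
            b = con.partner2.res_id.seqid.num
            disulfide = frozenset({a, b})
            break
    if sidecar is not None:
        topo = read_topology_sidecar(sidecar)
        if topo.n_residues != len(numbers):
            raise FormatError(
                f"{sidecar}: sidecar says {topo.n_residues} residues, "
                f"PDB has {len(numbers)}"
            )
    else:
        if disulfide is not None and not disulfide <= cys:
            raise FormatError(
                f"{path}: SSBOND names non-cysteine residues {sorted(disulfide - cys)}"
            )
        topo = ChainTopology(
            n_residues=len(numbers),
            cysteines=frozenset(cys),
            disulfide=disulfide,
        )
    frame = Frame(time=0.0, coords=np.array(coords) / _NM_TO_A)
    return topo, frame
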