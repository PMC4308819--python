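"""File formats: trajectories, series, clustering results, graphs, configs.

All on-disk coordinates are Angstrom. Multi-model PDB parsing/writing goes
through biotite; XYZ is read and written directly (the plain 4-column text
flavor, element symbol plus coordinates, one block per frame) so element
metadata round-trips exactly. CSV series carry a header row and a leading
comment line stating units.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from biotite.structure import AtomArray, AtomArrayStack
from biotite.structure.io.pdb import PDBFile

from .cluster import Clustering, ElbowTrace
from .geometry import Frame, Trajectory
from .graph import TransitionGraph

__all__ = [
    "read_trajectory",
    "write_trajectory",
    "read_pdb_trajectory",
    "write_pdb_trajectory",
    "read_xyz_trajectory",
    "write_xyz_trajectory",
    "write_series_csv",
    "read_series_csv",
    "write_labels_csv",
    "read_labels_csv",
    "write_clustering_json",
    "read_clustering_json",
    "write_graphml",
    "write_dot",
    "write_paths_tsv",
    "write_profile_csv",
    "load_config",
]


class TrajectoryFormatError(ValueError):
    """Raised when a trajectory file is malformed or inconsistent."""


def read_trajectory(path, fmt: str | None = None) -> Trajectory:
    """Read a multi-model PDB or XYZ trajectory (format from suffix if omitted)."""
    path = Path(path)
    if fmt is None:
        fmt = "xyz" if path.suffix.lower() == ".xyz" else "pdb_multimodel"
    if fmt == "pdb_multimodel":
        return read_pdb_trajectory(path)
    if fmt == "xyz":
        return read_xyz_trajectory(path)
    raise ValueError(f"unknown trajectory format {fmt!r}")


def write_trajectory(traj: Trajectory, path, fmt: str | None = None) -> None:
    path = Path(path)
    if fmt is None:
        fmt = "xyz" if path.suffix.lower() == ".xyz" else "pdb_multimodel"
    if fmt == "pdb_multimodel":
        write_pdb_trajectory(traj, path)
    elif fmt == "xyz":
        write_xyz_trajectory(traj, path)
    else:
        raise ValueError(f"unknown trajectory format {fmt!r}")


def read_pdb_trajectory(path) -> Trajectory:
    try:
        stack = PDBFile.read(str(path)).get_structure(model=None)
    except Exception as err:
        raise TrajectoryFormatError(f"cannot parse PDB {path}: {err}") from err
    coords = np.asarray(stack.coord, dtype=float)
    if coords.ndim == 2:  # biotite collapses single-model files
        coords = coords[None, :, :]
    return Trajectory(
        coords=np.asarray(coords, dtype=float),
        atom_names=list(stack.atom_name),
        residue_names=list(stack.res_name),
        residue_ids=np.asarray(stack.res_id, dtype=int),
        chain_ids=list(stack.chain_id),
        elements=list(stack.element),
    )


def _to_atom_array_stack(traj: Trajectory) -> AtomArrayStack:
    n_frames, n_atoms = traj.n_frames, traj.n_atoms
    stack = AtomArrayStack(n_frames, n_atoms)
    stack.coord = np.asarray(traj.coords, dtype=np.float32)
    stack.atom_name = np.array(traj.atom_names or [f"C{i+1}" for i in range(n_atoms)])
    stack.res_name = np.array(traj.residue_names or ["UNK"] * n_atoms)
    stack.res_id = np.asarray(
        traj.residue_ids if traj.residue_ids is not None else np.ones(n_atoms, dtype=int)
    )
    stack.chain_id = np.array(traj.chain_ids or ["A"] * n_atoms)
    stack.element = np.array(traj.elements or ["C"] * n_atoms)
    stack.hetero = np.zeros(n_atoms, dtype=bool)
    return stack


def write_pdb_trajectory(traj: Trajectory, path) -> None:
    f = PDBFile()
    f.set_structure(_to_atom_array_stack(traj))
    f.write(str(path))


def read_xyz_trajectory(path) -> Trajectory:
    """Read plain XYZ: repeated blocks of (count, comment, count atom lines)."""
    lines = Path(path).read_text().splitlines()
    frames: list[np.ndarray] = []
    elements: list[str] | None = None
    i = 0
    model = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        model += 1
        try:
            n = int(lines[i].split()[0])
        except ValueError as err:
            raise TrajectoryFormatError(
                f"{path}: model {model}: expected atom count, got {lines[i]!r}"
            ) from err
        body = lines[i + 2 : i + 2 + n]
        if len(body) < n:
            raise TrajectoryFormatError(f"{path}: model {model}: truncated frame")
        elems, coords = [], np.empty((n, 3))
        for a, line in enumerate(body):
            parts = line.split()
            if len(parts) < 4:
                raise TrajectoryFormatError(f"{path}: model {model}: bad atom line {line!r}")
            elems.append(parts[0])
            coords[a] = [float(x) for x in parts[1:4]]
        if elements is None:
            elements = elems
        elif len(elems) != len(elements):
            raise TrajectoryFormatError(
                f"{path}: model {model}: atom count differs from model 1"
            )
        frames.append(coords)
        i += 2 + n
    if not frames:
        raise TrajectoryFormatError(f"{path}: no frames found")
    return Trajectory(
        coords=np.stack(frames),
        elements=elements,
        atom_names=[f"{e}{i+1}" for i, e in enumerate(elements)],
    )


def write_xyz_trajectory(traj: Trajectory, path) -> None:
    elements = traj.elements or ["C"] * traj.n_atoms
    with open(path, "w") as fh:
        for t in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\nframe {t}\n")
            for e, (x, y, z) in zip(elements, traj.coords[t]):
                fh.write(f"{e} {x:.6f} {y:.6f} {z:.6f}\n")


def write_series_csv(
    path, values, column: str, units: str, index_name: str = "frame_index", stamp: str | None = None
):
    with open(path, "w") as fh:
        fh.write(f"# units: {column} [{units}]\n")
        if stamp:
            fh.write(f"# {stamp}\n")
        pd.DataFrame(
            {index_name: np.arange(len(values)), column: np.asarray(values)}
        ).to_csv(fh, index=False)


def read_series_csv(path, column: str | None = None) -> np.ndarray:
    df = pd.read_csv(path, comment="#")
    return df[column].to_numpy() if column else df.iloc[:, -1].to_numpy()


def write_labels_csv(path, labels) -> None:
    write_series_csv(path, np.asarray(labels, dtype=int), "label", "cluster index")


def read_labels_csv(path) -> np.ndarray:
    return read_series_csv(path, "label").astype(int)


def write_clustering_json(
    path, clustering: Clustering, trace: ElbowTrace | None = None, stamp: str | None = None
):
    payload = {
        "k": int(clustering.k),
        "labels": [int(x) for x in clustering.labels],
        "medoids": [int(x) for x in clustering.medoids],
        "total_cost": clustering.total_cost,
        "n_iterations": int(clustering.n_iterations),
        "cost_history": list(clustering.cost_history),
    }
    if trace is not None:
        payload["elbow"] = {
            "costs": list(trace.costs),
            "chosen_k": int(trace.chosen_k),
            "relative_decrements": list(trace.relative_decrements),
        }
    if stamp:
        payload["stamp"] = stamp
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_clustering_json(path) -> Clustering:
    d = json.loads(Path(path).read_text())
    return Clustering(
        k=d["k"],
        labels=np.asarray(d["labels"], dtype=int),
        medoids=np.asarray(d["medoids"], dtype=int),
        total_cost=d["total_cost"],
        n_iterations=d["n_iterations"],
        cost_history=d.get("cost_history", []),
    )


def write_graphml(path, tgraph: TransitionGraph, stamp: str | None = None) -> None:
    G = tgraph.graph
    if stamp:
        G = G.copy()
        G.graph["stamp"] = stamp
    nx.write_graphml(G, str(path))


def write_dot(path, tgraph: TransitionGraph, stamp: str | None = None) -> None:
    G = tgraph.graph
    with open(path, "w") as fh:
        if stamp:
            fh.write(f"// {stamp}\n")
        fh.write("graph transitions {\n")
        for node, attrs in sorted(G.nodes(data=True), key=lambda kv: repr(kv[0])):
            extra = "".join(
                f', {k}="{v}"' for k, v in sorted(attrs.items()) if k in ("size", "annotation")
            )
            fh.write(f'  "{node}" [label="{node}"{extra}];\n')
        for a, b, attrs in sorted(G.edges(data=True), key=lambda e: (repr(e[0]), repr(e[1]))):
            fh.write(
                f'  "{a}" -- "{b}" [label="{attrs.get("count", "")}", '
                f'weight="{attrs.get("weight", 0.0):.6f}"];\n'
            )
        fh.write("}\n")


def write_paths_tsv(path, paths_by_sink: dict, stamp: str | None = None) -> None:
    with open(path, "w") as fh:
        if stamp:
            fh.write(f"# {stamp}\n")
        fh.write("sink\trank\ttotal_weight\tnodes\tedge_counts\n")
        for sink in paths_by_sink:
            for rank, p in enumerate(paths_by_sink[sink], start=1):
                nodes = ",".join(str(n) for n in p.nodes)
                counts = ",".join(str(c) for c in p.edge_counts)
                fh.write(f"{sink}\t{rank}\t{p.total_weight:.6f}\t{nodes}\t{counts}\n")


def write_profile_csv(path, profile, stamp: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("# units: s [path index], F [energy, caller's units]\n")
        if stamp:
            fh.write(f"# {stamp}\n")
        data = {"s": profile.s, "F": profile.F}
        if profile.band_lo is not None:
            data["band_lo"] = profile.band_lo
            data["band_hi"] = profile.band_hi
        pd.DataFrame(data).to_csv(fh, index=False)


def load_config(path, known_keys: set[str]) -> dict:
    """Load a YAML config, rejecting unknown top-level keys by name."""
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    unknown = set(cfg) - known_keys
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return cfg
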