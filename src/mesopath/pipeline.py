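"""Stage-per-section pipeline: simulate -> rmsd -> cluster -> graph ->
path-CV -> free energy -> kinetics.

A :class:`PipelineConfig` (usually loaded from YAML) names the stages to
run; sections that are absent are skipped. Every stage logs its inputs,
parameters and wall time into ``manifest.json`` in the output directory,
and every artifact is stamped with the config hash and the seed, so a
rerun with the same config and seed is bit-identical for the artifacts
(the manifest records timing and is the one file allowed to differ).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import cluster as _cluster
from . import free_energy as _fes
from . import graph as _graph
from . import io as _io
from . import kinetics as _kin
from . import pathcv as _pathcv
from . import synthetic as _syn
from .geometry import (
    SelectionPair,
    Trajectory,
    classify_binding_ensemble,
    pairwise_rmsd_matrix,
    rmsd_to_reference_series,
)

__all__ = ["PipelineConfig", "run_pipeline", "KNOWN_SECTIONS"]

logger = logging.getLogger(__name__)

KNOWN_SECTIONS = {
    "seed",
    "output_dir",
    "simulate",
    "trajectories",
    "reference",
    "rmsd",
    "clustering",
    "graph",
    "pathcv",
    "fes",
    "kinetics",
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see the bundled demo YAML)."""

    config: dict
    path: str | None = None

    def __post_init__(self) -> None:
        unknown = set(self.config) - KNOWN_SECTIONS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(config=_io.load_config(path, KNOWN_SECTIONS), path=str(path))

    @property
    def seed(self) -> int:
        return int(self.config.get("seed", 0))

    def section(self, name: str) -> dict | None:
        return self.config.get(name)

    def digest(self) -> str:
        blob = json.dumps(self.config, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class StageError(RuntimeError):
    """A pipeline stage failed; earlier outputs are retained."""


def _simulate(cfg: dict, seed: int, outdir: Path, stamp: str, manifest: list):
    t0 = time.perf_counter()
    n_states = int(cfg.get("n_states", 3))
    n_atoms = int(cfg.get("n_atoms", 8))
    separation = float(cfg.get("separation", 6.0))
    noise_sigma = float(cfg.get("noise_sigma", 0.5))
    stay = float(cfg.get("stay_probability", 0.9))
    n_frames = int(cfg.get("n_frames", 300))
    n_replicas = int(cfg.get("n_replicas", 2))
    refs = _syn.make_separated_references(n_states, n_atoms, separation, seed=seed)
    # nearest-neighbour chain: binding proceeds state 0 -> n_states-1
    T = np.zeros((n_states, n_states))
    for i in range(n_states):
        neigh = [j for j in (i - 1, i + 1) if 0 <= j < n_states]
        T[i, i] = stay
        for j in neigh:
            T[i, j] = (1.0 - stay) / len(neigh)
    trajs, labels = [], []
    for r in range(n_replicas):
        model = _syn.MesostateModel(
            reference_conformations=refs,
            transition_matrix=T,
            noise_sigma=noise_sigma,
            rigid_motion=bool(cfg.get("rigid_motion", False)),
            seed=seed + 1000 + r,
        )
        traj, lab = _syn.gen_mesostate_trajectory(model, n_frames)
        trajs.append(traj)
        labels.append(lab)
        _io.write_xyz_trajectory(traj, outdir / f"replica_{r}.xyz")
        _io.write_series_csv(
            outdir / f"replica_{r}_true_labels.csv", lab, "label", "state index", stamp=stamp
        )
    reference = Trajectory(coords=refs[-1][None], elements=["C"] * n_atoms).frame(0)
    manifest.append(
        {"stage": "simulate", "params": cfg, "outputs": [f"replica_{r}.xyz" for r in range(n_replicas)],
         "wall_time_s": time.perf_counter() - t0}
    )
    return trajs, labels, reference


def _load_trajectories(config: PipelineConfig):
    paths = config.section("trajectories") or []
    trajs = [_io.read_trajectory(p) for p in paths]
    ref_path = config.section("reference")
    reference = _io.read_trajectory(ref_path).frame(0) if ref_path else None
    return trajs, reference


def _selection(trajs, cfg) -> SelectionPair:
    n_atoms = trajs[0].n_atoms
    sel = (cfg or {}).get("selection", {})
    align = sel.get("align", list(range(n_atoms)))
    measure = sel.get("measure", list(range(n_atoms)))
    return SelectionPair(align_set=np.asarray(align), measure_set=np.asarray(measure))


def run_pipeline(config: PipelineConfig, output_dir=None) -> dict:
    """Run all configured stages in dependency order; returns result paths."""
    outdir = Path(output_dir or config.config.get("output_dir", "mesopath_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    stamp = f"config_hash={config.digest()} seed={seed}"
    manifest: list = []
    results: dict = {"output_dir": str(outdir)}

    try:
        if config.section("simulate") is not None:
            trajs, true_labels, reference = _simulate(
                config.section("simulate"), seed, outdir, stamp, manifest
            )
        else:
            trajs, reference = _load_trajectories(config)
    except StageError:
        raise
    except Exception as err:
        raise StageError(f"stage 'simulate/load' failed: {err}") from err

    selection = _selection(trajs, config.config) if trajs else None

    if config.section("rmsd") is not None:
        try:
            t0 = time.perf_counter()
            cfg = config.section("rmsd")
            tail = float(cfg.get("tail_fraction", 0.1))
            ensembles = []
            for r, traj in enumerate(trajs):
                series = rmsd_to_reference_series(traj, reference, selection)
                _io.write_series_csv(
                    outdir / f"rmsd_replica_{r}.csv", series, "rmsd", "Angstrom", stamp=stamp
                )
                ensembles.append(classify_binding_ensemble(series, tail_fraction=tail))
            (outdir / "ensembles.json").write_text(
                json.dumps({"ensembles": ensembles, "stamp": stamp}, indent=1)
            )
            results["ensembles"] = ensembles
            manifest.append({"stage": "rmsd", "params": cfg, "wall_time_s": time.perf_counter() - t0})
        except Exception as err:
            raise StageError(f"stage 'rmsd' failed: {err}") from err

    clustering = None
    if config.section("clustering") is not None:
        try:
            t0 = time.perf_counter()
            cfg = config.section("clustering")
            all_coords = np.concatenate([t.coords for t in trajs])
            pooled = Trajectory(coords=all_coords, elements=trajs[0].elements)
            D = pairwise_rmsd_matrix(pooled, selection)
            clustering, trace = _cluster.auto_k_cluster(
                D,
                threshold=float(cfg.get("threshold", 0.01)),
                k_max=int(cfg["k_max"]) if "k_max" in cfg else None,
            )
            _io.write_clustering_json(outdir / "clustering.json", clustering, trace, stamp=stamp)
            results["k"] = clustering.k
            manifest.append(
                {"stage": "clustering", "params": cfg, "k": clustering.k,
                 "wall_time_s": time.perf_counter() - t0}
            )
        except Exception as err:
            raise StageError(f"stage 'clustering' failed: {err}") from err

    tgraph = paths_by_sink = None
    if config.section("graph") is not None:
        if clustering is None:
            raise StageError("stage 'graph' needs the clustering stage")
        try:
            t0 = time.perf_counter()
            cfg = config.section("graph")
            lengths = [t.n_frames for t in trajs]
            bounds = np.cumsum([0] + lengths)
            seqs = [clustering.labels[a:b] for a, b in zip(bounds[:-1], bounds[1:])]
            tgraph = _graph.build_transition_graph(seqs, lag=int(cfg.get("lag", 1)))
            source = cfg.get("source", "first")
            sinks = cfg.get("sinks", "last")
            if source == "first":
                source = int(seqs[0][0])
            if sinks == "last":
                sinks = [int(seqs[0][-1])]
            tgraph.annotate(source, "out")
            paths_by_sink = _graph.extract_disjoint_paths(tgraph, source, sinks)
            _io.write_graphml(outdir / "transitions.graphml", tgraph, stamp=stamp)
            _io.write_dot(outdir / "transitions.dot", tgraph, stamp=stamp)
            _io.write_paths_tsv(outdir / "binding_paths.tsv", paths_by_sink, stamp=stamp)
            results["n_paths"] = {str(k): len(v) for k, v in paths_by_sink.items()}
            manifest.append(
                {"stage": "graph", "params": cfg, "wall_time_s": time.perf_counter() - t0}
            )
        except StageError:
            raise
        except Exception as err:
            raise StageError(f"stage 'graph' failed: {err}") from err

    if config.section("pathcv") is not None:
        if paths_by_sink is None:
            raise StageError("stage 'pathcv' needs the graph stage")
        try:
            t0 = time.perf_counter()
            cfg = config.section("pathcv")
            sink = list(paths_by_sink)[0]
            route = paths_by_sink[sink][0]
            medoid_frames = [clustering.medoids[c] for c in route.nodes]
            pooled = Trajectory(
                coords=np.concatenate([t.coords for t in trajs]), elements=trajs[0].elements
            )
            refs = [pooled.frame(int(m)) for m in medoid_frames]
            path_def = _pathcv.PathDefinition(
                references=refs, lam=float(cfg.get("lambda_nm2", 100.0)), selection=selection
            )
            sz = np.array([_pathcv.compute_s_z(f, path_def) for f in trajs[0]])
            _io.write_series_csv(outdir / "path_s.csv", sz[:, 0], "s", "path index", stamp=stamp)
            _io.write_series_csv(outdir / "path_z.csv", sz[:, 1], "z", "nm^2", stamp=stamp)
            n_centers = int(cfg.get("n_centers", min(11, sz.shape[0])))
            centers_idx = _pathcv.select_equidistant_centers(sz[:, 0], n_centers)
            _io.write_series_csv(
                outdir / "umbrella_centers.csv",
                sz[centers_idx, 0],
                "s_center",
                "path index",
                index_name="candidate_index",
                stamp=stamp,
            )
            results["z_small_fraction"] = _pathcv.z_fraction_below(
                sz[:, 1], float(cfg.get("z_bound_nm2", 1e-4))
            )
            manifest.append(
                {"stage": "pathcv", "params": cfg, "wall_time_s": time.perf_counter() - t0}
            )
        except StageError:
            raise
        except Exception as err:
            raise StageError(f"stage 'pathcv' failed: {err}") from err

    if config.section("fes") is not None:
        try:
            t0 = time.perf_counter()
            cfg = config.section("fes")
            n_windows = int(cfg.get("n_windows", 15))
            kappa = float(cfg.get("kappa", 50.0))
            n_samples = int(cfg.get("n_samples", 2000))
            h = float(cfg.get("barrier_kBT", 3.0))
            s0 = 1 + (n_windows - 1) / 2.0
            w = (n_windows - 1) / 2.6
            pot = _syn.Potential1D(
                form="double_well",
                params={"h": h, "s0": s0, "w": w},
                domain=(0.0, float(n_windows + 1)),
            )
            centers = np.arange(1.0, n_windows + 1.0)
            windows = [
                _fes.UmbrellaWindow(
                    center=c,
                    kappa=kappa,
                    samples=_syn.gen_restrained_samples(
                        pot, kappa, c, n_samples, method="overdamped_langevin",
                        seed=seed + 2000 + i,
                    ),
                )
                for i, c in enumerate(centers)
            ]
            grid = np.linspace(centers[0], centers[-1], int(cfg.get("grid_points", 400)))
            if int(cfg.get("n_boot", 0)) >= 100:
                profile = _fes.bootstrap_profile(
                    windows, grid, n_boot=int(cfg["n_boot"]), seed=seed + 3000,
                    sigma=float(cfg.get("sigma", _fes.DEFAULT_SIGMA)),
                    lambda_reg=float(cfg.get("lambda_reg", _fes.DEFAULT_LAMBDA_REG)),
                )
            else:
                profile, _, _, _ = _fes.profile_from_windows(
                    windows, grid,
                    sigma=float(cfg.get("sigma", _fes.DEFAULT_SIGMA)),
                    lambda_reg=float(cfg.get("lambda_reg", _fes.DEFAULT_LAMBDA_REG)),
                )
            _io.write_profile_csv(outdir / "free_energy.csv", profile, stamp=stamp)
            results["barrier_kBT"] = float(profile.F.max() - profile.F.min())
            manifest.append(
                {"stage": "fes", "params": cfg, "wall_time_s": time.perf_counter() - t0}
            )
        except Exception as err:
            raise StageError(f"stage 'fes' failed: {err}") from err

    if config.section("kinetics") is not None:
        try:
            t0 = time.perf_counter()
            cfg = dict(config.section("kinetics"))
            if "residence_time_s" in cfg:
                cfg["k_off"] = _kin.koff_from_residence_time(cfg.pop("residence_time_s"))
            if "half_life_s" in cfg:
                cfg["k_off"] = _kin.koff_from_half_life(cfg.pop("half_life_s"))
            system = _kin.ReactionSystem(
                V_cell=float(cfg["V_cell_A3"]),
                n_sites=int(cfg["n_sites"]),
                n_ligands=int(cfg["n_ligands"]),
                k_on=cfg.get("k_on"),
                k_off=cfg.get("k_off"),
                K_D=cfg.get("K_D"),
            )
            dt = _kin.mean_first_binding_time(system)
            report = {
                "k_on_per_M_per_s": system.k_on,
                "mean_first_binding_time_s": dt,
                "mean_first_binding_time_ns": dt * 1e9,
                "stamp": stamp,
            }
            (outdir / "kinetics.json").write_text(json.dumps(report, indent=1, sort_keys=True))
            results["mean_first_binding_time_ns"] = dt * 1e9
            manifest.append(
                {"stage": "kinetics", "params": cfg, "wall_time_s": time.perf_counter() - t0}
            )
        except Exception as err:
            raise StageError(f"stage 'kinetics' failed: {err}") from err

    (outdir / "manifest.json").write_text(
        json.dumps({"config_hash": config.digest(), "seed": seed, "stages": manifest},
                   indent=1, default=str)
    )
    return results
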