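"""Configuration, dataset simulation, and the end-to-end pipeline driver.

A run proceeds: read topology and replica trajectories → align every frame
to a reference structure → split replicas into windows → per-window
contact graph → per-window generalized correlations → cross-window
aggregation and persistent-edge report → optimal-path ensemble with the
Jaccard filter and route classification → binding-mode clustering →
interface contact surface area → JSON/TSV reports plus a manifest.

All parameters live in a flat TOML config with defaults matching the
standard analysis (6 Å / 0.75 contacts, k = 7, d = 3, persistence
r > 0.3 in ≥ 15 windows, bandwidth 2.5 Å, probe 1.7 Å, 960 sphere
points, 2 windows per replica).  Unknown keys are rejected.  Outputs are
reproducible bit-for-bit from config + inputs: nothing time- or
platform-dependent is written.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import contacts, correlation, paths as pathmod
from .clustering import cdr_features, mean_shift
from .core import (MolecularSystem, align_frames, parse_selection, read_pdb,
                   read_xyz, split_windows, write_pdb)
from .surface import contact_surface_area, window_contact_area
from .synthetic import (SyntheticSpec, build_system, planted_binder,
                        sample_gaussian_trajectory)

logger = logging.getLogger("allosnet")


@dataclass
class PipelineConfig:
    """Validated parameters for one pipeline run."""

    topology: str = ""
    trajectories: list[str] = field(default_factory=list)
    # stage parameters (defaults = the standard analysis values)
    cutoff: float = 6.0
    min_freq: float = 0.75
    include_adjacent: bool = True
    k: int = 7
    d: int = 3
    r_threshold: float = 0.3
    min_windows: int = 15
    n_windows: int = 2
    path_threshold: float | None = None    # None → derived from the ensemble
    bandwidth: float = 2.5
    probe: float = 1.7
    n_points: int = 960
    surface_stride: int = 50
    align_atoms: str = "ca"                # "ca" or "backbone"
    seed: int = 0
    # named residue sets: label → chain:range expression
    sets: dict[str, str] = field(default_factory=dict)
    # role bindings (labels into `sets`)
    binder_set: str = "binder"
    source_region: str = "receptor_R1"
    target_set: str = "R2_contact"
    align_set: str = "align_ref"
    region_sets: list[str] = field(default_factory=lambda: [
        "receptor_R1", "receptor_linker", "receptor_R2", "partner",
        "binder"])
    via_regions: list[str] = field(default_factory=lambda: ["partner"])
    cluster_heavy_set: str = "binder_heavy_cdr"
    cluster_light_set: str = "binder_light_cdr"
    surface_group_a: str = "receptor_all"
    surface_group_b: str = "binder"

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if not 0 < self.min_freq <= 1:
            raise ValueError("min_freq must be in (0, 1]")
        if self.k < 1 or self.d < 1:
            raise ValueError("k and d must be ≥ 1")
        if not 0 <= self.r_threshold < 1:
            raise ValueError("r_threshold must be in [0, 1)")
        if self.n_windows < 1:
            raise ValueError("n_windows must be ≥ 1")
        if self.path_threshold is not None and \
                not 0 <= self.path_threshold <= 1:
            raise ValueError("path_threshold must be in [0, 1]")
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        if self.probe < 0:
            raise ValueError("probe must be non-negative")
        if self.n_points < 92:
            raise ValueError("n_points must be ≥ 92")
        if self.align_atoms not in ("ca", "backbone"):
            raise ValueError("align_atoms must be 'ca' or 'backbone'")

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            out[f.name] = getattr(self, f.name)
        return out


# ---------------------------------------------------------------------------
# Dataset simulation (synthetic inputs on disk)
# ---------------------------------------------------------------------------

def _nodes_to_expr(system: MolecularSystem, nodes: list[int]) -> str:
    """Compact chain:range expression for a node list."""
    by_chain: dict[str, list[int]] = {}
    for n in sorted(nodes):
        r = system.residues[n]
        by_chain.setdefault(r.chain_id, []).append(r.res_id)
    parts = []
    for chain, ids in by_chain.items():
        ranges = []
        start = prev = ids[0]
        for i in ids[1:]:
            if i == prev + 1:
                prev = i
                continue
            ranges.append((start, prev))
            start = prev = i
        ranges.append((start, prev))
        spans = ",".join(f"{a}-{b}" if a != b else f"{a}"
                         for a, b in ranges)
        parts.append(f"{chain}:{spans}")
    return " ".join(parts)


def simulate(spec: SyntheticSpec, out_dir, write_config: bool = True
             ) -> Path:
    """Write a synthetic dataset (PDB topology + replica trajectories,
    ground-truth JSON, and a ready-to-run pipeline config) to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    system, replicas, truth = sample_gaussian_trajectory(spec)

    eq = replicas[0][0]  # not equilibrium, but a valid topology frame
    write_pdb(system, eq[None, :, :], out / "topology.pdb")
    traj_files = []
    for r, frames in enumerate(replicas):
        name = f"replica_{r:02d}.pdb"
        write_pdb(system, frames, out / name)
        traj_files.append(name)

    with open(out / "ground_truth.json", "w") as fh:
        json.dump({
            "binder_mode": spec.binder_mode,
            "noise_sigma": spec.noise_sigma,
            "seed": spec.seed,
            "rho": truth.rho.tolist(),
            "interface_pairs": [list(p) for p in truth.interface_pairs],
        }, fh, indent=1, sort_keys=True)

    if write_config:
        has_binder = "binder" in spec.named_sets
        set_exprs = {label: _nodes_to_expr(system, nodes)
                     for label, nodes in spec.named_sets.items()}
        set_exprs["receptor_all"] = _nodes_to_expr(
            system, spec.named_sets["receptor_R1"]
            + spec.named_sets["receptor_linker"]
            + spec.named_sets["receptor_R2"]
            + spec.named_sets["partner"])
        if has_binder:
            binder = spec.named_sets["binder"]
            half = len(binder) // 2
            set_exprs["binder_heavy_cdr"] = _nodes_to_expr(
                system, binder[:half])
            set_exprs["binder_light_cdr"] = _nodes_to_expr(
                system, binder[half:])
        lines = [
            f'topology = "topology.pdb"',
            "trajectories = ["
            + ", ".join(f'"{t}"' for t in traj_files) + "]",
            f"seed = {spec.seed}",
        ]
        if not has_binder:
            lines += ['binder_set = ""', 'surface_group_b = ""',
                      'cluster_heavy_set = ""', 'cluster_light_set = ""',
                      'region_sets = ["receptor_R1", "receptor_linker", '
                      '"receptor_R2", "partner"]']
        lines.append("")
        lines.append("[sets]")
        for label, expr in sorted(set_exprs.items()):
            lines.append(f'{label} = "{expr}"')
        (out / "pipeline.toml").write_text("\n".join(lines) + "\n")
    return out


def simulate_from_toml(spec_path, out_dir) -> Path:
    """Build a :class:`SyntheticSpec` from a small TOML file and write it."""
    with open(spec_path, "rb") as fh:
        raw = tomllib.load(fh)
    allowed = {"mode", "noise_sigma", "n_replicas", "frames_per_replica",
               "seed"}
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown spec keys: {sorted(unknown)}")
    spec = planted_binder(
        raw.get("mode", "localized_strong"),
        noise_sigma=raw.get("noise_sigma", 0.4),
        n_replicas=raw.get("n_replicas", 10),
        frames_per_replica=raw.get("frames_per_replica", 600),
        seed=raw.get("seed", 0))
    return simulate(spec, out_dir)


# ---------------------------------------------------------------------------
# Pipeline stages
# ---------------------------------------------------------------------------

def load_inputs(config: PipelineConfig, base_dir=None
                ) -> tuple[MolecularSystem, list[np.ndarray]]:
    base = Path(base_dir) if base_dir is not None else Path(".")
    topo_path = base / config.topology
    system, topo_frames = read_pdb(topo_path)
    replicas: list[np.ndarray] = []
    for t in config.trajectories:
        p = base / t
        if p.suffix.lower() == ".xyz":
            _, frames = read_xyz(p)
        elif p.suffix.lower() == ".dcd":
            from .core import read_dcd
            _, frames = read_dcd(topo_path, p)
        else:
            _, frames = read_pdb(p)
        if frames.shape[1] != system.n_atoms:
            raise ValueError(f"{t}: atom count {frames.shape[1]} != "
                             f"topology {system.n_atoms}")
        replicas.append(frames)
    if not replicas:
        replicas = [topo_frames]
    return system, replicas


def resolve_sets(system: MolecularSystem, config: PipelineConfig) -> None:
    """Materialise config set expressions into the system's named sets."""
    for label, expr in config.sets.items():
        system.named_sets[label] = parse_selection(expr, system)


def prepare_windows(system: MolecularSystem, replicas: list[np.ndarray],
                    config: PipelineConfig):
    """Align all replicas to the reference and split into windows."""
    names = ("CA",) if config.align_atoms == "ca" else \
        ("N", "CA", "C", "O")
    align_idx = system.atom_indices(system.get_set(config.align_set),
                                    names=names)
    reference = replicas[0][0]
    windows = []
    wid = 0
    for r, frames in enumerate(replicas):
        aligned = align_frames(frames, reference, align_idx)
        for w in split_windows(aligned, config.n_windows, replica_id=r,
                               first_window_id=wid):
            windows.append(w)
            wid += 1
    total = len(windows)
    if config.min_windows > total:
        raise ValueError(f"min_windows = {config.min_windows} exceeds the "
                         f"{total} available windows")
    return windows, reference


def network_stage(system, windows, config: PipelineConfig):
    """Contact graphs + per-window correlations + aggregation."""
    graphs, per_window = [], []
    for w in windows:
        g = contacts.build_contact_graph(
            system, w, cutoff=config.cutoff, min_freq=config.min_freq,
            include_adjacent=config.include_adjacent)
        graphs.append(g)
        per_window.append(correlation.window_correlations(
            system, w, g, k=config.k, d=config.d))
    network = correlation.aggregate_windows(
        per_window, r_threshold=config.r_threshold,
        min_windows=config.min_windows)
    return graphs, network


def persistent_interface(system, network, config: PipelineConfig):
    """Persistent edges crossing the binder / source-region interface."""
    if not config.binder_set:
        return [], []
    binder = set(system.get_set(config.binder_set))
    source_region = set(system.get_set(config.source_region))
    persistent = network.persistent_edges()
    iface = [e for e in persistent
             if (e[0] in binder and e[1] in source_region)
             or (e[1] in binder and e[0] in source_region)]
    sources = sorted({n for e in iface for n in e if n in source_region})
    return iface, sources


def path_stage(system, graphs, network, sources, config: PipelineConfig):
    """Pooled, filtered, classified optimal-path ensemble."""
    targets = sorted(set(system.get_set(config.target_set)))
    empty = pathmod.PathEnsemble(paths=[])
    if not sources:
        return empty, empty, pd.DataFrame(
            columns=["nodes", "trace", "route_class", "n_windows",
                     "class_fraction"])
    records = []
    for g, rmap in zip(graphs, network.per_window):
        records.extend(pathmod.optimal_paths(g, rmap, sources, targets))
    ensemble = pathmod.pool_unique_paths(records)
    filtered = pathmod.filter_paths(ensemble, config.path_threshold)

    region_of: dict[int, str] = {}
    for label in config.region_sets:
        for n in system.get_set(label):
            region_of.setdefault(n, label)
    for n in range(system.n_residues):
        region_of.setdefault(n, "other")
    via = tuple(config.via_regions)
    routes = pathmod.classify_routes(filtered, region_of, via_regions=via)
    return ensemble, filtered, routes


def cluster_stage(system, windows, reference, config: PipelineConfig):
    if not config.cluster_heavy_set or not config.cluster_light_set:
        return None, None
    features = cdr_features(
        system, windows, reference,
        align_set=system.get_set(config.align_set),
        heavy_cdr_set=system.get_set(config.cluster_heavy_set),
        light_cdr_set=system.get_set(config.cluster_light_set))
    result = mean_shift(features, bandwidth=config.bandwidth)
    return features, result


def surface_stage(system, windows, config: PipelineConfig):
    if not config.surface_group_b:
        return None
    ga = system.atom_indices(system.get_set(config.surface_group_a))
    gb = system.atom_indices(system.get_set(config.surface_group_b))
    radii = system.radii()
    sub = windows[0].coords[::config.surface_stride]
    return window_contact_area(sub, radii, ga, gb, probe=config.probe,
                               n_points=config.n_points)


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

def binder_contrast(mode: str, seed: int, *, n_replicas: int = 10,
                    frames_per_replica: int = 600,
                    config: PipelineConfig | None = None) -> dict:
    """In-memory network + path metrics for one binder mode.

    Runs generation → alignment → windows → contacts → correlations →
    aggregation → path ensemble for a planted binder and returns the
    headline numbers used to compare a localized-strong binder against a
    diffuse-weak one: persistent interface edge count, unique and
    filtered source→target path counts, and the via-partner route
    fraction.
    """
    cfg = config or PipelineConfig()
    spec = planted_binder(mode, seed=seed, n_replicas=n_replicas,
                          frames_per_replica=frames_per_replica)
    system, replicas, _ = sample_gaussian_trajectory(spec)
    windows, _ = prepare_windows(system, replicas, cfg)
    graphs, network = network_stage(system, windows, cfg)
    iface, sources = persistent_interface(system, network, cfg)
    ensemble, filtered, routes = path_stage(system, graphs, network,
                                            sources, cfg)
    n_via = int((routes["route_class"] == "via-partner").sum()) \
        if len(routes) else 0
    return {
        "mode": mode,
        "seed": seed,
        "n_windows": len(windows),
        "persistent_interface_edges": len(iface),
        "source_nodes": sources,
        "unique_paths": len(ensemble),
        "filtered_paths": len(filtered),
        "via_partner_paths": n_via,
        "via_partner_fraction": (n_via / len(filtered)) if len(filtered)
        else 0.0,
    }


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _dump_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: PipelineConfig, out_dir, base_dir=None) -> dict:
    """Execute every stage and write all outputs under ``out_dir``.

    Returns the summary dictionary (also written as ``summary.json``).
    On a stage failure, outputs written so far are kept and a ``FAILED``
    marker names the stage and error.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    base = Path(base_dir) if base_dir is not None else Path(".")
    stage = "read"
    try:
        logger.info("pipeline start: seed=%d cutoff=%.2f min_freq=%.2f "
                    "k=%d r_threshold=%.2f min_windows=%d",
                    config.seed, config.cutoff, config.min_freq, config.k,
                    config.r_threshold, config.min_windows)
        system, replicas = load_inputs(config, base)
        resolve_sets(system, config)

        stage = "align/window"
        windows, reference = prepare_windows(system, replicas, config)

        stage = "contacts/correlation"
        graphs, network = network_stage(system, windows, config)
        edge_rows = []
        for g in graphs:
            for (i, j), e in sorted(g.edges.items()):
                edge_rows.append({"window": g.window_id, "node_i": i,
                                  "node_j": j, "frequency": e.frequency,
                                  "min_distance": e.min_distance})
        pd.DataFrame(edge_rows, columns=["window", "node_i", "node_j",
                                         "frequency", "min_distance"]
                     ).to_csv(out / "window_edges.tsv", sep="\t",
                              index=False)
        correlation.write_window_tsv(network,
                                     out / "window_correlations.tsv")
        network.to_dataframe(system).to_csv(out / "correlation_summary.tsv",
                                            sep="\t", index=False)

        stage = "paths"
        iface, sources = persistent_interface(system, network, config)
        ensemble, filtered, routes = path_stage(system, graphs, network,
                                                sources, config)
        ensemble.to_dataframe().to_csv(out / "paths_unfiltered.tsv",
                                       sep="\t", index=False)
        filtered.to_dataframe().to_csv(out / "paths_filtered.tsv",
                                       sep="\t", index=False)
        routes.to_csv(out / "routes.tsv", sep="\t", index=False)
        _dump_json({
            "paths": [{"nodes": [system.node_label(n) for n in p.nodes],
                       "node_indices": list(p.nodes),
                       "distance": p.distance,
                       "windows": sorted(p.windows)}
                      for p in filtered.paths],
            "derived_threshold": filtered.threshold,
            "applied_threshold": filtered.applied_threshold,
        }, out / "paths.json")

        stage = "clusters"
        features, clusters = cluster_stage(system, windows, reference,
                                           config)
        if features is not None:
            features.assign(label=clusters.labels).to_csv(
                out / "cluster_features.tsv", sep="\t", index=False)
            _dump_json({"bandwidth": clusters.bandwidth,
                        "n_clusters": clusters.n_clusters,
                        "clusters": clusters.summary()},
                       out / "clusters.json")

        stage = "surface"
        area = surface_stage(system, windows, config)
        if area is not None:
            _dump_json({"mean_nm2": area["mean_nm2"],
                        "se_nm2": area["se_nm2"],
                        "n_frames": int(len(area["per_frame_nm2"])),
                        "per_frame_nm2": area["per_frame_nm2"].tolist()},
                       out / "surface.json")

        stage = "report"
        n_correlated_windows = {
            f"{e[0]}-{e[1]}": network.stats[e].n_windows_correlated
            for e in iface}
        via = [r for r in routes["route_class"]] if len(routes) else []
        summary = {
            "n_windows": len(windows),
            "n_nodes": system.n_residues,
            "persistent_edges": len(network.persistent_edges()),
            "persistent_interface_edges": len(iface),
            "interface_edge_windows": n_correlated_windows,
            "source_nodes": sources,
            "unique_paths": len(ensemble),
            "filtered_paths": len(filtered),
            "path_threshold": filtered.threshold,
            "via_partner_paths": int(sum(c == "via-partner" for c in via)),
            "n_clusters": clusters.n_clusters if clusters else None,
            "contact_area_nm2": area["mean_nm2"] if area else None,
        }
        _dump_json(summary, out / "summary.json")

        manifest = {
            "config": config.to_dict(),
            "inputs": {config.topology: _sha256(base / config.topology),
                       **{t: _sha256(base / t)
                          for t in config.trajectories}},
        }
        _dump_json(manifest, out / "manifest.json")
        return summary
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise
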