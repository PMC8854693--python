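"""Topology and trajectory data model.

Defines the static molecular topology (:class:`MolecularSystem`), aligned
trajectory blocks (:class:`TrajectoryWindow`), closed-form rigid-body
superposition (Kabsch), per-frame RMSD series, and replica-to-window
partitioning.  All coordinates are stored internally in ångström; readers
convert nanometre inputs on the way in (×10).

Every downstream stage (contact graphs, correlations, paths, clustering,
surface area) consumes these types, so the conventions set here — one
network node per Cα atom (or designated bead), 0-based global residue
("node") indices, atom order fixed by the topology — hold package-wide.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

logger = logging.getLogger("allosnet")

# Bondi-type van der Waals radii (Å); overridable per atom via config.
VDW_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
    "P": 1.80,
}
DEFAULT_VDW_RADIUS = 1.70

#: Backbone atom names used for trajectory alignment by default.
BACKBONE_ATOMS = ("N", "CA", "C", "O")


class StructuralError(ValueError):
    """Topology/selection inconsistency (mismatched sizes, bad references)."""


class DegenerateGeometryError(ValueError):
    """Too few or collinear points for a unique rigid superposition."""


@dataclass(frozen=True)
class Residue:
    chain_id: str
    res_id: int          # 1-based residue number within the chain (PDB field)
    res_name: str
    node_index: int      # 0-based global index; node id in all networks


@dataclass(frozen=True)
class Atom:
    residue_index: int   # node_index of the parent residue
    name: str
    element: str
    is_heavy: bool
    radius: float        # vdW radius, Å


class MolecularSystem:
    """Static topology: chains, residues, atoms, and named residue sets.

    Parameters
    ----------
    residues, atoms
        Ordered records; atom order defines the coordinate column order of
        every trajectory frame for this system.
    named_sets
        Mapping from a label (e.g. ``"receptor_R1"``) to a list of residue
        node indices.
    """

    def __init__(self, residues: list[Residue], atoms: list[Atom],
                 named_sets: dict[str, list[int]] | None = None):
        self.residues = list(residues)
        self.atoms = list(atoms)
        self.named_sets = {k: list(v) for k, v in (named_sets or {}).items()}
        self.chains: list[str] = []
        for r in self.residues:
            if r.chain_id not in self.chains:
                self.chains.append(r.chain_id)
        self._validate()
        # Per-residue atom index lists, in atom order.
        self._res_atoms: list[list[int]] = [[] for _ in self.residues]
        for ai, a in enumerate(self.atoms):
            self._res_atoms[a.residue_index].append(ai)

    def _validate(self) -> None:
        n = len(self.residues)
        for i, r in enumerate(self.residues):
            if r.node_index != i:
                raise StructuralError(
                    f"residue {i} carries node_index {r.node_index}")
        for a in self.atoms:
            if not 0 <= a.residue_index < n:
                raise StructuralError(
                    f"atom {a.name} references residue {a.residue_index}")
            if a.is_heavy != (a.element.upper() != "H"):
                raise StructuralError(
                    f"atom {a.name}: is_heavy inconsistent with element "
                    f"{a.element!r}")
        for label, idx in self.named_sets.items():
            for i in idx:
                if not 0 <= i < n:
                    raise StructuralError(
                        f"named set {label!r} references residue {i}")

    # -- lookups -----------------------------------------------------------

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def residue_atoms(self, node_index: int) -> list[int]:
        return self._res_atoms[node_index]

    def heavy_atoms(self, node_index: int) -> list[int]:
        return [i for i in self._res_atoms[node_index]
                if self.atoms[i].is_heavy]

    def node_atom(self, node_index: int, name: str = "CA") -> int:
        """Atom index of the residue's node atom (Cα or designated bead)."""
        for i in self._res_atoms[node_index]:
            if self.atoms[i].name == name:
                return i
        raise StructuralError(
            f"residue {self.node_label(node_index)} has no {name} atom")

    def node_atom_indices(self, nodes=None, name: str = "CA") -> np.ndarray:
        nodes = range(self.n_residues) if nodes is None else nodes
        return np.array([self.node_atom(i, name) for i in nodes], dtype=int)

    def atom_indices(self, nodes, names=None) -> np.ndarray:
        """Atom indices of the given residues, optionally restricted by name."""
        out = []
        for i in nodes:
            for ai in self._res_atoms[i]:
                if names is None or self.atoms[ai].name in names:
                    out.append(ai)
        return np.array(out, dtype=int)

    def node_label(self, node_index: int) -> str:
        r = self.residues[node_index]
        return f"{r.chain_id}:{r.res_id}:{r.res_name}"

    def get_set(self, label: str) -> list[int]:
        try:
            return self.named_sets[label]
        except KeyError:
            raise KeyError(f"unknown named set {label!r}; have "
                           f"{sorted(self.named_sets)}") from None

    def radii(self, atom_indices=None) -> np.ndarray:
        atoms = self.atoms if atom_indices is None else \
            [self.atoms[i] for i in atom_indices]
        return np.array([a.radius for a in atoms])


@dataclass
class TrajectoryWindow:
    """One contiguous block of aligned frames from a single replica."""

    replica_id: int
    window_id: int
    coords: np.ndarray            # (n_frames, n_atoms, 3), Å
    frame_spacing: float = 1.0    # metadata only (e.g. ns between frames)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, atoms, 3)")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


@dataclass(frozen=True)
class SuperpositionResult:
    """Least-squares rigid transform: ``aligned = coords @ rotation.T + translation``."""

    rotation: np.ndarray     # (3, 3), proper orthonormal
    translation: np.ndarray  # (3,), Å
    rmsd: float              # Å, over the fitted selection

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


# ---------------------------------------------------------------------------
# Superposition and RMSD
# ---------------------------------------------------------------------------

def _check_fit_geometry(x: np.ndarray) -> None:
    if x.shape[0] < 3:
        raise DegenerateGeometryError(
            f"need ≥3 points for superposition, got {x.shape[0]}")
    c = x - x.mean(axis=0)
    # rank < 2 ⟺ all points collinear ⟹ rotation about the line undetermined
    if np.linalg.matrix_rank(c, tol=1e-8) < 2:
        raise DegenerateGeometryError("selection points are collinear")


def superpose(mobile: np.ndarray, reference: np.ndarray,
              selection=None) -> SuperpositionResult:
    """Kabsch least-squares superposition of ``mobile`` onto ``reference``.

    The transform is fitted on ``selection`` (atom indices; all atoms when
    omitted) and minimises the RMSD over that selection.  The SVD solution
    is corrected for reflections so the rotation is always proper
    (determinant +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if selection is not None:
        sel = np.asarray(selection, dtype=int)
        m, r = mobile[sel], reference[sel]
    else:
        m, r = mobile, reference
    if m.shape != r.shape:
        raise StructuralError(
            f"selection size mismatch: mobile {m.shape} vs reference {r.shape}")
    if m.size == 0:
        raise StructuralError("empty selection")
    _check_fit_geometry(m)

    cm, cr = m.mean(axis=0), r.mean(axis=0)
    h = (m - cm).T @ (r - cr)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = cr - rot @ cm
    aligned = m @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((aligned - r) ** 2, axis=1))))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd)


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD (no fitting)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape:
        raise StructuralError(f"shape mismatch {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def align_frames(frames: np.ndarray, reference: np.ndarray,
                 fit_selection) -> np.ndarray:
    """Superpose every frame on ``reference`` using ``fit_selection`` atoms."""
    frames = np.asarray(frames, dtype=float)
    out = np.empty_like(frames)
    for i, fr in enumerate(frames):
        res = superpose(fr, reference, fit_selection)
        out[i] = res.transform(fr)
    return out


def rmsd_series(window: TrajectoryWindow, reference: np.ndarray,
                fit_selection, measure_selection) -> np.ndarray:
    """Per-frame RMSD over ``measure_selection`` after fitting on ``fit_selection``.

    Each frame is superposed on the reference via the fit selection; the
    RMSD is then measured over the (possibly different) measure selection
    without refitting — the standard "align on A, measure B" protocol.
    """
    fit = np.asarray(fit_selection, dtype=int)
    mea = np.asarray(measure_selection, dtype=int)
    if fit.size == 0 or mea.size == 0:
        raise StructuralError("fit and measure selections must be non-empty")
    ref = np.asarray(reference, dtype=float)
    out = np.empty(window.n_frames)
    for i, fr in enumerate(window.coords):
        res = superpose(fr, ref, fit)
        out[i] = rmsd(res.transform(fr[mea]), ref[mea])
    return out


# ---------------------------------------------------------------------------
# Window partitioning
# ---------------------------------------------------------------------------

def split_windows(replica_frames: np.ndarray, n_windows: int,
                  replica_id: int = 0, frame_spacing: float = 1.0,
                  first_window_id: int = 0) -> list[TrajectoryWindow]:
    """Partition one replica's frames into contiguous equal-length windows.

    Frames that do not divide evenly are dropped from the tail (never
    padded), with a logged warning.
    """
    if n_windows < 1:
        raise ValueError(f"n_windows must be ≥1, got {n_windows}")
    frames = np.asarray(replica_frames, dtype=float)
    n = frames.shape[0]
    size = n // n_windows
    if size == 0:
        raise ValueError(f"{n} frames cannot fill {n_windows} windows")
    if n % n_windows:
        logger.warning("replica %d: dropping %d trailing frame(s) to form "
                       "%d windows of %d", replica_id, n % n_windows,
                       n_windows, size)
    return [
        TrajectoryWindow(replica_id=replica_id,
                         window_id=first_window_id + w,
                         coords=frames[w * size:(w + 1) * size],
                         frame_spacing=frame_spacing)
        for w in range(n_windows)
    ]


# ---------------------------------------------------------------------------
# Named-set expressions
# ---------------------------------------------------------------------------

def parse_selection(expr: str, system: MolecularSystem) -> list[int]:
    """Resolve a chain/residue-range expression to node indices.

    Syntax: ``"B:34-145,289-341"`` or ``"B:34-145 C:1-10"`` — 1-based
    inclusive residue numbers matching the PDB residue field.  A bare
    ``"B"`` selects the whole chain.
    """
    lookup: dict[tuple[str, int], int] = {
        (r.chain_id, r.res_id): r.node_index for r in system.residues}
    out: list[int] = []
    for part in expr.split():
        chain, _, ranges = part.partition(":")
        if not ranges:
            out.extend(r.node_index for r in system.residues
                       if r.chain_id == chain)
            continue
        for rng in ranges.split(","):
            lo, _, hi = rng.partition("-")
            lo_i = int(lo)
            hi_i = int(hi) if hi else lo_i
            for res_id in range(lo_i, hi_i + 1):
                key = (chain, res_id)
                if key not in lookup:
                    raise KeyError(
                        f"selection {expr!r}: residue {chain}:{res_id} "
                        f"not in topology")
                out.append(lookup[key])
    return out


# ---------------------------------------------------------------------------
# PDB / XYZ input and output
# ---------------------------------------------------------------------------

def element_from_atom(atom_name: str, element_field: str = "") -> str:
    """Element symbol, preferring the PDB element column (77–78)."""
    el = element_field.strip()
    if el:
        return el.capitalize()
    name = atom_name.strip().lstrip("0123456789")
    if not name:
        raise StructuralError(f"cannot infer element from {atom_name!r}")
    if len(name) > 1 and name[:2].capitalize() in VDW_RADII:
        return name[:2].capitalize()
    return name[0].upper()


def _system_from_atom_array(arr: struc.AtomArray,
                            radius_overrides: dict[str, float] | None = None
                            ) -> MolecularSystem:
    residues: list[Residue] = []
    atoms: list[Atom] = []
    res_key_to_node: dict[tuple[str, int], int] = {}
    overrides = radius_overrides or {}
    for i in range(arr.array_length()):
        key = (str(arr.chain_id[i]), int(arr.res_id[i]))
        if key not in res_key_to_node:
            res_key_to_node[key] = len(residues)
            residues.append(Residue(chain_id=key[0], res_id=key[1],
                                    res_name=str(arr.res_name[i]),
                                    node_index=len(residues)))
        element = element_from_atom(str(arr.atom_name[i]),
                                    str(arr.element[i]))
        name = str(arr.atom_name[i])
        radius = overrides.get(name,
                               VDW_RADII.get(element, DEFAULT_VDW_RADIUS))
        atoms.append(Atom(residue_index=res_key_to_node[key], name=name,
                          element=element,
                          is_heavy=element.upper() != "H", radius=radius))
    return MolecularSystem(residues, atoms)


def read_pdb(path, radius_overrides: dict[str, float] | None = None
             ) -> tuple[MolecularSystem, np.ndarray]:
    """Read a (possibly multi-model) PDB file.

    Returns the topology and a frame block of shape
    ``(n_models, n_atoms, 3)`` in Å.
    """
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    system = _system_from_atom_array(stack[0], radius_overrides)
    return system, np.asarray(stack.coord, dtype=float)


def write_pdb(system: MolecularSystem, frames: np.ndarray, path) -> None:
    """Write frames as a multi-model PDB with the system's topology."""
    frames = np.atleast_3d(np.asarray(frames, dtype=float))
    if frames.ndim == 3 and frames.shape[-1] != 3:
        raise ValueError("frames must have shape (models, atoms, 3)")
    n_atoms = system.n_atoms
    arr = struc.AtomArray(n_atoms)
    for i, a in enumerate(system.atoms):
        r = system.residues[a.residue_index]
        arr.chain_id[i] = r.chain_id
        arr.res_id[i] = r.res_id
        arr.res_name[i] = r.res_name
        arr.atom_name[i] = a.name
        arr.element[i] = a.element.upper()
        arr.hetero[i] = False
    arr.coord = frames[0]
    stack = struc.from_template(arr, frames)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def read_xyz(path) -> tuple[list[str], np.ndarray]:
    """Read a plain multi-frame XYZ file → (element symbols, frames in Å)."""
    frames = []
    elements: list[str] = []
    with open(path) as fh:
        lines = fh.read().split("\n")
    pos = 0
    while pos < len(lines) and lines[pos].strip():
        n = int(lines[pos].strip())
        block = lines[pos + 2: pos + 2 + n]
        coords = np.empty((n, 3))
        frame_elements = []
        for i, line in enumerate(block):
            parts = line.split()
            frame_elements.append(parts[0])
            coords[i] = [float(x) for x in parts[1:4]]
        if not elements:
            elements = frame_elements
        frames.append(coords)
        pos += 2 + n
        while pos < len(lines) and not lines[pos].strip():
            pos += 1
    return elements, np.array(frames)


def read_dcd(topology_path, dcd_path) -> tuple[MolecularSystem, np.ndarray]:
    """Read a binary DCD trajectory against a PDB topology.

    Same contract as :func:`read_pdb`: returns the topology and a
    ``(n_frames, n_atoms, 3)`` block in Å.  Requires MDAnalysis.
    """
    import MDAnalysis as mda
    system, _ = read_pdb(topology_path)
    u = mda.Universe(str(topology_path), str(dcd_path))
    if len(u.atoms) != system.n_atoms:
        raise StructuralError(
            f"DCD atom count {len(u.atoms)} != topology {system.n_atoms}")
    frames = np.array([u.atoms.positions.copy() for _ in u.trajectory],
                      dtype=float)
    return system, frames


def write_xyz(elements: list[str], frames: np.ndarray, path,
              comment: str = "") -> None:
    frames = np.atleast_3d(np.asarray(frames, dtype=float))
    with open(path, "w") as fh:
        for frame in frames:
            fh.write(f"{len(elements)}\n{comment}\n")
            for el, (x, y, z) in zip(elements, frame):
                fh.write(f"{el} {x:.6f} {y:.6f} {z:.6f}\n")
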