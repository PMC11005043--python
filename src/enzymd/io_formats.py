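"""Readers and writers for the on-disk formats used across the pipeline.

Structures are exchanged as PDB (ATOM/HETATM), trajectories as multi-model
PDB or plain-text XYZ, feature tables as CSV with ``BLOCK:name`` headers and
the run configuration as JSON.  Everything downstream works on the in-memory
types defined here; no other module touches a file format directly.

Time metadata is deliberately kept out of the trajectory formats (neither
PDB nor XYZ carries it robustly) and supplied through :class:`RunConfig`.
Coordinates are written at 3-decimal precision, the PDB convention.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "StructureModel",
    "TrajectoryData",
    "RunConfig",
    "StructureParseError",
    "TrajectoryStructureError",
    "ConfigError",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "read_feature_table",
    "write_feature_table",
    "load_config",
]


class StructureParseError(ValueError):
    """A structure file could not be parsed (message names the line)."""


class TrajectoryStructureError(ValueError):
    """A trajectory violates structural invariants (message names the frame)."""


class ConfigError(ValueError):
    """A run-configuration document is invalid (message names the key)."""


_BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})


@dataclass
class StructureModel:
    """A static molecular model: per-atom metadata plus Cartesian coordinates.

    Residue identifiers are 1-based and preserved exactly as found in the
    source file; they are never renumbered by I/O.  ``ligand_flag`` marks
    atoms belonging to the (HETATM) ligand used to define the binding site.
    """

    atom_names: list[str]
    elements: list[str]
    residue_ids: np.ndarray  # int, 1-based
    residue_names: list[str]
    chains: list[str]
    coords: np.ndarray  # (N, 3) float, Angstrom
    ligand_flag: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        n = len(self.atom_names)
        if self.ligand_flag is None:
            self.ligand_flag = np.zeros(n, dtype=bool)
        self.ligand_flag = np.asarray(self.ligand_flag, dtype=bool)
        lens = {
            n,
            len(self.elements),
            len(self.residue_ids),
            len(self.residue_names),
            len(self.chains),
            self.coords.shape[0],
            len(self.ligand_flag),
        }
        if len(lens) != 1:
            raise ValueError("per-atom arrays of StructureModel differ in length")
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (N, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    # ---- selection helpers used throughout the feature modules ----

    def mask(self, kind: str, include_ligand: bool = False) -> np.ndarray:
        """Boolean atom mask for ``kind`` in {'heavy', 'backbone', 'calpha'}.

        Ligand atoms are excluded unless ``include_ligand`` is set; hydrogens
        are always excluded ('heavy' and narrower selections only).
        """
        elements = np.array([e.upper() for e in self.elements])
        heavy = elements != "H"
        if not include_ligand:
            heavy &= ~self.ligand_flag
        if kind == "heavy":
            return heavy
        names = np.array(self.atom_names)
        if kind == "backbone":
            return heavy & np.isin(names, list(_BACKBONE_NAMES))
        if kind == "calpha":
            return heavy & (names == "CA")
        raise ValueError(f"unknown selection kind: {kind!r}")

    def protein_residue_ids(self) -> np.ndarray:
        """Sorted unique residue ids of non-ligand atoms."""
        return np.unique(self.residue_ids[~self.ligand_flag])


@dataclass
class TrajectoryData:
    """Ordered coordinate frames for one replicate of one variant."""

    frames: np.ndarray  # (F, N, 3) float, Angstrom
    dt_ps: float
    structure: StructureModel  # shared atom metadata / reference geometry

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (F, N, 3)")
        if self.frames.shape[0] < 1:
            raise ValueError("trajectory must contain at least one frame")
        if self.frames.shape[1] != self.structure.n_atoms:
            raise TrajectoryStructureError(
                f"trajectory atom count {self.frames.shape[1]} does not match "
                f"reference structure ({self.structure.n_atoms} atoms)"
            )
        if self.dt_ps <= 0:
            raise ValueError("dt_ps must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def length_ns(self) -> float:
        """Simulated time span covered by the frame intervals, in ns."""
        return (self.n_frames - 1) * self.dt_ps / 1000.0


# --------------------------------------------------------------------------
# PDB structures
# --------------------------------------------------------------------------

def _check_pdb_lines(lines: Sequence[str]) -> None:
    for i, line in enumerate(lines, start=1):
        if line.startswith(("ATOM", "HETATM")):
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                try:
                    float(line[lo:hi])
                except ValueError:
                    raise StructureParseError(
                        f"malformed coordinate field on line {i}: {line.rstrip()!r}"
                    ) from None


def read_structure(
    path: str | Path, dialect: str = "pdb", ligand_resname: str | None = "LIG"
) -> StructureModel:
    """Read a PDB structure into a :class:`StructureModel`.

    HETATM atoms whose residue name equals ``ligand_resname`` are flagged as
    ligand.  Only the first MODEL of a multi-model file is read (use
    :func:`read_trajectory` for the full series).
    """
    if dialect != "pdb":
        raise ValueError(f"unsupported structure dialect: {dialect!r}")
    path = Path(path)
    lines = path.read_text().splitlines()
    _check_pdb_lines(lines)

    from Bio.PDB import PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = next(PDBParser(QUIET=True).get_structure("s", str(path)).get_models())

    atom_names, elements, rids, rnames, chains, coords, lig = [], [], [], [], [], [], []
    for chain in model:
        for residue in chain:
            hetfield, resseq, _ = residue.id
            is_ligand = bool(hetfield.strip()) and (
                ligand_resname is not None and residue.resname.strip() == ligand_resname
            )
            for atom in residue:
                atom_names.append(atom.get_name())
                elem = atom.element or atom.get_name()[0]
                elements.append(elem.strip().capitalize())
                rids.append(int(resseq))
                rnames.append(residue.resname.strip())
                chains.append(chain.id)
                coords.append(atom.coord)
                lig.append(is_ligand)
    if not atom_names:
        raise StructureParseError(f"no ATOM/HETATM records in {path}")
    return StructureModel(
        atom_names, elements, np.array(rids), rnames, chains,
        np.array(coords, dtype=float), np.array(lig),
    )


def _pdb_atom_line(i: int, name: str, resname: str, chain: str, resid: int,
                   xyz: np.ndarray, element: str, hetatm: bool) -> str:
    record = "HETATM" if hetatm else "ATOM  "
    name_f = f" {name:<3s}" if len(name) < 4 else name[:4]
    return (
        f"{record}{i:>5d} {name_f}{'':1s}{resname:>3s} {chain:1s}{resid:>4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {element.upper():>2s}"
    )


def write_structure(structure: StructureModel, path: str | Path) -> None:
    """Write a :class:`StructureModel` as PDB (coordinates to 3 decimals)."""
    lines = []
    for i in range(structure.n_atoms):
        lines.append(_pdb_atom_line(
            i + 1, structure.atom_names[i], structure.residue_names[i],
            structure.chains[i], int(structure.residue_ids[i]),
            structure.coords[i], structure.elements[i],
            bool(structure.ligand_flag[i]),
        ))
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# Trajectories
# --------------------------------------------------------------------------

def _scan_xyz_counts(path: Path) -> list[int]:
    counts = []
    lines = path.read_text().splitlines()
    i = 0
    frame = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise TrajectoryStructureError(
                f"frame {frame}: expected atom-count line, got {lines[i]!r}"
            ) from None
        counts.append(n)
        i += n + 2
        frame += 1
    return counts


def _scan_pdb_model_counts(lines: Sequence[str]) -> list[int]:
    counts, current, in_model = [], 0, False
    for line in lines:
        if line.startswith("MODEL"):
            in_model, current = True, 0
        elif line.startswith("ENDMDL"):
            counts.append(current)
            in_model = False
        elif line.startswith(("ATOM", "HETATM")):
            current += 1
    if not counts and current:  # single implicit model
        counts = [current]
    elif in_model and current:
        counts.append(current)
    return counts


def read_trajectory(
    path: str | Path,
    dialect: str,
    dt_ps: float,
    structure: StructureModel | None = None,
) -> TrajectoryData:
    """Read a trajectory (``dialect`` in {'multi-model-pdb', 'xyz'}).

    XYZ carries no residue topology, so a reference ``structure`` is required
    for that dialect; for multi-model PDB it defaults to the first model.
    Frame order is preserved; ``dt_ps`` comes from the run configuration.
    """
    path = Path(path)
    if dialect == "xyz":
        counts = _scan_xyz_counts(path)
    elif dialect == "multi-model-pdb":
        counts = _scan_pdb_model_counts(path.read_text().splitlines())
    else:
        raise ValueError(f"unsupported trajectory dialect: {dialect!r}")
    if not counts:
        raise TrajectoryStructureError(f"no frames found in {path}")
    for f, n in enumerate(counts):
        if n != counts[0]:
            raise TrajectoryStructureError(
                f"frame {f} has {n} atoms, expected {counts[0]}"
            )

    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        universe = mda.Universe(str(path))
        frames = np.array([universe.atoms.positions.copy().astype(float)
                           for _ in universe.trajectory])

    if structure is None:
        if dialect != "multi-model-pdb":
            raise ValueError("a reference structure is required for XYZ input")
        structure = read_structure(path)
    return TrajectoryData(frames, dt_ps, structure)


def write_trajectory(traj: TrajectoryData, path: str | Path, dialect: str) -> None:
    """Write a trajectory as multi-model PDB or XYZ text (3-decimal coords)."""
    path = Path(path)
    s = traj.structure
    if dialect == "xyz":
        out = []
        for f in range(traj.n_frames):
            out.append(str(s.n_atoms))
            out.append(f"frame {f}")
            for i in range(s.n_atoms):
                x, y, z = traj.frames[f, i]
                out.append(f"{s.elements[i]:<2s} {x:12.3f} {y:12.3f} {z:12.3f}")
        path.write_text("\n".join(out) + "\n")
    elif dialect == "multi-model-pdb":
        out = []
        for f in range(traj.n_frames):
            out.append(f"MODEL     {f + 1:>4d}")
            for i in range(s.n_atoms):
                out.append(_pdb_atom_line(
                    i + 1, s.atom_names[i], s.residue_names[i], s.chains[i],
                    int(s.residue_ids[i]), traj.frames[f, i], s.elements[i],
                    bool(s.ligand_flag[i]),
                ))
            out.append("ENDMDL")
        out.append("END")
        path.write_text("\n".join(out) + "\n")
    else:
        raise ValueError(f"unsupported trajectory dialect: {dialect!r}")


# --------------------------------------------------------------------------
# Feature tables
# --------------------------------------------------------------------------

def write_feature_table(table, path: str | Path) -> None:
    """Write a FeatureTable as CSV with ``BLOCK:name`` column headers."""
    df = table.to_frame(tagged=True)
    df.to_csv(path, index=True, index_label="variant_id")


def read_feature_table(path: str | Path):
    """Read a CSV feature table; block/aggregation tags are recovered from
    the ``BLOCK:name_mean``-style header convention."""
    import pandas as pd

    from .dataset_assembly import FeatureTable

    df = pd.read_csv(path, index_col=0)
    if df.index.duplicated().any():
        dupes = sorted(set(df.index[df.index.duplicated()]))
        raise ValueError(f"duplicate variant ids in {path}: {dupes}")
    return FeatureTable.from_tagged_frame(df)


# --------------------------------------------------------------------------
# Run configuration
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Pipeline configuration with the protocol's default settings.

    ``chunk_ns`` is the trajectory chunk length used by the robustness
    statistics; ``dt_ps`` the frame spacing (100 ps x 101 frames spans 10 ns
    at desk scale; set ``frames_per_traj=1001`` and ``dt_ps=10`` for the
    full-resolution layout).  ``lower_q``/``upper_q`` are the residual
    quantiles delimiting poor predictions and ``mutation_count_cut`` the
    co-occurring-mutation flag used by the enrichment diagnostic.
    """

    seed: int = 0
    chunk_ns: float = 10.0
    replicates: int = 5
    train_frac: float = 0.8
    bootstrap: int = 500
    cv_folds: int = 5
    lower_q: float = 0.05
    upper_q: float = 0.95
    mutation_count_cut: int = 5
    dt_ps: float = 100.0
    frames_per_traj: int = 101
    ligand_resname: str = "LIG"
    fca_convention: str = "b_minus_a"  # or "a_minus_b"


def load_config(path: str | Path) -> RunConfig:
    """Load a JSON run configuration, filling defaults and rejecting unknown
    keys and type-mismatched values."""
    with open(path) as fh:
        raw = json.load(fh)
    if not isinstance(raw, dict):
        raise ConfigError("configuration document must be a JSON object")
    fields = {f.name: f for f in dataclasses.fields(RunConfig)}
    for key, value in raw.items():
        if key not in fields:
            raise ConfigError(f"unknown configuration key: {key!r}")
        expected = fields[key].type
        if expected in ("int", int):
            ok = isinstance(value, int) and not isinstance(value, bool)
        elif expected in ("float", float):
            ok = isinstance(value, (int, float)) and not isinstance(value, bool)
        else:
            ok = isinstance(value, str)
        if not ok:
            raise ConfigError(
                f"configuration key {key!r} expects {expected}, got {value!r}"
            )
    cfg = RunConfig(**raw)
    if cfg.fca_convention not in ("b_minus_a", "a_minus_b"):
        raise ConfigError(f"invalid fca_convention: {cfg.fca_convention!r}")
    return cfg
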