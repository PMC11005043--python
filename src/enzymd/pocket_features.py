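"""Binding-site definition and the 80-column pocket descriptor block.

The binding site is the set of template residues with any heavy atom within
3.5 A (inclusive) of the peptide-like ligand.  The descriptors are
deterministic geometric/chemical proxies for grid-based pocket analysis:
convex-hull volume for cavity size, maximum atom-pair distance for length,
mean distance to the hull surface for depth, Shrake-Rupley solvent
accessible surface area, Kyte-Doolittle hydrophobicity, residue charge and
polarity classes at pH 8 (His neutral), per-residue pocket occupancy over
the trajectory and a normalized B-factor score B = (8 pi^2 / 3) RMSF^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .io_formats import StructureModel, TrajectoryData
from . import scales

__all__ = [
    "BindingSite",
    "VDW_RADII",
    "define_binding_site",
    "shrake_rupley_sasa",
    "pocket_geometry",
    "pocket_chemistry",
    "pocket_occupancy",
    "normalized_bfactor",
    "pocket_feature_block",
]

VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "P": 1.80}

_POLAR = set("STNQYCHKRDE")
_CHARGE_PH8 = {"D": -1, "E": -1, "K": 1, "R": 1}  # His neutral at pH 8


@dataclass
class BindingSite:
    """Template-defined binding site, fixed across frames."""

    residue_ids: np.ndarray  # 1-based, sorted
    atom_indices: np.ndarray  # heavy protein atoms of those residues
    ligand_atom_indices: np.ndarray
    cutoff: float = 3.5

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids)


def define_binding_site(template: StructureModel, cutoff: float = 3.5) -> BindingSite:
    """Residues with any heavy atom at distance <= cutoff from any ligand
    heavy atom (inclusive boundary)."""
    lig_idx = np.flatnonzero(template.ligand_flag
                             & (np.array(template.elements) != "H"))
    if lig_idx.size == 0:
        raise ValueError("template has no ligand atoms")
    prot_idx = np.flatnonzero(template.mask("heavy"))
    d = np.linalg.norm(
        template.coords[prot_idx, None, :] - template.coords[None, lig_idx, :],
        axis=2,
    )
    near = prot_idx[(d <= cutoff).any(axis=1)]
    residue_ids = np.unique(template.residue_ids[near])
    if residue_ids.size == 0:
        raise ValueError(
            f"no residues within {cutoff} A of the ligand; increase the cutoff"
        )
    atom_indices = np.flatnonzero(
        np.isin(template.residue_ids, residue_ids) & template.mask("heavy")
    )
    return BindingSite(residue_ids, atom_indices, lig_idx, cutoff)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.column_stack(
        (np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi))
    )


def shrake_rupley_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = 1.4,
    n_points: int = 960,
    targets: np.ndarray | None = None,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (A^2) by sphere-point
    sampling.  ``targets`` restricts the computation to a subset of atoms
    (all atoms still occlude)."""
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if (radii <= 0).any():
        raise ValueError("radii must be positive")
    n = coords.shape[0]
    if targets is None:
        targets = np.arange(n)
    targets = np.asarray(targets)
    pts = _sphere_points(n_points).astype(np.float32)
    ext = radii + probe
    c32 = coords.astype(np.float32)
    ext32 = ext.astype(np.float32)
    # neighbour prefilter on squared distances
    d2 = ((coords[targets, None, :] - coords[None, :, :]) ** 2).sum(2)
    areas = np.zeros(len(targets))
    for t, i in enumerate(targets):
        neigh = np.flatnonzero((d2[t] < (ext[i] + ext) ** 2)
                               & (np.arange(n) != i))
        if neigh.size:
            surface = c32[i] + ext32[i] * pts
            diff = surface[:, None, :] - c32[neigh][None, :, :]
            buried = ((diff**2).sum(2) < (ext32[neigh] ** 2)[None, :]).any(1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[t] = 4.0 * np.pi * ext[i] ** 2 * frac
    return areas


def pocket_geometry(site: BindingSite, frame: np.ndarray) -> dict[str, float]:
    """Convex-hull volume proxy, maximum pairwise length and mean depth
    (distance to the hull surface) of the site heavy atoms in one frame."""
    pts = np.asarray(frame, dtype=float)[site.atom_indices]
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
    length = float(d.max()) if len(pts) > 1 else 0.0
    try:
        hull = ConvexHull(pts)
    except (QhullError, ValueError):
        warnings.warn("degenerate site geometry; hull volume set to 0")
        return {"volume_proxy": 0.0, "length": length, "depth_proxy": 0.0}
    # hull.equations: unit outward normals; -(A x + b) is the distance of an
    # interior point to each facet plane
    margins = -(pts @ hull.equations[:, :3].T + hull.equations[:, 3][None, :])
    depth = float(np.clip(margins.min(axis=1), 0.0, None).mean())
    return {"volume_proxy": float(hull.volume), "length": length,
            "depth_proxy": depth}


# ---------------------------------------------------------------------------
# Chemistry
# ---------------------------------------------------------------------------

def pocket_chemistry(site: BindingSite, sequence: str) -> dict:
    """Sequence-determined site chemistry: Kyte-Doolittle mean, residue
    class counts and per-residue charges at pH 8."""
    aas = []
    for rid in site.residue_ids:
        if rid > len(sequence):
            raise ValueError(f"site residue {rid} beyond sequence bounds")
        aas.append(sequence[rid - 1])
    charges = {int(rid): _CHARGE_PH8.get(aa, 0)
               for rid, aa in zip(site.residue_ids, aas)}
    return {
        "hydrophobicity_mean": float(
            np.mean([scales.KYTE_DOOLITTLE[aa] for aa in aas])
        ),
        "n_positive": sum(1 for aa in aas if _CHARGE_PH8.get(aa, 0) > 0),
        "n_negative": sum(1 for aa in aas if _CHARGE_PH8.get(aa, 0) < 0),
        "n_polar": sum(1 for aa in aas if aa in _POLAR),
        "n_apolar": sum(1 for aa in aas if aa not in _POLAR),
        "charges": charges,
    }


# ---------------------------------------------------------------------------
# Trajectory-dependent site descriptors
# ---------------------------------------------------------------------------

def _site_residue_atom_lists(site: BindingSite, structure: StructureModel):
    return [
        np.flatnonzero(
            (structure.residue_ids == rid) & structure.mask("heavy")
        )
        for rid in site.residue_ids
    ]


def pocket_occupancy(
    site: BindingSite, traj: TrajectoryData, cutoff: float | None = None
) -> np.ndarray:
    """Per-site-residue fraction of frames spent near the template ligand
    centroid.

    The residue-to-pocket distance is the minimum heavy-atom distance to the
    (frame-fixed) ligand centroid.  With ``cutoff=None`` each residue's
    threshold is its distance in the reference structure plus a 2 A slack,
    so an unperturbed trajectory scores occupancy 1 everywhere; a scalar
    cutoff applies uniformly instead.
    """
    s = traj.structure
    centroid = s.coords[site.ligand_atom_indices].mean(axis=0)
    atom_lists = _site_residue_atom_lists(site, s)
    occ = np.zeros(site.n_residues)
    for r, idx in enumerate(atom_lists):
        ref_d = np.linalg.norm(s.coords[idx] - centroid, axis=1).min()
        thr = (ref_d + 2.0) if cutoff is None else cutoff
        d = np.linalg.norm(traj.frames[:, idx, :] - centroid, axis=2).min(axis=1)
        occ[r] = float((d <= thr).mean())
    return occ


def _occupancy_series(
    site: BindingSite, traj: TrajectoryData
) -> np.ndarray:
    """Binary (frames x site residues) in-pocket indicator with the default
    per-residue threshold (see pocket_occupancy)."""
    s = traj.structure
    centroid = s.coords[site.ligand_atom_indices].mean(axis=0)
    out = np.zeros((traj.n_frames, site.n_residues))
    for r, idx in enumerate(_site_residue_atom_lists(site, s)):
        ref_d = np.linalg.norm(s.coords[idx] - centroid, axis=1).min()
        d = np.linalg.norm(traj.frames[:, idx, :] - centroid, axis=2).min(axis=1)
        out[:, r] = d <= ref_d + 2.0
    return out


def normalized_bfactor(site: BindingSite, traj: TrajectoryData) -> np.ndarray:
    """Per-site-residue normalized B-factor: B = (8 pi^2 / 3) RMSF^2 on
    Calpha, z-scored across the site residues."""
    from .trajectory_features import AtomSelection, rmsf

    if traj.n_frames < 2:
        raise ValueError("normalized B-factor needs at least 2 frames")
    fl = rmsf(traj, AtomSelection("calpha", restrict_to_binding_site=True),
              site_residue_ids=site.residue_ids)
    b = (8.0 * np.pi**2 / 3.0) * fl**2
    sd = b.std(ddof=0)
    if sd == 0:
        return np.zeros_like(b)
    return (b - b.mean()) / sd


# ---------------------------------------------------------------------------
# 80-column block
# ---------------------------------------------------------------------------

N_SITE_SLOTS = 16  # canonical per-residue slots, ordered by residue id


def _replicate_pocket_features(
    site: BindingSite, traj: TrajectoryData, sequence: str,
    n_slots: int, sasa_stride: int, sasa_points: int,
) -> dict[str, float]:
    s = traj.structure
    radii = np.array([VDW_RADII.get(e.capitalize(), 1.7) for e in s.elements])
    heavy = np.flatnonzero(s.mask("heavy"))
    out: dict[str, float] = {}

    geom = {"volume_proxy": [], "length": [], "depth_proxy": []}
    for f in range(traj.n_frames):
        g = pocket_geometry(site, traj.frames[f])
        for k in geom:
            geom[k].append(g[k])
    for k, series in geom.items():
        arr = np.asarray(series)
        out[f"{k}_mean"] = float(arr.mean())
        out[f"{k}_std"] = float(arr.std(ddof=0))

    sasa = []
    for f in range(0, traj.n_frames, sasa_stride):
        areas = shrake_rupley_sasa(
            traj.frames[f][heavy], radii[heavy], n_points=sasa_points,
            targets=np.searchsorted(heavy, site.atom_indices),
        )
        sasa.append(areas.sum())
    sasa = np.asarray(sasa)
    out["sasa_mean"] = float(sasa.mean())
    out["sasa_std"] = float(sasa.std(ddof=0))

    chem = pocket_chemistry(site, sequence)
    out["hydrophobicity_mean"] = chem["hydrophobicity_mean"]
    out["hydrophobicity_std"] = 0.0  # sequence-determined, frame-invariant

    occ = _occupancy_series(site, traj)
    bfac = normalized_bfactor(site, traj)
    for slot in range(n_slots):
        if slot < site.n_residues:
            out[f"occ_slot{slot + 1:02d}_mean"] = float(occ[:, slot].mean())
            out[f"occ_slot{slot + 1:02d}_std"] = float(occ[:, slot].std(ddof=0))
            out[f"bfac_slot{slot + 1:02d}_mean"] = float(bfac[slot])
            out[f"bfac_slot{slot + 1:02d}_std"] = 0.0
        else:
            for key in ("occ", "bfac"):
                out[f"{key}_slot{slot + 1:02d}_mean"] = 0.0
                out[f"{key}_slot{slot + 1:02d}_std"] = 0.0

    out["n_positive"] = float(chem["n_positive"])
    out["n_negative"] = float(chem["n_negative"])
    out["n_polar"] = float(chem["n_polar"])
    out["n_apolar"] = float(chem["n_apolar"])
    out["net_charge"] = float(chem["n_positive"] - chem["n_negative"])
    out["apolar_fraction"] = float(
        chem["n_apolar"] / max(site.n_residues, 1)
    )
    return out


def pocket_feature_block(
    site: BindingSite,
    replicates: list[TrajectoryData],
    sequence: str,
    n_slots: int = N_SITE_SLOTS,
    sasa_stride: int = 5,
    sasa_points: int = 240,
) -> dict[str, float]:
    """The 80 pocket features for one variant, averaged over replicates:
    frame mean+std of {volume, length, depth, SASA, hydrophobicity} (10),
    per-slot occupancy mean+std (32), per-slot normalized B-factor
    mean+std (32) and six charge/polarity counts.

    SASA is evaluated every ``sasa_stride``-th frame with ``sasa_points``
    sphere points per atom (a desk-scale setting; the standalone SASA
    routine defaults to 960).  A site smaller or larger than ``n_slots``
    is zero-padded or truncated with a warning.
    """
    from .dataset_assembly import aggregate_replicates

    if not replicates:
        raise ValueError("need at least one replicate trajectory")
    if site.n_residues != n_slots:
        warnings.warn(
            f"binding site has {site.n_residues} residues; "
            f"{'padding' if site.n_residues < n_slots else 'truncating'} "
            f"to {n_slots} slots"
        )
    per_rep = [
        _replicate_pocket_features(site, traj, sequence, n_slots,
                                   sasa_stride, sasa_points)
        for traj in replicates
    ]
    # B-factor varies between replicates, not within: use the across-replicate
    # spread as its std column
    mean, std = aggregate_replicates(per_rep)
    for slot in range(min(n_slots, site.n_residues)):
        mean[f"bfac_slot{slot + 1:02d}_std"] = std[f"bfac_slot{slot + 1:02d}_mean"]
    return mean
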