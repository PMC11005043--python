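"""Synthetic variant libraries, toy fluctuation trajectories and a planted
activity response.

The generator emulates the statistical structure of a directed-evolution
study on an engineered enterokinase light chain: an error-prone-PCR-like
library (312 variants, 0-9 co-occurring substitutions confined to hot-spot
regions covering ~30% of the 235-residue sequence), five replicate
trajectories per variant, and a fold-change-in-activities (FCA) response
planted as a linear function of standardized observed features (by default
+1 on the mean alpha-helix fraction and -1 on the mean turn fraction) plus
Gaussian noise.

Trajectories are an Ornstein-Uhlenbeck (mean-reverting Gaussian) walk
around the template geometry -- the simplest process with the two
properties the downstream robustness statistics probe: temporal
autocorrelation within a replicate and variability between replicates.
No physical realism beyond that is claimed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import StructureModel, TrajectoryData
from .sequence_layer import MutationSpec, VariantRecord, apply_mutations
from . import scales

__all__ = [
    "SynthSpec",
    "make_template",
    "make_variant_library",
    "simulate_replicates",
    "plant_response",
    "default_spec",
    "default_template",
    "build_synthetic_dataset",
]

_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}

# ideal backbone internal coordinates (lengths in Angstrom, angles in deg)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8
HELIX_PHI_PSI = (-57.0, -47.0)
SHEET_PHI_PSI = (-119.0, 113.0)


@dataclass
class SynthSpec:
    """Generator settings; defaults emulate the study library conditions."""

    n_variants: int = 312
    hot_positions: list[int] = field(default_factory=list)  # 1-based
    max_mutations: int = 9
    replicates: int = 5
    frames_per_traj: int = 101
    dt_ps: float = 100.0
    flexibility_base: float = 0.25  # per-coordinate stationary sd, Angstrom
    effect_coefs: dict[str, float] = field(
        default_factory=lambda: {"ss_h_alpha": 1.0, "ss_turn": -1.0}
    )
    noise_sd: float = 0.5
    seed: int = 0
    mutation_rate: float = 4.2  # Poisson mean of substitutions per variant
    ou_rho: float = 0.9  # frame-to-frame autocorrelation
    loop_boost: float = 1.0  # relative amplitude increase in loops
    mutation_boost: float = 1.5  # relative increase within +-2 of a mutation

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if self.max_mutations < 0:
            raise ValueError("max_mutations must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.ou_rho < 1.0:
            raise ValueError("ou_rho must lie in [0, 1)")


# ---------------------------------------------------------------------------
# Template construction from ideal internal geometry
# ---------------------------------------------------------------------------

def _place_atom(a, b, c, bond: float, angle_deg: float, dihedral_deg: float):
    """Position atom d given the three previous atoms and internal
    coordinates (NeRF construction)."""
    angle = np.radians(angle_deg)
    dihedral = np.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(dihedral),
        bond * np.sin(angle) * np.sin(dihedral),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _validate_spans(spans, length, other=()):
    occupied = set()
    for lo, hi in list(spans) + list(other):
        if lo < 1 or hi > length or lo > hi:
            raise ValueError(f"span ({lo}, {hi}) outside [1, {length}]")
        if occupied & set(range(lo, hi + 1)):
            raise ValueError("secondary-structure spans overlap")
        occupied |= set(range(lo, hi + 1))


def make_template(
    length: int,
    helix_spans: list[tuple[int, int]] = (),
    sheet_spans: list[tuple[int, int]] = (),
    seed: int = 0,
    sequence: str | None = None,
    ligand_anchor_residues: tuple[int, ...] | None = None,
) -> tuple[StructureModel, str]:
    """Build a backbone-only template structure from ideal internal geometry.

    Helix spans get (phi, psi) = (-57, -47), sheet spans (-119, 113); loop
    residues draw extended-coil dihedrals from the seeded generator.  A
    6-atom peptide-like ligand (HETATM, resname LIG) is placed within
    3.5 A of three anchor residues so a non-empty binding site exists.
    """
    _validate_spans(helix_spans, length, sheet_spans)
    rng = np.random.default_rng(seed)
    if sequence is None:
        sequence = "".join(rng.choice(list(scales.AMINO_ACIDS), size=length))
    if len(sequence) != length:
        raise ValueError("sequence length mismatch")

    in_helix = np.zeros(length + 1, dtype=bool)
    in_sheet = np.zeros(length + 1, dtype=bool)
    for lo, hi in helix_spans:
        in_helix[lo : hi + 1] = True
    for lo, hi in sheet_spans:
        in_sheet[lo : hi + 1] = True

    def phi_psi(pos: int) -> tuple[float, float]:
        if in_helix[pos]:
            return HELIX_PHI_PSI
        if in_sheet[pos]:
            return SHEET_PHI_PSI
        return (float(rng.uniform(-160, -60)), float(rng.uniform(90, 180)))

    dihedrals = [phi_psi(i + 1) for i in range(length)]

    N = np.zeros((length, 3))
    CA = np.zeros((length, 3))
    C = np.zeros((length, 3))
    O = np.zeros((length, 3))
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (_B_N_CA, 0.0, 0.0)
    ang = np.radians(180.0 - _A_N_CA_C)
    C[0] = CA[0] + _B_CA_C * np.array([np.cos(np.pi - ang), np.sin(np.pi - ang), 0.0])
    for i in range(length - 1):
        _, psi = dihedrals[i]
        N[i + 1] = _place_atom(N[i], CA[i], C[i], _B_C_N, _A_CA_C_N, psi)
        CA[i + 1] = _place_atom(CA[i], C[i], N[i + 1], _B_N_CA, _A_C_N_CA, 180.0)
        phi_next, _ = dihedrals[i + 1]
        C[i + 1] = _place_atom(C[i], N[i + 1], CA[i + 1], _B_CA_C, _A_N_CA_C, phi_next)
        # carbonyl O opposite the next amide N
        O[i] = _place_atom(N[i + 1], CA[i], C[i], _B_C_O, _A_CA_C_O, 180.0)
    O[-1] = _place_atom(N[-1], CA[-1], C[-1], _B_C_O, _A_CA_C_O, 135.0)

    atom_names, elements, rids, rnames, chains, coords, lig = [], [], [], [], [], [], []
    for i in range(length):
        for name, pos in (("N", N[i]), ("CA", CA[i]), ("C", C[i]), ("O", O[i])):
            atom_names.append(name)
            elements.append(name[0])
            rids.append(i + 1)
            rnames.append(_AA3[sequence[i]])
            chains.append("A")
            coords.append(pos)
            lig.append(False)

    # peptide-like ligand: one atom 2.5 A off each anchor CA plus bridges
    if ligand_anchor_residues is None:
        mid = length // 2
        ligand_anchor_residues = (mid - 1, mid, mid + 1)
    anchors = [a for a in ligand_anchor_residues if 1 <= a <= length]
    if len(anchors) < 3:
        raise ValueError("need at least three ligand anchor residues")
    lig_coords = []
    for a in anchors[:3]:
        lig_coords.append(CA[a - 1] + 2.5 * _off_chain_direction(N, CA, C, a - 1))
    for i in range(3):
        lig_coords.append(0.5 * (lig_coords[i] + lig_coords[(i + 1) % 3]))
    for j, pos in enumerate(lig_coords):
        atom_names.append(f"L{j + 1}")
        elements.append(["C", "N", "O"][j % 3])
        rids.append(length + 1)
        rnames.append("LIG")
        chains.append("A")
        coords.append(pos)
        lig.append(True)

    structure = StructureModel(
        atom_names, elements, np.array(rids), rnames, chains,
        np.array(coords), np.array(lig),
    )
    return structure, sequence


def _off_chain_direction(N, CA, C, i):
    """Unit vector from CA_i roughly along the side-chain (CB) direction,
    i.e. away from the local backbone plane."""
    v1 = N[i] - CA[i]
    v2 = C[i] - CA[i]
    d = -(v1 + v2)
    n = np.cross(v1, v2)
    direction = d + 0.8 * n / max(np.linalg.norm(n), 1e-9) * np.linalg.norm(d)
    return direction / np.linalg.norm(direction)


# ---------------------------------------------------------------------------
# Variant library
# ---------------------------------------------------------------------------

def make_variant_library(
    spec: SynthSpec, template_sequence: str
) -> list[VariantRecord]:
    """Draw an epPCR-like library: variant 0 is the unmutated template, the
    rest carry 0..max_mutations substitutions confined to hot positions
    (counts Poisson-distributed with mean ``mutation_rate``, clipped)."""
    if not spec.hot_positions:
        raise ValueError("hot_positions must be non-empty")
    length = len(template_sequence)
    for p in spec.hot_positions:
        if not 1 <= p <= length:
            raise ValueError(f"hot position {p} beyond sequence length {length}")
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 101)))
    hot = np.array(sorted(set(spec.hot_positions)))
    variants = [VariantRecord("v000", [], template_sequence)]
    for i in range(1, spec.n_variants):
        k = int(min(rng.poisson(spec.mutation_rate), spec.max_mutations,
                    len(hot)))
        positions = sorted(rng.choice(hot, size=k, replace=False))
        muts = []
        for pos in positions:
            ref = template_sequence[pos - 1]
            alt = ref
            while alt == ref:
                alt = str(rng.choice(list(scales.AMINO_ACIDS)))
            muts.append(MutationSpec(ref, int(pos), alt))
        variants.append(
            VariantRecord(
                f"v{i:03d}", muts, apply_mutations(template_sequence, muts)
            )
        )
    return variants


# ---------------------------------------------------------------------------
# Replicate trajectories
# ---------------------------------------------------------------------------

def _residue_amplitudes(
    variant: VariantRecord, template: StructureModel, spec: SynthSpec
) -> np.ndarray:
    """Per-atom stationary fluctuation amplitude: base level, boosted in
    loop regions of the static template and around mutated positions."""
    from .trajectory_features import assign_secondary_structure, BackboneIndex

    bb = BackboneIndex(template)
    labels = assign_secondary_structure(template.coords, bb)
    structured = np.isin(labels, ["H", "G", "E_para", "E_anti"])
    res_amp = np.full(bb.n_res, spec.flexibility_base)
    res_amp[~structured] *= 1.0 + spec.loop_boost
    mutated = np.zeros(bb.n_res, dtype=bool)
    for m in variant.mutations:
        lo, hi = max(0, m.position - 3), min(bb.n_res, m.position + 2)
        mutated[lo:hi] = True
    res_amp[mutated] *= 1.0 + spec.mutation_boost
    # map residue amplitude onto atoms (ligand follows the base level)
    amp = np.full(template.n_atoms, spec.flexibility_base)
    rid_to_amp = dict(zip(bb.residue_ids, res_amp))
    for a in range(template.n_atoms):
        if not template.ligand_flag[a]:
            amp[a] = rid_to_amp.get(int(template.residue_ids[a]),
                                    spec.flexibility_base)
    return amp


def simulate_replicates(
    variant: VariantRecord,
    template: StructureModel,
    spec: SynthSpec,
    variant_index: int = 0,
) -> list[TrajectoryData]:
    """Replicate trajectories as an OU walk around the template.

    Displacements follow x_{t+1} = rho x_t + eta with eta scaled so the
    stationary per-coordinate sd equals the per-atom amplitude; replicates
    differ only in their seed stream.
    """
    if spec.frames_per_traj < 2:
        raise ValueError("frames_per_traj must be >= 2")
    amp = _residue_amplitudes(variant, template, spec)[:, None]
    rho = spec.ou_rho
    eta_sd = amp * np.sqrt(1.0 - rho**2)
    out = []
    for rep in range(spec.replicates):
        rng = np.random.default_rng(
            np.random.SeedSequence((spec.seed, 7919, variant_index, rep))
        )
        F, n = spec.frames_per_traj, template.n_atoms
        x = amp * rng.standard_normal((n, 3))  # stationary start
        frames = np.empty((F, n, 3))
        for f in range(F):
            frames[f] = template.coords + x
            x = rho * x + eta_sd * rng.standard_normal((n, 3))
        out.append(TrajectoryData(frames, spec.dt_ps, template))
    return out


# ---------------------------------------------------------------------------
# Planted response
# ---------------------------------------------------------------------------

def plant_response(
    features: pd.DataFrame, spec: SynthSpec
) -> tuple[np.ndarray, dict]:
    """Plant FCA_i = sum_j coef_j * z(feature_ij) + eps_i with
    eps ~ N(0, noise_sd^2); z is the per-column standardization.

    Returns the response and the ground truth (coefficients and the
    standardization parameters) for recovery experiments.
    """
    for name in spec.effect_coefs:
        if name not in features.columns:
            raise ValueError(f"planted feature column missing: {name!r}")
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 4242)))
    n = len(features)
    fca = np.zeros(n)
    z_params = {}
    for name, coef in spec.effect_coefs.items():
        col = features[name].to_numpy(dtype=float)
        mu, sd = col.mean(), col.std(ddof=0)
        if sd == 0:
            raise ValueError(f"planted feature {name!r} has zero variance")
        fca += coef * (col - mu) / sd
        z_params[name] = (float(mu), float(sd))
    fca += spec.noise_sd * rng.standard_normal(n)
    truth = {"coefs": dict(spec.effect_coefs), "noise_sd": spec.noise_sd,
             "z_params": z_params}
    return fca, truth


# ---------------------------------------------------------------------------
# Default study-scale conditions and end-to-end dataset assembly
# ---------------------------------------------------------------------------

_TEMPLATE_LENGTH = 235
_HELIX_SPANS = [(8, 25), (40, 58), (75, 90), (110, 128), (150, 168), (190, 208)]
_SHEET_SPANS = [(30, 36), (65, 71), (97, 103), (135, 141), (175, 181), (215, 221)]
# epPCR hot-spot regions; 70 positions over 235 residues = 29.8% coverage,
# emulating the reported fraction of positions mutated at least once
_HOT_REGIONS = [(41, 64), (100, 128), (176, 192)]


def default_hot_positions() -> list[int]:
    positions = []
    for lo, hi in _HOT_REGIONS:
        positions.extend(range(lo, hi + 1))
    return positions[:70]


def default_template(seed: int = 0) -> tuple[StructureModel, str]:
    """The study-scale emulation template: 235 residues, mixed helix/sheet
    topology, ligand anchored mid-chain."""
    return make_template(
        _TEMPLATE_LENGTH, _HELIX_SPANS, _SHEET_SPANS, seed=seed,
        ligand_anchor_residues=(117, 118, 119),
    )


def default_spec(seed: int = 0, **overrides) -> SynthSpec:
    spec = SynthSpec(hot_positions=default_hot_positions(), seed=seed)
    for key, value in overrides.items():
        if not hasattr(spec, key):
            raise AttributeError(f"unknown SynthSpec field {key!r}")
        setattr(spec, key, value)
    return spec


def build_synthetic_dataset(
    spec: SynthSpec,
    template: StructureModel | None = None,
    template_sequence: str | None = None,
    blocks: tuple[str, ...] = ("SEQ", "MD", "POCKET"),
    plant: bool = True,
):
    """Generate a library and featurize it end to end.

    Trajectories are simulated and featurized one variant at a time and
    discarded, so memory stays flat in library size.  Returns
    ``(FeatureTable, variants, truth)`` where truth holds the planted
    coefficients (None when ``plant`` is False).
    """
    from .dataset_assembly import assemble_feature_table
    from .pocket_features import define_binding_site, pocket_feature_block
    from .sequence_layer import seq_feature_block
    from .trajectory_features import md_feature_block

    if template is None:
        template, template_sequence = default_template(seed=spec.seed)
    if template_sequence is None:
        raise ValueError("template_sequence required with an explicit template")
    variants = make_variant_library(spec, template_sequence)

    seq_df = seq_feature_block(variants) if "SEQ" in blocks else None
    md_rows, pocket_rows = [], []
    need_traj = "MD" in blocks or "POCKET" in blocks
    if need_traj:
        site = define_binding_site(template)
        for i, variant in enumerate(variants):
            reps = simulate_replicates(variant, template, spec, variant_index=i)
            if "MD" in blocks:
                md_rows.append(
                    md_feature_block(reps, template, site.residue_ids)
                )
            if "POCKET" in blocks:
                pocket_rows.append(
                    pocket_feature_block(site, reps, variant.sequence)
                )
    ids = [v.id for v in variants]
    md_df = pd.DataFrame(md_rows, index=ids) if "MD" in blocks else None
    pocket_df = pd.DataFrame(pocket_rows, index=ids) if "POCKET" in blocks else None

    table = assemble_feature_table(seq_df, md_df, pocket_df)
    truth = None
    if plant:
        fca, truth = plant_response(table.values, spec)
        table = table.with_response(fca)
        for v, y in zip(variants, fca):
            v.fca = float(y)
    return table, variants, truth
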