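"""Variant bookkeeping and sequence-based biodescriptors.

Covers mutation parsing/application ("S38T/L74F" notation, 1-based
positions), the variant identity matrix and mutation-site occurrence
summaries, the fold-change-in-activities (FCA) response, and the 80
sequence/structure descriptors: 66 scale-family means plus 14 global
physicochemical properties.

All descriptors are per-residue table lookups averaged over the sequence
(the instability index, which is dipeptide-based, is the one deliberate
exception), so they carry composition rather than position information.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import scales

__all__ = [
    "MutationSpec",
    "VariantRecord",
    "parse_mutations",
    "format_mutations",
    "apply_mutations",
    "identity_matrix",
    "mutation_site_occurrence",
    "compute_fca",
    "compute_scale_descriptors",
    "compute_global_properties",
    "seq_feature_block",
    "net_charge",
    "isoelectric_point",
    "read_variants_csv",
    "write_variants_csv",
    "write_fasta",
    "read_fasta",
]

_MUT_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


@dataclass(frozen=True)
class MutationSpec:
    """A single amino-acid substitution, e.g. S38T."""

    ref_aa: str
    position: int  # 1-based
    alt_aa: str

    def __post_init__(self) -> None:
        for aa in (self.ref_aa, self.alt_aa):
            if aa not in scales.AMINO_ACIDS:
                raise ValueError(f"non-standard residue in mutation: {aa!r}")
        if self.ref_aa == self.alt_aa:
            raise ValueError(f"mutation {self} has identical ref and alt residues")
        if self.position < 1:
            raise ValueError("mutation positions are 1-based")

    def __str__(self) -> str:
        return f"{self.ref_aa}{self.position}{self.alt_aa}"


@dataclass
class VariantRecord:
    """One library member: mutations, full sequence and activity response."""

    id: str
    mutations: list[MutationSpec]
    sequence: str
    activity_a: float = np.nan  # no pre-heat setting
    activity_b: float = np.nan  # with pre-heat setting
    fca: float = np.nan

    @property
    def n_mutations(self) -> int:
        return len(self.mutations)


def parse_mutations(spec_string: str) -> list[MutationSpec]:
    """Parse a "/"-separated mutation string such as "S38T/L74F/M100K/S127T".

    The empty string denotes the unmutated template.  Token order is
    preserved; malformed tokens, duplicated positions and identical
    ref/alt residues are rejected with the offending token named.
    """
    if not spec_string:
        return []
    out: list[MutationSpec] = []
    seen: set[int] = set()
    for token in spec_string.split("/"):
        m = _MUT_RE.match(token)
        if not m:
            raise ValueError(f"malformed mutation token: {token!r}")
        ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
        if ref == alt:
            raise ValueError(f"mutation token {token!r} has ref == alt")
        if pos in seen:
            raise ValueError(f"duplicate mutation position in token {token!r}")
        seen.add(pos)
        out.append(MutationSpec(ref, pos, alt))
    return out


def format_mutations(mutations: list[MutationSpec]) -> str:
    return "/".join(str(m) for m in mutations)


def apply_mutations(template_sequence: str, mutations: list[MutationSpec]) -> str:
    """Apply substitutions to the template, checking each reference residue."""
    seq = list(template_sequence)
    for m in mutations:
        if m.position > len(seq):
            raise ValueError(f"mutation {m} beyond sequence length {len(seq)}")
        found = seq[m.position - 1]
        if found != m.ref_aa:
            raise ValueError(
                f"mutation {m}: expected {m.ref_aa!r} at position {m.position}, "
                f"found {found!r}"
            )
        seq[m.position - 1] = m.alt_aa
    return "".join(seq)


def identity_matrix(variants: list[VariantRecord]) -> np.ndarray:
    """Pairwise percent sequence identity (equal-length sequences only)."""
    lengths = {len(v.sequence) for v in variants}
    if len(lengths) > 1:
        raise ValueError(f"sequences differ in length: {sorted(lengths)}")
    arr = np.array([list(v.sequence) for v in variants])
    eq = arr[:, None, :] == arr[None, :, :]
    return 100.0 * eq.mean(axis=2)


def mutation_site_occurrence(
    variants: list[VariantRecord],
) -> tuple[dict[int, float], float]:
    """Normalized per-site mutation occurrence and the fraction of positions
    mutated at least once across the library."""
    if not variants:
        raise ValueError("need at least one variant")
    counts: dict[int, int] = {}
    for v in variants:
        for m in v.mutations:
            counts[m.position] = counts.get(m.position, 0) + 1
    length = len(variants[0].sequence)
    if not counts:
        return {}, 0.0
    peak = max(counts.values())
    normalized = {pos: c / peak for pos, c in sorted(counts.items())}
    return normalized, len(counts) / length


def compute_fca(
    activity_a: float,
    activity_b: float,
    template_a: float,
    template_b: float,
    convention: str = "b_minus_a",
) -> float:
    """Fold change in activities: the difference between a variant's fold
    activity (variant/template ratio) in the two experimental settings.

    Setting a is without, setting b with pre-incubation heating.  The sign
    convention is configurable since only the difference is defined.
    """
    if template_a <= 0 or template_b <= 0:
        raise ValueError("template activities must be positive")
    fold_a = activity_a / template_a
    fold_b = activity_b / template_b
    if convention == "b_minus_a":
        return fold_b - fold_a
    if convention == "a_minus_b":
        return fold_a - fold_b
    raise ValueError(f"unknown FCA convention: {convention!r}")


# ---------------------------------------------------------------------------
# 66 scale-family descriptors
# ---------------------------------------------------------------------------

_FAMILY_PREFIX = {
    "BLOSUM": "BLOSUM",
    "Cruciani": "PP",
    "FASGAI": "F",
    "KideraFactor": "KF",
    "MSWHIM": "MSWHIM",
    "ProtFP": "ProtFP",
    "ST": "ST",
    "T": "T",
    "VHSE": "VHSE",
    "Z": "Z",
}


def _check_sequence(sequence: str) -> np.ndarray:
    if not sequence:
        raise ValueError("sequence must be non-empty")
    idx = np.array([scales.AMINO_ACIDS.find(aa) for aa in sequence])
    if (idx < 0).any():
        bad = sorted({aa for aa in sequence if aa not in scales.AMINO_ACIDS})
        raise ValueError(f"non-standard residues in sequence: {bad}")
    return idx


def compute_scale_descriptors(sequence: str) -> dict[str, float]:
    """The 66 scale-based descriptors: per-family, per-component means of
    the residue scale values over the sequence."""
    idx = _check_sequence(sequence)
    out: dict[str, float] = {}
    for family in scales.SCALE_FAMILIES:
        mat, dim = scales.family_matrix(family)
        means = mat[idx].mean(axis=0)
        prefix = _FAMILY_PREFIX[family]
        for k in range(dim):
            out[f"{prefix}{k + 1}"] = float(means[k])
    return out


# ---------------------------------------------------------------------------
# 14 global properties
# ---------------------------------------------------------------------------

def net_charge(sequence: str, ph: float) -> float:
    """Net peptide charge from the Henderson-Hasselbalch equation with the
    EMBOSS pKa set (free termini included)."""
    _check_sequence(sequence)
    counts = {g: 0 for g in scales.PKA_EMBOSS}
    counts["Nterm"] = counts["Cterm"] = 1
    for aa in sequence:
        if aa in counts:
            counts[aa] += 1
    pos = sum(
        counts[g] / (1.0 + 10.0 ** (ph - scales.PKA_EMBOSS[g]))
        for g in scales.POSITIVE_PKA
    )
    neg = sum(
        counts[g] / (1.0 + 10.0 ** (scales.PKA_EMBOSS[g] - ph))
        for g in scales.NEGATIVE_PKA
    )
    return pos - neg


def isoelectric_point(sequence: str, tol: float = 1e-4) -> float:
    """pH at which the net charge vanishes, solved by bisection to
    |charge| < tol."""
    lo, hi = 0.0, 14.0
    # net_charge is strictly decreasing in pH, so brentq is safe
    ph = brentq(lambda p: net_charge(sequence, p), lo, hi, xtol=1e-8)
    assert abs(net_charge(sequence, ph)) < tol
    return float(ph)


def molecular_weight(sequence: str) -> float:
    """Average molecular weight: residue masses plus one water."""
    _check_sequence(sequence)
    return sum(scales.RESIDUE_MASS[aa] for aa in sequence) + scales.WATER_MASS


def compute_global_properties(sequence: str, ph: float = 8.0) -> dict[str, float]:
    """The 14 global physicochemical properties of a variant sequence.

    ProtParam-style properties (aromaticity, instability index, GRAVY,
    secondary-structure propensity fractions, reduced molar extinction
    coefficient) are delegated to Biopython; molecular weight, net charge
    and the isoelectric point use the module's own mass/pKa tables.  The
    net charge is evaluated at pH 8.0, the experimental assay pH.
    Flexibility is the composition mean of the Vihinen normalized B-factor
    scale.
    """
    from Bio.SeqUtils.ProtParam import ProteinAnalysis
    from Bio.SeqUtils import ProtParamData

    _check_sequence(sequence)
    pa = ProteinAnalysis(sequence)
    helix, turn, sheet = pa.secondary_structure_fraction()
    ext_reduced, _ = pa.molar_extinction_coefficient()
    counts = {aa: sequence.count(aa) for aa in "AVIL"}
    n = len(sequence)
    aliphatic = 100.0 * (
        counts["A"] / n
        + scales.ALIPHATIC_A * counts["V"] / n
        + scales.ALIPHATIC_B * (counts["I"] + counts["L"]) / n
    )
    boman = -float(np.mean([scales.TRANSFER_FREE_ENERGY[aa] for aa in sequence]))
    flex = float(np.mean([ProtParamData.Flex[aa] for aa in sequence]))
    return {
        "length": float(n),
        "molecular_weight": molecular_weight(sequence),
        "isoelectric_point": isoelectric_point(sequence),
        "aromaticity": float(pa.aromaticity()),
        "instability_index": float(pa.instability_index()),
        "gravy": float(pa.gravy()),
        "net_charge_ph8": net_charge(sequence, ph),
        "extinction_reduced": float(ext_reduced),
        "flexibility_mean": flex,
        "helix_propensity": float(helix),
        "turn_propensity": float(turn),
        "sheet_propensity": float(sheet),
        "aliphatic_index": float(aliphatic),
        "boman_index": boman,
    }


def seq_feature_block(variants: list[VariantRecord]) -> pd.DataFrame:
    """80-column sequence feature block (66 scale + 14 global descriptors),
    one row per variant."""
    rows = []
    for v in variants:
        row = compute_scale_descriptors(v.sequence)
        row.update(compute_global_properties(v.sequence))
        rows.append(row)
    return pd.DataFrame(rows, index=[v.id for v in variants])


# ---------------------------------------------------------------------------
# Variant CSV / FASTA round-trips
# ---------------------------------------------------------------------------

def write_variants_csv(variants: list[VariantRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "id": [v.id for v in variants],
            "mutations": [format_mutations(v.mutations) for v in variants],
            "activity_a": [v.activity_a for v in variants],
            "activity_b": [v.activity_b for v in variants],
            "fca": [v.fca for v in variants],
        }
    )
    df.to_csv(path, index=False)


def read_variants_csv(path: str | Path, template_sequence: str) -> list[VariantRecord]:
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    out = []
    for _, row in df.iterrows():
        muts = parse_mutations(str(row["mutations"]) if pd.notna(row["mutations"]) else "")
        out.append(
            VariantRecord(
                id=str(row["id"]),
                mutations=muts,
                sequence=apply_mutations(template_sequence, muts),
                activity_a=float(row.get("activity_a", np.nan)),
                activity_b=float(row.get("activity_b", np.nan)),
                fca=float(row.get("fca", np.nan)),
            )
        )
    return out


def write_fasta(variants: list[VariantRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for v in variants:
            fh.write(f">{v.id} {format_mutations(v.mutations)}\n")
            for i in range(0, len(v.sequence), 60):
                fh.write(v.sequence[i : i + 60] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
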