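"""Steric feasibility of predicted interface residues on assembled complexes.

Interface residues predicted from pairwise models are mapped (by explicit
per-subunit offsets, never by alignment) onto an assembled whole-complex
model, solvent accessibility is computed in the complex context with a
deterministic Shrake-Rupley scheme, and each mapped residue is classified
accessible when its relative SASA meets a threshold (default 0.25).  The
percent-accessible summary quantifies how many predicted binding-site
residues remain available on the assembled complex surface.

The exposure classification is a quantitative surrogate for what is often
judged visually on rendered surfaces; the threshold and the max-ASA
normalisation table are recorded in every report.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .model_io import StructureModel

__all__ = [
    "SASAResult",
    "ResidueMapping",
    "SubunitOffset",
    "FeasibilityReport",
    "MappingError",
    "VDW_RADII",
    "MAX_ASA_TABLES",
    "sphere_points",
    "compute_sasa",
    "relative_sasa",
    "map_interface_residues",
    "feasibility_percent",
]

# van der Waals radii (A), Bondi-style single-atom set
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "D": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
}

# theoretical maximum accessible surface areas per residue type (A^2),
# Tien et al. 2013 ("theoretical" column)
MAX_ASA_TABLES: dict[str, dict[str, float]] = {
    "tien2013": {
        "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0,
        "CYS": 167.0, "GLN": 225.0, "GLU": 223.0, "GLY": 104.0,
        "HIS": 224.0, "ILE": 197.0, "LEU": 201.0, "LYS": 236.0,
        "MET": 224.0, "PHE": 240.0, "PRO": 159.0, "SER": 155.0,
        "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
    },
}


class MappingError(ValueError):
    """Interface-to-complex residue mapping violated its contract."""


@dataclass
class SASAResult:
    """Per-residue solvent-accessible surface area on one model."""

    residue_sasa: dict[tuple[str, int], float]  # (chain_id, seq_index) -> A^2
    residue_names: dict[tuple[str, int], str]
    probe_radius: float
    n_points: int

    def relative(self, key: tuple[str, int], table: str = "tien2013") -> float:
        return relative_sasa(self.residue_sasa[key], self.residue_names[key], table)


@dataclass(frozen=True)
class ResidueMapping:
    """One pairwise-model interface residue located in the complex model."""

    source_subunit: str
    source_seq_index: int
    residue_name: str
    target_chain_id: str
    target_seq_index: int
    offset: int  # provenance: target = source + offset


@dataclass
class SubunitOffset:
    """Explicit truncation bookkeeping for one subunit in the complex.

    ``kept_ranges`` are inclusive (start, end) intervals in *source*
    numbering; residues outside them were trimmed from the complex input.
    ``offset`` converts source numbering to complex numbering on the kept
    ranges.  ``None`` kept_ranges means the subunit is untrimmed.
    """

    chain_id: str
    offset: int = 0
    kept_ranges: list[tuple[int, int]] | None = None

    def keeps(self, seq_index: int) -> bool:
        if self.kept_ranges is None:
            return True
        return any(lo <= seq_index <= hi for lo, hi in self.kept_ranges)


@dataclass
class FeasibilityReport:
    complex_id: str
    residues: list[tuple[ResidueMapping, float, bool]]  # (mapping, rSASA, accessible)
    percent_accessible: float
    n_unmappable: int
    rsa_threshold: float
    max_asa_table: str

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "subunit": m.source_subunit,
                "source_res": m.source_seq_index,
                "residue": m.residue_name,
                "complex_chain": m.target_chain_id,
                "complex_res": m.target_seq_index,
                "relative_sasa": round(rsa, 4),
                "accessible": acc,
            }
            for m, rsa, acc in self.residues
        ]
        return pd.DataFrame(rows)


def sphere_points(n: int) -> np.ndarray:
    """n deterministic, near-uniform unit-sphere points (golden spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = math.pi * (1.0 + math.sqrt(5.0)) * i
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def compute_sasa(
    model: StructureModel,
    probe_radius: float = 1.4,
    n_points: int = 960,
    default_radius: float = 1.70,
) -> SASAResult:
    """Shrake-Rupley SASA per residue, heavy atoms only.

    Each atom's extended sphere (vdW + probe) is sampled at ``n_points``
    golden-spiral points; a point is solvent-accessible when it lies outside
    every neighbouring atom's extended sphere.  Deterministic for fixed
    ``n_points``.  Unknown elements fall back to ``default_radius`` with a
    warning.
    """
    coords: list[list[float]] = []
    radii: list[float] = []
    owner: list[tuple[str, int]] = []
    names: dict[tuple[str, int], str] = {}
    unknown: set[str] = set()
    for chain in model.chains:
        for res in chain.residues:
            key = (chain.chain_id, res.seq_index)
            names[key] = res.name
            for atom in res.heavy_atoms():
                el = atom.element.upper()
                r = VDW_RADII.get(el)
                if r is None:
                    unknown.add(el)
                    r = default_radius
                coords.append([atom.x, atom.y, atom.z])
                radii.append(r)
                owner.append(key)
    if unknown:
        warnings.warn(
            f"unknown element(s) {sorted(unknown)}: using default radius "
            f"{default_radius} A",
            stacklevel=2,
        )
    if not coords:
        raise ValueError("model has no non-hydrogen atoms")

    xyz = np.asarray(coords, float)
    rad = np.asarray(radii, float)
    ext = rad + probe_radius
    unit = sphere_points(n_points)

    tree = cKDTree(xyz)
    max_ext = float(ext.max())
    residue_sasa: dict[tuple[str, int], float] = {k: 0.0 for k in names}
    for i in range(len(xyz)):
        pts = xyz[i] + ext[i] * unit
        neighbours = [j for j in tree.query_ball_point(xyz[i], ext[i] + max_ext) if j != i]
        accessible = np.ones(n_points, dtype=bool)
        occluded = False
        for j in neighbours:
            # exactly coincident equal spheres: count the surface once (the
            # sample points sit on the boundary, where > / < is ill-defined)
            if ext[j] == ext[i] and np.array_equal(xyz[j], xyz[i]):
                if j < i:
                    occluded = True
                    break
                continue
            d2 = np.sum((pts - xyz[j]) ** 2, axis=1)
            accessible &= d2 > ext[j] ** 2
            if not accessible.any():
                break
        frac = 0.0 if occluded else accessible.mean()
        residue_sasa[owner[i]] += frac * 4.0 * math.pi * ext[i] ** 2
    return SASAResult(
        residue_sasa=residue_sasa,
        residue_names=names,
        probe_radius=probe_radius,
        n_points=n_points,
    )


def relative_sasa(
    absolute_sasa: float, residue_name: str, table: str = "tien2013"
) -> float:
    """Absolute SASA divided by the residue-type theoretical maximum."""
    try:
        max_asa = MAX_ASA_TABLES[table]
    except KeyError:
        raise ValueError(
            f"unknown max-ASA table {table!r}; available: {sorted(MAX_ASA_TABLES)}"
        )
    name = residue_name.upper()
    if name not in max_asa:
        raise KeyError(
            f"residue type {residue_name!r} not in max-ASA table {table!r} "
            f"(known: {sorted(max_asa)})"
        )
    return float(absolute_sasa) / max_asa[name]


def map_interface_residues(
    interface_residues: Sequence[tuple[str, int, str]],
    complex_model: StructureModel,
    offsets: Mapping[str, SubunitOffset],
) -> tuple[list[ResidueMapping], list[tuple[str, int, str]]]:
    """Locate pairwise-model interface residues in the assembled complex.

    ``interface_residues`` are (subunit_name, seq_index, residue_name)
    triples in pairwise-model numbering.  Mapping is purely arithmetic via
    the explicit per-subunit ``offsets`` config: residues inside a trimmed
    range are returned in the unmappable list; a residue whose mapped
    position is absent from, or named differently in, the complex raises
    :class:`MappingError` (off-by-one guard), as does a mapping collision.
    """
    mappings: list[ResidueMapping] = []
    unmappable: list[tuple[str, int, str]] = []
    seen_targets: dict[tuple[str, int], tuple[str, int]] = {}
    for subunit, seq_index, res_name in interface_residues:
        if subunit not in offsets:
            raise MappingError(f"no offset config for subunit {subunit!r}")
        cfg = offsets[subunit]
        if not cfg.keeps(seq_index):
            unmappable.append((subunit, seq_index, res_name))
            continue
        target_seq = seq_index + cfg.offset
        try:
            target_res = complex_model.residue(cfg.chain_id, target_seq)
        except KeyError:
            raise MappingError(
                f"{subunit} residue {seq_index}: mapped position "
                f"{cfg.chain_id}/{target_seq} absent from complex"
            )
        if target_res.name.upper() != res_name.upper():
            raise MappingError(
                f"{subunit} residue {seq_index} ({res_name}) maps to "
                f"{cfg.chain_id}/{target_seq} ({target_res.name}): name mismatch "
                "(possible off-by-one in offsets)"
            )
        tkey = (cfg.chain_id, target_seq)
        if tkey in seen_targets and seen_targets[tkey] != (subunit, seq_index):
            raise MappingError(
                f"mapping collision at {cfg.chain_id}/{target_seq}: "
                f"{seen_targets[tkey]} and {(subunit, seq_index)}"
            )
        seen_targets[tkey] = (subunit, seq_index)
        mappings.append(
            ResidueMapping(
                source_subunit=subunit,
                source_seq_index=seq_index,
                residue_name=target_res.name,
                target_chain_id=cfg.chain_id,
                target_seq_index=target_seq,
                offset=cfg.offset,
            )
        )
    return mappings, unmappable


def feasibility_percent(
    mappings: Sequence[ResidueMapping],
    sasa: SASAResult,
    rsa_threshold: float = 0.25,
    max_asa_table: str = "tien2013",
    n_unmappable: int = 0,
    complex_id: str = "complex",
) -> FeasibilityReport:
    """Fraction of mapped interface residues still solvent-accessible.

    Accessible means relative SASA >= ``rsa_threshold`` on the assembled
    complex (a residue buried by its own complex partners counts as
    inaccessible).  The percentage is over mapped residues only; unmappable
    residues are carried as a separate count.
    """
    if not mappings:
        raise ValueError("no mapped residues: percent accessible is undefined")
    rows: list[tuple[ResidueMapping, float, bool]] = []
    n_accessible = 0
    for m in mappings:
        key = (m.target_chain_id, m.target_seq_index)
        if key not in sasa.residue_sasa:
            raise MappingError(f"no SASA value for complex residue {key}")
        rsa = relative_sasa(sasa.residue_sasa[key], m.residue_name, max_asa_table)
        acc = rsa >= rsa_threshold
        n_accessible += acc
        rows.append((m, rsa, acc))
    return FeasibilityReport(
        complex_id=complex_id,
        residues=rows,
        percent_accessible=100.0 * n_accessible / len(mappings),
        n_unmappable=n_unmappable,
        rsa_threshold=rsa_threshold,
        max_asa_table=max_asa_table,
    )
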