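"""Structural data model and I/O for predicted complex models.

Predicted models (AlphaFold-style) store per-residue confidence (pLDDT,
0-100) in the B-factor field of every atom of a residue.  This module reads
and writes PDB/mmCIF files through :mod:`gemmi`, exposing a small in-memory
hierarchy (:class:`StructureModel` -> :class:`Chain` -> :class:`Residue` ->
:class:`Atom`) that the contact-extraction and accessibility stages consume,
plus the predicted-aligned-error (PAE) matrix that accompanies such models.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "StructureModel",
    "PAEMatrix",
    "StructureFormatError",
    "MissingConfidenceError",
    "read_structure",
    "write_structure",
    "read_pae",
    "models_equal",
]


class StructureFormatError(ValueError):
    """The file could not be parsed in the declared format or violates a
    structural assumption (insertion codes, empty chains, bad PAE shape)."""


class MissingConfidenceError(StructureFormatError):
    """No per-residue confidence data present in the B-factor field."""


@dataclass
class Atom:
    """A single atom with coordinates in Angstrom."""

    name: str
    element: str
    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError(f"atom {self.name!r}: empty element symbol")
        if not all(math.isfinite(v) for v in (self.x, self.y, self.z)):
            raise ValueError(f"atom {self.name!r}: non-finite coordinates")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class Residue:
    """One residue: 1-based author numbering, 3-letter name, pLDDT 0-100."""

    seq_index: int
    name: str
    atoms: list[Atom]
    plddt: float

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"residue {self.name} {self.seq_index}: no atoms")
        if not 0.0 <= self.plddt <= 100.0:
            raise ValueError(
                f"residue {self.name} {self.seq_index}: pLDDT {self.plddt} "
                "outside [0, 100]"
            )

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue]
    subunit_name: str | None = None

    def __post_init__(self) -> None:
        idx = [r.seq_index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError(
                f"chain {self.chain_id}: residue numbering not strictly increasing"
            )

    def residue(self, seq_index: int) -> Residue:
        for r in self.residues:
            if r.seq_index == seq_index:
                return r
        raise KeyError(f"chain {self.chain_id}: no residue {seq_index}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class StructureModel:
    """A (possibly multi-chain) predicted model with confidence data."""

    model_id: str
    chains: list[Chain]
    rank: int | None = None

    def __post_init__(self) -> None:
        if not self.chains:
            raise ValueError(f"model {self.model_id}: no chains")
        ids = [c.chain_id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise ValueError(f"model {self.model_id}: duplicate chain ids {ids}")

    @property
    def mean_plddt(self) -> float:
        vals = [r.plddt for c in self.chains for r in c.residues]
        return float(np.mean(vals))

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"model {self.model_id}: no chain {chain_id!r}")

    def residue(self, chain_id: str, seq_index: int) -> Residue:
        return self.chain(chain_id).residue(seq_index)

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains)


@dataclass
class PAEMatrix:
    """Predicted aligned error in Angstrom, indexed by concatenated residue
    order; ``chain_boundaries`` maps chain id -> (start, stop) index range
    (half-open) when a companion model is supplied."""

    values: np.ndarray
    chain_boundaries: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise StructureFormatError(
                f"PAE matrix must be square, got shape {self.values.shape}"
            )
        if np.any(self.values < 0):
            raise StructureFormatError("PAE matrix contains negative entries")

    @property
    def n(self) -> int:
        return self.values.shape[0]


# --------------------------------------------------------------------------
# structure reading / writing via gemmi

_FORMATS = {"pdb": gemmi.CoorFormat.Pdb, "mmcif": gemmi.CoorFormat.Mmcif}


def _coor_format(format: str, path: Path) -> gemmi.CoorFormat:
    if format == "auto":
        suffix = path.suffix.lower()
        if suffix in (".pdb", ".ent"):
            return gemmi.CoorFormat.Pdb
        if suffix in (".cif", ".mmcif"):
            return gemmi.CoorFormat.Mmcif
        return gemmi.CoorFormat.Detect
    try:
        return _FORMATS[format]
    except KeyError:
        raise ValueError(f"unknown format {format!r}; use pdb, mmcif or auto")


def read_structure(path: str | Path, format: str = "auto") -> StructureModel:
    """Read a PDB/mmCIF model; pLDDT is taken from the B-factor field.

    Per-residue confidence is the B-factor of the CA atom when present and
    the mean atom B-factor otherwise (AlphaFold writes identical values on
    all atoms of a residue, so both conventions agree on real inputs).
    A model whose B-factor column is entirely zero/blank carries no
    confidence information and is rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(str(path), format=_coor_format(format, path))
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureFormatError(f"{path}: no models in file")
    gmodel = st[0]

    any_bfactor = False
    chains: list[Chain] = []
    for gchain in gmodel:
        residues: list[Residue] = []
        for gres in gchain:
            icode = gres.seqid.icode
            if icode not in ("", " ", "\x00"):
                raise StructureFormatError(
                    f"{path}: insertion code {icode!r} at {gchain.name} "
                    f"{gres.seqid.num} not supported"
                )
            atoms: list[Atom] = []
            bfactors: list[float] = []
            ca_b: float | None = None
            kept_altloc: str | None = None
            for gatom in gres:
                altloc = gatom.altloc
                if altloc not in ("", "\x00"):
                    if kept_altloc is None:
                        kept_altloc = altloc
                    elif altloc != kept_altloc:
                        continue  # keep first altloc only
                atoms.append(
                    Atom(
                        name=gatom.name,
                        element=gatom.element.name or "X",
                        x=gatom.pos.x,
                        y=gatom.pos.y,
                        z=gatom.pos.z,
                    )
                )
                bfactors.append(gatom.b_iso)
                if gatom.name == "CA":
                    ca_b = gatom.b_iso
            if not atoms:
                continue
            if any(b != 0.0 for b in bfactors):
                any_bfactor = True
            plddt = ca_b if ca_b is not None else float(np.mean(bfactors))
            residues.append(
                Residue(
                    seq_index=gres.seqid.num,
                    name=gres.name,
                    atoms=atoms,
                    plddt=min(max(plddt, 0.0), 100.0),
                )
            )
        if residues:
            chains.append(Chain(chain_id=gchain.name, residues=residues))
    if not chains:
        raise StructureFormatError(f"{path}: no chains with atoms")
    if not any_bfactor:
        raise MissingConfidenceError(
            f"{path}: no confidence data (B-factor column empty or all zero)"
        )
    return StructureModel(model_id=path.stem, chains=chains)


def write_structure(model: StructureModel, path: str | Path, format: str = "auto") -> None:
    """Write a model as PDB or mmCIF; pLDDT goes into every atom's B-factor.

    ``read_structure(write_structure(m))`` round-trips to an equal model
    (coordinates to 3 decimals, pLDDT to 2 decimals, numbering exact).
    """
    path = Path(path)
    fmt = format
    if fmt == "auto":
        fmt = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; use pdb, mmcif or auto")

    for chain in model.chains:
        if not chain.residues:
            raise ValueError(f"model {model.model_id}: chain {chain.chain_id} is empty")

    st = gemmi.Structure()
    st.name = model.model_id
    gmodel = gemmi.Model("1")
    for chain in model.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.seq_index, " ")
            for atom in res.atoms:
                gatom = gemmi.Atom()
                gatom.name = atom.name
                gatom.element = gemmi.Element(atom.element)
                gatom.pos = gemmi.Position(atom.x, atom.y, atom.z)
                gatom.b_iso = res.plddt
                gatom.occ = 1.0
                gres.add_atom(gatom)
            gchain.add_residue(gres)
        gmodel.add_chain(gchain)
    st.add_model(gmodel)
    st.setup_entities()
    if fmt == "pdb":
        st.write_pdb(str(path))
    else:
        st.make_mmcif_document().write_file(str(path))


def models_equal(
    a: StructureModel,
    b: StructureModel,
    coord_tol: float = 5e-4,
    plddt_tol: float = 5e-3,
) -> bool:
    """Structural equality at file precision (3-decimal coords, 2-decimal B)."""
    if len(a.chains) != len(b.chains):
        return False
    for ca, cb in zip(a.chains, b.chains):
        if ca.chain_id != cb.chain_id or len(ca) != len(cb):
            return False
        for ra, rb in zip(ca.residues, cb.residues):
            if (ra.seq_index, ra.name) != (rb.seq_index, rb.name):
                return False
            if abs(ra.plddt - rb.plddt) > plddt_tol:
                return False
            if len(ra.atoms) != len(rb.atoms):
                return False
            for aa, ab in zip(ra.atoms, rb.atoms):
                if aa.name != ab.name or aa.element.upper() != ab.element.upper():
                    return False
                if (
                    abs(aa.x - ab.x) > coord_tol
                    or abs(aa.y - ab.y) > coord_tol
                    or abs(aa.z - ab.z) > coord_tol
                ):
                    return False
    return True


# --------------------------------------------------------------------------
# PAE matrices

def _pae_from_obj(obj: object, dialect: str) -> np.ndarray | None:
    """Pull the PAE matrix out of one of the two supported JSON layouts.

    colabfold: ``[{"predicted_aligned_error": [[...]], ...}]`` (or the bare
    dict); af3: ``{"pae": [[...]], "token_chain_ids": [...], ...}``.
    """
    if isinstance(obj, list) and obj and isinstance(obj[0], dict):
        obj = obj[0]
    if not isinstance(obj, dict):
        return None
    if dialect in ("colabfold", "auto") and "predicted_aligned_error" in obj:
        return np.asarray(obj["predicted_aligned_error"], dtype=float)
    if dialect in ("af3", "auto") and "pae" in obj:
        return np.asarray(obj["pae"], dtype=float)
    return None


def read_pae(
    path: str | Path,
    dialect: str = "auto",
    model: StructureModel | None = None,
) -> PAEMatrix:
    """Read a PAE JSON file (ColabFold or AF3-server dialect).

    When ``model`` is given, chain boundaries in concatenated-residue index
    space are attached and the matrix dimension is checked against the
    model's residue count.
    """
    if dialect not in ("colabfold", "af3", "auto"):
        raise ValueError(f"unknown PAE dialect {dialect!r}")
    with open(path) as fh:
        obj = json.load(fh)
    values = _pae_from_obj(obj, dialect)
    if values is None:
        raise StructureFormatError(f"{path}: no PAE matrix found ({dialect} dialect)")
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise StructureFormatError(
            f"{path}: PAE matrix not square (shape {values.shape})"
        )
    boundaries: dict[str, tuple[int, int]] = {}
    if model is not None:
        if model.n_residues != values.shape[0]:
            raise StructureFormatError(
                f"{path}: PAE dimension {values.shape[0]} != model residue "
                f"count {model.n_residues}"
            )
        start = 0
        for chain in model.chains:
            boundaries[chain.chain_id] = (start, start + len(chain))
            start += len(chain)
    return PAEMatrix(values=values, chain_boundaries=boundaries)


def write_pae(
    matrix: np.ndarray | PAEMatrix,
    path: str | Path,
    dialect: str = "colabfold",
) -> None:
    """Write a PAE matrix in either supported JSON dialect (generator/O tests)."""
    values = matrix.values if isinstance(matrix, PAEMatrix) else np.asarray(matrix)
    listed = [[float(v) for v in row] for row in values]
    if dialect == "colabfold":
        obj: object = [
            {
                "predicted_aligned_error": listed,
                "max_predicted_aligned_error": float(np.max(values, initial=0.0)),
            }
        ]
    elif dialect == "af3":
        obj = {"pae": listed}
    else:
        raise ValueError(f"unknown PAE dialect {dialect!r}")
    with open(path, "w") as fh:
        json.dump(obj, fh)
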