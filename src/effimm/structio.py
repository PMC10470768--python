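"""Macromolecular structure parsing and light-weight coordinate containers.

Structures are read from PDB or mmCIF via :mod:`gemmi` into a small
hierarchical model (chains -> residues -> heavy atoms) that carries exactly
what the downstream geometry needs: coordinates, element-based van der Waals
radii and author residue numbering (including insertion codes).  Only the
first model is kept; hydrogens and waters are dropped, HETATM groups are
excluded unless requested, and alternate locations are resolved to the
highest-occupancy conformer (ties broken alphabetically by altloc id).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Set, Tuple

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "Residue",
    "StructureModel",
    "DomainPartition",
    "ActiveSiteSpec",
    "VDW_RADII",
    "DEFAULT_VDW_RADIUS",
    "read_structure",
    "write_pdb",
    "extract_sequence",
    "write_fasta",
]

# Bondi-style element radii (Angstrom); anything unlisted falls back to carbon.
VDW_RADII: Dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}
DEFAULT_VDW_RADIUS = 1.70

THREE_TO_ONE: Dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

ResidueKey = Tuple[str, int, str]  # (chain_id, res_seq, icode)

_WATER_NAMES = {"HOH", "WAT", "DOD"}


class StructureParseError(ValueError):
    """Raised when a coordinate file cannot be parsed."""


class ElementError(ValueError):
    """Raised when an atom's element cannot be resolved to a radius."""


@dataclasses.dataclass
class AtomRecord:
    serial: int
    name: str
    element: str
    altloc: str
    chain_id: str
    res_seq: int
    icode: str
    res_name: str
    xyz: np.ndarray
    occupancy: float = 1.0
    vdw_radius: float = DEFAULT_VDW_RADIUS

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")


@dataclasses.dataclass
class Residue:
    chain_id: str
    res_seq: int
    icode: str
    res_name: str
    atoms: List[AtomRecord] = dataclasses.field(default_factory=list)

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.res_seq, self.icode)

    def atom(self, name: str) -> Optional[AtomRecord]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


class StructureModel:
    """Ordered chains of ordered residues of heavy atoms.

    Residue identity is the triple ``(chain_id, res_seq, icode)``; atom names
    are unique within a residue after altloc resolution.
    """

    def __init__(self, id: str, source_format: str = "pdb") -> None:
        self.id = id
        self.source_format = source_format
        self.chains: Dict[str, List[Residue]] = {}
        self._index: Dict[ResidueKey, Residue] = {}

    # -- construction -----------------------------------------------------
    def add_residue(self, residue: Residue) -> None:
        if residue.key in self._index:
            raise ValueError(f"duplicate residue {residue.key}")
        self.chains.setdefault(residue.chain_id, []).append(residue)
        self._index[residue.key] = residue

    # -- access ------------------------------------------------------------
    def residues(self, chain_ids: Optional[Iterable[str]] = None) -> Iterator[Residue]:
        ids = list(chain_ids) if chain_ids is not None else list(self.chains)
        for cid in ids:
            if cid not in self.chains:
                raise KeyError(f"chain {cid!r} not in structure {self.id!r}")
            yield from self.chains[cid]

    def atoms(self, chain_ids: Optional[Iterable[str]] = None) -> Iterator[AtomRecord]:
        for res in self.residues(chain_ids):
            yield from res.atoms

    def residue(self, key: ResidueKey) -> Residue:
        return self._index[key]

    def has_residue(self, key: ResidueKey) -> bool:
        return key in self._index

    def residue_keys(self, chain_ids: Optional[Iterable[str]] = None) -> List[ResidueKey]:
        return [r.key for r in self.residues(chain_ids)]

    @property
    def n_atoms(self) -> int:
        return sum(1 for _ in self.atoms())

    def coords(self, chain_ids: Optional[Iterable[str]] = None) -> np.ndarray:
        pts = [a.xyz for a in self.atoms(chain_ids)]
        return np.asarray(pts, dtype=float).reshape(-1, 3)

    def ca_coords(self, chain_id: str) -> np.ndarray:
        pts = []
        for res in self.chains[chain_id]:
            ca = res.atom("CA")
            if ca is not None:
                pts.append(ca.xyz)
        return np.asarray(pts, dtype=float).reshape(-1, 3)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Return a rigidly transformed copy (x -> R x + t)."""
        out = StructureModel(self.id, self.source_format)
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        for res in self.residues():
            new = Residue(res.chain_id, res.res_seq, res.icode, res.res_name)
            for a in res.atoms:
                new.atoms.append(dataclasses.replace(a, xyz=R @ a.xyz + t))
            out.add_residue(new)
        return out

    def subset(self, chain_ids: Iterable[str], new_id: Optional[str] = None) -> "StructureModel":
        out = StructureModel(new_id or self.id, self.source_format)
        for res in self.residues(chain_ids):
            new = Residue(res.chain_id, res.res_seq, res.icode, res.res_name)
            new.atoms = [dataclasses.replace(a) for a in res.atoms]
            out.add_residue(new)
        return out


@dataclasses.dataclass
class DomainPartition:
    """Disjoint rigid-body segments, e.g. the two subdomains of a split toxin fold."""

    name: str
    segments: Dict[str, Set[ResidueKey]]

    def __post_init__(self) -> None:
        seen: Set[ResidueKey] = set()
        for label, keys in self.segments.items():
            overlap = seen & set(keys)
            if overlap:
                raise ValueError(f"partition {self.name!r}: body {label!r} overlaps others at {sorted(overlap)[:3]}")
            seen |= set(keys)

    def validate_against(self, structure: StructureModel) -> None:
        for label, keys in self.segments.items():
            missing = [k for k in keys if not structure.has_residue(k)]
            if missing:
                raise ValueError(
                    f"partition {self.name!r}: body {label!r} references absent residues {missing[:3]}"
                )


@dataclasses.dataclass
class ActiveSiteSpec:
    """Residues forming the catalytic site (e.g. the HxxD motif His/Asp pair)."""

    residues: Set[Tuple[str, int]]
    motif_label: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("active site must name at least one residue")

    def keys_in(self, structure: StructureModel) -> List[ResidueKey]:
        keys = []
        for res in structure.residues():
            if (res.chain_id, res.res_seq) in self.residues:
                keys.append(res.key)
        if not keys:
            raise ValueError(f"no active-site residues {sorted(self.residues)} found in {structure.id!r}")
        return keys


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def element_radius(element: str, atom_name: str = "") -> float:
    """Van der Waals radius for an element symbol, inferring from the atom name if empty."""
    el = element.strip().upper()
    if not el:
        # PDB convention: first letter of a left-justified atom name
        guess = atom_name.strip().lstrip("0123456789")[:1].upper()
        if not guess:
            raise ElementError(f"cannot infer element for atom {atom_name!r}")
        el = guess
    return VDW_RADII.get(el, DEFAULT_VDW_RADIUS)


def _normalize_element(element: str, atom_name: str) -> str:
    el = element.strip().upper()
    if el:
        return el
    guess = atom_name.strip().lstrip("0123456789")[:1].upper()
    if not guess:
        raise ElementError(f"cannot infer element for atom {atom_name!r}")
    return guess


def read_structure(
    path: str | Path,
    format: str = "auto",
    include_hetatm: bool = False,
) -> StructureModel:
    """Read the first model of a PDB/mmCIF file into a :class:`StructureModel`.

    Hydrogens and waters are always dropped; HETATM groups are kept only when
    ``include_hetatm`` is set.  Alternate locations are resolved to the
    conformer with the highest occupancy (alphabetical altloc on ties).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format
    if fmt == "auto":
        fmt = "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            raise ValueError(f"unknown format {format!r}")
    except (RuntimeError, ValueError) as exc:  # gemmi reports the offending line
        raise StructureParseError(f"{path}: {exc}") from exc

    if len(st) == 0:
        raise StructureParseError(f"{path}: no models")
    model = st[0]

    out = StructureModel(st.name or path.stem, source_format=fmt)
    serial = 0
    for chain in model:
        for res in chain:
            if res.name in _WATER_NAMES:
                continue
            het = res.het_flag == "H"
            if het and not include_hetatm:
                continue
            icode = res.seqid.icode.strip()
            residue = Residue(chain.name, res.seqid.num, icode, res.name)
            # altloc resolution: best occupancy per atom name
            best: Dict[str, gemmi.Atom] = {}
            for atom in res:
                if atom.element.is_hydrogen:
                    continue
                prev = best.get(atom.name)
                if prev is None or (atom.occ, -ord(atom.altloc or "~")) > (prev.occ, -ord(prev.altloc or "~")):
                    best[atom.name] = atom
            for name in best:
                atom = best[name]
                serial += 1
                el = _normalize_element(atom.element.name if atom.element else "", name)
                residue.atoms.append(
                    AtomRecord(
                        serial=serial,
                        name=name,
                        element=el,
                        altloc=(atom.altloc or "").strip(),
                        chain_id=chain.name,
                        res_seq=res.seqid.num,
                        icode=icode,
                        res_name=res.name,
                        xyz=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        occupancy=min(max(atom.occ, 0.0), 1.0),
                        vdw_radius=element_radius(el, name),
                    )
                )
            if residue.atoms:
                if out.has_residue(residue.key):
                    # second copy of a residue id in the same chain (rare
                    # microheterogeneity) -- keep the first occurrence
                    continue
                out.add_residue(residue)
    if out.n_atoms == 0:
        raise StructureParseError(f"{path}: no heavy atoms after filtering")
    return out


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def write_pdb(structure: StructureModel, path: str | Path) -> None:
    """Write a minimal PDB file (ATOM records only, one model)."""
    lines = []
    serial = 0
    for res in structure.residues():
        for a in res.atoms:
            serial += 1
            name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
            lines.append(
                f"ATOM  {serial:5d} {name:<4s}{'':1s}{a.res_name:>3s} {a.chain_id[:1]}"
                f"{a.res_seq:4d}{a.icode or ' ':1s}   "
                f"{a.xyz[0]:8.3f}{a.xyz[1]:8.3f}{a.xyz[2]:8.3f}"
                f"{a.occupancy:6.2f}{0.0:6.2f}          {a.element:>2s}\n"
            )
    lines.append("END\n")
    Path(path).write_text("".join(lines))


def extract_sequence(
    structure: StructureModel,
    chain_id: str,
    selenomethionine_as_met: bool = False,
) -> str:
    """One-letter sequence of a chain in author order; nonstandard residues map to X."""
    if chain_id not in structure.chains:
        raise KeyError(f"chain {chain_id!r} not in structure {structure.id!r}")
    table = dict(THREE_TO_ONE)
    if selenomethionine_as_met:
        table["MSE"] = "M"
    return "".join(table.get(res.res_name, "X") for res in structure.chains[chain_id])


def write_fasta(sequences: Dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
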