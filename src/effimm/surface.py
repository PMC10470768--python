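"""Solvent-accessible surface area and atomic-solvation energetics.

SASA is computed with the Shrake-Rupley numerical method: each atom is
covered with a deterministic golden-spiral point set on a sphere of radius
``r_vdw + probe``, and a point counts as exposed unless it falls strictly
inside a neighbouring atom's probe-expanded sphere.  Per-atom area is then
``exposed_fraction * 4 pi (r + probe)^2``.

Solvation energy follows the classic atomic-solvation-parameter model,
``E = sum sigma(element) * ASA(atom)``, with an Eisenberg-style default
parameter table (hydrophobic atoms gain energy on burial).  The interface
statistic reported for effector/immunity complexes is the solvation-energy
*gain* each body realises on complex formation, normalised as a percentage
of that body's monomer solvation energy -- a ratio, so the absolute sigma
scale largely cancels.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .structio import AtomRecord, ResidueKey, StructureModel

__all__ = [
    "SasaParams",
    "SasaResult",
    "SolvationParams",
    "InterfaceEnergetics",
    "EISENBERG_SIGMA",
    "golden_spiral_points",
    "compute_sasa",
    "solvation_energy",
    "interface_solvation_gain",
]


@dataclasses.dataclass(frozen=True)
class SasaParams:
    probe_radius: float = 1.4
    n_points: int = 960

    def __post_init__(self) -> None:
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be positive")
        if self.n_points < 100:
            raise ValueError("n_points must be at least 100")


@dataclasses.dataclass
class SasaResult:
    per_atom: Dict[int, float]          # atom serial -> area (A^2)
    per_residue: Dict[ResidueKey, float]
    total: float
    params: SasaParams

    def residue_area(self, key: ResidueKey) -> float:
        return self.per_residue.get(key, 0.0)


@dataclasses.dataclass
class SolvationParams:
    """Atomic solvation parameters (energy per A^2), keyed by element symbol."""

    sigma: Dict[str, float]
    label: str = "custom"

    def value(self, element: str) -> float:
        try:
            return self.sigma[element.upper()]
        except KeyError:
            raise KeyError(
                f"no solvation parameter for element {element!r} in set {self.label!r}"
            ) from None


# Eisenberg-McLachlan-flavoured set (kcal/mol/A^2): burial of carbon and
# sulfur is favourable; polar nitrogen/oxygen slightly unfavourable.
EISENBERG_SIGMA = SolvationParams(
    sigma={"C": 0.0160, "S": 0.0210, "N": -0.0060, "O": -0.0060, "P": 0.0160, "SE": 0.0210},
    label="eisenberg",
)


@dataclasses.dataclass
class InterfaceEnergetics:
    gain_A: float
    gain_B: float
    monomer_energy_A: float
    monomer_energy_B: float
    percent_A: Optional[float]
    percent_B: Optional[float]
    buried_area_A: float
    buried_area_B: float


def golden_spiral_points(n: int) -> np.ndarray:
    """``n`` near-uniform unit-sphere points from the Fibonacci/golden spiral.

    Deterministic (no RNG), so every SASA number is bit-reproducible.
    """
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * math.pi * (3.0 - math.sqrt(5.0))
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _selected_atoms(
    structure: StructureModel, selection: Optional[Iterable[ResidueKey]]
) -> List[AtomRecord]:
    if selection is None:
        atoms = list(structure.atoms())
    else:
        keys = set(selection)
        atoms = [a for res in structure.residues() if res.key in keys for a in res.atoms]
    return atoms


def compute_sasa(
    structure: StructureModel,
    selection: Optional[Iterable[ResidueKey]] = None,
    params: SasaParams = SasaParams(),
) -> SasaResult:
    """Shrake-Rupley SASA of ``selection`` (default: whole structure).

    Occluders are restricted to the same selection, so passing one body of a
    complex yields that body's *isolated* surface in its bound conformation.
    """
    atoms = _selected_atoms(structure, selection)
    if not atoms:
        raise ValueError("empty selection")

    centers = np.array([a.xyz for a in atoms])
    radii = np.array([a.vdw_radius for a in atoms]) + params.probe_radius
    unit = golden_spiral_points(params.n_points)

    tree = cKDTree(centers)
    max_r = radii.max()
    per_atom: Dict[int, float] = {}
    per_residue: Dict[ResidueKey, float] = {}
    for i, atom in enumerate(atoms):
        Ri = radii[i]
        pts = centers[i] + Ri * unit
        neighbours = tree.query_ball_point(centers[i], Ri + max_r)
        exposed = np.ones(len(pts), dtype=bool)
        for j in neighbours:
            if j == i:
                continue
            d = np.linalg.norm(centers[j] - centers[i])
            if d >= Ri + radii[j]:
                continue
            # strict inequality: boundary points count as exposed
            d2 = np.einsum("ij,ij->i", pts - centers[j], pts - centers[j])
            exposed &= ~(d2 < radii[j] ** 2)
        area = exposed.sum() / params.n_points * 4.0 * math.pi * Ri * Ri
        per_atom[atom.serial] = area
        key = (atom.chain_id, atom.res_seq, atom.icode)
        per_residue[key] = per_residue.get(key, 0.0) + area

    return SasaResult(
        per_atom=per_atom,
        per_residue=per_residue,
        total=float(sum(per_atom.values())),
        params=params,
    )


def solvation_energy(
    structure: StructureModel,
    selection: Optional[Iterable[ResidueKey]],
    sasa: SasaResult,
    params: SolvationParams = EISENBERG_SIGMA,
) -> float:
    """``sum sigma(element) * ASA(atom)`` over the selected atoms.

    Additive over disjoint selections by construction.
    """
    atoms = _selected_atoms(structure, selection)
    total = 0.0
    for a in atoms:
        area = sasa.per_atom.get(a.serial)
        if area is None:
            raise ValueError(f"atom serial {a.serial} missing from SASA result; recompute on the same selection")
        total += params.value(a.element) * area
    return total


def interface_solvation_gain(
    complex_structure: StructureModel,
    body_a: Sequence[str],
    body_b: Sequence[str],
    sasa_params: SasaParams = SasaParams(),
    solvation_params: SolvationParams = EISENBERG_SIGMA,
) -> InterfaceEnergetics:
    """Solvation-energy gain of each body on complex formation.

    For body X: ``gain_X = E(X isolated, bound conformation) - E(X with the
    partner present as occluders)``; ``percent_X = 100 * gain_X /
    |E(X isolated)|``.  Percentages are reported as ``None`` when the monomer
    energy magnitude is below 1e-6 (undefined ratio).
    """
    set_a, set_b = set(body_a), set(body_b)
    if set_a & set_b:
        raise ValueError(f"bodies overlap on chains {sorted(set_a & set_b)}")
    keys_a = structure_keys(complex_structure, set_a)
    keys_b = structure_keys(complex_structure, set_b)

    sasa_a = compute_sasa(complex_structure, keys_a, sasa_params)
    sasa_b = compute_sasa(complex_structure, keys_b, sasa_params)
    sasa_ab = compute_sasa(complex_structure, keys_a + keys_b, sasa_params)

    e_a_iso = solvation_energy(complex_structure, keys_a, sasa_a, solvation_params)
    e_b_iso = solvation_energy(complex_structure, keys_b, sasa_b, solvation_params)
    e_a_cplx = solvation_energy(complex_structure, keys_a, sasa_ab, solvation_params)
    e_b_cplx = solvation_energy(complex_structure, keys_b, sasa_ab, solvation_params)

    gain_a = e_a_iso - e_a_cplx
    gain_b = e_b_iso - e_b_cplx
    buried_a = sum(sasa_a.per_atom.values()) - sum(
        sasa_ab.per_atom[s] for s in sasa_a.per_atom
    )
    buried_b = sum(sasa_b.per_atom.values()) - sum(
        sasa_ab.per_atom[s] for s in sasa_b.per_atom
    )

    def pct(gain: float, mono: float) -> Optional[float]:
        if abs(mono) < 1e-6:
            return None
        return 100.0 * gain / abs(mono)

    return InterfaceEnergetics(
        gain_A=gain_a,
        gain_B=gain_b,
        monomer_energy_A=e_a_iso,
        monomer_energy_B=e_b_iso,
        percent_A=pct(gain_a, e_a_iso),
        percent_B=pct(gain_b, e_b_iso),
        buried_area_A=buried_a,
        buried_area_B=buried_b,
    )


def structure_keys(structure: StructureModel, chain_ids: Set[str]) -> List[ResidueKey]:
    missing = chain_ids - set(structure.chains)
    if missing:
        raise ValueError(f"chains {sorted(missing)} absent from {structure.id!r}")
    return structure.residue_keys(sorted(chain_ids))
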