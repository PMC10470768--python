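"""Residue-level interface statistics for two-body complexes.

Covers the contact map between an effector and its immunity protein, the
per-residue surface burial on complexation, classification of residues as
buried "core" in the free effector fold, the core-contact fraction (what
share of immunity-contacting effector residues belong to the effector's own
hydrophobic core -- high values indicate the partner engages residues that
the free fold keeps buried, i.e. fold disruption rather than surface
binding), and steric occlusion of the catalytic site by the partner.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .structio import ActiveSiteSpec, ResidueKey, StructureModel
from .surface import SasaParams, compute_sasa, structure_keys

logger = logging.getLogger(__name__)

__all__ = [
    "InterfaceReport",
    "OcclusionReport",
    "MAX_ASA",
    "contact_residues",
    "core_residues",
    "core_contact_fraction",
    "active_site_occlusion",
    "map_residues",
]

# Theoretical maximum accessible areas per residue type (A^2), Tien-style
# Gly-X-Gly reference values; used to turn absolute ASA into relative ASA.
MAX_ASA: Dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}


@dataclasses.dataclass
class InterfaceReport:
    contact_pairs: Set[Tuple[ResidueKey, ResidueKey]]
    effector_contacting: Set[ResidueKey]
    per_residue_dasa: Dict[ResidueKey, float]
    core_set: Set[ResidueKey] = dataclasses.field(default_factory=set)
    core_contact_count: int = 0
    contact_count: int = 0
    core_contact_fraction: Optional[float] = None
    undefined: bool = False


@dataclasses.dataclass
class OcclusionReport:
    site_asa_free: float
    site_asa_bound: float
    occlusion_fraction: Optional[float]
    undefined: bool = False


def contact_residues(
    complex_structure: StructureModel,
    body_a: Sequence[str],
    body_b: Sequence[str],
    mode: str = "distance",
    cutoff: float = 4.5,
    dasa_threshold: float = 0.1,
    sasa_params: SasaParams = SasaParams(),
) -> InterfaceReport:
    """Interface contacts between two chain sets.

    ``distance`` mode: a residue pair is in contact iff any heavy-atom pair
    lies within ``cutoff`` (default 4.5 A).  ``dasa`` mode: a body-A residue
    is contacting iff its ASA drops by more than ``dasa_threshold`` A^2 when
    body B is added as occluder; pairs are then assigned by the distance
    criterion for reporting.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    set_a, set_b = set(body_a), set(body_b)
    if set_a & set_b:
        raise ValueError(f"bodies overlap on chains {sorted(set_a & set_b)}")
    keys_a = structure_keys(complex_structure, set_a)
    keys_b = structure_keys(complex_structure, set_b)

    atoms_a = [a for r in complex_structure.residues(sorted(set_a)) for a in r.atoms]
    atoms_b = [a for r in complex_structure.residues(sorted(set_b)) for a in r.atoms]
    pairs: Set[Tuple[ResidueKey, ResidueKey]] = set()
    if atoms_a and atoms_b:
        tree_b = cKDTree(np.array([a.xyz for a in atoms_b]))
        hits = tree_b.query_ball_point(np.array([a.xyz for a in atoms_a]), cutoff)
        for ia, js in enumerate(hits):
            ka = (atoms_a[ia].chain_id, atoms_a[ia].res_seq, atoms_a[ia].icode)
            for j in js:
                kb = (atoms_b[j].chain_id, atoms_b[j].res_seq, atoms_b[j].icode)
                pairs.add((ka, kb))

    dasa: Dict[ResidueKey, float] = {}
    if mode == "dasa":
        sasa_a = compute_sasa(complex_structure, keys_a, sasa_params)
        sasa_ab = compute_sasa(complex_structure, keys_a + keys_b, sasa_params)
        for k in keys_a:
            delta = sasa_a.residue_area(k) - sasa_ab.residue_area(k)
            if delta > dasa_threshold:
                dasa[k] = delta
        contacting = set(dasa)
    elif mode == "distance":
        contacting = {ka for ka, _ in pairs}
    else:
        raise ValueError(f"unknown contact mode {mode!r}")

    return InterfaceReport(
        contact_pairs=pairs,
        effector_contacting=contacting,
        per_residue_dasa=dasa,
        contact_count=len(contacting),
    )


def core_residues(
    monomer: StructureModel,
    rsasa_threshold: float = 0.25,
    sasa_params: SasaParams = SasaParams(),
    chain_ids: Optional[Sequence[str]] = None,
) -> Set[ResidueKey]:
    """Residues whose relative accessibility in the monomer is below threshold.

    rSASA = ASA(residue) / max ASA of its residue type; types absent from the
    reference table fall back to the largest tabulated value (logged).
    """
    keys = monomer.residue_keys(chain_ids)
    sasa = compute_sasa(monomer, keys, sasa_params)
    fallback = max(MAX_ASA.values())
    core: Set[ResidueKey] = set()
    for key in keys:
        res = monomer.residue(key)
        ref = MAX_ASA.get(res.res_name)
        if ref is None:
            logger.warning("residue type %s not in reference-area table; using %.0f", res.res_name, fallback)
            ref = fallback
        if sasa.residue_area(key) / ref < rsasa_threshold:
            core.add(key)
    return core


def map_residues(
    source: StructureModel,
    source_chain: str,
    target: StructureModel,
    target_chain: str,
    mode: str = "alignment",
) -> Dict[ResidueKey, ResidueKey]:
    """Pair residues of one chain with another, by number or by alignment.

    ``number`` matches on ``res_seq``/``icode``; ``alignment`` tolerates
    numbering offsets by globally aligning the two sequences.
    """
    src = [r for r in source.chains[source_chain]]
    tgt = [r for r in target.chains[target_chain]]
    mapping: Dict[ResidueKey, ResidueKey] = {}
    if mode == "number":
        tgt_by_num = {(r.res_seq, r.icode): r for r in tgt}
        for r in src:
            other = tgt_by_num.get((r.res_seq, r.icode))
            if other is not None:
                mapping[r.key] = other.key
        return mapping
    if mode != "alignment":
        raise ValueError(f"unknown pairing mode {mode!r}")
    from .conformation import align_residue_indices  # local import to avoid cycle

    from .structio import extract_sequence

    seq_s = extract_sequence(source, source_chain)
    seq_t = extract_sequence(target, target_chain)
    for i, j in align_residue_indices(seq_s, seq_t):
        mapping[src[i].key] = tgt[j].key
    return mapping


def core_contact_fraction(
    effector_free: StructureModel,
    complexes: Sequence[Tuple[StructureModel, Sequence[str], Sequence[str]]],
    free_chain: Optional[str] = None,
    pairing_mode: str = "alignment",
    contact_mode: str = "distance",
    cutoff: float = 4.5,
    rsasa_threshold: float = 0.25,
    sasa_params: SasaParams = SasaParams(),
) -> InterfaceReport:
    """Fraction of immunity-contacting effector residues that are core in the free fold.

    ``complexes`` is a list of ``(structure, effector_chains, immunity_chains)``;
    counts are pooled over all complexes before dividing (so two complexes with
    10/20 and 7/23 core-contacting residues give 17/43).  Contacts are computed
    on each complex, core residues on the free effector structure, and the two
    are linked through a residue mapping (alignment-based by default).
    """
    free_chain = free_chain or next(iter(effector_free.chains))
    core = core_residues(effector_free, rsasa_threshold, sasa_params, [free_chain])

    pooled_contacts = 0
    pooled_core = 0
    all_pairs: Set[Tuple[ResidueKey, ResidueKey]] = set()
    contacting_all: Set[ResidueKey] = set()
    dasa_all: Dict[ResidueKey, float] = {}
    for cplx, eff_chains, imm_chains in complexes:
        rep = contact_residues(cplx, eff_chains, imm_chains, contact_mode, cutoff, sasa_params=sasa_params)
        all_pairs |= rep.contact_pairs
        contacting_all |= rep.effector_contacting
        dasa_all.update(rep.per_residue_dasa)
        for eff_chain in eff_chains:
            mapping = map_residues(cplx, eff_chain, effector_free, free_chain, pairing_mode)
            chain_contacts = [k for k in rep.effector_contacting if k[0] == eff_chain]
            for k in chain_contacts:
                mapped = mapping.get(k)
                if mapped is None:
                    continue
                pooled_contacts += 1
                if mapped in core:
                    pooled_core += 1

    if pooled_contacts == 0:
        return InterfaceReport(
            contact_pairs=all_pairs,
            effector_contacting=contacting_all,
            per_residue_dasa=dasa_all,
            core_set=core,
            core_contact_count=0,
            contact_count=0,
            core_contact_fraction=None,
            undefined=True,
        )
    return InterfaceReport(
        contact_pairs=all_pairs,
        effector_contacting=contacting_all,
        per_residue_dasa=dasa_all,
        core_set=core,
        core_contact_count=pooled_core,
        contact_count=pooled_contacts,
        core_contact_fraction=pooled_core / pooled_contacts,
    )


def active_site_occlusion(
    complex_structure: StructureModel,
    effector_chains: Sequence[str],
    immunity_chains: Sequence[str],
    site: ActiveSiteSpec,
    sasa_params: SasaParams = SasaParams(),
) -> OcclusionReport:
    """How much of the active site's surface the immunity protein covers.

    Both terms use the *bound* effector conformation: site ASA with only the
    effector present, versus with the immunity chains added as occluders.
    """
    keys_eff = structure_keys(complex_structure, set(effector_chains))
    keys_imm = structure_keys(complex_structure, set(immunity_chains))
    site_keys = [k for k in site.keys_in(complex_structure) if k[0] in set(effector_chains)]
    if not site_keys:
        raise ValueError("active-site residues not found in effector chains")

    sasa_free = compute_sasa(complex_structure, keys_eff, sasa_params)
    sasa_bound = compute_sasa(complex_structure, keys_eff + keys_imm, sasa_params)
    free = sum(sasa_free.residue_area(k) for k in site_keys)
    bound = sum(sasa_bound.residue_area(k) for k in site_keys)
    if free <= 0:
        return OcclusionReport(site_asa_free=free, site_asa_bound=bound, occlusion_fraction=None, undefined=True)
    frac = (free - bound) / free
    return OcclusionReport(
        site_asa_free=free,
        site_asa_bound=bound,
        occlusion_fraction=min(max(frac, 0.0), 1.0),
    )
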