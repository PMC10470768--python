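"""Superposition, RMSD and rigid-body hinge/rotation decomposition.

The central use case is the immunity-induced conformational shift of a
toxin domain: the fold splits into two subdomains, one is held fixed and
the other undergoes a large rigid rotation.  Superposing the free and bound
states on the fixed subdomain and fitting a Kabsch rotation to the moving
subdomain yields an axis-angle description of the motion; the hinge angle
is measured at the subdomain boundary as the angle subtended by the moving
body's centroid before and after the shift.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .structio import DomainPartition, ResidueKey, StructureModel, extract_sequence

__all__ = [
    "SuperpositionResult",
    "RotationDecomposition",
    "SplitResult",
    "kabsch",
    "rotation_angle_axis",
    "align_residue_indices",
    "sequence_identity",
    "superpose",
    "subdomain_rotation",
    "detect_rigid_split",
]


class InsufficientPairsError(ValueError):
    """Fewer than three paired atoms: the rigid fit is underdetermined."""


@dataclasses.dataclass
class SuperpositionResult:
    rotation: np.ndarray          # 3x3, proper orthonormal
    translation: np.ndarray       # 3-vector; mobile -> reference is x -> R x + t
    rmsd: float
    n_pairs: int
    pairing: List[Tuple[ResidueKey, ResidueKey]]


@dataclasses.dataclass
class RotationDecomposition:
    total_angle: float            # degrees in [0, 180]
    axis: np.ndarray              # unit 3-vector
    hinge_angle: float            # degrees
    fixed_body: str
    moving_body: str
    fixed_rmsd: float
    moving_rmsd: float


@dataclasses.dataclass
class SplitResult:
    is_split: bool
    boundary: Optional[int]       # index into the paired-residue list
    boundary_residue: Optional[ResidueKey]
    body_rmsds: Tuple[float, ...]
    single_rmsd: float
    inter_body_angle: float       # degrees


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> Tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition (reflection-corrected).

    Returns ``(R, t, rmsd)`` with ``R @ x + t`` mapping mobile onto reference.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must both be (n, 3)")
    if len(P) < 3:
        raise InsufficientPairsError(f"need at least 3 paired atoms, got {len(P)}")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    diff = (P @ R.T + t) - Q
    rmsd = float(np.sqrt(np.mean(np.einsum("ij,ij->i", diff, diff))))
    return R, t, rmsd


def rotation_angle_axis(R: np.ndarray) -> Tuple[float, np.ndarray]:
    """Axis-angle of a proper rotation; angle in degrees in [0, 180]."""
    tr = float(np.trace(R))
    angle = math.degrees(math.acos(min(1.0, max(-1.0, (tr - 1.0) / 2.0))))
    # antisymmetric part gives the axis away from 0/180 degrees
    v = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    if np.linalg.norm(v) > 1e-8:
        axis = v / np.linalg.norm(v)
    else:
        # near 180 deg: axis is the eigenvector of R for eigenvalue +1
        w, vec = np.linalg.eigh((R + R.T) / 2.0)
        axis = vec[:, np.argmax(w)]
        axis = axis / np.linalg.norm(axis)
    return angle, axis


def sequence_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity over aligned (non-gap) columns of a global alignment."""
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aligner.mode = "global"
    a = seq_a.replace("X", "A")
    b = seq_b.replace("X", "A")
    aln = aligner.align(a, b)[0]
    matches = aligned = 0
    for (sa, ea), (sb, eb) in zip(aln.aligned[0], aln.aligned[1]):
        for i, j in zip(range(sa, ea), range(sb, eb)):
            aligned += 1
            matches += seq_a[i] == seq_b[j]
    return 100.0 * matches / aligned if aligned else 0.0


def align_residue_indices(seq_a: str, seq_b: str) -> List[Tuple[int, int]]:
    """Index pairs of aligned (non-gap) columns from a global alignment.

    BLOSUM62 scoring, gap open 10 / extend 0.5; columns aligning an X are
    dropped, as are mismatched columns with a negative substitution score.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aligner.mode = "global"
    # X is not scored by BLOSUM62's alphabet handling of lowercase; mask to A
    matrix = aligner.substitution_matrix
    a = seq_a.replace("X", "A")
    b = seq_b.replace("X", "A")
    aln = aligner.align(a, b)[0]
    pairs: List[Tuple[int, int]] = []
    for (sa, ea), (sb, eb) in zip(aln.aligned[0], aln.aligned[1]):
        for i, j in zip(range(sa, ea), range(sb, eb)):
            if seq_a[i] == "X" or seq_b[j] == "X":
                continue
            if seq_a[i] != seq_b[j] and matrix[a[i], b[j]] < 0:
                continue
            pairs.append((i, j))
    return pairs


def _pair_ca(
    mobile: StructureModel,
    reference: StructureModel,
    mobile_chain: str,
    reference_chain: str,
    pairing_mode: str,
) -> Tuple[np.ndarray, np.ndarray, List[Tuple[ResidueKey, ResidueKey]]]:
    res_m = [r for r in mobile.chains[mobile_chain] if r.atom("CA") is not None]
    res_r = [r for r in reference.chains[reference_chain] if r.atom("CA") is not None]
    pairs: List[Tuple[ResidueKey, ResidueKey]] = []
    if pairing_mode == "number":
        by_num = {(r.res_seq, r.icode): r for r in res_r}
        for r in res_m:
            other = by_num.get((r.res_seq, r.icode))
            if other is not None:
                pairs.append((r.key, other.key))
    elif pairing_mode == "alignment":
        seq_m = _seq_of(res_m)
        seq_r = _seq_of(res_r)
        for i, j in align_residue_indices(seq_m, seq_r):
            pairs.append((res_m[i].key, res_r[j].key))
    else:
        raise ValueError(f"unknown pairing mode {pairing_mode!r}")
    xm = np.array([mobile.residue(a).atom("CA").xyz for a, _ in pairs]).reshape(-1, 3)
    xr = np.array([reference.residue(b).atom("CA").xyz for _, b in pairs]).reshape(-1, 3)
    return xm, xr, pairs


def _seq_of(residues) -> str:
    from .structio import THREE_TO_ONE

    return "".join(THREE_TO_ONE.get(r.res_name, "X") for r in residues)


def superpose(
    mobile: StructureModel,
    reference: StructureModel,
    mobile_chain: Optional[str] = None,
    reference_chain: Optional[str] = None,
    pairing_mode: str = "number",
) -> SuperpositionResult:
    """Optimal C-alpha superposition of one chain onto another."""
    mobile_chain = mobile_chain or next(iter(mobile.chains))
    reference_chain = reference_chain or next(iter(reference.chains))
    xm, xr, pairs = _pair_ca(mobile, reference, mobile_chain, reference_chain, pairing_mode)
    if len(pairs) < 3:
        raise InsufficientPairsError(f"only {len(pairs)} residue pairs")
    R, t, rmsd = kabsch(xm, xr)
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_pairs=len(pairs), pairing=pairs)


def subdomain_rotation(
    state_free: StructureModel,
    state_bound: StructureModel,
    partition: DomainPartition,
    pairing_mode: str = "number",
    fixed_body: Optional[str] = None,
) -> RotationDecomposition:
    """Axis-angle and hinge quantification of a two-subdomain motion.

    Both states are first superposed on the fixed body; the Kabsch rotation
    that then maps the moving body free -> bound gives the total rotation
    angle and axis.  The hinge angle is subtended at the boundary C-alpha
    centroid by the moving-body centroid in the free versus bound state.
    """
    labels = list(partition.segments)
    if len(labels) != 2:
        raise ValueError("partition must have exactly two bodies")
    if fixed_body is None:
        fixed_body = labels[0]
    moving_body = labels[1] if fixed_body == labels[0] else labels[0]
    partition.validate_against(state_free)
    partition.validate_against(state_bound)

    def body_ca(structure: StructureModel, label: str) -> np.ndarray:
        pts = []
        for key in sorted(partition.segments[label]):
            ca = structure.residue(key).atom("CA")
            if ca is not None:
                pts.append(ca.xyz)
        return np.asarray(pts, dtype=float).reshape(-1, 3)

    fixed_free = body_ca(state_free, fixed_body)
    fixed_bound = body_ca(state_bound, fixed_body)
    moving_free = body_ca(state_free, moving_body)
    moving_bound = body_ca(state_bound, moving_body)
    if len(moving_free) < 3 or len(fixed_free) < 3:
        raise InsufficientPairsError("each body needs at least 3 residues with CA")
    if len(fixed_free) != len(fixed_bound) or len(moving_free) != len(moving_bound):
        raise ValueError("bodies must contain the same residues in both states")

    # put the bound state into the free state's frame via the fixed body
    R0, t0, fixed_rmsd = kabsch(fixed_bound, fixed_free)
    moving_bound_aligned = moving_bound @ R0.T + t0

    R1, _, moving_rmsd = kabsch(moving_free, moving_bound_aligned)
    total_angle, axis = rotation_angle_axis(R1)

    # hinge vertex: centroid of boundary CAs (residues of either body whose
    # sequence neighbours lie in the other body), falling back to the
    # fixed-body centroid when the bodies are not sequence-contiguous
    hinge_vertex = _boundary_centroid(state_free, partition)
    if hinge_vertex is None:
        hinge_vertex = fixed_free.mean(axis=0)
    v_free = moving_free.mean(axis=0) - hinge_vertex
    v_bound = moving_bound_aligned.mean(axis=0) - hinge_vertex
    cosang = float(np.dot(v_free, v_bound) / (np.linalg.norm(v_free) * np.linalg.norm(v_bound)))
    hinge_angle = math.degrees(math.acos(min(1.0, max(-1.0, cosang))))

    return RotationDecomposition(
        total_angle=total_angle,
        axis=axis,
        hinge_angle=hinge_angle,
        fixed_body=fixed_body,
        moving_body=moving_body,
        fixed_rmsd=fixed_rmsd,
        moving_rmsd=moving_rmsd,
    )


def _boundary_centroid(structure: StructureModel, partition: DomainPartition) -> Optional[np.ndarray]:
    labels = list(partition.segments)
    by_key: Dict[ResidueKey, str] = {}
    for label in labels:
        for key in partition.segments[label]:
            by_key[key] = label
    pts = []
    for chain_id, residues in structure.chains.items():
        for a, b in zip(residues, residues[1:]):
            la, lb = by_key.get(a.key), by_key.get(b.key)
            if la is not None and lb is not None and la != lb:
                for res in (a, b):
                    ca = res.atom("CA")
                    if ca is not None:
                        pts.append(ca.xyz)
    if not pts:
        return None
    return np.mean(np.asarray(pts, dtype=float), axis=0)


def detect_rigid_split(
    state_free: StructureModel,
    state_bound: StructureModel,
    chain: Optional[str] = None,
    pairing_mode: str = "number",
    min_body: int = 15,
    rmsd_tol: float = 2.0,
    improvement_factor: float = 2.0,
) -> SplitResult:
    """Scan for a single boundary splitting a chain into two rigid bodies.

    For every candidate boundary the two segments are fitted rigidly
    (independent Kabsch superpositions) and scored by the pooled per-body
    RMSD.  The chain is declared split when the best two-body fit improves
    on the single-body RMSD by at least ``improvement_factor`` and each body
    fits within ``rmsd_tol``.
    """
    chain_free = chain or next(iter(state_free.chains))
    chain_bound = chain or next(iter(state_bound.chains))
    xm, xr, pairs = _pair_ca(state_free, state_bound, chain_free, chain_bound, pairing_mode)
    n = len(pairs)
    if n < 2 * min_body:
        raise InsufficientPairsError(f"{n} paired residues < 2 * min_body ({min_body})")

    _, _, single_rmsd = kabsch(xm, xr)

    best: Optional[Tuple[float, int, float, float, float]] = None
    for b in range(min_body, n - min_body + 1):
        R1, _, r1 = kabsch(xm[:b], xr[:b])
        R2, _, r2 = kabsch(xm[b:], xr[b:])
        pooled = math.sqrt((b * r1 * r1 + (n - b) * r2 * r2) / n)
        if best is None or pooled < best[0]:
            angle, _ = rotation_angle_axis(R2 @ R1.T)
            best = (pooled, b, r1, r2, angle)

    pooled, b, r1, r2, angle = best
    # single-body fit already at coordinate precision: nothing to split
    improves = single_rmsd > 1e-3 and pooled * improvement_factor <= single_rmsd
    is_split = bool(improves and r1 <= rmsd_tol and r2 <= rmsd_tol)
    return SplitResult(
        is_split=is_split,
        boundary=b if is_split else None,
        boundary_residue=pairs[b][0][0:3] if is_split else None,
        body_rmsds=(r1, r2),
        single_rmsd=single_rmsd,
        inter_body_angle=angle,
    )
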