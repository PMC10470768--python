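"""Deterministic generators for every fixture the test surface needs.

Structures are idealised poly-alanine constructs (helices, two-domain
pairs with a planted hinge rotation, atom cages capping a surface patch,
toy effector/immunity complexes); tabular fixtures are simulated
metagenomic hit tables with planted group fold-changes, and binding / melt
curves with controlled noise.  Every generator takes an explicit seed, uses
its own ``numpy.random.Generator`` (no global RNG state), and returns its
ground truth alongside the data.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .structio import (
    ActiveSiteSpec,
    AtomRecord,
    DomainPartition,
    Residue,
    ResidueKey,
    StructureModel,
    element_radius,
)

__all__ = [
    "make_helix",
    "make_cage",
    "merge_structures",
    "make_core_contact_toy",
    "make_two_domain_pair",
    "make_toy_complex",
    "HitTable",
    "STRUCTURAL_FAMILIES",
    "simulate_hit_tables",
    "simulate_longitudinal_cohort",
    "simulate_binding_curve",
    "simulate_melt_curve",
]

# heavy-atom offsets (A) of an alanine residue in a local frame where the
# helix axis is z and the CA sits at the origin
_ALA_OFFSETS = {
    "N": np.array([-1.20, -0.60, -0.60]),
    "CA": np.array([0.00, 0.00, 0.00]),
    "C": np.array([1.30, -0.40, 0.60]),
    "O": np.array([1.90, -1.45, 0.55]),
    "CB": np.array([0.20, 1.45, -0.45]),
}
_HELIX_RISE = 1.5        # A per residue
_HELIX_TWIST = 100.0     # degrees per residue
_HELIX_RADIUS = 2.3      # CA radius giving ~3.8 A CA-CA distance


def _rot_z(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def rotation_about_axis(axis: Sequence[float], deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about a (normalised) axis."""
    k = np.asarray(axis, dtype=float)
    k = k / np.linalg.norm(k)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    th = math.radians(deg)
    return np.eye(3) + math.sin(th) * K + (1 - math.cos(th)) * (K @ K)


def make_helix(
    n_res: int,
    chain_id: str = "A",
    start_res_seq: int = 1,
    structure_id: str = "helix",
) -> StructureModel:
    """Ideal poly-alanine alpha-helix along z (rise 1.5 A, twist 100 deg).

    Five heavy atoms per residue (N, CA, C, O, CB) at canonical offsets.
    """
    if n_res < 4:
        raise ValueError("a helix needs at least 4 residues")
    st = StructureModel(structure_id)
    serial = 0
    for i in range(n_res):
        R = _rot_z(_HELIX_TWIST * i)
        ca = R @ np.array([_HELIX_RADIUS, 0.0, 0.0]) + np.array([0.0, 0.0, _HELIX_RISE * i])
        res = Residue(chain_id, start_res_seq + i, "", "ALA")
        for name in ("N", "CA", "C", "O", "CB"):
            serial += 1
            xyz = ca + R @ _ALA_OFFSETS[name]
            el = name[0]
            res.atoms.append(
                AtomRecord(serial, name, el, "", chain_id, start_res_seq + i, "", "ALA",
                           xyz, 1.0, element_radius(el))
            )
        st.add_residue(res)
    return st


def make_cage(
    center: Sequence[float],
    radius: float = 8.0,
    n_atoms: int = 200,
    chain_id: str = "B",
    start_res_seq: int = 1,
    solid_angle: float = 1.0,
    direction: Sequence[float] = (0.0, 0.0, 1.0),
    structure_id: str = "cage",
) -> StructureModel:
    """Shell of carbon pseudo-atoms on a sphere around ``center``.

    ``solid_angle`` in (0, 1] restricts the shell to a cap of that fractional
    solid angle opening towards ``direction`` (1.0 = full enclosing sphere).
    One single-atom GLY-like residue per atom, so residue-level statistics
    stay well defined.
    """
    from .surface import golden_spiral_points

    pts = golden_spiral_points(n_atoms)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    if solid_angle < 1.0:
        # keep points whose dot with direction is in the top fraction
        cos_min = 1.0 - 2.0 * solid_angle
        pts = pts[pts @ d > cos_min]
    st = StructureModel(structure_id)
    c = np.asarray(center, dtype=float)
    for i, p in enumerate(pts):
        res = Residue(chain_id, start_res_seq + i, "", "GLY")
        res.atoms.append(
            AtomRecord(i + 1, "CA", "C", "", chain_id, start_res_seq + i, "", "GLY",
                       c + radius * p, 1.0, element_radius("C"))
        )
        st.add_residue(res)
    return st


def merge_structures(structure_id: str, *parts: StructureModel) -> StructureModel:
    """Combine structures (disjoint chains/residues) into one model."""
    return _merge(structure_id, *parts)


def _merge(structure_id: str, *parts: StructureModel) -> StructureModel:
    out = StructureModel(structure_id)
    serial = 0
    for part in parts:
        for res in part.residues():
            new = Residue(res.chain_id, res.res_seq, res.icode, res.res_name)
            for a in res.atoms:
                serial += 1
                new.atoms.append(dataclasses.replace(a, serial=serial))
            out.add_residue(new)
    return out


@dataclasses.dataclass
class TwoDomainTruth:
    boundary_index: int          # first residue index (0-based) of the moving body
    boundary_res_seq: int
    rotation_deg: float
    axis: np.ndarray
    partition: DomainPartition


def make_two_domain_pair(
    n_per_domain: int = 40,
    rotation_deg: float = 180.0,
    axis: Sequence[float] = (1.0, 0.0, 0.0),
    hinge_translation: float = 0.0,
    jitter_sd: float = 0.0,
    seed: int = 0,
    chain_id: str = "A",
) -> Tuple[StructureModel, StructureModel, TwoDomainTruth]:
    """Free/bound pair of a 2-domain chain with a planted rigid rotation.

    The free state is a single ideal helix of ``2 * n_per_domain`` residues;
    in the bound state the second half is rigidly rotated by ``rotation_deg``
    about ``axis`` through the boundary CA (plus an optional translation
    along the axis), with optional Gaussian coordinate jitter on both states.
    """
    if not 0.0 <= rotation_deg <= 180.0:
        raise ValueError("rotation_deg must be within [0, 180]")
    n = 2 * n_per_domain
    free = make_helix(n, chain_id=chain_id, structure_id="two_domain_free")
    bound = make_helix(n, chain_id=chain_id, structure_id="two_domain_bound")

    residues = bound.chains[chain_id]
    pivot = residues[n_per_domain].atom("CA").xyz.copy()
    R = rotation_about_axis(axis, rotation_deg)
    t = np.asarray(axis, dtype=float) / np.linalg.norm(axis) * hinge_translation
    for res in residues[n_per_domain:]:
        for a in res.atoms:
            a.xyz = R @ (a.xyz - pivot) + pivot + t

    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        for st in (free, bound):
            for a in st.atoms():
                a.xyz = a.xyz + rng.normal(0.0, jitter_sd, 3)

    keys = [r.key for r in free.chains[chain_id]]
    partition = DomainPartition(
        name="planted",
        segments={"body1": set(keys[:n_per_domain]), "body2": set(keys[n_per_domain:])},
    )
    truth = TwoDomainTruth(
        boundary_index=n_per_domain,
        boundary_res_seq=free.chains[chain_id][n_per_domain].res_seq,
        rotation_deg=rotation_deg,
        axis=np.asarray(axis, dtype=float) / np.linalg.norm(axis),
        partition=partition,
    )
    return free, bound, truth


def make_toy_complex(
    occlusion: str = "none",
    conf_change: str = "none",
    seed: int = 0,
    n_res: int = 60,
    immunity_bulk: Optional[int] = None,
) -> Tuple[StructureModel, StructureModel, ActiveSiteSpec, DomainPartition]:
    """Toy effector/immunity complex with a known mechanism.

    ``occlusion``: ``none`` (immunity binds a surface patch far from the site),
    ``partial`` (loose half-cap over the site) or ``full`` (tight cap over
    the site).  ``conf_change``: ``none`` or ``split`` (effector in the
    complex has its second subdomain rotated 150 deg).  ``immunity_bulk``
    adds a helix appendage to the immunity body, lowering the fraction of
    its own surface it buries; by default a full cap carries a 100-residue
    appendage (capping-like, low fractional burial) -- pass
    ``immunity_bulk=0`` for a snug plug that buries a large share of its
    own surface (plugging-like).

    Returns ``(effector_free, complex, site, partition)``.
    """
    if occlusion not in {"none", "partial", "full"}:
        raise ValueError(f"bad occlusion {occlusion!r}")
    if immunity_bulk is None:
        immunity_bulk = 100 if occlusion == "full" else 0
    if conf_change not in {"none", "split"}:
        raise ValueError(f"bad conf_change {conf_change!r}")
    half = n_res // 2
    effector_free = make_helix(n_res, chain_id="A", structure_id="effector_free")

    if conf_change == "split":
        _, bound_eff, _ = make_two_domain_pair(
            n_per_domain=half, rotation_deg=150.0, axis=(1.0, 0.0, 0.0), seed=seed, chain_id="A"
        )
        bound_eff.id = "effector_bound"
    else:
        bound_eff = make_helix(n_res, chain_id="A", structure_id="effector_bound")

    # active site: two residues mid-chain, mimicking an HxxD motif spacing
    mid = half
    site = ActiveSiteSpec(residues={("A", mid), ("A", mid + 3)}, motif_label="HxxD")
    site_atoms = np.array([
        a.xyz for res in bound_eff.chains["A"]
        if res.res_seq in {mid, mid + 3} for a in res.atoms
    ])
    site_center = site_atoms.mean(axis=0)
    # outward direction: away from the helix axis (z)
    outward = site_center - np.array([0.0, 0.0, site_center[2]])
    outward = outward / np.linalg.norm(outward)

    if occlusion == "full":
        imm = make_cage(site_center + 2.0 * outward, radius=7.0, n_atoms=350,
                        chain_id="B", solid_angle=1.0, structure_id="immunity")
    elif occlusion == "partial":
        imm = make_cage(site_center + 4.0 * outward, radius=8.0, n_atoms=160,
                        chain_id="B", solid_angle=0.35, direction=-outward,
                        structure_id="immunity")
    else:
        # bind an exosite: a helix touching the chain terminus away from the site
        end_ca = bound_eff.chains["A"][-1].atom("CA").xyz
        imm = make_helix(20, chain_id="B", structure_id="immunity")
        shift = end_ca + np.array([6.0, 0.0, 0.0]) - imm.chains["B"][0].atom("CA").xyz
        imm = imm.transformed(np.eye(3), shift)

    if immunity_bulk > 0:
        imm_max = max(r.res_seq for r in imm.chains["B"])
        bulk = make_helix(immunity_bulk, chain_id="B", start_res_seq=imm_max + 1,
                          structure_id="bulk")
        anchor = np.array([40.0, 40.0, 0.0])
        bulk = bulk.transformed(np.eye(3), anchor)
        imm = _merge("immunity", imm, bulk)

    cplx = _merge("toy_complex", bound_eff, imm)
    keys = [r.key for r in effector_free.chains["A"]]
    partition = DomainPartition(
        name="effector_subdomains",
        segments={"body1": set(keys[:half]), "body2": set(keys[half:])},
    )
    return effector_free, cplx, site, partition


def make_core_contact_toy() -> Tuple[StructureModel, StructureModel]:
    """Fixture with a planted core-contact fraction of exactly 2/4.

    The free effector is four well-separated single-atom probe residues.
    Two of them are built so their relative accessibility falls below the
    core threshold with no occluders at all (a small-radius atom against a
    large reference area), the other two sit well above it.  The complex
    adds one immunity residue 4.0 A from each probe, making all four
    contacting; exactly the two low-rSASA probes are core.
    Returns ``(effector_free, complex)``; chains are A (effector) and B.
    """
    # (res_name, vdw_radius): TRP/0.8 -> rSASA ~ 0.21 (core);
    # GLY/1.7 -> rSASA ~ 1.16 (surface)
    spec = [("TRP", 0.8), ("TRP", 0.8), ("GLY", 1.70), ("GLY", 1.70)]
    eff = StructureModel("core_toy_free")
    for i, (res_name, radius) in enumerate(spec):
        p = np.array([0.0, 0.0, 40.0 * i])
        res = Residue("A", i + 1, "", res_name)
        res.atoms.append(AtomRecord(i + 1, "CA", "C", "", "A", i + 1, "", res_name,
                                    p, 1.0, radius))
        eff.add_residue(res)
    cplx = _merge("core_toy_complex", eff)
    for i, (res_name, _) in enumerate(spec):
        p = np.array([4.0, 0.0, 40.0 * i])
        res = Residue("B", i + 1, "", "GLY")
        res.atoms.append(AtomRecord(100 + i, "CA", "C", "", "B", i + 1, "", "GLY",
                                    p, 1.0, element_radius("C")))
        cplx.add_residue(res)
    return eff, cplx


# ---------------------------------------------------------------------------
# Metagenomic hit tables
# ---------------------------------------------------------------------------

STRUCTURAL_FAMILIES = ["TssB", "TssC", "TssD", "TssE", "TssF", "TssG", "TssI", "TssJ", "TssK"]


@dataclasses.dataclass
class HitTable:
    """Sample x gene-family hit counts with per-sample normalisation data."""

    counts: pd.DataFrame            # samples x families, non-negative ints
    read_totals: pd.Series          # reads per sample
    bact_abundance: pd.Series       # Bacteroidales relative abundance (0, 1]
    sample_meta: pd.DataFrame       # columns: group, subject, week

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative hit counts")
        if (self.read_totals <= 0).any():
            raise ValueError("read totals must be positive")


def simulate_hit_tables(
    n_samples_per_group: int = 30,
    n_families: int = 150,
    planted: Optional[Dict[str, Dict[str, float]]] = None,
    depth_range: Tuple[float, float] = (5e6, 2e7),
    abundance_range: Tuple[float, float] = (0.05, 0.6),
    lognormal_sigma: float = 0.5,
    base_rate: float = 2e-6,
    groups: Sequence[str] = ("UC", "CD", "nonIBD"),
    seed: int = 0,
) -> Tuple[HitTable, Dict[str, Dict[str, float]]]:
    """Simulated multi-group hit-count table with planted fold-changes.

    ``planted`` maps family -> {group: fold_change}; e.g.
    ``{"Ntox15": {"UC": 3.0}}`` plants a 3-fold enrichment of the toxin
    family in the ulcerative-colitis group.  Counts are Poisson draws whose
    mean is ``base_rate * depth * abundance * fold * lognormal(sigma)``
    (per-sample, per-family biological noise).  The first families are named
    after T6SS structural components plus "Ntox15" and "Tdi"; the remainder
    are generic.  Returns the table and the planted truth.
    """
    planted = planted or {}
    rng = np.random.default_rng(seed)
    named = STRUCTURAL_FAMILIES + ["Ntox15", "Tdi"]
    if n_families < len(named):
        families = named[:n_families]
    else:
        families = named + [f"fam{i:04d}" for i in range(n_families - len(named))]

    samples, meta_rows = [], []
    for g in groups:
        for i in range(n_samples_per_group):
            sid = f"{g}_{i:03d}"
            samples.append(sid)
            meta_rows.append({"sample": sid, "group": g, "subject": f"subj_{sid}", "week": 0})
    meta = pd.DataFrame(meta_rows).set_index("sample")

    depth = rng.uniform(*depth_range, size=len(samples))
    abundance = rng.uniform(*abundance_range, size=len(samples))
    # per-family baseline rates spread over ~1 order of magnitude
    fam_rate = base_rate * rng.lognormal(0.0, 0.8, size=len(families))

    counts = np.zeros((len(samples), len(families)), dtype=int)
    for j, fam in enumerate(families):
        folds = np.array([planted.get(fam, {}).get(meta.iloc[i]["group"], 1.0) for i in range(len(samples))])
        noise = rng.lognormal(0.0, lognormal_sigma, size=len(samples))
        mean = fam_rate[j] * depth * abundance * folds * noise
        counts[:, j] = rng.poisson(mean)

    table = HitTable(
        counts=pd.DataFrame(counts, index=samples, columns=families),
        read_totals=pd.Series(depth, index=samples, name="reads"),
        bact_abundance=pd.Series(abundance, index=samples, name="bacteroidales"),
        sample_meta=meta,
    )
    return table, planted


def simulate_longitudinal_cohort(
    n_subjects_per_group: int = 20,
    n_weeks: int = 10,
    drift_per_group: Optional[Dict[str, float]] = None,
    noise_sd: float = 0.5,
    baseline: float = 5.0,
    groups: Sequence[str] = ("UC", "CD", "nonIBD"),
    seed: int = 0,
) -> pd.DataFrame:
    """Per-sample normalized T6SS aggregate values over time.

    Each subject's series is ``baseline + drift * week + N(0, noise_sd)``,
    with a subject-level random intercept.  Returns a tidy frame with
    columns ``value, subject, week, group``.
    """
    drift_per_group = drift_per_group or {"UC": 0.2, "CD": 0.0, "nonIBD": 0.0}
    rng = np.random.default_rng(seed)
    rows = []
    for g in groups:
        drift = drift_per_group.get(g, 0.0)
        for s in range(n_subjects_per_group):
            intercept = baseline + rng.normal(0.0, 1.0)
            for w in range(n_weeks):
                rows.append({
                    "value": intercept + drift * w + rng.normal(0.0, noise_sd),
                    "subject": f"{g}_{s:03d}",
                    "week": w,
                    "group": g,
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Assay curves
# ---------------------------------------------------------------------------

def simulate_binding_curve(
    kd: float = 50e-9,
    rmax: float = 1.0,
    n_doses: int = 8,
    dose_span: Tuple[float, float] = (1e-9, 1e-5),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Log-spaced one-site equilibrium binding curve R = Rmax C / (Kd + C)."""
    conc = np.geomspace(*dose_span, n_doses)
    resp = rmax * conc / (kd + conc)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        resp = resp + rng.normal(0.0, noise_sd, size=conc.shape)
    return conc, resp


def simulate_melt_curve(
    tm: float = 60.0,
    steepness: float = 1.2,
    t_range: Tuple[float, float] = (25.0, 95.0),
    step: float = 0.5,
    baseline_slope: float = 0.0,
    amplitude: float = 1000.0,
    noise_frac: float = 0.0,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Sigmoidal thermal-unfolding fluorescence curve sampled at fixed steps.

    ``F(T) = amplitude / (1 + exp(-(T - tm)/steepness)) + baseline_slope*T``,
    optionally with multiplicative Gaussian noise of fractional SD
    ``noise_frac``.
    """
    temps = np.arange(t_range[0], t_range[1] + step / 2, step)
    fluor = amplitude / (1.0 + np.exp(-(temps - tm) / steepness)) + baseline_slope * temps
    if noise_frac > 0:
        rng = np.random.default_rng(seed)
        fluor = fluor * (1.0 + rng.normal(0.0, noise_frac, size=temps.shape))
    return temps, fluor
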