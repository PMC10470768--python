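"""Rule-based classification of effector-immunity neutralization mechanisms.

Four structural mechanisms are distinguished: *capping* (non-disruptive
steric occlusion of the active site), *plugging* (insertion of the immunity
protein into a pre-formed active-site cleft, burying a large share of the
immunity surface), *exosite* (binding away from the active site), and
*fold disruption* (an immunity-induced conformational shift that splits the
effector into subdomains, destroying the active site rather than covering
it).  Classification is by an ordered, fully deterministic rule cascade on
quantitative features computed by the surface / interface / conformation
modules; every comparison made is recorded in a rule trace.
"""

from __future__ import annotations

import dataclasses
from typing import List, Optional, Sequence, Tuple

from .conformation import detect_rigid_split, subdomain_rotation, superpose
from .interface import active_site_occlusion
from .structio import ActiveSiteSpec, DomainPartition, StructureModel
from .surface import EISENBERG_SIGMA, SasaParams, SolvationParams, interface_solvation_gain

__all__ = ["MechanismFeatures", "MechanismCall", "ClassifierConfig", "classify_mechanism"]


@dataclasses.dataclass
class ClassifierConfig:
    split_angle_min: float = 60.0      # degrees: subdomain rotation calling fold disruption
    conf_change_rmsd_min: float = 5.0  # A: global shift calling fold disruption
    occlusion_min: float = 0.5         # site-coverage fraction separating capping/plugging from exosite
    plugging_gain_min: float = 15.0    # % immunity solvation gain separating plugging from capping
    pairing_mode: str = "number"
    min_body: int = 15
    rmsd_tol: float = 2.0
    sasa_params: SasaParams = dataclasses.field(default_factory=SasaParams)
    solvation_params: SolvationParams = dataclasses.field(default_factory=lambda: EISENBERG_SIGMA)


@dataclasses.dataclass
class MechanismFeatures:
    conf_change_rmsd: Optional[float]
    split_detected: Optional[bool]
    subdomain_angle: Optional[float]
    occlusion_fraction: Optional[float]
    effector_gain_percent: Optional[float]
    immunity_gain_percent: Optional[float]


@dataclasses.dataclass
class MechanismCall:
    label: str                    # capping | plugging | exosite | fold_disruption | indeterminate
    features: MechanismFeatures
    rule_trace: List[str]
    no_free_state: bool = False


def classify_mechanism(
    effector_free: Optional[StructureModel],
    complex_structure: StructureModel,
    effector_chains: Sequence[str],
    immunity_chains: Sequence[str],
    site: ActiveSiteSpec,
    partition: Optional[DomainPartition] = None,
    config: ClassifierConfig = ClassifierConfig(),
) -> MechanismCall:
    """Classify one effector-immunity complex.

    Decision order: (1) fold disruption when the effector splits into rigid
    subdomains rotated by >= ``split_angle_min`` (or the global free-vs-bound
    RMSD exceeds ``conf_change_rmsd_min``); (2) otherwise, high active-site
    occlusion is plugging when the immunity buries >= ``plugging_gain_min``
    percent of its own solvation energy, capping when it does not; (3) low
    occlusion is exosite.  Without a free-state structure only the
    occlusion/energetics rules apply.
    """
    trace: List[str] = []
    cfg = config

    conf_rmsd: Optional[float] = None
    split_detected: Optional[bool] = None
    subdomain_angle: Optional[float] = None
    if effector_free is not None:
        eff_chain = effector_chains[0]
        free_chain = next(iter(effector_free.chains))
        sup = superpose(
            complex_structure, effector_free,
            mobile_chain=eff_chain, reference_chain=free_chain,
            pairing_mode=cfg.pairing_mode,
        )
        conf_rmsd = sup.rmsd
        trace.append(f"conf_change_rmsd={conf_rmsd:.2f}A (n={sup.n_pairs})")
        if partition is not None:
            decomp = subdomain_rotation(
                effector_free,
                complex_structure,
                partition,
                pairing_mode=cfg.pairing_mode,
            )
            split_detected = True
            subdomain_angle = decomp.total_angle
            trace.append(f"subdomain_angle={subdomain_angle:.1f}deg (partition supplied)")
        else:
            split = detect_rigid_split(
                effector_free, complex_structure,
                chain=None, pairing_mode=cfg.pairing_mode,
                min_body=cfg.min_body, rmsd_tol=cfg.rmsd_tol,
            )
            split_detected = split.is_split
            subdomain_angle = split.inter_body_angle if split.is_split else None
            trace.append(
                f"split_detected={split.is_split}"
                + (f", inter_body_angle={split.inter_body_angle:.1f}deg" if split.is_split else "")
            )

    occ = active_site_occlusion(
        complex_structure, effector_chains, immunity_chains, site, cfg.sasa_params
    )
    energetics = interface_solvation_gain(
        complex_structure, effector_chains, immunity_chains,
        cfg.sasa_params, cfg.solvation_params,
    )
    features = MechanismFeatures(
        conf_change_rmsd=conf_rmsd,
        split_detected=split_detected,
        subdomain_angle=subdomain_angle,
        occlusion_fraction=occ.occlusion_fraction,
        effector_gain_percent=energetics.percent_A,
        immunity_gain_percent=energetics.percent_B,
    )
    trace.append(f"occlusion_fraction={_fmt(occ.occlusion_fraction)}")
    trace.append(f"immunity_gain_percent={_fmt(energetics.percent_B)}")

    # rule cascade
    if effector_free is not None:
        big_rotation = split_detected and subdomain_angle is not None and subdomain_angle >= cfg.split_angle_min
        big_shift = conf_rmsd is not None and conf_rmsd >= cfg.conf_change_rmsd_min
        trace.append(
            f"rule1 fold_disruption: split&angle>={cfg.split_angle_min} -> {bool(big_rotation)}; "
            f"rmsd>={cfg.conf_change_rmsd_min} -> {big_shift}"
        )
        if big_rotation or big_shift:
            return MechanismCall("fold_disruption", features, trace)

    if occ.occlusion_fraction is None:
        trace.append("occlusion undefined -> indeterminate")
        return MechanismCall("indeterminate", features, trace, no_free_state=effector_free is None)
    if occ.occlusion_fraction >= cfg.occlusion_min:
        trace.append(f"rule2 occlusion>={cfg.occlusion_min} -> capping/plugging branch")
        gain = energetics.percent_B
        if gain is not None and gain >= cfg.plugging_gain_min:
            trace.append(f"immunity gain {gain:.1f}% >= {cfg.plugging_gain_min}% -> plugging")
            return MechanismCall("plugging", features, trace, no_free_state=effector_free is None)
        trace.append("immunity gain below plugging threshold -> capping")
        return MechanismCall("capping", features, trace, no_free_state=effector_free is None)
    trace.append(f"rule3 occlusion<{cfg.occlusion_min} -> exosite")
    return MechanismCall("exosite", features, trace, no_free_state=effector_free is None)


def _fmt(x: Optional[float]) -> str:
    return "undefined" if x is None else f"{x:.3f}"
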