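import math

import numpy as np
import pytest

from conftest import single_atom_structure, sphere_area, two_sphere_exposed_area
from effimm.interface import (
    active_site_occlusion,
    contact_residues,
    core_contact_fraction,
    core_residues,
    map_residues,
)
from effimm.structio import ActiveSiteSpec
from effimm.surface import compute_sasa
from effimm.synthdata import make_cage, make_helix, make_toy_complex, merge_structures, rotation_about_axis


def test_distant_bodies_have_no_contacts():
    st = single_atom_structure([[0, 0, 0], [100, 0, 0]], ["A", "B"])
    rep = contact_residues(st, ["A"], ["B"])
    assert rep.contact_pairs == set()
    assert rep.contact_count == 0


def test_single_pair_at_cutoff_boundary():
    st = single_atom_structure([[0, 0, 0], [4.0, 0, 0], [0, 30, 0], [4.0, 60, 0]],
                               ["A", "B", "A", "B"])
    rep = contact_residues(st, ["A"], ["B"], cutoff=4.5)
    assert rep.contact_pairs == {(("A", 1, ""), ("B", 2, ""))}
    with pytest.raises(ValueError):
        contact_residues(st, ["A"], ["B"], cutoff=-1)


def test_contact_set_symmetric_under_role_swap():
    eff, cplx, site, part = make_toy_complex("full", "none")
    ab = contact_residues(cplx, ["A"], ["B"])
    ba = contact_residues(cplx, ["B"], ["A"])
    assert {(b, a) for a, b in ab.contact_pairs} == ba.contact_pairs


def test_dasa_mode_two_carbon_toy():
    st = single_atom_structure([[0, 0, 0], [3.1, 0, 0]], ["A", "B"])
    rep = contact_residues(st, ["A"], ["B"], mode="dasa")
    assert rep.effector_contacting == {("A", 1, "")}
    buried = sphere_area(3.1) - two_sphere_exposed_area(3.1, 3.1)
    assert rep.per_residue_dasa[("A", 1, "")] == pytest.approx(buried, rel=0.02)
    assert rep.per_residue_dasa[("A", 1, "")] == pytest.approx(30.19, rel=0.02)


def test_dasa_contacting_residues_are_near_partner():
    """Necessary condition: every dASA-contacting residue has an atom within
    2*(probe + max radius) of the partner body."""
    eff, cplx, site, part = make_toy_complex("full", "none")
    rep = contact_residues(cplx, ["A"], ["B"], mode="dasa")
    assert rep.effector_contacting
    b_coords = np.array([a.xyz for a in cplx.atoms(["B"])])
    limit = 2 * (1.4 + 1.8)
    for key in rep.effector_contacting:
        res = cplx.residue(key)
        dmin = min(np.linalg.norm(b_coords - a.xyz, axis=1).min() for a in res.atoms)
        assert dmin <= limit


def test_isolated_glycine_is_not_core():
    st = single_atom_structure([[0, 0, 0]], ["A"])
    assert core_residues(st) == set()


def test_fully_caged_residue_is_core():
    inner = single_atom_structure([[0, 0, 0]], ["A"])
    cage = make_cage([0, 0, 0], radius=5.0, n_atoms=400, chain_id="A", start_res_seq=10)
    st = merge_structures("caged", inner, cage)
    assert ("A", 1, "") in core_residues(st)


def test_core_set_matches_direct_rsasa_recomputation():
    from effimm.interface import MAX_ASA

    helix = make_helix(30)
    core = core_residues(helix, rsasa_threshold=0.25)
    sasa = compute_sasa(helix)
    expect = {
        r.key
        for r in helix.residues()
        if sasa.residue_area(r.key) / MAX_ASA[r.res_name] < 0.25
    }
    assert core == expect


def test_residue_mapping_by_number_and_alignment():
    a = make_helix(20, start_res_seq=1)
    b = make_helix(20, start_res_seq=101)  # offset numbering
    by_num = map_residues(a, "A", b, "A", mode="number")
    assert by_num == {}
    by_aln = map_residues(a, "A", b, "A", mode="alignment")
    assert len(by_aln) == 20
    assert by_aln[("A", 1, "")] == ("A", 101, "")


def test_core_contact_fraction_toy_construction():
    """Planted case: effector caged around known residues; the fraction equals
    core-contacting / contacting computed independently."""
    eff_free, cplx, site, part = make_toy_complex("full", "none")
    rep = core_contact_fraction(eff_free, [(cplx, ["A"], ["B"])], pairing_mode="number")
    assert rep.contact_count > 0
    assert 0.0 <= rep.core_contact_fraction <= 1.0
    # independent recomputation from the parts
    contacts = contact_residues(cplx, ["A"], ["B"]).effector_contacting
    core = core_residues(eff_free)
    n_core = sum(1 for k in contacts if k in core)
    assert rep.core_contact_count == n_core
    assert rep.core_contact_fraction == pytest.approx(n_core / len(contacts))


def test_core_contact_fraction_planted_two_of_four():
    """Constructed case with exactly 2 core residues among 4 contacting."""
    from effimm.synthdata import make_core_contact_toy

    eff, cplx = make_core_contact_toy()
    rep = core_contact_fraction(eff, [(cplx, ["A"], ["B"])], pairing_mode="number")
    assert rep.contact_count == 4
    assert rep.core_contact_count == 2
    assert rep.core_contact_fraction == pytest.approx(0.5)


def test_core_contact_fraction_pools_counts_not_fractions():
    eff_free, cplx, site, part = make_toy_complex("full", "none")
    single = core_contact_fraction(eff_free, [(cplx, ["A"], ["B"])], pairing_mode="number")
    double = core_contact_fraction(
        eff_free, [(cplx, ["A"], ["B"]), (cplx, ["A"], ["B"])], pairing_mode="number"
    )
    assert double.contact_count == 2 * single.contact_count
    assert double.core_contact_fraction == pytest.approx(single.core_contact_fraction)


def test_core_contact_fraction_undefined_for_distant_bodies():
    helix_a = make_helix(20, chain_id="A")
    helix_b = make_helix(20, chain_id="B").transformed(np.eye(3), np.array([200.0, 0, 0]))
    cplx = merge_structures("apart", helix_a, helix_b)
    rep = core_contact_fraction(helix_a, [(cplx, ["A"], ["B"])], pairing_mode="number")
    assert rep.undefined and rep.core_contact_fraction is None


def test_core_contact_fraction_invariant_to_rigid_motion():
    eff_free, cplx, site, part = make_toy_complex("full", "none")
    R = rotation_about_axis([1, 1, 0], 63.0)
    moved = cplx.transformed(R, np.array([3.0, -9.0, 14.0]))
    a = core_contact_fraction(eff_free, [(cplx, ["A"], ["B"])], pairing_mode="number")
    b = core_contact_fraction(eff_free, [(moved, ["A"], ["B"])], pairing_mode="number")
    assert a.core_contact_fraction == pytest.approx(b.core_contact_fraction, abs=1e-9)


def test_occlusion_zero_when_immunity_far():
    eff = make_helix(20, chain_id="A")
    imm = make_helix(10, chain_id="B").transformed(np.eye(3), np.array([100.0, 0, 0]))
    cplx = merge_structures("far", eff, imm)
    site = ActiveSiteSpec({("A", 10), ("A", 13)})
    rep = active_site_occlusion(cplx, ["A"], ["B"], site)
    assert rep.occlusion_fraction == pytest.approx(0.0, abs=1e-9)


def test_occlusion_full_when_site_caged():
    eff = make_helix(20, chain_id="A")
    site = ActiveSiteSpec({("A", 10)})
    center = eff.residue(("A", 10, "")).atom("CA").xyz
    cage = make_cage(center, radius=5.5, n_atoms=600, chain_id="B")
    cplx = merge_structures("caged", eff, cage)
    rep = active_site_occlusion(cplx, ["A"], ["B"], site)
    assert rep.occlusion_fraction > 0.95


def test_occlusion_equals_compositional_recomputation():
    eff_free, cplx, site, part = make_toy_complex("partial", "none")
    rep = active_site_occlusion(cplx, ["A"], ["B"], site)
    site_keys = [k for k in site.keys_in(cplx) if k[0] == "A"]
    keys_a = [k for k in cplx.residue_keys() if k[0] == "A"]
    free = sum(compute_sasa(cplx, keys_a).residue_area(k) for k in site_keys)
    bound = sum(compute_sasa(cplx).residue_area(k) for k in site_keys)
    assert rep.occlusion_fraction == pytest.approx(1 - bound / free, abs=1e-9)
    assert 0.0 < rep.occlusion_fraction < 1.0
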