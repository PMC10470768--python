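import math

import numpy as np
import pytest

from conftest import single_atom_structure, sphere_area, two_sphere_exposed_area
from effimm.surface import (
    EISENBERG_SIGMA,
    SasaParams,
    compute_sasa,
    golden_spiral_points,
    interface_solvation_gain,
    solvation_energy,
)
from effimm.synthdata import make_helix, rotation_about_axis


R_EXP = 1.70 + 1.4  # probe-expanded carbon radius


def test_single_carbon_sphere_area():
    st = single_atom_structure([[0, 0, 0]], ["A"])
    res = compute_sasa(st)
    assert res.total == pytest.approx(sphere_area(R_EXP), rel=1e-12)
    assert res.total == pytest.approx(120.76, abs=0.01)


@pytest.mark.parametrize("n_points,tol", [(960, 0.01), (3840, 0.0025)])
def test_sphere_convergence(n_points, tol):
    st = single_atom_structure([[0, 0, 0]], ["A"])
    res = compute_sasa(st, params=SasaParams(n_points=n_points))
    assert abs(res.total - sphere_area(R_EXP)) / sphere_area(R_EXP) <= tol


def test_two_distant_atoms_do_not_occlude():
    st = single_atom_structure([[0, 0, 0], [100, 0, 0]], ["A", "B"])
    res = compute_sasa(st)
    for area in res.per_atom.values():
        assert area == pytest.approx(sphere_area(R_EXP), rel=1e-12)


def test_two_sphere_cap_oracle():
    """Shrake-Rupley agrees with the spherical-cap closed form within 1%."""
    d = 3.1
    st = single_atom_structure([[0, 0, 0], [d, 0, 0]], ["A", "B"])
    res = compute_sasa(st)
    expect = two_sphere_exposed_area(R_EXP, d)
    assert expect == pytest.approx(90.57, abs=0.01)
    for area in res.per_atom.values():
        assert abs(area - expect) / expect <= 0.01


def test_per_residue_sums_match_per_atom():
    helix = make_helix(15)
    res = compute_sasa(helix)
    assert sum(res.per_residue.values()) == pytest.approx(sum(res.per_atom.values()), abs=1e-6)
    assert all(a >= 0 for a in res.per_atom.values())


def test_empty_selection_raises():
    with pytest.raises(ValueError):
        compute_sasa(make_helix(5), selection=[])


def test_golden_spiral_is_deterministic_and_unit():
    pts = golden_spiral_points(960)
    np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
    np.testing.assert_array_equal(pts, golden_spiral_points(960))


def test_solvation_energy_values_and_additivity():
    st = single_atom_structure([[0, 0, 0], [100, 0, 0]], ["A", "B"])
    sasa = compute_sasa(st)
    total = solvation_energy(st, None, sasa)
    one = solvation_energy(st, [("A", 1, "")], sasa)
    other = solvation_energy(st, [("B", 2, "")], sasa)
    assert one == pytest.approx(0.0160 * sphere_area(R_EXP), rel=1e-9)
    assert one == pytest.approx(1.932, abs=0.005)
    assert total == pytest.approx(one + other, rel=1e-12)


def test_missing_sigma_raises():
    st = single_atom_structure([[0, 0, 0]], ["A"], element="ZZ")
    sasa = compute_sasa(st)
    with pytest.raises(KeyError):
        solvation_energy(st, None, sasa)


def test_interface_gain_two_carbon_toy():
    """Cap-oracle case: 30.19 A^2 buried of 120.76, gain 0.483, percent 25%."""
    st = single_atom_structure([[0, 0, 0], [3.1, 0, 0]], ["A", "B"])
    eg = interface_solvation_gain(st, ["A"], ["B"])
    buried_expect = sphere_area(R_EXP) - two_sphere_exposed_area(R_EXP, 3.1)
    assert buried_expect == pytest.approx(30.19, abs=0.01)
    assert eg.buried_area_A == pytest.approx(buried_expect, rel=0.02)
    assert eg.gain_A == pytest.approx(0.0160 * buried_expect, rel=0.02)
    assert eg.percent_A == pytest.approx(25.0, abs=0.5)
    assert eg.percent_A == pytest.approx(eg.percent_B, abs=0.5)


def test_interface_gain_zero_for_distant_bodies():
    st = single_atom_structure([[0, 0, 0], [100, 0, 0]], ["A", "B"])
    eg = interface_solvation_gain(st, ["A"], ["B"])
    assert eg.gain_A == 0.0 and eg.gain_B == 0.0
    assert eg.percent_A == 0.0 and eg.percent_B == 0.0


def test_interface_gain_symmetric_for_homodimer():
    """C2-symmetric dimer (B = involutive 180-degree copy of A): equal percents."""
    from effimm.synthdata import merge_structures

    helix = make_helix(12, chain_id="A")
    other = make_helix(12, chain_id="B")
    R = rotation_about_axis([1, 0, 0], 180.0)
    p = helix.coords().mean(axis=0)
    t = np.array([0.0, 7.0, 0.0])  # R t = -t, so the map is an involution
    symm = other.transformed(R, p - R @ p + t)
    cplx = merge_structures("dimer", helix, symm)
    eg = interface_solvation_gain(cplx, ["A"], ["B"])
    assert eg.gain_A > 0
    assert eg.percent_A == pytest.approx(eg.percent_B, abs=0.3)


def test_overlapping_bodies_raise():
    st = single_atom_structure([[0, 0, 0], [3, 0, 0]], ["A", "B"])
    with pytest.raises(ValueError, match="overlap"):
        interface_solvation_gain(st, ["A", "B"], ["B"])


def test_percent_invariant_under_rigid_motion():
    st = single_atom_structure([[0, 0, 0], [3.1, 0, 0], [1.5, 2.5, 0]], ["A", "A", "B"])
    eg = interface_solvation_gain(st, ["A"], ["B"])
    R = rotation_about_axis([1, 2, 3], 77.0)
    moved = st.transformed(R, np.array([5.0, -4.0, 11.0]))
    eg2 = interface_solvation_gain(moved, ["A"], ["B"])
    assert eg2.percent_A == pytest.approx(eg.percent_A, abs=0.2)
    assert eg2.percent_B == pytest.approx(eg.percent_B, abs=0.2)


def test_occlusion_monotonicity_random_fixtures(rng):
    """Every atom's ASA in the complex is <= its ASA in the isolated body."""
    for _ in range(3):
        pos_a = rng.uniform(0, 12, size=(25, 3))
        pos_b = rng.uniform(6, 18, size=(25, 3))
        st = single_atom_structure(
            np.vstack([pos_a, pos_b]), ["A"] * 25 + ["B"] * 25
        )
        keys_a = [k for k in st.residue_keys() if k[0] == "A"]
        iso = compute_sasa(st, keys_a)
        full = compute_sasa(st)
        for serial, area in iso.per_atom.items():
            assert full.per_atom[serial] <= area + 1e-9


def test_agreement_with_biotite_oracle(rng):
    """Independent Shrake-Rupley implementation agrees within 2% total area."""
    biotite_struct = pytest.importorskip("biotite.structure")
    pos = rng.uniform(0, 15, size=(50, 3))
    st = single_atom_structure(pos, ["A"] * 50)
    mine = compute_sasa(st, params=SasaParams(n_points=960))

    arr = biotite_struct.AtomArray(50)
    arr.coord = pos.astype(np.float32)
    arr.chain_id[:] = "A"
    arr.res_id[:] = np.arange(1, 51)
    arr.res_name[:] = "GLY"
    arr.atom_name[:] = "CA"
    arr.element[:] = "C"
    ref = biotite_struct.sasa(arr, probe_radius=1.4, point_number=960, vdw_radii="Single")
    assert mine.total == pytest.approx(float(np.sum(ref)), rel=0.02)
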