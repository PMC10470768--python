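import math

import numpy as np
import pytest

from effimm.structio import AtomRecord, Residue, StructureModel


def single_atom_structure(positions, chain_ids, element="C", radius=1.70):
    """One single-atom pseudo-residue per position (the workhorse SASA toy)."""
    st = StructureModel("toy")
    for i, (p, c) in enumerate(zip(positions, chain_ids)):
        res = Residue(c, i + 1, "", "GLY")
        res.atoms.append(
            AtomRecord(i + 1, "CA", element, "", c, i + 1, "", "GLY",
                       np.asarray(p, dtype=float), 1.0, radius)
        )
        st.add_residue(res)
    return st


def sphere_area(r):
    return 4.0 * math.pi * r * r


def two_sphere_exposed_area(R, d):
    """Exposed area of each of two equal probe-expanded spheres (radius R,
    centre distance d < 2R): total minus the occluded spherical cap."""
    cap = 2.0 * math.pi * R * (R - d / 2.0)
    return sphere_area(R) - cap


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
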