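"""Hinge/rotation decomposition of a two-subdomain conformational shift.

Constructs a chain whose second subdomain is rotated 150 degrees about a
known axis (with coordinate jitter), detects the rigid-body split without
being told the boundary, and decomposes the motion into a rotation angle,
axis and hinge angle -- the quantification used for an immunity-induced
toxin-domain shift.
"""

from effimm.conformation import detect_rigid_split, subdomain_rotation
from effimm.synthdata import make_two_domain_pair

free, bound, truth = make_two_domain_pair(
    n_per_domain=40, rotation_deg=150.0, axis=(1.0, 0.0, 0.0), jitter_sd=0.2, seed=11
)

split = detect_rigid_split(free, bound)
print(f"split detected: {split.is_split}, boundary at paired residue {split.boundary}"
      f" (planted at {truth.boundary_index})")
print(f"per-body RMSDs: {split.body_rmsds[0]:.2f} / {split.body_rmsds[1]:.2f} A"
      f" vs single-body {split.single_rmsd:.2f} A")

decomp = subdomain_rotation(free, bound, truth.partition)
print(f"subdomain rotation: {decomp.total_angle:.1f} deg about axis "
      f"({decomp.axis[0]:+.2f}, {decomp.axis[1]:+.2f}, {decomp.axis[2]:+.2f})")
print(f"hinge angle at the boundary: {decomp.hinge_angle:.1f} deg")
print("The recovered angle matches the planted 150-degree motion; the huge")
print("improvement of the two-body fit over one rigid body is what flags a split fold.")
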