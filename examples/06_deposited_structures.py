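"""Analyse the deposited toxin/immunity coordinate sets (needs network).

Retrieves the deposited entries (8FZY, 8FZZ, 8G0K) from the RCSB archive,
assigns roles from their chain contents (one toxin-domain-alone entry, two
effector/immunity complexes), and reports the immunity-induced subdomain
rotation, the pooled core-contact statistic, the immunity protein's RMSD
to its homolog 6ITW, and the identity between the two toxin domains.
Run it anywhere with access to files.rcsb.org.
"""

import sys
import tempfile

from effimm.conformation import detect_rigid_split, sequence_identity, subdomain_rotation, superpose
from effimm.deposits import TOXIN_DEPOSITS, fetch_rcsb, identify_deposits
from effimm.interface import core_contact_fraction
from effimm.structio import DomainPartition, extract_sequence, read_structure

cache = tempfile.mkdtemp(prefix="rcsb_")
try:
    paths = {acc: fetch_rcsb(acc, cache) for acc in TOXIN_DEPOSITS}
except OSError as exc:
    sys.exit(f"cannot reach the RCSB archive: {exc}")

roles = identify_deposits(paths)
alone = next(v for v in roles.values() if v["role"] == "effector_alone")
complexes = [v for v in roles.values() if v["role"] == "complex"]
free_chain = alone["chains"][0]
print({acc: v["role"] for acc, v in roles.items()})

for entry in complexes:
    cplx = entry["structure"]
    eff_chain = entry["effector_chains"][0]
    split = detect_rigid_split(
        alone["structure"].subset([free_chain]),
        cplx.subset([eff_chain]), pairing_mode="alignment",
    )
    if split.is_split:
        keys = [r.key for r in alone["structure"].chains[free_chain]]
        part = DomainPartition("auto", {
            "body1": set(keys[: split.boundary]), "body2": set(keys[split.boundary:]),
        })
        d = subdomain_rotation(alone["structure"], cplx.subset([eff_chain]), part,
                               pairing_mode="alignment")
        print(f"{cplx.id}: subdomain rotation {d.total_angle:.0f} deg, hinge {d.hinge_angle:.0f} deg")

pooled = core_contact_fraction(
    alone["structure"].subset([free_chain]),
    [(e["structure"], e["effector_chains"][:1], e["immunity_chains"]) for e in complexes],
    pairing_mode="alignment",
)
print(f"core-contacting residues: {pooled.core_contact_count} of {pooled.contact_count} "
      f"({100 * pooled.core_contact_fraction:.0f}%)")

ref = read_structure(fetch_rcsb("6ITW", cache))
ref_chain = next(iter(ref.chains))
rmsds = [
    superpose(e["structure"], ref, mobile_chain=e["immunity_chains"][0],
              reference_chain=ref_chain, pairing_mode="alignment").rmsd
    for e in complexes
]
print(f"immunity vs 6ITW Calpha RMSD: best {min(rmsds):.2f} A")

seqs = [extract_sequence(e["structure"], e["effector_chains"][0]) for e in complexes]
print(f"toxin-domain sequence identity: {sequence_identity(seqs[0], seqs[1]):.0f}%")
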