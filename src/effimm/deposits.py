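"""Retrieval and role assignment for deposited coordinate sets.

The deposited accessions for the toxin-domain work are 8FZY, 8FZZ and 8G0K
(one effector toxin domain alone, two effector/immunity complexes), plus
comparator entries such as 6ITW.  Which accession holds which structure is
not stated, so roles are assigned at run time from the entry contents: an
entry whose polymer chains reduce to a single distinct sequence is the
effector-alone structure, while entries with two distinct sequences are
effector/immunity complexes (the shorter sequence is taken as the
immunity protein).
"""

from __future__ import annotations

import urllib.request
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

from .structio import StructureModel, extract_sequence, read_structure

__all__ = ["fetch_rcsb", "distinct_chain_groups", "identify_deposits"]

RCSB_URL = "https://files.rcsb.org/download/{accession}.pdb"
TOXIN_DEPOSITS = ("8FZY", "8FZZ", "8G0K")


def fetch_rcsb(accession: str, cache_dir: str | Path, timeout: float = 10.0) -> Path:
    """Download a PDB entry (cached); raises URLError when the archive is unreachable."""
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    out = cache_dir / f"{accession.upper()}.pdb"
    if out.exists() and out.stat().st_size > 0:
        return out
    url = RCSB_URL.format(accession=accession.upper())
    with urllib.request.urlopen(url, timeout=timeout) as resp:
        out.write_bytes(resp.read())
    return out


def _identity(a: str, b: str) -> float:
    from .conformation import align_residue_indices

    pairs = align_residue_indices(a, b)
    matches = sum(1 for i, j in pairs if a[i] == b[j])
    return matches / max(len(a), len(b)) if a and b else 0.0


def distinct_chain_groups(structure: StructureModel, identity_cutoff: float = 0.9) -> List[List[str]]:
    """Group polymer chains by near-identical sequence."""
    groups: List[Tuple[str, List[str]]] = []  # (representative seq, chain ids)
    for cid in structure.chains:
        seq = extract_sequence(structure, cid)
        if len(seq) < 20:
            continue
        for rep, members in groups:
            if _identity(rep, seq) >= identity_cutoff:
                members.append(cid)
                break
        else:
            groups.append((seq, [cid]))
    return [members for _, members in groups]


def identify_deposits(
    paths: Dict[str, str | Path],
) -> Dict[str, Dict]:
    """Assign roles to the toxin-domain deposits from their chain contents.

    ``paths`` maps accession -> local PDB path.  Returns, per accession, a
    dict with ``role`` (``effector_alone`` | ``complex``), the parsed
    structure, and for complexes the effector/immunity chain lists (the
    longer distinct sequence is the effector toxin domain).
    """
    out: Dict[str, Dict] = {}
    for acc, path in paths.items():
        st = read_structure(path)
        groups = distinct_chain_groups(st)
        if len(groups) == 1:
            out[acc] = {"role": "effector_alone", "structure": st, "chains": groups[0]}
        elif len(groups) >= 2:
            sized = sorted(
                groups,
                key=lambda g: -len(extract_sequence(st, g[0])),
            )
            out[acc] = {
                "role": "complex",
                "structure": st,
                "effector_chains": sized[0],
                "immunity_chains": sized[1],
            }
        else:
            raise ValueError(f"{acc}: no polymer chains found")
    return out
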