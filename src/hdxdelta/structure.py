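"""Map per-residue uptake differences onto a structure via the B-factor
column, for colouring Wood's-plot results in molecular viewers."""

from __future__ import annotations

import gemmi

__all__ = ["export_structure_map", "SENTINEL_BFACTOR"]

#: B-factor written for residues without peptide coverage.
SENTINEL_BFACTOR = -99.9


def export_structure_map(
    residue_values: dict[int, float],
    pdb_in: str,
    pdb_out: str,
    chain: str = "A",
    sentinel: float = SENTINEL_BFACTOR,
) -> int:
    """Write per-residue values (e.g. time-averaged delta-HDX %) into the
    B-factor field of one chain of a PDB file.

    ``residue_values`` maps author residue numbers (matching the chain's
    numbering) to values; residues absent from the map receive
    ``sentinel``.  Coordinates are untouched.  Returns the number of
    residues annotated with a real value.
    """
    structure = gemmi.read_structure(pdb_in)
    structure.setup_entities()
    annotated = 0
    found = False
    for model in structure:
        for ch in model:
            if ch.name != chain:
                continue
            found = True
            for residue in ch:
                value = residue_values.get(residue.seqid.num)
                if value is not None:
                    annotated += 1
                for atom in residue:
                    atom.b_iso = sentinel if value is None else value
    if not found:
        raise ValueError(f"chain {chain!r} not found in {pdb_in}")
    structure.write_pdb(pdb_out)
    return annotated
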