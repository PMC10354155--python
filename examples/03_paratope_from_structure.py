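"""Extract paratope positions from an antibody-antigen complex.

Uses a synthetic PDB-format complex with planted contact geometry: contact
residues sit 3.0 A from the antigen, the rest 10.0 A away, so the expected
answer is known by construction.  With a real structure, pass the real PDB
file, the chain ids, and a numbering backend covering the chain sequences.
"""

import tempfile
from pathlib import Path

from absearch import PositionKey
from absearch.numbering import FixtureNumberingBackend
from absearch.regions import extract_paratope
from absearch.synthetic import make_toy_complex

chain = [(PositionKey(35), "S"), (PositionKey(36), "Y"), (PositionKey(57), "G"),
         (PositionKey(58), "T"), (PositionKey(109), "A"), (PositionKey(110), "R"),
         (PositionKey(111), "D"), (PositionKey(114), "E")]
planted = [PositionKey(36), PositionKey(57), PositionKey(110)]

pdb_text, numbering_tsv = make_toy_complex(chain, planted)

with tempfile.TemporaryDirectory() as tmp:
    structure = Path(tmp) / "complex.pdb"
    structure.write_text(pdb_text)
    backend = FixtureNumberingBackend(numbering_tsv.splitlines())

    for cutoff in (2.0, 4.5, 25.0):
        paratope = extract_paratope(structure, ["H"], ["A"],
                                    numbering_backend=backend, cutoff=cutoff)
        print(f"cutoff {cutoff:>4.1f} A -> paratope:",
              ",".join(str(k) for k in paratope["H"]) or "(none)")

# At 4.5 A exactly the planted contacts (36, 57, 110) are returned; at 2.0 A
# nothing is close enough, and at 25.0 A even the 20-A non-contact residues
# qualify.  The returned keys feed straight into mask_from_positions.
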