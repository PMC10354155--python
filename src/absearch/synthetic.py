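"""Synthetic IMGT-numbered antibody repertoires with controlled structure.

Real repertoire data cannot ship with the package, so every pipeline stage
is exercised on generated repertoires that emulate its salient features:
fixed framework positions with point mutations at a controlled per-position
rate, variable-length CDR3s mapped onto the 111/112 insertion slots by the
IMGT convention, optional ambiguous residues, and AIRR-style metadata
columns (species, disease, v_call, j_call, redundancy).  Background
residues are drawn from fixed per-position frequency profiles rather than
uniformly, so identity distributions look like real data: high framework
identity, diverse CDRs — the regime in which tie handling actually matters.

The generator also plants exact-edit-distance neighbours of a query, whose
region identity is known in closed form, giving analytic ground truth for
sensitivity checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .canonical import (CanonicalScheme, PositionKey, STANDARD_AMINO_ACIDS,
                        imgt_traversal_key)
from .numbering import NumberedResidue, NumberedSequence
from .regions import RegionMask

# Framework/CDR1/CDR2 templates as (start_position, residue_run) segments;
# consecutive positions within a run, gaps between runs per typical IMGT
# occupancy of human V domains.  CDR3 (105-117 + insertions) is generated
# per sequence.
_HEAVY_SEGMENTS: tuple[tuple[int, str], ...] = (
    (1, "EVQLVESGG"), (11, "GLVQPGGSLRLSCAAS"),
    (27, "GFTF"), (35, "SSYA"),
    (39, "MSWVRQAPGKGLEWVSA"),
    (56, "ISGS"), (62, "GGST"),
    (66, "YYADSVK"), (74, "GRFTISRDNSKNTLYLQMNSLRAEDTAVYYC"),
    (118, "WGQGTLVTVSS"),
)
_LIGHT_SEGMENTS: tuple[tuple[int, str], ...] = (
    (1, "DIQMTQSPS"), (11, "SLSASVGDRVTITCRA"),
    (27, "QSIS"), (35, "SYLN"),
    (39, "WYQQKPGKAPKLLIYAA"),
    (56, "AAS"),
    (66, "GVPSRFS"), (74, "GSGSGTDFTLTISSLQPEDFATYYCQQSYST"),
    (118, "FGQGTKVEIKR"),
)

_V_CALLS = {
    "H": ("IGHV1-58*01", "IGHV3-23*01", "IGHV1-69*01", "IGHV4-34*01"),
    "K": ("IGKV1-39*01", "IGKV3-20*01", "IGKV1-5*01"),
    "L": ("IGLV1-40*01", "IGLV2-14*01", "IGLV3-21*01"),
}
_J_CALLS = {
    "H": ("IGHJ3*02", "IGHJ4*02", "IGHJ6*01"),
    "K": ("IGKJ1*01", "IGKJ2*01", "IGKJ4*01"),
    "L": ("IGLJ2*01", "IGLJ3*02"),
}


def template_for(chain_type: str) -> dict[int, str]:
    """Default framework template (position -> residue) for a chain type."""
    segments = _HEAVY_SEGMENTS if chain_type == "H" else _LIGHT_SEGMENTS
    template: dict[int, str] = {}
    for start, run in segments:
        for i, res in enumerate(run):
            template[start + i] = res
    return template


def cdr3_keys(length: int, max_insertions_per_side: int = 36) -> list[PositionKey]:
    """IMGT position keys of a CDR3 of the given length, in sequence order.

    Residues fill positions 105..117 from both ends (gap in the middle of
    the loop when shorter than 13); longer loops add insertion slots
    alternating between 111 (ascending) and 112 (descending), 112 first,
    following the IMGT junction convention.
    """
    if length < 1:
        raise ValueError("CDR3 length must be >= 1")
    capacity = 13 + 2 * max_insertions_per_side
    if length > capacity:
        raise ValueError(f"CDR3 length {length} exceeds scheme capacity {capacity}")
    if length <= 13:
        head = math.ceil(length / 2)
        tail = length - head
        return ([PositionKey(105 + i) for i in range(head)]
                + [PositionKey(117 - tail + 1 + i) for i in range(tail)])
    extra = length - 13
    at_111 = extra // 2
    at_112 = extra - at_111
    return ([PositionKey(p) for p in range(105, 112)]
            + [PositionKey(111, k) for k in range(1, at_111 + 1)]
            + [PositionKey(112, k) for k in range(at_112, 0, -1)]
            + [PositionKey(p) for p in range(112, 118)])


def cdr3_capacity(scheme: CanonicalScheme) -> int:
    """Maximum CDR3 length the scheme can hold (plain 105-117 + insertion slots)."""
    return sum(1 for key in scheme.slots if 105 <= key.position <= 117)


@dataclass(frozen=True)
class RepertoireSpec:
    """Parameters of one synthetic repertoire.

    Rates are per-residue probabilities in [0, 1]; CDR3 lengths are drawn
    uniformly from the inclusive range and must fit the scheme's CDR3
    capacity.  The same seed always yields the same repertoire.
    """

    n_sequences: int
    seed: int
    chain_type: str = "H"
    species_mix: dict[str, float] = field(
        default_factory=lambda: {"human": 0.9, "mouse": 0.1})
    disease_mix: dict[str, float] = field(
        default_factory=lambda: {"healthy": 0.8, "SARS-CoV-2": 0.1, "influenza": 0.1})
    cdr3_length_range: tuple[int, int] = (8, 20)
    mutation_rate: float = 0.03
    ambiguous_rate: float = 0.0
    redundancy_geometric_p: float = 0.5
    id_prefix: str = "syn"

    def __post_init__(self) -> None:
        for rate in (self.mutation_rate, self.ambiguous_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate out of [0, 1]: {rate}")
        if not 0.0 < self.redundancy_geometric_p <= 1.0:
            raise ValueError("redundancy_geometric_p must be in (0, 1]")
        if self.cdr3_length_range[0] < 1 or self.cdr3_length_range[0] > self.cdr3_length_range[1]:
            raise ValueError(f"bad CDR3 length range: {self.cdr3_length_range}")
        if self.n_sequences < 0:
            raise ValueError("n_sequences must be non-negative")


def _position_profile(position: int, insertion: int) -> np.ndarray:
    """Fixed residue frequency profile of one position (deterministic)."""
    rng = np.random.default_rng(hash((position, insertion)) % (2 ** 31))
    weights = rng.dirichlet(np.full(len(STANDARD_AMINO_ACIDS), 0.5))
    return weights


def _sample_labels(rng: np.random.Generator, mix: dict[str, float],
                   n: int) -> np.ndarray:
    labels = list(mix)
    probs = np.array([mix[k] for k in labels], dtype=float)
    return np.array(labels)[rng.choice(len(labels), size=n, p=probs / probs.sum())]


def generate_aligned_repertoire(spec: RepertoireSpec, scheme: CanonicalScheme
                                ) -> tuple[np.ndarray, pd.DataFrame]:
    """Generate a repertoire directly as an aligned uint8 matrix (fast path).

    Same sampling model as :func:`generate_repertoire` (which decodes this
    matrix), fully vectorised so databases of 10^4+ rows are cheap.
    Returns (matrix of shape n x scheme-length, metadata table).
    """
    if spec.cdr3_length_range[1] > cdr3_capacity(scheme):
        raise ValueError(
            f"CDR3 length {spec.cdr3_length_range[1]} exceeds the scheme's "
            f"CDR3 capacity {cdr3_capacity(scheme)}")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_sequences
    L = len(scheme)
    aa = STANDARD_AMINO_ACIDS
    n_aa = len(aa)
    mat = np.zeros((n, L), dtype=np.uint8)

    # framework + CDR1/2: template residue everywhere, point mutations on top
    template = template_for(spec.chain_type)
    fw_positions = sorted(template)
    fw_slots = np.array([scheme.slot_index[PositionKey(p)] for p in fw_positions])
    fw_codes = np.array([scheme.code_of(template[p]) for p in fw_positions],
                        dtype=np.uint8)
    mat[:, fw_slots] = fw_codes
    mutate = rng.random((n, len(fw_positions))) < spec.mutation_rate
    for j, pos in enumerate(fw_positions):
        hit = np.flatnonzero(mutate[:, j])
        if hit.size == 0:
            continue
        w = _position_profile(pos, 0).copy()
        w[aa.index(template[pos])] = 0.0  # a mutation always changes the residue
        codes = rng.choice(n_aa, size=hit.size, p=w / w.sum()) + 1
        mat[hit, fw_slots[j]] = codes.astype(np.uint8)

    # CDR3: sample a length per sequence, fill the IMGT-gapped key set
    lengths = rng.integers(spec.cdr3_length_range[0],
                           spec.cdr3_length_range[1] + 1, size=n)
    max_per_side = max(
        (k.insertion for k in scheme.slots if k.position in (111, 112)), default=0)
    all_keys = sorted({k for length in range(spec.cdr3_length_range[0],
                                             spec.cdr3_length_range[1] + 1)
                       for k in cdr3_keys(length, max_per_side)},
                      key=imgt_traversal_key)
    active = {length: set(cdr3_keys(length, max_per_side))
              for length in range(spec.cdr3_length_range[0],
                                  spec.cdr3_length_range[1] + 1)}
    for key in all_keys:
        rows = np.flatnonzero(np.array([key in active[int(l)] for l in lengths]))
        if rows.size == 0:
            continue
        w = _position_profile(key.position, key.insertion)
        codes = rng.choice(n_aa, size=rows.size, p=w) + 1
        mat[rows, scheme.slot_index[key]] = codes.astype(np.uint8)

    if spec.ambiguous_rate:
        x_code = scheme.codes.get("X")
        if x_code is not None:
            hit = (rng.random((n, L)) < spec.ambiguous_rate) & (mat != 0)
            mat[hit] = x_code

    metadata = pd.DataFrame({
        "sequence_id": [f"{spec.id_prefix}{i:06d}" for i in range(n)],
        "species": _sample_labels(rng, spec.species_mix, n),
        "chain": spec.chain_type,
        "disease": _sample_labels(rng, spec.disease_mix, n),
        "v_call": np.array(_V_CALLS[spec.chain_type])[
            rng.integers(len(_V_CALLS[spec.chain_type]), size=n)],
        "j_call": np.array(_J_CALLS[spec.chain_type])[
            rng.integers(len(_J_CALLS[spec.chain_type]), size=n)],
        "redundancy": rng.geometric(spec.redundancy_geometric_p, size=n),
    }, columns=["sequence_id", "species", "chain", "disease",
                "v_call", "j_call", "redundancy"])
    return mat, metadata


def generate_repertoire(spec: RepertoireSpec, scheme: CanonicalScheme
                        ) -> tuple[list[NumberedSequence], pd.DataFrame]:
    """Generate numbered sequences plus an AIRR-style metadata table.

    Deterministic given the spec's seed.  Metadata columns: sequence_id,
    species, chain, disease, v_call, j_call, redundancy — the minimum set
    the database builder consumes.  Sequences are decoded from the matrix
    produced by :func:`generate_aligned_repertoire`, so the two routes are
    exactly consistent.
    """
    mat, metadata = generate_aligned_repertoire(spec, scheme)
    sequences = []
    for i in range(spec.n_sequences):
        residues = [NumberedResidue(scheme.slots[s].position,
                                    scheme.slots[s].insertion,
                                    scheme.alphabet[mat[i, s] - 1])
                    for s in np.flatnonzero(mat[i])]
        sequences.append(NumberedSequence(
            sequence_id=metadata["sequence_id"].iloc[i],
            chain_type=spec.chain_type,
            species=metadata["species"].iloc[i],
            residues=residues))
    return sequences, metadata


def plant_neighbors(query: NumberedSequence, k: int, mask: RegionMask,
                    edits: int, scheme: CanonicalScheme,
                    seed: int = 0) -> list[NumberedSequence]:
    """Plant k variants differing from the query at exactly `edits` masked residues.

    Substitutions only (never gaps, never X), so each variant's identity to
    the query over the mask is exactly 100 * (m - edits) / m with m the
    query's masked residue count.
    """
    rng = np.random.default_rng(seed)
    editable = [i for i, res in enumerate(query.residues)
                if scheme.slot_index.get(PositionKey(res.position, res.insertion))
                in mask.slot_set]
    if edits < 0 or edits > len(editable):
        raise ValueError(
            f"cannot make {edits} edits: query has {len(editable)} residues in mask")
    variants = []
    for v in range(k):
        chosen = set(rng.choice(editable, size=edits, replace=False).tolist()) if edits else set()
        residues = []
        for i, res in enumerate(query.residues):
            if i in chosen:
                alternatives = [a for a in STANDARD_AMINO_ACIDS if a != res.residue]
                new = alternatives[rng.integers(len(alternatives))]
                residues.append(NumberedResidue(res.position, res.insertion, new))
            else:
                residues.append(res)
        variants.append(NumberedSequence(
            sequence_id=f"{query.sequence_id}_nb{v}", chain_type=query.chain_type,
            species=query.species, residues=residues))
    return variants


_THREE_LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}


def make_toy_complex(chain_residues: Sequence[tuple[PositionKey, str]],
                     contact_keys: Sequence[PositionKey],
                     near_distance: float = 3.0,
                     far_distance: float = 20.0,
                     antibody_chain: str = "H",
                     antigen_chain: str = "A",
                     species: str = "human") -> tuple[str, str]:
    """Build a synthetic PDB-format antibody-antigen complex with known contacts.

    The antigen is a single alanine whose only atom sits at the origin; each
    antibody residue is one CA atom placed on a circle around it at exactly
    ``near_distance`` (for keys in ``contact_keys``) or ``far_distance``.
    Returns (pdb_text, numbering_tsv_text): the structure plus a fixture
    numbering table for the antibody chain sequence, so paratope extraction
    can be verified against the planted contact set by construction.
    """
    contact = set(contact_keys)
    lines = ["ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C"]
    serial = 2
    n = len(chain_residues)
    for i, (key, res) in enumerate(chain_residues):
        d = near_distance if key in contact else far_distance
        theta = 2.0 * math.pi * i / max(n, 1)
        x, y = d * math.cos(theta), d * math.sin(theta)
        lines.append(
            f"ATOM  {serial:>5}  CA  {_THREE_LETTER[res]} {antibody_chain}{i + 1:>4}    "
            f"{x:8.3f}{y:8.3f}{0.0:8.3f}  1.00  0.00           C")
        serial += 1
    lines.append("END")
    pdb_text = "\n".join(lines) + "\n"

    tsv_lines = ["# sequence_id\tchain_type\tspecies\timgt_position\tinsertion_code\tresidue"]
    for key, res in chain_residues:
        code = "" if key.insertion == 0 else chr(ord("A") + key.insertion - 1)
        tsv_lines.append(f"toy_ab\t{antibody_chain if antibody_chain in 'HKL' else 'H'}\t"
                         f"{species}\t{key.position}\t{code}\t{res}")
    return pdb_text, "\n".join(tsv_lines) + "\n"


def inject_rare_insertion(seq: NumberedSequence,
                          key: PositionKey = PositionKey(81, 9),
                          residue: str = "G") -> NumberedSequence:
    """Copy a sequence with an extra residue at an off-scheme insertion.

    The default key, insertion ordinal 9 at position 81 (81I), is the kind
    of rare insertion that cannot be vectorised and routes the sequence to
    the unusual sidecar.
    """
    pairs = [(PositionKey(r.position, r.insertion), r.residue) for r in seq.residues]
    pairs.append((key, residue))
    pairs.sort(key=lambda kr: imgt_traversal_key(kr[0]))
    return NumberedSequence(
        sequence_id=seq.sequence_id, chain_type=seq.chain_type, species=seq.species,
        residues=[NumberedResidue(k.position, k.insertion, r) for k, r in pairs])
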