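"""Region masks over the canonical alignment, and paratope extraction.

A region is simply a set of alignment slots.  The default suite mirrors the
way practitioners search repertoires: the whole V domain with variable
length, and the CDRs / CDR3 with exact length matching.  Arbitrary position
lists (e.g. a structurally determined paratope) are first-class: any subset
of the scheme's slots can be searched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, TextIO, Union

import numpy as np

from .canonical import (CanonicalScheme, PositionKey, insertion_code_to_ordinal,
                        ordinal_to_insertion_code)
from .errors import RegionError
from .numbering import NumberedSequence, number_with_backend

logger = logging.getLogger(__name__)

# IMGT delimitations of the three CDR loops (inclusive position ranges).
# Insertion slots at a position inside a range belong to that CDR.
CDR_BOUNDARIES: dict[str, tuple[int, int]] = {
    "cdr1": (27, 38),
    "cdr2": (56, 65),
    "cdr3": (105, 117),
}


@dataclass(frozen=True)
class RegionMask:
    """A named set of 0-based slot indices, plus the length-matched flag."""

    name: str
    slot_set: frozenset[int]
    length_matched: bool = False

    def __post_init__(self) -> None:
        if not self.slot_set:
            raise RegionError(f"region {self.name!r} is empty")
        if any(s < 0 for s in self.slot_set):
            raise RegionError(f"region {self.name!r} has negative slot indices")

    @property
    def slots(self) -> np.ndarray:
        """Sorted slot indices as an array (scheme order)."""
        return np.fromiter(sorted(self.slot_set), dtype=np.int64)

    def __len__(self) -> int:
        return len(self.slot_set)


@dataclass(frozen=True)
class RegionSuite:
    """The ordered list of region masks evaluated in one search."""

    masks: tuple[RegionMask, ...]

    def __post_init__(self) -> None:
        names = [m.name for m in self.masks]
        if len(set(names)) != len(names):
            raise RegionError(f"duplicate region names in suite: {names}")
        if not self.masks:
            raise RegionError("region suite is empty")

    def __iter__(self):
        return iter(self.masks)

    def __len__(self) -> int:
        return len(self.masks)

    def __getitem__(self, name: str) -> RegionMask:
        for m in self.masks:
            if m.name == name:
                return m
        raise KeyError(name)


def _slots_in_ranges(scheme: CanonicalScheme, ranges: Iterable[tuple[int, int]]) -> frozenset[int]:
    pairs = list(ranges)
    return frozenset(
        i for i, key in enumerate(scheme.slots)
        if any(lo <= key.position <= hi for lo, hi in pairs))


def default_regions(scheme: CanonicalScheme,
                    boundaries: dict[str, tuple[int, int]] = CDR_BOUNDARIES) -> RegionSuite:
    """The default search suite: whole domain, all CDRs, CDR3.

    The whole-domain mask spans every slot with variable length allowed;
    the CDR masks use exact length matching, so a CDR3 of length 12 is never
    compared against one of length 13.
    """
    whole = RegionMask("whole", frozenset(range(len(scheme))), length_matched=False)
    cdrs = RegionMask("cdrs", _slots_in_ranges(scheme, boundaries.values()), length_matched=True)
    cdr3 = RegionMask("cdr3", _slots_in_ranges(scheme, [boundaries["cdr3"]]), length_matched=True)
    return RegionSuite((whole, cdrs, cdr3))


def mask_from_positions(position_list: Sequence[Union[PositionKey, int, tuple[int, int]]],
                        scheme: CanonicalScheme,
                        length_matched: bool = False,
                        name: str = "custom") -> RegionMask:
    """Build a mask from explicit position keys.

    Bare integers mean plain positions; (position, insertion-ordinal) tuples
    and PositionKeys are accepted too.  Every key must be one of the
    scheme's slots; offenders are reported together.
    """
    if not position_list:
        raise RegionError("position list is empty")
    keys: list[PositionKey] = []
    for item in position_list:
        if isinstance(item, PositionKey):
            keys.append(item)
        elif isinstance(item, tuple):
            keys.append(PositionKey(item[0], item[1]))
        else:
            keys.append(PositionKey(int(item)))
    unknown = [k for k in keys if k not in scheme.slot_index]
    if unknown:
        raise RegionError("positions absent from the scheme: "
                          + ", ".join(str(k) for k in unknown))
    return RegionMask(name, frozenset(scheme.slot_index[k] for k in keys), length_matched)


def mask_to_file(mask: RegionMask, scheme: CanonicalScheme, stream: TextIO) -> None:
    """Serialize a mask as a position-list file (same format as scheme definitions)."""
    stream.write(f"# region\t{mask.name}\n")
    stream.write(f"# length_matched\t{'true' if mask.length_matched else 'false'}\n")
    for slot in sorted(mask.slot_set):
        key = scheme.slots[slot]
        stream.write(f"{key.position}\t{ordinal_to_insertion_code(key.insertion)}\n")


def mask_from_file(source: Union[str, Path, TextIO], scheme: CanonicalScheme) -> RegionMask:
    """Read a mask written by :func:`mask_to_file`."""
    if isinstance(source, (str, Path)) and (isinstance(source, Path) or "\n" not in source):
        with open(source) as fh:
            lines = fh.readlines()
    elif isinstance(source, str):
        lines = source.splitlines()
    else:
        lines = source.readlines()
    name, length_matched = "custom", False
    keys: list[tuple[int, int]] = []
    for line in lines:
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            parts = line[1:].strip().split("\t")
            if len(parts) == 2 and parts[0] == "region":
                name = parts[1]
            elif len(parts) == 2 and parts[0] == "length_matched":
                length_matched = parts[1].lower() == "true"
            continue
        cols = line.split("\t")
        keys.append((int(cols[0]),
                     insertion_code_to_ordinal(cols[1]) if len(cols) > 1 else 0))
    return mask_from_positions(keys, scheme, length_matched=length_matched, name=name)


def extract_paratope(structure: Union[str, Path],
                     antibody_chain_ids: Sequence[str],
                     antigen_chain_ids: Sequence[str],
                     numbering_backend,
                     cutoff: float = 4.5,
                     side_chain_only: bool = False) -> dict[str, list[PositionKey]]:
    """Extract paratope position keys from an antibody-antigen complex.

    A paratope residue is any antibody residue with at least one heavy
    (non-hydrogen) atom within ``cutoff`` angstroms of any antigen heavy
    atom.  By default all heavy atoms are considered; ``side_chain_only``
    restricts the antibody side to side-chain atoms.  Each antibody chain's
    sequence is numbered with the backend and structure residues mapped to
    IMGT keys by their order; residues outside the numbered V domain (tags,
    constant domain) are ignored with a warning.
    """
    import gemmi

    st = gemmi.read_structure(str(structure))
    st.setup_entities()
    model = st[0]
    chains = {ch.name: ch for ch in model}
    for cid in list(antibody_chain_ids) + list(antigen_chain_ids):
        if cid not in chains:
            raise RegionError(f"chain {cid!r} not found in structure "
                              f"(available: {sorted(chains)})")

    backbone = {"N", "CA", "C", "O"}
    antigen_coords = []
    for cid in antigen_chain_ids:
        for res in chains[cid]:
            for atom in res:
                if not atom.is_hydrogen():
                    antigen_coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
    if not antigen_coords:
        raise RegionError("antigen chains contain no heavy atoms")
    antigen_xyz = np.asarray(antigen_coords)

    result: dict[str, list[PositionKey]] = {}
    for cid in antibody_chain_ids:
        chain = chains[cid]
        residues = [r for r in chain if any(not a.is_hydrogen() for a in r)]
        seq = gemmi.one_letter_code([r.name for r in residues]).upper()
        seq = "".join(c if c.isalpha() else "X" for c in seq)
        numbered = number_with_backend(seq, numbering_backend)
        if numbered is None:
            raise RegionError(f"chain {cid!r} sequence could not be numbered")
        offset = _map_numbered_to_chain(numbered, seq, cid)
        keys: list[PositionKey] = []
        for i, nres in enumerate(numbered.residues):
            res = residues[offset + i]
            coords = [[a.pos.x, a.pos.y, a.pos.z] for a in res
                      if not a.is_hydrogen()
                      and not (side_chain_only and a.name in backbone)]
            if not coords:
                continue
            d2 = ((np.asarray(coords)[:, None, :] - antigen_xyz[None, :, :]) ** 2).sum(-1)
            if cutoff > 0 and d2.min() <= cutoff ** 2:
                keys.append(PositionKey(nres.position, nres.insertion))
        result[cid] = keys
    return result


def _map_numbered_to_chain(numbered: NumberedSequence, chain_seq: str, chain_id: str) -> int:
    """Locate the numbered V-domain inside the full chain sequence."""
    vseq = numbered.sequence
    offset = chain_seq.find(vseq)
    if offset < 0:
        raise RegionError(
            f"numbered sequence of chain {chain_id!r} does not match the structure residues")
    trailing = len(chain_seq) - offset - len(vseq)
    if offset or trailing:
        logger.warning("chain %s: %d leading and %d trailing structure residues "
                       "outside the numbered V domain are ignored",
                       chain_id, offset, trailing)
    return offset
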