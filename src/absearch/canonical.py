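"""Canonical alignment scheme and fixed-length vector encoding.

Antibody V-domain sequences numbered under the IMGT scheme can be slotted
into a fixed catalogue of (position, insertion) keys.  The default catalogue
holds the 128 plain IMGT positions plus 36 insertion slots each at positions
111 and 112 — the CDR3 insertion region — for 200 slots in total.  Each
numbered sequence then becomes an integer vector of length 200 (gap = 0),
and sequence identity over any region reduces to elementwise comparison.

Sequences carrying an insertion outside the catalogue (rare insertions such
as 81I, seen in a tiny fraction of repertoire data) cannot be vectorised;
``encode`` returns them as :class:`UnusualSequence` markers so they can be
set aside rather than silently dropped.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Iterator, TextIO, Union

import numpy as np

from .errors import EncodingError, SchemeError
from .numbering import NumberedResidue, NumberedSequence

#: The 20 standard amino acids, in the order that fixes their integer codes.
STANDARD_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Ambiguous residue, coded like any other so it can be matched (or not) by policy.
AMBIGUOUS_RESIDUE = "X"
#: Full default alphabet string; integer code of character c is index+1.
DEFAULT_ALPHABET = STANDARD_AMINO_ACIDS + AMBIGUOUS_RESIDUE
#: Code reserved for an empty slot.
GAP_CODE = 0

#: Number of insertion slots kept at each of IMGT 111 and 112 in the default scheme.
CDR3_INSERTIONS_PER_SIDE = 36


@dataclass(frozen=True)
class PositionKey:
    """One alignment slot: an IMGT position plus an insertion ordinal.

    ``insertion`` is an ordinal, not a letter: 0 means no insertion, k means
    the k-th insertion code (A -> 1, B -> 2, ...).  Ordinals keep the CDR3
    traversal rule (ascending at 111, descending at 112) purely numeric.
    """

    position: int
    insertion: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.position <= 128:
            raise SchemeError(f"IMGT position out of range 1..128: {self.position}")
        if self.insertion < 0:
            raise SchemeError(f"negative insertion ordinal: {self.insertion}")

    def __str__(self) -> str:
        return f"{self.position}{ordinal_to_insertion_code(self.insertion)}"


def insertion_code_to_ordinal(code: str) -> int:
    """Map an insertion letter to its ordinal ('' -> 0, 'A' -> 1, 'B' -> 2, ...)."""
    code = code.strip()
    if not code:
        return 0
    if len(code) == 1 and "A" <= code.upper() <= "Z":
        return ord(code.upper()) - ord("A") + 1
    if code.isdigit():  # already an ordinal
        return int(code)
    raise SchemeError(f"unrecognised insertion code: {code!r}")


def ordinal_to_insertion_code(ordinal: int) -> str:
    """Inverse of :func:`insertion_code_to_ordinal` for ordinals 0..26; beyond Z uses digits."""
    if ordinal == 0:
        return ""
    if ordinal <= 26:
        return chr(ord("A") + ordinal - 1)
    return str(ordinal)


def imgt_traversal_key(key: PositionKey) -> tuple[int, int, int]:
    """Sort key implementing the IMGT traversal rule.

    Plain positions ascend.  CDR3 insertions sit between plain 111 and plain
    112: insertions at 111 ascend (111, 111A, 111B, ...) and insertions at
    112 descend (..., 112B, 112A, 112), preserving the physical adjacency of
    the loop.  Insertions at any other position ascend after their parent.
    """
    if key.insertion == 0:
        return (key.position, 0, 0)
    if key.position == 112:
        return (111, 2, -key.insertion)
    return (key.position, 1, key.insertion)


@dataclass(frozen=True)
class CanonicalScheme:
    """An ordered catalogue of alignment slots plus the residue alphabet.

    ``scheme_id`` is a content hash of the ordered slot list and the
    alphabet; databases stamp it into their manifest so a query encoded
    under a different scheme is rejected instead of silently misaligned.
    """

    slots: tuple[PositionKey, ...]
    alphabet: str = DEFAULT_ALPHABET
    slot_index: dict[PositionKey, int] = field(init=False, repr=False, compare=False)
    codes: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.slots:
            raise SchemeError("a scheme must have at least one slot")
        index = {key: i for i, key in enumerate(self.slots)}
        if len(index) != len(self.slots):
            seen: set[PositionKey] = set()
            dup = next(k for k in self.slots if k in seen or seen.add(k))
            raise SchemeError(f"duplicate slot in scheme definition: {dup}")
        if len(set(self.alphabet)) != len(self.alphabet):
            raise SchemeError("alphabet contains repeated residues")
        object.__setattr__(self, "slot_index", index)
        object.__setattr__(self, "codes", {c: i + 1 for i, c in enumerate(self.alphabet)})

    def __len__(self) -> int:
        return len(self.slots)

    @property
    def scheme_id(self) -> str:
        h = hashlib.sha256()
        for key in self.slots:
            h.update(f"{key.position}.{key.insertion}\n".encode())
        h.update(self.alphabet.encode())
        return h.hexdigest()

    def code_of(self, residue: str) -> int:
        try:
            return self.codes[residue]
        except KeyError:
            raise EncodingError(f"residue {residue!r} not in scheme alphabet") from None

    def residue_of(self, code: int) -> str:
        if not 1 <= code <= len(self.alphabet):
            raise EncodingError(f"code {code} outside alphabet range")
        return self.alphabet[code - 1]


@dataclass(frozen=True)
class UnusualSequence:
    """A sequence that cannot be vectorised because of off-scheme insertions."""

    sequence: NumberedSequence
    offending_keys: tuple[PositionKey, ...]
    source: str = ""

    @property
    def raw_sequence(self) -> str:
        return self.sequence.sequence


def default_scheme(alphabet: str = DEFAULT_ALPHABET) -> CanonicalScheme:
    """Build the default 200-slot scheme.

    IMGT positions 1..128 with no insertion (128 slots) plus CDR3 insertion
    slots 111.1..111.36 and 112.36..112.1 (72 slots), ordered by the IMGT
    traversal rule, giving 200 unique positions.
    """
    keys = [PositionKey(p) for p in range(1, 129)]
    keys += [PositionKey(111, k) for k in range(1, CDR3_INSERTIONS_PER_SIDE + 1)]
    keys += [PositionKey(112, k) for k in range(1, CDR3_INSERTIONS_PER_SIDE + 1)]
    keys.sort(key=imgt_traversal_key)
    return CanonicalScheme(slots=tuple(keys), alphabet=alphabet)


def load_scheme(source: Union[str, TextIO, Iterable[str]],
                alphabet: str = DEFAULT_ALPHABET) -> CanonicalScheme:
    """Load a scheme from a tab-separated definition.

    One row per slot in slot order; columns = imgt_position, insertion_code
    (empty for none).  Lines starting with '#' are ignored.
    """
    keys: list[PositionKey] = []
    for lineno, line in enumerate(_iter_lines(source), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) not in (1, 2):
            raise SchemeError(f"scheme definition line {lineno}: expected 1-2 columns, got {len(parts)}")
        try:
            position = int(parts[0])
        except ValueError:
            raise SchemeError(f"scheme definition line {lineno}: bad position {parts[0]!r}") from None
        ordinal = insertion_code_to_ordinal(parts[1]) if len(parts) == 2 else 0
        keys.append(PositionKey(position, ordinal))
    if not keys:
        raise SchemeError("scheme definition is empty")
    return CanonicalScheme(slots=tuple(keys), alphabet=alphabet)


def dump_scheme(scheme: CanonicalScheme, stream: TextIO) -> None:
    """Write a scheme definition readable by :func:`load_scheme`."""
    stream.write("# imgt_position\tinsertion_code\n")
    for key in scheme.slots:
        stream.write(f"{key.position}\t{ordinal_to_insertion_code(key.insertion)}\n")


def encode(seq: NumberedSequence,
           scheme: CanonicalScheme) -> Union[np.ndarray, UnusualSequence]:
    """Encode a numbered sequence as a fixed-length uint8 vector.

    Every residue lands at its slot; unoccupied slots hold the gap code 0.
    If any residue's (position, insertion) key is absent from the scheme the
    sequence cannot be vectorised and an :class:`UnusualSequence` marker is
    returned instead, carrying the offending keys.  A residue outside the
    alphabet raises :class:`~absearch.errors.EncodingError`.
    """
    vec = np.zeros(len(scheme), dtype=np.uint8)
    offending: list[PositionKey] = []
    for res in seq.residues:
        key = PositionKey(res.position, res.insertion)
        slot = scheme.slot_index.get(key)
        if slot is None:
            offending.append(key)
            continue
        vec[slot] = scheme.code_of(res.residue)
    if offending:
        # validate the rest of the alphabet anyway so errors outrank unusualness
        for res in seq.residues:
            scheme.code_of(res.residue)
        return UnusualSequence(sequence=seq, offending_keys=tuple(offending),
                               source=seq.sequence_id)
    return vec


def decode(vec: np.ndarray, scheme: CanonicalScheme) -> list[tuple[PositionKey, str]]:
    """Return (PositionKey, residue) pairs for all non-gap slots, in slot order."""
    vec = np.asarray(vec)
    if vec.shape != (len(scheme),):
        raise SchemeError(f"vector length {vec.shape} does not match scheme length {len(scheme)}")
    return [(scheme.slots[i], scheme.residue_of(int(c)))
            for i, c in enumerate(vec) if c != GAP_CODE]


def decoded_to_numbered(pairs: list[tuple[PositionKey, str]], sequence_id: str = "",
                        chain_type: str = "H", species: str = "") -> NumberedSequence:
    """Convenience: wrap decode() output back into a NumberedSequence."""
    residues = [NumberedResidue(k.position, k.insertion, r) for k, r in pairs]
    return NumberedSequence(sequence_id=sequence_id, chain_type=chain_type,
                            species=species, residues=residues)


def _iter_lines(source: Union[str, TextIO, Iterable[str]]) -> Iterator[str]:
    if isinstance(source, str):
        if "\n" in source or "\t" in source:
            yield from source.splitlines()
        else:
            with open(source) as fh:
                yield from fh
    else:
        yield from source
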