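"""IMGT numbering contract and backends.

A V-domain sequence must be assigned IMGT position numbers before it can be
slotted into the canonical alignment.  Numbering itself (an HMM alignment
problem) is out of scope here: this module defines the data model for a
numbered sequence, a tabular fixture backend so the whole pipeline is
testable with no external tool, and an optional adapter to an external
ANARCI-compatible numbering program.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, TextIO, Union

from .errors import BackendUnavailableError, ParseError

logger = logging.getLogger(__name__)

VALID_CHAIN_TYPES = ("H", "K", "L")
_VALID_RESIDUES = set("ACDEFGHIKLMNPQRSTVWYX")
GAP_SYMBOL = "-"


@dataclass(frozen=True)
class NumberedResidue:
    """One residue with its IMGT position and insertion ordinal (0 = none)."""

    position: int
    insertion: int
    residue: str

    def __post_init__(self) -> None:
        if not 1 <= self.position <= 128:
            raise ValueError(f"IMGT position out of range 1..128: {self.position}")
        if self.insertion < 0:
            raise ValueError(f"negative insertion ordinal: {self.insertion}")
        if self.residue not in _VALID_RESIDUES:
            raise ValueError(f"unknown residue symbol: {self.residue!r}")

    @property
    def key(self) -> tuple[int, int]:
        return (self.position, self.insertion)


@dataclass
class NumberedSequence:
    """An ordered list of numbered residues plus chain and species labels."""

    sequence_id: str
    chain_type: str
    species: str
    residues: list[NumberedResidue] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.chain_type not in VALID_CHAIN_TYPES:
            raise ValueError(f"chain_type must be one of {VALID_CHAIN_TYPES}: {self.chain_type!r}")
        keys = [r.key for r in self.residues]
        if len(set(keys)) != len(keys):
            seen: set[tuple[int, int]] = set()
            dup = next(k for k in keys if k in seen or seen.add(k))
            raise ValueError(f"duplicate residue key {dup} in sequence {self.sequence_id!r}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        """The raw amino-acid string, residues in numbering order."""
        return "".join(r.residue for r in self.residues)

    def keys(self) -> list[tuple[int, int]]:
        return [r.key for r in self.residues]


def _insertion_ordinal(code: str) -> int:
    code = code.strip()
    if not code:
        return 0
    if len(code) == 1 and "A" <= code.upper() <= "Z":
        return ord(code.upper()) - ord("A") + 1
    if code.isdigit():
        return int(code)
    raise ValueError(f"unrecognised insertion code {code!r}")


def parse_numbering_table(source: Union[str, Path, TextIO, Iterable[str]]) -> list[NumberedSequence]:
    """Parse the tab-separated fixture numbering format.

    Columns: sequence_id, chain_type, species, imgt_position, insertion_code,
    residue — one residue per row, rows of one record contiguous.  Lines
    starting with '#' are comments.  Rows whose residue is the gap symbol
    '-' are dropped.  Record order and residue order are preserved.
    """
    records: dict[str, NumberedSequence] = {}
    for lineno, raw in enumerate(_iter_lines(source), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 6:
            raise ParseError(f"numbering table line {lineno}: expected 6 columns, got {len(parts)}")
        seq_id, chain, species, pos_s, ins_s, residue = (p.strip() for p in parts)
        if seq_id not in records:
            try:
                records[seq_id] = NumberedSequence(seq_id, chain, species, [])
            except ValueError as e:
                raise ParseError(f"record {seq_id!r}, line {lineno}: {e}") from None
        if residue == GAP_SYMBOL:
            continue
        try:
            pos = int(pos_s)
            ins = _insertion_ordinal(ins_s)
            res = NumberedResidue(pos, ins, residue)
        except ValueError as e:
            raise ParseError(f"record {seq_id!r}, line {lineno}: {e}") from None
        records[seq_id].residues.append(res)
    out = []
    for rec in records.values():
        if not rec.residues:
            logger.warning("numbering record %r is empty", rec.sequence_id)
        # re-validate key uniqueness now that residues were appended post-init
        try:
            NumberedSequence(rec.sequence_id, rec.chain_type, rec.species, rec.residues)
        except ValueError as e:
            raise ParseError(f"record {rec.sequence_id!r}: {e}") from None
        out.append(rec)
    return out


def write_numbering_table(sequences: Iterable[NumberedSequence], stream: TextIO) -> None:
    """Emit the fixture numbering format consumed by :func:`parse_numbering_table`."""
    stream.write("# sequence_id\tchain_type\tspecies\timgt_position\tinsertion_code\tresidue\n")
    for seq in sequences:
        for r in seq.residues:
            code = "" if r.insertion == 0 else (chr(ord("A") + r.insertion - 1)
                                                if r.insertion <= 26 else str(r.insertion))
            stream.write(f"{seq.sequence_id}\t{seq.chain_type}\t{seq.species}\t"
                         f"{r.position}\t{code}\t{r.residue}\n")


class FixtureNumberingBackend:
    """Numbering backend backed by a pre-computed fixture table.

    Looks sequences up by their raw amino-acid string; a sequence absent
    from the fixture yields the failure marker (None).
    """

    def __init__(self, source: Union[str, Path, TextIO, Iterable[str], list[NumberedSequence]]):
        seqs = source if isinstance(source, list) and all(
            isinstance(s, NumberedSequence) for s in source) else parse_numbering_table(source)
        self._by_sequence: dict[str, NumberedSequence] = {}
        for s in seqs:
            self._by_sequence.setdefault(s.sequence, s)

    def number(self, sequence: str) -> Optional[NumberedSequence]:
        return self._by_sequence.get(sequence)


class ExternalToolBackend:
    """Adapter to an ANARCI-compatible command-line numbering tool.

    Contract: the tool consumes a FASTA file (``-i``), is given the IMGT
    scheme (``--scheme imgt``) and an output CSV prefix (``--csv -o``), and
    writes per-chain CSVs whose header is metadata columns followed by one
    column per IMGT position (e.g. ``1``, ``111A``), gap cells holding '-'.
    Never used by the test suite; construction fails loudly when the tool is
    absent rather than falling back silently.
    """

    def __init__(self, executable: str = "ANARCI", species: str = "human"):
        if shutil.which(executable) is None:
            raise BackendUnavailableError(
                f"external numbering tool {executable!r} is not on PATH; "
                "configure a FixtureNumberingBackend instead")
        self.executable = executable
        self.species = species

    def number(self, sequence: str) -> Optional[NumberedSequence]:
        import csv

        with tempfile.TemporaryDirectory() as tmp:
            fasta = Path(tmp) / "query.fasta"
            fasta.write_text(f">query\n{sequence}\n")
            prefix = Path(tmp) / "numbered"
            proc = subprocess.run(
                [self.executable, "-i", str(fasta), "--scheme", "imgt",
                 "--csv", "-o", str(prefix)],
                capture_output=True, text=True)
            if proc.returncode != 0:
                logger.warning("numbering tool failed: %s", proc.stderr.strip())
                return None
            for chain in VALID_CHAIN_TYPES:
                out = prefix.with_name(f"{prefix.name}_{chain}.csv")
                if not out.exists():
                    continue
                with open(out) as fh:
                    rows = list(csv.DictReader(fh))
                if not rows:
                    continue
                row = rows[0]
                residues = []
                for col, val in row.items():
                    if not col or not col[0].isdigit() or val in (GAP_SYMBOL, "", None):
                        continue
                    pos_s = "".join(ch for ch in col if ch.isdigit())
                    ins_s = col[len(pos_s):]
                    residues.append(NumberedResidue(int(pos_s), _insertion_ordinal(ins_s), val))
                return NumberedSequence("query", chain, row.get("species", self.species), residues)
        return None


def number_with_backend(sequence: str, backend) -> Optional[NumberedSequence]:
    """Number an amino-acid string with the configured backend.

    Returns the backend's NumberedSequence, or None when the backend cannot
    number the sequence.  Non-amino-acid characters are rejected up front.
    """
    if backend is None:
        raise BackendUnavailableError("no numbering backend configured")
    bad = set(sequence) - _VALID_RESIDUES
    if bad or not sequence:
        raise ValueError(f"input is not an amino-acid sequence (offending characters: {sorted(bad)})")
    return backend.number(sequence)


def _iter_lines(source) -> Iterator[str]:
    if isinstance(source, Path):
        with open(source) as fh:
            yield from fh
    elif isinstance(source, str):
        if "\n" in source or "\t" in source:
            yield from source.splitlines()
        else:
            with open(source) as fh:
                yield from fh
    else:
        yield from source
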