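"""Sharded aligned-sequence database: build, persist, load, resolve.

The database layout on disk mirrors the two-index design used by large
pre-aligned repertoire releases:

* ``shards/`` — raw binary matrices of uint8 alignment codes (row-major,
  dimensions in the manifest) plus a parallel int64 index-pair file per
  shard; memory-mappable and language-neutral;
* ``metadata/`` — the original per-source CSV tables, untouched; every
  aligned row carries an (file_id, row_in_file) pair that addresses its
  metadata record;
* ``manifest.tsv`` — plain-text key/value header plus a shard table with
  content hashes, so integrity is checkable without a database engine;
* ``scheme.tsv`` — the canonical scheme the vectors were encoded under;
  its content hash (scheme_id) guards against cross-scheme searches;
* ``unusual.fasta`` — sequences with off-scheme insertions, excluded from
  every shard but preserved for search by other means;
* ``filter_report.csv`` — per-rule drop counts of the reduction filters.

Shards are partitioned by (chain_type, species) so searches can be
restricted to the relevant partitions cheaply.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .canonical import (DEFAULT_ALPHABET, CanonicalScheme, UnusualSequence,
                        dump_scheme, encode, load_scheme)
from .errors import BuildError, LoadError, ResolutionError
from .numbering import NumberedSequence

logger = logging.getLogger(__name__)

MANIFEST_NAME = "manifest.tsv"
SCHEME_NAME = "scheme.tsv"
UNUSUAL_NAME = "unusual.fasta"
FILTER_REPORT_NAME = "filter_report.csv"
DEFAULT_SHARD_SIZE = 2 ** 20

#: Minimum metadata columns expected of AIRR-style tables.
METADATA_COLUMNS = ("sequence_id", "species", "chain", "disease",
                    "v_call", "j_call", "redundancy")


@dataclass(frozen=True)
class FilterConfig:
    """Dataset-reduction rules, applied in the declared order."""

    drop_ambiguous: bool = False
    min_redundancy: Optional[int] = None
    require_position_one: bool = False
    deduplicate: bool = False

    @classmethod
    def none(cls) -> "FilterConfig":
        return cls()


@dataclass
class DatabaseShard:
    """One loaded shard: aligned codes plus per-row metadata index pairs."""

    matrix: np.ndarray            # N x L uint8
    index_pairs: np.ndarray       # N x 2 int64 (metadata_file_id, row_in_file)
    chain_type: str
    species: str
    scheme_id: str
    global_offset: int = 0        # row number of this shard's first row in scan order

    def __post_init__(self) -> None:
        if self.matrix.shape[0] != self.index_pairs.shape[0]:
            raise LoadError("shard matrix and index pairs disagree on row count")


@dataclass
class ShardEntry:
    matrix_file: str
    index_file: str
    chain_type: str
    species: str
    rows: int
    matrix_sha256: str
    index_sha256: str


@dataclass
class Manifest:
    """Structured view of manifest.tsv."""

    root: Path
    scheme_id: str
    vector_length: int
    total_input: int
    total_encoded: int
    total_unusual: int
    total_filtered: int
    metadata_files: list[str]
    shards: list[ShardEntry] = field(default_factory=list)

    @property
    def partitions(self) -> list[tuple[str, str]]:
        seen: list[tuple[str, str]] = []
        for sh in self.shards:
            part = (sh.chain_type, sh.species)
            if part not in seen:
                seen.append(part)
        return seen


def apply_reduction_filters(
    records: Sequence[tuple[NumberedSequence, pd.Series]],
    filters: FilterConfig,
) -> tuple[list[tuple[NumberedSequence, pd.Series]], dict[str, int]]:
    """Apply the reduction rules used to derive small/tiny database variants.

    Rules, in order: drop sequences containing the ambiguous residue X;
    drop sequences seen fewer than ``min_redundancy`` times (redundancy is
    read from the metadata column when present, else computed by exact
    duplicate counting within the input); drop sequences without a residue
    at IMGT position one; drop exact duplicates, keeping the first.
    Filters are total: every record is either retained or counted against
    exactly one rule.
    """
    drops = {"ambiguous": 0, "redundancy": 0, "position_one": 0, "duplicate": 0}
    retained = list(records)

    if filters.drop_ambiguous:
        kept = []
        for seq, meta in retained:
            if "X" in seq.sequence:
                drops["ambiguous"] += 1
            else:
                kept.append((seq, meta))
        retained = kept

    if filters.min_redundancy is not None:
        counts: dict[str, int] = {}
        for seq, _ in retained:
            counts[seq.sequence] = counts.get(seq.sequence, 0) + 1
        kept = []
        for seq, meta in retained:
            redundancy = meta.get("redundancy") if hasattr(meta, "get") else None
            if redundancy is None or (isinstance(redundancy, float) and np.isnan(redundancy)):
                redundancy = counts[seq.sequence]
            if int(redundancy) < filters.min_redundancy:
                drops["redundancy"] += 1
            else:
                kept.append((seq, meta))
        retained = kept

    if filters.require_position_one:
        kept = []
        for seq, meta in retained:
            if any(r.position == 1 and r.insertion == 0 for r in seq.residues):
                kept.append((seq, meta))
            else:
                drops["position_one"] += 1
        retained = kept

    if filters.deduplicate:
        seen: set[tuple] = set()
        kept = []
        for seq, meta in retained:
            fingerprint = tuple((r.position, r.insertion, r.residue) for r in seq.residues)
            if fingerprint in seen:
                drops["duplicate"] += 1
            else:
                seen.add(fingerprint)
                kept.append((seq, meta))
        retained = kept

    return retained, drops


def build_database(
    numbered_seqs: Sequence[NumberedSequence],
    metadata: Union[pd.DataFrame, Sequence[pd.DataFrame]],
    scheme: CanonicalScheme,
    out_dir: Union[str, Path],
    shard_size: int = DEFAULT_SHARD_SIZE,
    filters: FilterConfig = FilterConfig.none(),
) -> Manifest:
    """Encode, partition, and persist a database.

    Metadata rows must correspond 1:1, in order, to the input sequences
    (concatenation order when several tables are given).  Sequences are
    filtered, encoded under ``scheme``, partitioned by (chain_type,
    species), and written in shards of at most ``shard_size`` rows.
    Sequences with off-scheme insertions go to the unusual sidecar.  The
    returned manifest's counts always conserve the input:
    encoded + unusual + filtered = inputs.
    """
    if shard_size < 1:
        raise BuildError("shard_size must be positive")
    tables = [metadata] if isinstance(metadata, pd.DataFrame) else list(metadata)
    total_meta = sum(len(t) for t in tables)
    if total_meta != len(numbered_seqs):
        raise BuildError(f"metadata rows ({total_meta}) != sequences ({len(numbered_seqs)})")

    out = Path(out_dir)
    (out / "shards").mkdir(parents=True, exist_ok=True)
    (out / "metadata").mkdir(exist_ok=True)

    # pair every sequence with its metadata row and (file_id, row) address
    records: list[tuple[NumberedSequence, pd.Series]] = []
    addresses: dict[int, tuple[int, int]] = {}
    k = 0
    for fid, table in enumerate(tables):
        for row in range(len(table)):
            records.append((numbered_seqs[k], table.iloc[row]))
            addresses[id(numbered_seqs[k])] = (fid, row)
            k += 1

    retained, drops = apply_reduction_filters(records, filters)
    n_filtered = sum(drops.values())

    partitions: dict[tuple[str, str], list[tuple[np.ndarray, tuple[int, int]]]] = {}
    unusual: list[UnusualSequence] = []
    for seq, _ in retained:
        encoded = encode(seq, scheme)
        if isinstance(encoded, UnusualSequence):
            unusual.append(encoded)
            continue
        partitions.setdefault((seq.chain_type, seq.species), []).append(
            (encoded, addresses[id(seq)]))

    n_encoded = sum(len(v) for v in partitions.values())
    if n_encoded + len(unusual) + n_filtered != len(numbered_seqs):
        raise BuildError("count conservation violated during build")  # pragma: no cover

    # persist metadata tables untouched
    meta_files = []
    for fid, table in enumerate(tables):
        name = f"metadata/meta_{fid}.csv"
        table.to_csv(out / name, index=False)
        meta_files.append(name)

    entries: list[ShardEntry] = []
    for (chain, species), rows in sorted(partitions.items()):
        for si in range(0, len(rows), shard_size):
            block = rows[si:si + shard_size]
            mat = np.stack([v for v, _ in block]).astype(np.uint8)
            idx = np.array([p for _, p in block], dtype=np.int64)
            stem = f"shards/{chain}_{_safe(species)}_{si // shard_size:04d}"
            (out / f"{stem}.mat").write_bytes(mat.tobytes())
            (out / f"{stem}.idx").write_bytes(idx.tobytes())
            entries.append(ShardEntry(
                matrix_file=f"{stem}.mat", index_file=f"{stem}.idx",
                chain_type=chain, species=species, rows=len(block),
                matrix_sha256=_sha256(out / f"{stem}.mat"),
                index_sha256=_sha256(out / f"{stem}.idx")))

    with open(out / SCHEME_NAME, "w") as fh:
        dump_scheme(scheme, fh)
    _write_unusual(unusual, out / UNUSUAL_NAME)
    pd.DataFrame({"rule": list(drops), "dropped": list(drops.values())}
                 ).to_csv(out / FILTER_REPORT_NAME, index=False)

    manifest = Manifest(root=out, scheme_id=scheme.scheme_id,
                        vector_length=len(scheme), total_input=len(numbered_seqs),
                        total_encoded=n_encoded, total_unusual=len(unusual),
                        total_filtered=n_filtered, metadata_files=meta_files,
                        shards=entries)
    _write_manifest(manifest, out / MANIFEST_NAME, alphabet=scheme.alphabet)
    return manifest


def build_database_from_vectors(
    matrix: np.ndarray,
    metadata: pd.DataFrame,
    scheme: CanonicalScheme,
    out_dir: Union[str, Path],
    chain_type: str = "H",
    species: str = "human",
    shard_size: int = DEFAULT_SHARD_SIZE,
) -> Manifest:
    """Persist an already-aligned matrix as a searchable database.

    The pre-aligned fast path: rows are taken as-is (no numbering, no
    filters, no unusual routing), metadata rows correspond 1:1 to matrix
    rows, and the whole matrix lands in one (chain_type, species)
    partition.  Useful for data that was vectorised elsewhere and for
    large synthetic benchmarks.
    """
    matrix = np.ascontiguousarray(np.asarray(matrix, dtype=np.uint8))
    if matrix.ndim != 2 or matrix.shape[1] != len(scheme):
        raise BuildError(f"matrix shape {matrix.shape} does not fit scheme "
                         f"length {len(scheme)}")
    if len(metadata) != matrix.shape[0]:
        raise BuildError(f"metadata rows ({len(metadata)}) != matrix rows "
                         f"({matrix.shape[0]})")
    out = Path(out_dir)
    (out / "shards").mkdir(parents=True, exist_ok=True)
    (out / "metadata").mkdir(exist_ok=True)
    metadata.to_csv(out / "metadata" / "meta_0.csv", index=False)

    entries: list[ShardEntry] = []
    n = matrix.shape[0]
    for si in range(0, max(n, 1) if n else 0, shard_size):
        block = matrix[si:si + shard_size]
        idx = np.stack([np.zeros(block.shape[0], dtype=np.int64),
                        np.arange(si, si + block.shape[0], dtype=np.int64)], axis=1)
        stem = f"shards/{chain_type}_{_safe(species)}_{si // shard_size:04d}"
        (out / f"{stem}.mat").write_bytes(block.tobytes())
        (out / f"{stem}.idx").write_bytes(idx.tobytes())
        entries.append(ShardEntry(
            matrix_file=f"{stem}.mat", index_file=f"{stem}.idx",
            chain_type=chain_type, species=species, rows=block.shape[0],
            matrix_sha256=_sha256(out / f"{stem}.mat"),
            index_sha256=_sha256(out / f"{stem}.idx")))

    with open(out / SCHEME_NAME, "w") as fh:
        dump_scheme(scheme, fh)
    _write_unusual([], out / UNUSUAL_NAME)
    pd.DataFrame({"rule": [], "dropped": []}).to_csv(out / FILTER_REPORT_NAME,
                                                     index=False)
    manifest = Manifest(root=out, scheme_id=scheme.scheme_id,
                        vector_length=len(scheme), total_input=n,
                        total_encoded=n, total_unusual=0, total_filtered=0,
                        metadata_files=["metadata/meta_0.csv"], shards=entries)
    _write_manifest(manifest, out / MANIFEST_NAME, alphabet=scheme.alphabet)
    return manifest


def _safe(label: str) -> str:
    return "".join(c if c.isalnum() or c in "-_" else "_" for c in label)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_unusual(unusual: Sequence[UnusualSequence], path: Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(u.raw_sequence), id=u.sequence.sequence_id or f"unusual_{i}",
                  description="offending_positions="
                  + ",".join(str(k) for k in u.offending_keys))
        for i, u in enumerate(unusual)]
    with open(path, "w") as fh:
        seqio_write(records, fh, "fasta")


def _write_manifest(m: Manifest, path: Path, alphabet: str) -> None:
    with open(path, "w") as fh:
        fh.write("# absearch database manifest\n")
        fh.write("format_version\t1\n")
        fh.write(f"scheme_id\t{m.scheme_id}\n")
        fh.write(f"alphabet\t{alphabet}\n")
        fh.write(f"vector_length\t{m.vector_length}\n")
        fh.write(f"total_input\t{m.total_input}\n")
        fh.write(f"total_encoded\t{m.total_encoded}\n")
        fh.write(f"total_unusual\t{m.total_unusual}\n")
        fh.write(f"total_filtered\t{m.total_filtered}\n")
        fh.write(f"metadata_files\t{','.join(m.metadata_files)}\n")
        fh.write("[shards]\n")
        fh.write("# matrix_file\tindex_file\tchain\tspecies\trows\tmatrix_sha256\tindex_sha256\n")
        for sh in m.shards:
            fh.write(f"{sh.matrix_file}\t{sh.index_file}\t{sh.chain_type}\t{sh.species}\t"
                     f"{sh.rows}\t{sh.matrix_sha256}\t{sh.index_sha256}\n")


def read_manifest(manifest_path: Union[str, Path]) -> tuple[Manifest, str]:
    """Parse manifest.tsv; returns the manifest and the alphabet string."""
    path = Path(manifest_path)
    if not path.exists():
        raise LoadError(f"manifest not found: {path}")
    header: dict[str, str] = {}
    shards: list[ShardEntry] = []
    in_shards = False
    for line in path.read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        if line.strip() == "[shards]":
            in_shards = True
            continue
        parts = line.split("\t")
        if not in_shards:
            header[parts[0]] = parts[1] if len(parts) > 1 else ""
        else:
            if len(parts) != 7:
                raise LoadError(f"malformed shard entry: {line!r}")
            shards.append(ShardEntry(parts[0], parts[1], parts[2], parts[3],
                                     int(parts[4]), parts[5], parts[6]))
    try:
        manifest = Manifest(
            root=path.parent, scheme_id=header["scheme_id"],
            vector_length=int(header["vector_length"]),
            total_input=int(header["total_input"]),
            total_encoded=int(header["total_encoded"]),
            total_unusual=int(header["total_unusual"]),
            total_filtered=int(header["total_filtered"]),
            metadata_files=[f for f in header.get("metadata_files", "").split(",") if f],
            shards=shards)
    except KeyError as e:
        raise LoadError(f"manifest missing field {e}") from None
    if sum(sh.rows for sh in shards) != manifest.total_encoded:
        raise LoadError("manifest shard rows do not sum to total_encoded")
    return manifest, header.get("alphabet", "")


class ShardedDatabase:
    """A loaded database: manifest, scheme, streaming shard access, metadata."""

    def __init__(self, manifest_path: Union[str, Path], verify_hashes: bool = True):
        self.manifest, alphabet = read_manifest(manifest_path)
        scheme_file = self.manifest.root / SCHEME_NAME
        if not scheme_file.exists():
            raise LoadError(f"scheme definition missing: {scheme_file}")
        self.scheme = load_scheme(str(scheme_file),
                                  alphabet=alphabet or DEFAULT_ALPHABET)
        if self.scheme.scheme_id != self.manifest.scheme_id:
            raise LoadError("scheme file hash does not match manifest scheme_id")
        self._verify = verify_hashes
        self._metadata_cache: Optional[list[pd.DataFrame]] = None

    @property
    def scheme_id(self) -> str:
        return self.manifest.scheme_id

    def iter_shards(self, chains: Optional[Iterable[str]] = None,
                    species: Optional[Iterable[str]] = None) -> Iterator[DatabaseShard]:
        """Yield shards in manifest order, optionally restricted to partitions.

        ``global_offset`` numbers rows consecutively over the *selected*
        shards in manifest order, giving every scanned row a stable rank
        used for deterministic tie-breaking.
        """
        chain_set = set(chains) if chains is not None else None
        species_set = set(species) if species is not None else None
        offset = 0
        L = self.manifest.vector_length
        for sh in self.manifest.shards:
            if chain_set is not None and sh.chain_type not in chain_set:
                continue
            if species_set is not None and sh.species not in species_set:
                continue
            mpath = self.manifest.root / sh.matrix_file
            ipath = self.manifest.root / sh.index_file
            for p in (mpath, ipath):
                if not p.exists():
                    raise LoadError(f"shard file missing: {p}")
            if self._verify:
                if _sha256(mpath) != sh.matrix_sha256:
                    raise LoadError(f"matrix hash mismatch for {sh.matrix_file}")
                if _sha256(ipath) != sh.index_sha256:
                    raise LoadError(f"index hash mismatch for {sh.index_file}")
            matrix = np.fromfile(mpath, dtype=np.uint8)
            if matrix.size != sh.rows * L:
                raise LoadError(f"{sh.matrix_file}: size {matrix.size} != rows*L "
                                f"({sh.rows}x{L})")
            index_pairs = np.fromfile(ipath, dtype=np.int64)
            if index_pairs.size != sh.rows * 2:
                raise LoadError(f"{sh.index_file}: row-count mismatch")
            yield DatabaseShard(matrix=matrix.reshape(sh.rows, L),
                                index_pairs=index_pairs.reshape(sh.rows, 2),
                                chain_type=sh.chain_type, species=sh.species,
                                scheme_id=self.manifest.scheme_id,
                                global_offset=offset)
            offset += sh.rows

    def metadata_tables(self) -> list[pd.DataFrame]:
        if self._metadata_cache is None:
            self._metadata_cache = [
                pd.read_csv(self.manifest.root / f, keep_default_na=True)
                for f in self.manifest.metadata_files]
        return self._metadata_cache


def load_database(manifest_path: Union[str, Path],
                  verify_hashes: bool = True) -> ShardedDatabase:
    """Open a persisted database for streaming search."""
    return ShardedDatabase(manifest_path, verify_hashes=verify_hashes)


def resolve_metadata(index_pair: Sequence[int],
                     tables: Sequence[pd.DataFrame]) -> pd.Series:
    """Resolve an (file_id, row_in_file) pair to its unique metadata record."""
    fid, row = int(index_pair[0]), int(index_pair[1])
    if not 0 <= fid < len(tables):
        raise ResolutionError(f"metadata file id {fid} out of range (have {len(tables)})")
    table = tables[fid]
    if not 0 <= row < len(table):
        raise ResolutionError(f"row {row} out of range for metadata file {fid} "
                              f"({len(table)} rows)")
    return table.iloc[row]
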