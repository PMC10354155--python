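"""Exhaustive multi-query, multi-region search over a sharded database.

Every selected database row is scored against every query for every region
— there is no prefiltering of any kind, so the best hit by the identity
definition is found every time.  Chunks stream through memory: each loaded
chunk is compared against all queries and all regions before the next chunk
is read, which amortises the data-loading bottleneck when searching with
many queries.  Per-(query, region) accumulators hold at most ``n_best``
hits; chunk results are merged in manifest order with a deterministic tie
rule (descending identity, then ascending database row), so the output is
identical for any chunk size or worker count.
"""

from __future__ import annotations

import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .dbstore import ShardedDatabase, resolve_metadata
from .errors import SearchError
from .identity import IdentityOptions, batch_identity, merge_top_n, top_n
from .regions import RegionMask, RegionSuite

logger = logging.getLogger(__name__)

IDENTITY_COLUMN = "Identity"


@dataclass(frozen=True)
class Query:
    """A query vector with its id and (optional) chain type for partition selection."""

    id: str
    vector: np.ndarray
    chain_type: Optional[str] = None


@dataclass(frozen=True)
class SearchConfig:
    """Parameters of one search run."""

    regions: RegionSuite
    n_best: int = 1000
    threshold: Optional[float] = None
    chunk_rows: int = 2 ** 16
    workers: int = 1
    chains: Optional[tuple[str, ...]] = None
    species: Optional[tuple[str, ...]] = None
    include_terminal_gaps: bool = True
    ambiguous_matches_nothing: bool = True

    def __post_init__(self) -> None:
        if self.n_best < 1:
            raise SearchError("n_best must be >= 1")
        if self.chunk_rows < 1:
            raise SearchError("chunk_rows must be >= 1")
        if self.workers < 1:
            raise SearchError("workers must be >= 1")


@dataclass(frozen=True)
class SearchHit:
    """One ranked hit: identity plus the index pair resolving to metadata."""

    query_id: str
    region: str
    identity: float
    index_pair: tuple[int, int]
    db_row: int
    rank: int


@dataclass
class SearchResults:
    """Hits grouped by (query id, region name), each group rank-ordered."""

    hits: dict[tuple[str, str], list[SearchHit]] = field(default_factory=dict)
    rows_scanned: int = 0

    def __getitem__(self, key: tuple[str, str]) -> list[SearchHit]:
        return self.hits[key]

    def groups(self) -> Iterable[tuple[tuple[str, str], list[SearchHit]]]:
        return self.hits.items()


def _options_for(mask: RegionMask, config: SearchConfig) -> IdentityOptions:
    return IdentityOptions(
        length_matched=mask.length_matched,
        include_terminal_gaps=config.include_terminal_gaps,
        ambiguous_matches_nothing=config.ambiguous_matches_nothing)


def search(queries: Sequence[Query], db: ShardedDatabase,
           config: SearchConfig) -> SearchResults:
    """Exhaustively scan the database for the top hits per query and region.

    Queries must be encoded under the database's scheme (length is checked;
    encode them with :func:`absearch.canonical.encode` against
    ``db.scheme``).  Partition selection defaults to all partitions of each
    query's chain type (all partitions when the query has no chain label
    and no selector is configured).
    """
    if not queries:
        raise SearchError("no queries given")
    if len(config.regions) == 0:
        raise SearchError("empty region suite")
    L = db.manifest.vector_length
    for q in queries:
        if np.asarray(q.vector).shape != (L,):
            raise SearchError(
                f"query {q.id!r} has length {np.asarray(q.vector).shape}, "
                f"database scheme {db.scheme_id[:12]} expects {L}; "
                "was it encoded under the same scheme?")

    chains = config.chains
    if chains is None:
        query_chains = {q.chain_type for q in queries if q.chain_type}
        chains = tuple(sorted(query_chains)) if query_chains else None

    accumulators: dict[tuple[str, str], list[list[tuple[int, float]]]] = {
        (q.id, m.name): [] for q in queries for m in config.regions}
    # (global_offset, index_pairs) per scanned shard, for resolving hit rows
    shard_pairs: list[tuple[int, np.ndarray]] = []
    rows_scanned = 0

    def score_chunk(chunk: np.ndarray, offset: int) -> dict[tuple[str, str], list[tuple[int, float]]]:
        out = {}
        for mask in config.regions:
            opts = _options_for(mask, config)
            for q in queries:
                idents, comp = batch_identity(q.vector, chunk, mask, opts)
                out[(q.id, mask.name)] = top_n(
                    idents, comp, config.n_best, threshold=config.threshold,
                    row_ids=np.arange(offset, offset + chunk.shape[0]))
        return out

    for shard in db.iter_shards(chains=chains, species=config.species):
        n = shard.matrix.shape[0]
        rows_scanned += n
        shard_pairs.append((shard.global_offset, shard.index_pairs))
        chunk_jobs = [(shard.matrix[s:s + config.chunk_rows],
                       shard.global_offset + s)
                      for s in range(0, n, config.chunk_rows)]
        if config.workers > 1 and len(chunk_jobs) > 1:
            with ThreadPoolExecutor(max_workers=config.workers) as pool:
                results = list(pool.map(lambda job: score_chunk(*job), chunk_jobs))
        else:
            results = [score_chunk(*job) for job in chunk_jobs]
        # merge strictly in chunk order, independent of scheduling
        for res in results:
            for key, part in res.items():
                accumulators[key] = [merge_top_n(accumulators[key] + [part],
                                                 config.n_best)]

    import bisect

    offsets = [off for off, _ in shard_pairs]

    def pair_of(row: int) -> tuple[int, int]:
        i = bisect.bisect_right(offsets, row) - 1
        off, pairs = shard_pairs[i]
        return (int(pairs[row - off, 0]), int(pairs[row - off, 1]))

    results = SearchResults(rows_scanned=rows_scanned)
    for (qid, region), parts in accumulators.items():
        merged = merge_top_n(parts, config.n_best)
        results.hits[(qid, region)] = [
            SearchHit(query_id=qid, region=region, identity=ident,
                      index_pair=pair_of(row), db_row=row, rank=rank)
            for rank, (row, ident) in enumerate(merged, start=1)]
    return results


def join_metadata(hits: Sequence[SearchHit],
                  tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Expand hits into a result table: metadata columns + identity last.

    One output row per hit, in the given (rank) order; the final column is
    the identity percentage.  An unresolvable index pair raises, naming it.
    """
    if len(tables) == 0:
        raise SearchError("no metadata tables supplied")
    columns = list(tables[0].columns)
    rows = []
    for hit in hits:
        record = resolve_metadata(hit.index_pair, tables)
        row = {c: record.get(c) for c in columns}
        row[IDENTITY_COLUMN] = hit.identity
        rows.append(row)
    return pd.DataFrame(rows, columns=columns + [IDENTITY_COLUMN])


def join_all(results: SearchResults, db: ShardedDatabase) -> dict[tuple[str, str], pd.DataFrame]:
    """join_metadata for every (query, region) group of a result set."""
    tables = db.metadata_tables()
    return {key: join_metadata(hits, tables) for key, hits in results.groups()}


def summarize_hits(result_table: pd.DataFrame,
                   group_by: Union[str, Sequence[str]]) -> pd.DataFrame:
    """Count hits per value combination of the grouping columns, descending."""
    cols = [group_by] if isinstance(group_by, str) else list(group_by)
    missing = [c for c in cols if c not in result_table.columns]
    if missing:
        raise SearchError(f"grouping column(s) not in result table: {missing}")
    if result_table.empty:
        return pd.DataFrame(columns=cols + ["count"])
    counts = (result_table.groupby(cols, dropna=False).size()
              .reset_index(name="count")
              .sort_values(["count"] + cols, ascending=[False] + [True] * len(cols),
                           kind="mergesort")
              .reset_index(drop=True))
    return counts
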