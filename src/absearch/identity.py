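"""Region-masked sequence identity over aligned vectors.

Identity between two aligned sequences over a region is the percentage of
identical residues across the region's slots, counting indels present in
only one of the sequences as mismatches:

    matches     = # masked slots where both codes are equal, non-gap
                  (and not the ambiguous residue, by default)
    denominator = # masked slots where at least one code is non-gap
    identity    = 100 * matches / denominator    (0 when denominator is 0)

Because every sequence is a fixed-length vector, a query against a chunk of
N targets is a handful of elementwise numpy operations.  Matches and
denominators are exact integers; the division to a percentage happens only
at reporting time, so equal fractions are exactly equal and ordering is
reproducible (float64 represents distinct fractions with denominators up to
the scheme length distinctly).

Two variants modify the slot set or the verdict per pair:

* length-matched mode compares a pair only when both sequences have the
  same number of residues (non-gap codes) within the mask — the region
  "length" counts residues, not slot spans, so it is insertion-aware;
* terminal trimming drops masked slots lying before the later of the two
  sequences' first residues, or after the earlier of their last residues,
  so that truncated reads are not penalised for missing ends.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .canonical import AMBIGUOUS_RESIDUE, CanonicalScheme, DEFAULT_ALPHABET, GAP_CODE
from .errors import SearchError
from .regions import RegionMask

#: Integer code of the ambiguous residue under the default alphabet.
DEFAULT_X_CODE = DEFAULT_ALPHABET.index(AMBIGUOUS_RESIDUE) + 1


@dataclass(frozen=True)
class IdentityOptions:
    """Switches of the identity definition; the three flags are independent."""

    length_matched: bool = False
    include_terminal_gaps: bool = True
    ambiguous_matches_nothing: bool = True
    x_code: int = DEFAULT_X_CODE


@dataclass(frozen=True)
class IdentityResult:
    """Identity percentage plus comparability; incomparable pairs score 0."""

    identity: float
    comparable: bool
    matches: int = 0
    denominator: int = 0


def _first_last_nongap(vec: np.ndarray) -> tuple[int, int]:
    """First and last non-gap slot of a vector; (L, -1) when all-gap."""
    nz = np.flatnonzero(vec != GAP_CODE)
    if nz.size == 0:
        return len(vec), -1
    return int(nz[0]), int(nz[-1])


def trim_terminal(a: np.ndarray, b: np.ndarray, mask: RegionMask) -> np.ndarray:
    """Effective mask slots after excluding terminal missing residues.

    Removes masked slots before the later of the two first non-gap slots
    and after the earlier of the two last non-gap slots (scheme slot
    order).  Either vector being all-gap empties the effective mask.
    """
    fa, la = _first_last_nongap(np.asarray(a))
    fb, lb = _first_last_nongap(np.asarray(b))
    lo, hi = max(fa, fb), min(la, lb)
    slots = mask.slots
    return slots[(slots >= lo) & (slots <= hi)]


def batch_identity(query: np.ndarray, targets: np.ndarray, mask: RegionMask,
                   opts: IdentityOptions = IdentityOptions()
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Identity of one query against every row of a target matrix.

    Returns (identities, comparable): a float64 percentage and a bool per
    row, exactly equal to :func:`pair_identity` applied row by row.
    """
    query = np.asarray(query)
    targets = np.atleast_2d(np.asarray(targets))
    if targets.shape[0] == 0:
        return np.empty(0), np.empty(0, dtype=bool)
    if targets.shape[1] != query.shape[0]:
        raise SearchError(
            f"target vector length {targets.shape[1]} != query length {query.shape[0]}")
    slots = mask.slots
    if slots.size and slots[-1] >= query.shape[0]:
        raise SearchError("region mask exceeds vector length")

    q = query[slots]
    t = targets[:, slots]
    eq = (t == q) & (q != GAP_CODE)
    if opts.ambiguous_matches_nothing:
        eq &= q != opts.x_code
    either = (t != GAP_CODE) | (q != GAP_CODE)

    if not opts.include_terminal_gaps:
        valid = _pairwise_valid(query, targets, slots)
        eq &= valid
        either &= valid
    else:
        valid = None

    matches = eq.sum(axis=1)
    denom = either.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        identities = np.where(denom > 0, 100.0 * matches / np.maximum(denom, 1), 0.0)

    # the mask can demand length matching on its own (e.g. CDR regions)
    if opts.length_matched or mask.length_matched:
        t_nongap = t != GAP_CODE
        q_nongap = np.broadcast_to(q != GAP_CODE, t.shape)
        if valid is not None:
            t_nongap = t_nongap & valid
            q_nongap = q_nongap & valid
        comparable = t_nongap.sum(axis=1) == q_nongap.sum(axis=1)
        identities = np.where(comparable, identities, 0.0)
    else:
        comparable = np.ones(targets.shape[0], dtype=bool)
    return identities, comparable


def _pairwise_valid(query: np.ndarray, targets: np.ndarray,
                    slots: np.ndarray) -> np.ndarray:
    """Per-row boolean matrix of masked slots inside both terminal spans."""
    L = query.shape[0]
    fq, lq = _first_last_nongap(query)
    nongap = targets != GAP_CODE
    any_row = nongap.any(axis=1)
    first = np.where(any_row, nongap.argmax(axis=1), L)
    last = np.where(any_row, L - 1 - nongap[:, ::-1].argmax(axis=1), -1)
    lo = np.maximum(first, fq)[:, None]
    hi = np.minimum(last, lq)[:, None]
    return (slots[None, :] >= lo) & (slots[None, :] <= hi)


def pair_identity(a: np.ndarray, b: np.ndarray, mask: RegionMask,
                  opts: IdentityOptions = IdentityOptions()) -> IdentityResult:
    """Identity between two aligned vectors over a region."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise SearchError(f"vector shapes differ: {a.shape} vs {b.shape}")
    identities, comparable = batch_identity(a, b[None, :], mask, opts)
    # recover the exact integer counts for reporting
    slots = trim_terminal(a, b, mask) if not opts.include_terminal_gaps else mask.slots
    a, b = np.asarray(a), np.asarray(b)
    qa, qb = a[slots], b[slots]
    eq = (qa == qb) & (qa != GAP_CODE)
    if opts.ambiguous_matches_nothing:
        eq &= qa != opts.x_code
    denom = int(((qa != GAP_CODE) | (qb != GAP_CODE)).sum())
    return IdentityResult(identity=float(identities[0]), comparable=bool(comparable[0]),
                          matches=int(eq.sum()) if comparable[0] else 0,
                          denominator=denom)


def top_n(identities: np.ndarray, comparable: np.ndarray, n: int,
          threshold: Optional[float] = None,
          row_ids: Optional[np.ndarray] = None) -> list[tuple[int, float]]:
    """The n largest comparable identities, optionally at or above a threshold.

    Sorted by descending identity; ties broken by ascending row id.  Fewer
    than n pairs are returned when fewer qualify.  ``row_ids`` relabels rows
    (e.g. with global database row numbers) without changing the tie rule.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    identities = np.asarray(identities, dtype=np.float64)
    comparable = np.asarray(comparable, dtype=bool)
    rows = np.arange(identities.shape[0]) if row_ids is None else np.asarray(row_ids)
    eligible = comparable.copy()
    if threshold is not None:
        eligible &= identities >= threshold
    idx = np.flatnonzero(eligible)
    if idx.size == 0:
        return []
    order = np.lexsort((rows[idx], -identities[idx]))
    chosen = idx[order[:n]]
    return [(int(rows[i]), float(identities[i])) for i in chosen]


def merge_top_n(parts: Sequence[list[tuple[int, float]]], n: int) -> list[tuple[int, float]]:
    """Merge per-chunk top-n lists into the global top-n, re-applying the tie rule."""
    pooled = [hit for part in parts for hit in part]
    if not pooled:
        return []
    rows = np.array([r for r, _ in pooled])
    idents = np.array([v for _, v in pooled])
    return top_n(idents, np.ones(len(pooled), dtype=bool), n, row_ids=rows)


def x_code_for(scheme: CanonicalScheme) -> int:
    """The ambiguous-residue code under a scheme's alphabet (0 if absent)."""
    return scheme.codes.get(AMBIGUOUS_RESIDUE, 0)
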