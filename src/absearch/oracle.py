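"""Brute-force reference search: the independent oracle.

A deliberately slow, scalar, pair-at-a-time implementation of the identity
definition and of ranked search — a naive double loop over all
(query, target) pairs with a full sort.  It shares no code with the numpy
kernels in :mod:`absearch.identity` or the streaming machinery in
:mod:`absearch.search`; its entire value is that agreement with it is
evidence the optimised path is correct.  Only suitable for small inputs.
"""

from __future__ import annotations

from typing import Optional, Sequence


def oracle_pair_identity(a: Sequence[int], b: Sequence[int],
                         slots: Sequence[int],
                         x_code: int = 21,
                         length_matched: bool = False,
                         include_terminal_gaps: bool = True,
                         ambiguous_matches_nothing: bool = True
                         ) -> tuple[float, bool]:
    """Identity of one pair of aligned code sequences over the given slots.

    Returns (identity percentage, comparable flag); an incomparable pair
    (length-matched mode, unequal residue counts) scores 0.
    """
    use = list(slots)
    if not include_terminal_gaps:
        fa, la = _span(a)
        fb, lb = _span(b)
        lo = fa if fa > fb else fb
        hi = la if la < lb else lb
        use = [s for s in use if lo <= s <= hi]

    if length_matched:
        na = sum(1 for s in use if a[s] != 0)
        nb = sum(1 for s in use if b[s] != 0)
        if na != nb:
            return 0.0, False

    matches = 0
    denominator = 0
    for s in use:
        ca = a[s]
        cb = b[s]
        if ca != 0 or cb != 0:
            denominator += 1
            if ca == cb and ca != 0:
                if ambiguous_matches_nothing and ca == x_code:
                    continue
                matches += 1
    if denominator == 0:
        return 0.0, True
    return 100.0 * matches / denominator, True


def _span(v: Sequence[int]) -> tuple[int, int]:
    first, last = len(v), -1
    for i, c in enumerate(v):
        if c != 0:
            if first == len(v):
                first = i
            last = i
    return first, last


def oracle_search(queries: Sequence[Sequence[int]],
                  rows: Sequence[Sequence[int]],
                  slots: Sequence[int],
                  n: int,
                  threshold: Optional[float] = None,
                  x_code: int = 21,
                  length_matched: bool = False,
                  include_terminal_gaps: bool = True,
                  ambiguous_matches_nothing: bool = True
                  ) -> list[list[tuple[int, float]]]:
    """Ranked hits per query: naive all-pairs scan plus full sort.

    Returns, for each query, up to n (row index, identity) pairs sorted by
    descending identity with ties broken by ascending row index, keeping
    only comparable pairs at or above the threshold when one is given.
    """
    sorted_slots = sorted(slots)
    row_lists = [list(r) for r in rows]
    out: list[list[tuple[int, float]]] = []
    for q in queries:
        qa = list(q)
        scored: list[tuple[float, int]] = []
        for i, row in enumerate(row_lists):
            ident, comparable = oracle_pair_identity(
                qa, row, sorted_slots, x_code=x_code,
                length_matched=length_matched,
                include_terminal_gaps=include_terminal_gaps,
                ambiguous_matches_nothing=ambiguous_matches_nothing)
            if not comparable:
                continue
            if threshold is not None and ident < threshold:
                continue
            scored.append((ident, i))
        scored.sort(key=lambda t: (-t[0], t[1]))
        out.append([(i, ident) for ident, i in scored[:n]])
    return out
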