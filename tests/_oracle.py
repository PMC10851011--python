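"""Independent exhaustive-recursion oracle for affine-gap global alignment.

Deliberately written as a plain recursion over edit choices (memoized on the
suffix pair and the preceding operation) so it shares no code path with the
package's dynamic-programming aligner.
"""

from __future__ import annotations

import functools


def affine_score(
    read: str,
    ref: str,
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -8.0,
    gap_extend: float = -1.0,
) -> float:
    """Optimal global affine-gap alignment score by exhaustive recursion."""

    @functools.lru_cache(maxsize=None)
    def best(i: int, j: int, prev: str) -> float:
        if i == len(read) and j == len(ref):
            return 0.0
        options = []
        if i < len(read) and j < len(ref):
            s = match if read[i] == ref[j] else mismatch
            options.append(s + best(i + 1, j + 1, "M"))
        if j < len(ref):  # deletion: ref base unmatched
            g = gap_extend if prev == "X" else gap_open
            options.append(g + best(i, j + 1, "X"))
        if i < len(read):  # insertion: read base unmatched
            g = gap_extend if prev == "Y" else gap_open
            options.append(g + best(i + 1, j, "Y"))
        return max(options)

    result = best(0, 0, "M")
    best.cache_clear()
    return result


def optimal_alignments(
    read: str,
    ref: str,
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -8.0,
    gap_extend: float = -1.0,
    limit: int = 200,
):
    """Enumerate the op lists of every optimal alignment (tiny inputs only).

    Ops are (kind, ref_start, ref_len, alt) tuples in the package's
    convention.  Enumeration stops after ``limit`` alignments.
    """

    @functools.lru_cache(maxsize=None)
    def best(i: int, j: int, prev: str) -> float:
        if i == len(read) and j == len(ref):
            return 0.0
        options = []
        if i < len(read) and j < len(ref):
            s = match if read[i] == ref[j] else mismatch
            options.append(s + best(i + 1, j + 1, "M"))
        if j < len(ref):
            g = gap_extend if prev == "X" else gap_open
            options.append(g + best(i, j + 1, "X"))
        if i < len(read):
            g = gap_extend if prev == "Y" else gap_open
            options.append(g + best(i + 1, j, "Y"))
        return max(options)

    results = []

    def walk(i, j, prev, ops):
        if len(results) >= limit:
            return
        if i == len(read) and j == len(ref):
            results.append(tuple(ops))
            return
        target_score = best(i, j, prev)
        if i < len(read) and j < len(ref):
            s = match if read[i] == ref[j] else mismatch
            if s + best(i + 1, j + 1, "M") == target_score:
                extra = [] if read[i] == ref[j] else [("sub", j, 1, read[i])]
                walk(i + 1, j + 1, "M", ops + extra)
        if j < len(ref):
            g = gap_extend if prev == "X" else gap_open
            if g + best(i, j + 1, "X") == target_score:
                walk(i, j + 1, "X", ops + [("del", j, 1, "")])
        if i < len(read):
            g = gap_extend if prev == "Y" else gap_open
            if g + best(i + 1, j, "Y") == target_score:
                walk(i + 1, j, "Y", ops + [("ins", j, 0, read[i])])

    walk(0, 0, "M", [])
    best.cache_clear()
    return results
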