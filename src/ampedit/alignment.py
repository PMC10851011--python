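"""Affine-gap global alignment and canonical edit-operation extraction.

Each read is aligned globally against an allele reference with Gotoh's
three-state dynamic programme.  A gap of length L scores
``gap_open + (L - 1) * gap_extend`` (the opening score includes the first gap
base).  The traceback is deterministic: at equal scores, diagonal moves are
preferred over deletions (gap in the read) over insertions (gap in the
reference).  Residual positional ambiguity of indels in repeat context is
removed by :func:`normalize_ops`, which left-aligns every indel and merges
adjacent compatible operations, yielding a unique canonical representative of
the edit-equivalence class.

Allele of origin is assigned by aligning against both references; ties are
broken by the read base aligned opposite the discriminating SNV.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .errors import InputError, InternalError
from .reference import AMBIGUOUS, AlleleReference, TARGET

NEG_INF = -1e18

# traceback states
_M, _X, _Y = 0, 1, 2  # diagonal / deletion (gap in read) / insertion (gap in ref)


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring parameters for the affine-gap global aligner.

    Defaults prefer one long gap over scattered mismatches, matching the
    dominant single-indel outcomes of Cas9 editing.
    """

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -8.0
    gap_extend: float = -1.0
    end_gap_policy: str = "penalized"

    def __post_init__(self) -> None:
        if not (self.gap_open <= self.gap_extend <= 0 <= self.match):
            raise InputError("require gap_open <= gap_extend <= 0 <= match")
        if self.mismatch >= 0:
            raise InputError("mismatch score must be negative")
        if self.end_gap_policy not in ("penalized", "free_ends"):
            raise InputError("end_gap_policy must be 'penalized' or 'free_ends'")


@dataclass(frozen=True)
class EditOp:
    """One edit operation on the reference.

    ``sub``: replace ``ref_len`` bases from ``ref_start`` by ``alt`` (same length).
    ``del``: delete ``ref_len`` bases from ``ref_start`` (``alt`` empty).
    ``ins``: insert ``alt`` at inter-base position ``ref_start`` (``ref_len`` 0).
    """

    kind: str
    ref_start: int
    ref_len: int
    alt: str

    def __post_init__(self) -> None:
        ok = (
            (self.kind == "sub" and self.ref_len == len(self.alt) >= 1)
            or (self.kind == "del" and self.ref_len >= 1 and self.alt == "")
            or (self.kind == "ins" and self.ref_len == 0 and len(self.alt) >= 1)
        )
        if not ok:
            raise InternalError(f"inconsistent EditOp: {self}")

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.ref_len

    @property
    def net_delta(self) -> int:
        return len(self.alt) - self.ref_len


@dataclass(frozen=True)
class AlignmentResult:
    allele: str
    score: float
    ops: tuple[EditOp, ...]
    aligned_span: tuple[int, int]
    read_id: str = ""


_BASE_INDEX = np.full(128, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_INDEX[ord(_b)] = _i


def _encode(seq: str) -> np.ndarray:
    arr = _BASE_INDEX[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr < 0).any():
        raise InputError("sequence contains non-ACGT characters")
    return arr


@njit(cache=True)
def _gotoh_fill(a, b, match, mismatch, gap_open, gap_extend, free_ends):  # pragma: no cover
    n, m = a.shape[0], b.shape[0]
    M = np.full((n + 1, m + 1), NEG_INF)
    X = np.full((n + 1, m + 1), NEG_INF)
    Y = np.full((n + 1, m + 1), NEG_INF)
    # pointer matrices: predecessor state, -1 = origin
    Mp = np.full((n + 1, m + 1), -1, dtype=np.int8)
    Xp = np.full((n + 1, m + 1), -1, dtype=np.int8)
    Yp = np.full((n + 1, m + 1), -1, dtype=np.int8)
    M[0, 0] = 0.0
    for j in range(1, m + 1):
        if free_ends:
            X[0, j] = 0.0
        else:
            X[0, j] = gap_open + (j - 1) * gap_extend
        Xp[0, j] = _M if j == 1 else _X
    for i in range(1, n + 1):
        if free_ends:
            Y[i, 0] = 0.0
        else:
            Y[i, 0] = gap_open + (i - 1) * gap_extend
        Yp[i, 0] = _M if i == 1 else _Y
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            # M: diagonal, predecessor preference M > X > Y
            best = M[i - 1, j - 1]
            ptr = _M
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                ptr = _X
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                ptr = _Y
            M[i, j] = best + s
            Mp[i, j] = ptr
            # X: deletion (consumes ref base j); free on terminal read rows
            if free_ends and (i == 0 or i == n):
                open_s, ext_s = 0.0, 0.0
            else:
                open_s, ext_s = gap_open, gap_extend
            best = M[i, j - 1] + open_s
            ptr = _M
            if X[i, j - 1] + ext_s > best:
                best = X[i, j - 1] + ext_s
                ptr = _X
            if Y[i, j - 1] + open_s > best:
                best = Y[i, j - 1] + open_s
                ptr = _Y
            X[i, j] = best
            Xp[i, j] = ptr
            # Y: insertion (consumes read base i); free on terminal ref columns
            if free_ends and (j == 0 or j == m):
                open_s, ext_s = 0.0, 0.0
            else:
                open_s, ext_s = gap_open, gap_extend
            best = M[i - 1, j] + open_s
            ptr = _M
            if X[i - 1, j] + open_s > best:
                best = X[i - 1, j] + open_s
                ptr = _X
            if Y[i - 1, j] + ext_s > best:
                best = Y[i - 1, j] + ext_s
                ptr = _Y
            Y[i, j] = best
            Yp[i, j] = ptr
    return M, X, Y, Mp, Xp, Yp


def _traceback(read: str, ref: str, mats) -> tuple[float, list[EditOp]]:
    M, X, Y, Mp, Xp, Yp = mats
    n, m = len(read), len(ref)
    scores = (M[n, m], X[n, m], Y[n, m])
    state = int(np.argmax(scores))  # argmax returns the first max: M > X > Y
    score = float(scores[state])
    i, j = n, m
    ops: list[EditOp] = []

    def push(kind: str, ref_start: int, ref_len: int, alt: str) -> None:
        # extend the most recent op leftwards when contiguous and same kind
        if ops:
            last = ops[-1]
            if (
                kind == last.kind == "del"
                and ref_start + ref_len == last.ref_start
            ):
                ops[-1] = replace(last, ref_start=ref_start, ref_len=last.ref_len + ref_len)
                return
            if kind == last.kind == "ins" and ref_start == last.ref_start:
                ops[-1] = replace(last, alt=alt + last.alt)
                return
            if (
                kind == last.kind == "sub"
                and ref_start + ref_len == last.ref_start
            ):
                ops[-1] = replace(
                    last,
                    ref_start=ref_start,
                    ref_len=last.ref_len + ref_len,
                    alt=alt + last.alt,
                )
                return
        ops.append(EditOp(kind, ref_start, ref_len, alt))

    while i > 0 or j > 0:
        if state == _M:
            prev = Mp[i, j]
            if read[i - 1] != ref[j - 1]:
                push("sub", j - 1, 1, read[i - 1])
            i, j = i - 1, j - 1
        elif state == _X:
            prev = Xp[i, j]
            push("del", j - 1, 1, "")
            j -= 1
        else:
            prev = Yp[i, j]
            push("ins", j, 0, read[i - 1])
            i -= 1
        state = int(prev)
    ops.reverse()
    return score, ops


def apply_ops(ref_seq: str, ops: list[EditOp] | tuple[EditOp, ...]) -> str:
    """Apply edit operations to a reference sequence, returning the edited read."""
    out = []
    pos = 0
    for op in sorted(ops, key=lambda o: (o.ref_start, 0 if o.kind == "ins" else 1)):
        if op.ref_start < pos or op.ref_end > len(ref_seq):
            raise InputError(f"op {op} out of bounds or overlapping")
        out.append(ref_seq[pos: op.ref_start])
        out.append(op.alt)
        pos = op.ref_end
    out.append(ref_seq[pos:])
    return "".join(out)


def _ref_sequence(ref: AlleleReference | str) -> str:
    return ref.sequence if isinstance(ref, AlleleReference) else ref


def global_align(
    read,
    ref: AlleleReference | str,
    params: AlignmentParams | None = None,
) -> AlignmentResult:
    """Optimal affine-gap global alignment of ``read`` against ``ref``.

    ``read`` may be a :class:`~ampedit.seqio.ReadRecord` or a plain string.
    The returned operations reconstruct the read exactly when applied to the
    reference (after trimming to ``aligned_span`` under free end gaps).
    """
    params = params or AlignmentParams()
    read_id = getattr(read, "read_id", "")
    read_seq = getattr(read, "sequence", read)
    ref_seq = _ref_sequence(ref)
    if not read_seq:
        raise InputError("empty read")
    if not ref_seq:
        raise InputError("empty reference")
    allele = ref.allele if isinstance(ref, AlleleReference) else ""
    free = params.end_gap_policy == "free_ends"
    mats = _gotoh_fill(
        _encode(read_seq),
        _encode(ref_seq),
        params.match,
        params.mismatch,
        params.gap_open,
        params.gap_extend,
        free,
    )
    score, ops = _traceback(read_seq, ref_seq, mats)
    span = (0, len(ref_seq))
    if free:
        # terminal reference deletions are span trimming, not edits
        if ops and ops[0].kind == "del" and ops[0].ref_start == 0:
            span = (ops[0].ref_end, span[1])
            ops = ops[1:]
        if ops and ops[-1].kind == "del" and ops[-1].ref_end == len(ref_seq):
            span = (span[0], ops[-1].ref_start)
            ops = ops[:-1]
    return AlignmentResult(
        allele=allele,
        score=score,
        ops=tuple(ops),
        aligned_span=span,
        read_id=read_id,
    )


_KIND_RANK = {"ins": 0, "del": 1, "sub": 2}


def _merge_adjacent(ops: list[EditOp]) -> list[EditOp]:
    """Merge contiguous same-kind ops (dels/subs abutting, inss at one position)."""
    out: list[EditOp] = []
    for op in ops:
        if out:
            last = out[-1]
            if op.kind == last.kind == "del" and op.ref_start == last.ref_end:
                out[-1] = replace(last, ref_len=last.ref_len + op.ref_len)
                continue
            if op.kind == last.kind == "ins" and op.ref_start == last.ref_start:
                out[-1] = replace(last, alt=last.alt + op.alt)
                continue
            if op.kind == last.kind == "sub" and op.ref_start == last.ref_end:
                out[-1] = replace(
                    last, ref_len=last.ref_len + op.ref_len, alt=last.alt + op.alt
                )
                continue
        out.append(op)
    return out


def _shift_left(ops: list[EditOp], ref_seq: str) -> list[EditOp]:
    """Left-align indels within repeat context, never crossing earlier ops."""
    out: list[EditOp] = []
    prev_end = 0  # rightmost reference coordinate claimed by earlier ops
    for op in ops:
        if op.ref_start < prev_end or op.ref_end > len(ref_seq):
            raise InternalError(f"overlapping or out-of-bounds op {op}")
        if op.kind == "del":
            s = op.ref_start
            while s > prev_end and ref_seq[s - 1] == ref_seq[s + op.ref_len - 1]:
                s -= 1
            op = replace(op, ref_start=s)
        elif op.kind == "ins":
            s, alt = op.ref_start, op.alt
            while s > prev_end and ref_seq[s - 1] == alt[-1]:
                alt = alt[-1] + alt[:-1]
                s -= 1
            op = replace(op, ref_start=s, alt=alt)
        out.append(op)
        prev_end = max(prev_end, op.ref_end if op.kind != "ins" else op.ref_start)
    return out


def normalize_ops(
    ops: list[EditOp] | tuple[EditOp, ...], ref: AlleleReference | str
) -> tuple[EditOp, ...]:
    """Canonicalize an op list: left-align indels in repeat context and merge
    adjacent compatible operations.

    Merging and shifting are iterated to a fixed point (a shifted indel can
    become mergeable with its left neighbour and vice versa), so the result
    is the unique canonical representative of the edit-equivalence class,
    independent of which optimal alignment produced the input, and the
    function is idempotent.
    """
    ref_seq = _ref_sequence(ref)
    cur = _merge_adjacent(
        sorted(ops, key=lambda o: (o.ref_start, _KIND_RANK[o.kind]))
    )
    while True:
        nxt = _merge_adjacent(_shift_left(cur, ref_seq))
        if nxt == cur:
            return tuple(cur)
        cur = nxt


def assign_allele(
    read,
    target: AlleleReference,
    non_target: AlleleReference,
    params: AlignmentParams | None = None,
) -> tuple[str, AlignmentResult]:
    """Assign a read to its allele of origin.

    The read is aligned to both references; the higher score wins.  On a
    score tie the read base aligned opposite the discriminating SNV decides
    (alt base -> target, ref base -> non_target); if that base is deleted or
    matches neither allele the read is *ambiguous* and the alignment against
    the target reference is returned.
    """
    params = params or AlignmentParams()
    res_t = global_align(read, target, params)
    res_n = global_align(read, non_target, params)
    if res_t.score > res_n.score:
        return TARGET, res_t
    if res_n.score > res_t.score:
        return res_n.allele, res_n
    # score tie: inspect the base opposite the discriminating position
    vi = target.variant_index
    base = _read_base_at(res_t, target, vi)
    if base == target.discriminating_base:
        return TARGET, res_t
    if base == non_target.discriminating_base:
        return non_target.allele, res_n
    return AMBIGUOUS, res_t


def _read_base_at(result: AlignmentResult, ref: AlleleReference, index: int) -> str | None:
    """The read base aligned opposite reference position ``index`` (None if deleted)."""
    for op in result.ops:
        if op.kind == "ins":
            continue
        if op.ref_start <= index < op.ref_end:
            if op.kind == "del":
                return None
            return op.alt[index - op.ref_start]
    lo, hi = result.aligned_span
    if not (lo <= index < hi):
        return None
    return ref.sequence[index]
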