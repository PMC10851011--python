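"""Per-read filtering and editing-outcome classification.

Reads qualify for analysis when they contain both *indicator sequences* —
the terminal k-mers of the reference window — guaranteeing full-span
amplicons.  Sequence changes are partitioned against the editing window:
indels and base-pair exchanges inside the window are editing outcomes;
substitutions outside the window are sequencing artifacts; reads whose only
changes are indels outside the window are flagged separately and not counted
as edited.  The discriminating SNV itself is never counted as an edit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .alignment import (
    AlignmentParams,
    AlignmentResult,
    EditOp,
    assign_allele,
    normalize_ops,
)
from .errors import ConfigurationError, InputError, InternalError
from .reference import AMBIGUOUS, NON_TARGET, TARGET, AlleleReference, EditingWindow

logger = logging.getLogger(__name__)

WT = "WT"
BASE_PAIR_EXCHANGE = "base_pair_exchange"
DELETION = "deletion"
INSERTION = "insertion"
DELETION_PLUS_INSERTION = "deletion_plus_insertion"

MUTATION_CLASSES = (WT, BASE_PAIR_EXCHANGE, DELETION, INSERTION, DELETION_PLUS_INSERTION)
#: classes counted as CRISPR-induced indel outcomes ("edited")
INDEL_CLASSES = frozenset({DELETION, INSERTION, DELETION_PLUS_INSERTION})


@dataclass(frozen=True)
class FilterPolicy:
    """Read-level filter configuration.

    ``indicator_len`` terminal k-mers of the reference window must both occur
    in the read, in order.  ``min_read_len`` defaults to reference length
    minus 30 when left unset.  Samples with fewer than
    ``min_reads_per_sample`` filtered reads trigger a warning (not an abort).
    """

    indicator_len: int = 15
    indicator_mode: str = "exact"
    min_reads_per_sample: int = 10000
    min_read_len: int | None = None

    def __post_init__(self) -> None:
        if self.indicator_len < 5:
            raise ConfigurationError("indicator_len must be >= 5")
        if self.indicator_mode not in ("exact", "max_1_mismatch"):
            raise ConfigurationError("indicator_mode must be 'exact' or 'max_1_mismatch'")

    def validate_for(self, ref_len: int) -> None:
        if 2 * self.indicator_len >= ref_len:
            raise ConfigurationError(
                f"indicator_len {self.indicator_len} too large for reference length {ref_len}"
            )

    def effective_min_read_len(self, ref_len: int) -> int:
        return self.min_read_len if self.min_read_len is not None else max(0, ref_len - 30)


@dataclass(frozen=True)
class IndelVariant:
    """Canonical description of the within-window edit of one read.

    ``key`` is built from the left-normalized within-window ops with offsets
    relative to the cut site: per-op tokens ``kind|offset|ref_len|alt``
    joined by ``;``.  ``display_label`` follows the field's shorthand
    (del9, insA, insT, delins..., sub...).
    """

    key: str
    net_delta: int
    display_label: str

    @classmethod
    def from_ops(cls, ops: tuple[EditOp, ...], cut_site: int) -> "IndelVariant":
        if not ops:
            raise InternalError("IndelVariant requires at least one op")
        tokens = [
            f"{op.kind}|{op.ref_start - cut_site}|{op.ref_len}|{op.alt}" for op in ops
        ]
        key = ";".join(tokens)
        net = sum(op.net_delta for op in ops)
        return cls(key=key, net_delta=net, display_label=_display_label(ops))


def _display_label(ops: tuple[EditOp, ...]) -> str:
    kinds = {op.kind for op in ops}
    n_del = sum(op.ref_len for op in ops if op.kind == "del")
    ins_bases = "".join(op.alt for op in ops if op.kind == "ins")
    sub_bases = "".join(op.alt for op in ops if op.kind == "sub")
    if kinds == {"del"}:
        return f"del{n_del}"
    if kinds == {"ins"}:
        return f"ins{ins_bases}"
    if kinds == {"sub"}:
        return f"sub{sub_bases}"
    if "del" in kinds and "ins" in kinds:
        return f"delins{n_del}+{ins_bases}"
    # indel plus substitution mixtures
    label = ""
    if n_del:
        label += f"del{n_del}"
    if ins_bases:
        label += f"ins{ins_bases}"
    if sub_bases:
        label += f"sub{sub_bases}"
    return label


def parse_variant_key(key: str, cut_site: int) -> tuple[EditOp, ...]:
    """Inverse of :meth:`IndelVariant.from_ops`: key string to absolute ops."""
    ops = []
    for token in key.split(";"):
        try:
            kind, offset, ref_len, alt = token.split("|")
            ops.append(EditOp(kind, int(offset) + cut_site, int(ref_len), alt))
        except (ValueError, InternalError) as exc:
            raise InputError(f"unparseable variant key token {token!r}") from exc
    return tuple(ops)


@dataclass(frozen=True)
class EditCall:
    """Editing outcome of one read."""

    read_id: str
    allele: str
    mutation_class: str
    variant: IndelVariant | None
    artifact_subs: int = 0
    offwindow_indels: int = 0
    passed_filter: bool = True


def _occurs(read_seq: str, kmer: str, start: int, mode: str) -> int:
    """Leftmost match position of ``kmer`` in ``read_seq[start:]``, or -1."""
    if mode == "exact":
        return read_seq.find(kmer, start)
    k = len(kmer)
    for i in range(start, len(read_seq) - k + 1):
        mism = 0
        for a, b in zip(read_seq[i: i + k], kmer):
            if a != b:
                mism += 1
                if mism > 1:
                    break
        if mism <= 1:
            return i
    return -1


def passes_indicator_filter(
    read, target: AlleleReference, policy: FilterPolicy | None = None
) -> bool:
    """True iff both indicator k-mers occur in the read, in order.

    The indicators are the first and last ``indicator_len`` bases of the
    target reference window (identical on both alleles whenever the flank is
    non-zero, so the filter is allele-neutral).
    """
    policy = policy or FilterPolicy()
    policy.validate_for(len(target))
    seq = getattr(read, "sequence", read)
    k = policy.indicator_len
    up = target.sequence[:k]
    down = target.sequence[-k:]
    i = _occurs(seq, up, 0, policy.indicator_mode)
    if i < 0:
        return False
    return _occurs(seq, down, i + k, policy.indicator_mode) >= 0


def classify_read(
    aln: AlignmentResult,
    window: EditingWindow,
    ref: AlleleReference | None = None,
) -> EditCall:
    """Classify one aligned read against the editing window.

    Ops are partitioned into within-window (overlapping the base range, or an
    insertion at an inter-base position of the insertion range) and outside.
    A substitution at the discriminating SNV position is dropped entirely
    (it reflects allele identity, not editing).  The mutation class follows
    the within-window ops: deletion and insertion present ->
    deletion_plus_insertion; deletion only -> deletion; insertion only ->
    insertion; substitutions only -> base_pair_exchange; none -> WT.
    """
    lo, hi = window.base_range
    if window.ref_length and (lo < 0 or hi > window.ref_length):
        raise InternalError("editing window outside reference")
    ops = aln.ops
    if ref is not None:
        ops = tuple(_drop_discriminating_sub(ops, ref.variant_index))
    within: list[EditOp] = []
    artifact_subs = 0
    offwindow_indels = 0
    for op in ops:
        if op.kind == "ins":
            inside = window.contains_insertion(op.ref_start)
        else:
            inside = window.overlaps(op.ref_start, op.ref_len)
        if inside:
            within.append(op)
        elif op.kind == "sub":
            artifact_subs += 1
        else:
            offwindow_indels += 1
    kinds = {op.kind for op in within}
    if not kinds:
        mclass = WT
    elif "del" in kinds and "ins" in kinds:
        mclass = DELETION_PLUS_INSERTION
    elif "del" in kinds:
        mclass = DELETION
    elif "ins" in kinds:
        mclass = INSERTION
    else:
        mclass = BASE_PAIR_EXCHANGE
    variant = (
        IndelVariant.from_ops(tuple(within), window.cut_site) if within else None
    )
    return EditCall(
        read_id=aln.read_id,
        allele=aln.allele,
        mutation_class=mclass,
        variant=variant,
        artifact_subs=artifact_subs,
        offwindow_indels=offwindow_indels,
    )


def _drop_discriminating_sub(ops: tuple[EditOp, ...], variant_index: int):
    """Remove the substituted base at the discriminating position, splitting
    multi-base substitutions if needed."""
    for op in ops:
        if op.kind != "sub" or not (op.ref_start <= variant_index < op.ref_end):
            yield op
            continue
        left_len = variant_index - op.ref_start
        if left_len:
            yield EditOp("sub", op.ref_start, left_len, op.alt[:left_len])
        right_len = op.ref_end - variant_index - 1
        if right_len:
            yield EditOp("sub", variant_index + 1, right_len, op.alt[left_len + 1:])


@dataclass
class SampleAccounting:
    """Read accounting for one sample."""

    n_input: int = 0
    n_failed_indicator: int = 0
    n_too_short: int = 0
    n_filtered: int = 0
    n_target: int = 0
    n_non_target: int = 0
    n_ambiguous: int = 0
    class_counts: dict = field(default_factory=dict)
    below_threshold: bool = False

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "n_input", "n_failed_indicator", "n_too_short", "n_filtered",
            "n_target", "n_non_target", "n_ambiguous", "below_threshold")}
        d["class_counts"] = dict(self.class_counts)
        return d


def call_sample(
    reads,
    target: AlleleReference,
    non_target: AlleleReference,
    window: EditingWindow,
    params: AlignmentParams | None = None,
    policy: FilterPolicy | None = None,
) -> tuple[list[EditCall], SampleAccounting]:
    """Filter, align, assign and classify every read of one sample.

    Alignment results are memoized by read sequence, which makes deep
    amplicon samples (many identical reads) cheap.  Emits a warning when the
    number of filtered reads falls below the policy threshold.
    """
    params = params or AlignmentParams()
    policy = policy or FilterPolicy()
    policy.validate_for(len(target))
    min_len = policy.effective_min_read_len(len(target))
    acct = SampleAccounting()
    calls: list[EditCall] = []
    cache: dict[str, EditCall] = {}
    for read in reads:
        acct.n_input += 1
        seq = getattr(read, "sequence", read)
        read_id = getattr(read, "read_id", f"read{acct.n_input}")
        if len(seq) < min_len:
            acct.n_too_short += 1
            continue
        if not passes_indicator_filter(seq, target, policy):
            acct.n_failed_indicator += 1
            continue
        acct.n_filtered += 1
        cached = cache.get(seq)
        if cached is None:
            allele, aln = assign_allele(seq, target, non_target, params)
            aln = AlignmentResult(
                allele=allele,
                score=aln.score,
                ops=normalize_ops(aln.ops, target if allele != NON_TARGET else non_target),
                aligned_span=aln.aligned_span,
            )
            ref_for_class = target if allele != NON_TARGET else non_target
            cached = classify_read(aln, window, ref=ref_for_class)
            cache[seq] = cached
        call = EditCall(
            read_id=read_id,
            allele=cached.allele,
            mutation_class=cached.mutation_class,
            variant=cached.variant,
            artifact_subs=cached.artifact_subs,
            offwindow_indels=cached.offwindow_indels,
        )
        calls.append(call)
        if call.allele == TARGET:
            acct.n_target += 1
        elif call.allele == NON_TARGET:
            acct.n_non_target += 1
        else:
            acct.n_ambiguous += 1
        acct.class_counts[call.mutation_class] = (
            acct.class_counts.get(call.mutation_class, 0) + 1
        )
    if acct.n_filtered < policy.min_reads_per_sample:
        acct.below_threshold = True
        logger.warning(
            "sample below %d filtered reads (%d)",
            policy.min_reads_per_sample,
            acct.n_filtered,
        )
    return calls, acct
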