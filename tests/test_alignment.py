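import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ampedit.alignment import (
    AlignmentParams,
    EditOp,
    apply_ops,
    assign_allele,
    global_align,
    normalize_ops,
)
from ampedit.errors import InputError

from _oracle import affine_score, optimal_alignments

DNA = st.text(alphabet="ACGT", min_size=1, max_size=12)


def test_identity_alignment_has_no_ops():
    res = global_align("ACGTACGT", "ACGTACGT")
    assert res.score == 2.0 * 8
    assert res.ops == ()


def test_single_deletion_example():
    # oracle-confirmed optimum: 4 matches and one opened 1-base gap
    read, ref = "ACGT", "ACGGT"
    assert affine_score(read, ref) == 4 * 2 - 8
    res = global_align(read, ref)
    assert res.score == 0
    ops = normalize_ops(res.ops, ref)
    assert len(ops) == 1 and ops[0].kind == "del" and ops[0].ref_len == 1
    assert ops[0].ref_start == 2  # left-aligned within the GG repeat


def test_single_insertion_example():
    read, ref = "ACGTTACGT", "ACGTACGT"
    assert affine_score(read, ref) == 8 * 2 - 8
    res = global_align(read, ref)
    assert res.score == 8
    ops = normalize_ops(res.ops, ref)
    assert len(ops) == 1 and ops[0].kind == "ins" and ops[0].alt == "T"
    assert ops[0].ref_start == 3  # left-aligned within the TT repeat


def test_empty_read_is_rejected():
    with pytest.raises(InputError):
        global_align("", "ACGT")


def test_invalid_params_rejected():
    with pytest.raises(InputError):
        AlignmentParams(gap_open=-1, gap_extend=-8)
    with pytest.raises(InputError):
        AlignmentParams(mismatch=1)


@settings(max_examples=300, deadline=None, derandomize=True)
@given(read=DNA, ref=DNA)
def test_score_matches_recursive_oracle_and_ops_reconstruct(read, ref):
    res = global_align(read, ref)
    assert res.score == affine_score(read, ref)
    assert apply_ops(ref, list(res.ops)) == read
    assert apply_ops(ref, list(normalize_ops(res.ops, ref))) == read


def test_score_matches_oracle_on_random_pair_sample():
    rng = np.random.default_rng(42)
    bases = np.array(list("ACGT"))
    for _ in range(1500):
        n, m = rng.integers(1, 13, size=2)
        read = "".join(bases[rng.integers(0, 4, n)])
        ref = "".join(bases[rng.integers(0, 4, m)])
        assert global_align(read, ref).score == affine_score(read, ref)


def test_biopython_cross_check_on_random_pairs():
    """Independent affine-gap score cross-check against Bio.Align."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -8
    aligner.extend_gap_score = -1
    rng = np.random.default_rng(7)
    bases = np.array(list("ACGT"))
    for _ in range(200):
        n, m = rng.integers(1, 30, size=2)
        read = "".join(bases[rng.integers(0, 4, n)])
        ref = "".join(bases[rng.integers(0, 4, m)])
        assert global_align(read, ref).score == aligner.score(ref, read)


def test_normalize_left_shifts_deletion_in_repeat():
    ref = "CAAAG"
    ops = normalize_ops([EditOp("del", 3, 1, "")], ref)
    assert ops == (EditOp("del", 1, 1, ""),)


def test_normalize_left_shifts_insertion_in_repeat():
    ref = "GTTTC"
    ops = normalize_ops([EditOp("ins", 4, 0, "T")], ref)
    assert ops == (EditOp("ins", 1, 0, "T"),)


def test_normalize_is_fixed_point_outside_repeats():
    ref = "ACGTACGT"
    ops = (EditOp("del", 4, 1, ""),)
    assert normalize_ops(ops, ref) == ops


def test_normalize_merges_adjacent_ops():
    ref = "ACGTACGTAC"
    merged = normalize_ops(
        [EditOp("del", 4, 1, ""), EditOp("del", 5, 1, "")], ref
    )
    assert merged == (EditOp("del", 4, 2, ""),)
    merged = normalize_ops(
        [EditOp("sub", 4, 1, "G"), EditOp("sub", 5, 1, "T")], ref
    )
    assert merged == (EditOp("sub", 4, 2, "GT"),)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    ref=st.text(alphabet="ACGT", min_size=4, max_size=12),
    start=st.integers(min_value=0, max_value=11),
    length=st.integers(min_value=1, max_value=3),
)
def test_normalize_idempotent_and_tie_invariant_for_injected_deletions(ref, start, length):
    """Every optimal alignment of a deletion-carrying read canonicalizes to
    the same op list, and normalization is idempotent."""
    if start + length >= len(ref):
        return
    read = ref[:start] + ref[start + length:]
    canonical = set()
    for raw in optimal_alignments(read, ref):
        ops = [EditOp(*o) for o in raw]
        norm = normalize_ops(ops, ref)
        assert normalize_ops(norm, ref) == norm
        canonical.add(norm)
    assert len(canonical) == 1


def test_assign_allele_exact_reads(demo):
    target, non_target = demo.target, demo.non_target
    allele, res = assign_allele(target.sequence, target, non_target)
    assert allele == "target" and res.ops == ()
    allele, res = assign_allele(non_target.sequence, target, non_target)
    assert allele == "non_target" and res.ops == ()


def test_assign_allele_with_distant_deletion(demo):
    """A 2-base deletion far from the variant keeps the allele decidable."""
    target, non_target = demo.target, demo.non_target
    read = non_target.sequence[:20] + non_target.sequence[22:]
    allele, res = assign_allele(read, target, non_target)
    assert allele == "non_target"
    # score difference equals the mismatch-vs-match swing at the SNV
    t_res = global_align(read, target)
    assert res.score - t_res.score == 2 - (-3)


def test_assign_allele_ambiguous_when_deletion_spans_variant(demo):
    target, non_target = demo.target, demo.non_target
    vi = target.variant_index
    read = target.sequence[: vi - 2] + target.sequence[vi + 3:]  # del5 over the SNV
    allele, res = assign_allele(read, target, non_target)
    assert allele == "ambiguous"
    assert res.allele == "target"  # result reported against the target reference


def test_free_end_gaps_do_not_penalize_truncated_reads():
    ref = "ACCTGATCGGATCCTAGCAT"
    read = ref[4:16]
    params = AlignmentParams(end_gap_policy="free_ends")
    res = global_align(read, ref, params)
    assert res.score == 2.0 * len(read)
    assert res.aligned_span == (4, 16)
    assert res.ops == ()
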