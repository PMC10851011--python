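import logging

import pytest

from ampedit.alignment import global_align, normalize_ops
from ampedit.classify import (
    FilterPolicy,
    IndelVariant,
    call_sample,
    classify_read,
    parse_variant_key,
    passes_indicator_filter,
)
from ampedit.errors import ConfigurationError
from ampedit.seqio import ReadRecord


def _classify(read_seq, demo, guide="B"):
    """Align a read to the target reference, normalize and classify."""
    target = demo.target
    res = global_align(read_seq, target)
    res = res.__class__(
        allele=res.allele,
        score=res.score,
        ops=normalize_ops(res.ops, target),
        aligned_span=res.aligned_span,
    )
    return classify_read(res, demo.windows[guide], ref=target)


def test_wt_read_classifies_as_wt(demo):
    call = _classify(demo.target.sequence, demo)
    assert call.mutation_class == "WT"
    assert call.variant is None and call.artifact_subs == 0


def test_substitution_outside_window_is_artifact(demo):
    cut = demo.windows["B"].cut_site
    pos = cut + 7  # outside the +/-5 window
    seq = demo.target.sequence
    read = seq[:pos] + ("A" if seq[pos] != "A" else "G") + seq[pos + 1:]
    call = _classify(read, demo)
    assert call.mutation_class == "WT"
    assert call.artifact_subs == 1


def test_substitution_inside_window_is_base_pair_exchange(demo):
    cut = demo.windows["B"].cut_site
    pos = cut + 2
    seq = demo.target.sequence
    read = seq[:pos] + ("G" if seq[pos] != "G" else "T") + seq[pos + 1:]
    call = _classify(read, demo)
    assert call.mutation_class == "base_pair_exchange"
    assert call.variant is not None and call.variant.display_label.startswith("sub")


def test_del9_spanning_cut_is_deletion_del9(demo):
    cut = demo.windows["B"].cut_site
    seq = demo.target.sequence
    read = seq[: cut - 4] + seq[cut + 5:]
    call = _classify(read, demo)
    assert call.mutation_class == "deletion"
    assert call.variant.display_label == "del9"
    assert call.variant.net_delta == -9


def test_offwindow_indel_is_flagged_not_edited(demo):
    seq = demo.target.sequence
    read = seq[:20] + seq[21:]  # 1-bp deletion between indicator and window
    call = _classify(read, demo)
    assert call.mutation_class == "WT"
    assert call.offwindow_indels == 1
    assert call.variant is None


def test_discriminating_base_never_counts_as_edit(demo):
    """A read matching the OTHER allele, forced against this reference,
    shows no base_pair_exchange at the SNV."""
    res = global_align(demo.non_target.sequence, demo.target)
    res = res.__class__(
        allele=res.allele, score=res.score,
        ops=normalize_ops(res.ops, demo.target), aligned_span=res.aligned_span,
    )
    for guide in ("A", "B"):
        call = classify_read(res, demo.windows[guide], ref=demo.target)
        assert call.mutation_class == "WT"
        assert call.artifact_subs == 0


def test_variant_key_round_trips(demo):
    win = demo.windows["B"]
    seq = demo.target.sequence
    read = seq[: win.cut_site - 4] + seq[win.cut_site + 5:]
    call = _classify(read, demo)
    ops = parse_variant_key(call.variant.key, win.cut_site)
    assert IndelVariant.from_ops(ops, win.cut_site).key == call.variant.key


def test_indicator_filter_rules(demo):
    target = demo.target
    assert passes_indicator_filter(target.sequence, target)
    assert not passes_indicator_filter(target.sequence[:-20], target)
    cut = demo.windows["B"].cut_site
    central_del = target.sequence[: cut - 4] + target.sequence[cut + 5:]
    assert passes_indicator_filter(central_del, target)


def test_indicator_filter_max_1_mismatch_mode(demo):
    target = demo.target
    policy = FilterPolicy(indicator_mode="max_1_mismatch")
    seq = target.sequence
    mutated = seq[:3] + ("A" if seq[3] != "A" else "G") + seq[4:]
    assert not passes_indicator_filter(mutated, target, FilterPolicy())
    assert passes_indicator_filter(mutated, target, policy)


def test_filter_policy_validation(demo):
    with pytest.raises(ConfigurationError):
        FilterPolicy(indicator_len=3)
    with pytest.raises(ConfigurationError):
        FilterPolicy(indicator_len=41).validate_for(81)


def _reads(seqs):
    return [ReadRecord(f"r{i}", s) for i, s in enumerate(seqs)]


def test_call_sample_mixed_fixture(demo, caplog):
    """6 target-WT + 3 target-del9 + 1 non-target-WT reads."""
    t, nt = demo.target, demo.non_target
    cut = demo.windows["B"].cut_site
    del9 = t.sequence[: cut - 4] + t.sequence[cut + 5:]
    seqs = [t.sequence] * 6 + [del9] * 3 + [nt.sequence]
    with caplog.at_level(logging.WARNING):
        calls, acct = call_sample(_reads(seqs), t, nt, demo.windows["B"])
    assert acct.n_input == acct.n_filtered == 10
    assert acct.n_target == 9 and acct.n_non_target == 1 and acct.n_ambiguous == 0
    edited = [c for c in calls if c.mutation_class == "deletion"]
    assert len(edited) == 3
    assert acct.below_threshold  # 10 < 10,000
    assert any("below" in rec.message for rec in caplog.records)


def test_call_sample_counts_invariant_under_read_order(demo):
    t, nt = demo.target, demo.non_target
    cut = demo.windows["B"].cut_site
    del9 = t.sequence[: cut - 4] + t.sequence[cut + 5:]
    seqs = [t.sequence] * 4 + [del9] * 2 + [nt.sequence] * 3
    _, a1 = call_sample(_reads(seqs), t, nt, demo.windows["B"])
    _, a2 = call_sample(_reads(list(reversed(seqs))), t, nt, demo.windows["B"])
    assert a1.as_dict() == a2.as_dict()


def test_call_sample_drops_short_reads(demo):
    t, nt = demo.target, demo.non_target
    short = t.sequence[:40]
    calls, acct = call_sample(_reads([short, t.sequence]), t, nt, demo.windows["B"])
    assert acct.n_too_short == 1 and acct.n_filtered == 1
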