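import numpy as np
import pytest

from ampedit.classify import EditCall, IndelVariant
from ampedit.errors import InputError
from ampedit.profiling import (
    compare_profiles,
    implied_cell_fraction,
    load_predicted_profile,
    replicate_concordance,
    summarize,
)


def _call(i, allele, mclass, key=None, label=None):
    variant = None
    if key is not None:
        variant = IndelVariant(key=key, net_delta=-9, display_label=label or key)
    return EditCall(read_id=f"r{i}", allele=allele, mutation_class=mclass, variant=variant)


def _fixture_calls():
    calls = [_call(i, "target", "WT") for i in range(6)]
    calls += [_call(6 + i, "target", "deletion", key="del|-4|9|", label="del9") for i in range(3)]
    calls.append(_call(9, "non_target", "WT"))
    return calls


def test_summarize_efficiencies_and_spectrum():
    profile = summarize(_fixture_calls(), sample_id="s1")
    assert profile.n_filtered == 10
    assert profile.n_target == 9 and profile.n_non_target == 1
    assert profile.efficiency_all_alleles == pytest.approx(30.0)
    assert profile.efficiency_within_target == pytest.approx(100 * 3 / 9)
    assert profile.spectrum[0].pct_of_edited_target == pytest.approx(100.0)
    assert profile.spectrum[0].display_label == "del9"


def test_summarize_all_non_target_gives_zero_efficiency():
    calls = [_call(i, "non_target", "WT") for i in range(5)]
    profile = summarize(calls)
    assert profile.efficiency_all_alleles == 0.0
    assert profile.spectrum == []


def test_summarize_empty_calls_yields_zero_profile():
    profile = summarize([])
    assert profile.n_filtered == 0
    assert profile.efficiency_all_alleles is None
    assert profile.spectrum == []


def test_efficiency_all_alleles_bounded_by_within_target():
    profile = summarize(_fixture_calls())
    assert profile.efficiency_all_alleles <= profile.efficiency_within_target


def test_spectrum_percentages_scale_invariant():
    calls = _fixture_calls()
    p1 = summarize(calls)
    p2 = summarize(calls + [
        EditCall(read_id=f"d{i}", allele=c.allele, mutation_class=c.mutation_class,
                 variant=c.variant)
        for i, c in enumerate(calls)
    ])
    assert p1.spectrum_pcts() == p2.spectrum_pcts()
    assert p1.efficiency_all_alleles == p2.efficiency_all_alleles


@pytest.mark.parametrize(
    "efficiency,expected", [(21.0, 42.0), (30.0, 60.0), (0.0, 0.0), (60.0, 100.0)]
)
def test_implied_cell_fraction(efficiency, expected):
    assert implied_cell_fraction(efficiency) == expected


def test_implied_cell_fraction_rejects_out_of_range():
    with pytest.raises(InputError):
        implied_cell_fraction(-1)
    with pytest.raises(InputError):
        implied_cell_fraction(101)


def test_compare_identical_spectra():
    spec = {"del9": 60.0, "insA": 40.0}
    cmp = compare_profiles(spec, dict(spec))
    assert cmp.pearson_r == pytest.approx(1.0)
    assert cmp.total_variation_distance == 0.0
    assert cmp.top_variant_match


def test_compare_disjoint_single_variant_spectra():
    cmp = compare_profiles({"del9": 100.0}, {"insT": 100.0})
    assert cmp.total_variation_distance == pytest.approx(1.0)
    assert not cmp.top_variant_match


def test_compare_tvd_hand_example():
    cmp = compare_profiles({"del9": 60.0, "insA": 40.0}, {"del9": 40.0, "insA": 60.0})
    assert cmp.total_variation_distance == pytest.approx(0.2)


def test_compare_rejects_zero_mass():
    with pytest.raises(InputError):
        compare_profiles({}, {"del9": 100.0})
    with pytest.raises(InputError):
        compare_profiles({"del9": 0.0}, {"del9": 100.0})


def test_replicate_concordance_identical_profiles():
    p = summarize(_fixture_calls(), sample_id="a")
    q = summarize(_fixture_calls(), sample_id="b")
    pairs, mean_r = replicate_concordance([p, q])
    assert len(pairs) == 1 and mean_r == pytest.approx(1.0)
    with pytest.raises(InputError):
        replicate_concordance([p])


def test_replicate_concordance_three_profiles_gives_three_pairs():
    profiles = [summarize(_fixture_calls(), sample_id=s) for s in "abc"]
    pairs, _ = replicate_concordance(profiles)
    assert len(pairs) == 3


def test_replicate_concordance_binomial_sampling():
    """Profiles drawn from the same spectrum at n=10,000 edited reads
    correlate above 0.95."""
    rng = np.random.default_rng(11)
    keys = ["del|-4|9|", "ins|0|0|A", "ins|-1|0|T", "del|-1|2|"]
    probs = [0.49, 0.27, 0.12, 0.12]
    profiles = []
    for rep in range(3):
        counts = rng.multinomial(10000, probs)
        calls = []
        i = 0
        for key, count in zip(keys, counts):
            for _ in range(count):
                calls.append(_call(i, "target", "deletion" if key.startswith("del") else "insertion", key=key))
                i += 1
        profiles.append(summarize(calls, sample_id=f"rep{rep}"))
    _, mean_r = replicate_concordance(profiles)
    assert mean_r > 0.95


def test_load_predicted_profile_renormalizes(tmp_path, demo):
    path = tmp_path / "predicted.tsv"
    path.write_text("variant\tfrequency\ndel9@-4\t49\ninsA@0\t27\n")
    spectrum = load_predicted_profile(path, demo.windows["B"], demo.target)
    assert sum(spectrum.values()) == pytest.approx(100.0)
    assert sorted(spectrum.values()) == pytest.approx(sorted([100 * 49 / 76, 100 * 27 / 76]))
    assert "del|-4|9|" in spectrum


def test_load_predicted_profile_single_row_is_100(tmp_path, demo):
    path = tmp_path / "predicted.tsv"
    path.write_text("variant\tfrequency\ndel9@-4\t100\n")
    spectrum = load_predicted_profile(path, demo.windows["B"], demo.target)
    assert list(spectrum.values()) == [pytest.approx(100.0)]


def test_load_predicted_profile_rejects_bad_rows(tmp_path, demo):
    bad = tmp_path / "bad.tsv"
    bad.write_text("variant\tfrequency\nwhat?\t50\n")
    with pytest.raises(Exception) as err:
        load_predicted_profile(bad, demo.windows["B"], demo.target)
    assert "line 2" in str(err.value)
    neg = tmp_path / "neg.tsv"
    neg.write_text("variant\tfrequency\ndel9@-4\t-5\n")
    with pytest.raises(InputError):
        load_predicted_profile(neg, demo.windows["B"], demo.target)
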