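"""Sample-level aggregation: editing efficiencies, indel spectra and
profile comparisons.

Editing efficiency is reported with two denominators: out of all filtered
alleles (the headline "indel frequency out of all sequenced alleles") and
within the target allele only.  A read counts as *edited* when its mutation
class is an indel class (deletion, insertion, deletion_plus_insertion);
within-window base-pair exchanges are tallied as their own outcome class.
Under the diploid, uni-allelic-target assumption an all-allele efficiency of
x% implies that min(100, 2x)% of cells carry an edit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .alignment import EditOp, normalize_ops
from .classify import (
    INDEL_CLASSES,
    EditCall,
    IndelVariant,
    parse_variant_key,
)
from .errors import InputError, InternalError, ParseError
from .reference import NON_TARGET, TARGET, AlleleReference, EditingWindow


@dataclass(frozen=True)
class SpectrumEntry:
    key: str
    display_label: str
    mutation_class: str
    count: int
    pct_of_filtered: float | None
    pct_of_edited_target: float | None


@dataclass
class EditingProfile:
    """Aggregate editing outcome of one sample."""

    sample_id: str
    n_input: int = 0
    n_filtered: int = 0
    n_target: int = 0
    n_non_target: int = 0
    n_ambiguous: int = 0
    n_edited_target: int = 0
    n_edited_non_target: int = 0
    n_bpx_target: int = 0
    n_offwindow_indel_reads: int = 0
    n_artifact_sub_reads: int = 0
    spectrum: list[SpectrumEntry] = field(default_factory=list)
    below_threshold: bool = False

    def _pct(self, num: int, den: int) -> float | None:
        return 100.0 * num / den if den else None

    @property
    def efficiency_all_alleles(self) -> float | None:
        return self._pct(self.n_edited_target, self.n_filtered)

    @property
    def efficiency_within_target(self) -> float | None:
        return self._pct(self.n_edited_target, self.n_target)

    @property
    def non_target_editing(self) -> float | None:
        return self._pct(self.n_edited_non_target, self.n_filtered)

    def spectrum_pcts(self) -> dict[str, float]:
        """Mapping variant key -> percent of edited target reads."""
        return {
            e.key: e.pct_of_edited_target
            for e in self.spectrum
            if e.pct_of_edited_target is not None
        }

    def summary_rows(self):
        return [
            ("sample_id", self.sample_id),
            ("n_input", self.n_input),
            ("n_filtered", self.n_filtered),
            ("n_target", self.n_target),
            ("n_non_target", self.n_non_target),
            ("n_ambiguous", self.n_ambiguous),
            ("n_edited_target", self.n_edited_target),
            ("n_edited_non_target", self.n_edited_non_target),
            ("n_base_pair_exchange_target", self.n_bpx_target),
            ("n_offwindow_indel_reads", self.n_offwindow_indel_reads),
            ("n_artifact_sub_reads", self.n_artifact_sub_reads),
            ("efficiency_all_alleles_pct", self.efficiency_all_alleles),
            ("efficiency_within_target_pct", self.efficiency_within_target),
            ("non_target_editing_pct", self.non_target_editing),
            ("implied_cell_fraction_pct",
             implied_cell_fraction(self.efficiency_all_alleles)
             if self.efficiency_all_alleles is not None else None),
            ("below_read_threshold", self.below_threshold),
        ]

    def as_dict(self) -> dict:
        d = dict(self.summary_rows())
        d["diploid_assumption"] = (
            "implied_cell_fraction assumes a diploid genotype with a single "
            "targetable allele per cell"
        )
        d["spectrum"] = [
            {
                "variant_key": e.key,
                "display_label": e.display_label,
                "mutation_class": e.mutation_class,
                "count": e.count,
                "pct_of_filtered": e.pct_of_filtered,
                "pct_of_edited_target": e.pct_of_edited_target,
            }
            for e in self.spectrum
        ]
        return d


def summarize(calls: list[EditCall], sample_id: str = "sample",
              n_input: int | None = None, below_threshold: bool = False) -> EditingProfile:
    """Aggregate per-read calls (one sample) into an :class:`EditingProfile`.

    The spectrum collects the canonical indel variants of edited target-allele
    reads, sorted by descending count then key.
    """
    profile = EditingProfile(sample_id=sample_id)
    profile.n_input = n_input if n_input is not None else len(calls)
    profile.below_threshold = below_threshold
    counts: dict[str, list] = {}
    for call in calls:
        profile.n_filtered += 1
        if call.allele == TARGET:
            profile.n_target += 1
        elif call.allele == NON_TARGET:
            profile.n_non_target += 1
        else:
            profile.n_ambiguous += 1
        edited = call.mutation_class in INDEL_CLASSES
        if edited and call.allele == TARGET:
            profile.n_edited_target += 1
            entry = counts.setdefault(
                call.variant.key,
                [0, call.variant.display_label, call.mutation_class],
            )
            entry[0] += 1
        if edited and call.allele == NON_TARGET:
            profile.n_edited_non_target += 1
        if call.mutation_class == "base_pair_exchange" and call.allele == TARGET:
            profile.n_bpx_target += 1
        if call.offwindow_indels:
            profile.n_offwindow_indel_reads += 1
        if call.artifact_subs:
            profile.n_artifact_sub_reads += 1
    for key, (count, label, mclass) in counts.items():
        profile.spectrum.append(
            SpectrumEntry(
                key=key,
                display_label=label,
                mutation_class=mclass,
                count=count,
                pct_of_filtered=profile._pct(count, profile.n_filtered),
                pct_of_edited_target=profile._pct(count, profile.n_edited_target),
            )
        )
    profile.spectrum.sort(key=lambda e: (-e.count, e.key))
    return profile


def implied_cell_fraction(efficiency_all_alleles: float) -> float:
    """Edited-cell fraction implied by an all-allele editing efficiency.

    Under a diploid genotype where only one allele is targetable, an
    efficiency of x% out of all sequenced alleles implies min(100, 2x)% of
    cells carry an edit (21% -> 42%, 30% -> 60%).
    """
    if not (0 <= efficiency_all_alleles <= 100):
        raise InputError("efficiency must be a percentage in [0, 100]")
    return min(100.0, 2.0 * efficiency_all_alleles)


@dataclass(frozen=True)
class ProfileComparison:
    keys: tuple[str, ...]
    a: tuple[float, ...]
    b: tuple[float, ...]
    pearson_r: float
    total_variation_distance: float
    top_variant_match: bool


def compare_profiles(a: dict[str, float], b: dict[str, float]) -> ProfileComparison:
    """Compare two spectra given as mappings key -> percent of edited reads.

    Frequencies missing from one spectrum count as 0.  Reports the Pearson
    correlation over the union of keys, the total variation distance
    TVD = 0.5 * sum|a - b| / 100, and whether the top variants agree.
    """
    if not a or sum(a.values()) <= 0 or not b or sum(b.values()) <= 0:
        raise InputError("cannot compare a spectrum with zero mass")
    keys = tuple(sorted(set(a) | set(b)))
    va = np.array([a.get(k, 0.0) for k in keys])
    vb = np.array([b.get(k, 0.0) for k in keys])
    if len(keys) < 2 or np.allclose(va, va[0]) or np.allclose(vb, vb[0]):
        # degenerate: correlation undefined; identical single-key spectra correlate perfectly
        r = 1.0 if np.allclose(va, vb) else 0.0
    else:
        r = float(stats.pearsonr(va, vb).statistic)
    tvd = float(0.5 * np.abs(va - vb).sum() / 100.0)
    top_a = keys[int(np.argmax(va))]
    top_b = keys[int(np.argmax(vb))]
    return ProfileComparison(
        keys=keys,
        a=tuple(va),
        b=tuple(vb),
        pearson_r=r,
        total_variation_distance=tvd,
        top_variant_match=top_a == top_b,
    )


def replicate_concordance(profiles: list[EditingProfile]):
    """All pairwise spectrum comparisons between replicate profiles and the
    mean Pearson correlation."""
    if len(profiles) < 2:
        raise InputError("replicate concordance needs >= 2 profiles")
    pairs = []
    for i in range(len(profiles)):
        for j in range(i + 1, len(profiles)):
            cmp = compare_profiles(profiles[i].spectrum_pcts(), profiles[j].spectrum_pcts())
            pairs.append(((profiles[i].sample_id, profiles[j].sample_id), cmp))
    mean_r = float(np.mean([c.pearson_r for _, c in pairs]))
    return pairs, mean_r


_DESCRIPTOR_HELP = "expected 'del{n}@{offset}', 'ins{bases}@{offset}' or 'delins{n}+{bases}@{offset}'"


def parse_variant_descriptor(descriptor: str, window: EditingWindow) -> tuple[EditOp, ...]:
    """Parse a predicted-profile descriptor into absolute edit ops.

    Grammar: ``del{n}@{offset}`` / ``ins{bases}@{offset}`` /
    ``delins{n}+{bases}@{offset}`` with offset relative to the cut site.
    Canonical pipe-delimited variant keys are accepted as well.
    """
    descriptor = descriptor.strip()
    if "|" in descriptor:
        return parse_variant_key(descriptor, window.cut_site)
    if "@" not in descriptor:
        raise InputError(f"bad variant descriptor {descriptor!r}; {_DESCRIPTOR_HELP}")
    body, _, off = descriptor.rpartition("@")
    try:
        offset = int(off)
    except ValueError as exc:
        raise InputError(f"bad offset in descriptor {descriptor!r}") from exc
    start = window.cut_site + offset
    try:
        if body.startswith("delins"):
            n, bases = body[6:].split("+")
            return (EditOp("del", start, int(n), ""), EditOp("ins", start, 0, bases.upper()))
        if body.startswith("del"):
            return (EditOp("del", start, int(body[3:]), ""),)
        if body.startswith("ins"):
            return (EditOp("ins", start, 0, body[3:].upper()),)
        if body.startswith("sub"):
            bases = body[3:].upper()
            return (EditOp("sub", start, len(bases), bases),)
    except (ValueError, InternalError) as exc:
        raise InputError(f"bad variant descriptor {descriptor!r}; {_DESCRIPTOR_HELP}") from exc
    raise InputError(f"bad variant descriptor {descriptor!r}; {_DESCRIPTOR_HELP}")


def load_predicted_profile(
    path,
    window: EditingWindow,
    ref: AlleleReference | None = None,
) -> dict[str, float]:
    """Load a two-column predicted indel profile (variant descriptor, frequency %).

    Descriptors are parsed into canonical variant keys relative to the
    configured cut site (left-normalized against ``ref`` when given) and
    frequencies are renormalized to sum to 100.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected two columns (variant, frequency)")
    spectrum: dict[str, float] = {}
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        descriptor, freq_str = str(row[0]), str(row[1])
        try:
            freq = float(freq_str.replace(",", "."))
        except ValueError as exc:
            raise ParseError(f"{path} line {line_no}: bad frequency {freq_str!r}") from exc
        if freq < 0:
            raise InputError(f"{path} line {line_no}: negative frequency")
        try:
            ops = parse_variant_descriptor(descriptor, window)
        except InputError as exc:
            raise ParseError(f"{path} line {line_no}: {exc}") from exc
        if ref is not None:
            ops = normalize_ops(ops, ref)
        key = IndelVariant.from_ops(tuple(ops), window.cut_site).key
        spectrum[key] = spectrum.get(key, 0.0) + freq
    total = sum(spectrum.values())
    if total <= 0:
        raise InputError(f"{path}: predicted profile has zero total frequency")
    return {k: 100.0 * v / total for k, v in spectrum.items()}
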