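"""Diploid amplicon reference model.

An amplicon locus carries a single discriminating SNV: the *target* allele
(the disease allele to be edited) holds the alternate base at the centre of a
+/- ``flank`` bp window and the *non-target* allele holds the reference base.
Guides are placed on either strand of the target reference; the blunt Cas9
cut is located ``cut_offset`` bases 5' of the PAM and an editing window of
``half_width`` bases on each side of the cut defines which sequence changes
count as editing outcomes.

Coordinates are 0-based and half-open throughout; cut sites and insertion
positions are inter-base coordinates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import (
    AmbiguousGuideError,
    ConfigurationError,
    GuideNotFoundError,
    InputError,
)

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

TARGET = "target"
NON_TARGET = "non_target"
AMBIGUOUS = "ambiguous"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _check_nucleotides(seq: str, what: str) -> None:
    if not seq:
        raise InputError(f"{what} is empty")
    if re.search(r"[^ACGT]", seq):
        raise InputError(f"{what} contains non-ACGT characters")


@dataclass(frozen=True)
class VariantSpec:
    """A single-nucleotide variant and its genomic context.

    ``context`` must contain the reference base at ``variant_index`` and at
    least ``flank`` bases on each side of it.  ``label`` is display-only
    metadata (e.g. an HGVS name such as "c.1943-256C>T").
    """

    label: str
    context: str
    variant_index: int
    ref_base: str
    alt_base: str
    flank: int = 40

    def __post_init__(self) -> None:
        object.__setattr__(self, "context", self.context.upper())
        _check_nucleotides(self.context, "context")
        for base, name in ((self.ref_base, "ref_base"), (self.alt_base, "alt_base")):
            if len(base) != 1 or base not in "ACGT":
                raise InputError(f"{name} must be a single A/C/G/T base, got {base!r}")
        if self.ref_base == self.alt_base:
            raise InputError("ref_base and alt_base must differ")
        if self.flank < 1:
            raise ConfigurationError("flank must be >= 1")
        if not (0 <= self.variant_index < len(self.context)):
            raise ConfigurationError("variant_index outside context")
        if self.context[self.variant_index] != self.ref_base:
            raise InputError(
                f"context[{self.variant_index}] is "
                f"{self.context[self.variant_index]!r}, expected ref_base {self.ref_base!r}"
            )
        left = self.variant_index
        right = len(self.context) - self.variant_index - 1
        if left < self.flank or right < self.flank:
            raise ConfigurationError(
                f"context too short for flank={self.flank}: "
                f"{left} bases left / {right} bases right of the variant"
            )


@dataclass(frozen=True)
class AlleleReference:
    """One of the two amplicon reference windows (length 2*flank + 1)."""

    allele: str
    sequence: str
    variant_index: int
    discriminating_base: str

    def __post_init__(self) -> None:
        if self.allele not in (TARGET, NON_TARGET):
            raise ConfigurationError(f"allele must be target/non_target, got {self.allele!r}")
        if self.sequence[self.variant_index] != self.discriminating_base:
            raise ConfigurationError("discriminating base does not match sequence")

    def __len__(self) -> int:
        return len(self.sequence)


def build_allele_references(spec: VariantSpec) -> tuple[AlleleReference, AlleleReference]:
    """Return the (target, non_target) reference pair around the variant.

    The target reference carries the alternate base at its centre, the
    non-target reference the reference base; the two sequences are otherwise
    identical and have length ``2*flank + 1``.
    """
    lo = spec.variant_index - spec.flank
    hi = spec.variant_index + spec.flank + 1
    window = spec.context[lo:hi]
    centre = spec.flank
    non_target_seq = window
    target_seq = window[:centre] + spec.alt_base + window[centre + 1:]
    target = AlleleReference(TARGET, target_seq, centre, spec.alt_base)
    non_target = AlleleReference(NON_TARGET, non_target_seq, centre, spec.ref_base)
    return target, non_target


@dataclass(frozen=True)
class GuideSpec:
    """A guide RNA: protospacer, PAM pattern, Cas9 ortholog and strand.

    ``cut_offset`` is the inter-base distance of the blunt cut measured 5' of
    the PAM (3 for the standard Cas9 blunt cut, used for all orthologs).
    """

    name: str
    protospacer: str
    pam: str
    ortholog: str = "SpCas9"
    strand: str = "plus"
    cut_offset: int = 3

    def __post_init__(self) -> None:
        object.__setattr__(self, "protospacer", self.protospacer.upper())
        object.__setattr__(self, "pam", self.pam.upper())
        _check_nucleotides(self.protospacer, f"protospacer of {self.name}")
        if any(c not in IUPAC_CODES for c in self.pam):
            raise InputError(f"PAM pattern of {self.name} contains non-IUPAC codes")
        if self.strand not in ("plus", "minus"):
            raise ConfigurationError("strand must be 'plus' or 'minus'")
        if not (0 <= self.cut_offset <= len(self.protospacer)):
            raise ConfigurationError("cut_offset outside protospacer")


@dataclass(frozen=True)
class EditingWindow:
    """The editing window around a cut site.

    ``base_range`` is the half-open interval of reference bases within which
    substitutions and deletions count as editing; ``insertion_range`` is the
    closed interval of inter-base positions for insertions.
    """

    cut_site: int
    half_width: int = 5
    ref_length: int = field(default=0)

    @property
    def base_range(self) -> tuple[int, int]:
        return (self.cut_site - self.half_width, self.cut_site + self.half_width)

    @property
    def insertion_range(self) -> tuple[int, int]:
        return (self.cut_site - self.half_width, self.cut_site + self.half_width)

    def contains_base(self, index: int) -> bool:
        lo, hi = self.base_range
        return lo <= index < hi

    def overlaps(self, start: int, length: int) -> bool:
        """True if the reference interval [start, start+length) overlaps the window."""
        lo, hi = self.base_range
        return start < hi and start + length > lo

    def contains_insertion(self, position: int) -> bool:
        lo, hi = self.insertion_range
        return lo <= position <= hi


def _pam_matches(pattern: str, seq: str) -> bool:
    return len(seq) == len(pattern) and all(
        b in IUPAC_CODES[p] for p, b in zip(pattern, seq)
    )


def _find_guide_sites(guide: GuideSpec, sequence: str) -> list[int]:
    """Protospacer+PAM match positions (protospacer start, in the given strand's coords)."""
    proto, pam = guide.protospacer, guide.pam
    hits = []
    start = 0
    while True:
        i = sequence.find(proto, start)
        if i < 0:
            break
        if _pam_matches(pam, sequence[i + len(proto): i + len(proto) + len(pam)]):
            hits.append(i)
        start = i + 1
    return hits


def locate_cut_site(
    guide: GuideSpec, ref: AlleleReference, half_width: int = 5
) -> EditingWindow:
    """Locate the blunt cut of ``guide`` on ``ref`` and derive the editing window.

    The protospacer+PAM must match exactly once on the stated strand.  The
    cut is placed ``cut_offset`` inter-base steps 5' of the PAM; for a minus
    strand guide the coordinate is mirrored back onto the plus strand.
    """
    strand_seq = (
        ref.sequence if guide.strand == "plus" else reverse_complement(ref.sequence)
    )
    hits = _find_guide_sites(guide, strand_seq)
    if not hits:
        raise GuideNotFoundError(
            f"guide {guide.name!r} ({guide.strand} strand) not found on {ref.allele} reference"
        )
    if len(hits) > 1:
        raise AmbiguousGuideError(
            f"guide {guide.name!r} matches the {ref.allele} reference {len(hits)} times"
        )
    cut_on_strand = hits[0] + len(guide.protospacer) - guide.cut_offset
    cut_site = (
        cut_on_strand if guide.strand == "plus" else len(ref.sequence) - cut_on_strand
    )
    window = EditingWindow(cut_site=cut_site, half_width=half_width, ref_length=len(ref))
    lo, hi = window.base_range
    if lo < 0 or hi > len(ref.sequence):
        raise ConfigurationError(
            f"editing window [{lo},{hi}) extends outside the reference (len {len(ref)})"
        )
    return window
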