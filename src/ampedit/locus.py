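"""Synthetic demonstration locus.

The published genomic context and guide sequences of the deep-intronic
LZTR1 intron-16 locus are not public, so the package ships a synthetic
stand-in with the same structure: an 81-nt diploid amplicon window whose
centre base is the discriminating SNV (maternal/non-target C, paternal/
target T), where the C>T exchange creates a near-consensus cryptic donor
splice site (CAG|GTAAGT) immediately at the variant.

Two guides are defined on the target allele:

* ``guide A`` - minus strand, cut immediately 3' of the variant (inter-base
  41), mirroring the published geometry where the dominant 9-bp deletion
  removes the entire cryptic donor motif.  Deletions of this guide span the
  discriminating base, so such reads are inherently allele-ambiguous; the
  guide is used for splice-impact demonstrations.
* ``guide B`` - plus strand, cut 5 bp downstream (inter-base 45), used as
  the simulator default so that every spectrum variant leaves the
  discriminating base intact and allele recovery can be validated.
"""

from __future__ import annotations

from dataclasses import dataclass

from .classify import IndelVariant
from .alignment import normalize_ops
from .profiling import parse_variant_descriptor
from .reference import (
    AlleleReference,
    EditingWindow,
    GuideSpec,
    VariantSpec,
    build_allele_references,
    locate_cut_site,
    reverse_complement,
)

#: 81-nt synthetic amplicon context carrying the reference (C) base at index 40.
CONTEXT = (
    "ACCATGACAGCATTACGAGCAAGGAAGC"   # 0-27   left flank
    "CACCAAC"                        # 28-34
    "CCAGGCAAGT"                     # 35-44  C>T at 40 creates CAG|GTAAGT
    "ACAC"                           # 45-48
    "GGA"                            # 49-51  guide B PAM (NGG at 48-50)
    "CAACCTCACCAGCAATCACCAACATCAGA"  # 52-80  right flank
)

VARIANT_INDEX = 40
#: motif start of the cryptic donor site (positions -3..+6 = 36..44)
DONOR_MOTIF_START = 36
#: motif-start search interval used for donor-site scoring
DONOR_SEARCH_INTERVAL = (28, 45)


@dataclass(frozen=True)
class DemoLocus:
    spec: VariantSpec
    target: AlleleReference
    non_target: AlleleReference
    guides: dict
    windows: dict

    def spectrum_keys(self, guide_name: str, descriptors) -> dict[str, float]:
        """Translate descriptor->frequency mappings into canonical variant keys."""
        window = self.windows[guide_name]
        out = {}
        for descriptor, freq in descriptors.items():
            ops = normalize_ops(
                parse_variant_descriptor(descriptor, window), self.target
            )
            out[IndelVariant.from_ops(ops, window.cut_site).key] = freq
        return out


def synthetic_lztr1_locus(half_width: int = 5) -> DemoLocus:
    """Build the synthetic demonstration locus (references, guides, windows)."""
    spec = VariantSpec(
        label="c.1943-256C>T",
        context=CONTEXT,
        variant_index=VARIANT_INDEX,
        ref_base="C",
        alt_base="T",
        flank=40,
    )
    target, non_target = build_allele_references(spec)
    guide_a = GuideSpec(
        name="guide A",
        protospacer=reverse_complement(target.sequence[38:58]),
        pam="NGG",
        ortholog="SpCas9",
        strand="minus",
    )
    guide_b = GuideSpec(
        name="guide B",
        protospacer=target.sequence[28:48],
        pam="NGG",
        ortholog="SpCas9",
        strand="plus",
    )
    guides = {"A": guide_a, "B": guide_b}
    windows = {
        name: locate_cut_site(g, target, half_width=half_width)
        for name, g in guides.items()
    }
    return DemoLocus(
        spec=spec, target=target, non_target=non_target, guides=guides, windows=windows
    )


#: default simulated indel spectrum (guide B; descriptor -> probability)
DEFAULT_SPECTRUM_B = {
    "del9@-4": 0.49,
    "insA@0": 0.27,
    "insT@0": 0.12,
    "del2@-1": 0.12,
}

#: paper-like spectrum at the cryptic donor site (guide A), used for
#: splice-impact demonstrations
SPLICE_DEMO_SPECTRUM_A = {
    "del9@-5": 0.49,
    "insT@0": 0.29,
    "insA@0": 0.12,
    "del2@-2": 0.10,
}
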