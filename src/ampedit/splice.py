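"""Donor splice-site scoring and splice-impact classification of indel variants.

The pathogenic deep-intronic C>T exchange creates a cryptic donor splice
site; an indel variant is therapeutically useful when the edited sequence is
less likely to be recognized as a donor site than the wild-type allele.
The comparator only needs a monotone splice score, provided either by a
position-weight-matrix log-odds donor model trained on donor-site sequences
(9 positions spanning the exon|intron boundary, -3..+6) or by externally
computed scores keyed by variant.

For each indel variant the edited target sequence is reconstructed, the best
donor score in a search interval is taken, and the variant is categorized
against the wild-type (non-target) and pathological (unedited target)
scores: *disrupting* when its best score falls below the wild-type score
(plus a configurable margin), *enhancing* when it reaches the pathological
score, *neutral* otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .alignment import apply_ops
from .classify import parse_variant_key
from .errors import InputError
from .reference import AlleleReference, EditingWindow

_BASES = "ACGT"

#: Idealized per-position base frequencies (%) of human U2 donor sites,
#: positions -3..+6 around the exon|intron boundary (synthetic stand-in used
#: to draw PWM training sequences at desk scale).
DONOR_BASE_FREQS = (
    {"A": 33, "C": 37, "G": 18, "T": 12},   # -3
    {"A": 60, "C": 13, "G": 12, "T": 15},   # -2
    {"A": 8, "C": 4, "G": 81, "T": 7},      # -1
    {"A": 0, "C": 0, "G": 100, "T": 0},     # +1 (G of the GT core)
    {"A": 0, "C": 0, "G": 0, "T": 100},     # +2 (T of the GT core)
    {"A": 59, "C": 3, "G": 35, "T": 3},     # +3
    {"A": 71, "C": 8, "G": 12, "T": 9},     # +4
    {"A": 6, "C": 6, "G": 84, "T": 4},      # +5
    {"A": 16, "C": 18, "G": 20, "T": 46},   # +6
)


@dataclass(frozen=True)
class SpliceModel:
    """A donor-site scorer: PWM log-odds weights or external per-variant scores."""

    kind: str = "pwm_logodds"
    motif_width: int = 9
    weights: tuple = ()            # pwm: tuple of per-position {base: log-odds}
    external: dict = field(default_factory=dict)  # variant key -> score
    background: tuple = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        if self.kind not in ("pwm_logodds", "external_scores"):
            raise InputError("model kind must be pwm_logodds or external_scores")
        if self.motif_width < 4:
            raise InputError("motif_width must be >= 4")
        if self.kind == "pwm_logodds" and len(self.weights) != self.motif_width:
            raise InputError("PWM weights must cover motif_width positions")

    def score_word(self, word: str) -> float:
        if len(word) != self.motif_width:
            raise InputError("word length must equal motif_width")
        return sum(self.weights[i][b] for i, b in enumerate(word))

    @property
    def consensus(self) -> str:
        return "".join(max(w, key=w.get) for w in self.weights)


def train_pwm(
    donor_site_seqs: list[str],
    background: tuple[float, float, float, float] | None = None,
    pseudocount: float = 0.5,
) -> SpliceModel:
    """Train a log-odds donor PWM from aligned donor-site sequences.

    ``weights[i][b] = log2(((count + pseudo) / (N + 4*pseudo)) / background[b])``.
    Requires at least 10 training sites, all the same width, ACGT only.
    """
    if len(donor_site_seqs) < 10:
        raise InputError(f"need >= 10 training sites, got {len(donor_site_seqs)}")
    width = len(donor_site_seqs[0])
    bg = background or (0.25, 0.25, 0.25, 0.25)
    counts = np.zeros((width, 4))
    for seq in donor_site_seqs:
        seq = seq.upper()
        if len(seq) != width:
            raise InputError("training sites differ in width")
        for i, base in enumerate(seq):
            if base not in _BASES:
                raise InputError("training sites must be ACGT only")
            counts[i, _BASES.index(base)] += 1
    n = len(donor_site_seqs)
    weights = []
    for i in range(width):
        row = {}
        for k, base in enumerate(_BASES):
            freq = (counts[i, k] + pseudocount) / (n + 4 * pseudocount)
            row[base] = math.log2(freq / bg[k])
        weights.append(row)
    return SpliceModel(
        kind="pwm_logodds", motif_width=width, weights=tuple(weights), background=tuple(bg)
    )


def synthetic_donor_training_set(n: int = 500, seed: int = 0) -> list[str]:
    """Draw ``n`` synthetic 9-mer donor sites from the idealized human donor
    base-frequency table (desk-scale stand-in for real donor annotations)."""
    rng = np.random.default_rng(seed)
    sites = []
    probs = [
        np.array([row[b] for b in _BASES], dtype=float) / sum(row.values())
        for row in DONOR_BASE_FREQS
    ]
    for _ in range(n):
        sites.append("".join(_BASES[rng.choice(4, p=p)] for p in probs))
    return sites


def reconstruct_variant_sequence(
    target: AlleleReference,
    variant,
    window: EditingWindow,
) -> str:
    """Apply an indel variant (IndelVariant or canonical key string) to the
    target reference, returning the post-edit sequence."""
    key = getattr(variant, "key", variant)
    ops = parse_variant_key(key, window.cut_site)
    for op in ops:
        if op.ref_start < 0 or op.ref_end > len(target.sequence):
            raise InputError(f"variant op {op} out of reference bounds")
    return apply_ops(target.sequence, list(ops))


def score_donor_sites(
    sequence: str,
    model: SpliceModel,
    search_interval: tuple[int, int],
    variant_key: str | None = None,
) -> tuple[int, float]:
    """Best donor-site position and score within ``search_interval``.

    The interval bounds motif *start* positions (half-open).  For external
    models the variant key is looked up instead and the position is -1.
    """
    if model.kind == "external_scores":
        if variant_key is None or variant_key not in model.external:
            raise InputError(f"no external score for variant {variant_key!r}")
        return -1, float(model.external[variant_key])
    lo, hi = search_interval
    lo = max(lo, 0)
    hi = min(hi, len(sequence) - model.motif_width + 1)
    if hi <= lo:
        raise InputError("search interval shorter than the motif")
    best_pos, best = lo, -math.inf
    for pos in range(lo, hi):
        s = model.score_word(sequence[pos: pos + model.motif_width])
        if s > best:
            best_pos, best = pos, s
    return best_pos, best


@dataclass(frozen=True)
class SpliceVerdict:
    variant_key: str
    best_donor_score: float
    score_pathological: float
    score_wt: float
    category: str  # disrupting / neutral / enhancing


def classify_splice_impact(
    spectrum: dict[str, float],
    target: AlleleReference,
    wt_sequence: str,
    window: EditingWindow,
    model: SpliceModel,
    search_interval: tuple[int, int],
    margin: float = 0.0,
) -> tuple[list[SpliceVerdict], float]:
    """Score every spectrum variant and return the spectrum-weighted
    fraction of disrupting outcomes (percent).

    ``spectrum`` maps canonical variant keys to percent-of-edited
    frequencies; ``wt_sequence`` is the wild-type (non-target) sequence.
    Categories: disrupting iff score < score_wt + margin; enhancing iff
    score >= score_pathological; neutral otherwise.
    """
    if not spectrum:
        raise InputError("empty spectrum")
    if model.kind == "external_scores":
        _, score_path = score_donor_sites("", model, (0, 1), variant_key="pathological")
        _, score_wt = score_donor_sites("", model, (0, 1), variant_key="wt")
    else:
        _, score_path = score_donor_sites(target.sequence, model, search_interval)
        _, score_wt = score_donor_sites(wt_sequence, model, search_interval)
    verdicts = []
    weighted_disrupting = 0.0
    total = sum(spectrum.values())
    if total <= 0:
        raise InputError("spectrum has zero mass")
    for key, freq in spectrum.items():
        if model.kind == "external_scores":
            _, score = score_donor_sites("", model, (0, 1), variant_key=key)
        else:
            seq = reconstruct_variant_sequence(target, key, window)
            _, score = score_donor_sites(seq, model, search_interval)
        if score < score_wt + margin:
            category = "disrupting"
        elif score >= score_path:
            category = "enhancing"
        else:
            category = "neutral"
        if category == "disrupting":
            weighted_disrupting += freq
        verdicts.append(
            SpliceVerdict(
                variant_key=key,
                best_donor_score=score,
                score_pathological=score_path,
                score_wt=score_wt,
                category=category,
            )
        )
    return verdicts, 100.0 * weighted_disrupting / total
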