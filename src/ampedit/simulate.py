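"""Synthetic amplicon read generator with ground truth.

Emulates the study's deep amplicon samples: a diploid locus with a single
discriminating SNV, a configurable fraction of target-allele reads carrying
an edit drawn from a known indel spectrum concentrated in the editing
window, and per-base substitution sequencing error producing out-of-window
artifacts.  Every emitted read has a truth record, so the whole pipeline can
be validated by parameter recovery.

The error model is substitution-only by default (an optional indel error
rate exercises the off-window-indel rule deliberately); qualities are
constant Q30 since classification ignores them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import apply_ops, normalize_ops
from .classify import INDEL_CLASSES, EditCall, IndelVariant, parse_variant_key
from .errors import ConfigurationError, InputError
from .reference import NON_TARGET, TARGET, AlleleReference, EditingWindow
from .seqio import ReadRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

WT_KEY = "WT"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated sample.

    Defaults mirror the study: an even diploid allele balance, a target-
    allele editing rate of 0.3 (the upper end of the reported 21%-30% range),
    a spectrum dominated by a 9-bp deletion with 1-bp A/T insertions and a
    2-bp deletion, and a 1e-3 per-base substitution error rate.
    """

    target: AlleleReference
    non_target: AlleleReference
    window: EditingWindow
    spectrum: dict  # canonical variant key -> probability
    n_reads: int = 20000
    allele_share_target: float = 0.5
    editing_rate: float = 0.3
    sub_error_rate: float = 0.001
    indel_error_rate: float = 0.0
    seed: int = 0
    quality_char: str = "?"  # Phred+33 Q30

    def __post_init__(self) -> None:
        if not (0 <= self.allele_share_target <= 1 and 0 <= self.editing_rate <= 1):
            raise ConfigurationError("allele_share_target and editing_rate must be in [0,1]")
        if not (0 <= self.sub_error_rate < 1):
            raise ConfigurationError("sub_error_rate must be in [0,1)")
        if self.n_reads < 1:
            raise ConfigurationError("n_reads must be positive")
        total = sum(self.spectrum.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"spectrum probabilities sum to {total}, expected 1")
        lo, hi = self.window.insertion_range
        for key in self.spectrum:
            for op in parse_variant_key(key, self.window.cut_site):
                inside = (
                    lo <= op.ref_start <= hi
                    if op.kind == "ins"
                    else self.window.overlaps(op.ref_start, op.ref_len)
                )
                if not inside:
                    raise ConfigurationError(f"spectrum op {op} outside the editing window")


@dataclass(frozen=True)
class TruthRecord:
    read_id: str
    true_allele: str
    true_variant: str  # canonical key or "WT"
    n_injected_errors: int


def canonical_spectrum(
    spectrum: dict, window: EditingWindow, target: AlleleReference
) -> dict[str, float]:
    """Left-normalize spectrum keys against the target reference."""
    out: dict[str, float] = {}
    for key, prob in spectrum.items():
        ops = normalize_ops(parse_variant_key(key, window.cut_site), target)
        ckey = IndelVariant.from_ops(ops, window.cut_site).key
        out[ckey] = out.get(ckey, 0.0) + prob
    return out


def simulate_reads(cfg: SimulationConfig) -> tuple[list[ReadRecord], list[TruthRecord]]:
    """Generate reads and their ground truth, deterministically per seed."""
    rng = np.random.default_rng(cfg.seed)
    spectrum = canonical_spectrum(cfg.spectrum, cfg.window, cfg.target)
    keys = sorted(spectrum)
    probs = np.array([spectrum[k] for k in keys])
    probs = probs / probs.sum()
    # pre-apply each variant once; remember which positions are inserted bases
    variant_seqs: dict[str, tuple[str, np.ndarray]] = {}
    for key in keys:
        ops = parse_variant_key(key, cfg.window.cut_site)
        seq = apply_ops(cfg.target.sequence, list(ops))
        protected = np.zeros(len(seq), dtype=bool)
        # mark inserted bases so errors target only template positions
        offset = 0
        for op in sorted(ops, key=lambda o: (o.ref_start, 0 if o.kind == "ins" else 1)):
            if op.kind == "ins":
                start = op.ref_start + offset
                protected[start: start + len(op.alt)] = True
            offset += op.net_delta
        variant_seqs[key] = (seq, protected)
    reads: list[ReadRecord] = []
    truth: list[TruthRecord] = []
    is_target = rng.random(cfg.n_reads) < cfg.allele_share_target
    is_edited = rng.random(cfg.n_reads) < cfg.editing_rate
    variant_draws = rng.choice(len(keys), size=cfg.n_reads, p=probs) if keys else None
    for i in range(cfg.n_reads):
        read_id = f"read{i:06d}"
        if is_target[i]:
            allele = TARGET
            if is_edited[i]:
                key = keys[variant_draws[i]]
                seq, protected = variant_seqs[key]
            else:
                key = WT_KEY
                seq, protected = cfg.target.sequence, None
        else:
            allele = NON_TARGET
            key = WT_KEY
            seq, protected = cfg.non_target.sequence, None
        seq_arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
        hit = rng.random(len(seq_arr)) < cfg.sub_error_rate
        if protected is not None:
            hit &= ~protected
        n_err = int(hit.sum())
        if n_err:
            for pos in np.flatnonzero(hit):
                choices = _BASES[_BASES != seq_arr[pos]]
                seq_arr[pos] = choices[rng.integers(3)]
        final = seq_arr.tobytes().decode("ascii")
        if cfg.indel_error_rate and rng.random() < cfg.indel_error_rate:
            # deliberate 1-bp deletion artifact between the upstream indicator
            # and the editing window (off-window by construction)
            pos = int(rng.integers(16, 30))
            final = final[:pos] + final[pos + 1:]
            n_err += 1
        reads.append(
            ReadRecord(read_id=read_id, sequence=final,
                       qualities=cfg.quality_char * len(final))
        )
        truth.append(TruthRecord(read_id, allele, key, n_err))
    return reads, truth


def default_simulation(guide: str = "B", **overrides) -> SimulationConfig:
    """Simulation of the synthetic demonstration locus under study conditions.

    Spectrum descriptors of the chosen guide are translated into canonical
    variant keys; any :class:`SimulationConfig` field can be overridden.
    """
    from . import locus as _locus

    demo = _locus.synthetic_lztr1_locus()
    descriptors = (
        _locus.DEFAULT_SPECTRUM_B if guide == "B" else _locus.SPLICE_DEMO_SPECTRUM_A
    )
    spectrum = demo.spectrum_keys(guide, descriptors)
    kwargs = dict(
        target=demo.target,
        non_target=demo.non_target,
        window=demo.windows[guide],
        spectrum=spectrum,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


def truth_table(truth: list[TruthRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "read_id": [t.read_id for t in truth],
            "true_allele": [t.true_allele for t in truth],
            "true_variant": [t.true_variant for t in truth],
            "n_injected_errors": [t.n_injected_errors for t in truth],
        }
    )


@dataclass
class RecoverySummary:
    n_truth: int
    n_calls: int
    allele_accuracy: float
    variant_key_accuracy: float
    true_efficiency_all: float
    est_efficiency_all: float
    efficiency_delta: float
    spectrum_true: dict = field(default_factory=dict)
    spectrum_est: dict = field(default_factory=dict)
    spectrum_deltas: dict = field(default_factory=dict)


def evaluate_recovery(
    truth: list[TruthRecord], calls: list[EditCall]
) -> RecoverySummary:
    """Confront pipeline calls with simulation truth.

    Reports allele accuracy, variant-key accuracy among edited-truth reads
    (both over reads that passed the filter), and the estimated-vs-true
    all-allele efficiency and per-key spectrum percentages.  Truth
    percentages use all simulated reads; estimates use the filtered reads.
    """
    if not truth:
        raise InputError("empty truth table")
    truth_by_id = {t.read_id: t for t in truth}
    if len(truth_by_id) != len(truth):
        raise InputError("duplicate read_ids in truth")
    calls_by_id = {}
    for c in calls:
        if c.read_id not in truth_by_id:
            raise InputError(f"call for unknown read_id {c.read_id!r}")
        calls_by_id[c.read_id] = c
    n_allele_ok = 0
    n_key_ok = 0
    n_edited_truth_called = 0
    est_edited = 0
    est_spectrum: dict[str, int] = {}
    for read_id, call in calls_by_id.items():
        t = truth_by_id[read_id]
        if call.allele == t.true_allele:
            n_allele_ok += 1
        edited_call = call.mutation_class in INDEL_CLASSES
        if t.true_variant != WT_KEY:
            n_edited_truth_called += 1
            if edited_call and call.variant and call.variant.key == t.true_variant:
                n_key_ok += 1
        if edited_call and call.allele == TARGET:
            est_edited += 1
            est_spectrum[call.variant.key] = est_spectrum.get(call.variant.key, 0) + 1
    n_calls = len(calls_by_id)
    true_edited = sum(1 for t in truth if t.true_variant != WT_KEY)
    true_spectrum_counts: dict[str, int] = {}
    for t in truth:
        if t.true_variant != WT_KEY:
            true_spectrum_counts[t.true_variant] = (
                true_spectrum_counts.get(t.true_variant, 0) + 1
            )
    true_eff = 100.0 * true_edited / len(truth)
    est_eff = 100.0 * est_edited / n_calls if n_calls else float("nan")
    spectrum_true = {
        k: 100.0 * v / true_edited for k, v in true_spectrum_counts.items()
    } if true_edited else {}
    spectrum_est = {
        k: 100.0 * v / est_edited for k, v in est_spectrum.items()
    } if est_edited else {}
    deltas = {
        k: spectrum_est.get(k, 0.0) - spectrum_true[k] for k in spectrum_true
    }
    return RecoverySummary(
        n_truth=len(truth),
        n_calls=n_calls,
        allele_accuracy=100.0 * n_allele_ok / n_calls if n_calls else float("nan"),
        variant_key_accuracy=(
            100.0 * n_key_ok / n_edited_truth_called if n_edited_truth_called else float("nan")
        ),
        true_efficiency_all=true_eff,
        est_efficiency_all=est_eff,
        efficiency_delta=est_eff - true_eff,
        spectrum_true=spectrum_true,
        spectrum_est=spectrum_est,
        spectrum_deltas=deltas,
    )
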