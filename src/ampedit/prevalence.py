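"""Population-frequency aggregation of disease variants across gnomAD datasets.

Each record carries up to three allele frequencies (gnomAD exome v2, genome
v2, genome v3); "not detected" entries count as frequency 0 when computing
the mean, except that records undetected in all three datasets keep a
missing mean (printed as "-").  Frequencies are handled as decimals (the
source tables print decimal commas) and means are rounded half-up to eight
decimal places, the print precision of the source.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal, InvalidOperation
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import InputError, ParseError

MISSING_MARKERS = {"", "-", "–", "nan", "na", "not detected", "nd", "."}

_FREQ_COLUMNS = ("freq_exome_v2", "freq_genome_v2", "freq_genome_v3")


def parse_frequency(text) -> Decimal | None:
    """Parse one frequency cell; decimal commas are normalized; missing
    markers ('not detected', '-', empty) yield None."""
    if text is None:
        return None
    text = str(text).strip().lower()
    if text in MISSING_MARKERS:
        return None
    try:
        value = Decimal(text.replace(",", "."))
    except InvalidOperation as exc:
        raise InputError(f"unparseable frequency {text!r}") from exc
    if not (0 <= value <= 1):
        raise InputError(f"frequency {value} outside [0, 1]")
    return value


@dataclass(frozen=True)
class VariantPrevalenceRecord:
    variant_label: str
    protein_label: str = ""
    inheritance: str = "recessive"
    freq_exome_v2: Decimal | None = None
    freq_genome_v2: Decimal | None = None
    freq_genome_v3: Decimal | None = None

    def __post_init__(self) -> None:
        if self.inheritance not in ("recessive", "dominant"):
            raise InputError(f"inheritance must be recessive/dominant, got {self.inheritance!r}")

    @property
    def frequencies(self) -> tuple[Decimal | None, Decimal | None, Decimal | None]:
        return (self.freq_exome_v2, self.freq_genome_v2, self.freq_genome_v3)


def mean_frequency(rec: VariantPrevalenceRecord) -> Decimal | None:
    """Mean of the three dataset frequencies with "not detected" counted as 0,
    rounded half-up to 8 decimal places; None when all three are missing."""
    freqs = rec.frequencies
    if all(f is None for f in freqs):
        return None
    total = sum((f if f is not None else Decimal(0)) for f in freqs)
    return (total / 3).quantize(Decimal("1e-8"), rounding=ROUND_HALF_UP)


def rank_variants(records: list[VariantPrevalenceRecord]) -> list[VariantPrevalenceRecord]:
    """Order records by descending mean frequency; all-missing records last;
    ties broken by variant label."""
    def sort_key(rec: VariantPrevalenceRecord):
        mean = mean_frequency(rec)
        return (mean is None, -(mean if mean is not None else Decimal(0)), rec.variant_label)

    return sorted(records, key=sort_key)


def load_prevalence_table(path) -> pd.DataFrame:
    """Read a variant-prevalence TSV (columns: variant_label, protein_label,
    inheritance, freq_exome_v2, freq_genome_v2, freq_genome_v3
    [, printed_mean]) as a string DataFrame."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = {"variant_label", *_FREQ_COLUMNS} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return df

def records_from_table(df: pd.DataFrame) -> list[VariantPrevalenceRecord]:
    records = []
    for _, row in df.iterrows():
        records.append(
            VariantPrevalenceRecord(
                variant_label=row["variant_label"],
                protein_label=row.get("protein_label", ""),
                inheritance=row.get("inheritance", "recessive") or "recessive",
                freq_exome_v2=parse_frequency(row["freq_exome_v2"]),
                freq_genome_v2=parse_frequency(row["freq_genome_v2"]),
                freq_genome_v3=parse_frequency(row["freq_genome_v3"]),
            )
        )
    return records


def format_mean(mean: Decimal | None) -> str:
    return "-" if mean is None else f"{mean:.8f}"


def annotate_and_rank(df: pd.DataFrame) -> pd.DataFrame:
    """Add mean_freq and rank columns and sort by rank."""
    records = records_from_table(df)
    means = [mean_frequency(r) for r in records]
    out = df.copy()
    out["mean_freq"] = [format_mean(m) for m in means]
    ranked = rank_variants(records)
    order = {rec.variant_label: i + 1 for i, rec in enumerate(ranked)}
    out["rank"] = [order[r.variant_label] for r in records]
    return out.sort_values("rank").reset_index(drop=True)


def bundled_prevalence_table_path() -> Path:
    """Path of the bundled LZTR1 variant-prevalence table (transcribed
    published gnomAD frequencies with their printed means)."""
    return Path(resources.files("ampedit").joinpath("data/lztr1_variant_prevalence.tsv"))
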