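"""Sequence and table I/O.

FASTA/FASTQ parsing and writing delegate to Bio.SeqIO; profile tables are
written as TSV (tab-separated, header row, "." for missing values) plus a
machine-readable JSON twin that echoes the full configuration.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path

import yaml
from Bio import SeqIO

from .errors import InputError, ParseError

logger = logging.getLogger(__name__)

_IUPAC_RE = re.compile(r"^[ACGTRYSWKMBDHVN]+$")


@dataclass(frozen=True)
class ReadRecord:
    """One (merged) amplicon read."""

    read_id: str
    sequence: str
    qualities: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InputError(f"read {self.read_id!r} has empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise InputError(f"read {self.read_id!r}: quality/sequence length mismatch")


@dataclass(frozen=True)
class SampleEntry:
    sample_id: str
    reads_path: str
    format: str = "auto"
    replicate: str = ""
    expected_profile: str | None = None


def _detect_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".fq", ".fastq"):
        return "fastq"
    if suffix in (".fa", ".fasta", ".fna"):
        return "fasta"
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return "fastq" if line.startswith("@") else "fasta"
    return "fasta"


def read_sequences(path, format: str = "auto"):
    """Yield :class:`ReadRecord` objects from a FASTA/FASTQ file in file order.

    Lowercase input is uppercased; records containing non-IUPAC characters
    are rejected and their count reported via a warning.  Malformed records
    raise :class:`ParseError` naming the record index.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"reads file not found: {path}")
    if format == "auto":
        format = _detect_format(path)
    if format not in ("fasta", "fastq"):
        raise InputError(f"unknown sequence format {format!r}")
    n_rejected = 0
    index = 0
    try:
        for record in SeqIO.parse(str(path), format):
            index += 1
            seq = str(record.seq).upper()
            if not seq or not _IUPAC_RE.match(seq):
                n_rejected += 1
                continue
            quals = None
            phred = record.letter_annotations.get("phred_quality")
            if phred is not None:
                quals = "".join(chr(q + 33) for q in phred)
            yield ReadRecord(read_id=record.id, sequence=seq, qualities=quals)
    except ValueError as exc:
        raise ParseError(f"{path}: malformed {format} record #{index + 1}: {exc}") from exc
    if index == 0:
        logger.warning("%s: empty sequence file", path)
    if n_rejected:
        logger.warning("%s: rejected %d records with non-IUPAC characters", path, n_rejected)


def write_fastq(records, path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            quals = rec.qualities or "I" * len(rec.sequence)
            fh.write(f"@{rec.read_id}\n{rec.sequence}\n+\n{quals}\n")


def write_fasta(records, path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.read_id}\n{rec.sequence}\n")


def read_sample_sheet(path) -> list[SampleEntry]:
    """Sample sheet as TSV (sample_id, reads_path[, format, replicate,
    expected_profile]) or YAML (list of mappings)."""
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        with open(path) as fh:
            raw = yaml.safe_load(fh) or []
        entries = [SampleEntry(**item) for item in raw]
    else:
        import pandas as pd

        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        if "sample_id" not in df.columns or "reads_path" not in df.columns:
            raise ParseError(f"{path}: sample sheet needs sample_id and reads_path columns")
        entries = []
        for _, row in df.iterrows():
            entries.append(
                SampleEntry(
                    sample_id=row["sample_id"],
                    reads_path=row["reads_path"],
                    format=row.get("format", "auto") or "auto",
                    replicate=row.get("replicate", "") or "",
                    expected_profile=row.get("expected_profile") or None,
                )
            )
    ids = [e.sample_id for e in entries]
    if len(set(ids)) != len(ids):
        raise InputError("duplicate sample_ids in sample sheet")
    return entries


def _fmt(value, digits: int = 4) -> str:
    if value is None:
        return "."
    if isinstance(value, float):
        return f"{value:.{digits}f}"
    return str(value)


def write_profile_tables(profile, out_dir, config: dict | None = None) -> dict:
    """Write summary TSV, spectrum TSV and a JSON twin for one profile.

    Returns the paths written.  Percentages that are undefined (zero
    denominator) are written as ".".
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prefix = profile.sample_id or "sample"
    summary_path = out_dir / f"{prefix}.summary.tsv"
    spectrum_path = out_dir / f"{prefix}.spectrum.tsv"
    json_path = out_dir / f"{prefix}.profile.json"

    rows = profile.summary_rows()
    with open(summary_path, "w") as fh:
        fh.write("metric\tvalue\n")
        for key, value in rows:
            fh.write(f"{key}\t{_fmt(value)}\n")
    with open(spectrum_path, "w") as fh:
        fh.write(
            "variant_key\tdisplay_label\tmutation_class\tcount\t"
            "pct_of_filtered\tpct_of_edited_target\n"
        )
        for entry in profile.spectrum:
            fh.write(
                "\t".join(
                    [
                        entry.key,
                        entry.display_label,
                        entry.mutation_class,
                        str(entry.count),
                        _fmt(entry.pct_of_filtered),
                        _fmt(entry.pct_of_edited_target),
                    ]
                )
                + "\n"
            )
    payload = profile.as_dict()
    if config is not None:
        payload["config"] = config
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {"summary": summary_path, "spectrum": spectrum_path, "json": json_path}


def read_profile_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
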