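"""Readers/writers for the external representations the pipeline touches.

Coordinate convention used throughout the package: genomic positions are
1-based and inclusive on the reference. Positions relative to a pause site
follow the field convention for pause maps: −1 is the pause nucleotide
itself (the 3′ end of the paused transcript), +1 the next nucleotide to be
incorporated, and there is no position 0. DNA is stored as ACGT; the RNA
alphabet appears only after transcription of a folding window.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

_DNA_OK = set("ACGTN")
_STRANDS = {"+", "-"}


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


@dataclass
class Genome:
    """A set of named DNA sequences (uppercase ACGTN)."""

    sequences: dict[str, str]
    id: str = ""

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not seq:
                raise FormatError(f"sequence {name!r} is empty")
            bad = set(seq) - _DNA_OK
            if bad:
                raise FormatError(
                    f"sequence {name!r} contains non-nucleotide characters: {sorted(bad)}"
                )

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sequences

    def length(self, name: str) -> int:
        return len(self.sequences[name])


@dataclass(frozen=True)
class PauseSite:
    """One pause coordinate: the 1-based position of the −1 nucleotide."""

    seq_name: str
    position: int
    strand: str
    site_id: str

    def __post_init__(self) -> None:
        if self.strand not in _STRANDS:
            raise FormatError(f"bad strand {self.strand!r} for site {self.site_id!r}")
        if self.position < 1:
            raise FormatError(f"position must be >= 1, got {self.position}")


@dataclass
class RunConfig:
    """Run-level configuration echoed into every report.

    Energy-bin thresholds are in kcal/mol and must be strictly decreasing
    (more negative = more stable); window offsets use the relative
    coordinate convention (negative, no zero).
    """

    energy_thresholds: tuple[float, float, float] = (-1.0, -3.0, -6.0)
    window_start: int = -30
    window_end: int = -11
    n_control_datasets: int = 100
    control_dataset_size: int = 26222
    seed: int = 0
    external_folder: str | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = self.energy_thresholds
        if not (t[0] > t[1] > t[2]):
            raise ValueError("energy thresholds must be strictly decreasing")
        if not (self.window_start < self.window_end):
            raise ValueError("window start must precede window end")


def normalize_dna(seq: str) -> str:
    """Uppercase and map U→T; reject anything outside ACGTN."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - _DNA_OK
    if bad:
        raise FormatError(f"non-nucleotide characters: {sorted(bad)}")
    return s


def read_fasta(path: str | Path, genome_id: str | None = None) -> Genome:
    """Load a FASTA file into a :class:`Genome`, normalizing to uppercase ACGTN."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    sequences: dict[str, str] = {}
    for rec in records:
        if rec.id in sequences:
            raise FormatError(f"{path}: duplicate record name {rec.id!r}")
        sequences[rec.id] = normalize_dna(str(rec.seq))
    return Genome(sequences=sequences, id=genome_id or path.stem)


def write_fasta(genome: Genome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


_PAUSE_COLUMNS = ["seq_name", "position", "strand", "site_id"]


def read_pause_table(path: str | Path, genome: Genome | None = None) -> list[PauseSite]:
    """Read a TSV pause table (columns seq_name, position, strand, site_id).

    If a genome is supplied, positions are validated against sequence bounds.
    Errors report the offending 1-based data line.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in _PAUSE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if df.empty:
        logger.warning("%s: empty pause table", path)
        return []
    sites: list[PauseSite] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            pos = int(row.position)
        except (TypeError, ValueError):
            raise FormatError(f"{path} line {i}: bad position {row.position!r}") from None
        if row.strand not in _STRANDS:
            raise FormatError(f"{path} line {i}: bad strand {row.strand!r}")
        if genome is not None:
            if row.seq_name not in genome:
                raise FormatError(f"{path} line {i}: unknown sequence {row.seq_name!r}")
            if not (1 <= pos <= genome.length(row.seq_name)):
                raise FormatError(
                    f"{path} line {i}: position {pos} outside {row.seq_name!r} "
                    f"(length {genome.length(row.seq_name)})"
                )
        sites.append(PauseSite(row.seq_name, pos, row.strand, str(row.site_id)))
    return sites


def write_pause_table(sites: Iterable[PauseSite], path: str | Path) -> None:
    df = pd.DataFrame(
        [(s.seq_name, s.position, s.strand, s.site_id) for s in sites],
        columns=_PAUSE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_kinetics_table(path: str | Path) -> pd.DataFrame:
    """Read a kinetics CSV: condition, replicate, time_s, paused_signal, escaped_signal.

    Validates that each (condition, replicate) series has ≥4 distinct,
    strictly increasing time points and non-negative signals.
    """
    df = pd.read_csv(path)
    required = ["condition", "replicate", "time_s", "paused_signal", "escaped_signal"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    for col in ("time_s", "paused_signal", "escaped_signal"):
        if (df[col] < 0).any():
            raise FormatError(f"{path}: negative values in {col}")
    for (cond, rep), grp in df.groupby(["condition", "replicate"]):
        t = grp["time_s"].to_numpy()
        if len(t) < 4:
            raise FormatError(
                f"{path}: series ({cond}, {rep}) has {len(t)} time points; >=4 required"
            )
        if not (t[1:] > t[:-1]).all():
            raise FormatError(
                f"{path}: series ({cond}, {rep}) times not strictly increasing"
            )
    return df


def write_report(
    records: Sequence[Mapping] | pd.DataFrame,
    path: str | Path,
    format: str = "tsv",
    config: RunConfig | None = None,
) -> None:
    """Write a report as TSV or JSON with deterministic column order.

    Floats are written with 4 decimals; the run config and seed are echoed
    in a header comment (TSV) or a ``_config`` key (JSON).
    """
    if format not in {"tsv", "json"}:
        raise ValueError(f"unsupported report format {format!r}")
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    header = None
    if config is not None:
        header = json.dumps(
            {
                "seed": config.seed,
                "energy_thresholds": list(config.energy_thresholds),
                "window": [config.window_start, config.window_end],
            },
            sort_keys=True,
        )
    if format == "tsv":
        buf = io.StringIO()
        if header:
            buf.write(f"# config {header}\n")
        df.to_csv(buf, sep="\t", index=False, float_format="%.4f")
        Path(path).write_text(buf.getvalue())
    else:
        payload = {"records": json.loads(df.to_json(orient="records", double_precision=4))}
        if header:
            payload["_config"] = json.loads(header)
        Path(path).write_text(json.dumps(payload, indent=1))


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN)."""
    return seq.translate(_RC)[::-1]


_RC = str.maketrans("ACGTN", "TGCAN")
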