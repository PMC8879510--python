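"""Plain-text I/O for the toolkit: FASTA sequence records and TSV trial tables.

FASTA parsing is delegated to Biopython; a light structural pre-scan runs
first so that malformed input is rejected with the offending line number,
which :mod:`Bio.SeqIO` does not report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

__all__ = [
    "SeqRecord",
    "FastaFormatError",
    "TrialTableError",
    "read_fasta",
    "write_fasta",
    "read_trials",
    "write_trials",
    "revcomp",
]

DNA_ALPHABET = frozenset("ACGTN")

#: Columns of a behavioural trial table. ``latency_ms`` is empty (NaN) for a
#: trial without any response; 0 ms is a legal latency and must not be used
#: as the no-response marker.
TRIAL_COLUMNS = ("fish_id", "group", "trial_index", "latency_ms")


class FastaFormatError(ValueError):
    """Raised for structurally invalid FASTA input; names the bad line."""


class TrialTableError(ValueError):
    """Raised for an invalid behavioural trial table."""


@dataclass(frozen=True)
class SeqRecord:
    """An uppercase DNA sequence over {A, C, G, T, N} with an identifier."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.seq:
            raise ValueError(f"record {self.id!r}: sequence must be non-empty")
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: characters {sorted(bad)} outside alphabet ACGTN"
            )

    def __len__(self) -> int:
        return len(self.seq)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return str(Seq(seq).reverse_complement())


def _prescan_fasta(path: Path) -> None:
    """Reject structural FASTA errors with line numbers before parsing."""
    header_line = None
    seen_seq = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header_line is not None and not seen_seq:
                    raise FastaFormatError(
                        f"{path}: record header at line {header_line} has an empty sequence"
                    )
                if line[1:].strip() == "":
                    raise FastaFormatError(
                        f"{path}: malformed header (no identifier) at line {lineno}"
                    )
                header_line = lineno
                seen_seq = False
            else:
                if header_line is None:
                    raise FastaFormatError(
                        f"{path}: sequence data before any '>' header at line {lineno}"
                    )
                seen_seq = True
    if header_line is not None and not seen_seq:
        raise FastaFormatError(
            f"{path}: record header at line {header_line} has an empty sequence"
        )


def read_fasta(path: Union[str, Path]) -> list[SeqRecord]:
    """Read a (possibly multi-record) FASTA file.

    Sequences are uppercased; U is converted to T with a warning. Records are
    returned in file order. Duplicate identifiers or structural problems
    raise :class:`FastaFormatError`.
    """
    path = Path(path)
    _prescan_fasta(path)
    records: list[SeqRecord] = []
    seen_ids: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if "U" in seq:
            warnings.warn(
                f"record {rec.id!r}: converted U to T (RNA-style input)",
                stacklevel=2,
            )
            seq = seq.replace("U", "T")
        if rec.id in seen_ids:
            raise FastaFormatError(f"{path}: duplicate record id {rec.id!r}")
        seen_ids.add(rec.id)
        records.append(SeqRecord(id=rec.id, seq=seq))
    return records


def write_fasta(records: Iterable[SeqRecord], path: Union[str, Path]) -> None:
    """Write records as FASTA, wrapped at 60 columns."""
    bio = [_BioRecord(Seq(r.seq), id=r.id, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta")


def read_trials(path: Union[str, Path]) -> pd.DataFrame:
    """Read a behavioural trial table (TSV).

    Expected columns: ``fish_id``, ``group``, ``trial_index`` (1..n per
    fish), ``latency_ms`` (empty field = no response). Validates that trial
    indices are unique per fish and latencies are non-negative.
    """
    df = pd.read_csv(path, sep="\t", dtype={"fish_id": str, "group": str})
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise TrialTableError(f"{path}: missing columns {sorted(missing)}")
    df["trial_index"] = df["trial_index"].astype(int)
    df["latency_ms"] = pd.to_numeric(df["latency_ms"], errors="coerce")
    if (df["latency_ms"].dropna() < 0).any():
        raise TrialTableError(f"{path}: negative latency values")
    dup = df.duplicated(subset=["fish_id", "trial_index"])
    if dup.any():
        row = df[dup].iloc[0]
        raise TrialTableError(
            f"{path}: duplicate trial_index {row['trial_index']} for fish {row['fish_id']!r}"
        )
    return df[list(TRIAL_COLUMNS)]


def write_trials(df: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a trial table as TSV; no-response latencies become empty fields."""
    df.to_csv(path, sep="\t", index=False, na_rep="")
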