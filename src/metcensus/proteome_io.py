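"""Proteome reading, filtering and methionine-composition statistics.

The dataset convention used throughout the pipeline: proteins shorter than
100 residues are dropped, and the initiator methionine at position 1 is
excluded from all spatial statistics — the Met count ``m`` and the effective
length both disregard position 1 when it is a Met.  Reported coordinates
remain canonical full-sequence 1-based positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy import stats

logger = logging.getLogger(__name__)

#: Residue letters accepted in input sequences; ambiguity codes are retained
#: in the sequence but never counted as methionine.
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYXUBZJO*")

DEFAULT_MIN_LENGTH = 100


@dataclass
class ProteinRecord:
    """One protein sequence with its methionine bookkeeping.

    ``met_positions`` are canonical 1-based positions of 'M'; ``m`` is the
    Met count with the initiator (position 1, when it is Met) excluded.
    """

    accession: str
    sequence: str
    is_membrane: bool = False

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def met_positions(self) -> list[int]:
        return [i + 1 for i, c in enumerate(self.sequence) if c == "M"]

    @property
    def initiator_is_met(self) -> bool:
        return self.sequence[:1] == "M"

    @property
    def m(self) -> int:
        """Met count excluding the initiator Met."""
        n = self.sequence.count("M")
        return n - 1 if self.initiator_is_met else n

    @property
    def effective_length(self) -> int:
        """Length with the initiator Met removed."""
        return self.length - 1 if self.initiator_is_met else self.length

    @property
    def stripped_met_positions(self) -> list[int]:
        """1-based Met positions on the initiator-stripped sequence."""
        if self.initiator_is_met:
            return [p - 1 for p in self.met_positions if p > 1]
        return list(self.met_positions)

    @property
    def is_zero_met(self) -> bool:
        return self.m == 0


def _parse_accession(header: str) -> str:
    """Accession from a UniProt-style ``sp|ACC|NAME`` header, else the first
    whitespace-delimited token."""
    token = header.split()[0]
    parts = token.split("|")
    if len(parts) >= 3 and parts[0] in ("sp", "tr"):
        return parts[1]
    return token


def read_proteome(
    fasta_path: str | Path,
    min_length: int = DEFAULT_MIN_LENGTH,
    membrane_accessions: Iterable[str] | None = None,
) -> list[ProteinRecord]:
    """Read a FASTA proteome, keeping sequences of at least ``min_length``
    residues, in file order.  Sequences with non-residue characters are
    skipped with a warning.
    """
    membrane = set(membrane_accessions or ())
    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            logger.warning("empty sequence for %s; skipped", rec.description)
            continue
        if not set(seq) <= VALID_RESIDUES:
            bad = sorted(set(seq) - VALID_RESIDUES)
            logger.warning("non-residue characters %s in %s; skipped", bad, rec.id)
            continue
        if len(seq) < min_length:
            continue
        acc = _parse_accession(rec.description)
        records.append(ProteinRecord(acc, seq, is_membrane=acc in membrane))
    return records


def write_proteome(records: Sequence[ProteinRecord], fasta_path: str | Path) -> None:
    """Write records as uppercase FASTA, 60 columns per line."""
    seqs = [SeqRecord(Seq(r.sequence), id=r.accession, description="") for r in records]
    with open(fasta_path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(seqs)


def met_content(record: ProteinRecord, strip_initiator: bool = True) -> float:
    """Relative Met frequency.  With ``strip_initiator`` both the count and
    the length drop position 1 when it is a Met."""
    if strip_initiator:
        return record.m / record.effective_length
    return len(record.met_positions) / record.length


def composition_summary(
    records: Sequence[ProteinRecord], strip_initiator: bool = True
) -> pd.DataFrame:
    """Per-protein Met composition table: accession, length, Met count,
    relative frequency (stripped and unstripped) and flags."""
    rows = [
        {
            "accession": r.accession,
            "length": r.length,
            "m": r.m,
            "met_freq": met_content(r, strip_initiator=strip_initiator),
            "met_freq_raw": met_content(r, strip_initiator=False),
            "zero_met": r.is_zero_met,
            "membrane": r.is_membrane,
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def split_membrane(
    records: Sequence[ProteinRecord], membrane_accessions: Iterable[str]
) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Partition records into (membrane, non-membrane) by accession list.
    Listed accessions absent from the proteome are logged and ignored."""
    membrane_set = set(membrane_accessions)
    present = {r.accession for r in records}
    for acc in sorted(membrane_set - present):
        logger.info("membrane accession %s not in proteome; ignored", acc)
    mem = [r for r in records if r.accession in membrane_set]
    non = [r for r in records if r.accession not in membrane_set]
    for r in mem:
        r.is_membrane = True
    return mem, non


def fisher_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the 2x2 table [[a, b], [c, d]]."""
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(p)


def membrane_contingency(
    records: Sequence[ProteinRecord], flag: dict[str, bool]
) -> tuple[np.ndarray, float]:
    """2x2 contingency of membrane status against any binary per-accession
    property, with its two-sided Fisher's exact p-value.

    Rows: membrane / non-membrane; columns: property True / False.
    """
    tbl = np.zeros((2, 2), dtype=int)
    for r in records:
        i = 0 if r.is_membrane else 1
        j = 0 if flag.get(r.accession, False) else 1
        tbl[i, j] += 1
    return tbl, fisher_2x2(*tbl.ravel())
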