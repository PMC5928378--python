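"""Readers/writers for the formats the pipeline touches and the shared record types.

Protein sequences are restricted to the 20 standard one-letter codes: every
downstream component (degenerate motif classes, hydropathy tables, residue
mass tables) is defined only over that alphabet.  Ambiguity codes
(B, Z, X, U, O, J) are rejected by default; in permissive mode they are
mapped to ``X``, which no motif class or mass table will ever match, so
affected windows drop out of the analysis instead of poisoning it.

All residue coordinates in this package are 1-based with inclusive ranges,
matching the convention of protein literature ("threonine-168").
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
AMBIGUOUS_AA = frozenset("BZXUOJ")
_LETTERS = frozenset(string.ascii_uppercase)


class RdhcError(Exception):
    """Base class for all data errors raised by this package."""


class SequenceAlphabetError(RdhcError):
    """A sequence contains a character outside the accepted alphabet."""


class DuplicateIdError(RdhcError):
    """Two records in one input share an identifier."""


class TableFormatError(RdhcError):
    """A tabular input is malformed (missing column, duplicate key, bad value)."""


@dataclass
class ProteinRecord:
    """A named amino-acid sequence with genome-of-origin metadata."""

    id: str
    sequence: str
    description: str = ""
    genome_id: str = ""

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.sequence)


@dataclass(frozen=True)
class GenomeAnnotation:
    """Per-genome flags used by the co-occurrence filter."""

    genome_id: str
    has_rdhA: bool
    taxon_label: str = ""


def clean_sequence(raw: str, *, permissive: bool = False, record_id: str = "?") -> str:
    """Normalise a raw sequence string and enforce the residue alphabet.

    Upper-cases, strips whitespace and digits (tolerates copy-pasted
    alignment blocks), and drops a single terminal ``*`` stop marker.

    Structural junk (any non-letter) is always a hard error and is reported
    first, at its 1-based position in the cleaned sequence.  Ambiguity codes
    are then rejected unless ``permissive``, in which case they become ``X``.
    """
    s = "".join(raw.split()).upper()
    s = s.translate(str.maketrans("", "", string.digits))
    if s.endswith("*"):
        s = s[:-1]
    for pos, ch in enumerate(s, start=1):
        if ch not in _LETTERS:
            raise SequenceAlphabetError(
                f"record {record_id!r}: illegal character {ch!r} at position {pos}"
            )
    out = []
    for pos, ch in enumerate(s, start=1):
        if ch in STANDARD_AA:
            out.append(ch)
        elif ch in AMBIGUOUS_AA:
            if permissive:
                out.append("X")
            else:
                raise SequenceAlphabetError(
                    f"record {record_id!r}: ambiguity code {ch!r} at position {pos} "
                    "(use permissive mode to mask to X)"
                )
        else:
            raise SequenceAlphabetError(
                f"record {record_id!r}: non-residue letter {ch!r} at position {pos}"
            )
    if not out:
        raise SequenceAlphabetError(f"record {record_id!r}: empty sequence")
    return "".join(out)


def read_fasta(path: str | Path, *, permissive: bool = False) -> list[ProteinRecord]:
    """Read a protein FASTA file into validated :class:`ProteinRecord` objects.

    The header token before the first whitespace becomes the id; the
    remainder of the header line is the description.  Duplicate ids and
    out-of-alphabet residues are hard errors — parsing never returns
    partial data.
    """
    records: list[ProteinRecord] = []
    seen: dict[str, int] = {}
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        if rec.id in seen:
            raise DuplicateIdError(
                f"duplicate id {rec.id!r} (entries {seen[rec.id] + 1} and {i + 1}) in {path}"
            )
        seen[rec.id] = i
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        genome = ""
        m = re.search(r"\bgenome=(\S+)", desc)
        if m:
            genome = m.group(1)
        seq = clean_sequence(str(rec.seq), permissive=permissive, record_id=rec.id)
        records.append(
            ProteinRecord(id=rec.id, sequence=seq, description=desc, genome_id=genome)
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as protein FASTA with lines wrapped at ``width``.

    A non-empty ``genome_id`` is carried in the header as a ``genome=``
    token so that genome-of-origin survives the FASTA round trip.
    """
    seqrecords = []
    for r in records:
        desc = r.description
        if r.genome_id and f"genome={r.genome_id}" not in desc:
            desc = f"genome={r.genome_id}" + (f" {desc}" if desc else "")
        seqrecords.append(SeqRecord(Seq(r.sequence), id=r.id, description=desc))
    writer = SeqIO.FastaIO.FastaWriter(str(path), wrap=width)
    writer.write_file(seqrecords)


def read_genome_table(path: str | Path) -> dict[str, GenomeAnnotation]:
    """Read the per-genome annotation TSV (columns genome_id, has_rdhA, taxon_label).

    Boolean flags accept ``0/1/true/false`` (case-insensitive).  Unknown
    columns are ignored; missing required columns and duplicate genome ids
    are hard errors.
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise TableFormatError(f"{path}: empty genome table") from exc
    required = {"genome_id", "has_rdhA"}
    missing = required - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: missing required column(s) {sorted(missing)}")
    if "taxon_label" not in df.columns:
        df["taxon_label"] = ""
    dups = df["genome_id"][df["genome_id"].duplicated()].tolist()
    if dups:
        raise TableFormatError(f"{path}: duplicate genome_id {sorted(set(dups))}")
    table: dict[str, GenomeAnnotation] = {}
    truthy = {"1": True, "true": True, "0": False, "false": False}
    for _, row in df.iterrows():
        raw = str(row["has_rdhA"]).strip().lower()
        if raw not in truthy:
            raise TableFormatError(
                f"{path}: has_rdhA value {row['has_rdhA']!r} for genome "
                f"{row['genome_id']!r} is not one of 0/1/true/false"
            )
        table[row["genome_id"]] = GenomeAnnotation(
            genome_id=row["genome_id"],
            has_rdhA=truthy[raw],
            taxon_label=str(row["taxon_label"]) if pd.notna(row["taxon_label"]) else "",
        )
    return table


def write_table(df: pd.DataFrame, path: str | Path, params: Mapping[str, object] | None = None) -> None:
    """Write a TSV with a '#'-prefixed comment header recording version and parameters."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# rdhc-miner {__version__}\n")
        for key, value in (params or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=False)
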