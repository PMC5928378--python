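"""Degenerate-motif engine for the RdhC family signatures.

Three motifs define the family at sequence level:

* ``FMN_CONSENSUS`` — ``[S/T]G[A/S]TX[S/T]``, the flavinylation consensus
  whose fully conserved threonine (4th element) is the covalent FMN
  acceptor;
* ``FTP_MOTIF`` — ``[DN]X2[ST]G[AS]TX[ST]``, the broader flavin-trafficking
  acceptor motif used for whole-proteome scans (acceptor is the 7th
  element);
* ``CX3CP`` — the conserved cysteine signature of unknown function.

Patterns are ordered lists of residue sets over the 20 standard amino
acids; ``X`` is the full alphabet and therefore never matches the ``X``
*character* that permissive parsing writes into masked sequences.
Overlapping hits are all reported.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .seqio import STANDARD_AA, ProteinRecord, RdhcError

AA_ORDER = tuple(sorted(STANDARD_AA))  # alphabetical, fixed column order
_AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}
FULL_SET = frozenset(STANDARD_AA)


class MotifSyntaxError(RdhcError):
    """The motif pattern string does not conform to the grammar."""


@dataclass(frozen=True)
class MotifPattern:
    """A compiled degenerate motif: ordered residue sets plus acceptor bookkeeping."""

    name: str
    elements: tuple[frozenset[str], ...]
    acceptor_offset: int | None = None  # 1-based offset of the modified residue

    def __post_init__(self) -> None:
        if not self.elements:
            raise MotifSyntaxError(f"motif {self.name!r}: zero-length pattern")
        for i, el in enumerate(self.elements, start=1):
            if not el:
                raise MotifSyntaxError(f"motif {self.name!r}: empty class at element {i}")
            if not el <= FULL_SET:
                raise MotifSyntaxError(
                    f"motif {self.name!r}: element {i} contains non-standard residues"
                )
        if self.acceptor_offset is not None and not (
            1 <= self.acceptor_offset <= len(self.elements)
        ):
            raise MotifSyntaxError(
                f"motif {self.name!r}: acceptor offset {self.acceptor_offset} outside pattern"
            )

    def __len__(self) -> int:
        return len(self.elements)

    def matches_window(self, window: str) -> bool:
        """True iff ``window`` (same length as the pattern) satisfies every element."""
        if len(window) != len(self.elements):
            return False
        return all(ch in el for ch, el in zip(window, self.elements))

    def match_probability(self, background: Sequence[float] | None = None) -> float:
        """Per-window match probability under an i.i.d. background.

        Default background is uniform over the 20 residues, in which case the
        probability is the product of class sizes divided by 20**len.
        """
        if background is None:
            return math.prod(len(el) for el in self.elements) / 20 ** len(self.elements)
        p = 1.0
        for el in self.elements:
            p *= sum(background[_AA_INDEX[aa]] for aa in el)
        return p

    def to_regex(self) -> str:
        parts = []
        for el in self.elements:
            if len(el) == 1:
                parts.append(next(iter(el)))
            else:
                parts.append("[" + "".join(sorted(el)) + "]")
        return "".join(parts)


@dataclass(frozen=True)
class MotifHit:
    """One (possibly overlapping) occurrence of a motif in a protein."""

    protein_id: str
    motif_name: str
    start: int  # 1-based
    end: int  # 1-based inclusive
    matched_subsequence: str
    acceptor_position: int | None = None  # 1-based protein coordinate


_ELEMENT_RE = re.compile(
    r"""
    (?:
        \[(?P<set>[A-Z/]*)\]      # bracketed class, slash optional
      | (?P<res>[A-Z])            # plain residue or X wildcard
    )
    (?:_(?P<rep1>\d+)_|\((?P<rep2>\d+)\)|(?P<rep3>\d+))?   # optional repetition
    """,
    re.VERBOSE,
)


def compile_motif(
    pattern_string: str,
    name: str | None = None,
    acceptor_offset: int | None = None,
) -> MotifPattern:
    """Compile a pattern string such as ``"[S/T]G[A/S]TX[S/T]"`` or ``"CX3CP"``.

    Grammar: plain residue letters; bracketed alternatives ``[ST]`` /
    ``[S/T]``; ``X`` for any residue; an optional repetition count after any
    element written ``X_3_``, ``X(3)`` or ``X3``.
    """
    s = pattern_string.strip()
    if not s:
        raise MotifSyntaxError("empty pattern")
    elements: list[frozenset[str]] = []
    pos = 0
    while pos < len(s):
        m = _ELEMENT_RE.match(s, pos)
        if not m or m.start() != pos:
            raise MotifSyntaxError(
                f"pattern {pattern_string!r}: cannot parse at offset {pos} ({s[pos:]!r})"
            )
        if m.group("set") is not None:
            letters = m.group("set").replace("/", "")
            if not letters:
                raise MotifSyntaxError(f"pattern {pattern_string!r}: empty class []")
            bad = set(letters) - STANDARD_AA
            if bad:
                raise MotifSyntaxError(
                    f"pattern {pattern_string!r}: illegal residue(s) {sorted(bad)} in class"
                )
            element = frozenset(letters)
        else:
            res = m.group("res")
            if res == "X":
                element = FULL_SET
            elif res in STANDARD_AA:
                element = frozenset(res)
            else:
                raise MotifSyntaxError(
                    f"pattern {pattern_string!r}: illegal residue {res!r}"
                )
        reps = int(m.group("rep1") or m.group("rep2") or m.group("rep3") or 1)
        if reps < 1:
            raise MotifSyntaxError(f"pattern {pattern_string!r}: zero repetition")
        elements.extend([element] * reps)
        pos = m.end()
    return MotifPattern(
        name=name or pattern_string,
        elements=tuple(elements),
        acceptor_offset=acceptor_offset,
    )


#: Built-in family signatures, addressable by name everywhere a pattern is accepted.
BUILTIN_MOTIFS: dict[str, MotifPattern] = {
    "FMN_CONSENSUS": compile_motif("[S/T]G[A/S]TX[S/T]", name="FMN_CONSENSUS", acceptor_offset=4),
    "FTP_MOTIF": compile_motif("[DN]X2[ST]G[AS]TX[ST]", name="FTP_MOTIF", acceptor_offset=7),
    "CX3CP": compile_motif("CX3CP", name="CX3CP"),
}


def get_motif(name_or_pattern: str | MotifPattern) -> MotifPattern:
    """Resolve a built-in motif name or compile an ad-hoc pattern string."""
    if isinstance(name_or_pattern, MotifPattern):
        return name_or_pattern
    if name_or_pattern in BUILTIN_MOTIFS:
        return BUILTIN_MOTIFS[name_or_pattern]
    return compile_motif(name_or_pattern)


def scan_sequence(record: ProteinRecord | str, pattern: MotifPattern | str) -> list[MotifHit]:
    """All (overlapping) motif occurrences in one protein, in ascending start order.

    A sequence shorter than the motif yields an empty list.  Masked ``X``
    characters in the sequence match nothing, including the wildcard.
    """
    pattern = get_motif(pattern)
    if isinstance(record, str):
        record = ProteinRecord(id="?", sequence=record)
    # lookahead regex reports overlapping matches
    rx = re.compile("(?=(" + pattern.to_regex() + "))")
    hits = []
    for m in rx.finditer(record.sequence):
        start = m.start() + 1
        end = start + len(pattern) - 1
        acceptor = (
            start + pattern.acceptor_offset - 1 if pattern.acceptor_offset else None
        )
        hits.append(
            MotifHit(
                protein_id=record.id,
                motif_name=pattern.name,
                start=start,
                end=end,
                matched_subsequence=m.group(1),
                acceptor_position=acceptor,
            )
        )
    return hits


def hits_to_frame(hits: Iterable[MotifHit]) -> pd.DataFrame:
    """Tabulate hits in the standard TSV column order."""
    rows = [
        {
            "protein_id": h.protein_id,
            "motif_name": h.motif_name,
            "start": h.start,
            "end": h.end,
            "matched": h.matched_subsequence,
            "acceptor_position": h.acceptor_position if h.acceptor_position else "",
        }
        for h in hits
    ]
    return pd.DataFrame(
        rows,
        columns=["protein_id", "motif_name", "start", "end", "matched", "acceptor_position"],
    )


def count_motif_proteins(
    records: Iterable[ProteinRecord], pattern: MotifPattern | str
) -> tuple[int, pd.DataFrame]:
    """Number of distinct proteins with >= 1 hit, plus the full hit table."""
    pattern = get_motif(pattern)
    all_hits: list[MotifHit] = []
    matched_ids: set[str] = set()
    for rec in records:
        hits = scan_sequence(rec, pattern)
        if hits:
            matched_ids.add(rec.id)
            all_hits.extend(hits)
    return len(matched_ids), hits_to_frame(all_hits)


@dataclass(frozen=True)
class ColumnProfile:
    """Per-column residue frequencies and information content of an alignment.

    ``frequencies`` is (n_columns, 20) over :data:`AA_ORDER`; each row sums
    to 1.  ``information_bits`` is log2(20) minus the column Shannon entropy.
    """

    columns: tuple[int, ...]  # 1-based alignment coordinates
    frequencies: np.ndarray
    information_bits: np.ndarray
    n_sequences: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.frequencies, columns=list(AA_ORDER))
        df.insert(0, "position", list(self.columns))
        df["IC_bits"] = self.information_bits
        return df


def column_frequencies(
    aligned_records: Sequence[ProteinRecord | str],
    column_range: tuple[int, int] | None = None,
    *,
    gap_penalized: bool = False,
    small_sample_correction: bool = False,
) -> ColumnProfile:
    """Weblogo-style column statistics of an aligned block (gaps ``-``).

    Frequencies and entropy are computed over non-gap residues.  With
    ``gap_penalized`` the information content is scaled by the non-gap
    fraction; ``small_sample_correction`` subtracts the standard
    (s-1)/(2 ln2 n) bias term (negligible for the alignment sizes this
    family analysis uses, hence off by default).
    """
    seqs = [r.sequence if isinstance(r, ProteinRecord) else r for r in aligned_records]
    if not seqs:
        raise RdhcError("empty alignment")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise RdhcError("aligned sequences have unequal lengths")
    if column_range is None:
        column_range = (1, length)
    lo, hi = column_range
    if not (1 <= lo <= hi <= length):
        raise RdhcError(f"column range {column_range} outside alignment 1..{length}")

    cols = tuple(range(lo, hi + 1))
    freqs = np.zeros((len(cols), 20))
    ics = np.zeros(len(cols))
    log2_20 = math.log2(20)
    for ci, col in enumerate(cols):
        counts = np.zeros(20)
        n_gap = 0
        for s in seqs:
            ch = s[col - 1]
            if ch == "-":
                n_gap += 1
            elif ch in _AA_INDEX:
                counts[_AA_INDEX[ch]] += 1
            else:
                raise RdhcError(f"alignment column {col}: illegal character {ch!r}")
        total = counts.sum()
        if total == 0:
            raise RdhcError(f"alignment column {col} contains only gaps")
        p = counts / total
        freqs[ci] = p
        nz = p[p > 0]
        entropy = -float(np.sum(nz * np.log2(nz)))
        ic = log2_20 - entropy
        if small_sample_correction:
            ic -= (20 - 1) / (2 * math.log(2) * total)
        if gap_penalized:
            ic *= total / len(seqs)
        ics[ci] = max(ic, 0.0)
    return ColumnProfile(
        columns=cols,
        frequencies=freqs,
        information_bits=ics,
        n_sequences=len(seqs),
    )


def consensus_from_profile(
    profile: ColumnProfile,
    class_threshold: float = 0.9,
    max_class_size: int = 2,
) -> str:
    """Derive a degenerate consensus pattern string from a column profile.

    Per column, residues are taken in descending frequency until their
    cumulative frequency reaches ``class_threshold``; a class larger than
    ``max_class_size`` collapses to the wildcard ``X``.  The defaults
    (0.9 / 2) mirror the shape of the published family consensus, whose
    classes are all of size <= 2.
    """
    parts = []
    for row in profile.frequencies:
        order = sorted(range(20), key=lambda i: (-row[i], AA_ORDER[i]))
        cum = 0.0
        chosen: list[int] = []
        for idx in order:
            chosen.append(idx)
            cum += row[idx]
            if cum >= class_threshold - 1e-12:
                break
        if len(chosen) > max_class_size:
            parts.append("X")
        elif len(chosen) == 1:
            parts.append(AA_ORDER[chosen[0]])
        else:
            parts.append("[" + "/".join(AA_ORDER[i] for i in chosen) + "]")
    return "".join(parts)
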