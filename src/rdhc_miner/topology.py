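"""Hydropathy-based transmembrane segmentation and I/H/O topology strings.

The family analysis needs a reproducible, dependency-free answer to two
questions about a candidate protein: how many transmembrane helices does it
have, and on which side of the membrane does a given domain sit.  Both are
answered from a Kyte–Doolittle sliding-window hydropathy profile: maximal
runs above a threshold become helices (H), and the loops between them
alternate inside (I) / outside (O) starting from the N-terminal side, which
is either forced by the caller or chosen by the positive-inside rule
(lysine + arginine enriched on cytoplasmic loops).

This is a deliberately simple, fully specified stand-in for ensemble
topology predictors; its defaults (window 19, threshold 1.6, helix length
15–30) are standard hydropathy practice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .seqio import ProteinRecord, RdhcError

#: Kyte–Doolittle hydropathy values (dimensionless).
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}


class TopologyError(RdhcError):
    """Invalid segment geometry or out-of-range coordinates."""


@dataclass(frozen=True)
class HydropathyProfile:
    """Smoothed per-residue hydropathy scores for one protein."""

    scores: np.ndarray  # length L, defined for every residue
    window: int


def hydropathy_profile(record: ProteinRecord | str, window: int = 19) -> HydropathyProfile:
    """Centered moving average of Kyte–Doolittle values.

    The average is defined where the full window fits; terminal residues
    inherit the nearest defined score, which prevents phantom helices from
    half-windows at the ends.
    """
    seq = record.sequence if isinstance(record, ProteinRecord) else record
    n = len(seq)
    if window < 1 or window % 2 == 0:
        raise TopologyError(f"window must be odd and >= 1, got {window}")
    if window > n:
        raise TopologyError(f"window {window} longer than sequence ({n})")
    try:
        values = np.array([KYTE_DOOLITTLE[ch] for ch in seq])
    except KeyError as exc:
        raise TopologyError(f"residue {exc.args[0]!r} has no hydropathy value") from exc
    kernel = np.ones(window) / window
    valid = np.convolve(values, kernel, mode="valid")  # length n - window + 1
    half = window // 2
    scores = np.empty(n)
    scores[half:n - half] = valid
    scores[:half] = valid[0]
    scores[n - half:] = valid[-1]
    return HydropathyProfile(scores=scores, window=window)


def _split_long(scores: np.ndarray, start: int, end: int, min_len: int, max_len: int) -> list[tuple[int, int]]:
    """Split a 1-based run longer than max_len at its internal profile minimum."""
    if end - start + 1 <= max(max_len, 2):
        return [(start, end)] if end - start + 1 >= min_len else []
    interior = scores[start:end - 1]  # residues start+1 .. end-1 (1-based)
    m = int(np.argmin(interior)) + start + 1  # 1-based position of the minimum
    out = []
    out.extend(_split_long(scores, start, m - 1, min_len, max_len))
    out.extend(_split_long(scores, m + 1, end, min_len, max_len))
    return out


def predict_tm_segments(
    profile: HydropathyProfile,
    threshold: float = 1.6,
    min_len: int = 15,
    max_len: int = 30,
    merge_gap: int = 3,
) -> list[tuple[int, int]]:
    """Maximal above-threshold runs, merged across short dips and length-filtered.

    Runs separated by <= ``merge_gap`` residues are merged; runs shorter
    than ``min_len`` are discarded; runs longer than ``max_len`` are split
    at the internal minimum of the profile (avoids fusing adjacent helices
    inside one strongly hydrophobic stretch).  Returns 1-based inclusive
    (start, end) pairs in ascending order.
    """
    above = profile.scores >= threshold
    runs: list[list[int]] = []
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            runs.append([i + 1, j + 1])  # 1-based
            i = j + 1
        else:
            i += 1
    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 <= merge_gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    segments: list[tuple[int, int]] = []
    for start, end in merged:
        segments.extend(_split_long(profile.scores, start, end, min_len, max_len))
    return segments


@dataclass(frozen=True)
class Topology:
    """Alternating I/H/O segmentation of a protein.

    ``segments`` tile 1..L with no gaps or overlaps; every H is flanked by
    one inside and one outside region, and consecutive loops never share a
    label.
    """

    segments: tuple[tuple[int, int, str], ...]
    n_term_side: str  # 'I' or 'O'

    @property
    def length(self) -> int:
        return self.segments[-1][1] if self.segments else 0

    @property
    def tm_count(self) -> int:
        return sum(1 for _, _, lab in self.segments if lab == "H")

    def label_string(self) -> str:
        """Flat per-residue string over {I, H, O}."""
        out = []
        for start, end, lab in self.segments:
            out.append(lab * (end - start + 1))
        return "".join(out)

    def label_at(self, pos: int) -> str:
        if not (1 <= pos <= self.length):
            raise TopologyError(f"position {pos} outside 1..{self.length}")
        for start, end, lab in self.segments:
            if start <= pos <= end:
                return lab
        raise AssertionError("segments do not tile the protein")  # pragma: no cover

    def loops(self) -> list[tuple[int, int, str]]:
        return [s for s in self.segments if s[2] != "H"]


def assign_topology(
    segments: Sequence[tuple[int, int]],
    length: int,
    n_term_side: str = "I",
) -> Topology:
    """Tile 1..L with loops alternating from ``n_term_side``; each helix flips the side."""
    if n_term_side not in ("I", "O"):
        raise TopologyError(f"n_term_side must be 'I' or 'O', got {n_term_side!r}")
    prev_end = 0
    for start, end in segments:
        if start <= prev_end:
            raise TopologyError(f"segments overlap or are unsorted near ({start}, {end})")
        if end < start or end > length:
            raise TopologyError(f"segment ({start}, {end}) outside 1..{length}")
        prev_end = end
    out: list[tuple[int, int, str]] = []
    side = n_term_side
    pos = 1
    for start, end in segments:
        if start > pos:
            out.append((pos, start - 1, side))
        out.append((start, end, "H"))
        side = "O" if side == "I" else "I"
        pos = end + 1
    if pos <= length:
        out.append((pos, length, side))
    return Topology(segments=tuple(out), n_term_side=n_term_side)


@dataclass(frozen=True)
class DomainLocation:
    """Where a residue range sits relative to the membrane."""

    fractions: dict  # {'I': f, 'H': f, 'O': f}, summing to 1
    majority_label: str
    fully_within_one_loop: bool


def locate_domain(topology: Topology, domain_start: int, domain_end: int) -> DomainLocation:
    """Fraction of a domain's residues in I/H/O, its majority side, and whether
    it lies entirely within a single loop."""
    if not (1 <= domain_start <= domain_end <= topology.length):
        raise TopologyError(
            f"domain ({domain_start}, {domain_end}) outside 1..{topology.length}"
        )
    counts = {"I": 0, "H": 0, "O": 0}
    labels = topology.label_string()
    for pos in range(domain_start, domain_end + 1):
        counts[labels[pos - 1]] += 1
    n = domain_end - domain_start + 1
    fractions = {k: v / n for k, v in counts.items()}
    majority = max(counts, key=lambda k: (counts[k], k))
    fully = any(
        lab != "H" and start <= domain_start and domain_end <= end
        for start, end, lab in topology.segments
    )
    return DomainLocation(
        fractions=fractions, majority_label=majority, fully_within_one_loop=fully
    )


def choose_orientation(segments: Sequence[tuple[int, int]], sequence: str) -> str:
    """Positive-inside rule: pick the N-terminal side that maximises K+R in
    inside loops; ties go to 'I'."""
    counts = {}
    for side in ("I", "O"):
        topo = assign_topology(segments, len(sequence), n_term_side=side)
        kr = 0
        for start, end, lab in topo.segments:
            if lab == "I":
                kr += sum(1 for ch in sequence[start - 1:end] if ch in "KR")
        counts[side] = kr
    return "I" if counts["I"] >= counts["O"] else "O"
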