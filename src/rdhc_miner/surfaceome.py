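"""In-silico tryptic digestion and surface-shaving peptide classification.

Surface shaving treats intact cells with trypsin so that only peptides
exposed on the outside of the membrane are released; cytoplasmic peptides
appear only when the membrane fraction itself is digested.  Comparing the
two detection sets against a predicted topology therefore tests the
topology: the prediction is *supported* when the shaved sample contains at
least one exposed (O-loop) peptide and no cytoplasmic (I-loop) peptide.

Trypsin specificity is the standard rule — cleavage C-terminal to K or R
except when the next residue is proline; no semi-tryptic peptides.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .seqio import ProteinRecord, RdhcError
from .topology import Topology

#: Typical MS observability window (residues); peptides outside are flagged
#: undetectable and skipped by the detection simulator.
DETECTABLE_MIN_LEN = 6
DETECTABLE_MAX_LEN = 40


@dataclass(frozen=True)
class Peptide:
    """A tryptic peptide located on its parent protein (1-based, inclusive)."""

    parent_id: str
    start: int
    end: int
    sequence: str
    missed_cleavages: int

    @property
    def coords(self) -> tuple[int, int]:
        return (self.start, self.end)


def digest(record: ProteinRecord | str, max_missed: int = 0) -> list[Peptide]:
    """Tryptic digest with up to ``max_missed`` missed cleavages.

    Cleaves after K/R except before P.  The zero-missed-cleavage peptides
    tile the parent exactly; higher missed-cleavage products are joins of
    consecutive fully tryptic peptides, deduplicated by coordinates.
    """
    if max_missed < 0:
        raise RdhcError(f"max_missed must be >= 0, got {max_missed}")
    if isinstance(record, str):
        record = ProteinRecord(id="?", sequence=record)
    seq = record.sequence
    n = len(seq)
    boundaries = [0]
    for i in range(n - 1):
        if seq[i] in "KR" and seq[i + 1] != "P":
            boundaries.append(i + 1)
    boundaries.append(n)
    base = [
        (boundaries[k] + 1, boundaries[k + 1])
        for k in range(len(boundaries) - 1)
    ]
    peptides: list[Peptide] = []
    for missed in range(min(max_missed, len(base) - 1) + 1):
        for k in range(len(base) - missed):
            start = base[k][0]
            end = base[k + missed][1]
            peptides.append(
                Peptide(
                    parent_id=record.id,
                    start=start,
                    end=end,
                    sequence=seq[start - 1:end],
                    missed_cleavages=missed,
                )
            )
    return peptides


@dataclass(frozen=True)
class PeptideLocalization:
    """A peptide's membrane-side assignment derived from the parent topology."""

    peptide: Peptide
    label: str  # exposed | cytoplasmic | membrane | mixed
    fractions: dict  # {'I': f, 'H': f, 'O': f}
    detectable: bool


def classify_peptide(
    peptide: Peptide,
    topology: Topology,
    exposure_threshold: float = 1.0,
) -> PeptideLocalization:
    """Label a peptide exposed / cytoplasmic / membrane / mixed.

    A peptide is *exposed* when its O-loop residue fraction reaches
    ``exposure_threshold`` (default 1.0: the whole peptide must lie in one
    outside loop, matching how shaving data are read peptide-by-peptide),
    and symmetrically for cytoplasmic (I) and membrane (H); anything else
    is mixed.
    """
    if peptide.end > topology.length:
        raise RdhcError(
            f"peptide {peptide.coords} extends beyond topology length {topology.length}"
        )
    if not 0.5 <= exposure_threshold <= 1.0:
        raise RdhcError(f"exposure_threshold must be in [0.5, 1], got {exposure_threshold}")
    labels = topology.label_string()
    counts = {"I": 0, "H": 0, "O": 0}
    for pos in range(peptide.start, peptide.end + 1):
        counts[labels[pos - 1]] += 1
    n = peptide.end - peptide.start + 1
    fractions = {k: v / n for k, v in counts.items()}
    if fractions["O"] >= exposure_threshold:
        label = "exposed"
    elif fractions["I"] >= exposure_threshold:
        label = "cytoplasmic"
    elif fractions["H"] >= exposure_threshold:
        label = "membrane"
    else:
        label = "mixed"
    detectable = DETECTABLE_MIN_LEN <= n <= DETECTABLE_MAX_LEN
    return PeptideLocalization(
        peptide=peptide, label=label, fractions=fractions, detectable=detectable
    )


def localize_digest(
    record: ProteinRecord,
    topology: Topology,
    max_missed: int = 0,
    exposure_threshold: float = 1.0,
) -> list[PeptideLocalization]:
    """Digest a protein and classify every peptide against its topology."""
    return [
        classify_peptide(p, topology, exposure_threshold)
        for p in digest(record, max_missed)
    ]


@dataclass(frozen=True)
class ShavingReport:
    """Counts of detected peptides per localization label and the topology verdict."""

    shaved_counts: dict  # label -> count among shaved detections
    control_counts: dict  # label -> count among membrane-control detections
    verdict: str  # supported | not_supported | uninformative

    def to_frame(self) -> pd.DataFrame:
        labels = ["exposed", "cytoplasmic", "membrane", "mixed"]
        return pd.DataFrame(
            {
                "label": labels,
                "detected_shaved": [self.shaved_counts.get(l, 0) for l in labels],
                "detected_control": [self.control_counts.get(l, 0) for l in labels],
            }
        )


def shaving_report(
    localizations: Sequence[PeptideLocalization],
    detections_shaved: Iterable[tuple[int, int]],
    detections_control: Iterable[tuple[int, int]],
) -> ShavingReport:
    """Score detection sets against the predicted topology.

    Detections are peptide (start, end) coordinate pairs; referencing a
    peptide absent from ``localizations`` is a hard error.  The verdict is
    *supported* when the shaved sample contains at least one exposed peptide
    and no cytoplasmic peptide, *not_supported* when any cytoplasmic peptide
    was shaved off intact cells, and *uninformative* when the shaved
    detections contain neither.
    """
    by_coords: Mapping[tuple[int, int], PeptideLocalization] = {
        loc.peptide.coords: loc for loc in localizations
    }

    def tally(detections: Iterable[tuple[int, int]], which: str) -> dict:
        counts: dict[str, int] = {}
        for coords in detections:
            coords = tuple(coords)
            if coords not in by_coords:
                raise RdhcError(f"{which} detection {coords} matches no known peptide")
            label = by_coords[coords].label
            counts[label] = counts.get(label, 0) + 1
        return counts

    shaved = tally(detections_shaved, "shaved")
    control = tally(detections_control, "control")
    if shaved.get("cytoplasmic", 0) > 0:
        verdict = "not_supported"
    elif shaved.get("exposed", 0) > 0:
        verdict = "supported"
    else:
        verdict = "uninformative"
    return ShavingReport(shaved_counts=shaved, control_counts=control, verdict=verdict)


def simulate_detections(
    localizations: Sequence[PeptideLocalization],
    sensitivity: float = 0.9,
    leakage: float = 0.0,
    seed: int = 0,
) -> tuple[set[tuple[int, int]], set[tuple[int, int]]]:
    """Bernoulli detection simulator for shaving experiments.

    Each detectable exposed peptide enters the shaved set with probability
    ``sensitivity``.  Each detectable cytoplasmic peptide enters the control
    (membrane) set with probability ``sensitivity`` and leaks into the
    shaved set with probability ``leakage`` (models partial cell lysis).
    Deterministic given ``seed``.
    """
    if not (0 <= sensitivity <= 1 and 0 <= leakage <= 1):
        raise RdhcError("sensitivity and leakage must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    shaved: set[tuple[int, int]] = set()
    control: set[tuple[int, int]] = set()
    for loc in localizations:
        if not loc.detectable:
            continue
        if loc.label == "exposed":
            if rng.random() < sensitivity:
                shaved.add(loc.peptide.coords)
        elif loc.label == "cytoplasmic":
            if rng.random() < sensitivity:
                control.add(loc.peptide.coords)
            if rng.random() < leakage:
                shaved.add(loc.peptide.coords)
    return shaved, control


def report_to_frame(localizations: Sequence[PeptideLocalization],
                    shaved: set[tuple[int, int]],
                    control: set[tuple[int, int]]) -> pd.DataFrame:
    """Per-peptide TSV rows: coordinates, label, and detection flags."""
    rows = []
    for loc in localizations:
        rows.append(
            {
                "protein_id": loc.peptide.parent_id,
                "start": loc.peptide.start,
                "end": loc.peptide.end,
                "sequence": loc.peptide.sequence,
                "missed_cleavages": loc.peptide.missed_cleavages,
                "label": loc.label,
                "detectable": int(loc.detectable),
                "detected_shaved": int(loc.peptide.coords in shaved),
                "detected_control": int(loc.peptide.coords in control),
            }
        )
    return pd.DataFrame(rows)
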