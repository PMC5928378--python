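"""Seeded generators for synthetic proteomes with planted RdhC architectures.

The generators emulate the structural properties the rest of the pipeline
assumes about real data: RdhC-like proteins with six hydrophobic
transmembrane stretches, an exocytoplasmic FMN-binding domain between the
first two helices carrying one planted FMN-consensus instance, and two
CX3CP motifs in the C-terminal membrane module — embedded in a majority of
i.i.d. random decoy proteins, with genome tables whose rdhA co-occurrence
is fully controllable (including the adversarial case of an RdhC-like
protein in an rdhA-less genome).

Design choices that keep planted truth exact: decoy residues are uniform
over the 20 standard residues (so enumerated motif false-positive rates
are exact); transmembrane stretches draw from {I,L,V,F,A,M} and loops from
a polar alphabet without cysteine, so planted CX3CP counts are exact;
lysine/arginine are enriched threefold on inside loops and depleted on
outside loops, which makes the positive-inside orientation heuristic
deterministic on default architectures; the FBD loop additionally carries
evenly spaced planted tryptic sites so it yields MS-observable peptides.
Every generator is a pure function of (spec, seed), and every generated
dataset ships a truth table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .clustering import pairwise_identity
from .flavin_mass import ProteoformMass, diagnostic_ions, fragment_ions
from .motifs import BUILTIN_MOTIFS, MotifPattern
from .seqio import GenomeAnnotation, ProteinRecord, RdhcError, write_fasta, write_table

TM_RESIDUES = "ILVFAM"  # hydrophobic, no cysteine
#: Draw weights for TM residues.  The mix leans on I/L/V so that a planted
#: helix has a mean hydropathy near 4, which keeps the sliding-window
#: profile of every helix above the detection threshold with a wide margin
#: (the documented contrast the recovery guarantees rely on).
TM_WEIGHTS = np.array([0.35, 0.30, 0.25, 0.06, 0.02, 0.02])
LOOP_RESIDUES = "DEGHKNPQRSTY"  # polar/charged, no cysteine
_MOTIF_X_RESIDUES = "".join(sorted(set("ACDEFGHIKLMNPQRSTVWY") - set("C")))
ALL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class RdhCArchitectureSpec:
    """Blueprint of a planted RdhC-like protein.

    Defaults mirror the canonical architecture: six transmembrane helices,
    an FMN-binding domain of 140-170 residues between helices 1 and 2
    (echoing the 160-residue span of the characterized family member), two
    CX3CP motifs in the C-terminal module, N-terminus inside.
    """

    n_tm: int = 6
    tm_len: tuple[int, int] = (23, 30)
    loop_len: tuple[int, int] = (12, 30)
    fbd_len: tuple[int, int] = (140, 170)
    n_cx3cp: int = 2
    motif: MotifPattern = BUILTIN_MOTIFS["FMN_CONSENSUS"]
    kr_enrichment: float = 3.0
    kr_depletion: float = 0.1

    def __post_init__(self) -> None:
        if self.n_tm < 2:
            raise RdhcError("RdhC architecture needs at least 2 TM helices "
                            "(the FBD loop sits between helices 1 and 2)")
        for name, (lo, hi) in (
            ("tm_len", self.tm_len), ("loop_len", self.loop_len), ("fbd_len", self.fbd_len)
        ):
            if lo > hi or lo < 1:
                raise RdhcError(f"infeasible {name} range ({lo}, {hi})")
        if self.loop_len[0] < 8:
            raise RdhcError("loops shorter than 8 residues cannot host planted motifs")


@dataclass
class TruthRow:
    """Ground truth for one generated protein."""

    protein_id: str
    is_rdhc: bool
    genome_id: str
    has_rdhA: bool
    tm_segments: tuple[tuple[int, int], ...] = ()
    fmn_start: int | None = None
    fmn_end: int | None = None
    fmn_acceptor: int | None = None
    cx3cp_starts: tuple[int, ...] = ()
    fbd_start: int | None = None
    fbd_end: int | None = None


def _loop_weights(kr_factor: float) -> np.ndarray:
    w = np.ones(len(LOOP_RESIDUES))
    for i, ch in enumerate(LOOP_RESIDUES):
        if ch in "KR":
            w[i] = kr_factor
    return w / w.sum()


def _draw(rng: np.random.Generator, alphabet: str, n: int, weights: np.ndarray | None = None) -> list[str]:
    idx = rng.choice(len(alphabet), size=n, p=weights)
    return [alphabet[i] for i in idx]


def _instantiate_motif(pattern: MotifPattern, rng: np.random.Generator) -> str:
    """Sample one residue per motif class; wildcard positions avoid cysteine
    so planted CX3CP counts stay exact."""
    out = []
    for el in pattern.elements:
        if len(el) == 20:
            out.append(_MOTIF_X_RESIDUES[rng.integers(len(_MOTIF_X_RESIDUES))])
        else:
            choices = sorted(el)
            out.append(choices[rng.integers(len(choices))])
    return "".join(out)


def generate_rdhc_protein(
    spec: RdhCArchitectureSpec | None = None,
    seed: int = 0,
    protein_id: str = "rdhc_0001",
    genome_id: str = "",
    has_rdhA: bool = True,
) -> tuple[ProteinRecord, TruthRow]:
    """Generate one RdhC-like protein plus its truth row.

    Layout (N-terminus inside): I-loop, TM1, the FBD outside loop carrying
    the planted FMN motif, TM2, then alternating loop/TM for the remaining
    helices, ending in a C-terminal loop.  CX3CP copies are planted in the
    loops after TM2, preferring the most C-terminal loops.  Deterministic
    given ``seed``.
    """
    spec = spec or RdhCArchitectureSpec()
    rng = np.random.default_rng(seed)
    inside_w = _loop_weights(spec.kr_enrichment)
    outside_w = _loop_weights(spec.kr_depletion)

    # plan segment sequence: (kind, side) with side flipping after each TM
    pieces: list[tuple[str, str]] = [("loop", "I"), ("tm", ""), ("fbd", "O"), ("tm", "")]
    side = "I"  # side after TM2
    for _ in range(spec.n_tm - 2):
        pieces.append(("loop", side))
        pieces.append(("tm", ""))
        side = "O" if side == "I" else "I"
    pieces.append(("loop", side))

    # draw residue blocks
    blocks: list[list[str]] = []
    kinds: list[tuple[str, str]] = []
    for kind, loop_side in pieces:
        if kind == "tm":
            n = int(rng.integers(spec.tm_len[0], spec.tm_len[1] + 1))
            blocks.append(_draw(rng, TM_RESIDUES, n, TM_WEIGHTS))
        else:
            if kind == "fbd":
                n = int(rng.integers(spec.fbd_len[0], spec.fbd_len[1] + 1))
            else:
                n = int(rng.integers(spec.loop_len[0], spec.loop_len[1] + 1))
            w = inside_w if loop_side == "I" else outside_w
            blocks.append(_draw(rng, LOOP_RESIDUES, n, w))
        kinds.append((kind, loop_side))

    # plant the FMN motif inside the FBD loop, away from the loop edges
    fbd_index = next(i for i, (k, _) in enumerate(kinds) if k == "fbd")
    motif_seq = _instantiate_motif(spec.motif, rng)
    fbd_block = blocks[fbd_index]
    lo = 3
    hi = len(fbd_block) - len(motif_seq) - 3
    offset = int(rng.integers(lo, hi + 1))
    fbd_block[offset:offset + len(motif_seq)] = list(motif_seq)
    # keep the planted site free of the [DN]X2 trafficking-motif prefix so
    # the family consensus and the broader acceptor motif stay distinguishable
    if fbd_block[offset - 3] in "DN":
        fbd_block[offset - 3] = "EGHQSTY"[int(rng.integers(7))]

    # plant evenly spaced tryptic sites (K/R) across the FBD: the otherwise
    # K/R-depleted outside loop must still yield MS-observable (6-40 residue)
    # peptides, as the exocytoplasmic domain does in real shaving data
    n_sites = max(2, len(fbd_block) // 35)
    motif_zone = range(max(0, offset - 4), offset + len(motif_seq) + 1)
    for k in range(n_sites):
        pos = round((k + 1) * len(fbd_block) / (n_sites + 1))
        while pos >= 1 and (pos in motif_zone or pos >= len(fbd_block) - 1):
            pos -= 8
        if pos < 1:
            continue
        fbd_block[pos] = "KR"[int(rng.integers(2))]
        if fbd_block[pos + 1] == "P":  # proline would block the cleavage
            fbd_block[pos + 1] = "S"

    # plant CX3CP copies in post-TM2 loops, most C-terminal loops first
    cx3cp_pattern = BUILTIN_MOTIFS["CX3CP"]
    post_tm2_loops = [i for i, (k, _) in enumerate(kinds) if k == "loop" and i > fbd_index]
    cx_positions: list[tuple[int, int]] = []  # (block index, offset)
    targets = list(reversed(post_tm2_loops))
    for j in range(spec.n_cx3cp):
        block_i = targets[j % len(targets)] if targets else fbd_index
        block = blocks[block_i]
        taken = [off for bi, off in cx_positions if bi == block_i]
        for _attempt in range(200):
            off = int(rng.integers(0, len(block) - len(cx3cp_pattern) + 1))
            if all(abs(off - t) >= len(cx3cp_pattern) for t in taken):
                break
        else:  # pragma: no cover - loops are long enough in practice
            raise RdhcError("could not place CX3CP motifs without overlap")
        # wildcard positions of CX3CP drawn from the loop alphabet (no P/C)
        inst = "C" + "".join(_draw(rng, LOOP_RESIDUES.replace("P", ""), 3)) + "CP"
        block[off:off + len(inst)] = list(inst)
        cx_positions.append((block_i, off))

    # assemble and record truth coordinates
    sequence_parts: list[str] = []
    pos = 1
    tm_coords: list[tuple[int, int]] = []
    block_starts: list[int] = []
    for (kind, _), block in zip(kinds, blocks):
        block_starts.append(pos)
        if kind == "tm":
            tm_coords.append((pos, pos + len(block) - 1))
        sequence_parts.append("".join(block))
        pos += len(block)
    sequence = "".join(sequence_parts)

    fbd_start = block_starts[fbd_index]
    fmn_start = fbd_start + offset
    acceptor = fmn_start + (spec.motif.acceptor_offset or 1) - 1
    cx_starts = tuple(
        sorted(block_starts[bi] + off for bi, off in cx_positions)
    )
    record = ProteinRecord(
        id=protein_id,
        sequence=sequence,
        description="synthetic RdhC-like protein",
        genome_id=genome_id,
    )
    truth = TruthRow(
        protein_id=protein_id,
        is_rdhc=True,
        genome_id=genome_id,
        has_rdhA=has_rdhA,
        tm_segments=tuple(tm_coords),
        fmn_start=fmn_start,
        fmn_end=fmn_start + len(spec.motif) - 1,
        fmn_acceptor=acceptor,
        cx3cp_starts=cx_starts,
        fbd_start=fbd_start,
        fbd_end=fbd_start + len(fbd_block) - 1,
    )
    return record, truth


def protected_positions(truth: TruthRow) -> set[int]:
    """1-based positions that carry planted signal (motifs) for one protein."""
    protected: set[int] = set()
    if truth.fmn_start is not None:
        protected.update(range(truth.fmn_start, truth.fmn_end + 1))
    for start in truth.cx3cp_starts:
        protected.update(range(start, start + 6))
    return protected


@dataclass(frozen=True)
class GenomeLayout:
    """Genome set and how planted proteins are distributed over it.

    ``adversarial_rdhc`` planted proteins are assigned to rdhA-less
    genomes (exercising the co-occurrence filter); the rest go round-robin
    to rdhA-positive genomes.  Decoys go round-robin over all genomes.
    """

    genomes: tuple[GenomeAnnotation, ...] = (
        GenomeAnnotation("g01", True, "synthetic OHRB 1"),
        GenomeAnnotation("g02", True, "synthetic OHRB 2"),
        GenomeAnnotation("g03", True, "synthetic OHRB 3"),
        GenomeAnnotation("g04", True, "synthetic OHRB 4"),
        GenomeAnnotation("g05", False, "synthetic non-OHRB"),
    )
    adversarial_rdhc: int = 1


@dataclass
class SyntheticProteome:
    """A generated proteome bundle: records, genome table and truth table."""

    records: list[ProteinRecord]
    genomes: dict
    truth: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.records, outdir / "proteome.fasta")
        genome_df = pd.DataFrame(
            [
                {"genome_id": g.genome_id, "has_rdhA": int(g.has_rdhA), "taxon_label": g.taxon_label}
                for g in self.genomes.values()
            ]
        )
        write_table(genome_df, outdir / "genomes.tsv")
        write_table(self.truth, outdir / "truth.tsv")


def _truth_to_row(t: TruthRow) -> dict:
    return {
        "protein_id": t.protein_id,
        "is_rdhc": int(t.is_rdhc),
        "genome_id": t.genome_id,
        "has_rdhA": int(t.has_rdhA),
        "tm_segments": ";".join(f"{s}-{e}" for s, e in t.tm_segments),
        "fmn_start": t.fmn_start if t.fmn_start else "",
        "fmn_end": t.fmn_end if t.fmn_end else "",
        "fmn_acceptor": t.fmn_acceptor if t.fmn_acceptor else "",
        "cx3cp_starts": ";".join(str(s) for s in t.cx3cp_starts),
        "fbd_start": t.fbd_start if t.fbd_start else "",
        "fbd_end": t.fbd_end if t.fbd_end else "",
    }


def generate_proteome(
    n_proteins: int = 500,
    rdhc_fraction: float = 0.05,
    genome_layout: GenomeLayout | None = None,
    seed: int = 0,
    spec: RdhCArchitectureSpec | None = None,
    decoy_len_range: tuple[int, int] = (80, 800),
) -> SyntheticProteome:
    """Generate a proteome of planted RdhC proteins among random decoys.

    Decoys are i.i.d. uniform draws over the 20 residues with log-uniform
    lengths in ``decoy_len_range``.  ``rdhc_fraction`` of the proteins are
    planted RdhC architectures; genome assignment follows ``genome_layout``.
    """
    if not (0 <= rdhc_fraction <= 1):
        raise RdhcError(f"rdhc_fraction must be in [0, 1], got {rdhc_fraction}")
    layout = genome_layout or GenomeLayout()
    spec = spec or RdhCArchitectureSpec()
    rng = np.random.default_rng(seed)
    n_rdhc = round(n_proteins * rdhc_fraction)
    positive = [g for g in layout.genomes if g.has_rdhA]
    negative = [g for g in layout.genomes if not g.has_rdhA]
    n_adv = min(layout.adversarial_rdhc, n_rdhc)
    if n_adv and not negative:
        raise RdhcError("layout requests adversarial RdhC proteins but has no rdhA-less genome")
    if n_rdhc > n_adv and not positive:
        raise RdhcError("layout has no rdhA-positive genome for planted RdhC proteins")

    records: list[ProteinRecord] = []
    truths: list[TruthRow] = []
    for i in range(n_rdhc):
        if i < n_adv:
            genome = negative[i % len(negative)]
        else:
            genome = positive[(i - n_adv) % len(positive)]
        child_seed = int(rng.integers(2**31))
        rec, truth = generate_rdhc_protein(
            spec,
            seed=child_seed,
            protein_id=f"rdhc_{i + 1:04d}",
            genome_id=genome.genome_id,
            has_rdhA=genome.has_rdhA,
        )
        records.append(rec)
        truths.append(truth)

    n_decoy = n_proteins - n_rdhc
    log_lo, log_hi = math.log(decoy_len_range[0]), math.log(decoy_len_range[1])
    for i in range(n_decoy):
        genome = layout.genomes[i % len(layout.genomes)]
        length = int(round(math.exp(rng.uniform(log_lo, log_hi))))
        seq = "".join(_draw(rng, ALL_RESIDUES, length))
        pid = f"decoy_{i + 1:04d}"
        records.append(
            ProteinRecord(
                id=pid, sequence=seq, description="synthetic decoy",
                genome_id=genome.genome_id,
            )
        )
        truths.append(
            TruthRow(
                protein_id=pid, is_rdhc=False,
                genome_id=genome.genome_id, has_rdhA=genome.has_rdhA,
            )
        )

    truth_df = pd.DataFrame([_truth_to_row(t) for t in truths])
    genomes = {g.genome_id: g for g in layout.genomes}
    return SyntheticProteome(records=records, genomes=genomes, truth=truth_df)


def mutate_family(
    seed_record: ProteinRecord,
    n_variants: int,
    target_identity: float,
    seed: int = 0,
    protected: Sequence[int] = (),
) -> list[ProteinRecord]:
    """Point-substitution variants of a seed at a controlled identity level.

    Each variant receives substitutions at distinct, non-protected
    positions until its identity to the seed falls within
    [target_identity - 0.01, target_identity].  Substitutions preserve the
    residue category (hydrophobic stays hydrophobic, polar stays polar) so
    planted topology survives.  Planted motif positions must be passed as
    ``protected``; reaching the target without touching them must be
    feasible or an error is raised.
    """
    if not (0 < target_identity <= 1):
        raise RdhcError(f"target_identity must be in (0, 1], got {target_identity}")
    rng = np.random.default_rng(seed)
    seq = seed_record.sequence
    L = len(seq)
    n_sub = math.ceil((1 - target_identity) * L - 1e-9)
    if n_sub > 0 and (L - n_sub) / L < target_identity - 0.01 - 1e-9:
        raise RdhcError(
            f"sequence of length {L} cannot hit identity window "
            f"[{target_identity - 0.01}, {target_identity}] with whole substitutions"
        )
    protected_set = set(protected)
    candidates = [i for i in range(1, L + 1) if i not in protected_set]
    if n_sub > len(candidates):
        raise RdhcError(
            f"target identity {target_identity} unreachable: needs {n_sub} substitutions "
            f"but only {len(candidates)} unprotected positions"
        )
    variants = []
    hydrophobic = set(TM_RESIDUES)
    for v in range(n_variants):
        if n_sub == 0:
            variants.append(
                ProteinRecord(
                    id=f"{seed_record.id}_v{v + 1}",
                    sequence=seq,
                    description=f"variant of {seed_record.id} at identity {target_identity}",
                    genome_id=seed_record.genome_id,
                )
            )
            continue
        sites = rng.choice(len(candidates), size=n_sub, replace=False)
        chars = list(seq)
        for si in sites:
            pos = candidates[si]
            old = chars[pos - 1]
            pool = TM_RESIDUES if old in hydrophobic else LOOP_RESIDUES
            choices = [c for c in pool if c != old]
            chars[pos - 1] = choices[int(rng.integers(len(choices)))]
        variants.append(
            ProteinRecord(
                id=f"{seed_record.id}_v{v + 1}",
                sequence="".join(chars),
                description=f"variant of {seed_record.id} at identity {target_identity}",
                genome_id=seed_record.genome_id,
            )
        )
    for var in variants:
        ident = pairwise_identity(var.sequence, seq)
        if not (target_identity - 0.01 - 1e-9 <= ident <= target_identity + 1e-9):
            raise RdhcError(
                f"variant {var.id} landed at identity {ident:.4f}, outside "
                f"[{target_identity - 0.01}, {target_identity}]"
            )  # pragma: no cover - construction guarantees the window
    return variants


def generate_spectrum(
    proteoform: ProteoformMass,
    noise_peaks: int = 0,
    mz_jitter_sd: float = 0.0,
    seed: int = 0,
    include_diagnostics: bool = True,
) -> tuple[np.ndarray, list[tuple[str, float]]]:
    """Synthetic MS/MS peak list for a proteoform, with stored truth.

    All singly charged b/y ions (plus the diagnostic flavin ions when
    requested) receive Gaussian m/z jitter of ``mz_jitter_sd``; uniform
    noise peaks are added over the observed m/z range.  Returns the sorted
    (m/z, intensity) array and the list of true (ion name, theoretical m/z).
    """
    rng = np.random.default_rng(seed)
    truth = fragment_ions(proteoform)
    if include_diagnostics:
        truth = truth + diagnostic_ions(proteoform.mode)
    mzs = np.array([mz for _, mz in truth])
    obs = mzs + rng.normal(0.0, mz_jitter_sd, size=len(mzs)) if mz_jitter_sd > 0 else mzs.copy()
    intensities = rng.uniform(50.0, 100.0, size=len(obs))
    if noise_peaks > 0:
        lo, hi = 100.0, float(mzs.max() * 1.1)
        noise_mz = rng.uniform(lo, hi, size=noise_peaks)
        noise_int = rng.uniform(1.0, 20.0, size=noise_peaks)
        obs = np.concatenate([obs, noise_mz])
        intensities = np.concatenate([intensities, noise_int])
    order = np.argsort(obs)
    peaks = np.column_stack([obs[order], intensities[order]])
    return peaks, truth
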