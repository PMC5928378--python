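"""Identity clustering, the rdhA co-occurrence filter, and the RdhC classifier.

The family curation pipeline reduces raw candidates in three steps:

1. structural classification (``classify_rdhc``): a candidate must carry
   enough transmembrane helices, an FMN consensus hit whose acceptor
   threonine sits in an outside loop, and at least two CX3CP motifs;
2. greedy identity clustering at a 95% threshold to collapse
   near-identical database entries into unique clusters;
3. genome co-occurrence: clusters are kept only when at least one member
   comes from a genome that also encodes a reductive dehalogenase (rdhA),
   the functional context that defines the family.

Identity is computed from a global alignment (match +1, mismatch 0, affine
gaps -10/-0.5) with the identical-pair count divided by the length of the
shorter sequence — the CD-HIT convention.  Greedy clustering processes
records by descending length (ties broken by id) and joins the first
cluster whose representative matches at or above the threshold, which makes
the partition deterministic.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import Align

from .motifs import MotifHit
from .seqio import GenomeAnnotation, ProteinRecord, RdhcError
from .topology import Topology


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -0.5
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(a: str, b: str, denominator: str = "shorter") -> float:
    """Fraction of identical aligned residue pairs between two sequences.

    ``denominator`` selects the normalisation: ``"shorter"`` (default,
    CD-HIT style — identical up to truncation scores 1.0) or ``"columns"``
    (alignment length including gap columns).
    """
    if not a or not b:
        raise RdhcError("pairwise_identity: empty sequence")
    alignment = _ALIGNER.align(a, b)[0]
    identities = alignment.counts().identities
    if denominator == "shorter":
        return identities / min(len(a), len(b))
    if denominator == "columns":
        return identities / alignment.length
    raise RdhcError(f"unknown identity denominator {denominator!r}")


def _composition_bound(ca: Counter, cb: Counter, shorter: int) -> float:
    """Upper bound on 'shorter'-denominator identity from residue composition.

    No alignment can pair more copies of a residue than both sequences
    contain, so sum(min counts)/shorter bounds the identity; used to skip
    hopeless alignments during greedy clustering without changing results.
    """
    overlap = sum(min(ca[r], cb[r]) for r in ca.keys() & cb.keys())
    return overlap / shorter


@dataclass
class Cluster:
    """A representative and its members at >= threshold identity."""

    representative_id: str
    member_ids: list[str]  # includes the representative
    threshold: float
    identities: dict  # member_id -> identity to representative
    rdha_flags: dict = field(default_factory=dict)  # member_id -> genome has_rdhA

    @property
    def size(self) -> int:
        return len(self.member_ids)


def greedy_cluster(
    records: Sequence[ProteinRecord],
    threshold: float = 0.95,
    denominator: str = "shorter",
) -> list[Cluster]:
    """Greedy incremental clustering against cluster representatives.

    Records are sorted by descending length (ties: lexicographic id); each
    joins the first existing cluster whose representative it matches at
    >= ``threshold`` identity, else founds a new cluster.  The output
    partitions the input.
    """
    if not (0 < threshold <= 1):
        raise RdhcError(f"threshold must be in (0, 1], got {threshold}")
    ordered = sorted(records, key=lambda r: (-len(r.sequence), r.id))
    clusters: list[Cluster] = []
    reps: list[ProteinRecord] = []
    comps: list[Counter] = []
    for rec in ordered:
        comp = Counter(rec.sequence)
        placed = False
        for cluster, rep, rep_comp in zip(clusters, reps, comps):
            shorter = min(len(rec.sequence), len(rep.sequence))
            if denominator == "shorter" and _composition_bound(rep_comp, comp, shorter) < threshold:
                continue
            ident = pairwise_identity(rec.sequence, rep.sequence, denominator)
            if ident >= threshold:
                cluster.member_ids.append(rec.id)
                cluster.identities[rec.id] = ident
                placed = True
                break
        if not placed:
            clusters.append(
                Cluster(
                    representative_id=rec.id,
                    member_ids=[rec.id],
                    threshold=threshold,
                    identities={rec.id: 1.0},
                )
            )
            reps.append(rec)
            comps.append(comp)
    return clusters


def cooccurrence_filter(
    clusters: Sequence[Cluster],
    genome_of: Mapping[str, str],
    genome_table: Mapping[str, GenomeAnnotation],
) -> list[Cluster]:
    """Retain clusters with >= 1 member from an rdhA-positive genome.

    Members from rdhA-less genomes are flagged (``rdha_flags``) but kept
    inside retained clusters.  Members whose genome is missing from the
    table are a hard error.
    """
    unknown = sorted(
        {
            genome_of.get(m, "?")
            for c in clusters
            for m in c.member_ids
            if genome_of.get(m, "?") not in genome_table
        }
    )
    if unknown:
        raise RdhcError(f"genome id(s) not in genome table: {unknown}")
    retained = []
    for cluster in clusters:
        flags = {
            m: genome_table[genome_of[m]].has_rdhA for m in cluster.member_ids
        }
        cluster.rdha_flags = flags
        if any(flags.values()):
            retained.append(cluster)
    return retained


@dataclass(frozen=True)
class RdhCCandidate:
    """Evidence and decision for one protein against the family definition."""

    protein_id: str
    fmn_hits: tuple[MotifHit, ...]
    cx3cp_hits: tuple[MotifHit, ...]
    tm_count: int
    fbd_side: str  # topology label at the best FMN acceptor, or '-'
    accepted: bool
    reasons: tuple[str, ...]  # empty when accepted


def classify_rdhc(
    record: ProteinRecord,
    fmn_hits: Sequence[MotifHit],
    cx3cp_hits: Sequence[MotifHit],
    topology: Topology,
    min_tm: int = 3,
    min_cx3cp: int = 2,
) -> RdhCCandidate:
    """Apply the structural family definition to one protein.

    Accept iff the protein has >= ``min_tm`` transmembrane helices, at
    least one FMN-consensus hit whose acceptor residue lies in an outside
    (O) loop, and >= ``min_cx3cp`` CX3CP hits.  Every failed clause
    contributes a reason code, so rejections are fully auditable.
    """
    reasons: list[str] = []
    if topology.tm_count < min_tm:
        reasons.append("tm<min")
    exposed_acceptors = [
        h for h in fmn_hits
        if h.acceptor_position is not None
        and h.acceptor_position <= topology.length
        and topology.label_at(h.acceptor_position) == "O"
    ]
    if not fmn_hits:
        reasons.append("fmn<1")
    elif not exposed_acceptors:
        reasons.append("fmn-acceptor-not-O")
    if len(cx3cp_hits) < min_cx3cp:
        reasons.append(f"cx3cp<{min_cx3cp}")
    if exposed_acceptors:
        fbd_side = "O"
    elif fmn_hits and fmn_hits[0].acceptor_position is not None and fmn_hits[0].acceptor_position <= topology.length:
        fbd_side = topology.label_at(fmn_hits[0].acceptor_position)
    else:
        fbd_side = "-"
    return RdhCCandidate(
        protein_id=record.id,
        fmn_hits=tuple(fmn_hits),
        cx3cp_hits=tuple(cx3cp_hits),
        tm_count=topology.tm_count,
        fbd_side=fbd_side,
        accepted=not reasons,
        reasons=tuple(reasons),
    )


@dataclass(frozen=True)
class FamilyReport:
    """Summary of a curated family: cluster count, sequences, size histogram."""

    n_clusters: int
    n_sequences: int
    size_histogram: dict  # cluster size -> number of clusters
    per_genome: pd.DataFrame  # genome_id, taxon_label, n_members (may be empty)


def family_report(
    clusters: Sequence[Cluster],
    genome_of: Mapping[str, str] | None = None,
    genome_table: Mapping[str, GenomeAnnotation] | None = None,
) -> FamilyReport:
    """Aggregate retained clusters into the family-level summary."""
    histogram: dict[int, int] = {}
    total = 0
    for c in clusters:
        histogram[c.size] = histogram.get(c.size, 0) + 1
        total += c.size
    rows = []
    if genome_of is not None:
        per_genome: dict[str, int] = {}
        for c in clusters:
            for m in c.member_ids:
                per_genome[genome_of[m]] = per_genome.get(genome_of[m], 0) + 1
        for gid in sorted(per_genome):
            taxon = genome_table[gid].taxon_label if genome_table and gid in genome_table else ""
            rows.append({"genome_id": gid, "taxon_label": taxon, "n_members": per_genome[gid]})
    return FamilyReport(
        n_clusters=len(clusters),
        n_sequences=total,
        size_histogram=dict(sorted(histogram.items())),
        per_genome=pd.DataFrame(rows, columns=["genome_id", "taxon_label", "n_members"]),
    )


def clusters_to_frame(
    clusters: Iterable[Cluster],
    genome_of: Mapping[str, str] | None = None,
    retained_ids: set[str] | None = None,
) -> pd.DataFrame:
    """Cluster membership table in the standard TSV column order."""
    rows = []
    for i, c in enumerate(clusters, start=1):
        for m in c.member_ids:
            rows.append(
                {
                    "cluster_id": f"c{i:04d}",
                    "representative": c.representative_id,
                    "member": m,
                    "identity": round(c.identities[m], 4),
                    "genome_id": genome_of.get(m, "") if genome_of else "",
                    "has_rdhA": int(c.rdha_flags.get(m, False)) if c.rdha_flags else "",
                    "retained": int(retained_ids is None or c.representative_id in retained_ids),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["cluster_id", "representative", "member", "identity", "genome_id", "has_rdhA", "retained"],
    )
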