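"""End-to-end flows: family curation and single-protein validation.

``run_curation`` reproduces the family-curation logic — scan every protein
for the FMN consensus and CX3CP motifs, predict its topology, apply the
structural classifier, cluster the accepted candidates at the identity
threshold, and drop clusters with no member from an rdhA-positive genome —
and returns the full evidence trail.  ``run_validation`` runs the
single-protein validation chain: topology, tryptic peptide localization,
and the flavinylated proteoform masses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from . import flavin_mass, motifs, surfaceome, topology as topo
from .clustering import (
    Cluster,
    FamilyReport,
    RdhCCandidate,
    classify_rdhc,
    clusters_to_frame,
    cooccurrence_filter,
    family_report,
    greedy_cluster,
)
from .config import PipelineConfig
from .seqio import GenomeAnnotation, ProteinRecord, RdhcError


def protein_topology(record: ProteinRecord, config: PipelineConfig) -> topo.Topology:
    """Topology of one protein under the configured hydropathy parameters."""
    window = min(config.topology_window, len(record.sequence))
    if window % 2 == 0:
        window -= 1
    profile = topo.hydropathy_profile(record, window=window)
    segments = topo.predict_tm_segments(
        profile,
        threshold=config.tm_threshold,
        min_len=config.tm_min_len,
        max_len=config.tm_max_len,
        merge_gap=config.tm_merge_gap,
    )
    if config.n_term_side == "auto":
        side = topo.choose_orientation(segments, record.sequence)
    else:
        side = config.n_term_side
    return topo.assign_topology(segments, len(record.sequence), n_term_side=side)


@dataclass
class CurationResult:
    """Everything the curation flow produced, ready for tabulation."""

    candidates: list  # RdhCCandidate per input protein
    accepted_records: list  # ProteinRecord
    clusters: list  # all clusters of accepted candidates
    retained_clusters: list  # after the rdhA co-occurrence filter
    report: FamilyReport

    def candidates_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.candidates:
            rows.append(
                {
                    "protein_id": c.protein_id,
                    "n_fmn_hits": len(c.fmn_hits),
                    "n_cx3cp_hits": len(c.cx3cp_hits),
                    "tm_count": c.tm_count,
                    "fbd_side": c.fbd_side,
                    "accepted": int(c.accepted),
                    "reasons": ";".join(c.reasons),
                }
            )
        return pd.DataFrame(
            rows,
            columns=["protein_id", "n_fmn_hits", "n_cx3cp_hits", "tm_count",
                     "fbd_side", "accepted", "reasons"],
        )


def run_curation(
    records: Sequence[ProteinRecord],
    genome_table: Mapping[str, GenomeAnnotation],
    config: PipelineConfig | None = None,
) -> CurationResult:
    """Scan -> classify -> cluster -> co-occurrence filter -> family report."""
    config = config or PipelineConfig()
    fmn = motifs.get_motif(config.fmn_motif)
    cx3cp = motifs.get_motif(config.cx3cp_motif)
    missing = sorted({r.genome_id for r in records} - set(genome_table))
    if missing:
        raise RdhcError(f"genome id(s) missing from genome table: {missing}")

    candidates: list[RdhCCandidate] = []
    accepted: list[ProteinRecord] = []
    for rec in records:
        fmn_hits = motifs.scan_sequence(rec, fmn)
        cx_hits = motifs.scan_sequence(rec, cx3cp)
        t = protein_topology(rec, config)
        cand = classify_rdhc(
            rec, fmn_hits, cx_hits, t,
            min_tm=config.min_tm, min_cx3cp=config.min_cx3cp,
        )
        candidates.append(cand)
        if cand.accepted:
            accepted.append(rec)

    clusters = greedy_cluster(
        accepted, threshold=config.cluster_threshold,
        denominator=config.identity_denominator,
    )
    genome_of = {r.id: r.genome_id for r in accepted}
    retained = cooccurrence_filter(clusters, genome_of, genome_table)
    report = family_report(retained, genome_of, genome_table)
    return CurationResult(
        candidates=candidates,
        accepted_records=accepted,
        clusters=clusters,
        retained_clusters=retained,
        report=report,
    )


@dataclass
class ValidationResult:
    """Topology, peptide localization and proteoform masses for one protein."""

    record: ProteinRecord
    topology: topo.Topology
    localizations: list
    shaved: set
    control: set
    shaving: surfaceome.ShavingReport
    masses: dict  # named intact masses (average Da)
    variant: flavin_mass.VariantReport | None = None


def run_validation(
    record: ProteinRecord,
    config: PipelineConfig | None = None,
    substitution: str | None = None,
    sensitivity: float = 1.0,
    leakage: float = 0.0,
) -> ValidationResult:
    """Single-protein validation: topology, shaving simulation, intact masses.

    The mass chain mirrors intact-protein MS of a flavoprotein: theoretical
    chain mass, N-terminal Met excision, then one covalent FMN adduct
    (FMN - H2O), all on the average-mass scale.
    """
    config = config or PipelineConfig()
    t = protein_topology(record, config)
    locs = surfaceome.localize_digest(
        record, t,
        max_missed=config.max_missed_cleavages,
        exposure_threshold=config.exposure_threshold,
    )
    shaved, control = surfaceome.simulate_detections(
        locs, sensitivity=sensitivity, leakage=leakage, seed=config.seed
    )
    shaving = surfaceome.shaving_report(locs, shaved, control)

    base = flavin_mass.protein_mass(record.sequence, "average")
    excised_seq = flavin_mass.apply_met_excision(record.sequence)
    excised = flavin_mass.protein_mass(excised_seq, "average")
    masses = {
        "theoretical_average_da": base,
        "met_excised_average_da": excised,
        "flavinylated_average_da": flavin_mass.flavinylate(excised, 1, "average"),
    }
    variant = flavin_mass.variant_effect(record.sequence, substitution) if substitution else None
    return ValidationResult(
        record=record,
        topology=t,
        localizations=locs,
        shaved=shaved,
        control=control,
        shaving=shaving,
        masses=masses,
        variant=variant,
    )
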