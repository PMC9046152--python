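"""Post-alignment taxonomic assignment of reads.

Each mate's alignments are acceptance-filtered (60 nt minimum, 15%
mismatch / 15% gap / 30% combined caps), the reference tiers are
interrogated in order (viral, then bacterial, then fungal/protozoan —
lower tiers are never consulted once a higher tier matched), a single
best hit is chosen per read, and a match score against any residual
human alignment removes human reads with partial microbial homology.
Pair-level species concordance is the unit every downstream criterion
counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .io_core import (
    AlignmentRecord,
    MICROBIAL_TIERS,
    PipelineConfig,
    TaxonomyTable,
    Tier,
    log_stage_counts,
)


@dataclass(frozen=True)
class AcceptedHit:
    """An acceptance-filtered alignment resolved to a species taxon."""

    aln: AlignmentRecord
    tier: Tier
    taxon_id: str


@dataclass(frozen=True)
class SpeciesAssignment:
    """Retained species-level call for one mate."""

    read_id: str
    mate: int
    taxon_id: str
    subject_accession: str
    subject_interval: tuple[int, int]
    match_score: float
    tier: Tier


@dataclass(frozen=True)
class ConcordantPair:
    """A pair whose mates both matched the same species taxon."""

    read_id: str
    taxon_id: str
    forward: SpeciesAssignment
    reverse: SpeciesAssignment

    @property
    def pair_score(self) -> float:
        return min(self.forward.match_score, self.reverse.match_score)


@dataclass
class AssignResult:
    assignments: list[SpeciesAssignment]
    unassigned: set[str]

    @property
    def assigned(self) -> set[str]:
        return {f"{a.read_id}/{a.mate}" for a in self.assignments}


def split_query(query_id: str) -> tuple[str, int]:
    """Split a ``read/mate`` query id into (read_id, mate)."""
    if query_id.endswith("/1") or query_id.endswith("/2"):
        return query_id[:-2], int(query_id[-1])
    return query_id, 1


def accept_alignment(aln: AlignmentRecord, cfg: PipelineConfig) -> bool:
    """Alignment acceptance rule (boundaries inclusive).

    Requires alignment_length >= 60 nt and mismatches <= 15%, gaps <= 15%,
    mismatches+gaps <= 30% of the alignment length.
    """
    length = aln.alignment_length
    return (
        length >= cfg.min_alignment_len
        and aln.mismatches * 100.0 <= cfg.max_mismatch_pct * length
        and aln.gaps * 100.0 <= cfg.max_gap_pct * length
        and (aln.mismatches + aln.gaps) * 100.0 <= cfg.max_combined_pct * length
    )


def best_hit(hits: Sequence[AcceptedHit]) -> AcceptedHit:
    """Deterministic best hit: greatest alignment length, ties broken by
    best (numerically smallest) e-value, then highest bit score, then
    lexicographically smallest subject accession."""
    if not hits:
        raise ValueError("best_hit requires a non-empty hit list")
    return min(
        hits,
        key=lambda h: (
            -h.aln.alignment_length,
            h.aln.e_value,
            -h.aln.bit_score,
            h.aln.subject_accession,
        ),
    )


def tiered_assign(
    read_hits: Mapping[Tier, Sequence[AcceptedHit]], cfg: PipelineConfig
) -> Optional[AcceptedHit]:
    """Pick the best hit from the highest-priority tier with any hit.

    The viral tier is interrogated first, then bacterial, then
    fungal/protozoan; lower tiers are never consulted once a higher tier
    matched.  Returns None when no tier has accepted hits.
    """
    for tier in MICROBIAL_TIERS:
        hits = read_hits.get(tier)
        if hits:
            return best_hit(hits)
    return None


def match_score(
    organism_hit: AlignmentRecord, human_hit: Optional[AlignmentRecord]
) -> float:
    """Identical-base count of the organism alignment minus that of the
    residual human alignment (0 when there is none)."""
    score = organism_hit.percent_identity / 100.0 * organism_hit.alignment_length
    if human_hit is not None:
        score -= human_hit.percent_identity / 100.0 * human_hit.alignment_length
    return score


def best_human_hits(
    human_alignments: Iterable[AlignmentRecord],
) -> dict[str, AlignmentRecord]:
    """Best residual human alignment per query (greatest length, then
    smallest e-value) for use in the match score."""
    best: dict[str, AlignmentRecord] = {}
    for aln in human_alignments:
        cur = best.get(aln.query_id)
        if cur is None or (-aln.alignment_length, aln.e_value) < (
            -cur.alignment_length,
            cur.e_value,
        ):
            best[aln.query_id] = aln
    return best


def assign_reads(
    tier_alignments: Mapping[Tier, Iterable[AlignmentRecord]],
    human_alignments: Iterable[AlignmentRecord],
    taxonomy: TaxonomyTable,
    cfg: PipelineConfig,
) -> AssignResult:
    """Assign every query appearing in the microbial alignment tables.

    Per query: acceptance-filter all hits, resolve species taxa, pick
    the tiered best hit, compute the match score against the residual
    human table, and retain the assignment when the score meets the
    retention threshold (>= 0 by default).  Queries with alignments but
    no retained assignment are reported as unassigned.
    """
    human_best = best_human_hits(human_alignments)
    per_query: dict[str, dict[Tier, list[AcceptedHit]]] = {}
    all_queries: set[str] = set()
    for tier, alignments in tier_alignments.items():
        for aln in alignments:
            all_queries.add(aln.query_id)
            if not accept_alignment(aln, cfg):
                continue
            taxon = taxonomy.species_of(aln.subject_accession)
            per_query.setdefault(aln.query_id, {}).setdefault(
                Tier(tier), []
            ).append(AcceptedHit(aln, Tier(tier), taxon))
    assignments: list[SpeciesAssignment] = []
    unassigned: set[str] = set()
    for query_id in sorted(all_queries):
        hit = tiered_assign(per_query.get(query_id, {}), cfg)
        if hit is None:
            unassigned.add(query_id)
            continue
        score = match_score(hit.aln, human_best.get(query_id))
        if score < cfg.match_score_retention_min:
            unassigned.add(query_id)
            continue
        read_id, mate = split_query(query_id)
        assignments.append(
            SpeciesAssignment(
                read_id=read_id,
                mate=mate,
                taxon_id=hit.taxon_id,
                subject_accession=hit.aln.subject_accession,
                subject_interval=hit.aln.subject_interval,
                match_score=score,
                tier=hit.tier,
            )
        )
    log_stage_counts(
        "assign",
        {
            "queries": len(all_queries),
            "assigned": len(assignments),
            "unassigned": len(unassigned),
        },
    )
    return AssignResult(assignments, unassigned)


def assign_pairs(
    assignments: Iterable[SpeciesAssignment],
) -> list[ConcordantPair]:
    """Emit a ConcordantPair for every read whose two mates both carry a
    retained assignment to the same species taxon.

    Species identity is by taxon id, so mates hitting different
    accessions of one species are concordant.  A mate with no retained
    assignment, or mates assigned to different species, blocks the pair.
    """
    by_read: dict[str, dict[int, SpeciesAssignment]] = {}
    order: list[str] = []
    for a in assignments:
        if a.read_id not in by_read:
            order.append(a.read_id)
        slot = by_read.setdefault(a.read_id, {})
        if a.mate in slot:
            raise ValueError(f"multiple retained assignments for {a.read_id}/{a.mate}")
        slot[a.mate] = a
    pairs: list[ConcordantPair] = []
    for read_id in order:
        mates = by_read[read_id]
        if 1 in mates and 2 in mates and mates[1].taxon_id == mates[2].taxon_id:
            pairs.append(
                ConcordantPair(read_id, mates[1].taxon_id, mates[1], mates[2])
            )
    return pairs


# ---------------------------------------------------------------------------
# assignment table IO
# ---------------------------------------------------------------------------

_ASSIGN_HEADER = (
    "read_id\tmate\ttaxon_id\taccession\tsubject_start\tsubject_end\t"
    "match_score\ttier\n"
)


def write_assignments(assignments: Iterable[SpeciesAssignment], path) -> None:
    with open(path, "w") as out:
        out.write(_ASSIGN_HEADER)
        for a in assignments:
            lo, hi = a.subject_interval
            out.write(
                f"{a.read_id}\t{a.mate}\t{a.taxon_id}\t{a.subject_accession}\t"
                f"{lo}\t{hi}\t{a.match_score:.4g}\t{a.tier.value}\n"
            )


def read_assignments(path) -> list[SpeciesAssignment]:
    out: list[SpeciesAssignment] = []
    with open(path) as handle:
        header = handle.readline()
        if not header.startswith("read_id\t"):
            raise ValueError(f"{path}: missing assignment header")
        for line in handle:
            cols = line.rstrip("\n").split("\t")
            out.append(
                SpeciesAssignment(
                    read_id=cols[0],
                    mate=int(cols[1]),
                    taxon_id=cols[2],
                    subject_accession=cols[3],
                    subject_interval=(int(cols[4]), int(cols[5])),
                    match_score=float(cols[6]),
                    tier=Tier(cols[7]),
                )
            )
    return out
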