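"""End-to-end orchestration: QC, host subtraction, assignment, calling.

Mirrors the analysis flow applied to each library: quality-filter the
pairs, subtract mates with an accepted host alignment, assign the rest
against the tiered microbial references (scoring against residual human
homology), reduce to species-concordant pairs, then evaluate the four
diagnostic criteria per taxon against the pooled water controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .assign import (
    AssignResult,
    ConcordantPair,
    SpeciesAssignment,
    accept_alignment,
    assign_pairs,
    assign_reads,
)
from .calling import SpeciesCall, SpeciesCountTable, call_species
from .io_core import (
    AlignmentRecord,
    PipelineConfig,
    ReadPair,
    TaxonomyTable,
    Tier,
    log_stage_counts,
)
from .read_qc import QCReport, run_qc
from .simdata import Bundle, SampleBundle


@dataclass
class SampleResult:
    """Per-library analysis products."""

    name: str
    total_pairs: int  # post-QC pair count: the WNS denominator
    qc_report: QCReport
    assignments: list[SpeciesAssignment]
    concordant: dict[str, list[ConcordantPair]] = field(default_factory=dict)
    unassigned: set[str] = field(default_factory=set)

    @property
    def pair_counts(self) -> dict[str, int]:
        return {taxon: len(pairs) for taxon, pairs in self.concordant.items()}


def subtract_host(
    host_alignments: Iterable[AlignmentRecord], cfg: PipelineConfig
) -> tuple[set[str], dict[str, AlignmentRecord]]:
    """Partition host alignments into subtracted queries and residual hits.

    A mate with an alignment passing the acceptance rule is host-derived
    and removed outright.  The best remaining (weak) host alignment per
    surviving mate is kept as the residual-human term of the match score.
    """
    subtracted: set[str] = set()
    residual: dict[str, AlignmentRecord] = {}
    for aln in host_alignments:
        if accept_alignment(aln, cfg):
            subtracted.add(aln.query_id)
            residual.pop(aln.query_id, None)
        elif aln.query_id not in subtracted:
            cur = residual.get(aln.query_id)
            if cur is None or (-aln.alignment_length, aln.e_value) < (
                -cur.alignment_length,
                cur.e_value,
            ):
                residual[aln.query_id] = aln
    return subtracted, residual


def analyze_sample(
    name: str,
    pairs: Iterable[ReadPair],
    host_alignments: Iterable[AlignmentRecord],
    tier_alignments: Mapping[Tier, Iterable[AlignmentRecord]],
    taxonomy: TaxonomyTable,
    cfg: PipelineConfig,
) -> SampleResult:
    """Run QC and taxonomic assignment for one library."""
    kept, report = run_qc(pairs, cfg)
    surviving = {p.read_id for p in kept}

    def of_survivors(alns: Iterable[AlignmentRecord]) -> list[AlignmentRecord]:
        return [a for a in alns if a.query_id.rsplit("/", 1)[0] in surviving]

    subtracted, residual = subtract_host(of_survivors(host_alignments), cfg)
    microbial = {
        Tier(tier): [
            a for a in of_survivors(alns) if a.query_id not in subtracted
        ]
        for tier, alns in tier_alignments.items()
    }
    result: AssignResult = assign_reads(
        microbial, residual.values(), taxonomy, cfg
    )
    concordant: dict[str, list[ConcordantPair]] = {}
    for pair in assign_pairs(result.assignments):
        concordant.setdefault(pair.taxon_id, []).append(pair)
    log_stage_counts(
        "analyze_sample",
        {
            "sample_pairs": len(kept),
            "host_subtracted_mates": len(subtracted),
            "assigned_mates": len(result.assignments),
            "concordant_pairs": sum(len(v) for v in concordant.values()),
        },
    )
    return SampleResult(
        name=name,
        total_pairs=len(kept),
        qc_report=report,
        assignments=result.assignments,
        concordant=concordant,
        unassigned=result.unassigned,
    )


def build_count_table(results: Mapping[str, SampleResult]) -> SpeciesCountTable:
    counts = SpeciesCountTable()
    for name, result in results.items():
        counts.totals[name] = result.total_pairs
        for taxon, n in result.pair_counts.items():
            counts.add(name, taxon, n)
    return counts


def call_all(
    results: Mapping[str, SampleResult],
    water_names: Iterable[str],
    cfg: PipelineConfig,
) -> dict[str, list[SpeciesCall]]:
    """Diagnostic calls for every taxon with any retained assignment in
    each non-water sample, normalized against the pooled waters."""
    waters = sorted(set(water_names))
    counts = build_count_table(results)
    calls: dict[str, list[SpeciesCall]] = {}
    for name, result in results.items():
        if name in waters:
            continue
        taxa = sorted({a.taxon_id for a in result.assignments})
        calls[name] = [
            call_species(name, taxon, result.assignments, counts, waters, cfg)
            for taxon in taxa
        ]
    return calls


def analyze_bundle(
    bundle: Bundle, cfg: Optional[PipelineConfig] = None
) -> tuple[dict[str, SampleResult], dict[str, list[SpeciesCall]]]:
    """Analyze a simulated experiment bundle end to end."""
    cfg = cfg or PipelineConfig()
    results = {
        name: analyze_sample(
            name,
            sample.pairs,
            sample.host_alignments,
            sample.tier_alignments,
            bundle.references.taxonomy,
            cfg,
        )
        for name, sample in bundle.samples.items()
    }
    calls = call_all(results, bundle.water_names, cfg)
    return results, calls
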