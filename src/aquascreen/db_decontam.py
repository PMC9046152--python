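"""Reference-database decontamination.

Microbial reference sequences that carry human-like segments cause
recurrent false positives in low-biomass libraries; any reference with
at least one qualifying human alignment (>= 60 bp, <= 15% gaps, <= 15%
mismatches, <= 30% gaps plus mismatches) is removed whole and recorded
in a manifest.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .io_core import AlignmentRecord, PipelineConfig, log_stage_counts, logger


@dataclass(frozen=True)
class DecontamVerdict:
    subject_accession: str
    flagged: bool
    triggering_alignment: Optional[AlignmentRecord] = None

    def __post_init__(self) -> None:
        if self.flagged != (self.triggering_alignment is not None):
            raise ValueError("flagged verdicts must carry a triggering alignment")


def is_humanlike(aln: AlignmentRecord, cfg: PipelineConfig) -> bool:
    """True iff the alignment meets the human-similarity removal rule.

    All boundaries are inclusive ("a maximum of 15% ..." admits exactly
    15%); percentages are computed against the alignment length.
    """
    length = aln.alignment_length
    if length <= 0:
        raise ValueError("alignment_length must be positive")
    return (
        length >= cfg.min_alignment_len
        and aln.gaps * 100.0 <= cfg.max_gap_pct * length
        and aln.mismatches * 100.0 <= cfg.max_mismatch_pct * length
        and (aln.gaps + aln.mismatches) * 100.0 <= cfg.max_combined_pct * length
    )


def clean_database(
    refs: Iterable[tuple[str, str]],
    human_alignments: Iterable[AlignmentRecord],
    cfg: PipelineConfig,
) -> tuple[list[tuple[str, str]], list[DecontamVerdict]]:
    """Remove references with any human-like alignment.

    ``refs`` are (accession, sequence) pairs; ``human_alignments`` are
    reference-vs-human alignments whose query ids are reference
    accessions.  Returns the surviving references (input order) and a
    manifest with one verdict per input reference.  Alignments naming
    unknown accessions are skipped with a warning.
    """
    refs = list(refs)
    known = {accession for accession, _ in refs}
    trigger: dict[str, AlignmentRecord] = {}
    for aln in human_alignments:
        if aln.query_id not in known:
            logger.warning(
                "human alignment for unknown accession %r skipped", aln.query_id
            )
            continue
        if aln.query_id not in trigger and is_humanlike(aln, cfg):
            trigger[aln.query_id] = aln
    cleaned = [(acc, seq) for acc, seq in refs if acc not in trigger]
    manifest = [
        DecontamVerdict(acc, acc in trigger, trigger.get(acc)) for acc, _ in refs
    ]
    log_stage_counts(
        "db_decontam", {"in": len(refs), "flagged": len(trigger), "out": len(cleaned)}
    )
    return cleaned, manifest


def write_manifest(manifest: Iterable[DecontamVerdict], path) -> None:
    with open(path, "w") as out:
        out.write("accession\tflagged\talignment_length\tmismatches\tgaps\n")
        for v in manifest:
            if v.triggering_alignment is None:
                out.write(f"{v.subject_accession}\tFalse\t\t\t\n")
            else:
                a = v.triggering_alignment
                out.write(
                    f"{v.subject_accession}\tTrue\t{a.alignment_length}\t"
                    f"{a.mismatches}\t{a.gaps}\n"
                )
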