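"""Read-cleaning cascade for paired-end libraries.

Order of operations per pair: adapter trimming, B-tail trimming,
duplicate removal, low-complexity filtering, then the custom quality
filter (chastity, homopolymer, N, first-half quality, minimum length).
A pair is dropped whenever either mate fails, since every downstream
criterion needs both mates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from itertools import groupby
from typing import Iterable, Optional, Sequence

from .io_core import PipelineConfig, ReadPair, ReadRecord, log_stage_counts

#: removal reasons in cascade order (first failing reason is recorded)
QC_REASONS = (
    "duplicate",
    "low_complexity",
    "chastity_fail",
    "homopolymer",
    "contains_N",
    "low_quality_first_half",
    "too_short",
)

#: Phred score of the Illumina Read Segment Quality Control Indicator
B_TAIL_QUALITY = 2


@dataclass
class QCReport:
    """Accounting of a QC run over read pairs; conserves counts exactly."""

    counts_in: int = 0
    counts_out: int = 0
    removed_by_reason: dict[str, int] = field(
        default_factory=lambda: {reason: 0 for reason in QC_REASONS}
    )
    #: pairs that survived but had adapter sequence trimmed (informational)
    adapter_only_trimmed: int = 0

    def validate(self) -> None:
        removed = sum(self.removed_by_reason.values())
        if self.counts_in != self.counts_out + removed:
            raise AssertionError(
                f"QC accounting broken: {self.counts_in} in != "
                f"{self.counts_out} out + {removed} removed"
            )


# ---------------------------------------------------------------------------
# per-read operations
# ---------------------------------------------------------------------------


def trim_adapters(
    read: ReadRecord,
    adapters: Sequence[str],
    min_overlap: int = 5,
    max_error_rate: float = 0.1,
) -> ReadRecord:
    """Remove the earliest adapter occurrence and everything 3' of it.

    A match is either a full adapter occurrence or a 3'-terminal partial
    of at least ``min_overlap`` bases, tolerating up to
    ``floor(max_error_rate * matched_length)`` mismatches.  A read that
    is all adapter becomes empty (removed later by the length filter).
    """
    if not adapters:
        raise ValueError("adapters must be non-empty")
    seq = read.sequence
    length = len(seq)
    best_cut: Optional[int] = None
    for adapter in adapters:
        alen = len(adapter)
        stop = best_cut if best_cut is not None else length
        for i in range(stop):
            m = min(alen, length - i)
            if m < min_overlap:
                break
            allowed = int(max_error_rate * m)
            errors = 0
            for a, b in zip(seq[i : i + m], adapter):
                if a != b:
                    errors += 1
                    if errors > allowed:
                        break
            if errors <= allowed:
                best_cut = i
                break
    if best_cut is None:
        return read
    return replace(
        read, sequence=seq[:best_cut], qualities=read.qualities[:best_cut]
    )


def trim_b_tail(read: ReadRecord) -> ReadRecord:
    """Strip the maximal trailing run of Q<=2 bases (the Illumina B-tail)."""
    end = len(read.qualities)
    while end > 0 and read.qualities[end - 1] <= B_TAIL_QUALITY:
        end -= 1
    if end == len(read.qualities):
        return read
    return replace(read, sequence=read.sequence[:end], qualities=read.qualities[:end])


def remove_duplicates(
    reads: Iterable[ReadRecord],
) -> tuple[list[ReadRecord], int]:
    """Drop exact full-sequence duplicates, keeping the first occurrence.

    Reverse complements and prefix duplicates are not duplicates.
    """
    seen: set[str] = set()
    kept: list[ReadRecord] = []
    removed = 0
    for read in reads:
        if read.sequence in seen:
            removed += 1
            continue
        seen.add(read.sequence)
        kept.append(read)
    return kept, removed


def triplet_entropy_score(
    sequence: str, window: int = 64, step: int = 32
) -> float:
    """Windowed nucleotide-triplet Shannon entropy on a 0-100 scale.

    Overlapping 3-mers are counted in windows of ``window`` bases moved by
    ``step`` (the final window is anchored at the 3' end so every window is
    full-size); each window scores 100 * H / log2(min(n_triplets, 64)) and
    the read score is the mean over windows.  A homopolymer scores 0.
    """
    length = len(sequence)
    if length < 4:
        return 0.0
    if length <= window:
        starts = [0]
    else:
        starts = list(range(0, length - window + 1, step))
        if starts[-1] != length - window:
            starts.append(length - window)
    scores = []
    for start in starts:
        win = sequence[start : start + window]
        n_triplets = len(win) - 2
        counts: dict[str, int] = {}
        for i in range(n_triplets):
            word = win[i : i + 3]
            counts[word] = counts.get(word, 0) + 1
        if len(counts) <= 1:
            scores.append(0.0)
            continue
        entropy = 0.0
        for c in counts.values():
            p = c / n_triplets
            entropy -= p * math.log2(p)
        scores.append(100.0 * entropy / math.log2(min(n_triplets, 64)))
    return sum(scores) / len(scores)


def low_complexity_filter(
    read: ReadRecord,
    entropy_threshold: float = 70.0,
    window: int = 64,
    step: int = 32,
) -> bool:
    """Return True to keep the read, False to drop it as low-complexity."""
    if entropy_threshold <= 0:
        return True
    return triplet_entropy_score(read.sequence, window, step) >= entropy_threshold


def _max_homopolymer_run(sequence: str) -> int:
    return max((len(list(g)) for _, g in groupby(sequence)), default=0)


def quality_filter(read: ReadRecord, cfg: PipelineConfig) -> Optional[str]:
    """Return None to keep, else the FIRST failing reason.

    Order: chastity_fail, homopolymer (> max_homopolymer consecutive
    identical bases), contains_N, low_quality_first_half (fewer than
    ceil(qual_fraction * floor(L/2)) of the first floor(L/2) bases at
    Q >= qual_threshold), too_short (< min_read_len).
    """
    if not read.chastity_pass:
        return "chastity_fail"
    if _max_homopolymer_run(read.sequence) > cfg.max_homopolymer:
        return "homopolymer"
    if "N" in read.sequence:
        return "contains_N"
    half = len(read.sequence) // 2
    needed = math.ceil(cfg.qual_fraction * half)
    good = sum(1 for q in read.qualities[:half] if q >= cfg.qual_threshold)
    if good < needed:
        return "low_quality_first_half"
    if len(read.sequence) < cfg.min_read_len:
        return "too_short"
    return None


# ---------------------------------------------------------------------------
# pair-level cascade
# ---------------------------------------------------------------------------


def run_qc(
    pairs: Iterable[ReadPair], cfg: PipelineConfig
) -> tuple[list[ReadPair], QCReport]:
    """Apply the full cleaning cascade to mate pairs.

    Duplicates are detected at pair level on the post-trimming
    (forward, reverse) sequence tuple.  The report attributes each
    dropped pair to exactly one reason (first failing mate, forward
    checked first) and conserves counts.
    """
    report = QCReport()
    kept: list[ReadPair] = []
    seen: set[tuple[str, str]] = set()
    for pair in pairs:
        report.counts_in += 1
        fwd = trim_adapters(
            pair.forward,
            cfg.adapter_sequences,
            cfg.adapter_min_overlap,
            cfg.adapter_max_error_rate,
        )
        rev = trim_adapters(
            pair.reverse,
            cfg.adapter_sequences,
            cfg.adapter_min_overlap,
            cfg.adapter_max_error_rate,
        )
        trimmed = len(fwd) != len(pair.forward) or len(rev) != len(pair.reverse)
        fwd = trim_b_tail(fwd)
        rev = trim_b_tail(rev)
        key = (fwd.sequence, rev.sequence)
        if key in seen:
            report.removed_by_reason["duplicate"] += 1
            continue
        seen.add(key)
        if not (
            low_complexity_filter(
                fwd, cfg.entropy_threshold, cfg.entropy_window, cfg.entropy_step
            )
            and low_complexity_filter(
                rev, cfg.entropy_threshold, cfg.entropy_window, cfg.entropy_step
            )
        ):
            report.removed_by_reason["low_complexity"] += 1
            continue
        reason = quality_filter(fwd, cfg) or quality_filter(rev, cfg)
        if reason is not None:
            report.removed_by_reason[reason] += 1
            continue
        if trimmed:
            report.adapter_only_trimmed += 1
        kept.append(ReadPair(fwd, rev))
    report.counts_out = len(kept)
    report.validate()
    log_stage_counts(
        "read_qc",
        {"in": report.counts_in, "out": report.counts_out, **report.removed_by_reason},
    )
    return kept, report


def write_qc_report(report: QCReport, path) -> None:
    """Emit the QC accounting as a two-column TSV."""
    with open(path, "w") as out:
        out.write(f"pairs_in\t{report.counts_in}\n")
        for reason in QC_REASONS:
            out.write(f"removed_{reason}\t{report.removed_by_reason[reason]}\n")
        out.write(f"adapter_only_trimmed\t{report.adapter_only_trimmed}\n")
        out.write(f"pairs_out\t{report.counts_out}\n")
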