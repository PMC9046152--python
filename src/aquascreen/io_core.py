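"""Domain types, file formats, and pipeline configuration.

The pipeline consumes paired-end FASTQ (Phred+33), 12-column BLAST-style
tabular alignment files, and two TSV taxonomy maps (accession -> taxon,
taxon -> species/genus/family lineage).  All coordinates are 1-based
inclusive; minus-strand subject hits are encoded BLAST-style with
subject_start > subject_end and normalized on access.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence, TextIO, Union

from Bio.SeqIO.QualityIO import FastqGeneralIterator

logger = logging.getLogger("aquascreen")

PathLike = Union[str, Path]


class FormatError(ValueError):
    """Malformed input file (message names the offending line)."""


class Tier(str, Enum):
    """Reference database tier; microbial tiers are interrogated in order."""

    VIRAL = "VIRAL"
    BACTERIAL = "BACTERIAL"
    FUNGAL_PROTOZOAN = "FUNGAL_PROTOZOAN"
    HOST = "HOST"
    RRNA = "RRNA"


#: tier interrogation order for read assignment (viral first)
MICROBIAL_TIERS = (Tier.VIRAL, Tier.BACTERIAL, Tier.FUNGAL_PROTOZOAN)

#: Illumina TruSeq adapter (short form) and the full indexed-adapter form
ADAPTER_SHORT = "AGATCGGAAGAGC"
ADAPTER_LONG = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCACCGATGTATCTCGTATGCCGTCTTCTGCTTG"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read with per-base Phred qualities.

    ``chastity_pass`` carries the Illumina purity flag from a
    Casava-1.8-style header field; reads lacking the field are assumed
    to pass (the filter can only act when the instrument recorded it).
    """

    read_id: str
    mate: int
    sequence: str
    qualities: tuple[int, ...]
    chastity_pass: bool = True

    def __post_init__(self) -> None:
        if not self.read_id:
            raise ValueError("read_id must be non-empty")
        if self.mate not in (1, 2):
            raise ValueError(f"mate must be 1 or 2, got {self.mate!r}")
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"{self.read_id}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReadPair:
    """A mate pair; both records share one read id."""

    forward: ReadRecord
    reverse: ReadRecord

    def __post_init__(self) -> None:
        if self.forward.read_id != self.reverse.read_id:
            raise ValueError(
                f"mate ids differ: {self.forward.read_id!r} vs {self.reverse.read_id!r}"
            )
        if (self.forward.mate, self.reverse.mate) != (1, 2):
            raise ValueError("forward must be mate 1 and reverse mate 2")

    @property
    def read_id(self) -> str:
        return self.forward.read_id


@dataclass(frozen=True)
class AlignmentRecord:
    """One pairwise alignment in the 12-column BLAST tabular dialect.

    ``gaps`` holds total gap positions (not gap openings); percent
    identity is as emitted by the aligner.  Subject coordinates with
    start > end encode a minus-strand hit.
    """

    query_id: str
    subject_accession: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gaps: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    e_value: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.alignment_length < 1:
            raise ValueError(f"{self.query_id}: alignment_length must be >= 1")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(f"{self.query_id}: percent_identity outside [0, 100]")
        if self.mismatches < 0 or self.gaps < 0:
            raise ValueError(f"{self.query_id}: negative mismatches/gaps")
        if self.mismatches + self.gaps > self.alignment_length:
            raise ValueError(
                f"{self.query_id}: mismatches + gaps exceed alignment length"
            )
        if self.e_value < 0:
            raise ValueError(f"{self.query_id}: negative e-value")

    @property
    def minus_strand(self) -> bool:
        return self.subject_start > self.subject_end

    @property
    def subject_interval(self) -> tuple[int, int]:
        """Subject interval normalized to (low, high), 1-based inclusive."""
        lo, hi = self.subject_start, self.subject_end
        return (hi, lo) if lo > hi else (lo, hi)


@dataclass(frozen=True)
class Lineage:
    species_id: str
    genus_id: str
    family_id: str
    species_name: str = ""
    genus_name: str = ""
    family_name: str = ""


@dataclass
class TaxonomyTable:
    """Accession -> taxon and taxon -> lineage lookups plus database tier."""

    accession_to_taxon: dict[str, str] = field(default_factory=dict)
    lineage: dict[str, Lineage] = field(default_factory=dict)
    tier: dict[str, Tier] = field(default_factory=dict)

    def species_of(self, accession: str) -> str:
        try:
            taxon = self.accession_to_taxon[accession]
        except KeyError:
            raise KeyError(f"accession {accession!r} has no taxon mapping") from None
        return self.lineage_of(taxon).species_id

    def tier_of(self, accession: str) -> Tier:
        try:
            return self.tier[accession]
        except KeyError:
            raise KeyError(f"accession {accession!r} has no tier mapping") from None

    def lineage_of(self, taxon: str) -> Lineage:
        try:
            return self.lineage[taxon]
        except KeyError:
            raise KeyError(f"taxon {taxon!r} has no lineage entry") from None


@dataclass
class PipelineConfig:
    """Every numeric threshold used by the pipeline, with the published defaults.

    Read acceptance and database decontamination share the 60 bp /
    15% mismatch / 15% gap / 30% combined rule.  Match-score thresholds
    are split: reads are *retained* at score >= ``match_score_retention_min``
    (0) but only contribute to a *diagnostic* call at a strictly positive
    score when ``match_score_diagnostic_strict`` is set.
    """

    min_alignment_len: int = 60
    max_mismatch_pct: float = 15.0
    max_gap_pct: float = 15.0
    max_combined_pct: float = 30.0
    min_read_len: int = 70
    qual_threshold: int = 30
    qual_fraction: float = 2.0 / 3.0
    max_homopolymer: int = 20
    discrete_overlap_bp: int = 50
    min_diagnostic_pairs: int = 3
    wns_cutoff: float = 1.0
    match_score_retention_min: float = 0.0
    match_score_diagnostic_strict: bool = True
    adapter_sequences: tuple[str, ...] = (ADAPTER_SHORT, ADAPTER_LONG)
    adapter_min_overlap: int = 5
    adapter_max_error_rate: float = 0.1
    entropy_threshold: float = 70.0
    entropy_window: int = 64
    entropy_step: int = 32
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "min_alignment_len",
            "min_read_len",
            "qual_threshold",
            "max_homopolymer",
            "discrete_overlap_bp",
            "min_diagnostic_pairs",
            "wns_cutoff",
            "adapter_min_overlap",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("max_mismatch_pct", "max_gap_pct", "max_combined_pct"):
            if not 0.0 <= getattr(self, name) <= 100.0:
                raise ValueError(f"{name} must be in [0, 100]")
        if not 0.0 < self.qual_fraction <= 1.0:
            raise ValueError("qual_fraction must be in (0, 1]")
        if not self.adapter_sequences:
            raise ValueError("adapter_sequences must be non-empty")


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------


def _parse_fastq_title(title: str, default_mate: int) -> tuple[str, int, bool]:
    """Split a FASTQ title into (read_id, mate, chastity_pass).

    Understands Casava 1.8 headers (``id 1:N:0:ACGT``; ``N`` = not
    filtered, so chastity passes) and legacy ``id/1`` suffixes.
    """
    parts = title.split(None, 1)
    read_id = parts[0]
    mate = default_mate
    chastity = True
    if read_id.endswith("/1") or read_id.endswith("/2"):
        mate = int(read_id[-1])
        read_id = read_id[:-2]
    if len(parts) == 2:
        sub = parts[1].split(":")
        if len(sub) >= 2 and sub[0] in ("1", "2") and sub[1] in ("Y", "N"):
            mate = int(sub[0])
            chastity = sub[1] == "N"
    return read_id, mate, chastity


def read_fastq(path: PathLike, default_mate: int = 1) -> Iterator[ReadRecord]:
    """Stream ReadRecords from a Phred+33 FASTQ file in file order.

    Raises FormatError (naming the line) for malformed 4-line blocks,
    length mismatches, or quality characters outside the Phred+33 range.
    """
    with open(path) as handle:
        n = 0
        iterator = FastqGeneralIterator(handle)
        while True:
            try:
                title, seq, qual = next(iterator)
            except StopIteration:
                return
            except ValueError as exc:
                raise FormatError(
                    f"{path}: malformed FASTQ record near line {4 * n + 1}: {exc}"
                ) from exc
            if len(seq) != len(qual):
                raise FormatError(
                    f"{path}: sequence/quality length mismatch near line {4 * n + 1}"
                )
            quals = []
            for ch in qual:
                q = ord(ch) - 33
                if q < 0 or q > 93:
                    raise FormatError(
                        f"{path}: quality character {ch!r} near line {4 * n + 1} "
                        "is not Phred+33 (other encodings are not supported)"
                    )
                quals.append(q)
            read_id, mate, chastity = _parse_fastq_title(title, default_mate)
            yield ReadRecord(read_id, mate, seq.upper(), tuple(quals), chastity)
            n += 1


def read_fastq_pairs(path1: PathLike, path2: PathLike) -> Iterator[ReadPair]:
    """Stream mate pairs from synchronized R1/R2 FASTQ files."""
    it1, it2 = read_fastq(path1, 1), read_fastq(path2, 2)
    for fwd, rev in zip(it1, it2):
        if fwd.read_id != rev.read_id:
            raise FormatError(
                f"unsynchronized mate files: {fwd.read_id!r} vs {rev.read_id!r}"
            )
        if fwd.mate != 1:
            fwd = replace(fwd, mate=1)
        if rev.mate != 2:
            rev = replace(rev, mate=2)
        yield ReadPair(fwd, rev)
    for leftover in (it1, it2):
        try:
            next(leftover)
        except StopIteration:
            continue
        raise FormatError("mate FASTQ files differ in record count")


def write_fastq(records: Iterable[ReadRecord], handle_or_path) -> None:
    """Write ReadRecords as Phred+33 FASTQ with Casava-style headers."""

    def _write(out: TextIO) -> None:
        for rec in records:
            flag = "N" if rec.chastity_pass else "Y"
            out.write(f"@{rec.read_id} {rec.mate}:{flag}:0:\n{rec.sequence}\n+\n")
            out.write("".join(chr(q + 33) for q in rec.qualities) + "\n")

    if hasattr(handle_or_path, "write"):
        _write(handle_or_path)
    else:
        with open(handle_or_path, "w") as out:
            _write(out)


# ---------------------------------------------------------------------------
# alignment tables
# ---------------------------------------------------------------------------

_ALN_COLUMNS = 12


def read_alignments(
    path: PathLike, column6: str = "gaps"
) -> Iterator[AlignmentRecord]:
    """Stream AlignmentRecords from a 12-column tab-separated file.

    ``column6`` selects the dialect for the sixth column: ``"gaps"``
    (default, total gap positions — what the percentage rules need) or
    ``"gap_openings"``, in which case a 13th column with total gaps is
    required and used instead.
    """
    if column6 not in ("gaps", "gap_openings"):
        raise ValueError("column6 must be 'gaps' or 'gap_openings'")
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if column6 == "gaps" and len(cols) != _ALN_COLUMNS:
                raise FormatError(
                    f"{path}:{lineno}: expected {_ALN_COLUMNS} columns, got {len(cols)}"
                )
            if column6 == "gap_openings" and len(cols) != _ALN_COLUMNS + 1:
                raise FormatError(
                    f"{path}:{lineno}: gap-openings dialect requires a 13th "
                    "total-gaps column"
                )
            try:
                gaps = int(cols[12]) if column6 == "gap_openings" else int(cols[5])
                record = AlignmentRecord(
                    query_id=cols[0],
                    subject_accession=cols[1],
                    percent_identity=float(cols[2]),
                    alignment_length=int(cols[3]),
                    mismatches=int(cols[4]),
                    gaps=gaps,
                    query_start=int(cols[6]),
                    query_end=int(cols[7]),
                    subject_start=int(cols[8]),
                    subject_end=int(cols[9]),
                    e_value=float(cols[10]),
                    bit_score=float(cols[11]),
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            yield record


def write_alignments(records: Iterable[AlignmentRecord], handle_or_path) -> None:
    """Write AlignmentRecords in the default (total-gaps) 12-column dialect."""

    def _write(out: TextIO) -> None:
        for r in records:
            out.write(
                "\t".join(
                    str(v)
                    for v in (
                        r.query_id,
                        r.subject_accession,
                        f"{r.percent_identity:.2f}",
                        r.alignment_length,
                        r.mismatches,
                        r.gaps,
                        r.query_start,
                        r.query_end,
                        r.subject_start,
                        r.subject_end,
                        f"{r.e_value:.3g}",
                        f"{r.bit_score:.1f}",
                    )
                )
                + "\n"
            )

    if hasattr(handle_or_path, "write"):
        _write(handle_or_path)
    else:
        with open(handle_or_path, "w") as out:
            _write(out)


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------


def read_taxonomy(accession_map: PathLike, lineage_map: PathLike) -> TaxonomyTable:
    """Load taxonomy from two TSVs.

    ``accession_map`` rows: accession <tab> taxon_id <tab> tier.
    ``lineage_map`` rows: taxon_id <tab> species_id <tab> genus_id <tab>
    family_id [<tab> species_name <tab> genus_name <tab> family_name].
    Duplicate accession rows with conflicting taxa are a load error.
    """
    table = TaxonomyTable()
    with open(accession_map) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(
                    f"{accession_map}:{lineno}: expected accession, taxon, tier"
                )
            accession, taxon, tier_name = cols[0], cols[1], cols[2]
            if accession in table.accession_to_taxon:
                if table.accession_to_taxon[accession] != taxon:
                    raise FormatError(
                        f"{accession_map}:{lineno}: accession {accession!r} mapped "
                        f"to conflicting taxa"
                    )
                continue
            try:
                table.tier[accession] = Tier(tier_name)
            except ValueError:
                raise FormatError(
                    f"{accession_map}:{lineno}: unknown tier {tier_name!r}"
                ) from None
            table.accession_to_taxon[accession] = taxon
    with open(lineage_map) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise FormatError(
                    f"{lineage_map}:{lineno}: expected taxon, species, genus, family"
                )
            names = cols[4:7] + [""] * (3 - len(cols[4:7]))
            table.lineage[cols[0]] = Lineage(cols[1], cols[2], cols[3], *names)
    return table


def write_taxonomy(
    table: TaxonomyTable, accession_map: PathLike, lineage_map: PathLike
) -> None:
    with open(accession_map, "w") as out:
        for accession in sorted(table.accession_to_taxon):
            taxon = table.accession_to_taxon[accession]
            out.write(f"{accession}\t{taxon}\t{table.tier[accession].value}\n")
    with open(lineage_map, "w") as out:
        for taxon in sorted(table.lineage):
            lin = table.lineage[taxon]
            out.write(
                f"{taxon}\t{lin.species_id}\t{lin.genus_id}\t{lin.family_id}\t"
                f"{lin.species_name}\t{lin.genus_name}\t{lin.family_name}\n"
            )


# ---------------------------------------------------------------------------
# configuration files
# ---------------------------------------------------------------------------


def load_config(path: PathLike) -> PipelineConfig:
    """Load a key=value config file; unknown keys are an error."""
    known = {f.name: f for f in fields(PipelineConfig)}
    kwargs = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise FormatError(f"{path}:{lineno}: expected key=value")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in known:
                raise FormatError(f"{path}:{lineno}: unknown config key {key!r}")
            if key == "adapter_sequences":
                kwargs[key] = tuple(s.strip() for s in value.split(",") if s.strip())
            elif key == "match_score_diagnostic_strict":
                kwargs[key] = value.lower() in ("1", "true", "yes")
            elif known[key].type in ("int", int):
                kwargs[key] = int(value)
            else:
                kwargs[key] = float(value)
    return PipelineConfig(**kwargs)


def save_config(cfg: PipelineConfig, path: PathLike) -> None:
    with open(path, "w") as out:
        for f in fields(PipelineConfig):
            value = getattr(cfg, f.name)
            if f.name == "adapter_sequences":
                value = ",".join(value)
            out.write(f"{f.name} = {value}\n")


def log_stage_counts(stage: str, counts: Mapping[str, int]) -> None:
    """Structured record-count logging at each pipeline stage."""
    summary = ", ".join(f"{k}={v}" for k, v in counts.items())
    logger.info("stage=%s %s", stage, summary)
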