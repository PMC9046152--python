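"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from aquascreen.assign import SpeciesAssignment
from aquascreen.calling import SpeciesCountTable
from aquascreen.io_core import (
    AlignmentRecord,
    Lineage,
    PipelineConfig,
    ReadPair,
    ReadRecord,
    TaxonomyTable,
    Tier,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

BASES = "ACGT"


@pytest.fixture
def cfg() -> PipelineConfig:
    return PipelineConfig()


def make_aln(
    query_id: str = "r1/1",
    subject: str = "NC_1",
    pid: float | None = None,
    length: int = 100,
    mismatches: int = 0,
    gaps: int = 0,
    qstart: int = 1,
    qend: int | None = None,
    sstart: int = 1,
    send: int | None = None,
    e_value: float = 1e-40,
    bit_score: float = 180.0,
) -> AlignmentRecord:
    """AlignmentRecord builder with consistent defaults."""
    if pid is None:
        pid = 100.0 * (length - mismatches - gaps) / length
    if qend is None:
        qend = qstart + length - 1
    if send is None:
        send = sstart + length - 1
    return AlignmentRecord(
        query_id=query_id,
        subject_accession=subject,
        percent_identity=pid,
        alignment_length=length,
        mismatches=mismatches,
        gaps=gaps,
        query_start=qstart,
        query_end=qend,
        subject_start=sstart,
        subject_end=send,
        e_value=e_value,
        bit_score=bit_score,
    )


def make_read(
    sequence: str,
    read_id: str = "r1",
    mate: int = 1,
    quality: int = 37,
    qualities: tuple[int, ...] | None = None,
    chastity: bool = True,
) -> ReadRecord:
    if qualities is None:
        qualities = (quality,) * len(sequence)
    return ReadRecord(read_id, mate, sequence, qualities, chastity)


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def make_pair(
    rng: np.random.Generator, read_id: str, length: int = 100, quality: int = 37
) -> ReadPair:
    return ReadPair(
        make_read(random_seq(rng, length), read_id, 1, quality),
        make_read(random_seq(rng, length), read_id, 2, quality),
    )


def toy_taxonomy() -> TaxonomyTable:
    """Three species (two sharing a genus), three tiers, plus lineage."""
    table = TaxonomyTable()
    entries = [
        ("NC_1", "10359", Tier.VIRAL, "G1", "FAM1"),
        ("NC_1b", "10359", Tier.VIRAL, "G1", "FAM1"),  # second accession, same species
        ("NC_2", "20001", Tier.VIRAL, "G1", "FAM1"),
        ("NC_3", "30001", Tier.BACTERIAL, "G2", "FAM2"),
        ("NC_4", "40001", Tier.FUNGAL_PROTOZOAN, "G3", "FAM3"),
    ]
    for accession, taxon, tier, genus, family in entries:
        table.accession_to_taxon[accession] = taxon
        table.tier[accession] = tier
        table.lineage[taxon] = Lineage(taxon, genus, family)
    return table


def concordant_evidence(
    taxon: str,
    intervals: list[tuple[int, int]],
    scores: list[float] | float = 10.0,
    accession: str = "ACC1",
    read_prefix: str = "p",
) -> list[SpeciesAssignment]:
    """Mate-level assignments forming one concordant pair per interval.

    Mate 1 covers the left end and mate 2 the right end of each linked
    interval, so link_pair reconstructs exactly the given interval.
    """
    if isinstance(scores, (int, float)):
        scores = [float(scores)] * len(intervals)
    out: list[SpeciesAssignment] = []
    for i, ((start, end), score) in enumerate(zip(intervals, scores)):
        mid = (start + end) // 2
        for mate, interval in ((1, (start, mid)), (2, (mid, end))):
            out.append(
                SpeciesAssignment(
                    read_id=f"{read_prefix}{i}",
                    mate=mate,
                    taxon_id=taxon,
                    subject_accession=accession,
                    subject_interval=interval,
                    match_score=score,
                    tier=Tier.VIRAL,
                )
            )
    return out


def count_table(
    sample_counts: dict[str, dict[str, int]], totals: dict[str, int]
) -> SpeciesCountTable:
    counts = SpeciesCountTable()
    counts.totals.update(totals)
    for sample, per_taxon in sample_counts.items():
        for taxon, n in per_taxon.items():
            counts.add(sample, taxon, n)
    return counts
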