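"""Deterministic synthetic data for desk-scale pipeline runs.

Emulates the study design end to end: toy genomes across the three
microbial tiers plus a host, viral spike-ins at stated genome-copy
levels, a reagent-contaminant ("kitome") panel shared at identical
expected fractions between samples and water controls, paired-end
insert-size structure, and i.i.d. sequencing error.  A naive ungapped
seed-and-extend aligner produces 12-column alignment records so no
external aligner is needed.  Every emitted read is recorded in a ground
truth manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .io_core import (
    AlignmentRecord,
    Lineage,
    ReadPair,
    ReadRecord,
    TaxonomyTable,
    Tier,
    write_alignments,
    write_fastq,
    write_taxonomy,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeSpec:
    taxon_id: str
    name: str
    tier: Tier
    length: int
    gc: float = 0.5


@dataclass(frozen=True)
class ContaminantSpec:
    """A kitome taxon present at the same expected read fraction in every
    library, water controls and samples alike."""

    taxon_id: str
    water_fraction: float


def _default_genomes() -> tuple[GenomeSpec, ...]:
    viral = tuple(
        GenomeSpec(f"V00{i}", f"Simulavirus {greek}", Tier.VIRAL, 8_000, 0.45)
        for i, greek in enumerate(
            ("alpha", "beta", "gamma", "delta", "epsilon"), start=1
        )
    )
    bacterial = tuple(
        GenomeSpec(f"B00{i}", f"Aquabacter sim{i}", Tier.BACTERIAL, 40_000, 0.55)
        for i in range(1, 5)
    )
    fungal = (GenomeSpec("F001", "Hydromyces aquae", Tier.FUNGAL_PROTOZOAN, 60_000, 0.4),)
    return viral + bacterial + fungal


def _default_panel() -> tuple[ContaminantSpec, ...]:
    taxa = ("B001", "B002", "B003", "B004", "F001")
    return tuple(ContaminantSpec(t, 4e-4) for t in taxa)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the simulated spike-in experiment.

    ``reads_per_genome_copy`` is the library efficiency: expected
    concordant pairs recovered per spiked genome copy.  At the default
    0.01 the Poisson sampling model puts the 200 genome-copy spike level
    in the stochastic marginal-detection regime (about one spike in
    three yields the three discrete pairs a positive call needs) while
    1000 and 5000 copies are detected essentially always.
    """

    rng_seed: int = 0
    genomes: tuple[GenomeSpec, ...] = field(default_factory=_default_genomes)
    spike_levels: tuple[int, ...] = (200, 1000, 5000)
    reads_per_genome_copy: float = 0.01
    read_length: int = 100
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    error_rate: float = 0.002
    contaminant_panel: tuple[ContaminantSpec, ...] = field(
        default_factory=_default_panel
    )
    n_water_controls: int = 5
    host_genome_length: int = 100_000
    host_read_fraction: float = 0.8
    #: post-QC library size (pairs) per library at desk scale
    library_size: int = 500
    base_quality: int = 37

    def __post_init__(self) -> None:
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        for g in self.genomes:
            if g.length < self.read_length:
                raise ValueError(f"genome {g.taxon_id} shorter than read length")
            if not 0.0 <= g.gc <= 1.0:
                raise ValueError("GC fraction must be in [0, 1]")
        if len({g.taxon_id for g in self.genomes}) != len(self.genomes):
            raise ValueError("duplicate taxon ids in genome panel")
        known = {g.taxon_id for g in self.genomes}
        for c in self.contaminant_panel:
            if c.taxon_id not in known:
                raise ValueError(f"contaminant {c.taxon_id} not in genome panel")
            if not 0.0 <= c.water_fraction <= 1.0:
                raise ValueError("water_fraction must be in [0, 1]")
        if not 0.0 <= self.host_read_fraction <= 1.0:
            raise ValueError("host_read_fraction must be in [0, 1]")


HOST_TAXON = "H001"
HOST_ACCESSION = "SIM_HOST"


def accession_for(taxon_id: str) -> str:
    return f"SIM_{taxon_id}"


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReadTruth:
    read_id: str
    source_taxon: Optional[str]  # None for unattributable background reads
    accession: Optional[str]
    fragment_start: int  # 1-based; 0 for background
    insert_length: int
    n_errors: int


@dataclass
class GroundTruth:
    sample: str
    is_water: bool
    spikes: dict[str, float] = field(default_factory=dict)
    reads: dict[str, ReadTruth] = field(default_factory=dict)
    pairs_by_taxon: dict[str, int] = field(default_factory=dict)
    planted: dict[str, list[str]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# genomes and taxonomy
# ---------------------------------------------------------------------------


def _random_genome(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p).tobytes().decode("ascii")


def make_genomes(cfg: SimConfig) -> tuple[dict[str, str], TaxonomyTable]:
    """Generate the reference genomes (plus host) and a 3-level taxonomy.

    Deterministic in cfg.rng_seed; viruses 1 and 2 share a genus and the
    viral genera share a family so taxonomic rollup is exercised.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.rng_seed))
    genomes: dict[str, str] = {}
    table = TaxonomyTable()
    for g in cfg.genomes:
        accession = accession_for(g.taxon_id)
        genomes[accession] = _random_genome(rng, g.length, g.gc)
        table.accession_to_taxon[accession] = g.taxon_id
        table.tier[accession] = g.tier
        if g.tier is Tier.VIRAL:
            genus = "G_VIR1" if g.taxon_id in ("V001", "V002") else f"G_{g.taxon_id}"
            family = "F_VIR"
        elif g.tier is Tier.BACTERIAL:
            genus = f"G_{g.taxon_id}"
            family = "F_BAC"
        else:
            genus = f"G_{g.taxon_id}"
            family = "F_FUN"
        table.lineage[g.taxon_id] = Lineage(
            g.taxon_id, genus, family, g.name, f"genus of {g.name}", family
        )
    genomes[HOST_ACCESSION] = _random_genome(rng, cfg.host_genome_length, 0.41)
    table.accession_to_taxon[HOST_ACCESSION] = HOST_TAXON
    table.tier[HOST_ACCESSION] = Tier.HOST
    table.lineage[HOST_TAXON] = Lineage(
        HOST_TAXON, "G_HOST", "F_HOST", "Simulated host", "host genus", "host family"
    )
    return genomes, table


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


def _mutate(seq: str, rng: np.random.Generator, rate: float) -> tuple[str, int]:
    if rate <= 0:
        return seq, 0
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii"), int(hits.size)


def _fragment_pair(
    cfg: SimConfig,
    rng: np.random.Generator,
    genome: str,
    read_id: str,
    taxon: str,
    accession: str,
) -> tuple[ReadPair, ReadTruth]:
    glen = len(genome)
    insert = int(round(rng.normal(cfg.insert_mean, cfg.insert_sd)))
    insert = max(cfg.read_length, min(insert, glen))
    start = int(rng.integers(0, glen - insert + 1))
    fwd_seq = genome[start : start + cfg.read_length]
    rev_seq = reverse_complement(genome[start + insert - cfg.read_length : start + insert])
    fwd_seq, e1 = _mutate(fwd_seq, rng, cfg.error_rate)
    rev_seq, e2 = _mutate(rev_seq, rng, cfg.error_rate)
    quals = (cfg.base_quality,) * cfg.read_length
    pair = ReadPair(
        ReadRecord(read_id, 1, fwd_seq, quals),
        ReadRecord(read_id, 2, rev_seq, quals),
    )
    truth = ReadTruth(read_id, taxon, accession, start + 1, insert, e1 + e2)
    return pair, truth


def _background_pair(
    cfg: SimConfig, rng: np.random.Generator, read_id: str
) -> tuple[ReadPair, ReadTruth]:
    quals = (cfg.base_quality,) * cfg.read_length
    fwd = rng.choice(_BASES, size=cfg.read_length).tobytes().decode("ascii")
    rev = rng.choice(_BASES, size=cfg.read_length).tobytes().decode("ascii")
    pair = ReadPair(
        ReadRecord(read_id, 1, fwd, quals), ReadRecord(read_id, 2, rev, quals)
    )
    return pair, ReadTruth(read_id, None, None, 0, 0, 0)


def simulate_sample(
    cfg: SimConfig,
    genomes: Mapping[str, str],
    spikes: Mapping[str, float],
    is_water: bool,
    sample_name: str,
    seed: int | np.random.SeedSequence,
) -> tuple[list[ReadPair], GroundTruth]:
    """Simulate one library.

    Pair counts per spiked taxon are Poisson(gc x reads_per_genome_copy);
    contaminant-panel taxa appear in water and non-water libraries alike
    at Poisson(water_fraction x library_size); non-water libraries carry
    host reads at host_read_fraction of the library size, water controls
    the same amount of unattributable random background, so expected
    per-taxon *fractions* match between the two (the WNS null).
    """
    if is_water and spikes:
        raise ValueError("water controls cannot carry spike-in taxa")
    for taxon, gc in spikes.items():
        if gc < 0:
            raise ValueError(f"negative genome copies for {taxon}")
        if accession_for(taxon) not in genomes:
            raise ValueError(f"spike taxon {taxon} not in genome set")
    rng = np.random.default_rng(seed)
    truth = GroundTruth(sample_name, is_water, dict(spikes))
    pairs: list[ReadPair] = []
    counter = 0

    def emit(taxon: Optional[str], n: int) -> None:
        nonlocal counter
        for _ in range(n):
            read_id = f"{sample_name}:{counter:06d}"
            counter += 1
            if taxon is None:
                pair, rt = _background_pair(cfg, rng, read_id)
            else:
                accession = accession_for(taxon)
                pair, rt = _fragment_pair(
                    cfg, rng, genomes[accession], read_id, taxon, accession
                )
            pairs.append(pair)
            truth.reads[read_id] = rt
        key = taxon if taxon is not None else "background"
        truth.pairs_by_taxon[key] = truth.pairs_by_taxon.get(key, 0) + n

    for taxon in sorted(spikes):
        emit(taxon, int(rng.poisson(spikes[taxon] * cfg.reads_per_genome_copy)))
    for contaminant in cfg.contaminant_panel:
        emit(
            contaminant.taxon_id,
            int(rng.poisson(contaminant.water_fraction * cfg.library_size)),
        )
    n_fill = int(rng.poisson(cfg.host_read_fraction * cfg.library_size))
    if is_water:
        emit(None, n_fill)
    else:
        for _ in range(n_fill):
            read_id = f"{sample_name}:{counter:06d}"
            counter += 1
            pair, rt = _fragment_pair(
                cfg, rng, genomes[HOST_ACCESSION], read_id, HOST_TAXON, HOST_ACCESSION
            )
            pairs.append(pair)
            truth.reads[read_id] = rt
        truth.pairs_by_taxon[HOST_TAXON] = (
            truth.pairs_by_taxon.get(HOST_TAXON, 0) + n_fill
        )
    return pairs, truth


# ---------------------------------------------------------------------------
# planted QC violations
# ---------------------------------------------------------------------------

PLANT_CATEGORIES = (
    "chastity_fail",
    "homopolymer",
    "contains_N",
    "low_quality_first_half",
    "too_short",
    "b_tail",
    "duplicate",
    "low_complexity",
)

_LOW_COMPLEXITY_MOTIFS = ("A", "C", "G", "T", "AC", "AG", "AT", "CA", "CG", "CT")


def plant_qc_violations(
    pairs: Sequence[ReadPair], counts: Mapping[str, int], seed: int
) -> tuple[list[ReadPair], dict[str, list[str]]]:
    """Inject exactly the requested per-category QC violations.

    Each planted pair receives exactly one violation, in its forward
    mate; duplicate planting copies a clean earlier pair's sequences
    into a later pair.  Returns the mutated pair list (original order)
    and the truth map category -> planted read ids.  ``b_tail`` reads
    are trimmed, not removed, by QC; all other categories are removed
    with the matching report reason (a fully low-complexity read is
    attributed to low_complexity even though it is also a homopolymer
    run, because complexity filtering precedes the quality filter).
    """
    for category in counts:
        if category not in PLANT_CATEGORIES:
            raise ValueError(f"unknown plant category {category!r}")
        if counts[category] < 0:
            raise ValueError("plant counts must be nonnegative")
    n_dup = counts.get("duplicate", 0)
    needed = sum(counts.values()) + n_dup  # duplicates also need a source pair
    if needed > len(pairs):
        raise ValueError(f"cannot plant {needed} violations in {len(pairs)} pairs")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pairs), size=needed, replace=False)
    out = list(pairs)
    planted: dict[str, list[str]] = {c: [] for c in counts}
    cursor = 0

    def mutate_forward(idx: int, **changes) -> None:
        fwd = replace(out[idx].forward, **changes)
        out[idx] = ReadPair(fwd, out[idx].reverse)

    for category in sorted(counts):
        if category == "duplicate":
            continue
        for k in range(counts[category]):
            idx = int(chosen[cursor])
            cursor += 1
            fwd = out[idx].forward
            length = len(fwd.sequence)
            if category == "chastity_fail":
                mutate_forward(idx, chastity_pass=False)
            elif category == "homopolymer":
                # run sits at the 5' end so only one entropy window sees it
                # and the read is caught by the homopolymer rule, not the
                # complexity filter
                seq = "G" * 21 + fwd.sequence[21:]
                mutate_forward(idx, sequence=seq)
            elif category == "contains_N":
                pos = length // 2
                seq = fwd.sequence[:pos] + "N" + fwd.sequence[pos + 1 :]
                mutate_forward(idx, sequence=seq)
            elif category == "low_quality_first_half":
                half = length // 2
                quals = (20,) * half + fwd.qualities[half:]
                mutate_forward(idx, qualities=quals)
            elif category == "too_short":
                cut = 60
                mutate_forward(
                    idx, sequence=fwd.sequence[:cut], qualities=fwd.qualities[:cut]
                )
            elif category == "b_tail":
                quals = fwd.qualities[:-10] + (2,) * 10
                mutate_forward(idx, qualities=quals)
            elif category == "low_complexity":
                motif = _LOW_COMPLEXITY_MOTIFS[k % len(_LOW_COMPLEXITY_MOTIFS)]
                seq = (motif * length)[:length]
                mutate_forward(idx, sequence=seq)
            planted[category].append(out[idx].read_id)
    for _ in range(n_dup):
        a, b = int(chosen[cursor]), int(chosen[cursor + 1])
        cursor += 2
        src, dst = (a, b) if a < b else (b, a)
        out[dst] = ReadPair(
            replace(out[src].forward, read_id=out[dst].read_id),
            replace(out[src].reverse, read_id=out[dst].read_id),
        )
        planted["duplicate"].append(out[dst].read_id)
    return out, planted


# ---------------------------------------------------------------------------
# naive seed-and-extend aligner
# ---------------------------------------------------------------------------


class KmerIndex:
    """Exact k-mer index over reference sequences for ungapped alignment.

    Alignments are seed-and-extend at a fixed diagonal, so gaps are
    always 0; an error-free read from a reference is guaranteed to be
    reported full-length at its true locus.  Bit score and e-value are
    monotone surrogates (matches minus twice mismatches).
    """

    def __init__(
        self, refs: Mapping[str, str], k: int = 16, seed_stride: int = 8
    ) -> None:
        if k < 4:
            raise ValueError("k must be >= 4")
        self.k = k
        self.seed_stride = seed_stride
        self.accessions = sorted(refs)
        self.seqs = [refs[a] for a in self.accessions]
        self.index: dict[str, list[tuple[int, int]]] = {}
        for ref_idx, seq in enumerate(self.seqs):
            for pos in range(len(seq) - k + 1):
                self.index.setdefault(seq[pos : pos + k], []).append((ref_idx, pos))

    def _seed_positions(self, length: int) -> list[int]:
        k = self.k
        if length < k:
            return []
        positions = list(range(0, length - k + 1, self.seed_stride))
        if positions[-1] != length - k:
            positions.append(length - k)
        return positions

    def align_read(self, read: ReadRecord) -> list[AlignmentRecord]:
        query_id = f"{read.read_id}/{read.mate}"
        length = len(read.sequence)
        best: dict[int, tuple] = {}  # ref_idx -> (key, record fields)
        for strand, seq in (("+", read.sequence), ("-", reverse_complement(read.sequence))):
            seen: set[tuple[int, int]] = set()
            for qpos in self._seed_positions(length):
                for ref_idx, rpos in self.index.get(seq[qpos : qpos + self.k], ()):
                    offset = rpos - qpos
                    if (ref_idx, offset) in seen:
                        continue
                    seen.add((ref_idx, offset))
                    ref = self.seqs[ref_idx]
                    qs = max(0, -offset)
                    qe = min(length, len(ref) - offset)
                    aln_len = qe - qs
                    if aln_len < self.k:
                        continue
                    mismatches = sum(
                        1
                        for a, b in zip(seq[qs:qe], ref[offset + qs : offset + qe])
                        if a != b
                    )
                    key = (-aln_len, mismatches)
                    if ref_idx in best and best[ref_idx][0] <= key:
                        continue
                    best[ref_idx] = (key, strand, qs, qe, offset, mismatches)
        records = []
        for ref_idx in sorted(best):
            _, strand, qs, qe, offset, mismatches = best[ref_idx]
            aln_len = qe - qs
            bit = float(aln_len - mismatches) - 2.0 * mismatches
            e_value = min(1e3, 2.0 ** (-bit)) if bit > -1000 else 1e3
            if strand == "+":
                q_start, q_end = qs + 1, qe
                s_start, s_end = offset + qs + 1, offset + qe
            else:
                q_start, q_end = length - qe + 1, length - qs
                s_start, s_end = offset + qe, offset + qs + 1
            records.append(
                AlignmentRecord(
                    query_id=query_id,
                    subject_accession=self.accessions[ref_idx],
                    percent_identity=round(100.0 * (aln_len - mismatches) / aln_len, 2),
                    alignment_length=aln_len,
                    mismatches=mismatches,
                    gaps=0,
                    query_start=q_start,
                    query_end=q_end,
                    subject_start=s_start,
                    subject_end=s_end,
                    e_value=e_value,
                    bit_score=bit,
                )
            )
        return records


def toy_align(
    reads: Iterable[ReadRecord], refs: Mapping[str, str], k: int = 16
) -> list[AlignmentRecord]:
    """Convenience wrapper: build an index over refs and align all reads."""
    index = KmerIndex(refs, k=k)
    out: list[AlignmentRecord] = []
    for read in reads:
        out.extend(index.align_read(read))
    return out


# ---------------------------------------------------------------------------
# the full spike-in experiment
# ---------------------------------------------------------------------------


@dataclass
class References:
    """Reference genomes, taxonomy, and prebuilt alignment indices."""

    genomes: dict[str, str]
    taxonomy: TaxonomyTable
    host_index: KmerIndex
    tier_indices: dict[Tier, KmerIndex]


@dataclass
class SampleBundle:
    """Complete simulated inputs for one library."""

    name: str
    is_water: bool
    pairs: list[ReadPair]
    truth: GroundTruth
    host_alignments: list[AlignmentRecord]
    tier_alignments: dict[Tier, list[AlignmentRecord]]


@dataclass
class Bundle:
    cfg: SimConfig
    references: References
    samples: dict[str, SampleBundle]
    water_names: list[str]
    sample_names: list[str]


def build_references(cfg: SimConfig, k: int = 16) -> References:
    genomes, taxonomy = make_genomes(cfg)
    by_tier: dict[Tier, dict[str, str]] = {}
    for accession, seq in genomes.items():
        by_tier.setdefault(taxonomy.tier[accession], {})[accession] = seq
    host_index = KmerIndex(by_tier.get(Tier.HOST, {}), k=k)
    tier_indices = {
        tier: KmerIndex(by_tier.get(tier, {}), k=k)
        for tier in (Tier.VIRAL, Tier.BACTERIAL, Tier.FUNGAL_PROTOZOAN)
    }
    return References(genomes, taxonomy, host_index, tier_indices)


def _align_library(
    pairs: Sequence[ReadPair], refs: References
) -> tuple[list[AlignmentRecord], dict[Tier, list[AlignmentRecord]]]:
    host: list[AlignmentRecord] = []
    tiers: dict[Tier, list[AlignmentRecord]] = {
        tier: [] for tier in refs.tier_indices
    }
    for pair in pairs:
        for read in (pair.forward, pair.reverse):
            host.extend(refs.host_index.align_read(read))
            for tier, index in refs.tier_indices.items():
                tiers[tier].extend(index.align_read(read))
    return host, tiers


def simulate_library_bundle(
    cfg: SimConfig,
    refs: References,
    name: str,
    spikes: Mapping[str, float],
    is_water: bool,
    seed: int | np.random.SeedSequence,
) -> SampleBundle:
    pairs, truth = simulate_sample(cfg, refs.genomes, spikes, is_water, name, seed)
    host, tiers = _align_library(pairs, refs)
    return SampleBundle(name, is_water, pairs, truth, host, tiers)


def run_replicate(
    cfg: SimConfig,
    refs: References,
    spikes: Mapping[str, float],
    replicate_seed: int,
) -> Bundle:
    """One experiment: n_water_controls water libraries plus one spiked
    sample, simulated and aligned against the prebuilt references."""
    ss = np.random.SeedSequence(entropy=(cfg.rng_seed, replicate_seed))
    children = ss.spawn(cfg.n_water_controls + 1)
    samples: dict[str, SampleBundle] = {}
    water_names = []
    for i in range(cfg.n_water_controls):
        name = f"water{i + 1}"
        water_names.append(name)
        samples[name] = simulate_library_bundle(
            cfg, refs, name, {}, True, children[i]
        )
    samples["sample"] = simulate_library_bundle(
        cfg, refs, "sample", spikes, False, children[-1]
    )
    return Bundle(cfg, refs, samples, water_names, ["sample"])


def run_spike_experiment(
    cfg: SimConfig,
    spike_taxon: Optional[str] = None,
    out_dir: Optional[Path] = None,
) -> Bundle:
    """Full fixture set: water controls plus one spiked sample per
    configured spike level, with alignments and ground truth.

    Deterministic in cfg.rng_seed (same config twice gives byte-identical
    outputs when written).  Writes FASTA/FASTQ/TSV files when out_dir is
    given.
    """
    refs = build_references(cfg)
    if spike_taxon is None:
        spike_taxon = next(
            g.taxon_id for g in cfg.genomes if g.tier is Tier.VIRAL
        )
    ss = np.random.SeedSequence(entropy=(cfg.rng_seed, 0x5EED))
    children = ss.spawn(cfg.n_water_controls + len(cfg.spike_levels))
    samples: dict[str, SampleBundle] = {}
    water_names, sample_names = [], []
    for i in range(cfg.n_water_controls):
        name = f"water{i + 1}"
        water_names.append(name)
        samples[name] = simulate_library_bundle(cfg, refs, name, {}, True, children[i])
    for j, level in enumerate(cfg.spike_levels):
        name = f"spike{level}"
        sample_names.append(name)
        samples[name] = simulate_library_bundle(
            cfg,
            refs,
            name,
            {spike_taxon: float(level)},
            False,
            children[cfg.n_water_controls + j],
        )
    bundle = Bundle(cfg, refs, samples, water_names, sample_names)
    if out_dir is not None:
        write_bundle(bundle, Path(out_dir))
    return bundle


def write_bundle(bundle: Bundle, out_dir: Path) -> None:
    """Write the complete fixture set as plain-text files."""
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "references.fa", "w") as fa:
        for accession in sorted(bundle.references.genomes):
            seq = bundle.references.genomes[accession]
            fa.write(f">{accession}\n")
            for i in range(0, len(seq), 80):
                fa.write(seq[i : i + 80] + "\n")
    write_taxonomy(
        bundle.references.taxonomy,
        out_dir / "accession2taxon.tsv",
        out_dir / "lineage.tsv",
    )
    with open(out_dir / "truth.tsv", "w") as truth_out:
        truth_out.write(
            "sample\tread_id\tsource_taxon\taccession\tfragment_start\t"
            "insert_length\tn_errors\n"
        )
        for name in sorted(bundle.samples):
            sample = bundle.samples[name]
            write_fastq(
                (p.forward for p in sample.pairs), out_dir / f"{name}_R1.fastq"
            )
            write_fastq(
                (p.reverse for p in sample.pairs), out_dir / f"{name}_R2.fastq"
            )
            write_alignments(sample.host_alignments, out_dir / f"{name}_host.tsv")
            for tier, alignments in sorted(sample.tier_alignments.items()):
                write_alignments(
                    alignments, out_dir / f"{name}_{tier.value.lower()}.tsv"
                )
            for read_id in sorted(sample.truth.reads):
                rt = sample.truth.reads[read_id]
                truth_out.write(
                    f"{name}\t{rt.read_id}\t{rt.source_taxon or ''}\t"
                    f"{rt.accession or ''}\t{rt.fragment_start}\t"
                    f"{rt.insert_length}\t{rt.n_errors}\n"
                )
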