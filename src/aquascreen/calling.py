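"""Per-taxon evidence aggregation and diagnostic-read calling.

A taxon is reported positive in a sample only when all four diagnostic
criteria hold: (1) at least one read pair with both mates matching the
species, (2) at least three mutually discrete linked pairs (< 50 bp
pairwise overlap), (3) a strictly positive match score for every
contributing pair, and (4) a Water Normalization Score above 1.0 (a
taxon entirely absent from the pooled water controls passes, since
absence from negative controls is the strongest anti-contamination
evidence).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .assign import ConcordantPair, SpeciesAssignment, assign_pairs
from .io_core import PipelineConfig, TaxonomyTable, logger

#: WNS sentinel for a taxon with zero reads in every pooled water control
ABSENT_IN_WATER = math.inf

CRITERIA = ("pair_concordance", "discrete_pairs", "match_score", "wns")


# ---------------------------------------------------------------------------
# counts and the Water Normalization Score
# ---------------------------------------------------------------------------


@dataclass
class SpeciesCountTable:
    """Concordant-pair counts per (sample, taxon) plus per-sample totals.

    Totals are the post-QC sequenced-pair denominators for the whole
    library (host and unassigned reads included), not per-species sums.
    """

    pair_counts: dict[tuple[str, str], int] = field(default_factory=dict)
    totals: dict[str, int] = field(default_factory=dict)

    def add(self, sample: str, taxon: str, n: int = 1) -> None:
        key = (sample, taxon)
        self.pair_counts[key] = self.pair_counts.get(key, 0) + n

    def count(self, sample: str, taxon: str) -> int:
        return self.pair_counts.get((sample, taxon), 0)

    def fraction(self, sample: str, taxon: str) -> float:
        total = self.totals[sample]
        if total < 1:
            raise ValueError(f"sample {sample!r} has total < 1")
        return self.count(sample, taxon) / total

    def taxa(self, samples: Optional[Iterable[str]] = None) -> set[str]:
        wanted = None if samples is None else set(samples)
        return {
            taxon
            for (sample, taxon), n in self.pair_counts.items()
            if n > 0 and (wanted is None or sample in wanted)
        }


@dataclass(frozen=True)
class WNSResult:
    """Water-normalized abundance of one taxon in one sample.

    ``wns`` is sample fraction over pooled water fraction; the value is
    the ABSENT_IN_WATER sentinel (infinity) when the taxon has reads in
    the sample but none in any water control.
    """

    taxon: str
    sample_fraction: float
    water_fraction: float
    wns: float
    sample: str = ""

    @property
    def absent_in_water(self) -> bool:
        return math.isinf(self.wns)


def compute_wns(
    counts: SpeciesCountTable,
    sample: str,
    water_samples: Iterable[str],
    taxon: str,
) -> WNSResult:
    """WNS = (sample count / sample total) / (pooled water count / pooled
    water total), pooling counts and totals across ALL water controls."""
    waters = sorted(set(water_samples))
    if not waters:
        raise ValueError("water_samples must be non-empty")
    if sample in waters:
        raise ValueError(f"sample {sample!r} cannot be normalized against itself")
    sample_fraction = counts.fraction(sample, taxon)
    water_count = sum(counts.count(w, taxon) for w in waters)
    water_total = sum(counts.totals[w] for w in waters)
    if water_total < 1:
        raise ValueError("pooled water total must be >= 1")
    water_fraction = water_count / water_total
    if water_fraction > 0:
        wns = sample_fraction / water_fraction
    elif sample_fraction > 0:
        wns = ABSENT_IN_WATER
    else:
        wns = 0.0
    return WNSResult(taxon, sample_fraction, water_fraction, wns, sample=sample)


def leave_one_out_water_wns(
    counts: SpeciesCountTable, water_samples: Iterable[str]
) -> list[WNSResult]:
    """WNS of each water control against the pool of the remaining waters,
    for every taxon detected in any water (the variability check behind
    the WNS cutoff)."""
    waters = sorted(set(water_samples))
    if len(waters) < 2:
        raise ValueError("leave-one-out requires at least 2 water samples")
    taxa = sorted(counts.taxa(waters))
    results: list[WNSResult] = []
    for held_out in waters:
        rest = [w for w in waters if w != held_out]
        for taxon in taxa:
            results.append(compute_wns(counts, held_out, rest, taxon))
    return results


# ---------------------------------------------------------------------------
# linked pairs and discreteness
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LinkedPair:
    """Forward and reverse mate intervals merged on one subject sequence."""

    taxon_id: str
    accession: str
    start: int
    end: int
    pair_match_score: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("linked interval must have start <= end")

    @property
    def insert_length(self) -> int:
        return self.end - self.start + 1


def link_pair(pair: ConcordantPair) -> Optional[LinkedPair]:
    """Link mates into one subject interval: [min(starts), max(ends)].

    Mates hitting different accessions of the same species have no
    single subject interval; they stay concordant for counting and WNS
    but are excluded from interval linking (None, logged).
    """
    if pair.forward.subject_accession != pair.reverse.subject_accession:
        logger.info(
            "pair %s concordant on %s via different accessions; excluded "
            "from discreteness",
            pair.read_id,
            pair.taxon_id,
        )
        return None
    lo = min(pair.forward.subject_interval[0], pair.reverse.subject_interval[0])
    hi = max(pair.forward.subject_interval[1], pair.reverse.subject_interval[1])
    return LinkedPair(pair.taxon_id, pair.forward.subject_accession, lo, hi, pair.pair_score)


def interval_overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Overlap in bases of two 1-based inclusive intervals (0 if disjoint)."""
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def count_discrete(
    linked: Sequence[LinkedPair], overlap_limit: int = 50
) -> int:
    """Size of a maximum subset of pairs that are mutually discrete
    (pairwise overlap < overlap_limit bases).

    Two intervals conflict iff they overlap by >= overlap_limit, which is
    exactly intersection of the end-shrunk intervals [start, end -
    overlap_limit + 1]; the conflict graph is therefore an interval graph
    and greedy earliest-end scheduling on the shrunk intervals is an
    exact maximum independent set.  Intervals shorter than the limit can
    never conflict and always count.
    """
    shrunk: list[tuple[int, int]] = []
    n_short = 0
    for lp in linked:
        if lp.insert_length < overlap_limit:
            n_short += 1
        else:
            shrunk.append((lp.end - overlap_limit + 1, lp.start))
    count = 0
    last_end = -math.inf
    for end, start in sorted(shrunk):
        if start > last_end:
            count += 1
            last_end = end
    return count + n_short


# ---------------------------------------------------------------------------
# the species caller
# ---------------------------------------------------------------------------


@dataclass
class SpeciesCall:
    """Final verdict for one taxon in one sample with a criteria audit trail."""

    sample: str
    taxon: str
    n_concordant_pairs: int
    n_discrete_pairs: int
    wns: float
    criteria_passed: dict[str, bool]
    verdict: str
    confirmation_status: str = ""

    @property
    def positive(self) -> bool:
        return self.verdict == "positive"


def call_species(
    sample: str,
    taxon: str,
    assignments: Iterable[SpeciesAssignment],
    counts: SpeciesCountTable,
    water_samples: Iterable[str],
    cfg: PipelineConfig,
    confirmation_status: str = "",
) -> SpeciesCall:
    """Evaluate the four diagnostic criteria for one taxon in one sample.

    ``assignments`` are the sample's retained mate-level assignments
    (any taxon; they are filtered here).  Mates whose partner is
    unassigned or discordant are excluded from the diagnostic evidence
    rather than vetoing the call.  The verdict is positive iff every
    criterion holds.
    """
    taxon_assignments = [a for a in assignments if a.taxon_id == taxon]
    pairs = assign_pairs(taxon_assignments)
    linked = [lp for lp in (link_pair(p) for p in pairs) if lp is not None]
    n_discrete = count_discrete(linked, cfg.discrete_overlap_bp)
    wns_result = compute_wns(counts, sample, water_samples, taxon)
    if cfg.match_score_diagnostic_strict:
        scores_ok = bool(pairs) and all(p.pair_score > 0 for p in pairs)
    else:
        scores_ok = bool(pairs) and all(p.pair_score >= 0 for p in pairs)
    criteria = {
        "pair_concordance": len(pairs) >= 1,
        "discrete_pairs": n_discrete >= cfg.min_diagnostic_pairs,
        "match_score": scores_ok,
        "wns": wns_result.absent_in_water or wns_result.wns > cfg.wns_cutoff,
    }
    verdict = "positive" if all(criteria.values()) else "negative"
    return SpeciesCall(
        sample=sample,
        taxon=taxon,
        n_concordant_pairs=len(pairs),
        n_discrete_pairs=n_discrete,
        wns=wns_result.wns,
        criteria_passed=criteria,
        verdict=verdict,
        confirmation_status=confirmation_status,
    )


# ---------------------------------------------------------------------------
# rollup, coverage, inserts, ordination
# ---------------------------------------------------------------------------


def rollup(
    species_counts: Mapping[str, int], taxonomy: TaxonomyTable, level: str = "genus"
) -> dict[str, int]:
    """Aggregate species-level counts to genus or family; species with an
    unresolvable lineage land in an 'unclassified' bucket with a warning.
    Totals are conserved."""
    if level not in ("genus", "family"):
        raise ValueError("level must be 'genus' or 'family'")
    out: dict[str, int] = {}
    for taxon, n in species_counts.items():
        try:
            lin = taxonomy.lineage_of(taxon)
            key = lin.genus_id if level == "genus" else lin.family_id
        except KeyError:
            logger.warning("taxon %r has no lineage; counted as unclassified", taxon)
            key = "unclassified"
        out[key] = out.get(key, 0) + n
    return out


@dataclass(frozen=True)
class CoverageStats:
    covered_fraction: float  # percent of genome covered by >= 1 read
    mean_depth_covered: float  # mean depth over covered positions only
    n_reads: int


def coverage_stats(
    intervals: Iterable[tuple[int, int]], genome_length: int
) -> CoverageStats:
    """Breadth and depth of coverage from 1-based inclusive subject intervals."""
    if genome_length < 1:
        raise ValueError("genome_length must be >= 1")
    depth = np.zeros(genome_length, dtype=np.int64)
    n = 0
    for lo, hi in intervals:
        if lo < 1 or hi > genome_length or lo > hi:
            raise ValueError(f"interval ({lo}, {hi}) outside [1, {genome_length}]")
        depth[lo - 1 : hi] += 1
        n += 1
    covered = depth > 0
    n_covered = int(covered.sum())
    return CoverageStats(
        covered_fraction=100.0 * n_covered / genome_length,
        mean_depth_covered=float(depth[covered].mean()) if n_covered else 0.0,
        n_reads=n,
    )


def insert_histogram(
    linked: Iterable[LinkedPair], bin_width: int = 100
) -> dict[int, int]:
    """Histogram of linked-pair insert lengths; keys are bin lower edges
    (bin [k, k + bin_width)), values are counts.  Sums to the number of
    linked pairs."""
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    hist: dict[int, int] = {}
    for lp in linked:
        edge = (lp.insert_length // bin_width) * bin_width
        hist[edge] = hist.get(edge, 0) + 1
    return hist


def log2_wns_matrix(wns_table: pd.DataFrame, floor: float = 2.0**-10) -> pd.DataFrame:
    """Log2-transform a samples x taxa WNS table for ordination.

    Entries are log2(max(wns, floor)); the ABSENT_IN_WATER sentinel maps
    to log2 of the table's maximum finite WNS (or the floor when no
    finite positive value exists).
    """
    if floor <= 0:
        raise ValueError("floor must be > 0")
    values = wns_table.to_numpy(dtype=float)
    finite = values[np.isfinite(values)]
    ceiling = float(finite.max()) if finite.size and finite.max() > 0 else floor
    filled = np.where(np.isinf(values), ceiling, values)
    return pd.DataFrame(
        np.log2(np.maximum(filled, floor)),
        index=wns_table.index,
        columns=wns_table.columns,
    )


def pca_coordinates(matrix: pd.DataFrame, n_components: int = 2) -> pd.DataFrame:
    """Principal-component coordinates of samples from a log2-WNS matrix
    (ordination is delegated to scikit-learn)."""
    from sklearn.decomposition import PCA

    n_components = min(n_components, matrix.shape[0], matrix.shape[1])
    pca = PCA(n_components=n_components, random_state=0)
    coords = pca.fit_transform(matrix.to_numpy(dtype=float))
    return pd.DataFrame(
        coords,
        index=matrix.index,
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )


def write_linked_bed(linked: Iterable[LinkedPair], path) -> None:
    """Linked-pair intervals as BED (0-based half-open) for genome browsers."""
    with open(path, "w") as out:
        for lp in linked:
            out.write(
                f"{lp.accession}\t{lp.start - 1}\t{lp.end}\t{lp.taxon_id}\t"
                f"{lp.pair_match_score:.4g}\n"
            )


def write_coverage_report(
    stats_by_taxon: Mapping[str, CoverageStats], path
) -> None:
    """Per-taxon genome coverage TSV (breadth %, mean depth, read count)."""
    with open(path, "w") as out:
        out.write("taxon\tcovered_fraction_pct\tmean_depth_covered\tn_reads\n")
        for taxon in sorted(stats_by_taxon):
            s = stats_by_taxon[taxon]
            out.write(
                f"{taxon}\t{s.covered_fraction:.2f}\t{s.mean_depth_covered:.3f}\t"
                f"{s.n_reads}\n"
            )


def write_calls(calls: Iterable[SpeciesCall], path) -> None:
    """Per-taxon report TSV: verdicts, diagnostic-read counts, WNS,
    criteria audit, and confirmation status."""
    with open(path, "w") as out:
        out.write(
            "sample\ttaxon\tverdict\tn_concordant_pairs\tn_discrete_pairs\twns\t"
            + "\t".join(CRITERIA)
            + "\tconfirmation_status\n"
        )
        for c in calls:
            wns = "ABSENT_IN_WATER" if math.isinf(c.wns) else f"{c.wns:.4g}"
            flags = "\t".join(str(c.criteria_passed[k]) for k in CRITERIA)
            out.write(
                f"{c.sample}\t{c.taxon}\t{c.verdict}\t{c.n_concordant_pairs}\t"
                f"{c.n_discrete_pairs}\t{wns}\t{flags}\t{c.confirmation_status}\n"
            )
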