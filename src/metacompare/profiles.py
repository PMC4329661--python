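"""Taxonomic and functional (Pfam) profile construction and comparison.

Per-read classifier output — taxon assignments at a given rank, or Pfam
family assignments with a superkingdom — is consumed as tables and turned
into per-sample count profiles. Samples of unequal sequencing depth are
made comparable by *smallest-dataset normalization*: every profile's counts
are scaled by N_min / N_sample, where N_min is the total of the shallowest
sample, so the shallowest profile is a fixed point of the operation and
within-sample relative abundances are preserved exactly.

Comparisons built on normalized profiles:

* scatter data — log10(count + 1) per taxon for two samples, with a
  pseudocount of one so absent taxa land at zero, restricted to taxa whose
  summed relative abundance reaches ``min_rel_sum`` (default 0.01%);
* unique environmental gene tags (EGTs) — taxa/Pfams absent (raw count
  exactly zero) in one sample with normalized abundance ≥ 5 in the other;
* rarefaction — mean distinct-taxon richness vs subsample depth by
  repeated subsampling without replacement;
* the archaeal methanogenesis comparison — archaeal Pfam counts restricted
  to a curated pathway map, normalized to the smallest dataset.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .community import RANKS

logger = logging.getLogger(__name__)

DEFAULT_EVALUE_THRESHOLD = 1e-5
DEFAULT_MIN_REL_SUM = 0.0001  # 0.01% summed relative abundance
DEFAULT_UNIQUE_MIN_ABUNDANCE = 5.0
DEFAULT_RAREFACTION_REPS = 10

_PFAM_RE = re.compile(r"^PF\d{5}$")


@dataclass(frozen=True)
class AssignmentRecord:
    """One read's taxonomic assignment at one rank."""

    read_id: str
    rank: str
    taxon: str
    evalue: float

    def __post_init__(self):
        if self.rank not in RANKS:
            raise ValueError(f"unknown rank {self.rank!r}")
        if not (math.isfinite(self.evalue) and self.evalue > 0):
            raise ValueError(f"evalue must be finite and positive, got {self.evalue}")


@dataclass(frozen=True)
class FunctionalRecord:
    """One read's Pfam family assignment, optionally with a superkingdom."""

    read_id: str
    pfam_acc: str
    superkingdom: str | None
    evalue: float

    def __post_init__(self):
        if not _PFAM_RE.match(self.pfam_acc):
            raise ValueError(f"pfam_acc must match PFxxxxx, got {self.pfam_acc!r}")
        if not (math.isfinite(self.evalue) and self.evalue > 0):
            raise ValueError(f"evalue must be finite and positive, got {self.evalue}")


@dataclass
class Profile:
    """Per-sample counts of taxa (or Pfams) at one rank.

    ``total_reads`` is the relative-abundance denominator — the number of
    reads in the sample, assigned or not. After normalization counts and
    total may be real-valued.
    """

    sample_id: str
    rank: str
    counts: dict
    total_reads: float

    def __post_init__(self):
        if self.total_reads < 0:
            raise ValueError("total_reads must be non-negative")
        for t, c in self.counts.items():
            if c < 0 or c > self.total_reads + 1e-9:
                raise ValueError(f"count for {t!r} out of [0, total_reads]")

    @property
    def richness(self) -> int:
        return sum(1 for c in self.counts.values() if c > 0)

    def relative(self, taxon: str) -> float:
        return self.counts.get(taxon, 0) / self.total_reads

    @property
    def assigned(self) -> float:
        return sum(self.counts.values())


@dataclass(frozen=True)
class ScatterPoint:
    taxon: str
    x: float
    y: float


@dataclass
class RarefactionCurve:
    rank_or_unit: str
    depths: list
    mean_richness: list
    sd_richness: list
    reps: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "depth": self.depths,
                "mean_richness": self.mean_richness,
                "sd_richness": self.sd_richness,
            }
        )


def filter_by_evalue(records, threshold: float = DEFAULT_EVALUE_THRESHOLD):
    """Keep records with evalue ≤ threshold (boundary inclusive)."""
    if not threshold > 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    return [r for r in records if r.evalue <= threshold]


def build_profile(records, rank: str, total_reads: int, sample_id: str = "sample") -> Profile:
    """Count taxon assignments at ``rank`` into a Profile.

    Each read may contribute at most one record at the given rank; a
    duplicated read_id is a hard error naming the read. Reads without a
    record at the rank contribute only to ``total_reads``.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    counts: dict[str, int] = {}
    seen: set[str] = set()
    for r in records:
        if r.rank != rank:
            continue
        if r.read_id in seen:
            raise ValueError(f"read {r.read_id!r} has multiple assignments at rank {rank!r}")
        seen.add(r.read_id)
        counts[r.taxon] = counts.get(r.taxon, 0) + 1
    return Profile(sample_id=sample_id, rank=rank, counts=counts, total_reads=total_reads)


def normalize_to_smallest(profiles):
    """Scale every profile's counts by N_min / N_sample (smallest-dataset normalization).

    The smallest profile is returned unchanged (a fixed point); all totals
    become N_min. Scaled counts are real-valued.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles to normalize")
    if any(p.total_reads <= 0 for p in profiles):
        raise ValueError("all profile totals must be positive")
    n_min = min(p.total_reads for p in profiles)
    out = []
    for p in profiles:
        scale = n_min / p.total_reads
        if scale == 1.0:
            out.append(Profile(p.sample_id, p.rank, dict(p.counts), p.total_reads))
        else:
            out.append(
                Profile(
                    p.sample_id,
                    p.rank,
                    {t: c * scale for t, c in p.counts.items()},
                    n_min,
                )
            )
    return out


def percentage_of_total(count, totals) -> float:
    """Percentage of ``count`` relative to the smallest dataset total.

    Returns 100 × count / min(totals), rounded half-up to 2 decimals — the
    convention under which published recruitment tables report both samples
    against the same (smallest) denominator.
    """
    if not totals:
        raise ValueError("totals must be non-empty")
    if any(t <= 0 for t in totals):
        raise ValueError("totals must all be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    pct = Decimal(100) * Decimal(str(count)) / Decimal(str(min(totals)))
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _check_normalized(a: Profile, b: Profile):
    if not math.isclose(a.total_reads, b.total_reads, rel_tol=1e-9):
        raise ValueError(
            "profiles must be normalized to the same total "
            f"(got {a.total_reads} and {b.total_reads}); call normalize_to_smallest first"
        )


def scatter_points(
    a: Profile,
    b: Profile,
    pseudocount: float = 1,
    min_rel_sum: float = DEFAULT_MIN_REL_SUM,
):
    """Log10 pseudocounted abundance pairs for two normalized profiles.

    A taxon is retained iff the sum of its relative abundances in the two
    samples reaches ``min_rel_sum``; its point is
    (log10(count_a + pseudocount), log10(count_b + pseudocount)), so an
    absent taxon sits at coordinate 0.
    """
    _check_normalized(a, b)
    points = []
    for taxon in sorted(set(a.counts) | set(b.counts)):
        ca, cb = a.counts.get(taxon, 0), b.counts.get(taxon, 0)
        if ca / a.total_reads + cb / b.total_reads < min_rel_sum:
            continue
        points.append(
            ScatterPoint(taxon, math.log10(ca + pseudocount), math.log10(cb + pseudocount))
        )
    return points


def unique_egts(a: Profile, b: Profile, min_abundance: float = DEFAULT_UNIQUE_MIN_ABUNDANCE):
    """Taxa/Pfams present in only one sample at meaningful abundance.

    A unit is *unique to a* iff its count in b is exactly zero (a raw zero
    scales to zero, so normalization cannot rescue absence) and its
    normalized count in a is ≥ ``min_abundance`` (inclusive, default 5).
    Returns (unique_to_a, unique_to_b) as sets.
    """
    _check_normalized(a, b)
    ua = {
        t
        for t, c in a.counts.items()
        if c >= min_abundance and b.counts.get(t, 0) == 0
    }
    ub = {
        t
        for t, c in b.counts.items()
        if c >= min_abundance and a.counts.get(t, 0) == 0
    }
    return ua, ub


def rarefy(
    records,
    rank: str,
    depths,
    reps: int = DEFAULT_RAREFACTION_REPS,
    seed: int = 0,
) -> RarefactionCurve:
    """Rarefaction of taxon richness by subsampling assigned reads.

    For each replicate the assigned reads are permuted once and richness is
    read off prefixes of the permutation, which is equivalent to nested
    subsampling without replacement and makes every replicate's curve
    non-decreasing in depth. Mean and SD over ``reps`` replicates are
    reported per depth.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    taxa = [r.taxon for r in records if r.rank == rank]
    n = len(taxa)
    depths = sorted(int(d) for d in depths)
    if not depths:
        raise ValueError("depths must be non-empty")
    if depths[0] < 1:
        raise ValueError("depths must be positive")
    if depths[-1] > n:
        raise ValueError(f"depth {depths[-1]} exceeds the {n} assigned reads")

    codes = pd.factorize(np.asarray(taxa))[0]
    n_taxa = codes.max() + 1 if n else 0
    rng = np.random.default_rng(seed)
    richness = np.empty((reps, len(depths)))
    for rep in range(reps):
        perm = codes[rng.permutation(n)]
        # first-occurrence position of each taxon in this permutation
        first = np.full(n_taxa, n, dtype=np.int64)
        # reversed assignment leaves the earliest index per taxon
        first[perm[::-1]] = np.arange(n - 1, -1, -1)
        first.sort()
        richness[rep] = np.searchsorted(first, depths, side="left")
    return RarefactionCurve(
        rank_or_unit=rank,
        depths=depths,
        mean_richness=richness.mean(axis=0).tolist(),
        sd_richness=(richness.std(axis=0, ddof=1) if reps > 1 else np.zeros(len(depths))).tolist(),
        reps=reps,
        seed=seed,
    )


def default_depths(n_assigned: int, k: int = 10):
    """``k`` evenly spaced subsample depths up to the assigned-read count."""
    if n_assigned < 1:
        raise ValueError("no assigned reads")
    return sorted({max(1, round(n_assigned * i / k)) for i in range(1, k + 1)})


#: Curated Pfam → pathway map for the methanogenesis comparison: methyl-CoM
#: reductase subunits, acetate activation (acetyl-CoA pathway), and the
#: Wood-Ljungdahl carbonyl/methyl branch. A starting set; supply your own
#: map for serious use.
DEFAULT_PATHWAY_MAP = {
    # acetyl-CoA pathway (acetoclastic entry)
    "PF00871": "acetyl-CoA pathway",  # acetate kinase
    "PF01515": "acetyl-CoA pathway",  # phosphate acetyltransferase
    # methanogenesis (methyl-coenzyme M reductase and cofactors)
    "PF02745": "methanogenesis",  # MCR alpha N-terminal
    "PF02249": "methanogenesis",  # MCR alpha
    "PF02241": "methanogenesis",  # MCR beta C-terminal
    "PF02783": "methanogenesis",  # MCR beta N-terminal
    "PF02240": "methanogenesis",  # MCR gamma
    "PF04609": "methanogenesis",  # coenzyme M methyltransferase-associated
    # Wood-Ljungdahl pathway
    "PF01268": "Wood-Ljungdahl pathway",  # formate--tetrahydrofolate ligase
    "PF03598": "Wood-Ljungdahl pathway",  # CO dehydrogenase/acetyl-CoA synthase beta
    "PF03599": "Wood-Ljungdahl pathway",  # CdhD, acetyl-CoA decarbonylase delta
}


def methanogenesis_comparison(
    a,
    b,
    totals,
    pathway_map: dict | None = None,
    sample_ids=("A", "B"),
) -> pd.DataFrame:
    """Archaeal methanogenesis-pathway Pfam abundances for two samples.

    Functional records are restricted to superkingdom *Archaea* and to
    Pfams in ``pathway_map``; per-Pfam counts are scaled by N_min/total
    (smallest-dataset normalization with the supplied sample totals).
    Records lacking a superkingdom are skipped with a warning count.
    Returns a tidy table (pathway, pfam_acc, count per sample).
    """
    pathway_map = DEFAULT_PATHWAY_MAP if pathway_map is None else pathway_map
    if not pathway_map:
        raise ValueError("pathway_map must be non-empty")
    if len(totals) != 2 or any(t <= 0 for t in totals):
        raise ValueError("totals must be two positive dataset sizes")
    n_min = min(totals)

    def counts_for(records, total):
        skipped = 0
        counts: dict[str, float] = {}
        for r in records:
            if r.superkingdom is None:
                skipped += 1
                continue
            if r.superkingdom != "Archaea" or r.pfam_acc not in pathway_map:
                continue
            counts[r.pfam_acc] = counts.get(r.pfam_acc, 0) + 1
        if skipped:
            logger.warning("%d functional records lacked a superkingdom; skipped", skipped)
        return {p: c * n_min / total for p, c in counts.items()}

    ca = counts_for(a, totals[0])
    cb = counts_for(b, totals[1])
    rows = []
    for pfam in sorted(set(ca) | set(cb), key=lambda p: (pathway_map[p], p)):
        rows.append(
            {
                "pathway": pathway_map[pfam],
                "pfam_acc": pfam,
                f"count_{sample_ids[0]}": ca.get(pfam, 0.0),
                f"count_{sample_ids[1]}": cb.get(pfam, 0.0),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["pathway", "pfam_acc", f"count_{sample_ids[0]}", f"count_{sample_ids[1]}"],
    )


# ---------------------------------------------------------------------------
# tabular I/O

def read_assignments_tsv(path):
    """Load a taxonomic assignment table (read_id, rank, taxon, evalue)."""
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str, "rank": str, "taxon": str})
    return [
        AssignmentRecord(row.read_id, row.rank, row.taxon, float(row.evalue))
        for row in df.itertuples()
    ]


def write_assignments_tsv(records, path):
    pd.DataFrame(
        {
            "read_id": [r.read_id for r in records],
            "rank": [r.rank for r in records],
            "taxon": [r.taxon for r in records],
            "evalue": [r.evalue for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def read_functional_tsv(path):
    """Load a functional assignment table (read_id, pfam_acc, superkingdom, evalue)."""
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str, "pfam_acc": str}, keep_default_na=False)
    return [
        FunctionalRecord(
            row.read_id, row.pfam_acc, row.superkingdom or None, float(row.evalue)
        )
        for row in df.itertuples()
    ]


def write_functional_tsv(records, path):
    pd.DataFrame(
        {
            "read_id": [r.read_id for r in records],
            "pfam_acc": [r.pfam_acc for r in records],
            "superkingdom": [r.superkingdom or "" for r in records],
            "evalue": [r.evalue for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def write_profile_tsv(profile: Profile, path):
    """Profile export with both denominators: assigned reads and all reads."""
    assigned = profile.assigned
    rows = [
        {
            "taxon": t,
            "count": c,
            "rel_abundance_total": c / profile.total_reads,
            "rel_abundance_assigned": (c / assigned) if assigned else 0.0,
        }
        for t, c in sorted(profile.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    pd.DataFrame(rows, columns=["taxon", "count", "rel_abundance_total", "rel_abundance_assigned"]).to_csv(
        path, sep="\t", index=False
    )


def write_krona_tsv(profile: Profile, lineages: dict, path):
    """Krona-compatible export: count followed by lineage columns.

    ``lineages`` maps each taxon to its full lineage tuple (superkingdom
    downwards); taxa without a lineage are written as a single column.
    """
    with open(path, "w") as fh:
        for taxon, count in sorted(profile.counts.items(), key=lambda kv: (-kv[1], kv[0])):
            lineage = lineages.get(taxon, (taxon,))
            fh.write("\t".join([str(count), *lineage]) + "\n")


def write_scatter_tsv(points, path):
    pd.DataFrame(
        {
            "taxon": [p.taxon for p in points],
            "log10_a": [p.x for p in points],
            "log10_b": [p.y for p in points],
        }
    ).to_csv(path, sep="\t", index=False)
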