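"""Fragment recruitment of metagenome reads to reference genomes.

A read is *recruited* when it aligns to a reference genome; plotting
per-read identity against alignment position shows how closely the resident
population matches that reference. The identity statistic used throughout
this package divides the number of identical bases by the **full read
length**, not by the aligned span — a short local alignment of a long read
therefore scores low by construction, which is the intended penalty.

Hits below the 55% identity floor are discarded (boundary inclusive: 55%
is retained); the per-genome ranking counts reads at ≥ 90% identity, and
percentages are always taken against the smallest dataset total so the two
samples share one denominator. Identity distributions are binned at 1%
from 55 to 100, the last bin closed so perfect hits are counted.

Alignments come either from BLAST tabular (outfmt 6) files or from the
built-in aligner: exact k-mer seeding on both strands followed by ungapped
extension over the full read span. The built-in aligner guarantees that a
read occurring verbatim in a genome yields a hit with identity 1.0 at the
true coordinates; it exists so the whole pipeline runs self-contained at
desk scale, not as a BLAST replacement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community import Genome, ReadSet, seq_to_codes
from .profiles import percentage_of_total

IDENTITY_FLOOR = 0.55
HIGH_IDENTITY = 0.90
DEFAULT_SEED_LENGTH = 15

#: histogram bin edges in percent identity: 45 one-percent bins over [55, 100]
HISTOGRAM_EDGES = tuple(range(55, 101))


@dataclass(frozen=True)
class AlignmentHit:
    """One read-to-genome alignment with full-read identity accounting.

    ``read_length`` is the full read length (the identity denominator);
    subject coordinates are 1-based inclusive with start ≤ end regardless
    of strand.
    """

    read_id: str
    genome_id: str
    identical_bases: int
    read_length: int
    subject_start: int
    subject_end: int
    strand: str = "+"
    score: float = 0.0

    def __post_init__(self):
        if self.read_length <= 0:
            raise ValueError(f"hit {self.read_id!r}: read_length must be positive")
        if not 0 <= self.identical_bases <= self.read_length:
            raise ValueError(
                f"hit {self.read_id!r}: identical_bases outside [0, read_length]"
            )
        if not 1 <= self.subject_start <= self.subject_end:
            raise ValueError(f"hit {self.read_id!r}: bad subject coordinates")
        if self.strand not in "+-":
            raise ValueError(f"hit {self.read_id!r}: strand must be + or -")

    @property
    def identity(self) -> float:
        return self.identical_bases / self.read_length


@dataclass(frozen=True)
class RecruitmentSummary:
    genome_id: str
    n_hits_retained: int
    n_ge_high: int
    percentage: float


@dataclass
class HistogramBins:
    """Normalized 1%-binned identity distribution over [55, 100]."""

    sample_id: str
    counts: np.ndarray
    raw_counts: np.ndarray
    edges: tuple = HISTOGRAM_EDGES

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_low_pct": self.edges[:-1],
                "bin_high_pct": self.edges[1:],
                "raw_count": self.raw_counts,
                "normalized_count": self.counts,
            }
        )


@dataclass(frozen=True)
class RecruitmentPoint:
    genome_id: str
    position: float
    identity: float  # percent


def compute_identity(hit: AlignmentHit) -> float:
    """Identity = identical bases / full read length (fraction in [0, 1])."""
    return hit.identity


def filter_hits(hits, floor: float = IDENTITY_FLOOR, inclusive: bool = True):
    """Drop hits below the identity floor (inclusive boundary by default)."""
    if inclusive:
        return [h for h in hits if h.identity >= floor]
    return [h for h in hits if h.identity > floor]


def _hit_order_key(h: AlignmentHit):
    # best first: higher identity, higher score, lower subject_start, genome id
    return (-h.identity, -h.score, h.subject_start, h.genome_id)


def best_hit_per_read(hits, scope: str = "per-genome"):
    """Reduce to the single best hit per (read, genome) — or per read.

    Ties break by higher score, then lower subject start, then
    lexicographic genome id. Output keeps the first-seen order of the
    surviving keys.
    """
    if scope not in ("per-genome", "global"):
        raise ValueError("scope must be 'per-genome' or 'global'")
    best: dict = {}
    order: list = []
    for h in hits:
        key = h.read_id if scope == "global" else (h.read_id, h.genome_id)
        if key not in best:
            best[key] = h
            order.append(key)
        elif _hit_order_key(h) < _hit_order_key(best[key]):
            best[key] = h
    return [best[k] for k in order]


def summarize(hits, totals, high: float = HIGH_IDENTITY, top: int | None = None):
    """Per-genome recruitment ranking.

    Expects hits already floored and reduced to best-hit per (read,
    genome). ``n_ge_high`` counts reads at identity ≥ ``high`` (inclusive);
    the percentage divides by the smallest dataset total. Sorted by
    ``n_ge_high`` descending (ties by genome id), optionally truncated.
    """
    per_genome: dict[str, list] = {}
    for h in hits:
        per_genome.setdefault(h.genome_id, []).append(h)
    summaries = [
        RecruitmentSummary(
            genome_id=gid,
            n_hits_retained=len(ghits),
            n_ge_high=sum(1 for h in ghits if h.identity >= high),
            percentage=percentage_of_total(
                sum(1 for h in ghits if h.identity >= high), totals
            ),
        )
        for gid, ghits in per_genome.items()
    ]
    summaries.sort(key=lambda s: (-s.n_ge_high, s.genome_id))
    return summaries[:top] if top else summaries


def histogram(hits, totals, sample_total: float | None = None, sample_id: str = "sample"):
    """1%-binned identity distribution, normalized to the smallest dataset.

    ``sample_total`` is the dataset total of the sample the hits belong to
    (defaults to the single entry when ``totals`` has length 1); raw bin
    counts are scaled by min(totals) / sample_total, so the smallest
    sample's histogram equals its raw histogram. Hits must already be
    floored at 55%.
    """
    if sample_total is None:
        if len(totals) != 1:
            raise ValueError("sample_total required when multiple totals are given")
        sample_total = totals[0]
    identities = np.array([h.identity * 100 for h in hits])
    if identities.size and (identities.min() < 55 or identities.max() > 100):
        raise ValueError("hit identity outside [55%, 100%]; apply filter_hits first")
    edges = np.asarray(HISTOGRAM_EDGES, dtype=float)
    raw, _ = np.histogram(identities, bins=edges)  # np.histogram closes the last bin
    scale = min(totals) / sample_total
    return HistogramBins(
        sample_id=sample_id, counts=raw * scale, raw_counts=raw, edges=HISTOGRAM_EDGES
    )


def recruitment_points(hits, abscissa: str = "midpoint"):
    """One plottable point per hit: alignment position vs percent identity."""
    if abscissa not in ("start", "midpoint", "end"):
        raise ValueError("abscissa must be start, midpoint or end")
    points = []
    for h in hits:
        if abscissa == "start":
            pos = float(h.subject_start)
        elif abscissa == "end":
            pos = float(h.subject_end)
        else:
            pos = (h.subject_start + h.subject_end) / 2
        points.append(RecruitmentPoint(h.genome_id, pos, h.identity * 100))
    return points


# ---------------------------------------------------------------------------
# built-in aligner

_COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.int8)  # A<->T, C<->G in code space


class GenomeIndex:
    """Exact k-mer index over one genome's forward strand."""

    def __init__(self, genome: Genome, k: int = DEFAULT_SEED_LENGTH):
        if k < 8:
            raise ValueError("seed length k must be >= 8")
        self.genome = genome
        self.k = k
        self.codes = seq_to_codes(genome.sequence)
        n = len(self.codes)
        self.kmers: dict[bytes, list] = {}
        if n >= k:
            view = self.codes.tobytes()
            for pos in range(n - k + 1):
                self.kmers.setdefault(view[pos : pos + k], []).append(pos)

    def seed_positions(self, read_codes: np.ndarray, stride: int):
        """Candidate alignment offsets: genome position − read kmer position."""
        k = self.k
        view = read_codes.tobytes()
        offsets = set()
        limit = len(read_codes) - k
        positions = list(range(0, limit + 1, stride))
        if positions and positions[-1] != limit:
            positions.append(limit)
        for rpos in positions:
            for gpos in self.kmers.get(view[rpos : rpos + k], ()):
                offsets.add(gpos - rpos)
        return offsets


def _evaluate_offset(gcodes: np.ndarray, rcodes: np.ndarray, offset: int):
    """Identical-base count of an ungapped full-read placement; clips at genome ends."""
    glen, rlen = len(gcodes), len(rcodes)
    gs, ge = max(offset, 0), min(offset + rlen, glen)
    if ge <= gs:
        return 0, 0, 0
    ident = int(np.count_nonzero(gcodes[gs:ge] == rcodes[gs - offset : ge - offset]))
    return ident, gs, ge


def align_reads(
    reads: ReadSet,
    genomes,
    k: int = DEFAULT_SEED_LENGTH,
    stride: int | None = None,
    indexes=None,
):
    """Align every read to every genome by k-mer seeding + ungapped extension.

    Both strands are searched (the read and its reverse complement against
    the forward reference). Every distinct seeded offset is evaluated over
    the full read span and the best placement per (read, genome) is
    reported, with ``identical_bases`` counted against the full read
    length. Unalignable reads are simply absent from the output.
    """
    if stride is None:
        stride = max(1, k // 2)
    if indexes is None:
        indexes = [GenomeIndex(g, k) for g in genomes]
    hits = []
    for read in reads:
        rcodes = seq_to_codes(read.sequence)
        rlen = len(rcodes)
        if rlen < k:
            continue
        rc = _COMPLEMENT[rcodes[::-1]]
        for index in indexes:
            best = None  # (ident, strand, gs, ge)
            for strand, codes in (("+", rcodes), ("-", rc)):
                for offset in index.seed_positions(codes, stride):
                    ident, gs, ge = _evaluate_offset(index.codes, codes, offset)
                    if ident == 0:
                        continue
                    cand = (ident, strand, gs, ge)
                    if best is None or cand[0] > best[0] or (
                        cand[0] == best[0] and cand[2] < best[2]
                    ):
                        best = cand
            if best is not None:
                ident, strand, gs, ge = best
                hits.append(
                    AlignmentHit(
                        read_id=read.id,
                        genome_id=index.genome.id,
                        identical_bases=ident,
                        read_length=rlen,
                        subject_start=gs + 1,
                        subject_end=ge,
                        strand=strand,
                        score=float(ident),
                    )
                )
    return hits


# ---------------------------------------------------------------------------
# BLAST tabular input

BLAST6_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen qstart qend sstart send evalue bitscore"
).split()


def read_blast6(path, read_lengths: dict, max_evalue: float | None = None):
    """Parse BLAST outfmt-6 hits into AlignmentHits.

    ``read_lengths`` maps read id → full read length, taken from the read
    file — the identity denominator must be the read length, not the
    aligned span. ``identical_bases`` is reconstructed as
    round(pident × alignment_length / 100). Subject coordinates are
    normalized to start ≤ end with the strand recorded.
    """
    df = pd.read_csv(path, sep="\t", names=BLAST6_COLUMNS, comment="#")
    if max_evalue is not None:
        df = df[df["evalue"] <= max_evalue]
    hits = []
    for row in df.itertuples():
        qid = str(row.qseqid)
        if qid not in read_lengths:
            raise KeyError(f"read {qid!r} in BLAST output but not in the read file")
        sstart, send = int(row.sstart), int(row.send)
        strand = "+" if sstart <= send else "-"
        if strand == "-":
            sstart, send = send, sstart
        ident = int(round(row.pident * row.length / 100.0))
        rlen = int(read_lengths[qid])
        hits.append(
            AlignmentHit(
                read_id=qid,
                genome_id=str(row.sseqid),
                identical_bases=min(ident, rlen),
                read_length=rlen,
                subject_start=sstart,
                subject_end=send,
                strand=strand,
                score=float(row.bitscore),
            )
        )
    return hits


def write_ranking_tsv(summaries, path):
    pd.DataFrame(
        {
            "genome_id": [s.genome_id for s in summaries],
            "n_hits_retained": [s.n_hits_retained for s in summaries],
            "n_ge_high": [s.n_ge_high for s in summaries],
            "percentage": [s.percentage for s in summaries],
        }
    ).to_csv(path, sep="\t", index=False)


def write_points_tsv(points, path):
    pd.DataFrame(
        {
            "genome_id": [p.genome_id for p in points],
            "position": [p.position for p in points],
            "identity_pct": [p.identity for p in points],
        }
    ).to_csv(path, sep="\t", index=False)
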