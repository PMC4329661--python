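"""Fragment recruitment: identity statistic, thresholds, aligner vs brute force."""

import numpy as np
import pytest
from scipy import stats

from metacompare import (
    AlignmentHit,
    CommunitySpec,
    ReadSet,
    align_reads,
    best_hit_per_read,
    compute_identity,
    filter_hits,
    generate_genome,
    histogram,
    read_blast6,
    recruitment_points,
    simulate_reads,
    summarize,
)
from metacompare.community import seq_to_codes

from conftest import mismatches_at_truth

TOTALS = [1_347_644, 1_532_780]


def hit(ident, rlen=400, read_id="r", genome_id="g", start=1, score=0.0, end=None):
    return AlignmentHit(
        read_id=read_id,
        genome_id=genome_id,
        identical_bases=ident,
        read_length=rlen,
        subject_start=start,
        subject_end=end if end is not None else start + rlen - 1,
        score=score,
    )


class TestIdentity:
    def test_full_length_perfect(self):
        assert compute_identity(hit(400)) == 1.0

    def test_floor_boundary_arithmetic(self):
        assert compute_identity(hit(220)) == pytest.approx(0.55)

    def test_denominator_is_read_length_not_span(self):
        # a 100-bp perfect local alignment of a 400-bp read scores 0.25
        h = hit(100, rlen=400, start=1, end=100)
        assert compute_identity(h) == 0.25

    def test_invalid_hits_rejected(self):
        with pytest.raises(ValueError):
            hit(401)
        with pytest.raises(ValueError):
            AlignmentHit("r", "g", 10, 0, 1, 10)


class TestFilterHits:
    @pytest.mark.parametrize(
        "ident,kept",
        [(219, False), (220, True), (221, True)],  # /400 = .5475, .55, .5525
        ids=["below-floor", "at-floor", "above-floor"],
    )
    def test_floor_boundary_inclusive(self, ident, kept):
        assert (len(filter_hits([hit(ident)])) == 1) is kept

    def test_empty(self):
        assert filter_hits([]) == []

    def test_exclusive_option(self):
        assert filter_hits([hit(220)], inclusive=False) == []


class TestBestHit:
    def test_highest_identity_wins(self):
        hits = [hit(360, read_id="r1"), hit(320, read_id="r1")]
        assert best_hit_per_read(hits) == [hits[0]]

    def test_tie_breaks_by_score_then_start(self):
        a = hit(360, score=50.0, start=100)
        b = hit(360, score=60.0, start=200)
        assert best_hit_per_read([a, b]) == [b]
        c = hit(360, score=50.0, start=50)
        assert best_hit_per_read([a, c]) == [c]

    def test_scope_global_vs_per_genome(self):
        hits = [hit(360, genome_id="g1"), hit(320, genome_id="g2")]
        assert len(best_hit_per_read(hits, scope="per-genome")) == 2
        assert best_hit_per_read(hits, scope="global") == [hits[0]]

    def test_distinct_reads_unaffected(self):
        hits = [hit(360, read_id="r1"), hit(320, read_id="r2")]
        assert best_hit_per_read(hits) == hits

    def test_floor_commutes_with_best_hit(self):
        """Flooring before or after best-by-identity selection is equivalent."""
        rng = np.random.default_rng(0)
        hits = [
            hit(int(v), read_id=f"r{i % 20}", genome_id=f"g{i % 3}", start=1 + i)
            for i, v in enumerate(rng.integers(150, 401, size=200))
        ]
        a = best_hit_per_read(filter_hits(hits))
        b = filter_hits(best_hit_per_read(hits))
        assert sorted(a, key=id) == sorted(b, key=id) or {
            (h.read_id, h.genome_id, h.identical_bases) for h in a
        } == {(h.read_id, h.genome_id, h.identical_bases) for h in b}


class TestSummarize:
    def test_published_percentage_convention(self):
        hits = [hit(380, read_id=f"r{i}", genome_id="M. bourgensis") for i in range(3)]
        (s,) = summarize(hits, TOTALS)
        assert s.n_ge_high == 3
        assert s.percentage == pytest.approx(100 * 3 / TOTALS[0], abs=0.01)

    @pytest.mark.parametrize("ident,counted", [(359, False), (360, True)])
    def test_high_threshold_inclusive(self, ident, counted):
        (s,) = summarize([hit(ident)], TOTALS)
        assert (s.n_ge_high == 1) is counted
        assert s.n_hits_retained == 1

    def test_sorted_by_high_count_and_zero_rows_listed(self):
        hits = [
            hit(380, read_id="r1", genome_id="big"),
            hit(380, read_id="r2", genome_id="big"),
            hit(300, read_id="r3", genome_id="small"),  # 0.75 < 0.90
        ]
        s = summarize(hits, TOTALS)
        assert [x.genome_id for x in s] == ["big", "small"]
        assert s[1].n_ge_high == 0 and s[1].percentage == 0.0

    def test_top_truncation(self):
        hits = [hit(380, read_id=f"r{i}", genome_id=f"g{i}") for i in range(5)]
        assert len(summarize(hits, TOTALS, top=3)) == 3


class TestHistogram:
    def test_perfect_hits_land_in_final_closed_bin(self):
        h = histogram([hit(400) for _ in range(5)], totals=[100])
        assert h.raw_counts[-1] == 5
        assert h.raw_counts[:-1].sum() == 0

    def test_raw_counts_conserve_hits(self):
        rng = np.random.default_rng(1)
        hits = [hit(int(v)) for v in rng.integers(220, 401, size=300)]
        h = histogram(hits, totals=[100])
        assert h.raw_counts.sum() == 300

    def test_normalization_smallest_sample_unscaled(self):
        hits = [hit(400)] * 4
        raw = histogram(hits, totals=[100, 200], sample_total=100)
        scaled = histogram(hits, totals=[100, 200], sample_total=200)
        assert raw.counts[-1] == 4  # smallest sample: histogram equals raw
        assert scaled.counts[-1] == pytest.approx(2.0)

    def test_unfloored_hits_rejected(self):
        with pytest.raises(ValueError, match="filter"):
            histogram([hit(100)], totals=[10])


class TestRecruitmentPoints:
    def test_midpoint_abscissa(self):
        (p,) = recruitment_points([hit(400, start=1, end=401)])
        assert p.position == 201.0

    def test_identity_carried_in_percent(self):
        (p,) = recruitment_points([hit(300)])
        assert p.identity == pytest.approx(75.0)

    def test_alternative_abscissas(self):
        (p,) = recruitment_points([hit(400, start=11, end=410)], abscissa="start")
        assert p.position == 11.0


class TestAligner:
    def test_exact_substring_recovered_at_true_coordinates(self, ref_genome, clean_reads):
        sub = ReadSet("s", clean_reads.reads[:50])
        hits = align_reads(sub, [ref_genome])
        by_read = {h.read_id: h for h in hits}
        for read in sub:
            h = by_read[read.id]
            assert h.identity == 1.0
            assert h.subject_start == read.truth_start + 1
            assert h.strand == "+"

    def test_reverse_complement_same_coordinates(self, ref_genome, clean_reads):
        comp = str.maketrans("ACGT", "TGCA")
        read = clean_reads.reads[0]
        rc = type(read)(id="rc", sequence=read.sequence.translate(comp)[::-1])
        (h,) = align_reads(ReadSet("s", [rc]), [ref_genome])
        assert h.strand == "-"
        assert h.identity == 1.0
        assert h.subject_start == read.truth_start + 1

    def test_identities_match_brute_force_at_divergence(self, ref_genome, diverged_reads):
        """>=99% of 5%-divergence reads hit, with identity == brute-force count."""
        hits = align_reads(diverged_reads, [ref_genome])
        by_read = {h.read_id: h for h in hits}
        assert len(by_read) >= 0.99 * len(diverged_reads)
        matched = 0
        for read in diverged_reads:
            h = by_read.get(read.id)
            if h is None:
                continue
            expected = len(read.sequence) - mismatches_at_truth(read, ref_genome)
            if h.subject_start == read.truth_start + 1:
                assert h.identical_bases == expected
                matched += 1
            else:
                assert h.identical_bases >= expected  # found an even better locus
        assert matched >= 0.99 * len(by_read)

    def test_unalignable_reads_absent(self, ref_genome):
        from metacompare import Read

        junk = ReadSet("s", [Read(id="junk", sequence="AC" * 200)])
        # a dinucleotide repeat may seed, but a read of Ns cannot; use a
        # genome-free sequence from a different alphabet composition
        other = generate_genome(20_000, 0.5, seed=999, genome_id="other")
        hits = align_reads(ReadSet("s", [Read(id="r", sequence=other.sequence[:400])]), [ref_genome])
        assert all(h.identity < 0.9 for h in hits)


def brute_force_best(read_seq, genome):
    """Exact best full-read placement over all offsets and both strands."""
    g = seq_to_codes(genome.sequence)
    windows = np.lib.stride_tricks.sliding_window_view(g, len(read_seq))
    comp = str.maketrans("ACGT", "TGCA")
    best = (0, None, None)
    for strand, seq in (("+", read_seq), ("-", read_seq.translate(comp)[::-1])):
        r = seq_to_codes(seq)
        scores = (windows == r).sum(axis=1)
        idx = int(scores.argmax())
        if scores[idx] > best[0]:
            best = (int(scores[idx]), strand, idx)
    return best


def test_pipeline_equivalence_with_exhaustive_aligner(ref_genome):
    """Seeded aligner equals the all-offsets brute force on a small instance."""
    spec = CommunitySpec(
        genomes=[ref_genome], abundances=[1.0], divergences=[0.05],
        n_reads=100, read_length_mean=400, read_length_sd=0, seed=55,
    )
    rs = simulate_reads(spec)
    hits = {h.read_id: h for h in align_reads(rs, [ref_genome])}
    for read in rs:
        ident, strand, idx = brute_force_best(read.sequence, ref_genome)
        h = hits.get(read.id)
        assert h is not None
        assert h.identical_bases == ident
        assert h.subject_start == idx + 1


def test_recruitment_specificity_between_diverged_references():
    """Reads 2% from genome A recruit to A, not to a 20%-diverged relative."""
    a = generate_genome(30_000, 0.5, seed=70, genome_id="A")
    codes = seq_to_codes(a.sequence).copy()
    rng = np.random.default_rng(71)
    mut = rng.random(len(codes)) < 0.20
    codes[mut] = (codes[mut] + rng.integers(1, 4, size=int(mut.sum()))) % 4
    from metacompare.community import codes_to_seq
    from metacompare import Genome

    b = Genome(id="B", sequence=codes_to_seq(codes))
    spec = CommunitySpec(
        genomes=[a, b], abundances=[1.0, 0.0], divergences=[0.02, 0.02],
        n_reads=500, read_length_mean=400, read_length_sd=0, seed=72,
    )
    rs = simulate_reads(spec)
    hits = filter_hits(align_reads(rs, [a, b]), 0.90)
    hits = best_hit_per_read(hits, scope="global")
    to_a = sum(1 for h in hits if h.genome_id == "A")
    assert to_a >= 0.99 * len(hits)
    assert len(hits) > 400


def test_blast6_parsing(tmp_path, ref_genome, clean_reads):
    """outfmt-6 rows reconstruct identical_bases and normalize minus-strand coords."""
    path = tmp_path / "hits.tsv"
    rows = [
        # qseqid sseqid pident length mismatch gapopen qstart qend sstart send evalue bitscore
        "r1\trefA\t95.00\t400\t20\t0\t1\t400\t101\t500\t1e-50\t700",
        "r2\trefA\t100.00\t200\t0\t0\t1\t200\t900\t701\t1e-30\t400",  # minus strand
    ]
    path.write_text("\n".join(rows) + "\n")
    lengths = {"r1": 400, "r2": 400}
    hits = read_blast6(path, lengths)
    h1, h2 = hits
    assert h1.identical_bases == 380 and h1.identity == pytest.approx(0.95)
    # 200 identical bases of a 400-bp read: half-length alignment scores 0.5
    assert h2.identical_bases == 200 and h2.identity == pytest.approx(0.50)
    assert h2.strand == "-" and h2.subject_start == 701 and h2.subject_end == 900

    with pytest.raises(KeyError):
        read_blast6(path, {"r1": 400})


def test_modal_bin_tracks_divergence(ref_genome, diverged_reads):
    """At 5% divergence the identity mode sits at the binomial prediction."""
    hits = best_hit_per_read(filter_hits(align_reads(diverged_reads, [ref_genome])))
    h = histogram(hits, totals=[len(diverged_reads)])
    modal_low = h.edges[int(np.argmax(h.raw_counts))]
    # exact binomial mode for L=400, p=0.95 lies in [94, 96)
    assert modal_low in (94, 95)
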