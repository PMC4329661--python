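"""Synthetic microbial communities and 454-like read simulation.

This module generates reference genomes with known taxonomy and simulates
pyrosequencing-style shotgun read sets from a community of those genomes.
Every downstream stage of the pipeline (duplicate/GC QC, taxonomic
profiling, fragment recruitment) can therefore be exercised against exact
ground truth: each simulated read records the genome it came from, its
0-based offset on that genome, and — for emulsion-PCR duplicate artifacts —
the read it duplicates.

The error model is substitution-only by default: each base of a read is
replaced by one of the three other bases independently with the per-genome
divergence probability. 454 homopolymer indels can be switched on via
``CommunitySpec.indel_rate`` but are off by default, because the statistics
computed downstream (read-length-normalized identity, profile counts)
depend only on identical-base fractions, not on indels.

Duplicate reads model emPCR artifacts: a duplicate shares its parent's
genome, start coordinate and length, but receives an independent error
draw. When ``gc_dup_coupling > 0`` GC-rich parents are more likely to be
duplicated, emulating the GC-coupled amplification bias the QC stage
removes.

All randomness in a simulation flows from the single integer seed in the
``CommunitySpec``; identical specs produce byte-identical FASTA output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

RANKS = ("superkingdom", "phylum", "class", "order", "family", "genus")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i
    _BASE_INDEX[ord(chr(_b).lower())] = _i

#: divergence at or above this cannot stay resolvable above the 55% identity floor
MAX_DIVERGENCE = 0.45

MIN_READ_LENGTH = 50


def seq_to_codes(sequence: str) -> np.ndarray:
    """Encode an ACGT string as an int8 array of base indices (A=0..T=3)."""
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    codes = _BASE_INDEX[raw]
    if (codes < 0).any():
        bad = chr(raw[np.argmax(codes < 0)])
        raise ValueError(f"sequence contains non-ACGT character {bad!r}")
    return codes


def codes_to_seq(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def gc_fraction(sequence: str) -> float:
    """GC content of a sequence as a fraction in [0, 1]."""
    if not sequence:
        return 0.0
    s = sequence.upper()
    return (s.count("G") + s.count("C")) / len(s)


@dataclass(frozen=True)
class Genome:
    """A reference genome with an ordered taxonomic lineage.

    The lineage maps ranks (superkingdom..genus) to names and must have no
    gaps: if a rank is populated, every rank above it is populated too.
    """

    id: str
    sequence: str
    taxon_lineage: dict = field(default_factory=dict)
    gc_target: float | None = None

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"genome {self.id!r}: sequence must be non-empty")
        unknown = set(self.taxon_lineage) - set(RANKS)
        if unknown:
            raise ValueError(f"genome {self.id!r}: unknown ranks {sorted(unknown)}")
        populated = [r in self.taxon_lineage for r in RANKS]
        if populated and any(populated):
            last = max(i for i, p in enumerate(populated) if p)
            if not all(populated[: last + 1]):
                raise ValueError(
                    f"genome {self.id!r}: lineage has gaps between populated ranks"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def gc(self) -> float:
        return gc_fraction(self.sequence)


@dataclass(frozen=True)
class Read:
    """A simulated (or real) sequencing read with optional provenance."""

    id: str
    sequence: str
    truth_genome: str | None = None
    truth_start: int | None = None
    is_duplicate_of: str | None = None

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def gc(self) -> float:
        return gc_fraction(self.sequence)


@dataclass
class ReadSet:
    """A named collection of reads; ``total_count`` always equals len(reads)."""

    sample_id: str
    reads: list

    @property
    def total_count(self) -> int:
        return len(self.reads)

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)

    def mean_length(self) -> float:
        if not self.reads:
            return 0.0
        return float(np.mean([len(r) for r in self.reads]))


@dataclass
class CommunitySpec:
    """Full description of a synthetic community sequencing experiment.

    Parameters
    ----------
    genomes : list of Genome
        Reference genomes making up the community.
    abundances : sequence of float
        Per-genome community fractions; must sum to 1 (±1e-9).
    divergences : sequence of float
        Per-genome substitution rate of sampled reads relative to the
        reference, each in [0, 0.45). Rates at or above 0.45 would push
        expected read identity below the 55% recruitment floor and are
        rejected.
    read_length_mean, read_length_sd : float
        Read lengths are drawn from a normal distribution truncated to
        [50 bp, 2 × mean]; 454 Titanium chemistry motivates the default
        mean of 387 bp.
    n_reads : int
        Total reads to simulate, including duplicates.
    duplicate_rate : float
        Fraction of reads that are emPCR duplicate artifacts, in [0, 1).
    gc_dup_coupling : float
        Strength (≥0) of the GC bias in duplicate formation: parents are
        chosen with weight exp(coupling × parent GC fraction). 0 = uniform.
    indel_rate : float
        Per-base probability of a homopolymer-associated single-base
        insertion or deletion (454-style). Off (0.0) by default.
    duplicate_fresh_errors : bool
        If True (default), duplicates get an independent error draw on the
        parent's reference window; if False they are byte-identical copies.
    seed : int
        Single global seed for all stochastic draws.
    """

    genomes: list
    abundances: list
    divergences: list
    n_reads: int
    read_length_mean: float = 387.0
    read_length_sd: float = 50.0
    duplicate_rate: float = 0.0
    gc_dup_coupling: float = 0.0
    indel_rate: float = 0.0
    duplicate_fresh_errors: bool = True
    sample_id: str = "synthetic"
    seed: int = 0

    def __post_init__(self):
        if not self.genomes:
            raise ValueError("at least one genome is required")
        k = len(self.genomes)
        if len(self.abundances) != k or len(self.divergences) != k:
            raise ValueError("abundances and divergences must match genomes in length")
        if abs(sum(self.abundances) - 1.0) > 1e-9:
            raise ValueError(f"abundances must sum to 1, got {sum(self.abundances)}")
        if any(a < 0 for a in self.abundances):
            raise ValueError("abundances must be non-negative")
        for g, d in zip(self.genomes, self.divergences):
            if not 0 <= d < MAX_DIVERGENCE:
                raise ValueError(
                    f"divergence for genome {g.id!r} must be in [0, {MAX_DIVERGENCE}), got {d}"
                )
        if self.n_reads < 0:
            raise ValueError("n_reads must be non-negative")
        if not 0 <= self.duplicate_rate < 1:
            raise ValueError("duplicate_rate must be in [0, 1)")
        if self.gc_dup_coupling < 0:
            raise ValueError("gc_dup_coupling must be >= 0")
        if self.read_length_mean <= 0:
            raise ValueError("read_length_mean must be positive")


def generate_genome(
    length: int,
    gc_target: float,
    seed: int,
    genome_id: str = "genome",
    taxon_lineage: dict | None = None,
) -> Genome:
    """Generate a random genome whose GC content targets ``gc_target``.

    Each position is G/C with probability ``gc_target`` (split evenly
    between G and C) and A/T otherwise, so for length ≥ 10 kb the realized
    GC fraction concentrates within ~0.02 of the target. Deterministic
    given ``seed``.
    """
    if length < 1000:
        raise ValueError(f"genome length must be >= 1000, got {length}")
    if not 0 < gc_target < 1:
        raise ValueError(f"gc_target must be in (0, 1), got {gc_target}")
    rng = np.random.default_rng(seed)
    is_gc = rng.random(length) < gc_target
    half = rng.integers(0, 2, size=length)
    # indices into ACGT: A=0 C=1 G=2 T=3
    codes = np.where(is_gc, np.where(half == 0, 2, 1), np.where(half == 0, 0, 3))
    return Genome(
        id=genome_id,
        sequence=codes_to_seq(codes.astype(np.int8)),
        taxon_lineage=dict(taxon_lineage or {}),
        gc_target=gc_target,
    )


def _draw_lengths(rng, n, mean, sd):
    lo, hi = MIN_READ_LENGTH, 2.0 * mean
    if sd <= 0:
        return np.full(n, int(round(mean)), dtype=np.int64)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    lengths = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)
    return np.clip(np.rint(lengths), lo, hi).astype(np.int64)


def _mutate(codes: np.ndarray, divergence: float, rng) -> np.ndarray:
    if divergence <= 0:
        return codes.copy()
    out = codes.copy()
    hit = rng.random(len(codes)) < divergence
    n_hit = int(hit.sum())
    if n_hit:
        # shift by 1-3 in base space => always a different base
        out[hit] = (out[hit] + rng.integers(1, 4, size=n_hit)) % 4
    return out


def _apply_homopolymer_indels(codes: np.ndarray, rate: float, rng) -> np.ndarray:
    """Single-base indels preferentially inside homopolymer runs."""
    if rate <= 0 or len(codes) < 2:
        return codes
    in_run = np.zeros(len(codes), dtype=bool)
    in_run[1:] = codes[1:] == codes[:-1]
    out = []
    for i, c in enumerate(codes):
        if in_run[i] and rng.random() < rate:
            if rng.random() < 0.5:
                continue  # deletion
            out.append(c)  # insertion: emit twice
        out.append(c)
    return np.asarray(out, dtype=codes.dtype)


def simulate_reads(spec: CommunitySpec) -> ReadSet:
    """Simulate a 454-like read set from a community specification.

    Non-duplicate reads draw their source genome from the abundance vector,
    a uniform start such that the read lies fully on the genome, and
    per-base substitutions at the genome's divergence rate. Duplicate reads
    (``duplicate_rate`` of the total, rounded) copy the genome/start/length
    of a parent read chosen with weight exp(gc_dup_coupling × parent GC),
    receive an independent error draw, and record ``is_duplicate_of``.
    Parents precede their duplicates in the output.
    """
    rng = np.random.default_rng(spec.seed)
    n_total = spec.n_reads
    if n_total == 0:
        return ReadSet(sample_id=spec.sample_id, reads=[])

    n_dup = int(round(spec.duplicate_rate * n_total))
    n_base = n_total - n_dup
    if n_base == 0 and n_dup > 0:
        raise ValueError("duplicate_rate leaves no parent reads to duplicate")

    genome_codes = [seq_to_codes(g.sequence) for g in spec.genomes]
    genome_ids = [g.id for g in spec.genomes]
    glens = np.array([len(g) for g in genome_codes])

    which = rng.choice(len(spec.genomes), size=n_base, p=np.asarray(spec.abundances))
    lengths = _draw_lengths(rng, n_base, spec.read_length_mean, spec.read_length_sd)
    lengths = np.minimum(lengths, glens[which])  # a read never exceeds its genome
    starts = (rng.random(n_base) * (glens[which] - lengths + 1)).astype(np.int64)

    width = len(str(n_total))
    reads: list[Read] = []
    base_meta = []  # (genome_idx, start, length) for duplicate parents
    for i in range(n_base):
        gi, s, ln = int(which[i]), int(starts[i]), int(lengths[i])
        window = genome_codes[gi][s : s + ln]
        mutated = _mutate(window, spec.divergences[gi], rng)
        mutated = _apply_homopolymer_indels(mutated, spec.indel_rate, rng)
        reads.append(
            Read(
                id=f"read_{i + 1:0{width}d}",
                sequence=codes_to_seq(mutated),
                truth_genome=genome_ids[gi],
                truth_start=s,
            )
        )
        base_meta.append((gi, s, ln))

    if n_dup:
        gcs = np.array([r.gc for r in reads])
        w = np.exp(spec.gc_dup_coupling * gcs)
        w /= w.sum()
        parents = rng.choice(n_base, size=n_dup, p=w)
        for j, pi in enumerate(parents):
            parent = reads[int(pi)]
            gi, s, ln = base_meta[int(pi)]
            if spec.duplicate_fresh_errors:
                window = genome_codes[gi][s : s + ln]
                mutated = _mutate(window, spec.divergences[gi], rng)
                mutated = _apply_homopolymer_indels(mutated, spec.indel_rate, rng)
                seq = codes_to_seq(mutated)
            else:
                seq = parent.sequence
            reads.append(
                Read(
                    id=f"read_{n_base + j + 1:0{width}d}",
                    sequence=seq,
                    truth_genome=parent.truth_genome,
                    truth_start=parent.truth_start,
                    is_duplicate_of=parent.id,
                )
            )

    return ReadSet(sample_id=spec.sample_id, reads=reads)


def genomes_from_defs(defs, seed: int = 0) -> list:
    """Materialize genome definitions (explicit sequences or generated).

    A definition either carries a ``sequence`` or is generated from
    ``length``/``gc`` with the per-genome sub-seed ``seed + 1000 + index``.
    ``seed`` identifies the *reference set*, not a sample: communities that
    share references must be built from the same defs and seed.
    """
    genomes = []
    for i, g in enumerate(defs):
        if "sequence" in g:
            genomes.append(
                Genome(
                    id=g["id"],
                    sequence=g["sequence"],
                    taxon_lineage=dict(g.get("lineage", {})),
                )
            )
        else:
            genomes.append(
                generate_genome(
                    length=int(g.get("length", 50_000)),
                    gc_target=float(g.get("gc", 0.5)),
                    seed=int(g.get("seed", seed + 1000 + i)),
                    genome_id=g["id"],
                    taxon_lineage=dict(g.get("lineage", {})),
                )
            )
    return genomes


def spec_from_dict(d: dict, genomes: list | None = None) -> CommunitySpec:
    """Build a CommunitySpec from a plain (YAML-friendly) dictionary.

    ``genomes`` overrides the dictionary's genome definitions with
    already-materialized Genome objects (used when several samples share
    one reference set).
    """
    d = dict(d)
    defs = d.pop("genomes", None)
    if genomes is None:
        if defs is None:
            raise ValueError("community spec needs genomes")
        genomes = genomes_from_defs(defs, int(d.get("seed", 0)))
    known = {f.name for f in dataclasses.fields(CommunitySpec)}
    kwargs = {k: v for k, v in d.items() if k in known}
    return CommunitySpec(genomes=genomes, **kwargs)
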