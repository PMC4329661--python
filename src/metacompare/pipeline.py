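"""End-to-end seeded runs: config, stage orchestration, manifest.

``run_pipeline`` regenerates every pipeline artifact from a single YAML
config: simulate two communities (or load read files), QC both, build and
compare taxonomic profiles (normalization, scatter, unique EGTs,
rarefaction), and recruit the QC'd reads against the reference genomes.
All outputs land in the config's output directory and are listed, with
SHA-256 checksums, in ``manifest.json``; an identical config yields
identical checksums.

When reads are simulated, per-read taxonomic assignment tables are derived
from the simulation ground truth (each read inherits its source genome's
lineage, with a nominal E-value far below threshold) — i.e. the pipeline
demonstration uses a perfect classifier, exercising every statistic
downstream of classification without shipping one.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .community import (
    RANKS,
    CommunitySpec,
    ReadSet,
    genomes_from_defs,
    simulate_reads,
    spec_from_dict,
)
from . import io as mio
from .profiles import (
    AssignmentRecord,
    build_profile,
    default_depths,
    filter_by_evalue,
    normalize_to_smallest,
    rarefy,
    scatter_points,
    unique_egts,
    write_assignments_tsv,
    write_krona_tsv,
    write_profile_tsv,
    write_scatter_tsv,
)
from .qc import run_qc, write_report_tsv
from .recruitment import (
    GenomeIndex,
    align_reads,
    best_hit_per_read,
    filter_hits,
    histogram,
    recruitment_points,
    summarize,
    write_points_tsv,
    write_ranking_tsv,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised for invalid or inconsistent run configuration."""


@dataclass
class RunConfig:
    """All knobs of a pipeline run; defaults are the published conventions.

    Thresholds: E-value 1e-5 (inclusive), identity floor 0.55 and high
    threshold 0.90 (both inclusive), pseudocount 1, scatter abundance
    filter 0.01%, unique-EGT minimum 5 — see the operation docstrings for
    their meaning.
    """

    outdir: str = "runs/demo"
    seed: int = 42
    rank: str = "family"
    evalue: float = 1e-5
    identity_floor: float = 0.55
    identity_high: float = 0.90
    pseudocount: float = 1.0
    min_rel_sum: float = 0.0001
    unique_min: float = 5.0
    qc_prefix_len: int = 50
    qc_length_tolerance: float = 0.02
    qc_gc_z: float = 3.0
    rarefaction_reps: int = 10
    rarefaction_depths: list | None = None
    aligner_k: int = 15
    totals: list | None = None  # dataset totals; default: unfiltered read counts
    communities: list = field(default_factory=list)  # simulate stage inputs
    reads: dict = field(default_factory=dict)  # sample_id -> FASTA/FASTQ path
    plots: bool = False

    def __post_init__(self):
        if self.rank not in RANKS:
            raise ConfigError(f"unknown rank {self.rank!r}")
        for name, lo, hi in (
            ("identity_floor", 0, 1),
            ("identity_high", 0, 1),
            ("min_rel_sum", 0, 1),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ConfigError(f"{name} must be in [{lo}, {hi}], got {v}")
        if self.evalue <= 0:
            raise ConfigError("evalue threshold must be positive")
        if not self.communities and not self.reads:
            raise ConfigError("config needs either communities to simulate or read files")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**d)
        except TypeError as e:
            raise ConfigError(str(e)) from e

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def default_demo_config(outdir: str, seed: int = 42) -> RunConfig:
    """A two-sample community emulating a wet- vs dry-fermenter comparison.

    Five shared reference genomes with log-spread abundances; the dominant
    methanogen sits close to its reference in the "dry" sample (2%
    divergence) and further away in the "wet" sample (8%), mirroring the
    situation fragment recruitment is designed to reveal. Sample depths
    differ so smallest-dataset normalization is exercised.
    """
    lineages = {
        "Methanoculleus_bourgensis": dict(
            zip(RANKS, ["Archaea", "Euryarchaeota", "Methanomicrobia",
                        "Methanomicrobiales", "Methanomicrobiaceae", "Methanoculleus"])
        ),
        "Clostridium_clariflavum": dict(
            zip(RANKS, ["Bacteria", "Firmicutes", "Clostridia",
                        "Clostridiales", "Clostridiaceae", "Clostridium"])
        ),
        "Clostridium_thermocellum": dict(
            zip(RANKS, ["Bacteria", "Firmicutes", "Clostridia",
                        "Clostridiales", "Clostridiaceae", "Clostridium"])
        ),
        "Treponema_sp": dict(
            zip(RANKS, ["Bacteria", "Spirochaetes", "Spirochaetia",
                        "Spirochaetales", "Spirochaetaceae", "Treponema"])
        ),
        "Bacteroides_sp": dict(
            zip(RANKS, ["Bacteria", "Bacteroidetes", "Bacteroidia",
                        "Bacteroidales", "Bacteroidaceae", "Bacteroides"])
        ),
    }
    genome_defs = [
        {"id": gid, "length": 40_000, "gc": gc, "lineage": lin}
        for (gid, lin), gc in zip(lineages.items(), (0.60, 0.40, 0.42, 0.45, 0.48))
    ]
    base = dict(
        genomes=genome_defs,
        read_length_mean=387.0,
        read_length_sd=40.0,
        duplicate_rate=0.1,
        gc_dup_coupling=2.0,
        # demo duplicates are same-template re-reads (byte copies) so the
        # prefix-cluster QC stage has something to find at nonzero divergence
        duplicate_fresh_errors=False,
    )
    communities = [
        dict(
            base,
            sample_id="wet",
            abundances=[0.10, 0.40, 0.25, 0.15, 0.10],
            divergences=[0.08, 0.03, 0.05, 0.05, 0.05],
            n_reads=4000,
            seed=seed,
        ),
        dict(
            base,
            sample_id="dry",
            abundances=[0.35, 0.30, 0.15, 0.05, 0.15],
            divergences=[0.02, 0.03, 0.05, 0.05, 0.05],
            n_reads=3000,
            seed=seed + 1,
        ),
    ]
    return RunConfig(outdir=outdir, seed=seed, communities=communities)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def truth_assignments(readset: ReadSet, genomes, evalue: float = 1e-9):
    """Perfect-classifier assignment records from simulation ground truth."""
    lineage_of = {g.id: g.taxon_lineage for g in genomes}
    records = []
    for read in readset:
        if read.truth_genome is None:
            continue
        for rank, taxon in lineage_of.get(read.truth_genome, {}).items():
            records.append(AssignmentRecord(read.id, rank, taxon, evalue))
    return records


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate → qc → profiles → recruitment and write a manifest.

    Returns the manifest dict (also written as ``manifest.json``). On
    failure, partially written outputs are removed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def out(name: str) -> Path:
        p = outdir / name
        written.append(p)
        return p

    try:
        return _run_pipeline(config, outdir, out)
    except Exception:
        for p in written:
            if p.exists():
                p.unlink()
        raise


def _run_pipeline(config: RunConfig, outdir: Path, out) -> dict:
    # ---- inputs: simulate or load -------------------------------------
    samples: dict[str, ReadSet] = {}
    genomes = []
    if config.communities:
        # one shared reference set for every community, seeded by the run
        genomes = genomes_from_defs(config.communities[0]["genomes"], config.seed)
        for cdict in config.communities:
            spec = spec_from_dict(dict(cdict), genomes=genomes)
            readset = simulate_reads(spec)
            samples[spec.sample_id] = readset
            logger.info("simulated %s: %d reads (seed %d)", spec.sample_id, len(readset), spec.seed)
            mio.write_fasta(readset, out(f"{spec.sample_id}.reads.fasta"))
            mio.write_truth_tsv(readset, out(f"{spec.sample_id}.truth.tsv"))
        mio.write_genomes_fasta(genomes, out("references.fasta"))
        mio.write_taxonomy_tsv(genomes, out("references.taxonomy.tsv"))
    for sample_id, path in config.reads.items():
        if not os.path.exists(path):
            raise FileNotFoundError(f"read file for sample {sample_id!r} not found: {path}")
        samples[sample_id] = mio.read_reads(path, sample_id)
    if not samples:
        raise ConfigError("no samples to process")

    totals = config.totals or [len(rs) for rs in samples.values()]
    if any(t <= 0 for t in totals):
        # an empty run still produces a manifest with zeroed reports
        totals = [max(t, 1) for t in totals]

    # ---- qc -----------------------------------------------------------
    filtered: dict[str, ReadSet] = {}
    for sample_id, readset in samples.items():
        clean, report = run_qc(
            readset,
            prefix_len=config.qc_prefix_len,
            length_tolerance=config.qc_length_tolerance,
            z_cutoff=config.qc_gc_z,
        )
        filtered[sample_id] = clean
        write_report_tsv(report, out(f"{sample_id}.qc.tsv"))
        mio.write_fasta(clean, out(f"{sample_id}.filtered.fasta"))

    # ---- profiles -----------------------------------------------------
    profiles = {}
    assignments = {}
    if genomes:
        lineages = {
            g.taxon_lineage[config.rank]: tuple(
                g.taxon_lineage[r] for r in RANKS if r in g.taxon_lineage
            )
            for g in genomes
            if config.rank in g.taxon_lineage
        }
        for sample_id, clean in filtered.items():
            records = filter_by_evalue(truth_assignments(clean, genomes), config.evalue)
            assignments[sample_id] = records
            write_assignments_tsv(records, out(f"{sample_id}.assignments.tsv"))
            profile = build_profile(records, config.rank, len(clean), sample_id)
            profiles[sample_id] = profile
            write_profile_tsv(profile, out(f"{sample_id}.profile.{config.rank}.tsv"))
            write_krona_tsv(profile, lineages, out(f"{sample_id}.krona.tsv"))

        if len(profiles) >= 2:
            ids = list(profiles)
            normed = normalize_to_smallest([profiles[i] for i in ids])
            pts = scatter_points(
                normed[0], normed[1], config.pseudocount, config.min_rel_sum
            )
            write_scatter_tsv(pts, out(f"scatter.{ids[0]}_vs_{ids[1]}.tsv"))
            ua, ub = unique_egts(normed[0], normed[1], config.unique_min)
            with open(out("unique_egts.tsv"), "w") as fh:
                fh.write("sample\ttaxon\n")
                for t in sorted(ua):
                    fh.write(f"{ids[0]}\t{t}\n")
                for t in sorted(ub):
                    fh.write(f"{ids[1]}\t{t}\n")

        for sample_id, records in assignments.items():
            at_rank = [r for r in records if r.rank == config.rank]
            if not at_rank:
                continue
            depths = config.rarefaction_depths or default_depths(len(at_rank))
            curve = rarefy(
                at_rank,
                config.rank,
                depths,
                reps=config.rarefaction_reps,
                seed=config.seed,
            )
            curve.to_frame().to_csv(
                out(f"{sample_id}.rarefaction.{config.rank}.tsv"), sep="\t", index=False
            )

    # ---- recruitment --------------------------------------------------
    if genomes:
        indexes = [GenomeIndex(g, config.aligner_k) for g in genomes]
        for sample_id, clean in filtered.items():
            hits = align_reads(clean, genomes, k=config.aligner_k, indexes=indexes)
            hits = filter_hits(hits, config.identity_floor)
            hits = best_hit_per_read(hits, scope="per-genome")
            ranking = summarize(hits, totals, high=config.identity_high)
            write_ranking_tsv(ranking, out(f"{sample_id}.recruitment.tsv"))
            pts = recruitment_points(hits)
            write_points_tsv(pts, out(f"{sample_id}.recruitment_points.tsv"))
            hist = histogram(hits, totals, sample_total=len(samples[sample_id]), sample_id=sample_id)
            hist.to_frame().to_csv(out(f"{sample_id}.histogram.tsv"), sep="\t", index=False)
            if config.plots:
                from .plotting import recruitment_panels

                top = ranking[0].genome_id if ranking else None
                panel_pts = [p for p in pts if p.genome_id == top]
                recruitment_panels(
                    panel_pts, hist, genome_label=top or "reference",
                    path=out(f"{sample_id}.recruitment.png"),
                )

    # ---- manifest -----------------------------------------------------
    manifest = {
        "tool": "metacompare",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "outputs": {},
    }
    for p in sorted(outdir.iterdir()):
        if p.name == "manifest.json" or not p.is_file():
            continue
        manifest["outputs"][p.name] = _sha256(p)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
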