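"""Seeded synthetic single-cell genome communities.

The generator emulates the statistical structure the downstream analyses
assume, so the whole pipeline is testable without any sequence downloads:

* two habitats (water column "lake" and "sediment" by default), each with a
  configurable number of genomes;
* planted metabolic guilds: a guild's carrier genomes encode every gene the
  calling rules require for each member pathway, while non-carriers pick up
  individual pathways at a low background rate;
* per-genome completeness drawn from a Beta distribution reparameterised by
  mean (0.387 by default, the typical completeness of single-cell
  assemblies in this setting) and a dispersion parameter;
* capture by the same contiguous-window mechanism as the artificial genome
  reduction (an i.i.d. gene-dropout mode is available for null
  comparisons), so the simulator and the bias assessment share one model;
* contamination simulated by injecting genes from a different genus at a
  small configurable rate (0.4% mean), giving the <5% ingest screen
  something to exercise;
* genus labels from a log-series abundance model, so richness estimators
  see realistic singleton/doubleton counts.

Every run is a pure function of (config, catalog): the same seed yields
byte-identical output files.  The emitted truth table (full pre-capture KO
inventory, true pathway presence, guild membership, genus) enables
parameter-recovery tests.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import PathwayCatalog
from .errors import ConfigError
from .io import NO_KO, SagRecord, write_gff3
from .reduction import Contig, ContigGenome, Gene, ReferencePair, reduce_genome

__all__ = ["GuildSpec", "CommunityConfig", "GenomeTruth", "TruthTable",
           "CommunityResult", "generate_complete_genomes", "draw_completeness",
           "apply_capture", "simulate_community", "write_community"]


@dataclass(frozen=True)
class GuildSpec:
    """A planted set of co-occurring pathways.

    ``carrier_fraction`` of the genomes in each applicable habitat carry the
    whole guild; outside carriers each member pathway occurs independently
    with probability ``background_fraction``.
    """

    guild_id: str
    member_pathways: tuple[str, ...]
    carrier_fraction: float = 0.4
    background_fraction: float = 0.05
    habitats: tuple[str, ...] | None = None   # None = all habitats

    def __post_init__(self) -> None:
        if not (0.0 <= self.background_fraction < self.carrier_fraction <= 1.0):
            raise ConfigError(
                f"guild {self.guild_id!r}: need background < carrier "
                f"fraction in [0, 1]"
            )
        if not self.member_pathways:
            raise ConfigError(f"guild {self.guild_id!r} has no member pathways")


DEFAULT_GUILDS = (
    GuildSpec(
        "organotroph",
        ("emp_glycolysis", "tca_cycle", "beta_oxidation", "cyt_aa3",
         "nar_nitrate_reduction", "co_oxidation"),
        carrier_fraction=0.45,
    ),
    GuildSpec(
        "lithotroph",
        ("cbb_cycle", "cyt_cbb3", "sox_complex", "rdsr", "sulfide_oxidation"),
        carrier_fraction=0.25,
    ),
)


@dataclass(frozen=True)
class CommunityConfig:
    """Knobs of the synthetic community.

    Fractions are in (0, 1]; intervals are inclusive and non-empty.  A fixed
    seed makes every derived artefact reproducible byte for byte.
    """

    n_genomes_per_habitat: int = 40
    habitats: tuple[str, ...] = ("lake", "sediment")
    mean_completeness: float = 0.387
    completeness_dispersion: float = 4.0
    contamination_rate: float = 0.004
    n_contigs_range: tuple[int, int] = (4, 10)
    genes_per_contig_range: tuple[int, int] = (12, 30)
    guilds: tuple[GuildSpec, ...] = DEFAULT_GUILDS
    background_carriage: float = 0.05
    multi_copy_fraction: float = 0.1
    unannotated_fraction: float = 0.1
    operon_pathways: tuple[str, ...] = ()
    genus_logseries_p: float = 0.9
    habitat_genus_exclusivity: float = 0.5   # fraction drawn from a
                                             # habitat-private genus pool
    capture_mode: str = "window"         # "window" | "iid"
    min_completeness_draw: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes_per_habitat < 1 or not self.habitats:
            raise ConfigError("need at least one genome in one habitat")
        if not (0.0 < self.mean_completeness <= 1.0):
            raise ConfigError("mean_completeness must lie in (0, 1]")
        if self.completeness_dispersion <= 0:
            raise ConfigError("completeness_dispersion must be positive")
        if not (0.0 <= self.contamination_rate < 1.0):
            raise ConfigError("contamination_rate must lie in [0, 1)")
        for name in ("n_contigs_range", "genes_per_contig_range"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ConfigError(f"{name} must be a non-empty interval")
        if self.capture_mode not in ("window", "iid"):
            raise ConfigError(f"unknown capture_mode {self.capture_mode!r}")

    def validate_against(self, catalog: PathwayCatalog) -> None:
        for guild in self.guilds:
            for pid in guild.member_pathways:
                if pid not in catalog:
                    raise ConfigError(
                        f"guild {guild.guild_id!r} references unknown "
                        f"pathway id {pid!r}"
                    )


@dataclass(frozen=True)
class GenomeTruth:
    genome_id: str
    genus: str
    habitat: str
    guilds: tuple[str, ...]
    pathways: Mapping[str, bool]
    inventory: Mapping[str, int]        # full pre-capture KO copy counts


@dataclass(frozen=True)
class TruthTable:
    genomes: Mapping[str, GenomeTruth]

    def prevalence(self, pathway_id: str, habitat: str | None = None) -> float:
        """Fraction of (habitat) genomes truly carrying the pathway."""
        pool = [
            g for g in self.genomes.values()
            if habitat is None or g.habitat == habitat
        ]
        if not pool:
            raise ValueError(f"no genomes for habitat {habitat!r}")
        return float(np.mean([g.pathways.get(pathway_id, False) for g in pool]))

    def to_json(self) -> dict:
        return {
            gid: {
                "genus": t.genus,
                "habitat": t.habitat,
                "guilds": list(t.guilds),
                "pathways": {k: bool(v) for k, v in sorted(t.pathways.items())},
                "inventory": {k: int(v) for k, v in sorted(t.inventory.items())},
            }
            for gid, t in sorted(self.genomes.items())
        }


def _required_kos(pathway, rng: np.random.Generator) -> list[str]:
    """Genes guaranteeing a positive call, per the calling rules."""
    if pathway.kind == "single_step":
        gene_set = pathway.gene_sets[int(rng.integers(len(pathway.gene_sets)))]
        return [s for s in gene_set if s not in pathway.accessory]
    kos = list(pathway.key_enzymes)
    for step in pathway.steps:
        kos.append(step[int(rng.integers(len(step)))])
    return list(dict.fromkeys(kos))


def _filler_ko(genus: str, j: int) -> str:
    # synthetic filler orthologs, disjoint from every catalog symbol and
    # (generically) distinct between genera, so injected contamination is
    # recognisably foreign
    pool = zlib.crc32(genus.encode()) % 997
    return f"KZ{pool:03d}{j:04d}"


def generate_complete_genomes(
    config: CommunityConfig,
    catalog: PathwayCatalog,
    rng: np.random.Generator | None = None,
) -> tuple[TruthTable, dict[str, ContigGenome]]:
    """Generate the complete (pre-capture) genomes and their truth table."""
    if len(catalog) == 0:
        raise ConfigError("catalog is empty")
    config.validate_against(catalog)
    rng = rng if rng is not None else np.random.default_rng(config.seed)

    pathway_ids = list(catalog.ids)
    background = {pid: config.background_carriage for pid in pathway_ids}
    for guild in config.guilds:
        for pid in guild.member_pathways:
            background[pid] = guild.background_fraction

    truths: dict[str, GenomeTruth] = {}
    genomes: dict[str, ContigGenome] = {}
    for habitat in config.habitats:
        for i in range(config.n_genomes_per_habitat):
            gid = f"{habitat}_sag_{i:04d}"
            genus_idx = int(rng.logseries(config.genus_logseries_p))
            # habitats host partially exclusive genus pools, mirroring the
            # distinct water-column vs sediment taxonomic composition
            if rng.random() < config.habitat_genus_exclusivity:
                genus = f"genus_{habitat}_{genus_idx:03d}"
            else:
                genus = f"genus_shared_{genus_idx:03d}"

            member_guilds = tuple(
                g.guild_id for g in config.guilds
                if (g.habitats is None or habitat in g.habitats)
                and rng.random() < g.carrier_fraction
            )
            guild_pathways = {
                pid
                for g in config.guilds if g.guild_id in member_guilds
                for pid in g.member_pathways
            }
            pathway_truth = {
                pid: (pid in guild_pathways or rng.random() < background[pid])
                for pid in pathway_ids
            }

            planted: dict[str, int] = {}
            placement: dict[str, list[str]] = {}   # pathway -> its KO run
            multi_copy = rng.random() < config.multi_copy_fraction
            for pid in pathway_ids:
                if not pathway_truth[pid]:
                    continue
                kos = _required_kos(catalog[pid], rng)
                placement[pid] = kos
                for ko in kos:
                    planted[ko] = max(planted.get(ko, 0), 2 if multi_copy else 1)

            n_contigs = int(rng.integers(config.n_contigs_range[0],
                                         config.n_contigs_range[1] + 1))
            sizes = rng.integers(config.genes_per_contig_range[0],
                                 config.genes_per_contig_range[1] + 1,
                                 size=n_contigs).tolist()
            n_planted_slots = sum(planted.values())
            while sum(sizes) < n_planted_slots + n_contigs:
                sizes.append(int(rng.integers(
                    config.genes_per_contig_range[0],
                    config.genes_per_contig_range[1] + 1)))

            kos_by_contig = _place_genes(
                sizes, planted, placement,
                set(config.operon_pathways), config, genus, rng,
            )

            contigs = []
            inventory: dict[str, int] = {}
            gene_no = 0
            for ci, contig_kos in enumerate(kos_by_contig):
                genes = []
                for pos, ko in enumerate(contig_kos):
                    gene_no += 1
                    start = pos * 1000 + 1
                    genes.append(Gene(
                        gene_id=f"{gid}_g{gene_no:05d}",
                        ko=ko,
                        start=start,
                        end=start + 899,
                        strand="+" if rng.random() < 0.5 else "-",
                    ))
                    if ko is not None:
                        inventory[ko] = inventory.get(ko, 0) + 1
                contigs.append(Contig(f"{gid}_c{ci:03d}", tuple(genes)))

            genomes[gid] = ContigGenome(gid, tuple(contigs))
            truths[gid] = GenomeTruth(gid, genus, habitat, member_guilds,
                                      pathway_truth, inventory)
    return TruthTable(truths), genomes


def _place_genes(
    sizes: Sequence[int],
    planted: Mapping[str, int],
    placement: Mapping[str, Sequence[str]],
    operon_pathways: set[str],
    config: CommunityConfig,
    genus: str,
    rng: np.random.Generator,
) -> list[list[str | None]]:
    """Distribute planted, filler and unannotated genes over contig slots.

    Operon pathways occupy consecutive slots on a single contig; all other
    planted copies land on uniformly random free slots (dispersed).
    """
    slots: list[list[str | None]] = [[None] * s for s in sizes]
    free = [(ci, pos) for ci, s in enumerate(sizes) for pos in range(s)]
    used: set[tuple[int, int]] = set()

    remaining = {ko: n for ko, n in planted.items()}
    for pid in sorted(placement):
        if pid not in operon_pathways:
            continue
        run = [ko for ko in placement[pid] if remaining.get(ko, 0) > 0]
        copies = max((planted[ko] for ko in run), default=1)
        run = run * copies
        candidates = [
            (ci, start)
            for ci, s in enumerate(sizes) if s >= len(run)
            for start in range(s - len(run) + 1)
            if all((ci, start + j) not in used for j in range(len(run)))
        ]
        if not candidates:
            continue          # fall back to dispersed placement below
        ci, start = candidates[int(rng.integers(len(candidates)))]
        for j, ko in enumerate(run):
            slots[ci][start + j] = ko
            used.add((ci, start + j))
            remaining[ko] = max(0, remaining[ko] - 1)

    flat = [ko for ko, n in sorted(remaining.items()) for _ in range(n)]
    open_slots = [fs for fs in free if fs not in used]
    order = rng.permutation(len(open_slots))
    if len(flat) > len(open_slots):
        raise ConfigError("not enough gene slots for the planted pathways")
    for ko, oi in zip(flat, order):
        ci, pos = open_slots[int(oi)]
        slots[ci][pos] = ko
        used.add((ci, pos))

    filler_no = 0
    for ci, contig in enumerate(slots):
        for pos, ko in enumerate(contig):
            if ko is not None:
                continue
            if rng.random() < config.unannotated_fraction:
                continue                      # stays unannotated
            filler_no += 1
            slots[ci][pos] = _filler_ko(genus, filler_no)
    return slots


def draw_completeness(config: CommunityConfig, n: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Beta(m*nu, (1-m)*nu) completeness draws, floored away from zero."""
    m, nu = config.mean_completeness, config.completeness_dispersion
    draws = rng.beta(m * nu, (1.0 - m) * nu, size=n)
    return np.clip(draws, config.min_completeness_draw, 1.0)


@dataclass
class CommunityResult:
    config: CommunityConfig
    truth: TruthTable
    complete_genomes: dict[str, ContigGenome]
    captured_genomes: dict[str, ContigGenome]
    records: dict[str, SagRecord]
    annotations: pd.DataFrame
    quality: pd.DataFrame
    metadata: pd.DataFrame


_HABITAT_TEXT = {
    "lake": ("water column of an Antarctic subglacial lake, filtered "
             "lake water"),
    "sediment": ("surficial sediment core from a subglacial lake beneath "
                 "the ice sheet"),
}


def apply_capture(
    genomes: Mapping[str, ContigGenome],
    completeness: Mapping[str, float],
    truth: TruthTable,
    config: CommunityConfig,
    rng: np.random.Generator,
) -> tuple[dict[str, ContigGenome], dict[str, SagRecord], pd.DataFrame]:
    """Capture partial genomes at the drawn completeness values.

    The default "window" mode reuses the contiguous-window reduction
    mechanism (so the generator and the bias assessment share one capture
    model); "iid" drops each gene independently.  Contamination injects
    foreign-genus filler genes on a separate contig at the per-genome drawn
    rate.  Returns (captured genomes incl. contaminant contigs, quality
    records, annotation table).
    """
    captured: dict[str, ContigGenome] = {}
    records: dict[str, SagRecord] = {}
    rows: list[tuple] = []
    for gid in sorted(genomes):
        genome = genomes[gid]
        c = float(completeness[gid])
        if not (0.0 < c <= 1.0):
            raise ConfigError(f"completeness draw for {gid} outside (0, 1]")
        if config.capture_mode == "window":
            part = reduce_genome(ReferencePair(genome, c, 1.0), rng)
        else:
            kept_contigs = []
            for contig in genome.contigs:
                keep = [g for g in contig.genes if rng.random() < c]
                kept_contigs.append(Contig(contig.contig_id, tuple(keep)))
            part = ContigGenome(gid, tuple(kept_contigs))

        contam = float(min(rng.exponential(config.contamination_rate), 0.049)) \
            if config.contamination_rate > 0 else 0.0
        n_contam = round(contam * part.n_genes)
        if n_contam > 0:
            my_genus = truth.genomes[gid].genus
            others = sorted({t.genus for t in truth.genomes.values()}
                            - {my_genus})
            donor = others[int(rng.integers(len(others)))] if others else my_genus
            genes = tuple(
                Gene(f"{gid}_x{j:03d}", _filler_ko(donor, 9000 + j),
                     j * 1000 + 1, j * 1000 + 900, "+")
                for j in range(n_contam)
            )
            part = ContigGenome(gid, part.contigs + (
                Contig(f"{gid}_contam", genes),))

        captured[gid] = part
        lengths = {
            ctg.contig_id: max((g.end for g in ctg.genes), default=1000)
            for ctg in part.contigs
        }
        records[gid] = SagRecord(
            genome_id=gid,
            habitat=truth.genomes[gid].habitat,
            completeness=c,
            contamination=contam,
            assembly_size=max(1, sum(lengths.values())),
            contig_lengths=lengths,
        )
        for ctg in part.contigs:
            for g in ctg.genes:
                rows.append((gid, ctg.contig_id, g.gene_id, g.start, g.end,
                             g.strand, g.ko if g.ko else NO_KO))
    annotations = pd.DataFrame(
        rows, columns=["genome_id", "contig_id", "gene_id", "start", "end",
                       "strand", "ko_id"],
    )
    return captured, records, annotations


def simulate_community(
    config: CommunityConfig,
    catalog: PathwayCatalog,
) -> CommunityResult:
    """Run the full generator: complete genomes, capture, tables."""
    rng = np.random.default_rng(config.seed)
    truth, complete = generate_complete_genomes(config, catalog, rng)
    gids = sorted(complete)
    draws = draw_completeness(config, len(gids), rng)
    completeness = dict(zip(gids, draws))
    captured, records, annotations = apply_capture(
        complete, completeness, truth, config, rng)

    quality = pd.DataFrame(
        {
            "genome_id": gids,
            "completeness_pct": [round(100 * records[g].completeness, 4)
                                 for g in gids],
            "contamination_pct": [round(100 * records[g].contamination, 4)
                                  for g in gids],
            "assembly_bp": [records[g].assembly_size for g in gids],
            "habitat": [records[g].habitat for g in gids],
        }
    )
    metadata = pd.DataFrame(
        {
            "genome_id": gids,
            "source_description": [
                _HABITAT_TEXT.get(records[g].habitat,
                                  "environmental genome, source unspecified")
                for g in gids
            ],
        }
    )
    return CommunityResult(config, truth, complete, captured, records,
                           annotations, quality, metadata)


def write_community(result: CommunityResult, outdir: str | Path) -> None:
    """Write the community as plain-text artefacts (TSV, GFF3, JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.annotations.to_csv(outdir / "annotations.tsv", sep="\t",
                              index=False)
    result.quality.to_csv(outdir / "quality.tsv", sep="\t", index=False)
    result.metadata.to_csv(outdir / "metadata.tsv", sep="\t", index=False)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(result.truth.to_json(), fh, indent=1, sort_keys=True)
    gff_dir = outdir / "gff"
    gff_dir.mkdir(exist_ok=True)
    for gid in sorted(result.captured_genomes):
        write_gff3(result.captured_genomes[gid],
                   gff_dir / f"{gid}.gff3",
                   result.records[gid].contig_lengths)
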