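"""Readers and writers for annotation, quality, pairs and GFF3 tables.

The interchange formats are deliberately plain:

* annotations TSV: genome_id, contig_id, gene_id, start, end, strand, ko_id
  (empty/"-" ko_id marks an unannotated gene);
* quality TSV (CheckM-style): genome_id, completeness_pct,
  contamination_pct, assembly_bp and optionally a habitat column;
* per-genome GFF3 with gene features carrying ``ID`` and ``ko`` attributes
  (consumed by the reduction simulator);
* pairs TSV: reference_id, target_completeness, reference_completeness.

Genomes at or above 5% estimated contamination are excluded on ingest,
mirroring the CheckM quality screen applied to single-cell assemblies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import gffutils
import pandas as pd

from .errors import IngestError
from .reduction import Contig, ContigGenome, Gene, ReferencePair

logger = logging.getLogger(__name__)

__all__ = ["SagRecord", "IngestResult", "load_annotations", "write_gff3",
           "read_gff3", "load_pairs", "MAX_CONTAMINATION"]

ANNOTATION_COLUMNS = ("genome_id", "contig_id", "gene_id", "start", "end",
                      "strand", "ko_id")
MAX_CONTAMINATION = 0.05
NO_KO = "-"


@dataclass(frozen=True)
class SagRecord:
    """Quality and provenance summary for one single-cell genome."""

    genome_id: str
    habitat: str
    completeness: float          # fraction in (0, 1]
    contamination: float         # fraction, < MAX_CONTAMINATION after ingest
    assembly_size: int
    contig_lengths: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.completeness <= 1.0):
            raise IngestError(
                f"{self.genome_id}: completeness must lie in (0, 1], got "
                f"{self.completeness}"
            )
        if self.contamination < 0:
            raise IngestError(f"{self.genome_id}: negative contamination")
        if self.assembly_size <= 0:
            raise IngestError(f"{self.genome_id}: non-positive assembly size")


@dataclass
class IngestResult:
    records: dict[str, SagRecord]
    annotations: pd.DataFrame
    excluded: list[str]


def _read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


def load_annotations(
    annotations_tsv: str | Path,
    quality_tsv: str | Path,
    max_contamination: float = MAX_CONTAMINATION,
) -> IngestResult:
    """Load and screen per-gene annotations with their quality table.

    Genomes with contamination >= ``max_contamination`` are dropped (the
    exclusion is logged and reported); completeness is stored as a fraction.
    A genome present in the annotations but absent from the quality table is
    an ingest error; malformed coordinates raise with the offending line
    number.
    """
    quality = _read_tsv(quality_tsv)
    if quality.empty:
        raise IngestError(f"quality table {quality_tsv} is empty")
    required = {"genome_id", "completeness_pct", "contamination_pct",
                "assembly_bp"}
    missing_cols = required - set(quality.columns)
    if missing_cols:
        raise IngestError(f"quality table lacks columns {sorted(missing_cols)}")

    ann = _read_tsv(annotations_tsv)
    if ann.empty:
        ann = pd.DataFrame(columns=list(ANNOTATION_COLUMNS))
    missing_cols = set(ANNOTATION_COLUMNS) - set(ann.columns)
    if missing_cols:
        raise IngestError(f"annotations lack columns {sorted(missing_cols)}")

    known = set(quality["genome_id"])
    orphans = sorted(set(ann["genome_id"]) - known)
    if orphans:
        raise IngestError(f"no quality row for genome(s) {orphans[:5]}")

    for col in ("start", "end"):
        try:
            ann[col] = ann[col].astype(int)
        except (TypeError, ValueError):
            bad = ann.index[pd.to_numeric(ann[col], errors="coerce").isna()][0]
            raise IngestError(
                f"malformed {col} at line {int(bad) + 2} of {annotations_tsv}"
            ) from None
    bad = ann.index[(ann["start"] > ann["end"]) | (ann["start"] < 1)]
    if len(bad):
        raise IngestError(
            f"invalid coordinates at line {int(bad[0]) + 2} of "
            f"{annotations_tsv}"
        )
    if ann.duplicated(subset=["genome_id", "gene_id"]).any():
        raise IngestError("duplicate (genome_id, gene_id) in annotations")

    records: dict[str, SagRecord] = {}
    excluded: list[str] = []
    contig_len = (
        ann.groupby(["genome_id", "contig_id"])["end"].max().to_dict()
        if len(ann) else {}
    )
    for row in quality.itertuples(index=False):
        completeness = float(row.completeness_pct) / 100.0
        contamination = float(row.contamination_pct) / 100.0
        if contamination >= max_contamination:
            excluded.append(row.genome_id)
            continue
        lengths = {
            cid: int(end)
            for (gid, cid), end in contig_len.items()
            if gid == row.genome_id
        }
        records[row.genome_id] = SagRecord(
            genome_id=row.genome_id,
            habitat=str(getattr(row, "habitat", "other")),
            completeness=completeness,
            contamination=contamination,
            assembly_size=int(float(row.assembly_bp)),
            contig_lengths=lengths,
        )
    if excluded:
        logger.info("excluded %d genome(s) at >= %.0f%% contamination: %s",
                    len(excluded), 100 * max_contamination, excluded)
    ann = ann[ann["genome_id"].isin(records)].reset_index(drop=True)
    ann["ko_id"] = ann["ko_id"].fillna(NO_KO)
    return IngestResult(records=records, annotations=ann, excluded=excluded)


def annotations_to_genomes(annotations: pd.DataFrame) -> dict[str, ContigGenome]:
    """Group an annotation table into ordered per-genome contig structures."""
    genomes: dict[str, ContigGenome] = {}
    if annotations.empty:
        return genomes
    for gid, sub in annotations.groupby("genome_id", sort=True):
        contigs = []
        for cid, genes in sub.groupby("contig_id", sort=True):
            genes = genes.sort_values("start")
            contigs.append(Contig(str(cid), tuple(
                Gene(str(r.gene_id),
                     None if r.ko_id in (NO_KO, "", None) else str(r.ko_id),
                     int(r.start), int(r.end), str(r.strand))
                for r in genes.itertuples(index=False)
            )))
        genomes[str(gid)] = ContigGenome(str(gid), tuple(contigs))
    return genomes


def write_gff3(genome: ContigGenome, path: str | Path,
               contig_lengths: Mapping[str, int] | None = None) -> None:
    """Write one genome as GFF3 with gene features (ID and ko attributes)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for contig in genome.contigs:
            length = (contig_lengths or {}).get(
                contig.contig_id,
                max((g.end for g in contig.genes), default=0),
            )
            fh.write(f"##sequence-region {contig.contig_id} 1 {length}\n")
        for contig in genome.contigs:
            for gene in contig.genes:
                attrs = f"ID={gene.gene_id}"
                if gene.ko:
                    attrs += f";ko={gene.ko}"
                fh.write(
                    "\t".join(
                        (contig.contig_id, "sagmetab", "gene",
                         str(gene.start), str(gene.end), ".", gene.strand,
                         ".", attrs)
                    ) + "\n"
                )


def read_gff3(path: str | Path, genome_id: str | None = None) -> ContigGenome:
    """Read a per-genome GFF3 back into an ordered contig structure.

    Contigs follow the ``##sequence-region`` pragma order when present,
    otherwise sorted seqid order; genes are ordered by start coordinate.
    """
    path = Path(path)
    try:
        db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                                keep_order=True,
                                merge_strategy="create_unique")
    except Exception as exc:
        raise IngestError(f"cannot parse GFF3 {path}: {exc}") from exc
    contig_order: list[str] = []
    for directive in db.directives:
        parts = directive.split()
        if parts and parts[0] == "sequence-region" and len(parts) >= 2:
            contig_order.append(parts[1])
    by_contig: dict[str, list[Gene]] = {}
    for feat in db.all_features(order_by=("seqid", "start")):
        if feat.featuretype not in ("gene", "CDS"):
            continue
        ko_vals = feat.attributes.get("ko", [])
        gene = Gene(
            gene_id=feat.id or f"{feat.seqid}:{feat.start}-{feat.end}",
            ko=ko_vals[0] if ko_vals else None,
            start=int(feat.start), end=int(feat.end),
            strand=feat.strand or "+",
        )
        by_contig.setdefault(feat.seqid, []).append(gene)
    if not contig_order:
        contig_order = sorted(by_contig)
    contigs = tuple(
        Contig(cid, tuple(sorted(by_contig.get(cid, ()),
                                 key=lambda g: g.start)))
        for cid in contig_order
    )
    return ContigGenome(genome_id or path.stem, contigs)


def load_pairs(pairs_tsv: str | Path, gff_dir: str | Path) -> list[ReferencePair]:
    """Load reference/target pairs, reading each reference genome's GFF3.

    Rows where the target completeness exceeds the reference completeness
    are excluded (logged), since the reduction cannot add genes.
    """
    table = _read_tsv(pairs_tsv)
    if table.empty:
        raise IngestError(f"pairs table {pairs_tsv} is empty")
    gff_dir = Path(gff_dir)
    pairs: list[ReferencePair] = []
    dropped = 0
    for row in table.itertuples(index=False):
        c_t = float(row.target_completeness)
        c_g = float(getattr(row, "reference_completeness", 1.0))
        if c_t > c_g:
            dropped += 1
            continue
        genome = read_gff3(gff_dir / f"{row.reference_id}.gff3",
                           str(row.reference_id))
        pairs.append(ReferencePair(genome, c_t, c_g))
    if dropped:
        logger.info("excluded %d pair(s) with target completeness above the "
                    "reference", dropped)
    return pairs
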