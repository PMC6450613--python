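"""Readers and writers for the external formats the pipeline touches:
FASTA (genome), GFF3 (gene annotation), VCF v4.2 (candidate call sets
and the designed manifest), and TSV (genotype matrices, filter reports,
manifest). Readers enforce the domain-type invariants at load rather
than coercing silently.
"""

from __future__ import annotations

import os
from typing import Iterable, Optional, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    MISSING,
    VALID_CODES,
    CandidateSNP,
    FamilyGenotypes,
    FilterReport,
    GeneAnnotation,
    GeneRecord,
    GenomeAssembly,
    GenotypeCallSet,
    InvalidInputError,
    MANIFEST_COLUMNS,
    PanelManifest,
    PopulationGenotypes,
)

# ---------------------------------------------------------------------------
# FASTA


def write_fasta(genome: GenomeAssembly, path: str) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.sequences.items()
    ]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str, contig_prefix: str = "contig") -> GenomeAssembly:
    """Load an assembly; sequences are uppercased, and names starting
    with ``contig_prefix`` are flagged as unplaced contigs."""
    sequences: dict[str, str] = {}
    is_chromosome: dict[str, bool] = {}
    for record in SeqIO.parse(path, "fasta"):
        sequences[record.id] = str(record.seq).upper()
        is_chromosome[record.id] = not record.id.startswith(contig_prefix)
    return GenomeAssembly(sequences=sequences, is_chromosome=is_chromosome)


# ---------------------------------------------------------------------------
# GFF3


def write_gff3(annotation: GeneAnnotation, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in annotation:
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{g.seq_name}\tsnparray\tgene\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )


def read_annotation(path: str, genome: Optional[GenomeAssembly] = None) -> GeneAnnotation:
    """Load gene records from GFF3 (via gffutils, in-memory db). Invalid
    coordinates raise with the offending record named."""
    import gffutils

    db = gffutils.create_db(
        path, ":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    records = []
    for feature in db.features_of_type("gene"):
        gene_id = feature.attributes.get("ID", [feature.id])[0]
        if feature.end < feature.start:
            raise InvalidInputError(f"gene {gene_id}: end < start")
        if genome is not None:
            length = genome.lengths.get(feature.seqid)
            if length is None or feature.end > length:
                raise InvalidInputError(
                    f"gene {gene_id}: interval outside sequence {feature.seqid}"
                )
        records.append(
            GeneRecord(gene_id, feature.seqid, feature.start, feature.end,
                       feature.strand or "+")
        )
    return GeneAnnotation(records=records)


# ---------------------------------------------------------------------------
# VCF

_INFO_FIELDS = [
    ("SOURCE", "1", "String", "Discovery platform"),
    ("AF", "A", "Float", "Estimated alternate allele frequency"),
    ("DP", "1", "Integer", "Read depth"),
    ("GQ", "1", "Float", "Genotype quality"),
    ("MQ", "1", "Float", "RMS mapping quality"),
    ("LFLANK", "1", "String", "Left flanking sequence"),
    ("RFLANK", "1", "String", "Right flanking sequence"),
    ("PROBE", "1", "String", "Submission probe, variant in brackets"),
    ("TIER", "1", "Integer", "Design tier"),
]


def _vcf_header(genome: Optional[GenomeAssembly]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    if genome is not None:
        for name, length in genome.lengths.items():
            header.contigs.add(name, length=length)
    for name, number, vtype, desc in _INFO_FIELDS:
        header.info.add(name, number, vtype, desc)
    return header


def write_vcf(
    candidates: Iterable[CandidateSNP],
    path: str,
    genome: Optional[GenomeAssembly] = None,
    probes: Optional[dict[str, str]] = None,
) -> None:
    """Write candidates (or manifest rows, via ``manifest_to_candidates``)
    as a sites-only VCF; flanks and platform ride in INFO so the record
    round-trips."""
    candidates = list(candidates)
    header = _vcf_header(genome)
    if genome is None:
        for name in sorted({c.seq_name for c in candidates}):
            header.contigs.add(name)
    with pysam.VariantFile(path, "w", header=header) as out:
        for c in sorted(candidates, key=lambda c: (c.seq_name, c.pos, c.id)):
            rec = out.new_record(
                contig=c.seq_name,
                start=c.pos - 1,
                stop=c.pos,
                alleles=(c.ref, c.alt),
                id=c.id,
            )
            if c.qual is not None:
                rec.qual = float(c.qual)
            rec.info["SOURCE"] = c.platform
            if c.af is not None:
                rec.info["AF"] = (float(c.af),)
            if c.dp is not None:
                rec.info["DP"] = int(round(c.dp))
            for key, value in (("GQ", c.gq), ("MQ", c.mq)):
                if value is not None:
                    rec.info[key] = float(value)
            if c.left_flank:
                rec.info["LFLANK"] = c.left_flank
            if c.right_flank:
                rec.info["RFLANK"] = c.right_flank
            if probes and c.id in probes:
                rec.info["PROBE"] = probes[c.id]
            if c.tier is not None:
                rec.info["TIER"] = int(c.tier)
            out.write(rec)


def read_vcf(path: str, genome: Optional[GenomeAssembly] = None) -> list[CandidateSNP]:
    """Load candidates from VCF; positions are validated against the
    genome when one is supplied. Malformed records raise with their
    record number."""
    out: list[CandidateSNP] = []
    with pysam.VariantFile(path) as vcf:
        for i, rec in enumerate(vcf, start=1):
            try:
                if rec.alts is None or len(rec.alts) != 1:
                    raise InvalidInputError("expected exactly one ALT allele")
                if genome is not None:
                    length = genome.lengths.get(rec.chrom)
                    if length is None:
                        raise InvalidInputError(f"unknown sequence {rec.chrom}")
                    if rec.pos > length:
                        raise InvalidInputError(
                            f"POS {rec.pos} exceeds {rec.chrom} length {length}"
                        )
                info = rec.info
                present = set(info.keys())

                def opt(key, cast=float, default=None):
                    if key not in present:
                        return default
                    value = info[key]
                    if isinstance(value, tuple):
                        value = value[0]
                    return cast(value)

                out.append(
                    CandidateSNP(
                        id=rec.id or f"rec{i}",
                        platform=opt("SOURCE", str, "unknown"),
                        seq_name=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=rec.alts[0],
                        left_flank=opt("LFLANK", str, ""),
                        right_flank=opt("RFLANK", str, ""),
                        af=opt("AF"),
                        dp=opt("DP"),
                        qual=float(rec.qual) if rec.qual is not None else None,
                        gq=opt("GQ"),
                        mq=opt("MQ"),
                        tier=opt("TIER", int),
                    )
                )
            except (ValueError, InvalidInputError) as exc:
                raise InvalidInputError(f"{path}: record {i}: {exc}") from exc
    return out


def manifest_to_candidates(manifest: PanelManifest) -> list[CandidateSNP]:
    out = []
    for row in manifest.table.itertuples(index=False):
        out.append(
            CandidateSNP(
                id=row.marker_id,
                platform=row.platform,
                seq_name=row.seq_name,
                pos=int(row.pos),
                ref=row.ref,
                alt=row.alt,
                tier=int(row.tier),
            )
        )
    return out


def write_manifest_vcf(
    manifest: PanelManifest, path: str, genome: Optional[GenomeAssembly] = None
) -> None:
    probes = dict(zip(manifest.table["marker_id"], manifest.table["probe"]))
    write_vcf(manifest_to_candidates(manifest), path, genome=genome, probes=probes)


# ---------------------------------------------------------------------------
# Genotype TSVs (markers x samples; codes aa/ab/bb/--)


def _check_codes(df: pd.DataFrame, path: str) -> None:
    for marker, row in df.iterrows():
        bad = set(row) - VALID_CODES
        if bad:
            raise InvalidInputError(
                f"{path}: marker {marker}: invalid genotype codes {sorted(bad)}"
            )


def write_population_genotypes(pop: PopulationGenotypes, path: str) -> None:
    pop.genotypes.to_csv(path, sep="\t", index_label="marker")


def read_population_genotypes(path: str, group: str = "") -> PopulationGenotypes:
    df = pd.read_csv(path, sep="\t", index_col="marker", dtype=str)
    _check_codes(df, path)
    return PopulationGenotypes(group=group or os.path.basename(path), genotypes=df)


def write_family_genotypes(fam: FamilyGenotypes, path: str) -> None:
    """Family TSV: parent1/parent2 genotype columns, then progeny."""
    df = fam.progeny.copy()
    df.insert(0, "parent1", [fam.parents[m][0] for m in df.index])
    df.insert(1, "parent2", [fam.parents[m][1] for m in df.index])
    df.to_csv(path, sep="\t", index_label="marker")


def read_family_genotypes(path: str, family_id: str = "") -> FamilyGenotypes:
    df = pd.read_csv(path, sep="\t", index_col="marker", dtype=str)
    for col in ("parent1", "parent2"):
        if col not in df.columns:
            raise InvalidInputError(f"{path}: missing {col} column")
    _check_codes(df, path)
    parents = {
        m: (df.loc[m, "parent1"], df.loc[m, "parent2"]) for m in df.index
    }
    progeny = df.drop(columns=["parent1", "parent2"])
    return FamilyGenotypes(
        family_id=family_id or os.path.basename(path), parents=parents, progeny=progeny
    )


def write_callset(callset: GenotypeCallSet, calls_path: str, samples_path: str) -> None:
    callset.calls.to_csv(calls_path, sep="\t", index_label="marker")
    callset.samples.to_csv(samples_path, sep="\t", index_label="sample")


def read_callset(calls_path: str, samples_path: str, group: str = "") -> GenotypeCallSet:
    calls = pd.read_csv(calls_path, sep="\t", index_col="marker", dtype=str)
    _check_codes(calls, calls_path)
    samples = pd.read_csv(samples_path, sep="\t", index_col="sample")
    samples["sex"] = samples.get("sex", pd.Series(dtype=str)).fillna("")
    return GenotypeCallSet(
        group=group or os.path.basename(calls_path), samples=samples, calls=calls
    )


# ---------------------------------------------------------------------------
# Reports and manifest TSVs


def write_filter_report(report: FilterReport, path: str) -> None:
    table = report.table.copy()
    table.insert(0, "rule", report.rule)
    table.to_csv(path, sep="\t", index_label="marker")


def write_manifest_tsv(manifest: PanelManifest, path: str) -> None:
    manifest.table.to_csv(path, sep="\t", index=False)


def read_manifest_tsv(path: str) -> PanelManifest:
    table = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "seq_name": str})
    missing = set(MANIFEST_COLUMNS) - set(table.columns)
    if missing:
        raise InvalidInputError(f"{path}: manifest missing columns {sorted(missing)}")
    return PanelManifest(table=table)
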