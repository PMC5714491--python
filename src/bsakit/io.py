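"""Readers and writers for the standard formats the pipeline touches.

SNP profiles travel as VCF v4.2 (INFO fields DP = depth, AO = alt
observation count, AF = alt frequency; AO/DP are preferred and AF is
only a fallback), the reference as FASTA (wrapped at 60 columns,
normalized to upper case), gene models and repeat intervals as GFF3
(1-based inclusive coordinates), cohorts and reports as TSV.
"""

from __future__ import annotations

import os
from typing import Iterable

import gffutils
import pandas as pd
import pysam
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .bsa import CandidateReport, SnpProfile, SnpRecord
from .errors import ConfigError, FormatError
from .genome import GeneModel, GenomeModel

VCF_HEADER = """\
##fileformat=VCFv4.2
##source=bsakit
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">
##INFO=<ID=AO,Number=A,Type=Integer,Description="Alternate allele observation count">
##INFO=<ID=AF,Number=A,Type=Float,Description="Alternate allele frequency">
"""


def write_vcf(profile: SnpProfile, path: str, contigs: dict[str, int] | None = None):
    """Serialize a profile as uncompressed VCF v4.2, sorted by coordinate."""
    lines = [VCF_HEADER.rstrip("\n")]
    if contigs:
        for name, length in contigs.items():
            lines.append(f"##contig=<ID={name},length={length}>")
    else:
        for name in sorted({r.chromosome for r in profile}):
            lines.append(f"##contig=<ID={name}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for rec in sorted(profile, key=lambda r: (r.chromosome, r.position, r.alt)):
        info = f"DP={rec.depth};AO={rec.alt_count};AF={rec.frequency:.6g}"
        lines.append(
            f"{rec.chromosome}\t{rec.position}\t.\t{rec.ref}\t{rec.alt}"
            f"\t.\tPASS\t{info}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vcf(path: str, line_id: str | None = None) -> SnpProfile:
    """Read a VCF v4.2 into a profile.

    Requires INFO/DP plus either AO (preferred; frequency is recomputed
    as AO/DP) or AF.  Multi-allelic rows are split into biallelic
    records.  Malformed records are reported with their position in the
    file.
    """
    if line_id is None:
        line_id = os.path.splitext(os.path.basename(path))[0]
    profile = SnpProfile(line_id)
    with pysam.VariantFile(path) as vcf:
        for idx, rec in enumerate(vcf, start=1):
            where = f"{path}: record {idx} ({rec.chrom}:{rec.pos})"
            info = rec.info
            if "DP" not in info:
                raise FormatError(f"{where}: missing INFO/DP")
            depth = int(info["DP"])
            alts = rec.alts or ()
            if not alts:
                raise FormatError(f"{where}: no ALT allele")
            ao = info.get("AO")
            af = info.get("AF")
            for ai, alt in enumerate(alts):
                alt_count = None
                freq = None
                if ao is not None:
                    values = ao if isinstance(ao, tuple) else (ao,)
                    alt_count = int(values[ai])
                elif af is not None:
                    values = af if isinstance(af, tuple) else (af,)
                    freq = float(values[ai])
                    alt_count = round(freq * depth)
                else:
                    raise FormatError(f"{where}: need INFO/AO or INFO/AF")
                if alt_count > depth:
                    raise FormatError(
                        f"{where}: AO ({alt_count}) exceeds DP ({depth})"
                    )
                try:
                    profile.add(
                        SnpRecord(
                            rec.chrom, rec.pos, rec.ref, str(alt),
                            alt_count, depth, freq,
                        )
                    )
                except Exception as exc:
                    raise FormatError(f"{where}: {exc}") from exc
    return profile


def write_fasta(genome: GenomeModel, path: str) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.chromosomes
    ]
    SeqIO.write(records, path, "fasta")  # 60-column wrapping


def read_fasta(path: str) -> dict[str, str]:
    """Read FASTA sequences, normalized to upper case."""
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}
    if not seqs:
        raise FormatError(f"{path}: no FASTA records found")
    return seqs


def write_gff3(genome: GenomeModel, path: str) -> None:
    """Gene models (gene + CDS features) and repeat_region features."""
    lines = ["##gff-version 3"]
    for name, seq in genome.chromosomes:
        lines.append(f"##sequence-region {name} 1 {len(seq)}")
    for gene in genome.genes:
        lo, hi = gene.span
        attrs = f"ID={gene.id}"
        if gene.is_causal_gene:
            attrs += ";causal=true"
        lines.append(
            f"{gene.chromosome}\tbsakit\tgene\t{lo}\t{hi}\t.\t{gene.strand}\t.\t{attrs}"
        )
        for s, e in sorted(gene.cds_intervals):
            lines.append(
                f"{gene.chromosome}\tbsakit\tCDS\t{s}\t{e}\t.\t{gene.strand}\t.\t"
                f"ID={gene.id}.cds;Parent={gene.id}"
            )
    for i, (chrom, s, e) in enumerate(genome.repeats, start=1):
        lines.append(
            f"{chrom}\tbsakit\trepeat_region\t{s}\t{e}\t.\t.\t.\tID=repeat{i}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_gff3(
    path: str, chrom_lengths: dict[str, int] | None = None
) -> tuple[list[GeneModel], list[tuple[str, int, int]]]:
    """Parse gene models and repeat intervals from GFF3.

    When chromosome lengths are supplied (e.g. from the FASTA), any
    feature extending beyond its chromosome raises a consistency error.
    """
    db = gffutils.create_db(
        path, dbfn=":memory:", keep_order=True, merge_strategy="create_unique"
    )
    genes: list[GeneModel] = []
    repeats: list[tuple[str, int, int]] = []
    for feat in db.features_of_type("repeat_region"):
        repeats.append((feat.seqid, feat.start, feat.end))
    for gene_feat in db.features_of_type("gene"):
        cds = sorted(
            ((c.start, c.end) for c in db.children(gene_feat, featuretype="CDS")),
        )
        if not cds:
            raise FormatError(f"{path}: gene {gene_feat.id} has no CDS features")
        strand = gene_feat.strand
        if strand not in ("+", "-"):
            raise FormatError(f"{path}: gene {gene_feat.id} lacks a strand")
        if strand == "-":
            cds = cds[::-1]
        causal = gene_feat.attributes.get("causal", ["false"])[0].lower() == "true"
        model = GeneModel(
            id=gene_feat.id,
            chromosome=gene_feat.seqid,
            strand=strand,
            cds_intervals=tuple(cds),
            is_causal_gene=causal,
        )
        if chrom_lengths is not None:
            length = chrom_lengths.get(model.chromosome)
            if length is None:
                raise FormatError(
                    f"{path}: gene {model.id} on unknown chromosome "
                    f"{model.chromosome}"
                )
            if model.span[1] > length:
                raise FormatError(
                    f"{path}: gene {model.id} CDS exceeds chromosome "
                    f"{model.chromosome} length {length}"
                )
        genes.append(model)
    return genes, repeats


def write_genome(genome: GenomeModel, fasta_path: str, gff_path: str) -> None:
    write_fasta(genome, fasta_path)
    write_gff3(genome, gff_path)


def read_genome(fasta_path: str, gff_path: str) -> GenomeModel:
    seqs = read_fasta(fasta_path)
    lengths = {n: len(s) for n, s in seqs.items()}
    genes, repeats = read_gff3(gff_path, chrom_lengths=lengths)
    return GenomeModel(
        chromosomes=list(seqs.items()), genes=genes, repeats=repeats
    )


def write_cohort_tsv(cohort, path: str) -> None:
    """One row per F2 individual: causal genotype, phenotype, marker dosages."""
    rows = []
    for i, (genotype, markers, phenotype) in enumerate(cohort.individuals()):
        row = {"individual": i + 1, "genotype": genotype, "phenotype": phenotype}
        for (chrom, pos, _, _), dosage in zip(cohort.snps, markers):
            row[f"{chrom}:{pos}"] = int(dosage)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_report(report: CandidateReport, tsv_path: str, audit_path: str) -> None:
    report.to_frame().to_csv(tsv_path, sep="\t", index=False)
    with open(audit_path, "w") as fh:
        fh.write(report.audit_json() + "\n")


def write_peaks_tsv(peaks: Iterable[tuple[float, float]], path: str) -> None:
    pd.DataFrame(peaks, columns=["mz", "intensity"]).to_csv(
        path, sep="\t", index=False
    )


def read_peaks_tsv(path: str) -> list[float]:
    """Two-column peak list (m/z, intensity); the intensity column is optional."""
    df = pd.read_csv(path, sep="\t")
    if "mz" not in df.columns:
        if df.shape[1] < 1:
            raise FormatError(f"{path}: expected an m/z column")
        df.columns = ["mz"] + list(df.columns[1:])
    return [float(v) for v in df["mz"]]


def load_yaml_config(path: str, allowed_keys: set[str]) -> dict:
    """Load a YAML mapping, rejecting unknown top-level keys."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    unknown = set(data) - allowed_keys
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
    return data
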