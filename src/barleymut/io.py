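"""Reading and writing the standard formats the pipeline exchanges.

VCF v4.2 through pysam, FASTA through pyfaidx (reading) / plain text
(writing), BED 0-based half-open, GFF3 for gene models, and two-column
tab-separated genotyping-panel positions.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import pysam
from pyfaidx import Fasta

from .models import GeneModel, Genotype, RegionMask, SampleCall, Variant

_GT_TO_TUPLE = {
    Genotype.HOM_REF: (0, 0),
    Genotype.HET: (0, 1),
    Genotype.HOM_ALT: (1, 1),
    Genotype.MISSING: (None, None),
}


def _tuple_to_gt(gt: tuple) -> Genotype:
    alleles = [a for a in gt if a is not None]
    if not alleles:
        return Genotype.MISSING
    dosage = sum(1 for a in alleles if a != 0)
    if dosage == 0:
        return Genotype.HOM_REF
    return Genotype.HET if dosage == 1 else Genotype.HOM_ALT


def build_vcf_header(samples: Sequence[str], contigs: Mapping[str, int]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom, length in contigs.items():
        header.contigs.add(chrom, length=length)
    header.info.add("SUPPORT", 1, "Integer", "Supporting reads reported by the SV caller")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("GQ", 1, "Integer", "Genotype quality")
    header.formats.add("AB", 1, "Float", "Alt-allele read fraction for heterozygous calls")
    for s in samples:
        header.add_sample(s)
    return header


def write_vcf(
    path: str | os.PathLike,
    variants: Iterable[Variant],
    samples: Sequence[str],
    contigs: Mapping[str, int],
) -> None:
    """Write variants as uncompressed VCF v4.2, sorted by (chrom, pos)."""
    header = build_vcf_header(samples, contigs)
    order = {c: i for i, c in enumerate(contigs)}
    variants = sorted(variants, key=lambda v: (order.get(v.chrom, 1 << 30), v.pos, v.ref, v.alt))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in variants:
            rec = out.new_record(
                contig=v.chrom,
                start=v.pos - 1,
                stop=v.pos - 1 + len(v.ref),
                alleles=(v.ref, v.alt),
                qual=v.qual,
            )
            if v.support_reads is not None:
                rec.info["SUPPORT"] = v.support_reads
            for s in samples:
                call = v.calls.get(s, SampleCall(Genotype.MISSING))
                rec.samples[s]["GT"] = _GT_TO_TUPLE[call.gt]
                if call.dp is not None:
                    rec.samples[s]["DP"] = call.dp
                if call.gq is not None:
                    rec.samples[s]["GQ"] = call.gq
                if call.allele_balance is not None:
                    rec.samples[s]["AB"] = call.allele_balance
            out.write(rec)


def read_vcf(path: str | os.PathLike) -> list[Variant]:
    """Read a VCF into Variant records (first ALT allele only)."""
    out: list[Variant] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            calls = {}
            for s in samples:
                fmt = rec.samples[s]
                calls[s] = SampleCall(
                    gt=_tuple_to_gt(fmt.get("GT", (None, None))),
                    dp=fmt.get("DP"),
                    gq=fmt.get("GQ"),
                    allele_balance=fmt.get("AB"),
                )
            out.append(
                Variant(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0] if rec.alts else rec.ref,
                    qual=rec.qual,
                    calls=calls,
                    support_reads=rec.info.get("SUPPORT"),
                )
            )
    return out


def write_fasta(path: str | os.PathLike, sequences: Mapping[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    with Fasta(str(path)) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def write_bed(path: str | os.PathLike, mask: RegionMask, name: str | None = None) -> None:
    label = name if name is not None else mask.label
    with open(path, "w") as fh:
        for chrom, start, end in mask.intervals():
            fh.write(f"{chrom}\t{start}\t{end}\t{label}\n")


def read_bed(path: str | os.PathLike, label: str | None = None) -> RegionMask:
    intervals = []
    inferred = label
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            intervals.append((fields[0], int(fields[1]), int(fields[2])))
            if inferred is None and len(fields) > 3:
                inferred = fields[3]
    return RegionMask.from_intervals(inferred or "mask", intervals)


def read_panel_positions(path: str | os.PathLike) -> set[tuple[str, int]]:
    """Genotyping-panel marker positions: 2-column TSV (chrom, 1-based pos) or VCF."""
    path = str(path)
    if path.endswith((".vcf", ".vcf.gz")):
        return {(v.chrom, v.pos) for v in read_vcf(path)}
    positions = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, pos = line.split("\t")[:2]
            positions.add((chrom, int(pos)))
    return positions


def _cds_phases(gene: GeneModel) -> list[int]:
    """GFF3 phase per CDS segment in genomic order."""
    segs = gene.cds if gene.strand == "+" else list(reversed(gene.cds))
    phases, carried = [], 0
    for s, e in segs:
        phases.append((3 - carried % 3) % 3)
        carried += e - s + 1
    return phases if gene.strand == "+" else list(reversed(phases))


def write_gff3(path: str | os.PathLike, genes: Sequence[GeneModel]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            mrna_id = f"{g.gene_id}.1"
            fh.write(
                f"{g.chrom}\tbarleymut\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            fh.write(
                f"{g.chrom}\tbarleymut\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna_id};Parent={g.gene_id}\n"
            )
            for (s, e), phase in zip(g.cds, _cds_phases(g)):
                fh.write(
                    f"{g.chrom}\tbarleymut\texon\t{s}\t{e}\t.\t{g.strand}\t.\tParent={mrna_id}\n"
                )
                fh.write(
                    f"{g.chrom}\tbarleymut\tCDS\t{s}\t{e}\t.\t{g.strand}\t{phase}\t"
                    f"ID={mrna_id}.cds;Parent={mrna_id}\n"
                )


def read_gff3(path: str | os.PathLike) -> list[GeneModel]:
    """Read single-transcript protein-coding gene models (gene + CDS features)."""
    genes: dict[str, GeneModel] = {}
    mrna_to_gene: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = line.rstrip(
                "\n"
            ).split("\t")
            attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            if ftype == "gene":
                gid = attr["ID"]
                genes[gid] = GeneModel(gid, chrom, int(start), int(end), strand)
            elif ftype == "mRNA":
                mrna_to_gene[attr["ID"]] = attr["Parent"]
            elif ftype == "CDS":
                gid = mrna_to_gene.get(attr["Parent"], attr["Parent"])
                genes[gid].cds.append((int(start), int(end)))
    for g in genes.values():
        g.cds.sort()
    return list(genes.values())
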