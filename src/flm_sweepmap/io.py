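"""Readers and writers for the standard formats the pipeline touches.

Conventions: coordinates are 0-based half-open internally; VCF and GFF3 are
1-based inclusive on disk and converted on read/write; BED and bedGraph are
0-based half-open on disk. Every writer produces deterministic byte output
for identical inputs, and every output is re-parseable by the matching
reader here.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .bsa import SNP_TABLE_COLUMNS, MappingInterval, PoolScanResult
from .expression import CoverageProfile, GeneModelAnnot
from .simulate import ReadSet

__all__ = [
    "read_snp_table",
    "write_snp_tsv",
    "write_snp_vcf",
    "write_fastq",
    "read_fastq",
    "write_fasta",
    "read_fasta",
    "write_bedgraph",
    "read_bedgraph",
    "write_intervals_bed",
    "write_profile_tsv",
    "read_gene_model_gff3",
    "write_gene_model_gff3",
    "write_manifest",
]


# ---------------------------------------------------------------- SNP tables

def write_snp_tsv(table: pd.DataFrame, path: str | Path) -> Path:
    """SNP pool table as TSV with 1-based positions."""
    path = Path(path)
    out = table[SNP_TABLE_COLUMNS].copy()
    out["pos"] = out["pos"].astype(np.int64) + 1
    out["called_in_both"] = out["called_in_both"].astype(bool)
    out.to_csv(path, sep="\t", index=False)
    return path


_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=PAF,Number=1,Type=Float,Description="Alternative-allele frequency in the resequenced alternative parent">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##contig=<ID={chrom}>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tearly\tlate
"""


def write_snp_vcf(table: pd.DataFrame, path: str | Path) -> Path:
    """SNP pool table as a two-sample (early/late) VCF 4.2.

    Pool counts go into AD/DP; the parental alternative-allele frequency
    into INFO/PAF. ``called_in_both`` is encoded through the sample GTs:
    both ``0/1`` when true, ``./.`` otherwise.
    """
    path = Path(path)
    chrom = str(table["chrom"].iloc[0]) if len(table) else "chr1"
    lines = [_VCF_HEADER.format(chrom=chrom)]
    for _, r in table.iterrows():
        gt = "0/1" if bool(r["called_in_both"]) else "./."
        e = f"{gt}:{int(r['depth_early']) - int(r['alt_early'])},{int(r['alt_early'])}:{int(r['depth_early'])}"
        l = f"{gt}:{int(r['depth_late']) - int(r['alt_late'])},{int(r['alt_late'])}:{int(r['depth_late'])}"
        lines.append(
            f"{r['chrom']}\t{int(r['pos']) + 1}\t.\t{r['ref']}\t{r['alt']}\t.\tPASS\t"
            f"PAF={float(r['parental_alt_freq']):g}\tGT:AD:DP\t{e}\t{l}\n"
        )
    path.write_text("".join(lines))
    return path


def _read_snp_tsv(path: Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = set(SNP_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad = table["pos"].isna() | (table["pos"] < 1)
    if bad.any():
        # +2: one for the header line, one for 1-based line numbering
        raise ValueError(f"{path}: malformed position at line {int(bad.idxmax()) + 2}")
    table["pos"] = table["pos"].astype(np.int64) - 1
    table["called_in_both"] = table["called_in_both"].astype(bool)
    return table[SNP_TABLE_COLUMNS]


def _read_snp_vcf(path: Path) -> pd.DataFrame:
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        names = list(vcf.header.samples)
        if names != ["early", "late"]:
            raise ValueError(f"{path}: expected samples ['early', 'late'], found {names}")
        for rec in vcf:
            try:
                se, sl = rec.samples["early"], rec.samples["late"]
                ad_e, ad_l = se["AD"], sl["AD"]
                dp_e, dp_l = se["DP"], sl["DP"]
                if dp_e is None or dp_l is None:
                    raise KeyError("DP")
                called = se["GT"] != (None, None) and sl["GT"] != (None, None)
                rows.append(
                    {
                        "chrom": rec.chrom,
                        "pos": rec.pos - 1,
                        "ref": rec.ref,
                        "alt": rec.alts[0] if rec.alts else ".",
                        "depth_early": int(dp_e),
                        "alt_early": int(ad_e[1]),
                        "depth_late": int(dp_l),
                        "alt_late": int(ad_l[1]),
                        "parental_alt_freq": float(rec.info.get("PAF", 1.0)),
                        "called_in_both": bool(called),
                    }
                )
            except (KeyError, IndexError, TypeError) as exc:
                raise ValueError(
                    f"{path}: missing FORMAT field near {rec.chrom}:{rec.pos} ({exc})"
                ) from exc
    return pd.DataFrame(rows, columns=SNP_TABLE_COLUMNS)


def read_snp_table(path: str | Path, format: str | None = None) -> pd.DataFrame:
    """Read a SNP pool table from TSV or VCF (auto-detected by extension)."""
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix == ".vcf" else "tsv"
    if format == "vcf":
        return _read_snp_vcf(path)
    if format == "tsv":
        return _read_snp_tsv(path)
    raise ValueError(f"unknown SNP table format {format!r}")


# ------------------------------------------------------------- reads / FASTA

def write_fastq(readset: ReadSet, path: str | Path, quality: int = 40) -> Path:
    """Simulated reads as Phred-33 FASTQ with constant base quality."""
    path = Path(path)
    records = []
    for r in readset.reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = [quality] * len(r.sequence)
        records.append(rec)
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fastq")
    return path


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


def write_fasta(sequences: dict[str, str], path: str | Path) -> Path:
    path = Path(path)
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    return path


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------- coverage

def write_bedgraph(profile: CoverageProfile, path: str | Path, chrom: str | None = None) -> Path:
    """Per-nucleotide coverage as bedGraph (0-based half-open, run-length)."""
    path = Path(path)
    chrom = chrom or profile.gene_id
    counts = profile.counts
    lines = [f'track type=bedGraph name="{profile.gene_id}:{profile.replicate}"\n']
    if counts.size:
        change = np.flatnonzero(np.diff(counts)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [counts.size]])
        for s, e in zip(starts, ends):
            lines.append(f"{chrom}\t{s + profile.offset}\t{e + profile.offset}\t{counts[s]:g}\n")
    path.write_text("".join(lines))
    return path


def read_bedgraph(path: str | Path, gene_id: str = "gene", replicate: str = "rep1") -> CoverageProfile:
    path = Path(path)
    rows = []
    for line in path.read_text().splitlines():
        if not line or line.startswith(("track", "#")):
            continue
        chrom, start, end, value = line.split("\t")
        rows.append((int(start), int(end), float(value)))
    if not rows:
        raise ValueError(f"{path}: empty bedGraph")
    offset = rows[0][0]
    length = rows[-1][1] - offset
    counts = np.zeros(length)
    for s, e, v in rows:
        counts[s - offset : e - offset] = v
    return CoverageProfile(gene_id=gene_id, replicate=replicate, counts=counts, offset=offset)


# ------------------------------------------------------------------ results

def write_intervals_bed(intervals: Sequence[MappingInterval], path: str | Path) -> Path:
    """Mapping intervals as BED4+2: name=peak position, then Δf_max and threshold."""
    path = Path(path)
    lines = ["# mapping intervals (0-based half-open); name=peak_pos score columns: peak_delta threshold\n"]
    for iv in intervals:
        lines.append(
            f"{iv.chrom}\t{iv.start}\t{iv.end}\tpeak={iv.peak_pos}\t{iv.peak_delta:.6f}\t{iv.threshold:g}\n"
        )
    path.write_text("".join(lines))
    return path


def write_profile_tsv(result: PoolScanResult, path: str | Path) -> Path:
    """Δf scan profile: positions (1-based), raw/smoothed frequencies, Δf, bands."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "pos": result.early.positions.astype(np.int64) + 1,
            "f_early": result.early.raw_f,
            "f_late": result.late.raw_f,
            "smooth_early": result.early.smooth_f,
            "smooth_late": result.late.smooth_f,
            "delta_f": result.delta.delta_f,
        }
    )
    if result.early.band_lo is not None:
        df["band_lo_early"] = result.early.band_lo
        df["band_hi_early"] = result.early.band_hi
        df["band_lo_late"] = result.late.band_lo
        df["band_hi_late"] = result.late.band_hi
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    return path


# -------------------------------------------------------------------- GFF3

def read_gene_model_gff3(path: str | Path, gene_id: str | None = None) -> GeneModelAnnot:
    """Read one gene's exon structure from GFF3 (exon features, 1-based on disk).

    Minus-strand genes are flipped so exons come back 5'→3' of the gene in
    gene-oriented coordinates (0 = transcription start).
    """
    path = Path(path)
    exons = []
    meta = None
    for line in path.read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ValueError(f"{path}: malformed GFF3 line: {line!r}")
        chrom, _, ftype, start, end, _, strand, _, attrs = fields
        attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
        gid = attr.get("Parent", attr.get("ID", "gene"))
        if gene_id is not None and gid != gene_id:
            continue
        if ftype == "exon":
            exons.append((int(start) - 1, int(end)))
            meta = (gid, chrom, strand)
    if not exons:
        raise ValueError(f"{path}: no exon features found" + (f" for {gene_id}" if gene_id else ""))
    gid, chrom, strand = meta
    exons.sort()
    span_start, span_end = exons[0][0], exons[-1][1]
    if strand == "-":
        exons = [(span_end - e, span_end - s) for s, e in reversed(exons)]
        span_start = 0
    else:
        exons = [(s - span_start, e - span_start) for s, e in exons]
    return GeneModelAnnot(gene_id=gid, chrom=chrom, strand=strand, exons=tuple(exons))


def write_gene_model_gff3(model: GeneModelAnnot, path: str | Path, genome_offset: int = 0) -> Path:
    """Write a gene model as GFF3 exon features (1-based inclusive on disk)."""
    path = Path(path)
    lines = ["##gff-version 3\n"]
    span = model.span
    lines.append(
        f"{model.chrom}\tflm-sweepmap\tgene\t{genome_offset + span[0] + 1}\t{genome_offset + span[1]}\t.\t{model.strand}\t.\tID={model.gene_id}\n"
    )
    for i, (s, e) in enumerate(model.exons):
        lines.append(
            f"{model.chrom}\tflm-sweepmap\texon\t{genome_offset + s + 1}\t{genome_offset + e}\t.\t{model.strand}\t.\t"
            f"ID={model.gene_id}.exon{i + 1};Parent={model.gene_id}\n"
        )
    path.write_text("".join(lines))
    return path


# ----------------------------------------------------------------- manifest

def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(files: Iterable[str | Path], out_dir: str | Path, run_info: dict | None = None) -> Path:
    """JSON manifest of written files with sizes and sha256 checksums."""
    out_dir = Path(out_dir)
    entries = []
    for f in files:
        f = Path(f)
        entries.append(
            {
                "path": str(f.relative_to(out_dir) if f.is_relative_to(out_dir) else f),
                "bytes": f.stat().st_size,
                "sha256": sha256_file(f),
            }
        )
    manifest = {"files": entries}
    if run_info:
        manifest["run"] = run_info
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
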