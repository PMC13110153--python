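"""Format readers and writers binding the pipeline stages together.

FASTA via Biopython, GFF3 via gffutils (in-memory database), VCF via cyvcf2
for reading and a minimal 8-column VCF 4.2 writer, plus plain TSV/CSV tables
for coverage, pileups and phenotypes.  Coordinates are 1-based inclusive
internally (GFF3/VCF native); BED output is 0-based half-open.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("tillmap")

VCF_COLUMNS = ["chrom", "pos", "ref", "alt", "qual", "depth", "is_indel", "line_id"]


# ---------------------------------------------------------------------------
# FASTA / GFF3
# ---------------------------------------------------------------------------


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seqs[name]), id=name, description="") for name in sorted(seqs)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_gff3(genome, path) -> None:
    """Write gene/mRNA/CDS features with phase, 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in sorted(genome.seqs):
            fh.write(f"##sequence-region {chrom} 1 {len(genome.seqs[chrom])}\n")
        for g in genome.genes.itertuples():
            fh.write(
                f"{g.chrom}\ttillmap\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            fh.write(
                f"{g.chrom}\ttillmap\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}.1;Parent={g.gene_id}\n"
            )
            exons = genome.exons[genome.exons.gene_id == g.gene_id].sort_values("exon_rank")
            cum = 0
            for e in exons.itertuples():
                phase = (3 - cum % 3) % 3
                fh.write(
                    f"{g.chrom}\ttillmap\tCDS\t{e.start}\t{e.end}\t.\t{g.strand}\t{phase}\t"
                    f"ID={g.gene_id}.cds;Parent={g.gene_id}.1\n"
                )
                cum += e.end - e.start + 1


def read_gff3(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Parse gene and CDS features back into gene/exon tables."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    gene_rows, exon_rows = [], []
    for g in db.features_of_type("gene"):
        gene_rows.append(
            dict(gene_id=g.id, chrom=g.seqid, start=g.start, end=g.end, strand=g.strand)
        )
        cds = sorted(
            db.children(g, featuretype="CDS"),
            key=lambda c: c.start,
        )
        ordered = cds if g.strand == "+" else list(reversed(cds))
        for rank, c in enumerate(ordered):
            exon_rows.append(
                dict(gene_id=g.id, chrom=c.seqid, start=c.start, end=c.end, exon_rank=rank)
            )
    genes = pd.DataFrame(gene_rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    genes["rank"] = genes.groupby("chrom").cumcount()
    exons = pd.DataFrame(exon_rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    return genes, exons


def read_genome(fasta_path, gff_path):
    """Load FASTA + GFF3 back into a :class:`~tillmap.synthetic.Genome`."""
    from .synthetic import Genome

    seqs = read_fasta(fasta_path)
    genes, exons = read_gff3(gff_path)
    return Genome(seqs=seqs, genes=genes, exons=exons)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def write_vcf(df: pd.DataFrame, path, sample: str, contigs: dict[str, str] | None = None) -> None:
    """Minimal single-sample VCF 4.2: CHROM POS ID REF ALT QUAL FILTER INFO(DP)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=tillmap\n##sample={sample}\n")
        if contigs:
            for name in sorted(contigs):
                fh.write(f"##contig=<ID={name},length={len(contigs[name])}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Raw read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in df.sort_values(["chrom", "pos"]).itertuples():
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t{r.qual:g}\t.\tDP={int(r.depth)}\n"
            )


def read_vcf_minimal(path, line_id: str | None = None) -> pd.DataFrame:
    """Stream a VCF into a variant table; multi-allelic records are split.

    Records lacking DP get missing depth (they then fail the depth filters)
    with a warning; malformed files raise with the first offending line
    number.
    """
    from cyvcf2 import VCF

    path = str(path)
    if line_id is None:
        line_id = Path(path).stem
    rows = []
    try:
        vcf = VCF(path)
        missing_dp = 0
        for v in vcf:
            dp = v.INFO.get("DP")
            if dp is None:
                missing_dp += 1
            for alt in v.ALT:
                rows.append(
                    dict(
                        chrom=v.CHROM,
                        pos=v.POS,
                        ref=v.REF,
                        alt=alt,
                        qual=v.QUAL if v.QUAL is not None else np.nan,
                        depth=float(dp) if dp is not None else np.nan,
                        is_indel=len(v.REF) != len(alt),
                        line_id=line_id,
                    )
                )
        if missing_dp:
            warnings.warn(f"{path}: {missing_dp} records lack DP; depth marked missing")
    except Exception as exc:  # surface the offending line for malformed input
        bad = _first_malformed_line(path)
        raise ValueError(
            f"failed to parse {path}"
            + (f" (first malformed line: {bad})" if bad else "")
            + f": {exc}"
        ) from exc
    df = pd.DataFrame(rows, columns=VCF_COLUMNS)
    if not df.empty and not (
        df.groupby("chrom", sort=False).pos.is_monotonic_increasing.all()
    ):
        df = df.sort_values(["chrom", "pos"]).reset_index(drop=True)
        logger.info("%s: records were unsorted; sorted on read", path)
    return df


def _first_malformed_line(path) -> int | None:
    try:
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                if line.startswith("#") or not line.strip():
                    continue
                if len(line.rstrip("\n").split("\t")) < 8:
                    return i
    except OSError:
        return None
    return None


def read_vcf_dir(vcf_dir) -> pd.DataFrame:
    """Concatenate all per-line VCFs of a directory (line id = file stem)."""
    frames = [
        read_vcf_minimal(p) for p in sorted(Path(vcf_dir).glob("*.vcf"))
    ]
    if not frames:
        raise ValueError(f"no .vcf files under {vcf_dir}")
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------


def write_coverage_table(coverage: pd.DataFrame, path) -> None:
    coverage.to_csv(path, sep="\t", index=False)


def read_coverage_table(path) -> pd.DataFrame:
    """Coverage TSV -> genes x samples matrix, sorted by (chrom, start).

    Duplicate gene ids are rejected; non-numeric counts raise naming the
    offending cell.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    meta_cols = ["gene_id", "chrom", "start", "end", "length"]
    missing = [c for c in meta_cols if c not in df.columns]
    if missing:
        raise ValueError(f"coverage table missing columns: {missing}")
    if df.gene_id.duplicated().any():
        dup = df.gene_id[df.gene_id.duplicated()].iloc[0]
        raise ValueError(f"duplicate gene id {dup!r} in coverage table")
    for col in df.columns:
        if col in ("gene_id", "chrom"):
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            row = df.index[coerced.isna()][0]
            raise ValueError(
                f"non-numeric count in column {col!r}, gene {df.gene_id.iloc[row]!r}"
            )
        df[col] = coerced
    if not df.groupby("chrom", sort=False).start.is_monotonic_increasing.all():
        warnings.warn("coverage table was unsorted; sorting by (chrom, start)")
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("line_id", "location", "rep"):
        if col not in df.columns:
            raise ValueError(f"phenotype table missing column {col!r}")
    if df.duplicated(["line_id", "location", "rep"]).any():
        raise ValueError("duplicate (line, location, rep) keys in phenotype table")
    return df


def read_pileups(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
    need = ["chrom", "pos", "sample", "ref_count", "alt_count"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"pileup table missing columns: {missing}")
    return df


def write_bed(intervals: pd.DataFrame, path, name_col: str | None = None) -> None:
    """Write 1-based inclusive intervals as 0-based half-open BED."""
    with open(path, "w") as fh:
        for i, r in enumerate(intervals.itertuples()):
            name = getattr(r, name_col) if name_col else f"region{i + 1}"
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{name}\n")


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    version: str
    config_hash: str
    inputs: dict[str, str] = field(default_factory=dict)   # path -> checksum
    outputs: dict[str, list[str]] = field(default_factory=dict)  # stage -> paths
    wall_clock: dict[str, float] = field(default_factory=dict)   # stage -> seconds

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)


class StageTimer:
    def __init__(self, manifest: RunManifest, stage: str):
        self.manifest, self.stage = manifest, stage

    def __enter__(self):
        self._t0 = time.perf_counter()
        logger.info("stage %s: started", self.stage)
        return self

    def __exit__(self, *exc):
        self.manifest.wall_clock[self.stage] = round(time.perf_counter() - self._t0, 3)
        logger.info("stage %s: finished in %.2fs", self.stage, self.manifest.wall_clock[self.stage])
        return False
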