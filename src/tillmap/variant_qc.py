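"""EMS variant quality control and annotation.

Implements the per-line filter chain (SNPs: QUAL >= 30 and depth 5-250;
indels: the stricter QUAL >= 50 and depth >= 10), removal of variants shared
by five or more independently mutagenised lines, the six strand-pooled
substitution-spectrum classes, genic-context annotation (exon > intron >
upstream 2 kb > downstream 2 kb > intergenic) and a minimal coding-effect
classifier over the standard genetic code.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .synthetic import Genome, revcomp

logger = logging.getLogger("tillmap")

VARIANT_KEY = ["chrom", "pos", "ref", "alt"]

#: strand-pooled class for every point substitution
SUBSTITUTION_CLASS = {
    ("C", "T"): "C/G>T/A",
    ("G", "A"): "C/G>T/A",
    ("C", "A"): "C/G>A/T",
    ("G", "T"): "C/G>A/T",
    ("A", "G"): "A/T>G/C",
    ("T", "C"): "A/T>G/C",
    ("A", "T"): "A/T>T/A",
    ("T", "A"): "A/T>T/A",
    ("A", "C"): "A/T>C/G",
    ("T", "G"): "A/T>C/G",
    ("C", "G"): "C/G>G/C",
    ("G", "C"): "C/G>G/C",
}

CONTEXT_CLASSES = ("exon", "intron", "upstream_2kb", "downstream_2kb", "intergenic")

IMPACT = {
    "stop_gained": "high",
    "stop_lost": "high",
    "start_lost": "high",
    "frameshift": "high",
    "missense": "moderate",
    "inframe_indel": "moderate",
    "synonymous": "low",
    "splice_region": "low",
    "noncoding": "modifier",
}

SPLICE_REGION_BP = 8
FLANK_BP = 2000


@dataclass
class FilterThresholds:
    """Quality/depth filter thresholds and the shared-line limit."""

    snp_min_qual: float = 30.0
    snp_min_depth: int = 5
    snp_max_depth: int = 250
    indel_min_qual: float = 50.0
    indel_min_depth: int = 10
    shared_line_limit: int = 5

    def __post_init__(self) -> None:
        if self.snp_min_depth > self.snp_max_depth:
            raise ValueError("snp_min_depth exceeds snp_max_depth")
        for name in (
            "snp_min_qual",
            "snp_min_depth",
            "snp_max_depth",
            "indel_min_qual",
            "indel_min_depth",
            "shared_line_limit",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class EffectCall:
    klass: str
    impact: str


def apply_variant_filters(
    records: pd.DataFrame, thresholds: FilterThresholds | None = None
) -> pd.DataFrame:
    """Keep SNPs with qual >= 30 and 5 <= depth <= 250; indels with
    qual >= 50 and 10 <= depth <= 250.  Order is preserved; missing depth or
    quality fails the respective bound."""
    t = thresholds or FilterThresholds()
    if (records.qual.dropna() < 0).any() or (records.depth.dropna() < 0).any():
        raise ValueError("negative quality or depth in variant records")
    qual = records.qual.to_numpy(dtype=float)
    depth = records.depth.to_numpy(dtype=float)
    is_indel = records.is_indel.to_numpy(dtype=bool)
    with np.errstate(invalid="ignore"):
        snp_keep = (qual >= t.snp_min_qual) & (depth >= t.snp_min_depth) & (
            depth <= t.snp_max_depth
        )
        indel_keep = (qual >= t.indel_min_qual) & (depth >= t.indel_min_depth) & (
            depth <= t.snp_max_depth
        )
    keep = np.where(is_indel, indel_keep, snp_keep)
    keep &= ~(np.isnan(qual) | np.isnan(depth))
    return records.loc[keep]


def remove_shared_variants(records: pd.DataFrame, limit: int = 5) -> pd.DataFrame:
    """Drop every occurrence of any variant seen in >= ``limit`` distinct lines.

    Variant identity is (chrom, pos, ref, alt): the EMS-recurrence argument
    concerns identical mutations, not positions.
    """
    if records.empty:
        return records
    n_lines = records.groupby(VARIANT_KEY)["line_id"].nunique()
    shared = n_lines[n_lines >= limit].index
    if len(shared) == 0:
        return records
    key = pd.MultiIndex.from_frame(records[VARIANT_KEY])
    return records.loc[~key.isin(shared)]


def classify_substitution(ref: str, alt: str) -> str:
    """Strand-pooled class of a point substitution (X>Y and its complement
    share a class)."""
    if len(ref) != 1 or len(alt) != 1:
        raise ValueError(f"not a point substitution: {ref}>{alt}")
    try:
        return SUBSTITUTION_CLASS[(ref.upper(), alt.upper())]
    except KeyError:
        raise ValueError(f"invalid substitution {ref}>{alt}") from None


def spectrum_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Counts and frequencies over the six pooled substitution classes."""
    snps = records[~records.is_indel]
    classes = [classify_substitution(r, a) for r, a in zip(snps.ref, snps.alt)]
    counts = pd.Series(classes).value_counts()
    from .config import SPECTRUM_CLASSES

    counts = counts.reindex(SPECTRUM_CLASSES, fill_value=0)
    total = counts.sum()
    freq = counts / total if total else counts.astype(float)
    return pd.DataFrame({"count": counts, "frequency": freq})


# ---------------------------------------------------------------------------
# genic context
# ---------------------------------------------------------------------------


class _ChromIndex:
    """Sorted-interval lookup on the (non-overlapping) genes of one chromosome."""

    def __init__(self, genes: pd.DataFrame, exons: pd.DataFrame):
        genes = genes.sort_values("start")
        self.gene_start = genes.start.to_numpy()
        self.gene_end = genes.end.to_numpy()
        self.strand = genes.strand.to_numpy()
        self.exons = {
            gid: grp[["start", "end"]].to_numpy()
            for gid, grp in exons.groupby("gene_id")
        }
        self.gene_id = genes.gene_id.to_numpy()

    def locate(self, pos: int) -> tuple[str, str | None]:
        """Return (context class, containing gene id or None)."""
        i = np.searchsorted(self.gene_start, pos, side="right") - 1
        if i >= 0 and pos <= self.gene_end[i]:
            gid = self.gene_id[i]
            for es, ee in self.exons.get(gid, ()):
                if es <= pos <= ee:
                    return "exon", gid
            return "intron", gid
        # flanks, strand-aware; precedence upstream > downstream
        for j in (i, i + 1):
            if 0 <= j < len(self.gene_id):
                if self.strand[j] == "+" and 0 < self.gene_start[j] - pos <= FLANK_BP:
                    return "upstream_2kb", None
                if self.strand[j] == "-" and 0 < pos - self.gene_end[j] <= FLANK_BP:
                    return "upstream_2kb", None
        for j in (i, i + 1):
            if 0 <= j < len(self.gene_id):
                if self.strand[j] == "-" and 0 < self.gene_start[j] - pos <= FLANK_BP:
                    return "downstream_2kb", None
                if self.strand[j] == "+" and 0 < pos - self.gene_end[j] <= FLANK_BP:
                    return "downstream_2kb", None
        return "intergenic", None


def build_context_index(genome: Genome) -> dict[str, _ChromIndex]:
    return {
        chrom: _ChromIndex(
            genome.genes[genome.genes.chrom == chrom],
            genome.exons[genome.exons.chrom == chrom],
        )
        for chrom in genome.genes.chrom.unique()
    }


def annotate_context(
    records: pd.DataFrame, genome: Genome, index: dict | None = None
) -> pd.Series:
    """Assign each variant exactly one context class under the stated
    precedence.  Variants on chromosomes absent from the gene models are
    intergenic (with a warning)."""
    index = index or build_context_index(genome)
    out = []
    warned = set()
    for r in records.itertuples():
        if r.chrom not in index:
            if r.chrom not in warned:
                warnings.warn(f"chromosome {r.chrom} absent from gene models")
                warned.add(r.chrom)
            out.append("intergenic")
        else:
            out.append(index[r.chrom].locate(r.pos)[0])
    return pd.Series(out, index=records.index, name="context")


# ---------------------------------------------------------------------------
# coding effect
# ---------------------------------------------------------------------------


def _gene_cds(genome: Genome, gene_id: str) -> tuple[pd.Series, pd.DataFrame, str]:
    gene = genome.genes[genome.genes.gene_id == gene_id].iloc[0]
    exons = genome.exons[genome.exons.gene_id == gene_id].sort_values("exon_rank")
    seq = genome.seqs[gene.chrom]
    return gene, exons, seq


def cds_sequence(genome: Genome, gene_id: str) -> str:
    """Spliced CDS in transcription order (starts ATG, ends stop)."""
    gene, exons, seq = _gene_cds(genome, gene_id)
    parts = []
    for e in exons.itertuples():
        piece = seq[e.start - 1 : e.end]
        parts.append(piece if gene.strand == "+" else revcomp(piece))
    return "".join(parts)


def _cds_offset(gene, exons: pd.DataFrame, pos: int) -> int | None:
    """0-based offset of a genomic position within the spliced CDS, or None."""
    off = 0
    for e in exons.itertuples():
        if e.start <= pos <= e.end:
            return off + (pos - e.start if gene.strand == "+" else e.end - pos)
        off += e.end - e.start + 1
    return None


def classify_effect(
    chrom: str, pos: int, ref: str, alt: str, genome: Genome, index: dict | None = None
) -> EffectCall:
    """Classify a variant's coding effect via local codon substitution.

    SNPs in a CDS are typed by translating the affected codon before and
    after; intronic SNPs within 8 bp of an exon boundary are splice_region;
    CDS indels are frameshift (length change not divisible by 3) or
    inframe_indel; everything else is noncoding/modifier.
    """
    index = index or build_context_index(genome)
    if chrom not in index:
        return EffectCall("noncoding", IMPACT["noncoding"])
    context, gid = index[chrom].locate(pos)
    if gid is None:
        return EffectCall("noncoding", IMPACT["noncoding"])
    gene, exons, seq = _gene_cds(genome, gid)
    if context == "intron":
        dist = min(
            min(abs(pos - e.start), abs(pos - e.end))
            for e in exons.itertuples()
        )
        if dist <= SPLICE_REGION_BP:
            return EffectCall("splice_region", IMPACT["splice_region"])
        return EffectCall("noncoding", IMPACT["noncoding"])
    is_indel = len(ref) != len(alt)
    if is_indel:
        klass = "frameshift" if (len(alt) - len(ref)) % 3 else "inframe_indel"
        return EffectCall(klass, IMPACT[klass])
    cds = cds_sequence(genome, gid)
    if len(cds) % 3:
        raise ValueError(f"CDS length of gene {gid} not divisible by 3")
    off = _cds_offset(gene, exons, pos)
    assert off is not None
    base = ref if gene.strand == "+" else revcomp(ref)
    alt_b = alt if gene.strand == "+" else revcomp(alt)
    if cds[off] != base:
        raise ValueError(f"reference mismatch at {chrom}:{pos} in gene {gid}")
    codon_i = off // 3
    codon = cds[codon_i * 3 : codon_i * 3 + 3]
    new_codon = codon[: off % 3] + alt_b + codon[off % 3 + 1 :]
    aa_old = str(Seq(codon).translate())
    aa_new = str(Seq(new_codon).translate())
    if codon_i == 0 and new_codon != "ATG":
        klass = "start_lost"
    elif aa_old != "*" and aa_new == "*":
        klass = "stop_gained"
    elif aa_old == "*" and aa_new != "*":
        klass = "stop_lost"
    elif aa_old == aa_new:
        klass = "synonymous"
    else:
        klass = "missense"
    return EffectCall(klass, IMPACT[klass])


def classify_effects(records: pd.DataFrame, genome: Genome) -> pd.DataFrame:
    """Vector wrapper over :func:`classify_effect` -> columns (effect, impact)."""
    index = build_context_index(genome)
    calls = [
        classify_effect(r.chrom, r.pos, r.ref, r.alt, genome, index)
        for r in records.itertuples()
    ]
    return pd.DataFrame(
        {"effect": [c.klass for c in calls], "impact": [c.impact for c in calls]},
        index=records.index,
    )


# ---------------------------------------------------------------------------
# population summaries
# ---------------------------------------------------------------------------


def summarize_mutation_load(
    records: pd.DataFrame, genome_size_bp: int, genome: Genome | None = None
) -> tuple[pd.DataFrame, dict]:
    """Per-line SNP/indel counts and densities per Mb, plus population-level
    spectrum / context / impact fractions (context and impact only when gene
    models are supplied)."""
    if genome_size_bp <= 0:
        raise ValueError("genome size must be positive")
    mb = genome_size_bp / 1e6
    if records.empty:
        per_line = pd.DataFrame(
            columns=["line_id", "n_snps", "n_indels", "snp_density_per_mb", "indel_density_per_mb"]
        )
        return per_line, dict(
            n_variants=0, n_snps=0, n_indels=0, mean_snp_density_per_mb=0.0, spectrum={}
        )
    grp = records.groupby("line_id")
    per_line = pd.DataFrame(
        {
            "n_snps": grp.is_indel.apply(lambda s: int((~s).sum())),
            "n_indels": grp.is_indel.sum().astype(int),
        }
    ).reset_index()
    per_line["snp_density_per_mb"] = per_line.n_snps / mb
    per_line["indel_density_per_mb"] = per_line.n_indels / mb
    spectrum = spectrum_summary(records)
    pop = dict(
        n_variants=len(records),
        n_snps=int((~records.is_indel).sum()),
        n_indels=int(records.is_indel.sum()),
        mean_snp_density_per_mb=float(per_line.snp_density_per_mb.mean()),
        spectrum=spectrum.frequency.to_dict(),
    )
    if genome is not None:
        snps = records[~records.is_indel]
        ctx = annotate_context(snps, genome)
        pop["context_fractions"] = (ctx.value_counts(normalize=True)).to_dict()
        eff = classify_effects(snps, genome)
        pop["impact_fractions"] = eff.impact.value_counts(normalize=True).to_dict()
        pop["effect_counts"] = eff.effect.value_counts().to_dict()
    return per_line, pop
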