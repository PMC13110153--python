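"""Synthetic cohort generator.

Produces every input the analysis pipeline consumes, with the statistical
structure the downstream methods assume:

* a toy multi-chromosome genome (FASTA) with non-overlapping multi-exon gene
  models (GFF3), including at least one homoeologous A/C chromosome pair;
* per-line EMS variant calls (VCF) whose pooled substitution spectrum, dose
  dependence and mutation density follow the study's reported rates;
* an F2 cohort in which two A-subgenome deletion segments co-segregate while
  a C-subgenome duplication segregates independently, each 1:2:1;
* copy-number-dependent per-gene read-count matrices at ~8x depth;
* per-locus bulk allele counts with the causal region perfectly linked to
  the deletion state;
* replicated two-location phenotypes whose variance components are solved so
  the expected entry-mean broad-sense heritability equals the target.

Everything is drawn from a single seeded generator: a fixed seed yields
byte-identical output files.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SPECTRUM_CLASSES, SimConfig, TraitModel, TraitSpec

logger = logging.getLogger("tillmap")

STOP_CODONS = ("TAA", "TAG", "TGA")
_BASES = np.array(["A", "C", "G", "T"])
_NONSTOP_CODONS = [
    "".join(c) for c in itertools.product("ACGT", repeat=3) if "".join(c) not in STOP_CODONS
]
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: alt allele emitted for each (pooled class, reference base)
CLASS_SUBSTITUTIONS = {
    "C/G>T/A": {"C": "T", "G": "A"},
    "C/G>A/T": {"C": "A", "G": "T"},
    "A/T>G/C": {"A": "G", "T": "C"},
    "A/T>T/A": {"A": "T", "T": "A"},
    "A/T>C/G": {"A": "C", "T": "G"},
    "C/G>G/C": {"C": "G", "G": "C"},
}

#: copy-ratio multiplier by (segment kind, variant copies)
COPY_MULTIPLIER = {
    ("deletion", 0): 1.0,
    ("deletion", 1): 0.5,
    ("deletion", 2): 0.0,
    ("duplication", 0): 1.0,
    ("duplication", 1): 1.5,
    ("duplication", 2): 2.0,
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Genome:
    """In-memory toy genome: sequences plus gene/exon tables.

    ``genes`` columns: gene_id, chrom, start, end, strand, rank (0-based gene
    index within the chromosome, by position).  ``exons`` columns: gene_id,
    chrom, start, end, exon_rank (transcription order).  Coordinates are
    1-based inclusive throughout.
    """

    seqs: dict[str, str]
    genes: pd.DataFrame
    exons: pd.DataFrame

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.seqs.values())

    def segment_interval(self, seg) -> tuple[int, int]:
        """Genomic (start, end) of a gene-rank-addressed segment."""
        sub = self.genes[self.genes.chrom == seg.chrom].sort_values("rank")
        lo = int(sub.iloc[seg.start_gene].start)
        hi = int(sub.iloc[seg.end_gene].end)
        return lo, hi


# ---------------------------------------------------------------------------
# toy genome
# ---------------------------------------------------------------------------


def build_toy_genome(config: SimConfig, rng: np.random.Generator | None = None) -> Genome:
    """Construct a deterministic toy genome with packed multi-exon genes.

    Raises ``ValueError`` when the requested genes cannot fit on a
    chromosome (infeasible packing).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    gs = config.genome_spec
    seqs: dict[str, str] = {}
    gene_rows, exon_rows = [], []
    for chrom in sorted(gs.chrom_lengths):
        length = gs.chrom_lengths[chrom]
        if length < 10_000:
            raise ValueError(f"chromosome {chrom} shorter than 10 kb")
        n_genes = gs.genes_per_chrom.get(chrom, 0)
        chrom_arr = rng.choice(_BASES, size=length)
        plans = [_plan_gene(gs, rng) for _ in range(n_genes)]
        footprint = sum(p["span"] for p in plans)
        min_gap = 20
        if footprint + (n_genes + 1) * min_gap > length:
            raise ValueError(
                f"infeasible packing: {n_genes} genes need {footprint} bp "
                f"plus gaps on {chrom} ({length} bp)"
            )
        slack = length - footprint - (n_genes + 1) * min_gap
        cuts = np.sort(rng.integers(0, slack + 1, size=n_genes))
        gaps = np.diff(np.concatenate([[0], cuts, [slack]])) + min_gap
        pos = 0
        for rank, plan in enumerate(plans):
            pos += int(gaps[rank])
            start = pos + 1  # 1-based
            gene_id = f"{chrom}g{rank:04d}"
            _place_gene(chrom_arr, start, plan)
            gene_rows.append(
                dict(
                    gene_id=gene_id,
                    chrom=chrom,
                    start=start,
                    end=start + plan["span"] - 1,
                    strand=plan["strand"],
                    rank=rank,
                )
            )
            for erank, (es, ee) in enumerate(plan["exon_coords"]):
                exon_rows.append(
                    dict(
                        gene_id=gene_id,
                        chrom=chrom,
                        start=start + es,
                        end=start + ee,
                        exon_rank=erank,
                    )
                )
            pos += plan["span"]
        seqs[chrom] = "".join(chrom_arr)
    genes = pd.DataFrame(gene_rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    exons = pd.DataFrame(exon_rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    return Genome(seqs=seqs, genes=genes, exons=exons)


def _plan_gene(gs, rng: np.random.Generator) -> dict:
    """Draw CDS/exon/intron structure and the spliced CDS sequence."""
    n_codons = int(rng.integers(gs.min_cds_codons, gs.max_cds_codons + 1))
    cds = "ATG" + "".join(rng.choice(_NONSTOP_CODONS, size=n_codons - 2)) + str(
        rng.choice(STOP_CODONS)
    )
    n_exons = int(rng.integers(1, gs.max_exons + 1))
    cds_len = len(cds)
    # split the CDS into n_exons pieces of length >= 10
    while True:
        if n_exons == 1:
            pieces = [cds_len]
            break
        cuts = np.sort(rng.integers(10, cds_len - 9, size=n_exons - 1))
        pieces = np.diff(np.concatenate([[0], cuts, [cds_len]]))
        if (pieces >= 10).all() and len(np.unique(cuts)) == n_exons - 1:
            pieces = pieces.tolist()
            break
    introns = [
        int(rng.integers(gs.min_intron, gs.max_intron + 1)) for _ in range(n_exons - 1)
    ]
    strand = "+" if rng.random() < 0.5 else "-"
    # exon sequences in transcription order
    exon_seqs, off = [], 0
    for p in pieces:
        exon_seqs.append(cds[off : off + p])
        off += p
    # genomic layout left->right
    if strand == "+":
        genomic_pieces = exon_seqs
    else:
        genomic_pieces = [revcomp(s) for s in reversed(exon_seqs)]
    coords, cursor = [], 0
    for i, piece in enumerate(genomic_pieces):
        coords.append((cursor, cursor + len(piece) - 1))
        cursor += len(piece)
        if i < len(introns):
            cursor += introns[i] if strand == "+" else introns[len(introns) - 1 - i]
    span = cursor
    if strand == "-":
        # exon_rank in transcription order: rightmost genomic exon is rank 0
        exon_coords = list(reversed(coords))
    else:
        exon_coords = coords
    return dict(
        strand=strand,
        span=span,
        exon_coords=exon_coords,
        genomic_pieces=genomic_pieces,
        genomic_offsets=[c[0] for c in coords],
    )


def _place_gene(chrom_arr: np.ndarray, start_1based: int, plan: dict) -> None:
    base0 = start_1based - 1
    for off, piece in zip(plan["genomic_offsets"], plan["genomic_pieces"]):
        chrom_arr[base0 + off : base0 + off + len(piece)] = list(piece)


# ---------------------------------------------------------------------------
# EMS variants
# ---------------------------------------------------------------------------


def simulate_ems_variants(
    genome: Genome, config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Draw per-line EMS variant sets.

    Returns ``(variants, truth)`` where ``variants`` maps line id to a
    variant table (chrom, pos, ref, alt, qual, depth, is_indel, origin) and
    ``truth`` is the generator's bookkeeping ledger of drawn per-line loads.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    genome_mb = genome.total_length / 1e6
    alloc = config.lines_per_dose()
    for dose in alloc:
        if dose not in config.ems_dose_labels:
            raise ValueError(f"unknown EMS dose label {dose!r}")
    pools = _base_pools(genome)
    line_doses = [
        (f"DH{num:04d}", dose)
        for num, dose in enumerate(
            (d for d in sorted(alloc) for _ in range(alloc[d])), start=1
        )
    ]
    variants: dict[str, pd.DataFrame] = {}
    truth_rows = []
    for line_id, dose in line_doses:
        snp_mean = config.ems_dose_labels[dose] * genome_mb
        n_snps = int(rng.poisson(snp_mean))
        n_indels = int(
            rng.poisson(snp_mean * config.indel_snp_ratio * config.indel_dose_slope)
        )
        df = _draw_line_variants(genome, config, rng, pools, n_snps, n_indels)
        df["line_id"] = line_id
        variants[line_id] = df
        truth_rows.append(
            dict(line_id=line_id, dose=dose, n_snps=n_snps, n_indels=n_indels)
        )
    _inject_shared_artifacts(variants, genome, config, rng, pools)
    for line_id in variants:
        variants[line_id] = (
            variants[line_id].sort_values(["chrom", "pos"]).reset_index(drop=True)
        )
    return variants, pd.DataFrame(truth_rows)


def _base_pools(genome: Genome) -> dict[str, dict[str, np.ndarray]]:
    pools = {}
    for chrom, seq in genome.seqs.items():
        arr = np.frombuffer(seq.encode(), dtype="S1")
        cg = np.flatnonzero((arr == b"C") | (arr == b"G")) + 1  # 1-based
        at = np.flatnonzero((arr == b"A") | (arr == b"T")) + 1
        pools[chrom] = {"CG": cg, "AT": at}
    return pools


def _draw_line_variants(genome, config, rng, pools, n_snps, n_indels) -> pd.DataFrame:
    chroms = sorted(genome.seqs)
    weights = np.array([len(genome.seqs[c]) for c in chroms], dtype=float)
    weights /= weights.sum()
    rows = []
    chrom_counts = rng.multinomial(n_snps, weights)
    for chrom, n_c in zip(chroms, chrom_counts):
        if n_c == 0:
            continue
        class_counts = rng.multinomial(n_c, config.spectrum_probs)
        n_cg = class_counts[[0, 1, 5]].sum()  # C/G-source classes
        n_at = class_counts[[2, 3, 4]].sum()
        cg_pos = rng.choice(pools[chrom]["CG"], size=n_cg, replace=False)
        at_pos = rng.choice(pools[chrom]["AT"], size=n_at, replace=False)
        cg_iter, at_iter = iter(cg_pos), iter(at_pos)
        seq = genome.seqs[chrom]
        for cls, count in zip(SPECTRUM_CLASSES, class_counts):
            source = cg_iter if cls.startswith("C/G") else at_iter
            for _ in range(count):
                pos = int(next(source))
                ref = seq[pos - 1]
                rows.append((chrom, pos, ref, CLASS_SUBSTITUTIONS[cls][ref], False))
    # small (1-3 bp) insertions/deletions
    indel_chroms = rng.multinomial(n_indels, weights)
    for chrom, n_c in zip(chroms, indel_chroms):
        seq = genome.seqs[chrom]
        positions = rng.integers(1, len(seq) - 4, size=n_c)
        for pos in positions:
            pos = int(pos)
            size = int(rng.integers(1, 4))
            anchor = seq[pos - 1]
            if rng.random() < 0.5:  # insertion
                ins = "".join(rng.choice(_BASES, size=size))
                rows.append((chrom, pos, anchor, anchor + ins, True))
            else:  # deletion
                rows.append((chrom, pos, seq[pos - 1 : pos + size], anchor, True))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "is_indel"])
    n = len(df)
    df["qual"] = np.round(
        np.clip(rng.normal(config.vcf_qual_mean, config.vcf_qual_sd, size=n), 1.0, None), 1
    )
    disp = 10.0
    df["depth"] = rng.negative_binomial(disp, disp / (disp + config.vcf_depth_mean), size=n)
    df["origin"] = "true"
    return df


def _inject_shared_artifacts(variants, genome, config, rng, pools) -> None:
    """Add identical non-EMS artifact variants to >=5 random lines each."""
    if config.n_shared_artifacts == 0:
        return
    line_ids = sorted(variants)
    chroms = sorted(genome.seqs)
    for _ in range(config.n_shared_artifacts):
        chrom = chroms[int(rng.integers(len(chroms)))]
        pool = pools[chrom]["CG" if rng.random() < 0.5 else "AT"]
        pos = int(rng.choice(pool))
        ref = genome.seqs[chrom][pos - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        n_carriers = int(rng.integers(5, min(11, len(line_ids) + 1)))
        carriers = rng.choice(line_ids, size=n_carriers, replace=False)
        for line_id in carriers:
            row = pd.DataFrame(
                [
                    dict(
                        chrom=chrom,
                        pos=pos,
                        ref=ref,
                        alt=alt,
                        is_indel=False,
                        qual=round(float(np.clip(rng.normal(55, 10), 31, None)), 1),
                        depth=int(rng.poisson(30)) + 5,
                        origin="artifact",
                        line_id=line_id,
                    )
                ]
            )
            variants[line_id] = pd.concat([variants[line_id], row], ignore_index=True)


# ---------------------------------------------------------------------------
# F2 cohort: genotypes and phenotypes
# ---------------------------------------------------------------------------

GENOTYPE_STATES = {0: "hom-ref", 1: "hemi", 2: "hom-alt"}


def solve_variance_components(model: TraitModel, spec: TraitSpec) -> dict[str, float]:
    """Solve V_G / V_GL / V_E so expected entry-mean H2 equals the target.

    The locus variance is computed analytically over the 1:2:1 x 1:2:1 joint
    genotype distribution; the non-genetic entry-mean variance
    ``N = V_G (1/H2 - 1)`` is split between G x L and residual by
    ``gl_noise_share``.
    """
    probs = {0: 0.25, 1: 0.5, 2: 0.25}
    vals, ws = [], []
    for d in (0, 1, 2):
        for p in (0, 1, 2):
            vals.append(_locus_effect(model, d, p))
            ws.append(probs[d] * probs[p])
    vals, ws = np.array(vals), np.array(ws)
    mean = float(np.sum(ws * vals))
    v_locus = float(np.sum(ws * (vals - mean) ** 2))
    v_g = v_locus + model.v_polygenic
    n_noise = v_g * (1.0 / model.h2_target - 1.0)
    L, R = spec.n_locations, spec.n_reps
    v_gl = spec.gl_noise_share * n_noise * L
    v_e = (1.0 - spec.gl_noise_share) * n_noise * L * R
    return dict(v_locus=v_locus, v_g=v_g, v_gl=v_gl, v_e=v_e, expected_h2=model.h2_target)


def _locus_effect(model: TraitModel, d_copies: int, p_copies: int) -> float:
    eff = model.del_effect_hom * d_copies / 2.0
    if d_copies == 1:
        eff += model.dominance
    eff += model.dup_modulation * (d_copies / 2.0) * (p_copies / 2.0)
    return eff


def simulate_f2_cohort(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Draw F2 genotypes (1:2:1 at both loci, independent) and phenotypes.

    Returns ``(genotypes, phenotypes, variance_ledger)``.  The two deletion
    segments share one indicator by construction, so their states are
    identical within every individual.
    """
    if config.n_f2 < 4:
        raise ValueError("n_f2 must be >= 4")
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    n = config.n_f2
    ids = [f"F2_{i:03d}" for i in range(1, n + 1)]
    d_copies = rng.binomial(2, 0.5, size=n)
    p_copies = rng.binomial(2, 0.5, size=n)
    genotypes = pd.DataFrame(
        dict(
            line_id=ids,
            d_copies=d_copies,
            p_copies=p_copies,
            d_state=[GENOTYPE_STATES[c] for c in d_copies],
            p_state=[GENOTYPE_STATES[c] for c in p_copies],
        )
    )
    spec = config.trait_spec
    L, R = spec.n_locations, spec.n_reps
    locations = [f"LOC{i + 1}" for i in range(L)]
    base = pd.DataFrame(
        [
            dict(line_id=lid, location=loc, rep=rep)
            for lid in ids
            for loc in locations
            for rep in range(1, R + 1)
        ]
    )
    ledger = {}
    for trait, model in spec.traits.items():
        comps = solve_variance_components(model, spec)
        ledger[trait] = comps
        locus = np.array([_locus_effect(model, d, p) for d, p in zip(d_copies, p_copies)])
        polygenic = rng.normal(0.0, np.sqrt(model.v_polygenic), size=n)
        g = dict(zip(ids, locus + polygenic))
        gl = {
            (lid, loc): rng.normal(0.0, np.sqrt(comps["v_gl"]))
            for lid in ids
            for loc in locations
        }
        loc_eff = dict(zip(locations, spec.location_effects))
        resid = rng.normal(0.0, np.sqrt(comps["v_e"]), size=len(base))
        base[trait] = [
            model.baseline + g[r.line_id] + loc_eff[r.location] + gl[(r.line_id, r.location)]
            for r in base.itertuples()
        ]
        base[trait] += resid
    return genotypes, base, ledger


# ---------------------------------------------------------------------------
# coverage matrix
# ---------------------------------------------------------------------------


def gene_copy_multipliers(genome: Genome, config: SimConfig, genotypes: pd.DataFrame):
    """Per-gene x per-sample copy-ratio multipliers implied by the genotypes.

    Includes the two parents when ``config.include_parents`` (wild-type
    parent all-normal; mutant parent homozygous for every segment, as a
    doubled-haploid parent is).
    """
    genes = genome.genes
    samples, states = [], []
    if config.include_parents:
        samples += ["WT_PARENT", "MUT_PARENT"]
        states += [(0, 0), (2, 2)]
    samples += list(genotypes.line_id)
    states += list(zip(genotypes.d_copies, genotypes.p_copies))
    mult = np.ones((len(genes), len(samples)))
    segments = config.hnrt_spec.segments if config.hnrt_spec is not None else []
    for seg in segments:
        mask = (
            (genes.chrom == seg.chrom)
            & (genes["rank"] >= seg.start_gene)
            & (genes["rank"] <= seg.end_gene)
        ).to_numpy()
        for j, (d, p) in enumerate(states):
            copies = d if seg.kind == "deletion" else p
            mult[mask, j] = COPY_MULTIPLIER[(seg.kind, int(copies))]
    return samples, mult


def simulate_coverage(
    genotypes: pd.DataFrame,
    genome: Genome,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-gene read counts ~ NB(mean proportional to copy number x length x depth)."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    genes = genome.genes.copy()
    lengths = (genes.end - genes.start + 1).to_numpy()
    mu0 = config.mean_depth * lengths / config.read_length
    samples, mult = gene_copy_multipliers(genome, config, genotypes)
    disp = config.coverage_dispersion
    out = genes[["gene_id", "chrom", "start", "end"]].copy()
    out["length"] = lengths
    counts = np.zeros(mult.shape, dtype=int)
    for j in range(mult.shape[1]):
        mu = mu0 * mult[:, j]
        nz = mu > 0
        counts[nz, j] = rng.negative_binomial(disp, disp / (disp + mu[nz]))
    return pd.concat(
        [out, pd.DataFrame(counts, columns=samples, index=out.index)], axis=1
    )


# ---------------------------------------------------------------------------
# bulk pileups
# ---------------------------------------------------------------------------


def causal_interval(genome: Genome, config: SimConfig) -> tuple[str, int, int]:
    """Genomic span linked to the deletion state: [D1.start, D2.end]."""
    dels = config.hnrt_spec.deletions
    chrom = dels[0].chrom
    lo = min(genome.segment_interval(d)[0] for d in dels)
    hi = max(genome.segment_interval(d)[1] for d in dels)
    return chrom, lo, hi


def simulate_bulk_pileups(
    genotypes: pd.DataFrame,
    genome: Genome,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    loci: pd.DataFrame | None = None,
    sampling_noise: bool = True,
) -> pd.DataFrame:
    """Per-individual, per-locus ref/alt read counts.

    Loci inside the causal interval have alt dosage equal to the deletion
    copy number; all other loci segregate independently 1:2:1 per
    individual.  With ``sampling_noise=False`` depth is fixed at the mean
    and counts are the exact dosage expectation (for limit tests).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 4)
    if loci is None:
        rows = []
        for chrom in sorted(genome.seqs):
            pos = np.sort(
                rng.choice(
                    np.arange(1, len(genome.seqs[chrom]) + 1),
                    size=config.n_loci_per_chrom,
                    replace=False,
                )
            )
            rows.append(pd.DataFrame(dict(chrom=chrom, pos=pos)))
        loci = pd.concat(rows, ignore_index=True)
    for r in loci.itertuples():
        if r.chrom not in genome.seqs:
            raise ValueError(f"locus on unknown chromosome {r.chrom}")
        if not 1 <= r.pos <= len(genome.seqs[r.chrom]):
            raise ValueError(f"locus {r.chrom}:{r.pos} outside the genome")
    chrom_c, lo, hi = causal_interval(genome, config)
    causal = ((loci.chrom == chrom_c) & (loci.pos >= lo) & (loci.pos <= hi)).to_numpy()
    n_ind, n_loci = len(genotypes), len(loci)
    dosage = rng.binomial(2, 0.5, size=(n_ind, n_loci))
    dosage[:, causal] = genotypes.d_copies.to_numpy()[:, None]
    if sampling_noise:
        depth = rng.poisson(config.mean_depth, size=(n_ind, n_loci))
        alt = rng.binomial(depth, dosage / 2.0)
    else:
        depth = np.full((n_ind, n_loci), int(round(config.mean_depth)))
        alt = np.round(depth * dosage / 2.0).astype(int)
    out = pd.DataFrame(
        dict(
            chrom=np.tile(loci.chrom.to_numpy(), n_ind),
            pos=np.tile(loci.pos.to_numpy(), n_ind),
            sample=np.repeat(genotypes.line_id.to_numpy(), n_loci),
            ref_count=(depth - alt).ravel(),
            alt_count=alt.ravel(),
        )
    )
    return out


# ---------------------------------------------------------------------------
# full cohort
# ---------------------------------------------------------------------------


@dataclass
class SimCohort:
    """All simulated artifacts of one cohort, in memory plus file paths."""

    genome: Genome
    variants: dict[str, pd.DataFrame]
    variant_truth: pd.DataFrame
    genotypes: pd.DataFrame
    phenotypes: pd.DataFrame
    variance_ledger: dict
    coverage: pd.DataFrame
    pileups: pd.DataFrame
    paths: dict[str, str] = field(default_factory=dict)


def simulate_cohort(config: SimConfig, out_dir: str | Path | None = None) -> SimCohort:
    """Run every generator stage under one seed; optionally write all files."""
    rng = np.random.default_rng(config.seed)
    genome = build_toy_genome(config, rng)
    variants, truth = simulate_ems_variants(genome, config, rng)
    genotypes, phenotypes, ledger = simulate_f2_cohort(config, rng)
    coverage = simulate_coverage(genotypes, genome, config, rng)
    pileups = simulate_bulk_pileups(genotypes, genome, config, rng)
    cohort = SimCohort(
        genome=genome,
        variants=variants,
        variant_truth=truth,
        genotypes=genotypes,
        phenotypes=phenotypes,
        variance_ledger=ledger,
        coverage=coverage,
        pileups=pileups,
    )
    if out_dir is not None:
        from . import io as tio

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": out / "genome.fasta",
            "gff": out / "genes.gff3",
            "genotypes": out / "genotypes.tsv",
            "phenotypes": out / "phenotypes.csv",
            "coverage": out / "coverage.tsv",
            "pileups": out / "pileups.tsv",
            "truth": out / "variant_truth.tsv",
        }
        tio.write_fasta(genome.seqs, paths["fasta"])
        tio.write_gff3(genome, paths["gff"])
        genotypes.to_csv(paths["genotypes"], sep="\t", index=False)
        phenotypes.to_csv(paths["phenotypes"], index=False, float_format="%.6f")
        tio.write_coverage_table(coverage, paths["coverage"])
        pileups.to_csv(paths["pileups"], sep="\t", index=False)
        truth.to_csv(paths["truth"], sep="\t", index=False)
        vcf_dir = out / "vcf"
        vcf_dir.mkdir(exist_ok=True)
        for line_id, df in sorted(variants.items()):
            p = vcf_dir / f"{line_id}.vcf"
            tio.write_vcf(df, p, sample=line_id, contigs=genome.seqs)
            paths[f"vcf:{line_id}"] = p
        cohort.paths = {k: str(v) for k, v in paths.items()}
    return cohort
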