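"""Pseudo-bulk MutMap mapping.

Extreme-phenotype bulks (default 25 + 25 lines, low-tail as the mutant bulk
for meal ADF, high-tail for the protein traits), per-locus SNP index
(alt / total reads in the bulk), the mutant-minus-reference delta, a 5-SNP
right-aligned sliding average per chromosome, and candidate-region calling
on smoothed delta > 0.9.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("tillmap")

DEFAULT_BULK_SIZE = 25
DEFAULT_WINDOW = 5
DEFAULT_THRESHOLD = 0.9
DEFAULT_MIN_LOCI = 3
DEFAULT_MIN_BULK_DEPTH = 10

#: bulk direction holding the mutant phenotype, per trait (ADF reversed)
MUTANT_DIRECTION = {
    "seed_protein": "high",
    "meal_protein": "high",
    "meal_adf": "low",
}


@dataclass
class Bulk:
    members: list[str]
    direction: str  # "high" | "low"
    trait: str
    counts: pd.DataFrame | None = None  # per-locus summed ref/alt


@dataclass
class CandidateRegion:
    chrom: str
    start: int
    end: int
    n_loci: int
    mean_delta: float
    threshold: float = DEFAULT_THRESHOLD


def entry_means(pheno: pd.DataFrame, trait: str) -> pd.Series:
    """Per-line mean over locations and reps."""
    if trait not in pheno.columns:
        raise ValueError(f"trait {trait!r} absent from phenotype table")
    return pheno.groupby("line_id")[trait].mean()


def build_bulks(
    pheno: pd.DataFrame,
    trait: str,
    n: int = DEFAULT_BULK_SIZE,
    mutant_direction: str | None = None,
) -> tuple[Bulk, Bulk]:
    """Select the two n-line extreme bulks on entry means.

    Ties are broken by line-id order, so membership is deterministic.
    Returns (mutant bulk, reference bulk).
    """
    if mutant_direction is None:
        try:
            mutant_direction = MUTANT_DIRECTION[trait]
        except KeyError:
            raise ValueError(
                f"no default mutant direction for trait {trait!r}; pass mutant_direction"
            ) from None
    if mutant_direction not in ("high", "low"):
        raise ValueError("mutant_direction must be 'high' or 'low'")
    means = entry_means(pheno, trait).dropna()
    if len(means) < 2 * n:
        raise ValueError(f"need >= {2 * n} lines with {trait!r} values, got {len(means)}")
    ordered = means.reset_index().sort_values(
        [trait, "line_id"], kind="mergesort"
    )  # stable: ties by line id
    low = ordered.head(n).line_id.tolist()
    high = ordered.tail(n).line_id.tolist()
    if mutant_direction == "low":
        return Bulk(low, "low", trait), Bulk(high, "high", trait)
    return Bulk(high, "high", trait), Bulk(low, "low", trait)


def bulk_counts(pileups: pd.DataFrame, bulk: Bulk) -> pd.DataFrame:
    """Sum per-individual ref/alt counts over bulk members, per locus."""
    sub = pileups[pileups["sample"].isin(bulk.members)]
    agg = (
        sub.groupby(["chrom", "pos"], as_index=False)[["ref_count", "alt_count"]]
        .sum()
        .sort_values(["chrom", "pos"])
        .reset_index(drop=True)
    )
    bulk.counts = agg
    return agg


def snp_index(alt_count, total_count):
    """SNP index = alt / total reads at a locus (scalar or arrays)."""
    alt = np.asarray(alt_count, dtype=float)
    total = np.asarray(total_count, dtype=float)
    if np.any(total < 1):
        raise ValueError("total read count must be >= 1; filter zero-depth loci first")
    out = alt / total
    return float(out) if out.ndim == 0 else out


def snp_index_track(
    counts: pd.DataFrame, min_total: int = DEFAULT_MIN_BULK_DEPTH
) -> pd.DataFrame:
    """Per-locus SNP index; loci with bulk depth below ``min_total`` are
    flagged missing and excluded."""
    total = counts.ref_count + counts.alt_count
    keep = total >= max(min_total, 1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("snp_index_track: dropped %d low-depth loci", n_dropped)
    out = counts.loc[keep, ["chrom", "pos"]].copy()
    out["index"] = snp_index(counts.alt_count[keep], total[keep])
    return out.reset_index(drop=True)


def delta_snp_index(mutant: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """Delta = mutant index - reference index on the shared loci."""
    merged = mutant.merge(
        reference, on=["chrom", "pos"], suffixes=("_mut", "_ref"), how="inner"
    )
    if merged.empty:
        raise ValueError("no shared loci between the two bulks")
    merged["delta"] = merged.index_mut - merged.index_ref
    return merged.sort_values(["chrom", "pos"]).reset_index(drop=True)


def sliding_average(
    track: pd.DataFrame, k: int = DEFAULT_WINDOW, value_col: str = "delta"
) -> pd.DataFrame:
    """Right-aligned k-locus rolling mean per chromosome.

    The first k-1 loci of each chromosome carry no smoothed value;
    chromosomes with fewer than k loci are skipped with a warning.
    """
    out = track.sort_values(["chrom", "pos"]).reset_index(drop=True).copy()
    smoothed = pd.Series(np.nan, index=out.index)
    for chrom, grp in out.groupby("chrom"):
        if len(grp) < k:
            warnings.warn(f"chromosome {chrom} has fewer than {k} loci; skipped")
            continue
        smoothed.loc[grp.index] = grp[value_col].rolling(k).mean()
    out[f"{value_col}_smoothed"] = smoothed
    return out


def call_candidate_regions(
    track: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    min_loci: int = DEFAULT_MIN_LOCI,
    value_col: str = "delta_smoothed",
) -> list[CandidateRegion]:
    """Maximal runs of >= min_loci consecutive loci with smoothed value
    above the threshold; bounds are the first/last locus of each run."""
    regions: list[CandidateRegion] = []
    for chrom, grp in track.groupby("chrom"):
        vals = grp[value_col].to_numpy()
        pos = grp.pos.to_numpy()
        above = vals > threshold  # NaN compares False
        start = None
        for i, flag in enumerate(np.append(above, False)):
            if flag and start is None:
                start = i
            elif not flag and start is not None:
                if i - start >= min_loci:
                    regions.append(
                        CandidateRegion(
                            chrom=chrom,
                            start=int(pos[start]),
                            end=int(pos[i - 1]),
                            n_loci=i - start,
                            mean_delta=float(vals[start:i].mean()),
                            threshold=threshold,
                        )
                    )
                start = None
    return regions


def run_mutmap(
    pileups: pd.DataFrame,
    pheno: pd.DataFrame,
    trait: str,
    mutant_direction: str | None = None,
    n_bulk: int = DEFAULT_BULK_SIZE,
    k: int = DEFAULT_WINDOW,
    threshold: float = DEFAULT_THRESHOLD,
    min_loci: int = DEFAULT_MIN_LOCI,
    min_bulk_depth: int = DEFAULT_MIN_BULK_DEPTH,
) -> dict:
    """Full bulk-to-regions pass; returns bulks, tracks and called regions."""
    mut_bulk, ref_bulk = build_bulks(pheno, trait, n=n_bulk, mutant_direction=mutant_direction)
    mut_track = snp_index_track(bulk_counts(pileups, mut_bulk), min_total=min_bulk_depth)
    ref_track = snp_index_track(bulk_counts(pileups, ref_bulk), min_total=min_bulk_depth)
    delta = delta_snp_index(mut_track, ref_track)
    smoothed = sliding_average(delta, k=k)
    regions = call_candidate_regions(smoothed, threshold=threshold, min_loci=min_loci)
    return dict(
        mutant_bulk=mut_bulk,
        reference_bulk=ref_bulk,
        track=smoothed,
        regions=regions,
    )
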