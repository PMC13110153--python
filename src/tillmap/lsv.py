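"""Gene-coverage-ratio structural-variant detection (LSV-viz style).

Per-sample TPM normalisation of a genes x samples count matrix, per-gene
copy ratios against the across-sample median (or a designated wild-type
reference sample), sliding-window smoothing (window 20 genes, step 5),
segment calling, hemizygous/homozygous classification at the expected copy
ratios (0, 0.5, 1, 1.5, 2), cross-cohort recurrent-locus aggregation and
co-segregation statistics, and permutation-based genotype-group phenotype
association.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

logger = logging.getLogger("tillmap")

META_COLS = ["gene_id", "chrom", "start", "end", "length"]
DEFAULT_WINDOW = 20
DEFAULT_STEP = 5
DEL_THRESH = 0.75
DUP_THRESH = 1.25
MIN_WINDOWS = 3
STATES = ("wild_type", "hemizygous", "homozygous")


@dataclass
class LsvSegment:
    sample: str
    chrom: str
    start_gene: int  # 0-based rank of first member gene on the chromosome
    end_gene: int    # inclusive
    start: int       # genomic coordinates of the member-gene union
    end: int
    kind: str        # "deletion" | "duplication"
    mean_ratio: float
    zygosity: str


@dataclass
class GenotypeGroupStats:
    trait: str
    group_means: dict[str, float]
    group_ns: dict[str, int]
    group_sds: dict[str, float]
    statistic: float
    p_value: float
    n_permutations: int


def split_coverage(coverage: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a coverage table into (gene metadata, counts matrix)."""
    meta = coverage[META_COLS].reset_index(drop=True)
    counts = coverage.drop(columns=META_COLS).reset_index(drop=True)
    return meta, counts


def tpm_normalize(counts: pd.DataFrame, lengths) -> pd.DataFrame:
    """Length-normalise counts and scale each sample column to one million."""
    lengths = np.asarray(lengths, dtype=float)
    if (lengths < 1).any():
        raise ValueError("gene lengths must be >= 1")
    rates = counts.to_numpy(dtype=float) / lengths[:, None]
    totals = rates.sum(axis=0)
    zero = totals == 0
    if zero.any():
        bad = counts.columns[zero][0]
        raise ValueError(f"sample {bad!r} has all-zero counts; cannot TPM-normalise")
    tpm = rates / totals * 1e6
    return pd.DataFrame(tpm, columns=counts.columns, index=counts.index)


def median_ratio_matrix(
    tpm: pd.DataFrame, reference_sample: str | None = None, recenter: bool = True
) -> pd.DataFrame:
    """Copy ratio per gene per sample.

    Denominator is the across-sample per-gene median, or the designated
    reference sample's TPM when given.  Genes whose denominator is zero are
    masked (NaN) rather than pseudocounted.

    With ``recenter`` (default) each sample's ratio track is divided by its
    own genome-wide median ratio.  TPM is compositional: a sample carrying a
    sizeable deletion redistributes the missing mass onto every other gene,
    shifting its whole ratio track off 1; as long as most genes are
    copy-normal the per-sample median is the diploid level and recentering
    removes the shift.
    """
    if reference_sample is not None:
        if reference_sample not in tpm.columns:
            raise ValueError(f"reference sample {reference_sample!r} not in matrix")
        denom = tpm[reference_sample].to_numpy(dtype=float)
    else:
        if tpm.shape[1] < 3:
            raise ValueError("median denominator needs >= 3 samples")
        denom = np.median(tpm.to_numpy(dtype=float), axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = tpm.to_numpy(dtype=float) / denom[:, None]
    ratio[denom == 0, :] = np.nan
    n_masked = int((denom == 0).sum())
    if n_masked:
        logger.info("median_ratio_matrix: masked %d zero-denominator genes", n_masked)
    if recenter:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            centers = np.nanmedian(ratio, axis=0)
        if np.any(centers <= 0) or np.any(np.isnan(centers)):
            raise ValueError("cannot recenter: a sample has non-positive median ratio")
        ratio = ratio / centers[None, :]
    return pd.DataFrame(ratio, columns=tpm.columns, index=tpm.index)


def smooth_track(
    ratios: pd.DataFrame,
    meta: pd.DataFrame,
    w: int = DEFAULT_WINDOW,
    s: int = DEFAULT_STEP,
) -> pd.DataFrame:
    """Sliding-window means over gene rank, per chromosome.

    Window j covers genes [j*s, j*s + w); a chromosome contributes
    floor((n_genes - w)/s) + 1 windows and is skipped (with a warning) when
    it has fewer than w genes.  Masked (NaN) genes are ignored within each
    window.  Returns a long-format frame: chrom, window, start_gene,
    end_gene, start, end, then one column per sample.
    """
    if not meta.start.groupby(meta.chrom).is_monotonic_increasing.all():
        raise ValueError("genes must be position-sorted within chromosomes")
    frames = []
    for chrom, grp in meta.groupby("chrom", sort=True):
        n = len(grp)
        if n < w:
            warnings.warn(f"chromosome {chrom} has {n} < {w} genes; skipped")
            continue
        idx = grp.index.to_numpy()
        vals = ratios.loc[idx].to_numpy(dtype=float)
        n_win = (n - w) // s + 1
        starts = np.arange(n_win) * s
        windows = sliding_window_view(vals, w, axis=0)[starts]  # (n_win, samples, w)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
            means = np.nanmean(windows, axis=2)
        block = pd.DataFrame(means, columns=ratios.columns)
        block.insert(0, "chrom", chrom)
        block.insert(1, "window", np.arange(n_win))
        block.insert(2, "start_gene", starts)
        block.insert(3, "end_gene", starts + w - 1)
        block.insert(4, "start", grp.start.to_numpy()[starts])
        block.insert(5, "end", grp.end.to_numpy()[starts + w - 1])
        frames.append(block)
    if not frames:
        raise ValueError("no chromosome had enough genes to smooth")
    return pd.concat(frames, ignore_index=True)


def classify_zygosity(mean_ratio: float, kind: str) -> str:
    """Zygosity bands at the midpoints of expected copy ratios.

    deletion: < 0.25 homozygous, 0.25-0.75 hemizygous;
    duplication: >= 1.75 homozygous, 1.25-1.75 hemizygous.
    """
    if kind == "deletion":
        if mean_ratio < 0.25:
            return "homozygous"
        if mean_ratio <= DEL_THRESH:
            return "hemizygous"
    elif kind == "duplication":
        if mean_ratio >= 1.75:
            return "homozygous"
        if mean_ratio >= DUP_THRESH:
            return "hemizygous"
    else:
        raise ValueError(f"unknown segment kind {kind!r}")
    raise ValueError(f"mean ratio {mean_ratio:.3f} is in the normal band; not a segment")


def call_lsv_segments(
    windows: pd.DataFrame,
    meta: pd.DataFrame,
    ratios: pd.DataFrame,
    del_thresh: float = DEL_THRESH,
    dup_thresh: float = DUP_THRESH,
    min_windows: int = MIN_WINDOWS,
    samples: list[str] | None = None,
) -> pd.DataFrame:
    """Call deletion/duplication segments per sample from smoothed windows.

    A segment is a maximal run of >= min_windows consecutive windows below
    del_thresh (deletion) or above dup_thresh (duplication); its gene span
    is the union of member windows.  Zygosity comes from the raw ratios of
    the member genes (not the window values, to avoid double-smoothing),
    summarised by their median: the union overhangs the true copy-number
    boundary by up to a window on each side, and the median is robust to
    those normal-copy edge genes where the mean is biased toward 1.
    Runs whose member-gene median falls in the normal band are discarded as
    smoothing artifacts.
    """
    if samples is None:
        samples = [c for c in windows.columns if c not in
                   ("chrom", "window", "start_gene", "end_gene", "start", "end")]
    rows = []
    for chrom, grp in windows.groupby("chrom", sort=True):
        gmeta = meta[meta.chrom == chrom].reset_index(drop=True)
        gratio = ratios.loc[meta.index[meta.chrom == chrom]].reset_index(drop=True)
        sg = grp.start_gene.to_numpy()
        eg = grp.end_gene.to_numpy()
        for sample in samples:
            vals = grp[sample].to_numpy(dtype=float)
            for kind, mask in (
                ("deletion", vals < del_thresh),
                ("duplication", vals > dup_thresh),
            ):
                for i0, i1 in _runs(mask, min_windows):
                    g0, g1 = int(sg[i0]), int(eg[i1 - 1])
                    member = gratio[sample].to_numpy(dtype=float)[g0 : g1 + 1]
                    level = float(np.nanmedian(member))
                    try:
                        zygosity = classify_zygosity(level, kind)
                    except ValueError:
                        logger.debug(
                            "dropped %s run on %s (%s): member median %.3f in normal band",
                            kind, chrom, sample, level,
                        )
                        continue
                    rows.append(
                        dict(
                            sample=sample,
                            chrom=chrom,
                            start_gene=g0,
                            end_gene=g1,
                            start=int(gmeta.start.iloc[g0]),
                            end=int(gmeta.end.iloc[g1]),
                            kind=kind,
                            mean_ratio=level,
                            zygosity=zygosity,
                        )
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "sample", "chrom", "start_gene", "end_gene", "start", "end",
            "kind", "mean_ratio", "zygosity",
        ],
    )


def _runs(mask: np.ndarray, min_len: int):
    """Maximal True runs of length >= min_len as (start, stop) index pairs."""
    out, start = [], None
    for i, flag in enumerate(np.append(mask, False)):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= min_len:
                out.append((start, i))
            start = None
    return out


# ---------------------------------------------------------------------------
# cohort-level aggregation
# ---------------------------------------------------------------------------


def recurrent_loci(
    segments: pd.DataFrame,
    n_samples: int,
    min_carrier_fraction: float = 0.05,
    trim_fraction: float = 0.5,
    core_trim: int = DEFAULT_WINDOW - DEFAULT_STEP,
    meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Consensus recurrent loci from per-sample segments.

    For every gene the number of distinct carrier samples whose segments
    cover it is counted; maximal gene runs with support >= the carrier
    minimum (``min_carrier_fraction`` of the cohort, at least 2) become
    loci, with bounds trimmed to genes supported by at least
    ``trim_fraction`` of the run's peak support.  Consensus support (rather
    than an interval union) keeps sporadic per-sample noise segments from
    chaining into or widening loci: window-level calls overhang the true
    copy-number boundary, but the overhang support decays where the shared
    boundary is, so the trimmed consensus tracks the recurrent event.
    Genomic coordinates are taken from ``meta`` when given.
    """
    min_carriers = max(2, int(np.ceil(min_carrier_fraction * n_samples)))
    loci = []
    for chrom, grp in segments.groupby("chrom", sort=True):
        n_genes = int(grp.end_gene.max()) + 1
        samples = grp["sample"].unique()
        covered = np.zeros((n_genes, len(samples)), dtype=bool)
        s_idx = {s: j for j, s in enumerate(samples)}
        for r in grp.itertuples():
            covered[r.start_gene : r.end_gene + 1, s_idx[r.sample]] = True
        support = covered.sum(axis=1)
        for g0, g1 in _runs(support >= min_carriers, 1):
            peak = int(support[g0:g1].max())
            core = np.flatnonzero(support[g0:g1] >= max(min_carriers, trim_fraction * peak))
            c0, c1 = g0 + int(core[0]), g0 + int(core[-1])
            # consensus core: interior genes clear of boundary effects.
            # Window-level calls overhang the true copy-number boundary by
            # up to (window - min tipping genes) on each side, so shave
            # core_trim genes per side off the trimmed bounds (capped at a
            # third of the span each, so a core always remains).
            shave = min(core_trim, (c1 - c0) // 3)
            d0, d1 = c0 + shave, c1 - shave
            carriers = int(covered[c0 : c1 + 1].any(axis=0).sum())
            if meta is not None:
                sub = meta[meta.chrom == chrom].reset_index(drop=True)
                start, end = int(sub.start.iloc[c0]), int(sub.end.iloc[c1])
            else:
                hits = grp[(grp.start_gene <= c1) & (grp.end_gene >= c0)]
                start, end = int(hits.start.min()), int(hits.end.max())
            loci.append(
                dict(
                    chrom=chrom,
                    start_gene=c0,
                    end_gene=c1,
                    core_start_gene=d0,
                    core_end_gene=d1,
                    start=start,
                    end=end,
                    kind=str(
                        grp[(grp.start_gene <= c1) & (grp.end_gene >= c0)].kind.mode().iloc[0]
                    ),
                    n_carriers=carriers,
                )
            )
    out = pd.DataFrame(
        loci,
        columns=["chrom", "start_gene", "end_gene", "core_start_gene", "core_end_gene",
                 "start", "end", "kind", "n_carriers"],
    )
    out.insert(0, "locus_id", [f"L{i + 1}" for i in range(len(out))])
    return out


#: (state, kind) bands over the calibrated copy ratio, midpoints between the
#: expected levels 0, 0.5, 1, 1.5, 2
_COPY_BANDS = (
    (0.25, "homozygous", "deletion"),
    (0.75, "hemizygous", "deletion"),
    (1.25, "wild_type", None),
    (1.75, "hemizygous", "duplication"),
    (np.inf, "homozygous", "duplication"),
)


def locus_level(ratios: pd.DataFrame, meta: pd.DataFrame, locus) -> pd.Series:
    """Per-sample mean ratio over a locus's consensus-core genes.

    The core (when present, from :func:`recurrent_loci`) excludes the
    boundary genes that window overhang drags into the locus, so a plain
    mean is unbiased there and more efficient than a median.
    """
    g0 = int(getattr(locus, "core_start_gene", locus.start_gene))
    g1 = int(getattr(locus, "core_end_gene", locus.end_gene))
    sub = meta[meta.chrom == locus.chrom].reset_index()
    idx = sub.loc[g0:g1, "index"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return ratios.loc[idx].mean()


_COPY_CLASSES = np.array([0.0, 0.5, 1.0, 1.5, 2.0])


def _refined_anchor(levels: pd.Series, calibrate_sample: str) -> float:
    """Copy-normal anchor level for one locus.

    Sample levels at a segregating locus cluster at multiples
    {0, 0.5, 1, 1.5, 2} of an unknown scale.  The calibration sample (a
    known copy-normal individual) gives a first estimate of that scale, but
    a single shallow-coverage sample carries several percent of sampling
    error, enough to push calibrated copy ratios across a zygosity band.
    The scale is therefore refit against the whole cohort: a grid around
    the first estimate minimising the squared distance of every level to
    its nearest class multiple, then one least-squares pass under the
    implied class assignment.
    """
    a0 = levels.get(calibrate_sample, np.nan)
    if not np.isfinite(a0) or a0 <= 0:
        return float("nan")
    vals = levels.to_numpy(dtype=float)
    vals = vals[np.isfinite(vals)]
    best_s, best_obj = a0, np.inf
    for s in a0 * np.linspace(0.7, 1.4, 71):
        resid = np.abs(vals[:, None] - s * _COPY_CLASSES[None, :]).min(axis=1)
        obj = float((resid**2).mean())
        if obj < best_obj:
            best_obj, best_s = obj, s
    assigned = _COPY_CLASSES[
        np.argmin(np.abs(vals[:, None] - best_s * _COPY_CLASSES[None, :]), axis=1)
    ]
    carriers = assigned > 0
    if carriers.any():
        best_s = float(
            (assigned[carriers] * vals[carriers]).sum() / (assigned[carriers] ** 2).sum()
        )
    return best_s


def locus_states(
    ratios: pd.DataFrame,
    meta: pd.DataFrame,
    loci: pd.DataFrame,
    samples: list[str],
    calibrate_sample: str | None = None,
) -> pd.DataFrame:
    """Per-sample genotype state at each recurrent locus.

    Each sample's locus level (mean ratio over consensus-core genes) is
    converted to a copy ratio and banded at the midpoints of the expected
    levels 0/0.5/1/1.5/2.  When ``calibrate_sample`` names a known
    copy-normal sample (e.g. the wild-type parent), levels are divided by
    the refined copy-normal anchor first: with a median denominator and a
    high-frequency variant, the per-gene cohort median is itself a carrier
    class, and the calibration restores the absolute copy scale.
    """
    out = pd.DataFrame("wild_type", index=list(samples), columns=loci.locus_id)
    for loc in loci.itertuples():
        levels = locus_level(ratios, meta, loc)
        if calibrate_sample is not None:
            anchor = _refined_anchor(levels, calibrate_sample)
            if not np.isfinite(anchor):
                warnings.warn(
                    f"locus {loc.locus_id}: unusable calibration level; skipped"
                )
                continue
            levels = levels / anchor
        for sample in samples:
            copy_ratio = levels[sample]
            if not np.isfinite(copy_ratio):
                continue
            for bound, state, _kind in _COPY_BANDS:
                if copy_ratio < bound:
                    out.loc[sample, loc.locus_id] = state
                    break
    return out


def assign_locus_kinds(
    ratios: pd.DataFrame,
    meta: pd.DataFrame,
    loci: pd.DataFrame,
    samples: list[str],
    calibrate_sample: str | None = None,
) -> pd.DataFrame:
    """Re-derive each locus's kind from the calibrated copy ratios.

    The majority variant type among non-wild-type samples decides; this is
    robust to the relabelling a median denominator causes at high-frequency
    loci (where wild-type samples are the ones deviating from the cohort
    median).
    """
    loci = loci.copy()
    for i, loc in enumerate(loci.itertuples()):
        levels = locus_level(ratios, meta, loc)
        if calibrate_sample is not None:
            anchor = _refined_anchor(levels, calibrate_sample)
            if np.isfinite(anchor):
                levels = levels / anchor
        kinds = []
        for sample in samples:
            v = levels.get(sample, np.nan)
            if not np.isfinite(v):
                continue
            for bound, state, kind in _COPY_BANDS:
                if v < bound:
                    if kind is not None:
                        kinds.append(kind)
                    break
        if kinds:
            loci.loc[loci.index[i], "kind"] = pd.Series(kinds).mode().iloc[0]
    return loci


def cosegregation_matrix(states: pd.DataFrame) -> pd.DataFrame:
    """Pairwise concordance and chi-square independence across loci.

    Concordance is the fraction of samples with identical state at the two
    loci; the chi-square statistic/p-value test independence of the state
    contingency table.  Loci with no variant calls at all are excluded with
    a warning.
    """
    loci = []
    for c in states.columns:
        if (states[c] == "wild_type").all():
            warnings.warn(f"locus {c} has no variant calls; excluded")
        else:
            loci.append(c)
    rows = []
    for i, a in enumerate(loci):
        for b in loci[i + 1 :]:
            conc = float((states[a] == states[b]).mean())
            table = pd.crosstab(states[a], states[b])
            if table.shape[0] > 1 and table.shape[1] > 1:
                chi2, p, dof, _ = stats.chi2_contingency(table)
            else:
                chi2, p, dof = 0.0, 1.0, 0
            rows.append(
                dict(
                    locus_a=a,
                    locus_b=b,
                    concordance=conc,
                    chi2=float(chi2),
                    p_value=float(p),
                    dof=int(dof),
                )
            )
    return pd.DataFrame(rows)


_SEVERITY = {"wild_type": 0, "hemizygous": 1, "homozygous": 2}


def genotype_group_association(
    calls: pd.Series,
    pheno: pd.DataFrame,
    trait: str,
    n_permutations: int = 10_000,
    rng: np.random.Generator | None = None,
) -> GenotypeGroupStats:
    """Group phenotypes by genotype class and test the association.

    ``calls`` maps line id -> state in {wild_type, hemizygous, homozygous}.
    The statistic is the difference of entry-mean trait means between the
    most-severe present class and wild type; significance by two-sided
    permutation of trait labels.  Absent classes are reported as absent.
    """
    from .mutmap import entry_means

    if rng is None:
        rng = np.random.default_rng(0)
    means = entry_means(pheno, trait)
    common = means.index.intersection(calls.index)
    y = means.loc[common].to_numpy(dtype=float)
    g = calls.loc[common].to_numpy()
    group_means, group_ns, group_sds = {}, {}, {}
    for state in STATES:
        mask = g == state
        group_ns[state] = int(mask.sum())
        group_means[state] = float(y[mask].mean()) if mask.any() else float("nan")
        group_sds[state] = float(y[mask].std(ddof=1)) if mask.sum() > 1 else float("nan")
    present = [s for s in STATES if group_ns[s] > 0]
    top = max(present, key=lambda s: _SEVERITY[s])
    if "wild_type" not in present or top == "wild_type":
        return GenotypeGroupStats(trait, group_means, group_ns, group_sds, 0.0, 1.0, 0)
    mask_top = g == top
    mask_wt = g == "wild_type"
    stat = float(y[mask_top].mean() - y[mask_wt].mean())
    # vectorised label permutation: shuffle phenotypes, masks fixed
    perm = np.tile(y, (n_permutations, 1))
    perm = rng.permuted(perm, axis=1)
    perm_stat = perm[:, mask_top].mean(axis=1) - perm[:, mask_wt].mean(axis=1)
    p = float((1 + np.sum(np.abs(perm_stat) >= abs(stat))) / (1 + n_permutations))
    return GenotypeGroupStats(trait, group_means, group_ns, group_sds, stat, p, n_permutations)


def run_lsv(
    coverage: pd.DataFrame,
    w: int = DEFAULT_WINDOW,
    s: int = DEFAULT_STEP,
    del_thresh: float = DEL_THRESH,
    dup_thresh: float = DUP_THRESH,
    min_windows: int = MIN_WINDOWS,
    reference_sample: str | None = None,
    calibrate_sample: str | None = None,
    exclude_reference: bool = True,
    min_carrier_fraction: float = 0.05,
    recenter: bool = True,
) -> dict:
    """Coverage table -> TPM -> ratios -> windows -> segments -> loci/states.

    ``reference_sample`` switches the per-gene ratio denominator from the
    cohort median to that sample's TPM; ``calibrate_sample`` names a known
    copy-normal sample used only to anchor the per-locus copy scale when
    typing states (needed with a median denominator whenever a variant is
    frequent enough that the cohort median is itself a carrier class).
    """
    meta, counts = split_coverage(coverage)
    tpm = tpm_normalize(counts, meta.length)
    ratios = median_ratio_matrix(tpm, reference_sample=reference_sample, recenter=recenter)
    call_samples = list(ratios.columns)
    drop = {reference_sample if exclude_reference else None, calibrate_sample} - {None}
    call_samples = [c for c in call_samples if c not in drop]
    windows = smooth_track(ratios, meta, w=w, s=s)
    segments = call_lsv_segments(
        windows, meta, ratios,
        del_thresh=del_thresh, dup_thresh=dup_thresh,
        min_windows=min_windows, samples=call_samples,
    )
    loci = recurrent_loci(segments, n_samples=len(call_samples),
                          min_carrier_fraction=min_carrier_fraction,
                          core_trim=w - s, meta=meta)
    loci = assign_locus_kinds(ratios, meta, loci, call_samples,
                              calibrate_sample=calibrate_sample)
    states = locus_states(ratios, meta, loci, call_samples,
                          calibrate_sample=calibrate_sample)
    return dict(
        tpm=tpm, ratios=ratios, windows=windows, segments=segments,
        loci=loci, states=states, meta=meta,
    )
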