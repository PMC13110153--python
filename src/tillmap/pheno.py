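"""Trait summaries and broad-sense heritability.

Entry means (per-line means over locations and reps), mid-parent values,
range spans, coefficient of variation, the standard error of a difference,
and a balanced two-way method-of-moments decomposition
``Y = m + L + G + G*L + residual`` (genotype and genotype-by-location
random) yielding entry-mean broad-sense heritability
``H2 = V_G / (V_G + V_GL/L + V_E/(L*R))``.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mutmap import entry_means

logger = logging.getLogger("tillmap")

TRAITS = ("seed_oil", "seed_protein", "meal_protein", "meal_adf")


@dataclass
class VarianceComponents:
    v_g: float
    v_gl: float
    v_e: float
    n_locations: int
    n_reps: int
    truncated: bool = False  # any negative estimate clipped to zero


@dataclass
class TraitSummary:
    trait: str
    mean: float
    min: float
    max: float
    range_span: float  # rounded to 1 decimal for reporting
    cv: float | None = None
    sed: float | None = None
    h2: float | None = None


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the tables' reporting convention)."""
    factor = 10 ** decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def trait_summary(table: pd.DataFrame, trait: str) -> TraitSummary:
    """Population summary over entry means: mean, min, max and range span."""
    means = entry_means(table, trait).dropna()
    if means.empty:
        raise ValueError(f"no observations for trait {trait!r}")
    lo, hi = float(means.min()), float(means.max())
    return TraitSummary(
        trait=trait,
        mean=float(means.mean()),
        min=lo,
        max=hi,
        range_span=round_half_away(hi - lo, 1),
    )


def mid_parent(p1_value: float, p2_value: float) -> float:
    """Arithmetic mean of the two parents, reported to 1 decimal."""
    if p1_value is None or p2_value is None or np.isnan(p1_value) or np.isnan(p2_value):
        raise ValueError("both parent values are required")
    return round_half_away((p1_value + p2_value) / 2.0, 1)


def coefficient_of_variation(table: pd.DataFrame, trait: str) -> float:
    """CV% = 100 x SD of entry means / mean of entry means."""
    means = entry_means(table, trait).dropna()
    m = means.mean()
    if m == 0:
        raise ValueError("zero mean; CV undefined")
    return float(100.0 * means.std(ddof=1) / m)


def variance_components(table: pd.DataFrame, trait: str) -> VarianceComponents:
    """Method-of-moments components from the line x location mean squares.

    Requires >= 2 lines and >= 2 locations.  Near-balanced data is balanced
    by cell-mean imputation (with a warning); negative estimates are
    truncated at zero and flagged.
    """
    df = table[["line_id", "location", trait]].dropna()
    lines = df.line_id.unique()
    locs = df.location.unique()
    G, L = len(lines), len(locs)
    if G < 2:
        raise ValueError("need >= 2 lines")
    if L < 2:
        raise ValueError("G x L inestimable with a single location")
    cell_counts = df.groupby(["line_id", "location"])[trait].count()
    R = int(cell_counts.max())
    if cell_counts.min() != R or len(cell_counts) != G * L:
        warnings.warn("unbalanced design: imputing missing cells by cell means")
        df = _balance(df, trait, lines, locs, R)
    y = df.set_index(["line_id", "location"])[trait]
    grand = y.mean()
    line_means = y.groupby("line_id").mean()
    loc_means = y.groupby("location").mean()
    cell_means = y.groupby(["line_id", "location"]).mean()
    ss_g = L * R * ((line_means - grand) ** 2).sum()
    interaction = (
        cell_means
        - line_means.reindex(cell_means.index.get_level_values(0)).to_numpy()
        - loc_means.reindex(cell_means.index.get_level_values(1)).to_numpy()
        + grand
    )
    ss_gl = R * (interaction ** 2).sum()
    ss_e = ((y - cell_means.reindex(y.index)) ** 2).sum()
    ms_g = ss_g / (G - 1)
    ms_gl = ss_gl / ((G - 1) * (L - 1))
    ms_e = ss_e / (G * L * (R - 1)) if R > 1 else 0.0
    if R == 1:
        raise ValueError("residual inestimable with a single rep per cell")
    v_e = ms_e
    v_gl = (ms_gl - ms_e) / R
    v_g = (ms_g - ms_gl) / (L * R)
    truncated = v_gl < 0 or v_g < 0
    if truncated:
        warnings.warn("negative variance estimate truncated at zero")
    return VarianceComponents(
        v_g=max(v_g, 0.0),
        v_gl=max(v_gl, 0.0),
        v_e=float(v_e),
        n_locations=L,
        n_reps=R,
        truncated=truncated,
    )


def _balance(df, trait, lines, locs, R):
    full = pd.MultiIndex.from_product([lines, locs], names=["line_id", "location"])
    cell_means = df.groupby(["line_id", "location"])[trait].mean().reindex(full)
    # empty cells fall back to the line mean, then the grand mean
    line_means = df.groupby("line_id")[trait].mean()
    fill = cell_means.isna()
    cell_means[fill] = line_means.reindex(
        cell_means.index.get_level_values(0)[fill]
    ).to_numpy()
    cell_means = cell_means.fillna(df[trait].mean())
    rows = []
    have = df.groupby(["line_id", "location"])[trait].count()
    for (lid, loc), mean in cell_means.items():
        n = int(have.get((lid, loc), 0))
        sub = df[(df.line_id == lid) & (df.location == loc)][trait].tolist()
        sub += [mean] * (R - n)
        rows += [dict(line_id=lid, location=loc, **{trait: v}) for v in sub]
    return pd.DataFrame(rows)


def broad_sense_heritability(components: VarianceComponents, clamp: bool = True) -> float:
    """Entry-mean H2 = V_G / (V_G + V_GL/L + V_E/(L*R))."""
    denom = (
        components.v_g
        + components.v_gl / components.n_locations
        + components.v_e / (components.n_locations * components.n_reps)
    )
    if denom == 0:
        raise ValueError("all variance components are zero; H2 undefined")
    h2 = components.v_g / denom
    return float(min(max(h2, 0.0), 1.0)) if clamp else float(h2)


def sed(components: VarianceComponents) -> float:
    """Standard error of a difference between entry means (residual basis)."""
    return float(
        np.sqrt(2.0 * components.v_e / (components.n_locations * components.n_reps))
    )


def summarize_traits(table: pd.DataFrame, traits=TRAITS) -> pd.DataFrame:
    """One row per trait: mean, min, max, span, CV, SED, H2."""
    rows = []
    for trait in traits:
        summ = trait_summary(table, trait)
        summ.cv = coefficient_of_variation(table, trait)
        comps = variance_components(table, trait)
        summ.sed = sed(comps)
        summ.h2 = broad_sense_heritability(comps)
        rows.append(
            dict(
                trait=trait, mean=summ.mean, min=summ.min, max=summ.max,
                range_span=summ.range_span, cv=summ.cv, sed=summ.sed, h2=summ.h2,
            )
        )
    return pd.DataFrame(rows)
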