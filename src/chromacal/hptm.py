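"""Histone-PTM relative abundance from peptidoform intensities.

A peptidoform table has one row per quantified peptide ion, an ``annotations``
column of semicolon-separated ``histone:residue:state`` triplets (state e.g.
``un``, ``me1``, ``me2``, ``me3``, ``ac``), and one intensity column per
sample. The relative abundance of a modification state at a residue is the
percentage its peptidoforms contribute to all peptidoforms covering that
residue in any state — so for each (histone, residue) and sample the state
abundances sum to 100. A co-modified peptidoform contributes its full
intensity to every residue it annotates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests


def sample_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in ("peptide_id", "annotations")]


def parse_annotations(cell: str) -> list[tuple[str, str, str]]:
    triplets = []
    for chunk in str(cell).split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split(":")
        if len(parts) != 3:
            raise ValueError(f"malformed annotation {chunk!r}")
        triplets.append((parts[0], parts[1], parts[2]))
    if not triplets:
        raise ValueError("peptidoform row with no residue annotations")
    return triplets


def normalize_total(table: pd.DataFrame) -> pd.DataFrame:
    """Scale every sample so its total intensity equals the grand mean total.

    Downstream relative abundances are scale-invariant, so this only matters
    for cross-sample displays of raw intensities.
    """
    cols = sample_columns(table)
    totals = table[cols].sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"samples with zero total intensity: {bad}")
    target = totals.mean()
    out = table.copy()
    out[cols] = table[cols] * (target / totals)
    return out


def rollup_relative_abundance(table: pd.DataFrame) -> pd.DataFrame:
    """Roll peptidoform intensities up to per-residue state percentages.

    Returns a frame keyed by (histone, residue, state) with one percentage
    column per sample. A residue with zero total intensity in a sample gets
    NaN there (flagged with a warning).
    """
    cols = sample_columns(table)
    num: dict[tuple[str, str, str], np.ndarray] = {}
    den: dict[tuple[str, str], np.ndarray] = {}
    for _, row in table.iterrows():
        intensity = row[cols].to_numpy(dtype=float)
        for histone, residue, state in parse_annotations(row["annotations"]):
            key = (histone, residue, state)
            num[key] = num.get(key, 0) + intensity
            rkey = (histone, residue)
            den[rkey] = den.get(rkey, 0) + intensity
    rows = []
    for (histone, residue, state), total in num.items():
        d = den[(histone, residue)]
        with np.errstate(divide="ignore", invalid="ignore"):
            abundance = np.where(d > 0, 100.0 * total / np.where(d > 0, d, 1.0), np.nan)
        if np.isnan(abundance).any():
            warnings.warn(
                f"residue {histone}{residue} has zero total intensity in some "
                "samples; abundance undefined there",
                stacklevel=2,
            )
        rows.append((histone, residue, state, *abundance))
    return pd.DataFrame(rows, columns=["histone", "residue", "state", *cols])


def hptm_differential(
    abund: pd.DataFrame,
    design: Mapping[str, str],
    alpha: float = 0.05,
    pseudocount: float = 0.01,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-state log2FC and Student t-test between two conditions, with BH
    correction across all states tested.

    ``abund`` is a rollup frame; ``design`` maps sample column -> condition.
    log2FC compares condition means of the percentage abundances with a small
    pseudocount (percentage points). Zero variance in both groups with equal
    means yields p = 1 by convention.
    """
    conditions = sorted(set(design.values()))
    if len(conditions) != 2:
        raise ValueError(f"need exactly 2 conditions, got {conditions}")
    cond1, cond2 = conditions
    s1 = [s for s, c in design.items() if c == cond1]
    s2 = [s for s, c in design.items() if c == cond2]
    if len(s1) < 2 or len(s2) < 2:
        raise ValueError("need >= 2 samples per condition")
    a = abund[s1].to_numpy(dtype=float)
    b = abund[s2].to_numpy(dtype=float)
    m1 = np.nanmean(a, axis=1)
    m2 = np.nanmean(b, axis=1)
    log2fc = np.log2(m1 + pseudocount) - np.log2(m2 + pseudocount)
    p = np.ones(len(abund))
    for i in range(len(abund)):
        x = a[i][~np.isnan(a[i])]
        y = b[i][~np.isnan(b[i])]
        if len(x) < 2 or len(y) < 2:
            p[i] = np.nan
            continue
        if x.std() == 0 and y.std() == 0:
            p[i] = 1.0 if x.mean() == y.mean() else 0.0
            continue
        p[i] = stats.ttest_ind(x, y, equal_var=equal_var).pvalue
    tested = ~np.isnan(p)
    q = np.full(len(abund), np.nan)
    if tested.any():
        q[tested] = multipletests(p[tested], method="fdr_bh")[1]
    out = abund.copy()
    out[f"mean_{cond1}"] = m1
    out[f"mean_{cond2}"] = m2
    out["log2fc"] = log2fc
    out["p"] = p
    out["q"] = q
    out["significant"] = q < alpha
    return out


@dataclass
class CrossDatasetFit:
    """OLS comparison of per-state fold changes from two datasets."""

    states: list[str]
    slope: float
    intercept: float
    r: float
    ci_lower: np.ndarray  # 95% CI of the mean response at each shared state
    ci_upper: np.ndarray
    x: np.ndarray
    y: np.ndarray


def cross_dataset_compare(
    x: Mapping[str, float], y: Mapping[str, float]
) -> CrossDatasetFit:
    """Regress dataset-y log2FCs on dataset-x log2FCs over shared states.

    Only states measured in both datasets are retained. Returns the OLS
    slope/intercept, Pearson r, and the pointwise 95% confidence band of the
    mean response.
    """
    shared = sorted(set(x) & set(y))
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared states, got {len(shared)}")
    xv = np.array([x[s] for s in shared], dtype=float)
    yv = np.array([y[s] for s in shared], dtype=float)
    X = sm.add_constant(xv)
    fit = sm.OLS(yv, X).fit()
    pred = fit.get_prediction(X).summary_frame(alpha=0.05)
    r = float(stats.pearsonr(xv, yv)[0]) if np.ptp(xv) > 0 and np.ptp(yv) > 0 else np.nan
    return CrossDatasetFit(
        states=shared,
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r=r,
        ci_lower=pred["mean_ci_lower"].to_numpy(),
        ci_upper=pred["mean_ci_upper"].to_numpy(),
        x=xv,
        y=yv,
    )
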