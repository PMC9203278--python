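"""Chromatin-proteome differential screening on label-free (LFQ) matrices.

The matrix carries one row per protein with boolean flag columns
(``reverse``, ``contaminant``, ``only_identified_by_site``) and one log2
intensity column per sample (NaN = not detected). The screen mirrors standard
label-free practice: drop flagged rows, require three valid values in at
least one group, impute the remaining missing values from a down-shifted
per-sample normal distribution (missingness is assumed to reflect censoring
at the detection limit), then call differentials with a two-sided Student
t-test gated by fold change (P < 0.05 and FC > 2 by default, no
multiple-testing correction — BH is available but off by default).
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

FLAG_COLUMNS = ("reverse", "contaminant", "only_identified_by_site")


def sample_columns(matrix: pd.DataFrame) -> list[str]:
    return [
        c
        for c in matrix.columns
        if c not in ("protein_id",) and c not in FLAG_COLUMNS
    ]


def filter_proteins(
    matrix: pd.DataFrame, design: Mapping[str, str], min_valid: int = 3
) -> pd.DataFrame:
    """Drop flagged rows, then keep rows with >= min_valid non-missing values
    in at least one group."""
    out = matrix
    for flag in FLAG_COLUMNS:
        if flag in out.columns:
            out = out[~out[flag].astype(bool)]
    groups: dict[str, list[str]] = {}
    for sample, group in design.items():
        groups.setdefault(group, []).append(sample)
    keep = np.zeros(len(out), dtype=bool)
    for cols in groups.values():
        keep |= out[cols].notna().sum(axis=1).to_numpy() >= min_valid
    return out[keep].reset_index(drop=True)


def impute_missing(
    matrix: pd.DataFrame,
    width: float = 0.3,
    downshift: float = 1.8,
    seed: int = 0,
) -> pd.DataFrame:
    """Impute missing values column-wise from a down-shifted normal.

    Per sample with observed mean mu and SD sigma, missing entries are drawn
    from Normal(mu - downshift * sigma, (width * sigma)^2) — the conventional
    defaults for detection-limit imputation. Observed values are never
    altered; the draw is deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    out = matrix.copy()
    for col in sample_columns(matrix):
        values = out[col].to_numpy(dtype=float)
        observed = values[~np.isnan(values)]
        missing = np.isnan(values)
        if not missing.any():
            continue
        if len(observed) < 2:
            raise ValueError(
                f"sample {col!r} has fewer than 2 observed values; "
                "imputation SD undefined"
            )
        mu, sigma = observed.mean(), observed.std(ddof=1)
        values[missing] = rng.normal(
            mu - downshift * sigma, width * sigma, size=int(missing.sum())
        )
        out[col] = values
    return out


def differential_proteins(
    matrix: pd.DataFrame,
    design: Mapping[str, str],
    alpha: float = 0.05,
    fc_min: float = 2.0,
    adjust: bool = False,
) -> pd.DataFrame:
    """Two-sided Student t-test per protein with a fold-change gate.

    log2FC is the difference of group means (first group minus second, groups
    ordered alphabetically); a protein is significant iff p < alpha and
    |log2FC| > log2(fc_min). ``adjust`` adds a BH q column and gates on it
    instead of raw p.
    """
    groups = sorted(set(design.values()))
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    g1 = [s for s, g in design.items() if g == groups[0]]
    g2 = [s for s, g in design.items() if g == groups[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("need >= 2 samples per group")
    a = matrix[g1].to_numpy(dtype=float)
    b = matrix[g2].to_numpy(dtype=float)
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    p = np.ones(len(matrix))
    for i in range(len(matrix)):
        if a[i].std() == 0 and b[i].std() == 0:
            p[i] = 1.0 if a[i].mean() == b[i].mean() else 0.0
            continue
        p[i] = stats.ttest_ind(a[i], b[i], equal_var=True).pvalue
    out = pd.DataFrame(
        {
            "protein_id": matrix["protein_id"].to_numpy(),
            f"mean_{groups[0]}": a.mean(axis=1),
            f"mean_{groups[1]}": b.mean(axis=1),
            "log2fc": log2fc,
            "p": p,
            "neg_log10_p": -np.log10(np.clip(p, 1e-300, None)),
        }
    )
    gate = np.abs(log2fc) > np.log2(fc_min)
    if adjust:
        out["q"] = multipletests(p, method="fdr_bh")[1]
        out["significant"] = (out["q"] < alpha) & gate
    else:
        out["significant"] = (p < alpha) & gate
    return out
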