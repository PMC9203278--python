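"""Writer/eraser-mark concordance: joining modifier-protein fold changes with
histone-mark fold changes over a curated write/erase edge network.

Each edge connects a chromatin modifier (protein) to the mark it writes or
erases. If the modifier's chromatin abundance drives the mark, a writer's
fold change should share the mark's sign and an eraser's should oppose it.
The scorer formalises that as a sign rule with a neutrality band: edges where
either fold change is small (|log2FC| < threshold) are neutral; otherwise the
edge is concordant iff sign(mark FC) == expected_sign x sign(modifier FC),
with expected_sign +1 for writes and -1 for erases. Edges whose modifier or
mark was not measured are carried with status "missing" (the grey nodes of an
integration diagram). Discordant writer/eraser edges are the interesting
ones: they indicate modifier activity changing independently of modifier
abundance on chromatin.
"""

from __future__ import annotations

from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

RELATIONS = ("writes", "erases")
EXPECTED_SIGN = {"writes": 1, "erases": -1}


def load_writer_eraser_edges() -> pd.DataFrame:
    """The curated write/erase edge table shipped with the package
    (modifier, mark, relation); user-replaceable with any same-shaped TSV."""
    with resources.files("chromacal.data").joinpath(
        "writer_eraser_edges.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")


def build_network(
    edges: pd.DataFrame,
    protein_fc: Mapping[str, float],
    mark_fc: Mapping[str, float],
) -> pd.DataFrame:
    """Join fold changes onto the edge list.

    Edges whose modifier or mark lacks a measured fold change get status
    "missing"; all others carry both fold changes and status "unscored"
    until :func:`score_concordance` is applied.
    """
    required = {"modifier", "mark", "relation"}
    if not required <= set(edges.columns):
        raise ValueError(f"edge table needs columns {sorted(required)}")
    bad = set(edges["relation"]) - set(RELATIONS)
    if bad:
        raise ValueError(f"unknown relations: {sorted(bad)}")
    dup = edges.duplicated(subset=["modifier", "mark", "relation"])
    if dup.any():
        raise ValueError(
            f"duplicate edges: {edges[dup][['modifier', 'mark']].values.tolist()}"
        )
    out = edges[["modifier", "mark", "relation"]].copy()
    out["modifier_fc"] = [protein_fc.get(m, np.nan) for m in out["modifier"]]
    out["mark_fc"] = [mark_fc.get(m, np.nan) for m in out["mark"]]
    out["expected_sign"] = [EXPECTED_SIGN[r] for r in out["relation"]]
    out["status"] = np.where(
        out["modifier_fc"].isna() | out["mark_fc"].isna(), "missing", "unscored"
    )
    return out


def score_concordance(table: pd.DataFrame, fc_threshold: float = 0.5) -> pd.DataFrame:
    """Apply the sign rule with a neutrality band of ``fc_threshold`` log2
    units; appends per-status counts in ``table.attrs['status_counts']``."""
    out = table.copy()
    statuses = []
    for row in out.itertuples(index=False):
        if row.status == "missing":
            statuses.append("missing")
            continue
        if (
            abs(row.modifier_fc) < fc_threshold
            or abs(row.mark_fc) < fc_threshold
        ):
            statuses.append("neutral")
        elif np.sign(row.mark_fc) == row.expected_sign * np.sign(row.modifier_fc):
            statuses.append("concordant")
        else:
            statuses.append("discordant")
    out["status"] = statuses
    out.attrs["status_counts"] = pd.Series(statuses).value_counts().to_dict()
    return out
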