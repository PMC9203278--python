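"""Synthetic data generators with known ground truth.

Three generators emulate the data modalities the pipeline consumes:

* :func:`simulate_cutrun` — two-condition, replicated CUT&RUN-style fragment
  sets over a small target genome plus an exogenous spike-in genome. Each
  sample receives spike-in fragments at a constant per-cell rate (the
  biological premise of spike-in calibration), while target fragments scale
  with a condition-specific global "coating" level and carry planted enriched
  regions. Totals are Poisson; placement is multinomial between a uniform
  background and the planted regions.
* :func:`simulate_peptidoforms` — histone peptidoform intensity tables with
  lognormal noise around known per-residue modification-state proportions.
* :func:`simulate_proteome` — label-free proteomics log2-intensity matrices
  with a planted differential subset and missingness concentrated below a
  global detection-limit quantile (missing-not-at-random).

Every generator is deterministic under its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .io import GENOME_SPIKEIN, GENOME_TARGET, fragments_frame

CONDITIONS = ("cond1", "cond2")
REGION_CLASSES = ("cond1_enriched", "cond2_enriched", "common")


@dataclass(frozen=True)
class PlantedRegion:
    chrom: str
    start: int
    end: int
    region_class: str  # cond1_enriched | cond2_enriched | common
    fold: float  # enrichment over background density, >= 1

    def active_in(self, condition: str) -> bool:
        return self.region_class == "common" or self.region_class == (
            condition + "_enriched"
        )

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class CutrunSimParams:
    """Design of a synthetic calibrated CUT&RUN experiment.

    ``global_level`` is the expected number of target fragments per
    cell-equivalent — the genome-wide coating level — and may differ between
    conditions; ``spikein_rate`` is the expected spike-in fragments per
    cell-equivalent and is condition-invariant by construction.
    ``depth_scale`` multiplies both target and spike-in expectations for a
    sample, emulating unequal sequencing depth.
    """

    target_genome: Mapping[str, int]
    spikein_genome: Mapping[str, int]
    n_cells: int = 50_000
    global_level: Mapping[str, float] = field(
        default_factory=lambda: {"cond1": 2.0, "cond2": 1.0}
    )
    planted_regions: Sequence[PlantedRegion] = ()
    spikein_rate: float = 0.4
    depth_scale: Mapping[str, float] | None = None  # per sample, default 1.0
    fragment_length: int = 150
    n_replicates: int = 2
    igg_flag: bool = False
    seed: int = 0

    def sample_names(self) -> list[str]:
        return [
            f"{cond}_r{i + 1}"
            for cond in CONDITIONS
            for i in range(self.n_replicates)
        ]

    def condition_of(self, sample: str) -> str:
        return sample.rsplit("_r", 1)[0]

    def scale_of(self, sample: str) -> float:
        if self.depth_scale is None:
            return 1.0
        return float(self.depth_scale.get(sample, 1.0))

    def validate(self) -> None:
        for chrom, length in {
            **dict(self.target_genome),
            **dict(self.spikein_genome),
        }.items():
            if length <= 0:
                raise ValueError(f"contig {chrom!r} has zero or negative length")
        for r in self.planted_regions:
            if r.region_class not in REGION_CLASSES:
                raise ValueError(f"unknown region class {r.region_class!r}")
            if r.fold < 1:
                raise ValueError("enrichment fold must be >= 1")
            if r.chrom not in self.target_genome:
                raise ValueError(f"planted region on unknown contig {r.chrom!r}")
            if r.start < 0 or r.end > self.target_genome[r.chrom]:
                raise ValueError(
                    f"planted region {r.chrom}:{r.start}-{r.end} outside genome"
                )
        if self.spikein_rate <= 0:
            raise ValueError("spikein_rate must be > 0")


@dataclass
class SyntheticTruth:
    """Ground-truth record emitted alongside simulated fragments."""

    params: CutrunSimParams
    target_totals: dict[str, int]
    spikein_totals: dict[str, int]
    global_ratio: float  # cond1 / cond2 coating-level ratio
    region_classes: pd.DataFrame  # chrom, start, end, region_class, fold


class CutrunSim(NamedTuple):
    samples: dict[str, pd.DataFrame]
    truth: SyntheticTruth


def _draw_uniform_fragments(rng, genome, n, fragment_length):
    contigs = list(genome)
    lengths = np.array([genome[c] for c in contigs], dtype=float)
    which = rng.choice(len(contigs), size=n, p=lengths / lengths.sum())
    starts = np.empty(n, dtype=np.int64)
    for i, clen in enumerate(int(genome[c]) for c in contigs):
        mask = which == i
        starts[mask] = rng.integers(0, clen, size=int(mask.sum()))
    chroms = np.array(contigs, dtype=object)[which]
    clens = np.array([genome[c] for c in contigs], dtype=np.int64)[which]
    ends = np.minimum(starts + fragment_length, clens)
    return chroms, starts, ends


def simulate_cutrun(params: CutrunSimParams) -> CutrunSim:
    """Generate per-sample fragment sets and the ground-truth record."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    L = float(sum(params.target_genome.values()))
    half = params.fragment_length // 2

    samples: dict[str, pd.DataFrame] = {}
    target_totals: dict[str, int] = {}
    spikein_totals: dict[str, int] = {}
    for sample in params.sample_names():
        cond = params.condition_of(sample)
        scale = params.scale_of(sample)
        active = (
            []
            if params.igg_flag
            else [r for r in params.planted_regions if r.active_in(cond)]
        )
        extra = np.array([(r.fold - 1.0) * r.width for r in active], dtype=float)
        planted_mass = extra.sum() / L
        lam_t = scale * params.n_cells * params.global_level[cond] * (1 + planted_mass)
        n_t = int(rng.poisson(lam_t))
        weights = np.concatenate([[L], extra])
        counts = rng.multinomial(n_t, weights / weights.sum())

        chroms, starts, ends = _draw_uniform_fragments(
            rng, params.target_genome, int(counts[0]), params.fragment_length
        )
        parts = [(chroms, starts, ends)]
        for r, k in zip(active, counts[1:]):
            # uniform midpoints inside the region => density ratio == fold
            mids = rng.integers(r.start, r.end, size=int(k))
            s = np.maximum(mids - half, 0)
            e = np.minimum(s + params.fragment_length, params.target_genome[r.chrom])
            parts.append((np.full(int(k), r.chrom, dtype=object), s, e))
        t_chrom = np.concatenate([p[0] for p in parts])
        t_start = np.concatenate([p[1] for p in parts])
        t_end = np.concatenate([p[2] for p in parts])

        n_s = int(rng.poisson(scale * params.n_cells * params.spikein_rate))
        s_chrom, s_start, s_end = _draw_uniform_fragments(
            rng, params.spikein_genome, n_s, params.fragment_length
        )

        n_total = len(t_chrom) + n_s
        if n_total == 0:
            frags = fragments_frame([], [], [], [])
        else:
            frags = fragments_frame(
                np.concatenate([t_chrom, s_chrom]),
                np.concatenate([t_start, s_start]),
                np.concatenate([t_end, s_end]),
                np.array(
                    [GENOME_TARGET] * len(t_chrom) + [GENOME_SPIKEIN] * n_s,
                    dtype=object,
                ),
                np.full(n_total, 42, dtype=np.int64),
            )
        samples[sample] = frags
        target_totals[sample] = len(t_chrom)
        spikein_totals[sample] = n_s

    truth = SyntheticTruth(
        params=params,
        target_totals=target_totals,
        spikein_totals=spikein_totals,
        global_ratio=params.global_level["cond1"] / params.global_level["cond2"],
        region_classes=pd.DataFrame(
            [
                (r.chrom, r.start, r.end, r.region_class, r.fold)
                for r in params.planted_regions
            ],
            columns=["chrom", "start", "end", "region_class", "fold"],
        ),
    )
    return CutrunSim(samples, truth)


# ---------------------------------------------------------------------------
# histone peptidoforms


@dataclass(frozen=True)
class ResidueSpec:
    """One histone residue with its modification-state proportions.

    ``proportions`` maps condition -> {state: proportion}; proportions must
    sum to 1 within each condition.
    """

    histone: str
    residue: str
    proportions: Mapping[str, Mapping[str, float]]


class PeptidoformSim(NamedTuple):
    table: pd.DataFrame
    design: dict[str, str]
    truth: pd.DataFrame


def simulate_peptidoforms(
    residues: Sequence[ResidueSpec],
    n_per_condition: int | Mapping[str, int],
    cv: float,
    seed: int,
    base_total: float = 1e6,
    conditions: Sequence[str] = CONDITIONS,
) -> PeptidoformSim:
    """Generate a peptidoform intensity table around known proportions.

    One row per (residue, state); intensities are lognormal around
    ``base_total * proportion`` with coefficient of variation ``cv``
    (mean-preserving, so the expected rollup equals the truth). ``cv=0``
    reproduces the truth exactly.
    """
    for spec in residues:
        for cond in conditions:
            total = sum(spec.proportions[cond].values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"{spec.histone}{spec.residue} proportions sum to {total} "
                    f"in {cond}, expected 1"
                )
    if isinstance(n_per_condition, int):
        n_per_condition = {c: n_per_condition for c in conditions}
    rng = np.random.default_rng(seed)
    sigma = float(np.sqrt(np.log1p(cv**2)))

    design = {
        f"{cond}_r{i + 1}": cond
        for cond in conditions
        for i in range(n_per_condition[cond])
    }
    rows = []
    truth_rows = []
    for spec in residues:
        states = list(spec.proportions[conditions[0]])
        for state in states:
            intensities = {}
            for sample, cond in design.items():
                p = spec.proportions[cond].get(state, 0.0)
                noise = 1.0
                if sigma > 0:
                    noise = float(
                        np.exp(sigma * rng.standard_normal() - sigma**2 / 2)
                    )
                intensities[sample] = base_total * p * noise
            rows.append(
                {
                    "peptide_id": f"{spec.histone}{spec.residue}_{state}",
                    "annotations": f"{spec.histone}:{spec.residue}:{state}",
                    **intensities,
                }
            )
        for cond in conditions:
            for state, p in spec.proportions[cond].items():
                truth_rows.append(
                    (spec.histone, spec.residue, state, cond, 100.0 * p)
                )
    table = pd.DataFrame(rows)
    truth = pd.DataFrame(
        truth_rows,
        columns=["histone", "residue", "state", "condition", "relative_abundance"],
    )
    return PeptidoformSim(table, design, truth)


# ---------------------------------------------------------------------------
# chromatin proteome (LFQ)


class ProteomeSim(NamedTuple):
    matrix: pd.DataFrame
    design: dict[str, str]
    truth: pd.DataFrame


def simulate_proteome(
    n_proteins: int,
    n_per_group: int,
    frac_differential: float,
    true_log2fc: float,
    cv: float,
    detection_limit_quantile: float,
    seed: int,
    flag_fraction: float = 0.02,
    baseline_mean: float = 25.0,
    baseline_sd: float = 2.0,
    groups: Sequence[str] = ("group1", "group2"),
) -> ProteomeSim:
    """Generate an LFQ-style log2-intensity matrix with planted differentials.

    ``cv`` is the SD of the per-replicate log2 intensities around each
    protein's baseline. A ``frac_differential`` subset of proteins is shifted
    up by ``true_log2fc`` in the first group. Values falling below the
    ``detection_limit_quantile`` of the pooled intensity distribution are set
    missing, emulating censoring at the detection limit. A ``flag_fraction``
    of extra decoy/contaminant rows is appended (excluded from the truth).
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2 (variance undefined downstream)")
    if not 0 <= frac_differential <= 1:
        raise ValueError("frac_differential must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_diff = round(n_proteins * frac_differential)

    samples = [f"{g}_r{i + 1}" for g in groups for i in range(n_per_group)]
    design = dict(zip(samples, [g for g in groups for _ in range(n_per_group)]))

    baseline = rng.normal(baseline_mean, baseline_sd, size=n_proteins)
    values = baseline[:, None] + rng.normal(
        0.0, cv, size=(n_proteins, 2 * n_per_group)
    )
    values[:n_diff, :n_per_group] += true_log2fc  # shift first group up

    if detection_limit_quantile > 0:
        threshold = np.quantile(values, detection_limit_quantile)
        values = np.where(values < threshold, np.nan, values)

    ids = [f"P{i:05d}" for i in range(n_proteins)]
    matrix = pd.DataFrame(values, columns=samples)
    matrix.insert(0, "protein_id", ids)
    for flag in ("reverse", "contaminant", "only_identified_by_site"):
        matrix.insert(1, flag, False)

    n_flagged = round(n_proteins * flag_fraction)
    if n_flagged:
        fb = rng.normal(baseline_mean, baseline_sd, size=n_flagged)
        fv = fb[:, None] + rng.normal(0.0, cv, size=(n_flagged, 2 * n_per_group))
        which = rng.integers(0, 3, size=n_flagged)
        flag_names = ["reverse", "contaminant", "only_identified_by_site"]
        extra = pd.DataFrame(fv, columns=samples)
        extra.insert(0, "protein_id", [f"FLAG_{i:04d}" for i in range(n_flagged)])
        for j, flag in enumerate(flag_names):
            extra.insert(1, flag, which == j)
        matrix = pd.concat([matrix, extra[matrix.columns]], ignore_index=True)

    truth = pd.DataFrame(
        {
            "protein_id": ids,
            "differential": [i < n_diff for i in range(n_proteins)],
            "true_log2fc": [true_log2fc if i < n_diff else 0.0 for i in range(n_proteins)],
        }
    )
    return ProteomeSim(matrix, design, truth)
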