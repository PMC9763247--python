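"""Merging phylogeny-derived origination times with fossil-based lifespans.

Extant species sampled in a dated phylogeny get their time of speciation
(Ts) from the age of their parent node — the divergence from the sister
lineage — in each posterior tree, with Te = 0 by definition.  Species whose
lifespan is already estimated from fossil occurrences keep that estimate
when they also appear in the tree.  The combined dataset feeds the
rates-only birth-death stage and the range-through diversity curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io_model import Lifespan, node_ages

__all__ = [
    "TipOrigination",
    "DiversityCurve",
    "TsComparison",
    "extract_tip_origination_ages",
    "combine_lifespans",
    "ltt_range_through",
    "compare_shared_ts",
]


@dataclass(frozen=True)
class TipOrigination:
    """Phylogeny-derived origination ages of one extant species: the age of
    its parent node in each sampled posterior tree."""

    species_id: str
    ts_samples: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.ts_samples:
            raise ValueError(f"{self.species_id}: no tree samples")
        if min(self.ts_samples) <= 0:
            raise ValueError(f"{self.species_id}: non-positive origination age")

    @property
    def ts_median(self) -> float:
        return float(median(self.ts_samples))


@dataclass(frozen=True)
class DiversityCurve:
    """Range-through species richness on a regular time grid."""

    times: np.ndarray
    richness: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        richness = np.asarray(self.richness)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "richness", richness)
        if times.shape != richness.shape:
            raise ValueError("times and richness must have equal length")
        if (richness < 0).any():
            raise ValueError("richness must be >= 0")

    def at(self, t: float) -> int:
        """Richness at time ``t`` (0 outside the curve's domain)."""
        if t > self.times[-1] or t < self.times[0]:
            return 0
        idx = int(np.searchsorted(self.times, t, side="right")) - 1
        return int(self.richness[idx])


def extract_tip_origination_ages(
    trees: Sequence, tip_ids: Sequence[str]
) -> list[TipOrigination]:
    """Ts of each tip = age of its parent node, matched by tip label across
    (possibly topologically different) trees."""
    samples: dict[str, list[float]] = {t: [] for t in tip_ids}
    wanted = set(tip_ids)
    for k, tree in enumerate(trees):
        ages = node_ages(tree)
        found = set()
        for leaf in tree.leaf_node_iter():
            label = leaf.taxon.label
            if label in wanted:
                if leaf.parent_node is None:
                    raise ValueError(f"tree {k}: tip {label!r} is the whole tree")
                samples[label].append(float(ages[leaf.parent_node]))
                found.add(label)
        missing = wanted - found
        if missing:
            raise ValueError(f"tree {k}: missing tip(s) {sorted(missing)}")
    return [TipOrigination(species_id=t, ts_samples=tuple(samples[t])) for t in tip_ids]


def combine_lifespans(
    fossil_lifespans: Sequence[Lifespan],
    tip_originations: Sequence[TipOrigination],
    tree_index: int | None = None,
) -> list[Lifespan]:
    """Union of fossil-based and phylogeny-based lifespans.

    Species present in both keep the fossil-based (Ts, Te); phylogeny-only
    species enter with (ts, 0, source="phylogeny") where ts is the median
    over trees, or the single tree ``tree_index`` when pairing replicates.
    Output is sorted by Ts descending.
    """
    fossil_ids = {l.species_id for l in fossil_lifespans}
    combined = list(fossil_lifespans)
    extinct_fossil = {l.species_id for l in fossil_lifespans if not l.extant}
    for tip in tip_originations:
        if tip.species_id in extinct_fossil:
            raise ValueError(
                f"{tip.species_id}: sampled in the phylogeny but extinct in the fossil data"
            )
        if tip.species_id in fossil_ids:
            continue  # overlap rule: keep the fossil-based estimate
        ts = tip.ts_median if tree_index is None else tip.ts_samples[tree_index]
        combined.append(Lifespan(species_id=tip.species_id, ts=ts, te=0.0, source="phylogeny"))
    return sorted(combined, key=lambda l: -l.ts)


def ltt_range_through(lifespans: Sequence[Lifespan], step: float = 0.1) -> DiversityCurve:
    """Range-through diversity: richness(t) = #{i : te_i <= t <= ts_i} on a
    regular grid over [0, max Ts] (endpoints inclusive; lifespans are
    continuous, so the curve has no Lazarus gaps by construction)."""
    if not lifespans:
        return DiversityCurve(times=np.zeros(1), richness=np.zeros(1, dtype=int))
    ts = np.sort(np.array([l.ts for l in lifespans]))
    te = np.sort(np.array([l.te for l in lifespans]))
    t_max = float(ts[-1])
    times = step * np.arange(int(np.floor(t_max / step)) + 1)
    if times[-1] < t_max:
        times = np.append(times, t_max)
    # richness(t) = #(ts >= t) - #(te > t)
    n_ts_ge = ts.size - np.searchsorted(ts, times, side="left")
    n_te_gt = te.size - np.searchsorted(te, times, side="right")
    return DiversityCurve(times=times, richness=(n_ts_ge - n_te_gt).astype(int))


@dataclass(frozen=True)
class TsComparison:
    mean_difference: float
    slope: float
    intercept: float
    r_value: float
    p_value: float
    n_used: int
    outlier_ids: tuple[str, ...]


def compare_shared_ts(
    fossil_ts: Mapping[str, float],
    phylo_ts: Mapping[str, float],
    n_outliers: int = 0,
) -> TsComparison:
    """Compare phylogeny- vs fossil-based Ts for species estimated by both.

    Mean difference is phylo - fossil; the regression is OLS of phylo on
    fossil.  ``n_outliers`` species with the largest absolute OLS residuals
    are removed and the statistics recomputed.
    """
    shared = sorted(set(fossil_ts) & set(phylo_ts))
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared species, got {len(shared)}")
    if n_outliers >= len(shared) - 2:
        raise ValueError("n_outliers leaves fewer than 3 pairs")
    x = np.array([fossil_ts[s] for s in shared])
    y = np.array([phylo_ts[s] for s in shared])
    outliers: tuple[str, ...] = ()
    if n_outliers:
        fit = stats.linregress(x, y)
        resid = np.abs(y - (fit.intercept + fit.slope * x))
        drop = np.argsort(-resid)[:n_outliers]
        outliers = tuple(shared[i] for i in sorted(drop))
        keep = np.setdiff1d(np.arange(len(shared)), drop)
        x, y = x[keep], y[keep]
    fit = stats.linregress(x, y)
    return TsComparison(
        mean_difference=float(np.mean(y - x)),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_value=float(fit.rvalue),
        p_value=float(fit.pvalue),
        n_used=int(x.size),
        outlier_ids=outliers,
    )
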