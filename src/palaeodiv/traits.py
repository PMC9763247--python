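"""Tooth-crown-height imputation and size-class partitioning.

Fossil shark species are known almost exclusively from teeth, so anterior
tooth crown height (mm) serves as the proxy for body size and feeding
ecology.  Extant species missing a tooth measurement get one imputed from a
per-family ordinary least-squares regression of crown height on compiled
body length (cm); every species is then assigned to one of three size
classes whose boundaries are configuration values (the published cut-offs
live in an external compilation and are deliberately not hard-coded here).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import Lifespan, TraitRecord

logger = logging.getLogger(__name__)

__all__ = [
    "SizeClassConfig",
    "FamilyFit",
    "fit_family_regressions",
    "impute_crown_heights",
    "assign_size_classes",
    "partition_lifespans",
]


@dataclass(frozen=True)
class SizeClassConfig:
    """Crown-height cut-offs (mm) between small/medium and medium/large."""

    cutoff_small_medium: float
    cutoff_medium_large: float

    def __post_init__(self) -> None:
        if not 0 < self.cutoff_small_medium < self.cutoff_medium_large:
            raise ValueError("require 0 < cutoff_small_medium < cutoff_medium_large")

    def classify(self, crown_height: float) -> str:
        if crown_height < self.cutoff_small_medium:
            return "small"
        if crown_height < self.cutoff_medium_large:
            return "medium"
        return "large"


@dataclass(frozen=True)
class FamilyFit:
    family: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_pairs: int


def fit_family_regressions(
    traits: Sequence[TraitRecord], min_pairs: int = 3
) -> tuple[dict[str, FamilyFit], list[str]]:
    """OLS of crown height on body length per family.

    Families with fewer than ``min_pairs`` complete pairs are returned in
    the unfitted list (with a logged warning) rather than fitted.
    """
    by_family: dict[str, list[TraitRecord]] = {}
    for t in traits:
        by_family.setdefault(t.family, []).append(t)
    fits: dict[str, FamilyFit] = {}
    unfitted: list[str] = []
    for fam in sorted(by_family):
        pairs = [
            (t.body_length, t.crown_height)
            for t in by_family[fam]
            if t.body_length is not None and t.crown_height is not None
        ]
        if len(pairs) < min_pairs:
            logger.warning("family %s: only %d complete pairs; not fitted", fam, len(pairs))
            unfitted.append(fam)
            continue
        x = np.array([p[0] for p in pairs])
        y = np.array([p[1] for p in pairs])
        if np.ptp(x) == 0:
            raise ValueError(f"family {fam}: zero variance in body_length")
        fit = stats.linregress(x, y)
        fits[fam] = FamilyFit(
            family=fam,
            slope=float(fit.slope),
            intercept=float(fit.intercept),
            r_squared=float(fit.rvalue**2),
            p_value=float(fit.pvalue),
            n_pairs=len(pairs),
        )
    return fits, unfitted


def impute_crown_heights(
    traits: Sequence[TraitRecord], fits: Mapping[str, FamilyFit]
) -> list[TraitRecord]:
    """Fill missing crown heights from the family regression equations;
    measured values are never altered and imputed records keep a flag."""
    problems = []
    out = []
    for t in traits:
        if t.crown_height is not None:
            out.append(t)
            continue
        if t.body_length is None:
            problems.append(t.species_id)
            continue
        fit = fits.get(t.family)
        if fit is None:
            problems.append(t.species_id)
            continue
        out.append(
            replace(t, crown_height=fit.intercept + fit.slope * t.body_length, imputed=True)
        )
    if problems:
        raise ValueError(
            "cannot impute crown height (missing body length or family fit) for: "
            + ", ".join(sorted(problems))
        )
    return out


def assign_size_classes(
    traits: Sequence[TraitRecord], config: SizeClassConfig
) -> dict[str, str]:
    """Species -> size class from (measured or imputed) crown height.

    Half-open boundaries: small below the first cut-off, medium from the
    first up to (excluding) the second, large at and above the second.
    """
    out = {}
    for t in traits:
        if t.crown_height is None:
            raise ValueError(f"{t.species_id}: no crown height (run imputation first)")
        out[t.species_id] = config.classify(t.crown_height)
    return out


def partition_lifespans(
    lifespans: Sequence[Lifespan], classed: Mapping[str, str]
) -> tuple[dict[str, list[Lifespan]], list[str]]:
    """Split lifespans into per-size-class sets for separate diversification
    runs; species absent from the classification are reported, not dropped
    silently."""
    parts: dict[str, list[Lifespan]] = {"small": [], "medium": [], "large": []}
    unclassified = []
    for ls in lifespans:
        cls = classed.get(ls.species_id)
        if cls is None:
            unclassified.append(ls.species_id)
            continue
        parts[cls].append(replace(ls, size_class=cls))
    return parts, unclassified
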