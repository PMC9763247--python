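"""Core domain types, table readers/writers and posterior-summary utilities.

All ages are expressed in Ma (million years) before present: the present is 0
and values increase into the past.  A species' lifespan runs from its time of
speciation ``ts`` back-to-front to its time of extinction ``te`` with
``ts > te >= 0``; extant species have ``te == 0`` exactly.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "FossilOccurrence",
    "Lifespan",
    "ShiftGrid",
    "PosteriorSummary",
    "TraitRecord",
    "read_occurrence_table",
    "write_occurrence_table",
    "occurrence_counts",
    "read_lifespan_table",
    "write_lifespan_table",
    "read_env_curve",
    "read_dated_trees",
    "node_ages",
    "hpd_interval",
    "effective_sample_size",
    "summarize_posterior",
]

STATUS_VALUES = ("extant", "extinct")
SOURCE_VALUES = ("fossil", "phylogeny")
SIZE_CLASSES = ("small", "medium", "large")


@dataclass(frozen=True)
class FossilOccurrence:
    """One dated fossil record of a species with stratigraphic age bounds."""

    species_id: str
    status: str
    min_age: float
    max_age: float
    locality: str | None = None

    def __post_init__(self) -> None:
        if not self.species_id:
            raise ValueError("species_id must be non-empty")
        if self.status not in STATUS_VALUES:
            raise ValueError(f"unknown status {self.status!r} (expected one of {STATUS_VALUES})")
        if not (0.0 <= self.min_age <= self.max_age):
            raise ValueError(
                f"{self.species_id}: require 0 <= min_age <= max_age, "
                f"got min_age={self.min_age}, max_age={self.max_age}"
            )


@dataclass(frozen=True)
class Lifespan:
    """A species' (Ts, Te) pair with provenance.

    ``source`` records whether the lifespan was estimated from fossil
    occurrences or extracted from a dated phylogeny; ``te == 0`` marks an
    extant species.
    """

    species_id: str
    ts: float
    te: float
    source: str = "fossil"
    size_class: str | None = None

    def __post_init__(self) -> None:
        if not self.species_id:
            raise ValueError("species_id must be non-empty")
        if not (self.ts > self.te >= 0.0):
            raise ValueError(
                f"{self.species_id}: require ts > te >= 0, got ts={self.ts}, te={self.te}"
            )
        if self.source not in SOURCE_VALUES:
            raise ValueError(f"unknown source {self.source!r}")
        if self.size_class is not None and self.size_class not in SIZE_CLASSES:
            raise ValueError(f"unknown size_class {self.size_class!r}")

    @property
    def extant(self) -> bool:
        return self.te == 0.0

    @property
    def duration(self) -> float:
        return self.ts - self.te


@dataclass(frozen=True)
class ShiftGrid:
    """Fixed rate-shift boundaries, listed from the origin side down to 0.

    ``edges`` is strictly decreasing and ends at 0; bin ``j`` spans
    ``[edges[j + 1], edges[j])`` (half-open towards the past, so an age equal
    to a boundary belongs to the younger bin; the oldest bin is closed at the
    origin edge).
    """

    edges: tuple[float, ...]

    def __post_init__(self) -> None:
        edges = tuple(float(e) for e in self.edges)
        object.__setattr__(self, "edges", edges)
        if len(edges) < 2:
            raise ValueError("a grid needs at least one bin (two edges)")
        if any(nxt >= prev for prev, nxt in zip(edges, edges[1:])):
            raise ValueError("edges must be strictly decreasing")
        if edges[-1] != 0.0:
            raise ValueError("last edge must be 0 (the present)")

    @classmethod
    def regular(cls, origin_age: float, width: float = 10.0) -> "ShiftGrid":
        """Evenly spaced bins of ``width`` Myr covering [0, origin_age]."""
        n = int(math.ceil(origin_age / width))
        return cls(tuple(float(origin_age - k * (origin_age / n)) for k in range(n + 1)))

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    @property
    def origin(self) -> float:
        return self.edges[0]

    def bin_of(self, age: float) -> int:
        """Index of the bin containing ``age`` ([lower, upper) convention)."""
        if not (0.0 <= age <= self.origin):
            raise ValueError(f"age {age} outside grid [0, {self.origin}]")
        for j in range(self.n_bins):
            if self.edges[j + 1] <= age < self.edges[j]:
                return j
        return 0  # age == origin: closed oldest bin


@dataclass(frozen=True)
class PosteriorSummary:
    mean: float
    hpd_low: float
    hpd_high: float
    ess: float
    n_samples: int

    def __post_init__(self) -> None:
        if self.hpd_low > self.hpd_high:
            raise ValueError("hpd_low must not exceed hpd_high")


@dataclass(frozen=True)
class TraitRecord:
    """Per-species trait measurements used for size-class assignment.

    ``body_length`` in cm, ``crown_height`` (anterior tooth crown height)
    in mm; at least one of the two must be present.
    """

    species_id: str
    family: str
    body_length: float | None = None
    crown_height: float | None = None
    imputed: bool = False

    def __post_init__(self) -> None:
        if self.body_length is None and self.crown_height is None:
            raise ValueError(f"{self.species_id}: need body_length or crown_height")
        for name in ("body_length", "crown_height"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{self.species_id}: {name} must be > 0, got {v}")


# ---------------------------------------------------------------------------
# Table IO (tab-separated, UTF-8, header row)
# ---------------------------------------------------------------------------


def read_occurrence_table(path: str | Path, dedup: bool = False) -> list[FossilOccurrence]:
    """Read a fossil occurrence table (TSV: species, status, min_age, max_age
    [, locality]).

    With ``dedup=True`` rows identical on (species, locality, min_age,
    max_age) collapse to a single occurrence, mirroring the curation rule
    that discards geographically and stratigraphically redundant records.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"species", "status", "min_age", "max_age"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    has_loc = "locality" in df.columns
    out: list[FossilOccurrence] = []
    status_by_species: dict[str, str] = {}
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        d = row._asdict()
        try:
            occ = FossilOccurrence(
                species_id=d["species"],
                status=d["status"],
                min_age=float(d["min_age"]),
                max_age=float(d["max_age"]),
                locality=(d["locality"] or None) if has_loc else None,
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: line {idx}: {exc}") from exc
        prev = status_by_species.setdefault(occ.species_id, occ.status)
        if prev != occ.status:
            raise ValueError(
                f"{path}: line {idx}: {occ.species_id} has conflicting status "
                f"({prev!r} vs {occ.status!r})"
            )
        out.append(occ)
    if dedup:
        seen: set[tuple] = set()
        unique = []
        for occ in out:
            key = (occ.species_id, occ.locality, occ.min_age, occ.max_age)
            if key not in seen:
                seen.add(key)
                unique.append(occ)
        out = unique
    return out


def write_occurrence_table(occurrences: Iterable[FossilOccurrence], path: str | Path) -> None:
    rows = [
        {
            "species": o.species_id,
            "status": o.status,
            "min_age": o.min_age,
            "max_age": o.max_age,
            "locality": o.locality or "",
        }
        for o in occurrences
    ]
    pd.DataFrame(rows, columns=["species", "status", "min_age", "max_age", "locality"]).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )


def occurrence_counts(occurrences: Iterable[FossilOccurrence]) -> dict[str, int]:
    """Number of occurrences per species."""
    return dict(Counter(o.species_id for o in occurrences))


def write_lifespan_table(lifespans: Iterable[Lifespan], path: str | Path) -> None:
    rows = [
        {
            "species": ls.species_id,
            "ts": ls.ts,
            "te": ls.te,
            "source": ls.source,
            "size_class": ls.size_class or "",
        }
        for ls in lifespans
    ]
    pd.DataFrame(rows, columns=["species", "ts", "te", "source", "size_class"]).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )


def read_lifespan_table(path: str | Path) -> list[Lifespan]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"species", "ts", "te"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        try:
            out.append(
                Lifespan(
                    species_id=d["species"],
                    ts=float(d["ts"]),
                    te=float(d["te"]),
                    source=d.get("source", "fossil") or "fossil",
                    size_class=d.get("size_class") or None,
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: line {idx}: {exc}") from exc
    return out


def read_env_curve(path: str | Path, name: str | None = None):
    """Read a two-column (age Ma, value) table into an :class:`EnvCurve`.

    Rows may be in any order; duplicate ages are averaged.  The curve name
    is taken from the value-column header when informative, else from the
    file name.
    """
    from .covariates import EnvCurve

    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (age, value)")
    age_col, val_col = df.columns[:2]
    try:
        ages = df[age_col].astype(float).to_numpy()
        values = df[val_col].astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric cell in table: {exc}") from exc
    if not (np.isfinite(ages).all() and np.isfinite(values).all()):
        raise ValueError(f"{path}: non-finite value in table")
    grouped = pd.DataFrame({"age": ages, "value": values}).groupby("age", sort=True).mean()
    if len(grouped) < 2:
        raise ValueError(f"{path}: need at least 2 distinct ages, got {len(grouped)}")
    if name is None:
        name = str(val_col) if str(val_col).lower() not in {"value", "v", "y"} else Path(path).stem
    return EnvCurve(name=name, ages=grouped.index.to_numpy(), values=grouped["value"].to_numpy())


# ---------------------------------------------------------------------------
# Dated trees
# ---------------------------------------------------------------------------


def node_ages(tree: dendropy.Tree) -> dict:
    """Map each node to its age (Ma before present).

    The age of a node is the maximum root-to-tip distance of the tree minus
    the node's distance from the root, so the deepest tips sit at age 0.
    """
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    height = max(leaf.root_distance for leaf in tree.leaf_node_iter())
    return {nd: height - nd.root_distance for nd in tree.preorder_node_iter()}


def read_dated_trees(
    path: str | Path,
    n_sample: int | None = None,
    seed: int | None = None,
    ultrametric_rtol: float = 1e-3,
) -> list[dendropy.Tree]:
    """Read dated trees (newick or NEXUS), optionally subsampling.

    ``n_sample`` trees are drawn without replacement using ``seed``
    (mirroring the draw of posterior trees from a Bayesian dating run).
    Trees must be ultrametric within ``ultrametric_rtol`` of tree height.
    """
    text = Path(path).read_text(encoding="utf-8")
    schema = "nexus" if text.lstrip().lower().startswith("#nexus") else "newick"
    trees = dendropy.TreeList.get(data=text, schema=schema)
    if len(trees) == 0:
        raise ValueError(f"{path}: no trees found")
    if n_sample is not None:
        if n_sample > len(trees):
            raise ValueError(f"requested {n_sample} trees but file holds {len(trees)}")
        rng = np.random.default_rng(seed)
        idx = sorted(rng.choice(len(trees), size=n_sample, replace=False))
        trees = [trees[i] for i in idx]
    out = []
    for k, tree in enumerate(trees):
        tree.calc_node_root_distances(return_leaf_distances_only=False)
        depths = {leaf.taxon.label: leaf.root_distance for leaf in tree.leaf_node_iter()}
        height = max(depths.values())
        worst = min(depths, key=depths.get)
        if height - depths[worst] > ultrametric_rtol * height:
            raise ValueError(
                f"{path}: tree {k} is not ultrametric within tolerance; worst tip "
                f"{worst!r} at depth {depths[worst]:.6g} vs height {height:.6g}"
            )
        out.append(tree)
    return out


# ---------------------------------------------------------------------------
# Posterior summaries
# ---------------------------------------------------------------------------


def hpd_interval(samples: Sequence[float], mass: float = 0.95) -> tuple[float, float]:
    """Highest posterior density interval of a sample.

    Returns the shortest contiguous window of the sorted samples containing
    ``ceil(mass * n)`` of them; ties go to the left-most such window.
    """
    if not 0.0 < mass <= 1.0:
        raise ValueError(f"mass must be in (0, 1], got {mass}")
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    k = int(math.ceil(mass * n))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k - 1 :] - x[: n - k + 1]
    i = int(np.argmin(widths))  # argmin takes the first minimum: left-most tie
    return float(x[i]), float(x[i + k - 1])


def effective_sample_size(samples: Sequence[float]) -> float:
    """ESS via Geyer's initial-positive-sequence autocorrelation estimator."""
    x = np.asarray(samples, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    x = x - x.mean()
    var = float(np.dot(x, x)) / n
    if var == 0.0:
        return float(n)
    # autocovariance via FFT
    m = int(2 ** math.ceil(math.log2(2 * n)))
    f = np.fft.rfft(x, m)
    acov = np.fft.irfft(f * np.conj(f), m)[:n].real / n
    rho = acov / acov[0]
    # sum consecutive pairs Gamma_m = rho[2m] + rho[2m+1] while positive
    tau = 0.0
    m_idx = 0
    while 2 * m_idx + 1 < n:
        gamma = rho[2 * m_idx] + rho[2 * m_idx + 1]
        if gamma <= 0.0:
            break
        tau += gamma
        m_idx += 1
    tau = max(2.0 * tau - 1.0, 1e-12)
    return float(n / tau)


def summarize_posterior(samples: Sequence[float], mass: float = 0.95) -> PosteriorSummary:
    """Mean, HPD interval and effective sample size of a posterior sample."""
    x = np.asarray(samples, dtype=float)
    low, high = hpd_interval(x, mass)
    return PosteriorSummary(
        mean=float(x.mean()),
        hpd_low=low,
        hpd_high=high,
        ess=effective_sample_size(x),
        n_samples=int(x.size),
    )
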