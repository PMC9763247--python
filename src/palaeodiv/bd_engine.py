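"""Piecewise birth-death likelihoods and MCMC (the BDCS model).

Two entry modes mirror the two stages of the analysis:

* :func:`mcmc_bdcs_occurrences` ("fossils" mode) jointly samples
  speciation/extinction rates on a fixed shift grid, the preservation
  process (epoch-wise rates, optional gamma heterogeneity across species)
  and every species' times of speciation and extinction (Ts, Te) from
  age-resampled fossil occurrences;
* :func:`mcmc_bdcs_lifespans` ("combined" mode) samples the rates only,
  from fixed (Ts, Te) lifespans.

Rates are events/lineage/Myr, constant within time bins.  The single oldest
Ts is treated as the conditioned origin of the process and contributes no
speciation factor to the likelihood.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammainc, gammaincinv, logsumexp

from ._kernels import run_bdcs_chain
from .io_model import FossilOccurrence, Lifespan, ShiftGrid, hpd_interval

logger = logging.getLogger(__name__)

__all__ = [
    "RateProfile",
    "PreservationModel",
    "McmcSettings",
    "BdTrace",
    "resample_occurrence_ages",
    "bd_loglik_piecewise",
    "preservation_loglik",
    "discrete_gamma_means",
    "mcmc_bdcs_occurrences",
    "mcmc_bdcs_lifespans",
    "tste_estimates",
    "replicate_lifespans",
    "rtt_summary",
]


@dataclass(frozen=True)
class RateProfile:
    """Piecewise-constant speciation/extinction rates on a shift grid."""

    grid: ShiftGrid
    lambda_: np.ndarray
    mu: np.ndarray

    def __post_init__(self) -> None:
        lam = np.asarray(self.lambda_, dtype=float)
        mu = np.asarray(self.mu, dtype=float)
        object.__setattr__(self, "lambda_", lam)
        object.__setattr__(self, "mu", mu)
        if lam.shape != (self.grid.n_bins,) or mu.shape != (self.grid.n_bins,):
            raise ValueError("need one lambda and one mu per bin")
        if (lam < 0).any() or (mu < 0).any():
            raise ValueError("rates must be >= 0")

    @property
    def net(self) -> np.ndarray:
        """Net diversification r = lambda - mu per bin (may be negative)."""
        return self.lambda_ - self.mu

    def rate_at(self, age: float) -> tuple[float, float]:
        j = self.grid.bin_of(age)
        return float(self.lambda_[j]), float(self.mu[j])


@dataclass(frozen=True)
class PreservationModel:
    """Epoch-wise fossil preservation rates with optional gamma
    heterogeneity across species.

    ``q`` is in occurrences/lineage/Myr on the intervals of ``q_grid``;
    ``alpha`` is the shape of the Gamma(mean 1) multiplier distribution
    across species (``None`` = homogeneous preservation); the gamma is
    discretized into ``n_categories`` equal-probability categories
    (mean-per-category) where a discrete representation is needed.
    """

    q_grid: ShiftGrid
    q: np.ndarray
    alpha: float | None = None
    n_categories: int = 4

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        object.__setattr__(self, "q", q)
        if q.shape != (self.q_grid.n_bins,):
            raise ValueError("need one q per preservation epoch")
        if (q < 0).any():
            raise ValueError("preservation rates must be >= 0")
        if self.alpha is not None and not self.alpha > 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if self.n_categories < 1:
            raise ValueError("n_categories must be >= 1")

    def rate_at(self, age: float) -> float:
        return float(self.q[self.q_grid.bin_of(age)])


@dataclass(frozen=True)
class McmcSettings:
    """Sampler settings shared by the BDCS and MBD samplers.

    Desk-scale defaults (1e6 iterations sampled every 1e3) keep a full
    recovery experiment tractable on one CPU; paper-scale presets are
    available via :meth:`paper_scale_fossils` / :meth:`paper_scale_combined`.
    ``extant_diversity`` enables the standing-diversity correction: latent
    extant lifespans are added so the birth-death process sees the stated
    number of living species even when some have no fossil record.
    """

    n_iterations: int = 1_000_000
    sampling_freq: int = 1_000
    burnin_fraction: float = 0.10
    seed: int = 0
    n_replicates: int = 20
    extant_diversity: int | None = None
    mult_window: float = 1.2
    time_window: float = 2.0
    frac_time_update: float = 0.1
    p_rates: float = 0.3
    p_preservation: float = 0.2

    def __post_init__(self) -> None:
        if self.n_iterations < self.sampling_freq:
            raise ValueError("n_iterations must be >= sampling_freq")
        if not 0.0 <= self.burnin_fraction < 1.0:
            raise ValueError("burnin_fraction must be in [0, 1)")

    @classmethod
    def paper_scale_fossils(cls, **kw) -> "McmcSettings":
        return cls(n_iterations=10_000_000, sampling_freq=10_000, **kw)

    @classmethod
    def paper_scale_combined(cls, **kw) -> "McmcSettings":
        return cls(n_iterations=20_000_000, sampling_freq=10_000, **kw)


@dataclass(frozen=True)
class BdTrace:
    """Thinned MCMC samples of one chain (one age-resampling replicate)."""

    species_ids: tuple[str, ...]
    grid: ShiftGrid
    q_grid: ShiftGrid | None
    lam: np.ndarray  # (n_samples, n_bins)
    mu: np.ndarray
    q: np.ndarray
    alpha: np.ndarray
    ts: np.ndarray  # (n_samples, n_species)
    te: np.ndarray
    loglik: np.ndarray
    logprior: np.ndarray
    acceptance: dict
    burnin_fraction: float = 0.10
    seed: int | None = None

    def __len__(self) -> int:
        return int(self.lam.shape[0])

    @property
    def burnin(self) -> int:
        return int(math.floor(self.burnin_fraction * len(self)))

    def post_burnin(self, arr: np.ndarray) -> np.ndarray:
        return arr[self.burnin :]


# ---------------------------------------------------------------------------
# Likelihoods
# ---------------------------------------------------------------------------


def resample_occurrence_ages(
    occurrences: Sequence[FossilOccurrence], seed: int | None = None
) -> np.ndarray:
    """Draw one point age per occurrence, uniform between its stratigraphic
    bounds; one call per randomised replicate."""
    rng = np.random.default_rng(seed)
    lo = np.array([o.min_age for o in occurrences])
    hi = np.array([o.max_age for o in occurrences])
    return lo + (hi - lo) * rng.random(len(occurrences))


def _bd_sufficient_stats(
    ts: np.ndarray, te: np.ndarray, grid: ShiftGrid
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    edges = np.asarray(grid.edges)
    nb = grid.n_bins
    B = np.zeros(nb)
    D = np.zeros(nb)
    S = np.zeros(nb)
    imax = int(np.argmax(ts))
    for i in range(ts.size):
        if i != imax:
            B[grid.bin_of(ts[i])] += 1
        if te[i] > 0:
            D[grid.bin_of(te[i])] += 1
    # summed lineage time per bin
    hi = np.minimum(ts[:, None], edges[None, :-1])
    lo = np.maximum(te[:, None], edges[None, 1:])
    S = np.clip(hi - lo, 0.0, None).sum(axis=0)
    return B, D, S


def bd_loglik_piecewise(lifespans: Sequence[Lifespan], rates: RateProfile) -> float:
    """Log-likelihood of lifespans under the piecewise-constant birth-death.

    ``sum_j [B_j ln(lambda_j) + D_j ln(mu_j) - (lambda_j + mu_j) S_j]`` where
    B_j counts speciation times in bin j (the single oldest Ts, the process
    origin, is excluded), D_j counts extinction times (Te > 0) and S_j is the
    total lineage time spent in bin j.
    """
    if len(lifespans) == 0:
        return 0.0
    ts = np.array([l.ts for l in lifespans])
    te = np.array([l.te for l in lifespans])
    if ts.max() > rates.grid.origin:
        raise ValueError(
            f"lifespan Ts={ts.max()} predates the grid origin {rates.grid.origin}"
        )
    B, D, S = _bd_sufficient_stats(ts, te, rates.grid)
    lam, mu = rates.lambda_, rates.mu
    with np.errstate(divide="ignore"):
        ll = -(lam + mu) @ S
        for j in range(rates.grid.n_bins):
            if B[j] > 0:
                if lam[j] <= 0:
                    return -np.inf
                ll += B[j] * math.log(lam[j])
            if D[j] > 0:
                if mu[j] <= 0:
                    return -np.inf
                ll += D[j] * math.log(mu[j])
    return float(ll)


def discrete_gamma_means(alpha: float, k: int) -> np.ndarray:
    """Mean rate multiplier in each of ``k`` equal-probability categories of
    a Gamma(shape alpha, mean 1) distribution (discrete-gamma practice)."""
    if not alpha > 0:
        raise ValueError("alpha must be > 0")
    if k == 1:
        return np.ones(1)
    bounds = gammaincinv(alpha, np.arange(1, k) / k)  # on the rate-alpha scale
    upper = np.concatenate([gammainc(alpha + 1.0, bounds), [1.0]])
    lower = np.concatenate([[0.0], gammainc(alpha + 1.0, bounds)])
    return k * (upper - lower)


def _q_interval_integrals(ts: float, te: float, pres: PreservationModel) -> float:
    edges = np.asarray(pres.q_grid.edges)
    hi = np.minimum(ts, edges[:-1])
    lo = np.maximum(te, edges[1:])
    return float(np.clip(hi - lo, 0.0, None) @ pres.q)


def preservation_loglik(
    ages_by_species: Mapping[str, Sequence[float]],
    ts: Mapping[str, float],
    te: Mapping[str, float],
    preservation: PreservationModel,
) -> float:
    """Inhomogeneous-Poisson log-density of the occurrence ages of every
    species on its (te, ts) lifespan, marginalized over the discretized
    gamma rate multiplier:

    ``ln( (1/K) sum_k prod_x [m_k q(x)] * exp(-m_k int_te^ts q) )`` summed
    over species.
    """
    if preservation.alpha is None:
        m = np.ones(1)
    else:
        m = discrete_gamma_means(preservation.alpha, preservation.n_categories)
    log_m = np.log(m)
    total = 0.0
    for sp, ages in ages_by_species.items():
        ages = np.asarray(ages, dtype=float)
        t_hi, t_lo = float(ts[sp]), float(te[sp])
        if ages.size and (ages.min() < t_lo or ages.max() > t_hi):
            raise ValueError(f"{sp}: occurrence age outside lifespan ({t_lo}, {t_hi})")
        slogq = sum(math.log(preservation.rate_at(a)) for a in ages)
        lam_int = _q_interval_integrals(t_hi, t_lo, preservation)
        n = ages.size
        total += logsumexp(n * log_m + slogq - m * lam_int) - math.log(m.size)
    return float(total)


# ---------------------------------------------------------------------------
# MCMC wrappers
# ---------------------------------------------------------------------------


def _group_occurrences(
    occurrences: Sequence[FossilOccurrence],
) -> tuple[list[str], dict[str, list[int]], dict[str, str]]:
    by_species: dict[str, list[int]] = {}
    status: dict[str, str] = {}
    for i, occ in enumerate(occurrences):
        by_species.setdefault(occ.species_id, []).append(i)
        status[occ.species_id] = occ.status
    return sorted(by_species), by_species, status


def _run_one_chain(
    seed: int,
    ages: np.ndarray,
    occurrences: Sequence[FossilOccurrence],
    rate_grid: ShiftGrid,
    q_grid: ShiftGrid,
    settings: McmcSettings,
    use_gamma: bool,
) -> BdTrace:
    species, by_species, status = _group_occurrences(occurrences)
    n_obs = len(species)
    n_aug = 0
    if settings.extant_diversity is not None:
        n_extant_obs = sum(1 for s in species if status[s] == "extant")
        n_aug = settings.extant_diversity - n_extant_obs
        if n_aug < 0:
            raise ValueError(
                f"extant_diversity={settings.extant_diversity} below the "
                f"{n_extant_obs} extant species observed"
            )
    n = n_obs + n_aug
    ids = tuple(species) + tuple(f"_latent_{k}" for k in range(n_aug))

    edges_bd = np.asarray(rate_grid.edges)
    edges_q = np.asarray(q_grid.edges)
    nq = q_grid.n_bins
    origin = rate_grid.origin

    c = np.zeros((n, nq))
    n_occ = np.zeros(n)
    max_occ = np.zeros(n)
    min_occ = np.zeros(n)
    extant = np.zeros(n, dtype=np.int8)
    has_occ = np.zeros(n, dtype=np.int8)
    for i, sp in enumerate(species):
        sp_ages = ages[by_species[sp]]
        if sp_ages.max() > origin:
            raise ValueError(f"{sp}: occurrence age {sp_ages.max()} beyond grid origin")
        n_occ[i] = sp_ages.size
        max_occ[i] = sp_ages.max()
        min_occ[i] = sp_ages.min()
        has_occ[i] = 1
        extant[i] = 1 if status[sp] == "extant" else 0
        for a in sp_ages:
            c[i, q_grid.bin_of(a)] += 1
    rng = np.random.default_rng(seed)
    for i in range(n_obs, n):
        extant[i] = 1  # latent species for the standing-diversity correction

    ts0 = np.zeros(n)
    te0 = np.zeros(n)
    for i in range(n_obs):
        ts0[i] = min(max_occ[i] + 0.5, origin)
        te0[i] = 0.0 if extant[i] else 0.5 * min_occ[i]
    if n_aug:
        ts0[n_obs:] = rng.uniform(0.5, max(1.0, 0.25 * origin), size=n_aug)

    obs_dur = float(np.sum(max_occ[:n_obs] - min_occ[:n_obs] + 1.0))
    q0 = np.full(nq, max(float(n_occ.sum()) / max(obs_dur, 1.0), 0.1))
    lam0 = np.full(rate_grid.n_bins, 0.1)
    mu0 = np.full(rate_grid.n_bins, 0.1)

    kernel_seed = int(np.random.default_rng(seed).integers(2**31 - 1))
    out = run_bdcs_chain(
        kernel_seed,
        settings.n_iterations,
        settings.sampling_freq,
        edges_bd,
        edges_q,
        lam0,
        mu0,
        q0,
        1.0,
        ts0,
        te0,
        extant,
        has_occ,
        c,
        n_occ,
        max_occ,
        min_occ,
        True,
        True,
        use_gamma,
        settings.p_rates,
        settings.p_preservation,
        settings.mult_window,
        settings.time_window,
        min(settings.frac_time_update, 12.0 / n),  # cap the joint (ts, te) block size
    )
    lam, mu, q, alpha, ts, te, ll, lp, acc = out
    if acc[2] < 0.01:
        logger.warning("chain (seed %d): (ts, te) acceptance %.3f; possibly stuck", seed, acc[2])
    return BdTrace(
        species_ids=ids,
        grid=rate_grid,
        q_grid=q_grid,
        lam=lam,
        mu=mu,
        q=q,
        alpha=alpha,
        ts=ts,
        te=te,
        loglik=ll,
        logprior=lp,
        acceptance={"rates": acc[0], "preservation": acc[1], "times": acc[2]},
        burnin_fraction=settings.burnin_fraction,
        seed=seed,
    )


def mcmc_bdcs_occurrences(
    occurrences: Sequence[FossilOccurrence],
    rate_grid: ShiftGrid,
    q_grid: ShiftGrid | None = None,
    settings: McmcSettings | None = None,
    gamma_heterogeneity: bool = True,
) -> tuple[list[BdTrace], pd.DataFrame]:
    """BDCS-Fossils: one MH chain per age-resampling replicate, jointly
    sampling rates, preservation and all (Ts, Te).

    Returns the traces and the pooled per-species Ts/Te table (posterior
    mean per replicate plus the across-replicate mean).
    """
    if settings is None:
        settings = McmcSettings()
    if q_grid is None:
        q_grid = ShiftGrid((ShiftGrid(rate_grid.edges).origin, 0.0))
    rng = np.random.default_rng(settings.seed)
    traces = []
    for r in range(settings.n_replicates):
        rep_seed = int(rng.integers(2**31 - 1))
        ages = resample_occurrence_ages(occurrences, seed=rep_seed)
        traces.append(
            _run_one_chain(
                rep_seed, ages, occurrences, rate_grid, q_grid, settings, gamma_heterogeneity
            )
        )
    return traces, tste_estimates(traces)


def mcmc_bdcs_lifespans(
    lifespan_replicates: Sequence[Sequence[Lifespan]] | Sequence[Lifespan],
    rate_grid: ShiftGrid,
    settings: McmcSettings | None = None,
) -> list[BdTrace]:
    """BDCS-Combined: rates-only sampling from fixed (Ts, Te) data, one
    chain per replicate lifespan set; preservation settings are ignored."""
    if settings is None:
        settings = McmcSettings()
    if lifespan_replicates and isinstance(lifespan_replicates[0], Lifespan):
        lifespan_replicates = [list(lifespan_replicates)] * settings.n_replicates
    rng = np.random.default_rng(settings.seed)
    edges_bd = np.asarray(rate_grid.edges)
    traces = []
    for rep in lifespan_replicates:
        rep = list(rep)
        n = len(rep)
        ts0 = np.array([l.ts for l in rep])
        te0 = np.array([l.te for l in rep])
        if ts0.max() > rate_grid.origin:
            raise ValueError(
                f"lifespan Ts={ts0.max()} predates the grid origin {rate_grid.origin}"
            )
        extant = np.array([1 if l.extant else 0 for l in rep], dtype=np.int8)
        kernel_seed = int(rng.integers(2**31 - 1))
        dummy_q_edges = np.array([rate_grid.origin, 0.0])
        out = run_bdcs_chain(
            kernel_seed,
            settings.n_iterations,
            settings.sampling_freq,
            edges_bd,
            dummy_q_edges,
            np.full(rate_grid.n_bins, 0.1),
            np.full(rate_grid.n_bins, 0.1),
            np.ones(1),
            1.0,
            ts0.copy(),
            te0.copy(),
            extant,
            np.ones(n, dtype=np.int8),
            np.zeros((n, 1)),
            np.zeros(n),
            ts0.copy(),
            te0.copy(),
            False,
            False,
            False,
            settings.p_rates,
            settings.p_preservation,
            settings.mult_window,
            settings.time_window,
            settings.frac_time_update,
        )
        lam, mu, q, alpha, ts, te, ll, lp, acc = out
        traces.append(
            BdTrace(
                species_ids=tuple(l.species_id for l in rep),
                grid=rate_grid,
                q_grid=None,
                lam=lam,
                mu=mu,
                q=q,
                alpha=alpha,
                ts=ts,
                te=te,
                loglik=ll,
                logprior=lp,
                acceptance={"rates": acc[0]},
                burnin_fraction=settings.burnin_fraction,
                seed=kernel_seed,
            )
        )
    return traces


def tste_estimates(traces: Sequence[BdTrace]) -> pd.DataFrame:
    """Per-species Ts/Te posterior means per replicate chain plus their
    across-replicate mean (latent augmentation species are excluded)."""
    frames = {}
    for r, tr in enumerate(traces):
        keep = [i for i, s in enumerate(tr.species_ids) if not s.startswith("_latent_")]
        ids = [tr.species_ids[i] for i in keep]
        frames[r] = pd.DataFrame(
            {
                f"ts_{r}": tr.post_burnin(tr.ts)[:, keep].mean(axis=0),
                f"te_{r}": tr.post_burnin(tr.te)[:, keep].mean(axis=0),
            },
            index=ids,
        )
    df = pd.concat(frames.values(), axis=1)
    df.index.name = "species"
    ts_cols = [c for c in df.columns if c.startswith("ts_")]
    te_cols = [c for c in df.columns if c.startswith("te_")]
    df["ts_mean"] = df[ts_cols].mean(axis=1)
    df["te_mean"] = df[te_cols].mean(axis=1)
    return df


def replicate_lifespans(
    tste: pd.DataFrame, extant_ids: Iterable[str] | None = None
) -> list[list[Lifespan]]:
    """Turn a Ts/Te estimate table into one lifespan set per replicate.

    Species listed in ``extant_ids`` (or whose Te estimate rounds to 0) get
    Te = 0 exactly.
    """
    extant = set(extant_ids or ())
    reps = sorted({int(c.split("_")[1]) for c in tste.columns if c.startswith("ts_") and c != "ts_mean"})
    out = []
    for r in reps:
        lset = []
        for sp, row in tste.iterrows():
            te = 0.0 if sp in extant or row[f"te_{r}"] < 1e-9 else float(row[f"te_{r}"])
            lset.append(Lifespan(species_id=str(sp), ts=float(row[f"ts_{r}"]), te=te))
        out.append(lset)
    return out


def rtt_summary(traces: Sequence[BdTrace], mass: float = 0.95) -> pd.DataFrame:
    """Rates-through-time summary over pooled post-burn-in samples.

    Per bin: posterior mean and HPD of lambda, mu and net diversification
    r = lambda - mu (computed per sample).  Adjacent bins are flagged
    significantly different when the mean of each lies outside the HPD of
    the other (both directions must hold).
    """
    if not traces:
        raise ValueError("need at least one trace")
    grid = traces[0].grid
    lam = np.vstack([tr.post_burnin(tr.lam) for tr in traces])
    mu = np.vstack([tr.post_burnin(tr.mu) for tr in traces])
    net = lam - mu
    rows = []
    for j in range(grid.n_bins):
        row = {"bin_old": grid.edges[j], "bin_young": grid.edges[j + 1]}
        for name, arr in (("lambda", lam), ("mu", mu), ("net", net)):
            lo, hi = hpd_interval(arr[:, j], mass)
            row[f"{name}_mean"] = float(arr[:, j].mean())
            row[f"{name}_hpd_low"] = lo
            row[f"{name}_hpd_high"] = hi
        rows.append(row)
    df = pd.DataFrame(rows)
    for name in ("lambda", "mu", "net"):
        sig = []
        for j in range(grid.n_bins - 1):
            m_j, m_k = df[f"{name}_mean"][j], df[f"{name}_mean"][j + 1]
            out_j = not (df[f"{name}_hpd_low"][j + 1] <= m_j <= df[f"{name}_hpd_high"][j + 1])
            out_k = not (df[f"{name}_hpd_low"][j] <= m_k <= df[f"{name}_hpd_high"][j])
            sig.append(bool(out_j and out_k))
        sig.append(False)  # youngest bin has no next neighbour
        df[f"{name}_sig_next"] = sig
    return df
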