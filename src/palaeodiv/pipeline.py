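"""Configuration-driven end-to-end orchestration.

Runs the stages of the combined palaeo/neontological analysis in order —
simulate (or ingest) -> BDCS-Fossils -> combine -> BDCS-Combined ->
env-prep -> MBD -> size classes — with one master seed from which every
stochastic stage derives its own seed deterministically.  Each stage writes
plain TSV artifacts into the run directory and appends to a structured log;
a failure aborts with the stage name while preserving partial outputs.
"""

from __future__ import annotations

import dataclasses
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bd_engine, covariates, io_model, mbd, phylo_combine, synthetic_data, traits

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Everything one run needs; serialized alongside its outputs."""

    seed: int = 0
    mode: str = "simulate"  # or "ingest"
    # simulate mode
    scenario: dict = field(
        default_factory=lambda: {
            "kind": "constant",
            "origin_age": 50.0,
            "lambda": 0.15,
            "mu": 0.05,
            "q": 1.0,
            "alpha": None,
            "stage_width": 5.0,
        }
    )
    # ingest mode paths
    occurrence_path: str | None = None
    tree_path: str | None = None
    curve_paths: list = field(default_factory=list)
    trait_path: str | None = None
    # analysis settings
    grid_width: float = 10.0
    dedup: bool = False
    gamma_heterogeneity: bool = True
    n_extant: int | None = None
    rm_dd: bool = True
    n_tree_draws: int = 20
    fossils_mcmc: dict = field(default_factory=lambda: {"n_iterations": 50_000, "sampling_freq": 100, "n_replicates": 3})
    combined_mcmc: dict = field(default_factory=lambda: {"n_iterations": 50_000, "sampling_freq": 100, "n_replicates": 3})
    mbd_mcmc: dict = field(default_factory=lambda: {"n_iterations": 20_000, "sampling_freq": 40, "n_replicates": 3})
    size_class_cutoffs: tuple[float, float] | None = (5.0, 12.0)
    run_per_class_bdcs: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "size_class_cutoffs" in doc and doc["size_class_cutoffs"] is not None:
            doc["size_class_cutoffs"] = tuple(doc["size_class_cutoffs"])
        return cls(**doc)

    def to_yaml(self, path: str | Path) -> None:
        doc = dataclasses.asdict(self)
        if doc["size_class_cutoffs"] is not None:
            doc["size_class_cutoffs"] = list(doc["size_class_cutoffs"])
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")


def _stage_seeds(master: int, n: int = 8) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def _build_scenario(cfg: RunConfig, seed: int):
    sc = cfg.scenario
    if sc.get("kind") == "carcharhiniform":
        scenario, curves, trait_table = synthetic_data.make_carcharhiniform_scenario(seed)
        return scenario, curves, trait_table
    origin = float(sc.get("origin_age", 50.0))
    grid = io_model.ShiftGrid((origin, 0.0))
    rates = bd_engine.RateProfile(
        grid=grid, lambda_=np.array([sc.get("lambda", 0.15)]), mu=np.array([sc.get("mu", 0.05)])
    )
    pres = bd_engine.PreservationModel(
        q_grid=grid, q=np.array([sc.get("q", 1.0)]), alpha=sc.get("alpha"), n_categories=4
    )
    width = float(sc.get("stage_width", 5.0))
    n = int(np.ceil(origin / width))
    edges = np.linspace(0.0, origin, n + 1)
    scenario = synthetic_data.SimScenario(
        origin_age=origin,
        rate_profile=rates,
        preservation=pres,
        stage_bins=tuple((float(a), float(b)) for a, b in zip(edges[:-1], edges[1:])),
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    curves = [
        synthetic_data.simulate_env_curves("trend", origin, seed=int(rng.integers(2**31 - 1))),
        synthetic_data.simulate_env_curves("white", origin, seed=int(rng.integers(2**31 - 1)), base=0.0, noise_sd=3.0),
    ]
    return scenario, curves, None


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Execute the whole workflow; returns the run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    log_path = outdir / "run.log"
    log_lines: list[str] = []

    def log(stage: str, msg: str) -> None:
        line = f"{stage}\t{msg}"
        log_lines.append(line)
        log_path.write_text("\n".join(log_lines) + "\n", encoding="utf-8")

    seeds = _stage_seeds(config.seed)
    stage = "setup"
    try:
        # ------------------------------------------------------------------
        stage = "simulate" if config.mode == "simulate" else "ingest"
        t0 = time.time()
        scenario = None
        trait_table = None
        tip_orig_by_tree: list[dict[str, float]] | None = None
        if config.mode == "simulate":
            scenario, curves, trait_table = _build_scenario(config, seeds[0])
            true_lifespans, parent = synthetic_data.simulate_bd_process(scenario)
            occ_ages = synthetic_data.simulate_preservation(
                true_lifespans, scenario.preservation, seed=seeds[1]
            )
            statuses = {l.species_id: ("extant" if l.extant else "extinct") for l in true_lifespans}
            occurrences = synthetic_data.discretize_occurrence_ages(
                occ_ages, scenario.stage_bins, statuses
            )
            io_model.write_occurrence_table(occurrences, outdir / "occurrences.tsv")
            io_model.write_lifespan_table(true_lifespans, outdir / "true_lifespans.tsv")
            synthetic_data.scenario_to_yaml(scenario, outdir / "scenario.yaml")
            # node ages of extant species stand in for the dated posterior trees
            tip_orig = [
                phylo_combine.TipOrigination(l.species_id, (l.ts,))
                for l in true_lifespans
                if l.extant
            ]
            origin = scenario.origin_age
            if trait_table is None:
                trait_table = synthetic_data.simulate_trait_table(
                    sorted(statuses), seed=seeds[2]
                )
        else:
            if not config.occurrence_path:
                raise ValueError("ingest mode needs occurrence_path")
            occurrences = io_model.read_occurrence_table(config.occurrence_path, dedup=config.dedup)
            origin = max(o.max_age for o in occurrences) + 10.0
            curves = None  # read in the env-prep stage
            tip_orig = None
            if config.tree_path:
                trees = io_model.read_dated_trees(
                    config.tree_path, n_sample=config.n_tree_draws, seed=seeds[2]
                )
                tips = sorted({l.taxon.label for l in trees[0].leaf_node_iter()})
                tip_orig = phylo_combine.extract_tip_origination_ages(trees, tips)
            if config.trait_path:
                df = pd.read_csv(config.trait_path, sep="\t")
                trait_table = [
                    io_model.TraitRecord(
                        species_id=str(r["species"]),
                        family=str(r["family"]),
                        body_length=None if pd.isna(r.get("body_length")) else float(r["body_length"]),
                        crown_height=None if pd.isna(r.get("crown_height")) else float(r["crown_height"]),
                    )
                    for _, r in df.iterrows()
                ]
        log(stage, f"done in {time.time() - t0:.1f}s; {len(occurrences)} occurrences")

        # ------------------------------------------------------------------
        stage = "bdcs-fossils"
        t0 = time.time()
        rate_grid = io_model.ShiftGrid.regular(origin, config.grid_width)
        q_grid = scenario.preservation.q_grid if scenario is not None else rate_grid
        settings = bd_engine.McmcSettings(
            seed=seeds[3], extant_diversity=config.n_extant, **config.fossils_mcmc
        )
        traces_f, tste = bd_engine.mcmc_bdcs_occurrences(
            occurrences, rate_grid, q_grid, settings,
            gamma_heterogeneity=config.gamma_heterogeneity,
        )
        tste.to_csv(outdir / "tste_fossils.tsv", sep="\t", float_format="%.6f")
        bd_engine.rtt_summary(traces_f).to_csv(
            outdir / "rtt_fossils.tsv", sep="\t", index=False, float_format="%.6f"
        )
        for tr in traces_f:
            log(stage, f"replicate seed={tr.seed} acceptance={tr.acceptance}")
        log(stage, f"done in {time.time() - t0:.1f}s")

        # ------------------------------------------------------------------
        stage = "combine"
        t0 = time.time()
        extant_ids = {o.species_id for o in occurrences if o.status == "extant"}
        fossil_reps = bd_engine.replicate_lifespans(tste, extant_ids=extant_ids)
        combined_reps = []
        if tip_orig:
            n_trees = len(tip_orig[0].ts_samples)
            for k, rep in enumerate(fossil_reps):
                combined_reps.append(
                    phylo_combine.combine_lifespans(rep, tip_orig, tree_index=k % n_trees)
                )
            combined_median = phylo_combine.combine_lifespans(fossil_reps[0], tip_orig)
        else:
            combined_reps = fossil_reps
            combined_median = fossil_reps[0]
        io_model.write_lifespan_table(combined_median, outdir / "combined_lifespans.tsv")
        ltt = phylo_combine.ltt_range_through(combined_median)
        pd.DataFrame({"time": ltt.times, "richness": ltt.richness}).to_csv(
            outdir / "ltt.tsv", sep="\t", index=False, float_format="%.4f"
        )
        log(stage, f"done in {time.time() - t0:.1f}s; {len(combined_median)} combined species")

        # ------------------------------------------------------------------
        stage = "bdcs-combined"
        t0 = time.time()
        settings_c = bd_engine.McmcSettings(
            seed=seeds[4], extant_diversity=config.n_extant, **config.combined_mcmc
        )
        traces_c = bd_engine.mcmc_bdcs_lifespans(combined_reps, rate_grid, settings_c)
        bd_engine.rtt_summary(traces_c).to_csv(
            outdir / "rtt_combined.tsv", sep="\t", index=False, float_format="%.6f"
        )
        log(stage, f"done in {time.time() - t0:.1f}s")

        # ------------------------------------------------------------------
        stage = "env-prep"
        t0 = time.time()
        if curves is None:
            curves = [io_model.read_env_curve(p) for p in config.curve_paths]
        if not curves:
            raise ValueError("no covariate curves available")
        prepped = []
        for c in curves:
            sub = covariates.spline_subsample(c, step=0.5, df=200) if len(c) >= 4 else c
            sub.write(outdir / f"curve_{sub.name.replace(' ', '_')}.tsv")
            prepped.append(sub)
        log(stage, f"done in {time.time() - t0:.1f}s; {len(prepped)} curves")

        # ------------------------------------------------------------------
        stage = "mbd"
        t0 = time.time()
        settings_m = mbd.default_mbd_settings(seed=seeds[5])
        for k, v in config.mbd_mcmc.items():
            settings_m = dataclasses.replace(settings_m, **{k: v})
        traces_m = mbd.mcmc_mbd(combined_reps, prepped, settings_m, rm_dd=config.rm_dd)
        summary, rates_tt = mbd.summarize_mbd(traces_m, curves=prepped if config.rm_dd else None)
        summary.to_csv(outdir / "mbd_summary.tsv", sep="\t", index=False, float_format="%.6f")
        if rates_tt is not None:
            rates_tt.to_csv(outdir / "mbd_rates.tsv", sep="\t", index=False, float_format="%.6f")
        log(stage, f"done in {time.time() - t0:.1f}s")

        # ------------------------------------------------------------------
        stage = "size-classes"
        t0 = time.time()
        if trait_table and config.size_class_cutoffs:
            fits, unfitted = traits.fit_family_regressions(trait_table)
            usable = [t for t in trait_table if t.crown_height is not None or t.family in fits]
            completed = traits.impute_crown_heights(usable, fits)
            classes = traits.assign_size_classes(
                completed, traits.SizeClassConfig(*config.size_class_cutoffs)
            )
            pd.DataFrame(
                sorted(classes.items()), columns=["species", "size_class"]
            ).to_csv(outdir / "size_classes.tsv", sep="\t", index=False)
            parts, unclassified = traits.partition_lifespans(combined_median, classes)
            log(stage, f"unfitted families: {unfitted}; unclassified species: {len(unclassified)}")
            if config.run_per_class_bdcs:
                for cls, subset in parts.items():
                    if len(subset) < 5:
                        continue
                    tr = bd_engine.mcmc_bdcs_lifespans([subset], rate_grid, settings_c)
                    bd_engine.rtt_summary(tr).to_csv(
                        outdir / f"rtt_{cls}.tsv", sep="\t", index=False, float_format="%.6f"
                    )
        log(stage, f"done in {time.time() - t0:.1f}s")
    except Exception as exc:
        log(stage, f"FAILED: {exc}")
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    return outdir
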