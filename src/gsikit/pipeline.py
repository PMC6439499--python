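"""Pipeline driver: simulate -> panel -> assign/power -> hybrid test ->
mixing models, with per-stage CSV artifacts and a JSON run manifest."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .admixture import hybrid_test
from .assign import assign_individuals, loo_self_assignment, lr_summary
from .mixing import MODELS, MixingConfig, aggregate_hauls, compare_models, predict_longitude_profile
from .panel import high_grade_panel, rank_loci, spread_select
from .popgen import BaselineSet, allele_counts, wc_fst
from .simulate import GeneratorConfig, LDBlockSpec, SurveyConfig, gen_baselines, gen_survey

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "gsikit_run"
    # generator scale knobs (defaults are desk-scale)
    n_candidate_loci: int = 600
    baseline_n: int = 100
    n_hauls: int = 40
    fish_per_haul: int = 20
    # stage parameters
    panel_size: int = 39
    spread_min_cm: float = 1.0
    hybrid_n_sim: int = 200
    hybrid_n_observed: int = 40
    models: tuple[str, ...] = MODELS
    n_draws: int = 600
    # optional external haul table for the mixing stage
    haul_table_path: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "models" in raw:
            raw["models"] = tuple(raw["models"])
        return cls(**raw)


def _write_manifest(outdir: Path, manifest: dict) -> None:
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")


def run_pipeline(cfg: PipelineConfig) -> tuple[int, dict]:
    """Execute all stages; any stage error aborts with non-zero status
    and a manifest recording the stages already completed."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "config": dataclasses.asdict(cfg), "stages": []}
    state: dict = {}

    stages = [
        ("simulate", _stage_simulate),
        ("panel", _stage_panel),
        ("assign_power", _stage_assign),
        ("hybrid_test", _stage_hybrid),
        ("mixmodel", _stage_mixmodel),
    ]
    for name, fn in stages:
        stage_dir = outdir / name
        stage_dir.mkdir(exist_ok=True)
        log.info("stage %s starting", name)
        try:
            info = fn(cfg, state, stage_dir)
        except Exception as exc:  # noqa: BLE001 - failure isolation by design
            log.error("stage %s failed: %s", name, exc)
            manifest["stages"].append({"name": name, "status": "failed", "error": str(exc)})
            _write_manifest(outdir, manifest)
            return 1, manifest
        manifest["stages"].append({"name": name, "status": "complete", **info})
        _write_manifest(outdir, manifest)
        log.info("stage %s complete", name)
    return 0, manifest


def _stage_simulate(cfg: PipelineConfig, state: dict, out: Path) -> dict:
    gen = GeneratorConfig(
        n_candidate_loci=cfg.n_candidate_loci,
        baseline_n=cfg.baseline_n,
        ld_blocks=LDBlockSpec(n_blocks=3, block_size=3),
        survey=SurveyConfig(n_hauls=cfg.n_hauls, fish_per_haul=cfg.fish_per_haul),
        seed=cfg.seed,
    )
    baselines = gen_baselines(gen)
    survey = gen_survey(gen, baselines)
    state["generator"] = gen
    state["baselines"] = baselines
    state["survey"] = survey

    gio.write_genepop(
        baselines.east, out / "baseline_east.gen", title="baseline east"
    )
    gio.write_genepop(
        baselines.west, out / "baseline_west.gen", title="baseline west"
    )
    gio.write_locus_map(baselines.loci, out / "locus_map.csv")
    gio.write_dosage_csv(survey.mixture, out / "mixture_dosage.csv")
    survey.metadata.to_csv(out / "metadata.csv", index=False)
    survey.hauls.to_csv(out / "hauls.csv", index=False)
    survey.truth.to_csv(out / "truth.csv", index=False)
    return {
        "outputs": sorted(p.name for p in out.iterdir()),
        "n_loci": cfg.n_candidate_loci,
        "n_fish": survey.mixture.n_individuals,
    }


def _stage_panel(cfg: PipelineConfig, state: dict, out: Path) -> dict:
    baselines = state["baselines"]
    counts_e = allele_counts(baselines.east)
    counts_w = allele_counts(baselines.west)
    fst = wc_fst(counts_e, counts_w)
    ranked = rank_loci(fst.locus_ids, fst.theta)
    sel = high_grade_panel(
        ranked, [baselines.east, baselines.west], panel_size=cfg.panel_size
    )
    state["panel"] = sel
    rows = [
        {
            "locus_id": r.locus_id,
            "fst": r.fst,
            "rank": r.rank,
            "status": sel.audit.get(r.locus_id, "not_considered"),
        }
        for r in ranked
    ]
    pd.DataFrame(rows).to_csv(out / "panel_audit.csv", index=False)
    Path(out / "panel_loci.txt").write_text("\n".join(sel.selected) + "\n")
    return {
        "outputs": sorted(p.name for p in out.iterdir()),
        "panel_size": len(sel.selected),
        "truncated": sel.truncated,
    }


def _stage_assign(cfg: PipelineConfig, state: dict, out: Path) -> dict:
    baselines = state["baselines"]
    survey = state["survey"]
    panel = state["panel"].selected
    base_set = BaselineSet(
        ["east", "west"],
        {
            "east": allele_counts(baselines.east),
            "west": allele_counts(baselines.west),
        },
        provenance="pooled synthetic baselines",
    )
    mix = survey.mixture.subset_loci(panel)
    results = assign_individuals(mix, base_set.subset_loci(panel))
    state["assignments"] = results
    pd.DataFrame(
        {
            "individual_id": [r.individual_id for r in results],
            "loglik_east": [r.loglik.get("east", np.nan) for r in results],
            "loglik_west": [r.loglik.get("west", np.nan) for r in results],
            "score_east": [r.score.get("east", np.nan) for r in results],
            "score_west": [r.score.get("west", np.nan) for r in results],
            "assigned": [r.assigned for r in results],
            "n_loci_used": [r.n_loci_used for r in results],
        }
    ).to_csv(out / "assignments.csv", index=False)

    rng = np.random.default_rng([cfg.seed, 3])
    hold_e = baselines.sample("east", cfg.baseline_n, rng).subset_loci(panel)
    hold_w = baselines.sample("west", cfg.baseline_n, rng).subset_loci(panel)
    report = loo_self_assignment({"east": hold_e, "west": hold_w})
    summary, dist = lr_summary(report)
    report.per_population.to_csv(out / "power_summary.csv")
    summary.to_csv(out / "lr_summary.csv", index=False)
    dist.to_csv(out / "lr_distribution.csv", index=False)
    return {
        "outputs": sorted(p.name for p in out.iterdir()),
        "n_assigned": sum(r.assigned in ("east", "west") for r in results),
        "misassignment": report.per_population["misassignment_rate"].to_dict(),
    }


def _stage_hybrid(cfg: PipelineConfig, state: dict, out: Path) -> dict:
    baselines = state["baselines"]
    survey = state["survey"]
    spread = spread_select(baselines.loci, min_cm=cfg.spread_min_cm)
    observed = survey.mixture.subset_individuals(
        survey.mixture.individuals[: cfg.hybrid_n_observed]
    ).subset_loci(spread)
    base_set = BaselineSet(
        ["east", "west"],
        {
            "east": allele_counts(baselines.east),
            "west": allele_counts(baselines.west),
        },
    )
    rep = hybrid_test(
        observed,
        base_set,
        n_sim=cfg.hybrid_n_sim,
        seed=np.random.default_rng([cfg.seed, 4]),
    )
    combined = pd.concat(
        [rep.observed, rep.simulated_parental, rep.simulated_f1], ignore_index=True
    )
    combined.to_csv(out / "admixture_estimates.csv", index=False)
    _plot_hybrid(rep, out / "admixture_plot.png")
    return {
        "outputs": sorted(p.name for p in out.iterdir()),
        "n_spread_loci": len(spread),
        "call_counts": rep.call_counts,
    }


def _plot_hybrid(rep, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(3, 1, figsize=(8, 9), sharey=True)
    for ax, (name, df) in zip(
        axes,
        (
            ("observed", rep.observed),
            ("simulated parental", rep.simulated_parental),
            ("simulated F1", rep.simulated_f1),
        ),
    ):
        d = df.sort_values("q_hat").reset_index(drop=True)
        x = np.arange(len(d))
        ax.vlines(x, d["ci_low"], d["ci_high"], color="0.7", lw=0.8)
        ax.plot(x, d["q_hat"], ".", ms=3, color="C0")
        ax.set_ylim(-0.02, 1.02)
        ax.set_ylabel("admixture q")
        ax.set_title(name)
    axes[-1].set_xlabel("individual (sorted)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _stage_mixmodel(cfg: PipelineConfig, state: dict, out: Path) -> dict:
    if cfg.haul_table_path is not None:
        hauls = gio.read_haul_table(cfg.haul_table_path)
    else:
        survey = state["survey"]
        hauls = aggregate_hauls(state["assignments"], survey.metadata)
    if len(hauls) < 4:
        raise ValueError("too few haul observations for model fitting")
    mix_cfg = MixingConfig(seed=cfg.seed, n_draws=cfg.n_draws)
    table, fits = compare_models(hauls, cfg.models, mix_cfg)
    table.to_csv(out / "waic_table.csv", index=False)
    coef = pd.concat(
        [f.beta_summary.assign(model=m) for m, f in fits.items()], ignore_index=True
    )
    coef.to_csv(out / "coefficients.csv", index=False)
    for mid, f in fits.items():
        if mid == "M3":
            prof = predict_longitude_profile(f)
            prof.curve.to_csv(out / "profile_M3.csv", index=False)
        elif mid == "M4":
            for stage in ("adult", "juvenile"):
                prof = predict_longitude_profile(f, life_stage=stage)
                prof.curve.to_csv(out / f"profile_M4_{stage}.csv", index=False)
    return {
        "outputs": sorted(p.name for p in out.iterdir()),
        "best_model": table["model"].iloc[0],
        "waic": dict(zip(table["model"], table["waic"])),
    }
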