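"""Simulate -> fit -> validate -> report orchestration from a single config.

Every stage draws its randomness from a per-stage seed expanded from the
config's root seed; outputs are written as CSV/JSON under the run directory
and recorded, with SHA-256 hashes, in a manifest so identical configs yield
identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .sampling import SamplerConfig

__all__ = ["RunConfig", "run_pipeline", "write_report", "load_config"]

KNOWN_STAGES = ("simulate", "fit", "metrics", "reliability", "sbc", "hte",
                "report")
TASKS = ("reward-effort", "attribution")


@dataclass(frozen=True)
class RunConfig:
    task: str = "reward-effort"
    stages: tuple[str, ...] = ("simulate", "fit", "metrics", "hte", "report")
    seed: int = 0
    profile: str = "test"
    out_dir: str = "runs/run0"
    n_subjects: int = 30
    intervention_effect: dict = field(default_factory=dict)
    sbc_datasets: int = 50

    def __post_init__(self):
        if self.task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}")
        unknown = set(self.stages) - set(KNOWN_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.profile not in ("test", "full"):
            raise ValueError("profile must be 'test' or 'full'")
        order = {s: i for i, s in enumerate(KNOWN_STAGES)}
        idx = [order[s] for s in self.stages]
        if idx != sorted(idx):
            raise ValueError("stages must respect the dependency order")

    def sampler(self, seed: int) -> SamplerConfig:
        if self.profile == "full":
            return SamplerConfig.full_profile(seed=seed)
        return SamplerConfig.test_profile(seed=seed)


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    return RunConfig(
        **{
            k: tuple(v) if k == "stages" else v
            for k, v in raw.items()
        }
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seed(root: int, stage: str) -> int:
    h = hashlib.sha256(f"{root}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": {**config.__dict__, "stages": list(config.stages)},
        "stages": {},
        "files": {},
    }
    state: dict = {}

    def done(stage: str, t0: float, files: list[Path]) -> None:
        manifest["stages"][stage] = {
            "status": "complete",
            "seconds": round(time.time() - t0, 2),
            "seed": _stage_seed(config.seed, stage),
        }
        for f in files:
            manifest["files"][str(f.relative_to(out))] = _sha256(f)
        _write_manifest(out, manifest)

    try:
        for stage in config.stages:
            t0 = time.time()
            seed = _stage_seed(config.seed, stage)
            if stage == "simulate":
                files = _stage_simulate(config, seed, out, state)
            elif stage == "fit":
                files = _stage_fit(config, seed, out, state)
            elif stage == "metrics":
                files = _stage_metrics(config, seed, out, state)
            elif stage == "reliability":
                files = _stage_reliability(config, seed, out, state)
            elif stage == "sbc":
                files = _stage_sbc(config, seed, out, state)
            elif stage == "hte":
                files = _stage_hte(config, seed, out, state)
            elif stage == "report":
                report = write_report(out)
                files = [out / "report.md"]
            done(stage, t0, files)
    except Exception as e:
        manifest["stages"][stage] = {"status": "failed", "error": str(e)}
        _write_manifest(out, manifest)
        raise
    return manifest


def _write_manifest(out: Path, manifest: dict) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _load_data(config: RunConfig, out: Path, state: dict) -> pd.DataFrame:
    if "data" in state:
        return state["data"]
    path = out / "data.csv"
    state["data"] = pd.read_csv(path)
    return state["data"]


def _stage_simulate(config, seed, out: Path, state) -> list[Path]:
    from . import synthetic as syn

    if config.task == "reward-effort":
        design = syn.generate_task_design(seed=seed)
        cohort = syn.default_reward_effort_cohort(
            n_subjects=config.n_subjects, seed=seed,
            true_intervention_effect={
                "rewSens": 0.0,
                "effSens": 0.0,
                **config.intervention_effect,
            },
        )
        df = syn.simulate_reward_effort_cohort(design, cohort)
        df, report = syn.apply_exclusion_rules(df, "reward-effort")
    else:
        cohort = syn.default_attribution_cohort(
            n_subjects=config.n_subjects, seed=seed,
            true_intervention_effect={
                **{p: 0.0 for p in syn.ATTRIBUTION_PARAMS},
                **config.intervention_effect,
            },
        )
        df = syn.simulate_attribution_cohort(cohort=cohort)
        df, report = syn.apply_exclusion_rules(df, "attribution")
    df.to_csv(out / "data.csv", index=False)
    report.to_frame().to_csv(out / "exclusions.csv", index=False)
    state["data"] = df
    return [out / "data.csv", out / "exclusions.csv"]


def _stage_fit(config, seed, out: Path, state) -> list[Path]:
    data = _load_data(config, out, state)
    mcmc = config.sampler(seed)
    if config.task == "reward-effort":
        from .reward_effort import fit_reward_effort, intervention_effect_summary

        fit = fit_reward_effort(data, mcmc=mcmc)
        effects = intervention_effect_summary(fit)
    else:
        from .attribution import fit_attribution, attribution_intervention_summary

        fit = fit_attribution(data, mcmc=mcmc)
        effects = attribution_intervention_summary(fit)
    fit_dir = out / "fit"
    fit.save(fit_dir, save_draws=False)
    (out / "effects.json").write_text(
        json.dumps([e.as_dict() for e in effects], indent=2)
    )
    state["fit"] = fit
    return [fit_dir / "summary.csv", fit_dir / "fit.json",
            out / "effects.json"]


def _stage_metrics(config, seed, out: Path, state) -> list[Path]:
    from .reliability import compute_fit_metrics

    metrics = compute_fit_metrics(
        state["fit"], _load_data(config, out, state), seed=seed
    )
    (out / "metrics.json").write_text(
        json.dumps(metrics.as_dict(), indent=2)
    )
    return [out / "metrics.json"]


def _stage_reliability(config, seed, out: Path, state) -> list[Path]:
    from .reliability import estimate_test_retest

    rel = estimate_test_retest(
        _load_data(config, out, state),
        model=config.task,
        mcmc=config.sampler(seed),
    )
    pd.DataFrame([r.as_dict() for r in rel]).to_csv(
        out / "reliability.csv", index=False
    )
    return [out / "reliability.csv"]


def _stage_sbc(config, seed, out: Path, state) -> list[Path]:
    from .sbc import plot_rank_histograms, sbc_run_batched

    res = sbc_run_batched(
        config.task, n_datasets=config.sbc_datasets, seed=seed
    )
    res.to_frame().to_csv(out / "sbc_ranks.csv", index=False)
    diag = res.diagnostics()
    diag.to_csv(out / "sbc_diagnostics.csv")
    plot_rank_histograms(res, out / "sbc_ranks.png")
    return [out / "sbc_ranks.csv", out / "sbc_diagnostics.csv"]


def _stage_hte(config, seed, out: Path, state) -> list[Path]:
    from .hte import hte_from_fit

    fit = state["fit"]
    params = (
        ("rewSens", "effSens")
        if config.task == "reward-effort"
        else ("pos,internal", "neg,internal")
    )
    results = {p: hte_from_fit(fit, p).as_dict() for p in params}
    (out / "hte.json").write_text(json.dumps(results, indent=2))
    return [out / "hte.json"]


def write_report(run_dir: str | Path) -> str:
    """Assemble a human-readable markdown summary from a run directory."""
    run_dir = Path(run_dir)
    missing = []
    lines = ["# Run report", ""]
    summary_path = run_dir / "fit" / "summary.csv"
    effects_path = run_dir / "effects.json"
    if effects_path.exists():
        effects = json.loads(effects_path.read_text())
        lines.append("## Intervention effects (90% CI)")
        for e in effects:
            flag = "excludes zero" if e["excludes_zero"] else "not excluded"
            smd = f", SMD {e['smd']:.2f}" if e.get("smd") is not None else ""
            lines.append(
                f"- {e['parameter']}: {e['mean']:.3f} "
                f"[{e['ci_low']:.3f}, {e['ci_high']:.3f}] ({flag}{smd})"
            )
        lines.append("")
    else:
        missing.append(str(effects_path))
    if summary_path.exists():
        df = pd.read_csv(summary_path)
        lines.append("## Posterior summary")
        lines.append(df.to_string(index=False, float_format="%.3f"))
        lines.append("")
    else:
        missing.append(str(summary_path))
    for name, title in (
        ("metrics.json", "Goodness of fit"),
        ("hte.json", "Heterogeneity of treatment effects"),
    ):
        p = run_dir / name
        if p.exists():
            lines.append(f"## {title}")
            lines.append("```json")
            lines.append(p.read_text().strip())
            lines.append("```")
            lines.append("")
    rel = run_dir / "reliability.csv"
    if rel.exists():
        lines.append("## Test-retest reliability")
        lines.append(pd.read_csv(rel).to_string(index=False,
                                                float_format="%.3f"))
        lines.append("")
    sbc = run_dir / "sbc_diagnostics.csv"
    if sbc.exists():
        lines.append("## Simulation-based calibration")
        lines.append(pd.read_csv(sbc).to_string(index=False,
                                                float_format="%.4f"))
        lines.append("")
    if missing:
        lines.append("## Missing artifacts")
        lines.extend(f"- {m}" for m in missing)
    text = "\n".join(lines)
    (run_dir / "report.md").write_text(text)
    return text
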