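"""End-to-end orchestration: simulate/load -> effects -> interactions -> tests.

``run_pipeline`` executes the full analysis behind one config and writes a
deterministic report bundle into the output directory:

* ``data.csv``          — the (simulated or copied) behavioral dataset
* ``effects.csv``       — arm x assay effect summaries (AUC / PI / %MPE)
* ``interactions.csv``  — observed vs expected comparison per combo x assay
* ``tests.csv``         — ANOVA and per-day nonparametric test results
* ``report.md``         — rendered summary-table blocks
* ``run.log``           — every parameter, the seed, and the package version

Identical config + seed always produce byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import AlgesiaError, AnalysisError, ValidationError
from .interaction import InteractionResult, interaction_frame, interaction_table
from .io_model import ArmRoleMap, read_dataset, write_dataset
from .metrics import effect_table
from .stats_tests import per_day_nonparametric, results_frame, rm_anova_timecourse
from .synthetic_data import SimulationConfig, simulate_dataset

__all__ = ["RunConfig", "run_pipeline", "render_tables", "plot_timecourses"]


@dataclass
class RunConfig:
    """One pipeline run: input mode, roles, decision parameters, output."""

    role_map: ArmRoleMap
    simulation: SimulationConfig | None = None
    data_path: str | None = None
    alpha: float = 0.05
    label_rule: str = "gated"
    outdir: str = "results"
    seed: int | None = None
    run_tests: bool = True

    def __post_init__(self):
        if (self.simulation is None) == (self.data_path is None):
            raise ValidationError(
                "exactly one input mode must be set: simulation or data_path"
            )
        if self.label_rule not in ("gated", "raw"):
            raise ValidationError(f"unknown label rule {self.label_rule!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sim = raw.get("simulation")
        if sim is not None:
            sim = SimulationConfig(
                **{
                    **sim,
                    "arms": sim["arms"],
                }
            )
        role = raw["role_map"]
        return cls(
            role_map=ArmRoleMap(
                vehicle_arm=role["vehicle_arm"],
                sham_arm=role["sham_arm"],
                combinations=[tuple(c) for c in role.get("combinations", [])],
            ),
            simulation=sim,
            data_path=raw.get("data_path"),
            alpha=float(raw.get("alpha", 0.05)),
            label_rule=raw.get("label_rule", "gated"),
            outdir=raw.get("outdir", "results"),
            seed=raw.get("seed"),
            run_tests=bool(raw.get("run_tests", True)),
        )


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the failing stage named."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, AlgesiaError):
                exc.args = (f"[stage: {name}] {exc}",)
            return False

    return _Ctx()


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns the bundle as in-memory objects."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    with _stage("input"):
        if config.simulation is not None:
            sim = config.simulation
            if config.seed is not None:
                sim = dataclasses.replace(sim, seed=config.seed)
            records = simulate_dataset(sim)
        else:
            records = read_dataset(config.data_path)
        config.role_map.validate_against(records)
        write_dataset(records, outdir / "data.csv")

    with _stage("effects"):
        effects = effect_table(
            records, config.role_map.vehicle_arm, config.role_map.sham_arm
        )
        effects.to_csv(outdir / "effects.csv", index=False)

    with _stage("interactions"):
        results = interaction_table(
            records,
            config.role_map,
            alpha=config.alpha,
            rule=config.label_rule,
        )
        interaction_frame(results).to_csv(outdir / "interactions.csv", index=False)

    tests = pd.DataFrame()
    if config.run_tests:
        with _stage("tests"):
            tests = _run_tests(records, config)
            tests.to_csv(outdir / "tests.csv", index=False)

    with _stage("report"):
        report = render_tables(results, effects, config.role_map)
        (outdir / "report.md").write_text(report)

    log = {
        "package_version": __version__,
        "alpha": config.alpha,
        "label_rule": config.label_rule,
        "seed": config.seed
        if config.seed is not None
        else (config.simulation.seed if config.simulation else None),
        "input_mode": "simulate" if config.simulation else "load",
        "data_path": config.data_path,
        "role_map": {
            "vehicle_arm": config.role_map.vehicle_arm,
            "sham_arm": config.role_map.sham_arm,
            "combinations": [list(c) for c in config.role_map.combinations],
        },
    }
    if config.simulation is not None:
        log["simulation"] = config.simulation.to_dict()
    (outdir / "run.log").write_text(yaml.safe_dump(log, sort_keys=True))

    return {
        "records": records,
        "effects": effects,
        "interactions": results,
        "tests": tests,
        "report": report,
        "outdir": outdir,
    }


def _run_tests(records: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    all_results = []
    arms = sorted(records["arm_label"].unique())
    control = config.role_map.vehicle_arm
    for assay in sorted(records["assay"].unique()):
        all_results.extend(
            rm_anova_timecourse(records, assay, arms, control, alpha=config.alpha)
        )
        for day in sorted(records["day"].unique()):
            all_results.extend(
                per_day_nonparametric(
                    records, assay, day, arms, control, alpha=config.alpha
                )
            )
    return results_frame(all_results)


def _fmt(x: float) -> str:
    """1 decimal; 3 significant figures for magnitudes below 1."""
    return f"{x:.3g}" if abs(x) < 1 else f"{x:.1f}"


def _pm(mean: float, sem: float) -> str:
    return f"{_fmt(mean)} ± {_fmt(sem)}"


def render_tables(
    results: list[InteractionResult],
    effects: pd.DataFrame,
    role_map: ArmRoleMap | None = None,
) -> str:
    """Markdown summary blocks, one per assay.

    Each combination contributes the conventional 4-row block — mono A,
    mono B, observed combo, expected combo — and the vehicle control arm
    closes the table when a role map is given.
    """
    if not results:
        raise AnalysisError("no interaction results to render")
    eff = effects.set_index(["assay", "arm_label"])
    components = (
        {c[0]: (c[1], c[2]) for c in role_map.combinations} if role_map else {}
    )
    lines: list[str] = []
    for assay in sorted({r.assay for r in results}):
        rows = [r for r in results if r.assay == assay]
        lines.append(f"## {assay} ({rows[0].statistic})\n")
        lines.append("| treatment | effect (mean ± SEM) | interaction |")
        lines.append("|---|---|---|")
        seen: set[str] = set()
        for r in rows:
            for comp in components.get(r.combo_arm, ()):
                if comp not in seen and (assay, comp) in eff.index:
                    e = eff.loc[(assay, comp)]
                    lines.append(f"| {comp} | {_pm(e['mean'], e['sem'])} | |")
                    seen.add(comp)
            lines.append(
                f"| Observed {r.combo_arm} | "
                f"{_pm(r.observed_mean, r.observed_sem)} | {r.classification} |"
            )
            lines.append(
                f"| Expected {r.combo_arm} | "
                f"{_pm(r.expected_mean, r.expected_sem)} | p={r.p_value:.3g} |"
            )
        if role_map is not None and (assay, role_map.vehicle_arm) in eff.index:
            e = eff.loc[(assay, role_map.vehicle_arm)]
            lines.append(
                f"| {role_map.vehicle_arm} (control) | "
                f"{_pm(e['mean'], e['sem'])} | |"
            )
        lines.append("")
    return "\n".join(lines) + "\n"


def plot_timecourses(
    records: pd.DataFrame, assay: str, arms: list[str], path
) -> None:
    """Mean +/- SEM time-course plot for the given arms (PNG/PDF by suffix)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    sub = records[records["assay"] == assay]
    for arm in arms:
        g = sub[sub["arm_label"] == arm].groupby("day")["value"]
        mean, sem = g.mean(), g.sem()
        ax.errorbar(mean.index, mean, yerr=sem, marker="o", capsize=3, label=arm)
    ax.set_xlabel("day after surgery")
    ax.set_ylabel(f"{assay} response")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
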