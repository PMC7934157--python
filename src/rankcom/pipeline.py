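"""End-to-end pipeline: simulate (or load) a cohort, score rankings,
calibrate the Monte Carlo null, flag meaningful differences, and emit
the descriptive statistics — as a reproducible report bundle.

All artifacts are plain text (CSV / JSON / markdown) and contain no
timestamps or absolute paths, so a re-run with the same configuration
is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import com as com_mod
from . import stats as stats_mod
from .errors import ContractError, DegenerateFitError, RankcomError
from .items import BUILTIN_ITEM_SETS, DISPLAY_NAMES, ItemSet
from .model import Cohort, read_cohort, write_cohort
from .synthetic import GeneratorConfig, generate_cohort

__all__ = ["RunConfig", "run_pipeline", "derive_seed"]

logger = logging.getLogger("rankcom")

ARTIFACTS = (
    "cohort.csv",
    "com.csv",
    "calibration.json",
    "meaningful_differences.json",
    "stats.json",
    "report.md",
)


def derive_seed(master: int, *path: int) -> int:
    """Derive an independent child seed (< 2**31) from a master seed and
    a fixed integer path, via numpy's SeedSequence."""
    ss = np.random.SeedSequence([int(master), *map(int, path)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``input_path`` / ``generator`` must be set.
    """

    out_dir: Path
    input_path: Optional[Path] = None
    generator: Optional[GeneratorConfig] = None
    item_sets: tuple[str, ...] = ("applications", "strategies")
    n_replicates: int = 1000
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.generator is None):
            raise ContractError(
                "exactly one of input_path / generator must be provided"
            )
        unknown = set(self.item_sets) - set(BUILTIN_ITEM_SETS)
        if unknown:
            raise ContractError(f"unknown item sets: {sorted(unknown)}")


def _round3(x: float) -> float:
    return float(round(x, 3))


def _com_rows(result: com_mod.ComResult) -> list[dict]:
    stratum = result.stratum or "pooled"
    return [
        {
            "item_set": result.item_set.name,
            "stratum": stratum,
            "item": item,
            "com": result.com[item],
            "T": result.T,
        }
        for item in result.item_set.items
    ]


def _write_json(path: Path, payload) -> None:
    path.write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def _report_md(
    cohort: Cohort,
    config: RunConfig,
    com_table: pd.DataFrame,
    calibrations: dict,
    meaningful: dict,
    stats_payload: dict,
) -> str:
    lines = ["# Preference-questionnaire analysis report", ""]
    lines.append(f"Cohort: {len(cohort)} respondents ({cohort.provenance}).")
    lines.append(f"Master seed: {config.seed}; null replicates: "
                 f"{config.n_replicates}.")
    lines.append("")
    for set_name in config.item_sets:
        item_set = BUILTIN_ITEM_SETS[set_name]
        cal = calibrations[set_name]
        lines.append(f"## {set_name.capitalize()} (K = {item_set.rank_depth})")
        lines.append("")
        lines.append(
            f"Chance SD (Monte Carlo, T = {cal['T']}, "
            f"{cal['n_replicates']} replicates, seed {cal['seed']}): "
            f"**{cal['chance_sd']:.3f}**"
        )
        lines.append("")
        sub = com_table[com_table["item_set"] == set_name]
        strata = list(dict.fromkeys(sub["stratum"]))
        lines.append("| Item | " + " | ".join(f"COM ({s})" for s in strata) + " |")
        lines.append("|---" * (1 + len(strata)) + "|")
        for item in item_set.items:
            cells = []
            for s in strata:
                v = sub[(sub["item"] == item) & (sub["stratum"] == s)]["com"]
                cells.append(f"{float(v.iloc[0]):.3f}" if len(v) else "")
            lines.append(
                f"| {DISPLAY_NAMES.get(item, item)} | " + " | ".join(cells) + " |"
            )
        lines.append("")
        pairs = meaningful[set_name]["within_pooled"]
        if pairs:
            lines.append("Meaningful within-cohort differences "
                         "(strictly larger than the chance SD):")
            for i, j in pairs:
                lines.append(
                    f"- {DISPLAY_NAMES.get(i, i)} vs {DISPLAY_NAMES.get(j, j)}"
                )
        else:
            lines.append("No meaningful within-cohort differences.")
        flagged = meaningful[set_name]["between_groups"]
        lines.append("")
        if flagged:
            lines.append("Meaningful NMD-vs-SO differences: "
                         + ", ".join(DISPLAY_NAMES.get(i, i) for i in flagged))
        else:
            lines.append("No meaningful NMD-vs-SO differences.")
        lines.append("")
    lines.append("## Group comparisons and willingness")
    lines.append("")
    for name, w in stats_payload["wilcoxon"].items():
        lines.append(
            f"- {name}: rank sum = {w['rank_sum']:.1f}, z = {w['z']:.3f}, "
            f"p = {w['p_two_sided']:.3f} ({w['method']})"
        )
    for g, reg in stats_payload["willingness_regression"].items():
        if "error" in reg:
            lines.append(f"- willingness ~ movements ({g}): {reg['error']}")
        else:
            lines.append(
                f"- willingness ~ movements ({g}): slope = {reg['slope']:.3f}, "
                f"intercept = {reg['intercept']:.3f}, r2 = {reg['r_squared']:.3f}, "
                f"n = {reg['n']}"
            )
    lines.append("")
    return "\n".join(lines)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run simulate → COM → stats and write the report bundle.

    Returns a mapping from artifact name to written path. Stage errors
    propagate as :class:`RankcomError` subclasses.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    if config.generator is not None:
        gen = config.generator
        logger.info("generating cohort with seed %d", gen.seed)
        cohort = generate_cohort(gen)
    else:
        cohort = read_cohort(config.input_path)
    paths["cohort.csv"] = out / "cohort.csv"
    write_cohort(cohort, paths["cohort.csv"])

    com_rows: list[dict] = []
    calibrations: dict[str, dict] = {}
    meaningful: dict[str, dict] = {}
    for k, set_name in enumerate(config.item_sets):
        item_set = BUILTIN_ITEM_SETS[set_name]
        assignment = com_mod.assign_rank_weights(cohort, item_set)
        pooled = com_mod.compute_com(assignment)
        com_rows += _com_rows(pooled)
        per_group: dict[str, com_mod.ComResult] = {}
        for g in ("NMD", "SO"):
            if any(v == g for v in assignment.groups.values()):
                per_group[g] = com_mod.compute_com(assignment, stratum=g)
                com_rows += _com_rows(per_group[g])
        cal_seed = derive_seed(config.seed, 1, k)
        logger.info("calibrating null for %s with seed %d", set_name, cal_seed)
        cal = com_mod.calibrate_null(
            item_set, assignment.T, config.n_replicates, seed=cal_seed
        )
        calibrations[set_name] = {
            "T": cal.T,
            "n_replicates": cal.n_replicates,
            "seed": cal.seed,
            "chance_sd": cal.chance_sd,
            "analytic_chance_sd": com_mod.analytic_chance_sd(item_set, cal.T),
        }
        within = sorted(com_mod.meaningful_differences(pooled, None, cal))
        between: list[str] = []
        if set(per_group) == {"NMD", "SO"}:
            between = sorted(
                com_mod.meaningful_differences(per_group["NMD"], per_group["SO"], cal)
            )
        meaningful[set_name] = {
            "chance_sd": cal.chance_sd,
            "within_pooled": [list(p) for p in within],
            "between_groups": between,
        }

    com_table = pd.DataFrame(com_rows)
    paths["com.csv"] = out / "com.csv"
    com_table.to_csv(paths["com.csv"], index=False, lineterminator="\n")
    paths["calibration.json"] = out / "calibration.json"
    _write_json(paths["calibration.json"], calibrations)
    paths["meaningful_differences.json"] = out / "meaningful_differences.json"
    _write_json(paths["meaningful_differences.json"], meaningful)

    summary = stats_mod.summarize_cohort(cohort)
    paths["summary.csv"] = out / "summary.csv"
    summary.to_csv(paths["summary.csv"], index=False, lineterminator="\n")

    stats_payload: dict = {"wilcoxon": {}, "willingness_regression": {}}
    nmd = [r for r in cohort if r.group == "NMD"]
    so = [r for r in cohort if r.group == "SO"]
    if nmd and so:
        comparisons = {
            "alsfrs_r": (
                [r.alsfrs_r for r in nmd],
                [r.alsfrs_r for r in so],
            ),
            "years_since_diagnosis": (
                [r.years_since_diagnosis for r in nmd
                 if r.years_since_diagnosis is not None],
                [r.years_since_diagnosis for r in so
                 if r.years_since_diagnosis is not None],
            ),
        }
        for name, (a, b) in comparisons.items():
            if a and b:
                w = stats_mod.wilcoxon_rank_sum(a, b)
                stats_payload["wilcoxon"][name] = {
                    "rank_sum": w.rank_sum,
                    "z": w.z,
                    "p_two_sided": w.p_two_sided,
                    "method": w.method,
                }
    for g in ("NMD", "SO"):
        try:
            reg = stats_mod.fit_willingness_regression(cohort, g)
            stats_payload["willingness_regression"][g] = {
                "slope": reg.slope,
                "intercept": reg.intercept,
                "r_squared": reg.r_squared,
                "n": reg.n,
                "slope_se": reg.slope_se,
            }
        except DegenerateFitError as exc:
            stats_payload["willingness_regression"][g] = {"error": str(exc)}
    paths["stats.json"] = out / "stats.json"
    _write_json(paths["stats.json"], stats_payload)

    report = _report_md(
        cohort, config, com_table, calibrations, meaningful, stats_payload
    )
    paths["report.md"] = out / "report.md"
    paths["report.md"].write_text(report, encoding="utf-8")
    return paths
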