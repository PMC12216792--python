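"""End-to-end orchestration: simulate/ingest -> NTT -> classify -> Y-maze ->
stats -> report.

`run_pipeline` takes a :class:`RunConfig`, executes every stage, writes all
result tables (CSV), a markdown report and a JSON manifest into the output
directory, and returns the in-memory results. The manifest serializes the
full configuration, seed and package version so any run is reproducible.

Stage failures are wrapped in :class:`~boldmaze.errors.PipelineError`
carrying the stage name and affected subjects; callers that need shell
semantics can map that to a nonzero exit (see ``examples/full_pipeline.py``).
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .arena import ntt_arena
from .errors import BoldmazeError, PipelineError
from .io import read_tracking_csv, read_turn_sequence
from .ntt import BoldnessConfig, compute_ntt_endpoints, score_cohort
from .simulate import CohortData, GeneratorConfig, generate_cohort
from .stats import (
    AnovaResult,
    ancova,
    assumption_checks,
    pearson_matrix,
    rm_anova,
    tukey_hsd,
    two_sample_t,
    two_way_anova,
)
from .ymaze import PATTERNS, bin_profiles, profile_to_row, tetragram_counts

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "render_report",
           "build_cohort_table"]

#: Variables entering the per-treatment correlation matrices.
CORRELATION_VARIABLES = [
    "distance_traveled_m", "max_speed_mps", "abs_turn_angle_deg",
    "dist_from_bottom_m", "total_turns", "alternations_pct",
    "repetitions_pct", "boldness_index",
]


@dataclass(frozen=True)
class RunConfig:
    """One reproducible pipeline run.

    Either ``generator`` (synthetic cohort) or ``input_dir`` (a directory
    with ``ntt/<fish>.csv``, ``ymaze_turns/<fish>.csv`` and a
    ``ground_truth.csv``-style metadata table with at least ``subject_id``
    and ``treatment``) must be provided.
    """

    out_dir: str
    seed: int = 0
    generator: Optional[GeneratorConfig] = None
    input_dir: Optional[str] = None
    boldness: BoldnessConfig = field(default_factory=BoldnessConfig)
    session_length_s: float = 3600.0
    bin_length_s: float = 600.0
    alpha: float = 0.05

    def __post_init__(self):
        if (self.generator is None) == (self.input_dir is None):
            raise ValueError("provide exactly one of generator / input_dir")


@dataclass
class PipelineResult:
    """All tables produced by one run, plus where they were written."""

    out_dir: Path
    cohort_table: pd.DataFrame
    endpoints: pd.DataFrame
    binned: pd.DataFrame
    anovas: dict[str, AnovaResult]
    t_tests: pd.DataFrame
    tukey: dict[str, pd.DataFrame]
    correlations: dict[str, pd.DataFrame]
    assumptions: pd.DataFrame
    report_md: str


def _load_cohort(cfg: RunConfig) -> CohortData:
    if cfg.generator is not None:
        gen = dataclasses.replace(cfg.generator, seed=cfg.seed)
        return generate_cohort(gen)
    root = Path(cfg.input_dir)
    meta = pd.read_csv(root / "ground_truth.csv")
    arena = ntt_arena()
    trajectories, events = {}, {}
    for fish_id in meta["subject_id"].astype(str):
        trajectories[fish_id] = read_tracking_csv(root / "ntt" / f"{fish_id}.csv", arena)
        events[fish_id] = read_turn_sequence(root / "ymaze_turns" / f"{fish_id}.csv")
    return CohortData(config=None, latent=meta,
                      ntt_trajectories=trajectories, turn_events=events)


def build_cohort_table(cohort: CohortData, cfg: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compute per-fish endpoints, boldness labels and Y-maze outcomes.

    Returns ``(cohort_table, binned_long)``: one row per fish joining
    phenotype, treatment, NTT endpoints, boldness index and tetragram
    outcomes; and the long-format per-bin alternation/repetition table.
    """
    endpoints = [
        compute_ntt_endpoints(traj, noise_floor=cfg.boldness.noise_floor_m)
        for traj in cohort.ntt_trajectories.values()
    ]
    boldness = score_cohort(endpoints, cfg.boldness)

    global_rows, binned_rows = [], []
    for fish_id, evs in cohort.turn_events.items():
        profile = tetragram_counts([e.token for e in evs], subject_id=fish_id)
        global_rows.append(profile_to_row(profile))
        for b, prof in enumerate(
                bin_profiles(evs, cfg.session_length_s, cfg.bin_length_s,
                             subject_id=fish_id).bins, start=1):
            binned_rows.append({
                "subject_id": fish_id, "bin": b,
                "total_turns": prof.total_turns,
                "alternations_pct": prof.alternations_pct,
                "repetitions_pct": prof.repetitions_pct,
            })

    meta_cols = [c for c in ("subject_id", "treatment", "sex") if c in cohort.latent.columns]
    table = (boldness
             .merge(cohort.latent[meta_cols], on="subject_id")
             .merge(pd.DataFrame(global_rows), on="subject_id"))
    table["group"] = table["treatment"] + "+" + table["phenotype"].str.capitalize()
    binned = pd.DataFrame(binned_rows).merge(
        table[["subject_id", "group"]], on="subject_id")
    return table, binned


def _run_stats(table: pd.DataFrame, binned: pd.DataFrame, cfg: RunConfig):
    anovas: dict[str, AnovaResult] = {}
    # bold vs shy on the four NTT endpoints (pre-stress comparison)
    t_rows = []
    for var in ("distance_traveled_m", "max_speed_mps",
                "abs_turn_angle_deg", "dist_from_bottom_m"):
        bold = table.loc[table.phenotype == "bold", var]
        shy = table.loc[table.phenotype == "shy", var]
        t, df, p = two_sample_t(bold, shy)
        t_rows.append({"endpoint": var, "t": t, "df": df, "p": p})
    t_tests = pd.DataFrame(t_rows)

    anovas["total_turns"] = two_way_anova(
        table, "total_turns", ("phenotype", "treatment"))
    # choice frequency: tetragram pattern (16 levels) x phenotype, per treatment
    long = table.melt(
        id_vars=["subject_id", "phenotype", "treatment"],
        value_vars=[f"pct_{p}" for p in PATTERNS],
        var_name="pattern", value_name="pct")
    for treat, sub in long.groupby("treatment"):
        anovas[f"choice_frequency_{treat}"] = two_way_anova(
            sub, "pct", ("pattern", "phenotype"))
    for dv in ("alternations_pct", "repetitions_pct"):
        anovas[f"ancova_{dv}"] = ancova(
            table, dv, ("phenotype", "treatment"), "total_turns")
        anovas[f"rm_{dv}"] = rm_anova(binned, dv)

    tukey = {
        dv: tukey_hsd(table[dv].to_numpy(), table["group"].to_numpy(), cfg.alpha)
        for dv in ("alternations_pct", "repetitions_pct")
    }
    correlations = pearson_matrix(table, CORRELATION_VARIABLES, by="treatment")

    assume_rows = []
    for dv in ("alternations_pct", "repetitions_pct", "total_turns"):
        groups = {g: sub[dv].to_numpy() for g, sub in table.groupby("group")}
        normality, bartlett_p = assumption_checks(groups)
        for g, p in normality.items():
            assume_rows.append({"variable": dv, "group": g,
                                "ks_normality_p": p, "bartlett_p": bartlett_p})
    return anovas, t_tests, tukey, correlations, pd.DataFrame(assume_rows)


def _group_mean_sem(df: pd.DataFrame, dv: str, by) -> pd.DataFrame:
    g = df.groupby(by, observed=True)[dv]
    out = g.agg(["mean", "sem", "count"]).reset_index()
    out.insert(0, "variable", dv)
    return out


def render_report(table: pd.DataFrame, binned: pd.DataFrame,
                  anovas: dict[str, AnovaResult],
                  correlations: dict[str, pd.DataFrame]) -> str:
    """Markdown summary: group means +/- SEM globally and per bin, ANOVA
    tables and per-treatment correlation matrices."""
    lines = ["# Cohort analysis report", ""]
    if table.empty:
        return "\n".join(lines + ["**Warning: no results to report.**", ""])
    lines.append(f"Fish analysed: {len(table)}; groups: "
                 f"{', '.join(sorted(table['group'].unique()))}", )
    lines.append("")
    lines.append("## Global strategies (mean ± SEM by group)\n")
    lines.append("| variable | group | mean | SEM | n |")
    lines.append("|---|---|---|---|---|")
    for dv in ("total_turns", "alternations_pct", "repetitions_pct"):
        for _, r in _group_mean_sem(table, dv, "group").iterrows():
            lines.append(f"| {dv} | {r['group']} | {r['mean']:.2f} | "
                         f"{r['sem']:.2f} | {int(r['count'])} |")
    lines.append("")
    lines.append("## Strategies across 10-min bins (mean ± SEM by group)\n")
    lines.append("| variable | group | bin | mean | SEM |")
    lines.append("|---|---|---|---|---|")
    for dv in ("alternations_pct", "repetitions_pct"):
        for _, r in _group_mean_sem(binned.dropna(subset=[dv]),
                                    dv, ["group", "bin"]).iterrows():
            lines.append(f"| {dv} | {r['group']} | {int(r['bin'])} | "
                         f"{r['mean']:.2f} | {r['sem']:.2f} |")
    lines.append("")
    lines.append("## Model results\n")
    for name, res in anovas.items():
        lines.append(f"### {name}: `{res.model}`\n")
        lines.append("| effect | df | F | p |")
        lines.append("|---|---|---|---|")
        for _, r in res.table.iterrows():
            lines.append(f"| {r['effect']} | {int(r['df_num'])}, {int(r['df_den'])} "
                         f"| {r['F']:.3f} | {r['p']:.4f} |")
        for note in res.notes:
            lines.append(f"- note: {note}")
        lines.append("")
    lines.append("## Pearson correlations per treatment\n")
    for treat, mat in correlations.items():
        lines.append(f"### {treat}\n")
        lines.append("```")
        lines.append(mat.round(2).to_string())
        lines.append("```")
        lines.append("")
    return "\n".join(lines)


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute every stage and write all outputs under ``cfg.out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except BoldmazeError as exc:
            raise PipelineError(name, str(exc)) from exc

    cohort = stage("ingest", _load_cohort, cfg)
    table, binned = stage("cohort_table", build_cohort_table, cohort, cfg)
    anovas, t_tests, tukey, correlations, assumptions = stage(
        "stats", _run_stats, table, binned, cfg)
    report_md = render_report(table, binned, anovas, correlations)

    table.to_csv(out / "cohort_table.csv", index=False)
    binned.to_csv(out / "tetragrams_binned.csv", index=False)
    t_tests.to_csv(out / "ntt_t_tests.csv", index=False)
    assumptions.to_csv(out / "assumption_checks.csv", index=False)
    for name, res in anovas.items():
        res.table.to_csv(out / f"anova_{name}.csv", index=False)
    for dv, tk in tukey.items():
        tk.to_csv(out / f"tukey_{dv}.csv", index=False)
    for treat, mat in correlations.items():
        mat.to_csv(out / f"correlations_{treat}.csv")
    (out / "report.md").write_text(report_md)

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config": json.loads(json.dumps(dataclasses.asdict(cfg), default=str)),
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("pipeline run complete: %s (%d fish)", out, len(table))

    return PipelineResult(
        out_dir=out, cohort_table=table, endpoints=table, binned=binned,
        anovas=anovas, t_tests=t_tests, tukey=tukey,
        correlations=correlations, assumptions=assumptions,
        report_md=report_md)
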