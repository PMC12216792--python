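"""Synthetic cohort generator.

Emulates a study of ~46 zebrafish carrying a continuous latent boldness
trait, split into control and acutely stressed arms, so that every pipeline
stage runs — and the study design's qualitative effect structure is testable
— without any raw recordings.

Two generative models, deliberately minimal:

* **NTT trajectories** — a correlated random walk in the side-view tank:
  per-frame heading persistence plus Gaussian speed, a constant vertical
  drift (upward for bold fish, downward for shy — geotaxis), and reflecting
  tank walls. The drift-to-diffusion ratio sets the stationary vertical
  distribution, so bold and shy fish separate on distance from bottom and the
  boldness classifier can recover the latent phenotype.

* **Y-maze turn streams** — turn times from a homogeneous Poisson process;
  tokens from a first-order Markov alternation model with time-varying
  alternation probability ``a(t)``. Controls hold ``a`` at a phenotype
  baseline; stressed fish get a Gaussian-shaped dip in ``a`` (equivalently a
  bump in repetition probability) centered on the phenotype's peak bin, the
  bold peak one bin earlier than the shy. The tetragram composition of this
  model is known in closed form — alternation fraction a^3, repetition
  fraction (1-a)^3 — which supplies independent test oracles.

Defaults are chosen so that at the study's group sizes (n = 11-12 per
phenotype x treatment cell) the pipeline reproduces the reported effect
*directions*: stress raises repetitions in both phenotypes, bold stressed
fish show the lowest alternations, and the bold repetition peak precedes the
shy one. Magnitudes are declared, field-typical values, not estimates of the
original animals.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .arena import ntt_arena
from .io import Trajectory, TurnEvent, write_tracking_csv, write_turn_sequence

__all__ = [
    "NttSimConfig",
    "YmazeSimConfig",
    "GeneratorConfig",
    "LatentRecord",
    "CohortData",
    "simulate_ntt",
    "simulate_ymaze",
    "generate_cohort",
]


@dataclass(frozen=True)
class NttSimConfig:
    """Novel-tank random-walk parameters.

    ``vertical_bias_*`` are constant vertical drifts in m/s (positive = up).
    The walk's effective vertical diffusion is ~2e-5 m^2/s (heading
    persistence correlates increments), so +/-2.5e-3 m/s crosses the 0.10 m
    column in ~40 s — the tank mixes well within a 6-min session and the
    bold/shy stationary means sit in the top/bottom fifth, the hallmark
    top-exploration vs. geotaxis contrast. Speeds are typical adult zebrafish
    cruise values; 30 Hz matches common webcam tracking.
    """

    vertical_bias_bold: float = 2.5e-3
    vertical_bias_shy: float = -2.5e-3
    vertical_bias_sd: float = 2e-4     # between-fish jitter (latent trait)
    speed_mean: float = 0.03           # m/s
    speed_sd: float = 0.015            # m/s
    heading_sd: float = 0.6            # rad per frame (persistence noise)
    step_hz: float = 30.0
    duration_s: float = 360.0


@dataclass(frozen=True)
class YmazeSimConfig:
    """Markov alternation-model parameters for the Y-maze turn stream.

    ``a_base_*`` are baseline P(alternate) per phenotype (bold lower: fewer
    alternations). ``stress_repeat_boost`` is the peak additive increase in
    P(repeat) under acute stress, applied as a Gaussian bump of width
    ``peak_width_s`` (SD) centered on the phenotype's peak bin (1-based
    10-min bins; bold bin 5, shy bin 6 — bold peaks one bin earlier).
    """

    a_base_bold: float = 0.70
    a_base_shy: float = 0.80
    a_base_sd: float = 0.02            # between-fish jitter (latent trait)
    stress_repeat_boost: float = 0.25
    peak_bin_bold: int = 5
    peak_bin_shy: int = 6
    peak_width_s: float = 300.0
    bin_length_s: float = 600.0
    turn_rate_per_min: float = 6.0
    duration_s: float = 3600.0


@dataclass(frozen=True)
class GeneratorConfig:
    """Whole-cohort generator settings; seed fully determines the output."""

    n_fish: int = 46
    treatment_split: float = 0.5       # fraction assigned to the stress arm
    seed: int = 0
    ntt: NttSimConfig = field(default_factory=NttSimConfig)
    ymaze: YmazeSimConfig = field(default_factory=YmazeSimConfig)


@dataclass(frozen=True)
class LatentRecord:
    """Ground truth for one synthetic fish: latent phenotype, treatment and
    the realized per-fish generative parameters (for recovery scoring)."""

    subject_id: str
    latent_phenotype: str              # bold | shy
    treatment: str                     # CTRL | CAS
    sex: str                           # M | F (no sex effects generated)
    vertical_bias: float               # m/s
    a_base: float                      # baseline P(alternate)
    peak_bin: int                      # stress repetition-peak bin (1-based)


@dataclass
class CohortData:
    """An in-memory synthetic study: ground truth plus per-fish recordings."""

    config: GeneratorConfig
    latent: pd.DataFrame
    ntt_trajectories: dict[str, Trajectory]
    turn_events: dict[str, list[TurnEvent]]


def _alternation_probability(t: float, latent: LatentRecord,
                             cfg: YmazeSimConfig) -> float:
    """Time-varying P(alternate) for one fish; clipped to [0, 1]."""
    a = latent.a_base
    if latent.treatment == "CAS":
        t_peak = (latent.peak_bin - 0.5) * cfg.bin_length_s
        a -= cfg.stress_repeat_boost * math.exp(
            -0.5 * ((t - t_peak) / cfg.peak_width_s) ** 2)
    return min(1.0, max(0.0, a))


def simulate_ntt(latent: LatentRecord, cfg: NttSimConfig,
                 rng: np.random.Generator) -> Trajectory:
    """Simulate one fish's side-view NTT trajectory.

    Correlated random walk: heading follows a Gaussian random walk, frame
    speed is |N(speed_mean, speed_sd)|, a vertical drift is added, and the
    path reflects off the tank walls. Fish start near the bottom center, the
    canonical novel-tank entry position.
    """
    arena = ntt_arena()
    n = int(round(cfg.duration_s * cfg.step_hz))
    dt = 1.0 / cfg.step_hz
    headings = np.cumsum(rng.normal(0.0, cfg.heading_sd, n))
    headings += rng.uniform(0, 2 * np.pi)
    speeds = np.abs(rng.normal(cfg.speed_mean, cfg.speed_sd, n))
    dx = (speeds * dt * np.cos(headings)).tolist()
    dy = (speeds * dt * np.sin(headings) + latent.vertical_bias * dt).tolist()

    lx, ly = arena.ntt_length, arena.ntt_depth
    x, y = lx / 2.0, 0.02
    xs = [x]
    ys = [y]
    for i in range(n):
        x += dx[i]
        y += dy[i]
        while x < 0 or x > lx:
            x = -x if x < 0 else 2 * lx - x
        while y < 0 or y > ly:
            y = -y if y < 0 else 2 * ly - y
        xs.append(x)
        ys.append(y)
    t = np.arange(n + 1) * dt
    return Trajectory(subject_id=latent.subject_id, arena_id=arena.kind,
                      t=t, x=np.array(xs), y=np.array(ys),
                      frame_rate_hint=cfg.step_hz)


def simulate_ymaze(latent: LatentRecord, cfg: YmazeSimConfig,
                   rng: np.random.Generator) -> list[TurnEvent]:
    """Simulate one fish's 60-min Y-maze turn stream.

    Turn completion times follow a Poisson process at ``turn_rate_per_min``;
    the first token is a fair coin, each later token alternates from its
    predecessor with probability ``a(t)``. Arm identities are tracked so the
    events carry consistent from/to arms (L = counterclockwise).
    """
    rate = cfg.turn_rate_per_min / 60.0
    times: list[float] = []
    t = 0.0
    while True:
        t += rng.exponential(1.0 / rate) if rate > 0 else math.inf
        if t > cfg.duration_s:
            break
        times.append(t)

    events: list[TurnEvent] = []
    arm = int(rng.integers(0, 3))
    prev_token: str | None = None
    for tt in times:
        if prev_token is None:
            token = "L" if rng.random() < 0.5 else "R"
        else:
            a = _alternation_probability(tt, latent, cfg)
            alternate = rng.random() < a
            token = ("R" if prev_token == "L" else "L") if alternate else prev_token
        to_arm = (arm + 1) % 3 if token == "L" else (arm + 2) % 3
        events.append(TurnEvent(token=token, t_completed=tt,
                                from_arm=arm, to_arm=to_arm))
        arm = to_arm
        prev_token = token
    return events


def _assign_latents(cfg: GeneratorConfig,
                    rng: np.random.Generator) -> list[LatentRecord]:
    """Balanced phenotype and treatment assignment with per-fish parameter
    jitter (the continuous latent trait around each phenotype's mean)."""
    n = cfg.n_fish
    width = len(str(n))
    ids = [f"fish{str(i + 1).zfill(width)}" for i in range(n)]

    phenotypes = ["bold"] * (n // 2) + ["shy"] * (n - n // 2)
    n_cas = int(round(n * cfg.treatment_split))
    # interleave treatment within phenotype so cells stay near-balanced
    treatments = []
    cas_left = n_cas
    for i, _ in enumerate(phenotypes):
        take_cas = cas_left > 0 and (i % 2 == 0 or cas_left >= len(phenotypes) - i)
        treatments.append("CAS" if take_cas else "CTRL")
        cas_left -= take_cas
    order = rng.permutation(n)

    records = []
    for idx, fish_id in enumerate(ids):
        k = order[idx]
        pheno, treat = phenotypes[k], treatments[k]
        bias_mean = (cfg.ntt.vertical_bias_bold if pheno == "bold"
                     else cfg.ntt.vertical_bias_shy)
        a_mean = (cfg.ymaze.a_base_bold if pheno == "bold"
                  else cfg.ymaze.a_base_shy)
        records.append(LatentRecord(
            subject_id=fish_id,
            latent_phenotype=pheno,
            treatment=treat,
            sex="F" if rng.random() < 0.5 else "M",
            vertical_bias=float(rng.normal(bias_mean, cfg.ntt.vertical_bias_sd)),
            a_base=float(np.clip(rng.normal(a_mean, cfg.ymaze.a_base_sd), 0.0, 1.0)),
            peak_bin=(cfg.ymaze.peak_bin_bold if pheno == "bold"
                      else cfg.ymaze.peak_bin_shy),
        ))
    return records


def generate_cohort(cfg: GeneratorConfig, out_dir=None) -> CohortData:
    """Generate a complete synthetic study, optionally written to disk.

    When ``out_dir`` is given the layout matches what the ingestion module
    consumes: ``ntt/<fish>.csv`` tracking files, ``ymaze_turns/<fish>.csv``
    turn-sequence files, and ``ground_truth.csv`` with the latent table.
    Identical config + seed reproduce identical cohorts.
    """
    root = np.random.SeedSequence(cfg.seed)
    assign_rng = np.random.default_rng(root.spawn(1)[0])
    latents = _assign_latents(cfg, assign_rng)

    trajectories: dict[str, Trajectory] = {}
    events: dict[str, list[TurnEvent]] = {}
    for i, latent in enumerate(latents):
        fish_seq = np.random.SeedSequence(entropy=cfg.seed, spawn_key=(1, i))
        ntt_rng, ymz_rng = (np.random.default_rng(s) for s in fish_seq.spawn(2))
        trajectories[latent.subject_id] = simulate_ntt(latent, cfg.ntt, ntt_rng)
        events[latent.subject_id] = simulate_ymaze(latent, cfg.ymaze, ymz_rng)

    latent_df = pd.DataFrame([{
        "subject_id": r.subject_id,
        "latent_phenotype": r.latent_phenotype,
        "treatment": r.treatment,
        "sex": r.sex,
        "vertical_bias": r.vertical_bias,
        "a_base": r.a_base,
        "peak_bin": r.peak_bin,
    } for r in latents])

    cohort = CohortData(config=cfg, latent=latent_df,
                        ntt_trajectories=trajectories, turn_events=events)
    if out_dir is not None:
        _write_cohort(cohort, Path(out_dir))
    return cohort


def _write_cohort(cohort: CohortData, out_dir: Path) -> None:
    ntt_dir = out_dir / "ntt"
    ymz_dir = out_dir / "ymaze_turns"
    ntt_dir.mkdir(parents=True, exist_ok=True)
    ymz_dir.mkdir(parents=True, exist_ok=True)
    for fish_id, traj in cohort.ntt_trajectories.items():
        write_tracking_csv(traj, ntt_dir / f"{fish_id}.csv")
    for fish_id, evs in cohort.turn_events.items():
        write_turn_sequence(evs, ymz_dir / f"{fish_id}.csv", fish_id=fish_id)
    cohort.latent.to_csv(out_dir / "ground_truth.csv", index=False)
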