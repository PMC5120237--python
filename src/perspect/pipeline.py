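"""End-to-end wiring: simulate -> fit -> evaluate -> run sessions -> analyze.

A single structured run configuration (YAML) drives every stage; one base
seed fans out to per-stage seeds by fixed offsets so stages stay
independently reproducible.  Every run writes its resolved configuration
and a manifest (seed, config hash, artifact list) next to the outputs, and
rerunning the same configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import trial_analysis as ta
from .algorithms import Algorithm, BPMFAlgorithm, BaselineAlgorithm, KNNAlgorithm, PMFAlgorithm
from .evaluation_protocol import ProtocolConfig, run_protocol
from .message_store import MessageLibrary, load_library
from .recommender_core import FactorModelConfig, PosteriorSamples, fit_bpmf
from .scheduler import Policy, PolicyKind, run_session, session_log
from .synthetic_data import (
    Arm,
    CohortConfig,
    FollowupEffects,
    GeneratorConfig,
    LibraryGenConfig,
    Participant,
    RatingDataset,
    TrueFactors,
    cohort_to_frame,
    generate_cohort,
    generate_library,
    generate_ratings,
    make_rating_oracle,
    simulate_followup,
)

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_config",
    "run_pipeline",
    "run_trial_simulation",
    "TrialResult",
    "STAGES",
]

STAGES = ("simulate", "fit", "evaluate", "run_sessions", "analyze")

_EVAL_ALGOS = {
    "bpmf": lambda cfg: BPMFAlgorithm(cfg.model),
    "pmf": lambda cfg: PMFAlgorithm(),
    "knn": lambda cfg: KNNAlgorithm(),
    "global_mean": lambda cfg: BaselineAlgorithm("GLOBAL_MEAN"),
    "message_mean": lambda cfg: BaselineAlgorithm("MESSAGE_MEAN"),
    "user_mean": lambda cfg: BaselineAlgorithm("USER_MEAN"),
}


class ConfigError(ValueError):
    """A run configuration failed validation (unknown key, bad value)."""


def _build(cls, doc: Mapping | None, where: str, **extra):
    doc = dict(doc or {})
    doc.update(extra)
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(doc) - known
    if unknown:
        raise ConfigError(f"{where}: unknown key(s) {sorted(unknown)}")
    # YAML gives lists where the dataclasses want tuples
    for f in dataclasses.fields(cls):
        if f.name in doc and isinstance(doc[f.name], list):
            doc[f.name] = tuple(doc[f.name])
    try:
        return cls(**doc)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{where}: {exc}") from exc


@dataclass
class RunConfig:
    """Resolved configuration for a pipeline run."""

    seed: int = 0
    output_dir: str = "perspect_run"
    stages: tuple[str, ...] = STAGES
    library: LibraryGenConfig = field(default_factory=LibraryGenConfig)
    pilot: GeneratorConfig = field(default_factory=GeneratorConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    model: FactorModelConfig = field(
        default_factory=lambda: FactorModelConfig(latent_dim=2, n_samples=40, burn_in=30)
    )
    protocol: ProtocolConfig = field(
        default_factory=lambda: ProtocolConfig(n_train_val_repeats=1)
    )
    followup: FollowupEffects = field(default_factory=FollowupEffects)
    evaluate_algorithms: tuple[str, ...] = ("bpmf", "global_mean")
    evaluate_max_users: int = 60
    oracle_noise_sd: float = 0.5

    def __post_init__(self) -> None:
        bad = [s for s in self.stages if s not in STAGES]
        if bad:
            raise ConfigError(f"unknown stage(s) {bad}; valid stages: {list(STAGES)}")
        bad_alg = [a for a in self.evaluate_algorithms if a not in _EVAL_ALGOS]
        if bad_alg:
            raise ConfigError(f"unknown algorithm(s) {bad_alg}")

    def stage_seed(self, k: int) -> int:
        return int((self.seed * 1000003 + 7919 * (k + 1)) % (2**31))

    def to_doc(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj):
                return {
                    f.name: enc(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)
                    if not f.name.startswith("_")
                }
            if isinstance(obj, tuple):
                return list(obj)
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, Mapping):
                return {k: enc(v) for k, v in obj.items()}
            return obj

        return enc(self)


def load_config(source: str | Path | Mapping, seed: int | None = None) -> RunConfig:
    """Parse a YAML file (or mapping) into a validated :class:`RunConfig`."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            doc = yaml.safe_load(fh) or {}
    else:
        doc = dict(source)
    known_sections = {
        "library": LibraryGenConfig,
        "pilot": GeneratorConfig,
        "cohort": CohortConfig,
        "model": FactorModelConfig,
        "protocol": ProtocolConfig,
        "followup": FollowupEffects,
    }
    top = {}
    for key, val in doc.items():
        if key in known_sections:
            top[key] = _build(known_sections[key], val, key)
        else:
            top[key] = val
    cfg = _build(RunConfig, top, "run config")
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    # fan the base seed out to the per-stage seeds by fixed offsets
    cfg = replace(
        cfg,
        library=replace(cfg.library, seed=cfg.stage_seed(0)),
        pilot=replace(cfg.pilot, seed=cfg.stage_seed(1)),
        model=replace(cfg.model, seed=cfg.stage_seed(2)),
        cohort=replace(cfg.cohort, seed=cfg.stage_seed(3)),
        protocol=replace(cfg.protocol, seed=cfg.stage_seed(4)),
    )
    return cfg


# --------------------------------------------------------------------------
# Programmatic trial simulation (the pipeline's computational core)


@dataclass
class TrialResult:
    """Everything a simulated two-arm trial produced."""

    library: MessageLibrary
    cohort: list[Participant]
    model: PosteriorSamples
    sessions: pd.DataFrame  # user, arm, day, message, predicted, rating
    followup: pd.DataFrame
    analysis: dict

    @property
    def days_agreed(self) -> dict:
        return self.analysis["days_agreed"]


def _analyze(sessions: pd.DataFrame, followup: pd.DataFrame, n_days: int) -> dict:
    """Full trial analysis from tidy session logs and follow-up outcomes."""
    series = {}
    for arm in (Arm.INTERVENTION, Arm.COMPARISON):
        logs = sessions[sessions["arm"] == arm.value]
        series[arm.value] = ta.daily_means(logs, arm, n_days=n_days)

    agreed = {a: ta.days_agreed(s) for a, s in series.items()}
    ai, ti = agreed[Arm.INTERVENTION.value]
    ac, tc = agreed[Arm.COMPARISON.value]
    table = [[ai, ti - ai], [ac, tc - ac]]
    try:
        chi2_stat, chi2_p = ta.chi2_2x2(table)
    except ValueError:
        chi2_stat, chi2_p = None, None  # degenerate (e.g. no agreed days at all)

    tt = ta.window_ttest(series[Arm.INTERVENTION.value], series[Arm.COMPARISON.value])

    completers = followup[followup["completed"]]
    influence_rows = []
    for col in [c for c in completers.columns if c.startswith("influence_")]:
        q = col[len("influence_") :]
        influence_rows.extend(
            {"arm": r["arm"], "question": q, "rating": int(r[col])}
            for _, r in completers.iterrows()
        )
    influence = pd.DataFrame(influence_rows)
    influence_tests = {}
    if len(influence):
        for q, tab in ta.dichotomize_influence(influence).items():
            try:
                stat, p = ta.chi2_2x2(tab)
            except ValueError:
                stat, p = None, None
            influence_tests[q] = {"counts": tab.counts.tolist(), "chi2": stat, "p": p}

    quit_counts = np.zeros((2, 2), dtype=int)
    for _, r in completers.iterrows():
        i = 0 if r["arm"] == Arm.INTERVENTION.value else 1
        quit_counts[i, 0 if bool(r["quit_one_day"]) else 1] += 1
    quit_test = None
    if quit_counts.sum() and (quit_counts.sum(0) > 0).all() and (quit_counts.sum(1) > 0).all():
        stat, p = ta.chi2_2x2(quit_counts)
        quit_test = {"counts": quit_counts.tolist(), "chi2": stat, "p": p}

    ladder_test = None
    if len(completers):
        base = dict(zip(completers["id"], completers["baseline_stage"]))
        post = dict(zip(completers["id"], completers["final_stage"]))
        arms = dict(zip(completers["id"], completers["arm"]))
        _, lad_tab = ta.ladder_movement(base, post, arms)
        try:
            stat, p = ta.chi2_2x2(lad_tab)
        except ValueError:
            stat, p = None, None
        ladder_test = {"counts": lad_tab.counts.tolist(), "chi2": stat, "p": p}

    return {
        "daily_means": {
            a: {"means": s.means.tolist(), "n": s.n.tolist()} for a, s in series.items()
        },
        "days_agreed": {
            Arm.INTERVENTION.value: {"count": ai, "total": ti, "proportion": ai / ti},
            Arm.COMPARISON.value: {"count": ac, "total": tc, "proportion": ac / tc},
            "table": table,
            "chi2": chi2_stat,
            "p": chi2_p,
        },
        "daily_rating_ttest": dataclasses.asdict(tt),
        "influence": influence_tests,
        "one_day_quit": quit_test,
        "ladder_movement": ladder_test,
    }


def run_trial_simulation(
    cfg: RunConfig,
    library: MessageLibrary | None = None,
    pilot: RatingDataset | None = None,
    truth: TrueFactors | None = None,
    model: PosteriorSamples | None = None,
) -> TrialResult:
    """Simulate one complete two-arm trial and analyze it.

    Generates a library and pilot rating corpus, fits the recommender on
    the pilot, block-randomizes a cohort, runs daily sessions (recommender
    policy for the intervention arm, seeded rule-based comparator for the
    other), simulates follow-up, and runs the trial analysis.
    """
    if library is None:
        library = generate_library(replace(cfg.library, seed=cfg.library.seed))
    if pilot is None or truth is None:
        pilot, truth = generate_ratings(cfg.pilot, library)
    if model is None:
        model = fit_bpmf(pilot, cfg.model)

    cohort = generate_cohort(cfg.cohort)
    oracle = make_rating_oracle(truth, noise_sd=cfg.oracle_noise_sd, seed=cfg.stage_seed(5))

    logs = []
    for k, participant in enumerate(cohort):
        if participant.arm is Arm.INTERVENTION:
            policy = Policy(kind=PolicyKind.PERSPECT, model=model)
        else:
            policy = Policy(kind=PolicyKind.RULE_BASED, seed=cfg.stage_seed(6) + k)
        state = run_session(
            participant, policy, library, oracle, n=cfg.cohort.n_messages_per_user
        )
        log = session_log(state)
        log.insert(0, "user", participant.id)
        log.insert(1, "arm", participant.arm.value)
        logs.append(log)
    sessions = pd.concat(logs, ignore_index=True)

    followup = simulate_followup(
        cohort,
        cfg.cohort.followup_rate,
        cfg.followup,
        seed=cfg.stage_seed(7),
        arm_effect=cfg.cohort.arm_effect,
    )
    analysis = _analyze(sessions, followup, n_days=cfg.cohort.n_messages_per_user)
    return TrialResult(
        library=library,
        cohort=cohort,
        model=model,
        sessions=sessions,
        followup=followup,
        analysis=analysis,
    )


# --------------------------------------------------------------------------
# File-based pipeline


def _hash_config(doc: dict) -> str:
    return hashlib.sha256(json.dumps(doc, sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the requested stages, writing artifacts under ``out_dir``.

    Stage outputs: ``library.csv``, ``pilot_ratings.csv``, ``cohort.csv``,
    ``item_factors.csv`` (simulate); ``model.npz`` (fit); ``eval_cells.csv``
    (evaluate); ``sessions.csv``, ``followup.csv`` (run_sessions);
    ``analysis.json``, ``daily_means.csv`` (analyze).  The resolved config
    and a manifest are always written.  Returns the manifest.
    """
    out = Path(out_dir if out_dir is not None else cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    doc = cfg.to_doc()
    artifacts: list[str] = []

    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)
    artifacts.append("config.yaml")

    library = pilot = truth = model = None
    sessions = followup = None

    if "simulate" in cfg.stages:
        library = generate_library(cfg.library)
        library.save(out / "library.csv")
        pilot, truth = generate_ratings(cfg.pilot, library)
        pilot.save(out / "pilot_ratings.csv")
        pd.DataFrame(
            truth.item_factors,
            index=pd.Index(truth.message_ids, name="message"),
            columns=[f"f{d}" for d in range(truth.item_factors.shape[1])],
        ).to_csv(out / "item_factors.csv")
        cohort_to_frame(generate_cohort(cfg.cohort)).to_csv(out / "cohort.csv", index=False)
        artifacts += ["library.csv", "pilot_ratings.csv", "item_factors.csv", "cohort.csv"]

    if "fit" in cfg.stages:
        if pilot is None:
            library = load_library(out / "library.csv")
            pilot = RatingDataset.load(out / "pilot_ratings.csv")
        model = fit_bpmf(pilot, cfg.model)
        model.save(out / "model.npz")
        artifacts.append("model.npz")

    if "evaluate" in cfg.stages:
        if pilot is None:
            pilot = RatingDataset.load(out / "pilot_ratings.csv")
        eval_data = pilot
        if cfg.evaluate_max_users and pilot.n_users > cfg.evaluate_max_users:
            keep = pilot.users[: cfg.evaluate_max_users]
            eval_data = pilot.subset_users(keep)
        algos: dict[str, Algorithm] = {
            name: _EVAL_ALGOS[name](cfg) for name in cfg.evaluate_algorithms
        }
        report = run_protocol(algos, eval_data, cfg.protocol)
        report.save(out / "eval_cells.csv")
        artifacts.append("eval_cells.csv")

    if "run_sessions" in cfg.stages or "analyze" in cfg.stages:
        result = run_trial_simulation(cfg, library=library, pilot=pilot, truth=truth, model=model)
        sessions, followup = result.sessions, result.followup
        if "run_sessions" in cfg.stages:
            sessions.to_csv(out / "sessions.csv", index=False)
            followup.to_csv(out / "followup.csv", index=False)
            artifacts += ["sessions.csv", "followup.csv"]
        if "analyze" in cfg.stages:
            with open(out / "analysis.json", "w") as fh:
                json.dump(result.analysis, fh, indent=1, sort_keys=True)
            dm = result.analysis["daily_means"]
            pd.DataFrame(
                {
                    "day": range(1, cfg.cohort.n_messages_per_user + 1),
                    **{f"mean_{a.lower()}": dm[a]["means"] for a in dm},
                    **{f"n_{a.lower()}": dm[a]["n"] for a in dm},
                }
            ).to_csv(out / "daily_means.csv", index=False)
            artifacts += ["analysis.json", "daily_means.csv"]

    manifest = {
        "seed": cfg.seed,
        "config_hash": _hash_config(doc),
        "stages": list(cfg.stages),
        "artifacts": sorted(set(artifacts)),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
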