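"""Study schedule: pretest, five training sessions, posttest.

Per listener: a pretest of one novel-talker then one trained-talker
adaptive block (plus an AzBio-in-noise score), five training sessions of
three trained-talker blocks each, and a posttest identical to the pretest —
19 threshold blocks and 2 AzBio scores.  The assembled long-format dataset
is what the statistics module consumes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import staircase as sc
from .listeners import (
    GeneratingParams,
    ListenerProfile,
    make_responder,
    true_threshold,
)
from .psychometric import DegenerateDesignError, fit_block, reversal_average

THRESHOLD_COLUMNS = [
    "listener", "phase", "session", "block", "talker",
    "threshold", "converged", "fallback_used", "n_trials",
]
TRACE_COLUMNS = [
    "listener", "phase", "session", "block", "talker",
    "trial", "level", "n_correct", "direction", "is_reversal", "step",
]

#: AzBio list identities used at test sessions (metadata only; lists are
#: equally intelligible and scores are simulated at the session level)
AZBIO_LISTS = (3, 5, 8, 9)


@dataclass
class StudyDataset:
    """Analysis-ready simulated study.

    ``tc_thresholds``: one row per adaptive block (listener × phase × block
    × talker).  ``azbio_scores``: one row per listener × {pre, post}.
    ``traces`` holds trial-level staircase records when the simulation ran
    the full procedure; it is empty in threshold-level mode.
    """

    tc_thresholds: pd.DataFrame
    azbio_scores: pd.DataFrame
    provenance: dict = field(default_factory=dict)
    traces: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=TRACE_COLUMNS))

    def validate(self) -> None:
        n_train = self.provenance.get("n_training_sessions", 5)
        per_listener = 2 + 3 * n_train + 2
        counts = self.tc_thresholds.groupby("listener").size()
        if not (counts == per_listener).all():
            raise ValueError(f"expected {per_listener} threshold rows per listener")
        az = self.azbio_scores.groupby("listener").size()
        if not (az == 2).all():
            raise ValueError("expected exactly 2 AzBio rows per listener")
        if not np.isfinite(self.tc_thresholds["threshold"]).all():
            raise ValueError("non-finite thresholds present")

    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.tc_thresholds.to_csv(path / "thresholds.csv", index=False)
        self.azbio_scores.to_csv(path / "azbio.csv", index=False)
        if len(self.traces):
            self.traces.to_csv(path / "traces.csv", index=False)
        (path / "provenance.json").write_text(json.dumps(self.provenance, indent=2))

    @classmethod
    def from_dir(cls, path) -> "StudyDataset":
        path = Path(path)
        prov = {}
        if (path / "provenance.json").exists():
            prov = json.loads((path / "provenance.json").read_text())
        traces = pd.DataFrame(columns=TRACE_COLUMNS)
        if (path / "traces.csv").exists():
            traces = pd.read_csv(path / "traces.csv")
        return cls(
            tc_thresholds=pd.read_csv(path / "thresholds.csv"),
            azbio_scores=pd.read_csv(path / "azbio.csv"),
            provenance=prov,
            traces=traces,
        )


def _schedule(n_training_sessions: int):
    """Enumerate (phase, session, block, talker) in presentation order."""
    sched = [("pre", None, 1, "novel"), ("pre", None, 2, "trained")]
    for s in range(1, n_training_sessions + 1):
        for b in range(1, 4):
            sched.append(("training", s, b, "trained"))
    sched += [("post", None, 1, "novel"), ("post", None, 2, "trained")]
    return sched


def _phase_label(phase: str, session) -> str:
    return f"train{session}" if phase == "training" else phase


def _config_hash(params: GeneratingParams, config: sc.StaircaseConfig) -> str:
    blob = json.dumps({"params": vars(params) | {"learning_curve": list(params.learning_curve)},
                       "staircase": vars(config)}, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def run_study(
    cohort: Sequence[ListenerProfile],
    params: GeneratingParams = GeneratingParams(),
    config: sc.StaircaseConfig = sc.StaircaseConfig(),
    rng_seed: int = 0,
    mode: str = "threshold_level",
    scoring: str = "keyword",
    exhaust_pool: bool = False,
) -> StudyDataset:
    """Simulate the full protocol for every listener in the cohort.

    In ``trial_level`` mode each block runs the adaptive staircase against
    the listener's psychometric curve and the block threshold is the
    psychometric fit (reversal-average fallback on degenerate blocks,
    flagged, never dropped).  In ``threshold_level`` mode block thresholds
    are drawn directly from the generating model plus residual noise.

    Block RNG streams are derived from (study seed, listener index, phase,
    block), so any block is reproducible in isolation.
    """
    ineligible = [p.id for p in cohort if not p.is_eligible()]
    if ineligible:
        raise ValueError(f"ineligible listeners in cohort: {ineligible}")

    sched = _schedule(params.n_training_sessions)
    thr_rows, trace_rows, az_rows = [], [], []

    for li, profile in enumerate(cohort):
        pool = sc.SentencePool(exhaust_pool=exhaust_pool) if mode == "trial_level" else None
        for phase, session, block, talker in sched:
            phase_code = {"pre": 0, "training": 1, "post": 2}[phase]
            rng = np.random.default_rng(
                np.random.SeedSequence([int(rng_seed), li, phase_code, session or 0, block])
            )
            label = _phase_label(phase, session)
            if mode == "threshold_level":
                thr = make_responder(profile, phase, session, talker, params,
                                     mode="threshold_level", rng=rng)
                thr_rows.append((profile.id, label, session, block, talker,
                                 float(thr), True, False, 0))
            else:
                responder = make_responder(profile, phase, session, talker, params,
                                           mode="trial_level", rng=rng)
                records = sc.run_block(responder, config, rng, pool=pool)
                try:
                    fit = fit_block(records, lapse=params.lapse, scoring=scoring,
                                    keywords_per_sentence=config.keywords_per_sentence,
                                    correct_majority=config.correct_majority)
                    thr, conv, fb = fit.threshold, fit.converged, fit.fallback_used
                except DegenerateDesignError:
                    thr, conv, fb = reversal_average(records), False, True
                thr_rows.append((profile.id, label, session, block, talker,
                                 float(thr), bool(conv), bool(fb), len(records)))
                trace_rows.extend(
                    (profile.id, label, session, block, talker, t.trial_index,
                     t.level, t.n_correct, t.direction, t.is_reversal, t.step_in_force)
                    for t in records
                )
        az_rows.append((profile.id, "pre", float(profile.azbio_pre)))
        # post = pre + change, unclamped: the change is modeled additively so
        # its mean stays exactly recoverable by the paired analysis
        az_rows.append((profile.id, "post", float(profile.azbio_pre + profile.azbio_change)))

    dataset = StudyDataset(
        tc_thresholds=pd.DataFrame(thr_rows, columns=THRESHOLD_COLUMNS),
        azbio_scores=pd.DataFrame(az_rows, columns=["listener", "phase", "score"]),
        provenance={
            "seed": int(rng_seed),
            "mode": mode,
            "scoring": scoring,
            "n_listeners": len(cohort),
            "n_training_sessions": params.n_training_sessions,
            "azbio_lists": list(AZBIO_LISTS),
            "config_hash": _config_hash(params, config),
        },
        traces=pd.DataFrame(trace_rows, columns=TRACE_COLUMNS),
    )
    dataset.validate()
    return dataset


def session_summary(dataset: StudyDataset) -> pd.DataFrame:
    """Across-listener mean ± SE of thresholds per phase × talker.

    Training sessions first average the three blocks within listener, so
    each listener contributes one value per cell; SE = SD/√n.
    """
    df = dataset.tc_thresholds
    if df.empty:
        raise ValueError("empty dataset")
    per_listener = (
        df.groupby(["phase", "talker", "listener"], sort=False)["threshold"]
        .mean()
        .reset_index()
    )
    out = (
        per_listener.groupby(["phase", "talker"], sort=False)["threshold"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    out["se"] = (out["sd"] / np.sqrt(out["n"])).fillna(0.0)
    out.loc[out["n"] <= 1, "se"] = 0.0
    train_labels = sorted(
        (p for p in df["phase"].unique() if str(p).startswith("train")),
        key=lambda p: int(str(p)[5:]),
    )
    order = ["pre"] + train_labels + ["post"]
    out["phase"] = pd.Categorical(out["phase"], categories=order, ordered=True)
    return out.sort_values(["phase", "talker"]).reset_index(drop=True)
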