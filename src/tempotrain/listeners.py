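"""Synthetic cochlear-implant listener cohorts.

Generates simulated listeners whose block thresholds follow the additive
structure the downstream mixed model assumes:

    threshold = mu + b_i + delta_time·[posttest] + delta_talker·[novel]
              + delta_interaction·[posttest ∧ novel]
              + delta_time·learning(session)·[training]

with per-listener random intercepts b_i ~ Normal(0, var_subject) and
block-level residual noise.  Speech-in-noise (AzBio) performance is
simulated directly as a pre score plus a paired change.  Default generating
values are the fitted effects the package's recovery experiments target.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .psychometric import PsychometricCurve, _prob

PHASES = ("pre", "training", "post")
TALKERS = ("trained", "novel")


class ConfigError(ValueError):
    """Invalid simulation configuration."""


class ProtocolViolationError(ValueError):
    """A phase/talker/session combination the study design does not contain."""


@dataclass(frozen=True)
class GeneratingParams:
    """Generating values for the simulated study.

    Threshold-scale parameters are percent time-compression.  ``sd_resid``
    is the block-level residual SD, derived from the reported SE of the
    test-time effect in the balanced design (SE² = 2·σ²/14 → σ ≈ 4.4).
    ``azbio_sd_change`` is the SD of the paired AzBio change implied by the
    reported mean ± SE at n = 14 (2.1·√14 ≈ 7.857).
    """

    mu: float = 25.8
    delta_time: float = 8.2
    delta_talker: float = 5.2
    delta_interaction: float = -1.9
    var_subject: float = 243.1
    sd_resid: float = 4.4
    slope: float = 0.15
    lapse: float = 0.0
    learning_curve: tuple = (0.2, 0.2, 0.2, 0.2, 0.2)
    azbio_mu_pre: float = 55.0
    azbio_sd_pre: float = 15.0
    azbio_delta: float = 6.3
    azbio_sd_change: float = 7.857

    def __post_init__(self) -> None:
        if self.var_subject < 0:
            raise ConfigError("var_subject must be non-negative")
        if self.sd_resid < 0:
            raise ConfigError("sd_resid must be non-negative")
        lc = np.asarray(self.learning_curve, float)
        if np.any(lc < 0) or abs(lc.sum() - 1.0) > 1e-9:
            raise ConfigError("learning_curve must be non-negative fractions summing to 1")

    @property
    def n_training_sessions(self) -> int:
        return len(self.learning_curve)

    def cumulative_learning(self, session: int) -> float:
        """Fraction of the full training gain realised by ``session`` (1-based)."""
        if not 1 <= session <= self.n_training_sessions:
            raise ProtocolViolationError(f"session {session} outside 1..{self.n_training_sessions}")
        return float(np.cumsum(self.learning_curve)[session - 1])

    def with_overrides(self, **kwargs) -> "GeneratingParams":
        return replace(self, **kwargs)


#: study eligibility criteria: cognitive screen and aided word recognition
MOCA_MIN = 22
CNC_MIN = 20.0


@dataclass(frozen=True)
class ListenerProfile:
    """One simulated listener: demographics plus latent simulation state."""

    id: str
    sex: str
    age: float
    moca: float
    duration_deafness: float
    duration_ci_use: float
    cnc_score: float
    n_cis: int
    b_i: float
    azbio_pre: float
    azbio_change: float

    def is_eligible(self) -> bool:
        return self.moca >= MOCA_MIN and self.cnc_score >= CNC_MIN


def load_demographics_fixture() -> pd.DataFrame:
    """Demographics of the 14 enrolled listeners (packaged transcription)."""
    with importlib.resources.files("tempotrain").joinpath(
        "data/enrolled_cohort_demographics.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def _fixture_demographics() -> list[dict]:
    df = load_demographics_fixture()
    out = []
    for _, r in df.iterrows():
        deaf = np.nanmean([r.dur_deafness_left, r.dur_deafness_right])
        ci = np.nanmean([r.dur_ci_use_left, r.dur_ci_use_right])
        n_cis = 2 if np.isfinite(r.dur_ci_use_left) and np.isfinite(r.dur_ci_use_right) else 1
        out.append(
            dict(id=r.code, sex=r.sex, age=float(r.age), moca=float(r.moca),
                 duration_deafness=float(deaf), duration_ci_use=float(ci),
                 cnc_score=float(r.cnc_score), n_cis=n_cis)
        )
    return out


def _parametric_demographics(rng: np.random.Generator, idx: int) -> dict:
    """One random demographic draw (may be ineligible; caller filters)."""
    return dict(
        id=f"L{idx:03d}",
        sex=rng.choice(["F", "M"]),
        age=float(rng.uniform(30.0, 82.0)),
        moca=float(np.clip(np.round(rng.normal(27.5, 2.0)), 0, 30)),
        duration_deafness=float(rng.gamma(1.2, 7.0)),
        duration_ci_use=float(rng.uniform(1.0, 25.0)),
        cnc_score=float(np.clip(rng.normal(80.0, 16.0), 0.0, 100.0)),
        n_cis=int(1 + rng.integers(0, 2)),
    )


def sample_cohort(
    n: int,
    params: GeneratingParams = GeneratingParams(),
    demographics_source: str = "parametric",
    rng_seed: Union[int, np.random.Generator, np.random.SeedSequence] = 0,
) -> list[ListenerProfile]:
    """Draw a cohort of eligible simulated listeners.

    ``demographics_source='fixture'`` copies the 14 enrolled listeners'
    demographics verbatim (n must be 14); ``'parametric'`` draws them from
    broad distributions and redraws until ``n`` pass the eligibility screen
    (MoCA ≥ 22, CNC ≥ 20%).  Latent state (random intercept, AzBio scores)
    is always drawn fresh.
    """
    if n < 2:
        raise ConfigError("cohort size must be at least 2")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )

    if demographics_source == "fixture":
        if n != 14:
            raise ConfigError("fixture demographics describe exactly 14 listeners")
        demos = _fixture_demographics()
    elif demographics_source == "parametric":
        demos, idx = [], 0
        while len(demos) < n:
            d = _parametric_demographics(rng, idx)
            idx += 1
            if d["moca"] >= MOCA_MIN and d["cnc_score"] >= CNC_MIN:
                demos.append(d)
    else:
        raise ConfigError(f"unknown demographics source: {demographics_source!r}")

    sd_b = float(np.sqrt(params.var_subject))
    cohort = []
    for d in demos:
        cohort.append(
            ListenerProfile(
                **d,
                b_i=float(rng.normal(0.0, sd_b)),
                azbio_pre=float(np.clip(rng.normal(params.azbio_mu_pre, params.azbio_sd_pre), 0.0, 100.0)),
                azbio_change=float(rng.normal(params.azbio_delta, params.azbio_sd_change)),
            )
        )
    return cohort


def cohort_frame(cohort: Sequence[ListenerProfile]) -> pd.DataFrame:
    """Cohort as a tidy table (one row per listener)."""
    return pd.DataFrame([vars(p) for p in cohort])


def true_threshold(
    profile: ListenerProfile,
    phase: str,
    session: Optional[int],
    talker: str,
    params: GeneratingParams = GeneratingParams(),
) -> float:
    """Noise-free block threshold implied by the generating model."""
    if phase not in PHASES:
        raise ProtocolViolationError(f"unknown phase {phase!r}")
    if talker not in TALKERS:
        raise ProtocolViolationError(f"unknown talker {talker!r}")
    if (phase == "training") != (session is not None):
        raise ProtocolViolationError("session must be given iff phase is 'training'")
    if phase == "training" and talker != "trained":
        raise ProtocolViolationError("training blocks use the trained talker only")

    theta = params.mu + profile.b_i
    if talker == "novel":
        theta += params.delta_talker
    if phase == "post":
        theta += params.delta_time
        if talker == "novel":
            theta += params.delta_interaction
    elif phase == "training":
        theta += params.delta_time * params.cumulative_learning(session)
    return float(theta)


def make_responder(
    profile: ListenerProfile,
    phase: str,
    session: Optional[int],
    talker: str,
    params: GeneratingParams = GeneratingParams(),
    mode: str = "trial_level",
    rng: Optional[np.random.Generator] = None,
):
    """Link the generating model to the measurement procedure.

    ``mode='trial_level'`` returns a callable level → keyword count drawn
    Binomial(5, p(level)) from the listener's psychometric curve — the input
    the staircase consumes.  ``mode='threshold_level'`` bypasses the
    procedure and returns a direct block-threshold draw
    θ_true + Normal(0, sd_resid²), for precise recovery experiments.
    """
    theta = true_threshold(profile, phase, session, talker, params)
    rng = np.random.default_rng() if rng is None else rng

    if mode == "threshold_level":
        return float(theta + rng.normal(0.0, params.sd_resid))
    if mode != "trial_level":
        raise ConfigError(f"unknown responder mode: {mode!r}")

    curve = PsychometricCurve(theta, params.slope, params.lapse)

    def responder(level: float) -> int:
        return int(rng.binomial(5, float(_prob(curve, level))))

    return responder
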