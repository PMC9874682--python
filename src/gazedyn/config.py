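"""Configuration objects for the synthetic sentence-reading experiment.

The defaults encode the design of the study the package models: 44 readers,
72 single-line sentences of 11-16 tokens, nine correlated language/literacy
skill measures, word lengths with mean ~6 and SD ~2 characters, and a strong
negative length-frequency correlation (r ~ -0.73).  The ground-truth effect
structure is segmented-linear in word length and word position, with
skill-dependent modifiers, so the downstream analysis stages have a known
signal to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "SKILL_MEASURES",
    "SKEWED_MEASURES",
    "DEFAULT_SKILL_CORRELATION",
    "SegmentedEffect",
    "LogisticEventModel",
    "GroundTruth",
    "ArtifactRates",
    "SimulationConfig",
    "default_ground_truth",
]

#: The nine skill measures carried by every simulated participant.
SKILL_MEASURES: tuple[str, ...] = (
    "ppvt",        # receptive vocabulary
    "wasi.v",      # expressive vocabulary
    "piat.l",      # listening comprehension
    "wid",         # word identification (decoding)
    "watt",        # word attack (decoding, non-words)
    "piat.r",      # reading comprehension
    "gort.comp",   # oral reading comprehension accuracy
    "gort.wpm",    # oral reading fluency (words per minute)
    "sspan.corr",  # verbal working memory (sentence span)
)

#: Measures given a deliberate negative skew by the generator so that the
#: Box-Cox stage of preprocessing has genuine work to do (|skew| > 0.5).
SKEWED_MEASURES: tuple[str, ...] = ("ppvt", "watt", "piat.r", "gort.comp")

# Pairwise correlations between the transformed, standardized skill measures
# of the reference sample (lower triangle, same order as SKILL_MEASURES).
_CORR_LOWER = [
    [1.000],
    [0.829, 1.000],
    [0.638, 0.541, 1.000],
    [0.816, 0.716, 0.441, 1.000],
    [0.376, 0.354, -0.025, 0.613, 1.000],
    [0.798, 0.718, 0.634, 0.714, 0.317, 1.000],
    [0.673, 0.610, 0.625, 0.586, 0.367, 0.648, 1.000],
    [0.577, 0.577, 0.177, 0.617, 0.347, 0.481, 0.348, 1.000],
    [0.626, 0.669, 0.380, 0.601, 0.392, 0.573, 0.557, 0.474, 1.000],
]


def _symmetrize(lower: list[list[float]]) -> np.ndarray:
    k = len(lower)
    m = np.zeros((k, k))
    for i, row in enumerate(lower):
        for j, v in enumerate(row):
            m[i, j] = m[j, i] = v
    return m


#: Population correlation matrix of the nine skill measures (positive definite).
DEFAULT_SKILL_CORRELATION: np.ndarray = _symmetrize(_CORR_LOWER)


@dataclass(frozen=True)
class SegmentedEffect:
    """A broken-line effect: two slopes meeting at breakpoint ``psi``.

    Slopes are in ms per unit of the (centered) predictor.
    """

    psi: float
    slope_below: float
    slope_above: float

    def value(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return np.where(
            x <= self.psi,
            self.slope_below * (x - self.psi),
            self.slope_above * (x - self.psi),
        )


@dataclass(frozen=True)
class LogisticEventModel:
    """Log-odds model for a binary scanpath event (skip/regress/refixate)."""

    intercept: float
    length_coef: float = 0.0
    frequency_coef: float = 0.0
    position_coef: float = 0.0

    def probability(self, length_c: float = 0.0, freq_z: float = 0.0,
                    position_c: float = 0.0) -> float:
        eta = (self.intercept + self.length_coef * length_c
               + self.frequency_coef * freq_z + self.position_coef * position_c)
        return 1.0 / (1.0 + np.exp(-eta))


@dataclass(frozen=True)
class GroundTruth:
    """Generative parameters whose recovery the pipeline is tested against.

    ``interaction_coefficients`` maps a skill name to per-lexical-property
    modifiers (ms per predictor unit per skill SD) that enter the structural
    mean of fixation durations multiplied by the reader's skill score.

    The event models separate three behaviors: ``multifix_model`` governs a
    second consecutive fixation inside the first-pass run (FFD < FPRT);
    ``refixation_model`` governs a return to an already-read word during the
    re-reading pass (refixation incidence); ``skipped_revisit_prob`` is the
    chance a word skipped on first pass is fixated during re-reading (these
    words contribute total-reading-time rows without first-pass measures).
    """

    baseline_duration: float = 230.0          # ms
    length_effect: SegmentedEffect = SegmentedEffect(1.4, 7.0, 24.0)
    position_effect: SegmentedEffect = SegmentedEffect(0.5, -15.0, 10.0)
    interaction_coefficients: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "oral_comp": {"length": -2.5},
            "sspan_corr": {"length": 2.9, "position": -2.2},
            "gort_wpm": {"position": 2.0},
            "decod_comp": {"frequency": 4.0},
        }
    )
    skip_model: LogisticEventModel = LogisticEventModel(
        intercept=-0.45, length_coef=-0.35, frequency_coef=0.25)
    regression_model: LogisticEventModel = LogisticEventModel(
        intercept=-1.75, position_coef=0.12)
    refixation_model: LogisticEventModel = LogisticEventModel(
        intercept=-1.85, length_coef=0.20)
    multifix_model: LogisticEventModel = LogisticEventModel(
        intercept=-0.90, length_coef=0.30)
    skipped_revisit_prob: float = 0.65
    duration_noise: float = 0.32              # lognormal sigma (log scale)

    def __post_init__(self) -> None:
        if self.baseline_duration <= 0:
            raise ValueError("baseline_duration must be positive")
        if self.duration_noise < 0:
            raise ValueError("duration_noise must be non-negative")


def default_ground_truth() -> GroundTruth:
    return GroundTruth()


@dataclass(frozen=True)
class ArtifactRates:
    """Per-fixation rates for recording artifacts injected by the generator."""

    short_fixation_rate: float = 0.02
    blink_rate: float = 0.010
    track_loss_rate: float = 0.005

    def __post_init__(self) -> None:
        for name in ("short_fixation_rate", "blink_rate", "track_loss_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class SimulationConfig:
    """Full description of one synthetic experiment.

    Parameters
    ----------
    n_participants, n_sentences
        Experiment scale; defaults mirror the 44-reader, 72-sentence design.
    tokens_per_sentence
        Inclusive (min, max) token count per sentence; min must be >= 3 so
        interior words survive boundary exclusion.
    skill_correlation
        Population correlation of the skill measures (unit diagonal, PSD).
    length_frequency_corr
        Target correlation between word length and log frequency, in [-1, 0].
    truth
        The generative effect structure (see :class:`GroundTruth`).
    artifact_rates
        Rates for sub-50 ms fixations, blinks and track loss.
    seed
        Root seed; every random stream is derived from it.
    """

    n_participants: int = 44
    n_sentences: int = 72
    tokens_per_sentence: tuple[int, int] = (11, 16)
    skill_correlation: np.ndarray = field(
        default_factory=lambda: DEFAULT_SKILL_CORRELATION.copy())
    skill_names: Sequence[str] = SKILL_MEASURES
    skewed_measures: Sequence[str] = SKEWED_MEASURES
    length_frequency_corr: float = -0.731
    length_mean: float = 6.03
    length_sd: float = 2.03
    log_frequency_mean: float = 10.16
    log_frequency_sd: float = 1.85
    truth: GroundTruth = field(default_factory=default_ground_truth)
    artifact_rates: ArtifactRates = field(default_factory=ArtifactRates)
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1 or self.n_sentences < 1:
            raise ValueError("experiment scale must be positive")
        lo, hi = self.tokens_per_sentence
        if lo > hi or lo < 3:
            raise ValueError(
                "tokens_per_sentence must be a non-empty range with min >= 3")
        c = np.asarray(self.skill_correlation, dtype=float)
        if c.shape[0] != c.shape[1] or c.shape[0] != len(self.skill_names):
            raise ValueError("skill_correlation shape does not match skill_names")
        if not np.allclose(np.diag(c), 1.0):
            raise ValueError("skill_correlation must have unit diagonal")
        if not np.allclose(c, c.T):
            raise ValueError("skill_correlation must be symmetric")
        if np.linalg.eigvalsh(c).min() < -1e-10:
            raise ValueError("skill_correlation must be positive semi-definite")
        if not -1.0 <= self.length_frequency_corr <= 0.0:
            raise ValueError("length_frequency_corr must lie in [-1, 0]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["skill_correlation"] = np.asarray(self.skill_correlation).tolist()
        d["skill_names"] = list(self.skill_names)
        d["skewed_measures"] = list(self.skewed_measures)
        d["tokens_per_sentence"] = list(self.tokens_per_sentence)
        return d
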