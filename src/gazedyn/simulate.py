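"""Synthetic sentence-reading experiments with known ground truth.

The generator produces the three tables a reading eye-movement analysis
consumes -- per-participant skill scores, sentence stimuli with per-word
lengths and log frequencies, and per-trial fixation sequences -- plus the
:class:`~gazedyn.config.GroundTruth` that produced them.  Scanpaths are
strictly left-to-right with probabilistic skips, refixations and first-pass
regressions, and lognormal fixation durations around a structural mean that
is segmented-linear in word length and word position and modulated by reader
skill.  This is deliberately not an oculomotor model (no saccade landing
sites, no preview): it emulates the statistical structure of word-level gaze
data, which is what the downstream stages operate on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import (
    ArtifactRates,
    GroundTruth,
    SimulationConfig,
    SKILL_MEASURES,
)

__all__ = [
    "COMPOSITE_COMPONENTS",
    "SyntheticDataset",
    "generate_skills",
    "generate_corpus",
    "simulate_trial",
    "simulate_dataset",
]

#: Composite skill constructs and their component measures.  Used both by the
#: generator (latent reader effects) and by preprocessing (observed composites).
COMPOSITE_COMPONENTS: dict[str, tuple[str, ...]] = {
    "oral_comp": ("ppvt", "wasi.v", "piat.l"),
    "decod_comp": ("wid", "watt"),
    "readcomp_comp": ("piat.r", "gort.comp"),
    "gort_wpm": ("gort.wpm",),
    "sspan_corr": ("sspan.corr",),
}

_SACCADE_GAP_MS = 25.0     # nominal inter-fixation gap used for onset times
_MIN_DURATION_MS = 60.0    # oculomotor floor for genuine fixations
_SKEW_K = 0.25             # curvature of the monotone skewing transform


@dataclass
class SyntheticDataset:
    """One complete simulated experiment."""

    skills: pd.DataFrame          # participant_id x skill measures
    stimuli: pd.DataFrame         # one row per word token
    fixations: pd.DataFrame       # one row per fixation/blink/track-loss event
    truth: GroundTruth
    reader_effects: pd.DataFrame  # latent standardized composite skills
    config: SimulationConfig = field(default_factory=SimulationConfig)


def _correlated_gaussian(n: int, corr: np.ndarray,
                         rng: np.random.Generator) -> np.ndarray:
    corr = np.asarray(corr, dtype=float)
    eigval, eigvec = np.linalg.eigh(corr)
    if eigval.min() < -1e-10:
        raise ValueError("correlation matrix is not positive semi-definite")
    factor = eigvec * np.sqrt(np.clip(eigval, 0.0, None))
    z = rng.standard_normal((n, corr.shape[0]))
    return z @ factor.T


def _skew_transform(x: np.ndarray, k: float = _SKEW_K) -> np.ndarray:
    """Monotone increasing map giving a standard normal a negative skew.

    ``y = (1 - exp(-k x)) / k``; re-standardized with the closed-form moments
    of the transformed standard normal so the output is population-Z-scaled.
    """
    y = (1.0 - np.exp(-k * x)) / k
    mean = (1.0 - np.exp(k * k / 2.0)) / k
    sd = np.sqrt((np.exp(k * k) - 1.0) * np.exp(k * k)) / k
    return (y - mean) / sd


def generate_skills(
    n: int,
    corr: np.ndarray,
    seed: int | np.random.SeedSequence,
    skill_names: Sequence[str] = SKILL_MEASURES,
    skew_measures: Sequence[str] = (),
) -> pd.DataFrame:
    """Draw ``n`` jointly Gaussian standardized skill profiles.

    Columns listed in ``skew_measures`` are passed through a monotone
    left-skewing transform (population |skew| ~ 0.8) so that raw scores show
    the negative skew typical of ceiling-prone psychometric tests, giving the
    Box-Cox stage genuine work.  Correlations among untransformed columns
    equal ``corr`` in population; skewed columns attenuate by < 2%.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    corr = np.asarray(corr, dtype=float)
    if corr.shape != (len(skill_names), len(skill_names)):
        raise ValueError("corr shape does not match skill_names")
    if not np.allclose(np.diag(corr), 1.0):
        raise ValueError("corr must have unit diagonal")
    rng = np.random.default_rng(seed)
    scores = _correlated_gaussian(n, corr, rng)
    out = pd.DataFrame(scores, columns=list(skill_names))
    for m in skew_measures:
        out[m] = _skew_transform(out[m].to_numpy())
    out.insert(0, "participant_id", [f"p{i + 1:03d}" for i in range(n)])
    return out


def _draw_lengths(n: int, mean: float, sd: float,
                  rng: np.random.Generator) -> np.ndarray:
    # Gamma keeps the mild right skew of real word-length distributions.
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    g = rng.gamma(shape, scale, size=n)
    return np.clip(np.round(g), 2, 14).astype(int)


def generate_corpus(
    n_sentences: int,
    token_range: tuple[int, int],
    length_frequency_corr: float,
    seed: int | np.random.SeedSequence,
    length_mean: float = 6.03,
    length_sd: float = 2.03,
    log_frequency_mean: float = 10.16,
    log_frequency_sd: float = 1.85,
) -> pd.DataFrame:
    """Generate sentence stimuli as one row per word token.

    Word lengths follow a discretized gamma law (mean ~6, SD ~2 characters);
    log frequencies are Gaussian with the requested negative correlation with
    length.  Words are laid out on a monospace line with single spaces, so
    each token occupies the half-open character interval
    ``[char_start, char_end)``.
    """
    lo, hi = token_range
    if lo > hi or lo < 3 or hi > 30:
        raise ValueError("token_range must satisfy 3 <= min <= max <= 30")
    if not -1.0 <= length_frequency_corr <= 0.0:
        raise ValueError("length_frequency_corr must lie in [-1, 0]")
    rng = np.random.default_rng(seed)
    letters = np.array(list("abcdefghijklmnopqrstuvwxyz"))
    rho = -length_frequency_corr  # magnitude

    rows = []
    for s in range(n_sentences):
        k = int(rng.integers(lo, hi + 1))
        lengths = _draw_lengths(k, length_mean, length_sd, rng)
        z_len = (lengths - length_mean) / length_sd
        eps = rng.standard_normal(k)
        freq = log_frequency_mean + log_frequency_sd * (
            -rho * z_len + np.sqrt(max(0.0, 1.0 - rho * rho)) * eps)
        start = 0
        sid = f"s{s + 1:03d}"
        for w in range(k):
            text = "".join(rng.choice(letters, size=lengths[w]))
            rows.append((sid, w + 1, text, int(lengths[w]), float(freq[w]),
                         start, start + int(lengths[w])))
            start += int(lengths[w]) + 1
    return pd.DataFrame(
        rows,
        columns=["sentence_id", "word_index", "word_text", "length_chars",
                 "log_frequency", "char_start", "char_end"],
    )


def _structural_mean(truth: GroundTruth, reader: Mapping[str, float],
                     length_c: float, position_c: float,
                     freq_z: float) -> float:
    m = (truth.baseline_duration
         + truth.length_effect.value(length_c)
         + truth.position_effect.value(position_c))
    for skill, mods in truth.interaction_coefficients.items():
        s = reader.get(skill, 0.0)
        m += s * (mods.get("length", 0.0) * length_c
                  + mods.get("position", 0.0) * position_c
                  + mods.get("frequency", 0.0) * freq_z)
    return m


def _draw_duration(mean: float, sigma: float, rng: np.random.Generator) -> float:
    mean = max(mean, _MIN_DURATION_MS)
    if sigma == 0.0:
        return mean
    d = mean * np.exp(sigma * rng.standard_normal() - 0.5 * sigma * sigma)
    return max(d, _MIN_DURATION_MS)


def simulate_trial(
    reader: Mapping[str, float],
    sentence: pd.DataFrame,
    truth: GroundTruth,
    seed: int | np.random.SeedSequence,
    length_mean: float = 6.03,
    length_sd: float = 2.03,
    log_frequency_mean: float = 10.16,
    log_frequency_sd: float = 1.85,
) -> pd.DataFrame:
    """Simulate one reader's scanpath over one sentence.

    The reader first sweeps left to right: each word is skipped with the
    skip model's probability; a fixated word may receive a second
    consecutive fixation (multifix model, giving FFD < FPRT), and at the
    end of its first-pass run may trigger a first-pass regression that
    sends one extra fixation to a random earlier word.  A re-reading pass
    then revisits read words with the refixation model's probability and
    first-pass-skipped words with ``skipped_revisit_prob``.  Fixation
    durations are lognormal draws whose mean is the segmented-linear
    structural mean (so they average to it).

    ``reader`` maps composite skill names (see ``COMPOSITE_COMPONENTS``) to
    standardized scores.
    """
    if len(sentence) == 0:
        raise ValueError("sentence must be non-empty")
    rng = np.random.default_rng(seed)
    k = len(sentence)
    lengths = sentence["length_chars"].to_numpy(dtype=float)
    freqs = sentence["log_frequency"].to_numpy(dtype=float)
    centers = (sentence["char_start"].to_numpy(dtype=float)
               + sentence["char_end"].to_numpy(dtype=float)) / 2.0
    length_c = (lengths - length_mean)
    freq_z = (freqs - log_frequency_mean) / log_frequency_sd
    position_c = np.arange(1, k + 1, dtype=float) - (k + 1) / 2.0

    fixes: list[tuple[int, float, float]] = []  # (word_index, duration, x_char)

    def fixate(w: int) -> None:
        i = w - 1
        m = _structural_mean(truth, reader, length_c[i], position_c[i],
                             freq_z[i])
        fixes.append((w, _draw_duration(m, truth.duration_noise, rng),
                      centers[i]))

    def event(model, i: int) -> bool:
        p = model.probability(length_c=length_c[i], freq_z=freq_z[i],
                              position_c=position_c[i])
        return rng.random() < p

    read_first_pass = np.zeros(k, dtype=bool)
    for w in range(1, k + 1):
        i = w - 1
        if event(truth.skip_model, i):
            continue
        read_first_pass[i] = True
        fixate(w)
        if event(truth.multifix_model, i):
            fixate(w)
        if w > 1 and event(truth.regression_model, i):
            fixate(int(rng.integers(1, w)))  # regressed-to word

    # re-reading pass: refixations of read words, late visits to skipped ones
    for w in range(1, k + 1):
        i = w - 1
        if read_first_pass[i]:
            if event(truth.refixation_model, i):
                fixate(w)
        elif rng.random() < truth.skipped_revisit_prob:
            fixate(w)

    out = pd.DataFrame(fixes, columns=["word_index", "duration_ms", "x_char"])
    out.insert(0, "fixation_index", np.arange(1, len(out) + 1))
    out["event"] = "fixation"
    return out


def _inject_artifacts(trial: pd.DataFrame, rates: ArtifactRates,
                      rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for rec in trial.itertuples(index=False):
        rows.append((rec.word_index, rec.duration_ms, rec.x_char, rec.event))
        if rng.random() < rates.short_fixation_rate:
            rows.append((rec.word_index, float(rng.uniform(10.0, 49.0)),
                         rec.x_char, "fixation"))
        if rng.random() < rates.blink_rate:
            rows.append((rec.word_index, float(rng.uniform(80.0, 300.0)),
                         rec.x_char, "blink"))
        if rng.random() < rates.track_loss_rate:
            rows.append((rec.word_index, float(rng.uniform(50.0, 500.0)),
                         rec.x_char, "track_loss"))
    out = pd.DataFrame(rows,
                       columns=["word_index", "duration_ms", "x_char", "event"])
    out.insert(0, "fixation_index", np.arange(1, len(out) + 1))
    return out


def latent_composites(skills: pd.DataFrame) -> pd.DataFrame:
    """Standardized composite scores from a (latent) skill score table."""
    out = pd.DataFrame({"participant_id": skills["participant_id"]})
    for comp, parts in COMPOSITE_COMPONENTS.items():
        avg = skills[list(parts)].mean(axis=1)
        sd = avg.std(ddof=1)
        out[comp] = (avg - avg.mean()) / sd if sd > 0 else 0.0
    return out


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate a full experiment: skills, stimuli and all trials.

    Deterministic given ``config`` (including its seed): every participant x
    sentence trial has its own child seed spawned from the root seed.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    s_skills, s_corpus, s_trials, s_artifacts = root.spawn(4)

    # Latent (Gaussian) skills drive behavior; observed scores add the skew.
    latent = generate_skills(config.n_participants, config.skill_correlation,
                             s_skills, config.skill_names)
    observed = latent.copy()
    for m in config.skewed_measures:
        observed[m] = _skew_transform(observed[m].to_numpy())
    effects = latent_composites(latent)

    stimuli = generate_corpus(
        config.n_sentences, config.tokens_per_sentence,
        config.length_frequency_corr, s_corpus,
        config.length_mean, config.length_sd,
        config.log_frequency_mean, config.log_frequency_sd)
    by_sentence = dict(tuple(stimuli.groupby("sentence_id", sort=True)))

    trial_seeds = s_trials.spawn(config.n_participants * config.n_sentences)
    art_rng = np.random.default_rng(s_artifacts)
    rates = config.artifact_rates
    inject = (rates.short_fixation_rate > 0 or rates.blink_rate > 0
              or rates.track_loss_rate > 0)

    frames = []
    idx = 0
    for p in range(config.n_participants):
        pid = effects.loc[p, "participant_id"]
        reader = {c: float(effects.loc[p, c]) for c in COMPOSITE_COMPONENTS}
        for sid in sorted(by_sentence):
            trial = simulate_trial(
                reader, by_sentence[sid], config.truth, trial_seeds[idx],
                config.length_mean, config.length_sd,
                config.log_frequency_mean, config.log_frequency_sd)
            idx += 1
            if inject:
                trial = _inject_artifacts(trial, rates, art_rng)
            trial.insert(0, "sentence_id", sid)
            trial.insert(0, "participant_id", pid)
            frames.append(trial)
    fixations = pd.concat(frames, ignore_index=True)

    # Nominal onset times: fixations abut with a constant saccade gap.
    durs = fixations["duration_ms"].to_numpy()
    trial_key = (fixations["participant_id"].astype(str) + "\x00"
                 + fixations["sentence_id"].astype(str))
    onset = np.empty(len(fixations))
    prev_end = 0.0
    prev_key = None
    for i, (key, d) in enumerate(zip(trial_key, durs)):
        if key != prev_key:
            prev_end = 0.0
            prev_key = key
        onset[i] = prev_end
        prev_end = onset[i] + d + _SACCADE_GAP_MS
    fixations.insert(3, "onset_ms", onset)

    return SyntheticDataset(skills=observed, stimuli=stimuli,
                            fixations=fixations, truth=config.truth,
                            reader_effects=effects, config=config)
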