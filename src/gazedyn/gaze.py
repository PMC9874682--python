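"""Word-level gaze measures from raw fixation sequences.

Implements the standard interest-area tally for single-line sentence
reading: clean the fixation stream (minimum duration, blinks, track loss),
resolve fixations to word regions, and compute five measures per word --
first fixation duration (FFD), first-pass reading time (FPRT, a.k.a. gaze
duration), total reading time (TRT), first-pass regression incidence, and
refixation incidence.

Conventions
-----------
* A word has a first-pass run only if its first fixation occurs before any
  fixation on a word to its right; the run is the maximal consecutive block
  of fixations on the word starting at that first entry.
* A word with no first-pass run counts as skipped: FFD/FPRT (and regression)
  are missing, not zero; TRT still accrues from later fixations.  By default
  such later fixations do not count as refixations (a refixation presupposes
  a first pass); set ``refixation_for_skipped=True`` to count them.
* Fixations landing on an inter-word space attach to the following word by
  default (monospace single-line rendering).
* The 50 ms cleaning rule is strict: durations < ``min_duration`` are
  removed, exactly 50 ms is kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "WordRegion",
    "word_regions",
    "clean_fixations",
    "assign_fixations_to_words",
    "compute_word_measures",
    "exclude_and_tabulate",
]

MEASURE_COLUMNS = ("ffd", "fprt", "trt", "regression", "refixation")


@dataclass(frozen=True)
class WordRegion:
    """Character interval occupied by one word on a monospace line."""

    sentence_id: str
    word_index: int
    char_start: int
    char_end: int  # half-open
    is_boundary: bool


def word_regions(stimuli: pd.DataFrame) -> dict[str, list[WordRegion]]:
    """Build ordered word regions per sentence from a stimuli table."""
    out: dict[str, list[WordRegion]] = {}
    for sid, grp in stimuli.groupby("sentence_id", sort=True):
        grp = grp.sort_values("word_index")
        k = len(grp)
        regs = [
            WordRegion(sid, int(r.word_index), int(r.char_start),
                       int(r.char_end),
                       is_boundary=(r.word_index in (1, k)))
            for r in grp.itertuples(index=False)
        ]
        out[sid] = regs
    return out


def clean_fixations(trial: pd.DataFrame,
                    min_duration: float = 50.0) -> pd.DataFrame:
    """Drop blinks, track loss and sub-threshold fixations; re-sequence.

    Keeps exactly the rows with ``event == "fixation"`` and
    ``duration_ms >= min_duration``, preserving order.
    """
    idx = trial["fixation_index"].to_numpy()
    if len(idx) > 1 and not np.all(np.diff(idx) > 0):
        raise ValueError("fixation_index must be strictly increasing")
    keep = (trial["event"] == "fixation") & (trial["duration_ms"] >= min_duration)
    out = trial.loc[keep].copy()
    out["fixation_index"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)


def assign_fixations_to_words(
    trial: pd.DataFrame,
    regions: list[WordRegion],
    space_attachment: str = "following",
) -> pd.DataFrame:
    """Resolve each fixation's ``x_char`` to a ``word_index``.

    Fixations already carrying a valid ``word_index`` pass through unchanged.
    A fixation on the space between words attaches to the following word
    (``space_attachment="following"``) or the preceding one (``"preceding"``).
    Fixations outside the sentence extent are dropped; the number dropped is
    stored in ``out.attrs["n_dropped"]``.
    """
    if space_attachment not in ("following", "preceding"):
        raise ValueError("space_attachment must be 'following' or 'preceding'")
    regions = sorted(regions, key=lambda r: r.word_index)
    starts = np.array([r.char_start for r in regions], dtype=float)
    ends = np.array([r.char_end for r in regions], dtype=float)
    indices = np.array([r.word_index for r in regions])

    has_word = ("word_index" in trial.columns
                and trial["word_index"].notna().all())
    out = trial.copy()
    n_dropped = 0
    if not has_word:
        resolved = np.full(len(trial), -1)
        x = out["x_char"].to_numpy(dtype=float)
        for i, xi in enumerate(x):
            hit = np.where((xi >= starts) & (xi < ends))[0]
            if hit.size:
                resolved[i] = indices[hit[0]]
                continue
            # inter-word space or just outside: apply the attachment rule
            if space_attachment == "following":
                nxt = np.where(starts > xi)[0]
                if nxt.size and xi >= starts[0] - 1:
                    resolved[i] = indices[nxt[0]]
            else:
                prv = np.where(ends <= xi)[0]
                if prv.size and xi < ends[-1] + 1:
                    resolved[i] = indices[prv[-1]]
        keep = resolved > 0
        n_dropped = int((~keep).sum())
        out = out.loc[keep].copy()
        out["word_index"] = resolved[keep]
        out["fixation_index"] = np.arange(1, len(out) + 1)
        out = out.reset_index(drop=True)
    out.attrs["n_dropped"] = n_dropped
    return out


def compute_word_measures(
    trial: pd.DataFrame,
    regions: list[WordRegion],
    refixation_for_skipped: bool = False,
) -> pd.DataFrame:
    """Five gaze measures for every word of one (cleaned, assigned) trial.

    Returns one row per word region with columns ``ffd``, ``fprt``, ``trt``
    (NaN when undefined), ``regression``/``refixation`` (0/1 floats, NaN when
    undefined), plus ``skipped_first_pass`` and ``never_fixated`` flags.
    """
    words = trial["word_index"].to_numpy(dtype=int)
    durs = trial["duration_ms"].to_numpy(dtype=float)
    known = {r.word_index for r in regions}
    if len(words) and not set(words.tolist()) <= known:
        raise ValueError("fixation references a word_index outside the sentence")

    n_fix = len(words)
    rows = []
    for reg in sorted(regions, key=lambda r: r.word_index):
        w = reg.word_index
        on_w = np.where(words == w)[0]
        trt = float(durs[on_w].sum()) if on_w.size else np.nan
        if not on_w.size:
            rows.append((reg.sentence_id, w, np.nan, np.nan, np.nan,
                         np.nan, np.nan, True, True))
            continue
        first = int(on_w[0])
        eligible = not np.any(words[:first] > w)
        if not eligible:
            refix = 1.0 if refixation_for_skipped else 0.0
            rows.append((reg.sentence_id, w, np.nan, np.nan, trt,
                         np.nan, refix, True, False))
            continue
        # first-pass run: maximal consecutive block on w starting at `first`
        end = first
        while end + 1 < n_fix and words[end + 1] == w:
            end += 1
        ffd = float(durs[first])
        fprt = float(durs[first:end + 1].sum())
        regression = np.nan
        if end + 1 < n_fix:
            regression = 1.0 if words[end + 1] < w else 0.0
        else:
            regression = 0.0  # run ends the trial: no regressive saccade seen
        refix = 1.0 if np.any(words[end + 1:] == w) else 0.0
        rows.append((reg.sentence_id, w, ffd, fprt, trt, regression, refix,
                     False, False))
    out = pd.DataFrame(rows, columns=[
        "sentence_id", "word_index", "ffd", "fprt", "trt",
        "regression", "refixation", "skipped_first_pass", "never_fixated"])
    return out


def _trial_measures(fixations: pd.DataFrame,
                    regions_by_sentence: dict[str, list[WordRegion]],
                    refixation_for_skipped: bool = False) -> pd.DataFrame:
    frames = []
    for (pid, sid), grp in fixations.groupby(
            ["participant_id", "sentence_id"], sort=True):
        m = compute_word_measures(grp, regions_by_sentence[sid],
                                  refixation_for_skipped)
        m.insert(0, "participant_id", pid)
        frames.append(m)
    return pd.concat(frames, ignore_index=True)


def exclude_and_tabulate(
    measures: pd.DataFrame,
    stimuli: pd.DataFrame,
    skip_filter: dict | None = None,
    keep_never_fixated: bool = False,
) -> pd.DataFrame:
    """Long-format analysis table: one row per (participant, sentence, word).

    Applies the two standard exclusions: sentence-initial and -final words
    are removed, and words with a high likelihood of being skipped (very
    short AND highly frequent) are removed when ``skip_filter`` is given as
    ``{"max_length": L, "min_log_frequency": F}`` (a word is dropped when
    ``length <= L`` and ``log_frequency >= F``).  Words never fixated in a
    trial are dropped (they carry no measures) unless ``keep_never_fixated``.
    Lexical covariates (position, current/previous/next length and log
    frequency) are joined from the stimuli table.
    """
    stim = stimuli.sort_values(["sentence_id", "word_index"]).copy()
    grp = stim.groupby("sentence_id")
    stim["n_tokens"] = grp["word_index"].transform("max")
    stim["len_prev"] = grp["length_chars"].shift(1)
    stim["len_next"] = grp["length_chars"].shift(-1)
    stim["freq_prev"] = grp["log_frequency"].shift(1)
    stim["freq_next"] = grp["log_frequency"].shift(-1)

    interior = stim[(stim["word_index"] > 1)
                    & (stim["word_index"] < stim["n_tokens"])].copy()
    if skip_filter:
        drop = ((interior["length_chars"] <= skip_filter["max_length"])
                & (interior["log_frequency"]
                   >= skip_filter["min_log_frequency"]))
        interior = interior[~drop]

    cov = interior[["sentence_id", "word_index", "word_text", "length_chars",
                    "log_frequency", "len_prev", "len_next", "freq_prev",
                    "freq_next"]].rename(columns={
                        "length_chars": "len_w", "log_frequency": "freq_w"})
    cov["position"] = interior["word_index"].astype(float)

    table = measures.merge(cov, on=["sentence_id", "word_index"], how="inner")
    if not keep_never_fixated:
        table = table[~table["never_fixated"]]
    return table.reset_index(drop=True)


def extract_measures(
    fixations: pd.DataFrame,
    stimuli: pd.DataFrame,
    min_duration: float = 50.0,
    skip_filter: dict | None = None,
    space_attachment: str = "following",
    refixation_for_skipped: bool = False,
    use_x_char: bool = False,
) -> pd.DataFrame:
    """Clean, assign and tabulate a whole experiment's fixation table."""
    regions = word_regions(stimuli)
    frames = []
    for (pid, sid), grp in fixations.groupby(
            ["participant_id", "sentence_id"], sort=True):
        t = clean_fixations(grp, min_duration)
        if use_x_char:
            t = t.drop(columns=["word_index"], errors="ignore")
        t = assign_fixations_to_words(t, regions[sid], space_attachment)
        m = compute_word_measures(t, regions[sid], refixation_for_skipped)
        m.insert(0, "participant_id", pid)
        frames.append(m)
    measures = pd.concat(frames, ignore_index=True)
    return exclude_and_tabulate(measures, stimuli, skip_filter)
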