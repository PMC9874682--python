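"""Gaze-measure extraction: cleaning, assignment, the five measures."""

import numpy as np
import pandas as pd
import pytest

from gazedyn.gaze import (assign_fixations_to_words, clean_fixations,
                          compute_word_measures, exclude_and_tabulate,
                          word_regions, WordRegion)

from conftest import make_trial


def regions_for(n_words, sid="s1", length=4):
    """Equal-width monospace regions with single-space separators."""
    regs = []
    start = 0
    for w in range(1, n_words + 1):
        regs.append(WordRegion(sid, w, start, start + length,
                               is_boundary=w in (1, n_words)))
        start += length + 1
    return regs


# --------------------------------------------------------------------------
# independent oracle: a single-pass state machine over the fixation stream

def oracle_measures(words, durs, n_words):
    """Literal walk of the fixation sequence per the measure definitions.

    Tracks, in one forward pass, each word's first entry, whether material to
    its right had been fixated before that entry, the consecutive first-pass
    run, the landing site of the saccade ending the run, and any later
    fixations.  Structured deliberately unlike the per-word implementation.
    """
    state = {w: {"seen_right_before_entry": False, "entered": False,
                 "run_done": False, "ffd": None, "fprt": 0.0, "trt": 0.0,
                 "reg": None, "refix": 0.0, "fixated": False}
             for w in range(1, n_words + 1)}
    prev_word = None
    for i, (w, d) in enumerate(zip(words, durs)):
        st = state[w]
        st["fixated"] = True
        st["trt"] += d
        if not st["entered"]:
            st["entered"] = True
            st["seen_right_before_entry"] = any(
                wj > w for wj in words[:i])
            if not st["seen_right_before_entry"]:
                st["ffd"] = d
                st["fprt"] += d
        else:
            if (not st["run_done"] and prev_word == w
                    and not st["seen_right_before_entry"]):
                st["fprt"] += d
            else:
                if not st["seen_right_before_entry"]:
                    st["refix"] = 1.0
        # a fixation on any other word closes every open run and records
        # the landing direction for the word whose run just ended
        for v, sv in state.items():
            if v != w and sv["entered"] and not sv["run_done"]:
                if prev_word == v and not sv["seen_right_before_entry"]:
                    sv["reg"] = 1.0 if w < v else 0.0
                sv["run_done"] = True
        prev_word = w
    out = {}
    for w, st in state.items():
        if not st["fixated"]:
            out[w] = dict(ffd=np.nan, fprt=np.nan, trt=np.nan, reg=np.nan,
                          refix=np.nan, skipped=True, never=True)
        elif st["seen_right_before_entry"]:
            out[w] = dict(ffd=np.nan, fprt=np.nan, trt=st["trt"], reg=np.nan,
                          refix=0.0, skipped=True, never=False)
        else:
            reg = st["reg"] if st["reg"] is not None else 0.0
            out[w] = dict(ffd=st["ffd"], fprt=st["fprt"], trt=st["trt"],
                          reg=reg, refix=st["refix"], skipped=False,
                          never=False)
    return out


# --------------------------------------------------------------------------
# cleaning

def test_clean_removes_short_blinks_and_track_loss():
    t = make_trial([(1, 40), (2, 200), (3, 49), (4, 50)])
    out = clean_fixations(t)
    assert list(out["duration_ms"]) == [200, 50]  # strict "< 50 ms" rule
    assert list(out["fixation_index"]) == [1, 2]

    t2 = make_trial([(1, 200), (2, 300), (3, 100), (4, 180)],
                    events=["fixation", "blink", "track_loss", "fixation"])
    assert list(clean_fixations(t2)["duration_ms"]) == [200, 180]

    assert len(clean_fixations(make_trial([]))) == 0


def test_clean_requires_ordered_input():
    t = make_trial([(1, 100), (2, 100)])
    t["fixation_index"] = [2, 1]
    with pytest.raises(ValueError):
        clean_fixations(t)


# --------------------------------------------------------------------------
# assignment

def test_assignment_interval_membership_and_space_rule():
    regs = regions_for(4)  # words at [0,4), [5,9), [10,14), [15,19)
    t = make_trial([(0, 100)], x_char=[10.0])  # char_start of word 3
    assert list(assign_fixations_to_words(t, regs)["word_index"]) == [3]

    t_space = make_trial([(0, 100)], x_char=[9.0])  # space between 2 and 3
    assert list(assign_fixations_to_words(
        t_space, regs, "following")["word_index"]) == [3]
    assert list(assign_fixations_to_words(
        t_space, regs, "preceding")["word_index"]) == [2]


def test_assignment_drops_out_of_range_and_counts():
    regs = regions_for(3)
    t = make_trial([(0, 100), (0, 120)], x_char=[2.0, 99.0])
    out = assign_fixations_to_words(t, regs)
    assert list(out["word_index"]) == [1]
    assert out.attrs["n_dropped"] == 1


def test_word_index_and_x_char_paths_agree(small_dataset):
    """Generator emits both encodings; they must resolve identically."""
    regs = word_regions(small_dataset.stimuli)
    fix = small_dataset.fixations
    sub = fix[(fix["participant_id"] == "p001")]
    for sid, grp in sub.groupby("sentence_id"):
        direct = assign_fixations_to_words(grp, regs[sid])
        via_x = assign_fixations_to_words(
            grp.drop(columns=["word_index"]), regs[sid])
        assert list(direct["word_index"]) == list(via_x["word_index"])


# --------------------------------------------------------------------------
# measures

def test_left_to_right_single_fixations():
    regs = regions_for(5)
    t = make_trial([(w, 200) for w in range(1, 6)])
    m = compute_word_measures(t, regs).set_index("word_index")
    for w in range(2, 5):
        row = m.loc[w]
        assert row["ffd"] == row["fprt"] == row["trt"] == 200
        assert row["regression"] == 0 and row["refixation"] == 0


def test_hand_trace_refixation_without_regression():
    regs = regions_for(5)
    t = make_trial([(2, 200), (3, 180), (3, 120), (4, 150)])
    m = compute_word_measures(t, regs).set_index("word_index")
    w3 = m.loc[3]
    assert w3["ffd"] == 180 and w3["fprt"] == 300 and w3["trt"] == 300
    assert w3["regression"] == 0 and w3["refixation"] == 0


def test_hand_trace_regression_and_refixation():
    regs = regions_for(5)
    t = make_trial([(2, 200), (3, 150), (2, 100), (3, 130), (4, 140)])
    m = compute_word_measures(t, regs).set_index("word_index")
    w3, w2 = m.loc[3], m.loc[2]
    assert w3["ffd"] == 150 and w3["fprt"] == 150
    assert w3["regression"] == 1 and w3["trt"] == 280 and w3["refixation"] == 1
    assert w2["fprt"] == 200 and w2["regression"] == 0
    assert w2["trt"] == 300 and w2["refixation"] == 1


def test_word_entered_from_right_has_no_first_pass():
    regs = regions_for(5)
    # word 2 skipped on first pass, entered later from word 3
    t = make_trial([(1, 100), (3, 150), (2, 120), (4, 140)])
    m = compute_word_measures(t, regs).set_index("word_index")
    w2 = m.loc[2]
    assert np.isnan(w2["ffd"]) and np.isnan(w2["fprt"])
    assert np.isnan(w2["regression"])
    assert w2["trt"] == 120 and bool(w2["skipped_first_pass"])
    assert w2["refixation"] == 0  # default: no first pass, no refixation


def test_unknown_word_index_raises():
    regs = regions_for(3)
    with pytest.raises(ValueError):
        compute_word_measures(make_trial([(7, 100)]), regs)


def test_oracle_equivalence_on_random_scanpaths():
    """Implementation equals the state-machine oracle on 1,200 scanpaths."""
    rng = np.random.default_rng(2024)
    for _ in range(1200):
        n_words = int(rng.integers(3, 9))
        n_fix = int(rng.integers(1, 13))
        words = rng.integers(1, n_words + 1, size=n_fix).tolist()
        durs = rng.integers(60, 400, size=n_fix).astype(float).tolist()
        m = compute_word_measures(
            make_trial(list(zip(words, durs))),
            regions_for(n_words)).set_index("word_index")
        oracle = oracle_measures(words, durs, n_words)
        for w, o in oracle.items():
            row = m.loc[w]
            for impl_col, key in (("ffd", "ffd"), ("fprt", "fprt"),
                                  ("trt", "trt"), ("regression", "reg"),
                                  ("refixation", "refix")):
                got, want = row[impl_col], o[key]
                if np.isnan(want):
                    assert np.isnan(got), (words, durs, w, impl_col)
                else:
                    assert got == pytest.approx(want), (words, durs, w,
                                                        impl_col)
            assert bool(row["skipped_first_pass"]) == o["skipped"]
            assert bool(row["never_fixated"]) == o["never"]


# --------------------------------------------------------------------------
# tabulation

def test_boundary_exclusion_arithmetic(small_dataset):
    from gazedyn.gaze import extract_measures

    stim = small_dataset.stimuli
    table = extract_measures(small_dataset.fixations, stim, skip_filter=None)
    per_sentence = table.groupby("sentence_id")["word_index"].nunique()
    n_tokens = stim.groupby("sentence_id")["word_index"].max()
    assert (per_sentence <= n_tokens.loc[per_sentence.index] - 2).all()
    assert (table["word_index"] > 1).all()


def test_skipped_word_row_keeps_late_measures():
    regs = regions_for(5)
    stim = pd.DataFrame({
        "sentence_id": ["s1"] * 5, "word_index": range(1, 6),
        "word_text": list("abcde"), "length_chars": [4] * 5,
        "log_frequency": [10.0] * 5,
        "char_start": [r.char_start for r in regs],
        "char_end": [r.char_end for r in regs]})
    t = make_trial([(1, 100), (3, 150), (2, 120), (4, 140), (5, 90)])
    m = compute_word_measures(t, regs)
    m.insert(0, "participant_id", "p1")
    table = exclude_and_tabulate(m, stim)
    row = table[table["word_index"] == 2].iloc[0]
    assert np.isnan(row["ffd"]) and np.isnan(row["fprt"])
    assert row["trt"] == 120 and row["refixation"] == 0


def test_row_count_with_filter_disabled(small_dataset, small_table):
    from gazedyn.gaze import extract_measures

    stim = small_dataset.stimuli
    full = extract_measures(small_dataset.fixations, stim, skip_filter=None)
    n_interior = int((stim.groupby("sentence_id")["word_index"].max() - 2)
                     .sum())
    n_trials = small_dataset.fixations.groupby(
        ["participant_id", "sentence_id"]).ngroups
    n_participants = small_dataset.fixations["participant_id"].nunique()
    assert n_trials == n_participants * stim["sentence_id"].nunique()
    # every interior word of every trial appears unless never fixated
    assert len(full) <= n_interior * n_participants
    assert len(full) > 0.5 * n_interior * n_participants
    # the skip-likelihood filter strictly reduces the table
    assert len(small_table) < len(full)


def test_measure_ordering_and_conservation(small_dataset):
    """FFD <= FPRT <= TRT, and total TRT conserves cleaned duration mass."""
    regs = word_regions(small_dataset.stimuli)
    fix = small_dataset.fixations
    for (pid, sid), grp in list(fix.groupby(
            ["participant_id", "sentence_id"]))[:120]:
        t = clean_fixations(grp)
        t = assign_fixations_to_words(t, regs[sid])
        m = compute_word_measures(t, regs[sid])
        present = m.dropna(subset=["ffd", "fprt", "trt"])
        assert (present["ffd"] <= present["fprt"] + 1e-9).all()
        assert (present["fprt"] <= present["trt"] + 1e-9).all()
        assert m["trt"].sum() == pytest.approx(t["duration_ms"].sum())
        binaries = m[["regression", "refixation"]].stack().dropna()
        assert set(binaries.unique()) <= {0.0, 1.0}
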