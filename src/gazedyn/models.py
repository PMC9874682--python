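"""Skill x lexical-property interaction models of the five gaze measures.

Each gaze measure is regressed on 23 fixed effects -- seven lexical
covariates (word position; current/previous/next centered length;
current/previous/next residualized frequency), four skill measures, and the
12 products of each skill with {position, current length, current
residualized frequency} -- with crossed random intercepts for participant
and for word-within-sentence plus a by-participant random slope of current
word frequency.  Continuous measures use the Gaussian (REML) family; the
two incidence measures use the Laplace logistic family.

Significance is controlled family-wise at alpha / n_tests (0.05 / 23 ~
0.00217); terms above that threshold but below the marginal listing
threshold (0.01) are flagged marginal.  Effect sizes use the mixed-model
Cohen's d conversion d = 2 * statistic / sqrt(df).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mixed import (
    MixedFitResult,
    RandomComponent,
    fit_glmm_logit,
    fit_lmm,
    indicator_matrix,
    slope_matrix,
)
from .preprocess import collinearity

__all__ = [
    "LEXICAL_TERMS",
    "SKILL_TERMS",
    "INTERACTION_LEXICAL",
    "ModelSpec",
    "build_fixed_effects",
    "fit_mixed",
    "significance_flags",
    "cohens_d",
    "first_pass_share",
    "GAZE_RESPONSES",
]

LEXICAL_TERMS: tuple[str, ...] = (
    "position_c", "len_w_c", "len_prev_c", "len_next_c",
    "freq_resid_w", "freq_resid_prev", "freq_resid_next",
)
SKILL_TERMS: tuple[str, ...] = ("oral_comp", "decod_comp", "gort_wpm",
                                "sspan_corr")
#: Lexical properties entering the skill interactions.
INTERACTION_LEXICAL: tuple[str, ...] = ("position_c", "len_w_c",
                                        "freq_resid_w")

#: Response column -> model family for the five gaze measures.
GAZE_RESPONSES: dict[str, str] = {
    "ffd": "gaussian",
    "fprt": "gaussian",
    "trt": "gaussian",
    "regression": "binomial",
    "refixation": "binomial",
}


def build_fixed_effects(
    lexical: tuple[str, ...] = LEXICAL_TERMS,
    skills: tuple[str, ...] = SKILL_TERMS,
    interaction_lexical: tuple[str, ...] = INTERACTION_LEXICAL,
) -> list[str]:
    """Ordered fixed-effect term list: lexical mains, skill mains, products.

    With 7 lexical covariates and 4 skills this yields the 23-term design
    (7 + 4 + 4 x 3).  Interaction terms are written ``skill:lexical``.
    """
    if not set(interaction_lexical) <= set(lexical):
        raise ValueError("interaction_lexical must be a subset of lexical")
    terms = list(lexical) + list(skills)
    for s in skills:
        for l in interaction_lexical:
            terms.append(f"{s}:{l}")
    return terms


@dataclass
class ModelSpec:
    """Specification of one gaze-measure model."""

    response: str
    family: str = "gaussian"
    fixed_terms: list[str] = field(default_factory=build_fixed_effects)
    alpha_family: float = 0.05
    n_tests: int = 23
    freq_slope_term: str = "freq_resid_w"

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "binomial"):
            raise ValueError("family must be 'gaussian' or 'binomial'")


def _design_from_table(table: pd.DataFrame, terms: list[str]) -> np.ndarray:
    cols = []
    for t in terms:
        if ":" in t:
            a, b = t.split(":", 1)
            cols.append(table[a].to_numpy(dtype=float)
                        * table[b].to_numpy(dtype=float))
        else:
            cols.append(table[t].to_numpy(dtype=float))
    return np.column_stack(cols)


def cohens_d(statistic: float, df: float) -> float:
    """Mixed-model effect size d = 2 * statistic / sqrt(df)."""
    if df <= 0:
        raise ValueError("df must be positive")
    return 2.0 * statistic / np.sqrt(df)


def significance_flags(p_values, alpha_family: float = 0.05,
                       n_tests: int = 23,
                       marginal_threshold: float = 0.01) -> pd.DataFrame:
    """Family-wise significance and marginal-listing flags.

    ``significant``: p < alpha_family / n_tests.  ``marginal``: not
    significant but p < ``marginal_threshold`` (the listing rule for tables
    of near-threshold interactions).
    """
    p = np.asarray(p_values, dtype=float)
    crit = alpha_family / n_tests
    sig = p < crit
    marg = (~sig) & (p < marginal_threshold)
    return pd.DataFrame({"p_value": p, "significant": sig, "marginal": marg,
                         "critical_p": crit})


def fit_mixed(spec: ModelSpec, table: pd.DataFrame,
              marginal_threshold: float = 0.01) -> dict:
    """Fit one gaze-measure mixed model on the long analysis table.

    Rows with a missing response (e.g. first-pass measures of skipped
    words) are dropped.  Returns a dict with the term table (estimate, SE,
    statistic, df, p, d, flags), the engine result, and the collinearity
    diagnostics of the fixed design.
    """
    needed = set()
    for t in spec.fixed_terms:
        needed.update(t.split(":"))
    missing = needed - set(table.columns)
    if missing:
        raise ValueError(f"table lacks covariates: {sorted(missing)}")
    cols = [spec.response] + sorted(needed)
    sub = table.dropna(subset=cols)
    if sub["participant_id"].nunique() < 2 or sub["sentence_id"].nunique() < 2:
        raise ValueError("need at least 2 participants and 2 sentences")

    y = sub[spec.response].to_numpy(dtype=float)
    X_terms = _design_from_table(sub, spec.fixed_terms)
    X = np.column_stack([np.ones(len(sub)), X_terms])
    names = ["(Intercept)"] + list(spec.fixed_terms)

    word_key = (sub["sentence_id"].astype(str) + ":"
                + sub["word_index"].astype(str))
    comps = [
        RandomComponent("participant", indicator_matrix(sub["participant_id"])),
        RandomComponent("word_in_sentence", indicator_matrix(word_key)),
        RandomComponent(
            "freq_slope_by_participant",
            slope_matrix(sub["participant_id"],
                         sub[spec.freq_slope_term].to_numpy(dtype=float))),
    ]
    if spec.family == "gaussian":
        res: MixedFitResult = fit_lmm(y, X, comps, term_names=names)
    else:
        res = fit_glmm_logit(y, X, comps, term_names=names)

    flags = significance_flags(res.p_values, spec.alpha_family, spec.n_tests,
                               marginal_threshold)
    terms = res.summary_frame()
    terms["df"] = res.df_resid
    terms["cohens_d"] = [cohens_d(s, res.df_resid) for s in res.statistic]
    terms["significant"] = flags["significant"]
    terms["marginal"] = flags["marginal"]

    diag = collinearity(X_terms, names=list(spec.fixed_terms))
    return {
        "spec": spec,
        "terms": terms,
        "result": res,
        "kappa": diag["kappa"],
        "max_vif": diag["max_vif"],
        "vif": diag["vif"],
        "n_obs": res.n_obs,
        "converged": res.converged,
        "boundary": res.boundary,
    }


def first_pass_share(n_first_pass: int, n_total: int) -> float:
    """Share of word-level observations that are first-pass events, in percent."""
    if n_total <= 0 or n_first_pass < 0 or n_first_pass > n_total:
        raise ValueError("need 0 <= n_first_pass <= n_total with n_total > 0")
    return 100.0 * n_first_pass / n_total
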