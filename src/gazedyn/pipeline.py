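"""End-to-end orchestration: simulate -> extract -> preprocess -> model ->
dynamics -> report, with one root seed, persisted intermediate tables, and a
run manifest recording configuration hash and per-stage row counts."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import gaze, io, preprocess
from .config import SimulationConfig
from .dynamics import dynamics_report, median_split, report_rows
from .models import (GAZE_RESPONSES, ModelSpec, build_fixed_effects,
                     fit_mixed)
from .simulate import simulate_dataset

log = logging.getLogger("gazedyn")

__all__ = ["PipelineConfig", "run", "report"]

#: Human-readable names used in reports.
_PRETTY = {
    "ffd": "first fixation duration",
    "fprt": "first-pass reading time",
    "trt": "total reading time",
    "regression": "incidence of first-pass regression",
    "refixation": "refixation incidence",
    "position_c": "word position",
    "len_w_c": "word length",
    "freq_resid_w": "word frequency",
    "oral_comp": "oral comprehension plus vocabulary",
    "decod_comp": "decoding",
    "gort_wpm": "oral reading fluency",
    "sspan_corr": "verbal working memory",
}


@dataclass
class PipelineConfig:
    """Configuration of one full run.

    Exactly one input mode is active: ``simulation`` (generate the data) or
    ``inputs`` (paths to fixation / stimuli / skill tables).
    """

    seed: int = 0
    output_dir: str = "gazedyn_out"
    simulation: dict | None = field(default_factory=dict)
    inputs: dict | None = None
    min_duration: float = 50.0
    skip_filter: dict | None = field(
        default_factory=lambda: {"max_length": 3, "min_log_frequency": 12.0})
    alpha_family: float = 0.05
    marginal_threshold: float = 0.01
    loess_span: float = 0.75
    loess_degree: int = 2
    segmented_tol: float = 1e-5
    segmented_max_iter: int = 50
    make_figures: bool = True
    responses: tuple[str, ...] = tuple(GAZE_RESPONSES)

    def __post_init__(self) -> None:
        if (self.simulation is not None) == (self.inputs is not None):
            raise ValueError(
                "exactly one of 'simulation' and 'inputs' must be set")
        if self.min_duration <= 0 or self.alpha_family <= 0:
            raise ValueError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "responses" in raw:
            raw["responses"] = tuple(raw["responses"])
        return cls(**raw)

    def canonical(self) -> str:
        import dataclasses

        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            return str(o)

        d = {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in self.__dict__.items() if k != "output_dir"}
        return json.dumps(d, sort_keys=True, default=enc)

    def hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]


def _simulation_config(cfg: PipelineConfig) -> SimulationConfig:
    sim = SimulationConfig(**(cfg.simulation or {}))
    sim.seed = cfg.seed
    return sim


def _load_inputs(cfg: PipelineConfig):
    fix = io.read_table(cfg.inputs["fixations"])
    stim = io.read_table(cfg.inputs["stimuli"])
    skills = io.read_table(cfg.inputs["skills"])
    return fix, stim, skills


def run(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the run manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config.hash(), "seed": config.seed,
                      "counts": {}, "warnings": []}
    counts = manifest["counts"]

    # --- stage 1: data ----------------------------------------------------
    if config.simulation is not None:
        sim = _simulation_config(config)
        log.info("stage=simulate seed=%d participants=%d sentences=%d",
                 config.seed, sim.n_participants, sim.n_sentences)
        ds = simulate_dataset(sim)
        fixations, stimuli, skills = ds.fixations, ds.stimuli, ds.skills
        io.write_table(skills, out / "skills.csv")
        io.write_table(stimuli, out / "stimuli.csv")
        io.write_table(fixations, out / "fixations.csv")
        io.write_ground_truth(ds.truth, out / "ground_truth.json")
    else:
        fixations, stimuli, skills = _load_inputs(config)
    counts["trials"] = int(fixations.groupby(
        ["participant_id", "sentence_id"]).ngroups)
    counts["fixation_rows"] = int(len(fixations))

    # --- stage 2: gaze measures ------------------------------------------
    n_clean = int(((fixations["event"] == "fixation")
                   & (fixations["duration_ms"] >= config.min_duration)).sum())
    counts["fixations_after_cleaning"] = n_clean
    counts["fixations_removed_by_cleaning"] = counts["fixation_rows"] - n_clean
    table = gaze.extract_measures(
        fixations, stimuli, min_duration=config.min_duration,
        skip_filter=config.skip_filter)
    counts["observations_retained"] = int(len(table))
    n_fp = int(table["fprt"].notna().sum())
    counts["first_pass_observations"] = n_fp
    counts["first_pass_share_pct"] = round(100.0 * n_fp / max(len(table), 1), 3)
    log.info("stage=extract rows=%d first_pass_share=%.3f%%",
             len(table), counts["first_pass_share_pct"])

    # --- stage 3: preprocessing ------------------------------------------
    prep = preprocess.prepare_skills(skills)
    profiles = prep["profiles"]
    io.write_table(profiles, out / "participant_scores.csv")
    io.write_json({"lambdas": prep["lambdas"], "shifts": prep["shifts"]},
                  out / "box_cox.json")
    comp_cols = ["oral_comp", "decod_comp", "readcomp_comp", "gort_wpm",
                 "sspan_corr"]
    io.write_table(preprocess.correlation_table(profiles[comp_cols])
                   .reset_index(names="measure"),
                   out / "skill_correlations.csv")
    table = preprocess.prepare_lexical(table)
    table = table.merge(profiles[["participant_id"] + comp_cols],
                        on="participant_id", how="left")
    io.write_table(table, out / "analysis_table.csv")

    # --- stage 4: interaction models -------------------------------------
    terms = build_fixed_effects()
    model_summaries = {}
    for resp in config.responses:
        spec = ModelSpec(response=resp, family=GAZE_RESPONSES[resp],
                         fixed_terms=terms, alpha_family=config.alpha_family,
                         n_tests=len(terms))
        fit = fit_mixed(spec, table,
                        marginal_threshold=config.marginal_threshold)
        io.write_table(fit["terms"], out / f"model_{resp}.csv")
        model_summaries[resp] = {
            "kappa": fit["kappa"], "max_vif": fit["max_vif"],
            "n_obs": fit["n_obs"], "converged": fit["converged"],
            "boundary": fit["boundary"],
            "terms": fit["terms"].to_dict(orient="records"),
        }
        log.info("stage=model response=%s n=%d kappa=%.2f max_vif=%.2f",
                 resp, fit["n_obs"], fit["kappa"], fit["max_vif"])
        if not fit["converged"]:
            manifest["warnings"].append(f"model {resp} did not converge")
    io.write_json(model_summaries, out / "models.json")
    counts["models_fit"] = len(model_summaries)

    # --- stage 5: segmented dynamics -------------------------------------
    dyn_rows = []
    for resp, summ in model_summaries.items():
        for t in summ["terms"]:
            if ":" not in t["term"] or not (t["significant"] or t["marginal"]):
                continue
            skill, lex = t["term"].split(":")
            split = median_split(
                profiles.set_index("participant_id")[skill], skill=skill)
            rep = dynamics_report(
                split, table, predictor=lex, response=resp,
                family=GAZE_RESPONSES[resp], span=config.loess_span,
                degree=config.loess_degree, tol=config.segmented_tol,
                max_iter=config.segmented_max_iter)
            dyn_rows.extend(report_rows(rep, skill, lex, resp))
            if config.make_figures:
                _two_panel_figure(rep, split, lex, resp,
                                  out / f"dynamics_{resp}_{skill}_{lex}")
    dyn_table = pd.DataFrame(dyn_rows)
    io.write_table(dyn_table, out / "dynamics.csv")
    counts["dynamics_panels"] = int(len(dyn_table))

    # --- stage 6: report ---------------------------------------------------
    manifest["n_fixed_effects"] = len(terms)
    manifest["critical_p"] = config.alpha_family / len(terms)
    io.write_json(manifest, out / "manifest.json")
    report_text = report(model_summaries, dyn_table, manifest)
    (out / "report.md").write_text(report_text)
    return manifest


def _two_panel_figure(rep: dict, split, predictor: str, response: str,
                      stem: Path) -> None:
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.6), sharey=True)
    for ax, group in zip(axes, ("high", "low")):
        r = rep[group]
        ax.set_title(f"{group} {_PRETTY.get(split.skill, split.skill)} "
                     f"(n={r['n']})", fontsize=9)
        if not r["fittable"]:
            ax.text(0.5, 0.5, "unfittable", ha="center", va="center",
                    transform=ax.transAxes)
            continue
        lo = r["loess"]
        ax.fill_between(lo.x_grid, lo.fitted - lo.se, lo.fitted + lo.se,
                        alpha=0.25, color="C0", lw=0)
        ax.plot(lo.x_grid, lo.fitted, color="C0", label="loess")
        grid = lo.x_grid
        ax.plot(grid, r["linear"].predict(grid), color="black", label="Lm")
        ax.plot(grid, r["segmented"].predict(grid), color="red",
                label="SegLm")
        seg = r["segmented"]
        ax.axvline(seg.psi, color="red", ls=":", lw=0.8)
        ax.annotate(f"Seg.Point={seg.psi:.2f}\n"
                    f"Slopes=({seg.slope_below:.2f}, {seg.slope_above:.2f})",
                    xy=(0.02, 0.98), xycoords="axes fraction", va="top",
                    fontsize=7)
        ax.set_xlabel(_PRETTY.get(predictor, predictor), fontsize=8)
    axes[0].set_ylabel(_PRETTY.get(response, response), fontsize=8)
    axes[1].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(f"{stem}.png", dpi=120)
    fig.savefig(f"{stem}.svg")
    plt.close(fig)


def report(model_summaries: dict, dyn_table: pd.DataFrame,
           manifest: dict) -> str:
    """Render the human-readable run summary (markdown)."""
    crit = manifest["critical_p"]
    lines = [
        "# Gaze-measure interaction analysis",
        "",
        f"Run `{manifest['config_hash']}` (seed {manifest['seed']}); "
        f"{manifest['counts'].get('observations_retained', 'NA')} word-level "
        f"observations retained; critical p = {crit:.5f} "
        f"({manifest['n_fixed_effects']} fixed effects).",
        "",
    ]
    for resp, summ in model_summaries.items():
        lines.append(f"## {_PRETTY.get(resp, resp)}")
        lines.append(f"kappa = {summ['kappa']:.2f}, "
                     f"max VIF = {summ['max_vif']:.2f}, "
                     f"n = {summ['n_obs']}")
        lines.append("")
        listed = [t for t in summ["terms"]
                  if ":" in t["term"] and (t["significant"] or t["marginal"])]
        lines.append("| Factor | Est. | SE | stat | p | d |")
        lines.append("|---|---|---|---|---|---|")
        if not listed:
            lines.append("| none below the marginal threshold | | | | | |")
        for t in listed:
            s, l = t["term"].split(":")
            name = (f"{_PRETTY.get(s, s)} x {_PRETTY.get(l, l)}")
            cells = (f"{name} | {t['estimate']:.3f} | {t['se']:.3f} | "
                     f"{t['statistic']:.3f} | {t['p_value']:.4f} | "
                     f"{t['cohens_d']:.3f}")
            if t["significant"]:
                cells = " | ".join(f"**{c.strip()}**"
                                   for c in cells.split("|"))
            lines.append(f"| {cells} |")
        lines.append("")
    lines.append("## Segmented dynamics")
    if dyn_table.empty:
        lines.append("No significant or marginal interactions to visualize.")
    else:
        for _, r in dyn_table.iterrows():
            if not r.get("fittable", False):
                lines.append(f"- {r['skill']} x {r['predictor']} on "
                             f"{r['response']} [{r['group']}]: unfittable")
                continue
            lines.append(
                f"- {_PRETTY.get(r['skill'], r['skill'])} x "
                f"{_PRETTY.get(r['predictor'], r['predictor'])} on "
                f"{_PRETTY.get(r['response'], r['response'])} "
                f"[{r['group']}]: Seg.Point={r['seg_point']:.3f}, "
                f"Slopes=({r['seg_slope_below']:.3f}, "
                f"{r['seg_slope_above']:.3f}), best={r['best']}")
    lines.append("")
    return "\n".join(lines)
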