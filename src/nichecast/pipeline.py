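"""Config-driven orchestration of the full climate-niche analysis.

A single YAML config describes the data source (a synthetic-landscape spec
or file paths), the two species, the screening/profiling/model/consensus
settings and one master seed.  ``run_pipeline`` executes the stages

    screen -> profile -> pseudo-absences -> fit -> evaluate -> project
    -> MESS/MEDI -> consensus -> overlap tests -> DFA

writing artifacts (ASCII grids, CSVs, JSON) to the output directory and
returning a run report with every stage's inputs, seeds, outputs and
headline statistics.  A failed stage marks itself failed in the report and
dependent stages are skipped.

All stage randomness is derived from the master seed through
``numpy.random.SeedSequence(master_seed).spawn()`` in stage order, so one
integer reproduces the whole run.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import envelope as env_mod
from . import extrapolation as ext_mod
from . import overlap as ov_mod
from . import sdm as sdm_mod
from . import synthetic as syn_mod
from .discriminant import StepwiseDiscriminant, classify
from .grids import (
    OccurrenceSet,
    correlation_screen,
    extract_values,
    morans_i,
    write_ascii_grid,
    write_occurrences_csv,
)

logger = logging.getLogger("nichecast")

__all__ = ["PipelineConfig", "run_pipeline", "default_config"]

_CONSENSUS_METHODS = {"mean", "medi_weighted"}


class PipelineConfig:
    """Validated pipeline configuration (see ``default_config``)."""

    def __init__(self, raw: dict):
        self.raw = dict(raw)
        self.master_seed = int(raw.get("seed", 0))
        self.out_dir = Path(raw.get("out_dir", "nichecast_run"))
        syn = raw.get("synthetic", {})
        self.n_rows = int(syn.get("n_rows", 60))
        self.n_cols = int(syn.get("n_cols", 60))
        self.n_presences = int(syn.get("n_presences", 300))
        self.species = list(raw.get("species", ["montane", "lowland"]))
        self.screen_threshold = float(raw.get("screen_threshold", 0.85))
        self.model_params = dict(
            raw.get(
                "model",
                {"learning_rate": 0.05, "max_trees": 2000, "n_step": 25, "cv_folds": 10},
            )
        )
        self.consensus_method = raw.get("consensus", "medi_weighted")
        if self.consensus_method not in _CONSENSUS_METHODS:
            raise ValueError(
                f"unknown consensus method {self.consensus_method!r}; "
                f"choose from {sorted(_CONSENSUS_METHODS)}"
            )
        self.n_reps = int(raw.get("overlap", {}).get("n_reps", 50))
        self.stages = raw.get("stages")  # None = all
        for key in ("occurrence_files", "layer_files"):
            for p in (raw.get(key) or {}).values():
                if not Path(p).exists():
                    raise ValueError(f"configured file does not exist: {p}")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})


def default_config(seed: int = 0, out_dir: str = "nichecast_run") -> PipelineConfig:
    return PipelineConfig({"seed": seed, "out_dir": out_dir})


def _stage_seeds(master: int, names: list[str]) -> dict[str, int]:
    seqs = np.random.SeedSequence(master).spawn(len(names))
    return {n: int(s.generate_state(1)[0] % (2**31)) for n, s in zip(names, seqs)}


_STAGES = [
    "landscape",
    "screen",
    "morans",
    "profile",
    "pseudoabsences",
    "fit",
    "evaluate",
    "project",
    "mess",
    "consensus",
    "overlap",
    "dfa",
]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the run report (also written
    to ``<out_dir>/report.json``)."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.master_seed, _STAGES)
    report: dict = {"seed": config.master_seed, "stages": {}}
    wanted = set(config.stages) if config.stages else set(_STAGES)
    failed = False

    state: dict = {}

    def run_stage(name, fn):
        nonlocal failed
        if name not in wanted:
            report["stages"][name] = {"status": "skipped (not requested)"}
            return
        if failed:
            report["stages"][name] = {"status": "skipped (upstream failure)"}
            return
        try:
            stats = fn() or {}
            report["stages"][name] = {"status": "ok", "seed": seeds[name], **stats}
        except Exception as exc:
            logger.exception("stage %s failed", name)
            report["stages"][name] = {"status": "failed", "error": str(exc)}
            failed = True

    # -- landscape -----------------------------------------------------------
    def landscape():
        stack = syn_mod.generate_landscape(
            config.n_rows,
            config.n_cols,
            syn_mod.default_layer_specs(),
            syn_mod.default_correlation_targets(),
            seed=seeds["landscape"],
        )
        state["stack"] = stack
        occ = {}
        rng = np.random.SeedSequence(seeds["landscape"]).spawn(len(config.species))
        for sp, ss in zip(config.species, rng):
            niche = syn_mod.preset_niche(sp)
            occ[sp] = syn_mod.generate_occurrences(
                stack, niche, config.n_presences, seed=int(ss.generate_state(1)[0] % 2**31)
            )
            write_occurrences_csv(occ[sp], out / f"occurrences_{sp}.csv")
        state["occ"] = occ
        state["niches"] = {sp: syn_mod.preset_niche(sp) for sp in config.species}
        for name in stack.names:
            write_ascii_grid(stack[name], out / f"layer_{name}.asc")
        shifts = [
            syn_mod.ScenarioShift(
                "gcm_mild",
                offsets={"temp_range": 2.0, "annual_precip": -120.0},
            ),
            syn_mod.ScenarioShift(
                "gcm_strong",
                offsets={"temp_range": 9.0, "annual_precip": -500.0},
                factors={"temp_seasonality": 1.4},
                offset_gradients={"temp_range": 3.0},
            ),
        ]
        state["scenarios"] = syn_mod.make_scenario_variants(stack, shifts)
        return {"n_layers": len(stack), "n_presences": {s: len(o) for s, o in occ.items()}}

    run_stage("landscape", landscape)

    # -- correlation screen --------------------------------------------------
    def screen():
        stack = state["stack"]
        frame, _, _ = stack.to_matrix()
        retained, corr = correlation_screen(frame, config.screen_threshold)
        corr.to_csv(out / "correlation_matrix.csv")
        state["predictors"] = retained
        return {"retained": retained, "n_dropped": len(stack.names) - len(retained)}

    run_stage("screen", screen)

    # -- spatial autocorrelation pre-check ------------------------------------
    def morans():
        stack = state["stack"]
        res = {}
        for sp, occ in state["occ"].items():
            r, c, ok = stack.grid.cell_of(occ.x, occ.y)
            counts = np.zeros(stack.grid.shape)
            np.add.at(counts, (r[ok], c[ok]), 1.0)
            res[sp] = morans_i(
                counts, contiguity="rook", inference="permutation",
                n_perm=199, seed=seeds["morans"],
            )
        return {"morans_i": {s: {k: round(v, 4) for k, v in d.items()} for s, d in res.items()}}

    run_stage("morans", morans)

    # -- envelope profile + classes -------------------------------------------
    def profile():
        stack = state["stack"]
        state["envelopes"], state["classified"] = {}, {}
        stats = {}
        for sp, occ in state["occ"].items():
            sm = extract_values(stack, occ.x, occ.y)
            sub = sm.frame[state["predictors"]]
            model = env_mod.BioclimEnvelope().fit(sub)
            score = model.score_stack(stack)
            classified = env_mod.jenks_classify(score, k=5)
            state["envelopes"][sp] = model
            state["classified"][sp] = classified
            write_ascii_grid(classified.classes, out / f"envelope_classes_{sp}.asc")
            stats[sp] = {"breaks": [round(b, 4) for b in classified.breaks.tolist()]}
        return stats

    run_stage("profile", profile)

    # -- pseudo-absences -------------------------------------------------------
    def pseudoabsences():
        stack = state["stack"]
        state["pa"] = {}
        stats = {}
        for i, (sp, occ) in enumerate(state["occ"].items()):
            r, c, ok = stack.grid.cell_of(occ.x, occ.y)
            presence_cells = np.zeros(stack.grid.shape, dtype=bool)
            presence_cells[r[ok], c[ok]] = True
            pa = env_mod.sample_pseudoabsences(
                state["classified"][sp],
                n=len(occ),
                seed=seeds["pseudoabsences"] + i,
                exclude_cells=presence_cells,
            )
            state["pa"][sp] = pa
            stats[sp] = {"n": len(pa)}
        return stats

    run_stage("pseudoabsences", pseudoabsences)

    # -- fit -------------------------------------------------------------------
    def fit():
        stack = state["stack"]
        state["models"], state["samples"] = {}, {}
        stats = {}
        for i, (sp, occ) in enumerate(state["occ"].items()):
            pa = state["pa"][sp]
            x = np.concatenate([occ.x, pa.x])
            y = np.concatenate([occ.y, pa.y])
            sm = extract_values(stack, x, y)
            resp = np.concatenate([np.ones(len(occ), int), np.zeros(len(pa), int)])
            sm = sm.with_response(resp)
            sm.predictors = state["predictors"]
            model = sdm_mod.BoostedSuitability(
                random_state=seeds["fit"] + i, **config.model_params
            ).fit(sm.frame[state["predictors"]], sm.response)
            state["models"][sp] = model
            state["samples"][sp] = sm
            stats[sp] = {"n_trees": model.n_trees_}
        return stats

    run_stage("fit", fit)

    # -- evaluate ----------------------------------------------------------------
    def evaluate():
        stats = {}
        for sp, model in state["models"].items():
            rep = sdm_mod.evaluate_model(model)
            with open(out / f"evaluation_{sp}.json", "w") as fh:
                json.dump(rep.to_dict(), fh, indent=2)
            stats[sp] = {
                "cv_auc": round(rep.cv_auc_mean, 3),
                "total_deviance": round(rep.mean_total_deviance, 3),
                "residual_deviance": round(rep.mean_residual_deviance, 3),
            }
        return stats

    run_stage("evaluate", evaluate)

    # -- project (current + scenarios) --------------------------------------------
    def project():
        state["projections"] = {}
        for sp, model in state["models"].items():
            cur = sdm_mod.project(model, state["stack"], scenario="current")
            projs = {"current": cur}
            for gcm, st in state["scenarios"].items():
                projs[gcm] = sdm_mod.project(model, st, scenario="past", gcm=gcm)
                write_ascii_grid(projs[gcm].suitability, out / f"projection_{sp}_{gcm}.asc")
            write_ascii_grid(cur.suitability, out / f"projection_{sp}_current.asc")
            state["projections"][sp] = projs
        return {sp: list(p) for sp, p in state["projections"].items()}

    run_stage("project", project)

    # -- MESS / MEDI ----------------------------------------------------------------
    def mess():
        state["medi"], state["mess"] = {}, {}
        stats = {}
        for sp, sm in state["samples"].items():
            ref = sm.frame[state["predictors"]]
            state["medi"][sp], state["mess"][sp] = {}, {}
            stats[sp] = {}
            occ, pa = state["occ"][sp], state["pa"][sp]
            ref_xy = (
                np.concatenate([occ.x, pa.x]),
                np.concatenate([occ.y, pa.y]),
            )
            for gcm, st in state["scenarios"].items():
                mres = ext_mod.compute_mess(ref, st, keep_per_variable=False)
                medi = ext_mod.mes_to_medi(mres)
                state["mess"][sp][gcm] = mres
                state["medi"][sp][gcm] = ext_mod.summarize_medi_at_points(medi, ref_xy)
                write_ascii_grid(mres.mes, out / f"mess_{sp}_{gcm}.asc")
                stats[sp][gcm] = {
                    "pct_area_mes_below_-20": ext_mod.extrapolated_area_fraction(mres),
                    "medi_weight": round(state["medi"][sp][gcm], 2),
                }
        with open(out / "extrapolation_report.json", "w") as fh:
            json.dump(stats, fh, indent=2)
        return stats

    run_stage("mess", mess)

    # -- consensus --------------------------------------------------------------------
    def consensus_stage():
        stats = {}
        state["consensus"] = {}
        for sp, projs in state["projections"].items():
            past = {g: p for g, p in projs.items() if g != "current"}
            cons = ext_mod.consensus(past, state["medi"][sp], method=config.consensus_method)
            mean_cons = ext_mod.consensus(past, method="mean")
            state["consensus"][sp] = cons
            write_ascii_grid(cons.combined, out / f"consensus_{sp}.asc")
            diff = np.nanmean(np.abs(cons.combined.values - mean_cons.combined.values))
            stats[sp] = {
                "method": cons.method,
                "mean_abs_diff_vs_mean_consensus": round(float(diff), 5),
            }
        return stats

    run_stage("consensus", consensus_stage)

    # -- overlap tests -------------------------------------------------------------------
    def overlap_stage():
        sp_a, sp_b = config.species[:2]
        pa_ = state["projections"][sp_a]["current"].suitability
        pb_ = state["projections"][sp_b]["current"].suitability
        d_geo = ov_mod.schoener_d(pa_, pb_)
        eq = ov_mod.equivalency_test(
            state["occ"][sp_a], state["occ"][sp_b], state["stack"],
            n_reps=config.n_reps, seed=seeds["overlap"],
        )
        bg_mask = state["stack"].valid_mask()
        bt = ov_mod.background_test(
            state["occ"][sp_a], state["occ"][sp_b], bg_mask, state["stack"],
            n_reps=config.n_reps, seed=seeds["overlap"] + 1,
        )
        pd_null = np.column_stack([eq.null, np.pad(bt.null, (0, len(eq.null) - len(bt.null)),
                                                   constant_values=np.nan)]) \
            if len(bt.null) < len(eq.null) else np.column_stack([eq.null, bt.null[: len(eq.null)]])
        np.savetxt(out / "overlap_nulls.csv", pd_null, delimiter=",",
                   header="equivalency,background", comments="")
        return {
            "schoener_d_geographic": round(d_geo, 4),
            "equivalency": {"d": round(eq.d_observed, 4), "p": round(eq.p, 4),
                            "pct5": round(eq.percentile_5, 4),
                            "rejected": bool(eq.rejects_at_5pct)},
            "background": {"d": round(bt.d_observed, 4), "p": round(bt.p, 4),
                           "pct5": round(bt.percentile_5, 4),
                           "rejected": bool(bt.rejects_at_5pct)},
        }

    run_stage("overlap", overlap_stage)

    # -- discriminant analysis over zone classes ------------------------------------------
    def dfa():
        sp_a, sp_b = config.species[:2]
        stack = state["stack"]
        sa = extract_values(stack, state["occ"][sp_a].x, state["occ"][sp_a].y)
        sb = extract_values(stack, state["occ"][sp_b].x, state["occ"][sp_b].y)
        # zone labels from the species' suitability ranking: cells suitable for
        # both above threshold = sympatric analogue
        ta = state["projections"][sp_a]["current"].suitability
        tb = state["projections"][sp_b]["current"].suitability
        ra, ca, oka = stack.grid.cell_of(state["occ"][sp_a].x, state["occ"][sp_a].y)
        rb, cb, okb = stack.grid.cell_of(state["occ"][sp_b].x, state["occ"][sp_b].y)
        thr = 0.5

        def zones(r, c, own, other, own_name):
            lab = []
            for ri, ci in zip(r, c):
                if own.values[ri, ci] >= thr and other.values[ri, ci] >= thr:
                    lab.append("sympatric")
                else:
                    lab.append(f"allopatric_{own_name}")
            return lab

        frames = pd.concat([sa.frame[state["predictors"]], sb.frame[state["predictors"]]],
                           ignore_index=True)
        labels = zones(ra[oka], ca[oka], ta, tb, sp_a) + zones(rb[okb], cb[okb], tb, ta, sp_b)
        model = StepwiseDiscriminant().fit(frames, labels)
        cm = classify(model, frames, labels)
        model.steps_.to_csv(out / "dfa_entry_trail.csv", index=False)
        cm.counts.to_csv(out / "dfa_classification_matrix.csv")
        return {
            "entered": model.selected_,
            "per_class_percent": {str(k): float(v) for k, v in cm.per_class_percent.items()},
            "total_percent_unweighted": cm.total_percent_unweighted,
            "total_percent_pooled": cm.total_percent_pooled,
        }

    run_stage("dfa", dfa)

    report["status"] = "failed" if failed else "ok"
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
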