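"""End-to-end orchestration: preprocess -> dyads -> split -> tune/train ->
multistage selection -> final evaluation -> explanation -> statistics.

The external test partition is carved out before any tuning or selection
and read exactly once, at final evaluation. All stage randomness derives
from the master seed through independent sub-seeds.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path
from typing import Any

import pandas as pd

from . import dyads as dy
from . import modeling as mdl
from . import select_explain as sel
from . import stats as st
from .core import MetabolomeMatrix, RunConfig, write_report
from .preprocess import preprocess_pipeline

logger = logging.getLogger(__name__)


def run_pipeline(
    mothers: MetabolomeMatrix,
    children: MetabolomeMatrix,
    *,
    annotation: pd.DataFrame | None = None,
    outcomes: pd.DataFrame | None = None,
    config: RunConfig | None = None,
    models: tuple[str, ...] | None = None,
    tune_trials: int | None = None,
    do_select: bool = True,
    do_explain: bool = False,
    do_stats: bool = True,
    do_cv: bool = True,
    do_importance: bool = True,
    outdir: str | Path | None = None,
) -> dict[str, Any]:
    """Run the whole detection pipeline and return a consolidated report.

    ``tune_trials`` overrides ``config.n_trials`` (0 skips tuning and uses
    each family's default hyperparameters). ``models`` restricts the model
    families; default is all three.
    """
    config = config or RunConfig()
    models = models or config.models
    trials = config.n_trials if tune_trials is None else tune_trials
    (seed_shuffle, seed_split, seed_fold, seed_tune, seed_select,
     seed_model, seed_pi, _spare) = config.spawn_seeds(8)
    t0 = time.time()
    report: dict[str, Any] = {"config": config.to_dict(), "seed": config.seed,
                              "stage_timings": {}}

    # -- preprocessing ---------------------------------------------------------
    mothers_p, children_p, log = preprocess_pipeline(
        mothers,
        children,
        missing_threshold=config.missing_threshold,
        impute_fraction=config.impute_fraction,
        variance_drop=config.variance_drop,
        corr_threshold=config.corr_threshold,
        annotation=annotation,
        exclude=config.exclude_class,
    )
    report["preprocess"] = {
        "n_input_metabolites": mothers.n_metabolites,
        "n_surviving_metabolites": mothers_p.n_metabolites,
        "dropped_missing": log.dropped_missing,
        "dropped_variance": log.dropped_variance,
        "dropped_correlation": [list(t) for t in log.dropped_correlation],
        "excluded_class": log.excluded_class,
        "warnings": log.warnings,
    }
    logger.info(
        "preprocessing: %d -> %d metabolites",
        mothers.n_metabolites, mothers_p.n_metabolites,
    )
    report["stage_timings"]["preprocess"] = time.time() - t0

    # -- dyad construction and split ------------------------------------------
    t0 = time.time()
    if config.group_split:
        train, test = dy.grouped_dyad_split(
            mothers_p,
            children_p,
            test_fraction=config.test_fraction,
            n_shuffles=config.n_shuffles,
            drop_fraction=config.random_drop_fraction,
            seed=seed_split,
            allow_true_pairs=config.allow_true_pair_collisions,
        )
        dataset = dy.DyadFeatureTable(
            table=pd.concat([train.table, test.table], ignore_index=True)
        )
        n_true = int(dataset.labels.sum())
        n_random = len(dataset) - n_true
        skipped: list[str] = []
    else:
        true_d = dy.build_true_dyads(mothers_p, children_p)
        rand_d = dy.build_random_dyads(
            mothers_p,
            children_p,
            n_shuffles=config.n_shuffles,
            drop_fraction=config.random_drop_fraction,
            seed=seed_shuffle,
            allow_true_pairs=config.allow_true_pair_collisions,
        )
        dataset = dy.assemble_dataset(true_d, rand_d)
        train, test = dy.split_train_test(dataset, config.test_fraction, seed=seed_split)
        n_true, n_random = len(true_d), len(rand_d)
        skipped = true_d.skipped_families
    report["dyads"] = {
        "n_true": n_true,
        "n_random": n_random,
        "n_train": len(train),
        "n_test": len(test),
        "grouped_split": config.group_split,
        "skipped_families": skipped,
    }
    logger.info("dyads: %d true + %d random -> %d train / %d test",
                n_true, n_random, len(train), len(test))
    report["stage_timings"]["dyads"] = time.time() - t0

    # -- per-model: tune, select, refit, evaluate ------------------------------
    report["models"] = {}
    for algo in models:
        t0 = time.time()
        spec = mdl.ModelSpec(algorithm=algo, seed=seed_model)
        model_rep: dict[str, Any] = {}

        best_params: dict[str, Any] = {}
        if trials > 0:
            best_params, trial_log = mdl.tune(
                spec, train, n_trials=trials, k=config.cv_folds, seed=seed_tune
            )
            model_rep["tuned_params"] = best_params
            model_rep["n_trials"] = len(trial_log)

        selected = train.feature_names
        if do_select:
            selected, trace = sel.multistage_select(
                spec,
                train,
                keep_fraction=config.keep_fraction,
                max_stages=config.max_stages,
                min_features=config.min_features,
                seed=seed_select,
                k=config.cv_folds,
                n_repeats=config.pi_repeats,
                improvement_tol=config.improvement_tol,
                params=best_params,
            )
            model_rep["selection"] = trace.to_dict()
        model_rep["selected_features"] = list(selected)

        train_sel = train.select_features(selected)
        test_sel = test.select_features(selected)
        cv_summary = None
        if do_cv:
            cv_summary = mdl.cross_validate(
                spec, train_sel, k=config.cv_folds, seed=seed_fold, params=best_params
            )
        model = mdl.fit_final(spec, train_sel, best_params)
        ev = mdl.evaluate(
            model, test_sel, algorithm=algo, cv_summary=cv_summary,
            seed=config.seed, config=config.to_dict(),
        )
        model_rep["evaluation"] = ev.to_dict()
        model_rep["_model"] = model
        model_rep["_test_table"] = test_sel

        if do_importance:
            imp, _ = sel.out_of_fold_importance(
                spec, train_sel, selected, k=config.cv_folds,
                n_repeats=config.pi_repeats, seed=seed_pi, params=best_params,
            )
            model_rep["importance"] = imp

        if do_explain:
            attr = sel.shapley_attributions(model, test_sel.features)
            model_rep["attributions"] = attr
            model_rep["local_accuracy_max_gap"] = float(attr.local_accuracy_gap().max())
        report["models"][algo] = model_rep
        logger.info("%s: test MCC %.3f (CV %.3f) on %d features",
                    algo, ev.mcc_test, ev.mcc_cv_mean, len(selected))
        report["stage_timings"][f"model_{algo}"] = time.time() - t0

    # -- companion statistics --------------------------------------------------
    if do_stats:
        t0 = time.time()
        report["stats"] = st.dyad_ttests(dataset, alpha=config.fdr_alpha)
        report["stage_timings"]["stats"] = time.time() - t0

    # -- outcome association on the best model's test predictions --------------
    if outcomes is not None and report["models"]:
        best_algo = max(
            report["models"], key=lambda a: report["models"][a]["evaluation"]["mcc_test"]
        )
        mrep = report["models"][best_algo]
        model, test_tab = mrep["_model"], mrep["_test_table"]
        proba = model.predict_proba(test_tab.X)[:, 1]
        frame = pd.DataFrame(
            {"child_id": test_tab.table["child_id"].to_numpy(), "proba": proba}
        )
        membership = (
            frame.groupby("child_id")["proba"].mean() >= 0.5
        ).astype(int)
        try:
            assoc = st.outcome_association(membership, outcomes)
            report["outcome_association"] = {
                "model": best_algo,
                "table": st.association_table(assoc),
            }
        except ValueError as exc:
            report["outcome_association"] = {"model": best_algo, "error": str(exc)}

    if outdir is not None:
        _write_outputs(report, Path(outdir))
    return report


def strip_objects(report: dict[str, Any]) -> dict[str, Any]:
    """Copy of the report with live models/tables made JSON-friendly."""
    import copy

    out: dict[str, Any] = {}
    for key, val in report.items():
        if key == "models":
            out["models"] = {}
            for algo, mrep in val.items():
                slim = {k: v for k, v in mrep.items() if not k.startswith("_")}
                if "importance" in slim:
                    slim["importance"] = slim["importance"].to_dict(orient="list")
                if "attributions" in slim:
                    attr = slim.pop("attributions")
                    slim["attribution_base_value"] = attr.base_value
                    slim["attribution_scale"] = attr.output_scale
                out["models"][algo] = slim
        elif key == "stats":
            out["stats"] = val.to_dict(orient="list")
        elif key == "outcome_association" and isinstance(val.get("table"), pd.DataFrame):
            out[key] = {**val, "table": val["table"].to_dict(orient="list")}
        else:
            out[key] = copy.deepcopy(val)
    return out


def _write_outputs(report: dict[str, Any], outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_report(strip_objects(report), outdir / "run_report.json")
    if "stats" in report:
        write_report(report["stats"], outdir / "stats.csv")
    for algo, mrep in report.get("models", {}).items():
        if "importance" in mrep:
            write_report(mrep["importance"], outdir / f"importance_{algo}.csv")
        if "selected_features" in mrep:
            (outdir / f"selected_{algo}.txt").write_text(
                "\n".join(mrep["selected_features"]) + "\n"
            )
        if "attributions" in mrep:
            mrep["attributions"].values.to_csv(
                outdir / f"attributions_{algo}.csv", index=False
            )
            sel.summary_plot(
                mrep["attributions"],
                str(outdir / f"shap_summary_{algo}.png"),
                feature_values=mrep["_test_table"].features,
            )
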