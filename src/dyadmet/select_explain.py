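"""Permutation-importance feature selection and model explanation.

Selection is multistage: fit under stratified CV, score every feature by
the out-of-fold drop in MCC when its column is permuted (mean of 5 repeats
across folds), keep the top third, and repeat — up to seven stages, stopping
early when CV stops improving or a floor of seven features is reached. The
external test set is never seen here. Explanations combine the final
permutation importances with exact Shapley attributions.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from math import ceil
from typing import Any

import numpy as np
import pandas as pd

from .dyads import DyadFeatureTable
from .modeling import ModelSpec, mcc_from_labels, stratified_folds
from .shapley import AttributionMatrix, shapley_attributions

__all__ = [
    "permutation_importance",
    "multistage_select",
    "SelectionTrace",
    "SelectionStage",
    "shapley_attributions",
    "AttributionMatrix",
    "summary_plot",
]

#: permuted-copies block size cap (rows) when batching predictions
_BATCH_ROWS = 50_000


def _feature_rng(seed: int, name: str) -> np.random.Generator:
    # keyed by feature name so importances do not depend on column order
    return np.random.default_rng([seed, zlib.crc32(name.encode())])


def permutation_importance(
    model,
    X: pd.DataFrame,
    y: np.ndarray,
    n_repeats: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean decrease in MCC when each feature's column is permuted.

    Returns an importance table with columns ``feature``, ``mean_importance``,
    ``sd_importance`` and 1-based ``rank`` (descending importance, ties by
    feature name). The permutation stream is keyed by feature name, so the
    result is invariant to column order.
    """
    if not isinstance(X, pd.DataFrame):
        raise TypeError("X must be a DataFrame with feature-named columns")
    y = np.asarray(y, dtype=int)
    Xv = X.to_numpy(dtype=float)
    n, m = Xv.shape
    expected = getattr(model, "n_features_in_", m)
    if m != expected:
        raise ValueError(f"model expects {expected} features, table has {m}")
    baseline = mcc_from_labels(y, model.predict(Xv))

    names = list(X.columns)
    drops = np.empty((m, n_repeats))
    chunk = max(1, min(m, _BATCH_ROWS // max(1, n * n_repeats)))
    for start in range(0, m, chunk):
        cols = range(start, min(start + chunk, m))
        blocks = []
        for j in cols:
            rng = _feature_rng(seed, names[j])
            for _ in range(n_repeats):
                Xp = Xv.copy()
                Xp[:, j] = Xp[rng.permutation(n), j]
                blocks.append(Xp)
        preds = model.predict(np.vstack(blocks))
        for bi, j in enumerate(
            jj for jj in cols for _ in range(n_repeats)
        ):
            r = bi % n_repeats
            drops[j, r] = baseline - mcc_from_labels(y, preds[bi * n : (bi + 1) * n])

    table = pd.DataFrame(
        {
            "feature": names,
            "mean_importance": drops.mean(axis=1),
            "sd_importance": drops.std(axis=1, ddof=1) if n_repeats > 1 else 0.0,
        }
    )
    return rank_importance(table)


def rank_importance(table: pd.DataFrame) -> pd.DataFrame:
    """Attach 1-based ranks: descending mean importance, ties by name."""
    out = table.sort_values(
        ["mean_importance", "feature"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def out_of_fold_importance(
    spec: ModelSpec,
    train: DyadFeatureTable,
    features: list[str],
    k: int,
    n_repeats: int,
    seed: int,
    params: dict[str, Any] | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """CV loop: fit per fold, permute on the validation part only.

    Returns the fold-averaged importance table and a CV summary. Scoring on
    held-out folds avoids the optimism of permuting on the fit data.
    """
    Xdf = train.features[features]
    y = train.y
    folds = stratified_folds(y, k, seed)
    fold_tables = []
    fold_mcc = []
    for fi, (tr, va) in enumerate(folds):
        model = spec.make_estimator(params)
        model.fit(Xdf.iloc[tr].to_numpy(), y[tr])
        fold_mcc.append(mcc_from_labels(y[va], model.predict(Xdf.iloc[va].to_numpy())))
        imp = permutation_importance(
            model, Xdf.iloc[va], y[va], n_repeats=n_repeats, seed=seed + fi
        )
        fold_tables.append(imp.set_index("feature")["mean_importance"])
    stacked = pd.concat(fold_tables, axis=1)
    table = pd.DataFrame(
        {
            "feature": stacked.index,
            "mean_importance": stacked.mean(axis=1).to_numpy(),
            "sd_importance": stacked.std(axis=1, ddof=1).to_numpy(),
        }
    )
    scores = np.asarray(fold_mcc)
    summary = {
        "fold_mcc": scores.tolist(),
        "mean_mcc": float(scores.mean()),
        "sd_mcc": float(scores.std(ddof=1)),
    }
    return rank_importance(table), summary


@dataclass
class SelectionStage:
    features: list[str]
    cv_mcc: float
    kept: list[str] | None = None
    importance: pd.DataFrame | None = None


@dataclass
class SelectionTrace:
    stages: list[SelectionStage] = field(default_factory=list)
    stop_reason: str = ""

    @property
    def stage_sizes(self) -> list[int]:
        return [len(s.features) for s in self.stages]

    def best_stage(self) -> SelectionStage:
        return max(self.stages, key=lambda s: s.cv_mcc)

    def to_dict(self) -> dict[str, Any]:
        return {
            "stop_reason": self.stop_reason,
            "stages": [
                {
                    "n_features": len(s.features),
                    "cv_mcc": s.cv_mcc,
                    "features": s.features,
                    "kept": s.kept,
                }
                for s in self.stages
            ],
        }


def multistage_select(
    spec: ModelSpec,
    train: DyadFeatureTable,
    keep_fraction: float = 0.33,
    max_stages: int = 7,
    min_features: int = 7,
    seed: int = 0,
    k: int = 10,
    n_repeats: int = 5,
    improvement_tol: float = 1e-3,
    params: dict[str, Any] | None = None,
) -> tuple[list[str], SelectionTrace]:
    """Iterative permutation-importance feature selection on the train table.

    Per stage the model is refit under stratified CV, features are ranked by
    mean out-of-fold permutation importance, and the top
    ``ceil(keep_fraction * n)`` survive. Stops when CV MCC no longer improves
    by more than ``improvement_tol``, when the cut would undershoot
    ``min_features`` (then exactly the top ``min_features`` are kept), or
    after ``max_stages``. Returns the feature set of the best-CV stage.
    """
    all_features = train.feature_names
    trace = SelectionTrace()
    if len(all_features) < min_features:
        import warnings

        warnings.warn(
            f"only {len(all_features)} features (< min_features={min_features}); "
            "selection skipped",
            stacklevel=2,
        )
        trace.stop_reason = "floor_reached"
        trace.stages.append(SelectionStage(features=all_features, cv_mcc=float("nan")))
        return all_features, trace

    current = list(all_features)
    for stage_idx in range(max_stages):
        imp, summary = out_of_fold_importance(
            spec, train, current, k, n_repeats, seed + stage_idx, params
        )
        stage = SelectionStage(features=current, cv_mcc=summary["mean_mcc"], importance=imp)
        trace.stages.append(stage)
        if stage_idx > 0 and stage.cv_mcc <= trace.stages[-2].cv_mcc + improvement_tol:
            trace.stop_reason = "no_improvement"
            break
        n = len(current)
        n_keep = ceil(keep_fraction * n)
        ranked = imp["feature"].tolist()
        if n_keep >= n:
            trace.stop_reason = "no_improvement"  # no shrink possible
            break
        if n_keep < min_features:
            kept = ranked[: min(min_features, n)]
            if len(kept) == n:  # already at the floor, nothing to shrink
                trace.stop_reason = "floor_reached"
                break
            stage.kept = kept
            # score the floor set so it can compete as the final stage
            _, floor_summary = _cv_only(spec, train, kept, k, seed + stage_idx + 1, params)
            trace.stages.append(
                SelectionStage(features=kept, cv_mcc=floor_summary["mean_mcc"])
            )
            trace.stop_reason = "floor_reached"
            break
        stage.kept = ranked[:n_keep]
        current = stage.kept
    else:
        trace.stop_reason = "max_stages"

    best = trace.best_stage()
    return list(best.features), trace


def _cv_only(spec, train, features, k, seed, params):
    Xdf = train.features[features]
    y = train.y
    scores = []
    for tr, va in stratified_folds(y, k, seed):
        model = spec.make_estimator(params)
        model.fit(Xdf.iloc[tr].to_numpy(), y[tr])
        scores.append(mcc_from_labels(y[va], model.predict(Xdf.iloc[va].to_numpy())))
    scores = np.asarray(scores)
    return None, {"mean_mcc": float(scores.mean()), "sd_mcc": float(scores.std(ddof=1))}


def summary_plot(
    attributions: AttributionMatrix,
    path: str,
    feature_values: pd.DataFrame | None = None,
    max_display: int = 20,
) -> None:
    """Beeswarm-style attribution summary, one row per feature.

    Features are ordered by mean |attribution| descending; point colour
    encodes the feature value (low dispersion = blue), so a blue cluster on
    the positive side reads "mother and child agree on this metabolite,
    pushing the prediction toward true dyad".
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vals = attributions.values
    if vals.empty:
        raise ValueError("empty attribution matrix")
    order = vals.abs().mean(axis=0).sort_values(ascending=False).index[:max_display]
    rng = np.random.default_rng(0)
    fig, ax = plt.subplots(figsize=(8, 0.45 * len(order) + 1.5))
    for i, feat in enumerate(order):
        x = vals[feat].to_numpy()
        yjit = np.full_like(x, len(order) - 1 - i, dtype=float)
        yjit += rng.uniform(-0.25, 0.25, size=len(x))
        if feature_values is not None and feat in feature_values.columns:
            c = feature_values[feat].to_numpy()
        else:
            c = np.zeros_like(x)
        sc = ax.scatter(x, yjit, c=c, cmap="coolwarm", s=12, alpha=0.8)
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_yticks(range(len(order)))
    ax.set_yticklabels(list(order)[::-1])
    ax.set_xlabel(f"Shapley attribution ({attributions.output_scale})")
    fig.colorbar(sc, ax=ax, label="feature value (dyad dispersion)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
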