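"""Per-cohort metabolite filtering, detection-limit imputation and scaling.

The canonical order is fixed: missingness filter -> detection-limit
imputation -> per-cohort min-max scaling -> low-variance filter ->
intercorrelation filter, with an optional biochemical-class exclusion.
Filters operate on BOTH cohorts jointly so mothers and children always keep
identical metabolite sets — downstream dyad features need both values per
metabolite. Every drop is recorded in a :class:`PreprocessLog`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DataError, MetabolomeMatrix


@dataclass
class PreprocessLog:
    """Audit trail of every metabolite dropped or altered."""

    dropped_missing: list[str] = field(default_factory=list)
    dropped_variance: list[str] = field(default_factory=list)
    dropped_correlation: list[tuple[str, str, float]] = field(default_factory=list)
    excluded_class: list[str] = field(default_factory=list)
    imputed_counts: dict[str, int] = field(default_factory=dict)
    scale_minmax: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def merged(self, other: "PreprocessLog") -> "PreprocessLog":
        return PreprocessLog(
            dropped_missing=self.dropped_missing + other.dropped_missing,
            dropped_variance=self.dropped_variance + other.dropped_variance,
            dropped_correlation=self.dropped_correlation + other.dropped_correlation,
            excluded_class=self.excluded_class + other.excluded_class,
            imputed_counts={**self.imputed_counts, **other.imputed_counts},
            scale_minmax={**self.scale_minmax, **other.scale_minmax},
            warnings=self.warnings + other.warnings,
        )


def _check_same_metabolites(mothers: MetabolomeMatrix, children: MetabolomeMatrix) -> None:
    if mothers.metabolite_names != children.metabolite_names:
        raise DataError("mothers and children carry different metabolite sets")


def filter_missing(
    mothers: MetabolomeMatrix,
    children: MetabolomeMatrix,
    threshold: float = 0.33,
) -> tuple[MetabolomeMatrix, MetabolomeMatrix, PreprocessLog]:
    """Drop metabolites whose missing fraction exceeds ``threshold``.

    "Over" is strict: a metabolite missing in exactly ``threshold`` of the
    subjects is kept. A metabolite is removed from both cohorts if it breaks
    the threshold in either one.
    """
    _check_same_metabolites(mothers, children)
    frac = pd.concat(
        [mothers.missing_fraction(), children.missing_fraction()], axis=1
    ).max(axis=1)
    dropped = [m for m in mothers.metabolite_names if frac[m] > threshold]
    keep = [m for m in mothers.metabolite_names if m not in set(dropped)]
    log = PreprocessLog(dropped_missing=dropped)
    return (
        mothers.with_data(mothers.data[keep]),
        children.with_data(children.data[keep]),
        log,
    )


def impute_detection_limit(
    matrix: MetabolomeMatrix, fraction: float = 0.1, log: PreprocessLog | None = None
) -> MetabolomeMatrix:
    """Fill missing cells with ``fraction`` x the metabolite's smallest
    observed concentration, a proxy for the platform detection limit.

    Minima are taken within this matrix only. A metabolite with no observed
    value at all is an error — the missingness filter should have removed it.
    """
    if matrix.scaled:
        raise DataError("impute before scaling, not after")
    data = matrix.data.copy()
    for col in data.columns:
        vals = data[col]
        n_missing = int(vals.isna().sum())
        if n_missing == 0:
            continue
        observed = vals.dropna()
        if observed.empty:
            raise DataError(f"metabolite {col!r} has no observed values")
        lod = fraction * float(observed.min())
        if lod == 0.0 and log is not None:
            log.warnings.append(f"metabolite {col!r}: minimum observed value 0, imputing 0")
        data[col] = vals.fillna(lod)
        if log is not None:
            log.imputed_counts[col] = log.imputed_counts.get(col, 0) + n_missing
    return matrix.with_data(data)


def minmax_scale_within_group(
    matrix: MetabolomeMatrix, log: PreprocessLog | None = None
) -> MetabolomeMatrix:
    """Scale each metabolite to [0, 1] within this cohort only.

    Mothers are scaled among mothers and children among children, so a value
    of 0.1 means "near the low end of this cohort's range" regardless of the
    other cohort. Constant columns map to 0.
    """
    if matrix.data.isna().any().any():
        raise DataError("missing values present; impute before scaling")
    vals = matrix.values
    lo = vals.min(axis=0)
    hi = vals.max(axis=0)
    span = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = (vals - lo) / np.where(span == 0, 1.0, span)
    scaled[:, span == 0] = 0.0
    if log is not None:
        log.scale_minmax[matrix.role] = {
            m: (float(a), float(b)) for m, a, b in zip(matrix.metabolite_names, lo, hi)
        }
    data = pd.DataFrame(scaled, index=matrix.data.index, columns=matrix.data.columns)
    return matrix.with_data(data, scaled=True)


def _pooled(mothers: MetabolomeMatrix, children: MetabolomeMatrix) -> pd.DataFrame:
    return pd.concat([mothers.data, children.data], axis=0, ignore_index=True)


def filter_low_variance(
    mothers: MetabolomeMatrix,
    children: MetabolomeMatrix,
    drop_fraction: float = 0.10,
) -> tuple[MetabolomeMatrix, MetabolomeMatrix, PreprocessLog]:
    """Drop the ``floor(drop_fraction * m)`` metabolites with the smallest
    pooled variance (both cohorts stacked). Ties keep the earlier column.
    """
    _check_same_metabolites(mothers, children)
    m = mothers.n_metabolites
    n_drop = int(np.floor(drop_fraction * m))
    log = PreprocessLog()
    if n_drop == 0:
        return mothers, children, log
    var = _pooled(mothers, children).var(axis=0, ddof=1).to_numpy()
    # ascending variance; among ties the later column sorts first (is dropped)
    order = np.lexsort((-np.arange(m), var))
    drop_idx = set(order[:n_drop])
    names = mothers.metabolite_names
    dropped = [n for i, n in enumerate(names) if i in drop_idx]
    keep = [n for i, n in enumerate(names) if i not in drop_idx]
    log.dropped_variance = dropped
    return (
        mothers.with_data(mothers.data[keep]),
        children.with_data(children.data[keep]),
        log,
    )


def filter_intercorrelated(
    mothers: MetabolomeMatrix,
    children: MetabolomeMatrix,
    threshold: float = 0.90,
) -> tuple[MetabolomeMatrix, MetabolomeMatrix, PreprocessLog]:
    """Greedy removal of highly intercorrelated metabolites.

    Pearson correlations are computed on the pooled (stacked) scaled values.
    Scanning columns left to right, for every ordered pair (i, j) with
    ``|r| > threshold`` and both columns still alive, column j is dropped;
    earlier columns therefore always win.
    """
    _check_same_metabolites(mothers, children)
    names = mothers.metabolite_names
    corr = np.corrcoef(_pooled(mothers, children).to_numpy(), rowvar=False)
    corr = np.nan_to_num(np.atleast_2d(corr), nan=0.0)
    alive = np.ones(len(names), dtype=bool)
    log = PreprocessLog()
    for i in range(len(names)):
        if not alive[i]:
            continue
        for j in range(i + 1, len(names)):
            if alive[j] and abs(corr[i, j]) > threshold:
                alive[j] = False
                log.dropped_correlation.append((names[i], names[j], float(corr[i, j])))
    keep = [n for n, a in zip(names, alive) if a]
    return (
        mothers.with_data(mothers.data[keep]),
        children.with_data(children.data[keep]),
        log,
    )


def exclude_class(
    mothers: MetabolomeMatrix,
    children: MetabolomeMatrix,
    annotation: pd.DataFrame,
    class_name: str,
) -> tuple[MetabolomeMatrix, MetabolomeMatrix, PreprocessLog]:
    """Remove every metabolite annotated with ``class_name`` (e.g. the
    xenobiotics) from both cohorts. Unknown class names are a no-op with a
    warning."""
    _check_same_metabolites(mothers, children)
    log = PreprocessLog()
    classes = annotation.set_index("name")["super_class"]
    if class_name not in set(classes.to_numpy()):
        msg = f"class {class_name!r} not present in annotation; nothing excluded"
        warnings.warn(msg, stacklevel=2)
        log.warnings.append(msg)
        return mothers, children, log
    to_drop = {n for n in mothers.metabolite_names if classes.get(n) == class_name}
    keep = [n for n in mothers.metabolite_names if n not in to_drop]
    log.excluded_class = [n for n in mothers.metabolite_names if n in to_drop]
    return (
        mothers.with_data(mothers.data[keep]),
        children.with_data(children.data[keep]),
        log,
    )


def preprocess_pipeline(
    mothers: MetabolomeMatrix,
    children: MetabolomeMatrix,
    *,
    missing_threshold: float = 0.33,
    impute_fraction: float = 0.1,
    variance_drop: float = 0.10,
    corr_threshold: float = 0.90,
    annotation: pd.DataFrame | None = None,
    exclude: str | None = None,
) -> tuple[MetabolomeMatrix, MetabolomeMatrix, PreprocessLog]:
    """Run the full preprocessing chain in its canonical order."""
    log = PreprocessLog()
    if exclude is not None:
        if annotation is None:
            raise DataError("class exclusion requested but no annotation given")
        mothers, children, sub = exclude_class(mothers, children, annotation, exclude)
        log = log.merged(sub)
    mothers, children, sub = filter_missing(mothers, children, missing_threshold)
    log = log.merged(sub)
    mothers = impute_detection_limit(mothers, impute_fraction, log)
    children = impute_detection_limit(children, impute_fraction, log)
    mothers = minmax_scale_within_group(mothers, log)
    children = minmax_scale_within_group(children, log)
    mothers, children, sub = filter_low_variance(mothers, children, variance_drop)
    log = log.merged(sub)
    mothers, children, sub = filter_intercorrelated(mothers, children, corr_threshold)
    log = log.merged(sub)
    return mothers, children, log
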