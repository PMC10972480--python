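"""Frequentist companion analyses to the dyad classifier.

Per-metabolite Welch t-tests compare the dispersion of true vs. random
dyads with Benjamini-Hochberg FDR control across metabolites; Mann-Whitney
U tests probe whether predicted dyad membership on the test set associates
with child outcomes (infections, breastfeeding, CRP).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .dyads import DyadFeatureTable


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def dyad_ttests(table: DyadFeatureTable, alpha: float = 0.05) -> pd.DataFrame:
    """Welch t-test per metabolite between true and random dyads.

    Zero-variance features (identical in both groups) are assigned t = 0,
    p = 1 and flagged. BH adjustment runs across all features; significance
    is called at ``p_adjusted < alpha``. Returns a table sorted by adjusted
    p-value with columns metabolite, t_statistic, p_raw, p_adjusted,
    significant, flag.
    """
    y = table.labels
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("need >= 2 rows per label for group tests")
    X1 = table.features[y == 1]
    X0 = table.features[y == 0]
    t_stats, p_raw, flags = [], [], []
    for col in table.feature_names:
        a, b = X1[col].to_numpy(), X0[col].to_numpy()
        if np.var(a) == 0 and np.var(b) == 0:
            t_stats.append(0.0)
            p_raw.append(1.0)
            flags.append("zero_variance")
            continue
        t, p = sps.ttest_ind(a, b, equal_var=False)
        t_stats.append(float(t))
        p_raw.append(float(p))
        flags.append("")
    p_adj = bh_adjust(np.array(p_raw))
    out = pd.DataFrame(
        {
            "metabolite": table.feature_names,
            "t_statistic": t_stats,
            "p_raw": p_raw,
            "p_adjusted": p_adj,
            "significant": p_adj < alpha,
            "flag": flags,
        }
    )
    return out.sort_values("p_adjusted", kind="stable").reset_index(drop=True)


@dataclass
class AssociationResult:
    outcome: str
    u_statistic: float
    p_value: float
    n_group1: int
    n_group0: int


def outcome_association(
    membership: pd.Series, outcomes: pd.DataFrame
) -> list[AssociationResult]:
    """Mann-Whitney U per outcome between predicted-dyad groups.

    ``membership`` is a 0/1 prediction indexed by child ID, computed on the
    external test set only so the grouping is unbiased. Small samples
    without ties use the exact null distribution; otherwise the
    tie-corrected normal approximation applies. Raw two-sided p-values are
    reported without multiplicity adjustment.
    """
    joined = outcomes.loc[outcomes.index.intersection(membership.index)]
    results = []
    for col in outcomes.columns:
        vals = joined[col].dropna()
        grp = membership.loc[vals.index]
        g1 = vals[grp == 1].to_numpy(dtype=float)
        g0 = vals[grp == 0].to_numpy(dtype=float)
        if len(g1) == 0 or len(g0) == 0:
            raise ValueError(f"outcome {col!r}: one predicted group is empty")
        if len(np.unique(vals.to_numpy())) < 2:
            warnings.warn(f"outcome {col!r} is constant; skipped", stacklevel=2)
            continue
        pooled = np.concatenate([g1, g0])
        has_ties = len(np.unique(pooled)) < len(pooled)
        small = min(len(g1), len(g0)) <= 20
        method = "exact" if (small and not has_ties) else "asymptotic"
        res = sps.mannwhitneyu(g1, g0, alternative="two-sided", method=method)
        results.append(
            AssociationResult(
                outcome=col,
                u_statistic=float(res.statistic),
                p_value=float(res.pvalue),
                n_group1=len(g1),
                n_group0=len(g0),
            )
        )
    return results


def association_table(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "outcome": [r.outcome for r in results],
            "U_statistic": [r.u_statistic for r in results],
            "p_value": [r.p_value for r in results],
            "n_group1": [r.n_group1 for r in results],
            "n_group0": [r.n_group0 for r in results],
        }
    )


def volcano_plot(stat_table: pd.DataFrame, annotation: pd.DataFrame, path: str,
                 alpha: float = 0.05) -> None:
    """Significance scatter across metabolite classes (best-effort)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    classes = annotation.set_index("name")["super_class"]
    tab = stat_table.copy()
    tab["super_class"] = [classes.get(m, "Unknown") for m in tab["metabolite"]]
    tab["neglog10p"] = -np.log10(np.maximum(tab["p_adjusted"], 1e-300))
    fig, ax = plt.subplots(figsize=(9, 5))
    for i, (cls, sub) in enumerate(tab.groupby("super_class")):
        jitter = np.random.default_rng(i).uniform(-0.25, 0.25, len(sub))
        ax.scatter(np.full(len(sub), i) + jitter, sub["neglog10p"], s=14, label=cls)
    ax.axhline(-np.log10(alpha), color="red", lw=0.8, ls="--")
    ax.set_xticks(range(tab["super_class"].nunique()))
    ax.set_xticklabels(sorted(tab["super_class"].unique()), rotation=30, ha="right")
    ax.set_ylabel("-log10 adjusted p")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
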