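"""Synthetic paired mother-child metabolomes with planted heritability.

Because real paired-cohort metabolome data is access-restricted, every
pipeline stage is validated on generated data with known ground truth.
Concentrations are log-normal. For a "heritable" metabolite j with coupling
beta_j, the child's log-value is

    c = mu + beta_j * (m - mu) + sqrt(1 - beta_j^2) * sigma * z,

so the child marginal matches the mother marginal exactly and the
mother-child correlation is beta_j; non-heritable metabolites are drawn
independently (beta = 0). Any dyad signal therefore lives purely in the
mother-child coupling — the quantity the classifier is supposed to detect.
Missingness is MCAR; a fraction of metabolites are unannotated ("X-####")
and a fraction are classed as xenobiotics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .core import MetabolomeMatrix, ROLE_CHILD, ROLE_MOTHER


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults give a mid-sized benchmark cohort."""

    n_families: int = 300
    n_metabolites: int = 200
    n_heritable: int = 10
    heritability: float | Sequence[float] = 0.9
    log_mean: float = 1.0
    log_sd: float = 1.0
    missing_rate: float = 0.05
    frac_unannotated: float = 0.3
    frac_xenobiotic: float = 0.1
    n_outcomes: int = 3
    outcome_effect: float = 0.0
    censor_quantile: float = 0.0  # optional left-censoring instead of MCAR
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_heritable > self.n_metabolites:
            raise ValueError("n_heritable exceeds n_metabolites")
        for name in ("missing_rate", "frac_unannotated", "frac_xenobiotic",
                     "censor_quantile"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        betas = np.atleast_1d(np.asarray(self.heritability, dtype=float))
        if np.any((betas < 0) | (betas > 1)):
            raise ValueError("heritability must lie in [0, 1]")
        if betas.size not in (1, self.n_heritable):
            raise ValueError("heritability must be scalar or length n_heritable")


@dataclass
class SyntheticTruth:
    """Ground truth of one generated dataset."""

    heritable_set: list[str]
    beta: dict[str, float]
    outcome_effects: dict[str, float] = field(default_factory=dict)


def _metabolite_names(cfg: SyntheticConfig, rng: np.random.Generator) -> tuple[list[str], pd.DataFrame]:
    m = cfg.n_metabolites
    n_unann = int(round(cfg.frac_unannotated * m))
    n_xeno = int(round(cfg.frac_xenobiotic * m))
    idx = rng.permutation(m)
    unann = set(idx[:n_unann].tolist())
    xeno = set(idx[n_unann : n_unann + n_xeno].tolist())
    classes = ["Amino Acid", "Lipid", "Nucleotide", "Carbohydrate",
               "Peptide", "Cofactors and Vitamins"]
    names, rows = [], []
    for j in range(m):
        if j in unann:
            name = f"X-{10000 + j}"
            rows.append((name, "Unknown", False))
        elif j in xeno:
            name = f"xenobiotic_{j:04d}"
            rows.append((name, "Xenobiotics", True))
        else:
            name = f"met_{classes[j % len(classes)].split()[0].lower()}_{j:04d}"
            rows.append((name, classes[j % len(classes)], True))
        names.append(name)
    annotation = pd.DataFrame(rows, columns=["name", "super_class", "annotated"])
    return names, annotation


def generate(
    cfg: SyntheticConfig,
) -> tuple[MetabolomeMatrix, MetabolomeMatrix, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Draw one paired cohort: (mothers, children, annotation, outcomes, truth)."""
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_families, cfg.n_metabolites
    names, annotation = _metabolite_names(cfg, rng)

    betas = np.zeros(m)
    heritable_idx = rng.choice(m, size=cfg.n_heritable, replace=False)
    requested = np.atleast_1d(np.asarray(cfg.heritability, dtype=float))
    if requested.size == 1:
        requested = np.full(cfg.n_heritable, requested[0])
    betas[heritable_idx] = requested

    mu, sd = cfg.log_mean, cfg.log_sd
    log_m = rng.normal(mu, sd, size=(n, m))
    noise = rng.normal(0.0, sd, size=(n, m))
    log_c = mu + betas * (log_m - mu) + np.sqrt(1.0 - betas**2) * noise

    conc_m = np.exp(log_m)
    conc_c = np.exp(log_c)

    if cfg.censor_quantile > 0:
        for conc in (conc_m, conc_c):
            cut = np.quantile(conc, cfg.censor_quantile, axis=0)
            conc[conc < cut] = np.nan
    if cfg.missing_rate > 0:
        conc_m[rng.random((n, m)) < cfg.missing_rate] = np.nan
        conc_c[rng.random((n, m)) < cfg.missing_rate] = np.nan

    fam_ids = [f"fam{i:04d}" for i in range(n)]
    mother_ids = [f"M{i:04d}" for i in range(n)]
    child_ids = [f"C{i:04d}" for i in range(n)]
    mothers = MetabolomeMatrix(
        data=pd.DataFrame(conc_m, index=pd.Index(mother_ids, name="subject_id"),
                          columns=names),
        family_ids=pd.Series(fam_ids, index=mother_ids),
        role=ROLE_MOTHER,
    )
    children = MetabolomeMatrix(
        data=pd.DataFrame(conc_c, index=pd.Index(child_ids, name="subject_id"),
                          columns=names),
        family_ids=pd.Series(fam_ids, index=child_ids),
        role=ROLE_CHILD,
    )

    # outcomes: infection-like counts plus one CRP-like continuous marker,
    # null by default; a nonzero effect shifts them with the child's mean
    # heritable-metabolite concordance
    herit_names = [names[j] for j in heritable_idx]
    concordance = np.zeros(n)
    if herit_names:
        disp = np.abs(log_m[:, heritable_idx] - log_c[:, heritable_idx]).mean(axis=1)
        concordance = -(disp - disp.mean()) / (disp.std() or 1.0)
    out_cols: dict[str, np.ndarray] = {}
    effects: dict[str, float] = {}
    for q in range(cfg.n_outcomes):
        name = f"infection_episodes_{q}" if q < cfg.n_outcomes - 1 else "crp_6m"
        shift = cfg.outcome_effect * concordance
        if name.startswith("infection"):
            lam = 2.0 * np.exp(shift)
            out_cols[name] = rng.poisson(lam).astype(float)
        else:
            out_cols[name] = np.exp(rng.normal(0.0, 0.5, n) + shift)
        effects[name] = cfg.outcome_effect
    outcomes = pd.DataFrame(out_cols, index=pd.Index(child_ids, name="child_id"))

    truth = SyntheticTruth(
        heritable_set=herit_names,
        beta={names[j]: float(betas[j]) for j in heritable_idx},
        outcome_effects=effects,
    )
    return mothers, children, annotation, outcomes, truth


def benchmark_run(
    cfg: SyntheticConfig,
    run_config=None,
    **pipeline_kwargs: Any,
) -> dict[str, Any]:
    """Generate a cohort, run the full pipeline, and add recovery metrics.

    Recovery compares the selected feature set and the significant t-test
    set against the planted heritable metabolites (precision/recall), on
    top of the per-model test metrics. See
    :func:`dyadmet.pipeline.run_pipeline` for the pipeline stages.
    """
    from .core import RunConfig
    from .pipeline import run_pipeline

    run_config = run_config or RunConfig(seed=cfg.seed)
    mothers, children, annotation, outcomes, truth = generate(cfg)
    report = run_pipeline(
        mothers, children, annotation=annotation, outcomes=outcomes,
        config=run_config, **pipeline_kwargs,
    )

    planted = set(truth.heritable_set)
    report["truth"] = {
        "heritable_set": sorted(planted),
        "beta": truth.beta,
    }
    for algo, model_rep in report["models"].items():
        selected = set(model_rep.get("selected_features", []))
        if selected:
            hits = planted & selected
            model_rep["recovery"] = {
                "n_planted": len(planted),
                "n_selected": len(selected),
                "n_recovered": len(hits),
                "precision": len(hits) / len(selected),
                "recall": len(hits) / len(planted) if planted else 0.0,
            }
    stat_tab = report.get("stats")
    if stat_tab is not None and planted:
        sig = set(stat_tab.loc[stat_tab["significant"], "metabolite"])
        report["ttest_recovery"] = {
            "n_significant": len(sig),
            "n_recovered": len(planted & sig),
            "recall": len(planted & sig) / len(planted),
        }
    return report
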