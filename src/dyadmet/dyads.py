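"""Dyad construction: true mother-child pairs vs. shuffled random pairs.

A dyad is summarised per metabolite by the dispersion of the mother's and
child's within-cohort scaled concentrations — the sample standard deviation
of the two values, ``|a - b| / sqrt(2)``. Concordant pairs therefore sit
near 0, discordant pairs near 1/sqrt(2). True dyads (same family) get label
1; random dyads built by shuffling mothers against children get label 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .core import DataError, MetabolomeMatrix

logger = logging.getLogger(__name__)

_SQRT2 = np.sqrt(2.0)

#: metadata columns preceding the feature block in a dyad table
META_COLS = ["mother_id", "child_id", "label"]


@dataclass
class DyadFeatureTable:
    """Rows are dyads; columns are per-metabolite dispersion features."""

    table: pd.DataFrame  # mother_id, child_id, label, then features
    skipped_families: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for col in META_COLS:
            if col not in self.table.columns:
                raise DataError(f"dyad table missing column {col!r}")
        pairs = self.table[["mother_id", "child_id"]].apply(tuple, axis=1)
        if pairs.duplicated().any():
            raise DataError("duplicated (mother_id, child_id) pair in dyad table")
        feats = self.features
        if feats.size and (np.nanmin(feats.to_numpy()) < 0):
            raise DataError("dispersion features must be >= 0")

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.table.columns if c not in META_COLS]

    @property
    def features(self) -> pd.DataFrame:
        return self.table[self.feature_names]

    @property
    def labels(self) -> np.ndarray:
        return self.table["label"].to_numpy(dtype=int)

    @property
    def X(self) -> np.ndarray:
        return self.features.to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.labels

    def __len__(self) -> int:
        return len(self.table)

    def select_features(self, names: list[str]) -> "DyadFeatureTable":
        """Restrict the feature block to ``names`` (metadata kept)."""
        missing = [n for n in names if n not in self.table.columns]
        if missing:
            raise DataError(f"unknown features: {missing}")
        return DyadFeatureTable(
            table=self.table[META_COLS + list(names)].copy(),
            skipped_families=list(self.skipped_families),
        )


def pair_dispersion(mother_values: np.ndarray, child_values: np.ndarray) -> np.ndarray:
    """Element-wise sample standard deviation of each {mother, child} pair.

    For two points the sample standard deviation (ddof=1) reduces to
    ``|a - b| / sqrt(2)``; identical values give exactly 0.
    """
    a = np.asarray(mother_values, dtype=float)
    b = np.asarray(child_values, dtype=float)
    if a.shape != b.shape:
        raise DataError(f"length mismatch: {a.shape} vs {b.shape}")
    return np.abs(a - b) / _SQRT2


def _family_maps(mothers: MetabolomeMatrix, children: MetabolomeMatrix):
    def one_per_family(matrix: MetabolomeMatrix) -> dict[str, str]:
        fam_to_subj: dict[str, str] = {}
        for subj, fam in matrix.family_ids.items():
            if fam in fam_to_subj:
                raise DataError(
                    f"family {fam!r} has more than one {matrix.role}; "
                    "only singleton dyads are modelled"
                )
            fam_to_subj[fam] = subj
        return fam_to_subj

    return one_per_family(mothers), one_per_family(children)


def _dispersion_rows(
    mothers: MetabolomeMatrix,
    children: MetabolomeMatrix,
    pairs: list[tuple[str, str]],
    label: int,
) -> pd.DataFrame:
    m_vals = mothers.data.loc[[m for m, _ in pairs]].to_numpy(dtype=float)
    c_vals = children.data.loc[[c for _, c in pairs]].to_numpy(dtype=float)
    feats = pair_dispersion(m_vals, c_vals)
    out = pd.DataFrame(feats, columns=mothers.metabolite_names)
    out.insert(0, "label", label)
    out.insert(0, "child_id", [c for _, c in pairs])
    out.insert(0, "mother_id", [m for m, _ in pairs])
    return out


def _check_ready(mothers: MetabolomeMatrix, children: MetabolomeMatrix) -> None:
    if not (mothers.scaled and children.scaled):
        raise DataError("matrices must be scaled before building dyads")
    if mothers.metabolite_names != children.metabolite_names:
        raise DataError("mothers and children carry different metabolite sets")


def build_true_dyads(
    mothers: MetabolomeMatrix, children: MetabolomeMatrix
) -> DyadFeatureTable:
    """One label-1 row per family present in both cohorts.

    Families lacking either member are skipped and logged, not an error.
    """
    _check_ready(mothers, children)
    fam_m, fam_c = _family_maps(mothers, children)
    shared = [f for f in fam_m if f in fam_c]
    skipped = sorted(set(fam_m) ^ set(fam_c))
    if skipped:
        logger.info("skipping %d incomplete families", len(skipped))
    pairs = [(fam_m[f], fam_c[f]) for f in shared]
    table = _dispersion_rows(mothers, children, pairs, label=1)
    return DyadFeatureTable(table=table, skipped_families=skipped)


def build_random_dyads(
    mothers: MetabolomeMatrix,
    children: MetabolomeMatrix,
    n_shuffles: int = 2,
    drop_fraction: float = 0.30,
    seed: int = 0,
    allow_true_pairs: bool = False,
) -> DyadFeatureTable:
    """Shuffle mothers against children ``n_shuffles`` times, then thin.

    Each round draws a uniform permutation of the children over the shared
    families; a round that recreates a true family pair (or duplicates a
    pair from an earlier round) is re-drawn, so label 0 stays uncontaminated
    unless ``allow_true_pairs`` is set. The pooled rounds are thinned by
    dropping ``round(drop_fraction * count)`` rows uniformly at random.
    """
    _check_ready(mothers, children)
    fam_m, fam_c = _family_maps(mothers, children)
    shared = [f for f in fam_m if f in fam_c]
    if len(shared) < 2:
        raise DataError("need at least 2 complete families to form random dyads")
    rng = np.random.default_rng(seed)
    mother_ids = [fam_m[f] for f in shared]
    child_ids = [fam_c[f] for f in shared]
    n = len(shared)

    seen: set[tuple[str, str]] = set()
    pairs: list[tuple[str, str]] = []
    for _ in range(n_shuffles):
        for _attempt in range(10_000):
            perm = rng.permutation(n)
            candidate = [(mother_ids[i], child_ids[perm[i]]) for i in range(n)]
            if allow_true_pairs:
                break
            has_self = any(shared[i] == shared[perm[i]] for i in range(n))
            if not has_self and not (set(candidate) & seen):
                break
        else:  # pragma: no cover - astronomically unlikely
            raise DataError("could not draw a collision-free shuffle")
        pairs.extend(candidate)
        seen.update(candidate)

    n_drop = int(round(drop_fraction * len(pairs)))
    if n_drop:
        drop = set(rng.choice(len(pairs), size=n_drop, replace=False).tolist())
        pairs = [p for i, p in enumerate(pairs) if i not in drop]
    table = _dispersion_rows(mothers, children, pairs, label=0)
    return DyadFeatureTable(table=table)


def assemble_dataset(
    true: DyadFeatureTable, random: DyadFeatureTable
) -> DyadFeatureTable:
    """Concatenate true and random dyads into one labelled dataset."""
    if true.feature_names != random.feature_names:
        raise DataError("true and random dyad tables have different feature columns")
    if len(true) == 0 or len(random) == 0:
        raise DataError("both dyad classes must be non-empty")
    table = pd.concat([true.table, random.table], ignore_index=True)
    out = DyadFeatureTable(table=table)  # re-validates pair uniqueness
    ratio = len(random) / len(true)
    logger.info("assembled %d dyads (class ratio 1 : %.2f)", len(out), ratio)
    return out


def grouped_dyad_split(
    mothers: MetabolomeMatrix,
    children: MetabolomeMatrix,
    test_fraction: float = 0.20,
    n_shuffles: int = 2,
    drop_fraction: float = 0.30,
    seed: int = 0,
    allow_true_pairs: bool = False,
) -> tuple[DyadFeatureTable, DyadFeatureTable]:
    """Family-partitioned dataset construction: split the families first,
    then build true AND random dyads independently within each partition.

    No subject ever contributes rows to both sides, so test performance
    cannot draw on memorized subject identities — under a no-signal null
    the expected test MCC is 0. This is the default construction; the
    row-level alternative (:func:`split_train_test` after
    :func:`assemble_dataset`) mirrors designs that split after pairing and
    is kept for sensitivity analysis.
    """
    _check_ready(mothers, children)
    fam_m, fam_c = _family_maps(mothers, children)
    shared = sorted(f for f in fam_m if f in fam_c)
    if len(shared) < 4:
        raise DataError("need at least 4 complete families for a grouped split")
    rng = np.random.default_rng(seed)
    n_test = int(round(test_fraction * len(shared)))
    if n_test < 2 and test_fraction > 0:
        n_test = 2
    test_fams = set(rng.choice(shared, size=n_test, replace=False).tolist()) if n_test else set()
    train_fams = set(shared) - test_fams
    sides = []
    for fams, side_seed in ((train_fams, seed + 1), (test_fams, seed + 2)):
        if not fams:
            sides.append(DyadFeatureTable(table=sides[0].table.iloc[0:0]))
            continue
        msub = mothers.subset_families(fams)
        csub = children.subset_families(fams)
        true_d = build_true_dyads(msub, csub)
        rand_d = build_random_dyads(
            msub, csub, n_shuffles=n_shuffles, drop_fraction=drop_fraction,
            seed=side_seed, allow_true_pairs=allow_true_pairs,
        )
        sides.append(assemble_dataset(true_d, rand_d))
    return sides[0], sides[1]


def split_train_test(
    table: DyadFeatureTable, test_fraction: float = 0.20, seed: int = 0
) -> tuple[DyadFeatureTable, DyadFeatureTable]:
    """Label-stratified random split; the test side is the external set that
    feature selection and tuning must never touch."""
    y = table.labels
    if len(np.unique(y)) < 2:
        raise DataError("both labels required before splitting")
    for cls in np.unique(y):
        if (y == cls).sum() < 2:
            raise DataError(f"label class {cls} has fewer than 2 rows")
    if test_fraction == 0:
        logger.warning("test_fraction is 0: external validation set is empty")
        empty = table.table.iloc[0:0]
        return DyadFeatureTable(table=table.table.copy()), DyadFeatureTable(table=empty)
    tr, te = train_test_split(
        table.table,
        test_size=test_fraction,
        stratify=y,
        random_state=seed,
        shuffle=True,
    )
    return (
        DyadFeatureTable(table=tr.reset_index(drop=True)),
        DyadFeatureTable(table=te.reset_index(drop=True)),
    )
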