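"""Domain types and file I/O for paired mother-child metabolome analysis.

The central container is :class:`MetabolomeMatrix`: a subjects x metabolites
concentration table for one cohort role (mothers or children), carrying the
family linkage needed to assemble dyads. Matrices are dense; missing values
are ``NaN``. All tables travel as delimited text (CSV/TSV).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

MISSING_TOKENS = {"", "na", "nan"}  # matched case-insensitively after strip

ROLE_MOTHER = "mother"
ROLE_CHILD = "child"


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass
class MetabolomeMatrix:
    """Subjects x metabolites concentrations for one cohort role.

    Parameters
    ----------
    data:
        DataFrame indexed by subject ID with metabolite names as columns.
        Missing cells are ``NaN``; observed concentrations must be >= 0
        (unscaled) or in [0, 1] (scaled).
    family_ids:
        Series mapping every subject ID in ``data.index`` to a family ID.
    role:
        ``"mother"`` or ``"child"``; constant for the whole matrix.
    scaled:
        True once per-metabolite min-max scaling has been applied.
    """

    data: pd.DataFrame
    family_ids: pd.Series
    role: str
    scaled: bool = False

    def __post_init__(self) -> None:
        if self.role not in (ROLE_MOTHER, ROLE_CHILD):
            raise DataError(f"role must be 'mother' or 'child', got {self.role!r}")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise DataError(f"duplicate subject IDs: {dupes}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise DataError(f"duplicate metabolite names: {dupes}")
        missing_fam = [s for s in self.data.index if s not in self.family_ids.index]
        if missing_fam:
            raise DataError(f"subjects without family mapping: {missing_fam}")
        self.family_ids = self.family_ids.loc[self.data.index]
        vals = self.data.to_numpy(dtype=float)
        observed = vals[~np.isnan(vals)]
        if observed.size and observed.min() < 0:
            raise DataError("negative concentrations are not allowed")
        if self.scaled and observed.size and observed.max() > 1.0 + 1e-12:
            raise DataError("scaled matrix holds values outside [0, 1]")

    # -- convenience accessors -------------------------------------------------
    @property
    def subject_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def metabolite_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: pd.DataFrame, scaled: bool | None = None) -> "MetabolomeMatrix":
        """Return a copy carrying ``data`` and the same metadata."""
        return MetabolomeMatrix(
            data=data,
            family_ids=self.family_ids,
            role=self.role,
            scaled=self.scaled if scaled is None else scaled,
        )

    def missing_fraction(self) -> pd.Series:
        """Per-metabolite fraction of missing cells."""
        return self.data.isna().mean(axis=0)

    def subset_families(self, families: set[str] | list[str]) -> "MetabolomeMatrix":
        """Restrict to subjects whose family is in ``families``."""
        families = set(families)
        keep = [s for s, f in self.family_ids.items() if f in families]
        return MetabolomeMatrix(
            data=self.data.loc[keep],
            family_ids=self.family_ids.loc[keep],
            role=self.role,
            scaled=self.scaled,
        )


@dataclass
class RunConfig:
    """All tunable pipeline parameters with study defaults.

    Fractions are in [0, 1]. The seed is recorded in every report; stage
    sub-seeds are derived from it with ``numpy.random.SeedSequence``.
    """

    missing_threshold: float = 0.33
    impute_fraction: float = 0.1
    variance_drop: float = 0.10
    corr_threshold: float = 0.90
    n_shuffles: int = 2
    random_drop_fraction: float = 0.30
    test_fraction: float = 0.20
    cv_folds: int = 10
    pi_repeats: int = 5
    keep_fraction: float = 0.33
    max_stages: int = 7
    min_features: int = 7
    fdr_alpha: float = 0.05
    seed: int = 0
    # less prominent switches
    n_trials: int = 50
    improvement_tol: float = 1e-3
    exclude_class: str | None = None
    pooled_scaling: bool = False
    train_only_fit: bool = False
    allow_true_pair_collisions: bool = False
    group_split: bool = True
    retune_per_stage: bool = False
    models: tuple[str, ...] = ("random_forest", "gradient_boosting", "elasticnet_logistic")

    def __post_init__(self) -> None:
        for name in (
            "missing_threshold",
            "impute_fraction",
            "variance_drop",
            "test_fraction",
            "random_drop_fraction",
            "keep_fraction",
            "fdr_alpha",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.min_features < 1:
            raise ValueError("min_features must be >= 1")
        if isinstance(self.models, list):
            self.models = tuple(self.models)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["models"] = list(self.models)
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload)

    def spawn_seeds(self, n: int) -> list[int]:
        """Derive ``n`` independent sub-seeds (< 2**31) from the master seed."""
        ss = np.random.SeedSequence(self.seed)
        return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


# -- reading -------------------------------------------------------------------

def _read_table(path: str | Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def _parse_cell(raw: str, row_id: str, column: str) -> float:
    token = raw.strip()
    if token.lower() in MISSING_TOKENS:
        return np.nan
    try:
        return float(token)
    except ValueError:
        raise DataError(
            f"non-numeric value {raw!r} for subject {row_id!r}, metabolite {column!r}"
        ) from None


def read_metabolome(
    path: str | Path, metadata_path: str | Path, role: str
) -> MetabolomeMatrix:
    """Read one cohort's concentration matrix plus its subject metadata.

    The matrix file has a header of metabolite names with subject IDs in the
    first column; the metadata file has columns ``subject_id``, ``family_id``
    and optionally ``role``. Empty cells and the tokens ``NA``/``NaN`` (any
    case) count as missing.
    """
    raw = _read_table(path)
    if raw.shape[1] < 2:
        raise DataError(f"{path}: expected an ID column plus metabolite columns")
    id_col = raw.columns[0]
    subject_ids = raw[id_col].astype(str).str.strip()
    if subject_ids.duplicated().any():
        dupes = subject_ids[subject_ids.duplicated()].unique().tolist()
        raise DataError(f"duplicate subject IDs in {path}: {dupes}")

    metabolites = list(raw.columns[1:])
    values = np.empty((len(raw), len(metabolites)))
    for j, col in enumerate(metabolites):
        col_raw = raw[col]
        for i, cell in enumerate(col_raw):
            values[i, j] = _parse_cell(cell, subject_ids.iloc[i], col)

    meta = _read_table(metadata_path)
    required = {"subject_id", "family_id"}
    if not required.issubset(meta.columns):
        raise DataError(f"{metadata_path}: needs columns {sorted(required)}")
    if "role" in meta.columns:
        meta = meta[meta["role"].str.strip() == role]
    fam = pd.Series(
        meta["family_id"].astype(str).str.strip().to_numpy(),
        index=meta["subject_id"].astype(str).str.strip(),
    )
    if fam.index.has_duplicates:
        dupes = fam.index[fam.index.duplicated()].unique().tolist()
        raise DataError(f"duplicate subject IDs in metadata: {dupes}")

    data = pd.DataFrame(values, index=pd.Index(subject_ids, name="subject_id"),
                        columns=metabolites)
    return MetabolomeMatrix(data=data, family_ids=fam, role=role, scaled=False)


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read the metabolite annotation table (name, super_class, annotated)."""
    tab = _read_table(path)
    needed = {"name", "super_class", "annotated"}
    if not needed.issubset(tab.columns):
        raise DataError(f"{path}: needs columns {sorted(needed)}")
    out = tab[["name", "super_class", "annotated"]].copy()
    out["annotated"] = out["annotated"].str.strip().str.lower().isin({"1", "true", "yes"})
    if out["name"].duplicated().any():
        raise DataError("duplicate metabolite names in annotation")
    return out


def harmonize_annotation(names: Iterable[str], annotation: pd.DataFrame | None) -> pd.DataFrame:
    """One annotation row per metabolite; absent names become Unknown/unannotated."""
    names = list(names)
    if annotation is None:
        annotation = pd.DataFrame(columns=["name", "super_class", "annotated"])
    known = annotation.set_index("name")
    rows = []
    for n in names:
        if n in known.index:
            rows.append((n, known.loc[n, "super_class"], bool(known.loc[n, "annotated"])))
        else:
            rows.append((n, "Unknown", False))
    return pd.DataFrame(rows, columns=["name", "super_class", "annotated"])


def read_outcomes(path: str | Path) -> pd.DataFrame:
    """Read the per-child outcomes table; first column is the child ID."""
    tab = _read_table(path)
    if tab.shape[1] < 2:
        raise DataError(f"{path}: expected a child_id column plus outcome columns")
    id_col = tab.columns[0]
    out = tab.set_index(tab[id_col].astype(str).str.strip()).drop(columns=[id_col])
    out.index.name = "child_id"
    for col in out.columns:
        out[col] = pd.to_numeric(out[col].replace({t: np.nan for t in ("", "NA", "NaN", "nan")}))
    if out.index.has_duplicates:
        raise DataError("duplicate child IDs in outcomes")
    return out


# -- writing -------------------------------------------------------------------

def write_metabolome(matrix: MetabolomeMatrix, path: str | Path,
                     metadata_path: str | Path | None = None) -> None:
    """Write the concentration matrix (and optionally metadata) as CSV."""
    matrix.data.to_csv(path, index_label="subject_id", na_rep="NA")
    if metadata_path is not None:
        meta = pd.DataFrame(
            {
                "subject_id": matrix.subject_ids,
                "family_id": matrix.family_ids.to_numpy(),
                "role": matrix.role,
            }
        )
        meta.to_csv(metadata_path, index=False)


class _ReportEncoder(json.JSONEncoder):
    def default(self, o: Any) -> Any:  # noqa: D102
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="list")
        if isinstance(o, pd.Series):
            return o.to_dict()
        return super().default(o)


def write_report(report: Any, path: str | Path) -> None:
    """Serialize a report (dataclass / dict / DataFrame) to JSON or CSV.

    ``.csv`` paths expect a DataFrame-like table; everything else is written
    as JSON. Round-tripping JSON preserves numeric fields exactly (floats are
    emitted with ``repr`` precision).
    """
    path = Path(path)
    if path.suffix == ".csv":
        table = report if isinstance(report, pd.DataFrame) else pd.DataFrame(report)
        table.to_csv(path, index=False)
        return
    with open(path, "w") as fh:
        json.dump(report, fh, cls=_ReportEncoder, indent=2)
        fh.write("\n")


def read_report(path: str | Path) -> Any:
    path = Path(path)
    if path.suffix == ".csv":
        return pd.read_csv(path)
    with open(path) as fh:
        return json.load(fh)
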