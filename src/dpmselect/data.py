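"""Tabular containers for mixed continuous/categorical patient-level data.

A :class:`MixedDataset` keeps continuous covariates, integer-coded
categorical covariates, a binary treatment indicator and a continuous
outcome in aligned row order, together with a boolean missingness mask for
every covariate cell.  Missing cells are represented in the mask, never by
sentinel values, so held-out true values can be stored alongside for
oracle comparisons.

On disk a dataset is a plain CSV with a header row (missing cells empty)
plus a YAML sidecar (:class:`ColumnSchema`) recording column roles and
category dictionaries, so categorical codes round-trip unambiguously.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

__all__ = ["ColumnSchema", "MixedDataset", "read_dataset", "write_dataset"]


@dataclass
class ColumnSchema:
    """Column roles and category dictionaries for a dataset.

    Parameters
    ----------
    continuous
        Ordered names of continuous covariate columns.
    categorical
        Mapping of categorical covariate name to its ordered category
        labels; the integer code of a category is its index in this list
        and code 0 is the reference level for dummy coding.
    treatment
        Name of the binary treatment column (values 0/1).
    outcome
        Name of the continuous outcome column.
    units
        Optional free-text unit labels per column.
    """

    continuous: list[str]
    categorical: dict[str, list[str]]
    treatment: str
    outcome: str
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = list(self.continuous) + list(self.categorical) + [self.treatment, self.outcome]
        if len(set(names)) != len(names):
            raise ValueError("column names must be unique across roles")
        for col, levels in self.categorical.items():
            if len(levels) != len(set(levels)):
                raise ValueError(f"duplicate category labels for column {col!r}")

    @property
    def cat_names(self) -> list[str]:
        return list(self.categorical)

    @property
    def n_levels(self) -> list[int]:
        return [len(self.categorical[c]) for c in self.categorical]

    @property
    def covariates(self) -> list[str]:
        return list(self.continuous) + list(self.categorical)

    def to_dict(self) -> dict[str, Any]:
        return {
            "continuous": list(self.continuous),
            "categorical": {k: list(v) for k, v in self.categorical.items()},
            "treatment": self.treatment,
            "outcome": self.outcome,
            "units": dict(self.units),
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ColumnSchema":
        return cls(
            continuous=list(d["continuous"]),
            categorical={k: [str(x) for x in v] for k, v in d["categorical"].items()},
            treatment=d["treatment"],
            outcome=d["outcome"],
            units=dict(d.get("units", {})),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ColumnSchema":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class MixedDataset:
    """Aligned columns of mixed-type patient data with a missingness mask.

    ``x_cont[i, j]`` / ``x_cat[i, j]`` are undefined wherever the
    corresponding mask entry is True; consumers must consult the mask.
    ``attrs`` carries optional provenance (e.g. generator ground truth).
    """

    schema: ColumnSchema
    x_cont: np.ndarray  # (n, J_C) float
    x_cat: np.ndarray  # (n, J_D) int codes
    treatment: np.ndarray  # (n,) int 0/1
    y: np.ndarray  # (n,) float
    miss_cont: np.ndarray  # (n, J_C) bool, True = missing
    miss_cat: np.ndarray  # (n, J_D) bool
    attrs: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.y)
        jc = len(self.schema.continuous)
        jd = len(self.schema.categorical)
        self.x_cont = np.asarray(self.x_cont, dtype=float).reshape(n, jc)
        self.x_cat = np.asarray(self.x_cat, dtype=int).reshape(n, jd)
        self.treatment = np.asarray(self.treatment, dtype=int).reshape(n)
        self.y = np.asarray(self.y, dtype=float).reshape(n)
        self.miss_cont = np.asarray(self.miss_cont, dtype=bool).reshape(n, jc)
        self.miss_cat = np.asarray(self.miss_cat, dtype=bool).reshape(n, jd)
        for j, (col, levels) in enumerate(self.schema.categorical.items()):
            codes = self.x_cat[~self.miss_cat[:, j], j]
            if codes.size and (codes.min() < 0 or codes.max() >= len(levels)):
                raise ValueError(f"category code out of range for column {col!r}")

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def j_cont(self) -> int:
        return self.x_cont.shape[1]

    @property
    def j_cat(self) -> int:
        return self.x_cat.shape[1]

    @property
    def n_missing_cells(self) -> int:
        return int(self.miss_cont.sum() + self.miss_cat.sum())

    def complete_rows(self) -> np.ndarray:
        """Boolean mask of rows with no missing covariate cell."""
        return ~(self.miss_cont.any(axis=1) | self.miss_cat.any(axis=1))

    def to_frame(self) -> pd.DataFrame:
        """Dataset as a DataFrame in schema column order (labels, NaN for missing)."""
        s = self.schema
        out: dict[str, Any] = {}
        for j, col in enumerate(s.continuous):
            v = self.x_cont[:, j].astype(object)
            v[self.miss_cont[:, j]] = np.nan
            out[col] = v.astype(float)
        for j, col in enumerate(s.cat_names):
            labels = np.array(s.categorical[col], dtype=object)
            v = np.where(self.miss_cat[:, j], None, labels[np.clip(self.x_cat[:, j], 0, None)])
            out[col] = v
        out[s.treatment] = self.treatment
        out[s.outcome] = self.y
        return pd.DataFrame(out)

    def copy(self) -> "MixedDataset":
        return MixedDataset(
            schema=self.schema,
            x_cont=self.x_cont.copy(),
            x_cat=self.x_cat.copy(),
            treatment=self.treatment.copy(),
            y=self.y.copy(),
            miss_cont=self.miss_cont.copy(),
            miss_cat=self.miss_cat.copy(),
            attrs=dict(self.attrs),
        )


def write_dataset(data: MixedDataset, path: str | Path, schema_path: str | Path | None = None) -> None:
    """Write a dataset as CSV (missing cells empty) and optional schema sidecar."""
    df = data.to_frame()
    df.to_csv(path, index=False, na_rep="")
    if schema_path is not None:
        data.schema.to_yaml(schema_path)


def read_dataset(path: str | Path, schema: ColumnSchema, require_outcome: bool = True) -> MixedDataset:
    """Read a CSV into a :class:`MixedDataset` using *schema* for typing.

    Empty cells in covariate columns become masked-missing (never zero).
    Raises on unknown category tokens (with row and column named), on
    non-numeric continuous cells, and — when ``require_outcome`` — on
    missing treatment or outcome cells.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in schema.covariates + [schema.treatment, schema.outcome] if c not in df.columns]
    if missing_cols:
        raise ValueError(f"file {path} lacks columns {missing_cols}")
    n = len(df)
    jc, jd = len(schema.continuous), len(schema.categorical)
    x_cont = np.zeros((n, jc))
    miss_cont = np.zeros((n, jc), dtype=bool)
    for j, col in enumerate(schema.continuous):
        raw = df[col].to_numpy()
        for i, tok in enumerate(raw):
            tok = tok.strip()
            if tok == "":
                miss_cont[i, j] = True
            else:
                try:
                    x_cont[i, j] = float(tok)
                except ValueError as exc:
                    raise ValueError(
                        f"non-numeric value {tok!r} in continuous column {col!r}, row {i}"
                    ) from exc
    x_cat = np.zeros((n, jd), dtype=int)
    miss_cat = np.zeros((n, jd), dtype=bool)
    for j, col in enumerate(schema.cat_names):
        lookup = {lab: k for k, lab in enumerate(schema.categorical[col])}
        raw = df[col].to_numpy()
        for i, tok in enumerate(raw):
            tok = tok.strip()
            if tok == "":
                miss_cat[i, j] = True
            elif tok in lookup:
                x_cat[i, j] = lookup[tok]
            else:
                raise ValueError(f"unknown category token {tok!r} in column {col!r}, row {i}")
    treat_raw = df[schema.treatment].to_numpy()
    y_raw = df[schema.outcome].to_numpy()
    if require_outcome:
        for i in range(n):
            if treat_raw[i].strip() == "":
                raise ValueError(f"missing treatment cell at row {i}")
            if y_raw[i].strip() == "":
                raise ValueError(f"missing outcome cell at row {i}")
    treatment = np.array([int(float(t)) if t.strip() else -1 for t in treat_raw])
    y = np.array([float(t) if t.strip() else np.nan for t in y_raw])
    return MixedDataset(
        schema=schema,
        x_cont=x_cont,
        x_cat=x_cat,
        treatment=treatment,
        y=y,
        miss_cont=miss_cont,
        miss_cat=miss_cat,
    )
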