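"""Long-format trial data and cLDA design matrices.

A trial is stored in long format: one row per (subject, visit) with the
study label (``current`` or ``historical``), treatment arm, time since
baseline and the outcome.  The analysis model is a constrained longitudinal
data analysis (cLDA) linear mixed model: the baseline mean is shared across
arms (no treatment main effect) and the treatment enters only through a
treatment-by-time interaction.  The historical study contributes a control
arm only, so its fixed-effect design has no interaction column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CURRENT",
    "HISTORICAL",
    "TREATMENT",
    "CONTROL",
    "REQUIRED_COLUMNS",
    "LongitudinalDataset",
    "DesignMatrices",
    "DataFormatError",
    "DataValidationError",
    "read_long_csv",
    "write_long_csv",
    "build_design",
]

CURRENT = "current"
HISTORICAL = "historical"
TREATMENT = "treatment"
CONTROL = "control"

#: canonical column names of the long CSV format
REQUIRED_COLUMNS = ("subject", "study", "arm", "time", "y")


class DataFormatError(ValueError):
    """The file/table does not have the expected long-format layout."""


class DataValidationError(ValueError):
    """The table is well-formed but violates a dataset invariant."""


@dataclass(frozen=True)
class LongitudinalDataset:
    """Validated long-format records of one or two studies.

    Parameters
    ----------
    frame
        Long-format table with columns ``subject, study, arm, time, y``;
        any further columns are treated as (time-constant or time-varying)
        covariates.
    time_unit
        Free-text label for the time axis (e.g. ``"years"``).
    """

    frame: pd.DataFrame
    time_unit: str = ""

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise DataFormatError(f"missing required column(s): {missing}")
        df = df.copy()
        df["subject"] = df["subject"].astype(str)
        df["study"] = df["study"].astype(str)
        df["arm"] = df["arm"].astype(str)
        df["time"] = pd.to_numeric(df["time"])
        df["y"] = pd.to_numeric(df["y"])

        bad_study = set(df["study"]) - {CURRENT, HISTORICAL}
        if bad_study:
            raise DataValidationError(f"unknown study label(s): {sorted(bad_study)}")
        bad_arm = set(df["arm"]) - {TREATMENT, CONTROL}
        if bad_arm:
            raise DataValidationError(f"unknown arm label(s): {sorted(bad_arm)}")
        hist_trt = (df["study"] == HISTORICAL) & (df["arm"] == TREATMENT)
        if hist_trt.any():
            raise DataValidationError(
                "historical records must all belong to the control arm"
            )
        if not np.isfinite(df["time"].to_numpy()).all():
            raise DataValidationError("non-finite time value")
        if (df["time"].to_numpy() < 0).any():
            raise DataValidationError("negative time value")
        if not np.isfinite(df["y"].to_numpy()).all():
            raise DataValidationError("non-finite outcome value")
        n_pairs = df.groupby("subject")[["study", "arm"]].nunique()
        multi = n_pairs[(n_pairs["study"] > 1) | (n_pairs["arm"] > 1)]
        if len(multi):
            raise DataValidationError(
                f"subject(s) appear in more than one (study, arm): {list(multi.index)}"
            )
        if df.duplicated(subset=["subject", "time"]).any():
            raise DataValidationError("duplicated (subject, time) pair")

        # deterministic ordering: study, then subject lexicographically, then time
        df = df.sort_values(["study", "subject", "time"], kind="mergesort")
        df = df.reset_index(drop=True)
        object.__setattr__(self, "frame", df)

    # -- accessors ---------------------------------------------------------

    @property
    def covariate_names(self) -> tuple[str, ...]:
        return tuple(c for c in self.frame.columns if c not in REQUIRED_COLUMNS)

    @property
    def n_records(self) -> int:
        return len(self.frame)

    @property
    def n_subjects(self) -> int:
        return self.frame["subject"].nunique()

    def study_frame(self, study: str) -> pd.DataFrame:
        if study not in (CURRENT, HISTORICAL):
            raise ValueError(f"unknown study {study!r}")
        return self.frame[self.frame["study"] == study]

    def has_study(self, study: str) -> bool:
        return bool((self.frame["study"] == study).any())

    def subset(self, study: str) -> "LongitudinalDataset":
        return LongitudinalDataset(self.study_frame(study).copy(), self.time_unit)

    def arms(self, study: str = CURRENT) -> set[str]:
        return set(self.study_frame(study)["arm"])

    def equals(self, other: "LongitudinalDataset", tol: float = 1e-12) -> bool:
        """Record-level equality up to floating-point formatting noise."""
        a, b = self.frame, other.frame
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        for col in a.columns:
            if a[col].dtype.kind in "fiu":
                if not np.allclose(a[col], b[col], rtol=0.0, atol=tol):
                    return False
            elif not (a[col].to_numpy() == b[col].to_numpy()).all():
                return False
        return True

    @staticmethod
    def concat(*parts: "LongitudinalDataset") -> "LongitudinalDataset":
        frames = [p.frame for p in parts if len(p.frame)]
        return LongitudinalDataset(pd.concat(frames, ignore_index=True))


@dataclass
class DesignMatrices:
    """Per-subject fixed/random-effect design matrices of the cLDA model.

    Fixed-effect columns are ordered ``(intercept, covariates..., time,
    treatment:time)``; the interaction column is present only for the
    current study and is identically zero for control subjects.  Random
    effects are a subject-level intercept and time slope, ``Z = (1, t)``.
    """

    subjects: list[str]
    X: list[np.ndarray]
    Z: list[np.ndarray]
    y: list[np.ndarray]
    columns: tuple[str, ...]
    has_treatment_column: bool
    _groups: list | None = field(default=None, repr=False)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_obs(self) -> int:
        return sum(len(v) for v in self.y)

    @property
    def p(self) -> int:
        return self.X[0].shape[1]

    @property
    def q(self) -> int:
        return self.Z[0].shape[1]

    def stacked(self) -> tuple[np.ndarray, np.ndarray]:
        """All rows of X and y stacked across subjects."""
        return np.vstack(self.X), np.concatenate(self.y)

    def groups(self) -> list["_VisitGroup"]:
        """Subjects grouped by identical visit-time pattern.

        Within a group every subject shares the same Z (hence the same
        marginal covariance), so one Cholesky factorisation serves the
        whole group.
        """
        if self._groups is None:
            buckets: dict[tuple, list[int]] = {}
            for i, z in enumerate(self.Z):
                key = tuple(np.round(z[:, -1] if z.shape[1] > 1 else z[:, 0], 12))
                buckets.setdefault((z.shape[0], key), []).append(i)
            groups = []
            for idx in buckets.values():
                groups.append(
                    _VisitGroup(
                        Z=np.ascontiguousarray(self.Z[idx[0]]),
                        X=np.ascontiguousarray(
                            np.stack([self.X[i] for i in idx])
                        ),
                        y=np.ascontiguousarray(
                            np.stack([self.y[i] for i in idx])
                        ),
                        indices=np.asarray(idx),
                    )
                )
            self._groups = groups
        return self._groups


@dataclass
class _VisitGroup:
    Z: np.ndarray          # (m, q) shared random-effect design
    X: np.ndarray          # (k, m, p)
    y: np.ndarray          # (k, m)
    indices: np.ndarray    # (k,) positions in the parent DesignMatrices

    @property
    def k(self) -> int:
        return self.X.shape[0]

    @property
    def m(self) -> int:
        return self.X.shape[1]


def read_long_csv(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    time_unit: str = "",
) -> LongitudinalDataset:
    """Read a long-format trial CSV.

    ``column_map`` remaps file column names onto the canonical names, e.g.
    ``{"id": "subject", "outcome": "y"}``.  Columns beyond the required five
    become covariates.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DataFormatError(
            f"{path.name}: missing required column(s) {missing}; "
            f"found {list(df.columns)}"
        )
    return LongitudinalDataset(df, time_unit=time_unit)


def write_long_csv(dataset: LongitudinalDataset, path: str | Path) -> None:
    dataset.frame.to_csv(path, index=False)


def build_design(
    dataset: LongitudinalDataset,
    covariate_names: Sequence[str] = (),
    for_study: str = CURRENT,
) -> DesignMatrices:
    """Build cLDA design matrices for one study of a dataset.

    The historical model carries no treatment term, so ``for_study=
    "historical"`` omits the interaction column.  Rows are ordered by time
    within subject (the dataset is already sorted), making the design
    invariant to the input record order.
    """
    df = dataset.study_frame(for_study)
    if df.empty:
        raise DataValidationError(f"dataset has no {for_study} records")
    for cov in covariate_names:
        if cov not in dataset.frame.columns:
            raise DataValidationError(f"unknown covariate column {cov!r}")
        if df[cov].isna().any():
            raise DataValidationError(
                f"missing value in covariate {cov!r}; no imputation is performed"
            )
    with_trt = for_study == CURRENT
    columns = ("intercept", *covariate_names, "time") + (
        ("treatment:time",) if with_trt else ()
    )

    subjects, Xs, Zs, ys = [], [], [], []
    for subj, sub in df.groupby("subject", sort=True):
        t = sub["time"].to_numpy(float)
        m = len(t)
        cols = [np.ones(m)]
        for cov in covariate_names:
            cols.append(sub[cov].to_numpy(float))
        cols.append(t)
        if with_trt:
            trt = 1.0 if (sub["arm"] == TREATMENT).all() else 0.0
            cols.append(trt * t)
        subjects.append(subj)
        Xs.append(np.column_stack(cols))
        Zs.append(np.column_stack([np.ones(m), t]))
        ys.append(sub["y"].to_numpy(float))
    return DesignMatrices(
        subjects=subjects,
        X=Xs,
        Z=Zs,
        y=ys,
        columns=columns,
        has_treatment_column=with_trt,
    )
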