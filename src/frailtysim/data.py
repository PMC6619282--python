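"""Long-format counting-process survival data containers and delimited-text IO.

One row is one at-risk interval ``(start, stop]`` of one subject: for clustered
failures a subject contributes a single row, for recurrent events in calendar
time a subject contributes one row per inter-event interval plus a final
censored interval.  Clusters group subjects (clustered data) or episodes of one
subject (recurrent data).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["SurvRecord", "SurvData", "read_csv", "write_csv"]


@dataclass(frozen=True)
class SurvRecord:
    """A single counting-process row."""

    cluster_id: int
    subject_id: int
    start: float
    stop: float
    status: int
    x: float
    true_frailty: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.start < self.stop:
            raise ValueError(
                f"require 0 <= start < stop, got ({self.start}, {self.stop})"
            )
        if self.status not in (0, 1):
            raise ValueError(f"status must be 0 or 1, got {self.status}")


@dataclass
class SurvData:
    """Column-oriented view of a set of :class:`SurvRecord` rows.

    ``X`` is an ``(n_rows, p)`` covariate matrix; ``covariates`` names its
    columns.  ``true_frailty`` is retained from simulation for diagnostics and
    is never used by estimators.
    """

    cluster: np.ndarray
    subject: np.ndarray
    start: np.ndarray
    stop: np.ndarray
    status: np.ndarray
    X: np.ndarray
    covariates: list[str] = field(default_factory=lambda: ["x"])
    true_frailty: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cluster = np.asarray(self.cluster)
        self.subject = np.asarray(self.subject)
        self.start = np.asarray(self.start, dtype=float)
        self.stop = np.asarray(self.stop, dtype=float)
        self.status = np.asarray(self.status, dtype=int)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[0] != self.start.shape[0] and self.X.shape[1] == self.start.shape[0]:
            self.X = self.X.T
        if self.X.size == 0:
            self.X = self.X.reshape(len(self.start), 0)
        if np.any(self.start < 0) or np.any(self.stop <= self.start):
            raise ValueError("rows must satisfy 0 <= start < stop")
        if self.X.shape != (len(self.start), len(self.covariates)):
            raise ValueError("covariate matrix shape does not match names")

    def __len__(self) -> int:
        return len(self.start)

    @property
    def n_events(self) -> int:
        return int(self.status.sum())

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.cluster))

    # -- conversions -------------------------------------------------------
    @classmethod
    def from_records(cls, records: Iterable[SurvRecord]) -> "SurvData":
        rows = list(records)
        if not rows:
            raise ValueError("empty record list")
        frail = None
        if rows[0].true_frailty is not None:
            frail = np.array([r.true_frailty for r in rows], dtype=float)
        return cls(
            cluster=np.array([r.cluster_id for r in rows]),
            subject=np.array([r.subject_id for r in rows]),
            start=np.array([r.start for r in rows]),
            stop=np.array([r.stop for r in rows]),
            status=np.array([r.status for r in rows]),
            X=np.array([[r.x] for r in rows]),
            covariates=["x"],
            true_frailty=frail,
        )

    def to_records(self) -> list[SurvRecord]:
        if self.X.shape[1] != 1:
            raise ValueError("record view only defined for a single covariate")
        frail = self.true_frailty
        return [
            SurvRecord(
                cluster_id=self.cluster[i],
                subject_id=self.subject[i],
                start=float(self.start[i]),
                stop=float(self.stop[i]),
                status=int(self.status[i]),
                x=float(self.X[i, 0]),
                true_frailty=None if frail is None else float(frail[i]),
            )
            for i in range(len(self))
        ]

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, covariates: Sequence[str] | None = None
    ) -> "SurvData":
        required = {"cluster_id", "subject_id", "start", "stop", "status"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(
                "long-format data needs columns cluster_id, subject_id, start, "
                f"stop, status (+ covariates); missing {sorted(missing)}"
            )
        if covariates is None:
            reserved = required | {"true_frailty"}
            covariates = [c for c in df.columns if c not in reserved]
        frail = (
            df["true_frailty"].to_numpy(float) if "true_frailty" in df.columns else None
        )
        return cls(
            cluster=df["cluster_id"].to_numpy(),
            subject=df["subject_id"].to_numpy(),
            start=df["start"].to_numpy(float),
            stop=df["stop"].to_numpy(float),
            status=df["status"].to_numpy(int),
            X=df[list(covariates)].to_numpy(float),
            covariates=list(covariates),
            true_frailty=frail,
        )

    def to_frame(self, include_frailty: bool = True) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "cluster_id": self.cluster,
                "subject_id": self.subject,
                "start": self.start,
                "stop": self.stop,
                "status": self.status,
            }
        )
        for j, name in enumerate(self.covariates):
            df[name] = self.X[:, j]
        if include_frailty and self.true_frailty is not None:
            df["true_frailty"] = self.true_frailty
        return df


def read_csv(path, covariates: Sequence[str] | None = None) -> SurvData:
    """Read long-format survival data from a delimited text file."""
    return SurvData.from_frame(pd.read_csv(path), covariates=covariates)


def write_csv(data: SurvData, path, include_frailty: bool = True) -> None:
    data.to_frame(include_frailty=include_frailty).to_csv(path, index=False)
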