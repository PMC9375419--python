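"""Core data model for two-arm cluster-randomised trial (CRT) data with a
binary outcome, plus readers/writers for delimited text formats.

A trial is held in cluster-aggregated form: because the only covariate in
the supported analyses is the cluster-constant arm indicator, every
estimator depends on the data only through ``(arm, events, size)`` per
cluster, so the aggregated representation is sufficient. Individual-level
files are aggregated on read.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataConsistencyError, DataFormatError, DesignError, ValidationError

__all__ = [
    "ClusterRecord",
    "TrialDataset",
    "read_individual",
    "read_aggregated",
    "write_aggregated",
]


@dataclass(frozen=True)
class ClusterRecord:
    """One cluster: arm assignment, event count and cluster size.

    ``arm`` is 0 for control and 1 for intervention. ``events`` counts
    individuals with the outcome among the ``size`` individuals observed
    in the cluster.
    """

    cluster_id: str
    arm: int
    events: int
    size: int

    def __post_init__(self) -> None:
        if self.arm not in (0, 1):
            raise ValidationError(f"arm must be 0 or 1, got {self.arm!r}")
        if self.size < 1:
            raise ValidationError(
                f"cluster {self.cluster_id!r}: size must be >= 1, got {self.size}"
            )
        if not 0 <= self.events <= self.size:
            raise ValidationError(
                f"cluster {self.cluster_id!r}: events must lie in [0, size], "
                f"got events={self.events}, size={self.size}"
            )


@dataclass(frozen=True)
class TrialDataset:
    """An ordered collection of :class:`ClusterRecord` forming one trial."""

    records: tuple[ClusterRecord, ...]

    def __post_init__(self) -> None:
        ids = [r.cluster_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DataConsistencyError(f"duplicate cluster ids: {dupes}")

    @classmethod
    def from_records(cls, records: Iterable[ClusterRecord]) -> "TrialDataset":
        return cls(tuple(records))

    @classmethod
    def from_arrays(
        cls,
        arm: Sequence[int],
        events: Sequence[int],
        size: Sequence[int],
        cluster_ids: Sequence[str] | None = None,
    ) -> "TrialDataset":
        arm = list(arm)
        if cluster_ids is None:
            cluster_ids = [f"c{i + 1}" for i in range(len(arm))]
        recs = [
            ClusterRecord(str(c), int(a), int(e), int(m))
            for c, a, e, m in zip(cluster_ids, arm, events, size, strict=True)
        ]
        return cls.from_records(recs)

    @property
    def n(self) -> int:
        """Total number of clusters."""
        return len(self.records)

    def __len__(self) -> int:
        return self.n

    @property
    def arm(self) -> np.ndarray:
        return np.array([r.arm for r in self.records], dtype=np.int64)

    @property
    def events(self) -> np.ndarray:
        return np.array([r.events for r in self.records], dtype=np.int64)

    @property
    def size(self) -> np.ndarray:
        return np.array([r.size for r in self.records], dtype=np.int64)

    @property
    def cluster_ids(self) -> list[str]:
        return [r.cluster_id for r in self.records]

    def clusters_per_arm(self) -> tuple[int, int]:
        arm = self.arm
        return int(np.sum(arm == 0)), int(np.sum(arm == 1))

    def require_two_arms(self, min_per_arm: int = 1) -> None:
        """Raise :class:`DesignError` unless both arms have at least
        ``min_per_arm`` clusters."""
        n0, n1 = self.clusters_per_arm()
        if n0 < min_per_arm or n1 < min_per_arm:
            raise DesignError(
                f"analysis requires >= {min_per_arm} cluster(s) per arm; "
                f"got {n0} control and {n1} intervention"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cluster": self.cluster_ids,
                "arm": self.arm,
                "events": self.events,
                "size": self.size,
            }
        )


def _map_arms(raw: pd.Series, control: str | None) -> pd.Series:
    """Map two arbitrary arm labels onto {0, 1}.

    ``control`` selects the label coded as 0; by default the
    lexicographically smaller label is control.
    """
    labels = sorted(raw.astype(str).unique())
    if len(labels) > 2:
        raise DataFormatError(f"more than two arm labels found: {labels}")
    if control is None:
        control = labels[0]
    else:
        control = str(control)
        if control not in labels:
            raise DataFormatError(
                f"control label {control!r} not present in arm column (labels: {labels})"
            )
    return raw.astype(str).map(lambda x: 0 if x == control else 1)


def _read_table(path, sep: str) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep=sep, dtype=str, skipinitialspace=True)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise DataFormatError(f"cannot parse {path}: {exc}") from exc


def read_individual(
    path, *, sep: str = ",", control: str | None = None
) -> TrialDataset:
    """Read individual-level rows ``cluster,arm,outcome`` and aggregate.

    ``outcome`` must be 0/1; the arm label must be constant within each
    cluster (clusters are randomised whole). Row order is irrelevant;
    clusters appear in order of first appearance.
    """
    df = _read_table(path, sep)
    required = {"cluster", "arm", "outcome"}
    if not required.issubset(df.columns):
        raise DataFormatError(
            f"individual-level file must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    if df.empty:
        return TrialDataset(())
    outcome = pd.to_numeric(df["outcome"], errors="coerce")
    if not outcome.isin([0, 1]).all():
        bad = df["outcome"][~outcome.isin([0, 1])].iloc[0]
        raise DataFormatError(f"outcome must be 0 or 1, got {bad!r}")
    df = df.assign(outcome=outcome.astype(int))

    arms_per_cluster = df.groupby("cluster", sort=False)["arm"].nunique()
    if (arms_per_cluster > 1).any():
        bad = arms_per_cluster[arms_per_cluster > 1].index.tolist()
        raise DataConsistencyError(
            f"arm varies within cluster(s) {bad}: CRTs randomise whole clusters"
        )
    df["arm01"] = _map_arms(df["arm"], control)
    grouped = df.groupby("cluster", sort=False).agg(
        arm=("arm01", "first"), events=("outcome", "sum"), size=("outcome", "count")
    )
    records = [
        ClusterRecord(str(cid), int(row["arm"]), int(row["events"]), int(row["size"]))
        for cid, row in grouped.iterrows()
    ]
    return TrialDataset.from_records(records)


def read_aggregated(
    path, *, sep: str = ",", control: str | None = None
) -> TrialDataset:
    """Read cluster-aggregated rows ``cluster,arm,events,size``."""
    df = _read_table(path, sep)
    required = {"cluster", "arm", "events", "size"}
    if not required.issubset(df.columns):
        raise DataFormatError(
            f"aggregated file must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    if df.empty:
        return TrialDataset(())
    for col in ("events", "size"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() or (vals != vals.round()).any():
            raise DataFormatError(f"column {col!r} must contain integers")
        df[col] = vals.astype(int)
    df["arm01"] = _map_arms(df["arm"], control)
    records = [
        ClusterRecord(str(r.cluster), int(r.arm01), int(r.events), int(r.size))
        for r in df.itertuples(index=False)
    ]
    return TrialDataset.from_records(records)


def write_aggregated(data: TrialDataset, path, *, sep: str = ",") -> None:
    """Write the aggregated format (columns ``cluster,arm,events,size``)."""
    data.to_frame().to_csv(path, sep=sep, index=False)
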