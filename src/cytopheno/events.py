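"""Per-cell event tables.

The central container is :class:`EventTable`: a dense cells x markers matrix
of antibody intensities (usually on the arcsinh scale) together with
per-cell annotations — subject, clinical group, tissue compartment
(blood vs lymph node) and, for synthetic cohorts, the latent population
each cell was drawn from.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["EventTable"]

ANNOTATION_COLUMNS = ("subject_id", "group", "compartment", "truth_population")


@dataclass
class EventTable:
    """Cells x markers intensity matrix with per-cell annotations.

    Parameters
    ----------
    values
        Real matrix of shape (n_cells, n_markers); no missing values.
    markers
        Ordered marker (channel) names, one per column.
    subject_id, group, compartment
        Per-cell annotation arrays of length n_cells. ``compartment`` is
        conventionally ``"blood"`` or ``"LN"``.
    truth_population
        Latent population label per cell; only present for synthetic data.
    """

    values: np.ndarray
    markers: list[str]
    subject_id: np.ndarray
    group: np.ndarray
    compartment: np.ndarray
    truth_population: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D cells x markers matrix")
        if self.values.shape[1] != len(self.markers):
            raise ValueError(
                f"values has {self.values.shape[1]} columns but "
                f"{len(self.markers)} marker names were given"
            )
        if np.isnan(self.values).any():
            raise ValueError("values must not contain missing entries")
        n = self.values.shape[0]
        for name in ANNOTATION_COLUMNS:
            arr = getattr(self, name)
            if arr is None:
                continue
            arr = np.asarray(arr)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one entry per cell")
            setattr(self, name, arr)
        self._check_subject_group_consistency()

    def _check_subject_group_consistency(self) -> None:
        df = pd.DataFrame({"s": self.subject_id, "g": self.group})
        per_subject = df.groupby("s", sort=False)["g"].nunique()
        bad = per_subject[per_subject > 1]
        if len(bad):
            raise ValueError(
                f"subjects mapped to more than one group: {list(bad.index)}"
            )

    # -- basic views ---------------------------------------------------

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def marker_index(self, marker: str) -> int:
        try:
            return self.markers.index(marker)
        except ValueError:
            raise KeyError(f"marker {marker!r} not in table") from None

    def marker_values(self, marker: str) -> np.ndarray:
        return self.values[:, self.marker_index(marker)]

    @property
    def subjects(self) -> list:
        """Subject ids in order of first appearance."""
        return list(pd.unique(self.subject_id))

    def take(self, index: np.ndarray) -> "EventTable":
        """Row-subset (or reorder) the table by cell index."""
        index = np.asarray(index)
        return replace(
            self,
            values=self.values[index],
            subject_id=self.subject_id[index],
            group=self.group[index],
            compartment=self.compartment[index],
            truth_population=(
                None if self.truth_population is None else self.truth_population[index]
            ),
        )

    # -- conversion ----------------------------------------------------

    def to_dataframe(self, include_truth: bool = True) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.markers)
        df["subject_id"] = self.subject_id
        df["group"] = self.group
        df["compartment"] = self.compartment
        if include_truth and self.truth_population is not None:
            df["truth_population"] = self.truth_population
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, markers: list[str] | None = None) -> "EventTable":
        if markers is None:
            markers = [c for c in df.columns if c not in ANNOTATION_COLUMNS]
        truth = None
        if "truth_population" in df.columns:
            truth = df["truth_population"].to_numpy()
        return cls(
            values=df[markers].to_numpy(dtype=float),
            markers=list(markers),
            subject_id=df["subject_id"].to_numpy(),
            group=df["group"].to_numpy(),
            compartment=df["compartment"].to_numpy(),
            truth_population=truth,
        )


def concat_tables(tables: list[EventTable]) -> EventTable:
    """Stack event tables that share the same marker panel."""
    if not tables:
        raise ValueError("no tables to concatenate")
    markers = tables[0].markers
    for t in tables[1:]:
        if t.markers != markers:
            raise ValueError("tables have differing marker panels")
    truth = None
    if all(t.truth_population is not None for t in tables):
        truth = np.concatenate([t.truth_population for t in tables])
    return EventTable(
        values=np.vstack([t.values for t in tables]),
        markers=list(markers),
        subject_id=np.concatenate([t.subject_id for t in tables]),
        group=np.concatenate([t.group for t in tables]),
        compartment=np.concatenate([t.compartment for t in tables]),
        truth_population=truth,
    )
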