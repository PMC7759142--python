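"""Response containers for the moral process-dissociation procedure (PDP).

The universal input is a binary response matrix over matched dilemma pairs:
each dilemma exists in a *congruent* (C) version, where both utilitarian and
deontological reasoning reject the harmful action, and an *incongruent* (IC)
version, where a utilitarian justification exists but a deontological norm
forbids the act.  A response of 1 means the participant judged the harm
unacceptable; 0 means acceptable.

CSV layout: a header row ``id,C_<label>,...,IC_<label>,...`` with the C
columns first and the IC columns following in the same pair order, one
participant per row.  A Likert matrix for the high-conflict moral dilemma
(HCMD) battery uses integer cells in 1..7 (7 = totally acceptable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["ResponseMatrix", "LikertMatrix"]


def _as_binary(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2-dimensional, got shape {arr.shape}")
    bad = ~np.isin(arr, (0.0, 1.0))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"{name} contains a non-binary entry {arr[r, c]!r} at row {r}, column {c}"
        )
    return arr.astype(np.int8)


@dataclass(frozen=True)
class ResponseMatrix:
    """Participants x matched C/IC binary dilemma responses (1 = unacceptable)."""

    c_items: np.ndarray
    ic_items: np.ndarray
    pair_labels: tuple[str, ...]
    participant_ids: tuple[str, ...] = field(default=())

    def __post_init__(self):
        c = _as_binary(self.c_items, "c_items")
        ic = _as_binary(self.ic_items, "ic_items")
        if c.shape != ic.shape:
            raise ValueError(
                f"c_items {c.shape} and ic_items {ic.shape} must have identical shape"
            )
        n, k = c.shape
        if n < 1:
            raise ValueError("response matrix must contain at least one participant")
        if k < 2:
            raise ValueError("at least two dilemma pairs are required")
        labels = tuple(str(x) for x in self.pair_labels)
        if len(labels) != k:
            raise ValueError(f"expected {k} pair labels, got {len(labels)}")
        ids = tuple(str(x) for x in self.participant_ids) or tuple(
            f"p{i + 1}" for i in range(n)
        )
        if len(ids) != n:
            raise ValueError(f"expected {n} participant ids, got {len(ids)}")
        object.__setattr__(self, "c_items", c)
        object.__setattr__(self, "ic_items", ic)
        object.__setattr__(self, "pair_labels", labels)
        object.__setattr__(self, "participant_ids", ids)

    @property
    def n_participants(self) -> int:
        return self.c_items.shape[0]

    @property
    def n_pairs(self) -> int:
        return self.c_items.shape[1]

    def item_frame(self) -> pd.DataFrame:
        """All 2k items as one DataFrame, C columns first."""
        cols = [f"C_{p}" for p in self.pair_labels] + [
            f"IC_{p}" for p in self.pair_labels
        ]
        return pd.DataFrame(
            np.hstack([self.c_items, self.ic_items]),
            index=pd.Index(self.participant_ids, name="id"),
            columns=cols,
        )

    def to_csv(self, path) -> None:
        self.item_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "ResponseMatrix":
        """Read ``id,C_*,...,IC_*`` CSV; rows with missing cells are dropped
        listwise (the scoring procedures assume complete rows) with a logged
        count."""
        df = pd.read_csv(path, index_col=0)
        c_cols = [c for c in df.columns if c.startswith("C_")]
        ic_cols = [c for c in df.columns if c.startswith("IC_")]
        if not c_cols or not ic_cols:
            raise ValueError("CSV must contain C_<label> and IC_<label> columns")
        labels = [c[2:] for c in c_cols]
        if [c[3:] for c in ic_cols] != labels:
            raise ValueError("C and IC column labels are not pair-aligned")
        complete = df[c_cols + ic_cols].notna().all(axis=1)
        n_dropped = int((~complete).sum())
        if n_dropped:
            logger.warning("dropped %d participants with missing responses", n_dropped)
        df = df.loc[complete]
        return cls(
            c_items=df[c_cols].to_numpy(),
            ic_items=df[ic_cols].to_numpy(),
            pair_labels=tuple(labels),
            participant_ids=tuple(map(str, df.index)),
        )

    def select_pairs(self, idx) -> "ResponseMatrix":
        """Sub-matrix restricted to the given pair indices (order preserved)."""
        idx = list(idx)
        return ResponseMatrix(
            c_items=self.c_items[:, idx],
            ic_items=self.ic_items[:, idx],
            pair_labels=tuple(self.pair_labels[i] for i in idx),
            participant_ids=self.participant_ids,
        )


@dataclass(frozen=True)
class LikertMatrix:
    """Participants x items, integer acceptability ratings in 1..7."""

    values: np.ndarray
    item_labels: tuple[str, ...] = field(default=())
    participant_ids: tuple[str, ...] = field(default=())

    def __post_init__(self):
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2:
            raise ValueError(f"values must be 2-dimensional, got shape {arr.shape}")
        if not np.isin(arr, np.arange(1.0, 8.0)).all():
            raise ValueError("Likert entries must be integers in 1..7")
        n, m = arr.shape
        if n < 1 or m < 1:
            raise ValueError("Likert matrix must be non-empty")
        labels = tuple(str(x) for x in self.item_labels) or tuple(
            f"hcmd{i + 1}" for i in range(m)
        )
        if len(labels) != m:
            raise ValueError(f"expected {m} item labels, got {len(labels)}")
        ids = tuple(str(x) for x in self.participant_ids) or tuple(
            f"p{i + 1}" for i in range(n)
        )
        if len(ids) != n:
            raise ValueError(f"expected {n} participant ids, got {len(ids)}")
        object.__setattr__(self, "values", arr.astype(np.int8))
        object.__setattr__(self, "item_labels", labels)
        object.__setattr__(self, "participant_ids", ids)

    @property
    def n_participants(self) -> int:
        return self.values.shape[0]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.participant_ids, name="id"),
            columns=self.item_labels,
        )

    def to_csv(self, path) -> None:
        self.frame().to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "LikertMatrix":
        df = pd.read_csv(path, index_col=0)
        complete = df.notna().all(axis=1)
        n_dropped = int((~complete).sum())
        if n_dropped:
            logger.warning("dropped %d participants with missing ratings", n_dropped)
        df = df.loc[complete]
        return cls(
            values=df.to_numpy(),
            item_labels=tuple(df.columns),
            participant_ids=tuple(map(str, df.index)),
        )
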