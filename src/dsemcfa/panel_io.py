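"""Long-format intensive-longitudinal item panels: read, validate, write.

A panel is a long table with one row per (person, session): a person id
column, an integer session index, K item-response columns (0-3 scale,
treated as continuous), and optional person-constant covariate columns.
Missing item responses are stored as NaN.  Persons contributing fewer than
two retained sessions are dropped (a lag-1 dynamic model needs at least
two occasions) and recorded in the validation report.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

PERSON_COL = "person_id"
SESSION_COL = "session"


class PanelSchemaError(ValueError):
    """A declared column is absent or malformed."""


class PanelParseError(ValueError):
    """A response cell could not be interpreted as a number."""


class EmptyPanelError(ValueError):
    """No rows survive validation."""


@dataclasses.dataclass(frozen=True)
class ValidationReport:
    """Summary of a validated panel.

    ``series_length_summary`` holds mean/sd/min/max of retained per-person
    series lengths; ``missing_rate_per_item`` the per-item proportion of
    missing cells among retained rows; ``dropped_persons`` the ids removed
    with the reason for removal.
    """

    n_persons: int
    n_rows: int
    series_length_summary: dict[str, float]
    missing_rate_per_item: dict[str, float]
    dropped_persons: list[tuple[str, str]]


@dataclasses.dataclass
class PanelDataset:
    """Validated long-format item panel.

    ``frame`` is sorted by (person, session); sessions are strictly
    increasing integers within person, covariates are person-constant, and
    every retained row has at least one non-missing item response.
    """

    frame: pd.DataFrame
    item_ids: list[str]
    covariate_ids: list[str]
    dropped_persons: list[tuple[str, str]] = dataclasses.field(default_factory=list)

    @property
    def person_ids(self) -> list:
        return list(self.frame[PERSON_COL].unique())

    @property
    def n_persons(self) -> int:
        return self.frame[PERSON_COL].nunique()

    def series_lengths(self) -> np.ndarray:
        return self.frame.groupby(PERSON_COL, sort=False).size().to_numpy()

    def to_arrays(self) -> "PanelArrays":
        """Pack the panel into dense (person, occasion, item) arrays.

        Sessions are compressed to consecutive observed occasions; persons
        are padded to the longest series with an observation mask.
        """
        persons = self.person_ids
        lengths = self.series_lengths()
        n, t_max, k = len(persons), int(lengths.max()), len(self.item_ids)
        y = np.full((n, t_max, k), np.nan)
        resp = self.frame[self.item_ids].to_numpy(dtype=float)
        row = 0
        for i, t_i in enumerate(lengths):
            y[i, :t_i, :] = resp[row : row + t_i]
            row += t_i
        covariates = np.empty((n, len(self.covariate_ids)))
        if self.covariate_ids:
            covariates = (
                self.frame.groupby(PERSON_COL, sort=False)[self.covariate_ids].first().to_numpy(dtype=float)
            )
        return PanelArrays(
            person_ids=list(persons),
            item_ids=list(self.item_ids),
            covariate_ids=list(self.covariate_ids),
            y=y,
            mask=~np.isnan(y),
            lengths=lengths.astype(int),
            covariates=covariates,
        )


@dataclasses.dataclass
class PanelArrays:
    """Dense padded view of a panel used by the likelihood and sampler."""

    person_ids: list
    item_ids: list[str]
    covariate_ids: list[str]
    y: np.ndarray  # (n, t_max, k), NaN where unobserved
    mask: np.ndarray  # (n, t_max, k) boolean
    lengths: np.ndarray  # (n,) observed occasions per person
    covariates: np.ndarray  # (n, p)

    @property
    def occasion_mask(self) -> np.ndarray:
        """(n, t_max) True where the occasion exists for the person."""
        t_max = self.y.shape[1]
        return np.arange(t_max)[None, :] < self.lengths[:, None]


def _clean(frame: pd.DataFrame, item_ids: Sequence[str], covariate_ids: Sequence[str]) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    frame = frame.sort_values([PERSON_COL, SESSION_COL], kind="stable").reset_index(drop=True)
    dropped: list[tuple[str, str]] = []

    all_missing = frame[list(item_ids)].isna().all(axis=1)
    frame = frame[~all_missing]

    for pid, grp in frame.groupby(PERSON_COL, sort=False):
        sess = grp[SESSION_COL].to_numpy()
        if not np.all(np.diff(sess) > 0):
            raise PanelSchemaError(f"sessions for person {pid!r} are not strictly increasing: {sess.tolist()}")
        for cov in covariate_ids:
            vals = grp[cov].dropna().unique()
            if len(vals) > 1:
                raise PanelSchemaError(f"covariate {cov!r} varies within person {pid!r}")

    counts = frame.groupby(PERSON_COL, sort=False).size()
    short = counts[counts < 2].index
    for pid in short:
        dropped.append((pid, "fewer than 2 sessions"))
    frame = frame[~frame[PERSON_COL].isin(set(short))].reset_index(drop=True)
    return frame, dropped


def load_panel(path: str | Path, item_ids: Sequence[str], covariate_ids: Sequence[str] = ()) -> PanelDataset:
    """Read and validate a long-format CSV panel.

    Persons with fewer than two retained sessions are dropped and recorded
    on the returned dataset.  Raises :class:`PanelSchemaError` for missing
    columns and :class:`PanelParseError` for non-numeric responses.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    needed = [PERSON_COL, SESSION_COL, *item_ids, *covariate_ids]
    missing_cols = [c for c in needed if c not in frame.columns]
    if missing_cols:
        raise PanelSchemaError(f"missing columns: {missing_cols}")
    frame[PERSON_COL] = frame[PERSON_COL].astype(str)
    for col in (SESSION_COL, *item_ids, *covariate_ids):
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            raise PanelParseError(f"non-numeric value in column {col!r} at row {int(bad.idxmax())}")
        frame[col] = coerced
    frame = frame[needed]
    frame, dropped = _clean(frame, item_ids, covariate_ids)
    if frame.empty:
        raise EmptyPanelError("no persons with >= 2 sessions")
    return PanelDataset(frame=frame, item_ids=list(item_ids), covariate_ids=list(covariate_ids), dropped_persons=dropped)


def write_panel(data: PanelDataset, path: str | Path) -> None:
    """Write a panel to CSV at full float precision (round-trips exactly)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # repr-precision floats so load_panel(write_panel(d)) is the identity
    data.frame.to_csv(path, index=False, float_format=lambda v: repr(float(v)))


def validate_panel(data: PanelDataset) -> ValidationReport:
    """Summarize a validated panel (retained persons only)."""
    if data.frame.empty:
        raise EmptyPanelError("empty panel")
    lengths = data.series_lengths()
    summary = {
        "mean": float(lengths.mean()),
        "sd": float(lengths.std(ddof=1)) if len(lengths) > 1 else 0.0,
        "min": float(lengths.min()),
        "max": float(lengths.max()),
    }
    missing = {k: float(data.frame[k].isna().mean()) for k in data.item_ids}
    return ValidationReport(
        n_persons=int(data.n_persons),
        n_rows=int(len(data.frame)),
        series_length_summary=summary,
        missing_rate_per_item=missing,
        dropped_persons=list(data.dropped_persons),
    )


def load_config(path: str | Path) -> dict:
    """Load a YAML run configuration (items, anchor, covariates, MCMC)."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise PanelSchemaError("config must be a YAML mapping")
    return cfg
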