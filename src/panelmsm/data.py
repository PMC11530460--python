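"""Panel dataset containers and long-format CSV input/output.

The on-disk schema is one row per subject per observation:
``subject_id, time_years, age, state`` plus one column per covariate and an
optional ``exact_death`` flag (1 on a death row whose time is the exact
death time rather than an interview date).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .structures import CovariateSpec

CORE_COLUMNS = ("subject_id", "time_years", "age", "state")


@dataclass
class SubjectRecord:
    """One subject's observation sequence.

    ``baseline_age`` is the age at the first observation; the age at time
    ``t`` is ``baseline_age + (t - times[0])``. ``death_exact`` marks the
    final observation, if it is the absorbing state, as an exactly observed
    event time.
    """

    subject_id: str
    times: np.ndarray
    states: np.ndarray
    covariates: dict
    baseline_age: float
    death_exact: bool = False

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=int)
        if self.times.shape != self.states.shape:
            raise ValueError(f"subject {self.subject_id}: times/states length mismatch")
        if len(self.times) == 0:
            raise ValueError(f"subject {self.subject_id}: no observations")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"subject {self.subject_id}: times must be strictly increasing")

    @property
    def n_obs(self) -> int:
        return len(self.times)

    def age_at(self, t: float) -> float:
        return self.baseline_age + (t - self.times[0])


@dataclass
class PanelDataset:
    """Collection of subject records sharing one covariate vocabulary."""

    records: list
    spec: CovariateSpec = None

    def __post_init__(self):
        seen = set()
        for rec in self.records:
            key = rec.subject_id
            if key in seen:
                raise ValueError(f"duplicate subject id {key!r}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_observations(self) -> int:
        return sum(r.n_obs for r in self.records)

    def validate_states(self, n_states: int, absorbing: Iterable) -> None:
        absorbing = tuple(absorbing)
        for rec in self.records:
            if rec.states.min() < 1 or rec.states.max() > n_states:
                raise ValueError(f"subject {rec.subject_id}: state outside 1..{n_states}")
            for k, s in enumerate(rec.states):
                if absorbing[s - 1] and k != rec.n_obs - 1:
                    raise ValueError(
                        f"subject {rec.subject_id}: absorbing state {s} is not final"
                    )

    def to_frame(self) -> pd.DataFrame:
        covnames = self.spec.names if self.spec is not None else sorted(
            {k for r in self.records for k in r.covariates}
        )
        rows = []
        for rec in self.records:
            for k, (t, s) in enumerate(zip(rec.times, rec.states)):
                row = {
                    "subject_id": rec.subject_id,
                    "time_years": float(t),
                    "age": rec.age_at(t),
                    "state": int(s),
                    "exact_death": int(
                        rec.death_exact and k == rec.n_obs - 1 and s == rec.states[-1]
                    )
                    if rec.death_exact and k == rec.n_obs - 1
                    else 0,
                }
                for c in covnames:
                    row[c] = rec.covariates.get(c)
                rows.append(row)
        return pd.DataFrame(rows)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, spec: CovariateSpec = None) -> "PanelDataset":
        missing = [c for c in CORE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")
        covnames = (
            list(spec.names)
            if spec is not None
            else [c for c in df.columns if c not in CORE_COLUMNS + ("exact_death",)]
        )
        for c in covnames:
            if c not in df.columns:
                raise ValueError(f"missing covariate column {c!r}")
        records = []
        for sid, grp in df.groupby("subject_id", sort=False):
            grp = grp.sort_values("time_years")
            if grp["time_years"].duplicated().any():
                raise ValueError(f"duplicate (subject, time) rows for subject {sid!r}")
            death_exact = False
            if "exact_death" in grp.columns:
                death_exact = bool(grp["exact_death"].iloc[-1])
            records.append(
                SubjectRecord(
                    subject_id=str(sid),
                    times=grp["time_years"].to_numpy(),
                    states=grp["state"].to_numpy(),
                    covariates={c: grp[c].iloc[0] for c in covnames},
                    baseline_age=float(grp["age"].iloc[0]),
                    death_exact=death_exact,
                )
            )
        return cls(records=records, spec=spec)

    @classmethod
    def read_csv(cls, path, spec: CovariateSpec = None) -> "PanelDataset":
        return cls.from_frame(pd.read_csv(path), spec=spec)
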