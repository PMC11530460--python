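"""Synthetic cohort generation: baseline sampling, exact continuous-time
trajectories (Gillespie), and degradation to panel observations.

The default configuration mirrors a large ageing panel study: six roughly
biennial waves, baseline age 67 (SD 9.5, truncated at 50), and realistic
baseline socioeconomic marginals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .data import PanelDataset, SubjectRecord
from .intensity import IntensityModel

#: Baseline covariate marginals of the default cohort (probabilities per level).
DEFAULT_MARGINALS = {
    "sex": {"male": 0.4426, "female": 0.5574},
    "marital": {"married": 0.6530, "single": 0.3470},
    "education": {"low": 0.2781, "middle": 0.5411, "high": 0.1807},
    "occupation": {"manual": 0.3102, "intermediate": 0.3524, "professional": 0.3373},
    "wealth": {"low": 0.3280, "middle": 0.3374, "high": 0.3345},
}


@dataclass
class CohortConfig:
    """Configuration of the synthetic cohort generator."""

    n_subjects: int = 8442
    wave_times: tuple = (0.0, 2.0, 4.0, 6.0, 8.0, 10.0)
    covariate_distribution: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MARGINALS.items()}
    )
    age_mean: float = 67.0
    age_sd: float = 9.5
    age_min: float = 50.0
    initial_state_probs: tuple = (0.75, 0.23, 0.02)
    dropout_per_wave: float = 0.05
    wave_jitter: float = 0.0
    seed: int = 0
    #: optional hook replacing independent marginal sampling; called as
    #: ``joint_sampler(rng, n) -> DataFrame`` with one column per covariate.
    joint_sampler: Optional[Callable] = None

    def __post_init__(self):
        wt = tuple(float(t) for t in self.wave_times)
        if wt[0] != 0.0 or any(b <= a for a, b in zip(wt, wt[1:])):
            raise ValueError("wave_times must start at 0 and be strictly increasing")
        self.wave_times = wt
        for name, probs in self.covariate_distribution.items():
            p = np.array(list(probs.values()), dtype=float)
            if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-3):
                raise ValueError(f"probabilities for {name!r} must be >= 0 and sum to 1")
        p0 = np.asarray(self.initial_state_probs, dtype=float)
        if np.any(p0 < 0) or not np.isclose(p0.sum(), 1.0, atol=1e-6):
            raise ValueError("initial_state_probs must be a probability vector")


@dataclass
class ExactPath:
    """One subject's exact continuous-time trajectory: state
    ``visited_states[k]`` is entered at ``jump_times[k]``."""

    subject_id: str
    jump_times: np.ndarray
    visited_states: np.ndarray
    absorbed: bool

    def state_at(self, t: float) -> int:
        k = int(np.searchsorted(self.jump_times, t + 1e-12) - 1)
        return int(self.visited_states[max(k, 0)])


def generate_cohort(config: CohortConfig, seed: Optional[int] = None) -> pd.DataFrame:
    """Sample baseline covariates, ages, and initial states.

    Covariates are drawn independently from the configured marginals unless
    ``config.joint_sampler`` is given. Reproducible for a fixed seed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_subjects
    width = max(len(str(max(n, 1))), 4)
    df = pd.DataFrame({"subject_id": [f"S{i + 1:0{width}d}" for i in range(n)]})
    if config.joint_sampler is not None:
        cov = config.joint_sampler(rng, n)
        for c in cov.columns:
            df[c] = cov[c].to_numpy()
    else:
        for name, probs in config.covariate_distribution.items():
            levels = list(probs)
            p = np.array([probs[lv] for lv in levels], dtype=float)
            df[name] = rng.choice(levels, size=n, p=p / p.sum())
    a = (config.age_min - config.age_mean) / config.age_sd
    df["age"] = scipy.stats.truncnorm.rvs(
        a, np.inf, loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng
    )
    p0 = np.asarray(config.initial_state_probs, dtype=float)
    df["state"] = rng.choice(np.arange(1, len(p0) + 1), size=n, p=p0 / p0.sum())
    return df


def simulate_paths(
    model: IntensityModel,
    cohort: pd.DataFrame,
    horizon: float,
    seed: int = 0,
) -> list:
    """Exact trajectories by the Gillespie scheme under piecewise-constant
    (age-band) intensities.

    Holding times are exponential with rate ``-q_rr`` for the band in
    force; draws crossing a band boundary are discarded and redrawn from
    the boundary (valid by memorylessness). Zero total outflow means the
    subject stays put.
    """
    rng = np.random.default_rng(seed)
    spec = model.spec
    cuts = spec.age_bands
    n_states = model.structure.n_states
    covnames = list(spec.names)
    qcache: dict = {}
    paths = []
    for row in cohort.itertuples(index=False):
        rowd = row._asdict()
        key = tuple(rowd[c] for c in covnames)
        if key not in qcache:
            z = spec.encode({c: rowd[c] for c in covnames})
            qcache[key] = [
                model.generator_at_band(z, b) for b in range(spec.n_bands)
            ]
        Qs = qcache[key]
        age0 = float(rowd["age"])
        state = int(rowd["state"])
        t = 0.0
        times = [0.0]
        states = [state]
        absorbed = model.structure.is_absorbing(state)
        while not absorbed and t < horizon:
            band = int(np.searchsorted(cuts, age0 + t, side="right"))
            next_cut = (cuts[band] - age0) if band < len(cuts) else np.inf
            out = -Qs[band][state - 1, state - 1]
            if out <= 0:
                if next_cut >= horizon:
                    break
                t = next_cut
                continue
            dwell = rng.exponential(1.0 / out)
            if t + dwell > min(next_cut, horizon):
                t = min(next_cut, horizon)
                continue
            t += dwell
            rates = Qs[band][state - 1].copy()
            rates[state - 1] = 0.0
            state = int(rng.choice(n_states, p=rates / rates.sum())) + 1
            times.append(t)
            states.append(state)
            absorbed = model.structure.is_absorbing(state)
        paths.append(
            ExactPath(
                subject_id=str(rowd["subject_id"]),
                jump_times=np.array(times),
                visited_states=np.array(states),
                absorbed=absorbed,
            )
        )
    return paths


def observe_panel(
    paths: Sequence,
    cohort: pd.DataFrame,
    wave_times: Sequence,
    dropout_per_wave: float = 0.0,
    death_exact: bool = True,
    seed: int = 0,
    wave_jitter: float = 0.0,
) -> PanelDataset:
    """Degrade exact paths to interval-censored panel observations.

    The first wave is always attended; each later wave is missed for good
    with probability ``dropout_per_wave`` (monotone dropout). With
    ``death_exact`` the absorbing time is recorded exactly (mortality-
    register behaviour, irrespective of interview dropout); otherwise death
    is recorded at the first attended wave after it, so dropped-out
    subjects are right-censored.
    """
    rng = np.random.default_rng(seed)
    wave_times = np.asarray(wave_times, dtype=float)
    covnames = [c for c in cohort.columns if c not in ("subject_id", "age", "state")]
    by_id = {str(r.subject_id): r for r in cohort.itertuples(index=False)}
    records = []
    for path in paths:
        row = by_id[path.subject_id]
        waves = wave_times.copy()
        if wave_jitter > 0:
            waves[1:] = waves[1:] + rng.uniform(-wave_jitter, wave_jitter, len(waves) - 1)
        n_attended = 1
        while n_attended < len(waves) and rng.random() >= dropout_per_wave:
            n_attended += 1
        death_time = None
        if path.absorbed:
            death_time = float(path.jump_times[-1])
        times, states = [], []
        for w in waves[:n_attended]:
            if death_time is not None and w >= death_time:
                break
            times.append(float(w))
            states.append(path.state_at(w))
        if not times:
            continue
        is_exact = False
        if death_time is not None:
            if death_exact:
                times.append(death_time)
                states.append(int(path.visited_states[-1]))
                is_exact = True
            else:
                later = [w for w in waves[:n_attended] if w >= death_time]
                if later:
                    times.append(float(later[0]))
                    states.append(int(path.visited_states[-1]))
        records.append(
            SubjectRecord(
                subject_id=path.subject_id,
                times=np.array(times),
                states=np.array(states),
                covariates={c: getattr(row, c) for c in covnames},
                baseline_age=float(row.age),
                death_exact=is_exact,
            )
        )
    return PanelDataset(records=records)


def simulate_dataset(
    model: IntensityModel,
    config: CohortConfig,
    death_exact: bool = True,
    seed: Optional[int] = None,
) -> tuple:
    """Convenience end-to-end generator: cohort -> paths -> panel.

    Returns ``(dataset, cohort, paths)``; all randomness flows from one
    seed (``config.seed`` unless overridden).
    """
    base = config.seed if seed is None else seed
    ss = np.random.SeedSequence(base).spawn(3)
    cohort = generate_cohort(config, seed=ss[0])
    horizon = config.wave_times[-1]
    paths = simulate_paths(model, cohort, horizon, seed=ss[1])
    dataset = observe_panel(
        paths,
        cohort,
        config.wave_times,
        dropout_per_wave=config.dropout_per_wave,
        death_exact=death_exact,
        seed=ss[2],
        wave_jitter=config.wave_jitter,
    )
    dataset.spec = model.spec
    return dataset, cohort, paths
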