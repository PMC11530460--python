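"""Post-fit summaries: hazard-ratio tables, occupancy curves, expected
total length of stay, sojourn times, and prevalence goodness-of-fit."""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.integrate
import scipy.linalg

from .data import PanelDataset
from .intensity import IntensityModel, build_generator, transition_probability
from .likelihood import FitResult
from .structures import AGE, age_segments

Z975 = 1.959963984540054


def hazard_ratios(fit: FitResult) -> pd.DataFrame:
    """Tidy HR table: one row per (transition, covariate, level) with
    ``hr = exp(beta)`` and delta-method 95% CI ``exp(beta +- 1.96 se)``.

    When the fit has no covariance matrix the CI columns are NaN.
    """
    lay = fit.model.layout
    se = fit.se
    rows = []
    for (trans, cname), idxs in lay.beta_index.items():
        cov = fit.model.spec[cname]
        for lv, i in zip(cov.dummy_levels, idxs):
            b = float(fit.estimates[i])
            if se is None:
                lo = hi = np.nan
            else:
                with np.errstate(over="ignore"):
                    lo = float(np.exp(b - Z975 * se[i]))
                    hi = float(np.exp(b + Z975 * se[i]))
            rows.append(
                {
                    "transition": f"{trans[0]}->{trans[1]}",
                    "covariate": cname,
                    "level": lv,
                    "reference": cov.reference,
                    "hr": float(np.exp(b)),
                    "lo95": lo,
                    "hi95": hi,
                }
            )
    return pd.DataFrame(rows)


def hazard_ratio_table(fit: FitResult) -> pd.DataFrame:
    """Wide layout with transitions as columns and 'HR (lo, hi)' cells."""
    tidy = hazard_ratios(fit)
    if tidy.empty:
        return tidy

    def cell(r):
        if np.isnan(r.lo95):
            return f"{r.hr:.2f}"
        return f"{r.hr:.2f} ({r.lo95:.2f}, {r.hi95:.2f})"

    tidy = tidy.assign(cell=[cell(r) for r in tidy.itertuples()])
    return tidy.pivot_table(
        index=["covariate", "level"],
        columns="transition",
        values="cell",
        aggfunc="first",
    )


def occupancy_curves(
    model: IntensityModel,
    covariate_pattern: Mapping,
    start_age: float,
    start_state: int,
    grid: Sequence,
) -> pd.DataFrame:
    """State-occupancy probabilities from ``start_state`` on a time grid,
    age bands applied piecewise. Tidy frame: time, state, probability."""
    grid = np.asarray(grid, dtype=float)
    if np.any(grid < 0) or np.any(np.diff(grid) < 0):
        raise ValueError("grid must be nonnegative and increasing")
    z = model.spec.encode(covariate_pattern)
    n = model.structure.n_states
    P = np.eye(n)
    prev_t = 0.0
    rows = []
    for t in grid:
        if t > prev_t:
            for band, dt in age_segments(start_age + prev_t, t - prev_t, model.spec.age_bands):
                if dt > 0:
                    P = P @ scipy.linalg.expm(model.generator_at_band(z, band) * dt)
            prev_t = t
        occ = P[start_state - 1]
        for s in range(n):
            rows.append({"time": float(t), "state": s + 1, "probability": float(occ[s])})
    return pd.DataFrame(rows)


def total_length_of_stay(
    model: IntensityModel,
    covariate_pattern: Mapping,
    start_age: float,
    start_state: int,
    horizon: float,
    tol: float = 1e-10,
) -> np.ndarray:
    """Expected years spent in each state over ``[0, horizon]``:
    ``totlos[s] = integral of P_{start,s}(u) du``, split at age-band
    boundaries and integrated adaptively within each band."""
    if horizon < 0:
        raise ValueError("horizon must be nonnegative")
    z = model.spec.encode(covariate_pattern)
    n = model.structure.n_states
    out = np.zeros(n)
    v = np.zeros(n)
    v[start_state - 1] = 1.0
    if horizon == 0:
        return out
    for band, dt in age_segments(start_age, horizon, model.spec.age_bands):
        if dt <= 0:
            continue
        Q = model.generator_at_band(z, band)

        def f(u, v=v, Q=Q):
            return v @ scipy.linalg.expm(Q * u)

        seg, _ = scipy.integrate.quad_vec(f, 0.0, dt, epsabs=tol, epsrel=tol)
        out += seg
        v = v @ scipy.linalg.expm(Q * dt)
    return out


def total_length_of_stay_ci(
    fit: FitResult,
    covariate_pattern: Mapping,
    start_age: float,
    start_state: int,
    horizon: float,
    draws: int = 500,
    seed: int = 0,
    grid_step: float = 0.02,
) -> pd.DataFrame:
    """Parametric-bootstrap CI for total length of stay: parameters are
    drawn from the fitted multivariate normal and the occupancy integral is
    re-evaluated per draw (composite Simpson on a fine grid)."""
    if fit.vcov is None:
        raise ValueError("fit has no covariance matrix; cannot bootstrap")
    rng = np.random.default_rng(seed)
    xhat = fit.estimates
    samples = rng.multivariate_normal(xhat, fit.vcov, size=draws, method="svd")
    grid = np.arange(0.0, horizon + grid_step / 2, grid_step)
    n = fit.model.structure.n_states
    boot = np.empty((draws, n))
    for d in range(draws):
        m = fit.model.with_vector(samples[d])
        occ = occupancy_curves(m, covariate_pattern, start_age, start_state, grid)
        probs = occ["probability"].to_numpy().reshape(len(grid), n)
        boot[d] = scipy.integrate.simpson(probs, x=grid, axis=0)
    point = total_length_of_stay(fit.model, covariate_pattern, start_age, start_state, horizon)
    lo, hi = np.percentile(boot, [2.5, 97.5], axis=0)
    return pd.DataFrame(
        {
            "state": np.arange(1, n + 1),
            "expected_years": point,
            "lo95": lo,
            "hi95": hi,
        }
    )


def sojourn_times(
    model: IntensityModel,
    covariate_pattern: Mapping,
    age: float,
    fit: Optional[FitResult] = None,
) -> pd.DataFrame:
    """Mean single-stay durations ``-1/q_rr`` for each transient state,
    with delta-method 95% CIs on the log scale when a fitted covariance is
    supplied."""
    Q = build_generator(model, covariate_pattern, age)
    rows = []
    vcov = fit.vcov if fit is not None else None
    for r in range(1, model.structure.n_states + 1):
        if model.structure.is_absorbing(r):
            continue
        qrr = -Q[r - 1, r - 1]
        soj = np.inf if qrr <= 0 else 1.0 / qrr
        lo = hi = np.nan
        if vcov is not None and np.isfinite(soj):
            g = _log_sojourn_grad(model, covariate_pattern, age, r)
            var = float(g @ vcov @ g)
            if var >= 0:
                half = Z975 * np.sqrt(var)
                lo, hi = soj * np.exp(-half), soj * np.exp(half)
        rows.append({"state": r, "sojourn_years": float(soj), "lo95": lo, "hi95": hi})
    return pd.DataFrame(rows)


def _log_sojourn_grad(model, pattern, age, state, h=1e-6) -> np.ndarray:
    x0 = model.to_vector()
    g = np.zeros_like(x0)
    for i in range(len(x0)):
        xp = x0.copy()
        xp[i] += h
        xm = x0.copy()
        xm[i] -= h
        qp = -build_generator(model.with_vector(xp), pattern, age)[state - 1, state - 1]
        qm = -build_generator(model.with_vector(xm), pattern, age)[state - 1, state - 1]
        if qp <= 0 or qm <= 0:
            g[i] = 0.0
        else:
            g[i] = (np.log(1 / qp) - np.log(1 / qm)) / (2 * h)
    return g


def prevalence_gof(
    model: IntensityModel,
    dataset: PanelDataset,
    grid: Sequence,
    window: Optional[float] = None,
) -> pd.DataFrame:
    """Observed versus model-expected state prevalence over time.

    Observed: each subject's state at a grid time is carried forward from
    the latest observation at or before it, provided that observation is
    within ``window`` years (absorbing-state observations persist
    regardless — deaths are known). Expected: the average over subjects of
    the model occupancy started from their first observed state, age and
    covariates. Default window = half the median gap between consecutive
    observations.
    """
    grid = np.asarray(grid, dtype=float)
    n = model.structure.n_states
    absorbing = model.structure.absorbing
    if window is None:
        gaps = np.concatenate(
            [np.diff(r.times) for r in dataset.records if r.n_obs >= 2] or [np.array([1.0])]
        )
        window = float(np.median(gaps)) / 2.0

    expected = np.zeros((len(grid), n))
    n_expected = 0
    occ_cache: dict = {}
    for rec in dataset.records:
        key = (
            tuple(sorted((k, rec.covariates[k]) for k in rec.covariates)),
            round(rec.baseline_age, 6),
            int(rec.states[0]),
        )
        if key not in occ_cache:
            curves = occupancy_curves(
                model, rec.covariates, rec.baseline_age, int(rec.states[0]), grid
            )
            occ_cache[key] = curves["probability"].to_numpy().reshape(len(grid), n)
        expected += occ_cache[key]
        n_expected += 1
    expected /= max(n_expected, 1)

    rows = []
    for gi, g in enumerate(grid):
        counts = np.zeros(n)
        for rec in dataset.records:
            rel = rec.times - rec.times[0]
            k = int(np.searchsorted(rel, g + 1e-12) - 1)
            if k < 0:
                continue
            state = int(rec.states[k])
            if absorbing[state - 1] or (g - rel[k]) <= window:
                counts[state - 1] += 1
        total = counts.sum()
        for s in range(n):
            rows.append(
                {
                    "time": float(g),
                    "state": s + 1,
                    "observed": float(counts[s] / total) if total > 0 else np.nan,
                    "expected": float(expected[gi, s]),
                    "n_observed": int(total),
                }
            )
    return pd.DataFrame(rows)
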