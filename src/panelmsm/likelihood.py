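"""Panel-data likelihood, maximum-likelihood fitting, and Hessian SEs.

Subjects are observed at interview waves, so each consecutive pair of
observations contributes ``log P_{rs}(dt)``; a final interval ending in an
exactly observed death contributes ``log sum_u P_{ru}(dt) q_{u,death}``.
Intervals are split at age-band boundaries and identical (pattern, band
path, length, state pair) intervals are aggregated, so one likelihood
evaluation is a single batched matrix-exponential call plus weighted sums.
The gradient is exact reverse-mode (adjoint of the matrix exponential).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.optimize

from ._expm import expm_batch, expm_batch_cached, expm_batch_vjp
from .data import PanelDataset, SubjectRecord
from .intensity import IntensityModel
from .structures import AGE, CovariateSpec, TransitionStructure, age_segments

LOGQ_BOUNDS = (-12.0, 5.0)
BETA_BOUNDS = (-8.0, 8.0)
RATE_FLOOR = 1e-4


def statetable(dataset: PanelDataset, n_states: Optional[int] = None) -> np.ndarray:
    """Counts of successive observed state pairs (r followed by s),
    including r == s pairs. Empty dataset gives a zero matrix."""
    if n_states is None:
        n_states = max((int(r.states.max()) for r in dataset.records), default=0)
    table = np.zeros((n_states, n_states), dtype=int)
    for rec in dataset.records:
        for a, b in zip(rec.states[:-1], rec.states[1:]):
            table[a - 1, b - 1] += 1
    return table


def _person_time(dataset: PanelDataset, n_states: int) -> np.ndarray:
    """Observed time attributed to the state at the left endpoint of each
    interval."""
    pt = np.zeros(n_states)
    for rec in dataset.records:
        for i in range(rec.n_obs - 1):
            pt[rec.states[i] - 1] += rec.times[i + 1] - rec.times[i]
    return pt


def crude_initial_values(
    dataset: PanelDataset,
    structure: TransitionStructure,
    spec: Optional[CovariateSpec] = None,
    floor: float = RATE_FLOOR,
) -> IntensityModel:
    """Occurrence/exposure starting values: observed r->s pairs divided by
    person-time in r, floored away from zero; all other parameters zero."""
    if not dataset.records:
        raise ValueError("empty dataset")
    if spec is None:
        spec = CovariateSpec(covariates=(), design={}, age_bands=())
    table = statetable(dataset, structure.n_states)
    pt = _person_time(dataset, structure.n_states)
    log_q0 = {}
    for r, s in structure.transitions:
        if pt[r - 1] <= 0:
            warnings.warn(f"no person-time observed in state {r}; floor rate used")
            rate = floor
        else:
            rate = table[r - 1, s - 1] / pt[r - 1]
            if rate <= 0:
                rate = floor
        log_q0[(r, s)] = float(np.log(rate))
    return IntensityModel(structure=structure, spec=spec, log_q0=log_q0)


@dataclass
class _Group:
    """Aggregated likelihood terms sharing a segment count."""

    seg: np.ndarray  # (n_k, m) indices into the unique-segment table
    fr: np.ndarray  # 0-based start states
    to: np.ndarray  # 0-based end states (unused for exact-death groups)
    cnt: np.ndarray
    exact: bool
    end_pq: Optional[np.ndarray] = None  # (pattern, band) index at event time


class LikelihoodWorkspace:
    """Precomputed design tensors and aggregated interval terms for one
    (dataset, model-structure) pair."""

    def __init__(
        self,
        dataset: PanelDataset,
        model: IntensityModel,
        death: Optional[str] = None,
    ):
        if death not in (None, "exact", "panel"):
            raise ValueError("death must be None, 'exact' or 'panel'")
        if model.zero_rates:
            raise ValueError("cannot fit a model with zero-rate transitions")
        structure, spec = model.structure, model.spec
        self.structure, self.spec = structure, spec
        self.layout = model.layout
        n = structure.n_states
        dataset.validate_states(n, structure.absorbing)
        reach = structure.reachability()

        self.used = [r for r in dataset.records if r.n_obs >= 2]
        self.n_dropped = len(dataset.records) - len(self.used)
        if self.n_dropped:
            warnings.warn(
                f"dropped {self.n_dropped} subject(s) with a single observation"
            )
        self.statetable = statetable(
            PanelDataset(records=self.used, spec=spec), n
        )
        self.n_subjects = len(self.used)
        self.n_observations = sum(r.n_obs for r in self.used)

        trans = structure.transitions
        self.trans = trans
        self.rows = np.array([r - 1 for r, _ in trans])
        self.cols = np.array([s - 1 for _, s in trans])
        # transitions feeding an absorbing state, for exact-event terms
        self.death_pairs = [
            (j, r - 1) for j, (r, s) in enumerate(trans) if structure.absorbing[s - 1]
        ]

        used_names = [c for c in spec.names if any(c in spec.design_for(t) for t in trans)]
        n_bands = spec.n_bands
        patterns: dict = {}
        pattern_z: list = []
        pat_of: list = []
        for rec in self.used:
            key = tuple(rec.covariates.get(c) for c in used_names)
            if key not in patterns:
                patterns[key] = len(patterns)
                pattern_z.append(
                    {c: spec[c].encode(rec.covariates[c]) for c in used_names}
                )
            pat_of.append(patterns[key])
        n_p = max(len(patterns), 1)
        if not patterns:
            pattern_z.append({})

        # design tensor: log q[pq, j] = B[pq, j, :] @ theta
        lay = self.layout
        B = np.zeros((n_p * n_bands, len(trans), lay.n_params))
        for p in range(n_p):
            z = pattern_z[p]
            for b in range(n_bands):
                pq = p * n_bands + b
                for j, t in enumerate(trans):
                    B[pq, j, lay.q0_index[t]] = 1.0
                    for cname in spec.design_for(t):
                        if cname == AGE:
                            if b > 0:
                                B[pq, j, lay.age_index[b - 1]] = 1.0
                        else:
                            B[pq, j, list(lay.beta_index[(t, cname)])] = z[cname]
        self.B = B
        self.n_pq = n_p * n_bands
        self.n_bands = n_bands

        # aggregate intervals
        cuts = spec.age_bands
        useg: dict = {}
        terms: dict = {}
        self.offenders: list = []
        for rec, pid in zip(self.used, pat_of):
            for i in range(rec.n_obs - 1):
                t0, t1 = rec.times[i], rec.times[i + 1]
                fr, to = int(rec.states[i]), int(rec.states[i + 1])
                is_exact = (
                    structure.absorbing[to - 1]
                    and i == rec.n_obs - 2
                    and (death == "exact" or (death is None and rec.death_exact))
                )
                if is_exact:
                    ok = any(
                        reach[fr - 1, r0] for _, r0 in self.death_pairs
                    )
                else:
                    ok = reach[fr - 1, to - 1]
                if not ok:
                    self.offenders.append((rec.subject_id, float(t0), fr, to))
                    continue
                segs = tuple(
                    (b, round(float(d), 9))
                    for b, d in age_segments(rec.age_at(t0), t1 - t0, cuts)
                )
                sids = []
                for b, d in segs:
                    k = (pid * n_bands + b, d)
                    if k not in useg:
                        useg[k] = len(useg)
                    sids.append(useg[k])
                end_pq = pid * n_bands + segs[-1][0]
                key = (tuple(sids), fr - 1, to - 1, is_exact, end_pq)
                terms[key] = terms.get(key, 0) + 1

        self.useg_pq = np.array([k[0] for k in useg], dtype=int)
        self.useg_dt = np.array([k[1] for k in useg], dtype=float)
        grouped: dict = {}
        for (sids, fr, to, is_exact, end_pq), cnt in terms.items():
            grouped.setdefault((is_exact, len(sids)), []).append(
                (sids, fr, to, cnt, end_pq)
            )
        self.groups: list = []
        for (is_exact, m), items in sorted(grouped.items()):
            self.groups.append(
                _Group(
                    seg=np.array([it[0] for it in items], dtype=int),
                    fr=np.array([it[1] for it in items], dtype=int),
                    to=np.array([it[2] for it in items], dtype=int),
                    cnt=np.array([it[3] for it in items], dtype=float),
                    exact=is_exact,
                    end_pq=np.array([it[4] for it in items], dtype=int)
                    if is_exact
                    else None,
                )
            )

    # -- evaluation ------------------------------------------------------

    def _q_table(self, theta: np.ndarray) -> np.ndarray:
        return np.exp(np.einsum("pjt,t->pj", self.B, theta))

    def negloglik(self, theta: np.ndarray, need_grad: bool = True):
        n = self.structure.n_states
        dtype = np.result_type(np.asarray(theta).dtype, float)
        q = self._q_table(theta)
        Q = np.zeros((self.n_pq, n, n), dtype=dtype)
        Q[:, self.rows, self.cols] = q
        idx = np.arange(n)
        Q[:, idx, idx] = -Q.sum(axis=2)
        if len(self.useg_pq) == 0:
            if need_grad:
                return 0.0, np.zeros(self.layout.n_params)
            return 0.0
        A = Q[self.useg_pq] * self.useg_dt[:, None, None]
        if need_grad:
            P, expm_cache = expm_batch_cached(A)
        else:
            P = expm_batch(A)

        ll = 0.0
        bar_P = np.zeros_like(P) if need_grad else None
        bar_q = np.zeros_like(q) if need_grad else None
        for grp in self.groups:
            n_k, m = grp.seg.shape
            ar = np.arange(n_k)
            mats = P[grp.seg]  # (n_k, m, n, n)
            prefixes = [mats[:, 0]]
            for i in range(1, m):
                prefixes.append(np.matmul(prefixes[-1], mats[:, i]))
            Pint = prefixes[-1]
            if grp.exact:
                v = Pint[ar, grp.fr]  # (n_k, n)
                dvec = np.zeros((n_k, n), dtype=dtype)
                for j, r0 in self.death_pairs:
                    dvec[:, r0] = q[grp.end_pq, j]
                dens = (v * dvec).sum(axis=1)
                ll = ll + (grp.cnt * _safe_log(dens)).sum()
                if need_grad:
                    w = grp.cnt / dens
                    bar_Pint = np.zeros_like(Pint)
                    bar_Pint[ar, grp.fr] = w[:, None] * dvec
                    bar_dvec = w[:, None] * v
                    for j, r0 in self.death_pairs:
                        np.add.at(bar_q[:, j], grp.end_pq, bar_dvec[:, r0])
            else:
                vals = Pint[ar, grp.fr, grp.to]
                ll = ll + (grp.cnt * _safe_log(vals)).sum()
                if need_grad:
                    bar_Pint = np.zeros_like(Pint)
                    bar_Pint[ar, grp.fr, grp.to] = grp.cnt / vals
            if need_grad:
                bar = bar_Pint
                bar_mats = np.empty_like(mats)
                for i in range(m - 1, 0, -1):
                    bar_mats[:, i] = np.matmul(
                        np.swapaxes(prefixes[i - 1], -1, -2), bar
                    )
                    bar = np.matmul(bar, np.swapaxes(mats[:, i], -1, -2))
                bar_mats[:, 0] = bar
                np.add.at(bar_P, grp.seg.reshape(-1), bar_mats.reshape(-1, n, n))

        if not need_grad:
            return -ll
        bar_A = expm_batch_vjp(expm_cache, bar_P)
        bar_Q = np.zeros_like(Q)
        np.add.at(bar_Q, self.useg_pq, bar_A * self.useg_dt[:, None, None])
        bar_q += bar_Q[:, self.rows, self.cols] - bar_Q[:, self.rows, self.rows]
        grad = np.einsum("pjt,pj->t", self.B, bar_q * q)
        return -ll, -grad


def _safe_log(x):
    if np.iscomplexobj(x):
        return np.log(x)
    return np.log(np.maximum(x, 1e-300))


def log_likelihood(
    dataset: PanelDataset, model: IntensityModel, death: Optional[str] = None
) -> float:
    """Panel log-likelihood of the model on the dataset.

    Returns ``-inf`` (with a warning listing offending records) if an
    observed state pair is impossible under the transition structure.
    """
    ws = LikelihoodWorkspace(dataset, model, death=death)
    if ws.offenders:
        detail = "; ".join(
            f"subject {sid} at t={t:g}: {fr}->{to}" for sid, t, fr, to in ws.offenders[:10]
        )
        warnings.warn(f"observed transitions impossible under the structure: {detail}")
        return -np.inf
    return -ws.negloglik(model.to_vector(), need_grad=False)


@dataclass
class FitResult:
    """Maximum-likelihood fit: estimates, covariance, and diagnostics."""

    model: IntensityModel
    estimates: np.ndarray
    param_names: tuple
    loglik: float
    converged: bool
    vcov: Optional[np.ndarray]
    n_subjects: int
    n_observations: int
    statetable: np.ndarray
    warnings: list = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)

    @property
    def se(self) -> Optional[np.ndarray]:
        if self.vcov is None:
            return None
        return np.sqrt(np.maximum(np.diag(self.vcov), 0.0))

    def index_of(self, name: str) -> int:
        return self.param_names.index(name)

    def beta_estimate(self, trans, covariate: str, level=None) -> tuple:
        """(estimate, se or None) for one coefficient."""
        r, s = trans
        label = f"{covariate}:{level}" if level is not None else covariate
        i = self.index_of(f"beta[{r}->{s}].{label}")
        se = self.se
        return float(self.estimates[i]), (None if se is None else float(se[i]))

    def to_dict(self) -> dict:
        from .config import model_to_dict

        return {
            "model": model_to_dict(self.model),
            "estimates": [float(v) for v in self.estimates],
            "param_names": list(self.param_names),
            "se": None if self.se is None else [float(v) for v in self.se],
            "vcov": None if self.vcov is None else self.vcov.tolist(),
            "loglik": float(self.loglik),
            "converged": bool(self.converged),
            "n_subjects": int(self.n_subjects),
            "n_observations": int(self.n_observations),
            "statetable": self.statetable.tolist(),
            "warnings": list(self.warnings),
            "diagnostics": {
                k: v for k, v in self.diagnostics.items() if k != "optimizer"
            },
        }


def _bounds_for(layout) -> list:
    bounds = []
    for name in layout.names:
        bounds.append(LOGQ_BOUNDS if name.startswith("logq") else BETA_BOUNDS)
    return bounds


def fit(
    dataset: PanelDataset,
    model_init: IntensityModel,
    death: Optional[str] = None,
    se: bool = True,
    gtol: float = 1e-6,
    maxiter: int = 2000,
) -> FitResult:
    """Maximise the panel log-likelihood by L-BFGS-B with exact gradients.

    The objective is scaled per subject, so ``gtol`` applies to the mean
    log-likelihood gradient.

    ``death`` overrides per-record exact-death flags ('exact'/'panel');
    ``se=False`` skips the finite-difference Hessian (vcov is then None).
    Non-convergence is reported honestly via ``converged`` plus optimiser
    diagnostics; a singular Hessian yields a pseudo-inverse vcov with a
    warning.
    """
    ws = LikelihoodWorkspace(dataset, model_init, death=death)
    if ws.offenders:
        detail = "; ".join(
            f"subject {sid} at t={t:g}: {fr}->{to}" for sid, t, fr, to in ws.offenders[:10]
        )
        raise ValueError(f"observed transitions impossible under the structure: {detail}")
    lay = ws.layout
    x0 = model_init.to_vector()
    bounds = _bounds_for(lay)
    scale = max(ws.n_subjects, 1)  # per-subject objective keeps steps sane

    def objective(x):
        v, g = ws.negloglik(x)
        return v / scale, g / scale

    res = scipy.optimize.minimize(
        objective,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": maxiter, "maxcor": 25, "ftol": 1e-13, "gtol": gtol},
    )
    res.fun = res.fun * scale
    xhat = res.x
    fit_warnings: list = []
    for t, i in lay.q0_index.items():
        if xhat[i] <= LOGQ_BOUNDS[0] + 1e-6 or np.exp(xhat[i]) < 10 * np.exp(LOGQ_BOUNDS[0]):
            fit_warnings.append(
                f"rate for transition {t[0]}->{t[1]} driven to the zero boundary"
            )

    vcov = None
    if se:
        H = _hessian(ws, xhat)
        vcov, warn = _invert_hessian(H)
        if warn:
            fit_warnings.append(warn)

    informing = {}
    for (trans, cname), idxs in lay.beta_index.items():
        r, s = trans
        informing[f"{r}->{s}:{cname}"] = int(ws.statetable[r - 1, s - 1])

    return FitResult(
        model=model_init.with_vector(xhat),
        estimates=xhat,
        param_names=lay.names,
        loglik=float(-res.fun),
        converged=bool(res.success),
        vcov=vcov,
        n_subjects=ws.n_subjects,
        n_observations=ws.n_observations,
        statetable=ws.statetable,
        warnings=fit_warnings,
        diagnostics={
            "n_iter": int(res.nit),
            "message": str(res.message),
            "dropped_subjects": ws.n_dropped,
            "transitions_informing_beta": informing,
            "optimizer": res,
        },
    )


def _hessian(ws: LikelihoodWorkspace, x: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
    """Central finite differences of the exact gradient."""
    p = len(x)
    H = np.zeros((p, p))
    for i in range(p):
        h = rel_step * max(1.0, abs(x[i]))
        xp = x.copy()
        xp[i] += h
        xm = x.copy()
        xm[i] -= h
        gp = ws.negloglik(xp, need_grad=True)[1]
        gm = ws.negloglik(xm, need_grad=True)[1]
        H[:, i] = (gp - gm) / (2 * h)
    return 0.5 * (H + H.T)


def _invert_hessian(H: np.ndarray):
    try:
        cond = np.linalg.cond(H)
    except np.linalg.LinAlgError:
        cond = np.inf
    if not np.isfinite(cond) or cond > 1e10:
        return np.linalg.pinv(H), (
            f"Hessian ill-conditioned (cond={cond:.2e}); vcov is a pseudo-inverse"
        )
    try:
        return np.linalg.inv(H), None
    except np.linalg.LinAlgError:
        return None, "Hessian singular; vcov unavailable"
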