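"""Proportional-intensity parameterisation of the generator matrix.

Each allowed transition ``r -> s`` has a baseline per-year rate
``exp(log_q0)``, multiplied by ``exp(beta' z)`` for its covariates and by
``exp(offset)`` for the age band in force, so hazard ratios are ``exp(beta)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import scipy.linalg

from .structures import AGE, CovariateSpec, Transition, TransitionStructure, age_segments


class ParameterLayout:
    """Flat parameter vector layout: log_q0 block, per-transition beta
    blocks (in design order), then shared age-band offsets (band 0 is the
    reference and carries no parameter)."""

    def __init__(self, structure: TransitionStructure, spec: CovariateSpec):
        self.structure = structure
        self.spec = spec
        names: list = []
        self.q0_index: dict = {}
        self.beta_index: dict = {}
        for trans in structure.transitions:
            r, s = trans
            self.q0_index[trans] = len(names)
            names.append(f"logq[{r}->{s}]")
        for trans in structure.transitions:
            r, s = trans
            for cname in spec.design_for(trans):
                if cname == AGE:
                    continue
                cov = spec[cname]
                idxs = []
                for lv in cov.dummy_levels:
                    label = f"{cname}:{lv}" if lv is not None else cname
                    idxs.append(len(names))
                    names.append(f"beta[{r}->{s}].{label}")
                self.beta_index[(trans, cname)] = tuple(idxs)
        self.age_index = tuple(range(len(names), len(names) + spec.n_bands - 1))
        for b in range(1, spec.n_bands):
            names.append(f"age_band[{b}]")
        self.names = tuple(names)

    @property
    def n_params(self) -> int:
        return len(self.names)


@dataclass
class IntensityModel:
    """Baseline log-intensities, covariate coefficients, and age-band
    offsets generating the intensity matrix Q.

    ``log_q0`` maps each allowed transition to its baseline log rate;
    ``beta[(r, s)][name]`` is the coefficient vector (one entry per
    non-reference level) of a covariate on that transition; ``age_offsets``
    has one additive log-intensity offset per age band beyond the first.
    Transitions in ``zero_rates`` have their rate pinned to exactly zero
    (the representation of a no-flow transition; ``-inf`` log rates are not
    used).
    """

    structure: TransitionStructure
    spec: CovariateSpec
    log_q0: dict
    beta: dict = field(default_factory=dict)
    age_offsets: np.ndarray = None
    zero_rates: frozenset = frozenset()

    def __post_init__(self):
        n_off = self.spec.n_bands - 1
        if self.age_offsets is None:
            self.age_offsets = np.zeros(n_off)
        self.age_offsets = np.asarray(self.age_offsets, dtype=float)
        if self.age_offsets.shape != (n_off,):
            raise ValueError(f"age_offsets must have length {n_off}")
        for trans in self.structure.transitions:
            if trans not in self.log_q0 and trans not in self.zero_rates:
                raise ValueError(f"missing log_q0 for transition {trans}")
            if not np.isfinite(self.log_q0.get(trans, 0.0)):
                raise ValueError(f"non-finite log_q0 for {trans}; use zero_rates for no flow")
        for trans, covs in self.beta.items():
            for cname, vec in covs.items():
                want = self.spec[cname].n_coef
                if np.shape(np.atleast_1d(vec)) != (want,):
                    raise ValueError(
                        f"beta[{trans}][{cname!r}] must have {want} entries"
                    )

    # -- parameter vector interface -------------------------------------

    @property
    def layout(self) -> ParameterLayout:
        return ParameterLayout(self.structure, self.spec)

    def to_vector(self) -> np.ndarray:
        lay = self.layout
        x = np.zeros(lay.n_params)
        for trans, i in lay.q0_index.items():
            x[i] = self.log_q0.get(trans, 0.0)
        for (trans, cname), idxs in lay.beta_index.items():
            vec = np.atleast_1d(self.beta.get(trans, {}).get(cname, np.zeros(len(idxs))))
            x[list(idxs)] = vec
        x[list(lay.age_index)] = self.age_offsets
        return x

    def with_vector(self, x: np.ndarray) -> "IntensityModel":
        """New model with parameters taken from a flat vector."""
        lay = self.layout
        x = np.asarray(x, dtype=float)
        if x.shape != (lay.n_params,):
            raise ValueError(f"expected parameter vector of length {lay.n_params}")
        log_q0 = {t: float(x[i]) for t, i in lay.q0_index.items()}
        beta: dict = {}
        for (trans, cname), idxs in lay.beta_index.items():
            beta.setdefault(trans, {})[cname] = x[list(idxs)].copy()
        return replace(
            self,
            log_q0=log_q0,
            beta=beta,
            age_offsets=x[list(lay.age_index)].copy(),
        )

    # -- intensity evaluation -------------------------------------------

    def _age_term(self, trans: Transition, band: int) -> float:
        if not self.spec.has_age(trans) or band == 0:
            return 0.0
        return float(self.age_offsets[band - 1])

    def _log_intensity(self, trans: Transition, z: Mapping, band: int) -> float:
        lp = self.log_q0[trans]
        for cname in self.spec.design_for(trans):
            if cname == AGE:
                continue
            coef = np.atleast_1d(self.beta.get(trans, {}).get(cname, 0.0))
            if coef.shape == (1,) and self.spec[cname].n_coef != 1:
                coef = np.zeros(self.spec[cname].n_coef)
            lp += float(coef @ z[cname])
        return lp + self._age_term(trans, band)

    def generator_at_band(self, z: Mapping, band: int) -> np.ndarray:
        """Intensity matrix Q for encoded covariates ``z`` in an age band."""
        n = self.structure.n_states
        Q = np.zeros((n, n))
        for trans in self.structure.transitions:
            r, s = trans
            if trans in self.zero_rates:
                continue
            Q[r - 1, s - 1] = np.exp(self._log_intensity(trans, z, band))
        np.fill_diagonal(Q, Q.diagonal() - Q.sum(axis=1))
        return Q


def build_generator(model: IntensityModel, covariate_values: Mapping, age: float) -> np.ndarray:
    """Generator (intensity) matrix Q at given covariates and age.

    Off-diagonals are nonnegative per-year rates (zero for disallowed
    pairs), rows sum to zero, and absorbing rows are identically zero.
    """
    z = model.spec.encode(covariate_values)
    return model.generator_at_band(z, model.spec.band_of(age))


def transition_probability(
    model: IntensityModel, covariate_values: Mapping, age_start: float, t: float
) -> np.ndarray:
    """P(t) = exp(Q t), composed as an ordered product of per-age-band
    exponentials when ``[age_start, age_start + t]`` crosses band cut-points.
    """
    if t < 0:
        raise ValueError("t must be nonnegative")
    z = model.spec.encode(covariate_values)
    n = model.structure.n_states
    P = np.eye(n)
    for band, dt in age_segments(age_start, t, model.spec.age_bands):
        if dt == 0.0:
            continue
        Q = model.generator_at_band(z, band)
        P = P @ scipy.linalg.expm(Q * dt)
    return P
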