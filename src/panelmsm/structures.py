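"""State spaces and covariate designs for continuous-time multistate models.

A :class:`TransitionStructure` is the directed graph of instantaneous
transitions that are allowed between states; a :class:`CovariateSpec`
declares which covariates act on which transition intensity and how age
enters through piecewise-constant bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

#: Name of the pseudo-covariate standing for the piecewise-constant age bands.
AGE = "age"

Transition = tuple[int, int]


@dataclass(frozen=True)
class TransitionStructure:
    """Directed graph of allowed instantaneous transitions.

    States are 1-based in all user-facing I/O. ``allowed`` contains ordered
    pairs ``(r, s)`` with ``r != s``; ``absorbing[k]`` flags state ``k+1``
    as absorbing (no outgoing pairs).
    """

    n_states: int
    allowed: frozenset
    absorbing: tuple
    state_names: tuple = None

    def __post_init__(self):
        if self.n_states < 2:
            raise ValueError("need at least two states")
        if len(self.absorbing) != self.n_states:
            raise ValueError("absorbing flags must have one entry per state")
        for r, s in self.allowed:
            if r == s:
                raise ValueError(f"self-transition ({r},{r}) not allowed")
            if not (1 <= r <= self.n_states and 1 <= s <= self.n_states):
                raise ValueError(f"transition ({r},{s}) outside state range")
            if self.absorbing[r - 1]:
                raise ValueError(f"absorbing state {r} has outgoing transition ({r},{s})")
        out = {r for r, _ in self.allowed}
        for k in range(1, self.n_states + 1):
            if not self.absorbing[k - 1] and k not in out:
                raise ValueError(f"non-absorbing state {k} has no outgoing transition")
        if self.state_names is not None and len(self.state_names) != self.n_states:
            raise ValueError("state_names length mismatch")

    @property
    def transitions(self) -> tuple:
        """Allowed transitions in canonical (row-major) order."""
        return tuple(sorted(self.allowed))

    def is_absorbing(self, state: int) -> bool:
        return bool(self.absorbing[state - 1])

    def reachability(self) -> np.ndarray:
        """Boolean matrix: ``[r-1, s-1]`` True iff s is reachable from r
        (including staying put) through allowed transitions."""
        n = self.n_states
        adj = np.eye(n, dtype=bool)
        for r, s in self.allowed:
            adj[r - 1, s - 1] = True
        reach = adj.copy()
        for _ in range(n):
            new = reach @ adj
            if (new == reach).all():
                break
            reach = new
        return reach

    @classmethod
    def default(cls) -> "TransitionStructure":
        """The four-state cognitive structure: NOCI (1) <-> CIND (2), both
        feeding dementia (3) and death (4); dementia feeds death; death
        absorbing. Seven allowed transitions."""
        allowed = frozenset(
            {(1, 2), (2, 1), (1, 3), (2, 3), (1, 4), (2, 4), (3, 4)}
        )
        return cls(
            n_states=4,
            allowed=allowed,
            absorbing=(False, False, False, True),
            state_names=("NOCI", "CIND", "dementia", "death"),
        )


@dataclass(frozen=True)
class Covariate:
    """A named covariate; categorical when ``levels`` is given (dummy-coded
    against ``reference``), continuous otherwise."""

    name: str
    levels: tuple = None
    reference: str = None

    def __post_init__(self):
        if self.levels is not None:
            if self.reference is None:
                object.__setattr__(self, "reference", self.levels[0])
            if self.reference not in self.levels:
                raise ValueError(
                    f"reference level {self.reference!r} not among levels of {self.name!r}"
                )

    @property
    def is_categorical(self) -> bool:
        return self.levels is not None

    @property
    def dummy_levels(self) -> tuple:
        """Non-reference levels, in declared order (one dummy each)."""
        if not self.is_categorical:
            return (None,)
        return tuple(lv for lv in self.levels if lv != self.reference)

    @property
    def n_coef(self) -> int:
        return len(self.dummy_levels)

    def encode(self, value) -> np.ndarray:
        """Dummy (or identity) encoding of a single value."""
        if not self.is_categorical:
            return np.array([float(value)])
        if value not in self.levels:
            raise ValueError(
                f"unknown level {value!r} for covariate {self.name!r}; "
                f"expected one of {list(self.levels)}"
            )
        return np.array([1.0 if value == lv else 0.0 for lv in self.dummy_levels])


@dataclass(frozen=True)
class CovariateSpec:
    """Covariate vocabulary, per-transition design, and age bands.

    ``design`` maps each allowed transition to the covariate names acting on
    its log-intensity; the pseudo-name :data:`AGE` selects the shared
    piecewise-constant age-band offsets. ``age_bands`` holds the interior
    cut-points (years, strictly increasing); ages are clamped to the outer
    bands.
    """

    covariates: tuple
    design: Mapping = field(default_factory=dict)
    age_bands: tuple = ()

    def __post_init__(self):
        names = [c.name for c in self.covariates]
        if len(set(names)) != len(names):
            raise ValueError("duplicate covariate names")
        cuts = tuple(float(c) for c in self.age_bands)
        if any(b <= a for a, b in zip(cuts, cuts[1:])):
            raise ValueError("age_bands cut-points must be strictly increasing")
        object.__setattr__(self, "age_bands", cuts)
        known = set(names) | {AGE}
        for trans, covs in dict(self.design).items():
            for cname in covs:
                if cname not in known:
                    raise ValueError(f"design for {trans} names unknown covariate {cname!r}")
        object.__setattr__(self, "design", dict(self.design))

    def __getitem__(self, name: str) -> Covariate:
        for c in self.covariates:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def names(self) -> tuple:
        return tuple(c.name for c in self.covariates)

    @property
    def n_bands(self) -> int:
        return len(self.age_bands) + 1

    def band_of(self, age: float) -> int:
        """0-based age band index for an age in years (outer bands clamp)."""
        return int(np.searchsorted(self.age_bands, age, side="right"))

    def design_for(self, trans: Transition) -> tuple:
        return tuple(self.design.get(trans, ()))

    def has_age(self, trans: Transition) -> bool:
        return AGE in self.design_for(trans)

    def encode(self, values: Mapping) -> dict:
        """Encode a full covariate value map; raises on missing names or
        unknown categorical levels."""
        out = {}
        for c in self.covariates:
            if c.name not in values:
                raise ValueError(f"missing value for covariate {c.name!r}")
            out[c.name] = c.encode(values[c.name])
        return out

    def used_names(self) -> tuple:
        """Covariate names appearing in at least one transition's design."""
        used = []
        for c in self.covariates:
            if any(c.name in self.design_for(t) for t in self.design):
                used.append(c.name)
        return tuple(used)


def age_segments(age_start: float, t: float, cuts: Sequence) -> list:
    """Split the age interval ``[age_start, age_start + t)`` at band
    cut-points. Returns ``[(band_index, duration), ...]`` in order."""
    if t < 0:
        raise ValueError("negative interval length")
    cuts = tuple(cuts)
    a = float(age_start)
    end = a + float(t)
    band = int(np.searchsorted(cuts, a, side="right"))
    if t == 0:
        return [(band, 0.0)]
    segs = []
    while True:
        nxt = cuts[band] if band < len(cuts) else np.inf
        if end <= nxt + 1e-12:
            segs.append((band, end - a))
            break
        segs.append((band, nxt - a))
        a = nxt
        band += 1
    return [(b, d) for b, d in segs if d > 1e-12] or [(band, 0.0)]
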