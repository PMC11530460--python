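import numpy as np
import pytest

from panelmsm import (
    CohortConfig,
    Covariate,
    CovariateSpec,
    IntensityModel,
    PanelDataset,
    SubjectRecord,
    TransitionStructure,
)


@pytest.fixture
def structure4():
    return TransitionStructure.default()


def make_two_state(q=0.5, beta=0.0, age_bands=(), age_offsets=None):
    """Two-state chain 1 -> 2 (absorbing) with one binary covariate x."""
    structure = TransitionStructure(
        n_states=2, allowed=frozenset({(1, 2)}), absorbing=(False, True)
    )
    cov = Covariate("x", ("a", "b"), "a")
    spec = CovariateSpec(
        covariates=(cov,), design={(1, 2): ("x",) + (("age",) if age_bands else ())},
        age_bands=age_bands,
    )
    return IntensityModel(
        structure=structure,
        spec=spec,
        log_q0={(1, 2): float(np.log(q))},
        beta={(1, 2): {"x": np.array([beta])}},
        age_offsets=age_offsets,
    )


def make_plain4(q0=None, age_bands=(), age_offsets=None, design_age=False):
    """Four-state default structure with no covariates (optionally age bands)."""
    from panelmsm.config import DEFAULT_Q0

    structure = TransitionStructure.default()
    design = {
        t: (("age",) if design_age else ()) for t in structure.transitions
    }
    spec = CovariateSpec(covariates=(), design=design, age_bands=age_bands)
    q0 = dict(DEFAULT_Q0 if q0 is None else q0)
    return IntensityModel(
        structure=structure,
        spec=spec,
        log_q0={t: float(np.log(v)) for t, v in q0.items()},
        age_offsets=age_offsets,
    )


def two_state_config(n, waves=(0.0, 2.0, 4.0, 6.0, 8.0), dropout=0.0, seed=0):
    return CohortConfig(
        n_subjects=n,
        wave_times=waves,
        covariate_distribution={"x": {"a": 0.5, "b": 0.5}},
        initial_state_probs=(1.0,),
        dropout_per_wave=dropout,
        seed=seed,
    )


def plain4_config(n, waves=(0.0, 2.0), dropout=0.0, seed=0):
    return CohortConfig(
        n_subjects=n,
        wave_times=waves,
        covariate_distribution={},
        initial_state_probs=(0.75, 0.23, 0.02),
        dropout_per_wave=dropout,
        seed=seed,
    )


def subject(sid, times, states, covs=None, age=55.0, death_exact=False):
    return SubjectRecord(
        subject_id=sid,
        times=np.asarray(times, dtype=float),
        states=np.asarray(states, dtype=int),
        covariates=covs or {},
        baseline_age=age,
        death_exact=death_exact,
    )


def dataset(records, spec=None):
    return PanelDataset(records=list(records), spec=spec)
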