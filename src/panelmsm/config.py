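"""Model configuration: default structures, the bundled simulation
scenario, and YAML/JSON (de)serialisation of intensity models.

The bundled "calibrated" scenario pairs fixture baseline intensities with
realistic socioeconomic hazard ratios so that end-to-end recovery of known
effects can be exercised without any restricted study data.
Reference levels are always the most disadvantaged group.
"""

from __future__ import annotations

from typing import Mapping, Optional

import numpy as np
import yaml

from .intensity import IntensityModel
from .structures import AGE, Covariate, CovariateSpec, TransitionStructure

#: Fixture baseline per-year intensities (not estimates from any dataset);
#: chosen so transition abundances are ordered realistically: 1<->2 common,
#: 2->3 moderate, 1->3 rare, death rates highest from dementia.
DEFAULT_Q0 = {
    (1, 2): 0.25,
    (2, 1): 0.15,
    (1, 3): 0.002,
    (2, 3): 0.05,
    (1, 4): 0.02,
    (2, 4): 0.06,
    (3, 4): 0.30,
}

#: Shared age-band log-offsets for bands beyond the first (<60 reference).
DEFAULT_AGE_OFFSETS = (0.3, 0.6, 0.9)

#: Effect sizes of the calibrated scenario, as hazard ratios vs the most
#: disadvantaged reference level.
CALIBRATED_HR = {
    (1, 2): {
        "education": {"middle": 0.73, "high": 0.57},
        "occupation": {"intermediate": 0.82, "professional": 0.67},
        "wealth": {"middle": 0.86, "high": 0.68},
    },
    (2, 1): {
        "education": {"middle": 1.37, "high": 1.81},
        "occupation": {"intermediate": 1.46, "professional": 1.81},
        "wealth": {"middle": 1.29, "high": 1.56},
    },
    (2, 3): {
        "education": {"middle": 0.38, "high": 0.31},
        "occupation": {"intermediate": 0.80, "professional": 0.63},
        "wealth": {"middle": 0.98, "high": 0.74},
    },
    (1, 3): {
        "education": {"middle": 0.81, "high": 0.91},
        "occupation": {"intermediate": 0.91, "professional": 0.88},
        "wealth": {"middle": 0.90, "high": 0.87},
    },
    (3, 4): {
        "education": {"middle": 0.69, "high": 0.61},
        "occupation": {"intermediate": 1.03, "professional": 0.96},
        "wealth": {"middle": 1.18, "high": 0.98},
    },
}

SEP_COVARIATES = ("education", "occupation", "wealth")
SEP_TRANSITIONS = ((1, 2), (2, 1), (1, 3), (2, 3), (3, 4))
#: transitions adjusted for demographics (all but the two dementia entries)
DEMOG_TRANSITIONS = ((1, 2), (2, 1), (1, 4), (2, 4), (3, 4))


def default_structure() -> TransitionStructure:
    return TransitionStructure.default()


def default_covariates(include_demographics: bool = True) -> tuple:
    covs = [
        Covariate("education", ("low", "middle", "high"), "low"),
        Covariate("occupation", ("manual", "intermediate", "professional"), "manual"),
        Covariate("wealth", ("low", "middle", "high"), "low"),
    ]
    if include_demographics:
        covs.append(Covariate("sex", ("male", "female"), "male"))
        covs.append(Covariate("marital", ("married", "single"), "married"))
    return tuple(covs)


def default_spec(
    include_demographics: bool = True, age_bands=(60.0, 70.0, 80.0)
) -> CovariateSpec:
    """Default per-transition design: socioeconomic covariates on the five
    reported transitions, demographics and age bands everywhere except the
    two transitions into dementia."""
    design: dict = {}
    for t in default_structure().transitions:
        names: list = []
        if t in SEP_TRANSITIONS:
            names.extend(SEP_COVARIATES)
        if t in DEMOG_TRANSITIONS:
            names.append(AGE)
            if include_demographics:
                names.extend(["sex", "marital"])
        design[t] = tuple(names)
    return CovariateSpec(
        covariates=default_covariates(include_demographics),
        design=design,
        age_bands=age_bands,
    )


def baseline_model(spec: Optional[CovariateSpec] = None) -> IntensityModel:
    """Default fixture model with all covariate effects at zero."""
    if spec is None:
        spec = default_spec()
    return IntensityModel(
        structure=default_structure(),
        spec=spec,
        log_q0={t: float(np.log(q)) for t, q in DEFAULT_Q0.items()},
        beta={},
        age_offsets=np.array(DEFAULT_AGE_OFFSETS),
    )


def calibrated_model(include_demographics: bool = False) -> IntensityModel:
    """The calibrated simulation scenario: fixture baseline intensities
    plus the calibrated socioeconomic log hazard ratios (demographic
    effects are zero, so they are excluded from the design by default)."""
    spec = default_spec(include_demographics=include_demographics)
    model = baseline_model(spec)
    beta: dict = {}
    for trans, covs in CALIBRATED_HR.items():
        beta[trans] = {}
        for cname, by_level in covs.items():
            cov = spec[cname]
            beta[trans][cname] = np.array(
                [float(np.log(by_level[lv])) for lv in cov.dummy_levels]
            )
    model.beta = beta
    return model


# -- serialisation ------------------------------------------------------


def _tkey(trans) -> str:
    return f"{trans[0]}-{trans[1]}"


def _tpair(key: str) -> tuple:
    r, s = key.split("-")
    return (int(r), int(s))


def model_to_dict(model: IntensityModel) -> dict:
    st, spec = model.structure, model.spec
    return {
        "states": list(st.state_names or [str(i + 1) for i in range(st.n_states)]),
        "absorbing": [i + 1 for i, a in enumerate(st.absorbing) if a],
        "transitions": [_tkey(t) for t in st.transitions],
        "age_bands": list(spec.age_bands),
        "covariates": [
            {
                "name": c.name,
                "levels": list(c.levels) if c.levels else None,
                "reference": c.reference,
            }
            for c in spec.covariates
        ],
        "design": {_tkey(t): list(spec.design_for(t)) for t in st.transitions},
        "parameters": {
            "log_q0": {_tkey(t): float(v) for t, v in model.log_q0.items()},
            "beta": {
                _tkey(t): {
                    cname: {
                        (lv if lv is not None else "value"): float(v)
                        for lv, v in zip(spec[cname].dummy_levels, np.atleast_1d(vec))
                    }
                    for cname, vec in covs.items()
                }
                for t, covs in model.beta.items()
            },
            "age_offsets": [float(v) for v in model.age_offsets],
            "zero_rates": [_tkey(t) for t in sorted(model.zero_rates)],
        },
    }


def model_from_dict(d: Mapping) -> IntensityModel:
    n = len(d["states"])
    absorbing = tuple(i + 1 in set(d.get("absorbing", [])) for i in range(n))
    structure = TransitionStructure(
        n_states=n,
        allowed=frozenset(_tpair(k) for k in d["transitions"]),
        absorbing=absorbing,
        state_names=tuple(d["states"]),
    )
    covariates = tuple(
        Covariate(
            c["name"],
            tuple(c["levels"]) if c.get("levels") else None,
            c.get("reference"),
        )
        for c in d.get("covariates", [])
    )
    spec = CovariateSpec(
        covariates=covariates,
        design={_tpair(k): tuple(v) for k, v in d.get("design", {}).items()},
        age_bands=tuple(d.get("age_bands", ())),
    )
    params = d.get("parameters", {})
    beta: dict = {}
    for tk, covs in params.get("beta", {}).items():
        trans = _tpair(tk)
        beta[trans] = {}
        for cname, by_level in covs.items():
            cov = spec[cname]
            if cov.is_categorical:
                beta[trans][cname] = np.array(
                    [float(by_level[lv]) for lv in cov.dummy_levels]
                )
            else:
                beta[trans][cname] = np.array([float(by_level["value"])])
    return IntensityModel(
        structure=structure,
        spec=spec,
        log_q0={_tpair(k): float(v) for k, v in params.get("log_q0", {}).items()},
        beta=beta,
        age_offsets=np.array(params.get("age_offsets", [0.0] * (spec.n_bands - 1))),
        zero_rates=frozenset(_tpair(k) for k in params.get("zero_rates", [])),
    )


def save_model(model: IntensityModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(model), fh, sort_keys=False)


def load_model(path) -> IntensityModel:
    with open(path) as fh:
        return model_from_dict(yaml.safe_load(fh))
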