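"""Physical constants and frozen empirical coefficients.

All internal units are CGS (cm, g, s) with particle diameters handled in µm
at the API boundary.  The values below are recorded in one place so that
every results file can echo the exact constants a run used, and so that a
sensitivity analysis can override them from a YAML file.
"""

from __future__ import annotations

import hashlib
import json
from typing import Any

import yaml

#: Boltzmann constant, erg/K.
BOLTZMANN_ERG_PER_K = 1.380649e-16

#: Default gas conditions inside the airway lumen (body conditions, 37 °C).
DEFAULT_GAS = {
    "temperature_k": 310.0,
    "air_viscosity_g_cm_s": 1.89e-4,
    "mean_free_path_um": 0.0712,
    "gravity_cm_s2": 981.0,
}

#: Rat inhalability curve, logistic in ln(d_ae):
#: IF(d) = 1 - 1/(1 + exp(a - b*ln(d_ae[µm]))).
#: Coefficients fixed once so that the mass-weighted inhalable fraction of
#: the two study atmospheres (MMAD 2.74 µm/GSD 2.8 and MMAD 2.01 µm/GSD 3.0)
#: falls in the 74-78 % band reported for resting rats.
RAT_INHALABILITY = {"a": 1.77952141, "b": 0.61169607}

#: Particle diameter (µm) above which human inhalability starts to fall off.
#: The study aerosols sit well below it, so the human curve is unity there.
HUMAN_INHALABILITY_CUTOFF_UM = 10.0

#: Extrathoracic (head) deposition coefficients per (species, route):
#: eta = 1 - exp(-a * (d_ae^2 * Q)^b), d_ae in µm, Q = mean inspiratory
#: flow in L/min.  Exponents b follow published impaction-parameter
#: correlations for the nasal and oral passages; the prefactors a are fixed
#: once against the whole-lung model's regional head depositions for the
#: study aerosol (51.3 % nasal / 14.3 % oral of inhaled mass in humans,
#: ~34.5 % of inhalable mass in rats breathing nose-only).
EXTRATHORACIC = {
    ("human", "nasal"): {"a": 1.7000393215e-3, "b": 1.17},
    ("human", "oral"): {"a": 2.0031994448e-5, "b": 1.40},
    ("rat", "nasal"): {"a": 2.9025181193e-2, "b": 1.17},
    ("rat", "nose-only"): {"a": 2.9025181193e-2, "b": 1.17},
}

#: Extrathoracic (head) dead-space volume, cm³: the fresh-aerosol front only
#: reaches the trachea after this volume has been displaced, which limits how
#: deep into the acinus the tidal plug can penetrate.
ET_DEAD_SPACE_CM3 = {"human": 50.0, "rat": 0.42}

#: Characteristic alveolar radius, cm (human alveoli ~210 µm across, rat
#: ~90 µm); sets the settling length scale for aerosol captured in the
#: alveolar sleeves.
ALVEOLUS_RADIUS_CM = {"human": 0.0105, "rat": 0.0045}

#: Lognormal discretization defaults: geometric bins over mmad*gsd^(±span).
N_BINS_DEFAULT = 1000
SPAN_SIGMAS_DEFAULT = 4.0

#: Gravity angle (degrees from the gravity vector) substituted when a
#: geometry table carries no orientation data: the mean of |cos| over an
#: isotropically oriented tube maps to this angle.
DEFAULT_GRAVITY_ANGLE_DEG = 38.24


def constants_dict() -> dict[str, Any]:
    """All tunable constants as one plain dict (for manifests and overrides)."""
    return {
        "gas": dict(DEFAULT_GAS),
        "rat_inhalability": dict(RAT_INHALABILITY),
        "human_inhalability_cutoff_um": HUMAN_INHALABILITY_CUTOFF_UM,
        "extrathoracic": {
            f"{sp}:{route}": dict(c) for (sp, route), c in EXTRATHORACIC.items()
        },
        "et_dead_space_cm3": dict(ET_DEAD_SPACE_CM3),
        "n_bins_default": N_BINS_DEFAULT,
        "span_sigmas_default": SPAN_SIGMAS_DEFAULT,
        "default_gravity_angle_deg": DEFAULT_GRAVITY_ANGLE_DEG,
    }


def config_hash(extra: dict[str, Any] | None = None) -> str:
    """Short stable hash of the constants (plus any run config) for manifests."""
    payload = constants_dict()
    if extra:
        payload = {"constants": payload, "run": extra}
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def dump_constants(path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(constants_dict(), fh, sort_keys=True)


def load_constants(path) -> dict[str, Any]:
    """Load a constants override file; unknown keys are rejected."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = set(constants_dict())
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown constant keys: {sorted(unknown)}")
    return data
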