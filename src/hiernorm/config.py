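"""Configuration schema: one nested dict, YAML-serializable.

``default_config()`` returns the calibrated defaults; ``load_config``
merges a user YAML file over them (shallow per section).  ``build_circuit``
materializes a two- or three-area hierarchy plus the noise model from a
config dict.
"""

from __future__ import annotations

import copy
import hashlib
import json

import yaml

from .network import Connectivity, RingGeometry
from .noise import NoiseSpec
from .params import AreaParameters

__all__ = ["default_config", "load_config", "build_circuit", "config_hash"]


def default_config() -> dict:
    return {
        "circuit": {
            "n_neurons": 72,
            "tuning_half_width": 40.0,
            "excit_width": 45.0,
            "inhib_width": 90.0,
            "inhib_strength": 0.5,
            "feedback_width": 15.0,
            "diag_boost": 2.0,
            "feedback_row_sum": 0.75,
            "areas": 2,  # 2 -> V1/V2, 3 -> V1/V4/V5
        },
        "params": {
            "tau_y": 1.0,
            "tau_u": 1.0,
            "tau_a": 1.0,
            "tau_q": 1.0,
            "alpha": 10.0,
            "sigma": 0.07,
            "pool_rate": 2.0,
        },
        "gains": {"beta": 1.0, "gamma": 1.0, "gamma_v4": 1.0, "gamma_v5": 1.0},
        "noise": {
            "synaptic_amp": 1.0,
            "tau_noise": 1.0,
            "mult_amp": 0.5,
            "modulator_frac": 1.0,
            "extrinsic_amp": 0.05,
            "extrinsic_corr": 0.5,
            "seed": 0,
        },
        "stimulus": {"orientation": 90.0},
        "experiment": {
            "contrasts": [0, 1, 3, 6, 10, 12, 25, 40, 50, 75, 100],
            "gamma_grid": [0.1, 0.25, 0.5, 1.0, 1.1],
            "beta_grid": [0.5, 1.0, 1.5, 2.0],
            "freq_min": 1.0,
            "freq_max": 1000.0,
            "freq_step": 1.0,
            "subset_size": 30,
            "n_repeats": 25,
            "seed": 0,
        },
    }


def load_config(path=None) -> dict:
    cfg = default_config()
    if path is not None:
        with open(path) as f:
            user = yaml.safe_load(f) or {}
        if not isinstance(user, dict):
            raise ValueError(f"config root must be a mapping, got {type(user)}")
        for section, values in user.items():
            if section not in cfg:
                raise ValueError(f"unknown config section {section!r}")
            if not isinstance(values, dict):
                raise ValueError(f"config section {section!r} must be a mapping")
            for key, val in values.items():
                if key not in cfg[section]:
                    raise ValueError(f"unknown key {section}.{key}")
                cfg[section][key] = val
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=float).encode()
    ).hexdigest()[:16]


def build_circuit(cfg: dict):
    """Build (spec, noise) from a config dict."""
    from .dynamics import three_area, two_area

    c = cfg["circuit"]
    geometry = RingGeometry(int(c["n_neurons"]))
    conn = Connectivity.default(
        geometry,
        tuning_half_width=c["tuning_half_width"],
        excit_width=c["excit_width"],
        inhib_width=c["inhib_width"],
        inhib_strength=c["inhib_strength"],
        feedback_width=c["feedback_width"],
        diag_boost=c["diag_boost"],
        feedback_row_sum=c["feedback_row_sum"],
    )
    params = AreaParameters(**cfg["params"])
    g = cfg["gains"]
    if int(c["areas"]) == 2:
        spec = two_area(
            geometry, conn, params, beta=g["beta"], gamma=g["gamma"]
        )
    elif int(c["areas"]) == 3:
        spec = three_area(
            gamma_v4=g["gamma_v4"],
            gamma_v5=g["gamma_v5"],
            geometry=geometry,
            conn=conn,
            params=params,
            beta=g["beta"],
        )
    else:
        raise ValueError("circuit.areas must be 2 or 3")
    noise = NoiseSpec(**cfg["noise"])
    return spec, noise
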