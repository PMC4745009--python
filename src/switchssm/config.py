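"""YAML/JSON configuration schemas for scenarios and fits.

A config file is a mapping with a ``kind`` key (``scenario`` or ``fit``);
remaining keys mirror :class:`~switchssm.simulator.Scenario` and
:class:`~switchssm.inference.FitConfig`.  Unknown keys are rejected with a
closest-match suggestion; omitted keys inherit the documented defaults
(1 h time step, 2 chains, reference scenario parameters).
"""

from __future__ import annotations

import difflib
import json
from pathlib import Path

import numpy as np
import yaml

from ._sampler import Priors
from .inference import FitConfig
from .model_core import ObsParams, ProcessParams, build_transition_matrix
from .simulator import Scenario, default_argos_classes

__all__ = ["load_config"]

_SCENARIO_KEYS = {
    "kind",
    "delta_gamma_label",
    "error_regime",
    "n_tracks",
    "track_length",
    "seed",
    "params",
    "obs",
    "argos_class_probs",
}
_PARAM_KEYS = {
    "gamma1",
    "gamma2",
    "theta1",
    "theta2",
    "alpha1",
    "alpha2",
    "sigma_sd",
    "sigma_x",
    "sigma_y",
    "rho",
}
_OBS_KEYS = {"omega_sd", "classes"}
_FIT_KEYS = {
    "kind",
    "model_form",
    "time_step",
    "n_chains",
    "n_iter",
    "n_burnin",
    "thin",
    "seed",
    "estimate_psi",
    "priors",
    "monitor",
}
_PRIOR_KEYS = {
    "sigma_scale",
    "sigma_df",
    "psi_max",
    "anchor_sd",
    "theta1_range",
    "theta2_range",
}


def _check_keys(mapping: dict, allowed: set, context: str) -> None:
    for key in mapping:
        if key not in allowed:
            hint = difflib.get_close_matches(key, allowed, n=1)
            suggestion = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ValueError(f"unknown key {key!r} in {context}{suggestion}")


def load_config(path) -> Scenario | FitConfig:
    """Load and validate a scenario or fit configuration file."""
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(raw, dict) or "kind" not in raw:
        raise ValueError("config must be a mapping with a 'kind' key")
    kind = raw["kind"]
    if kind == "scenario":
        return _scenario_from(raw)
    if kind == "fit":
        return _fit_from(raw)
    raise ValueError(f"unknown config kind {kind!r} (expected 'scenario' or 'fit')")


def _scenario_from(raw: dict) -> Scenario:
    _check_keys(raw, _SCENARIO_KEYS, "scenario config")
    kwargs = {
        k: raw[k]
        for k in ("delta_gamma_label", "error_regime", "n_tracks", "track_length", "seed")
        if k in raw
    }
    if "params" in raw:
        p = dict(raw["params"])
        _check_keys(p, _PARAM_KEYS, "scenario params")
        if "sigma_sd" in p:
            sx = sy = float(p.pop("sigma_sd"))
        else:
            sx = float(p.pop("sigma_x", 5.0))
            sy = float(p.pop("sigma_y", 5.0))
        rho = float(p.pop("rho", 0.0))
        cov = rho * sx * sy
        kwargs["params"] = ProcessParams(
            gamma=(p.get("gamma1", 0.95), p.get("gamma2", 0.10)),
            theta=(p.get("theta1", 0.0), p.get("theta2", float(np.pi))),
            sigma=np.array([[sx**2, cov], [cov, sy**2]]),
            alpha=build_transition_matrix(p.get("alpha1", 0.90), p.get("alpha2", 0.10)),
        )
    regime = kwargs.get("error_regime", raw.get("error_regime"))
    if "obs" in raw:
        o = dict(raw["obs"])
        _check_keys(o, _OBS_KEYS, "scenario obs")
        if regime == "gps":
            sd = float(o.get("omega_sd", 0.05))
            kwargs["obs"] = ObsParams(regime="gps", omega=np.eye(2) * sd**2)
        elif regime == "argos":
            table = o.get("classes")
            if table is None:
                table = default_argos_classes()
                tau, nu = table["tau"], table["nu"]
            else:
                tau = {q: (row["tau_x"], row["tau_y"]) for q, row in table.items()}
                nu = {q: float(row["nu"]) for q, row in table.items()}
            kwargs["obs"] = ObsParams(regime="argos", tau=tau, nu=nu)
    return Scenario(**kwargs)


def _fit_from(raw: dict) -> FitConfig:
    _check_keys(raw, _FIT_KEYS, "fit config")
    kwargs = {k: v for k, v in raw.items() if k not in ("kind", "priors", "monitor")}
    if "priors" in raw:
        p = dict(raw["priors"])
        _check_keys(p, _PRIOR_KEYS, "fit priors")
        for key in ("theta1_range", "theta2_range"):
            if key in p:
                p[key] = tuple(float(v) for v in p[key])
        kwargs["priors"] = Priors(**p)
    if "monitor" in raw:
        kwargs["monitor"] = tuple(raw["monitor"])
    return FitConfig(**kwargs)
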