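"""Configuration parsing and result serialization.

Config files are YAML or JSON.  A belief document looks like::

    labels: ["A+B", "A+C"]
    means: [0.2877, 0.2877]
    variances: [0.08, 0.08]
    correlation: 0.6          # scalar (n=2) or full matrix

A design is either ``{alpha, information}`` or
``{alpha, power, target_effect}`` (or ``target_hr``, converted with the
natural log).  A scenario document mirrors :class:`SimScenario` fields.
Defaults: alpha 0.05, go threshold 0.6, prior mixture weights 0.5/0.5.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import pandas as pd
import yaml

from .beliefs import MvnBelief, PlannedDesign
from .simulate import SimResult, SimScenario

__all__ = [
    "load_document",
    "parse_belief",
    "parse_design",
    "parse_scenario",
    "parse_config",
    "write_results",
]


class ConfigError(ValueError):
    """A configuration document violates the schema."""


def load_document(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def parse_belief(doc: dict) -> MvnBelief:
    for key in ("means", "variances"):
        if key not in doc:
            raise ConfigError(f"belief document missing required field '{key}'")
    return MvnBelief.from_dict(doc)


def parse_design(doc: dict) -> PlannedDesign:
    alpha = doc.get("alpha", 0.05)
    if "information" in doc:
        return PlannedDesign(alpha=alpha, information=float(doc["information"]))
    if "power" in doc and ("target_effect" in doc or "target_hr" in doc):
        effect = (
            float(doc["target_effect"])
            if "target_effect" in doc
            else -math.log(float(doc["target_hr"]))
        )
        return PlannedDesign.from_power(alpha, float(doc["power"]), effect)
    raise ConfigError(
        "design needs either 'information' or ('power' and 'target_effect'/'target_hr')"
    )


def parse_scenario(doc: dict) -> SimScenario:
    design = parse_design(doc.get("design", {"alpha": 0.05, "information": 125.0}))
    known = {
        "mu1", "mu2", "prior_var", "rho", "theta_true", "v_obs",
        "threshold", "n_reps", "seed", "w00", "w10",
    }
    unknown = set(doc) - known - {"design"}
    if unknown:
        raise ConfigError(f"unknown scenario fields: {sorted(unknown)}")
    kwargs = {k: doc[k] for k in known if k in doc}
    if "theta_true" in kwargs:
        kwargs["theta_true"] = tuple(kwargs["theta_true"])
    try:
        return SimScenario(design=design, **kwargs)
    except (TypeError, ValueError) as err:
        raise ConfigError(str(err)) from err


def parse_config(path: str | Path) -> dict:
    """Parse a config file into typed objects.

    Recognized top-level sections: ``belief`` (or ``prior``), ``design``,
    ``scenario``.  Returns a dict with whichever objects were present.
    """
    doc = load_document(path)
    out: dict = {}
    belief_doc = doc.get("belief", doc.get("prior"))
    if belief_doc is not None:
        out["belief"] = parse_belief(belief_doc)
    if "design" in doc:
        out["design"] = parse_design(doc["design"])
    if "scenario" in doc:
        out["scenario"] = parse_scenario(doc["scenario"])
    if not out:
        raise ConfigError("config contains none of: belief/prior, design, scenario")
    return out


def write_results(results, path: str | Path, format: str = "csv") -> Path:
    """Write results losslessly; CSV uses full double precision (repr)."""
    path = Path(path)
    if isinstance(results, SimResult):
        frame = results.summary.copy()
        frame.insert(0, "scenario_seed", results.scenario.seed)
    elif isinstance(results, pd.DataFrame):
        frame = results
    else:
        if format != "json":
            raise ConfigError("non-tabular results can only be written as JSON")
        path.write_text(json.dumps(results, indent=2))
        return path
    if format == "csv":
        frame.to_csv(path, index=False, float_format="%.17g")
    elif format == "json":
        path.write_text(frame.to_json(orient="records", double_precision=15))
    else:
        raise ConfigError(f"unknown output format {format!r}")
    return path
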