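"""Model coefficients with units and invariants.

Two parameter sets are used by the simulator:

* :class:`CombinedParameters` — the coefficients of the combined
  antiangiogenic (AG) + immunotherapy (IM) + radiotherapy (RT) tumor model,
  identified from mouse studies.  All rates are per day, concentrations in
  mg/mL, RT dose rates in Gy/day and volumes in mm³.
* :class:`LegacyAGParameters` — the coefficients of the earlier
  Bevacizumab-only tumor growth model (Michaelis–Menten clearance plus a
  saturable inhibition term), kept as a validation reference.

Defaults are returned by :func:`default_combined_parameters` and
:func:`default_legacy_parameters`; user overrides come in through
:func:`load_parameters` which accepts a mapping, a JSON document or flat
``key = value`` text and re-validates every invariant.
"""

from __future__ import annotations

import configparser
import dataclasses
import json
import os
from dataclasses import dataclass
from typing import Any, Mapping

from .errors import ConfigurationError, ValidationError

__all__ = [
    "CombinedParameters",
    "LegacyAGParameters",
    "default_combined_parameters",
    "default_legacy_parameters",
    "load_parameters",
]


def _require(condition: bool, field: str, message: str) -> None:
    if not condition:
        raise ValidationError(f"{field}: {message}")


@dataclass(frozen=True)
class CombinedParameters:
    """Coefficients of the combined three-therapy tumor model.

    Attributes
    ----------
    a : float
        Tumor growth rate, 1/day.
    n : float
        Necrosis (reaction) rate, 1/day.
    c_a, c_i, c_r : float
        Clearance rates for the AG drug, the IM drug and the RT drive,
        1/day.  ``c_i`` is stored as a plain rate assuming a unit (1 mL)
        distribution volume.
    C50_a, C50_i : float
        Half-effect concentrations of the AG and IM drugs, mg/mL.
    C50_r : float
        Half-effect RT dose rate, Gy/day.
    C50_t : float
        Half-effect tumor level, percent of the initial volume.
    Emax_a, Emax_i, Emax_r : float
        Maximum efficacies as fractions in [0, 1].
    gamma : float
        Hill sigmoidicity exponent; the patient response/resistance dial.
    sigma : float
        Drug synergy coefficient in the interaction index.
    V0 : float
        Initial proliferating tumor volume, mm³.
    unit_rate : float
        Conversion of the dimensionless combined effect E to a kill rate,
        1/day.  The Hill surfaces are dimensionless; multiplying by
        ``unit_rate`` (default 1.0/day) yields the rate that enters the
        tumor balance.
    """

    a: float
    n: float
    c_a: float
    c_i: float
    c_r: float
    C50_a: float
    C50_i: float
    C50_r: float
    C50_t: float
    Emax_a: float
    Emax_i: float
    Emax_r: float
    gamma: float
    sigma: float
    V0: float
    unit_rate: float = 1.0

    def __post_init__(self) -> None:
        for f in ("a", "n", "c_a", "c_i", "c_r"):
            _require(getattr(self, f) >= 0, f, "rate must be >= 0")
        for f in ("C50_a", "C50_i", "C50_r", "C50_t"):
            _require(getattr(self, f) > 0, f, "half-effect level must be > 0")
        for f in ("Emax_a", "Emax_i", "Emax_r"):
            _require(0.0 <= getattr(self, f) <= 1.0, f, "Emax must lie in [0, 1]")
        _require(self.gamma > 0, "gamma", "sigmoidicity must be > 0")
        _require(self.sigma >= 0, "sigma", "synergy coefficient must be >= 0")
        _require(self.V0 > 0, "V0", "initial volume must be > 0")
        _require(self.unit_rate >= 0, "unit_rate", "rate conversion must be >= 0")

    def replace(self, **overrides: float) -> "CombinedParameters":
        """Return a copy with ``overrides`` applied (re-validated)."""
        unknown = set(overrides) - {f.name for f in dataclasses.fields(self)}
        if unknown:
            raise ConfigurationError(
                f"unknown parameter field(s): {', '.join(sorted(unknown))}"
            )
        return dataclasses.replace(self, **overrides)

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class LegacyAGParameters:
    """Coefficients of the Bevacizumab-only tumor growth model.

    ``b_ak`` is the product of the reaction rate ``b_a`` and a unit
    normalization rate k; it scales the drug-consumption term of the
    inhibitor balance.  ``K_Ba`` is the Michaelis–Menten constant of the
    inhibitor clearance and ``ED50_a`` the half-effect concentration of the
    saturable inhibition term.  Units: rates 1/day, concentrations mg/mL,
    ``b_ak`` in mg/(mL·day).
    """

    a: float
    b_a: float
    c_a: float
    n_a: float
    b_ak: float
    K_Ba: float
    ED50_a: float

    def __post_init__(self) -> None:
        for f in ("a", "b_a", "c_a", "n_a", "b_ak", "K_Ba", "ED50_a"):
            _require(getattr(self, f) > 0, f, "must be > 0")

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


def default_combined_parameters() -> CombinedParameters:
    """Default coefficient set of the combined model (mouse studies).

    Maximum efficacies are stored as fractions (0.70, 0.43, 0.50) of their
    percent values.  The IM clearance 11.6/24 is a literature clearance of
    11.6 mL/h re-expressed per day and interpreted as a rate for a unit
    distribution volume.
    """
    return CombinedParameters(
        a=0.25,
        n=0.10,
        c_a=0.1825,
        c_i=11.6 / 24.0,
        c_r=3.0 / 24.0,
        C50_a=0.44,
        C50_i=32e-6,
        C50_r=20.0,
        C50_t=50.0,
        Emax_a=0.70,
        Emax_i=0.43,
        Emax_r=0.50,
        gamma=2.5,
        sigma=4.0,
        V0=1000.0,
        unit_rate=1.0,
    )


def default_legacy_parameters() -> LegacyAGParameters:
    """Averaged mouse-identified coefficients for Bevacizumab monotherapy."""
    return LegacyAGParameters(
        a=0.4579,
        b_a=0.1685,
        c_a=0.1825,
        n_a=0.1030,
        b_ak=1.0839e-6,
        K_Ba=0.4409,
        ED50_a=50e-6,
    )


def _parse_document(text: str) -> dict[str, Any]:
    stripped = text.lstrip()
    if stripped.startswith("{"):
        try:
            parsed = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ConfigurationError(f"malformed JSON config: {exc}") from exc
        if not isinstance(parsed, dict):
            raise ConfigurationError("config JSON must be an object of key/value pairs")
        return parsed
    # INI-style: accept either a bare [parameters] section or header-less lines
    parser = configparser.ConfigParser()
    body = text if stripped.startswith("[") else "[parameters]\n" + text
    try:
        parser.read_string(body)
    except configparser.Error as exc:
        raise ConfigurationError(f"malformed config document: {exc}") from exc
    out: dict[str, Any] = {}
    for section in parser.sections():
        for key, value in parser.items(section):
            out[key] = value
    return out


_FIELD_NAMES = {f.name for f in dataclasses.fields(CombinedParameters)}
# configparser lower-cases keys; map them back to canonical field names
_CANONICAL = {name.lower(): name for name in _FIELD_NAMES}


def load_parameters(
    source: Mapping[str, Any] | str | os.PathLike | None = None,
    base: CombinedParameters | None = None,
) -> CombinedParameters:
    """Merge a flat key/value config into the default combined parameters.

    ``source`` may be a mapping, a path to a JSON/INI file, or the document
    text itself.  Keys must be CombinedParameters field names; values are
    coerced to float.  Unknown keys raise :class:`ConfigurationError`;
    out-of-range values raise :class:`ValidationError` naming the field.
    """
    if base is None:
        base = default_combined_parameters()
    if source is None:
        return base
    if isinstance(source, Mapping):
        raw = dict(source)
    else:
        if isinstance(source, os.PathLike) or (
            isinstance(source, str) and os.path.exists(source)
        ):
            with open(source, "r", encoding="utf-8") as fh:
                text = fh.read()
        else:
            text = str(source)
        raw = _parse_document(text)

    overrides: dict[str, float] = {}
    for key, value in raw.items():
        name = _CANONICAL.get(str(key).lower())
        if name is None:
            raise ConfigurationError(f"unknown parameter key: {key!r}")
        try:
            overrides[name] = float(value)
        except (TypeError, ValueError) as exc:
            raise ConfigurationError(f"{key}: not a number ({value!r})") from exc
    return base.replace(**overrides)
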