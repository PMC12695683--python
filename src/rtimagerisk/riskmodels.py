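"""Scalar radiobiological models over DVH inputs.

Implements the dose-response machinery used to assess cumulative imaging
dose:

* logistic NTCP on mean dose,  NTCP = 1 / (1 + exp(gamma * (D50 - D)));
* LKB (probit) NTCP on gEUD,   NTCP = Phi((gEUD - D50) / (m * D50));
* generalized EUD,             gEUD = (sum_i v_i D_i^(1/n))^n;
* Schneider's organ equivalent dose with linear-exponential cell kill,
  OED = sum_i v_i D_i exp(-alpha' D_i);
* BEIR VII-style excess absolute risk with age modification,
  EAR = EAR0 * OED * mu(e, a),  mu = exp[gamma_e (e - e0)] * (a / a0)^gamma_a.

Sums run over differential-DVH bin midpoints. A 1 Gy photon dose is treated
as 1 Sv (configurable via ``gy_to_sv``). Organ-specific parameters come from
a JSON registry; every entry carries a literature citation and user files
merge over the shipped defaults.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.special import expit, ndtr

from .dvh import DifferentialDVH
from .errors import ParameterError, RegistrySchemaError

#: default cell-sterilization parameter (1/Gy) of the linear-exponential
#: OED mechanism, applied to all organs
DEFAULT_ALPHA_PRIME = 0.085

#: reference age at exposure and attained age (years) at which mu(e, a) = 1
DEFAULT_E0 = 30.0
DEFAULT_A0 = 70.0

#: photon dose equivalence, Sv per Gy
DEFAULT_GY_TO_SV = 1.0


@dataclass(frozen=True)
class NTCPParams:
    """Organ-specific complication-model parameters.

    ``gamma`` is the logistic slope in 1/Gy; ``m`` and ``n`` are the
    unitless LKB slope and volume-effect exponent.
    """

    organ: str
    model: str  # "logistic" | "lkb"
    d50: float
    gamma: float | None = None
    m: float | None = None
    n: float | None = None
    source: str = ""

    def __post_init__(self):
        if self.model not in ("logistic", "lkb"):
            raise ParameterError(f"unknown NTCP model {self.model!r}")
        if self.d50 <= 0:
            raise ParameterError("d50 must be positive")
        if self.model == "logistic" and (self.gamma is None or self.gamma <= 0):
            raise ParameterError("logistic model requires gamma > 0")
        if self.model == "lkb":
            if self.m is None or self.m <= 0:
                raise ParameterError("lkb model requires m > 0")
            if self.n is None or not 0 < self.n <= 1:
                raise ParameterError("lkb model requires 0 < n <= 1")


@dataclass(frozen=True)
class EARParams:
    """Organ-specific excess-absolute-risk parameters.

    ``ear0`` is the baseline excess cases per 10 000 person-years per Sv at
    the reference ages; ``gamma_e`` (per year) and ``gamma_a`` (exponent)
    modify risk with age at exposure and attained age.
    """

    organ: str
    ear0: float
    alpha_prime: float = DEFAULT_ALPHA_PRIME
    gamma_e: float = 0.0
    gamma_a: float = 0.0
    e0: float = DEFAULT_E0
    a0: float = DEFAULT_A0
    source: str = ""

    def __post_init__(self):
        if self.ear0 < 0:
            raise ParameterError("ear0 must be non-negative")
        if self.alpha_prime < 0:
            raise ParameterError("alpha_prime must be non-negative")
        if self.a0 <= 0:
            raise ParameterError("a0 must be positive")


def gamma_from_gamma50(gamma50: float, d50: float) -> float:
    """Convert the normalized dose-response slope gamma50 to the logistic
    slope in 1/Gy: gamma = 4 * gamma50 / D50."""
    if d50 <= 0:
        raise ParameterError("d50 must be positive")
    return 4.0 * gamma50 / d50


def ntcp_logistic(mean_dose: float, params: NTCPParams) -> float:
    """Logistic NTCP on mean dose: 1 / (1 + exp(gamma * (D50 - D))).

    Evaluated via the numerically stable logistic sigmoid, so extreme
    arguments underflow to 0 or saturate at 1 without overflow.
    """
    if params.model != "logistic":
        raise ParameterError("params.model must be 'logistic'")
    if mean_dose < 0:
        raise ParameterError("dose must be non-negative")
    return float(expit(params.gamma * (mean_dose - params.d50)))


def geud(dvh: DifferentialDVH, n: float) -> float:
    """Generalized equivalent uniform dose over DVH bin midpoints.

    gEUD = (sum_i v_i D_i^(1/n))^n. Equals the (midpoint) mean dose at
    n = 1 and approaches the maximum dose as n -> 0+.
    """
    if n <= 0:
        raise ParameterError("volume-effect exponent n must be positive")
    d = dvh.bin_midpoints
    v = dvh.volume_fraction
    return float(np.dot(v, d ** (1.0 / n)) ** n)


def ntcp_lkb(eud: float, params: NTCPParams) -> float:
    """LKB (probit) NTCP: Phi(t) with t = (EUD - D50) / (m * D50)."""
    if params.model != "lkb":
        raise ParameterError("params.model must be 'lkb'")
    if params.m is None or params.m <= 0:
        raise ParameterError("m must be positive")
    t = (eud - params.d50) / (params.m * params.d50)
    return float(ndtr(t))


def oed(dvh: DifferentialDVH, alpha_prime: float = DEFAULT_ALPHA_PRIME) -> float:
    """Organ equivalent dose with linear-exponential cell sterilization.

    OED = sum_i v_i D_i exp(-alpha' D_i) over DVH bin midpoints; the volume
    fractions v_i absorb the 1/V normalization. With alpha' = 0 this reduces
    to the (midpoint) mean dose, and OED <= mean dose for any alpha' >= 0.
    """
    if alpha_prime < 0:
        raise ParameterError("alpha_prime must be non-negative")
    d = dvh.bin_midpoints
    v = dvh.volume_fraction
    return float(np.dot(v, d * np.exp(-alpha_prime * d)))


def mu_age(e: float, a: float, params: EARParams) -> float:
    """Age-modification factor mu(e, a) = exp[gamma_e (e - e0)] (a/a0)^gamma_a.

    Normalized to 1 at the reference ages (e0, a0); strictly decreasing in
    age at exposure when gamma_e < 0.
    """
    if e >= a:
        raise ParameterError("age at exposure must be below attained age")
    if e <= 0:
        raise ParameterError("age at exposure must be positive")
    return float(np.exp(params.gamma_e * (e - params.e0)) * (a / params.a0) ** params.gamma_a)


def ear(
    oed_value: float,
    age_at_exposure: float,
    params: EARParams,
    attained_age: float = DEFAULT_A0,
    gy_to_sv: float = DEFAULT_GY_TO_SV,
) -> float:
    """Excess absolute risk: EAR = EAR0 * OED * mu(e, a).

    Returned in excess cases per 10 000 person-years. Linear in both OED and
    EAR0; OED in Gy is converted to Sv with ``gy_to_sv`` (1.0 for the photon
    imaging beam).
    """
    if oed_value < 0:
        raise ParameterError("OED must be non-negative")
    return params.ear0 * oed_value * gy_to_sv * mu_age(age_at_exposure, attained_age, params)


# ---------------------------------------------------------------------------
# Parameter registry
# ---------------------------------------------------------------------------

_NTCP_FIELDS = {"model", "d50", "source"}
_EAR_FIELDS = {"ear0", "source"}


@dataclass
class ParameterRegistry:
    """Per-organ NTCP and EAR parameter tables with citation provenance."""

    ntcp: dict
    ear: dict
    meta: dict

    def ntcp_for(self, organ: str) -> NTCPParams:
        try:
            return self.ntcp[organ]
        except KeyError:
            raise KeyError(f"no NTCP parameters registered for organ {organ!r}") from None

    def ear_for(self, organ: str) -> EARParams:
        try:
            return self.ear[organ]
        except KeyError:
            raise KeyError(f"no EAR parameters registered for organ {organ!r}") from None

    @property
    def organs(self):
        return sorted(set(self.ntcp) | set(self.ear))


def _parse_ntcp(organ: str, rec: dict) -> NTCPParams:
    missing = _NTCP_FIELDS - rec.keys()
    if missing:
        raise RegistrySchemaError(
            f"organ {organ!r}: NTCP record missing field(s) {sorted(missing)}"
        )
    if not rec["source"]:
        raise RegistrySchemaError(f"organ {organ!r}: empty source citation")
    gamma = rec.get("gamma")
    if gamma is None and rec.get("gamma50") is not None:
        gamma = gamma_from_gamma50(float(rec["gamma50"]), float(rec["d50"]))
    try:
        return NTCPParams(
            organ=organ,
            model=rec["model"],
            d50=float(rec["d50"]),
            gamma=gamma,
            m=rec.get("m"),
            n=rec.get("n"),
            source=rec["source"],
        )
    except ParameterError as exc:
        raise RegistrySchemaError(f"organ {organ!r}: {exc}") from exc


def _parse_ear(organ: str, rec: dict) -> EARParams:
    missing = _EAR_FIELDS - rec.keys()
    if missing:
        raise RegistrySchemaError(
            f"organ {organ!r}: EAR record missing field(s) {sorted(missing)}"
        )
    if not rec["source"]:
        raise RegistrySchemaError(f"organ {organ!r}: empty source citation")
    try:
        return EARParams(
            organ=organ,
            ear0=float(rec["ear0"]),
            alpha_prime=float(rec.get("alpha_prime", DEFAULT_ALPHA_PRIME)),
            gamma_e=float(rec.get("gamma_e", 0.0)),
            gamma_a=float(rec.get("gamma_a", 0.0)),
            e0=float(rec.get("e0", DEFAULT_E0)),
            a0=float(rec.get("a0", DEFAULT_A0)),
            source=rec["source"],
        )
    except ParameterError as exc:
        raise RegistrySchemaError(f"organ {organ!r}: {exc}") from exc


def _registry_from_dict(doc: dict) -> ParameterRegistry:
    ntcp = {o: _parse_ntcp(o, rec) for o, rec in doc.get("ntcp", {}).items()}
    ear_ = {o: _parse_ear(o, rec) for o, rec in doc.get("ear", {}).items()}
    return ParameterRegistry(ntcp=ntcp, ear=ear_, meta=doc.get("meta", {}))


def load_parameter_registry(path=None) -> ParameterRegistry:
    """Load the organ parameter registry (JSON or YAML).

    With no path, returns the shipped default registry. With a path, the
    user file is merged over the defaults organ-by-organ, so overridden
    organs win and the rest keep their defaults.
    """
    with resources.files("rtimagerisk.data").joinpath("default_registry.json").open() as fh:
        doc = json.load(fh)
    if path is not None:
        text = open(path).read()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            user = yaml.safe_load(text)
        else:
            user = json.loads(text)
        for section in ("ntcp", "ear"):
            doc.setdefault(section, {}).update(user.get(section, {}))
        doc.setdefault("meta", {}).update(user.get("meta", {}))
    return _registry_from_dict(doc)
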