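"""Model parameters for the corticothalamic mean-field unit.

Each unit couples four neural populations — cortical excitatory (e) and
inhibitory (i), thalamic reticular (r) and relay (s) — through synaptic
strengths ``nu_ab`` (V*s, target<-source).  A fifth index ``n`` denotes the
external (noise) drive entering the relay population.  Membrane potentials
are converted to firing rates by a saturating sigmoid, dendrites act as a
second-order low-pass filter with rise rate ``beta_d`` and decay rate
``alpha_d``, and the cortical excitatory field obeys damped axonal dynamics
with rate ``gamma_e``.  The full corticothalamic loop delay ``t0`` is split
equally over the descending (cortex->thalamus) and ascending legs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "CouplingSet",
    "CorticothalamicParams",
    "firing_rate",
    "load_params",
    "save_params",
]

# couplings whose presynaptic population is inhibitory must be <= 0
_INHIBITORY_SOURCED = ("nu_ei", "nu_ii", "nu_sr")


@dataclass(frozen=True)
class CouplingSet:
    """Synaptic coupling strengths ``nu_ab`` (V*s), indexed target<-source.

    Sources ``i`` and ``r`` are inhibitory, so ``nu_ei``, ``nu_ii`` and
    ``nu_sr`` are non-positive; all other couplings are non-negative.
    """

    nu_ee: float
    nu_ei: float
    nu_es: float
    nu_ie: float
    nu_ii: float
    nu_is: float
    nu_re: float
    nu_rs: float
    nu_se: float
    nu_sr: float
    nu_sn: float

    def __post_init__(self) -> None:
        for name in self.field_names():
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
            if name in _INHIBITORY_SOURCED:
                if v > 0:
                    raise ValueError(
                        f"{name} has an inhibitory source and must be <= 0, got {v}"
                    )
            elif v < 0:
                raise ValueError(
                    f"{name} has an excitatory source and must be >= 0, got {v}"
                )

    @staticmethod
    def field_names() -> tuple[str, ...]:
        return tuple(f.name for f in dataclasses.fields(CouplingSet))

    @classmethod
    def random_intracortical(
        cls,
        nu_ee: float,
        nu_ei: float,
        nu_es: float,
        nu_re: float,
        nu_rs: float,
        nu_se: float,
        nu_sr: float,
        nu_sn: float,
    ) -> "CouplingSet":
        """Build a set under the random-intracortical-connectivity assumption.

        Both cortical populations then receive statistically identical input:
        ``nu_ie = nu_ee``, ``nu_ii = nu_ei``, ``nu_is = nu_es``.
        """
        return cls(
            nu_ee=nu_ee, nu_ei=nu_ei, nu_es=nu_es,
            nu_ie=nu_ee, nu_ii=nu_ei, nu_is=nu_es,
            nu_re=nu_re, nu_rs=nu_rs, nu_se=nu_se, nu_sr=nu_sr, nu_sn=nu_sn,
        )

    def replace(self, **kw: float) -> "CouplingSet":
        return dataclasses.replace(self, **kw)

    def as_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in self.field_names()}


def _default_couplings() -> CouplingSet:
    # Calibrated alpha-regime operating point (V*s), intracortical values
    # under the random-connectivity assumption.  The thalamocortical loop
    # places the dominant resonance near 1/t0 ~ 10 Hz; the point is chosen so
    # the low-activity fixed point keeps a margin of several times the
    # long-range network gain, the baseline is linearly stable for every
    # network mode, and the measured inhibitory reduction path crosses the
    # alpha instability late in the 50-step schedule (see docs/methods.md).
    return CouplingSet.random_intracortical(
        nu_ee=0.92e-3,
        nu_ei=-2.57e-3,
        nu_es=1.22e-3,
        nu_re=0.38e-3,
        nu_rs=0.33e-3,
        nu_se=1.96e-3,
        nu_sr=-1.22e-3,
        nu_sn=1.26e-3,
    )


@dataclass(frozen=True)
class CorticothalamicParams:
    """Full parameter set for one corticothalamic unit plus run settings.

    Parameters
    ----------
    Q_max : float
        Maximum population firing rate (s^-1).
    theta : float
        Mean firing threshold (V).
    sigma_prime : float
        Sigmoid slope parameter (V).
    alpha_d, beta_d : float
        Dendritic decay and rise rates (s^-1); ``beta_d > alpha_d``.
    gamma_e : float
        Cortical axonal damping rate (s^-1).
    t0 : float
        Full corticothalamic loop delay (s), split t0/2 per leg.
    couplings : CouplingSet
        Synaptic strengths (V*s).
    noise_mean, noise_std : float
        Mean and white-noise amplitude of the external drive ``phi_n`` to the
        relay population (s^-1; the amplitude scales a unit-variance white
        process of spectral density ``noise_std**2``).
    dt : float
        Integration step (s).
    duration, transient : float
        Simulated time per run and the initial span discarded (s).
    """

    Q_max: float = 250.0
    theta: float = 0.015
    sigma_prime: float = 0.00365
    alpha_d: float = 50.0
    beta_d: float = 200.0
    gamma_e: float = 100.0
    t0: float = 0.080
    couplings: CouplingSet = field(default_factory=_default_couplings)
    noise_mean: float = 7.4
    noise_std: float = 0.1
    dt: float = 1e-4
    duration: float = 12.0
    transient: float = 2.0

    def __post_init__(self) -> None:
        if not self.Q_max > 0:
            raise ValueError("Q_max must be > 0")
        if not self.sigma_prime > 0:
            raise ValueError("sigma_prime must be > 0")
        if not (self.beta_d > self.alpha_d > 0):
            raise ValueError("require beta_d > alpha_d > 0")
        if not self.gamma_e > 0:
            raise ValueError("gamma_e must be > 0")
        if self.t0 < 0:
            raise ValueError("t0 must be >= 0")
        if not self.dt > 0:
            raise ValueError("dt must be > 0")
        if not (self.duration > self.transient >= 0):
            raise ValueError("require duration > transient >= 0")
        if self.noise_std < 0:
            raise ValueError("noise_std must be >= 0")

    def replace(self, **kw) -> "CorticothalamicParams":
        return dataclasses.replace(self, **kw)

    def as_dict(self) -> dict:
        d = {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if f.name != "couplings"
        }
        d["couplings"] = self.couplings.as_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CorticothalamicParams":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        if "couplings" in d:
            cd = dict(d["couplings"])
            unknown_c = set(cd) - set(CouplingSet.field_names())
            if unknown_c:
                raise ValueError(f"unknown coupling keys: {sorted(unknown_c)}")
            d["couplings"] = CouplingSet(**cd)
        return cls(**d)

    def params_hash(self) -> str:
        """Stable short identifier of the configuration."""
        payload = json.dumps(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def firing_rate(V, params: CorticothalamicParams):
    """Convert membrane potential (V) to population firing rate (s^-1).

    The saturating sigmoid ``Q(V) = Q_max / (1 + exp(-(V - theta)/sigma'))``,
    strictly increasing with range (0, Q_max).
    """
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("membrane potential must be finite")
    with np.errstate(over="ignore"):  # exp overflow saturates to 0 correctly
        out = params.Q_max / (
            1.0 + np.exp(-(V - params.theta) / params.sigma_prime)
        )
    return out if out.ndim else float(out)


def firing_rate_slope(V, params: CorticothalamicParams):
    """dQ/dV at potential ``V`` (s^-1 V^-1), used by the linearization."""
    q = firing_rate(V, params)
    return q * (1.0 - q / params.Q_max) / params.sigma_prime


def save_params(params: CorticothalamicParams, path: str | Path) -> None:
    """Write a params config as YAML (or JSON if the suffix is .json)."""
    path = Path(path)
    d = params.as_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=True))


def load_params(path: str | Path) -> CorticothalamicParams:
    """Read a params config (YAML or JSON). Unknown keys are an error."""
    path = Path(path)
    text = path.read_text()
    d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(d, dict):
        raise ValueError(f"{path}: expected a mapping of parameter fields")
    return CorticothalamicParams.from_dict(d)
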