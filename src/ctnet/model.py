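"""Forward simulation of the delay-coupled corticothalamic network.

``steady_state`` finds the fixed point of one unit (used for initialization
and by the linearized spectral oracle); ``simulate_network`` integrates the
full stochastic delay system with a fixed-step Heun scheme and returns the
per-region cortical excitatory field phi_e after transient removal.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import optimize

from . import _kernel
from .connectome import Connectome
from .errors import SimulationInstabilityError, SteadyStateError
from .params import CorticothalamicParams, firing_rate

__all__ = [
    "SteadyState",
    "SimulationResult",
    "steady_state",
    "simulate_network",
    "save_result",
    "load_result",
]

GUARD_V = 1.0          # V; orders of magnitude beyond physiological range
GUARD_PHI_FACTOR = 10  # phi_e guard = 10 * Q_max

# reduction policies shared with the perturbation module
POLICY_INTRACORTICAL = "intracortical"
POLICY_WITH_LONGRANGE = "intracortical+longrange"
POLICIES = (POLICY_INTRACORTICAL, POLICY_WITH_LONGRANGE)


@dataclass(frozen=True)
class SteadyState:
    """Fixed-point potentials (V) of one unit with the search residual."""

    V_e: float
    V_i: float
    V_r: float
    V_s: float
    residual: float

    def as_array(self) -> np.ndarray:
        return np.array([self.V_e, self.V_i, self.V_r, self.V_s])


@dataclass
class SimulationResult:
    """Per-region cortical excitatory field phi_e (s^-1) after the transient.

    ``series`` has shape (n_regions, n_samples); ``fs`` is the record rate.
    """

    series: np.ndarray
    fs: float
    seed: int
    params_hash: str

    @property
    def n_regions(self) -> int:
        return self.series.shape[0]

    @property
    def n_samples(self) -> int:
        return self.series.shape[1]


def _fixed_point_residual(v, params: CorticothalamicParams, nu, extra_ee, drive):
    """Time-independent model equations; at the fixed point phi_e = Q(V_e)."""
    ve, vi, vr, vs = v
    qe = firing_rate(ve, params)
    qi = firing_rate(vi, params)
    qr = firing_rate(vr, params)
    qs = firing_rate(vs, params)
    return np.array(
        [
            (nu["nu_ee"] + extra_ee) * qe + nu["nu_ei"] * qi + nu["nu_es"] * qs - ve,
            nu["nu_ie"] * qe + nu["nu_ii"] * qi + nu["nu_is"] * qs - vi,
            nu["nu_re"] * qe + nu["nu_rs"] * qs - vr,
            nu["nu_se"] * qe + nu["nu_sr"] * qr + nu["nu_sn"] * drive - vs,
        ]
    )


def _bracketed_root(h, bracket):
    """brentq with geometric bracket expansion (the targets are monotone)."""
    b = bracket
    for _ in range(8):
        try:
            return optimize.brentq(h, -b, b, xtol=1e-13)
        except ValueError:
            b *= 4.0
    raise SteadyStateError("could not bracket a monotone sub-block root")


def _sigmoid(v, params):
    """Scalar firing-rate sigmoid (fast path for the fixed-point search)."""
    z = (v - params.theta) / params.sigma_prime
    if z < -500.0:
        return 0.0
    return params.Q_max / (1.0 + math.exp(-z))


def _thalamic_potentials(x, params, nu, drive, bracket=2.0):
    """V_r, V_s given the cortical excitatory field x = phi_e*.

    The relay equation is strictly decreasing in V_s (its only V_s-dependent
    term enters through the inhibitory reticular coupling nu_sr <= 0), so
    the root is unique and bracketable.
    """
    def h(vs):
        vr = nu["nu_re"] * x + nu["nu_rs"] * _sigmoid(vs, params)
        return (
            nu["nu_se"] * x
            + nu["nu_sr"] * _sigmoid(vr, params)
            + nu["nu_sn"] * drive
            - vs
        )

    vs = _bracketed_root(h, bracket)
    vr = nu["nu_re"] * x + nu["nu_rs"] * _sigmoid(vs, params)
    return vr, vs


def _inhibitory_potential(x, qs, params, nu, bracket=2.0):
    """V_i given phi_e* and Q_s*; strictly decreasing in V_i (nu_ii <= 0)."""
    def h(vi):
        return (
            nu["nu_ie"] * x + nu["nu_ii"] * _sigmoid(vi, params)
            + nu["nu_is"] * qs - vi
        )

    return _bracketed_root(h, bracket)


def steady_state(
    params: CorticothalamicParams,
    external_drive: float | None = None,
    extra_ee_gain: float = 0.0,
    tol: float = 1e-9,
) -> SteadyState:
    """Fixed point of one isolated unit under a constant external drive.

    The four time-independent model equations reduce to a scalar problem in
    the cortical excitatory field x = phi_e* in (0, Q_max): the thalamic and
    inhibitory sub-blocks are monotone in their own potential, so their
    roots are unique given x, leaving ``Q(V_e(x)) - x = 0``.  When several
    branches coexist the lowest-activity one is returned.

    Parameters
    ----------
    external_drive : float, optional
        Constant drive level phi_n (s^-1) entering the relay population via
        nu_sn; defaults to ``params.noise_mean``.
    extra_ee_gain : float
        Additional effective e->e gain (V*s), e.g. the long-range loop gain
        ``global_coupling`` at a spatially uniform network fixed point.
    tol : float
        Maximum acceptable residual norm (V).

    Raises
    ------
    SteadyStateError
        If no root is bracketed or the residual exceeds ``tol``.  Callers
        may fall back to the long-time mean of a noise-free simulation.
    """
    drive = params.noise_mean if external_drive is None else external_drive
    nu = params.couplings.as_dict()

    def g(x):
        vr, vs = _thalamic_potentials(x, params, nu, drive)
        qs = _sigmoid(vs, params)
        vi = _inhibitory_potential(x, qs, params, nu)
        ve = (
            (nu["nu_ee"] + extra_ee_gain) * x
            + nu["nu_ei"] * _sigmoid(vi, params)
            + nu["nu_es"] * qs
        )
        return _sigmoid(ve, params) - x, ve, vi, vr, vs

    grid = np.linspace(0.0, params.Q_max, 201)
    vals = np.array([g(x)[0] for x in grid])
    sign_changes = np.flatnonzero(np.sign(vals[:-1]) != np.sign(vals[1:]))
    if vals[0] == 0.0:
        x_root = 0.0
    elif sign_changes.size == 0:
        raise SteadyStateError("no fixed point bracketed in (0, Q_max)")
    else:
        k = sign_changes[0]  # lowest-activity branch
        x_root = optimize.brentq(
            lambda x: g(x)[0], grid[k], grid[k + 1], xtol=1e-14
        )
    _, ve, vi, vr, vs = g(x_root)
    res = float(
        np.linalg.norm(
            _fixed_point_residual(
                np.array([ve, vi, vr, vs]), params, nu, extra_ee_gain, drive
            )
        )
    )
    if res > tol:
        raise SteadyStateError(
            f"fixed-point residual {res:.3e} V exceeds tolerance {tol:g}"
        )
    return SteadyState(
        V_e=float(ve), V_i=float(vi), V_r=float(vr), V_s=float(vs), residual=res
    )


def _broadcast_scales(s, n):
    s = np.asarray(s, dtype=float)
    if s.ndim == 0:
        s = np.full(n, float(s))
    if s.shape != (n,):
        raise ValueError(f"coupling scale must be scalar or length-{n}")
    if np.any(s <= 0) or np.any(s > 1):
        raise ValueError("coupling scales must lie in (0, 1]")
    return s


def _coupling_arrays(params, s_e, s_i, n, policy):
    """Per-region coupling vectors with the reduction applied.

    Under the default policy only intracortical couplings are scaled:
    excitatory-sourced nu_ee, nu_ie by s_E and inhibitory-sourced nu_ei,
    nu_ii by s_I; thalamic and noise couplings are untouched.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown reduction policy {policy!r}")
    c = params.couplings
    nu = {k: np.full(n, getattr(c, k)) for k in c.field_names()}
    nu["nu_ee"] = nu["nu_ee"] * s_e
    nu["nu_ie"] = nu["nu_ie"] * s_e
    nu["nu_ei"] = nu["nu_ei"] * s_i
    nu["nu_ii"] = nu["nu_ii"] * s_i
    return nu


def simulate_network(
    params: CorticothalamicParams,
    connectome: Connectome | None = None,
    coupling_scales=(1.0, 1.0),
    seed: int = 0,
    policy: str = POLICY_INTRACORTICAL,
    record_every: int = 4,
) -> SimulationResult:
    """Integrate the network and return phi_e sampled at ``1/(dt*record_every)``.

    Parameters
    ----------
    connectome : Connectome, optional
        Structural network; ``None`` simulates a single isolated unit.
    coupling_scales : (s_E, s_I)
        Multiplicative reduction factors in (0, 1], scalars or per-region
        vectors, applied per the reduction ``policy``.
    seed : int
        Master seed; per-region noise streams are spawned from it, so
        identical configurations and seeds give bit-identical output.

    Raises
    ------
    SimulationInstabilityError
        If any state sample exceeds the divergence guard; the error names
        the integration step and region.
    """
    if connectome is None:
        n = 1
        w_net = np.zeros((1, 1))
        d_net = 0
    else:
        n = connectome.n_regions
        w_net = connectome.global_coupling * connectome.row_normalized()
        d_net = int(round(connectome.inter_delay / params.dt))
    s_e = _broadcast_scales(coupling_scales[0], n)
    s_i = _broadcast_scales(coupling_scales[1], n)
    if policy == POLICY_WITH_LONGRANGE and connectome is not None:
        # region j's incoming long-range excitatory synapses scale with s_E[j]
        w_net = w_net * s_e[:, None]

    d_ct = int(round(0.5 * params.t0 / params.dt))
    if params.t0 > 0 and params.t0 / params.dt < 10:
        raise ValueError("dt too coarse to resolve t0 (need t0/dt >= 10)")

    nu = _coupling_arrays(params, s_e, s_i, n, policy)

    # initialize at the uniform fixed point (mean scales approximate the
    # graded case; the discarded transient absorbs the difference)
    mean_params = params.replace(
        couplings=params.couplings.replace(
            nu_ee=params.couplings.nu_ee * float(s_e.mean()),
            nu_ie=params.couplings.nu_ie * float(s_e.mean()),
            nu_ei=params.couplings.nu_ei * float(s_i.mean()),
            nu_ii=params.couplings.nu_ii * float(s_i.mean()),
        )
    )
    extra = float(w_net.sum(axis=1).mean())
    try:
        fp = steady_state(mean_params, extra_ee_gain=extra)
        v0 = fp.as_array()
    except SteadyStateError:
        v0 = np.zeros(4)  # fall back to rest; transient absorbs the approach

    n_steps = int(round(params.duration / params.dt))
    ss = np.random.SeedSequence([int(seed)])
    streams = [np.random.Generator(np.random.Philox(s)) for s in ss.spawn(n)]
    noise = np.empty((n_steps, n))
    for j, g in enumerate(streams):
        noise[:, j] = g.standard_normal(n_steps)

    status, step, region, rec = _kernel.integrate(
        n_steps,
        params.dt,
        record_every,
        params.Q_max,
        params.theta,
        params.sigma_prime,
        params.alpha_d,
        params.beta_d,
        params.gamma_e,
        nu["nu_ee"], nu["nu_ei"], nu["nu_es"],
        nu["nu_ie"], nu["nu_ii"], nu["nu_is"],
        nu["nu_re"], nu["nu_rs"], nu["nu_se"], nu["nu_sr"], nu["nu_sn"],
        np.ascontiguousarray(w_net),
        d_ct,
        d_net,
        noise,
        params.noise_mean,
        params.noise_std,
        np.full(n, v0[0]), np.full(n, v0[1]), np.full(n, v0[2]), np.full(n, v0[3]),
        GUARD_V,
        GUARD_PHI_FACTOR * params.Q_max,
    )
    if status != _kernel.STATUS_OK:
        raise SimulationInstabilityError(step=int(step), region=int(region))

    fs = 1.0 / (params.dt * record_every)
    i0 = int(round(params.transient * fs))
    n_keep = int(round((params.duration - params.transient) * fs))
    series = rec[i0 : i0 + n_keep].T.copy()
    return SimulationResult(
        series=series, fs=fs, seed=int(seed), params_hash=params.params_hash()
    )


def dendritic_impulse_response(alpha_d: float, beta_d: float, t) -> np.ndarray:
    """Closed-form impulse response of the second-order dendritic filter.

    ``h(t) = alpha*beta*(exp(-alpha*t) - exp(-beta*t))/(beta - alpha)``,
    peaking at ``t* = ln(beta/alpha)/(beta - alpha)`` with unit DC gain.
    """
    t = np.asarray(t, dtype=float)
    return alpha_d * beta_d * (np.exp(-alpha_d * t) - np.exp(-beta_d * t)) / (
        beta_d - alpha_d
    )


def simulate_dendritic_filter(
    alpha_d: float, beta_d: float, drive: np.ndarray, dt: float
) -> np.ndarray:
    """Heun integration of the isolated dendritic filter (same update rule as
    the network kernel); used to verify DC gain and impulse-peak timing."""
    ab, apb = alpha_d * beta_d, alpha_d + beta_d
    v = dv = 0.0
    out = np.empty(len(drive))
    for k, p in enumerate(drive):
        a1v, a1d = dv, ab * (p - v) - apb * dv
        v1, d1 = v + dt * a1v, dv + dt * a1d
        p1 = drive[k + 1] if k + 1 < len(drive) else p
        a2v, a2d = d1, ab * (p1 - v1) - apb * d1
        v += 0.5 * dt * (a1v + a2v)
        dv += 0.5 * dt * (a1d + a2d)
        out[k] = v
    return out


def save_result(result: SimulationResult, path: str | Path) -> None:
    """Write the series as a delimited table plus a JSON metadata sidecar."""
    path = Path(path)
    t = np.arange(result.n_samples) / result.fs
    header = "time\t" + "\t".join(f"R{i:03d}" for i in range(result.n_regions))
    np.savetxt(
        path,
        np.column_stack([t, result.series.T]),
        delimiter="\t",
        header=header,
        comments="",
    )
    meta = {"fs": result.fs, "seed": result.seed, "params_hash": result.params_hash}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def load_result(path: str | Path) -> SimulationResult:
    path = Path(path)
    data = np.loadtxt(path, delimiter="\t", skiprows=1)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return SimulationResult(
        series=data[:, 1:].T.copy(),
        fs=float(meta["fs"]),
        seed=int(meta["seed"]),
        params_hash=str(meta["params_hash"]),
    )
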