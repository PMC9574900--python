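"""Step-wise synaptic reduction experiment.

A run reduces cortical excitatory and/or inhibitory synaptic couplings
linearly over ``n_iterations`` steps toward empirically measured end-points
(defaults: -12.5% excitatory, -14.9% inhibitory, the normal-appearing
gray-matter layer-VI values), simulating the network at each step and
recording alpha-band power and mean PLV with their percent changes from
baseline.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .connectome import Connectome
from .errors import SimulationInstabilityError
from .model import POLICIES, POLICY_INTRACORTICAL, simulate_network
from .params import CorticothalamicParams, CouplingSet

__all__ = [
    "CONDITIONS",
    "ENDPOINTS_NAGM",
    "ENDPOINTS_DEMYEL",
    "ReductionSchedule",
    "IterationOutcome",
    "ExperimentResult",
    "MetricsConfig",
    "scale_at",
    "apply_reduction",
    "run_experiment",
]

CONDITIONS = ("excitatory", "inhibitory", "combined")

# measured layer-VI density end-points (fractional reductions vs control)
ENDPOINTS_NAGM = {"excitatory": 0.125, "inhibitory": 0.149}
# demyelinated-cortex preset; not used by the default experiment
ENDPOINTS_DEMYEL = {"excitatory": 0.185, "inhibitory": 0.293}


@dataclass(frozen=True)
class ReductionSchedule:
    """Condition, end-points and spatial profile of a 50-step reduction."""

    condition: str
    n_iterations: int = 50
    endpoint_E: float = ENDPOINTS_NAGM["excitatory"]
    endpoint_I: float = ENDPOINTS_NAGM["inhibitory"]
    spatial_mode: str = "uniform"
    region_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        for ep in (self.endpoint_E, self.endpoint_I):
            if not 0 <= ep < 1:
                raise ValueError("end-point fractions must lie in [0, 1)")
        if self.spatial_mode not in ("uniform", "graded"):
            raise ValueError("spatial_mode must be 'uniform' or 'graded'")
        if self.spatial_mode == "graded":
            w = np.asarray(self.region_weights, dtype=float)
            if w.ndim != 1 or np.any(w < 0) or np.any(w > 1):
                raise ValueError("region_weights must be a vector in [0, 1]")
            if not np.isclose(w.max(), 1.0):
                raise ValueError(
                    "graded mode requires max(region_weights) == 1 so the "
                    "most-affected region reaches the end-point exactly"
                )
            object.__setattr__(self, "region_weights", w)
        elif self.region_weights is not None:
            raise ValueError("region_weights only apply in graded mode")


def scale_at(schedule: ReductionSchedule, i: int):
    """Coupling factors (s_E, s_I) at iteration ``i``.

    Linear interpolation ``s_X(i) = 1 - endpoint_X * (i / n_iterations)`` for
    the synapse type(s) named by the condition; the untouched type stays 1.
    In graded mode the factors are per-region vectors.
    """
    if not 0 <= i <= schedule.n_iterations:
        raise ValueError(
            f"iteration {i} outside 0..{schedule.n_iterations}"
        )
    frac = i / schedule.n_iterations
    profile = (
        schedule.region_weights if schedule.spatial_mode == "graded" else 1.0
    )
    s_e: float | np.ndarray = 1.0
    s_i: float | np.ndarray = 1.0
    if schedule.condition in ("excitatory", "combined"):
        s_e = 1.0 - schedule.endpoint_E * frac * profile
    if schedule.condition in ("inhibitory", "combined"):
        s_i = 1.0 - schedule.endpoint_I * frac * profile
    if schedule.spatial_mode == "graded":
        n = schedule.region_weights.size
        s_e = np.broadcast_to(np.asarray(s_e, dtype=float), (n,)).copy()
        s_i = np.broadcast_to(np.asarray(s_i, dtype=float), (n,)).copy()
    return s_e, s_i


def apply_reduction(
    couplings: CouplingSet,
    s_E: float,
    s_I: float,
    policy: str = POLICY_INTRACORTICAL,
) -> CouplingSet:
    """Return a new CouplingSet with the cortical reductions applied.

    The default policy scales the intracortical excitatory couplings
    (nu_ee, nu_ie) by ``s_E`` and the intracortical inhibitory couplings
    (nu_ei, nu_ii) by ``s_I``; thalamic and noise couplings are untouched.
    Under the long-range policy the connectome gain is additionally scaled
    by ``s_E`` inside the simulator; the coupling set itself is identical.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown reduction policy {policy!r}")
    for s in (s_E, s_I):
        if not 0 < s <= 1:
            raise ValueError("reduction factors must lie in (0, 1]")
    return couplings.replace(
        nu_ee=couplings.nu_ee * s_E,
        nu_ie=couplings.nu_ie * s_E,
        nu_ei=couplings.nu_ei * s_I,
        nu_ii=couplings.nu_ii * s_I,
    )


@dataclass(frozen=True)
class MetricsConfig:
    """Settings for the per-iteration outcome measures."""

    band: tuple[float, float] = _metrics.ALPHA_BAND
    window_s: float = 4.0
    overlap: float = 0.5
    target_fs: float = _metrics.METRICS_FS
    edge_trim_s: float = 1.0


@dataclass(frozen=True)
class IterationOutcome:
    """Outcomes of one reduction step."""

    iteration: int
    alpha_power: float
    mean_plv: float
    pct_power: float
    pct_plv: float


@dataclass
class ExperimentResult:
    """Outcome curve of one condition; ``failed_at`` marks an aborted run."""

    condition: str
    outcomes: list[IterationOutcome]
    seed: int
    failed_at: int | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([dataclasses.asdict(o) for o in self.outcomes])
        df.insert(0, "condition", self.condition)
        return df

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)
        meta = {
            "condition": self.condition,
            "seed": self.seed,
            "failed_at": self.failed_at,
        }
        p = Path(path)
        p.with_suffix(p.suffix + ".json").write_text(json.dumps(meta, indent=2))


def iteration_seed(master_seed: int, iteration: int) -> int:
    """Deterministic per-iteration seed derived from the master seed."""
    ss = np.random.SeedSequence([int(master_seed), int(iteration)])
    return int(ss.generate_state(1, np.uint32)[0])


def run_experiment(
    params: CorticothalamicParams,
    connectome: Connectome,
    schedule: ReductionSchedule,
    metrics_cfg: MetricsConfig | None = None,
    seed: int = 0,
    iterations=None,
    policy: str = POLICY_INTRACORTICAL,
    noise_mode: str = "fresh",
) -> ExperimentResult:
    """Run the reduction experiment and return per-iteration outcomes.

    Parameters
    ----------
    iterations : sequence of int, optional
        Subset of 0..n_iterations to evaluate (must include 0, ascending);
        defaults to every iteration.
    noise_mode : {"fresh", "frozen"}
        Fresh draws a new noise realization per iteration (seed derived
        from the master seed and the iteration index); frozen re-uses the
        iteration-0 realization to isolate pure coupling effects.

    Notes
    -----
    Iteration 0 depends only on the master seed and shared baseline
    configuration, so all three conditions share an identical baseline.
    If the integrator diverges at some iteration, the partial outcome list
    is returned with ``failed_at`` set to that iteration index.
    """
    if metrics_cfg is None:
        metrics_cfg = MetricsConfig()
    if noise_mode not in ("fresh", "frozen"):
        raise ValueError("noise_mode must be 'fresh' or 'frozen'")
    if iterations is None:
        iterations = range(schedule.n_iterations + 1)
    iterations = [int(i) for i in iterations]
    if iterations[0] != 0:
        raise ValueError("the iteration list must start at 0 (the baseline)")
    if any(b <= a for a, b in zip(iterations, iterations[1:])):
        raise ValueError("iterations must be strictly ascending")

    outcomes: list[IterationOutcome] = []
    base_power = base_plv = None
    failed_at = None
    for i in iterations:
        s_e, s_i = scale_at(schedule, i)
        it_seed = iteration_seed(seed, 0 if noise_mode == "frozen" else i)
        try:
            sim = simulate_network(
                params, connectome, coupling_scales=(s_e, s_i),
                seed=it_seed, policy=policy,
            )
        except SimulationInstabilityError:
            failed_at = i
            break
        sim = _metrics.downsample(sim, metrics_cfg.target_fs)
        spec = _metrics.welch_psd(
            sim, window_s=metrics_cfg.window_s, overlap=metrics_cfg.overlap
        )
        power = _metrics.alpha_power(spec, metrics_cfg.band)
        plv = _metrics.mean_plv(
            _metrics.plv_matrix(
                sim, band=metrics_cfg.band, edge_trim_s=metrics_cfg.edge_trim_s
            )
        )
        if base_power is None:
            base_power, base_plv = power, plv
        outcomes.append(
            IterationOutcome(
                iteration=i,
                alpha_power=power,
                mean_plv=plv,
                pct_power=_metrics.percent_change(power, base_power),
                pct_plv=_metrics.percent_change(plv, base_plv),
            )
        )
    return ExperimentResult(
        condition=schedule.condition, outcomes=outcomes, seed=int(seed),
        failed_at=failed_at,
    )


def summarize_conditions(results: list[ExperimentResult]) -> pd.DataFrame:
    """Three-condition summary table (one row per condition x iteration)."""
    return pd.concat([r.to_frame() for r in results], ignore_index=True)
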