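"""Synthetic generators for the structural connectome and histology table.

The empirical tractography matrix and the post-mortem density data behind
the study design are not distributable, so both inputs are emulated:

* ``generate_connectome`` draws a nonnegative, symmetric, connected,
  heavy-tailed weight matrix using log-normal weights modulated by an
  exponential distance rule over random 3D region positions — the standard
  empirical regularity of tractography networks.
* ``generate_histology`` draws a nested long-format density table: 9
  control subjects and 33 MS subjects contributing two ROIs each, giving 9
  NC, 29 normal-appearing (NAGM) and 13 demyelinated (DEMYEL) subject-level
  measurements after ROI averaging, with log-normal subject and ROI noise,
  multiplicative group effects per marker x layer, and per-group covariate
  distributions (post-mortem delay shorter in MS).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import Connectome

__all__ = [
    "ConnectomeSimConfig",
    "HistologySimConfig",
    "generate_connectome",
    "generate_histology",
    "DEFAULT_LAYER_VI_MULTIPLIERS",
]

SYNAPSE_MARKERS = ("exc_synapse", "inh_synapse")
NEURON_MARKERS = ("NeuN", "PV", "CR")
LAYERS = ("I", "II", "III", "VI")

# layer-VI group effects as multiplicative factors vs control
# (NAGM: -12.5% exc / -14.9% inh; DEMYEL: -18.5% exc / -29.3% inh)
DEFAULT_LAYER_VI_MULTIPLIERS = {
    ("NAGM", "exc_synapse"): 0.875,
    ("NAGM", "inh_synapse"): 0.851,
    ("DEMYEL", "exc_synapse"): 0.815,
    ("DEMYEL", "inh_synapse"): 0.707,
}
# transient layer-I excitatory increase; off by default because it did not
# survive the neuronal-density covariate correction
LAYER_I_EXC_PRESET = {("NAGM", "exc_synapse", "I"): 1.10}


@dataclass(frozen=True)
class ConnectomeSimConfig:
    """Settings of the synthetic tractography-like network."""

    n_regions: int = 78
    edge_density: float = 0.30
    weight_mu: float = 0.0       # log-normal location of raw weights
    weight_sigma: float = 1.0    # log-normal scale (heavy tail)
    distance_lambda: float = 0.35  # e-fold distance of the exponential rule
    global_coupling: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 2:
            raise ValueError("n_regions must be >= 2")
        if not 0 < self.edge_density <= 1:
            raise ValueError("edge_density must lie in (0, 1]")
        if self.weight_sigma < 0 or self.distance_lambda <= 0:
            raise ValueError("weight_sigma >= 0 and distance_lambda > 0 required")


def generate_connectome(cfg: ConnectomeSimConfig) -> Connectome:
    """Sample a synthetic structural connectome.

    Regions get uniform random positions in the unit cube; each pair is
    connected with probability proportional to ``exp(-d / lambda)`` scaled
    to hit the requested edge density, with log-normal weights attenuated
    by the same distance rule.  If the sampled graph is disconnected, the
    closest inter-component pairs are bridged deterministically.  Weights
    are normalized to a maximum of 1.
    """
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(cfg.seed)))
    n = cfg.n_regions
    pos = rng.uniform(size=(n, 3))
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    iu = np.triu_indices(n, k=1)
    affinity = np.exp(-d[iu] / cfg.distance_lambda)
    if cfg.edge_density >= 1:
        present = np.ones(affinity.size, dtype=bool)
    else:
        # bisect the gain c so that mean(min(1, c*affinity)) hits the target
        lo, hi = 0.0, 1.0
        while np.minimum(hi * affinity, 1.0).mean() < cfg.edge_density:
            hi *= 2.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if np.minimum(mid * affinity, 1.0).mean() < cfg.edge_density:
                lo = mid
            else:
                hi = mid
        p = np.minimum(hi * affinity, 1.0)
        present = rng.uniform(size=p.size) < p
    raw = rng.lognormal(cfg.weight_mu, cfg.weight_sigma, size=affinity.size)
    vals = np.where(present, raw * np.exp(-d[iu] / cfg.distance_lambda), 0.0)
    w = np.zeros((n, n))
    w[iu] = vals
    w = w + w.T

    # deterministic bridging of disconnected components
    from scipy.sparse.csgraph import connected_components

    for _ in range(n):
        ncomp, labels = connected_components(w > 0, directed=False)
        if ncomp == 1:
            break
        main = np.argmax(np.bincount(labels))
        other = int(np.flatnonzero(labels != main)[0])
        cand = np.flatnonzero(labels == labels[other])
        rest = np.flatnonzero(labels != labels[other])
        dd = d[np.ix_(cand, rest)]
        a, b = np.unravel_index(int(np.argmin(dd)), dd.shape)
        i, j = int(cand[a]), int(rest[b])
        w[i, j] = w[j, i] = np.median(w[w > 0])
    else:
        raise RuntimeError("could not connect the sampled graph")

    w = w / w.max()
    return Connectome(weights=w, global_coupling=cfg.global_coupling)


@dataclass(frozen=True)
class HistologySimConfig:
    """Settings of the nested synthetic density table.

    33 MS subjects contribute two ROIs each: ``n_ms_with_demyel`` have at
    least one demyelinated ROI and ``n_ms_demyel_only`` of those have no
    NAGM ROI, so the subject-level tissue counts after averaging are
    ``n_nc`` NC, ``n_ms - n_ms_demyel_only`` NAGM and ``n_ms_with_demyel``
    DEMYEL (defaults: 9 / 29 / 13).
    """

    n_nc: int = 9
    n_ms: int = 33
    n_ms_with_demyel: int = 13
    n_ms_demyel_only: int = 4
    rois_per_subject: int = 2
    baseline: dict = field(default_factory=lambda: {
        # counts/mm^2; synapse baselines per layer, neurons whole-cortex
        "exc_synapse": {"I": 5.2e5, "II": 6.0e5, "III": 5.6e5, "VI": 4.8e5},
        "inh_synapse": {"I": 1.6e5, "II": 1.9e5, "III": 1.8e5, "VI": 1.5e5},
        "NeuN": 620.0,
        "PV": 28.0,
        "CR": 35.0,
    })
    effect_multiplier: dict = field(
        default_factory=lambda: dict(DEFAULT_LAYER_VI_MULTIPLIERS)
    )
    between_subject_sd: float = 0.15   # log scale
    within_subject_sd: float = 0.10    # log scale
    age_mean: dict = field(default_factory=lambda: {"NC": 73.0, "MS": 62.0})
    age_sd: float = 8.0
    female_frac: dict = field(default_factory=lambda: {"NC": 0.56, "MS": 0.64})
    pmd_mean: dict = field(default_factory=lambda: {"NC": 570.0, "MS": 320.0})
    pmd_sd: float = 90.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_nc, self.n_ms, self.n_ms_with_demyel) < 1:
            raise ValueError("all group sizes must be >= 1")
        if self.n_ms_with_demyel > self.n_ms:
            raise ValueError("n_ms_with_demyel cannot exceed n_ms")
        if self.n_ms_demyel_only > self.n_ms_with_demyel:
            raise ValueError("n_ms_demyel_only cannot exceed n_ms_with_demyel")
        if self.between_subject_sd < 0 or self.within_subject_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        for k, v in self.effect_multiplier.items():
            mult = v if isinstance(v, (int, float)) else None
            if mult is None:
                raise ValueError(f"multiplier for {k} must be numeric")
            if mult <= 0:
                raise ValueError(f"multiplier for {k} must be > 0")

    def config_hash(self) -> str:
        d = dict(self.__dict__)
        d["effect_multiplier"] = {
            "|".join(map(str, k)): v for k, v in self.effect_multiplier.items()
        }
        payload = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _multiplier(cfg: HistologySimConfig, group: str, marker: str, layer):
    if group == "NC":
        return 1.0
    if marker in SYNAPSE_MARKERS:
        if (group, marker, layer) in cfg.effect_multiplier:
            return cfg.effect_multiplier[(group, marker, layer)]
        # bare (group, marker) keys are the layer-VI effects
        if layer == "VI":
            return cfg.effect_multiplier.get((group, marker), 1.0)
        return 1.0
    return cfg.effect_multiplier.get((group, marker), 1.0)


def generate_histology(cfg: HistologySimConfig) -> pd.DataFrame:
    """Draw a long-format density table (one row per ROI-level record).

    log density = log(baseline * multiplier) + subject effect + ROI noise,
    with the subject effect N(0, between_subject_sd^2) shared across all of
    a subject's records and ROI noise N(0, within_subject_sd^2) per record.
    Layer-VI effects default to the measured multipliers; all other cells
    are null unless configured otherwise.
    """
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(cfg.seed)))
    rows = []

    def subject_covariates(group_key: str):
        age = float(rng.normal(cfg.age_mean[group_key], cfg.age_sd))
        sex = "F" if rng.uniform() < cfg.female_frac[group_key] else "M"
        pmd = float(max(rng.normal(cfg.pmd_mean[group_key], cfg.pmd_sd), 30.0))
        return age, sex, pmd

    def tissue_plan(idx: int) -> list[str]:
        # first n_ms_demyel_only subjects: all ROIs demyelinated; the next
        # (n_ms_with_demyel - n_ms_demyel_only): one DEMYEL + NAGM rest;
        # remaining subjects: NAGM only
        if idx < cfg.n_ms_demyel_only:
            return ["DEMYEL"] * cfg.rois_per_subject
        if idx < cfg.n_ms_with_demyel:
            return ["DEMYEL"] + ["NAGM"] * (cfg.rois_per_subject - 1)
        return ["NAGM"] * cfg.rois_per_subject

    subjects = [("NC", f"NC{i+1:02d}", ["NC"] * cfg.rois_per_subject)
                for i in range(cfg.n_nc)]
    subjects += [("MS", f"MS{i+1:02d}", tissue_plan(i)) for i in range(cfg.n_ms)]

    for group_key, sid, tissues in subjects:
        age, sex, pmd = subject_covariates(group_key)
        subj_eff = float(rng.normal(0.0, cfg.between_subject_sd))
        for r, tissue in enumerate(tissues):
            roi_id = f"{sid}_roi{r+1}"
            for marker in SYNAPSE_MARKERS:
                for layer in LAYERS:
                    base = cfg.baseline[marker][layer]
                    mult = _multiplier(cfg, tissue, marker, layer)
                    noise = float(rng.normal(0.0, cfg.within_subject_sd))
                    rows.append(
                        dict(
                            subject_id=sid, group=tissue, marker=marker,
                            layer=layer, roi_id=roi_id,
                            density=float(
                                np.exp(np.log(base * mult) + subj_eff + noise)
                            ),
                            age=age, sex=sex, pmd=pmd,
                        )
                    )
            for marker in NEURON_MARKERS:
                base = cfg.baseline[marker]
                mult = _multiplier(cfg, tissue, marker, None)
                noise = float(rng.normal(0.0, cfg.within_subject_sd))
                rows.append(
                    dict(
                        subject_id=sid, group=tissue, marker=marker,
                        layer=None, roi_id=roi_id,
                        density=float(
                            np.exp(np.log(base * mult) + subj_eff + noise)
                        ),
                        age=age, sex=sex, pmd=pmd,
                    )
                )
    return pd.DataFrame(rows)


def write_with_provenance(df_or_conn, path: str | Path, cfg) -> None:
    """Write a generated artifact plus a JSON sidecar (seed, config hash)."""
    path = Path(path)
    if isinstance(df_or_conn, Connectome):
        from .connectome import write_connectome

        write_connectome(df_or_conn, path)
        digest = hashlib.sha256(
            json.dumps(cfg.__dict__, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
    else:
        df_or_conn.to_csv(path, index=False)
        digest = cfg.config_hash()
    sidecar = {"seed": cfg.seed, "config_hash": digest}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))
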