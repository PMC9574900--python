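"""Nested density contrasts between tissue types.

ROI-level densities (counts/mm^2) are averaged per subject x tissue type x
marker x layer, then compared between tissue types (NC reference, MS
normal-appearing gray matter, MS demyelinated cortex) with linear
mixed-effects models: fixed effects tissue type (+ layer and the tissue
type x layer interaction for synapse markers) and the covariates age, sex
and post-mortem delay; a random intercept per subject absorbs the nesting
(a subject can contribute several tissue types, and synapse markers several
layers).  When the interaction is significant, per-layer follow-up models
give pairwise tissue-type contrasts; percent differences come from
covariate-adjusted group means.

Estimation uses REML via :mod:`statsmodels`; contrast p-values use a t
reference with between-within denominator degrees of freedom (subjects
minus fixed-effect columns), a conventional small-sample approximation.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import SchemaError, SingularFitError

__all__ = [
    "REQUIRED_COLUMNS",
    "GROUPS",
    "ContrastResult",
    "validate_records",
    "aggregate_rois",
    "fit_density_model",
    "fit_layer_contrasts",
    "percent_difference",
    "read_density_table",
    "contrasts_to_frame",
]

REQUIRED_COLUMNS = (
    "subject_id", "group", "marker", "layer", "roi_id", "density",
    "age", "sex", "pmd",
)
GROUPS = ("NC", "NAGM", "DEMYEL")
SYNAPSE_MARKERS = ("exc_synapse", "inh_synapse")
NEURON_MARKERS = ("NeuN", "PV", "CR")
_PAIRS = (("NAGM", "NC"), ("DEMYEL", "NC"), ("DEMYEL", "NAGM"))


@dataclass(frozen=True)
class ContrastResult:
    """One covariate-adjusted tissue-type contrast (or interaction test)."""

    marker: str
    layer: str | None
    comparison: str
    estimate: float          # adjusted mean difference, counts/mm^2
    pct_diff: float          # percent difference vs the reference group
    ci_low: float
    ci_high: float
    p_value: float
    metadata: dict = dataclasses.field(default_factory=dict, compare=False)


def validate_records(df: pd.DataFrame) -> pd.DataFrame:
    """Validate the long-format density table against the schema."""
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"missing columns: {sorted(missing)}")
    if len(df) == 0:
        raise SchemaError("empty density table")
    if not df["group"].isin(GROUPS).all():
        bad = sorted(set(df["group"]) - set(GROUPS))
        raise SchemaError(f"unknown tissue types: {bad}")
    if (df["density"] <= 0).any() or not np.isfinite(df["density"]).all():
        raise SchemaError("densities must be positive and finite")
    syn = df["marker"].isin(SYNAPSE_MARKERS)
    if df.loc[syn, "layer"].isna().any():
        raise SchemaError("synapse records must carry a cortical layer")
    if df.loc[~syn, "layer"].notna().any():
        raise SchemaError("neuron records are whole-cortex and carry no layer")
    cov = df.groupby("subject_id")[["age", "sex", "pmd"]].nunique()
    if (cov > 1).any().any():
        bad = cov.index[(cov > 1).any(axis=1)].tolist()
        raise SchemaError(f"conflicting covariates within subjects: {bad}")
    return df


def aggregate_rois(records: pd.DataFrame) -> pd.DataFrame:
    """Average same-tissue-type ROIs within a subject.

    Records of the same subject x tissue type x marker x layer are replaced
    by their arithmetic mean; differing tissue types within a subject stay
    separate, so one subject can contribute both a NAGM and a DEMYEL
    measurement.  Idempotent.
    """
    df = validate_records(records.copy())
    keys = ["subject_id", "group", "marker", "layer"]
    spec = dict(
        density=("density", "mean"),
        age=("age", "first"),
        sex=("sex", "first"),
        pmd=("pmd", "first"),
        n_rois=("density", "size"),
    )
    # extra columns (e.g. a subject-level covariate) are carried through
    extra = [c for c in df.columns if c not in REQUIRED_COLUMNS + ("n_rois",)]
    for c in extra:
        spec[c] = (c, "first")
    agg = df.groupby(keys, dropna=False, as_index=False).agg(**spec)
    agg["roi_id"] = agg["subject_id"] + "_" + agg["group"] + "_mean"
    return agg[list(REQUIRED_COLUMNS) + ["n_rois"] + extra]


def percent_difference(adjusted_mean_a: float, adjusted_mean_ref: float) -> float:
    """Percent difference of an adjusted mean vs a reference adjusted mean."""
    if adjusted_mean_ref <= 0:
        raise ValueError("reference adjusted mean must be > 0")
    return 100.0 * (adjusted_mean_a - adjusted_mean_ref) / adjusted_mean_ref


def _design(df: pd.DataFrame, with_layer: bool, extra_covariate: str | None):
    """Fixed-effects design with treatment coding (NC and layer-I reference).

    Continuous and binary covariates are mean-centered, so adjusted group
    means are direct linear combinations of the intercept and the group /
    layer dummies, and the fit is well conditioned regardless of the raw
    covariate scales.
    """
    X = pd.DataFrame(index=df.index)
    X["Intercept"] = 1.0
    for g in GROUPS[1:]:
        X[f"group[{g}]"] = (df["group"] == g).astype(float)
    if with_layer:
        layers = sorted(x for x in df["layer"].dropna().unique())
        for lay in layers[1:]:
            X[f"layer[{lay}]"] = (df["layer"] == lay).astype(float)
        for g in GROUPS[1:]:
            for lay in layers[1:]:
                X[f"group[{g}]:layer[{lay}]"] = (
                    (df["group"] == g) & (df["layer"] == lay)
                ).astype(float)
    cov_cols = {"age": df["age"].astype(float),
                "sex[M]": (df["sex"] == "M").astype(float),
                "pmd": df["pmd"].astype(float)}
    if extra_covariate is not None:
        cov_cols[extra_covariate] = df[extra_covariate].astype(float)
    for name, col in cov_cols.items():
        centered = col - col.mean()
        sd = centered.std()
        X[name] = centered / sd if sd > 0 else centered
    return X


def _fit_mixedlm(y, X, groups):
    """REML fit with a subject random intercept; explicit singular-fit errors.

    Returns ``(fe_params, fe_cov, columns)`` in the units of ``y`` (the
    response is standardized internally for numerical stability).
    """
    keep = [c for c in X.columns if c == "Intercept" or X[c].nunique() > 1]
    X = X[keep]
    if np.linalg.matrix_rank(X.values) < X.shape[1]:
        raise SingularFitError("fixed-effects design matrix is rank deficient")
    y = np.asarray(y, float)
    scale = float(y.std())
    if scale == 0.0:
        raise SingularFitError(
            "residual variance component is zero (constant densities)"
        )
    model = sm.MixedLM(endog=y / scale, exog=X, groups=groups)
    fit = None
    last_exc = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("lbfgs", "powell", "nm"):
            try:
                cand = model.fit(reml=True, method=method, maxiter=500)
            except (np.linalg.LinAlgError, ValueError) as exc:
                last_exc = exc
                continue
            if cand.converged:
                fit = cand
                break
    if fit is None:
        raise SingularFitError(
            "mixed-model did not converge"
            + (f" ({last_exc})" if last_exc is not None else "")
            + "; the subject random-intercept variance component is likely "
            "singular"
        )
    k = X.shape[1]
    fe = fit.fe_params.values * scale
    cov = np.asarray(fit.cov_params())[:k, :k] * scale**2
    return fe, cov, list(X.columns)


def _bw_df(df: pd.DataFrame, n_fixed: int) -> float:
    """Between-within denominator df: subject-level units minus fixed effects."""
    return max(float(df["subject_id"].nunique() - n_fixed), 1.0)


def _adjusted_means(fe, cols, layer=None):
    """Predicted group means at covariate averages (and a fixed layer).

    Covariates are centered in the design, so the mean-covariate row is the
    intercept plus the relevant group / layer dummies.
    """
    means = {}
    for g in GROUPS:
        row = {c: 0.0 for c in cols}
        row["Intercept"] = 1.0
        if g != "NC" and f"group[{g}]" in row:
            row[f"group[{g}]"] = 1.0
        if layer is not None:
            if f"layer[{layer}]" in row:
                row[f"layer[{layer}]"] = 1.0
            if g != "NC" and f"group[{g}]:layer[{layer}]" in row:
                row[f"group[{g}]:layer[{layer}]"] = 1.0
        vec = np.array([row[c] for c in cols])
        means[g] = float(vec @ fe)
    return means


def _pairwise_contrasts(fe, cov, cols, df, marker, layer, extra_covariate=None):
    """NAGM-NC, DEMYEL-NC and DEMYEL-NAGM contrasts from one per-layer fit."""
    out = []
    means = _adjusted_means(fe, cols)
    dof = _bw_df(df, len(cols))
    for a, ref in _PAIRS:
        if not {a, ref} <= set(df["group"].unique()):
            continue
        c = np.zeros(len(cols))
        if a != "NC":
            c[cols.index(f"group[{a}]")] = 1.0
        if ref != "NC":
            c[cols.index(f"group[{ref}]")] = -1.0
        est = float(c @ fe)
        se = float(np.sqrt(c @ cov @ c))
        tcrit = stats.t.ppf(0.975, dof)
        p = 2 * stats.t.sf(abs(est / se), dof) if se > 0 else np.nan
        out.append(
            ContrastResult(
                marker=marker,
                layer=layer,
                comparison=f"{a} vs {ref}",
                estimate=est,
                pct_diff=percent_difference(means[a], means[ref]),
                ci_low=est - tcrit * se,
                ci_high=est + tcrit * se,
                p_value=float(p),
                metadata={
                    "df": dof,
                    "adjusted_means": means,
                    "random_effects": "subject intercept",
                    "covariates": ["age", "sex", "pmd"]
                    + ([extra_covariate] if extra_covariate else []),
                    "estimation": "REML, between-within df",
                },
            )
        )
    return out


def _interaction_test(fe, cov, cols, df, marker) -> ContrastResult:
    ix = [i for i, c in enumerate(cols) if ":layer[" in c]
    b = fe[ix]
    V = cov[np.ix_(ix, ix)]
    stat = float(b @ np.linalg.solve(V, b))
    # F reference: Wald chi2 / q with between-within denominator df
    q = len(ix)
    dof = _bw_df(df, len(cols))
    fstat = stat / q
    p = float(stats.f.sf(fstat, q, dof))
    return ContrastResult(
        marker=marker,
        layer=None,
        comparison="tissue type x layer interaction",
        estimate=fstat,
        pct_diff=np.nan,
        ci_low=np.nan,
        ci_high=np.nan,
        p_value=p,
        metadata={"df_num": q, "df_den": dof, "wald_chi2": stat},
    )


def fit_layer_contrasts(
    records: pd.DataFrame,
    marker: str,
    layer: str | None,
    extra_covariate: str | None = None,
) -> list[ContrastResult]:
    """Pairwise tissue-type contrasts for one marker (and layer, if synaptic).

    Fits the per-layer mixed model directly: density ~ tissue type + age +
    sex + pmd with a subject random intercept.  This is the follow-up model
    the interaction gate of :func:`fit_density_model` dispatches to; it is
    exposed for calibration studies that target one layer.
    """
    df = aggregate_rois(records)
    mask = df["marker"] == marker
    if layer is not None:
        mask &= df["layer"] == layer
    sub = df[mask].reset_index(drop=True)
    if len(sub) == 0:
        raise ValueError(f"no records for marker {marker!r}, layer {layer!r}")
    if sub["group"].nunique() < 2:
        raise ValueError("need at least 2 tissue types")
    X = _design(sub, with_layer=False, extra_covariate=extra_covariate)
    fe, cov, cols = _fit_mixedlm(sub["density"], X, sub["subject_id"])
    return _pairwise_contrasts(fe, cov, cols, sub, marker, layer,
                               extra_covariate)


def fit_density_model(
    records: pd.DataFrame,
    marker_class: str,
    extra_covariate: str | None = None,
    interaction_alpha: float = 0.05,
) -> list[ContrastResult]:
    """Fit the nested tissue-type contrasts for one marker class.

    Parameters
    ----------
    records : DataFrame
        Aggregated (or raw ROI-level) density records; raw records are
        aggregated first.
    marker_class : {"synapse", "neuron"}
        Synapse markers are fitted per marker with tissue type, layer and
        their interaction; when the interaction p-value is below
        ``interaction_alpha``, per-layer follow-up models with pairwise
        tissue-type contrasts are added.  Neuron markers are fitted
        whole-cortex with tissue-type contrasts directly.
    extra_covariate : str, optional
        Additional fixed covariate column (e.g. a neuronal density used as
        a tissue-compaction control).

    Raises
    ------
    SingularFitError
        On singular or non-convergent fits, naming the variance component.
    """
    if marker_class not in ("synapse", "neuron"):
        raise ValueError("marker_class must be 'synapse' or 'neuron'")
    df = aggregate_rois(records)
    markers = SYNAPSE_MARKERS if marker_class == "synapse" else NEURON_MARKERS
    markers = [m for m in markers if (df["marker"] == m).any()]
    if not markers:
        raise ValueError(f"no {marker_class} markers present in the table")
    results: list[ContrastResult] = []
    for marker in markers:
        sub = df[df["marker"] == marker].reset_index(drop=True)
        if sub["group"].nunique() < 2:
            raise ValueError(f"{marker}: need at least 2 tissue types")
        if marker_class == "synapse":
            layers = sorted(sub["layer"].dropna().unique())
            if len(layers) < 2:
                raise ValueError(f"{marker}: need at least 2 layers")
            X = _design(sub, with_layer=True, extra_covariate=extra_covariate)
            fe, cov, cols = _fit_mixedlm(sub["density"], X, sub["subject_id"])
            inter = _interaction_test(fe, cov, cols, sub, marker)
            results.append(inter)
            if inter.p_value < interaction_alpha:
                for lay in layers:
                    lsub = sub[sub["layer"] == lay].reset_index(drop=True)
                    lX = _design(lsub, with_layer=False,
                                 extra_covariate=extra_covariate)
                    lfe, lcov, lcols = _fit_mixedlm(
                        lsub["density"], lX, lsub["subject_id"]
                    )
                    results.extend(
                        _pairwise_contrasts(
                            lfe, lcov, lcols, lsub, marker, lay, extra_covariate
                        )
                    )
        else:
            X = _design(sub, with_layer=False, extra_covariate=extra_covariate)
            fe, cov, cols = _fit_mixedlm(sub["density"], X, sub["subject_id"])
            results.extend(
                _pairwise_contrasts(fe, cov, cols, sub, marker, None,
                                    extra_covariate)
            )
    return results


def contrasts_to_frame(results: list[ContrastResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        d = dataclasses.asdict(r)
        d.pop("metadata")
        rows.append(d)
    return pd.DataFrame(rows)


def read_density_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV/TSV density table with strict schema validation."""
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    df["layer"] = df["layer"].where(df["layer"].notna(), None)
    return validate_records(df)


def save_contrasts(
    results: list[ContrastResult], out_dir: str | Path, stem: str = "contrasts"
) -> None:
    """Write the contrast table (CSV) and a JSON metadata sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    contrasts_to_frame(results).to_csv(out / f"{stem}.csv", index=False)
    meta = [
        {"marker": r.marker, "layer": r.layer, "comparison": r.comparison,
         **{k: v for k, v in r.metadata.items() if k != "adjusted_means"}}
        for r in results
    ]
    (out / f"{stem}_metadata.json").write_text(json.dumps(meta, indent=2))
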