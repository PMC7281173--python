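"""Parametric empirical-Bayes ComBat harmonization of the feature table.

Removes scanner-batch location/scale effects per feature: features are
standardized against the batch-size-weighted grand mean and pooled variance,
per-batch location (gamma) and scale (delta^2) are estimated on the
standardized data and shrunk toward normal / inverse-gamma priors whose
hyperparameters are moment-matched across features, iterating the coupled
EB updates to convergence.  Harmonization operates on the extracted feature
table (SUVs + texture features), never on voxels; laboratory values are not
scanner-derived and are not harmonized.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MAX_ITER = 100
TOL = 1e-6


@dataclass
class CombatModel:
    feature_names: list[str]
    batch_labels: list[str]
    grand_mean: np.ndarray          # per feature
    pooled_var: np.ndarray          # per feature
    gamma_star: dict[str, np.ndarray]   # batch -> per-feature shrunken location
    delta2_star: dict[str, np.ndarray]  # batch -> per-feature shrunken scale^2
    prior_params: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "feature_names": self.feature_names,
            "batch_labels": self.batch_labels,
            "grand_mean": self.grand_mean.tolist(),
            "pooled_var": self.pooled_var.tolist(),
            "gamma_star": {k: v.tolist() for k, v in self.gamma_star.items()},
            "delta2_star": {k: v.tolist() for k, v in self.delta2_star.items()},
            "prior_params": self.prior_params,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CombatModel":
        p = json.loads(Path(path).read_text())
        return cls(
            feature_names=p["feature_names"],
            batch_labels=p["batch_labels"],
            grand_mean=np.asarray(p["grand_mean"]),
            pooled_var=np.asarray(p["pooled_var"]),
            gamma_star={k: np.asarray(v) for k, v in p["gamma_star"].items()},
            delta2_star={k: np.asarray(v) for k, v in p["delta2_star"].items()},
            prior_params=p.get("prior_params", {}),
        )


def _inverse_gamma_moments(delta2_hat: np.ndarray) -> tuple[float, float]:
    """Moment-matched inverse-gamma prior (lambda, theta) for batch scales."""
    m = float(np.mean(delta2_hat))
    s2 = float(np.var(delta2_hat, ddof=1)) if delta2_hat.size > 1 else 0.0
    if s2 <= 0:
        # flat-ish prior when scales are identical across features
        return 2.0 + 1e-4, m * (1.0 + 1e-4)
    lam = (2.0 * s2 + m ** 2) / s2
    theta = (m * s2 + m ** 3) / s2
    return lam, theta


def combat_fit(features: pd.DataFrame, batch: pd.Series | np.ndarray) -> CombatModel:
    """Fit per-batch location/scale adjustments with EB shrinkage.

    ``features``: samples x features (numeric).  ``batch``: per-sample batch
    labels (>= 2 batches, each with >= 2 samples).
    """
    X = features.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("feature table contains missing values")
    names = list(features.columns)
    batch = pd.Series(np.asarray(batch).astype(str), index=features.index)
    levels = sorted(batch.unique())
    if len(levels) < 2:
        raise ValueError("need >= 2 batches for harmonization")
    sizes = {b: int((batch == b).sum()) for b in levels}
    for b, n in sizes.items():
        if n < 2:
            raise ValueError(f"singleton batch: {b!r} has {n} sample(s)")
    zero_var = [names[g] for g in range(X.shape[1]) if np.var(X[:, g]) == 0]
    if zero_var:
        raise ValueError(f"zero-variance feature(s): {zero_var}")

    n_total = X.shape[0]
    batch_idx = {b: np.flatnonzero((batch == b).to_numpy()) for b in levels}
    batch_means = np.vstack([X[batch_idx[b]].mean(axis=0) for b in levels])
    weights = np.array([sizes[b] / n_total for b in levels])
    grand_mean = weights @ batch_means
    # pooled variance of residuals around batch means
    resid = X.copy()
    for k, b in enumerate(levels):
        resid[batch_idx[b]] -= batch_means[k]
    pooled_var = (resid ** 2).sum(axis=0) / n_total
    pooled_sd = np.sqrt(pooled_var)

    Z = (X - grand_mean) / pooled_sd

    gamma_hat = {b: Z[batch_idx[b]].mean(axis=0) for b in levels}
    delta2_hat = {b: Z[batch_idx[b]].var(axis=0, ddof=1) for b in levels}

    gamma_star, delta2_star, priors = {}, {}, {}
    for b in levels:
        n_b = sizes[b]
        g_hat, d2_hat = gamma_hat[b], delta2_hat[b]
        gamma_bar = float(np.mean(g_hat))
        tau2 = float(np.var(g_hat, ddof=1)) if g_hat.size > 1 else 1.0
        tau2 = max(tau2, 1e-12)
        lam, theta = _inverse_gamma_moments(d2_hat)
        zb = Z[batch_idx[b]]

        g_star = g_hat.copy()
        d2_star = d2_hat.copy()
        for _ in range(MAX_ITER):
            g_new = (n_b * tau2 * g_hat + d2_star * gamma_bar) / (n_b * tau2 + d2_star)
            ss = ((zb - g_new) ** 2).sum(axis=0)
            d2_new = (theta + 0.5 * ss) / (n_b / 2.0 + lam - 1.0)
            change = max(
                float(np.max(np.abs(g_new - g_star))),
                float(np.max(np.abs(d2_new - d2_star))),
            )
            g_star, d2_star = g_new, d2_new
            if change < TOL:
                break
        gamma_star[b] = g_star
        delta2_star[b] = np.maximum(d2_star, 1e-12)
        priors[b] = {"gamma_bar": gamma_bar, "tau2": tau2, "lambda": lam, "theta": theta}

    return CombatModel(
        feature_names=names,
        batch_labels=levels,
        grand_mean=grand_mean,
        pooled_var=pooled_var,
        gamma_star=gamma_star,
        delta2_star=delta2_star,
        prior_params=priors,
    )


def combat_apply(
    features: pd.DataFrame, batch: pd.Series | np.ndarray, model: CombatModel
) -> pd.DataFrame:
    """Adjust a feature table with a fitted model:
    y* = sd_pooled * (z - gamma*) / delta* + grand_mean."""
    if list(features.columns) != model.feature_names:
        raise ValueError(
            f"feature names do not match model: {list(features.columns)} vs "
            f"{model.feature_names}"
        )
    batch = pd.Series(np.asarray(batch).astype(str), index=features.index)
    unseen = sorted(set(batch.unique()) - set(model.batch_labels))
    if unseen:
        raise ValueError(f"unseen batch label(s): {unseen}")
    X = features.to_numpy(dtype=float)
    pooled_sd = np.sqrt(model.pooled_var)
    Z = (X - model.grand_mean) / pooled_sd
    out = np.empty_like(Z)
    for b in model.batch_labels:
        idx = np.flatnonzero((batch == b).to_numpy())
        if idx.size == 0:
            continue
        delta_star = np.sqrt(model.delta2_star[b])
        out[idx] = (Z[idx] - model.gamma_star[b]) / delta_star
    out = out * pooled_sd + model.grand_mean
    return pd.DataFrame(out, index=features.index, columns=features.columns)


def identity_model(feature_names: list[str], batch_labels: list[str],
                   grand_mean=None, pooled_var=None) -> CombatModel:
    """A no-op model (gamma* = 0, delta* = 1 for every batch)."""
    p = len(feature_names)
    gm = np.zeros(p) if grand_mean is None else np.asarray(grand_mean, dtype=float)
    pv = np.ones(p) if pooled_var is None else np.asarray(pooled_var, dtype=float)
    return CombatModel(
        feature_names=list(feature_names),
        batch_labels=list(batch_labels),
        grand_mean=gm,
        pooled_var=pv,
        gamma_star={b: np.zeros(p) for b in batch_labels},
        delta2_star={b: np.ones(p) for b in batch_labels},
    )
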