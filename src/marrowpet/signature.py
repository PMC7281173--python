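"""Radiomic signature: correlation-matrix PCA with Kaiser retention.

The 19 harmonized features (3 SUV metrics + 16 texture features) are
z-scored and the correlation matrix eigendecomposed; components with
eigenvalue > 1 (Kaiser criterion) are retained and their scores constitute
the radiomic signature fed to the classifier.  Correlation-matrix (rather
than covariance) PCA is used because feature scales differ by orders of
magnitude (SUV vs. cluster prominence).
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class RadiomicSignature:
    feature_names: list[str]
    means: np.ndarray
    sds: np.ndarray                  # sample SD (ddof=1)
    loadings: np.ndarray             # features x retained components (orthonormal)
    eigenvalues: np.ndarray          # all, descending; sums to n_features
    n_retained: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "feature_names": self.feature_names,
                    "means": self.means.tolist(),
                    "sds": self.sds.tolist(),
                    "loadings": self.loadings.tolist(),
                    "eigenvalues": self.eigenvalues.tolist(),
                    "n_retained": self.n_retained,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "RadiomicSignature":
        p = json.loads(Path(path).read_text())
        return cls(
            feature_names=p["feature_names"],
            means=np.asarray(p["means"]),
            sds=np.asarray(p["sds"]),
            loadings=np.asarray(p["loadings"]),
            eigenvalues=np.asarray(p["eigenvalues"]),
            n_retained=int(p["n_retained"]),
        )


def fit_signature(features: pd.DataFrame) -> RadiomicSignature:
    """Eigendecompose the feature correlation matrix; retain eigenvalues > 1.

    Deterministic up to column sign; the sign is fixed so each loading
    column's largest-magnitude entry is positive.
    """
    X = features.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("feature table contains missing values")
    n, p = X.shape
    if n <= p:
        warnings.warn(
            f"n_samples ({n}) <= n_features ({p}): PCA eigenvalues will be unstable",
            stacklevel=2,
        )
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    zero = [features.columns[g] for g in np.flatnonzero(sds == 0)]
    if zero:
        raise ValueError(f"zero-variance feature(s): {zero}")
    Z = (X - means) / sds
    corr = (Z.T @ Z) / (n - 1)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    n_retained = int((evals > 1.0).sum())
    if n_retained == 0:
        raise ValueError("no component with eigenvalue > 1")
    near_one = np.abs(evals - 1.0) < 0.05
    if near_one.all():
        warnings.warn(
            "correlation matrix is near identity: retained component count is unstable",
            stacklevel=2,
        )
    loadings = evecs[:, :n_retained]
    # fix sign: largest-|entry| of each column positive
    for k in range(n_retained):
        j = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[j, k] < 0:
            loadings[:, k] = -loadings[:, k]
    return RadiomicSignature(
        feature_names=list(features.columns),
        means=means,
        sds=sds,
        loadings=loadings,
        eigenvalues=evals,
        n_retained=n_retained,
    )


def apply_signature(features: pd.DataFrame, sig: RadiomicSignature) -> pd.DataFrame:
    """Project a feature table onto the retained components (scores table)."""
    missing = [c for c in sig.feature_names if c not in features.columns]
    if missing:
        raise ValueError(f"missing feature column(s): {missing}")
    X = features[sig.feature_names].to_numpy(dtype=float)
    Z = (X - sig.means) / sig.sds
    scores = Z @ sig.loadings
    cols = [f"PC{k + 1}" for k in range(sig.n_retained)]
    return pd.DataFrame(scores, index=features.index, columns=cols)
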