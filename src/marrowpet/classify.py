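"""MLP classification with repeated 70/30 splits and median-(range) reporting.

For each endpoint x feature-set cell a small feed-forward network (default
one hidden layer of three tanh units, softmax-equivalent output) is trained
on a stratified 70% split and evaluated on the held-out 30%, five times.
By default the five repetitions re-randomize only the weight initialization
(the split is fixed per endpoint); re-randomizing the split as well is
available via ``resample_split``.  Inputs are standardized with
training-split statistics only.  AUC is the Mann-Whitney concordance
(concordant pairs + half the ties, over all positive-negative pairs),
computed on the test split.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.neural_network import MLPClassifier

from .cohort import ENDPOINTS, EndpointSpec

DEFAULT_FEATURE_SETS = ("suv", "signature", "signature+labs")
LAB_COLUMNS = ["wbc", "ldh"]


@dataclass(frozen=True)
class MLPConfig:
    n_hidden_layers: int = 1
    units_per_layer: int = 3
    max_epochs: int = 400
    alpha: float = 1e-4          # L2 penalty

    def __post_init__(self):
        if self.n_hidden_layers < 1:
            raise ValueError("need >= 1 hidden layer")
        if self.units_per_layer < 3:
            raise ValueError("need >= 3 units per hidden layer")


@dataclass
class RunResult:
    seed: int
    endpoint: str
    feature_set: str
    train_accuracy: float  # %
    test_accuracy: float   # %
    auc: float


@dataclass
class RunReport:
    runs: list[RunResult] = field(default_factory=list)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.runs])

    def summary(self) -> pd.DataFrame:
        """Median (min-max) of each outcome over the runs per cell."""
        df = self.frame()
        rows = []
        for (ep, fs), grp in df.groupby(["endpoint", "feature_set"], sort=False):
            row = {"endpoint": ep, "feature_set": fs, "n_runs": len(grp)}
            for metric in ("train_accuracy", "test_accuracy", "auc"):
                v = grp[metric].to_numpy()
                row[f"{metric}_median"] = float(np.median(v))
                row[f"{metric}_min"] = float(v.min())
                row[f"{metric}_max"] = float(v.max())
            rows.append(row)
        return pd.DataFrame(rows)


def stratified_split(
    labels: np.ndarray, train_fraction: float = 0.70, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/test indices preserving class proportions
    within one sample (train size rounded half-up per class)."""
    labels = np.asarray(labels).astype(bool)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("single-class input: both classes must be present")
    if counts.min() < 2:
        raise ValueError("each class needs >= 2 members")
    rng = np.random.default_rng(seed)
    train, test = [], []
    for c in classes:
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        n_train = int(np.floor(train_fraction * len(idx) + 0.5))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train.append(idx[:n_train])
        test.append(idx[n_train:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


@dataclass
class FittedMLP:
    model: MLPClassifier

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Probability of the positive class per sample."""
        return self.model.predict_proba(np.asarray(X, dtype=float))[:, 1]


def train_mlp(X: np.ndarray, y: np.ndarray, config: MLPConfig = MLPConfig(),
              seed: int = 0) -> FittedMLP:
    """Fit the tanh MLP; deterministic given seed.  Expects features already
    standardized with training-split statistics."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate single-class training split")
    model = MLPClassifier(
        hidden_layer_sizes=(config.units_per_layer,) * config.n_hidden_layers,
        activation="tanh",
        solver="lbfgs",
        alpha=config.alpha,
        max_iter=config.max_epochs,
        random_state=int(seed),
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warnings at fixed epoch budget
        model.fit(X, y)
    return FittedMLP(model)


def auc(prob: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC: (concordant + 0.5 * tied pairs) / (n+ * n-)."""
    prob = np.asarray(prob, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("single-class labels: AUC undefined")
    ranks = rankdata(prob)
    rank_sum_pos = float(ranks[labels].sum())
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def _standardize(train: np.ndarray, test: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (train - mu) / sd, (test - mu) / sd


def _single_run(X: np.ndarray, y: np.ndarray, split_seed: int, weight_seed: int,
                train_fraction: float, mlp: MLPConfig) -> tuple[float, float, float]:
    tr, te = stratified_split(y, train_fraction, split_seed)
    Xtr, Xte = _standardize(X[tr], X[te])
    fitted = train_mlp(Xtr, y[tr], mlp, seed=weight_seed)
    p_tr = fitted.predict_proba(Xtr)
    p_te = fitted.predict_proba(Xte)
    train_acc = 100.0 * float(np.mean((p_tr >= 0.5) == y[tr]))
    test_acc = 100.0 * float(np.mean((p_te >= 0.5) == y[te]))
    return train_acc, test_acc, auc(p_te, y[te])


def endpoint_labels(cohort: pd.DataFrame, spec: EndpointSpec):
    """(row positions into cohort, boolean labels) for one endpoint."""
    frame = cohort.reset_index(drop=True)
    if spec.involved_only:
        pos = np.flatnonzero(frame["involved"].astype(bool).to_numpy())
        frame = frame.iloc[pos]
    else:
        pos = np.arange(len(frame))
    labels = frame.apply(spec.label, axis=1).to_numpy(dtype=bool)
    return pos, labels


def feature_matrix(feature_set: str, suv: pd.DataFrame, scores: pd.DataFrame,
                   cohort: pd.DataFrame) -> np.ndarray:
    if feature_set == "suv":
        return suv.to_numpy(dtype=float)
    if feature_set == "signature":
        return scores.to_numpy(dtype=float)
    if feature_set == "signature+labs":
        labs = cohort[LAB_COLUMNS].to_numpy(dtype=float)
        return np.hstack([scores.to_numpy(dtype=float), labs])
    raise ValueError(f"unknown feature set {feature_set!r}")


def run_experiment(
    cohort: pd.DataFrame,
    suv: pd.DataFrame,
    scores: pd.DataFrame,
    endpoints: tuple[str, ...] = tuple(ENDPOINTS),
    feature_sets: tuple[str, ...] = DEFAULT_FEATURE_SETS,
    n_runs: int = 5,
    master_seed: int = 0,
    train_fraction: float = 0.70,
    resample_split: bool = False,
    mlp: MLPConfig = MLPConfig(),
) -> RunReport:
    """Train/evaluate every endpoint x feature-set cell ``n_runs`` times.

    The laboratory-augmented feature set applies to involvement-type
    endpoints only (Ki-67 is itself a laboratory-adjacent marker and the
    labs-added comparison is defined for marrow-involvement prediction).
    Rows of ``suv`` and ``scores`` must align with ``cohort``.
    """
    if not (len(cohort) == len(suv) == len(scores)):
        raise ValueError("cohort, suv and scores tables must align row-wise")
    report = RunReport()
    for ep_name in endpoints:
        spec = ENDPOINTS[ep_name]
        pos, labels = endpoint_labels(cohort, spec)
        if min(labels.sum(), (~labels).sum()) < 2:
            raise ValueError(f"endpoint {ep_name!r} has < 2 members in a class")
        for fs in feature_sets:
            if fs == "signature+labs" and spec.involved_only:
                continue
            X_full = feature_matrix(fs, suv, scores, cohort)
            X = X_full[pos]
            for r in range(n_runs):
                split_seed = master_seed + r if resample_split else master_seed
                weight_seed = master_seed + r
                tr_acc, te_acc, a = _single_run(
                    X, labels, split_seed, weight_seed, train_fraction, mlp
                )
                report.runs.append(
                    RunResult(weight_seed, ep_name, fs, tr_acc, te_acc, a)
                )
    return report
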