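"""The integrated deep-learning evaluation (IDLE) risk model.

Architecture: two hidden layers of logistic units trained jointly (with a
sigmoid read-out head) on the binary event-by-horizon label with
cross-entropy loss and an L2 penalty, magnitude pruning of small weights
(the layers double as feature selectors), and a random survival forest on
the input variables the pruned network routes into the second hidden layer.
The forest's predicted cumulative hazard at the horizon, min-max normalised
to [0, 1] over the training set, is the risk score.  Scores for evaluation are produced by
leave-one-patient-out cross-validation (LOOCV): each patient is scored by a
model trained on the other n-1, with standardization statistics, layer
weights, pruning thresholds and the forest all re-derived inside the fold so
no test-fold information enters training.

Single-platform ablations drop the CT or the tissue feature block while
keeping demographics and the screening-to-surgery interval, and use exactly
the same fitting procedure.

Shaped after the statsmodels convention: :class:`IDLEModel` holds the data,
``fit`` / ``fit_loocv`` return results objects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ct.registry import FEATURE_NAMES as CT_FEATURE_NAMES
from .tissue import CLINICAL_COLUMNS, TISSUE_COLUMNS

PLATFORMS = ("integrated", "ldct_only", "tissue_only")


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture and training hyperparameters.

    ``l2_grid`` is searched per fit on an internal 75/25 split of the
    training patients by validation cross-entropy; ``prune_percentile`` is
    the per-layer percentile of |w| below which weights are zeroed;
    ``horizon_tau`` (years) defines the binary label for the hidden layers
    and the horizon at which the forest's cumulative hazard is read off.
    """

    h1_units: int = 32
    h2_units: int = 16
    l2_grid: tuple = (0.001, 0.01, 0.1)
    prune_percentile: float = 90.0
    horizon_tau: float = 5.0
    n_trees: int = 500
    min_node: int = 5
    max_iter: int = 600
    tol: float = 1e-7

    def validate(self):
        if self.h1_units < 1 or self.h2_units < 1:
            raise ValueError("hidden layers need at least one unit")
        if any(l2 < 0 for l2 in self.l2_grid):
            raise ValueError("l2 penalties must be >= 0")
        if not 0 <= self.prune_percentile <= 100:
            raise ValueError("prune_percentile must be a percentile")


def _sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def _init_weights(p, h1, h2, rng):
    W1 = rng.normal(0.0, 1.0, size=(p + 1, h1)) / np.sqrt(p + 1)
    W2 = rng.normal(0.0, 1.0, size=(h1 + 1, h2)) / np.sqrt(h1 + 1)
    w3 = rng.normal(0.0, 1.0, size=(h2 + 1, 1)) / np.sqrt(h2 + 1)
    W1[:-1] *= 3.0  # larger input-layer spread keeps the units diverse
    return W1, W2, w3


def _forward(X, W1, W2, w3):
    A1 = _sigmoid(np.hstack([X, np.ones((X.shape[0], 1))]) @ W1)
    A2 = _sigmoid(np.hstack([A1, np.ones((A1.shape[0], 1))]) @ W2)
    out = _sigmoid(np.hstack([A2, np.ones((A2.shape[0], 1))]) @ w3)[:, 0]
    return A1, A2, out


def _train_mlp(X, y, W1, W2, w3, l2, max_iter, tol,
               masks=None, lr: float = 0.05):
    """Full-batch Adam on cross-entropy + l2 * sum of squared weights
    (biases unpenalised).

    The penalty doubles as the feature selector: at the strengths chosen by
    the validation grid it forces weights onto label-correlated inputs, so
    post-training weight magnitude ranks feature relevance.  ``masks``
    optionally fixes pruned weights at zero (their gradients are masked), so
    a post-pruning retraining phase only optimises surviving weights.
    Operates on copies and returns the trained weights.
    """
    n = X.shape[0]
    Xb = np.hstack([X, np.ones((n, 1))])
    params = [W1.copy(), W2.copy(), w3.copy()]
    if masks is not None:
        for P, m in zip(params, masks):
            P[:-1][~m] = 0.0
    mom = [np.zeros_like(P) for P in params]
    vel = [np.zeros_like(P) for P in params]
    b1, b2, eps = 0.9, 0.999, 1e-8
    yv = y.astype(float)
    for it in range(1, max_iter + 1):
        W1c, W2c, w3c = params
        A1 = _sigmoid(Xb @ W1c)
        A1b = np.hstack([A1, np.ones((n, 1))])
        A2 = _sigmoid(A1b @ W2c)
        A2b = np.hstack([A2, np.ones((n, 1))])
        out = _sigmoid(A2b @ w3c)[:, 0]
        d3 = (out - yv)[:, None] / n
        g3 = A2b.T @ d3
        d2 = (d3 @ w3c[:-1].T) * A2 * (1 - A2)
        g2 = A1b.T @ d2
        d1 = (d2 @ W2c[:-1].T) * A1 * (1 - A1)
        g1 = Xb.T @ d1
        grads = [g1, g2, g3]
        for P, g in zip(params, grads):
            g[:-1] += 2.0 * l2 * P[:-1]
        if masks is not None:
            for g, m in zip(grads, masks):
                g[:-1][~m] = 0.0
        gmax = 0.0
        for P, g, mo, ve in zip(params, grads, mom, vel):
            mo *= b1
            mo += (1 - b1) * g
            ve *= b2
            ve += (1 - b2) * g * g
            mhat = mo / (1 - b1 ** it)
            vhat = ve / (1 - b2 ** it)
            P -= lr * mhat / (np.sqrt(vhat) + eps)
            gmax = max(gmax, float(np.abs(g).max()))
        if gmax < tol:
            break
    return params


def _prune_mask(W, percentile):
    """Keep-mask for weights (not biases): |w| below the layer-wide
    percentile is pruned.  Percentile 0 keeps everything."""
    if percentile <= 0:
        return np.ones_like(W[:-1], dtype=bool)
    thr = np.percentile(np.abs(W[:-1]).ravel(), percentile)
    return ~(np.abs(W[:-1]) < thr)


def _xent(out, y):
    o = np.clip(out, 1e-12, 1 - 1e-12)
    return float(np.mean(-(y * np.log(o) + (1 - y) * np.log(1 - o))))


def _select_l2(X, y, config, rng):
    """Pick the penalty with the lowest cross-entropy on an internal 25%
    validation split (whole set when the split would be degenerate)."""
    grid = config.l2_grid
    if len(grid) == 1:
        return grid[0]
    n = X.shape[0]
    idx = rng.permutation(n)
    n_val = max(n // 4, 1)
    val, tr = idx[:n_val], idx[n_val:]
    if tr.size < 8 or len(np.unique(y[tr])) < 2 or len(np.unique(y[val])) < 2:
        tr = val = idx
    best, best_loss = grid[0], np.inf
    init = _init_weights(X.shape[1], config.h1_units, config.h2_units,
                         np.random.default_rng(rng.integers(2 ** 31)))
    for l2 in grid:
        W1, W2, w3 = _train_mlp(X[tr], y[tr], *init, l2,
                                config.max_iter, config.tol)
        _, _, out = _forward(X[val], W1, W2, w3)
        loss = _xent(out, y[val])
        if loss < best_loss:
            best, best_loss = l2, loss
    return best


def event_by_horizon_labels(outcomes: pd.DataFrame, tau: float):
    """Binary event-by-tau labels and the mask of label-usable patients.

    label 1: event at or before tau; label 0: followed beyond tau without an
    event by tau; patients censored before tau without an event carry no
    label (mask False) and are used only by the survival forest.
    """
    time = outcomes["time"].to_numpy(dtype=float)
    event = outcomes["event"].to_numpy(dtype=int)
    label = ((event == 1) & (time <= tau)).astype(float)
    usable = ((event == 1) & (time <= tau)) | (time > tau)
    return label, usable


@dataclass
class NetworkTrace:
    """Per-input-feature selection counts across both hidden layers."""
    feature_names: tuple
    layer1_counts: np.ndarray
    layer2_counts: np.ndarray

    @property
    def selection_counts(self) -> pd.Series:
        return pd.Series(self.layer1_counts + self.layer2_counts,
                         index=list(self.feature_names), name="selection_count")


def fit_hidden_layers(X: np.ndarray, labels: np.ndarray, config: NetworkConfig,
                      rng, feature_names=None):
    """Fit and prune both hidden layers; returns (W1, W2, trace).

    Both layers are optimised jointly with a sigmoid read-out head on the
    binary event-by-horizon label (cross-entropy + L2); per-layer magnitude
    pruning then zeroes the smallest weights, and the surviving weights are
    re-optimised with the zeros held fixed.  The read-out head exists only
    to train the layers; downstream risk comes from the survival forest.
    """
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite model inputs")
    if len(np.unique(labels)) < 2:
        raise ValueError("hidden-layer training needs both label classes")
    l2 = _select_l2(X, labels, config, rng)
    init = _init_weights(X.shape[1], config.h1_units, config.h2_units, rng)
    W1, W2, w3 = _train_mlp(X, labels, *init, l2, config.max_iter, config.tol)
    masks = [_prune_mask(W1, config.prune_percentile),
             _prune_mask(W2, config.prune_percentile),
             np.ones_like(w3[:-1], dtype=bool)]
    W1, W2, w3 = _train_mlp(X, labels, W1, W2, w3, l2,
                            config.max_iter // 2, config.tol, masks=masks)
    nz1 = W1[:-1] != 0.0          # p x h1
    nz2 = W2[:-1] != 0.0          # h1 x h2
    l1 = nz1.sum(axis=1)
    l2c = ((nz1.astype(int) @ nz2.astype(int)) > 0).sum(axis=1)
    names = tuple(feature_names) if feature_names is not None else tuple(
        f"x{i}" for i in range(X.shape[1]))
    return W1, W2, NetworkTrace(names, l1, l2c)


def fit_survival_forest(H2: np.ndarray, outcomes: pd.DataFrame,
                        config: NetworkConfig, seed: int):
    """Random survival forest on the network-selected input variables.

    Log-rank splitting and ``min_node`` minimum leaf size; every candidate
    feature is considered at each split (the selection stage has already
    reduced the inputs to a small subset, and full mtry lets the trees model
    cross-feature interactions), and the risk read-out is the ensemble
    cumulative hazard at the horizon.
    """
    from sksurv.ensemble import RandomSurvivalForest
    from sksurv.util import Surv

    event = outcomes["event"].to_numpy(dtype=bool)
    if event.sum() == 0:
        raise ValueError("survival forest needs at least one event")
    y = Surv.from_arrays(event, outcomes["time"].to_numpy(dtype=float))
    # full mtry on a sparse selection; sqrt fallback keeps wide inputs cheap
    mtry = None if H2.shape[1] <= 25 else "sqrt"
    rsf = RandomSurvivalForest(
        n_estimators=config.n_trees, min_samples_leaf=config.min_node,
        max_features=mtry, random_state=int(seed), n_jobs=1)
    rsf.fit(H2, y)
    return rsf


def _chf_at_tau(rsf, H2, tau):
    chf = rsf.predict_cumulative_hazard_function(H2, return_array=True)
    times = rsf.unique_times_
    idx = int(np.searchsorted(times, tau, side="right")) - 1
    if idx < 0:
        return np.zeros(H2.shape[0])
    return chf[:, idx]


class IDLEModel:
    """Integrated deep-learning evaluation of progression risk.

    Parameters
    ----------
    X : DataFrame
        Raw (unstandardized) per-patient inputs indexed by patient_id:
        clinical block, tissue block, CT feature block.
    outcomes : DataFrame
        Columns patient_id, time (years), event (0/1).
    platform : str
        'integrated' uses every column, 'ldct_only' drops the tissue block,
        'tissue_only' drops the CT block; demographics and the
        screening-to-surgery interval stay in all platforms.
    """

    def __init__(self, X: pd.DataFrame, outcomes: pd.DataFrame,
                 platform: str = "integrated", config: NetworkConfig | None = None):
        if platform not in PLATFORMS:
            raise ValueError(f"platform must be one of {PLATFORMS}")
        self.config = config or NetworkConfig()
        self.config.validate()
        self.platform = platform
        outcomes = outcomes.set_index("patient_id") if "patient_id" in outcomes.columns \
            else outcomes
        common = X.index.intersection(outcomes.index)
        if len(common) != len(X.index):
            raise KeyError("X and outcomes must share patient ids")
        self.X = self._platform_columns(X)
        self.outcomes = outcomes.loc[self.X.index].reset_index(names="patient_id")
        if self.X.isna().any().any():
            raise ValueError("model inputs contain missing values")

    def _platform_columns(self, X: pd.DataFrame) -> pd.DataFrame:
        ct = [c for c in X.columns if c in CT_FEATURE_NAMES]
        tissue = [c for c in X.columns if c in TISSUE_COLUMNS]
        if self.platform == "ldct_only":
            return X.drop(columns=tissue)
        if self.platform == "tissue_only":
            return X.drop(columns=ct)
        return X

    # -- fitting -----------------------------------------------------------

    def _standardize(self, Xdf, mu=None, sd=None):
        A = Xdf.to_numpy(dtype=float)
        if mu is None:
            mu = A.mean(axis=0)
            sd = A.std(axis=0, ddof=0)
        out = np.where(sd > 0, (A - mu) / np.where(sd > 0, sd, 1.0), 0.0)
        return out, mu, sd

    def fit(self, seed: int = 0) -> "IDLEResults":
        """Fit on every patient; returns the trained network + forest.

        The hidden layers are trained on the event-by-horizon label and act
        as the feature selector: the survival forest is grown on the input
        variables that retain a nonzero chained path into the second hidden
        layer after pruning.
        """
        rng = np.random.default_rng(seed)
        Xs, mu, sd = self._standardize(self.X)
        labels, usable = event_by_horizon_labels(self.outcomes, self.config.horizon_tau)
        W1, W2, trace = fit_hidden_layers(Xs[usable], labels[usable], self.config,
                                          rng, self.X.columns)
        selected = trace.layer2_counts > 0
        if not selected.any():
            selected = trace.layer1_counts > 0
        if not selected.any():
            selected = np.ones(Xs.shape[1], dtype=bool)
        rsf = fit_survival_forest(Xs[:, selected], self.outcomes, self.config,
                                  rng.integers(2 ** 31))
        raw = _chf_at_tau(rsf, Xs[:, selected], self.config.horizon_tau)
        bounds = (float(raw.min()), float(raw.max()))
        return IDLEResults(self, W1, W2, rsf, trace, selected, (mu, sd), bounds, raw)

    def fit_loocv(self, seed: int = 0) -> "LOOCVResults":
        """Leave-one-patient-out scores: one fit per held-out patient."""
        n = len(self.X)
        if n < 10:
            raise ValueError("LOOCV needs at least 10 patients")
        scores = np.full(n, np.nan)
        failures = []
        for i in range(n):
            keep = np.ones(n, dtype=bool)
            keep[i] = False
            sub = IDLEModel.__new__(IDLEModel)
            sub.config, sub.platform = self.config, self.platform
            sub.X = self.X.iloc[keep]
            sub.outcomes = self.outcomes.iloc[keep].reset_index(drop=True)
            try:
                # every fold starts from the same seed so identical training
                # sets (e.g. duplicated patients) give identical scores
                res = sub.fit(seed)
                scores[i] = res.predict(self.X.iloc[[i]])[0]
            except ValueError as exc:
                failures.append((self.X.index[i], str(exc)))
        table = pd.DataFrame({"patient_id": self.X.index,
                              "platform": self.platform,
                              "idle_score": scores})
        return LOOCVResults(self, table, failures)


@dataclass
class IDLEResults:
    """A trained IDLE network: pruned layers, the per-feature selection
    trace, the forest on the selected input variables, and the [0, 1]
    normalisation bounds."""

    model: IDLEModel
    W1: np.ndarray
    W2: np.ndarray
    forest: object
    trace: NetworkTrace
    selected: np.ndarray
    scaler: tuple
    risk_bounds: tuple
    training_risks: np.ndarray

    def hidden_activations(self, Xdf: pd.DataFrame):
        """Layer-1 and layer-2 activations for raw input rows."""
        if list(Xdf.columns) != list(self.model.X.columns):
            raise ValueError("input schema does not match the trained model")
        Xs, _, _ = self.model._standardize(Xdf, *self.scaler)
        A1 = _sigmoid(np.hstack([Xs, np.ones((Xs.shape[0], 1))]) @ self.W1)
        H2 = _sigmoid(np.hstack([A1, np.ones((A1.shape[0], 1))]) @ self.W2)
        return A1, H2

    def predict(self, Xdf: pd.DataFrame) -> np.ndarray:
        """IDLE scores in [0, 1]: forest cumulative hazard at the horizon,
        min-max normalised by the training-risk bounds and clipped."""
        if list(Xdf.columns) != list(self.model.X.columns):
            raise ValueError("input schema does not match the trained model")
        Xs, _, _ = self.model._standardize(Xdf, *self.scaler)
        raw = _chf_at_tau(self.forest, Xs[:, self.selected],
                          self.model.config.horizon_tau)
        lo, hi = self.risk_bounds
        if hi <= lo:
            return np.full(raw.shape, 0.5)
        return np.clip((raw - lo) / (hi - lo), 0.0, 1.0)

    def selection_ranking(self) -> pd.DataFrame:
        counts = self.trace.selection_counts.sort_values(ascending=False)
        return pd.DataFrame({"feature": counts.index,
                             "selection_count": counts.to_numpy(),
                             "rank": np.arange(1, len(counts) + 1)})

    def summary(self) -> str:
        c = self.model.config
        top = self.selection_ranking().head(8)
        lines = [
            "IDLE network fit",
            f"  platform: {self.model.platform}",
            f"  patients: {len(self.model.X)}  inputs: {self.model.X.shape[1]}",
            f"  hidden units: {c.h1_units}/{c.h2_units}  prune pct: {c.prune_percentile}",
            f"  forest: {c.n_trees} trees, horizon tau = {c.horizon_tau} y",
            f"  training risk bounds: [{self.risk_bounds[0]:.4f}, {self.risk_bounds[1]:.4f}]",
            "  most-selected features:",
        ]
        for _, r in top.iterrows():
            lines.append(f"    {r['rank']:>3}. {r['feature']} ({int(r['selection_count'])})")
        return "\n".join(lines)


@dataclass
class LOOCVResults:
    """Leave-one-patient-out IDLE scores for one platform."""

    model: IDLEModel
    scores: pd.DataFrame
    failed_folds: list

    def summary(self) -> str:
        s = self.scores["idle_score"]
        return "\n".join([
            f"LOOCV IDLE scores ({self.model.platform})",
            f"  patients scored: {s.notna().sum()} / {len(s)}"
            + (f"  ({len(self.failed_folds)} failed folds)" if self.failed_folds else ""),
            f"  score range: [{s.min():.3f}, {s.max():.3f}]  mean {s.mean():.3f}",
        ])


def loocv_scores(X: pd.DataFrame, outcomes: pd.DataFrame, platform: str,
                 config: NetworkConfig | None = None, seed: int = 0) -> pd.DataFrame:
    """Functional wrapper: LOOCV risk-score table for one platform."""
    return IDLEModel(X, outcomes, platform, config).fit_loocv(seed).scores
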