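"""Single-unit perturbation-condition decoding with a two-layer backprop net.

Features are release-aligned binned firing rates of one (or more) units;
targets are -1/0/+1 condition codes.  The network has one tanh hidden layer
and a linear scalar output, trained by full-batch gradient descent on the
squared error of the training half of the trials.  Test outputs are turned
into decisions with the +/-0.6 threshold rule; outputs in the (0.4, 0.6)
dead zones yield no decision and count as incorrect.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .simulate.design import TrialRecord

TASKS = ("condition", "direction")

#: decision thresholds of the output rule
THRESHOLD = 0.6
ZERO_BAND = 0.4

CLUSTERS = (("low", 0.0, 0.2), ("fair", 0.2, 0.5), ("high", 0.5, 1.0))


class DecodeError(ValueError):
    pass


# --- feature extraction ----------------------------------------------------

@dataclass
class FeatureMatrix:
    """Trial-by-feature matrix with -1/0/+1 labels for one target side."""

    X: np.ndarray
    y: np.ndarray
    trial_ids: np.ndarray
    side: str
    task: str
    window: tuple[float, float]
    bin_width: float

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


def _condition_label(trial: TrialRecord, task: str) -> Optional[int]:
    c = trial.condition
    unperturbed_90 = (not trial.perturbed and trial.initial_orientation == 90.0
                      and trial.final_orientation == 90.0)
    if task == "condition":
        if c in ("random_CW", "random_CCW"):
            return -1
        if unperturbed_90:
            return 0
        if c in ("repeat_CW", "repeat_CCW"):
            return 1
    elif task == "direction":
        if c == "repeat_CCW":
            return -1
        if unperturbed_90:
            return 0
        if c == "repeat_CW":
            return 1
    else:
        raise DecodeError(f"unknown task {task!r}; choose from {TASKS}")
    return None


def _random_direction_label(trial: TrialRecord) -> Optional[int]:
    return {"random_CCW": -1, "random_CW": 1}.get(trial.condition)


def binned_rates(spikes: np.ndarray, t_ref: float,
                 window: tuple[float, float], bin_width: float) -> np.ndarray:
    lo, hi = window
    nbins = int(round((hi - lo) / bin_width))
    edges = t_ref + lo + np.arange(nbins + 1) * bin_width
    counts, _ = np.histogram(np.asarray(spikes), bins=edges)
    return counts / bin_width


def extract_features(
    spikes_by_trial: dict[int, np.ndarray],
    trials: Iterable[TrialRecord],
    task: str = "condition",
    side: str = "right",
    window: tuple[float, float] = (-0.300, 0.500),
    bin_width: float = 0.020,
    label_fn=None,
) -> FeatureMatrix:
    """Binned-rate features around center release for one target side.

    ``label_fn`` overrides the task labelling (used for the random-trial
    cross-test); trials it maps to None are dropped.
    """
    if label_fn is None:
        label_fn = lambda t: _condition_label(t, task)
    rows, labels, ids = [], [], []
    for trial in trials:
        if trial.target_side != side:
            continue
        lab = label_fn(trial)
        if lab is None:
            continue
        rows.append(binned_rates(spikes_by_trial.get(trial.trial_id, np.empty(0)),
                                 trial.t_center_release, window, bin_width))
        labels.append(lab)
        ids.append(trial.trial_id)
    if not rows:
        raise DecodeError("no trials matched the requested task/side")
    return FeatureMatrix(X=np.vstack(rows), y=np.asarray(labels, dtype=float),
                         trial_ids=np.asarray(ids), side=side, task=task,
                         window=window, bin_width=bin_width)


# --- network ---------------------------------------------------------------

@dataclass
class BpNetwork:
    """Two-layer perceptron: tanh hidden layer, linear scalar output."""

    W1: np.ndarray  # (hidden, inputs)
    b1: np.ndarray  # (hidden,)
    w2: np.ndarray  # (hidden,)
    b2: float

    def forward(self, X: np.ndarray) -> np.ndarray:
        H = np.tanh(X @ self.W1.T + self.b1)
        return H @ self.w2 + self.b2

    @classmethod
    def init(cls, n_inputs: int, hidden: int, rng: np.random.Generator) -> "BpNetwork":
        return cls(
            W1=rng.uniform(-1, 1, (hidden, n_inputs)) / np.sqrt(n_inputs),
            b1=np.zeros(hidden),
            w2=rng.uniform(-1, 1, hidden) / np.sqrt(hidden),
            b2=0.0,
        )


@dataclass
class Scaler:
    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Scaler":
        sd = X.std(axis=0, ddof=0)
        return cls(mean=X.mean(axis=0), sd=np.where(sd > 0, sd, 1.0))

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd


def stratified_split(y: np.ndarray, rng: np.random.Generator,
                     train_frac: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Random half split keeping every class present in both halves."""
    train_idx, test_idx = [], []
    for cls in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == cls))
        if idx.size < 2:
            raise DecodeError(f"class {cls} has fewer than 2 trials")
        n_train = max(1, min(idx.size - 1, int(round(train_frac * idx.size))))
        train_idx.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])
    return np.sort(np.asarray(train_idx)), np.sort(np.asarray(test_idx))


@dataclass
class TrainedDecoder:
    network: BpNetwork
    scaler: Scaler
    loss_history: np.ndarray
    train_idx: np.ndarray
    test_idx: np.ndarray
    features: FeatureMatrix


def fit_network(X: np.ndarray, y: np.ndarray, hidden: int = 10,
                learning_rate: float = 0.05, epochs: int = 800,
                weight_decay: float = 0.0, loss_tol: float = 0.0,
                rng: np.random.Generator | None = None
                ) -> tuple[BpNetwork, np.ndarray]:
    """Full-batch gradient descent on the squared error; returns loss per epoch.

    The step uses the mean-squared-error gradient so the learning rate is
    insensitive to the number of training trials; the minimiser is the same
    as for the summed squared error.  ``weight_decay`` adds an L2 penalty on
    the weights (not the biases); training stops early once the mean squared
    error drops below ``loss_tol``.
    """
    rng = rng or np.random.default_rng()
    n, d = X.shape
    net = BpNetwork.init(d, hidden, rng)
    losses = []
    for epoch in range(epochs):
        Z = X @ net.W1.T + net.b1
        H = np.tanh(Z)
        out = H @ net.w2 + net.b2
        err = out - y
        sse = float(np.sum(err**2))
        losses.append(sse)
        if sse / n < loss_tol:
            break
        g = 2.0 * err / n
        gw2 = H.T @ g + 2.0 * weight_decay * net.w2
        gb2 = float(np.sum(g))
        gH = np.outer(g, net.w2) * (1.0 - H**2)
        gW1 = gH.T @ X + 2.0 * weight_decay * net.W1
        gb1 = gH.sum(axis=0)
        net.w2 -= learning_rate * gw2
        net.b2 -= learning_rate * gb2
        net.W1 -= learning_rate * gW1
        net.b1 -= learning_rate * gb1
    return net, np.asarray(losses)


def train_bp(features: FeatureMatrix, hidden: int = 10,
             learning_rate: float = 0.05, epochs: int = 800,
             weight_decay: float = 0.05, loss_tol: float = 0.0,
             seed: int | np.random.Generator = 0,
             train_frac: float = 0.5) -> TrainedDecoder:
    """Stratified 50/50 split, z-score on training statistics, train the net."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    train_idx, test_idx = stratified_split(features.y, rng, train_frac)
    if np.unique(features.y[train_idx]).size < np.unique(features.y).size:
        raise DecodeError("a class is absent from the training set")
    scaler = Scaler.fit(features.X[train_idx])
    net, losses = fit_network(scaler.transform(features.X[train_idx]),
                              features.y[train_idx], hidden, learning_rate,
                              epochs, weight_decay, loss_tol, rng)
    return TrainedDecoder(network=net, scaler=scaler, loss_history=losses,
                          train_idx=train_idx, test_idx=test_idx,
                          features=features)


# --- decision rule and scoring ---------------------------------------------

def decide(outputs: np.ndarray) -> np.ndarray:
    """Threshold rule: -1 / 0 / +1, NaN where no decision applies."""
    out = np.asarray(outputs, dtype=float)
    dec = np.full(out.shape, np.nan)
    dec[out <= -THRESHOLD] = -1
    dec[out >= THRESHOLD] = 1
    dec[np.abs(out) <= ZERO_BAND] = 0
    return dec


@dataclass
class DecodeResult:
    outputs: np.ndarray
    decisions: np.ndarray
    labels: np.ndarray
    trial_ids: np.ndarray

    @property
    def rate(self) -> float:
        """Correct prediction rate; no-decision trials count as incorrect."""
        if self.labels.size == 0:
            return np.nan
        ok = np.isfinite(self.decisions) & (self.decisions == self.labels)
        return float(np.mean(ok))

    @property
    def cluster(self) -> str:
        return cluster_of(self.rate)


def classify(decoder: TrainedDecoder, X: np.ndarray, y: np.ndarray,
             trial_ids: np.ndarray | None = None) -> DecodeResult:
    out = decoder.network.forward(decoder.scaler.transform(X))
    return DecodeResult(outputs=out, decisions=decide(out), labels=np.asarray(y),
                        trial_ids=(trial_ids if trial_ids is not None
                                   else np.arange(len(y))))


def classify_test_set(decoder: TrainedDecoder,
                      n_per_class: int | None = None,
                      rng: np.random.Generator | None = None) -> DecodeResult:
    """Score the held-out half; optionally subsample n trials per class."""
    fm = decoder.features
    idx = decoder.test_idx
    if n_per_class is not None:
        rng = rng or np.random.default_rng()
        picked = []
        for cls in np.unique(fm.y[idx]):
            cls_idx = idx[fm.y[idx] == cls]
            if cls_idx.size < n_per_class:
                raise DecodeError("not enough test trials to subsample")
            picked.extend(rng.choice(cls_idx, n_per_class, replace=False))
        idx = np.sort(np.asarray(picked))
    return classify(decoder, fm.X[idx], fm.y[idx], fm.trial_ids[idx])


def cross_test_random(decoder: TrainedDecoder,
                      spikes_by_trial: dict[int, np.ndarray],
                      trials: Iterable[TrialRecord]) -> DecodeResult:
    """Feed random-perturbation trials to a direction-task network.

    Trials are labelled by their actual perturbation direction (CW = +1,
    CCW = -1); unperturbed trials of the random set are excluded since they
    carry no direction label.  Scoring uses the same threshold rule.
    """
    if decoder.features.task != "direction":
        raise DecodeError("cross-test requires a direction-task decoder")
    fm = extract_features(spikes_by_trial, trials, task="direction",
                          side=decoder.features.side,
                          window=decoder.features.window,
                          bin_width=decoder.features.bin_width,
                          label_fn=_random_direction_label)
    return classify(decoder, fm.X, fm.y, fm.trial_ids)


def cluster_of(rate: float) -> str:
    """low: [0, 0.2], fair: (0.2, 0.5], high: (0.5, 1]."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    for name, lo, hi in CLUSTERS:
        if rate <= hi:
            return name
    return "high"


def cluster_rates(rates: Iterable[float]) -> dict[str, int]:
    """Fixed-boundary histogram of per-neuron correct prediction rates."""
    counts = {name: 0 for name, _, _ in CLUSTERS}
    for r in rates:
        counts[cluster_of(float(r))] += 1
    return counts
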