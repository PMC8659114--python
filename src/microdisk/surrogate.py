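"""Single-hidden-layer MLP surrogate trained by Levenberg-Marquardt.

The surrogate regresses a concentration profile (S or H) on the radial
coordinate R with a 1-H-1 network: log-sigmoid hidden units, linear output.
Training is full-batch Levenberg-Marquardt on the sum-of-squares error with
an analytic Jacobian, Nguyen-Widrow initialization, and early stopping after
a fixed number of consecutive validation-error increases; the weights at the
best validation error are the ones returned.  All of it is implemented here
directly — the optimizer is the point of the module.

`MLPSurrogateRegressor` exposes the pipeline as a scikit-learn estimator
(fit/predict/get_params); the module-level functions underneath are the
spec'd primitives and remain usable on their own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "MLPSurrogate",
    "LMConfig",
    "Dataset",
    "TrainingRecord",
    "init_network",
    "forward",
    "split_dataset",
    "lm_train",
    "MLPSurrogateRegressor",
]


@dataclass
class MLPSurrogate:
    """Weights of a 1-H-1 network plus the affine input map to [-1, 1].

    Prediction: b_out + sum_j w_out[j] * logsig(w_in[j]*x + b_hidden[j])
    where x = input_scale[0]*R + input_scale[1] and
    logsig(z) = 1/(1 + exp(-z)).
    """

    w_in: np.ndarray
    b_hidden: np.ndarray
    w_out: np.ndarray
    b_out: float
    input_scale: tuple[float, float]

    def __post_init__(self) -> None:
        self.w_in = np.asarray(self.w_in, dtype=float)
        self.b_hidden = np.asarray(self.b_hidden, dtype=float)
        self.w_out = np.asarray(self.w_out, dtype=float)
        if not (self.w_in.shape == self.b_hidden.shape == self.w_out.shape):
            raise ValueError("weight vectors must share one length")
        if self.w_in.size < 1:
            raise ValueError("need at least one hidden unit")
        for arr in (self.w_in, self.b_hidden, self.w_out):
            if not np.all(np.isfinite(arr)):
                raise ValueError("weights must be finite")

    @property
    def n_hidden(self) -> int:
        return self.w_in.size

    @property
    def n_params(self) -> int:
        return 3 * self.n_hidden + 1

    def pack(self) -> np.ndarray:
        return np.concatenate(
            [self.w_in, self.b_hidden, self.w_out, [self.b_out]]
        )

    def unpack(self, theta: np.ndarray) -> "MLPSurrogate":
        H = self.n_hidden
        return MLPSurrogate(
            w_in=theta[:H].copy(),
            b_hidden=theta[H:2 * H].copy(),
            w_out=theta[2 * H:3 * H].copy(),
            b_out=float(theta[3 * H]),
            input_scale=self.input_scale,
        )


@dataclass(frozen=True)
class LMConfig:
    """Levenberg-Marquardt damping schedule and stopping rules.

    ``mu`` multiplies the identity added to J'J; an accepted step shrinks it
    by ``mu_dec``, a rejected one grows it by ``mu_inc`` until ``mu_max``
    aborts.  ``grad_tol`` is on the max-norm of the MSE gradient.
    """

    mu0: float = 1e-3
    mu_inc: float = 10.0
    mu_dec: float = 0.1
    mu_max: float = 1e10
    grad_tol: float = 1e-7
    max_epochs: int = 1000
    max_val_fail: int = 6

    def __post_init__(self) -> None:
        if self.mu_inc <= 1 or not 0 < self.mu_dec < 1:
            raise ValueError("need mu_inc > 1 and 0 < mu_dec < 1")
        if self.grad_tol <= 0:
            raise ValueError("grad_tol must be positive")


@dataclass
class Dataset:
    """(R, target) pairs with an optional train/val/test split labelling."""

    inputs: np.ndarray
    targets: np.ndarray
    split: Optional[np.ndarray] = None  # entries in {"train","val","test"}

    def __post_init__(self) -> None:
        self.inputs = np.asarray(self.inputs, dtype=float)
        self.targets = np.asarray(self.targets, dtype=float)
        if self.inputs.shape != self.targets.shape:
            raise ValueError("inputs and targets must share one shape")
        if not np.all(np.isfinite(self.targets)):
            raise ValueError("targets must be finite")

    def subset(self, label: str) -> tuple[np.ndarray, np.ndarray]:
        if self.split is None:
            raise ValueError("dataset has no split labels")
        m = self.split == label
        return self.inputs[m], self.targets[m]


@dataclass
class TrainingRecord:
    """Per-epoch diagnostics of one LM run."""

    mse_train: list = field(default_factory=list)
    mse_val: list = field(default_factory=list)
    mse_test: list = field(default_factory=list)
    mu_history: list = field(default_factory=list)
    grad_history: list = field(default_factory=list)
    final_gradient: float = np.nan
    final_mu: float = np.nan
    epochs: int = 0
    stop_reason: str = ""
    best_val_mse: float = np.inf
    best_epoch: int = -1


def _logsig(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def init_network(n_hidden: int, q: float, seed: int) -> MLPSurrogate:
    """Nguyen-Widrow initialization over the scaled input range [-1, 1].

    Hidden weights get magnitude 0.7*n_hidden (single input), signs random,
    hidden biases spread the active regions uniformly across the range.
    Deterministic given ``seed``.
    """
    if n_hidden < 1:
        raise ValueError("n_hidden must be >= 1")
    if q <= 1:
        raise ValueError("q must exceed 1")
    rng = np.random.default_rng(seed)
    beta = 0.7 * float(n_hidden)
    signs = rng.choice([-1.0, 1.0], size=n_hidden)
    w_in = beta * signs
    if n_hidden == 1:
        centers = np.array([0.0])
    else:
        centers = np.linspace(-1.0, 1.0, n_hidden)
    b_hidden = -w_in * centers + 0.1 * beta * rng.standard_normal(n_hidden) / n_hidden
    w_out = rng.uniform(-0.5, 0.5, size=n_hidden) / np.sqrt(n_hidden)
    # affine map R in [1, q] -> [-1, 1]
    a = 2.0 / (q - 1.0)
    b = -(q + 1.0) / (q - 1.0)
    return MLPSurrogate(w_in=w_in, b_hidden=b_hidden, w_out=w_out,
                        b_out=0.0, input_scale=(a, b))


def forward(net: MLPSurrogate, R: np.ndarray) -> np.ndarray:
    """Network prediction at radii R (input scaling applied internally)."""
    R = np.atleast_1d(np.asarray(R, dtype=float))
    a, b = net.input_scale
    x = a * R + b
    Z = np.outer(x, net.w_in) + net.b_hidden  # (N, H)
    return net.b_out + _logsig(Z) @ net.w_out


def _forward_jacobian(theta: np.ndarray, net: MLPSurrogate,
                      x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Prediction and d(pred)/d(theta) at pre-scaled inputs x (N, P)."""
    H = net.n_hidden
    w_in = theta[:H]
    b_h = theta[H:2 * H]
    w_out = theta[2 * H:3 * H]
    b_out = theta[3 * H]
    Z = np.outer(x, w_in) + b_h
    A = _logsig(Z)
    pred = b_out + A @ w_out
    dA = A * (1.0 - A)                    # logsig'
    J = np.empty((x.size, theta.size))
    J[:, :H] = (dA * w_out) * x[:, None]  # d/d w_in
    J[:, H:2 * H] = dA * w_out            # d/d b_hidden
    J[:, 2 * H:3 * H] = A                 # d/d w_out
    J[:, 3 * H] = 1.0                     # d/d b_out
    return pred, J


def split_dataset(ds: Dataset, fractions: tuple[float, float, float],
                  seed: int) -> Dataset:
    """Random disjoint train/val/test assignment, deterministic given seed."""
    n = ds.inputs.size
    if n < 3:
        raise ValueError("need at least 3 points to split")
    f = np.asarray(fractions, dtype=float)
    if np.any(f <= 0):
        raise ValueError("fractions must be positive")
    f = f / f.sum()
    n_train = int(round(f[0] * n))
    n_val = int(round(f[1] * n))
    n_train = min(n_train, n - 2)
    n_val = min(n_val, n - n_train - 1)
    labels = np.empty(n, dtype=object)
    perm = np.random.default_rng(seed).permutation(n)
    labels[perm[:n_train]] = "train"
    labels[perm[n_train:n_train + n_val]] = "val"
    labels[perm[n_train + n_val:]] = "test"
    return Dataset(inputs=ds.inputs, targets=ds.targets, split=labels)


def lm_train(net: MLPSurrogate, ds: Dataset, cfg: LMConfig = LMConfig()
             ) -> tuple[MLPSurrogate, TrainingRecord]:
    """Full-batch Levenberg-Marquardt fit with validation early stopping.

    Minimizes the training MSE via (J'J + mu*I) delta = J'e; an accepted
    step (training MSE decreased) shrinks mu, a rejected one grows it and
    retries.  Stops on grad_tol, mu_max, max_epochs, or ``max_val_fail``
    consecutive validation-MSE increases; returns the weights with the best
    validation MSE seen.
    """
    if ds.split is None:
        raise ValueError("dataset must be split before training")
    a, b = net.input_scale
    xs = {k: a * v + b for k, (v, _) in
          {k: ds.subset(k) for k in ("train", "val", "test")}.items()}
    ts = {k: ds.subset(k)[1] for k in ("train", "val", "test")}

    theta = net.pack()
    rec = TrainingRecord()
    mu = cfg.mu0
    val_fail = 0
    n_train = xs["train"].size

    pred, J = _forward_jacobian(theta, net, xs["train"])
    e = ts["train"] - pred
    mse = float(np.mean(e**2))

    def eval_mse(th, key):
        if xs[key].size == 0:
            return np.nan
        p, _ = _forward_jacobian(th, net, xs[key])
        return float(np.mean((ts[key] - p) ** 2))

    for epoch in range(1, cfg.max_epochs + 1):
        if not np.isfinite(mse):
            rec.stop_reason = "non_finite_loss"
            break
        g = 2.0 * (J.T @ e) / n_train           # gradient of the training MSE
        gnorm = float(np.max(np.abs(g)))
        if gnorm <= cfg.grad_tol:
            rec.stop_reason = "grad_tol"
            break
        A = J.T @ J
        accepted = False
        while mu <= cfg.mu_max:
            try:
                delta = np.linalg.solve(
                    A + mu * np.eye(theta.size), J.T @ e
                )
            except np.linalg.LinAlgError:
                mu *= cfg.mu_inc
                continue
            trial = theta + delta
            trial_pred, trial_J = _forward_jacobian(trial, net, xs["train"])
            trial_e = ts["train"] - trial_pred
            trial_mse = float(np.mean(trial_e**2))
            if np.isfinite(trial_mse) and trial_mse < mse:
                theta, pred, J, e, mse = trial, trial_pred, trial_J, trial_e, trial_mse
                mu = max(mu * cfg.mu_dec, 1e-20)
                accepted = True
                break
            mu *= cfg.mu_inc
        if not accepted:
            rec.stop_reason = "mu_max"
            break

        mse_val = eval_mse(theta, "val")
        rec.mse_train.append(mse)
        rec.mse_val.append(mse_val)
        rec.mse_test.append(eval_mse(theta, "test"))
        rec.mu_history.append(mu)
        rec.grad_history.append(gnorm)
        rec.epochs = epoch
        if np.isnan(mse_val) or mse_val < rec.best_val_mse:
            rec.best_val_mse = mse_val if not np.isnan(mse_val) else np.inf
            rec.best_epoch = epoch
            best_theta = theta.copy()
            val_fail = 0
        else:
            val_fail += 1
            if val_fail >= cfg.max_val_fail:
                rec.stop_reason = "val_fail"
                break
    else:
        rec.stop_reason = "max_epochs"

    if not rec.stop_reason:
        rec.stop_reason = "max_epochs"
    g = 2.0 * (J.T @ e) / n_train
    rec.final_gradient = float(np.max(np.abs(g)))
    rec.final_mu = mu
    if rec.best_epoch < 0 or not np.isfinite(rec.best_val_mse):
        best_theta = theta.copy()
        rec.best_val_mse = eval_mse(theta, "val")
    return net.unpack(best_theta), rec


class MLPSurrogateRegressor(RegressorMixin, BaseEstimator):
    """scikit-learn wrapper around the LM-trained 1-H-1 surrogate.

    Parameters mirror `LMConfig` plus the architecture and split settings.
    Fitted attributes: ``net_`` (weights), ``record_`` (TrainingRecord),
    ``best_val_mse_``, ``n_iter_``, ``stop_reason_``.
    """

    def __init__(self, n_hidden: int = 60,
                 fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
                 mu0: float = 1e-3, mu_inc: float = 10.0, mu_dec: float = 0.1,
                 mu_max: float = 1e10, grad_tol: float = 1e-7,
                 max_epochs: int = 1000, max_val_fail: int = 6,
                 random_state: int = 0):
        self.n_hidden = n_hidden
        self.fractions = fractions
        self.mu0 = mu0
        self.mu_inc = mu_inc
        self.mu_dec = mu_dec
        self.mu_max = mu_max
        self.grad_tol = grad_tol
        self.max_epochs = max_epochs
        self.max_val_fail = max_val_fail
        self.random_state = random_state

    def _lm_config(self) -> LMConfig:
        return LMConfig(mu0=self.mu0, mu_inc=self.mu_inc, mu_dec=self.mu_dec,
                        mu_max=self.mu_max, grad_tol=self.grad_tol,
                        max_epochs=self.max_epochs,
                        max_val_fail=self.max_val_fail)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("surrogate regresses on the single radius column")
            X = X[:, 0]
        y = np.asarray(y, dtype=float)
        if X.shape != y.shape:
            raise ValueError("X and y length mismatch")
        q = float(np.max(X))
        ds = Dataset(inputs=X, targets=y)
        ds = split_dataset(ds, tuple(self.fractions), seed=self.random_state)
        net0 = init_network(self.n_hidden, q, seed=self.random_state)
        self.net_, self.record_ = lm_train(net0, ds, self._lm_config())
        self.best_val_mse_ = self.record_.best_val_mse
        self.n_iter_ = self.record_.epochs
        self.stop_reason_ = self.record_.stop_reason
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, 0]
        if not hasattr(self, "net_"):
            raise AttributeError("estimator is not fitted")
        return forward(self.net_, X)
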