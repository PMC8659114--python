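"""Goodness-of-fit metrics and the multi-run stability study.

Implements the error measures used to score the surrogate against the
reference solution: MSE, mean absolute deviation (MAD), Theil's inequality
coefficient (TIC), Nash-Sutcliffe efficiency (NSE) and its complement
ENSE = 1 - NSE, plus Pearson correlation.  NSE is computed, by default,
with the denominator centred on the mean of the *predictions* — the form
this model family is scored with — and optionally in the standard
observation-centred form.

The stability study retrains the surrogate across consecutive seeds and
aggregates each metric's min/mean/std, the way robustness of a stochastic
training pipeline is usually reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

from .surrogate import (
    Dataset,
    LMConfig,
    forward,
    init_network,
    lm_train,
    split_dataset,
)

__all__ = [
    "FitMetrics",
    "StabilityReport",
    "fit_metrics",
    "error_histogram",
    "stability_study",
]


@dataclass(frozen=True)
class FitMetrics:
    mse: float
    mad: float
    tic: float
    nse: float
    ense: float
    r: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("mse", "mad", "tic", "nse", "ense", "r")}


def fit_metrics(target, predicted, *, nse_form: str = "prediction-mean"
                ) -> FitMetrics:
    """All fit metrics between a target series and its prediction.

    MAD  = (1/N) sum |t - p|
    TIC  = sqrt((1/N) sum (t-p)^2) / (sqrt((1/N) sum t^2) + sqrt((1/N) sum p^2))
    NSE  = 1 - sum (t-p)^2 / sum (t - c)^2, with c the mean of the
           predictions (``nse_form="prediction-mean"``, the default) or of
           the observations (``nse_form="observation-mean"``).
    ENSE = 1 - NSE.

    Degenerate denominators raise rather than silently return zero.
    """
    t = np.asarray(target, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if t.shape != p.shape or t.ndim != 1:
        raise ValueError("target and prediction must be equal-length vectors")
    N = t.size
    if N < 2:
        raise ValueError("need at least two points")
    diff = t - p
    mse = float(np.mean(diff**2))
    mad = float(np.mean(np.abs(diff)))
    denom_tic = np.sqrt(np.mean(t**2)) + np.sqrt(np.mean(p**2))
    if denom_tic == 0.0:
        raise ZeroDivisionError("TIC undefined: both series identically zero")
    tic = float(np.sqrt(mse) / denom_tic)
    if nse_form == "prediction-mean":
        center = np.mean(p)
    elif nse_form == "observation-mean":
        center = np.mean(t)
    else:
        raise ValueError(f"unknown nse_form {nse_form!r}")
    denom_nse = float(np.sum((t - center) ** 2))
    if denom_nse == 0.0:
        raise ZeroDivisionError("NSE undefined: zero variance denominator")
    nse = float(1.0 - np.sum(diff**2) / denom_nse)
    if np.std(t) == 0.0 or np.std(p) == 0.0:
        r = np.nan
    else:
        r = float(np.corrcoef(t, p)[0, 1])
    return FitMetrics(mse=mse, mad=mad, tic=tic, nse=nse, ense=1.0 - nse, r=r)


def error_histogram(errors, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Uniform histogram of prediction errors; right-open bins, last closed."""
    e = np.asarray(errors, dtype=float)
    if e.size == 0:
        raise ValueError("empty error vector")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    lo, hi = float(np.min(e)), float(np.max(e))
    if lo == hi:
        hi = lo + 1.0 if lo == 0.0 else lo + abs(lo) * 1e-6
    edges = np.linspace(lo, hi, n_bins + 1)
    counts, edges = np.histogram(e, bins=edges)
    return edges, counts


@dataclass
class StabilityReport:
    """min/mean/std of each fit metric over repeated seeded training runs."""

    n_runs: int
    seeds: list
    stats: dict  # metric -> {"min", "mean", "std"}
    per_run: list = field(default_factory=list)  # FitMetrics per run
    failures: list = field(default_factory=list)  # (seed, message)


_STAB_METRICS = ("mse", "mad", "tic", "ense")


def stability_study(inputs, targets, *, n_hidden: int = 60,
                    n_runs: int = 20, base_seed: int = 1,
                    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
                    cfg: LMConfig = LMConfig(),
                    eval_on: str = "full") -> StabilityReport:
    """Retrain the surrogate over ``n_runs`` consecutive seeds and aggregate.

    Each run re-splits and re-initializes with seed ``base_seed + i`` on the
    same (inputs, targets) dataset, then scores predictions against the
    reference values on the full grid (``eval_on="full"``) or on the test
    subset (``eval_on="test"``).  Runs that abort are excluded and reported.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    inputs = np.asarray(inputs, dtype=float)
    targets = np.asarray(targets, dtype=float)
    q = float(np.max(inputs))
    seeds = list(range(base_seed, base_seed + n_runs))
    per_run, failures = [], []
    for seed in seeds:
        try:
            ds = split_dataset(Dataset(inputs=inputs, targets=targets),
                               fractions, seed=seed)
            net0 = init_network(n_hidden, q, seed=seed)
            net, rec = lm_train(net0, ds, cfg)
            if eval_on == "full":
                x_eval, t_eval = inputs, targets
            elif eval_on == "test":
                x_eval, t_eval = ds.subset("test")
            else:
                raise ValueError(f"unknown eval_on {eval_on!r}")
            m = fit_metrics(t_eval, forward(net, x_eval))
            per_run.append((seed, m, rec))
        except (RuntimeError, ValueError, FloatingPointError) as exc:
            failures.append((seed, str(exc)))
    if not per_run:
        raise RuntimeError("all stability runs failed")
    stats = {}
    for name in _STAB_METRICS:
        vals = np.array([getattr(m, name) for _, m, _ in per_run])
        stats[name] = {"min": float(np.min(vals)),
                       "mean": float(np.mean(vals)),
                       "std": float(np.std(vals, ddof=1))}
    return StabilityReport(n_runs=len(per_run), seeds=seeds, stats=stats,
                           per_run=per_run, failures=failures)
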