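"""Scenario orchestration: datasets, the default case grid, comparison tables.

Two study scenarios are built in: a thick film (q = 5, 1143-point grid) and
a thin film (q = 1.5, 1251-point grid), each with three (alpha, gamma_E,
gamma_S) cases spanning strongly to mildly saturated kinetics.  For every
case this module can generate the reference datasets, train S- and
H-surrogates, assemble the closed-form/numerical/surrogate comparison
table, and export everything as CSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .bvp import SolverOptions, solve_coupled, solve_substrate
from .closed_forms import HamConfig, ham_profiles, madm_profiles
from .metrics import fit_metrics
from .params import ConcentrationProfile, ModelParams, RadialGrid, write_profile_csv
from .surrogate import Dataset, LMConfig, forward, init_network, lm_train, split_dataset

__all__ = [
    "ScenarioSpec",
    "default_scenarios",
    "generate_dataset",
    "comparison_table",
    "run_scenario",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """A film geometry plus its list of (alpha, gamma_E, gamma_S) cases."""

    name: str
    q: float
    n_points: int
    cases: tuple  # of (alpha, gamma_E, gamma_S)

    def __post_init__(self) -> None:
        if self.q <= 1:
            raise ValueError("q must exceed 1")
        if self.n_points < 3:
            raise ValueError("n_points must be >= 3")
        if len(self.cases) == 0:
            raise ValueError("need at least one case")

    def params(self, case_index: int) -> ModelParams:
        alpha, g_e, g_s = self.cases[case_index]
        return ModelParams(gamma_E=g_e, gamma_S=g_s, alpha=alpha, q=self.q)


_CASES = ((100.0, 30.0, 30.0), (50.0, 20.0, 20.0), (10.0, 10.0, 10.0))


def default_scenarios() -> list[ScenarioSpec]:
    """The built-in study grid: thick film (q=5) and thin film (q=1.5).

    gamma_S defaults to gamma_E in every case (equal diffusivities,
    DH = DS).
    """
    return [
        ScenarioSpec(name="I", q=5.0, n_points=1143, cases=_CASES),
        ScenarioSpec(name="II", q=1.5, n_points=1251, cases=_CASES),
    ]


def generate_dataset(params: ModelParams, n_points: int,
                     opts: SolverOptions | None = None
                     ) -> tuple[Dataset, Dataset, ConcentrationProfile]:
    """Solve the BVP on an ``n_points`` grid; return (R,S) and (R,H) datasets."""
    if n_points < 3:
        raise ValueError("n_points must be >= 3")
    if opts is None:
        opts = SolverOptions(n=n_points)
    elif opts.n != n_points:
        opts = SolverOptions(n=n_points, newton_tol=opts.newton_tol,
                             max_newton_iters=opts.max_newton_iters,
                             damping=opts.damping,
                             continuation_steps=opts.continuation_steps)
    prof = solve_coupled(params, opts)
    ds_S = Dataset(inputs=prof.grid.R, targets=prof.S)
    ds_H = Dataset(inputs=prof.grid.R, targets=prof.H)
    return ds_S, ds_H, prof


def comparison_table(scenario: ScenarioSpec, R_list,
                     ham_h: float = -1.0,
                     surrogates: dict | None = None,
                     opts: SolverOptions | None = None) -> pd.DataFrame:
    """Side-by-side substrate values: MADM, HAM, numerical, surrogate.

    One row per (case, R); the surrogate column is included for cases whose
    trained S-network is supplied in ``surrogates`` (case index -> net).
    """
    R_list = np.asarray(R_list, dtype=float)
    if np.any(R_list < 1.0) or np.any(R_list > scenario.q + 1e-12):
        raise ValueError("R values must lie in [1, q]")
    if opts is None:
        opts = SolverOptions(n=scenario.n_points)
    rows = []
    for ci in range(len(scenario.cases)):
        params = scenario.params(ci)
        grid_pts = np.unique(np.concatenate(
            [[1.0, (1.0 + scenario.q) / 2.0], R_list, [scenario.q]]))
        grid = RadialGrid(grid_pts)
        madm = madm_profiles(params, grid)
        ham = ham_profiles(params, HamConfig(h=ham_h), grid)
        num = solve_substrate(params, opts)
        num_interp = np.interp(R_list, num.grid.R, num.S)
        net = (surrogates or {}).get(ci)
        for j, R in enumerate(R_list):
            k = int(np.searchsorted(grid.R, R))
            row = {
                "case": ci + 1,
                "alpha": params.alpha,
                "gamma_E": params.gamma_E,
                "R": R,
                "madm": madm.S[k],
                "ham": ham.S[k],
                "numerical": num_interp[j],
            }
            if net is not None:
                row["surrogate"] = float(forward(net, np.array([R]))[0])
            rows.append(row)
    return pd.DataFrame(rows)


def run_scenario(spec: ScenarioSpec, out_dir, seed: int = 1,
                 n_hidden: int = 60,
                 fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
                 lm_cfg: LMConfig = LMConfig(),
                 opts: SolverOptions | None = None) -> dict:
    """Solve, train S- and H-surrogates, score, and export CSVs per case.

    Layout: ``<out_dir>/<scenario>/case<k>/{profile,dataset_S,dataset_H,
    net_S,net_H,metrics,training_S,training_H}.csv``.  Deterministic given
    ``seed``.  Per-case failures are isolated; the returned bundle lists
    them and the caller decides the exit status.
    """
    out_dir = Path(out_dir)
    bundle = {"scenario": spec.name, "cases": [], "failures": []}
    for ci in range(len(spec.cases)):
        case_dir = out_dir / f"scenario_{spec.name}" / f"case{ci + 1}"
        try:
            bundle["cases"].append(
                _run_case(spec, ci, case_dir, seed, n_hidden, fractions,
                          lm_cfg, opts)
            )
        except Exception as exc:  # isolate per-case failures
            bundle["failures"].append({"case": ci + 1, "error": str(exc)})
    return bundle


def _net_to_frame(net) -> pd.DataFrame:
    rows = []
    for j in range(net.n_hidden):
        rows.append({"block": "hidden", "index": j, "w_in": net.w_in[j],
                     "b_hidden": net.b_hidden[j], "w_out": net.w_out[j]})
    rows.append({"block": "output", "index": 0, "b_out": net.b_out,
                 "scale_a": net.input_scale[0], "scale_b": net.input_scale[1]})
    return pd.DataFrame(rows)


def _record_to_frame(rec) -> pd.DataFrame:
    return pd.DataFrame({
        "epoch": np.arange(1, rec.epochs + 1),
        "mse_train": rec.mse_train,
        "mse_val": rec.mse_val,
        "mse_test": rec.mse_test,
        "mu": rec.mu_history,
        "grad": rec.grad_history,
    })


def _run_case(spec, ci, case_dir, seed, n_hidden, fractions, lm_cfg, opts):
    case_dir.mkdir(parents=True, exist_ok=True)
    params = spec.params(ci)
    ds_S, ds_H, prof = generate_dataset(params, spec.n_points, opts)
    write_profile_csv(prof, case_dir / "profile.csv")
    result = {"case": ci + 1, "params": params, "metrics": {}, "records": {}}
    metric_rows = []
    for label, ds in (("S", ds_S), ("H", ds_H)):
        pd.DataFrame({"R": ds.inputs, label: ds.targets}).to_csv(
            case_dir / f"dataset_{label}.csv", index=False)
        split = split_dataset(ds, fractions, seed=seed)
        net0 = init_network(n_hidden, spec.q, seed=seed)
        net, rec = lm_train(net0, split, lm_cfg)
        m = fit_metrics(ds.targets, forward(net, ds.inputs))
        result["metrics"][label] = m
        result["records"][label] = rec
        result.setdefault("nets", {})[label] = net
        _net_to_frame(net).to_csv(case_dir / f"net_{label}.csv", index=False)
        _record_to_frame(rec).to_csv(case_dir / f"training_{label}.csv",
                                     index=False)
        metric_rows.append({"target": label, **m.as_dict(),
                            "best_val_mse": rec.best_val_mse,
                            "epochs": rec.epochs,
                            "stop_reason": rec.stop_reason})
    pd.DataFrame(metric_rows).to_csv(case_dir / "metrics.csv", index=False)
    return result
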