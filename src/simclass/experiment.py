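"""Factorial simulation driver.

Sweeps the design factors (n, p, sigma_b, sigma_e, theta_min, r, correlation),
replicates each cell, and aggregates the mean and standard error of the LOOCV
error/sensitivity/specificity per method.  Per-replication seeds are derived
by hashing (master_seed, cell key, rep index), so serial and parallel runs
produce identical tables.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .evaluate import PerformanceEstimate, loocv
from .learners import METHODS, build_grid, tune
from .simdata import SimConfig, simulate_dataset

__all__ = [
    "FactorGrid",
    "CellResult",
    "derive_seed",
    "run_replication",
    "run_cell",
    "run_factorial",
    "rank_methods",
]

FACTOR_COLUMNS = (
    "n",
    "p",
    "sigma_b",
    "sigma_e",
    "theta_min",
    "r",
    "corr_kind",
    "rho_fixed",
    "family",
    "cholesky_mode",
)


@dataclass
class FactorGrid:
    """Full-factorial design: one level list per factor."""

    n: list[int] = field(default_factory=lambda: [100])
    p: list[int] = field(default_factory=lambda: [25])
    sigma_b: list[float] = field(default_factory=lambda: [2.5])
    sigma_e: list[float] = field(default_factory=lambda: [1.5])
    theta_min: list[float] = field(default_factory=lambda: [2.0])
    r: list[int] = field(default_factory=lambda: [3])
    corr: list[dict] = field(
        default_factory=lambda: [{"corr_kind": "hub_toeplitz_blocks"}]
    )
    family: list[str] = field(default_factory=lambda: ["gaussian"])
    methods: tuple[str, ...] = METHODS
    n_reps: int = 500
    master_seed: int = 0
    parallel_workers: int = 1
    grid_overrides: dict | None = None

    def __post_init__(self) -> None:
        for name in ("n", "p", "sigma_b", "sigma_e", "theta_min", "r", "corr", "family"):
            if not getattr(self, name):
                raise ValueError(f"factor level list {name!r} must be non-empty")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")

    def cells(self) -> list[dict]:
        out = []
        for vals in itertools.product(
            self.n, self.p, self.sigma_b, self.sigma_e, self.theta_min, self.r,
            self.corr, self.family,
        ):
            n, p, sb, se, tm, r, corr, fam = vals
            cell = {
                "n": n, "p": p, "sigma_b": sb, "sigma_e": se,
                "theta_min": tm, "r": r, "family": fam,
            }
            cell.update(corr)
            out.append(cell)
        return out


@dataclass
class CellResult:
    cell: dict
    method: str
    mean_error: float | None
    se_error: float | None
    mean_sensitivity: float | None
    se_sensitivity: float | None
    mean_specificity: float | None
    se_specificity: float | None
    n_effective_reps: int

    def to_row(self) -> dict:
        row = {c: self.cell.get(c) for c in FACTOR_COLUMNS}
        row.update(
            method=self.method,
            mean_error=self.mean_error,
            se_error=self.se_error,
            mean_sens=self.mean_sensitivity,
            se_sens=self.se_sensitivity,
            mean_spec=self.mean_specificity,
            se_spec=self.se_specificity,
            n_effective_reps=self.n_effective_reps,
        )
        return row


def derive_seed(master_seed: int, *parts) -> int:
    """Deterministic 31-bit seed from the master seed and arbitrary key parts.

    Hash-based so the seed for a (cell, rep) pair does not depend on the order
    cells are executed in — serial and parallel runs agree.
    """
    key = repr((int(master_seed),) + tuple(parts)).encode()
    digest = hashlib.sha256(key).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def _cell_key(cell: dict) -> tuple:
    return tuple(sorted((k, repr(v)) for k, v in cell.items()))


def _config_for_cell(cell: dict, seed: int) -> SimConfig:
    kwargs = {k: v for k, v in cell.items() if k not in ("corr_kind", "rho_fixed")}
    kwargs.setdefault("cholesky_mode", "standardize")
    return SimConfig(
        corr_kind=cell.get("corr_kind", "hub_toeplitz_blocks"),
        rho_fixed=cell.get("rho_fixed"),
        seed=seed,
        **kwargs,
    )


def run_replication(
    cell: dict,
    methods: tuple[str, ...],
    rep_seed: int,
    grid_overrides: dict | None = None,
) -> dict[str, PerformanceEstimate]:
    """One replication of a design cell: simulate, tune each method once by
    10-fold CV on the full dataset, then LOOCV with the tuned parameters."""
    config = _config_for_cell(cell, rep_seed)
    ds = simulate_dataset(config)
    rng = np.random.default_rng(derive_seed(rep_seed, "tuning"))
    out: dict[str, PerformanceEstimate] = {}
    for method in methods:
        overrides = (grid_overrides or {}).get(method)
        if method == "lda" and ds.p >= ds.n - 1:
            # degenerate for every leave-one-out training fold
            out[method] = PerformanceEstimate(method, None, None, None, missing=True)
            continue
        grid = build_grid(method, ds.p, ds.n, rng, overrides)
        params = tune(method, ds.X, ds.y, grid, rng)
        out[method] = loocv(
            method, params, ds.X, ds.y, seed=derive_seed(rep_seed, "loocv", method)
        )
    return out


def _aggregate(
    cell: dict, method: str, estimates: list[PerformanceEstimate]
) -> CellResult:
    ok = [e for e in estimates if not e.missing]
    if not ok:
        return CellResult(cell, method, None, None, None, None, None, None, 0)

    def mean_se(vals: list[float | None]) -> tuple[float | None, float | None]:
        v = np.array([x for x in vals if x is not None], dtype=float)
        if v.size == 0:
            return None, None
        m = float(v.mean())
        se = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else None
        return m, se

    me, see = mean_se([e.error for e in ok])
    ms, ses = mean_se([e.sensitivity for e in ok])
    msp, sesp = mean_se([e.specificity for e in ok])
    return CellResult(cell, method, me, see, ms, ses, msp, sesp, len(ok))


def run_cell(
    cell: dict,
    methods: tuple[str, ...],
    n_reps: int,
    master_seed: int,
    grid_overrides: dict | None = None,
) -> list[CellResult]:
    """Replicate one design cell and aggregate per method."""
    key = _cell_key(cell)
    per_method: dict[str, list[PerformanceEstimate]] = {m: [] for m in methods}
    for rep in range(n_reps):
        rep_seed = derive_seed(master_seed, key, rep)
        for method, est in run_replication(cell, methods, rep_seed, grid_overrides).items():
            per_method[method].append(est)
    return [_aggregate(cell, m, ests) for m, ests in per_method.items()]


def run_factorial(
    grid: FactorGrid,
    out_path: str | None = None,
    resume: bool = False,
) -> pd.DataFrame:
    """Run every cell of the factorial design; long-format results table.

    With ``out_path`` the table is written incrementally after each cell and
    ``resume=True`` skips cells already present in the file.
    """
    cells = grid.cells()
    done: set[tuple] = set()
    rows: list[dict] = []
    if resume and out_path:
        try:
            prev = pd.read_csv(out_path)
            rows = prev.to_dict("records")
            for rec in rows:
                done.add(
                    tuple(_norm_value(rec.get(c)) for c in FACTOR_COLUMNS)
                    + (rec["method"],)
                )
        except FileNotFoundError:
            pass
    todo = [
        c for c in cells
        if not all(
            tuple(_norm_value(_full_cell(c).get(col)) for col in FACTOR_COLUMNS) + (m,)
            in done
            for m in grid.methods
        )
    ]
    worker = delayed(run_cell)
    if grid.parallel_workers > 1:
        results = Parallel(n_jobs=grid.parallel_workers)(
            worker(c, grid.methods, grid.n_reps, grid.master_seed, grid.grid_overrides)
            for c in todo
        )
    else:
        results = [
            run_cell(c, grid.methods, grid.n_reps, grid.master_seed, grid.grid_overrides)
            for c in todo
        ]
    for cell_results in results:
        for res in cell_results:
            rows.append(res.to_row())
        if out_path:
            pd.DataFrame(rows).to_csv(out_path, index=False)
    df = pd.DataFrame(rows)
    if out_path:
        df.to_csv(out_path, index=False)
    return df


def _norm_value(v) -> str:
    """Canonical string for a factor value, stable across CSV round-trips."""
    if v is None:
        return ""
    if isinstance(v, (int, float, np.integer, np.floating)):
        return "" if np.isnan(float(v)) else repr(float(v))
    return str(v)


def _full_cell(cell: dict) -> dict:
    full = {c: None for c in FACTOR_COLUMNS}
    full.update(cell)
    return full


def sustained_competitive_level(
    cell_results: dict[int | float, list[CellResult]],
    method: str,
) -> int | float | None:
    """Smallest sweep level from which ``method`` stays competitive with the
    best of the other methods at every subsequent level.

    Competitive means its mean error does not exceed the best other method's
    by more than twice the pooled standard error.  Backs boundary statements
    of the form "method X needs at least n = ... to perform well".
    """
    levels = sorted(cell_results)
    competitive = {}
    for lev in levels:
        res = {r.method: r for r in cell_results[lev] if r.mean_error is not None}
        if method not in res:
            competitive[lev] = False
            continue
        target = res[method]
        others = [r for m, r in res.items() if m != method]
        if not others:
            competitive[lev] = True
            continue
        best = min(others, key=lambda r: r.mean_error)
        pooled = np.sqrt((target.se_error or 0.0) ** 2 + (best.se_error or 0.0) ** 2)
        competitive[lev] = target.mean_error <= best.mean_error + 2 * pooled
    for i, lev in enumerate(levels):
        if all(competitive[l2] for l2 in levels[i:]):
            return lev
    return None


def sustained_best_level(
    cell_results: dict[int | float, list[CellResult]],
    method: str,
) -> int | float | None:
    """Smallest sweep level from which ``method`` has the strictly lowest mean
    error at every subsequent level.

    Backs "method of choice" boundary statements: unlike
    :func:`sustained_competitive_level`, this does not degenerate at sweep
    levels where every method sits at chance (there, everything is trivially
    within 2 SE of everything else, but nothing is best).
    """
    levels = sorted(cell_results)
    is_best = {}
    for lev in levels:
        res = {r.method: r for r in cell_results[lev] if r.mean_error is not None}
        if method not in res:
            is_best[lev] = False
            continue
        others = [r.mean_error for m, r in res.items() if m != method]
        is_best[lev] = (not others) or res[method].mean_error < min(others)
    for i, lev in enumerate(levels):
        if all(is_best[l2] for l2 in levels[i:]):
            return lev
    return None


def error_crossover_level(
    cell_results: dict[int | float, list[CellResult]],
    method_a: str,
    method_b: str,
) -> float:
    """Sweep level at which the mean-error curves of two methods cross.

    Linear interpolation of d(level) = mean_error(a) - mean_error(b) between
    the first adjacent levels where d changes sign.  Returns the lowest level
    if ``a`` is never better, the highest if ``a`` is always better.
    """
    levels = sorted(cell_results)
    d = []
    for lev in levels:
        res = {r.method: r for r in cell_results[lev]}
        d.append(res[method_a].mean_error - res[method_b].mean_error)
    for i in range(len(levels) - 1):
        if d[i] <= 0 <= d[i + 1] or d[i] >= 0 >= d[i + 1]:
            if d[i] == d[i + 1]:
                return 0.5 * (levels[i] + levels[i + 1])
            frac = abs(d[i]) / (abs(d[i]) - 0 + abs(d[i + 1]))
            return levels[i] + frac * (levels[i + 1] - levels[i])
    return float(levels[-1] if d[-1] < 0 else levels[0])


def rank_methods(results: pd.DataFrame, cell: dict) -> pd.DataFrame:
    """Order methods by mean error within one design cell.

    Adds a ``tie_with_next`` flag set when the gap to the next-ranked method is
    below twice the pooled standard error.
    """
    mask = np.ones(len(results), dtype=bool)
    for k, v in cell.items():
        col = results[k]
        mask &= (col == v) if v is not None else col.isna()
    sub = results[mask & results["mean_error"].notna()]
    if sub.empty:
        raise ValueError(f"no results for cell {cell!r}")
    sub = sub.sort_values("mean_error").reset_index(drop=True)
    ties = []
    for i in range(len(sub)):
        if i + 1 < len(sub):
            se1 = sub.loc[i, "se_error"] or 0.0
            se2 = sub.loc[i + 1, "se_error"] or 0.0
            pooled = np.sqrt(se1**2 + se2**2)
            ties.append(abs(sub.loc[i + 1, "mean_error"] - sub.loc[i, "mean_error"]) < 2 * pooled)
        else:
            ties.append(False)
    sub["tie_with_next"] = ties
    return sub
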