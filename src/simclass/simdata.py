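"""Synthetic two-group gene-expression-like data under a random-effects model.

Each feature j of subject i is generated on the log2 scale as

    x_ij = mu_j + b_i + eps_ij,        b_i ~ N(0, sigma_b^2),  eps ~ N(0, sigma_e^2)

with r technical replicates averaged per subject, so the marginal variance of
the replicate-averaged value is v = sigma_b^2 + sigma_e^2 / r.  Inter-feature
dependence is imposed afterwards by a Cholesky-root transformation toward a
block-diagonal hub-Toeplitz correlation matrix R, and a class signal is injected
by shifting group G2 by z_j * delta_j where delta_j is drawn from a truncated
normal on [alpha, inf) with alpha = log2(theta_min) — theta_min being the
minimum fold change of any feature carrying signal.

A Poisson family (counts with intensity lambda_rate, dependence via a Gaussian
copula) is available as a non-normal sensitivity variant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import toeplitz
from scipy.optimize import brentq

__all__ = [
    "SimConfig",
    "CorrelationModel",
    "EffectModel",
    "LabelledDataset",
    "sample_base_expressions",
    "simulate_replicate_average",
    "make_block_partition",
    "hub_toeplitz_block",
    "assemble_correlation",
    "impose_correlation",
    "sample_effect_sizes",
    "truncnorm_mean",
    "average_fold_change",
    "inject_group_effect",
    "simulate_dataset",
    "simulate_poisson_dataset",
    "poisson_copula_correlation",
    "write_dataset",
    "read_dataset",
]

# base-expression surrogate: normalised log2 microarray intensities cluster in
# roughly this range; the exact location only shifts features and carries no
# class signal
_MU_MEAN = 7.5
_MU_SD = 2.0
_MU_LO = 2.0
_MU_HI = 14.0

_PD_EIGEN_TOL = 1e-10
_PD_EIGEN_FLOOR = 1e-8


@dataclass
class SimConfig:
    """All simulation factors for one design cell.

    Parameters are on the log2-expression scale unless noted.  ``theta_min`` is
    the minimum fold change (>= 1), so the effect-size truncation point is
    ``alpha = log2(theta_min) >= 0``.
    """

    n: int = 100
    p: int = 25
    sigma_b: float = 2.5
    sigma_e: float = 1.5
    r: int = 3
    theta_min: float = 2.0
    tau: float = 1.0
    family: Literal["gaussian", "poisson"] = "gaussian"
    lambda_rate: float = 4.0
    corr_kind: Literal[
        "independent", "hub_toeplitz_blocks", "exchangeable_single_block"
    ] = "hub_toeplitz_blocks"
    rho_max_range: tuple[float, float] = (0.6, 0.8)
    rho_min_range: tuple[float, float] = (0.2, 0.4)
    rho_fixed: float | None = None
    nu: float = 1.0
    cholesky_mode: Literal["standardize", "literal"] = "standardize"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ValueError(f"n must be >= 4, got {self.n}")
        if self.p < 1:
            raise ValueError(f"p must be >= 1, got {self.p}")
        if self.family == "gaussian":
            if self.sigma_b <= 0 or self.sigma_e <= 0:
                raise ValueError("sigma_b and sigma_e must be positive")
        if self.r < 1:
            raise ValueError("r must be >= 1")
        if self.theta_min < 1:
            raise ValueError(
                f"theta_min must be >= 1 (alpha = log2(theta_min) >= 0), got {self.theta_min}"
            )
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.family not in ("gaussian", "poisson"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "poisson" and self.lambda_rate <= 0:
            raise ValueError("lambda_rate must be positive")
        if self.corr_kind not in (
            "independent",
            "hub_toeplitz_blocks",
            "exchangeable_single_block",
        ):
            raise ValueError(f"unknown corr_kind {self.corr_kind!r}")
        if self.rho_min_range[1] >= self.rho_max_range[0]:
            raise ValueError(
                "rho_min_range upper bound must be below rho_max_range lower bound"
            )
        if self.cholesky_mode not in ("standardize", "literal"):
            raise ValueError(f"unknown cholesky_mode {self.cholesky_mode!r}")

    @property
    def alpha(self) -> float:
        return float(np.log2(self.theta_min))

    @property
    def marginal_variance(self) -> float:
        """v = sigma_b^2 + sigma_e^2 / r for replicate-averaged data."""
        return self.sigma_b**2 + self.sigma_e**2 / self.r


@dataclass
class CorrelationModel:
    """Block partition plus the assembled p x p correlation matrix."""

    block_sizes: list[int]
    rho_sequences: list[np.ndarray]
    R: np.ndarray
    pd_repaired: bool = False


@dataclass
class EffectModel:
    """Per-feature effect sizes delta (sorted descending) and signs z."""

    alpha: float
    tau: float
    delta: np.ndarray
    z: np.ndarray


@dataclass
class LabelledDataset:
    """Replicate-averaged, correlated, effect-injected n x p data with labels."""

    X: np.ndarray
    y: np.ndarray  # strings "G1"/"G2"
    n1: int
    n2: int
    mu: np.ndarray
    marginal_variance: float
    effects: EffectModel
    config: SimConfig
    correlation: CorrelationModel | None = None

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


def sample_base_expressions(p: int, rng: np.random.Generator) -> np.ndarray:
    """Draw p base log2 expression levels mu.

    Surrogate for averaging a large normalised expression compendium: i.i.d.
    Normal(7.5, 2^2) truncated to [2, 14], the range typical of normalised
    log2 microarray intensities.
    """
    if p < 1:
        raise ValueError(f"p must be >= 1, got {p}")
    a = (_MU_LO - _MU_MEAN) / _MU_SD
    b = (_MU_HI - _MU_MEAN) / _MU_SD
    return stats.truncnorm.rvs(
        a, b, loc=_MU_MEAN, scale=_MU_SD, size=p, random_state=rng
    )


def base_expression_moments() -> tuple[float, float]:
    """Mean and SD of the base-expression surrogate distribution."""
    a = (_MU_LO - _MU_MEAN) / _MU_SD
    b = (_MU_HI - _MU_MEAN) / _MU_SD
    m, v = stats.truncnorm.stats(a, b, loc=_MU_MEAN, scale=_MU_SD, moments="mv")
    return float(m), float(np.sqrt(v))


def simulate_replicate_average(
    config: SimConfig, mu: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Simulate replicate-averaged expression, columns independent.

    Entry (i, j) = mu_j + b_ij + mean over r replicates of eps; marginally
    Normal(mu_j, sigma_b^2 + sigma_e^2 / r).
    """
    if config.sigma_b <= 0 or config.sigma_e <= 0:
        raise ValueError("sigma_b and sigma_e must be positive")
    n, p, r = config.n, len(mu), config.r
    b = rng.normal(0.0, config.sigma_b, size=(n, p))
    eps = rng.normal(0.0, config.sigma_e, size=(n, p, r)).mean(axis=2)
    return mu[None, :] + b + eps


def make_block_partition(p: int, rng: np.random.Generator) -> list[int]:
    """Random block partition of p features.

    H = 1 for p < 5; otherwise H ~ Uniform{1, ..., floor(p/3)}.  If H divides p
    all blocks have size p/H, else the first absorbs the remainder:
    d_1 = floor(p/H) + mod(p, H), d_h = floor(p/H) for h >= 2.
    """
    if p < 1:
        raise ValueError(f"p must be >= 1, got {p}")
    if p < 5:
        return [p]
    H = int(rng.integers(1, p // 3 + 1))
    base = p // H
    sizes = [base + p % H] + [base] * (H - 1)
    return sizes


def hub_toeplitz_rho_sequence(
    d_h: int, rho_max: float, rho_min: float, nu: float = 1.0
) -> np.ndarray:
    """Correlation sequence rho_{h,l} for lags l = 2..d_h.

    Declines from rho_max (hub-adjacent) to rho_min with rate exponent nu:
    rho_l = rho_max - ((l-2)/(d_h-2))^nu * (rho_max - rho_min).  For d_h = 2 the
    single off-diagonal lag is the hub correlation rho_max.
    """
    if d_h < 1:
        raise ValueError(f"block size must be >= 1, got {d_h}")
    if not (0 <= rho_min <= rho_max < 1):
        raise ValueError(f"need 0 <= rho_min <= rho_max < 1, got ({rho_min}, {rho_max})")
    if d_h == 1:
        return np.empty(0)
    if d_h == 2:
        return np.array([rho_max])
    l = np.arange(2, d_h + 1)
    frac = ((l - 2) / (d_h - 2)) ** nu
    return rho_max - frac * (rho_max - rho_min)


def hub_toeplitz_block(
    d_h: int, rho_max: float, rho_min: float, nu: float = 1.0
) -> np.ndarray:
    """Symmetric Toeplitz block with first row (1, rho_2, ..., rho_{d_h})."""
    seq = hub_toeplitz_rho_sequence(d_h, rho_max, rho_min, nu)
    first_row = np.concatenate([[1.0], seq])
    return toeplitz(first_row)


def _repair_pd(R: np.ndarray) -> tuple[np.ndarray, bool]:
    """Clip eigenvalues if R is not numerically PD; rescale to unit diagonal."""
    w = np.linalg.eigvalsh(R)
    if w.min() > _PD_EIGEN_TOL:
        return R, False
    w, V = np.linalg.eigh(R)
    w = np.clip(w, _PD_EIGEN_FLOOR, None)
    R2 = (V * w) @ V.T
    d = np.sqrt(np.diag(R2))
    R2 = R2 / np.outer(d, d)
    np.fill_diagonal(R2, 1.0)
    return R2, True


def assemble_correlation(
    config: SimConfig, rng: np.random.Generator
) -> CorrelationModel:
    """Draw and assemble the p x p target correlation matrix R.

    hub_toeplitz_blocks: rho_max ~ U(rho_max_range) and rho_min ~ U(rho_min_range)
    are drawn once per dataset and shared across blocks; the block partition is
    random (see :func:`make_block_partition`).
    """
    p = config.p
    if config.corr_kind == "independent":
        return CorrelationModel([p], [np.empty(0)], np.eye(p))
    if config.corr_kind == "exchangeable_single_block":
        rho = config.rho_fixed
        if rho is None:
            raise ValueError("exchangeable_single_block requires rho_fixed")
        if p > 1 and not (-1.0 / (p - 1) < rho < 1.0):
            raise ValueError(
                f"exchangeable rho must lie in (-1/(p-1), 1) = ({-1.0/(p-1):.4f}, 1)"
            )
        R = np.full((p, p), float(rho))
        np.fill_diagonal(R, 1.0)
        R, repaired = _repair_pd(R)
        return CorrelationModel([p], [np.full(max(p - 1, 0), float(rho))], R, repaired)
    # hub_toeplitz_blocks
    rho_max = float(rng.uniform(*config.rho_max_range))
    rho_min = float(rng.uniform(*config.rho_min_range))
    sizes = make_block_partition(p, rng)
    seqs = [hub_toeplitz_rho_sequence(d, rho_max, rho_min, config.nu) for d in sizes]
    R = np.zeros((p, p))
    start = 0
    for d, seq in zip(sizes, seqs):
        R[start : start + d, start : start + d] = toeplitz(
            np.concatenate([[1.0], seq])
        )
        start += d
    R, repaired = _repair_pd(R)
    return CorrelationModel(sizes, seqs, R, repaired)


def impose_correlation(
    X_bar: np.ndarray, mu: np.ndarray, v: float, R: np.ndarray
) -> np.ndarray:
    """Impose correlation R on column-independent data, preserving means/variances.

    Standardizes residuals (X - mu)/sqrt(v), multiplies by the upper Cholesky
    factor U with U'U = R (row-vector convention), rescales by sqrt(v) and
    re-centres at mu, so rows of the output have mean mu and covariance v R.
    With R = I the transform is the identity.
    """
    p = X_bar.shape[1]
    if np.array_equal(R, np.eye(p)):
        return X_bar
    try:
        L = np.linalg.cholesky(R)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - repaired upstream
        raise RuntimeError("correlation matrix is not positive definite") from exc
    Z = (X_bar - mu[None, :]) / np.sqrt(v)
    return Z @ L.T * np.sqrt(v) + mu[None, :]


def truncnorm_mean(alpha: float, tau: float = 1.0) -> float:
    """Mean of N(0, tau^2) truncated to [alpha, inf): tau*phi(a/t)/(1-Phi(a/t))."""
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if tau <= 0:
        raise ValueError("tau must be positive")
    s = alpha / tau
    return tau * stats.norm.pdf(s) / stats.norm.sf(s)


def average_fold_change(theta_min: float, tau: float = 1.0) -> float:
    """Average fold change theta = 2^E[delta | delta >= log2(theta_min)]."""
    return float(2.0 ** truncnorm_mean(np.log2(theta_min), tau))


def sample_effect_sizes(
    p: int, theta_min: float, tau: float, rng: np.random.Generator
) -> EffectModel:
    """Draw p effect sizes from the [alpha, inf)-truncated normal, sorted descending.

    Signs z are i.i.d. uniform on {-1, +1}; alpha = log2(theta_min).
    """
    if theta_min < 1:
        raise ValueError("theta_min must be >= 1 so alpha = log2(theta_min) >= 0")
    if tau <= 0:
        raise ValueError("tau must be positive")
    alpha = float(np.log2(theta_min))
    delta = stats.truncnorm.rvs(
        alpha / tau, np.inf, loc=0.0, scale=tau, size=p, random_state=rng
    )
    delta = np.sort(delta)[::-1]
    z = rng.choice([-1, 1], size=p)
    return EffectModel(alpha=alpha, tau=tau, delta=delta, z=z)


def inject_group_effect(
    Y_bar: np.ndarray,
    effects: EffectModel,
    n1: int,
    *,
    mu: np.ndarray | None = None,
    marginal_variance: float | None = None,
    config: SimConfig | None = None,
    correlation: CorrelationModel | None = None,
) -> LabelledDataset:
    """Shift rows n1..n (group G2) by z_j * delta_j feature-wise; attach labels."""
    n, p = Y_bar.shape
    if len(effects.delta) != p or len(effects.z) != p:
        raise ValueError("effect-size vector length does not match feature count")
    X = Y_bar.copy()
    shift = effects.z * effects.delta
    X[n1:, :] += shift[None, :]
    y = np.array(["G1"] * n1 + ["G2"] * (n - n1))
    return LabelledDataset(
        X=X,
        y=y,
        n1=n1,
        n2=n - n1,
        mu=mu if mu is not None else np.zeros(p),
        marginal_variance=marginal_variance if marginal_variance is not None else np.nan,
        effects=effects,
        config=config,
        correlation=correlation,
    )


def simulate_dataset(config: SimConfig) -> LabelledDataset:
    """Run the full Gaussian pipeline: base expressions -> replicate-averaged
    noise -> correlation -> group-effect injection.  Deterministic given
    ``config.seed``."""
    if config.family == "poisson":
        return simulate_poisson_dataset(config)
    rng = np.random.default_rng(config.seed)
    mu = sample_base_expressions(config.p, rng)
    X_bar = simulate_replicate_average(config, mu, rng)
    corr = assemble_correlation(config, rng)
    v = config.marginal_variance
    if config.cholesky_mode == "standardize":
        Y_bar = impose_correlation(X_bar, mu, v, corr.R)
    else:
        # reference-pipeline transform exactly as printed: Y = X C with C the
        # Cholesky root of V^{1/2} R V^{1/2}; rows end up with covariance
        # v^2 R (correlation still R) and the means are mixed by C, so the
        # effective noise scale is v rather than sqrt(v)
        C = np.linalg.cholesky(v * corr.R).T
        Y_bar = X_bar @ C
    effects = sample_effect_sizes(config.p, config.theta_min, config.tau, rng)
    n1 = config.n // 2
    return inject_group_effect(
        Y_bar,
        effects,
        n1,
        mu=mu,
        marginal_variance=v,
        config=config,
        correlation=corr,
    )


def poisson_copula_correlation(rho_z: float, lam: float) -> float:
    """Count-scale correlation produced by a Gaussian copula with latent
    correlation ``rho_z`` and Poisson(lam) margins.

    Uses the identity E[X1 X2] = sum_{j,k>=1} P(X1 >= j, X2 >= k), where each
    joint survival probability is a bivariate-normal orthant probability at
    the copula thresholds — exact up to the series truncation.  The copula
    attenuates correlation: |returned| <= |rho_z|.  Serves as documentation
    of the attenuation and as the target of the optional NORTA correction.
    """
    if rho_z == 0:
        return 0.0
    # truncate where the marginal survival is negligible
    jmax = int(stats.poisson.isf(1e-14, lam)) + 1
    j = np.arange(1, jmax + 1)
    thresh = stats.norm.ppf(np.clip(stats.poisson.cdf(j - 1, lam), 1e-300, 1 - 1e-16))
    cov = np.array([[1.0, rho_z], [rho_z, 1.0]])
    bvn = stats.multivariate_normal(mean=[0.0, 0.0], cov=cov)
    pts = np.stack(
        [np.repeat(-thresh, jmax), np.tile(-thresh, jmax)], axis=1
    )
    # P(Z1 >= a, Z2 >= b) = Phi2(-a, -b) by symmetry of the centred BVN
    surv = bvn.cdf(pts).reshape(jmax, jmax)
    exy = float(surv.sum())
    return float((exy - lam**2) / lam)


def _norta_corrected_rho(target: float, lam: float) -> float:
    """Latent Gaussian correlation whose copula yields count correlation ``target``."""
    if target == 0:
        return 0.0
    f = lambda r: poisson_copula_correlation(r, lam) - target
    lo, hi = (0.0, 0.999) if target > 0 else (-0.999, 0.0)
    return brentq(f, lo, hi, xtol=1e-4)


def simulate_poisson_dataset(
    config: SimConfig, *, norta_correction: bool = False
) -> LabelledDataset:
    """Poisson-family variant: single-replicate counts with intensity lambda.

    Dependence is imposed with a Gaussian copula: correlated standard normals
    (target R) are mapped through Phi and the Poisson(lambda) quantile function.
    Realized count correlation is attenuated relative to R unless
    ``norta_correction`` pre-distorts the latent correlations.  The group effect
    z*delta is then added to the counts of G2 as a real-valued shift.
    """
    if config.lambda_rate <= 0:
        raise ValueError("lambda_rate must be positive")
    rng = np.random.default_rng(config.seed)
    corr = assemble_correlation(config, rng)
    R_latent = corr.R
    if norta_correction and not np.array_equal(R_latent, np.eye(config.p)):
        R_latent = R_latent.copy()
        cache: dict[float, float] = {}
        idx = np.triu_indices(config.p, k=1)
        for i, j in zip(*idx):
            t = R_latent[i, j]
            if t != 0.0:
                key = round(float(t), 6)
                if key not in cache:
                    cache[key] = _norta_corrected_rho(t, config.lambda_rate)
                R_latent[i, j] = R_latent[j, i] = cache[key]
        R_latent, _ = _repair_pd(R_latent)
    Z = rng.standard_normal((config.n, config.p))
    if not np.array_equal(R_latent, np.eye(config.p)):
        Z = Z @ np.linalg.cholesky(R_latent).T
    counts = stats.poisson.ppf(stats.norm.cdf(Z), config.lambda_rate)
    effects = sample_effect_sizes(config.p, config.theta_min, config.tau, rng)
    n1 = config.n // 2
    return inject_group_effect(
        counts,
        effects,
        n1,
        mu=np.full(config.p, config.lambda_rate),
        marginal_variance=config.lambda_rate,
        config=config,
        correlation=corr,
    )


def write_dataset(dataset: LabelledDataset, path: str | Path, sep: str = "\t") -> None:
    """Write samples x features table with a final ``group`` column, plus a JSON
    sidecar (<path>.meta.json) recording the configuration and random draws."""
    path = Path(path)
    p = dataset.p
    cols = [f"f{j + 1:04d}" for j in range(p)]
    df = pd.DataFrame(dataset.X, columns=cols)
    df["group"] = dataset.y
    df.to_csv(path, sep=sep, index=False)
    corr = dataset.correlation
    meta = {
        "config": asdict(dataset.config) if dataset.config is not None else None,
        "seed": dataset.config.seed if dataset.config is not None else None,
        "delta": dataset.effects.delta.tolist(),
        "z": dataset.effects.z.tolist(),
        "alpha": dataset.effects.alpha,
        "block_sizes": corr.block_sizes if corr is not None else None,
        "pd_repaired": corr.pd_repaired if corr is not None else None,
        "marginal_variance": None
        if np.isnan(dataset.marginal_variance)
        else dataset.marginal_variance,
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2))


def read_dataset(path: str | Path, sep: str = "\t") -> tuple[np.ndarray, np.ndarray, dict | None]:
    """Read a table written by :func:`write_dataset`; returns (X, y, meta)."""
    df = pd.read_csv(path, sep=sep)
    y = df.pop("group").to_numpy()
    meta_path = Path(str(path) + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else None
    return df.to_numpy(dtype=float), y, meta
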