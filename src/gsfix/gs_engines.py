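"""Genomic prediction engines: GBLUP (spectral REML) and a Gibbs sampler,
plus the single-environment (SE), across-environment (A-E) and
genotype-by-environment (GxE) multi-environment models.

All models are Gaussian mixed models y = Xf b + sum_k Z_k u_k + e with
u_k ~ N(0, K_k sigma_k^2).  The SE model has one genetic kernel (the VanRaden
K).  The A-E model stacks the environments with per-environment intercepts
and one shared genetic kernel (marker effects constant across environments).
The GxE model adds one kernel per environment, which is the kernel form of
decomposing marker effects into a common main vector b0 and environment-
specific deviations b_i; for these linear kernels the two parameterizations
are algebraically identical.

Two solvers: a deterministic spectral REML for the single-kernel case
(one-dimensional profile likelihood on the eigendecomposition of K) and a
block Gibbs sampler with scaled-inverse-chi-square variance priors for the
multi-kernel case, mirroring a Bayesian ridge / RKHS fit.  Large-effect
markers enter as fixed-effect columns of Xf and are removed from the marker
set used to build K.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .kinship_gwas import KinshipMatrix, vanraden_kinship
from .synthetic_data import GenotypeMatrix

logger = logging.getLogger("gsfix.gs_engines")

__all__ = [
    "GsModelSpec",
    "ChainConfig",
    "GsFit",
    "build_fixed_design",
    "solve_gblup_reml",
    "gblup_predict",
    "solve_bayes_gibbs",
    "fit_environment_model",
]


# ---------------------------------------------------------------------------
# specs and results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GsModelSpec:
    """Which environment model to fit and which markers are fixed effects."""

    model_type: str  # "SE" | "AE" | "GXE"
    environments: tuple = ()
    fixed_snps: tuple = ()

    def __post_init__(self) -> None:
        if self.model_type not in ("SE", "AE", "GXE"):
            raise ValueError("model_type must be one of SE, AE, GXE")
        object.__setattr__(self, "environments", tuple(str(e) for e in self.environments))
        object.__setattr__(self, "fixed_snps", tuple(self.fixed_snps))
        if len(set(self.fixed_snps)) != len(self.fixed_snps):
            raise ValueError("duplicate fixed SNP IDs")
        if self.model_type in ("AE", "GXE") and len(self.environments) < 2:
            raise ValueError(f"{self.model_type} model requires >= 2 environments")
        if self.model_type == "SE" and len(self.environments) != 1:
            raise ValueError("SE model takes exactly one environment")


@dataclass(frozen=True)
class ChainConfig:
    """Gibbs chain settings; defaults follow the full-length analysis chain."""

    n_iter: int = 20_000
    burn_in: int = 5_000
    thin: int = 5
    seed: int = 0
    prior_df: float = 5.0
    prior_r2: float = 0.5  # prior mode splits response variance evenly

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("burn_in must be < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.prior_df <= 0 or not (0 < self.prior_r2 < 1):
            raise ValueError("invalid prior settings")


@dataclass
class GsFit:
    """One fitted GS model: fixed effects, genetic values, variance components."""

    beta: np.ndarray
    beta_names: list[str]
    u: dict[str, np.ndarray]
    sigma2: dict[str, float]
    fitted: np.ndarray
    meta: dict = field(default_factory=dict)
    alpha: np.ndarray | None = None  # V^{-1}(y - Xb) * sigma_u2, for kernel prediction
    loglik: float = np.nan
    u_sd: dict[str, np.ndarray] | None = None
    n_samples: int = 0

    @property
    def predictions(self) -> pd.DataFrame | None:
        """Family x environment grid of predicted cell values (environment models)."""
        return self.meta.get("predictions")


# ---------------------------------------------------------------------------
# fixed-effect design
# ---------------------------------------------------------------------------

def build_fixed_design(
    G: GenotypeMatrix, fixed_snps
) -> tuple[np.ndarray, GenotypeMatrix]:
    """[1 | genotype columns of fixed_snps], and G with those markers removed.

    The returned reduced matrix is the marker set used to build K, so fixed
    markers do not enter the genomic relationship matrix.
    """
    fixed_snps = list(fixed_snps)
    if len(set(fixed_snps)) != len(fixed_snps):
        raise ValueError("duplicate fixed SNP IDs")
    n = G.n_families
    if not fixed_snps:
        return np.ones((n, 1)), G
    idx = G.marker_index(fixed_snps)  # raises KeyError on unknown IDs
    Xf = np.column_stack([np.ones(n), G.codes[:, idx]])
    keep = np.ones(G.n_markers, dtype=bool)
    keep[idx] = False
    return Xf, G.subset_markers(keep)


# ---------------------------------------------------------------------------
# spectral REML GBLUP
# ---------------------------------------------------------------------------

def solve_gblup_reml(y: np.ndarray, Xf: np.ndarray, K) -> GsFit:
    """Deterministic GBLUP: y = Xf b + u + e, u ~ N(0, K su2).

    The restricted likelihood is profiled down to the single variance ratio
    gamma = sigma_u^2/sigma_e^2 on the eigendecomposition of K and optimized
    by bounded scalar search; b is then the GLS estimate and u the BLUP.
    """
    y = np.asarray(y, dtype=float)
    Xf = np.asarray(Xf, dtype=float)
    Kmat = K.K if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)
    n = len(y)
    if Xf.shape[0] != n or Kmat.shape != (n, n):
        raise ValueError("dimension mismatch between y, Xf and K")
    p = Xf.shape[1]
    if np.linalg.matrix_rank(Xf) < p:
        raise ValueError("Xf is rank-deficient")
    s, U = np.linalg.eigh(Kmat)
    if s[0] < -1e-8 * max(1.0, abs(s[-1])):
        raise ValueError("K is not positive semidefinite")
    s = np.clip(s, 0.0, None)
    yt = U.T @ y
    Xt = U.T @ Xf

    def neg2ll(log_g: float) -> float:
        g = np.exp(log_g)
        w = g * s + 1.0
        Xw = Xt / w[:, None]
        A = Xt.T @ Xw
        sign, logdetA = np.linalg.slogdet(A)
        if sign <= 0:
            return np.inf
        coef = np.linalg.solve(A, Xw.T @ yt)
        rss = max(float(yt @ (yt / w)) - float((Xw.T @ yt) @ coef), 1e-300)
        return float(np.sum(np.log(w)) + logdetA + (n - p) * np.log(rss))

    res = optimize.minimize_scalar(
        neg2ll, bounds=(-25.0, 25.0), method="bounded", options={"xatol": 1e-11}
    )
    g = float(np.exp(res.x))
    w = g * s + 1.0
    Xw = Xt / w[:, None]
    A = Xt.T @ Xw
    beta = np.linalg.solve(A, Xw.T @ yt)
    rss = max(float(yt @ (yt / w)) - float((Xw.T @ yt) @ beta), 1e-300)
    sigma_e2 = rss / (n - p)
    sigma_u2 = g * sigma_e2
    rt = yt - Xt @ beta
    # u = su2 * K V^{-1} r ; in the eigenbasis V^{-1} is diag(1/(w se2))
    u = U @ (g * s / w * rt)
    alpha = U @ (g / w * rt)  # = su2 V^{-1} r, so u_new = K_cross @ alpha
    fitted = Xf @ beta + u
    loglik = -0.5 * (res.fun + (n - p) * (1.0 + np.log(2.0 * np.pi) - np.log(n - p)))
    return GsFit(
        beta=beta, beta_names=[f"b{i}" for i in range(p)],
        u={"u": u}, sigma2={"u": float(sigma_u2), "e": float(sigma_e2)},
        fitted=fitted, alpha=alpha, loglik=float(loglik),
        meta={"gamma": g, "n": n},
    )


def gblup_predict(fit: GsFit, Xf_new: np.ndarray, K_cross: np.ndarray) -> np.ndarray:
    """Predict new lines: Xf_new b + K_cross alpha (K_cross = K[new, train])."""
    return np.asarray(Xf_new) @ fit.beta + np.asarray(K_cross) @ fit.alpha


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------

def _kernel_basis(Z: np.ndarray | None, Kmat: np.ndarray, n_obs: int):
    """Orthogonalized basis for exact block draws of one kernel's effects.

    With K = E diag(d) E' and u = E sqrt(d) delta, delta ~ N(0, I sk2), the
    conditional posterior precision of delta is T'T/se2 + I/sk2 with
    T = Z E sqrt(d).  Diagonalizing T'T = F diag(lam) F' once makes every
    Gibbs draw an exact joint Gaussian draw at matrix-vector cost.
    """
    d, E = np.linalg.eigh(Kmat)
    keep = d > max(d[-1], 0.0) * 1e-10
    if not keep.any():
        raise ValueError("kernel matrix is numerically zero")
    d, E = d[keep], E[:, keep]
    B = E * np.sqrt(d)  # q x m, u = B delta
    T = B if Z is None else np.asarray(Z) @ B
    G2 = T.T @ T
    lam, F = np.linalg.eigh(G2)
    lam = np.clip(lam, 0.0, None)
    TF = T @ F  # n_obs x m
    BF = B @ F  # q x m, u = BF delta_F
    return TF, BF, lam


def solve_bayes_gibbs(
    y: np.ndarray,
    Xf: np.ndarray,
    kernels: list,
    chain: ChainConfig,
) -> GsFit:
    """Block Gibbs sampler for y = Xf b + sum_k Z_k u_k + e, u_k ~ N(0, K_k sk2).

    ``kernels`` is a list of (name, Z_k, K_k); Z_k may be None for identity
    incidence.  Flat prior on b; scaled-inverse-chi-square priors on all
    variances with ``prior_df`` degrees of freedom and scales set so the prior
    mode splits the response variance between genetic and residual sides.
    Returns posterior means over the post-burn-in, thinned samples.
    """
    y = np.asarray(y, dtype=float)
    Xf = np.asarray(Xf, dtype=float)
    n = len(y)
    if Xf.shape[0] != n:
        raise ValueError("Xf rows must match y")
    rng = np.random.default_rng(chain.seed)
    vy = float(np.var(y)) if n > 1 else 1.0
    vy = vy if vy > 0 else 1.0
    df0 = chain.prior_df
    nk = len(kernels)

    bases = []
    for name, Z, Kmat in kernels:
        TF, BF, lam = _kernel_basis(Z, np.asarray(Kmat, dtype=float), n)
        md = float(np.mean(np.sum(TF * TF, axis=1)))  # mean diag of ZKZ'
        md = md if md > 0 else 1.0
        S0 = chain.prior_r2 * vy / (nk * md) * (df0 + 2.0) / df0
        bases.append({
            "name": name, "TF": TF, "BF": BF, "lam": lam,
            "m": TF.shape[1], "S0": S0,
            "delta": np.zeros(TF.shape[1]), "g": np.zeros(n),
        })
    S0_e = (1.0 - chain.prior_r2) * vy * (df0 + 2.0) / df0

    XtX = Xf.T @ Xf
    try:
        XtX_inv = np.linalg.inv(XtX)
        L_beta = np.linalg.cholesky(XtX_inv)
    except np.linalg.LinAlgError as exc:
        raise ValueError("Xf is rank-deficient") from exc

    beta = np.linalg.solve(XtX, Xf.T @ y)
    sigma_e2 = vy / 2.0
    sigma_k2 = np.full(nk, vy / (2.0 * max(nk, 1)))
    resid = y - Xf @ beta

    keep_every = chain.thin
    n_keep = 0
    acc = {
        "beta": np.zeros_like(beta),
        "sigma_e2": 0.0,
        "sigma_k2": np.zeros(nk),
        "fitted": np.zeros(n),
        "u": [np.zeros(b["BF"].shape[0]) for b in bases],
        "u2": [np.zeros(b["BF"].shape[0]) for b in bases],
        "beta2": np.zeros_like(beta),
        "sigma_k2_2": np.zeros(nk),
    }

    for it in range(chain.n_iter):
        # fixed effects (flat prior)
        r_b = resid + Xf @ beta
        mean_b = XtX_inv @ (Xf.T @ r_b)
        beta = mean_b + np.sqrt(sigma_e2) * (L_beta @ rng.standard_normal(len(beta)))
        resid = r_b - Xf @ beta

        # kernel effects, one exact joint draw per kernel
        for k, b in enumerate(bases):
            r_k = resid + b["g"]
            a = b["lam"] / sigma_e2 + 1.0 / sigma_k2[k]
            mhat = (b["TF"].T @ r_k) / sigma_e2 / a
            b["delta"] = mhat + rng.standard_normal(b["m"]) / np.sqrt(a)
            b["g"] = b["TF"] @ b["delta"]
            resid = r_k - b["g"]
            ss = float(b["delta"] @ b["delta"])
            sigma_k2[k] = (ss + df0 * b["S0"]) / rng.chisquare(df0 + b["m"])

        sigma_e2 = (float(resid @ resid) + df0 * S0_e) / rng.chisquare(df0 + n)

        if not np.isfinite(sigma_e2) or sigma_e2 > 1e12 * vy or np.any(sigma_k2 > 1e12 * vy):
            raise RuntimeError(
                f"Gibbs sampler diverged at iteration {it}: "
                f"sigma_e2={sigma_e2:.3g}, sigma_k2={sigma_k2}"
            )

        if it >= chain.burn_in and (it - chain.burn_in) % keep_every == 0:
            n_keep += 1
            acc["beta"] += beta
            acc["beta2"] += beta ** 2
            acc["sigma_e2"] += sigma_e2
            acc["sigma_k2"] += sigma_k2
            acc["sigma_k2_2"] += sigma_k2 ** 2
            acc["fitted"] += Xf @ beta + sum(b["g"] for b in bases)
            for k, b in enumerate(bases):
                uk = b["BF"] @ b["delta"]
                acc["u"][k] += uk
                acc["u2"][k] += uk ** 2

    if n_keep == 0:
        raise RuntimeError("no post-burn-in samples retained")
    beta_mean = acc["beta"] / n_keep
    u_mean = {b["name"]: acc["u"][k] / n_keep for k, b in enumerate(bases)}
    u_var = {
        b["name"]: np.maximum(acc["u2"][k] / n_keep - (acc["u"][k] / n_keep) ** 2, 0.0)
        for k, b in enumerate(bases)
    }
    sigma2 = {b["name"]: float(acc["sigma_k2"][k] / n_keep) for k, b in enumerate(bases)}
    sigma2["e"] = float(acc["sigma_e2"] / n_keep)
    return GsFit(
        beta=beta_mean, beta_names=[f"b{i}" for i in range(len(beta_mean))],
        u=u_mean, sigma2=sigma2, fitted=acc["fitted"] / n_keep,
        u_sd={k: np.sqrt(v) for k, v in u_var.items()},
        n_samples=n_keep,
        meta={"chain": chain},
    )


# ---------------------------------------------------------------------------
# environment models
# ---------------------------------------------------------------------------

def fit_environment_model(
    spec: GsModelSpec,
    pheno: dict[str, pd.Series],
    G: GenotypeMatrix,
    chain: ChainConfig | None = None,
    solver: str = "auto",
    standardize: bool = False,
    K: KinshipMatrix | None = None,
) -> GsFit:
    """Fit the SE, A-E or GxE model to per-environment family values.

    ``pheno`` maps environment name -> Series indexed by family (NaN entries
    are treated as unobserved cells, which is how cross-validation masks
    records).  Families are restricted to those indexed in every requested
    environment.  ``K`` may be passed pre-built (aligned to ``G.family_ids``);
    otherwise it is built from ``G`` with the fixed SNPs removed.

    solver "auto" uses spectral REML for SE and the Gibbs sampler for AE/GXE.
    With ``standardize=True`` the stacked response is scaled to mean 0,
    variance 1 before fitting (the convention used for full-data variance
    decomposition); prediction accuracy is invariant to this scaling.
    """
    envs = list(spec.environments)
    for e in envs:
        if e not in pheno:
            raise KeyError(f"environment {e!r} not in phenotype data")
    fams = [f for f in G.family_ids if all(f in pheno[e].index for e in envs)]
    if not fams:
        raise ValueError("empty family intersection across environments")
    n_lines = len(fams)

    Xf_line, Gred = build_fixed_design(G, spec.fixed_snps)
    fam_idx = {f: i for i, f in enumerate(G.family_ids)}
    line_rows = np.array([fam_idx[f] for f in fams])
    snp_cols = Xf_line[line_rows, 1:]  # per-line fixed-SNP codes
    if K is None:
        K = vanraden_kinship(Gred)
    Kmat = (K.K if isinstance(K, KinshipMatrix) else np.asarray(K))[
        np.ix_(line_rows, line_rows)
    ]

    # stacked observed records
    y_parts, line_ix, env_ix = [], [], []
    for j, e in enumerate(envs):
        ser = pheno[e].reindex(fams)
        obs = ser.notna().to_numpy()
        y_parts.append(ser.to_numpy(float)[obs])
        line_ix.append(np.flatnonzero(obs))
        env_ix.append(np.full(int(obs.sum()), j))
    y = np.concatenate(y_parts)
    lines = np.concatenate(line_ix)
    env_of = np.concatenate(env_ix)
    n_obs = len(y)
    if n_obs == 0:
        raise ValueError("no observed records")

    y_mean, y_sd = float(y.mean()), float(y.std())
    if standardize:
        if y_sd <= 0:
            raise ValueError("cannot standardize a constant response")
        y = (y - y_mean) / y_sd

    # fixed design: one intercept per environment + shared fixed-SNP effects
    Xf = np.zeros((n_obs, len(envs) + snp_cols.shape[1]))
    for j in range(len(envs)):
        Xf[env_ix_mask(env_of, j), j] = 1.0
    if snp_cols.shape[1]:
        Xf[:, len(envs):] = snp_cols[lines]
    beta_names = [f"mu_{e}" for e in envs] + [f"snp_{m}" for m in spec.fixed_snps]

    Z_shared = np.zeros((n_obs, n_lines))
    Z_shared[np.arange(n_obs), lines] = 1.0

    if solver == "auto":
        solver = "reml" if spec.model_type == "SE" else "gibbs"

    if solver == "reml":
        if spec.model_type == "GXE":
            raise NotImplementedError("GXE is fit with the Gibbs solver")
        K_rec = Z_shared @ Kmat @ Z_shared.T
        fit = solve_gblup_reml(y, Xf, K_rec)
        # genetic values per line from the record-level BLUP via cross-covariance
        u_lines = Kmat @ Z_shared.T @ fit.alpha
        fit.u = {"u0": u_lines}
        fit.sigma2 = {"u0": fit.sigma2["u"], "e": fit.sigma2["e"]}
        u_env = {}
    else:
        kernels = [("u0", Z_shared, Kmat)]
        if spec.model_type == "GXE":
            for j, e in enumerate(envs):
                Zj = np.zeros((n_obs, n_lines))
                rows = env_ix_mask(env_of, j)
                Zj[rows, lines[rows]] = 1.0
                kernels.append((f"u:{e}", Zj, Kmat))
        chain = chain or ChainConfig()
        fit = solve_bayes_gibbs(y, Xf, kernels, chain)
        u_env = {e: fit.u[f"u:{e}"] for e in envs if f"u:{e}" in fit.u}

    fit.beta_names = beta_names
    # prediction grid: mu_env + snp effects + u0 (+ u_env)
    nsnp = snp_cols.shape[1]
    snp_part = snp_cols @ fit.beta[len(envs):] if nsnp else np.zeros(n_lines)
    grid = {}
    for j, e in enumerate(envs):
        cell = fit.beta[j] + snp_part + fit.u["u0"]
        if e in u_env:
            cell = cell + u_env[e]
        grid[e] = cell
    pred = pd.DataFrame(grid, index=pd.Index(fams, name="family"))
    if standardize:
        pred = pred * y_sd + y_mean
    fit.meta.update({
        "model_type": spec.model_type,
        "environments": envs,
        "families": fams,
        "predictions": pred,
        "standardized": standardize,
        "y_mean": y_mean,
        "y_sd": y_sd,
    })
    return fit


def env_ix_mask(env_of: np.ndarray, j: int) -> np.ndarray:
    return env_of == j
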