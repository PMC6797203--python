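"""Multi-environment phenotype mixed model: BLUEs, variance components, heritability.

The phenotypic model for a trait recorded on family ``i`` in environment ``j``,
replicate ``m`` is

    y_ijm = mu + g_i + e_j + ge_ij + delta_(j)m + eps_ijm

with genotype (family) effects ``g``, environment effects ``e``, genotype-by-
environment interaction ``ge``, replicate-within-environment effects ``delta``
and residual ``eps``.  BLUEs treat ``g`` as fixed with everything else random;
variance components treat every term as random.  Both fits are REML solutions
obtained by maximizing the restricted likelihood profiled over the residual
variance, evaluated through Henderson's mixed-model equations.

Entry-mean broad-sense heritability is

    H^2 = sigma_g^2 / (sigma_g^2 + sigma_ge^2 / Ne + sigma_eps^2 / (r * Ne))

for ``Ne`` environments and ``r`` replicates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, sparse
from scipy.linalg import cho_factor, cho_solve

logger = logging.getLogger("gsfix.pheno_mixed")

__all__ = [
    "PhenotypeTable",
    "VarianceComponents",
    "BlueResult",
    "fit_blue_model",
    "estimate_variance_components",
    "broad_sense_heritability",
    "summarize_phenotypes",
    "env_family_means",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeTable:
    """Long-format phenotype records (family, environment, replicate, value)."""

    records: pd.DataFrame

    REQUIRED = ("family", "env", "rep", "value")

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"phenotype table lacks columns {missing}")
        df = df.loc[:, list(self.REQUIRED)].copy()
        df["family"] = df["family"].astype(str)
        df["env"] = df["env"].astype(str)
        df["rep"] = df["rep"].astype(str)
        df["value"] = pd.to_numeric(df["value"], errors="raise")
        df = df.dropna(subset=["value"]).reset_index(drop=True)
        if not np.isfinite(df["value"].to_numpy()).all():
            raise ValueError("non-finite phenotype values")
        dup = df.duplicated(subset=["family", "env", "rep"])
        if dup.any():
            key = df.loc[dup.idxmax(), ["family", "env", "rep"]].tolist()
            raise ValueError(f"duplicate (family, env, rep) key: {tuple(key)}")
        self.records = df

    @property
    def families(self) -> list[str]:
        return sorted(self.records["family"].unique())

    @property
    def environments(self) -> list[str]:
        return sorted(self.records["env"].unique())

    @property
    def n_records(self) -> int:
        return len(self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class VarianceComponents:
    """REML variance components of the all-random phenotype model (trait units squared)."""

    sigma_g2: float
    sigma_ge2: float
    sigma_rep2: float
    sigma_e2: float
    sigma_env2: float = 0.0  # environment main-effect variance; not used by H^2
    loglik: float = np.nan
    n_iter: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma_g2", "sigma_ge2", "sigma_rep2", "sigma_e2", "sigma_env2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class BlueResult:
    """Per-family BLUEs (mu + g_i) from the genotype-fixed mixed model."""

    blues: pd.Series  # index: family, values: BLUE
    overall_mean: float
    variance_components: dict = field(default_factory=dict)
    loglik: float = np.nan
    n_iter: int = 0

    def aligned(self, families) -> np.ndarray:
        return self.blues.reindex(list(families)).to_numpy()


# ---------------------------------------------------------------------------
# REML core (Henderson's MME, profiled restricted likelihood)
# ---------------------------------------------------------------------------

def _indicator(codes: pd.Series) -> tuple[sparse.csr_matrix, list]:
    """Sparse 0/1 incidence matrix for a categorical factor."""
    levels, idx = np.unique(codes.to_numpy(), return_inverse=True)
    n = len(codes)
    Z = sparse.csr_matrix(
        (np.ones(n), (np.arange(n), idx)), shape=(n, len(levels))
    )
    return Z, list(levels)


_LOG_GAMMA_LO = -23.0
_LOG_GAMMA_HI = 18.0


def _reml_crossed(y: np.ndarray, X: np.ndarray, Z_blocks: list) -> dict:
    """REML for y = X b + sum_k Z_k u_k + e with u_k ~ N(0, I sigma_k^2).

    ``Z_blocks`` is a list of (name, Z_k) with sparse incidence matrices.
    Maximizes the restricted log-likelihood over the variance ratios
    gamma_k = sigma_k^2 / sigma_e^2 (profiling out sigma_e^2), using the
    mixed-model-equations factorization for each evaluation.
    """
    n, p = X.shape
    names = [nm for nm, _ in Z_blocks]
    qs = [Z.shape[1] for _, Z in Z_blocks]
    yty = float(y @ y)

    # Absorb the largest random block before factorizing: a factor's Z'Z is
    # diagonal, so its MME rows reduce to a cheap Schur complement.  With a
    # GxE term of ~n_family*n_env levels this cuts each likelihood
    # evaluation from O((p+q)^3) to O((p+rest)^3).
    absorb = int(np.argmax(qs)) if max(qs) > 100 else -1
    top_blocks = [(k, Z) for k, (_, Z) in enumerate(Z_blocks) if k != absorb]
    W_top = sparse.hstack(
        [sparse.csr_matrix(X)] + [Z for _, Z in top_blocks], format="csr"
    )
    A0 = np.asarray((W_top.T @ W_top).todense())
    Wty_top = np.asarray(W_top.T @ y).ravel()
    offs = np.cumsum([p] + [qs[k] for k, _ in top_blocks])
    top_slices = {k: slice(offs[i], offs[i + 1]) for i, (k, _) in enumerate(top_blocks)}
    if absorb >= 0:
        Z_a = Z_blocks[absorb][1].tocsc()
        counts_a = np.asarray(Z_a.multiply(Z_a).sum(axis=0)).ravel()
        B = (W_top.T @ Z_a).tocsr()  # (p+rest) x q_absorb, sparse
        Zaty = np.asarray(Z_a.T @ y).ravel()

    # degenerate response: no residual variation at all
    scale = float(np.var(y)) if n > 1 else 0.0

    def neg2_relL(log_g: np.ndarray, want_sol: bool = False):
        log_g = np.clip(log_g, _LOG_GAMMA_LO, _LOG_GAMMA_HI)
        M = A0.copy()
        for k, lg in enumerate(log_g):
            if k in top_slices:
                sl = top_slices[k]
                M[np.arange(sl.start, sl.stop), np.arange(sl.start, sl.stop)] += np.exp(-lg)
        logdet_extra = 0.0
        rhs = Wty_top
        if absorb >= 0:
            S = counts_a + np.exp(-log_g[absorb])
            M = M - np.asarray((B @ sparse.diags(1.0 / S) @ B.T).todense())
            logdet_extra = float(np.sum(np.log(S)))
            rhs = Wty_top - B @ (Zaty / S)
        try:
            c, low = cho_factor(M, lower=True)
        except np.linalg.LinAlgError:
            return (np.inf, None) if want_sol else np.inf
        sol_top = cho_solve((c, low), rhs)
        # y'Py*se2 = ||y - W sol||^2 + sum_k u_k'u_k/gamma_k, both terms
        # positive; the y'y - sol'W'y shortcut loses ~6 digits to
        # cancellation, above the curvature scale of the profile likelihood
        resid = y - W_top @ sol_top
        penalty = 0.0
        for k, lg in enumerate(log_g):
            if k in top_slices:
                uk = sol_top[top_slices[k]]
                penalty += np.exp(-lg) * float(uk @ uk)
        if absorb >= 0:
            u_a = (Zaty - B.T @ sol_top) / S
            resid = resid - Z_a @ u_a
            penalty += np.exp(-log_g[absorb]) * float(u_a @ u_a)
        rss = max(float(resid @ resid) + penalty, 1e-300)
        logdet = 2.0 * float(np.sum(np.log(np.diag(c)))) + logdet_extra
        val = (n - p) * np.log(rss / (n - p)) + logdet
        val += float(np.sum(np.array(qs) * log_g))
        if want_sol:
            sol = {"top": sol_top, "u_a": u_a if absorb >= 0 else None}
            return val, (sol, rss)
        return val

    nblk = len(qs)
    # moment-based start: level-mean variances of the OLS residuals give a
    # scale-aware initial gamma for each factor (components can differ by
    # orders of magnitude, where a flat gamma=1 start strands the search at
    # the zero boundary)
    beta0 = np.linalg.lstsq(X, y, rcond=None)[0]
    r0 = y - X @ beta0
    v0 = max(float(np.var(r0)), 1e-12)
    x_mom = np.zeros(nblk)
    for k, (_, Z) in enumerate(Z_blocks):
        counts = np.asarray(Z.sum(axis=0)).ravel()
        nonzero = counts > 0
        means = np.asarray(Z.T @ r0).ravel()[nonzero] / counts[nonzero]
        vk = max(float(np.var(means)) - v0 / max(float(counts.mean()), 1.0), v0 * 1e-3)
        x_mom[k] = np.log(vk / v0)
    x0 = np.zeros(nblk)  # gamma_k = 1 start
    if scale <= 0 or not np.isfinite(scale):
        # constant response
        result = {nm: 0.0 for nm in names}
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        return {
            "sigma2": result, "sigma_e2": 0.0, "beta": beta,
            "u": {nm: np.zeros(q) for nm, q in zip(names, qs)},
            "loglik": np.nan, "n_iter": 0,
        }

    bounds = [(_LOG_GAMMA_LO, _LOG_GAMMA_HI)] * nblk
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        candidates = []
        for start in (x_mom, x0):
            res = optimize.minimize(
                neg2_relL, start, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": 60, "ftol": 1e-13, "gtol": 1e-9},
            )
            candidates.append(res)
        res = min(candidates, key=lambda r: r.fun)
        # polish: Nelder-Mead is insensitive to the noisy numeric gradient;
        # pulling boundary coordinates back inside lets the simplex re-test
        # them, and fatol above the ~1e-13 roundoff floor of the objective
        # lets it terminate instead of churning to maxfev
        x_in = np.clip(res.x, -8.0, _LOG_GAMMA_HI)
        res2 = optimize.minimize(
            neg2_relL, x_in, method="Nelder-Mead", bounds=bounds,
            options={"xatol": 1e-9, "fatol": 1e-11, "maxfev": 2000},
        )
    best = res2 if res2.fun <= res.fun else res
    log_g = np.clip(best.x, _LOG_GAMMA_LO, _LOG_GAMMA_HI)
    val, (sol, rss) = neg2_relL(log_g, want_sol=True)
    sigma_e2 = rss / (n - p)
    gammas = np.exp(log_g)
    # boundary: gamma at the lower bound means the component is zero
    sigma2 = {
        nm: (0.0 if lg <= _LOG_GAMMA_LO + 1e-6 else float(g * sigma_e2))
        for nm, g, lg in zip(names, gammas, log_g)
    }
    beta = sol["top"][:p]
    u = {}
    for k, nm in enumerate(names):
        if k in top_slices:
            u[nm] = np.asarray(sol["top"][top_slices[k]])
        else:
            u[nm] = np.asarray(sol["u_a"])
    loglik = -0.5 * (val + (n - p) * (1.0 + np.log(2.0 * np.pi)))
    return {
        "sigma2": sigma2, "sigma_e2": float(sigma_e2), "beta": beta, "u": u,
        "loglik": float(loglik), "n_iter": int(res.nit + res2.nit),
    }


def _model_frames(pheno: PhenotypeTable, genotype_random: bool):
    df = pheno.records
    fam_Z, fam_levels = _indicator(df["family"])
    env_Z, env_levels = _indicator(df["env"])
    ge_Z, _ = _indicator(df["family"] + "\x1f" + df["env"])
    rep_Z, _ = _indicator(df["env"] + "\x1f" + df["rep"])
    y = df["value"].to_numpy(float)
    if genotype_random:
        X = np.ones((len(df), 1))
        blocks = [("g", fam_Z), ("env", env_Z), ("ge", ge_Z), ("rep", rep_Z)]
    else:
        # full-rank reference-level contrasts for the fixed genotype effect
        X = np.column_stack([np.ones(len(df)), np.asarray(fam_Z[:, 1:].todense())])
        blocks = [("env", env_Z), ("ge", ge_Z), ("rep", rep_Z)]
    return y, X, blocks, fam_levels, env_levels


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def fit_blue_model(pheno: PhenotypeTable) -> BlueResult:
    """BLUEs of family means: genotype fixed; env, GxE, rep-in-env random (REML)."""
    if len(pheno.environments) < 2:
        raise ValueError("need >= 2 environments to fit the multi-environment model")
    if len(pheno.families) < 2:
        raise ValueError("need >= 2 families")
    y, X, blocks, fam_levels, _ = _model_frames(pheno, genotype_random=False)

    # short-circuit the exactly deterministic case y_ijm = c_i
    fam_means = pheno.records.groupby("family")["value"].mean()
    resid = pheno.records["value"].to_numpy() - fam_means.reindex(
        pheno.records["family"]).to_numpy()
    if np.allclose(resid, 0.0, atol=1e-12 * max(1.0, float(np.abs(y).max()))):
        blues = fam_means.reindex(fam_levels)
        return BlueResult(
            blues=blues, overall_mean=float(blues.mean()),
            variance_components={"env": 0.0, "ge": 0.0, "rep": 0.0, "e": 0.0},
            loglik=np.nan, n_iter=0,
        )

    fit = _reml_crossed(y, X, blocks)
    beta = fit["beta"]
    vals = beta[0] + np.concatenate([[0.0], beta[1:]])
    blues = pd.Series(vals, index=fam_levels, name="blue")
    vc = dict(fit["sigma2"])
    vc["e"] = fit["sigma_e2"]
    return BlueResult(
        blues=blues, overall_mean=float(blues.mean()),
        variance_components=vc, loglik=fit["loglik"], n_iter=fit["n_iter"],
    )


def estimate_variance_components(pheno: PhenotypeTable) -> VarianceComponents:
    """REML variance components with genotype, env, GxE, rep all random."""
    if len(pheno.environments) < 2:
        raise ValueError("need >= 2 environments")
    if len(pheno.families) < 2:
        raise ValueError("need >= 2 families")
    y, X, blocks, _, _ = _model_frames(pheno, genotype_random=True)
    fit = _reml_crossed(y, X, blocks)
    s = fit["sigma2"]
    return VarianceComponents(
        sigma_g2=s["g"], sigma_ge2=s["ge"], sigma_rep2=s["rep"],
        sigma_e2=fit["sigma_e2"], sigma_env2=s["env"],
        loglik=fit["loglik"], n_iter=fit["n_iter"],
    )


def broad_sense_heritability(vc: VarianceComponents, Ne: int, r: int) -> float:
    """Entry-mean H^2 = sigma_g^2 / (sigma_g^2 + sigma_ge^2/Ne + sigma_e^2/(r*Ne))."""
    if Ne < 1 or r < 1:
        raise ValueError("Ne and r must be >= 1")
    denom = vc.sigma_g2 + vc.sigma_ge2 / Ne + vc.sigma_e2 / (r * Ne)
    if denom <= 0:
        raise ValueError("all variance components are zero; H^2 undefined")
    return float(vc.sigma_g2 / denom)


def summarize_phenotypes(pheno: PhenotypeTable) -> pd.DataFrame:
    """Per-environment n (families with data), mean, sd, range and CV%."""
    if pheno.n_records == 0:
        raise ValueError("empty phenotype table")
    rows = []
    for env, grp in pheno.records.groupby("env"):
        v = grp["value"].to_numpy(float)
        mean = float(v.mean())
        sd = float(v.std(ddof=1)) if len(v) > 1 else 0.0
        rows.append({
            "env": env,
            "n": int(grp["family"].nunique()),
            "mean": mean,
            "sd": sd,
            "min": float(v.min()),
            "max": float(v.max()),
            "cv_pct": 100.0 * sd / mean if mean != 0 else np.nan,
        })
    return pd.DataFrame(rows).set_index("env").sort_index()


def env_family_means(pheno: PhenotypeTable) -> dict[str, pd.Series]:
    """Family means per environment (input to the per-environment GS models)."""
    out = {}
    for env, grp in pheno.records.groupby("env"):
        out[str(env)] = grp.groupby("family")["value"].mean()
    return out
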