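"""Cross-validation machinery for genomic prediction.

Schemes
-------
SINGLE : repeated k-fold CV of one response vector (the BLUEs); per repeat,
    lines are partitioned into k folds, each fold predicted from the rest,
    and one prediction accuracy (Pearson r between pooled predictions and
    observations) is recorded.
CV1 : multi-environment scheme for untested lines — a fold's lines are masked
    in every environment.
CV2 : multi-environment scheme for partially tested lines — line-by-
    environment cells are masked so each masked line keeps its record in the
    other environment; which environment is masked alternates within a fold
    so the masked-cell counts stay balanced.

Genotypes are known for all lines, so the kinship matrix is built once from
all genotypes and only phenotypes are masked.

Seeding: one integer master seed; repeat ``r`` of any routine draws from
``numpy.random.SeedSequence([master, salt, r])`` with a fixed per-routine
salt, so any single repeat or draw is re-runnable in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .gs_engines import (
    ChainConfig,
    GsModelSpec,
    build_fixed_design,
    fit_environment_model,
    gblup_predict,
    solve_bayes_gibbs,
    solve_gblup_reml,
)
from .kinship_gwas import KinshipMatrix, _align_response, vanraden_kinship
from .synthetic_data import GenotypeMatrix

logger = logging.getLogger("gsfix.cv_engine")

__all__ = [
    "CvScheme",
    "CvResult",
    "pearson_pa",
    "run_cv_single",
    "choose_n_fixed_snps",
    "random_snp_null",
    "run_cv_multi",
    "mas_predict_cv",
]

_SALT_FOLDS = 11
_SALT_CHAIN = 13
_SALT_NULL = 17


@dataclass(frozen=True)
class CvScheme:
    kind: str = "SINGLE"  # SINGLE | CV1 | CV2
    k: int = 5
    n_repeats: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("SINGLE", "CV1", "CV2"):
            raise ValueError("kind must be SINGLE, CV1 or CV2")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class CvResult:
    """Prediction accuracies per repeat (columns = validation environments)."""

    pa: np.ndarray
    env_names: list[str] | None = None
    meta: dict = field(default_factory=dict)

    @property
    def mean(self):
        return float(np.mean(self.pa)) if self.pa.ndim == 1 else self.pa.mean(axis=0)

    @property
    def sd(self):
        return float(np.std(self.pa, ddof=1)) if self.pa.ndim == 1 else self.pa.std(axis=0, ddof=1)


def pearson_pa(predicted, observed) -> float:
    """Sample Pearson correlation between predicted and observed values."""
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(observed, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("predicted and observed must be equal-length vectors (>= 3)")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("prediction accuracy undefined: zero variance")
    return float(np.corrcoef(x, y)[0, 1])


def _rng(master: int, salt: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([master, salt, index]))


def _chain_seed(master: int, repeat: int, fold: int) -> int:
    ss = np.random.SeedSequence([master, _SALT_CHAIN, repeat, fold])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _folds(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)
    if min(len(f) for f in folds) < 2:
        raise ValueError("a fold would contain fewer than 2 lines")
    return folds


# ---------------------------------------------------------------------------
# single-response CV
# ---------------------------------------------------------------------------

def run_cv_single(
    blues,
    G: GenotypeMatrix,
    fixed_snps,
    scheme: CvScheme,
    solver: str = "reml",
    chain: ChainConfig | None = None,
    K: KinshipMatrix | None = None,
) -> CvResult:
    """Repeated k-fold CV of a GBLUP with optional fixed-effect markers."""
    if scheme.kind != "SINGLE":
        raise ValueError("run_cv_single requires a SINGLE scheme")
    y = _align_response(blues, G.family_ids)
    n = len(y)
    Xf, Gred = build_fixed_design(G, fixed_snps)
    if K is None:
        K = vanraden_kinship(Gred)
    Kmat = K.K if isinstance(K, KinshipMatrix) else np.asarray(K)
    chain = chain or ChainConfig()

    pa = np.empty(scheme.n_repeats)
    for rep in range(scheme.n_repeats):
        rng = _rng(scheme.seed, _SALT_FOLDS, rep)
        preds = np.empty(n)
        for fold_i, val in enumerate(_folds(n, scheme.k, rng)):
            tr = np.setdiff1d(np.arange(n), val)
            if solver == "reml":
                fit = solve_gblup_reml(y[tr], Xf[tr], Kmat[np.ix_(tr, tr)])
                preds[val] = gblup_predict(fit, Xf[val], Kmat[np.ix_(val, tr)])
            elif solver == "gibbs":
                Z = np.zeros((len(tr), n))
                Z[np.arange(len(tr)), tr] = 1.0
                ch = replace(chain, seed=_chain_seed(scheme.seed, rep, fold_i))
                fit = solve_bayes_gibbs(y[tr], Xf[tr], [("u0", Z, Kmat)], ch)
                preds[val] = Xf[val] @ fit.beta + fit.u["u0"][val]
            else:
                raise ValueError(f"unknown solver {solver!r}")
        pa[rep] = pearson_pa(preds, y)
    return CvResult(pa=pa, meta={
        "scheme": scheme, "fixed_snps": list(fixed_snps), "solver": solver,
        "model": "GBLUP",
    })


def choose_n_fixed_snps(
    blues,
    G: GenotypeMatrix,
    ranked_snps: list[str],
    max_n: int,
    scheme: CvScheme,
    alpha: float = 0.05,
    solver: str = "reml",
    chain: ChainConfig | None = None,
) -> tuple[int, pd.DataFrame]:
    """Smallest sufficient number of fixed markers by sequential t-tests.

    For n = 1..max_n the 100 (or n_repeats) PAs with the top-n markers fixed
    are compared with those of top-(n-1) by a two-tailed Welch t-test over
    repeats (fold partitions are shared across n, pairing the repeats).
    Returns the largest n whose every step up from 0 is significant while the
    next step is not, together with the full test table.
    """
    if max_n > len(ranked_snps):
        raise ValueError("max_n exceeds the number of ranked markers")
    results = []
    for n_fix in range(max_n + 1):
        res = run_cv_single(blues, G, ranked_snps[:n_fix], scheme,
                            solver=solver, chain=chain)
        results.append(res.pa)
    rows = [{"n_fixed": 0, "mean_pa": float(np.mean(results[0])),
             "sd_pa": float(np.std(results[0], ddof=1)) if len(results[0]) > 1 else np.nan,
             "p_vs_prev": np.nan, "significant": False}]
    n_star = 0
    chain_intact = True
    for n_fix in range(1, max_n + 1):
        t, p = stats.ttest_ind(results[n_fix], results[n_fix - 1], equal_var=False)
        sig = bool(p < alpha and t > 0)
        rows.append({
            "n_fixed": n_fix, "mean_pa": float(np.mean(results[n_fix])),
            "sd_pa": float(np.std(results[n_fix], ddof=1)) if len(results[n_fix]) > 1 else np.nan,
            "p_vs_prev": float(p), "significant": sig,
        })
        if chain_intact and sig:
            n_star = n_fix
        else:
            chain_intact = False
    table = pd.DataFrame(rows)
    return n_star, table


def random_snp_null(
    blues,
    G: GenotypeMatrix,
    scheme: CvScheme,
    n_fixed: int = 4,
    n_draws: int = 200,
    solver: str = "reml",
    chain: ChainConfig | None = None,
) -> np.ndarray:
    """Null distribution of mean PA with randomly chosen fixed markers.

    Each draw samples ``n_fixed`` markers uniformly without replacement and
    runs the full CV; the vector of per-draw mean PAs is returned.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if n_fixed >= G.n_markers:
        raise ValueError("n_fixed must be smaller than the number of markers")
    out = np.empty(n_draws)
    for d in range(n_draws):
        rng = _rng(scheme.seed, _SALT_NULL, d)
        snps = list(rng.choice(np.asarray(G.marker_ids, dtype=object),
                               size=n_fixed, replace=False))
        res = run_cv_single(blues, G, snps, scheme, solver=solver, chain=chain)
        out[d] = res.mean
    return out


# ---------------------------------------------------------------------------
# multi-environment CV (CV1 / CV2)
# ---------------------------------------------------------------------------

def run_cv_multi(
    pheno_pair: dict[str, pd.Series],
    G: GenotypeMatrix,
    model_type: str,
    fixed_snps,
    scheme: CvScheme,
    chain: ChainConfig | None = None,
    solver: str = "gibbs",
    K: KinshipMatrix | None = None,
) -> CvResult:
    """CV1/CV2 cross-validation of the A-E or GxE model on two environments.

    Families are restricted to those phenotyped in every environment of the
    pair.  Per repeat, PA is computed per validation environment over that
    environment's masked cells pooled across folds.
    """
    if scheme.kind not in ("CV1", "CV2"):
        raise ValueError("run_cv_multi requires a CV1 or CV2 scheme")
    if model_type not in ("AE", "GXE"):
        raise ValueError("model_type must be AE or GXE")
    envs = list(pheno_pair)
    if len(envs) < 2:
        raise ValueError("need a pair of environments")
    fams = [
        f for f in G.family_ids
        if all(f in pheno_pair[e].index and pd.notna(pheno_pair[e].get(f))
               for e in envs)
    ]
    if len(fams) < scheme.k * 2:
        raise ValueError("too few jointly phenotyped families")
    n = len(fams)
    obs = {e: pheno_pair[e].reindex(fams) for e in envs}
    spec = GsModelSpec(model_type=model_type, environments=tuple(envs),
                       fixed_snps=tuple(fixed_snps))
    if K is None:
        _, Gred = build_fixed_design(G, fixed_snps)
        K = vanraden_kinship(Gred)
    chain = chain or ChainConfig()

    pa = np.empty((scheme.n_repeats, len(envs)))
    for rep in range(scheme.n_repeats):
        rng = _rng(scheme.seed, _SALT_FOLDS, rep)
        collected = {e: ([], []) for e in envs}  # env -> (pred, obs)
        for fold_i, val in enumerate(_folds(n, scheme.k, rng)):
            masked = {e: obs[e].copy() for e in envs}
            cells = []  # (env, line position)
            for t, line in enumerate(val):
                if scheme.kind == "CV1":
                    mask_envs = envs
                else:  # CV2: alternate the masked environment within the fold
                    mask_envs = [envs[t % len(envs)]]
                for e in mask_envs:
                    masked[e].iloc[line] = np.nan
                    cells.append((e, line))
            ch = replace(chain, seed=_chain_seed(scheme.seed, rep, fold_i))
            fit = fit_environment_model(spec, masked, G, chain=ch,
                                        solver=solver, K=K)
            pred = fit.meta["predictions"]
            for e, line in cells:
                fam = fams[line]
                collected[e][0].append(float(pred.loc[fam, e]))
                collected[e][1].append(float(obs[e].iloc[line]))
        for j, e in enumerate(envs):
            pa[rep, j] = pearson_pa(collected[e][0], collected[e][1])
    return CvResult(pa=pa, env_names=envs, meta={
        "scheme": scheme, "model": model_type, "fixed_snps": list(fixed_snps),
        "solver": solver, "n_families": n,
    })


# ---------------------------------------------------------------------------
# MAS baseline
# ---------------------------------------------------------------------------

def mas_predict_cv(
    blues,
    G: GenotypeMatrix,
    snps: list[str],
    scheme: CvScheme,
) -> CvResult:
    """Marker-assisted selection baseline: OLS of the BLUEs on a few markers."""
    if len(snps) < 1:
        raise ValueError("need at least one marker")
    y = _align_response(blues, G.family_ids)
    n = len(y)
    X = np.column_stack([np.ones(n), G.codes[:, G.marker_index(snps)]])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        logger.warning("MAS design is rank-deficient; aliased markers contribute nothing")
    pa = np.empty(scheme.n_repeats)
    for rep in range(scheme.n_repeats):
        rng = _rng(scheme.seed, _SALT_FOLDS, rep)
        preds = np.empty(n)
        for val in _folds(n, scheme.k, rng):
            tr = np.setdiff1d(np.arange(n), val)
            coef, *_ = np.linalg.lstsq(X[tr], y[tr], rcond=None)
            preds[val] = X[val] @ coef
        pa[rep] = pearson_pa(preds, y)
    return CvResult(pa=pa, meta={"scheme": scheme, "model": "MAS", "snps": list(snps)})
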