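"""Marker QC, VanRaden kinship, mixed-model GWAS and PVE decomposition.

The genomic relationship matrix follows VanRaden: with genotype matrix ``M``
coded -1/0/1 and ``P`` the column matrix 2(p_j - 0.5) of allele frequencies,

    K = W W' / (2 * sum_j p_j q_j),   W = M - P.

The association scan fits, for each marker, y* = X b + Z g + w tau + eps with
g ~ N(0, K sigma_u^2).  Background variance components are estimated once
under the null model on the eigendecomposition of K and reused for every
marker (the P3D shortcut); each marker is then tested by generalized least
squares in the rotated space with a Wald t-test.  Phenotypic variance
explained by the top-ranked markers comes from one multiple regression of the
BLUEs on the selected markers, decomposed into sequential (Type-I) sums of
squares over the total corrected sum of squares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .synthetic_data import GenotypeMatrix

logger = logging.getLogger("gsfix.kinship_gwas")

__all__ = [
    "KinshipMatrix",
    "filter_markers",
    "impute_missing",
    "vanraden_kinship",
    "gwas_scan",
    "select_top_snps",
    "pve_multiple_regression",
]


@dataclass
class KinshipMatrix:
    """VanRaden genomic relationship matrix with its centering quantities."""

    K: np.ndarray
    W: np.ndarray
    p: np.ndarray  # frequency of the +1 (recurrent) allele per marker
    denominator: float  # 2 * sum_j p_j q_j
    family_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        n = self.K.shape[0]
        if self.K.shape != (n, n):
            raise ValueError("K must be square")
        if not np.allclose(self.K, self.K.T, atol=1e-10):
            raise ValueError("K must be symmetric")

    @property
    def n(self) -> int:
        return self.K.shape[0]

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.K)[0])

    def subset(self, idx: np.ndarray) -> "KinshipMatrix":
        idx = np.asarray(idx)
        fams = [self.family_ids[i] for i in idx] if self.family_ids else []
        return KinshipMatrix(
            K=self.K[np.ix_(idx, idx)], W=self.W[idx, :],
            p=self.p, denominator=self.denominator, family_ids=fams,
        )


# ---------------------------------------------------------------------------
# marker QC and imputation
# ---------------------------------------------------------------------------

def filter_markers(
    G: GenotypeMatrix,
    parent_genotypes: np.ndarray,
    max_missing: float = 0.05,
) -> GenotypeMatrix:
    """Drop markers missing in a parent, non-polymorphic between parents,
    or with missing rate strictly above ``max_missing``.

    ``parent_genotypes`` is a (2, n_markers) array aligned to ``G.marker_ids``
    (row 0 = recurrent parent, row 1 = donor parent).
    """
    parents = np.asarray(parent_genotypes, dtype=float)
    if parents.shape != (2, G.n_markers):
        raise ValueError("parent_genotypes must be a (2, n_markers) array aligned to G")
    miss_parent = np.isnan(parents).any(axis=0)
    non_poly = ~miss_parent & (parents[0] == parents[1])
    miss_rate = np.isnan(G.codes).mean(axis=0)
    too_missing = miss_rate > max_missing  # strict: rate == threshold is kept
    keep = ~(miss_parent | non_poly | too_missing)
    logger.info(
        "marker QC: %d in; removed %d parent-missing, %d non-polymorphic, "
        "%d over missing-rate %.3g; %d kept",
        G.n_markers, int(miss_parent.sum()), int(non_poly.sum()),
        int((too_missing & ~miss_parent & ~non_poly).sum()), max_missing, int(keep.sum()),
    )
    if not keep.any():
        raise ValueError("all markers removed by QC filters")
    return G.subset_markers(keep)


def impute_missing(G: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing codes with the marker's expected value (observed column mean)."""
    codes = G.codes.copy()
    obs = ~np.isnan(codes)
    n_obs = obs.sum(axis=0)
    if np.any(n_obs == 0):
        j = int(np.argmin(n_obs))
        raise ValueError(f"marker {G.marker_ids[j]!r} has no observed genotypes")
    col_mean = np.nansum(codes, axis=0) / n_obs
    idx = np.where(np.isnan(codes))
    codes[idx] = col_mean[idx[1]]
    return GenotypeMatrix(
        family_ids=list(G.family_ids), marker_ids=list(G.marker_ids),
        codes=codes, bc1f2_family=G.bc1f2_family,
    )


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------

def vanraden_kinship(G: GenotypeMatrix, exclude: set | None = None) -> KinshipMatrix:
    """K = WW' / (2 sum p_j q_j) with W = M - P, P_ij = 2(p_j - 0.5).

    Allele frequencies are computed from the (imputed) sample.  Markers whose
    IDs appear in ``exclude`` are left out of the computation.
    """
    if np.isnan(G.codes).any():
        raise ValueError("genotypes must be imputed (no missing) before kinship")
    keep = np.ones(G.n_markers, dtype=bool)
    if exclude:
        unknown = set(exclude) - set(G.marker_ids)
        if unknown:
            raise KeyError(f"exclude set contains unknown markers: {sorted(unknown)[:5]}")
        keep = ~np.isin(np.asarray(G.marker_ids, dtype=object), list(exclude))
    M = G.codes[:, keep]
    if M.shape[1] == 0:
        raise ValueError("no markers remain after exclusion")
    p = (M.mean(axis=0) + 1.0) / 2.0  # frequency of the +1 allele
    q = 1.0 - p
    denom = float(2.0 * np.sum(p * q))
    if denom <= 0:
        raise ValueError(
            "kinship denominator 2*sum(p*q) is zero: all markers are monomorphic"
        )
    W = M - 2.0 * (p - 0.5)
    K = W @ W.T / denom
    return KinshipMatrix(K=K, W=W, p=p, denominator=denom,
                         family_ids=list(G.family_ids))


# ---------------------------------------------------------------------------
# GWAS
# ---------------------------------------------------------------------------

def _spectral_null_reml(y: np.ndarray, X: np.ndarray, s: np.ndarray, U: np.ndarray):
    """REML of y = Xb + g + e, g ~ N(0, K su2), via the eigendecomposition K = U diag(s) U'.

    Returns (gamma_hat, sigma_u2, sigma_e2, rotated y and X).  gamma = su2/se2.
    """
    n, p = X.shape
    yt = U.T @ y
    Xt = U.T @ X

    def neg2ll(log_g: float) -> float:
        g = np.exp(log_g)
        w = g * s + 1.0
        Xw = Xt / w[:, None]
        A = Xt.T @ Xw
        b = Xw.T @ yt
        try:
            coef = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            return np.inf
        rss = float(yt @ (yt / w)) - float(b @ coef)
        rss = max(rss, 1e-300)
        sign, logdetA = np.linalg.slogdet(A)
        if sign <= 0:
            return np.inf
        return float(np.sum(np.log(w)) + logdetA + (n - p) * np.log(rss))

    res = optimize.minimize_scalar(
        neg2ll, bounds=(-25.0, 25.0), method="bounded",
        options={"xatol": 1e-11},
    )
    g = float(np.exp(res.x))
    w = g * s + 1.0
    Xw = Xt / w[:, None]
    coef = np.linalg.solve(Xt.T @ Xw, Xw.T @ yt)
    rss = float(yt @ (yt / w)) - float((Xw.T @ yt) @ coef)
    se2 = rss / (n - p)
    return g, g * se2, se2, yt, Xt


def gwas_scan(
    blues,
    G: GenotypeMatrix,
    K: KinshipMatrix,
    force_gamma: float | None = None,
    exact: bool = False,
) -> pd.DataFrame:
    """Single-marker mixed-model scan of the BLUEs against every marker.

    Null-model variance components are estimated once by spectral REML and
    reused for each marker (P3D); set ``exact=True`` to re-estimate them per
    marker.  ``force_gamma`` pins the background variance ratio
    sigma_u^2/sigma_e^2 (0 gives the ordinary least-squares scan).

    ``blues`` may be a BlueResult, a pandas Series indexed by family, or an
    array aligned to ``G.family_ids``.
    """
    y = _align_response(blues, G.family_ids)
    if K.family_ids and list(K.family_ids) != list(G.family_ids):
        raise ValueError("family IDs of K and G are not aligned")
    if K.n != G.n_families:
        raise ValueError("K dimension does not match number of families")
    s, U = np.linalg.eigh(K.K)
    if s[0] < -1e-8 * max(1.0, s[-1]):
        raise ValueError("K is not positive semidefinite")
    s = np.clip(s, 0.0, None)
    n = len(y)
    X = np.ones((n, 1))
    if force_gamma is not None:
        gamma = float(force_gamma)
        yt, Xt = U.T @ y, U.T @ X
        w = gamma * s + 1.0
        su2 = se2 = np.nan
    else:
        gamma, su2, se2, yt, Xt = _spectral_null_reml(y, X, s, U)
        w = gamma * s + 1.0

    Mt = U.T @ G.codes  # rotated marker columns
    iw = 1.0 / w
    one = Xt[:, 0]
    a11 = float(np.sum(one * one * iw))
    a12 = (one * iw) @ Mt
    a22 = np.einsum("ij,ij->j", Mt * iw[:, None], Mt)
    b1 = float(np.sum(one * yt * iw))
    b2 = (yt * iw) @ Mt
    det = a11 * a22 - a12 ** 2
    ok = det > 1e-12 * max(a11, 1.0)
    tau = np.where(ok, (a11 * b2 - a12 * b1) / np.where(ok, det, 1.0), np.nan)
    beta0 = np.where(ok, (b1 - a12 * tau) / a11, np.nan)
    yty = float(np.sum(yt * yt * iw))
    rss = yty - (beta0 * b1 + tau * b2)
    rss = np.clip(rss, 1e-300, None)
    df = n - 2
    sigma2 = rss / df
    se = np.sqrt(sigma2 * a11 / np.where(ok, det, np.nan))
    tstat = tau / se
    pval = 2.0 * stats.t.sf(np.abs(tstat), df)

    if exact:
        for j in range(G.n_markers):
            if not ok[j]:
                continue
            Xj = np.column_stack([X, G.codes[:, j]])
            gj, _, _, ytj, Xtj = _spectral_null_reml(y, Xj, s, U)
            wj = gj * s + 1.0
            Xw = Xtj / wj[:, None]
            A = Xtj.T @ Xw
            coef = np.linalg.solve(A, Xw.T @ ytj)
            rssj = max(float(ytj @ (ytj / wj)) - float((Xw.T @ ytj) @ coef), 1e-300)
            s2 = rssj / (n - 2)
            cov = np.linalg.inv(A) * s2
            tau[j] = coef[1]
            se[j] = np.sqrt(cov[1, 1])
            pval[j] = 2.0 * stats.t.sf(abs(tau[j] / se[j]), n - 2)

    pval = np.clip(pval, np.finfo(float).tiny, 1.0)
    res = pd.DataFrame({
        "marker": G.marker_ids,
        "chrom": G.chrom,
        "pos": G.pos,
        "effect": tau,
        "se": se,
        "p": pval,
        "neglog10p": -np.log10(pval),
    })
    res.attrs["sigma_u2"] = su2
    res.attrs["sigma_e2"] = se2
    res.attrs["gamma"] = gamma
    return res


def _align_response(blues, family_ids) -> np.ndarray:
    from .pheno_mixed import BlueResult

    if isinstance(blues, BlueResult):
        y = blues.aligned(family_ids)
    elif isinstance(blues, pd.Series):
        y = blues.reindex(list(family_ids)).to_numpy(float)
    else:
        y = np.asarray(blues, dtype=float)
        if y.shape != (len(family_ids),):
            raise ValueError("response length does not match families")
    if np.isnan(y).any():
        raise ValueError("response contains missing values after alignment to families")
    return y


def select_top_snps(res: pd.DataFrame, n: int = 50) -> list[str]:
    """Top ``n`` markers by descending -log10 p; ties broken by (chrom, pos)."""
    if n > len(res):
        raise ValueError("n exceeds the number of tested markers")
    order = np.lexsort((res["pos"].to_numpy(), res["chrom"].to_numpy(),
                        -res["neglog10p"].to_numpy()))
    return [res["marker"].iloc[i] for i in order[:n]]


# ---------------------------------------------------------------------------
# PVE decomposition
# ---------------------------------------------------------------------------

def pve_multiple_regression(
    blues,
    G: GenotypeMatrix,
    snps: list[str],
    ss_total: str = "corrected",
) -> pd.DataFrame:
    """Sequential (Type-I) sum-of-squares PVE from one multiple regression.

    The BLUEs are regressed on all selected markers jointly, in the given
    order; each marker's SS_reg is its sequential increment and PVE_j =
    SS_reg_j / SS_tol.  ``ss_total`` chooses the denominator: ``"corrected"``
    (default) uses the total corrected SS of the response, ``"model"`` the
    model SS of the joint regression.  Aliased (collinear) markers are dropped
    with a warning.
    """
    y = _align_response(blues, G.family_ids)
    if len(snps) >= len(y):
        raise ValueError("need fewer selected markers than families")
    if ss_total not in ("corrected", "model"):
        raise ValueError("ss_total must be 'corrected' or 'model'")
    idx = G.marker_index(snps)
    Xs = G.codes[:, idx]
    n = len(y)
    ss_tol = float(np.sum((y - y.mean()) ** 2))

    # sequential orthogonalization (modified Gram-Schmidt against fitted columns)
    basis = [np.ones(n) / np.sqrt(n)]
    rows = []
    kept = []
    for name, x in zip(snps, Xs.T):
        v = x.astype(float).copy()
        for b in basis:
            v -= (b @ v) * b
        nv = np.linalg.norm(v)
        if nv < 1e-8 * max(1.0, np.linalg.norm(x)):
            logger.warning("marker %s is aliased with earlier columns; dropped from PVE", name)
            continue
        v /= nv
        basis.append(v)
        kept.append(name)
        rows.append(float((v @ y) ** 2))  # sequential SS increment
    ss_model = float(np.sum(rows))
    denom = ss_tol if ss_total == "corrected" else max(ss_model, 1e-300)
    out = pd.DataFrame({
        "marker": kept,
        "ss_reg": rows,
        "pve": [r / denom if denom > 0 else np.nan for r in rows],
    })
    out.attrs["ss_tol"] = ss_tol
    out.attrs["ss_model"] = ss_model
    return out
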