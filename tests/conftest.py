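import numpy as np
import pandas as pd
import pytest

import gsfix as gx


@pytest.fixture(scope="session")
def genome_map_small():
    return gx.GenomeMap.default(n_chromosomes=5, markers_per_chromosome=40)


@pytest.fixture(scope="session")
def pop150(genome_map_small):
    """150 BC1F3 plants on a 5-chromosome map (shared across tests)."""
    scheme = gx.CrossingScheme(n_bc1f3=150)
    return gx.simulate_cross(genome_map_small, scheme, seed=101)


@pytest.fixture(scope="session")
def trait_pheno(pop150):
    """Two-environment trait with one large and two minor QTL."""
    arch = gx.TraitArchitecture(
        qtl=[(80, 0.9), (150, 0.35), (177, 0.3)],
        env_means=(70.0, 72.0), gxe_sd=0.15, rep_sd=0.2, resid_sd=0.9,
    )
    return gx.simulate_trait(pop150, arch, n_envs=2, n_reps=2, seed=55)


@pytest.fixture(scope="session")
def blues150(trait_pheno):
    return gx.fit_blue_model(trait_pheno)


def balanced_phenotypes(f=60, E=3, r=2, sg=2.0, senv=1.5, sge=0.8, srep=0.5,
                        se=1.0, seed=7, mu=10.0):
    """Balanced random-effects data cube plus its long-format table."""
    rng = np.random.default_rng(seed)
    g = rng.normal(0, sg, f)
    e = rng.normal(0, senv, E)
    ge = rng.normal(0, sge, (f, E))
    rep = rng.normal(0, srep, (E, r))
    eps = rng.normal(0, se, (f, E, r))
    y = mu + g[:, None, None] + e[None, :, None] + ge[:, :, None] + rep[None, :, :] + eps
    recs = [
        dict(family=f"F{i:03d}", env=f"E{j}", rep=f"r{m}", value=y[i, j, m])
        for i in range(f) for j in range(E) for m in range(r)
    ]
    return gx.PhenotypeTable(pd.DataFrame(recs)), y


def anova_ems_components(y: np.ndarray) -> dict:
    """Method-of-moments variance components from the balanced ANOVA table.

    Independent oracle: orthogonal sums of squares of the f x E x r data cube
    and the classical expected-mean-square equations.
    """
    f, E, r = y.shape
    gbar = y.mean()
    yg = y.mean(axis=(1, 2))
    ye = y.mean(axis=(0, 2))
    yge = y.mean(axis=2)
    yer = y.mean(axis=0)
    MS_G = E * r * np.sum((yg - gbar) ** 2) / (f - 1)
    MS_E = f * r * np.sum((ye - gbar) ** 2) / (E - 1)
    MS_GE = r * np.sum((yge - yg[:, None] - ye[None, :] + gbar) ** 2) / ((f - 1) * (E - 1))
    MS_rep = f * np.sum((yer - ye[:, None]) ** 2) / (E * (r - 1))
    MS_res = np.sum(
        (y - yge[:, :, None] - yer[None, :, :] + ye[None, :, None]) ** 2
    ) / ((f - 1) * E * (r - 1))
    e = MS_res
    rep = (MS_rep - MS_res) / f
    ge = (MS_GE - MS_res) / r
    g = (MS_G - MS_GE) / (E * r)
    env = (MS_E - MS_res - f * rep - r * ge) / (f * r)
    return {"g": g, "ge": ge, "rep": rep, "e": e, "env": env}
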