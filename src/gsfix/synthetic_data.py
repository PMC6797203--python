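"""Simulation of a maize BC1F3:4 backcross-self population and its trait.

The crossing scheme emulated here: an F1 between a donor line (Zheng58) and a
recurrent line (PH4CV) is backcrossed to the recurrent parent to give BC1F1
plants; each BC1F1 is pollinated with bulked pollen from the other BC1F1
plants ("bulk-BC1F2"); a fixed number of plants per bulk-BC1F2 family is
selfed once, and BC1F3 plants are grown from the resulting ears.  Phenotyped
material is the selfed (BC1F3:4) family of each genotyped BC1F3 plant; family
phenotypes are generated from the BC1F3 parent genotype, with within-family
segregation folded into the residual.

Meiosis follows the Haldane model: the crossover count on a chromosome is
Poisson with mean equal to its genetic length in Morgans and breakpoints are
uniform (no interference).  Under this pedigree the single-locus expectation
for a BC1F3 plant is 21/32 recurrent homozygote, 6/32 heterozygote, 5/32
donor homozygote (donor-allele frequency 1/4 in BC1F1, random union, one
selfing halving heterozygosity).

Genotypes are coded +1 (homozygous recurrent, PH4CV), 0 (heterozygous),
-1 (homozygous donor, Zheng58); missing is NaN internally and "NA" on disk.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pheno_mixed import PhenotypeTable

logger = logging.getLogger("gsfix.synthetic_data")

__all__ = [
    "ChromosomeMap",
    "GenomeMap",
    "CrossingScheme",
    "TraitArchitecture",
    "GenotypeMatrix",
    "simulate_cross",
    "simulate_trait",
    "genotype_composition",
    "inject_missingness",
    "EXPECTED_BC1F3_PROPORTIONS",
]

#: exact single-locus genotype-class expectation for a BC1F3 plant
#: (recurrent homozygote, heterozygote, donor homozygote)
EXPECTED_BC1F3_PROPORTIONS = (21.0 / 32.0, 6.0 / 32.0, 5.0 / 32.0)

MARKER_ID_RE = re.compile(r"^chr(\d+)_(\d+)$", re.IGNORECASE)


def parse_marker_id(marker_id: str) -> tuple[int, int]:
    """Parse a ``chrN_position`` marker ID into (chromosome, 1-based bp)."""
    m = MARKER_ID_RE.match(marker_id)
    if not m:
        raise ValueError(f"malformed marker ID {marker_id!r}; expected 'chrN_pos'")
    return int(m.group(1)), int(m.group(2))


# ---------------------------------------------------------------------------
# genome map and scheme
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChromosomeMap:
    """One chromosome: genetic length (Morgans), physical length (bp), marker bp positions."""

    chrom: int
    length_morgans: float
    length_bp: int
    positions_bp: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions_bp, dtype=np.int64)
        object.__setattr__(self, "positions_bp", pos)
        if self.length_morgans <= 0 or self.length_bp <= 0:
            raise ValueError("chromosome lengths must be positive")
        if pos.size < 1:
            raise ValueError(f"chromosome {self.chrom} has no markers")
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"marker positions on chromosome {self.chrom} must be strictly increasing")
        if pos[0] < 1 or pos[-1] > self.length_bp:
            raise ValueError("marker positions outside the chromosome")

    @property
    def genetic_positions(self) -> np.ndarray:
        """Marker positions in Morgans, by linear bp<->cM interpolation."""
        return self.positions_bp / self.length_bp * self.length_morgans

    @property
    def marker_ids(self) -> list[str]:
        return [f"chr{self.chrom}_{p}" for p in self.positions_bp]


@dataclass(frozen=True)
class GenomeMap:
    chromosomes: tuple[ChromosomeMap, ...]

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("empty genome map")
        object.__setattr__(self, "chromosomes", tuple(self.chromosomes))

    @property
    def n_markers(self) -> int:
        return int(sum(c.positions_bp.size for c in self.chromosomes))

    @property
    def marker_ids(self) -> list[str]:
        out: list[str] = []
        for c in self.chromosomes:
            out.extend(c.marker_ids)
        return out

    @classmethod
    def default(
        cls,
        n_chromosomes: int = 10,
        markers_per_chromosome: int = 200,
        length_morgans: float = 1.8,
        length_bp: int = 200_000_000,
    ) -> "GenomeMap":
        """Evenly spaced dense map; 10 chromosomes of 1.8 M each by default."""
        chroms = []
        for c in range(1, n_chromosomes + 1):
            pos = np.linspace(1, length_bp, markers_per_chromosome).astype(np.int64)
            pos = np.unique(pos)
            chroms.append(ChromosomeMap(c, length_morgans, length_bp, pos))
        return cls(tuple(chroms))


@dataclass(frozen=True)
class CrossingScheme:
    """Backcross-self pedigree sizes (defaults follow the emulated population)."""

    recurrent: str = "PH4CV"
    donor: str = "Zheng58"
    n_bc1f2_families: int = 43
    n_selfed_per_family: int = 3
    n_bc1f3: int = 481
    pollen_bulk_size: int = 10
    ear_capacity: int = 50  # BC1F3 plants obtainable per selfed BC1F2 ear

    def __post_init__(self) -> None:
        for name in ("n_bc1f2_families", "n_selfed_per_family", "n_bc1f3", "ear_capacity"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.pollen_bulk_size < 10:
            raise ValueError("pollen_bulk_size must be >= 10 (bulked pollen)")
        capacity = self.n_bc1f2_families * self.n_selfed_per_family * self.ear_capacity
        if self.n_bc1f3 > capacity:
            raise ValueError("n_bc1f3 exceeds ear capacity of the scheme")


@dataclass(frozen=True)
class TraitArchitecture:
    """Additive trait: QTL effects, environment means, GxE / replicate / residual noise.

    ``qtl`` is a sequence of (marker index, additive effect in trait units);
    heterozygotes (code 0) contribute zero additive value.  ``gxe_sd`` is the
    per-QTL scale of environment-specific effect deviations, drawn once per
    (QTL, environment) and shared across replicates.  If ``target_h2`` is set,
    the residual standard deviation is solved from the entry-mean heritability
    formula given the realized genetic and GxE variances.
    """

    qtl: tuple = ()
    env_means: tuple = (0.0,)
    gxe_sd: float = 0.0
    rep_sd: float = 0.0
    resid_sd: float = 1.0
    target_h2: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "qtl", tuple((int(i), float(a)) for i, a in self.qtl))
        object.__setattr__(self, "env_means", tuple(float(v) for v in self.env_means))
        for name in ("gxe_sd", "rep_sd", "resid_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.target_h2 is not None and not (0.0 < self.target_h2 < 1.0):
            raise ValueError("target_h2 must lie in (0, 1)")


# ---------------------------------------------------------------------------
# genotype matrix
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Families x markers in {-1, 0, +1, NaN}; +1 = recurrent (PH4CV) homozygote."""

    family_ids: list[str]
    marker_ids: list[str]
    codes: np.ndarray
    bc1f2_family: list[str] | None = None  # pedigree family label per plant
    _chrom: np.ndarray = field(init=False, repr=False)
    _pos: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.shape != (len(self.family_ids), len(self.marker_ids)):
            raise ValueError("codes shape does not match ID lists")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("marker IDs are not unique")
        # note: imputed matrices may hold fractional codes; strict {-1,0,1}
        # validation happens at read time (io_cli), not here
        parsed = [parse_marker_id(m) for m in self.marker_ids]
        self._chrom = np.array([c for c, _ in parsed], dtype=int)
        self._pos = np.array([p for _, p in parsed], dtype=np.int64)

    @property
    def n_families(self) -> int:
        return len(self.family_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def chrom(self) -> np.ndarray:
        return self._chrom

    @property
    def pos(self) -> np.ndarray:
        return self._pos

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.codes)

    def marker_index(self, marker_ids) -> np.ndarray:
        lookup = {m: i for i, m in enumerate(self.marker_ids)}
        try:
            return np.array([lookup[m] for m in marker_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown marker ID {exc.args[0]!r}") from None

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            family_ids=list(self.family_ids),
            marker_ids=[self.marker_ids[i] for i in keep],
            codes=self.codes[:, keep].copy(),
            bc1f2_family=self.bc1f2_family,
        )

    def subset_families(self, families) -> "GenotypeMatrix":
        lookup = {f: i for i, f in enumerate(self.family_ids)}
        idx = [lookup[f] for f in families]
        ped = [self.bc1f2_family[i] for i in idx] if self.bc1f2_family else None
        return GenotypeMatrix(
            family_ids=list(families),
            marker_ids=list(self.marker_ids),
            codes=self.codes[idx, :].copy(),
            bc1f2_family=ped,
        )


# ---------------------------------------------------------------------------
# meiosis and pedigree simulation
# ---------------------------------------------------------------------------

def _gamete(h1: np.ndarray, h2: np.ndarray, gpos: np.ndarray, length_m: float,
            rng: np.random.Generator) -> np.ndarray:
    """One recombinant gamete under the Haldane model (Poisson crossovers)."""
    start = int(rng.integers(2))
    n_cx = int(rng.poisson(length_m)) if length_m > 0 else 0
    if n_cx == 0:
        return (h1 if start == 0 else h2).copy()
    breaks = np.sort(rng.uniform(0.0, length_m, size=n_cx))
    seg = np.searchsorted(breaks, gpos, side="right")
    use_first = (start + seg) % 2 == 0
    return np.where(use_first, h1, h2)


class _Plant:
    """Diploid plant: per-chromosome haplotype pairs (1 = recurrent allele)."""

    __slots__ = ("haps",)

    def __init__(self, haps: list[tuple[np.ndarray, np.ndarray]]):
        self.haps = haps

    def gamete(self, gmap: GenomeMap, rng: np.random.Generator) -> list[np.ndarray]:
        return [
            _gamete(h1, h2, c.genetic_positions, c.length_morgans, rng)
            for (h1, h2), c in zip(self.haps, gmap.chromosomes)
        ]

    @classmethod
    def from_gametes(cls, g1: list[np.ndarray], g2: list[np.ndarray]) -> "_Plant":
        return cls([(a, b) for a, b in zip(g1, g2)])

    def codes(self) -> np.ndarray:
        return np.concatenate([h1 + h2 - 1.0 for h1, h2 in self.haps])


def simulate_cross(gmap: GenomeMap, scheme: CrossingScheme, seed: int) -> GenotypeMatrix:
    """Simulate BC1F3 genotypes through F1 -> BC1F1 -> bulk-BC1F2 -> one selfing.

    The pollen parent of each bulk-BC1F2 seed is drawn uniformly from the
    BC1F1 plants excluding the mother (bulked-pollen random mating).  BC1F3
    plants are assigned round-robin across the selfed BC1F2 ears so family
    structure is balanced; the pedigree family of each plant is recorded.
    """
    rng = np.random.default_rng(seed)
    ones = [np.ones(c.positions_bp.size) for c in gmap.chromosomes]
    zeros = [np.zeros(c.positions_bp.size) for c in gmap.chromosomes]
    f1 = _Plant([(o, z) for o, z in zip(ones, zeros)])

    n_fam = scheme.n_bc1f2_families
    bc1f1 = [
        _Plant.from_gametes(f1.gamete(gmap, rng), [o.copy() for o in ones])
        for _ in range(n_fam)
    ]

    bc1f2: list[tuple[int, _Plant]] = []
    for fam in range(n_fam):
        mother = bc1f1[fam]
        for _ in range(scheme.n_selfed_per_family):
            if n_fam > 1:
                father_idx = int(rng.integers(n_fam - 1))
                if father_idx >= fam:
                    father_idx += 1  # exclude selfing at the intermating step
            else:
                father_idx = fam
            egg = mother.gamete(gmap, rng)
            sperm = bc1f1[father_idx].gamete(gmap, rng)
            bc1f2.append((fam, _Plant.from_gametes(egg, sperm)))

    n = scheme.n_bc1f3
    rows = np.empty((n, gmap.n_markers))
    fam_labels: list[str] = []
    for i in range(n):
        fam, parent = bc1f2[i % len(bc1f2)]
        plant = _Plant.from_gametes(parent.gamete(gmap, rng), parent.gamete(gmap, rng))
        rows[i] = plant.codes()
        fam_labels.append(f"F{fam + 1:02d}")

    family_ids = [f"BC1F3_{i + 1:04d}" for i in range(n)]
    return GenotypeMatrix(
        family_ids=family_ids,
        marker_ids=gmap.marker_ids,
        codes=rows,
        bc1f2_family=fam_labels,
    )


# ---------------------------------------------------------------------------
# composition, missingness, trait
# ---------------------------------------------------------------------------

def genotype_composition(G: GenotypeMatrix) -> tuple[pd.DataFrame, pd.Series]:
    """Per-plant and mean proportions of (recurrent hom, het, donor hom).

    Proportions are over non-missing markers and sum to 1 per plant.
    """
    if G.n_families == 0 or G.n_markers == 0:
        raise ValueError("empty genotype matrix")
    obs = ~np.isnan(G.codes)
    n_obs = obs.sum(axis=1)
    if np.any(n_obs == 0):
        bad = G.family_ids[int(np.argmin(n_obs))]
        raise ValueError(f"family {bad!r} has no observed markers")
    per = pd.DataFrame(
        {
            "recurrent_hom": np.nansum(G.codes == 1.0, axis=1) / n_obs,
            "het": np.nansum(G.codes == 0.0, axis=1) / n_obs,
            "donor_hom": np.nansum(G.codes == -1.0, axis=1) / n_obs,
        },
        index=pd.Index(G.family_ids, name="family"),
    )
    return per, per.mean()


def inject_missingness(G: GenotypeMatrix, rate: float, seed: int) -> GenotypeMatrix:
    """Set each entry missing independently with probability ``rate``."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("missingness rate must be in [0, 1)")
    codes = G.codes.copy()
    if rate > 0:
        rng = np.random.default_rng(seed)
        mask = rng.random(codes.shape) < rate
        codes[mask] = np.nan
    return GenotypeMatrix(
        family_ids=list(G.family_ids),
        marker_ids=list(G.marker_ids),
        codes=codes,
        bc1f2_family=G.bc1f2_family,
    )


def simulate_trait(
    G: GenotypeMatrix,
    arch: TraitArchitecture,
    n_envs: int,
    n_reps: int,
    seed: int,
    env_names: list[str] | None = None,
) -> PhenotypeTable:
    """Simulate y_ijm = env_mean_j + sum_q a_q g_iq + sum_q d_qj g_iq + delta_(j)m + eps.

    GxE deviations d_qj ~ N(0, gxe_sd^2) are drawn per (QTL, environment) and
    shared across replicates; replicate effects delta are drawn per
    (environment, replicate).  With ``target_h2`` set, the residual sd is
    solved from H^2 = s_g / (s_g + s_ge/Ne + s_e/(r Ne)) using the realized
    genetic and interaction variances of the simulated population.
    """
    if n_envs < 1 or n_reps < 1:
        raise ValueError("n_envs and n_reps must be >= 1")
    for idx, _ in arch.qtl:
        if not 0 <= idx < G.n_markers:
            raise ValueError(f"QTL marker index {idx} out of range")
    if env_names is None:
        env_names = [f"E{j + 1}" for j in range(n_envs)]
    if len(env_names) != n_envs:
        raise ValueError("env_names length must equal n_envs")
    env_means = np.asarray(arch.env_means, dtype=float)
    if env_means.size == 1:
        env_means = np.repeat(env_means, n_envs)
    if env_means.size != n_envs:
        raise ValueError("env_means length must equal n_envs (or be scalar)")

    rng = np.random.default_rng(seed)
    n = G.n_families
    q_idx = np.array([i for i, _ in arch.qtl], dtype=int)
    q_eff = np.array([a for _, a in arch.qtl], dtype=float)
    gq = np.nan_to_num(G.codes[:, q_idx], nan=0.0) if q_idx.size else np.zeros((n, 0))
    additive = gq @ q_eff if q_idx.size else np.zeros(n)

    d = rng.normal(0.0, arch.gxe_sd, size=(q_idx.size, n_envs)) if q_idx.size else np.zeros((0, n_envs))
    inter = gq @ d  # (n, n_envs)

    resid_sd = arch.resid_sd
    if arch.target_h2 is not None:
        # realized variance components of the simulated genetic architecture
        s_g = float(np.var(additive + inter.mean(axis=1)))
        dev = inter - inter.mean(axis=1, keepdims=True)
        dev = dev - dev.mean(axis=0, keepdims=True)
        s_ge = float(np.var(dev))
        h2 = arch.target_h2
        s_e = n_reps * n_envs * s_g * (1.0 / h2 - 1.0) - n_reps * s_ge
        if s_e <= 0:
            raise ValueError(
                "target_h2 unattainable: GxE variance alone already exceeds the target"
            )
        resid_sd = float(np.sqrt(s_e))

    delta = rng.normal(0.0, arch.rep_sd, size=(n_envs, n_reps))
    recs = []
    for j in range(n_envs):
        for m in range(n_reps):
            eps = rng.normal(0.0, resid_sd, size=n)
            y = env_means[j] + additive + inter[:, j] + delta[j, m] + eps
            recs.append(pd.DataFrame({
                "family": G.family_ids,
                "env": env_names[j],
                "rep": f"r{m + 1}",
                "value": y,
            }))
    return PhenotypeTable(pd.concat(recs, ignore_index=True))
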