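"""Founder genomes, trait architecture and gamete transmission.

The simulated genome consists of biallelic sites on a fixed genetic map,
split into neutral SNP markers (used for genomic relationships) and QTL
(which carry additive effects).  Founder haplotypes are drawn site-wise
from a configurable allele-frequency spectrum; descendants are produced by
Mendelian transmission with Poisson-distributed crossovers (Haldane model,
no interference).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# genome map


@dataclass(frozen=True)
class GenomeMap:
    """Genetic map of SNP and QTL positions (Morgan) per chromosome.

    Positions must be strictly increasing within a chromosome and the SNP
    and QTL position sets are disjoint.  Sites on a chromosome are the
    merged, sorted union of SNP and QTL positions.
    """

    snp_positions: tuple[np.ndarray, ...]
    qtl_positions: tuple[np.ndarray, ...]
    chromosome_length: float = 1.0

    def __post_init__(self):
        if len(self.snp_positions) != len(self.qtl_positions):
            raise ValueError("per-chromosome SNP and QTL lists differ in length")
        for snp, qtl in zip(self.snp_positions, self.qtl_positions):
            for pos in (snp, qtl):
                if np.any(np.diff(pos) <= 0):
                    raise ValueError("positions must be strictly increasing")
                if pos.size and (pos[0] < 0 or pos[-1] > self.chromosome_length):
                    raise ValueError("position outside chromosome")
            if np.intersect1d(snp, qtl).size:
                raise ValueError("SNP and QTL positions overlap")

    @property
    def n_chromosomes(self) -> int:
        return len(self.snp_positions)

    @property
    def site_positions(self) -> tuple[np.ndarray, ...]:
        """Merged SNP+QTL positions per chromosome."""
        return tuple(
            np.sort(np.concatenate([s, q]))
            for s, q in zip(self.snp_positions, self.qtl_positions)
        )

    @property
    def n_sites(self) -> int:
        return sum(s.size + q.size for s, q in zip(self.snp_positions, self.qtl_positions))

    @property
    def n_snps(self) -> int:
        return sum(s.size for s in self.snp_positions)

    @property
    def n_qtl(self) -> int:
        return sum(q.size for q in self.qtl_positions)

    def _global_indices(self, which: str) -> np.ndarray:
        """Global site indices (over concatenated chromosomes) of SNPs or QTL."""
        out = []
        offset = 0
        for snp, qtl, sites in zip(self.snp_positions, self.qtl_positions, self.site_positions):
            sel = snp if which == "snp" else qtl
            out.append(offset + np.searchsorted(sites, sel))
            offset += sites.size
        return np.concatenate(out).astype(np.intp)

    @property
    def snp_indices(self) -> np.ndarray:
        return self._global_indices("snp")

    @property
    def qtl_indices(self) -> np.ndarray:
        return self._global_indices("qtl")

    @classmethod
    def uniform(cls, n_chromosomes: int = 10, snps_per_chromosome: int = 5000,
                qtl_per_chromosome: int = 1000, chromosome_length: float = 1.0) -> "GenomeMap":
        """Evenly spaced sites, QTL interleaved evenly among the SNPs.

        The default 10 chromosomes of 1 Morgan with 5000 SNP + 1000 QTL each
        mirror a cattle-scale genome.
        """
        n_sites = snps_per_chromosome + qtl_per_chromosome
        sites = (np.arange(n_sites) + 0.5) / n_sites * chromosome_length
        qtl_idx = np.round(np.linspace(0, n_sites - 1, qtl_per_chromosome)).astype(int)
        qtl_mask = np.zeros(n_sites, dtype=bool)
        qtl_mask[qtl_idx] = True
        snp = tuple(sites[~qtl_mask].copy() for _ in range(n_chromosomes))
        qtl = tuple(sites[qtl_mask].copy() for _ in range(n_chromosomes))
        return cls(snp_positions=snp, qtl_positions=qtl,
                   chromosome_length=chromosome_length)


@dataclass(frozen=True)
class HaplotypePair:
    """The two haploid allele vectors of one individual over all sites."""

    maternal: np.ndarray
    paternal: np.ndarray

    def __post_init__(self):
        if self.maternal.shape != self.paternal.shape:
            raise ValueError("haplotype length mismatch")
        for h in (self.maternal, self.paternal):
            if not np.isin(h, (0, 1)).all():
                raise ValueError("alleles must be 0/1")

    @property
    def dosage(self) -> np.ndarray:
        return self.maternal.astype(np.int16) + self.paternal


@dataclass
class TraitArchitecture:
    """Additive trait: QTL allele-substitution effects and heritabilities.

    ``h2_cow``/``h2_bull`` control the precision of the phenotypes used for
    bull assignment (more information per bull than per cow), and
    ``target_tbv_variance`` is the genetic variance the phenotyped cohort is
    rescaled to.
    """

    qtl_effects: np.ndarray
    h2_cow: float = 0.3
    h2_bull: float = 0.8
    target_tbv_variance: float = 0.1

    def __post_init__(self):
        for h2 in (self.h2_cow, self.h2_bull):
            if not 0 < h2 < 1:
                raise ValueError("heritability must be in (0, 1)")

    @classmethod
    def sample(cls, gmap: GenomeMap, rng: np.random.Generator, **kw) -> "TraitArchitecture":
        """Draw standard-normal allele-substitution effects for every QTL."""
        return cls(qtl_effects=rng.standard_normal(gmap.n_qtl), **kw)


@dataclass
class FounderPopulation:
    """Founder haplotypes plus the map and target frequencies they were drawn at.

    ``haplotypes`` has shape ``(n_founders, 2, n_sites)`` with entries in {0, 1}.
    """

    haplotypes: np.ndarray
    gmap: GenomeMap
    site_frequencies: np.ndarray = field(repr=False, default=None)

    @property
    def n_founders(self) -> int:
        return self.haplotypes.shape[0]

    def pair(self, i: int) -> HaplotypePair:
        return HaplotypePair(maternal=self.haplotypes[i, 0], paternal=self.haplotypes[i, 1])


# ---------------------------------------------------------------------------
# founder simulation


def simulate_founders(n_founders: int, gmap: GenomeMap, seed,
                      freq_spectrum=(0.5, 0.5), backend: str = "beta",
                      max_resample: int = 100) -> FounderPopulation:
    """Simulate founder haplotypes with every site segregating.

    The default backend draws a per-site allele frequency from a U-shaped
    Beta(``freq_spectrum``) spectrum and founder alleles as independent
    Bernoulli draws, so founders are exchangeable and sites independent.
    ``backend="coalescent"`` instead takes segregating sites from an
    msprime coalescent simulation (one tree sequence per chromosome), which
    adds linkage disequilibrium at extra cost.

    Sites that come out monomorphic in the finite founder sample are
    redrawn up to ``max_resample`` times; persistent failure raises.
    """
    if n_founders < 2:
        raise ValueError("need at least 2 founders")
    if gmap.n_sites <= 0:
        raise ValueError("genome map has no sites")
    rng = np.random.default_rng(seed)
    if backend == "coalescent":
        return _simulate_founders_msprime(n_founders, gmap, rng)
    if backend != "beta":
        raise ValueError(f"unknown founder backend {backend!r}")

    a, b = freq_spectrum
    n_sites = gmap.n_sites
    freqs = rng.beta(a, b, size=n_sites)
    haps = (rng.random((n_founders, 2, n_sites)) < freqs).astype(np.uint8)
    for _ in range(max_resample):
        counts = haps.sum(axis=(0, 1))
        bad = (counts == 0) | (counts == 2 * n_founders)
        if not bad.any():
            break
        freqs[bad] = rng.beta(a, b, size=int(bad.sum()))
        haps[:, :, bad] = (rng.random((n_founders, 2, int(bad.sum()))) < freqs[bad]).astype(np.uint8)
    else:
        raise RuntimeError(
            f"{int(bad.sum())} sites failed to segregate after {max_resample} resampling rounds"
        )
    return FounderPopulation(haplotypes=haps, gmap=gmap, site_frequencies=freqs)


def _simulate_founders_msprime(n_founders: int, gmap: GenomeMap,
                               rng: np.random.Generator) -> FounderPopulation:
    """Coalescent founder backend: sample segregating sites from msprime."""
    import msprime  # optional backend

    sites_per_chr = [s.size for s in gmap.site_positions]
    haps = np.empty((n_founders, 2, gmap.n_sites), dtype=np.uint8)
    offset = 0
    for n_sites in sites_per_chr:
        seed_anc, seed_mut = rng.integers(1, 2**31 - 1, size=2)
        ts = msprime.sim_ancestry(
            samples=n_founders, population_size=10_000, sequence_length=1e8,
            recombination_rate=1e-8, random_seed=int(seed_anc))
        mts = msprime.sim_mutations(ts, rate=2e-9, random_seed=int(seed_mut),
                                    model=msprime.BinaryMutationModel())
        gm = mts.genotype_matrix()  # (variants, 2*n_founders)
        seg = np.flatnonzero((gm.sum(axis=1) > 0) & (gm.sum(axis=1) < 2 * n_founders))
        if seg.size < n_sites:
            raise RuntimeError("coalescent backend produced too few segregating sites")
        pick = np.sort(rng.choice(seg, size=n_sites, replace=False))
        block = gm[pick].T.reshape(n_founders, 2, n_sites)
        haps[:, :, offset:offset + n_sites] = np.minimum(block, 1).astype(np.uint8)
        offset += n_sites
    return FounderPopulation(haplotypes=haps, gmap=gmap, site_frequencies=None)


# ---------------------------------------------------------------------------
# breeding values and phenotypes


def true_breeding_value(individual: HaplotypePair, arch: TraitArchitecture,
                        gmap: GenomeMap) -> float:
    """TBV of one individual: QTL dosage dotted with substitution effects."""
    dosage = individual.dosage[gmap.qtl_indices]
    return float(dosage @ arch.qtl_effects)


def true_breeding_values(haplotypes: np.ndarray, arch: TraitArchitecture,
                         gmap: GenomeMap) -> np.ndarray:
    """Vectorised TBV over ``(n, 2, n_sites)`` haplotypes."""
    dosage = haplotypes[:, 0, gmap.qtl_indices].astype(np.float64) \
        + haplotypes[:, 1, gmap.qtl_indices]
    return dosage @ arch.qtl_effects


def founder_phenotypes(tbvs: np.ndarray, sex: np.ndarray, arch: TraitArchitecture,
                       seed) -> np.ndarray:
    """Selection phenotypes: TBV plus sex-specific environmental noise.

    Noise variance is sigma_g^2 (1 - h^2) / h^2 at the realised TBV variance,
    so the phenotype has the requested heritability for each sex; the
    regression of phenotype on TBV is 1 in expectation.
    """
    rng = np.random.default_rng(seed)
    tbvs = np.asarray(tbvs, dtype=float)
    sex = np.asarray(sex)
    var_g = tbvs.var()
    if var_g <= 0:
        raise ValueError("TBV variance must be positive")
    h2 = np.where(sex == "M", arch.h2_bull, arch.h2_cow)
    noise_sd = np.sqrt(var_g * (1.0 - h2) / h2)
    return tbvs + rng.standard_normal(tbvs.size) * noise_sd


# ---------------------------------------------------------------------------
# meiosis


def meiosis(parent: HaplotypePair, gmap: GenomeMap, seed) -> np.ndarray:
    """One gamete from one parent (convenience wrapper over :func:`make_gametes`)."""
    haps = np.stack([parent.maternal, parent.paternal])[None]
    return make_gametes(haps, gmap, np.random.default_rng(seed))[0]


def make_gametes(haplotypes: np.ndarray, gmap: GenomeMap,
                 rng: np.random.Generator) -> np.ndarray:
    """One gamete per parent, shape ``(n, n_sites)``.

    Per chromosome: crossover count ~ Poisson(length in Morgan), crossover
    positions uniform, starting haplotype chosen at random; chromosomes
    assort independently.  With zero length the gamete is an intact copy of
    one haplotype.
    """
    n = haplotypes.shape[0]
    out = np.empty((n, gmap.n_sites), dtype=haplotypes.dtype)
    offset = 0
    for sites in gmap.site_positions:
        n_sites = sites.size
        length = gmap.chromosome_length
        n_co = rng.poisson(length, size=n)
        max_co = int(n_co.max()) if n else 0
        start = rng.integers(0, 2, size=n)
        if max_co == 0:
            parity = np.broadcast_to(start[:, None], (n, n_sites))
        else:
            pos = rng.random((n, max_co)) * length
            valid = np.arange(max_co)[None, :] < n_co[:, None]
            pos = np.where(valid, pos, np.inf)
            # crossovers before each site flip the source haplotype
            n_before = (pos[:, :, None] < sites[None, None, :]).sum(axis=1)
            parity = (start[:, None] + n_before) % 2
        chrom = haplotypes[:, :, offset:offset + n_sites]
        out[:, offset:offset + n_sites] = np.take_along_axis(
            chrom, parity[:, None, :], axis=1)[:, 0, :]
        offset += n_sites
    return out


# ---------------------------------------------------------------------------
# genotype IO (whitespace dosage matrix + sidecar map)


def write_dosages(path, ids: np.ndarray, dosages: np.ndarray, gmap: GenomeMap,
                  map_path=None) -> None:
    """Write an animals x SNP dosage matrix with a marker-ID header row.

    First column is the animal id; markers are named ``chrC_snpJ``.  The
    optional sidecar map file holds chromosome, marker id and position.
    """
    names = [f"chr{c + 1}_snp{j + 1}"
             for c, snp in enumerate(gmap.snp_positions) for j in range(snp.size)]
    df = pd.DataFrame(dosages, columns=names)
    df.insert(0, "id", ids)
    df.to_csv(path, sep=" ", index=False)
    if map_path is not None:
        rows = [(c + 1, f"chr{c + 1}_snp{j + 1}", p)
                for c, snp in enumerate(gmap.snp_positions) for j, p in enumerate(snp)]
        pd.DataFrame(rows, columns=["chromosome", "marker", "position"]).to_csv(
            map_path, sep=" ", index=False)


def read_dosages(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a dosage matrix written by :func:`write_dosages` -> (ids, dosages)."""
    df = pd.read_csv(path, sep=r"\s+")
    ids = df["id"].to_numpy()
    return ids, df.drop(columns="id").to_numpy()
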