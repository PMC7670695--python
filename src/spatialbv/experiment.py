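"""Replicate studies over scenarios, models and genetic sources.

One replicate simulates a complete data set (founders, population,
spatial environment, phenotypes) and fits every requested model to that
same data set, so model comparisons are paired.  Results accumulate in a
tidy table (replicate, scenario, model, genetic_source, metric, value)
that :func:`aggregate` pivots into the mean ± s.e. layout of the study
tables.

Two problem-size profiles are provided: ``full_profile`` is the full study
condition (100 villages x 20 herds, 5000 SNP + 1000 QTL per chromosome),
and ``desk_profile`` is a reduced configuration (100 villages x 4 herds,
1000 SNP + 100 QTL per chromosome) that keeps a multi-model,
multi-replicate study tractable on a single CPU.
"""

from __future__ import annotations

import dataclasses
import sys
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import phenotypes as phen_mod
from .genomes import FounderPopulation, GenomeMap, TraitArchitecture, simulate_founders
from .inference import McmcConfig, ModelSpec, PosteriorSummary, build_model_data, fit
from .metrics import EvaluationReport, evaluate
from .population import (BreedingScenario, StudyData, layout,
                         run_study_population)
from .relatedness import RelationshipMatrix, genomic_G, pedigree_A
from .spatial import (SpatialEnvironment, observe_covariates,
                      simulate_environment, variance_partition)

MODELS = ("G", "GH", "GS", "GHS", "GHSC")
SOURCES = ("pedigree", "genomic")


def _log(msg: str) -> None:
    print(f"[spatialbv {time.strftime('%H:%M:%S')}] {msg}", file=sys.stderr)


@dataclass
class SimConfig:
    """All simulation parameters for one data set."""

    n_villages: int = 100
    herds_per_village: int = 20
    herd_size_lambda: float = 1.5
    location_variance: float = 3.5e-4
    n_founders: int = 5000
    n_chromosomes: int = 10
    snps_per_chromosome: int = 5000
    qtl_per_chromosome: int = 1000
    chromosome_length: float = 1.0
    h2_cow: float = 0.3
    h2_bull: float = 0.8
    sigma2_g: float = 0.1
    sigma2_h: float = 0.25
    sigma2_s: float = 0.4
    sigma2_e: float = 0.25
    n_generations: int = 12
    n_prediction: int = 200
    pedigree_from: int = 8
    founder_ranking: str = "tbv"
    bull_ranking: str = "phenotype"
    founder_backend: str = "beta"
    prop_spatial: float | None = None   # overrides sigma2_s/sigma2_h when set

    def resolved_variances(self) -> tuple[float, float]:
        if self.prop_spatial is None:
            return self.sigma2_s, self.sigma2_h
        return variance_partition(self.prop_spatial)

    def genome_map(self) -> GenomeMap:
        return GenomeMap.uniform(self.n_chromosomes, self.snps_per_chromosome,
                                 self.qtl_per_chromosome, self.chromosome_length)


def full_profile(**overrides) -> SimConfig:
    return dataclasses.replace(SimConfig(), **overrides)


def desk_profile(**overrides) -> SimConfig:
    """Reduced problem size for single-CPU multi-replicate studies.

    Keeps the full study's 100-village spatial resolution but cuts herds per
    village (4 instead of 20, ~790 records instead of ~3860) and marker
    density (1000 SNP + 100 QTL per chromosome).
    """
    base = SimConfig(n_villages=100, herds_per_village=4, n_founders=2000,
                     snps_per_chromosome=1000, qtl_per_chromosome=100,
                     n_prediction=100)
    return dataclasses.replace(base, **overrides)


def desk_mcmc(**overrides) -> McmcConfig:
    return dataclasses.replace(McmcConfig(n_iter=800, burn_in=300, thin=6),
                               **overrides)


@dataclass
class Dataset:
    """One simulated data set plus everything the models and metrics need."""

    study: StudyData
    spatial_env: SpatialEnvironment
    covariates: pd.DataFrame
    records: pd.DataFrame            # phenotype records with components
    config: SimConfig
    scenario: BreedingScenario

    @property
    def true_bv_obs(self) -> np.ndarray:
        return self._sorted(self.study.phenotyped)["tbv"].to_numpy()

    @property
    def true_bv_pred(self) -> np.ndarray:
        return self._sorted(self.study.prediction)["tbv"].to_numpy()

    @property
    def true_spatial_obs(self) -> np.ndarray:
        df = self._sorted(self.study.phenotyped)
        return self.spatial_env.total_effect[df["herd"].to_numpy() - 1]

    @staticmethod
    def _sorted(df: pd.DataFrame) -> pd.DataFrame:
        return df.sort_values("id")

    def checksum(self) -> float:
        """Stable fingerprint of the simulated phenotypes (pairing contract)."""
        return float(np.sum(self.records["y"].to_numpy() ** 2))


def simulate_dataset(config: SimConfig, connectedness: str, seed) -> Dataset:
    """Simulate one complete data set for one connectedness scenario.

    The master seed is split into named substreams (genome, layout,
    population, spatial, phenotype) so each stage is independently
    reproducible.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    s_genome, s_layout, s_pop, s_spatial, s_phen = ss.spawn(5)
    gmap = config.genome_map()
    founders = simulate_founders(config.n_founders, gmap, s_genome,
                                 backend=config.founder_backend)
    arch = TraitArchitecture.sample(
        gmap, np.random.default_rng(s_genome.spawn(1)[0]),
        h2_cow=config.h2_cow, h2_bull=config.h2_bull,
        target_tbv_variance=config.sigma2_g)
    lay = layout(config.n_villages, config.herds_per_village,
                 config.location_variance, config.herd_size_lambda, s_layout)
    scenario = BreedingScenario.for_connectedness(connectedness, config.n_villages)
    study = run_study_population(
        scenario, lay, founders, arch, s_pop,
        n_generations=config.n_generations, n_prediction=config.n_prediction,
        pedigree_from=config.pedigree_from,
        founder_ranking=config.founder_ranking, bull_ranking=config.bull_ranking)

    sigma2_s, sigma2_h = config.resolved_variances()
    rng_sp = np.random.default_rng(s_spatial)
    env = simulate_environment(lay.herd_coords, rng_sp, sigma_s2=sigma2_s)
    cov = observe_covariates(env, rng_sp)
    records = phen_mod.assemble(study.phenotyped, env, herd_var=sigma2_h,
                                resid_var=config.sigma2_e, seed=s_phen)
    return Dataset(study=study, spatial_env=env, covariates=cov,
                   records=records, config=config, scenario=scenario)


def relationship_for(dataset: Dataset, source: str) -> RelationshipMatrix:
    """K over phenotyped + prediction animals for one genetic source."""
    study = dataset.study
    order = np.concatenate([np.sort(study.phenotyped["id"].to_numpy()),
                            np.sort(study.prediction["id"].to_numpy())])
    if source == "pedigree":
        return pedigree_A(study.pedigree).submatrix(order)
    if source == "genomic":
        G = genomic_G(study.snp_dosages, ids=study.snp_ids, ridge=1e-6)
        return G.submatrix(order)
    raise ValueError(f"unknown genetic source {source!r}")


def fit_model(dataset: Dataset, model: str, source: str,
              mcmc: McmcConfig | None = None, seed=None,
              K: RelationshipMatrix | None = None) -> PosteriorSummary:
    """Fit one named model to one simulated data set."""
    spec = ModelSpec.named(model, genetic_source=source)
    if K is None:
        K = relationship_for(dataset, source)
    data = build_model_data(
        dataset.records[["id", "herd", "y"]], dataset.study.layout.herd_coords,
        K, dataset.study.prediction["id"].to_numpy(),
        covariate_table=dataset.covariates if spec.use_covariates else None)
    return fit(data, spec, mcmc=mcmc, seed=seed)


def _mcmc_for_model(base: McmcConfig, model: str) -> McmcConfig:
    """Shorter chains for the 2-3 hyper-parameter non-spatial models."""
    if "S" in model:
        return base
    return dataclasses.replace(base, n_iter=int(0.7 * base.n_iter),
                               burn_in=int(0.7 * base.burn_in))


@dataclass
class StudyConfig:
    """Grid of scenario cells for a replicate study."""

    connectedness: tuple = ("weak",)
    models: tuple = ("G", "GH", "GS", "GHS")
    sources: tuple = ("pedigree", "genomic")
    n_replicates: int = 5
    sim: SimConfig = field(default_factory=desk_profile)
    mcmc: McmcConfig = field(default_factory=desk_mcmc)
    base_seed: int = 2025

    def cell_seed(self, connectedness: str, replicate: int) -> np.random.SeedSequence:
        """Deterministic derived seed per grid cell."""
        code = {"weak": 1, "intermediate": 2, "strong": 3}[connectedness]
        return np.random.SeedSequence([self.base_seed, code, replicate])


def run_replicate(config: StudyConfig, connectedness: str,
                  replicate: int) -> pd.DataFrame:
    """Simulate one data set and fit all requested models to it (paired)."""
    ss = config.cell_seed(connectedness, replicate)
    s_data, s_chains = ss.spawn(2)
    t0 = time.time()
    dataset = simulate_dataset(config.sim, connectedness, s_data)
    _log(f"{connectedness} rep {replicate}: simulated "
         f"{len(dataset.records)} records in {time.time() - t0:.1f}s")
    frames = []
    chain_seeds = s_chains.spawn(len(config.sources) * len(config.models))
    i = 0
    for source in config.sources:
        K = relationship_for(dataset, source)
        for model in config.models:
            t0 = time.time()
            summary = fit_model(dataset, model, source,
                                mcmc=_mcmc_for_model(config.mcmc, model),
                                seed=chain_seeds[i], K=K)
            i += 1
            report = evaluate(summary, dataset.true_bv_obs, dataset.true_bv_pred,
                              dataset.true_spatial_obs)
            rows = report.rows(
                replicate=replicate, scenario=connectedness, model=model,
                genetic_source=source, dic=summary.dic,
                data_checksum=dataset.checksum())
            medians = summary.hyper_samples.median()
            extra = pd.DataFrame([
                dict(replicate=replicate, scenario=connectedness, model=model,
                     genetic_source=source, dic=summary.dic,
                     data_checksum=dataset.checksum(),
                     metric=f"median_{name}", value=val)
                for name, val in medians.items()])
            frames.append(pd.concat([rows, extra], ignore_index=True))
            _log(f"  {source:8s} {model:4s}: acc_ebv="
                 f"{report.accuracy_ebv:.3f} ({time.time() - t0:.1f}s)")
    return pd.concat(frames, ignore_index=True)


def run_study(config: StudyConfig) -> pd.DataFrame:
    """Run the full grid; results merge deterministically by (scenario, rep)."""
    frames = [run_replicate(config, conn, rep)
              for conn in config.connectedness
              for rep in range(config.n_replicates)]
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["scenario", "replicate", "genetic_source",
                            "model", "metric"]).reset_index(drop=True)


def aggregate(results: pd.DataFrame, metric: str | None = None) -> pd.DataFrame:
    """Mean ± s.e. by scenario x source x model, one column pair per scenario.

    Missing grid cells are reported (as NaN rows), never imputed.
    """
    df = results if metric is None else results[results["metric"] == metric]
    if df.empty:
        raise ValueError("no rows to aggregate")
    g = df.groupby(["metric", "genetic_source", "model", "scenario"])["value"]
    agg = g.agg(mean="mean", se=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0,
                n="count").reset_index()
    return agg.pivot_table(index=["metric", "genetic_source", "model"],
                           columns="scenario", values=["mean", "se"],
                           dropna=False)
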