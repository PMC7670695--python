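"""Village/herd geography and multi-generation smallholder breeding.

The simulated country is a unit square with villages placed uniformly and
herds scattered bivariate-normally around their village centre.  Herd sizes
are zero-truncated Poisson.  Genetic connectedness between villages is
controlled by the mating regime: every village its own natural-mating bull
(weak), 75% of herds on the village bull and the rest on a small national
AI pool (intermediate), or all cows mated to a large national AI pool
(strong).  Cows are replaced by their female calves; dams of male calves
are retained, which keeps herd sizes constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genomes import (FounderPopulation, GenomeMap, TraitArchitecture,
                      make_gametes, true_breeding_values)

SEX_MALE, SEX_FEMALE = "M", "F"


# ---------------------------------------------------------------------------
# geography


@dataclass
class HerdLayout:
    """Village centres, herd coordinates, herd-to-village map and herd sizes."""

    village_coords: np.ndarray      # (V, 2) in the unit square
    herd_coords: np.ndarray         # (H, 2)
    herd_to_village: np.ndarray     # (H,) village index per herd
    herd_sizes: np.ndarray          # (H,) positive counts
    location_variance: float = 3.5e-4

    def __post_init__(self):
        if np.any(self.herd_sizes < 1):
            raise ValueError("herd sizes must be >= 1")
        if not (np.isfinite(self.herd_coords).all()
                and np.isfinite(self.village_coords).all()):
            raise ValueError("coordinates must be finite")

    @property
    def n_villages(self) -> int:
        return self.village_coords.shape[0]

    @property
    def n_herds(self) -> int:
        return self.herd_coords.shape[0]

    @property
    def n_cows(self) -> int:
        return int(self.herd_sizes.sum())


def sample_herd_sizes(n_herds: int, lam: float = 1.5, seed=None) -> np.ndarray:
    """Zero-truncated Poisson(λ) herd sizes (mean λ/(1−e^−λ) ≈ 1.93 at λ=1.5)."""
    if lam <= 0:
        raise ValueError("lam must be positive")
    rng = np.random.default_rng(seed)
    sizes = rng.poisson(lam, size=n_herds)
    while True:
        zero = sizes == 0
        if not zero.any():
            return sizes
        sizes[zero] = rng.poisson(lam, size=int(zero.sum()))


def layout(n_villages: int = 100, herds_per_village: int = 20,
           location_variance: float = 3.5e-4, herd_size_lambda: float = 1.5,
           seed=None) -> HerdLayout:
    """Sample the full geography: village centres, herd coordinates, herd sizes.

    Village coordinates are U(0,1)²; herd coordinates are bivariate normal
    around the village centre with isotropic ``location_variance`` (reference
    levels: 1.0e-4 strong, 3.5e-4 intermediate, 9.0e-4 weak clustering).
    """
    if n_villages <= 0 or herds_per_village <= 0 or location_variance < 0:
        raise ValueError("layout parameters must be positive")
    rng = np.random.default_rng(seed)
    village = rng.uniform(0, 1, size=(n_villages, 2))
    herd_to_village = np.repeat(np.arange(n_villages), herds_per_village)
    herd = village[herd_to_village] + \
        rng.standard_normal((n_villages * herds_per_village, 2)) * np.sqrt(location_variance)
    sizes = sample_herd_sizes(n_villages * herds_per_village, herd_size_lambda, rng)
    return HerdLayout(village_coords=village, herd_coords=herd,
                      herd_to_village=herd_to_village, herd_sizes=sizes,
                      location_variance=location_variance)


# ---------------------------------------------------------------------------
# breeding scenarios


@dataclass(frozen=True)
class BreedingScenario:
    """Mating regime controlling genetic connectedness.

    ``n_primary_bulls`` (one per village at the weak/intermediate regimes,
    the national AI pool at the strong regime) plus ``n_extra_ai`` reserve
    AI bulls are assigned from the best males (110 total at full scale).
    """

    connectedness: str                  # weak | intermediate | strong
    n_primary_bulls: int = 100
    n_extra_ai: int = 10
    village_bull_fraction: float = 1.0  # fraction of herds on the village bull

    def __post_init__(self):
        if not 0 <= self.village_bull_fraction <= 1:
            raise ValueError("village_bull_fraction must be in [0, 1]")

    @property
    def uses_village_bulls(self) -> bool:
        return self.connectedness in ("weak", "intermediate")

    @property
    def n_village_bulls(self) -> int:
        return self.n_primary_bulls if self.uses_village_bulls else 0

    @property
    def n_ai_bulls(self) -> int:
        return self.n_extra_ai if self.uses_village_bulls else self.n_primary_bulls

    @property
    def n_bulls(self) -> int:
        return self.n_primary_bulls + self.n_extra_ai

    @classmethod
    def for_connectedness(cls, connectedness: str, n_villages: int = 100) -> "BreedingScenario":
        if connectedness == "weak":
            return cls("weak", n_primary_bulls=n_villages, village_bull_fraction=1.0)
        if connectedness == "intermediate":
            return cls("intermediate", n_primary_bulls=n_villages, village_bull_fraction=0.75)
        if connectedness == "strong":
            return cls("strong", n_primary_bulls=n_villages, village_bull_fraction=0.0)
        raise ValueError(f"unknown connectedness {connectedness!r}")


# ---------------------------------------------------------------------------
# population state


@dataclass
class Cohort:
    """Current cow population plus the service bulls."""

    cow_id: np.ndarray
    cow_herd: np.ndarray            # herd index (0-based)
    cow_gen: np.ndarray
    cow_tbv: np.ndarray
    cow_haps: np.ndarray            # (n, 2, n_sites) uint8
    village_bull_id: np.ndarray     # (V,) or empty
    village_bull_haps: np.ndarray
    ai_bull_id: np.ndarray
    ai_bull_haps: np.ndarray
    herd_is_ai: np.ndarray          # (H,) bool, fixed at scenario setup
    generation: int = 0

    @property
    def n_cows(self) -> int:
        return self.cow_id.size


@dataclass
class PedigreeRecorder:
    """Append-only pedigree with integer ids (0 = unknown parent)."""

    ids: list = field(default_factory=list)
    sires: list = field(default_factory=list)
    dams: list = field(default_factory=list)
    sexes: list = field(default_factory=list)
    generations: list = field(default_factory=list)
    herds: list = field(default_factory=list)
    _next: int = 1

    def register(self, n: int, sire, dam, sex, generation, herd) -> np.ndarray:
        new = np.arange(self._next, self._next + n)
        self._next += n
        self.ids.extend(new.tolist())
        for store, val in ((self.sires, sire), (self.dams, dam), (self.sexes, sex),
                          (self.generations, generation), (self.herds, herd)):
            store.extend(np.broadcast_to(np.asarray(val), (n,)).tolist())
        return new

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"id": self.ids, "sire": self.sires, "dam": self.dams,
                             "sex": self.sexes, "generation": self.generations,
                             "herd": self.herds})


def _rank_desc(values: np.ndarray, ids: np.ndarray) -> np.ndarray:
    """Indices sorted by descending value, ties broken by ascending id."""
    return np.lexsort((ids, -values))


def _selection_phenotype(tbv: np.ndarray, arch: TraitArchitecture,
                         rng: np.random.Generator) -> np.ndarray:
    """Bull-selection phenotype at bull heritability (h² = 0.8 by default)."""
    var_g = tbv.var()
    if var_g <= 0:
        return tbv.copy()
    noise_sd = np.sqrt(var_g * (1 - arch.h2_bull) / arch.h2_bull)
    return tbv + rng.standard_normal(tbv.size) * noise_sd


def assign_founders(founders: FounderPopulation, lay: HerdLayout,
                    scenario: BreedingScenario, arch: TraitArchitecture,
                    seed, recorder: PedigreeRecorder | None = None,
                    founder_ranking: str = "tbv") -> tuple[Cohort, PedigreeRecorder]:
    """Assign founder sexes, pick the best males as bulls, place cows in herds.

    Founder sex is Bernoulli(0.5).  The top ``scenario.n_bulls`` males —
    ranked by true breeding value by default, or by the bull-heritability
    phenotype with ``founder_ranking="phenotype"`` — become the service
    bulls; remaining females fill the herds uniformly at random and surplus
    cows are discarded.
    """
    rng = np.random.default_rng(seed)
    recorder = recorder or PedigreeRecorder()
    gmap = founders.gmap
    n = founders.n_founders
    sex = np.where(rng.random(n) < 0.5, SEX_MALE, SEX_FEMALE)
    tbv = true_breeding_values(founders.haplotypes, arch, gmap)

    males = np.flatnonzero(sex == SEX_MALE)
    females = np.flatnonzero(sex == SEX_FEMALE)
    if males.size < scenario.n_bulls:
        raise ValueError(
            f"need {scenario.n_bulls} bulls but only {males.size} founder males")
    if females.size < lay.n_cows:
        raise ValueError(
            f"need {lay.n_cows} founder cows but only {females.size} females")

    if founder_ranking == "phenotype":
        score = _selection_phenotype(tbv[males], arch, rng)
    elif founder_ranking == "tbv":
        score = tbv[males]
    else:
        raise ValueError(f"unknown founder_ranking {founder_ranking!r}")
    ranked_males = males[_rank_desc(score, males)]
    bulls = ranked_males[:scenario.n_bulls]
    primary, extra = bulls[:scenario.n_primary_bulls], bulls[scenario.n_primary_bulls:]
    if scenario.uses_village_bulls:
        village_idx, ai_idx = primary, extra
    else:
        village_idx, ai_idx = primary[:0], primary

    cows = rng.permutation(females)[:lay.n_cows]
    cow_herd = np.repeat(np.arange(lay.n_herds), lay.herd_sizes)

    # fixed at setup: which herds use AI under this scenario
    herd_is_ai = np.zeros(lay.n_herds, dtype=bool)
    if scenario.connectedness == "strong":
        herd_is_ai[:] = True
    elif scenario.village_bull_fraction < 1.0:
        n_ai_herds = int(round((1 - scenario.village_bull_fraction) * lay.n_herds))
        herd_is_ai[rng.choice(lay.n_herds, size=n_ai_herds, replace=False)] = True

    # register founders that enter the study population
    cow_ids = recorder.register(cows.size, 0, 0, SEX_FEMALE, 0,
                                cow_herd + 1)
    vb_ids = recorder.register(village_idx.size, 0, 0, SEX_MALE, 0, 0)
    ai_ids = recorder.register(ai_idx.size, 0, 0, SEX_MALE, 0, 0)

    haps = founders.haplotypes
    cohort = Cohort(cow_id=cow_ids, cow_herd=cow_herd,
                    cow_gen=np.zeros(cows.size, dtype=int),
                    cow_tbv=tbv[cows], cow_haps=haps[cows],
                    village_bull_id=vb_ids, village_bull_haps=haps[village_idx],
                    ai_bull_id=ai_ids, ai_bull_haps=haps[ai_idx],
                    herd_is_ai=herd_is_ai, generation=0)
    return cohort, recorder


def breed_generation(cohort: Cohort, scenario: BreedingScenario, lay: HerdLayout,
                     gmap: GenomeMap, arch: TraitArchitecture,
                     recorder: PedigreeRecorder, rng: np.random.Generator,
                     bull_ranking: str = "phenotype",
                     keep_male_haps: bool = False) -> Cohort | tuple:
    """One discrete generation: every cow has one calf, herds stay full.

    Female calves replace their dams in the same herd; dams of male calves
    are retained and re-bred.  Male calves become bull candidates for their
    herd's service type (village pool or AI pool) and the service bulls are
    refreshed from those candidates, ranked by the bull-heritability
    phenotype (or TBV with ``bull_ranking="tbv"``).
    """
    t = cohort.generation + 1
    n = cohort.n_cows
    herd_village = lay.herd_to_village

    # sire per cow
    use_ai = cohort.herd_is_ai[cohort.cow_herd]
    sire_slot = np.empty(n, dtype=int)           # index into the relevant pool
    sire_id = np.empty(n, dtype=int)
    if scenario.uses_village_bulls:
        vil = herd_village[cohort.cow_herd]
        sire_slot[~use_ai] = vil[~use_ai]
        sire_id[~use_ai] = cohort.village_bull_id[vil[~use_ai]]
    elif (~use_ai).any():
        raise RuntimeError("natural-mating herd but scenario has no village bulls")
    if use_ai.any():
        if cohort.ai_bull_id.size == 0:
            raise RuntimeError("AI-serviced herds but the AI bull pool is empty")
        draw = rng.integers(0, cohort.ai_bull_id.size, size=int(use_ai.sum()))
        sire_slot[use_ai] = draw
        sire_id[use_ai] = cohort.ai_bull_id[draw]

    sire_haps = np.empty_like(cohort.cow_haps)
    if scenario.uses_village_bulls and (~use_ai).any():
        sire_haps[~use_ai] = cohort.village_bull_haps[sire_slot[~use_ai]]
    if use_ai.any():
        sire_haps[use_ai] = cohort.ai_bull_haps[sire_slot[use_ai]]

    dam_gamete = make_gametes(cohort.cow_haps, gmap, rng)
    sire_gamete = make_gametes(sire_haps, gmap, rng)
    calf_haps = np.stack([dam_gamete, sire_gamete], axis=1)
    calf_sex = np.where(rng.random(n) < 0.5, SEX_MALE, SEX_FEMALE)
    calf_tbv = true_breeding_values(calf_haps, arch, gmap)
    calf_ids = recorder.register(n, sire_id, cohort.cow_id, calf_sex, t,
                                 cohort.cow_herd + 1)

    female = calf_sex == SEX_FEMALE
    # next cow population: female calves replace dams, other dams retained
    cow_id = np.where(female, calf_ids, cohort.cow_id)
    cow_gen = np.where(female, t, cohort.cow_gen)
    cow_tbv = np.where(female, calf_tbv, cohort.cow_tbv)
    cow_haps = np.where(female[:, None, None], calf_haps, cohort.cow_haps)

    # refresh service bulls from this generation's male calves
    male = ~female
    male_ids, male_tbv = calf_ids[male], calf_tbv[male]
    male_herd = cohort.cow_herd[male]
    male_haps = calf_haps[male]
    score = male_tbv if bull_ranking == "tbv" else \
        _selection_phenotype(male_tbv, arch, rng)

    vb_id, vb_haps = cohort.village_bull_id, cohort.village_bull_haps
    if scenario.uses_village_bulls:
        natural = ~cohort.herd_is_ai[male_herd]
        cand_village = herd_village[male_herd]
        vb_id, vb_haps = vb_id.copy(), vb_haps.copy()
        for v in range(lay.n_villages):
            if not cohort.herd_is_ai[herd_village == v].all():
                sel = natural & (cand_village == v)
                if not sel.any():
                    # no male calf this round: the sitting bull serves again
                    continue
                pick = np.flatnonzero(sel)[_rank_desc(score[sel], male_ids[sel])[0]]
                vb_id[v] = male_ids[pick]
                vb_haps[v] = male_haps[pick]

    ai_id, ai_haps = cohort.ai_bull_id, cohort.ai_bull_haps
    ai_cand = cohort.herd_is_ai[male_herd]
    if ai_cand.any() and cohort.ai_bull_id.size:
        k = min(cohort.ai_bull_id.size, int(ai_cand.sum()))
        order = np.flatnonzero(ai_cand)[_rank_desc(score[ai_cand], male_ids[ai_cand])[:k]]
        ai_id = male_ids[order]
        ai_haps = male_haps[order]

    out = Cohort(cow_id=cow_id, cow_herd=cohort.cow_herd, cow_gen=cow_gen,
                 cow_tbv=cow_tbv, cow_haps=cow_haps,
                 village_bull_id=vb_id, village_bull_haps=vb_haps,
                 ai_bull_id=ai_id, ai_bull_haps=ai_haps,
                 herd_is_ai=cohort.herd_is_ai, generation=t)
    if keep_male_haps:
        return out, (calf_ids[female], calf_tbv[female], calf_haps[female],
                     cohort.cow_herd[female])
    return out


# ---------------------------------------------------------------------------
# whole-study population run


@dataclass
class StudyData:
    """Training records, prediction cohort and supporting structures."""

    pedigree: pd.DataFrame          # generations >= pedigree_from only
    phenotyped: pd.DataFrame        # id, herd (1-based), tbv (rescaled)
    prediction: pd.DataFrame        # id, herd, tbv (rescaled, same affine map)
    snp_ids: np.ndarray             # phenotyped + prediction animal ids
    snp_dosages: np.ndarray         # aligned to snp_ids
    layout: HerdLayout
    tbv_shift: float                # raw -> scaled: (tbv - shift) * scale
    tbv_scale: float


def _ancestor_closure(ped: pd.DataFrame, keep: set, allowed: set) -> set:
    """Targets plus their ancestors, traversing only through ``allowed`` ids."""
    sire = dict(zip(ped["id"], ped["sire"]))
    dam = dict(zip(ped["id"], ped["dam"]))
    out, stack = set(), list(keep)
    while stack:
        i = stack.pop()
        if i in out:
            continue
        out.add(i)
        for p in (sire.get(i, 0), dam.get(i, 0)):
            if p in allowed:
                stack.append(p)
    return out


def run_study_population(scenario: BreedingScenario, lay: HerdLayout,
                         founders: FounderPopulation, arch: TraitArchitecture,
                         seed, n_generations: int = 12, n_prediction: int = 200,
                         pedigree_from: int = 8, founder_ranking: str = "tbv",
                         bull_ranking: str = "phenotype") -> StudyData:
    """Run the full multi-generation study for one scenario.

    Generations 1..11 turn the cow population over; the cows standing after
    generation ``n_generations - 1`` are the phenotyped training set whose
    TBVs are affinely rescaled to mean 0 and variance exactly equal to the
    trait's ``target_tbv_variance`` (0.1).  The same map is applied to the
    final generation of calves, of which ``n_prediction`` females form the
    prediction cohort.  The exported pedigree is truncated at generation
    ``pedigree_from`` (parents before it treated as unknown) and restricted
    to the phenotyped/prediction animals and their retained ancestors.
    """
    rng = np.random.default_rng(seed)
    gmap = founders.gmap
    cohort, recorder = assign_founders(founders, lay, scenario, arch, rng,
                                       founder_ranking=founder_ranking)
    for _ in range(n_generations - 1):
        cohort = breed_generation(cohort, scenario, lay, gmap, arch, recorder,
                                  rng, bull_ranking=bull_ranking)

    # rescale TBV on the phenotyped cohort; same affine map everywhere after
    shift = cohort.cow_tbv.mean()
    sd = cohort.cow_tbv.std()
    if sd == 0:
        raise RuntimeError("phenotyped cohort has zero TBV variance")
    scale = np.sqrt(arch.target_tbv_variance) / sd
    phen = pd.DataFrame({"id": cohort.cow_id, "herd": cohort.cow_herd + 1,
                         "tbv": (cohort.cow_tbv - shift) * scale})
    phen_haps = cohort.cow_haps.copy()

    cohort, (f_ids, f_tbv, f_haps, f_herd) = breed_generation(
        cohort, scenario, lay, gmap, arch, recorder, rng,
        bull_ranking=bull_ranking, keep_male_haps=True)
    if f_ids.size < n_prediction:
        raise RuntimeError(
            f"only {f_ids.size} female calves available for a prediction "
            f"cohort of {n_prediction}")
    pick = np.sort(rng.choice(f_ids.size, size=n_prediction, replace=False))
    pred = pd.DataFrame({"id": f_ids[pick], "herd": f_herd[pick] + 1,
                         "tbv": (f_tbv[pick] - shift) * scale})

    # truncate the pedigree: ancestors kept from ``pedigree_from`` onwards;
    # phenotyped animals born earlier (retained dams) stay, as base animals
    ped = recorder.frame()
    allowed = set(ped.loc[ped["generation"] >= pedigree_from, "id"])
    keep = _ancestor_closure(ped, set(phen["id"]) | set(pred["id"]), allowed)
    ped = ped[ped["id"].isin(keep)].copy()
    known = set(ped["id"])
    ped["sire"] = ped["sire"].where(ped["sire"].isin(known), 0)
    ped["dam"] = ped["dam"].where(ped["dam"].isin(known), 0)
    ped = ped.sort_values(["generation", "id"]).reset_index(drop=True)

    snp_idx = gmap.snp_indices
    dos_phen = phen_haps[:, 0, snp_idx].astype(np.int16) + phen_haps[:, 1, snp_idx]
    dos_pred = f_haps[pick][:, 0, snp_idx].astype(np.int16) + f_haps[pick][:, 1, snp_idx]
    return StudyData(pedigree=ped, phenotyped=phen, prediction=pred,
                     snp_ids=np.concatenate([phen["id"], pred["id"]]),
                     snp_dosages=np.vstack([dos_phen, dos_pred]),
                     layout=lay, tbv_shift=float(shift), tbv_scale=float(scale))


# ---------------------------------------------------------------------------
# CSV interfaces


def write_pedigree(ped: pd.DataFrame, path) -> None:
    ped[["id", "sire", "dam", "sex", "generation", "herd"]].to_csv(path, index=False)


def read_pedigree(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_herds(lay: HerdLayout, path) -> None:
    pd.DataFrame({"herd": np.arange(1, lay.n_herds + 1),
                  "village": lay.herd_to_village + 1,
                  "x": lay.herd_coords[:, 0],
                  "y": lay.herd_coords[:, 1]}).to_csv(path, index=False)


def read_herds(path) -> pd.DataFrame:
    return pd.read_csv(path)
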