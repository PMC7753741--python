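"""Synthetic study generator with known ground truth.

Emulates the sampled study design: five mountain regions (NT, VT, ZT, RD,
FG; VT diploid, the rest autotetraploid), each with foothill and alpine
populations, where genetic divergence is deep between regions and shallow
between ecotypes within a region (parallel-origin demography, no alpine
bottleneck), and 16 phenotypic traits (12 organ measurements + 4 ratios)
fall into parallel / plastic / genetically non-parallel classes with a
region-specific leaf-lobe signal carried by the FG region.

Every generated dataset can be accompanied by a JSON manifest recording
seeds, demographic parameters and per-trait truth for recovery tests.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .coalescent import DemeSample, DemographicScenario, Event, simulate_genotype_matrix
from .io import (DEFAULT_MEASURED_TRAITS, DEFAULT_RATIOS, DEFAULT_REGIONS,
                 ENV_VARIABLES, GenotypeMatrix, TraitTable, pearson_corr_screen)

logger = logging.getLogger("parallodrome")


@dataclass
class StudyDesign:
    """Sampling layout of the synthetic study."""

    regions: tuple = DEFAULT_REGIONS
    diploid_regions: tuple = ("VT",)
    pops_per_ecotype: int = 3           # per region
    field_individuals_per_pop: int = 17
    genotyped_per_pop: int = 4
    garden_regions: tuple = ("NT", "VT", "ZT", "FG")
    garden_pops_per_ecotype: int = 2
    garden_individuals_per_pop: int = 14
    field_missing_rate: float = 0.015

    def ploidy_of(self, region: str) -> int:
        return 2 if region in self.diploid_regions else 4

    def populations(self, garden: bool = False) -> pd.DataFrame:
        """One row per population: population, region, ecotype, ploidy."""
        regions = self.garden_regions if garden else self.regions
        k = self.garden_pops_per_ecotype if garden else self.pops_per_ecotype
        rows = []
        for r in regions:
            for eco, tag in (("foothill", "f"), ("alpine", "a")):
                for i in range(1, k + 1):
                    rows.append({
                        "population": f"{r}_{tag}{i}", "region": r,
                        "ecotype": eco, "ploidy": self.ploidy_of(r),
                    })
        return pd.DataFrame(rows)


@dataclass
class DemographyParams:
    """Parallel-origin demography of the synthetic genotypes.

    Regions split from a common ancestor at ``T_root`` (star-like), the
    alpine deme of each region splits from its foothill deme at
    ``T_within``, and populations split within their region x ecotype
    deme at ``T_pop``; all demes share relative size ``N`` (no alpine
    bottleneck).  Times in coalescent units of 2 N0 generations.
    """

    T_pop: float = 0.01
    T_within: float = 0.05
    T_root: float = 0.5
    N: float = 1.0

    def __post_init__(self):
        if not 0 < self.T_pop < self.T_within < self.T_root:
            raise ValueError("need 0 < T_pop < T_within < T_root")


def study_scenario(design: StudyDesign, params: DemographyParams) -> DemographicScenario:
    """Compile the study design into a population-level deme tree."""
    pops = design.populations()
    demes = {p: params.N for p in pops["population"]}
    events = []
    foothill_leads = []
    for r in design.regions:
        leads = {}
        for eco, tag in (("foothill", "f"), ("alpine", "a")):
            names = [f"{r}_{tag}{i}" for i in range(1, design.pops_per_ecotype + 1)]
            leads[eco] = names[0]
            events += [Event(params.T_pop, "merge", n, names[0]) for n in names[1:]]
        events.append(Event(params.T_within, "merge", leads["alpine"], leads["foothill"]))
        foothill_leads.append(leads["foothill"])
    root = foothill_leads[0]
    events += [Event(params.T_root, "merge", l, root) for l in foothill_leads[1:]]
    return DemographicScenario(demes=demes, events=events)


def simulate_study_genotypes(design: StudyDesign | None = None,
                             demo_params: DemographyParams | None = None,
                             n_loci: int = 4500, seed: int = 0) -> GenotypeMatrix:
    """Polarized genotype matrix under the parallel-origin study demography.

    One segregating SNP per unlinked 150-kb locus (mirroring per-window
    thinned RAD data); ``design.genotyped_per_pop`` individuals per
    population at the region's ploidy.
    """
    design = design or StudyDesign()
    demo_params = demo_params or DemographyParams()
    scenario = study_scenario(design, demo_params)
    samples = [
        DemeSample(deme=row.population, n_individuals=design.genotyped_per_pop,
                   ploidy=row.ploidy, population=row.population,
                   region=row.region, ecotype=row.ecotype)
        for row in design.populations().itertuples()
    ]
    return simulate_genotype_matrix(scenario, samples, n_loci=n_loci, theta=1.0,
                                    seed=seed, one_snp_per_locus=True)


# --------------------------------------------------------------------------
# phenotypes
# --------------------------------------------------------------------------

@dataclass
class TraitGen:
    """Generating parameters of one measured trait.

    ``scale`` matches the downstream transform: "log" traits follow the
    linear model on the log scale and are exponentiated to measurements
    (log-normal, as befits traits the analysis log-transforms); "linear"
    traits follow it directly on the measurement scale (near-normal, as
    befits the log-exempt flower organs PL, PW, SL, SW).
    """

    name: str
    klass: str                      # parallel | plastic | nonparallel_genetic | null
    mu: float = 1.0                 # baseline (log or measurement scale)
    alpha: float = 0.0              # ecotype (alpine) effect
    beta: dict = field(default_factory=dict)    # region -> offset
    gamma: dict = field(default_factory=dict)   # region -> extra alpine effect
    plastic: float = 0.0            # field-only alpine effect (pi)
    sigma_u: float = 0.1            # population random-intercept SD
    sigma_e: float = 0.25           # residual SD
    scale: str = "log"

    def __post_init__(self):
        if self.scale not in ("log", "linear"):
            raise ValueError(f"unknown scale {self.scale!r} for trait {self.name}")
        for v in [self.mu, self.alpha, self.plastic, self.sigma_u, self.sigma_e,
                  *self.beta.values(), *self.gamma.values()]:
            if not np.isfinite(v):
                raise ValueError(f"non-finite parameter in trait {self.name}")
        has_gamma = any(g != 0 for g in self.gamma.values())
        rules = {
            "parallel": self.alpha != 0 and not has_gamma,
            "plastic": self.alpha == 0 and self.plastic != 0 and not has_gamma,
            "nonparallel_genetic": has_gamma,
            "null": self.alpha == 0 and self.plastic == 0 and not has_gamma,
        }
        if self.klass not in rules:
            raise ValueError(f"unknown trait class {self.klass!r}")
        if not rules[self.klass]:
            raise ValueError(
                f"trait {self.name}: parameters inconsistent with class {self.klass}"
            )


def effect_class(alpha: float, gamma: dict, plastic: float) -> str:
    """Trait class implied by a set of (possibly derived) effects."""
    if any(g != 0 for g in gamma.values()):
        return "nonparallel_genetic"
    if alpha != 0:
        return "parallel"
    if plastic != 0:
        return "plastic"
    return "null"


def default_trait_config() -> list:
    """The default 12 measured traits: 6-6-4 parallel/plastic/non-parallel
    after ratio derivation.

    Stem height and floral organs diverge in parallel (shorter stems,
    larger flowers in alpine plants); leaf size traits respond
    plastically in the field only; leaf lobe traits and the stem leaf
    carry an FG-region-specific, genetically determined signal.  The
    derived ratios inherit PL/PW -> parallel, SL/SW and LL/LW -> plastic,
    LLD/LL -> non-parallel.  Flower organs (the log-exempt columns) are
    generated on the measurement scale in mm; effect magnitudes follow
    the power calibration in scripts/calibrate_traits.py.
    """
    beta_common = {"NT": 0.10, "VT": -0.05, "ZT": 0.0, "RD": 0.05, "FG": -0.10}
    return [
        TraitGen("SH", "parallel", mu=np.log(30.0), alpha=-0.50, beta=beta_common),
        TraitGen("LL", "plastic", mu=np.log(40.0), plastic=-0.40, beta=beta_common),
        TraitGen("LW", "plastic", mu=np.log(12.0), plastic=-0.15, beta=beta_common),
        TraitGen("LLD", "nonparallel_genetic", mu=np.log(5.0),
                 gamma={"FG": -0.90}),
        TraitGen("LLN", "nonparallel_genetic", mu=np.log(7.0),
                 gamma={"FG": -0.85}),
        TraitGen("RL", "nonparallel_genetic", mu=np.log(25.0),
                 gamma={"FG": -0.80}),
        TraitGen("CL", "parallel", mu=np.log(3.0), alpha=0.35),
        TraitGen("CW", "parallel", mu=np.log(1.8), alpha=0.30),
        TraitGen("PL", "parallel", mu=4.5, alpha=1.80, sigma_u=0.20,
                 sigma_e=0.55, scale="linear"),
        TraitGen("PW", "parallel", mu=2.5, alpha=0.30, sigma_u=0.11,
                 sigma_e=0.30, scale="linear"),
        TraitGen("SL", "plastic", mu=2.8, plastic=1.00, sigma_u=0.13,
                 sigma_e=0.35, scale="linear"),
        TraitGen("SW", "plastic", mu=1.5, plastic=0.30, sigma_u=0.07,
                 sigma_e=0.18, scale="linear"),
    ]


def _log_scale_effects(t: TraitGen):
    """Approximate log-scale (relative) effects of a trait.

    For log-scale traits the generating effects already live on the log
    scale; for linear-scale traits additive effects are converted to the
    relative effects they imply at the baseline mean.
    """
    if t.scale == "log":
        return t.alpha, dict(t.gamma), t.plastic
    return (t.alpha / t.mu,
            {r: g / t.mu for r, g in t.gamma.items()},
            t.plastic / t.mu)


def trait_truth(config=None, ratios=None) -> dict:
    """Ground-truth class per final trait (measured + derived ratios).

    A ratio's class follows from the difference of its components'
    log-scale effects (log num - log den).
    """
    config = config or default_trait_config()
    ratios = ratios or DEFAULT_RATIOS
    by_name = {t.name: t for t in config}
    truth = {t.name: t.klass for t in config}
    for rname, (num, den) in ratios.items():
        (aa, ag, ap), (ba, bg, bp) = (_log_scale_effects(by_name[n])
                                      for n in (num, den))
        gamma = {r: ag.get(r, 0.0) - bg.get(r, 0.0) for r in set(ag) | set(bg)}
        truth[rname] = effect_class(aa - ba, gamma, ap - bp)
    return truth


def simulate_phenotypes(design: StudyDesign | None = None, config=None,
                        dataset: str = "field", seed: int = 0) -> TraitTable:
    """Raw (untransformed) measured-trait table for one dataset.

    On the log scale each trait is mu + alpha [alpine] + beta_region +
    gamma_region [alpine] + pi [alpine][field] + u_pop + eps, with the
    population intercept u_pop ~ N(0, sigma_u^2) drawn once per
    (population, trait); log-scale traits are exponentiated to positive
    measurements, linear-scale traits are used as-is.  Field data get
    ``design.field_missing_rate`` missing cells; ratios are NOT derived
    here (that is preprocessing's job).
    """
    design = design or StudyDesign()
    config = config or default_trait_config()
    if dataset not in ("field", "garden"):
        raise ValueError("dataset must be field or garden")
    rng = np.random.default_rng(seed)
    garden = dataset == "garden"
    pops = design.populations(garden=garden)
    n_per = (design.garden_individuals_per_pop if garden
             else design.field_individuals_per_pop)
    rows = []
    for prow in pops.itertuples():
        for j in range(1, n_per + 1):
            rows.append({
                "sample_id": f"{prow.population}_{dataset[0]}{j}",
                "population": prow.population, "region": prow.region,
                "ecotype": prow.ecotype,
            })
    df = pd.DataFrame(rows)
    alpine = (df["ecotype"] == "alpine").to_numpy(float)
    pop_codes, pop_labels = pd.factorize(df["population"])
    for t in config:
        u = rng.normal(0.0, t.sigma_u, size=len(pop_labels))
        beta = df["region"].map(lambda r: t.beta.get(r, 0.0)).to_numpy(float)
        gamma = df["region"].map(lambda r: t.gamma.get(r, 0.0)).to_numpy(float)
        val = (t.mu + t.alpha * alpine + beta + gamma * alpine
               + (0.0 if garden else t.plastic) * alpine
               + u[pop_codes]
               + rng.normal(0.0, t.sigma_e, size=len(df)))
        df[t.name] = np.exp(val) if t.scale == "log" else val
    if not garden and design.field_missing_rate > 0:
        names = [t.name for t in config]
        mask = rng.random((len(df), len(names))) < design.field_missing_rate
        vals = df[names].to_numpy()
        vals[mask] = np.nan
        df[names] = vals
    return TraitTable(data=df, dataset=dataset,
                      trait_names=[t.name for t in config], transformed=False)


# --------------------------------------------------------------------------
# environment
# --------------------------------------------------------------------------

#: per-variable (foothill mean, alpine mean, population SD)
ENV_PROFILE = {
    "Precipitation": (70.0, 95.0, 14.0),
    "Temperature": (12.0, 6.0, 3.0),
    "PAR": (95.0, 115.0, 11.0),
    "soil_pH": (6.2, 5.6, 0.35),
    "Vegetation_cover": (55.0, 35.0, 11.0),
    "EIV_Light": (6.8, 7.5, 0.4),
    "EIV_Nutrients": (4.5, 3.5, 0.55),
    "EIV_Moisture": (4.8, 4.4, 0.25),
}


def simulate_environment(design: StudyDesign | None = None, seed: int = 0,
                         max_tries: int = 20) -> pd.DataFrame:
    """Populations x 8 environment table: ecotype shift, no region effect.

    Alpine sites are colder, brighter, wetter and less vegetated than
    foothill sites; regions do not differ.  The table is resampled (fresh
    sub-seed) until no variable pair exceeds |Pearson r| = 0.8, keeping
    the collinearity screen satisfied by construction.
    """
    design = design or StudyDesign()
    pops = design.populations()
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        data = {}
        alpine = (pops["ecotype"] == "alpine").to_numpy(float)
        for var in ENV_VARIABLES:
            foot, alp, sd = ENV_PROFILE[var]
            data[var] = (foot + (alp - foot) * alpine
                         + rng.normal(0.0, sd, size=len(pops)))
        env = pd.DataFrame(data, index=pd.Index(pops["population"], name="population"))
        if not pearson_corr_screen(env, threshold=0.8):
            return env
    raise RuntimeError("could not satisfy the correlation screen; widen SDs")


# --------------------------------------------------------------------------
# full study
# --------------------------------------------------------------------------

def simulate_study(out_dir, design: StudyDesign | None = None,
                   demo_params: DemographyParams | None = None,
                   config=None, n_loci: int = 4500, seed: int = 0) -> dict:
    """Write a complete synthetic study: VCF, metadata, field and garden
    trait CSVs, environment CSV, and a ground-truth manifest.

    Deterministic: the same design, configuration and seed reproduce the
    files byte for byte.  Returns the manifest.
    """
    import os

    from .io import write_trait_table, write_vcf

    design = design or StudyDesign()
    demo_params = demo_params or DemographyParams()
    config = config or default_trait_config()
    rng = np.random.default_rng(seed)
    seeds = {k: int(rng.integers(2**31 - 1))
             for k in ("genotypes", "field", "garden", "environment")}
    os.makedirs(out_dir, exist_ok=True)
    G = simulate_study_genotypes(design, demo_params, n_loci=n_loci,
                                 seed=seeds["genotypes"])
    write_vcf(G, os.path.join(out_dir, "genotypes.vcf"))
    G.samples.to_csv(os.path.join(out_dir, "samples.csv"), index=False)
    for dataset in ("field", "garden"):
        T = simulate_phenotypes(design, config, dataset=dataset,
                                seed=seeds[dataset])
        write_trait_table(T, os.path.join(out_dir, f"traits_{dataset}.csv"))
    env = simulate_environment(design, seed=seeds["environment"])
    env.to_csv(os.path.join(out_dir, "environment.csv"))
    manifest = {
        "seed": seed,
        "stage_seeds": seeds,
        "demography": asdict(demo_params),
        "design": asdict(design),
        "trait_truth": trait_truth(config),
        "trait_config": [asdict(t) for t in config],
        "n_loci": n_loci,
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
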