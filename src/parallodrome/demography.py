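"""Parallel- vs single-origin test on joint allele frequency spectra.

For a pair of regions, each sampled by one alpine and one foothill
population, four candidate histories are compared: the alpine and foothill
demes of a region are sisters (parallel origin, P), or the demes of the
same ecotype are sisters across regions (single origin, S), each with or
without a within-region alpine<->foothill migration epoch (PM, SM).  Each
scenario is fitted to the observed joint AFS by maximizing a simulated
multinomial composite likelihood (Monte-Carlo expected spectra with common
random numbers), and the scenarios are ranked by AIC/Akaike weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .coalescent import (DemeSample, DemographicScenario, Event, JointAFS,
                         expected_joint_afs)
from .io import GenotypeMatrix

logger = logging.getLogger("parallodrome")

TOPOLOGIES = ("P", "PM", "S", "SM")

#: epsilon floor applied to expected cells before the log
EXPECTED_FLOOR = 1e-12

DEFAULT_BASE_PARAMS = {"N": 1.0, "T_within": 0.1, "T_root": 0.5, "m": 0.5}


def deme_names(pair):
    """Deme naming convention for a region pair: <region>_<ecotype>.

    Order: A-alpine, A-foothill, B-alpine, B-foothill — also the
    population order of every spectrum this module builds.
    """
    a, b = pair
    return [f"{a}_alpine", f"{a}_foothill", f"{b}_alpine", f"{b}_foothill"]


def scenario_for(topology: str, pair, N: float, T_within: float, T_root: float,
                 m: float = 0.0) -> DemographicScenario:
    """Build one of the four candidate scenarios at explicit parameters.

    All four demes share size N.  P/PM: within-region merges (alpine into
    foothill) at T_within, root merge at T_root.  S/SM: within-ecotype
    merges (region A into region B) at T_within, root at T_root.  PM/SM:
    symmetric alpine<->foothill migration within each region at rate m
    from time 0 until the first merge.
    """
    if topology not in TOPOLOGIES:
        raise ValueError(f"unknown topology {topology!r}")
    if not (0 < T_within < T_root):
        raise ValueError("need 0 < T_within < T_root")
    a_alp, a_foot, b_alp, b_foot = names = deme_names(pair)
    demes = {n: N for n in names}
    if topology in ("P", "PM"):
        events = [
            Event(T_within, "merge", a_alp, a_foot),
            Event(T_within, "merge", b_alp, b_foot),
            Event(T_root, "merge", b_foot, a_foot),
        ]
    else:
        events = [
            Event(T_within, "merge", a_alp, b_alp),
            Event(T_within, "merge", a_foot, b_foot),
            Event(T_root, "merge", b_alp, b_foot),
        ]
    migration = {}
    if topology in ("PM", "SM"):
        if m <= 0:
            raise ValueError(f"topology {topology} requires migration rate m > 0")
        for x, y in ((a_alp, a_foot), (b_alp, b_foot)):
            migration[(x, y)] = m
            migration[(y, x)] = m
        if topology == "SM":
            # the within-region pairs survive the T_within merges; the
            # migration epoch ends at the first merge regardless
            events += [
                Event(T_within, "set_migration", x, y, 0.0)
                for x, y in ((b_alp, b_foot), (b_foot, b_alp))
            ]
    n_params = 4 if topology in ("PM", "SM") else 3
    return DemographicScenario(demes=demes, events=sorted(events, key=lambda e: e.time),
                               migration=migration, topology_code=topology,
                               n_params=n_params)


def build_scenarios(pair, base_params=None):
    """The four candidate scenarios for one region pair at base parameters."""
    p = dict(DEFAULT_BASE_PARAMS)
    if base_params:
        p.update(base_params)
    return [
        scenario_for(t, pair, p["N"], p["T_within"], p["T_root"],
                     p["m"] if t in ("PM", "SM") else 0.0)
        for t in TOPOLOGIES
    ]


def _params_from_scenario(scenario: DemographicScenario):
    """Recover (pair, N, T_within, T_root, m) from a candidate scenario."""
    names = list(scenario.demes)
    pair = (names[0].rsplit("_", 1)[0], names[2].rsplit("_", 1)[0])
    merge_times = sorted(e.time for e in scenario.events if e.kind == "merge")
    m = max(scenario.migration.values()) if scenario.migration else 0.0
    return pair, {
        "N": float(next(iter(scenario.demes.values()))),
        "T_within": merge_times[0],
        "T_root": merge_times[-1],
        "m": float(m),
    }


def samples_for_afs(afs: JointAFS):
    """Diploid sample config matching a spectrum's populations and sizes.

    Only lineage counts matter to the coalescent; individuals are modelled
    as diploid bundles, so each population's size must be even.
    """
    out = []
    for pop, n in zip(afs.pops, afs.sample_sizes):
        if n % 2:
            raise ValueError(f"population {pop} has odd lineage count {n}")
        out.append(DemeSample(deme=pop, n_individuals=n // 2, ploidy=2))
    return out


# --------------------------------------------------------------------------
# observed spectra
# --------------------------------------------------------------------------

def observed_joint_afs(G: GenotypeMatrix, pops, projection=None,
                       folded: bool = False, drop_unprojectable: bool = False) -> JointAFS:
    """Joint AFS of 2-4 populations from a genotype matrix.

    ``projection`` gives per-population target lineage counts; loci
    genotyped in more lineages are down-projected hypergeometrically
    (fractional mass over cells), loci with fewer are dropped.  Without
    projection, loci missing any genotype in any chosen population are
    dropped so that counts stay integral.  Unfolded spectra require a
    polarized matrix.
    """
    pops = list(pops)
    if not 2 <= len(pops) <= 4:
        raise ValueError("joint AFS supports 2-4 populations")
    if not folded and not G.polarized:
        raise ValueError(
            "unpolarized genotypes cannot yield an unfolded spectrum; "
            "run in folded mode"
        )
    counts = []
    for pop in pops:
        idx = G.sample_index(population=pop)
        if len(idx) == 0:
            raise ValueError(f"no samples in population {pop!r}")
        counts.append(G.allele_counts(idx))
    full_n = [int(G.ploidy[G.sample_index(population=pop)].sum()) for pop in pops]
    if projection is None:
        projection = full_n
    projection = [int(m) for m in projection]
    dims = tuple(m + 1 for m in projection)
    afs = np.zeros(dims)
    n_loci = G.n_loci
    n_used = 0
    for l in range(n_loci):
        vecs = []
        usable = True
        for (derived, lineages), m in zip(counts, projection):
            n_l, d_l = int(lineages[l]), int(derived[l])
            if n_l < m:
                usable = False
                break
            if n_l == m:
                v = np.zeros(m + 1)
                v[d_l] = 1.0
            elif drop_unprojectable:
                usable = False
                break
            else:
                j = np.arange(m + 1)
                v = stats.hypergeom.pmf(j, n_l, d_l, m)
            vecs.append(v)
        if not usable:
            continue
        cell = vecs[0]
        for v in vecs[1:]:
            cell = np.multiply.outer(cell, v)
        afs += cell
        n_used += 1
    if n_used == 0:
        raise ValueError("no locus could be projected onto the requested sizes")
    out = JointAFS(afs, pops, folded=False)
    if folded:
        out = out.fold()
    return out


# --------------------------------------------------------------------------
# composite likelihood and fitting
# --------------------------------------------------------------------------

def composite_log_likelihood(obs: JointAFS, expected: JointAFS) -> float:
    """Multinomial composite log-likelihood sum_c O_c ln E_c.

    ``expected`` is (re)normalized over unmasked cells and floored at
    EXPECTED_FLOOR before the log; SNPs are treated as independent draws.
    """
    if obs.dims != expected.dims or obs.folded != expected.folded:
        raise ValueError("observed and expected spectra do not match")
    mask = obs.mask | expected.mask
    e = np.where(mask, 0.0, expected.counts)
    tot = e.sum()
    if tot <= 0:
        raise ValueError("expected spectrum has no unmasked mass")
    e = np.maximum(e / tot, EXPECTED_FLOOR)
    o = np.where(mask, 0.0, obs.counts)
    return float((o * np.log(e)).sum())


@dataclass
class ScenarioFit:
    scenario: DemographicScenario
    max_composite_loglik: float
    mle_params: dict
    n_params: int
    n_snps: int
    converged: bool
    n_evaluations: int = 0


@dataclass
class OptSettings:
    """Optimizer budget for one scenario fit."""

    n_reps: int = 20_000        # coalescent replicates per likelihood evaluation
    max_iter: int = 120         # Nelder-Mead iterations per restart
    restarts: int = 3
    log_bound: float = np.log(1e3)   # |log parameter| soft bound


def evaluate_scenario(obs: JointAFS, scenario: DemographicScenario,
                      n_reps: int = 20_000, seed: int = 0) -> ScenarioFit:
    """Zero-dimensional fit: composite likelihood at fixed parameters (k=0)."""
    samples = samples_for_afs(obs)
    exp = expected_joint_afs(scenario, samples, n_reps, seed, folded=obs.folded)
    _, params = _params_from_scenario(scenario)
    return ScenarioFit(
        scenario=scenario,
        max_composite_loglik=composite_log_likelihood(obs, exp),
        mle_params=params,
        n_params=0,
        n_snps=int(round(obs.total())),
        converged=True,
        n_evaluations=1,
    )


def fit_scenario(obs: JointAFS, scenario: DemographicScenario,
                 opt: OptSettings | None = None, seed: int = 0) -> ScenarioFit:
    """Maximize the simulated composite likelihood of one scenario.

    Nelder-Mead over log-transformed parameters (shared size N, T_within,
    the increment T_root - T_within and, for PM/SM, the rate m), with a
    fixed simulation seed across evaluations (common random numbers) so
    the Monte-Carlo likelihood surface is deterministic.  Best of
    ``opt.restarts`` jittered starts is returned.
    """
    opt = opt or OptSettings()
    topology = scenario.topology_code
    if topology not in TOPOLOGIES:
        raise ValueError("scenario must carry one of the four topology codes")
    pair, base = _params_from_scenario(scenario)
    samples = samples_for_afs(obs)
    free = ["N", "T_within", "dT"] + (["m"] if topology in ("PM", "SM") else [])
    x0 = np.log([base["N"], base["T_within"],
                 max(base["T_root"] - base["T_within"], 1e-3)] +
                ([max(base["m"], 1e-2)] if topology in ("PM", "SM") else []))
    rng = np.random.default_rng(seed)
    crn_seed = int(rng.integers(2**31 - 1))
    n_evals = 0

    def unpack(x):
        p = dict(zip(free, np.exp(x)))
        return dict(N=p["N"], T_within=p["T_within"],
                    T_root=p["T_within"] + p["dT"], m=p.get("m", 0.0))

    def objective(x):
        nonlocal n_evals
        if np.any(np.abs(x) > opt.log_bound):
            return 1e12
        n_evals += 1
        params = unpack(x)
        scen = scenario_for(topology, pair, params["N"], params["T_within"],
                            params["T_root"], params["m"])
        exp = expected_joint_afs(scen, samples, opt.n_reps, crn_seed,
                                 folded=obs.folded)
        return -composite_log_likelihood(obs, exp)

    best = None
    for r in range(opt.restarts):
        start = x0 if r == 0 else x0 + rng.normal(0, 0.7, size=len(x0))
        start = np.clip(start, -opt.log_bound + 1e-6, opt.log_bound - 1e-6)
        res = optimize.minimize(
            objective, start, method="Nelder-Mead",
            options={"maxiter": opt.max_iter, "xatol": 0.02, "fatol": 0.2},
        )
        if not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError(
            "non-finite composite likelihood at every start point; widen bounds"
        )
    params = unpack(best.x)
    mle = scenario_for(topology, pair, params["N"], params["T_within"],
                       params["T_root"], params["m"])
    return ScenarioFit(
        scenario=mle,
        max_composite_loglik=float(-best.fun),
        mle_params={k: float(v) for k, v in params.items()
                    if k != "m" or topology in ("PM", "SM")},
        n_params=len(free),
        n_snps=int(round(obs.total())),
        converged=bool(best.success),
        n_evaluations=n_evals,
    )


@dataclass
class ModelComparison:
    fits: list
    aic: np.ndarray
    delta_aic: np.ndarray
    akaike_weights: np.ndarray
    warning: str | None = None

    def weight(self, topology: str) -> float:
        for f, w in zip(self.fits, self.akaike_weights):
            if f.scenario.topology_code == topology:
                return float(w)
        raise KeyError(topology)

    def table(self):
        import pandas as pd
        rows = [
            {"topology": f.scenario.topology_code, "k": f.n_params,
             "loglik": f.max_composite_loglik, "aic": a, "delta_aic": d,
             "weight": w, "converged": f.converged}
            for f, a, d, w in zip(self.fits, self.aic, self.delta_aic,
                                  self.akaike_weights)
        ]
        return (pd.DataFrame(rows)
                .sort_values("weight", ascending=False)
                .reset_index(drop=True))


def compare_scenarios(fits) -> ModelComparison:
    """Rank scenario fits by AIC = 2k - 2 loglik and Akaike weights."""
    fits = list(fits)
    aic = np.array([2 * f.n_params - 2 * f.max_composite_loglik for f in fits])
    delta = aic - aic.min()
    w = np.exp(-delta / 2)
    w = w / w.sum()
    warning = None
    if not all(f.converged for f in fits):
        bad = [f.scenario.topology_code for f in fits if not f.converged]
        warning = f"non-converged fit(s): {bad}"
        logger.warning("compare_scenarios: %s", warning)
    return ModelComparison(fits=fits, aic=aic, delta_aic=delta,
                           akaike_weights=w, warning=warning)


def origin_test(obs: JointAFS, pair, base_params=None,
                opt: OptSettings | None = None, seed: int = 0) -> ModelComparison:
    """Fit all four scenarios to one observed spectrum and compare them."""
    scenarios = build_scenarios(pair, base_params)
    rng = np.random.default_rng(seed)
    fits = [
        fit_scenario(obs, scen, opt=opt, seed=int(rng.integers(2**31 - 1)))
        for scen in scenarios
    ]
    return compare_scenarios(fits)
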