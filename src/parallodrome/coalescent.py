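"""Multi-deme Kingman coalescent: genotype matrices and joint allele
frequency spectra under configurable split/migration demographies.

Scaling convention
------------------
Time is measured in coalescent units of 2*N0 generations for a reference
size N0; deme sizes are expressed relative to N0, so a deme of size N
coalesces each lineage pair at rate 1/N.  theta = 4*N0*mu per locus: with
two lineages in a size-1 deme the expected pairwise difference equals
theta.  Migration rates are per lineage per coalescent time unit,
backwards in time.

Loci are unlinked (free recombination between, none within) and mutate
under the infinite-sites model.  Autotetraploid individuals contribute
four exchangeable lineages (polysomic inheritance, no double reduction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kingman
from .io import GenotypeMatrix, META_COLUMNS

logger = logging.getLogger("parallodrome")

_EV_KINDS = {"merge": _kingman.EV_MERGE,
             "set_migration": _kingman.EV_SET_MIG,
             "set_size": _kingman.EV_SET_SIZE}


@dataclass(frozen=True)
class Event:
    """A scheduled demographic event (times in coalescent units)."""

    time: float
    kind: str            # merge | set_migration | set_size
    a: str               # source deme (merge: lineages move a -> b)
    b: str | None = None
    value: float = 0.0

    def __post_init__(self):
        if self.kind not in _EV_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.time < 0:
            raise ValueError("event time must be >= 0")
        if self.kind in ("merge", "set_migration") and self.b is None:
            raise ValueError(f"{self.kind} event needs a destination deme")
        if self.kind == "set_migration" and self.value < 0:
            raise ValueError("migration rate must be >= 0")


@dataclass
class DemographicScenario:
    """A deme tree: sizes, scheduled events, and starting migration rates.

    ``topology_code`` tags the four candidate histories of the origin test:
    P (parallel), PM (parallel + migration), S (single), SM (single +
    migration).  ``migration`` holds rates active from time 0 as
    {(source, dest): rate}; further epochs are encoded as set_migration
    events.
    """

    demes: dict                      # name -> relative size (> 0)
    events: list = field(default_factory=list)
    migration: dict = field(default_factory=dict)
    topology_code: str = ""
    n_params: int = 0

    def __post_init__(self):
        for name, size in self.demes.items():
            if not size > 0:
                raise ValueError(f"deme {name!r} has non-positive size {size}")
        self.events = sorted(self.events, key=lambda e: e.time)
        names = set(self.demes)
        for ev in self.events:
            if ev.a not in names or (ev.b is not None and ev.b not in names):
                raise ValueError(f"event references unknown deme: {ev}")
        for (a, b), m in self.migration.items():
            if a not in names or b not in names:
                raise ValueError(f"migration references unknown deme: ({a}, {b})")
            if m < 0:
                raise ValueError("migration rate must be >= 0")
        has_mig = any(m > 0 for m in self.migration.values()) or any(
            ev.kind == "set_migration" and ev.value > 0 for ev in self.events
        )
        if self.topology_code in ("P", "S") and has_mig:
            raise ValueError(f"topology {self.topology_code} admits no migration")
        if self.topology_code in ("PM", "SM") and not has_mig:
            raise ValueError(f"topology {self.topology_code} requires migration")
        self._check_single_root()

    def _check_single_root(self):
        alive = set(self.demes)
        for ev in self.events:
            if ev.kind == "merge":
                if ev.a not in alive:
                    raise ValueError(f"merge from already-merged deme {ev.a!r}")
                alive.discard(ev.a)
        if len(alive) != 1:
            raise ValueError(
                f"scenario does not coalesce to a single root deme; "
                f"remaining: {sorted(alive)}"
            )

    # --- compilation to the numba kernel's arrays -------------------------
    def compile(self):
        names = list(self.demes)
        idx = {n: i for i, n in enumerate(names)}
        sizes = np.array([float(self.demes[n]) for n in names])
        mig = np.zeros((len(names), len(names)))
        for (a, b), m in self.migration.items():
            mig[idx[a], idx[b]] = m
        n_ev = len(self.events)
        ev_time = np.array([e.time for e in self.events], dtype=float)
        ev_type = np.array([_EV_KINDS[e.kind] for e in self.events], dtype=np.int64)
        ev_a = np.array([idx[e.a] for e in self.events], dtype=np.int64)
        ev_b = np.array(
            [idx[e.b] if e.b is not None else -1 for e in self.events],
            dtype=np.int64,
        )
        ev_val = np.array([e.value for e in self.events], dtype=float)
        if n_ev == 0:
            ev_time = np.empty(0); ev_type = np.empty(0, np.int64)
            ev_a = np.empty(0, np.int64); ev_b = np.empty(0, np.int64)
            ev_val = np.empty(0)
        return names, idx, sizes, mig, ev_time, ev_type, ev_a, ev_b, ev_val


@dataclass
class DemeSample:
    """Sampling configuration for one deme: individuals, ploidy, labels."""

    deme: str
    n_individuals: int
    ploidy: int
    population: str | None = None
    region: str = ""
    ecotype: str = ""

    def __post_init__(self):
        if self.ploidy not in (2, 4):
            raise ValueError("ploidy must be 2 or 4")
        if self.n_individuals < 0:
            raise ValueError("n_individuals must be >= 0")
        if self.population is None:
            self.population = self.deme

    @property
    def n_lineages(self) -> int:
        return self.n_individuals * self.ploidy


def _sample_layout(scenario: DemographicScenario, samples):
    """Flatten a SampleConfig into per-lineage deme/population indices."""
    names, idx, *_ = scenario.compile()
    lin_deme, lin_pop, pops = [], [], []
    rows = []
    for s in samples:
        if s.deme not in idx:
            raise ValueError(f"sample config references unknown deme {s.deme!r}")
        p = len(pops)
        pops.append(s.population)
        for i in range(s.n_individuals):
            rows.append(
                {"sample_id": f"{s.population}_{i}", "population": s.population,
                 "region": s.region, "ecotype": s.ecotype, "ploidy": s.ploidy}
            )
            lin_deme.extend([idx[s.deme]] * s.ploidy)
            lin_pop.extend([p] * s.ploidy)
    if not lin_deme:
        raise ValueError("sample config has no lineages")
    return (np.array(lin_deme, np.int64), np.array(lin_pop, np.int64),
            pops, pd.DataFrame(rows, columns=META_COLUMNS))


class JointAFS:
    """Joint derived-allele-count spectrum over 1-4 populations.

    ``counts[d1, ..., dk]`` is the (possibly expected, hence real-valued)
    number of SNPs with derived count ``d_p`` in population p; axis p has
    length n_p + 1.  ``mask`` flags cells excluded from all computation;
    the all-ancestral and all-derived corners are masked by default.
    """

    def __init__(self, counts, pops, folded=False, mask=None):
        self.counts = np.array(counts, dtype=float)
        self.pops = list(pops)
        if self.counts.ndim != len(self.pops):
            raise ValueError("counts dimensionality must match population list")
        self.folded = folded
        if mask is None:
            mask = np.zeros(self.counts.shape, dtype=bool)
            mask[(0,) * self.counts.ndim] = True
            if not folded:
                mask[tuple(s - 1 for s in self.counts.shape)] = True
        self.mask = np.asarray(mask, dtype=bool)
        if np.any(self.counts[~self.mask] < 0):
            raise ValueError("negative spectrum entries")
        self.counts[self.mask] = 0.0

    @property
    def dims(self):
        return self.counts.shape

    @property
    def sample_sizes(self):
        return tuple(s - 1 for s in self.counts.shape)

    def total(self) -> float:
        return float(self.counts[~self.mask].sum())

    def normalized(self) -> "JointAFS":
        tot = self.total()
        if tot <= 0:
            raise ValueError("spectrum has no unmasked mass")
        return JointAFS(self.counts / tot, self.pops, self.folded, self.mask.copy())

    def fold(self) -> "JointAFS":
        """Collapse derived/ancestral symmetry (minor-allele spectrum)."""
        if self.folded:
            return self
        n_tot = sum(self.sample_sizes)
        out = np.zeros_like(self.counts)
        mask = np.ones(self.counts.shape, dtype=bool)
        for cell in np.ndindex(self.counts.shape):
            if self.mask[cell]:
                continue
            conj = tuple(s - 1 - c for s, c in zip(self.counts.shape, cell))
            d = sum(cell)
            if 2 * d < n_tot or (2 * d == n_tot and cell <= conj):
                out[cell] += self.counts[cell]
                mask[cell] = False
            else:
                out[conj] += self.counts[cell]
                mask[conj] = False
        mask[(0,) * self.counts.ndim] = True
        out[(0,) * self.counts.ndim] = 0.0
        return JointAFS(out, self.pops, folded=True, mask=mask)

    def marginal(self, pop) -> "JointAFS":
        """1-D spectrum of one population (sums over the others)."""
        axis = self.pops.index(pop)
        keep = [i for i in range(self.counts.ndim) if i != axis]
        counts = np.where(self.mask, 0.0, self.counts).sum(axis=tuple(keep))
        return JointAFS(counts, [pop], folded=self.folded)

    # --- plain-text serialization (dadi-style layout) ---------------------
    def to_file(self, path) -> None:
        """Header: dims, 'folded'/'unfolded', population names; then the
        row-major flattened counts; then the flattened 0/1 mask."""
        with open(path, "w") as fh:
            dims = " ".join(str(d) for d in self.dims)
            fold = "folded" if self.folded else "unfolded"
            fh.write(f"{dims} {fold} {' '.join(self.pops)}\n")
            fh.write(" ".join(f"{x:.17g}" for x in self.counts.ravel()) + "\n")
            fh.write(" ".join("1" if m else "0" for m in self.mask.ravel()) + "\n")

    @classmethod
    def from_file(cls, path) -> "JointAFS":
        with open(path) as fh:
            header = fh.readline().split()
            flat = np.array([float(x) for x in fh.readline().split()])
            mask = np.array([c == "1" for c in fh.readline().split()])
        k = 0
        dims = []
        while k < len(header) and header[k].isdigit():
            dims.append(int(header[k]))
            k += 1
        folded = header[k] == "folded"
        pops = header[k + 1:]
        return cls(flat.reshape(dims), pops, folded=folded, mask=mask.reshape(dims))


def _strides_for(dims):
    """Row-major strides mapping a count vector to a flat cell index."""
    strides = np.ones(len(dims), dtype=np.int64)
    for j in range(len(dims) - 2, -1, -1):
        strides[j] = strides[j + 1] * dims[j + 1]
    return strides


def simulate_locus(scenario: DemographicScenario, samples, theta: float, rng_seed: int):
    """Simulate one unlinked locus; infinite-sites Poisson mutations.

    Returns ``(states, deme_counts)``: per-lineage derived states
    (n_lineages x n_mutations int8; zero columns mean the locus is
    monomorphic) and the per-population derived counts of each mutation.
    """
    if theta <= 0:
        raise ValueError("theta must be > 0")
    lin_deme, lin_pop, pops, _ = _sample_layout(scenario, samples)
    names, idx, sizes, mig, *ev = scenario.compile()
    parent, node_time, ok = _kingman._simulate_tree(
        lin_deme, len(names), sizes, mig, *ev, int(rng_seed) % _kingman._MOD)
    if not ok:
        raise RuntimeError("lineages cannot reach a common ancestor (stranded demes)")
    states = _kingman._mutate_tree(parent, node_time, len(lin_deme), theta, False)
    n_pops = len(pops)
    deme_counts = np.zeros((states.shape[1], n_pops), dtype=int)
    for p in range(n_pops):
        deme_counts[:, p] = states[lin_pop == p].sum(axis=0)
    return states, deme_counts


def simulate_genotype_matrix(scenario: DemographicScenario, samples, n_loci: int,
                             theta: float, seed: int, spacing: int = 150_000,
                             one_snp_per_locus: bool = False) -> GenotypeMatrix:
    """Assemble unlinked simulated loci into a polarized GenotypeMatrix.

    Each locus occupies its own window of ``spacing`` bp on a synthetic
    chromosome; SNP positions within a locus are consecutive from the
    window start.  Default mutation model is Poisson(theta/2 * branch
    length); with ``one_snp_per_locus`` each locus carries exactly one
    segregating site (branch chosen proportionally to length), mirroring
    per-window thinned RAD data.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    if theta <= 0:
        raise ValueError("theta must be > 0")
    lin_deme, lin_pop, pops, sample_df = _sample_layout(scenario, samples)
    names, idx, sizes, mig, *ev = scenario.compile()
    n_lineages = len(lin_deme)
    ploidies = sample_df["ploidy"].to_numpy()
    # lineage -> individual map (lineages of an individual are consecutive)
    lin_ind = np.repeat(np.arange(len(sample_df)), ploidies)

    rng = np.random.default_rng(seed)
    base = int(rng.integers(_kingman._MOD))
    chroms, poss, cols = [], [], []
    for l in range(n_loci):
        s = (base + 1000003 * (l + 1)) % _kingman._MOD
        parent, node_time, ok = _kingman._simulate_tree(
            lin_deme, len(names), sizes, mig, *ev, s)
        if not ok:
            raise RuntimeError("lineages cannot reach a common ancestor (stranded demes)")
        states = _kingman._mutate_tree(parent, node_time, n_lineages, theta,
                                       one_snp_per_locus)
        for j in range(states.shape[1]):
            chroms.append("chr1")
            poss.append(l * spacing + 1 + j)
            # per-individual dosage = derived lineages of that individual
            cols.append(np.bincount(lin_ind, weights=states[:, j],
                                    minlength=len(sample_df)).astype(np.int16))
    if cols:
        dosages = np.column_stack(cols)
    else:
        dosages = np.empty((len(sample_df), 0), dtype=np.int16)
    loci = pd.DataFrame({
        "chrom": chroms, "pos": poss,
        "ref": ["A"] * len(poss), "alt": ["T"] * len(poss),
        "ancestral": ["A"] * len(poss),
    })
    return GenotypeMatrix(samples=sample_df, loci=loci, dosages=dosages,
                          polarized=True)


def expected_joint_afs(scenario: DemographicScenario, samples, n_reps: int,
                       seed: int, folded: bool = False) -> JointAFS:
    """Monte-Carlo expected joint AFS (branch-length weighted, normalized).

    Averages, over ``n_reps`` replicate genealogies, the branch length
    subtending each joint derived-count cell; the result is normalized to
    sum 1 over unmasked cells.  Corners are masked (and structurally empty:
    every branch subtends a proper, non-empty leaf subset).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    lin_deme, lin_pop, pops, _ = _sample_layout(scenario, samples)
    names, idx, sizes, mig, *ev = scenario.compile()
    n_per_pop = np.bincount(lin_pop, minlength=len(pops))
    dims = tuple(int(n) + 1 for n in n_per_pop)
    strides = _strides_for(dims)
    flat = np.zeros(int(np.prod(dims)))
    ok = _kingman._expected_afs_mc(
        lin_deme, lin_pop, len(names), len(pops), sizes, mig, *ev,
        strides, int(n_reps), int(seed) % _kingman._MOD, flat)
    if not ok:
        raise RuntimeError("lineages cannot reach a common ancestor (stranded demes)")
    afs = JointAFS(flat.reshape(dims), pops)
    if afs.total() <= 0:
        raise RuntimeError("expected spectrum has all mass in masked corners")
    if folded:
        afs = afs.fold()
    return afs.normalized()


def sample_joint_afs(scenario: DemographicScenario, samples, n_snps: int,
                     seed: int, folded: bool = False) -> JointAFS:
    """Observed-style joint AFS of ``n_snps`` unlinked segregating SNPs.

    Each SNP comes from an independent genealogy, its mutation placed on a
    branch drawn with probability proportional to branch length
    (i.e. conditional on segregating under infinite sites).
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    lin_deme, lin_pop, pops, _ = _sample_layout(scenario, samples)
    names, idx, sizes, mig, *ev = scenario.compile()
    n_per_pop = np.bincount(lin_pop, minlength=len(pops))
    dims = tuple(int(n) + 1 for n in n_per_pop)
    strides = _strides_for(dims)
    flat = np.zeros(int(np.prod(dims)))
    ok = _kingman._sample_snps_mc(
        lin_deme, lin_pop, len(names), len(pops), sizes, mig, *ev,
        strides, int(n_snps), int(seed) % _kingman._MOD, flat)
    if not ok:
        raise RuntimeError("lineages cannot reach a common ancestor (stranded demes)")
    afs = JointAFS(flat.reshape(dims), pops)
    if folded:
        afs = afs.fold()
    return afs
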