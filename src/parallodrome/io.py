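"""Readers, writers and validation for the pipeline's standard formats.

Genotypes travel as VCF 4.x (GT field, per-sample ploidy 2 or 4, optional
INFO/AA ancestral-allele annotation) accompanied by a mandatory sample
metadata table; phenotypes and environmental variables travel as UTF-8 CSV
with a header row.  Everything downstream operates on the in-memory
containers defined here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("parallodrome")

#: Mountain-region codes of the default study design.
DEFAULT_REGIONS = ("NT", "VT", "ZT", "RD", "FG")

ECOTYPES = ("foothill", "alpine")

#: dosage value marking a missing genotype
MISSING = -1

META_COLUMNS = ["sample_id", "population", "region", "ecotype", "ploidy"]

#: Default 16-trait registry: 12 organ measurements + 4 derived ratios.
#: The four flower-organ columns PL, PW, SL, SW are exempt from the log
#: transform; every other column (ratios included) is log-transformed.
DEFAULT_MEASURED_TRAITS = [
    "SH",   # stem height
    "LL",   # rosette leaf length
    "LW",   # rosette leaf width
    "LLD",  # leaf lobe depth
    "LLN",  # leaf lobe number
    "RL",   # stem leaf length
    "CL",   # calyx length
    "CW",   # calyx width
    "PL",   # petal length
    "PW",   # petal width
    "SL",   # sepal length
    "SW",   # sepal width
]
#: ratio name -> (numerator, denominator), computed on untransformed values
DEFAULT_RATIOS = {
    "LWR": ("LL", "LW"),
    "LDR": ("LLD", "LL"),
    "PWR": ("PL", "PW"),
    "SWR": ("SL", "SW"),
}
DEFAULT_TRAITS = DEFAULT_MEASURED_TRAITS + list(DEFAULT_RATIOS)
LOG_EXEMPT = ("PL", "PW", "SL", "SW")

#: The eight environmental variables recorded per population.
ENV_VARIABLES = [
    "Precipitation",
    "Temperature",
    "PAR",
    "soil_pH",
    "Vegetation_cover",
    "EIV_Light",
    "EIV_Nutrients",
    "EIV_Moisture",
]


class MetadataError(ValueError):
    """Raised when a metadata table violates its invariants."""


def validate_meta(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample metadata table and return it with normalised dtypes.

    Required columns: sample_id, population, region, ecotype, ploidy.
    Invariants enforced: unique sample ids; each population maps to exactly
    one region and one ecotype; ploidy in {2, 4} and constant within a
    population.
    """
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise MetadataError(f"metadata missing columns: {missing}")
    meta = meta.copy()
    meta["ploidy"] = meta["ploidy"].astype(int)
    if meta["sample_id"].duplicated().any():
        dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise MetadataError(f"duplicate sample ids: {dups}")
    bad_ploidy = sorted(set(meta["ploidy"]) - {2, 4})
    if bad_ploidy:
        raise MetadataError(f"ploidy must be 2 or 4, got {bad_ploidy}")
    bad_eco = sorted(set(meta["ecotype"]) - set(ECOTYPES))
    if bad_eco:
        raise MetadataError(f"unknown ecotype value(s): {bad_eco}")
    for col in ("region", "ecotype", "ploidy"):
        per_pop = meta.groupby("population")[col].nunique()
        incons = per_pop[per_pop > 1].index.tolist()
        if incons:
            raise MetadataError(
                f"populations with inconsistent {col}: {incons}"
            )
    return meta


def read_meta(path) -> pd.DataFrame:
    """Read and validate a sample metadata CSV."""
    return validate_meta(pd.read_csv(path, dtype={"sample_id": str, "population": str}))


@dataclass
class GenotypeMatrix:
    """Individuals x loci allele-dosage matrix with per-sample ploidy.

    ``dosages[i, l]`` counts alternate (or derived, when ``polarized``)
    alleles of sample ``i`` at locus ``l``; ``MISSING`` (-1) marks missing
    genotypes.  ``samples`` carries sample_id/population/region/ecotype/
    ploidy; ``loci`` carries chrom/pos (1-based)/ref/alt/ancestral
    (``None`` when unknown).  Loci are kept sorted by (chrom, pos).
    """

    samples: pd.DataFrame
    loci: pd.DataFrame
    dosages: np.ndarray
    polarized: bool = False

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=np.int16)
        if self.dosages.shape != (len(self.samples), len(self.loci)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )
        ploidy = np.broadcast_to(
            self.samples["ploidy"].to_numpy()[:, None], self.dosages.shape
        )
        valid = self.dosages != MISSING
        if np.any(self.dosages[valid] < 0) or np.any(self.dosages[valid] > ploidy[valid]):
            raise ValueError("dosage outside [0, ploidy]")
        if self.polarized and self.loci["ancestral"].isna().any():
            raise ValueError("polarized matrix requires ancestral allele at every locus")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def ploidy(self) -> np.ndarray:
        return self.samples["ploidy"].to_numpy()

    def sample_index(self, population=None, region=None, ecotype=None) -> np.ndarray:
        """Row indices of samples matching the given labels."""
        mask = np.ones(self.n_samples, dtype=bool)
        if population is not None:
            mask &= (self.samples["population"] == population).to_numpy()
        if region is not None:
            mask &= (self.samples["region"] == region).to_numpy()
        if ecotype is not None:
            mask &= (self.samples["ecotype"] == ecotype).to_numpy()
        return np.flatnonzero(mask)

    def allele_counts(self, idx) -> tuple[np.ndarray, np.ndarray]:
        """Per-locus (derived/alt count, genotyped lineage count) over rows ``idx``.

        Missing genotypes are excluded pairwise: a missing sample contributes
        neither alleles nor lineages at that locus.
        """
        idx = np.asarray(idx)
        dos = self.dosages[idx]
        ok = dos != MISSING
        ploidy = self.ploidy[idx][:, None]
        derived = np.where(ok, dos, 0).sum(axis=0).astype(float)
        lineages = (ok * ploidy).sum(axis=0)
        return derived, lineages

    def frequencies(self, impute: bool = False) -> np.ndarray:
        """Per-individual allele-frequency matrix dosage/ploidy (NaN = missing).

        With ``impute=True`` missing cells are replaced by the locus mean
        frequency (used for distance- and PCA-based analyses).
        """
        freq = np.where(self.dosages == MISSING, np.nan,
                        self.dosages / self.ploidy[:, None].astype(float))
        if impute:
            col_mean = np.nanmean(freq, axis=0)
            nan_r, nan_c = np.nonzero(np.isnan(freq))
            freq[nan_r, nan_c] = col_mean[nan_c]
        return freq

    def take_loci(self, locus_idx) -> "GenotypeMatrix":
        locus_idx = np.asarray(locus_idx)
        return replace(
            self,
            loci=self.loci.iloc[locus_idx].reset_index(drop=True),
            dosages=self.dosages[:, locus_idx],
        )

    def take_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            samples=self.samples.iloc[idx].reset_index(drop=True),
            dosages=self.dosages[idx],
        )


def read_vcf(path, meta: pd.DataFrame, polarize: bool = False) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a :class:`GenotypeMatrix`.

    Parameters
    ----------
    path : str
        VCF (plain or bgzipped).
    meta : DataFrame
        Validated sample metadata; every VCF sample must be present.
    polarize : bool
        If True, require an INFO/AA ancestral-allele tag and count derived
        alleles; records whose AA matches neither REF nor ALT are skipped.

    Multiallelic and non-SNP records are skipped (count logged).  A mismatch
    between metadata ploidy and the arity of the GT field is an error.
    """
    from cyvcf2 import VCF

    meta = validate_meta(meta)
    vcf = VCF(str(path))
    unknown = [s for s in vcf.samples if s not in set(meta["sample_id"])]
    if unknown:
        raise MetadataError(f"VCF sample(s) missing from metadata: {unknown}")
    samples = (
        meta.set_index("sample_id").loc[vcf.samples].reset_index()[META_COLUMNS]
    )
    ploidy = samples["ploidy"].to_numpy()

    rows_chrom, rows_pos, rows_ref, rows_alt, rows_aa = [], [], [], [], []
    dosage_cols = []
    n_skipped = 0
    for v in vcf:
        if len(v.ALT) != 1 or not v.is_snp:
            n_skipped += 1
            continue
        aa = v.INFO.get("AA")
        if polarize:
            if aa is None:
                raise ValueError(
                    f"{v.CHROM}:{v.POS}: no INFO/AA tag; polarization requires "
                    "an ancestral allele (use folded mode otherwise)"
                )
            if aa not in (v.REF, v.ALT[0]):
                n_skipped += 1
                continue
        col = np.empty(len(samples), dtype=np.int16)
        for i, gt in enumerate(v.genotypes):
            alleles = gt[:-1]  # last element is the phase flag
            if len(alleles) != ploidy[i]:
                raise ValueError(
                    f"{v.CHROM}:{v.POS}: sample {samples['sample_id'][i]} has "
                    f"GT arity {len(alleles)} but metadata ploidy {ploidy[i]}"
                )
            if any(a < 0 for a in alleles):
                col[i] = MISSING
            else:
                col[i] = sum(alleles)
        if polarize and aa == v.ALT[0]:
            # derived allele is REF: flip dosages
            ok = col != MISSING
            col[ok] = ploidy[ok] - col[ok]
            ref, alt = v.ALT[0], v.REF
        else:
            ref, alt = v.REF, v.ALT[0]
        rows_chrom.append(v.CHROM)
        rows_pos.append(v.POS)
        rows_ref.append(ref)
        rows_alt.append(alt)
        rows_aa.append(aa)
        dosage_cols.append(col)
    if n_skipped:
        logger.info("read_vcf: skipped %d multiallelic/non-SNP/unpolarizable records", n_skipped)
    loci = pd.DataFrame(
        {"chrom": rows_chrom, "pos": rows_pos, "ref": rows_ref,
         "alt": rows_alt, "ancestral": rows_aa}
    )
    dosages = (
        np.column_stack(dosage_cols) if dosage_cols
        else np.empty((len(samples), 0), dtype=np.int16)
    )
    order = np.lexsort((loci["pos"].to_numpy(), loci["chrom"].to_numpy())) if len(loci) else np.array([], dtype=int)
    loci = loci.iloc[order].reset_index(drop=True)
    dosages = dosages[:, order] if len(loci) else dosages
    return GenotypeMatrix(samples=samples, loci=loci, dosages=dosages,
                          polarized=bool(polarize))


def write_vcf(G: GenotypeMatrix, path) -> None:
    """Write a GenotypeMatrix as a minimal VCF 4.2 text file.

    Dosage d at ploidy p becomes an unphased GT with d copies of the allele
    the dosage counts (ALT, or the derived allele when polarized) and p-d of
    the other; missing dosage becomes './.'-style GT of the right arity.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(G.loci["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(G.samples["sample_id"]) + "\n")
        ploidy = G.ploidy
        for l in range(G.n_loci):
            row = G.loci.iloc[l]
            aa = row["ancestral"]
            info = f"AA={aa}" if aa is not None and not pd.isna(aa) else "."
            gts = []
            for i in range(G.n_samples):
                d = G.dosages[i, l]
                p = ploidy[i]
                if d == MISSING:
                    gts.append("/".join(["."] * p))
                else:
                    gts.append("/".join(["0"] * (p - d) + ["1"] * d))
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t.\t{row['ref']}\t{row['alt']}"
                f"\t.\t.\t{info}\tGT\t" + "\t".join(gts) + "\n"
            )


@dataclass
class TraitTable:
    """Individuals x traits phenotype table with a field/garden flag."""

    data: pd.DataFrame           # sample_id, population, region, ecotype + traits
    dataset: str                 # "field" | "garden"
    trait_names: list = field(default_factory=list)
    transformed: bool = False

    ID_COLUMNS = ("sample_id", "population", "region", "ecotype")

    def __post_init__(self):
        if self.dataset not in ("field", "garden"):
            raise ValueError(f"dataset must be field or garden, got {self.dataset!r}")
        for c in self.ID_COLUMNS:
            if c not in self.data.columns:
                raise ValueError(f"trait table missing column {c!r}")
        if not self.trait_names:
            self.trait_names = [c for c in self.data.columns if c not in self.ID_COLUMNS]

    @property
    def traits(self) -> pd.DataFrame:
        return self.data[self.trait_names]

    def values(self) -> np.ndarray:
        return self.traits.to_numpy(dtype=float)


def read_trait_table(path, dataset: str, trait_names=None, meta: pd.DataFrame | None = None) -> TraitTable:
    """Read a phenotype CSV into an (untransformed) TraitTable.

    Missing cells are preserved as NaN for downstream imputation.  Trait
    columns must be numeric; when ``trait_names`` is given the file must
    contain exactly those columns.  When ``meta`` is supplied, every
    individual's population must be known.
    """
    df = pd.read_csv(path, dtype={"sample_id": str, "population": str})
    for c in TraitTable.ID_COLUMNS:
        if c not in df.columns:
            raise ValueError(f"trait table missing column {c!r}")
    present = [c for c in df.columns if c not in TraitTable.ID_COLUMNS]
    if trait_names is not None:
        if sorted(present) != sorted(trait_names):
            raise ValueError(
                f"trait columns {present} do not match declared list {list(trait_names)}"
            )
        present = list(trait_names)
    for c in present:
        col = pd.to_numeric(df[c], errors="coerce")
        bad = df.index[col.isna() & df[c].notna()]
        if len(bad):
            raise ValueError(f"non-numeric value in trait {c!r}, row(s) {bad.tolist()}")
        df[c] = col
    if meta is not None:
        known = set(meta["population"])
        unknown = sorted(set(df["population"]) - known)
        if unknown:
            raise ValueError(f"individuals from unknown population(s): {unknown}")
    return TraitTable(data=df, dataset=dataset, trait_names=present, transformed=False)


def write_trait_table(T: TraitTable, path) -> None:
    T.data.to_csv(path, index=False)


def read_env_table(path, variables=ENV_VARIABLES) -> pd.DataFrame:
    """Read the populations x environment CSV (one row per population).

    Returns a DataFrame indexed by population with exactly the configured
    variables (default: the eight climatic/local parameters).
    """
    df = pd.read_csv(path, dtype={"population": str})
    if "population" not in df.columns:
        raise ValueError("environment table missing 'population' column")
    if df["population"].duplicated().any():
        raise ValueError("environment table must have one row per population")
    missing = [v for v in variables if v not in df.columns]
    if missing:
        raise ValueError(f"environment table missing variable(s): {missing}")
    extra = [c for c in df.columns if c not in list(variables) + ["population"]]
    if extra:
        raise ValueError(f"unexpected environment column(s): {extra}")
    return df.set_index("population")[list(variables)].astype(float)


def pearson_corr_screen(table, threshold: float = 0.8):
    """All unordered variable pairs with \\|Pearson r\\| above ``threshold``.

    An empty list means the collinearity screen passes.  Constant columns
    (undefined r) are excluded with a warning.  Accepts a DataFrame or a
    2-D array (rows = observations).
    """
    df = pd.DataFrame(table)
    if len(df) < 3:
        raise ValueError("correlation screen needs at least 3 rows")
    if df.isna().any().any():
        raise ValueError("correlation screen requires complete data")
    sd = df.std(ddof=0)
    constant = sd.index[sd == 0].tolist()
    if constant:
        logger.warning("pearson_corr_screen: excluding constant column(s) %s", constant)
        df = df.drop(columns=constant)
    cols = list(df.columns)
    r = np.corrcoef(df.to_numpy(dtype=float), rowvar=False)
    out = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            if abs(r[i, j]) > threshold:
                out.append((cols[i], cols[j], float(r[i, j])))
    return out
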