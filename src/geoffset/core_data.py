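"""Core data containers and I/O for the landscape-genomics pipeline.

The pipeline operates on four tabular objects: a variant annotation table,
an individuals x variants dosage matrix, an individual->population map with
population coordinates, and sites x variables environmental matrices tagged
with climate period/model/scenario.  Everything is stored in plain numpy /
pandas structures and round-trips through TSV (and VCF for genotypes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1  # dosage sentinel in GenotypeMatrix arrays

VCLASSES = ("SNP", "INDEL", "SV")
FUNC_CLASSES = ("synonymous", "tolerated", "deleterious", "LOF", "noncoding", "unknown")
ANCESTRAL_STATES = ("ref", "alt", "unknown")

#: indel/SV length boundary: alleles differing by more than this many bp are SVs
SV_MIN_LEN = 50


@dataclass
class VariantTable:
    """Per-variant annotation: position, class (SNP/indel/SV), alleles,
    ancestral state and functional category."""

    df: pd.DataFrame

    COLUMNS = (
        "variant_id",
        "chrom",
        "pos",
        "vclass",
        "ref_allele",
        "alt_allele",
        "ancestral",
        "func_class",
    )

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True)
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"VariantTable missing columns: {sorted(missing)}")
        if df["variant_id"].duplicated().any():
            raise ValueError("variant_id values must be unique")
        if (df["pos"] < 1).any():
            raise ValueError("positions are 1-based; pos >= 1 required")
        bad_vc = set(df["vclass"]) - set(VCLASSES)
        if bad_vc:
            raise ValueError(f"unknown vclass values: {sorted(bad_vc)}")
        snps = df["vclass"] == "SNP"
        if snps.any():
            ref_len = df.loc[snps, "ref_allele"].str.len()
            alt_len = df.loc[snps, "alt_allele"].str.len()
            if (ref_len != 1).any() or (alt_len != 1).any():
                raise ValueError("SNP records must have single-base ref and alt alleles")
        self.df = df[list(self.COLUMNS)]

    @property
    def variant_ids(self) -> list[str]:
        return self.df["variant_id"].tolist()

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, variant_ids: Sequence[str]) -> "VariantTable":
        keep = self.df[self.df["variant_id"].isin(set(variant_ids))]
        return VariantTable(keep.copy())

    def __eq__(self, other: object) -> bool:
        return isinstance(other, VariantTable) and self.df.equals(other.df)


@dataclass
class GenotypeMatrix:
    """Alt-allele dosages (0/1/2, -1 = missing) for individuals x variants."""

    individuals: list[str]
    variants: list[str]
    dosage: np.ndarray  # int8, shape (n_ind, n_var)

    def __post_init__(self) -> None:
        self.individuals = list(self.individuals)
        self.variants = list(self.variants)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.individuals), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.variants)} variants"
            )
        valid = np.isin(self.dosage, (0, 1, 2, MISSING))
        if not valid.all():
            raise ValueError("dosages must be 0, 1, 2 or missing (-1)")

    @property
    def n_ind(self) -> int:
        return len(self.individuals)

    @property
    def n_var(self) -> int:
        return len(self.variants)

    def missing_mask(self) -> np.ndarray:
        return self.dosage == MISSING

    def dosage_float(self) -> np.ndarray:
        """Dosages as float with NaN for missing calls."""
        out = self.dosage.astype(float)
        out[self.dosage == MISSING] = np.nan
        return out

    def subset_variants(self, variant_ids: Sequence[str]) -> "GenotypeMatrix":
        index = {v: i for i, v in enumerate(self.variants)}
        cols = [index[v] for v in variant_ids]
        return GenotypeMatrix(self.individuals, list(variant_ids), self.dosage[:, cols])

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, GenotypeMatrix)
            and self.individuals == other.individuals
            and self.variants == other.variants
            and np.array_equal(self.dosage, other.dosage)
        )


@dataclass
class PopulationMap:
    """individual -> population assignment plus population coordinates."""

    ind_to_pop: dict[str, str]
    coords: pd.DataFrame  # index population_id, columns lon, lat

    def __post_init__(self) -> None:
        coords = self.coords
        if not {"lon", "lat"}.issubset(coords.columns):
            raise ValueError("coords must have lon and lat columns")
        if ((coords["lon"].abs() > 180) | (coords["lat"].abs() > 90)).any():
            raise ValueError("coordinates outside [-180,180] x [-90,90]")
        unknown = set(self.ind_to_pop.values()) - set(coords.index)
        if unknown:
            raise ValueError(f"populations without coordinates: {sorted(unknown)}")
        self.coords = coords[["lon", "lat"]].astype(float)

    @property
    def populations(self) -> list[str]:
        return list(self.coords.index)

    def members(self, pop: str) -> list[str]:
        return [i for i, p in self.ind_to_pop.items() if p == pop]

    def pop_of(self, individuals: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self.ind_to_pop[i] for i in individuals])
        except KeyError as exc:  # pragma: no cover - message formatting
            raise KeyError(f"individual {exc.args[0]!r} not assigned to a population")

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, PopulationMap)
            and self.ind_to_pop == other.ind_to_pop
            and self.coords.equals(other.coords)
        )


@dataclass
class EnvMatrix:
    """Sites x environmental-variables matrix for one climate slice.

    ``period`` is "current" or "future"; future slices carry the climate
    model name, the SSP scenario and the projection window (e.g. 2061-2080).
    """

    site_ids: list[str]
    variables: list[str]
    values: np.ndarray  # float, shape (n_sites, n_vars)
    period: str = "current"
    model: str = "none"
    scenario: str = "none"
    window: str = "none"

    def __post_init__(self) -> None:
        self.site_ids = list(self.site_ids)
        self.variables = list(self.variables)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.site_ids), len(self.variables)):
            raise ValueError("values shape does not match site/variable lists")
        if np.isnan(self.values).any():
            raise ValueError("EnvMatrix does not allow missing values")
        if len(set(self.variables)) != len(self.variables):
            raise ValueError("variable names must be unique")

    @property
    def df(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.site_ids, columns=self.variables)

    def column(self, variable: str) -> np.ndarray:
        return self.values[:, self.variables.index(variable)]

    def select(self, variables: Sequence[str]) -> "EnvMatrix":
        cols = [self.variables.index(v) for v in variables]
        return replace(self, variables=list(variables), values=self.values[:, cols])

    def reindex(self, site_ids: Sequence[str]) -> "EnvMatrix":
        order = [self.site_ids.index(s) for s in site_ids]
        return replace(self, site_ids=list(site_ids), values=self.values[order])

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, EnvMatrix)
            and self.site_ids == other.site_ids
            and self.variables == other.variables
            and np.array_equal(self.values, other.values)
            and (self.period, self.model, self.scenario, self.window)
            == (other.period, other.model, other.scenario, other.window)
        )


@dataclass
class AlleleFreqMatrix:
    """Population x variant alt-allele frequencies with observed allele counts.

    Cells where a population had no called genotypes are NaN with
    ``n_alleles`` 0; downstream statistics must tolerate these.
    """

    populations: list[str]
    variants: list[str]
    freq: np.ndarray  # float, NaN = missing
    n_alleles: np.ndarray  # int, non-missing allele count per cell

    def __post_init__(self) -> None:
        self.populations = list(self.populations)
        self.variants = list(self.variants)
        self.freq = np.asarray(self.freq, dtype=float)
        self.n_alleles = np.asarray(self.n_alleles, dtype=int)
        shape = (len(self.populations), len(self.variants))
        if self.freq.shape != shape or self.n_alleles.shape != shape:
            raise ValueError("freq/n_alleles shape mismatch")
        obs = self.n_alleles > 0
        if ((self.freq[obs] < 0) | (self.freq[obs] > 1)).any():
            raise ValueError("frequencies must lie in [0, 1]")
        counts = self.freq[obs] * self.n_alleles[obs]
        if not np.allclose(counts, np.round(counts), atol=1e-9):
            raise ValueError("freq * n_alleles must be integral")

    def subset_variants(self, variant_ids: Sequence[str]) -> "AlleleFreqMatrix":
        index = {v: i for i, v in enumerate(self.variants)}
        cols = [index[v] for v in variant_ids]
        return AlleleFreqMatrix(
            self.populations, list(variant_ids), self.freq[:, cols], self.n_alleles[:, cols]
        )

    def global_freq(self) -> np.ndarray:
        """Alt-allele frequency pooled over all populations (per variant)."""
        counts = np.where(self.n_alleles > 0, self.freq * self.n_alleles, 0.0)
        totals = self.n_alleles.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore"):
            return np.where(totals > 0, counts.sum(axis=0) / totals, np.nan)

    def imputed(self) -> np.ndarray:
        """Frequencies with missing cells replaced by the variant mean."""
        out = self.freq.copy()
        col_mean = np.nanmean(out, axis=0)
        nan_r, nan_c = np.where(np.isnan(out))
        out[nan_r, nan_c] = col_mean[nan_c]
        return out

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, AlleleFreqMatrix)
            and self.populations == other.populations
            and self.variants == other.variants
            and np.array_equal(self.freq, other.freq, equal_nan=True)
            and np.array_equal(self.n_alleles, other.n_alleles)
        )


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def classify_alleles(ref: str, alt: str, svtype: str | None = None) -> str:
    """Classify a biallelic record as SNP, INDEL or SV.

    Symbolic ALT alleles (``<DEL>`` etc.) and records with an SVTYPE INFO key
    are SVs; otherwise an allele-length difference > 50 bp makes an SV, any
    other length difference an indel, and equal single bases a SNP.
    """
    if svtype is not None or alt.startswith("<"):
        return "SV"
    if len(ref) == 1 and len(alt) == 1:
        return "SNP"
    if abs(len(ref) - len(alt)) > SV_MIN_LEN:
        return "SV"
    return "INDEL"


def read_vcf(
    path: str | Path, allowed_classes: Iterable[str] = VCLASSES
) -> tuple[VariantTable, GenotypeMatrix]:
    """Read a biallelic diploid VCF into a VariantTable + GenotypeMatrix.

    Multi-allelic records are skipped (logged); ``./.`` genotypes become
    missing dosages.  Ancestral state and functional class default to
    "unknown" / "unknown" unless AA / FUNC INFO keys are present.
    """
    from cyvcf2 import VCF

    allowed = set(allowed_classes)
    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    rows: list[tuple] = []
    dosages: list[np.ndarray] = []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        alt = rec.ALT[0]
        svtype = rec.INFO.get("SVTYPE")
        vclass = classify_alleles(rec.REF, alt, svtype)
        if vclass not in allowed:
            continue
        gts = rec.genotypes
        if gts is None:
            raise ValueError(f"record {rec.CHROM}:{rec.POS} has no GT field")
        dos = np.empty(len(individuals), dtype=np.int8)
        for i, g in enumerate(gts):
            alleles = g[:-1]
            if len(alleles) != 2:
                raise ValueError(
                    f"non-diploid genotype for sample {individuals[i]} at "
                    f"{rec.CHROM}:{rec.POS}"
                )
            if alleles[0] < 0 or alleles[1] < 0:
                dos[i] = MISSING
            else:
                dos[i] = alleles[0] + alleles[1]
        vid = rec.ID if rec.ID else f"{rec.CHROM}:{rec.POS}"
        ancestral = rec.INFO.get("AA") or "unknown"
        func = rec.INFO.get("FUNC") or "unknown"
        rows.append((vid, rec.CHROM, rec.POS, vclass, rec.REF, alt, ancestral, func))
        dosages.append(dos)
    if n_multi:
        logger.info("read_vcf: skipped %d multi-allelic records", n_multi)
    df = pd.DataFrame(rows, columns=list(VariantTable.COLUMNS))
    dosage = (
        np.stack(dosages, axis=1) if dosages else np.empty((len(individuals), 0), np.int8)
    )
    variants = VariantTable(df)
    return variants, GenotypeMatrix(individuals, variants.variant_ids, dosage)


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(path: str | Path, variants: VariantTable, genotypes: GenotypeMatrix) -> None:
    """Write a minimal VCF v4.2 with GT plus AA/FUNC INFO annotations."""
    df = variants.df.set_index("variant_id").loc[genotypes.variants].reset_index()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele state">\n')
        fh.write('##INFO=<ID=FUNC,Number=1,Type=String,Description="Functional class">\n')
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in df["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.individuals)
            + "\n"
        )
        for j, row in enumerate(df.itertuples(index=False)):
            info = f"AA={row.ancestral};FUNC={row.func_class}"
            if row.vclass == "SV" and row.alt_allele.startswith("<"):
                info += f";SVTYPE={row.alt_allele.strip('<>')}"
            gts = "\t".join(_GT_STRINGS[int(d)] for d in genotypes.dosage[:, j])
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.variant_id}\t{row.ref_allele}\t"
                f"{row.alt_allele}\t.\tPASS\t{info}\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Allele frequencies and MAF filtering
# ---------------------------------------------------------------------------

def allele_frequencies(G: GenotypeMatrix, M: PopulationMap) -> AlleleFreqMatrix:
    """Per-population alt-allele frequencies from observed (non-missing) calls.

    p = (sum of dosages over called individuals) / (2 * n_called); a
    population with no calls at a variant yields a NaN cell with 0 alleles.
    """
    pops = M.populations
    pop_labels = M.pop_of(G.individuals)  # raises on unmapped individual
    n_var = G.n_var
    freq = np.full((len(pops), n_var), np.nan)
    n_alleles = np.zeros((len(pops), n_var), dtype=int)
    dos = G.dosage
    called = dos != MISSING
    for pi, pop in enumerate(pops):
        rows = pop_labels == pop
        if not rows.any():
            continue
        sub = dos[rows]
        sub_called = called[rows]
        counts = np.where(sub_called, sub, 0).sum(axis=0)
        n_all = 2 * sub_called.sum(axis=0)
        n_alleles[pi] = n_all
        with np.errstate(invalid="ignore", divide="ignore"):
            freq[pi] = np.where(n_all > 0, counts / np.maximum(n_all, 1), np.nan)
    return AlleleFreqMatrix(pops, list(G.variants), freq, n_alleles)


def global_minor_allele_freq(x: GenotypeMatrix | AlleleFreqMatrix) -> np.ndarray:
    """Pooled minor-allele frequency per variant over all non-missing alleles."""
    if isinstance(x, GenotypeMatrix):
        dos = x.dosage_float()
        alt = np.nansum(dos, axis=0)
        total = 2 * np.sum(~np.isnan(dos), axis=0).astype(float)
        with np.errstate(invalid="ignore"):
            p = np.where(total > 0, alt / np.maximum(total, 1), np.nan)
    else:
        p = x.global_freq()
    return np.minimum(p, 1.0 - p)


def maf_filter(
    x: GenotypeMatrix | AlleleFreqMatrix, threshold: float = 0.10
) -> tuple[GenotypeMatrix | AlleleFreqMatrix, list[str]]:
    """Keep variants whose pooled minor-allele frequency strictly exceeds
    ``threshold`` (the "MAF > 10%" convention).  Returns (subset, kept ids)."""
    if not 0 <= threshold < 0.5:
        raise ValueError("MAF threshold must lie in [0, 0.5)")
    maf = global_minor_allele_freq(x)
    keep = np.where(np.nan_to_num(maf, nan=-1.0) > threshold)[0]
    kept_ids = [x.variants[i] for i in keep]
    return x.subset_variants(kept_ids), kept_ids


# ---------------------------------------------------------------------------
# TSV round-trip I/O
# ---------------------------------------------------------------------------

def write_variant_table(vt: VariantTable, path: str | Path) -> None:
    vt.df.to_csv(path, sep="\t", index=False)


def read_variant_table(path: str | Path) -> VariantTable:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return VariantTable(df)


def write_population_map(M: PopulationMap, path: str | Path) -> None:
    rows = [
        (ind, pop, M.coords.at[pop, "lon"], M.coords.at[pop, "lat"])
        for ind, pop in M.ind_to_pop.items()
    ]
    pd.DataFrame(rows, columns=["individual_id", "population_id", "lon", "lat"]).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_population_map(path: str | Path) -> PopulationMap:
    df = pd.read_csv(
        path, sep="\t", dtype={"individual_id": str, "population_id": str},
        float_precision="round_trip",
    )
    ind_to_pop = dict(zip(df["individual_id"], df["population_id"]))
    coords = (
        df.drop_duplicates("population_id")
        .set_index("population_id")[["lon", "lat"]]
    )
    coords.index.name = None
    return PopulationMap(ind_to_pop, coords)


def write_env_matrix(E: EnvMatrix, path: str | Path) -> None:
    df = E.df.copy()
    df.insert(0, "site_id", E.site_ids)
    with open(path, "w") as fh:
        fh.write(
            f"# period={E.period}\tmodel={E.model}\tscenario={E.scenario}\twindow={E.window}\n"
        )
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_env_matrix(path: str | Path) -> EnvMatrix:
    with open(path) as fh:
        header = fh.readline()
        meta = {}
        if header.startswith("#"):
            for token in header[1:].strip().split("\t"):
                k, _, v = token.partition("=")
                meta[k.strip()] = v
            df = pd.read_csv(fh, sep="\t", dtype={"site_id": str}, float_precision="round_trip")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t", dtype={"site_id": str}, float_precision="round_trip")
    sites = df["site_id"].tolist()
    variables = [c for c in df.columns if c != "site_id"]
    return EnvMatrix(
        sites,
        variables,
        df[variables].to_numpy(float),
        period=meta.get("period", "current"),
        model=meta.get("model", "none"),
        scenario=meta.get("scenario", "none"),
        window=meta.get("window", "none"),
    )


def write_freq_matrix(F: AlleleFreqMatrix, path: str | Path) -> None:
    """Long-format freqs.tsv: population, variant, freq, n_alleles."""
    pop_idx, var_idx = np.meshgrid(
        np.arange(len(F.populations)), np.arange(len(F.variants)), indexing="ij"
    )
    df = pd.DataFrame(
        {
            "population_id": np.array(F.populations)[pop_idx.ravel()],
            "variant_id": np.array(F.variants)[var_idx.ravel()],
            "freq": F.freq.ravel(),
            "n_alleles": F.n_alleles.ravel(),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_freq_matrix(path: str | Path) -> AlleleFreqMatrix:
    df = pd.read_csv(
        path, sep="\t", dtype={"population_id": str, "variant_id": str},
        float_precision="round_trip",
    )
    pops = df["population_id"].drop_duplicates().tolist()
    variants = df["variant_id"].drop_duplicates().tolist()
    freq = df["freq"].to_numpy(float).reshape(len(pops), len(variants))
    n_alleles = df["n_alleles"].to_numpy(int).reshape(len(pops), len(variants))
    return AlleleFreqMatrix(pops, variants, freq, n_alleles)
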