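"""Readers and writers for the file formats the pipeline touches.

Three tabular inputs drive the analysis:

* a SNP weight table in the PGS-Catalog scoring-file convention
  (``rsID``, ``effect_allele``, ``other_allele``, ``effect_weight``),
  giving the per-allele height effect in centimetres for each scored SNP;
* per-individual allele dosages, either as a VCF (``DS`` preferred,
  additive ``GT`` count otherwise) or as a tab-delimited dosage matrix;
* a phenotype/covariate table with earnings, demographics, preference
  scores, auxiliary polygenic scores, province and 42 ancestry
  proportions.

All readers validate strictly and return typed in-memory containers so
downstream modules never touch raw files.  Dosages are always expressed
on the weight table's effect allele: when the source counts the other
allele the dosage is reflected (``2 - d``) and a flip flag recorded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")

#: The 42 ancestral populations carried as per-individual admixture
#: proportions, ordered from highest to lowest cohort mean.
ANCESTRY_POPULATIONS = (
    "northern_han", "southern_han", "mongolian", "naxi_yi", "japanese",
    "gaoshan", "korean", "dai", "she", "kinh", "tibetan", "tungus",
    "ashkenazi", "balkan", "bantusa", "bengali", "cambodian", "egyptian",
    "english", "eskimo", "finnish_russian", "french", "hungarian",
    "iranian", "kyrgyz", "lahu", "mala", "mayan", "mbuti", "miao_yao",
    "papuan", "pima", "sardinian", "saudi", "sindhi", "somali", "spanish",
    "thai", "uygur", "uzbek", "yakut", "yoruba",
)

ANCESTRY_COLUMNS = tuple(f"anc_{p}" for p in ANCESTRY_POPULATIONS)

#: Phenotype columns every table must provide (ancestry columns aside).
REQUIRED_PHENOTYPE_COLUMNS = (
    "sample_id", "earnings", "age", "male", "schooling", "height",
    "risk_loving", "altruism", "trust",
    "pgs_cognitive", "pgs_depression", "pgs_delay", "pgs_reproduction",
    "province", "student",
)

_WEIGHT_COLUMN_ALIASES = {
    "rsid": "snp_id", "snp_id": "snp_id", "snp": "snp_id", "id": "snp_id",
    "effect_allele": "effect_allele", "other_allele": "other_allele",
    "reference_allele": "other_allele",
    "effect_weight": "beta", "beta": "beta", "effect_size": "beta",
}


@dataclass
class WeightTable:
    """Per-SNP effect alleles and effect sizes (cm per effect-allele copy)."""

    table: pd.DataFrame  # columns: snp_id, effect_allele, other_allele, beta

    def __post_init__(self) -> None:
        t = self.table
        if t["snp_id"].duplicated().any():
            dups = t.loc[t["snp_id"].duplicated(), "snp_id"].tolist()
            raise ValueError(f"duplicate snp_id in weight table: {dups[:5]}")
        for col in ("effect_allele", "other_allele"):
            bad = ~t[col].isin(VALID_ALLELES)
            if bad.any():
                raise ValueError(
                    f"unknown allele symbol in column {col!r}: "
                    f"{sorted(set(t.loc[bad, col]))}"
                )
        if (t["effect_allele"] == t["other_allele"]).any():
            raise ValueError("effect_allele equals other_allele for some SNPs")
        betas = t["beta"].to_numpy()
        if not np.all(np.isfinite(betas)):
            raise ValueError("non-finite effect size in weight table")
        ambiguous = (
            t["effect_allele"].map({"A": "T", "T": "A", "C": "G", "G": "C"})
            == t["other_allele"]
        )
        if ambiguous.any():
            logger.warning(
                "%d strand-ambiguous (A/T or C/G) SNPs kept as-is",
                int(ambiguous.sum()),
            )

    @property
    def n_snps(self) -> int:
        return len(self.table)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.table["snp_id"].to_numpy()

    @property
    def betas(self) -> np.ndarray:
        return self.table["beta"].to_numpy(dtype=float)


@dataclass
class DosageMatrix:
    """n x J effect-allele dosages with missingness encoded as NaN."""

    sample_ids: np.ndarray
    snp_ids: np.ndarray
    dosages: np.ndarray          # float (n, J), NaN where missing
    flipped: np.ndarray          # bool (J,), True where source alleles reflected

    def __post_init__(self) -> None:
        n, j = self.dosages.shape
        if len(self.sample_ids) != n or len(self.snp_ids) != j:
            raise ValueError("dosage matrix dimensions inconsistent with id lists")
        if self.dosages.size and not np.all(np.isnan(self.dosages)):
            if np.nanmin(self.dosages) < 0 or np.nanmax(self.dosages) > 2:
                raise ValueError("dosage outside [0, 2]")
        if len(self.flipped) != j:
            raise ValueError("flip flags inconsistent with SNP count")

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosages)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]


@dataclass
class PhenotypeTable:
    """Validated phenotype/covariate table with log earnings attached."""

    table: pd.DataFrame
    n_dropped_nonpositive: int = 0
    exclusion_counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in REQUIRED_PHENOTYPE_COLUMNS if c not in t.columns]
        if missing:
            raise ValueError(f"missing required phenotype columns: {missing}")
        anc = [c for c in t.columns if c.startswith("anc_")]
        if len(anc) != 42:
            raise ValueError(f"expected 42 ancestry columns, found {len(anc)}")
        if t["sample_id"].duplicated().any():
            raise ValueError("duplicated sample_id in phenotype table")
        sums = t[anc].to_numpy(dtype=float).sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-8):
            raise ValueError("ancestry proportions do not sum to 1")
        if "log_earnings" not in t.columns:
            t["log_earnings"] = np.log(t["earnings"].to_numpy(dtype=float))

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def ancestry_columns(self) -> list[str]:
        return [c for c in self.table.columns if c.startswith("anc_")]


# ---------------------------------------------------------------------------
# weight table i/o


def read_weights(path: str | Path) -> WeightTable:
    """Read a PGS-Catalog-style scoring file into a :class:`WeightTable`."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#", dtype=str)
    renames = {}
    for col in df.columns:
        key = col.strip().lower()
        if key in _WEIGHT_COLUMN_ALIASES:
            renames[col] = _WEIGHT_COLUMN_ALIASES[key]
    df = df.rename(columns=renames)
    needed = ["snp_id", "effect_allele", "other_allele", "beta"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"weight file lacks columns {missing}")
    try:
        beta = pd.to_numeric(df["beta"], errors="raise").astype(float)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric effect size in weight file: {exc}") from exc
    out = pd.DataFrame(
        {
            "snp_id": df["snp_id"].str.strip(),
            "effect_allele": df["effect_allele"].str.strip().str.upper(),
            "other_allele": df["other_allele"].str.strip().str.upper(),
            "beta": beta,
        }
    )
    return WeightTable(out)


def write_weights(weights: WeightTable, path: str | Path) -> None:
    df = weights.table.rename(
        columns={"snp_id": "rsID", "beta": "effect_weight"}
    )[["rsID", "effect_allele", "other_allele", "effect_weight"]]
    df.to_csv(path, sep="\t", index=False)


def default_weights() -> WeightTable:
    """Bundled synthetic 697-SNP height scoring file (stand-in weights)."""
    ref = resources.files("polyiv.data") / "synthetic_height_weights.tsv"
    with resources.as_file(ref) as path:
        return read_weights(path)


# ---------------------------------------------------------------------------
# dosage i/o


def read_dosages(path: str | Path, weights: WeightTable) -> DosageMatrix:
    """Read genotype dosages and align them to the weight table's alleles.

    VCF input uses the ``DS`` FORMAT field when present, otherwise the
    additive count of ALT alleles from ``GT`` (half-calls are missing).
    Delimited input is a SNP-by-sample matrix with ``snp_id``,
    ``counted_allele`` and ``other_allele`` leader columns.  SNPs listed
    in the weight table but absent from the source come back wholly
    missing; SNPs whose alleles cannot be reconciled are dropped with a
    warning.
    """
    path = Path(path)
    if path.suffix in {".vcf", ".gz", ".bcf"}:
        sample_ids, records = _read_vcf_records(path)
    else:
        sample_ids, records = _read_dosage_tsv(path)

    n = len(sample_ids)
    j = weights.n_snps
    dosages = np.full((n, j), np.nan)
    flipped = np.zeros(j, dtype=bool)
    wt = weights.table.set_index("snp_id")
    for col, snp_id in enumerate(weights.snp_ids):
        if snp_id not in records:
            continue
        counted, other, values = records[snp_id]
        eff = wt.at[snp_id, "effect_allele"]
        alt = wt.at[snp_id, "other_allele"]
        if counted == eff and (other == alt or other is None):
            dosages[:, col] = values
        elif counted == alt and (other == eff or other is None):
            dosages[:, col] = 2.0 - values
            flipped[col] = True
        else:
            logger.warning(
                "SNP %s dropped: source alleles %s/%s do not match %s/%s",
                snp_id, counted, other, eff, alt,
            )
    return DosageMatrix(
        sample_ids=np.asarray(sample_ids),
        snp_ids=weights.snp_ids.copy(),
        dosages=dosages,
        flipped=flipped,
    )


def _read_vcf_records(path: Path):
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    records: dict[str, tuple[str, str | None, np.ndarray]] = {}
    for variant in vcf:
        if variant.ID is None or len(variant.ALT) != 1:
            continue
        ds = None
        try:
            ds = variant.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            values = np.asarray(ds, dtype=float).reshape(-1)
            values = np.where(values < 0, np.nan, values)
        else:
            values = np.empty(len(sample_ids))
            for i, gt in enumerate(variant.genotypes):
                alleles = gt[:-1]
                if any(a < 0 for a in alleles):
                    values[i] = np.nan
                else:
                    values[i] = float(sum(1 for a in alleles if a == 1))
        records[variant.ID] = (variant.ALT[0], variant.REF, values)
    vcf.close()
    if np.nanmin([np.nanmin(v[2]) for v in records.values()] or [0]) < 0 or (
        np.nanmax([np.nanmax(v[2]) for v in records.values()] or [0]) > 2
    ):
        raise ValueError("dosage outside [0, 2] in VCF")
    return sample_ids, records


def _read_dosage_tsv(path: Path):
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str})
    leaders = [c for c in ("snp_id", "counted_allele", "other_allele") if c in df.columns]
    if "snp_id" not in leaders:
        raise ValueError("dosage matrix lacks a snp_id column")
    sample_cols = [c for c in df.columns if c not in leaders]
    values = df[sample_cols].to_numpy(dtype=float)
    if np.nanmin(values, initial=0) < 0 or np.nanmax(values, initial=0) > 2:
        raise ValueError("dosage outside [0, 2] in matrix")
    records = {}
    for i, row in df.iterrows():
        counted = row.get("counted_allele")
        other = row.get("other_allele")
        records[row["snp_id"]] = (
            None if pd.isna(counted) else str(counted),
            None if (other is None or pd.isna(other)) else str(other),
            values[i],
        )
    return sample_cols, records


def write_vcf(dosages: DosageMatrix, weights: WeightTable, path: str | Path) -> None:
    """Write hard-called genotypes as VCF 4.2 (REF = other, ALT = effect).

    Non-integer or missing dosages are emitted as ``DS`` alongside ``GT``.
    """
    wt = weights.table.set_index("snp_id")
    hard = np.all(
        np.isin(dosages.dosages[~np.isnan(dosages.dosages)], (0.0, 1.0, 2.0))
    )
    gt_codes = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if not hard:
            fh.write(
                '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n'
            )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in dosages.sample_ids)
            + "\n"
        )
        fmt = "GT" if hard else "GT:DS"
        for col, snp_id in enumerate(dosages.snp_ids):
            eff = wt.at[snp_id, "effect_allele"]
            oth = wt.at[snp_id, "other_allele"]
            vals = dosages.dosages[:, col]
            fields = []
            for v in vals:
                if np.isnan(v):
                    fields.append("./." if hard else "./.:.")
                elif hard:
                    fields.append(gt_codes[v])
                else:
                    gt = gt_codes.get(v, "./.")
                    fields.append(f"{gt}:{float(v)!r}")
            fh.write(
                f"1\t{1000 + col}\t{snp_id}\t{oth}\t{eff}\t.\tPASS\t.\t{fmt}\t"
                + "\t".join(fields)
                + "\n"
            )


# ---------------------------------------------------------------------------
# phenotype i/o


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read the phenotype table, dropping rows with non-positive earnings."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required phenotype columns: {missing}")
    anc = [c for c in df.columns if c.startswith("anc_")]
    if len(anc) != 42:
        raise ValueError(f"expected 42 ancestry columns, found {len(anc)}")
    bad = ~(df["earnings"].to_numpy(dtype=float) > 0)
    n_dropped = int(bad.sum())
    if n_dropped:
        logger.info("dropped %d rows with non-positive earnings", n_dropped)
        df = df.loc[~bad].reset_index(drop=True)
    df = df.drop(columns=["log_earnings"], errors="ignore")
    return PhenotypeTable(df, n_dropped_nonpositive=n_dropped)


def write_phenotypes(pheno: PhenotypeTable, path: str | Path) -> None:
    pheno.table.to_csv(path, sep="\t", index=False)
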