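"""Reading, writing and validation of every external artifact the pipeline touches.

The pipeline consumes four inputs — a candidate-SNP marker panel, a genotype
matrix (VCF or a simple rsID-headered dosage table), a covariate table and a
quantitative phenotype vector — and emits delimiter-separated QC, pruning and
scan-result tables.  Genotypes are stored as minor-allele dosages: 0 and 2 are
the major- and minor-allele homozygotes, 1 the heterozygote, NaN a missing
call.  Minor-allele orientation is defined once, by the panel table, so the
coding is stable across datasets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SnpMarker",
    "GenotypeMatrix",
    "CovariateTable",
    "PhenotypeVector",
    "FormatError",
    "ValidationError",
    "read_marker_panel",
    "load_reference_panel",
    "read_genotypes",
    "read_covariates",
    "read_phenotype",
    "write_genotypes",
    "write_covariates",
    "write_phenotype",
    "write_scan_results",
    "align_cohort",
]

logger = logging.getLogger(__name__)

COVARIATE_COLUMNS = ("sex", "age", "bmi", "physical_activity", "calcium_intake")


class FormatError(ValueError):
    """A file does not conform to the expected layout (missing column, bad cell)."""


class ValidationError(ValueError):
    """Structurally valid input that violates a domain invariant."""


@dataclass(frozen=True)
class SnpMarker:
    """One candidate-panel entry: identity, locus, alleles and population MAF."""

    rsid: str
    chromosome: str
    gene: str
    major_allele: str
    minor_allele: str
    panel_maf: float | None = None

    def __post_init__(self) -> None:
        if not self.rsid:
            raise ValidationError("marker rsid must be non-empty")
        if self.major_allele == self.minor_allele:
            raise ValidationError(
                f"{self.rsid}: major and minor allele are both {self.major_allele!r}"
            )
        if self.panel_maf is not None and not 0.0 <= self.panel_maf <= 0.5:
            raise ValidationError(
                f"{self.rsid}: panel MAF {self.panel_maf} outside [0, 0.5]"
            )


@dataclass
class GenotypeMatrix:
    """Samples x markers minor-allele dosage matrix with explicit missingness.

    ``dosages`` is a float array; entries are 0/1/2 (count of the marker's
    minor allele) or NaN for a missing call.
    """

    sample_ids: list[str]
    markers: list[SnpMarker]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if n != len(self.sample_ids):
            raise ValidationError(
                f"dosage rows ({n}) != sample ids ({len(self.sample_ids)})"
            )
        if m != len(self.markers):
            raise ValidationError(
                f"dosage columns ({m}) != markers ({len(self.markers)})"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids in genotype matrix")
        ok = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = self.dosages[~ok].flat[0]
            raise ValidationError(f"dosage value {bad!r} not in {{0, 1, 2, NaN}}")

    @property
    def rsids(self) -> list[str]:
        return [m.rsid for m in self.markers]

    def column(self, rsid: str) -> np.ndarray:
        """Dosage column for one marker."""
        try:
            j = self.rsids.index(rsid)
        except ValueError:
            raise KeyError(f"marker {rsid!r} not in matrix") from None
        return self.dosages[:, j]

    def subset(self, rsids: Sequence[str]) -> "GenotypeMatrix":
        """New matrix restricted to ``rsids``, in the given order."""
        idx = {m.rsid: j for j, m in enumerate(self.markers)}
        cols = [idx[r] for r in rsids]
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            markers=[self.markers[j] for j in cols],
            dosages=self.dosages[:, cols].copy(),
        )

    def take_samples(self, row_idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in row_idx],
            markers=list(self.markers),
            dosages=self.dosages[row_idx, :].copy(),
        )


@dataclass
class CovariateTable:
    """Per-sample adjustment variables, aligned to the phenotype and genotypes."""

    sample_ids: list[str]
    data: pd.DataFrame  # columns: sex, age, bmi, physical_activity, calcium_intake

    def __post_init__(self) -> None:
        missing = [c for c in COVARIATE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValidationError(f"covariate table lacks columns {missing}")
        if len(self.data) != len(self.sample_ids):
            raise ValidationError("covariate rows != sample ids")
        sex = self.data["sex"].to_numpy(dtype=float)
        if not np.isin(sex[~np.isnan(sex)], (0.0, 1.0)).all():
            raise ValidationError("sex must be coded 0 (male) / 1 (female)")

    def as_array(self) -> np.ndarray:
        """n x 5 float array in canonical column order (NaN marks missing)."""
        return self.data.loc[:, list(COVARIATE_COLUMNS)].to_numpy(dtype=float)

    def take_samples(self, row_idx: np.ndarray) -> "CovariateTable":
        return CovariateTable(
            sample_ids=[self.sample_ids[i] for i in row_idx],
            data=self.data.iloc[row_idx].reset_index(drop=True),
        )


@dataclass
class PhenotypeVector:
    """Broadband ultrasound attenuation (BUA, dB/MHz) per sample; NaN = missing."""

    sample_ids: list[str]
    bua: np.ndarray

    def __post_init__(self) -> None:
        self.bua = np.asarray(self.bua, dtype=float)
        if self.bua.ndim != 1 or len(self.bua) != len(self.sample_ids):
            raise ValidationError("phenotype length != sample ids")
        if np.isinf(self.bua).any():
            raise ValidationError("phenotype contains non-finite (inf) values")

    def take_samples(self, row_idx: np.ndarray) -> "PhenotypeVector":
        return PhenotypeVector(
            sample_ids=[self.sample_ids[i] for i in row_idx],
            bua=self.bua[row_idx].copy(),
        )


# ---------------------------------------------------------------------------
# readers


def _read_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV (default) or CSV by sniffing the header line's delimiter."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_marker_panel(path: str | Path) -> list[SnpMarker]:
    """Parse a marker-panel table into an ordered list of :class:`SnpMarker`.

    Required columns: rsid, chromosome, gene, major_allele, minor_allele.
    A ``maf`` column is optional; extra columns (e.g. published HWE p-values)
    are ignored.  Duplicate rsIDs are rejected.
    """
    df = _read_table(path)
    required = ["rsid", "chromosome", "gene", "major_allele", "minor_allele"]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"panel file {path} missing required column {col!r}")
    markers: list[SnpMarker] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        rsid = row["rsid"].strip()
        if rsid in seen:
            raise ValidationError(f"duplicate marker {rsid!r} in panel {path}")
        seen.add(rsid)
        maf = None
        if "maf" in df.columns and row["maf"].strip() not in ("", "NA"):
            maf = float(row["maf"])
        markers.append(
            SnpMarker(
                rsid=rsid,
                chromosome=row["chromosome"].strip(),
                gene=row["gene"].strip(),
                major_allele=row["major_allele"].strip(),
                minor_allele=row["minor_allele"].strip(),
                panel_maf=maf,
            )
        )
    return markers


def load_reference_panel() -> list[SnpMarker]:
    """The packaged 32-SNP candidate panel for heel-QUS/BMD loci."""
    with resources.as_file(
        resources.files("epiqus.data").joinpath("table1_panel.tsv")
    ) as p:
        return read_marker_panel(p)


_MISSING_TOKENS = {"", "NA", "NaN", "nan", ".", "-9"}


def read_genotypes(
    path: str | Path, panel: Sequence[SnpMarker]
) -> GenotypeMatrix:
    """Read genotypes from a VCF (``.vcf``/``.vcf.gz``) or a dosage matrix.

    Dosages are oriented so each value counts copies of the panel's declared
    minor allele.  Panel markers absent from the file are reported via a
    logger warning and dropped from the returned matrix.
    """
    path = Path(path)
    if path.suffix == ".vcf" or path.name.endswith(".vcf.gz"):
        return _read_genotypes_vcf(path, panel)
    return _read_genotypes_matrix(path, panel)


def _read_genotypes_matrix(
    path: Path, panel: Sequence[SnpMarker]
) -> GenotypeMatrix:
    df = _read_table(path)
    if df.columns[0] not in ("sample_id", "sample", "id", "iid"):
        raise FormatError(
            f"dosage matrix {path}: first column must be the sample id "
            f"(got {df.columns[0]!r})"
        )
    sample_ids = df.iloc[:, 0].tolist()
    present = [m for m in panel if m.rsid in df.columns]
    missing_markers = [m.rsid for m in panel if m.rsid not in df.columns]
    if missing_markers:
        logger.warning(
            "%d panel markers absent from %s: %s",
            len(missing_markers), path, ", ".join(missing_markers),
        )
    if not present:
        raise FormatError(f"dosage matrix {path} contains no panel markers")
    n = len(sample_ids)
    dos = np.full((n, len(present)), np.nan)
    for j, m in enumerate(present):
        col = df[m.rsid]
        for i, cell in enumerate(col):
            cell = cell.strip()
            if cell in _MISSING_TOKENS:
                continue
            try:
                v = float(cell)
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric dosage {cell!r} at row {i + 2}, "
                    f"marker {m.rsid}"
                ) from None
            dos[i, j] = v
    return GenotypeMatrix(sample_ids=sample_ids, markers=present, dosages=dos)


def _read_genotypes_vcf(path: Path, panel: Sequence[SnpMarker]) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    by_rsid = {m.rsid: m for m in panel}
    cols: dict[str, np.ndarray] = {}
    for variant in vcf:
        rsid = variant.ID
        if rsid is None or rsid not in by_rsid:
            continue
        m = by_rsid[rsid]
        ref, alts = variant.REF, variant.ALT
        if len(alts) != 1:
            raise ValidationError(
                f"{path}: marker {rsid} is not biallelic (ALT={alts})"
            )
        alt = alts[0]
        if {ref, alt} != {m.major_allele, m.minor_allele}:
            raise ValidationError(
                f"{path}: marker {rsid} alleles {ref}/{alt} do not match panel "
                f"{m.major_allele}/{m.minor_allele}"
            )
        col = np.full(len(sample_ids), np.nan)
        for i, gt in enumerate(variant.genotypes):
            a0, a1 = gt[0], gt[1]
            if a0 < 0 or a1 < 0:  # any missing allele -> missing call
                continue
            col[i] = a0 + a1
        if alt == m.major_allele:  # file counts major allele: flip orientation
            col = 2.0 - col
        cols[rsid] = col
    present = [m for m in panel if m.rsid in cols]
    absent = [m.rsid for m in panel if m.rsid not in cols]
    if absent:
        logger.warning(
            "%d panel markers absent from %s: %s",
            len(absent), path, ", ".join(absent),
        )
    if not present:
        raise FormatError(f"VCF {path} contains no panel markers")
    dos = np.column_stack([cols[m.rsid] for m in present])
    return GenotypeMatrix(sample_ids=sample_ids, markers=present, dosages=dos)


_SEX_CODES = {"0": 0.0, "1": 1.0, "M": 0.0, "F": 1.0, "m": 0.0, "f": 1.0}


def read_covariates(path: str | Path) -> CovariateTable:
    """Read the per-sample covariate table (sex, age, BMI, activity, calcium).

    Sex is accepted as 0/1 or M/F and normalised to 0 = male, 1 = female.
    """
    df = _read_table(path)
    if df.columns[0] not in ("sample_id", "sample", "id", "iid"):
        raise FormatError(f"covariate table {path}: first column must be sample id")
    for col in COVARIATE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"covariate table {path} missing column {col!r}")
    sample_ids = df.iloc[:, 0].tolist()
    out: dict[str, list[float]] = {c: [] for c in COVARIATE_COLUMNS}
    for i, (_, row) in enumerate(df.iterrows()):
        sex_raw = row["sex"].strip()
        if sex_raw in _MISSING_TOKENS:
            out["sex"].append(np.nan)
        elif sex_raw in _SEX_CODES:
            out["sex"].append(_SEX_CODES[sex_raw])
        else:
            raise ValidationError(
                f"{path}: row {i + 2}: sex {sex_raw!r} not in {{0,1,M,F}}"
            )
        for col in COVARIATE_COLUMNS[1:]:
            cell = row[col].strip()
            if cell in _MISSING_TOKENS:
                out[col].append(np.nan)
                continue
            try:
                out[col].append(float(cell))
            except ValueError:
                raise FormatError(
                    f"{path}: row {i + 2}: non-numeric {col} value {cell!r}"
                ) from None
    return CovariateTable(sample_ids=sample_ids, data=pd.DataFrame(out))


def read_phenotype(path: str | Path) -> PhenotypeVector:
    """Read the BUA phenotype table (columns: sample id, ``bua``)."""
    df = _read_table(path)
    if "bua" not in df.columns:
        raise FormatError(f"phenotype table {path} missing column 'bua'")
    sample_ids = df.iloc[:, 0].tolist()
    vals = []
    for i, cell in enumerate(df["bua"]):
        cell = cell.strip()
        if cell in _MISSING_TOKENS:
            vals.append(np.nan)
        else:
            try:
                vals.append(float(cell))
            except ValueError:
                raise FormatError(
                    f"{path}: row {i + 2}: non-numeric BUA value {cell!r}"
                ) from None
    return PhenotypeVector(sample_ids=sample_ids, bua=np.asarray(vals))


# ---------------------------------------------------------------------------
# writers


def write_genotypes(genotypes: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(genotypes.dosages, columns=genotypes.rsids)
    df = df.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    df.insert(0, "sample_id", genotypes.sample_ids)
    df.to_csv(path, sep="\t", index=False)


def write_covariates(covariates: CovariateTable, path: str | Path) -> None:
    df = covariates.data.loc[:, list(COVARIATE_COLUMNS)].copy()
    df["sex"] = df["sex"].astype("Int64")  # 0/1, not 0.0/1.0
    df.insert(0, "sample_id", covariates.sample_ids)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_phenotype(phenotype: PhenotypeVector, path: str | Path) -> None:
    df = pd.DataFrame({"sample_id": phenotype.sample_ids, "bua": phenotype.bua})
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_scan_results(results: Sequence, path: str | Path) -> None:
    """Write interaction-scan results, one row per SNP pair, sorted by p.

    Emits both the publication rendering (beta and 95% CI to 3 decimals,
    p-value to 3 decimals) and full-precision machine-readable columns.
    Non-estimable pairs sort to the end.
    """
    rows = []
    for r in results:
        if r.estimable:
            rendered_beta = (
                f"{r.beta_interaction:.3f} ({r.ci_low:.3f}, {r.ci_high:.3f})"
            )
            rendered_p = f"{r.p_value:.3f}"
        else:
            rendered_beta, rendered_p = "NE", "NE"
        rows.append(
            {
                "SNP1": r.rsid1,
                "gene1": r.gene1,
                "SNP2": r.rsid2,
                "gene2": r.gene2,
                "beta_95ci": rendered_beta,
                "p": rendered_p,
                "beta_interaction": r.beta_interaction,
                "se": r.se,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p_value": r.p_value,
                "n_used": r.n_used,
                "coding": r.coding,
                "estimable": r.estimable,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "SNP1", "gene1", "SNP2", "gene2", "beta_95ci", "p",
            "beta_interaction", "se", "ci_low", "ci_high", "p_value",
            "n_used", "coding", "estimable",
        ],
    )
    if len(df):
        sort_p = df["p_value"].where(df["estimable"], np.inf)
        order = np.lexsort(
            (df["SNP2"], df["SNP1"], -df["beta_interaction"].abs().fillna(0),
             sort_p.fillna(np.inf))
        )
        df = df.iloc[order]
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# alignment


def align_cohort(
    genotypes: GenotypeMatrix,
    covariates: CovariateTable,
    phenotype: PhenotypeVector,
) -> tuple[GenotypeMatrix, CovariateTable, PhenotypeVector]:
    """Intersect the three artifacts on sample id and drop incomplete samples.

    Samples missing any covariate or the phenotype are dropped (complete-case
    analysis) with a logged count; per-marker genotype missingness is kept and
    handled per pair downstream.  Raises if no samples survive.
    """
    cov_idx = {s: i for i, s in enumerate(covariates.sample_ids)}
    phe_idx = {s: i for i, s in enumerate(phenotype.sample_ids)}
    g_rows, c_rows, p_rows = [], [], []
    n_unmatched = n_incomplete = 0
    cov_arr = covariates.as_array()
    for i, s in enumerate(genotypes.sample_ids):
        if s not in cov_idx or s not in phe_idx:
            n_unmatched += 1
            continue
        ci, pi = cov_idx[s], phe_idx[s]
        if np.isnan(cov_arr[ci]).any() or np.isnan(phenotype.bua[pi]):
            n_incomplete += 1
            continue
        g_rows.append(i)
        c_rows.append(ci)
        p_rows.append(pi)
    if n_unmatched:
        logger.warning("%d samples lacked covariates or phenotype rows", n_unmatched)
    if n_incomplete:
        logger.info("%d samples dropped for missing covariate/phenotype values",
                    n_incomplete)
    if not g_rows:
        raise ValidationError("no samples remain after alignment")
    g = genotypes.take_samples(np.asarray(g_rows))
    c = covariates.take_samples(np.asarray(c_rows))
    p = phenotype.take_samples(np.asarray(p_rows))
    assert g.sample_ids == c.sample_ids == p.sample_ids
    return g, c, p
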