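"""Case-control genotype/factor matrices: containers, I/O and simple pre-filters.

SNP genotypes are coded 0/1/2 for aa/Aa/AA (code 2 = major homozygote);
environmental factors are small non-negative integer category codes.
Phenotypes are binary case/control labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

SNP = "snp"
ENVIRONMENT = "environment"

CASE = 1
CONTROL = 0

_SNP_CODES = frozenset({0, 1, 2})


class ParseError(ValueError):
    """Raised when a genotype table violates the format contract."""


@dataclass(frozen=True)
class FactorValueSpec:
    """Valid category codes for one factor, optionally with readable names."""

    factor_id: str
    levels: tuple[int, ...]
    level_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not self.levels:
            raise ValueError("levels must be non-empty")
        if len(set(self.levels)) != len(self.levels):
            raise ValueError("level codes must be distinct")
        if self.level_names is not None and len(self.level_names) != len(self.levels):
            raise ValueError("level_names must match levels in length")


@dataclass(frozen=True)
class PhenotypeLabels:
    """Binary phenotype vector; 1 = case, 0 = control."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.int8)
        object.__setattr__(self, "labels", labels)
        if labels.ndim != 1:
            raise ValueError("labels must be a 1-D vector")
        if not np.isin(labels, [CASE, CONTROL]).all():
            raise ValueError("labels must be 0 (control) or 1 (case)")
        if self.n_cases == 0 or self.n_controls == 0:
            raise ValueError("single-class data: need at least one case and one control")

    def __len__(self) -> int:
        return self.labels.shape[0]

    @property
    def n_cases(self) -> int:
        return int((self.labels == CASE).sum())

    @property
    def n_controls(self) -> int:
        return int((self.labels == CONTROL).sum())


@dataclass
class GenotypeMatrix:
    """m samples x n factors of category codes with an explicit missing mask.

    ``values`` holds small non-negative integers; entries under
    ``missing_mask`` are ignored (their stored value is arbitrary).
    """

    factor_ids: list[str]
    factor_kinds: list[str]
    values: np.ndarray
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int16)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x factors)")
        m, n = self.values.shape
        if len(self.factor_ids) != n or len(self.factor_kinds) != n:
            raise ValueError("factor_ids/factor_kinds must match the number of columns")
        if len(set(self.factor_ids)) != n:
            raise ValueError("duplicate factor id")
        if any(not fid for fid in self.factor_ids):
            raise ValueError("factor ids must be non-empty")
        if any(k not in (SNP, ENVIRONMENT) for k in self.factor_kinds):
            raise ValueError("factor kinds must be 'snp' or 'environment'")
        if self.missing_mask is None:
            self.missing_mask = np.zeros((m, n), dtype=bool)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != (m, n):
            raise ValueError("missing_mask shape mismatch")
        snp_cols = [j for j, k in enumerate(self.factor_kinds) if k == SNP]
        for j in snp_cols:
            observed = self.values[~self.missing_mask[:, j], j]
            bad = ~np.isin(observed, [0, 1, 2])
            if bad.any():
                i = int(np.nonzero(~self.missing_mask[:, j])[0][np.nonzero(bad)[0][0]])
                raise ParseError(
                    f"invalid genotype code {self.values[i, j]} at "
                    f"(row {i}, column {self.factor_ids[j]}); SNP codes are 0/1/2"
                )
        if (self.values[~self.missing_mask] < 0).any():
            raise ValueError("category codes must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_factors(self) -> int:
        return self.values.shape[1]

    def column(self, factor_id: str) -> np.ndarray:
        return self.values[:, self.factor_ids.index(factor_id)]

    def select(self, factor_ids: Sequence[str]) -> "GenotypeMatrix":
        """Restrict to the given factors, preserving their requested order."""
        idx = [self.factor_ids.index(f) for f in factor_ids]
        return GenotypeMatrix(
            factor_ids=[self.factor_ids[j] for j in idx],
            factor_kinds=[self.factor_kinds[j] for j in idx],
            values=self.values[:, idx].copy(),
            missing_mask=self.missing_mask[:, idx].copy(),
        )


# ---------------------------------------------------------------------------
# I/O


def read_genotype_table(
    path: str | Path,
    dialect: str = "tsv",
    label_column: str = "class",
    missing_token: str = "NA",
    environment_columns: Sequence[str] = (),
) -> tuple[GenotypeMatrix, PhenotypeLabels]:
    """Read a delimited genotype table into a matrix and phenotype labels.

    ``tsv``/``csv``: header row of factor ids, one sample per row, a label
    column (default "class") with 1 = case / 0 = control, missing cells as
    ``missing_token``.  ``plink_raw``: PLINK additive-coded .raw with
    FID/IID/PAT/MAT/SEX/PHENOTYPE leading columns, PHENOTYPE 2 = case,
    1 = control.
    """
    path = Path(path)
    if dialect in ("tsv", "csv"):
        df = pd.read_csv(
            path,
            sep="\t" if dialect == "tsv" else ",",
            na_values=[missing_token],
            keep_default_na=False,
            dtype=str,
        )
        if label_column not in df.columns:
            raise ParseError(f"label column {label_column!r} not found in {path}")
        raw_labels = df.pop(label_column)
        labels = _parse_labels(raw_labels, {"1": CASE, "0": CONTROL})
        env = set(environment_columns)
        kinds = [ENVIRONMENT if c in env else SNP for c in df.columns]
    elif dialect == "plink_raw":
        df = pd.read_csv(
            path, sep=r"\s+", na_values=[missing_token], keep_default_na=False, dtype=str
        )
        meta = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
        if not set(meta).issubset(df.columns):
            raise ParseError(f"{path} is not a PLINK .raw file (missing {meta} columns)")
        raw_labels = df["PHENOTYPE"]
        labels = _parse_labels(raw_labels, {"2": CASE, "1": CONTROL})
        df = df.drop(columns=meta)
        kinds = [SNP] * df.shape[1]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    missing = df.isna().to_numpy()
    values = np.zeros(df.shape, dtype=np.int16)
    for j, col in enumerate(df.columns):
        present = ~missing[:, j]
        cells = df[col].to_numpy()[present]
        try:
            codes = cells.astype(float)
        except ValueError as exc:
            raise ParseError(f"non-numeric cell in column {col!r}: {exc}") from None
        if (codes != np.round(codes)).any():
            i = int(np.nonzero(present)[0][np.nonzero(codes != np.round(codes))[0][0]])
            raise ParseError(f"non-integer code at (row {i}, column {col})")
        values[present, j] = codes.astype(np.int16)
    gm = GenotypeMatrix(list(df.columns), kinds, values, missing)
    if gm.n_samples != len(labels):
        raise ParseError("label/sample count mismatch")
    return gm, labels


def _parse_labels(raw: pd.Series, mapping: dict[str, int]) -> PhenotypeLabels:
    out = np.empty(len(raw), dtype=np.int8)
    for i, tok in enumerate(raw):
        tok = str(tok).strip()
        if tok not in mapping:
            raise ParseError(f"unknown phenotype value {tok!r} at row {i}")
        out[i] = mapping[tok]
    return PhenotypeLabels(out)


def write_genotype_table(
    gm: GenotypeMatrix,
    labels: PhenotypeLabels,
    path: str | Path,
    dialect: str = "tsv",
    label_column: str = "class",
    missing_token: str = "NA",
) -> None:
    """Write the matrix in the delimited-text format read_genotype_table reads."""
    if dialect not in ("tsv", "csv"):
        raise ValueError("write supports tsv/csv only")
    sep = "\t" if dialect == "tsv" else ","
    cells = gm.values.astype(object)
    cells[gm.missing_mask] = missing_token
    df = pd.DataFrame(cells, columns=gm.factor_ids)
    df[label_column] = labels.labels
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Pre-filters


def filter_by_missingness(gm: GenotypeMatrix, max_rate: float = 0.20) -> GenotypeMatrix:
    """Drop factors whose missing fraction is strictly greater than ``max_rate``.

    A factor missing exactly ``max_rate`` of its values is retained; column
    order is preserved. The 0.20 default mirrors the usual quality filter of
    excluding markers with more than 20% missing genotypes.
    """
    if not 0.0 <= max_rate <= 1.0:
        raise ValueError("max_rate must be in [0, 1]")
    rates = gm.missing_mask.mean(axis=0)
    keep = [f for f, r in zip(gm.factor_ids, rates) if r <= max_rate]
    if not keep:
        import warnings

        warnings.warn("missingness filter removed every factor", stacklevel=2)
        return GenotypeMatrix([], [], np.zeros((gm.n_samples, 0), dtype=np.int16))
    return gm.select(keep)


def impute_mode(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each missing cell with its column's most frequent code.

    Frequency ties break toward the smallest code. Raises on an all-missing
    column.
    """
    values = gm.values.copy()
    mask = gm.missing_mask
    for j in range(gm.n_factors):
        if not mask[:, j].any():
            continue
        observed = values[~mask[:, j], j]
        if observed.size == 0:
            raise ValueError(f"column {gm.factor_ids[j]!r} is entirely missing")
        codes, counts = np.unique(observed, return_counts=True)
        mode = codes[np.argmax(counts)]  # np.unique sorts, so ties -> smallest
        values[mask[:, j], j] = mode
    return GenotypeMatrix(
        list(gm.factor_ids),
        list(gm.factor_kinds),
        values,
        np.zeros_like(mask),
    )


def allelic_chi2(
    snp_column: np.ndarray, labels: PhenotypeLabels
) -> tuple[float, float, int]:
    """Pearson chi-square on the 2x2 allele-count-by-class table.

    Each genotype g contributes g copies of the major allele A and 2-g of a.
    No continuity correction. A zero margin (monomorphic SNP or empty class
    allele pool) yields statistic 0 with p = 1.

    Returns ``(statistic, p_value, df)`` with df = 1.
    """
    g = np.asarray(snp_column, dtype=float)
    y = labels.labels
    if not np.isin(g, [0, 1, 2]).all():
        raise ValueError("snp_column must contain genotype codes 0/1/2 only")
    table = np.empty((2, 2), dtype=float)
    for row, cls in enumerate((CASE, CONTROL)):
        gg = g[y == cls]
        table[row, 0] = gg.sum()            # A alleles
        table[row, 1] = (2 - gg).sum()      # a alleles
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 0.0, 1.0, 1
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    stat = float(((table - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(stat, df=1))
    return stat, p, 1


def filter_by_association(
    gm: GenotypeMatrix, labels: PhenotypeLabels, alpha: float = 0.05
) -> GenotypeMatrix:
    """Keep SNPs whose allelic chi-square p-value is below ``alpha``.

    Environment factors are always retained (the test is allelic).
    """
    keep = []
    for j, fid in enumerate(gm.factor_ids):
        if gm.factor_kinds[j] != SNP:
            keep.append(fid)
            continue
        _, p, _ = allelic_chi2(gm.values[:, j], labels)
        if p < alpha:
            keep.append(fid)
    return gm.select(keep)


def discretize_age(ages: Sequence[float]) -> np.ndarray:
    """Gaussian discretization of age into {"young", "medium", "elderly"}.

    With mu the mean and sigma the population standard deviation:
    x <= mu - sigma/2 -> young; x >= mu + sigma/2 -> elderly; else medium.
    """
    x = np.asarray(ages, dtype=float)
    sigma = float(np.std(x))  # population sd, fixed for reproducibility
    if sigma == 0.0:
        raise ValueError("constant ages: sigma is zero")
    mu = float(np.mean(x))
    out = np.full(x.shape, "medium", dtype=object)
    out[x <= mu - sigma / 2] = "young"
    out[x >= mu + sigma / 2] = "elderly"
    return out


AGE_SPEC = FactorValueSpec("Age", (0, 1, 2), ("young", "medium", "elderly"))
SEX_SPEC = FactorValueSpec("Sex", (0, 1))
SMOKING_SPEC = FactorValueSpec("Smoking", (0, 1))
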