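"""Reading, preprocessing and writing of expression and covariate tables.

Expression matrices arrive as delimited text (subjects in rows, genes in
columns, log2 scale assumed upstream).  Preprocessing mirrors the standard
gene-set pipeline: listwise deletion of incomplete subjects, sign
orientation of genes whose expected response direction is opposite to the
rest of the set (e.g. anti-viral and antibody genes in the CTRA set), and
z-standardization of every column (mean 0, unit variance, n-1 denominator).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: category labels accepted in orientation files, mapped to signs.  A
#: positive mean effect then reads as a concordant response of the whole set
#: (up-regulated categories positive, down-regulated categories negated).
CATEGORY_SIGNS = {"pro-inflammatory": 1, "anti-viral": -1, "antibody": -1}


class ParseError(ValueError):
    """A cell of a delimited matrix could not be interpreted as a number."""


@dataclass
class RawExpressionTable:
    """A numeric subjects x genes matrix plus identifiers and a drop report."""

    values: np.ndarray
    subject_ids: list[str]
    gene_ids: list[str]
    dropped_subjects: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise ValueError("empty expression matrix")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("subject_ids are not unique")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids are not unique")
        if np.isnan(self.values).any():
            raise ValueError("missing values remain after cleaning")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]


@dataclass
class OrientedExpressionMatrix:
    """Standardized, sign-oriented outcome matrix Y.

    Every column has mean 0 and unit sample variance (n-1 denominator);
    columns of genes with orientation -1 were negated before
    standardization so that a positive coefficient means a set-concordant
    response.
    """

    values: np.ndarray
    gene_ids: list[str]
    orientation_applied: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, m = self.values.shape
        if n < 2 or m < 1:
            raise ValueError(f"need n >= 2 and m >= 1, got {n} x {m}")

    def validate(self, atol: float = 1e-10) -> None:
        mu = self.values.mean(axis=0)
        var = self.values.var(axis=0, ddof=1)
        if not (np.all(np.abs(mu) < atol) and np.all(np.abs(var - 1.0) < atol)):
            raise ValueError("columns are not standardized to mean 0 / variance 1")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]


@dataclass
class DesignSpec:
    """Design split into nuisance block X (with intercept) and focal block Z.

    ``X`` carries the intercept and all nuisance covariates; ``Z`` carries
    the focal predictor(s), standardized to z-scores.  Tests of one focal
    predictor treat the other focal columns as nuisance (the reduced model
    for focal k is [X, Z without column k]).
    """

    X: np.ndarray
    Z: np.ndarray
    x_names: list[str]
    z_names: list[str]
    focal_standardized: bool = True

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.Z = np.asarray(self.Z, dtype=float)
        if self.Z.ndim == 1:
            self.Z = self.Z[:, None]
        if self.X.shape[0] != self.Z.shape[0]:
            raise ValueError("X and Z row counts differ")
        _check_full_rank(self.full_matrix(), self.x_names + self.z_names)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def q(self) -> int:
        return self.X.shape[1]

    @property
    def d(self) -> int:
        return self.Z.shape[1]

    def full_matrix(self) -> np.ndarray:
        return np.hstack([self.X, self.Z])

    def full_names(self) -> list[str]:
        return list(self.x_names) + list(self.z_names)

    def focal_index(self, focal: str) -> int:
        """Column index of ``focal`` in the full [X Z] matrix."""
        try:
            return self.q + self.z_names.index(focal)
        except ValueError:
            raise KeyError(f"unknown focal predictor {focal!r}") from None

    def reduced(self, focal: str) -> "DesignSpec":
        """Design with ``focal`` removed from Z and the rest moved to X."""
        if focal not in self.z_names:
            raise KeyError(f"unknown focal predictor {focal!r}")
        k = self.z_names.index(focal)
        keep = [j for j in range(self.d) if j != k]
        X = np.hstack([self.X, self.Z[:, keep]])
        x_names = list(self.x_names) + [self.z_names[j] for j in keep]
        return DesignSpec(X, np.empty((self.n, 0)), x_names, [],
                          self.focal_standardized)


def _check_full_rank(M: np.ndarray, names: list[str]) -> None:
    if M.shape[1] == 0:
        return
    _, R = np.linalg.qr(M)
    diag = np.abs(np.diag(R))
    tol = max(M.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    bad = [names[j] for j in np.nonzero(diag <= tol)[0]]
    if bad:
        raise ValueError(f"design is rank deficient; collinear columns: {bad}")


def _sniff_delimiter(path: Path, skip_prefix: str | None) -> str:
    with open(path) as fh:
        for line in fh:
            if skip_prefix and line.startswith(skip_prefix):
                continue
            if line.strip():
                return "\t" if "\t" in line else ","
    raise ValueError(f"{path}: no data lines found")


def read_matrix(path, dialect: str = "plain", delimiter: str | None = None
                ) -> RawExpressionTable:
    """Read a delimited subjects x genes matrix with header and row ids.

    ``dialect='series-matrix'`` skips metadata lines beginning with ``!``
    (the GEO Series Matrix convention).  Rows containing any missing value
    are dropped and reported.  Delimiter auto-detection is limited to tab
    and comma; pass ``delimiter`` explicitly for anything else.
    """
    path = Path(path)
    if dialect not in ("plain", "series-matrix"):
        raise ValueError(f"unknown dialect {dialect!r}")
    comment = "!" if dialect == "series-matrix" else None
    sep = delimiter or _sniff_delimiter(path, comment)
    df = pd.read_csv(path, sep=sep, comment=comment, index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: empty matrix")
    # treat conventional NA strings as missing, anything else non-numeric as a
    # parse error with the offending cell named
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna() & ~df.astype(str).isin(["NA", "NaN", "nan", ""])
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"{path}: non-numeric value {df.iat[i, j]!r} at row "
            f"{df.index[i]!r}, column {df.columns[j]!r}"
        )
    keep = numeric.notna().all(axis=1)
    dropped = [str(s) for s in numeric.index[~keep]]
    if dropped:
        logger.info("dropped %d row(s) with missing values: %s", len(dropped), dropped)
    cleaned = numeric.loc[keep]
    if cleaned.shape[0] == 0:
        raise ValueError(f"{path}: no complete rows remain")
    return RawExpressionTable(
        values=cleaned.to_numpy(dtype=float),
        subject_ids=[str(s) for s in cleaned.index],
        gene_ids=[str(g) for g in cleaned.columns],
        dropped_subjects=dropped,
    )


def write_matrix(path, values: np.ndarray, row_ids, col_ids, sep: str = "\t") -> None:
    """Write a matrix as delimited text (full float round-trip precision)."""
    df = pd.DataFrame(np.asarray(values, float), index=list(row_ids),
                      columns=list(col_ids))
    df.to_csv(path, sep=sep, float_format="%.17g")


def standardize_columns(M: np.ndarray) -> np.ndarray:
    """Center and scale every column to mean 0, sample variance 1 (ddof=1)."""
    M = np.asarray(M, dtype=float)
    if M.ndim == 1:
        M = M[:, None]
    sd = M.std(axis=0, ddof=1)
    zero = np.nonzero(sd == 0)[0]
    if zero.size:
        raise ValueError(f"constant column(s) cannot be standardized: {zero.tolist()}")
    return (M - M.mean(axis=0)) / sd


def read_orientation(path, delimiter: str | None = None) -> dict[str, int]:
    """Read a two-column gene orientation file.

    The second column is either a sign (+1/-1) or a category label from
    ``CATEGORY_SIGNS`` ({pro-inflammatory: +1, anti-viral: -1, antibody: -1}).
    """
    path = Path(path)
    sep = delimiter or _sniff_delimiter(path, None)
    df = pd.read_csv(path, sep=sep, header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: orientation file needs two columns")
    # tolerate a header row
    first = str(df.iat[0, 1]).strip().lower()
    if first not in CATEGORY_SIGNS and first not in ("1", "+1", "-1"):
        df = df.iloc[1:]
    out: dict[str, int] = {}
    for _, (gene, val) in df.iloc[:, :2].iterrows():
        key = str(gene).strip()
        sval = str(val).strip().lower()
        if sval in CATEGORY_SIGNS:
            sign = CATEGORY_SIGNS[sval]
        else:
            try:
                sign = int(float(sval))
            except ValueError:
                raise ValueError(f"{path}: bad orientation {val!r} for gene {key!r}")
        if sign not in (1, -1):
            raise ValueError(f"{path}: orientation for {key!r} must be +1/-1, got {sign}")
        out[key] = sign
    return out


def orient_genes(values: np.ndarray, gene_ids: list[str],
                 orientation: dict[str, int]) -> np.ndarray:
    """Negate columns whose orientation is -1; |z| of each entry unchanged.

    Every analyzed gene must appear in ``orientation``; genes listed there
    but absent from the matrix only trigger a warning.
    """
    missing = [g for g in gene_ids if g not in orientation]
    if missing:
        raise ValueError(f"genes missing from orientation file: {missing}")
    unknown = sorted(set(orientation) - set(gene_ids))
    if unknown:
        logger.warning("orientation file lists %d unknown gene(s): %s",
                       len(unknown), unknown)
    signs = np.array([orientation[g] for g in gene_ids], dtype=float)
    return np.asarray(values, dtype=float) * signs


def prepare_expression(raw: RawExpressionTable,
                       orientation: dict[str, int] | None = None
                       ) -> OrientedExpressionMatrix:
    """Orient (optional) then standardize an expression table into Y.

    Because columns are re-standardized afterwards, orienting before or
    after standardization yields the same matrix.
    """
    values = raw.values
    if orientation is not None:
        values = orient_genes(values, raw.gene_ids, orientation)
    out = OrientedExpressionMatrix(
        values=standardize_columns(values),
        gene_ids=list(raw.gene_ids),
        orientation_applied=orientation is not None,
    )
    out.validate()
    return out


def build_design(covariates: pd.DataFrame, focal: list[str],
                 standardize_focal: bool = True,
                 add_intercept: bool = True) -> DesignSpec:
    """Split a covariate table into a DesignSpec.

    ``focal`` columns become the standardized Z block; everything else is
    nuisance and enters X untouched, after an intercept column.
    """
    missing = [c for c in focal if c not in covariates.columns]
    if missing:
        raise KeyError(f"focal column(s) not in covariate table: {missing}")
    nuisance = [c for c in covariates.columns if c not in focal]
    Xn = covariates[nuisance].to_numpy(dtype=float)
    if add_intercept:
        X = np.hstack([np.ones((len(covariates), 1)), Xn])
        x_names = ["intercept"] + nuisance
    else:
        X, x_names = Xn, list(nuisance)
    Z = covariates[focal].to_numpy(dtype=float)
    if standardize_focal:
        Z = standardize_columns(Z)
    return DesignSpec(X=X, Z=Z, x_names=x_names, z_names=list(focal),
                      focal_standardized=standardize_focal)
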