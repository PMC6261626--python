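"""Domain containers and tab-separated matrix I/O.

Three matrix containers move through the pipeline: a region-by-time
observation matrix (``TimeSeriesMatrix``), the asymmetric regression
coefficient matrix produced by the multivariate estimators
(``RegressionWeights``), and the symmetric non-negative connectivity
matrix (``AdjacencyMatrix``) consumed by the community-detection and
graph-metric stages.  Each container validates its own invariants at
construction time so downstream code can rely on them.

File format: tab-separated text with one header row of region labels.
Time-series files carry no row labels (rows are time points); square
matrices carry the region labels both as header and as a first column.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeriesMatrix",
    "RegressionWeights",
    "AdjacencyMatrix",
    "SolverConfig",
    "MatrixFormatError",
    "MatrixParseError",
    "ShapeError",
    "DegenerateInputError",
    "ConfigError",
    "read_matrix",
    "write_matrix",
    "unit_normalize",
]

_NORM_ATOL = 1e-9
_SYM_ATOL = 1e-12


class MatrixFormatError(ValueError):
    """Structurally malformed matrix file (ragged rows, missing header...)."""


class MatrixParseError(ValueError):
    """A cell could not be parsed as a number; message names row and column."""


class ShapeError(ValueError):
    """Matrix dimensions violate a contract (e.g. square expected)."""


class DegenerateInputError(ValueError):
    """Input is degenerate for the requested operation (e.g. zero column)."""


class ConfigError(ValueError):
    """Invalid solver or run configuration."""


def _check_labels(labels: Sequence[str], n: int) -> list:
    labels = [str(lab) for lab in labels]
    if len(labels) != n:
        raise ShapeError(f"expected {n} labels, got {len(labels)}")
    return labels


@dataclass
class TimeSeriesMatrix:
    """T x N observation matrix: rows are time points, columns are regions."""

    values: np.ndarray
    labels: list = field(default_factory=list)
    normalized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ShapeError("time-series values must be a 2-D matrix")
        t, n = self.values.shape
        if t < 2 or n < 2:
            raise ShapeError(f"need T >= 2 and N >= 2, got T={t}, N={n}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time-series contains non-finite entries")
        if not self.labels:
            self.labels = [f"R{i + 1}" for i in range(n)]
        self.labels = _check_labels(self.labels, n)
        if self.normalized:
            norms = np.linalg.norm(self.values, axis=0)
            if not np.allclose(norms, 1.0, atol=_NORM_ATOL, rtol=0):
                raise ValueError("normalized flag set but columns are not unit norm")

    @property
    def n_times(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


@dataclass
class RegressionWeights:
    """N x N regression coefficient matrix with a structurally zero diagonal."""

    values: np.ndarray
    labels: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ShapeError("regression weights must be square")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("regression weights contain non-finite entries")
        if np.any(np.diag(self.values) != 0.0):
            raise ValueError("regression weights must have an exactly zero diagonal")
        n = self.values.shape[0]
        if not self.labels:
            self.labels = [f"R{i + 1}" for i in range(n)]
        self.labels = _check_labels(self.labels, n)

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass
class AdjacencyMatrix:
    """Symmetric, non-negative, zero-diagonal N x N connectivity matrix."""

    values: np.ndarray
    labels: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ShapeError("adjacency matrix must be square")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("adjacency matrix contains non-finite entries")
        if np.max(np.abs(self.values - self.values.T), initial=0.0) > _SYM_ATOL:
            raise ValueError("adjacency matrix is not symmetric within 1e-12")
        if np.any(self.values < 0):
            raise ValueError("adjacency matrix has negative entries")
        if np.any(np.diag(self.values) != 0.0):
            raise ValueError("adjacency matrix must have an exactly zero diagonal")
        n = self.values.shape[0]
        if not self.labels:
            self.labels = [f"R{i + 1}" for i in range(n)]
        self.labels = _check_labels(self.labels, n)

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


_PROX_SCALES = ("paper_factor_2", "standard_factor_1")


@dataclass
class SolverConfig:
    """ADMM solver settings.

    ``mu1`` and ``mu2`` weight the l1 and nuclear-norm penalties; ``beta_init``
    is the starting value of both augmented-Lagrangian penalty parameters,
    which are multiplied by ``rho`` each iteration up to ``beta_max``.
    ``prox_scale`` selects the shrinkage-threshold convention: the published
    algorithm thresholds at 2*mu/beta (``paper_factor_2``), equivalent to the
    standard derivation with both penalties doubled; ``standard_factor_1``
    uses mu/beta.
    """

    mu1: float = 0.25
    mu2: float = 0.1
    beta_init: float = 0.1
    rho: float = 1.1
    beta_max: float = 1e10
    tol: float = 1e-6
    max_iter: int = 500
    prox_scale: str = "paper_factor_2"

    def __post_init__(self):
        if self.mu1 < 0 or self.mu2 < 0:
            raise ConfigError("penalty weights mu1, mu2 must be >= 0")
        if self.beta_init <= 0:
            raise ConfigError("beta_init must be > 0")
        if self.rho <= 1:
            raise ConfigError("rho must be > 1")
        if self.beta_max < self.beta_init:
            raise ConfigError("beta_max must be >= beta_init")
        if self.tol <= 0:
            raise ConfigError("tol must be > 0")
        if int(self.max_iter) < 1:
            raise ConfigError("max_iter must be a positive integer")
        self.max_iter = int(self.max_iter)
        if self.prox_scale not in _PROX_SCALES:
            raise ConfigError(f"prox_scale must be one of {_PROX_SCALES}")

    @property
    def prox_factor(self) -> float:
        """Multiplier s applied to mu inside the proximal thresholds."""
        return 2.0 if self.prox_scale == "paper_factor_2" else 1.0

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SolverConfig":
        return cls(**json.loads(text))


AnyMatrix = Union[TimeSeriesMatrix, RegressionWeights, AdjacencyMatrix]


def read_matrix(path, expect_square: bool = False) -> AnyMatrix:
    """Read a TSV/CSV matrix file.

    With ``expect_square`` the first column holds row labels and the result is
    returned as an :class:`AdjacencyMatrix` when it satisfies the adjacency
    invariants, otherwise as :class:`RegressionWeights` (zero-diagonal) or a
    plain label/value pair error.  Without it the file is a time-series: one
    header row of region labels, numeric body, no row labels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        df = pd.read_csv(
            path,
            sep=sep,
            header=0,
            index_col=0 if expect_square else None,
            dtype=str,
            keep_default_na=False,
        )
    except pd.errors.ParserError as exc:
        raise MatrixFormatError(f"{path}: malformed matrix file ({exc})") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise MatrixFormatError(f"{path}: empty matrix body")

    numeric = df.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad = numeric.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        row_name = df.index[i] if expect_square else i + 1
        raise MatrixParseError(
            f"{path}: non-numeric cell {df.iat[i, j]!r} at row {row_name}, "
            f"column {df.columns[j]!r}"
        )
    values = numeric.to_numpy(dtype=float)
    labels = [str(c) for c in df.columns]

    if expect_square:
        if values.shape[0] != values.shape[1]:
            raise ShapeError(
                f"{path}: square matrix expected, got {values.shape[0]}x{values.shape[1]}"
            )
        row_labels = [str(r) for r in df.index]
        if row_labels != labels:
            raise MatrixFormatError(f"{path}: row labels do not match column labels")
        try:
            return AdjacencyMatrix(values, labels)
        except ValueError:
            return RegressionWeights(values, labels)
    return TimeSeriesMatrix(values, labels)


def write_matrix(m: AnyMatrix, path) -> None:
    """Write a matrix container as TSV; round-trips values to 1e-12."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    if isinstance(m, TimeSeriesMatrix):
        df = pd.DataFrame(m.values, columns=m.labels)
        df.to_csv(path, sep=sep, index=False, float_format="%.17g")
    else:
        df = pd.DataFrame(m.values, columns=m.labels, index=m.labels)
        df.to_csv(path, sep=sep, index=True, float_format="%.17g")


def unit_normalize(x: TimeSeriesMatrix, demean: bool = False) -> TimeSeriesMatrix:
    """Scale every region column to unit Euclidean norm.

    ``demean`` subtracts each column mean first (correlation-like behaviour);
    the default rescales the raw column, preserving its direction.  A column
    whose norm is (numerically) zero is degenerate and raises, naming the
    region.
    """
    values = x.values.astype(float, copy=True)
    if demean:
        values -= values.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(values, axis=0)
    bad = np.flatnonzero(norms <= 1e-12)
    if bad.size:
        raise DegenerateInputError(
            f"region {x.labels[bad[0]]!r} has zero-norm time-series; cannot normalize"
        )
    return TimeSeriesMatrix(values / norms, list(x.labels), normalized=True)
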