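"""Statistical kernel: G-tests on 2x2 tables, chi-square tails, Tajima's
relative rate test and bootstrap standard deviations.

The G-test (log-likelihood-ratio test of independence) is the workhorse for
every enrichment comparison in the pipeline: domain enrichment among unmapped
reads, amino-acid property changes between lineages, and SSR polymorphism
contrasts between genomic region classes.  By default no Williams correction
is applied; an uncorrected G with a chi-square df=1 upper tail reproduces the
published enrichment P-values exactly, and the correction is exposed as an
option for users who want the small-sample adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.special import xlogy
from scipy.stats import chi2


class InvalidTableError(ValueError):
    """A contingency table with a zero row or column margin."""


class UndefinedTestError(ValueError):
    """A test statistic whose denominator is empty (e.g. m1 + m2 = 0)."""


class InsufficientDataError(ValueError):
    """Fewer resampling units than the bootstrap requires."""


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b; c, d): rows are groups, columns are outcomes."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0:
                raise InvalidTableError("negative count in 2x2 table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def validate_margins(self) -> None:
        o = self.as_array()
        if np.any(o.sum(axis=0) == 0) or np.any(o.sum(axis=1) == 0):
            raise InvalidTableError("zero row or column margin")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p_value: float

    def __post_init__(self) -> None:
        if self.statistic < 0:
            raise ValueError("negative test statistic")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")

    def to_dict(self) -> dict:
        return {"statistic": self.statistic, "df": self.df, "p_value": self.p_value}


@dataclass(frozen=True)
class BootstrapConfig:
    n_replicates: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def chi2_upper_tail(x: float, df: int = 1) -> float:
    """Upper tail (survival function) of the chi-square distribution.

    For df=1 this equals erfc(sqrt(x/2)).
    """
    if x < 0:
        raise ValueError("chi-square statistic must be non-negative")
    if df < 1:
        raise ValueError("df must be a positive integer")
    return float(chi2.sf(x, df))


def gtest_2x2(table: ContingencyTable2x2, williams_correction: bool = False) -> TestResult:
    """Log-likelihood-ratio G-test of independence on a 2x2 table.

    G = 2 * sum O_ij * ln(O_ij / E_ij) with expected counts from the row and
    column margins and the convention 0*ln(0/E) = 0.  The p-value is the
    chi-square upper tail with df=1.  ``williams_correction`` divides G by
    q = 1 + ((N/r1 + N/r2 - 1) * (N/c1 + N/c2 - 1)) / (6N).
    """
    table.validate_margins()
    o = table.as_array()
    n = o.sum()
    e = np.outer(o.sum(axis=1), o.sum(axis=0)) / n
    g = 2.0 * float(xlogy(o, o / e).sum())
    g = max(g, 0.0)  # guard tiny negative round-off on equal proportions
    if williams_correction:
        r = o.sum(axis=1)
        c = o.sum(axis=0)
        q = 1.0 + ((n / r[0] + n / r[1] - 1.0) * (n / c[0] + n / c[1] - 1.0)) / (6.0 * n)
        g /= q
    return TestResult(statistic=g, df=1, p_value=chi2_upper_tail(g, 1))


def pearson_chi2(observed: np.ndarray) -> TestResult:
    """Pearson chi-square test of independence on an r x c table."""
    o = np.asarray(observed, dtype=float)
    if np.any(o.sum(axis=0) == 0) or np.any(o.sum(axis=1) == 0):
        raise InvalidTableError("zero row or column margin")
    e = np.outer(o.sum(axis=1), o.sum(axis=0)) / o.sum()
    stat = float(((o - e) ** 2 / e).sum())
    df = (o.shape[0] - 1) * (o.shape[1] - 1)
    return TestResult(statistic=stat, df=df, p_value=chi2_upper_tail(stat, df))


def tajima_rrt(m1: int, m2: int) -> TestResult:
    """Tajima's relative rate test from lineage-specific substitution counts.

    m1 (m2) is the number of sites where only taxon 1 (taxon 2) differs from
    the other taxon and the outgroup.  Under rate equality both expectations
    are (m1+m2)/2 and chi-square = (m1-m2)^2 / (m1+m2) with df=1.
    """
    if m1 < 0 or m2 < 0:
        raise ValueError("counts must be non-negative")
    if m1 + m2 == 0:
        raise UndefinedTestError("Tajima test undefined for m1 + m2 = 0")
    stat = (m1 - m2) ** 2 / (m1 + m2)
    return TestResult(statistic=stat, df=1, p_value=chi2_upper_tail(stat, 1))


def bootstrap_sd(
    values_per_unit: Sequence,
    statistic: Callable[[list], float],
    config: BootstrapConfig = BootstrapConfig(),
) -> float:
    """Bootstrap standard deviation of a statistic over resampled units.

    Units (genes) are resampled with replacement ``n_replicates`` times; the
    statistic is applied to each resample and the SD (ddof=1) of the replicate
    values is returned.  Deterministic for a fixed seed.
    """
    units = list(values_per_unit)
    if len(units) < 2:
        raise InsufficientDataError("bootstrap needs at least 2 resampling units")
    rng = np.random.default_rng(config.seed)
    n = len(units)
    reps = np.empty(config.n_replicates, dtype=float)
    for i in range(config.n_replicates):
        idx = rng.integers(0, n, size=n)
        reps[i] = statistic([units[j] for j in idx])
    return float(np.std(reps, ddof=1))


def read_tables_tsv(path) -> list[tuple[str, ContingencyTable2x2]]:
    """Read labelled 2x2 tables from a TSV with columns
    row_label, group1_with, group1_without, group2_with, group2_without."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        out.append(
            (
                str(row.iloc[0]),
                ContingencyTable2x2(int(row.iloc[1]), int(row.iloc[2]), int(row.iloc[3]), int(row.iloc[4])),
            )
        )
    return out
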