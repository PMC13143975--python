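"""Conditional-independence testing on mixed, incomplete data.

Every discovery step in the pipeline reduces to the question "is x
independent of y given S?".  Three exchangeable backends answer it:

* :class:`FisherZTester` — partial correlation on midrank-transformed
  columns with the Fisher z statistic; the default for any mix of binary,
  ordinal and cardinal variables.
* :class:`G2Tester` — the G² log-likelihood-ratio test on stratified
  contingency tables, for all-discrete variable sets.
* :class:`OracleCITester` — exact graphical d-separation on a ground-truth
  model; embodies perfect faithfulness for benchmarking.

Missing data are handled by test-wise deletion: each test uses exactly the
rows complete in {x, y} ∪ S, and the degrees of freedom / effective sample
size are adjusted to that count.  Tests that cannot be computed (too few
complete rows, zero residual variance, empty strata) return the conservative
"independent by insufficiency" outcome and are logged, never dropped.
"""

from __future__ import annotations

import math
from abc import ABC, abstractmethod
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .datamodel import Dataset, ValidationError
from .synthetic import GroundTruthModel, d_separated

_SQRT2 = math.sqrt(2.0)
# |r| is clipped here before atanh; deterministic duplicates still yield p = 0
_R_CLIP = 1.0 - 1e-16
# relative threshold below which a residual variance counts as zero
_VAR_REL_TOL = 1e-10


@dataclass(frozen=True)
class CITestResult:
    """Outcome of one conditional-independence test."""

    x: str
    y: str
    S: tuple[str, ...]
    statistic: float
    p_value: float
    n_effective: float
    independent: bool
    insufficient: bool = False
    method: str = "fisherz"
    df: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p-value {self.p_value} outside [0,1]")


class CITester(ABC):
    """Common caching/canonicalisation layer over a CI backend.

    Results are memoised under the canonical (sorted) argument order, so
    ``test(x, y, S)`` and ``test(y, x, S)`` are identical objects and the
    interleaved search never pays twice for the same query.
    """

    def __init__(self, alpha: float = 0.05) -> None:
        if not (0 < alpha < 1):
            raise ValidationError(f"alpha must be in (0,1), got {alpha}")
        self.alpha = alpha
        self._cache: dict[tuple, CITestResult] = {}
        self.insufficient_log: list[tuple] = []
        self.n_tests = 0

    @property
    @abstractmethod
    def variables(self) -> list[str]:
        """Names this backend can test."""

    @abstractmethod
    def _compute(self, x: str, y: str, S: tuple[str, ...]) -> CITestResult:
        ...

    def test(self, x: str, y: str, S: Iterable[str] = ()) -> CITestResult:
        if x == y:
            raise ValidationError("x and y must be distinct")
        S = tuple(sorted(set(S)))
        if x in S or y in S:
            raise ValidationError("x and y must not appear in S")
        a, b = sorted((x, y))
        key = (a, b, S)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        res = self._compute(a, b, S)
        if res.insufficient:
            self.insufficient_log.append(key)
        self._cache[key] = res
        self.n_tests += 1
        return res

    def restrict(self, drop: Iterable[str]) -> "CITester":
        """A tester over the same source with the given columns hidden."""
        raise NotImplementedError

    def _insufficient(self, x, y, S, n_eff, method) -> CITestResult:
        return CITestResult(
            x=x, y=y, S=S, statistic=0.0, p_value=1.0, n_effective=n_eff,
            independent=True, insufficient=True, method=method,
        )


def _midrank_matrix(values: np.ndarray) -> np.ndarray:
    """Midranks per column over observed cells; NaN cells stay NaN."""
    ranked = np.full(values.shape, np.nan)
    for j in range(values.shape[1]):
        col = values[:, j]
        obs = ~np.isnan(col)
        if obs.any():
            ranked[obs, j] = stats.rankdata(col[obs])
    return ranked


class FisherZTester(CITester):
    """Fisher-z partial correlation on midrank-transformed columns.

    The midrank transform is applied once per column over its observed cells;
    each test then takes the test-wise complete rows of the transformed
    columns.  The statistic is sqrt(n_eff - |S| - 3) * |atanh(r)| with a
    two-sided normal p-value, where r is the partial correlation of x and y
    given S on the complete cases.
    """

    method = "fisherz"

    def __init__(self, data: Dataset, alpha: float = 0.05) -> None:
        super().__init__(alpha)
        self.data = data
        self._ranked = _midrank_matrix(data.values)
        self._observed = ~np.isnan(data.values)

    @property
    def variables(self) -> list[str]:
        return self.data.columns

    def restrict(self, drop: Iterable[str]) -> "FisherZTester":
        return FisherZTester(self.data.drop_columns(drop), self.alpha)

    def _compute(self, x: str, y: str, S: tuple[str, ...]) -> CITestResult:
        idx = [self.data.col_index(v) for v in (x, y, *S)]
        mask = self._observed[:, idx].all(axis=1)
        n_eff = int(mask.sum())
        k = len(S)
        if n_eff < k + 4:
            return self._insufficient(x, y, S, n_eff, self.method)
        sub = self._ranked[np.ix_(mask.nonzero()[0], idx)]
        r = _partial_correlation(sub)
        if r is None:
            return self._insufficient(x, y, S, n_eff, self.method)
        r = max(-_R_CLIP, min(_R_CLIP, r))
        stat = math.sqrt(n_eff - k - 3) * abs(math.atanh(r))
        p = math.erfc(stat / _SQRT2)
        return CITestResult(
            x=x, y=y, S=S, statistic=stat, p_value=min(1.0, p),
            n_effective=n_eff, independent=p > self.alpha, method=self.method,
        )


def _partial_correlation(sub: np.ndarray) -> Optional[float]:
    """Partial correlation of columns 0,1 of ``sub`` given the rest.

    Returns None when a residual variance is (numerically) zero — the
    "insufficient" path, covering constant columns and variables fully
    determined by the conditioning set.
    """
    C = np.cov(sub, rowvar=False)
    C = np.atleast_2d(C)
    base = max(C[0, 0], C[1, 1])
    if base <= 0 or not np.isfinite(base):
        return None
    if sub.shape[1] == 2:
        P = C
    else:
        A = C[2:, 2:]
        B = C[2:, :2]
        try:
            sol = np.linalg.solve(A, B)
        except np.linalg.LinAlgError:
            sol = np.linalg.lstsq(A, B, rcond=None)[0]
        P = C[:2, :2] - C[:2, 2:] @ sol
    var_x, var_y = P[0, 0], P[1, 1]
    tol = _VAR_REL_TOL * base
    if var_x <= tol or var_y <= tol:
        return None
    r = P[0, 1] / math.sqrt(var_x * var_y)
    if not np.isfinite(r):
        return None
    return float(r)


class G2Tester(CITester):
    """G² (log-likelihood ratio) test for all-discrete variable sets.

    G² = 2 Σ observed·ln(observed/expected), summed over the x,y contingency
    table within each stratum of S; df = (levels(x)-1)(levels(y)-1)·Π levels(s)
    with levels counted on the test-wise complete cases.
    """

    method = "g2"

    def __init__(self, data: Dataset, alpha: float = 0.05) -> None:
        super().__init__(alpha)
        bad = [
            v.name for v in data.table if v.vtype not in ("binary", "ordinal")
        ]
        if bad:
            raise ValidationError(
                f"G² requires binary/ordinal variables; cardinal: {bad}"
            )
        self.data = data
        self._observed = ~np.isnan(data.values)

    @property
    def variables(self) -> list[str]:
        return self.data.columns

    def restrict(self, drop: Iterable[str]) -> "G2Tester":
        return G2Tester(self.data.drop_columns(drop), self.alpha)

    def _compute(self, x: str, y: str, S: tuple[str, ...]) -> CITestResult:
        idx = [self.data.col_index(v) for v in (x, y, *S)]
        mask = self._observed[:, idx].all(axis=1)
        n_eff = int(mask.sum())
        if n_eff < len(S) + 4:
            return self._insufficient(x, y, S, n_eff, self.method)
        sub = self.data.values[np.ix_(mask.nonzero()[0], idx)].astype(int)
        xcol, ycol, scols = sub[:, 0], sub[:, 1], sub[:, 2:]
        x_levels = np.unique(xcol)
        y_levels = np.unique(ycol)
        s_level_counts = [len(np.unique(scols[:, j])) for j in range(scols.shape[1])]
        df = (len(x_levels) - 1) * (len(y_levels) - 1)
        for c in s_level_counts:
            df *= c
        if df <= 0:
            return self._insufficient(x, y, S, n_eff, self.method)
        g2 = 0.0
        if scols.shape[1]:
            strata_keys = [tuple(row) for row in scols]
            order = {}
            for i, kk in enumerate(strata_keys):
                order.setdefault(kk, []).append(i)
            groups = order.values()
        else:
            groups = [range(len(xcol))]
        for rows in groups:
            rows = list(rows)
            if len(rows) < 2:
                continue
            g2 += _g2_stratum(xcol[rows], ycol[rows], x_levels, y_levels)
        p = float(stats.chi2.sf(g2, df))
        return CITestResult(
            x=x, y=y, S=S, statistic=g2, p_value=p, n_effective=n_eff,
            independent=p > self.alpha, method=self.method, df=float(df),
        )


def _g2_stratum(xc, yc, x_levels, y_levels) -> float:
    table = np.zeros((len(x_levels), len(y_levels)))
    xi = np.searchsorted(x_levels, xc)
    yi = np.searchsorted(y_levels, yc)
    np.add.at(table, (xi, yi), 1.0)
    total = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    obs = table > 0
    return float(2.0 * np.sum(table[obs] * np.log(table[obs] / expected[obs])))


class OracleCITester(CITester):
    """Perfect-faithfulness oracle: p = 1 if d-separated, else 0.

    ``n_effective`` is reported as infinity — the oracle sees the population,
    not a sample.
    """

    method = "oracle"

    def __init__(
        self,
        model: GroundTruthModel,
        alpha: float = 0.05,
        variables: Optional[Sequence[str]] = None,
    ) -> None:
        super().__init__(alpha)
        self.model = model
        self._variables = (
            list(variables) if variables is not None else list(model.dag.nodes)
        )

    @property
    def variables(self) -> list[str]:
        return self._variables

    def restrict(self, drop: Iterable[str]) -> "OracleCITester":
        drop = set(drop)
        return OracleCITester(
            self.model, self.alpha,
            [v for v in self._variables if v not in drop],
        )

    def _compute(self, x: str, y: str, S: tuple[str, ...]) -> CITestResult:
        sep = d_separated(self.model, x, y, S)
        return CITestResult(
            x=x, y=y, S=S, statistic=0.0 if sep else math.inf,
            p_value=1.0 if sep else 0.0, n_effective=math.inf,
            independent=sep, method=self.method,
        )


def make_tester(
    data: Dataset, alpha: float = 0.05, method: str = "fisherz"
) -> CITester:
    """Build the configured CI backend for a dataset.

    ``"auto"`` selects G² when every variable is discrete with at most six
    observed levels, otherwise Fisher-z on midranks.
    """
    if method == "fisherz":
        return FisherZTester(data, alpha)
    if method == "g2":
        return G2Tester(data, alpha)
    if method == "auto":
        for var in data.table:
            if var.vtype == "cardinal":
                return FisherZTester(data, alpha)
            col = data.column(var.name)
            obs = col[~np.isnan(col)]
            if np.unique(obs).size > 6:
                return FisherZTester(data, alpha)
        return G2Tester(data, alpha)
    raise ValueError(f"unknown CI method {method!r}")
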