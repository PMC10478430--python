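"""Statistical primitives used across the concordance analyses.

Four tools cover every inferential step of the pipeline:

* a one-proportion z-test with a *complement* null convention
  (p0 = 1 - p_hat), which is how the published altered-versus-unaltered
  proportions were tested;
* Cohen's kappa for paired categorical calls, with the Fleiss
  large-sample standard error;
* Pearson's product-moment correlation;
* Benjamini-Hochberg step-up adjustment of a family of p-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.inter_rater import cohens_kappa as _sm_cohens_kappa
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateError, DomainError, ValidationError

__all__ = [
    "PropTestResult",
    "KappaResult",
    "PearsonResult",
    "AdjustedPValues",
    "one_proportion_z",
    "cohens_kappa",
    "pearson_r",
    "bh_adjust",
]


@dataclass(frozen=True)
class PropTestResult:
    k: int
    n: int
    p_hat: float
    p0: float
    z: float
    p_value: float

    @property
    def difference(self) -> float:
        return self.p_hat - self.p0

    def to_dict(self) -> dict:
        return {"k": self.k, "n": self.n, "p_hat": self.p_hat, "p0": self.p0,
                "z": self.z, "p_value": self.p_value, "difference": self.difference}


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    po: float
    pe: float
    se: float
    ci95: tuple[float, float]
    defined: bool
    n: int

    def to_dict(self) -> dict:
        return {"kappa": self.kappa, "po": self.po, "pe": self.pe, "se": self.se,
                "ci95_low": self.ci95[0], "ci95_high": self.ci95[1],
                "defined": self.defined, "n": self.n}


@dataclass(frozen=True)
class PearsonResult:
    r: float
    r_squared: float
    p_value: float
    n: int


@dataclass(frozen=True)
class AdjustedPValues:
    raw: tuple[float, ...]
    adjusted: tuple[float, ...]


def one_proportion_z(
    k: int,
    n: int,
    null_policy: str | float = "complement",
    rounding: str = "none",
) -> PropTestResult:
    """Two-sided one-proportion z-test.

    With ``null_policy="complement"`` the null proportion is the complement
    of the observed one, p0 = 1 - k/n, i.e. the test asks whether the
    altered fraction differs from the unaltered fraction.  A float value
    fixes p0 conventionally.  ``rounding="three_decimals"`` rounds p_hat and
    p0 to three decimals *before* the z formula; this reproduces z-scores
    computed from 3-decimal spreadsheet intermediates.

    z = (p_hat - p0) / sqrt(p0 (1 - p0) / n), p two-sided from N(0, 1).
    """
    if n < 1:
        raise DomainError("n must be >= 1")
    if not (0 <= k <= n):
        raise ValidationError(f"k must lie in [0, n], got k={k}, n={n}")
    p_hat = k / n
    if null_policy == "complement":
        p0 = 1.0 - p_hat
    else:
        p0 = float(null_policy)
    if rounding == "three_decimals":
        p_hat = round(p_hat, 3)
        p0 = round(p0, 3)
    elif rounding != "none":
        raise ValidationError(f"unknown rounding policy {rounding!r}")
    if p0 <= 0.0 or p0 >= 1.0:
        raise DegenerateError(f"null proportion p0={p0} is degenerate")
    z = (p_hat - p0) / np.sqrt(p0 * (1.0 - p0) / n)
    p_value = 2.0 * sps.norm.sf(abs(z))
    return PropTestResult(k=k, n=n, p_hat=p_hat, p0=p0, z=float(z), p_value=float(p_value))


def _as_square_table(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise ValidationError(f"contingency table must be square, got shape {t.shape}")
    if t.size == 0:
        raise DomainError("empty contingency table")
    if (t < 0).any():
        raise ValidationError("contingency counts must be nonnegative")
    if not np.allclose(t, np.round(t)):
        raise ValidationError("contingency counts must be integers")
    return t


def cohens_kappa(table) -> KappaResult:
    """Cohen's kappa for a square contingency table of paired counts.

    po is the observed agreement (trace fraction), pe the chance agreement
    from the margins, kappa = (po - pe)/(1 - pe).  The standard error is
    the Fleiss large-sample estimate; ci95 = kappa +/- 1.96 se.

    ``defined`` is False when the statistic carries no information: either
    pe = 1 (all mass on one cell) or one of the two raters used a single
    category, in which case po = pe identically and agreement beyond
    chance cannot be estimated.
    """
    t = _as_square_table(table)
    total = t.sum()
    if total < 1:
        raise DomainError("contingency table must contain at least one observation")
    po = float(np.trace(t) / total)
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    pe = float((rows * cols).sum() / total**2)
    constant_margin = (np.count_nonzero(rows) <= 1) or (np.count_nonzero(cols) <= 1)
    if constant_margin:
        return KappaResult(kappa=float("nan"), po=po, pe=pe, se=float("nan"),
                           ci95=(float("nan"), float("nan")), defined=False, n=int(total))
    kappa = (po - pe) / (1.0 - pe)
    se = float(_sm_cohens_kappa(t, return_results=True).std_kappa)
    ci = (kappa - 1.96 * se, kappa + 1.96 * se)
    return KappaResult(kappa=float(kappa), po=po, pe=pe, se=se, ci95=ci,
                       defined=True, n=int(total))


def pearson_r(x: Sequence[float], y: Sequence[float]) -> PearsonResult:
    """Pearson product-moment correlation with the two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.shape} vs {y.shape}")
    n = x.size
    if n < 3:
        raise DomainError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateError("zero variance in one of the vectors")
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    return PearsonResult(r=r, r_squared=r * r, p_value=float(res.pvalue), n=n)


def bh_adjust(p_values: Sequence[float]) -> AdjustedPValues:
    """Benjamini-Hochberg step-up FDR adjustment, returned in input order.

    adjusted_(i) = min_{j >= i} (m / j) p_(j), capped at 1.  Equal raw
    p-values receive equal adjusted values, so tie order is irrelevant.
    """
    raw = tuple(float(p) for p in p_values)
    if len(raw) == 0:
        raise DomainError("empty p-value list")
    if any(not (0.0 <= p <= 1.0) for p in raw):
        raise ValidationError("p-values must lie in [0, 1]")
    adjusted = multipletests(raw, method="fdr_bh")[1]
    return AdjustedPValues(raw=raw, adjusted=tuple(float(a) for a in adjusted))
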