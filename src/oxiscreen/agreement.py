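"""Paired diagnostic-agreement statistics for a screen-vs-reference design.

Each patient contributes one paired observation: a reference diagnosis
(e.g. from a scored polygraph) and a screening value (an ODI, thresholded
at 15 dips/hour by convention).  The counts populate a 2x2 table

    a = reference+, screen+     b = reference-, screen+
    c = reference+, screen-     d = reference-, screen-

from which sensitivity, specificity and predictive values follow, and on
whose discordant cells (b, c) the McNemar test of marginal homogeneity
operates.  The module also implements the discordant-pair sample-size
formula for the McNemar design and Bland–Altman limits of agreement for
method comparison.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

ODI_THRESHOLD = 15.0

MCNEMAR_METHODS = ("exact", "continuity_corrected", "asymptotic")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Paired screen-vs-reference counts."""

    a: int  # reference positive, screen positive
    b: int  # reference negative, screen positive
    c: int  # reference positive, screen negative
    d: int  # reference negative, screen negative

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"cell {name} must be a nonnegative integer")
        if self.n < 1:
            raise ValueError("table must contain at least one pair")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        """Rows = screen +/-, columns = reference +/-."""
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


@dataclass(frozen=True)
class AgreementStats:
    """Sensitivity/specificity/PPV/NPV plus the McNemar p-value.

    A metric whose denominator is zero is ``None`` (undefined), never 0.
    """

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    mcnemar_p: float
    method: str


@dataclass(frozen=True)
class PowerParams:
    """Inputs to the discordant-pair McNemar sample-size calculation.

    ``psi`` is the ratio of the two discordant probabilities p01/p10
    (false positives over false negatives) and ``pdisc`` their sum.
    """

    alpha: float = 0.05
    beta: float = 0.20
    psi: float = 12.0
    pdisc: float = 0.39

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1 or not 0 < self.beta < 1:
            raise ValueError("alpha and beta must lie in (0, 1)")
        if self.psi <= 0:
            raise ValueError("psi must be positive")
        if self.psi == 1:
            raise ValueError(
                "psi = 1 means no marginal difference; the required sample "
                "size is unbounded"
            )
        if not 0 < self.pdisc <= 1:
            raise ValueError("pdisc must lie in (0, 1]")

    @property
    def p10(self) -> float:
        return self.pdisc / (self.psi + 1.0)

    @property
    def p01(self) -> float:
        return self.psi * self.pdisc / (self.psi + 1.0)


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    loa_low: float
    loa_high: float
    pairs: int


def build_table(
    pairs: Sequence[tuple[bool, float]],
    threshold: float = ODI_THRESHOLD,
) -> ContingencyTable2x2:
    """Cross-tabulate (reference_positive, screen ODI) pairs.

    Screen-positive means ODI >= threshold (the boundary counts as
    positive).  The four cells partition the input exactly.
    """
    if not pairs:
        raise ValueError("build_table requires at least one pair")
    a = b = c = d = 0
    for ref_pos, odi in pairs:
        screen_pos = odi >= threshold
        if ref_pos and screen_pos:
            a += 1
        elif not ref_pos and screen_pos:
            b += 1
        elif ref_pos:
            c += 1
        else:
            d += 1
    return ContingencyTable2x2(a=a, b=b, c=c, d=d)


def mcnemar_test(table: ContingencyTable2x2, method: str = "exact") -> float:
    """McNemar test of marginal homogeneity on the discordant cells.

    ``exact`` is the two-sided exact binomial test of min(b, c) against
    Binomial(b + c, 1/2); ``continuity_corrected`` is the chi-square test
    on (|b - c| - 1)^2 / (b + c); ``asymptotic`` drops the correction.
    The concordant cells a and d never affect the result.  With no
    discordant pairs at all the test carries no information and returns 1.
    """
    if method not in MCNEMAR_METHODS:
        raise ValueError(f"method must be one of {MCNEMAR_METHODS}")
    b, c = table.b, table.c
    n_disc = b + c
    if n_disc == 0:
        logger.info("no discordant pairs; McNemar p = 1.0 by convention")
        return 1.0
    if method == "exact":
        return float(min(1.0, 2.0 * stats.binom.cdf(min(b, c), n_disc, 0.5)))
    corr = 1.0 if method == "continuity_corrected" else 0.0
    statistic = (abs(b - c) - corr) ** 2 / n_disc
    return float(stats.chi2.sf(statistic, df=1))


def diagnostic_metrics(
    table: ContingencyTable2x2, method: str = "exact"
) -> AgreementStats:
    """Sensitivity, specificity, PPV, NPV and McNemar p for one table."""

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    return AgreementStats(
        sensitivity=ratio(table.a, table.a + table.c),
        specificity=ratio(table.d, table.b + table.d),
        ppv=ratio(table.a, table.a + table.b),
        npv=ratio(table.d, table.c + table.d),
        mcnemar_p=mcnemar_test(table, method),
        method=method,
    )


def mcnemar_sample_size(params: PowerParams) -> int:
    """Pairs needed for the McNemar design at the given error rates.

    Uses the normal-approximation (conditional-on-discordance) formula

        n = ceil( [ z_{1-a/2} sqrt(pd) + z_{1-b} sqrt(pd - (p01-p10)^2) ]^2
                  / (p01 - p10)^2 )

    which models the asymptotic (uncorrected) McNemar statistic.  The
    exact binomial variant of the test is conservative, so its realised
    power at the returned n runs a few points below nominal; plan with the
    asymptotic test in mind or add a safety margin if the exact test will
    be used.
    """
    p01, p10 = params.p01, params.p10
    diff = p01 - p10
    z_a = stats.norm.ppf(1.0 - params.alpha / 2.0)
    z_b = stats.norm.ppf(1.0 - params.beta)
    num = (
        z_a * math.sqrt(params.pdisc)
        + z_b * math.sqrt(params.pdisc - diff**2)
    ) ** 2
    return int(math.ceil(num / diff**2))


def simulate_mcnemar_power(
    n_pairs: int,
    params: PowerParams,
    n_rep: int = 10_000,
    method: str = "asymptotic",
    seed: int | None = None,
) -> float:
    """Monte-Carlo power of the McNemar test at a given number of pairs.

    Each replicate draws (b, c) ~ Multinomial(n_pairs; p01, p10, 1 - pdisc)
    and rejects when the chosen test's p-value is <= alpha.
    """
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(
        n_pairs, [params.p01, params.p10, 1.0 - params.pdisc], size=n_rep
    )
    b = counts[:, 0].astype(float)
    c = counts[:, 1].astype(float)
    nd = b + c
    safe_nd = np.maximum(nd, 1.0)
    if method == "exact":
        p = np.minimum(1.0, 2.0 * stats.binom.cdf(np.minimum(b, c), safe_nd, 0.5))
    elif method in ("asymptotic", "continuity_corrected"):
        corr = 1.0 if method == "continuity_corrected" else 0.0
        statistic = np.maximum(np.abs(b - c) - corr, 0.0) ** 2 / safe_nd
        p = stats.chi2.sf(statistic, df=1)
    else:
        raise ValueError(f"method must be one of {MCNEMAR_METHODS}")
    p = np.where(nd == 0, 1.0, p)
    return float((p <= params.alpha).mean())


def bland_altman(
    x: Sequence[float], y: Sequence[float]
) -> BlandAltmanResult:
    """Bland–Altman bias and 1.96-SD limits of agreement for paired data.

    ``bias`` is mean(x - y); the limits use the sample (n-1) standard
    deviation of the differences.
    """
    x_arr = np.asarray(x, dtype=float)
    y_arr = np.asarray(y, dtype=float)
    if x_arr.shape != y_arr.shape or x_arr.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    if x_arr.size < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    diff = x_arr - y_arr
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return BlandAltmanResult(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        pairs=x_arr.size,
    )


def bland_altman_plot_data(
    x: Sequence[float], y: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """Plot coordinates with the first measurement as abscissa.

    Returns (x, x - y): the first night's value against the night-to-night
    difference, the variant used for short-term reproducibility of the
    ODI (rather than the conventional pairwise-mean abscissa).
    """
    x_arr = np.asarray(x, dtype=float)
    y_arr = np.asarray(y, dtype=float)
    if x_arr.shape != y_arr.shape:
        raise ValueError("x and y must have equal length")
    return x_arr, x_arr - y_arr


def paired_median_iqr(
    differences: Sequence[float],
) -> tuple[float, float, float]:
    """Median and quartiles (25th, 75th) of paired differences.

    Quantiles use linear interpolation between order statistics, the
    default convention of mainstream statistical software.
    """
    arr = np.asarray(differences, dtype=float)
    if arr.size == 0:
        raise ValueError("paired_median_iqr requires a nonempty input")
    q25, med, q75 = np.percentile(arr, [25, 50, 75])
    return float(med), float(q25), float(q75)
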