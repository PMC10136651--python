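"""Correlation, regression and Bland-Altman agreement over matched VAF pairs.

Only mutations detected in both tissues with a quantitative VAF (SNV, MNP,
insertion, deletion; fusion and FLT3-ITD assays produce no VAF) enter the
agreement analysis.  Correlations are Spearman (mid-rank ties, p from the
t-approximation with n-2 degrees of freedom) with Kendall's tau-b as the
tie-corrected sensitivity analysis.  Bland-Altman limits of agreement are
placed at the mean difference plus/minus exactly two sample standard
deviations of the differences.
"""

from __future__ import annotations

import enum
import itertools
import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datamodel import (
    MatchStatus,
    MatchedVariant,
    SamplePair,
    VAF_CLASSES,
    ValidationError,
)

logger = logging.getLogger(__name__)


class Strength(str, enum.Enum):
    NEGLIGIBLE = "negligible"
    WEAK = "weak"
    MODERATE = "moderate"
    STRONG = "strong"
    VERY_STRONG = "very_strong"


@dataclass(frozen=True)
class VafPair:
    """One mutation's BM and PB VAFs with the covariates used for strata."""

    pair_id: str
    gene: str
    bm_vaf: float
    pb_vaf: float
    pb_blast_pct: float | None = None
    anc: float | None = None
    days_apart: int | None = None
    diagnosis: str | None = None


@dataclass(frozen=True)
class CorrelationResult:
    method: str  # "spearman" or "kendall"
    r: float | None
    p_value: float | None
    n: int
    strength_label: Strength | None

    def as_dict(self) -> dict:
        return {
            "method": self.method,
            "r": self.r,
            "p_value": self.p_value,
            "n": self.n,
            "strength": self.strength_label.value if self.strength_label else None,
        }


@dataclass(frozen=True)
class BlandAltmanResult:
    """Mean difference, its sample SD, and the d +/- 2*SD limits of agreement."""

    mean_diff: float
    sd_diff: float
    lower_limit: float
    upper_limit: float
    outliers: tuple[VafPair, ...]
    n: int

    def as_dict(self) -> dict:
        return {
            "mean_diff": self.mean_diff,
            "sd_diff": self.sd_diff,
            "lower_limit": self.lower_limit,
            "upper_limit": self.upper_limit,
            "n": self.n,
            "n_outliers": len(self.outliers),
            "outlier_genes": sorted(p.gene for p in self.outliers),
        }


def classify_strength(r: float | None) -> Strength | None:
    """Correlation-strength label on |r|, contiguous half-open bands.

    [0, 0.10) negligible, [0.10, 0.40) weak, [0.40, 0.70) moderate,
    [0.70, 0.90) strong, [0.90, 1] very strong.
    """
    if r is None or math.isnan(r):
        return None
    a = abs(r)
    if a < 0.10:
        return Strength.NEGLIGIBLE
    if a < 0.40:
        return Strength.WEAK
    if a < 0.70:
        return Strength.MODERATE
    if a < 0.90:
        return Strength.STRONG
    return Strength.VERY_STRONG


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, r_obs: float) -> float:
    """Two-sided exact permutation p for Spearman's r (enumerates n! pairings)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(rx)
    count = total = 0
    for perm in itertools.permutations(range(n)):
        r = np.corrcoef(rx, ry[list(perm)])[0, 1]
        total += 1
        if abs(r) >= abs(r_obs) - 1e-12:
            count += 1
    return count / total


def spearman(x, y, p_method: str = "t") -> CorrelationResult:
    """Spearman rank correlation with mid-rank ties.

    ``p_method``: ``"t"`` for the t-distribution approximation (n-2 df), or
    ``"exact"`` for full permutation enumeration (feasible for n <= 10).
    A constant input vector yields an undefined coefficient (None).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("spearman: input vectors differ in length")
    n = len(x)
    if n < 2:
        raise ValidationError("spearman: need at least 2 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("spearman: constant input vector; coefficient undefined")
        return CorrelationResult("spearman", None, None, n, None)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r, p = stats.spearmanr(x, y)
    r = float(r)
    if p_method == "exact":
        if n > 10:
            raise ValidationError("exact permutation p only supported for n <= 10")
        p = _exact_spearman_p(x, y, r)
    return CorrelationResult("spearman", r, float(p), n, classify_strength(r))


def kendall_tau(x, y) -> CorrelationResult:
    """Kendall's tau-b (tie-corrected), the sensitivity analysis for Spearman."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("kendall_tau: input vectors differ in length")
    n = len(x)
    if n < 2:
        raise ValidationError("kendall_tau: need at least 2 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("kendall_tau: constant input vector; coefficient undefined")
        return CorrelationResult("kendall", None, None, n, None)
    res = stats.kendalltau(x, y)
    tau = float(res.statistic)
    if math.isnan(tau):
        return CorrelationResult("kendall", None, None, n, None)
    return CorrelationResult("kendall", tau, float(res.pvalue), n, classify_strength(tau))


def regression_line(x, y) -> tuple[float, float]:
    """Ordinary least-squares (slope, intercept).

    Plotted alongside the bisecting identity line (slope 1, intercept 0):
    systematic BM/PB disagreement shows as the fitted line departing from it.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2:
        raise ValidationError("regression_line: need at least 2 observations")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept)


def collect_vaf_pairs(
    matched: list[MatchedVariant],
    pairs: list[SamplePair],
) -> list[VafPair]:
    """Extract the both-tissue, VAF-bearing mutations as (BM, PB) VAF pairs."""
    pair_index = {p.pair_id: p for p in pairs}
    out: list[VafPair] = []
    for m in matched:
        if m.status is not MatchStatus.BOTH or m.var_class not in VAF_CLASSES:
            continue
        if m.bm_vaf is None or m.pb_vaf is None:
            continue
        sp = pair_index.get(m.pair_id)
        out.append(
            VafPair(
                pair_id=m.pair_id,
                gene=m.gene,
                bm_vaf=m.bm_vaf,
                pb_vaf=m.pb_vaf,
                pb_blast_pct=sp.pb.pb_blast_pct if sp else None,
                anc=sp.pb.anc if sp else None,
                days_apart=sp.days_apart if sp else None,
                diagnosis=sp.bm.diagnosis.value if sp else None,
            )
        )
    return out


def bland_altman(vaf_pairs: list[VafPair]) -> BlandAltmanResult:
    """Bland-Altman agreement of BM vs PB VAFs.

    Differences are BM - PB; the limits of agreement are the mean difference
    plus/minus exactly 2 sample standard deviations (n-1 denominator).
    Outliers are the pairs whose difference falls strictly outside the
    limits.
    """
    if len(vaf_pairs) < 2:
        raise ValidationError("bland_altman: need at least 2 VAF pairs")
    diffs = np.array([p.bm_vaf - p.pb_vaf for p in vaf_pairs])
    mean = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    lower, upper = mean - 2.0 * sd, mean + 2.0 * sd
    outliers = tuple(p for p, d in zip(vaf_pairs, diffs) if d < lower or d > upper)
    return BlandAltmanResult(mean, sd, lower, upper, outliers, len(vaf_pairs))


#: Built-in stratification criteria over VAF pairs.  Covariates that are
#: missing exclude the pair from the stratum.
STRATA = {
    "pb_blasts_zero": lambda p: p.pb_blast_pct is not None and p.pb_blast_pct == 0,
    "pb_blasts_ge1": lambda p: p.pb_blast_pct is not None and p.pb_blast_pct >= 1,
    "anc_lt1": lambda p: p.anc is not None and p.anc < 1.0,
    "anc_ge1": lambda p: p.anc is not None and p.anc >= 1.0,
    "same_day_only": lambda p: p.days_apart == 0,
    "min_vaf_5": lambda p: p.bm_vaf >= 5.0 and p.pb_vaf >= 5.0,
}


def stratify(vaf_pairs: list[VafPair], *criteria: str) -> dict[str, list[VafPair]]:
    """Subset VAF pairs by named criteria.

    Returns one subset per criterion; when several criteria are given, an
    additional entry keyed by ``"&".join(criteria)`` holds their
    intersection (criteria compose conjunctively).  The ``min_vaf_5``
    criterion drops a pair when either tissue's VAF is below 5 percent, so
    the retained set is well-defined at pair level.
    """
    for c in criteria:
        if c not in STRATA:
            raise ValidationError(f"unknown stratification criterion: {c}")
    out = {c: [p for p in vaf_pairs if STRATA[c](p)] for c in criteria}
    if len(criteria) > 1:
        out["&".join(criteria)] = [
            p for p in vaf_pairs if all(STRATA[c](p) for c in criteria)
        ]
    return out


def blast_vaf_correlation(
    matched: list[MatchedVariant],
    pairs: list[SamplePair],
    tissue: str,
) -> CorrelationResult:
    """Spearman correlation of mutation VAFs against the sample's blast percent.

    For ``tissue="BM"`` every mutation with a BM VAF is paired with that
    sample's BM (aspirate) blast percentage; analogously for PB.  Samples
    with a missing blast percentage are excluded.
    """
    if tissue not in ("BM", "PB"):
        raise ValidationError("tissue must be 'BM' or 'PB'")
    pair_index = {p.pair_id: p for p in pairs}
    xs, ys = [], []
    for m in matched:
        sp = pair_index.get(m.pair_id)
        if sp is None:
            continue
        if tissue == "BM":
            vaf, blasts = m.bm_vaf, sp.bm.bm_blast_pct
        else:
            vaf, blasts = m.pb_vaf, sp.pb.pb_blast_pct
        if vaf is None or blasts is None:
            continue
        xs.append(vaf)
        ys.append(blasts)
    if len(xs) < 2:
        logger.warning("blast_vaf_correlation(%s): fewer than 2 usable mutations", tissue)
        return CorrelationResult("spearman", None, None, len(xs), None)
    return spearman(xs, ys)
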