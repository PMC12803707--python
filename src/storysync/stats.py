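"""Group-level inference: condition trends, t-to-z maps, Bonferroni, FDR.

The group pipeline for a per-region effect is always the same: one scalar
per subject, a one-sample (or paired) t test against zero, conversion of
the t value to a signed standard-normal z score (``z = Phi^-1(F_t(t))``),
and thresholding of |z| at the Bonferroni-corrected cutoff
``Phi^-1(1 - alpha/m)`` — 3.89 for alpha 0.05 over 1,000 regions.  For the
21 time points of an epoch time course, Benjamini–Hochberg FDR is used
instead of Bonferroni.

Condition trends on ISC are captured by an ordinary quadratic fit of the
five per-condition ISC values on the condition codes −2..+2: the linear
coefficient measures monotone change of ISC with masking, the quadratic
coefficient end-point-driven change.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .design import CONDITION_CODES, CONDITIONS
from .errors import InvalidInputError, InvalidParameterError

logger = logging.getLogger(__name__)

#: Largest |z| representable reliably by the double-precision normal quantile.
Z_CAP = 8.2

ZMAP_COLUMNS = ("region", "effect_name", "t", "df", "z", "p", "significant")


def fit_condition_trend(isc_by_condition, codes=None) -> tuple[float, float, float]:
    """OLS fit of ISC on condition code: ``isc = a + b*x + c*x**2``.

    ``isc_by_condition`` is a mapping condition -> ISC or a length-5
    sequence in ``CONDITIONS`` order; NaNs are dropped.  Returns
    ``(intercept, linear, quadratic)``; all-NaN output if fewer than 3
    defined values remain.
    """
    if codes is None:
        codes = [CONDITION_CODES[c] for c in CONDITIONS]
    if isinstance(isc_by_condition, dict):
        y = np.array([isc_by_condition.get(c, np.nan) for c in CONDITIONS], float)
    else:
        y = np.asarray(isc_by_condition, dtype=float)
        if y.size != len(codes):
            raise InvalidInputError(
                f"expected {len(codes)} ISC values, got {y.size}"
            )
    x = np.asarray(codes, dtype=float)
    ok = np.isfinite(y)
    if ok.sum() < 3:
        return (np.nan, np.nan, np.nan)
    X = np.column_stack([np.ones(ok.sum()), x[ok], x[ok] ** 2])
    beta, *_ = np.linalg.lstsq(X, y[ok], rcond=None)
    return (float(beta[0]), float(beta[1]), float(beta[2]))


def one_sample_t_to_z(values) -> tuple[float, int, float]:
    """One-sample t test against zero with t -> z conversion.

    ``t = mean / (sd / sqrt(n))`` with ``df = n - 1``; the z score is the
    standard-normal quantile of the t cumulative probability, computed on
    whichever tail is smaller so extreme t values stay accurate, and capped
    at ±8.2 (with a log message) where the quantile saturates.  Zero sample
    variance gives an infinite-t flag (±inf t, ±8.2 z).
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    n = x.size
    if n < 2:
        raise InvalidInputError(f"need at least 2 finite values, got {n}")
    df = n - 1
    sd = x.std(ddof=1)
    m = x.mean()
    if sd == 0:
        if m == 0:
            return (0.0, df, 0.0)
        t = np.inf if m > 0 else -np.inf
        logger.warning("zero-variance sample: infinite t flagged, z capped")
        return (float(t), df, float(np.sign(m) * Z_CAP))
    t = m / (sd / np.sqrt(n))
    z = t_to_z(t, df)
    return (float(t), df, z)


def t_to_z(t: float, df: int) -> float:
    """Signed standard-normal equivalent of a t statistic."""
    if not np.isfinite(t):
        return float(np.sign(t) * Z_CAP)
    # work on the smaller tail for numerical accuracy
    if t >= 0:
        z = -sps.norm.ppf(sps.t.sf(t, df))
    else:
        z = sps.norm.ppf(sps.t.cdf(t, df))
    if abs(z) > Z_CAP or not np.isfinite(z):
        logger.warning("z = %s capped at ±%s", z, Z_CAP)
        z = np.sign(t) * Z_CAP
    return float(z)


def paired_t_to_z(a, b) -> tuple[float, int, float]:
    """Paired t test: one-sample test on the element-wise differences."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise InvalidInputError(
            f"paired samples differ in shape: {a.shape} vs {b.shape}"
        )
    return one_sample_t_to_z(a - b)


def bonferroni_z_threshold(alpha: float = 0.05, m: int = 1000) -> float:
    """Bonferroni-corrected z cutoff ``Phi^-1(1 - alpha/m)``.

    Applied two-sidedly as ``|z| >= threshold``; (0.05, 1000) gives 3.89.
    """
    if not 0 < alpha < 1:
        raise InvalidParameterError(f"alpha must be in (0, 1), got {alpha}")
    if m < 1:
        raise InvalidParameterError(f"m must be >= 1, got {m}")
    return float(sps.norm.ppf(1.0 - alpha / m))


def fdr_bh(pvals, q: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg step-up rejection mask at FDR level ``q``."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InvalidInputError("p-values must be finite and in [0, 1]")
    if not 0 < q < 1:
        raise InvalidParameterError(f"q must be in (0, 1), got {q}")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def group_zmap(
    values_by_region: pd.DataFrame,
    effect_name: str,
    alpha: float = 0.05,
    m: int | None = None,
) -> pd.DataFrame:
    """One-sample t -> z per region, thresholded at the Bonferroni cutoff.

    ``values_by_region`` is (subjects x regions); NaNs reduce a region's n
    (logged).  ``m`` defaults to the number of regions tested.
    """
    regions = list(values_by_region.columns)
    if m is None:
        m = len(regions)
    thr = bonferroni_z_threshold(alpha, m)
    rows = []
    for region in regions:
        vals = values_by_region[region].to_numpy(dtype=float)
        n_missing = int((~np.isfinite(vals)).sum())
        if n_missing:
            logger.info("region %s: %d subjects missing", region, n_missing)
        t, df, z = one_sample_t_to_z(vals)
        p = 2.0 * sps.t.sf(abs(t), df) if np.isfinite(t) else 0.0
        rows.append((region, effect_name, t, df, z, p, bool(abs(z) >= thr)))
    return pd.DataFrame(rows, columns=list(ZMAP_COLUMNS))


def trend_zmaps(
    isc_table: pd.DataFrame, alpha: float = 0.05, m: int | None = None
) -> pd.DataFrame:
    """Group z maps of the linear and quadratic ISC-on-clarity trends.

    Fits the quadratic trend per (subject, region, mode) from the pooled
    IscTable, then runs the one-sample group test on each coefficient.
    Returns the concatenated ZMap frames with effect names
    ``"<mode>_linear"`` and ``"<mode>_quadratic"``.
    """
    out = []
    for mode, sub in isc_table.groupby("mode", sort=False):
        wide = sub.pivot_table(
            index=["subject", "region"], columns="condition", values="isc",
            dropna=False,
        )
        coefs = {
            (subj, region): fit_condition_trend(
                {c: wide.loc[(subj, region)].get(c, np.nan) for c in CONDITIONS}
            )
            for subj, region in wide.index
        }
        for name, pos in (("linear", 1), ("quadratic", 2)):
            tab = pd.DataFrame(
                {
                    "subject": [k[0] for k in coefs],
                    "region": [k[1] for k in coefs],
                    "value": [coefs[k][pos] for k in coefs],
                }
            ).pivot(index="subject", columns="region", values="value")
            out.append(group_zmap(tab, f"{mode}_{name}", alpha=alpha, m=m))
    return pd.concat(out, ignore_index=True)
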