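"""Dose-response inference: simple linear regression with a slope t-test.

The experimental question — does extract concentration (or culture time)
affect transcriptome entropy? — is answered by ordinary least squares of
per-sample entropy y on the covariate x, followed by a two-sided t-test of
the null hypothesis beta = 0:

    beta_hat = Sxy / Sxx,  se = sqrt(SSE / (n - 2) / Sxx),
    t = beta_hat / se,     p = 2 * SF_t(|t|, n - 2)

computed from first principles via centered sums; the Student-t survival
function uses the regularized incomplete beta function,
p = I_{df/(df+t^2)}(df/2, 1/2).

The dose covariate enters as the decimal dilution fraction exactly as
recorded (0, 0.001, 0.01); a log10(dose + d0) encoding is available since
a zero control dose precludes a pure log scale. The test is two-sided.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import betainc

from .errors import (
    InsufficientDataError,
    PerfectFitWarning,
    ValidationError,
    ZeroVarianceError,
)
from .io import SampleSheet

__all__ = [
    "SlopeTest",
    "fit_slope",
    "student_t_two_sided_p",
    "run_paper_contrasts",
    "slope_tests_to_frame",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SlopeTest:
    """Result of a slope t-test of entropy against a covariate.

    ``beta_hat`` is in bits per covariate unit; ``df = n - 2``;
    ``perfect_fit`` marks SSE = 0 inputs, for which p is reported as 0.
    """

    beta_hat: float
    intercept_hat: float
    se_beta: float
    t_stat: float
    df: int
    p_two_sided: float
    n: int
    perfect_fit: bool = False
    contrast_name: str = ""
    covariate_encoding: str = "fraction"


def student_t_two_sided_p(t_stat: float, df: float) -> float:
    """Two-sided tail probability of Student's t with ``df`` degrees of
    freedom: p = I_{df/(df+t^2)}(df/2, 1/2). Symmetric in +-t; p(0) = 1.
    """
    if df < 1:
        raise ValidationError(f"degrees of freedom must be >= 1, got {df}")
    t = float(t_stat)
    if not np.isfinite(t):
        return 0.0
    return float(betainc(df / 2.0, 0.5, df / (df + t * t)))


def fit_slope(x, y) -> SlopeTest:
    """OLS slope of y on x with a two-sided t-test on the slope.

    Requires n >= 3 and at least two distinct x values. A zero-residual
    fit with a nonzero slope sets ``perfect_fit`` and reports p = 0 with a
    :class:`PerfectFitWarning` instead of raising, so simulation sweeps
    never abort; a constant y gives beta = 0, t = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be one-dimensional and equal length")
    n = x.size
    if n < 3:
        raise InsufficientDataError(f"need at least 3 samples, got {n}")
    xbar, ybar = x.mean(), y.mean()
    dx, dy = x - xbar, y - ybar
    sxx = float(dx @ dx)
    if sxx == 0.0:
        raise ZeroVarianceError("covariate is constant; slope is unidentifiable")
    sxy = float(dx @ dy)
    beta = sxy / sxx
    intercept = ybar - beta * xbar
    resid = dy - beta * dx
    sse = float(resid @ resid)
    df = n - 2
    se = float(np.sqrt(sse / df / sxx))
    if se > 0.0:
        t = beta / se
        p = student_t_two_sided_p(t, df)
        perfect = False
    elif beta == 0.0:
        t, p, perfect = 0.0, 1.0, False
    else:
        t = float(np.sign(beta)) * np.inf
        p = 0.0
        perfect = True
        warnings.warn(
            "residual sum of squares is zero; p-value reported as 0",
            PerfectFitWarning,
            stacklevel=2,
        )
    return SlopeTest(
        beta_hat=beta,
        intercept_hat=intercept,
        se_beta=se,
        t_stat=t,
        df=df,
        p_two_sided=p,
        n=n,
        perfect_fit=perfect,
    )


def run_paper_contrasts(
    results: pd.DataFrame,
    sheet: SampleSheet,
    covariate: str = "dose",
    strain: str | None = None,
    treatments: tuple[str, ...] | None = None,
    encoding: str = "fraction",
    log_offset: float = 1e-4,
    name: str = "",
) -> SlopeTest:
    """Join diversity results to the sample sheet, filter, and test the slope.

    ``results`` must carry ``sample_id`` and ``H_bits`` columns (the output
    of :func:`liberality.diversity.diversity_table`). ``covariate`` is
    ``"dose"`` or ``"time_h"``. For dose regressions the conventional
    subset is one strain with treatments ("control", "mulberry") — the
    untreated controls plus the two extract dilutions — excluding midgut
    and cabbage arms; pass ``treatments=None`` to keep all samples (the
    usual choice for a time course). ``encoding="log10"`` uses
    log10(dose + log_offset) in place of the raw fraction.
    """
    if covariate not in ("dose", "time_h"):
        raise ValidationError(f"covariate must be 'dose' or 'time_h', got {covariate!r}")
    for col in ("sample_id", "H_bits"):
        if col not in results.columns:
            raise ValidationError(f"results table lacks required column {col!r}")
    res = results.copy()
    res["sample_id"] = res["sample_id"].astype(str)
    missing = set(res["sample_id"]) - set(sheet.sample_ids)
    if missing:
        raise ValidationError(
            f"samples absent from the sheet: {sorted(missing)}"
        )
    merged = res.merge(sheet.data, on="sample_id", how="inner")
    if strain is not None:
        merged = merged[merged["strain"] == strain]
    if treatments is not None:
        merged = merged[merged["treatment"].isin(treatments)]
    if len(merged) < 3:
        raise InsufficientDataError(
            f"contrast selects only {len(merged)} samples; need >= 3"
        )
    x = merged[covariate].to_numpy(float)
    if encoding == "log10":
        if covariate != "dose":
            raise ValidationError("log10 encoding applies to the dose covariate only")
        x = np.log10(x + log_offset)
    elif encoding != "fraction":
        raise ValidationError(f"unknown covariate encoding {encoding!r}")
    logger.info(
        "contrast %s: covariate=%s encoding=%s strain=%s treatments=%s samples=%s",
        name or "<unnamed>",
        covariate,
        encoding,
        strain,
        treatments,
        list(merged["sample_id"]),
    )
    fit = fit_slope(x, merged["H_bits"].to_numpy(float))
    return SlopeTest(
        **{
            **fit.__dict__,
            "contrast_name": name,
            "covariate_encoding": encoding,
        }
    )


def slope_tests_to_frame(tests: list[SlopeTest]) -> pd.DataFrame:
    """Tabulate slope tests in the column order used for on-disk output."""
    cols = [
        "contrast_name",
        "n",
        "beta_hat",
        "intercept_hat",
        "se_beta",
        "t_stat",
        "df",
        "p_two_sided",
        "covariate_encoding",
        "perfect_fit",
    ]
    return pd.DataFrame([{c: getattr(t, c) for c in cols} for t in tests])
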