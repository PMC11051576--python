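"""Method-agreement statistics: ICC, Bland–Altman, goodness of fit.

These are the statistics used to validate the contrast-derived
calculated Agatston score against the native-scan reference:

* intraclass correlation coefficient (default form: two-way
  mixed-effects, absolute agreement, single measure — ICC(A,1), the
  standard choice for comparing two fixed measurement methods), with an
  F-based 95% confidence interval;
* Bland–Altman analysis of the differences ``d = A - B`` against the
  means ``(A + B) / 2``: mean difference (bias), limits of agreement
  ``bias ± 1.96·SD``, and a proportional-bias test (two-sided t-test on
  the OLS slope of differences on means);
* R² as the squared Pearson correlation of the paired scores.

ICC point estimates and confidence intervals are delegated to
``pingouin.intraclass_corr`` (ANOVA mean squares under the hood); the
test suite cross-checks them against an explicit sums-of-squares
computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .conversion import ConversionModel

__all__ = [
    "ICCResult",
    "BlandAltmanResult",
    "AgreementReport",
    "icc",
    "bland_altman",
    "bland_altman_plot",
    "validate_conversion",
]

logger = logging.getLogger("avcscore.agreement")

# user-facing form names -> pingouin's Type codes
_ICC_FORMS = {
    "a1": "ICC(A,1)",  # two-way, absolute agreement, single measure
    "c1": "ICC(C,1)",  # two-way, consistency, single measure
    "1": "ICC(1,1)",  # one-way random, single measure
    "ak": "ICC(A,k)",
    "ck": "ICC(C,k)",
    "1k": "ICC(1,k)",
}


@dataclass
class ICCResult:
    estimate: float
    ci95: tuple[float, float]
    pvalue: float
    form: str  # user-facing form name

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class BlandAltmanResult:
    mean_difference: float
    sd_difference: float
    loa_low: float
    loa_high: float
    proportional_bias_slope: float
    proportional_bias_p: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class AgreementReport:
    n: int
    icc: float
    icc_ci95: tuple[float, float]
    icc_pvalue: float
    icc_form: str
    r2: float
    bland_altman: BlandAltmanResult
    difference_convention: str
    model: Optional[dict] = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["icc_ci95"] = list(self.icc_ci95)
        d["bland_altman"] = self.bland_altman.to_dict()
        return d


def _as_pairs(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("paired measurements must have equal length")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("paired measurements contain non-finite values")
    return a, b


def icc(a, b, form: str = "a1") -> ICCResult:
    """Intraclass correlation between two measurement methods.

    ``form`` selects the ICC variant: ``"a1"`` (default, absolute
    agreement ICC(A,1)), ``"c1"`` (consistency), ``"1"`` (one-way), and
    their average-measure counterparts ``"ak"``, ``"ck"``, ``"1k"``.
    """
    import pingouin as pg

    a, b = _as_pairs(a, b)
    n = a.size
    if n < 5:
        raise ValueError(f"ICC needs at least 5 pairs, got {n}")
    if form not in _ICC_FORMS:
        raise ValueError(f"unknown ICC form {form!r}; choose from {sorted(_ICC_FORMS)}")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        raise ValueError("all measurements identical: total variance is zero")
    data = pd.DataFrame(
        {
            "subject": np.tile(np.arange(n), 2),
            "rater": np.repeat(["A", "B"], n),
            "score": pooled,
        }
    )
    table = pg.intraclass_corr(
        data=data, targets="subject", raters="rater", ratings="score"
    ).set_index("Type")
    row = table.loc[_ICC_FORMS[form]]
    ci_col = "CI95%" if "CI95%" in table.columns else "CI95"
    estimate = float(row["ICC"])
    lo, hi = (float(v) for v in row[ci_col])
    # perfect agreement makes the residual mean square zero and the
    # F-based interval degenerate; collapse it onto the point estimate
    if not np.isfinite(lo):
        lo = estimate
    if not np.isfinite(hi):
        hi = estimate
    return ICCResult(
        estimate=estimate,
        ci95=(lo, hi),
        pvalue=float(row["pval"]),
        form=form,
    )


def bland_altman(a, b) -> BlandAltmanResult:
    """Bland–Altman agreement of method A against method B (d = A − B)."""
    a, b = _as_pairs(a, b)
    n = a.size
    if n < 3:
        raise ValueError(f"Bland–Altman analysis needs at least 3 pairs, got {n}")
    d = a - b
    m = (a + b) / 2.0
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    if np.ptp(d) == 0 or np.ptp(m) == 0:
        # perfectly constant differences (or degenerate means): no
        # proportional trend can exist, and the t-test is undefined
        slope, p = 0.0, 1.0
    else:
        fit = sps.linregress(m, d)
        slope, p = float(fit.slope), float(fit.pvalue)
    return BlandAltmanResult(
        mean_difference=mean_d,
        sd_difference=sd_d,
        loa_low=mean_d - 1.96 * sd_d,
        loa_high=mean_d + 1.96 * sd_d,
        proportional_bias_slope=slope,
        proportional_bias_p=p,
        n=n,
    )


def bland_altman_plot(a, b, path, labels=("method A", "method B")) -> None:
    """Write a Bland–Altman scatter with bias and limits of agreement."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    a, b = _as_pairs(a, b)
    res = bland_altman(a, b)
    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.scatter((a + b) / 2, a - b, s=18, alpha=0.8)
    ax.axhline(res.mean_difference, color="k", lw=1.2, label="bias")
    for y in (res.loa_low, res.loa_high):
        ax.axhline(y, color="k", lw=1.0, ls="--")
    ax.set_xlabel(f"mean of {labels[0]} and {labels[1]}")
    ax.set_ylabel(f"{labels[0]} − {labels[1]}")
    ax.set_title(
        f"bias {res.mean_difference:.1f}, LoA [{res.loa_low:.1f}, "
        f"{res.loa_high:.1f}], proportional-bias p = "
        f"{res.proportional_bias_p:.3f}"
    )
    ax.legend(loc="best", frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def validate_conversion(
    cohort: pd.DataFrame,
    model: ConversionModel,
    icc_form: str = "a1",
) -> AgreementReport:
    """Agreement of the calculated Agatston score with the native reference.

    Applies ``model`` to the cohort's contrast-derived volumes, then
    reports ICC (with 95% CI), R² and the Bland–Altman statistics for
    native vs calculated scores.  Differences use the convention
    ``native − calculated``.
    """
    native = np.asarray(cohort["native_agatston"], dtype=float)
    calc = model.predict(cohort["cect_volume_mm3"])
    icc_res = icc(native, calc, form=icc_form)
    ba = bland_altman(native, calc)
    r = sps.pearsonr(native, calc)
    report = AgreementReport(
        n=len(native),
        icc=icc_res.estimate,
        icc_ci95=icc_res.ci95,
        icc_pvalue=icc_res.pvalue,
        icc_form=icc_form,
        r2=float(r.statistic**2),
        bland_altman=ba,
        difference_convention="native - calculated",
        model=model.to_dict(),
    )
    logger.info(
        "validation: n=%d, ICC=%.3f (%.3f-%.3f), R2=%.3f, bias=%.1f, "
        "proportional-bias p=%.3f",
        report.n,
        report.icc,
        *report.icc_ci95,
        report.r2,
        ba.mean_difference,
        ba.proportional_bias_p,
    )
    return report
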