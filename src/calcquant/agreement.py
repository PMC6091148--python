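"""Agreement statistics between paired volume measurements and readers.

Implements the full statistical layer for method comparison of per-segment
calcium volumes (MR vs CTA) and ordinal reader scores:

* Pearson product-moment correlation with a Fisher-z confidence interval;
* intraclass correlation, two-way random effects, single measurement,
  absolute agreement — ICC(2,1) — with the F-distribution interval;
* Bland–Altman bias (MR − CTA) and 95% limits of agreement;
* Cohen's kappa with linear (or quadratic) weights over the 5-point scale
  and the Fleiss–Cohen–Everitt large-sample interval;
* the conventional interpretation scale: < 0.40 poor, 0.40–0.59 fair,
  0.60–0.74 good, ≥ 0.75 excellent (half-open intervals so every value
  receives exactly one label).

The model-style entry point is :class:`AgreementAnalysis` — built from a
paired-volumes DataFrame, its :meth:`~AgreementAnalysis.fit` returns an
:class:`AgreementResults` carrying pooled and stratified reports with a
``summary()`` table and scatter / Bland–Altman plots.

Segments are treated as independent observations (as in the clinical
analysis this mirrors); confidence intervals do not account for within-
patient clustering of segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "pearson_ci",
    "icc_agreement",
    "bland_altman",
    "weighted_kappa",
    "interpret_coefficient",
    "AgreementReport",
    "agreement_report",
    "stratified_agreement",
    "AgreementAnalysis",
    "AgreementResults",
]


def interpret_coefficient(value: float) -> str:
    """Label a correlation/agreement coefficient on the conventional scale."""
    if not np.isfinite(value):
        raise ValueError("coefficient must be finite")
    if value < 0.40:
        return "poor"
    if value < 0.60:
        return "fair"
    if value < 0.75:
        return "good"
    return "excellent"


def _paired(x, y, min_n: int):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} pairs, got {x.size}")
    return x, y


def pearson_ci(x, y, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Pearson r with the Fisher-z confidence interval (SE = 1/sqrt(n-3))."""
    x, y = _paired(x, y, 3)
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum())
    sy = np.sqrt((yc**2).sum())
    if sx == 0 or sy == 0:
        raise ValueError("zero variance input")
    r = float((xc * yc).sum() / (sx * sy))
    r = min(1.0, max(-1.0, r))
    if abs(r) >= 1.0 - 1e-12:
        r = 1.0 if r > 0 else -1.0  # exactly collinear up to float error
        return r, (r, r)
    z = np.arctanh(r)
    half = stats.norm.ppf(1 - alpha / 2) / np.sqrt(x.size - 3)
    return r, (float(np.tanh(z - half)), float(np.tanh(z + half)))


def _two_way_mean_squares(x: np.ndarray, y: np.ndarray):
    """Mean squares of the two-way (subjects x raters) ANOVA, k = 2 raters."""
    data = np.column_stack([x, y])
    n, k = data.shape
    grand = data.mean()
    msr = k * np.var(data.mean(axis=1), ddof=1)
    msc = n * np.var(data.mean(axis=0), ddof=1)
    sst = ((data - grand) ** 2).sum()
    sse = sst - msr * (n - 1) - msc * (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return msr, msc, max(mse, 0.0), n, k


def icc_agreement(x, y, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """ICC(2,1): two-way random effects, single measurement, absolute agreement.

    Unlike Pearson r, a systematic offset between the two measurement sets
    lowers the ICC.  The confidence interval follows the standard
    F-distribution construction with Satterthwaite degrees of freedom.
    """
    x, y = _paired(x, y, 3)
    msr, msc, mse, n, k = _two_way_mean_squares(x, y)
    denom = msr + (k - 1) * mse + k / n * (msc - mse)
    if denom <= 0:
        raise ValueError("zero total variance")
    icc = float((msr - mse) / denom)
    if mse == 0 and msc <= mse:
        return icc, (icc, icc)
    a = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
    if not np.isfinite(a):
        return icc, (icc, icc)
    b = 1 + k * icc * (n - 1) / (n * (1 - icc))
    v_num = (a * msc + b * mse) ** 2
    v_den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = v_num / v_den if v_den > 0 else n - 1
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_l * mse) / (
        f_l * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f_u * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_u * msr
    )
    return icc, (float(min(lower, icc)), float(max(upper, icc)))


def bland_altman(mr, cta) -> tuple[float, float, float]:
    """Bias (mean of MR − CTA) and 95% limits of agreement (bias ± 1.96 SD)."""
    mr, cta = _paired(mr, cta, 2)
    d = mr - cta
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def _weight_matrix(n_categories: int, weights: str) -> np.ndarray:
    i, j = np.meshgrid(np.arange(n_categories), np.arange(n_categories), indexing="ij")
    dist = np.abs(i - j) / (n_categories - 1)
    if weights == "linear":
        return 1.0 - dist
    if weights == "quadratic":
        return 1.0 - dist**2
    raise ValueError(f"unknown weights {weights!r}")


def weighted_kappa(
    r1,
    r2,
    weights: str = "linear",
    n_categories: int = 5,
    alpha: float = 0.05,
) -> tuple[float, tuple[float, float]]:
    """Weighted Cohen's kappa for paired ordinal scores in 1..n_categories.

    Observed and chance agreement are weighted over the *full* category
    space (default the 5-point Likert scale), so unobserved categories do
    not change the metric's meaning.  CI by the Fleiss–Cohen–Everitt
    large-sample variance.
    """
    r1 = np.asarray(r1)
    r2 = np.asarray(r2)
    if r1.shape != r2.shape or r1.ndim != 1 or r1.size < 2:
        raise ValueError("ratings must be equal-length vectors with n >= 2")
    for r in (r1, r2):
        if np.any((r < 1) | (r > n_categories)):
            raise ValueError(f"categories must lie in 1..{n_categories}")
    n = r1.size
    counts = np.zeros((n_categories, n_categories))
    np.add.at(counts, (r1 - 1, r2 - 1), 1)
    p = counts / n
    w = _weight_matrix(n_categories, weights)
    p_row = p.sum(axis=1)
    p_col = p.sum(axis=0)
    po = float((w * p).sum())
    pe = float((w * np.outer(p_row, p_col)).sum())
    if pe >= 1.0 - 1e-15:
        # degenerate marginals (all mass on one category pair)
        return 1.0 if po >= 1.0 - 1e-15 else 0.0, (np.nan, np.nan)
    kappa = (po - pe) / (1 - pe)
    w_row = w @ p_col      # E_j[w_ij]
    w_col = w.T @ p_row    # E_i[w_ij]
    term = w - (w_row[:, None] + w_col[None, :]) * (1 - kappa)
    var = ((p * term**2).sum() - (kappa - pe * (1 - kappa)) ** 2) / (
        n * (1 - pe) ** 2
    )
    se = np.sqrt(max(var, 0.0))
    half = stats.norm.ppf(1 - alpha / 2) * se
    return float(kappa), (
        float(max(-1.0, kappa - half)),
        float(min(1.0, kappa + half)),
    )


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


@dataclass
class AgreementReport:
    """Agreement of one set of paired volume measurements (MR vs CTA)."""

    n: int
    pearson_r: float = np.nan
    pearson_ci95: tuple[float, float] = (np.nan, np.nan)
    icc: float = np.nan
    icc_ci95: tuple[float, float] = (np.nan, np.nan)
    slope: float = np.nan
    intercept: float = np.nan
    bias_mm3: float = np.nan
    loa_mm3: tuple[float, float] = (np.nan, np.nan)
    r_label: str = ""
    icc_label: str = ""

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "pearson_r": self.pearson_r,
            "pearson_ci95": list(self.pearson_ci95),
            "icc": self.icc,
            "icc_ci95": list(self.icc_ci95),
            "slope": self.slope,
            "intercept": self.intercept,
            "bias_mm3": self.bias_mm3,
            "loa_mm3": list(self.loa_mm3),
            "r_label": self.r_label,
            "icc_label": self.icc_label,
        }


def agreement_report(mr, cta, alpha: float = 0.05) -> AgreementReport:
    """Full agreement report; strata smaller than 3 pairs report n only."""
    mr = np.asarray(mr, dtype=float)
    cta = np.asarray(cta, dtype=float)
    if mr.size < 3:
        return AgreementReport(n=int(mr.size))
    r, r_ci = pearson_ci(mr, cta, alpha)
    icc, icc_ci = icc_agreement(mr, cta, alpha)
    slope, intercept = np.polyfit(cta, mr, 1)
    bias, lo, hi = bland_altman(mr, cta)
    return AgreementReport(
        n=int(mr.size),
        pearson_r=r,
        pearson_ci95=r_ci,
        icc=icc,
        icc_ci95=icc_ci,
        slope=float(slope),
        intercept=float(intercept),
        bias_mm3=bias,
        loa_mm3=(lo, hi),
        r_label=interpret_coefficient(r),
        icc_label=interpret_coefficient(icc),
    )


def stratified_agreement(
    pairs: pd.DataFrame, by: str | None = None
) -> dict[str, AgreementReport]:
    """Pooled plus per-stratum agreement reports.

    ``pairs`` needs columns ``mr_mm3`` and ``cta_mm3``; ``by`` names a
    stratum column (e.g. ``field``, ``group``).
    """
    for col in ("mr_mm3", "cta_mm3"):
        if col not in pairs.columns:
            raise ValueError(f"pairs table missing column {col!r}")
    out = {"pooled": agreement_report(pairs["mr_mm3"], pairs["cta_mm3"])}
    if by is not None:
        if by not in pairs.columns:
            raise ValueError(f"unknown stratum key {by!r}")
        for value, sub in pairs.groupby(by, sort=True):
            out[f"{by}={value}"] = agreement_report(sub["mr_mm3"], sub["cta_mm3"])
    return out


class AgreementAnalysis:
    """Method-comparison model for paired per-segment calcium volumes.

    Parameters
    ----------
    pairs : DataFrame
        One row per segment with ``mr_mm3``, ``cta_mm3`` and optional
        stratum columns (``field``, ``group``, ``region``...).
    """

    def __init__(self, pairs: pd.DataFrame):
        for col in ("mr_mm3", "cta_mm3"):
            if col not in pairs.columns:
                raise ValueError(f"pairs table missing column {col!r}")
        if (pairs[["mr_mm3", "cta_mm3"]] < 0).any().any():
            raise ValueError("volumes must be non-negative")
        self.pairs = pairs.reset_index(drop=True)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "AgreementAnalysis":
        return cls(df)

    @classmethod
    def from_csv(cls, path) -> "AgreementAnalysis":
        return cls(pd.read_csv(path))

    def fit(self, by: str | None = None, alpha: float = 0.05) -> "AgreementResults":
        reports = stratified_agreement(self.pairs, by=by)
        return AgreementResults(pairs=self.pairs, by=by, reports=reports)


@dataclass
class AgreementResults:
    """Fitted agreement estimates, pooled and per stratum."""

    pairs: pd.DataFrame
    by: str | None
    reports: dict[str, AgreementReport] = field(default_factory=dict)

    @property
    def pooled(self) -> AgreementReport:
        return self.reports["pooled"]

    def to_dict(self) -> dict:
        return {name: rep.to_dict() for name, rep in self.reports.items()}

    def summary(self) -> str:
        lines = [
            "Agreement of per-segment calcification volume (MR vs CTA)",
            "=" * 74,
            f"{'stratum':<18}{'n':>5}{'r':>8}{'ICC':>8}{'slope':>8}"
            f"{'bias':>9}{'LoA':>22}",
            "-" * 74,
        ]
        for name, rep in self.reports.items():
            if np.isnan(rep.pearson_r):
                lines.append(f"{name:<18}{rep.n:>5}{'—':>8}")
                continue
            lines.append(
                f"{name:<18}{rep.n:>5}{rep.pearson_r:>8.3f}{rep.icc:>8.3f}"
                f"{rep.slope:>8.3f}{rep.bias_mm3:>9.1f}"
                f"  [{rep.loa_mm3[0]:>8.1f},{rep.loa_mm3[1]:>8.1f}]"
            )
        lines.append("-" * 74)
        rep = self.pooled
        lines.append(
            f"pooled correlation {rep.r_label}; agreement {rep.icc_label}; "
            f"bias is MR − CTA in mm³"
        )
        return "\n".join(lines)

    # plotting ------------------------------------------------------------
    def plot_scatter(self, ax=None):
        """MR-vs-CTA scatter with the regression line and line of unity."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = self.pairs["cta_mm3"].to_numpy()
        y = self.pairs["mr_mm3"].to_numpy()
        ax.scatter(x, y, s=18, alpha=0.7)
        lim = max(x.max(), y.max()) * 1.05 if x.size else 1.0
        xs = np.linspace(0, lim, 50)
        rep = self.pooled
        if not np.isnan(rep.slope):
            ax.plot(xs, rep.slope * xs + rep.intercept, "-", lw=1.5,
                    label=f"y = {rep.slope:.2f}x + {rep.intercept:.1f}")
        ax.plot(xs, xs, "--", color="gray", lw=1, label="unity")
        ax.set_xlabel("CTA volume (mm³)")
        ax.set_ylabel("MR volume (mm³)")
        ax.legend()
        return ax

    def plot_bland_altman(self, ax=None):
        """Difference-vs-mean plot with bias and 95% limits of agreement."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = self.pairs["cta_mm3"].to_numpy()
        y = self.pairs["mr_mm3"].to_numpy()
        mean = (x + y) / 2.0
        diff = y - x
        ax.scatter(mean, diff, s=18, alpha=0.7)
        rep = self.pooled
        ax.axhline(rep.bias_mm3, color="k", lw=1.2)
        for v in rep.loa_mm3:
            ax.axhline(v, color="k", lw=1, ls="--")
        ax.set_xlabel("mean of MR and CTA (mm³)")
        ax.set_ylabel("MR − CTA (mm³)")
        return ax
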