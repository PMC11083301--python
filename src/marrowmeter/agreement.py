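"""Agreement statistics for paired cellularity readings.

Two observers (human or automated) each report one cellularity percentage
per slide. Concordance is summarised by Lin's concordance correlation
coefficient,

    CCC = 2 rho sigma_x sigma_y / (sigma_x^2 + sigma_y^2 + (mu_x - mu_y)^2),

which discounts the Pearson correlation rho for both location (mean) and
scale (variance) shifts; variances here use the population (1/n)
convention of Lin's original estimator. The 95% confidence interval is
computed on the Fisher z scale using Lin's asymptotic variance of
atanh(CCC) and transformed back, so the interval always contains the point
estimate. Agreement grades follow Altman's convention: CCC above 0.8 is
OPTIMAL, between 0.6 and 0.8 (inclusive of both bounds) SUBSTANTIAL,
below 0.6 BELOW_SUBSTANTIAL.

Method comparison uses Bland-Altman analysis on the paired differences
d_i = x_i - y_i: bias d-bar, sample standard deviation S_d (1/(n-1)), and
the limits of agreement ULA = d-bar + 1.96 S_d, LAL = d-bar - 1.96 S_d,
covering ~95% of differences when they are normal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd


class AgreementGrade(str, Enum):
    OPTIMAL = "optimal"
    SUBSTANTIAL = "substantial"
    BELOW_SUBSTANTIAL = "below_substantial"


@dataclass
class RaterSeries:
    """Paired per-slide cellularity percentages from two observers."""

    values_x: np.ndarray
    values_y: np.ndarray
    slide_ids: list[str] | None = None
    label_x: str = "x"
    label_y: str = "y"

    def __post_init__(self) -> None:
        self.values_x = np.asarray(self.values_x, dtype=np.float64)
        self.values_y = np.asarray(self.values_y, dtype=np.float64)
        if self.values_x.shape != self.values_y.shape or self.values_x.ndim != 1:
            raise ValueError(
                f"values_x/values_y: need equal-length 1-D series, got "
                f"{self.values_x.shape} vs {self.values_y.shape}"
            )
        for name, v in (("values_x", self.values_x), ("values_y", self.values_y)):
            if v.size and (v.min() < 0 or v.max() > 100):
                raise ValueError(f"{name}: values must be percentages in [0,100]")
        if self.slide_ids is None:
            self.slide_ids = [f"slide_{i}" for i in range(len(self.values_x))]
        elif len(self.slide_ids) != len(self.values_x):
            raise ValueError("slide_ids: length mismatch with values")

    def __len__(self) -> int:
        return len(self.values_x)


@dataclass
class CCCResult:
    """Lin's coefficient with its ingredients, CI, and Altman grade."""

    ccc: float
    pearson_rho: float
    mu_x: float
    mu_y: float
    var_x: float
    var_y: float
    ci_low: float
    ci_high: float
    grade: AgreementGrade
    n: int


@dataclass
class BlandAltmanResult:
    """Bias and 95% limits of agreement for paired differences x - y."""

    bias: float
    sd_diff: float
    ula: float
    lal: float
    means: np.ndarray = field(repr=False)
    diffs: np.ndarray = field(repr=False)


def classify_agreement(ccc: float) -> AgreementGrade:
    """Altman grade for a concordance coefficient.

    Strictly above 0.8 is OPTIMAL; [0.6, 0.8] is SUBSTANTIAL (0.8 itself is
    not "greater than 0.8"); below 0.6 is BELOW_SUBSTANTIAL.
    """
    if not -1 <= ccc <= 1:
        raise ValueError(f"ccc: must be in [-1,1], got {ccc}")
    if ccc > 0.8:
        return AgreementGrade.OPTIMAL
    if ccc >= 0.6:
        return AgreementGrade.SUBSTANTIAL
    return AgreementGrade.BELOW_SUBSTANTIAL


def _lin_ci(ccc: float, rho: float, mu_x: float, mu_y: float,
            sx: float, sy: float, n: int, conf: float = 0.95) -> tuple[float, float]:
    """95% CI via Lin's asymptotic variance of the z-transformed CCC."""
    from scipy import stats

    zcrit = stats.norm.ppf(0.5 + conf / 2)
    c = ccc
    if abs(c) >= 1.0 - 1e-15:
        return c, c
    if abs(rho) < 1e-12 or sx == 0 or sy == 0:
        se = np.sqrt(1.0 / max(n - 3, 1))  # rho-degenerate fallback
    else:
        u = (mu_x - mu_y) / np.sqrt(sx * sy)
        one_mc2 = 1.0 - c * c
        var_z = (
            (1 - rho * rho) * c * c / (one_mc2 * rho * rho)
            + 2 * c**3 * (1 - c) * u * u / (rho * one_mc2**2)
            - c**4 * u**4 / (2 * rho * rho * one_mc2**2)
        ) / (n - 2)
        se = np.sqrt(max(var_z, 0.0))
    z = np.arctanh(c)
    return float(np.tanh(z - zcrit * se)), float(np.tanh(z + zcrit * se))


def lin_ccc(series: RaterSeries) -> CCCResult:
    """Lin's concordance correlation coefficient for one rater pair.

    Uses population (1/n) variances. Raises if fewer than 3 pairs or if
    both series are constant (concordance undefined). If exactly one series
    is constant the coefficient is 0 and rho is reported as nan.
    """
    x, y = series.values_x, series.values_y
    n = len(series)
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    mu_x, mu_y = float(x.mean()), float(y.mean())
    var_x = float(x.var())  # ddof=0
    var_y = float(y.var())
    if var_x == 0 and var_y == 0:
        raise ValueError("CCC undefined: both series are constant")
    cov = float(((x - mu_x) * (y - mu_y)).mean())
    denom = var_x + var_y + (mu_x - mu_y) ** 2
    ccc = 2 * cov / denom
    if var_x > 0 and var_y > 0:
        rho = cov / np.sqrt(var_x * var_y)
    else:
        rho = float("nan")
    ci_low, ci_high = _lin_ci(
        ccc, rho if np.isfinite(rho) else 0.0, mu_x, mu_y,
        np.sqrt(var_x), np.sqrt(var_y), n,
    )
    # clip tiny float excursions so downstream grading never sees |ccc|>1
    ccc = float(np.clip(ccc, -1.0, 1.0))
    return CCCResult(
        ccc=ccc,
        pearson_rho=float(rho),
        mu_x=mu_x,
        mu_y=mu_y,
        var_x=var_x,
        var_y=var_y,
        ci_low=min(ci_low, ccc),
        ci_high=max(ci_high, ccc),
        grade=classify_agreement(ccc),
        n=n,
    )


def bland_altman(series: RaterSeries) -> BlandAltmanResult:
    """Bias and limits of agreement for the paired differences x - y."""
    x, y = series.values_x, series.values_y
    if len(series) < 2:
        raise ValueError(f"need at least 2 pairs, got {len(series)}")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd,
        ula=bias + 1.96 * sd,
        lal=bias - 1.96 * sd,
        means=(x + y) / 2.0,
        diffs=d,
    )


def bland_altman_plot(result: BlandAltmanResult, path: str | Path, title: str = "") -> Path:
    """Scatter of difference vs. mean with bias and limit lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(result.means, result.diffs, s=18, alpha=0.8)
    for yval, style, lbl in (
        (result.bias, "-", f"bias {result.bias:.2f}"),
        (result.ula, "--", f"ULA {result.ula:.2f}"),
        (result.lal, "--", f"LAL {result.lal:.2f}"),
    ):
        ax.axhline(yval, linestyle=style, color="crimson", linewidth=1)
        ax.annotate(lbl, (0.99, yval), xycoords=("axes fraction", "data"),
                    ha="right", va="bottom", fontsize=8, color="crimson")
    ax.set_xlabel("mean of paired measurements (%)")
    ax.set_ylabel("difference (pp)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


@dataclass
class PairwiseCCCTable:
    """All pairwise CCCs for a rater panel plus each-vs-panel-mean CCCs."""

    matrix: pd.DataFrame
    results: dict[tuple[str, str], CCCResult]
    vs_mean: pd.DataFrame

    def to_csv(self, path: str | Path) -> Path:
        """Long-format table: pair, ccc, ci_low, ci_high, grade."""
        rows = [
            {
                "rater_a": a,
                "rater_b": b,
                "ccc": r.ccc,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "grade": r.grade.value,
            }
            for (a, b), r in self.results.items()
        ]
        path = Path(path)
        pd.DataFrame(rows).to_csv(path, index=False)
        return path


def pairwise_ccc_table(ratings: "pd.DataFrame | dict") -> PairwiseCCCTable:
    """Pairwise CCC matrix over a rater panel.

    ``ratings``: one column per rater, one row per slide (DataFrame or
    dict of equal-length sequences). The matrix is symmetric with unit
    diagonal. ``vs_mean`` holds, for each rater, the CCC against the mean
    of the *other* raters (leave-one-out panel mean), the way an automated
    reader is compared against the mean of the human panel.
    """
    df = pd.DataFrame(ratings)
    if df.shape[1] < 2:
        raise ValueError("need at least 2 raters")
    if df.isna().any().any():
        raise ValueError("ragged input: raters must rate every slide")
    names = list(df.columns)
    mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    results: dict[tuple[str, str], CCCResult] = {}
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if j <= i:
                continue
            r = lin_ccc(RaterSeries(df[a].to_numpy(), df[b].to_numpy(),
                                    label_x=a, label_y=b))
            results[(a, b)] = r
            mat.loc[a, b] = mat.loc[b, a] = r.ccc
    rows = []
    for a in names:
        others_mean = df.drop(columns=a).mean(axis=1).to_numpy()
        r = lin_ccc(RaterSeries(df[a].to_numpy(), others_mean,
                                label_x=a, label_y="panel_mean"))
        results[(a, "panel_mean")] = r
        rows.append(
            {"rater": a, "ccc": r.ccc, "ci_low": r.ci_low,
             "ci_high": r.ci_high, "grade": r.grade.value}
        )
    return PairwiseCCCTable(matrix=mat, results=results,
                            vs_mean=pd.DataFrame(rows).set_index("rater"))
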