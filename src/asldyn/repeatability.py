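"""Test-retest repeatability of CBF via a one-way random-effects model.

Repeated grey-matter CBF measurements y_ij on subject i are modelled as

    y_ij = mu + b_i + e_ij,   b_i ~ N(0, sigma_b^2),  e_ij ~ N(0, sigma_w^2)

fitted by REML.  The within-subject SD (wSD = sigma_w) and within-subject
coefficient of variation (wCV = wSD / mu) summarise measurement
repeatability; the repeatability coefficient RC = 2.77 * wSD (the
Bland-Altman 1.96 * sqrt(2) convention) is the smallest change between two
scans of one subject that can be called real at ~95% confidence.  A
longitudinal change in tumour CBF is flagged as significant when its
magnitude strictly exceeds RC.

REML is computed by profiling the restricted likelihood down to a scalar
optimisation over the variance ratio theta = sigma_b^2 / sigma_w^2, which
is fast, deterministic, and matches the balanced-design ANOVA closed forms
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "RepeatedMeasures",
    "VarianceComponents",
    "ChangeAssessment",
    "fit_variance_components",
    "detect_significant_change",
    "one_sample_test",
]

#: Bland-Altman repeatability-coefficient multiplier, 1.96 * sqrt(2)
RC_FACTOR = 2.77


@dataclass(frozen=True)
class RepeatedMeasures:
    """Long-format repeated measurements: one (subject, value) per record."""

    subjects: tuple[str, ...]
    values: tuple[float, ...]
    metric: str = "gm_median_cbf"

    def __post_init__(self) -> None:
        if len(self.subjects) != len(self.values):
            raise ValueError("subjects and values must have equal length")
        object.__setattr__(self, "subjects", tuple(str(s) for s in self.subjects))
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, float]], metric: str = "gm_median_cbf"
    ) -> "RepeatedMeasures":
        subjects, values = zip(*records)
        return cls(subjects=subjects, values=values, metric=metric)

    def groups(self) -> dict[str, np.ndarray]:
        out: dict[str, list[float]] = {}
        for s, v in zip(self.subjects, self.values):
            out.setdefault(s, []).append(v)
        return {s: np.asarray(v, dtype=float) for s, v in out.items()}


@dataclass(frozen=True)
class VarianceComponents:
    """REML variance components and the derived repeatability summaries."""

    grand_mean: float
    sigma_between: float
    sigma_within: float

    @property
    def wsd(self) -> float:
        return self.sigma_within

    @property
    def wcv_pct(self) -> float:
        """Within-subject coefficient of variation, percent of the grand mean."""
        return 100.0 * self.sigma_within / self.grand_mean

    @property
    def rc(self) -> float:
        """Repeatability coefficient, 2.77 * wSD."""
        return RC_FACTOR * self.sigma_within


def _reml_objective(theta: float, groups: list[np.ndarray]) -> tuple[float, float, float]:
    """Profiled -2 restricted log-likelihood at variance ratio theta.

    Returns (criterion, mu_hat, sigma_w^2_hat).  Per-subject covariance is
    sigma_w^2 (I + theta J); both mu and sigma_w^2 profile out in closed form.
    """
    n_i = np.array([g.size for g in groups], dtype=float)
    ybar = np.array([g.mean() for g in groups])
    w = n_i / (1.0 + n_i * theta)
    mu = float(np.sum(w * ybar) / np.sum(w))
    q = 0.0
    for g, ni in zip(groups, n_i):
        r = g - mu
        q += float(r @ r) - theta / (1.0 + ni * theta) * float(r.sum()) ** 2
    n_total = n_i.sum()
    sw2 = q / (n_total - 1.0)
    crit = (
        (n_total - 1.0) * np.log(max(sw2, 1e-300))
        + np.sum(np.log1p(n_i * theta))
        + np.log(np.sum(w))
    )
    return float(crit), mu, float(sw2)


def _reml_score(theta: float, groups: list[np.ndarray]) -> float:
    """d/d_theta of the profiled -2 restricted log-likelihood.

    By the envelope theorem the dependence of mu_hat on theta drops out, so
    dQ/d_theta = -sum_i s_i^2 / (1 + n_i theta)^2 with s_i the per-subject
    residual sum at mu_hat(theta).
    """
    n_i = np.array([g.size for g in groups], dtype=float)
    _, mu, sw2 = _reml_objective(theta, groups)
    s = np.array([float((g - mu).sum()) for g in groups])
    n_total = n_i.sum()
    q = sw2 * (n_total - 1.0)
    dq = -np.sum(s**2 / (1.0 + n_i * theta) ** 2)
    w = n_i / (1.0 + n_i * theta)
    return float(
        (n_total - 1.0) * dq / q
        + np.sum(w)
        - np.sum(w**2) / np.sum(w)
    )


def fit_variance_components(data: RepeatedMeasures) -> VarianceComponents:
    """REML fit of the one-way random-effects model.

    Only subjects with at least two measurements identify the within-subject
    variance; at least two such subjects are required.  The variance ratio
    theta = sigma_b^2 / sigma_w^2 solves the REML score equation (found by
    bracketed root-finding to machine precision); theta = 0 is the boundary
    solution when the score is nonnegative there.
    """
    groups = {s: g for s, g in data.groups().items() if g.size >= 2}
    if len(groups) < 2:
        raise ValueError(
            "variance-component estimation needs >= 2 subjects with >= 2 scans each"
        )
    glist = list(groups.values())

    # degenerate data: no within-subject scatter at all
    ssw = sum(float(np.sum((g - g.mean()) ** 2)) for g in glist)
    if ssw == 0.0:
        means = np.array([g.mean() for g in glist])
        return VarianceComponents(
            grand_mean=float(means.mean()),
            sigma_between=float(means.std(ddof=1)),
            sigma_within=0.0,
        )

    if _reml_score(0.0, glist) >= 0.0:
        theta = 0.0  # criterion increasing at the boundary: sigma_b = 0
    else:
        hi = 1.0
        while _reml_score(hi, glist) < 0.0:
            hi *= 10.0
            if hi > 1e12:  # pragma: no cover - score must change sign
                raise RuntimeError("REML score equation has no finite root")
        theta = float(
            optimize.brentq(
                _reml_score, 0.0, hi, args=(glist,), xtol=1e-14, rtol=1e-15
            )
        )
    _, mu, sw2 = _reml_objective(theta, glist)
    return VarianceComponents(
        grand_mean=mu,
        sigma_between=float(np.sqrt(theta * sw2)),
        sigma_within=float(np.sqrt(sw2)),
    )


@dataclass(frozen=True)
class ChangeAssessment:
    """A longitudinal change judged against the repeatability coefficient."""

    change: float
    rc: float
    significant: bool
    direction: str  # "increase", "decrease" or "none"


def detect_significant_change(
    baseline_value: float, later_value: float, vc: VarianceComponents
) -> ChangeAssessment:
    """Flag a change whose magnitude strictly exceeds RC = 2.77 * wSD."""
    change = float(later_value) - float(baseline_value)
    significant = abs(change) > vc.rc
    if change > 0:
        direction = "increase"
    elif change < 0:
        direction = "decrease"
    else:
        direction = "none"
    return ChangeAssessment(
        change=change, rc=vc.rc, significant=significant, direction=direction
    )


def one_sample_test(
    values: Sequence[float], null_mean: float = 0.0
) -> tuple[float, float]:
    """Two-sided one-sample t-test of the mean against ``null_mean``.

    Degenerate zero-variance samples return p = 1 when every value equals
    the null mean and p = 0 otherwise (the data are then non-stochastic).
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 2:
        raise ValueError("one-sample t-test needs at least two values")
    if np.ptp(vals) == 0.0:
        if vals[0] == null_mean:
            return 0.0, 1.0
        return float(np.inf if vals[0] > null_mean else -np.inf), 0.0
    t, p = stats.ttest_1samp(vals, null_mean)
    return float(t), float(p)
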