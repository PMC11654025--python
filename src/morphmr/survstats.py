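"""Survival statistics from first principles.

Implements the estimators and tests the response-criteria comparison needs:
the Kaplan-Meier product-limit estimator and its median, the 1-df log-rank
(Mantel-Cox) test, fixed-horizon mortality AUC for a binary marker with a
DeLong-style variance, a paired DeLong comparison of two correlated AUCs,
and a two-sided proportion test (Fisher's exact when any expected cell is
small, Pearson chi-square otherwise).

Horizon AUC convention: patients who die at or before the horizon are cases,
patients known alive at the horizon are controls, and patients censored
before the horizon are excluded and counted (``n_excluded``) — the simplest
defensible rule; no inverse-probability-of-censoring weighting is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats


@dataclass
class SurvivalSample:
    """Follow-up times (months) with death indicators."""

    times: np.ndarray
    events: np.ndarray
    group_labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events, dtype=bool)
        if self.times.shape != self.events.shape or self.times.ndim != 1:
            raise ValueError("times and events must be equal-length 1-d arrays")
        if self.times.size == 0:
            raise ValueError("empty survival sample")
        if np.any(self.times <= 0):
            raise ValueError("survival times must be positive")
        if self.group_labels is not None:
            self.group_labels = np.asarray(self.group_labels)
            if self.group_labels.shape != self.times.shape:
                raise ValueError("group_labels length mismatch")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass
class KMCurve:
    """Product-limit curve: right-continuous step function S(t)."""

    event_times: np.ndarray      # distinct observed times, ascending
    survival_probs: np.ndarray   # S(t) just after each time
    at_risk: np.ndarray          # number at risk just before each time
    n_events: np.ndarray         # deaths at each time

    def survival_at(self, t: float) -> float:
        """S(t) for arbitrary t (right-continuous)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival_probs[idx])


@dataclass
class LogRankResult:
    chi_square: float
    p_value: float
    observed_a: float = 0.0
    expected_a: float = 0.0


@dataclass
class AUCResult:
    auc: float
    ci_low: float
    ci_high: float
    p_vs_half: float
    horizon_months: float
    n_cases: int
    n_controls: int
    n_excluded: int
    sensitivity: float = float("nan")
    specificity: float = float("nan")
    defined: bool = True


def km_estimate(sample: SurvivalSample) -> KMCurve:
    """Kaplan-Meier product-limit estimator over all distinct observed times."""
    order = np.argsort(sample.times, kind="stable")
    times, events = sample.times[order], sample.events[order]
    distinct = np.unique(times)
    n = len(times)
    at_risk, n_events, probs = [], [], []
    s = 1.0
    for t in distinct:
        risk = int(np.sum(times >= t))
        d = int(np.sum((times == t) & events))
        if risk > 0 and d > 0:
            s *= 1.0 - d / risk
        at_risk.append(risk)
        n_events.append(d)
        probs.append(s)
    return KMCurve(
        event_times=distinct,
        survival_probs=np.asarray(probs),
        at_risk=np.asarray(at_risk),
        n_events=np.asarray(n_events),
    )


def km_median(curve: KMCurve) -> Optional[float]:
    """Smallest observed time with S(t) <= 0.5; None if never reached."""
    below = np.flatnonzero(curve.survival_probs <= 0.5)
    if below.size == 0:
        return None
    return float(curve.event_times[below[0]])


def log_rank(sample_a: SurvivalSample, sample_b: SurvivalSample) -> LogRankResult:
    """Two-sample 1-df log-rank (Mantel-Cox) test.

    Sums observed-minus-expected deaths in arm A over the pooled distinct
    event times with the hypergeometric variance; the statistic is symmetric
    in the two arms.
    """
    if sample_a.events.sum() + sample_b.events.sum() == 0:
        raise ValueError("log-rank requires at least one event")
    ta, ea = sample_a.times, sample_a.events
    tb, eb = sample_b.times, sample_b.events
    event_times = np.unique(np.concatenate([ta[ea], tb[eb]]))

    o_minus_e, var = 0.0, 0.0
    obs_a = exp_a = 0.0
    for t in event_times:
        na = int(np.sum(ta >= t))
        nb = int(np.sum(tb >= t))
        nj = na + nb
        if nj == 0:
            continue
        da = int(np.sum((ta == t) & ea))
        db = int(np.sum((tb == t) & eb))
        dj = da + db
        e_a = dj * na / nj
        o_minus_e += da - e_a
        obs_a += da
        exp_a += e_a
        if nj > 1:
            var += dj * (na / nj) * (nb / nj) * (nj - dj) / (nj - 1)

    if var <= 0.0:
        return LogRankResult(chi_square=0.0, p_value=1.0, observed_a=obs_a, expected_a=exp_a)
    chi2 = o_minus_e**2 / var
    p = float(stats.chi2.sf(chi2, df=1))
    return LogRankResult(chi_square=float(chi2), p_value=p, observed_a=obs_a, expected_a=exp_a)


# ---------------------------------------------------------------------------
# fixed-horizon mortality AUC


def _midrank(x: np.ndarray) -> np.ndarray:
    """Midranks (1-based), ties averaged."""
    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = len(x)
    ranks = np.empty(n, dtype=float)
    i = 0
    while i < n:
        j = i
        while j < n - 1 and xs[j + 1] == xs[i]:
            j += 1
        ranks[i : j + 1] = 0.5 * (i + j) + 1.0
        i = j + 1
    out = np.empty(n, dtype=float)
    out[order] = ranks
    return out


def _delong_placements(cases: np.ndarray, controls: np.ndarray) -> Tuple[float, np.ndarray, np.ndarray]:
    """AUC plus DeLong structural components V10 (cases) and V01 (controls)."""
    m, n = len(cases), len(controls)
    combined = np.concatenate([cases, controls])
    tz = _midrank(combined)
    tx = _midrank(cases)
    ty = _midrank(controls)
    auc = (tz[:m].sum() / m - (m + 1) / 2.0) / n
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    return float(auc), v10, v01


def _delong_variance(v10: np.ndarray, v01: np.ndarray) -> float:
    m, n = len(v10), len(v01)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def _horizon_split(sample: SurvivalSample, horizon_months: float) -> Tuple[np.ndarray, np.ndarray, int]:
    """Boolean case/control masks and the excluded (censored-early) count."""
    if horizon_months <= 0:
        raise ValueError("horizon must be positive")
    cases = sample.events & (sample.times <= horizon_months)
    controls = sample.times >= horizon_months
    # deaths exactly at the horizon count as cases, not controls
    controls &= ~cases
    excluded = int(len(sample) - cases.sum() - controls.sum())
    return cases, controls, excluded


def horizon_mortality_auc(
    marker: Sequence[bool] | np.ndarray,
    sample: SurvivalSample,
    horizon_months: float,
    alpha: float = 0.05,
) -> AUCResult:
    """Discrimination of death-by-horizon from a binary marker.

    For a binary marker the AUC equals (sensitivity + specificity) / 2; the
    confidence interval and the test against 0.5 use the DeLong variance of
    the marker scores.  An undefined result (no cases or no controls) is
    returned flagged rather than raised.
    """
    marker = np.asarray(marker, dtype=float).reshape(-1)
    if marker.shape[0] != len(sample):
        raise ValueError("marker length must match the survival sample")
    cases_mask, controls_mask, excluded = _horizon_split(sample, horizon_months)
    m, n = int(cases_mask.sum()), int(controls_mask.sum())
    if m == 0 or n == 0:
        return AUCResult(
            auc=float("nan"), ci_low=float("nan"), ci_high=float("nan"),
            p_vs_half=float("nan"), horizon_months=horizon_months,
            n_cases=m, n_controls=n, n_excluded=excluded, defined=False,
        )
    sens = float(marker[cases_mask].mean())
    spec = float(1.0 - marker[controls_mask].mean())
    auc, v10, v01 = _delong_placements(marker[cases_mask], marker[controls_mask])
    var = _delong_variance(v10, v01)
    se = float(np.sqrt(var))
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    if se > 0:
        p_half = float(2.0 * stats.norm.sf(abs(auc - 0.5) / se))
    else:
        p_half = 1.0 if auc == 0.5 else 0.0
    return AUCResult(
        auc=float(auc),
        ci_low=float(max(0.0, auc - z * se)),
        ci_high=float(min(1.0, auc + z * se)),
        p_vs_half=p_half,
        horizon_months=horizon_months,
        n_cases=m,
        n_controls=n,
        n_excluded=excluded,
        sensitivity=sens,
        specificity=spec,
    )


def compare_auc(
    marker_a: Sequence[bool] | np.ndarray,
    marker_b: Sequence[bool] | np.ndarray,
    sample: SurvivalSample,
    horizon_months: float,
) -> float:
    """Paired DeLong test for two correlated horizon AUCs on the same patients.

    Returns the two-sided p-value; symmetric in the two markers.
    """
    a = np.asarray(marker_a, dtype=float).reshape(-1)
    b = np.asarray(marker_b, dtype=float).reshape(-1)
    if a.shape[0] != len(sample) or b.shape[0] != len(sample):
        raise ValueError("both markers must cover the same patients as the sample")
    cases_mask, controls_mask, _ = _horizon_split(sample, horizon_months)
    m, n = int(cases_mask.sum()), int(controls_mask.sum())
    if m == 0 or n == 0:
        raise ValueError("horizon AUC comparison undefined without cases and controls")
    auc_a, v10_a, v01_a = _delong_placements(a[cases_mask], a[controls_mask])
    auc_b, v10_b, v01_b = _delong_placements(b[cases_mask], b[controls_mask])
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = float(cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1])
    diff = auc_a - auc_b
    if var_diff <= 0:
        return 1.0 if diff == 0 else 0.0
    z = abs(diff) / np.sqrt(var_diff)
    return float(2.0 * stats.norm.sf(z))


def proportion_test(a_yes: int, a_n: int, b_yes: int, b_n: int) -> float:
    """Two-sided 2x2 proportion test.

    Fisher's exact test when any expected cell count falls below 5, Pearson
    chi-square (no continuity correction) otherwise.
    """
    for yes, n in ((a_yes, a_n), (b_yes, b_n)):
        if n <= 0:
            raise ValueError("group totals must be positive")
        if not 0 <= yes <= n:
            raise ValueError("successes must lie in [0, n]")
    table = np.array([[a_yes, a_n - a_yes], [b_yes, b_n - b_yes]], dtype=float)
    total = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    if expected.min() < 5.0:
        return float(stats.fisher_exact(table, alternative="two-sided")[1])
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(p)
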