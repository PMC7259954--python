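"""Mechanochemical predictors derived from the coarse P-loop model.

Two scalars summarize each motor's five-state model: the A/B free-energy
difference dG_AB = -ln(pi_A/pi_B) in kT (negative when the
nucleotide-favorable A state is preferred — the duty-ratio proxy), and
P(A→B), the one-lag probability of leaving A for B (the ADP-release-rate
proxy).  Panel evaluation correlates these against observed duty ratios and
ADP release rates; because absolute in-silico transition rates are not
directly comparable to in-vitro rates, ADP comparisons default to rank
order within condition groups (experiments are only comparable when
measured under the same conditions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


def delta_g(pi5: np.ndarray, state_a: int = 0, state_b: int = 1) -> float:
    """A/B free-energy difference in kT: -ln(pi_a / pi_b).

    Negative values mean state ``a`` is more probable.  Antisymmetric in its
    state arguments.
    """
    pi5 = np.asarray(pi5, dtype=float)
    pa, pb = pi5[state_a], pi5[state_b]
    if pa <= 0 or pb <= 0:
        raise ValueError("both state probabilities must be positive")
    return float(-np.log(pa / pb))


def correlate(x, y, method: str = "pearson") -> float:
    """Pearson product-moment or Spearman rank correlation.

    Zero variance in either variable is undefined and returned as NaN with a
    warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length inputs with at least 3 points")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero variance: correlation undefined, returning NaN")
        return float("nan")
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise ValueError(f"unknown method {method!r}")


def classify_duty(dg_ab: float, threshold: float = 0.0) -> str:
    """'high' duty ratio if dG_AB < threshold (A state preferred), else 'low'."""
    if not np.isfinite(dg_ab):
        raise ValueError("dG_AB must be finite")
    return "high" if dg_ab < threshold else "low"


@dataclass
class MotorResult:
    """Per-motor predictor values with jackknife uncertainties and the
    experimental observables they are compared against."""

    name: str
    dg_ab: float
    dg_ab_se: float = 0.0
    p_ab: float = float("nan")
    p_ab_se: float = 0.0
    duty_obs: float = float("nan")
    adp_obs: float = float("nan")
    condition_group: str = "all"

    def __post_init__(self):
        if self.dg_ab_se < 0 or self.p_ab_se < 0:
            raise ValueError("standard errors must be non-negative")
        if np.isfinite(self.duty_obs) and not 0.0 <= self.duty_obs <= 1.0:
            raise ValueError("duty_obs must be in [0, 1]")


@dataclass
class PanelEvaluation:
    pearson_duty: float
    spearman_duty: float
    pearson_adp: float
    spearman_adp: float
    group_pearson_adp: dict
    group_rank_order_correct: dict
    duty_class_predictions: dict


def evaluate_panel(results) -> PanelEvaluation:
    """Correlate the predictors against the panel observables.

    Duty ratio is compared against -dG_AB (so a positive correlation means
    the predictor works); ADP release rate against P(A→B), overall and per
    condition group.  Per group the rank order of P(A→B) vs ADP rate is also
    reported (exact rank agreement, defined for groups of >= 2); group
    correlations are skipped below 3 members.
    """
    results = list(results)
    if len(results) < 3:
        raise ValueError("panel evaluation needs at least 3 motors")
    neg_dg = [-r.dg_ab for r in results]
    duty = [r.duty_obs for r in results]
    pab = [r.p_ab for r in results]
    adp = [r.adp_obs for r in results]
    evaluation = PanelEvaluation(
        pearson_duty=correlate(neg_dg, duty, "pearson"),
        spearman_duty=correlate(neg_dg, duty, "spearman"),
        pearson_adp=correlate(pab, adp, "pearson"),
        spearman_adp=correlate(pab, adp, "spearman"),
        group_pearson_adp={},
        group_rank_order_correct={},
        duty_class_predictions={r.name: classify_duty(r.dg_ab) for r in results},
    )
    groups = sorted({r.condition_group for r in results})
    for g in groups:
        members = [r for r in results if r.condition_group == g]
        if len(members) >= 3:
            evaluation.group_pearson_adp[g] = correlate(
                [m.p_ab for m in members], [m.adp_obs for m in members], "pearson")
        if len(members) >= 2:
            rank_pred = np.argsort(np.argsort([m.p_ab for m in members]))
            rank_obs = np.argsort(np.argsort([m.adp_obs for m in members]))
            evaluation.group_rank_order_correct[g] = bool(np.all(rank_pred == rank_obs))
    return evaluation
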