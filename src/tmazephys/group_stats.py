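"""Group-level statistics.

Two-sample comparisons are normality-gated: if both samples pass
Shapiro-Wilk at alpha = 0.05 a two-tailed t test is used, otherwise the
Mann-Whitney U test (unpaired) or Wilcoxon signed-rank test (paired).
Alternation rates are tested against the 0.5 chance level with a
one-sample signed-rank test.  Movement confounds are removed by pooled
linear regression of the measure on time spent immobile, comparing the
residuals between groups.  Circular group means (theta phase lags) are
compared with the Watson-Williams test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as spst

__all__ = [
    "GroupComparison", "ResidualizedComparison", "WatsonWilliamsResult",
    "compare_groups", "chance_test", "residualize", "watson_williams",
    "paired_run_contrast",
]

NORMALITY_ALPHA = 0.05


@dataclass
class GroupComparison:
    measure: str
    groups: tuple
    values_a: np.ndarray
    values_b: np.ndarray
    test: str                 # "t", "mann-whitney", "paired-t", "wilcoxon"
    statistic: float
    p_value: float
    normality_p: tuple        # Shapiro-Wilk p per group (or for differences)
    normal: bool

    def to_dict(self) -> dict:
        return {"measure": self.measure, "groups": list(self.groups),
                "test": self.test, "statistic": self.statistic,
                "p_value": self.p_value, "normal": self.normal,
                "n": [int(len(self.values_a)), int(len(self.values_b))],
                "mean": [float(np.mean(self.values_a)),
                         float(np.mean(self.values_b))]}


@dataclass
class ResidualizedComparison:
    measure: str
    covariate: str
    slope: float
    intercept: float
    residuals_a: np.ndarray
    residuals_b: np.ndarray
    comparison: GroupComparison


@dataclass
class WatsonWilliamsResult:
    f_statistic: float
    p_value: float
    pooled_resultant: float
    valid: bool               # resultant-length validity condition
    flags: list = field(default_factory=list)


def _shapiro_p(x: np.ndarray) -> float:
    x = np.asarray(x, float)
    if np.ptp(x) == 0:
        return 0.0   # a constant sample is treated as non-normal
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(spst.shapiro(x).pvalue)


def compare_groups(values_a, values_b, paired: bool = False,
                   measure: str = "", groups: tuple = ("A", "B"),
                   alpha_normal: float = NORMALITY_ALPHA) -> GroupComparison:
    """Normality-gated two-sample comparison with a full audit trail."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 observations per group")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired comparison requires equal sample sizes")
        diff = a - b
        p_norm = (_shapiro_p(diff),)
        normal = p_norm[0] > alpha_normal
        if normal:
            res = spst.ttest_rel(a, b)
            test = "paired-t"
        else:
            if np.all(diff == 0):
                return GroupComparison(measure, groups, a, b, "wilcoxon",
                                       0.0, 1.0, p_norm, normal)
            res = spst.wilcoxon(a, b)
            test = "wilcoxon"
    else:
        p_norm = (_shapiro_p(a), _shapiro_p(b))
        normal = p_norm[0] > alpha_normal and p_norm[1] > alpha_normal
        if normal:
            res = spst.ttest_ind(a, b)
            test = "t"
        else:
            res = spst.mannwhitneyu(a, b, alternative="two-sided")
            test = "mann-whitney"
    return GroupComparison(measure, groups, a, b, test,
                           float(res.statistic), float(res.pvalue),
                           p_norm, normal)


def chance_test(rates, chance: float = 0.5,
                measure: str = "alternation_rate") -> GroupComparison:
    """One-sample signed-rank test of per-animal rates against chance."""
    r = np.asarray(rates, float)
    if len(r) < 3:
        raise ValueError("need at least 3 animals")
    diff = r - chance
    if np.all(diff == 0):
        stat, p = 0.0, 1.0
    else:
        res = spst.wilcoxon(diff)
        stat, p = float(res.statistic), float(res.pvalue)
    return GroupComparison(measure, (measure, f"chance={chance}"), r,
                           np.full_like(r, chance), "wilcoxon-one-sample",
                           stat, p, (np.nan,), False)


def residualize(values, covariate, labels, measure: str = "",
                covariate_name: str = "time_immobile") -> ResidualizedComparison:
    """Remove a linear covariate effect pooled across all animals.

    A single OLS of the measure on the covariate is fitted over both
    groups together; residuals (observed minus fitted) are compared
    between groups with the normality-gated test.
    """
    v = np.asarray(values, float)
    c = np.asarray(covariate, float)
    labels = np.asarray(labels)
    if np.ptp(c) == 0:
        raise ValueError("constant covariate; residualization undefined")
    uniq = list(dict.fromkeys(labels.tolist()))
    if len(uniq) != 2:
        raise ValueError(f"expected exactly 2 groups, got {uniq}")
    slope, intercept = np.polyfit(c, v, 1)
    resid = v - (intercept + slope * c)
    ra, rb = resid[labels == uniq[0]], resid[labels == uniq[1]]
    comp = compare_groups(ra, rb, measure=f"{measure}|{covariate_name}",
                          groups=tuple(uniq))
    return ResidualizedComparison(measure=measure, covariate=covariate_name,
                                  slope=float(slope), intercept=float(intercept),
                                  residuals_a=ra, residuals_b=rb,
                                  comparison=comp)


def _kappa_from_r(r: float) -> float:
    """Maximum-likelihood von Mises concentration from a resultant length."""
    if r < 0.53:
        return 2 * r + r ** 3 + 5 * r ** 5 / 6
    if r < 0.85:
        return -0.4 + 1.39 * r + 0.43 / (1 - r)
    return 1.0 / (r ** 3 - 4 * r ** 2 + 3 * r)


def watson_williams(*angle_groups, min_per_group: int = 5,
                    min_resultant: float = 0.45) -> WatsonWilliamsResult:
    """Watson-Williams one-way test for equal circular means.

    Assumes von Mises samples with common, adequate concentration; the
    standard validity condition (pooled within-group resultant length
    above 0.45 for two groups) is checked and the result flagged, not
    suppressed, when it fails.
    """
    groups = [np.asarray(g, float) for g in angle_groups]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if len(g) < min_per_group:
            raise ValueError(f"need >= {min_per_group} angles per group")
    n = np.array([len(g) for g in groups])
    N = int(n.sum())
    # per-group and total resultant *lengths* (not normalized)
    R_i = np.array([np.abs(np.sum(np.exp(1j * g))) for g in groups])
    all_angles = np.concatenate(groups)
    R_t = float(np.abs(np.sum(np.exp(1j * all_angles))))
    rw = float(R_i.sum() / N)   # mean within-group resultant length

    flags = []
    valid = rw > min_resultant
    if not valid:
        flags.append(f"low concentration (rw={rw:.2f} <= {min_resultant})")

    kappa = _kappa_from_r(rw)
    correction = 1.0 + 3.0 / (8.0 * kappa) if kappa > 0 else 1.0
    denom = N - R_i.sum()
    if denom <= 0:
        return WatsonWilliamsResult(np.inf, 0.0, rw, valid,
                                    flags + ["degenerate: zero dispersion"])
    F = correction * ((N - k) * (R_i.sum() - R_t)) / ((k - 1) * denom)
    F = max(F, 0.0)
    p = float(spst.f.sf(F, k - 1, N - k))
    return WatsonWilliamsResult(float(F), p, rw, valid, flags)


def paired_run_contrast(sample_values: dict, choice_values: dict) -> dict:
    """Sample-run vs choice-run contrast with a group interaction.

    Parameters are mappings ``group -> per-animal values`` (aligned
    within group).  Returns per-group paired run-effect tests and the
    interaction: the between-group comparison of within-animal
    (choice - sample) deltas.
    """
    groups = list(sample_values)
    if set(groups) != set(choice_values):
        raise ValueError("sample and choice values must cover the same groups")
    out = {"run_effect": {}, "deltas": {}}
    for g in groups:
        s = np.asarray(sample_values[g], float)
        c = np.asarray(choice_values[g], float)
        if len(s) != len(c):
            raise ValueError(f"group {g}: run data not paired per animal")
        out["run_effect"][g] = compare_groups(
            c, s, paired=True, measure=f"run_effect[{g}]", groups=("choice", "sample"))
        out["deltas"][g] = c - s
    if len(groups) == 2:
        a, b = groups
        out["interaction"] = compare_groups(
            out["deltas"][a], out["deltas"][b],
            measure="run_x_group_interaction", groups=(a, b))
    return out
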