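"""Cut-off derivation and classification of pleomorphic lobular carcinoma.

Three pieces: empirical ROC analysis with a Youden-index cut-off, the
published median/IQR cut-off rule set for separating pleomorphic ILC from
classic and solid ILC, and a multivariable logistic model of the four size
parameters.

Conventions (fixed here rather than left to a library default): a case is
called positive when its statistic is *strictly greater* than the
threshold, matching the "> 48.2 μm²" phrasing of the published rules;
candidate ROC thresholds are the distinct observed score values; Youden
ties break toward the smallest threshold (the higher-sensitivity cut).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .cohort import CaseSummary

__all__ = [
    "CutoffRule",
    "RocResult",
    "RuleClassification",
    "FeatureEffect",
    "LogitModel",
    "roc_curve",
    "youden_threshold",
    "apply_rules",
    "published_rules",
    "fit_logistic",
]


@dataclass(frozen=True)
class CutoffRule:
    """One (parameter, statistic) > threshold decision rule."""

    parameter: str  # area | perimeter | min_feret | max_feret
    statistic: str  # median | iqr
    threshold: float
    direction: str = "greater"
    note: str = ""

    def __post_init__(self) -> None:
        if self.parameter not in ("area", "perimeter", "min_feret", "max_feret"):
            raise ValueError(f"unknown parameter {self.parameter!r}")
        if self.statistic not in ("median", "iqr"):
            raise ValueError(f"unknown statistic {self.statistic!r}")
        if self.direction != "greater":
            raise ValueError("only 'greater' rules are defined")
        if not self.threshold > 0:
            raise ValueError("threshold must be positive")

    def fires(self, summary: CaseSummary) -> bool:
        return summary.value(self.parameter, self.statistic) > self.threshold


def published_rules() -> list[CutoffRule]:
    """The published 8-rule cut-off set for pleomorphic ILC.

    Median rules capture nuclear size, IQR rules capture nuclear size
    variability (pleomorphism); all thresholds in μm (area μm²).
    """
    note = "published cut-off, pILC vs classic/solid ILC"
    vals = {
        ("area", "median"): 48.2,
        ("perimeter", "median"): 25.2,
        ("min_feret", "median"): 6.8,
        ("max_feret", "median"): 9.1,
        ("area", "iqr"): 19.4,
        ("perimeter", "iqr"): 5.3,
        ("min_feret", "iqr"): 1.5,
        ("max_feret", "iqr"): 2.2,
    }
    return [
        CutoffRule(parameter=p, statistic=s, threshold=t, note=note)
        for (p, s), t in vals.items()
    ]


@dataclass
class RocResult:
    """Empirical ROC curve with the Youden-optimal operating point."""

    auc: float
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    chosen_threshold: float
    chosen_sens: float
    chosen_spec: float

    @property
    def youden_j(self) -> float:
        return self.chosen_sens + self.chosen_spec - 1.0


def roc_curve(scores, labels) -> RocResult:
    """Empirical ROC of ``scores`` against binary ``labels``.

    Positives are called by ``score > threshold``; the candidate thresholds
    are the distinct observed scores (plus −inf, the call-everything
    point). AUC is the tie-aware Mann–Whitney probability that a random
    positive outscores a random negative (ties ½), identical to the
    trapezoidal area under this curve. The chosen threshold maximizes
    Youden's J = sensitivity + specificity − 1, ties toward the smallest
    threshold.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D")
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")

    # tie-aware Mann-Whitney AUC via midranks
    ranks = rankdata(s)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    thresholds = np.concatenate([[-np.inf], np.unique(s)])
    sens = np.empty_like(thresholds)
    spec = np.empty_like(thresholds)
    pos, neg = s[y == 1], s[y == 0]
    for i, t in enumerate(thresholds):
        sens[i] = np.mean(pos > t)
        spec[i] = np.mean(neg <= t)
    j = sens + spec - 1.0
    best = int(np.flatnonzero(j == j.max())[0])  # smallest threshold among ties
    return RocResult(
        auc=float(auc),
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        chosen_threshold=float(thresholds[best]),
        chosen_sens=float(sens[best]),
        chosen_spec=float(spec[best]),
    )


def youden_threshold(scores, labels) -> float:
    """Youden-optimal cut-off for calling positives by ``score > t``."""
    return roc_curve(scores, labels).chosen_threshold


@dataclass
class RuleClassification:
    """Per-rule flags plus the combined call for one case summary."""

    key: str
    flags: dict[tuple[str, str], bool]
    call: bool
    combination: str


def apply_rules(
    summary: CaseSummary,
    rules: list[CutoffRule],
    combination: str = "single_parameter",
    vote_k: int | None = None,
) -> RuleClassification:
    """Evaluate cut-off rules on a case summary and combine them.

    Combination policies:

    * ``single_parameter`` — the call rests on the maximum-diameter rules
      alone (all ``max_feret`` rules present must fire); maximum diameter
      is the most influential single parameter in the multivariable model.
    * ``all_of`` / ``any_of`` — conjunction / disjunction of all rules.
    * ``vote_k`` — at least ``vote_k`` rules fire.

    Flags use strict ``>``: a summary exactly at a threshold does not fire.
    A rule referencing a parameter the summary lacks raises ``KeyError``.
    """
    flags = {(r.parameter, r.statistic): r.fires(summary) for r in rules}
    fired = list(flags.values())
    if combination == "single_parameter":
        mx = [f for (p, _), f in flags.items() if p == "max_feret"]
        if not mx:
            raise ValueError("single_parameter policy needs max_feret rules")
        call = all(mx)
    elif combination == "all_of":
        call = all(fired)
    elif combination == "any_of":
        call = any(fired)
    elif combination == "vote_k":
        if vote_k is None:
            raise ValueError("vote_k policy needs vote_k")
        call = sum(fired) >= vote_k
    else:
        raise ValueError(f"unknown combination {combination!r}")
    return RuleClassification(
        key=summary.key, flags=flags, call=bool(call), combination=combination
    )


@dataclass(frozen=True)
class FeatureEffect:
    """One feature's effect in the logistic model (Wald inference)."""

    name: str
    coefficient: float
    std_error: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass
class LogitModel:
    """Multivariable logistic fit with per-feature odds ratios."""

    features: list[FeatureEffect]
    intercept: float
    converged: bool
    separation: bool
    log_likelihood: float

    def effect(self, name: str) -> FeatureEffect:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)


def fit_logistic(
    X,
    labels,
    feature_names: list[str] | None = None,
    standardize: bool = False,
) -> LogitModel:
    """Maximum-likelihood logistic regression of a binary outcome.

    Odds ratios are per unit of the raw feature (μm or μm²) unless
    ``standardize``, in which case features are z-scored first and odds
    ratios are per standard deviation. Confidence intervals and p-values
    are Wald-type. Non-convergence and (quasi-)complete separation are
    reported via flags, never silently.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and len(np.asarray(labels)) != 1:
        X = X.T
    y = np.asarray(labels).astype(float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and labels disagree on sample count")
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    const = np.ptp(X, axis=0) == 0
    if np.any(const):
        raise ValueError(f"constant feature at column(s) {np.flatnonzero(const)}")
    if feature_names is None:
        feature_names = [f"x{i}" for i in range(X.shape[1])]
    if standardize:
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)

    design = sm.add_constant(X, has_constant="add")
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            res = sm.Logit(y, design).fit(disp=0, maxiter=200)
        except (PerfectSeparationWarning, np.linalg.LinAlgError):
            # separation or a singular Newton Hessian: refit by BFGS and flag
            separation = True
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, design).fit(
                    disp=0, maxiter=500, method="bfgs"
                )
    converged = bool(res.mle_retvals.get("converged", False))
    fitted = res.predict(design)
    if np.all((fitted < 1e-8) | (fitted > 1 - 1e-8)):
        separation = True
    if separation:
        warnings.warn(
            "complete or quasi-complete separation: odds ratios unreliable",
            stacklevel=2,
        )

    ci = res.conf_int(alpha=0.05)
    ci = np.asarray(ci)
    effects = []
    for i, name in enumerate(feature_names, start=1):
        coef = float(res.params[i])
        with np.errstate(over="ignore"):  # inf CI bound under separation
            effects.append(
                FeatureEffect(
                    name=name,
                    coefficient=coef,
                    std_error=float(res.bse[i]),
                    odds_ratio=float(np.exp(coef)),
                    ci_low=float(np.exp(ci[i, 0])),
                    ci_high=float(np.exp(ci[i, 1])),
                    p_value=float(res.pvalues[i]),
                )
            )
    return LogitModel(
        features=effects,
        intercept=float(res.params[0]),
        converged=converged,
        separation=separation,
        log_likelihood=float(res.llf),
    )
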