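"""Per-case and per-variant summary statistics of nucleus measurements.

Nuclear size is described by the median of each size parameter and nuclear
size *variability* (the quantitative face of pleomorphism) by the
interquartile range, per case or pooled across all nuclei of a variant.
Lesion summaries are also expressed as ratios to reference-cell summaries
(resting lymphocytes, normal TDLU epithelium, pleomorphism-score-matched
IBC-NST), the field's internal size standards.

Two quantile conventions are provided because the common linear
interpolation rule (h = (n−1)p + 1) and SPSS's default weighted-average
rule (HAVERAGE, h = (n+1)p) disagree on small samples; ``interp_linear``
is the default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .io import CohortManifest
from .morphometry import MorphometricRecord

__all__ = [
    "PARAMETERS",
    "ParamSummary",
    "CaseSummary",
    "ReferenceRatios",
    "quantile",
    "summarize_records",
    "summarize_cases",
    "summaries_to_dataframe",
    "reference_ratio",
    "compare_groups",
]

PARAMETERS = ("area", "perimeter", "min_feret", "max_feret")

_NUMPY_METHOD = {"interp_linear": "linear", "spss_haverage": "weibull"}


def quantile(values, p: float, method: str = "interp_linear") -> float:
    """Order-statistic quantile of ``values`` at fraction ``p``.

    ``interp_linear`` interpolates at h = (n−1)p + 1; ``spss_haverage``
    at h = (n+1)p (SPSS's default, numpy's ``weibull``). ``p=0.5`` is the
    median under both.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("quantile of an empty list")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite values")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    try:
        np_method = _NUMPY_METHOD[method]
    except KeyError:
        raise ValueError(f"unknown quantile method {method!r}") from None
    return float(np.quantile(v, p, method=np_method))


@dataclass(frozen=True)
class ParamSummary:
    """median / Q1 / Q3 / IQR for one size parameter."""

    median: float
    q1: float
    q3: float

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    def __post_init__(self) -> None:
        if not self.q1 <= self.median <= self.q3:
            raise ValueError("quartiles must satisfy q1 <= median <= q3")

    def statistic(self, name: str) -> float:
        if name == "median":
            return self.median
        if name == "iqr":
            return self.iqr
        raise ValueError(f"unknown statistic {name!r}")


@dataclass
class CaseSummary:
    """Summary of one case (or one pooled variant) over its nuclei.

    ``key`` is a case_id for per-case summaries or a variant label for
    pooled ones. ``stats`` may cover a subset of the four parameters when
    built from published per-case tables that only print some of them.
    """

    key: str
    n_nuclei: int
    stats: dict[str, ParamSummary] = field(default_factory=dict)
    variant: str | None = None

    def __post_init__(self) -> None:
        if self.n_nuclei < 1:
            raise ValueError("a summary needs at least one nucleus")

    def value(self, parameter: str, statistic: str) -> float:
        if parameter not in self.stats:
            raise KeyError(f"summary {self.key!r} has no parameter {parameter!r}")
        return self.stats[parameter].statistic(statistic)

    @classmethod
    def from_quartiles(
        cls,
        key: str,
        quartiles: dict[str, tuple[float, float, float]],
        n_nuclei: int = 1,
        variant: str | None = None,
    ) -> "CaseSummary":
        """Build a summary directly from (median, q1, q3) per parameter —
        the form in which published tables report cases."""
        stats = {
            p: ParamSummary(median=m, q1=q1, q3=q3)
            for p, (m, q1, q3) in quartiles.items()
        }
        return cls(key=key, n_nuclei=n_nuclei, stats=stats, variant=variant)


def summarize_records(
    values_by_param: dict[str, np.ndarray],
    key: str,
    method: str = "interp_linear",
    variant: str | None = None,
) -> CaseSummary:
    n = len(next(iter(values_by_param.values())))
    stats = {}
    for p, vals in values_by_param.items():
        stats[p] = ParamSummary(
            median=quantile(vals, 0.5, method),
            q1=quantile(vals, 0.25, method),
            q3=quantile(vals, 0.75, method),
        )
    return CaseSummary(key=key, n_nuclei=n, stats=stats, variant=variant)


def summarize_cases(
    records: list[MorphometricRecord],
    manifest: CohortManifest | None = None,
    pooling: str = "per_case",
    method: str = "interp_linear",
) -> list[CaseSummary]:
    """Summarize nucleus records per case or pooled per variant.

    ``per_case`` groups records by ``case_id``; ``pooled_by_variant``
    pools all nuclei of every case sharing a variant label (manifest
    required). The IQR is always recomputed as Q3 − Q1 from our own
    quartiles. Manifest cases with no records are omitted with a warning.
    """
    if pooling not in ("per_case", "pooled_by_variant"):
        raise ValueError(f"unknown pooling {pooling!r}")
    if pooling == "pooled_by_variant" and manifest is None:
        raise ValueError("pooled_by_variant needs a cohort manifest")

    if manifest is not None:
        known = set(manifest.case_ids)
        for r in records:
            if r.case_id not in known:
                raise ValueError(f"record case_id {r.case_id!r} not in manifest")

    groups: dict[str, list[MorphometricRecord]] = {}
    for r in records:
        key = r.case_id if pooling == "per_case" else manifest.variant_of(r.case_id)
        groups.setdefault(key, []).append(r)

    if manifest is not None:
        expected = (
            manifest.case_ids
            if pooling == "per_case"
            else list(dict.fromkeys(v for _, v, _ in manifest.entries))
        )
        missing = [k for k in expected if k not in groups]
        if missing:
            warnings.warn(
                f"omitting {len(missing)} group(s) with zero nuclei: {missing}",
                stacklevel=2,
            )

    out = []
    for key, recs in groups.items():
        vals = {p: np.array([r.value(p) for r in recs]) for p in PARAMETERS}
        variant = None
        if pooling == "pooled_by_variant":
            variant = key
        elif manifest is not None:
            variant = manifest.variant_of(key)
        out.append(summarize_records(vals, key, method, variant))
    return out


def summaries_to_dataframe(summaries: list[CaseSummary]):
    """Flatten summaries to a table: one row per case/variant, columns
    ``<param>_median/_q1/_q3/_iqr`` (raw, unrounded)."""
    import pandas as pd

    rows = []
    for s in summaries:
        row = {"key": s.key, "variant": s.variant, "n_nuclei": s.n_nuclei}
        for p, ps in s.stats.items():
            row[f"{p}_median"] = ps.median
            row[f"{p}_q1"] = ps.q1
            row[f"{p}_q3"] = ps.q3
            row[f"{p}_iqr"] = ps.iqr
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ReferenceRatios:
    """Lesion/reference median ratios per parameter.

    ``raw`` keeps full precision; ``displayed`` is rounded to one decimal,
    the convention published tables use ("times larger than lymphocytes").
    """

    raw: dict[str, float]
    displayed: dict[str, float]


def reference_ratio(lesion: CaseSummary, reference: CaseSummary) -> ReferenceRatios:
    """Elementwise lesion/reference median ratios over shared parameters."""
    params = [p for p in PARAMETERS if p in lesion.stats and p in reference.stats]
    if not params:
        raise ValueError("summaries share no parameters")
    raw = {}
    for p in params:
        denom = reference.value(p, "median")
        if denom == 0:
            raise ValueError(f"reference median for {p!r} is zero")
        raw[p] = lesion.value(p, "median") / denom
    return ReferenceRatios(raw=raw, displayed={p: round(v, 1) for p, v in raw.items()})


def compare_groups(x, y, test: str = "mannwhitney"):
    """Two-sided two-sample comparison of nucleus-level values.

    ``mannwhitney`` (non-normal data, the usual case for nuclear areas)
    returns (U, p); ``ttest`` returns (t, p). Thin convenience wrapper —
    no multiplicity correction is applied.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if test == "mannwhitney":
        res = sps.mannwhitneyu(x, y, alternative="two-sided")
    elif test == "ttest":
        res = sps.ttest_ind(x, y)
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)
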