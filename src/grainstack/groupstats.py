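"""Subject-level group statistics.

Two-group comparisons follow a standard postmortem-tissue design: an
analysis of covariance adjusting for tissue-quality covariates (postmortem
interval, RNA integrity number, tissue pH), independent and paired t-tests,
Pearson correlations, and qPCR relative expression normalized to the
geometric mean of two reference genes (ACTB, GAPDH).  All tests are
two-tailed at alpha = 0.05 and summaries are mean +/- sample s.d.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateInputError

__all__ = [
    "SubjectRecord",
    "ComparisonResult",
    "CtTable",
    "subjects_to_frame",
    "ancova_compare",
    "t_test",
    "pearson_correlation",
    "relative_expression",
    "summarize",
]

DEFAULT_COVARIATES = ("pmi", "rin", "ph")


@dataclass
class SubjectRecord:
    """One subject: group membership, tissue covariates, measurements."""

    id: str
    group: str
    age: float
    pmi: float  # postmortem interval, hours
    rin: float  # RNA integrity number
    ph: float
    measurements: dict[str, float] = field(default_factory=dict)


def subjects_to_frame(subjects: list[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for s in subjects:
        row = {"id": s.id, "group": s.group, "age": s.age, "pmi": s.pmi,
               "rin": s.rin, "ph": s.ph}
        row.update(s.measurements)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ComparisonResult:
    """Outcome of one two-group comparison."""

    measurement: str
    group_names: tuple[str, str]  # (reference, other)
    group_means: tuple[float, float]
    group_sds: tuple[float, float]
    effect: float  # other - reference, adjusted where applicable
    percent_change: float  # (mean_ref - mean_other) / mean_ref * 100
    statistic: float
    p_value: float
    test: str
    covariates_retained: list[str] = field(default_factory=list)
    covariate_pvalues: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")


def _group_summary(values: np.ndarray) -> tuple[float, float]:
    return float(np.mean(values)), float(np.std(values, ddof=1)) if len(values) > 1 else float("nan")


def ancova_compare(
    subjects: list[SubjectRecord],
    measurement: str,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    reference_group: str | None = None,
    alpha: float = 0.05,
) -> ComparisonResult:
    """Two-group ANCOVA of ``measurement`` adjusting for tissue covariates.

    Fits ``measurement ~ group + covariates`` by OLS and reports the group
    effect from the full model.  Covariates reaching p < alpha are flagged in
    ``covariates_retained`` (reporting-time filtering; the model itself is
    never re-selected, so the group estimate is always adjusted for every
    usable covariate).  Constant or collinear covariates are dropped with a
    warning before fitting.
    """
    import statsmodels.api as sm

    df = subjects_to_frame(subjects).dropna(subset=[measurement])
    groups = sorted(df["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, found {groups}")
    if reference_group is None:
        reference_group = groups[0]
    other_group = next(g for g in groups if g != reference_group)
    for g in (reference_group, other_group):
        if (df["group"] == g).sum() < 2:
            raise ValueError(f"need >= 2 subjects per group; group {g!r} is smaller")

    usable = []
    for cov in covariates:
        col = df[cov].to_numpy(dtype=float)
        if np.ptp(col) == 0:
            warnings.warn(f"covariate {cov!r} is constant; dropped from the model")
            continue
        usable.append(cov)
    # drop collinear covariates (exact linear dependence among covariates)
    while usable:
        X = df[usable].to_numpy(dtype=float)
        X = np.column_stack([np.ones(len(df)), X])
        if np.linalg.matrix_rank(X) == X.shape[1]:
            break
        dropped = usable.pop()
        warnings.warn(f"covariate {dropped!r} is collinear; dropped from the model")

    dummy = (df["group"] == other_group).astype(float).to_numpy()
    design = pd.DataFrame({"group": dummy})
    for cov in usable:
        design[cov] = df[cov].to_numpy(dtype=float)
    X = sm.add_constant(design)
    model = sm.OLS(df[measurement].to_numpy(dtype=float), X).fit()

    ref_vals = df.loc[df["group"] == reference_group, measurement].to_numpy(dtype=float)
    oth_vals = df.loc[df["group"] == other_group, measurement].to_numpy(dtype=float)
    mean_ref, sd_ref = _group_summary(ref_vals)
    mean_oth, sd_oth = _group_summary(oth_vals)

    cov_p = {cov: float(model.pvalues[cov]) for cov in usable}
    return ComparisonResult(
        measurement=measurement,
        group_names=(reference_group, other_group),
        group_means=(mean_ref, mean_oth),
        group_sds=(sd_ref, sd_oth),
        effect=float(model.params["group"]),
        percent_change=float((mean_ref - mean_oth) / mean_ref * 100) if mean_ref != 0 else float("nan"),
        statistic=float(model.tvalues["group"]),
        p_value=float(model.pvalues["group"]),
        test="ancova",
        covariates_retained=[c for c in usable if cov_p[c] < alpha],
        covariate_pvalues=cov_p,
    )


def t_test(
    values_a, values_b, paired: bool = False,
    group_names: tuple[str, str] = ("a", "b"),
    measurement: str = "",
) -> ComparisonResult:
    """Two-tailed independent or paired t-test."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need n >= 2 per sample")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired samples must have equal lengths")
        diff = a - b
        if np.ptp(diff) == 0:
            if diff[0] == 0:  # identical samples: no difference at all
                t, p = 0.0, 1.0
            else:
                raise DegenerateInputError("paired differences have zero variance")
        else:
            t, p = sps.ttest_rel(a, b)
    else:
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            raise DegenerateInputError("both samples have zero variance")
        t, p = sps.ttest_ind(a, b)

    mean_a, sd_a = _group_summary(a)
    mean_b, sd_b = _group_summary(b)
    return ComparisonResult(
        measurement=measurement,
        group_names=group_names,
        group_means=(mean_a, mean_b),
        group_sds=(sd_a, sd_b),
        effect=float(mean_b - mean_a),
        percent_change=float((mean_a - mean_b) / mean_a * 100) if mean_a != 0 else float("nan"),
        statistic=float(t),
        p_value=float(p),
        test="paired t-test" if paired else "independent t-test",
    )


def pearson_correlation(x, y) -> tuple[float, float]:
    """Pearson R and two-tailed p-value (t transform)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("correlation undefined for zero-variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class CtTable:
    """qPCR threshold cycles: long-format (sample, gene, ct) with replicates."""

    data: pd.DataFrame  # columns: sample, gene, ct

    def __post_init__(self) -> None:
        required = {"sample", "gene", "ct"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"CtTable needs columns {sorted(required)}")
        if (self.data["ct"] <= 0).any():
            raise ValueError("threshold cycles must be > 0")

    def collapsed(self) -> pd.DataFrame:
        """Replicates collapsed by arithmetic mean -> sample x gene matrix."""
        return self.data.groupby(["sample", "gene"])["ct"].mean().unstack("gene")


def relative_expression(
    ct: CtTable,
    target: str,
    references: tuple[str, str] = ("ACTB", "GAPDH"),
    method: str = "ct-geomean",
) -> pd.Series:
    """Per-sample relative expression of ``target`` by delta-Ct.

    Default (``ct-geomean``): reference Ct = geometric mean of the two
    reference-gene cycle numbers, sqrt(Ct_1 * Ct_2);
    ``expression = 2 ** -(Ct_target - Ct_reference)``.  The alternative
    ``efficiency`` method averages the reference Cts arithmetically, which
    equals the geometric mean of the 2^-Ct efficiencies.
    """
    wide = ct.collapsed()
    missing = [g for g in (target, *references) if g not in wide.columns]
    if missing:
        raise ValueError(f"missing gene(s) in Ct table: {missing}")
    if wide[list(references)].isna().any().any():
        raise ValueError("every sample needs both reference genes")
    if method == "ct-geomean":
        ref = np.sqrt(wide[references[0]] * wide[references[1]])
    elif method == "efficiency":
        ref = 0.5 * (wide[references[0]] + wide[references[1]])
    else:
        raise ValueError(f"unknown method {method!r}")
    delta_ct = wide[target] - ref
    return np.power(2.0, -delta_ct).rename(f"{target}_relative_expression")


def summarize(values) -> tuple[float, float]:
    """Arithmetic mean and sample s.d. (n-1 denominator)."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need n >= 2 to report mean +/- s.d.")
    return float(np.mean(v)), float(np.std(v, ddof=1))
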