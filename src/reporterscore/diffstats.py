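"""Per-KO differential tests between two sample groups.

Given a KO x sample abundance table and a two-group assignment, this module
produces one :class:`KOStat` per feature: a two-sided P value and a signed
test statistic whose sign is positive when the treatment group's location
exceeds the reference group's. These P values are the raw material of the
reporter-score inverse-normal transform; the signs feed only the directed
(Reporter-Feature-style) mode.

Supported tests: Student's t (pooled variance), Welch's t (default; unequal
variances are the norm in abundance data) and the two-sample Wilcoxon
rank-sum test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, ValidationError

logger = logging.getLogger(__name__)

METHODS = ("student_t", "welch_t", "wilcoxon")
DEFAULT_METHOD = "welch_t"


@dataclass(frozen=True)
class KOStat:
    """Differential-test result for one KO.

    ``statistic`` is signed: positive iff the treatment group's mean (or
    rank location) exceeds the reference group's. ``p_value`` is two-sided.
    """

    ko_id: str
    p_value: float
    statistic: float
    test_name: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(
                f"p_value for {self.ko_id} outside [0, 1]: {self.p_value}"
            )
        if not np.isfinite(self.statistic):
            raise ValidationError(
                f"statistic for {self.ko_id} is not finite: {self.statistic}"
            )


@dataclass
class AbundanceTable:
    """Feature x sample numeric matrix with unique identifiers on both axes."""

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValidationError("duplicate feature ids in abundance table")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids in abundance table")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValidationError(
                f"abundance matrix shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if np.isnan(self.values).any():
            raise ValidationError("abundance table contains missing values")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "AbundanceTable":
        return cls(
            feature_ids=[str(i) for i in df.index],
            sample_ids=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.feature_ids, columns=self.sample_ids
        )


@dataclass
class GroupAssignment:
    """Maps sample ids to exactly two group labels, one of them the reference."""

    assignments: dict[str, str]
    reference: str

    labels: tuple[str, str] = field(init=False)

    def __post_init__(self) -> None:
        labels = sorted(set(self.assignments.values()))
        if len(labels) != 2:
            raise ValidationError(
                f"expected exactly two group labels, found {labels}"
            )
        if self.reference not in labels:
            raise ValidationError(
                f"reference group {self.reference!r} not among labels {labels}"
            )
        self.labels = (self.reference, self.treatment)

    @property
    def treatment(self) -> str:
        return next(
            lab for lab in set(self.assignments.values()) if lab != self.reference
        )

    def samples(self, label: str) -> list[str]:
        return [s for s, g in self.assignments.items() if g == label]


def _rank_sum_one(
    treat: np.ndarray, ref: np.ndarray
) -> tuple[float, float]:
    """Two-sample Wilcoxon rank-sum: (signed standardized statistic, p).

    Exact enumeration when both groups have <= 20 samples and the pooled data
    are tie-free; otherwise the normal approximation with tie correction.
    The continuity correction is disabled so perfectly balanced tied inputs
    yield p = 1 exactly.
    """
    n1, n2 = len(treat), len(ref)
    pooled = np.concatenate([treat, ref])
    has_ties = len(np.unique(pooled)) < len(pooled)
    mu_u = n1 * n2 / 2.0
    if not has_ties and n1 <= 20 and n2 <= 20:
        res = stats.mannwhitneyu(treat, ref, alternative="two-sided", method="exact")
        sd_u = np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
        z = (res.statistic - mu_u) / sd_u if sd_u > 0 else 0.0
        return float(z), float(res.pvalue)
    # tie-corrected variance of U
    _, counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1)) if n > 1 else 0.0
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    ranks = stats.rankdata(pooled)
    u1 = np.sum(ranks[:n1]) - n1 * (n1 + 1) / 2.0
    if var_u <= 0:
        logger.warning("all pooled values identical in rank-sum test; p set to 1")
        return 0.0, 1.0
    z = (u1 - mu_u) / np.sqrt(var_u)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def test_two_groups(
    table: AbundanceTable,
    groups: GroupAssignment,
    method: str = DEFAULT_METHOD,
    log_transform: bool = False,
) -> list[KOStat]:
    """Run the chosen two-group test on every feature of ``table``.

    Returns one :class:`KOStat` per feature, in input feature order, with
    two-sided P values. With ``log_transform`` abundances are mapped through
    log(x + 1) first (no transform is the default).

    Features with zero variance in both groups under the t variants are
    reported as p = 1 / statistic = 0 with a logged warning so a flat KO
    cannot abort a run.
    """
    if method not in METHODS:
        raise ConfigError(f"unknown test method {method!r}; choose from {METHODS}")

    missing = [s for s in groups.assignments if s not in table.sample_ids]
    if missing:
        raise ValidationError(
            f"samples in metadata but not in abundance table: {missing}"
        )
    ref_samples = groups.samples(groups.reference)
    trt_samples = groups.samples(groups.treatment)
    min_n = 2 if method != "wilcoxon" else 1
    for lab, samp in ((groups.reference, ref_samples), (groups.treatment, trt_samples)):
        if len(samp) < min_n:
            raise ValidationError(
                f"group {lab!r} has {len(samp)} samples; {min_n} required for {method}"
            )

    col = {s: j for j, s in enumerate(table.sample_ids)}
    values = table.values
    if log_transform:
        if (values < 0).any():
            raise ValidationError("negative abundances cannot be log-transformed")
        values = np.log1p(values)
    trt = values[:, [col[s] for s in trt_samples]]
    ref = values[:, [col[s] for s in ref_samples]]

    if method == "wilcoxon":
        out = []
        for i, ko in enumerate(table.feature_ids):
            z, p = _rank_sum_one(trt[i], ref[i])
            out.append(KOStat(ko, p, z, method))
        return out

    equal_var = method == "student_t"
    with warnings.catch_warnings():
        # near-constant features trigger scipy's precision-loss warning;
        # the degenerate rows are overwritten below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(trt, ref, axis=1, equal_var=equal_var)
    tvals = np.asarray(res.statistic, dtype=float)
    pvals = np.asarray(res.pvalue, dtype=float)
    flat = (trt.var(axis=1) == 0) & (ref.var(axis=1) == 0)
    if flat.any():
        for i in np.flatnonzero(flat):
            logger.warning(
                "feature %s has zero variance in both groups; p set to 1",
                table.feature_ids[i],
            )
        tvals[flat] = 0.0
        pvals[flat] = 1.0
    return [
        KOStat(ko, float(pvals[i]), float(tvals[i]), method)
        for i, ko in enumerate(table.feature_ids)
    ]


def stats_to_frame(ko_stats: list[KOStat]) -> pd.DataFrame:
    """Serialize KOStat rows as the `ko`, `p_value`, `statistic`, `test` table."""
    return pd.DataFrame(
        {
            "ko": [s.ko_id for s in ko_stats],
            "p_value": [s.p_value for s in ko_stats],
            "statistic": [s.statistic for s in ko_stats],
            "test": [s.test_name for s in ko_stats],
        }
    )
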