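"""Subgroup-vs-pooled-reference equivalence statistics.

The engine answers one question per (test, category, subgroup): do the
feature values of participants in a device-defined subgroup (an OS
platform, an OS version, a device model) come from the same distribution
as everybody else in the category pooled together?

Procedure per comparison:

1. features are covariate-adjusted (age, sex, disease status) with a
   Huber robust linear model, keeping values on their native scale
   (adjusted = fitted intercept + residual);
2. the observed statistic difference (mean, or median for the
   sensitivity analysis) between subgroup and pooled reference is tested
   by Monte-Carlo permutation: pooled values are randomly re-split at
   the original group sizes, p = (1 + #{|perm diff| >= |observed|}) /
   (B + 1);
3. the 95% interval of |difference| expected under the null is the
   (alpha/2, 1-alpha/2) quantile pair of the permuted |differences|;
4. Cohen's d, absolute and percent differences are reported, and
   unadjusted p-values are Benjamini-Hochberg corrected within each
   (test, category) family.

Only subgroups with at least ``min_subgroup_n`` participants enter,
both as subject and as part of a reference.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .types import BUNDLED_TESTS, SchemaError, TESTS

log = logging.getLogger(__name__)

#: Subgroup categories and the cohort column + platform filter each uses.
CATEGORY_DEFS = {
    "os_platform": ("os_platform", None),
    "ios_version": ("os_version", "iOS"),
    "android_version": ("os_version", "Android"),
    "device_model": ("device_model", None),
    "device_class": ("device_class", None),
}

DEFAULT_CATEGORIES = ("os_platform", "ios_version", "android_version",
                      "device_model")


@dataclass
class AnalysisConfig:
    n_permutations: int = 10_000
    min_subgroup_n: int = 20
    alpha: float = 0.05
    ci_level: float = 0.95
    statistic: str = "mean"  # or "median"
    fdr_method: str = "fdr_bh"
    categories: Sequence[str] = DEFAULT_CATEGORIES
    covariates: Sequence[str] = ("age", "sex", "ms_status")
    huber_t: float = 1.345
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise SchemaError("n_permutations must be >= 1")
        if self.min_subgroup_n < 2:
            raise SchemaError("min_subgroup_n must be >= 2")
        for name in ("alpha", "ci_level"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise SchemaError(f"{name} must lie in (0, 1)")
        if self.statistic not in ("mean", "median"):
            raise SchemaError(f"unknown statistic {self.statistic!r}")
        for cat in self.categories:
            if cat not in CATEGORY_DEFS:
                raise SchemaError(f"unknown category {cat!r}")

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown analysis config keys: "
                              f"{sorted(unknown)}")
        return cls(**data)


@dataclass
class PermutationResult:
    observed_diff: float
    null_diffs: np.ndarray
    p_unadjusted: float
    ci_low: float
    ci_high: float


# ---------------------------------------------------------------------------
# first-valid-session selection
# ---------------------------------------------------------------------------

def select_first_valid(session_table: pd.DataFrame) -> pd.DataFrame:
    """Per-participant features from the first fully valid test run.

    ``session_table`` needs columns participant_id, test_type,
    run_index, valid, feature_name, value (one row per session). The
    five bundled tests are taken together: the earliest run in which
    *all five* are valid supplies those five features; a participant
    with no fully valid run contributes none of them. The 2-minute walk
    is self-administered separately, so its feature comes from the first
    valid walk independently. Participants with neither are excluded
    (an outcome, not an error).
    """
    required = {"participant_id", "test_type", "run_index", "valid",
                "feature_name", "value"}
    missing = required - set(session_table.columns)
    if missing:
        raise SchemaError(f"session table missing columns {sorted(missing)}")
    out = []
    for pid, grp in session_table.groupby("participant_id", sort=True):
        bundle = grp[grp.test_type.isin(BUNDLED_TESTS)]
        for run in sorted(bundle.run_index.unique()):
            run_rows = bundle[bundle.run_index == run]
            have = set(run_rows.test_type)
            if have >= set(BUNDLED_TESTS) and run_rows.valid.all():
                out.append(run_rows)
                break
        walks = grp[(grp.test_type == "MWT2") & grp.valid]
        if len(walks):
            out.append(walks.sort_values("run_index").iloc[:1])
    if not out:
        return session_table.iloc[0:0][["participant_id", "test_type",
                                        "feature_name", "value"]]
    return (pd.concat(out, ignore_index=True)
            [["participant_id", "test_type", "feature_name", "value"]])


# ---------------------------------------------------------------------------
# covariate adjustment
# ---------------------------------------------------------------------------

def adjust_covariates(features: pd.DataFrame, cohort: pd.DataFrame,
                      config: AnalysisConfig = AnalysisConfig()
                      ) -> pd.DataFrame:
    """Remove age/sex/disease effects with a Huber robust linear model.

    Fits, per test, value ~ age + male + MS by M-estimation (Huber psi,
    tuning constant 1.345 for 95% Gaussian efficiency) and returns the
    table with an ``adjusted_value`` column equal to intercept +
    residual, i.e. covariate effects removed but the feature kept on its
    native scale. Participants with missing covariates are dropped with
    a log entry.
    """
    merged = features.merge(cohort[["participant_id", "age", "sex",
                                    "ms_status"]],
                            on="participant_id", how="left")
    missing = merged[["age", "sex", "ms_status"]].isna().any(axis=1)
    if missing.any():
        dropped = merged.loc[missing, "participant_id"].unique()
        log.warning("dropping %d participants with missing covariates: %s",
                    len(dropped), list(dropped[:5]))
        merged = merged[~missing]
    pieces = []
    for test, grp in merged.groupby("test_type", sort=True):
        y = grp["value"].to_numpy(dtype=float)
        X = np.column_stack([
            grp["age"].to_numpy(dtype=float),
            (grp["sex"] == "male").to_numpy(dtype=float),
            (grp["ms_status"] == "MS").to_numpy(dtype=float),
        ])
        # center covariates so the intercept sits at the cohort-mean
        # covariate profile and adjusted values keep the native level
        X = sm.add_constant(X - X.mean(axis=0), has_constant="add")
        if len(grp) <= X.shape[1] or np.allclose(y.std(), 0.0):
            adjusted = y  # too few points to fit; leave unadjusted
        else:
            fit = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=config.huber_t)
                         ).fit()
            adjusted = fit.params[0] + (y - fit.predict(X))
        piece = grp.copy()
        piece["adjusted_value"] = adjusted
        pieces.append(piece)
    return pd.concat(pieces, ignore_index=True)


def fit_robust_slope(y: np.ndarray, x: np.ndarray,
                     huber_t: float = 1.345) -> tuple[float, float]:
    """Huber-M slope and its standard error for a single covariate."""
    X = sm.add_constant(np.asarray(x, dtype=float))
    fit = sm.RLM(np.asarray(y, dtype=float), X,
                 M=sm.robust.norms.HuberT(t=huber_t)).fit()
    return float(fit.params[1]), float(fit.bse[1])


# ---------------------------------------------------------------------------
# subgroup construction
# ---------------------------------------------------------------------------

def build_subgroups(cohort: pd.DataFrame, category: str,
                    config: AnalysisConfig = AnalysisConfig()) -> dict:
    """Qualifying subgroup -> (member ids, pooled reference ids).

    The reference for each subgroup is the union of all *other
    qualifying* subgroups of the same category; subgroups under the
    minimum size take part in neither role. Version categories are
    restricted to their platform.
    """
    if category not in CATEGORY_DEFS:
        raise SchemaError(f"unknown category {category!r}")
    column, platform = CATEGORY_DEFS[category]
    pool = cohort if platform is None else cohort[
        cohort.os_platform == platform]
    counts = pool[column].value_counts()
    qualifying = [lab for lab in counts.index
                  if counts[lab] >= config.min_subgroup_n]
    if len(qualifying) < 2:
        log.info("category %s has %d qualifying subgroups; no comparisons",
                 category, len(qualifying))
        return {}
    members = {lab: set(pool.loc[pool[column] == lab, "participant_id"])
               for lab in qualifying}
    return {lab: (members[lab],
                  set().union(*(members[o] for o in qualifying if o != lab)))
            for lab in qualifying}


# ---------------------------------------------------------------------------
# permutation testing and effect sizes
# ---------------------------------------------------------------------------

def _stat_fn(name: str):
    return np.mean if name == "mean" else np.median


def permutation_test(subgroup: np.ndarray, reference: np.ndarray,
                     config: AnalysisConfig = AnalysisConfig(),
                     rng: Optional[np.random.Generator] = None
                     ) -> PermutationResult:
    """Monte-Carlo permutation test of the statistic difference.

    Pooled values are randomly re-split ``n_permutations`` times at the
    original group sizes; the two-sided p-value uses the add-one
    convention (1 + #{|perm| >= |obs|}) / (B + 1), which never reaches
    zero and converges to the plain proportion as B grows. The interval
    (ci_low, ci_high) holds the central ci_level quantiles of the
    permuted |differences| — the differences expected under the null.
    """
    subgroup = np.asarray(subgroup, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if subgroup.size == 0 or reference.size == 0:
        raise SchemaError("both groups must be nonempty")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    stat = _stat_fn(config.statistic)
    observed = float(stat(subgroup) - stat(reference))
    pooled = np.concatenate([subgroup, reference])
    n1, N = subgroup.size, pooled.size
    B = config.n_permutations

    null = np.empty(B)
    chunk = max(1, min(B, int(4e6 // max(N, 1))))
    use_mean = config.statistic == "mean"
    total = pooled.sum()
    for start in range(0, B, chunk):
        b = min(chunk, B - start)
        keys = rng.random((b, N))
        if use_mean:
            idx = np.argpartition(keys, n1 - 1, axis=1)[:, :n1]
            sub_sum = pooled[idx].sum(axis=1)
            null[start:start + b] = (sub_sum / n1
                                     - (total - sub_sum) / (N - n1))
        else:
            order = np.argsort(keys, axis=1)
            perm = pooled[order]
            null[start:start + b] = (np.median(perm[:, :n1], axis=1)
                                     - np.median(perm[:, n1:], axis=1))
    abs_null = np.abs(null)
    p = (1.0 + int((abs_null >= abs(observed) - 1e-12).sum())) / (B + 1.0)
    lo, hi = np.quantile(abs_null, [(1 - config.ci_level) / 2,
                                    (1 + config.ci_level) / 2])
    return PermutationResult(observed_diff=observed, null_diffs=null,
                             p_unadjusted=float(p), ci_low=float(lo),
                             ci_high=float(hi))


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """|mean difference| / pooled SD (degrees-of-freedom weighted)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise SchemaError("Cohen's d needs >= 2 values per group")
    return cohens_d_from_stats(a.size, a.mean(), a.std(ddof=1),
                               b.size, b.mean(), b.std(ddof=1))


def cohens_d_from_stats(n1: int, mean1: float, sd1: float,
                        n2: int, mean2: float, sd2: float) -> float:
    """Cohen's d from per-group summary statistics."""
    pooled_var = (((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2)
                  / (n1 + n2 - 2))
    if pooled_var == 0:
        if mean1 == mean2:
            return 0.0
        raise SchemaError("Cohen's d undefined: zero pooled SD with "
                          "unequal means")
    return abs(mean1 - mean2) / float(np.sqrt(pooled_var))


def percent_difference(subgroup_mean: float, reference_mean: float) -> float:
    """100 * |subgroup - reference| / |reference|."""
    if reference_mean == 0:
        raise SchemaError("percent difference undefined for zero "
                          "reference mean")
    return 100.0 * abs(subgroup_mean - reference_mean) / abs(reference_mean)


def adjust_fdr(p_values: Sequence[float], method: str = "fdr_bh"
               ) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment within one family."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise SchemaError("p-values must lie in (0, 1]")
    return multipletests(p, method=method)[1]


def rank_sum_test(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact enumeration for small samples (combined n <= 12, no ties),
    tie-corrected normal approximation otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise SchemaError("both groups must be nonempty")
    combined = np.concatenate([a, b])
    no_ties = np.unique(combined).size == combined.size
    method = "exact" if (combined.size <= 12 and no_ties) else "asymptotic"
    return float(mannwhitneyu(a, b, alternative="two-sided",
                              method=method).pvalue)


# ---------------------------------------------------------------------------
# full equivalence analysis
# ---------------------------------------------------------------------------

COMPARISON_COLUMNS = [
    "test_type", "category", "subgroup", "statistic", "n_subgroup",
    "n_reference", "mean_subgroup", "sd_subgroup", "mean_reference",
    "sd_reference", "absolute_difference", "percent_difference",
    "effect_size", "ci_low", "ci_high", "p_unadjusted", "p_adjusted",
]


def run_equivalence(adjusted: pd.DataFrame, cohort: pd.DataFrame,
                    config: AnalysisConfig = AnalysisConfig()
                    ) -> pd.DataFrame:
    """All subgroup-vs-reference comparisons, FDR-corrected per family.

    ``adjusted`` needs columns participant_id, test_type and
    adjusted_value (one row per participant per test). Returns one row
    per (test, category, subgroup) with group summaries, the permutation
    result and BH-adjusted p-values (family = category x test).
    """
    if "adjusted_value" not in adjusted.columns:
        raise SchemaError("run_equivalence expects covariate-adjusted "
                          "features (adjust_covariates output)")
    ss = np.random.SeedSequence(config.seed)
    rows = []
    for category in config.categories:
        partitions = build_subgroups(cohort, category, config)
        if not partitions:
            continue
        for test in TESTS:
            sub_table = adjusted[adjusted.test_type == test]
            values = sub_table.set_index("participant_id")["adjusted_value"]
            family = []
            for label in sorted(partitions):
                member_ids, reference_ids = partitions[label]
                sub = values.reindex(sorted(member_ids)).dropna().to_numpy()
                ref = values.reindex(sorted(reference_ids)).dropna(
                    ).to_numpy()
                if (sub.size < config.min_subgroup_n
                        or ref.size < config.min_subgroup_n):
                    continue
                rng = np.random.default_rng(ss.spawn(1)[0])
                perm = permutation_test(sub, ref, config, rng)
                stat = _stat_fn(config.statistic)
                family.append({
                    "test_type": test, "category": category,
                    "subgroup": label, "statistic": config.statistic,
                    "n_subgroup": sub.size, "n_reference": ref.size,
                    "mean_subgroup": float(sub.mean()),
                    "sd_subgroup": float(sub.std(ddof=1)),
                    "mean_reference": float(ref.mean()),
                    "sd_reference": float(ref.std(ddof=1)),
                    "absolute_difference": abs(float(stat(sub))
                                               - float(stat(ref))),
                    "percent_difference": percent_difference(
                        float(stat(sub)), float(stat(ref))),
                    "effect_size": cohens_d(sub, ref),
                    "ci_low": perm.ci_low, "ci_high": perm.ci_high,
                    "p_unadjusted": perm.p_unadjusted,
                })
            if family:
                adj = adjust_fdr([r["p_unadjusted"] for r in family],
                                 config.fdr_method)
                for r, pa in zip(family, adj):
                    r["p_adjusted"] = float(pa)
                rows.extend(family)
    return pd.DataFrame(rows, columns=COMPARISON_COLUMNS)


def screen_size_comparison(adjusted: pd.DataFrame, cohort: pd.DataFrame,
                           config: AnalysisConfig = AnalysisConfig()
                           ) -> pd.DataFrame:
    """Smartphone-vs-tablet comparison by Mann-Whitney U, per test."""
    classes = cohort.set_index("participant_id")["device_class"]
    rows = []
    for test in TESTS:
        grp = adjusted[adjusted.test_type == test].copy()
        grp["device_class"] = grp.participant_id.map(classes)
        phones = grp.loc[grp.device_class == "smartphone",
                         "adjusted_value"].to_numpy()
        tablets = grp.loc[grp.device_class == "tablet",
                          "adjusted_value"].to_numpy()
        if phones.size < 2 or tablets.size < 2:
            continue
        rows.append({
            "test_type": test,
            "n_smartphone": phones.size, "n_tablet": tablets.size,
            "mean_smartphone": float(phones.mean()),
            "mean_tablet": float(tablets.mean()),
            "percent_difference": percent_difference(float(tablets.mean()),
                                                     float(phones.mean())),
            "effect_size": cohens_d(tablets, phones),
            "p_value": rank_sum_test(phones, tablets),
        })
    return pd.DataFrame(rows)
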