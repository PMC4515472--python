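"""Statistical layer: comparative-Ct qPCR analysis and the tests applied to
counts, measurements and ranks.

Expression is quantified by the comparative-Ct (2^-ΔΔCt) method against a
housekeeping gene (rp49).  Mitosis counts, which are over-dispersed, are
tested with a negative-binomial GLM followed by a likelihood-ratio test.
Normally distributed measurements use Welch's t-test; paired qPCR batches
use a paired t-test; rank-based reporter experiments use the Mann-Whitney
test (exact by enumeration at small n, tie-corrected normal approximation
otherwise).  Families of comparisons are Holm-adjusted; family membership
is always declared by the caller, never guessed.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CtTable",
    "CountData",
    "TestResult",
    "comparative_ct",
    "paired_t",
    "nb_glm_lrt",
    "welch_t",
    "mann_whitney",
    "holm_adjust",
    "hatch_fraction",
]

CONDITIONS = ("virgin", "mated")


@dataclass
class CtTable:
    """Long-format qPCR table.

    ``data`` columns: gene, sample_id, condition (virgin/mated), batch_id,
    ct.  Technical replicates are separate rows.
    """

    data: pd.DataFrame
    housekeeping_gene: str = "rp49"

    def __post_init__(self) -> None:
        required = {"gene", "sample_id", "condition", "batch_id", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"CtTable missing columns {sorted(missing)}")
        if (self.data["ct"] <= 0).any():
            raise ValueError("Ct values must be positive")
        bad = set(self.data["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown conditions {sorted(bad)}")


@dataclass
class CountData:
    """Long-format count table: unit_id, group, count (non-negative int)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"unit_id", "group", "count"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"CountData missing columns {sorted(missing)}")
        counts = self.data["count"]
        if (counts < 0).any() or not np.allclose(counts, counts.astype(int)):
            raise ValueError("counts must be non-negative integers")
        if self.data["group"].nunique() < 2:
            raise ValueError("need at least 2 groups")


@dataclass
class TestResult:
    """Outcome of one hypothesis test."""

    method: str
    statistic: float
    df: Optional[float]
    p_raw: float
    exact: bool = False
    p_adjusted: Optional[float] = None
    family_id: Optional[str] = None
    flags: tuple[str, ...] = ()
    extra: dict = field(default_factory=dict)


def comparative_ct(table: CtTable, gene: str) -> pd.DataFrame:
    """Relative expression of ``gene`` by the comparative-Ct method.

    Technical replicate Cts are averaged per (sample, gene) first; per
    sample ΔCt = Ct_gene - Ct_housekeeping; per batch
    ΔΔCt = mean ΔCt(mated) - mean ΔCt(virgin) and fold = 2^(-ΔΔCt).

    Returns a per-batch frame with columns ``batch_id, delta_ct_virgin,
    delta_ct_mated, ddct, fold``.
    """
    df = table.data
    hk = table.housekeeping_gene
    genes = set(df["gene"])
    if gene not in genes:
        raise ValueError(f"gene {gene!r} not in table")
    if hk not in genes:
        raise ValueError(f"housekeeping gene {hk!r} not in table")
    mean_ct = (
        df[df["gene"].isin([gene, hk])]
        .groupby(["batch_id", "condition", "sample_id", "gene"], as_index=False)["ct"]
        .mean()
    )
    wide = mean_ct.pivot_table(
        index=["batch_id", "condition", "sample_id"], columns="gene", values="ct"
    )
    missing_hk = wide[wide[hk].isna()] if hk in wide else wide
    if hk not in wide.columns or wide[hk].isna().any():
        samples = sorted(missing_hk.index.get_level_values("sample_id"))
        raise ValueError(f"housekeeping Ct missing for sample(s) {samples}")
    if wide[gene].isna().any():
        samples = sorted(
            wide[wide[gene].isna()].index.get_level_values("sample_id")
        )
        raise ValueError(f"gene Ct missing for sample(s) {samples}")
    wide = wide.reset_index()
    wide["delta_ct"] = wide[gene] - wide[hk]
    per_batch = (
        wide.groupby(["batch_id", "condition"])["delta_ct"].mean().unstack("condition")
    )
    for cond in CONDITIONS:
        if cond not in per_batch.columns or per_batch[cond].isna().any():
            raise ValueError(f"every batch needs both conditions; {cond!r} missing")
    out = pd.DataFrame(
        {
            "batch_id": per_batch.index,
            "delta_ct_virgin": per_batch["virgin"].to_numpy(),
            "delta_ct_mated": per_batch["mated"].to_numpy(),
        }
    )
    out["ddct"] = out["delta_ct_mated"] - out["delta_ct_virgin"]
    out["fold"] = 2.0 ** (-out["ddct"])
    return out


def paired_t(
    differences: Sequence[float], tail: Literal["one", "two"] = "two"
) -> TestResult:
    """Paired t-test on within-batch differences.

    ``tail='one'`` tests for a positive mean difference (used when a prior
    experiment predicts the direction).  Zero variance of the differences is
    a degenerate input and is flagged rather than raising.
    """
    d = np.asarray(differences, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 paired differences")
    sd = d.std(ddof=1)
    if sd == 0:
        return TestResult(
            method="paired t",
            statistic=np.nan,
            df=float(d.size - 1),
            p_raw=np.nan,
            flags=("zero_variance",),
        )
    t = d.mean() / (sd / np.sqrt(d.size))
    dof = d.size - 1
    if tail == "two":
        p = 2 * sps.t.sf(abs(t), dof)
    else:
        p = sps.t.sf(t, dof)
    return TestResult(method="paired t", statistic=float(t), df=float(dof), p_raw=float(p))


def _fit_nb_alpha(y: np.ndarray, X: np.ndarray) -> tuple[float, tuple[str, ...]]:
    """ML estimate of the NB2 dispersion alpha (var = mu + alpha mu^2)."""
    flags: tuple[str, ...] = ()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.NegativeBinomial(y, X).fit(disp=0, maxiter=200)
            alpha = float(res.params[-1])
            if not res.mle_retvals.get("converged", True):
                flags = ("nb_ml_not_converged",)
        except Exception:
            alpha, flags = np.nan, ("nb_ml_failed",)
    if not np.isfinite(alpha) or alpha <= 0:
        # method-of-moments fallback on pooled residual dispersion
        mu = y.mean()
        alpha = max((y.var(ddof=1) - mu) / mu**2 if mu > 0 else 0.0, 1e-8)
        flags = flags + ("alpha_from_moments",)
    return max(alpha, 1e-8), flags


def nb_glm_lrt(data: CountData) -> TestResult:
    """Negative-binomial GLM with a likelihood-ratio test of the group term.

    The model uses a log link with variance mu + mu^2/theta; the dispersion
    is estimated by maximum likelihood on the full (group) model and held
    fixed when fitting the intercept-only null, and the group effect is
    tested by 2*(llf_full - llf_null) against chi-square with
    (groups - 1) degrees of freedom.
    """
    df = data.data
    y = df["count"].to_numpy(dtype=float)
    if y.sum() == 0:
        raise ValueError("all counts are zero; nothing to model")
    groups = pd.Categorical(df["group"])
    k = len(groups.categories)
    if min(pd.Series(groups).value_counts()) < 2:
        raise ValueError("every group needs at least 2 units")
    X_full = np.column_stack(
        [np.ones(len(y))] + [(groups.codes == i).astype(float) for i in range(1, k)]
    )
    X_null = np.ones((len(y), 1))

    alpha, flags = _fit_nb_alpha(y, X_full)
    fam = sm.families.NegativeBinomial(alpha=alpha)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = sm.GLM(y, X_full, family=fam).fit()
        null = sm.GLM(y, X_null, family=fam).fit()
    lr = max(2.0 * (full.llf - null.llf), 0.0)
    dof = k - 1
    p = float(sps.chi2.sf(lr, dof))
    return TestResult(
        method="negative binomial GLM LRT",
        statistic=float(lr),
        df=float(dof),
        p_raw=p,
        flags=flags,
        extra={
            "alpha": alpha,
            "theta": 1.0 / alpha,
            "group_means": df.groupby("group")["count"].mean().to_dict(),
        },
    )


def welch_t(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sample t-test with Welch's unequal-variance correction
    (Welch-Satterthwaite degrees of freedom), two-tailed."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        degenerate = float(x.mean() != y.mean())
        return TestResult(
            method="Welch t",
            statistic=np.nan,
            df=np.nan,
            p_raw=np.nan if degenerate else 1.0,
            flags=("zero_variance",),
        )
    res = sps.ttest_ind(x, y, equal_var=False)
    return TestResult(
        method="Welch t",
        statistic=float(res.statistic),
        df=float(res.df),
        p_raw=float(res.pvalue),
    )


def _u_statistic(ranks: np.ndarray, idx: Sequence[int], n1: int) -> float:
    return float(ranks[list(idx)].sum() - n1 * (n1 + 1) / 2)


def mann_whitney(
    x: Sequence[float], y: Sequence[float], exact_threshold: int = 12
) -> TestResult:
    """Mann-Whitney-Wilcoxon rank-sum test, two-sided.

    For combined n <= ``exact_threshold`` the p-value is computed exactly by
    enumerating every assignment of the pooled observations to the two
    groups (ties handled naturally through mid-ranks of the pooled sample);
    otherwise the tie-corrected, continuity-corrected normal approximation
    is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u_obs = _u_statistic(ranks, range(n1), n1)
    mu = n1 * n2 / 2.0
    if n1 + n2 <= exact_threshold:
        total = 0
        extreme = 0
        crit = abs(u_obs - mu) - 1e-12
        for comb in itertools.combinations(range(n1 + n2), n1):
            u = _u_statistic(ranks, comb, n1)
            total += 1
            if abs(u - mu) >= crit:
                extreme += 1
        p = extreme / total
        return TestResult(
            method="Mann-Whitney (exact)",
            statistic=u_obs,
            df=None,
            p_raw=float(p),
            exact=True,
        )
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return TestResult(
        method="Mann-Whitney (normal approximation)",
        statistic=float(res.statistic),
        df=None,
        p_raw=float(res.pvalue),
        exact=False,
    )


def holm_adjust(
    p_values: Sequence[float], family_id: Optional[str] = None
) -> list[float]:
    """Holm step-down adjustment of one declared family of p-values.

    Sort ascending, multiply the i-th by (m - i + 1), enforce monotonicity
    by a running maximum, cap at 1, restore input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="holm")[1])


def hatch_fraction(
    vials: pd.DataFrame, family_id: str = "hatch"
) -> tuple[pd.DataFrame, pd.DataFrame, list[TestResult]]:
    """Per-vial hatched fraction with Welch comparisons between groups.

    ``vials`` columns: group, eggs_laid, eggs_hatched.  Vials with zero eggs
    laid are excluded with a warning; hatched > laid is a validation error.
    Returns (per-vial frame, per-group summary, Holm-adjusted pairwise Welch
    results).
    """
    required = {"group", "eggs_laid", "eggs_hatched"}
    if required - set(vials.columns):
        raise ValueError(f"vials frame needs columns {sorted(required)}")
    if (vials["eggs_hatched"] > vials["eggs_laid"]).any():
        raise ValueError("eggs_hatched cannot exceed eggs_laid")
    zero = vials["eggs_laid"] == 0
    if zero.any():
        warnings.warn(f"excluding {int(zero.sum())} vial(s) with zero eggs laid")
    df = vials[~zero].copy()
    df["fraction"] = df["eggs_hatched"] / df["eggs_laid"]
    summary = (
        df.groupby("group")["fraction"].agg(["mean", "std", "count"]).reset_index()
    )
    groups = list(summary["group"])
    results: list[TestResult] = []
    pairs = list(itertools.combinations(groups, 2))
    for a, b in pairs:
        res = welch_t(
            df.loc[df["group"] == a, "fraction"],
            df.loc[df["group"] == b, "fraction"],
        )
        res.family_id = family_id
        res.extra["pair"] = (a, b)
        results.append(res)
    valid = [r for r in results if np.isfinite(r.p_raw)]
    if valid:
        adjusted = holm_adjust([r.p_raw for r in valid], family_id)
        for r, p_adj in zip(valid, adjusted):
            r.p_adjusted = p_adj
    return df, summary, results
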