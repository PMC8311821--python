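"""Group statistics for the speech and clinical measures.

Two-tailed independent t tests (Welch form, fractional Satterthwaite df) for
approximately normal variables and Mann-Whitney U tests for skewed ones;
Pearson or Spearman correlations under the same skewness policy; and
control-referenced standardization of neuropsychological task scores into
cognitive-domain composites.

The Mann-Whitney z uses the tie-corrected normal approximation without
continuity correction; an exact permutation p-value by full enumeration is
used at small combined sample sizes.  No multiple-testing correction is
applied by default (a Benjamini-Hochberg flag is available on the table
builder for users who want one).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

EXACT_ENUMERATION_MAX_N = 12


@dataclass
class GroupComparison:
    test_name: str  # student_t | welch_t | mann_whitney
    statistic: float  # t or U (of the first group)
    p: float  # two-tailed
    df: float = float("nan")  # fractional for Welch
    z: float = float("nan")  # for the U test
    p_exact: float = float("nan")  # enumeration p, small samples only
    n1: int = 0
    n2: int = 0
    summary_a: dict = field(default_factory=dict)
    summary_b: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        return {
            "test": self.test_name,
            "statistic": self.statistic,
            "df": self.df,
            "z": self.z,
            "p": self.p,
        }


def _clean(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x[~np.isnan(x)]


def _summary(x: np.ndarray) -> dict:
    return {
        "n": int(x.size),
        "mean": float(np.mean(x)),
        "sd": float(np.std(x, ddof=1)) if x.size > 1 else float("nan"),
        "median": float(np.median(x)),
        "iqr": float(np.subtract(*np.percentile(x, [75, 25]))),
    }


# ---------------------------------------------------------------------------
# Mann-Whitney U


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U of the first sample via midrank sums."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r_a = ranks[: a.size].sum()
    return float(r_a - a.size * (a.size + 1) / 2.0)


def mann_whitney_exact_p(a, b) -> float:
    """Two-tailed permutation p by full enumeration of group labelings.

    p = P(|U - n1 n2 / 2| >= |U_obs - n1 n2 / 2|) over all C(n1+n2, n1)
    assignments (midranks handle ties).  Exponential in n; intended for
    n1 + n2 <= ~12.
    """
    a, b = _clean(a), _clean(b)
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    mu = n1 * n2 / 2.0
    offset = n1 * (n1 + 1) / 2.0
    dev_obs = abs(ranks[:n1].sum() - offset - mu)
    count = total = 0
    for idx in itertools.combinations(range(n1 + n2), n1):
        u = ranks[list(idx)].sum() - offset
        count += abs(u - mu) >= dev_obs - 1e-12
        total += 1
    return count / total


def mann_whitney(group_a, group_b, exact: bool | None = None) -> GroupComparison:
    """Mann-Whitney U with tie-corrected normal z (no continuity correction).

    ``statistic`` is U of the first group, so complete separation with the
    first group lower gives U = 0 and a negative z.  ``exact`` forces the
    enumeration p on or off; by default it is computed when
    n1 + n2 <= 12 and then reported as ``p``.
    """
    a, b = _clean(group_a), _clean(group_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2, n = a.size, b.size, a.size + b.size
    u = _u_statistic(a, b)
    mu = n1 * n2 / 2.0

    pooled = np.concatenate([a, b])
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all values identical
        z, p_norm = 0.0, 1.0
    else:
        z = (u - mu) / np.sqrt(var)
        p_norm = 2.0 * sps.norm.sf(abs(z))

    comp = GroupComparison(
        test_name="mann_whitney",
        statistic=u,
        z=float(z),
        p=float(min(p_norm, 1.0)),
        n1=n1,
        n2=n2,
        summary_a=_summary(a),
        summary_b=_summary(b),
    )
    if exact or (exact is None and n <= EXACT_ENUMERATION_MAX_N):
        comp.p_exact = mann_whitney_exact_p(a, b)
        comp.p = comp.p_exact
    return comp


# ---------------------------------------------------------------------------
# t tests


def welch_t(group_a, group_b) -> GroupComparison:
    """Welch's unequal-variance t with Satterthwaite fractional df."""
    a, b = _clean(group_a), _clean(group_b)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need n >= 2")
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    n1, n2 = a.size, b.size
    se2 = va / n1 + vb / n2
    diff = np.mean(a) - np.mean(b)
    if se2 == 0.0:
        t = 0.0 if diff == 0.0 else float(np.sign(diff) * np.inf)
        df, p = float("nan"), (1.0 if diff == 0.0 else 0.0)
    else:
        t = diff / np.sqrt(se2)
        df = se2**2 / ((va / n1) ** 2 / (n1 - 1) + (vb / n2) ** 2 / (n2 - 1))
        p = 2.0 * sps.t.sf(abs(t), df)
    return GroupComparison(
        test_name="welch_t",
        statistic=float(t),
        df=float(df),
        p=float(p),
        n1=n1,
        n2=n2,
        summary_a=_summary(a),
        summary_b=_summary(b),
    )


# ---------------------------------------------------------------------------
# Test selection policy


@dataclass(frozen=True)
class SkewPolicy:
    """When to fall back to rank-based tests.

    A variable is 'skewed' when either group's sample skewness exceeds the
    threshold in magnitude.  ``force`` overrides selection entirely.
    """

    threshold: float = 1.0
    force: str | None = None  # "welch_t" | "mann_whitney" | None


def sample_skewness(x) -> float:
    x = _clean(x)
    return float(sps.skew(x)) if x.size >= 3 else 0.0


def choose_test(sample_a, sample_b, policy: SkewPolicy | None = None) -> str:
    policy = policy or SkewPolicy()
    if policy.force is not None:
        return policy.force
    skewed = abs(sample_skewness(sample_a)) > policy.threshold or abs(
        sample_skewness(sample_b)
    ) > policy.threshold
    return "mann_whitney" if skewed else "welch_t"


def compare_groups(sample_a, sample_b, policy: SkewPolicy | None = None) -> GroupComparison:
    name = choose_test(sample_a, sample_b, policy)
    return mann_whitney(sample_a, sample_b) if name == "mann_whitney" else welch_t(sample_a, sample_b)


# ---------------------------------------------------------------------------
# Correlations


@dataclass
class CorrelationResult:
    method: str
    coefficient: float
    p: float
    n: int
    constant_input: bool = False


def correlate(x, y, method: str = "auto", policy: SkewPolicy | None = None) -> CorrelationResult:
    """Pearson or Spearman correlation with pairwise missing-data removal.

    ``auto`` applies the same skewness policy as group testing: ranks when
    either variable is skewed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be paired")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult(method, float("nan"), float("nan"), int(x.size), constant_input=True)
    if method == "auto":
        policy = policy or SkewPolicy()
        skewed = abs(sample_skewness(x)) > policy.threshold or abs(sample_skewness(y)) > policy.threshold
        method = "spearman" if skewed else "pearson"
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return CorrelationResult(method, float(r), float(p), int(x.size))


# ---------------------------------------------------------------------------
# Cognitive-domain standardization


def standardize_cognition(
    raw: pd.DataFrame,
    control_ids,
    domain_map: dict,
    id_col: str = "participant_id",
) -> pd.DataFrame:
    """Control-referenced z-scores organised into cognitive domains.

    ``domain_map`` maps domain name -> list of (task column, orientation)
    where orientation is +1 when higher raw scores mean better performance
    and -1 otherwise (completion times, error counts).  Each task is
    standardized against the control group's mean and SD and sign-oriented so
    higher is always better; a domain score is the mean of its member-task
    z-scores and the Grand score the mean of the domain scores.  Tasks whose
    control SD is zero carry no signal and are dropped with a warning.
    """
    import warnings

    control = raw[raw[id_col].isin(set(control_ids))]
    if control.empty:
        raise ValueError("no control participants found")
    out = pd.DataFrame({id_col: raw[id_col]})
    domain_scores = {}
    for domain, tasks in domain_map.items():
        cols = []
        for task, orientation in tasks:
            mu = control[task].mean()
            sd = control[task].std(ddof=1)
            if not np.isfinite(sd) or sd == 0:
                warnings.warn(f"task {task!r} has zero control SD; excluded", stacklevel=2)
                continue
            z = orientation * (raw[task] - mu) / sd
            out[f"z_{task}"] = z
            cols.append(z)
        if not cols:
            raise ValueError(f"domain {domain!r} has no usable tasks")
        domain_scores[domain] = pd.concat(cols, axis=1).mean(axis=1)
        out[domain] = domain_scores[domain]
    out["Grand"] = pd.concat(domain_scores.values(), axis=1).mean(axis=1)
    return out


# ---------------------------------------------------------------------------
# Publication-style group table


def group_table(
    df: pd.DataFrame,
    variables,
    group_col: str = "group",
    groups: tuple | None = None,
    policy: SkewPolicy | None = None,
    fdr: bool = False,
) -> pd.DataFrame:
    """One row per variable: group summaries, chosen test, statistic, p.

    ``fdr=True`` adds Benjamini-Hochberg adjusted p-values (off by default;
    the headline analyses report uncorrected two-tailed p).
    """
    if groups is None:
        groups = tuple(pd.unique(df[group_col]))
    if len(groups) != 2:
        raise ValueError("group_table compares exactly two groups")
    ga, gb = groups
    rows = []
    for var in variables:
        a = df.loc[df[group_col] == ga, var].to_numpy(dtype=float)
        b = df.loc[df[group_col] == gb, var].to_numpy(dtype=float)
        comp = compare_groups(a, b, policy)
        rows.append(
            {
                "variable": var,
                f"{ga}_n": comp.summary_a["n"],
                f"{ga}_mean": comp.summary_a["mean"],
                f"{ga}_sd": comp.summary_a["sd"],
                f"{gb}_n": comp.summary_b["n"],
                f"{gb}_mean": comp.summary_b["mean"],
                f"{gb}_sd": comp.summary_b["sd"],
                "test": comp.test_name,
                "statistic": comp.statistic,
                "df": comp.df,
                "z": comp.z,
                "p": comp.p,
            }
        )
    table = pd.DataFrame(rows)
    if fdr:
        from statsmodels.stats.multitest import multipletests

        table["p_fdr"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    return table
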