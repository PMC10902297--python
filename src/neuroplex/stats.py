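"""Group contrasts, subgrouping, cognition regressions and FDR control.

The statistical workflow mirrors a two-group connectome study: pooled
t-tests (optionally as the group term of a linear model when covariates
such as education, grey-matter volume and total intracranial volume are
controlled), median-split subgroups with the individuals nearest the
median removed to reduce split bias, covariate-adjusted parametric and
rank (Spearman) correlations between nodal metrics and cognition, and
Benjamini-Hochberg FDR control within each analysis family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from .datatypes import MultiplexNetwork
from .multiplex import binarize_to_density

__all__ = [
    "StatResult",
    "SubgroupAssignment",
    "summary_ttest",
    "group_contrast",
    "median_split",
    "cognition_regression",
    "fdr_bh",
    "layer_contribution",
    "unimodal_baseline",
]


@dataclass
class StatResult:
    """One test: effect name, statistic, raw and FDR-adjusted p, n, covariates."""

    effect_name: str
    statistic: float
    p_raw: float
    n: int
    covariates_used: tuple[str, ...] = ()
    p_fdr: float | None = None
    estimate: float | None = None
    se: float | None = None
    method: str = "t"

    def __post_init__(self) -> None:
        if not np.isnan(self.p_raw) and not 0 <= self.p_raw <= 1:
            raise ValueError("p_raw outside [0, 1]")


@dataclass
class SubgroupAssignment:
    """Median-split assignment: subject -> {'low', 'high', 'removed'}."""

    assignment: dict = field(default_factory=dict)

    @property
    def low(self) -> list:
        return [s for s, a in self.assignment.items() if a == "low"]

    @property
    def high(self) -> list:
        return [s for s, a in self.assignment.items() if a == "high"]

    @property
    def removed(self) -> list:
        return [s for s, a in self.assignment.items() if a == "removed"]


def summary_ttest(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> float:
    """Pooled two-sample t statistic from summary statistics (group1 - group2)."""
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
    return float((mean1 - mean2) / np.sqrt(sp2 * (1 / n1 + 1 / n2)))


def _pooled_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, int]:
    # pooled two-sample t; tolerates one degenerate (constant) group
    n1, n2 = a.size, b.size
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 <= 0:
        raise ValueError("constant metric within both groups")
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    df = n1 + n2 - 2
    p = 2 * sstats.t.sf(abs(t), df)
    return float(t), float(p), df


def group_contrast(
    values: np.ndarray | pd.Series,
    cohort: pd.DataFrame,
    covariates: tuple[str, ...] = (),
    *,
    groups: tuple[str, str] = ("young", "old"),
    effect_name: str = "group",
) -> StatResult:
    """Two-group contrast of a per-subject nodal metric.

    With no covariates this is exactly the classical pooled two-sample t
    (first-listed group minus second).  With covariates, the statistic
    is the group-term t from the linear model ``metric ~ group +
    covariates``, sign-flipped to keep the same orientation.
    """
    values = np.asarray(values, dtype=float)
    if len(values) != len(cohort):
        raise ValueError("metric length does not match cohort")
    g = cohort["group"].to_numpy()
    in1, in2 = g == groups[0], g == groups[1]
    if in1.sum() < 2 or in2.sum() < 2:
        raise ValueError("each group needs at least 2 subjects")
    if np.std(values) == 0:
        raise ValueError("constant metric")

    if not covariates:
        t, p, _ = _pooled_t(values[in1], values[in2])
        return StatResult(effect_name, t, p, int(in1.sum() + in2.sum()))

    import statsmodels.api as sm

    use = in1 | in2
    x = np.column_stack(
        [in2[use].astype(float)]
        + [cohort.loc[use, c].to_numpy(dtype=float) for c in covariates]
    )
    x = sm.add_constant(x, has_constant="add")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("singular covariate design")
    fit = sm.OLS(values[use], x).fit()
    # column 1 is the group dummy (second group = 1); flip to group1 - group2
    t = -float(fit.tvalues[1])
    p = float(fit.pvalues[1])
    return StatResult(
        effect_name, t, p, int(use.sum()), covariates_used=tuple(covariates)
    )


def median_split(
    values: pd.Series, n_remove_per_side: int = 4
) -> SubgroupAssignment:
    """Median split with the individuals nearest the median removed.

    ``values`` is indexed by subject id.  Subjects are ranked by
    ``(value, subject_id)`` (a deterministic resolution of ties); the
    lower half is 'low', the upper half 'high', and the
    ``n_remove_per_side`` subjects closest to the median on each side are
    marked 'removed'.  The group size must be even and large enough that
    both subgroups stay non-empty.
    """
    n = len(values)
    if n % 2 != 0:
        raise ValueError(
            f"median split needs an even group size, got {n}; the design "
            "removes equally many subjects from each side of the median"
        )
    if n <= 2 * n_remove_per_side + 2:
        raise ValueError(f"too few subjects ({n}) for {n_remove_per_side} removals per side")
    if values.nunique() == 1:
        raise ValueError("all values identical: median split undefined")

    order = sorted(values.items(), key=lambda kv: (kv[1], str(kv[0])))
    half = n // 2
    assignment = {}
    for rank, (subject, _val) in enumerate(order):
        if rank < half - n_remove_per_side:
            assignment[subject] = "low"
        elif rank < half + n_remove_per_side:
            assignment[subject] = "removed"
        else:
            assignment[subject] = "high"
    return SubgroupAssignment(assignment)


def _residualize(y: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def cognition_regression(
    metric: np.ndarray | pd.Series,
    score: np.ndarray | pd.Series,
    covariates: pd.DataFrame | None = None,
    method: str = "parametric",
    *,
    effect_name: str = "cognition",
) -> StatResult:
    """Association between a nodal metric and a cognition score.

    parametric:
        Partial correlation of metric and score given the covariates
        (the sign is the effect direction); also reports the covariate-
        adjusted OLS slope of score on metric with its standard error.
    spearman:
        Rank correlation computed on covariate-residualised values, for
        non-continuous scores.
    """
    metric = np.asarray(metric, dtype=float)
    score = np.asarray(score, dtype=float)
    if metric.shape != score.shape:
        raise ValueError("metric and score lengths differ")
    k = 0 if covariates is None else covariates.shape[1]
    n = metric.size
    if n < 4 + k:
        raise ValueError(f"need at least {4 + k} subjects, got {n}")
    if np.std(score) == 0:
        raise ValueError("constant score")
    if np.std(metric) == 0:
        raise ValueError("constant metric")

    design = np.ones((n, 1))
    names: tuple[str, ...] = ()
    if covariates is not None and k:
        cov = covariates.to_numpy(dtype=float)
        design = np.column_stack([design, cov])
        names = tuple(covariates.columns)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient covariate design")

    rm = _residualize(metric, design)
    rs = _residualize(score, design)

    if method == "parametric":
        r = float(np.corrcoef(rm, rs)[0, 1])
        df = n - 2 - k
        t = r * np.sqrt(df / max(1e-300, 1.0 - r**2))
        p = float(2 * sstats.t.sf(abs(t), df))
        slope = float(np.dot(rm, rs) / np.dot(rm, rm))
        resid = rs - slope * rm
        se = float(
            np.sqrt(np.dot(resid, resid) / (df) / np.dot(rm, rm))
        )
        return StatResult(
            effect_name, r, min(1.0, p), n, names, estimate=slope, se=se, method="r"
        )
    if method == "spearman":
        rho, p = sstats.spearmanr(
            sstats.rankdata(rm), sstats.rankdata(rs)
        )
        return StatResult(effect_name, float(rho), float(p), n, names, method="rho")
    raise ValueError(f"unknown method {method!r}")


def fdr_bh(
    p_values, q: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and rejection set."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values outside [0, 1]")
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def layer_contribution(
    networks: list[MultiplexNetwork], region: int | str, q: float = 0.05
) -> list[StatResult]:
    """Paired contrasts of per-layer degrees at one region across subjects.

    For every layer pair, tests whether the region's degree differs
    between the layers (paired t-test across subjects), FDR-corrected
    over the pairs.  Identifies which layer drives a multiplex effect.
    """
    if not networks:
        raise ValueError("empty network list")
    labels = networks[0].labels
    if isinstance(region, str):
        if region not in labels:
            raise ValueError(f"region {region!r} missing from node labels")
        region = labels.index(region)
    if not 0 <= region < networks[0].n_nodes:
        raise ValueError(f"region index {region} out of range")

    degrees = np.stack([mx.degrees()[:, region] for mx in networks])  # (S, M)
    m = degrees.shape[1]
    tags = networks[0].layer_tags
    results = []
    for a in range(m):
        for b in range(a + 1, m):
            diff = degrees[:, a] - degrees[:, b]
            if np.allclose(diff, 0):
                t, p = 0.0, 1.0
            else:
                t, p = sstats.ttest_rel(degrees[:, a], degrees[:, b])
            results.append(
                StatResult(
                    f"degree[{tags[a]}] - degree[{tags[b]}] @ {labels[region]}",
                    float(t),
                    float(p),
                    degrees.shape[0],
                    method="paired-t",
                )
            )
    p_adj, _rej = fdr_bh([r.p_raw for r in results], q)
    for r, adj in zip(results, p_adj):
        r.p_fdr = float(adj)
    return results


def unimodal_baseline(
    matrices: list, cohort: pd.DataFrame, *, density: float = 0.22, q: float = 0.05
) -> pd.DataFrame:
    """Single-modality control analyses: global mean weight + nodal degrees.

    Contrasts the global mean connectivity and each node's binarised
    degree between the groups, FDR-corrected within the nodal family.
    Returns a tidy results table.  Serves as the unimodal comparison
    that quantifies the added value of the multiplex analysis.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    if len(matrices) != len(cohort):
        raise ValueError("one matrix per cohort row required")
    n = matrices[0].n_nodes
    iu = np.triu_indices(n, k=1)
    global_mean = np.array([m.values[iu].mean() for m in matrices])
    degrees = np.stack(
        [binarize_to_density(m, density).sum(axis=1) for m in matrices]
    )

    rows = []
    g = group_contrast(global_mean, cohort, effect_name="global_mean_weight")
    rows.append(
        dict(effect=g.effect_name, node=None, statistic=g.statistic, p_raw=g.p_raw,
             p_fdr=g.p_raw, n=g.n)
    )
    nodal = [
        group_contrast(degrees[:, i], cohort, effect_name=f"degree@{matrices[0].labels[i]}")
        for i in range(n)
    ]
    p_adj, _ = fdr_bh([r.p_raw for r in nodal], q)
    for i, (r, adj) in enumerate(zip(nodal, p_adj)):
        rows.append(
            dict(effect=r.effect_name, node=i, statistic=r.statistic, p_raw=r.p_raw,
                 p_fdr=float(adj), n=r.n)
        )
    out = pd.DataFrame(rows)
    out["density"] = [np.nan] + [density] * n
    return out
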