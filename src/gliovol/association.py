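"""Imaging-genomic statistics.

For every gene mutated in at least ``min_mut`` patients of the cohort and
every one of the 11 volumetric features, the mutant group is compared to
the wild-type group with a two-sided pooled-variance Student's t test, and
the feature's power to predict mutation status is quantified by the ROC
AUC with the mutated class as positive.  Because a feature may predict
mutation in either direction, performance is reported as the *absolute*
AUC, 0.5 + |AUC - 0.5|, which folds direction so that strength is
comparable across features; the raw AUC is retained alongside so the
direction stays recoverable.

The AUC p-value tests H0: AUC = 0.5 through the tie-corrected normal
approximation to the Mann-Whitney U statistic (a seeded exact-permutation
alternative is available for small strata), and the 95% confidence
interval uses the DeLong variance estimator.  Significance is declared at
p < 0.05 per test with no multiplicity correction by default; a
Benjamini-Hochberg switch is available.

Also provided: a Shapiro-Wilk normality screen per feature, the pairwise
Pearson correlation matrix of the 11 features, and a two-group Ward
clustering of patients with chi-squared tests of independence from
clinical variables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from .exceptions import DegenerateInputError
from .volumetrics import FEATURE_NAMES

__all__ = [
    "MutationTable",
    "AssociationResult",
    "NormalityResult",
    "student_t_two_sided",
    "shapiro_wilk",
    "roc_auc",
    "absolute_auc",
    "auc_significance",
    "association_scan",
    "normality_screen",
    "correlation_matrix",
    "cluster_and_test",
    "ClusterTestResult",
]


# ---------------------------------------------------------------------------
# mutation table


class MutationTable:
    """Patient x gene binary mutation-status matrix.

    Wraps a DataFrame with unique patient ids as index, gene names as
    columns and values in {0, 1}.
    """

    def __init__(self, status: pd.DataFrame):
        status = status.copy()
        if status.index.has_duplicates:
            dupes = status.index[status.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate patient ids: {dupes}")
        values = status.to_numpy()
        if not np.all(np.isin(values, (0, 1))):
            raise ValueError("mutation status values must be exactly 0 or 1")
        self.status = status.astype(np.int64)

    @classmethod
    def from_csv(cls, path: str | Path) -> "MutationTable":
        return cls(pd.read_csv(path, index_col=0))

    @property
    def patients(self) -> list[str]:
        return list(self.status.index)

    @property
    def genes(self) -> list[str]:
        return list(self.status.columns)

    @property
    def counts(self) -> pd.Series:
        """Per-gene mutation counts (column sums)."""
        return self.status.sum(axis=0)

    def restrict(self, patients) -> "MutationTable":
        """Restrict to the given patients, preserving their order."""
        return MutationTable(self.status.loc[list(patients)])

    def genes_passing(self, min_mut: int) -> list[str]:
        counts = self.counts
        return [g for g in self.genes if counts[g] >= min_mut]


# ---------------------------------------------------------------------------
# elementary statistics


def student_t_two_sided(group_a, group_b) -> tuple[float, float]:
    """Classical pooled-variance (equal-variance) Student's t test.

    Returns ``(t_stat, p)`` with df = n_a + n_b - 2 and a two-sided p from
    the t distribution.  The sign convention is ``mean(a) - mean(b)``.

    Raises
    ------
    DegenerateInputError
        If either group has fewer than two values or the pooled variance
        is zero with unequal means.  Identical constant groups return
        (0.0, 1.0).
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise DegenerateInputError(f"t test needs n >= 2 per group, got {na} and {nb}")
    df = na + nb - 2
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if pooled_var == 0:
        if diff == 0:
            return 0.0, 1.0
        raise DegenerateInputError("zero pooled variance with unequal means")
    t_stat = diff / np.sqrt(pooled_var * (1.0 / na + 1.0 / nb))
    p = 2.0 * stats.t.sf(abs(t_stat), df)
    return float(t_stat), float(p)


def welch_t_two_sided(group_a, group_b) -> tuple[float, float]:
    """Welch's unequal-variance t test (optional alternative)."""
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise DegenerateInputError("t test needs n >= 2 per group")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


@dataclass
class NormalityResult:
    """Shapiro-Wilk screen of one feature across all patients."""

    feature: str
    w_stat: float
    p_sw: float
    n: int
    flags: tuple[str, ...] = ()


def shapiro_wilk(values, feature: str = "") -> NormalityResult:
    """Shapiro-Wilk normality test (Royston approximation via SciPy).

    Constant input is undefined and returned flagged with NaN statistics.
    Requires 3 <= n <= 5000.
    """
    v = np.asarray(values, dtype=np.float64)
    v = v[np.isfinite(v)]
    n = v.size
    if not 3 <= n <= 5000:
        raise DegenerateInputError(f"Shapiro-Wilk requires 3 <= n <= 5000, got {n}")
    if v.min() == v.max():
        return NormalityResult(feature, float("nan"), float("nan"), n, ("constant_input",))
    w, p = stats.shapiro(v)
    return NormalityResult(feature, float(w), float(p), n)


def roc_auc(scores, labels) -> float:
    """ROC AUC with mutated (label 1) as the positive class.

    Computed as the normalized Mann-Whitney U statistic using midranks,
    which equals (concordant pairs + 0.5 * tied pairs) / (n_pos * n_neg);
    higher scores count toward predicting label 1.
    """
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels)
    if not np.all(np.isin(y, (0, 1))):
        raise ValueError("labels must be 0/1")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateInputError("both classes must be present for ROC AUC")
    ranks = stats.rankdata(s)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def absolute_auc(auc_raw: float) -> float:
    """Direction-folded AUC: 0.5 + |x - 0.5|, in [0.5, 1]."""
    if not 0.0 <= auc_raw <= 1.0:
        raise ValueError(f"AUC must lie in [0, 1], got {auc_raw}")
    return 0.5 + abs(auc_raw - 0.5)


def _delong_se(scores: np.ndarray, labels: np.ndarray) -> float:
    """DeLong standard error of the empirical AUC (midrank formulation)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    rank_all = stats.rankdata(np.concatenate([pos, neg]))
    v10 = (rank_all[:m] - stats.rankdata(pos)) / n  # placements of positives
    v01 = 1.0 - (rank_all[m:] - stats.rankdata(neg)) / m
    s10 = v10.var(ddof=1) if m > 1 else float("nan")
    s01 = v01.var(ddof=1) if n > 1 else float("nan")
    return float(np.sqrt(s10 / m + s01 / n))


def auc_significance(
    scores,
    labels,
    method: str = "normal",
    n_permutations: int = 2000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float, float]:
    """p-value and 95% CI for H0: AUC = 0.5.

    ``method='normal'`` uses the tie-corrected normal approximation to the
    Mann-Whitney U statistic; ``method='permutation'`` uses a seeded label
    permutation of |AUC - 0.5| (recommended when the smaller class has
    fewer than 10 members).  The CI is DeLong, centred on the
    direction-folded (absolute) AUC so that the reported AUC always lies
    inside its interval; bounds are clipped to [0, 1].

    Returns ``(p_auc, ci95_low, ci95_high)``.
    """
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos < 2 or n_neg < 2:
        raise DegenerateInputError("AUC inference needs >= 2 per class")
    auc = roc_auc(s, y)

    if method == "normal":
        n = n_pos + n_neg
        _, tie_counts = np.unique(s, return_counts=True)
        tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)))
        var_u = n_pos * n_neg / 12.0 * ((n + 1) - tie_term)
        if var_u <= 0:  # all scores tied
            p = float("nan")
        else:
            # continuity-corrected, as in R's wilcox.test
            dev = max(abs(auc - 0.5) * n_pos * n_neg - 0.5, 0.0)
            p = float(2.0 * stats.norm.sf(dev / np.sqrt(var_u)))
    elif method == "permutation":
        if rng is None:
            raise ValueError("permutation method requires a seeded rng")
        observed = abs(auc - 0.5)
        hits = 0
        y_perm = y.copy()
        for _ in range(n_permutations):
            rng.shuffle(y_perm)
            if abs(roc_auc(s, y_perm) - 0.5) >= observed - 1e-12:
                hits += 1
        p = float((1 + hits) / (1 + n_permutations))
    else:
        raise ValueError(f"unknown AUC p-value method: {method!r}")

    # DeLong CI around the folded AUC (the reported column); folding the
    # scores leaves the DeLong variance unchanged by symmetry.
    se = _delong_se(s, y)
    a_abs = absolute_auc(auc)
    z975 = stats.norm.ppf(0.975)
    ci_low = max(0.0, a_abs - z975 * se)
    ci_high = min(1.0, a_abs + z975 * se)
    return p, float(ci_low), float(ci_high)


# ---------------------------------------------------------------------------
# cohort-level scans


@dataclass
class AssociationResult:
    """One gene x feature row of the association scan."""

    gene: str
    feature: str
    n_mut: int
    n_wt: int
    mut_minus_wt_diff: float
    t_stat: float
    p_t: float
    auc_raw: float
    auc_abs: float
    p_auc: float
    ci95_low: float
    ci95_high: float
    testable: bool = True


RESULT_COLUMNS = [
    "gene",
    "feature",
    "n_mut",
    "n_wt",
    "mut_minus_wt_diff",
    "t_stat",
    "p_t",
    "auc_raw",
    "auc_abs",
    "p_auc",
    "ci95_low",
    "ci95_high",
    "testable",
]


def _panel_features(panels) -> pd.DataFrame:
    """Accept a panel DataFrame or a list of VolumetricPanel objects."""
    if isinstance(panels, pd.DataFrame):
        return panels[FEATURE_NAMES].astype(float)
    from .volumetrics import panels_to_frame

    return panels_to_frame(list(panels))[FEATURE_NAMES].astype(float)


def association_scan(
    panels,
    mutations: MutationTable,
    min_mut: int = 5,
    alpha: float = 0.05,
    multiplicity: str = "none",
    auc_p_method: str = "normal",
    welch: bool = False,
    n_permutations: int = 2000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Mutant-vs-wild-type scan over genes x 11 features.

    Genes mutated in fewer than ``min_mut`` of the shared patients are
    excluded.  Missing feature values (undefined ratios) are dropped per
    feature per patient.  Rows where either group ends up with fewer than
    two usable values are marked untestable rather than raised.

    Returns a tidy DataFrame with one row per (gene, feature) and columns
    ``mut_minus_wt_diff, t_stat, p_t, auc_raw, auc_abs, p_auc, ci95_low,
    ci95_high, significant_t, significant_auc``.  With
    ``multiplicity='bh'`` the significance columns use Benjamini-Hochberg
    adjusted p-values (also reported as ``p_t_adj``/``p_auc_adj``).
    """
    features = _panel_features(panels)
    shared = [p for p in features.index if p in set(mutations.patients)]
    if len(shared) < 2:
        raise DegenerateInputError(
            f"need >= 2 patients shared between panels and mutation table, got {len(shared)}"
        )
    features = features.loc[shared]
    muts = mutations.restrict(shared)
    genes = muts.genes_passing(min_mut)
    if not genes:
        warnings.warn(
            f"no gene mutated in at least {min_mut} patients; empty association result",
            UserWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng(seed) if seed is not None else None

    rows: list[AssociationResult] = []
    for gene in genes:
        status = muts.status[gene].to_numpy()
        for feature in FEATURE_NAMES:
            values = features[feature].to_numpy()
            ok = np.isfinite(values)
            v, y = values[ok], status[ok]
            n_mut = int((y == 1).sum())
            n_wt = int((y == 0).sum())
            row = AssociationResult(
                gene, feature, n_mut, n_wt,
                *(float("nan"),) * 8, testable=False,
            )
            if n_mut >= 2 and n_wt >= 2:
                mut_vals, wt_vals = v[y == 1], v[y == 0]
                try:
                    if welch:
                        t_stat, p_t = welch_t_two_sided(mut_vals, wt_vals)
                    else:
                        t_stat, p_t = student_t_two_sided(mut_vals, wt_vals)
                    auc = roc_auc(v, y)
                    p_auc, ci_low, ci_high = auc_significance(
                        v, y, method=auc_p_method,
                        n_permutations=n_permutations, rng=rng,
                    )
                    row = AssociationResult(
                        gene, feature, n_mut, n_wt,
                        float(mut_vals.mean() - wt_vals.mean()),
                        t_stat, p_t, auc, absolute_auc(auc),
                        p_auc, ci_low, ci_high, testable=True,
                    )
                except DegenerateInputError:
                    pass
            rows.append(row)

    result = pd.DataFrame([r.__dict__ for r in rows], columns=RESULT_COLUMNS)
    if multiplicity == "bh":
        for col in ("p_t", "p_auc"):
            adj = np.full(len(result), np.nan)
            ok = result[col].notna().to_numpy()
            if ok.any():
                adj[ok] = multipletests(result.loc[ok, col], method="fdr_bh")[1]
            result[f"{col}_adj"] = adj
        result["significant_t"] = result["p_t_adj"] < alpha
        result["significant_auc"] = result["p_auc_adj"] < alpha
    elif multiplicity == "none":
        result["significant_t"] = result["p_t"] < alpha
        result["significant_auc"] = result["p_auc"] < alpha
    else:
        raise ValueError(f"unknown multiplicity mode: {multiplicity!r}")
    return result


def normality_screen(panels) -> pd.DataFrame:
    """Shapiro-Wilk W and p per feature across all patients."""
    features = _panel_features(panels)
    rows = []
    for feature in FEATURE_NAMES:
        values = features[feature].dropna()
        if len(values) < 3:
            rows.append(
                {"feature": feature, "w_stat": np.nan, "p_sw": np.nan,
                 "n": len(values), "flags": "insufficient_n"}
            )
            continue
        res = shapiro_wilk(values, feature)
        rows.append(
            {"feature": feature, "w_stat": res.w_stat, "p_sw": res.p_sw,
             "n": res.n, "flags": ";".join(res.flags)}
        )
    return pd.DataFrame(rows)


def correlation_matrix(panels) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise-complete Pearson correlations of the 11 features.

    Returns ``(matrix, flagged)`` where ``flagged`` lists zero-variance
    features whose rows/columns are undefined (NaN off-diagonal).
    """
    features = _panel_features(panels)
    if len(features.dropna(how="any")) < 3 and len(features) < 3:
        raise DegenerateInputError("correlation matrix needs >= 3 patients")
    matrix = features.corr(method="pearson", min_periods=3)
    flagged = [
        f for f in FEATURE_NAMES
        if features[f].dropna().nunique() <= 1
    ]
    for f in flagged:
        matrix.loc[f, :] = np.nan
        matrix.loc[:, f] = np.nan
    valid = [f for f in FEATURE_NAMES if f not in flagged]
    for f in valid:
        matrix.loc[f, f] = 1.0
    return matrix, flagged


@dataclass
class ClusterTestResult:
    """Two-group imaging clustering plus clinical-independence tests."""

    assignments: pd.Series  # patient_id -> 0/1
    tests: pd.DataFrame  # one row per clinical variable: chi2, p, dof, n
    flags: tuple[str, ...] = ()


DEFAULT_KPS_BINS = (40, 60, 80, 100)


def _bin_clinical(series: pd.Series, variable: str, kps_bins, age_bin_width: int) -> pd.Series:
    s = series.dropna()
    if variable == "kps":
        # snap to the displayed KPS levels
        levels = np.asarray(kps_bins, dtype=float)
        idx = np.abs(s.to_numpy(dtype=float)[:, None] - levels[None, :]).argmin(axis=1)
        return pd.Series(levels[idx], index=s.index)
    if variable == "age":
        return (s.astype(float) // age_bin_width).astype(int)
    return s


def cluster_and_test(
    panels,
    clinical: pd.DataFrame,
    kps_bins=DEFAULT_KPS_BINS,
    age_bin_width: int = 10,
) -> ClusterTestResult:
    """Cluster patients into two groups on z-scored features and test the
    grouping for independence from clinical variables.

    Features are z-scored across patients and the patients clustered by
    Ward-linkage hierarchical clustering on Euclidean distance, cut at two
    groups.  Each clinical variable (gender, disease-free status, KPS,
    age) is cross-tabulated against group membership and tested with a
    chi-squared test of independence; KPS is snapped to its displayed
    levels and age binned by decade; missing clinical values are excluded
    per variable.
    """
    features = _panel_features(panels)
    complete = features.dropna(how="any")
    flags: list[str] = []
    dropped = sorted(set(features.index) - set(complete.index))
    if dropped:
        flags.append(f"patients_dropped_missing_features:{','.join(map(str, dropped))}")
    if len(complete) < 4:
        raise DegenerateInputError(f"clustering needs >= 4 complete patients, got {len(complete)}")

    sd = complete.std(ddof=1)
    usable = sd[sd > 0].index.tolist()
    constant = [f for f in complete.columns if f not in usable]
    if constant:
        flags.append(f"constant_features_excluded:{','.join(constant)}")
    z = (complete[usable] - complete[usable].mean()) / sd[usable]
    if z.shape[1] == 0 or len(np.unique(z.to_numpy(), axis=0)) == 1:
        assignments = pd.Series(0, index=complete.index, name="cluster")
        flags.append("all_patients_identical_single_cluster")
    else:
        linkage = hierarchy.linkage(z.to_numpy(), method="ward")
        labels = hierarchy.fcluster(linkage, t=2, criterion="maxclust") - 1
        assignments = pd.Series(labels, index=complete.index, name="cluster")

    rows = []
    for variable in [c for c in ("gender", "dfs", "kps", "age") if c in clinical.columns]:
        col = clinical.loc[clinical.index.intersection(assignments.index), variable]
        binned = _bin_clinical(col, variable, kps_bins, age_bin_width)
        groups = assignments.loc[binned.index]
        table = pd.crosstab(groups, binned)
        if table.shape[0] < 2 or table.shape[1] < 2:
            rows.append({"variable": variable, "chi2": np.nan, "p": np.nan,
                         "dof": 0, "n": int(binned.size), "flags": "degenerate_table"})
            continue
        chi2, p, dof, _ = stats.chi2_contingency(table)
        rows.append({"variable": variable, "chi2": float(chi2), "p": float(p),
                     "dof": int(dof), "n": int(binned.size), "flags": ""})
    tests = pd.DataFrame(rows, columns=["variable", "chi2", "p", "dof", "n", "flags"])
    return ClusterTestResult(assignments=assignments, tests=tests, flags=tuple(flags))
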