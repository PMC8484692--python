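"""Cohort statistics: genus-table filters, compositional differential
abundance, diversity/ordination/PERMANOVA, ortholog-level testing and the
Y-maze alternation ratio.

Differential abundance re-implements the Dirichlet/CLR Monte-Carlo scheme
used for compositional count tables: per instance, sample compositions are
drawn from Dirichlet(counts + 0.5), centred-log-ratio transformed, and a
two-sided Wilcoxon rank-sum test is run per feature; the reported p value
is the expectation over instances, with Benjamini-Hochberg q values over
features.  Fold changes are log2 ratios of group median relative
abundances, with a half-minimum pseudo-abundance when a median is zero.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

__all__ = [
    "filter_genus_table",
    "wilcoxon_rank_sum",
    "bh_fdr",
    "spearman",
    "bray_curtis",
    "within_group_distance_test",
    "pcoa",
    "OrdinationResult",
    "permanova",
    "shannon",
    "clr_mc_differential_abundance",
    "ortholog_da_report",
    "alternation_ratio",
]


# ---------------------------------------------------------------------------
# table filters

def filter_genus_table(
    counts: pd.DataFrame,
    min_sample_reads: int = 10_000,
    min_prevalence: int = 3,
    min_mean_rel_abund: float = 1e-4,
) -> tuple[pd.DataFrame, list[str]]:
    """Sample and genus filters for a raw genus count table (samples x genera).

    Order: samples with fewer than ``min_sample_reads`` total reads are
    removed first; then genera detected in fewer than ``min_prevalence``
    of the remaining samples; then genera whose mean relative abundance is
    below ``min_mean_rel_abund`` (0.01% by default).  Returns the filtered
    table and a log of removals.
    """
    log: list[str] = []
    totals = counts.sum(axis=1)
    keep_samples = totals >= min_sample_reads
    for s in counts.index[~keep_samples]:
        log.append(f"sample {s}: removed ({totals[s]} < {min_sample_reads} reads)")
    table = counts.loc[keep_samples]

    prevalence = (table > 0).sum(axis=0)
    keep = prevalence >= min_prevalence
    for g in table.columns[~keep]:
        log.append(f"genus {g}: removed (detected in {prevalence[g]} samples)")
    table = table.loc[:, keep]

    rel = table.div(table.sum(axis=1), axis=0)
    mean_rel = rel.mean(axis=0)
    keep = mean_rel >= min_mean_rel_abund
    for g in table.columns[~keep]:
        log.append(f"genus {g}: removed (mean rel. abundance {mean_rel[g]:.2e})")
    table = table.loc[:, keep]
    if table.empty or table.shape[1] == 0:
        raise ValueError("table empty after filtering")
    return table, log


# ---------------------------------------------------------------------------
# elementary tests

def wilcoxon_rank_sum(x, y, exact_threshold: int = 25) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p value.

    Exact null enumeration when both samples have <= ``exact_threshold``
    observations and there are no ties; otherwise the normal approximation
    with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty input")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if has_ties and np.all(pooled == pooled[0]):
        return 1.0
    exact = (not has_ties) and x.size <= exact_threshold and y.size <= exact_threshold
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return float(min(res.pvalue, 1.0))


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg q values (order-preserving, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho with average ranks; exact permutation p for n <= 9."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("rho undefined for a constant vector")
    rho = float(sps.spearmanr(x, y).statistic)
    n = x.size
    if n <= 9:
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        perms = np.array(list(itertools.permutations(range(n))))
        permuted = ry[perms]  # (n!, n)
        rx_c = rx - rx.mean()
        py_c = permuted - permuted.mean(axis=1, keepdims=True)
        denom = np.sqrt((rx_c**2).sum() * (py_c**2).sum(axis=1))
        rhos = (py_c @ rx_c) / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        p = float(sps.spearmanr(x, y).pvalue)
    return rho, p


# ---------------------------------------------------------------------------
# community structure

def bray_curtis(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity of non-negative sample rows."""
    values = np.asarray(table, dtype=float)
    if (values < 0).any():
        raise ValueError("negative abundances")
    zero_rows = values.sum(axis=1) == 0
    with np.errstate(invalid="ignore"):
        mat = squareform(pdist(values, metric="braycurtis"))
    if zero_rows.any():
        warnings.warn("all-zero samples present; their mutual distance is set to 0")
        mat = np.nan_to_num(mat, nan=0.0)
    return pd.DataFrame(mat, index=table.index, columns=table.index)


def within_group_distance_test(
    dist: pd.DataFrame, groups: pd.Series, reference: str
) -> pd.DataFrame:
    """Compare within-group pairwise distances of each group to the reference.

    Returns one row per non-reference group with the two-sided Wilcoxon
    rank-sum p value and the group median within-group distances.
    """
    groups = groups.reindex(dist.index)

    def within(label: str) -> np.ndarray:
        members = groups.index[groups == label]
        if len(members) < 2:
            raise ValueError(f"group {label} has fewer than 2 members")
        sub = dist.loc[members, members].to_numpy()
        iu = np.triu_indices(len(members), k=1)
        return sub[iu]

    ref = within(reference)
    rows = []
    for label in sorted(set(groups.dropna()) - {reference}):
        other = within(label)
        rows.append({
            "group": label,
            "reference": reference,
            "median_group": float(np.median(other)),
            "median_reference": float(np.median(ref)),
            "p_value": wilcoxon_rank_sum(other, ref),
        })
    return pd.DataFrame(rows)


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    negative_eigenvalues: np.ndarray


def pcoa(dist: pd.DataFrame) -> OrdinationResult:
    """Principal coordinates analysis by Gower double-centring.

    Coordinates are eigenvectors scaled by sqrt(eigenvalue) for positive
    eigenvalues; negative eigenvalues are reported unchanged (no
    correction applied).
    """
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    n = d.shape[0]
    a = -0.5 * d**2
    centering = np.eye(n) - np.ones((n, n)) / n
    b = centering @ a @ centering
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = 1e-9 * max(abs(eigvals).max(), 1.0)
    positive = eigvals > tol
    coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])
    index = dist.index if isinstance(dist, pd.DataFrame) else pd.RangeIndex(n)
    coordinates = pd.DataFrame(
        coords, index=index, columns=[f"PC{i + 1}" for i in range(coords.shape[1])]
    )
    pos_sum = eigvals[positive].sum()
    proportion = eigvals[positive] / pos_sum if pos_sum > 0 else eigvals[positive]
    return OrdinationResult(
        coordinates=coordinates,
        eigenvalues=eigvals[positive],
        proportion_explained=proportion,
        negative_eigenvalues=eigvals[eigvals < -tol],
    )


def permanova(
    dist: pd.DataFrame,
    groups: pd.Series,
    n_permutations: int = 9999,
    seed: int = 0,
) -> tuple[float, float, float]:
    """One-way PERMANOVA: (pseudo-F, R^2, permutation p).

    R^2 = SS_between / SS_total from squared distances; the p value is
    (1 + #{permuted F >= observed F}) / (1 + n_permutations) with seeded
    label permutations.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    labels = pd.Series(groups).reindex(dist.index) if isinstance(dist, pd.DataFrame) else pd.Series(groups)
    codes, uniques = pd.factorize(labels)
    if len(uniques) < 2 or np.bincount(codes).min() < 2:
        raise ValueError("need >= 2 groups with >= 2 members each")
    d2 = np.asarray(dist, dtype=float) ** 2
    n = d2.shape[0]
    k = len(uniques)
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n

    rng = np.random.default_rng(seed)

    def pseudo_f(assign: np.ndarray) -> float:
        ss_within = 0.0
        for g in range(k):
            mask = assign == g
            ng = mask.sum()
            ss_within += d2[np.ix_(mask, mask)].sum() / (2 * ng)
        ss_between = ss_total - ss_within
        return (ss_between / (k - 1)) / (ss_within / (n - k))

    f_obs = pseudo_f(codes)
    r2 = _ss_between(d2, codes, k) / ss_total if ss_total > 0 else 0.0

    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(codes)
        if pseudo_f(perm) >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return float(f_obs), float(r2), float(p)


def _ss_between(d2: np.ndarray, codes: np.ndarray, k: int) -> float:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in range(k):
        mask = codes == g
        ss_within += d2[np.ix_(mask, mask)].sum() / (2 * mask.sum())
    return ss_total - ss_within


def shannon(counts, base: float = 2.0) -> float:
    """Shannon-Wiener diversity over positive proportions."""
    arr = np.asarray(counts, dtype=float)
    if (arr < 0).any():
        raise ValueError("negative counts")
    total = arr.sum()
    if total == 0:
        raise ValueError("all-zero sample")
    p = arr[arr > 0] / total
    return float(-(p * np.log(p) / np.log(base)).sum())


# ---------------------------------------------------------------------------
# differential abundance

def _log2_median_ratio(rel: pd.DataFrame, case_mask: np.ndarray) -> pd.Series:
    med_case = rel.loc[case_mask].median(axis=0)
    med_ctrl = rel.loc[~case_mask].median(axis=0)
    positives = rel.values[rel.values > 0]
    pseudo = positives.min() / 2 if positives.size else 1e-12
    return np.log2(med_case.where(med_case > 0, pseudo) / med_ctrl.where(med_ctrl > 0, pseudo))


def _ranksum_p_matrix(clr: np.ndarray, case_mask: np.ndarray, exact_threshold: int = 25) -> np.ndarray:
    """Vectorized two-sided rank-sum p per feature column of a CLR matrix."""
    x = clr[case_mask]
    y = clr[~case_mask]
    exact = x.shape[0] <= exact_threshold and y.shape[0] <= exact_threshold
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True, axis=0,
    )
    return np.minimum(np.asarray(res.pvalue, dtype=float), 1.0)


def clr_mc_differential_abundance(
    counts: pd.DataFrame,
    groups: pd.Series,
    case_label: str | None = None,
    n_instances: int = 128,
    seed: int = 0,
) -> pd.DataFrame:
    """Dirichlet/CLR Monte-Carlo differential abundance between two groups.

    Per instance, each sample's composition is drawn from
    Dirichlet(counts + 0.5) and CLR-transformed; a two-sided Wilcoxon
    rank-sum test is run per feature and the reported p value is the mean
    over instances.  q values are BH-corrected over features.
    """
    labels = groups.reindex(counts.index)
    uniq = sorted(labels.dropna().unique())
    if len(uniq) != 2:
        raise ValueError("exactly two groups required")
    if case_label is None:
        case_label = uniq[1]
    case_mask = (labels == case_label).to_numpy()
    if case_mask.sum() < 3 or (~case_mask).sum() < 3:
        raise ValueError("each group needs n >= 3")
    values = counts.to_numpy(dtype=float)
    if np.any(values.sum(axis=1) == 0):
        raise ValueError("sample with all-zero counts")

    rng = np.random.default_rng(seed)
    alpha = values + 0.5
    p_sum = np.zeros(values.shape[1])
    for _ in range(n_instances):
        comp = rng.standard_gamma(alpha)
        comp /= comp.sum(axis=1, keepdims=True)
        logc = np.log(comp)
        clr = logc - logc.mean(axis=1, keepdims=True)
        p_sum += _ranksum_p_matrix(clr, case_mask)
    p = p_sum / n_instances
    rel = counts.div(counts.sum(axis=1), axis=0)
    result = pd.DataFrame(
        {
            "median_case": rel.loc[case_mask].median(axis=0),
            "median_control": rel.loc[~case_mask].median(axis=0),
            "log2_fold_change": _log2_median_ratio(rel, case_mask),
            "p_value": p,
            "q_value": bh_fdr(p),
        },
        index=counts.columns,
    )
    result["significant"] = result["p_value"] < 0.05
    result.attrs["test"] = f"clr_mc(n_instances={n_instances}, prior=0.5)"
    return result


def ortholog_da_report(
    og_table: pd.DataFrame,
    groups: pd.Series,
    case_label: str | None = None,
    og_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Per-ortholog Wilcoxon rank-sum between cohorts with BH correction.

    ``og_ids`` restricts testing (e.g., to consensus specific orthologs);
    requested ids absent from the table are listed as untested rows with
    NaN statistics.
    """
    labels = groups.reindex(og_table.index)
    uniq = sorted(labels.dropna().unique())
    if len(uniq) != 2:
        raise ValueError("exactly two groups required")
    if case_label is None:
        case_label = uniq[1]
    case_mask = (labels == case_label).to_numpy()
    wanted = list(og_table.columns) if og_ids is None else list(og_ids)
    tested = [og for og in wanted if og in og_table.columns]
    untested = [og for og in wanted if og not in og_table.columns]

    positives = og_table.values[og_table.values > 0]
    pseudo = positives.min() / 2 if positives.size else 1e-12
    rows = []
    for og in tested:
        x = og_table.loc[case_mask, og].to_numpy()
        y = og_table.loc[~case_mask, og].to_numpy()
        med_case, med_ctrl = float(np.median(x)), float(np.median(y))
        lfc = math.log2((med_case if med_case > 0 else pseudo) /
                        (med_ctrl if med_ctrl > 0 else pseudo))
        rows.append({
            "og_id": og,
            "median_case": med_case,
            "median_control": med_ctrl,
            "median_abundance": float(np.median(og_table[og])),
            "log2_fold_change": lfc,
            "p_value": wilcoxon_rank_sum(x, y),
            "tested": True,
        })
    report = pd.DataFrame(rows).set_index("og_id") if rows else pd.DataFrame(
        columns=["median_case", "median_control", "median_abundance",
                 "log2_fold_change", "p_value", "tested"]
    )
    if len(report):
        report["q_value"] = bh_fdr(report["p_value"].to_numpy())
        report["significant"] = report["p_value"] < 0.05
    for og in untested:
        report.loc[og] = {"tested": False}
    return report


# ---------------------------------------------------------------------------
# behaviour

def alternation_ratio(entries: str | list[str]) -> tuple[int, float]:
    """Y-maze alternation: triples of 3 distinct arms / (entries - 2).

    ``entries`` is the arm-entry sequence over {A, B, C}; consecutive
    duplicates are invalid (re-entering the same arm is not an entry).
    """
    seq = list(entries)
    if len(seq) < 3:
        raise ValueError("need at least 3 arm entries")
    if any(a == b for a, b in zip(seq, seq[1:])):
        raise ValueError("consecutive duplicate arm entries are not allowed")
    if set(seq) - {"A", "B", "C"}:
        raise ValueError("arms must be A, B or C")
    alternations = sum(
        1 for i in range(len(seq) - 2) if len({seq[i], seq[i + 1], seq[i + 2]}) == 3
    )
    return len(seq), alternations / (len(seq) - 2)
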