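"""Community diversity and ordination statistics.

Alpha diversity uses the Gini–Simpson index D = 1 − Σpᵢ² (higher = more
diverse) and Pielou evenness Je = H′ / ln S with natural-log Shannon
entropy over the S taxa with nonzero abundance. Beta diversity uses
Bray-Curtis dissimilarity, tested by a distance-based PERMANOVA with a
seeded label-permutation null, decomposed per taxon by SIMPER, and
visualised by an unscaled (mean-centred) PCA restricted to taxa reaching a
minimum relative abundance in at least one sample.

All abundance inputs may be percentages or proportions; the indices
renormalise internally and are scale-invariant.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_N_PERMUTATIONS = 999
DEFAULT_PCA_MIN_ABUNDANCE = 0.9


@dataclass
class PermanovaResult:
    pseudo_F: float
    p_value: float
    n_permutations: int
    seed: int
    groups: tuple[str, str] | None = None  # set for pairwise comparisons
    p_adjusted: float | None = None


@dataclass
class OrdinationResult:
    scores: pd.DataFrame       # samples x components
    loadings: pd.DataFrame     # taxa x components
    variance_explained: np.ndarray


# ---------------------------------------------------------------------------
# alpha diversity

def _proportions(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("abundances must be non-negative")
    total = p.sum()
    if total <= 0:
        raise ValueError("abundance vector sums to zero")
    return p / total


def simpson(p) -> float:
    """Gini–Simpson diversity D = 1 − Σ pᵢ²."""
    p = _proportions(p)
    return float(1.0 - np.sum(p**2))


def pielou(p) -> float:
    """Pielou evenness Je = H′ / ln S over nonzero taxa; nan when S < 2."""
    p = _proportions(p)
    p = p[p > 0]
    s = p.size
    if s < 2:
        return float("nan")
    h = -np.sum(p * np.log(p))
    return float(h / math.log(s))


# ---------------------------------------------------------------------------
# beta diversity

def bray_curtis(x, y) -> float:
    """BC = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ), in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("abundances must be non-negative")
    denom = (x + y).sum()
    if denom == 0:
        raise ValueError("both vectors are all-zero")
    return float(np.abs(x - y).sum() / denom)


def distance_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis over the rows (samples) of an abundance table."""
    ids = list(table.index)
    values = table.to_numpy(dtype=float)
    n = len(ids)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = bray_curtis(values[i], values[j])
    return pd.DataFrame(d, index=ids, columns=ids)


def _ss_partition(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float, int]:
    """(SS_total, SS_within, k) from squared distances and group labels."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    values = np.unique(labels)
    for v in values:
        mask = labels == v
        n_g = int(mask.sum())
        if n_g > 1:
            sub = d2[np.ix_(mask, mask)]
            ss_within += sub[np.triu_indices(n_g, k=1)].sum() / n_g
    return float(ss_total), float(ss_within), len(values)


def permanova(
    dm: pd.DataFrame | np.ndarray,
    groups,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
) -> PermanovaResult:
    """Distance-based PERMANOVA with a seeded permutation p-value.

    pseudo-F = (SS_between / (k−1)) / (SS_within / (n−k)) where SS_total is
    the sum over unordered pairs of d²/n and SS_within accumulates the same
    quantity within each group. p = (1 + #{F_perm >= F_obs}) / (1 + P).
    Degenerate inputs (all distances zero) yield nan F and p.
    """
    d = np.asarray(dm, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    labels = np.asarray(pd.factorize(np.asarray(groups))[0])
    n = d.shape[0]
    if labels.size != n:
        raise ValueError("groups length must match matrix size")
    k = len(np.unique(labels))
    if k < 2:
        raise ValueError("need at least two groups")
    if n - k == 0:
        raise ValueError("residual degrees of freedom are zero")

    d2 = d**2

    def f_stat(lab: np.ndarray) -> float:
        ss_total, ss_within, kk = _ss_partition(d2, lab)
        ss_between = ss_total - ss_within
        if ss_within <= 0 and ss_between <= 0:
            return float("nan")
        if ss_within <= 0:
            return float("inf")
        return (ss_between / (kk - 1)) / (ss_within / (n - kk))

    f_obs = f_stat(labels)
    if math.isnan(f_obs):
        return PermanovaResult(float("nan"), float("nan"), n_permutations, seed)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        f_perm = f_stat(rng.permutation(labels))
        if not math.isnan(f_perm) and f_perm >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return PermanovaResult(float(f_obs), float(p), n_permutations, seed)


def permanova_null_rejections(
    n_samples: int,
    groups,
    n_datasets: int,
    n_taxa: int = 10,
    n_permutations: int = 199,
    alpha: float = 0.05,
    seed: int = 0,
) -> np.ndarray:
    """p-values from PERMANOVA on ``n_datasets`` label-exchangeable tables.

    Every dataset draws all samples from one common abundance distribution,
    so group labels carry no signal; the returned p-values calibrate the
    test's type-I error. Vectorised over permutations for speed.
    """
    groups = np.asarray(groups)
    if groups.size != n_samples:
        raise ValueError("groups length must equal n_samples")
    rng = np.random.default_rng(seed)
    labels = pd.factorize(groups)[0]
    uniq = np.unique(labels)
    pvals = np.empty(n_datasets)
    for rep in range(n_datasets):
        table = rng.dirichlet(np.ones(n_taxa), size=n_samples) * 100.0
        d = np.zeros((n_samples, n_samples))
        for i, j in itertools.combinations(range(n_samples), 2):
            d[i, j] = d[j, i] = bray_curtis(table[i], table[j])
        d2 = d**2
        perm_idx = np.vstack(
            [labels] + [rng.permutation(labels) for _ in range(n_permutations)]
        )
        # vectorised SS_within over all permutations at once
        ss_total = d2[np.triu_indices(n_samples, k=1)].sum() / n_samples
        ss_w = np.zeros(perm_idx.shape[0])
        for v in uniq:
            m = (perm_idx == v).astype(float)
            n_g = m[0].sum()
            ss_w += np.einsum("pi,ij,pj->p", m, d2, m) / (2.0 * n_g)
        k = uniq.size
        ss_b = ss_total - ss_w
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (ss_b / (k - 1)) / (ss_w / (n_samples - k))
        pvals[rep] = (1 + np.sum(f[1:] >= f[0])) / (1 + n_permutations)
    return pvals


def benjamini_hochberg(pvals) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_last, idx in enumerate(order[::-1]):
        rank = m - rank_from_last
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


def pairwise_permanova(
    dm: pd.DataFrame,
    groups,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
    adjust: str = "none",
) -> list[PermanovaResult]:
    """One PERMANOVA per group pair on the corresponding sub-matrix."""
    if adjust not in ("none", "bh"):
        raise ValueError("adjust must be 'none' or 'bh'")
    groups = np.asarray(groups)
    d = np.asarray(dm, dtype=float)
    results = []
    for ga, gb in itertools.combinations(pd.unique(groups), 2):
        mask = (groups == ga) | (groups == gb)
        if mask.sum() < 3:  # n - k = 0 -> no residual df
            import warnings

            warnings.warn(f"skipping pair ({ga}, {gb}): too few samples")
            continue
        sub = d[np.ix_(mask, mask)]
        res = permanova(sub, groups[mask], n_permutations, seed)
        res.groups = (str(ga), str(gb))
        results.append(res)
    if adjust == "bh" and results:
        adj = benjamini_hochberg([r.p_value for r in results])
        for r, a in zip(results, adj):
            r.p_adjusted = float(a)
    elif adjust == "none":
        for r in results:
            r.p_adjusted = r.p_value
    return results


def simper(table: pd.DataFrame, groups) -> pd.DataFrame:
    """Per-taxon decomposition of between-group Bray-Curtis dissimilarity.

    For each ordered group pair and taxon i the contribution is the mean
    over cross-group sample pairs (x, y) of |xᵢ − yᵢ| / Σⱼ(xⱼ + yⱼ); taxa
    are ranked by contribution within each pair, and contributions sum to
    the mean between-group Bray-Curtis dissimilarity.
    """
    groups = np.asarray(groups)
    values = table.to_numpy(dtype=float)
    taxa = list(table.columns)
    uniq = pd.unique(groups)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    rows = []
    for ga, gb in itertools.combinations(uniq, 2):
        xa = values[groups == ga]
        xb = values[groups == gb]
        if len(xa) == 0 or len(xb) == 0:
            raise ValueError(f"empty group in pair ({ga}, {gb})")
        contrib = np.zeros(len(taxa))
        n_pairs = 0
        for x in xa:
            for y in xb:
                denom = (x + y).sum()
                if denom == 0:
                    raise ValueError("sample pair with zero total abundance")
                contrib += np.abs(x - y) / denom
                n_pairs += 1
        contrib /= n_pairs
        mean_bc = contrib.sum()
        order = np.argsort(-contrib, kind="mergesort")
        for rank, idx in enumerate(order, start=1):
            rows.append({
                "group_a": ga, "group_b": gb, "taxon": taxa[idx],
                "contribution": contrib[idx],
                "contribution_pct": 100.0 * contrib[idx] / mean_bc if mean_bc else 0.0,
                "mean_bray_curtis": mean_bc, "rank": rank,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ordination

def pca(
    table: pd.DataFrame,
    min_abundance: float = DEFAULT_PCA_MIN_ABUNDANCE,
    scale: bool = False,
) -> OrdinationResult:
    """Unscaled PCA of a samples × taxa relative-abundance table.

    Taxa must reach ``min_abundance`` (inclusive) in at least one sample to
    enter; columns are mean-centred (and optionally standardised), the
    covariance matrix eigendecomposed, and each component's sign fixed so
    its largest-magnitude loading is positive.
    """
    keep = table.columns[(table.max(axis=0) >= min_abundance)]
    if len(keep) < 2:
        raise ValueError(
            f"fewer than 2 taxa reach {min_abundance}% in any sample"
        )
    x = table[keep].to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    centred = x - x.mean(axis=0)
    if scale:
        sd = centred.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        centred = centred / sd
    cov = np.cov(centred, rowvar=False, ddof=1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    total_var = eigval.sum()
    if total_var <= 0:
        raise ValueError("table has zero variance after filtering")
    # deterministic sign: largest |loading| per component is positive
    for c in range(eigvec.shape[1]):
        pivot = np.argmax(np.abs(eigvec[:, c]))
        if eigvec[pivot, c] < 0:
            eigvec[:, c] = -eigvec[:, c]
    scores = centred @ eigvec
    comp_names = [f"PC{i+1}" for i in range(eigvec.shape[1])]
    return OrdinationResult(
        scores=pd.DataFrame(scores, index=table.index, columns=comp_names),
        loadings=pd.DataFrame(eigvec, index=keep, columns=comp_names),
        variance_explained=eigval / total_var,
    )


def diversity_table(table: pd.DataFrame) -> pd.DataFrame:
    """Simpson (D) and Pielou (Je) per sample of a samples × taxa table."""
    rows = []
    for sample_id, row in table.iterrows():
        rows.append({
            "Sample": sample_id,
            "Simpson (D)": round(simpson(row.values), 2),
            "Pielou (Je)": round(pielou(row.values), 2),
        })
    return pd.DataFrame(rows)
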