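"""Enrichment statistics and hierarchical clustering of gene features.

Three statistical layers sit on top of the scanning and ARE modules:

* a two-sided Wilcoxon rank-sum test comparing binding-site abundance
  between gene groups and background (random or shuffled) sequences;
* a one-way ANOVA comparing ARE counts across the Early/Middle/Late
  expression groups, returning group means with 95% confidence
  half-widths;
* agglomerative UPGMA clustering of per-gene feature vectors (expression
  group, distinct/all binding-site counts, a site-dispersion statistic,
  and the three ARE class counts) under either a percent-disagreement
  distance over discretised features or plain Euclidean distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .are import AREReport
from .pwm import ScanReport

NUMERIC_FEATURES = ("distinct_tfbs", "all_tfbs", "dispersion", "are1", "are2", "are3")


@dataclass
class GeneFeatureVector:
    gene_id: str
    group: str
    distinct_tfbs: int
    all_tfbs: int
    dispersion: float
    are1: int
    are2: int
    are3: int


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n_per_group: tuple[int, ...]
    group_means: tuple[float, ...] = ()
    ci_half_widths: tuple[float, ...] = ()


@dataclass
class Dendrogram:
    """Agglomerative merge history in scipy linkage convention.

    ``merges[i]`` is (left_id, right_id, height, size): leaf ids are
    0..n-1, internal node i has id n+i.  Heights are the average
    inter-cluster distances at merge time.
    """

    leaf_labels: list[str]
    merges: list[tuple[int, int, float, int]]
    linkage: str = "UPGMA"
    metric: str = "percent_disagreement"

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def to_linkage(self) -> np.ndarray:
        return np.array([[a, b, h, s] for a, b, h, s in self.merges], dtype=float)

    def to_newick(self) -> str:
        n = self.n_leaves
        nodes: dict[int, tuple[str, float]] = {
            i: (lab, 0.0) for i, lab in enumerate(self.leaf_labels)
        }
        for i, (a, b, h, _) in enumerate(self.merges):
            sa, ha = nodes.pop(a)
            sb, hb = nodes.pop(b)
            rep = f"({sa}:{h - ha:.6g},{sb}:{h - hb:.6g})"
            nodes[n + i] = (rep, h)
        (rep, _), = nodes.values()
        return rep + ";"


# ---------------------------------------------------------------------------
# tests


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses the exact null distribution when the smaller sample has at most
    10 observations and there are no ties; otherwise the normal
    approximation with tie correction (and continuity correction).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        warnings.warn("all values identical across both samples; p = 1")
        return TestResult(statistic=float(x.size * y.size / 2), p_value=1.0,
                          method="wilcoxon_rank_sum",
                          n_per_group=(x.size, y.size))
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(x.size, y.size) <= 10 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      method="wilcoxon_rank_sum", n_per_group=(x.size, y.size))


def anova_oneway(groups: Sequence[Sequence[float]]) -> TestResult:
    """One-way ANOVA across >= 2 groups of counts.

    Returns the F statistic and p-value, plus per-group means and
    t-based 95% confidence-interval half-widths (the data behind a
    means-and-CI plot).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 values each")
    if all(np.var(a) == 0 for a in arrays):
        raise ValueError(
            "zero within-group variance in every group; use an exact test"
        )
    f, p = sps.f_oneway(*arrays)
    means = tuple(float(a.mean()) for a in arrays)
    half = tuple(
        float(sps.t.ppf(0.975, a.size - 1) * a.std(ddof=1) / np.sqrt(a.size))
        for a in arrays
    )
    return TestResult(statistic=float(f), p_value=float(p), method="anova_oneway",
                      n_per_group=tuple(a.size for a in arrays),
                      group_means=means, ci_half_widths=half)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Rank-based alternative to the one-way ANOVA for count data."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 values each")
    h, p = sps.kruskal(*arrays)
    return TestResult(statistic=float(h), p_value=float(p), method="kruskal_wallis",
                      n_per_group=tuple(a.size for a in arrays))


# ---------------------------------------------------------------------------
# features


def locus_dispersion(loci: Sequence[tuple[int, int]]) -> float:
    """Coefficient of variation of gaps between consecutive locus starts.

    A scatter statistic for binding-site placement: 0 for regularly
    spaced or fewer than 3 loci, larger for irregular spacing.
    """
    if len(loci) < 3:
        return 0.0
    starts = np.sort([s for s, _ in loci])
    gaps = np.diff(starts).astype(float)
    mean = gaps.mean()
    if mean == 0:
        return 0.0
    return float(gaps.std() / mean)


def build_features(
    scan_reports: Mapping[str, ScanReport],
    are_reports: Mapping[str, AREReport],
    manifest: Sequence[tuple[str, str]],
) -> list[GeneFeatureVector]:
    """Join per-gene scan and ARE reports into clustering inputs.

    ``manifest`` is a sequence of (gene_id, group) records; every gene
    must have both reports.
    """
    missing = [g for g, _ in manifest
               if g not in scan_reports or g not in are_reports]
    if missing:
        raise KeyError(f"genes missing reports: {missing}")
    out = []
    for gene_id, group in manifest:
        sr = scan_reports[gene_id]
        ar = are_reports[gene_id]
        out.append(
            GeneFeatureVector(
                gene_id=gene_id,
                group=group,
                distinct_tfbs=sr.distinct_total,
                all_tfbs=sr.all_total,
                dispersion=locus_dispersion(sr.loci),
                are1=ar.count_class1,
                are2=ar.count_class2,
                are3=ar.count_class3,
            )
        )
    return out


def make_binning(features: Sequence[GeneFeatureVector], n_bins: int = 3) -> dict[str, np.ndarray]:
    """Quantile bin edges per numeric feature, computed over the dataset."""
    if not features:
        raise ValueError("no features")
    edges = {}
    qs = np.linspace(0, 1, n_bins + 1)[1:-1]
    for name in NUMERIC_FEATURES:
        vals = np.array([getattr(f, name) for f in features], dtype=float)
        edges[name] = np.quantile(vals, qs)
    return edges


def _discretize(fv: GeneFeatureVector, binning: Mapping[str, np.ndarray],
                include_group: bool) -> tuple:
    cats = [int(np.searchsorted(binning[name], getattr(fv, name), side="right"))
            for name in NUMERIC_FEATURES]
    if include_group:
        cats.append(fv.group)
    return tuple(cats)


def percent_disagreement(
    u: GeneFeatureVector,
    v: GeneFeatureVector,
    binning: Mapping[str, np.ndarray],
    include_group: bool = True,
) -> float:
    """Fraction of discretised features on which two genes differ.

    Numeric features are binned with the supplied quantile edges; the
    expression group participates as one categorical feature unless
    disabled.
    """
    cu = _discretize(u, binning, include_group)
    cv = _discretize(v, binning, include_group)
    return sum(a != b for a, b in zip(cu, cv)) / len(cu)


def feature_distance_matrix(
    features: Sequence[GeneFeatureVector],
    metric: str = "percent_disagreement",
    binning: Mapping[str, np.ndarray] | None = None,
    include_group: bool = True,
) -> np.ndarray:
    """Symmetric pairwise distance matrix under the chosen metric."""
    n = len(features)
    d = np.zeros((n, n))
    if metric == "percent_disagreement":
        if binning is None:
            binning = make_binning(features)
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = percent_disagreement(
                    features[i], features[j], binning, include_group
                )
    elif metric == "euclidean":
        x = np.array([[getattr(f, name) for name in NUMERIC_FEATURES]
                      for f in features], dtype=float)
        diff = x[:, None, :] - x[None, :, :]
        d = np.sqrt((diff ** 2).sum(axis=2))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return d


# ---------------------------------------------------------------------------
# clustering


def upgma(dist_matrix: np.ndarray, leaf_labels: Sequence[str] | None = None,
          metric: str = "percent_disagreement") -> Dendrogram:
    """Unweighted pair-group average (UPGMA) agglomeration.

    The merge height is the average inter-cluster distance; ties are
    broken by the smallest pair of cluster ids.
    """
    d = np.asarray(dist_matrix, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN")
    if (d < 0).any() or not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
        raise ValueError("need a symmetric non-negative matrix with zero diagonal")
    n = d.shape[0]
    if leaf_labels is None:
        leaf_labels = [str(i) for i in range(n)]
    labels = list(leaf_labels)
    if len(labels) != n:
        raise ValueError("leaf_labels length mismatch")
    # active clusters: id -> (members, row index in working matrix)
    work = d.copy()
    ids = list(range(n))
    sizes = {i: 1 for i in range(n)}
    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    active = ids[:]
    # index into `work` by position in `active`
    for _ in range(n - 1):
        m = len(active)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                key = (work[i, j], min(active[i], active[j]),
                       max(active[i], active[j]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        (_, _, _), bi, bj = best[0], best[1], best[2]
        hi, hj = active[bi], active[bj]
        height = work[bi, bj]
        size = sizes[hi] + sizes[hj]
        merges.append((min(hi, hj), max(hi, hj), float(height), size))
        # UPGMA update: size-weighted average of the two rows
        new_row = (sizes[hi] * work[bi, :] + sizes[hj] * work[bj, :]) / size
        keep = [k for k in range(m) if k not in (bi, bj)]
        new_work = np.zeros((m - 1, m - 1))
        new_work[:-1, :-1] = work[np.ix_(keep, keep)]
        new_work[-1, :-1] = new_row[keep]
        new_work[:-1, -1] = new_row[keep]
        work = new_work
        active = [active[k] for k in keep] + [next_id]
        sizes[next_id] = size
        next_id += 1
    return Dendrogram(leaf_labels=labels, merges=merges, linkage="UPGMA",
                      metric=metric)


def cut_clusters(dendrogram: Dendrogram, k: int) -> np.ndarray:
    """Leaf cluster assignments after cutting the k-1 highest merges.

    Merges are applied in order; the last k-1 merges are withheld,
    leaving k clusters labelled 0..k-1 in order of their smallest leaf.
    """
    n = dendrogram.n_leaves
    if not 1 <= k <= n:
        raise ValueError("k must be between 1 and the number of leaves")
    parent = list(range(n + len(dendrogram.merges)))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for idx, (a, b, _, _) in enumerate(dendrogram.merges[: n - k]):
        node = n + idx
        parent[find(a)] = node
        parent[find(b)] = node
    roots: dict[int, int] = {}
    out = np.empty(n, dtype=int)
    for leaf in range(n):
        r = find(leaf)
        if r not in roots:
            roots[r] = len(roots)
        out[leaf] = roots[r]
    return out
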