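"""Immune cell estimation, benchmarking and immune-subtype clustering.

Cell abundance is estimated by the marker-mean scheme: the mean normalized
expression of a cell type's marker genes.  Estimates are benchmarked four
ways -- against tumour purity (negative correlations expected), against
copy number at the marker locus (no correlation expected), across methods
(concordance), and against IHC counts -- and consensus hierarchical
clustering of the estimates defines immune subtypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

from .io import CopyNumberSegmentTable, ExpressionMatrix, GeneSetCollection

__all__ = [
    "score_signatures",
    "BenchmarkReport",
    "benchmark_estimates",
    "rank_methods",
    "ImmuneConsensusClusterer",
    "immune_consensus_cluster",
    "compare_groups",
]


def score_signatures(
    expr: ExpressionMatrix, signatures: GeneSetCollection
) -> pd.DataFrame:
    """Marker-mean immune estimates: cell types x samples.

    The estimate for a cell type is the arithmetic mean of its marker gene
    rows present in the matrix.  Cell types with no marker present are
    dropped with a warning; per-type marker coverage is recorded in
    ``.attrs['coverage']``.  The score is linear in the expression values.
    """
    rows, coverage = [], {}
    shared: dict[str, list[str]] = {}
    all_markers: dict[str, set] = {ct.name: set(ct.genes) for ct in signatures}
    for name, genes in all_markers.items():
        for other, genes2 in all_markers.items():
            if other > name and genes & genes2:
                shared.setdefault(name, []).append(other)
    if shared:
        warnings.warn(f"marker genes shared across cell types: {shared}", stacklevel=2)
    for gs in signatures:
        present = [g for g in sorted(gs.genes) if g in expr.frame.index]
        coverage[gs.name] = len(present) / len(gs.genes)
        if not present:
            warnings.warn(
                f"cell type {gs.name!r} has no markers in the matrix; dropped",
                stacklevel=2,
            )
            continue
        rows.append(pd.Series(expr.frame.loc[present].mean(axis=0), name=gs.name))
    out = pd.DataFrame(rows)
    out.attrs["coverage"] = coverage
    return out


# ---------------------------------------------------------------------------
# Benchmarking


@dataclass
class BenchmarkReport:
    """The four benchmark analyses, per method."""

    purity: dict[str, pd.DataFrame] = field(default_factory=dict)
    copy_number: dict[str, pd.DataFrame] = field(default_factory=dict)
    cross_method: pd.DataFrame | None = None
    ihc: dict[str, pd.DataFrame] = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)
    summary: pd.DataFrame | None = None


def _corr_frame(x: pd.DataFrame, y: pd.Series, method: str) -> pd.DataFrame:
    rows = []
    for name, row in x.iterrows():
        common = row.index.intersection(y.index)
        a, b = row[common].astype(float), y[common].astype(float)
        if method == "pearson":
            r, p = stats.pearsonr(a, b)
        else:
            r, p = stats.spearmanr(a, b)
        rows.append((name, float(r), float(p), len(common)))
    return pd.DataFrame(rows, columns=["name", "r", "p", "n"]).set_index("name")


def _gene_copy_value(
    segments: CopyNumberSegmentTable, gene_locations: pd.DataFrame, gene: str
) -> pd.Series:
    """Per-sample copy value at the gene's midpoint (length-weighted mean if
    the gene spans several segments)."""
    loc = gene_locations.loc[gene]
    mid = (loc["start"] + loc["end"]) / 2.0
    seg = segments.frame
    hit = seg[
        (seg["chrom"] == loc["chrom"]) & (seg["start"] <= mid) & (seg["end"] >= mid)
    ]
    if hit.empty:
        return pd.Series(dtype=float)
    return hit.groupby("sample")["copy_value"].mean()


def benchmark_estimates(
    estimates: dict[str, pd.DataFrame],
    purity: pd.Series | None = None,
    segments: CopyNumberSegmentTable | None = None,
    signatures: GeneSetCollection | None = None,
    gene_locations: pd.DataFrame | None = None,
    ihc_counts: pd.DataFrame | None = None,
    ihc_map: dict[str, str] | None = None,
    method: str = "pearson",
    alpha: float = 0.05,
) -> BenchmarkReport:
    """Run the four-part benchmark over several estimate matrices.

    ``estimates`` maps method name -> (cell types x samples).  Analyses with
    fewer than 3 shared samples are skipped with the reason recorded.  The
    summary table carries, per method: the count of negative purity
    correlations, the count of significant copy-number confounds, and the
    mean IHC correlation, supporting best-method selection.
    """
    report = BenchmarkReport()
    for name, est in estimates.items():
        if purity is not None:
            shared = est.columns.intersection(purity.index)
            if len(shared) < 3:
                report.skipped.append(f"{name}/purity: <3 shared samples")
            else:
                report.purity[name] = _corr_frame(est[shared], purity, method)
        if segments is not None and signatures is not None and gene_locations is not None:
            rows = []
            for gs in signatures:
                if gs.name not in est.index:
                    continue
                for gene in sorted(gs.genes):
                    if gene not in gene_locations.index:
                        continue
                    cn = _gene_copy_value(segments, gene_locations, gene)
                    shared = est.columns.intersection(cn.index)
                    if len(shared) < 3:
                        continue
                    r, p = stats.pearsonr(
                        est.loc[gs.name, shared].astype(float), cn[shared]
                    )
                    rows.append((gs.name, gene, float(r), float(p), len(shared)))
            if rows:
                report.copy_number[name] = pd.DataFrame(
                    rows, columns=["cell_type", "gene", "r", "p", "n"]
                )
            else:
                report.skipped.append(f"{name}/copy_number: no testable markers")
        if ihc_counts is not None:
            mapping = ihc_map or {}
            rows = []
            for marker in ihc_counts.columns:
                ct = mapping.get(marker, marker)
                if ct not in est.index:
                    continue
                counts = ihc_counts[marker].dropna()
                shared = est.columns.intersection(counts.index)
                if len(shared) < 3:
                    report.skipped.append(f"{name}/ihc[{marker}]: <3 shared samples")
                    continue
                r, p = stats.pearsonr(
                    est.loc[ct, shared].astype(float), counts[shared].astype(float)
                )
                rows.append((marker, ct, float(r), float(p), len(shared)))
            if rows:
                report.ihc[name] = pd.DataFrame(
                    rows, columns=["marker", "cell_type", "r", "p", "n"]
                ).set_index("marker")

    # cross-method concordance per cell type, for every method pair
    names = list(estimates)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            ea, eb = estimates[a], estimates[b]
            cells = ea.index.intersection(eb.index)
            samples = ea.columns.intersection(eb.columns)
            if len(samples) < 3:
                report.skipped.append(f"{a}~{b}: <3 shared samples")
                continue
            for ct in cells:
                r, _ = stats.pearsonr(
                    ea.loc[ct, samples].astype(float), eb.loc[ct, samples].astype(float)
                )
                rows.append((a, b, ct, float(r)))
    if rows:
        report.cross_method = pd.DataFrame(
            rows, columns=["method_a", "method_b", "cell_type", "r"]
        )

    summary_rows = []
    for name in names:
        n_neg = (
            int((report.purity[name]["r"] < 0).sum()) if name in report.purity else np.nan
        )
        n_cn = (
            int((report.copy_number[name]["p"] < alpha).sum())
            if name in report.copy_number
            else 0
        )
        mean_ihc = (
            float(report.ihc[name]["r"].mean()) if name in report.ihc else np.nan
        )
        summary_rows.append((name, n_neg, n_cn, mean_ihc))
    report.summary = pd.DataFrame(
        summary_rows,
        columns=["method", "n_negative_purity_corr", "n_cn_confounds", "mean_ihc_r"],
    ).set_index("method")
    return report


def rank_methods(report: BenchmarkReport) -> list[str]:
    """Order methods best-first: more negative purity correlations, fewer
    copy-number confounds, higher mean IHC correlation."""
    s = report.summary.copy()
    s["_key"] = list(
        zip(
            -s["n_negative_purity_corr"].fillna(-1),
            s["n_cn_confounds"].fillna(0),
            -s["mean_ihc_r"].fillna(-np.inf),
        )
    )
    return list(s.sort_values("_key").index)


# ---------------------------------------------------------------------------
# Consensus clustering of immune estimates


class ImmuneConsensusClusterer(ClusterMixin, BaseEstimator):
    """Resampled hierarchical consensus clustering of sample profiles.

    Per resample, a fraction of samples is drawn without replacement and
    clustered by agglomerative linkage on 1 - Pearson correlation distance;
    the consensus matrix is the co-clustering frequency normalized by
    co-sampling frequency.  The final partition cuts the average-linkage
    dendrogram of (1 - consensus) at ``k``.  Per-cluster consensus values
    support choosing ``k`` from a range.
    """

    def __init__(
        self,
        k: int = 3,
        n_resamples: int = 50,
        resample_fraction: float = 0.8,
        linkage: str = "average",
        random_state: int | None = None,
    ):
        self.k = k
        self.n_resamples = n_resamples
        self.resample_fraction = resample_fraction
        self.linkage = linkage
        self.random_state = random_state

    def fit(self, X, y=None):
        """Fit on a features x samples DataFrame (columns are clustered)."""
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if isinstance(X, ExpressionMatrix):
            X = X.frame
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X))
        samples = list(X.columns)
        n = len(samples)
        if n < self.k:
            raise ValueError("fewer samples than clusters")
        values = X.to_numpy(dtype=float)
        sds = values.std(axis=0)
        if (sds == 0).any():
            bad = [samples[i] for i in np.nonzero(sds == 0)[0]]
            raise ValueError(
                f"constant profile (undefined correlation) for sample(s) {bad[:5]}"
            )
        corr = np.corrcoef(values.T)
        dist = 1.0 - corr
        np.fill_diagonal(dist, 0.0)

        rng = np.random.default_rng(self.random_state)
        m = max(self.k, int(round(self.resample_fraction * n)))
        together = np.zeros((n, n))
        sampled = np.zeros((n, n))
        idx = np.arange(n)
        for _ in range(self.n_resamples):
            take = np.sort(rng.choice(idx, size=m, replace=False))
            sub = dist[np.ix_(take, take)]
            Z = hierarchy.linkage(squareform(sub, checks=False), method=self.linkage)
            labels = hierarchy.fcluster(Z, t=self.k, criterion="maxclust")
            co = labels[:, None] == labels[None, :]
            together[np.ix_(take, take)] += co
            sampled[np.ix_(take, take)] += 1
        with np.errstate(invalid="ignore", divide="ignore"):
            consensus = np.where(sampled > 0, together / sampled, 0.0)
        np.fill_diagonal(consensus, 1.0)

        Zc = hierarchy.average(squareform(1.0 - consensus, checks=False))
        labels = hierarchy.fcluster(Zc, t=self.k, criterion="maxclust")
        self.labels_ = pd.Series(labels, index=samples, name="immune_cluster")
        self.consensus_matrix_ = pd.DataFrame(
            consensus, index=samples, columns=samples
        )
        self.cluster_consensus_ = pd.Series(
            {
                c: float(
                    consensus[np.ix_(labels == c, labels == c)].mean()
                )
                for c in np.unique(labels)
            },
            name="cluster_consensus",
        )
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_.to_numpy()


def immune_consensus_cluster(
    estimates: pd.DataFrame,
    k: int,
    n_resample: int = 50,
    seed: int | None = None,
    **kwargs,
) -> pd.Series:
    """Functional wrapper over :class:`ImmuneConsensusClusterer`."""
    est = ImmuneConsensusClusterer(
        k=k, n_resamples=n_resample, random_state=seed, **kwargs
    )
    return est.fit(estimates).labels_


# ---------------------------------------------------------------------------
# Group comparisons


def compare_groups(groups, test: str = "wilcoxon"):
    """Two-sided group comparison.

    ``groups`` -- mapping of group name -> 1-D values for ``wilcoxon``
    (exactly 2 groups; Mann-Whitney U with normal approximation and tie
    correction) and ``kruskal`` (>= 2 groups); or a 2x2 table for
    ``fisher`` (exact, two-sided).  Returns (statistic, p).
    """
    if test == "fisher":
        table = np.asarray(groups)
        if table.shape != (2, 2):
            raise ValueError("fisher expects a 2x2 count table")
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        return float(odds), float(p)
    values = {k: np.asarray(v, dtype=float) for k, v in dict(groups).items()}
    if any(v.size == 0 for v in values.values()):
        raise ValueError("empty group")
    if test == "wilcoxon":
        if len(values) != 2:
            raise ValueError("wilcoxon rank-sum expects exactly 2 groups")
        a, b = values.values()
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        return float(res.statistic), float(res.pvalue)
    if test == "kruskal":
        if len(values) < 2:
            raise ValueError("kruskal expects >= 2 groups")
        try:
            with np.errstate(invalid="ignore"):
                stat, p = stats.kruskal(*values.values())
        except ValueError:
            return 0.0, 1.0
        if np.isnan(stat) or np.isnan(p):  # all values identical
            return 0.0, 1.0
        return float(stat), float(p)
    raise ValueError("test must be one of 'wilcoxon', 'kruskal', 'fisher'")
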