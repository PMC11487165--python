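"""Intratumour heterogeneity as Shannon diversity over binned VAFs.

A tumour's somatic mutations are binned by variant allele frequency into ten
equal bins over [0, 1] -- [0, 0.1), [0.1, 0.2), ..., [0.9, 1.0] (half-open,
closed top) -- and the diversity index is the Shannon entropy of the bin
proportions in natural log units, H' = -sum p_i ln p_i, bounded by ln(10).
A flat VAF distribution (many coexisting clones) maximizes H'; a single
tight clonal cluster drives it to zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import MutationTable

__all__ = [
    "N_BINS",
    "VAFHistogram",
    "vaf_histogram",
    "shannon_ith",
    "ith_index",
    "ith_group_compare",
]

N_BINS = 10
BIN_EDGES = np.linspace(0.0, 1.0, N_BINS + 1)


@dataclass
class VAFHistogram:
    counts: np.ndarray  # length 10
    n_mutations: int
    n_excluded: int  # records without usable allele counts

    @property
    def proportions(self) -> np.ndarray:
        if self.n_mutations == 0:
            raise ValueError("histogram has no mutations")
        return self.counts / self.n_mutations


def _bin_index(vafs: np.ndarray) -> np.ndarray:
    # [0, .1), [.1, .2), ..., [.9, 1.0]; the final bin is closed at 1.0.
    idx = np.digitize(vafs, BIN_EDGES[1:-1], right=False)
    idx[vafs >= BIN_EDGES[-2]] = N_BINS - 1
    return idx


def vaf_histogram(
    muts: MutationTable,
    sample: str | None = None,
    non_silent_only: bool = False,
    purity: float | None = None,
) -> VAFHistogram:
    """Ten-bin VAF histogram for one sample's mutations.

    Records without usable allele counts (missing, or zero depth) are
    excluded and tallied; zero usable mutations is an error since H' is then
    undefined.  By default all mutation classes are used; pass
    ``non_silent_only=True`` to restrict to functional classes.  ``purity``
    optionally rescales each VAF by 1/purity (clipped at 1) before binning;
    raw VAFs are the default and no equivalence between the two is claimed.
    """
    table = muts if sample is None else muts.for_sample(sample)
    frame = table.frame
    if non_silent_only:
        frame = frame[table.non_silent_mask()]
        table = MutationTable(frame.copy())
    vafs = table.vaf().to_numpy(dtype=float)
    if purity is not None:
        if not 0 < purity <= 1:
            raise ValueError("purity must lie in (0, 1]")
        vafs = np.minimum(vafs / purity, 1.0)
    usable = np.isfinite(vafs)
    n_excluded = int((~usable).sum())
    vafs = vafs[usable]
    if vafs.size == 0:
        raise ValueError(
            f"no mutations with usable allele counts"
            + (f" for sample {sample!r}" if sample else "")
        )
    bad = (vafs < 0) | (vafs > 1)
    if bad.any():
        raise ValueError("VAF outside [0, 1]")
    counts = np.bincount(_bin_index(vafs), minlength=N_BINS)
    return VAFHistogram(counts=counts, n_mutations=int(vafs.size),
                        n_excluded=n_excluded)


def shannon_ith(hist: VAFHistogram) -> float:
    """Shannon diversity H' = -sum_{p_i > 0} p_i ln p_i (nats)."""
    if hist.n_mutations == 0:
        raise ValueError("empty histogram: H' undefined")
    p = hist.proportions
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def _rarefied_ith(hist: VAFHistogram, depth: int, n_boot: int,
                  rng: np.random.Generator) -> float:
    """Mean H' over bootstrap subsamples of ``depth`` mutations."""
    p = hist.proportions
    values = []
    for _ in range(n_boot):
        counts = rng.multinomial(depth, p)
        values.append(shannon_ith(VAFHistogram(counts, depth, 0)))
    return float(np.mean(values))


def ith_index(
    muts: MutationTable,
    non_silent_only: bool = False,
    on_empty: str = "error",
    rarefy_to: int | None = None,
    n_boot: int = 100,
    seed: int | None = None,
) -> pd.Series:
    """Per-sample Shannon ITH over the whole table.

    ``on_empty`` controls samples with no usable VAFs: ``error`` (default)
    raises, ``drop`` omits them, ``zero`` scores them 0 with a warning.
    H' grows with the number of usable mutations; ``rarefy_to`` optionally
    reports the bootstrap mean H' at a common depth (``n_boot`` resamples)
    to blunt that dependence.
    """
    if on_empty not in ("error", "drop", "zero"):
        raise ValueError("on_empty must be 'error', 'drop' or 'zero'")
    if rarefy_to is not None and rarefy_to < 1:
        raise ValueError("rarefy_to must be >= 1")
    rng = np.random.default_rng(seed)
    out = {}
    for sample in muts.samples:
        try:
            hist = vaf_histogram(muts, sample, non_silent_only=non_silent_only)
            if rarefy_to is None:
                out[sample] = shannon_ith(hist)
            else:
                out[sample] = _rarefied_ith(hist, rarefy_to, n_boot, rng)
        except ValueError:
            if on_empty == "error":
                raise
            if on_empty == "zero":
                warnings.warn(
                    f"sample {sample!r} has no usable VAFs; ITH set to 0",
                    stacklevel=2,
                )
                out[sample] = 0.0
    return pd.Series(out, name="ith", dtype=float)


def ith_group_compare(ith: pd.Series, labels: pd.Series) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon rank-sum comparisons of ITH across groups.

    Pairs where either group has fewer than 2 samples are skipped with the
    reason recorded; per-group medians ride along in ``.attrs['medians']``.
    """
    labels = labels.reindex(ith.index)
    groups = sorted(labels.dropna().unique())
    if len(groups) < 2:
        warnings.warn("fewer than 2 groups; nothing to compare", stacklevel=2)
        out = pd.DataFrame(columns=["group_a", "group_b", "statistic", "p", "note"])
        out.attrs["medians"] = {}
        return out
    values = {g: ith[labels == g].dropna() for g in groups}
    rows = []
    for i, a in enumerate(groups):
        for b in groups[i + 1:]:
            if len(values[a]) < 2 or len(values[b]) < 2:
                rows.append((a, b, np.nan, np.nan, "group with <2 samples"))
                continue
            res = stats.mannwhitneyu(
                values[a], values[b], alternative="two-sided", method="asymptotic"
            )
            rows.append((a, b, float(res.statistic), float(res.pvalue), ""))
    out = pd.DataFrame(rows, columns=["group_a", "group_b", "statistic", "p", "note"])
    out.attrs["medians"] = {g: float(np.median(v)) for g, v in values.items() if len(v)}
    return out
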