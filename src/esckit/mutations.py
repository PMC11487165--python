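"""Mutation-level statistics: burden-adjusted pathway functional-mutation
enrichment, copy-number event classification, DNA-vs-RNA allelic imbalance
and reporting helpers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .io import CopyNumberSegmentTable, GeneSetCollection, MutationTable

__all__ = [
    "FunctionalEnrichmentMatrix",
    "functional_enrichment",
    "enrichment_subtype_test",
    "CN_THRESHOLDS",
    "classify_cn",
    "allelic_imbalance",
    "percent_of",
]


@dataclass
class FunctionalEnrichmentMatrix:
    scores: pd.DataFrame  # gene sets x samples
    burden: pd.Series  # per-sample total functional (non-silent) mutation count
    set_sizes: pd.Series  # per-set gene count
    zero_burden_samples: list


def functional_enrichment(
    muts: MutationTable,
    sets: GeneSetCollection,
    samples=None,
    burden: str = "non_silent",
    adjust=None,
) -> FunctionalEnrichmentMatrix:
    """Mutation-burden-adjusted functional-mutation enrichment per gene set.

    All non-silent mutations count as functionally relevant.  The score of
    set *g* in sample *s* is ``(F_{s,g} / N_g) / max(T_s, 1)`` where F is the
    number of non-silent mutations falling in the set's genes (multiple hits
    in one gene each count), N_g the set size and T_s the sample's total
    burden.  ``burden`` selects whether T_s counts non-silent mutations
    (default) or all records; ``adjust`` may replace the per-mutation
    normalization with any callable ``f(F_over_N, T) -> score``.

    The score is invariant under uniform burden scaling: doubling every
    mutation doubles both F and T and leaves the score unchanged.
    """
    if len(sets) == 0:
        raise ValueError("sets must be non-empty")
    if burden not in ("non_silent", "all"):
        raise ValueError("burden must be 'non_silent' or 'all'")
    frame = muts.frame
    ns = muts.non_silent_mask()
    if samples is None:
        samples = sorted(frame["sample"].unique())
    samples = list(samples)

    if burden == "non_silent":
        T = frame.loc[ns, "sample"].value_counts()
    else:
        T = frame["sample"].value_counts()
    T = T.reindex(samples).fillna(0).astype(int)
    zero_burden = [s for s in samples if T[s] == 0]
    if zero_burden:
        warnings.warn(
            f"{len(zero_burden)} sample(s) with zero burden score 0 everywhere",
            stacklevel=2,
        )

    functional = frame[ns]
    counts = pd.crosstab(functional["gene"], functional["sample"])
    counts = counts.reindex(columns=samples, fill_value=0)

    rows, sizes = [], {}
    for gs in sets:
        sizes[gs.name] = len(gs.genes)
        present = counts.index.intersection(sorted(gs.genes))
        F = (
            counts.loc[present].sum(axis=0)
            if len(present)
            else pd.Series(0, index=samples)
        )
        f_over_n = F / len(gs.genes)
        if adjust is None:
            score = f_over_n / np.maximum(T, 1)
        else:
            score = pd.Series(
                [adjust(f_over_n[s], T[s]) for s in samples], index=samples
            )
        rows.append(score.rename(gs.name))
    scores = pd.DataFrame(rows)
    return FunctionalEnrichmentMatrix(
        scores=scores,
        burden=T,
        set_sizes=pd.Series(sizes, name="set_size"),
        zero_burden_samples=zero_burden,
    )


def enrichment_subtype_test(
    scores: pd.DataFrame,
    labels: pd.Series,
    purity: pd.Series | None = None,
) -> pd.DataFrame:
    """Kruskal-Wallis comparison of per-set enrichment scores across subtypes.

    Returns, per set: the KW statistic and p, the subtype with the highest
    median score, and (when purity is given) the Pearson correlation between
    score and tumour cellularity across all samples.
    """
    labels = labels.reindex(scores.columns)
    if labels.isna().any():
        raise ValueError("labels missing for some samples")
    groups = labels.unique()
    if len(groups) < 2:
        raise ValueError("need at least 2 subtype groups")
    sizes = labels.value_counts()
    small = sizes[sizes < 2]
    if len(small):
        raise ValueError(f"groups with <2 samples: {list(small.index)}")
    rows = []
    for set_name, row in scores.iterrows():
        by_group = [row[labels == g].to_numpy(dtype=float) for g in groups]
        try:
            with np.errstate(invalid="ignore"):
                stat, p = stats.kruskal(*by_group)
        except ValueError:
            stat, p = 0.0, 1.0
        if np.isnan(stat) or np.isnan(p):  # all scores identical everywhere
            stat, p = 0.0, 1.0
        medians = {g: float(np.median(v)) for g, v in zip(groups, by_group)}
        top = max(medians, key=medians.get)
        entry = {
            "set": set_name,
            "kw_stat": float(stat),
            "p": float(p),
            "top_subtype": top,
        }
        if purity is not None:
            shared = row.index.intersection(purity.index)
            if len(shared) >= 3:
                r, rp = stats.pearsonr(
                    row[shared].astype(float), purity[shared].astype(float)
                )
                entry["purity_r"], entry["purity_p"] = float(r), float(rp)
        rows.append(entry)
    return pd.DataFrame(rows).set_index("set")


# ---------------------------------------------------------------------------
# Copy-number event classification

#: log2(copy / mean ploidy) thresholds; boundary ownership is exactly as the
#: comparison operators state: amplification >= 1, deletion <= -1,
#: gain > log2(1.25), loss < log2(0.75).
CN_THRESHOLDS = {
    "amplification": np.log2(4 / 2),
    "gain": np.log2(2.5 / 2),
    "loss": np.log2(1.5 / 2),
    "deletion": np.log2(1 / 2),
}


def classify_cn(segments: CopyNumberSegmentTable) -> pd.DataFrame:
    """Classify each segment as amplification/gain/neutral/loss/deletion.

    The log2 ratio is ``log2(copy_value / sample mean ploidy)``.
    """
    frame = segments.frame.copy()
    ploidy = frame["sample"].map(segments.mean_ploidy)
    frame["log2_ratio"] = np.log2(frame["copy_value"] / ploidy)
    lr = frame["log2_ratio"]
    cls = np.select(
        [
            lr >= CN_THRESHOLDS["amplification"],
            lr <= CN_THRESHOLDS["deletion"],
            lr > CN_THRESHOLDS["gain"],
            lr < CN_THRESHOLDS["loss"],
        ],
        ["amplification", "deletion", "gain", "loss"],
        default="neutral",
    )
    frame["cn_class"] = cls
    return frame


# ---------------------------------------------------------------------------
# Allelic imbalance


def allelic_imbalance(
    dna: tuple[int, int], rna: tuple[int, int], zero_cell_correction: float = 0.5
) -> dict:
    """Two-sided Fisher exact test of DNA vs RNA ref/alt counts.

    Tests the 2x2 assay-by-allele table.  The reported odds ratio applies a
    Haldane-style ``zero_cell_correction`` to every cell when any cell is
    zero, keeping it finite; the p-value is always the uncorrected exact one.
    """
    dna_ref, dna_alt = dna
    rna_ref, rna_alt = rna
    for c in (dna_ref, dna_alt, rna_ref, rna_alt):
        if c < 0:
            raise ValueError("counts must be non-negative")
    if dna_ref + dna_alt == 0 or rna_ref + rna_alt == 0:
        raise ValueError("each assay needs a positive total read count")
    table = np.array([[dna_ref, dna_alt], [rna_ref, rna_alt]])
    _, p = stats.fisher_exact(table, alternative="two-sided")
    if (table == 0).any():
        t = table + zero_cell_correction
    else:
        t = table.astype(float)
    odds = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    return {
        "odds_ratio": float(odds),
        "p": float(p),
        "dna_alt_fraction": dna_alt / (dna_ref + dna_alt),
        "rna_alt_fraction": rna_alt / (rna_ref + rna_alt),
    }


def percent_of(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Percentage ``100 * numerator / denominator`` rounded half-up."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must lie in [0, denominator]")
    q = Decimal(numerator) * 100 / Decimal(denominator)
    exp = Decimal(1).scaleb(-decimals)
    return float(q.quantize(exp, rounding=ROUND_HALF_UP))
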