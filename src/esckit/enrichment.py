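"""Shared enrichment statistics.

Hypergeometric over-representation (ORA), Benjamini-Hochberg FDR,
pre-ranked GSEA with a gene-label permutation null, and a mean-z
single-sample pathway-activity score used in place of GSVA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, GeneSetCollection

__all__ = [
    "bh_adjust",
    "hypergeom_ora",
    "gsea_preranked",
    "single_sample_pathway_score",
]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving.

    Wraps the statsmodels implementation; values outside [0, 1] are rejected.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p.ravel(), method="fdr_bh")[1].reshape(p.shape)


def hypergeom_ora(
    query,
    sets: GeneSetCollection,
    universe,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of *query* in each set.

    Sets are intersected with the universe first (empty intersections are
    dropped with a warning); BH adjustment is applied across all sets tested
    in this call.  Returns a DataFrame indexed by set name with columns
    k (overlap), n (query size), K (set size in universe), N (universe size),
    p, adj_p and neg_log10_p.
    """
    universe = frozenset(universe)
    query = frozenset(query)
    if not universe:
        raise ValueError("empty universe")
    if not query:
        raise ValueError("empty query")
    extra = query - universe
    if extra:
        warnings.warn(
            f"{len(extra)} query gene(s) outside the universe were dropped",
            stacklevel=2,
        )
        query = query & universe
        if not query:
            raise ValueError("query has no genes inside the universe")
    sets_u = sets.restricted_to(universe)
    N, n = len(universe), len(query)
    rows = []
    for gs in sets_u:
        K = len(gs.genes)
        k = len(gs.genes & query)
        # P[X >= k] for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((gs.name, k, n, K, N, min(p, 1.0)))
    out = pd.DataFrame(
        rows, columns=["set", "k", "n", "K", "N", "p"]
    ).set_index("set")
    out["adj_p"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    with np.errstate(divide="ignore"):
        out["neg_log10_p"] = -np.log10(out["p"])
    return out


# ---------------------------------------------------------------------------
# Pre-ranked GSEA


def _rank_order(scores: pd.Series) -> pd.Series:
    """Descending score order; ties broken by gene id for a stable ranking."""
    frame = scores.rename("score").rename_axis("gene").reset_index()
    frame = frame.sort_values(["score", "gene"], ascending=[False, True])
    return pd.Series(frame["score"].to_numpy(), index=frame["gene"].to_numpy())


def _enrichment_score(scores: np.ndarray, in_set: np.ndarray, weight: float) -> float:
    """Signed max-deviation running-sum enrichment score.

    Hit steps are |score|^weight normalized to sum 1 over set members; miss
    steps are 1/(N - Nh).  Returns the running-sum value of largest absolute
    magnitude (positive deviations win ties, matching np.argmax on |RS|).
    """
    n = scores.size
    nh = int(in_set.sum())
    if nh == 0 or nh == n:
        raise ValueError("gene set must hit a strict, non-empty subset of the list")
    w = np.abs(scores) ** weight
    hit_total = w[in_set].sum()
    steps = np.where(in_set, (w / hit_total if hit_total > 0 else 0.0), -1.0 / (n - nh))
    if hit_total == 0:  # all member scores zero under weighting: uniform hits
        steps = np.where(in_set, 1.0 / nh, -1.0 / (n - nh))
    rs = np.cumsum(steps)
    return float(rs[np.argmax(np.abs(rs))])


@dataclass
class GSEAResult:
    table: pd.DataFrame  # index set name: ES, NES, p, fdr_q, size
    n_perm: int
    seed: int | None


def gsea_preranked(
    ranked: pd.Series,
    sets: GeneSetCollection,
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int | None = None,
    fdr_pooling: str = "per_sign",
) -> GSEAResult:
    """Pre-ranked GSEA with a gene-label permutation null.

    ``ranked`` maps gene -> ranking score (finite, unique genes).  For each
    set the weighted running-sum enrichment score (ES) is computed; the null
    is formed by randomly relabelling which genes belong to the set
    (``n_perm`` draws).  NES = ES / mean(|null ES| of matching sign); the
    nominal p is the one-sided frequency of same-sign null ES at least as
    extreme.  FDR q pools observed and null NES either separately by sign
    (``per_sign``, default) or together (``pooled``).
    """
    if ranked.index.duplicated().any():
        raise ValueError("duplicate gene ids in ranked list")
    if not np.isfinite(ranked.to_numpy(dtype=float)).all():
        raise ValueError("ranking scores must be finite")
    if fdr_pooling not in ("per_sign", "pooled"):
        raise ValueError("fdr_pooling must be 'per_sign' or 'pooled'")
    ordered = _rank_order(ranked.astype(float))
    genes = np.asarray(ordered.index)
    scores = ordered.to_numpy()
    n = genes.size
    rng = np.random.default_rng(seed)

    rows = []
    null_nes_store: list[np.ndarray] = []
    for gs in sets:
        members = gs.genes & set(genes)
        if not members:
            warnings.warn(f"set {gs.name!r} shares no genes with the ranking; skipped",
                          stacklevel=2)
            continue
        in_set = np.isin(genes, list(members))
        es = _enrichment_score(scores, in_set, weight)
        nh = int(in_set.sum())
        null_es = np.empty(n_perm)
        idx = np.arange(n)
        for b in range(n_perm):
            perm = rng.choice(idx, size=nh, replace=False)
            mask = np.zeros(n, dtype=bool)
            mask[perm] = True
            null_es[b] = _enrichment_score(scores, mask, weight)
        pos = null_es[null_es >= 0]
        neg = null_es[null_es < 0]
        if es >= 0:
            denom = pos.mean() if pos.size else np.nan
            p = (np.sum(pos >= es) + 1) / (pos.size + 1) if pos.size else 1.0
        else:
            denom = np.abs(neg).mean() if neg.size else np.nan
            p = (np.sum(neg <= es) + 1) / (neg.size + 1) if neg.size else 1.0
        nes = es / denom if denom and np.isfinite(denom) and denom > 0 else np.nan
        with np.errstate(invalid="ignore", divide="ignore"):
            null_nes = np.where(
                null_es >= 0,
                null_es / (pos.mean() if pos.size else np.nan),
                null_es / (np.abs(neg).mean() if neg.size else np.nan),
            )
        null_nes_store.append(null_nes[np.isfinite(null_nes)])
        rows.append((gs.name, es, nes, float(p), nh))

    table = pd.DataFrame(
        rows, columns=["set", "ES", "NES", "p", "size"]
    ).set_index("set")

    # FDR q: fraction of null NES >= NES* over fraction of observed NES >= NES*
    # (mirrored for the negative side), pooled across sets.
    q = np.full(len(table), np.nan)
    if null_nes_store:
        all_null = np.concatenate(null_nes_store)
        obs = table["NES"].to_numpy()
        for i, nes in enumerate(obs):
            if not np.isfinite(nes):
                q[i] = np.nan
                continue
            if fdr_pooling == "per_sign":
                null_side = all_null[all_null >= 0] if nes >= 0 else all_null[all_null < 0]
                obs_side = obs[obs >= 0] if nes >= 0 else obs[obs < 0]
            else:
                null_side, obs_side = np.abs(all_null), np.abs(obs)
                nes = abs(nes)
            if null_side.size == 0 or obs_side.size == 0:
                q[i] = np.nan
                continue
            if nes >= 0:
                num = np.mean(null_side >= nes)
                den = np.mean(obs_side >= nes)
            else:
                num = np.mean(null_side <= nes)
                den = np.mean(obs_side <= nes)
            q[i] = min(1.0, num / den) if den > 0 else np.nan
    table["fdr_q"] = q
    return GSEAResult(table=table, n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# Single-sample pathway activity (mean-z), the documented stand-in for GSVA


def single_sample_pathway_score(
    expr: ExpressionMatrix, sets: GeneSetCollection, ddof: int = 0
) -> pd.DataFrame:
    """Mean-z single-sample pathway activity.

    Each gene is z-scored across samples (zero-variance genes score 0 with a
    warning); a pathway's score in a sample is the mean z of its member genes
    present in the matrix.  Returns sets x samples; a ``coverage`` attribute
    column is attached via ``.attrs['coverage']``.
    """
    if expr.shape[1] < 2:
        raise ValueError("z-scoring needs at least 2 samples")
    values = expr.frame
    mu = values.mean(axis=1)
    sd = values.std(axis=1, ddof=ddof)
    zero_var = sd == 0
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} zero-variance gene(s) scored as z = 0",
            stacklevel=2,
        )
    z = values.sub(mu, axis=0).div(sd.where(~zero_var, 1.0), axis=0)
    z[zero_var] = 0.0
    rows, coverage = [], {}
    for gs in sets:
        present = [g for g in gs.genes if g in z.index]
        coverage[gs.name] = len(present) / len(gs.genes)
        if not present:
            warnings.warn(f"set {gs.name!r} has no genes in the matrix; skipped",
                          stacklevel=2)
            continue
        rows.append(pd.Series(z.loc[present].mean(axis=0), name=gs.name))
    out = pd.DataFrame(rows)
    out.attrs["coverage"] = coverage
    return out
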