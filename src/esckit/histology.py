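"""Histology tile meta-feature inference.

The pipeline starts from a tile-feature table (CNN feature extraction is
upstream): QC away high-background tiles, sample a fixed number of tiles per
slide, split patients into discovery/test halves, test every (group,
feature) pair with a one-vs-rest two-sided Wilcoxon rank-sum, BH-adjust
across ALL pairs jointly, select the top features per group that are
significant, directionally higher in the target group and unique to it, sum
them into a per-tile meta-feature, and validate direction and significance
on the held-out half.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .enrichment import bh_adjust
from .io import TileFeatureTable

__all__ = [
    "qc_and_sample_tiles",
    "SplitPlan",
    "patient_split",
    "MetaFeatureSelector",
    "select_meta_features",
    "validate_meta_features",
]


def qc_and_sample_tiles(
    table: TileFeatureTable,
    max_background: float = 0.20,
    tiles_per_slide: int = 50,
    seed: int | None = None,
) -> TileFeatureTable:
    """Remove tiles with background_fraction strictly above ``max_background``
    then sample exactly ``tiles_per_slide`` per slide without replacement.

    Slides with fewer passing tiles contribute all of them (warned); a slide
    with zero passing tiles is an error.  Per-slide tallies are recorded in
    ``.attrs['per_slide']`` of the returned meta frame.
    """
    if tiles_per_slide < 1:
        raise ValueError("tiles_per_slide must be >= 1")
    rng = np.random.default_rng(seed)
    passing = table.meta["background_fraction"] <= max_background
    slides = table.meta["slide_id"].unique()
    empty = [s for s in slides if not passing[table.meta["slide_id"] == s].any()]
    if empty:
        raise ValueError(f"slide(s) with zero passing tiles: {empty[:5]}")
    keep_idx: list[int] = []
    tallies = {}
    short = []
    for slide in slides:
        idx = np.nonzero((table.meta["slide_id"] == slide).to_numpy()
                         & passing.to_numpy())[0]
        if idx.size <= tiles_per_slide:
            chosen = idx
            if idx.size < tiles_per_slide:
                short.append(slide)
        else:
            chosen = rng.choice(idx, size=tiles_per_slide, replace=False)
        keep_idx.extend(sorted(chosen.tolist()))
        tallies[slide] = int(len(chosen))
    if short:
        warnings.warn(
            f"{len(short)} slide(s) had fewer than {tiles_per_slide} passing "
            "tiles and contribute all of them",
            stacklevel=2,
        )
    out = table.select_rows(np.asarray(sorted(keep_idx)))
    out.meta.attrs["per_slide"] = tallies
    return out


@dataclass
class SplitPlan:
    discovery_patients: list[str]
    test_patients: list[str]
    discovery_fraction: float
    seed: int | None
    retries: int = 0

    def __post_init__(self) -> None:
        overlap = set(self.discovery_patients) & set(self.test_patients)
        if overlap:
            raise ValueError(f"patients in both halves: {sorted(overlap)[:5]}")


def patient_split(
    table: TileFeatureTable,
    discovery_fraction: float = 0.65,
    seed: int | None = None,
    max_retries: int = 100,
) -> SplitPlan:
    """Patient-level discovery/test split targeting a tile fraction.

    Patients are randomly ordered and assigned to discovery until its tile
    count reaches the target fraction; no patient appears in both halves.
    When group labels exist, the split is re-drawn (up to ``max_retries``)
    until every group is represented in both halves; a group with a single
    patient makes that impossible and is an error.
    """
    if not 0 < discovery_fraction < 1:
        raise ValueError("discovery_fraction must lie in (0, 1)")
    meta = table.meta
    patients = meta["patient_id"].unique()
    if len(patients) < 2:
        raise ValueError("need at least 2 patients to split")
    has_groups = "group" in meta.columns and meta["group"].notna().all()
    if has_groups:
        per_group = meta.drop_duplicates("patient_id").groupby("group")["patient_id"].nunique()
        singles = per_group[per_group < 2]
        if len(singles):
            raise ValueError(
                f"group(s) with a single patient cannot appear in both halves: "
                f"{list(singles.index)}"
            )
    tile_counts = meta["patient_id"].value_counts()
    total = int(tile_counts.sum())
    target = discovery_fraction * total
    rng = np.random.default_rng(seed)
    group_of = meta.drop_duplicates("patient_id").set_index("patient_id")["group"] \
        if has_groups else None
    for attempt in range(max_retries):
        discovery: list[str] = []
        test: list[str] = []
        if has_groups:
            # stratified seeding: one random patient per group on each side
            for grp in group_of.unique():
                members = rng.permutation(group_of.index[group_of == grp])
                discovery.append(members[0])
                test.append(members[1])
        assigned = set(discovery) | set(test)
        rest = [p for p in rng.permutation(patients) if p not in assigned]
        cum = int(tile_counts[discovery].sum()) if discovery else 0
        for p in rest:
            if cum < target:
                discovery.append(p)
                cum += int(tile_counts[p])
            else:
                test.append(p)
        if not test:
            test = [discovery.pop()]
        if has_groups:
            all_groups = set(group_of)
            if (set(group_of[discovery]) != all_groups
                    or set(group_of[test]) != all_groups):
                continue
        return SplitPlan(
            discovery_patients=list(discovery),
            test_patients=list(test),
            discovery_fraction=discovery_fraction,
            seed=seed,
            retries=attempt,
        )
    raise RuntimeError(
        f"could not produce a split with every group in both halves "
        f"within {max_retries} retries"
    )


# ---------------------------------------------------------------------------
# Meta-feature selection


class MetaFeatureSelector(TransformerMixin, BaseEstimator):
    """One-vs-rest Wilcoxon tile-feature selection with joint BH FDR.

    For every (group, feature) pair on the discovery tiles, a two-sided
    Mann-Whitney U compares target-group tiles against the rest; p-values
    are BH-adjusted across all pairs in one family.  Candidate features for
    a group must be significant at ``fdr_cutoff``, higher in the target
    group (by mean, or median with ``higher_by='median'``), and significant
    with the higher direction in exactly one group.  The ``top_n`` per group
    are taken by smallest adjusted p (option: largest standardized effect),
    ties by larger |effect| then feature name.  A tile's meta-feature value
    for a group is the sum of that group's selected features.

    Fitted attributes: ``selected_`` (group -> feature list), ``stats_``
    (full pair table), ``groups_``.
    """

    def __init__(
        self,
        fdr_cutoff: float = 0.01,
        top_n: int = 5,
        higher_by: str = "mean",
        rank_by: str = "adj_p",
    ):
        self.fdr_cutoff = fdr_cutoff
        self.top_n = top_n
        self.higher_by = higher_by
        self.rank_by = rank_by

    def fit(self, X: TileFeatureTable, y=None):
        if self.higher_by not in ("mean", "median"):
            raise ValueError("higher_by must be 'mean' or 'median'")
        if self.rank_by not in ("adj_p", "effect"):
            raise ValueError("rank_by must be 'adj_p' or 'effect'")
        meta, feats = X.meta, X.features
        if "group" not in meta.columns:
            raise ValueError("tile table needs a 'group' column to fit")
        groups = sorted(meta["group"].dropna().unique())
        if len(groups) < 2:
            raise ValueError("need >= 2 groups")
        counts = meta["group"].value_counts()
        if (counts < 2).any():
            raise ValueError("each group needs >= 2 tiles")
        values = feats.to_numpy(dtype=float)
        names = np.asarray(feats.columns)

        records = []
        for g in groups:
            in_g = (meta["group"] == g).to_numpy()
            a, b = values[in_g], values[~in_g]
            res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                     method="asymptotic", axis=0)
            if self.higher_by == "mean":
                diff = a.mean(axis=0) - b.mean(axis=0)
            else:
                diff = np.median(a, axis=0) - np.median(b, axis=0)
            pooled = np.sqrt((a.var(axis=0, ddof=1) + b.var(axis=0, ddof=1)) / 2)
            with np.errstate(invalid="ignore", divide="ignore"):
                effect = np.where(pooled > 0, (a.mean(axis=0) - b.mean(axis=0)) / pooled, 0.0)
            records.append(
                pd.DataFrame(
                    {
                        "group": g,
                        "feature": names,
                        "p": res.pvalue,
                        "higher": diff > 0,
                        "effect": effect,
                    }
                )
            )
        stats_table = pd.concat(records, ignore_index=True)
        # Constant features yield NaN p from the U test: never selectable.
        stats_table["p"] = stats_table["p"].fillna(1.0)
        stats_table["adj_p"] = bh_adjust(stats_table["p"].to_numpy())
        stats_table["candidate"] = (
            (stats_table["adj_p"] < self.fdr_cutoff) & stats_table["higher"]
        )
        # uniqueness: significant-and-higher in exactly one group
        sig_per_feature = stats_table.groupby("feature")["candidate"].sum()
        unique_feats = set(sig_per_feature[sig_per_feature == 1].index)
        stats_table["unique"] = stats_table["feature"].isin(unique_feats)

        selected: dict[str, list[str]] = {}
        for g in groups:
            cand = stats_table[
                (stats_table["group"] == g)
                & stats_table["candidate"]
                & stats_table["unique"]
            ].copy()
            if self.rank_by == "adj_p":
                cand = cand.sort_values(
                    ["adj_p", "effect", "feature"], ascending=[True, False, True]
                )
            else:
                cand = cand.sort_values(
                    ["effect", "adj_p", "feature"], ascending=[False, True, True]
                )
            chosen = cand["feature"].head(self.top_n).tolist()
            if len(chosen) < self.top_n:
                warnings.warn(
                    f"group {g!r}: only {len(chosen)} candidate feature(s) "
                    f"available (requested {self.top_n})",
                    stacklevel=2,
                )
            selected[g] = chosen
        self.groups_ = groups
        self.stats_ = stats_table
        self.selected_ = selected
        self.fdr_cutoff_ = self.fdr_cutoff
        return self

    def transform(self, X: TileFeatureTable) -> pd.DataFrame:
        """Per-tile meta-feature values (tiles x groups): sum of each group's
        selected features."""
        check_is_fitted(self, "selected_")
        out = {}
        for g, feats in self.selected_.items():
            out[g] = (
                X.features[feats].sum(axis=1)
                if feats
                else pd.Series(np.nan, index=X.features.index)
            )
        frame = pd.DataFrame(out)
        frame.index = X.meta["tile_id"]
        return frame

    def validate(self, test: TileFeatureTable) -> pd.DataFrame:
        """Meta-feature validation on a held-out tile table.

        Per group: two-sided Wilcoxon of the group's meta value, target vs
        rest, plus the per-feature discovery-direction concordance fraction
        on the test tiles.  Groups absent from the test set are skipped.
        """
        check_is_fitted(self, "selected_")
        meta, feats = test.meta, test.features
        if len(meta) == 0:
            raise ValueError("empty test table")
        if "group" not in meta.columns:
            raise ValueError("test table needs a 'group' column")
        rows = []
        for g in self.groups_:
            in_g = (meta["group"] == g).to_numpy()
            if in_g.sum() == 0:
                rows.append((g, np.nan, np.nan, False, np.nan, "group absent from test"))
                continue
            sel = self.selected_[g]
            if not sel:
                rows.append((g, np.nan, np.nan, False, np.nan, "no features selected"))
                continue
            metav = feats[sel].sum(axis=1).to_numpy()
            a, b = metav[in_g], metav[~in_g]
            res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                     method="asymptotic")
            higher = a.mean() > b.mean()
            per_feature = [
                feats.loc[in_g, f].mean() > feats.loc[~in_g, f].mean() for f in sel
            ]
            rows.append(
                (
                    g,
                    float(res.statistic),
                    float(res.pvalue),
                    bool(higher),
                    float(np.mean(per_feature)),
                    "",
                )
            )
        return pd.DataFrame(
            rows,
            columns=["group", "statistic", "p", "direction_concordant",
                     "feature_direction_fraction", "note"],
        ).set_index("group")


def select_meta_features(
    discovery: TileFeatureTable,
    fdr_cutoff: float = 0.01,
    top_n: int = 5,
    **kwargs,
) -> MetaFeatureSelector:
    """Fit a :class:`MetaFeatureSelector` on the discovery tiles."""
    return MetaFeatureSelector(fdr_cutoff=fdr_cutoff, top_n=top_n, **kwargs).fit(
        discovery
    )


def validate_meta_features(
    model: MetaFeatureSelector, test: TileFeatureTable
) -> pd.DataFrame:
    return model.validate(test)
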