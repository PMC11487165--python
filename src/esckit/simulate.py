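"""Synthetic cohort generator.

Emulates the statistical structure every downstream stage assumes -- a
four-subtype block expression matrix with planted marker genes, immune
marker expression driven by known cell fractions with purity confounding,
negative-binomial mutation burdens with planted pathway enrichment and
clonal/subclonal VAF mixtures, tile-feature tables with planted
group-discriminative features, and survival times tied to subtype and
intratumour heterogeneity.  Every generator returns the ground truth next to
the data so recovery tests never re-derive it.

All randomness flows through ``numpy.random.default_rng`` (PCG64) seeded
from the config, so output is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    ExpressionMatrix,
    GeneSetCollection,
    MutationTable,
    SampleSheet,
    TileFeatureTable,
    write_expression,
    write_gmt,
    write_mutations,
    write_sample_sheet,
    write_tiles,
)

__all__ = [
    "CohortSimConfig",
    "simulate_expression",
    "simulate_immune",
    "simulate_mutations",
    "simulate_tile_features",
    "simulate_survival",
    "simulate_cohort",
]

SUBTYPES = ("differentiated", "immunogenic", "metabolic", "stemness")


@dataclass
class CohortSimConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the scale of a ~120-tumour cohort: 30 samples per
    subtype, 2,000 genes with 50 markers per subtype, ~150 non-silent
    mutations per sample, 91 slides with 50 usable tiles each.
    """

    # expression
    n_per_subtype: int = 30
    n_genes: int = 2000
    n_markers_per_subtype: int = 50
    marker_effect: float = 2.0  # log-scale mean shift in the subtype's samples
    noise_sd: float = 1.0

    # immune layer
    n_immune_cell_types: int = 13
    immune_signal_scale: float = 20.0
    immune_noise_sd: float = 0.15
    immune_purity_confounding: float = 0.8  # weight of purity in the signal
    purity_alpha: float = 8.0  # purity ~ Beta(alpha, beta); mean 0.73, sd 0.13
    purity_beta: float = 3.0

    # mutations
    burden_mean: float = 150.0  # mean non-silent burden per sample
    burden_dispersion: float = 3.0  # NB size parameter (smaller = more spread)
    enrichment_factors: dict = field(default_factory=dict)  # subtype -> {set: factor}
    variant_class_probs: dict = field(
        default_factory=lambda: {
            "missense": 0.50,
            "nonsense": 0.05,
            "frameshift": 0.06,
            "splice_site": 0.04,
            "inframe_indel": 0.02,
            "synonymous": 0.28,
            "other": 0.05,
        }
    )
    vaf_cluster_means: tuple = (0.45, 0.18)  # clonal, subclonal beta means
    vaf_cluster_weights: tuple = (0.6, 0.4)
    vaf_concentration: float = 30.0  # beta a+b for each cluster
    mean_depth: float = 80.0

    # tiles
    n_slides: int = 91
    tiles_per_slide_raw: int = 80  # tiles per slide before QC/sampling
    n_tile_features: int = 300
    n_planted_features_per_group: int = 5
    planted_feature_shift: float = 3.0
    tile_noise_sd: float = 1.0
    background_over_fraction: float = 0.2  # tiles with background_fraction > 0.20

    # survival
    baseline_hazard: float = 1.0 / 1000.0  # per day
    subtype_log_hazard: dict = field(
        default_factory=lambda: {
            "differentiated": 0.0,
            "immunogenic": -0.2,
            "metabolic": 0.1,
            "stemness": 0.7,
        }
    )
    ith_log_hazard: float = 0.3  # per unit of Shannon H'
    censoring_rate: float = 1.0 / 2500.0  # exponential censoring hazard

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_per_subtype", "n_genes", "n_markers_per_subtype",
                     "n_immune_cell_types", "n_slides", "tiles_per_slide_raw",
                     "n_tile_features", "n_planted_features_per_group"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_markers_per_subtype * len(SUBTYPES) > self.n_genes:
            raise ValueError("marker genes across subtypes exceed n_genes")
        if abs(sum(self.vaf_cluster_weights) - 1.0) > 1e-9:
            raise ValueError("vaf_cluster_weights must sum to 1")
        if abs(sum(self.variant_class_probs.values()) - 1.0) > 1e-9:
            raise ValueError("variant_class_probs must sum to 1")
        for sub, factors in self.enrichment_factors.items():
            for name, f in factors.items():
                if f <= 0:
                    raise ValueError(
                        f"enrichment factor for {sub}/{name} must be > 0"
                    )
        if self.censoring_rate < 0:
            raise ValueError("censoring_rate must be >= 0")
        if not 0 <= self.background_over_fraction <= 1:
            raise ValueError("background_over_fraction must lie in [0, 1]")

    def rng(self, stream: str) -> np.random.Generator:
        """Named independent RNG stream derived from the config seed."""
        digest = hashlib.sha256(f"{self.seed}:{stream}".encode()).digest()
        return np.random.default_rng(int.from_bytes(digest[:4], "big"))


def _sample_ids(config: CohortSimConfig) -> tuple[list[str], pd.Series]:
    ids, labels = [], []
    for s, name in enumerate(SUBTYPES):
        for i in range(config.n_per_subtype):
            ids.append(f"S{s * config.n_per_subtype + i + 1:03d}")
            labels.append(name)
    return ids, pd.Series(labels, index=ids, name="subtype")


def simulate_expression(
    config: CohortSimConfig,
) -> tuple[ExpressionMatrix, dict]:
    """Block-structured log-scale expression with planted subtype markers.

    Background genes are i.i.d. N(0, noise_sd); each subtype's marker genes
    gain ``marker_effect`` in that subtype's samples.  Returns the matrix and
    a truth dict with ``labels`` (Series) and ``markers`` (subtype -> genes).
    """
    rng = config.rng("expression")
    sample_ids, labels = _sample_ids(config)
    n_samples = len(sample_ids)
    gene_ids = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    X = rng.normal(0.0, config.noise_sd, size=(config.n_genes, n_samples))
    markers: dict[str, list[str]] = {}
    for s, name in enumerate(SUBTYPES):
        lo = s * config.n_markers_per_subtype
        hi = lo + config.n_markers_per_subtype
        cols = np.asarray(labels.to_numpy() == name)
        X[lo:hi][:, cols] += config.marker_effect
        markers[name] = gene_ids[lo:hi]
    expr = ExpressionMatrix(pd.DataFrame(X, index=gene_ids, columns=sample_ids))
    return expr, {"labels": labels, "markers": markers}


def simulate_immune(
    config: CohortSimConfig, signatures: GeneSetCollection
) -> tuple[ExpressionMatrix, dict]:
    """Immune-marker expression driven by known cell fractions and purity.

    Cell-type fractions are Dirichlet; tumour purity is Beta.  A marker
    gene's expression is ``scale * fraction * (1 - w * purity) + noise``
    with confounding weight ``w``, so the purity-correlation benchmark has a
    known (negative) sign while the planted fractions stay recoverable by
    marker-mean scoring.  Truth carries ``fractions`` (cell types x samples)
    and ``purity``.
    """
    if len(signatures) == 0:
        raise ValueError("signatures must be non-empty")
    rng = config.rng("immune")
    sample_ids, labels = _sample_ids(config)
    n = len(sample_ids)
    cell_types = signatures.names()
    fractions = rng.dirichlet(np.ones(len(cell_types)), size=n).T  # types x samples
    purity = rng.beta(config.purity_alpha, config.purity_beta, size=n)
    rows, genes = [], []
    for t, ct in enumerate(cell_types):
        signal = (
            config.immune_signal_scale
            * fractions[t]
            * (1.0 - config.immune_purity_confounding * purity)
        )
        for g in sorted(signatures[ct].genes):
            rows.append(signal + rng.normal(0, config.immune_noise_sd, size=n))
            genes.append(g)
    frame = pd.DataFrame(rows, index=pd.Index(genes), columns=sample_ids)
    frame = frame.groupby(level=0).mean()  # markers shared across types: average
    expr = ExpressionMatrix(frame)
    truth = {
        "fractions": pd.DataFrame(fractions, index=cell_types, columns=sample_ids),
        "purity": pd.Series(purity, index=sample_ids, name="purity"),
        "labels": labels,
    }
    return expr, truth


def simulate_mutations(
    config: CohortSimConfig,
    gene_sets: GeneSetCollection,
    subtype_labels: pd.Series | None = None,
    n_background_genes: int = 1000,
) -> tuple[MutationTable, dict]:
    """Somatic mutations with planted pathway enrichment and VAF mixtures.

    Per-sample non-silent burden is negative binomial (``burden_mean``,
    ``burden_dispersion``); within a sample, mutations land on genes with
    uniform base rates, multiplied by the sample subtype's enrichment factor
    for genes of planted sets.  Variant classes follow the configured
    multinomial (silent records are added on top of the non-silent burden in
    proportion), and VAFs come from the sample's clonal/subclonal beta
    mixture, realized as binomial read counts at Poisson depth.
    """
    if len(gene_sets) == 0:
        raise ValueError("gene_sets must be non-empty")
    rng = config.rng("mutations")
    if subtype_labels is None:
        _, subtype_labels = _sample_ids(config)
    sample_ids = list(subtype_labels.index)

    set_genes = sorted(set().union(*(gs.genes for gs in gene_sets)))
    background = [f"BG{i + 1:05d}" for i in range(n_background_genes)]
    genes = np.asarray(set_genes + background)
    n_genes = genes.size
    membership = {
        gs.name: np.isin(genes, sorted(gs.genes)) for gs in gene_sets
    }

    classes = list(config.variant_class_probs)
    class_p = np.asarray([config.variant_class_probs[c] for c in classes])
    nonsilent_frac = sum(
        p for c, p in config.variant_class_probs.items()
        if c not in ("synonymous", "other")
    )

    frames = []
    for sid in sample_ids:
        subtype = subtype_labels.loc[sid]
        weights = np.ones(n_genes)
        for set_name, factor in config.enrichment_factors.get(subtype, {}).items():
            weights[membership[set_name]] *= factor
        weights /= weights.sum()
        # burden_mean counts non-silent mutations; scale to the total so the
        # class multinomial keeps the non-silent expectation on target.
        if config.burden_mean <= 0:
            continue
        r = config.burden_dispersion
        mean_total = config.burden_mean / max(nonsilent_frac, 1e-12)
        total = rng.negative_binomial(r, r / (r + mean_total))
        if total == 0:
            continue
        gene_counts = rng.multinomial(total, weights)
        hit = np.nonzero(gene_counts)[0]
        gene_col = np.repeat(genes[hit], gene_counts[hit])
        m = gene_col.size
        class_col = np.asarray(classes)[rng.choice(len(classes), size=m, p=class_p)]
        comp = rng.choice(
            len(config.vaf_cluster_weights), size=m, p=config.vaf_cluster_weights
        )
        means = np.asarray(config.vaf_cluster_means)[comp]
        a = means * config.vaf_concentration
        b = (1 - means) * config.vaf_concentration
        vafs = rng.beta(a, b)
        depth = rng.poisson(config.mean_depth, size=m) + 1
        alt = rng.binomial(depth, vafs)
        frames.append(
            pd.DataFrame(
                {
                    "sample": sid,
                    "gene": gene_col,
                    "variant_class": class_col,
                    "ref_count": depth - alt,
                    "alt_count": alt,
                }
            )
        )
    if frames:
        table = MutationTable(pd.concat(frames, ignore_index=True))
    else:
        table = MutationTable(
            pd.DataFrame(columns=["sample", "gene", "variant_class",
                                  "ref_count", "alt_count"])
        )
    truth = {
        "enrichment_factors": config.enrichment_factors,
        "labels": subtype_labels,
    }
    return table, truth


def simulate_tile_features(
    config: CohortSimConfig, group_sizes: dict[str, int] | None = None
) -> tuple[TileFeatureTable, dict]:
    """Tile-feature table with planted group-discriminative features.

    One slide per patient; each group's planted features are shifted upward
    by ``planted_feature_shift`` in that group's tiles, all other features
    are exchangeable noise.  ``background_over_fraction`` of tiles draw a
    background fraction above 0.20 (the QC threshold), the rest below.
    Planted feature sets are disjoint across groups by construction.
    """
    rng = config.rng("tiles")
    if group_sizes is None:
        base, extra = divmod(config.n_slides, len(SUBTYPES))
        group_sizes = {
            name: base + (1 if i < extra else 0)
            for i, name in enumerate(SUBTYPES)
        }
    groups = list(group_sizes)
    n_planted_total = config.n_planted_features_per_group * len(groups)
    if n_planted_total > config.n_tile_features:
        raise ValueError("planted features exceed n_tile_features")
    feature_names = [f"F{i + 1:04d}" for i in range(config.n_tile_features)]
    planted = {}
    for i, g in enumerate(groups):
        lo = i * config.n_planted_features_per_group
        planted[g] = feature_names[lo: lo + config.n_planted_features_per_group]

    metas, blocks = [], []
    slide_no = 0
    for g in groups:
        for _ in range(group_sizes[g]):
            slide_no += 1
            slide = f"SL{slide_no:03d}"
            patient = f"P{slide_no:03d}"
            nt = config.tiles_per_slide_raw
            feats = rng.normal(0.0, config.tile_noise_sd,
                               size=(nt, config.n_tile_features))
            cols = [feature_names.index(f) for f in planted[g]]
            feats[:, cols] += config.planted_feature_shift
            over = rng.random(nt) < config.background_over_fraction
            bf = np.where(
                over,
                rng.uniform(0.2, 1.0, size=nt),
                rng.uniform(0.0, 0.2, size=nt),
            )
            metas.append(
                pd.DataFrame(
                    {
                        "tile_id": [f"{slide}_T{j + 1:03d}" for j in range(nt)],
                        "slide_id": slide,
                        "patient_id": patient,
                        "group": g,
                        "background_fraction": bf,
                    }
                )
            )
            blocks.append(feats)
    meta = pd.concat(metas, ignore_index=True)
    features = pd.DataFrame(np.vstack(blocks), columns=feature_names)
    table = TileFeatureTable(meta, features)
    return table, {"planted_features": planted, "group_sizes": group_sizes}


def simulate_survival(
    config: CohortSimConfig,
    subtype_labels: pd.Series,
    ith_values: pd.Series | None = None,
) -> SampleSheet:
    """Exponential survival with log-hazard = beta_subtype + beta_ith * ITH,
    under independent exponential censoring."""
    rng = config.rng("survival")
    samples = list(subtype_labels.index)
    if ith_values is None:
        ith_values = pd.Series(0.0, index=samples)
    missing = set(samples) - set(ith_values.index)
    if missing:
        raise ValueError(f"ith_values missing for samples {sorted(missing)[:5]}")
    log_h = np.asarray(
        [
            config.subtype_log_hazard.get(subtype_labels.loc[s], 0.0)
            + config.ith_log_hazard * ith_values.loc[s]
            for s in samples
        ]
    )
    hazard = config.baseline_hazard * np.exp(log_h)
    event_time = rng.exponential(1.0 / hazard)
    if config.censoring_rate > 0:
        censor_time = rng.exponential(1.0 / config.censoring_rate, size=len(samples))
    else:
        censor_time = np.full(len(samples), np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    frame = pd.DataFrame(
        {
            "subtype": subtype_labels.loc[samples].to_numpy(),
            "time": time,
            "event": event,
            "ith": ith_values.loc[samples].to_numpy(),
        },
        index=pd.Index(samples, name="sample"),
    )
    return SampleSheet(frame)


def _default_hallmark_like_sets(n_sets: int = 10, genes_per_set: int = 50) -> GeneSetCollection:
    """Deterministic named gene sets standing in for a hallmark collection."""
    coll = GeneSetCollection()
    from .io import GeneSet

    for i in range(n_sets):
        genes = frozenset(
            f"PW{i + 1:02d}_{j + 1:03d}" for j in range(genes_per_set)
        )
        coll.add(GeneSet(f"PATHWAY_{i + 1:02d}", "synthetic pathway", genes))
    return coll


def simulate_cohort(
    config: CohortSimConfig,
    out_dir: str | Path | None = None,
    gene_sets: GeneSetCollection | None = None,
    signatures: GeneSetCollection | None = None,
) -> dict:
    """Generate the full labelled cohort; optionally write all tables.

    Returns a dict with the data objects and a ``truth`` sub-dict.  When
    ``out_dir`` is given, writes every table in its TSV format plus
    ``truth.json`` and ``manifest.json`` (seed and config hash).
    """
    from .ith import ith_index
    from . import resources

    if gene_sets is None:
        gene_sets = _default_hallmark_like_sets()
    if signatures is None:
        signatures = resources.danaher_signatures()

    expr, expr_truth = simulate_expression(config)
    immune_expr, immune_truth = simulate_immune(config, signatures)
    muts, mut_truth = simulate_mutations(config, gene_sets, expr_truth["labels"])
    tiles, tile_truth = simulate_tile_features(config)
    ith = ith_index(muts, on_empty="zero")
    ith = ith.reindex(expr_truth["labels"].index).fillna(0.0)
    sheet = simulate_survival(config, expr_truth["labels"], ith)
    sheet.frame["purity"] = immune_truth["purity"].reindex(sheet.frame.index)

    result = {
        "expression": expr,
        "immune_expression": immune_expr,
        "mutations": muts,
        "tiles": tiles,
        "sample_sheet": sheet,
        "gene_sets": gene_sets,
        "signatures": signatures,
        "truth": {
            "labels": expr_truth["labels"],
            "markers": expr_truth["markers"],
            "immune_fractions": immune_truth["fractions"],
            "purity": immune_truth["purity"],
            "enrichment_factors": mut_truth["enrichment_factors"],
            "planted_features": tile_truth["planted_features"],
            "ith": ith,
        },
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_expression(expr, out / "expression.tsv")
        write_expression(immune_expr, out / "immune_expression.tsv")
        write_mutations(muts, out / "mutations.tsv")
        write_tiles(tiles, out / "tiles.tsv")
        write_sample_sheet(sheet, out / "sample_sheet.tsv")
        write_gmt(gene_sets, out / "gene_sets.gmt")
        write_gmt(signatures, out / "signatures.gmt")
        truth_json = {
            "labels": result["truth"]["labels"].to_dict(),
            "markers": result["truth"]["markers"],
            "purity": result["truth"]["purity"].round(6).to_dict(),
            "enrichment_factors": result["truth"]["enrichment_factors"],
            "planted_features": result["truth"]["planted_features"],
            "ith": result["truth"]["ith"].round(6).to_dict(),
        }
        (out / "truth.json").write_text(json.dumps(truth_json, indent=1))
        cfg = asdict(config)
        manifest = {
            "seed": config.seed,
            "config": cfg,
            "config_sha256": hashlib.sha256(
                json.dumps(cfg, sort_keys=True, default=str).encode()
            ).hexdigest(),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return result
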