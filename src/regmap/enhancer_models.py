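"""Per-domain linear models of enhancer activity over open chromatin.

Candidate enhancers ("open regions") are non-overlapping 500 bp windows in
the top accessibility fraction of at least one developmental stage.  Each
open region is tentatively assigned the expression domains of its two
nearest genes.  For a domain D, a linear model

    y^r = sum_m alpha_m * Z_m^r * S_m^D * E_m^D * R_m^D
        + sum_s gamma_s * A_s^r + beta

predicts whether region r drives expression in D, where Z is the region's
multi-species motif score, S the TF-domain association strength, E the
TF-expression indicator, R the TF's FPKM at D's stage, and A the region's
per-stage accessibility.  Models are trained by ridge-regularized least
squares on noisy training sets assembled from gene proximity and
accessibility, evaluated on left-out data and on reference enhancers
(RFVO), gated, and applied genome-wide.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge, RidgeCV

from regmap.associations import AssociationResult, ExpressionAtlas, GeneModel
from regmap.binding_eval import roc_auc
from regmap.core_tracks import AccessibilityMask, WindowTrack

logger = logging.getLogger(__name__)

__all__ = [
    "OpenRegion",
    "EnhancerModel",
    "ReferenceEnhancer",
    "TFRecord",
    "TrainingSets",
    "EnhancerEvaluation",
    "InsufficientTrainingData",
    "build_open_regions",
    "assign_candidate_domains",
    "build_training_sets",
    "featurize",
    "featurize_regions",
    "train_enhancer_model",
    "score_regions",
    "evaluate_enhancer_model",
    "good_model_gate",
    "annotate_genome_wide",
    "rank_statistic",
    "score_percentiles",
    "write_model",
    "read_model",
]


class InsufficientTrainingData(ValueError):
    """Domain skipped: too few positive or negative training examples."""


@dataclass
class ReferenceEnhancer:
    """Benchmark enhancer interval with its annotated expression domains."""

    chrom: str
    start: int
    end: int
    domains: frozenset[str]

    def __post_init__(self):
        self.domains = frozenset(self.domains)
        if not self.domains:
            raise ValueError("reference enhancer needs at least one domain")


@dataclass
class TFRecord:
    """TF with its motif and per-stage expression level (FPKM)."""

    tf_id: str
    motif_id: str
    fpkm: dict[str, float]

    def __post_init__(self):
        for stage, v in self.fpkm.items():
            if not (np.isfinite(v) and v >= 0):
                raise ValueError(f"bad FPKM for {self.tf_id} at {stage}")


@dataclass
class OpenRegion:
    """A candidate-enhancer window with accessibility and gene context."""

    window_idx: int
    chrom: str
    start: int
    end: int
    accessibility: np.ndarray  # aligned with the stage list
    accessible_stages: frozenset[str]
    neighbors: list[tuple[str, int]] = field(default_factory=list)  # (gene, signed bp)
    candidate_domains: frozenset[str] = frozenset()
    overlaps_reference: bool = False
    ref_domains: frozenset[str] = frozenset()


@dataclass
class EnhancerModel:
    """Trained per-domain linear model: motif coefficients + stage + intercept."""

    domain: str
    motif_ids: list[str]
    stages: list[str]
    alpha: np.ndarray  # per motif
    gamma: np.ndarray  # per stage
    beta: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=np.float64)
        self.gamma = np.asarray(self.gamma, dtype=np.float64)
        if self.alpha.shape != (len(self.motif_ids),):
            raise ValueError("one alpha per motif required")
        if self.gamma.shape != (len(self.stages),):
            raise ValueError("one gamma per stage required")
        if not (
            np.all(np.isfinite(self.alpha))
            and np.all(np.isfinite(self.gamma))
            and math.isfinite(self.beta)
        ):
            raise ValueError("non-finite model coefficients")

    @property
    def coef(self) -> np.ndarray:
        return np.concatenate([self.alpha, self.gamma])


@dataclass
class TrainingSets:
    """Noisy positive/negative open-region examples with a 75/25 split."""

    domain: str
    pos_train: list[OpenRegion]
    pos_test: list[OpenRegion]
    neg_train: list[OpenRegion]
    neg_test: list[OpenRegion]
    seed: int


@dataclass
class EnhancerEvaluation:
    test_auroc: float | None
    rfvo_auroc: float | None
    reason: str = ""


def _interval_overlaps(chrom, start, end, others) -> bool:
    return any(c == chrom and s < end and e > start for c, s, e in others)


def build_open_regions(
    masks: Mapping[str, AccessibilityMask],
    acc_tracks: Mapping[str, WindowTrack],
    motif_tracks: Mapping[str, WindowTrack],
    reference: Sequence[ReferenceEnhancer] | None = None,
    motif_content_percentile: float = 5.0,
    stages: Sequence[str] | None = None,
) -> list[OpenRegion]:
    """Non-overlapping accessible windows with enhancer-like motif content.

    Windows accessible in any stage are kept greedily by descending maximum
    per-stage accessibility (ties by genomic order), each kept window
    excluding later overlapping ones.  When reference enhancers are given,
    regions whose best (unmasked, multi-species) motif score falls below the
    q-th percentile of the same statistic over the reference set are dropped.
    """
    stages = list(stages) if stages is not None else list(masks)
    grid = next(iter(masks.values())).grid
    any_accessible = np.zeros(grid.n_windows, dtype=bool)
    for st in stages:
        any_accessible |= masks[st].values
    if not any_accessible.any():
        raise ValueError("no accessible windows in any stage")
    acc_matrix = np.stack([acc_tracks[st].values for st in stages])  # (S, W)
    max_acc = acc_matrix.max(axis=0)
    cand = np.flatnonzero(any_accessible)
    order = cand[np.argsort(-max_acc[cand], kind="stable")]
    starts, ends, chrom_idx = grid.starts, grid.ends, grid.chrom_index
    kept: list[int] = []
    blocked = np.zeros(grid.n_windows, dtype=bool)
    span = grid.window_length // grid.stride  # windows within overlap range
    for wi in order:
        if blocked[wi]:
            continue
        kept.append(int(wi))
        lo = max(wi - span + 1, 0)
        hi = min(wi + span, grid.n_windows)
        same = chrom_idx[lo:hi] == chrom_idx[wi]
        blocked[np.arange(lo, hi)[same]] = True
    kept.sort()

    if reference:
        motif_matrix = np.stack([t.values for t in motif_tracks.values()])
        best_motif = motif_matrix.max(axis=0)

        def interval_stat(chrom, s, e):
            # best motif score over all windows overlapping the interval,
            # measured identically for references and candidate regions
            wins = grid.overlapping_windows(chrom, s, e)
            return float(best_motif[wins].max()) if wins.size else 0.0

        ref_stats = [
            interval_stat(ref.chrom, ref.start, ref.end) for ref in reference
        ]
        threshold = float(np.percentile(ref_stats, motif_content_percentile))
        kept = [
            wi
            for wi in kept
            if interval_stat(
                grid.chroms[chrom_idx[wi]],
                int(starts[wi]),
                int(ends[wi]),
            )
            >= threshold
        ]

    ref_list = list(reference) if reference else []
    regions = []
    for wi in kept:
        chrom = grid.chroms[chrom_idx[wi]]
        s, e = int(starts[wi]), int(ends[wi])
        overlapping = [
            r for r in ref_list if r.chrom == chrom and r.start < e and r.end > s
        ]
        regions.append(
            OpenRegion(
                window_idx=wi,
                chrom=chrom,
                start=s,
                end=e,
                accessibility=acc_matrix[:, wi].copy(),
                accessible_stages=frozenset(
                    st for st in stages if masks[st].values[wi]
                ),
                overlaps_reference=bool(overlapping),
                ref_domains=frozenset().union(
                    *[r.domains for r in overlapping]
                ) if overlapping else frozenset(),
            )
        )
    return regions


def assign_candidate_domains(
    regions: Sequence[OpenRegion],
    genes: Sequence[GeneModel],
    atlas: ExpressionAtlas,
) -> list[OpenRegion]:
    """Attach the two nearest genes and their domains; drop unannotated regions.

    Distance is to the gene span (0 when overlapping; ties by gene id);
    candidate domains are the union of the neighbors' atlas annotations.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    out = []
    for region in regions:
        chrom_genes = by_chrom.get(region.chrom, [])
        if not chrom_genes:
            logger.warning(
                "region %s:%d-%d on chromosome without genes; discarded",
                region.chrom,
                region.start,
                region.end,
            )
            continue

        def distance(g: GeneModel) -> int:
            if g.start < region.end and g.end > region.start:
                return 0
            if g.start >= region.end:
                return g.start - region.end + 1
            return region.start - g.end + 1

        ranked = sorted(chrom_genes, key=lambda g: (distance(g), g.gene_id))
        nearest = ranked[:2]
        neighbors = []
        for g in nearest:
            d = distance(g)
            signed = 0 if d == 0 else (d if g.start >= region.end else -d)
            neighbors.append((g.gene_id, signed))
        domains = frozenset().union(
            *[atlas.gene_domains.get(g.gene_id, frozenset()) for g in nearest]
        )
        if not domains:
            continue
        region.neighbors = neighbors
        region.candidate_domains = domains
        out.append(region)
    return out


def build_training_sets(
    domain: str,
    regions: Sequence[OpenRegion],
    atlas: ExpressionAtlas,
    stage_of_domain: str,
    seed: int = 0,
    max_positives: int = 500,
    min_examples: int = 10,
    proximity_bp: int = 5000,
    train_fraction: float = 0.75,
) -> TrainingSets:
    """Assemble noisy positive/negative sets for one domain and split 75/25.

    Positives: regions with a neighbor gene annotated with the domain within
    ``proximity_bp``, accessible in the domain's stage, not overlapping any
    reference enhancer (capped by seeded subsampling).  Negatives: an equal
    count of accessible regions with no domain-annotated neighbor, sampled
    uniformly with the same seed stream.
    """
    rng = np.random.default_rng(seed)
    pos, neg = [], []
    for region in regions:
        if stage_of_domain not in region.accessible_stages:
            continue
        if region.overlaps_reference:
            continue
        annotated = [
            (g, d)
            for g, d in region.neighbors
            if domain in atlas.gene_domains.get(g, frozenset())
        ]
        if any(abs(d) <= proximity_bp for _, d in annotated):
            pos.append(region)
        elif not annotated:
            neg.append(region)
    if len(pos) > max_positives:
        idx = rng.choice(len(pos), size=max_positives, replace=False)
        pos = [pos[i] for i in np.sort(idx)]
    if len(pos) < min_examples or len(neg) < min_examples:
        raise InsufficientTrainingData(
            f"domain {domain!r}: {len(pos)} positives, {len(neg)} negatives "
            f"(need >= {min_examples} of each)"
        )
    # class-balanced: subsample the larger side to the smaller count
    if len(neg) >= len(pos):
        idx = rng.choice(len(neg), size=len(pos), replace=False)
        neg = [neg[i] for i in np.sort(idx)]
    else:
        idx = rng.choice(len(pos), size=len(neg), replace=False)
        pos = [pos[i] for i in np.sort(idx)]

    def split(items: list[OpenRegion]):
        perm = rng.permutation(len(items))
        n_train = int(train_fraction * len(items))
        return (
            [items[i] for i in perm[:n_train]],
            [items[i] for i in perm[n_train:]],
        )

    pos_train, pos_test = split(pos)
    neg_train, neg_test = split(neg)
    return TrainingSets(
        domain=domain,
        pos_train=pos_train,
        pos_test=pos_test,
        neg_train=neg_train,
        neg_test=neg_test,
        seed=seed,
    )


def featurize_regions(
    regions: Sequence[OpenRegion],
    domain: str,
    motif_tracks: Mapping[str, WindowTrack],
    assoc: Mapping[tuple[str, str], AssociationResult],
    supports: Mapping[tuple[str, str], str],
    tf_records: Sequence[TFRecord],
    stage_of_domain: str,
    expressed_categories: frozenset[str] = frozenset(
        {"specific", "related", "ubiquitous"}
    ),
) -> np.ndarray:
    """Feature matrix (n_regions x (n_motifs + n_stages)) for domain D.

    Motif feature: Z_m^r * S_m^D * E_m^D * R_m^D with S the capped -log10 p
    of the TF-domain association (0 when untested), E in {0,1} from the
    support label, and R the TF's FPKM at D's stage.  Stage features are the
    region's accessibility vector.
    """
    n_stage = regions[0].accessibility.size if regions else 0
    X = np.zeros((len(regions), len(tf_records) + n_stage))
    widx = np.array([r.window_idx for r in regions], dtype=np.int64)
    for mi, rec in enumerate(tf_records):
        if rec.motif_id not in motif_tracks:
            raise KeyError(f"unknown motif id {rec.motif_id!r}")
        res = assoc.get((rec.tf_id, domain))
        S = res.S if res is not None else 0.0
        support = supports.get((rec.tf_id, domain), "none")
        E = 1.0 if support in expressed_categories else 0.0
        R = rec.fpkm.get(stage_of_domain, 0.0)
        if S == 0.0 or E == 0.0 or R == 0.0:
            continue
        Z = motif_tracks[rec.motif_id].values[widx]
        X[:, mi] = Z * S * E * R
    for ri, region in enumerate(regions):
        X[ri, len(tf_records) :] = region.accessibility
    return X


def featurize(
    region: OpenRegion,
    domain: str,
    motif_tracks: Mapping[str, WindowTrack],
    assoc: Mapping[tuple[str, str], AssociationResult],
    supports: Mapping[tuple[str, str], str],
    tf_records: Sequence[TFRecord],
    stage_of_domain: str,
) -> np.ndarray:
    return featurize_regions(
        [region], domain, motif_tracks, assoc, supports, tf_records, stage_of_domain
    )[0]


def train_enhancer_model(
    X: np.ndarray,
    y: np.ndarray,
    motif_ids: Sequence[str],
    stages: Sequence[str],
    domain: str = "",
    ridge_lambda: float | None = 1e-6,
    metadata: dict | None = None,
) -> EnhancerModel:
    """Ridge-regularized least squares of {0,1} labels on raw features.

    ``ridge_lambda=None`` selects the penalty by efficient leave-one-out
    cross-validation over a log-spaced grid, which matters when the number
    of training examples is small relative to the number of motif features.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite features")
    if np.unique(y).size < 2:
        raise ValueError("training labels are single-class")
    if X.shape[0] <= 2:
        raise ValueError("need more than 2 examples")
    if ridge_lambda is None:
        model = RidgeCV(alphas=np.logspace(-6, 8, 29), fit_intercept=True)
        model.fit(X, y)
        ridge_lambda = float(model.alpha_)
    else:
        model = Ridge(alpha=ridge_lambda, fit_intercept=True)
        model.fit(X, y)
    n_motif = len(motif_ids)
    meta = {"ridge_lambda": ridge_lambda, "n_train": int(X.shape[0])}
    meta.update(metadata or {})
    return EnhancerModel(
        domain=domain,
        motif_ids=list(motif_ids),
        stages=list(stages),
        alpha=model.coef_[:n_motif],
        gamma=model.coef_[n_motif:],
        beta=float(model.intercept_),
        metadata=meta,
    )


def score_regions(model: EnhancerModel, X: np.ndarray) -> np.ndarray:
    """Linear model evaluation y = X @ [alpha, gamma] + beta."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != model.coef.size:
        raise ValueError(
            f"feature dimension {X.shape} does not match model "
            f"({model.coef.size} coefficients)"
        )
    return X @ model.coef + model.beta


def evaluate_enhancer_model(
    model: EnhancerModel,
    training: TrainingSets,
    regions: Sequence[OpenRegion],
    features: Callable[[Sequence[OpenRegion]], np.ndarray],
    domain: str,
    min_rfvo_positives: int = 10,
) -> EnhancerEvaluation:
    """Left-out test AUROC plus, when possible, the RFVO AUROC.

    RFVO uses regions overlapping reference enhancers annotated with the
    domain as positives, and regions with neither reference overlap nor a
    domain-annotated neighbor as negatives; it is reported only when at
    least ``min_rfvo_positives`` positives exist.
    """
    reasons = []
    test_regions = training.pos_test + training.neg_test
    if training.pos_test and training.neg_test:
        y = np.array(
            [1] * len(training.pos_test) + [0] * len(training.neg_test), dtype=bool
        )
        scores = score_regions(model, features(test_regions))
        test_auroc, _ = roc_auc(scores, y)
    else:
        test_auroc = None
        reasons.append("left-out test set degenerate")

    rfvo_pos = [r for r in regions if domain in r.ref_domains]
    # negatives: no reference overlap and no neighbor annotated with domain
    rfvo_neg = [
        r
        for r in regions
        if not r.overlaps_reference and domain not in r.candidate_domains
    ]
    # eligibility: enough reference-overlapping regions annotated with the
    # domain (the region's tentative domain assignment)
    n_annotated = sum(
        1
        for r in regions
        if r.overlaps_reference and domain in r.candidate_domains
    )
    if n_annotated < min_rfvo_positives or not rfvo_pos:
        rfvo_auroc = None
        reasons.append(
            f"only {n_annotated} reference-overlapping regions annotated "
            f"with {domain!r} ({len(rfvo_pos)} reference-positive)"
        )
    elif not rfvo_neg:
        rfvo_auroc = None
        reasons.append("no eligible RFVO negatives")
    else:
        both = rfvo_pos + rfvo_neg
        y = np.array([1] * len(rfvo_pos) + [0] * len(rfvo_neg), dtype=bool)
        scores = score_regions(model, features(both))
        rfvo_auroc, _ = roc_auc(scores, y)
    return EnhancerEvaluation(
        test_auroc=test_auroc, rfvo_auroc=rfvo_auroc, reason="; ".join(reasons)
    )


def good_model_gate(
    test_auroc: float | None, rfvo_auroc: float | None
) -> bool:
    """'Good' model rule: RFVO AUROC > 0.7 or left-out test AUROC > 0.6."""
    if test_auroc is None and rfvo_auroc is None:
        raise ValueError("at least one metric must be present")
    if rfvo_auroc is not None and rfvo_auroc > 0.7:
        return True
    return test_auroc is not None and test_auroc > 0.6


def score_percentiles(scores: np.ndarray) -> np.ndarray:
    """Inclusive percentile (0-100] of each score within its distribution."""
    from scipy.stats import rankdata

    return 100.0 * rankdata(scores, method="max") / scores.size


def annotate_genome_wide(
    domain_scores: Mapping[str, np.ndarray],
    regions: Sequence[OpenRegion],
    atlas: ExpressionAtlas,
    top_percent: float = 5.0,
) -> pd.DataFrame:
    """Assign domains to open regions via gated models.

    A region is assigned domain D when a neighbor gene is annotated with D
    and its model-D score reaches the top ``top_percent`` of scores over all
    open regions (inclusive threshold).  One region may receive several
    domains.
    """
    rows = []
    for domain, scores in domain_scores.items():
        scores = np.asarray(scores, dtype=np.float64)
        if scores.size != len(regions):
            raise ValueError("scores must cover every open region")
        threshold = float(np.percentile(scores, 100.0 - top_percent))
        pct = score_percentiles(scores)
        for ri, region in enumerate(regions):
            if scores[ri] < threshold:
                continue
            neighbor_domains = frozenset().union(
                *[
                    atlas.gene_domains.get(g, frozenset())
                    for g, _ in region.neighbors
                ]
            ) if region.neighbors else frozenset()
            if domain not in neighbor_domains:
                continue
            rows.append(
                (
                    region.chrom,
                    region.start,
                    region.end,
                    region.window_idx,
                    domain,
                    float(scores[ri]),
                    float(pct[ri]),
                )
            )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "window_idx", "domain", "score", "percentile"],
    )


def rank_statistic(
    candidate_percentiles: Mapping[str, float], true_domain: str
) -> float | None:
    """Normalized rank of the true domain among a region's candidates.

    Candidates are ranked by model-score percentile, descending (ties broken
    by domain id for determinism).  Returns 1 when the true domain ranks
    first (or is the only candidate), 0 when it ranks last, and None when
    the true domain is not among the candidates.
    """
    if true_domain not in candidate_percentiles:
        return None
    k = len(candidate_percentiles)
    if k == 1:
        return 1.0
    ranked = sorted(candidate_percentiles.items(), key=lambda kv: (-kv[1], kv[0]))
    rank = next(i for i, (d, _) in enumerate(ranked, start=1) if d == true_domain)
    return (k - rank) / (k - 1)


# ---------------------------------------------------------------------------
# model serialization


def write_model(model: EnhancerModel, tsv_path, json_path) -> None:
    terms = (
        [("beta", model.beta)]
        + list(zip(model.motif_ids, model.alpha))
        + list(zip([f"stage:{s}" for s in model.stages], model.gamma))
    )
    pd.DataFrame(terms, columns=["term", "coefficient"]).to_csv(
        tsv_path, sep="\t", index=False
    )
    with open(json_path, "w") as fh:
        json.dump(
            {
                "domain": model.domain,
                "motif_ids": model.motif_ids,
                "stages": model.stages,
                "metadata": model.metadata,
            },
            fh,
            indent=2,
        )


def read_model(tsv_path, json_path) -> EnhancerModel:
    terms = pd.read_csv(tsv_path, sep="\t")
    with open(json_path) as fh:
        meta = json.load(fh)
    coefs = dict(zip(terms["term"], terms["coefficient"]))
    return EnhancerModel(
        domain=meta["domain"],
        motif_ids=meta["motif_ids"],
        stages=meta["stages"],
        alpha=np.array([coefs[m] for m in meta["motif_ids"]]),
        gamma=np.array([coefs[f"stage:{s}"] for s in meta["stages"]]),
        beta=float(coefs["beta"]),
        metadata=meta.get("metadata", {}),
    )
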