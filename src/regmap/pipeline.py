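"""End-to-end orchestration: from input bundle to regulatory map.

Runs the full chain on a :class:`~regmap.synthetic_data.WorldBundle` (or any
equivalently shaped inputs): multi-species motif scoring, accessibility
aggregation and masking, TF-domain association discovery, expression
support, enhancer-model training/evaluation/gating, genome-wide domain
assignment, and the rank statistic over reference-enhancer regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from regmap import associations as assoc_mod
from regmap import binding_eval, core_tracks, enhancer_models, motif_scoring
from regmap.associations import AssociationResult, RegulatoryRegionSet
from regmap.core_tracks import AccessibilityMask, WindowTrack
from regmap.enhancer_models import (
    EnhancerEvaluation,
    EnhancerModel,
    InsufficientTrainingData,
    OpenRegion,
    TrainingSets,
)
from regmap.synthetic_data import WorldBundle

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    """Outputs of every pipeline stage for one world."""

    motif_tracks: dict[str, WindowTrack]  # multi-species, unmasked
    motif_tracks_ref: dict[str, WindowTrack]
    acc_tracks: dict[str, WindowTrack]
    masks: dict[str, AccessibilityMask]
    chip_tracks: dict[str, WindowTrack]
    assoc_results: list[AssociationResult]
    supports: dict[tuple[str, str], str]
    open_regions: list[OpenRegion]
    training: dict[str, TrainingSets]
    models: dict[str, EnhancerModel]
    evaluations: dict[str, EnhancerEvaluation]
    gated_domains: set[str]
    domain_scores: dict[str, np.ndarray]  # genome-wide, gated domains only
    assignments: pd.DataFrame
    rank_records: list[tuple[dict, str]]  # (candidate percentiles, true domain)
    skipped_domains: dict[str, str] = field(default_factory=dict)
    chip_motif_ranks: dict[str, float] = field(default_factory=dict)


def run_pipeline(
    bundle: WorldBundle,
    seed: int = 0,
    accessible_fraction: float = 0.10,
    target_k: int | None = None,
    ridge_lambda: float | None = None,
    evaluate_chip: bool = False,
) -> PipelineResult:
    """Run every stage of the regulatory-map pipeline on one input bundle."""
    grid = bundle.grid
    stages = list(bundle.config.stages)
    cfg = bundle.config

    # --- backgrounds: reference genome plus per-species segment samples
    bg_ref = motif_scoring.train_background(
        list(bundle.genome.values()), order=1, label="ref"
    )
    bgs = {"ref": bg_ref}
    for sp in bundle.orthology.species:
        if sp == bundle.orthology.ref_species:
            continue
        present, seqs = bundle.orthology.segments[sp]
        sample = np.flatnonzero(present)[::10]
        bgs[sp] = motif_scoring.train_background(
            [motif_scoring.decode_sequence(seqs[i]) for i in sample],
            order=1,
            label=sp,
        )

    # --- motif scoring (multi-species averaged + reference-only)
    motif_tracks: dict[str, WindowTrack] = {}
    motif_tracks_ref: dict[str, WindowTrack] = {}
    for pwm in bundle.pwms:
        multi, ref = motif_scoring.score_grid_multispecies(
            bundle.genome, pwm, grid, bgs, bundle.orthology
        )
        motif_tracks[pwm.motif_id] = multi
        motif_tracks_ref[pwm.motif_id] = ref
        logger.info("scored motif %s", pwm.motif_id)

    # --- accessibility windows and masks
    acc_tracks = {
        st: core_tracks.aggregate_base_track(bundle.accessibility[st], grid)
        for st in stages
    }
    masks = {
        st: core_tracks.top_fraction_mask(acc_tracks[st], accessible_fraction, st)
        for st in stages
    }
    chip_tracks = {
        tf: core_tracks.aggregate_base_track(track, grid)
        for tf, track in bundle.chip.items()
    }

    # --- optional binding evaluation: rank of the matched motif per ChIP set
    chip_motif_ranks: dict[str, float] = {}
    if evaluate_chip:
        tf_stage = stages[0]
        n_each = min(200, grid.n_windows // 20)
        motif_list = [r.motif_id for r in bundle.tf_records]
        tracks = [
            core_tracks.apply_mask(motif_tracks[m], masks[tf_stage])
            for m in motif_list
        ]
        for ti, rec in enumerate(bundle.tf_records):
            eval_set = binding_eval.select_eval_windows(
                chip_tracks[rec.tf_id],
                masks[tf_stage],
                bundle.coding,
                n_pos=n_each,
                n_rand=n_each,
                seed=seed + ti,
            )
            _, ranks = binding_eval.cross_correlation_matrix(
                tracks, [chip_tracks[rec.tf_id]], eval_set, matched=[(ti, 0)]
            )
            chip_motif_ranks[rec.tf_id] = ranks[0]

    # --- regulatory regions and associations
    region_sets: dict[str, RegulatoryRegionSet] = {
        mode: assoc_mod.build_regulatory_regions(
            bundle.genes, mode, bundle.insulators, bundle.chrom_sizes
        )
        for mode in assoc_mod.REGION_MODES
    }
    masked: dict[tuple[str, str], WindowTrack] = {}
    for rec in bundle.tf_records:
        for st in stages:
            masked[rec.motif_id, st] = core_tracks.apply_mask(
                motif_tracks[rec.motif_id], masks[st]
            )
    results: list[AssociationResult] = []
    supports: dict[tuple[str, str], str] = {}
    for rec in bundle.tf_records:
        score_cache: dict[str, dict[str, dict[str, float]]] = {}
        for domain in bundle.atlas.domains:
            st = bundle.atlas.stage(domain)
            if st not in score_cache:
                score_cache[st] = {
                    mode: assoc_mod.gene_scores(
                        masked[rec.motif_id, st], region_sets[mode]
                    )
                    for mode in assoc_mod.REGION_MODES
                }
            res = assoc_mod.associate(
                rec.tf_id,
                domain,
                {m: masked[rec.motif_id, st] for m in assoc_mod.REGION_MODES},
                region_sets,
                bundle.atlas,
                k=target_k,
                _score_cache=score_cache[st],
            )
            support = assoc_mod.expression_support(rec.tf_id, domain, bundle.atlas)
            res.support = support
            supports[rec.tf_id, domain] = support
            results.append(res)
    assoc_map = {(r.tf, r.domain): r for r in results}

    # --- open regions and per-domain enhancer models
    regions = enhancer_models.build_open_regions(
        masks,
        acc_tracks,
        motif_tracks,
        bundle.reference_enhancers,
        stages=stages,
    )
    regions = enhancer_models.assign_candidate_domains(
        regions, bundle.genes, bundle.atlas
    )
    training: dict[str, TrainingSets] = {}
    models: dict[str, EnhancerModel] = {}
    evaluations: dict[str, EnhancerEvaluation] = {}
    gated: set[str] = set()
    skipped: dict[str, str] = {}
    domain_scores: dict[str, np.ndarray] = {}
    motif_ids = [r.motif_id for r in bundle.tf_records]
    for domain in bundle.atlas.domains:
        st = bundle.atlas.stage(domain)

        def features(regs):
            return enhancer_models.featurize_regions(
                regs,
                domain,
                motif_tracks,
                assoc_map,
                supports,
                bundle.tf_records,
                st,
            )

        try:
            tsets = enhancer_models.build_training_sets(
                domain, regions, bundle.atlas, st, seed=seed
            )
        except InsufficientTrainingData as exc:
            skipped[domain] = str(exc)
            logger.info("skipping %s: %s", domain, exc)
            continue
        training[domain] = tsets
        train_regions = tsets.pos_train + tsets.neg_train
        y = np.array(
            [1.0] * len(tsets.pos_train) + [0.0] * len(tsets.neg_train)
        )
        model = enhancer_models.train_enhancer_model(
            features(train_regions),
            y,
            motif_ids,
            stages,
            domain=domain,
            ridge_lambda=ridge_lambda,
            metadata={"seed": seed},
        )
        models[domain] = model
        ev = enhancer_models.evaluate_enhancer_model(
            model, tsets, regions, features, domain
        )
        evaluations[domain] = ev
        if enhancer_models.good_model_gate(ev.test_auroc, ev.rfvo_auroc):
            gated.add(domain)
            domain_scores[domain] = enhancer_models.score_regions(
                model, features(regions)
            )

    assignments = enhancer_models.annotate_genome_wide(
        domain_scores, regions, bundle.atlas
    )

    # --- rank statistic inputs for reference-overlapping regions
    percentiles = {
        d: enhancer_models.score_percentiles(s) for d, s in domain_scores.items()
    }
    rank_records: list[tuple[dict, str]] = []
    for ri, region in enumerate(regions):
        if not region.overlaps_reference:
            continue
        cand = {
            d: float(percentiles[d][ri])
            for d in region.candidate_domains
            if d in gated
        }
        if not cand:
            continue
        for true_domain in sorted(region.ref_domains):
            rank_records.append((cand, true_domain))

    return PipelineResult(
        motif_tracks=motif_tracks,
        motif_tracks_ref=motif_tracks_ref,
        acc_tracks=acc_tracks,
        masks=masks,
        chip_tracks=chip_tracks,
        assoc_results=results,
        supports=supports,
        open_regions=regions,
        training=training,
        models=models,
        evaluations=evaluations,
        gated_domains=gated,
        domain_scores=domain_scores,
        assignments=assignments,
        rank_records=rank_records,
        skipped_domains=skipped,
        chip_motif_ranks=chip_motif_ranks,
    )
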