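"""Synthetic regulatory world with planted ground truth.

Generates an internally consistent bundle -- genome, motifs, orthologous
segments, stage-specific accessibility, ChIP-like occupancy, gene models,
expression atlas, TF expression, insulators and reference enhancers -- in
which a known TF-to-domain regulatory map is planted: each expression
domain is driven by a small set of regulator TFs whose binding sites are
written into enhancers placed near the domain's target genes, and
accessibility peaks cover those enhancers in the domain's stage.  Every
pipeline stage can therefore be evaluated against known truth without any
external data.

The world emulates the statistical structure of embryonic regulatory data
(top-decile accessibility masks, hypergeometric gene-set regimes, noisy
occupancy, partially conserved orthologs); it makes no attempt to imitate
real sequence composition or phylogeny.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from regmap import core_tracks, motif_scoring
from regmap.associations import ExpressionAtlas, GeneModel, read_atlas, read_genes_tsv, write_genes_tsv
from regmap.core_tracks import BaseTrack, WindowGrid, tile_genome
from regmap.enhancer_models import ReferenceEnhancer, TFRecord
from regmap.motif_scoring import PWM, OrthologyMap, encode_sequence, decode_sequence

logger = logging.getLogger(__name__)

__all__ = [
    "WorldConfig",
    "GroundTruth",
    "WorldBundle",
    "PlantedSite",
    "PlantedEnhancer",
    "simulate_world",
    "write_bundle",
    "read_bundle",
    "recovery_report",
]


@dataclass(frozen=True)
class WorldConfig:
    """Knobs of the synthetic world; defaults define the standard conditions."""

    seed: int = 0
    chrom_lengths: tuple[int, ...] = (300_000, 300_000)
    n_tfs: int = 20
    motif_width_range: tuple[int, int] = (6, 10)
    n_genes: int = 120
    n_domains: int = 12
    stages: tuple[str, ...] = ("s05", "s09", "s11", "s14")
    tf_domain_density: float = 0.02
    enhancers_per_domain: int = 8
    sites_per_enhancer: int = 4
    acc_peak_height: float = 8.0
    acc_peak_sd: float = 200.0
    acc_noise: float = 1.0
    chip_peak_height: float = 5.0
    chip_peak_sd: float = 200.0
    chip_noise: float = 0.5
    n_ortholog_species: int = 3
    mutation_rate: float = 0.15
    site_preservation: float = 0.8
    reference_fraction: float = 0.3
    gc_content: float = 0.5
    extra_annotation_rate: float = 1.2
    extra_enhancer_fraction: float = 0.85  # extra annotations backed by an enhancer
    decoy_sites_per_kb: float = 8.0  # spurious motif matches outside enhancers
    decoy_open_fraction: float = 0.1  # decoy clusters with a DNase-like peak
    window_length: int = 500
    stride: int = 50
    signal_bin: int = 10  # bp resolution of generated bedGraph tracks

    def __post_init__(self):
        counts = (
            self.n_tfs,
            self.n_genes,
            self.n_domains,
            self.enhancers_per_domain,
            self.sites_per_enhancer,
            self.n_ortholog_species,
        )
        if any(c <= 0 for c in counts) or any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("all counts and lengths must be positive")
        rates = (
            self.tf_domain_density,
            self.mutation_rate,
            self.site_preservation,
            self.reference_fraction,
            self.gc_content,
        )
        if any(not 0 <= r <= 1 for r in rates):
            raise ValueError("rates must lie in [0, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "WorldConfig":
        d = dict(d)
        for key in ("chrom_lengths", "motif_width_range", "stages"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class PlantedSite:
    tf: str
    chrom: str
    start: int
    end: int
    strand: str


@dataclass
class PlantedEnhancer:
    chrom: str
    start: int
    end: int
    domain: str
    target_gene: str
    sites: list[PlantedSite]


@dataclass
class GroundTruth:
    """What was planted: the regulatory map, enhancers, true annotations."""

    tf_domain_pairs: set[tuple[str, str]]
    enhancers: list[PlantedEnhancer]
    gene_true_domains: dict[str, set[str]]

    def __post_init__(self):
        for enh in self.enhancers:
            if enh.domain not in self.gene_true_domains.get(enh.target_gene, set()):
                raise ValueError(
                    "planted enhancer domain missing from target gene annotations"
                )


@dataclass
class WorldBundle:
    """All pipeline inputs for one synthetic world."""

    config: WorldConfig
    genome: dict[str, str]
    chrom_sizes: dict[str, int]
    grid: WindowGrid
    pwms: list[PWM]
    tf_records: list[TFRecord]
    genes: list[GeneModel]
    atlas: ExpressionAtlas
    accessibility: dict[str, BaseTrack]
    chip: dict[str, BaseTrack]
    insulators: list[tuple[str, int, int]]
    coding: list[tuple[str, int, int]]
    reference_enhancers: list[ReferenceEnhancer]
    orthology: OrthologyMap


def _sample_pwm(rng: np.random.Generator, width: int, motif_id: str) -> PWM:
    """Random PWM with one dominant base per column."""
    probs = np.empty((4, width))
    for j in range(width):
        dom = rng.integers(0, 4)
        p_dom = rng.uniform(0.92, 0.99)
        probs[:, j] = (1.0 - p_dom) / 3.0
        probs[dom, j] = p_dom
    return PWM(motif_id=motif_id, probs=probs)


def _sample_site(rng: np.random.Generator, pwm: PWM) -> np.ndarray:
    cum = np.cumsum(pwm.probs, axis=0)
    u = rng.random(pwm.width)
    return (u[None, :] < cum).argmax(axis=0).astype(np.int8)


def _bump_profile(nbins, bin_size, centers, height, sd):
    x = (np.arange(nbins) + 0.5) * bin_size
    out = np.zeros(nbins)
    for c in centers:
        lo = max(0, int((c - 4 * sd) // bin_size))
        hi = min(nbins, int((c + 4 * sd) // bin_size) + 1)
        out[lo:hi] += height * np.exp(-((x[lo:hi] - c) ** 2) / (2 * sd**2))
    return out


def simulate_world(config: WorldConfig) -> tuple[WorldBundle, GroundTruth]:
    """Generate one synthetic world; deterministic given the config seed."""
    rng = np.random.default_rng(config.seed)
    chroms = [f"chr{i + 1}" for i in range(len(config.chrom_lengths))]
    chrom_sizes = dict(zip(chroms, config.chrom_lengths))
    gc = config.gc_content
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    genome_codes = {
        c: rng.choice(4, size=L, p=base_p).astype(np.int8)
        for c, L in chrom_sizes.items()
    }

    # --- TFs and motifs
    wmin, wmax = config.motif_width_range
    tf_ids = [f"TF{t:02d}" for t in range(config.n_tfs)]
    motif_ids = [f"M{t:02d}" for t in range(config.n_tfs)]
    pwms = [
        _sample_pwm(rng, int(rng.integers(wmin, wmax + 1)), motif_ids[t])
        for t in range(config.n_tfs)
    ]

    # --- genes: TF genes first, interleaved across chromosomes
    gene_ids = tf_ids + [f"g{i:03d}" for i in range(config.n_tfs, config.n_genes)]
    genes: list[GeneModel] = []
    n_chrom = len(chroms)
    per_chrom = [
        config.n_genes // n_chrom + (1 if i < config.n_genes % n_chrom else 0)
        for i in range(n_chrom)
    ]
    # TSS positions are jittered around a regular spacing and strands drawn
    # at random so neighboring genes do not share identical upstream regions
    gi = 0
    for ci, chrom in enumerate(chroms):
        spacing = chrom_sizes[chrom] // per_chrom[ci]
        for k in range(per_chrom[ci]):
            jitter = int(rng.integers(-spacing // 4, spacing // 4 + 1))
            tss = spacing // 2 + k * spacing + jitter
            tss = int(np.clip(tss, 1600, chrom_sizes[chrom] - 1600))
            strand = "+" if rng.random() < 0.5 else "-"
            span_len = 1500
            if strand == "+":
                start, end = tss, min(tss + span_len, chrom_sizes[chrom])
            else:
                start, end = max(tss - span_len, 0), tss + 1
            genes.append(
                GeneModel(
                    gene_id=gene_ids[gi],
                    chrom=chrom,
                    strand=strand,
                    tss=tss,
                    start=start,
                    end=end,
                )
            )
            gi += 1
    gene_by_id = {g.gene_id: g for g in genes}

    # --- planted TF -> domain map
    domain_ids = [f"D{i:02d}" for i in range(config.n_domains)]
    domain_stage = {
        d: config.stages[i % len(config.stages)] for i, d in enumerate(domain_ids)
    }
    regulators: dict[str, list[str]] = {}
    for d in domain_ids:
        regs = [tf for tf in tf_ids if rng.random() < config.tf_domain_density]
        if not regs and config.tf_domain_density > 0:
            regs = [tf_ids[int(rng.integers(config.n_tfs))]]
        regulators[d] = regs
    tf_domain_pairs = {(tf, d) for d, regs in regulators.items() for tf in regs}

    # --- enhancers planted near target genes, sites written into the genome
    pwm_by_tf = dict(zip(tf_ids, pwms))
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for g in genes:
        occupied[g.chrom].append((g.start, g.end))
    enhancers: list[PlantedEnhancer] = []
    enhancer_intervals: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    enh_len = config.window_length

    # enhancers keep a margin from one another so each has its own
    # accessibility peak and candidate window after overlap resolution
    enh_margin = 400

    def plant_enhancer(g: GeneModel, d: str, required: bool = True) -> bool:
        L = chrom_sizes[g.chrom]
        placed = None
        for _ in range(200):
            offset = int(rng.integers(-5000 + enh_len // 2, 5000 - enh_len // 2))
            start = g.tss + offset - enh_len // 2
            if start < 0 or start + enh_len > L:
                continue
            if any(
                s - enh_margin < start + enh_len and e + enh_margin > start
                for s, e in enhancer_intervals[g.chrom]
            ):
                continue
            if any(s < start + enh_len and e > start for s, e in occupied[g.chrom]):
                continue
            placed = start
            break
        if placed is None:
            if not required:
                return False
            raise ValueError(
                "infeasible enhancer placement: genome too crowded for "
                f"domain {d} near gene {g.gene_id}"
            )
        occupied[g.chrom].append((placed, placed + enh_len))
        enhancer_intervals[g.chrom].append((placed, placed + enh_len))
        # non-overlapping sites from the domain's regulators; with no
        # planted regulation (density 0) sites come from random TFs
        regs = regulators[d]
        site_occ: list[tuple[int, int]] = []
        sites: list[PlantedSite] = []
        for si in range(config.sites_per_enhancer):
            tf = (
                regs[si % len(regs)]
                if regs
                else tf_ids[int(rng.integers(config.n_tfs))]
            )
            pwm = pwm_by_tf[tf]
            w = pwm.width
            for _ in range(100):
                off = int(rng.integers(0, enh_len - w + 1))
                if any(s < off + w and e > off for s, e in site_occ):
                    continue
                site_occ.append((off, off + w))
                strand = "+" if rng.random() < 0.5 else "-"
                bases = _sample_site(rng, pwm)
                if strand == "-":
                    bases = (3 - bases)[::-1]
                genome_codes[g.chrom][placed + off : placed + off + w] = bases
                sites.append(
                    PlantedSite(
                        tf=tf,
                        chrom=g.chrom,
                        start=placed + off,
                        end=placed + off + w,
                        strand=strand,
                    )
                )
                break
        enhancers.append(
            PlantedEnhancer(
                chrom=g.chrom,
                start=placed,
                end=placed + enh_len,
                domain=d,
                target_gene=g.gene_id,
                sites=sites,
            )
        )
        return True

    for d in domain_ids:
        n_e = config.enhancers_per_domain
        target_idx = rng.choice(config.n_genes, n_e, replace=n_e > config.n_genes)
        for ti in np.sort(target_idx):
            if plant_enhancer(genes[int(ti)], d, required=False):
                continue
            # neighborhood full: fall back to another gene with free space
            for _ in range(60):
                alt = int(rng.integers(config.n_genes))
                if plant_enhancer(genes[alt], d, required=False):
                    break
            else:
                raise ValueError(
                    "infeasible enhancer placement: genome too crowded for "
                    f"domain {d}"
                )

    # --- extra gene-domain annotations: atlas annotations beyond the core
    # planted targets; most reflect genuine expression and therefore carry a
    # real (unannotated-in-reference-thinking) enhancer of the domain
    targeted = {(e.target_gene, e.domain) for e in enhancers}
    domains_of_gene: dict[str, set[str]] = {}
    for e in enhancers:
        domains_of_gene.setdefault(e.target_gene, set()).add(e.domain)
    extra_pairs: list[tuple[str, str]] = []
    for g in genes:
        n_extra = rng.poisson(config.extra_annotation_rate)
        if not n_extra:
            continue
        # a gene's annotations spread across developmental stages: prefer
        # domains whose stage the gene is not yet annotated in
        current = domains_of_gene.get(g.gene_id, set())
        used_stages = {domain_stage[d] for d in current}
        order = rng.permutation(config.n_domains)
        chosen: list[str] = []
        for pass_stage_filter in (True, False):
            for i in order:
                d = domain_ids[i]
                if len(chosen) >= n_extra:
                    break
                if d in current or d in chosen:
                    continue
                if pass_stage_filter and domain_stage[d] in used_stages:
                    continue
                chosen.append(d)
                used_stages.add(domain_stage[d])
        for d in chosen:
            if (g.gene_id, d) not in targeted:
                extra_pairs.append((g.gene_id, d))
    for gid, d in extra_pairs:
        if rng.random() < config.extra_enhancer_fraction:
            plant_enhancer(gene_by_id[gid], d, required=False)

    # --- decoy clusters: homotypic site clusters scattered outside the
    # annotated enhancers, emulating real unannotated enhancers and chance
    # motif clusters; they give background open chromatin enhancer-like
    # motif content without any link to the expression atlas
    decoy_sites: list[PlantedSite] = []
    sites_per_cluster = config.sites_per_enhancer
    n_events = int(
        config.decoy_sites_per_kb
        * sum(chrom_sizes.values())
        / 1000
        / sites_per_cluster
    )
    for _ in range(n_events):
        tf = tf_ids[int(rng.integers(config.n_tfs))]
        pwm = pwm_by_tf[tf]
        w = pwm.width
        chrom = chroms[int(rng.integers(n_chrom))]
        for _ in range(20):
            pos = int(rng.integers(0, chrom_sizes[chrom] - 320))
            offs = np.sort(rng.choice(300 - w, size=sites_per_cluster, replace=False))
            # re-draw until sites are pairwise non-overlapping within cluster
            if np.any(np.diff(offs) < w):
                continue
            spots = [(pos + int(o), pos + int(o) + w) for o in offs]
            if any(
                s < e2 and e > s2
                for s2, e2 in spots
                for s, e in occupied[chrom]
            ):
                continue
            for s2, _e2 in spots:
                bases = _sample_site(rng, pwm)
                strand = "+" if rng.random() < 0.5 else "-"
                if strand == "-":
                    bases = (3 - bases)[::-1]
                genome_codes[chrom][s2 : s2 + w] = bases
                decoy_sites.append(
                    PlantedSite(
                        tf=tf, chrom=chrom, start=s2, end=s2 + w, strand=strand
                    )
                )
            break

    # --- atlas annotations: planted truth plus random extras
    gene_true_domains: dict[str, set[str]] = {}
    for enh in enhancers:
        gene_true_domains.setdefault(enh.target_gene, set()).add(enh.domain)
    gene_domains: dict[str, set[str]] = {g.gene_id: set() for g in genes}
    for gid, doms in gene_true_domains.items():
        gene_domains[gid] |= doms
    for tf, d in tf_domain_pairs:  # regulators are expressed where they act
        gene_domains[tf].add(d)
    for gid, d in extra_pairs:
        gene_domains[gid].add(d)
    # simple stage-wise ontology: first domain of each stage parents the rest
    ontology_edges = []
    for stage in config.stages:
        stage_doms = [d for d in domain_ids if domain_stage[d] == stage]
        for child in stage_doms[1:]:
            ontology_edges.append((stage_doms[0], child))
    ubiquitous: dict[str, set[str]] = {}
    for tf in tf_ids:
        flagged = {st for st in config.stages if rng.random() < 0.05}
        if flagged:
            ubiquitous[tf] = flagged
    atlas = ExpressionAtlas(
        gene_domains=gene_domains,
        domain_stage=domain_stage,
        ontology_edges=ontology_edges,
        tf_genes=tf_ids,
        ubiquitous=ubiquitous,
    )

    # --- TF expression: FPKM elevated in stages where the TF acts
    active_stages = {
        tf: {domain_stage[d] for t2, d in tf_domain_pairs if t2 == tf}
        for tf in tf_ids
    }
    tf_records = []
    for tf, motif in zip(tf_ids, motif_ids):
        fpkm = {}
        for st in config.stages:
            v = float(rng.gamma(2.0, 1.0))
            if st in active_stages[tf]:
                v += 5.0
            fpkm[st] = v
        tf_records.append(TFRecord(tf_id=tf, motif_id=motif, fpkm=fpkm))

    # --- accessibility per stage: bumps over active enhancers, bumps over
    # the open decoy clusters (spurious stage-specific DNase peaks), and
    # positive background noise
    bin_size = config.signal_bin
    cluster_centers: dict[str, list[tuple[str, float, float]]] = {
        st: [] for st in config.stages
    }
    for ci in range(0, len(decoy_sites), sites_per_cluster):
        cluster = decoy_sites[ci : ci + sites_per_cluster]
        if rng.random() >= config.decoy_open_fraction:
            continue
        st = config.stages[int(rng.integers(len(config.stages)))]
        height = float(rng.uniform(0.5, 1.1)) * config.acc_peak_height
        center = (cluster[0].start + cluster[-1].end) / 2
        cluster_centers[st].append((cluster[0].chrom, center, height))
    accessibility: dict[str, BaseTrack] = {}
    for st in config.stages:
        intervals = {}
        for chrom, L in chrom_sizes.items():
            nbins = L // bin_size
            centers = [
                (e.start + e.end) / 2
                for e in enhancers
                if e.chrom == chrom and domain_stage[e.domain] == st
            ]
            sig = _bump_profile(
                nbins, bin_size, centers, config.acc_peak_height, config.acc_peak_sd
            )
            for c_chrom, center, height in cluster_centers[st]:
                if c_chrom == chrom:
                    sig += _bump_profile(
                        nbins, bin_size, [center], height, config.acc_peak_sd
                    )
            sig += np.abs(rng.normal(0.0, config.acc_noise, nbins)) + 0.05
            starts = np.arange(nbins, dtype=np.int64) * bin_size
            intervals[chrom] = (starts, starts + bin_size, sig)
        accessibility[st] = BaseTrack(intervals)

    # --- ChIP-like occupancy per TF: bumps at planted sites + noise
    chip: dict[str, BaseTrack] = {}
    for tf in tf_ids:
        intervals = {}
        for chrom, L in chrom_sizes.items():
            nbins = L // bin_size
            tf_sites = [
                s for e in enhancers for s in e.sites if s.tf == tf
            ] + [s for s in decoy_sites if s.tf == tf]
            centers = [
                (s.start + s.end) / 2 for s in tf_sites if s.chrom == chrom
            ]
            sig = _bump_profile(
                nbins, bin_size, centers, config.chip_peak_height, config.chip_peak_sd
            )
            sig += np.abs(rng.normal(0.0, config.chip_noise, nbins))
            starts = np.arange(nbins, dtype=np.int64) * bin_size
            intervals[chrom] = (starts, starts + bin_size, sig)
        chip[tf] = BaseTrack(intervals)

    # --- insulators, coding regions
    # insulator marks sit at intergenic boundaries, never between a gene
    # and its own planted enhancers (boundaries delimit regulatory units)
    linkages: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for enh in enhancers:
        g = gene_by_id[enh.target_gene]
        lo = min(g.start, enh.start)
        hi = max(g.end, enh.end)
        linkages[g.chrom].append((lo, hi))
    insulators: list[tuple[str, int, int]] = []
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, chrom_genes in genes_by_chrom.items():
        chrom_genes = sorted(chrom_genes, key=lambda g: g.start)
        for g1, g2 in zip(chrom_genes, chrom_genes[1:]):
            lo, hi = g1.end + 100, g2.start - 100
            if hi - lo < 200:
                continue
            mid = (lo + hi) // 2 + int(rng.integers(-400, 401))
            mid = int(np.clip(mid, lo + 100, hi - 100))
            # candidate boundary points, preferring the jittered midpoint
            candidates = np.arange(lo + 100, hi - 99, 50)
            candidates = candidates[np.argsort(np.abs(candidates - mid))]
            for c in candidates:
                s, e = int(c) - 100, int(c) + 100
                if not any(l < e and h > s for l, h in linkages[chrom]):
                    insulators.append(
                        (chrom, max(s, 0), min(e, chrom_sizes[chrom]))
                    )
                    break
    coding = [(g.chrom, g.start, g.end) for g in genes]

    # --- reference enhancer export
    n_ref = int(round(config.reference_fraction * len(enhancers)))
    ref_idx = rng.choice(len(enhancers), size=n_ref, replace=False)
    reference = [
        ReferenceEnhancer(
            chrom=enhancers[i].chrom,
            start=enhancers[i].start,
            end=enhancers[i].end,
            domains=frozenset({enhancers[i].domain}),
        )
        for i in np.sort(ref_idx)
    ]

    # --- orthologous segments: mutated genome copies with site preservation
    grid = tile_genome(chrom_sizes, config.window_length, config.stride)
    species = ["ref"] + [f"sp{j + 1}" for j in range(config.n_ortholog_species)]
    raw_w = np.array([2.0] + [2.0 * 0.5 ** (j + 1) for j in range(config.n_ortholog_species)])
    weights = raw_w / raw_w.sum()
    segments: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for sp in species[1:]:
        sp_codes = {}
        for chrom, codes in genome_codes.items():
            L = codes.size
            mutate = rng.random(L) < config.mutation_rate
            shift = rng.integers(1, 4, size=L).astype(np.int8)
            mutated = np.where(mutate, (codes + shift) % 4, codes).astype(np.int8)
            sp_codes[chrom] = mutated
        all_sites = [s for e in enhancers for s in e.sites] + decoy_sites
        for site in all_sites:
            if rng.random() < config.site_preservation:
                sp_codes[site.chrom][site.start : site.end] = genome_codes[
                    site.chrom
                ][site.start : site.end]
        mats = []
        for chrom in grid.chroms:
            sl = grid.chrom_slice(chrom)
            if sl.stop == sl.start:
                continue
            starts = grid.starts[sl]
            idx = starts[:, None] + np.arange(grid.window_length)[None, :]
            mats.append(sp_codes[chrom][idx])
        seqs = np.concatenate(mats, axis=0)
        present = np.ones(grid.n_windows, dtype=bool)
        segments[sp] = (present, seqs)
    orthology = OrthologyMap(
        ref_species="ref", species=species, weights=weights, segments=segments
    )

    genome = {c: decode_sequence(codes) for c, codes in genome_codes.items()}
    bundle = WorldBundle(
        config=config,
        genome=genome,
        chrom_sizes=chrom_sizes,
        grid=grid,
        pwms=pwms,
        tf_records=tf_records,
        genes=genes,
        atlas=atlas,
        accessibility=accessibility,
        chip=chip,
        insulators=insulators,
        coding=coding,
        reference_enhancers=reference,
        orthology=orthology,
    )
    truth = GroundTruth(
        tf_domain_pairs=tf_domain_pairs,
        enhancers=enhancers,
        gene_true_domains=gene_true_domains,
    )
    return bundle, truth


# ---------------------------------------------------------------------------
# bundle round trip


def _write_fasta(path: Path, records: Mapping[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _read_fasta(path: Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def _write_bedgraph(path: Path, track: BaseTrack) -> None:
    with open(path, "w") as fh:
        for chrom, (s, e, v) in track.intervals.items():
            for si, ei, vi in zip(s, e, v):
                fh.write(f"{chrom}\t{si}\t{ei}\t{vi:.6g}\n")


def write_bundle(bundle: WorldBundle, truth: GroundTruth, directory) -> None:
    """Serialize a world to plain-text files readable by the package's readers."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    _write_fasta(d / "genome.fa", bundle.genome)
    motif_scoring.write_meme(bundle.pwms, d / "motifs.meme")
    with open(d / "chrom_sizes.tsv", "w") as fh:
        for c, L in bundle.chrom_sizes.items():
            fh.write(f"{c}\t{L}\n")
    for st, track in bundle.accessibility.items():
        _write_bedgraph(d / f"accessibility_{st}.bedGraph", track)
    for tf, track in bundle.chip.items():
        _write_bedgraph(d / f"chip_{tf}.bedGraph", track)
    for name, ivs in (
        ("insulators.bed", bundle.insulators),
        ("coding.bed", bundle.coding),
    ):
        with open(d / name, "w") as fh:
            for chrom, s, e in ivs:
                fh.write(f"{chrom}\t{s}\t{e}\n")
    with open(d / "reference_enhancers.bed", "w") as fh:
        for r in bundle.reference_enhancers:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")
    with open(d / "reference_domains.tsv", "w") as fh:
        fh.write("chrom\tstart\tend\tdomain\n")
        for r in bundle.reference_enhancers:
            for dom in sorted(r.domains):
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{dom}\n")
    write_genes_tsv(bundle.genes, d / "genes.tsv")
    atlas = bundle.atlas
    with open(d / "atlas_gene_domain.tsv", "w") as fh:
        fh.write("gene_id\tdomain\n")
        for g, doms in atlas.gene_domains.items():
            for dom in sorted(doms):
                fh.write(f"{g}\t{dom}\n")
    with open(d / "atlas_domain_stage.tsv", "w") as fh:
        fh.write("domain\tstage\n")
        for dom, st in atlas.domain_stage.items():
            fh.write(f"{dom}\t{st}\n")
    with open(d / "atlas_ontology.tsv", "w") as fh:
        fh.write("parent\tchild\n")
        for p, c in atlas.ontology_edges:
            fh.write(f"{p}\t{c}\n")
    with open(d / "tf_table.tsv", "w") as fh:
        fh.write("tf\tmotif\tubiquitous_stages\n")
        for rec in bundle.tf_records:
            ubiq = ",".join(sorted(atlas.ubiquitous.get(rec.tf_id, ())))
            fh.write(f"{rec.tf_id}\t{rec.motif_id}\t{ubiq}\n")
    with open(d / "fpkm.tsv", "w") as fh:
        fh.write("tf\tstage\tvalue\n")
        for rec in bundle.tf_records:
            for st, v in rec.fpkm.items():
                fh.write(f"{rec.tf_id}\t{st}\t{v:.6g}\n")
    ortho_dir = d / "orthologs"
    ortho_dir.mkdir(exist_ok=True)
    with open(d / "species_weights.tsv", "w") as fh:
        fh.write("species\tweight\n")
        for sp, w in zip(bundle.orthology.species, bundle.orthology.weights):
            fh.write(f"{sp}\t{w:.9f}\n")
    grid = bundle.grid
    for sp in bundle.orthology.species:
        if sp == bundle.orthology.ref_species:
            continue
        present, seqs = bundle.orthology.segments[sp]
        records = {}
        for wi in np.flatnonzero(present):
            chrom = grid.chroms[grid.chrom_index[wi]]
            s = int(grid.starts[wi])
            records[f"{chrom}:{s}-{s + grid.window_length}"] = decode_sequence(
                seqs[wi]
            )
        _write_fasta(ortho_dir / f"{sp}.fa", records)
    with open(d / "ground_truth.json", "w") as fh:
        json.dump(
            {
                "tf_domain_pairs": sorted(map(list, truth.tf_domain_pairs)),
                "enhancers": [
                    {
                        "chrom": e.chrom,
                        "start": e.start,
                        "end": e.end,
                        "domain": e.domain,
                        "target_gene": e.target_gene,
                        "sites": [dataclasses.asdict(s) for s in e.sites],
                    }
                    for e in truth.enhancers
                ],
                "gene_true_domains": {
                    g: sorted(doms) for g, doms in truth.gene_true_domains.items()
                },
            },
            fh,
            indent=1,
        )
    with open(d / "manifest.json", "w") as fh:
        json.dump({"config": bundle.config.to_dict(), "seed": bundle.config.seed}, fh, indent=1)


def read_bundle(directory) -> tuple[WorldBundle, GroundTruth]:
    """Re-read a written world bundle with the package's own readers."""
    d = Path(directory)
    with open(d / "manifest.json") as fh:
        config = WorldConfig.from_dict(json.load(fh)["config"])
    genome = _read_fasta(d / "genome.fa")
    chrom_sizes = core_tracks.read_chrom_sizes(d / "chrom_sizes.tsv")
    grid = tile_genome(chrom_sizes, config.window_length, config.stride)
    pwms = motif_scoring.read_meme(d / "motifs.meme")
    genes = read_genes_tsv(d / "genes.tsv")
    atlas = read_atlas(
        d / "atlas_gene_domain.tsv",
        d / "atlas_domain_stage.tsv",
        d / "atlas_ontology.tsv",
        d / "tf_table.tsv",
    )
    # genes with no annotation carry no TSV rows; restore them
    for g in genes:
        atlas.gene_domains.setdefault(g.gene_id, frozenset())
    import pandas as pd

    fpkm_df = pd.read_csv(d / "fpkm.tsv", sep="\t")
    tf_df = pd.read_csv(d / "tf_table.tsv", sep="\t").fillna("")
    tf_records = []
    for row in tf_df.itertuples():
        sub = fpkm_df[fpkm_df["tf"] == row.tf]
        tf_records.append(
            TFRecord(
                tf_id=row.tf,
                motif_id=row.motif,
                fpkm=dict(zip(sub["stage"], sub["value"])),
            )
        )
    accessibility = {
        st: core_tracks.read_bedgraph(d / f"accessibility_{st}.bedGraph")
        for st in config.stages
    }
    chip = {
        rec.tf_id: core_tracks.read_bedgraph(d / f"chip_{rec.tf_id}.bedGraph")
        for rec in tf_records
    }

    def _read_bed(path):
        out = []
        with open(path) as fh:
            for line in fh:
                if line.strip():
                    parts = line.split("\t")
                    out.append((parts[0], int(parts[1]), int(parts[2])))
        return out

    insulators = _read_bed(d / "insulators.bed")
    coding = _read_bed(d / "coding.bed")
    ref_dom = pd.read_csv(d / "reference_domains.tsv", sep="\t")
    reference = []
    for (chrom, s, e), sub in ref_dom.groupby(["chrom", "start", "end"], sort=True):
        reference.append(
            ReferenceEnhancer(
                chrom=chrom, start=int(s), end=int(e), domains=frozenset(sub["domain"])
            )
        )
    wdf = pd.read_csv(d / "species_weights.tsv", sep="\t")
    species = list(wdf["species"])
    weights = wdf["weight"].to_numpy()
    segments = {}
    for sp in species:
        if sp == "ref":
            continue
        records = _read_fasta(d / "orthologs" / f"{sp}.fa")
        present = np.zeros(grid.n_windows, dtype=bool)
        seqs = np.full((grid.n_windows, grid.window_length), 4, dtype=np.int8)
        for wi in range(grid.n_windows):
            chrom = grid.chroms[grid.chrom_index[wi]]
            s = int(grid.starts[wi])
            key = f"{chrom}:{s}-{s + grid.window_length}"
            if key in records:
                present[wi] = True
                seqs[wi] = encode_sequence(records[key])
        segments[sp] = (present, seqs)
    orthology = OrthologyMap(
        ref_species="ref", species=species, weights=weights, segments=segments
    )
    with open(d / "ground_truth.json") as fh:
        gt = json.load(fh)
    truth = GroundTruth(
        tf_domain_pairs={(tf, dom) for tf, dom in gt["tf_domain_pairs"]},
        enhancers=[
            PlantedEnhancer(
                chrom=e["chrom"],
                start=e["start"],
                end=e["end"],
                domain=e["domain"],
                target_gene=e["target_gene"],
                sites=[PlantedSite(**s) for s in e["sites"]],
            )
            for e in gt["enhancers"]
        ],
        gene_true_domains={g: set(v) for g, v in gt["gene_true_domains"].items()},
    )
    bundle = WorldBundle(
        config=config,
        genome=genome,
        chrom_sizes=chrom_sizes,
        grid=grid,
        pwms=pwms,
        tf_records=tf_records,
        genes=genes,
        atlas=atlas,
        accessibility=accessibility,
        chip=chip,
        insulators=insulators,
        coding=coding,
        reference_enhancers=reference,
        orthology=orthology,
    )
    return bundle, truth


def recovery_report(
    assoc_results,
    truth: GroundTruth,
    assignments=None,
    rank_records: Sequence[tuple[dict, str]] | None = None,
    shuffle_seed: int = 0,
) -> dict:
    """Compare pipeline outputs against the planted ground truth.

    Returns association AUROC against the planted TF-domain map, the
    fraction of planted enhancers assigned their true domain (when
    genome-wide assignments are given), and rank-statistic summaries with a
    label-shuffled control (when per-region candidate percentiles and true
    domains are given).
    """
    from regmap.associations import evaluate_vs_expression
    from regmap.enhancer_models import rank_statistic

    out: dict = {}
    if assoc_results is not None:
        auroc, _ = evaluate_vs_expression(assoc_results, truth.tf_domain_pairs)
        out["association_auroc"] = auroc
    if assignments is not None:
        recovered = 0
        for enh in truth.enhancers:
            hit = assignments[
                (assignments["chrom"] == enh.chrom)
                & (assignments["start"] < enh.end)
                & (assignments["end"] > enh.start)
                & (assignments["domain"] == enh.domain)
            ]
            if len(hit):
                recovered += 1
        out["enhancer_domain_recovery"] = recovered / len(truth.enhancers)
    if rank_records:
        stats = [rank_statistic(pcts, dom) for pcts, dom in rank_records]
        valid = [s for s in stats if s is not None]
        out["n_rank_records"] = len(rank_records)
        out["n_rank_excluded"] = len(stats) - len(valid)
        if valid:
            out["rank_statistic_mean"] = float(np.mean(valid))
            out["rank_top_fraction"] = float(np.mean([s == 1.0 for s in valid]))
        rng = np.random.default_rng(shuffle_seed)
        doms = [dom for _, dom in rank_records]
        perm = rng.permutation(len(doms))
        shuffled = [
            rank_statistic(rank_records[i][0], doms[perm[i]])
            for i in range(len(rank_records))
        ]
        sh_valid = [s for s in shuffled if s is not None]
        out["rank_statistic_shuffled_mean"] = (
            float(np.mean(sh_valid)) if sh_valid else float("nan")
        )
    return out
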