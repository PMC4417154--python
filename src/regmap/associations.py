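"""TF-to-expression-domain association discovery.

For every TF and expression domain, a motif-derived target gene set (the
genes whose regulatory regions carry the strongest accessibility-masked
motif scores) is tested for overlap with the domain's gene set by a
hypergeometric test.  Three regulatory-region definitions are tried -- 1 kb
upstream (p1K), 5 kb upstream (p5K), and the gene span extended up to 50 kb
per side until an insulator mark (IG) -- and the definition giving the
lowest p-value is kept.  Association strength is S = -log10(p), capped so
that downstream features stay finite when p underflows.

Associations are classified by expression support of the TF (annotated in
the domain itself, in a stage-matched ontology relative, or ubiquitously
expressed in the domain's stage) and evaluated against TF-expression ground
truth by AUROC.
"""

from __future__ import annotations

import graphlib
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from regmap.binding_eval import roc_auc
from regmap.core_tracks import WindowGrid, WindowTrack

__all__ = [
    "GeneModel",
    "ExpressionAtlas",
    "RegulatoryRegionSet",
    "AssociationResult",
    "SUPPORT_CATEGORIES",
    "S_CAP",
    "REGION_MODES",
    "build_regulatory_regions",
    "gene_scores",
    "gene_motif_score",
    "tf_target_set",
    "hypergeom_sf",
    "associate",
    "filter_significant",
    "bonferroni_level",
    "expression_support",
    "evaluate_vs_expression",
    "region_class_bias",
    "read_genes_tsv",
    "write_genes_tsv",
    "read_atlas",
]

S_CAP = 300.0
REGION_MODES = ("p1K", "p5K", "IG")
SUPPORT_CATEGORIES = ("specific", "related", "ubiquitous", "none")


@dataclass(frozen=True)
class GeneModel:
    """Gene with TSS and span; strand-aware upstream regions derive from it."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    start: int
    end: int

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        if not (self.start <= self.tss <= self.end):
            raise ValueError(f"TSS outside span for {self.gene_id}")


class ExpressionAtlas:
    """Gene-domain annotations, domain stages, domain ontology, TF metadata.

    The ontology is a DAG of (parent, child) edges between domains; 'related'
    domains of D are its ancestors and descendants restricted to D's stage.
    """

    def __init__(
        self,
        gene_domains: Mapping[str, Iterable[str]],
        domain_stage: Mapping[str, str],
        ontology_edges: Sequence[tuple[str, str]] = (),
        tf_genes: Sequence[str] = (),
        ubiquitous: Mapping[str, Iterable[str]] | None = None,
    ):
        self.gene_domains = {g: frozenset(d) for g, d in gene_domains.items()}
        self.domain_stage = dict(domain_stage)
        for g, doms in self.gene_domains.items():
            for d in doms:
                if d not in self.domain_stage:
                    raise ValueError(f"domain {d!r} (gene {g!r}) has no stage")
        self.ontology_edges = [tuple(e) for e in ontology_edges]
        graph: dict[str, set[str]] = {}
        for parent, child in self.ontology_edges:
            graph.setdefault(child, set()).add(parent)
        # raises CycleError on a cyclic ontology
        tuple(graphlib.TopologicalSorter(graph).static_order())
        self._parents: dict[str, set[str]] = {}
        self._children: dict[str, set[str]] = {}
        for parent, child in self.ontology_edges:
            self._parents.setdefault(child, set()).add(parent)
            self._children.setdefault(parent, set()).add(child)
        self.tf_genes = list(tf_genes)
        self.ubiquitous = {
            tf: frozenset(st) for tf, st in (ubiquitous or {}).items()
        }

    @property
    def genes(self) -> list[str]:
        return list(self.gene_domains)

    @property
    def domains(self) -> list[str]:
        return list(self.domain_stage)

    def stage(self, domain: str) -> str:
        if domain not in self.domain_stage:
            raise KeyError(f"unknown domain {domain!r}")
        return self.domain_stage[domain]

    def domain_genes(self, domain: str) -> frozenset[str]:
        self.stage(domain)
        return frozenset(
            g for g, doms in self.gene_domains.items() if domain in doms
        )

    def related_domains(self, domain: str) -> frozenset[str]:
        """Ancestors and descendants of the domain sharing its stage."""
        stage = self.stage(domain)
        out: set[str] = set()
        for rel in (self._parents, self._children):
            frontier = set(rel.get(domain, ()))
            seen: set[str] = set()
            while frontier:
                d = frontier.pop()
                if d in seen:
                    continue
                seen.add(d)
                out.add(d)
                frontier |= rel.get(d, set()) - seen
        return frozenset(d for d in out if self.domain_stage.get(d) == stage)


@dataclass
class RegulatoryRegionSet:
    """Per-gene regulatory intervals under one region definition."""

    mode: str
    intervals: dict[str, list[tuple[str, int, int]]]

    def __post_init__(self):
        if self.mode not in REGION_MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        self._index_cache: dict[int, tuple] = {}

    def genes_with_regions(self) -> frozenset[str]:
        return frozenset(
            g
            for g, ivs in self.intervals.items()
            if any(e > s for _, s, e in ivs)
        )

    def window_index(self, grid: WindowGrid):
        """Concatenated overlapping-window indices with per-gene offsets."""
        key = id(grid)
        if key not in self._index_cache:
            genes = list(self.intervals)
            chunks = []
            offsets = np.zeros(len(genes) + 1, dtype=np.int64)
            for gi, g in enumerate(genes):
                wins = [
                    grid.overlapping_windows(chrom, s, e)
                    for chrom, s, e in self.intervals[g]
                ]
                merged = (
                    np.unique(np.concatenate(wins)) if wins else np.empty(0, np.int64)
                )
                chunks.append(merged)
                offsets[gi + 1] = offsets[gi] + merged.size
            flat = (
                np.concatenate(chunks) if chunks else np.empty(0, np.int64)
            )
            self._index_cache[key] = (genes, flat, offsets)
        return self._index_cache[key]


@dataclass
class AssociationResult:
    """One TF x domain hypergeometric overlap test (best of three modes)."""

    tf: str
    domain: str
    mode: str
    n: int  # target-set size (best mode)
    K: int  # domain-set size within universe (best mode)
    x: int  # overlap (best mode)
    N: int  # universe size (best mode)
    p_value: float
    per_mode_p: dict[str, float] = field(default_factory=dict)
    support: str | None = None

    @property
    def S(self) -> float:
        """Association strength -log10(p), capped."""
        if self.p_value <= 0:
            return S_CAP
        return min(-math.log10(self.p_value), S_CAP)


def build_regulatory_regions(
    genes: Sequence[GeneModel],
    mode: str,
    insulators: Sequence[tuple[str, int, int]] = (),
    chrom_sizes: Mapping[str, int] | None = None,
    ig_extension: int = 50_000,
) -> RegulatoryRegionSet:
    """Construct per-gene regulatory intervals for one region definition.

    p1K/p5K: strand-aware upstream interval of 1000/5000 bp, clipped at
    chromosome bounds.  IG: the gene span extended up to ``ig_extension`` bp
    on each side, with each extension truncated at the nearest insulator
    boundary between the gene and the extension limit.
    """
    chrom_sizes = chrom_sizes or {}
    ins_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in insulators:
        ins_by_chrom.setdefault(chrom, []).append((s, e))
    out: dict[str, list[tuple[str, int, int]]] = {}
    for g in genes:
        size = chrom_sizes.get(g.chrom)
        if mode in ("p1K", "p5K"):
            length = 1000 if mode == "p1K" else 5000
            if g.strand == "+":
                s, e = g.tss - length, g.tss
            else:
                s, e = g.tss, g.tss + length
        elif mode == "IG":
            left_limit = g.start - ig_extension
            right_limit = g.end + ig_extension
            for ins_s, ins_e in ins_by_chrom.get(g.chrom, ()):
                if left_limit < ins_e <= g.start:
                    left_limit = ins_e
                if g.end <= ins_s < right_limit:
                    right_limit = ins_s
            s, e = left_limit, right_limit
        else:
            raise ValueError(f"unknown mode {mode!r}")
        s = max(s, 0)
        if size is not None:
            e = min(e, size)
        e = max(e, s)
        out[g.gene_id] = [(g.chrom, s, e)]
    return RegulatoryRegionSet(mode=mode, intervals=out)


def gene_scores(
    masked_track: WindowTrack, region_set: RegulatoryRegionSet
) -> dict[str, float]:
    """Max masked window score over each gene's regulatory intervals.

    Genes whose regions overlap no window score 0.
    """
    genes, flat, offsets = region_set.window_index(masked_track.grid)
    vals = masked_track.values[flat] if flat.size else np.empty(0)
    out = {}
    for gi, g in enumerate(genes):
        lo, hi = offsets[gi], offsets[gi + 1]
        out[g] = float(vals[lo:hi].max()) if hi > lo else 0.0
    return out


def gene_motif_score(
    masked_track: WindowTrack, region_set: RegulatoryRegionSet, gene: str
) -> float:
    if gene not in region_set.intervals:
        raise KeyError(f"gene {gene!r} not in region set")
    wins = [
        masked_track.grid.overlapping_windows(chrom, s, e)
        for chrom, s, e in region_set.intervals[gene]
    ]
    flat = np.concatenate(wins) if wins else np.empty(0, np.int64)
    if flat.size == 0:
        return 0.0
    return float(masked_track.values[flat].max())


def tf_target_set(scores: Mapping[str, float], k: int) -> frozenset[str]:
    """The k genes with the highest positive scores.

    Ties are broken by lexicographically ascending gene id; genes scoring 0
    are excluded even if fewer than k genes remain.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    positive = [(g, s) for g, s in scores.items() if s > 0]
    positive.sort(key=lambda gs: (-gs[1], gs[0]))
    return frozenset(g for g, _ in positive[:k])


def hypergeom_sf(x: int, N: int, K: int, n: int) -> float:
    """P(X >= x) drawing n from a universe of N containing K successes."""
    if not (0 <= x <= min(K, n) <= N and K <= N and n <= N):
        raise ValueError(f"inconsistent counts x={x} N={N} K={K} n={n}")
    return float(stats.hypergeom.sf(x - 1, N, K, n))


def default_target_k(universe_size: int) -> int:
    """Target-set size: min(1000, 20% of the universe), at least 1."""
    return max(1, min(1000, int(0.2 * universe_size)))


def associate(
    tf: str,
    domain: str,
    masked_tracks_by_mode: Mapping[str, WindowTrack],
    region_sets: Mapping[str, RegulatoryRegionSet],
    atlas: ExpressionAtlas,
    k: int | None = None,
    _score_cache: Mapping[str, Mapping[str, float]] | None = None,
) -> AssociationResult:
    """Best-of-three-modes hypergeometric association of one TF and domain.

    ``masked_tracks_by_mode[mode]`` is the TF's multi-species motif track
    masked by the accessibility of the domain's stage.  The universe for a
    mode is the set of atlas genes with a non-empty region under that mode.
    Modes tie-break by the declared precedence p1K > p5K > IG.
    """
    domain_set = atlas.domain_genes(domain)
    per_mode_p: dict[str, float] = {}
    per_mode_counts: dict[str, tuple[int, int, int, int]] = {}
    for mode in REGION_MODES:
        region_set = region_sets[mode]
        universe = region_set.genes_with_regions() & set(atlas.genes)
        if _score_cache is not None and mode in _score_cache:
            scores = _score_cache[mode]
        else:
            scores = gene_scores(masked_tracks_by_mode[mode], region_set)
        scores = {g: scores.get(g, 0.0) for g in universe}
        kk = k if k is not None else default_target_k(len(universe))
        target = tf_target_set(scores, kk)
        K = len(domain_set & universe)
        x = len(target & domain_set)
        N = len(universe)
        n = len(target)
        p = 1.0 if n == 0 else hypergeom_sf(x, N, K, n)
        per_mode_p[mode] = p
        per_mode_counts[mode] = (n, K, x, N)
    best_mode = min(REGION_MODES, key=lambda m: (per_mode_p[m], REGION_MODES.index(m)))
    n, K, x, N = per_mode_counts[best_mode]
    return AssociationResult(
        tf=tf,
        domain=domain,
        mode=best_mode,
        n=n,
        K=K,
        x=x,
        N=N,
        p_value=per_mode_p[best_mode],
        per_mode_p=per_mode_p,
    )


def filter_significant(
    results: Sequence[AssociationResult], alpha: float
) -> tuple[list[AssociationResult], float]:
    """Keep associations with p < alpha; report the Bonferroni-corrected level.

    The corrected level is ``alpha * (number of TF x domain tests)``, capped
    at 1.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    kept = [r for r in results if r.p_value < alpha]
    tfs = {r.tf for r in results}
    domains = {r.domain for r in results}
    corrected = bonferroni_level(alpha, len(tfs), len(domains))
    return kept, corrected


def bonferroni_level(alpha: float, n_tfs: int, n_domains: int) -> float:
    """Family-wise significance level for an n_tfs x n_domains test grid."""
    return min(1.0, alpha * n_tfs * n_domains)


def expression_support(tf: str, domain: str, atlas: ExpressionAtlas) -> str:
    """Classify TF expression support for an association.

    'specific' if the TF gene is annotated with the domain; else 'related'
    if annotated with a stage-matched ontology ancestor or descendant; else
    'ubiquitous' if the TF is flagged ubiquitously expressed in the domain's
    stage; else 'none'.
    """
    if tf not in atlas.tf_genes:
        raise KeyError(f"{tf!r} is not a TF gene in the atlas")
    stage = atlas.stage(domain)  # raises on unknown domain
    annotated = atlas.gene_domains.get(tf, frozenset())
    if domain in annotated:
        return "specific"
    if annotated & atlas.related_domains(domain):
        return "related"
    if stage in atlas.ubiquitous.get(tf, frozenset()):
        return "ubiquitous"
    return "none"


def evaluate_vs_expression(
    results: Sequence[AssociationResult],
    truth: set[tuple[str, str]],
) -> tuple[float, np.ndarray]:
    """AUROC of association strength S against known (tf, domain) pairs."""
    if not truth:
        raise ValueError("empty truth set")
    pairs = {(r.tf, r.domain) for r in results}
    outside = set(truth) - pairs
    if outside:
        raise ValueError(f"{len(outside)} truth pairs outside the tested grid")
    scores = np.array([r.S for r in results])
    labels = np.array([(r.tf, r.domain) in truth for r in results])
    return roc_auc(scores, labels)


def region_class_bias(
    results: Sequence[AssociationResult],
    alpha_sig: float = 1e-7,
    alpha_null: float = 1e-3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Proximal (p1K) vs distal (IG) specificity counts and binomial bias.

    An association is p1K-specific when its p1K p-value is significant and
    its IG p-value clearly is not (and symmetrically for IG-specific).  For
    each TF and each domain the (p1K-specific, IG-specific) split is tested
    two-sided against 0.5.
    """
    if not alpha_sig < alpha_null:
        raise ValueError("alpha_sig must be smaller than alpha_null")
    rows = []
    for r in results:
        p1 = r.per_mode_p.get("p1K", 1.0)
        pig = r.per_mode_p.get("IG", 1.0)
        p1k_specific = p1 < alpha_sig and pig > alpha_null
        ig_specific = pig < alpha_sig and p1 > alpha_null
        rows.append((r.tf, r.domain, p1k_specific, ig_specific))
    df = pd.DataFrame(rows, columns=["tf", "domain", "p1k_specific", "ig_specific"])

    def _summarize(by: str) -> pd.DataFrame:
        grouped = df.groupby(by)[["p1k_specific", "ig_specific"]].sum().astype(int)
        pvals = []
        for _, row in grouped.iterrows():
            a, b = int(row["p1k_specific"]), int(row["ig_specific"])
            total = a + b
            pvals.append(
                1.0 if total == 0 else float(stats.binomtest(a, total, 0.5).pvalue)
            )
        grouped["binomial_p"] = pvals
        return grouped

    return _summarize("tf"), _summarize("domain")


# ---------------------------------------------------------------------------
# I/O


def read_genes_tsv(path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    return [
        GeneModel(
            gene_id=row.gene_id,
            chrom=row.chrom,
            strand=row.strand,
            tss=int(row.tss),
            start=int(row.start),
            end=int(row.end),
        )
        for row in df.itertuples()
    ]


def write_genes_tsv(genes: Sequence[GeneModel], path) -> None:
    pd.DataFrame(
        [(g.gene_id, g.chrom, g.strand, g.tss, g.start, g.end) for g in genes],
        columns=["gene_id", "chrom", "strand", "tss", "start", "end"],
    ).to_csv(path, sep="\t", index=False)


def read_atlas(
    gene_domain_path,
    domain_stage_path,
    ontology_path,
    tf_path=None,
) -> ExpressionAtlas:
    """Read the atlas triple (+ optional TF table with ubiquitous flags)."""
    gd = pd.read_csv(gene_domain_path, sep="\t", dtype=str)
    gene_domains: dict[str, set[str]] = {}
    for row in gd.itertuples():
        gene_domains.setdefault(row.gene_id, set()).add(row.domain)
    ds = pd.read_csv(domain_stage_path, sep="\t", dtype=str)
    domain_stage = dict(zip(ds["domain"], ds["stage"]))
    onto = pd.read_csv(ontology_path, sep="\t", dtype=str)
    edges = list(zip(onto["parent"], onto["child"]))
    tf_genes: list[str] = []
    ubiquitous: dict[str, set[str]] = {}
    if tf_path is not None:
        tfs = pd.read_csv(tf_path, sep="\t", dtype=str).fillna("")
        tf_genes = list(dict.fromkeys(tfs["tf"]))
        for row in tfs.itertuples():
            stages = getattr(row, "ubiquitous_stages", "") or ""
            if isinstance(stages, str) and stages:
                ubiquitous[row.tf] = set(stages.split(","))
    return ExpressionAtlas(
        gene_domains=gene_domains,
        domain_stage=domain_stage,
        ontology_edges=edges,
        tf_genes=tf_genes,
        ubiquitous=ubiquitous,
    )
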