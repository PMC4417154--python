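"""Stubb-style HMM window scores for PWMs and multi-species averaging.

A window score is the log-likelihood ratio between a generative HMM that may
emit motif sites at a fitted per-position entry probability ``p`` and the
pure background model (``p = 0``).  Unlike threshold-based scanners, the
score integrates any number of strong or weak sites on either strand.
``p`` is fitted per window by EM, capped at ``1/w`` to avoid degenerate
all-site solutions on repetitive sequence.

Multi-species scores are phylogenetically weighted averages of the score of
orthologous segments, with weights renormalized over species actually
aligned at each window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from regmap import _stubb
from regmap.core_tracks import WindowGrid, WindowTrack

__all__ = [
    "PWM",
    "BackgroundModel",
    "StubbFit",
    "OrthologyMap",
    "build_pwm",
    "train_background",
    "stubb_score",
    "stubb_loglik",
    "score_genome",
    "multispecies_average",
    "score_grid_multispecies",
    "encode_sequence",
    "decode_sequence",
    "revcomp",
    "read_meme",
    "write_meme",
]

_ALPHABET = "ACGT"
_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

EM_MAX_ITER = 200
EM_TOL = 1e-9


def encode_sequence(seq: str) -> np.ndarray:
    """Map a nucleotide string to int8 codes A=0 C=1 G=2 T=3, other=4."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_sequence(codes: np.ndarray) -> str:
    return "".join("ACGTN"[c] for c in codes)


def revcomp(seq: str) -> str:
    comp = str.maketrans("ACGTNacgtn", "TGCANtgcan")
    return seq.translate(comp)[::-1]


@dataclass(frozen=True)
class PWM:
    """Position weight matrix: per-column probabilities over A,C,G,T."""

    motif_id: str
    probs: np.ndarray  # (4, w)
    pseudocount: float = 0.0

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=np.float64)
        object.__setattr__(self, "probs", p)
        if p.ndim != 2 or p.shape[0] != 4 or p.shape[1] < 1:
            raise ValueError("PWM probabilities must be 4 x w with w >= 1")
        if np.any(p <= 0):
            raise ValueError("PWM entries must be strictly positive")
        if np.any(np.abs(p.sum(axis=0) - 1.0) > 1e-9):
            raise ValueError("PWM columns must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    def consensus(self) -> str:
        return "".join(_ALPHABET[i] for i in self.probs.argmax(axis=0))


def build_pwm(count_matrix, pseudocount: float = 0.5, motif_id: str = "") -> PWM:
    """Build a PWM from a 4 x w count matrix with additive pseudocounts."""
    counts = np.asarray(count_matrix, dtype=np.float64)
    if counts.ndim != 2 or counts.shape[0] != 4:
        raise ValueError("count matrix must be 4 x w")
    if np.any(counts < 0):
        raise ValueError("negative counts")
    if np.any(counts.sum(axis=0) <= 0):
        raise ValueError("every column needs at least one positive count")
    probs = (counts + pseudocount) / (counts.sum(axis=0) + 4.0 * pseudocount)
    return PWM(motif_id=motif_id, probs=probs, pseudocount=pseudocount)


class BackgroundModel:
    """Order-k Markov background over A,C,G,T with add-pseudocount smoothing.

    Conditional tables are kept for every order 0..k; scoring a position uses
    the highest order whose context is available and free of ambiguous bases.
    Context codes are little-endian: the base immediately left of the scored
    position carries weight 4**0.
    """

    def __init__(self, order: int, probs: list[np.ndarray], label: str = ""):
        if order < 0 or len(probs) != order + 1:
            raise ValueError("need one conditional table per order 0..k")
        self.order = order
        self.probs = [np.asarray(p, dtype=np.float64) for p in probs]
        self.label = label
        for j, p in enumerate(self.probs):
            if p.shape != (4**j, 4):
                raise ValueError(f"order-{j} table must be {4 ** j} x 4")
            if np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-9):
                raise ValueError("conditional distributions must sum to 1")

    def logprob_matrix(self, seqs: np.ndarray) -> np.ndarray:
        """Per-position background log-probabilities for encoded rows.

        Ambiguous bases emit with probability 0.25 (and invalidate contexts).
        """
        seqs = np.atleast_2d(seqs)
        nw, n = seqs.shape
        base_ok = seqs < 4
        clipped = np.minimum(seqs, 3).astype(np.int64)
        with np.errstate(divide="ignore"):
            lp0 = np.log(self.probs[0][0])
        out = np.where(base_ok, lp0[clipped], math.log(0.25))
        ctx = np.zeros((nw, n), dtype=np.int64)
        ctx_ok = base_ok.copy()
        for j in range(1, self.order + 1):
            if j > n:
                break
            ctx[:, j:] += clipped[:, :-j] * 4 ** (j - 1)
            ok = np.zeros((nw, n), dtype=bool)
            ok[:, j:] = base_ok[:, j:]
            for d in range(1, j + 1):
                ok[:, j:] &= base_ok[:, j - d : n - d]
            with np.errstate(divide="ignore"):
                lpj = np.log(self.probs[j])
            vals = lpj[ctx, clipped]
            out = np.where(ok, vals, out)
        return out

    def seq_loglik(self, seq: str) -> float:
        return float(self.logprob_matrix(encode_sequence(seq)[None, :]).sum())


def train_background(
    sequences: Sequence[str],
    order: int = 1,
    pseudocount: float = 0.5,
    max_n_fraction: float = 0.1,
    label: str = "",
) -> BackgroundModel:
    """Fit Markov conditional frequencies from sequences.

    Non-ACGT characters are tolerated up to ``max_n_fraction`` of the total
    length; they are excluded from counts and invalidate spanned contexts.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    codes = [encode_sequence(s) for s in sequences if len(s)]
    total = sum(len(c) for c in codes)
    if total == 0:
        raise ValueError("no sequence data")
    n_bad = sum(int((c >= 4).sum()) for c in codes)
    if n_bad > max_n_fraction * total:
        raise ValueError(
            f"{n_bad}/{total} non-ACGT characters exceeds allowed fraction "
            f"{max_n_fraction}"
        )
    probs = []
    for j in range(order + 1):
        counts = np.full((4**j, 4), pseudocount, dtype=np.float64)
        for c in codes:
            if len(c) <= j:
                continue
            ok = c < 4
            valid = ok[j:].copy()
            ctx = np.zeros(len(c) - j, dtype=np.int64)
            for d in range(1, j + 1):
                ctx += np.minimum(c[j - d : len(c) - d], 3).astype(np.int64) * 4 ** (
                    d - 1
                )
                valid &= ok[j - d : len(c) - d]
            np.add.at(counts, (ctx[valid], c[j:][valid]), 1.0)
        row_tot = counts.sum(axis=1, keepdims=True)
        # rows never observed and unsmoothed fall back to uniform
        with np.errstate(invalid="ignore"):
            p = np.where(row_tot > 0, counts / np.where(row_tot > 0, row_tot, 1), 0.25)
        probs.append(p)
    return BackgroundModel(order=order, probs=probs, label=label)


@dataclass
class StubbFit:
    """Result of the EM fit of the site-entry probability for one window."""

    p_hat: float
    loglik: float  # log L(p_hat), nats
    loglik_null: float  # log L(0), nats
    n_iter: int
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    has_ambiguous: bool = False


def _site_rho(seqs: np.ndarray, pwm: PWM, bg_lp: np.ndarray) -> np.ndarray:
    """Site/background odds per window and site end position (1-based).

    Returns an (nw, n+1) array with zeros for positions where no full-width
    site can end (or where the site would span an ambiguous base).
    """
    w = pwm.width
    logp = np.log(pwm.probs)  # (4, w), finite by PWM positivity
    logp_rc = logp[::-1, ::-1].copy()  # logp_rc[b, j] = logp[3-b, w-1-j]
    return _stubb.site_rho_kernel(
        np.ascontiguousarray(seqs),
        logp,
        logp_rc,
        np.ascontiguousarray(bg_lp),
        w,
    )


def _em_windows(
    seqs: np.ndarray,
    pwm: PWM,
    bg: BackgroundModel,
    store_trace: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Run the EM fit for a batch of equal-length encoded windows."""
    seqs = np.ascontiguousarray(np.atleast_2d(seqs))
    nw, n = seqs.shape
    w = pwm.width
    if n < w:
        z = np.zeros(nw)
        return z, z.copy(), np.zeros(nw, dtype=np.int64), np.empty((nw, 0))
    bg_lp = bg.logprob_matrix(seqs)
    rho = _site_rho(seqs, pwm, bg_lp)
    p_init, p_max = 1.0 / (4.0 * w), 1.0 / w
    if store_trace:
        trace = np.full((nw, EM_MAX_ITER), np.nan)
        ll, p_hat, n_iter = _stubb.em_batch(
            rho, w, p_init, p_max, EM_MAX_ITER, EM_TOL, True, trace
        )
    else:
        trace = np.empty((nw, 0))
        # windows whose likelihood could leave the representable range go
        # through the scalar kernel, which rescales; the rest take the
        # vectorized path (identical model and stopping rule)
        bound = np.log1p(p_max * rho).sum(axis=1)
        risky = bound > 600.0
        if risky.any():
            ll = np.empty(nw)
            p_hat = np.empty(nw)
            n_iter = np.empty(nw, dtype=np.int64)
            lr, pr, ir = _stubb.em_batch(
                np.ascontiguousarray(rho[risky]),
                w, p_init, p_max, EM_MAX_ITER, EM_TOL, False, np.empty((1, 1)),
            )
            lv, pv, iv = _stubb.em_batch_vec(
                np.ascontiguousarray(rho[~risky]), w, p_init, p_max,
                EM_MAX_ITER, EM_TOL,
            )
            ll[risky], p_hat[risky], n_iter[risky] = lr, pr, ir
            ll[~risky], p_hat[~risky], n_iter[~risky] = lv, pv, iv
        else:
            ll, p_hat, n_iter = _stubb.em_batch_vec(
                rho, w, p_init, p_max, EM_MAX_ITER, EM_TOL
            )
    # p = 0 is always feasible: never report a fit worse than the null
    worse = ll <= 0.0
    ll = np.where(worse, 0.0, ll)
    p_hat = np.where(worse, 0.0, p_hat)
    return ll, p_hat, n_iter, trace


def stubb_score(
    window_seq: str, pwm: PWM, bg: BackgroundModel
) -> tuple[float, StubbFit]:
    """Score one window: log L(p_hat) - log L(0), clamped at 0 (nats)."""
    if len(window_seq) < 1:
        raise ValueError("window sequence must be non-empty")
    codes = encode_sequence(window_seq)[None, :]
    ll, p_hat, n_iter, trace = _em_windows(codes, pwm, bg, store_trace=True)
    ll0 = float(bg.logprob_matrix(codes).sum())
    tr = trace[0]
    fit = StubbFit(
        p_hat=float(p_hat[0]),
        loglik=ll0 + float(ll[0]),
        loglik_null=ll0,
        n_iter=int(n_iter[0]),
        loglik_trace=tr[np.isfinite(tr)] + ll0 if tr.size else np.empty(0),
        has_ambiguous=bool((codes >= 4).any()),
    )
    return float(ll[0]), fit


def stubb_loglik(window_seq: str, pwm: PWM, bg: BackgroundModel, p: float) -> float:
    """Absolute log-likelihood (nats) of a window at a fixed site probability."""
    codes = encode_sequence(window_seq)[None, :]
    if len(window_seq) < pwm.width:
        return float(bg.logprob_matrix(codes).sum()) + math.log1p(-p) * len(window_seq)
    bg_lp = bg.logprob_matrix(codes)
    rho = _site_rho(codes, pwm, bg_lp)
    rel = _stubb.forward_batch(rho, pwm.width, p)
    return float(bg_lp.sum() + rel[0])


def _window_matrix(chrom_seq: str, grid: WindowGrid, chrom: str) -> np.ndarray:
    codes = encode_sequence(chrom_seq)
    sl = grid.chrom_slice(chrom)
    starts = grid.starts[sl]
    idx = starts[:, None] + np.arange(grid.window_length)[None, :]
    return codes[idx]


def score_genome(
    genome: Mapping[str, str], pwm: PWM, grid: WindowGrid, bg: BackgroundModel
) -> WindowTrack:
    """One HMM score per grid window; deterministic."""
    values = np.zeros(grid.n_windows)
    for chrom in grid.chroms:
        if chrom not in genome:
            raise ValueError(f"no sequence for chromosome {chrom!r}")
        sl = grid.chrom_slice(chrom)
        if sl.stop == sl.start:
            continue
        seqs = _window_matrix(str(genome[chrom]), grid, chrom)
        ll, _, _, _ = _em_windows(seqs, pwm, bg)
        values[sl] = ll
    return WindowTrack(grid, values)


@dataclass
class OrthologyMap:
    """Orthologous segments per reference window plus species weights.

    ``segments[sp]`` is ``(present, seqs)``: a boolean presence flag per
    reference window and an (n_windows, window_length) int8 matrix of encoded
    segment sequences (rows where ``present`` is False are ignored).  The
    reference species is implicit (its sequence is the genome itself).
    """

    ref_species: str
    species: list[str]  # includes ref_species
    weights: np.ndarray  # aligned with species; sums to 1
    segments: dict[str, tuple[np.ndarray, np.ndarray]]

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.ref_species not in self.species:
            raise ValueError("reference species missing from species list")
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("species weights must be >= 0 and sum to 1")

    def weight(self, sp: str) -> float:
        return float(self.weights[self.species.index(sp)])


def multispecies_average(
    scores: Mapping[str, float], orthology: OrthologyMap
) -> float:
    """Weighted average of per-species scores, renormalized over present species."""
    if not scores:
        raise ValueError("no species scores given")
    if orthology.ref_species not in scores:
        raise ValueError("reference species score is required")
    wsum = 0.0
    total = 0.0
    for sp, sc in scores.items():
        wt = orthology.weight(sp)
        wsum += wt
        total += wt * sc
    if wsum <= 0:
        raise ValueError("total weight of present species is zero")
    return total / wsum


def score_grid_multispecies(
    genome: Mapping[str, str],
    pwm: PWM,
    grid: WindowGrid,
    bg_by_species: Mapping[str, BackgroundModel],
    orthology: OrthologyMap,
) -> tuple[WindowTrack, WindowTrack]:
    """Multi-species averaged window scores (and the single-species track).

    Each non-reference species' orthologous segments are scored with that
    species' background model; per-window weights are renormalized over the
    species present at the window.
    """
    ref = orthology.ref_species
    ref_track = score_genome(genome, pwm, grid, bg_by_species[ref])
    num = orthology.weight(ref) * ref_track.values
    den = np.full(grid.n_windows, orthology.weight(ref))
    for sp in orthology.species:
        if sp == ref:
            continue
        present, seqs = orthology.segments[sp]
        if not present.any():
            continue
        ll, _, _, _ = _em_windows(seqs[present], pwm, bg_by_species[sp])
        wt = orthology.weight(sp)
        num[present] += wt * ll
        den[present] += wt
    return WindowTrack(grid, num / den), ref_track


# ---------------------------------------------------------------------------
# MEME minimal format I/O


def read_meme(path) -> list[PWM]:
    """Read PWMs from a MEME minimal-format file (via Biopython)."""
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "minimal")
    out = []
    for m in parsed:
        mat = np.array([m.pwm[b] for b in _ALPHABET], dtype=np.float64)
        # guard against zero entries from rounded input files
        mat = np.maximum(mat, 1e-9)
        mat /= mat.sum(axis=0)
        out.append(PWM(motif_id=m.name, probs=mat))
    return out


def write_meme(pwms: Sequence[PWM], path, background=None) -> None:
    bgfreq = background if background is not None else [0.25] * 4
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(
            " ".join(f"{b} {f:.5f}" for b, f in zip(_ALPHABET, bgfreq)) + "\n\n"
        )
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.motif_id}\n")
            # large nsites keeps read-back probabilities near exact under
            # parsers that reconstruct integer counts
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width} "
                f"nsites= 100000 E= 0\n"
            )
            for col in pwm.probs.T:
                fh.write(" ".join(f"{x:.6f}" for x in col) + "\n")
            fh.write("\n")
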