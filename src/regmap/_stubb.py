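"""Numba kernels for the window-scoring HMM's EM fit.

The generative model emits each position either as one background base with
factor (1-p)*bg, or as the last base of a w-bp motif site with factor
p * 0.5 * (P_W(+) + P_W(-)).  All quantities here are expressed as odds
against the all-background model, so the forward variable F'(i) satisfies

    F'(0) = 1
    F'(i) = (1-p) * F'(i-1) + p * rho(i) * F'(i-w)      (site term for i >= w)

where rho(i) is the site/background odds of the w-mer ending at position i.
L(p)/L(0) = F'(n), hence the window score is log F'(n) at the fitted p.

The E-step needs only the posterior expected site count E[k].  Rather than a
backward pass, it is obtained from the derivative of the log-likelihood,
propagated alongside the forward recursion:

    d logL/dp = E[k]/p - (n - w E[k])/(1-p)
    =>  E[k]  = (d logL/dp + n/(1-p)) * p(1-p) / (1 - p + w p)
"""

import numpy as np
from numba import njit

# rescale threshold: keeps products representable for arbitrarily site-rich
# windows without moving to log space in the hot loop
_BIG = 1e280
_LOG_BIG = np.log(_BIG)


@njit(cache=True, fastmath=True)
def em_batch(rho, w, p_init, p_max, max_iter, tol, store_trace, trace):
    """Fit the per-window site-entry probability by EM, batched over windows.

    Parameters
    ----------
    rho : (n_windows, n+1) float64
        Site/background odds of the site ending at position i (1-based);
        entries with i < w must be 0.
    trace : (n_windows, max_iter) float64
        Per-iteration log-likelihood ratios, written only if ``store_trace``.

    Returns
    -------
    ll : log L(p_hat) - log L(0) per window (may be negative; caller clamps)
    p_hat, n_iter
    """
    nw = rho.shape[0]
    n = rho.shape[1] - 1
    out_ll = np.zeros(nw)
    out_p = np.zeros(nw)
    out_iter = np.zeros(nw, np.int64)
    F = np.empty(n + 1)
    D = np.empty(n + 1)  # dF/dp alongside F
    for r in range(nw):
        rho_r = rho[r]
        p = p_init
        ll_prev = -np.inf
        ll = 0.0
        p_eval = p
        n_iter = 0
        for it in range(max_iter):
            q = 1.0 - p
            off = 0.0
            F[0] = 1.0
            D[0] = 0.0
            for i in range(1, min(w, n + 1)):
                F[i] = q * F[i - 1]
                D[i] = q * D[i - 1] - F[i - 1]
            for i in range(w, n + 1):
                fprev = F[i - 1]
                fsite = F[i - w]
                ri = rho_r[i]
                val = q * fprev + p * ri * fsite
                F[i] = val
                D[i] = q * D[i - 1] - fprev + ri * (p * D[i - w] + fsite)
                if val > _BIG:
                    inv = 1.0 / _BIG
                    for j in range(i + 1):
                        F[j] *= inv
                        D[j] *= inv
                    off += _LOG_BIG
            ll = np.log(F[n]) + off
            p_eval = p
            n_iter = it + 1
            if store_trace:
                trace[r, it] = ll
            if it > 0 and abs(ll - ll_prev) < tol:
                break
            ll_prev = ll
            # E-step: expected site count from the score function
            dlogl = D[n] / F[n]
            n_s = (dlogl + n / q) * p * q / (q + w * p)
            if n_s < 0.0:
                n_s = 0.0
            # M-step: p = n_s / (n_s + n_b) with n_b = n - w * n_s
            denom = n - (w - 1.0) * n_s
            p_new = p_max if denom <= 0.0 else n_s / denom
            if p_new > p_max:
                p_new = p_max
            elif p_new < 0.0:
                p_new = 0.0
            p = p_new
        out_ll[r] = ll
        out_p[r] = p_eval
        out_iter[r] = n_iter
    return out_ll, out_p, out_iter


@njit(cache=True, fastmath=True)
def site_rho_kernel(seqs, logp, logp_rc, bg_lp, w):
    """Site/background odds rho per window and 1-based site end position.

    ``logp_rc[b, j] = logp[3 - b, w - 1 - j]`` is the reverse-complement
    column table.  w-mers touching an ambiguous base (code > 3) get rho 0.
    """
    nw, n = seqs.shape
    rho = np.zeros((nw, n + 1))
    if n < w:
        return rho
    half_log2 = np.log(2.0)
    for r in range(nw):
        # prefix sums of background log-probabilities for span odds
        bgsum = 0.0
        pref = np.empty(n + 1)
        pref[0] = 0.0
        for i in range(n):
            bgsum += bg_lp[r, i]
            pref[i + 1] = bgsum
        for t in range(n - w + 1):
            f = 0.0
            rc = 0.0
            ok = True
            for j in range(w):
                b = seqs[r, t + j]
                if b > 3:
                    ok = False
                    break
                f += logp[b, j]
                rc += logp_rc[b, j]
            if not ok:
                continue
            # log(0.5 * (e^f + e^rc)) via the larger term
            if f >= rc:
                site = f + np.log1p(np.exp(rc - f)) - half_log2
            else:
                site = rc + np.log1p(np.exp(f - rc)) - half_log2
            lr = site - (pref[t + w] - pref[t])
            if lr > 690.0:
                lr = 690.0
            rho[r, t + w] = np.exp(lr)
    return rho


@njit(cache=True, fastmath=True)
def em_batch_vec(rho, w, p_init, p_max, max_iter, tol):
    """Active-set vectorized EM: identical model to :func:`em_batch`.

    Windows are processed position-by-position with the window dimension
    innermost, so the per-position dependency chain no longer bounds
    throughput.  Converged windows are compacted out after each EM round.
    No rescaling is performed: callers must route windows whose
    log-likelihood could exceed the representable range (log bound > ~600)
    to the scalar kernel.
    """
    nw = rho.shape[0]
    n = rho.shape[1] - 1
    out_ll = np.zeros(nw)
    out_p = np.zeros(nw)
    out_iter = np.zeros(nw, np.int64)
    # position-major working state so the inner window loop is contiguous;
    # `orig` maps compacted column -> original window
    rho_t = np.ascontiguousarray(rho.T)  # (n+1, nw)
    orig = np.arange(nw)
    p = np.full(nw, p_init)
    ll_prev = np.full(nw, -np.inf)
    # ring buffers: F(i) only ever references F(i-1) and F(i-w), so w+1
    # rows suffice and the working set stays cache-resident
    m = w + 1
    F = np.empty((m, nw))
    D = np.empty((m, nw))
    na = nw
    for it in range(max_iter):
        # ---- forward + derivative, vectorized over active windows
        for k in range(na):
            F[0, k] = 1.0
            D[0, k] = 0.0
        for i in range(1, min(w, n + 1)):
            c, c1 = i % m, (i - 1) % m
            for k in range(na):
                q = 1.0 - p[k]
                F[c, k] = q * F[c1, k]
                D[c, k] = q * D[c1, k] - F[c1, k]
        for i in range(w, n + 1):
            c, c1, cw = i % m, (i - 1) % m, (i - w) % m
            for k in range(na):
                q = 1.0 - p[k]
                ri = rho_t[i, k]
                fw = F[cw, k]
                dw = D[cw, k]
                F[c, k] = q * F[c1, k] + p[k] * ri * fw
                D[c, k] = q * D[c1, k] - F[c1, k] + ri * (p[k] * dw + fw)
        # ---- convergence check, E-step, M-step; compact the active set
        cn = n % m
        keep = 0
        for k in range(na):
            ll = np.log(F[cn, k])
            r = orig[k]
            out_ll[r] = ll
            out_p[r] = p[k]
            out_iter[r] = it + 1
            if it > 0 and abs(ll - ll_prev[k]) < tol:
                continue  # converged: drop from active set
            q = 1.0 - p[k]
            dlogl = D[cn, k] / F[cn, k]
            n_s = (dlogl + n / q) * p[k] * q / (q + w * p[k])
            if n_s < 0.0:
                n_s = 0.0
            denom = n - (w - 1.0) * n_s
            p_new = p_max if denom <= 0.0 else n_s / denom
            if p_new > p_max:
                p_new = p_max
            elif p_new < 0.0:
                p_new = 0.0
            if keep != k:
                for i in range(n + 1):
                    rho_t[i, keep] = rho_t[i, k]
            orig[keep] = r
            p[keep] = p_new
            ll_prev[keep] = ll
            keep += 1
        na = keep
        if na == 0:
            break
    return out_ll, out_p, out_iter


@njit(cache=True, fastmath=True)
def forward_batch(rho, w, p):
    """log L(p) - log L(0) per window at a fixed site probability p."""
    nw = rho.shape[0]
    n = rho.shape[1] - 1
    out = np.zeros(nw)
    F = np.empty(n + 1)
    q = 1.0 - p
    for r in range(nw):
        rho_r = rho[r]
        off = 0.0
        F[0] = 1.0
        for i in range(1, min(w, n + 1)):
            F[i] = q * F[i - 1]
        for i in range(w, n + 1):
            val = q * F[i - 1] + p * rho_r[i] * F[i - w]
            F[i] = val
            if val > _BIG:
                inv = 1.0 / _BIG
                for j in range(i + 1):
                    F[j] *= inv
                off += _LOG_BIG
        out[r] = np.log(F[n]) + off
    return out
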