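"""Numba kernel for the collapsed Gibbs sweep.

The kernel consumes one pre-drawn uniform per token (``rand``), so all
randomness lives in the caller's numpy Generator and results are
bit-identical to the pure-Python reference sweep in :mod:`biolda.model`.
Weight layout and the linear-scan inverse-CDF draw must stay in lockstep
with that reference: bio-terms of the document in ``bd_flat`` order
(outer), topics 0..T-1 (inner).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def sweep_kernel(w, tok_doc, j_doc, bd_flat, bd_ptr, z, x,
                 n_bt, n_wt, n_jt, n_t, n_b,
                 alpha, beta, mu, use_journal, rand, probs):
    N = w.shape[0]
    T = n_bt.shape[1]
    V = n_wt.shape[0]
    J = n_jt.shape[0]
    vbeta = V * beta
    jmu = J * mu
    talpha = T * alpha
    for i in range(N):
        d = tok_doc[i]
        wi = w[i]
        ji = j_doc[d]
        zi = z[i]
        xi = x[i]
        # remove current assignment (the "-di" convention)
        n_bt[xi, zi] -= 1
        n_wt[wi, zi] -= 1
        n_jt[ji, zi] -= 1
        n_t[zi] -= 1
        n_b[xi] -= 1
        s = bd_ptr[d]
        e = bd_ptr[d + 1]
        total = 0.0
        idx = 0
        for k in range(s, e):
            b = bd_flat[k]
            fb = 1.0 / (n_b[b] + talpha)
            for t in range(T):
                p = (n_bt[b, t] + alpha) * fb \
                    * (n_wt[wi, t] + beta) / (n_t[t] + vbeta)
                if use_journal:
                    p *= (n_jt[ji, t] + mu) / (n_t[t] + jmu)
                probs[idx] = p
                total += p
                idx += 1
        u = rand[i] * total
        acc = 0.0
        sel = idx - 1
        for m in range(idx):
            acc += probs[m]
            if u < acc:
                sel = m
                break
        b_new = bd_flat[s + sel // T]
        t_new = sel % T
        z[i] = t_new
        x[i] = b_new
        n_bt[b_new, t_new] += 1
        n_wt[wi, t_new] += 1
        n_jt[ji, t_new] += 1
        n_t[t_new] += 1
        n_b[b_new] += 1
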