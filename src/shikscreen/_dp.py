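"""Numba dynamic-programming kernels for local profile-HMM alignment.

State layout (Plan7-like, single-hit local):

- match states ``M_0 .. M_{L-1}``, insert states ``I_k`` between ``M_k``
  and ``M_{k+1}`` (k = 0..L-2), delete states ``D_k`` parallel to the
  match states (reachable for k >= 1).
- A path enters directly at some match state ``M_s`` and exits from some
  match state ``M_e`` (s <= e); the joint entry/exit probability is
  uniform over the L(L+1)/2 valid (s, e) pairs and enters the score as a
  single additive term ``en = log2(2 / (L (L+1)))``.
- Residues outside the aligned region are emitted by the background null
  and cancel exactly, so only the aligned region is scored.

All scores are log2-odds (bits) against the background null; emission
arrays passed in are already log-odds. Unknown residues are coded -1 and
score 0 bits everywhere.

The DP convention indexes ``i`` by the number of residues consumed, so
``VM[i][k]`` is the best (or total, for forward) score of a path ending
in ``M_k`` whose last emitted residue is ``x[i-1]``.
"""

from __future__ import annotations

import math

import numba
import numpy as np

NEG_INF = -np.inf
_LN2 = math.log(2.0)


@numba.njit(cache=True)
def _la2(a: float, b: float) -> float:
    """log2(2**a + 2**b), robust to -inf."""
    if a < b:
        a, b = b, a
    if b == NEG_INF:
        return a
    return a + math.log1p(2.0 ** (b - a)) / _LN2


@numba.njit(cache=True)
def viterbi_kernel(x, mat_lo, ins_lo, ltmm, ltmi, ltmd, ltim, ltii, ltdm, ltdd, en):
    """Best local alignment score and its spans.

    Returns ``(score, seq_start, seq_end, model_start, model_end)`` with
    half-open spans on the sequence and on the match states.
    """
    n = x.shape[0]
    L = mat_lo.shape[0]
    vm = np.full((n + 1, L), NEG_INF)
    vi = np.full((n + 1, L), NEG_INF)
    vd = np.full((n + 1, L), NEG_INF)
    # backpointers: 0 = entry, 1 = from M, 2 = from I, 3 = from D
    pm = np.zeros((n + 1, L), dtype=np.int8)
    pi = np.zeros((n + 1, L), dtype=np.int8)
    pd = np.zeros((n + 1, L), dtype=np.int8)

    best = NEG_INF
    bi = 0
    bk = 0
    for i in range(1, n + 1):
        xi = x[i - 1]
        for k in range(L):
            em = 0.0 if xi < 0 else mat_lo[k, xi]
            s = en
            p = 0
            if k > 0:
                v = vm[i - 1, k - 1] + ltmm[k - 1]
                if v > s:
                    s = v
                    p = 1
                v = vi[i - 1, k - 1] + ltim[k - 1]
                if v > s:
                    s = v
                    p = 2
                v = vd[i - 1, k - 1] + ltdm[k - 1]
                if v > s:
                    s = v
                    p = 3
            vm[i, k] = em + s
            pm[i, k] = p
            if vm[i, k] > best:
                best = vm[i, k]
                bi = i
                bk = k
            if k < L - 1:
                emi = 0.0 if xi < 0 else ins_lo[xi]
                a = vm[i - 1, k] + ltmi[k]
                b = vi[i - 1, k] + ltii[k]
                if a >= b:
                    vi[i, k] = emi + a
                    pi[i, k] = 1
                else:
                    vi[i, k] = emi + b
                    pi[i, k] = 2
        for k in range(1, L):
            a = vm[i, k - 1] + ltmd[k - 1]
            b = vd[i, k - 1] + ltdd[k - 1]
            if a >= b:
                vd[i, k] = a
                pd[i, k] = 1
            else:
                vd[i, k] = b
                pd[i, k] = 3

    # traceback from (bi, bk) in state M to the entry point
    i = bi
    k = bk
    state = 1  # 1 = M, 2 = I, 3 = D
    si = bi - 1
    sk = bk
    while True:
        if state == 1:
            p = pm[i, k]
            if p == 0:
                si = i - 1
                sk = k
                break
            if p == 1:
                i, k, state = i - 1, k - 1, 1
            elif p == 2:
                i, k, state = i - 1, k - 1, 2
            else:
                i, k, state = i - 1, k - 1, 3
        elif state == 2:
            p = pi[i, k]
            if p == 1:
                i, state = i - 1, 1
            else:
                i, state = i - 1, 2
        else:
            p = pd[i, k]
            if p == 1:
                k, state = k - 1, 1
            else:
                k, state = k - 1, 3

    return best, si, bi, sk, bk + 1


@numba.njit(cache=True)
def forward_kernel(x, mat_lo, ins_lo, ltmm, ltmi, ltmd, ltim, ltii, ltdm, ltdd, en):
    """Total log2-odds over all local alignment paths."""
    n = x.shape[0]
    L = mat_lo.shape[0]
    fm = np.full((n + 1, L), NEG_INF)
    fi = np.full((n + 1, L), NEG_INF)
    fd = np.full((n + 1, L), NEG_INF)

    total = NEG_INF
    for i in range(1, n + 1):
        xi = x[i - 1]
        for k in range(L):
            em = 0.0 if xi < 0 else mat_lo[k, xi]
            s = en
            if k > 0:
                s = _la2(s, fm[i - 1, k - 1] + ltmm[k - 1])
                s = _la2(s, fi[i - 1, k - 1] + ltim[k - 1])
                s = _la2(s, fd[i - 1, k - 1] + ltdm[k - 1])
            fm[i, k] = em + s
            total = _la2(total, fm[i, k])
            if k < L - 1:
                emi = 0.0 if xi < 0 else ins_lo[xi]
                fi[i, k] = emi + _la2(
                    fm[i - 1, k] + ltmi[k], fi[i - 1, k] + ltii[k]
                )
        for k in range(1, L):
            fd[i, k] = _la2(fm[i, k - 1] + ltmd[k - 1], fd[i, k - 1] + ltdd[k - 1])

    return total
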