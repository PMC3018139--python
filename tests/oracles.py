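"""Independent brute-force oracles used by the test suite.

These enumerate objects exhaustively (alignment paths, sliding windows)
and are deliberately written without reference to the package's dynamic
programming, so they can certify it on tiny instances.
"""

from __future__ import annotations

import math

import numpy as np


def enumerate_path_scores(hmm, codes: np.ndarray) -> list[float]:
    """Log2-odds score of every local alignment path, by explicit DFS.

    A path enters at match state ``s`` emitting residue ``a``, threads
    match/insert/delete states, and exits at some match state. Feasible
    for L <= 4 and sequences up to ~6 residues.
    """
    L = hmm.length
    n = len(codes)
    with np.errstate(divide="ignore"):
        mat_lo = np.log2(hmm.match_emissions) - np.log2(hmm.background)
        ins_lo = np.log2(hmm.insert_emissions) - np.log2(hmm.background)
        lt = {
            nm: np.log2(getattr(hmm, nm))
            for nm in ("t_mm", "t_mi", "t_md", "t_im", "t_ii", "t_dm", "t_dd")
        }
    en = math.log2(2.0 / (L * (L + 1)))

    def em_m(k, i):
        return 0.0 if codes[i] < 0 else float(mat_lo[k, codes[i]])

    def em_i(i):
        return 0.0 if codes[i] < 0 else float(ins_lo[codes[i]])

    scores: list[float] = []

    def walk(state: str, k: int, i: int, acc: float) -> None:
        # `state` just emitted/occupied index k; i = next residue index
        if state == "M":
            scores.append(acc)  # exit here
            if k + 1 < L:
                if i < n:
                    walk("M", k + 1, i + 1, acc + lt["t_mm"][k] + em_m(k + 1, i))
                if i < n and k <= L - 2:
                    walk("I", k, i + 1, acc + lt["t_mi"][k] + em_i(i))
                walk("D", k + 1, i, acc + lt["t_md"][k])
        elif state == "I":
            if i < n:
                walk("M", k + 1, i + 1, acc + lt["t_im"][k] + em_m(k + 1, i))
                walk("I", k, i + 1, acc + lt["t_ii"][k] + em_i(i))
        else:  # D
            if k + 1 < L:
                if i < n:
                    walk("M", k + 1, i + 1, acc + lt["t_dm"][k] + em_m(k + 1, i))
                walk("D", k + 1, i, acc + lt["t_dd"][k])

    for s in range(L):
        for a in range(n):
            walk("M", s, a + 1, en + em_m(s, a))
    return scores


def brute_viterbi(hmm, codes: np.ndarray) -> float:
    return max(enumerate_path_scores(hmm, codes))


def brute_forward(hmm, codes: np.ndarray) -> float:
    scores = enumerate_path_scores(hmm, codes)
    m = max(scores)
    return m + math.log2(sum(2.0 ** (s - m) for s in scores))


def brute_max_in_window(starts: list[int], window: int) -> int:
    """Max number of starts in any half-open window [w, w+window), by
    checking every window anchored at a gene start."""
    best = 0
    for w in starts:
        best = max(best, sum(1 for s in starts if w <= s < w + window))
    return best


def random_profile(rng: np.random.Generator, L: int):
    """A random, fully normalized ProfileHMM for oracle testing."""
    from shikscreen.profile_hmm import ProfileHMM

    me = rng.dirichlet(np.ones(20) * 0.5, size=L)
    bg = rng.dirichlet(np.ones(20) * 5.0)
    m_rows = rng.dirichlet(np.ones(3), size=L)
    i_rows = rng.dirichlet(np.ones(2), size=L)
    d_rows = rng.dirichlet(np.ones(2), size=L)
    m_rows[L - 1] = [1.0, 0.0, 0.0]
    i_rows[L - 1] = [1.0, 0.0]
    d_rows[L - 1] = [1.0, 0.0]
    return ProfileHMM(
        match_emissions=me,
        insert_emissions=rng.dirichlet(np.ones(20) * 5.0),
        background=bg,
        t_mm=m_rows[:, 0],
        t_mi=m_rows[:, 1],
        t_md=m_rows[:, 2],
        t_im=i_rows[:, 0],
        t_ii=i_rows[:, 1],
        t_dm=d_rows[:, 0],
        t_dd=d_rows[:, 1],
        name="random",
    )
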