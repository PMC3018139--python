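"""Profile hidden Markov models: build, score, calibrate.

A :class:`ProfileHMM` is a position-specific probabilistic model of a
protein family with match, insert and delete states. Sequences are
scored in single-hit local mode by dynamic programming, producing
log2-odds ("bit") scores against a background null model. Statistical
significance comes from an extreme-value (Gumbel) fit to the scores of
random background sequences, from which E-values are computed for a
database of a given size.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable

import numpy as np
from scipy import stats

from ._dp import forward_kernel, viterbi_kernel
from .alphabet import AMINO_ACIDS, BACKGROUND, encode_sequence
from .errors import CalibrationError, NoMatchStatesError, NotCalibratedError
from .msa import Alignment

PROFILE_FORMAT_VERSION = 1

#: Residues below this length are log-normal-sampled during calibration.
_MIN_CALIB_LENGTH = 30


@dataclass(frozen=True)
class Calibration:
    """Gumbel (type-I extreme value) fit to background bit scores.

    ``P(S > s) = 1 - exp(-exp(-lam * (s - mu)))``.
    """

    mu: float
    lam: float
    n_calib: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.lam > 0:
            raise ValueError("Gumbel scale parameter lambda must be > 0")

    def survival(self, bit_score: float) -> float:
        """Per-sequence probability of a background score above ``bit_score``."""
        return float(stats.gumbel_r.sf(bit_score, loc=self.mu, scale=1.0 / self.lam))


@dataclass(frozen=True)
class ScoredAlignment:
    """A scored local alignment of a protein against a profile.

    Spans are half-open: ``seq_span`` on the protein residues,
    ``model_span`` on the profile match states.
    """

    bit_score: float
    seq_span: tuple[int, int]
    model_span: tuple[int, int]


@dataclass
class ProfileHMM:
    """Position-specific emission/transition model of a protein family.

    Transition arrays are probability rows per source state index ``k``:
    ``t_mm/t_mi/t_md`` from match ``M_k``, ``t_im/t_ii`` from insert
    ``I_k``, ``t_dm/t_dd`` from delete ``D_k``. Rows at unused boundary
    indices are fixed to the deterministic "advance to match" move so
    every row still sums to one.
    """

    match_emissions: np.ndarray  # (L, 20)
    insert_emissions: np.ndarray  # (20,)
    background: np.ndarray  # (20,)
    t_mm: np.ndarray
    t_mi: np.ndarray
    t_md: np.ndarray
    t_im: np.ndarray
    t_ii: np.ndarray
    t_dm: np.ndarray
    t_dd: np.ndarray
    name: str = ""
    calibration: Calibration | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.match_emissions = np.asarray(self.match_emissions, dtype=float)
        self.insert_emissions = np.asarray(self.insert_emissions, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        L = self.length
        if L < 1:
            raise ValueError("profile must have at least one match state")
        if self.match_emissions.shape != (L, 20):
            raise ValueError("match_emissions must be (L, 20)")
        for nm in ("t_mm", "t_mi", "t_md", "t_im", "t_ii", "t_dm", "t_dd"):
            setattr(self, nm, np.asarray(getattr(self, nm), dtype=float))
            if getattr(self, nm).shape != (L,):
                raise ValueError(f"{nm} must have length L={L}")
        self._check_normalized()
        self._logs: dict | None = None

    # -- invariants ----------------------------------------------------
    def _check_normalized(self, tol: float = 1e-9) -> None:
        if not np.allclose(self.match_emissions.sum(axis=1), 1.0, atol=tol):
            raise ValueError("match emission rows must sum to 1")
        if not math.isclose(self.insert_emissions.sum(), 1.0, abs_tol=tol):
            raise ValueError("insert emissions must sum to 1")
        if not math.isclose(self.background.sum(), 1.0, abs_tol=tol):
            raise ValueError("background must sum to 1")
        m_rows = self.t_mm + self.t_mi + self.t_md
        i_rows = self.t_im + self.t_ii
        d_rows = self.t_dm + self.t_dd
        for nm, rows in (("match", m_rows), ("insert", i_rows), ("delete", d_rows)):
            if not np.allclose(rows, 1.0, atol=tol):
                raise ValueError(f"{nm} transition rows must sum to 1")

    @property
    def length(self) -> int:
        """Number of match states L."""
        return self.match_emissions.shape[0]

    @property
    def entry_bits(self) -> float:
        """Fixed entry/exit term: log2 of the uniform (entry, exit) pair
        probability 2 / (L (L+1))."""
        L = self.length
        return math.log2(2.0 / (L * (L + 1)))

    # -- scoring -------------------------------------------------------
    def _log_arrays(self) -> dict:
        if self._logs is None:
            with np.errstate(divide="ignore"):
                self._logs = {
                    "mat_lo": np.log2(self.match_emissions)
                    - np.log2(self.background)[None, :],
                    "ins_lo": np.log2(self.insert_emissions)
                    - np.log2(self.background),
                    "ltmm": np.log2(self.t_mm),
                    "ltmi": np.log2(self.t_mi),
                    "ltmd": np.log2(self.t_md),
                    "ltim": np.log2(self.t_im),
                    "ltii": np.log2(self.t_ii),
                    "ltdm": np.log2(self.t_dm),
                    "ltdd": np.log2(self.t_dd),
                }
        return self._logs

    def _viterbi_codes(self, codes: np.ndarray) -> ScoredAlignment:
        lg = self._log_arrays()
        score, si, ei, sk, ek = viterbi_kernel(
            codes,
            lg["mat_lo"],
            lg["ins_lo"],
            lg["ltmm"],
            lg["ltmi"],
            lg["ltmd"],
            lg["ltim"],
            lg["ltii"],
            lg["ltdm"],
            lg["ltdd"],
            self.entry_bits,
        )
        return ScoredAlignment(
            bit_score=float(score),
            seq_span=(int(si), int(ei)),
            model_span=(int(sk), int(ek)),
        )

    def _forward_codes(self, codes: np.ndarray) -> float:
        lg = self._log_arrays()
        return float(
            forward_kernel(
                codes,
                lg["mat_lo"],
                lg["ins_lo"],
                lg["ltmm"],
                lg["ltmi"],
                lg["ltmd"],
                lg["ltim"],
                lg["ltii"],
                lg["ltdm"],
                lg["ltdd"],
                self.entry_bits,
            )
        )


def build_profile(
    aln: Alignment,
    pseudocount_weight: float = 1.0,
    background: np.ndarray = BACKGROUND,
    name: str = "",
    max_gap_fraction: float = 0.5,
) -> ProfileHMM:
    """Estimate a profile HMM from a multiple sequence alignment.

    Columns with a gap fraction strictly greater than ``max_gap_fraction``
    (default 0.5) are treated as insert columns; the remaining columns
    become match states. Match emissions are
    ``(count + w * background) / (n_observed + w)`` with ``w`` the
    pseudocount weight; transitions are counted from the gap structure of
    each row (trimmed to its first/last emitted match residue, since entry
    and exit are local) with a uniform pseudocount of ``w / n_targets``
    per allowed move. Insert emissions are fixed at the background so
    inserted residues are score-neutral.
    """
    if pseudocount_weight < 0:
        raise ValueError("pseudocount_weight must be >= 0")
    background = np.asarray(background, dtype=float)
    background = background / background.sum()
    w = float(pseudocount_weight)

    n_rows, n_cols = aln.n_rows, aln.n_cols
    gap_frac = np.array(
        [sum(c in "-." for c in aln.column(j)) / n_rows for j in range(n_cols)]
    )
    is_match = gap_frac <= max_gap_fraction
    L = int(is_match.sum())
    if L == 0:
        raise NoMatchStatesError(
            "no match states: every alignment column is more than "
            f"{max_gap_fraction:.0%} gaps"
        )
    match_of_col = np.cumsum(is_match) - 1  # match index for match columns

    aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

    # emissions
    counts = np.zeros((L, 20))
    for row in aln.sequences:
        for j in range(n_cols):
            if is_match[j]:
                idx = aa_index.get(row[j])
                if idx is not None:
                    counts[match_of_col[j], idx] += 1
    denom = counts.sum(axis=1) + w
    match_em = np.empty_like(counts)
    for k in range(L):
        if denom[k] > 0:
            match_em[k] = (counts[k] + w * background) / denom[k]
        else:  # column of only ambiguity codes with zero pseudocount
            match_em[k] = background

    # transitions
    c_mm = np.zeros(L)
    c_mi = np.zeros(L)
    c_md = np.zeros(L)
    c_im = np.zeros(L)
    c_ii = np.zeros(L)
    c_dm = np.zeros(L)
    c_dd = np.zeros(L)
    n_match_upto = np.cumsum(is_match)  # match states at or before column j
    for row in aln.sequences:
        path: list[tuple[str, int]] = []
        for j in range(n_cols):
            ch = row[j]
            if is_match[j]:
                k = int(match_of_col[j])
                path.append(("M" if ch not in "-." else "D", k))
            elif ch not in "-.":
                # insert between match k and k+1; flanking inserts are
                # outside the local model
                k = int(n_match_upto[j]) - 1
                if 0 <= k <= L - 2:
                    path.append(("I", k))
        emit_pos = [t for t, (s, _) in enumerate(path) if s == "M"]
        if not emit_pos:
            continue  # row aligns no match residue: contributes no transitions
        trimmed = path[emit_pos[0] : emit_pos[-1] + 1]
        for (s1, k1), (s2, _k2) in zip(trimmed, trimmed[1:]):
            if s1 == "M":
                if s2 == "M":
                    c_mm[k1] += 1
                elif s2 == "I":
                    c_mi[k1] += 1
                else:
                    c_md[k1] += 1
            elif s1 == "I":
                if s2 == "M":
                    c_im[k1] += 1
                else:
                    c_ii[k1] += 1
            else:
                if s2 == "M":
                    c_dm[k1] += 1
                else:
                    c_dd[k1] += 1

    def _norm(rows: list[np.ndarray]) -> list[np.ndarray]:
        n_t = len(rows)
        stacked = np.stack(rows, axis=1) + w / n_t
        tot = stacked.sum(axis=1, keepdims=True)
        uniform = np.full(n_t, 1.0 / n_t)
        out = np.where(tot > 0, stacked / np.where(tot > 0, tot, 1.0), uniform)
        return [out[:, t] for t in range(n_t)]

    t_mm, t_mi, t_md = _norm([c_mm, c_mi, c_md])
    t_im, t_ii = _norm([c_im, c_ii])
    t_dm, t_dd = _norm([c_dm, c_dd])
    # boundary rows: no states beyond M_{L-1}
    t_mm[L - 1], t_mi[L - 1], t_md[L - 1] = 1.0, 0.0, 0.0
    t_im[L - 1], t_ii[L - 1] = 1.0, 0.0
    t_dm[L - 1], t_dd[L - 1] = 1.0, 0.0

    return ProfileHMM(
        match_emissions=match_em,
        insert_emissions=background.copy(),
        background=background,
        t_mm=t_mm,
        t_mi=t_mi,
        t_md=t_md,
        t_im=t_im,
        t_ii=t_ii,
        t_dm=t_dm,
        t_dd=t_dd,
        name=name,
        provenance={
            "builder": "shikscreen.build_profile",
            "n_rows": n_rows,
            "n_cols": n_cols,
            "pseudocount_weight": w,
            "max_gap_fraction": max_gap_fraction,
        },
    )


def viterbi_score(hmm: ProfileHMM, seq: str) -> ScoredAlignment:
    """Best local log2-odds alignment of ``seq`` against the profile."""
    codes = encode_sequence(seq)
    return hmm._viterbi_codes(codes)


def forward_score(hmm: ProfileHMM, seq: str) -> float:
    """Total log2-odds over all local alignments (log-sum over paths)."""
    codes = encode_sequence(seq)
    return hmm._forward_codes(codes)


def default_length_distribution(rng: np.random.Generator, size: int) -> np.ndarray:
    """Log-normal protein lengths, median 300 residues, sigma 0.4."""
    lengths = np.rint(rng.lognormal(math.log(300.0), 0.4, size=size)).astype(int)
    return np.maximum(lengths, _MIN_CALIB_LENGTH)


def calibrate(
    hmm: ProfileHMM,
    n_samples: int = 200,
    length_distribution: Callable[[np.random.Generator, int], np.ndarray]
    | None = None,
    seed: int = 0,
) -> ProfileHMM:
    """Fit the E-value null: score random background sequences and fit a
    Gumbel distribution to the resulting bit scores by maximum likelihood.

    Returns a new profile with ``calibration`` set; reproducible for a
    fixed seed.
    """
    if n_samples < 50:
        raise ValueError("n_samples must be >= 50 for a stable Gumbel fit")
    if length_distribution is None:
        length_distribution = default_length_distribution
    rng = np.random.default_rng(seed)
    lengths = np.asarray(length_distribution(rng, n_samples), dtype=int)
    scores = np.empty(n_samples)
    for i, n in enumerate(lengths):
        codes = rng.choice(20, size=int(n), p=hmm.background).astype(np.int64)
        scores[i] = hmm._viterbi_codes(codes).bit_score
    if np.std(scores) < 1e-12:
        raise CalibrationError(
            f"degenerate calibration score distribution for profile {hmm.name!r}"
        )
    loc, scale = stats.gumbel_r.fit(scores)
    cal = Calibration(mu=float(loc), lam=1.0 / float(scale), n_calib=n_samples, seed=seed)
    return replace(hmm, calibration=cal)


def evalue(hmm: ProfileHMM, bit_score: float, database_size: int) -> float:
    """Expected number of background hits scoring above ``bit_score`` in a
    database of ``database_size`` sequences."""
    if hmm.calibration is None:
        raise NotCalibratedError(
            f"profile {hmm.name!r} has no E-value calibration; run calibrate() first"
        )
    if database_size < 1:
        raise ValueError("database_size must be >= 1")
    return database_size * hmm.calibration.survival(bit_score)


def coverage(
    sa: ScoredAlignment,
    hmm: ProfileHMM,
    mode: str = "model",
    seq_length: int | None = None,
) -> float:
    """Fraction of the profile's match states (mode="model") or of the
    query protein (mode="sequence") spanned by the alignment."""
    if mode == "model":
        return (sa.model_span[1] - sa.model_span[0]) / hmm.length
    if mode == "sequence":
        if seq_length is None:
            raise ValueError("sequence-mode coverage needs seq_length")
        return (sa.seq_span[1] - sa.seq_span[0]) / seq_length
    raise ValueError(f"unknown coverage mode {mode!r}")


# -- serialization -----------------------------------------------------


def profile_to_dict(hmm: ProfileHMM) -> dict:
    doc = {
        "format": "shikscreen-profile",
        "version": PROFILE_FORMAT_VERSION,
        "name": hmm.name,
        "length": hmm.length,
        "alphabet": AMINO_ACIDS,
        "match_emissions": hmm.match_emissions.tolist(),
        "insert_emissions": hmm.insert_emissions.tolist(),
        "background": hmm.background.tolist(),
        "transitions": {
            nm: getattr(hmm, nm).tolist()
            for nm in ("t_mm", "t_mi", "t_md", "t_im", "t_ii", "t_dm", "t_dd")
        },
        "provenance": hmm.provenance,
    }
    if hmm.calibration is not None:
        c = hmm.calibration
        doc["calibration"] = {
            "mu": c.mu,
            "lambda": c.lam,
            "n_calib": c.n_calib,
            "seed": c.seed,
        }
    return doc


def profile_from_dict(doc: dict) -> ProfileHMM:
    if doc.get("format") != "shikscreen-profile":
        raise ValueError("not a shikscreen profile document")
    if doc.get("version") != PROFILE_FORMAT_VERSION:
        raise ValueError(f"unsupported profile version {doc.get('version')!r}")
    cal = None
    if "calibration" in doc:
        c = doc["calibration"]
        cal = Calibration(
            mu=c["mu"], lam=c["lambda"], n_calib=c["n_calib"], seed=c.get("seed")
        )
    tr = doc["transitions"]
    return ProfileHMM(
        match_emissions=np.array(doc["match_emissions"]),
        insert_emissions=np.array(doc["insert_emissions"]),
        background=np.array(doc["background"]),
        name=doc.get("name", ""),
        calibration=cal,
        provenance=doc.get("provenance", {}),
        **{nm: np.array(tr[nm]) for nm in tr},
    )


def write_profile(hmm: ProfileHMM, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(profile_to_dict(hmm), fh, indent=1)
        fh.write("\n")


def read_profile(path: str | Path) -> ProfileHMM:
    with open(path) as fh:
        return profile_from_dict(json.load(fh))
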