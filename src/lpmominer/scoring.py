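"""Log-space Forward and Viterbi scoring over a profile HMM.

All dynamic programming is done with natural logarithms; bit scores
(``log2`` of the Forward odds ratio against the null model) appear only at
the reporting boundary. Ambiguity codes (X/B/Z/U/O) emit with the same
probability (1/K) in every emitting state *and* in the null model, so their
log-odds contribution is exactly zero.

Viterbi ties are broken deterministically: among equal-scoring predecessors
the state kind order is B < M < I < D, then the lower node index wins.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .hmm import ProfileHMM, NullModel
from .io_formats import Sequence

NEG_INF = -np.inf


def encode(residues: str, alphabet: str) -> np.ndarray:
    """Map residues to alphabet indices; ambiguity codes map to -1."""
    idx = {a: i for i, a in enumerate(alphabet)}
    out = np.empty(len(residues), dtype=np.int64)
    for i, ch in enumerate(residues):
        if ch in idx:
            out[i] = idx[ch]
        elif ch in "XBZUO":
            out[i] = -1
        else:
            raise ValueError(f"residue {ch!r} not in model alphabet")
    return out


def _logs(hmm: ProfileHMM) -> dict:
    """Natural-log model parameters, cached on the model object."""
    cached = hmm.__dict__.get("_log_cache")
    if cached is not None:
        return cached
    with np.errstate(divide="ignore"):
        logs = {
            "mat": np.log(hmm.match_emissions),
            "ins": np.log(hmm.insert_emissions),
            "lq": np.log(hmm.null.q),
            "t": {k: np.log(v) for k, v in hmm.transitions.items()},
        }
    logs["le"] = -math.log(hmm.M)
    logs["lpf"] = math.log(hmm.p_flank) if hmm.p_flank > 0 else NEG_INF
    logs["l1pf"] = math.log1p(-hmm.p_flank)
    logs["lamb"] = -math.log(hmm.K)     # ambiguity emission, every state
    hmm.__dict__["_log_cache"] = logs
    return logs


def null_logprob(seq, null: NullModel) -> float:
    """ln P(seq) under the i.i.d. background with geometric length."""
    residues = seq.residues if isinstance(seq, Sequence) else seq
    x = encode(residues, null.alphabet)
    with np.errstate(divide="ignore"):
        lq = np.log(null.q)
    lamb = -math.log(len(null.alphabet))
    em = np.where(x >= 0, lq[np.maximum(x, 0)], lamb)
    return math.log1p(-null.p1) + len(x) * math.log(null.p1) + float(em.sum())


def forward_batch(hmm: ProfileHMM, X: np.ndarray) -> np.ndarray:
    """Forward log-probabilities for ``n`` equal-length encoded sequences.

    ``X`` is an ``(n, L)`` integer array (-1 for ambiguity codes). Returns
    an ``(n,)`` array of natural-log probabilities.
    """
    lg = _logs(hmm)
    M = hmm.M
    t = lg["t"]
    n, L = X.shape
    if L == 0:
        return np.full(n, NEG_INF)

    fN = np.zeros(n)
    fB = fN + lg["l1pf"]
    fM = np.full((n, M + 1), NEG_INF)
    fI = np.full((n, M + 1), NEG_INF)
    fD = np.full((n, M + 1), NEG_INF)
    fC = np.full(n, NEG_INF)

    lme = t["ME"][1:]
    for i in range(L):
        r = X[:, i]
        amb = r < 0
        ra = np.maximum(r, 0)
        eM = lg["mat"][1:, :].T[ra]          # (n, M)
        eI = lg["ins"][1:, :].T[ra]
        lqr = lg["lq"][ra]
        if amb.any():
            eM[amb] = lg["lamb"]
            eI[amb] = lg["lamb"]
            lqr = np.where(amb, lg["lamb"], lqr)

        newM = np.full((n, M + 1), NEG_INF)
        prev = np.logaddexp(fM[:, 0:M] + t["MM"][0:M],
                            fI[:, 0:M] + t["IM"][0:M])
        prev = np.logaddexp(prev, fD[:, 0:M] + t["DM"][0:M])
        prev = np.logaddexp(prev, fB[:, None] + lg["le"])
        newM[:, 1:] = eM + prev

        newI = np.full((n, M + 1), NEG_INF)
        newI[:, 1:] = eI + np.logaddexp(
            np.logaddexp(fM[:, 1:] + t["MI"][1:], fI[:, 1:] + t["II"][1:]),
            fD[:, 1:] + t["DI"][1:],
        )

        newD = np.full((n, M + 1), NEG_INF)
        for k in range(2, M + 1):
            src = np.logaddexp(newM[:, k - 1] + t["MD"][k - 1],
                               newI[:, k - 1] + t["ID"][k - 1])
            newD[:, k] = np.logaddexp(src, newD[:, k - 1] + t["DD"][k - 1])

        with np.errstate(invalid="ignore"):
            stack = newM[:, 1:] + lme
        mmax = stack.max(axis=1)
        safe = mmax > NEG_INF
        fE = np.full(n, NEG_INF)
        if safe.any():
            fE[safe] = mmax[safe] + np.log(
                np.exp(stack[safe] - mmax[safe, None]).sum(axis=1))
        fE = np.logaddexp(fE, newD[:, M])

        fN = fN + lg["lpf"] + lqr
        fC = np.logaddexp(fC + lg["lpf"] + lqr, fE)
        fB = fN + lg["l1pf"]
        fM, fI, fD = newM, newI, newD

    return fC + lg["l1pf"]


def forward(hmm: ProfileHMM, seq) -> float:
    """ln P(seq | model), summed over all state paths."""
    residues = seq.residues if isinstance(seq, Sequence) else seq
    x = encode(residues, hmm.alphabet)
    return float(forward_batch(hmm, x[None, :])[0])


@dataclass
class StatePath:
    """A state path through the model; 1-based sequence positions."""

    steps: list   # (kind in {N,B,M,I,D,E,C}, node, pos or None)

    def match_positions(self) -> dict:
        """node -> sequence position for every M step."""
        return {node: pos for kind, node, pos in self.steps if kind == "M"}

    def envelope(self):
        pos = [p for kind, _, p in self.steps if kind == "M"]
        return (min(pos), max(pos)) if pos else None


def viterbi(hmm: ProfileHMM, seq):
    """Best state path and its log probability.

    Returns ``(log_p, StatePath)``. Ties are broken toward B < M < I < D
    and then toward the lower node index (see module docstring).
    """
    residues = seq.residues if isinstance(seq, Sequence) else seq
    x = encode(residues, hmm.alphabet)
    lg = _logs(hmm)
    M, L = hmm.M, len(x)
    t = lg["t"]

    # value arrays indexed [i][k]; pointer arrays record predecessor codes
    vN = np.full(L + 1, NEG_INF)
    vC = np.full(L + 1, NEG_INF)
    vM = np.full((L + 1, M + 1), NEG_INF)
    vI = np.full((L + 1, M + 1), NEG_INF)
    vD = np.full((L + 1, M + 1), NEG_INF)
    vE = np.full(L + 1, NEG_INF)
    pM = np.zeros((L + 1, M + 1), dtype=np.int8)   # 0=B 1=M 2=I 3=D
    pI = np.zeros((L + 1, M + 1), dtype=np.int8)   # 1=M 2=I 3=D
    pD = np.zeros((L + 1, M + 1), dtype=np.int8)
    pE = np.zeros(L + 1, dtype=np.int32)           # node of best M (or -1: D_M)
    pC = np.zeros(L + 1, dtype=np.int8)            # 0=from E, 1=loop

    vN[0] = 0.0

    def em(row, k, r):
        return lg["lamb"] if r < 0 else row[k, r]

    for i in range(1, L + 1):
        r = x[i - 1]
        lqr = lg["lamb"] if r < 0 else lg["lq"][r]
        vN[i] = vN[i - 1] + lg["lpf"] + lqr
        vB_prev = vN[i - 1] + lg["l1pf"]
        for k in range(1, M + 1):
            # priority order: B, M, I, D; strict > keeps the earliest best
            best, ptr = vB_prev + lg["le"], 0
            cand = vM[i - 1, k - 1] + t["MM"][k - 1]
            if cand > best:
                best, ptr = cand, 1
            cand = vI[i - 1, k - 1] + t["IM"][k - 1]
            if cand > best:
                best, ptr = cand, 2
            cand = vD[i - 1, k - 1] + t["DM"][k - 1]
            if cand > best:
                best, ptr = cand, 3
            vM[i, k] = em(lg["mat"], k, r) + best
            pM[i, k] = ptr

            best, ptr = vM[i - 1, k] + t["MI"][k], 1
            cand = vI[i - 1, k] + t["II"][k]
            if cand > best:
                best, ptr = cand, 2
            cand = vD[i - 1, k] + t["DI"][k]
            if cand > best:
                best, ptr = cand, 3
            vI[i, k] = em(lg["ins"], k, r) + best
            pI[i, k] = ptr
        for k in range(2, M + 1):
            best, ptr = vM[i, k - 1] + t["MD"][k - 1], 1
            cand = vI[i, k - 1] + t["ID"][k - 1]
            if cand > best:
                best, ptr = cand, 2
            cand = vD[i, k - 1] + t["DD"][k - 1]
            if cand > best:
                best, ptr = cand, 3
            vD[i, k] = best
            pD[i, k] = ptr
        # E: lower node index wins ties; D_M considered last
        best, ptr = NEG_INF, 0
        for k in range(1, M + 1):
            cand = vM[i, k] + t["ME"][k]
            if cand > best:
                best, ptr = cand, k
        if vD[i, M] > best:
            best, ptr = vD[i, M], -1
        vE[i], pE[i] = best, ptr
        # C: entering from E preferred over looping on ties
        if vE[i] >= vC[i - 1] + lg["lpf"] + lqr:
            vC[i], pC[i] = vE[i], 0
        else:
            vC[i], pC[i] = vC[i - 1] + lg["lpf"] + lqr, 1

    log_p = vC[L] + lg["l1pf"] if L > 0 else NEG_INF
    if not np.isfinite(log_p):
        return NEG_INF, StatePath([("N", 0, None)])

    # traceback
    steps: list = []
    i = L
    while i > 0 and pC[i] == 1:
        steps.append(("C", 0, i))
        i -= 1
    steps.append(("E", 0, None))
    if pE[i] == -1:
        kind, k = "D", M
    else:
        kind, k = "M", pE[i]
    while True:
        if kind == "M":
            steps.append(("M", k, i))
            ptr = pM[i, k]
            i -= 1
            if ptr == 0:
                break
            kind = {1: "M", 2: "I", 3: "D"}[ptr]
            k -= 1
        elif kind == "I":
            steps.append(("I", k, i))
            ptr = pI[i, k]
            i -= 1
            kind = {1: "M", 2: "I", 3: "D"}[ptr]
        else:
            steps.append(("D", k, None))
            ptr = pD[i, k]
            kind = {1: "M", 2: "I", 3: "D"}[ptr]
            k -= 1
    steps.append(("B", 0, None))
    while i > 0:
        steps.append(("N", 0, i))
        i -= 1
    steps.reverse()
    return float(log_p), StatePath(steps)


def bit_score(hmm: ProfileHMM, seq) -> float:
    """log2 odds of the Forward probability against the null model."""
    return (forward(hmm, seq) - null_logprob(seq, hmm.null)) / math.log(2)


def bit_scores_batch(hmm: ProfileHMM, X: np.ndarray) -> np.ndarray:
    """Bit scores for equal-length encoded sequences (used by calibration)."""
    fwd = forward_batch(hmm, X)
    lg = _logs(hmm)
    em = np.where(X >= 0, lg["lq"][np.maximum(X, 0)], lg["lamb"]).sum(axis=1)
    null = math.log1p(-hmm.null.p1) + X.shape[1] * math.log(hmm.null.p1) + em
    return (fwd - null) / math.log(2)


@dataclass
class ScoreResult:
    """Full scoring record for one sequence against one model."""

    log_p_model: float
    log_p_viterbi: float
    bit_score: float
    path: StatePath
    envelope: tuple | None


def score(hmm: ProfileHMM, seq) -> ScoreResult:
    """Forward + Viterbi scoring with alignment envelope."""
    fwd = forward(hmm, seq)
    vit, path = viterbi(hmm, seq)
    null = null_logprob(seq, hmm.null)
    return ScoreResult(
        log_p_model=fwd,
        log_p_viterbi=vit,
        bit_score=(fwd - null) / math.log(2),
        path=path,
        envelope=path.envelope(),
    )


# --------------------------------------------------------------------------
# bias-composition filter
# --------------------------------------------------------------------------

@dataclass
class MaskResult:
    """Low-complexity masking outcome."""

    masked: str               # residues, flagged windows replaced by 'X'
    intervals: list           # merged (start, end), 1-based inclusive
    masked_fraction: float


def _window_entropy(window: str) -> float:
    counts: dict = {}
    for ch in window:
        counts[ch] = counts.get(ch, 0) + 1
    n = len(window)
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


def bias_mask(seq, W: int = 40, H_min: float = 2.2) -> MaskResult:
    """Mask low-complexity windows by Shannon entropy.

    Every length-``W`` window (step 1) with entropy below ``H_min`` bits is
    flagged; flagged windows are merged and their residues replaced by 'X'
    (which scores at background). Sequences shorter than ``W`` are treated
    as a single whole-sequence window.
    """
    residues = seq.residues if isinstance(seq, Sequence) else seq
    L = len(residues)
    if L == 0:
        raise ValueError("cannot mask an empty sequence")
    flagged = np.zeros(L, dtype=bool)
    if L < W:
        if _window_entropy(residues) < H_min:
            flagged[:] = True
    else:
        for s in range(L - W + 1):
            if _window_entropy(residues[s:s + W]) < H_min:
                flagged[s:s + W] = True
    intervals = []
    i = 0
    while i < L:
        if flagged[i]:
            j = i
            while j + 1 < L and flagged[j + 1]:
                j += 1
            intervals.append((i + 1, j + 1))
            i = j + 1
        else:
            i += 1
    chars = list(residues)
    for s, e in intervals:
        for p in range(s - 1, e):
            chars[p] = "X"
    return MaskResult("".join(chars), intervals, flagged.mean())
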