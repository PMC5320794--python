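"""Independent brute-force oracle: exhaustive state-path enumeration.

Written against the model *definition* (linear-space recursion over explicit
paths), not the DP implementation, so it can certify the Forward and Viterbi
recurrences on small models.
"""
import math

import numpy as np

from lpmominer.hmm import NullModel, ProfileHMM

TRANS_KEYS = ("MM", "MI", "MD", "ME", "IM", "II", "ID", "DM", "DI", "DD")


def random_small_model(rng, M=None, K=4, alphabet="ACGT"):
    """A random valid model over a reduced alphabet."""
    if M is None:
        M = int(rng.integers(1, 5))
    alphabet = alphabet[:K]
    q = rng.dirichlet(np.ones(K))
    null = NullModel(q, rng.uniform(0.2, 0.8), alphabet)
    mat = np.zeros((M + 1, K))
    ins = np.zeros((M + 1, K))
    mat[0] = q
    ins[0] = q
    for k in range(1, M + 1):
        mat[k] = rng.dirichlet(np.ones(K))
        ins[k] = rng.dirichlet(np.ones(K))
    eps = rng.uniform(0.0, 0.3)
    t = {key: np.zeros(M + 1) for key in TRANS_KEYS}
    for k in range(1, M):
        m = rng.dirichlet(np.ones(3)) * (1 - eps)
        t["MM"][k], t["MI"][k], t["MD"][k] = m
        t["ME"][k] = eps
        i_ = rng.dirichlet(np.ones(3))
        t["IM"][k], t["II"][k], t["ID"][k] = i_
        if k >= 2:
            d = rng.dirichlet(np.ones(3))
            t["DM"][k], t["DI"][k], t["DD"][k] = d
    t["ME"][M] = 1.0
    return ProfileHMM(alphabet=alphabet, match_emissions=mat,
                      insert_emissions=ins, transitions=t, null=null,
                      epsilon=eps, p_flank=float(rng.uniform(0.0, 0.6)))


def enumerate_paths(hmm, x):
    """(ln sum, ln max) over all state paths emitting exactly ``x``."""
    M = hmm.M
    t = hmm.transitions
    L = len(x)
    q = hmm.null.q
    pf = hmm.p_flank
    probs = []

    def finish(p, i):
        for j in range(i, L):
            p *= pf * q[x[j]]
        probs.append(p * (1 - pf))

    def core(state, k, i, p):
        if p == 0.0:
            return
        if state == "M":
            if i >= L:
                return
            p *= hmm.match_emissions[k][x[i]]
            i += 1
            if k == M:
                finish(p, i)
                return
            finish(p * t["ME"][k], i)
            core("M", k + 1, i, p * t["MM"][k])
            core("I", k, i, p * t["MI"][k])
            core("D", k + 1, i, p * t["MD"][k])
        elif state == "I":
            if i >= L:
                return
            p *= hmm.insert_emissions[k][x[i]]
            i += 1
            core("M", k + 1, i, p * t["IM"][k])
            core("I", k, i, p * t["II"][k])
            core("D", k + 1, i, p * t["ID"][k])
        else:
            if k == M:
                finish(p, i)
                return
            core("M", k + 1, i, p * t["DM"][k])
            core("I", k, i, p * t["DI"][k])
            core("D", k + 1, i, p * t["DD"][k])

    for n0 in range(0, L + 1):
        p = 1.0 - pf
        for j in range(n0):
            p *= pf * q[x[j]]
        for k in range(1, M + 1):
            core("M", k, n0, p / M)
    if not probs:
        return -math.inf, -math.inf
    return math.log(sum(probs)), math.log(max(probs))
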