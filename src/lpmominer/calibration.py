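"""Gumbel E-value calibration and the trusted-cutoff procedure.

Profile-search bit scores of unrelated sequences follow an extreme-value
(Gumbel) law. The calibration simulates i.i.d. background sequences, scores
them against the model, and fits location ``mu`` and scale ``lambda`` by
maximum likelihood; E-values then follow as

    E(s) = Z * (1 - exp(-exp(-lambda * (s - mu))))

with ``Z`` the effective database size. The trusted cutoff takes the
E-value of the lowest-scoring curated true positive: by construction every
labeled positive scores at or below it, so sensitivity on the labeled set
is exactly 100%.
"""
from __future__ import annotations

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp

from .hmm import GumbelParams, ProfileHMM, Thresholds
from .scoring import bit_scores_batch


class CalibrationError(RuntimeError):
    """Raised when the Gumbel fit cannot be performed."""


def fit_gumbel(scores, n_sim: int = 0, seed: int = 0) -> GumbelParams:
    """Maximum-likelihood Gumbel fit to a score sample.

    ``lambda`` solves the standard one-dimensional MLE equation by root
    finding; ``mu`` follows in closed form.
    """
    s = np.asarray(scores, dtype=float)
    if s.std() == 0:
        raise CalibrationError("all calibration scores identical; cannot fit")
    mean = s.mean()

    def mle_eq(lam: float) -> float:
        w = -lam * s
        w = w - w.max()
        e = np.exp(w)
        return 1.0 / lam - mean + float((s * e).sum() / e.sum())

    lo = 1e-8
    hi = 2.0 / s.std()
    while mle_eq(hi) > 0:
        hi *= 2.0
        if hi > 1e6:
            raise CalibrationError("Gumbel MLE did not bracket a root")
    lam = brentq(mle_eq, lo, hi, xtol=1e-12)
    mu = -(logsumexp(-lam * s) - np.log(len(s))) / lam
    return GumbelParams(mu=float(mu), lam=float(lam),
                        n_sim=n_sim or len(s), seed=seed)


def calibrate_gumbel(hmm: ProfileHMM, n_sim: int = 500, L_cal: int = 350,
                     seed: int = 0) -> GumbelParams:
    """Simulate null sequences, score them, and fit the Gumbel null law.

    Deterministic given ``seed``. ``L_cal`` is a fixed calibration length
    rather than one matched per target (documented simplification).
    """
    if n_sim < 50:
        raise ValueError("n_sim must be at least 50")
    rng = np.random.default_rng(seed)
    X = rng.choice(hmm.K, size=(n_sim, L_cal), p=hmm.null.q)
    scores = bit_scores_batch(hmm, X)
    return fit_gumbel(scores, n_sim=n_sim, seed=seed)


def evalue(score_bits: float, gumbel: GumbelParams, Z: float) -> float:
    """Expected number of false positives at or above ``score_bits``."""
    if Z < 1:
        raise ValueError("Z must be at least 1")
    u = np.exp(-gumbel.lam * (np.asarray(score_bits, dtype=float) - gumbel.mu))
    E = Z * -np.expm1(-u)
    return float(E) if np.ndim(score_bits) == 0 else E


def trusted_cutoff(evalues_of_true_positives) -> float:
    """E-value of the lowest-scoring labeled true positive (the maximum
    E-value in the set); everything scoring better is trusted."""
    evals = list(evalues_of_true_positives)
    if not evals:
        raise ValueError("need at least one labeled true positive")
    return max(evals)


def calibrate(hmm: ProfileHMM, positives=None, Z: float | None = None,
              n_sim: int = 500, L_cal: int = 350, seed: int = 0,
              default_E: float = 1e-3) -> ProfileHMM:
    """Attach Gumbel parameters (and thresholds, if positives are given)
    to the model in place, returning it for chaining."""
    hmm.gumbel = calibrate_gumbel(hmm, n_sim=n_sim, L_cal=L_cal, seed=seed)
    if positives is not None:
        from .scoring import bit_score

        z = Z if Z is not None else max(len(positives), 1)
        evals = [evalue(bit_score(hmm, p), hmm.gumbel, z) for p in positives]
        hmm.thresholds = Thresholds(trusted_E=trusted_cutoff(evals),
                                    default_E=default_E, Z=z)
    return hmm
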