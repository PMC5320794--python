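"""Profile hidden Markov models of protein families.

The model follows the classic match/insert/delete profile architecture with
single-hit local alignment:

* ``M_k``, ``I_k``, ``D_k`` core states for nodes ``k = 1..M``;
* uniform entry ``B -> M_k`` with probability ``1/M`` (local in the model);
* early exit ``M_k -> E`` with a constant probability ``epsilon`` for
  ``k < M``; ``M_M -> E = 1`` and ``D_M -> E = 1``;
* unaligned flanks ``N`` (before) and ``C`` (after) that emit background
  residues with a self-loop probability ``p_flank``.

Tying ``p_flank`` to the null model's geometric length parameter ``p1``
makes flank residues cancel exactly in the log-odds score, so bit scores do
not depend on how much unrelated sequence surrounds the domain.

Probabilities are stored in linear space; the scoring layer takes logs once.
Node indexing is 1-based throughout (index 0 of per-node arrays is padding).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io_formats import AMINO_ACIDS, Alignment

#: Robinson & Robinson (1991) background amino-acid frequencies, the standard
#: null composition used by profile-search tools, in ACDEFGHIKLMNPQRSTVWY order.
ROBINSON_FREQS = np.array([
    0.078050, 0.019250, 0.053640, 0.062950, 0.038560,
    0.073770, 0.021990, 0.051420, 0.057440, 0.090190,
    0.022430, 0.044870, 0.052030, 0.042640, 0.051290,
    0.071200, 0.058410, 0.064410, 0.013300, 0.032160,
])
ROBINSON_FREQS = ROBINSON_FREQS / ROBINSON_FREQS.sum()

_PROB_TOL = 1e-12


class ModelError(ValueError):
    """Raised for invalid model parameters or model-building failures."""


@dataclass
class NullModel:
    """I.i.d. background model with geometric length distribution.

    P(x) = (1 - p1) * p1^L * prod_i q(x_i)
    """

    q: np.ndarray
    p1: float
    alphabet: str = AMINO_ACIDS

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if len(self.q) != len(self.alphabet):
            raise ModelError("null q length must match alphabet size")
        if abs(self.q.sum() - 1.0) > 1e-9 or (self.q < 0).any():
            raise ModelError("null q must be a probability distribution")
        if not (0.0 < self.p1 < 1.0):
            raise ModelError("p1 must lie in (0, 1)")

    @classmethod
    def standard(cls, expected_length: float = 350.0) -> "NullModel":
        """Robinson background with E[L] = expected_length."""
        p1 = expected_length / (expected_length + 1.0)
        return cls(ROBINSON_FREQS.copy(), p1)


@dataclass
class ModelAnnotations:
    """Hallmark-column metadata, as 1-based match-node indices."""

    brace1_col: int | None = None
    brace2_col: int | None = None
    motif_cols: tuple | None = None
    conserved_cols: list = field(default_factory=list)

    def validate(self, M: int) -> None:
        cols = list(self.conserved_cols)
        if self.brace1_col is not None:
            cols.append(self.brace1_col)
        if self.brace2_col is not None:
            cols.append(self.brace2_col)
        if self.motif_cols is not None:
            a, b, c = self.motif_cols
            if not (a < b < c and b == a + 1 and c == a + 2):
                raise ModelError("motif_cols must be consecutive and increasing")
            cols.extend(self.motif_cols)
        for c in cols:
            if not (1 <= c <= M):
                raise ModelError(f"annotation column {c} outside [1..{M}]")


@dataclass
class GumbelParams:
    """Fitted Gumbel null-score distribution (bit-score scale)."""

    mu: float
    lam: float
    n_sim: int
    seed: int

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ModelError("Gumbel lambda must be positive")


@dataclass
class Thresholds:
    """E-value cutoffs for reporting hits."""

    trusted_E: float
    default_E: float = 1e-3
    Z: float | None = None

    def __post_init__(self) -> None:
        import warnings

        if self.trusted_E <= 0 or self.default_E <= 0:
            raise ModelError("E-value thresholds must be positive")
        if self.trusted_E > self.default_E:
            warnings.warn(
                "trusted_E exceeds default_E; check the positive set",
                stacklevel=2,
            )


# transition keys and the nodes for which each is defined (see module docs)
_TRANS_KEYS = ("MM", "MI", "MD", "ME", "IM", "II", "ID", "DM", "DI", "DD")


@dataclass
class ProfileHMM:
    """A single-hit local profile HMM.

    ``match_emissions[k]`` / ``insert_emissions[k]`` are the emission
    distributions of node ``k`` (row 0 is padding; insert rows 0 and M are
    stored but unused by the search architecture). ``transitions[key][k]``
    is the probability of the key'd transition out of node ``k``.
    """

    alphabet: str
    match_emissions: np.ndarray      # (M+1, K), row 0 padding
    insert_emissions: np.ndarray     # (M+1, K)
    transitions: dict                # key -> (M+1,) arrays
    null: NullModel
    epsilon: float = 0.05
    p_flank: float | None = None     # defaults to null.p1
    annotations: ModelAnnotations = field(default_factory=ModelAnnotations)
    n_seqs: int | None = None
    gumbel: GumbelParams | None = None
    thresholds: Thresholds | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.p_flank is None:
            self.p_flank = self.null.p1
        self.match_emissions = np.asarray(self.match_emissions, dtype=float)
        self.insert_emissions = np.asarray(self.insert_emissions, dtype=float)
        self.validate()

    @property
    def M(self) -> int:
        return self.match_emissions.shape[0] - 1

    @property
    def K(self) -> int:
        return len(self.alphabet)

    def validate(self) -> None:
        M, K = self.M, self.K
        if M < 1:
            raise ModelError("model must have at least one match state")
        if self.match_emissions.shape != (M + 1, K):
            raise ModelError("match_emissions has wrong shape")
        if self.insert_emissions.shape != (M + 1, K):
            raise ModelError("insert_emissions shape must be (M+1, K)")
        for arr in (self.match_emissions[1:], self.insert_emissions):
            if (arr < -_PROB_TOL).any() or (arr > 1 + _PROB_TOL).any():
                raise ModelError("emission probabilities outside [0, 1]")
        if np.abs(self.match_emissions[1:].sum(axis=1) - 1).max() > _PROB_TOL:
            raise ModelError("a match emission row does not sum to 1")
        used_ins = self.insert_emissions[1:M] if M > 1 else np.empty((0, K))
        if used_ins.size and np.abs(used_ins.sum(axis=1) - 1).max() > _PROB_TOL:
            raise ModelError("an insert emission row does not sum to 1")
        t = self.transitions
        for key in _TRANS_KEYS:
            if key not in t or len(t[key]) != M + 1:
                raise ModelError(f"transition array {key!r} missing or wrong length")
        # M-state rows: k < M must satisfy MM+MI+MD+ME = 1; node M exits surely
        if M > 1:
            row = t["MM"][1:M] + t["MI"][1:M] + t["MD"][1:M] + t["ME"][1:M]
            if np.abs(row - 1).max() > _PROB_TOL:
                raise ModelError("a match-state transition row does not sum to 1")
            row = t["IM"][1:M] + t["II"][1:M] + t["ID"][1:M]
            if np.abs(row - 1).max() > _PROB_TOL:
                raise ModelError("an insert-state transition row does not sum to 1")
        if abs(t["ME"][M] - 1.0) > _PROB_TOL:
            raise ModelError("M_M -> E must have probability 1")
        if M > 2:
            row = t["DM"][2:M] + t["DI"][2:M] + t["DD"][2:M]
            if np.abs(row - 1).max() > _PROB_TOL:
                raise ModelError("a delete-state transition row does not sum to 1")
        if not (0.0 <= self.epsilon < 1.0):
            raise ModelError("epsilon must lie in [0, 1)")
        if not (0.0 <= self.p_flank < 1.0):
            raise ModelError("p_flank must lie in [0, 1)")
        self.annotations.validate(M)

    def consensus(self) -> str:
        """Highest-probability residue of each match node."""
        idx = self.match_emissions[1:].argmax(axis=1)
        return "".join(self.alphabet[i] for i in idx)

    def with_annotations(self, ann: ModelAnnotations) -> "ProfileHMM":
        ann.validate(self.M)
        return replace(self, annotations=ann)


@dataclass
class BuildConfig:
    """Parameters of model construction from an alignment."""

    alpha: float = 1.0            # background-proportional pseudocount mass
    epsilon: float = 0.05         # per-node early-exit probability
    gap_threshold: float = 0.5    # match column iff gap fraction < this
    weighting: bool = True        # Henikoff position-based weights
    null: NullModel | None = None
    # transition pseudocount vectors; the +1 Laplace default is flat, but
    # small training sets benefit from match-favoring priors
    trans_pseudo_m: tuple = (1.0, 1.0, 1.0)   # (MM, MI, MD)
    trans_pseudo_i: tuple = (1.0, 1.0, 1.0)   # (IM, II, ID)
    trans_pseudo_d: tuple = (1.0, 1.0, 1.0)   # (DM, DI, DD)


def assign_match_columns(aln: Alignment, gap_threshold: float = 0.5) -> list:
    """1-based alignment columns whose gap fraction is strictly below the
    threshold (ties go to insert)."""
    if aln.n_rows == 0:
        raise ModelError("empty alignment")
    cols = []
    for j in range(1, aln.n_columns + 1):
        col = aln.column(j)
        if col.count("-") / len(col) < gap_threshold:
            cols.append(j)
    if not cols:
        raise ModelError("alignment has no match columns (all too gappy)")
    return cols


def henikoff_weights(aln: Alignment, match_cols) -> np.ndarray:
    """Henikoff & Henikoff position-based sequence weights.

    Computed over match columns only; in a column with ``r`` distinct residue
    types, a sequence showing residue ``a`` (present in ``n_a`` rows)
    contributes ``1/(r * n_a)``; gaps contribute nothing. Weights are
    normalized to sum to the number of sequences.
    """
    if not match_cols:
        raise ModelError("need at least one match column")
    n = aln.n_rows
    raw = np.zeros(n)
    for j in match_cols:
        col = aln.column(j)
        counts: dict = {}
        for ch in col:
            if ch != "-":
                counts[ch] = counts.get(ch, 0) + 1
        r = len(counts)
        if r == 0:
            continue
        for i, ch in enumerate(col):
            if ch != "-":
                raw[i] += 1.0 / (r * counts[ch])
    total = raw.sum()
    if total == 0:
        return np.full(n, 1.0)
    return raw * (n / total)


def _column_states(row: str, match_set: set) -> list:
    """Core-state walk of one aligned row: list of (kind, node)."""
    states, node = [], 0
    for j, ch in enumerate(row, start=1):
        if j in match_set:
            node += 1
            states.append(("M" if ch != "-" else "D", node))
        elif ch != "-":
            states.append(("I", node))
    return states


def build_hmm(aln: Alignment, config: BuildConfig | None = None) -> ProfileHMM:
    """Estimate a profile HMM from a multiple alignment.

    Match emissions use weighted counts with background-proportional
    pseudocounts, ``e_k(a) = (c_k(a) + alpha*q(a)) / (C_k + alpha)``. Insert
    states emit the background. Core transitions come from weighted observed
    M/I/D transitions with a +1 Laplace pseudocount per allowed transition;
    entry, exit and flank probabilities follow the local single-hit
    architecture described in the module docstring.
    """
    cfg = config or BuildConfig()
    null = cfg.null or NullModel.standard()
    alphabet = null.alphabet
    K = len(alphabet)
    aa_index = {a: i for i, a in enumerate(alphabet)}

    match_cols = assign_match_columns(aln, cfg.gap_threshold)
    M = len(match_cols)
    match_set = set(match_cols)
    weights = (henikoff_weights(aln, match_cols) if cfg.weighting
               else np.ones(aln.n_rows))

    # --- emissions -------------------------------------------------------
    counts = np.zeros((M + 1, K))
    for i, row in enumerate(aln.rows):
        w = weights[i]
        for k, j in enumerate(match_cols, start=1):
            ch = row.residues[j - 1]
            if ch in aa_index:            # gaps and ambiguity codes skipped
                counts[k, aa_index[ch]] += w
    mat = np.empty((M + 1, K))
    mat[0] = null.q
    totals = counts[1:].sum(axis=1, keepdims=True)
    mat[1:] = (counts[1:] + cfg.alpha * null.q) / (totals + cfg.alpha)
    ins = np.tile(null.q, (M + 1, 1))

    # --- transitions -----------------------------------------------------
    tcounts = {key: np.zeros(M + 1) for key in _TRANS_KEYS}
    for i, row in enumerate(aln.rows):
        w = weights[i]
        states = _column_states(row.residues, match_set)
        for (k1, n1), (k2, _n2) in zip(states, states[1:]):
            key = k1 + k2
            if key in tcounts:
                tcounts[key][n1] += w

    pm = np.asarray(cfg.trans_pseudo_m, dtype=float)
    pi = np.asarray(cfg.trans_pseudo_i, dtype=float)
    pd_ = np.asarray(cfg.trans_pseudo_d, dtype=float)
    t = {key: np.zeros(M + 1) for key in _TRANS_KEYS}
    for k in range(1, M):
        m = np.array([tcounts["MM"][k], tcounts["MI"][k], tcounts["MD"][k]]) + pm
        m = m / m.sum() * (1.0 - cfg.epsilon)
        t["MM"][k], t["MI"][k], t["MD"][k] = m
        t["ME"][k] = cfg.epsilon
        i_ = np.array([tcounts["IM"][k], tcounts["II"][k], tcounts["ID"][k]]) + pi
        i_ = i_ / i_.sum()
        t["IM"][k], t["II"][k], t["ID"][k] = i_
        if k >= 2:
            d = np.array([tcounts["DM"][k], tcounts["DI"][k], tcounts["DD"][k]]) + pd_
            d = d / d.sum()
            t["DM"][k], t["DI"][k], t["DD"][k] = d
    t["ME"][M] = 1.0

    return ProfileHMM(
        alphabet=alphabet,
        match_emissions=mat,
        insert_emissions=ins,
        transitions=t,
        null=null,
        epsilon=cfg.epsilon,
        n_seqs=aln.n_rows,
        name="",
    )


@dataclass
class AnnotationRules:
    """Knobs for automatic hallmark-column detection."""

    h_min: float = 0.7            # minimum H frequency at each brace column
    brace_override: tuple | None = None
    motif_override: tuple | None = None
    conserved_min: float = 0.9    # G/P conservation floor


def annotate_model(hmm: ProfileHMM, aln: Alignment,
                   rules: AnnotationRules | None = None) -> ModelAnnotations:
    """Locate hallmark columns (histidine brace, N/Q/E-X-F/Y motif,
    conserved glycines/proline) in the training alignment.

    Frequencies are taken over non-gap residues of each match column. The
    brace is the pair of columns with the highest H frequency (each at least
    ``h_min``); the motif is the consecutive node triple C-terminal of the
    second brace column maximizing ``freq([NQE]) + freq([FY])`` at its outer
    positions. Explicit overrides win.
    """
    rules = rules or AnnotationRules()
    match_cols = assign_match_columns(aln)
    if len(match_cols) != hmm.M:
        raise ModelError("alignment does not match the model's architecture")

    def freqs(node: int) -> dict:
        col = aln.column(match_cols[node - 1])
        residues = [c for c in col if c != "-"]
        n = len(residues)
        out: dict = {}
        for ch in residues:
            out[ch] = out.get(ch, 0) + 1
        return {ch: c / n for ch, c in out.items()} if n else {}

    M = hmm.M
    fr = {k: freqs(k) for k in range(1, M + 1)}

    if rules.brace_override is not None:
        brace1, brace2 = rules.brace_override
    else:
        h = [(fr[k].get("H", 0.0), k) for k in range(1, M + 1)]
        top = sorted(h, key=lambda p: (-p[0], p[1]))[:2]
        if len(top) < 2 or min(f for f, _ in top) < rules.h_min:
            raise ModelError(
                "no column pair reaches the histidine-frequency floor "
                f"({rules.h_min}); annotate the brace manually"
            )
        brace1, brace2 = sorted(k for _, k in top)

    if rules.motif_override is not None:
        motif = tuple(rules.motif_override)
    else:
        best, motif = -1.0, None
        for k in range(brace2 + 1, M - 1):
            score = (sum(fr[k].get(a, 0.0) for a in "NQE")
                     + sum(fr[k + 2].get(a, 0.0) for a in "FY"))
            if score > best:
                best, motif = score, (k, k + 1, k + 2)
        if motif is None:
            raise ModelError("no room for a motif triple after the brace")

    special = {brace1, brace2, *motif}
    conserved = [
        k for k in range(1, M + 1)
        if k not in special
        and max(fr[k].get("G", 0.0), fr[k].get("P", 0.0)) >= rules.conserved_min
    ]
    ann = ModelAnnotations(brace1, brace2, motif, conserved)
    ann.validate(M)
    return ann


# --------------------------------------------------------------------------
# LPHMM1 text format
# --------------------------------------------------------------------------

def _fmt(values) -> str:
    with np.errstate(divide="ignore"):
        logs = np.log(np.asarray(values, dtype=float))
    return " ".join("-inf" if v == -np.inf else f"{v:.12e}" for v in logs)


def _parse(tokens) -> np.ndarray:
    return np.exp(np.array([float(t) for t in tokens]))


def save_hmm(hmm: ProfileHMM, path) -> None:
    """Write a model in the plain-text LPHMM1 format.

    The format stores natural-log probabilities at full precision, a header
    with the null model, architecture constants and annotations, optional
    calibration/threshold blocks, then one NODE block per match node.
    """
    a = hmm.annotations
    lines = ["LPHMM1"]
    if hmm.name:
        lines.append(f"NAME {hmm.name}")
    lines.append(f"ALPH {hmm.alphabet}")
    lines.append(f"M {hmm.M}")
    if hmm.n_seqs is not None:
        lines.append(f"NSEQ {hmm.n_seqs}")
    lines.append(f"EPSILON {hmm.epsilon:.12e}")
    lines.append(f"PFLANK {hmm.p_flank:.12e}")
    lines.append(f"P1 {hmm.null.p1:.12e}")
    lines.append("NULL " + _fmt(hmm.null.q))
    ann_parts = []
    if a.brace1_col is not None:
        ann_parts.append(f"brace1={a.brace1_col}")
    if a.brace2_col is not None:
        ann_parts.append(f"brace2={a.brace2_col}")
    if a.motif_cols is not None:
        ann_parts.append("motif=" + ",".join(map(str, a.motif_cols)))
    if a.conserved_cols:
        ann_parts.append("conserved=" + ",".join(map(str, a.conserved_cols)))
    if ann_parts:
        lines.append("ANNOT " + " ".join(ann_parts))
    if hmm.gumbel is not None:
        g = hmm.gumbel
        lines.append(f"GUMBEL mu={g.mu:.12e} lambda={g.lam:.12e} "
                     f"n_sim={g.n_sim} seed={g.seed}")
    if hmm.thresholds is not None:
        th = hmm.thresholds
        z = "none" if th.Z is None else f"{th.Z:.12e}"
        lines.append(f"THRESH trusted={th.trusted_E:.12e} "
                     f"default={th.default_E:.12e} Z={z}")
    for k in range(1, hmm.M + 1):
        lines.append(f"NODE {k}")
        lines.append("  MATCH " + _fmt(hmm.match_emissions[k]))
        lines.append("  INSERT " + _fmt(hmm.insert_emissions[k]))
        tr = " ".join(
            f"{key}={'-inf' if hmm.transitions[key][k] == 0 else format(np.log(hmm.transitions[key][k]), '.12e')}"
            for key in _TRANS_KEYS
        )
        lines.append("  TRANS " + tr)
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_hmm(path) -> ProfileHMM:
    """Read a model written by :func:`save_hmm`."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines or lines[0] != "LPHMM1":
        raise ModelError(f"{path}: not an LPHMM1 file")
    header: dict = {}
    i = 1
    while i < len(lines) and not lines[i].startswith("NODE "):
        if lines[i].strip():
            key, _, rest = lines[i].partition(" ")
            header[key] = rest
        i += 1
    try:
        alphabet = header["ALPH"]
        M = int(header["M"])
        eps = float(header["EPSILON"])
        p_flank = float(header["PFLANK"])
        p1 = float(header["P1"])
        q = _parse(header["NULL"].split())
    except KeyError as exc:
        raise ModelError(f"{path}: missing header field {exc}") from exc

    K = len(alphabet)
    mat = np.zeros((M + 1, K))
    ins = np.zeros((M + 1, K))
    mat[0] = q
    ins[0] = q
    t = {key: np.zeros(M + 1) for key in _TRANS_KEYS}
    nodes_seen = 0
    while i < len(lines):
        line = lines[i].strip()
        if line == "END":
            break
        if not line.startswith("NODE "):
            raise ModelError(f"{path}: unexpected line {line!r}")
        k = int(line.split()[1])
        try:
            mat[k] = _parse(lines[i + 1].split()[1:])
            ins[k] = _parse(lines[i + 2].split()[1:])
            for item in lines[i + 3].split()[1:]:
                key, _, val = item.partition("=")
                t[key][k] = 0.0 if val == "-inf" else float(np.exp(float(val)))
        except (IndexError, ValueError) as exc:
            raise ModelError(f"{path}: truncated or corrupt NODE {k}") from exc
        nodes_seen += 1
        i += 4
    else:
        raise ModelError(f"{path}: missing END marker (truncated file)")
    if nodes_seen != M:
        raise ModelError(
            f"{path}: header declares M={M} but found {nodes_seen} nodes"
        )

    ann = ModelAnnotations()
    if "ANNOT" in header:
        for item in header["ANNOT"].split():
            key, _, val = item.partition("=")
            if key == "brace1":
                ann.brace1_col = int(val)
            elif key == "brace2":
                ann.brace2_col = int(val)
            elif key == "motif":
                ann.motif_cols = tuple(int(x) for x in val.split(","))
            elif key == "conserved":
                ann.conserved_cols = [int(x) for x in val.split(",")]
    gumbel = None
    if "GUMBEL" in header:
        kv = dict(item.split("=") for item in header["GUMBEL"].split())
        gumbel = GumbelParams(float(kv["mu"]), float(kv["lambda"]),
                              int(kv["n_sim"]), int(kv["seed"]))
    thresholds = None
    if "THRESH" in header:
        kv = dict(item.split("=") for item in header["THRESH"].split())
        z = None if kv["Z"] == "none" else float(kv["Z"])
        thresholds = Thresholds(float(kv["trusted"]), float(kv["default"]), z)

    return ProfileHMM(
        alphabet=alphabet,
        match_emissions=mat,
        insert_emissions=ins,
        transitions=t,
        null=NullModel(q, p1, alphabet),
        epsilon=eps,
        p_flank=p_flank,
        annotations=ann,
        n_seqs=int(header["NSEQ"]) if "NSEQ" in header else None,
        gumbel=gumbel,
        thresholds=thresholds,
        name=header.get("NAME", ""),
    )
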