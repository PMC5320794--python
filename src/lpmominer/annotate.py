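"""Hallmark-feature annotation of candidate LPMO proteins.

An LPMO hit is annotated for the features practitioners curate by hand:
a secretion signal (with an explicit heuristic, since neural predictors
notoriously miss the weak cleavage sites of some LPMO families), the
copper-binding histidine brace, the N/Q/E-X-F/Y active-site motif, S/T/A
rich linker regions and CBM1 carbohydrate-binding modules, assembled into a
domain-architecture summary string.

The signal-peptide call is a classic three-part heuristic: a positively
charged n-region, a hydrophobic h-region (mean Kyte-Doolittle hydropathy of
some run of at least six residues >= 1.5) and an A-X-A-style (-3,-1)
cleavage-site rule. Because mature LPMOs start with the brace histidine, a
cleavage candidate followed by 'H' is preferred; a call that only that
preference selected is flagged ``weak`` rather than silently accepted.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .hmm import ProfileHMM
from .io_formats import Sequence
from .scoring import StatePath, score

#: Kyte & Doolittle (1982) hydropathy index.
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

_MINUS1_SET = set("AGSCTQ")     # small/neutral residues allowed at -1
_MINUS3_SET = set("AGSCTVIL")   # at -3
_POSITIVE = set("KR")
_NEGATIVE = set("DE")


@dataclass
class SignalPeptideCall:
    """Outcome of the secretion-signal heuristic."""

    present: bool
    cleavage_after: int | None = None   # mature protein starts at +1
    weak: bool = False

    @property
    def mature_start(self) -> int:
        return (self.cleavage_after + 1) if self.present else 1


def _hydropathy(residues: str) -> float:
    vals = [KYTE_DOOLITTLE.get(ch, 0.0) for ch in residues]
    return sum(vals) / len(vals)


def _h_region_start(residues: str, c: int) -> int | None:
    """Earliest start of a >=6-residue run with mean hydropathy >= 1.5
    inside positions [c-12, c-1]; None if no such run."""
    lo = max(1, c - 12)
    hi = c - 1
    for start in range(lo, hi - 4):
        for end in range(start + 5, hi + 1):
            if _hydropathy(residues[start - 1:end]) >= 1.5:
                return start
    return None


def call_signal_peptide(seq) -> SignalPeptideCall:
    """Heuristic secretion-signal detection (see module docstring)."""
    residues = seq.residues if isinstance(seq, Sequence) else seq
    if len(residues) < 30:
        return SignalPeptideCall(False)
    valid = []
    for c in range(10, min(45, len(residues) - 1) + 1):
        if residues[c - 1] not in _MINUS1_SET:
            continue
        if c - 3 < 0 or residues[c - 3] not in _MINUS3_SET:
            continue
        h_start = _h_region_start(residues, c)
        if h_start is None:
            continue
        n_region = residues[:h_start - 1]
        charge = (sum(ch in _POSITIVE for ch in n_region)
                  - sum(ch in _NEGATIVE for ch in n_region))
        if charge < 0:
            continue
        valid.append(c)
    if not valid:
        return SignalPeptideCall(False)
    his_sites = [c for c in valid if c < len(residues) and residues[c] == "H"]
    if his_sites:
        chosen = his_sites[0]
        return SignalPeptideCall(True, chosen, weak=chosen != valid[0])
    return SignalPeptideCall(True, valid[0], weak=False)


@dataclass
class BraceResult:
    ok: bool
    pos1: int | None = None
    pos2: int | None = None
    reason: str = ""


def check_histidine_brace(seq, signal: SignalPeptideCall, hmm: ProfileHMM,
                          path: StatePath) -> BraceResult:
    """The brace holds iff the mature protein's first residue is H and the
    residue aligned to the second brace column is H."""
    residues = seq.residues if isinstance(seq, Sequence) else seq
    pos1 = signal.mature_start
    if pos1 > len(residues) or residues[pos1 - 1] != "H":
        return BraceResult(False, pos1, None,
                           f"mature residue 1 (position {pos1}) is not H")
    node2 = hmm.annotations.brace2_col
    if node2 is None:
        return BraceResult(False, pos1, None, "model has no brace annotation")
    match_pos = path.match_positions()
    if node2 not in match_pos:
        return BraceResult(False, pos1, None, "column deleted")
    pos2 = match_pos[node2]
    if residues[pos2 - 1] != "H":
        return BraceResult(False, pos1, pos2,
                           f"second brace position {pos2} is "
                           f"{residues[pos2 - 1]!r}, not H")
    return BraceResult(True, pos1, pos2)


@dataclass
class MotifResult:
    status: str                  # canonical | variant | absent
    residues: tuple = ()
    positions: tuple = ()


def check_motif(seq, hmm: ProfileHMM, path: StatePath) -> MotifResult:
    """Match the residues aligned to the motif columns against [NQE]-X-[FY].

    A mismatch only at the first position while the third matches is a
    ``variant`` (a warning level, never a rejection — characterized LPMOs
    with an alanine there exist); anything else non-canonical is ``absent``.
    """
    residues = seq.residues if isinstance(seq, Sequence) else seq
    cols = hmm.annotations.motif_cols
    if cols is None:
        return MotifResult("absent")
    match_pos = path.match_positions()
    obs, pos = [], []
    for node in cols:
        if node in match_pos:
            p = match_pos[node]
            obs.append(residues[p - 1])
            pos.append(p)
        else:
            obs.append("-")
            pos.append(0)
    first_ok = obs[0] in "NQE"
    third_ok = obs[2] in "FY"
    if first_ok and third_ok:
        status = "canonical"
    elif third_ok:
        status = "variant"
    else:
        status = "absent"
    return MotifResult(status, tuple(obs), tuple(pos))


def find_linkers(seq, w: int = 20, frac: float = 0.6,
                 min_len: int = 15) -> list:
    """Merged spans covered by any window with S/T/A fraction >= ``frac``;
    spans shorter than ``min_len`` are dropped. 1-based inclusive."""
    residues = seq.residues if isinstance(seq, Sequence) else seq
    L = len(residues)
    if L < w:
        return []
    is_sta = [ch in "STA" for ch in residues]
    covered = [False] * L
    run = sum(is_sta[:w])
    for s in range(L - w + 1):
        if s > 0:
            run += is_sta[s + w - 1] - is_sta[s - 1]
        if run / w >= frac:
            for p in range(s, s + w):
                covered[p] = True
    spans, i = [], 0
    while i < L:
        if covered[i]:
            j = i
            while j + 1 < L and covered[j + 1]:
                j += 1
            if j - i + 1 >= min_len:
                spans.append((i + 1, j + 1))
            i = j + 1
        else:
            i += 1
    return spans


def find_cbm1(seq, cbm1_model: ProfileHMM, e_cutoff: float = 1e-3,
              max_copies: int = 10) -> list:
    """CBM1 spans: envelopes with E <= ``e_cutoff`` under the sub-model.

    Detected envelopes are masked and the search repeated, so multiple
    non-overlapping copies are reported. The sub-model must be calibrated.
    """
    from .calibration import evalue

    if cbm1_model.gumbel is None:
        raise ValueError("CBM1 sub-model is not calibrated; run calibrate")
    residues = seq.residues if isinstance(seq, Sequence) else seq
    Z = cbm1_model.thresholds.Z if cbm1_model.thresholds else 1.0
    spans = []
    for _ in range(max_copies):
        res = score(cbm1_model, residues)
        if res.envelope is None:
            break
        E = evalue(res.bit_score, cbm1_model.gumbel, Z)
        if E > e_cutoff:
            break
        s, e = res.envelope
        spans.append((s, e))
        residues = residues[:s - 1] + "X" * (e - s + 1) + residues[e:]
    return sorted(spans)


@dataclass
class ArchitectureReport:
    """Assembled hallmark annotation of one protein (Fig-4-style summary)."""

    signal: SignalPeptideCall
    brace: BraceResult
    motif: MotifResult
    linker_spans: list = field(default_factory=list)
    cbm1_spans: list = field(default_factory=list)
    conserved_checks: dict = field(default_factory=dict)
    architecture: str = ""


def build_architecture(seq, hmm: ProfileHMM, hit=None,
                       cbm1_model: ProfileHMM | None = None) -> ArchitectureReport:
    """Run every hallmark check and render an ordered architecture string
    such as ``SP-LPMO-linker-CBM1``."""
    residues = seq.residues if isinstance(seq, Sequence) else seq
    result = hit if hit is not None else score(hmm, residues)
    signal = call_signal_peptide(residues)
    brace = check_histidine_brace(residues, signal, hmm, result.path)
    motif = check_motif(residues, hmm, result.path)
    linkers = find_linkers(residues)
    cbm1 = (find_cbm1(residues, cbm1_model)
            if cbm1_model is not None else [])

    conserved = {}
    match_pos = result.path.match_positions()
    for node in hmm.annotations.conserved_cols:
        expected = hmm.alphabet[hmm.match_emissions[node].argmax()]
        if node in match_pos:
            obs = residues[match_pos[node] - 1]
            conserved[node] = (obs == expected, obs)
        else:
            conserved[node] = (False, "-")

    elements = []
    if signal.present:
        elements.append((1, "SP"))
    env = result.envelope
    core_start = env[0] if env else signal.mature_start
    elements.append((core_start, "LPMO"))
    core_end = env[1] if env else len(residues)
    for s, e in linkers:
        # a span wholly inside the core is part of the domain, not a linker
        if e > core_end:
            elements.append((max(s, core_end + 1), "linker"))
        elif e < core_start:
            elements.append((s, "linker"))
    for s, _e in cbm1:
        elements.append((s, "CBM1"))
    elements.sort()
    arch = "-".join(name for _, name in elements)

    return ArchitectureReport(
        signal=signal, brace=brace, motif=motif,
        linker_spans=linkers, cbm1_spans=cbm1,
        conserved_checks=conserved, architecture=arch,
    )
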