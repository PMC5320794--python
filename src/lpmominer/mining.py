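"""End-to-end proteome mining and family assignment.

``mine`` scores every protein of a proteome against the combined model,
applies an E-value threshold (the conservative trusted cutoff or the
relaxed default of 1e-3), annotates hits for hallmark features and assigns
each to a known family — or flags it as a novel-family candidate when no
family sub-model scores E <= ``family_cutoff_E``.

The bias-composition filter is opt-in and off by default: profile searches
for LPMOs must run unfiltered to keep true positives whose domains contain
genuinely biased (e.g. S/T-rich) regions.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .annotate import build_architecture
from .calibration import evalue
from .hmm import ProfileHMM, Thresholds
from .scoring import bias_mask, score


class MiningError(RuntimeError):
    """Raised for unusable mining inputs (e.g. an uncalibrated model)."""


@dataclass
class FamilyModelSet:
    """The combined detection model plus per-family sub-models."""

    combined: ProfileHMM
    per_family: dict = field(default_factory=dict)
    family_cutoff_E: float = 1e-5
    cbm1: ProfileHMM | None = None

    def __post_init__(self) -> None:
        for name, model in self.per_family.items():
            if model.alphabet != self.combined.alphabet:
                raise MiningError(f"family model {name!r} uses a different "
                                  "alphabet than the combined model")


REPORT_COLUMNS = [
    "protein_id", "bits", "evalue", "threshold", "family",
    "architecture", "brace_ok", "motif_status", "bias_filtered",
    "masked_intervals", "env_from", "env_to",
]


@dataclass
class MiningReport:
    """Tabular mining outcome (one row per reported hit)."""

    table: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)

    def ids(self) -> list:
        return list(self.table["protein_id"])


#: match-favoring transition pseudocount vectors used for family sub-models,
#: whose training subsets are small (down to one sequence): flat +1 Laplace
#: would put ~0.5 on M->M and swamp the signal with transition penalties.
FAMILY_TRANS_PSEUDO = {
    "trans_pseudo_m": (0.90, 0.05, 0.05),
    "trans_pseudo_i": (0.70, 0.25, 0.05),
    "trans_pseudo_d": (0.70, 0.05, 0.25),
}


def build_family_models(aln, family_map: dict, config=None,
                        single_seq_alpha: float = 2.0,
                        calibration_seed: int = 0, n_sim: int = 500) -> dict:
    """Per-family profile HMMs from family subsets of the training
    alignment, with match-favoring transition priors suited to small
    subsets; single-sequence families get a moderately larger emission
    pseudocount mass. Each sub-model is calibrated."""
    from dataclasses import replace as dc_replace

    from .calibration import calibrate_gumbel
    from .hmm import BuildConfig, build_hmm
    from .io_formats import Alignment

    cfg = config or BuildConfig()
    cfg = dc_replace(cfg, **FAMILY_TRANS_PSEUDO)
    models = {}
    families = sorted(set(family_map.values()))
    for fam in families:
        rows = [r for r in aln.rows if family_map.get(r.id) == fam]
        if not rows:
            continue
        sub_cfg = (dc_replace(cfg, alpha=single_seq_alpha)
                   if len(rows) == 1 else cfg)
        model = build_hmm(Alignment(rows), sub_cfg)
        model.name = fam
        model.gumbel = calibrate_gumbel(model, n_sim=n_sim,
                                        seed=calibration_seed)
        models[fam] = model
    return models


def assign_family(protein, models: FamilyModelSet, Z: float = 1.0):
    """Best family by E-value if any reaches the family cutoff, else
    ``novel-candidate``. Ties break toward the family trained on more
    sequences, then alphabetically."""
    from .scoring import bit_score

    best = None
    for fam in sorted(models.per_family):
        model = models.per_family[fam]
        if model.gumbel is None:
            raise MiningError(f"family model {fam!r} is not calibrated")
        E = evalue(bit_score(model, protein), model.gumbel, Z)
        n_train = model.n_seqs or 0
        key = (E, -n_train, fam)
        if best is None or key < best[0]:
            best = (key, fam, E)
    if best is None or best[2] > models.family_cutoff_E:
        return "novel-candidate", (best[2] if best else None)
    return best[1], best[2]


def mine(proteome, models: FamilyModelSet, thresholds: Thresholds | None = None,
         bias_filter: bool = False, threshold: str = "default",
         annotate: bool = True) -> MiningReport:
    """Scan a proteome and report every hit at the chosen threshold.

    ``threshold`` selects ``default`` (the relaxed 1e-3 cutoff) or
    ``trusted`` (the max E-value of the labeled positives). With
    ``bias_filter`` each protein is low-complexity masked before scoring.
    The result is a deterministic function of its inputs.
    """
    combined = models.combined
    if combined.gumbel is None:
        raise MiningError("combined model is not calibrated; run calibrate "
                          "before mining")
    th = thresholds or combined.thresholds
    if th is None:
        raise MiningError("no thresholds available; run calibrate with a "
                          "labeled positive set or pass thresholds")
    cutoff = th.trusted_E if threshold == "trusted" else th.default_E
    Z = th.Z if th.Z is not None else max(len(proteome), 1)

    from .scoring import bit_score as _bit_score

    rows = []
    for seq in proteome:
        if bias_filter:
            masked = bias_mask(seq)
            residues = masked.masked
            intervals = masked.intervals
        else:
            residues = seq.residues
            intervals = []
        bits = _bit_score(combined, residues)
        E = evalue(bits, combined.gumbel, Z)
        if E > cutoff:
            continue
        family, fam_E = assign_family(seq.residues, models, Z=Z)
        res = score(combined, seq.residues)     # Viterbi only for hits
        if annotate:
            report = build_architecture(seq.residues, combined, hit=res,
                                        cbm1_model=models.cbm1)
            arch = report.architecture
            brace_ok = report.brace.ok
            motif_status = report.motif.status
        else:
            arch, brace_ok, motif_status = "", None, ""
        env = res.envelope or (None, None)
        rows.append({
            "protein_id": seq.id,
            "bits": bits,
            "evalue": E,
            "threshold": cutoff,
            "family": family,
            "architecture": arch,
            "brace_ok": brace_ok,
            "motif_status": motif_status,
            "bias_filtered": bias_filter,
            "masked_intervals": ";".join(f"{s}-{e}" for s, e in intervals),
            "env_from": env[0],
            "env_to": env[1],
        })
    table = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    return MiningReport(table)


def neighbors(genes, gene_id: str, n: int = 1) -> list:
    """Up to ``n`` genes up- and downstream of ``gene_id`` on its contig,
    ordered by genomic distance."""
    by_id = {g.gene_id: g for g in genes}
    if gene_id not in by_id:
        raise KeyError(f"unknown gene id {gene_id!r}")
    target = by_id[gene_id]
    contig_genes = sorted((g for g in genes if g.contig == target.contig),
                          key=lambda g: g.start)
    idx = next(i for i, g in enumerate(contig_genes)
               if g.gene_id == gene_id)
    up = contig_genes[max(0, idx - n):idx][::-1]
    down = contig_genes[idx + 1:idx + 1 + n]
    out, i = [], 0
    while i < max(len(up), len(down)):
        if i < len(down):
            out.append(down[i])
        if i < len(up):
            out.append(up[i])
        i += 1
    out.sort(key=lambda g: abs((g.start + g.end) // 2
                               - (target.start + target.end) // 2))
    return out
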