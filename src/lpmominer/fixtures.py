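"""Seeded synthetic fixtures: training alignments, positives, decoys.

The package ships a synthetic 14-row training alignment emulating the
composition of the curated LPMO training set (4 AA9-like, 8 AA10-like,
1 AA11-like and 1 AA13-like rows). Its hallmark structure mirrors what the
real families share:

* an N-terminal histidine (match node 1) and a second conserved histidine
  (node 60) — the copper-binding histidine brace;
* the N/Q/E-X-F/Y active-site motif at nodes 80-82, with one AA10 row
  carrying an alanine at the first motif position (families genuinely
  contain such variants);
* three conserved glycines (nodes 20, 40, 70) and a proline (node 50);
* an S/T-rich conserved block (nodes 90-113), the kind of genuinely biased
  composition that composition filters are prone to masking;
* family-specific consensus residues at all remaining columns, so the
  families diverge everywhere outside the hallmarks, as real LPMO families
  do;
* a 6-column insertion private to the AA9-like rows and short deletions in
  the single-sequence rows, to exercise insert/delete states.

Everything here is a pure function of its seed; sequences carry provenance
in their FASTA descriptions so truth labels are machine-readable.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .hmm import ProfileHMM, NullModel
from .io_formats import Alignment, Sequence, aligned_row

# hallmark layout of the synthetic training model (1-based match nodes)
BRACE1_NODE = 1
BRACE2_NODE = 60
MOTIF_NODES = (80, 81, 82)
CONSERVED_NODES = (20, 40, 50, 70)     # G, G, P, G
ST_BLOCK = (90, 113)                   # inclusive node range, S/T-rich
N_CONSENSUS = 120
AA9_INSERT_AFTER = 30                  # 6 insert columns follow this node
TRAINING_SEED = 7
CBM1_SEED = 11

#: A designed secretion signal: positive charge, a leucine h-region, an
#: A-X-A cleavage site, and a histidine immediately after cleavage.
SIGNAL_PEPTIDE = "MKKLLLLLLLLLLASA"

_FAMILY_SIZES = {"AA9": 4, "AA10": 8, "AA11": 1, "AA13": 1}


@dataclass
class FixtureSpec:
    """Parameters of the mining fixture generator."""

    seed: int = 0
    n_positives: int = 5
    n_decoys: int = 50
    decoy_len: tuple = (100, 400)
    signal_peptide: bool = True
    linker: bool = False
    cbm1: bool = False
    low_complexity: bool = False
    mutation_rate: float = 0.5

    def __post_init__(self) -> None:
        if self.n_positives < 0 or self.n_decoys < 0:
            raise ValueError("fixture counts must be non-negative")
        if not (0.0 <= self.mutation_rate <= 1.0):
            raise ValueError("mutation rate must lie in [0, 1]")


def _draw(rng, q, alphabet) -> str:
    return alphabet[rng.choice(len(alphabet), p=q)]


def make_training_alignment(seed: int = TRAINING_SEED):
    """Synthetic 14-row training alignment and its id -> family map."""
    rng = np.random.default_rng(seed)
    null = NullModel.standard()
    alphabet, q = null.alphabet, null.q
    st_lo, st_hi = ST_BLOCK

    def st_residue(r) -> str:
        return r.choice(["S", "T", "A"], p=[0.55, 0.40, 0.05])

    shared = {BRACE1_NODE: "H", BRACE2_NODE: "H",
              MOTIF_NODES[0]: "N", MOTIF_NODES[2]: "F",
              CONSERVED_NODES[0]: "G", CONSERVED_NODES[1]: "G",
              CONSERVED_NODES[2]: "P", CONSERVED_NODES[3]: "G"}
    free_cols = [c for c in range(1, N_CONSENSUS + 1)
                 if c not in shared and not (st_lo <= c <= st_hi)
                 and c != MOTIF_NODES[1]]

    fam_consensus = {}
    for fam in _FAMILY_SIZES:
        cons = dict(shared)
        cons[MOTIF_NODES[1]] = _draw(rng, q, alphabet)
        for c in free_cols:
            cons[c] = _draw(rng, q, alphabet)
        fam_consensus[fam] = cons
    aa9_insert = "".join(_draw(rng, q, alphabet) for _ in range(6))

    rows, family_map = [], {}
    for fam, size in _FAMILY_SIZES.items():
        for i in range(1, size + 1):
            rid = f"{fam}_syn{i}"
            family_map[rid] = fam
            cons = fam_consensus[fam]
            residues = []
            for c in range(1, N_CONSENSUS + 1):
                if st_lo <= c <= st_hi:
                    residues.append(st_residue(rng))
                elif c in shared or c == MOTIF_NODES[1]:
                    residues.append(cons[c])
                elif rng.random() < 0.08:
                    residues.append(_draw(rng, q, alphabet))
                else:
                    residues.append(cons[c])
            # planted motif variant: one AA10 row has A at the first
            # motif position (alanine-for-asparagine substitution)
            if rid == "AA10_syn3":
                residues[MOTIF_NODES[0] - 1] = "A"
            # private deletions in the single-sequence families
            if fam == "AA11":
                for c in range(105, 109):
                    residues[c - 1] = "-"
            if fam == "AA13":
                for c in range(44, 47):
                    residues[c - 1] = "-"
            # AA9-private insertion block
            if fam == "AA9":
                ins = "".join(ch if rng.random() > 0.1
                              else _draw(rng, q, alphabet) for ch in aa9_insert)
            else:
                ins = "-" * 6
            aligned = ("".join(residues[:AA9_INSERT_AFTER]) + ins
                       + "".join(residues[AA9_INSERT_AFTER:]))
            rows.append(aligned_row(rid, aligned, f"family={fam} synthetic"))
    return Alignment(rows), family_map


def make_cbm1_alignment(seed: int = CBM1_SEED) -> Alignment:
    """Synthetic 8-row CBM1-like alignment (36 columns, aromatic-rich)."""
    rng = np.random.default_rng(seed)
    null = NullModel.standard()
    alphabet, q = null.alphabet, null.q
    planted = {5: "C", 10: "Y", 20: "C", 25: "W", 30: "Y"}
    cons = [planted.get(c, _draw(rng, q, alphabet)) for c in range(1, 37)]
    rows = []
    for i in range(1, 9):
        residues = [ch if (c + 1 in planted or rng.random() > 0.06)
                    else _draw(rng, q, alphabet)
                    for c, ch in enumerate(cons)]
        rows.append(aligned_row(f"CBM1_syn{i}", "".join(residues),
                                "family=CBM1 synthetic"))
    return Alignment(rows)


def load_training_alignment():
    """The packaged synthetic training alignment (and family map)."""
    from .io_formats import read_alignment

    path = resources.files("lpmominer").joinpath(
        "data/lpmo_training_synthetic.sto")
    with resources.as_file(path) as p:
        aln = read_alignment(p, "stockholm")
    family_map = {r.id: r.id.split("_")[0] for r in aln.rows}
    return aln, family_map


def load_cbm1_alignment() -> Alignment:
    from .io_formats import read_alignment

    path = resources.files("lpmominer").joinpath("data/cbm1_synthetic.sto")
    with resources.as_file(path) as p:
        return read_alignment(p, "stockholm")


# --------------------------------------------------------------------------
# generative sampling
# --------------------------------------------------------------------------

def _sample_one(hmm: ProfileHMM, rng, full_length: bool):
    """One core sample; returns (residues list, node-of-position list)."""
    t = hmm.transitions
    M = hmm.M
    residues, nodes = [], []
    k = 1 if full_length else int(rng.integers(1, M + 1))
    state = "M"
    while True:
        if state == "M":
            r = rng.choice(hmm.K, p=hmm.match_emissions[k])
            residues.append(hmm.alphabet[r])
            nodes.append(k)
            if k == M:
                break
            probs = np.array([t["MM"][k], t["MI"][k], t["MD"][k], t["ME"][k]])
            if full_length:
                probs[3] = 0.0
            probs = probs / probs.sum()
            choice = rng.choice(4, p=probs)
            if choice == 3:
                break
            state = "MID"[choice]
            if state != "I":
                k += 1
        elif state == "I":
            r = rng.choice(hmm.K, p=hmm.insert_emissions[k])
            residues.append(hmm.alphabet[r])
            nodes.append(0)
            probs = np.array([t["IM"][k], t["II"][k], t["ID"][k]])
            choice = rng.choice(3, p=probs / probs.sum())
            state = "MID"[choice]
            if state != "I":
                k += 1
        else:  # delete
            if k == M:
                break
            probs = np.array([t["DM"][k], t["DI"][k], t["DD"][k]])
            choice = rng.choice(3, p=probs / probs.sum())
            state = "MID"[choice]
            if state != "I":
                k += 1
    return residues, nodes


def sample_from_hmm(hmm: ProfileHMM, seed: int, n: int,
                    full_length: bool = True) -> list:
    """Generative samples of the model's core domain.

    With ``full_length`` the path enters at node 1 and early exits are
    suppressed, so every sample traverses the whole model; otherwise entry
    and exit follow the local-alignment architecture. Flank states are not
    sampled (callers add their own context).
    """
    rng = np.random.default_rng(seed)
    out = []
    for i in range(1, n + 1):
        residues, _ = _sample_one(hmm, rng, full_length)
        out.append(Sequence(f"sample{i:04d}", "".join(residues),
                            "label=model-sample synthetic"))
    return out


def _forced_core(hmm: ProfileHMM, rng, max_tries: int = 400,
                 guard: int = 4):
    """Full-length core sample with every hallmark node matched and set to
    its canonical residue.

    The sample is also required to be indel-free within ``guard`` nodes of
    each hallmark, so that alignment-based annotation finds the hallmark
    residues where the generative path put them (an indel right next to a
    hallmark lets the aligner slide the gap and look up the wrong residue).
    """
    ann = hmm.annotations
    forced = {}
    if ann.brace1_col:
        forced[ann.brace1_col] = "H"
    if ann.brace2_col:
        forced[ann.brace2_col] = "H"
    if ann.motif_cols:
        forced[ann.motif_cols[0]] = "N"
        forced[ann.motif_cols[2]] = "F"
    guarded = set()
    for node in forced:
        guarded.update(range(max(1, node - guard),
                             min(hmm.M, node + guard) + 1))
    for _ in range(max_tries):
        residues, nodes = _sample_one(hmm, rng, full_length=True)
        node_pos = {node: i for i, node in enumerate(nodes) if node > 0}
        if not all(node in node_pos for node in forced):
            continue
        clean = True
        for i, node in enumerate(nodes):
            if node == 0:  # insertion: check the flanking match nodes
                prev = nodes[i - 1] if i else 0
                if prev in guarded:
                    clean = False
                    break
        if clean and all(g in node_pos for g in guarded):
            for node, aa in forced.items():
                residues[node_pos[node]] = aa
            return "".join(residues)
    raise RuntimeError("could not sample a core visiting all hallmark nodes")


def _linker(rng, length: int = 30) -> str:
    return "".join(rng.choice(["S", "T", "A"], p=[0.45, 0.35, 0.20])
                   for _ in range(length))


def make_lpmo_fixture(spec: FixtureSpec, hmm: ProfileHMM,
                      cbm1_model: ProfileHMM | None = None) -> list:
    """Synthetic positive proteins with the canonical domain architecture.

    Each positive is a designed signal peptide (histidine at +1) followed by
    a full-length core sampled from the model with the brace and motif
    columns forced to their canonical residues, plus optional linker and
    CBM1 tail. With ``low_complexity`` an extra positive is added whose
    detectable homology lies entirely in the model's S/T-rich block,
    embedded in a 50-residue low-complexity run — the kind of true positive
    a composition filter removes.
    """
    rng = np.random.default_rng(spec.seed)
    null = hmm.null
    positives = []
    for i in range(1, spec.n_positives + 1):
        parts = []
        tags = ["label=positive"]
        if spec.signal_peptide:
            parts.append(SIGNAL_PEPTIDE)
            tags.append("signal=yes")
        parts.append(_forced_core(hmm, rng))
        if spec.linker:
            parts.append(_linker(rng))
            tags.append("linker=yes")
        if spec.cbm1:
            if cbm1_model is None:
                raise ValueError("cbm1 flag requires a CBM1 sub-model")
            core, _ = _sample_one(cbm1_model, rng, full_length=True)
            parts.append("".join(core))
            tags.append("cbm1=yes")
        positives.append(Sequence(f"POS{i:03d}", "".join(parts),
                                  " ".join(tags) + " synthetic"))
    if spec.low_complexity:
        st_lo, st_hi = ST_BLOCK
        segment = []
        for k in range(st_lo, st_hi + 1):
            r = rng.choice(hmm.K, p=hmm.match_emissions[k])
            segment.append(hmm.alphabet[r])
        pad = 50 - len(segment)
        run = "".join(segment) + "".join(
            rng.choice(["S", "T"]) for _ in range(max(pad, 0)))
        tail = "".join(_draw(rng, null.q, null.alphabet) for _ in range(30))
        positives.append(Sequence(
            "POSBIAS1", SIGNAL_PEPTIDE + run + tail,
            "label=positive low_complexity=yes synthetic"))
    return positives


def make_decoys(null: NullModel, seed: int, n: int,
                length_range: tuple = (100, 400)) -> list:
    """I.i.d. background sequences with uniform random lengths."""
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    out = []
    for i in range(1, n + 1):
        L = int(rng.integers(lo, hi + 1))
        residues = "".join(null.alphabet[j]
                           for j in rng.choice(len(null.alphabet), size=L,
                                               p=null.q))
        out.append(Sequence(f"DECOY{i:03d}", residues,
                            "label=decoy synthetic"))
    return out


def make_novel_candidates(aln, family_map: dict, combined: ProfileHMM,
                          family_models: dict | None = None,
                          seed: int = 0, n: int = 3,
                          mutation_rate: float = 0.6,
                          combined_E: float = 1e-3,
                          family_cutoff_E: float = 1e-5,
                          Z: float = 56.0, max_tries: int = 60) -> list:
    """Sequences that hit the combined model but no single family sub-model.

    A novel family shares the hallmarks and scattered residues with *every*
    known family without resembling any one of them, so candidates are
    built as per-column mosaics: at each family-discriminative column the
    residue comes from a uniformly chosen training family (or, at
    ``mutation_rate``, from the background); hallmark columns keep their
    canonical residues and the S/T-rich block is skipped (the novel family
    has its own architecture there). The combined model's mixture emissions
    credit every mosaic column while each single family matches only its
    own quarter.

    When ``family_models`` is provided each candidate is verified against
    the stated properties (combined E <= ``combined_E``, every family E >
    ``family_cutoff_E``) and resampled until it passes, so the returned
    set carries the novel-candidate property by construction.
    """
    from collections import defaultdict

    from .calibration import evalue
    from .hmm import assign_match_columns
    from .scoring import bit_score

    rng = np.random.default_rng(seed)
    ann = combined.annotations
    hallmark = {}
    if ann.brace1_col:
        hallmark[ann.brace1_col] = "H"
    if ann.brace2_col:
        hallmark[ann.brace2_col] = "H"
    if ann.motif_cols:
        hallmark[ann.motif_cols[0]] = "N"
        hallmark[ann.motif_cols[2]] = "F"
    conserved = set(ann.conserved_cols)
    mcols = assign_match_columns(aln)
    byfam = defaultdict(list)
    for r in aln.rows:
        byfam[family_map[r.id]].append(r)
    famnames = sorted(byfam)
    st_lo, st_hi = ST_BLOCK

    def one() -> str:
        residues = []
        for node in range(1, combined.M + 1):
            if st_lo <= node <= st_hi:
                continue
            if node in hallmark:
                residues.append(hallmark[node])
                continue
            if node in conserved:
                residues.append(
                    combined.alphabet[combined.match_emissions[node].argmax()])
                continue
            if rng.random() < mutation_rate:
                residues.append(_draw(rng, combined.null.q, combined.alphabet))
                continue
            ch = "-"
            while ch == "-":
                fam = famnames[rng.integers(len(famnames))]
                row = byfam[fam][rng.integers(len(byfam[fam]))]
                ch = row.residues[mcols[node - 1] - 1]
            residues.append(ch)
        return "".join(residues)

    def verified(s: str) -> bool:
        if family_models is None:
            return True
        cE = evalue(bit_score(combined, s), combined.gumbel, Z)
        if cE > combined_E:
            return False
        for m in family_models.values():
            if evalue(bit_score(m, s), m.gumbel, Z) <= family_cutoff_E:
                return False
        return True

    out = []
    for i in range(1, n + 1):
        for _ in range(max_tries):
            s = one()
            if verified(s):
                break
        else:
            raise RuntimeError("could not construct a verified novel "
                               "candidate; check the model set")
        out.append(Sequence(f"NOVEL{i:03d}", s,
                            "label=novel-candidate synthetic"))
    return out


def make_expression_fixture(seed: int, n_genes: int = 200,
                            n_conditions: int = 7, k_planted: int = 3,
                            separation: float = 5.0):
    """Planted-cluster expression matrix and its true labels.

    Cluster centers are drawn from N(0, separation^2) per condition and
    unit-variance Gaussian noise is added, so ``separation`` is the center
    spread in units of the within-cluster standard deviation.
    """
    if k_planted > n_genes:
        raise ValueError("k_planted cannot exceed n_genes")
    rng = np.random.default_rng(seed)
    centers = rng.normal(0.0, separation, size=(k_planted, n_conditions))
    labels = np.array([i % k_planted for i in range(n_genes)])
    rng.shuffle(labels)
    X = centers[labels] + rng.normal(0.0, 1.0, size=(n_genes, n_conditions))
    conditions = ["barley", "oat", "triticale", "alfalfa", "canola", "flax",
                  "glucose"][:n_conditions]
    if n_conditions > 7:
        conditions += [f"cond{i}" for i in range(8, n_conditions + 1)]
    genes = [f"g{i:04d}" for i in range(1, n_genes + 1)]
    df = pd.DataFrame(X, index=genes, columns=conditions)
    df.index.name = "gene"
    return df, pd.Series(labels, index=genes, name="cluster")


def make_gff_fixture(path) -> None:
    """A small GFF3 with a cellulolytic-cluster-style locus: the candidate
    gene g2 sits directly next to a glycoside-hydrolase-like gene g3."""
    lines = [
        "##gff-version 3",
        "chrI\tsyn\tgene\t1000\t2000\t.\t+\t.\tID=g1;product=unrelated",
        "chrI\tsyn\tgene\t5000\t6200\t.\t+\t.\tID=g2;product=lpmo-candidate",
        "chrI\tsyn\tgene\t6500\t8000\t.\t-\t.\tID=g3;product=gh55-like",
        "chrI\tsyn\tgene\t12000\t12900\t.\t+\t.\tID=g4;product=unrelated",
        "chrII\tsyn\tgene\t100\t900\t.\t+\t.\tID=g5;product=lonely",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
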