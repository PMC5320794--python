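"""Per-column sequence-logo statistics and a deterministic SVG renderer.

For each alignment column the logo reports residue frequencies normalized
over non-gap residues, the gap fraction (drawn as a bar), the information
content ``log2(20) - H`` with ``H`` the Shannon entropy of the frequency
vector, and a ``collapsed`` flag for columns without a clear consensus
(max frequency < 0.5), which are rendered as a single vertical bar.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import AMINO_ACIDS, Alignment

#: cinema-style color classes (polar positive blue, polar negative red,
#: polar neutral green, aliphatic grey, aromatic magenta, special cases).
CINEMA_PALETTE = {
    "H": "#0000ff", "K": "#0000ff", "R": "#0000ff",
    "D": "#ff0000", "E": "#ff0000",
    "N": "#008000", "Q": "#008000", "S": "#008000", "T": "#008000",
    "A": "#7f7f7f", "V": "#7f7f7f", "L": "#7f7f7f", "I": "#7f7f7f",
    "M": "#7f7f7f",
    "F": "#ff00ff", "W": "#ff00ff", "Y": "#ff00ff",
    "P": "#a52a2a", "G": "#a52a2a", "C": "#ffff00",
}

MAX_INFO = math.log2(20)


@dataclass
class LogoMatrix:
    """Column statistics backing a sequence logo."""

    freqs: pd.DataFrame        # columns x residues, rows sum to 1 (or 0)
    gap_fraction: np.ndarray
    info_bits: np.ndarray
    consensus: list
    collapsed: np.ndarray

    @property
    def n_columns(self) -> int:
        return len(self.freqs)


def logo_stats(aln: Alignment, weights=None) -> LogoMatrix:
    """Weighted per-column frequencies, gap fractions and information.

    ``weights`` defaults to equal sequence weights; frequencies are over
    non-gap residues only (ambiguity codes are ignored).
    """
    n, C = aln.n_rows, aln.n_columns
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if len(w) != n:
        raise ValueError("one weight per sequence required")
    aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}
    freqs = np.zeros((C, len(AMINO_ACIDS)))
    gap_fraction = np.zeros(C)
    info = np.zeros(C)
    consensus, collapsed = [], np.zeros(C, dtype=bool)
    for j in range(C):
        col = aln.column(j + 1)
        gap_w = sum(wi for wi, ch in zip(w, col) if ch == "-")
        gap_fraction[j] = gap_w / w.sum()
        for wi, ch in zip(w, col):
            if ch in aa_index:
                freqs[j, aa_index[ch]] += wi
        total = freqs[j].sum()
        if total > 0:
            freqs[j] /= total
            nz = freqs[j][freqs[j] > 0]
            entropy = float(-(nz * np.log2(nz)).sum())
            info[j] = MAX_INFO - entropy
            best = int(freqs[j].argmax())
            consensus.append(AMINO_ACIDS[best])
            collapsed[j] = freqs[j, best] < 0.5
        else:
            consensus.append("-")
            collapsed[j] = True
    return LogoMatrix(
        freqs=pd.DataFrame(freqs, columns=list(AMINO_ACIDS),
                           index=range(1, C + 1)),
        gap_fraction=gap_fraction,
        info_bits=info,
        consensus=consensus,
        collapsed=collapsed,
    )


def logo_table(matrix: LogoMatrix) -> pd.DataFrame:
    """TSV-friendly flat table of the logo statistics."""
    df = matrix.freqs.copy()
    df.insert(0, "column", df.index)
    df["gap_fraction"] = matrix.gap_fraction
    df["info_bits"] = matrix.info_bits
    df["consensus"] = matrix.consensus
    df["collapsed"] = matrix.collapsed
    return df.reset_index(drop=True)


def render_logo(matrix: LogoMatrix, path, col_width: int = 14,
                height: int = 160) -> None:
    """Write a deterministic SVG sequence logo.

    Letters are stacked by frequency with total stack height proportional
    to the column's information content; gap fractions appear as grey bars
    under the baseline; collapsed columns are drawn as a single vertical
    bar rather than letters.
    """
    C = matrix.n_columns
    pad = 24
    bar_h = 18
    usable = height - bar_h - 4
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" '
        f'width="{C * col_width + 2 * pad}" height="{height + 2 * pad}">',
        f'<g transform="translate({pad},{pad})">',
    ]
    for j in range(C):
        x = j * col_width
        if matrix.collapsed[j]:
            parts.append(
                f'<rect x="{x + col_width * 0.4:.1f}" y="0" '
                f'width="{col_width * 0.2:.1f}" height="{usable}" '
                f'fill="#404040"/>'
            )
        else:
            stack_h = usable * matrix.info_bits[j] / MAX_INFO
            y = usable
            freqs = matrix.freqs.iloc[j]
            for aa in sorted(AMINO_ACIDS, key=lambda a: (freqs[a], a)):
                f = freqs[aa]
                if f <= 0.0:
                    continue
                h = stack_h * f
                y -= h
                color = CINEMA_PALETTE[aa]
                scale = h / 12.0
                parts.append(
                    f'<text x="{(x + 1) / max(scale, 1e-9):.3f}" '
                    f'y="{(y + h) / max(scale, 1e-9):.3f}" '
                    f'font-family="monospace" font-size="12" '
                    f'fill="{color}" '
                    f'transform="scale({scale:.4f})">{aa}</text>'
                )
        gap_h = bar_h * matrix.gap_fraction[j]
        if gap_h > 0:
            parts.append(
                f'<rect x="{x + 1:.1f}" y="{usable + 4}" '
                f'width="{col_width - 2:.1f}" height="{gap_h:.2f}" '
                f'fill="#b0b0b0"/>'
            )
    parts.append("</g></svg>")
    with open(path, "w") as fh:
        fh.write("\n".join(parts) + "\n")
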