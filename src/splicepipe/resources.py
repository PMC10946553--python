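"""Built-in motif resources: splice-site frequency models and ESR hexamer tables.

The donor model covers a 9-mer spanning the last 3 exonic bases and the first
6 intronic bases (… e-3 e-2 e-1 | G T i+3 i+4 i+5 i+6).  The acceptor model
covers a 23-mer spanning intron -20 .. -1 and the first 3 exonic bases
(polypyrimidine tract, the AG dinucleotide, and the exon start).  The branch
point model is a 7-mer centred on the branch adenosine (yTnAynn).

Frequencies approximate the familiar human consensus (Shapiro–Senapathy-style
per-position base usage); they are the package defaults used both to *score*
sites and to *sample* true sites in the synthetic reference generator, so the
site models are learnable from generated data by construction.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

DONOR_WIDTH = 9
DONOR_EXONIC = 3  # exonic bases at the 5' end of the donor window
ACCEPTOR_WIDTH = 23
ACCEPTOR_INTRONIC = 20  # intronic bases at the 5' end of the acceptor window
BP_WIDTH = 7
BP_CENTER = 3  # index of the branch adenosine within the 7-mer

# rows: window positions, columns: A C G T
_DONOR_FREQS = np.array(
    [
        [0.33, 0.36, 0.18, 0.13],  # exon -3
        [0.60, 0.13, 0.14, 0.13],  # exon -2
        [0.08, 0.04, 0.81, 0.07],  # exon -1
        [0.004, 0.002, 0.992, 0.002],  # intron +1 (G)
        [0.002, 0.002, 0.004, 0.992],  # intron +2 (T)
        [0.55, 0.03, 0.37, 0.05],  # intron +3
        [0.71, 0.08, 0.12, 0.09],  # intron +4
        [0.06, 0.05, 0.82, 0.07],  # intron +5
        [0.17, 0.17, 0.21, 0.45],  # intron +6
    ]
)

_PPT_ROW = np.array([0.10, 0.31, 0.11, 0.48])


def _acceptor_freqs() -> np.ndarray:
    rows = []
    # intron -20 .. -6: polypyrimidine tract, mildly position-varying
    for k in range(15):
        jitter = 0.02 * np.sin(0.7 * k)
        row = _PPT_ROW + np.array([jitter, -jitter, 0.0, 0.0])
        rows.append(row)
    rows.append([0.24, 0.30, 0.22, 0.24])  # -5
    rows.append([0.24, 0.31, 0.21, 0.24])  # -4
    rows.append([0.06, 0.74, 0.06, 0.14])  # -3
    rows.append([0.992, 0.002, 0.004, 0.002])  # -2 (A)
    rows.append([0.002, 0.002, 0.992, 0.004])  # -1 (G)
    rows.append([0.24, 0.14, 0.49, 0.13])  # exon +1
    rows.append([0.28, 0.22, 0.25, 0.25])  # exon +2
    rows.append([0.24, 0.26, 0.26, 0.24])  # exon +3
    freqs = np.array(rows)
    return freqs / freqs.sum(axis=1, keepdims=True)


_ACCEPTOR_FREQS = _acceptor_freqs()

_BP_FREQS = np.array(
    [
        [0.18, 0.32, 0.14, 0.36],  # -3 (y)
        [0.12, 0.24, 0.10, 0.54],  # -2 (T-rich)
        [0.22, 0.26, 0.22, 0.30],  # -1
        [0.95, 0.01, 0.02, 0.02],  # branch A
        [0.10, 0.40, 0.10, 0.40],  # +1 (y)
        [0.22, 0.26, 0.24, 0.28],  # +2
        [0.25, 0.25, 0.25, 0.25],  # +3
    ]
)


def donor_frequencies() -> np.ndarray:
    """Per-position base frequencies of the default donor 9-mer model."""
    f = _DONOR_FREQS.copy()
    return f / f.sum(axis=1, keepdims=True)


def acceptor_frequencies() -> np.ndarray:
    """Per-position base frequencies of the default acceptor 23-mer model."""
    return _ACCEPTOR_FREQS.copy()


def branch_point_frequencies() -> np.ndarray:
    """Per-position base frequencies of the default branch-point 7-mer model."""
    f = _BP_FREQS.copy()
    return f / f.sum(axis=1, keepdims=True)


def write_pwm_tsv(freqs: np.ndarray, path) -> None:
    df = pd.DataFrame(freqs, columns=list(BASES))
    df.index.name = "position"
    df.to_csv(path, sep="\t")


def read_pwm_tsv(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df[list(BASES)].to_numpy(dtype=float)


def all_hexamers() -> list[str]:
    out = []
    for i in range(4096):
        h, n = [], i
        for _ in range(6):
            h.append(BASES[n % 4])
            n //= 4
        out.append("".join(reversed(h)))
    return out


def synthesize_esr_table(
    seed: int,
    n_enhancers: int = 160,
    n_silencers: int = 160,
    effect: float = 2.0,
    noise_sd: float = 0.30,
) -> dict[str, float]:
    """Build a 4,096-entry hexamer score table with planted ESE/ESS hexamers.

    Background hexamers score ~N(0, noise_sd); planted enhancers score near
    ``+effect`` and silencers near ``-effect`` so that ESR-mediated splicing
    defects are learnable from generated collections.
    """
    rng = np.random.default_rng(seed)
    hexamers = all_hexamers()
    scores = rng.normal(0.0, noise_sd, size=4096)
    special = rng.choice(4096, size=n_enhancers + n_silencers, replace=False)
    scores[special[:n_enhancers]] = rng.normal(effect, 0.25, size=n_enhancers)
    scores[special[n_enhancers:]] = rng.normal(-effect, 0.25, size=n_silencers)
    return dict(zip(hexamers, scores.astype(float)))


def planted_enhancers(table: dict[str, float], cutoff: float = 1.0) -> list[str]:
    return sorted(h for h, s in table.items() if s >= cutoff)


def planted_silencers(table: dict[str, float], cutoff: float = -1.0) -> list[str]:
    return sorted(h for h, s in table.items() if s <= cutoff)


def write_esr_tsv(table: dict[str, float], path) -> None:
    buf = io.StringIO()
    buf.write("hexamer\tscore\n")
    for h in sorted(table):
        buf.write(f"{h}\t{table[h]:.6f}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_esr_tsv(path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    table = dict(zip(df["hexamer"], df["score"].astype(float)))
    if len(table) != 4096:
        raise ValueError(f"ESR table must have 4096 hexamers, got {len(table)}")
    return table
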