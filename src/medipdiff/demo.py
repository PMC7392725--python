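"""Bundled demonstration motif set.

A small JASPAR-style library of synthetic position frequency matrices with
strong, mutually distinct consensus sequences. The first entry is a
CTCF-like 19 bp matrix used as the default "planted" transcription factor by
the simulator; the rest provide a background library for enrichment ranking.
The matrices are synthetic stand-ins constructed for self-contained runs,
not database motifs.
"""

from __future__ import annotations

import numpy as np
from Bio.motifs import jaspar as bio_jaspar

from .motifs import ALPHABET, PWM, pwm_from_pfm

# (name, consensus); counts put 97/100 on the consensus base per column
_DEMO_CONSENSI = [
    ("CTCF", "TGGCCACCAGGGGGCGCTA"),
    ("MAXL", "CACGTGGTCAAC"),
    ("SP1L", "GGGGCGGGGTAG"),
    ("YY1L", "CAAGATGGCGGC"),
    ("EGRL", "GCGTGGGCGTGG"),
    ("NRFL", "GCGCATGCGCAT"),
]


def _counts_for(consensus: str, strong: int = 97) -> np.ndarray:
    counts = np.ones((4, len(consensus)), dtype=float)
    for j, base in enumerate(consensus):
        counts[ALPHABET.index(base), j] = strong
    return counts


def demo_pfms(pseudocount: float = 0.1) -> list[PWM]:
    """The bundled PWMs; index 0 is the CTCF-like planted motif."""
    return [
        pwm_from_pfm(_counts_for(cons), tf_name=name, pseudocount=pseudocount)
        for name, cons in _DEMO_CONSENSI
    ]


def demo_bio_motifs() -> list:
    """The same library as Bio.motifs objects (for JASPAR-format export)."""
    out = []
    for i, (name, cons) in enumerate(_DEMO_CONSENSI, start=1):
        counts = _counts_for(cons)
        motif = bio_jaspar.Motif(
            matrix_id=f"MD{i:04d}.1",
            name=name,
            counts={b: list(counts[k]) for k, b in enumerate(ALPHABET)},
        )
        out.append(motif)
    return out
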