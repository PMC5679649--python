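"""Shared file I/O: FASTA, TSV tables, and MEME minimal motif format.

All genomic indices in outputs are 0-based with half-open intervals.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .network import ALPHABET
from .profiles import FourierSpectrum, MotifCall, NucleotideProfile
from .sampler import BackgroundModel

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_meme_motif",
    "read_meme_motif",
    "write_profile_tsv",
    "write_spectrum_tsv",
]


def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA records as (id, sequence), wrapped lines joined, uppercased.

    Record order is preserved.  A file whose first non-blank line is not a
    header is rejected with the offending line number.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"FASTA file not found: {path}")
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(
                        f"{path}: line {lineno}: expected a '>' FASTA header, "
                        f"got {line.strip()[:30]!r}"
                    )
                break
    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, "fasta")]
    for rid, seq in records:
        if not seq:
            raise ValueError(f"{path}: record {rid!r} has an empty sequence")
    return records


def write_fasta(records, path) -> None:
    """Write (id, sequence) pairs as FASTA."""
    seqrecs = [SeqRecord(Seq(seq), id=str(rid), description="") for rid, seq in records]
    SeqIO.write(seqrecs, path, "fasta")


def write_meme_motif(call: MotifCall, background: BackgroundModel, path, name: str = "maxent_motif", nsites: int | None = None) -> None:
    """Write a motif call in MEME minimal motif format.

    The letter-probability matrix is the motif PSSM; background letter
    frequencies come from the i.i.d. background model.
    """
    pssm = np.asarray(call.pssm, dtype=float)
    if pssm.ndim != 2 or pssm.shape[1] != 4 or not np.allclose(pssm.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("motif pssm must be (width, 4) with rows summing to 1")
    bg = background.probs
    lines = [
        "MEME version 4",
        "",
        "ALPHABET= ACGT",
        "",
        "Background letter frequencies",
        " ".join(f"{b} {p:.6f}" for b, p in zip(ALPHABET, bg)),
        "",
        f"MOTIF {name}",
        f"letter-probability matrix: alength= 4 w= {pssm.shape[0]}"
        + (f" nsites= {nsites}" if nsites else ""),
    ]
    for row in pssm:
        lines.append(" ".join(f"{p:.6f}" for p in row))
    lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


def read_meme_motif(path) -> np.ndarray:
    """Read back the first letter-probability matrix from a MEME minimal file."""
    with open(path) as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines):
        if line.startswith("letter-probability matrix"):
            w = int(line.split("w=")[1].split()[0])
            rows = [list(map(float, lines[i + 1 + j].split())) for j in range(w)]
            return np.array(rows)
    raise ValueError(f"{path}: no letter-probability matrix found")


def write_profile_tsv(profile: NucleotideProfile, path) -> None:
    df = pd.DataFrame(profile.freq, columns=list(ALPHABET))
    df.insert(0, "position", np.arange(profile.length))
    df.to_csv(path, sep="\t", index=False)


def write_spectrum_tsv(spectrum: FourierSpectrum, path) -> None:
    pd.DataFrame(
        {"period": spectrum.periods, "normalized_amplitude": spectrum.normalized_amplitude}
    ).to_csv(path, sep="\t", index=False)
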