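"""Small nucleotide-sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

BASES = np.frombuffer(b"ACGT", dtype="S1")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-safe)."""
    return seq.translate(_COMP)[::-1]


def random_seq(rng: np.random.Generator, length: int) -> str:
    """I.i.d. uniform ACGT sequence of the given length."""
    if length <= 0:
        return ""
    return rng.choice(BASES, size=length).tobytes().decode()


def write_fasta(path, records, width: int = 70) -> None:
    """Write (name, sequence) pairs as a FASTA file."""
    with open(path, "w") as fh:
        for name, s in records:
            fh.write(f">{name}\n")
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def read_fasta(path) -> dict:
    """Read a plain (uncompressed) FASTA file into {name: sequence}."""
    out: dict[str, list] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                out[name] = []
            else:
                out[name].append(line)
    return {k: "".join(v) for k, v in out.items()}
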