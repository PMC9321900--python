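"""JC69 sequence evolution along segment genealogies.

Each segment of a locus evolves independently along that segment's gene
tree under the Jukes-Cantor model: the root state of every site is uniform
on {T, C, A, G}; along a branch of length ``t`` (expected substitutions per
site) a site keeps its state with probability ``1/4 + (3/4) exp(-4t/3)``
and changes to each of the other three states with probability
``1/4 - (1/4) exp(-4t/3)``.  Segments are concatenated in breakpoint order
into the per-locus alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO
from typing import TextIO

import numpy as np

from .arg_simulator import LocusGenealogy

__all__ = ["Alignment", "evolve_jc", "write_alignment", "read_alignment",
           "ALPHABET"]

ALPHABET = "TCAG"
_CODE = {b: i for i, b in enumerate(ALPHABET)}


@dataclass
class Alignment:
    """A per-locus nucleotide matrix over the alphabet {T, C, A, G}."""

    labels: list[str]
    matrix: np.ndarray  # (num_sequences, n) int8 codes into ALPHABET

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.labels):
            raise ValueError("matrix shape does not match labels")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate sequence labels")
        if self.matrix.size and (self.matrix.min() < 0 or self.matrix.max() > 3):
            raise ValueError("states must be codes 0..3 (T,C,A,G)")

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def sequence(self, label: str) -> str:
        row = self.matrix[self.labels.index(label)]
        return "".join(ALPHABET[c] for c in row)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Alignment):
            return NotImplemented
        return self.labels == other.labels and np.array_equal(self.matrix,
                                                              other.matrix)


def evolve_jc(g: LocusGenealogy, rng: np.random.Generator) -> Alignment:
    """Evolve one locus under JC69 over the locus' segment trees."""
    nseq = len(g.sample_labels)
    out = np.empty((nseq, g.n), dtype=np.int8)
    for left, right, tree in g.segment_trees():
        m = right - left
        states: dict[int, np.ndarray] = {
            tree.root: rng.integers(0, 4, size=m, dtype=np.int8)}
        # preorder: parents before children
        order = sorted(tree.age, key=lambda v: -tree.age[v])
        for v in order:
            if v == tree.root:
                continue
            t = tree.age[tree.parent[v]] - tree.age[v]
            if t < 0:
                raise ValueError(f"negative branch length {t} at node {v}")
            p_same = 0.25 + 0.75 * np.exp(-4.0 * t / 3.0)
            parent_state = states[tree.parent[v]]
            changed = rng.random(m) > p_same
            st = parent_state.copy()
            if changed.any():
                # jump uniformly to one of the three other states
                shift = rng.integers(1, 4, size=int(changed.sum()), dtype=np.int8)
                st[changed] = (st[changed] + shift) % 4
            states[v] = st
        for node, lab in tree.labels.items():
            out[g.sample_labels.index(lab), left:right] = states[node]
    return Alignment(labels=list(g.sample_labels), matrix=out)


# ---------------------------------------------------------------------------
# PHYLIP / FASTA I/O


def write_alignment(a: Alignment, format: str, sink: TextIO) -> None:
    """Write one locus in sequential PHYLIP (bpp-style) or FASTA."""
    fmt = format.upper()
    if fmt == "PHYLIP":
        sink.write(f"{len(a.labels)} {a.n_sites}\n")
        width = max(len(x) for x in a.labels) + 2
        for lab in a.labels:
            sink.write(f"{lab:<{width}}{a.sequence(lab)}\n")
    elif fmt == "FASTA":
        for lab in a.labels:
            sink.write(f">{lab}\n{a.sequence(lab)}\n")
    else:
        raise ValueError(f"unknown alignment format {format!r}")


def _matrix_from(labels: list[str], seqs: list[str]) -> Alignment:
    n = len(seqs[0])
    if any(len(s) != n for s in seqs):
        raise ValueError("sequences of unequal length")
    mat = np.empty((len(seqs), n), dtype=np.int8)
    for i, s in enumerate(seqs):
        try:
            mat[i] = [_CODE[b] for b in s.upper()]
        except KeyError as exc:
            raise ValueError(f"non-TCAG state in sequence {labels[i]!r}") from exc
    return Alignment(labels=labels, matrix=mat)


def read_alignment(source: TextIO, format: str) -> list[Alignment]:
    """Read one or more concatenated loci written by :func:`write_alignment`.

    Multilocus PHYLIP files are locus blocks concatenated in replicate
    order; a FASTA stream is read as a single locus.
    """
    fmt = format.upper()
    if fmt == "PHYLIP":
        loci: list[Alignment] = []
        lines = [ln.rstrip("\n") for ln in source if ln.strip()]
        i = 0
        while i < len(lines):
            nseq, nsites = (int(x) for x in lines[i].split())
            i += 1
            labels, seqs = [], []
            for _ in range(nseq):
                parts = lines[i].split(None, 1)
                labels.append(parts[0])
                seqs.append(parts[1].replace(" ", ""))
                i += 1
            if any(len(s) != nsites for s in seqs):
                raise ValueError("PHYLIP block length mismatch")
            loci.append(_matrix_from(labels, seqs))
        return loci
    if fmt == "FASTA":
        from Bio import SeqIO

        labels, seqs = [], []
        for rec in SeqIO.parse(source, "fasta"):
            labels.append(rec.id)
            seqs.append(str(rec.seq))
        if not labels:
            raise ValueError("no FASTA records found")
        return [_matrix_from(labels, seqs)]
    raise ValueError(f"unknown alignment format {format!r}")


def alignment_to_string(a: Alignment, format: str) -> str:
    buf = StringIO()
    write_alignment(a, format, buf)
    return buf.getvalue()
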