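"""Synthetic germline reference sets for IGH V/D/J segments and constant genes.

Real repertoire annotation runs against the IMGT germline database; this
module generates a self-contained synthetic stand-in with the structural
features the pipeline relies on:

* V segments are in frame from their first base up to a conserved
  cysteine codon (TGT/TGC) placed as the last codon — the 5' anchor of
  the CDR3.
* J segments carry a conserved tryptophan codon (TGG) twelve nucleotides
  in — the 3' anchor of the CDR3 — and are codon-structured and
  stop-free in the anchor frame.
* D segments are stop-free in all three reading frames so that a
  productive junction can always be sampled.
* Constant genes (one per isotype) have mutually distant 50-nt prefixes
  so that 10-mer isotype calling is decidable.

All generation is driven by a single :class:`numpy.random.Generator`
seed and is byte-reproducible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .isotypes import ISOTYPES

BASES = "ACGT"
STOP_CODONS = {"TAA", "TAG", "TGA"}
_NONSTOP = [
    "".join(c) for c in itertools.product(BASES, repeat=3)
    if "".join(c) not in STOP_CODONS
]

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class GermlineError(ValueError):
    """A germline set violates one of its structural invariants."""


@dataclass(frozen=True)
class VSegment:
    name: str
    seq: str
    cys_start: int  # 0-based start of the conserved Cys codon


@dataclass(frozen=True)
class DSegment:
    name: str
    seq: str


@dataclass(frozen=True)
class JSegment:
    name: str
    seq: str
    anchor_start: int  # 0-based start of the conserved Trp/Phe codon


@dataclass(frozen=True)
class CGene:
    isotype: str
    seq: str


@dataclass
class GermlineSet:
    v_segments: list[VSegment]
    d_segments: list[DSegment]
    j_segments: list[JSegment]
    c_genes: list[CGene]
    _v_by_name: dict = field(init=False, repr=False, default=None)

    def __post_init__(self):
        self._v_by_name = {s.name: s for s in self.v_segments}
        self._d_by_name = {s.name: s for s in self.d_segments}
        self._j_by_name = {s.name: s for s in self.j_segments}
        self._c_by_isotype = {c.isotype: c for c in self.c_genes}

    def v(self, name: str) -> VSegment:
        return self._v_by_name[name]

    def d(self, name: str) -> DSegment:
        return self._d_by_name[name]

    def j(self, name: str) -> JSegment:
        return self._j_by_name[name]

    def c(self, isotype: str) -> CGene:
        return self._c_by_isotype[isotype]

    def validate(self, min_c_prefix_hamming: int = 5) -> None:
        names = [s.name for s in self.v_segments + self.d_segments
                 + self.j_segments] + [c.isotype for c in self.c_genes]
        if len(set(names)) != len(names):
            raise GermlineError("segment names are not unique")
        for segs in (self.v_segments, self.d_segments, self.j_segments):
            for s in segs:
                if set(s.seq) - set(BASES):
                    raise GermlineError(f"non-ACGT base in {s.name}")
        for v in self.v_segments:
            if len(v.seq) < 150:
                raise GermlineError(f"{v.name}: V segment shorter than 150 nt")
            if v.cys_start % 3 != 0 or v.seq[v.cys_start:v.cys_start + 3] not in ("TGT", "TGC"):
                raise GermlineError(f"{v.name}: Cys anchor missing or out of frame")
            for i in range(0, v.cys_start, 3):
                if v.seq[i:i + 3] in STOP_CODONS:
                    raise GermlineError(f"{v.name}: stop codon upstream of Cys anchor")
        for j in self.j_segments:
            if j.anchor_start < 0 or j.seq[j.anchor_start:j.anchor_start + 3] not in ("TGG", "TTT", "TTC"):
                raise GermlineError(f"{j.name}: Trp/Phe anchor missing")
        for c in self.c_genes:
            if len(c.seq) < 50:
                raise GermlineError(f"{c.isotype}: constant gene shorter than 50 nt")
            if set(c.seq) - set(BASES):
                raise GermlineError(f"non-ACGT base in {c.isotype}")
        prefixes = [c.seq[:50] for c in self.c_genes]
        for a in range(len(prefixes)):
            for b in range(a + 1, len(prefixes)):
                d = sum(x != y for x, y in zip(prefixes[a], prefixes[b]))
                if d < min_c_prefix_hamming:
                    raise GermlineError(
                        f"constant-gene prefixes of {self.c_genes[a].isotype} and "
                        f"{self.c_genes[b].isotype} differ at only {d} positions")

    # ---------------------------------------------------------------- FASTA
    def to_fasta(self, path) -> None:
        """One record per segment; anchors are encoded in the description."""
        with open(path, "w") as fh:
            for v in self.v_segments:
                fh.write(f">{v.name} cys={v.cys_start}\n{v.seq}\n")
            for d in self.d_segments:
                fh.write(f">{d.name}\n{d.seq}\n")
            for j in self.j_segments:
                fh.write(f">{j.name} anchor={j.anchor_start}\n{j.seq}\n")
            for c in self.c_genes:
                fh.write(f">{c.isotype}\n{c.seq}\n")

    @classmethod
    def from_fasta(cls, path) -> "GermlineSet":
        from Bio import SeqIO
        vs, ds, js, cs = [], [], [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            seq = str(rec.seq).upper()
            fields = dict(
                kv.split("=") for kv in rec.description.split()[1:] if "=" in kv)
            if rec.id in ISOTYPES:
                cs.append(CGene(rec.id, seq))
            elif rec.id.startswith("IGHV"):
                vs.append(VSegment(rec.id, seq, int(fields["cys"])))
            elif rec.id.startswith("IGHD"):
                ds.append(DSegment(rec.id, seq))
            elif rec.id.startswith("IGHJ"):
                js.append(JSegment(rec.id, seq, int(fields["anchor"])))
            else:
                raise GermlineError(f"unrecognized germline record {rec.id!r}")
        gs = cls(vs, ds, js, cs)
        gs.validate()
        return gs


def _random_codons(rng: np.random.Generator, n: int) -> str:
    idx = rng.integers(0, len(_NONSTOP), size=n)
    return "".join(_NONSTOP[i] for i in idx)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def _stop_free_all_frames(seq: str) -> bool:
    for off in range(3):
        for i in range(off, len(seq) - 2, 3):
            if seq[i:i + 3] in STOP_CODONS:
                return False
    return True


def make_germline_set(
    n_v: int,
    n_d: int,
    n_j: int,
    seed: int,
    v_length: int = 294,
    j_length: int = 48,
    c_length: int = 60,
    min_v_hamming: int = 30,
    min_c_prefix_hamming: int = 5,
) -> GermlineSet:
    """Generate a synthetic germline reference set.

    V gene names encode a family (``IGHV{f}-S{i}``, families cycling 1..7)
    so family-level statistics behave like real nomenclature. The set is
    deterministic given ``seed`` and is validated before being returned.
    """
    if n_v < 2 or n_j < 1 or n_d < 1:
        raise GermlineError("need n_v >= 2, n_d >= 1, n_j >= 1")
    if v_length % 3 or v_length < 150:
        raise GermlineError("v_length must be a multiple of 3 and >= 150")
    rng = np.random.default_rng(seed)

    v_segments: list[VSegment] = []
    while len(v_segments) < n_v:
        body = _random_codons(rng, v_length // 3 - 1)
        cys = "TGT" if rng.random() < 0.5 else "TGC"
        seq = body + cys
        if all(sum(a != b for a, b in zip(seq, v.seq)) >= min_v_hamming
               for v in v_segments):
            fam = len(v_segments) % 7 + 1
            v_segments.append(
                VSegment(f"IGHV{fam}-S{len(v_segments) + 1:02d}", seq, v_length - 3))

    d_segments: list[DSegment] = []
    while len(d_segments) < n_d:
        length = int(rng.integers(12, 22))
        seq = _random_seq(rng, length)
        if _stop_free_all_frames(seq):
            d_segments.append(DSegment(f"IGHD{len(d_segments) + 1}-S", seq))

    if j_length % 3 or j_length < 15:
        raise GermlineError("j_length must be a multiple of 3 and >= 15")
    j_segments: list[JSegment] = []
    for i in range(n_j):
        codons = [_random_codons(rng, 1) for _ in range(j_length // 3)]
        codons[4] = "TGG"  # conserved Trp anchor, nt 12-14
        j_segments.append(JSegment(f"IGHJ{i + 1}-S", "".join(codons), 12))

    c_genes: list[CGene] = []
    for iso in ISOTYPES:
        while True:
            seq = _random_seq(rng, c_length)
            if all(sum(a != b for a, b in zip(seq[:50], c.seq[:50])) >= min_c_prefix_hamming
                   for c in c_genes):
                c_genes.append(CGene(iso, seq))
                break

    gs = GermlineSet(v_segments, d_segments, j_segments, c_genes)
    gs.validate(min_c_prefix_hamming=min_c_prefix_hamming)
    return gs


def build_vdj(germline: GermlineSet, v_name: str, d_name: str, j_name: str,
              n1: str, n2: str) -> str:
    """Assemble a recombined V(D)J nucleotide sequence with N insertions."""
    return (germline.v(v_name).seq + n1 + germline.d(d_name).seq
            + n2 + germline.j(j_name).seq)
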