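"""V/J gene assignment, SHM counting and CDR3 extraction.

An in-repo replacement for external annotation services: consensus BCR
sequences are compared against the packaged germline set by anchored
ungapped alignment (the simulated amplicon layout has no indels; records
with indels would fail the identity threshold and are dropped).

Mutation counting is codon-aware: for each codon of the aligned V region
the observed codon (with all of its observed mutations) is translated
and compared to the germline codon; every mutated nucleotide in a codon
counts as non-silent iff the amino acids differ, otherwise silent. The
count covers the aligned V region only, not the CDR3/junction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .germline import GermlineSet

_table = unambiguous_dna_by_id[1]
CODON_AA = dict(_table.forward_table)
for stop in _table.stop_codons:
    CODON_AA[stop] = "*"


def translate(seq: str) -> str:
    return "".join(CODON_AA.get(seq[i:i + 3], "X")
                   for i in range(0, len(seq) - 2, 3))


@dataclass
class VJAssignment:
    v_call: str
    j_call: str
    v_length: int        # aligned V region length (anchored at position 0)
    v_identity: float
    j_identity: float


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def assign_vj(sequence: str, germline: GermlineSet,
              min_v_identity: float = 0.7,
              min_j_identity: float = 0.7) -> VJAssignment | None:
    """Best V by matches over the sequence prefix, best J over the suffix.

    Identity is computed over the full germline segment length (bases the
    sequence does not cover count as mismatches). Ties break by fewest
    mismatches, then name order. Returns None when either best identity
    falls below its threshold."""
    arr = _encode(sequence)
    best_v = None
    for v in germline.v_segments:
        g = _encode(v.seq)
        ln = min(len(g), len(arr))
        matches = int((arr[:ln] == g[:ln]).sum())
        identity = matches / len(g)
        key = (-matches, len(g) - matches, v.name)
        if best_v is None or key < best_v[0]:
            best_v = (key, v, identity)
    best_j = None
    for j in germline.j_segments:
        g = _encode(j.seq)
        ln = min(len(g), len(arr))
        matches = int((arr[-ln:] == g[-ln:]).sum()) if ln else 0
        identity = matches / len(g)
        key = (-matches, len(g) - matches, j.name)
        if best_j is None or key < best_j[0]:
            best_j = (key, j, identity)
    if best_v is None or best_j is None:
        return None
    _, v, v_id = best_v
    _, j, j_id = best_j
    if v_id < min_v_identity or j_id < min_j_identity:
        return None
    return VJAssignment(v.name, j.name, min(len(v.seq), len(sequence)),
                        v_id, j_id)


def count_shm(sequence: str, v_seq: str) -> tuple[int, int, int]:
    """Count (total, silent, non-silent) mutated nucleotides in the
    aligned V region, anchored at position 0 in the germline V frame."""
    ln = min(len(sequence), len(v_seq))
    ln3 = ln - ln % 3
    obs = _encode(sequence[:ln3])
    ger = _encode(v_seq[:ln3])
    diff_pos = np.nonzero(obs != ger)[0]
    total = len(diff_pos)
    if total == 0:
        return 0, 0, 0
    silent = 0
    nonsilent = 0
    for codon_start in np.unique(diff_pos // 3) * 3:
        o = sequence[codon_start:codon_start + 3]
        g = v_seq[codon_start:codon_start + 3]
        n_mut = sum(a != b for a, b in zip(o, g))
        if CODON_AA[o] == CODON_AA[g]:
            silent += n_mut
        else:
            nonsilent += n_mut
    return total, silent, nonsilent


def extract_cdr3(sequence: str, v_call: str, j_call: str,
                 germline: GermlineSet) -> str | None:
    """Translated region strictly between the conserved V Cys codon and
    the conserved J Trp/Phe codon. Returns None when either anchor is
    absent (e.g. mutated away by SHM) or the region is frame-broken."""
    v = germline.v(v_call)
    j = germline.j(j_call)
    cys = v.cys_start
    anchor_abs = len(sequence) - len(j.seq) + j.anchor_start
    if anchor_abs < cys + 3 or anchor_abs + 3 > len(sequence):
        return None
    if CODON_AA.get(sequence[cys:cys + 3]) != "C":
        return None
    if CODON_AA.get(sequence[anchor_abs:anchor_abs + 3]) not in ("W", "F"):
        return None
    region = sequence[cys + 3:anchor_abs]
    if len(region) % 3:
        return None
    return translate(region)


AIRR_COLUMNS = [
    "sequence_id", "sequence", "v_call", "d_call", "j_call", "c_call",
    "junction_aa", "cdr3_length", "duplicate_count", "n_mut_total",
    "n_mut_silent", "n_mut_nonsilent", "v_identity", "v_seq_length",
    "sample_id",
]


def annotate_sequences(records, germline: GermlineSet,
                       sample_id: str = "sample",
                       min_v_identity: float = 0.7,
                       min_j_identity: float = 0.7):
    """Annotate an iterable of ``(sequence_id, sequence, isotype,
    duplicate_count)`` into an AIRR-style rearrangement DataFrame.

    Unannotatable records (no V/J above threshold) are dropped and
    counted. Records whose CDR3 anchors are missing keep ``junction_aa``
    as NA but are retained."""
    rows = []
    n_dropped = 0
    for sequence_id, sequence, isotype, duplicate_count in records:
        vj = assign_vj(sequence, germline, min_v_identity, min_j_identity)
        if vj is None:
            n_dropped += 1
            continue
        v_seq = germline.v(vj.v_call).seq
        total, silent, nonsilent = count_shm(sequence, v_seq)
        cdr3 = extract_cdr3(sequence, vj.v_call, vj.j_call, germline)
        rows.append({
            "sequence_id": sequence_id,
            "sequence": sequence,
            "v_call": vj.v_call,
            "d_call": None,
            "j_call": vj.j_call,
            "c_call": isotype,
            "junction_aa": cdr3,
            "cdr3_length": None if cdr3 is None else len(cdr3),
            "duplicate_count": int(duplicate_count),
            "n_mut_total": total,
            "n_mut_silent": silent,
            "n_mut_nonsilent": nonsilent,
            "v_identity": vj.v_identity,
            "v_seq_length": vj.v_length,
            "sample_id": sample_id,
        })
    df = pd.DataFrame(rows, columns=AIRR_COLUMNS)
    return df, n_dropped


def annotate_consensus(consensus_records, germline: GermlineSet,
                       sample_id: str = "sample", **kwargs):
    """Annotate preprocessed ConsensusBCR records."""
    it = ((rec.barcode, rec.sequence, rec.isotype, rec.duplicate_count)
          for rec in consensus_records)
    return annotate_sequences(it, germline, sample_id, **kwargs)


def annotate_cells(cells, germline: GermlineSet, sample_id: str = "sim",
                   **kwargs):
    """Annotate simulated cells directly (one record per cell; duplicate
    count = RNA copies), bypassing read emission. Used for statistics-level
    studies where sequencing noise is not under test."""
    from .simulate import cell_sequence
    it = ((f"cell{c.cell_id}", cell_sequence(c, germline), c.isotype,
           c.rna_copies) for c in cells)
    return annotate_sequences(it, germline, sample_id, **kwargs)
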