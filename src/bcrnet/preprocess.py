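"""Raw paired FASTQ -> error-corrected, isotype-labelled consensus BCRs.

Stages, in order:

1. ``quality_filter`` — keep pairs where both mates have median Phred > 34.
2. ``merge_pairs`` — merge mates sharing an *identical* overlap of > 50 bp.
3. ``extract_barcode`` — locate the 15-nt NNNNTNNNNTNNNNT barcode at the
   V-side 5' end on either strand, orient the read V -> constant.
4. ``assign_isotype`` — 10-mer matching of the read's constant-side
   segment against the first 50 bp of each constant gene.
5. ``build_consensus`` — per-barcode majority-vote consensus with a
   mean per-position support ("certainty") filter at > 0.8.
6. ``estimate_precorrection_error`` — mismatch rate of member reads
   against their group consensus (the pre-correction error rate).
7. ``frame_and_ig_filter`` — require V and J similarity and an open
   V-to-J reading frame.

Coordinates are 0-based half-open internally; the barcode's conserved
T positions are 5, 10, 15 in 1-based descriptions.
"""

from __future__ import annotations

import gzip
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np

from .germline import GermlineSet, STOP_CODONS, revcomp
from .simulate import BARCODE_LENGTH, BARCODE_T_POSITIONS

PHRED_OFFSET = 33


class FastqParseError(ValueError):
    pass


@dataclass
class ReadPair:
    read_id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str


@dataclass
class MergedRead:
    sequence: str
    quality: str


@dataclass
class BarcodeGroup:
    barcode: str
    reads: list                    # trimmed (VDJ) member reads, modal length
    consensus: str
    certainty: float
    read_count: int                # reads supporting the consensus
    n_length_dropped: int = 0
    isotype: str | None = None


@dataclass
class ConsensusBCR:
    barcode: str
    sequence: str                  # barcode/primers and constant region trimmed
    isotype: str
    duplicate_count: int
    certainty: float
    v_call: str | None = None
    j_call: str | None = None


def _open_in(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_fastq_pairs(r1_path, r2_path):
    """Yield ReadPair records; mate ids must match after /1 // /2 suffixes."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    def bare(title):
        name = title.split()[0]
        if name.endswith("/1") or name.endswith("/2"):
            name = name[:-2]
        return name

    with _open_in(r1_path) as f1, _open_in(r2_path) as f2:
        it2 = FastqGeneralIterator(f2)
        for i, (t1, s1, q1) in enumerate(FastqGeneralIterator(f1)):
            try:
                t2, s2, q2 = next(it2)
            except StopIteration:
                raise FastqParseError(f"R2 ended before R1 at record {i}")
            if bare(t1) != bare(t2):
                raise FastqParseError(
                    f"mate id mismatch at record {i}: {t1!r} vs {t2!r}")
            yield ReadPair(bare(t1), s1.upper(), q1, s2.upper(), q2)


def median_phred(qual: str) -> float:
    arr = np.frombuffer(qual.encode(), dtype=np.uint8)
    return float(np.median(arr)) - PHRED_OFFSET


def quality_filter(pairs, min_median: float = 34.0):
    """Retain pairs where *both* mates have median Phred strictly above
    the threshold."""
    kept, dropped = [], 0
    for p in pairs:
        if median_phred(p.qual1) > min_median and median_phred(p.qual2) > min_median:
            kept.append(p)
        else:
            dropped += 1
    return kept, dropped


def merge_pair(pair: ReadPair, min_overlap: int = 50) -> MergedRead | None:
    """Merge mates iff they share an identical overlap strictly longer
    than ``min_overlap`` bp; quality of the overlap is taken from R1."""
    rc2 = revcomp(pair.seq2)
    rq2 = pair.qual2[::-1]
    seq1, q1 = pair.seq1, pair.qual1
    max_l = min(len(seq1), len(rc2))
    k = 20
    if max_l > k:
        # fast path: anchor the start of the reverse-complemented mate
        anchor = rc2[:k]
        start = seq1.find(anchor)
        while start != -1:
            ln = len(seq1) - start
            if min_overlap < ln <= max_l and seq1[start:] == rc2[:ln]:
                return MergedRead(seq1 + rc2[ln:], q1 + rq2[ln:])
            start = seq1.find(anchor, start + 1)
    for ln in range(max_l, min_overlap, -1):
        if seq1[-ln:] == rc2[:ln]:
            return MergedRead(seq1 + rc2[ln:], q1 + rq2[ln:])
    return None


def merge_pairs(pairs, min_overlap: int = 50):
    merged, dropped = [], 0
    for p in pairs:
        m = merge_pair(p, min_overlap)
        if m is None:
            dropped += 1
        else:
            merged.append(m)
    return merged, dropped


def _has_conserved_ts(seq: str) -> bool:
    return (len(seq) >= BARCODE_LENGTH
            and all(seq[p] == "T" for p in BARCODE_T_POSITIONS))


def extract_barcode(merged: MergedRead | str):
    """Return ``(barcode, oriented_vdj_plus_constant)`` or None.

    The barcode sits at the 5' (V-primer) end of the amplicon; the read
    is reverse-complemented if the conserved T's are found only on the
    other strand, so the returned sequence always runs V -> constant.
    """
    seq = merged.sequence if isinstance(merged, MergedRead) else merged
    if _has_conserved_ts(seq):
        return seq[:BARCODE_LENGTH], seq[BARCODE_LENGTH:]
    rc = revcomp(seq)
    if _has_conserved_ts(rc):
        return rc[:BARCODE_LENGTH], rc[BARCODE_LENGTH:]
    return None


def _kmers(seq: str, k: int):
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def assign_isotype(oriented_seq: str, c_genes, k: int = 10,
                   prefix_len: int = 50, trail: int | None = None):
    """k-mer match the constant-side segment against each constant gene's
    first ``prefix_len`` bp; unique argmax wins, ties and all-zero are
    ambiguous (None). Returns (isotype_or_None, best_score)."""
    trail = prefix_len if trail is None else trail
    segment = oriented_seq[-trail:]
    seg_kmers = _kmers(segment, k)
    best, best_score, tied = None, 0, False
    for c in c_genes:
        score = len(seg_kmers & _kmers(c.seq[:prefix_len], k))
        if score > best_score:
            best, best_score, tied = c.isotype, score, False
        elif score == best_score and score > 0:
            tied = True
    if best_score == 0 or tied:
        return None, best_score
    return best, best_score


def build_consensus(reads: list[str], barcode: str = "") -> BarcodeGroup:
    """Majority-vote consensus of the reads sharing one barcode.

    Only reads of the modal length enter the consensus (mixed lengths are
    counted and dropped; length ties resolve to the shorter). Ties at a
    position resolve to the lexicographically smallest base. Certainty is
    the mean over positions of the fraction of reads matching the
    consensus base; a singleton group has certainty 1.0.
    """
    if not reads:
        raise ValueError("empty barcode group")
    lengths = Counter(len(r) for r in reads)
    top = max(lengths.values())
    modal_len = min(l for l, n in lengths.items() if n == top)
    kept = [r for r in reads if len(r) == modal_len]
    n_dropped = len(reads) - len(kept)
    if len(kept) == 1:
        return BarcodeGroup(barcode, kept, kept[0], 1.0, 1, n_dropped)
    mat = np.frombuffer("".join(kept).encode(), dtype=np.uint8)
    mat = mat.reshape(len(kept), modal_len)
    counts = np.stack([(mat == ord(b)).sum(axis=0) for b in "ACGT"])
    maj = counts.argmax(axis=0)            # first max -> A<C<G<T tie-break
    consensus = bytes(b"ACGT"[i] for i in maj).decode()
    certainty = float((counts.max(axis=0) / len(kept)).mean())
    return BarcodeGroup(barcode, kept, consensus, certainty, len(kept), n_dropped)


def collapse_barcode_groups(
    tagged,
    c_genes,
    certainty_threshold: float = 0.8,
    k: int = 10,
    constant_trail: int = 50,
):
    """Group oriented reads by barcode, call isotypes, build consensi.

    ``tagged`` is an iterable of ``(barcode, oriented_seq)`` where the
    oriented sequence still carries the constant trail. Returns
    ``(consensus_records, all_groups, counts)``; a group is retained iff
    its certainty is strictly above the threshold and its member isotype
    votes have a unique winner.
    """
    by_barcode = defaultdict(list)
    for barcode, seq in tagged:
        by_barcode[barcode].append(seq)

    records, groups = [], []
    counts = {"groups": len(by_barcode), "low_certainty": 0,
              "ambiguous_isotype": 0, "length_dropped_reads": 0,
              "too_short": 0}
    for barcode in sorted(by_barcode):
        members = by_barcode[barcode]
        votes = Counter()
        trimmed = []
        for seq in members:
            if len(seq) <= constant_trail:
                counts["too_short"] += 1
                continue
            iso, _ = assign_isotype(seq, c_genes, k=k, prefix_len=constant_trail)
            if iso is not None:
                votes[iso] += 1
            trimmed.append(seq[:-constant_trail])
        if not trimmed:
            continue
        group = build_consensus(trimmed, barcode)
        counts["length_dropped_reads"] += group.n_length_dropped
        ranked = votes.most_common()
        if ranked and (len(ranked) == 1 or ranked[0][1] > ranked[1][1]):
            group.isotype = ranked[0][0]
        groups.append(group)
        if group.certainty <= certainty_threshold:
            counts["low_certainty"] += 1
            continue
        if group.isotype is None:
            counts["ambiguous_isotype"] += 1
            continue
        records.append(ConsensusBCR(
            barcode=barcode, sequence=group.consensus, isotype=group.isotype,
            duplicate_count=group.read_count, certainty=group.certainty))
    return records, groups, counts


def estimate_precorrection_error(groups: list[BarcodeGroup]):
    """Per-base mismatch rate of member reads against their group
    consensus; singleton groups are excluded. Returns
    ``(rate, mismatches, bases)`` or None if no multi-read group exists.
    The denominator is the total number of member bases compared."""
    mismatches = 0
    bases = 0
    for g in groups:
        if g.read_count < 2:
            continue
        cons = np.frombuffer(g.consensus.encode(), dtype=np.uint8)
        for r in g.reads:
            arr = np.frombuffer(r.encode(), dtype=np.uint8)
            mismatches += int((arr != cons).sum())
            bases += len(arr)
    if bases == 0:
        return None
    return mismatches / bases, mismatches, bases


def frame_and_ig_filter(
    records: list[ConsensusBCR],
    germline: GermlineSet,
    min_v_identity: float = 0.7,
    min_j_identity: float = 0.7,
):
    """Keep records with significant V and J similarity and an open
    V-to-J reading frame (no stop codon from the V start through the
    junction)."""
    from . import annotate as _annotate
    kept, dropped = [], {"no_vj": 0, "stop_codon": 0}
    for rec in records:
        vj = _annotate.assign_vj(rec.sequence, germline,
                                 min_v_identity=min_v_identity,
                                 min_j_identity=min_j_identity)
        if vj is None:
            dropped["no_vj"] += 1
            continue
        seq = rec.sequence
        frame_end = len(seq) - len(seq) % 3
        if any(seq[i:i + 3] in STOP_CODONS for i in range(0, frame_end, 3)):
            dropped["stop_codon"] += 1
            continue
        rec.v_call, rec.j_call = vj.v_call, vj.j_call
        kept.append(rec)
    return kept, dropped


def run_preprocess(
    r1_path,
    r2_path,
    germline: GermlineSet,
    min_median_phred: float = 34.0,
    min_overlap: int = 50,
    kmer: int = 10,
    certainty: float = 0.8,
    constant_trail: int = 50,
    min_v_identity: float = 0.7,
    min_j_identity: float = 0.7,
):
    """Full preprocessing pipeline; returns (records, stats)."""
    pairs = list(read_fastq_pairs(r1_path, r2_path))
    n_raw = len(pairs)
    pairs, n_lowq = quality_filter(pairs, min_median_phred)
    merged, n_unmerged = merge_pairs(pairs, min_overlap)
    tagged = []
    n_no_barcode = 0
    for m in merged:
        hit = extract_barcode(m)
        if hit is None:
            n_no_barcode += 1
        else:
            tagged.append(hit)
    records, groups, counts = collapse_barcode_groups(
        tagged, germline.c_genes, certainty_threshold=certainty,
        k=kmer, constant_trail=constant_trail)
    err = estimate_precorrection_error(groups)
    records, frame_dropped = frame_and_ig_filter(
        records, germline, min_v_identity, min_j_identity)
    stats = {
        "raw_pairs": n_raw,
        "low_quality_pairs": n_lowq,
        "unmerged_pairs": n_unmerged,
        "no_barcode": n_no_barcode,
        "barcode_groups": counts["groups"],
        "low_certainty_groups": counts["low_certainty"],
        "ambiguous_isotype_groups": counts["ambiguous_isotype"],
        "length_dropped_reads": counts["length_dropped_reads"],
        "frame_filter_dropped": frame_dropped,
        "precorrection_error_rate": None if err is None else err[0],
        "precorrection_mismatches": None if err is None else err[1],
        "precorrection_bases": None if err is None else err[2],
        "consensus_bcrs": len(records),
    }
    return records, stats
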