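"""Simulation of clonally structured, isotype-resolved BCR repertoires.

The generative model emulates the biology the pipeline is built to
measure, with every latent variable recorded so downstream estimates can
be checked against ground truth:

* **Clonal structure** — ``n_clones`` independent V(D)J recombination
  events; clone sizes follow a geometric or Zipf law.
* **Junctional diversity** — 0-12 untemplated N nucleotides on each side
  of the D segment, resampled until the V-to-J reading frame is open.
* **SHM** — each non-founder cell inherits its parent's sequence and
  adds ``Binomial(L, shm_rate)`` fresh point substitutions, uniformly
  placed (no hotspot bias). Substitutions creating an in-frame stop
  codon are resampled by default: expressed BCRs are productive.
* **CSR** — a row-stochastic transition matrix over the nine constant
  genes in locus order; only downstream (deletional) transitions carry
  mass. Each non-founder cell draws its isotype from its parent's row.
* **Cell types and RNA abundance** — unswitched, unmutated cells are
  naive; the rest are memory or plasmablast. Plasmablasts carry ~1000x
  the BCR RNA of naive cells, which is what unique-BCR normalization is
  designed to cancel.
* **Library construction** — every RNA molecule receives a unique
  15-nt barcode matching NNNNTNNNNTNNNNT, is PCR-amplified into
  ``1 + Poisson(pcr_duplicates)`` copies, and each copy is sequenced as
  a read pair with >50 bp true overlap. The injected ``error_rate`` acts
  per amplified copy (polymerase errors, shared by the two mates);
  an optional ``seq_error_rate`` adds independent per-mate errors.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .germline import BASES, GermlineSet, STOP_CODONS, build_vdj, revcomp
from .isotypes import ISOTYPES, LOCUS_RANK, UNSWITCHED, is_switched

BARCODE_T_POSITIONS = (4, 9, 14)  # 0-based; 1-based 5, 10, 15
BARCODE_LENGTH = 15


class ConfigurationError(ValueError):
    """Invalid simulation or pipeline configuration."""


@dataclass
class PlantedClone:
    """A dominant (CLL-like) clone: SHM steps clipped to at most one
    nucleotide per cell so the clone stays a single network component."""
    n_cells: int
    step_mutation_prob: float = 0.3
    switch_prob: float = 0.02


@dataclass
class SimConfig:
    n_clones: int = 200
    clone_size_law: str = "geometric"   # "geometric" | "zipf" | "constant"
    clone_size_p: float = 0.25          # geometric success probability
    clone_size_zipf_a: float = 2.0
    clone_size_const: int = 1
    shm_rate: float = 0.002             # per base per cell generation
    switch_matrix: dict | None = None   # row-stochastic over ISOTYPES
    founder_igd_prob: float = 0.3
    founder_switch_probs: dict | float = 0.0  # per-V-gene or global
    plasmablast_prob: float = 0.02      # among non-naive cells
    rna_copies: dict = field(default_factory=lambda: {
        "naive": 1, "memory": 4, "plasmablast": 1000})
    junction_n_max: int = 12
    avoid_stop_codons: bool = True
    planted_clone: PlantedClone | None = None


@dataclass
class SimCell:
    cell_id: int
    clone_id: int
    cell_type: str
    v_name: str
    d_name: str
    j_name: str
    n1: str                       # junction insertions, V-D side
    n2: str                       # junction insertions, D-J side
    isotype: str
    shm_positions: tuple          # ((pos, from_base, to_base), ...)
    rna_copies: int


@dataclass
class SimTruth:
    """Ground-truth record tying every emitted read back to its origin."""
    cells: list = field(default_factory=list)
    sequences: dict = field(default_factory=dict)      # cell_id -> true VDJ
    clone_members: dict = field(default_factory=dict)  # clone_id -> [cell_id]
    switch_events: Counter = field(default_factory=Counter)  # (from, to) -> n
    error_rate: float | None = None
    molecules: list = field(default_factory=list)      # (mol_id, cell_id, barcode)
    barcode_to_molecule: dict = field(default_factory=dict)
    reads: list = field(default_factory=list)          # (read_id, mol_id)

    def cell(self, cell_id: int) -> SimCell:
        return self.cells[cell_id]

    def n_shm(self, cell_id: int) -> int:
        return len(self.cells[cell_id].shm_positions)

    def n_shm_v(self, cell_id: int, germline: GermlineSet) -> int:
        """Mutation count restricted to the V segment (what the annotator
        counts)."""
        c = self.cells[cell_id]
        vlen = len(germline.v(c.v_name).seq)
        return sum(1 for p, _, _ in c.shm_positions if p < vlen)

    def to_tsv(self, path, germline: GermlineSet) -> None:
        mol_by_id = {m[0]: m for m in self.molecules}
        with open(path, "w") as fh:
            fh.write("read_id\tmolecule_id\tbarcode\tclone_id\tv_name\t"
                     "j_name\tisotype\tn_shm\n")
            for read_id, mol_id in self.reads:
                _, cell_id, barcode = mol_by_id[mol_id]
                c = self.cells[cell_id]
                fh.write(f"{read_id}\t{mol_id}\t{barcode}\t{c.clone_id}\t"
                         f"{c.v_name}\t{c.j_name}\t{c.isotype}\t"
                         f"{len(c.shm_positions)}\n")


# --------------------------------------------------------------- CSR matrix

def default_switch_matrix(stay: float = 0.9) -> dict:
    """Downstream-only transition matrix; switch mass from IgM/IgD is
    spread over switched genes with IgG1/IgA1 favoured, later genes rarer."""
    weights = {"IGHG3": 0.18, "IGHG1": 0.30, "IGHA1": 0.22,
               "IGHG2": 0.12, "IGHG4": 0.05, "IGHE": 0.03, "IGHA2": 0.10}
    m = {}
    for src in ISOTYPES:
        downstream = [t for t in ISOTYPES if LOCUS_RANK[t] > LOCUS_RANK[src]]
        row = dict.fromkeys(ISOTYPES, 0.0)
        if not downstream:
            row[src] = 1.0
        else:
            w = np.array([weights.get(t, 1.0) for t in downstream], float)
            w /= w.sum()
            row[src] = stay
            for t, wt in zip(downstream, w):
                row[t] = (1.0 - stay) * wt
        m[src] = row
    return m


def identity_switch_matrix() -> dict:
    return {src: {t: 1.0 if t == src else 0.0 for t in ISOTYPES}
            for src in ISOTYPES}


def validate_switch_matrix(matrix: dict) -> np.ndarray:
    """Check row sums and the deletional (downstream-only) constraint;
    return the matrix as an array in ISOTYPES order."""
    arr = np.zeros((len(ISOTYPES), len(ISOTYPES)))
    for i, src in enumerate(ISOTYPES):
        row = matrix[src]
        s = sum(row.values())
        if abs(s - 1.0) > 1e-9:
            raise ConfigurationError(f"switch matrix row {src} sums to {s}")
        for j, tgt in enumerate(ISOTYPES):
            p = row.get(tgt, 0.0)
            if p < 0 or p > 1:
                raise ConfigurationError("transition probability outside [0,1]")
            if p > 0 and tgt != src and LOCUS_RANK[tgt] <= LOCUS_RANK[src]:
                raise ConfigurationError(
                    f"upstream transition {src}->{tgt} has positive mass")
            arr[i, j] = p
    return arr


# --------------------------------------------------------------- repertoire

def _translate_ok(seq: str) -> bool:
    return all(seq[i:i + 3] not in STOP_CODONS for i in range(0, len(seq) - 2, 3))


def _sample_junction(rng, d_len: int, n_max: int):
    while True:
        n1 = int(rng.integers(0, n_max + 1))
        n2 = int(rng.integers(0, n_max + 1))
        if (n1 + d_len + n2) % 3 == 0:
            return n1, n2


def _random_bases(rng, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def _mutate(rng, seq: str, n_new: int, taken: set, avoid_stops: bool):
    """Add n_new substitutions at fresh positions; returns (seq, muts)."""
    muts = []
    free = [p for p in range(len(seq)) if p not in taken]
    if n_new > len(free):
        n_new = len(free)
    chars = list(seq)
    chosen = rng.choice(len(free), size=n_new, replace=False) if n_new else []
    for idx in np.atleast_1d(chosen):
        pos = free[int(idx)]
        old = chars[pos]
        alts = [b for b in BASES if b != old]
        order = rng.permutation(3)
        placed = False
        for k in order:
            new = alts[int(k)]
            chars[pos] = new
            if not avoid_stops:
                placed = True
                break
            c0 = pos - pos % 3
            if "".join(chars[c0:c0 + 3]) not in STOP_CODONS:
                placed = True
                break
        if not placed:
            chars[pos] = old   # every substitution here is nonsense; skip
            continue
        muts.append((pos, old, chars[pos]))
        taken.add(pos)
    return "".join(chars), muts


def _clone_sizes(rng, cfg: SimConfig, n: int) -> np.ndarray:
    if cfg.clone_size_law == "geometric":
        return rng.geometric(cfg.clone_size_p, size=n)
    if cfg.clone_size_law == "zipf":
        return rng.zipf(cfg.clone_size_zipf_a, size=n)
    if cfg.clone_size_law == "constant":
        return np.full(n, cfg.clone_size_const, dtype=int)
    raise ConfigurationError(f"unknown clone size law {cfg.clone_size_law!r}")


def simulate_repertoire(germline: GermlineSet, config: SimConfig,
                        seed: int) -> tuple[list[SimCell], SimTruth]:
    """Sample a repertoire of cells with full ground truth.

    Clone 0 is the planted dominant clone when ``config.planted_clone``
    is set; its per-cell SHM step is at most one nucleotide.
    """
    rng = np.random.default_rng(seed)
    matrix = validate_switch_matrix(config.switch_matrix
                                    or default_switch_matrix())
    iso_index = {iso: i for i, iso in enumerate(ISOTYPES)}
    switched_targets = [iso for iso in ISOTYPES if is_switched(iso)]

    truth = SimTruth()
    cells: list[SimCell] = []
    sizes = list(_clone_sizes(rng, config, config.n_clones))
    planted = config.planted_clone
    if planted is not None:
        sizes.insert(0, planted.n_cells)

    for clone_id, size in enumerate(sizes):
        is_planted = planted is not None and clone_id == 0
        # --- founder recombination
        v = germline.v_segments[int(rng.integers(len(germline.v_segments)))]
        d = germline.d_segments[int(rng.integers(len(germline.d_segments)))]
        j = germline.j_segments[int(rng.integers(len(germline.j_segments)))]
        for _ in range(200):
            n1_len, n2_len = _sample_junction(rng, len(d.seq), config.junction_n_max)
            n1 = _random_bases(rng, n1_len)
            n2 = _random_bases(rng, n2_len)
            founder_seq = build_vdj(germline, v.name, d.name, j.name, n1, n2)
            if not config.avoid_stop_codons or _translate_ok(founder_seq):
                break
        else:
            raise ConfigurationError("could not sample a productive junction")

        # --- founder isotype
        if is_planted:
            founder_iso = "IGHM"
        else:
            p_sw = (config.founder_switch_probs.get(v.name, 0.0)
                    if isinstance(config.founder_switch_probs, dict)
                    else float(config.founder_switch_probs))
            if rng.random() < p_sw:
                row = np.array([matrix[iso_index["IGHM"], iso_index[t]]
                                for t in switched_targets])
                if row.sum() <= 0:
                    row = np.ones(len(switched_targets))
                row = row / row.sum()
                founder_iso = switched_targets[
                    int(rng.choice(len(switched_targets), p=row))]
            elif rng.random() < config.founder_igd_prob:
                founder_iso = "IGHD"
            else:
                founder_iso = "IGHM"

        clone_cells: list[tuple[str, str, set, tuple]] = []  # seq, iso, taken, muts
        members = []
        for i in range(int(size)):
            if i == 0:
                seq, iso, muts = founder_seq, founder_iso, ()
                taken: set = set()
            else:
                parent_seq, parent_iso, parent_taken, parent_muts = \
                    clone_cells[int(rng.integers(i))]
                iso = ISOTYPES[int(rng.choice(len(ISOTYPES),
                                              p=matrix[iso_index[parent_iso]]))]
                if iso != parent_iso:
                    truth.switch_events[(parent_iso, iso)] += 1
                taken = set(parent_taken)
                if is_planted:
                    n_new = int(rng.random() < planted.step_mutation_prob)
                else:
                    n_new = int(rng.binomial(len(parent_seq), config.shm_rate))
                seq, new_muts = _mutate(rng, parent_seq, n_new, taken,
                                        config.avoid_stop_codons)
                muts = tuple(parent_muts) + tuple(new_muts)
            if is_planted and i > 0 and iso == parent_iso and \
                    rng.random() < planted.switch_prob:
                # rare within-clone CSR of the malignant clone
                row = matrix[iso_index[iso]].copy()
                row[iso_index[iso]] = 0.0
                if row.sum() > 0:
                    row /= row.sum()
                    new_iso = ISOTYPES[int(rng.choice(len(ISOTYPES), p=row))]
                    truth.switch_events[(iso, new_iso)] += 1
                    iso = new_iso
            clone_cells.append((seq, iso, taken, muts))

            if iso in UNSWITCHED and not muts:
                cell_type = "naive"
            elif rng.random() < config.plasmablast_prob:
                cell_type = "plasmablast"
            else:
                cell_type = "memory"
            cell = SimCell(
                cell_id=len(cells), clone_id=clone_id, cell_type=cell_type,
                v_name=v.name, d_name=d.name, j_name=j.name, n1=n1, n2=n2,
                isotype=iso, shm_positions=muts,
                rna_copies=int(config.rna_copies[cell_type]))
            cells.append(cell)
            truth.sequences[cell.cell_id] = seq
            members.append(cell.cell_id)
        truth.clone_members[clone_id] = members
    truth.cells = cells
    return cells, truth


def cell_sequence(cell: SimCell, germline: GermlineSet) -> str:
    """Reconstruct a cell's true V(D)J sequence from its truth record."""
    seq = list(build_vdj(germline, cell.v_name, cell.d_name, cell.j_name,
                         cell.n1, cell.n2))
    for pos, old, new in cell.shm_positions:
        assert seq[pos] == old
        seq[pos] = new
    return "".join(seq)


# -------------------------------------------------------------------- reads

def _make_barcode(rng, used: set) -> str:
    while True:
        ns = _random_bases(rng, 12)
        bc = ns[0:4] + "T" + ns[4:8] + "T" + ns[8:12] + "T"
        if bc not in used:
            used.add(bc)
            return bc


def _open_out(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "wt")
    return open(path, "w")


def emit_reads(
    cells: list[SimCell],
    germline: GermlineSet,
    error_rate: float,
    pcr_duplicates: float,
    seed: int,
    r1_path,
    r2_path,
    truth: SimTruth | None = None,
    read_length: int = 280,
    constant_trail: int = 50,
    min_overlap: int = 50,
    seq_error_rate: float = 0.0,
) -> SimTruth:
    """Write paired FASTQ for a repertoire and record barcode ground truth.

    Amplicon layout (V-primer-first orientation, fixed):
    ``[15-nt barcode][V(D)J][first constant_trail nt of the constant gene]``.
    R1 is the amplicon 5' end, R2 the reverse complement of its 3' end;
    the mates overlap by ``2*read_length - len(amplicon)`` bases.
    """
    if not (0 <= error_rate < 0.1):
        raise ConfigurationError("error_rate must be in [0, 0.1)")
    rng = np.random.default_rng(seed)
    if truth is None:
        truth = SimTruth(cells=list(cells))
    truth.error_rate = error_rate
    used_barcodes: set = set()
    base_arr = np.frombuffer(b"ACGT", dtype=np.uint8)

    with _open_out(r1_path) as f1, _open_out(r2_path) as f2:
        for cell in cells:
            vdj = truth.sequences.get(cell.cell_id) or cell_sequence(cell, germline)
            amplicon_tail = vdj + germline.c(cell.isotype).seq[:constant_trail]
            amp_len = BARCODE_LENGTH + len(amplicon_tail)
            if 2 * read_length - amp_len <= min_overlap:
                raise ConfigurationError(
                    f"amplicon of {amp_len} nt leaves <= {min_overlap} bp "
                    f"overlap at read length {read_length}")
            for _ in range(cell.rna_copies):
                barcode = _make_barcode(rng, used_barcodes)
                mol_id = len(truth.molecules)
                truth.molecules.append((mol_id, cell.cell_id, barcode))
                truth.barcode_to_molecule[barcode] = mol_id
                amplicon = barcode + amplicon_tail
                n_pairs = 1 + int(rng.poisson(pcr_duplicates))
                for p in range(n_pairs):
                    copy = np.frombuffer(amplicon.encode(), dtype=np.uint8).copy()
                    n_err = int(rng.binomial(len(copy), error_rate))
                    if n_err:
                        pos = rng.choice(len(copy), size=n_err, replace=False)
                        shift = rng.integers(1, 4, size=n_err)
                        idx = np.searchsorted(base_arr, copy[pos])
                        copy[pos] = base_arr[(idx + shift) % 4]
                    copy_s = copy.tobytes().decode()
                    r1 = copy_s[:read_length]
                    r2 = revcomp(copy_s[-read_length:])
                    if seq_error_rate > 0:
                        r1 = _per_mate_errors(rng, r1, seq_error_rate)
                        r2 = _per_mate_errors(rng, r2, seq_error_rate)
                    read_id = f"mol{mol_id}.{p}"
                    truth.reads.append((read_id, mol_id))
                    q1 = "I" * len(r1)
                    q2 = "I" * len(r2)
                    f1.write(f"@{read_id}/1\n{r1}\n+\n{q1}\n")
                    f2.write(f"@{read_id}/2\n{r2}\n+\n{q2}\n")
    return truth


def _per_mate_errors(rng, seq: str, rate: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    n = int(rng.binomial(len(arr), rate))
    if n:
        base_arr = np.frombuffer(b"ACGT", dtype=np.uint8)
        pos = rng.choice(len(arr), size=n, replace=False)
        shift = rng.integers(1, 4, size=n)
        idx = np.searchsorted(base_arr, arr[pos])
        arr[pos] = base_arr[(idx + shift) % 4]
    return arr.tobytes().decode()
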