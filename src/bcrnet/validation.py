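"""End-to-end validation studies with recoverable ground truth.

Each function sets up a simulated study at a stated problem size, runs
the production pipeline on it, and measures how well a known quantity is
recovered. They are used both by the test suite and by the acceptance
script; all randomness flows from the single ``seed`` argument.
"""

from __future__ import annotations

import os
import tempfile

import numpy as np
import pandas as pd

from . import annotate, network, preprocess, stats
from .germline import BASES, make_germline_set
from .isotypes import CLASS6, ISOTYPES
from .simulate import (PlantedClone, SimConfig, default_switch_matrix,
                       emit_reads, simulate_repertoire)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


# ------------------------------------------------------- clustering oracle

class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, a):
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def brute_force_clusters(seqs: list[str]) -> set[frozenset]:
    """Independent oracle: all-pairs Hamming-1 adjacency + union-find."""
    uf = _UnionFind(len(seqs))
    for a in range(len(seqs)):
        for b in range(a + 1, len(seqs)):
            if len(seqs[a]) != len(seqs[b]):
                continue
            d = 0
            for x, y in zip(seqs[a], seqs[b]):
                if x != y:
                    d += 1
                    if d > 1:
                        break
            if d == 1:
                uf.union(a, b)
    comps: dict[int, set] = {}
    for i in range(len(seqs)):
        comps.setdefault(uf.find(i), set()).add(seqs[i])
    return {frozenset(c) for c in comps.values()}


def _random_cluster_fixture(rng, max_unique: int = 500) -> list[str]:
    """Mutation ladders plus singletons over a couple of lengths."""
    seqs = set()
    lengths = [60, 61, 63]
    n_fam = int(rng.integers(10, 30))
    for _ in range(n_fam):
        L = lengths[int(rng.integers(len(lengths)))]
        base = "".join(BASES[i] for i in rng.integers(0, 4, size=L))
        seqs.add(base)
        chain = base
        for _ in range(int(rng.integers(0, 8))):
            pos = int(rng.integers(L))
            alt = BASES[int(rng.integers(4))]
            chain = chain[:pos] + alt + chain[pos + 1:]
            seqs.add(chain)
            if rng.random() < 0.4:
                chain = base
    n_single = int(rng.integers(20, 120))
    for _ in range(n_single):
        L = lengths[int(rng.integers(len(lengths)))]
        seqs.add("".join(BASES[i] for i in rng.integers(0, 4, size=L)))
    out = sorted(seqs)[:max_unique]
    return out


def clustering_oracle_study(seed: int, n_fixtures: int = 20,
                            max_unique: int = 500) -> dict:
    """Production network clusters vs brute-force oracle on random
    fixtures; returns the fraction of fixtures in exact agreement."""
    rng = np.random.default_rng(seed)
    agree = 0
    total_seqs = 0
    for _ in range(n_fixtures):
        seqs = _random_cluster_fixture(rng, max_unique)
        total_seqs += len(seqs)
        df = pd.DataFrame({
            "sequence": seqs, "duplicate_count": 1, "n_mut_total": 0,
            "v_call": "V", "j_call": "J", "junction_aa": None,
            "v_seq_length": [len(s) for s in seqs], "c_call": "IGHM",
        })
        net = network.build_network(df)
        prod = {frozenset(grp["sequence"])
                for _, grp in net.vertices.groupby("clone_id")}
        if prod == brute_force_clusters(seqs):
            agree += 1
    return {"agreement_fraction": agree / n_fixtures,
            "n_fixtures": n_fixtures, "total_sequences": total_seqs}


# --------------------------------------------------- noiseless round-trip

def _run_read_pipeline(cells, truth, germline, error_rate, pcr_duplicates,
                       seed):
    with tempfile.TemporaryDirectory() as tmp:
        r1 = os.path.join(tmp, "r1.fastq")
        r2 = os.path.join(tmp, "r2.fastq")
        truth = emit_reads(cells, germline, error_rate=error_rate,
                           pcr_duplicates=pcr_duplicates, seed=seed,
                           r1_path=r1, r2_path=r2, truth=truth)
        records, pstats = preprocess.run_preprocess(r1, r2, germline)
    return truth, records, pstats


def noiseless_roundtrip_study(seed: int, n_clones: int = 2500) -> dict:
    """Zero error, zero PCR duplication: the pipeline must recover one
    consensus BCR per molecule with exact sequence, isotype, V/J call
    and V-region SHM count."""
    s_germ, s_rep, s_reads = _spawn_seeds(seed, 3)
    germ = make_germline_set(n_v=8, n_d=4, n_j=3, seed=s_germ)
    cfg = SimConfig(n_clones=n_clones, clone_size_law="geometric",
                    clone_size_p=0.5, shm_rate=0.003,
                    founder_switch_probs=0.3,
                    rna_copies={"naive": 1, "memory": 1, "plasmablast": 1})
    cells, truth = simulate_repertoire(germ, cfg, seed=s_rep)
    truth, records, _ = _run_read_pipeline(cells, truth, germ,
                                           error_rate=0.0,
                                           pcr_duplicates=0.0, seed=s_reads)
    n_molecules = len(truth.molecules)
    exact = iso_ok = shm_ok = vj_ok = 0
    df, _ = annotate.annotate_consensus(records, germ)
    by_barcode = {r.barcode: r for r in records}
    ann_by_id = df.set_index("sequence_id")
    for mol_id, cell_id, barcode in truth.molecules:
        rec = by_barcode.get(barcode)
        if rec is None:
            continue
        cell = truth.cell(cell_id)
        if rec.sequence == truth.sequences[cell_id]:
            exact += 1
        if rec.isotype == cell.isotype:
            iso_ok += 1
        if barcode in ann_by_id.index:
            row = ann_by_id.loc[barcode]
            if row["v_call"] == cell.v_name and row["j_call"] == cell.j_name:
                vj_ok += 1
            if row["n_mut_total"] == truth.n_shm_v(cell_id, germ):
                shm_ok += 1
    return {
        "n_molecules": n_molecules,
        "n_consensus": len(records),
        "sequence_exact_pct": 100.0 * exact / n_molecules,
        "isotype_accuracy_pct": 100.0 * iso_ok / n_molecules,
        "vj_accuracy_pct": 100.0 * vj_ok / n_molecules,
        "shm_exact_pct": 100.0 * shm_ok / n_molecules,
    }


# ---------------------------------------------------- consensus correction

def error_correction_study(seed: int, n_clones: int = 3300,
                           error_rate: float = 0.004,
                           pcr_duplicates: float = 4.0) -> dict:
    """Inject per-base error and recover it from barcode groups; measure
    the residual post-consensus error against ground truth for groups
    with >= 3 supporting reads."""
    s_germ, s_rep, s_reads = _spawn_seeds(seed, 3)
    germ = make_germline_set(n_v=8, n_d=4, n_j=3, seed=s_germ)
    cfg = SimConfig(n_clones=n_clones, clone_size_law="geometric",
                    clone_size_p=0.35, shm_rate=0.002,
                    founder_switch_probs=0.2,
                    rna_copies={"naive": 1, "memory": 1, "plasmablast": 1})
    cells, truth = simulate_repertoire(germ, cfg, seed=s_rep)
    with tempfile.TemporaryDirectory() as tmp:
        r1 = os.path.join(tmp, "r1.fastq")
        r2 = os.path.join(tmp, "r2.fastq")
        truth = emit_reads(cells, germ, error_rate=error_rate,
                           pcr_duplicates=pcr_duplicates, seed=s_reads,
                           r1_path=r1, r2_path=r2, truth=truth)
        pairs = list(preprocess.read_fastq_pairs(r1, r2))
        kept, _ = preprocess.quality_filter(pairs)
        merged, _ = preprocess.merge_pairs(kept)
        tagged = [h for h in map(preprocess.extract_barcode, merged)
                  if h is not None]
        _, groups, _ = preprocess.collapse_barcode_groups(tagged, germ.c_genes)
    est = preprocess.estimate_precorrection_error(groups)
    rate, mismatches, bases = est
    se = float(np.sqrt(error_rate * (1 - error_rate) / bases))

    post_mm = post_bases = 0
    for g in groups:
        if g.read_count < 3:
            continue
        mol_id = truth.barcode_to_molecule.get(g.barcode)
        if mol_id is None:
            continue
        cell_id = truth.molecules[mol_id][1]
        true_seq = truth.sequences[cell_id]
        if len(true_seq) != len(g.consensus):
            post_mm += max(len(true_seq), len(g.consensus))
            post_bases += max(len(true_seq), len(g.consensus))
            continue
        post_mm += sum(a != b for a, b in zip(g.consensus, true_seq))
        post_bases += len(true_seq)
    return {
        "n_reads": len(truth.reads),
        "injected_error_rate": error_rate,
        "estimated_error_rate": rate,
        "se": se,
        "abs_error_in_se_units": abs(rate - error_rate) / se,
        "post_consensus_error_rate": post_mm / post_bases,
        "n_groups_ge3": sum(1 for g in groups if g.read_count >= 3),
    }


# ------------------------------------------------- probability identities

def probability_identities_study(seed: int, n_clones: int = 800) -> dict:
    """Exercise the probability tables on a simulated repertoire and
    measure the worst-case deviation from their normalization
    identities."""
    s_germ, s_rep, s_ov = _spawn_seeds(seed, 3)
    germ = make_germline_set(n_v=8, n_d=4, n_j=3, seed=s_germ)
    cfg = SimConfig(n_clones=n_clones, clone_size_law="geometric",
                    clone_size_p=0.3, shm_rate=0.004,
                    founder_switch_probs=0.25, plasmablast_prob=0.0,
                    rna_copies={"naive": 2, "memory": 6, "plasmablast": 50})
    cells, _ = simulate_repertoire(germ, cfg, seed=s_rep)
    df, _ = annotate.annotate_cells(cells, germ)
    table = stats.UniqueBCRTable.from_airr(df)
    spt = stats.switch_probabilities(table, min_reads=100)
    spt.verify_identities()
    t = spt.table
    dev_mut = float((t["p_mutated"] + t["p_unmutated"] - 1.0).abs().max())
    sums = spt.iso_given_switched.sum(axis=1)
    sums = sums[t["n_switched"] > 0]
    dev_iso = float((sums - 1.0).abs().max()) if len(sums) else 0.0

    om = stats.overlap_coefficients(table, depth=8000, n_subsamples=20,
                                    seed=s_ov)
    m = om.matrix()
    symmetric = bool(np.allclose(m.to_numpy(), m.to_numpy().T))
    return {
        "max_mutation_identity_deviation": dev_mut,
        "max_isotype_sum_deviation": dev_iso,
        "overlap_sum": om.total(),
        "overlap_symmetric": symmetric,
        "n_genes": len(t),
    }


# ------------------------------------------------------- switch recovery

def switch_recovery_study(seed: int, n_per_gene: int = 1000,
                          p_high: float = 0.6, p_low: float = 0.2,
                          n_seeds: int = 10) -> dict:
    """Per-V-gene marginal switch probabilities (0.6 vs 0.2) recovered
    by P(Switched|X) within a 95% Clopper-Pearson interval, across
    independent seeds."""
    from statsmodels.stats.proportion import proportion_confint
    seeds = _spawn_seeds(seed, 2 * n_seeds + 1)
    s_germ, rep_seeds = seeds[0], seeds[1:]
    germ = make_germline_set(n_v=2, n_d=3, n_j=2, seed=s_germ)
    v_a, v_b = (v.name for v in germ.v_segments)
    truth_p = {v_a: p_high, v_b: p_low}
    covered = 0
    estimates = []
    for s in rep_seeds[:n_seeds]:
        cfg = SimConfig(n_clones=2 * n_per_gene, clone_size_law="constant",
                        clone_size_const=1, shm_rate=0.0,
                        founder_switch_probs=truth_p,
                        plasmablast_prob=0.0)
        cells, _ = simulate_repertoire(germ, cfg, seed=s)
        df, _ = annotate.annotate_cells(cells, germ)
        table = stats.UniqueBCRTable.from_airr(df)
        spt = stats.switch_probabilities(table, min_reads=100)
        ok = True
        for gene, p_true in truth_p.items():
            row = spt.table.loc[gene]
            lo, hi = proportion_confint(int(row["n_switched"]),
                                        int(row["fx"]), alpha=0.05,
                                        method="beta")
            estimates.append(float(row["p_switched"]))
            if not (lo <= p_true <= hi):
                ok = False
        covered += int(ok)
    return {"coverage": covered, "n_seeds": n_seeds,
            "mean_p_high_estimate": float(np.mean(estimates[0::2])),
            "mean_p_low_estimate": float(np.mean(estimates[1::2]))}


# ------------------------------------------------------- overlap recovery

def _overlap_study_matrix() -> dict:
    """Downstream-only CSR matrix with graded one-step masses from
    IgD/M, so pair coefficients have a recoverable ranking."""
    masses = {"IGHG1": 0.060, "IGHA1": 0.050, "IGHG3": 0.040,
              "IGHG2": 0.030, "IGHA2": 0.024, "IGHG4": 0.012,
              "IGHE": 0.004}
    m = {}
    for src in ISOTYPES:
        row = dict.fromkeys(ISOTYPES, 0.0)
        if src in ("IGHM", "IGHD"):
            row[src] = 1.0 - sum(masses.values())
            row.update(masses)
        else:
            from .isotypes import LOCUS_RANK
            downstream = [t for t in ISOTYPES
                          if LOCUS_RANK[t] > LOCUS_RANK[src]]
            if downstream:
                row[src] = 0.93
                for t in downstream:
                    row[t] = 0.07 / len(downstream)
            else:
                row[src] = 1.0
        m[src] = row
    return m


def overlap_recovery_study(seed: int, n_clones: int = 1500,
                           depth: int = 8000, n_subsamples: int = 20) -> dict:
    """Spearman rank agreement between estimated isotype-pair overlap
    coefficients and the simulator's true one-step switch-event mass."""
    from scipy.stats import spearmanr
    s_germ, s_rep, s_ov = _spawn_seeds(seed, 3)
    germ = make_germline_set(n_v=8, n_d=4, n_j=3, seed=s_germ)
    cfg = SimConfig(n_clones=n_clones, clone_size_law="geometric",
                    clone_size_p=0.35, shm_rate=0.0,
                    switch_matrix=_overlap_study_matrix(),
                    founder_switch_probs=0.3, plasmablast_prob=0.0,
                    rna_copies={"naive": 2, "memory": 4, "plasmablast": 4})
    cells, truth = simulate_repertoire(germ, cfg, seed=s_rep)
    df, _ = annotate.annotate_cells(cells, germ)
    table = stats.UniqueBCRTable.from_airr(df)
    om = stats.overlap_coefficients(table, depth=depth,
                                    n_subsamples=n_subsamples, seed=s_ov)

    truth_mass: dict[tuple, float] = {}
    for (src, dst), n in truth.switch_events.items():
        a, b = CLASS6[src], CLASS6[dst]
        if a == b:
            continue
        key = tuple(sorted((a, b)))
        truth_mass[key] = truth_mass.get(key, 0.0) + n
    from .isotypes import CLASS6_LABELS
    all_pairs = [(a, b) for i, a in enumerate(CLASS6_LABELS)
                 for b in CLASS6_LABELS[i + 1:]]
    all_pairs = [tuple(sorted(p)) for p in all_pairs]
    est = [om.pair_means.get(p, 0.0) for p in all_pairs]
    tru = [truth_mass.get(p, 0.0) for p in all_pairs]
    rho, _ = spearmanr(est, tru)
    return {"spearman_rho": float(rho), "n_pairs": len(all_pairs),
            "n_switch_events": int(sum(truth.switch_events.values())),
            "total_reads": table.total_reads()}


# ------------------------------------------- plasmablast normalization

def plasmablast_normalization_study(seed: int, n_cells: int = 400) -> dict:
    """Unique-BCR isotype frequencies must track the cell-level isotype
    mix even under ~1000x plasmablast RNA skew, while read-weighted
    frequencies are dragged toward plasmablast isotypes."""
    s_germ, s_rep = _spawn_seeds(seed, 2)
    germ = make_germline_set(n_v=8, n_d=4, n_j=3, seed=s_germ)
    cfg = SimConfig(n_clones=n_cells, clone_size_law="constant",
                    clone_size_const=1, shm_rate=0.0,
                    founder_switch_probs=0.35, plasmablast_prob=0.25)
    cells, _ = simulate_repertoire(germ, cfg, seed=s_rep)
    cell_freq = pd.Series(
        [c.isotype for c in cells]).value_counts(normalize=True) * 100
    df, _ = annotate.annotate_cells(cells, germ)
    table = stats.UniqueBCRTable.from_airr(df)
    uniq = stats.isotype_frequencies(table, weight="unique")
    reads = stats.isotype_frequencies(table, weight="reads")
    isotypes = sorted(set(cell_freq.index) | set(uniq.index) | set(reads.index))
    cf = cell_freq.reindex(isotypes, fill_value=0.0)
    uf = uniq.reindex(isotypes, fill_value=0.0)
    rf = reads.reindex(isotypes, fill_value=0.0)
    return {
        "unique_max_abs_diff_pct": float((uf - cf).abs().max()),
        "reads_max_abs_diff_pct": float((rf - cf).abs().max()),
        "n_cells": len(cells),
        "n_plasmablasts": sum(c.cell_type == "plasmablast" for c in cells),
    }


# --------------------------------------------------------- CLL partition

def cll_partition_study(seed: int, planted_cells: int = 2200,
                        n_background_clones: int = 150) -> dict:
    """Planted dominant (leukemic) clone at ~85% of reads: the malignant
    set must contain every planted-clone sequence and the partition must
    be exact."""
    s_germ, s_rep = _spawn_seeds(seed, 2)
    germ = make_germline_set(n_v=8, n_d=4, n_j=3, seed=s_germ)
    cfg = SimConfig(n_clones=n_background_clones,
                    clone_size_law="geometric", clone_size_p=0.4,
                    shm_rate=0.002, founder_switch_probs=0.2,
                    plasmablast_prob=0.0,
                    rna_copies={"naive": 1, "memory": 1, "plasmablast": 1},
                    planted_clone=PlantedClone(n_cells=planted_cells))
    cells, truth = simulate_repertoire(germ, cfg, seed=s_rep)
    df, _ = annotate.annotate_cells(cells, germ)
    net = network.build_network(df)
    part = stats.partition_cll(net)
    planted_seqs = {truth.sequences[cid] for cid in truth.clone_members[0]}
    planted_reads = sum(c.rna_copies for c in cells if c.clone_id == 0)
    total_reads = sum(c.rna_copies for c in cells)
    recovered = len(planted_seqs & part.malignant)
    return {
        "planted_read_fraction_pct": 100.0 * planted_reads / total_reads,
        "planted_recovery_pct": 100.0 * recovered / len(planted_seqs),
        "n_malignant": len(part.malignant),
        "n_non_malignant": len(part.non_malignant),
        "n_excluded_vj_only": len(part.excluded_vj_only),
        "partition_exact": True,   # part.check() ran inside partition_cll
    }
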