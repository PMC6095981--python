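"""Pipeline orchestration: simulate -> preprocess -> annotate -> network
-> stats, with a JSON manifest recording seeds, thresholds and per-stage
record counts. Identical config + seed gives byte-identical outputs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate as _annotate
from . import network as _network
from . import preprocess as _preprocess
from . import stats as _stats
from .germline import GermlineSet, make_germline_set
from .simulate import ConfigurationError, SimConfig, emit_reads, simulate_repertoire

DEFAULT_CONFIG = {
    "seed": 1,
    "sample_id": "sample",
    "germline": {"n_v": 8, "n_d": 4, "n_j": 3},
    "simulate": {"n_clones": 100, "clone_size_law": "geometric",
                 "clone_size_p": 0.3, "shm_rate": 0.002,
                 "founder_switch_probs": 0.25, "plasmablast_prob": 0.02},
    "reads": {"error_rate": 0.001, "pcr_duplicates": 2.0,
              "read_length": 280, "constant_trail": 50},
    "preprocess": {"min_median_phred": 34.0, "min_overlap": 50,
                   "kmer": 10, "certainty": 0.8},
    "stats": {"overlap_depth": 8000, "overlap_subsamples": 20,
              "min_reads": 100, "cll_mode": False},
}


def _merge_config(user: dict | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (user or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _stage_seeds(seed: int) -> dict:
    ss = np.random.SeedSequence(seed)
    names = ["germline", "repertoire", "reads", "overlap"]
    return {n: int(s.generate_state(1)[0] % (2**31))
            for n, s in zip(names, ss.spawn(len(names)))}


def load_germline(cfg: dict, outdir: Path, seeds: dict) -> GermlineSet:
    gcfg = cfg["germline"]
    if "path" in gcfg:
        path = Path(gcfg["path"])
        if not path.exists():
            raise ConfigurationError(f"germline FASTA not found: {path}")
        return GermlineSet.from_fasta(path)
    germ = make_germline_set(gcfg["n_v"], gcfg["n_d"], gcfg["n_j"],
                             seed=seeds["germline"])
    germ.to_fasta(outdir / "germline.fasta")
    return germ


def run_pipeline(config: dict | None, outdir) -> dict:
    """Run all stages; returns the manifest (also written to JSON)."""
    cfg = _merge_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(int(cfg["seed"]))
    manifest = {"seed": cfg["seed"], "stage_seeds": seeds, "config": cfg,
                "counts": {}, "failed_stage": None}
    try:
        germ = load_germline(cfg, outdir, seeds)

        sim_kwargs = dict(cfg["simulate"])
        sim = SimConfig(**sim_kwargs)
        cells, truth = simulate_repertoire(germ, sim, seed=seeds["repertoire"])
        manifest["counts"]["cells"] = len(cells)
        manifest["counts"]["clones"] = len(truth.clone_members)

        r1 = outdir / "reads_R1.fastq.gz"
        r2 = outdir / "reads_R2.fastq.gz"
        rcfg = cfg["reads"]
        truth = emit_reads(cells, germ, error_rate=rcfg["error_rate"],
                           pcr_duplicates=rcfg["pcr_duplicates"],
                           seed=seeds["reads"], r1_path=r1, r2_path=r2,
                           read_length=rcfg["read_length"],
                           constant_trail=rcfg["constant_trail"])
        truth.to_tsv(outdir / "truth.tsv", germ)
        manifest["counts"]["molecules"] = len(truth.molecules)
        manifest["counts"]["read_pairs"] = len(truth.reads)

        pcfg = cfg["preprocess"]
        records, pstats = _preprocess.run_preprocess(
            r1, r2, germ,
            min_median_phred=pcfg["min_median_phred"],
            min_overlap=pcfg["min_overlap"], kmer=pcfg["kmer"],
            certainty=pcfg["certainty"],
            constant_trail=cfg["reads"]["constant_trail"])
        manifest["counts"]["preprocess"] = pstats
        with open(outdir / "consensus.fasta", "w") as fh:
            for rec in records:
                fh.write(f">{rec.barcode}|{rec.duplicate_count}|{rec.isotype}\n"
                         f"{rec.sequence}\n")

        airr, n_dropped = _annotate.annotate_consensus(
            records, germ, sample_id=cfg["sample_id"])
        manifest["counts"]["unannotatable"] = n_dropped
        manifest["counts"]["annotated"] = len(airr)

        net = _network.build_network(airr)
        clone_of = dict(zip(net.vertices["sequence"], net.vertices["clone_id"]))
        airr["clone_id"] = airr["sequence"].map(clone_of)
        airr.to_csv(outdir / "rearrangements.tsv", sep="\t", index=False)
        edges = pd.DataFrame(
            [(net.vertices.loc[a, "sequence"], net.vertices.loc[b, "sequence"])
             for a, b in net.graph.edges], columns=["from", "to"])
        edges.to_csv(outdir / "edges.tsv", sep="\t", index=False)
        vert = net.vertices.copy()
        vert["isotypes"] = vert["isotypes"].map(lambda s: ",".join(sorted(s)))
        vert.to_csv(outdir / "vertices.tsv", sep="\t", index=False)
        manifest["counts"]["unique_sequences"] = len(net.vertices)
        manifest["counts"]["clusters"] = net.n_clusters

        scfg = cfg["stats"]
        table = _stats.UniqueBCRTable.from_airr(airr)
        freq = pd.DataFrame({
            "unique_pct": _stats.isotype_frequencies(table, weight="unique"),
            "read_pct": _stats.isotype_frequencies(table, weight="reads"),
        })
        freq.to_csv(outdir / "isotype_frequencies.tsv", sep="\t")
        _stats.sample_summaries(table).to_csv(
            outdir / "isotype_summaries.tsv", sep="\t")
        om = _stats.overlap_coefficients(
            table, depth=scfg["overlap_depth"],
            n_subsamples=scfg["overlap_subsamples"], seed=seeds["overlap"])
        om.matrix().to_csv(outdir / "overlap_matrix.tsv", sep="\t")
        spt = _stats.switch_probabilities(table, min_reads=scfg["min_reads"])
        spt.table.to_csv(outdir / "switch_probabilities.tsv", sep="\t")
        spt.iso_given_switched.to_csv(
            outdir / "isotype_given_switched.tsv", sep="\t")
        try:
            prof = _stats.ighv_isotype_profiles(table,
                                                min_reads=scfg["min_reads"])
            prof.profiles.to_csv(outdir / "ighv_profiles.tsv", sep="\t")
        except ValueError:
            manifest["counts"]["ighv_profiles"] = "no gene passed filter"
        _network.clone_summaries(net).drop(
            columns=["isotype_set", "isotype_classes"]).to_csv(
            outdir / "clone_summaries.tsv", sep="\t", index=False)
        if scfg.get("cll_mode"):
            part = _stats.partition_cll(net)
            manifest["counts"]["cll_partition"] = {
                "malignant": len(part.malignant),
                "non_malignant": len(part.non_malignant),
                "excluded_vj_only": len(part.excluded_vj_only),
            }
    except Exception as exc:               # record the failure point
        manifest["failed_stage"] = f"{type(exc).__name__}: {exc}"
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
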