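"""Repertoire statistics over unique BCRs.

All frequency and probability analyses count *unique BCRs* — distinct
V(D)J nucleotide sequences after barcode correction — rather than reads,
to cancel per-cell RNA abundance differences (plasmablasts carry orders
of magnitude more BCR RNA than naive cells). Read support is kept
alongside for the read-count gene filters and for subsampled overlap
coefficients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .isotypes import (CLASS6, CLASS6_LABELS, CLASS6_SWITCHED, CLASS7,
                       CLASS7_LABELS, is_switched)
from .network import ClonalNetwork, largest_cluster

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- container

@dataclass
class UniqueBCRTable:
    """Unique V(D)J sequences with per-isotype presence and read support.

    ``unique``: one row per distinct sequence (v_call, j_call,
    junction_aa, n_mut_total, isotypes, total_reads).
    ``presence``: one row per (sequence, isotype[, sample]) with summed
    read counts — the "presence events" used as counting units.
    """
    unique: pd.DataFrame
    presence: pd.DataFrame

    @classmethod
    def from_airr(cls, df: pd.DataFrame) -> "UniqueBCRTable":
        presence = (df.groupby(["sequence", "c_call", "sample_id"], sort=True)
                    ["duplicate_count"].sum().reset_index())
        unique = df.groupby("sequence", sort=True).agg(
            v_call=("v_call", "first"),
            j_call=("j_call", "first"),
            junction_aa=("junction_aa", "first"),
            cdr3_length=("cdr3_length", "first"),
            n_mut_total=("n_mut_total", "first"),
            n_mut_silent=("n_mut_silent", "first"),
            n_mut_nonsilent=("n_mut_nonsilent", "first"),
            total_reads=("duplicate_count", "sum"),
        )
        unique["isotypes"] = df.groupby("sequence", sort=True)["c_call"].agg(
            lambda s: frozenset(s))
        unique["switched"] = unique["isotypes"].map(
            lambda isos: any(is_switched(i) for i in isos))
        unique["mutated"] = unique["n_mut_total"] >= 1
        return cls(unique=unique, presence=presence)

    def n_unique(self) -> int:
        return len(self.unique)

    def total_reads(self) -> int:
        return int(self.unique["total_reads"].sum())


def _grouped_label(grouping: str | None):
    if grouping is None:
        return lambda iso: iso
    if grouping == "class6":
        return CLASS6.__getitem__
    if grouping == "class7":
        return CLASS7.__getitem__
    raise ValueError(f"unknown grouping {grouping!r}")


# -------------------------------------------------------------- frequencies

def isotype_frequencies(table: UniqueBCRTable, grouping: str | None = None,
                        weight: str = "unique") -> pd.Series:
    """Per-isotype percentage of unique BCRs (or of reads).

    ``weight='unique'`` (the headline normalization): each distinct
    (sequence, isotype) presence event counts once, so a sequence seen
    in k isotypes contributes to k numerators; the denominator is the
    total number of presence events, so percentages sum to 100.
    ``weight='reads'`` weights by duplicate_count instead (the biased
    quantity the unique normalization is designed to replace).
    """
    if table.presence.empty:
        raise ValueError("empty table")
    lab = _grouped_label(grouping)
    p = table.presence.copy()
    p["iso"] = p["c_call"].map(lab)
    if weight == "unique":
        events = p.drop_duplicates(["sequence", "iso"])
        counts = events.groupby("iso").size().astype(float)
    elif weight == "reads":
        counts = p.groupby("iso")["duplicate_count"].sum().astype(float)
    else:
        raise ValueError(f"unknown weight {weight!r}")
    return 100.0 * counts / counts.sum()


def sample_summaries(table: UniqueBCRTable,
                     grouping: str | None = "class6") -> pd.DataFrame:
    """Per-isotype mean CDR3 length and median silent / non-silent SHM,
    over unique-BCR presence events. Isotypes without records are
    simply absent from the result."""
    lab = _grouped_label(grouping)
    p = table.presence.copy()
    p["iso"] = p["c_call"].map(lab)
    events = p.drop_duplicates(["sequence", "iso"]).merge(
        table.unique[["cdr3_length", "n_mut_silent", "n_mut_nonsilent"]],
        left_on="sequence", right_index=True)
    return events.groupby("iso").agg(
        n_unique=("sequence", "size"),
        mean_cdr3_length=("cdr3_length", "mean"),
        median_mut_silent=("n_mut_silent", "median"),
        median_mut_nonsilent=("n_mut_nonsilent", "median"),
    )


# ---------------------------------------------------------- CLL partition

@dataclass
class RepertoirePartition:
    malignant: frozenset          # rules (1) | (2)
    non_malignant: frozenset      # fails (1), (2) and (3)
    excluded_vj_only: frozenset   # matches only rule (3): quarantined
    largest_cluster_id: int

    def check(self, all_sequences) -> None:
        allset = frozenset(all_sequences)
        assert self.malignant | self.non_malignant | self.excluded_vj_only == allset
        assert not (self.malignant & self.non_malignant)
        assert not (self.malignant & self.excluded_vj_only)
        assert not (self.non_malignant & self.excluded_vj_only)


def partition_cll(net: ClonalNetwork) -> RepertoirePartition:
    """Separate malignant from non-malignant BCRs in a CLL repertoire.

    Rule (1): members of the largest (leukemic) cluster by reads.
    Rule (2): identical CDR3 amino-acid region to any rule-(1) BCR.
    Rule (3): same V-J gene combination as a rule-(1) BCR.
    The leukemic repertoire is (1) | (2); the non-malignant repertoire
    excludes (1), (2) *and* (3); sequences matching only (3) belong to
    neither and are quarantined.
    """
    v = net.vertices
    cid = largest_cluster(net, by="reads")
    in_cluster = v["clone_id"] == cid
    cluster = v[in_cluster]
    cdr3s = set(cluster["junction_aa"].dropna())
    vjs = set(zip(cluster["v_call"], cluster["j_call"]))
    is_malignant = in_cluster | v["junction_aa"].isin(cdr3s)
    vj_match = pd.Series(list(zip(v["v_call"], v["j_call"])),
                         index=v.index).isin(vjs)
    malignant = frozenset(v.loc[is_malignant, "sequence"])
    vj_only = frozenset(v.loc[~is_malignant & vj_match, "sequence"])
    non = frozenset(v.loc[~is_malignant & ~vj_match, "sequence"])
    part = RepertoirePartition(malignant, non, vj_only, cid)
    part.check(v["sequence"])
    return part


# ---------------------------------------------------------------- overlap

@dataclass
class OverlapMatrix:
    pair_means: dict              # (classA, classB) sorted tuple -> mean
    pair_se: dict
    n_subsamples: int
    subsample_depth: int
    subsampled: bool
    labels: list = field(default_factory=lambda: list(CLASS6_LABELS))

    def matrix(self) -> pd.DataFrame:
        m = pd.DataFrame(0.0, index=self.labels, columns=self.labels)
        for (a, b), val in self.pair_means.items():
            m.loc[a, b] = val
            m.loc[b, a] = val
        return m

    def total(self) -> float:
        return float(sum(self.pair_means.values()))


def overlap_coefficients(table: UniqueBCRTable, depth: int = 8000,
                         n_subsamples: int = 20, seed: int = 0) -> OverlapMatrix:
    """Mean isotype-pair overlap coefficients over read subsamples.

    Per subsample (``depth`` reads drawn without replacement, weighted by
    read support): every unique V(D)J sequence whose observed isotype
    set — IgD and IgM merged — has size exactly two increments that pair;
    pair counts are then normalized to sum to one ("normalized to the
    total number of events") and averaged over subsamples. Samples with
    fewer than ``depth`` reads are computed once without subsampling.
    """
    rng = np.random.default_rng(seed)
    p = table.presence.copy()
    p["cls"] = p["c_call"].map(CLASS6)
    grouped = (p.groupby(["sequence", "cls"])["duplicate_count"]
               .sum().reset_index())
    counts = grouped["duplicate_count"].to_numpy(dtype=np.int64)
    seq_codes, _ = pd.factorize(grouped["sequence"], sort=True)
    cls_codes = grouped["cls"].map(
        {c: i for i, c in enumerate(CLASS6_LABELS)}).to_numpy()
    total = int(counts.sum())

    subsampled = total >= depth
    if not subsampled:
        logger.warning("only %d reads (< depth %d): computing once "
                       "without subsampling", total, depth)
        draws = [counts]
    else:
        draws = [rng.multivariate_hypergeometric(counts, depth,
                                                 method="marginals")
                 for _ in range(n_subsamples)]

    sub_values: list[dict] = []
    for draw in draws:
        mask = draw > 0
        sub_seq = seq_codes[mask]
        sub_cls = cls_codes[mask]
        order = np.lexsort((sub_cls, sub_seq))
        sub_seq, sub_cls = sub_seq[order], sub_cls[order]
        bounds = np.flatnonzero(np.r_[True, np.diff(sub_seq) != 0, True])
        pairs = []
        for s, e in zip(bounds[:-1], bounds[1:]):
            if e - s == 2:
                a, b = sorted((CLASS6_LABELS[sub_cls[s]],
                               CLASS6_LABELS[sub_cls[s + 1]]))
                pairs.append((a, b))
        vals: dict[tuple, float] = {}
        for pair in pairs:
            vals[pair] = vals.get(pair, 0.0) + 1.0 / len(pairs)
        sub_values.append(vals)

    all_pairs = sorted({p for vals in sub_values for p in vals})
    if not all_pairs:
        logger.warning("no two-isotype events in any subsample")
    means, ses = {}, {}
    for pair in all_pairs:
        series = np.array([vals.get(pair, 0.0) for vals in sub_values])
        means[pair] = float(series.mean())
        ses[pair] = (float(series.std(ddof=1) / np.sqrt(len(series)))
                     if len(series) > 1 else 0.0)
    return OverlapMatrix(means, ses, len(draws), depth, subsampled)


# --------------------------------------------------- switch probabilities

def v_family(v_call: str) -> str:
    return v_call.split("-")[0]


@dataclass
class SwitchProbabilityTable:
    table: pd.DataFrame           # indexed by gene (or family)
    iso_given_switched: pd.DataFrame  # gene x switched class, rows sum to 1
    level: str
    min_reads: int

    def verify_identities(self, atol: float = 0.0) -> None:
        t = self.table
        assert np.allclose(t["p_mutated"] + t["p_unmutated"], 1.0, atol=atol)
        sums = self.iso_given_switched.sum(axis=1)
        support = t.loc[self.iso_given_switched.index, "n_switched"]
        assert np.allclose(sums[support > 0], 1.0, atol=atol)
        probs = t[[c for c in t.columns if c.startswith("p_")]].to_numpy(float)
        finite = probs[np.isfinite(probs)]
        assert ((finite >= 0) & (finite <= 1)).all()


def switch_probabilities(table: UniqueBCRTable, level: str = "gene",
                         min_reads: int = 100,
                         min_samples: int | None = None) -> SwitchProbabilityTable:
    """Conditional class-switch probabilities per V gene (or family).

    Counting unit: unique BCRs. A unique BCR is *switched* if any of its
    isotypes is neither IgM nor IgD, and *mutated* if it carries >= 1
    nucleotide mutation in its V gene. Genes must be supported by more
    than ``min_reads`` reads in total; with ``min_samples`` set, also by
    presence in more than that many samples. P(IsotypeY | X, switched)
    is computed over switched-isotype presence events (grouped classes),
    so it sums to one per gene whenever support is positive.
    """
    u = table.unique.copy()
    u["gene"] = u["v_call"] if level == "gene" else u["v_call"].map(v_family)
    support = u.groupby("gene")["total_reads"].sum()
    keep = set(support[support > min_reads].index)
    if min_samples is not None:
        seq_gene = u["gene"]
        pres = table.presence.merge(seq_gene.rename("gene"),
                                    left_on="sequence", right_index=True)
        n_samp = pres.groupby("gene")["sample_id"].nunique()
        keep &= set(n_samp[n_samp > min_samples].index)
    u = u[u["gene"].isin(keep)]
    dropped = sorted(set(support.index) - keep)
    if dropped:
        logger.info("genes below support filters: %s", dropped)

    grp = u.groupby("gene")
    t = pd.DataFrame({
        "fx": grp.size(),
        "read_support": grp["total_reads"].sum(),
        "n_mutated": grp["mutated"].sum(),
        "n_switched": grp["switched"].sum(),
        "n_switched_mutated": grp.apply(
            lambda g: int((g["switched"] & g["mutated"]).sum()),
            include_groups=False),
        "n_switched_unmutated": grp.apply(
            lambda g: int((g["switched"] & ~g["mutated"]).sum()),
            include_groups=False),
    })
    t["n_unmutated"] = t["fx"] - t["n_mutated"]
    t["p_mutated"] = t["n_mutated"] / t["fx"]
    t["p_unmutated"] = t["n_unmutated"] / t["fx"]
    t["p_switched"] = t["n_switched"] / t["fx"]
    with np.errstate(invalid="ignore", divide="ignore"):
        t["p_switched_mutated"] = np.where(
            t["n_mutated"] > 0, t["n_switched_mutated"] / t["n_mutated"], np.nan)
        t["p_switched_unmutated"] = np.where(
            t["n_unmutated"] > 0, t["n_switched_unmutated"] / t["n_unmutated"],
            np.nan)

    # P(IsotypeY | geneX, switched) over switched presence events
    ev = u.reset_index()[["sequence", "gene", "isotypes"]].explode("isotypes")
    ev = ev[ev["isotypes"].map(is_switched)]
    ev["cls"] = ev["isotypes"].map(CLASS6)
    ev = ev.drop_duplicates(["sequence", "cls"])
    counts = ev.groupby(["gene", "cls"]).size().unstack(fill_value=0)
    counts = counts.reindex(index=t.index, columns=CLASS6_SWITCHED,
                            fill_value=0)
    totals = counts.sum(axis=1)
    iso_given = counts.div(totals.where(totals > 0), axis=0)
    return SwitchProbabilityTable(t, iso_given, level, min_reads)


# ----------------------------------------------------- IGHV/IGHJ profiles

@dataclass
class IsotypeGeneProfiles:
    profiles: pd.DataFrame        # gene x isotype class, % summing to 100
    correlation: pd.DataFrame
    correlation_p: pd.DataFrame
    nonrandomness: pd.DataFrame   # chi-squared vs unmutated IgD/M
    method: str


def ighv_isotype_profiles(table: UniqueBCRTable, min_reads: int = 100,
                          method: str = "spearman",
                          gene_column: str = "v_call") -> IsotypeGeneProfiles:
    """Isotype-specific V (or J) gene usage profiles and their pairwise
    correlation, over unique BCR sequences.

    Genes represented by fewer than ``min_reads`` reads are excluded.
    Each retained isotype class's gene frequencies sum to 100%. The
    non-randomness test compares each class's gene-usage vector against
    unmutated IgD/M usage in an R x 2 chi-squared contingency test.
    """
    u = table.unique
    support = u.groupby(gene_column)["total_reads"].sum()
    genes = sorted(support[support >= min_reads].index)
    if not genes:
        raise ValueError("no gene passes the read-support filter")

    ev = u.reset_index()[["sequence", gene_column, "isotypes", "mutated"]] \
        .explode("isotypes")
    ev["cls"] = ev["isotypes"].map(CLASS7)
    ev = ev[ev[gene_column].isin(genes)]
    events = ev.drop_duplicates(["sequence", "cls"])
    counts = (events.groupby([gene_column, "cls"]).size()
              .unstack(fill_value=0)
              .reindex(index=genes, fill_value=0))
    counts = counts[[c for c in CLASS7_LABELS if c in counts.columns
                     and counts[c].sum() > 0]]
    profiles = 100.0 * counts / counts.sum(axis=0)

    classes = list(profiles.columns)
    corr = pd.DataFrame(np.eye(len(classes)), index=classes, columns=classes)
    pval = pd.DataFrame(np.zeros((len(classes), len(classes))),
                        index=classes, columns=classes)
    fn = sps.spearmanr if method == "spearman" else sps.pearsonr
    for i, a in enumerate(classes):
        for b in classes[i + 1:]:
            r, p = fn(profiles[a], profiles[b])
            corr.loc[a, b] = corr.loc[b, a] = r
            pval.loc[a, b] = pval.loc[b, a] = p

    # reference: unmutated IgD/M unique sequences
    ref = ev[(~ev["mutated"]) & ev["cls"].isin(["IgM", "IgD"])] \
        .drop_duplicates("sequence")
    ref_counts = (ref.groupby(gene_column).size()
                  .reindex(genes, fill_value=0))
    rows = []
    for cls in classes:
        obs = counts[cls]
        mask = (obs + ref_counts) > 0
        contingency = np.vstack([obs[mask], ref_counts[mask]])
        if contingency.shape[1] < 2 or contingency.sum(axis=1).min() == 0:
            rows.append({"isotype": cls, "chi2": np.nan, "p": np.nan,
                         "dof": 0})
            continue
        chi2, p, dof, _ = sps.chi2_contingency(contingency)
        rows.append({"isotype": cls, "chi2": chi2, "p": p, "dof": dof})
    nonrandom = pd.DataFrame(rows).set_index("isotype")
    return IsotypeGeneProfiles(profiles, corr, pval, nonrandom, method)


# ------------------------------------------------------------ cohort tests

def wilcoxon_rank_sum(x, y) -> dict:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) comparison of one
    metric between two cohorts."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    degenerate = (np.std(np.r_[x, y]) == 0)
    stat, p = sps.ranksums(x, y)
    return {"statistic": float(stat), "p_value": float(p),
            "n1": len(x), "n2": len(y), "degenerate": bool(degenerate)}


def anova_one_way(df: pd.DataFrame, response: str, factor: str) -> pd.DataFrame:
    """One-way ANOVA of a conditional probability on gene identity."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    model = smf.ols(f"{response} ~ C({factor})", data=df).fit()
    return sm.stats.anova_lm(model, typ=2)


def anova_two_way(df: pd.DataFrame, response: str, factor_a: str,
                  factor_b: str) -> pd.DataFrame:
    """Two-way ANOVA with interaction (gene x mutational status)."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    model = smf.ols(f"{response} ~ C({factor_a}) * C({factor_b})",
                    data=df).fit()
    return sm.stats.anova_lm(model, typ=2)


def benjamini_hochberg(pvalues) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests
    return multipletests(np.asarray(pvalues, float), method="fdr_bh")[1]
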