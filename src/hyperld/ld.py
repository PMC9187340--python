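"""Linkage-disequilibrium statistics between biallelic sites.

r^2 between two sites is the squared, allele-frequency-normalised
covariance of their minor-allele indicator vectors across haploid
genotypes:

    r^2 = (p_AB - p_A p_B)^2 / (p_A (1-p_A) p_B (1-p_B))

with p_A, p_B the minor-allele frequencies and p_AB the frequency of
genotypes carrying the minor allele at both sites.  The signed statistic
D = p_AB - p_A p_B, with both sites polarised to minor alleles, separates
attraction (coupling, D > 0) from repulsion (D < 0) of minor alleles.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genomes import SnpTable, UndefinedStatisticError, SYNONYMOUS, NONSYNONYMOUS

logger = logging.getLogger(__name__)

SAME_GENE = "same_gene"
ADJACENT_GENES = "adjacent_genes"
INTERGENIC = "intergenic"

NN = "nonsyn-nonsyn"
SS = "syn-syn"
MIXED = "mixed"


class LdUndefinedError(UndefinedStatisticError):
    """LD is undefined (a site is monomorphic in the given vectors)."""


def _minor_polarized(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=np.uint8)
    k = int(v.sum())
    if k == 0 or k == v.size:
        raise LdUndefinedError("site is monomorphic; LD undefined")
    return v if 2 * k <= v.size else (1 - v).astype(np.uint8)


def r_squared(states_i: np.ndarray, states_j: np.ndarray) -> float:
    """r^2 between two biallelic sites given 0/1 state vectors."""
    x = _minor_polarized(states_i)
    y = _minor_polarized(states_j)
    if x.size != y.size:
        raise ValueError("state vectors differ in length")
    pa = x.mean()
    pb = y.mean()
    pab = (x & y).mean()
    d = pab - pa * pb
    return float(d * d / (pa * (1 - pa) * pb * (1 - pb)))


def d_minor(states_i: np.ndarray, states_j: np.ndarray) -> float:
    """Signed D with both sites polarised to their minor alleles."""
    x = _minor_polarized(states_i)
    y = _minor_polarized(states_j)
    if x.size != y.size:
        raise ValueError("state vectors differ in length")
    return float((x & y).mean() - x.mean() * y.mean())


def pairwise_r2(states: np.ndarray) -> np.ndarray:
    """All-pairs r^2 matrix for an (m_snps, n_genotypes) 0/1 matrix.

    Equals the squared Pearson correlation of the indicator vectors;
    every row must be polymorphic.
    """
    states = np.asarray(states, dtype=float)
    if states.shape[0] < 2:
        return np.ones((states.shape[0],) * 2)
    c = np.corrcoef(states)
    return c * c


def mean_pairwise_r2(states: np.ndarray) -> float:
    """Mean r^2 over all unordered pairs of rows."""
    m = states.shape[0]
    if m < 2:
        raise LdUndefinedError("need at least 2 SNPs")
    r2 = pairwise_r2(states)
    iu = np.triu_indices(m, 1)
    return float(r2[iu].mean())


# ---------------------------------------------------------------------------
# pair tables


def _class_pair(a: str, b: str) -> str:
    if a == NONSYNONYMOUS and b == NONSYNONYMOUS:
        return NN
    if a == SYNONYMOUS and b == SYNONYMOUS:
        return SS
    return MIXED


def pair_table(snps: SnpTable, maf_min: float = 0.0,
               max_distance: int = 2000) -> pd.DataFrame:
    """All unordered within-contig SNP pairs up to ``max_distance`` apart.

    Both SNPs must have MAF strictly greater than ``maf_min``.  Returns
    one row per pair with r2, signed minor-allele D, distance, gene/exon
    relation, and the functional class pair.
    """
    frames = []
    for contig, sub in snps.df.groupby("contig", sort=False):
        keep = sub.index[sub["maf"].values > maf_min]
        if len(keep) < 2:
            continue
        pos = snps.df.loc[keep, "pos"].to_numpy()
        order = np.argsort(pos, kind="stable")
        idx = keep.to_numpy()[order]
        pos = pos[order]
        st = snps.states[idx].astype(np.uint8)
        maf = snps.df.loc[idx, "maf"].to_numpy()
        gene = snps.df.loc[idx, "gene_id"].fillna("").to_numpy(dtype=object)
        exon = snps.df.loc[idx, "exon_index"].fillna(-1).to_numpy(dtype=int)
        cls = snps.df.loc[idx, "site_class"].to_numpy(dtype=object)
        n = st.shape[1]
        rows_i, rows_j = [], []
        m = len(idx)
        hi = np.searchsorted(pos, pos + max_distance, side="right")
        for i in range(m):
            j_end = hi[i]
            if j_end <= i + 1:
                continue
            rows_i.append(np.full(j_end - i - 1, i))
            rows_j.append(np.arange(i + 1, j_end))
        if not rows_i:
            continue
        ii = np.concatenate(rows_i)
        jj = np.concatenate(rows_j)
        pa = maf[ii]
        pb = maf[jj]
        pab = (st[ii] & st[jj]).mean(axis=1)
        d = pab - pa * pb
        r2 = d * d / (pa * (1 - pa) * pb * (1 - pb))
        gi, gj = gene[ii], gene[jj]
        has_i = gi != ""
        has_j = gj != ""
        relation = np.where(has_i & has_j & (gi == gj), SAME_GENE,
                            np.where(has_i & has_j, ADJACENT_GENES, INTERGENIC))
        ei, ej = exon[ii], exon[jj]
        exon_rel = np.where(relation == SAME_GENE,
                            np.where(ei == ej, "same_exon", "different_exons"),
                            "na")
        frames.append(pd.DataFrame({
            "contig": contig,
            "i": idx[ii], "j": idx[jj],
            "pos_i": pos[ii], "pos_j": pos[jj],
            "distance": pos[jj] - pos[ii],
            "maf_i": pa, "maf_j": pb,
            "r2": r2, "d_minor": d,
            "relation": relation, "exon_relation": exon_rel,
            "class_pair": [_class_pair(a, b) for a, b in zip(cls[ii], cls[jj])],
        }))
    if not frames:
        return pd.DataFrame(columns=[
            "contig", "i", "j", "pos_i", "pos_j", "distance", "maf_i",
            "maf_j", "r2", "d_minor", "relation", "exon_relation",
            "class_pair"])
    return pd.concat(frames, ignore_index=True)


def _bin_of(distance: np.ndarray, bin_edges: np.ndarray) -> np.ndarray:
    """Bin index per distance; [left, right) bins with the last bin closed.

    Returns -1 for distances outside [bin_edges[0], bin_edges[-1]].
    """
    which = np.digitize(distance, bin_edges) - 1
    which[distance == bin_edges[-1]] = len(bin_edges) - 2
    which[(which < 0) | (which > len(bin_edges) - 2)] = -1
    return which


# ---------------------------------------------------------------------------
# distance-stratified profile


@dataclass
class LdProfile:
    """Mean r^2 per distance bin, class pair and gene relation."""

    bin_edges: np.ndarray
    table: pd.DataFrame  # bin_left, bin_right, relation, class_pair, mean_r2, n_pairs, se
    n_pairs_total: int


def ld_profile(snps: SnpTable, maf_min: float = 0.05,
               max_distance: int = 2000,
               bin_edges: np.ndarray | None = None,
               min_pairs_per_contig: int = 10) -> LdProfile:
    """Distance-stratified LD profile.

    Pairs with both MAFs > ``maf_min`` and distance <= ``max_distance``
    contribute to their (distance bin, class pair, relation) cell.  The
    standard error of a cell is computed across contigs (population SD of
    per-contig means / sqrt(#contigs)); contigs contributing fewer than
    ``min_pairs_per_contig`` pairs to the cell are skipped for the SE.
    """
    if bin_edges is None:
        bin_edges = np.arange(0, max_distance + 1, 50)
    bin_edges = np.asarray(bin_edges)
    pairs = pair_table(snps, maf_min=maf_min, max_distance=max_distance)
    pairs = pairs[pairs["distance"] <= max_distance].copy()
    if len(pairs) == 0:
        return LdProfile(bin_edges, pd.DataFrame(columns=[
            "bin_left", "bin_right", "relation", "class_pair", "mean_r2",
            "n_pairs", "se"]), 0)
    which = _bin_of(pairs["distance"].to_numpy(), bin_edges)
    ok = which >= 0
    pairs = pairs[ok]
    which = which[ok]
    pairs = pairs.assign(bin=which)
    rows = []
    for (b, rel, cp), cell in pairs.groupby(["bin", "relation", "class_pair"]):
        per_contig = cell.groupby("contig")["r2"].agg(["mean", "count"])
        eligible = per_contig[per_contig["count"] >= min_pairs_per_contig]
        se = (float(eligible["mean"].std(ddof=0) / np.sqrt(len(eligible)))
              if len(eligible) >= 2 else np.nan)
        rows.append((bin_edges[b], bin_edges[b + 1], rel, cp,
                     float(cell["r2"].mean()), len(cell), se))
    table = pd.DataFrame(rows, columns=["bin_left", "bin_right", "relation",
                                        "class_pair", "mean_r2", "n_pairs",
                                        "se"])
    return LdProfile(bin_edges, table.sort_values(
        ["relation", "class_pair", "bin_left"]).reset_index(drop=True),
        int(len(pairs)))


# ---------------------------------------------------------------------------
# MAF-matched contrast


def maf_matched_contrast(snps: SnpTable, relation: str | None = SAME_GENE,
                         maf_bin_width: float = 0.05,
                         n_resamples: int = 1000, rng_seed: int = 0,
                         maf_min: float = 0.0, max_distance: int = 2000,
                         bin_edges: np.ndarray | None = None) -> pd.DataFrame:
    """Nonsyn vs syn LD contrast controlling for the joint MAF distribution.

    Within each distance bin, syn-syn pairs are resampled with replacement
    to match the joint 2-D MAF histogram (unordered, bin width
    ``maf_bin_width``) of the nonsyn-nonsyn pairs.  MAF cells with nonsyn
    pairs but no syn pairs are excluded from both classes (logged).
    Returns one row per distance bin with the nonsyn mean, the matched
    syn mean and its resampling percentile interval.
    """
    if bin_edges is None:
        bin_edges = np.arange(0, max_distance + 1, 250)
    bin_edges = np.asarray(bin_edges)
    rng = np.random.default_rng(rng_seed)
    pairs = pair_table(snps, maf_min=maf_min, max_distance=max_distance)
    if relation is not None:
        pairs = pairs[pairs["relation"] == relation]
    lo = np.minimum(pairs["maf_i"], pairs["maf_j"])
    hi = np.maximum(pairs["maf_i"], pairs["maf_j"])
    pairs = pairs.assign(
        cell_lo=np.floor(lo / maf_bin_width).astype(int),
        cell_hi=np.floor(hi / maf_bin_width).astype(int),
        bin=_bin_of(pairs["distance"].to_numpy(), bin_edges))
    pairs = pairs[pairs["bin"] >= 0]
    out = []
    for b, sub in pairs.groupby("bin"):
        nn = sub[sub["class_pair"] == NN]
        ss = sub[sub["class_pair"] == SS]
        if len(nn) == 0 or len(ss) == 0:
            continue
        ss_by_cell = {cell: g["r2"].to_numpy()
                      for cell, g in ss.groupby(["cell_lo", "cell_hi"])}
        kept_nn = []
        draw_pools = []
        for cell, g in nn.groupby(["cell_lo", "cell_hi"]):
            pool = ss_by_cell.get(cell)
            if pool is None:
                logger.info("MAF cell %s has nonsyn pairs but no syn pairs; "
                            "excluded from both classes", cell)
                continue
            kept_nn.append(g["r2"].to_numpy())
            draw_pools.append((pool, len(g)))
        if not kept_nn:
            continue
        nn_vals = np.concatenate(kept_nn)
        total = nn_vals.size
        means = np.empty(n_resamples)
        for r in range(n_resamples):
            acc = 0.0
            for pool, k in draw_pools:
                acc += pool[rng.integers(0, pool.size, size=k)].sum()
            means[r] = acc / total
        out.append((bin_edges[b], bin_edges[b + 1], total,
                    float(nn_vals.mean()), float(means.mean()),
                    float(np.percentile(means, 2.5)),
                    float(np.percentile(means, 97.5)),
                    float(ss["r2"].mean()), len(ss)))
    return pd.DataFrame(out, columns=[
        "bin_left", "bin_right", "n_nonsyn", "nonsyn_mean",
        "syn_matched_mean", "syn_matched_lo", "syn_matched_hi",
        "syn_unmatched_mean", "n_syn"])


# ---------------------------------------------------------------------------
# gene-level statistics


def gene_ld_stats(snps: SnpTable, max_pair_distance: int = 300,
                  min_pairs: int = 100, maf_min: float = 0.0) -> pd.DataFrame:
    """Per-gene mean r^2 over short-range within-gene pairs.

    Only pairs of SNPs within ``max_pair_distance`` nucleotides are used
    (controls for gene length); genes with fewer than ``min_pairs`` such
    pairs are excluded.  ``excess`` = ld_nonsyn - ld_syn; class means are
    NaN when a gene has no pair of that class.
    """
    pairs = pair_table(snps, maf_min=maf_min, max_distance=max_pair_distance)
    pairs = pairs[pairs["relation"] == SAME_GENE]
    gene_of = snps.df["gene_id"]
    pairs = pairs.assign(gene_id=gene_of.loc[pairs["i"]].to_numpy())
    rows = []
    for gene, sub in pairs.groupby("gene_id"):
        if len(sub) < min_pairs:
            continue
        nn = sub.loc[sub["class_pair"] == NN, "r2"]
        ss = sub.loc[sub["class_pair"] == SS, "r2"]
        ld_nonsyn = float(nn.mean()) if len(nn) else np.nan
        ld_syn = float(ss.mean()) if len(ss) else np.nan
        rows.append((gene, float(sub["r2"].mean()), ld_syn, ld_nonsyn,
                     len(sub), len(ss), len(nn), ld_nonsyn - ld_syn))
    return pd.DataFrame(rows, columns=[
        "gene_id", "ld_all", "ld_syn", "ld_nonsyn", "n_pairs", "n_pairs_syn",
        "n_pairs_nonsyn", "excess"])


_SYN_FRACTION_CACHE: dict[str, float] = {}


def _codon_site_counts(codon: str) -> tuple[float, float]:
    """NG86-style fractional (synonymous, nonsynonymous) site counts."""
    from Bio.Seq import Seq

    key = codon
    if key in _SYN_FRACTION_CACHE:
        syn = _SYN_FRACTION_CACHE[key]
        return syn, 3.0 - syn
    aa0 = str(Seq(codon).translate())
    syn = 0.0
    for pos in range(3):
        for alt in "ACGT":
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1:]
            if str(Seq(mutant).translate()) == aa0:
                syn += 1 / 3
    _SYN_FRACTION_CACHE[key] = syn
    return syn, 3.0 - syn


def gene_pn_ps(aln, ann, snps: SnpTable) -> float:
    """pn/ps for one gene: per-site nonsynonymous over synonymous diversity.

    Site counts are computed from the major-allele (consensus) coding
    sequence by enumerating all nine single-nucleotide changes per codon
    and apportioning fractional synonymous/nonsynonymous weights.
    Returns NaN when ps is undefined (zero synonymous sites or SNPs).
    """
    from .genomes import consensus_sequence, NUCLEOTIDES, _COMPLEMENT

    cons = consensus_sequence(aln)
    cpos = ann.coding_positions()
    n_codons = len(cpos) // 3
    syn_sites = 0.0
    nonsyn_sites = 0.0
    for k in range(n_codons):
        pos3 = cpos[3 * k:3 * k + 3]
        bases = [str(cons[q]) for q in pos3]
        if ann.strand == "-":
            bases = [b.translate(_COMPLEMENT) for b in bases]
        codon = "".join(bases)
        if any(b not in NUCLEOTIDES for b in codon):
            continue
        if codon in ("TAA", "TAG", "TGA"):
            continue
        s, ns = _codon_site_counts(codon)
        syn_sites += s
        nonsyn_sites += ns
    sub = snps.df[(snps.df["gene_id"] == ann.gene_id)]
    n_syn = int((sub["site_class"] == SYNONYMOUS).sum())
    n_nonsyn = int((sub["site_class"] == NONSYNONYMOUS).sum())
    if syn_sites == 0 or n_syn == 0 or nonsyn_sites == 0:
        return float("nan")
    return (n_nonsyn / nonsyn_sites) / (n_syn / syn_sites)


# ---------------------------------------------------------------------------
# correlations


def spearman(x: np.ndarray, y: np.ndarray, rng_seed: int = 0,
             exact_below: int = 30, n_perm: int = 10000) -> tuple[float, float]:
    """Spearman rho with a permutation p-value for small samples.

    Uses the large-sample approximation for n >= ``exact_below`` and a
    seeded two-sided permutation test below it.  Raises
    :class:`UndefinedStatisticError` if either variable is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3 or np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedStatisticError("Spearman correlation undefined")
    rho, p = stats.spearmanr(x, y)
    if x.size >= exact_below:
        return float(rho), float(p)
    rng = np.random.default_rng(rng_seed)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(ry)
        if abs(np.corrcoef(rx, perm)[0, 1]) >= obs - 1e-12:
            count += 1
    return float(rho), (1 + count) / (n_perm + 1)


def correlate_gene_stats(stats_df: pd.DataFrame, x: str, y: str,
                         control: str | None = None, n_strata: int = 5,
                         rng_seed: int = 0) -> dict:
    """Spearman correlation between two per-gene statistics.

    With ``control``, the correlation is computed within quantile strata
    of the control variable and combined by pooling within-stratum ranks.
    """
    sub = stats_df[[c for c in {x, y, control} if c]].dropna()
    if len(sub) < 3:
        raise UndefinedStatisticError("need at least 3 genes")
    report: dict = {"n": len(sub)}
    rho, p = spearman(sub[x], sub[y], rng_seed=rng_seed)
    report["rho"] = rho
    report["pvalue"] = p
    if control is not None:
        edges = np.quantile(sub[control], np.linspace(0, 1, n_strata + 1))
        strata = np.clip(np.searchsorted(edges, sub[control], side="right") - 1,
                         0, n_strata - 1)
        per = []
        pooled_rx, pooled_ry = [], []
        for s in range(n_strata):
            g = sub[strata == s]
            if len(g) < 3:
                per.append({"stratum": s, "n": len(g), "rho": np.nan,
                            "pvalue": np.nan})
                continue
            try:
                r_s, p_s = spearman(g[x], g[y], rng_seed=rng_seed + s + 1)
            except UndefinedStatisticError:
                r_s, p_s = np.nan, np.nan
            per.append({"stratum": s, "n": len(g), "rho": r_s, "pvalue": p_s})
            pooled_rx.append((stats.rankdata(g[x]) - 0.5) / len(g))
            pooled_ry.append((stats.rankdata(g[y]) - 0.5) / len(g))
        report["per_stratum"] = per
        if pooled_rx:
            rx = np.concatenate(pooled_rx)
            ry = np.concatenate(pooled_ry)
            r_c, p_c = stats.pearsonr(rx, ry)
            report["combined_rho"] = float(r_c)
            report["combined_pvalue"] = float(p_c)
    return report
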