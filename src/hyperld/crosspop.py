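"""Cross-population LD comparison at shared SNPs.

Two divergent populations projected onto the same reference coordinates
share many SNP positions, mostly through recurrent mutation.  Correlation
between the LD of the same SNP pair measured independently in each
population — after excluding haploblocks and high-LD genes, where linkage
alone inflates LD — is a signature of epistatic selection shared between
the populations.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .genomes import SnpTable, UndefinedStatisticError
from .ld import spearman, _class_pair
from .haploblocks import HaploblockSet

logger = logging.getLogger(__name__)

IDENTICAL = "identical_nucleotides"
SAME_AA = "same_aa_different_nucleotides"
DIFFERENT = "different"


def match_shared_snps(snps_a: SnpTable, snps_b: SnpTable) -> pd.DataFrame:
    """Positions polymorphic in both populations, with allele matching.

    ``identical_nucleotides``: the same two alleles segregate in both
    populations (regardless of which is minor).  ``same_aa_different_
    nucleotides``: coding sites where the two encoded amino acids
    coincide across populations while the nucleotide allele pairs differ.
    Returns one row per shared SNP with the row indices in each table.
    """
    a = snps_a.df.reset_index().rename(columns={"index": "idx_a"})
    b = snps_b.df.reset_index().rename(columns={"index": "idx_b"})
    merged = a.merge(b, on=["contig", "pos"], suffixes=("_a", "_b"))
    cats = []
    for _, row in merged.iterrows():
        alleles_a = {row["major_a"], row["minor_a"]}
        alleles_b = {row["major_b"], row["minor_b"]}
        if alleles_a == alleles_b:
            cats.append(IDENTICAL)
            continue
        aa_a = {row["aa_major_a"], row["aa_minor_a"]}
        aa_b = {row["aa_major_b"], row["aa_minor_b"]}
        if (all(pd.notna(x) for x in aa_a | aa_b) and aa_a == aa_b):
            cats.append(SAME_AA)
        else:
            cats.append(DIFFERENT)
    merged["allele_match"] = cats
    return merged


def _gene_exclusion_set(gene_ld: pd.DataFrame, quantile: float) -> set[str]:
    if gene_ld is None or len(gene_ld) == 0:
        return set()
    thr = float(np.quantile(gene_ld["ld_all"].dropna(), quantile))
    return set(gene_ld.loc[gene_ld["ld_all"] > thr, "gene_id"])


def shared_pair_ld(shared: pd.DataFrame, snps_a: SnpTable, snps_b: SnpTable,
                   blocks_a: HaploblockSet | None = None,
                   blocks_b: HaploblockSet | None = None,
                   gene_ld_a: pd.DataFrame | None = None,
                   gene_ld_b: pd.DataFrame | None = None,
                   max_distance: int = 2000,
                   gene_ld_quantile: float = 0.8) -> pd.DataFrame:
    """Per-pair LD of shared SNPs in both populations, with exclusions.

    SNPs inside a haploblock in either population, or inside a gene whose
    short-range mean LD exceeds that population's ``gene_ld_quantile``,
    are excluded.  Pairs further apart than ``max_distance`` are skipped.
    """
    keep = np.ones(len(shared), dtype=bool)
    for blocks, tag in ((blocks_a, "a"), (blocks_b, "b")):
        if blocks is None:
            continue
        for contig, grp in shared.groupby("contig"):
            pos = grp["pos"].to_numpy()
            inside = blocks.membership_mask(pos, contig)
            keep[grp.index[inside]] = False
    excl_genes = (_gene_exclusion_set(gene_ld_a, gene_ld_quantile) |
                  _gene_exclusion_set(gene_ld_b, gene_ld_quantile))
    if excl_genes:
        in_bad = shared["gene_id_a"].isin(excl_genes) | \
            shared["gene_id_b"].isin(excl_genes)
        keep &= ~in_bad.to_numpy()
    shared = shared[keep].reset_index(drop=True)

    rows = []
    for contig, grp in shared.groupby("contig"):
        grp = grp.sort_values("pos").reset_index(drop=True)
        pos = grp["pos"].to_numpy()
        hi = np.searchsorted(pos, pos + max_distance, side="right")
        for i in range(len(grp)):
            for j in range(i + 1, hi[i]):
                ri, rj = grp.iloc[i], grp.iloc[j]
                if pos[j] == pos[i]:
                    continue
                r2a = _safe_r2(snps_a, int(ri["idx_a"]), int(rj["idx_a"]))
                r2b = _safe_r2(snps_b, int(ri["idx_b"]), int(rj["idx_b"]))
                if r2a is None or r2b is None:
                    continue
                same_alleles = (ri["allele_match"] == IDENTICAL and
                                rj["allele_match"] == IDENTICAL)
                both_same_aa = all(m in (IDENTICAL, SAME_AA) for m in
                                   (ri["allele_match"], rj["allele_match"]))
                match = ("same_alleles" if same_alleles else
                         "same_aa" if both_same_aa else "different")
                gi, gj = ri["gene_id_a"], rj["gene_id_a"]
                relation = ("same_gene" if pd.notna(gi) and pd.notna(gj)
                            and gi == gj else "different_genes")
                rows.append((contig, pos[i], pos[j], pos[j] - pos[i],
                             match, relation,
                             _class_pair(ri["site_class_a"],
                                         rj["site_class_a"]),
                             r2a, r2b))
    return pd.DataFrame(rows, columns=[
        "contig", "pos_i", "pos_j", "distance", "allele_match", "relation",
        "class_pair", "r2_pop_a", "r2_pop_b"])


def _safe_r2(snps: SnpTable, i: int, j: int) -> float | None:
    from .ld import r_squared, LdUndefinedError
    try:
        return r_squared(snps.states[i], snps.states[j])
    except LdUndefinedError:
        return None


def ld_correlation(table: pd.DataFrame,
                   by: tuple[str, ...] = ("allele_match", "class_pair",
                                          "relation"),
                   min_pairs: int = 3, rng_seed: int = 0) -> pd.DataFrame:
    """Spearman correlation of r^2 between populations, per stratum."""
    rows = []
    for key, grp in table.groupby(list(by)):
        key = key if isinstance(key, tuple) else (key,)
        if len(grp) < min_pairs:
            rows.append((*key, len(grp), np.nan, np.nan, "too_few_pairs"))
            continue
        try:
            rho, p = spearman(grp["r2_pop_a"], grp["r2_pop_b"],
                              rng_seed=rng_seed)
            rows.append((*key, len(grp), rho, p, "ok"))
        except UndefinedStatisticError:
            rows.append((*key, len(grp), np.nan, np.nan, "undefined"))
    return pd.DataFrame(rows, columns=[*by, "n_pairs", "rho", "pvalue",
                                       "status"])
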