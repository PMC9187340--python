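"""Haploblock detection from windowed LD.

A haploblock is a genomic segment in which the sampled gene pool consists
of two highly divergent haplotypes, producing locally extreme LD.  The
scan computes mean r^2 over all non-singleton SNP pairs inside a sliding
window (250 nt, step 20 nt, at least 10 SNPs), sets a per-population
threshold where the empirical window-LD distribution becomes heavy-tailed
relative to a moment-matched lognormal, and merges runs of qualifying
overlapping windows into blocks.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genomes import SnpTable
from .ld import mean_pairwise_r2

logger = logging.getLogger(__name__)


@dataclass
class WindowTrack:
    """Sliding-window mean r^2 on a fixed grid."""

    window_len: int
    step: int
    min_snps: int
    contig_lengths: dict[str, int]
    table: pd.DataFrame  # contig, start, end, n_snps, mean_r2, valid

    def valid_values(self) -> np.ndarray:
        t = self.table
        return t.loc[t["valid"], "mean_r2"].to_numpy()

    def to_bedgraph(self, path) -> None:
        t = self.table[self.table["valid"]]
        t[["contig", "start", "end", "mean_r2"]].to_csv(
            path, sep="\t", header=False, index=False)


@dataclass
class TailFit:
    """Lognormal moment fit and heavy-tail threshold of window LD."""

    threshold: float | None
    mean: float
    variance: float
    mu_log: float
    sigma_log: float
    tail_ratio: float


@dataclass
class HaploblockSet:
    """Called haploblocks plus genome summary fractions.

    ``summary`` fractions are over all assayed positions (total contig
    length): ``fraction_in_blocks`` + ``fraction_background`` +
    ``fraction_unscorable`` = 1.  Scorable positions are those covered by
    at least one valid window.
    """

    blocks: pd.DataFrame  # contig, start, end, mean_r2, n_windows [, stats]
    summary: dict
    contig_lengths: dict[str, int]
    scorable: dict[str, np.ndarray]  # contig -> (k, 2) interval array
    minor_fractions: list[np.ndarray] = field(default_factory=list)
    haplotype_assignment: list[np.ndarray] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.blocks)

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for k, row in self.blocks.iterrows():
                score = int(round(1000 * min(max(row["mean_r2"], 0.0), 1.0)))
                fh.write(f"{row['contig']}\t{int(row['start'])}\t"
                         f"{int(row['end'])}\thb{k}\t{score}\n")

    def membership_mask(self, positions: np.ndarray,
                        contig: str) -> np.ndarray:
        """Boolean: which of ``positions`` fall inside a block."""
        mask = np.zeros(len(positions), dtype=bool)
        sub = self.blocks[self.blocks["contig"] == contig]
        for _, row in sub.iterrows():
            mask |= (positions >= row["start"]) & (positions < row["end"])
        return mask


def window_ld_scan(snps: SnpTable, contig_lengths: dict[str, int],
                   window_len: int = 250, step: int = 20,
                   min_snps: int = 10) -> WindowTrack:
    """Mean r^2 over all SNP pairs fully inside each grid window.

    Windows with fewer than ``min_snps`` SNPs are marked invalid.  The
    SNP table should already exclude singletons (the default extraction
    convention).
    """
    rows = []
    df = snps.df
    for contig, length in contig_lengths.items():
        sel = np.flatnonzero((df["contig"] == contig).to_numpy())
        pos = df["pos"].to_numpy()[sel]
        order = np.argsort(pos)
        pos = pos[order]
        st = snps.states[sel][order]
        if length < window_len:
            continue
        starts = np.arange(0, length - window_len + 1, step)
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, starts + window_len, side="left")
        for s, a, b in zip(starts, lo, hi):
            k = b - a
            if k < min_snps:
                rows.append((contig, int(s), int(s + window_len), int(k),
                             np.nan, False))
            else:
                rows.append((contig, int(s), int(s + window_len), int(k),
                             mean_pairwise_r2(st[a:b]), True))
    table = pd.DataFrame(rows, columns=["contig", "start", "end", "n_snps",
                                        "mean_r2", "valid"])
    return WindowTrack(window_len, step, min_snps, dict(contig_lengths), table)


def fit_tail_threshold(track: WindowTrack, tail_ratio: float = 2.0,
                       scan_grid: np.ndarray | None = None,
                       min_windows: int = 100) -> TailFit:
    """Heavy-tail LD threshold against a moment-matched lognormal.

    The lognormal is fit by matching the mean and variance of the valid
    window means on the raw scale.  The threshold is the smallest grid
    value t above the empirical median at which the empirical survival is
    at least ``tail_ratio`` times the lognormal survival, and stays so at
    every larger grid value with nonzero empirical survival.  Returns
    ``threshold=None`` when the distribution shows no such heavy tail.
    """
    vals = track.valid_values()
    if vals.size < min_windows:
        raise ValueError(
            f"need at least {min_windows} valid windows, got {vals.size}")
    m = float(vals.mean())
    v = float(vals.var(ddof=0))
    if v == 0 or m <= 0:
        logger.info("degenerate window LD distribution; no threshold")
        return TailFit(None, m, v, np.nan, np.nan, tail_ratio)
    sigma2 = np.log1p(v / (m * m))
    mu = np.log(m) - sigma2 / 2
    sigma = float(np.sqrt(sigma2))
    if scan_grid is None:
        levels = np.arange(0.500, 0.9995, 0.001)
        scan_grid = np.quantile(vals, levels)
    grid = np.unique(np.asarray(scan_grid, dtype=float))
    median = float(np.median(vals))
    grid = grid[grid > median]
    if grid.size == 0:
        return TailFit(None, m, v, float(mu), sigma, tail_ratio)
    s_emp = np.array([(vals > t).mean() for t in grid])
    s_ln = stats.lognorm.sf(grid, s=sigma, scale=np.exp(mu))
    ok = (s_emp >= tail_ratio * s_ln) | (s_emp == 0)
    persists = np.logical_and.accumulate(ok[::-1])[::-1]
    candidates = np.flatnonzero(persists & (s_emp > 0) &
                                (s_emp >= tail_ratio * s_ln))
    threshold = float(grid[candidates[0]]) if candidates.size else None
    return TailFit(threshold, m, v, float(mu), sigma, tail_ratio)


def call_haploblocks(track: WindowTrack, threshold: float) -> HaploblockSet:
    """Merge overlapping qualifying windows into haploblocks.

    A window qualifies when it is valid and its mean r^2 exceeds the
    threshold; any continuous chain of mutually overlapping qualifying
    windows becomes one block (span = union of member windows).
    Qualifying windows whose spans do not overlap yield distinct blocks.
    """
    blocks = []
    scorable: dict[str, np.ndarray] = {}
    total_len = 0
    scorable_len = 0
    block_len = 0
    for contig, length in track.contig_lengths.items():
        total_len += length
        sub = track.table[track.table["contig"] == contig]
        sub = sub.sort_values("start")
        valid = sub[sub["valid"]]
        scor = _union_intervals(valid[["start", "end"]].to_numpy())
        scorable[contig] = scor
        scorable_len += int((scor[:, 1] - scor[:, 0]).sum()) if len(scor) else 0
        qual = sub["valid"].to_numpy() & (
            np.nan_to_num(sub["mean_r2"].to_numpy(), nan=-np.inf) > threshold)
        starts = sub["start"].to_numpy()[qual]
        ends = sub["end"].to_numpy()[qual]
        r2s = sub["mean_r2"].to_numpy()[qual]
        i = 0
        n = qual.sum()
        while i < n:
            j = i
            b_end = int(ends[i])
            while j + 1 < n and starts[j + 1] < b_end:
                j += 1
                b_end = max(b_end, int(ends[j]))
            b_start = int(starts[i])
            blocks.append((contig, b_start, b_end,
                           float(np.mean(r2s[i:j + 1])), j - i + 1))
            block_len += b_end - b_start
            i = j + 1
    blocks_df = pd.DataFrame(blocks, columns=["contig", "start", "end",
                                              "mean_r2", "n_windows"])
    summary = {
        "fraction_in_blocks": block_len / total_len if total_len else 0.0,
        "fraction_background": ((scorable_len - block_len) / total_len
                                if total_len else 0.0),
        "fraction_unscorable": ((total_len - scorable_len) / total_len
                                if total_len else 0.0),
        "n_blocks": len(blocks_df),
    }
    return HaploblockSet(blocks_df, summary, dict(track.contig_lengths),
                         scorable)


def _union_intervals(iv: np.ndarray) -> np.ndarray:
    if len(iv) == 0:
        return np.zeros((0, 2), dtype=int)
    iv = iv[np.argsort(iv[:, 0])]
    out = [[int(iv[0, 0]), int(iv[0, 1])]]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], int(e))
        else:
            out.append([int(s), int(e)])
    return np.array(out, dtype=int)


def haploblock_stats(blocks: HaploblockSet, snps: SnpTable) -> HaploblockSet:
    """Enrich blocks with MAF and two-haplotype structure statistics.

    Per block: mean MAF of contained SNPs; per genotype, the fraction of
    contained SNPs at which it carries the minor allele; genotypes with
    minor fraction >= 0.5 are assigned to the minor haplotype.  Blocks
    with fewer than 2 SNPs get NaN statistics.
    """
    df = blocks.blocks.copy()
    mean_mafs = []
    n_snps_list = []
    fractions = []
    assignments = []
    for _, row in df.iterrows():
        sel = ((snps.df["contig"] == row["contig"]) &
               (snps.df["pos"] >= row["start"]) &
               (snps.df["pos"] < row["end"])).to_numpy()
        k = int(sel.sum())
        n_snps_list.append(k)
        if k < 2:
            mean_mafs.append(np.nan)
            fractions.append(np.full(snps.n_genotypes, np.nan))
            assignments.append(np.array(["unassigned"] * snps.n_genotypes))
            continue
        mean_mafs.append(float(snps.df.loc[sel, "maf"].mean()))
        frac = snps.states[sel].mean(axis=0)
        fractions.append(frac)
        assignments.append(np.where(frac >= 0.5, "minor", "major"))
    df["mean_maf"] = mean_mafs
    df["n_snps"] = n_snps_list
    lengths = (df["end"] - df["start"]).to_numpy()
    summary = dict(blocks.summary)
    if len(df):
        summary["fraction_shorter_1kb"] = float((lengths < 1000).mean())
        summary["median_length"] = float(np.median(lengths))
    return HaploblockSet(df, summary, blocks.contig_lengths, blocks.scorable,
                         minor_fractions=fractions,
                         haplotype_assignment=assignments)


def cross_population_overlap(blocks_a: HaploblockSet,
                             blocks_b: HaploblockSet) -> dict:
    """Observed vs independence-expected joint haploblock coverage.

    Computed over positions scorable in both populations; the expected
    joint fraction is the product of the two marginal block fractions.
    """
    common_contigs = set(blocks_a.contig_lengths) & set(blocks_b.contig_lengths)
    if not common_contigs:
        raise ValueError("no shared contigs between block sets")
    n_common = 0
    n_a = n_b = n_both = 0
    for contig in common_contigs:
        length = min(blocks_a.contig_lengths[contig],
                     blocks_b.contig_lengths[contig])
        scor = np.zeros(length, dtype=bool)
        in_a = np.zeros(length, dtype=bool)
        in_b = np.zeros(length, dtype=bool)
        mask_a = np.zeros(length, dtype=bool)
        for s, e in blocks_a.scorable.get(contig, []):
            mask_a[s:min(e, length)] = True
        mask_b = np.zeros(length, dtype=bool)
        for s, e in blocks_b.scorable.get(contig, []):
            mask_b[s:min(e, length)] = True
        scor = mask_a & mask_b
        for _, row in blocks_a.blocks[blocks_a.blocks["contig"] == contig].iterrows():
            in_a[int(row["start"]):min(int(row["end"]), length)] = True
        for _, row in blocks_b.blocks[blocks_b.blocks["contig"] == contig].iterrows():
            in_b[int(row["start"]):min(int(row["end"]), length)] = True
        n_common += int(scor.sum())
        n_a += int((in_a & scor).sum())
        n_b += int((in_b & scor).sum())
        n_both += int((in_a & in_b & scor).sum())
    if n_common == 0:
        raise ValueError("no positions scorable in both populations")
    fa = n_a / n_common
    fb = n_b / n_common
    return {
        "fraction_a": fa,
        "fraction_b": fb,
        "observed": n_both / n_common,
        "expected": fa * fb,
        "n_positions": n_common,
    }


def expected_joint_fraction(fraction_a: float, fraction_b: float) -> float:
    """Joint coverage expected if two block sets are placed independently."""
    return fraction_a * fraction_b
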