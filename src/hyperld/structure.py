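"""LD between SNPs in codons encoding physically interacting residues.

Two complementary tests relate within-protein LD to tertiary structure:

* a genome-wide distance-matched permutation test: for every pair of
  physically close residues (within 10 A, at least 5 aa apart in the
  sequence) the null resamples a physically distant pair at the same
  amino-acid separation, so sequence proximity cannot masquerade as
  structural signal;
* a per-gene 2x2 contingency test (close/far x high/low LD, with the
  high-LD cut at the per-gene 0.9 quantile and the amino-acid separation
  restricted to 30-100), summarised by an odds ratio and chi-square
  p-value, with Benjamini-Hochberg FDR across genes.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .genomes import SnpTable, SYNONYMOUS, NONSYNONYMOUS
from .ld import NN, SS, _class_pair

logger = logging.getLogger(__name__)

CONTACT_CUTOFF = 10.0  # Angstrom


class ContactMapError(ValueError):
    pass


@dataclass
class ContactMap:
    """Symmetric inter-residue distance matrix (Angstrom), NaN = unknown."""

    protein_id: str
    distances: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ContactMapError("distance matrix must be square")
        if np.nanmin(d, initial=0.0) < 0:
            raise ContactMapError("negative distances")
        self.distances = d

    @property
    def n_residues(self) -> int:
        return self.distances.shape[0]

    def contacts(self, cutoff: float = CONTACT_CUTOFF) -> set[tuple[int, int]]:
        d = self.distances
        out = set()
        for i in range(d.shape[0]):
            for j in range(i + 1, d.shape[1]):
                if np.isfinite(d[i, j]) and d[i, j] <= cutoff:
                    out.add((i, j))
        return out


def load_contact_map(path, protein_id: str | None = None,
                     n_residues: int | None = None) -> ContactMap:
    """Read a residue-pair distance TSV (res_i, res_j, dist_A; 1-based).

    Entries are ingested symmetrically; conflicting duplicate distances
    raise an error naming the pair.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["i", "j", "dist"],
                     dtype={"i": int, "j": int, "dist": float})
    size = n_residues or int(max(df["i"].max(), df["j"].max()))
    d = np.full((size, size), np.nan)
    np.fill_diagonal(d, 0.0)
    seen: dict[tuple[int, int], float] = {}
    for _, row in df.iterrows():
        i, j = int(row["i"]) - 1, int(row["j"]) - 1
        if i == j:
            continue
        key = (min(i, j), max(i, j))
        val = float(row["dist"])
        if key in seen and not np.isclose(seen[key], val):
            raise ContactMapError(
                f"conflicting distances for residue pair "
                f"({key[0] + 1}, {key[1] + 1})")
        seen[key] = val
    for (i, j), val in seen.items():
        d[i, j] = d[j, i] = val
    return ContactMap(protein_id or str(path), d)


def contact_map_from_structure(pdb_path, protein_id: str | None = None,
                               chain: str | None = None,
                               mode: str = "min-heavy") -> ContactMap:
    """Build a contact map from atomic coordinates (PDB).

    ``mode='min-heavy'`` (default): distance = minimum over heavy-atom
    pairs.  ``mode='ca'``: C-alpha to C-alpha distance.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.Polypeptide import is_aa

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(protein_id or "protein", str(pdb_path))
    model = next(structure.get_models())
    residues = []
    for ch in model:
        if chain is not None and ch.id != chain:
            continue
        residues.extend(r for r in ch if is_aa(r, standard=True))
    coords = []
    for res in residues:
        if mode == "ca":
            atoms = [a for a in res if a.get_name() == "CA"]
        elif mode == "min-heavy":
            atoms = [a for a in res if a.element != "H"]
        else:
            raise ValueError(f"unknown mode {mode!r}")
        coords.append(np.array([a.coord for a in atoms]) if atoms else None)
    n = len(residues)
    d = np.full((n, n), np.nan)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(i + 1, n):
            if coords[i] is None or coords[j] is None:
                continue
            diff = coords[i][:, None, :] - coords[j][None, :, :]
            d[i, j] = d[j, i] = float(np.sqrt((diff ** 2).sum(-1)).min())
    return ContactMap(protein_id or str(pdb_path), d)


# ---------------------------------------------------------------------------
# residue-pair LD table


def residue_pair_ld(snps: SnpTable, contact: ContactMap,
                    residue_map: pd.DataFrame, gene_id: str) -> pd.DataFrame:
    """Pairs of SNPs mapped to residue pairs with LD and physical distance.

    ``residue_map`` has columns (gene_id, codon_index, residue_index),
    0-based.  One row per SNP pair whose codons map to distinct residues;
    ``aa_distance`` is the residue-index separation.
    """
    rmap = residue_map[residue_map["gene_id"] == gene_id]
    codon_to_res = dict(zip(rmap["codon_index"].astype(int),
                            rmap["residue_index"].astype(int)))
    sub = snps.df[snps.df["gene_id"] == gene_id]
    sub = sub[sub["codon_id"].notna()]
    entries = []
    for i in sub.index:
        codon_idx = int(str(sub.at[i, "codon_id"]).rsplit(":", 1)[1])
        res = codon_to_res.get(codon_idx)
        if res is not None:
            entries.append((i, res, sub.at[i, "site_class"]))
    rows = []
    d = contact.distances
    for a in range(len(entries)):
        ia, ra, ca = entries[a]
        for b in range(a + 1, len(entries)):
            ib, rb, cb = entries[b]
            if ra == rb:
                continue
            from .ld import r_squared
            rows.append((contact.protein_id, min(ra, rb), max(ra, rb),
                         abs(ra - rb), d[ra, rb],
                         r_squared(snps.states[ia], snps.states[ib]),
                         _class_pair(ca, cb)))
    return pd.DataFrame(rows, columns=["protein_id", "residue_i", "residue_j",
                                       "aa_distance", "physical_distance",
                                       "r2", "class_pair"])


# ---------------------------------------------------------------------------
# genome-wide permutation test


@dataclass
class PermutationTestResult:
    observed_mean: float
    null_means: np.ndarray
    p_value: float
    n_close: int
    n_dropped: int

    @property
    def matched_mean(self) -> float:
        return float(self.null_means.mean())


def contact_ld_permutation_test(pairs: pd.DataFrame,
                                contact_cutoff: float = CONTACT_CUTOFF,
                                min_aa_separation: int = 5,
                                n_perm: int = 1000,
                                rng_seed: int = 0,
                                aa_tolerance: int = 2,
                                class_pair: str | None = None) -> PermutationTestResult:
    """Distance-matched permutation test of contact-associated LD.

    Observed statistic: mean r^2 over physically close residue pairs
    (distance <= cutoff, aa separation >= ``min_aa_separation``).  The
    null permutes the close/far labels within amino-acid-separation
    strata: each replicate redraws, for every separation, as many pairs
    as are observed close there from the pooled close+far pairs at that
    separation (without replacement), so sequence proximity is controlled
    exactly and the p-value is valid under exchangeability.  Close pairs
    at separations with no far pair within +/- ``aa_tolerance`` are
    dropped from both the observed and the null statistic.
    p = (1 + #{null mean >= observed}) / (n_perm + 1).
    """
    rng = np.random.default_rng(rng_seed)
    sub = pairs[pairs["aa_distance"] >= min_aa_separation]
    if class_pair is not None:
        sub = sub[sub["class_pair"] == class_pair]
    dist = sub["physical_distance"].to_numpy()
    close = sub[np.isfinite(dist) & (dist <= contact_cutoff)]
    far = sub[np.isfinite(dist) & (dist > contact_cutoff)]
    if len(close) == 0:
        raise ValueError("no eligible physically close pairs: not testable")
    far_by_aa: dict[int, np.ndarray] = {
        int(aa): g["r2"].to_numpy() for aa, g in far.groupby("aa_distance")}
    close_by_aa: dict[int, np.ndarray] = {
        int(aa): g["r2"].to_numpy() for aa, g in close.groupby("aa_distance")}

    strata = []          # (close values, pooled close+far values)
    dropped = 0
    for aa, close_vals in sorted(close_by_aa.items()):
        far_vals = far_by_aa.get(aa)
        if far_vals is None:
            for delta in range(1, aa_tolerance + 1):
                far_vals = (far_by_aa.get(aa - delta)
                            if far_by_aa.get(aa - delta) is not None
                            else far_by_aa.get(aa + delta))
                if far_vals is not None:
                    logger.debug("aa distance %d matched at +/-%d",
                                 aa, delta)
                    break
        if far_vals is None:
            dropped += len(close_vals)
            continue
        strata.append((close_vals, np.concatenate([close_vals, far_vals])))
    if not strata:
        raise ValueError("no close pair has a matchable far pair: "
                         "not testable")
    kept = np.concatenate([c for c, _ in strata])
    observed = float(kept.mean())
    k = kept.size
    null_sums = np.zeros(n_perm)
    for close_vals, pool in strata:
        c = close_vals.size
        for b in range(n_perm):
            null_sums[b] += pool[rng.choice(pool.size, size=c,
                                            replace=False)].sum()
    null_means = null_sums / k
    p = (1 + int((null_means >= observed - 1e-15).sum())) / (n_perm + 1)
    return PermutationTestResult(observed, null_means, p, k, dropped)


# ---------------------------------------------------------------------------
# per-gene contingency test


@dataclass
class GeneContactTest:
    protein_id: str
    close_high: int
    close_low: int
    far_high: int
    far_low: int
    odds_ratio: float
    chi2_p: float
    bh_q: float | None = None

    @property
    def table(self) -> np.ndarray:
        return np.array([[self.close_high, self.close_low],
                         [self.far_high, self.far_low]])


def odds_ratio_2x2(a: int, b: int, c: int, d: int) -> float:
    """(a*d)/(b*c) with Haldane 0.5 continuity correction on any zero cell."""
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    return (a * d) / (b * c)


def gene_contact_association(pairs: pd.DataFrame,
                             cutoff: float = CONTACT_CUTOFF,
                             aa_band: tuple[int, int] = (30, 100),
                             high_ld_quantile: float = 0.9,
                             min_close: int = 5,
                             class_pair: str | None = None) -> GeneContactTest | None:
    """Per-gene close/far x high/low-LD contingency test.

    Pairs outside the ``aa_band`` residue separation are excluded; high
    LD means r^2 at or above the per-gene ``high_ld_quantile`` of the
    banded pairs.  Genes with fewer than ``min_close`` physically close
    pairs, or without two distinct r^2 values, are not testable (None).
    """
    sub = pairs[(pairs["aa_distance"] >= aa_band[0]) &
                (pairs["aa_distance"] <= aa_band[1])]
    if class_pair is not None:
        sub = sub[sub["class_pair"] == class_pair]
    dist = sub["physical_distance"].to_numpy()
    sub = sub[np.isfinite(dist)]
    if len(sub) == 0 or sub["r2"].nunique() < 2:
        return None
    thr = float(np.quantile(sub["r2"], high_ld_quantile))
    high = sub["r2"].to_numpy() >= thr
    close = sub["physical_distance"].to_numpy() <= cutoff
    a = int((close & high).sum())
    b = int((close & ~high).sum())
    c = int((~close & high).sum())
    d = int((~close & ~high).sum())
    if a + b < min_close:
        return None
    orr = odds_ratio_2x2(a, b, c, d)
    raw = np.array([[a, b], [c, d]])
    if raw.sum(axis=0).min() == 0 or raw.sum(axis=1).min() == 0:
        p = np.nan
    else:
        _, p, _, _ = sps.chi2_contingency(raw, correction=False)
    pid = str(pairs["protein_id"].iloc[0]) if len(pairs) else "?"
    return GeneContactTest(pid, a, b, c, d, float(orr), float(p))


def fdr_adjust(tests: list[GeneContactTest],
               alpha: float = 0.05) -> tuple[list[GeneContactTest],
                                             list[GeneContactTest]]:
    """Benjamini-Hochberg step-up over all eligible genes in a population.

    Returns (tests with bh_q filled, significant subset at bh_q <= alpha).
    """
    if not tests:
        raise ValueError("no tests to adjust")
    pvals = np.array([t.chi2_p for t in tests])
    ok = np.isfinite(pvals)
    qvals = np.full(len(tests), np.nan)
    if ok.any():
        _, q, _, _ = multipletests(pvals[ok], method="fdr_bh")
        qvals[ok] = q
    for t, q in zip(tests, qvals):
        t.bh_q = float(q) if np.isfinite(q) else None
    significant = [t for t in tests
                   if t.bh_q is not None and t.bh_q <= alpha]
    return tests, significant
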