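"""Structure-controlled synthetic data with known ground truth.

Generates haploid multi-genotype alignments with codon-structured genes,
a tunable background site-frequency spectrum, planted two-haplotype
haploblocks, planted coupled nonsynonymous pairs, and contact maps whose
segment structure mirrors planted LD segments.  Every generator is
seed-deterministic and returns a truth record sufficient to score
recovery of the planted features.

Defaults emulate a hyperpolymorphic haploid population: a few dozen
genotypes, a high per-site polymorphism probability, and a neutral-like
MAF law truncated at singletons.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genomes import (HaploidAlignment, GeneAnnotation, NUCLEOTIDES,
                      write_haploid_alignment, write_gene_annotations)
from .structure import ContactMap

logger = logging.getLogger(__name__)

_SENSE_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                 if a + b + c not in ("TAA", "TAG", "TGA")]


@dataclass
class PlantedBlock:
    """A two-haplotype segment: span, minor-haplotype frequency, SNP density."""

    start: int
    end: int
    minor_freq: float = 0.3
    snp_density: float = 0.08   # divergence SNPs per nucleotide in the span
    noise: float = 0.0          # per-SNP carrier-flip probability


@dataclass
class PlantedPair:
    """A coupled nonsynonymous SNP pair inside one gene."""

    gene_index: int
    codon_i: int
    codon_j: int
    maf: float = 0.2
    target_r2: float = 1.0


@dataclass
class SynthSpec:
    """Specification of one synthetic population."""

    n_genotypes: int = 30
    contig_length: int = 6000
    contig_id: str = "synth1"
    n_genes: int = 4
    gene_length: int = 900       # multiple of 3
    poly_prob: float = 0.08      # per-site background polymorphism probability
    blocks: tuple[PlantedBlock, ...] = ()
    pairs: tuple[PlantedPair, ...] = ()
    rng_seed: int = 0

    def gene_layout(self) -> list[tuple[int, int, str]]:
        """Evenly spaced single-exon genes, alternating strand."""
        if self.n_genes == 0:
            return []
        gap = max((self.contig_length - self.n_genes * self.gene_length)
                  // (self.n_genes + 1), 0)
        out = []
        pos = gap
        for g in range(self.n_genes):
            out.append((pos, pos + self.gene_length,
                        "+" if g % 2 == 0 else "-"))
            pos += self.gene_length + gap
        if out and out[-1][1] > self.contig_length:
            raise ValueError("gene layout exceeds contig length")
        return out


def _neutral_minor_counts(n: int, size: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Minor-allele counts from a folded neutral-like SFS, no singletons.

    P(count = k) is proportional to 1/k + 1/(n-k) folded onto
    k in [2, n//2]."""
    ks = np.arange(2, n // 2 + 1)
    wts = 1.0 / ks + 1.0 / (n - ks)
    # at the fold point k = n-k, both terms describe the same class
    if n % 2 == 0:
        wts[-1] /= 2
    wts /= wts.sum()
    return rng.choice(ks, size=size, p=wts)


def generate_population(spec: SynthSpec):
    """Generate (HaploidAlignment, annotations, truth record).

    Background SNPs are independent across sites; planted haploblock SNPs
    are fully coupled to a minor-haplotype genotype set of the requested
    frequency (optionally noised); planted pairs are coupled nonsynonymous
    SNPs hitting the requested r^2 (an infeasible target raises with the
    feasible bound).
    """
    rng = np.random.default_rng(spec.rng_seed)
    n, L = spec.n_genotypes, spec.contig_length
    layout = spec.gene_layout()

    ref = rng.choice(list(NUCLEOTIDES), size=L)
    annotations = []
    for g, (s, e, strand) in enumerate(layout):
        codons = rng.choice(_SENSE_CODONS, size=(e - s) // 3)
        seq = list("".join(codons))
        if strand == "-":
            comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
            seq = [comp[b] for b in seq[::-1]]
        ref[s:e] = seq
        annotations.append(GeneAnnotation(
            gene_id=f"gene{g}", contig_id=spec.contig_id, strand=strand,
            exons=((s, e),), phase=0))

    aln = np.tile(ref, (n, 1))
    truth = {"contig_id": spec.contig_id, "n_genotypes": n,
             "contig_length": L, "blocks": [], "pairs": [],
             "genes": [{"gene_id": a.gene_id, "start": a.span[0],
                        "end": a.span[1], "strand": a.strand}
                       for a in annotations]}

    in_block = np.zeros(L, dtype=bool)
    for blk in spec.blocks:
        in_block[blk.start:blk.end] = True

    pair_positions: set[int] = set()
    for pp in spec.pairs:
        gs, ge, strand = layout[pp.gene_index]
        rec = _plant_pair(aln, ref, gs, ge, strand, pp, rng)
        rec["gene_id"] = f"gene{pp.gene_index}"
        truth["pairs"].append(rec)
        pair_positions.update((rec["pos_i"], rec["pos_j"]))

    for blk in spec.blocks:
        k = max(int(round(blk.minor_freq * n)), 2)
        carriers = rng.choice(n, size=k, replace=False)
        n_snps = max(int(round(blk.snp_density * (blk.end - blk.start))), 2)
        avail = np.setdiff1d(np.arange(blk.start, blk.end),
                             np.fromiter(pair_positions, int, len(pair_positions)))
        positions = np.sort(rng.choice(avail, size=min(n_snps, avail.size),
                                       replace=False))
        for pos in positions:
            alt = _other_base(ref[pos], rng)
            members = carriers
            if blk.noise > 0:
                flip = rng.random(n) < blk.noise
                memb_mask = np.zeros(n, dtype=bool)
                memb_mask[carriers] = True
                memb_mask ^= flip
                members = np.flatnonzero(memb_mask)
            aln[members, pos] = alt
        truth["blocks"].append({
            "start": int(blk.start), "end": int(blk.end),
            "minor_freq": k / n, "carriers": sorted(map(int, carriers)),
            "positions": [int(p) for p in positions]})

    background = np.flatnonzero(~in_block)
    background = np.setdiff1d(background,
                              np.fromiter(pair_positions, int,
                                          len(pair_positions)))
    chosen = background[rng.random(background.size) < spec.poly_prob]
    counts = _neutral_minor_counts(n, chosen.size, rng)
    for pos, k in zip(chosen, counts):
        carriers = rng.choice(n, size=k, replace=False)
        aln[carriers, pos] = _other_base(ref[pos], rng)

    alignment = HaploidAlignment(
        contig_id=spec.contig_id,
        genotype_ids=[f"g{i:03d}" for i in range(n)],
        columns=aln)
    return alignment, annotations, truth


def _other_base(base: str, rng: np.random.Generator) -> str:
    options = [b for b in NUCLEOTIDES if b != base]
    return options[rng.integers(0, 3)]


def _nonsyn_substitution(codon: str, rng: np.random.Generator):
    """A (position offset, alt base) making an amino-acid change."""
    from Bio.Seq import Seq

    aa0 = str(Seq(codon).translate())
    options = []
    for off in range(3):
        for alt in NUCLEOTIDES:
            if alt == codon[off]:
                continue
            mutant = codon[:off] + alt + codon[off + 1:]
            if str(Seq(mutant).translate()) != aa0:
                options.append((off, alt))
    return options[rng.integers(0, len(options))]


def _plant_pair(aln: np.ndarray, ref: np.ndarray, gene_start: int,
                gene_end: int, strand: str, pp: PlantedPair,
                rng: np.random.Generator) -> dict:
    n = aln.shape[0]
    k = max(int(round(pp.maf * n)), 2)
    p = k / n
    # feasible r given equal MAFs: overlap m in [max(0, 2k-n), k]
    target_r = np.sqrt(pp.target_r2)
    m_real = target_r * k * (n - k) / n + k * p
    m = int(round(m_real))
    if m > k or m < max(0, 2 * k - n):
        denom = k * (n - k) / n
        feas = ((k - k * p) / denom) ** 2
        raise ValueError(
            f"target r2 {pp.target_r2} infeasible for maf {pp.maf} at "
            f"n={n}; feasible r2 <= {feas:.3f}")
    positions = []
    alts = []
    for codon_idx in (pp.codon_i, pp.codon_j):
        if strand == "+":
            c0 = gene_start + 3 * codon_idx
            codon = "".join(ref[c0:c0 + 3])
            off, alt = _nonsyn_substitution(codon, rng)
            positions.append(c0 + off)
            alts.append(alt)
        else:
            # codon codon_idx reads 3' -> 5' on the genomic strand
            c0 = gene_end - 3 * (codon_idx + 1)
            comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
            codon = "".join(comp[b] for b in ref[c0:c0 + 3][::-1])
            off, alt = _nonsyn_substitution(codon, rng)
            positions.append(gene_end - 1 - 3 * codon_idx - off)
            alts.append(comp[alt])
    carriers_i = rng.choice(n, size=k, replace=False)
    shared = rng.choice(carriers_i, size=m, replace=False)
    others = np.setdiff1d(np.arange(n), carriers_i)
    extra = rng.choice(others, size=k - m, replace=False)
    carriers_j = np.concatenate([shared, extra])
    aln[carriers_i, positions[0]] = alts[0]
    aln[carriers_j, positions[1]] = alts[1]
    x = np.zeros(n)
    x[carriers_i] = 1
    y = np.zeros(n)
    y[carriers_j] = 1
    realized = float(np.corrcoef(x, y)[0, 1] ** 2)
    return {"pos_i": int(min(positions)), "pos_j": int(max(positions)),
            "maf": p, "target_r2": pp.target_r2, "realized_r2": realized,
            "carriers_i": sorted(map(int, carriers_i)),
            "carriers_j": sorted(map(int, carriers_j))}


# ---------------------------------------------------------------------------
# contact maps


def generate_contact_map(n_residues: int, segments: list[tuple[int, int]],
                         protein_id: str = "synthP",
                         within_range: tuple[float, float] = (4.0, 8.0),
                         between_range: tuple[float, float] = (14.0, 30.0),
                         rng_seed: int = 0) -> ContactMap:
    """A segmented contact map: residues in the same segment are close.

    Within-segment pair distances are drawn below the 10 A contact
    cutoff, between-segment pairs well above it.
    """
    rng = np.random.default_rng(rng_seed)
    seg_of = np.full(n_residues, -1)
    for s_idx, (a, b) in enumerate(segments):
        seg_of[a:b] = s_idx
    d = np.zeros((n_residues, n_residues))
    iu = np.triu_indices(n_residues, 1)
    same = seg_of[iu[0]] == seg_of[iu[1]]
    vals = np.where(same & (seg_of[iu[0]] >= 0),
                    rng.uniform(*within_range, size=same.size),
                    rng.uniform(*between_range, size=same.size))
    d[iu] = vals
    d[(iu[1], iu[0])] = vals
    return ContactMap(protein_id, d)


def identity_residue_map(gene_id: str, n_codons: int) -> pd.DataFrame:
    """Codon i -> residue i mapping for a fully resolved structure."""
    return pd.DataFrame({"gene_id": gene_id,
                         "codon_index": np.arange(n_codons),
                         "residue_index": np.arange(n_codons)})


def mirrored_contact_for_gene(truth: dict, gene_id: str, gene_length_nt: int,
                              rng_seed: int = 0) -> tuple[ContactMap, pd.DataFrame]:
    """Contact map whose segments mirror the planted blocks inside a gene.

    Planted block spans intersecting the gene are converted to residue
    segments; residues outside any block form implicit background
    (between-segment distances).
    """
    gene = next(g for g in truth["genes"] if g["gene_id"] == gene_id)
    n_codons = gene_length_nt // 3
    segments = []
    for blk in truth["blocks"]:
        lo = max(blk["start"], gene["start"])
        hi = min(blk["end"], gene["end"])
        if hi <= lo:
            continue
        if gene["strand"] == "+":
            seg = ((lo - gene["start"]) // 3,
                   (hi - gene["start"] + 2) // 3)
        else:
            seg = ((gene["end"] - hi) // 3,
                   (gene["end"] - lo + 2) // 3)
        segments.append((max(seg[0], 0), min(seg[1], n_codons)))
    cmap = generate_contact_map(n_codons, segments, protein_id=gene_id,
                                rng_seed=rng_seed)
    return cmap, identity_residue_map(gene_id, n_codons)


# ---------------------------------------------------------------------------
# two-population mode


def generate_two_populations(spec_a: SynthSpec, spec_b: SynthSpec | None = None,
                             share_fraction: float = 0.25):
    """Two populations on one coordinate system sharing SNP positions.

    Population B reuses a ``share_fraction`` subset of A's background SNP
    positions (same alleles, independently drawn carriers) on the same
    reference sequence; planted pairs are shared, planted blocks are
    population-private.  Returns (aln_a, aln_b, annotations, truth).
    """
    if spec_b is None:
        spec_b = SynthSpec(**{**asdict(spec_a), "blocks": (),
                              "rng_seed": spec_a.rng_seed + 1})
        spec_b.pairs = spec_a.pairs
    if (spec_b.contig_length != spec_a.contig_length or
            spec_b.n_genes != spec_a.n_genes):
        raise ValueError("populations must share the coordinate system")
    aln_a, anns, truth_a = generate_population(spec_a)
    rng = np.random.default_rng(spec_a.rng_seed + 10_007)

    # rebuild B on A's reference so coordinates and codons coincide
    ref = _consensus_of(aln_a, truth_a)
    n_b = spec_b.n_genotypes
    aln = np.tile(ref, (n_b, 1))
    truth_b = {"contig_id": spec_b.contig_id, "blocks": [], "pairs": [],
               "genes": truth_a["genes"], "n_genotypes": n_b,
               "contig_length": spec_b.contig_length}

    for rec in truth_a["pairs"]:
        k = max(int(round(rec["maf"] * n_b)), 2)
        # replant the same positions with the same alternate alleles
        pos_i, pos_j = rec["pos_i"], rec["pos_j"]
        alt_i = _planted_alt(aln_a, truth_a, pos_i, ref)
        alt_j = _planted_alt(aln_a, truth_a, pos_j, ref)
        target_r = np.sqrt(rec["target_r2"])
        p = k / n_b
        m = int(round(target_r * k * (n_b - k) / n_b + k * p))
        m = min(max(m, max(0, 2 * k - n_b)), k)
        carriers_i = rng.choice(n_b, size=k, replace=False)
        shared = rng.choice(carriers_i, size=m, replace=False)
        others = np.setdiff1d(np.arange(n_b), carriers_i)
        carriers_j = np.concatenate([shared,
                                     rng.choice(others, size=k - m,
                                                replace=False)])
        aln[carriers_i, pos_i] = alt_i
        aln[carriers_j, pos_j] = alt_j
        truth_b["pairs"].append({**rec,
                                 "carriers_i": sorted(map(int, carriers_i)),
                                 "carriers_j": sorted(map(int, carriers_j))})

    for blk in spec_b.blocks:
        k = max(int(round(blk.minor_freq * n_b)), 2)
        carriers = rng.choice(n_b, size=k, replace=False)
        n_snps = max(int(round(blk.snp_density * (blk.end - blk.start))), 2)
        positions = np.sort(rng.choice(np.arange(blk.start, blk.end),
                                       size=n_snps, replace=False))
        for pos in positions:
            aln[carriers, pos] = _other_base(ref[pos], rng)
        truth_b["blocks"].append({"start": blk.start, "end": blk.end,
                                  "minor_freq": k / n_b,
                                  "positions": [int(p) for p in positions]})

    # background: share a fraction of A's segregating positions
    pair_pos = {rec["pos_i"] for rec in truth_a["pairs"]} | \
        {rec["pos_j"] for rec in truth_a["pairs"]}
    block_pos_a = {p for b in truth_a["blocks"] for p in b["positions"]}
    n_distinct = np.array([len(np.unique(aln_a.columns[:, j]))
                           for j in range(spec_a.contig_length)])
    seg_a = [int(j) for j in np.flatnonzero(n_distinct > 1)
             if j not in pair_pos and j not in block_pos_a]
    shared_pos = [p for p in seg_a if rng.random() < share_fraction]
    counts = _neutral_minor_counts(n_b, len(shared_pos), rng)
    for pos, k in zip(shared_pos, counts):
        col = aln_a.columns[:, pos]
        alts = [b for b in np.unique(col) if b != ref[pos]]
        aln[rng.choice(n_b, size=k, replace=False), pos] = alts[0]
    # private B background on positions monomorphic in A
    in_block_b = np.zeros(spec_b.contig_length, dtype=bool)
    for blk in spec_b.blocks:
        in_block_b[blk.start:blk.end] = True
    mono = np.setdiff1d(np.flatnonzero(~in_block_b),
                        np.array(seg_a + sorted(pair_pos), dtype=int))
    chosen = mono[rng.random(mono.size) < spec_b.poly_prob *
                  (1 - share_fraction)]
    counts = _neutral_minor_counts(n_b, chosen.size, rng)
    for pos, k in zip(chosen, counts):
        aln[rng.choice(n_b, size=k, replace=False), pos] = \
            _other_base(ref[pos], rng)

    aln_b = HaploidAlignment(contig_id=spec_b.contig_id,
                             genotype_ids=[f"h{i:03d}" for i in range(n_b)],
                             columns=aln)
    truth = {"pop_a": truth_a, "pop_b": truth_b,
             "shared_background_positions": shared_pos}
    return aln_a, aln_b, anns, truth


def _consensus_of(aln_a: HaploidAlignment, truth_a: dict) -> np.ndarray:
    from .genomes import consensus_sequence
    return consensus_sequence(aln_a)


def _planted_alt(aln_a: HaploidAlignment, truth_a: dict, pos: int,
                 ref: np.ndarray) -> str:
    col = aln_a.columns[:, pos]
    alts = [b for b in np.unique(col) if b != ref[pos]]
    return str(alts[0]) if alts else str(ref[pos])


# ---------------------------------------------------------------------------
# file emission


def write_population(path_dir, alignment: HaploidAlignment,
                     annotations, truth: dict) -> dict[str, Path]:
    """Emit FASTA + GFF3 + truth JSON consumable by the pipeline."""
    path_dir = Path(path_dir)
    path_dir.mkdir(parents=True, exist_ok=True)
    fasta = path_dir / f"{alignment.contig_id}.fa"
    gff = path_dir / f"{alignment.contig_id}.gff3"
    truth_path = path_dir / f"{alignment.contig_id}.truth.json"
    write_haploid_alignment(alignment, fasta)
    write_gene_annotations(annotations, gff)
    truth_path.write_text(json.dumps(truth, indent=1))
    return {"fasta": fasta, "gff": gff, "truth": truth_path}
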