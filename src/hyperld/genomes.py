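"""Haploid alignment I/O, SNP extraction, functional classification, diversity.

The unit of input is a multi-FASTA alignment of haploid genotypes over one
contig or scaffold: every record has the same length, and column ``j`` of
every record is the state of the same genomic position ``j``.  Coordinates
are 0-based half-open everywhere inside the package; GFF3 annotations
(1-based closed) are converted on read.

Gap policy is whole-column exclusion: any column containing ``-`` or ``N``
in any genotype is dropped from SNP extraction and from nucleotide-diversity
denominators, mirroring an analysis restricted to gap-free alignment
columns.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

NUCLEOTIDES = ("A", "C", "G", "T")
_KNOWN = frozenset("ACGT-N")
_COMPLEMENT = str.maketrans("ACGTN-", "TGCAN-")

SYNONYMOUS = "synonymous"
NONSYNONYMOUS = "nonsynonymous"
NONCODING = "noncoding"


class AlignmentFormatError(ValueError):
    """An input alignment violates the format contract."""


class UndefinedStatisticError(ValueError):
    """A requested statistic is undefined for the given input."""


# ---------------------------------------------------------------------------
# domain types


@dataclass
class HaploidAlignment:
    """Aligned haploid genotypes over one contig.

    ``columns`` is an (n_genotypes, length) array of single characters from
    {A, C, G, T, -, N}.
    """

    contig_id: str
    genotype_ids: list[str]
    columns: np.ndarray

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns, dtype="<U1")
        if self.columns.ndim != 2:
            raise AlignmentFormatError("columns must be a 2-D matrix")
        n = self.columns.shape[0]
        if n < 2:
            raise AlignmentFormatError(f"need at least 2 genotypes, got {n}")
        if len(self.genotype_ids) != n:
            raise AlignmentFormatError("genotype_ids length does not match matrix")
        if len(set(self.genotype_ids)) != n:
            raise AlignmentFormatError("genotype_ids must be unique")

    @property
    def n_genotypes(self) -> int:
        return self.columns.shape[0]

    @property
    def length(self) -> int:
        return self.columns.shape[1]


@dataclass(frozen=True)
class GeneAnnotation:
    """One protein-coding gene: ordered exons on a contig strand.

    ``exons`` are 0-based half-open intervals in genomic order.  ``phase``
    is the number of bases of the first *translated* exon to skip before
    the first complete codon (the first exon in transcription order, i.e.
    the genomically last interval for minus-strand genes).
    """

    gene_id: str
    contig_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    phase: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        ex = tuple(sorted((int(s), int(e)) for s, e in self.exons))
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping exons in gene {self.gene_id}")
        object.__setattr__(self, "exons", ex)

    def coding_positions(self) -> np.ndarray:
        """Genomic positions of coding bases, in translation order."""
        pos = np.concatenate([np.arange(s, e) for s, e in self.exons])
        if self.strand == "-":
            pos = pos[::-1]
        return pos[self.phase:]

    def exon_index_of(self, position: int) -> int | None:
        """Index of the exon containing ``position``, in transcription order."""
        order = self.exons if self.strand == "+" else self.exons[::-1]
        for i, (s, e) in enumerate(order):
            if s <= position < e:
                return i
        return None

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass
class SnpTable:
    """Biallelic polymorphic sites with per-genotype minor-allele states.

    ``df`` has one row per SNP with columns: contig, pos, major, minor, maf,
    singleton, site_class, gene_id, exon_index, codon_id, aa_major, aa_minor.
    ``states`` is an (n_snps, n_genotypes) uint8 matrix, 1 = minor allele.
    """

    genotype_ids: list[str]
    df: pd.DataFrame
    states: np.ndarray

    COLUMNS = (
        "contig", "pos", "major", "minor", "maf", "singleton",
        "site_class", "gene_id", "exon_index", "codon_id",
        "aa_major", "aa_minor",
    )

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.uint8)
        if len(self.df) != self.states.shape[0]:
            raise ValueError("df and states disagree on SNP count")
        if len(self.df) and self.states.shape[1] != len(self.genotype_ids):
            raise ValueError("states and genotype_ids disagree on sample size")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_genotypes(self) -> int:
        return len(self.genotype_ids)

    def subset(self, mask: np.ndarray) -> "SnpTable":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return SnpTable(self.genotype_ids,
                        self.df.iloc[idx].reset_index(drop=True),
                        self.states[idx])

    @classmethod
    def concat(cls, tables: Sequence["SnpTable"]) -> "SnpTable":
        if not tables:
            raise ValueError("no tables to concatenate")
        gids = tables[0].genotype_ids
        for t in tables[1:]:
            if t.genotype_ids != gids:
                raise ValueError("genotype panels differ between tables")
        df = pd.concat([t.df for t in tables], ignore_index=True)
        states = np.vstack([t.states for t in tables]) if len(df) else \
            np.zeros((0, len(gids)), dtype=np.uint8)
        return cls(gids, df, states)

    # -- serialization ------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        out = self.df.copy()
        out["states"] = ["".join(map(str, row)) for row in self.states]
        with open(path, "w") as fh:
            fh.write("#genotypes=" + ",".join(self.genotype_ids) + "\n")
            out.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SnpTable":
        with open(path) as fh:
            header = fh.readline().strip()
            if not header.startswith("#genotypes="):
                raise AlignmentFormatError("missing #genotypes header line")
            gids = header.split("=", 1)[1].split(",")
            df = pd.read_csv(fh, sep="\t", dtype={"gene_id": "string",
                                                  "codon_id": "string",
                                                  "states": str})
        states = (np.array([list(s) for s in df.pop("states")], dtype="<U1")
                  .astype(np.uint8) if len(df) else
                  np.zeros((0, len(gids)), dtype=np.uint8))
        for col in cls.COLUMNS:
            if col not in df.columns:
                df[col] = pd.NA
        return cls(gids, df[list(cls.COLUMNS)].copy(), states)


# ---------------------------------------------------------------------------
# operations


def read_haploid_alignment(path: str | Path, format: str = "fasta",
                           contig_id: str | None = None) -> HaploidAlignment:
    """Read an aligned multi-FASTA of haploid genotypes.

    Symbols are uppercased; anything outside {A,C,G,T,-,N} maps to N.
    Unequal record lengths raise :class:`AlignmentFormatError` naming the
    offending record.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), format))
    if len(records) < 2:
        raise AlignmentFormatError(
            f"{path}: need at least 2 records, got {len(records)}")
    length = len(records[0].seq)
    rows = []
    for i, rec in enumerate(records):
        if len(rec.seq) != length:
            raise AlignmentFormatError(
                f"{path}: record {i + 1} ({rec.id!r}) has length "
                f"{len(rec.seq)}, expected {length}")
        rows.append(list(str(rec.seq).upper()))
    mat = np.array(rows, dtype="<U1")
    mat[~np.isin(mat, list(_KNOWN))] = "N"
    return HaploidAlignment(
        contig_id=contig_id or path.stem,
        genotype_ids=[rec.id for rec in records],
        columns=mat,
    )


def write_haploid_alignment(aln: HaploidAlignment, path: str | Path) -> None:
    records = [SeqRecord(Seq("".join(row)), id=gid, description="")
               for gid, row in zip(aln.genotype_ids, aln.columns)]
    SeqIO.write(records, str(path), "fasta")


def consensus_sequence(aln: HaploidAlignment) -> np.ndarray:
    """Per-column majority nucleotide (ties broken alphabetically).

    Columns with no A/C/G/T at all become 'N'.
    """
    counts = np.stack([(aln.columns == b).sum(axis=0) for b in NUCLEOTIDES])
    best = np.argmax(counts, axis=0)  # argmax takes first on ties = alphabetical
    cons = np.array(NUCLEOTIDES, dtype="<U1")[best]
    cons[counts.sum(axis=0) == 0] = "N"
    return cons


def gap_free_columns(aln: HaploidAlignment) -> np.ndarray:
    """Boolean mask of columns free of gaps and Ns in every genotype."""
    return ~np.any((aln.columns == "-") | (aln.columns == "N"), axis=0)


def extract_snps(aln: HaploidAlignment,
                 annotations: Sequence[GeneAnnotation] | None = None,
                 drop_singletons: bool = True,
                 gap_policy: str = "drop_column") -> SnpTable:
    """Extract biallelic SNPs from gap-free columns.

    Columns with a gap or N anywhere are excluded entirely; columns with
    three or more alleles are excluded.  Major/minor assignment is by
    count, ties (MAF exactly 0.5) broken so the alphabetically first
    allele is major.  With ``drop_singletons`` (the default analysis
    convention), SNPs whose minor allele occurs in exactly one genotype
    are removed.
    """
    if gap_policy != "drop_column":
        raise ValueError(f"unsupported gap_policy {gap_policy!r}")
    n = aln.n_genotypes
    good = gap_free_columns(aln)
    counts = np.stack([(aln.columns == b).sum(axis=0) for b in NUCLEOTIDES])
    present = counts > 0
    biallelic = good & (present.sum(axis=0) == 2)

    rows = []
    states = []
    base_arr = np.array(NUCLEOTIDES, dtype="<U1")
    for j in np.flatnonzero(biallelic):
        which = np.flatnonzero(present[:, j])
        a1, a2 = base_arr[which]          # alphabetical order by construction
        c1, c2 = counts[which, j]
        if c1 >= c2:                      # tie -> alphabetically first is major
            major, minor, cmin = a1, a2, c2
        else:
            major, minor, cmin = a2, a1, c1
        if drop_singletons and cmin == 1:
            continue
        rows.append((aln.contig_id, int(j), major, minor, cmin / n, cmin == 1))
        states.append((aln.columns[:, j] == minor).astype(np.uint8))

    df = pd.DataFrame(rows, columns=["contig", "pos", "major", "minor",
                                     "maf", "singleton"])
    df["site_class"] = NONCODING
    df["gene_id"] = pd.Series([pd.NA] * len(df), dtype="string")
    df["exon_index"] = pd.Series([pd.NA] * len(df), dtype="Int64")
    df["codon_id"] = pd.Series([pd.NA] * len(df), dtype="string")
    df["aa_major"] = pd.Series([pd.NA] * len(df), dtype="string")
    df["aa_minor"] = pd.Series([pd.NA] * len(df), dtype="string")
    st = (np.vstack(states) if states
          else np.zeros((0, n), dtype=np.uint8))
    table = SnpTable(list(aln.genotype_ids), df, st)
    if annotations:
        _assign_genes(table, annotations)
    return table


def _assign_genes(snps: SnpTable, annotations: Sequence[GeneAnnotation]) -> None:
    df = snps.df
    for ann in annotations:
        in_contig = df["contig"] == ann.contig_id
        for s, e in ann.exons:
            sel = in_contig & (df["pos"] >= s) & (df["pos"] < e)
            df.loc[sel, "gene_id"] = ann.gene_id
            for i in df.index[sel]:
                df.at[i, "exon_index"] = ann.exon_index_of(int(df.at[i, "pos"]))


def classify_coding_sites(snps: SnpTable, aln: HaploidAlignment,
                          annotations: Sequence[GeneAnnotation] | Iterable[GeneAnnotation]) -> SnpTable:
    """Classify exonic SNPs as synonymous or nonsynonymous.

    Each SNP is classified independently against the major-allele
    background: the other two codon positions are filled with the
    alignment consensus (majority) base, and the two alleles are
    substituted in turn.  Minus-strand codons are reverse-complemented
    before translation.  Codons truncated by the contig edge, or with an
    undetermined background base, stay ``noncoding`` with a warning.
    Stop-gained changes count as nonsynonymous.
    """
    anns = [a for a in annotations if a.contig_id == aln.contig_id]
    df = snps.df.copy()
    cons = consensus_sequence(aln)
    pos_to_row: dict[int, list[int]] = {}
    on_contig = df["contig"] == aln.contig_id
    for i in df.index[on_contig]:
        pos_to_row.setdefault(int(df.at[i, "pos"]), []).append(i)

    for ann in anns:
        cpos = ann.coding_positions()
        n_codons = len(cpos) // 3
        cpos = cpos[:3 * n_codons]
        index_of = {int(p): k for k, p in enumerate(cpos)}
        for p, rows in pos_to_row.items():
            k = index_of.get(p)
            if k is None:
                continue
            codon_idx, offset = divmod(k, 3)
            codon_pos = cpos[3 * codon_idx:3 * codon_idx + 3]
            bases = [str(cons[q]) for q in codon_pos]
            for i in rows:
                major = str(df.at[i, "major"])
                minor = str(df.at[i, "minor"])
                if ann.strand == "-":
                    bases_t = [b.translate(_COMPLEMENT) for b in bases]
                    major_t = major.translate(_COMPLEMENT)
                    minor_t = minor.translate(_COMPLEMENT)
                else:
                    bases_t, major_t, minor_t = list(bases), major, minor
                codon_major = list(bases_t)
                codon_major[offset] = major_t
                codon_minor = list(bases_t)
                codon_minor[offset] = minor_t
                if any(b not in NUCLEOTIDES for b in codon_major):
                    logger.warning(
                        "gene %s: codon %d has undetermined background; "
                        "SNP at %s:%d left noncoding",
                        ann.gene_id, codon_idx, aln.contig_id, p)
                    continue
                aa_major = str(Seq("".join(codon_major)).translate())
                aa_minor = str(Seq("".join(codon_minor)).translate())
                df.at[i, "gene_id"] = ann.gene_id
                df.at[i, "exon_index"] = ann.exon_index_of(p)
                df.at[i, "codon_id"] = f"{ann.gene_id}:{codon_idx}"
                df.at[i, "aa_major"] = aa_major
                df.at[i, "aa_minor"] = aa_minor
                df.at[i, "site_class"] = (SYNONYMOUS if aa_major == aa_minor
                                          else NONSYNONYMOUS)
    return SnpTable(snps.genotype_ids, df, snps.states.copy())


def nucleotide_diversity(aln: HaploidAlignment,
                         column_mask: np.ndarray | None = None) -> float:
    """Average pairwise per-site difference frequency (pi).

    Columns with a gap or N in any genotype are excluded from both the
    numerator and the denominator.  Raises
    :class:`UndefinedStatisticError` when no comparable column remains.
    """
    good = gap_free_columns(aln)
    if column_mask is not None:
        good = good & np.asarray(column_mask, dtype=bool)
    cols = aln.columns[:, good]
    if cols.shape[1] == 0:
        raise UndefinedStatisticError("no comparable (gap-free) columns")
    n = aln.n_genotypes
    total = 0.0
    npairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += np.mean(cols[i] != cols[j])
            npairs += 1
    return total / npairs


# ---------------------------------------------------------------------------
# GFF3 I/O


def read_gene_annotations(path: str | Path) -> list[GeneAnnotation]:
    """Read gene models from GFF3 (1-based closed -> 0-based half-open).

    Coding intervals are taken from CDS children when present, otherwise
    from exon children.  The phase of the first translated CDS is used.
    """
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    genes = []
    for gene in db.features_of_type("gene"):
        parts = list(db.children(gene, featuretype="CDS"))
        if not parts:
            parts = list(db.children(gene, featuretype="exon"))
        if not parts:
            parts = [gene]
        parts.sort(key=lambda f: f.start)
        exons = tuple((f.start - 1, f.end) for f in parts)
        first = parts[-1] if gene.strand == "-" else parts[0]
        phase = int(first.frame) if first.frame not in (None, ".", "") else 0
        genes.append(GeneAnnotation(
            gene_id=gene.id, contig_id=gene.seqid,
            strand=gene.strand, exons=exons, phase=phase))
    return genes


def write_gene_annotations(annotations: Sequence[GeneAnnotation],
                           path: str | Path) -> None:
    """Write gene models as GFF3 (gene + CDS features)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for ann in annotations:
            s0, e0 = ann.span
            fh.write("\t".join([
                ann.contig_id, "hyperld", "gene", str(s0 + 1), str(e0),
                ".", ann.strand, ".", f"ID={ann.gene_id}"]) + "\n")
            order = ann.exons if ann.strand == "+" else ann.exons[::-1]
            consumed = 0
            for i, (s, e) in enumerate(order):
                if i == 0:
                    phase = ann.phase
                else:
                    phase = (3 - (consumed - ann.phase) % 3) % 3
                consumed += e - s
                fh.write("\t".join([
                    ann.contig_id, "hyperld", "CDS", str(s + 1), str(e),
                    ".", ann.strand, str(phase),
                    f"ID={ann.gene_id}.cds{i};Parent={ann.gene_id}"]) + "\n")
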