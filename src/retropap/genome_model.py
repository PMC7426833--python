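"""Core domain types and file I/O.

Coordinate conventions
----------------------
Internally every interval is 0-based, half-open ``[start, end)`` on the
forward genomic axis; strand is carried as metadata and never flips
coordinates.  On disk, GFF3 is 1-based inclusive and BED is 0-based
half-open, converted on read/write.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
import pandas as pd
from skbio import TreeNode

log = logging.getLogger("retropap")

#: InterPro identifier of the retrotransposon Gag domain; the term used to
#: select Gag-like elements from an annotation.
GAG_TERM = "IPR005162"

_VALID_BASES = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case ACGTN string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """A located span: 0-based half-open on a named sequence."""

    sequence_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start},{self.end}) on {self.sequence_id}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.sequence_id == other.sequence_id
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GenomeAssembly:
    """A named set of sequences (chromosomes or contigs) for one accession."""

    accession_id: str
    sequences: dict[str, str]
    anchored: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError(f"assembly {self.accession_id} has no sequences")
        for sid, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"empty sequence {sid}")
        for sid in self.sequences:
            self.anchored.setdefault(sid, True)

    def __len__(self) -> int:
        return len(self.sequences)

    def total_bp(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def fetch(self, iv: GenomicInterval) -> str:
        seq = self.sequences[iv.sequence_id]
        if iv.end > len(seq):
            raise ValueError(f"{iv} exceeds sequence length {len(seq)}")
        return seq[iv.start : iv.end]


@dataclass
class GeneModel:
    """A protein-coding gene with its spliced transcript and protein."""

    gene_id: str
    locus: GenomicInterval
    exons: list[GenomicInterval]
    cds: list[GenomicInterval]
    transcript_seq: str
    protein_seq: str | None  # None = flagged non-coding

    def __post_init__(self) -> None:
        ex = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(ex, ex[1:]):
            if a.end > b.start:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        self.exons = ex
        self.cds = sorted(self.cds, key=lambda c: c.start)
        if sum(len(e) for e in self.exons) != len(self.transcript_seq):
            raise ValueError(f"{self.gene_id}: transcript/exon length mismatch")


@dataclass
class GagElement:
    """A retrotransposon Gag-like element annotation."""

    element_id: str
    locus: GenomicInterval
    class_label: str = "LTR/gypsy"
    term_ids: set[str] = field(default_factory=lambda: {GAG_TERM})


@dataclass
class ExpressionMatrix:
    """FPKM values for genes and elements across tissue samples.

    ``values`` is a features x samples DataFrame; ``sample_groups`` maps each
    sample to exactly one tissue-group label; ``ripening_group`` names the
    post-harvest-ripening group.
    """

    values: pd.DataFrame
    sample_groups: dict[str, str]
    ripening_group: str

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if v.size and (not (v >= 0).all() or not pd.notna(v).all()):
            raise ValueError("FPKM values must be finite and >= 0")
        missing = set(self.values.columns) - set(self.sample_groups)
        if missing:
            raise ValueError(f"samples without group assignment: {sorted(missing)}")
        if self.ripening_group not in set(self.sample_groups.values()):
            raise ValueError(f"ripening group {self.ripening_group!r} absent")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.values.columns:
            seen.setdefault(self.sample_groups[s], None)
        return list(seen)

    def group_means(self) -> pd.DataFrame:
        """Per-feature mean FPKM in each tissue group (features x groups)."""
        cols = pd.Series({s: self.sample_groups[s] for s in self.values.columns})
        return self.values.T.groupby(cols).mean().T[self.groups()]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path, accession_id: str | None = None) -> GenomeAssembly:
    """Read a multi-FASTA file into a :class:`GenomeAssembly`.

    Sequences are upper-cased; symbols outside ACGTN are mapped to N with a
    logged count.  Duplicate record IDs and empty files are hard errors.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    sequences: dict[str, str] = {}
    n_mapped = 0
    for rec in records:
        if rec.id in sequences:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        bad = sum(1 for c in seq if c not in _VALID_BASES)
        if bad:
            n_mapped += bad
            seq = "".join(c if c in _VALID_BASES else "N" for c in seq)
        sequences[rec.id] = seq
    if n_mapped:
        log.warning("read_fasta(%s): mapped %d non-ACGTN symbols to N", path, n_mapped)
    if accession_id is None:
        accession_id = str(path)
    return GenomeAssembly(accession_id=accession_id, sequences=sequences)


def write_fasta(assembly: GenomeAssembly, path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in assembly.sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# GFF3 / BED
# ---------------------------------------------------------------------------

ELEMENT_ATTR = "gag_like"  # attribute key marking element rows in GFF3


def _splice(assembly: GenomeAssembly, ivs: list[GenomicInterval], strand: str) -> str:
    parts = [assembly.fetch(iv) for iv in sorted(ivs, key=lambda i: i.start)]
    seq = "".join(parts)
    return revcomp(seq) if strand == "-" else seq


def read_gff3(path, assembly: GenomeAssembly,
              element_attr: str = ELEMENT_ATTR,
              gag_term: str = GAG_TERM) -> tuple[list[GeneModel], list[GagElement]]:
    """Read gene models and Gag-like element rows from a GFF3 file.

    1-based inclusive GFF3 coordinates become internal 0-based half-open.
    Rows carrying ``element_attr`` (any feature type) become
    :class:`GagElement`; gene/mRNA/exon/CDS hierarchies become
    :class:`GeneModel` with transcript and protein sequences derived from
    *assembly*.  A CDS whose spliced length is not a multiple of three is
    logged and the gene flagged non-coding (``protein_seq=None``).
    """
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    genes: list[GeneModel] = []
    elements: list[GagElement] = []

    for feat in db.all_features():
        if element_attr in feat.attributes:
            iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end,
                                 feat.strand if feat.strand in "+-" else ".")
            terms = set(feat.attributes.get("term_ids", [gag_term])[0].split(","))
            terms.add(gag_term)
            elements.append(GagElement(
                element_id=feat.id, locus=iv,
                class_label=feat.attributes.get("class_label", ["LTR/gypsy"])[0],
                term_ids=terms))

    for gene in db.features_of_type("gene"):
        if element_attr in gene.attributes:
            continue
        locus = GenomicInterval(gene.seqid, gene.start - 1, gene.end, gene.strand)
        exons: list[GenomicInterval] = []
        cds: list[GenomicInterval] = []
        for mrna in db.children(gene, featuretype="mRNA"):
            for ex in db.children(mrna, featuretype="exon"):
                if ex.start - 1 < gene.start - 1 or ex.end > gene.end:
                    raise ValueError(f"exon of {gene.id} outside parent span")
                exons.append(GenomicInterval(ex.seqid, ex.start - 1, ex.end, ex.strand))
            for c in db.children(mrna, featuretype="CDS"):
                cds.append(GenomicInterval(c.seqid, c.start - 1, c.end, c.strand))
        if not exons:
            exons = [locus]
        if not cds:
            cds = list(exons)
        transcript = _splice(assembly, exons, gene.strand)
        cds_seq = _splice(assembly, cds, gene.strand)
        if len(cds_seq) % 3 != 0:
            log.warning("%s: spliced CDS not a multiple of 3; marked non-coding",
                        gene.id)
            protein = None
        else:
            protein = str(Seq(cds_seq).translate()).rstrip("*")
        genes.append(GeneModel(gene_id=gene.id, locus=locus, exons=exons,
                               cds=cds, transcript_seq=transcript,
                               protein_seq=protein))
    return genes, elements


def write_gff3(genes: list[GeneModel], elements: list[GagElement], path,
               source: str = "retropap") -> None:
    """Write gene models and element rows as GFF3 (1-based inclusive)."""
    def row(seqid, ftype, iv, attrs):
        return "\t".join([seqid, source, ftype, str(iv.start + 1), str(iv.end),
                          ".", iv.strand if iv.strand in "+-" else ".", ".", attrs])

    lines = ["##gff-version 3"]
    for g in genes:
        lines.append(row(g.locus.sequence_id, "gene", g.locus, f"ID={g.gene_id}"))
        mid = f"{g.gene_id}.t1"
        lines.append(row(g.locus.sequence_id, "mRNA", g.locus,
                         f"ID={mid};Parent={g.gene_id}"))
        for i, ex in enumerate(g.exons, 1):
            lines.append(row(ex.sequence_id, "exon", ex,
                             f"ID={mid}.exon{i};Parent={mid}"))
        for i, c in enumerate(g.cds, 1):
            lines.append(row(c.sequence_id, "CDS", c,
                             f"ID={mid}.cds{i};Parent={mid}"))
    for e in elements:
        attrs = (f"ID={e.element_id};{ELEMENT_ATTR}=1;"
                 f"class_label={e.class_label};term_ids={','.join(sorted(e.term_ids))}")
        lines.append(row(e.locus.sequence_id, "repeat_region", e.locus, attrs))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_bed_elements(path) -> list[GagElement]:
    """Read elements from a 4-column BED sidecar (0-based half-open)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            seqid, start, end, name = line.split("\t")[:4]
            out.append(GagElement(element_id=name,
                                  locus=GenomicInterval(seqid, int(start), int(end))))
    return out


def write_bed_elements(elements: list[GagElement], path) -> None:
    with open(path, "w") as fh:
        for e in elements:
            fh.write(f"{e.locus.sequence_id}\t{e.locus.start}\t{e.locus.end}"
                     f"\t{e.element_id}\n")


# ---------------------------------------------------------------------------
# TSV matrices
# ---------------------------------------------------------------------------

def read_expression_tsv(matrix_path, groups_path, ripening_group: str) -> ExpressionMatrix:
    """Read an FPKM matrix TSV (first column = feature IDs, header = samples)
    plus a 2-column sample->group TSV."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    groups_df = pd.read_csv(groups_path, sep="\t", index_col=0)
    sample_groups = groups_df.iloc[:, 0].to_dict()
    return ExpressionMatrix(values=values, sample_groups=sample_groups,
                            ripening_group=ripening_group)


def write_expression_tsv(matrix: ExpressionMatrix, matrix_path, groups_path) -> None:
    matrix.values.to_csv(matrix_path, sep="\t", index_label="feature_id")
    pd.Series(matrix.sample_groups, name="group").loc[matrix.sample_ids].to_csv(
        groups_path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def write_newick(tree: TreeNode) -> str:
    """Serialize a tree (e.g. a clustering dendrogram) as a Newick string."""
    names = [t.name for t in tree.tips()] or [tree.name]
    if len(names) != len(set(names)):
        raise ValueError("duplicate leaf labels")
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def read_newick(text: str) -> TreeNode:
    return TreeNode.read(io.StringIO(text), format="newick")
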