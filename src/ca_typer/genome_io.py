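"""Genome intake: annotated-genome readers, the uniform gene data model, writers.

Every downstream stage (domain scanning, linker reannotation, synteny,
CA-type assignment) consumes the :class:`GenomeRecord` / :class:`GeneFeature`
model built here.  Coordinates are stored 1-based inclusive (GenBank
convention); GFF3 input already uses that convention and passes through.
Compound (joined) locations are collapsed to min-start/max-end and flagged,
since downstream synteny only needs gene order.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .config import DEFAULT_TAG_REGEX

log = logging.getLogger(__name__)


class GenomeFormatError(ValueError):
    """Raised when an input file does not parse under the named standard."""


@dataclass
class GeneFeature:
    """A protein-coding gene, strand-aware, 1-based inclusive coordinates."""

    locus_tag: str
    contig_id: str
    start: int            # 1-based, inclusive
    end: int              # 1-based, inclusive, >= start
    strand: str           # "+" or "-"
    product_label: str = ""
    protein_seq: str = ""
    compound: bool = False  # collapsed from a joined location

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.locus_tag}: strand must be '+' or '-'")
        if self.end < self.start:
            raise ValueError(f"{self.locus_tag}: end < start")
        if self.end - self.start + 1 < 3:
            raise ValueError(f"{self.locus_tag}: span shorter than one codon")

    @property
    def length_nt(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomeRecord:
    """A genome: ordered contigs plus its annotated coding genes."""

    genome_id: str
    organism_name: str = ""
    contigs: list[tuple[str, str]] = field(default_factory=list)
    genes: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        contig_ids = [c for c, _ in self.contigs]
        if len(set(contig_ids)) != len(contig_ids):
            raise ValueError(f"{self.genome_id}: duplicate contig ids")
        lengths = {c: len(s) for c, s in self.contigs}
        tags = set()
        for g in self.genes:
            if g.locus_tag in tags:
                raise ValueError(f"{self.genome_id}: duplicate locus_tag {g.locus_tag}")
            tags.add(g.locus_tag)
            if g.contig_id not in lengths:
                raise ValueError(f"{g.locus_tag}: unknown contig {g.contig_id}")
            if not (1 <= g.start <= g.end <= lengths[g.contig_id]):
                raise ValueError(f"{g.locus_tag}: coordinates outside contig")

    def sort_genes(self) -> None:
        self.genes.sort(key=lambda g: (g.contig_id, g.start))

    def contig_seq(self, contig_id: str) -> str:
        for c, s in self.contigs:
            if c == contig_id:
                return s
        raise KeyError(contig_id)

    def genes_on(self, contig_id: str) -> list[GeneFeature]:
        return [g for g in self.genes if g.contig_id == contig_id]

    @property
    def proteins(self) -> dict[str, str]:
        return {g.locus_tag: g.protein_seq for g in self.genes}


@dataclass
class ProteinSet:
    """Locus-tag keyed amino-acid sequences for one genome."""

    genome_id: str
    proteins: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.proteins)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _feature_locus_tag(feat: SeqFeature, idx: int) -> str:
    q = feat.qualifiers
    for key in ("locus_tag", "gene", "protein_id"):
        if key in q and q[key]:
            return q[key][0]
    return f"cds_{idx:04d}"


def _translate_cds(nt: str) -> str:
    prot = str(Seq(nt).translate(table=11, to_stop=False))
    return prot.rstrip("*")


def read_genome(path: str | Path, format: str = "genbank") -> GenomeRecord:
    """Read an annotated genome (GenBank flat file or GFF3+FASTA pair).

    For ``format="gff3"`` *path* is the GFF3 file; the genomic FASTA is
    looked up next to it (same stem, ``.fna``/``.fasta``/``.fa``) unless the
    GFF3 embeds ``##FASTA``.  Coordinates are normalized to 1-based
    inclusive; genes come back sorted by (contig_id, start).
    """
    path = Path(path)
    if format in ("genbank", "gb", "gbk"):
        return _read_genbank(path)
    if format in ("gff3", "gff"):
        return _read_gff3(path)
    raise ValueError(f"unknown format {format!r}")


def _read_genbank(path: Path) -> GenomeRecord:
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # Biopython raises assorted ValueErrors
        raise GenomeFormatError(f"{path}: not parseable as GenBank: {exc}") from exc
    if not records:
        raise GenomeFormatError(f"{path}: no GenBank records found")
    contigs: list[tuple[str, str]] = []
    genes: list[GeneFeature] = []
    organism = ""
    idx = 0
    for rec in records:
        contigs.append((rec.id, str(rec.seq).upper()))
        organism = organism or rec.annotations.get("organism", "")
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            idx += 1
            tag = _feature_locus_tag(feat, idx)
            loc = feat.location
            start = int(loc.start) + 1  # Biopython is 0-based half-open
            end = int(loc.end)
            compound = len(getattr(loc, "parts", [loc])) > 1
            strand = "-" if loc.strand == -1 else "+"
            prot = feat.qualifiers.get("translation", [""])[0]
            if not prot:
                nt = str(feat.extract(rec.seq))
                if len(nt) < 3:
                    raise GenomeFormatError(
                        f"{path}: CDS {tag} has no translation and no translatable span"
                    )
                prot = _translate_cds(nt)
            if not prot:
                raise GenomeFormatError(f"{path}: CDS {tag} translates to empty protein")
            genes.append(
                GeneFeature(
                    locus_tag=tag,
                    contig_id=rec.id,
                    start=start,
                    end=end,
                    strand=strand,
                    product_label=feat.qualifiers.get("product", [""])[0],
                    protein_seq=prot.upper().rstrip("*"),
                    compound=compound,
                )
            )
    genome_id = path.stem
    rec = GenomeRecord(genome_id=genome_id, organism_name=organism, contigs=contigs, genes=genes)
    rec.sort_genes()
    return rec


def _gff3_attributes(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def _read_gff3(path: Path) -> GenomeRecord:
    fasta_seqs: dict[str, str] = {}
    rows: list[tuple[str, int, int, str, dict[str, str]]] = []
    fasta_mode = False
    fasta_lines: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if fasta_mode:
                fasta_lines.append(line)
                continue
            if line.startswith("##FASTA"):
                fasta_mode = True
                continue
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GenomeFormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
            if cols[2] != "CDS":
                continue
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError as exc:
                raise GenomeFormatError(f"{path}:{lineno}: bad coordinates") from exc
            rows.append((cols[0], start, end, cols[6], _gff3_attributes(cols[8])))
    if fasta_lines:
        from io import StringIO

        for rec in SeqIO.parse(StringIO("\n".join(fasta_lines)), "fasta"):
            fasta_seqs[rec.id] = str(rec.seq).upper()
    else:
        for ext in (".fna", ".fasta", ".fa"):
            cand = path.with_suffix(ext)
            if cand.exists():
                for rec in SeqIO.parse(str(cand), "fasta"):
                    fasta_seqs[rec.id] = str(rec.seq).upper()
                break
        else:
            raise GenomeFormatError(f"{path}: no genomic FASTA found alongside GFF3")

    # merge multi-row CDS (same ID) to min-start/max-end
    merged: dict[str, list] = {}
    order: list[str] = []
    for i, (contig, start, end, strand, attrs) in enumerate(rows):
        key = attrs.get("ID", f"row{i}")
        if key in merged:
            m = merged[key]
            m[1] = min(m[1], start)
            m[2] = max(m[2], end)
            m[5] = True
        else:
            merged[key] = [contig, start, end, strand, attrs, False]
            order.append(key)

    genes = []
    for idx, key in enumerate(order, 1):
        contig, start, end, strand, attrs, compound = merged[key]
        tag = attrs.get("locus_tag") or attrs.get("Name") or attrs.get("ID") or f"cds_{idx:04d}"
        if contig not in fasta_seqs:
            raise GenomeFormatError(f"{path}: CDS {tag} references unknown contig {contig}")
        nt = fasta_seqs[contig][start - 1 : end]
        if strand == "-":
            nt = str(Seq(nt).reverse_complement())
        prot = attrs.get("translation") or _translate_cds(nt)
        if not prot:
            raise GenomeFormatError(f"{path}: CDS {tag} has no translatable sequence")
        genes.append(
            GeneFeature(
                locus_tag=tag,
                contig_id=contig,
                start=start,
                end=end,
                strand="-" if strand == "-" else "+",
                product_label=attrs.get("product", ""),
                protein_seq=prot.upper().rstrip("*"),
                compound=compound,
            )
        )
    rec = GenomeRecord(
        genome_id=path.stem,
        contigs=[(c, s) for c, s in fasta_seqs.items()],
        genes=genes,
    )
    rec.sort_genes()
    return rec


def read_proteins(path: str | Path, tag_regex: str = DEFAULT_TAG_REGEX) -> ProteinSet:
    """Read a protein FASTA keyed by locus tags extracted from headers."""
    path = Path(path)
    pat = re.compile(tag_regex)
    proteins: dict[str, str] = {}
    n = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n += 1
        m = pat.search(rec.description if not pat.match(rec.id) else rec.id)
        tag = m.group(1) if m and m.groups() else rec.id
        if tag in proteins:
            raise ValueError(f"{path}: duplicate locus tag {tag}")
        seq = str(rec.seq).upper().rstrip("*")
        nuc_frac = sum(seq.count(c) for c in "ACGTN") / max(len(seq), 1)
        if len(seq) >= 20 and nuc_frac >= 0.95:
            log.warning("%s: record %s looks nucleotide (%.0f%% ACGTN); kept", path, tag, 100 * nuc_frac)
        proteins[tag] = seq
    if n == 0:
        log.warning("%s: empty protein FASTA", path)
    return ProteinSet(genome_id=path.stem, proteins=proteins)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_genome(genome: GenomeRecord, out_dir: str | Path) -> tuple[Path, Path]:
    """Write the canonical pair: GFF3 (+embedded FASTA) and a protein FASTA.

    Returns (gff3_path, faa_path).  ``read_genome(gff3, format="gff3")``
    round-trips the data model field-for-field (modulo product free text the
    GFF3 dialect cannot carry, which we do carry via ``product=``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gff = out_dir / f"{genome.genome_id}.gff3"
    faa = out_dir / f"{genome.genome_id}.faa"
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for contig, seq in genome.contigs:
            fh.write(f"##sequence-region {contig} 1 {len(seq)}\n")
        for g in genome.genes:
            attrs = f"ID={g.locus_tag};locus_tag={g.locus_tag}"
            if g.product_label:
                attrs += f";product={g.product_label}"
            attrs += f";translation={g.protein_seq}"
            fh.write(
                "\t".join(
                    [g.contig_id, "ca_typer", "CDS", str(g.start), str(g.end), ".", g.strand, "0", attrs]
                )
                + "\n"
            )
        fh.write("##FASTA\n")
        for contig, seq in genome.contigs:
            fh.write(f">{contig}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    with open(faa, "w") as fh:
        for g in genome.genes:
            fh.write(f">{g.locus_tag} {g.product_label}\n{g.protein_seq}\n")
    return gff, faa


def write_genbank(genome: GenomeRecord, path: str | Path) -> Path:
    """Write the genome as a multi-record GenBank flat file."""
    path = Path(path)
    records = []
    for contig, seq in genome.contigs:
        rec = SeqRecord(Seq(seq), id=contig, name=contig[:16], description=genome.organism_name)
        rec.annotations["molecule_type"] = "DNA"
        rec.annotations["organism"] = genome.organism_name
        for g in genome.genes_on(contig):
            feat = SeqFeature(
                FeatureLocation(g.start - 1, g.end, strand=1 if g.strand == "+" else -1),
                type="CDS",
                qualifiers={
                    "locus_tag": [g.locus_tag],
                    "product": [g.product_label or "hypothetical protein"],
                    "transl_table": ["11"],
                    "translation": [g.protein_seq],
                },
            )
            rec.features.append(feat)
        records.append(rec)
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "genbank")
    return path


def read_genome_dir(in_dir: str | Path) -> Iterator[GenomeRecord]:
    """Yield genomes from a directory of .gbk/.gb/.gbff or .gff3 files.

    When a genome is present in both formats (same stem), the GenBank copy
    wins so each genome is yielded once.
    """
    in_dir = Path(in_dir)
    seen: set[str] = set()
    paths = sorted(in_dir.iterdir(), key=lambda p: (p.suffix not in (".gb", ".gbk", ".gbff"), p.name))
    for p in paths:
        if p.stem in seen:
            continue
        if p.suffix in (".gb", ".gbk", ".gbff"):
            seen.add(p.stem)
            yield read_genome(p, "genbank")
        elif p.suffix in (".gff3", ".gff"):
            seen.add(p.stem)
            yield read_genome(p, "gff3")
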