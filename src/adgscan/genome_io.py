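"""Annotated-genome reading, gene models and upstream-region extraction.

Coordinates are 0-based half-open internally; GenBank's 1-based inclusive
intervals are converted at the boundary. A gene on a circular genome may
wrap the origin, in which case ``start > end`` and the gene occupies
``[start, length) + [0, end)``.

Promoters in this system are directional, so upstream windows are always
returned on the coding strand (reverse-complemented for minus-strand genes)
and no reverse-strand scanning is performed downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class EmptyAnnotationError(ValueError):
    """Raised when a genome file contains no CDS features."""


class GenomeParseError(ValueError):
    """Raised when a genome file cannot be parsed in the declared format."""


@dataclass
class GeneRecord:
    """One annotated CDS with genome coordinates (0-based half-open)."""

    gene_id: str
    start: int
    end: int
    strand: str  # "+" or "-"
    product: str = ""
    protein_seq: str | None = None
    locus_class: str = "unset"  # single | operon_lead | operon_internal | unset

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.protein_seq is not None and len(self.protein_seq) < 1:
            raise ValueError("protein_seq must have length >= 1 when present")

    @property
    def wraps(self) -> bool:
        return self.start > self.end


@dataclass
class UpstreamRegion:
    """Coding-strand sequence of the window immediately 5' of a start codon."""

    gene_id: str
    sequence: str
    truncated: bool = False
    genome_id: str = ""

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class Genome:
    id: str
    sequence: str
    topology: str = "linear"  # linear | circular
    genes: list[GeneRecord] = field(default_factory=list)
    source_format: str = "synthetic"  # genbank | gff3+fasta | synthetic

    def __post_init__(self):
        if not self.id:
            raise ValueError("genome id must be nonempty")
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"unknown topology {self.topology!r}")
        self.genes.sort(key=lambda g: (g.start, g.end))
        n = len(self)
        for g in self.genes:
            if g.wraps and self.topology != "circular":
                raise ValueError(
                    f"gene {g.gene_id} wraps the origin of a linear genome"
                )
            if not (0 <= g.start < n and 0 < g.end <= n):
                raise ValueError(
                    f"gene {g.gene_id} coordinates outside [0, {n})"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def gene(self, gene_id: str) -> GeneRecord:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(f"gene {gene_id!r} not found in genome {self.id}")

    def fetch(self, start: int, end: int) -> str:
        """Genome substring; wraps around the origin for circular genomes.

        For linear genomes, out-of-range positions are clipped.
        """
        n = len(self)
        if self.topology == "circular":
            length = end - start
            if length < 0 or length > n:
                raise ValueError("requested window longer than the genome")
            start %= n
            doubled = self.sequence + self.sequence
            return doubled[start : start + length]
        return self.sequence[max(start, 0) : min(end, n)]

    def gene_sequence(self, gene: GeneRecord) -> str:
        """Coding-strand sequence of a gene (handles origin wrap)."""
        if gene.wraps:
            raw = self.sequence[gene.start :] + self.sequence[: gene.end]
        else:
            raw = self.sequence[gene.start : gene.end]
        return revcomp(raw) if gene.strand == "-" else raw


# ---------------------------------------------------------------------------
# Readers


def read_genome(path, format: str = "genbank", fasta_path=None,
                topology: str | None = None) -> Genome:
    """Read an annotated genome.

    Parameters
    ----------
    path : str or Path
        GenBank flat file, or GFF3 file when ``format="gff3"``.
    format : {"genbank", "gff3"}
    fasta_path : str or Path, required for GFF3 input
        FASTA file with the genome sequence.
    topology : optional override ("linear"/"circular"); GFF3 input defaults
        to linear because GFF3 carries no topology flag.
    """
    if format == "genbank":
        return _read_genbank(path, topology)
    if format in ("gff3", "gff3+fasta"):
        if fasta_path is None:
            raise ValueError("GFF3 input requires fasta_path")
        return _read_gff3(path, fasta_path, topology or "linear")
    raise ValueError(f"unknown format {format!r}")


def _feature_gene_id(feature, idx: int) -> str:
    for key in ("locus_tag", "protein_id", "gene"):
        if key in feature.qualifiers:
            return feature.qualifiers[key][0]
    return f"cds_{idx}"


def _read_genbank(path, topology: str | None) -> Genome:
    try:
        record = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # noqa: BLE001 - surface parser context
        raise GenomeParseError(f"cannot parse {path} as GenBank: {exc}") from exc
    topo = topology or record.annotations.get("topology", "linear")
    seq = str(record.seq).upper()
    genes = []
    for idx, feature in enumerate(record.features):
        if feature.type != "CDS":
            continue
        loc = feature.location
        strand = "-" if loc.strand == -1 else "+"
        start, end = int(loc.start), int(loc.end)
        parts = sorted(loc.parts, key=lambda p: int(p.start))
        if len(parts) > 1 and int(parts[-1].end) == len(seq) and int(parts[0].start) == 0:
            # CDS joined across the origin of a circular genome
            start, end = int(parts[1].start), int(parts[0].end)
        protein = feature.qualifiers.get("translation", [None])[0]
        genes.append(
            GeneRecord(
                gene_id=_feature_gene_id(feature, idx),
                start=start,
                end=end,
                strand=strand,
                product=feature.qualifiers.get("product", [""])[0],
                protein_seq=protein,
            )
        )
    if not genes:
        raise EmptyAnnotationError(f"{path}: no CDS features found")
    genome = Genome(
        id=record.id or record.name,
        sequence=seq,
        topology=topo,
        genes=genes,
        source_format="genbank",
    )
    _fill_translations(genome)
    return genome


def _read_gff3(gff_path, fasta_path, topology: str) -> Genome:
    import gffutils

    try:
        record = SeqIO.read(str(fasta_path), "fasta")
    except Exception as exc:  # noqa: BLE001
        raise GenomeParseError(f"cannot parse {fasta_path} as FASTA: {exc}") from exc
    try:
        db = gffutils.create_db(
            str(gff_path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # noqa: BLE001
        raise GenomeParseError(f"cannot parse {gff_path} as GFF3: {exc}") from exc
    genes = []
    for idx, feat in enumerate(db.features_of_type("CDS", order_by="start")):
        gene_id = (
            feat.attributes.get("ID", [None])[0]
            or feat.attributes.get("locus_tag", [None])[0]
            or f"cds_{idx}"
        )
        genes.append(
            GeneRecord(
                gene_id=gene_id,
                start=feat.start - 1,  # GFF3 is 1-based inclusive
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else "+",
                product=feat.attributes.get("product", [""])[0],
            )
        )
    if not genes:
        raise EmptyAnnotationError(f"{gff_path}: no CDS features found")
    genome = Genome(
        id=record.id,
        sequence=str(record.seq).upper(),
        topology=topology,
        genes=genes,
        source_format="gff3+fasta",
    )
    _fill_translations(genome)
    return genome


def _fill_translations(genome: Genome):
    """Derive missing protein sequences from the nucleotide sequence."""
    for g in genome.genes:
        if g.protein_seq:
            continue
        cds = genome.gene_sequence(g)
        if len(cds) < 6 or len(cds) % 3:
            continue
        aa = str(Seq(cds).translate(table=11))
        g.protein_seq = aa[:-1] if aa.endswith("*") else aa


# ---------------------------------------------------------------------------
# Locus classification


def classify_loci(
    genome: Genome, max_gap: int = 30, require_same_strand: bool = True
) -> Genome:
    """Label every gene single / operon_lead / operon_internal (in place).

    A gene is operon_internal iff its transcriptionally upstream neighbour
    (previous gene in coordinate order for "+", next for "-") lies on the
    same strand with an intergenic gap of at most ``max_gap`` nt. The 5'-most
    gene of each such run is the operon_lead; everything else is single.
    """
    if genome.topology not in ("linear", "circular"):
        raise ValueError("genome topology must be set before locus classification")
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    genes = genome.genes
    n = len(genes)
    L = len(genome)
    circular = genome.topology == "circular"

    def upstream_neighbor(i: int):
        g = genes[i]
        if g.strand == "+":
            if i > 0:
                return i - 1
            return n - 1 if circular and n > 1 else None
        if i < n - 1:
            return i + 1
        return 0 if circular and n > 1 else None

    def gap_to(i: int, j: int) -> int:
        """Intergenic gap between gene i and its upstream neighbour j."""
        g, u = genes[i], genes[j]
        if g.strand == "+":
            gap = g.start - u.end
        else:
            gap = u.start - g.end
        if circular:
            gap %= L
        return gap

    internal = [False] * n
    upstream_of = [None] * n
    for i, g in enumerate(genes):
        j = upstream_neighbor(i)
        if j is None or j == i:
            continue
        if require_same_strand and genes[j].strand != g.strand:
            continue
        if gap_to(i, j) <= max_gap:
            internal[i] = True
            upstream_of[i] = j

    leads = set()
    for i in range(n):
        if internal[i] and not internal[upstream_of[i]]:
            leads.add(upstream_of[i])
    for i, g in enumerate(genes):
        if internal[i]:
            g.locus_class = "operon_internal"
        elif i in leads:
            g.locus_class = "operon_lead"
        else:
            g.locus_class = "single"
    return genome


# ---------------------------------------------------------------------------
# Upstream windows


def upstream_interval(genome: Genome, gene: GeneRecord, L_up: int):
    """Genome interval of the upstream window, before clipping.

    Returns (start, end) on the genome's forward strand; for circular
    genomes the interval may run past the ends and should be fetched with
    :meth:`Genome.fetch`.
    """
    if gene.strand == "+":
        return gene.start - L_up, gene.start
    return gene.end, gene.end + L_up


def extract_upstream(genome: Genome, gene: GeneRecord, L_up: int = 100) -> UpstreamRegion:
    """The ``L_up`` bases immediately 5' of the start codon, coding strand.

    Truncates at the ends of linear genomes; wraps across the origin of
    circular genomes.
    """
    if L_up < 1:
        raise ValueError("L_up must be >= 1")
    if gene not in genome.genes:
        # allow lookup by id so callers can pass detached records
        try:
            gene = genome.gene(gene.gene_id)
        except KeyError as exc:
            raise KeyError(f"gene not in genome {genome.id}") from exc
    start, end = upstream_interval(genome, gene, L_up)
    raw = genome.fetch(start, end)
    seq = revcomp(raw) if gene.strand == "-" else raw
    truncated = genome.topology == "linear" and len(seq) < L_up
    return UpstreamRegion(
        gene_id=gene.gene_id, sequence=seq, truncated=truncated, genome_id=genome.id
    )


def usable_upstream_regions(
    genome: Genome, L_up: int = 100, max_n_fraction: float = 0.10
) -> list[UpstreamRegion]:
    """Upstream regions of single / operon-lead genes, excluding windows with
    more than ``max_n_fraction`` ambiguous bases."""
    regions = []
    for g in genome.genes:
        if g.locus_class not in ("single", "operon_lead"):
            continue
        r = extract_upstream(genome, g, L_up)
        if r.length == 0:
            continue
        n_frac = r.sequence.count("N") / r.length
        if n_frac > max_n_fraction:
            continue
        regions.append(r)
    return regions


# ---------------------------------------------------------------------------
# Writers


def write_upstream_fasta(genome: Genome, regions, L_up: int, path):
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f">{genome.id}|{r.gene_id}|upstream{L_up}\n{r.sequence}\n")


def write_upstream_bed(genome: Genome, genes, L_up: int, path):
    """BED6 of upstream windows in genome coordinates (linear clipping)."""
    with open(path, "w") as fh:
        for g in genes:
            start, end = upstream_interval(genome, g, L_up)
            start, end = max(start, 0), min(end, len(genome))
            if end <= start:
                continue
            fh.write(
                f"{genome.id}\t{start}\t{end}\t{g.gene_id}_upstream\t0\t{g.strand}\n"
            )


def write_genbank(genome: Genome, path):
    record = SeqRecord(
        Seq(genome.sequence),
        id=genome.id,
        name=genome.id[:16].replace("|", "_"),
        description="",
        annotations={
            "molecule_type": "DNA",
            "topology": genome.topology,
        },
    )
    for g in genome.genes:
        qualifiers = {"locus_tag": [g.gene_id]}
        if g.product:
            qualifiers["product"] = [g.product]
        if g.protein_seq:
            qualifiers["translation"] = [g.protein_seq]
        feature = SeqFeature(
            FeatureLocation(g.start, g.end, strand=1 if g.strand == "+" else -1),
            type="CDS",
            qualifiers=qualifiers,
        )
        record.features.append(feature)
    SeqIO.write([record], str(path), "genbank")


def write_gff3_fasta(genome: Genome, gff_path, fasta_path):
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {len(genome)}\n")
        for g in genome.genes:
            attrs = f"ID={g.gene_id}"
            if g.product:
                attrs += f";product={g.product}"
            fh.write(
                f"{genome.id}\tadgscan\tCDS\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t0\t{attrs}\n"
            )
    with open(fasta_path, "w") as fh:
        fh.write(f">{genome.id}\n")
        seq = genome.sequence
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")
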