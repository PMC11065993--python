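"""Dual-criteria anti-defense gene (ADG) calling.

A gene is called an ADG when it satisfies both criteria: (1) its regulatory
occurrence contains a predicted strong promoter (TATA-box plus purine-rich
BRE), and (2) it shares that regulatory sequence with at least ``min_shared``
genes of the same genome. A gene may satisfy the motif criterion either
through a significant discovery site (site p-value below the threshold) or
through a significant scan hit (e-value below the threshold).

Genes failing exactly one criterion, and genes caught by the enumerated
low-probability rules (core-protein product, promoter too close to the
start codon, co-transcribed downstream of an ADG), are kept on a separate
low-probability list rather than counted as ADGs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome_io import Genome, GeneRecord
from .matrix_scan import MotifHit
from .motif_discovery import MotifResult
from .promoter_core import (
    TATA_WIDTH,
    PromoterCall,
    call_promoter,
    classify_motif,
)

DEFAULT_CORE_KEYWORDS = (
    "capsid",
    "coat protein",
    "polymerase",
    "terminase",
    "portal",
    "integrase",
    "glycosyltransferase",
    "holliday junction",
    "structural protein",
    "virion",
    "tail",
)

START_CODONS = ("ATG", "GTG", "TTG")


@dataclass
class PipelineConfig:
    """All numeric thresholds of the pipeline, echoed into every report."""

    L_up: int = 100
    w_min: int = 30
    w_max: int = 100
    n_motifs: int = 3
    site_p_threshold: float = 1e-8
    e_threshold: float = 1e-8
    min_shared: int = 3
    max_mm: int = 1
    purine_min: float = 2.0 / 3.0
    max_gap: int = 30
    min_tss_gap: int = 10
    min_sequences: int = 5
    family_evalue: float = 1e-3
    host_screen_evalue: float = 1e-10
    small_protein_max: int = 150
    viral_context_min_hits: int = 5
    core_keywords: tuple = DEFAULT_CORE_KEYWORDS
    pseudocount: float = 0.25
    granularity: float = 1e-3

    def __post_init__(self):
        for name in (
            "site_p_threshold", "e_threshold", "family_evalue",
            "host_screen_evalue", "purine_min",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def as_dict(self) -> dict:
        d = dict(self.__dict__)
        d["core_keywords"] = list(self.core_keywords)
        return d


@dataclass
class ADGCall:
    genome_id: str
    gene_id: str
    status: str  # adg | low_probability | negative
    motif_id: str | None = None
    hit: MotifHit | None = None
    promoter: PromoterCall | None = None
    reasons: list = field(default_factory=list)
    site_offset: int | None = None
    site_seq: str | None = None
    site_p_value: float | None = None
    region_length: int | None = None
    reannotated_start: int | None = None


def _gene_evidence(motifs: list[MotifResult], hits: list[MotifHit], config):
    """Per gene: list of motif-occurrence evidence from discovery sites and
    passing scan hits; plus the set of passing genes per motif."""
    evidence: dict[str, list[dict]] = {}
    passing_genes: dict[str, set[str]] = {}
    for m in motifs:
        for s in m.sites:  # retained sites already satisfy the p threshold
            evidence.setdefault(s.region_id, []).append(
                {
                    "motif_id": m.pwm.motif_id,
                    "offset": s.offset,
                    "seq": s.sequence,
                    "p_value": s.p_value,
                    "hit": None,
                    "region_length": None,
                }
            )
            passing_genes.setdefault(m.pwm.motif_id, set()).add(s.region_id)
    for h in hits:
        if not h.passed:
            continue
        evidence.setdefault(h.gene_id, []).append(
            {
                "motif_id": h.motif_id,
                "offset": h.offset,
                "seq": h.site_seq,
                "p_value": h.p_value,
                "hit": h,
                "region_length": h.region_length,
            }
        )
        passing_genes.setdefault(h.motif_id, set()).add(h.gene_id)
    return evidence, passing_genes


def call_adgs(
    genome: Genome,
    motifs: list[MotifResult],
    hits: list[MotifHit],
    config: PipelineConfig | None = None,
) -> list[ADGCall]:
    """Emit one call per gene, applying the dual ADG criteria."""
    config = config or PipelineConfig()
    for h in hits:
        if h.genome_id and h.genome_id != genome.id:
            raise ValueError(
                f"hit for genome {h.genome_id} passed with genome {genome.id}"
            )
    strong_motif = {
        m.pwm.motif_id: classify_motif(m, config.max_mm, config.purine_min)
        for m in motifs
    }
    evidence, passing_genes = _gene_evidence(motifs, hits, config)
    best_hit_by_gene: dict[str, MotifHit] = {}
    for h in hits:
        cur = best_hit_by_gene.get(h.gene_id)
        if cur is None or h.p_value < cur.p_value:
            best_hit_by_gene[h.gene_id] = h

    calls = []
    for gene in genome.genes:
        evs = evidence.get(gene.gene_id, [])
        if not evs:
            calls.append(
                ADGCall(genome_id=genome.id, gene_id=gene.gene_id, status="negative")
            )
            continue

        def rank(ev):
            ok_strong = strong_motif.get(ev["motif_id"], False)
            ok_shared = len(passing_genes.get(ev["motif_id"], ())) >= config.min_shared
            return (not (ok_strong and ok_shared), ev["p_value"])

        ev = min(evs, key=rank)
        promoter = call_promoter(ev["seq"], config.max_mm, config.purine_min)
        reasons = []
        motif_is_strong = strong_motif.get(ev["motif_id"], False)
        site_is_strong = promoter is not None and promoter.is_strong
        if not (motif_is_strong and site_is_strong):
            reasons.append("no_strong_promoter")
        if len(passing_genes.get(ev["motif_id"], ())) < config.min_shared:
            reasons.append("motif_not_shared")
        status = "adg" if not reasons else "low_probability"
        calls.append(
            ADGCall(
                genome_id=genome.id,
                gene_id=gene.gene_id,
                status=status,
                motif_id=ev["motif_id"],
                hit=ev["hit"] or best_hit_by_gene.get(gene.gene_id),
                promoter=promoter,
                reasons=reasons,
                site_offset=ev["offset"],
                site_seq=ev["seq"],
                site_p_value=ev["p_value"],
                region_length=ev["region_length"]
                or (ev["hit"].region_length if ev["hit"] else config.L_up),
            )
        )
    return calls


def flag_low_probability(
    calls: list[ADGCall], genome: Genome, config: PipelineConfig | None = None
) -> list[ADGCall]:
    """Apply the low-probability demotion/addition rules (in place).

    - core_protein: ADG whose product matches a configured core-gene keyword.
    - tss_too_close: ADG whose TATA-box 3' end lies within ``min_tss_gap`` nt
      of the start codon, so the likely transcription start site falls at or
      inside the coding sequence.
    - downstream_in_operon: operon-internal gene co-transcribed behind an
      ADG operon lead.
    """
    config = config or PipelineConfig()
    by_id = {c.gene_id: c for c in calls}

    for gene in genome.genes:
        c = by_id.get(gene.gene_id)
        if c is None or c.status != "adg":
            continue
        product = (gene.product or "").lower()
        if any(k in product for k in config.core_keywords):
            c.status = "low_probability"
            c.reasons.append("core_protein")
            continue
        if c.promoter is not None and c.region_length:
            tata_end = c.site_offset + c.promoter.tata_offset + TATA_WIDTH
            gap_to_start = c.region_length - tata_end
            if gap_to_start < config.min_tss_gap:
                c.status = "low_probability"
                c.reasons.append("tss_too_close")

    adg_leads = {
        c.gene_id
        for c in calls
        if c.status == "adg"
        and genome.gene(c.gene_id).locus_class == "operon_lead"
    }
    for gene, lead_id in _operon_members(genome).items():
        if lead_id in adg_leads:
            c = by_id.get(gene)
            if c is not None and c.status == "negative":
                c.status = "low_probability"
                c.reasons.append("downstream_in_operon")
    return calls


def _operon_members(genome: Genome) -> dict[str, str]:
    """Map each operon_internal gene id to its operon lead's gene id."""
    out: dict[str, str] = {}
    genes = genome.genes
    # plus-strand operons run left to right
    lead = None
    for g in genes:
        if g.strand != "+":
            lead = None
            continue
        if g.locus_class == "operon_lead":
            lead = g.gene_id
        elif g.locus_class == "operon_internal" and lead is not None:
            out[g.gene_id] = lead
        else:
            lead = None
    # minus-strand operons run right to left
    lead = None
    for g in reversed(genes):
        if g.strand != "-":
            lead = None
            continue
        if g.locus_class == "operon_lead":
            lead = g.gene_id
        elif g.locus_class == "operon_internal" and lead is not None:
            out[g.gene_id] = lead
        else:
            lead = None
    return out


@dataclass
class StartReannotation:
    shift_nt: int  # in-frame distance from the annotated start, coding coords
    new_start: int  # genome offset of the new 5' boundary
    new_end: int
    new_protein_length: int  # aa, excluding the stop codon


def reannotate_start(
    genome: Genome,
    gene: GeneRecord,
    hit: MotifHit | None = None,
    config: PipelineConfig | None = None,
    *,
    motif_end_local: int | None = None,
    window_into_gene: int = 0,
) -> StartReannotation | None:
    """Move a start codon downstream when the promoter lies inside the ORF.

    ``motif_end_local`` is the coding-strand position within the gene of the
    first base after the motif occurrence; when a ``hit`` from a scan window
    whose 3' end extends ``window_into_gene`` nt into the gene is supplied,
    it is derived from the hit. Returns the first in-frame ATG/GTG/TTG start
    at or after that position, provided no more than half of the ORF is
    consumed; otherwise None. A promoter entirely upstream of the annotated
    start returns None (no change).
    """
    config = config or PipelineConfig()
    if motif_end_local is None:
        if hit is None:
            raise ValueError("need either a hit or motif_end_local")
        width = len(hit.site_seq)
        motif_end_local = hit.offset + width - (hit.region_length - window_into_gene)
    if motif_end_local <= 0:
        return None
    cds = genome.gene_sequence(gene)
    orf_len = len(cds)
    d = motif_end_local + (-motif_end_local) % 3  # first in-frame codon boundary
    while d <= orf_len // 2:
        if cds[d : d + 3] in START_CODONS:
            if gene.strand == "+":
                new_start, new_end = gene.start + d, gene.end
            else:
                new_start, new_end = gene.start, gene.end - d
            return StartReannotation(
                shift_nt=d,
                new_start=new_start,
                new_end=new_end,
                new_protein_length=(orf_len - d) // 3 - 1,
            )
        d += 3
    return None


def write_calls_tsv(calls: list[ADGCall], path):
    import pandas as pd

    rows = []
    for c in calls:
        rows.append(
            {
                "genome": c.genome_id,
                "gene": c.gene_id,
                "status": c.status,
                "reasons": ",".join(c.reasons),
                "motif": c.motif_id or "",
                "site_offset": c.site_offset,
                "site_p_value": c.site_p_value,
                "e_value": c.hit.e_value if c.hit else None,
                "tata_seq": c.promoter.tata_seq if c.promoter else "",
                "bre_seq": c.promoter.bre_seq if c.promoter else "",
                "promoter_strong": c.promoter.is_strong if c.promoter else False,
                "reannotated_start": c.reannotated_start,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
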