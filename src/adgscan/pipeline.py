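"""End-to-end orchestration: discover -> scan -> promoter -> call -> families.

Motif discovery is strictly per genome — regulatory sequences are conserved
among early genes of the same virus but diverge between viruses, so pooling
upstream sets across genomes would blur the virus-specific motifs. The only
cross-genome stage is protein-family clustering and the motif-prevalence
statistic.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field

from . import __version__
from .adg_caller import (
    ADGCall,
    PipelineConfig,
    call_adgs,
    flag_low_probability,
    write_calls_tsv,
)
from .genome_io import Genome, classify_loci, read_genome, usable_upstream_regions
from .matrix_scan import MotifHit, scan_regions, write_hits_tsv
from .motif_discovery import (
    DiscoveryConfig,
    DiscoveryError,
    MotifResult,
    discover_motifs,
)
from .motif_model import build_background, write_meme
from .protein_families import (
    PrevalenceRecord,
    ProteinFamily,
    ProteinRecord,
    cluster_families,
    motif_prevalence,
    pairwise_align,
    write_families_tsv,
    write_prevalence_tsv,
)


@dataclass
class GenomeResult:
    genome: Genome
    regions: list = field(default_factory=list)
    motifs: list[MotifResult] = field(default_factory=list)
    hits: list[MotifHit] = field(default_factory=list)
    calls: list[ADGCall] = field(default_factory=list)
    skipped_reason: str | None = None

    @property
    def adg_gene_ids(self) -> set[str]:
        return {c.gene_id for c in self.calls if c.status == "adg"}

    @property
    def motif_positive_gene_ids(self) -> set[str]:
        """Genes whose upstream region carries a significant motif occurrence."""
        return {c.gene_id for c in self.calls if c.motif_id is not None}


@dataclass
class RunManifest:
    config: dict
    inputs: dict  # genome id -> sha256 of sequence
    counts: dict  # per-genome and total stage counts
    version: str
    timestamp: str

    @property
    def checksum(self) -> str:
        payload = json.dumps(
            {"config": self.config, "inputs": self.inputs, "counts": self.counts},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()

    def to_json(self) -> str:
        d = dict(self.__dict__)
        d["checksum"] = self.checksum
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass
class PipelineResult:
    per_genome: list[GenomeResult]
    families: list[ProteinFamily]
    prevalence: list[PrevalenceRecord]
    manifest: RunManifest


def _discovery_config(config: PipelineConfig) -> DiscoveryConfig:
    return DiscoveryConfig(
        w_min=config.w_min,
        w_max=config.w_max,
        n_motifs=config.n_motifs,
        site_p_threshold=config.site_p_threshold,
        min_sequences=config.min_sequences,
        pseudocount=config.pseudocount,
        granularity=config.granularity,
    )


def analyze_genome(genome: Genome, config: PipelineConfig | None = None) -> GenomeResult:
    """Run all per-genome stages on one genome."""
    config = config or PipelineConfig()
    classify_loci(genome, max_gap=config.max_gap)
    regions = usable_upstream_regions(genome, L_up=config.L_up)
    result = GenomeResult(genome=genome, regions=regions)
    if len(regions) < config.min_sequences:
        result.skipped_reason = "too_few_regions"
        return result
    background = build_background(regions)
    try:
        motifs = discover_motifs(
            regions,
            _discovery_config(config),
            background,
            motif_prefix=genome.id,
        )
    except DiscoveryError:
        result.skipped_reason = "too_few_regions"
        return result
    result.motifs = motifs
    for m in motifs:
        result.hits.extend(
            scan_regions(
                m.pwm,
                regions,
                e_threshold=config.e_threshold,
                genome_id=genome.id,
                granularity=config.granularity,
            )
        )
    calls = call_adgs(genome, motifs, result.hits, config)
    result.calls = flag_low_probability(calls, genome, config)
    return result


def _adg_protein_records(per_genome: list[GenomeResult]) -> list[ProteinRecord]:
    records = []
    for gr in per_genome:
        for c in gr.calls:
            if c.status != "adg":
                continue
            gene = gr.genome.gene(c.gene_id)
            if gene.protein_seq:
                records.append(
                    ProteinRecord(
                        genome_id=gr.genome.id,
                        gene_id=gene.gene_id,
                        seq=gene.protein_seq,
                    )
                )
    return records


def family_prevalence(
    families: list[ProteinFamily],
    per_genome: list[GenomeResult],
    config: PipelineConfig,
) -> list[PrevalenceRecord]:
    """Motif prevalence per family, counting homologs genome-set-wide.

    Each family's longest member is aligned against every single/operon-lead
    gene product in the analyzed genomes; hits at the family e-value extend
    the homolog set beyond the ADG members themselves.
    """
    flags: dict[tuple[str, str], bool] = {}
    candidates: list[ProteinRecord] = []
    for gr in per_genome:
        positive = gr.motif_positive_gene_ids
        for g in gr.genome.genes:
            if g.locus_class not in ("single", "operon_lead") or not g.protein_seq:
                continue
            key = (gr.genome.id, g.gene_id)
            flags[key] = g.gene_id in positive
            candidates.append(
                ProteinRecord(genome_id=gr.genome.id, gene_id=g.gene_id,
                              seq=g.protein_seq)
            )
    records = []
    for fam in families:
        member_keys = {m.key for m in fam.members}
        rep = max(fam.members, key=lambda m: len(m.seq))
        extended = list(fam.members)
        for cand in candidates:
            if cand.key in member_keys:
                continue
            st = pairwise_align(rep.seq, cand.seq)
            if st.evalue_proxy <= config.family_evalue:
                extended.append(cand)
                member_keys.add(cand.key)
        ext_fam = ProteinFamily(family_id=fam.family_id, members=extended)
        records.append(motif_prevalence(ext_fam, flags))
    return records


def run_pipeline(
    genomes,
    config: PipelineConfig | None = None,
    outdir=None,
    compute_families: bool = True,
) -> PipelineResult:
    """Run the full pipeline over Genome objects or genome file paths.

    Per-genome stages never interact across genomes; a genome whose upstream
    set is too small is skipped with a recorded reason and the run continues.
    """
    config = config or PipelineConfig()
    loaded: list[Genome] = []
    for g in genomes:
        if isinstance(g, Genome):
            loaded.append(g)
        else:
            loaded.append(read_genome(g, format="genbank"))

    per_genome = [analyze_genome(g, config) for g in loaded]

    families: list[ProteinFamily] = []
    prevalence: list[PrevalenceRecord] = []
    if compute_families:
        records = _adg_protein_records(per_genome)
        if records:
            families = cluster_families(records, threshold_evalue=config.family_evalue)
            prevalence = family_prevalence(families, per_genome, config)

    counts = {"genomes": len(per_genome), "families": len(families), "per_genome": {}}
    for gr in per_genome:
        counts["per_genome"][gr.genome.id] = {
            "genes": len(gr.genome.genes),
            "regions": len(gr.regions),
            "motifs": len(gr.motifs),
            "hits_passed": sum(1 for h in gr.hits if h.passed),
            "adgs": len(gr.adg_gene_ids),
            "low_probability": sum(
                1 for c in gr.calls if c.status == "low_probability"
            ),
            "skipped": gr.skipped_reason or "",
        }
    manifest = RunManifest(
        config=config.as_dict(),
        inputs={
            g.id: hashlib.sha256(g.sequence.encode()).hexdigest() for g in loaded
        },
        counts=counts,
        version=__version__,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    result = PipelineResult(
        per_genome=per_genome,
        families=families,
        prevalence=prevalence,
        manifest=manifest,
    )
    if outdir is not None:
        _write_outputs(result, outdir, config)
    return result


def _write_outputs(result: PipelineResult, outdir, config: PipelineConfig):
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    all_calls, all_hits = [], []
    for gr in result.per_genome:
        all_calls.extend(gr.calls)
        all_hits.extend(gr.hits)
        if gr.motifs:
            write_meme(
                [m.pwm for m in gr.motifs], out / f"{gr.genome.id}.motifs.meme"
            )
    write_calls_tsv(all_calls, out / "calls.tsv")
    if all_hits:
        write_hits_tsv(all_hits, out / "hits.tsv")
    if result.families:
        write_families_tsv(result.families, out / "families.tsv")
    if result.prevalence:
        write_prevalence_tsv(result.prevalence, out / "prevalence.tsv")
    (out / "manifest.json").write_text(result.manifest.to_json())
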