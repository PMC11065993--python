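"""Protein-family clustering, motif prevalence and the antitoxin screen.

ADG proteins from different genomes are grouped into families by
single-linkage over significant pairwise local alignments (Smith-Waterman,
BLOSUM62, BLAST-style gap existence 11 / extension 1). Pair significance is
a Karlin-Altschul e-value computed from the alignment score with fixed
gapped BLOSUM62 parameters (lambda 0.267, K 0.041) — a single-pass stand-in
for an iterative profile search, so absolute family counts on real data may
differ from profile-based clusterings even at the same threshold.

Motif prevalence of a family is the fraction of its homologous genes whose
upstream region carries the genome-specific regulatory motif; it separates
genuinely early-expressed families (prevalence near 1) from families whose
members mostly lack the early promoter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

# Gapped Karlin-Altschul parameters for BLOSUM62 with gap open 11 / extend 1
_KA_LAMBDA = 0.267
_KA_K = 0.041

_NAME_PREFIX = {"single": "ADG", "mag": "mADG", "ssv_operon": "ADGSSV"}


@dataclass
class ProteinRecord:
    genome_id: str
    gene_id: str
    seq: str
    provenance: str = "single"  # single | mag | ssv_operon

    @property
    def key(self) -> tuple[str, str]:
        return (self.genome_id, self.gene_id)


@dataclass
class AlignmentStats:
    score: float
    pid: float  # percent identity over aligned columns
    coverage: float  # percent of the shorter sequence spanned
    evalue_proxy: float


@dataclass
class ProteinFamily:
    family_id: str
    members: list[ProteinRecord]
    min_coverage: float = 100.0
    min_pid: float = 100.0

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def singleton(self) -> bool:
        return self.n_members == 1


@dataclass
class PrevalenceRecord:
    family_id: str
    n_homologs: int
    n_with_motif: int

    @property
    def prevalence(self) -> float:
        return self.n_with_motif / self.n_homologs


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -12  # BLAST existence 11 + first extension 1
    aligner.extend_gap_score = -1
    return aligner


_ALIGNER = _aligner()


def karlin_altschul_evalue(score: float, m: int, n: int) -> float:
    return _KA_K * m * n * math.exp(-_KA_LAMBDA * score)


def pairwise_align(a: str, b: str) -> AlignmentStats:
    """Local alignment statistics between two protein sequences.

    Percent identity is identities over aligned columns (gap columns
    included); coverage is the aligned span of the shorter sequence over its
    length. The e-value proxy scales the raw score by Karlin-Altschul
    statistics with fixed gapped BLOSUM62 parameters.
    """
    if not a or not b:
        raise ValueError("sequences must be nonempty")
    aln = _ALIGNER.align(a, b)[0]
    score = float(aln.score)
    identities = 0
    columns = 0
    blocks_a, blocks_b = aln.aligned
    prev_a_end = prev_b_end = None
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        if prev_a_end is not None:
            columns += (a0 - prev_a_end) + (b0 - prev_b_end)  # gap columns
        for i in range(a1 - a0):
            columns += 1
            if a[a0 + i] == b[b0 + i]:
                identities += 1
        prev_a_end, prev_b_end = a1, b1
    pid = 100.0 * identities / columns if columns else 0.0
    shorter = min(len(a), len(b))
    if len(blocks_a):
        span_a = blocks_a[-1][1] - blocks_a[0][0]
        span_b = blocks_b[-1][1] - blocks_b[0][0]
        span = span_a if len(a) <= len(b) else span_b
    else:
        span = 0
    coverage = 100.0 * span / shorter if shorter else 0.0
    return AlignmentStats(
        score=score,
        pid=pid,
        coverage=coverage,
        evalue_proxy=karlin_altschul_evalue(score, len(a), len(b)),
    )


def cluster_families(
    proteins: list[ProteinRecord],
    threshold_evalue: float = 1e-3,
    min_length: int = 10,
) -> list[ProteinFamily]:
    """Single-linkage families over pairs with e-value <= threshold.

    The input is canonically sorted before linkage so the output is invariant
    to input order. Family ids are assigned by descending size, then by the
    lexicographically first member; the naming prefix follows the members'
    provenance (viral single gene ADG.NN, MAG mADG.NN, SSV operon ADGSSV.NN).
    """
    if not proteins:
        raise ValueError("protein set must be nonempty")
    records = sorted(proteins, key=lambda p: p.key)
    for p in records:
        if len(p.seq) < min_length:
            raise ValueError(
                f"protein {p.gene_id} shorter than {min_length} aa"
            )
    n = len(records)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    stats: dict[tuple[int, int], AlignmentStats] = {}
    for i in range(n):
        for j in range(i + 1, n):
            st = pairwise_align(records[i].seq, records[j].seq)
            stats[(i, j)] = st
            if st.evalue_proxy <= threshold_evalue:
                union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    ordered = sorted(
        groups.values(), key=lambda idxs: (-len(idxs), records[idxs[0]].key)
    )

    families = []
    counters: dict[str, int] = {}
    for idxs in ordered:
        members = [records[i] for i in idxs]
        provs = [m.provenance for m in members]
        prefix = _NAME_PREFIX.get(
            max(set(provs), key=lambda p: (provs.count(p), p)), "ADG"
        )
        counters[prefix] = counters.get(prefix, 0) + 1
        min_cov, min_pid = 100.0, 100.0
        for a in range(len(idxs)):
            for b in range(a + 1, len(idxs)):
                key = (min(idxs[a], idxs[b]), max(idxs[a], idxs[b]))
                st = stats[key]
                min_cov = min(min_cov, st.coverage)
                min_pid = min(min_pid, st.pid)
        families.append(
            ProteinFamily(
                family_id=f"{prefix}.{counters[prefix]:02d}",
                members=members,
                min_coverage=min_cov,
                min_pid=min_pid,
            )
        )
    return families


def motif_prevalence(
    family: ProteinFamily, adg_flags: dict[tuple[str, str], bool]
) -> PrevalenceRecord:
    """Fraction of a family's homologous genes that carry the motif.

    ``adg_flags`` maps (genome_id, gene_id) to whether the gene's upstream
    region carries the genome-specific regulatory sequence. Homologs are
    counted within the analyzed genome set.
    """
    if family.n_members == 0:
        raise ValueError("family has no members")
    missing = [m.key for m in family.members if m.key not in adg_flags]
    if missing:
        raise KeyError(f"no motif flag for members: {missing}")
    n_with = sum(1 for m in family.members if adg_flags[m.key])
    return PrevalenceRecord(
        family_id=family.family_id,
        n_homologs=family.n_members,
        n_with_motif=n_with,
    )


# ---------------------------------------------------------------------------
# Small-protein host-homolog (antitoxin candidate) screen


@dataclass
class AntitoxinCandidate:
    viral_protein: ProteinRecord
    host_genome_id: str
    host_gene_id: str
    evalue_proxy: float
    toxin_partner: str | None = None  # adjacent small gene id, if any
    convergent_pair: bool = False


def screen_host_homologs(
    viral_proteins: list[ProteinRecord],
    host_proteins: list[ProteinRecord],
    host_genomes,
    config=None,
) -> list[AntitoxinCandidate]:
    """Find small viral proteins with host homologs outside integrated viruses.

    Viral proteins shorter than ``small_protein_max`` aa are compared to all
    host proteins; hits at e-value <= ``host_screen_evalue`` are kept. A host
    neighbourhood (+-5 genes) in which ``viral_context_min_hits`` or more
    genes themselves hit viral proteins is treated as an integrated virus and
    excluded. Remaining candidates are annotated with an adjacent small gene
    (putative toxin partner), flagging convergent gene pairs.
    """
    from .adg_caller import PipelineConfig

    config = config or PipelineConfig()
    genomes = {g.id: g for g in host_genomes}
    host_by_key = {p.key: p for p in host_proteins}

    # all (small viral protein) -> host hits, and host genes with any viral hit
    hits: list[tuple[ProteinRecord, ProteinRecord, float]] = []
    host_genes_with_viral_hit: set[tuple[str, str]] = set()
    for vp in viral_proteins:
        for hp in host_proteins:
            st = pairwise_align(vp.seq, hp.seq)
            if st.evalue_proxy <= config.host_screen_evalue:
                host_genes_with_viral_hit.add(hp.key)
                if len(vp.seq) < config.small_protein_max:
                    hits.append((vp, hp, st.evalue_proxy))

    candidates = []
    for vp, hp, ev in hits:
        genome = genomes.get(hp.genome_id)
        if genome is None:
            continue
        order = [g.gene_id for g in genome.genes]
        try:
            pos = order.index(hp.gene_id)
        except ValueError:
            continue
        lo, hi = max(0, pos - 5), min(len(order), pos + 6)
        n_viral_context = sum(
            1
            for gid in order[lo:hi]
            if gid != hp.gene_id and (genome.id, gid) in host_genes_with_viral_hit
        )
        if n_viral_context >= config.viral_context_min_hits:
            continue  # integrated virus context
        partner = None
        convergent = False
        host_gene = genome.gene(hp.gene_id)
        for npos in (pos - 1, pos + 1):
            if not (0 <= npos < len(order)):
                continue
            neighbor = genome.genes[npos]
            nrec = host_by_key.get((genome.id, neighbor.gene_id))
            nlen = len(nrec.seq) if nrec else (neighbor.end - neighbor.start) // 3
            if nlen < config.small_protein_max:
                partner = neighbor.gene_id
                # convergent: 3' ends facing (+ gene followed by - gene)
                left, right = (host_gene, neighbor) if npos > pos else (neighbor, host_gene)
                convergent = left.strand == "+" and right.strand == "-"
                break
        candidates.append(
            AntitoxinCandidate(
                viral_protein=vp,
                host_genome_id=hp.genome_id,
                host_gene_id=hp.gene_id,
                evalue_proxy=ev,
                toxin_partner=partner,
                convergent_pair=convergent,
            )
        )
    return candidates


def write_families_tsv(families: list[ProteinFamily], path):
    import pandas as pd

    rows = []
    for f in families:
        for m in f.members:
            rows.append(
                {
                    "family": f.family_id,
                    "genome": m.genome_id,
                    "gene": m.gene_id,
                    "protein_length": len(m.seq),
                    "n_members": f.n_members,
                    "min_coverage": round(f.min_coverage, 1),
                    "min_pid": round(f.min_pid, 1),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_prevalence_tsv(records: list[PrevalenceRecord], path):
    import pandas as pd

    pd.DataFrame(
        [
            {
                "family": r.family_id,
                "n_homologs": r.n_homologs,
                "n_with_motif": r.n_with_motif,
                "prevalence": round(r.prevalence, 4),
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)
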