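"""Significance-thresholded PWM scanning of upstream-region sets.

Each region contributes at most its single best-scoring occurrence (ties go
to the smallest offset), consistent with the zero-or-one-site model used in
discovery. The hit's p-value is the exact score-distribution tail from
:mod:`adgscan.motif_model`; the e-value is a Bonferroni correction over the
number of positions actually scanned in the run, so the multiple-testing
scope is the corresponding genome's upstream set, and the count is recorded
on every hit for reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_io import Genome, UpstreamRegion, classify_loci, usable_upstream_regions
from .motif_model import PWMMotif, encode


@dataclass
class MotifHit:
    genome_id: str
    gene_id: str
    motif_id: str
    offset: int
    score: float
    p_value: float
    e_value: float
    passed: bool
    site_seq: str
    region_length: int
    n_positions_scanned: int


def scan_regions(
    pwm: PWMMotif,
    regions: list[UpstreamRegion],
    e_threshold: float = 1e-8,
    genome_id: str = "",
    granularity: float = 1e-3,
) -> list[MotifHit]:
    """Best occurrence of ``pwm`` per region with exact p- and e-values."""
    if not regions:
        raise ValueError("regions must be nonempty")
    W = pwm.width
    if all(r.length < W for r in regions):
        raise ValueError(
            f"motif width {W} exceeds every region length"
        )
    dist = pwm.score_distribution(granularity)
    ints = dist.int_scores

    per_region = []
    n_positions = 0
    for r in regions:
        if r.length < W:
            continue
        enc = encode(r.sequence)
        windows = np.lib.stride_tricks.sliding_window_view(enc, W)
        valid = ~np.any(windows == 4, axis=1)
        idx = np.nonzero(valid)[0]
        if len(idx) == 0:
            continue
        n_positions += len(idx)
        # integer lattice score of each valid window
        kw = ints[np.arange(W)[None, :], windows[idx].astype(np.int64)].sum(axis=1)
        best = int(np.argmax(kw))  # argmax takes the first (smallest offset) on ties
        per_region.append((r, int(idx[best]), int(kw[best])))

    hits = []
    for r, offset, kint in per_region:
        p = dist.pvalue_int(kint)
        e = p * n_positions
        word = r.sequence[offset : offset + W]
        score = float(
            pwm.log_odds[np.arange(W), encode(word)].sum()
        )
        hits.append(
            MotifHit(
                genome_id=genome_id or r.genome_id,
                gene_id=r.gene_id,
                motif_id=pwm.motif_id,
                offset=offset,
                score=score,
                p_value=p,
                e_value=e,
                passed=e < e_threshold,
                site_seq=word,
                region_length=r.length,
                n_positions_scanned=n_positions,
            )
        )
    return hits


def scan_host_geneset(
    pwm: PWMMotif,
    host: Genome,
    L_up: int = 100,
    e_threshold: float = 1e-8,
    max_gap: int = 30,
    granularity: float = 1e-3,
) -> list[MotifHit]:
    """Scan upstream windows of all single / operon-lead genes of a host genome.

    Supports the host-regulon use case: finding host housekeeping genes whose
    promoters match a virus-derived early-gene motif.
    """
    if any(g.locus_class == "unset" for g in host.genes):
        classify_loci(host, max_gap=max_gap)
    regions = usable_upstream_regions(host, L_up=L_up)
    return scan_regions(
        pwm, regions, e_threshold=e_threshold, genome_id=host.id,
        granularity=granularity,
    )


def write_hits_tsv(hits: list[MotifHit], path):
    import pandas as pd

    rows = [
        {
            "genome": h.genome_id,
            "gene": h.gene_id,
            "motif": h.motif_id,
            "offset": h.offset,
            "score_bits": h.score,
            "p_value": h.p_value,
            "e_value": h.e_value,
            "passed": h.passed,
            "n_positions_scanned": h.n_positions_scanned,
            "site": h.site_seq,
        }
        for h in hits
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
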