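"""Ground-truth-labelled synthetic genomes and protein sets.

The generator emulates the data regime of small archaeal virus genomes:
20-80 kb linear or circular molecules with a few dozen protein-coding
genes, partial operon structure, AT-rich base composition, and a
virus-specific early regulatory sequence implanted upstream of designated
anti-defense genes (ADGs). The implanted motif carries the biologically
expected architecture — a purine-rich BRE followed by a TTTAWATA TATA-box,
embedded in moderately conserved virus-specific flanks — with the promoter
core held nearly invariant and the flank conservation tuned to an average
per-column information content target.

Sequences are i.i.d. at the specified GC (order-0), matching the scanning
statistics; real genomes have codon and dinucleotide structure this
generator does not attempt to reproduce.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_io import Genome, GeneRecord, revcomp
from .motif_model import BASES, BackgroundModel, PWMMotif

_STOPS = ("TAA", "TAG", "TGA")

# standard (table 11) codons per amino acid, fixed order for determinism
_AA_CODONS: dict[str, list[str]] = {}
for _b1 in "TCAG":
    for _b2 in "TCAG":
        for _b3 in "TCAG":
            _codon = _b1 + _b2 + _b3
            if _codon in _STOPS:
                continue
            from Bio.Seq import Seq as _Seq

            _aa = str(_Seq(_codon).translate(table=11))
            _AA_CODONS.setdefault(_aa, []).append(_codon)


@dataclass
class SimSpec:
    """Study conditions for one simulated genome."""

    seed: int
    n_genes: int = 40
    topology: str = "linear"
    gc: float = 0.38
    operon_fraction: float = 0.3
    n_adg: int = 8
    implant_pwm: PWMMotif | None = None
    implant_ic: float = 1.2  # bits/column; the promoter core is near-invariant
    implant_width: int = 40
    adg_positions: str = "termini_biased"  # termini_biased | one_end | uniform
    L_up: int = 100
    intergenic_range: tuple[int, int] = (160, 280)
    operon_gap_range: tuple[int, int] = (5, 26)
    gene_len_codons: tuple[int, int] = (80, 300)
    margin: int = 200
    genome_length: int | None = None  # optional hard cap; layout must fit
    adg_protein_pool: list[str] | None = None
    genome_id: str | None = None

    def __post_init__(self):
        if not (0.0 < self.gc < 1.0):
            raise ValueError("gc must be in (0, 1)")
        if self.n_adg > self.n_genes:
            raise ValueError("n_adg cannot exceed n_genes")


@dataclass
class ImplantTruth:
    gene_id: str
    region_offset: int  # offset of the implant within the L_up upstream window
    distance_to_start: int  # nt between implant 3' end and the start codon
    site: str


@dataclass
class GroundTruth:
    genome_id: str
    implants: list[ImplantTruth]
    pwm: PWMMotif
    width: int

    @property
    def implanted_gene_ids(self) -> set[str]:
        return {t.gene_id for t in self.implants}


# ---------------------------------------------------------------------------
# Implant motif construction

# implant architecture (relative columns within the default width-40 motif)
BRE_COLS = range(10, 16)
TATA_COLS = range(16, 24)
_TATA = "TTTAWATA"


def _column(dominant: str, p: float) -> np.ndarray:
    rest = (1.0 - p) / 3.0
    row = np.full(4, rest)
    row[BASES.index(dominant)] = p
    return row


def make_implant_pwm(
    ic_target: float = 1.2,
    width: int = 40,
    background: BackgroundModel | None = None,
    rng: np.random.Generator | None = None,
) -> PWMMotif:
    """Structured implant matrix: BRE + TATA core with tunable flanks.

    TATA columns are held at 0.97 on the consensus base (the W column splits
    A/T evenly); BRE columns favour purines at 0.95. The dominant-base
    probability of the virus-specific flank columns is solved by bisection so
    the motif's average information content (relative to the background)
    meets ``ic_target``.
    """
    background = background or BackgroundModel.uniform()
    rng = rng or np.random.default_rng(0)
    bg = background.array

    def ic_of(probs: np.ndarray) -> float:
        with np.errstate(divide="ignore", invalid="ignore"):
            t = probs * (np.log2(probs) - np.log2(bg)[None, :])
        return float(np.nansum(t)) / probs.shape[0]

    flank_cols = [w for w in range(width) if w not in BRE_COLS and w not in TATA_COLS]
    flank_bases = [BASES[i] for i in rng.integers(0, 4, size=len(flank_cols))]
    purine_major = ["G" if i else "A" for i in rng.integers(0, 2, size=len(BRE_COLS))]

    def build(p_flank: float) -> np.ndarray:
        probs = np.zeros((width, 4))
        fi = 0
        for w in range(width):
            if w in TATA_COLS:
                c = _TATA[w - TATA_COLS.start]
                if c == "W":
                    probs[w] = (0.485, 0.015, 0.015, 0.485)
                else:
                    probs[w] = _column(c, 0.97)
            elif w in BRE_COLS:
                major = purine_major[w - BRE_COLS.start]
                minor = "A" if major == "G" else "G"
                row = np.full(4, 0.025)
                row[BASES.index(major)] = 0.55
                row[BASES.index(minor)] = 0.40
                probs[w] = row
            else:
                probs[w] = _column(flank_bases[fi], p_flank)
                fi += 1
        return probs

    lo, hi = 0.26, 0.995
    for _ in range(60):
        mid = (lo + hi) / 2
        if ic_of(build(mid)) < ic_target:
            lo = mid
        else:
            hi = mid
    probs = build((lo + hi) / 2)
    return PWMMotif(
        motif_id="implant",
        counts=probs * 0.0,
        probs=probs,
        background=background,
        pseudocount=0.0,
    )


def sample_site(pwm: PWMMotif, rng: np.random.Generator) -> str:
    return "".join(
        BASES[rng.choice(4, p=row / row.sum())] for row in pwm.probs
    )


# ---------------------------------------------------------------------------
# Genome simulation


def _random_bases(n: int, bg: np.ndarray, rng) -> str:
    return "".join(BASES[i] for i in rng.choice(4, size=n, p=bg))


def _random_codon(bg: np.ndarray, rng) -> str:
    while True:
        c = _random_bases(3, bg, rng)
        if c not in _STOPS:
            return c


def _random_orf(n_codons: int, bg, rng) -> str:
    body = "".join(_random_codon(bg, rng) for _ in range(n_codons - 1))
    return "ATG" + body + _STOPS[rng.integers(0, 3)]


def _reverse_translate(aa: str, rng) -> str:
    codons = []
    for i, a in enumerate(aa):
        if i == 0 and a == "M":
            codons.append("ATG")
            continue
        options = _AA_CODONS.get(a)
        if not options:
            raise ValueError(f"cannot encode residue {a!r}")
        codons.append(options[rng.integers(0, len(options))])
    return "".join(codons) + _STOPS[rng.integers(0, 3)]


def simulate_genome(spec: SimSpec) -> tuple[Genome, GroundTruth]:
    """Generate one labelled genome; identical specs give identical output."""
    rng = np.random.default_rng(spec.seed)
    background = BackgroundModel.from_gc(spec.gc)
    bg = background.array
    genome_id = spec.genome_id or f"synth{spec.seed:04d}"

    # block structure: operons of 2-4 same-strand genes, or singles
    blocks: list[tuple[str, int]] = []  # (strand, size)
    remaining = spec.n_genes
    while remaining > 0:
        if remaining >= 2 and rng.random() < spec.operon_fraction:
            size = int(min(rng.integers(2, 5), remaining))
        else:
            size = 1
        blocks.append(("+" if rng.random() < 0.5 else "-", size))
        remaining -= size

    # gene ids follow layout order, so block membership is known up front;
    # the transcriptional lead of a block is leftmost for "+", rightmost for "-"
    member_ids: list[list[str]] = []
    gene_no = 0
    for _, size in blocks:
        member_ids.append([f"g{gene_no + k + 1:03d}" for k in range(size)])
        gene_no += size
    lead_ids = [
        ids[0] if strand == "+" else ids[-1]
        for (strand, _), ids in zip(blocks, member_ids)
    ]

    # choose ADG genes among block leads / singles
    if spec.n_adg > len(lead_ids):
        raise ValueError("not enough single/lead genes to place all ADGs")
    if spec.adg_positions == "one_end":
        adg_ids = lead_ids[: spec.n_adg]
    elif spec.adg_positions == "uniform":
        adg_ids = sorted(
            rng.choice(lead_ids, size=spec.n_adg, replace=False).tolist()
        )
    else:  # termini_biased: alternately from both genome ends
        picks, left, right = [], 0, len(lead_ids) - 1
        for i in range(spec.n_adg):
            if i % 2 == 0:
                picks.append(lead_ids[left])
                left += 1
            else:
                picks.append(lead_ids[right])
                right -= 1
        adg_ids = sorted(picks)

    # ADG genes may encode shared proteins (for cross-genome family tests)
    pool_orfs: dict[str, str] = {}
    if spec.adg_protein_pool:
        for i, gid in enumerate(adg_ids):
            aa = spec.adg_protein_pool[i % len(spec.adg_protein_pool)]
            pool_orfs[gid] = _reverse_translate(aa, rng)

    lo_c, hi_c = spec.gene_len_codons
    pieces: list[str] = [_random_bases(spec.margin, bg, rng)]
    genes: list[GeneRecord] = []
    pos = spec.margin
    for (strand, size), ids in zip(blocks, member_ids):
        for k, gid in enumerate(ids):
            if gid in pool_orfs:
                orf = pool_orfs[gid]
            else:
                orf = _random_orf(int(rng.integers(lo_c, hi_c)), bg, rng)
            placed = orf if strand == "+" else revcomp(orf)
            pieces.append(placed)
            genes.append(
                GeneRecord(
                    gene_id=gid,
                    start=pos,
                    end=pos + len(orf),
                    strand=strand,
                    product="hypothetical protein",
                )
            )
            pos += len(orf)
            if k < size - 1:
                gap = int(rng.integers(*spec.operon_gap_range))
                pieces.append(_random_bases(gap, bg, rng))
                pos += gap
        gap = int(rng.integers(*spec.intergenic_range))
        pieces.append(_random_bases(gap, bg, rng))
        pos += gap
    pieces.append(_random_bases(spec.margin, bg, rng))
    sequence = list("".join(pieces))

    if spec.genome_length is not None and len(sequence) > spec.genome_length:
        raise ValueError(
            f"layout needs {len(sequence)} nt but genome_length is "
            f"{spec.genome_length}"
        )

    by_id = {g.gene_id: g for g in genes}

    pwm = spec.implant_pwm or make_implant_pwm(
        ic_target=spec.implant_ic,
        width=spec.implant_width,
        background=background,
        rng=rng,
    )
    width = pwm.width

    implants = []
    for gid in adg_ids:
        g = by_id[gid]
        site = sample_site(pwm, rng)
        d_end = int(rng.integers(15, 31))  # implant 3' end to start codon
        if g.strand == "+":
            a = g.start - d_end - width
            sequence[a : a + width] = list(site)
        else:
            a = g.end + d_end
            sequence[a : a + width] = list(revcomp(site))
        implants.append(
            ImplantTruth(
                gene_id=gid,
                region_offset=spec.L_up - width - d_end,
                distance_to_start=d_end,
                site=site,
            )
        )

    genome = Genome(
        id=genome_id,
        sequence="".join(sequence),
        topology=spec.topology,
        genes=genes,
        source_format="synthetic",
    )
    from .genome_io import _fill_translations

    _fill_translations(genome)
    truth = GroundTruth(
        genome_id=genome_id, implants=implants, pwm=pwm, width=width
    )
    return genome, truth


def simulate_cohort(
    seed: int,
    n_genomes: int,
    divergence: float = 0.2,
    protein_length: int = 120,
    **spec_kwargs,
) -> list[tuple[Genome, GroundTruth]]:
    """Simulate genomes whose ADGs encode homologous proteins.

    A pool of ancestor ADG proteins is drawn once; each genome carries
    mutated copies (per-site substitution probability ``divergence``), so the
    cohort's ADGs cluster into cross-genome families with known membership.
    """
    rng = np.random.default_rng(seed)
    n_adg = spec_kwargs.get("n_adg", SimSpec.__dataclass_fields__["n_adg"].default)
    ancestors = [
        "M" + _random_protein(protein_length - 1, rng) for _ in range(n_adg)
    ]
    out = []
    for g in range(n_genomes):
        pool = [
            "M" + _mutate_protein(a[1:], divergence, rng) for a in ancestors
        ]
        sub_seed = int(rng.integers(0, 2**31 - 1))
        spec = SimSpec(
            seed=sub_seed,
            genome_id=f"synthco{seed:03d}_{g:02d}",
            adg_protein_pool=pool,
            **spec_kwargs,
        )
        out.append(simulate_genome(spec))
    return out


_AA20 = "ACDEFGHIKLMNPQRSTVWY"


def _random_protein(n: int, rng) -> str:
    return "".join(_AA20[i] for i in rng.integers(0, 20, size=n))


def _mutate_protein(aa: str, rate: float, rng) -> str:
    out = []
    for c in aa:
        if rng.random() < rate:
            alternatives = _AA20.replace(c, "")
            out.append(alternatives[rng.integers(0, len(alternatives))])
        else:
            out.append(c)
    return "".join(out)


def simulate_protein_families(
    seed: int,
    n_families: int,
    sizes: list[int],
    divergence: float,
    length: int = 120,
):
    """Protein records in known families: each family is a mutated ancestor.

    Returns (records, truth) where truth maps (genome_id, gene_id) to the
    0-based family index.
    """
    if not (0.0 <= divergence < 1.0):
        raise ValueError("divergence must be in [0, 1)")
    if len(sizes) != n_families:
        raise ValueError("need one size per family")
    from .protein_families import ProteinRecord

    rng = np.random.default_rng(seed)
    records, truth = [], {}
    counter = 0
    for fam in range(n_families):
        ancestor = _random_protein(length, rng)
        for _ in range(sizes[fam]):
            counter += 1
            seq = _mutate_protein(ancestor, divergence, rng)
            rec = ProteinRecord(
                genome_id=f"simfam{seed}", gene_id=f"p{counter:03d}", seq=seq
            )
            records.append(rec)
            truth[rec.key] = fam
    return records, truth


def write_truth_tsv(truth: GroundTruth, path):
    import pandas as pd

    pd.DataFrame(
        [
            {
                "genome": truth.genome_id,
                "gene": t.gene_id,
                "region_offset": t.region_offset,
                "distance_to_start": t.distance_to_start,
                "site": t.site,
            }
            for t in truth.implants
        ]
    ).to_csv(path, sep="\t", index=False)
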