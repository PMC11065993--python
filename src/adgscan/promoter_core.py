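"""Archaeal strong-promoter core detection: TATA-box plus BRE.

The early-gene promoter core recognised here is the archaeal TATA-box
(consensus TTTAWATA, W = A or T) immediately preceded by a 6-nt TFB
recognition element (BRE). A strong BRE is purine-rich; the strongest
TFB-binding variants carry G at position -6 and A at position -3, counting
upstream from the TATA-box start with -1 the base immediately 5' of it.
Those two positional preferences are reported as flags but not required for
"strong" status; strength requires a TATA match within ``max_mm`` mismatches
and a BRE purine fraction of at least ``purine_min``.
"""

from __future__ import annotations

from dataclasses import dataclass

TATA_CONSENSUS = "TTTAWATA"
_ALLOWED = {"A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"}, "W": {"A", "T"}}
_TATA_SETS = [_ALLOWED[c] for c in TATA_CONSENSUS]
_PURINES = frozenset("AG")

TATA_WIDTH = len(TATA_CONSENSUS)
BRE_WIDTH = 6


@dataclass
class PromoterCall:
    tata_offset: int
    tata_seq: str
    tata_mismatches: int
    bre_seq: str
    bre_purine_fraction: float
    bre_G_minus6: bool
    bre_A_minus3: bool
    is_strong: bool


def tata_mismatches(word: str) -> int:
    """Mismatch count of an 8-mer against the degenerate TATA consensus."""
    if len(word) != TATA_WIDTH:
        raise ValueError("TATA-box word must be 8 nt")
    return sum(1 for c, allowed in zip(word, _TATA_SETS) if c not in allowed)


def find_tata(sequence: str, max_mm: int = 1) -> list[tuple[int, int]]:
    """All (offset, mismatches) where an 8-mer matches TTTAWATA with <= max_mm
    mismatches, sorted by (mismatches, offset). Short sequences give []."""
    seq = sequence.upper()
    out = []
    for o in range(len(seq) - TATA_WIDTH + 1):
        mm = tata_mismatches(seq[o : o + TATA_WIDTH])
        if mm <= max_mm:
            out.append((o, mm))
    out.sort(key=lambda t: (t[1], t[0]))
    return out


def call_promoter(
    sequence: str, max_mm: int = 1, purine_min: float = 2.0 / 3.0
) -> PromoterCall | None:
    """Best TATA candidate with a complete 6-nt BRE window immediately 5'.

    Candidates need at least 6 bases 5' of the TATA start. Returns None when
    no candidate qualifies.
    """
    seq = sequence.upper()
    candidates = [(o, mm) for o, mm in find_tata(seq, max_mm) if o >= BRE_WIDTH]
    if not candidates:
        return None
    offset, mm = candidates[0]
    bre = seq[offset - BRE_WIDTH : offset]
    purine_fraction = sum(1 for c in bre if c in _PURINES) / BRE_WIDTH
    return PromoterCall(
        tata_offset=offset,
        tata_seq=seq[offset : offset + TATA_WIDTH],
        tata_mismatches=mm,
        bre_seq=bre,
        bre_purine_fraction=purine_fraction,
        bre_G_minus6=bre[0] == "G",
        bre_A_minus3=bre[3] == "A",
        is_strong=(mm <= max_mm) and (purine_fraction >= purine_min),
    )


def classify_motif(motif, max_mm: int = 1, purine_min: float = 2.0 / 3.0) -> bool:
    """True iff a motif is a strong-promoter motif.

    Requires a strong promoter call on the majority consensus of the motif
    matrix, and a strong call at a consistent TATA offset (within +-2 nt) on
    at least half of the individual site sequences.
    """
    if len(motif.sites) < 2:
        raise ValueError("motif must have at least 2 sites")
    consensus_call = call_promoter(motif.pwm.consensus, max_mm, purine_min)
    if consensus_call is None or not consensus_call.is_strong:
        return False
    ref = consensus_call.tata_offset
    n_ok = 0
    for site in motif.sites:
        c = call_promoter(site.sequence, max_mm, purine_min)
        if c is not None and c.is_strong and abs(c.tata_offset - ref) <= 2:
            n_ok += 1
    return n_ok >= 0.5 * len(motif.sites)


def write_promoter_tsv(calls: dict, path):
    """Write per-site promoter calls; ``calls`` maps label -> PromoterCall/None."""
    import pandas as pd

    rows = []
    for label, c in calls.items():
        if c is None:
            rows.append({"site": label, "tata_found": False})
            continue
        rows.append(
            {
                "site": label,
                "tata_found": True,
                "tata_offset": c.tata_offset,
                "tata_seq": c.tata_seq,
                "tata_mismatches": c.tata_mismatches,
                "bre_seq": c.bre_seq,
                "bre_purine_fraction": round(c.bre_purine_fraction, 4),
                "bre_G_minus6": c.bre_G_minus6,
                "bre_A_minus3": c.bre_A_minus3,
                "is_strong": c.is_strong,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
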