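"""Position-weight-matrix mathematics.

A PWM here is the standard per-column base-probability model for a fixed-width
DNA motif, scored as a summed log2 likelihood ratio against an order-0
background. Significance of a score is the exact tail probability of the
score distribution of a background-distributed random word, computed by
dynamic programming over a discretized score grid (the classic convolution
of per-column score distributions, as used by FIMO/TFM-Pvalue).

Scores are discretized by flooring each column's log-odds onto a lattice of
``granularity`` bits. Both the distribution and observed word scores are
placed on the same lattice, so p-values of scanned words are exactly
self-consistent. ``score_pvalue`` for an arbitrary real threshold uses a
conservative (superset) bin cut so that thresholds at or below the minimum
achievable score always return 1.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

# IUPAC code for every nonempty subset of {A,C,G,T}
_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G",
    frozenset("T"): "T", frozenset("AC"): "M", frozenset("AG"): "R",
    frozenset("AT"): "W", frozenset("CG"): "S", frozenset("CT"): "Y",
    frozenset("GT"): "K", frozenset("ACG"): "V", frozenset("ACT"): "H",
    frozenset("AGT"): "D", frozenset("CGT"): "B", frozenset("ACGT"): "N",
}


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as int8: A=0 C=1 G=2 T=3, anything else 4."""
    arr = np.full(len(seq), 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        arr[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(b)] = i
    return arr


def decode(arr: np.ndarray) -> str:
    return "".join("ACGTN"[i] for i in arr)


@dataclass(frozen=True)
class BackgroundModel:
    """Order-0 background base distribution."""

    probs: tuple[float, float, float, float]

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (4,):
            raise ValueError("background needs exactly 4 probabilities")
        if not np.all(p > 0):
            raise ValueError("background probabilities must be strictly positive")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("background probabilities must sum to 1")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.probs, dtype=float)

    def __getitem__(self, base: str) -> float:
        return self.probs[_BASE_INDEX[base]]

    @classmethod
    def uniform(cls) -> "BackgroundModel":
        return cls((0.25, 0.25, 0.25, 0.25))

    @classmethod
    def from_gc(cls, gc: float) -> "BackgroundModel":
        at = (1.0 - gc) / 2.0
        return cls((at, gc / 2.0, gc / 2.0, at))


def build_background(regions) -> BackgroundModel:
    """Empirical base frequencies over a set of regions, +1 smoothing per base.

    ``regions`` is an iterable of objects with a ``sequence`` attribute, or
    plain strings. Non-ACGT characters are ignored in the counts.
    """
    counts = np.ones(4, dtype=float)  # +1 smoothing
    total = 0
    for r in regions:
        seq = r if isinstance(r, str) else r.sequence
        enc = encode(seq)
        for i in range(4):
            counts[i] += int(np.sum(enc == i))
        total += len(seq)
    if total == 0:
        raise ValueError("cannot build a background from empty input")
    return BackgroundModel(tuple(counts / counts.sum()))


@dataclass
class PWMMotif:
    """A probability matrix over ``width`` columns with its background.

    ``counts`` holds the (possibly posterior-weighted) site counts the matrix
    was estimated from; ``probs`` are the smoothed column distributions.
    """

    motif_id: str
    counts: np.ndarray  # W x 4
    probs: np.ndarray  # W x 4
    background: BackgroundModel
    pseudocount: float
    source_site_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("probs must be W x 4")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each probs row must sum to 1")
        self._distributions: dict[float, ScoreDistribution] = {}

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """W x 4 log2(p/bg); -inf where a column probability is exactly 0."""
        bg = self.background.array
        with np.errstate(divide="ignore"):
            return np.log2(self.probs) - np.log2(bg)

    @property
    def consensus(self) -> str:
        """Majority-base consensus (column argmax, ties to ACGT order)."""
        return "".join(BASES[i] for i in np.argmax(self.probs, axis=1))

    @property
    def consensus_iupac(self) -> str:
        """IUPAC consensus: a column's code covers bases with probability >= 0.25."""
        out = []
        for row in self.probs:
            chosen = frozenset(BASES[i] for i in range(4) if row[i] >= 0.25)
            if not chosen:  # flat-ish column, fall back to argmax
                chosen = frozenset(BASES[int(np.argmax(row))])
            out.append(_IUPAC[chosen])
        return "".join(out)

    def information_content(self) -> np.ndarray:
        """Per-column information content in bits relative to the background."""
        with np.errstate(divide="ignore", invalid="ignore"):
            term = self.probs * (np.log2(self.probs) - np.log2(self.background.array))
        return np.nansum(term, axis=1)

    def score_distribution(self, granularity: float = 1e-3) -> "ScoreDistribution":
        if granularity not in self._distributions:
            self._distributions[granularity] = ScoreDistribution.from_pwm(
                self, granularity
            )
        return self._distributions[granularity]


def build_pwm(
    sites,
    background: BackgroundModel,
    pseudocount: float = 0.25,
    motif_id: str = "motif",
    site_ids=None,
) -> PWMMotif:
    """Estimate a PWM from aligned, equal-length ACGT site strings.

    Column probabilities are (count + pseudocount * bg) / (n_sites + pseudocount),
    i.e. the pseudocount is one total extra observation distributed by the
    background, MEME-style.
    """
    sites = list(sites)
    if len(sites) < 2:
        raise ValueError("need at least 2 sites to build a PWM")
    width = len(sites[0])
    if any(len(s) != width for s in sites):
        raise ValueError("sites must all have equal length")
    counts = np.zeros((width, 4), dtype=float)
    for s in sites:
        enc = encode(s)
        if np.any(enc > 3):
            raise ValueError(f"site contains a non-ACGT base: {s!r}")
        counts[np.arange(width), enc] += 1.0
    probs = pwm_probs_from_counts(counts, background, pseudocount)
    return PWMMotif(
        motif_id=motif_id,
        counts=counts,
        probs=probs,
        background=background,
        pseudocount=pseudocount,
        source_site_ids=list(site_ids) if site_ids is not None else [],
    )


def pwm_probs_from_counts(
    counts: np.ndarray, background: BackgroundModel, pseudocount: float
) -> np.ndarray:
    counts = np.asarray(counts, dtype=float)
    n = counts.sum(axis=1, keepdims=True)
    smoothed = counts + pseudocount * background.array[None, :]
    return smoothed / (n + pseudocount)


def score_word(pwm: PWMMotif, word: str) -> float:
    """Log-likelihood-ratio score (bits) of one word of length ``pwm.width``."""
    if len(word) != pwm.width:
        raise ValueError(
            f"word length {len(word)} does not match motif width {pwm.width}"
        )
    enc = encode(word)
    if np.any(enc > 3):
        raise ValueError(f"word contains a non-ACGT base: {word!r}")
    return float(pwm.log_odds[np.arange(pwm.width), enc].sum())


@dataclass
class ScoreDistribution:
    """Exact distribution of the discretized PWM score of a background word.

    ``pmf[i]`` is the probability that the integer lattice score equals
    ``offset + i``; real scores are recovered as ``(offset + i) * granularity``.
    """

    granularity: float
    offset: int
    pmf: np.ndarray
    width: int
    int_scores: np.ndarray  # W x 4 per-column lattice scores (floored)

    @classmethod
    def from_pwm(cls, pwm: PWMMotif, granularity: float = 1e-3) -> "ScoreDistribution":
        if granularity <= 0:
            raise ValueError("granularity must be positive")
        llr = pwm.log_odds
        if not np.all(np.isfinite(llr)):
            # -inf columns (zero probability) cannot appear in a scoring path
            # with positive probability under the motif; clamp to a very low
            # finite score so the DP stays bounded.
            llr = np.where(np.isfinite(llr), llr, -64.0)
        ints = np.floor(llr / granularity + 1e-9).astype(np.int64)
        bg = pwm.background.array
        col_min = ints.min(axis=1)
        shifted = ints - col_min[:, None]
        pmf = np.array([1.0])
        for w in range(pwm.width):
            new = np.zeros(len(pmf) + int(shifted[w].max()))
            for b in range(4):
                s = int(shifted[w, b])
                new[s : s + len(pmf)] += pmf * bg[b]
            pmf = new
        return cls(
            granularity=granularity,
            offset=int(col_min.sum()),
            pmf=pmf,
            width=pwm.width,
            int_scores=ints,
        )

    @property
    def sf(self) -> np.ndarray:
        """Survival function: sf[i] = P(lattice score >= offset + i)."""
        if not hasattr(self, "_sf"):
            self._sf = np.cumsum(self.pmf[::-1])[::-1]
        return self._sf

    def pvalue_int(self, k: int) -> float:
        """P(lattice score >= k)."""
        i = k - self.offset
        if i <= 0:
            return 1.0
        if i >= len(self.pmf):
            return 0.0
        return float(self.sf[i])

    def word_int_score(self, word_enc: np.ndarray) -> int:
        return int(self.int_scores[np.arange(self.width), word_enc].sum())

    def pvalue(self, threshold: float) -> float:
        """Conservative P(score >= threshold).

        Each column score loses at most one lattice step to flooring, so a
        word whose exact score reaches ``threshold`` has lattice score K with
        (K + width) * granularity > threshold; all such K are included.
        """
        if not math.isfinite(threshold):
            raise ValueError("threshold must be finite")
        k_cut = int(math.floor(threshold / self.granularity - self.width + 1e-9)) + 1
        return self.pvalue_int(k_cut)


def score_pvalue(pwm: PWMMotif, threshold: float, granularity: float = 1e-3) -> float:
    """Exact P(score of a background-distributed word >= threshold)."""
    return pwm.score_distribution(granularity).pvalue(threshold)


def word_pvalue(pwm: PWMMotif, word: str, granularity: float = 1e-3) -> float:
    """P-value of one observed word, evaluated on the score lattice.

    Self-consistent with the scanning machinery: the word's score is floored
    column-wise onto the same lattice as the distribution.
    """
    enc = encode(word)
    if len(word) != pwm.width or np.any(enc > 3):
        raise ValueError("word must be an ACGT string of the motif width")
    dist = pwm.score_distribution(granularity)
    return dist.pvalue_int(dist.word_int_score(enc))


# ---------------------------------------------------------------------------
# MEME minimal motif text format


def write_meme(motifs, handle_or_path, background: BackgroundModel | None = None):
    """Write motifs in MEME minimal motif format (version 4)."""
    motifs = list(motifs)
    if background is None:
        background = motifs[0].background if motifs else BackgroundModel.uniform()
    own = isinstance(handle_or_path, (str, bytes)) or hasattr(handle_or_path, "__fspath__")
    fh = open(handle_or_path, "w") if own else handle_or_path
    try:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(
            " ".join(f"{b} {background[b]:.6f}" for b in BASES) + "\n\n"
        )
        for m in motifs:
            nsites = max(int(round(m.counts.sum(axis=1).max())), 1)
            fh.write(f"MOTIF {m.motif_id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.width} "
                f"nsites= {nsites} E= 0\n"
            )
            for row in m.probs:
                fh.write(" ".join(f"{p:.6f}" for p in row) + "\n")
            fh.write("\n")
    finally:
        if own:
            fh.close()


def read_meme(handle_or_path, pseudocount: float = 0.25) -> list[PWMMotif]:
    """Read motifs from MEME minimal motif format."""
    own = isinstance(handle_or_path, (str, bytes)) or hasattr(handle_or_path, "__fspath__")
    fh = open(handle_or_path) if own else handle_or_path
    try:
        text = fh.read()
    finally:
        if own:
            fh.close()
    lines = io.StringIO(text).read().splitlines()
    background = BackgroundModel.uniform()
    motifs: list[PWMMotif] = []
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            toks = lines[i + 1].split()
            probs = {toks[j]: float(toks[j + 1]) for j in range(0, len(toks), 2)}
            total = sum(probs[b] for b in BASES)
            background = BackgroundModel(tuple(probs[b] / total for b in BASES))
            i += 2
            continue
        if line.startswith("MOTIF"):
            motif_id = line.split()[1]
            j = i + 1
            while "letter-probability matrix" not in lines[j]:
                j += 1
            header = lines[j]
            w = int(header.split("w=")[1].split()[0])
            nsites = int(header.split("nsites=")[1].split()[0])
            rows = []
            for k in range(j + 1, j + 1 + w):
                rows.append([float(x) for x in lines[k].split()])
            probs = np.asarray(rows)
            probs = probs / probs.sum(axis=1, keepdims=True)
            counts = probs * nsites
            motifs.append(
                PWMMotif(
                    motif_id=motif_id,
                    counts=counts,
                    probs=probs,
                    background=background,
                    pseudocount=pseudocount,
                )
            )
            i = j + 1 + w
            continue
        i += 1
    return motifs
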