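"""Per-genome discovery of conserved upstream regulatory motifs.

The model is ZOOPS (zero-or-one occurrence per sequence) expectation
maximization: each upstream region carries at most one motif site, matching
the one-early-promoter-per-gene picture. Discovery is fully deterministic —
instead of random restarts, every substring of the candidate width is
evaluated as a one-site seed and the seed with the best initial ZOOPS
likelihood starts EM. Width is selected on a coarse grid by the best
converged likelihood, found sites are masked with N, and the next motif is
sought in the residue.

Site significance is the exact PWM score p-value from
:mod:`adgscan.motif_model`; only sites below ``site_p_threshold`` are
retained, and motifs with fewer than two passing sites are discarded,
terminating the search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .genome_io import UpstreamRegion
from .motif_model import (
    BackgroundModel,
    PWMMotif,
    build_background,
    build_pwm,
    decode,
    encode,
    pwm_probs_from_counts,
    score_word,
    word_pvalue,
)

_LN2 = float(np.log(2.0))


@dataclass
class DiscoveryConfig:
    """Knobs of the motif search.

    Widths span 30-100 nt so that a full regulatory sequence (promoter core
    plus flanking operator-like segments) fits in one motif; the grid steps
    by 10 nt because the conserved core dominates the likelihood and
    intermediate widths add little.
    """

    w_min: int = 30
    w_max: int = 100
    w_step: int = 10
    n_motifs: int = 3
    site_p_threshold: float = 1e-8
    em_tol: float = 1e-6
    em_max_iter: int = 200
    min_sequences: int = 5
    pseudocount: float = 0.25
    granularity: float = 1e-3
    seed_gamma: float = 0.5

    def __post_init__(self):
        if not (1 <= self.w_min <= self.w_max):
            raise ValueError("need 1 <= w_min <= w_max")
        if not (0.0 < self.site_p_threshold < 1.0):
            raise ValueError("site_p_threshold must be in (0, 1)")

    @property
    def widths(self) -> list[int]:
        ws = list(range(self.w_min, self.w_max + 1, self.w_step))
        if ws[-1] != self.w_max:
            ws.append(self.w_max)
        return ws


@dataclass
class MotifSite:
    region_id: str
    offset: int
    sequence: str
    score: float
    p_value: float


@dataclass
class MotifResult:
    pwm: PWMMotif
    sites: list[MotifSite]
    zoops_lambda: float
    log_likelihood: float
    passed_threshold: bool

    @property
    def site_gene_ids(self) -> set[str]:
        return {s.region_id for s in self.sites}


class DiscoveryError(ValueError):
    """Raised when the input region set cannot support discovery."""


# ---------------------------------------------------------------------------
# Window bookkeeping


class _WindowSet:
    """All N-free windows of one width across a set of encoded regions."""

    def __init__(self, encoded: list[np.ndarray], region_ids: list[str], width: int):
        self.width = width
        self.region_ids = region_ids
        rows = []
        owners = []
        offsets = []
        for r, enc in enumerate(encoded):
            if len(enc) < width:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(enc, width)
            valid = ~np.any(windows == 4, axis=1)
            idx = np.nonzero(valid)[0]
            if len(idx):
                rows.append(windows[idx])
                owners.append(np.full(len(idx), r))
                offsets.append(idx)
        if rows:
            self.windows = np.concatenate(rows)  # n_win x W, int8
            self.owners = np.concatenate(owners)
            self.offsets = np.concatenate(offsets)
        else:
            self.windows = np.empty((0, width), dtype=np.int8)
            self.owners = np.empty(0, dtype=int)
            self.offsets = np.empty(0, dtype=int)
        self.n_regions = len(encoded)
        # contiguous segments per region (owners are nondecreasing)
        self.seg_bounds = np.searchsorted(self.owners, np.arange(self.n_regions + 1))
        self.onehot = np.zeros((len(self.windows), width * 4), dtype=np.float32)
        if len(self.windows):
            flat = self.windows.astype(np.int64) + 4 * np.arange(width)[None, :]
            np.put_along_axis(
                self.onehot, flat.astype(np.int64), 1.0, axis=1
            )

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def region_window_counts(self) -> np.ndarray:
        return np.diff(self.seg_bounds)

    def segment_logsumexp(self, values: np.ndarray) -> np.ndarray:
        """logsumexp of ``values`` (n_win[, k]) grouped by owning region.

        Regions without windows get -inf.
        """
        shape = (self.n_regions,) + values.shape[1:]
        out = np.full(shape, -np.inf)
        for r in range(self.n_regions):
            a, b = self.seg_bounds[r], self.seg_bounds[r + 1]
            if b > a:
                out[r] = logsumexp(values[a:b], axis=0)
        return out


def _window_scores_bits(ws: _WindowSet, probs: np.ndarray, bg: np.ndarray) -> np.ndarray:
    llr = np.log2(probs) - np.log2(bg)[None, :]
    return ws.onehot @ llr.astype(np.float32).reshape(-1)


# ---------------------------------------------------------------------------
# Seeding


def _best_seed(ws: _WindowSet, background: BackgroundModel, config: DiscoveryConfig):
    """Evaluate every window as a one-site seed; return the best window index.

    A seed's objective is the ZOOPS log-likelihood (relative to background)
    with the seed's single-site PWM and a fixed site prior ``seed_gamma``.
    The seed PWM gives every matching base log-odds m(b) and every mismatch a
    constant value, so all seed-vs-window scores reduce to one weighted
    inner product of one-hot encodings (a single matrix multiply).
    """
    bg = background.array
    pc = config.pseudocount
    mismatch = np.log2(pc / (1.0 + pc))
    match = np.log2((1.0 + pc * bg) / (1.0 + pc)) - np.log2(bg)
    weights = (match - mismatch).astype(np.float32)  # per base
    W = ws.width
    weighted = ws.onehot * np.tile(weights, W)[None, :]
    scores = ws.onehot @ weighted.T  # n_win x n_seeds, bits above W*mismatch
    scores = scores.astype(np.float64) * 1.0 + W * mismatch
    ln_scores = scores * _LN2
    lse = ws.segment_logsumexp(ln_scores)  # n_regions x n_seeds
    n_win = ws.region_window_counts().astype(float)
    gamma = config.seed_gamma
    with np.errstate(divide="ignore"):
        logj = np.where(n_win > 0, np.log(np.maximum(n_win, 1.0)), 0.0)
        site_term = np.where(n_win[:, None] > 0, lse - logj[:, None], -np.inf)
        obj = np.sum(
            np.logaddexp(np.log1p(-gamma), np.log(gamma) + site_term), axis=0
        )
    return int(np.argmax(obj))


# ---------------------------------------------------------------------------
# EM


def _em_iteration(ws: _WindowSet, probs: np.ndarray, gamma: float,
                  background: BackgroundModel, pseudocount: float):
    """One ZOOPS E+M step on prebuilt window structures."""
    bg = background.array
    scores_ln = _window_scores_bits(ws, probs, bg).astype(np.float64) * _LN2
    n_win = ws.region_window_counts().astype(float)
    lse = ws.segment_logsumexp(scores_ln)
    with np.errstate(divide="ignore"):
        logj = np.where(n_win > 0, np.log(np.maximum(n_win, 1.0)), 0.0)
        site_term = np.where(n_win > 0, lse - logj, -np.inf)
        log_denom = np.logaddexp(np.log1p(-gamma), np.log(gamma) + site_term)
    loglik = float(np.sum(log_denom))
    # posterior that window j of region r is the site
    z = np.exp(
        np.log(gamma)
        - logj[ws.owners]
        + scores_ln
        - log_denom[ws.owners]
    )
    counts = (ws.onehot.T @ z.astype(np.float32)).astype(np.float64).reshape(ws.width, 4)
    new_probs = pwm_probs_from_counts(counts, background, pseudocount)
    q_per_region = np.zeros(ws.n_regions)
    np.add.at(q_per_region, ws.owners, z)
    active = n_win > 0
    new_gamma = float(np.clip(q_per_region[active].mean(), 1e-6, 1.0 - 1e-6))
    return new_probs, new_gamma, loglik, counts, z


def em_step(pwm: PWMMotif, lam: float, regions, background: BackgroundModel):
    """Public single ZOOPS EM step.

    Returns (updated PWMMotif, updated lambda, log-likelihood of the inputs
    relative to the pure-background model). The likelihood sequence across
    successive calls is nondecreasing (standard EM guarantee).
    """
    if not (0.0 < lam < 1.0):
        raise ValueError("lambda must be in (0, 1)")
    encoded = [encode(r.sequence) for r in regions]
    ids = [r.gene_id for r in regions]
    ws = _WindowSet(encoded, ids, pwm.width)
    probs, gamma, loglik, counts, _ = _em_iteration(
        ws, pwm.probs, lam, background, pwm.pseudocount
    )
    new_pwm = PWMMotif(
        motif_id=pwm.motif_id,
        counts=counts,
        probs=probs,
        background=background,
        pseudocount=pwm.pseudocount,
    )
    return new_pwm, gamma, loglik


def _run_em(ws: _WindowSet, seed_index: int, background: BackgroundModel,
            config: DiscoveryConfig):
    """Run EM to convergence from a one-site seed; return (loglik, probs, gamma, z)."""
    bg = background.array
    pc = config.pseudocount
    seed = ws.windows[seed_index]
    counts = np.zeros((ws.width, 4))
    counts[np.arange(ws.width), seed] = 1.0
    probs = pwm_probs_from_counts(counts, background, pc)
    gamma = config.seed_gamma
    prev = -np.inf
    z = None
    for _ in range(config.em_max_iter):
        probs, gamma, loglik, counts, z = _em_iteration(ws, probs, gamma, background, pc)
        if np.isfinite(prev) and abs(loglik - prev) <= config.em_tol * max(abs(prev), 1.0):
            prev = loglik
            break
        prev = loglik
    return prev, probs, gamma, z


# ---------------------------------------------------------------------------
# Discovery driver


def discover_motifs(
    regions: list[UpstreamRegion],
    config: DiscoveryConfig | None = None,
    background: BackgroundModel | None = None,
    motif_prefix: str = "motif",
) -> list[MotifResult]:
    """Find up to ``config.n_motifs`` conserved motifs in a region set.

    Deterministic: exhaustive-substring seeding, ZOOPS EM per width on the
    grid, width chosen by converged likelihood, then exact-p-value site
    retention and N-masking before the next round.
    """
    config = config or DiscoveryConfig()
    usable = [r for r in regions if r.length >= config.w_min]
    if len(usable) < config.min_sequences:
        raise DiscoveryError(
            f"need at least {config.min_sequences} regions of length >= "
            f"{config.w_min}, got {len(usable)}"
        )
    if background is None:
        background = build_background(usable)
    encoded = [encode(r.sequence) for r in usable]
    ids = [r.gene_id for r in usable]

    results: list[MotifResult] = []
    for round_idx in range(config.n_motifs):
        best = None  # (loglik, width, probs, gamma, z, ws)
        for width in config.widths:
            ws = _WindowSet(encoded, ids, width)
            counts_per_region = ws.region_window_counts()
            if int(np.sum(counts_per_region > 0)) < config.min_sequences:
                continue
            seed_idx = _best_seed(ws, background, config)
            loglik, probs, gamma, z = _run_em(ws, seed_idx, background, config)
            if best is None or loglik > best[0]:
                best = (loglik, width, probs, gamma, z, ws)
        if best is None:
            break
        loglik, width, probs, gamma, z, ws = best

        em_pwm = PWMMotif(
            motif_id=f"{motif_prefix}_{round_idx + 1}",
            counts=probs * 0.0,
            probs=probs,
            background=background,
            pseudocount=config.pseudocount,
        )
        # candidate site per region: maximum-posterior window (ZOOPS)
        candidates: list[MotifSite] = []
        for r in range(ws.n_regions):
            a, b = ws.seg_bounds[r], ws.seg_bounds[r + 1]
            if b <= a:
                continue
            j = a + int(np.argmax(z[a:b]))
            word = decode(ws.windows[j])
            p = word_pvalue(em_pwm, word, config.granularity)
            if p < config.site_p_threshold:
                candidates.append(
                    MotifSite(
                        region_id=ids[r],
                        offset=int(ws.offsets[j]),
                        sequence=word,
                        score=score_word(em_pwm, word),
                        p_value=p,
                    )
                )
        if len(candidates) < 2:
            break

        # final PWM rebuilt from the retained sites themselves
        final = build_pwm(
            [c.sequence for c in candidates],
            background,
            pseudocount=config.pseudocount,
            motif_id=f"{motif_prefix}_{round_idx + 1}",
            site_ids=[c.region_id for c in candidates],
        )
        sites = [
            MotifSite(
                region_id=c.region_id,
                offset=c.offset,
                sequence=c.sequence,
                score=score_word(final, c.sequence),
                p_value=word_pvalue(final, c.sequence, config.granularity),
            )
            for c in candidates
        ]
        sites.sort(key=lambda s: (s.p_value, s.region_id))
        results.append(
            MotifResult(
                pwm=final,
                sites=sites,
                zoops_lambda=gamma,
                log_likelihood=loglik,
                passed_threshold=len(sites) >= 2,
            )
        )
        # mask retained sites before the next round
        id_to_index = {g: i for i, g in enumerate(ids)}
        for s in sites:
            enc = encoded[id_to_index[s.region_id]]
            enc[s.offset : s.offset + final.width] = 4
    return results
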