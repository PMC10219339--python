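"""Binding-site motif discovery (ZOOPS EM), PWM scanning, and site geometry.

The finder fits a zero-or-one-occurrence-per-sequence (ZOOPS) mixture by
expectation-maximisation: each sequence either contains no site (probability
1 - gamma) or exactly one site at an unknown offset and strand, uniform a
priori over positions. The E-step computes site-position posteriors under
the current position weight matrix (PWM) against a 0-order background; the
M-step re-estimates the PWM from posterior-weighted counts (with
pseudocounts) and the site prior gamma. Multiple seeded restarts are run
and the best final log likelihood wins. Scanning scores log2-odds
(PWM vs background) at every offset on both strands.

Notes on scope: this is a self-contained ZOOPS finder, not a full motif
suite — no multiple-motif erasure and no analytical E-value statistics;
the objective reported is the data log likelihood plus total information
content.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"
_IDX = {c: i for i, c in enumerate(ALPHABET)}
# IUPAC codes for base pairs, used when no single base dominates a column
_IUPAC_PAIRS = {
    frozenset("AC"): "M", frozenset("AG"): "R", frozenset("AT"): "W",
    frozenset("CG"): "S", frozenset("CT"): "Y", frozenset("GT"): "K",
}


class MotifError(ValueError):
    pass


def encode(seq: str) -> np.ndarray:
    """Map ACGT to 0..3; anything else (treated as N) to 4."""
    return np.array([_IDX.get(c, 4) for c in seq.upper()], dtype=np.int8)


def revcomp(seq: str) -> str:
    return seq.upper().translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


@dataclass(frozen=True)
class Pwm:
    """Position probability matrix over ACGT with its estimation context."""

    probs: np.ndarray  # (width, 4), rows sum to 1
    background: np.ndarray  # (4,), sums to 1
    pseudocount: float = 0.25
    n_sites: float = 0.0  # expected number of contributing sites

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or p.shape[1] != 4:
            raise MotifError("probs must be a width x 4 matrix")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
            raise MotifError("PWM rows must sum to 1")
        if self.pseudocount > 0 and np.any(p <= 0):
            raise MotifError("PWM entries must be positive with a pseudocount")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    def reverse_complement(self) -> "Pwm":
        return Pwm(
            probs=self.probs[::-1, ::-1].copy(),
            background=self.background[::-1].copy(),
            pseudocount=self.pseudocount,
            n_sites=self.n_sites,
        )

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in np.argmax(self.probs, axis=1))


@dataclass(frozen=True)
class SiteHit:
    sequence_id: str
    offset: int  # 0-based within the scanned sequence
    strand: str
    score: float  # log2-odds (bits)
    position_vs_anchor: float | None = None  # site centre minus anchor, bp


@dataclass
class MotifResult:
    pwm: Pwm
    # log likelihood of the winning restart, relative to the background-only
    # model (the per-base background terms cancel in the mixture)
    log_likelihood: float
    # per-iteration EM objective (log likelihood + Dirichlet log prior from
    # the pseudocounts) of the winning restart; non-decreasing by EM theory
    ll_trace: list[float]
    site_prior: float
    site_posteriors: list[float]  # per-sequence probability a site is present
    best_sites: list[SiteHit]  # per-sequence MAP site under the model
    # shuffled-sequence calibration: the same EM on per-sequence shuffles;
    # a fit not clearly above this chance level is flagged insignificant
    null_log_likelihood: float | None = None
    significant: bool = True


def _background_from(seqs: list[np.ndarray]) -> np.ndarray:
    counts = np.ones(4)  # one pseudo-observation per base
    for s in seqs:
        valid = s[s < 4]
        counts += np.bincount(valid, minlength=4)
    return counts / counts.sum()


def _window_log_ratios(
    enc: np.ndarray, log_odds_fwd: np.ndarray, log_odds_rev: np.ndarray
) -> np.ndarray:
    """Log-likelihood ratio (site vs background) at every (strand, offset).

    Returns a (2, m) array; N positions contribute zero (scored as
    background on both hypotheses).
    """
    w = log_odds_fwd.shape[0]
    m = enc.size - w + 1
    # score tables indexed [base, position]; base 4 (N) scores 0
    table_f = np.vstack([log_odds_fwd.T, np.zeros(w)])
    table_r = np.vstack([log_odds_rev.T, np.zeros(w)])
    idx = np.lib.stride_tricks.sliding_window_view(enc, w)  # (m, w)
    cols = np.arange(w)
    out = np.empty((2, m))
    out[0] = table_f[idx, cols].sum(axis=1)
    out[1] = table_r[idx, cols].sum(axis=1)
    return out


def _em_once(
    encs: list[np.ndarray],
    width: int,
    background: np.ndarray,
    init_probs: np.ndarray,
    site_prior: float,
    pseudocount: float,
    max_iter: int,
    tol: float,
    both_strands: bool,
) -> tuple[np.ndarray, float, list[float], float, list[np.ndarray]]:
    probs = init_probs.copy()
    gamma = site_prior
    log_bg = np.log(background)
    # the EM-monotone objective is the data log likelihood plus the
    # Dirichlet(1 + pseudocount) log prior implied by the smoothed M-step
    obj_trace: list[float] = []
    ll = -np.inf
    n_strands = 2 if both_strands else 1
    posteriors: list[np.ndarray] = []
    for _ in range(max_iter):
        log_odds = np.log(probs) - log_bg[None, :]
        log_odds_rc = log_odds[::-1, ::-1]
        ll = 0.0
        new_counts = np.full((width, 4), pseudocount)
        gamma_sum = 0.0
        posteriors = []
        for enc in encs:
            m = enc.size - width + 1
            ratios = _window_log_ratios(enc, log_odds, log_odds_rc)[:n_strands]
            # mixture: no-site vs site at each (strand, offset)
            flat = ratios.ravel()
            prior_site = gamma / (n_strands * m)
            a = np.log1p(-gamma) if gamma < 1 else -np.inf
            b = np.log(prior_site) + flat
            mx = max(a, b.max())
            denom = np.exp(a - mx) + np.exp(b - mx).sum()
            ll += mx + np.log(denom)
            z = np.exp(b - mx) / denom  # posterior over (strand, offset)
            z = z.reshape(n_strands, m)
            posteriors.append(z)
            gamma_sum += z.sum()
            # accumulate PWM counts (N bases excluded)
            idx = np.lib.stride_tricks.sliding_window_view(enc, width)  # (m, w)
            for s in range(n_strands):
                weights = z[s]
                if weights.sum() < 1e-12:
                    continue
                onehot_counts = np.zeros((width, 4))
                for a_ in range(4):
                    onehot_counts[:, a_] = (weights[:, None] * (idx == a_)).sum(axis=0)
                if s == 1:
                    onehot_counts = onehot_counts[::-1, ::-1]
                new_counts += onehot_counts
        prior_term = float(pseudocount * np.log(probs).sum()) if pseudocount > 0 else 0.0
        obj_trace.append(ll + prior_term)
        new_probs = new_counts / new_counts.sum(axis=1, keepdims=True)
        new_gamma = min(max(gamma_sum / len(encs), 1e-6), 1 - 1e-6)
        if len(obj_trace) >= 2 and abs(obj_trace[-1] - obj_trace[-2]) < tol:
            probs, gamma = new_probs, new_gamma
            break
        probs, gamma = new_probs, new_gamma
    return probs, gamma, obj_trace, ll, posteriors


def _shifted_init(
    encs: list[np.ndarray],
    width: int,
    posteriors: list[np.ndarray],
    delta: int,
    pseudocount: float,
) -> np.ndarray | None:
    """Initial PWM from the MAP site alignment shifted by ``delta`` columns.

    Used to escape register (phase) local optima: EM converged one or two
    columns off the true window keeps the alignment but not the frame, so
    re-seeding from the shifted alignment lets a further EM run compare
    frames on likelihood.
    """
    counts = np.full((width, 4), max(pseudocount, 1e-3))
    n_used = 0
    for enc, z in zip(encs, posteriors):
        if z.sum() < 0.5:
            continue
        s, j = np.unravel_index(np.argmax(z), z.shape)
        j2 = j + delta if s == 0 else j - delta
        if not (0 <= j2 <= enc.size - width):
            continue
        window = enc[j2 : j2 + width]
        onehot = np.zeros((width, 4))
        for k, b in enumerate(window):
            if b < 4:
                onehot[k, b] = 1.0
        if s == 1:
            onehot = onehot[::-1, ::-1]
        counts += onehot
        n_used += 1
    if n_used == 0:
        return None
    return counts / counts.sum(axis=1, keepdims=True)


def _seed_init(enc: np.ndarray, off: int, width: int) -> np.ndarray:
    """Smoothed one-hot PWM from the w-mer at ``off`` (classic EM seeding)."""
    init = np.full((width, 4), 0.5 / 3)
    for k, b in enumerate(enc[off : off + width]):
        if b < 4:
            init[k, b] = 0.5
        else:
            init[k] = 0.25
    return init


def _quick_ll(
    encs: list[np.ndarray],
    width: int,
    background: np.ndarray,
    probs: np.ndarray,
    gamma: float,
    n_strands: int,
) -> float:
    """Mixture log likelihood (vs background) of a PWM without any M-step."""
    log_odds = np.log(probs) - np.log(background)[None, :]
    log_odds_rc = log_odds[::-1, ::-1]
    ll = 0.0
    for enc in encs:
        m = enc.size - width + 1
        ratios = _window_log_ratios(enc, log_odds, log_odds_rc)[:n_strands]
        a = np.log1p(-gamma)
        b = np.log(gamma / (n_strands * m)) + ratios.ravel()
        mx = max(a, b.max())
        ll += mx + np.log(np.exp(a - mx) + np.exp(b - mx).sum())
    return float(ll)


def _run_restarts(
    encs: list[np.ndarray],
    width: int,
    background: np.ndarray,
    rng: np.random.Generator,
    n_starts: int,
    site_prior: float,
    pseudocount: float,
    max_iter: int,
    tol: float,
    both_strands: bool,
    n_candidates: int = 200,
):
    """Starting-point search followed by full EM from the best seeds.

    Candidate w-mer seeds are taken at a deterministic stride across every
    sequence (phase randomised by ``rng``), scored by a single E-step, and
    the top ``n_starts`` are run to convergence.
    """
    n_strands = 2 if both_strands else 1
    windows = [(i, off) for i, enc in enumerate(encs)
               for off in range(enc.size - width + 1)]
    stride = max(1, len(windows) // n_candidates)
    phase = int(rng.integers(stride))
    scored = []
    for i, off in windows[phase::stride]:
        init = _seed_init(encs[i], off, width)
        scored.append((_quick_ll(encs, width, background, init, site_prior,
                                 n_strands), i, off))
    scored.sort(reverse=True)
    best = None
    for _, i, off in scored[: max(1, n_starts)]:
        result = _em_once(
            encs, width, background, _seed_init(encs[i], off, width),
            site_prior, pseudocount, max_iter, tol, both_strands,
        )
        if best is None or result[3] > best[3]:
            best = result
    return best


def discover_motif(
    sequences: Sequence[str] | Mapping[str, str],
    width: int,
    n_starts: int = 5,
    seed: int | None = None,
    max_iter: int = 200,
    tol: float = 1e-6,
    both_strands: bool = True,
    site_prior: float = 0.8,
    pseudocount: float = 0.25,
    calibrate: bool = True,
    significance_factor: float = 1.5,
) -> MotifResult:
    """Fit a ZOOPS motif model of the given width by seeded EM restarts.

    Each restart is seeded from a random w-mer drawn from the data
    (smoothed towards uniform) — the classic subsequence-seeding strategy —
    and the winner is refined against small register shifts. With
    ``calibrate`` the winning likelihood is compared against the same fit
    on per-sequence shuffles; when it does not exceed the chance level by
    ``significance_factor`` the input carries no consistent motif and the
    returned matrix is flattened to the background composition (an
    information content near zero), flagged ``significant=False``.

    Deterministic for a fixed ``seed``. Non-ACGT characters are treated as
    N: they score as background and are excluded from count estimation.
    """
    if isinstance(sequences, Mapping):
        ids = list(sequences.keys())
        seqs = [sequences[k] for k in ids]
    else:
        ids = [f"seq{i}" for i in range(len(sequences))]
        seqs = list(sequences)
    if width < 4:
        raise MotifError("motif width must be at least 4")
    if len(seqs) < 5:
        raise MotifError("need at least 5 sequences")
    usable = [(i, s) for i, s in enumerate(seqs) if len(s) >= width]
    if not usable:
        raise MotifError("all sequences shorter than the motif width")
    if len(usable) < len(seqs):
        logger.warning(
            "%d sequence(s) shorter than width %d ignored",
            len(seqs) - len(usable), width,
        )
    if any(set(s.upper()) - set("ACGT") for _, s in usable):
        logger.warning("non-ACGT characters present; treated as N")

    encs = [encode(s) for _, s in usable]
    background = _background_from(encs)
    rng = np.random.default_rng(seed)

    best = _run_restarts(
        encs, width, background, rng, n_starts, site_prior, pseudocount,
        max_iter, tol, both_strands,
    )

    # register refinement: challenge the winner with +/-1..2 column shifts
    # seeded from its MAP alignment, keeping the best data likelihood;
    # sweeps repeat (against a fixed base per pass) until no shift improves
    for _ in range(3):
        base = best
        for delta in (-2, -1, 1, 2):
            init = _shifted_init(encs, width, base[4], delta, pseudocount)
            if init is None:
                continue
            shifted = _em_once(
                encs, width, background, init, base[1], pseudocount,
                max_iter, tol, both_strands,
            )
            if shifted[3] > best[3]:
                best = shifted
        if best is base:
            break
    probs, gamma, ll_trace, ll, posteriors = best

    null_ll = None
    significant = True
    if calibrate:
        shuffled = [
            "".join(rng.permutation(list(s))) for _, s in usable
        ]
        null_encs = [encode(s) for s in shuffled]
        null_best = _run_restarts(
            null_encs, width, background, rng, min(2, max(1, n_starts)),
            site_prior, pseudocount, max_iter, tol, both_strands,
        )
        null_ll = float(null_best[3])
        significant = ll > significance_factor * max(null_ll, 1e-9)
        if not significant:
            logger.warning(
                "motif fit not above chance (LL %.1f vs shuffled %.1f); "
                "returning background-level matrix", ll, null_ll,
            )
            probs = np.tile(background, (width, 1))

    pwm = Pwm(
        probs=probs, background=background, pseudocount=pseudocount,
        n_sites=float(sum(z.sum() for z in posteriors)),
    )
    presence: list[float] = []
    best_sites: list[SiteHit] = []
    for (orig_i, seq), z in zip(usable, posteriors):
        presence.append(float(z.sum()))
        s, j = np.unravel_index(np.argmax(z), z.shape)
        best_sites.append(
            SiteHit(
                sequence_id=ids[orig_i], offset=int(j),
                strand="+" if s == 0 else "-", score=float(z[s, j]),
            )
        )
    return MotifResult(
        pwm=pwm, log_likelihood=float(ll), ll_trace=[float(x) for x in ll_trace],
        site_prior=float(gamma), site_posteriors=presence, best_sites=best_sites,
        null_log_likelihood=null_ll, significant=significant,
    )


def log_odds_matrix(pwm: Pwm) -> np.ndarray:
    """Per-position log2(p/background), the additive scanning score."""
    return np.log2(pwm.probs) - np.log2(pwm.background)[None, :]


def scan_best_site(
    pwm: Pwm,
    sequence: str,
    both_strands: bool = True,
    sequence_id: str = "seq",
    anchor_index: float | None = None,
) -> SiteHit:
    """Best log2-odds window over all offsets (and strands if enabled).

    Ties break to the smallest offset with the + strand first. N positions
    score zero. ``anchor_index`` (0-based position of the TSS/start codon
    within the sequence) converts the hit into a signed position of the
    site centre relative to that anchor, negative meaning upstream.
    """
    w = pwm.width
    if len(sequence) < w:
        raise MotifError("sequence shorter than motif width")
    enc = encode(sequence)
    lo = log_odds_matrix(pwm)
    strands = [("+", _scan_scores(enc, lo))]
    if both_strands:
        strands.append(("-", _scan_scores(enc, lo[::-1, ::-1])))
    top = max(float(sc.max()) for _, sc in strands)
    # tie-break: smallest offset wins, then + strand before -
    candidates = [
        (int(off), si, strand)
        for si, (strand, sc) in enumerate(strands)
        for off in np.nonzero(sc >= top - 1e-12)[0]
    ]
    best_off, best_si, best_strand = min(candidates)
    best_score = float(strands[best_si][1][best_off])
    pos = None
    if anchor_index is not None:
        pos = float(best_off + (w - 1) / 2.0 - anchor_index)
    return SiteHit(
        sequence_id=sequence_id, offset=best_off, strand=best_strand,
        score=best_score, position_vs_anchor=pos,
    )


def _scan_scores(enc: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    w = log_odds.shape[0]
    # (w, 5) score table: base 4 (N) scores 0 at every position
    table = np.hstack([log_odds, np.zeros((w, 1))])
    idx = np.lib.stride_tricks.sliding_window_view(enc, w)  # (m, w)
    return table[np.arange(w)[None, :], idx].sum(axis=1)


def site_position_summary(
    positions_by_group: Mapping[str, Sequence[float]],
) -> dict[str, dict]:
    """Box statistics (median, quartiles, range, n) per group of site positions."""
    out: dict[str, dict] = {}
    for group, positions in positions_by_group.items():
        arr = np.asarray(list(positions), dtype=float)
        if arr.size == 0:
            logger.warning("group %r has no site positions; omitted", group)
            continue
        q1, med, q3 = np.percentile(arr, [25, 50, 75])
        out[group] = {
            "median": float(med), "q1": float(q1), "q3": float(q3),
            "min": float(arr.min()), "max": float(arr.max()), "n": int(arr.size),
        }
    return out


def palindromicity(pwm: Pwm) -> float:
    """Self-reverse-complementarity of a PWM, in [0, 1].

    One minus the mean per-column total-variation distance between the
    matrix and its reverse complement; 1 means perfectly palindromic
    (dyad-symmetric), 0 maximally asymmetric.
    """
    rc = pwm.probs[::-1, ::-1]
    tv = 0.5 * np.abs(pwm.probs - rc).sum(axis=1)
    return float(1.0 - tv.mean())


def consensus_and_ic(pwm: Pwm, use_background: bool = False) -> dict:
    """IUPAC consensus string and per-column information content (bits).

    Uniform-background IC (2 + sum p log2 p) by default; relative entropy
    against the PWM's stored background when ``use_background`` is set.
    A column's IUPAC letter is the top base if its probability is >= 0.5,
    else a two-base degenerate code if the top pair reaches 0.75, else N.
    """
    p = pwm.probs
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    if use_background:
        bits = (np.where(p > 0, p * np.log2(p / pwm.background[None, :]), 0.0)).sum(axis=1)
    else:
        bits = 2.0 + plogp.sum(axis=1)
    letters = []
    for row in p:
        order = np.argsort(row)[::-1]
        if row[order[0]] >= 0.5:
            letters.append(ALPHABET[order[0]])
        elif row[order[0]] + row[order[1]] >= 0.75:
            pair = frozenset(ALPHABET[order[0]] + ALPHABET[order[1]])
            letters.append(_IUPAC_PAIRS[pair])
        else:
            letters.append("N")
    return {
        "iupac_string": "".join(letters),
        "per_column_bits": [float(b) for b in bits],
        "total_bits": float(bits.sum()),
    }


def write_meme_motif(
    pwms: Mapping[str, Pwm] | Iterable[tuple[str, Pwm]], handle: TextIO
) -> None:
    """Write PWMs in MEME minimal motif format for external logo renderers."""
    items = pwms.items() if isinstance(pwms, Mapping) else pwms
    items = list(items)
    handle.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
    if items:
        bg = items[0][1].background
        handle.write(
            "Background letter frequencies\n"
            + " ".join(f"{b} {f:.4f}" for b, f in zip(ALPHABET, bg))
            + "\n\n"
        )
    for name, pwm in items:
        handle.write(f"MOTIF {name}\n")
        handle.write(
            f"letter-probability matrix: alength= 4 w= {pwm.width} "
            f"nsites= {max(1, round(pwm.n_sites))} E= 0\n"
        )
        for row in pwm.probs:
            handle.write(" ".join(f"{x:.6f}" for x in row) + "\n")
        handle.write("\n")
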