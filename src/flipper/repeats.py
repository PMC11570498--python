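"""Tandem-repeat detection in the 20-120-residue period band.

Linker proteins cross-link Rubisco holoenzymes with sticker motifs spaced
20-120 residues apart (~2-8 nm), so the screen looks specifically for
tandem repeats whose unit length falls in that band.  The detector is a
seed-and-refine scheme over candidate periods:

1. *Seed*: for each period p, the lag-p self-match profile is scanned
   with p-wide windows; dense windows mark candidate regions.  The window
   threshold is ``2*min_identity - 1``, the pairwise agreement guaranteed
   between two copies that each match a common consensus at
   ``min_identity`` — so any repeat the scorer would accept can seed.
2. *Refine*: within each seeded region every decomposition
   (start, copy count, optional trailing partial copy) is scored exactly:
   the consensus is the column-wise majority over the copies (ties to the
   alphabetically first residue) and the score is the total number of
   consensus-matching residues, ``copies * period * identity``.  The
   best-scoring valid decomposition wins.
3. *Resolve*: harmonic hits (period a multiple of a covering hit's, with
   comparable identity) are suppressed, then overlaps are resolved
   greedily by score (ties: smaller period, then smaller start).

A valid decomposition needs >= ``min_copies`` copies (a trailing partial
counts fractionally when it spans at least half a period), overall and
boundary-copy identity >= ``min_identity``, and a consensus with >=
``min_distinct`` distinct residues (the low-complexity guard, which also
rejects short-period repeats surfacing at harmonic lags inside the band).
The model is substitution-only: no indels within units, matching the
near-equal-length repeat units of the known linkers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class RepeatConfig:
    """Detector parameters.

    The 20-120 period band is the Rubisco cross-linking length scale;
    ``min_copies`` 3 is the minimum valence for condensation; identity,
    distinct-residue and jitter settings are declared defaults.
    """

    period_min: int = 20
    period_max: int = 120
    min_copies: float = 3.0
    min_identity: float = 0.7
    min_distinct: int = 5
    jitter: int = 2

    def __post_init__(self) -> None:
        if not 2 <= self.period_min <= self.period_max:
            raise ValueError("need 2 <= period_min <= period_max")
        if self.min_copies < 2:
            raise ValueError("min_copies must be >= 2")
        if not 0.0 < self.min_identity <= 1.0:
            raise ValueError("min_identity must be in (0, 1]")


@dataclass(frozen=True)
class RepeatHit:
    """One detected tandem-repeat region.

    ``start``/``end`` are 0-based half-open (reports convert to 1-based
    inclusive via ``start_1``/``end_1``).  ``copies`` may carry a
    fractional trailing copy; ``identity`` is the length-weighted mean
    per-copy fraction of matches to the consensus; ``matches`` is the
    integer count of consensus-matching residues, which equals
    ``copies * period * identity`` and serves as the exact score.
    """

    start: int
    end: int
    period: int
    copies: float
    consensus: str
    identity: float
    matches: int

    @property
    def score(self) -> float:
        return float(self.matches)

    @property
    def start_1(self) -> int:
        return self.start + 1

    @property
    def end_1(self) -> int:
        return self.end

    def overlaps(self, other: "RepeatHit") -> bool:
        return min(self.end, other.end) > max(self.start, other.start)

    def span_overlap(self, other: "RepeatHit") -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def periodicity_profile(seq: str, p: int) -> list[int]:
    """Lag-p self-match indicators: ``m[i] = 1`` iff ``seq[i] == seq[i+p]``."""
    if not 1 <= p < len(seq):
        raise ValueError(f"lag {p} outside [1, {len(seq) - 1}]")
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return (arr[:-p] == arr[p:]).astype(int).tolist()


def _refine_region(seq: str, lo: int, hi: int, p: int,
                   cfg: RepeatConfig) -> RepeatHit | None:
    """Exhaustively score every (start, copies, partial) decomposition of
    period p inside ``seq[lo:hi]`` and return the best valid one.

    The search is bounded: starts are visited left to right and abandoned
    once the remaining region cannot out-score the current best (a score
    can never exceed the region length).
    """
    sub = np.frombuffer(seq[lo:hi].encode("ascii"), dtype=np.uint8)
    L = sub.size
    if L < 2 * p:
        return None
    mi = cfg.min_identity
    alphabet = np.unique(sub)  # sorted, so argmax ties fall alphabetically
    if alphabet.size < cfg.min_distinct:
        return None  # no consensus over this region can pass the guard
    lut = np.zeros(256, dtype=np.int64)
    lut[alphabet] = np.arange(alphabet.size)
    codes = lut[sub]
    arange_a = np.arange(alphabet.size)

    best: tuple | None = None  # ((-matches, total_len, s0), c, cons_codes)
    for s0 in range(0, L - 2 * p + 1):
        avail = L - s0
        if best is not None and avail < -best[0][0]:
            break  # a decomposition can never out-score its own length
        c_max = avail // p
        units = codes[s0: s0 + c_max * p].reshape(c_max, p)
        counts = np.cumsum(units[:, :, None] == arange_a[None, None, :], axis=0)
        for c in range(2, c_max + 1):
            cons = np.argmax(counts[c - 1], axis=-1)
            ids = (units[:c] == cons).sum(axis=1)
            if ids[0] / p < mi or ids[c - 1] / p < mi:
                continue
            # best trailing partial copy: >= half a period, identity >= mi,
            # maximal matches (smallest length on ties)
            e = s0 + c * p
            tail = codes[e: min(e + p - 1, L)]
            r_best = mt_best = 0
            if tail.size:
                cum = np.cumsum(tail == cons[:tail.size])
                for r in range((p + 1) // 2, tail.size + 1):
                    mt = int(cum[r - 1])
                    if mt / r >= mi and mt > mt_best:
                        r_best, mt_best = r, mt
            total_len = c * p + r_best
            total_match = int(ids.sum()) + mt_best
            if total_match / total_len < mi:
                continue
            if total_len / p < cfg.min_copies:
                continue
            if np.unique(cons).size < cfg.min_distinct:
                continue
            key = (-total_match, total_len, s0)
            if best is None or key < best[0]:
                best = (key, c, cons.copy())
    if best is None:
        return None
    (neg_match, total_len, s0), c, cons = best
    matches = -neg_match
    consensus = "".join(chr(alphabet[i]) for i in cons)
    return RepeatHit(start=lo + s0, end=lo + s0 + total_len, period=p,
                     copies=total_len / p, consensus=consensus,
                     identity=matches / total_len, matches=matches)


def _sort_key(h: RepeatHit) -> tuple:
    # score, then smaller period, then tighter span, then earlier start
    return (-h.matches, h.period, h.end - h.start, h.start)


def _suppress_harmonics(hits: list[RepeatHit], cfg: RepeatConfig) -> list[RepeatHit]:
    """Drop a hit at period ~k*p when a hit at the fundamental period p
    covers >= 80% of its span with identity within 0.05."""
    keep = []
    for h in hits:
        doomed = False
        for g in hits:
            if g is h or g.period >= h.period:
                continue
            k = round(h.period / g.period)
            if k < 2 or abs(h.period - k * g.period) > cfg.jitter:
                continue
            span = h.end - h.start
            # the fundamental explains the harmonic when it covers the
            # span with comparable or better identity (a harmonic padded
            # with flank junk scores longer but dirtier)
            if span and g.span_overlap(h) >= 0.8 * span and \
                    g.identity >= h.identity - 0.05:
                doomed = True
                break
        if not doomed:
            keep.append(h)
    return keep


def _resolve_overlaps(hits: list[RepeatHit]) -> list[RepeatHit]:
    kept: list[RepeatHit] = []
    for h in sorted(hits, key=_sort_key):
        if not any(h.overlaps(g) for g in kept):
            kept.append(h)
    return kept


def find_tandem_repeats(seq: str, cfg: RepeatConfig | None = None) -> list[RepeatHit]:
    """Detect tandem repeats with period inside the configured band.

    Returns non-overlapping hits sorted by start position; an empty list
    when nothing passes (including sequences shorter than two minimal
    periods).  Deterministic: identical sequence and config give an
    identical hit list.
    """
    cfg = cfg or RepeatConfig()
    n = len(seq)
    if n < 2 * cfg.period_min:
        return []
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    seed_thresh = max(0.0, 2.0 * cfg.min_identity - 1.0)
    candidates: list[RepeatHit] = []
    p_hi = min(cfg.period_max, n // 2)
    for p in range(cfg.period_min, p_hi + 1):
        m = (arr[:-p] == arr[p:]).astype(np.int32)
        if m.size < p:
            continue
        csum = np.concatenate(([0], np.cumsum(m)))
        wmeans = (csum[p:] - csum[:-p]) / p
        ok = wmeans >= seed_thresh
        if not ok.any():
            continue
        # maximal runs of qualifying window starts; runs separated by at
        # most one period merge, since one mutated column can depress up
        # to p consecutive windows inside a real repeat
        idx = np.flatnonzero(ok)
        breaks = np.flatnonzero(np.diff(idx) > p)
        run_starts = np.concatenate(([0], breaks + 1))
        run_ends = np.concatenate((breaks, [idx.size - 1]))
        for rs, re in zip(run_starts, run_ends):
            a, b = int(idx[rs]), int(idx[re])
            covered = (b - a) + p  # matched stretch of the lag profile
            if covered < (cfg.min_copies - 1) * p:
                continue
            # margins admit one junk interior copy plus a good copy and a
            # trailing partial beyond the windowed stretch on either side
            hit = _refine_region(seq, max(0, a - 2 * p), min(b + 5 * p, n), p, cfg)
            if hit is not None:
                candidates.append(hit)
    candidates = _suppress_harmonics(candidates, cfg)
    candidates = _resolve_overlaps(candidates)
    return sorted(candidates, key=lambda h: h.start)


def best_hit(hits: list[RepeatHit]) -> RepeatHit | None:
    """Highest-scoring hit (ties: smaller period, then smaller start);
    None for an empty list."""
    if not hits:
        return None
    return min(hits, key=_sort_key)
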