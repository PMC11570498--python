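"""Independent brute-force oracles used by the test suite.

These deliberately use naive exhaustive enumeration (plain Python loops,
no seeding, no pruning) so they share no machinery with the library code
they check.
"""

from __future__ import annotations

import math

from flipper.repeats import RepeatConfig


def _consensus(units: list[str], p: int) -> str:
    cols = []
    for j in range(p):
        counts: dict[str, int] = {}
        for u in units:
            counts[u[j]] = counts.get(u[j], 0) + 1
        cols.append(min(counts, key=lambda c: (-counts[c], c)))
    return "".join(cols)


def best_decomposition(seq: str, cfg: RepeatConfig, periods=None):
    """Exhaustively enumerate every (start, period, copies, trailing
    partial) tandem decomposition and return the best valid one as
    ``(start, end, period, full_copies, copies, matches)`` or None.

    Validity: boundary copies (and any trailing partial, which must span
    at least half a period) each match the majority-vote consensus at
    ``min_identity``; overall length-weighted identity >= ``min_identity``;
    total copies >= ``min_copies``; consensus passes the distinct-residue
    guard.  Score = total consensus-matching residues; ties prefer the
    smaller period, then the tighter span, then the earlier start.
    """
    n = len(seq)
    best = None
    mi = cfg.min_identity
    if periods is None:
        periods = range(cfg.period_min, min(cfg.period_max, n // 2) + 1)
    for p in periods:
        for s in range(0, n - 2 * p + 1):
            for c in range(2, (n - s) // p + 1):
                units = [seq[s + i * p: s + (i + 1) * p] for i in range(c)]
                cons = _consensus(units, p)
                ids = [sum(a == b for a, b in zip(u, cons)) for u in units]
                if ids[0] / p < mi or ids[-1] / p < mi:
                    continue
                if len(set(cons)) < cfg.min_distinct:
                    continue
                e = s + c * p
                r_best = mt_best = 0
                for r in range(math.ceil(p / 2), p):
                    if e + r > n:
                        break
                    mt = sum(a == b for a, b in zip(seq[e:e + r], cons))
                    if mt / r >= mi and mt > mt_best:
                        r_best, mt_best = r, mt
                total_len = c * p + r_best
                total_match = sum(ids) + mt_best
                if total_match / total_len < mi:
                    continue
                if total_len / p < cfg.min_copies:
                    continue
                key = (-total_match, p, total_len, s)
                if best is None or key < best[0]:
                    best = (key, (s, s + total_len, p, c, total_len / p, total_match))
    return None if best is None else best[1]


def top_hit(seq: str, cfg: RepeatConfig):
    """The overall best decomposition after harmonic suppression.

    Mirrors the documented top-hit contract: the best decomposition is
    taken per period; a decomposition at period ~k*p is discarded when
    the period-p one covers >= 80% of its span with identity no more than
    0.05 worse; the survivor with the best (score, period, span, start)
    key wins.
    """
    n = len(seq)
    per_period = {}
    for p in range(cfg.period_min, min(cfg.period_max, n // 2) + 1):
        d = best_decomposition(seq, cfg, periods=[p])
        if d is not None:
            per_period[p] = d
    survivors = []
    for p, d in per_period.items():
        s, e, _, _, copies, matches = d
        identity = matches / (e - s)
        doomed = False
        for q, g in per_period.items():
            if q >= p:
                continue
            k = round(p / q)
            if k < 2 or abs(p - k * q) > cfg.jitter:
                continue
            gs, ge = g[0], g[1]
            overlap = max(0, min(e, ge) - max(s, gs))
            g_identity = g[5] / (ge - gs)
            if overlap >= 0.8 * (e - s) and g_identity >= identity - 0.05:
                doomed = True
                break
        if not doomed:
            survivors.append(d)
    if not survivors:
        return None
    return min(survivors, key=lambda d: (-d[5], d[2], d[1] - d[0], d[0]))


def make_planted_case(rng, alphabet: str = "ABCD", max_len: int = 60):
    """A random string containing a planted tandem repeat (substitution
    rate 0, 5 or 10%) with random flanks; returns the string."""
    p = int(rng.integers(3, 11))
    c = int(rng.integers(3, 6))
    unit = "".join(rng.choice(list(alphabet), size=p))
    rate = float(rng.choice([0.0, 0.05, 0.10]))
    units = []
    for _ in range(c):
        u = list(unit)
        for j in range(p):
            if rng.random() < rate:
                u[j] = alphabet[rng.integers(len(alphabet))]
        units.append("".join(u))
    fl1 = "".join(rng.choice(list(alphabet), size=int(rng.integers(0, 11))))
    fl2 = "".join(rng.choice(list(alphabet), size=int(rng.integers(0, 11))))
    return (fl1 + "".join(units) + fl2)[:max_len]
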