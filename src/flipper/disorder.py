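"""Intrinsic-disorder scoring.

Two sources are supported: a self-contained charge-hydropathy
unfoldability index (negative = predicted disordered), and per-residue
probability tables produced by an external predictor (score >= 0.5 =
disordered).  The built-in index follows the classic observation that
disordered regions combine low mean hydropathy with high mean net charge:

    I = 2.785 * <H> - |<R>| - 1.151

where <H> is the windowed mean Kyte-Doolittle hydropathy rescaled to
[0, 1] and <R> is the windowed mean integer charge (K, R -> +1; D, E ->
-1).  External predictors are interchangeable here because the screen
thresholds only the fraction of residues called disordered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from flipper.physchem import KYTE_DOOLITTLE

logger = logging.getLogger(__name__)

_A = 2.785
_B = 1.151

_CHARGE = {"K": 1.0, "R": 1.0, "D": -1.0, "E": -1.0}


@dataclass(frozen=True)
class DisorderProfile:
    """Per-residue disorder scores and binary calls for one protein.

    ``source`` is ``builtin`` (unfoldability index, disordered where the
    score is negative) or ``external`` (probability, disordered at
    >= 0.5).
    """

    scores: tuple[float, ...]
    calls: tuple[bool, ...]
    source: str

    def __post_init__(self) -> None:
        if len(self.scores) != len(self.calls):
            raise ValueError("scores and calls differ in length")

    @property
    def fraction_disordered(self) -> float:
        return fraction_disordered(self)


def fraction_disordered(prof: DisorderProfile) -> float:
    """Mean of the per-residue disorder calls."""
    if not prof.calls:
        raise ValueError("empty disorder profile")
    return sum(prof.calls) / len(prof.calls)


def foldindex_profile(seq: str, window: int = 51,
                      his_charge: float = 0.0) -> DisorderProfile:
    """Windowed charge-hydropathy unfoldability index.

    The window is centred on each residue and truncated at the termini.
    X residues contribute zero to both the hydropathy and charge means but
    count toward the window size.  ``his_charge`` optionally assigns a
    partial positive charge to histidine (0 by default).
    """
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be a positive odd integer")
    if not seq:
        raise ValueError("empty sequence")
    n = len(seq)
    h = np.array([(KYTE_DOOLITTLE.get(c, 0.0) + 4.5) / 9.0 if c != "X" else 0.0
                  for c in seq])
    r = np.array([_CHARGE.get(c, his_charge if c == "H" else 0.0) for c in seq])
    half = window // 2
    ch = np.concatenate(([0.0], np.cumsum(h)))
    cr = np.concatenate(([0.0], np.cumsum(r)))
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    width = hi - lo
    mean_h = (ch[hi] - ch[lo]) / width
    mean_r = (cr[hi] - cr[lo]) / width
    scores = _A * mean_h - np.abs(mean_r) - _B
    return DisorderProfile(scores=tuple(float(s) for s in scores),
                           calls=tuple(bool(s < 0.0) for s in scores),
                           source="builtin")


def load_external_scores(path: str | Path, proteome_ids: Iterable[str],
                         ) -> tuple[dict[str, DisorderProfile], list[str]]:
    """Load per-residue disorder probabilities from a TSV.

    Expects columns (id, pos, score): 1-based contiguous positions, scores
    in [0, 1].  Returns ``(profiles, missing_ids)`` where ``missing_ids``
    lists proteome ids absent from the file — those proteins must be
    flagged as lacking disorder data, never silently passed.  Ids in the
    file but not the proteome are skipped with a warning.
    """
    ids = list(proteome_ids)
    wanted = set(ids)
    df = pd.read_csv(path, sep="\t", header=0,
                     names=["id", "pos", "score"],
                     dtype={"id": str, "pos": int, "score": float})
    if ((df["score"] < 0.0) | (df["score"] > 1.0)).any():
        raise ValueError("disorder scores outside [0, 1]")
    profiles: dict[str, DisorderProfile] = {}
    for pid, grp in df.groupby("id", sort=False):
        if pid not in wanted:
            logger.warning("disorder table id %r not in proteome; skipped", pid)
            continue
        grp = grp.sort_values("pos")
        pos = grp["pos"].to_numpy()
        if pos[0] != 1 or not np.array_equal(pos, np.arange(1, len(pos) + 1)):
            raise ValueError(f"non-contiguous positions for {pid!r}")
        scores = tuple(float(s) for s in grp["score"])
        profiles[pid] = DisorderProfile(
            scores=scores,
            calls=tuple(s >= 0.5 for s in scores),
            source="external",
        )
    missing = [i for i in ids if i not in profiles]
    return profiles, missing


def write_external_scores(profiles: Mapping[str, Iterable[float]],
                          path: str | Path) -> None:
    """Write per-residue scores in the TSV shape ``load_external_scores``
    reads (6 significant digits)."""
    with open(path, "w", newline="\n") as fh:
        fh.write("id\tpos\tscore\n")
        for pid, scores in profiles.items():
            for i, s in enumerate(scores, start=1):
                fh.write(f"{pid}\t{i}\t{format(float(s), '.6g')}\n")
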