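"""Seeded synthetic proteomes with planted linker architectures.

The generator emulates the architecture the screen targets: an N-terminal
leader followed by 3-8 near-identical repeat units, each a short
amphipathic sticker motif (hydrophobic plus balanced charged residues)
followed by a disordered low-hydropathy spacer, with total unit length in
the 20-120-residue cross-linking band.  Three decoy classes cover the
failure modes: ordered globular-like composition (not disordered),
disordered but non-repetitive, and low-complexity short-period repeats
(period below the band, few distinct residues).  A DIA-style enrichment
table with planted true positives rounds out end-to-end tests.

Everything is a pure function of the seed: one seed gives byte-identical
FASTA, truth-table and enrichment outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from flipper.disorder import foldindex_profile
from flipper.pipeline import EnrichmentRow
from flipper.repeats import RepeatConfig, find_tandem_repeats
from flipper.seqio import ProteinRecord, write_fasta, write_table

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# spacer composition biased toward disorder-promoting residues, with a
# lysine excess over glutamate: pyrenoid linkers are basic proteins, and
# a consistent net-positive composition keeps the pI stably alkaline
# (near-balanced acidic/basic content makes the pI wildly unstable)
_SPACER_RES = np.array(list("SPGEKTA"))
_SPACER_P = np.array([0.22, 0.14, 0.18, 0.10, 0.16, 0.10, 0.10])

# globular-like composition: hydrophobic-rich, order-promoting
_GLOB_RES = np.array(list("AVLIFMWYGCSTNDKR"))
_GLOB_P = np.array([0.11, 0.10, 0.12, 0.09, 0.06, 0.03, 0.02, 0.04,
                    0.09, 0.02, 0.07, 0.06, 0.05, 0.05, 0.05, 0.04])

_STICKER_LEN = 10

CLASS_LINKER = "linker"
CLASS_GLOBULAR = "globular"
CLASS_DISORDERED = "disordered_nonrepetitive"
CLASS_LOWCOMPLEX = "low_complexity"
DECOY_CLASSES = (CLASS_GLOBULAR, CLASS_DISORDERED, CLASS_LOWCOMPLEX)

_CLASS_CODE = {CLASS_LINKER: 0, CLASS_GLOBULAR: 1,
               CLASS_DISORDERED: 2, CLASS_LOWCOMPLEX: 3}


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters; the defaults define the benchmark conditions."""

    seed: int = 0
    n_linkers: int = 10
    n_decoys_per_class: int = 200
    n_repeats_range: tuple[int, int] = (3, 8)
    period_range: tuple[int, int] = (20, 120)
    repeat_region_band: tuple[int, int] = (160, 720)
    substitution_rate: float = 0.05
    leader_range: tuple[int, int] = (15, 40)
    decoy_length_range: tuple[int, int] = (150, 600)
    max_resamples: int = 10

    def __post_init__(self) -> None:
        if self.period_range[0] < _STICKER_LEN * 2:
            raise ValueError("period must accommodate a sticker plus spacer")
        if not 0.0 <= self.substitution_rate < 1.0:
            raise ValueError("substitution_rate outside [0, 1)")


def _rng(spec: SyntheticSpec, klass: str, index: int, attempt: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, _CLASS_CODE[klass], index, attempt])


def _draw(rng: np.random.Generator, residues: np.ndarray, p: np.ndarray, n: int) -> str:
    return "".join(rng.choice(residues, size=n, p=p / p.sum()))


def _draw_exact(rng: np.random.Generator, residues: np.ndarray, p: np.ndarray,
                n: int) -> str:
    """A shuffled sequence with near-deterministic composition (largest-
    remainder rounding of the target weights).

    Used for linker spacers and leaders: a spacer is drawn once and
    replicated across every repeat copy, so an unlucky multinomial draw
    would be amplified by the copy number and swing bulk properties like
    the pI far outside the family's band.
    """
    w = p / p.sum()
    ideal = w * n
    counts = np.floor(ideal).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(ideal - counts))
    counts[order[:remainder]] += 1
    pool = np.repeat(residues, counts)
    return "".join(rng.permutation(pool))


def _make_sticker(rng: np.random.Generator) -> str:
    """Amphipathic 10-mer: 3 hydrophobic, 1 acidic, 3 basic, 3 neutral,
    in random arrangement (net basic, like the helical linker motifs)."""
    parts = (list(rng.choice(list("LIVFM"), size=3))
             + list(rng.choice(list("DE"), size=1))
             + list(rng.choice(list("KR"), size=3))
             + list(rng.choice(list("STGQN"), size=3)))
    return "".join(rng.permutation(parts))


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0.0:
        return seq
    chars = list(seq)
    hits = np.flatnonzero(rng.random(len(chars)) < rate)
    for i in hits:
        chars[i] = AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))]
    return "".join(chars)


def make_linker(spec: SyntheticSpec, index: int) -> tuple[ProteinRecord, dict]:
    """One linker-architecture protein plus its ground-truth row.

    Resamples (up to ``max_resamples``) until the built-in disorder
    predictor calls at least half of the residues disordered, so linkers
    are guaranteed to clear the disorder stage.
    """
    for attempt in range(spec.max_resamples):
        rng = _rng(spec, CLASS_LINKER, index, attempt)
        period = int(rng.integers(spec.period_range[0], spec.period_range[1] + 1))
        # copy number and period are drawn jointly: short units get more
        # copies, long units fewer, keeping the repeat-region length in a
        # fixed band (as in the natural linker family) so one calibrated
        # length window brackets every generated linker
        lo, hi = spec.n_repeats_range
        band_lo, band_hi = spec.repeat_region_band
        n_ok = [n for n in range(lo, hi + 1) if band_lo <= n * period <= band_hi]
        if not n_ok:
            n_ok = [min(range(lo, hi + 1),
                        key=lambda n: abs(n * period - (band_lo + band_hi) / 2))]
        n_rep = int(rng.choice(n_ok))
        sticker = _make_sticker(rng)
        spacer = _draw_exact(rng, _SPACER_RES, _SPACER_P, period - _STICKER_LEN)
        unit = sticker + spacer
        leader = _draw_exact(rng, _SPACER_RES, _SPACER_P,
                             int(rng.integers(*spec.leader_range)))
        tail = _draw_exact(rng, _SPACER_RES, _SPACER_P, int(rng.integers(0, 21)))
        units = [_mutate(unit, spec.substitution_rate, rng) for _ in range(n_rep)]
        seq = leader + "".join(units) + tail
        if foldindex_profile(seq).fraction_disordered >= 0.5:
            truth = {
                "class": CLASS_LINKER,
                "period": period,
                "copies": n_rep,
                "repeat_start": len(leader) + 1,
                "repeat_end": len(leader) + n_rep * period,
            }
            return ProteinRecord(f"linker_{index}", "synthetic linker", seq), truth
    raise RuntimeError(
        f"could not generate a disorder-passing linker in {spec.max_resamples} tries; "
        "incompatible generator parameters")


def make_reference_linker(seed: int = 0) -> ProteinRecord:
    """A fixed mid-range, substitution-free linker to calibrate against.

    Plays the role the natural reference linker plays for a real screen:
    five exact copies of a 60-residue unit, the centre of the repeat band,
    so the calibrated length window brackets the whole generated family.
    """
    spec = SyntheticSpec(seed=seed, n_repeats_range=(5, 5),
                         period_range=(60, 60), substitution_rate=0.0)
    rec, _ = make_linker(spec, 0)
    return ProteinRecord("reference_linker", "synthetic calibration reference",
                         rec.sequence)


def _decoy_ok(klass: str, seq: str) -> bool:
    if klass == CLASS_GLOBULAR:
        return foldindex_profile(seq).fraction_disordered < 0.5
    # both repeat-free classes must yield no hit in the screening band
    return not find_tandem_repeats(seq, RepeatConfig())


def make_decoy(spec: SyntheticSpec, klass: str, index: int) -> tuple[ProteinRecord, dict]:
    """One decoy protein of the requested class plus its truth row.

    Each class is verified post-generation to fail where intended:
    globular decoys are predicted ordered; disordered-nonrepetitive and
    low-complexity decoys carry no tandem repeat in the screening band
    (the low-complexity guard rejects short-period repeats seen at
    harmonic lags).
    """
    if klass not in DECOY_CLASSES:
        raise ValueError(f"unknown decoy class {klass!r}")
    for attempt in range(spec.max_resamples):
        rng = _rng(spec, klass, index, attempt)
        length = int(rng.integers(*spec.decoy_length_range))
        if klass == CLASS_GLOBULAR:
            seq = _draw(rng, _GLOB_RES, _GLOB_P, length)
        elif klass == CLASS_DISORDERED:
            seq = _draw(rng, _SPACER_RES, _SPACER_P, length)
        else:
            unit_len = int(rng.integers(3, 11))  # period below the band
            unit = "".join(rng.choice(list("GPSQ"), size=unit_len))
            reps = length // unit_len + 1
            seq = (unit * reps)[:length]
        if _decoy_ok(klass, seq):
            truth = {"class": klass, "period": None, "copies": None,
                     "repeat_start": None, "repeat_end": None}
            return ProteinRecord(f"{klass}_{index}", "synthetic decoy", seq), truth
    raise RuntimeError(
        f"could not generate a conforming {klass} decoy in {spec.max_resamples} tries")


def generate_proteome(spec: SyntheticSpec, out_dir: str | Path | None = None,
                      ) -> tuple[list[ProteinRecord], list[dict]]:
    """Full labelled proteome: planted linkers plus all decoy classes.

    Record order is shuffled and ids are reassigned sequentially after the
    shuffle, so an id reveals nothing about its class; labels live only in
    the truth table.  With ``out_dir`` set, writes ``proteome.fasta`` and
    ``truth.tsv`` there.
    """
    items: list[tuple[ProteinRecord, dict]] = []
    for i in range(spec.n_linkers):
        items.append(make_linker(spec, i))
    for klass in DECOY_CLASSES:
        for i in range(spec.n_decoys_per_class):
            items.append(make_decoy(spec, klass, i))
    order = np.random.default_rng([spec.seed, 97]).permutation(len(items))
    records: list[ProteinRecord] = []
    truth: list[dict] = []
    for new_idx, old_idx in enumerate(order):
        rec, row = items[old_idx]
        pid = f"sP{new_idx:05d}"
        records.append(ProteinRecord(pid, rec.description, rec.sequence))
        truth.append({"id": pid, **row})
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(records, out / "proteome.fasta")
        write_table(truth, out / "truth.tsv", format="tsv")
    return records, truth


def generate_enrichment_table(ids: Sequence[str], true_positive_ids: Iterable[str],
                              effect: tuple[float, float] = (8.0, 1.0),
                              seed: int = 0,
                              lfc_threshold: float = 4.0,
                              logp_threshold: float = 4.0) -> list[EnrichmentRow]:
    """DIA-co-IP-shaped enrichment table with planted positives.

    True positives draw fold change and significance above the thresholds
    (clamped there, so they always pass a strict filter at those
    thresholds); background proteins draw below.  Summed intensities are
    lognormal, as in label-free quantification.
    """
    tp = set(true_positive_ids)
    if not tp <= set(ids):
        raise ValueError("true positives must be a subset of ids")
    rng = np.random.default_rng([seed, 11])
    mean, sd = effect
    rows = []
    for pid in ids:
        if pid in tp:
            lfc = max(lfc_threshold + 0.2, float(rng.normal(mean, sd)))
            logp = max(logp_threshold + 0.2, float(rng.normal(mean, 1.5)))
        else:
            lfc = min(lfc_threshold - 0.2, float(rng.normal(0.0, 1.5)))
            logp = min(logp_threshold - 0.2, float(rng.exponential(1.0)))
        rows.append(EnrichmentRow(
            id=pid, log2_fc=lfc, neg_log10_adj_p=logp,
            summed_intensity=float(rng.lognormal(mean=13.0, sigma=1.5)),
        ))
    return rows
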