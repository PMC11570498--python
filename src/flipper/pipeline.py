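"""The screening pipeline: stage orchestration, calibration and triage.

Stages run in a fixed order — (1) physicochemical band filter, (2)
tandem-repeat presence in the 20-120-residue period band, (3)
interacting-residue (sticker) content of the best repeat's consensus,
(4) disorder-fraction threshold.  Every input protein receives a report
with pass flags evaluated up to its first failure; per-stage survivor
counts are recorded alongside.  Thresholds for stage 1 are calibrated
from a reference linker (EPYC1 or a synthetic surrogate) rather than
fixed, since linkers from different lineages share architecture, not
sequence.

Candidate triage against co-IP enrichment tables (strict thresholds on
log2 fold change and -log10 adjusted P) and the set intersection that
pinpoints the linker are also implemented here.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from flipper.disorder import DisorderProfile, foldindex_profile
from flipper.physchem import DEFAULT_SCALES, PhyschemProfile, ResidueScales, profile
from flipper.repeats import RepeatConfig, RepeatHit, best_hit, find_tandem_repeats
from flipper.seqio import ProteinRecord

logger = logging.getLogger(__name__)

STAGES = ("physchem", "repeat", "sticker", "disorder")


@dataclass(frozen=True)
class FilterConfig:
    """All pipeline thresholds; every field is user-overridable."""

    length_min: int = 100
    length_max: int = 1000
    pi_min: float = 7.0
    pi_max: float = 14.0
    min_frac_zeta: float = 0.1
    min_frac_phi: float = 0.05
    repeat: RepeatConfig = field(default_factory=RepeatConfig)
    min_sticker_phi: int = 1
    min_sticker_zeta: int = 2
    min_fraction_disordered: float = 0.5
    disorder_source: str = "builtin"
    mature_trim: int = 0  # N-terminal residues dropped before all computation

    def __post_init__(self) -> None:
        if self.length_min > self.length_max or self.pi_min > self.pi_max:
            raise ValueError("empty length or pI band")
        if not 0.0 <= self.min_fraction_disordered <= 1.0:
            raise ValueError("disorder threshold outside [0, 1]")
        if self.mature_trim < 0:
            raise ValueError("mature_trim must be >= 0")


@dataclass(frozen=True)
class CandidateReport:
    """Stage-by-stage record for one protein.

    Flags are True/False up to the first failing stage and None after it;
    ``rank_score`` is defined only when every stage passes.
    """

    id: str
    physchem: PhyschemProfile | None
    repeat_hit: RepeatHit | None
    fraction_disordered: float | None
    pass_physchem: bool | None
    pass_repeat: bool | None
    pass_sticker: bool | None
    pass_disorder: bool | None
    rank_score: float | None

    @property
    def passes_all(self) -> bool:
        return bool(self.pass_physchem and self.pass_repeat
                    and self.pass_sticker and self.pass_disorder)

    def to_row(self) -> dict:
        hit = self.repeat_hit
        ph = self.physchem
        return {
            "id": self.id,
            "length": ph.length if ph else None,
            "pI": ph.pI if ph else None,
            "gravy": ph.gravy if ph else None,
            "frac_phi": ph.frac_phi if ph else None,
            "frac_zeta": ph.frac_zeta if ph else None,
            "repeat_start": hit.start_1 if hit else None,
            "repeat_end": hit.end_1 if hit else None,
            "repeat_period": hit.period if hit else None,
            "repeat_copies": hit.copies if hit else None,
            "repeat_identity": hit.identity if hit else None,
            "repeat_consensus": hit.consensus if hit else None,
            "fraction_disordered": self.fraction_disordered,
            "pass_physchem": self.pass_physchem,
            "pass_repeat": self.pass_repeat,
            "pass_sticker": self.pass_sticker,
            "pass_disorder": self.pass_disorder,
            "rank_score": self.rank_score,
        }


@dataclass(frozen=True)
class StageCounts:
    """Survivor counts after each stage; first entry is the input size."""

    counts: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        vals = [c for _, c in self.counts]
        if any(b > a for a, b in zip(vals, vals[1:])):
            raise ValueError("stage counts must be nonincreasing")

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    @property
    def final(self) -> int:
        return self.counts[-1][1]


@dataclass(frozen=True)
class EnrichmentRow:
    """One protein of a differential-abundance (co-IP) table."""

    id: str
    log2_fc: float
    neg_log10_adj_p: float
    summed_intensity: float = 0.0

    def __post_init__(self) -> None:
        for v in (self.log2_fc, self.neg_log10_adj_p, self.summed_intensity):
            if not math.isfinite(v):
                raise ValueError(f"non-finite enrichment value for {self.id!r}")
        if self.summed_intensity < 0:
            raise ValueError("summed_intensity must be >= 0")


def calibrate_config(reference: ProteinRecord,
                     *,
                     pi_margin: float = 2.0,
                     length_factors: tuple[float, float] = (0.3, 3.0),
                     frac_factor: float = 0.5,
                     repeat: RepeatConfig | None = None,
                     min_fraction_disordered: float = 0.5,
                     scales: ResidueScales = DEFAULT_SCALES,
                     mature_trim: int = 0) -> FilterConfig:
    """Derive stage-1 thresholds from a reference linker's own features.

    The pI band is the reference pI +/- ``pi_margin``; the length band is
    ``length_factors`` times the reference length; the minimum phi/zeta
    fractions are ``frac_factor`` times the reference's.  The repeat band
    stays fixed at the cross-linking length scale.  The reference must
    pass the config calibrated from itself; failure signals
    miscalibration and raises.
    """
    seq = reference.sequence[mature_trim:]
    rep = repeat or RepeatConfig()
    if len(seq) < 2 * rep.period_min:
        raise ValueError(
            f"reference {reference.id!r} shorter than two minimal repeat periods")
    ref = profile(seq, scales)
    cfg = FilterConfig(
        length_min=max(1, int(length_factors[0] * ref.length)),
        length_max=int(length_factors[1] * ref.length),
        pi_min=max(0.0, ref.pI - pi_margin),
        pi_max=min(14.0, ref.pI + pi_margin),
        min_frac_zeta=frac_factor * ref.frac_zeta,
        min_frac_phi=frac_factor * ref.frac_phi,
        repeat=rep,
        min_fraction_disordered=min_fraction_disordered,
        mature_trim=mature_trim,
    )
    check, _ = run_flipper([ProteinRecord(reference.id, reference.description, seq)],
                           replace(cfg, mature_trim=0), scales=scales)
    if not check[0].passes_all:
        failed = [s for s in STAGES if getattr(check[0], f"pass_{s}") is not True]
        raise ValueError(
            f"reference {reference.id!r} fails its own calibrated config "
            f"at stage(s) {failed}; miscalibrated reference")
    return cfg


def _sticker_counts(consensus: str, scales: ResidueScales) -> tuple[int, int]:
    n_phi = sum(1 for c in consensus if c in scales.phi_set)
    n_zeta = sum(1 for c in consensus if c in scales.zeta_set)
    return n_phi, n_zeta


def run_flipper(proteome: Sequence[ProteinRecord], cfg: FilterConfig,
                disorder_profiles: Mapping[str, DisorderProfile] | None = None,
                scales: ResidueScales = DEFAULT_SCALES,
                ) -> tuple[list[CandidateReport], StageCounts]:
    """Run all four stages over a proteome.

    ``disorder_profiles`` supplies external per-residue scores when
    ``cfg.disorder_source == "external"``; a survivor of stages 1-3 with
    no external profile raises (missing data must never silently pass).
    Output is a pure function of (proteome, cfg): no randomness, no
    hidden state.
    """
    if not proteome:
        raise ValueError("empty proteome")
    reports: list[CandidateReport] = []
    survivors = {s: 0 for s in STAGES}
    for rec in proteome:
        seq = rec.sequence[cfg.mature_trim:]
        ph = profile(seq, scales) if seq else None
        p_phys = bool(
            ph is not None
            and cfg.length_min <= ph.length <= cfg.length_max
            and cfg.pi_min <= ph.pI <= cfg.pi_max
            and ph.frac_zeta >= cfg.min_frac_zeta
            and ph.frac_phi >= cfg.min_frac_phi
        )
        hit = None
        p_rep = p_stick = p_dis = None
        frac_dis = None
        if p_phys:
            survivors["physchem"] += 1
            hit = best_hit(find_tandem_repeats(seq, cfg.repeat))
            p_rep = hit is not None
            if p_rep:
                survivors["repeat"] += 1
                n_phi, n_zeta = _sticker_counts(hit.consensus, scales)
                p_stick = (n_phi >= cfg.min_sticker_phi
                           and n_zeta >= cfg.min_sticker_zeta)
                if p_stick:
                    survivors["sticker"] += 1
                    if cfg.disorder_source == "builtin":
                        prof = foldindex_profile(seq)
                    else:
                        if disorder_profiles is None or rec.id not in disorder_profiles:
                            raise ValueError(
                                f"external disorder scores missing for survivor {rec.id!r}")
                        prof = disorder_profiles[rec.id]
                    frac_dis = prof.fraction_disordered
                    p_dis = frac_dis >= cfg.min_fraction_disordered
                    if p_dis:
                        survivors["disorder"] += 1
        rank = None
        if p_dis:
            rank = hit.copies * hit.identity * frac_dis
        reports.append(CandidateReport(
            id=rec.id, physchem=ph, repeat_hit=hit,
            fraction_disordered=frac_dis,
            pass_physchem=p_phys,
            pass_repeat=p_rep, pass_sticker=p_stick, pass_disorder=p_dis,
            rank_score=rank,
        ))
    counts = StageCounts(counts=(
        ("input", len(proteome)),
        *((s, survivors[s]) for s in STAGES),
    ))
    for name, c in counts.counts:
        logger.info("stage %-9s: %d surviving", name, c)
    return reports, counts


def rank_candidates(reports: Iterable[CandidateReport]) -> list[CandidateReport]:
    """Passes-all candidates ordered by rank score (repeat copies x repeat
    identity x disordered fraction), descending; ties broken by id."""
    cands = [r for r in reports if r.passes_all]
    return sorted(cands, key=lambda r: (-r.rank_score, r.id))


def enrichment_filter(rows: Iterable[EnrichmentRow],
                      lfc_min: float = 4.0, logp_min: float = 4.0) -> set[str]:
    """Ids enriched beyond both thresholds; inequalities are strict."""
    return {r.id for r in rows
            if r.log2_fc > lfc_min and r.neg_log10_adj_p > logp_min}


def intersect_candidates(flipper_ids: Iterable[str],
                         enriched_ids: Iterable[str]) -> set[str]:
    """Intersection of screen survivors with co-IP-enriched proteins; the
    two set sizes and the overlap size are logged."""
    a, b = set(flipper_ids), set(enriched_ids)
    overlap = a & b
    logger.info("screen candidates: %d; enriched: %d; overlap: %d",
                len(a), len(b), len(overlap))
    return overlap


# --- TOML config round trip (CLI support) ---------------------------------

def config_to_toml(cfg: FilterConfig) -> str:
    def fmt(v: object) -> str:
        if isinstance(v, bool):
            return str(v).lower()
        if isinstance(v, str):
            return f'"{v}"'
        return repr(v)

    lines = ["[filter]"]
    for name in ("length_min", "length_max", "pi_min", "pi_max",
                 "min_frac_zeta", "min_frac_phi", "min_sticker_phi",
                 "min_sticker_zeta", "min_fraction_disordered",
                 "disorder_source", "mature_trim"):
        lines.append(f"{name} = {fmt(getattr(cfg, name))}")
    lines.append("")
    lines.append("[filter.repeat]")
    for name in ("period_min", "period_max", "min_copies", "min_identity",
                 "min_distinct", "jitter"):
        lines.append(f"{name} = {fmt(getattr(cfg.repeat, name))}")
    return "\n".join(lines) + "\n"


def config_from_toml(path: str | Path) -> FilterConfig:
    import tomllib

    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    section = data.get("filter", data)
    rep = RepeatConfig(**section.pop("repeat", {}))
    return FilterConfig(repeat=rep, **section)
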