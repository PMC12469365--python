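"""Synthetic study inputs: transcript models with CDS, screening-style
variant tables with SpliceAI score vectors, and gel lanes rendered from
known transcript mixtures.

Everything is deterministic under a fixed seed. The generators emulate the
statistical shape of a minigene screening cohort — a multi-exon gene, a
variant table whose highest delta scores concentrate between 0.1 and 0.3
with a high-scoring tail, and lanes whose Gaussian bands carry areas
proportional to species fractions — not any particular gel chemistry.
"""
from __future__ import annotations

import math
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coords import parse_cposition
from .densitometry import Ladder, LaneProfile, calibrate_sizes, \
    detect_and_integrate, match_transcripts, predict_fragment_size, \
    refine_fractions, subtract_background
from .events import SpliceEvent
from .model import MinigeneConstruct, TranscriptModel, assign_construct, \
    UnassignableError
from .reclassify import bin_residual

__all__ = [
    "GeneratorConfig", "gen_model", "gen_variant_table", "gen_ladder",
    "gen_lane", "synthetic_cohort_recovery",
]

_STOPS = {"TAA", "TAG", "TGA"}
_NONSTOP = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
            if a + b + c not in _STOPS]


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic study; defaults mirror the emulated cohort.

    Scores for above-threshold variants are 0.1 + 0.9*Beta(1.2, 4) —
    most mass between 0.1 and 0.3 with a high tail; sub-threshold scores
    are 0.1*Beta(1, 9). Lane bands are Gaussians of ``band_sigma_px``
    with additive noise at ``snr`` (peak amplitude / noise sigma).
    """

    seed: int = 0
    # gene model
    n_exons: int = 13
    exon_length_range: tuple[int, int] = (63, 150)
    intron_length_range: tuple[int, int] = (80, 300)
    # variant table
    n_variants: int = 73
    site_proportions: tuple[float, float, float] = (0.55, 0.35, 0.10)
    above_threshold_frac: float = 0.5
    in_window_frac: float = 0.9
    window_bp: int = 5000
    # lanes
    n_points: int = 1200
    band_sigma_px: float = 6.0
    snr: float = 30.0
    ladder_sizes: tuple[int, ...] = (2000, 1500, 1000, 700, 500, 300, 200,
                                     100)
    baseline_level: float = 0.05  # offset+ramp, as fraction of peak max

    def __post_init__(self) -> None:
        if self.n_exons < 3 or self.n_variants < 1:
            raise ValueError("infeasible generator configuration")
        if not math.isclose(sum(self.site_proportions), 1.0, abs_tol=1e-9):
            raise ValueError("site proportions must sum to 1")
        for lo, hi in (self.exon_length_range, self.intron_length_range):
            if lo <= 0 or hi < lo:
                raise ValueError("length ranges must be positive and "
                                 "ordered")


def _rng(cfg: GeneratorConfig, salt: int = 0) -> np.random.Generator:
    return np.random.default_rng((cfg.seed, salt))


def gen_model(cfg: GeneratorConfig) -> TranscriptModel:
    """Random multi-exon model with CDS, intron sequences and constructs.

    The CDS starts ATG, ends with a stop and contains no internal
    in-frame stop; at least one exon has a length not divisible by 3, so
    single-exon skips can frameshift. Constructs are sliding 5-exon
    windows overlapping by one exon.
    """
    rng = _rng(cfg, salt=1)
    lo, hi = cfg.exon_length_range
    for _ in range(1000):
        lengths = rng.integers(lo, hi + 1, size=cfg.n_exons)
        total = int(lengths.sum())
        excess = total % 3
        lengths[-1] -= excess  # keep CDS length divisible by 3
        if lengths[-1] < lo:
            continue
        if any(l % 3 for l in lengths):
            break
    else:  # pragma: no cover - ranges this wide always succeed
        raise ValueError("could not draw a frame-shifting exon structure")
    total = int(lengths.sum())
    n_codons = total // 3
    codons = ["ATG"] + [ _NONSTOP[i] for i in
                         rng.integers(0, len(_NONSTOP), size=n_codons - 2)] \
        + ["TAA"]
    cds = "".join(codons)
    exons = []
    start = 1
    for i, length in enumerate(lengths, start=1):
        end = start + int(length) - 1
        exons.append((i, parse_cposition(str(start)),
                      parse_cposition(str(end))))
        start = end + 1
    ilo, ihi = cfg.intron_length_range
    introns = {}
    for i in range(1, cfg.n_exons):
        n = int(rng.integers(ilo, ihi + 1))
        interior = "".join("ACGT"[j] for j in
                           rng.integers(0, 4, size=n - 4))
        introns[i] = "GT" + interior + "AG"
    constructs = []
    first = 1
    k = 1
    while first < cfg.n_exons:
        last = min(first + 4, cfg.n_exons)
        constructs.append(MinigeneConstruct(
            name=f"WT-{k}", first_exon=first, last_exon=last,
            flank_5_len=150, flank_3_len=150))
        if last == cfg.n_exons:
            break
        first, k = last, k + 1
    return TranscriptModel(
        gene_label=f"SYN-{cfg.seed}", exons=exons, cds_sequence=cds,
        intron_sequences=introns, constructs=constructs)


def _spliceai_row(rng: np.random.Generator, cfg: GeneratorConfig
                  ) -> tuple[tuple, tuple, bool, str]:
    """Four-score vector, positions, expected selection and reason."""
    selectable = rng.random() < cfg.above_threshold_frac
    main = int(rng.integers(0, 4))
    # sub-threshold scores capped at 0.09 so 2-decimal table rounding
    # can never lift them across the 0.1 cut-off
    scores = list(np.minimum(0.1 * rng.beta(1.0, 9.0, size=4), 0.09))
    positions = [int(p) for p in rng.integers(-2000, 2001, size=4)]
    if selectable:
        scores[main] = 0.1 + 0.9 * rng.beta(1.2, 4.0)
        in_window = rng.random() < cfg.in_window_frac
        if in_window:
            positions[main] = int(rng.integers(-cfg.window_bp,
                                               cfg.window_bp + 1))
            return tuple(scores), tuple(positions), True, "selected"
        positions[main] = int(rng.choice([-1, 1]) *
                              rng.integers(cfg.window_bp + 1,
                                           3 * cfg.window_bp))
        return tuple(scores), tuple(positions), False, "outside_window"
    return tuple(scores), tuple(positions), False, "no_score_above_threshold"


def gen_variant_table(cfg: GeneratorConfig, model: TranscriptModel
                      ) -> tuple[pd.DataFrame, dict]:
    """Variant table in the screening-TSV dialect plus ground truth.

    Variants are placed exonic / near-splice-site (NCSS) / deep-intronic
    in the configured proportions; each row's expected selection outcome
    (and rejection reason) is computed by the generator's own logic,
    independently of the intake module.
    """
    rng = _rng(cfg, salt=2)
    rows = []
    truth = {}
    seen = set()
    bases = "ACGT"
    for i in range(cfg.n_variants):
        site = rng.choice(["exonic", "NCSS", "deep"],
                          p=cfg.site_proportions)
        if site == "exonic":
            base = int(rng.integers(1, model.cds_length + 1))
            c_pos = str(base)
            vtype = str(rng.choice(["Missense", "Synonymous"]))
        else:
            intron = int(rng.integers(1, len(model.exons)))
            donor = bool(rng.integers(0, 2))
            ilen = model.intron_length(intron)
            if site == "NCSS":
                off = int(rng.integers(3, 21))
            else:
                off = int(rng.integers(21, max(22, ilen // 2)))
            if donor:
                c_pos = f"{model.exon_span(intron)[1]}+{off}"
            else:
                c_pos = f"{model.exon_span(intron + 1)[0]}-{off}"
            vtype = "NCSS"
        ref, alt = rng.choice(list(bases), size=2, replace=False)
        c_not = f"c.{c_pos}{ref}>{alt}"
        if c_not in seen:
            continue
        seen.add(c_not)
        scores, positions, expect_sel, reason = _spliceai_row(rng, cfg)
        try:
            construct = assign_construct(c_not, model)
        except UnassignableError:
            construct = ""
        rows.append({
            "c. Notation": c_not, "p. Notation": "p.(?)",
            "Variant Type": vtype,
            "ACMG Classification August 2023":
                str(rng.choice(["VUS", "LB"], p=[0.7, 0.3])),
            "ACMG Classification October 2024": "VUS",
            "Source": str(rng.choice(["ClinVar", "LOVD"])),
            "Wild-Type Construct": construct,
            "Acceptor Gain": round(scores[0], 2),
            "Acceptor Loss": round(scores[1], 2),
            "Donor Gain": round(scores[2], 2),
            "Donor Loss": round(scores[3], 2),
            "Acceptor Gain Position": positions[0],
            "Acceptor Loss Position": positions[1],
            "Donor Gain Position": positions[2],
            "Donor Loss Position": positions[3],
        })
        truth[c_not] = {"site": str(site), "expected_selected": expect_sel,
                        "reason": reason}
    return pd.DataFrame(rows), truth


def gen_ladder(cfg: GeneratorConfig) -> tuple[Ladder, callable]:
    """Size standard plus the migration map position(size) it embodies."""
    smax, smin = max(cfg.ladder_sizes), min(cfg.ladder_sizes)
    pad = cfg.n_points * 0.05

    def position(size_bp: float) -> float:
        frac = (math.log10(smax) - math.log10(size_bp)) / \
               (math.log10(smax) - math.log10(smin))
        return pad + frac * (cfg.n_points - 2 * pad)

    rungs = tuple((position(s), float(s))
                  for s in sorted(cfg.ladder_sizes, reverse=True))
    return Ladder(rungs=rungs), position


def gen_lane(cfg: GeneratorConfig, construct: MinigeneConstruct,
             mixture, model: TranscriptModel,
             lane_id: str = "") -> tuple[LaneProfile, dict]:
    """Render a lane from (event set, fraction) species.

    One Gaussian band per species at the migration its predicted fragment
    size implies, area proportional to fraction, additive Gaussian noise
    at the configured SNR plus a small offset+ramp baseline. The ground
    truth bundle reports centers, sizes, fractions and an overlap warning
    when two bands sit closer than one sigma.
    """
    total = sum(f for _, f in mixture)
    if not math.isclose(total, 100.0, abs_tol=1e-6):
        raise ValueError(f"mixture fractions sum to {total}, expected 100")
    rng = _rng(cfg, salt=zlib.crc32(lane_id.encode()))
    _, position = gen_ladder(cfg)
    x = np.arange(cfg.n_points, dtype=float)
    y = np.zeros_like(x)
    sigma = cfg.band_sigma_px
    bands = []
    for events, frac in mixture:
        size = predict_fragment_size(construct, events, model)
        center = position(size)
        amp = frac / (sigma * math.sqrt(2 * math.pi))
        y += amp * np.exp(-0.5 * ((x - center) / sigma) ** 2)
        bands.append({"events": [e.to_dict() for e in events],
                      "fraction": float(frac), "size_bp": int(size),
                      "center_px": float(center)})
    peak = float(y.max()) if y.max() > 0 else 1.0
    baseline = cfg.baseline_level * peak * (0.5 + 0.5 * x / x.size)
    noise = rng.normal(0.0, peak / cfg.snr, size=x.size)
    y = np.clip(y + baseline + noise, 0.0, None)
    centers = sorted(b["center_px"] for b in bands)
    overlap = any(b - a < sigma for a, b in zip(centers, centers[1:]))
    truth = {"lane_id": lane_id, "construct": construct.name,
             "bands": bands, "band_sigma_px": sigma, "snr": cfg.snr,
             "overlap_warning": overlap}
    return LaneProfile(positions=x, intensities=y,
                       lane_id=lane_id or construct.name), truth


# ----------------------------------------------------------------------
# end-to-end synthetic cohort
# ----------------------------------------------------------------------

def _event_menu(construct: MinigeneConstruct, model: TranscriptModel,
                position, min_sep_px: float) -> list[tuple]:
    """Single-aberration candidates with mutually separated migrations."""
    candidates = [()]
    for exon in construct.exon_range():
        candidates.append((SpliceEvent.exon_skip(exon),))
    for intron in range(construct.first_exon, construct.last_exon):
        candidates.append(
            (SpliceEvent(kind="intron_retention", intron=intron),))
    kept = []
    centers = []
    for events in candidates:
        c = position(predict_fragment_size(construct, events, model))
        if all(abs(c - o) >= min_sep_px for o in centers):
            kept.append(events)
            centers.append(c)
    return kept


def synthetic_cohort_recovery(cfg: GeneratorConfig, n_variants: int = 40,
                              bin_probs: tuple[float, float, float, float]
                              = (0.2, 0.25, 0.4, 0.15)) -> dict:
    """Simulate -> quantify -> classify a cohort; score bin recovery.

    Each synthetic variant gets a true residual-WT fraction drawn per bin
    (``none`` / ``low`` / ``high`` / splice-silent; values kept >2 points
    from the 5%/20% cut-offs so the +-2-point densitometry tolerance
    cannot flip a bin), aberrant species drawn from the construct's
    single-aberration menu, a rendered lane, and the full densitometry +
    binning pipeline run on it. Returns recovery counts and per-variant
    detail.
    """
    rng = _rng(cfg, salt=3)
    model = gen_model(cfg)
    ladder, position = gen_ladder(cfg)
    min_sep = 4.0 * cfg.band_sigma_px
    results = []
    n_ok = 0
    for i in range(n_variants):
        construct = model.constructs[int(rng.integers(0,
                                                      len(model.constructs)))]
        menu = [ev for ev in
                _event_menu(construct, model, position, min_sep) if ev]
        kind = rng.choice(["none", "low", "high", "full"], p=bin_probs)
        if kind == "none":
            wt_true = 0.0
        elif kind == "low":
            wt_true = float(rng.uniform(7.5, 17.5))
        elif kind == "high":
            wt_true = float(rng.uniform(22.5, 90.0))
        else:
            wt_true = 100.0
        mixture = []
        if wt_true > 0:
            mixture.append(((), wt_true))
        if wt_true < 100.0:
            remaining = 100.0 - wt_true
            n_ab = int(rng.integers(1, min(3, len(menu)) + 1))
            # every aberrant band must clear the 5%-of-max prominence
            # floor, so cap the species count by the mass available
            n_ab = max(1, min(n_ab, int(remaining // 7.0) or 1))
            chosen = rng.choice(len(menu), size=n_ab, replace=False)
            shares = rng.dirichlet(np.ones(n_ab) * 4.0) * remaining
            if np.any(shares < 7.0):
                shares = np.full(n_ab, remaining / n_ab)
            for j, idx in enumerate(chosen):
                mixture.append((menu[int(idx)], float(shares[j])))
        lane, _ = gen_lane(cfg, construct, mixture, model,
                           lane_id=f"v{i:03d}")
        lane = subtract_background(lane, window=int(20 * cfg.band_sigma_px))
        bands = detect_and_integrate(lane, min_prominence=0.05,
                                     smooth_sigma=cfg.band_sigma_px)
        bands = refine_fractions(lane, bands,
                                 band_sigma=cfg.band_sigma_px)
        sized, _ = calibrate_sizes(bands, ladder)
        candidates = [(ev, float(predict_fragment_size(construct, ev,
                                                       model)))
                      for ev in _event_menu(construct, model, position,
                                            min_sep)]
        gaps = sorted(s for _, s in candidates)
        min_gap = min(b - a for a, b in zip(gaps, gaps[1:]))
        matched = match_transcripts(sized, candidates,
                                    tolerance_bp=max(5.0, 0.45 * min_gap))
        wt_meas = min(100.0, sum(b.fraction for b in matched
                                 if b.identity == ()))
        ok = bin_residual(wt_meas) == bin_residual(wt_true)
        n_ok += ok
        results.append({"lane": lane.lane_id, "construct": construct.name,
                        "wt_true": wt_true, "wt_measured": wt_meas,
                        "bin_true": bin_residual(wt_true),
                        "bin_measured": bin_residual(wt_meas),
                        "recovered": bool(ok)})
    return {"n": n_variants, "n_recovered": n_ok,
            "recovery": n_ok / n_variants, "detail": results}
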