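"""Variant-table intake: reading, deduplication and SpliceAI-based
selection.

The input dialect mirrors clinical screening tables: one row per variant
with c./p. notation, variant type, two ACMG class columns (screening
timepoint and follow-up), database source, assigned wild-type construct,
and the four SpliceAI delta scores (acceptor gain/loss, donor gain/loss)
with the nt distance to each predicted gain/loss site.

Selection keeps a variant when its prior ACMG class is no more severe than
a cutoff (default VUS) and at least one SpliceAI component reaches the
score threshold *with its predicted site inside the analysis window* —
a high score pointing at a site beyond the window does not qualify.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .coords import normalize_dashes

__all__ = [
    "VariantRecord", "SelectionConfig", "SelectionResult", "SchemaError",
    "ACMG_CLASSES", "acmg_severity", "read_variant_table", "dedup_variants",
    "spliceai_select", "highest_score",
]

ACMG_CLASSES = ("B", "LB", "VUS", "LP", "P")
SCORE_NAMES = ("acceptor_gain", "acceptor_loss", "donor_gain", "donor_loss")
REJECTION_REASONS = ("class_too_high", "no_score_above_threshold",
                     "outside_window")


class SchemaError(ValueError):
    pass


def acmg_severity(cls: str) -> int:
    try:
        return ACMG_CLASSES.index(cls)
    except ValueError:
        raise SchemaError(f"unknown ACMG class {cls!r}") from None


@dataclass(frozen=True)
class VariantRecord:
    c_notation: str
    p_notation: str = ""
    variant_type: str = ""
    acmg_prior: str = "VUS"       # class at the screening timepoint
    acmg_followup: str = ""       # later class, carried for reporting only
    source: str = ""              # LOVD | ClinVar | both
    construct: str | None = None
    scores: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    positions: tuple[int, int, int, int] = (0, 0, 0, 0)
    notes: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if len(self.scores) != 4 or len(self.positions) != 4:
            raise SchemaError("exactly four score/position pairs required")
        if any(not 0.0 <= s <= 1.0 for s in self.scores):
            raise SchemaError(f"{self.c_notation}: scores must lie in [0,1]")
        acmg_severity(self.acmg_prior)


@dataclass(frozen=True)
class SelectionConfig:
    score_threshold: float = 0.1
    window_bp: int = 5000
    max_prior_class: str = "VUS"
    inclusive: bool = True  # threshold comparison >= (else strictly >)

    def __post_init__(self) -> None:
        if not 0.0 <= self.score_threshold <= 1.0:
            raise ValueError("score_threshold must lie in [0,1]")
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        acmg_severity(self.max_prior_class)


@dataclass
class SelectionResult:
    selected: list[VariantRecord]
    rejected: list[tuple[VariantRecord, str]]

    def rejection_counts(self) -> dict[str, int]:
        counts = {r: 0 for r in REJECTION_REASONS}
        for _, reason in self.rejected:
            counts[reason] += 1
        return counts


# -- table reading ------------------------------------------------------

def _canon(name: str) -> str:
    return re.sub(r"[^a-z0-9]+", "_", str(name).strip().lower()).strip("_")

_ALIASES = {
    "c_notation": ("c_notation", "cdna_variant", "variant"),
    "p_notation": ("p_notation", "protein_variant"),
    "variant_type": ("variant_type",),
    "acmg_prior": ("acmg_classification_august_2023", "acmg_prior",
                   "acmg_class"),
    "acmg_followup": ("acmg_classification_october_2024", "acmg_followup"),
    "source": ("source",),
    "construct": ("wild_type_construct", "construct"),
    "acceptor_gain": ("acceptor_gain",),
    "acceptor_loss": ("acceptor_loss",),
    "donor_gain": ("donor_gain",),
    "donor_loss": ("donor_loss",),
    "acceptor_gain_pos": ("acceptor_gain_position", "acceptor_gain_1"),
    "acceptor_loss_pos": ("acceptor_loss_position", "acceptor_loss_1"),
    "donor_gain_pos": ("donor_gain_position", "donor_gain_1"),
    "donor_loss_pos": ("donor_loss_position", "donor_loss_1"),
}
_REQUIRED = ("c_notation", "acceptor_gain", "acceptor_loss", "donor_gain",
             "donor_loss", "acceptor_gain_pos", "acceptor_loss_pos",
             "donor_gain_pos", "donor_loss_pos")


def _resolve_columns(columns) -> dict[str, str]:
    canon = {_canon(c): c for c in columns}
    mapping = {}
    for key, aliases in _ALIASES.items():
        for a in aliases:
            if a in canon:
                mapping[key] = canon[a]
                break
    missing = [k for k in _REQUIRED if k not in mapping]
    if missing:
        raise SchemaError("variant table is missing required column(s): "
                          + ", ".join(missing))
    return mapping


def _num(value: str, row: int, what: str) -> float:
    try:
        return float(normalize_dashes(str(value)))
    except ValueError:
        raise SchemaError(f"row {row}: unparseable {what} {value!r}") \
            from None


def read_variant_table(path: str | Path) -> list[VariantRecord]:
    """Read a TSV variant table into records (dash glyphs normalized)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    cols = _resolve_columns(df.columns)
    records = []
    for i, row in df.iterrows():
        get = lambda k, default="": str(row[cols[k]]).strip() \
            if k in cols else default
        scores = tuple(_num(get(n), i, f"score {n}") for n in SCORE_NAMES)
        positions = tuple(int(_num(get(n + "_pos"), i, f"position {n}"))
                          for n in SCORE_NAMES)
        construct = get("construct") or None
        records.append(VariantRecord(
            c_notation=normalize_dashes(get("c_notation")),
            p_notation=normalize_dashes(get("p_notation")),
            variant_type=get("variant_type"),
            acmg_prior=get("acmg_prior", "VUS") or "VUS",
            acmg_followup=get("acmg_followup"),
            source=get("source"),
            construct=construct,
            scores=scores, positions=positions))
    return records


# -- operations ---------------------------------------------------------

def dedup_variants(records) -> list[VariantRecord]:
    """Merge records sharing a c. notation (first-seen order preserved).

    Merged records get source ``both`` when sources differ; conflicting
    prior classes resolve to the more severe one, with the discarded class
    recorded in ``notes``.
    """
    out: dict[str, VariantRecord] = {}
    for rec in records:
        key = rec.c_notation
        if key not in out:
            out[key] = rec
            continue
        kept = out[key]
        source = kept.source if kept.source == rec.source else "both"
        if acmg_severity(rec.acmg_prior) > acmg_severity(kept.acmg_prior):
            winner, loser = rec.acmg_prior, kept.acmg_prior
        else:
            winner, loser = kept.acmg_prior, rec.acmg_prior
        notes = kept.notes
        if winner != loser:
            notes = (notes + "; " if notes else "") + \
                f"merged prior classes {winner}/{loser}, kept {winner}"
        out[key] = replace(kept, source=source, acmg_prior=winner,
                           notes=notes)
    return list(out.values())


def _passes(score: float, cfg: SelectionConfig) -> bool:
    return score >= cfg.score_threshold if cfg.inclusive \
        else score > cfg.score_threshold


def spliceai_select(records, cfg: SelectionConfig | None = None
                    ) -> SelectionResult:
    """Partition records into selected and rejected-with-reason."""
    cfg = cfg or SelectionConfig()
    max_sev = acmg_severity(cfg.max_prior_class)
    selected, rejected = [], []
    for rec in records:
        if acmg_severity(rec.acmg_prior) > max_sev:
            rejected.append((rec, "class_too_high"))
            continue
        any_above = False
        hit = False
        for score, pos in zip(rec.scores, rec.positions):
            if _passes(score, cfg):
                any_above = True
                if abs(pos) <= cfg.window_bp:
                    hit = True
                    break
        if hit:
            selected.append(rec)
        elif any_above:
            rejected.append((rec, "outside_window"))
        else:
            rejected.append((rec, "no_score_above_threshold"))
    return SelectionResult(selected=selected, rejected=rejected)


def highest_score(record: VariantRecord) -> float:
    """Largest of the four SpliceAI delta scores."""
    return max(record.scores)
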