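"""ACMG reclassification of quantified splice assays.

Implements the gene-specific ClinGen rule set for RNA evidence from
minigene assays: residual wild-type transcript fraction is binned at
0% / 5% / 20%, complete loss of wild-type transcript supports
PVS1-very-strong (pathogenic), <5% residual supports PVS1-strong (likely
pathogenic), and a splice-silent result (100% wild-type) for a variant
whose only plausible mechanism is splicing (synonymous or non-canonical
splice-site) supports BP7 at strong level (benign). PP3-supporting is
recorded for in-silico evidence but never changes a class by itself.

This is deliberately *not* a full ACMG evidence combiner: only the
splice-assay criteria are applied; variants outside their reach keep
their prior class. The enzyme-activity PS3 pathway is not implemented —
the gene-specific recommendations advise against applying it to splicing
assays.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .coords import normalize_dashes, parse_cposition
from .events import AberrantTranscript, SpliceEvent
from .intake import VariantRecord, acmg_severity
from .model import MinigeneConstruct, TranscriptModel

__all__ = [
    "QuantifiedAssay", "CriteriaAssignment", "AssayError",
    "bin_residual", "assign_criteria", "summarize_cohort",
    "baseline_adjust", "read_assay_table", "parse_identity_text",
    "RESIDUAL_BINS",
]

RESIDUAL_BINS = ("none", "sub5", "low", "high")


class AssayError(ValueError):
    pass


@dataclass
class QuantifiedAssay:
    variant: VariantRecord
    wt_fraction: float
    aberrant: tuple[AberrantTranscript, ...] = ()
    construct: str = ""
    highest_score: float | None = None
    r_notation: str = ""
    p_notation_observed: str = ""
    aberrant_total_reported: float | None = None

    def __post_init__(self) -> None:
        self.aberrant = tuple(self.aberrant)
        if not 0.0 <= self.wt_fraction <= 100.0:
            raise AssayError(
                f"{self.variant.c_notation}: wt fraction out of range")
        # per-species percentages are rounded independently of the totals
        # column, so conservation is checked against the reported total
        # when one is carried
        ab = self.aberrant_total if self.aberrant_total_reported is None \
            else self.aberrant_total_reported
        total = self.wt_fraction + ab
        if not 99.0 <= total <= 101.0:
            raise AssayError(
                f"{self.variant.c_notation}: fractions sum to {total}")

    @property
    def aberrant_total(self) -> float:
        return sum(t.fraction for t in self.aberrant)

    @property
    def effective_wt_fraction(self) -> float:
        """WT fraction after discounting baseline-consistent species."""
        return self.wt_fraction + sum(
            t.fraction for t in self.aberrant if t.baseline_consistent)


@dataclass
class CriteriaAssignment:
    c_notation: str
    criteria: frozenset[tuple[str, str]]  # (code, strength)
    final_class: str
    residual_bin: str
    rationale: str
    construct: str = ""
    wt_fraction: float = 0.0
    prior_class: str = ""

    def has(self, code: str, strength: str | None = None) -> bool:
        return any(c == code and (strength is None or s == strength)
                   for c, s in self.criteria)


def bin_residual(wt_fraction: float) -> str:
    """Bin a residual wild-type percentage at the 0 / 5 / 20 cut-offs.

    ``none`` = exactly 0, ``sub5`` = (0, 5), ``low`` = [5, 20),
    ``high`` = [20, 100].
    """
    if not 0.0 <= wt_fraction <= 100.0:
        raise AssayError(f"wt fraction {wt_fraction} outside [0, 100]")
    if wt_fraction == 0.0:
        return "none"
    if wt_fraction < 5.0:
        return "sub5"
    if wt_fraction < 20.0:
        return "low"
    return "high"


def assign_criteria(assay: QuantifiedAssay, site_class: str | None = None,
                    pp3_threshold: float = 0.2) -> CriteriaAssignment:
    """Apply the splice-assay rules to one quantified assay.

    ``site_class`` (from :func:`minisplice.model.classify_variant_site`)
    refines the splice-silent branch: BP7-strong applies only when
    splicing is the sole plausible mechanism (synonymous or intronic
    variants); a splice-silent missense variant keeps its class.
    """
    wt = assay.wt_fraction
    vtype = assay.variant.variant_type
    if wt == 100.0 and any(not t.artefact for t in assay.aberrant):
        raise AssayError(f"{assay.variant.c_notation}: aberrant species "
                         "listed alongside 100% wild-type")
    rbin = bin_residual(wt)
    criteria: set[tuple[str, str]] = set()
    prior = assay.variant.acmg_prior
    score = assay.highest_score
    if score is None:
        score = max(assay.variant.scores)
    if score >= pp3_threshold:
        criteria.add(("PP3", "supporting"))

    if rbin == "none":
        criteria.add(("PVS1", "very_strong"))
        final = "P"
        why = "complete absence of wild-type transcript"
    elif rbin == "sub5":
        criteria.add(("PVS1", "strong"))
        final = "LP"
        why = f"residual wild-type transcript {wt:g}% (<5%)"
    elif wt == 100.0 and (vtype in ("Synonymous", "NCSS")
                          or (site_class or "exonic") != "exonic"):
        criteria.add(("BP7", "strong"))
        final = "B"
        why = ("no effect on splicing and no other plausible mechanism "
               f"({vtype or site_class})")
    elif wt == 100.0:
        final = prior
        why = "no effect on splicing; missense mechanism remains possible"
    else:
        final = prior
        why = (f"residual wild-type transcript {wt:g}% gives no splice "
               "criterion")
    return CriteriaAssignment(
        c_notation=assay.variant.c_notation,
        criteria=frozenset(criteria), final_class=final, residual_bin=rbin,
        rationale=why, construct=assay.construct, wt_fraction=wt,
        prior_class=prior)


def summarize_cohort(assignments) -> dict:
    """Machine-readable cohort counts per bin/criterion/class/construct."""
    assignments = list(assignments)
    if not assignments:
        raise AssayError("nothing to summarize")
    bins = {b: 0 for b in RESIDUAL_BINS}
    criteria: dict[str, int] = {}
    classes: dict[str, int] = {}
    constructs: dict[str, int] = {}
    no_effect = 0
    for a in assignments:
        bins[a.residual_bin] += 1
        for code, strength in a.criteria:
            key = f"{code}:{strength}"
            criteria[key] = criteria.get(key, 0) + 1
        classes[a.final_class] = classes.get(a.final_class, 0) + 1
        if a.construct:
            constructs[a.construct] = constructs.get(a.construct, 0) + 1
        if a.wt_fraction == 100.0:
            no_effect += 1
    return {"n": len(assignments), "bins": bins, "criteria": criteria,
            "final_classes": classes, "constructs": constructs,
            "no_effect": no_effect}


def baseline_adjust(assay: QuantifiedAssay,
                    construct: MinigeneConstruct | None,
                    tolerance: float = 10.0) -> QuantifiedAssay:
    """Flag aberrant species that match the construct's baseline splicing.

    A species whose event set equals a constitutive wild-type-construct
    species and whose fraction is within ``tolerance`` points of the
    baseline fraction is flagged ``baseline_consistent`` (and thereby
    excluded from :attr:`QuantifiedAssay.effective_wt_fraction`). The
    assay's raw fractions are never modified. Constructs without baseline
    data return the assay unchanged.
    """
    if construct is None or not construct.baseline:
        return assay
    adjusted = []
    for t in assay.aberrant:
        flag = False
        for base_events, base_frac in construct.baseline:
            if frozenset(t.events) == frozenset(base_events) and \
                    abs(t.fraction - base_frac) <= tolerance:
                flag = True
        adjusted.append(replace(t, baseline_consistent=flag))
    return replace(assay, aberrant=tuple(adjusted))


# ----------------------------------------------------------------------
# assay-table reading (quantification-table dialect)
# ----------------------------------------------------------------------

_PAREN_RE = re.compile(r"\(([^()]*)\)")
_PCT_RE = re.compile(r"(\d+(?:\.\d+)?)\s*%")


def _skip_events(indices: list[int]) -> list[SpliceEvent]:
    """Group exon indices into contiguous runs, one skip event per run."""
    runs: list[list[int]] = []
    for i in sorted(indices):
        if runs and i == runs[-1][-1] + 1:
            runs[-1].append(i)
        else:
            runs.append([i])
    return [SpliceEvent.exon_skip(*run) for run in runs]


def _chunk_events(text: str, model: TranscriptModel) -> list[SpliceEvent] | None:
    """Events for one species description, or None for unidentified."""
    t = text.lower()
    m = re.search(r"exon[s]?\s+([\d\s+and]+?)\s+skipping", t)
    if m:
        idx = [int(x) for x in re.findall(r"\d+", m.group(1))]
        return _skip_events(idx)
    m = re.search(r"intron\s+(\d+)\s+retention", t)
    if m:
        return [SpliceEvent(kind="intron_retention", intron=int(m.group(1)))]
    m = re.search(r"(\d+)\s*basepair\s*([53])'?\s*truncation\s*of\s*exon"
                  r"\s*(\d+)", t)
    if m:
        n, side, exon = int(m.group(1)), m.group(2), int(m.group(3))
        s, e = model.exon_span(exon)
        if side == "3":
            a, b = e - n + 1, e
        else:
            a, b = s, s + n - 1
        return [SpliceEvent(kind="exon_truncation",
                            start=parse_cposition(str(a)),
                            end=parse_cposition(str(b)),
                            side="5prime" if side == "5" else "3prime")]
    m = re.search(r"(\d+)\s*basepair\s*([53])'?\s*elongation\s*of\s*exon"
                  r"\s*(\d+)", t)
    if m:
        n, side, exon = int(m.group(1)), m.group(2), int(m.group(3))
        s, e = model.exon_span(exon)
        if side == "5":
            start = parse_cposition(f"{s}-{n}")
            end = parse_cposition(f"{s}-1")
            side_name = "5prime"
        else:
            start = parse_cposition(f"{e}+1")
            end = parse_cposition(f"{e}+{n}")
            side_name = "3prime"
        return [SpliceEvent(kind="exon_elongation", start=start, end=end,
                            side=side_name)]
    m = re.search(r"exon\s+(\d+)\s+elongation\s+until\s+(\d+)\s*\+\s*(\d+)",
                  t)
    if m:
        exon, anchor, n = int(m.group(1)), int(m.group(2)), int(m.group(3))
        return [SpliceEvent(kind="exon_elongation",
                            start=parse_cposition(f"{anchor}+1"),
                            end=parse_cposition(f"{anchor}+{n}"),
                            side="3prime")]
    m = re.search(r"(\d+)[-\s]*bp\s+pseudo[-\s]?exon", t)
    if m and "artefact" not in t:
        raise AssayError(f"pseudo-exon without coordinates: {text!r}")
    if "unidentified" in t:
        return None
    raise AssayError(f"unrecognized transcript identity: {text!r}")


def _split_species(text: str) -> list[str]:
    """Split an identity cell on top-level commas / 'and'."""
    parts: list[str] = []
    depth = 0
    cur = ""
    for ch in text:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if ch == "," and depth == 0:
            parts.append(cur)
            cur = ""
        else:
            cur += ch
    parts.append(cur)
    out: list[str] = []
    for p in parts:
        # split on ' and ' outside parentheses, but only between species:
        # a species is complete once its '(..%)' closed, so 'exon 6 and 7
        # skipping' stays together while '... (92%) and exon ...' splits
        depth = 0
        cur = ""
        i = 0
        while i < len(p):
            if p[i] == "(":
                depth += 1
            elif p[i] == ")":
                depth -= 1
            if depth == 0 and ")" in cur and p[i:i + 5] == " and ":
                out.append(cur)
                cur = ""
                i += 5
                continue
            cur += p[i]
            i += 1
        out.append(cur)
    cleaned = []
    for p in out:
        p = p.strip().strip(".").strip()
        p = re.sub(r"^(and|of|an?)\s+", "", p, flags=re.I).strip()
        if p:
            cleaned.append(p)
    return cleaned


def parse_identity_text(text: str, aberrant_total: float,
                        model: TranscriptModel) -> list[AberrantTranscript]:
    """Parse an 'identity of aberrant transcripts' cell into species.

    Handles the cohort vocabulary: exon skipping (single, contiguous and
    compound, e.g. 'exon 7 + 10 skipping'), intron retention, exon
    truncation/elongation, unidentified transcripts, and artefact
    parentheticals. A species printed without an explicit percentage
    receives the unaccounted remainder of the aberrant total.
    """
    text = normalize_dashes(text).replace("′", "'").strip()
    if not text:
        return []
    species: list[AberrantTranscript] = []
    pending: list[dict] = []
    for chunk in _split_species(text):
        parens = _PAREN_RE.findall(chunk)
        main = _PAREN_RE.sub("", chunk).strip().strip(".").strip()
        fractions: list[float] = []
        for par in parens:
            pct = [float(x) for x in _PCT_RE.findall(par)]
            if "artefact" in par.lower():
                species.append(AberrantTranscript(
                    events=(), fraction=pct[0] if pct else 0.0,
                    artefact=True, unidentified=True, label=par.strip()))
            else:
                fractions.extend(pct)
        if not main:
            continue
        if "artefact" in main.lower():
            species.append(AberrantTranscript(
                events=(), fraction=fractions[0] if fractions else 0.0,
                artefact=True, unidentified=True, label=main))
            continue
        events = _chunk_events(main, model)
        if events is None:  # unidentified transcript(s)
            if not fractions:
                pending.append({"events": None, "label": main})
            for f in fractions:
                species.append(AberrantTranscript(
                    events=(), fraction=f, unidentified=True, label=main))
            continue
        if fractions:
            species.append(AberrantTranscript(
                events=tuple(events), fraction=fractions[0], label=main))
        else:
            pending.append({"events": tuple(events), "label": main})
    if pending:
        remainder = aberrant_total - sum(t.fraction for t in species)
        share = max(remainder, 0.0) / len(pending)
        for p in pending:
            if p["events"] is None:
                species.append(AberrantTranscript(
                    events=(), fraction=share, unidentified=True,
                    label=p["label"]))
            else:
                species.append(AberrantTranscript(
                    events=p["events"], fraction=share, label=p["label"]))
    return species


_ASSAY_ALIASES = {
    "c_notation": ("cdna_variant", "c_notation", "variant"),
    "p_predicted": ("predicted_protein_variant", "protein_variant"),
    "acmg_prior": ("acmg_classification_august_2023",),
    "acmg_followup": ("acmg_classification_october_2024",),
    "highest_score": ("highest_spliceai_score", "highest_score"),
    "p_observed": ("observed_protein_variant",),
    "r_notation": ("rna_variant",),
    "wt_pct": ("percentage_of_wt_transcript", "wt_transcript",
               "percentage_of_wt_transcript_"),
    "aberrant_pct": ("percentage_of_aberrant_transcript",
                     "percentage_of_aberrant_transcript_"),
    "identity": ("identity_of_aberrant_transcript_s", "identity",
                 "identity_of_aberrant_transcripts"),
}


def _pct_value(text: str) -> float:
    m = _PCT_RE.search(str(text))
    if m:
        return float(m.group(1))
    return float(str(text).strip() or 0.0)


def read_assay_table(path: str | Path, model: TranscriptModel,
                     variants: list[VariantRecord] | None = None
                     ) -> list[QuantifiedAssay]:
    """Read a quantification TSV into assays, joining variant metadata.

    ``variants`` (e.g. from :func:`minisplice.intake.read_variant_table`)
    supplies variant type, construct and score vectors by c. notation;
    rows without a match fall back to the assay table's own columns.
    """
    from .intake import _canon  # shared header canonicalization
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    canon = {_canon(c): c for c in df.columns}
    cols = {}
    for key, aliases in _ASSAY_ALIASES.items():
        for a in aliases:
            if a in canon:
                cols[key] = canon[a]
                break
    for req in ("c_notation", "wt_pct", "aberrant_pct"):
        if req not in cols:
            raise AssayError(f"assay table missing required column {req}")
    by_c = {v.c_notation: v for v in (variants or [])}
    assays = []
    for _, row in df.iterrows():
        get = lambda k: normalize_dashes(str(row[cols[k]])).strip() \
            if k in cols else ""
        c_not = get("c_notation")
        wt = _pct_value(get("wt_pct"))
        ab_total = _pct_value(get("aberrant_pct"))
        var = by_c.get(c_not)
        if var is None:
            var = VariantRecord(
                c_notation=c_not, p_notation=get("p_predicted"),
                acmg_prior=get("acmg_prior") or "VUS",
                acmg_followup=get("acmg_followup"))
        species = parse_identity_text(get("identity"), ab_total, model)
        score = float(get("highest_score")) if get("highest_score") else None
        assays.append(QuantifiedAssay(
            variant=var, wt_fraction=wt, aberrant=tuple(species),
            construct=var.construct or "",
            highest_score=score, r_notation=get("r_notation"),
            p_notation_observed=get("p_observed"),
            aberrant_total_reported=ab_total))
    return assays
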