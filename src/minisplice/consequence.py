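"""HGVS-style RNA (r.) and protein (p.) consequences of splice events.

RNA notation is coordinate arithmetic only. Protein notation additionally
requires the model's CDS sequence: the altered transcript is rebuilt
segment by segment, translated, and compared with the reference protein to
locate the first changed residue and, for frameshifts, the new stop
(``fs*N`` counts from the first changed residue to the stop inclusive).

Cohort tables print compound multi-event species in a non-standard joined
style (``r.644_725del_999_1128del``); ``dialect="compound"`` reproduces it,
``dialect="hgvs"`` emits the bracketed standard form.
"""
from __future__ import annotations

import re
from dataclasses import dataclass

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .coords import CodingPosition, ParseError, normalize_dashes, \
    parse_cposition
from .events import AberrantTranscript, SpliceEvent
from .model import ModelError, TranscriptModel, codon_index, interval_length

__all__ = [
    "ConsequenceReport", "rna_notation", "allele_notation", "parse_rna",
    "delta_length", "protein_consequence", "first_affected_codon",
    "events_to_transcript_sequence",
]

_POS = r"\d+(?:[+-]\d+)?"
_OP_RE = re.compile(
    rf"_?(?P<a>{_POS})_(?P<b>{_POS})"
    rf"(?:(?P<del>del)|ins(?P<c>{_POS})_(?P<d>{_POS}))")


@dataclass
class ConsequenceReport:
    r_notation: str
    delta_len: int
    frame: str  # "in_frame" | "frameshift"
    p_notation: str | None
    first_affected_codon: int


# ----------------------------------------------------------------------
# coordinate-level arithmetic
# ----------------------------------------------------------------------

def delta_length(events, model: TranscriptModel) -> int:
    """Signed nt length change of a transcript carrying ``events``."""
    total = 0
    for ev in events:
        if ev.kind == "exon_skip":
            total -= sum(model.exon_length(i) for i in ev.exons)
        elif ev.kind == "exon_truncation":
            total -= interval_length(ev.start, ev.end, model)
        elif ev.kind in ("pseudoexon", "exon_elongation"):
            total += interval_length(ev.start, ev.end, model)
        elif ev.kind == "intron_retention":
            total += model.intron_length(ev.intron)
    return total


def _event_sort_base(ev: SpliceEvent, model: TranscriptModel) -> int:
    if ev.kind == "exon_skip":
        return model.exon_span(ev.exons[0])[0]
    if ev.kind == "intron_retention":
        return model.exon_span(ev.intron)[1]
    return ev.start.base if ev.start.is_exonic or ev.start.offset > 0 \
        else ev.start.base - 1


def _op_string(ev: SpliceEvent, model: TranscriptModel) -> str:
    if ev.kind == "exon_skip":
        a = model.exon_span(ev.exons[0])[0]
        b = model.exon_span(ev.exons[-1])[1]
        return f"{a}_{b}del"
    if ev.kind == "exon_truncation":
        return f"{ev.start}_{ev.end}del"
    if ev.kind == "exon_elongation":
        if ev.start.offset < 0:  # acceptor side: before the exon start
            s = ev.end.base
            return f"{s - 1}_{s}ins{ev.start}_{ev.end}"
        e = ev.start.base  # donor side: after the exon end
        return f"{e}_{e + 1}ins{ev.start}_{ev.end}"
    if ev.kind == "pseudoexon":
        intron = model.intron_of(ev.start)
        e = model.exon_span(intron)[1]
        return f"{e}_{e + 1}ins{ev.start}_{ev.end}"
    if ev.kind == "intron_retention":
        e = model.exon_span(ev.intron)[1]
        return f"{e}_{e + 1}ins{e}+1_{e + 1}-1"
    raise ModelError(f"unknown event kind {ev.kind}")  # pragma: no cover


def _transcript_body(events, model: TranscriptModel,
                     dialect: str = "compound") -> str:
    if not events:
        return "="
    evs = sorted(events, key=lambda e: _event_sort_base(e, model))
    ops = [_op_string(e, model) for e in evs]
    if len(ops) == 1:
        return ops[0]
    if dialect == "compound":
        return "_".join(ops)
    return "[" + ";".join(ops) + "]"


def rna_notation(events, model: TranscriptModel,
                 dialect: str = "compound") -> str:
    """Serialize one transcript's events, e.g. ``r.644_725del``."""
    return "r." + _transcript_body(events, model, dialect)


def allele_notation(species, model: TranscriptModel,
                    dialect: str = "compound",
                    wildtype_last: bool = False,
                    force_brackets: bool = False) -> str:
    """Serialize several co-occurring species: ``r.[x,y,=]``.

    Each entry of ``species`` is a (possibly empty = wild-type) event list;
    order is preserved unless ``wildtype_last`` moves empty species to the
    end, the conventional placement when composing from scratch. A single
    non-wild-type species is written bare unless ``force_brackets``
    (tables conventionally bracket even single aberrant species).
    """
    species = list(species)
    if wildtype_last:
        species.sort(key=lambda evs: (len(evs) == 0,))
    if len(species) == 1 and not (force_brackets and species[0]):
        return rna_notation(species[0], model, dialect)
    bodies = [_transcript_body(evs, model, dialect) for evs in species]
    return "r.[" + ",".join(bodies) + "]"


# ----------------------------------------------------------------------
# r.-string parsing
# ----------------------------------------------------------------------

def _deletion_event(a: CodingPosition, b: CodingPosition,
                    model: TranscriptModel) -> SpliceEvent:
    if not (a.is_exonic and b.is_exonic):
        raise ParseError(f"intronic deletion bounds {a}..{b} unsupported")
    ea, eb = model.exon_containing(a.base), model.exon_containing(b.base)
    if a.base == model.exon_span(ea)[0] and b.base == model.exon_span(eb)[1]:
        return SpliceEvent.exon_skip(*range(ea, eb + 1))
    if ea != eb:
        raise ParseError(f"deletion {a}_{b} is neither whole exons "
                         "nor within one exon")
    s, e = model.exon_span(ea)
    if b.base == e:
        return SpliceEvent(kind="exon_truncation", start=a, end=b,
                           side="3prime")
    if a.base == s:
        return SpliceEvent(kind="exon_truncation", start=a, end=b,
                           side="5prime")
    raise ParseError(f"deletion {a}_{b} does not abut an exon boundary")


def _insertion_event(c: CodingPosition, d: CodingPosition,
                     model: TranscriptModel) -> SpliceEvent:
    if c.is_exonic or d.is_exonic:
        raise ParseError(f"insertion of exonic interval {c}_{d} unsupported")
    intron = model.intron_of(c)
    abuts_donor = c.offset == 1
    abuts_acceptor = d.offset == -1
    if abuts_donor and abuts_acceptor:
        return SpliceEvent(kind="intron_retention", intron=intron)
    if abuts_acceptor:
        return SpliceEvent(kind="exon_elongation", start=c, end=d,
                           side="5prime")
    if abuts_donor:
        return SpliceEvent(kind="exon_elongation", start=c, end=d,
                           side="3prime")
    return SpliceEvent(kind="pseudoexon", start=c, end=d)


def _parse_species(body: str, model: TranscriptModel) -> list[SpliceEvent]:
    if body == "=":
        return []
    events = []
    pos = 0
    while pos < len(body):
        m = _OP_RE.match(body, pos)
        if not m:
            raise ParseError(f"cannot parse r. species at {body[pos:]!r}")
        a, b = parse_cposition(m.group("a")), parse_cposition(m.group("b"))
        if m.group("del"):
            events.append(_deletion_event(a, b, model))
        else:
            c = parse_cposition(m.group("c"))
            d = parse_cposition(m.group("d"))
            events.append(_insertion_event(c, d, model))
        pos = m.end()
    return events


def parse_rna(text: str, model: TranscriptModel) -> list[list[SpliceEvent]]:
    """Parse an r. string into species event lists (``[]`` = wild-type)."""
    s = normalize_dashes(text).replace(" ", "").strip()
    if not s.startswith("r."):
        raise ParseError(f"r. string must start with 'r.': {text!r}")
    s = s[2:]
    if s.startswith("[") and s.endswith("]"):
        parts = s[1:-1].split(",")
    else:
        parts = [s]
    return [_parse_species(p, model) for p in parts]


# ----------------------------------------------------------------------
# protein-level consequences
# ----------------------------------------------------------------------

def events_to_transcript_sequence(events, model: TranscriptModel) -> str:
    """Spliced coding-region sequence of a transcript carrying ``events``."""
    if model.cds_sequence is None:
        raise ModelError("model has no cds_sequence; protein-level "
                         "consequences unavailable")
    cds = model.cds_sequence
    skipped: set[int] = set()
    trunc: dict[int, tuple[int, int]] = {}
    elong5: dict[int, str] = {}
    elong3: dict[int, str] = {}
    intron_ins: dict[int, str] = {}
    for ev in events:
        if ev.kind == "exon_skip":
            skipped.update(ev.exons)
        elif ev.kind == "exon_truncation":
            exon = model.exon_containing(ev.start.base)
            if model.exon_containing(ev.end.base) != exon:
                raise ModelError("truncation interval spans exons")
            trunc[exon] = (ev.start.base, ev.end.base)
        elif ev.kind == "exon_elongation":
            seq = model.intronic_sequence(ev.start, ev.end)
            if ev.start.offset < 0:
                elong5[model.exon_containing(ev.end.base)] = seq
            else:
                elong3[model.exon_containing(ev.start.base)] = seq
        elif ev.kind == "pseudoexon":
            intron_ins[model.intron_of(ev.start)] = \
                model.intronic_sequence(ev.start, ev.end)
        elif ev.kind == "intron_retention":
            if ev.intron not in model.intron_sequences:
                raise ModelError(f"intron {ev.intron} sequence unknown; "
                                 "cannot build retained transcript")
            intron_ins[ev.intron] = model.intron_sequences[ev.intron]
    pieces: list[str] = []
    for idx, start, end in model.exons:
        if idx not in skipped:
            s, e = start.base, end.base
            seg = cds[s - 1:e]
            if idx in trunc:
                a, b = trunc[idx]
                seg = cds[s - 1:a - 1] + cds[b:e]
            if idx in elong5:
                seg = elong5[idx] + seg
            if idx in elong3:
                seg = seg + elong3[idx]
            pieces.append(seg)
        if idx in intron_ins:
            pieces.append(intron_ins[idx])
    return "".join(pieces)


def _translate(seq: str) -> str:
    """Translate up to and including the first stop ('*')."""
    prot = str(Seq(seq[:len(seq) - len(seq) % 3]).translate())
    stop = prot.find("*")
    return prot if stop < 0 else prot[:stop + 1]


def _p_frameshift(ref_p: str, mut_p: str) -> str:
    first = None
    for i, (a, b) in enumerate(zip(ref_p, mut_p)):
        if a != b:
            first = i
            break
    if first is None:
        first = min(len(ref_p), len(mut_p))
    if first >= len(mut_p):  # mutant truncated exactly at a former residue
        return f"p.{seq3(ref_p[first])}{first + 1}Ter"
    new = mut_p[first]
    if new == "*":
        return f"p.{seq3(ref_p[first])}{first + 1}*"
    stop = mut_p.find("*", first)
    tail = "?" if stop < 0 else str(stop - first + 1)
    return f"p.{seq3(ref_p[first])}{first + 1}{seq3(new)}fs*{tail}"


def _p_inframe(ref_p: str, mut_p: str) -> str:
    if mut_p == ref_p:
        return "p.(=)"
    p = 0
    while p < min(len(ref_p), len(mut_p)) and ref_p[p] == mut_p[p]:
        p += 1
    s = 0
    while s < min(len(ref_p), len(mut_p)) - p and \
            ref_p[-1 - s] == mut_p[-1 - s]:
        s += 1
    ref_mid = ref_p[p:len(ref_p) - s]
    mut_mid = mut_p[p:len(mut_p) - s]
    if ref_mid and not mut_mid:
        if len(ref_mid) == 1:
            return f"p.{seq3(ref_mid)}{p + 1}del"
        return (f"p.{seq3(ref_mid[0])}{p + 1}_"
                f"{seq3(ref_mid[-1])}{p + len(ref_mid)}del")
    ins = seq3(mut_mid)
    if not ref_mid:
        return (f"p.{seq3(ref_p[p - 1])}{p}_"
                f"{seq3(ref_p[p])}{p + 1}ins{ins}")
    if len(ref_mid) == 1:
        return f"p.{seq3(ref_mid)}{p + 1}delins{ins}"
    return (f"p.{seq3(ref_mid[0])}{p + 1}_"
            f"{seq3(ref_mid[-1])}{p + len(ref_mid)}delins{ins}")


def first_affected_codon(events, model: TranscriptModel) -> int:
    """Codon of the 5'-most exonic position a transcript's events alter.

    Coordinate-only lower bound on the protein position: when the junction
    codon resynthesizes the reference residue the sequence-based first
    *changed* residue can sit one codon downstream.
    """
    if not events:
        raise ModelError("no events")
    bases = []
    for ev in events:
        if ev.kind == "exon_skip":
            bases.append(model.exon_span(ev.exons[0])[0])
        elif ev.kind == "exon_truncation":
            bases.append(ev.start.base)
        elif ev.kind in ("pseudoexon", "exon_elongation", "intron_retention"):
            if ev.kind == "intron_retention":
                downstream = ev.intron + 1
            elif ev.start.offset > 0:  # donor-side insertion
                downstream = model.exon_containing(ev.start.base) + 1
            else:
                downstream = model.exon_containing(ev.end.base)
            bases.append(model.exon_span(downstream)[0])
    return codon_index(min(bases), model)


def protein_consequence(events, model: TranscriptModel,
                        dialect: str = "compound") -> ConsequenceReport:
    """Full consequence report for one transcript's events.

    Requires ``model.cds_sequence``; raises :class:`ModelError` otherwise.
    """
    mut = events_to_transcript_sequence(events, model)
    delta = len(mut) - model.cds_length
    frame = "in_frame" if delta % 3 == 0 else "frameshift"
    ref_p = _translate(model.cds_sequence)
    mut_p = _translate(mut)
    if not events:
        p_not = "p.(=)"
        fac = 0
    else:
        p_not = _p_frameshift(ref_p, mut_p) if frame == "frameshift" \
            else _p_inframe(ref_p, mut_p)
        fac = first_affected_codon(events, model)
    return ConsequenceReport(
        r_notation=rna_notation(events, model, dialect),
        delta_len=delta, frame=frame, p_notation=p_not,
        first_affected_codon=fac)
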