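"""Transcript model: exon map in c. coordinates, codon arithmetic,
variant-site classification and minigene construct geometry.

The model is a single-transcript coding-coordinate view of a gene: ordered
exons tile the CDS range ``c.1..cds_length`` without gaps (introns exist
only between consecutive exons and have no c. extent of their own). An
optional CDS sequence enables protein-level consequence prediction; per-
intron sequences or splice-site flank snippets enable sizing and sequence
resolution of intron-derived insertions.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .coords import CodingPosition, ParseError, parse_cposition, \
    parse_variant_position
from .events import SpliceEvent

__all__ = [
    "TranscriptModel", "MinigeneConstruct", "ModelError", "UnassignableError",
    "codon_index", "classify_variant_site", "assign_construct",
    "interval_length", "load_model", "load_bundled_model", "bundled_path",
]

SITE_CLASSES = ("exonic", "canonical_splice", "NCSS", "deep_intronic")


class ModelError(ValueError):
    pass


class UnassignableError(ModelError):
    """No minigene construct contains the variant position."""


@dataclass
class MinigeneConstruct:
    """A wild-type minigene: an exon window plus reporter flanks.

    ``baseline`` lists splice products the *wild-type* construct produces
    constitutively (event tuple, expected lane fraction in percent), e.g.
    partial skipping of a cassette exon.
    """

    name: str
    first_exon: int
    last_exon: int
    flank_5_len: int
    flank_3_len: int
    baseline: tuple[tuple[tuple[SpliceEvent, ...], float], ...] = ()

    def __post_init__(self) -> None:
        if self.first_exon > self.last_exon:
            raise ModelError(f"{self.name}: empty exon span")
        total = sum(f for _, f in self.baseline)
        if total > 100.0 + 1e-9:
            raise ModelError(f"{self.name}: baseline fractions sum to {total}")

    def exon_range(self) -> range:
        return range(self.first_exon, self.last_exon + 1)


@dataclass
class TranscriptModel:
    gene_label: str
    exons: list[tuple[int, CodingPosition, CodingPosition]]
    cds_sequence: str | None = None
    exon_provenance: dict[int, dict] = field(default_factory=dict)
    intron_sequences: dict[int, str] = field(default_factory=dict)
    intron_flanks: dict[int, dict] = field(default_factory=dict)
    constructs: list[MinigeneConstruct] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ModelError("model needs at least one exon")
        prev_end = 0
        for idx, start, end in self.exons:
            if start.offset or end.offset:
                raise ModelError(f"exon {idx} bounds must be exonic")
            if start.base != prev_end + 1:
                raise ModelError(
                    f"exon {idx} does not tile c. space "
                    f"(starts at {start.base}, expected {prev_end + 1})")
            if end.base < start.base:
                raise ModelError(f"exon {idx} has negative length")
            prev_end = end.base
        if self.cds_sequence is not None:
            self.cds_sequence = self.cds_sequence.upper()
            if len(self.cds_sequence) != self.cds_length:
                raise ModelError(
                    f"CDS length {len(self.cds_sequence)} != exon map end "
                    f"{self.cds_length}")
        if self.cds_length % 3:
            raise ModelError("CDS length not divisible by 3")
        for c in self.constructs:
            if c.first_exon < self.exons[0][0] or \
                    c.last_exon > self.exons[-1][0]:
                raise ModelError(f"construct {c.name} outside exon map")

    # -- geometry -------------------------------------------------------
    @property
    def cds_length(self) -> int:
        return self.exons[-1][2].base

    @property
    def exon_indices(self) -> list[int]:
        return [i for i, _, _ in self.exons]

    def exon_span(self, index: int) -> tuple[int, int]:
        for i, s, e in self.exons:
            if i == index:
                return s.base, e.base
        raise ModelError(f"no exon {index} in model")

    def exon_length(self, index: int) -> int:
        s, e = self.exon_span(index)
        return e - s + 1

    def exon_containing(self, base: int) -> int:
        if not 1 <= base <= self.cds_length:
            raise ModelError(f"c.{base} outside model span "
                             f"1..{self.cds_length}")
        for i, s, e in self.exons:
            if s.base <= base <= e.base:
                return i
        raise ModelError(f"c.{base} not covered by any exon")  # unreachable

    def intron_of(self, pos: CodingPosition) -> int:
        """Intron index (= upstream exon index) an intronic position lies in."""
        if pos.is_exonic:
            raise ModelError(f"c.{pos} is exonic")
        exon = self.exon_containing(pos.base)
        s, e = self.exon_span(exon)
        if pos.offset > 0:
            if pos.base != e:
                raise ModelError(f"c.{pos}: +offset must anchor a donor base")
            return exon
        if pos.base != s:
            raise ModelError(f"c.{pos}: -offset must anchor an acceptor base")
        return exon - 1

    def intron_length(self, intron: int) -> int:
        if intron in self.intron_sequences:
            return len(self.intron_sequences[intron])
        raise ModelError(f"intron {intron} length unknown "
                         "(no intron sequence in model)")

    def intronic_sequence(self, start: CodingPosition,
                          end: CodingPosition) -> str:
        """Nucleotides of a closed intronic interval, 5'->3'.

        Resolved from a full intron sequence when present, else from stored
        donor/acceptor flank snippets.
        """
        intron = self.intron_of(start)
        if self.intron_of(end) != intron:
            raise ModelError(f"interval {start}..{end} spans introns")
        n = interval_length(start, end, self)
        if intron in self.intron_sequences:
            seq = self.intron_sequences[intron]
            if start.offset > 0:
                return seq[start.offset - 1:start.offset - 1 + n]
            return seq[len(seq) + end.offset - n + 1:len(seq) + end.offset + 1]
        flanks = self.intron_flanks.get(intron, {})
        if start.offset < 0 and "acceptor" in flanks:
            acc = flanks["acceptor"]  # last len(acc) bases of the intron
            lo = len(acc) + start.offset  # offset -k -> index len-k
            hi = len(acc) + end.offset + 1
            if lo >= 0:
                return acc[lo:hi]
        if start.offset > 0 and "donor" in flanks:
            don = flanks["donor"]  # first len(don) bases of the intron
            if end.offset <= len(don):
                return don[start.offset - 1:end.offset]
        raise ModelError(
            f"no sequence available for intron {intron} interval "
            f"{start}..{end}")

    def construct_by_name(self, name: str) -> MinigeneConstruct:
        for c in self.constructs:
            if c.name == name:
                return c
        raise ModelError(f"no construct named {name!r}")


def interval_length(start: CodingPosition, end: CodingPosition,
                    model: TranscriptModel | None = None) -> int:
    """Closed-interval length in nt between two c. positions.

    Handles exonic intervals, intervals within one intron anchored on the
    same exonic base, and (given a model with intron lengths) intervals
    anchored across a whole intron.
    """
    if start.is_exonic and end.is_exonic:
        n = end.base - start.base + 1
    elif start.base == end.base and (start.offset > 0) == (end.offset > 0):
        n = end.offset - start.offset + 1
    elif model is not None and start.offset > 0 and end.offset < 0:
        intron = model.intron_of(start)
        if model.intron_of(end) != intron:
            raise ModelError("interval spans more than one intron")
        ilen = model.intron_length(intron)
        n = (ilen + end.offset + 1) - start.offset + 1
    else:
        raise ModelError(f"cannot size interval {start}..{end}")
    if n <= 0:
        raise ModelError(f"empty or inverted interval {start}..{end}")
    return n


def codon_index(pos: CodingPosition | int,
                model: TranscriptModel | None = None) -> int:
    """1-based index of the codon containing an exonic c. position."""
    if isinstance(pos, CodingPosition):
        if not pos.is_exonic:
            raise ModelError(f"c.{pos} is intronic; codons are exonic only")
        base = pos.base
    else:
        base = int(pos)
    if base < 1 or (model is not None and base > model.cds_length):
        raise ModelError(f"c.{base} outside CDS")
    return (base - 1) // 3 + 1


def classify_variant_site(variant_c: str, model: TranscriptModel,
                          ncss_window: int = 20) -> str:
    """Site class of a variant: exonic, canonical_splice, NCSS or
    deep_intronic.

    The non-canonical splice-site (NCSS) window covers intronic offsets
    ``3 <= |offset| <= ncss_window``; the invariant +-1/+-2 dinucleotides
    are canonical_splice; anything deeper is deep_intronic.
    """
    pos = parse_variant_position(variant_c)
    if not 1 <= pos.base <= model.cds_length:
        raise ModelError(f"{variant_c!r} outside model span")
    model.exon_containing(pos.base)
    off = abs(pos.offset)
    if off == 0:
        return "exonic"
    if off <= 2:
        return "canonical_splice"
    if off <= ncss_window:
        return "NCSS"
    return "deep_intronic"


def assign_construct(variant_c: str, model: TranscriptModel,
                     constructs: list[MinigeneConstruct] | None = None,
                     declared: str | None = None) -> str:
    """Name of the minigene construct covering a variant position.

    A construct covers a position when the position's anchor base lies
    within its exon window (intervening introns included). When several
    constructs cover it, a ``declared`` name from the input table wins;
    otherwise the construct whose window centre is nearest is chosen.
    """
    constructs = constructs if constructs is not None else model.constructs
    pos = parse_variant_position(variant_c)
    candidates = []
    for c in constructs:
        lo, _ = model.exon_span(c.first_exon)
        _, hi = model.exon_span(c.last_exon)
        if lo <= pos.base <= hi:
            candidates.append((c, (lo + hi) / 2.0))
    if declared:
        names = [c.name for c, _ in candidates]
        if declared in names:
            return declared
        if any(c.name == declared for c in constructs):
            raise UnassignableError(
                f"declared construct {declared} does not cover {variant_c}")
        raise ModelError(f"unknown construct {declared!r}")
    if not candidates:
        raise UnassignableError(f"no construct covers {variant_c}")
    candidates.sort(key=lambda t: abs(pos.base - t[1]))
    return candidates[0][0].name


# -- model file I/O -----------------------------------------------------

def _parse_baseline(entries: list[dict]) -> tuple:
    out = []
    for b in entries:
        events = tuple(SpliceEvent.from_dict(e) for e in b["events"])
        out.append((events, float(b["fraction"])))
    return tuple(out)


def load_model(path: str | Path | dict) -> TranscriptModel:
    """Read a transcript-model JSON file (or pre-parsed dict)."""
    data = path if isinstance(path, dict) else \
        json.loads(Path(path).read_text())
    try:
        exons = [(int(i), parse_cposition(str(s)), parse_cposition(str(e)))
                 for i, s, e in data["exons"]]
    except (KeyError, ParseError, TypeError) as exc:
        raise ModelError(f"bad exon table in model file: {exc}") from exc
    constructs = [
        MinigeneConstruct(
            name=c["name"], first_exon=int(c["first_exon"]),
            last_exon=int(c["last_exon"]),
            flank_5_len=int(c["flank_5_len"]),
            flank_3_len=int(c["flank_3_len"]),
            baseline=_parse_baseline(c.get("baseline", [])),
        )
        for c in data.get("constructs", [])
    ]
    return TranscriptModel(
        gene_label=data.get("gene_label", ""),
        exons=exons,
        cds_sequence=data.get("cds_sequence"),
        exon_provenance={int(k): v for k, v in
                         data.get("exon_provenance", {}).items()},
        intron_sequences={int(k): v for k, v in
                          data.get("intron_sequences", {}).items()},
        intron_flanks={int(k): v for k, v in
                       data.get("intron_flanks", {}).items()},
        constructs=constructs,
    )


def save_model(model: TranscriptModel, path: str | Path) -> None:
    data = {
        "gene_label": model.gene_label,
        "exons": [[i, s.serialize(), e.serialize()]
                  for i, s, e in model.exons],
        "cds_sequence": model.cds_sequence,
        "exon_provenance": {str(k): v
                            for k, v in model.exon_provenance.items()},
        "intron_sequences": {str(k): v
                             for k, v in model.intron_sequences.items()},
        "intron_flanks": {str(k): v for k, v in model.intron_flanks.items()},
        "constructs": [
            {"name": c.name, "first_exon": c.first_exon,
             "last_exon": c.last_exon, "flank_5_len": c.flank_5_len,
             "flank_3_len": c.flank_3_len,
             "baseline": [{"events": [e.to_dict() for e in events],
                           "fraction": f} for events, f in c.baseline]}
            for c in model.constructs],
    }
    Path(path).write_text(json.dumps(data, indent=1) + "\n")


def bundled_path(name: str) -> Path:
    """Filesystem path of a packaged data fixture."""
    return Path(resources.files("minisplice.data") / name)


def load_bundled_model() -> TranscriptModel:
    """The packaged RPE65 minigene model.

    Exon map from the cohort's observed r. coordinates; the CDS is a
    synthetic, constraint-engineered stand-in (see the fixture's
    ``cds_provenance`` field), not the biological RPE65 mRNA.
    """
    return load_model(bundled_path("rpe65_model_synthetic_cds.json"))
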