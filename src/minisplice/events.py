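"""Splice-event algebra: the aberrant products a minigene assay can reveal.

Events are coordinate-level descriptions (exon skips, pseudo-exon
inclusions, exon truncations/elongations, intron retentions); sequence-level
interpretation lives in :mod:`minisplice.consequence`.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .coords import CodingPosition, parse_cposition

__all__ = ["SpliceEvent", "AberrantTranscript", "EVENT_KINDS"]

EVENT_KINDS = frozenset({
    "exon_skip", "pseudoexon", "exon_truncation", "exon_elongation",
    "intron_retention",
})


@dataclass(frozen=True)
class SpliceEvent:
    """One splicing aberration on a single transcript.

    Payload by kind:

    * ``exon_skip`` — ``exons``: contiguous 1-based exon indices removed.
    * ``pseudoexon`` — ``start``/``end``: intronic interval included as an
      extra exon (both positions inside the same intron).
    * ``exon_truncation`` — ``start``/``end``: exonic interval removed;
      must abut one exon boundary (``side`` is 5' or 3' of that exon).
    * ``exon_elongation`` — ``start``/``end``: intronic interval retained
      adjacent to an exon boundary (acceptor side: negative offsets;
      donor side: positive offsets).
    * ``intron_retention`` — ``intron``: 1-based intron index retained in
      full (intron *k* follows exon *k*).
    """

    kind: str
    exons: tuple[int, ...] = ()
    start: CodingPosition | None = None
    end: CodingPosition | None = None
    side: str | None = None  # "5prime" | "3prime" where applicable
    intron: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind == "exon_skip":
            if not self.exons:
                raise ValueError("exon_skip needs exon indices")
            idx = list(self.exons)
            if idx != sorted(idx) or any(
                    b - a != 1 for a, b in zip(idx, idx[1:])):
                raise ValueError(
                    f"exon_skip indices must be contiguous ascending: {idx}")
        elif self.kind == "intron_retention":
            if self.intron is None:
                raise ValueError("intron_retention needs an intron index")
        else:
            if self.start is None or self.end is None:
                raise ValueError(f"{self.kind} needs a start/end interval")

    # -- construction helpers -------------------------------------------
    @classmethod
    def exon_skip(cls, *exons: int) -> "SpliceEvent":
        return cls(kind="exon_skip", exons=tuple(exons))

    @classmethod
    def from_dict(cls, d: dict) -> "SpliceEvent":
        kind = d["kind"]
        kw: dict = {"kind": kind}
        if "exons" in d:
            kw["exons"] = tuple(d["exons"])
        for key in ("start", "end"):
            if d.get(key) is not None:
                v = d[key]
                kw[key] = v if isinstance(v, CodingPosition) else \
                    parse_cposition(str(v))
        if d.get("side") is not None:
            kw["side"] = d["side"]
        if d.get("intron") is not None:
            kw["intron"] = int(d["intron"])
        return cls(**kw)

    def to_dict(self) -> dict:
        d: dict = {"kind": self.kind}
        if self.exons:
            d["exons"] = list(self.exons)
        if self.start is not None:
            d["start"] = self.start.serialize()
        if self.end is not None:
            d["end"] = self.end.serialize()
        if self.side is not None:
            d["side"] = self.side
        if self.intron is not None:
            d["intron"] = self.intron
        return d


@dataclass
class AberrantTranscript:
    """One observed splice product: its events and its lane fraction."""

    events: tuple[SpliceEvent, ...] = ()
    fraction: float = 0.0
    artefact: bool = False
    unidentified: bool = False
    label: str = ""
    baseline_consistent: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        self.events = tuple(self.events)
        if self.unidentified and self.events:
            raise ValueError("unidentified transcript cannot carry events")
        if not 0.0 <= self.fraction <= 100.0:
            raise ValueError(f"fraction out of range: {self.fraction}")
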