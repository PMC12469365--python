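"""RNA/protein consequence annotation against independent oracles.

The protein oracle is deliberately primitive: string surgery on the CDS
plus naive codon-table translation, sharing no code with the package's
segment-assembly + Biopython path.
"""
import re

import numpy as np
import pytest

from minisplice.consequence import (allele_notation, delta_length,
                                    events_to_transcript_sequence,
                                    first_affected_codon, parse_rna,
                                    protein_consequence, rna_notation)
from minisplice.coords import normalize_dashes, parse_cposition
from minisplice.events import SpliceEvent
from minisplice.model import ModelError, TranscriptModel
from minisplice.synth import GeneratorConfig, gen_model

_CODONS = {}
_BASES = "TCAG"
_AA = ("FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG")
for _i, _a in enumerate(_AA):
    _CODONS[_BASES[_i // 16] + _BASES[_i // 4 % 4] + _BASES[_i % 4]] = _a

AA3 = {"A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
       "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
       "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
       "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val"}


def oracle_translate(seq):
    out = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        aa = _CODONS[seq[i:i + 3]]
        out.append(aa)
        if aa == "*":
            break
    return "".join(out)


def oracle_frameshift(ref_cds, mut_cds):
    """(first changed residue, ref aa, new aa, codons to stop inclusive)."""
    ref_p, mut_p = oracle_translate(ref_cds), oracle_translate(mut_cds)
    first = next(i for i, (a, b) in enumerate(zip(ref_p, mut_p)) if a != b)
    stop = mut_p.index("*", first)
    return first + 1, ref_p[first], mut_p[first], stop - first + 1


_FS_RE = re.compile(r"^p\.([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2})fs\*(\d+)$")


# ----------------------------------------------------------------------
# r. notation
# ----------------------------------------------------------------------

def test_rna_notation_examples(model):
    assert rna_notation([SpliceEvent.exon_skip(7)], model) == "r.644_725del"
    assert rna_notation([], model) == "r.="
    elong = SpliceEvent.from_dict({"kind": "exon_elongation",
                                   "start": "1339-2", "end": "1339-1"})
    assert rna_notation([elong], model) == "r.1338_1339ins1339-2_1339-1"
    ret = SpliceEvent(kind="intron_retention", intron=4)
    assert rna_notation([ret], model) == "r.353_354ins353+1_354-1"


def test_rna_notation_dialects(model):
    two = [SpliceEvent.exon_skip(7), SpliceEvent.exon_skip(10)]
    assert rna_notation(two, model, dialect="compound") == \
        "r.644_725del_999_1128del"
    assert rna_notation(two, model, dialect="hgvs") == \
        "r.[644_725del;999_1128del]"


def test_rna_roundtrip_on_cohort_strings(model, assays):
    """parse + serialize is the identity on all 59 quantified r. strings."""
    assert len(assays) == 59
    for assay in assays:
        norm = normalize_dashes(assay.r_notation).replace(" ", "")
        species = parse_rna(assay.r_notation, model)
        out = allele_notation(species, model, dialect="compound",
                              force_brackets=norm.startswith("r.["))
        assert out == norm


# ----------------------------------------------------------------------
# length / frame arithmetic
# ----------------------------------------------------------------------

@pytest.mark.parametrize("events,delta", [
    ([SpliceEvent.exon_skip(7)], -82),
    ([SpliceEvent.from_dict({"kind": "pseudoexon", "start": "1129-293",
                             "end": "1129-218"})], 76),
    ([SpliceEvent.exon_skip(4)], -108),
    ([SpliceEvent.from_dict({"kind": "exon_elongation", "start": "1339-2",
                             "end": "1339-1"})], 2),
])
def test_delta_length(model, events, delta):
    assert delta_length(events, model) == delta


def test_exon4_skip_is_in_frame(model):
    report = protein_consequence([SpliceEvent.exon_skip(4)], model)
    assert report.frame == "in_frame"
    assert report.delta_len == -108


def _random_events(rng, m):
    events = []
    n_exons = len(m.exons)
    for _ in range(rng.integers(1, 3)):
        kind = rng.choice(["exon_skip", "intron_retention", "truncation"])
        if kind == "exon_skip":
            first = int(rng.integers(2, n_exons))
            width = int(rng.integers(1, min(3, n_exons - first) + 1))
            events.append(SpliceEvent.exon_skip(*range(first,
                                                       first + width)))
        elif kind == "intron_retention":
            events.append(SpliceEvent(kind="intron_retention",
                                      intron=int(rng.integers(1, n_exons))))
        else:
            exon = int(rng.integers(2, n_exons))
            s, e = m.exon_span(exon)
            n = int(rng.integers(1, min(20, e - s)))
            events.append(SpliceEvent(
                kind="exon_truncation", start=parse_cposition(str(s)),
                end=parse_cposition(str(s + n - 1)), side="5prime"))
    return events


def test_frame_equals_mod3_oracle_over_random_events():
    """Frame call matches the delta-length mod-3 oracle, 1000 cases."""
    rng = np.random.default_rng(20260928)
    m = gen_model(GeneratorConfig(seed=11))
    for _ in range(1000):
        events = _random_events(rng, m)
        report = protein_consequence(events, m)
        assert (report.frame == "in_frame") == (report.delta_len % 3 == 0)


# ----------------------------------------------------------------------
# protein consequences
# ----------------------------------------------------------------------

def test_no_events_is_silent(model):
    assert protein_consequence([], model).p_notation == "p.(=)"


@pytest.mark.parametrize("events,expected", [
    ([SpliceEvent.exon_skip(7)], "p.Asp215Valfs*4"),
    ([SpliceEvent.exon_skip(6, 7)], "p.Val166Phefs*18"),
    ([SpliceEvent.exon_skip(7, 8)], "p.Asp215Glyfs*7"),
    ([SpliceEvent.exon_skip(10)], "p.Phe334Leufs*7"),
    ([SpliceEvent.exon_skip(12)], "p.Phe416Leufs*2"),
    ([SpliceEvent.exon_skip(5)], "p.Phe119Leufs*6"),
    ([SpliceEvent.exon_skip(7), SpliceEvent.exon_skip(10)],
     "p.Asp215Valfs*4"),
])
def test_cohort_protein_notations(model, events, expected):
    """Frameshift consequences the quantified cohort reports."""
    assert protein_consequence(events, model).p_notation == expected


def test_elongation_protein_notation(model):
    elong = SpliceEvent.from_dict({"kind": "exon_elongation",
                                   "start": "1339-2", "end": "1339-1"})
    assert protein_consequence([elong], model).p_notation == \
        "p.Leu447Serfs*5"


def test_protein_requires_cds():
    m = TranscriptModel(gene_label="X",
                        exons=[(1, parse_cposition("1"),
                                parse_cposition("90"))])
    with pytest.raises(ModelError):
        protein_consequence([], m)


def test_frameshift_matches_bruteforce_oracle(model):
    """fs*N and the first changed residue agree with naive translation."""
    cds = model.cds_sequence
    cases = {
        "exon 7 skip": ((644, 725),),
        "exon 10 skip": ((999, 1128),),
        "exon 12 skip": ((1244, 1338),),
        "exon 6+7 skip": ((496, 725),),
    }
    for name, spans in cases.items():
        keep = [True] * len(cds)
        for a, b in spans:
            for i in range(a - 1, b):
                keep[i] = False
        mut = "".join(c for c, k in zip(cds, keep) if k)
        pos, ref_aa, new_aa, n = oracle_frameshift(cds, mut)
        events = [SpliceEvent.exon_skip(
            model.exon_containing(a),
            *range(model.exon_containing(a) + 1,
                   model.exon_containing(b) + 1))
            for a, b in spans]
        got = protein_consequence(events, model).p_notation
        m = _FS_RE.match(got)
        assert m, f"{name}: {got} is not a frameshift notation"
        assert (int(m.group(2)), m.group(1), m.group(3), int(m.group(4))) \
            == (pos, AA3[ref_aa], AA3[new_aa], n), name


def test_random_models_match_oracle():
    """Package surgery+translation equals oracle surgery+translation."""
    for seed in (5, 6, 7):
        m = gen_model(GeneratorConfig(seed=seed))
        rng = np.random.default_rng(seed)
        for _ in range(50):
            events = _random_events(rng, m)
            mut = events_to_transcript_sequence(events, m)
            # independent surgery: operate directly on the CDS string
            oracle_mut = _oracle_surgery(m, events)
            assert mut == oracle_mut
            report = protein_consequence(events, m)
            if report.frame == "frameshift" and "fs*" in report.p_notation:
                fs = _FS_RE.match(report.p_notation)
                if fs:
                    pos, ref_aa, new_aa, n = oracle_frameshift(
                        m.cds_sequence, oracle_mut)
                    assert (int(fs.group(2)), int(fs.group(4))) == (pos, n)


def _oracle_surgery(m, events):
    pieces = {}
    for idx, s, e in m.exons:
        pieces[("e", idx)] = m.cds_sequence[s.base - 1:e.base]
    for idx in range(1, len(m.exons)):
        pieces[("i", idx)] = None  # spliced out by default
    # truncations first; a skip of the same exon then wins, matching the
    # package's order-independent semantics
    for ev in events:
        if ev.kind == "intron_retention":
            pieces[("i", ev.intron)] = m.intron_sequences[ev.intron]
        elif ev.kind == "exon_truncation":
            exon = m.exon_containing(ev.start.base)
            s, e = m.exon_span(exon)
            seq = m.cds_sequence[s - 1:e]
            a, b = ev.start.base - s, ev.end.base - s
            pieces[("e", exon)] = seq[:a] + seq[b + 1:]
    for ev in events:
        if ev.kind == "exon_skip":
            for x in ev.exons:
                pieces[("e", x)] = ""
    out = []
    for idx, _, _ in m.exons:
        out.append(pieces[("e", idx)])
        nxt = pieces.get(("i", idx))
        if nxt:
            out.append(nxt)
    return "".join(out)


@pytest.mark.parametrize("events,codon", [
    ([SpliceEvent.exon_skip(7)], 215),
    ([SpliceEvent.exon_skip(12)], 415),  # junction codon resynthesizes Ser
    ([SpliceEvent.exon_skip(4)], 82),
])
def test_first_affected_codon(model, events, codon):
    assert first_affected_codon(events, model) == codon


def test_first_affected_codon_for_intronic_insertions(model):
    elong = SpliceEvent.from_dict({"kind": "exon_elongation",
                                   "start": "1339-2", "end": "1339-1"})
    assert first_affected_codon([elong], model) == 447
    ret = SpliceEvent(kind="intron_retention", intron=7)
    assert first_affected_codon([ret], model) == \
        (726 - 1) // 3 + 1  # downstream junction codon
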