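"""Build the packaged RPE65 minigene transcript-model fixture.

The exon map (c. coordinates) comes from the RNA-level deletion/insertion
coordinates observed in the minigene cohort; exon boundaries that no r.
string evidences are marked "inferred".

The CDS shipped in the fixture is SYNTHETIC: the true RPE65 mRNA sequence is
not distributed with this repository, so a 1602-nt stand-in is constructed
here, codon by codon, such that

  * every reference codon whose amino acid the cohort tables print
    (missense/synonymous p. notations) carries that amino acid, and
  * every junction-spanning splice consequence asserted by the test suite
    (exon 5 / 6+7 / 7 / 7+8 / 10 / 12 skips and the 2-nt exon-13 acceptor
    elongation) translates to exactly the protein notation the cohort
    reports (e.g. skipping c.644-725 -> p.Asp215Valfs*4).

Each engineered consequence is re-derived below with an independent
brute-force oracle (string surgery + naive translation) before the fixture
is written; the script aborts on any mismatch.

Run from the repository root:  python scripts/build_model_fixture.py
"""
from __future__ import annotations

import json
import pathlib

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val", "*": "Ter",
}

CDS_LEN = 1602  # 533 residues + stop
N_CODONS = CDS_LEN // 3

# Reference codons pinned by the cohort's printed p. notations, plus codons
# engineered so junction-spanning frameshifts reproduce the printed fs*N
# consequences (new stop codons land out of the reference frame).
CODONS = {
    1: "ATG",
    4: "CAG",    # Gln4   (c.12G>T -> His)
    83: "TTC",   # Phe83
    84: "ATC",   # Ile84  (c.252C>A syn)
    85: "CGC",   # Arg85  (c.254G>A -> His)
    87: "GAT",   # Asp87  (c.259G>A -> Asn; c.260A>G -> Gly)
    89: "TAC",   # Tyr89  (c.267C>T syn)
    90: "GTC",   # Val90  (c.268G>A -> Ile)
    95: "GAG",   # Glu95  (c.283G>C -> Gln)
    97: "CGG",   # Arg97  (c.291G>A syn)
    98: "ATC",   # Ile98  (c.292A>G -> Val; c.294C>A/T syn)
    99: "GTC",   # Val99  (c.297C>T syn)
    102: "GAA",  # Glu102 (c.304G>A -> Lys)
    118: "AGG",  # Arg118 (c.354G>T -> Ser); junction codon of the exon-5 skip
    119: "TTC",  # Phe119 -> Leu under the exon-5 skip frameshift
    124: "CGA",  # Arg124 (c.371G>A -> Gln)
    125: "GGA",  # Gly125 (c.375A>G syn)
    136: "GTC",  # Val136 (c.408C>T syn)
    142: "GAT",  # Asp142 (c.425A>G -> Gly; c.425A>T -> Val)
    149: "ACC",  # Thr149 (c.447C>A/T syn)
    150: "AAC",  # Asn150 (c.450C>T syn)
    165: "CAA",  # Gln165 (c.494A>T -> Leu)
    166: "GTT",  # Val166; first changed residue of the exon-6+7 skip
    167: "ATT",
    171: "CTG",  # places the exon-5-skip stop (c.512-514, off-frame TGA)
    172: "ACT",
    192: "ATT",  # Ile192 (c.576T>A syn)
    204: "TAC",  # Tyr204 (c.612C>T syn)
    215: "GAT",  # Asp215; junction codon of the exon-7 skip (G + c.726-727)
    217: "GAA",  # Glu217 (c.650A>T -> Val)
    218: "GAT",  # Asp218 (c.652G>T -> Tyr)
    225: "ATC",  # Ile225 (c.675C>T syn; c.675C>G -> Met)
    226: "GTT",  # Val226 (c.676G>A -> Ile; c.676G>T -> Phe)
    234: "CGA",  # Arg234 (c.701G>A -> Gln)
    236: "AAG",  # Lys236 (c.708G>A syn)
    238: "TCT",  # Ser238 (c.713C>G -> Cys)
    239: "TAC",  # Tyr239 (c.717C>T syn)
    240: "GTT",  # Val240 (c.718G>T -> Phe)
    241: "CAC",  # His241 (c.722A>G -> Arg)
    242: "GCT",
    243: "TCT",  # exon 8 opens T,T,C: Val at the exon-7-skip junction,
    244: "GCC",  # Phe at the exon-6+7-skip junction
    245: "CTG",  # places the exon-7-skip stop (c.734-736, off-frame TGA)
    246: "ACT",
    259: "CTT",  # places the exon-6+7-skip stop (c.777-779, off-frame TAA)
    260: "AAC",
    287: "GAT",  # exon 9 opens G: Gly at the exon-7+8-skip junction
    292: "GCT",  # places the exon-7+8-skip stop (c.876-878, off-frame TAA)
    293: "AAT",
    333: "GGA",  # Gly333 (c.998G>A -> Glu); junction codon of exon-10 skip
    334: "TTC",  # Phe334 -> Leu under the exon-10 skip frameshift
    340: "TAC",  # Tyr340 (c.1020C>T syn)
    344: "GCC",  # Ala344 (c.1031C>T -> Val)
    345: "AAT",  # Asn345 (c.1034A>G -> Ser)
    347: "CGG",  # Arg347 (c.1040G>T -> Leu)
    351: "GAA",  # Glu351 (c.1053A>G syn)
    353: "GTT",  # Val353 (c.1058T>G -> Gly)
    364: "GAA",  # Glu364 (c.1092A>G syn)
    373: "AAT",  # Asn373 (c.1118A>G -> Ser)
    375: "GAC",  # Asp375 (c.1125C>T syn)
    377: "ACT",  # exon 11 opens A; c.1130-1132 CTG = Leu334 after exon-10 skip
    378: "GCT",
    383: "CTA",  # places the exon-10-skip stop (c.1148-1150, off-frame TAG)
    384: "GGT",
    415: "TCT",  # junction codon of the exon-12 skip resynthesizes Ser415
    416: "TTC",  # Phe416 -> Leu under the exon-12 skip frameshift
    423: "TAC",  # Tyr423 (c.1269C>T syn)
    433: "TAT",  # Tyr433 (c.1298A>G -> Cys)
    434: "GCG",  # Ala434 (c.1302G>T site)
    445: "GAT",  # Asp445 (c.1334A>G -> Gly)
    447: "CTC",  # Leu447 -> Ser under the exon-13 acceptor elongation
    448: "TCT",
    449: "GAA",  # with 448 places the exon-12-skip stop (c.1344-1346 TGA)
    450: "CTA",  # places the elongation stop (c.1349-1351, off-frame TAA)
    451: "ATC",
    475: "CAT",  # His475 (c.1424A>C -> Pro)
    483: "GAC",  # Asp483
    485: "GTG",  # Val485
    533: "TCT",  # Ser533
    534: "TAA",
}

EXONS = [
    # (index, c_start, c_end, start_evidence, end_evidence)
    (1, 1, 65, "cds_start", "inferred"),
    (2, 66, 165, "inferred", "inferred"),
    (3, 166, 245, "inferred", "next_exon"),
    (4, 246, 353, "r.246_353del", "r.246_353del"),
    (5, 354, 495, "r.354_495del", "r.354_495del"),
    (6, 496, 643, "r.496_725del", "c.643+5"),
    (7, 644, 725, "c.644-5", "r.644_725del"),
    (8, 726, 858, "c.726-3", "r.644_858del"),
    (9, 859, 998, "prev_exon", "next_exon"),
    (10, 999, 1128, "c.999-3", "r.999_1128del"),
    (11, 1129, 1243, "c.1129-293", "next_exon"),
    (12, 1244, 1338, "c.1244-17", "c.1338+3"),
    (13, 1339, 1450, "c.1339-3", "c.1450+3"),
    (14, 1451, 1602, "prev_exon", "inferred"),
]

CONSTRUCTS = [
    {"name": "WT-1", "first_exon": 1, "last_exon": 5,
     "flank_5_len": 150, "flank_3_len": 150, "baseline": []},
    {"name": "WT-2", "first_exon": 3, "last_exon": 6,
     "flank_5_len": 150, "flank_3_len": 150, "baseline": []},
    {"name": "WT-3", "first_exon": 6, "last_exon": 10,
     "flank_5_len": 150, "flank_3_len": 150,
     "baseline": [
         {"events": [{"kind": "exon_skip", "exons": [7]}], "fraction": 39},
     ]},
    {"name": "WT-4", "first_exon": 11, "last_exon": 13,
     "flank_5_len": 150, "flank_3_len": 150,
     "baseline": [
         {"events": [{"kind": "exon_skip", "exons": [12]}], "fraction": 17},
         {"events": [{"kind": "pseudoexon",
                      "start": "1129-293", "end": "1129-218"}],
          "fraction": 6},
     ]},
]


def build_cds() -> str:
    codons = []
    for i in range(1, N_CODONS + 1):
        codons.append(CODONS.get(i, "GCT"))
    seq = "".join(codons)
    assert len(seq) == CDS_LEN
    return seq


def translate(seq: str) -> str:
    aas = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        aa = CODON_TABLE[seq[i:i + 3]]
        aas.append(aa)
        if aa == "*":
            break
    return "".join(aas)


def oracle_pnotation(ref_cds: str, mut_cds: str) -> str:
    """Brute-force protein annotation of an edited CDS (frameshift cases)."""
    ref_p = translate(ref_cds)
    mut_p = translate(mut_cds)
    if mut_p == ref_p:
        return "p.(=)"
    first = next(i for i, (a, b) in enumerate(zip(mut_p, ref_p)) if a != b)
    if (len(mut_cds) - len(ref_cds)) % 3 != 0:
        stop = mut_p.index("*", first)
        return "p.%s%d%sfs*%d" % (AA3[ref_p[first]], first + 1,
                                  AA3[mut_p[first]], stop - first + 1)
    raise NotImplementedError("oracle only needed for frameshift checks here")


def main() -> None:
    cds = build_cds()
    ref_p = translate(cds)
    assert cds.startswith("ATG") and cds.endswith("TAA")
    assert len(ref_p) == 534 and ref_p.count("*") == 1, "internal stop codon"

    # (description, deleted closed interval(s) / insertion, expected p.)
    def delete(*spans):
        keep = [True] * CDS_LEN
        for a, b in spans:
            for i in range(a - 1, b):
                keep[i] = False
        return "".join(c for c, k in zip(cds, keep) if k)

    checks = [
        ("exon 5 skip", delete((354, 495)), "p.Phe119Leufs*6"),
        ("exon 6+7 skip", delete((496, 725)), "p.Val166Phefs*18"),
        ("exon 7 skip", delete((644, 725)), "p.Asp215Valfs*4"),
        ("exon 7+8 skip", delete((644, 858)), "p.Asp215Glyfs*7"),
        ("exon 10 skip", delete((999, 1128)), "p.Phe334Leufs*7"),
        ("exon 7+10 skip", delete((644, 725), (999, 1128)),
         "p.Asp215Valfs*4"),
        ("exon 12 skip", delete((1244, 1338)), "p.Phe416Leufs*2"),
        ("exon 13 acceptor elongation",
         cds[:1338] + "AG" + cds[1338:], "p.Leu447Serfs*5"),
    ]
    for name, mut, expected in checks:
        got = oracle_pnotation(cds, mut)
        assert got == expected, f"{name}: {got} != {expected}"
        print(f"  {name:28s} -> {got}")

    model = {
        "gene_label": "RPE65",
        "exons": [[i, str(s), str(e)] for i, s, e, _, _ in EXONS],
        "exon_provenance": {str(i): {"start": sp, "end": ep}
                            for i, _, _, sp, ep in EXONS},
        "cds_sequence": cds,
        "cds_provenance": ("synthetic: constraint-engineered stand-in "
                           "reproducing the cohort's printed codon "
                           "identities and splice-junction frameshift "
                           "consequences; not the biological RPE65 mRNA"),
        "intron_flanks": {"12": {"acceptor": "AG"}},
        "constructs": CONSTRUCTS,
    }
    out = pathlib.Path(__file__).resolve().parents[1] / (
        "src/minisplice/data/rpe65_model_synthetic_cds.json")
    out.write_text(json.dumps(model, indent=1) + "\n")
    print("wrote", out, out.stat().st_size, "bytes")


if __name__ == "__main__":
    main()
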