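{
 "gene_label": "RPE65",
 "exons": [
  [
   1,
   "1",
   "65"
  ],
  [
   2,
   "66",
   "165"
  ],
  [
   3,
   "166",
   "245"
  ],
  [
   4,
   "246",
   "353"
  ],
  [
   5,
   "354",
   "495"
  ],
  [
   6,
   "496",
   "643"
  ],
  [
   7,
   "644",
   "725"
  ],
  [
   8,
   "726",
   "858"
  ],
  [
   9,
   "859",
   "998"
  ],
  [
   10,
   "999",
   "1128"
  ],
  [
   11,
   "1129",
   "1243"
  ],
  [
   12,
   "1244",
   "1338"
  ],
  [
   13,
   "1339",
   "1450"
  ],
  [
   14,
   "1451",
   "1602"
  ]
 ],
 "exon_provenance": {
  "1": {
   "start": "cds_start",
   "end": "inferred"
  },
  "2": {
   "start": "inferred",
   "end": "inferred"
  },
  "3": {
   "start": "inferred",
   "end": "next_exon"
  },
  "4": {
   "start": "r.246_353del",
   "end": "r.246_353del"
  },
  "5": {
   "start": "r.354_495del",
   "end": "r.354_495del"
  },
  "6": {
   "start": "r.496_725del",
   "end": "c.643+5"
  },
  "7": {
   "start": "c.644-5",
   "end": "r.644_725del"
  },
  "8": {
   "start": "c.726-3",
   "end": "r.644_858del"
  },
  "9": {
   "start": "prev_exon",
   "end": "next_exon"
  },
  "10": {
   "start": "c.999-3",
   "end": "r.999_1128del"
  },
  "11": {
   "start": "c.1129-293",
   "end": "next_exon"
  },
  "12": {
   "start": "c.1244-17",
   "end": "c.1338+3"
  },
  "13": {
   "start": "c.1339-3",
   "end": "c.1450+3"
  },
  "14": {
   "start": "prev_exon",
   "end": "inferred"
  }
 },
 "cds_sequence": "ATGGCTGCTCAGGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTTTCATCCGCGCTGATGCTTACGTCGCTGCTGCTGCTGAGGCTCGGATCGTCGCTGCTGAAGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTAGGTTCGCTGCTGCTGCTCGAGGAGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGTCGCTGCTGCTGCTGCTGATGCTGCTGCTGCTGCTGCTACCAACGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTCAAGTTATTGCTGCTGCTCTGACTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTATTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTTACGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGATGCTGAAGATGCTGCTGCTGCTGCTGCTATCGTTGCTGCTGCTGCTGCTGCTGCTCGAGCTAAGGCTTCTTACGTTCACGCTTCTGCCCTGACTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTCTTAACGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGATGCTGCTGCTGCTGCTAATGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGGATTCGCTGCTGCTGCTGCTTACGCTGCTGCTGCCAATGCTCGGGCTGCTGCTGAAGCTGTTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGAAGCTGCTGCTGCTGCTGCTGCTGCTAATGCTGACGCTACTGCTGCTGCTGCTGCTCTAGGTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTTCTTTCGCTGCTGCTGCTGCTGCTTACGCTGCTGCTGCTGCTGCTGCTGCTGCTTATGCGGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGATGCTCTCTCTGAACTAATCGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTCATGCTGCTGCTGCTGCTGCTGCTGACGCTGTGGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTGCTTCTTAA",
 "cds_provenance": "synthetic: constraint-engineered stand-in reproducing the cohort's printed codon identities and splice-junction frameshift consequences; not the biological RPE65 mRNA",
 "intron_flanks": {
  "12": {
   "acceptor": "AG"
  }
 },
 "constructs": [
  {
   "name": "WT-1",
   "first_exon": 1,
   "last_exon": 5,
   "flank_5_len": 150,
   "flank_3_len": 150,
   "baseline": []
  },
  {
   "name": "WT-2",
   "first_exon": 3,
   "last_exon": 6,
   "flank_5_len": 150,
   "flank_3_len": 150,
   "baseline": []
  },
  {
   "name": "WT-3",
   "first_exon": 6,
   "last_exon": 10,
   "flank_5_len": 150,
   "flank_3_len": 150,
   "baseline": [
    {
     "events": [
      {
       "kind": "exon_skip",
       "exons": [
        7
       ]
      }
     ],
     "fraction": 39
    }
   ]
  },
  {
   "name": "WT-4",
   "first_exon": 11,
   "last_exon": 13,
   "flank_5_len": 150,
   "flank_3_len": 150,
   "baseline": [
    {
     "events": [
      {
       "kind": "exon_skip",
       "exons": [
        12
       ]
      }
     ],
     "fraction": 17
    },
    {
     "events": [
      {
       "kind": "pseudoexon",
       "start": "1129-293",
       "end": "1129-218"
      }
     ],
     "fraction": 6
    }
   ]
  }
 ]
}
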