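{
  "version": "1.0",
  "comment": "Average residue masses (Da) for the 20 canonical amino acids; a peptide mass is the sum of residue masses plus one water, minus 2.016 Da per disulfide bond.",
  "water": 18.015,
  "disulfide": 2.016,
  "masses": {
    "A": 71.0788,
    "R": 156.1875,
    "N": 114.1038,
    "D": 115.0886,
    "C": 103.1388,
    "E": 129.1155,
    "Q": 128.1307,
    "G": 57.0519,
    "H": 137.1411,
    "I": 113.1594,
    "L": 113.1594,
    "K": 128.1741,
    "M": 131.1926,
    "F": 147.1766,
    "P": 97.1167,
    "S": 87.0782,
    "T": 101.1051,
    "W": 186.2132,
    "Y": 163.1760,
    "V": 99.1326
  }
}
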