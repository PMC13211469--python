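{
  "version": "1.0",
  "comment": "Curated preprotoxin maturation annotations for the canonical Saccharomyces killer toxins. Coordinates are 1-based inclusive residue indices on the primary translation product (ppTox). 'signal_cleavage' is the P1 residue of signal-peptidase cleavage (cleavage occurs after it). 'kex2_sites' are curated Kex2 P1 positions. 'kex1_trim' gives the number of C-terminal residues removed by Kex1 carboxypeptidase from the named Kex2-released chain. 'mature_chains' are the chains retained in the secreted toxin, post-trim. 'disulfide_pairs' are predicted cysteine pairings; 'interchain_disulfides' counts bonds linking distinct mature chains.",
  "toxins": {
    "K1": {
      "length": 316,
      "domain_order": ["delta", "alpha", "gamma", "beta"],
      "domains": [["delta", 27, 44], ["alpha", 45, 147], ["gamma", 148, 234], ["beta", 235, 316]],
      "signal_cleavage": 26,
      "kex2_sites": [44, 149, 188, 233],
      "kex1_trim": {"alpha": 2},
      "mature_chains": [["alpha", 45, 147], ["beta", 235, 316]],
      "disulfide_pairs": [[95, 239], [92, 107], [245, 312]],
      "interchain_disulfides": 1,
      "notes": "Kex2 cleaves after R44, R149 and R233 (plus an internal gamma site after R188); Kex1 removes the R148-R149 dipeptide to create the mature alpha C-terminus. Mature toxin: disulfide-linked alpha/beta heterodimer. Printed gamma/beta boundaries (148/235) follow the source diagrams and do not coincide exactly with the Kex2 P1 positions; both conventions are kept."
    },
    "K1L": {
      "length": 340,
      "domain_order": ["delta", "alpha", "gamma", "beta"],
      "domains": [["delta", 27, 36], ["alpha", 37, 147], ["gamma", 148, 248], ["beta", 249, 340]],
      "signal_cleavage": 26,
      "kex2_sites": [36, 147, 248],
      "kex1_trim": null,
      "mature_chains": [["alpha", 37, 147], ["beta", 249, 340]],
      "disulfide_pairs": [[94, 257]],
      "interchain_disulfides": 1,
      "notes": "Six cysteines split evenly between alpha and beta; predicted interdomain bond C94-C257."
    },
    "K2": {
      "length": 362,
      "domain_order": ["delta", "alpha", "gamma", "beta"],
      "domains": [["delta", 55, 79], ["alpha", 80, 165], ["gamma", 166, 268], ["beta", 269, 362]],
      "signal_cleavage": 54,
      "kex2_sites": [79, 165, 221, 268],
      "kex1_trim": null,
      "mature_chains": [["alpha", 80, 165], ["beta", 269, 362]],
      "disulfide_pairs": [],
      "interchain_disulfides": 0,
      "notes": "Signal peptidase site is displaced ~30 residues from the N-terminus (canonical predictors miss it). Kex2 cleaves after R79, R165, R221 and R268. No interdomain alpha-beta disulfide is predicted; the mature heterodimer is held by non-covalent contacts. Theoretical masses ~8.7 kDa (alpha) and ~10.5 kDa (beta)."
    },
    "K21": {
      "length": 346,
      "domain_order": ["delta", "alpha", "gamma", "beta"],
      "domains": [["delta", 41, 59], ["alpha", 60, 129], ["gamma", 130, 240], ["beta", 241, 346]],
      "signal_cleavage": 40,
      "kex2_sites": [59, 129, 240],
      "kex1_trim": null,
      "mature_chains": [["alpha", 60, 129], ["beta", 241, 346]],
      "disulfide_pairs": [],
      "interchain_disulfides": 0,
      "notes": "Hydrophobic region at 23-39 displaced from the N-terminus; positive triad R9/R14/K22. Four cysteines positioned like K2."
    },
    "KHS": {
      "length": 350,
      "domain_order": ["delta", "alpha", "gamma", "beta"],
      "domains": [["delta", 37, 63], ["alpha", 64, 132], ["gamma", 133, 237], ["beta", 238, 350]],
      "signal_cleavage": 36,
      "kex2_sites": [63, 132, 237],
      "kex1_trim": null,
      "mature_chains": [["alpha", 64, 132], ["beta", 238, 350]],
      "disulfide_pairs": [],
      "interchain_disulfides": 0,
      "notes": "All domain boundaries are dibasic motifs; signal cleavage predicted after L36, displaced from the N-terminus (positive residues R20/R23/R26, hydrophobic span 27-46)."
    },
    "K45": {
      "length": 370,
      "domain_order": ["delta", "alpha", "gamma", "beta"],
      "domains": [["delta", 28, 56], ["alpha", 57, 179], ["gamma", 180, 267], ["beta", 268, 370]],
      "signal_cleavage": 27,
      "kex2_sites": [56, 97, 179, 267],
      "kex1_trim": null,
      "mature_chains": [["alpha", 57, 179], ["beta", 268, 370]],
      "disulfide_pairs": [],
      "interchain_disulfides": 0,
      "notes": "Extra dibasic motif K96-R97 inside the alpha domain with no known function. Five cysteines; one removed with the signal region, the rest form intradomain bonds."
    },
    "K74": {
      "length": null,
      "domain_order": ["delta", "alpha", "gamma", "beta"],
      "domains": [],
      "signal_cleavage": null,
      "kex2_sites": [110, 220],
      "kex1_trim": null,
      "mature_chains": [],
      "disulfide_pairs": [],
      "interchain_disulfides": 1,
      "notes": "Only the alpha/gamma (after R110) and gamma/beta (after R220) cleavage positions are established; full domain spans and the signal site are not printed, so no boundaries are curated. Reduction releases a ~13 kDa beta domain, suggesting a disulfide-linked heterodimer."
    },
    "K28": {
      "length": 345,
      "domain_order": ["delta", "alpha", "gamma", "beta"],
      "domains": [["delta", 36, 49], ["alpha", 50, 149], ["gamma", 150, 245], ["beta", 246, 344]],
      "signal_cleavage": 36,
      "kex2_sites": [49, 149, 245],
      "kex1_trim": {"beta": 1},
      "mature_chains": [["alpha", 50, 149], ["beta", 246, 344]],
      "disulfide_pairs": [[56, 333]],
      "interchain_disulfides": 1,
      "notes": "Signal cleaved after G36. Alpha (10.5 kDa) and beta (11.0 kDa) start at residues 50 and 246. Kex1 removes a C-terminal arginine to expose the HDEL ER-retention motif. Interdomain bond C56-C333."
    },
    "Klus": {
      "length": 242,
      "domain_order": ["gamma", "delta", "alpha", "beta"],
      "domains": [["gamma", 24, 67], ["delta", 68, 98], ["alpha", 99, 167], ["beta", 168, 242]],
      "signal_cleavage": 23,
      "kex2_sites": [67, 98, 167],
      "kex1_trim": null,
      "mature_chains": [["alpha", 99, 167], ["beta", 168, 242]],
      "disulfide_pairs": [[114, 188], [141, 162]],
      "interchain_disulfides": 1,
      "notes": "Non-canonical domain order gamma-delta-alpha-beta: the N-terminal domain contributes a beta-strand to the sheet wrapping the alpha-domain helix, so it is assigned gamma. C114-C188 tethers the mature alpha/beta heterodimer."
    },
    "KHR": {
      "length": 296,
      "domain_order": ["delta", "gamma", "alpha", "beta"],
      "domains": [["delta", 22, 77], ["gamma", 78, 130], ["alpha", 131, 183], ["beta", 184, 296]],
      "signal_cleavage": 21,
      "kex2_sites": [77, 130, 183],
      "kex1_trim": null,
      "mature_chains": [["alpha", 131, 183], ["beta", 184, 296]],
      "disulfide_pairs": [[138, 151], [248, 279]],
      "interchain_disulfides": 0,
      "notes": "Domain order delta-gamma-alpha-beta (gamma and delta reversed relative to Klus). Theoretical alpha+beta heterodimer mass 18.4 kDa, close to the ~20 kDa observed for mature extracellular KHR. A dibasic site splits the alpha domain but is bridged by C138-C151."
    },
    "K62": {
      "length": 272,
      "domain_order": ["delta", "beta"],
      "domains": [["delta", 32, 112], ["beta", 113, 272]],
      "signal_cleavage": 31,
      "kex2_sites": [112],
      "kex1_trim": null,
      "mature_chains": [["beta", 113, 272]],
      "disulfide_pairs": [[146, 271], [201, 262], [227, 237]],
      "interchain_disulfides": 0,
      "notes": "Aerolysin-family outlier: a single dibasic KR motif at 111-112 separates the N-terminal receptor-binding domain (mapped to 'delta' here) from the aerolysin core domain (mapped to 'beta'). Signal cleavage between residues 31 and 32. All three disulfides lie in the core domain and are essential for toxicity."
    }
  }
}
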