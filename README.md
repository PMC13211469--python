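# killerkit

Annotation and structural quantification of *Saccharomyces* killer toxins —
the secreted antifungal proteins ("killer toxins") of killer yeasts — and of
their homologs. The package is aimed at people studying preprotoxin
maturation and toxin structure models: it annotates preprotoxins, quantifies
geometric features of 3-D models, and analyzes homolog hit sets.

## What it computes

**Preprotoxin maturation** (`killerkit.maturation`). A killer preprotoxin
(ppTox) is matured along the secretory pathway: signal peptidase removes the
N-terminal signal region, the Golgi endopeptidase Kex2 cleaves after basic
residues (usually dibasic KR/RR motifs, P1 convention: cleavage occurs
*after* the reported residue), and Kex1 carboxypeptidase trims C-terminal
basic residues. These cuts delimit up to four domains (canonically
delta–alpha–gamma–beta); the secreted toxin is typically the alpha/beta
chain pair, sometimes disulfide-linked. The module scans cleavage motifs,
ranks signal-region candidates with a hydropathy/charge heuristic (the
h-region is *not* anchored at the N-terminus, since some toxins carry ~30
extra residues before it), partitions sequences, derives mature products and
their average masses

    mass(seq) = Σ residue masses + 18.015 Da − 2.016 Da × (disulfide bonds),

inventories cysteines, and validates curated per-toxin boundary tables
(K1, K1L, K2, K21, KHS, K45, K74, K28, Klus, KHR, K62) shipped as package
data.

**Structure metrics** (`killerkit.struct_metrics`). On PDB models carrying
per-residue confidence (pLDDT) in the temperature-factor column: optimal
rigid superposition RMSD (Kabsch, reflections excluded), backbone φ/ψ
dihedrals with Ramachandran favored/allowed/outlier summaries,
solvent-accessible surface area (Shrake–Rupley, deterministic golden-spiral
points, 1.4 Å probe), helix burial (isolated-minus-in-context SASA of a
span, in Å² and percent), geometric disulfide detection (SG–SG ≤ 2.5 Å),
Eisenberg hydrophobic moments μH = |Σₙ Hₙ·e^(inδ)| at δ = 100°/residue for
amphipathicity and helical wheels, and confidence summaries.

**Homolog-set analytics** (`killerkit.set_analytics`). Length filtering of
homology-search hit tables (hits shorter than 75% or longer than 150% of the
query are discounted; bounds strict), pairwise/global overlap and Jaccard
statistics, single-linkage family clustering, taxon tallies, and ΔΔG
stability classification (|ΔΔG| ≤ 2 kcal/mol → stable).

**Synthetic data** (`killerkit.synthetic`). Deterministic generators with
exact planted ground truth: preprotoxins with planted signal regions, Kex
motifs and cysteines; ideal backbones built by internal coordinates at known
(φ, ψ); sphere scenes with analytic SASA; hit tables with planted families.

## Worked example

Generate a synthetic preprotoxin with known ground truth and annotate it:

```sh
killerkit generate --kind preprotoxin --seed 7 -o demo
killerkit annotate demo/preprotoxin.fasta -o demo
```

`demo/synthetic_pptox.annotation.json` then contains (abridged):

```
sites:      [{position 44, motif RR}, {position 149, motif RR}, {position 233, motif RR}]
partition:  segment_1 1–44, segment_2 45–149, segment_3 150–233, segment_4 234–316
signal:     h-region 6–17 (mean hydropathy 4.2), best cleavage after 20
cysteines:  segment_2: [95, 107], segment_4: [239, 312]
```

i.e. the three planted dibasic Kex2 sites (cleavage after residues 44, 149
and 233), the resulting four-segment partition, the planted hydrophobic
h-region with its signal-peptidase candidate, and the planted cysteines —
all matching `demo/preprotoxin.truth.json` exactly. A to-scale domain
diagram is written as `synthetic_pptox.diagram.svg`.

Mature-product mass arithmetic from stated subunit masses:

```python
>>> from killerkit import maturation
>>> config = maturation.load_toxin_config("K1")
>>> product = maturation.derive_mature_products(
...     config, chain_masses={"alpha": 11100.0, "beta": 9500.0})
>>> product.total_kda()
20.6
```

An 11.1 kDa alpha chain and a 9.5 kDa beta chain joined by one interchain
disulfide give a 20.6 kDa mature heterodimer (the −2.016 Da bond correction
is invisible at 0.1 kDa precision).

Other subcommands: `killerkit struct model.pdb --span 97 119` (confidence,
Ramachandran, disulfides, helix burial, optional RMSD against a second
model), `killerkit families hits.tsv` (filter → overlap → cluster → taxa).

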