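# alphastrand

Detection and counting of **α-strand / α-sheet** backbone motifs in protein
structures and conformational ensembles.

The α-sheet is an atypical secondary structure implicated as a toxic
intermediate in amyloid aggregation (amyloid-β in Alzheimer's disease,
α-synuclein, transthyretin and others). Its building block, the α-strand, is
defined purely by backbone dihedral signs: a run of successive residues whose
(φ, ψ) alternate between the right-handed helical quadrant
(−180 < φ < 0, −180 < ψ < 0, "α_R") and the left-handed quadrant
(0 < φ < 180, 0 < ψ < 180, "α_L"). In amyloid-β 1–42, the central-region
tripeptide V24-G25-S26 (VGS) is the canonical strand-forming window, formed
via a peptide-plane flip — the concerted rotation of a rigid CO–NH unit that
moves ψᵢ and φᵢ₊₁ together while the flanking torsions stay put.

This package is for structural bioinformaticians who want to detect these
motifs in PDB entries (including multi-model NMR ensembles), in per-frame
dihedral tables from MD trajectories, or across whole structure collections:

- `structure_io` — PDB/mmCIF reading (gemmi-backed), backbone extraction,
  chain-break detection, dihedral-table parsing, TSV/JSON report round trips;
- `dihedral_core` — IUPAC torsions and the α_R/α_L/other/undefined
  classification;
- `strand_scan` — maximal alternating runs, anchored-window matching,
  sequence-motif-restricted scanning;
- `trajectory_analysis` — frames × residues state matrices, per-window
  counts, formation events, first-appearance times, transition traces and
  peptide-plane flip detection;
- `collection_search` — batch mining with X-ray/NMR method stratification;
- `synthetic` — backbone builder (internal-coordinate placement), ideal
  strands, two-state flip-kinetics simulator and planted collections, all
  with exact ground-truth manifests;
- `manifest_report` — the shipped 39-system simulation manifest and the
  Aβ 1–42 wild-type/mutant sequences.

## Worked example

```python
from alphastrand import (ideal_alpha_strand, scan_structure, states_for_model)

model = ideal_alpha_strand("VGSNK", first_res_seq=24)   # Aβ region 24–28
for ref, state in states_for_model(model, "A"):
    print(ref[1], ref[2], state.code)
for hit in scan_structure(model, min_len=3):
    print(hit.start_res, hit.length, hit.pattern_string, hit.window_sequence)
```

prints

```
23 GLY U
24 VAL R
25 GLY L
26 SER R
27 ASN L
28 LYS R
29 GLY U
24 5 RLRLR VGSNK
```

— the five requested residues alternate α_R/α_L starting from α_R (`U` marks
the capping termini, which lack one dihedral each), and the scanner reports a
single maximal run of length 5 at residue 24 spelling α_Rα_Lα_Rα_Lα_R over
the sequence VGSNK.

The same machinery runs from the shell, e.g.

```sh
alphastrand scan strand.pdb --motif VGS --start R
alphastrand traj-summary rama.xvg --window 24:26 --pattern RLR --stride-ps 2
alphastrand mine structures/ --motif VGS --pattern RLR
alphastrand manifest summarize
```

The last command validates the shipped manifest and prints
`systems: 39` and `aggregated simulation time: 1950 ns`.

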