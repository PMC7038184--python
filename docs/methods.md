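# Methods

## Conformational states and the α-strand definition

Each residue is assigned one of four states from its backbone dihedrals
(degrees, range (−180, 180]):

- **α_R** iff −180 < φ < 0 and −180 < ψ < 0 — the (−, −) sign quadrant;
- **α_L** iff 0 < φ < 180 and 0 < ψ < 180 — the (+, +) quadrant;
- **OTHER** for any other defined pair, *including* the measure-zero
  boundaries φ or ψ ∈ {0, ±180}, because the quadrant rule uses strict
  inequalities;
- **UNDEFINED** when either dihedral is missing (chain termini, residues
  flanking a chain break, incomplete backbones, NaN input).

An **α-strand** is a maximal run of ≥ `min_len` (default 3) successive
residues whose states strictly alternate between α_R and α_L. Either start
state is accepted by the generic scanner; analyses of the amyloid-β 24–26
window conventionally require the run to start in α_R (α_Rα_Lα_R…), and the
motif-restricted scanner exposes that as `required_start`. Runs never span
OTHER, UNDEFINED or a chain break: the definition requires each residue of
the run to *be* in one of the two quadrants. When `required_start` is set
and a maximal run begins in the other quadrant, its first residue is trimmed
so every reported run starts correctly; no other overlap handling is needed
because maximal runs are disjoint by construction. Sequence-motif-restricted
scans report every matching window, overlaps included.

No β region is defined numerically: transitions into the helical quadrants
are reported as state changes from OTHER, avoiding an invented boundary for
the β basin. Likewise no hydrogen-bond-based sheet pairing is computed — the
package detects strands, not sheet contacts.

## Torsion angles

`dihedral_angle` uses the normal-vector formulation
atan2((n₁×n₂)·û₂, n₁·n₂) with n₁ = b₁×b₂, n₂ = b₂×b₃, which realises the
IUPAC convention (cis = 0°, trans = 180°, clockwise positive sighting from
the second to the third atom). φᵢ is C(i−1)-N(i)-Cα(i)-C(i), ψᵢ is
N(i)-Cα(i)-C(i)-N(i+1), ωᵢ is Cα(i−1)-C(i−1)-N(i)-Cα(i). Triples whose
cross-product norm falls below 1e−9 (collinear atoms) yield an undefined
torsion. Two symmetries are verified in the tests: the four-point torsion is
*invariant* under order reversal (reversal maps n₁ → −n₂, n₂ → −n₁,
b₂ → −b₂, leaving both atan2 arguments unchanged) and *negated* under mirror
reflection; it is invariant under rigid motions. The torsion implementation
is cross-checked against an independently coded projection oracle at 1e−6°.

## Structure reading

gemmi parses PDB and mmCIF (multi-model via MODEL/ENDMDL). Policy choices:

- **Altloc:** keep the highest-occupancy alternate location per backbone
  atom; ties keep the first encountered. Dihedrals need one conformer.
- **Nonstandard residues** with complete N/Cα/C are retained, one-letter
  code `X`; they are dihedral-eligible but can never match a sequence motif.
- **Chain breaks:** an author-numbering jump > 1 or a C(i)–N(i+1) distance
  above 2.5 Å marks a break; φ/ψ across it are undefined. The 2.5 Å cutoff
  comfortably separates the 1.33 Å peptide bond from any genuine gap.
- **Numbering:** author residue numbers are authoritative (the amyloid-β
  window "24–26" is an author-number window).
- Files without a single amino-acid residue parse to an empty model list,
  the non-protein flag used by collection mining.

Dihedral tables are whitespace-delimited `phi psi label` rows with `#`/`@`
comments (the dialect of trajectory dihedral extractors). Frames are
inferred from label recurrence, or taken from an explicit leading frame
column; angles outside [−360, 360] are rejected, the rest wrapped into
(−180, 180]. Frame times are `frame_index × stride_ps`, stride defaulting to
2 ps — the recording interval of the trajectories the manifest describes.

## Trajectory statistics

The "number of α-strands" reported for an anchored window is the
**frame count**: the number of recorded frames in which the window spells
its pattern. Totals of order 10³ against 25,000 recorded frames (50 ns at
2 ps) are consistent with that reading; the **event count** (maximal runs of
consecutive matching frames) is computed alongside so the distinct-event
reading is also available. First-appearance time is the time of the earliest
matching frame, reported as ABSENT (None) rather than a sentinel when the
pattern never occurs, and convertible to ns for plotting. Because the
match sets of nested windows nest (24–28 matches ⊆ 24–27 ⊆ 24–26 when the
patterns extend each other), frame counts are monotonically non-increasing
and first-appearance times non-decreasing with window length; the tests
assert this.

**Peptide-plane flips.** No numeric flip criterion is standard, so the
detector encodes the geometry directly: between two compared frames, plane
(i, i+1) flips when circular |Δψᵢ| ≥ θ and |Δφᵢ₊₁| ≥ θ *jointly*, while the
flanking torsions (φᵢ, ψᵢ₊₁) each move less than a neighbour threshold.
Both thresholds default to 90°, the half-turn that separates quadrant
crossings; both are configurable in (0, 180]. An undefined flanking torsion
(chain end) imposes no constraint. Comparison modes: `consecutive`
(frame-to-frame, the default — a flip and its reversal give two events) and
`vs_initial` (every frame against frame 0 — a reverted flip shows no net
change). Circular differences wrap through ±180°, so −45° → 150° is a 165°
change, not 195°. Simultaneous flips on adjacent planes share a torsion and
are inherently inseparable; the synthetic generator refuses to plant them.

## Synthetic generators

`build_backbone` places N/Cα/C/O sequentially by internal coordinates
(natural-extension reference frames): ψᵢ orients N(i+1), ω(i+1) orients
Cα(i+1), φ(i+1) orients C(i+1); O(i) sits in the C(i) plane trans to N(i+1).
Bond lengths 1.458 / 1.525 / 1.329 / 1.231 Å (N–Cα, Cα–C, C–N, C=O) and
angles 111.2° / 116.2° / 121.7° / 120.8° (N-Cα-C, Cα-C-N, C-N-Cα, Cα-C-O)
are standard peptide geometry; only dihedral *signs* matter downstream, so
the analysis is insensitive to these constants. Atom pairs closer than
0.5 Å raise a construction error (rare: ~0.2 % of random dihedral draws).
Round-trip error (build, then re-measure) is ~1e−13° in memory and < 0.02°
through 3-decimal PDB text.

Representative quadrant dihedrals are (−60, −45) for α_R, (60, 45) for α_L,
(−120, 130) for an extended OTHER context — arbitrary quadrant interiors
chosen away from boundaries. `ideal_alpha_strand` flanks the requested
sequence with one glycine cap on each side: a free peptide's termini always
classify UNDEFINED, so without caps a tripeptide strand could never be
detected; with them, the maximal run spans exactly the requested residues.

`simulate_states` is a statistical stand-in for MD ensembles: each residue
whose baseline state is α_R or α_L follows an independent two-state Markov
chain to the opposite quadrant (per-frame probabilities `flip_on_prob`,
`flip_off_prob`; stationary flipped fraction on/(on+off)); OTHER-baseline
residues are static. A planted window overrides sampled states in listed
frames. The ground-truth manifest records the exact per-frame window
matches and per-residue transition tallies. Defaults mirror the recording
conditions of the study systems (2 ps stride); trajectory lengths in tests
are hundreds to thousands of frames — large enough for tight binomial
checks while keeping the suite in seconds. What passing tests show is that
the *counting machinery* is exact on its inputs; they cannot show that real
MD ensembles of amyloid-β behave like two-state chains, nor anything about
temperature, pH or mutation effects, which here would just be different
rate parameters.

`plant_collection` writes multi-model PDB entries: hit entries carry one
planted motif occurrence per model (motif embedded mid-chain in OTHER
context), decoys contain the motif sequence with non-alternating states.
Decoy/flank sequences are drawn from an alphabet excluding V/G/S so motifs
occur only where planted. Experimental-method headers alternate X-ray/NMR
for stratification tests. All generators are bit-reproducible from a single
seed.

## Kinetics recovery as a family-wise test

Rate recovery compares the count of baseline→flipped transitions against its
exact binomial law. Ten seeds are checked as one family: per-seed acceptance
regions at the simultaneous 99 % level (Bonferroni, 0.1 % per seed) plus a
pooled-count check at 99 %. Ten *independent* 99 % tests would jointly
reject a correct simulator about 10 % of the time; the family-wise
formulation tests the same hypothesis at the intended confidence.

## Manifest and sequences

`data/table1.tsv` transcribes the 39-system simulation manifest (three NMR
starting structures × wild type and six mutants × temperature and pH
conditions, 50 ns each; total 1950 ns). Load-time validation: temperatures
in {310, 498} K, low-pH systems neutralised by anions, unique ids. The
wild-type Aβ 1–42 sequence is validated at load against the central-region
anchors V24-G25-S26-N27-K28. `apply_variant` performs single
substitutions with wild-type-letter checking, so re-applying a mutation
errors; G25P removes the VGS motif, which is the sequence-level signature of
the strand-abolishing mutation.

## Known limitations

- Counts from mining a live structure archive depend on the archive
  snapshot; published censuses drift as entries accumulate.
- The flip detector's concerted-change rule cannot separate simultaneous
  flips of adjacent planes (shared torsion), and frame-to-frame comparison
  misses flips slower than the frame spacing.
- Monomer extraction conventions for multi-chain fibril entries (e.g. which
  chain/model to excise) are the caller's choice; the reader exposes every
  chain of every model and takes no view.
- The two-quadrant rule is deliberately coarse: it is the motif definition,
  not a general secondary-structure assignment.
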