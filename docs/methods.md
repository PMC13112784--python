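# Methods

## Scope and model

`intprof` profiles the non-covalent environment of designated residues
("targets", partner class **M**) in a protonated protein complex. Every
heavy atom of a target's side chain (plus its bonded hydrogens) is tested
against all atoms of the surrounding residues — the rest of the antibody
(**Ab**), the antigen (**Ag**), water molecules (**S**) and, in
double-mutation mode, the second target residue — under 36 operational
interaction definitions. An interaction is assigned only when the
participant atom types (SYBYL element + hybridization codes) *and* all
geometric/charge predicates of a rule hold. Interactions within a target
residue are never extracted.

The registry holds 28 direct labels — 4 hydrogen bonds (`HB_OH_O`,
`HB_NH_O`, `HB_OH_N`, `HB_NH_N`), 4 long-range electrostatic analogues
(`Ele_*`), π-family contacts (`PI_PI`, `CH_PI`, `NH_PI`, `OH_PI`,
`SH_PI`, `S_PI`), weak hydrogen bonds (`CH_O`, `CH_N`, `CH_S`, `OH_S`,
`NH_S`, `SH_O`, `SH_N`, `SH_S`), chalcogen contacts (`S_O`, `S_N`,
`S_S`), dipole contacts (`OMulPol`, `Dipo`) and the buffered van der
Waals contact (`vdW`) — plus 5 metal (`Fe_A`, `Zn_A`, `Ca_A`, `Mg_A`,
`Ni_A`) and 3 ion (`Na_A`, `K_A`, `Cl_A`) coordination labels.

## Geometric definitions

Notation: D = donor heavy atom, H = donor hydrogen, A = acceptor heavy
atom, Dn/An = heavy atoms covalently bonded to D/A, cn = aromatic ring
centroid, Nr = foot of the perpendicular from an atom to a plane,
R_vdW(X) = van der Waals radius (Bondi set by default, overridable by
the radius file).

**X–H···Y template** (CH···O and all other weak/strong hydrogen bonds):

    d(D:A) ≤ R_vdW(D) + R_vdW(A) + buffer        (buffer 1.0 Å)
    d(D:A) ≤ d(Dn:A)   for every heavy neighbor Dn of D
    d(D:A) ≤ d(D:An)   for every heavy neighbor An of A
    d(H:A) ≤ d(D:A)
    d(H:A) ≤ 3.22 Å
    94.58° ≤ ∠(D:H:A) ≤ 180°

The published operational definitions state the neighbor conditions
against indexed neighbors (Dn₁, An₁, An₂); since requiring them for the nearest one
or two neighbors is equivalent to requiring them for all, they are
applied to every heavy neighbor and are vacuously true when a
participant has none (e.g. a water oxygen acceptor). Conventional
hydrogen bonds and electrostatic contacts additionally split on the
heavy-atom distance at 3.2 Å: d(D:A) ≤ 3.2 Å → `HB_*`, otherwise
`Ele_*` up to the vdW gate. The boundary value 3.2 Å itself counts as a
hydrogen bond. Salt bridges are not a separate class; they fall into
`HB_*`/`Ele_*` by distance.

**X–H···π template** (CH···π and congeners), per ring atom A, at most
one hit per (D, ring):

    d(D:A) ≤ R_vdW(D) + R_vdW(A) + buffer
    d(D:A) ≤ d(Dn:A)   for every heavy neighbor of D
    d(H:A) ≤ d(D:A)
    d(Nr:cn) ≤ 1.4 · d(cn:A)          (Nr = projection of H on the ring plane)
    d(A:H) ≤ 3.195 Å   OR   (3.195 < d(A:H) ≤ 3.325 Å AND ∠(D:H:A) ≥ 124.455°)

Candidate ring atoms are scanned by increasing d(H:A) (serial-number
tie-break) and the first qualifying atom is reported, so one donor/ring
pair yields one hit rather than six. The projected reference atom is the
donor hydrogen (configurable to D). `S_PI` uses the same gate and
ring-circle condition with the sulfur atom in place of H, restricted to
sulfur donors; `PI_PI` (face-to-face stacking) requires centroid
separation ≤ 5.5 Å, interplanar angle ≤ 30° and a centroid offset within
1.4 ring radii — the latter two thresholds are this package's
reconstruction, exposed in the criteria config.

**Orthogonal multipolar contact** between bond dipoles (Dp1+, Dp1−) and
(Dp2+, Dp2−), with |δ⁺ − δ⁻| ≥ 0.2 e in both dipoles:

    d(Dp1−:Dp2+) ≤ R_vdW(Dp1−) + R_vdW(Dp2+) + 0.7 Å
    d(Dp1−:Dp2+) ≤ d(Dp1+:Dp2+)
    75°  ≤ ∠(Dp2−:Dp2+:Dp1−) ≤ 105°
    0°   ≤ ∠(Nr:Dp1−:Dp2+)  ≤ 35°
    150° ≤ ∠(Nr:Dp1−:Dp1+)  ≤ 180°

Nr is the foot of the perpendicular from Dp1− onto the sp² plane of
dipole 2's group (Dp2+ and its covalent neighbors); this reproduces the
canonical perpendicular C=O···C=O motif. When Nr coincides with Dp2+
(an exactly perpendicular approach) the ∠(Nr:Dp1−:Dp2+) condition is
satisfied with angle 0; when Dp1− lies in the plane the perpendicular
degenerates and the contact is rejected. The 0.7 Å buffer is fixed per
rule and does not track the global buffer. `Dipo` is reconstructed as an
antiparallel bond-dipole contact: both charge gaps ≥ 0.2 e,
d(Dp1−:Dp2+) within the 1.0 Å-buffered gate, and the two bond-dipole
vectors anti-aligned within [135°, 180°].

**Chalcogen contacts** `S_O`/`S_N`/`S_S`: a divalent sulfur (exactly two
heavy neighbors — thioether or disulfide; thiols belong to the `SH_*`
rules) within the buffered vdW gate of an sp²/charged acceptor (O.2,
O.co2, N.2, N.ar, or another divalent S), with the same donor-side
neighbor condition as above. Restricting the acceptor set makes the
water oxygen (O.3) ineligible, which is what fixes the water-capable
label count at 11 (below).

**Metal/ion coordination**: distance gate to any N/O/S atom, 3.0 Å for
metals and 3.4 Å for ions by default (the source files for these values
are not public; both are criteria-config parameters).

**van der Waals**: any heavy-atom pair of different residues within
R_vdW sum + 1.0 Å that carries no other label. All distance-gated rules
share the buffer parameter (default 1.0 Å, per-rule overridable), so
detected-contact sets grow monotonically with the buffer.

Only the CH···O, CH···π and OMulPol thresholds have published values;
every other X–H···Y/X–H···π rule inherits its family template with
per-rule overrides available in the criteria file, so dedicated
per-rule values can be dropped in when known.

## Priority resolution and determinism

When several rules accept the same unordered atom pair for the same
target, a priority order keeps exactly one label. The default order is
metals/ions > `HB_*` > `Ele_*` > `OMulPol` > `Dipo` > chalcogen >
X–H···π > `PI_PI`/`S_PI` > weak hydrogen bonds > `vdW`, fully
overridable by the priority file. This implements the definition of
`vdW` as "contacts not assigned to any other type". Hits are sorted by
(target key, partner key, label, atom serials); repeated runs on the
same input produce byte-identical output files. Spatial culling
(default 8 Å heavy-atom radius, ≥ any rule's reach) is proven lossless
by a test comparing against unculled detection.

## Water bridges

Waters in direct contact with a target produce `M#label#S` hits. Each
such water is then profiled against its own environment (antibody and
antigen residues; never other waters), and every pair of one
target–water leg and one water–environment leg becomes a bridge
`M#label1#S#label2#X` through that single water; two targets touching
the same water form an `M#…#S#…#M` bridge. Chains through two or more
waters are not followed. Each (leg1, leg2) combination is emitted once
and counted once.

## Descriptors

Direct hits map to `M#label#class` names; aggregation erases detail in
two modes. *Grouped* (the default feature set): partner class is erased
(`M#CH_O#`), all target–water hits pool into `M##S` and all bridges into
`M##S##`, metal and ion labels are dropped — 28 + 2 = 30 descriptors,
31 with the rotamer-energy term appended. *Individual*: water terms stay
separate as `M#X#S`, `M#X#S#X#` and unordered mixed pairs `M#X#S#Y#`.
The water-capable label set is derived by satisfiability of each rule's
participant constraints against a water template (an O.3 oxygen with two
hydrogens and no C/N/S or π system): 11 labels (`HB_OH_O`, `HB_NH_O`,
`HB_OH_N`, `Ele_OH_O`, `Ele_NH_O`, `Ele_OH_N`, `CH_O`, `OH_S`, `SH_O`,
`OH_PI`, `vdW`), giving 11 same-label and C(11,2) = 55 mixed bridge
types. Column order is fixed (registry order, then water terms) for
reproducible CSVs.

## Rotamer energy

A side-chain conformation's rarity is scored as

    E = −R·T·ln(p / p_max),   R = 0.001987 kcal/(mol·K),  T = 300 K

where p is the backbone-dependent rotamer library probability of the
observed rotamer at the residue's (φ, ψ) bin and p_max the largest
probability in that bin, so the most common rotamer scores 0 and rarer
ones are penalized. (φ, ψ) map to the nearest library grid point
(round-half-away-from-zero); no interpolation, for determinism. The
observed rotamer is identified by the nearest library χ means under
wrapped angular distance — the library's own χ conventions therefore
carry through unchanged. For a residue pair the probabilities are
multiplied under an independence assumption, making the pair energy
exactly the sum of the single-residue energies; context-dependent
rotamer coupling is out of scope. Zero probabilities are clamped to
10⁻⁶ with a warning. The parser accepts any whitespace-separated
backbone-dependent library in the standard layout (residue, φ, ψ,
count, rotamer indices, probability, χ means).

## Crystal-structure-likeness

A modeled side chain is compared to its reference conformation by
heavy-atom RMSD over the side chain excluding Cβ, **without**
superposition: fixed-backbone side-chain modeling leaves model and
reference in a shared frame, which is the comparison frame. Chemically
indistinguishable namings are handled by minimizing over a per-residue
table of name swaps (Phe/Tyr ring flip CD1↔CD2 + CE1↔CE2, Asp OD1↔OD2,
Glu OE1↔OE2, Arg NH1↔NH2; identity always included; table extensible),
so a χ₂-flipped phenylalanine scores 0. RMSD < 1.0 Å (configurable to
0.8/1.2 Å for robustness sweeps) labels the structure crystal-like; a
residue pair is crystal-like iff both residues are.

## Machine-learning harness

Rows of a descriptor table belong to sequence clusters; all splitting is
cluster-level so no cluster ever straddles partitions. The two-way
splitter shuffles unique cluster ids with a seeded generator and cuts at
⌈ratio·n⌉ — 51 clusters at 2:1 give 34/17. Training uses a three-way
64/16/20 cluster split (build / early-stop / eval). The classifier is a
gradient-boosted tree ensemble (XGBoost native API) with learning rate
0.025, at most 20,000 boosting rounds, and early stopping after 100
rounds without improvement of the early-stop partition's MCC (optimized
as negative MCC, lower-is-better). MCC uses the zero-denominator → 0
convention. Metrics (MCC, accuracy, precision, balanced accuracy =
(sensitivity+specificity)/2, AUROC, AUPRC) are derived from the
confusion matrix and probability scores on the eval partition.
Attribution is permutation importance: each feature column is shuffled
n times (default 100) and the mean drop from the baseline test MCC ± sd
is reported. A hyperparameter grid search is deliberately not built in;
`train_classifier` accepts arbitrary booster parameter overrides so a
config-driven search can wrap it.

## Synthetic fixtures: what they do and do not show

`make_probe(label, satisfy)` builds, for each of the 36 labels, a
minimal two/three-residue system that either satisfies the rule (exactly
one hit of that label survives priority resolution) or violates exactly
one of its conditions (zero hits of that label). Geometries use
idealized bond lengths (C–H 1.09 Å, N–H 1.01 Å, O–H 0.96 Å, S–H 1.34 Å,
C=O 1.23 Å) and the template charge set, and keep ≥ 0.05 Å / 2° margins
to every threshold so tests never sit on a rule boundary.
`make_toy_complex` arranges a glutamine-like target among antibody and
antigen fragments with two waters — one bridging target to antigen, one
touching the target only — and applies a seed-dependent rigid motion to
the whole complex; its full expected hit multiset was computed once with
the exhaustive all-pairs oracle and is frozen in the package.

These fixtures exercise rule thresholds, priority resolution, water
bridging, aggregation arithmetic and invariances. They are *not*
realistic chemistry: no crystallographic packing, no hydrogen-placement
ambiguity, no incomplete side chains, no alternate conformations, and
bond geometry far cleaner than any refinement produces. Passing tests
therefore demonstrate that the operational definitions are implemented
exactly as stated, not that the definitions themselves capture every
interaction in real complexes. Likewise the ML checks use count-valued
synthetic tables with one informative column — they validate the
harness (leak-free splitting, early stopping, attribution), not any
biological claim.

## Numerical choices

- Ring planes by principal-axis best fit; planarity gate 0.35 Å
  (configurable), measured leave-one-out (each member against the plane
  of the others) so a single strongly puckered atom is caught.
- Partial charges are a self-consistent Gasteiger-like template set
  shipped with the typing dictionary; the only charge-sensitive
  predicate is the |δ⁺−δ⁻| ≥ 0.2 e dipole gate, and the templates are
  chosen so genuinely polar bonds (C=O, C–O, C–N) clear it while C–C and
  C–H do not.
- AltLoc policy: blank/'A' kept, other locations dropped; a residue
  present only in other locations is an error (or silently reduced).
- Residue identity is (chain, resseq, icode) as found in the file — no
  renumbering; MOL2 substructures are 1-based in file order and the
  round-trip PDB→MOL2→memory is lossless for types, charges (1e-4),
  bonds and coordinates (1e-3 Å).
- Two hydrogen-name dialects ship with the typing dictionary (PDB v3 /
  pdb2pqr style and GROMACS ff99SB-ildn style); unknown hydrogens can
  optionally be matched by nearest heavy atom (off by default).
- Degenerate geometry is rejected, never silently patched: coincident
  angle vertices, collinear ring members and in-plane dipole
  perpendiculars all raise or reject.

## Known limitations

- The non-published per-rule thresholds (all rules outside CH···O,
  CH···π, OMulPol) are reconstructions; conclusions about *relative*
  frequencies of those interaction types depend on them. Every value is
  externalized to the criteria config.
- Protonation, tautomers and hydrogen-network optimization are upstream
  concerns; results are only as good as the hydrogen placement of the
  input.
- The dipole rules rely on template (not structure-specific) charges.
- `NH_PI` covers both cation–π and amide–π donors with one parameter
  set; the registry does not distinguish them.
- The independence assumption of the pair rotamer energy ignores
  steric/hydrogen-bond coupling between adjacent side chains.
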