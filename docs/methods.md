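# Methods

## The model

`sodscan` operationalises a style of structural reasoning that is usually
done by eye in a molecular-graphics program: replace one side chain on a
fixed, high-resolution backbone, try every plausible conformation of the
new side chain, and ask whether any of them preserves the packing and
hydrogen bonding that the wild-type residue provides. The underlying
assumptions are deliberately those of the manual workflow:

* **Rigid backbone.** The template backbone and all neighbouring side
  chains are frozen; only the substituted side chain is rebuilt. Real
  proteins relax — a clash predicted on a rigid template may be absorbed
  by backbone movement in vivo. Verdicts are therefore statements about
  strain against the native conformation, not free-energy predictions
  (no ΔΔG is computed, by design).
* **Discrete conformers.** Side-chain conformational freedom is explored
  through rotamers: either a compact library of modal chi values
  (staggered sp3 wells at −60/60/180°, reduced sets for sp2-terminal
  dihedrals) or an exhaustive chi grid. "All possible rotamers" is
  approximated by the grid mode (default 30° steps).
* **Geometric chemistry.** Contacts and hydrogen bonds are geometric
  classifications of atom pairs, not energies.

## Pipeline and parameters

| parameter | default | meaning |
|---|---|---|
| clash overlap | 0.4 Å | pair clashes when r_i + r_j − d exceeds this |
| contact shell | 0.5 Å | pair is a favourable contact up to this beyond the radius sum |
| environment radius | 8 Å | residues with any atom this close to the mutated residue's CB (CA for Gly) are the scoring environment |
| H-bond distance | 3.5 Å | max donor–acceptor heavy-atom distance |
| H-bond angle | 90° | min antecedent–donor–acceptor angle |
| f_contact | 0.6 | fraction of wild-type side-chain contacts the best clash-free rotamer must keep |
| clash-free fraction | 0.5 | variant must keep at least this multiple of the wild type's own clash-free rotamer fraction |

Radii are Bondi values (C 1.70, N 1.55, O 1.52, S 1.80 Å); the default
table also covers P, the halogens and the common structural metals
(Zn, Cu, Fe, Mg, Ca, Mn, Na, K) so metalloprotein templates parse without
special handling, but deliberately not Se — selenomethionine entries
require an explicit extended table, which keeps the user aware that the
template is a derivative. All thresholds are parameters of `ScanParams`
and are echoed into every report.

Pairs within one covalent neighbourhood (1-2, 1-3, 1-4 through the probe
residue's own bonds and its peptide links) are excluded from clash and
contact counting; pairs between different residues are never excluded.
Category priority for a pair is clash > hydrogen bond > contact, so each
pair is counted once.

### Classification rules

Over all candidate rotamers of the substitution (plus the template's own
measured chi whenever the substitution shares the wild type's chi
structure — a glutamine at a glutamate site can by construction access
the conformation the template exhibits):

* **Steric clash** — the variant's clash-free rotamer fraction is below
  0.5 × the wild-type amino acid's own clash-free fraction, where the
  wild type is re-scored through exactly the same build-and-score path.
  The *relative* form is essential: at any packed site most library
  rotamers of the wild-type residue itself collide, so an absolute
  fraction threshold would brand every identity substitution a clash.
  The relative rule makes "identity ⇒ None" a theorem (the candidate
  sets coincide) while still flagging substitutions, like valine at a
  groove, for which no orientation works at all.
* **Loss of van der Waals** — the best clash-free rotamer (most contacts,
  H-bonds as tie-break) retains fewer than f_contact of the wild-type
  side chain's contacts. Glycine, with no side-chain atoms, always
  triggers this when the wild type made any contact.
* **Loss of H-bonds** — the wild-type side chain donates or accepts
  hydrogen bonds in the template and no clash-free rotamer of the
  variant re-forms at least as many.
* **None** — nothing triggered. Dual labels are possible (a substitution
  can both lose contacts in its clash-free rotamers and clash in most
  others); `None` is exclusive.
* **Deletions** are never modelled geometrically. Removing a residue
  in-frame shifts every C-terminal residue out of register with its
  stabilising partners, so deletions receive a rule-based
  `Loss of H-bonds`, flagged `rule_based` in the call.

Backbone flexibility introduced by glycine is *not* modelled: a Gly at a
position whose wild-type side chain makes no contacts above threshold
classifies as `None`.

### Hydrogen-bond census

Across an ensemble of superposed protomers, a donor atom is assigned at
most one partner per protomer: the criteria-satisfying acceptor at
minimal donor–acceptor distance (ties broken lexicographically by label).
Counts therefore partition the ensemble, matching the way such censuses
are reported (e.g. a lysine that bonds one aspartate side chain in 5
protomers, nothing in 23 and a glutamate in 8).

### Superposition

Kabsch superposition (SVD with the determinant correction restricting to
proper rotations) over a backbone N/CA/C/O selection of a user-given
residue range; per-protomer RMSD is reported over the selection only,
unweighted. Sequences must agree at paired positions; mismatches are
errors rather than silently aligned.

## Inclusion-count statistics

Percentages are computed as 100·k/n and displayed rounded half-up to
integer percent; non-zero values below 0.8 % display as "≤ 1%". The 0.8
cut-off is a display convention chosen to reproduce the published
rendering of the two wild-type background cells (0.76 % prints as "≤ 1%"
while 0.81 % prints as "1%"); it does not affect any computation.
A variant is an aggregator when its raw percentage strictly exceeds the
cutoff (default 5 %) at either timepoint. Any cutoff between the
background (~1 %) and the lowest aggregating value (6 %) yields the same
dichotomy on the packaged panel; sensitivity to the cutoff can be probed
by re-running `aggregator_table` at other values. The
consequence-vs-aggregation association is a Fisher exact test on the 2×2
(consequence ≠ None × aggregator); the odds ratio uses the Haldane
(+0.5) correction when a margin is zero. This statistic is the package's
own formalisation of a qualitative claim; the source assay publishes
counts only, and reports say so.

## Synthetic fixtures

* **Mini hairpin** — two ideal antiparallel β-strands (φ = −139°,
  ψ = 135°, standard peptide geometry) with a central glutamate on strand
  A and, on strand B, a lysine whose side chain descends toward the
  glutamate site the way a lysine packs against a glutamate at a
  loop–loop interface. Strand B's placement (8.5 Å along the packing
  axis, 1.5 Å register shift, 2 Å lateral offset) was chosen once, by
  construction, so that: the Glu at χ = (−60°, −60°, 0°) packs at contact
  distance with no clash (11 contacts); every Val χ1 rotamer collides
  with the descending lysine; and moving strand B 2 Å further away
  relieves the Val clashes. Tests verify these properties with
  brute-force oracles rather than trusting the construction.
  What the fixture does *not* emulate: real loop irregularity, solvent,
  and the long-range context of a β-barrel — so passing verdicts here
  demonstrate the engine's logic, not accuracy on real structures (the
  template-based concordance check covers that, given the template).
* **Conformer ensemble** — N copies of an Ala–Lys–Ala scaffold plus two
  acceptor residues (an aspartate parked 2.85 Å off the lysine NZ in one
  χ-well, a glutamate off another well). Each copy is assigned a partner
  state from an explicit partition, gets ±4° uniform chi noise inside its
  well (small enough never to flip an assignment — the margin to the
  3.5 Å criterion is ≥ 0.6 Å; verified across seeds) and its own random
  rigid motion. The default partition is (5, 23, 8) of 36.
* **Count tables** — binomial draws per variant × timepoint with a seeded
  generator; defaults emulate a ~0.8 % background and a strongly
  aggregating variant at a few hundred cells per condition, the scale of
  the packaged table.

All generators are byte-deterministic given a seed.

## Numerical choices

* Dihedrals follow the IUPAC sign convention (verified against an
  independent implementation); angles are reported in (−180°, 180°].
* Side chains are built by NeRF internal-coordinate placement; CB is
  placed from N/C/CA with torsion(C, N, CA, CB) = −122.6°, giving
  L-configuration (improper N–C–CA–CB ≈ +122.8°, checked against an
  embedded L-alanine reference). Build→measure chi round-trips are exact
  to < 1e-6°, property-tested over all chi-bearing amino acids.
* Aromatic rings are placed atom-by-atom from ideal internal coordinates;
  ring closure is approximate at the 0.01-Å level, well below the 0.4 Å
  clash tolerance.
* Kabsch superposition refuses < 3 points or collinear point sets; the
  proper-rotation branch is enforced via the SVD determinant sign.
* Neighbour search uses a KD-tree; equivalence with O(n²) enumeration is
  asserted property-based in the test suite.
* The Fisher p-value from scipy is cross-checked against a direct
  hypergeometric enumeration oracle to 1e-12. On an 11-variant panel the
  exact test is conservative (discrete support), so the null-calibration
  test asserts validity (P(p ≤ t) ≤ t + Monte-Carlo margin), not exact
  uniformity, which a discrete exact test cannot have.

## Known limitations

* No backbone relaxation, no explicit hydrogens (heavy-atom H-bond
  criteria only), no metal-coordination chemistry beyond parsing, no
  ΔΔG or stability estimate, no symmetry expansion.
* The rotamer library is compact and modal, not a statistical
  backbone-dependent library; backbone-dependent filtering is a coarse
  φ/ψ-region rule on χ1 wells.
* Deletion calls are rule-based by design and carry no geometric
  evidence.
* Scanning scores one protomer at a time; inter-subunit environments are
  visible only if the partner chain's residues are merged into the
  scanned protomer.
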