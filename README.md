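# sodscan

Structural-consequence scanning of point substitutions in protein
structures, built around the question of why some amino-acid replacements
in Cu/Zn superoxide dismutase (SOD1) make the protein aggregate while
others at the very same position are tolerated. Missense mutations in
SOD1 cause familial amyotrophic lateral sclerosis (fALS), and a common
property of the disease alleles is a heightened propensity of the protein
to misfold and form cytosolic inclusions. `sodscan` is for structural
biologists and protein-misfolding researchers who want to ask, for any
template structure and any panel of substitutions: *does this replacement
fit?*

## What it computes

Given a high-resolution template (PDB or mmCIF) and a variant such as
E40V or E133del, the package:

1. **Superposes protomer ensembles** (Kabsch least-squares over a backbone
   selection) and measures side-chain conformers (chi dihedrals) and
   per-protomer hydrogen-bond partners, summarised as a census — e.g. a
   donor that bonds acceptor A in 5 protomers, nothing in 23 and
   acceptor B in 8.
2. **Enumerates candidate rotamers** for the substituted residue — a
   compact library of modal chi values, or an exhaustive chi grid — and
   **builds each side chain** on the fixed backbone from ideal internal
   coordinates (bond length, bond angle, dihedral; L-configuration CB).
3. **Scores every placed side chain** against its environment (all
   residues within 8 Å of the mutated residue's CB): steric clashes
   (van der Waals overlap > 0.4 Å, Bondi radii), favourable van der Waals
   contacts (within 0.5 Å beyond the radius sum) and geometric hydrogen
   bonds (donor–acceptor ≤ 3.5 Å, antecedent angle ≥ 90°), with 1-2/1-3/1-4
   covalent exclusions.
4. **Classifies the variant** into the vocabulary
   `Steric clash` / `Loss of van der Waals` / `Loss of H-bonds` / `None`:
   a substitution is a steric clash when its clash-free rotamer fraction
   falls below half of the wild-type amino acid's own clash-free fraction
   at the site; it loses van der Waals support when its best clash-free
   rotamer keeps < 60 % of the wild-type side chain's contacts; in-frame
   deletions are called rule-based `Loss of H-bonds` (register shift).
5. **Models the inclusion assay**: per-variant cell counts at 24 h / 48 h
   become percentages (round half-up; sub-background values render as
   "≤ 1%"), variants are dichotomised as aggregators (> 5 % at either
   timepoint), and the association between predicted consequence and
   aggregation is tested with a Fisher exact 2×2 (hypergeometric) test.
   The count table for the 11-variant panel around E40 and E133 (plus the
   classic G93A control) ships with the package.

A synthetic-fixtures module generates fully controlled test systems with
no downloads: a two-strand "mini hairpin" whose central Glu packs against
a descending lysine (so Glu→Val clashes in every rotamer, Glu→Gly strips
the contacts, and Glu→Gln is tolerated — by construction), seeded
protomer ensembles with a prescribed hydrogen-bond partition, and
binomial inclusion-count tables.

## Worked example

```python
from sodscan import classify_variant, VariantSpec
from sodscan.fixtures import make_mini_hairpin

protomer = make_mini_hairpin().protomers[0]
for sub in ("GLN", "VAL", "GLY"):
    call = classify_variant(protomer, VariantSpec(4, "GLU", sub))
    ev = call.evidence
    print(sub, call.label_text(), ev["clash_free_fraction"],
          ev["wild_type"]["n_contacts"], "->", ev["best_rotamer"]["n_contacts"])
```

prints

```
GLN None 0.1622 11 -> 11
VAL Steric clash 0.0 11 -> 7
GLY Loss of van der Waals 1.0 11 -> 0
```

Gln keeps a clash-free rotamer fraction comparable to Glu's own (0.16 vs
0.21) and all 11 wild-type van der Waals contacts, so it is tolerated.
No Val rotamer is clash-free (fraction 0.0): steric clash. Gly is always
clash-free but retains 0 of 11 contacts: loss of van der Waals.

The same machinery from the shell:

```bash
sodscan scan template.pdb --variant E40G --variant E40V --variant E40Q
sodscan table            # packaged count table: percentages + association
sodscan census ensemble.pdb --donor 91:NZ --acceptor 92 --acceptor 40
sodscan fixtures --kind mini_hairpin --out demo/
```

`sodscan table` reports, among other things, the 2×2 association between
predicted consequence and aggregation for the packaged panel:
contingency [[6, 0], [0, 5]], Fisher exact p = 0.00216, odds ratio 143
(Haldane-corrected). The association statistic is this package's
formalisation; the source assay reports counts only.

To scan the actual SOD1 template, fetch PDB entry 2v0a (wild-type human
SOD1 at 1.15 Å) from the wwPDB and save it as `data/templates/2v0a.pdb`;
the panel-concordance test in `tests/test_acceptance.py` then runs
against it.

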