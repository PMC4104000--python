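# colefuse

A design toolkit for chimeric zinc-finger nucleases built from the nuclease
domain of colicin E7 (NColE7).

## The problem

Conventional zinc-finger nucleases fuse a FokI cleavage domain to a
zinc-finger (ZF) DNA-binding array. FokI keeps its nonspecific activity even
when the binding domain is damaged, which is a cytotoxicity risk. NColE7
(residues 446–576) offers a way out: its catalytic HNH motif sits at the
C-terminus but is only active when the positively charged N-terminal loop
("KRNK", especially R447) reaches the active site. Splitting NColE7 around
the ZF array therefore yields a *positively controlled* nuclease — it can
only cut when the fingers are bound at their specific site and deliver the
controlling loop back to the catalytic centre.

`colefuse` implements the computational pipeline for designing such
chimeras:

1. **Model construction** (`colefuse.superpose`) — superimpose the DNA of a
   nuclease/DNA complex onto the DNA of a ZF/DNA complex over every
   equal-length base-pair window (both orientations), remove the donor DNA,
   keep the fingers' specific site, and rank the merged models by a steric
   clash score (the scorer is pluggable).
2. **Fusion bookkeeping** (`colefuse.fusion`) — the NX–ZF–CY composition
   algebra: which nuclease residues a model retains, which are missing, and
   which experimentally important mutation sites fall in the gap. Includes
   the composite DNA sequence builder that prolongs the ZF site
   (`GAACTATGAGG…`) into the duplex used by the models.
3. **Linker design** (`colefuse.linkers`) — digest protein structures into a
   backbone-fragment library; search it by length, end-to-end distance and
   anchor-residue RMSD; graft candidates as polyalanine; scan linker
   positions over 18 amino acids (Cys and Pro excluded) with a pluggable
   stability scorer.
4. **Simulation setup** (`colefuse.simsetup`) — harmonic Zn-site restraints
   (Zn–N(His): r₀ = 0.209 nm, k = 14 710 kJ mol⁻¹ nm⁻²; Zn–S(Cys):
   r₀ = 0.231 nm, k = 18 150 kJ mol⁻¹ nm⁻²), neutralization + 0.2 M NaCl
   ion counts, and a YAML manifest of the MD protocol.
5. **Ensemble analysis** (`colefuse.trajectory`) — RMSD/RMSF/radius of
   gyration, hydrogen bonds, the four catalytic-geometry series
   (N560(CG)–H545(CA), H545–V555 H-bond, Zn–O(scissile phosphate),
   R447(NE)–P), pairwise protein–DNA interaction energies, and block
   averaging.
6. **Synthetic fixtures** (`colefuse.fixtures`) — seeded generators for
   ideal B-DNA, toy protein–DNA complexes with Zn sites, fragment libraries
   and toy trajectories, so the whole pipeline runs without downloads.

The MD engine itself is out of scope: the toolkit prepares simulation
inputs and analyzes coordinate ensembles (multi-model PDB); it does not
integrate equations of motion.

## Worked example

```python
import colefuse as cf

# fusion bookkeeping for a reverse-orientation model
comp = cf.parse_model_name("N46-ZF-C45")
n_range, c_range, missing, count = cf.retained_and_missing(comp)
print(missing, count)
# (492, 531) 40

muts = cf.load_mutation_table()
print(cf.map_mutations_to_model(comp, muts))
# {'single': ['K525'], 'double': ['E508'], 'triple': []}

# composite DNA for both orientations
print(cf.build_composite_dna(orientation="straight"))
# GAACTATGAGGCAGAACT
print(cf.build_composite_dna(orientation="reverse"))
# AACTATGAGGCAGAACTATGAGG

# Zn restraints on a synthetic HNH-like site
from colefuse.fixtures import BdnaSpec, make_toy_complex, HNH_SITE
site = make_toy_complex(BdnaSpec("GAACT"), zn_sites=(HNH_SITE,), seed=1)
for term in cf.zn_site_restraints(site):
    print(term.r0, term.k)
# 0.209 14710.0   (three times, one per coordinating histidine)

print(cf.ion_counts(net_charge=-6, n_waters=12000, conc_M=0.2))
# (49, 43)   i.e. 6 neutralizing Na+ plus 43 NaCl pairs
```

The `N46–ZF–C45` model is missing nuclease residues 492–531 (40 of 131);
the only single-site inactivating mutation falling in that gap is K525, and
E508 from a double mutant — exactly the interactions that model cannot
maintain. The ion counts follow from 0.2 M × 12 000 waters / 55.345 M ≈ 43
salt pairs plus six sodium counter-ions.

The same stages are scriptable from the shell:

```sh
colefuse fixtures --make bdna --seq GAACTATGAGGCAGAACT --out dna.pdb
colefuse composition --model N46-ZF-C45 --model C123-ZF-N7
colefuse build-models --acceptor zf.pdb --donor nuclease.pdb --window 5 --window 8 --out-dir models/
colefuse sim-setup --structure complex.pdb --net-charge -6 --out-dir sim/
colefuse analyze --traj traj.pdb --obs rmsd,rmsf,rgyr --sel chain=P --out-dir report/
```

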