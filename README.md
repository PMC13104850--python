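# entangle-age

Tools for linking **native non-covalent lasso entanglements (NCLEs)**
in protein structures to **age-associated structural changes** measured
by limited-proteolysis mass spectrometry (LiP-MS), with coarse-grained
refolding simulation and topology-aware trajectory analysis.

An NCLE is a backbone loop, closed by a non-covalent residue–residue
contact (i, j), through which one of the chain termini is threaded.
Threading is detected with the discretized Gaussian linking number
between the loop segment and each terminal tail,

    g = (1/4π) Σ_m Σ_n (R_m − R_n)/|R_m − R_n|³ · (dR_m × dR_n),

where R_l and dR_l are bond midpoints and bond vectors of the Cα trace;
|g| ≥ 0.6 on either tail marks an entangled loop, the sign encodes
chirality, and the tail residue where the cumulative partial linking
passes ±0.5 is the crossing residue.  The package then asks, for a
proteome-scale table of proteins:

- are natively entangled proteins more likely to exhibit age-associated
  structural change?  (2×2 odds ratio with Woolf CI and Fisher test;
  logistic regression `log p/(1−p) = β0 + β1·E + β2·L*` adjusting for
  standardized protein length);
- are the changes concentrated in the entangled regions of those
  proteins?  (same statistics at residue level);
- does a structure-based (Gō) model of such proteins misfold by
  failing to form the native entanglement?  (temperature-quench
  Langevin dynamics; per-frame fraction of native contacts Q and
  fraction of contacts with changed linking G; k-means++/PCCA+ state
  clustering; misfolding probability
  `P_mis = N_mis/(N_native + N_mis) × 100%`);
- are the misfolded states consistent with the proteolysis evidence?
  (window-SASA permutation tests with Benjamini–Hochberg adjustment).

Every stage has a synthetic-data generator with planted ground truth
(`entangle_age.synth`), so the whole pipeline runs and is tested
without downloading anything.

## Worked example

Protein-level association from a table of 2,256 proteins of which
1,686 carry at least one native NCLE, with 368 and 70 changed proteins
in the entangled and non-entangled groups:

```python
from entangle_age.assoc import contingency

r = contingency(counts=(368, 1318, 70, 500))
print(r.summary())
```

```
2x2 table a=368 b=1318 c=70 d=500
OR = 1.99 (95% CI [1.51, 2.63]), Fisher p = 3.25e-07
prevalence: overall 19.4%, exposed 21.8%, unexposed 12.3%
```

Natively entangled proteins have twice the odds of an age-associated
structural change; 21.8% of them changed versus 12.3% of the rest.

Detecting a planted entanglement and measuring its linking number:

```python
from entangle_age.synth import gen_mini_protein
from entangle_age.structures import heavy_atom_contacts
from entangle_age.entanglement import detect_ncles, cluster_ncles

s, truth = gen_mini_protein("entangled_hairpin", seed=0)
cm = heavy_atom_contacts(s, cutoff=8.0, min_seq_sep=3)   # Cα-only trace
reps = [n for n in cluster_ncles(detect_ncles(s, cm)) if n.representative]
print(reps[0].loop, round(reps[0].gN, 2),
      [(c.residue, c.sign) for c in reps[0].crossings])
```

```
(24, 34) 0.77 [(11, 1)]
```

One representative NCLE: a loop closed near residues 24–34, threaded by
the N-terminus at residue 11 with positive chirality — matching the
planted construction (loop contact (24, 35), crossing residue 11).

A command-line interface mirrors the library:
`entangle-age contacts|detect|assoc|sim|traj|sasa|synth --help`.

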