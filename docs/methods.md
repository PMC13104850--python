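# Methods

This package implements a pipeline that asks whether proteins carrying
native non-covalent lasso entanglements (NCLEs) — backbone loops closed
by a non-covalent contact and pierced by a terminal segment — are more
likely to show age-associated structural changes, and whether those
changes concentrate in the entangled regions.  It combines geometric
entanglement detection from structures, limited-proteolysis mass
spectrometry (LiP-MS) evidence, association statistics, coarse-grained
refolding simulation, trajectory topology metrics, and a solvent-
accessibility consistency test.  Every stage has a synthetic-data
generator with planted ground truth, so the full pipeline runs and is
validated without any external download.

## Entanglement detection

A backbone loop is the chain segment between residues i < j whose
heavy atoms are within 4.5 Å (the loop-closing contact; pairs with
|i − j| ≤ 3 are excluded).  Threading of either terminus through that
loop is quantified with the discretized Gaussian linking number over
bond midpoints R_l = (r_l + r_{l+1})/2 and bond vectors
dR_l = r_{l+1} − r_l:

    g = (1/4π) Σ_m Σ_n (R_m − R_n)/|R_m − R_n|³ · (dR_m × dR_n),

with the loop bonds n ∈ [i, j−1], the N-tail bonds m ∈ [6, i−5] and the
C-tail bonds m ∈ [j+6, N−5] (1-based; empty ranges contribute exactly
zero).  The five bonds at each chain end and flanking the loop are
excluded so that closure noise does not masquerade as threading.  A
loop counts as entangled when |gN| ≥ 0.6 or |gC| ≥ 0.6.  The threshold
is applied to the magnitude: g is signed by chirality, and a
left-handed thread is as much an entanglement as a right-handed one.

Crossing residues — where the thread pierces the loop plane — are read
off the cumulative partial-linking profile along the tail: each passage
of the cumulative g through a half-integer level k + 0.5 marks one
crossing, with the sign of the step.  This replaces the external
topology package used in the original analysis with a self-contained
construction that is validated against fixtures of known geometry; it
agrees with the planted crossing to within ±2 residues on all
generator fixtures.  A tail with two crossings of opposite sign is a
slipknot (thread in, thread back out) and is excluded.

Degenerate NCLEs — many nearby contacts closing essentially the same
loop around the same thread — are clustered: two NCLEs are merged when
their crossing patterns match in terminus and sign and all crossing
residues agree within ±5 positions.  The representative is the member
with the shortest loop, ties broken by the smaller loop start.  Both
the ±5 window and the shortest-loop rule are this package's
concretization of a clustering protocol that the source analysis
delegates to earlier work; they are deterministic and order-independent.

The *entangled region* of a protein is the union of (1) residues within
±3 sequence positions of any representative loop-closing or crossing
residue and (2) residues with any heavy atom within 4.5 Å of those key
residues.

## Cα contact cutoff for synthetic fixtures

The 4.5 Å heavy-atom contact rule presumes side chains.  Synthetic
fixtures in this package are Cα-only traces, whose contact distances
run 5–7 Å, so all fixture-based analyses (NCLE detection on generated
mini-proteins, the Gō-model native pair list, Q) use an 8 Å Cα cutoff —
the field-standard choice for Cα-level structure-based models.  The
4.5 Å default applies unchanged whenever an all-atom structure is
supplied.

## LiP-MS classification

A peptide is significant when |fold change| > 5 and adjusted p < 0.05
(both strict); a protein exhibits an age-associated structural change
when at least one of its peptides is significant.  Proteins with no
observed peptides are "unobserved", not "unchanged".  Altered cleavage
sites map to residues: the proteinase-K-generated terminus for
half-tryptic peptides, the central residue (floor of the midpoint for
even spans — the ±3 buffer absorbs the half-residue ambiguity) for
tryptic ones; each site is dilated by ±3 residues, clipped to the
chain.  The fold-change column may be stored linear or log2; a reader
flag converts, and the threshold is always applied on the linear scale.

## Association statistics

Protein-level: exposure = has ≥1 representative NCLE, outcome =
LiP-MS change.  Residue-level (entangled proteins only): exposure =
residue in the entangled region, outcome = residue in an altered
(buffered) cleavage window.  Crude association is the 2×2
cross-product odds ratio with a Woolf (logit-scale) 95% interval,
exp(ln OR ± 1.96·√(1/a + 1/b + 1/c + 1/d)), and a two-sided Fisher
exact p-value.  Zero cells leave the OR flagged undefined unless the
Haldane 0.5 correction is requested (off by default).  The adjusted
association is a maximum-likelihood logistic regression

    log p/(1−p) = β0 + β1·E + β2·L*,

with L* the protein length standardized to mean 0 and SD 1; the
adjusted odds ratio is exp(β1) with a Wald interval.  Length is the
confounder: longer proteins both carry more NCLEs and present more
peptides.  Woolf was chosen for the crude CI because it reproduces
both printed reference intervals from their printed counts exactly at
the reported precision; the package treats that agreement as the
operative definition of "the CI method used".

Supporting procedures: percentile bootstrap of the median (10⁶
resamples by default, chunked, seed-deterministic), the one-sided
Brunner–Munzel rank test (t approximation; the normal limit under
complete separation), and transcript-normalized abundance calls —
protein fold change mean(aged)/mean(young) over replicates, divided by
the transcript fold change only when the transcript itself changed
(|log2 FC| > 1 and Welch two-tailed p < 0.01); a protein is called
increased when normalized FC > 1 with Welch p < 0.01.

## Coarse-grained Gō model and quench protocol

Each residue is one bead at its Cα.  Energies (kcal/mol, Å, radians):
bonds k(r−r0)² with k = 50; angles k(θ−θ0)² with k = 20; torsions
kd1·(1−cos(φ−φ0)) + kd3·(1−cos 3(φ−φ0)); a 12-10 well
ε[5(σ/r)¹² − 6(σ/r)¹⁰] on every native pair with σ the native
separation; r⁻¹² repulsion (σ_rep = 4 Å, ε_rep = 1) between all other
pairs with |i−j| ≥ 3.  All equilibrium values come from the native
structure, so native interactions are attractive and everything else
repulsive — misfolding in this model is topological, not energetic.
The uniform well depth (ε = 1.2 kcal/mol) and torsion amplitudes
(kd1 = 0.5, kd3 = 0.25 kcal/mol) were calibrated once on the bundled
helix-bundle fixture so that it is stable at 300 K and melts at 600 K
with a sharp transition between; stronger torsions keep transient
helical contacts alive in the 600 K coil and blur the melt.  The
calibration stands in for force-field parameters that the upstream
literature does not print, and absolute misfolded-state populations
are therefore not comparable with the reference analysis (see
Limitations).

Dynamics are Langevin with the BAOAB splitting, dt = 15 fs, friction
0.05 ps⁻¹, bead mass 110 amu, frames saved every 5000 steps.  The
torsion force uses an exact analytic gradient (finite-difference
verified) with the plane normals floored at sin²θ ≈ 10⁻³ to bound the
force through transiently collinear backbone angles; without the
floor, rare near-collinear events pump energy into the chain.  With
friction off and dt/4 the integrator conserves energy to < 0.5% over
10⁵ steps on the fixture.  The refolding protocol is a 15 ns leg at
600 K (unfold) followed by a quench leg at 300 K; production scale in
the reference workflow is 50 × 1.5 μs per protein, and the package's
desk-scale defaults are 10 trajectories × 50 ns, adequate for the
≤60-residue fixtures.  Mirror-image trajectories (a known Cα-model
artifact) are flagged by comparing the median sign of the torsions
over natively helical segments in the final frames against the native
sign; flagged trajectories should be re-run with a new seed.  This
heuristic replaces a published protocol that is not reproduced here.

## Trajectory metrics, clustering, misfolding probability

Q is the fraction of native contacts formed: pair (i, j) counts when
its Cα distance is ≤ 1.2 × its native distance (boundary inclusive,
Θ(0) = 1).  G is the fraction of native contacts whose loop has a
changed linking number: for every native contact, gN and gC of its
loop are recomputed per frame and compared to the native reference
after rounding to the nearest integer — raw g fluctuates thermally;
an integer change is the topological event.  The sum runs over all
native contacts whether or not they are formed in the frame.

Frames pooled over trajectories are clustered on standardized (Q, G):
k-means++ into 100 microstates (reduced with a warning when there are
fewer frames), a lag-τ transition-count matrix between microstates
(default lag 10 saved frames; counts symmetrized and lightly
regularized), and PCCA+ — implemented here as the Deuflhard–Weber
inner-simplex algorithm on the leading right eigenvectors — lumping
microstates into macrostates.  The macrostate count is a configuration
choice first; "auto" takes the largest spectral gap, a reproducible
stand-in for the visual log-probability inspection of the reference
workflow.  The native macrostate maximizes mean Q − mean G.  The
misfolding probability over the analysis window (the final 200 ns at
production scale) is

    P_mis = N_mis / (N_native + N_mis) × 100%,

where N_native counts frames of the native macrostate and N_mis counts
frames of non-native macrostates that are still near-native, Q ≥
q_floor.  The floor defaults to 0.6; the reference analysis labels
states near Q ≈ 0.9 "near-native misfolded" but states no floor, so
the parameter is explicit and reported.  Frames of non-native
macrostates below the floor belong to neither count; the alternative
reading (count them as native) is rejected because an unfolded frame
is not a folded one.

## Solvent accessibility consistency

For each altered cleavage site, the per-conformation mean
solvent-accessible surface area over the residues within ±5 positions
is compared between each misfolded-state ensemble and the native
ensemble.  SASA is Shrake–Rupley with a 1.4 Å probe; coarse-grained
frames use one 3.4 Å sphere per residue at the Cα (validated against
one- and two-sphere closed forms to 2%), and rebuilt all-atom models
can be supplied instead when an external reconstruction stack is
available.  The two-sided permutation test on |Δmean| uses 10⁵
permutations and the +1 finite-sample correction, so p is never 0.
All (state, site) p-values of one protein form a single
Benjamini–Hochberg family (the reference reports one adjusted p per
state–peptide pair without stating the family; the choice is exposed
in the API); a state is consistent with the proteolysis evidence when
any of its sites has adjusted p < 0.05.

## Synthetic data

The generators emit data plus a ground-truth sidecar (never embedded
in the data files): threaded/unthreaded circle-plus-tail curves with
planted linking number (loop first, tail through the center or
outside; the uninformative approach segments sit inside the linking
sums' exclusion windows); 40–60-residue mini-proteins (plain helix
hairpin, or an entangled variant whose thread, loop contact and
crossing residue are planted and verified |g| ≥ 0.6 at construction);
LiP-MS-style peptide tables with planted protein- and residue-level
odds ratios (prevalence defaults 21.8%/12.3% with 74.7% entangled over
2,256 proteins — the observed scale of the reference dataset — and a
logistic mode with planted β and optional length confounding, where
length drives both exposure and outcome so the crude OR is biased but
the adjusted one is not); Markov-switching Gaussian mixtures over
(Q, G) with exact planted stationary occupancies (mean dwell 20
frames); and per-site window-SASA ensembles with planted mean shifts.

What the generators do not emulate: real mass-spectrometry noise
(missing peptides, intensity-dependent variance), correlated contact
breaking in trajectories, or structure-prediction error.  Tests
passing on these fixtures demonstrate the correctness of the
computations and the recoverability of planted effects at realistic
sizes — not the biological conclusions on real data.

## Numerical and design choices

- All residue indices are 1-based with inclusive spans, matching PDB
  numbering.
- Structures are renumbered gap-free on load; residues missing a Cα are
  dropped with a warning (the linking integrals need an unbroken trace).
- k-means and all stochastic procedures take explicit integer seeds;
  trajectories are bit-reproducible per (model, protocol, seed).
- The bootstrap and permutation routines are chunked to bound memory at
  ~160 MB regardless of iteration count.
- Degenerate geometry: asphericity returns its limiting value on
  collinear/coincident points; the permutation test returns p = 1 on
  all-tied data; Brunner–Munzel falls back to the normal approximation
  under complete separation.

## Problem sizes used in validation

The bundled acceptance script regenerates every quantity from scratch
at desk scale: association tables at the printed reference counts;
logistic-recovery over 100 replicates of n = 20,000 proteins;
linking-number checks over 50 seeded fixtures; fold/unfold checks over
20 seeds of the 56-residue helix-bundle fixture (2 ns stability legs,
6 ns melt legs) plus a reduced unfold–quench refolding demonstration;
clustering recovery on 5,000-frame planted series; and the
permutation/BH stage on 200-replicate null and power simulations.

## Known limitations

- Absolute misfolding fractions from the Gō model are not comparable
  to the reference simulations (different, unpublished force-field
  constants; desk-scale sampling).  The package demonstrates the
  machinery (Q/G/P_mis, clustering, consistency testing) on planted
  fixtures instead.
- Crossing-residue identification by half-integer profile crossings is
  an approximation to the cited topology package; it is exact on clean
  fixtures but can shift a residue or two under strong thermal noise.
- Knots and covalent lassos are not detected; supply exclusion lists
  from external annotation tools.
- Single chains only; no nucleic acids, no multi-model ensembles beyond
  the first model of a file.
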