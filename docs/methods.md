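# Methods

## Problem and model

`allodecoder` integrates two orthogonal per-residue measurements of a G
protein-coupled receptor (the β2-adrenergic receptor/Gs system is the
motivating case) into a single classification of each residue's role in
signal transduction:

1. **Mutational pharmacology.** Every residue is mutated and the mutant's
   agonist concentration-response curve is measured with a BRET G-protein
   activation sensor. Fitting a Hill curve gives the signal amplitude
   (efficacy proxy) and logEC50 (potency). Discretizing the normalized
   values against wild-type-derived cut-offs yields a per-mutant call.
2. **State-specific structure contacts.** Non-covalent residue-residue
   contacts are computed independently in an active (G protein-bound) and an
   inactive structure with the van der Waals gap rule. Contacts present only
   in the active state are candidates for the interactions that *form* upon
   activation.

Crossing "mutation impairs signaling" with "residue makes at least one
active-state-specific contact" gives the four residue classes — driver,
modulator, passenger, bystander. Drivers that share an active-state-specific
contact with another driver of matching effect type (both impair potency, or
both impair efficacy; total loss of signal matches either) form the edges of
the allosteric network and are promoted to connected drivers.

## Pharmacology stage

Each biological replicate is fitted separately to

    response(c) = pre + (post − pre) / (1 + 10^(logEC50 − c)),

with the Hill slope fixed at 1 (`scipy.optimize.curve_fit`, least squares;
initial values from the edge-point means and grid median). The sensor signal
decreases upon activation, so `pre ≥ post`; amplitude is reported as
|pre − post|. A fit is *unfittable* when the optimizer fails, the fitted
baseline gap is below 0.015 raw BRET (the empirical fit floor, ≈ 20% of the
wild-type amplitude), or the fitted logEC50 leaves the measured grid span by
more than one log unit. The default measurement grid is the 11 half-log
agonist concentrations from 10^−8.5 to 10^−3.5 M plus the vehicle well,
which we place at −10.5 log M — far enough below the lowest concentration to
act as a zero-agonist point while keeping the grid strictly increasing.

Curation acts on whole replicates only (failed transfection / unfittable
noise); single points are never removed. Amplitudes are normalized to the
mean amplitude of batch-matched wild-type fits (correcting day-to-day
variation; a global-mean option exists), logEC50 to the mean over all
wild-type fits. No abundance correction is applied.

Cut-offs (defaults, on the normalized scales): efficacy loss < 0.74
(two wild-type standard deviations), potency loss ΔlogEC50 > 0.87
(7.4-fold), gain > 1.28 or < −0.71, abundance floor 25% of wild type.
Inequalities are strict; equality at a cut-off is wild-type-like. Order of
precedence: low abundance ≻ no fittable signal ≻ loss calls ≻ gain ≻
wild-type-like. A mutant crossing a loss cut-off on one parameter and a gain
cut-off on the other is reported as the loss call with a conflict flag —
the data do not say how to label such a mutant, so we surface rather than
decide. Gain-of-function mutants are reported but treated as *not*
pharmacologically important downstream, because the classification targets
impairment.

## Contact stage

Atoms are heavy atoms only; altlocs resolve to highest occupancy; waters are
excluded. Two atoms contact when center distance minus the sum of their
element vdW radii is ≤ 0.5 Å (C 1.70, N 1.55, O 1.52, S 1.80 Å by default,
configurable — published contact resources do not all share one table). An
absolute slack of 1e-6 Å on the comparison absorbs single-precision
coordinate storage. Pairs within one residue and the covalent peptide
C(i)–N(i+1) pair are excluded: covalent bonds are not non-covalent contacts.
Candidate pairs come from a k-d tree; a test asserts equality with the
brute-force all-pairs rule on models up to 500 atoms.

Residue contacts aggregate atom contacts per residue pair and are filtered:
pairs contacting exclusively via backbone atoms are dropped, as are pairs
within the same secondary-structure element (labels come from the annotation
table, not from geometry — deterministic and matching segment-level
exclusion), and pairs with a residue unresolved in either state. The
partition into active-only / inactive-only / shared is plain set algebra on
residue-pair keys.

Binding sites use the simpler 4 Å heavy-atom distance criterion (the
convention for interface definitions), distinct from the vdW-gap rule used
for the contact network; interface matrices, however, count vdW-gap
contacts, so their cells are comparable with the network's multiplicities.

Superposition is least-squares Kabsch over common Cα atoms (optionally a
fixed-core subset) in double precision. Backbone dihedral deltas use the
minimal-angle wrap Δ = ((a − b + 180) mod 360) − 180, mapped onto (−180,
180]; termini are reported as missing, never zero. Accessible surface area
is numerical Shrake–Rupley-style quadrature (960 points/atom, deterministic
sphere sampling; probe 1.4 Å) — single- and two-sphere closed forms agree
within 1%. Ligand-buried area is ASA(apo) − ASA(complex), clipped at zero.

## Classification and network

`no_signal` mutants count as pharmacologically important with effect type
"both": total loss of signaling implies both parameters are affected.
`both_reduced` drivers match either a potency-only or an efficacy-only
partner (effect sets intersect). Residues excluded for low abundance or
unresolved in either structure are `unclassified` with a reason code.
Edge weights are the atom-contact multiplicities of the underlying
active-state-specific contact.

## Enrichment

Hypergeometric over/under-representation uses exact tail sums
(`scipy.stats.hypergeom`), `p_over = P(X ≥ obs)`, `p_under = P(X ≤ obs)`;
the two tails share the `P(X = obs)` atom, so `p_over + p_under ≥ 1`.
Conservation-score group comparisons use two-sided Mann–Whitney rank-sum
tests with tie correction; p-values are reported raw with the conventional
star bands and no multiple-testing correction. Groups with fewer than two
scored members are reported as non-testable rather than dropped. The
background set for site-composition tests is configurable (classified
residues by default; termini excludable) because the appropriate background
depends on the study design.

## Synthetic data

The generators define the study conditions for all tests:

* **Screen**: wild-type curve pre = 0.80 raw BRET, amplitude = 0.075,
  logEC50 = −6.4 (typical for adrenaline/Gs); 3 replicates/mutant across 2
  batches with batch-paired wild-type controls; additive i.i.d. Gaussian
  noise, default σ = 0.003 raw BRET per point (~4% of the wild-type
  amplitude, keeping replicate-level amplitude scatter in the few-percent
  range seen for well-behaved BRET titrations). Mutant effects are
  programmed as amplitude factors, logEC50 shifts and abundance percentages.
* **Structures**: an idealized 4-helix × 20-residue Cα/pseudo-side-chain
  bundle (helix radius 2.3 Å, 100° turn, 1.5 Å rise, helices on a 16 Å
  square). A programmed contact is realized by a CG pseudo-atom pair placed
  3.6 Å apart near the CA–CA midpoint (vdW gap 0.2 Å) in the states where
  the contact is on and retracted to its own helix otherwise, leaving > 6 Å
  between partners — a wide margin on both sides of the 0.5 Å cutoff.
  The bundle is small enough for the brute-force contact oracle and has
  multiple SSEs so the same-helix filter is exercised.
* **Annotations**: Bernoulli SNP presence with class-dependent rates;
  conservation scores Normal(5 + class shift, 1) at three phylogenetic
  levels.

Every generator is a pure function of (parameters, seed).

What the toys do **not** emulate: real side-chain packing and contact
density (hundreds of contacts per state, most shared), correlated
experimental noise, plate drift, abundance-signal coupling, insertion codes
and missing loops. Passing tests therefore demonstrate correctness of the
fitting, filtering, set algebra, classification and statistics — not that
the specific published contact counts would be reproduced, which depends on
the radii table calibration of the upstream contact resource.

## Numerical choices

* Hill fit convergence: `curve_fit` defaults with xtol/ftol 1e-12; an
  unfittable status instead of an exception on failure.
* Contact boundary: gap ≤ cutoff + 1e-6 Å (storage precision slack).
* Quadrature: 960 points/atom, deterministic; ASA tolerance target 1%.
* Ties in rank-sum tests: scipy tie-corrected two-sided p.
* Canonical contact ordering: lexicographic on (residue key, atom name);
  shuffling atom order does not change any output.
* Pipeline idempotence: identical configs produce byte-identical tables;
  the manifest records input SHA-256 hashes, parameters and seed.

## Scale of the shipped analyses

The default test suite and the acceptance script run entirely on the
synthetic study: an 80-residue bundle, an 80-mutant screen (plus 57
wild-type control curves), 500-atom contact-oracle models and 200-seed null
calibrations. These sizes were chosen so every check runs in seconds while
keeping each statistical check adequately powered.

## Known limitations

* Secondary structure comes from the annotation table; no geometric SSE
  assignment.
* The effect-match rule treats effect types as sets; graded effect sizes do
  not weight edges.
* Relative ASA uses theoretical per-residue maxima for the 20 standard
  amino acids; non-standard residues never receive the surface-exposed tag.
* Constitutive activity (pre-transition baseline shifts) is deliberately
  not interpreted.
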