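# Methods

## The model

`ccpdock` treats protein-DNA docking as a search for chemical
complementarity between two heavily coarse-grained molecules.

**Representation.** Each amino-acid residue is one pseudo-atom at its
C-beta (C-alpha for glycine), annotated with the residue type, a formal
charge (ASP/GLU −1, LYS/ARG +1, HIS configurable and neutral by default),
and an average side-chain extent ⟨e⟩ in Å — the typical reach of the side
chain beyond C-beta. Each nucleotide contributes three interacting centers:
the phosphate **P** (at the phosphorus atom; absent for a 5′-terminal
nucleotide), a major-groove face **M** and a minor-groove face **m**. With
5 base types (A, C, G, U, T) this gives 15 kinds of nucleic-acid centers
and 20 × 15 = 300 pairwise interaction types.

**Pair energy.** Every (residue, center) pair interacts with

    f(r) = 1 / max(3.5, r − ⟨e⟩)        [r in Å]

i.e. a plateau of 1/3.5 while the separation is within the side chain's
reach, decaying as 1/r beyond it like a screened electrostatic potential.
The long 1/r tail is physically defensible because a desolvated
biomolecular interface has low dielectric permittivity: at ε = 4 and 298 K
the Bjerrum length — the distance where two unit charges interact with
thermal energy, e²/(4π ε₀ ε k_B T) — is ≈140 Å, far larger than any
interface (the package exposes `scoring.bjerrum_length` as a validation
utility; no dielectric constant enters the score itself, whose weights
absorb all scale).

**Chemical Context Profile (CCP).** The CCP of a pose is the
300-dimensional nonnegative vector whose (aa, base, moiety) entry is the
sum of f(r) over all pairs of that type. A residue interacts with the
phosphate of every nucleotide but with only the groove whose center is
nearest its C-beta (exact ties go to the major groove). No distance cutoff
is applied by default; a cutoff argument exists purely as a performance
knob and must be left unset for exact behavior.

**Chemical Context Discrepancy (CCD).** Two poses of the same complex are
compared by the angle between their CCPs:

    CCD = arccos( v_nat · v_mdl / (|v_nat| |v_mdl|) )  ∈ [0°, 90°]

(entries are nonnegative, so the cosine is nonnegative). The CCD is the
package's native-likeness measure in place of RMSD: it is insensitive to
the rotational/translational degeneracy of helical DNA — a 180° flip of a
near-palindromic duplex has a huge RMSD but nearly the same contact
chemistry and hence a small CCD. Strictly, the angle vanishes for
*proportional* profiles, not only identical ones; because every center is
triangulated by many others, two genuinely different poses with
proportional profiles are not realizable in practice, and the
implementation documents rather than enforces the distinction.

**Scoring function.** A pose is scored (lower = better) as

    S = ω · CCP₆₀ + ω_area |CCP| + 1 · Coulomb

where CCP₆₀ is the nucleotide-independent reduction of the profile (base
types summed out; 20 aa × 3 moieties = 60 keys), ω is a sparse weight
vector over those keys, |CCP| is the Euclidean norm of the full 300-dim
profile (a fast proxy for buried surface area — hence its negative,
attractive weight), and Coulomb is Σ q_i q_P f(r, ⟨e⟩) over charged
residues and phosphates with q_P = −1, fixed at weight 1 so all other
weights are expressed on its scale. The shipped default model has exactly
15 pairwise components (8 attractive, 7 repulsive) plus the |CCP| weight
−0.3550520; the strongest terms involve the phosphate (e.g. ASP-P
−1.2437400, ALA-P +1.8794400). Whether the Coulomb term should honor the
extent plateau is an open choice; the default reuses f(r, ⟨e⟩), and
`coulomb_form="bare"` switches to 1/max(3.5, r).

## Pose assessment

* **DNA RMSD** — proteins are superposed by least squares (Kabsch, on
  matched C-alpha/C-beta coordinates), the transform is applied to the
  model DNA, and the RMSD is taken over the P, C2′ and C4 atoms, which
  exist in every nucleotide regardless of type; matching is by chain and
  residue index only, so the measure is sequence-independent.
  5′-terminal nucleotides contribute only C2′/C4.
* **Contacts** — a contact exists when a protein pseudo-atom and a
  nucleotide center are separated by less than 7 Å. Using pseudo-atoms
  rather than all heavy atoms is a consequence of the representation and
  is the one place this package's numbers could drift from an all-atom
  assessment; the cutoff is configurable.
* **f_nat** = TP/(TP+FN): the fraction of native contacts recovered.
* **Protein "MCC"** = sqrt(precision × recall) over the sets of protein
  residues in DNA contact. This geometric mean of precision and recall is
  the docking-assessment convention adopted here; it is *not* the standard
  Matthews correlation coefficient (no true negatives enter). A
  `standard_matthews` option exists but is not the default.
* **Rank enrichment** — the fraction of the best `top_n` decoys by a truth
  annotation (e.g. RMSD) that survive pre-filtering to the best
  `subset_size` decoys by a selector annotation (e.g. geometric SCS rank).

## Decoy generation

`dockgen` is a compact Katchalski-Katzir FFT docking stage. The protein is
the static molecule (its side-chain flexibility argues for letting the
DNA scan it): it is rasterized with a one-voxel +1 surface shell over a
penalized core (default −15, the usual soft-overlap compromise). The
mobile molecule rasterizes to +1 occupancy. For each rotation from a
deduplicated z-y-z Euler grid (duplicates removed below half the angular
spacing; at 90° the set is exactly the 24-element cube rotation group),
the translational cross-correlation of the grids — the surface
complementarity score, SCS — is computed for every voxel shift by FFT,
zero-padded so no wrap-around occurs. The best 10 translations per
rotation are pooled, sorted by SCS (ties broken by rotation index, then
translation) and ranked. Desk-scale defaults are a 1.5 Å grid and 30°
rotations; the production-style 0.5 Å / 10° settings are accepted but
slow, and reproducing any particular reference implementation's rotation
count is a non-goal. Voxel occupancy uses a 1.8 Å van-der-Waals proxy
radius around each input point.

## Weight training

Training instances carry, per decoy: the 60-dim reduced profile, the
Coulomb energy, |CCP|, and the decoy's **CCD rank** (1-based, ascending
CCD, ties stable by pose id).

**Objective.** For each complex, all decoys are scored, the best 50 by
score are selected, and the complex contributes

    −100 · [any selected decoy has CCD rank < 100]  −  1 · (count of such decoys)

summed over complexes (lower is better). Rank-based terms make complexes
of different sizes commensurable where raw CCD values are not. The
composition of the two terms as a per-complex sum is this package's
reading of the training rule; both thresholds and bonuses are
configurable (`ObjectiveSpec`). At the canonical scale — 34 complexes,
top-50 each — the pooled training set has 1,700 decoys.

**FSFS.** Forward sequential feature selection over the 60 reduced keys:
each round activates the single inactive feature whose activation yields
the best objective, permanently. Screening every candidate subset with a
full weight optimization is quadratically expensive, and how weights are
set during screening is an open design point; the shipped evaluator
weights each active feature by its Pearson correlation with the CCD rank
(sign-carrying, so features enriched in bad poses screen as repulsive)
and measures the objective with those weights. Appearance counts across
repeated runs/splits (`fsfs_repeated`) identify robustly important
features.

**PSO.** Weights of the selected features (plus, optionally, the |CCP|
weight) are then optimized by particle swarm (N = 50, standard
constriction-style coefficients 0.7298/1.49618) with two modifications:
whenever a particle improves its personal best, a local stochastic
refinement tries single random dimensions in both directions, keeping
improvements, until 10 consecutive failures; and the run halts early
after a step count drawn uniformly from 1–100 (overridable), a cheap
guard against overfitting the training complexes. The optimizer is fully
reproducible from its seed and never returns a point worse than the best
initial particle. An optional `max_evals` cap bounds the total objective
evaluations.

**Binder / non-binder separation.** `separation_report` summarizes how
well scores separate known binders from control proteins:
Z = (χ − μ)/σ with μ and the *population* standard deviation from the
binder scores and χ the *median* of the non-binder scores (the caption
convention leaves the estimator of σ open; population SD is used and
documented), plus the integral of the pointwise minimum of the two
normalized score densities (shared Freedman–Diaconis histogram bins by
default, Gaussian KDE as an option). Control sets are conventionally
split at isoelectric point 7; `isoelectric_point` solves the
Henderson–Hasselbalch charge equation by bisection with an EMBOSS-style
pKa table (N-term 8.6, C-term 3.6, K 10.8, R 12.5, H 6.5, D 3.9, E 4.1,
C 8.5, Y 10.1), overridable.

## Field mapping

A protein's propensity to bind DNA is mapped by probing space with a test
moiety, exactly as a test charge probes an electrostatic field: the value
at a point is Σ ω(aa, probe)·f(r, ⟨e⟩) over protein sites, plus — for the
phosphate probe only — the protein's Coulomb field Σ q·(−1)·f(r, ⟨e⟩).
Lower is more favorable. Probe points default to a quasi-uniform offset
shell 3 Å beyond the site cloud (Fibonacci sampling pruned to the shell;
molecular-surface generation is out of scope). Tracks along a posed DNA
evaluate the three fields at each nucleotide's own centers per strand,
indexed from base-pair step 2 because the 5′ phosphate does not exist.
Raw values are emitted (PDB B-factor column + TSV); any normalization or
coloring is left to plotting.

## Synthetic data

The fixture generators define the package's test conditions:

* `build_bdna` — an idealized fiber-model duplex: rise 3.38 Å, twist 36°
  per base-pair step, backbones at phase ±77° (so the two strands are
  154° apart across the minor groove), P/C2′/C4 at radii 8.9/7.0/3.0 Å,
  groove centers at 2 Å radius on opposite faces of each pair. Groove-edge
  base atoms are emitted as small zero-sum clusters around the intended
  centers so a write→parse→reduce round trip recovers them exactly. This
  is a geometric stand-in, not a physical model: it honors helical
  symmetry, complementarity, antiparallelism and the missing 5′
  phosphate, but has no sequence-dependent shape, no sugar pucker, and
  only schematic groove geometry — conclusions about real groove
  readout do not follow from tests that pass on it.
* `flip_bases` — the purine-preserving sequence challenge A↔G, C↔U
  (C↔T for DNA).
* `make_decoys` — seeded rigid DNA perturbations of a native pose
  (per-axis Gaussian translations, default 5 Å; axis-random Gaussian
  rotations, default 20°), decoy 1 always the identity, each annotated
  with DNA RMSD and CCD against the native.
* `make_training_suite` — 34 complexes × 1,000 decoys by default, as
  feature tables rather than structures: features are half-normal draws
  over the 60 keys, the synthetic CCD is the standardized planted score
  plus Gaussian noise of relative scale 0.3, and the Coulomb column is
  noise of amplitude 0.3. The noise scale was chosen so the planted
  score's point-biserial correlation with CCD-top-100 membership exceeds
  0.5 (verified by a construction-check test) — enough signal that
  training must work, enough noise that it is not trivial. Because CCD
  here is score-plus-noise by construction, recovery results demonstrate
  the correctness of the training machinery, not docking accuracy on
  real complexes.

## Numerical choices and problem sizes

* The cosine inside the CCD arccos is clamped to [−1, 1]; self-CCD is
  therefore zero only to ~1e-4 degrees and tests compare accordingly.
* Groove-center placement (centroids of fixed base-edge atom sets, listed
  in `constants.py`) is an explicit approximation and overridable; the
  true centers the model idealizes are not uniquely defined.
* Default side-chain extents are computed from idealized extended
  side-chain geometry (C-beta to most distal heavy atom) plus a 0.5 Å
  pad; they are placeholders for empirically averaged values and every
  correctness test passes explicit extents instead of relying on them.
* Altloc resolution keeps the highest occupancy, first on ties.
* Rigid-motion invariance is asserted to 1e-9 Å; FFT-vs-direct
  correlation to 1e-6 on grids ≤ 32³.
* Test problem sizes: property suites run the training stack at
  34 × 1,000 decoys (3 seeds for feature recovery, 5 for sign recovery
  with a 6,000-evaluation PSO cap) and docking toys on ~20 Å grids —
  sizes chosen so the whole suite runs in well under a minute while still
  exercising the canonical 34-complex/top-50/1,700-decoy arithmetic.

## Known limitations

* The shipped default weights are transcribed constants; retraining on
  real complexes requires external structures and is out of scope, as are
  all-atom refinement, side-chain rebuilding, solvent models and
  physically calibrated (kcal/mol) energies.
* Contacts and RMSD operate on the pseudo-atom representation; numbers
  are comparable within the package but not interchangeable with all-atom
  CAPRI-style assessments.
* The FFT stage scores geometry only (no electrostatic grids); bit
  parity with any particular docking program is a non-goal.
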