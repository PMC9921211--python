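# Methods

## Active-set curation and potency ranking

A bioactive record carries an IC50 and/or Kd in µM; `nd` cells are
undetermined and `<N` cells are treated as the value N but flagged as
qualified. Curation keeps a record iff at least one determined affinity is
≤ the cutoff (default 100 µM); dropping is logged, and an all-dropped input
yields an empty set with a warning rather than an error, since downstream
operations validate emptiness themselves.

Potency is `min` over the determined values of {IC50, Kd}. This is a
deliberate reconstruction choice: affinity tables routinely mix
IC50-only, Kd-only and dual-valued records, and ranking by the most potent
available measurement is the only convention that interleaves them without
discarding data. Bioactivity ranks are dense 1..n ascending in potency with
ties broken stably by input order (determinism over any claim about truly
tied compounds). LOA is the same potency converted to mol/L; TOD tags the
measurement the potency came from, with Kd preferred on an exact IC50 = Kd
tie because Kd is a direct binding measurement while IC50 is assay-dependent.

## Decoy selection

The selector preserves the contract of property-matched benchmark decoys
without reproducing any specific external pipeline: matched bulk
physicochemistry, dissimilar topology, fixed decoys-per-active ratio.

- Descriptors: MW, cLogP, H-bond donors, H-bond acceptors, rotatable bonds,
  aromatic rings, formal charge (RDKit for real molecules; synthetic pools
  supply the vectors directly).
- Distance: mean over the 7 descriptors of |Δ|/scale, with scales defaulting
  to the actives' observed ranges (1.0 where a range collapses). Equal
  weighting is the neutral choice absent evidence for anything else.
- Latent-active exclusion: candidates with maximum Tanimoto ≥ 0.3 (default)
  to any active fingerprint are ineligible. Fingerprints are hashed
  circular-substructure bit vectors (Morgan radius 2, 2048 bits) or, for
  synthetic pools, sparse random bits (density 0.05, expected pairwise
  Tanimoto ≈ 0.026, far under the threshold).
- Greedy assignment: actives are served in input order; each takes its
  `ratio` nearest unused eligible candidates, ties broken by pool order.
  Greedy is not globally optimal in summed distance, but it is transparent,
  deterministic, and exact on the contract that matters (the count); a
  shortfall raises an error naming the active and the deficit rather than
  silently under-filling.

## Screening metrics

Libraries are sorted stably by score (direction is explicit metadata;
lower-is-better by default, matching ant-colony/ChemPLP-style docking
scores). Fitness is the negated score.

- ROC: entries with tied scores advance jointly, giving diagonal segments;
  AUC is the trapezoid area and equals the Mann–Whitney U statistic over
  (n_actives · n_decoys), which the tests assert on random libraries.
- pROC-AUC = (1/n) Σ −log₁₀(Dᵢ) with Dᵢ = (decoys ranked above active i) /
  n_decoys. Dᵢ is clamped below at a floor, default 1/n_decoys (one-decoy
  resolution), so a perfectly ranked library scores log₁₀(n_decoys) instead
  of diverging. The floor is configurable; its value is a reporting
  convention, not a property of the ranking. Random-ranking expectation is
  E[−log₁₀ U] = 1/ln 10 ≈ 0.4343.
- EF(f): subset size ⌈f·N⌉. With 25 actives in 775 entries the 1% subset is
  8 compounds; a pure-active subset gives the ceiling EF = N/n = 31 and a
  single active gives (1/8)/(25/775) = 3.875. Ceiling rounding is pinned by
  those identities (floor rounding would give a 4-compound subset and
  different values).
- The chemotype table joins active entries to curated records by id
  (unknown active ids are a hard join error); per-cluster fitness summaries
  use linearly interpolated quartiles.

## Trajectory analysis

Internal units are Å and ps. Distance series are reported in nm; RMSD,
RMSF and RoG in Å.

- Superposition: Kabsch SVD with the determinant correction enforcing a
  proper rotation; the fit is computed on the selection and applied to the
  whole frame. A rotational fit requires ≥ 3 non-collinear selected atoms;
  a translation-only mode (`rotate=False`) matches centroids and handles
  degenerate selections when rotation is meaningless.
- RMSF: per atom, √ of the time-mean squared deviation from the time-mean
  position, after two passes of superposition to the running mean structure
  (standard practice; one pass is nearly converged, two is cheap).
  Per-residue values are the Cα atom's RMSF for protein residues and the
  mean over atoms for ligand/other residues, which lack a Cα.
- H-bonds: donor–acceptor distance ≤ 3.5 Å and D–H···A angle within 30° of
  linear, both configurable; these are the common geometric criteria.
  Hydrogens are attached to donors by covalent distance (≤ 1.25 Å) in the
  first frame; donors without one are skipped with a warning. A pair counts
  at most once per frame even if two hydrogens qualify.
- PCA: frames are superposed to the mean structure (default on), the
  selected coordinates flattened to 3N and the covariance across frames
  diagonalized via SVD of the centered frame matrix — numerically identical
  to eigendecomposition but stable for large 3N. Eigenvalues are descending;
  projection variances equal eigenvalues (ddof = 1). Cα is the default
  selection; heavy-atom PCA is one selection string away.
- FEL: 2-D histogram of two projections (default 50×50 over the data range),
  ΔG = −kT ln(count/max count) with kT = 0.0019872·T kcal/mol, T default
  300 K. The most populated bin is exactly 0 and empty bins are +inf; bin
  counts always sum to the frame count.

## Synthetic generators

The generators define the test-bed conditions rather than emulate physics:

- Score lists: active and decoy scores are Normal(µ_a, σ) and Normal(µ_d, σ),
  lower-is-better. Defaults (σ = 8, µ_d = −90) give plausible docking-score
  magnitudes; the µ separation is the single difficulty dial (10σ forces
  perfect ranking, 0 gives the random-ranking baseline). The benchmark-scale
  defaults are 25 actives and 750 decoys, the 1:30 composition of the
  curated Fascin set. Actives carry cyclic cluster labels 1..7 so chemotype
  joins are exercisable.
- Pools: a matched candidate perturbs a random active's descriptors (±2% MW,
  ±0.1 cLogP, ±1 counts); unmatched candidates draw from broad drug-like
  ranges. All fingerprints are sparse random bits, so pool eligibility is
  guaranteed by construction, which is what the ratio contract needs.
- Trajectories: harmonic mode moves each atom along a fixed random direction
  as a·sin(ωt + φ) with an integer number of periods in the window, so the
  sampled RMSF ground truth is a/√2; gaussian mode is i.i.d. per-frame
  jitter (RMSF σ√3); drift is a rigid translation ramp (zero RMSD after
  superposition). Default 2000 frames keeps the a/√2 recovery inside 2%.

What these generators do *not* model: correlated collective motions,
anharmonicity, solvent, score distributions with heavy tails or
tool-specific biases, and real chemotype structure in pools. Passing tests
therefore validate the *metrics and their implementations*, not any claim
about real docking tools or force fields.

## Problem sizes and determinism

Every stochastic test and the acceptance script run from explicit integer
seeds; the statistical checks state their tolerance as multiples of the
standard error at the stated sizes (200 replicates for the random-ranking
pROC mean; 100 random libraries for the rank-sum equivalence; 2000-frame
trajectories for amplitude recovery). All sizes are desk-scale by design;
the full suite runs in well under a minute.

## Known limitations

- The decoy selector is a documented surrogate, not a reimplementation of
  any published decoy pipeline's internal scoring; it should not be used to
  reproduce a specific external decoy set.
- The trajectory reader handles multi-model PDB and XYZ (via MDAnalysis)
  plus a metadata sidecar; compressed binary formats (XTC/TRR) are out of
  scope for the core.
- H-bond detection uses static first-frame hydrogen assignment; it will
  miscount if bonds break/form chemically mid-trajectory (not a scenario
  the toy generators produce).
- No plotting: outputs are CSV/JSON tables intended for any plotting tool.
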