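# Methods

This note documents the models and procedures implemented in `sevscan`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic fixtures do and do not demonstrate.

## Structural features

A PDB file is reduced to its standard amino-acid residues: first model
only, alternate locations resolved to the highest-occupancy conformer
(ties broken alphabetically by altloc id), selenomethionine and a few
other modified residues mapped to their standard parents, other
non-standard residues skipped with a warning, hydrogens and hetero
groups dropped. Insertion codes are preserved and part of the residue
key.

**areaSAS** is computed with the Shrake–Rupley algorithm: each atom's
expanded sphere (van der Waals radius + probe, Bondi radii, probe
1.4 Å) is sampled with a deterministic golden-spiral point set (960
points by default) and a point counts as exposed when it lies outside
every neighbour's expanded sphere. Per-residue area is the sum over the
residue's atoms, so residue areas add up exactly to the atom-wise total.
The algorithm is exactly invariant to translation and input order;
rotation invariance holds only to the angular sampling resolution
(about one sample ring at the occlusion boundary, a few Å² per atom at
960 points), because the sample sphere is fixed in space. Accuracy
against the analytic isolated-sphere area is well within 2% at 960
points.

**areaSES** has no exact algorithm in this package. The backend is
pluggable (any callable mapping residues to areas, e.g. an adapter to an
external molecular-surface tool); the shipped fallback is the same point
sampling on the bare van der Waals envelope (probe 0), which tracks the
solvent-excluded surface qualitatively and is clearly an approximation.
It can be disabled, leaving areaSES missing.

**Torsions** use the standard four-atom dihedral with the IUPAC sign
convention, range (−180°, 180°]. φ is undefined at the first residue of
a chain, ψ at the last, and both across chain breaks (peptide C–N
distance > 2.5 Å) or when a backbone atom is absent; undefined torsions
are reported missing (NaN), never zero.

**bFactor** is the mean over a residue's heavy atoms — a deliberate
choice among unstated alternatives (CA-only was the other candidate);
with per-residue-constant B-factors the two coincide.

**Conservation** is consumed as an external per-position score file
(whitespace/tab-delimited, configurable columns) and joined by sequence
position. The input direction — lower = more conserved — is preserved;
no re-normalisation is applied. Duplicate positions are an error;
positions in the file but not the structure produce a warning; residues
without an entry carry a missing value.

Missing values everywhere are explicit NaN markers; downstream stages
either drop incomplete rows (the learner) or skip and tally the
position (the saturation scan).

## Residue interaction network

Two residues are connected when any heavy-atom pair lies strictly
closer than the contact cutoff, default 5.0 Å. A minimum ordinal
sequence separation (default 1) only excludes self-contacts, so
peptide-bonded neighbours stay connected — contact networks that drop
backbone neighbours lose the chain topology that most centralities
rely on. The graph is simple, undirected and unweighted, and isolated
residues remain as nodes.

Centralities: degree; betweenness as raw shortest-path pair counts
(unnormalised, so a 3-path's middle node scores exactly 1); closeness in
the reachable-scaled convention (scaled by the fraction of reachable
nodes, which handles disconnected components; the convention is recorded
in the output metadata); Burt's constraint from the proportional-tie
formula with uniform weights, missing for isolated nodes; HITS authority
and PageRank (damping 0.85) by deterministic power iteration to 1e-12;
and the k-core number. On a star graph the centre's constraint is 1/k,
strictly decreasing in the number of leaves — low constraint marks
central residues.

Probe-based contact definitions used by dedicated RIN tools produce
similar but not identical edge sets; a distance-cutoff network at 5 Å
reproduces node counts exactly and edge counts approximately.

## Substitution distance index

Properties (AAindex1 flat file or CSV; any number of properties, each a
numeric value per amino acid) are filtered to complete cases — a
property missing any amino acid is excluded rather than imputed,
matching the pipeline's global removal policy — then standardised to
zero mean and unit variance. Standardisation is a deliberate choice:
raw property scales are incommensurate (pKa units vs frequencies vs
volumes), and unstandardised PCA would let large-scale properties
dominate. PCA retains the smallest number of components whose cumulative
explained variance reaches the target (default 0.99); Euclidean
distances between the 20 amino acids in component space form the
substitution matrix, serialised with rows/columns in alphabetical
one-letter order. Because Euclidean distance is rotation-invariant, the
matrix does not depend on the orientation of the component basis, and at
a variance target of 1.0 it equals the distance in the full standardised
property space.

## Curation

Activity strings are normalised deterministically, in this order: plain
numbers pass through; the fixed censored-value substitutions ">5"→5,
"<10"→10, "<11"→11, "<1"→0; dash ranges "a–b" become the arithmetic
mean; worded ranges ("0 to 2"), censored ranges ("<1 to 2") and any
other censored value ("<2") are rejected as ambiguous; anything else is
unparseable. Severity bands on % activity are half-open — [0,1) severe,
[1,5) moderate, [5,40] mild — resolving the overlapping clinical
definitions ("1–5", "5–40") at the boundaries; (40,100] is labelled
non-hemophilic and excluded from modelling. Values above 100% are
rejected.

Row filters run per record in a fixed order and every rejection is
attributed to exactly one named rule, so the tally always sums to
input − kept, and re-sanitising sanitised output is a no-op. The
EAHAD-style dialect checks: variant-type/effect scope (point missense
only), position within the mature protein (default length 2332),
stop codons, synonymous records, activity > 100, ambiguous/unparseable
activity, records with neither activity nor inhibitor information,
discrepancy between first- and second-stage activity columns, ambiguous
severity labels ("mild/moderate"). "Discrepancy" is not defined by the
registries; here it means the two values imply different severity
bands — two measurements of 2% and 3% agree clinically even though they
differ numerically. The CHAMP-style dialect adds duplicate removal on
(position, wt, mut). Clinical mature-protein numbering converts to
structure numbering via a configurable offset (default 0; legacy FVIII
numbering aligns with the 2R7E structure, HGVS numbering needs +19 for
the signal peptide).

Binary labels merge mild and moderate against severe, with per-class
counts and exclusion tallies reported.

## ADASYN

The implementation follows the adaptive synthetic sampling scheme: the
synthetic budget is G = (m_majority − m_minority)·β (default β = 1,
full balance); each minority example's hardness r_i is the fraction of
majority points among its K nearest neighbours in the whole dataset
(K = 5 default, Euclidean distance, ties by row index); quotas are the
normalised hardness weights apportioned by largest remainder, so they
sum to G exactly (the original description rounds per-example, which
misses the budget by a few rows). Each synthetic point interpolates its
seed with a uniformly chosen minority neighbour at λ ~ U(0,1); the
parent indices and λ are logged, so every synthetic row is verifiably an
exact convex combination of two minority originals. When no minority
point has any majority neighbour (Σr = 0, undefined in the original
scheme) quotas fall back to uniform. Original rows are never modified;
a fixed seed reproduces the augmentation bit-for-bit.

## Learning

The design matrix has one row per mutation: areaSAS, areaSES,
kdHydrophobicity, PSI, PHI, bFactor, conservation, degree, betweenness,
closeness, constraint, authority, pagerank, kcore, and aa_distance =
d(wt, mut). Mutations at unmapped positions and rows with any missing
attribute are dropped and tallied. A wild-type letter that disagrees
with the structure at the mapped position is counted but kept, since
registry and structure numbering conventions differ legitimately.

Model comparison uses a single stratified 10-fold partition computed
once from the seed and shared by every model and hyperparameter
combination, so all learners see identical splits. Inside each training
fold — and only there — features are min–max scaled to [0,1] (z-score
available) and ADASYN is applied; validation folds are never augmented
and are scaled with training-fold parameters, so no information leaks.
Hyperparameters maximise mean fold kappa with mean AUC as tiebreaker.
Kappa is computed from the 2×2 confusion as (p_o − p_e)/(1 − p_e), with
the degenerate p_e = 1 case defined as 0; AUC is the rank statistic with
ties counting one half.

The six learners and default grids (each grid samples the documented
ranges coarsely so a full search stays fast; `PAPER_GRID_RANGES` records
the full ranges and custom grids can be passed in): decision tree
(min split 2–50, min leaf 1–20, complexity 1e-4–1), random forest
(4–100 trees, 2–7 features per split, leaf 1–5), SVM with radial and
polynomial kernels (γ up to 1.5; polynomial offset up to 2, degree
2–5) — SVMs have no native probabilities, so Severity Scores come from
Platt-style sigmoid calibration of the decision values; Gaussian naïve
Bayes (no hyperparameters); gradient-boosted trees (depth 1–25, L2
penalty 0–1, learning rate). The ensemble averages the severe-class
probabilities of the top-2 models by cross-validated kappa; member
choice is configurable for workflows that select by an external
challenge set instead. Averaging can only shrink score variance
(convexity), which is the point: two well-performing but differently
biased members disagree instance by instance, and their mean tracks the
truth better than either.

## Gray zone

A Severity Score below lo is called mild/moderate, at or above hi
severe, and inside the half-open band [lo, hi) unknown. The sweep
evaluates every grid pair (default resolution 0.01, matching the
two-decimal precision such thresholds are reported at) and records
per-class accuracy among classified instances (missing, never zero,
when a class has no classified instance), pooled accuracy, coverage and
the abstention count. Selection maximises the minimum of the two
per-class accuracies subject to a coverage floor — a formalisation of
"best classification for both classes" — with deterministic
tie-breaking: larger coverage, then narrower band, then lower lo. A
perfect scorer therefore selects an empty band.

## Saturation scan

Every feature-complete position contributes 19 rows (one per
non-wild-type amino acid); within a position all structural and network
columns are constant and only aa_distance varies, which also makes the
scan a sensitivity probe of the classifier to a single feature.
Positions with any missing feature — chain termini always, since φ or ψ
is undefined there — are skipped and tallied. Prediction is
deterministic given a trained ensemble; rows are sorted by position
then mutant code for reproducible diffs. The per-position display score
written into the PDB B-factor column (score × 100, two decimals,
sentinel −1.00 for unscored residues, all other bytes preserved) is the
mean of the 19 substitution scores by default; max is available — the
mean was chosen because a position's typical, not worst-case,
substitution effect is what the per-residue colouring claims to show.

## Synthetic fixtures and what passing tests show

The generators produce ideal-geometry backbones (N, CA, C, O placed by
internal-to-Cartesian construction with ideal bond lengths/angles;
α-helix −57°/−47°, fully extended, or seeded random-coil torsions from
the two main Ramachandran basins), ConSurf-like conservation scores,
random property tables with optionally planted low rank, and labeled
mutation tables. Labels follow a known model: a linear predictor in
standardised degree (+), conservation (−; low score = conserved =
fragile) and substitution distance (+), plus Gaussian noise, thresholded
at a quantile so the severe fraction is controlled. Defaults mirror the
curated-registry conditions: ~440 mutations, ~37% severe, moderate
noise (sd 0.5 on a unit-scale predictor). The signal-recovery
experiments use noise 0 with strong coefficients; the overfitting guard
uses zero coefficients with unit noise and a 50% severe fraction —
coin-flip labels, under which augmentation is naturally a no-op and the
chance accuracy equals the majority rate.

Passing these tests shows the machinery is correct: features are
computed as specified, no training information leaks into validation
folds, the ensemble recovers a planted signal and does not hallucinate
one from noise. It does **not** show clinical validity: real structures
have missing regions, crystallographic noise and correlated features;
real registries have measurement discordance between assays; real
severity is not a threshold on three features. Problem sizes in the
shipped experiments (60-residue structures, 300 mutations, 10-fold CV,
coarse default grids) were chosen so the whole suite and the
reproduction script each run in well under a minute of compute per
training; all are parameters, and scale up unchanged.

## Known limitations

- areaSES is an approximation unless an external surface backend is
  plugged in.
- Rotation invariance of the sampled surface areas is limited by the
  fixed sample sphere (~1% at 960 points).
- Contact-map edges approximate probe-based RIN construction; edge
  counts differ slightly between the two definitions.
- The PCA component count at a fixed variance target can shift by ±1
  depending on whether properties are standardised first;
  standardisation is the default and the alternative is exposed via
  `standardize=False`.
- Single-model-first PDB handling; no mmCIF, no NMR multi-model logic,
  no protonation.
- Severity-band boundary handling (half-open intervals) is a documented
  convention, configurable where registries disagree.
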