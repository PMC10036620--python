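# Methods

This note documents the models, conventions and numerical choices behind
`gpcrdyn`, in the spirit of the methods sections of simulation-analysis
packages: what is computed, under which assumptions, with which defaults,
and what the synthetic tests do and do not demonstrate.

## Coordinate conventions and residue labelling

Coordinates are Ångström, times picoseconds, residue numbers 1-based as
in the PDB. Insertion codes are rejected (the SSTR2 systems do not use
them), and element symbols are inferred from atom names when the element
column is missing, with the `CA`-name ambiguity resolved by residue name
(an atom named CA in residue CA is calcium; everywhere else it is an
alpha-carbon, and Cα selections additionally require element C).

Ballesteros–Weinstein labels `t.mm` are generated from a map of helix
endpoint anchors: within a helix the minor number increments by one per
residue, and the map validates that both declared endpoints agree with
this rule. The bundled SSTR2 map covers TM1 = A44^1.33–R70^1.59 through
TM7 = P288^7.29–L315^7.56 plus the six loops (ECL1–3, ICL1–3). Loop
residues have no BW label but a retrievable loop name. Because deposited
structures sometimes renumber residues, the map is a plain JSON file and
user-overridable.

## Collective variables

Loop gating: δ is the distance between the ECL2 tip — the mass-weighted
centroid of the Q187, W188, G189 Cα atoms, which for all-carbon
selections equals the plain centroid — and the centroid of all Cα atoms
of the seven TM helices. β is the three-point angle with its vertex at
the ECL2 base (A181/I195 Cα centroid), between the W188 Cα and the ECL3
base (S281/P288 Cα centroid). Activation: d is the C225–S305 Cα
distance; θ the T255–C268–I80 Cα angle with vertex at C268 (the
middle-listed atom, the conventional reading of a three-point angle).
Both pairs are invariant under global rigid motion, which the tests
verify against direct recomputation after random roto-translations.

## State classification

The closed-loop box is 24 < δ < 33 Å and 29 < β < 48°, with *strict*
inequalities: a frame exactly on an edge counts as open, which is
conservative with respect to claiming closure. A border-zone flag (the
band within 1 Å / 2° outside the box, configurable) is exported as a
diagnostic column in the scatter CSV, not as a third class — occupancy
percentages always use the single closed box.

Activation uses two independent criteria, d < 19 Å and θ > 45°. Frames
satisfying both are active, frames failing both inactive; when the
criteria disagree the frame is labelled *intermediate*. The intermediate
label is this package's explicit rule for the region antagonist-bound
receptors occupy between the active and inactive clusters; boundary
values (d = 19, θ = 45) fall on the inactive side of each criterion.

Occupancy is 100 × state frames / total frames, per replica and pooled;
the pooled figure is by construction the frame-count-weighted mean of the
per-replica figures. Rare states are reported as raw count plus
percentage, so "~0%" is distinguishable from exactly zero.

## Superposition, RMSD, RMSF

Rigid superposition is the Kabsch algorithm via SVD with the determinant
correction guaranteeing a proper rotation; fewer than three fit atoms or
a collinear fit set is an error. The RMSD/RMSF reference is frame 0, and
the fit selection defaults to the TM-bundle Cα so loop motion is measured
rather than absorbed by the fit (the scientific contrast is rigid helices
versus mobile loops). RMSF of an atom is the root-mean-square deviation
from its time-average position after superposition. The flexibility
integral is the trapezoidal integral of the Cα RMSF profile over residue
index at unit spacing — the quadrature is a package choice, since a
simple sum and the trapezoid differ only by half the end values.

## Surface areas

SASA follows Shrake–Rupley: quasi-uniform golden-spiral points on each
atom's inflated sphere (r_i + probe), a point is accessible when outside
every other inflated sphere, and the accessible fraction scales the
sphere area. SES mode projects the accessible patches back onto the van
der Waals sphere (factor (r_i/(r_i+probe))²), approximating the contact
part of the Connolly surface; reentrant probe patches are not
triangulated, so SES totals underestimate surfaces with deep grooves.
Defaults: probe 1.4 Å, Bondi-type radii, 1000 points per atom (sampling
error well under 1% by the convergence test); all three surfaced in the
API. For ligand steric-bulk comparisons the recommended selection is the
free ligand's heavy atoms, and the estimator is the plain mean ± sd over
saved frames.

## Clustering

Frames from all replicas are concatenated (keeping replica/frame
provenance) and clustered on the ligand RMSD matrix: each frame pair is
superposed on the receptor Cα, then RMSD is taken over ligand heavy
atoms. Agglomeration uses scipy's average linkage by default (complete
and single are available), cut at k = 4 clusters by default; both are
configurable. Labels 1..k are ordered by decreasing population with ties
broken by lowest member frame index, and the representative of a cluster
is the member with minimal mean distance to its co-members (ties to the
lowest frame index), making the output fully deterministic. Average
linkage on small matrices is verified against naive brute-force
agglomeration over many random instances.

## Interaction fingerprints

Detection is purely geometric, per (receptor residue, ligand residue,
type) and frame:

| type        | criterion (defaults)                                     |
|-------------|----------------------------------------------------------|
| hydrophobic | template-hydrophobic heavy-atom pair ≤ 4.5 Å             |
| hbond       | donor–acceptor ≤ 3.5 Å and D–H⋯A ≥ 130° when H present    |
| π-π         | ring centroids ≤ 5.5 Å, plane angle ≤ 35° or 60–90°       |
| salt bridge | cationic–anionic group atoms ≤ 4.0 Å                      |
| cation-π    | cationic nitrogen to ring centroid ≤ 4.5 Å                |

These are widely used fingerprint conventions; all cutoffs and windows
are configurable so results can be matched to any other detector's
settings. Without explicit hydrogens the hydrogen bond falls back to the
distance criterion alone. Hydrophobic atoms are side-chain carbons and
sulfurs only, so a Cα-only model produces no spurious contacts.
Templates cover the twenty standard residues; D-amino acids alias the
corresponding L-residue chemistry (chirality does not change interaction
typing), and bespoke templates cover threoninol, the acetyl cap and
4-nitro-phenylalanine (whose nitro oxygens are excluded as acceptors by
default, being weak). Persistence is 100 × frames containing the event /
pooled frames; the reported view keeps entries ≥ 10% (configurable)
while retaining everything internally. The pocket-region map
(top/middle/bottom) ships as a partial, user-editable JSON reconstructed
from explicitly assigned residues; F208 appears in both bottom- and
middle-region contexts in the source material and is assigned to middle
here; reports fail loudly on residues the map does not cover.

## Energetics aggregation

The generalized-Born energy evaluation is upstream of this package; what
is defined here is the exchange format (cluster table: cluster, weight,
dg_mean, dg_sd; decomposition: residue, ligand, contribution) and the
aggregation: ΔG = Σ wᵢ ΔGᵢ over clusters with weights validated to sum
to 1 within 10⁻³, and spread propagated as √(Σ wᵢ sdᵢ²) — a declared
rule, since whether published spreads are across frames, clusters or
replicas is generally unstated. The per-residue report keeps residues
whose most favourable contribution over the ligands is ≤ −1.0 kcal/mol
("reached" read as more favourable than), grouped top → middle → bottom.

## Synthetic ground truth

The generator emulates exactly the features the metrics consume, nothing
more. Seven straight Cα helices (1.5 Å rise, 11 Å bundle radius,
alternating direction) carry SSTR2 numbering 44–315; loops are smooth
arcs. The ECL2 tip is placed to hit chosen (δ, β) targets exactly:
the tip W188 sits in the plane spanned by the base-to-ECL3 direction and
the outward radial, where the angle constraint holds by construction and
the distance is solved by 1-D root finding; Q187/G189 flank it
perpendicular so the tip centroid coincides with W188. Among the
admissible placements the solver prefers a tip-to-base lever arm near
12 Å, because a short arm amplifies positional noise into angle noise.
I195 is pinned so the ECL2 base does not move with the tip.

Hidden states follow a stationary two-state Markov chain parameterized
by the stationary closed probability p and the mean closed dwell time
(default 20 frames), giving realistic frame-to-frame correlation rather
than i.i.d. sampling; transition rates follow from detailed balance.
Frames are the state's anchor plus isotropic Gaussian noise (default
0.25 Å per atom), and anchors are validated to clear the classifier box
by configurable margins (0.5 Å in δ, 2° in β — the β box is only 19°
wide, so margins much larger than a few degrees are geometrically
impossible) before any frame is produced. The companion
`occupancy_interval` gives the autocorrelation-inflated normal interval
(variance factor (1+ρ)/(1−ρ)); for very rare states the occupancy is a
sum of few geometric dwells and the normal interval underestimates the
skewed tails, which is worth remembering when reading sub-percent
occupancies.

Ligand poses plant one interaction per receptor partner: proxy
side-chain atoms are grown radially from the partner's Cα and the ligand
residue is posed to satisfy exactly one detector criterion with a 0.5 Å
margin while staying clear of every other criterion (e.g. stacked rings
are placed at 5.0 Å centroid distance — inside the π-π cutoff but
outside hydrophobic range; planted cation hydrogens point away from
acceptors so no hydrogen bond co-fires). Mutually encroaching plants are
rejected at generation time. Same seed, bit-identical output.

What passing these tests shows: the estimators are correct on inputs
whose ground truth is known exactly, under realistic temporal
correlation. What they do not show: behaviour on real force-field
geometry (side-chain packing, correlated loop modes, water), detector
agreement with any specific published fingerprint library's version, or
surface areas under alternative radii sets — those require the deposited
trajectories, for which the pipeline config is the entry point.

## Problem sizes

Default test and acceptance scales are 10,000-frame synthetic replicas
for occupancy recovery (5 seeds per condition), ≤ 8-frame matrices for
brute-force clustering comparisons (120 random instances), 10,000 sample
points for closed-form surface checks, and 20–50-frame complexes for
fingerprint ground truth — sizes at which every oracle is exact or its
statistical interval is well-calibrated.
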