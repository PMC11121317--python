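# Methods

## Problem and model

`parepi` predicts whether a given antibody paratope and antigen epitope are
compatible binding partners, working from the 3D structure of the interface
rather than from sequence alone. The central simplification is geometric:
each side of an antibody–antigen interface is reduced to a 2D image, and the
binding question becomes an image-pair classification problem.

The pipeline has four stages:

1. **Interface extraction.** Every residue is coarse-grained to a C&mu;
   pseudoatom — the mean of its heavy side-chain atoms, or the C&alpha; for
   glycine and for residues with no resolved side-chain atoms. An antibody
   residue belongs to the paratope (and an antigen residue to the epitope) iff
   its C&mu; lies within 6 Å of the C&mu; of some partner residue. Members
   farther than 40 Å from the geometric centre of the CDR residues at the
   interface (or of all antibody interface residues when no CDR annotation is
   given) are removed; this suppresses spurious secondary contacts on large
   antigens.
2. **Image rendering.** Each patch is projected onto the plane of its top two
   principal axes and rasterised: one circle per residue C&mu; (radius from
   the residue's mean volume, r = (3V/4&pi;)^(1/3)), or one 1 Å circle per
   heavy side-chain atom in per-atom mode. Circles are coloured by three
   min–max-scaled side-chain properties mapped to RGB — polarizability
   (Charton–Charton), isoelectric point (Zimmerman) and hydropathy
   (Kyte–Doolittle) — and their opacity falls linearly with distance D from
   the projection plane, &alpha; = clamp(1 − D/d_max, &alpha;_min, 1) with
   d_max = 6 Å, &alpha;_min = 0.1. Circles are painted farthest-from-plane
   first so interface-proximal residues dominate overlaps. A four-colour
   scheme (aromatic green, basic red, acidic blue) and per-channel knock-outs
   are available as ablations, as is disabling the distance–transparency map.
3. **Classification.** The paratope and epitope images are stacked into an
   H×W×6 tensor and passed through two residual blocks of 3×3 convolutions
   (32 kernels, leaky-ReLU with slope 0.1, "same" zero padding; the first
   block's skip is a 1×1 channel projection, the second's is the identity),
   then parallel max- and average-pooling with window s = 4, channelwise
   concatenation to (H/4)×(W/4)×64, flattening, dropout 0.75 and a single
   sigmoid unit: ŷ = &sigma;(w·f + b). Training minimises binary
   cross-entropy with Adam (lr 10⁻³), Kaiming-normal convolution and
   Xavier-normal dense initialisation, plateau-based learning-rate reduction
   (factor 0.1) and early stopping on the validation loss. Ten stratified
   cross-validation folds give ten models; the deployed score is the mean of
   their sigmoid outputs.
4. **Interpretation.** Because a dot product is a Hadamard product followed
   by a total sum, the elementwise product h = w ∘ f decomposes the logit
   into per-feature contributions. h is reshaped to the pooled tensor shape,
   split into its max- and average-pool halves, unpooled back to pixel
   resolution (max-unpooling places values at cached argmax positions;
   average-unpooling spreads value/s² per cell — both conserve the total),
   averaged over channels, and the two maps are summed into one signed
   contribution image. The identity &Sigma;h + b = logit holds by
   construction and is verified to 10⁻⁴ relative tolerance.

Everything numerical is plain NumPy, including the convolution, pooling and
backpropagation; scoring is done sample-by-sample so a pair's score is
bit-exactly independent of batch composition.

## Sample construction

Cognate complexes are positives. Negatives come from three generators:
pairing the paratope of one complex with the epitope of another (non-cognate);
re-rendering the cognate epitope with an extra in-plane rotation (multiples of
30° with magnitude ≥ 60°, because the screening binder rule treats ±30° as
still-binding); and re-rendering it with an in-plane translation of at least
8 Å, which exceeds a typical residue-circle radius. The default ratio is one
negative of each kind per positive. Complexes are split 80/20 into train/test
before negatives are drawn, and non-cognate partners come only from the same
side, so no complex contributes material to both sides. Ten 90/10
subtrain/validation folds are built inside the training set; since every
complex contributes an identical bundle of samples, complex-balanced folds are
stratified at the sample level within one sample.

## Frame conventions

PCA determines each patch's projection plane, but eigenvectors carry an
arbitrary sign and, for in-plane-isotropic patches, an unstable in-plane
direction. Conventions adopted:

- the normal n always points from the patch toward its partner's centroid;
- a standalone patch frame fixes the e1 sign by requiring a non-negative
  third central moment of the projected u coordinates (exact ties break by
  the lexicographically smallest residue id at maximal u), and e2 = n × e1
  closes a right-handed triple;
- for a cognate pair, the epitope's plane is its own, but its in-plane e1 is
  the unit projection of the paratope's e1 onto the epitope plane. Purely
  per-patch conventions cannot guarantee the same in-plane orientation on the
  two sides of an interface (for near-isotropic patches both the PCA axis and
  any odd-moment sign rule flip under sub-Å coordinate noise), and a cognate
  pair must render as mutually aligned views; transporting the axis is exact
  for ideally opposed patches and degrades only with the tilt between planes;
- the epitope image is mirrored about the u axis after projection: two facing
  views superimpose only after one reflection.

These choices make the rendered pair invariant under rigid motions of the
whole complex. Rasterisation is analytic (hard-edged circle coverage at pixel
centres, alpha compositing over white) with coordinates quantised to 10⁻⁶ Å
and opacities to 10⁻⁹ before painting, so invariance holds bit-exactly.
Rotations compose by angle addition before a single matrix is applied, so a
360° rotation is exactly the identity and +60° followed by −60° restores the
image bit-exactly.

## Synthetic data

The toy generator emulates the one property of real interfaces the classifier
is meant to exploit: shape and physicochemical complementarity between two
roughly planar, mutually facing residue patches. A matched complex places
8–14 paratope residues (biased toward the aromatic/charged composition of
real paratopes) in an annulus of 1.5–9 Å radius with ≥ 2.8 Å spacing and
0.6 Å out-of-plane scatter, and puts each epitope residue opposite its
partner with 0.4 Å lateral jitter and a per-pair gap of 4–5.5 Å clipped below
the 6 Å contact cutoff, assigning it a fixed chemical complement
(Arg↔Asp, Lys↔Glu, aromatics opposite polar residues). Mismatched mode draws
independent layouts and compositions. Residues carry a C&alpha; plus 0–3
pseudo side-chain atoms whose mean is the intended C&mu;; coordinates are
quantised to the PDB's 3-decimal precision and every complex is serialised to
PDB text and re-read through the public parser, so fixtures exercise the
identical code path as real data.

What the generator does **not** emulate: real antibody geometry (CDR loops,
backbone connectivity, packing), residue-contact energetics, experimental
noise (missing atoms, alternate conformations beyond what tests construct
explicitly), and the weak, partial complementarity of real interfaces.
Passing the synthetic discrimination test therefore shows that the pipeline
is implemented correctly end to end and that the model can learn
shape-and-colour complementarity from rendered pairs; it says nothing about
accuracy on experimentally solved complexes, which requires training on a
curated structural corpus.

## Problem sizes and schedules

The synthetic benchmark uses 100 matched complexes (100 positives + 300
negatives, 64×64 images), a single subtrain/validation fold, and a desk-scale
training schedule: the same optimiser with at most 25 epochs, early-stop
patience 5, plateau patience 3, and an absolute convergence stop once the
validation BCE falls below 5×10⁻³. A few hundred clearly separable samples
converge within a couple of dozen epochs, so the longer default schedule
(200 epochs, patience 10/5) sized for corpus-scale training is unnecessary
here. Screening self-retrieval uses 50-entry libraries and 10 seeded
repeats; pose rescoring uses 10 complexes with one near-native pose and 10
decoys each (in-plane antigen rotations of ≥ 60° plus the cognate).

## Numerical choices and edge cases

- Sequence identity for redundancy removal: global alignment with match 1,
  mismatch 0, gap 0 (i.e. maximal match count), identity = matches divided by
  the longer sequence length; clusters form greedily longest-antigen-first,
  which makes the kept set invariant under input permutation.
- Altlocs keep the highest-occupancy conformer, ties toward altloc 'A'.
  Residues with no resolved side-chain atoms fall back to C&alpha;; residues
  with no C&alpha; either are skipped. UNK residues are parsed (code 'X'),
  reported, and cause discard at curation.
- Degenerate patches (fewer than 3 points, or collinear: second PCA
  eigenvalue below 10⁻⁹ of the first) raise a frame error; complexes with no
  residue pair within the cutoff raise a no-interface error, which pose
  rescoring maps to score 0 and a worst-tied rank.
- BCE clips scores to [10⁻⁷, 1−10⁻⁷]; training aborts on a non-finite loss.
- Pose ranks sort by descending score with ties broken by pose id; screening
  ranks by the maximum over the 12 rotation scores (mean available via
  config) and applies the binder rule at the 0°, +30° and −30° entries with
  threshold &tau; = 0.5 by default.
- The first residual block reconciles 6 input channels with 32 block channels
  through a 1×1 convolution on the skip path; pooling happens once, after the
  two-block stack, with parallel max and average windows — the only
  arrangement consistent with a (H/4)×(W/4)×64 flattened feature vector.

## Known limitations

- The per-patch 2D projection loses depth structure beyond the single
  distance-to-plane scalar; strongly curved interfaces are distorted.
- CDR identification is geometric (interface residues) unless an explicit
  CDR annotation is supplied; borderline 40 Å filtering may differ from
  numbering-based CDR definitions.
- mmCIF input, hydrogens, structure repair, nanobodies/scFv and hard-negative
  mining are out of scope.
- Training at corpus scale (thousands of complexes, 100×100 images, ten
  folds) is computationally feasible in this implementation but slow on a
  single CPU; the NumPy backend is written for correctness and transparency
  first.
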