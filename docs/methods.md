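# Methods

## The problem

Microbial (type I) rhodopsins absorb light through a retinal chromophore
bound via a Schiff base to a conserved lysine.  The wavelength of peak
absorption (λmax, in nm) is tuned by the electrostatic and steric
environment that the ~24 residues lining the binding pocket impose on the
chromophore.  `rhopocket` regresses λmax from a predicted 3D structure of
the opsin: it extracts the pocket, describes each heavy atom by
physicochemical features, represents the pocket as a sparse atom graph and
applies a four-layer graph convolution/attention network with a mean
readout.  Because the structure enters only through interatomic distances,
predictions are invariant under rigid motions of the input by
construction.

Wavelength is inversely proportional to photon energy (E = hc/λ,
hc = 1239.84198 eV·nm).  Energies in eV are linear in the physically
meaningful quantity, so all error metrics are reported in both units;
training can target either (default nm, matching the L1 loss definition).

## Pipeline

1. **Structure input** (`structure`).  PDB models with per-atom pLDDT in
   the B-factor column.  Only heavy atoms of the 20 standard residues in
   the first chain are kept (altloc blank/'A'); HETATM groups, including
   retinal, are skipped — the chromophore is treated as implicit in the
   pocket geometry.  When several ranked models per sequence are given,
   the one with the highest mean pLDDT is used (the standard monomer
   ranking of prediction pipelines).

2. **Pocket location** (`pocket`).  The query sequence is globally
   aligned (Needleman–Wunsch, BLOSUM62, affine gaps open 10 / extend 0.5 —
   EMBOSS defaults) to an annotated reference; the 24 reference pocket
   positions are transferred across alignment columns.  A deterministic
   pairwise alignment replaces a family MSA here because it is
   self-contained and testable against an exhaustive-enumeration oracle;
   a user-supplied MSA (Clustal or aligned FASTA) containing reference
   and query is accepted as an alternative.  A pocket position aligned to
   a query gap is an error by default (silent truncation would corrupt
   the fixed-size pocket semantics); `allow_partial` downgrades it to a
   warning.  The packaged reference is the canonical bacteriorhodopsin
   sequence with 24 positions approximating the retinal-contact shell
   (including K216); the exact position list is replaceable
   configuration, not a claim of authority.

3. **Featurization** (`features`).  36 values per heavy atom:
   * 18 residue-level descriptors of the parent amino acid: acid/base
     3-way one-hot; neutral 5-class one-hot (aliphatic, aromatic, polar
     neutral, cysteine, proline/glycine; charged residues all-zero);
     neutral 2-class polar flag; Kyte–Doolittle hydropathy plus a
     hydrophobic indicator; isoelectric point; side-chain log(P)
     (Fauchère–Pliška); residue molecular weight; organic and inorganic
     value (carbon-count / polar-heteroatom proxies); Grantham polarity;
     Zamyatnin residue volume.  Values ship as a 20×18 TSV and are
     user-replaceable; the exact choice of descriptors matters less than
     their constancy within a residue.
   * 15-way one-hot of the tripos 5.2 atom type, assigned from a curated
     residue×atom lookup (backbone handled by wildcard rows).  Types
     unused by standard residues (N.3, N.2, "other") are constant zero
     and removed by normalization.
   * CHARMM22 heavy-atom partial charge (curated table; hydrogen charges
     are *not* folded into heavy atoms, keeping the table consistent
     with heavy-atom-only structures), per-atom solvent-accessible
     surface area, and the van der Waals radius (C 1.70, N 1.55, O 1.52,
     S 1.80 Å — one table serves both the radius feature and SASA).

   **SASA** is Shrake–Rupley with a 1.4 Å probe and 960 deterministic
   golden-spiral quadrature points per atom, computed on the full-length
   structure before pocket extraction (burial context matters) and then
   subset to pocket atoms.  Coordinates are first moved into a canonical
   molecular frame (centroid origin, PCA axes, signs fixed by the
   largest-magnitude projection) so the quadrature — and therefore every
   downstream prediction — is rigid-motion invariant to floating-point
   precision rather than to quadrature error.  The frame is unstable
   only for degenerate point clouds (exactly symmetric structures),
   which real and synthetic pockets are not.

   Feature columns constant across the training pool (variance < 1e-12)
   are removed; the rest are z-scored with train-set statistics only.

4. **Graph** (`graphs`).  Nodes are pocket heavy atoms; a pair of
   directed edges joins every atom pair strictly closer than 2 Å, which
   captures covalent bonds and leaves the graph sparse.  Disulfide
   bridges (~2.05 Å) fall outside the cutoff by design fidelity to the
   threshold.  The edge weight is 1/d (strictly decreasing, bounded on
   chemical bond lengths); the weight function is a single swappable
   component.  Isolated atoms are kept — they still contribute through
   the readout.  Non-covalent relationships are carried by message
   passing through intermediate nodes, not by explicit long-range edges.

## Network

GCN → GAT → GAT → GCN with hidden widths 32/32/32 (configurable),
single-head attention, no self-loops anywhere.

* **GCN layer**: H′ᵢ = Σ_{j∈N(i)} (w_ij/√(d̃ᵢd̃ⱼ)) (Hⱼ W) + b with weighted
  degrees d̃ᵢ = Σⱼ w_ij.  The 1/d edge weights enter the symmetric
  normalization so the distance information is not discarded in the
  convolution layers.
* **GAT layer**: logit e_ij = LeakyReLU₀.₂(a_dst·(Hᵢ W) + a_src·(Hⱼ W) +
  a_e·w_ij), softmax over each node's in-neighbourhood, single head.
  The edge weight reaches the attention as a learned scalar contribution
  to the logit.
* Batch normalization (momentum 0.1, ε 1e-5) + ELU (α 1) follow the
  first three layers.  The final scalar layer feeds the mean readout
  directly, without BN/ELU: an ELU after the last layer would bound the
  standardized output below −1 and make labels more than one standard
  deviation below the mean unreachable.  Whether the last layer carries
  its own normalization is genuinely open in this architecture family;
  both variants are implemented (`final_norm`), linear readout is the
  default.
* Mean aggregation over each graph's nodes gives one scalar; a frozen
  affine head (mean/std of the training labels) maps it to the target
  unit.  This target standardization changes only the parameterization,
  not the loss: L1 in label units is proportional to L1 in standardized
  units.  Without it, the stated optimizer budget cannot move a
  zero-initialized head to the ~550 nm label scale.

All tensor math runs on a small reverse-mode autodiff engine written for
this package (`autodiff`); the layers are verified against dense matrix
oracles and analytic gradients against central finite differences
(relative tolerance 1e-4).

## Training protocol

Adam (β₁ 0.9, β₂ 0.999, ε 1e-8), learning rate 1e-4, 1000 epochs, L2
weight decay 1e-5 added to the gradient, plus an L1 penalty α = 1e-4 on
the *mean* absolute value of all trainable parameters (normalizing by the
parameter count keeps α comparable across widths).  Loss: mean absolute
error in the training unit.  Mini-batches of 32 with seeded reshuffling
each epoch; full-batch mode (batch_size ≥ n) is used where bit-exact
determinism or minimum gradient noise matters.  All randomness flows from
explicit integer seeds; identical seeds give bit-identical histories.

**Splitting.**  The unit of train/test assignment is the wild-type group:
a parent sequence plus all its mutants.  Ten groups (and every record in
them) form the test set; because most mutants differ by one or two
substitutions, record-level splitting would leak near-duplicates.  The
two-sample Kolmogorov–Smirnov statistic between train and test label
distributions is reported as a similarity diagnostic (statistic only).

**Metrics.**  Per-record absolute errors; prediction and label are each
converted nm↔eV record-wise before the error in the other unit is taken;
median, mean and standard deviation are reported in both units.

## Ablation protocols

Feature ablations operate on the 14 named feature groups of the schema
(acid base property, partial atom charge, neutral 5-class, hydropathy,
isoelectric point, log(P), tripos atom type, molecular weight,
organic/inorganic value, polarity index, neutral 2-class, atomic radius,
surface area, atomic volume): *drop-one* removes a group's columns before
normalization and retrains; *keep-one* retains only that group;
*no-features* trains on a single constant node feature, so the prediction
rests on graph structure alone.  The attention ablation swaps both GAT
layers for GCN layers of the same widths and reuses the identical
training pipeline; the parameter counts differ exactly by the attention
vectors (2·width + 1 per layer).

## Synthetic data

The fixture generator emulates the geometric and bookkeeping properties
of predicted pocket structures, not their chemistry:

* residues are built from idealized heavy-atom tree templates (uniform
  1.5 Å bonds, tetrahedral branching, anti-extended chains) and placed on
  a wide helix, guaranteeing every covalent neighbour pair lies in
  1.2–1.6 Å and every non-bonded pair beyond 2 Å — so the 2 Å edge rule
  recovers exactly the covalent topology and no atom is isolated;
* aromatic rings are left open (tree topology), residues are far enough
  apart that no inter-residue edges form, and B-factors carry synthetic
  pLDDT values in 60–95;
* mutant families differ from their parent by 1–2 substitutions with the
  parent's coordinates untouched elsewhere, mirroring the mutant-rich
  composition of experimental λmax datasets;
* labels are planted as a clipped affine function of the per-graph mean
  node feature vector plus Gaussian noise (default σ = 2 nm), giving a
  known optimum for recovery tests; a variant plants labels from the gap
  between a softmax-weighted (β = 6) and the plain mean of each node's
  neighbour partial charges — a quantity a single attention layer can
  express but a plain convolution cannot — for the attention ablation
  experiment.

Passing on these fixtures demonstrates that the pipeline, optimization
and invariances behave as specified; it does not certify predictive
accuracy on real rhodopsins, whose labels are not an affine function of
pooled features and whose structures contain ring closures, disulfides
and contact (not just covalent) geometry.

## Study conditions for the packaged experiments

Chosen once for a single CPU and documented here as the package's own
problem sizes: overfit capacity — 10 pockets of 24 residues, 1000 epochs
(published recipe), expecting train median ≪ 2 nm; parameter recovery —
200 train / 50 test pockets of 8 residues, σ = 2 nm, full-batch, 600
epochs, comparing test MAE to the L1-optimal floor σ·√(2/π); attention
ablation — 5 paired seeds, 40 train / 20 test pockets of 6 residues, 250
epochs full-batch; end-to-end benchmark — 20 wild-type groups × 3
mutants of 8-residue pockets, 5 groups held out, 400 epochs.

## Numerical choices and edge cases

* Distances in double precision; cutoff comparison is strict (< 2 Å).
* Softmax logits are shifted by the per-neighbourhood maximum (detached)
  before exponentiation.
* Batch norm uses biased variance for normalization and unbiased for the
  running estimate; train mode with a single node row is an error.
* |x| uses the subgradient 0 at x = 0.
* Constant-label training sets fall back to unit label scale.
* Empty edge sets are legal everywhere: layers then reduce to their bias
  (isolated nodes likewise), and predictions remain defined.
* Zero-variance alignment ties are broken deterministically by the
  alignment engine; scores (the tested contract) are tie-independent.

## Known limitations

* The packaged residue-descriptor, charge and atom-type tables are
  curated approximations shipped as configuration; swap in laboratory
  tables via `FeatureTables.load(...)` for production use.
* The pairwise-alignment position transfer assumes the query is homologous
  to the reference; remote sequences should come with a curated MSA.
* The canonical SASA frame can rotate discontinuously for near-degenerate
  structures; per-atom areas remain correct to quadrature accuracy, only
  their last-digit reproducibility across conformers is affected.
* Hidden widths default to 32/32/32; no claim is made that this
  reproduces any particular published parameter count, which cannot be
  inverted to unique widths.
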