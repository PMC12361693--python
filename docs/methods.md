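# Methods

This note documents the models, numerical choices and limitations behind
`opsinsol`. It describes what each stage computes and why the defaults
are what they are; every empirical number quoted here is one the test
suite or `scripts/acceptance.py` computes at run time.

## QTY redesign

The substitution map is fixed: L→Q, I→T, V→T, F→Y, applied only inside
annotated transmembrane (TM) segments. Everything else — including the
hydrophobic A, M and W inside TM helices — is left untouched. Segments
are 1-based inclusive, matching the UniProt TRANSMEM convention; SS3
strings (H/E/C) are an alternative annotation source, with maximal H-runs
of at least `min_helix_len = 5` residues treated as helices (shorter runs
are almost always prediction noise, and 5 is well below any real TM
helix length of ~20). Non-standard residues (B, Z, X, U, O) are rejected
outright: their masses and pK values are undefined, so silently passing
them would corrupt the downstream characteristics.

Truncating a sequence to match an experimental construct (as one does
for ChR2-style constructs) is deliberately the caller's job; the design
operator works on whatever sequence it receives.

The four substitutions never touch an ionizable side chain, which gives
the module its two strongest invariants: the counts of D, E, K, R and H
are conserved exactly, and the only pI-relevant change is the weakly
acidic phenol of each gained tyrosine (pK ≈ 10). A design with no F→Y
events therefore has an identically zero pI shift.

## Sequence characteristics

**Molecular weight** uses average free-amino-acid masses with one water
(18.02 Da) condensed per peptide bond. The table fixes the QTY-relevant
masses at L/I 131.17, V 117.15, T 119.12, Q 146.14, F 165.19 and
Y 181.19 Da, so the per-substitution deltas are +14.97, −12.05, +1.97
and +16.00 Da; the full-sequence mass difference and the sum of ledger
deltas agree to 1e−9 by construction, and the test suite asserts it.

**Isoelectric point** comes from the Henderson–Hasselbalch net charge

    Z(pH) = Σ_basic 1/(1+10^(pH−pK)) − Σ_acidic 1/(1+10^(pK−pH))

over the N-terminus, C-terminus, and the side chains of D, E, C, Y
(acidic) and H, K, R (basic). Z is strictly decreasing in pH, so the
root is unique; it is found by bisection on (0, 14) to 1e−4 pH. The
default pK set is the Bjellqvist set (the common pI-server convention);
published pI values rarely state their pK set, so the set is
configurable and agreement with external pI values is treated as
tolerance-bearing (±0.1–0.2 pH), not exact. Cysteines are treated as
reduced and ionizable; there is no disulfide or PTM handling.

**Variation rates** are percentages of substituted positions over the
whole chain ("overall") or over the TM residue count ("tm"), reported to
2 decimals as characteristic tables conventionally print them.

## Superposition

Residue pairing is a global Needleman–Wunsch alignment (match +1,
mismatch 0, gap −1) in which the QTY-equivalent pairs L:Q, I:T, V:T and
F:Y score as matches — so a native chain pairs unambiguously with its
redesigned variant, and a missing helix in one model simply drops out of
the pairing. The alignment itself is delegated to Biopython's
`PairwiseAligner` with a custom substitution matrix; tests pin the exact
alignments the scoring implies on small cases.

The rigid fit is the Kabsch SVD solution on paired Cα atoms, with the
reflection branch corrected so the rotation is always proper. Cα-only
fitting is deliberate: side chains differ between native and QTY models
by construction. Refinement mimics "super"-style tools: after each fit,
pairs whose deviation exceeds `reject_sd = 2.0` standard deviations are
dropped and the fit repeated, up to `max_cycles = 5`, stopping early at
convergence or when fewer than 3 pairs would remain. With Gaussian
coordinate noise a 2-SD cutoff keeps rejecting the tail on every cycle —
that is the intended behaviour of such tools, which is why the cycle cap
exists. Because the exact parameterization of any given tool's rejection
loop is unknowable from outside, RMSDs from other software are matched
with a stated tolerance (±0.05 Å), never bit-exactly.

Pairwise RMSD matrices are symmetrized by averaging the (i,j) and (j,i)
fits, which can differ marginally through the rejection loop. Matrix
comparison (native set vs variant set) reports the Pearson correlation
and mean absolute difference over strict upper triangles plus a per-pair
table sorted by |difference|. Terminal trimming is explicit and
user-supplied — no automatic "unstructured loop" detection — and
preserves residue numbering.

Degenerate fits (< 3 pairs, collinear point sets) are errors rather than
best-effort answers, and an exactly-zero-deviation fit short-circuits
the rejection loop (deviations below ~1e−8 Å are floating-point dust,
not outliers).

## Hydrophobic surface

SASA is Shrake–Rupley: each atom's van-der-Waals sphere (Bondi-style
radii, C 1.70 / N 1.55 / O 1.52 / S 1.80 Å) is expanded by the probe
radius (1.4 Å, a water molecule) and sampled with a 960-point Fibonacci
lattice; the accessible fraction is the share of points inside no
neighbour's expanded sphere. 960 points put the isolated-sphere error
well under 0.5% and the total-area change on doubling the point count
under 1%. Hydrogens are excluded by default so predicted (heavy-atom)
models and experimental structures are treated alike.

One subtlety: a lattice fixed in the laboratory frame makes SASA depend
slightly (≲0.5%) on molecular orientation. The lattice is therefore
oriented in a molecule-fixed frame built from the coordinate principal
axes, with axis signs fixed by the third moment of the projections (a
rotation-covariant choice), making SASA exactly invariant under rigid
motion. Structures with a degenerate inertia spectrum fall back to the
laboratory frame.

The hydrophobic surface fraction divides the SASA of the nonpolar
residues {L, I, V, F, A, M, W} by the total protein SASA (hetero groups
excluded). A Kyte–Doolittle-threshold alternative set is available. The
fraction is a *proxy* for rendered hydrophobicity patches: rendering
tools draw potential fields, not residue sums, so the package asserts
only the direction of the native→QTY change, not a magnitude. The
"renaming mode" (`qty_rename`) substitutes residue identities while
freezing geometry; it exists for controlled tests that isolate the
chemical effect from conformational change, and is not a claim about
real variant structures, which should be evaluated on their own models.

## Trajectory analytics

**Isomerization** is modelled as a rigid Rodrigues rotation of the
moving moiety (C13–C15 with attached hydrogens/methyls) about the axis
through C11 along C11→C12, by 180°. The operator is an involution and
preserves all intra-moving-set distances to 1e−9; the C10–C11–C12–C13
dihedral flips by exactly 180°. Connectivity of the moving set is the
caller's responsibility (the package has no bond table).

**RMSD series** fit every frame to a reference on a fit selection
(typically Cα) and measure over a separate selection, enabling the
usual complex / helix / pocket / ligand split. **Running averages** are
centred moving means with the window expressed in time units (default
1 ns) and converted through the frame spacing; edges truncate rather
than pad, so the output length equals the input length. **RMSF** fits
frames to the mean structure (two passes, starting from the first
frame), computes per-atom fluctuation, and averages atoms within a
residue; a `superpose=False` escape hatch supports pre-aligned
trajectories and exact toy oracles. **Radius of gyration** is the
standard mass-weighted form.

**Pocket definition** takes every non-water residue with a heavy atom
within 5.0 Å of any ligand heavy atom in a reference frame. Published
binding-pocket figures rarely enumerate their residue sets, so the
derivation cutoff is recorded inside the `PocketDefinition` for
provenance. **Hydrogen bonds** use donor–acceptor distance ≤ 3.5 Å and
H–D–A angle ≤ 30°, the common geometric convention consistent with a
≤3.5 Å display criterion; a donor–acceptor pair counts once even when
two hydrogens qualify, and donors without resolvable hydrogens are
skipped with a warning rather than silently miscounted. **Pocket
waters** are water oxygens within 3.5 Å of any pocket heavy atom,
boundary inclusive.

**Interaction energy** is the short-range pair sum over two disjoint
groups within a 1.2 nm cutoff: Coulomb `f·qᵢqⱼ/r` with
f = 138.935458 kJ·mol⁻¹·nm·e⁻², and Lennard-Jones
`4ε[(σ/r)¹² − (σ/r)⁶]` under Lorentz–Berthelot combination (geometric
available). There is no PME or long-range correction by design: the
quantity mirrors what MD engines report as "short-range" energies, which
is a simulation diagnostic rather than a physical binding free energy.
Coordinates are Å and converted to nm internally; parameters arrive as a
plain TSV (atom index, charge e, σ nm, ε kJ/mol).

The **signed pseudo-logarithm** used for displaying wide-range energies
is `sign(x)·log₁₀(1+|x|/s)` with scale s = 1 kJ/mol. Base and scale are
a documented package choice — the transform's name is standard but its
constants rarely are — and both are arguments.

Trajectories are consumed, never produced: multi-MODEL PDB is read
natively, and any binary format can be adapted by constructing a
`Trajectory` (topology, strictly increasing times, frame coordinates)
from an external reader. By convention the isomerization event sits at
t = 0 with pre-event frames at negative times.

## Synthetic study conditions

The generators define the conditions everything is tested under:

- **7-TM sequences**: seven 23-residue helices with 24-residue
  connecting/terminal stretches (353 residues, ~46% TM coverage — a
  typical opsin once its soluble termini are counted). TM composition is
  ~46% L/I/V/F plus A/G/T/S-rich filler; loops are polar and contain no
  L/I/V/F, so every substitution is confined to TM segments and the
  planted count is exact. The implied TM variation (~46%) and overall
  variation (~21%) sit inside the ranges observed for real opsin
  redesigns.
- **Bundles**: ideal helices (rise 1.5 Å, twist 100°, radius 2.3 Å),
  antiparallel on an 8.5 Å circle, loops interpolated linearly. Cα-only.
- **Structure pairs**: rigid motion plus i.i.d. per-axis Gaussian noise
  of σ = 0.5 Å; the fitted RMSD closed form is σ√3.
- **Harmonic trajectories**: 2000 frames of per-residue Gaussian
  scatter; planted RMSF is σ√3 per residue.
- **Pocket scenes**: a 3-atom ligand ringed by four residues at 4 Å,
  waters planted at 3 Å (inside) or 50 Å (outside), and
  donor–H···acceptor triplets at 2.8 Å/0° planted 30 Å away and 10 Å
  apart so all non-planted pairs miss the criteria by ≥1 Å or ≥30°.

What they do **not** emulate: real side chains and packing (bundles are
Cα-only, so absolute SASA values are not protein-like), correlated
protein motions (harmonic scatter has no covariance structure, so only
amplitude recovery is tested, not dynamics), force-field ensembles,
membranes or solvent. Passing tests therefore demonstrate that the
*operators* are correct against planted truth and closed forms — not
that any particular biological conclusion holds for real trajectories.

Every generator takes an explicit integer seed, uses its own
`numpy` Generator (no global state), and is byte-deterministic.

## Orchestration

`RunConfig` carries every stage parameter with the defaults above,
round-trips through YAML, and is hashed (output paths and log level
excluded) into the provenance header of every output file together with
the seed. Identical configs and seeds reproduce outputs byte for byte.
Logging goes to stderr; results go to TSV/JSON files only.

`scripts/acceptance.py` re-runs the stages at the sizes quoted there —
12 redesigns, 589-atom bundles for the noise-pair fit, 2000-frame RMSF
recovery, 960-point sphere check — chosen so a complete run takes a few
seconds while keeping sampling error comfortably inside the closed-form
tolerances.

## Known limitations

- Structure handling is single-conformer, heavy-atom, fixed-column PDB;
  no mmCIF, no altloc handling (last record wins), no bond topology.
- The rejection loop approximates "super"-class tools; exact RMSD
  reproduction against any specific tool version is out of scope, and
  comparisons carry the ±0.05 Å tolerance stated above.
- pI values depend on the pK set; absolute agreement with external
  calculators is only as good as the shared convention.
- H-bond detection is geometric only (no energy criterion) and requires
  explicit hydrogens on donors.
- Reference-data checks (real opsin sequences with TRANSMEM annotations,
  and deposited native/QTY model pairs) require those files to be staged
  locally under `data/`; the package ships no third-party data.
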