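# Methods

This note records the models, conventions and numerical choices behind
`minimask`, and what its synthetic tests do and do not establish about real
design campaigns.

## Structural model and IO

Structures are chain → residue → atom hierarchies with residues renumbered
1-based and sequential per chain; author numbering survives only as
metadata. All cross-model bookkeeping (coverage mapping, Cα pairing,
confidence alignment) is positional, which matches how structure-prediction
outputs are organized and avoids any dependence on author numbering.
Insertion codes are rejected outright: silently renumbering them would
corrupt the index-based mapping between models of the same sequence.
Alternate locations resolve to the highest-occupancy atom; hydrogens are
kept when present but excluded from the default contact atom set.

Confidence data (pLDDT vector + PAE matrix) are aligned to a structure *by
order* via an explicit residue map, never by numbering. Three JSON dialects
are read into one canonical container; the triplet-list dialect must carry a
pLDDT vector somewhere in the file because the container requires both
quantities.

## Triage metrics

- **Contacts** use heavy atoms by default. Steric occlusion is a side-chain
  phenomenon, so Cα-only contacts undercount the blocked set; a `ca` mode is
  kept for sensitivity analysis. Contact queries run on KD-trees; the test
  suite pins them against O(N²) all-pairs scans.
- **Coverage** takes its denominator (interface set) from the
  binder–receptor model and its numerator (blocked subset) from the
  binder–mask model, mapped by residue index. An empty interface yields
  coverage 0 with a warning flag rather than an error, so one degenerate
  design cannot abort a batch. Note the ratio is *not* monotone in the
  cutoff: widening the cutoff grows the interface denominator as well as the
  blocked set, and the fraction can drop. The contact sets themselves are
  monotone, and that is the property the tests assert.
- **Interchain PAE** is the unweighted per-entry mean over both off-diagonal
  blocks. Aggregation conventions differ between tools; the per-entry mean
  is the least surprising and is symmetric in the two chains by
  construction.
- **Orientation** compares terminal Cα distances; exact ties (within
  1e-6 Å) resolve to "not C-terminal", the conservative call for downstream
  cloning order.
- **Superposition** is SVD Kabsch with reflection correction (proper
  rotation, det +1) and optional weights; degenerate (rank < 2) point sets
  are rejected. An independent quaternion-eigenvalue implementation lives in
  the test suite as the oracle.

### Filter cascade

Gates and strictness: complex pLDDT > 90 and mask pLDDT > 80 (strict
inequalities), interchain PAE ≤ 8 Å (inclusive, so a design printing exactly
the threshold passes), coverage ≥ 0.60 (default; campaigns tighten toward
0.80 to size shortlists), C-terminal orientation required by default, and —
when a generative backbone is available — Cα RMSD < 1.5 Å. Survivors are
ranked by (coverage desc, interchain PAE asc, complex pLDDT desc, design id);
the ranking is a declared convention of this package, chosen so the most
completely blocked, most confidently packed designs surface first, and the
id tie-break makes the order total and deterministic.

The diverse shortlist (default k = 5) is greedy max-min selection seeded
with the top-ranked survivor; distance = (1 − normalized global sequence
identity) + 0.2·|Δlength|/max length. Identity comes from a global alignment
with unit match, zero mismatch and linear gap −1, normalized by the longer
length. The 0.2 length weight is a tunable convention that keeps length
diversity from dominating composition diversity for 15–25 residue masks.
Selections are returned in rank order, which makes re-selection idempotent.

## Constructs and masses

Default segment order N→C: His-tag (`MHHHHHH`) — binder — GS linker
(`GSGS`) — MMP2/9 motif (`GPLGLAG`, scissile bond PLG|LAG) — mask. Tag,
linker and motif sequences are configurable; the canonical PLG↓LAG substrate
is the default because exact campaign motifs vary. Proteolysis is modeled as
hydrolysis: each product is a free peptide, so the two products jointly gain
exactly one water relative to the parent — the conservation law the tests
check to ±0.01 Da. Photocleavage is pure mass/sequence bookkeeping: the
construct carries an o-nitrophenyl (NP) unit as a named modification, and on
photolysis each product retains the fragment mass registered in the
modification table. The built-in NP and maleimide entries are computed from
nominal element compositions and are meant to be overridden with the
compositions of the linker actually synthesized.

Masses default to the average scale because LC–MS deconvolution of ~10 kDa
proteins reports average mass; monoisotopic is available throughout. The
test oracle is an independent residue-composition table built on CIAAW
atomic weights, which agrees with the implementation to well under 0.01 Da
for mask-scale (≤ 30 residue) peptides.

## Helix tools

Helical wheels use the standard 100°/residue twist; hydrophobicity is the
Eisenberg consensus scale (the standard for hydrophobic moments; other
scales can be supplied). Moments are normalized per residue so 15- and
25-residue masks are comparable. Ideal helices (rise 1.5 Å, twist 100°,
radius 2.3 Å) satisfy the closed form d(Cα,Cα) = √(rise² + (2r·sin(twist/2))²)
≈ 3.83 Å exactly by construction and serve as the geometric primitive for
fixtures.

## Kinetics and potency

Only the 1:1 Langmuir model is implemented — the analyses this package
supports use monovalent mask–binder interactions, and mass-transport or
bivalent corrections would add parameters the desk-scale data cannot
constrain. Fitting is global: kon, koff and Rmax are shared across all
concentrations of a series (≥3 concentrations spanning ≥10-fold), which is
standard for BLI and far better conditioned than per-curve averaging. KD is
always reported as koff/kon, the kinetic definition. Initialization follows
the observed-rate relation k_obs = kon·C + koff: per-curve k_obs comes from
a single-exponential least-squares fit of the association phase (a
log-linear transform was tried and rejected — its residuals diverge on noisy
near-plateau points and can send the global fit to a spurious minimum), and
a linear regression of k_obs on concentration seeds kon and koff.
Non-convergence and unidentifiable inputs (all-zero curves, flat
dose-response) raise errors instead of returning numbers.

4PL dose-response fits initialize IC50 from a 12-point log-spaced grid over
the observed concentration range and keep the best converged fit. Fold
shifts IC50(masked)/IC50(unmasked) are binned at inclusive lower edges
[2, 10, 100): published efficiency bins ("over 100-fold", "10–20-fold",
"2–5-fold") are open-ended, and software needs a complete partition, so
exactly 100-fold classifies as ≥100-fold.

## Synthetic fixtures

The generator emulates the study system's geometry, not its physics: a
three-helix-bundle binder built from ideal Cα-trace helices, a flat
two-helix "receptor" slab placed 8 Å from the interface helix to induce a
periodic, realistic interface set, and a masking helix slid along the
interface groove. Coverage is planted by the sliding window (granularity one
interface residue; unrealizable targets round to the nearest achievable),
orientation by which binder terminus the mask's linker-attachment residue
approaches (placed 6 Å out, beyond the contact cutoff, so it never perturbs
the blocked set). Confidence files carry requested block means with seeded
Gaussian jitter (0.8 by default), with planted condition levels placed well
away from the gates (e.g. complex pLDDT 93 vs 86 around the >90 gate) so the
intended flag survives the jitter. Truth is nevertheless *measured* from the
emitted coordinates and arrays by the module's own double-loop verifier —
deliberately independent of the KD-tree metrics — so every fixture is
self-validating.

What passing fixture tests shows: the metrics, cascade and selection are
implemented exactly as specified, at full numeric fidelity, under complete
ground-truth control. What it does not show: performance on real predicted
complexes, where side-chain packing, loop geometry, correlated confidence
errors and borderline metric values near the thresholds all occur. The
suite's condition levels deliberately avoid the near-threshold regime
because planted labels must be unambiguous.

## Problem sizes and determinism

Default test/acceptance scales: a 40-design fixture suite (binder 42
residues, receptor 28, masks 15–25), 100-point superposition batches,
200-construct mass batches, six-concentration kinetic series at 0.2 s
sampling. These sizes make every oracle comparison exact or tight while the
whole suite runs in seconds on one core. All randomness flows from explicit
seeds (numpy `default_rng`); the pipeline's reports contain no timestamps,
so a rerun with the same seed and config is byte-identical.

## Known limitations

- Interface definitions are distance-based only; no solvent-accessibility
  or energy terms.
- Coverage granularity in fixtures is one interface residue; arbitrary
  fractions are rounded.
- The NP photoproduct masses are nominal defaults, not a model of the
  photochemistry.
- NMR multi-model files, nucleic acids and ligand chemistry are out of
  scope; one model per file is read.
- The 1:1 kinetic model ignores mass transport, avidity and rebinding.
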