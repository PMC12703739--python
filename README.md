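# minimask

Desk-scale computational toolkit for **masked de novo miniprotein binders**:
small (~7 kDa) designed binders — typically three-helix bundles — whose
receptor-binding interface is sterically occluded by a short (15–25 residue)
designed masking helix tethered through a cleavable linker. Protease (MMP2/9)
or 365 nm light severs the linker at the disease site and restores binding.

`minimask` implements the *in-silico* side of that workflow for people who
design and characterize such constructs:

- **Triage** of candidate mask designs from predicted complex structures and
  confidence data: per-design metrics, the filter cascade, ranking, and a
  sequence-diverse shortlist.
- **Construct assembly** and in-silico cleavage with exact mass bookkeeping
  (average and monoisotopic), for checking LC–MS deconvolution masses.
- **Biophysical analyses**: interface contact maps, helical-wheel
  amphipathicity, 1:1 Langmuir kinetics fitting of BLI sensorgrams, and IC50
  fold-shift classification of masking efficiency.
- A **synthetic fixture generator** that emits complete design bundles
  (structures + confidence + planted ground truth) so the entire pipeline is
  testable without any external downloads.

## The metrics and models

For a binder chain *b*, mask *m* and receptor *r* (predicted structures, with
per-residue pLDDT and pairwise PAE):

- **Interface residues**: residue *i* of *b* is at the interface iff its
  minimum heavy-atom distance to *r* is ≤ 5 Å (configurable cutoff).
- **Mask coverage**: `|{i ∈ interface(b,r) : dist(i, m) ≤ 5 Å}| / |interface(b,r)|`
  — the fraction of receptor-contacting binder residues sterically blocked by
  the mask.
- **Confidence gates**: complex pLDDT > 90, mask pLDDT > 80 (strict), mean
  interchain PAE ≤ 8 Å over both off-diagonal blocks (inclusive).
- **Orientation**: a design is C-terminal iff the mask N-terminal Cα is
  closer to the binder C-terminal Cα than the opposite pairing.
- **Backbone agreement**: Kabsch (SVD) superposed Cα RMSD between the
  generative backbone and the predicted model, gate < 1.5 Å.
- **Kinetics**: 1:1 Langmuir, `R(t) = Rmax·C/(C+KD)·(1−e^{−(kon·C+koff)t})`
  in association and exponential `e^{−koff·t}` decay in dissociation; global
  least squares shares kon, koff, Rmax across concentrations and reports
  KD = koff/kon.
- **Potency**: four-parameter logistic (4PL) IC50 fits; masking efficiency =
  IC50(masked)/IC50(unmasked), binned at ≥100-, 10–100-, 2–10-, <2-fold.

## Worked example

Generate a small synthetic suite and triage it:

```bash
minimask make-fixtures --n 8 --seed 1 --out designs
minimask triage --designs designs --select 3 --out report
```

```
INFO thresholds: complex pLDDT>90.0 mask pLDDT>80.0 PAE<=8.0 coverage>=0.6 C-terminal=True rmsd<1.5
INFO evaluated 8 -> passed 1 -> selected 1 (0 failed to load)
```

`report/report.tsv` holds one row per design, ranked (coverage desc, PAE asc,
complex pLDDT desc):

```
rank  design_id   passed  complex_plddt  mask_plddt  interchain_pae  coverage  ...
1     design_001  true    93.032579      87.939577   6.002893        0.666667  ...
2     design_003  false   85.970265      82.315116   5.998878        1.000000  ...
```

design_001 clears every gate (pLDDT 93.0 > 90, mask 87.9 > 80, PAE 6.0 ≤ 8,
coverage 0.67 ≥ 0.6, C-terminal) and is shortlisted; design_003 fails on
complex pLDDT (86.0) despite full coverage. Mask sequences of the shortlist
land in `report/selection.fasta`.

Mass bookkeeping and fold shifts:

```bash
$ minimask mass GPLGLAG          # the default MMP2/9-cleavable motif
583.68
$ minimask fold-shift 700e-9 7e-9
{"fold_shift": 100.0, "category": ">=100-fold"}
```

Kinetics: `minimask fit-kinetics --csv sensorgrams.csv` (columns
`time,response,conc,t_assoc_end`) prints kon, koff, KD = koff/kon and Rmax
from a global 1:1 fit.

## Input formats

- **Structures**: PDB or mmCIF (`gemmi`-parsed). Residues are renumbered
  1-based per chain; insertion codes are rejected; altlocs resolve to highest
  occupancy.
- **Confidence JSON**, three dialects:
  - `plain`: `{"plddt": [...], "pae": [[...], ...]}`
  - `af_pkl_json`: `{"plddt": [...], "predicted_aligned_error": [[...], ...]}`
  - `afdb`: 1-based triplet lists `{"residue1": [...], "residue2": [...],
    "distance": [...]}` plus a `"plddt"` vector (in the same dict or as a
    sibling list entry).
- **Pipeline layout**: `designs/binder_receptor.pdb` (shared reference) and
  per design `designs/<id>/binder_mask.pdb` + `confidence.json`
  (+ optional `design_backbone.pdb` for the RMSD gate). Chain roles follow
  the id convention binder=A, mask=M, receptor=R (configurable).

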