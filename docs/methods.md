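# Methods

## Model and assumptions

The screen targets one chemistry: a ligand carrying an aldehyde or ketone
condenses with the ε-amine of a specific lysine (Schiff base, −H2O), and
reductive amination (+H2) fixes the bond. The net mass the cross-link adds
to the carrier peptide is therefore the free-ligand monoisotopic mass minus
one oxygen atom; conversely a measured Δ-mass is converted to the
free-ligand mass by adding 15.994915 Da. Everything else about the ligand
is treated as unknown — the pipeline never assumes a composition, only a
mass.

Detection rests on the observation that fragment ions not containing the
modified residue are invariant under any modification of that residue. For
a peptide of length *n* with the site at position *k*, the invariant ladder
ions are b1..b(k−1) and y1..y(n−k); the screen uses them at charges 1 and 2
plus four precursor-survivor ions (2+/3+, each with and without NH3 loss)
computed per spectrum from that spectrum's own observed precursor — the
only precursor-derived targets computable before the ligand is identified.
For DSVTRQKEPRAPW with k = 7 this yields 24 ladder + 4 survivor = 28
targets.

Assumptions worth stating: centroided DDA data; one reporter peptide and
one modified site per analysis; monoisotopic or near-monoisotopic precursor
picks (M..M+4 handled by the control window and isotope correction); no
chimeric-spectrum deconvolution; no FDR machinery — the screen is a
thresholded shortlist feeding biochemical validation, not a
statistically controlled identification.

## Screening criteria and defaults

| parameter | default | unit | rationale |
|---|---|---|---|
| fragment tolerance | ±0.03 | Da | matches the proteomic search setting used for this data type; ppm mode available |
| precursor tolerance | 5 | ppm | orbitrap-class accuracy |
| min. reporter ions | 10 | count | the shortlisting threshold; 4 = permissive benchmarking mode |
| RT window | ±15 at 120 min | min | scaled by gradient_length/120 |
| control Δ-mass window | −0.05..4.05 | Da | unmodified peptide incl. M+1..M+4 mis-picks |
| candidate Δ-mass threshold | > 40 | Da | excludes small adducts/artifacts |
| cluster tolerance | 50 | ppm of Δ-mass | sized to the propagated precursor error on the Δ-mass (~40–45 ppm for a 220 Da ligand), so spectra of one ligand merge |
| XIC tolerance | 10 | ppm | MS1 extraction width |

Peak assignment is greedy: reporters take their most intense in-tolerance
peak, each peak serves at most one reporter, reporters are processed in
order of best-candidate intensity with ties broken by smaller |m/z error|.
Unknown precursor charges are enumerated over 2–5, each enumeration scored
and flagged independently.

The reference retention time is the intensity-weighted median RT of
control-class hits (weights: summed matched-reporter intensity). When a run
contains no control hits the screen demands an explicit `reference_rt` in
the config rather than guessing.

Manual visual vetting of shortlisted spectra is replaced
by three deterministic scores that annotate but never delete hits:
matched-TIC fraction (≥ 0.1 flags as clean), ladder continuity (longest
consecutive matched b- or y-run, ≥ 3), and cosine similarity of the
reporter-intensity vector to the control consensus (≥ 0.5). The exact
weighting a human eye applies is irrecoverable; these are declared proxies,
and their thresholds are report-time flags only.

Isotope correction: for each hit the integer k ∈ 0..4 minimizing
|Δ-mass − k·1.003355| is reported together with the corrected residual.
This is meaningful for control-window deltas (monoisotopic mis-picks); for
large Δ-masses the raw value is authoritative and the corrected value is
reported alongside, never in place of it.

## Error propagation for annotation

The instrument's relative accuracy applies to the whole cross-linked
precursor (peptide + Δ). Subtracting the exactly known theoretical peptide
mass leaves the entire absolute error on the Δ-mass, so the relative
accuracy of the inferred ligand mass degrades as the ligand shrinks:

    tol_ppm(ligand) = precursor_ppm · (peptide_mass + Δ) / denominator

with the denominator convention selectable between the Δ-mass (default —
reproduces the ~41 ppm value for Ac-6-FP at 5 ppm precursor accuracy) and
the free-ligand mass. Compound matching casts a wide net (200 ppm), ranks
by |ppm error|, and flags matches inside the propagated tolerance clamped
to the practical 30–60 ppm shortlisting band. Matching is strictly local
against a TSV table (a small bundled table of B-vitamin vitamers, pterins
and riboflavin-pathway compounds ships with the package); no network
service is consulted. Note the bundled pyridoxal 5′-phosphate entry
computes to a Δ-mass of 231.03 from its formula C8H10NO6P.

## Quantification

Cross-linking yield = 100 × AUC(modified) / AUC(unmodified), both XICs
summing the M, M+1, M+2 isotope targets at the same charge and integrated
trapezoidally over RT. Yields are nominal ratios: no ionization-efficiency
correction is attempted, matching how such yields are reported for this
chemistry. Free small-molecule XICs would use M only. A zero unmodified AUC
leaves the yield undefined and flagged, never silently zero.

## What the synthetic generator emulates — and what it does not

`synthdata.simulate_run` emulates: Gaussian elution (default apex 42 min,
σ 0.15 min on a 120 min gradient; the modified species elutes 1.5 min from
the unmodified, inside the <2 min proximity observed for this chemistry);
3-isotope MS1 envelopes at a fixed relative abundance so planted AUC ratios
are exact; DDA-style MS2 spectra with full b/y ladders at charges 1–2
(per-ion presence probability = `ladder_completeness`), survivor ions,
log-normal intensities, Gaussian ppm mass error (precursor sd 5/3 ppm so
~99.7% of draws fall inside the 5 ppm accuracy bound; fragment sd 3 ppm), uniform noise
peaks over 100–2000 m/z, precursor charges 2–5 (weighted toward 3+, the
dominant state for this peptide), and optional monoisotopic mis-picks up to
M+4. Decoy spectra are shuffled-sequence b/y ladders at random precursor
masses (900–2200 Da) and random RTs; shuffles conserving either terminal
residue of the reporter peptide are redrawn, since such a "decoy" contains
fragment ions genuinely identical to reporter ions and is a mislabeled
half-target rather than a negative.

Not emulated: chromatographic tailing, dynamic exclusion, co-isolation
interference, intensity-dependent mass error, electronic noise floors, and
real instrument duty cycles. Consequently, passing tests demonstrate the
screen's logic (criteria, windows, counting, quantification algebra) under
controlled error models — they do not certify sensitivity or specificity on
real acquisitions, where spectral quality varies far more.

One measured property of the decoy model deserves note: shuffled decoys
share the reporter peptide's residue composition, so their fragment masses
coincide with reporter targets far more often than uniform chance at
±0.03 Da (~1.2 accidental matches per decoy spectrum), and a neutral-mass
coincidence matches at both charge states at once. At the permissive
4-reporter threshold about 1.2% of decoys survive the full screen; at the
10-reporter default, retention is zero across the test suite's hundred
seeded runs and ~0.01–0.05% in expectation. This is an intrinsic property
of conservative same-composition decoys, not of the matching code.

## Numerical choices

* One embedded constants table (atomic monoisotopic masses to ≥ 6 decimals,
  residue compositions, proton 1.00727646688 Da, isotope spacing
  1.003355 Da, NH3 17.026549 Da); all mass arithmetic flows through it, and
  the test suite checks it against an independent mass table to < 1e−4 Da.
* Masses are carried at full float precision; rounding happens only at
  report time (tables: masses 4 dp, ppm 1 dp, RT 2 dp).
* Single-linkage Δ-mass clustering recursively splits any chain whose
  members stray beyond tolerance from the intensity-weighted mean, so the
  representative-distance invariant holds by construction.
* Degenerate inputs fail loudly: empty peptides, unknown elements, ligand
  masses at or below one oxygen, zero/negative charges, MS2 scans without
  precursors, XICs from MS1-free (MGF) runs.

## Problem sizes used in the checks

The acceptance script measures screen recall and decoy retention over 40
seeded runs (100 decoys each, ligand masses drawn 60–400 Da) and yield
recovery over 8 seeds per planted ratio {0.4%, 8%, 10%, 30%} with 5%
multiplicative MS1 noise; the test suite runs the larger versions (100
seeded screen runs; 50 noisy yield seeds) with MS1 generation disabled
where only MS2 behaviour is under test. These sizes give binomial/relative
uncertainties well inside the asserted bounds.

## Known limitations

* Single site, single reporter peptide per run; no localization scoring
  between alternative sites.
* Charges beyond 5 and fragment charges beyond 2 are out of scope.
* The Δ-mass alone cannot distinguish isomers; annotation is a shortlist
  for biochemical validation, not an identification.
* MGF input disables XIC quantification (no MS1 scans by format).
* The mzML writer emits plain (non-indexed) mzML with 64-bit uncompressed
  arrays only; the reader additionally accepts zlib-compressed and 32-bit
  arrays.
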