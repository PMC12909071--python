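# Methods

This note documents the models and procedures implemented in `quadrufold`,
the parameters that matter, the numerical choices made where the design
was genuinely open, and what the synthetic-data generators do and do not
emulate.

## Quadruplex motif scanning (`gq_scan`)

A candidate quadruplex is four G-tracts joined by loops of 1–7 nt
(`G_x N_{1-7} G_x N_{1-7} G_x N_{1-7} G_x`). Tracts are **maximal** runs of
G: a run of five guanines contributes one tract of length 5, never several
sub-tracts, which avoids combinatorial double counting. Motifs are all
4-combinations of distinct tracts, in sequence order, whose three gaps lie
in `[1, max_loop]`; gaps may themselves contain tracts that are skipped.
The layer class of a motif is `min over tracts of min(length, 4)` — the
number of G-tetrads its shortest column can stack, capped at 4 because
longer tracts add no class beyond "≥ 4".

The canonical formula requires `x ≥ 3`, but two-layer quadruplexes form
(with much lower stability), so the scanner defaults to `min_tract = 2`
and reports the class per motif; `min_tract = 3` is the strict mode. A
transcript's class is the maximum over its motifs, `none` when it has no
motif. Coordinates are 0-based half-open everywhere, including the
BED-like TSV export. `T` is silently mapped to `U`; any other non-ACGU
character is an error naming the offending position — IUPAC ambiguity
codes are deliberately unsupported. Single-stranded RNA is scanned as
given: the reverse complement of a motif-bearing sequence generally has no
motif, and none is looked for.

Out of scope by design: thermodynamic stability scores and imperfect
(bulged, G-missing) quadruplexes.

## Peptide activity rule (`peptides`)

The composition profile counts residues exactly; net charge is the integer
side-chain model at neutral pH, `(+1 per R/K) − (1 per D/E)`, with His and
the termini ignored (designed repeat peptides carry a C-terminal amide, so
terminal charges approximately cancel). The activity call is binary:

    active  ⇔  arg_count ≥ min_arg (default 13)  AND  net_charge > 0

Lysine counts toward charge but not toward `arg_count` — Lys partially
substitutes for Arg but is not graded, and no ordinal potency scale is
attempted because observed differences (e.g. RP vs RQ context) are
secondary. The packaged SRSF1 RS-region sequence is a **synthetic
reconstruction** (`data/srsf1_rs_synthetic.fasta`); it matches the
region's reported composition — the truncated RS1 window (first 27
residues) carries exactly 10 Arg and the region has three Tyr — and is
used only for composition arithmetic, never as a reference proteome
sequence.

## Ensemble FRET unfolding (`fret`)

Spectra are wavelength–intensity tables on a strictly increasing grid
covering 530–700 nm. Normalization optionally subtracts a baseline (a
buffer-only spectrum on the same grid, or a flat offset — both are
supported because either convention is common) and divides by the donor
intensity at 566 nm, linearly interpolated when off-grid; a non-positive
reference is an error. The unfolding fraction at dose X is
`(F₆₇₀,₀ − F₆₇₀,X)/F₆₇₀,₀` on the normalized intensities. The acceptor
readout wavelength defaults to 670 nm (the Cy5 emission maximum is near
672 nm; both wavelengths are parameters). Negative fractions are reported,
not clipped — they flag anomalous spectra. No smoothing is applied (scan
averaging is assumed upstream), and no EC50/Hill model is fitted to the
dose curves. Properties guaranteed and tested: normalization idempotence,
scale invariance of the curve, and order insensitivity of the titration
input.

## Quadratic K_D fitting (`fp_binding`)

With the labelled RNA at `L_T = 10 nM` — comparable to the dissociation
constants of interest — ligand depletion makes the hyperbolic binding
curve wrong, so the bound fraction uses the exact quadratic root of the
one-site equilibrium (discriminant clamped at zero against roundoff; it is
analytically non-negative). Fitting is per replicate by Levenberg–
Marquardt least squares with K_D parametrized as `log K_D` for
conditioning over the 4-decade titration (2-fold ladder, 8000 → 0.488 nM,
15 points); initialization takes `F_min`/`F_max` from the data extremes
and K_D from the concentration nearest half-maximal signal. K_D is
reported as mean ± SD across replicates (SD undefined below two converged
replicates), matching replicate-level error estimation rather than pooled
fitting. A fitted amplitude smaller than three residual SDs is flagged
unidentifiable — the signature of a non-binding peptide — and excluded
from the mean. Polarization is assumed intensity-invariant over the
titration; no anisotropy conversion or multi-site model is provided.

## smFRET populations (`smfret`)

Efficiency is the proximity ratio `E = I_A/(I_A + γ I_D)` with γ = 1 (no
instrument correction factors are modelled); background-subtracted
intensities may stray outside [0, 1] and are clamped, and molecules with
non-positive total intensity are dropped with a reported count. Histograms
(bin width 0.02 on [0, 1], last bin closed) are display artifacts only:
population fitting uses the raw efficiencies with a two-component Gaussian
mixture fitted by expectation-maximization (scikit-learn's implementation
behind this module's surface, cross-checked in the tests against an
independent all-pairs/empirical oracle where separable). Components are
always reported low-E first; fits where one weight nearly vanishes *or*
the means are closer than two component widths are flagged `degenerate` —
EM splits a single population into two overlapping halves, so weight alone
does not detect collapse. For time courses the low-E fraction is the total
weight of components below the midpoint of the two state means, which
reads ~0 (not ~0.5) once a state has emptied. An optional histogram-area
estimator (`fraction below threshold`) is exposed for comparison; the two
agree in the separable limit. Trace extraction, photobleaching detection
and dwell-time analysis are out of scope.

## Protein–RNA contacts (`contacts`)

Frames arrive as multi-model PDB (one MODEL per frame, hydrogens present —
MD output); binary trajectory formats are not parsed. Criteria and
boundary semantics, deliberately fixed and tested:

- **H-bond**: donor–acceptor distance **≤ 3.5 Å** and donor–H–acceptor
  angle **≥ 120°** (both inclusive). Donors/acceptors come from a packaged
  chemistry table (protein backbone N–H and side-chain N/O; RNA base N/O,
  ribose O2′/O4′, phosphate OP1/OP2/O5′/O3′); hydrogens are assigned to
  donors geometrically (≤ 1.25 Å, same residue). The donor–H–acceptor
  convention is the standard reading of a distance-plus-angle criterion.
  One bond is counted per unique donor–acceptor atom pair (best hydrogen).
- **Salt bridge**: minimum N–O distance between a cationic group (Arg
  NE/NH1/NH2, Lys NZ) and a phosphate (OP1/OP2) **strictly < 4.0 Å**, one
  contact per group pair.
- **Stacking**: ring-centroid distance **< 4.0 Å** and angle between
  least-squares ring-plane normals (sign-folded to [0°, 90°]) **≤ 30°**.
  The Arg guanidinium (CZ/NE/NH1/NH2) is a planar cation–π partner
  alongside Tyr/Phe/Trp/His rings; the reference points (centroids,
  normals) are a documented choice since several conventions exist.
  Collinear "rings" are skipped with a warning.

Reports give per-frame counts of base H-bonds, backbone (ribose +
phosphate) H-bonds, salt bridges and stacking, attribution by residue type
(Arg/Ser/Tyr/other), a base-only H-bond view by residue type, and
mean ± SD across frames; replicate trajectories aggregate as mean ± SD of
per-trajectory means. A Kabsch-superposed RMSD-to-first-frame utility
serves as the equilibration check. Energies, water-mediated contacts and
trajectory generation itself are out of scope.

## Synthetic data (`synth`)

All generators draw from `numpy.random.default_rng(seed)` and are
byte-reproducible. What they emulate, and what they do not:

- **Transcripts**: iid background (G probability 0.15) with every
  background G-run at or above `min_tract` resampled away and non-G flanks
  forced around planted spans, so planted motifs are the *only* motifs —
  exact-recovery tests rely on this. Planted motifs use equal tract
  lengths (= layer count) and configurable loops. Real 5′UTRs have
  composition structure and imperfect motifs this does not model.
- **Spectra**: two Gaussian peaks (donor 566/12 nm, acceptor 670/14 nm);
  the acceptor amplitude is proportional to the folded fraction under a
  saturating dose model `u(c) = u_max·c/(c + EC50)` (defaults
  u_max = 0.9, EC50 = 200 nM), the donor amplitude fixed, noise iid
  Gaussian per wavelength. This makes the recovered statistic equal the
  generating unfolded fraction exactly at zero noise; donor de-quenching,
  crosstalk and photophysics are not modelled, so passing tests show
  statistic correctness, not spectroscopic realism.
- **FP titrations**: exact quadratic-model evaluations on the 2-fold
  ladder plus Gaussian noise (default σ = 2 mP, 3 replicates).
- **smFRET**: mixture draws clamped to [0, 1]; defaults are the
  duplex/hairpin two-state parameters (means 0.46/0.92, SDs 0.05/0.04,
  weights 0.39/0.61, n = 6000). Clamping leaves a small point mass at 1.0;
  at these widths its effect on fitted means is ≪ 0.01.
- **Frames**: each planted contact sits in its own 30 Å grid cell as a
  minimal residue pair (Ser donors for H-bonds — never cationic, so no
  stray salt bridges; lone Arg NH1 for salt bridges — no hydrogen or
  guanidinium plane, so no stray H-bonds or stacking), with decoys just
  outside every cutoff (3.8 Å / ~80° H-bonds, 4.3 Å salt bridge, 4.4 Å and
  45°-tilt stacking) and per-frame Gaussian jitter (0.02 Å) small against
  all margins. These are geometric test articles, not physical conformers.

## Problem sizes

The test suite and the acceptance script run at the sizes the analyses
are designed for where that is cheap (smFRET at n = 6000; the 15-point FP
ladder with 3 replicates; 500+ transcripts for planted-motif recovery) and
at small frame counts (2–5 frames, ≤ a few hundred atoms) for contact
detection, where counts are scale-free. The transcript-pool *absolute*
layer distribution over a specific regulated-mRNA set is not reproducible
here because that transcript list is not deposited; the package
substitutes exact planted-motif recovery, which checks the same scanner
end to end.

## Known limitations

- The activity rule is binary; partially active peptides are not ranked.
- γ = 1 and no donor-leakage correction in smFRET; absolute E values from
  real instruments need calibration before comparison.
- The contact chemistry table covers standard residues and unmodified
  ribonucleotides only.
- The quadratic fit assumes one site; cooperative binding will show as a
  systematic residual, not a warning.
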