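# Methods

This note records the models, conventions and design choices behind each
module, what the synthetic generators do and do not emulate, and the known
limitations.

## Sequence handling and numbering

Residue numbers are full-length and 1-based from the receptor's initiator
methionine.  The stored domain fragments begin at residue 17; anchoring is
done by locating a motif that occurs exactly once (the A-strand `KVEG`,
placed at 24–27) and solving for the offset.  Overlapping motif occurrences
count as distinct candidates, so an ambiguous anchor is always rejected.

Hyphens inside the stored printed sequences are typesetting artifacts, not
alignment gaps, and the parser strips them (together with whitespace and
digits).  Stripping yields 108 human and 107 mouse residues — consistent
with the single-residue deletion in the rodent CDR2 — which is the reason
for treating the hyphens this way.

Global alignment uses BLOSUM62 with affine gap penalties (open 10,
extend 0.5; a gap run of length L costs 10 + 0.5·(L−1)), computed by
Biopython's `PairwiseAligner`.  Determinism among co-optimal alignments
comes from the aligner's fixed enumeration order; the human/mouse domain
pair has a unique optimum under the defaults, pinned by a regression test
(single gap in the mouse row at the human-66 column).  Percent identity
defaults to the alignment-column denominator, with gap columns counting
against identity; because published rounding conventions are rarely
stated, reports carry the unrounded value plus round-half-up and truncated
integers (the human/mouse domain pair gives 64.8%, i.e. 65 or 64).

Mutants are described by compact labels (`E41Q`, `N66-`, `EM41-42QL`,
`KQYPR79-83TPCLD`, …).  Every edit is validated against the wild-type
residue before any is applied; deletions shorten the sequence while the
original offset is retained, so substituted residues keep wild-type
numbering.  Substitution-only specs are invertible; deletions are not.

Cysteine classification aligns a query against an annotated reference
(human bridges 37–104 and 49–58 by default): a query cysteine is bridged
iff its alignment column carries a bridge-annotated reference cysteine,
and every call is reported at the reference (human-aligned) column number.
The mouse free cysteine therefore reports as column 81 — descriptions that
count in mouse-local numbering would call the same residue 80, a
discrepancy the human-aligned convention avoids.

CDR boundaries are configurable because exact structure-based limits for
this receptor are not published; the shipped defaults bracket the residues
known to lie in each region (A strand 24–27, CDR1 38–42, the two-residue
CDR2 65–66, DE loop 79–83, CDR3 105–111).

## Melting-temperature estimation

Temperatures are carried in kelvin internally (°C + 273.15 exactly; the
heating protocol's −273 °C start maps to 0.15 K).  The default schedule
ramps 0.15 → 200.15 K in 4 ns and 200.15 → 400.15 K over the next 200 ns,
then holds; crossings during the hold are reported at the hold temperature
with a post-ramp flag, since the schedule carries no rate information
there.

Native contacts are all atom pairs within a cutoff whose residues are at
least `min_seq_separation` apart: 4.5 Å / 4 residues for all-heavy-atom
models, 8 Å for Cα-only models.  The exact convention used by any given
analysis package varies, so contact retention supports both "within the
defining cutoff" (default) and "within λ× the reference distance"
(λ = 1.2).  Q is the retained fraction per frame; R_g is the unweighted
root-mean-square distance to the centroid (mass weighting optional).

Both order parameters are smoothed with a centred moving mean (default 51
frames, shrinking at the edges).  Tm is the temperature at the first
crossing of the smoothed series through the criterion threshold (Q < 0.8
falling, R_g > 14 Å rising), with the crossing time interpolated linearly
between the bracketing frames.  A profile that passes exactly through the
threshold at a frame returns that frame's temperature exactly.  Every Tm
should be read against the temperature span of one smoothing window at the
crossing (`window_temperature_span`), which is the method's resolution
limit — about 5 K for 2000 frames over the default ramp.

Repeats aggregate as sample mean and SD (n−1); repeats with no crossing
are censored — excluded from mean/SD but counted — because there is no
principled imputation for a run that never melts.  Group comparison is a
pooled-variance two-sided Student's *t* test, accepting either raw samples
or (mean, SD, n) summaries so published tables can be tested directly;
zero pooled variance is degenerate (p = 1 for equal means, 0 otherwise,
flagged).  Welch's correction is available behind a flag.

Published per-construct Tm tables from µs-scale MD are *not* recomputable
by this module — they require the MD engine and an unstated contact
definition — and are shipped only as summary-statistic inputs
(`fcmurkit.data.TABLE1`) for the comparison entry point.

## Complex geometry

Residues are addressed as (chain id, author residue number); insertion
codes are unsupported (a documented limitation — none of the supported
inputs need them).  An interface residue pair is any residue pair with a
heavy-atom distance ≤ 5.0 Å (configurable); "most contacts with Cµ4" is
operationalised as a strict > 0.75 fraction at residue-pair granularity,
so exactly 75% fails.  The clash threshold (2.5 Å heavy-atom) and the
pseudo-glycan exclusion sphere (6 Å around the site's side-chain tip atom,
falling back to Cα with a warning for Cα-only models) are explicit
surrogates for visual inspection criteria that are otherwise unstated.
Cµ3/Cµ4 residue ranges are required configuration, not hard-coded, because
ligand numbering differs between structures.

C-terminus accessibility combines a clearance test (no non-receptor heavy
atom within 8 Å of the C-terminal Cα) with a half-space test (the Cα lies
on the far side of the receptor centroid from the environment centroid,
i.e. points away from the ligand toward where a membrane stalk would
connect).

Kabsch superposition is computed via SVD with a determinant correction so
the rotation is always proper — mirror images keep a residual RMSD —
and degenerate (collinear/coincident) point sets are rejected.  Tiling
superposes the source subunit's Cα set onto each other subunit and carries
the docked receptor pair along; every placement (including the source
pair) is scored for clash against the disc and all other placements, and
for C-terminus accessibility.

The docking-score calibration fits log10 K_a against score by ordinary
least squares, reflecting an approximately linear score–affinity
relationship over K_a = 10^4–10^10 M⁻¹; with two points it interpolates
exactly.  Pose generation, energy minimisation and SASA are out of scope —
poses are inputs and this module is a gatekeeper.

## Cytometry statistics

MFIs default to arithmetic means ("mean fluorescence intensity" read
literally) with a geometric-mean option, since cytometry software varies.
The index is the exact difference ratio
(PE_t − PE_c)/(GFP_t − GFP_c); a non-positive GFP difference means the GFP
gate failed and raises an error rather than returning a signed artifact.
The index is invariant to a common additive PE background and scales as
expected under independent per-channel gains.  Inputs are assumed
compensated; gating labels are inputs (no automated gating).  Construct
versus wild-type comparison uses the unpaired pooled-variance Student's
*t* test (Welch behind a flag; pairing across experiments is not assumed)
with tiers at p < 0.05/0.01/0.001.

## Synthetic generators

All generators are pure functions of (params, seed) and bit-reproducible;
each emits a ground-truth record sufficient to re-derive the expected
downstream quantities.

**Heating trajectories.**  The folded reference is a 28-residue Cα helix
(rise 1.5 Å, twist 100°, radius 2.3 Å) with frozen Gaussian jitter
(SD 0.8 Å) — compact enough that its R_g (≈ 12.5 Å) sits safely below the
14 Å threshold while the jitter gives a rich, distance-diverse contact set
at the 8 Å Cα cutoff.  Below the programmed `t_melt`, frames add 0.3 Å
positional noise; above it, coordinates expand by a factor 1 + 0.04·ΔT
with noise growing 0.01 Å/K.  The expansion rate makes the transition
sharp on the scale of one smoothing window, which is what "two-state" means
operationally here: both criteria cross within a few kelvin of `t_melt`
(median recovery error ≈ 1–3 K over seeds 1–20 at 320/350/380 K, against a
≈ 5 K window span).  Default problem size is 2000 frames over the 204 ns
ramp — small enough to run in well under a second per repeat while leaving
the smoothing window ≈ 0.5 K per frame of resolution.  What this does not
emulate: real unfolding kinetics, hysteresis, partial unfolding
intermediates, or force-field physics; passing recovery tests demonstrates
correctness of the estimator, not realism of MD.

**Pentamer complexes.**  Five two-chain subunits are arranged with exact
C5 symmetry on a 40 Å ring; each chain is a radial Cα spoke whose inner
half is the Cµ3 analog and outer half the Cµ4 analog, with the two chains
of a subunit related by a proper C2 rotation about the radial axis (one
receptor site on each face of the disc).  In `good_pose` mode a 12-residue
receptor domain sits over the Cµ4 grid with its required-residue analogs
4.1 Å above ligand atoms, an arm contributing a few Cµ3-boundary contacts
(so the Cµ4 fraction is ≈ 0.85, not trivially 1), forbidden analogs on the
far face, the C-terminus pointing outward, and no distance close to the
5.0 Å contact cutoff (nearest off-contacts at ≥ 5.08 Å), so verdicts are
stable under rigid motion and floating-point noise.  `clashing`,
`buried_cterm` and `constraint_violating` modes each break their labelled
property by construction.  The real IgM-Fc disc is an asymmetric hexagon
with a missing segment; exact symmetry was chosen because it makes the
ten-placement count and tiling self-consistency exactly checkable, and
asymmetry adds nothing testable at this level.

**Cytometry panels.**  Replicate indices are baseline × multiplier ×
log-normal noise with unit mean and programmed CV (exact at CV = 0), so
the expected index of every construct is its programmed multiple of the
wild-type baseline (2.0 by default).  The default multiplier panel mirrors
the direction of the experimental effects — strong reduction for the CDR2
deletion, DE-loop swap and CDR3 mutant analogs (0.2–0.3×), enhancement for
the CDR1 swaps (1.2–2×), near-background for mouse WT — with magnitudes
chosen as round values; they are conditions of the synthetic study, not
measured quantities.  Event tables draw log-normal events whose arithmetic
means equal the per-channel MFIs.  Spillover/compensation and gating are
not modelled.

## Numerical conventions and degenerate inputs

Ties in the alignment DP are resolved by the aligner's deterministic
enumeration order.  Moving-mean windows must be odd and no longer than the
series.  Contact retention is inclusive (≤ cutoff); clash is strict
(< threshold).  Sample SDs use the n−1 denominator everywhere, with SD
reported as 0 and flagged when n = 1.  Empty contact sets, all-censored
repeat lists, empty populations, non-positive GFP differences, unresolvable
residue references, collinear superposition inputs and subunit Cα-count
mismatches all raise typed errors naming the offending item.

## Known limitations

No MD, docking search, homology modelling or energy minimisation; poses
and trajectories are inputs.  No FCS binary parsing or automated gating.
Insertion codes unsupported.  Full-length receptor alignments beyond the
Ig-like domain are out of scope (exon boundaries for the other regions are
not available), so exact reproduction of published whole-region identity
percentages is not guaranteed — the module reports the domain-pair value
(64.8% over columns) with both integer renderings.
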