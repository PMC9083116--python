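# Methods

This note records the models, conventions and numerical choices behind
unfoldkit, and what its synthetic-data tests do and do not demonstrate
about real trajectories.

## Scope and data model

The package analyses trajectories; it does not produce them. Input is a
multi-model PDB file over one fixed topology (first MODEL defines the
topology; every later MODEL must have the same atom count, enforced with
an error naming the offending model). Coordinates are Å internally
everywhere; conversion to nm (RMSD, Rg) and nm² (SASA) happens only in
the pipeline's reporting layer, matching how such tables are
conventionally printed. Structures are assumed protein-only; solvent must
be stripped upstream. Residues are re-indexed 0-based and contiguous;
original file numbering is kept for labels. Van der Waals radii come from
a single per-element table (C 1.70, N 1.55, O 1.52, S 1.80, H 1.20 Å);
unknown elements fall back to carbon values.

## Order parameters

**Superposition.** Weighted Kabsch via SVD of the cross-covariance
matrix; the reflection case is corrected so the rotation is always proper
(det +1). Degenerate (collinear) point sets still return the minimal
RMSD but are flagged non-unique. Verified against scipy's quaternion
solver to 1e-8 on random point sets.

**Native contacts.** A contact is any heavy-atom pair from residues at
least `min_sequence_separation` apart whose reference distance is
≤ `cutoff`. Defaults: cutoff 4.0 Å; separation 3. The separation default
excludes trivially permanent neighbour contacts that would inflate the
Nc floor; it is a package choice (exposed in the API) since contact
definitions in the literature often say only "two different residues".
Per frame, Nc re-evaluates the strict cutoff (`tolerance_factor` 1.0 by
default); a soft/switching-function variant is deliberately out of scope.

**SASA.** Shrake–Rupley quadrature with sphere points from the
deterministic golden-spiral rule — reproducible with no seed. Default
960 points (isolated-sphere error < 1 %); the pipeline uses 240 points
and a frame stride for throughput, which changes totals by well under a
percent on the toy systems. Probe radius 1.4 Å. Side-chain SASA is
computed in the context of the whole structure and summed over the
residue's side-chain heavy atoms; glycine has none and is an error.

**H-bond counting.** Backbone N···O ≤ 3.5 Å with D–H···A ≥ 120°,
|Δresidue| ≥ 2. When the topology lacks amide hydrogens, H is
reconstructed 1.01 Å from N, anti to the preceding residue's carbonyl
(the same rule the secondary-structure module uses), and the angle test
is applied to the reconstructed position. A pure distance criterion was
rejected because an ideal α-helix packs N(i+2)···O(i) and N(i+3)···O(i)
inside 3.5 Å; the angle screen leaves the expected i→i+4 ladder
(8 bonds in a 12-residue helix).

**RMSF.** Each frame is superposed on the mean structure, the mean is
re-estimated, and the cycle runs twice (further passes change nothing
measurable on well-behaved input); RMSF is the per-atom root mean square
about the final mean. Alignment can be disabled.

All reported mean ± SD values use the sample (n−1) standard deviation.
The equilibration discard defaults to 0 and is a config knob.

## Free-energy landscapes

F = −RT ln P on the joint histogram of two order parameters, R fixed at
1.9872×10⁻³ kcal mol⁻¹ K⁻¹, units kcal/mol. Unvisited bins are masked
rather than assigned a sentinel: −RT ln 0 is undefined, and masking keeps
basin ΔF meaningful. The surface is shifted so the minimum over visited
bins is 0; exp(−F/RT) renormalised over visited bins reproduces the
empirical histogram to machine precision, which is the module's own
consistency invariant. Default 60×60 bins.

Basins are grid-local minima: unmasked bins no worse than every unmasked
8-neighbour and within `depth_threshold` (default 2 kcal/mol) of the
global minimum; tied connected plateaus merge to their first bin in
row-major order. This is deliberately not watershed segmentation — the
use case is counting and comparing well-separated states, for which
basin ΔF converges to −RT ln(p₂/p₁) as sampling grows (recovered within
±0.1 kcal/mol at 50,000 frames in the tests). Note that discrete-valued
order parameters (Nc takes n_pairs+1 levels) can alias against the bin
grid and fragment a basin; recovery checks therefore use continuous
axes (Rg, RMSD).

## DCCM

Normalised covariance of selected-atom (default Cα) displacements about
the window mean. Superposition onto the window mean is ON by default:
without it, global rotation dominates the correlations; the convention is
selectable because published maps rarely state theirs. Atoms with zero
variance in a window get zero off-diagonal correlation and a warning.
Default windows are the first and last 10 % of frames, for start-vs-end
comparisons.

## Secondary structure

A simplified Kabsch–Sander scheme: the classic electrostatic H-bond
energy (coupling 27.888 kcal·Å/mol, bond below −0.5 kcal/mol, energies
clamped at −9.9), amide H reconstructed when absent; helices H/G/I from
two consecutive 4-/3-/5-turns, strands from parallel/antiparallel bridge
patterns (ladders → E, isolated bridges → B, terminal residues never E),
T from turn spans, S from a Cα direction change > 70°, priority
H > G > I > E > B > T > S > C. No β-bulge handling and no
chirality-based 3₁₀/π disambiguation: the target is the coarse
helix/strand/turn/bend/coil categories an unfolding timeline tracks, not
byte-identical DSSP output. On ideal helix and hairpin fixtures the
assignment agrees 100 % with mdtraj's DSSP; the tested guarantee is
≥ 90 % residue-frame agreement with differences confined to segment
termini.

## Synthetic trajectories

The generator emulates exactly what the analyses assume — a
fixed-topology protein interconverting among a native state, a partially
unfolded intermediate and an expanded unfolded state — and nothing more.

**Toy protein.** A deterministic helix+hairpin fold built from ideal
backbone dihedrals (NeRF chain construction): α-helix (φ,ψ) = (−57,−47),
strands (−139,135), a two-residue hairpin turn (90,−90)/(−150,30) chosen
by a one-off grid search to maximise cross-strand Kabsch–Sander bonds,
and an extended loop that keeps the helix clear of the sheet.
Consecutive Cα–Cα distances are 3.80 Å by construction. Side chains are
CB pseudo-atoms tilted 60° out of the backbone plane (keeps sheet faces
clash-free), one loop glycine (no side chain) and one strand tryptophan
with an idealised 10-heavy-atom indole whose ring runs along the strand
axis; at the default size (30 residues) the Trp faces the sheet, so its
side-chain SASA rises from ~140 Å² (native/intermediate) to ~190 Å²
(unfolded). The hairpin's H-bond geometry is looser than a real sheet's
(N···O 3.3–4.8 Å): the energetic DSSP criterion accepts it, the stricter
geometric H-bond counter mostly does not — so H-bond counts on the toy
reflect chiefly the helix. Sizes below ~14 residues cannot host both a
helix and a pairing hairpin; the tested configuration is 30 residues.

**Templates.** Intermediate: helix and loop dihedrals set to extended,
hairpin untouched — it retains the hairpin's share of native contacts
(0.47 at the default size, within the 0.4–0.6 design band, because the
layout puts ~27 % of non-loop residues in the helix). Unfolded: fully
extended chain; every contact at separation ≥ 3 is broken by more than
cutoff + 6 jitter-sigmas (minimum long-range heavy-atom distance 7.9 Å),
so unfolded frames score Nc = 0 even with jitter. Rg orders strictly
native < intermediate < unfolded.

**Dynamics.** The hidden state resamples from the occupancy distribution
with probability 1/dwell per frame, making the occupancies the exact
stationary law; the realised per-state mean dwell is dwell/(1−p_state),
slightly longer than the nominal value — populations, which every
recovery test uses, are unaffected. Frames are template + i.i.d. Gaussian
jitter, default σ = 0.3 Å per coordinate (small against the 4 Å cutoff,
so state identity dominates Nc). One master seed drives everything;
per-temperature seeds are spawned from it, and fixed seeds give
bit-identical output.

With σ = 0.3 Å the native state's mean Nc is ≈ 0.80, not ≈ 1: a folded
protein's contact distances crowd the cutoff (toy: median 3.5 Å), so
strict per-frame re-evaluation flickers marginal pairs. This mirrors
what published unfolding studies report for folded baselines (native-run
Nc ≈ 0.8) and is a property of the strict-cutoff definition, not noise
mis-calibration.

**Thermal ladder.** Default 300/350/400/450/500 K schedule:
native 1.0 → 0.80/0.20 (native/intermediate) → 0.40/0.50/0.10 →
0.05/0.35/0.60 → 0.05/0.95 (intermediate/unfolded). Chosen once so
occupancy mass moves native → intermediate → unfolded with temperature;
dwell 25 frames keeps occupancy-sampling autocorrelation small enough
that 1,500-frame runs give strictly monotone mean Nc and Rg across the
ladder. Temperature labels are labels: nothing kinetic is calibrated to
kelvin; only the FEL uses T thermodynamically.

**What passing tests show — and not.** Recovery tests demonstrate the
analysis code measures what was put in (populations, contact fractions,
correlations, secondary structure). They do not validate force-field
realism, solvent effects, kinetics, or any claim about a specific real
protein: real trajectories have correlated, anisotropic fluctuations,
partial contacts and dihedral heterogeneity the jitter model does not
emulate.

## Pipeline

`run_unfolding_analysis` sorts the input trajectories by temperature,
takes the native reference as frame 0 of the coldest trajectory (for
synthetic ladders, the native template; overridable by a PDB path),
builds one native contact set, and per temperature computes the five
series, the summary row, the configured FEL pairs (a pair whose axis is
constant at some temperature — e.g. Nc ≡ 0 when fully unfolded — is
skipped with a warning rather than aborting the run), start/end DCCMs
and the secondary-structure timeline. Every output is plain text, every
defaulted parameter is logged, reruns with the same config and seed are
byte-identical, and a COMPLETE marker distinguishes finished bundles
from aborted ones. Problem sizes used by the shipped verification runs —
1,500 frames per temperature, 240-point SASA quadrature with stride 5,
50,000 frames for the two-state free-energy recovery — are the package's
standard demonstration sizes; all are config knobs.
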