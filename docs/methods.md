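# Methods

This note records the models behind each stage, the defaults and why they
were chosen, what the synthetic generator does and does not emulate, and
the numerical choices a maintainer would want to know.  Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Chemical shift index

Secondary shifts are Δδ = δ_obs − δ_rc against a Wishart-style random-coil
Cα/Cβ reference table shipped as `hed/data/random_coil.csv` (swappable via
`load_random_coil_table(path)`).  The composite statistic is
Δδ(Cα) − Δδ(Cβ), the standard way to combine the two nuclei because helix
and strand move them in opposite directions; glycine, which has no Cβ,
falls back to Δδ(Cα) alone.  The index is +1/−1 where the composite is
*strictly* beyond ±threshold (default 0.7 ppm, configurable), 0 otherwise.
No sequence-dependent neighbor corrections are applied.  Per-atom Δδ
tracks are reported alongside the composite so either can be plotted.

## Kabsch–Sander secondary structure

`assign_ss` is a self-contained implementation (no external DSSP binary):
electrostatic H-bond energy with coupling constant 0.084·332 kcal·Å/mol,
bond threshold −0.5 kcal/mol, CA–CA 9 Å pair prescreen, chain breaks at
C(i)–N(i+1) > 2.5 Å.  Amide hydrogens are built geometrically
(H = N + 1.0 Å along C′(i−1) − O(i−1)) whenever the file carries none, the
convention X-ray-style inputs need; proline never donates.  Helices come
from two consecutive n-turns (n = 4 → H over i..i+3; n = 3 → G over
i..i+2), strands from the classic parallel/antiparallel bridge patterns
(bridges stacking into ladders → E, isolated → B), turns from any
3/4/5-turn span, bends from a Cα(i−2)→Cα(i)→Cα(i+2) virtual-bond angle
above 70°.  Overlaps resolve as H > G > E > B > T > S > C.  π-helices are
not detected.  The test suite checks ≥95% residue agreement against
mdtraj's independent DSSP on ideal and noise-perturbed peptides;
disagreements concentrate at element boundaries, as expected for any two
implementations of this algorithm.

Ensemble propensities are plain per-class frequencies over models.
Element definition takes residues whose helix (H+G) or strand (E+B)
frequency is strictly above the threshold (default 0.8) and keeps maximal
runs of length ≥3 (helix) or ≥2 (strand).  Counting G with H is the
default because 3₁₀ segments at helix termini are part of the same
element for this purpose; an H-only mode is available
(`helix_classes=("H",)`).

## Ensemble geometry

Superposition is the Kabsch SVD solution with the determinant correction
for proper rotations; collinear selections (second singular value ≈ 0)
are rejected because the rotation is underdetermined.  RMSF uses, by
default, iterative alignment to the mean structure (2 rounds), which is
order-invariant; alignment to model 1 is available (`reference="first"`)
for workflows that defined fluctuations that way.

The bend metric d(Cα_{i−4}, Cα_{i+4}) uses a half-window of 4 by default
and, for ensembles, the per-residue mean over models.  Calibration on
ideal geometry: an extended strand (φ = −135°, ψ = +135°) gives ≈27.6 Å,
matching the ~28 Å textbook reference.  An ideal straight α-helix
(φ = −57°, ψ = −47°, rise ≈ 1.56 Å/residue) gives ≈12.8 Å; note that any
straight helix with the canonical 1.5 Å rise and 3.6 residues/turn is
bounded below by ≈12.4 Å over an 8-residue span, so quoted reference
values of ~11 Å for helices reflect measurements on real, slightly curved
or frayed helical segments rather than ideal geometry.  The acceptance
script reports the ideal-geometry value as computed.

Backbone ASA is Shrake–Rupley with a deterministic Fibonacci sphere
(default 960 points, <2% from a 4000-point evaluation), probe 1.4 Å, vdW
radii N 1.55 / C 1.70 / O 1.52 / S 1.80 Å; hydrogens are ignored both as
targets and occluders.  Relative exposure divides each residue's backbone
(N, Cα, C, O) ASA by that of the central residue in an extended
Gly-X-Gly-style tripeptide built on demand by the synthetic builder, so
fully exposed tail residues score ≈1.

## Rescoring and model selection

χ² sums ((δ_pred − δ_obs)/σ)² over matched (chain, residue, atom-type)
keys; σ is the predictor's per-value uncertainty, so atom types with
larger prediction errors contribute less.  E_CS = E + c·χ² with c = 0.25.
Selection is deterministic: reference = single lowest-E_CS model (ties by
model id), shortlist = 20 lowest E_CS, final = 10 lowest core-Cα-RMSD to
the reference, ties broken by (E_CS, model id).  The tie-break rules are
this package's choice — any deterministic rule would do — and the RMSD
reference is fixed once, before the shortlist is taken.  Shift prediction
is intentionally an interface (`ShiftPredictor`): empirical predictors
are large external programs, and the pipeline only needs the resulting
table.  A `TableLookupPredictor` ships for tests and examples.

## Exchange and NOE dynamics

H/D protection classifies each residue by the latest timepoint at which
its amide signal is identifiable (default grid 11/39/67/431 min);
absence at the first timepoint means fast exchange.  Observation sets
should be prefix-closed in time; violations are flagged, not fatal, and
the latest observation wins.

The fast-exchange forward model is two-site Bloch–McConnell saturation
transfer, isolated in the single function `hetex_intensity`:

    I(d) = I_eq · (R1 + kex·w) / (R1 + kex) · (1 − exp(−(R1 + kex)·d))

with w the normalized water magnetization during the relaxation delay d
(0 under water saturation; the measured water fraction, default 1,
otherwise).  Both the fitter and the synthetic generator call this one
function, so parameter-recovery tests are self-consistent by
construction.  Fitting is bounded nonlinear least squares
(kex ∈ [0, 10³] s⁻¹, R1 ∈ [10⁻³, 50] s⁻¹, I_eq > 0) with three starts
(kex = 0.2, 1, 5 s⁻¹) to avoid local minima; non-convergence is reported
in the result record rather than raised, so one bad residue cannot abort
a table-wide fit.  The default delays 0.566/0.878/1.659 s define the
sensitivity window 0.1–10 s⁻¹ flagged in `in_window`: above it the
exponential saturates and only the kex/R1 ratio is well determined, which
is why recovery accuracy degrades toward the fast edge.  Residues
adjacent to Ser/Thr can read fast through OH-relayed NOE; they are
flagged (`near_ser_thr`), never auto-corrected.

hetNOE is the plain intensity ratio with classes flexible (< 0),
intermediate ([0, 0.5]) and rigid (> 0.5) — thresholds configurable —
plus run-length region calling (`classify_regions`, default minimum run
3) to turn per-residue classes into contiguous segments.

## Synthetic generator

All generators are pure functions of (spec, seed).  The peptide builder
uses sequential internal-coordinate (NeRF) placement with ideal bond
geometry (N–Cα 1.458, Cα–C 1.525, C–N 1.329 Å; angles 111.2/116.2/121.7°;
ω = 180°), carbonyl O anti to the next amide nitrogen, and Cβ at the
standard L-improper (122.55°).  Class dihedrals: H (−57°, −47°),
E (−135°, +135°); coil residues draw from the broad extended basin
(φ ∈ [−180°, −60°], ψ ∈ [60°, 180°]) with a 2.5 Å Cα–Cα minimum-distance
rejection and retries — enough to keep toy chains self-avoiding, with no
claim of Ramachandran realism.  Ensembles add isotropic Gaussian noise
(σ = 0.2 Å core, 3 Å tails by default, mimicking a converged fold with
disordered termini).  Shift tables use offsets H (+2.8, −0.5),
E (−1.5, +2.2) ppm for (Cα, Cβ) — conventional magnitudes for fully
formed elements.  Score tables draw a latent quality q per model that
jointly drives energy (−350 + 150q ± 10), χ² (200 + 400q ± 20, clipped at
0) and coordinate noise (0.3 + 3q Å), producing the energy/RMSD funnel a
fragment-assembly pool shows.

What the generator does **not** emulate: real shift dispersion and
neighbor effects, spectral overlap and missing assignments, anisotropic
or correlated coordinate fluctuations, sidechains beyond Cβ, and
force-field-quality sterics.  Passing tests therefore demonstrate
correctness of the algorithms under known ground truth, not performance
on experimental spectra.

## Problem sizes

Default test and acceptance runs use 18–60-residue peptides, ensembles of
5–50 models, selection pools of 30 (oracle comparisons, 100 seeds) and
1000 (end-to-end), and 100 synthetic residues for noisy exchange-rate
recovery — sizes chosen so every check runs comfortably on a laptop while
still exercising the same code paths as full-scale data.

## Known limitations

* The NMR-STAR reader handles only the atom-chemical-shift loop, not the
  full STAR grammar; insertion codes and altloc ensembles (beyond
  first-altloc selection) are unsupported.
* The DSSP variant omits π-helices and ladder bulges; agreement with
  reference implementations is by design approximate at element
  boundaries.
* The saturation-transfer model treats water magnetization as constant
  during each delay at its measured value; a fully time-dependent water
  recovery would require the water R1, which the experiment's per-delay
  water measurements make unnecessary.
* kex estimates outside the 0.1–10 s⁻¹ window are reported but only the
  `in_window` flag should be trusted there.
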