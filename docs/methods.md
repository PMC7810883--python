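# Methods

This note records the models, conventions and numerical choices behind
`pdzdyn`, in the spirit of a package methods section: what is computed,
under which assumptions, with which defaults, and what the synthetic
benchmarks do and do not demonstrate.

## Units, numbering and I/O conventions

Internal units are nm and ns throughout, because every decision threshold
the package exists for (the 1.0 nm contact cutoff, the 20 ns minimum
dwell) is stated in those units. PDB files are converted from Å at the
boundary; Å/ps input to the text formats is accepted behind explicit
`units`/`time_unit` flags and scaled by exactly 0.1 / 10⁻³.

Residue numbering is the author/PDB numbering (243–338 for the hDVL3 PDZ
construct) and is never remapped; phosphoserine is `SEP`. Only the first
MODEL of a PDB is used as a topology; a multi-model PDB is read as a
trajectory only through the explicit trajectory reader. Alternate
locations other than blank/"A" are dropped; insertion codes are a hard
error rather than a silent renumbering hazard.

Trajectories round-trip through three formats: multi-model PDB (text;
since frame spacing is constant by invariant, times travel in a single
`REMARK 250 PDZDYN TIMES_NS T0=… DT=…` header), GROMACS XTC (via the
MDAnalysis xdrlib bindings; XDR is big-endian by format definition, and
coordinates are stored at the format's 0.001 nm precision), and a
long-format CSV fallback. Frame times must be strictly increasing with
constant spacing (relative tolerance 10⁻³).

The selection grammar is deliberately minimal — `resid N[-M]`,
`resname X`, `name X`, `chain X`, `and`/`or`/`not`, parentheses — which
covers every pair the analyses monitor while keeping resolution a pure,
order-deterministic function.

## Superposition and fluctuations

Optimal superposition is the Kabsch SVD solution with optional weights;
the determinant correction guarantees a proper rotation, and (near-)
collinear references are rejected with an error instead of being resolved
by an arbitrary reflection-adjacent optimum. Trajectory alignment solves
all per-frame problems in one stacked SVD. The default fit set is all Cα;
a selection may exclude flexible regions (termini, the β2–β3 loop) when a
rigid-core fit is wanted.

RMSF is computed per atom about the time-mean position of the aligned
trajectory; the per-residue profile reports the Cα value (the field
convention for per-residue plots), with a mass-weighted heavy-atom
variant available (`mode="heavy"`). RMSF refuses unaligned trajectories
unless explicitly overridden, because RMSF on an unaligned trajectory
silently includes rigid-body motion. Replica combination uses the sample
(n−1) standard deviation — with two replicas, the unbiased choice.
ΔRMSF is variant − wild type on the residue intersection, so positive
means increased fluctuation in the variant.

The first 10% of frames are discarded as equilibration by the pipeline
default (overridable and logged); analyses on synthetic data use the full
window since the generator is stationary by construction.

## Contact occurrence criteria

A frame is in contact iff distance ≤ cutoff, boundary inclusive; for
continuous distances the boundary convention is measure-zero, but it is
documented and configurable. Multi-atom selections ("any phosphate
oxygen") reduce to the minimum inter-set distance per frame; naming a
single atom (`name P`) recovers the single-atom convention. Which atom
defines "the phosphate" is genuinely open; both are supported. With a
periodic box present, distances use the orthorhombic minimum-image
convention.

The occurrence rule counts an interaction only when (a) at least one
*contiguous* contact event lasts ≥ 20 ns and (b) occupancy exceeds 25% of
the analysed window (strict inequality). The dwell clause is read as
contiguous because an accumulated-time reading would be implied by the
occupancy clause for any 300–1000 ns window, making it redundant; only
the contiguous reading gives both clauses force. Event duration counts
frames inclusively ((last − first + 1)·Δt), gaps are not merged by
default (`gap_tolerance_ns = 0`, the strictest reading), and the
occupancy denominator is the full analysed window, not the union of
events. Per-replica decisions aggregate to the "k/n" occurrence ratio.

Ion bridges: an ion bridges two anionic sites at a frame iff it is within
0.35 nm of at least one atom of each site — a typical Na⁺–oxygen
coordination distance; per-ion residence is its share of the frames where
any bridge exists, and ions at residence ≥ 0.5 are "stable", below
"diffuse". Both thresholds are parameters and are echoed into outputs.

## Secondary structure

The assigner is a Kabsch–Sander implementation reduced to four classes:
H (α-helix, two consecutive i→i+4 turns), G (3₁₀, two consecutive i→i+3
turns), E (parallel/antiparallel bridge patterns, |i−j| ≥ 3), C
(everything else — π-helices, bends and turns are deliberately collapsed
into C). Priority on overlap is H > E > G. The H-bond energy is the
standard electrostatic model E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH −
1/r_CN) kcal/mol with a bond at E < −0.5 kcal/mol. The amide hydrogen is
constructed geometrically when absent (1.01 Å from N, anti to the
preceding carbonyl), since MD topologies may or may not carry hydrogens;
an explicit H/HN is preferred. Proline never donates; residues missing
any of N/CA/C/O are labelled C with a warning. On ideal-geometry
constructs (helix, extended chain, two-strand antiparallel sheet) the
assignment agrees exactly with mdtraj's DSSP 3-class reduction, which the
tests enforce.

Unfolding/refolding events are read from the per-frame helical fraction
(H or G) of a region with hysteresis: an unfolding event requires the
fraction to stay below 0.3 for ≥ 5 ns (defaults; all configurable), a
refolding event symmetrically above 0.7. Hysteresis plus the dwell
requirement suppresses the threshold chatter a fast-breathing short helix
produces, and guarantees strict alternation of event kinds per region.

## Conformational clustering

Daura neighbor-counting ("leader") clustering on pairwise RMSD: the
unassigned frame with the most unassigned neighbors within the cutoff
becomes a leader (ties broken by lowest frame index), its neighborhood
forms the cluster and is removed, and final labels are sorted by
descending cluster size. Default cutoff 0.15 nm on loop Cα — a standard
conformer-counting scale for a mobile loop. When planted conformers are
separated by more than twice the cutoff, memberships are provably stable
under frame permutation, which a test asserts. The three-cluster result
on synthetic loops mirrors the qualitative three-conformation finding for
the β2–β3 loop; no numerical reproduction of the original clustering is
claimed, since its algorithm and cutoff are not stated.

## NMR titration analysis

CSP uses the weighted two-nucleus norm Δδ_obs = √(δ¹H² + (δ¹⁵N/6)²) with
the nitrogen weight exactly 1/6 (not the 0.14/0.2 variants also common in
the literature). Intensity profiles are normalised to the no-peptide
reference; a peak missing at a titration point is scored 0 with a
"beyond detection" flag from that point onward.

The affinity ranking is deliberately qualitative. For each reporter
residue the normalised intensity-decay curve is integrated over the
ligand-ratio span and the variant score is the mean of (1 − AUC/span):
larger means faster broadening, i.e. stronger apparent binding in the
fast-to-intermediate exchange regime. Ties within tolerance are reported,
not broken. No Kd is fitted, because the readout being operationalised is
an ordering; the AUC score is this package's operationalisation, not a
literature-standard statistic.

## The synthetic generator

The generator targets the statistical structure the analyses assume — not
physical realism (no excluded volume, no force field, no water).

* **Topology.** A 94-residue toy PDZ-like chain (numbered 243–336) built
  at ideal backbone geometry: helices at (φ,ψ) = (−57°,−47°), strands
  extended at (−139°,135°), loops at PPII-like (−70°,150°); one CB pseudo
  side-chain per residue, and a P atom 2.5 Å beyond CB on `SEP` residues.
  Contact schedules act on the pseudo side-chain atoms, so contacts and
  backbone secondary structure are independent channels.
* **Fluctuations.** Per-atom isotropic Ornstein–Uhlenbeck noise with
  stationary per-coordinate σ (default 0.05 nm, per-residue overridable)
  and relaxation time τ = 1 ns. OU rather than i.i.d. noise makes
  convergence and dwell statistics nontrivial; the planted per-residue
  RMSF is √3·σ. The AR(1) recursion is evaluated with a single
  `scipy.signal.lfilter` pass started from a stationary draw.
* **Contacts.** Telegraph switching sampled in continuous time
  (exponential dwells) and read on the frame grid: stationary occupancy
  k_on/(k_on+k_off), mean contact dwell 1/k_off. In-contact frames place
  atom B at `contact_nm` from atom A (plus 0.01 nm jitter), out-of-contact
  frames at `apart_nm`, with contact < cutoff < apart guaranteed by
  validation.
* **Unfolding.** Region dihedrals interpolate linearly helix→coil across
  the scheduled window; frames are rebuilt from internal coordinates
  (cached per interpolation weight, so static stretches cost one build).
* **Ions.** Na⁺ atoms parked far from the chain, teleported to the
  midpoint of the two sites during scripted bridging intervals.
* **Titrations.** Two-state binding: bound fraction f from the exact
  quadratic equation at [P] = 100 µM and ligand ratios 0→4 (the standard
  titration range here); fast-exchange shifts δ = f·Δδ_max; and a
  phenomenological broadening law I = I₀·exp(−β·f(1−f)·s·w_r) with
  β = 10, exchange scale s = (10 µM)/Kd (slower exchange — more
  broadening — for tighter binding) and w_r the residue's relative shift
  difference, so non-shifting residues do not broaden. Peaks below 5% of
  reference intensity are dropped as broadened beyond detection. Default
  planted Kd values 1/10/100 µM for wt/S280E/S263E give the qualitative
  phenomenology: wt broadens out fastest, S263E barely at all. Noise:
  0.002/0.012 ppm on ¹H/¹⁵N shifts, 2% relative on intensities.

All draws flow from one integer seed; identical seeds give bit-identical
files, which the fixture-manifest test enforces.

## Benchmark problem sizes

The recovery benchmarks run at: 2×10⁵ frames (dt 0.5 ns, Cα-only chain)
for RMSF recovery; 10⁵ frames at dt 0.01 ns with symmetric telegraph
rates of 1/ns (mean dwell 100 frames) for occupancy/dwell recovery; 1000
random boolean series against a brute-force run-length oracle; 500–1000
frame trajectories for unfolding and ion classification; 100 seeded
titration replicates for the affinity-ordering rate; 60 frames for the
three-conformer clustering check. These sizes make every statistical
tolerance (3 standard errors, 5% RMSF band, 95% ordering recovery)
comfortably testable on a single CPU.

## What passing tests do and do not show

Recovery of planted truth demonstrates that the estimators are correct
and correctly calibrated under the generator's assumptions: stationary
Gaussian fluctuations, Markovian contacts, ideal backbone geometry,
two-state fast-exchange binding. Real trajectories violate all of these
in degree — anharmonic and correlated fluctuations, non-exponential
dwells, distorted geometry, intermediate-exchange lineshapes — so
passing tests certify the analysis code, not any claim about the original
trajectories or spectra, which are not redistributable. In particular the
published per-residue RMSF profile is not numerically reproduced (the
atom selection behind it is unstated), and the secondary-structure
panels' exact palette/algorithm are unknown; both analyses are validated
against oracles and planted truth instead.

## Known limitations

* The minimum-image convention assumes an orthorhombic box; triclinic
  boxes are not reduced.
* The DSSP reduction is 4-class; π-helix, turn and bend are reported as C.
* The Kd fit is intentionally absent: ranking is ordinal only.
* The clustering is O(F²) in frames; stride before clustering long runs.
* The generator's ions are scripted, not diffusing, so ion *kinetics*
  (beyond residence fractions) are not meaningful test targets.
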