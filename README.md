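# pdzdyn

Trajectory and NMR-titration analysis of phosphorylation effects in the
Dishevelled-3 (DVL3) PDZ domain — and, more generally, a tested toolkit for
the question "what does phosphorylating a serine (or mutating it to
glutamate) do to a small domain's dynamics and binding?"

The PDZ domain is a ~90-residue interaction module that binds C-terminal
peptides in a groove between its β2 strand and α2 helix. Phosphorylation of
PDZ serines (S263, S268, S280, S311 in hDVL3 numbering, residues 243–338)
can switch peptide binding off, loosen or stiffen the binding groove
allosterically, and reshape the long β2–β3 loop that acts as a secondary
binding site. `pdzdyn` implements the analyses by which such effects are
read out of microsecond MD trajectories and HSQC titrations:

* **Per-residue fluctuations.** RMSF_i = √⟨|x_i(t) − ⟨x_i⟩|²⟩ on a
  Kabsch-aligned trajectory, averaged over replicas with sample standard
  deviation, and ΔRMSF = RMSF(variant) − RMSF(wt) per residue.
* **Contact occurrence statistics.** Distance time series between named
  atoms (e.g. R320:Cζ to the pS263 phosphate), contact defined as
  d ≤ 1.0 nm, and an interaction *counted* only when at least one
  contiguous contact event lasts ≥ 20 ns **and** occupancy exceeds 25% of
  the analysed window; per-variant results are reported as "k/n"
  occurrence ratios over replicas.
* **Ion-mediated bridges.** Frames in which one Na⁺ coordinates two
  anionic sites simultaneously (within 0.35 nm of each), with each ion
  classified *stable* or *diffuse* by its residence fraction.
* **Secondary structure.** A Kabsch–Sander (DSSP-style) hydrogen-bond
  assignment reduced to {H, G, E, C}, per-region helical fraction, and
  hysteresis detection of unfolding/refolding events such as the fast
  breathing of the short α1 helix.
* **Loop conformers.** Daura neighbor-counting RMSD clustering, the
  standard way to count distinct β2–β3 loop conformations.
* **NMR titrations.** Weighted chemical-shift perturbation
  Δδ_obs = √( δ(¹H)² + (δ(¹⁵N)/6)² ), normalised intensity-decay profiles
  with "broadened beyond detection" handling, and a qualitative affinity
  ranking of variants by how fast their reporter peaks (L260, G261, G279,
  G285) broaden — reproducing orderings such as wt > S280E > S263E.

Because microsecond trajectories are not shippable, the package includes a
first-class synthetic-data generator (`pdzdyn.synthetic`) that plants every
one of those signals with analytically known truth: Ornstein–Uhlenbeck
positional noise of stated σ, telegraph contacts with stated rates,
scheduled helix unfolding, scripted bridging ions, and two-state
fast-exchange titrations. Every analysis is tested by recovering what the
generator planted.

## Worked example

Generate the synthetic fixture bundle and run the analyses:

```bash
pdzdyn synth --out fixtures --seed 3
# -> wrote fixture bundle to fixtures (planted RMSF 0.0520 nm)

pdzdyn rmsf --traj fixtures/traj_wt.pdb --top fixtures/toy.pdb --out rmsf_wt.csv
# -> wrote rmsf_wt.csv (94 residues)
head -3 rmsf_wt.csv
# residue_number,rmsf_nm,std_nm
# 243,0.050640,0.000000
# 244,0.050568,0.000000

pdzdyn contacts --traj fixtures/traj_pS263.pdb --top fixtures/toy.pdb \
    --pair "resid 320 and name CB" "resid 263 and name P" --outdir contacts_out
# -> occurrence ratio 1/1; wrote contacts_out/occurrence.json
```

The generator planted per-coordinate σ = 0.03 nm, so the expected
per-residue RMSF is √3·σ ≈ 0.052 nm; the measured 0.0506 nm sits within
the sampling error of the 1 µs-equivalent synthetic run. The planted
R320–phosphate telegraph contact (stationary occupancy 0.8, mean dwell
200 ns) passes both occurrence clauses, hence "1/1". A whole
variant-comparison study (RMSF, ΔRMSF vs wt, the occurrence table,
secondary-structure timelines, loop clustering and CSP tables) runs from
one config file:

```bash
pdzdyn run --config config.yaml
```

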