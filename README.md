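# retgeom

Quantitative geometry and radiation-damage kinetics for retinal-protein
crystal structures.

Atomic-resolution (≤1.3 Å) structures of bacteriorhodopsin resolve individual
atoms, which turns questions about color tuning and proton pumping into
questions about sub-0.1 Å geometry: how twisted is the retinal polyene, how
long are the hydrogen bonds around the Schiff base, which alternate
conformations coexist in the proton release region, and how much of what we
measure is X-ray damage rather than biology. `retgeom` packages those
analyses for structural biologists working with PDB/mmCIF coordinate files:

* **Coordinate I/O** — PDB and mmCIF parsing (via gemmi) into a uniform atom
  model with faithful altloc, occupancy, B-factor and anisotropic-tensor
  handling; PDB v3.3 output; composition census (residues, retinal, lipids,
  waters).
* **Geometry core** — distances, angles, IUPAC-signed dihedrals, geometric
  placement of vinylic hydrogens (1.0 Å, in-plane external bisector), Kabsch
  superposition and common-Cα RMSD.
* **Polyene helicity** — per-bond torsions along the conjugated backbone
  (C5–C6 … C15–Nζ) and the helicity

  η = wrap(180° − torsion) · (−1)ⁿ,

  the per-bond deviation from planarity with alternating parity index *n*;
  ensemble mean ± sample SD and profile comparison with a deviation
  threshold.
* **Hydrogen-bond networks** — distance-criterion N/O···N/O bonds (default
  cutoff 3.2 Å, short-bond flag below 2.5 Å), weak CH···O contacts with the
  C–H···O angle at the inferred hydrogen, per-altloc conformer networks with
  occupancies, and water coordination censuses (complete = 4 partners).
* **Replicate statistics** — distances over ensembles of isomorphous
  structures reported as mean ± sample SD, with the conservative rule that a
  difference is significant only when |Δ| > k·SD (k = 4).
* **Damage kinetics** — sentinel-atom ⟨ΔB⟩ (Asp85 Oδ1/Oδ2, Lys216 Nζ,
  Wat402), through-origin calibration q = k·⟨ΔB⟩, single-exponential dose
  kinetics q(D) = A·(1 − e^(−D/τ)) with a deterministic multi-start fit, and
  the closed-form dose at a tolerated damage fraction.
* **Synthetic structures** — generators for polyenes with exactly prescribed
  torsions, donor/acceptor clusters with alternate conformations, noisy
  replicate ensembles and damage dose series, so the whole pipeline runs and
  is testable without any downloads.

## Worked example

Profile a nearly planar chromophore against a reference with a −10° twist at
C5–C6 (`examples/helicity_profile.py`):

```text
bond      n   eta_study  eta_ref
C5-C6      1       1.5    -10.0
C6-C7      2       3.0      2.0
...
bonds deviating by more than 5 degrees (sorted by |delta|):
  C5-C6: +11.5 deg
  C11-C12: -9.0 deg
  C14-C15: +7.5 deg
```

The `+11.5°` at C5–C6 says the study chain is far closer to planar there than
the reference; only three bonds clear the 5° reproducibility threshold.

Replicate uncertainty and the 4σ rule (`examples/replicate_significance.py`):

```text
Schiff base N to water O: 2.76 +/- 0.02 A (n=3)
difference from reference: -0.100 A, 4*sd = 0.074 A -> significant
```

Three replicates at ~0.02 Å coordinate precision resolve a 0.10 Å shift.

Damage budget under damage-suppressed cryo kinetics
(`examples/damage_kinetics.py`):

```text
calibration on 8 high-dose points: q = 6.54 * <deltaB>  (rmse 0.0049)
exponential fit: plateau A = 0.691, dose constant tau = 2.140 MGy
dose at 5% damage: 0.161 MGy
```

The calibration recovers the simulated slope, and the fitted kinetics say
roughly 0.15 MGy can be spent before 5% of the molecules are damaged.

The other scripts in `examples/` cover conformer-resolved hydrogen-bond
networks and water coordination. A thin CLI mirrors the library:
`retgeom info|helicity|hbonds|compare|damage|simulate --help`.

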