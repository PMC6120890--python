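# Methods

This note records the models, conventions and numerical choices behind
`retgeom`, and what its synthetic generators do and do not emulate.

## Coordinate model and altloc handling

Every conformer of every atom site is its own record with its own occupancy
and B factor, in file order. Selections resolve alternates by policy; the
default `highest_occupancy` keeps one conformer per site, breaking ties by
altloc letter ascending (so "A" wins a 0.5/0.5 split), which matches the
usual "major conformation" language. Residues keep author numbering; no
renumbering is ever applied. Waters are identified by residue code HOH (WAT
and DOD accepted), retinal by RET, and any other HETATM residue counts as
lipid in the composition census — the right default for purple-membrane
crystals, and configurable where deposits use other codes. Composition
counts are over distinct `(chain, res_seq, icode)` keys, so a residue in two
conformations counts once; `protein_atoms` deliberately counts every altloc
record. Parsing and PDB writing go through gemmi; mmCIF `auth_*` numbering
is preferred, with `label_*` as fallback.

## Geometry conventions

Dihedrals follow the right-handed IUPAC convention, reported in (−180°,
180°] with +180° preferred over −180°; the implementation is the
projection/atan2 form, which is stable near 0° and 180°, and is
cross-checked in the tests against an independent reference implementation
to 1e-9°. The torsion is invariant under chain reversal and negates under
mirror reflection. A cross-product norm below 1e-10 Å² (collinear points)
raises a degenerate-geometry error rather than returning noise.

Vinylic hydrogens are placed in the plane of an sp2 carbon and its two heavy
neighbors, 1.0 Å from the carbon along the external bisector — the standard
C–H length assumed when X-ray models carry no hydrogens. CH···O angles are
measured at this inferred hydrogen. Carbons without exactly two heavy
neighbors (detected by a 1.8 Å covalent-distance criterion) yield contacts
flagged `angle_missing` instead of a guessed angle.

Superposition is Kabsch (SVD with reflection correction); the test suite
cross-checks RMSDs against the closed-form quaternion method. Cα RMSD
between two models pairs atoms by the strict `(chain, res_seq, icode)`
intersection — residues missing from either model (disordered loops,
termini) are silently not compared, and the pair count is always reported
alongside the RMSD so the comparison set is explicit. Cα altlocs resolve to
the highest-occupancy conformer before pairing.

## Polyene helicity

The conjugated path is C4–C5–…–C15–Nζ–CE, with C4 and CE as anchors and the
eleven bonds C5–C6 … C15–Nζ indexed; the torsion of bond i–(i+1) is the
dihedral over path atoms (i−1, i, i+1, i+2), always along the main chain and
never through the C19/C20 methyls. The terminal C15=Nζ bond uses (C14, C15,
Nζ, CE). Helicity is η = wrap(180° − torsion)·(−1)ⁿ, wrapped into (−180°,
180°] so η is continuous across the ±180° torsion seam. The parity index n
has no absolute definition in the literature that introduced the formula, so
the origin is calibrated once against a reference structure of known sign:
`calibrate_parity` picks the origin that makes the reference bond's η carry
the published sign (negative at C5–C6 for the twisted reference
conformation). The default origin n = 1 at C5–C6 satisfies this for the
packaged synthetic reference. Ensemble SD uses the n−1 (sample) denominator.

Because the deposited coordinate sets this analysis was designed around
cannot be fetched in an offline build, the packaged reference and
ground-state chromophores are synthetic stand-ins (`synthetic_*` functions,
labelled as such): chains whose per-bond helicities are set to round values
that reproduce the published qualitative picture — a −10° C5–C6 twist in the
reference, a 1.5° near-planar C5–C6 in the ground state, and deviations
above 5° at exactly C5–C6, C11–C12 and C14–C15. Analyses of real deposits
simply read the files and need no stand-ins.

## Hydrogen bonds

Classical hydrogen bonds are distance-defined: all N/O pairs listed in the
donor/acceptor chemistry table within the cutoff (default 3.2 Å), because
deposits carry no hydrogens and published network figures at this resolution
are distance-defined. Detection is over all polar pairs rather than
donor×acceptor products, so a carboxyl–carboxylate contact (one partner
necessarily protonated, as in the proton-release glutamate pair) is still
found; the donor/acceptor orientation in the output is a labelling
heuristic, not a detection criterion. Excluded: 1–2/1–3 pairs within a
residue (a small fixed table: carboxylate O–O, amide O–N, guanidinium N–N,
imidazole N–N), pairs of conformers of the same site, pairs with
incompatible altlocs (A vs B), and any explicitly supplied covalent pairs.
Bonds shorter than 2.5 Å are flagged short — between the ~2.4 Å
low-barrier-type contacts seen in proton-release regions and the ~2.8 Å
standard bond. Neighbor search uses a k-d tree; a brute-force all-pairs
oracle in the tests guarantees exactness. Per-conformer networks are
computed on blank+label submodels, so blank-altloc bonds are shared by every
network, and a network's occupancy is the mean over its member atoms (spread
above 0.05 is logged). Water coordination counts distinct polar heavy-atom
sites within the cutoff; 4 or more is "complete" (tetrahedral).

## Replicate statistics

A distance over an ensemble of isomorphous structures is reported as mean ±
sample SD (n−1), computed at full precision and rounded only for display.
The significance rule is deliberately strict: |mean − reference| must
*exceed* k·SD (default k = 4); equality is not significant, consistent with
"more than k times" phrasing. The ± values are sample SDs, not SEMs.

## Damage kinetics

The sentinel set is the four atoms that inflate fastest under irradiation:
Asp85 Oδ1/Oδ2, Lys216 Nζ and Wat402 O. ⟨ΔB⟩ is the mean of (B_dosed −
B_ref) over that set, using deposited isotropic B. The calibration q =
k·⟨ΔB⟩ is through-origin least squares (k = Σq·ΔB / ΣΔB²) on datasets where
both quantities exist; it is always data-derived at run time, never a
hard-coded constant, and extends q estimates to doses too low for direct
refinement (clipped to [0, 1] with a flag). Kinetics are the two-parameter
saturation q(D) = A·(1 − e^(−D/τ)) with A ∈ (0, 1] free by default (the
plateau is generally unknown; a fixed-A variant exists). Fitting is
deterministic: 16 log-spaced τ starts spanning 0.1–10× the dose range,
bounded least squares in (A, log τ), best SSE wins — no randomness, no seed.
The dose at a tolerated fraction f < A is the closed form −τ·ln(1 − f/A).

## Synthetic generators: what they emulate

* `generate_polyene` builds chains by sequential internal-coordinate (NeRF)
  placement; bond length 1.45 Å and angle 120° are typical of conjugated
  chains and irrelevant to torsion recovery, which is exact to ≪1e-6°.
* `generate_hbond_cluster` places donor/acceptor atoms at exact separations,
  with altloc groups carrying shared occupancies. It makes no attempt at
  realistic residue geometry beyond the specified pair distances.
* `perturb_replicates` models independently refined isomorphous replicates
  as iid Gaussian coordinate noise per axis. Real replicate error is
  correlated along the chain and B-factor dependent; iid noise is the
  simplest model with the right second moments, which is all the replicate
  statistics consume. Two scales are used in the shipped analyses: 0.02
  Å/axis emulates well-ordered core atoms (giving distance SDs near 0.03 Å
  over three replicates) and 0.1/√6 ≈ 0.041 Å/axis emulates whole-chain
  scatter (giving pairwise all-Cα RMSDs near 0.1 Å); real structures show
  exactly this split between core precision and global scatter.
* `generate_dose_series` emulates the experimental design of a damage
  assessment: twelve successive low-dose datasets from 0.01 to 0.23 MGy plus
  four post-burn datasets (0.47–1.19 MGy), with q directly refinable only
  above 0.15 MGy and the ⟨ΔB⟩ proxy available everywhere. Default kinetics
  A = 0.6, τ = 0.5 MGy give a well-resolved saturation curve over that
  schedule (the true experimental plateaus are not published); the
  temperature presets instead fix τ so that 5% damage accumulates by 0.15
  MGy (15 K) or 0.08 MGy (100 K), the published operating points, with the
  plateau held at 0.6. Default noise σ_q = 0.02, σ_b = 0.003 Å². The
  calibration slope default k = 6.7 fraction·Å⁻² matches the published
  relation; in every analysis path the slope is re-derived from the data.

Passing tests on these generators demonstrate the correctness of the
mathematics and the statistical behavior of the estimators under the stated
noise models; they do not validate refinement software, map quality, or any
claim about a particular deposited structure.

## Degenerate inputs and tie-breaks

Occupancy ties in altloc resolution: letter ascending. Dihedral/bisector
degeneracies raise typed errors. The exponential fit refuses series with
fewer than three q observations or zero dose spread. `dose_at_fraction`
refuses f ≥ A. Boundary significance (|Δ| = k·SD) is not significant.
Empty selections and empty hydrogen-bond lists are valid results, not
errors.

## Known limitations

No symmetry expansion (contacts across crystallographic symmetry are
invisible); no bond-order/chemistry perception beyond the small built-in
tables; classical hydrogen bonds carry no angular criterion (impossible
without hydrogens); CH···O placement supports only sp2 carbons with two
heavy neighbors; anisotropic tensors are carried but ⟨ΔB⟩ uses deposited
isotropic B; the damage model is single-exponential by construction and
cannot represent multi-site kinetics.
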