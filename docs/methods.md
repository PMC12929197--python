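# Methods

## The screening problem

Nitrogenase turnover requires a steady supply of low-potential electrons,
delivered to the Fe protein (NifH homodimer, one [4Fe-4S] cluster) by small
protein electron carriers — ferredoxins ([2Fe-2S] or one/two [4Fe-4S]
clusters) or flavodoxins (FMN). Most organisms encode several such carriers,
and midpoint potential alone does not predict which of them can reduce the Fe
protein. `nifcompat` implements a structure-based screen: given docked
carrier/Fe-protein complexes, it measures how close the redox cofactors come
(the edge-to-edge distance *R*), converts distance and potentials into an
electron-tunneling rate, audits the electrostatic complementarity of the
interface, and classifies each carrier.

## Distance measurement

*R* is the minimum Euclidean distance over all cross pairs of "edge atoms" of
the two cofactors. Edge atoms are the Fe atoms for FeS clusters; for FMN they
are the 14 heavy atoms of the conjugated isoalloxazine ring system (N1, C2,
N3, C4, C4A, N5, C5A, C6-C9, C9A, N10, C10), since the ribityl tail and
phosphate are not part of the electron conduit. The FMN subset is a package
choice — distance conventions for flavins vary — and a config switch
(`include_sulfur=True`) optionally adds the inorganic sulfurs to the FeS edge
set; the default is Fe-only. Carriers with two clusters contribute the
cluster nearest the receptor, with exact ties broken toward the lower residue
number. Hydrogens are ignored throughout and only the first alternate
location of an atom is kept.

Per carrier, *R* is averaged arithmetically over the top docking poses
(typically three). The per-pose values are always retained because some
carriers are bimodal — a subset of poses near 10 Å and others beyond 14 Å —
and the mean alone hides that.

## Tunneling-rate model

Rates come from the Moser–Dutton empirical ruler for single-step tunneling:

- exergonic (ΔG⁰ ≤ 0): log₁₀k = 13.0 − (1.2 − 0.8ρ)(R − 3.6) − 3.1(ΔG⁰ + λ)²/λ
- endergonic (ΔG⁰ > 0): log₁₀k = 13.0 − (1.2 − 0.8ρ)(R − 3.6) − 3.1(−ΔG⁰ + λ)²/λ − ΔG⁰/0.06

with R in Å, energies in eV, λ = 0.65 eV (generic cellular reorganization
energy), ρ = 0.76 (protein-medium packing density), and ΔG⁰ = (E_donor −
E_acceptor)/1000 from midpoint potentials in mV. The branches agree exactly
at ΔG⁰ = 0 and satisfy the detailed-balance identity
log₁₀k_en(ΔG) = log₁₀k_ex(−ΔG) − ΔG/0.06. The distance attenuation is
(1.2 − 0.8·0.76) = 0.592 decades per Å. The model deliberately excludes
temperature dependence, nuclear tunneling corrections and multi-step hopping.

The Fe-protein acceptor potential defaults to −415 mV. Reported values for
the ADP-bound protein span −415 to −470 mV; −415 mV is the choice that makes
the model's own worked example self-consistent (a −321 mV donor crosses the
10⁶ s⁻¹ contour at 10 Å, and at 14.7 Å a donor near −800 mV is needed). It is
a configuration parameter everywhere it is used. For carriers with two
distinct cluster potentials the higher (less negative) one is used.

Threshold questions ("what distance/potential reaches 10⁶ s⁻¹?") are solved
on the discrete screening grids — donor potentials −1000…−200 mV in 25 mV
steps (33 values), distances 4…20 Å in 1 Å steps (17 values) — by direct
evaluation, not continuous root-finding: the screen's resolution is the
grid's. Note that at 14.7 Å the grid-exact crossing of the 10⁶ s⁻¹ threshold
under the default acceptor is −775 mV; coarser statements of this number
round it toward −850 mV, and the package reports the grid-exact value.
Comparisons are done in log₁₀ space; linear rates are derived on demand.

## Classification thresholds

- distance: mean R ≤ 10 Å (inclusive), the envelope below which carriers
  known to support nitrogen fixation cluster;
- rate: log₁₀k ≥ 6, the slowest rate computed for a carrier that supports
  nitrogen fixation.

A carrier passing both is `compatible`, failing both `incompatible`, and
disagreeing `marginal` — the third verdict is a package addition, since the
two criteria can genuinely dissociate (short distance with weak driving
force, or the reverse). The rate is evaluated at the mean R rather than as a
mean of per-pose rates (matching how mean rate vs mean distance is normally
plotted); both are emitted, and because the rate is log-linear in R the two
aggregates differ only through Jensen's inequality, in the exergonic branch
by a constant factor.

## Salt-bridge census

A salt bridge is a cross-interface pair of one Arg/Lys and one Asp/Glu whose
side-chain charged-group heavy atoms (Arg NE/NH1/NH2, Lys NZ, Asp OD1/OD2,
Glu OE1/OE2) approach within 4.0 Å — the conventional crystallographic
criterion, exposed as a parameter since interaction calls in docking studies
are sometimes made at other radii. One bridge is counted per residue pair
(closest atom pair recorded). Histidine is excluded (ambiguous protonation),
as are backbone termini. Bridges are mapped onto the conserved R. palustris
Fe-protein hotspots R101, R140, E112, E69, with the homodimer's chains
labeled a/b in ascending chain-id order — arbitrary but deterministic.

## Distance-activity regression

`fit_distance_activity` is ordinary least squares of relative nitrogenase
activity on mean cofactor distance, reporting slope, intercept and
r² = 1 − SS_res/SS_tot. A constant predictor is rejected as degenerate;
constant activity yields r² = 0 by convention. On synthetic cohorts the
planted slope is negative and recovered by the fit; no literature value of
r² is asserted, because published activity sets pair distances from one
study with activities from another and are not reproducible from structures
alone.

## Synthetic complexes: what they emulate and what they do not

`make_toy_complex` emits a standards-conformant PDB pseudo-complex: two
poly-alanine receptor chains (A, B) carrying one idealized cubane [4Fe-4S]
cluster (Fe–Fe ≈ 2.7 Å), and a carrier chain C with the requested cofactor
geometry (cubane SF4, planar FES rhombus, or planar three-ring isoalloxazine
built as fused 1.4 Å hexagons). The ligand cofactor is translated along +x so
that exactly one edge-atom pair realizes the requested R; every other cross
pair is strictly farther by construction, and all contractual coordinates
are laid on a 3-decimal grid so fixed-width PDB output does not perturb
them (round-trip error ≤ 1 mÅ). Requested salt bridges are grafted charged
residues on isolated lanes 14 Å apart, with the primary charged-atom pair at
exactly the requested separation (default 3.5 Å) and all other side-chain
atoms retreating from the partner; decoy charged pairs sit 1.5 Å beyond the
census cutoff. Receptor bridge residues cycle through the hotspot
identities R101a, E112b, R140a, E69b so the hotspot report is exercised.
Every emitted complex is re-measured before return and generation fails
loudly if any contract is violated. Generation is a pure function of the
spec: identical specs give byte-identical PDB text.

These fixtures are *not* docking poses: the protein bodies have no fold,
no realistic interface burial, rotamers or electrostatic surfaces, and the
cofactors are idealized. Passing tests therefore demonstrate that the
measurement and classification machinery is exact on controlled geometry —
not that docking-derived distances are accurate for real complexes.

`make_cohort` plants the statistical structure of a carrier screen: per-role
distance distributions (defaults: nif-linked 8.5 ± 1.0 Å, other bacterial
12.0 ± 1.0 Å, plant 15.5 ± 1.0 Å; truncated to [4, 19.5] Å — above
van-der-Waals contact and below where the activity law would clip at zero),
per-role potentials (−430 ± 60, −400 ± 80, −370 ± 50 mV), cohort sizes
8/8/11, three poses per carrier, and a linear activity law
activity = max(0, 160 − 8·R + N(0, 5)). The distance means mirror the
qualitative group separation seen in carrier screens and are synthetic
choices, not literature values; potentials reflect the typical ranges of
nif-linked bacterial, other bacterial and plant ferredoxins. Roughly half
of the 2[4Fe-4S] carriers are given two distinct cluster potentials to
exercise the higher-potential rule.

## Numerical choices and degenerate inputs

- All distance work is float64; the minimum-distance search uses a full
  pairwise matrix (cofactor edge sets are ≤ 14 atoms, brute force is exact).
- Evaluating the ruler below 3.6 Å warns but proceeds (extrapolation).
- Empty edge-atom sets, absent receptor clusters, malformed PDB coordinate
  fields (reported with line number), zero-variance regression predictors and
  geometrically unsatisfiable generator specs all raise typed errors.
- Threshold solvers return None (not an error) when no grid point qualifies.
- Report serialization is deterministic: carriers sorted by id, fixed field
  order, values rounded to 3–4 decimals for display only.

## Problem sizes

Default test and demonstration sizes — toy complexes of ~200 atoms, cohorts
of 27 carriers × 3 poses, 50-replicate regression-recovery studies on
structure-free cohorts — were chosen so the whole suite exercises every
code path in seconds while keeping all statistical checks comfortably
powered; the generators scale to larger cohorts if needed.

## Known limitations

- The screen inherits every limitation of the docking poses it is fed; it
  does not assess binding kinetics, association/dissociation rates, or the
  conformational ensembles emphasized by dynamic-docking models, and the
  tunneling step it scores is usually not rate-limiting for nitrogenase.
- The FMN edge definition and the 4.0 Å bridge cutoff are conventions, not
  measurements; both are parameters.
- mmCIF input is not supported (PDB text only), and cofactors must already
  be present in the models — the package does not graft clusters onto apo
  structures.
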