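# nifcompat

Structure-based compatibility screening between protein electron carriers
(ferredoxins and flavodoxins) and the Fe protein of nitrogenase.

Biological nitrogen fixation depends on small electron-carrier proteins
delivering low-potential electrons to the Fe protein (NifH), but most
organisms encode several candidate carriers and midpoint potential alone
does not predict which of them works. `nifcompat` screens docked
carrier/Fe-protein complexes in three steps:

1. **Geometry** — detect the redox cofactors ([4Fe-4S], [2Fe-2S], [3Fe-4S]
   clusters and FMN) in a PDB-format complex and measure the edge-to-edge
   distance *R* (Å): the minimum distance between the carrier cofactor's
   edge atoms (Fe atoms; isoalloxazine ring for FMN) and the Fe atoms of the
   Fe protein's [4Fe-4S] cluster.
2. **Rates** — convert *R* and the midpoint potentials into an
   electron-tunneling rate with the Moser–Dutton empirical ruler
   (λ = 0.65 eV, ρ = 0.76):

       exergonic  (ΔG⁰ ≤ 0):  log₁₀k = 13.0 − (1.2 − 0.8ρ)(R − 3.6) − 3.1(ΔG⁰ + λ)²/λ
       endergonic (ΔG⁰ > 0):  log₁₀k = 13.0 − (1.2 − 0.8ρ)(R − 3.6) − 3.1(−ΔG⁰ + λ)²/λ − ΔG⁰/0.06

   with ΔG⁰ = (E_donor − E_acceptor)/1000 eV and the Fe-protein acceptor at
   −415 mV by default.
3. **Classification** — carriers with mean R ≤ 10 Å and k ≥ 10⁶ s⁻¹ are
   called compatible; the package also censuses interface salt bridges
   (Arg/Lys ↔ Asp/Glu within 4.0 Å), maps them to the conserved Fe-protein
   hotspots R101/R140/E112/E69, and regresses nitrogenase activity on
   cofactor distance.

A synthetic-complex generator (`nifcompat.synthetic`) builds PDB
pseudo-complexes with exactly controlled cofactor distances and planted
salt-bridge counts, plus whole carrier cohorts with planted group structure,
so the entire pipeline is testable without docking software. See
`docs/methods.md` for the model details and its limitations.

## Worked example

A plant-type [2Fe-2S] ferredoxin with a midpoint potential of −321 mV docks
with its cofactor 14.7 Å from the Fe protein's cluster. Is that good enough?

```python
from nifcompat import (driving_force, log10_tunneling_rate,
                       max_distance_for_rate, required_potential_for_rate)

dg = driving_force(-321, -415)          # donor vs Fe-protein acceptor
res = log10_tunneling_rate(14.7, dg)
print(f"driving force: {dg:+.3f} eV")
print(f"log10 k at 14.7 A: {res.log10_rate:.2f}  ({res.regime})")
print("max distance for 10^6 1/s:", max_distance_for_rate(-321, -415, 6.0), "A")
print("required potential at 14.7 A:", required_potential_for_rate(14.7, -415, 6.0), "mV")
```

prints

```
driving force: +0.094 eV
log10 k at 14.7 A: 3.39  (endergonic)
max distance for 10^6 1/s: 10.0 A
required potential at 14.7 A: -775.0 mV
```

Transfer is uphill by 94 meV and, at 14.7 Å, nearly three orders of
magnitude too slow for the 10⁶ s⁻¹ viability threshold. Either the cofactor
distance must shrink to 10 Å, or — keeping the geometry — the carrier's
potential would have to drop below −775 mV on the 25 mV screening grid,
lower than any known [2Fe-2S] ferredoxin. Shortening the distance is the
practical engineering route.

The same screen runs on structures:

```python
from nifcompat import (ComplexSpec, make_toy_complex, parse_structure,
                       split_receptor_ligand, nearest_ligand_cofactor,
                       find_salt_bridges)

pdb_text, manifest = make_toy_complex(ComplexSpec(target_R=8.5, n_bridges=3, seed=7))
model = split_receptor_ligand(parse_structure(pdb_text)[0], {"A", "B"})
cof, meas = nearest_ligand_cofactor(model)
print(f"measured R: {meas.R:.3f} A ({cof.kind}); bridges: {len(find_salt_bridges(model))}")
```

prints `measured R: 8.500 A (FE4S4); bridges: 3` — the generator's planted
ground truth, recovered by the measurement pipeline.

## Command line

```
nifcompat simulate --distance 8.5 --bridges 3 --seed 7 --out toy.pdb
nifcompat measure toy.pdb --receptor-chains A,B
nifcompat bridges toy.pdb --cutoff 4.0
nifcompat classify --carriers carriers.tsv --complexes dir/ --acceptor-mv -415
nifcompat grid --acceptor-mv -415 --plot rates.png
```

`classify` expects a carrier TSV (columns: carrier_id, organism, role_class,
potential_mv_1, potential_mv_2, activity; blanks allowed) and complexes
named `<carrier_id>_model<N>.pdb`; it emits a JSON report with per-carrier
distances, rates, verdicts and salt-bridge counts.

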