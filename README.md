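# ugiqc

Analysis pipeline for large covalent acrylamide libraries made by the
ammonia/acrylic-acid Ugi four-component reaction (U-4CR): virtual product
enumeration, plate management, adduct-based mass-spectral detection on two
platforms, cross-platform agreement and stability statistics, and
descriptor-based modelling of precipitation outcomes.

It is written for library chemists and analytical data scientists running
precipitation-first parallel synthesis campaigns: hundreds to thousands of
U-4CR reactions in 96-well plates, products identified by NMR purity and
tracked over storage by acoustic ejection MS (AEMS) and UPLC-MS in
positive and negative ion modes.

## What it computes

- **Enumeration** — for an aldehyde R-CHO and isocyanide R'-NC, the
  product CH2=CH-C(=O)-NH-CH(R)-C(=O)-NH-R' (acrylamide warhead, two
  secondary amides), with elemental composition, monoisotopic mass from a
  pinned isotope table (mass additivity: component sum minus one water),
  and the five descriptors SLogP, TopoPSA, SMR, MW, nHBDon.
- **Detection** — expected m/z for [M+H]+, [M+Na]+ and [M-H]- inside a
  50-650 Da window; best-peak matching at a ppm tolerance with an S/N
  threshold against a median noise floor; any-adduct / all-adducts
  compound rules.
- **Agreement** — confusion matrices (compound- and adduct-level) against
  a reference platform; conservative (both platforms) and permissive
  (either platform) stability estimates; Pearson correlation of AUCs with
  absent compounds stripped.
- **Outcomes** — green/red/black labelling (precipitated + purity > 80% =
  green), per-class descriptor distributions, and a seeded
  random-forest/permutation-importance ranking of descriptors against
  precipitation success.
- **Synthetic campaigns** — a seeded generator producing building blocks,
  reactions, outcomes, purities, two-year survival and per-platform peak
  lists with a ground-truth ledger (see `docs/methods.md`).

## Worked example

```python
from ugiqc import BuildingBlock, assemble_product, compute_descriptors
from ugiqc.detection import DEFAULT_ADDUCTS, adduct_mz

ald = BuildingBlock(id="ALD1", role="aldehyde", smiles="O=Cc1ccccc1")
iso = BuildingBlock(id="ISO1", role="isocyanide", smiles="[C-]#[N+]C(C)(C)C")
p = assemble_product(ald, iso)
print(p.smiles, p.composition.hill_formula(), round(p.monoisotopic_mass, 4))
d = compute_descriptors(p.smiles)
print(f"slogp {d.slogp:.3f} topopsa {d.topopsa:.2f} nhbdon {d.nhbdon}")
for a in DEFAULT_ADDUCTS:
    print(a.name, round(adduct_mz(p.monoisotopic_mass, a), 4))
```

prints

```
C=CC(=O)NC(C(=O)NC(C)(C)C)c1ccccc1 C15H20N2O2 260.1525
slogp 1.945 topopsa 58.20 nhbdon 2
[M+H]+ 261.1598
[M+Na]+ 283.1417
[M-H]- 259.1452
```

i.e. the benzaldehyde / tert-butyl-isocyanide product is a 260.1525 Da
acrylamide with two amide N-H donors, and its three singly charged adduct
targets all fall inside the 50-650 Da acquisition window.

From the shell, a whole synthetic campaign and its report:

```sh
ugiqc --seed 7 simulate --out campaign/
ugiqc report campaign/ --out report/
```

`report/report.json` contains the precipitation rate (raw fraction and
whole-percent, e.g. 0.632 → "63%"), the retained-library count, per-platform
detection rates, conservative/permissive stability estimates, compound- and
adduct-level confusion matrices, AUC correlations per mode, and the paths
of per-plate success-heatmap grids; the effective configuration is echoed
into the report for provenance.

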