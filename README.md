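# eetnet

Pigment-network analysis for photosynthetic supercomplex structures:

* **structure_io** — read mmCIF/PDB (via biotite), resolve altlocs
  deterministically, extract pigment/lipid cofactors into a typed inventory,
  and produce census tables. Component-code and chain-naming maps are
  profile-driven (`src/eetnet/profiles/`); carotenoid codes can be inferred
  from an mmCIF `chem_comp` table.
* **fret** — Qy transition dipoles from the NB→ND chlorin axis, the
  orientation factor κ² = (û_D·û_A − 3(û_D·R̂)(û_A·R̂))², Förster rates
  k = C·κ²/(n⁴r⁶) with C = 32.26, n = 1.55 and r the Mg–Mg distance in nm,
  and lifetime-filtered undirected rate networks over chlorophyll-a pairs
  within a strict 30 Å Mg–Mg cutoff. Export to edge CSV / GraphML / JSON.
* **contacts** — shortest inter-pigment distances (phytol tails excluded by
  default), carotenoid–chlorophyll contact maps, Mg axial-ligand detection,
  distance-only polar-contact (H-bond proxy) search, and two-layer
  (stromal/lumenal) classification of chlorophylls along the
  covariance-smallest membrane normal with an exact 1-D 2-means split.
* **synthetic** — declarative structure fixtures with analytic ground truth
  (census, closed-form rate edges, planted layer partitions), written as
  legal mmCIF/PDB; see `docs/fixture-spec.md`.
* **report / cli** — an end-to-end pipeline (`eet run`) that writes census,
  full and lifetime-filtered networks, contact/ligand/layer tables, and an
  optional pass/fail comparison against a YAML expectation file
  (`src/eetnet/expectations/8wb4.yaml` ships the published reference values
  for PDB entry 8WB4).

## CLI

```sh
eet census   --structure toy.cif --profile default
eet fret     --structure toy.cif --cutoff 30 --tau 10 --out net.graphml
eet contacts --structure toy.cif --threshold 5 --out contacts.csv
eet ligands  --structure toy.cif --cutoff 3.5 --out ligands.csv
eet layers   --structure toy.cif --stromal-ref 0,0,100 --out layers.csv
eet fixture  --spec spec.yaml --out toy.cif --truth truth.json
eet profile-infer --structure entry.cif      # carotenoid codes from chem_comp
eet run      --config run.yaml               # full pipeline + expectations
```

`--profile` accepts a bundled profile name (`default`, `8wb4`) or a YAML path
with `code_map`, `naming_map`, optional `monomers` and `infer_carotenoids`
sections.

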