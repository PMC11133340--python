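# Synthetic fixture spec (YAML schema)

`eet fixture --spec spec.yaml --out toy.cif --truth truth.json` and
`eetnet.FixtureSpec.from_yaml` consume this schema:

```yaml
seed: 17             # drives the positional noise only
noise_sigma: 0.0     # angstrom; Gaussian per coordinate, applied to the
                     # written file AFTER the ground truth is computed.
                     # Keep 0 when exact edge oracles are wanted.
placements:
  - kind: CHL_A      # one of CHL_A, CHL_C, ALX, ACAR, CRO, MON, LMG, SQD, LHG
    chain: A
    resnum: 601
    position: [0.0, 0.0, 0.0]     # Mg position for chlorophylls, anchor else
    dipole: [0.0, 0.0, 1.0]       # unit vector; chlorophylls only
    extra_atoms:                  # optional extra atoms for this residue
      - {name: C7, element: C, position: [3.0, 0.0, 0.0]}
  - kind: ALX        # non-chlorophylls without extra_atoms get a default
    chain: B         # 5-carbon chain along +x from the anchor
    resnum: 615
    position: [0.0, 5.0, 0.0]
two_layer:           # optional: marks the planted two-layer ground truth
  z_low: 0.0
  z_high: 18.0
  n_low: 10
  n_high: 7
```

Rules enforced by validation:

* residue identities (`chain`, `resnum`) are unique;
* every chlorophyll has a unit-norm `dipole`;
* `noise_sigma >= 0`.

Chlorophyll placements are written as a residue with `MG` at `position` and
`NB`/`ND` ring nitrogens 1 A on either side along `dipole`, so the NB->ND
axis realizes the requested direction exactly.  Chlorophyll a reuses the real
`CLA` component code (the default code map applies); the fixture-local codes
for the other kinds are in `eetnet.synthetic.FIXTURE_CODE_MAP`.

The ground-truth JSON contains the expected census, the analytic edge list
(all chlorophyll-a pairs under the Mg-Mg cutoff, computed in closed form from
the spec vectors without touching the file) and the planted layer labels.
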