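# iortsim

Desk-scale Monte Carlo electron dose engine and dosimetric analysis toolkit
for intraoperative electron radiotherapy (IOERT) shielding-disc studies.

The package models a mobile-linac beamline (titanium exit window, PMMA
collimation, water phantom) with a two-layer Al–Pb shielding disc in
arbitrary pose (depth, lateral shift, tilt, 180° flip), transports electrons
with a vectorized condensed-history scheme (restricted collision losses,
Møller δ-rays, Highland multiple scattering, Bohr straggling, banked
bremsstrahlung photons with kerma-approximation transport), scores energy on
a voxel grid, and computes the full dosimetric metric set:

- percentage depth dose (PDD) and lateral profiles, with reference
  parameters R100/R90/R50/R30/R10/Rp, field size, symmetry, homogeneity
- beam-quality energies Ē0 (TRS-398, from R50) and E0p (AAPM, from Rp)
- shielding factor SF = 100·(1 − Dd/Dnd) over the normal-tissue region
- backscattering factor (BSF) curve and maximum proximal to the disc
- maximum leakage dose (MLD) scaled to a 23 or 21 Gy prescription
- dose–volume histograms and the under-80% fraction of the treatment zone
- film-based disc-misalignment estimation (50% isodose centroid offset)
- source-model calibration by coordinate descent against reference curves

## CLI

Configuration is a strict TOML schema (unknown keys rejected); dose grids
are MetaImage `.mhd`/`.raw` pairs with a JSON stats sidecar.

```bash
iortsim describe  --config run.toml                  # geometry table
iortsim simulate  --config run.toml --out dose.mhd   # run the Monte Carlo
iortsim analyze   dose.mhd --config run.toml \
                  [--no-disc-ref ref.mhd] --out metrics.json
iortsim calibrate --ref refs.csv --config run.toml \
                  --param mean_energy=7.9,8.1,8.3 --budget 10 --out cal.json
iortsim film-check dose.mhd --config run.toml        # misalignment estimate
iortsim fixtures  analytic_pdd --param r50=34.8 --out curve.csv
```

Minimal config:

```toml
seed = 1

[source]
preset = "10MeV"          # or mean_energy = 8.1, sigma_energy = 1.1, ...

[disc.pose]
depth = 24.5              # mm; lateral_shift / tilt / flipped optional

[transport]
n_histories = 200000
n_batches = 10

[scoring]
voxel_size = 0.5          # mm, isotropic over the 70x150x150 mm detector
```

Every run logs seed, config hash and version for reproducibility; results
are deterministic for a fixed seed (single worker).

## Package layout

| module            | contents                                                  |
|-------------------|-----------------------------------------------------------|
| `materials`/`physics` | material library (CSV), stopping powers, CSDA range, Highland sigma, photon attenuation |
| `geometry`        | beamline/phantom/disc model, point classification, exact ray–boundary distances |
| `source`          | Gaussian beam model, presets, primary sampling            |
| `transport`       | vectorized condensed-history engine, single-particle step APIs |
| `scoring`         | voxel grid, dose conversion, regions, batch uncertainty   |
| `analysis`        | curves, reference points, SF/BSF/MLD/DVH/film metrics     |
| `calibration`     | match report and coordinate-descent source tuning         |
| `config`/`mhd`/`cli` | TOML schema, MetaImage I/O, command-line interface     |
| `fixtures`        | synthetic grids/curves/films with known ground truth      |
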