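# atriofiber

Automated construction of left-atrial computational models:

1. **Segmentation** — statistics-based tagged segmentation of the atrial
   wall from a contrast voxel image (pooled sample statistics → thresholds
   `LT = mean_myo − 3·sd`, `UT = mean_blood + 3·sd`, `MT = mean of means`;
   dilation-grown wall capped at 3 mm; MV/PV orifice tagging from 3-point
   cutting bodies; constrained level-set smoothing with a 50%-of-voxel
   displacement cap and isotropic 100 µm resampling).
2. **Atlas & regions** — landmark transfer (nearest-neighbor via a
   topology-preserving registration), derived landmarks, Dijkstra
   auxiliary lines on corridors, and region growing into a partition with
   per-region Laplace boundary assignments.
3. **Surface fibers** — per-region Laplace solves (`u=0` / `u=1` /
   zero-flux); fiber axis = normalized in-plane gradient (optionally
   rotated 90° for encircling patterns around orifices); neighbor fill,
   interregional smoothing, tangential projection.
4. **Transmural fibers** — transmural Laplace coordinate φ, endo↔epi
   correspondence by exact element-hopping field-line tracing, and
   per-tetrahedron blending with 2-layer / 5-layer / linear / sigmoidal
   interpolation weights, projected orthogonal to the local field line.
5. **Electrophysiology** — monodomain reaction–diffusion with the
   Courtemanche–Ramirez–Nattel atrial cell model (Rush–Larsen gates,
   implicit lumped-mass diffusion, 10 µs global step), steady-state
   pacing, conductivity fitting to 1.20 / 0.40 m/s conduction velocities,
   and −20 mV local-activation-time maps, plus a random-fiber isotropic
   reference.

No clinical data are required: the `synthetic` package generates voxel
phantoms, slab meshes, and an ellipsoidal shell-atrium with PV/MV/LAA
openings, a 20-landmark mini-atlas, and an 11-region atlas with
constructive ground-truth labels.

## CLI

```sh
atriofiber run --config config.yaml --out out/          # full pipeline
atriofiber phantom shell-atrium --out out/              # synthetic inputs
atriofiber segment --config config.yaml --out out/
atriofiber smooth --config config.yaml --out out/
atriofiber regions --config config.yaml --out out/
atriofiber fibers-surface --out out/
atriofiber fibers-volume --scheme five_layer --out out/
atriofiber fit-cv --cvl 1.2 --cvt 0.4 --res 0.2 --out out/
atriofiber simulate --config config.yaml --out out/
```

The YAML config is schema-validated (unknown keys rejected); every stage
records its outputs with SHA-256 hashes in `out/manifest.json`, so
deterministic stages are byte-for-byte reproducible across reruns.

Meshes are read/written in CARP text format (`.pts`/`.elem`/`.lon`, mm,
with a `units=` option) and legacy-ASCII VTK; voxel images as NIfTI-1 or
uncompressed MetaImage (`.mha`).

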