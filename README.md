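# cloudvol

Point-cloud to body-volume pipeline for livestock phenotyping: smooth a
surface point cloud, estimate and consistently orient normals, reconstruct
a watertight triangle mesh with a screened ("improved") Poisson solve over
an octree-partitioned domain, compute volume by signed tetrahedral
summation, and fit/evaluate a linear volume → body-weight model.

## Pipeline stages

| Stage | Module | Method |
|---|---|---|
| Smoothing | `cloudvol.smoothing` | Moving-least-squares projection onto local polynomial height fields |
| Normals | `cloudvol.normals` | Local-PCA normals; maximum-spanning-tree sign propagation over a KNN graph with tangency-corrected edge weights (inward convention) |
| Reconstruction | `cloudvol.poisson` | Indicator-function Poisson solve (`Delta chi = div V`) and screened variant (`(Delta - lambda I) chi = div V`) with dynamic per-sample confidence weights `tau`; quadratic B-spline splatting; marching-cubes isosurface at the mean sample indicator value |
| Volume | `cloudvol.volume` | Signed tetrahedral summation with face-orientation repair; slice-integration baseline (convex-hull contours) |
| Weight model | `cloudvol.weight` | Closed-form least squares, Pearson r, R², absolute/relative error statistics |
| Fixtures | `cloudvol.synthetic` | Analytic-volume primitives (cube, cylinder, sphere, L-prism, thin plate), a composite piglet shape with constructive-mesh ground truth, burr/outlier/occlusion corruption, volume-weight tables |

## CLI

All stages are exposed through a single `cloudvol` entry point:

```sh
cloudvol synth shape --kind cube --density 1e4 --seed 1 --out cube.ply
cloudvol smooth --in cube.ply --out smoothed.ply --k 30 --basis quadratic --bandwidth 2.0
cloudvol normals --in smoothed.ply --out oriented.ply --k-pca 20 --k-graph 10 --mode tangency
cloudvol reconstruct --in oriented.ply --out mesh.ply --depth 8 --method improved --lambda 4.0
cloudvol volume mesh --in mesh.ply
cloudvol volume slicing --in cube.ply --axis z --interval auto

cloudvol synth table --n 300 --a 1070.4 --b -1.6524 --sigma 3.0 --seed 1 --out table.csv
cloudvol weight fit --table table.csv --out model.json
cloudvol weight predict --model model.json --volume 0.1

cloudvol pipeline --in cube.ply --out-mesh mesh.ply --out-report report.json --depth 8
```

`cloudvol pipeline` also accepts `--config file` where the file is JSON or
flat `key=value` lines mirroring every flag; the JSON report contains the
volume, signed raw sum, facet count, per-stage timings and (when a model
is supplied) the predicted weight.

File formats: XYZ text, PLY (ASCII and binary little-endian), OBJ.

## Notes

- Units are opaque: volumes are reported in (input unit)³.
- Normals follow the inward convention throughout; `mesh_volume` takes the
  absolute value of the signed sum, so results are convention-independent.
- Octree depth is limited to 9 for the dense solver (memory); the
  validated argument range is [4, 12].
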