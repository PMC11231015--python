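# sonocomplete

Shape completion for lumbar vertebrae seen in 3D ultrasound.

Spinal ultrasound shows only the posterior surface of each vertebra: bone
reflects almost all acoustic energy, so everything beneath the first bone
interface is lost to acoustic shadowing, interfaces nearly parallel to the
beam return no echo (grazing incidence), and scattering introduces further
occlusion. Clinicians mentally complete the hidden 3D anatomy; this package
does it computationally, for applications such as facet-joint and epidural
injection guidance where the target lies in the occluded part.

It is aimed at researchers in ultrasound-guided spine interventions and
medical 3D shape analysis, and provides the full pipeline:

1. **Synthetic training data.** Per-vertebra meshes come from labeled CT
   volumes (NIfTI label maps), standard mesh files, or a built-in procedural
   generator of stylized five-level lumbar spines (so nothing external is
   required). Spines are reposed rigidly along sampled sagittal curvatures
   (sitting flexes, prone mildly extends), then partial views are produced
   by first-hit ray casting from virtual probes over each spinous process
   with an incidence-angle cut, a scattering pass (a laterally shifted scene
   copy additionally occludes the original), per-vertebra masking, and
   neighboring-cloud fusion that emulates imperfect level separation.
2. **Completion network.** A coarse-to-fine variational model: permutation-
   invariant encoders produce a latent shape *prior* from the partial cloud
   and a *posterior* from the complete cloud (training only); a decoder maps
   the latent and global feature to a coarse completion, refined by
   multi-scale neighborhood self-attention over the concatenated partial +
   coarse cloud. Training minimizes `w·KL(q‖p) + CD(coarse, gt) + CD(fine, gt)`;
   inference decodes the prior mean (a MAP point estimate, deterministic).
3. **Evaluation.** Chamfer distance (squared, mean per direction, ×10⁴ on
   unit-normalized clouds), exact-assignment Earth Mover's Distance,
   Knapitsch-style F1, plus anatomy-aware measures: Chamfer distance between
   spinous-process centerline annotations (SP-CD) and the Euclidean error of
   facet-joint centers against ground truth, with 5 mm as the accepted
   tolerance for injection delivery.
4. **Post-processing.** Completed clouds are meshed by Poisson surface
   reconstruction of density-estimated, consistently oriented normals.

## Worked example

```python
import numpy as np
from sonocomplete import (
    VertebraParams, make_spine, OcclusionConfig, generate_dataset,
    PRESETS, train, chamfer,
)
from sonocomplete.completion_model import make_sphere_benchmark

# 1. a synthetic five-level lumbar spine (stylized, deterministic)
spine, landmarks = make_spine(params=VertebraParams(resolution=2.5), seed=3)
print("levels:", [lab for lab, _ in spine.levels])

# 2. ultrasound-consistent partial views paired with complete ground truth
cfg = OcclusionConfig(grid=(32, 32, 60.0), n_points=256, n_gt=256)
pairs, manifest = generate_dataset([spine], cfg, seed=1)
vis = [m["n_partial_raw"] for m in manifest if m["status"] == "ok"]
print(f"{len(pairs)} training pairs, raw visible points per vertebra: {vis}")
part, gt = pairs[2].partial.points, pairs[2].complete.points
print(f"L3 identity-baseline CD (x10^4, normalized): {chamfer(part, gt):.1f}")

# 3. smoke-scale learning check: spheres with an occluded cap
bench = make_sphere_benchmark(200, PRESETS["smoke"], seed=0)
model, history = train(bench, PRESETS["smoke"])
i = history["split"]["test"][0]
pair = bench[i]
g, prior = model.encode_partial(pair.partial.points)
fine = model.refine(pair.partial.points[None], model.decode_coarse(prior.mean, g))
print(f"held-out sphere: CD(partial, gt) = {chamfer(pair.partial.points, pair.complete.points):.1f}, "
      f"CD(completion, gt) = {chamfer(fine.value[0], pair.complete.points):.1f}")
```

Output:

```
levels: ['L1', 'L2', 'L3', 'L4', 'L5']
5 training pairs, raw visible points per vertebra: [28, 49, 61, 60, 40]
L3 identity-baseline CD (x10^4, normalized): 2376.2
held-out sphere: CD(partial, gt) = 970.0, CD(completion, gt) = 179.3
```

The occlusion simulator leaves only a few dozen visible surface points per
vertebra — the posterior arch — out of the 256-point ground truth, and the
smoke-trained completion cuts the held-out Chamfer distance to well under
half of the identity baseline (the partial cloud itself).

## Command line

`sono-complete` exposes the pipeline stages as subcommands:

```sh
sono-complete fixtures  --out runs/demo --seed 1          # synthetic spines
sono-complete gen-data  --out runs/demo --shift-mm 2      # partial/complete pairs
sono-complete train     --data runs/demo --preset smoke
sono-complete complete  --input partial.ply --checkpoint runs/demo/checkpoints/model.npz --out completed
sono-complete evaluate  --pred completed_fine.ply --gt gt.ply --out report.csv
sono-complete reconstruct --input completed_fine.ply --out mesh.ply --depth 6
sono-complete run       --out runs/demo                   # everything, in order
```

`gen-data --no-scatter --no-fusion --max-incidence-deg 180` reproduces the
simplified, physics-free generation used as an ablation condition;
`--fusion-fraction 0` disables only the neighboring-cloud fusion.

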