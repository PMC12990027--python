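# jawmotion

Turn four static occlusal records of a mandibular arch — STL meshes captured
at maximum intercuspation (MIP, or centric occlusion for edentulous cases),
right laterotrusion, left laterotrusion and full protrusion, all expressed in
a common frame anchored to the fixed maxillary arch — into a continuous,
time-sequenced mandibular motion trajectory, exported as a CAD-compatible XML
jaw-motion file (`.xml` or `.jawMotion`).

The pipeline is scanner-agnostic: it consumes only STL geometry.

## How it works

1. **`mesh_io`** reads the four STL records (binary or ASCII, auto-detected),
   merging the triangle soup into an indexed mesh by exact coordinate
   equality.  Coordinates are interpreted as millimetres.
2. **`registration`** estimates, per excursive record, the rigid transform
   (unit quaternion + translation) carrying the MIP mesh onto it.  Records
   that still share vertex ordering use the closed-form least-squares fit
   (SVD with reflection correction); remeshed records fall back to iterative
   closest point.  `rebase_anchor` inverts transforms captured with the
   mandible as the registration anchor.
3. **`motion`** inserts a user-defined number of transitional frames
   ("quantified points") between consecutive static records — shortest-arc
   SLERP for rotation, linear interpolation for translation — and assembles
   the closed-loop trajectory MIP → protrusive → MIP → right → MIP → left →
   MIP at a uniform frame interval.  With the default 100 points per segment
   this yields 607 frames (7 keyframes + 6 × 100).
4. **`jawmotion_export`** serializes the trajectory as timestamped 4×4
   homogeneous matrices in an open, documented XML dialect
   (see `docs/jawmotion-schema.md`) and parses it back for verification.
5. **`synthetic_jaw`** generates parametric arch meshes with ground-truth
   excursive poses, so the whole pipeline is testable without scan data.
   Its default magnitudes (8 mm protrusion, 10° laterotrusion, 50 mm condyle
   offset) are clinically plausible placeholders, not measured values.

## CLI

```sh
# synthetic record set with known ground truth (4 STL files + truth.xml)
jawmotion fixture --out-dir fixtures/ --seed 42

# generate the motion file from four labelled records
jawmotion generate \
    --mip fixtures/mip.stl \
    --right fixtures/right_laterotrusive.stl \
    --left fixtures/left_laterotrusive.stl \
    --protrusive fixtures/protrusive.stl \
    -o motion.xml --frames-per-segment 100

# validate and summarize an existing motion file
jawmotion inspect motion.xml
```

Useful flags: `--extension-mode jawMotion` (identical payload under the
`.jawMotion` extension), `--sequence` (playback order; must start and end at
MIP), `--no-icp` (require corresponded records), `--json-summary`
(machine-readable result line on stdout), `--show-config`.  Logs go to
stderr; exit status is 0 iff a valid output file was produced.

## Scope notes

Clinical scanning, prosthesis design in third-party CAD, condylar-path
curvature, Bennett side-shift and neuromuscular dynamics are out of scope:
the trajectory is a simplified piecewise interpolation between static
extremes at a fixed vertical dimension.
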