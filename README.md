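# rangewedge

Measurement-based evaluation of proton range uncertainty, plus a daily
CBCT dose-verification workflow, on fully synthetic phantoms.

The core method: a 2D detector plane measured behind a wedge-shaped target is
compared against candidate 2D planes extracted at 1-mm spacing from a 3D
proton dose computed on CT or CBCT (each converted with its own HU→density
table). The depth whose plane maximizes the 3 mm/3% gamma passing rate is the
apparent measurement depth; its offset from the physical detector depth,
normalized by the water-equivalent path length (WEPL) to the detector, is the
percentage range error. Because the wedge's distal surface slopes laterally,
sub-millimetre depth offsets translate into lateral displacements of the dose
gradient that the gamma comparison resolves.

Everything a treatment-planning system and a physical detector would provide
is replaced by first-class synthetic components: an analytic Bragg-curve
pencil-beam dose engine, digital head/thorax phantoms with a wedge target on
a solid-water base, per-tissue-class CBCT HU distortion, and simulated
ion-chamber-array measurements (10-mm pitch).

## Modules

| module | contents |
|---|---|
| `rangewedge.grids_io` | `ImageGrid` / `PlanarDose` / `StructureMask` / `RigidTransform`; DICOM CT series and RT Dose I/O (built-in minimal explicit-VR codec); detector-plane ASCII; rigid resampling; even–odd polygon rasterization |
| `rangewedge.hu_density` | piecewise-linear HU→density tables per modality, group-based CBCT calibration from VOI samples (with pool-adjacent-violators monotonicity repair), density→relative-stopping-power lookup, solid-water overrides |
| `rangewedge.proton_sim` | two-sided Gaussian/plateau Bragg model, WEPL ray tracing, layered spot-beam dose engine, wedge-plan optimizer (nonnegative least squares with ±3.5% range-scenario robustness), digital phantoms, CBCT distortion, detector simulation |
| `rangewedge.gamma` | 2D gamma index (3 mm/3%, global normalization, 10% threshold) with a brute-force oracle |
| `rangewedge.range_eval` | depth sweep, passing-rate maximization with parabolic refinement, percentage range error |
| `rangewedge.monitor` | DVH computation, V100%/Dmean/Dmax metrics, daily verification reports, fraction trending |

## CLI

```bash
# generate a full synthetic study (DICOM CT + CBCT, beam, RT Dose, measurement)
rangewedge simulate --site head --seed 1 --out study/

# gamma-compare two detector ASCII planes
rangewedge gamma --ref study/measurement.txt --eval plane.txt --dd 3 --dta 3

# range-error sweep: CSV of depth / pass rate / range error + best estimate
rangewedge range-eval --image study/ct --table study/hu_density_ct.yaml \
    --rsp study/rsp.yaml --beam study/beam.yaml --meas study/measurement.txt \
    --window 10 --step 1 --out sweep.csv

# daily verification and trending
rangewedge verify --plan-image study/ct --daily study/cbct --xform reg.txt \
    --table cbct.yaml --rsp study/rsp.yaml --beam study/beam.yaml \
    --target-mask study/wedge_mask.npy --out fx1.json
rangewedge trend --reports reports/ --out trend.csv
```

## Conventions

Right-handed frame, mm units, voxel-center geometry; `values[i, j, k]` maps
to `origin + (i, j, k) * spacing`. Axis 1 is the anterior–posterior beam
axis. The measurement is always the gamma reference. Positive range error
means the calculation overestimates range (the measured pattern is found at a
deeper calculated plane). The percentage denominator is the central-axis WEPL
from the phantom entry surface to the physical detector plane.
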