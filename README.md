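# mtpm — tissue phase mapping for murine cardiac MRI

`mtpm` analyses **tissue phase mapping (TPM)** data: phase-contrast cine
MRI of the beating mouse heart in which myocardial velocity is encoded in
the phase of the MR signal.  It takes the four scans acquired per
short-axis slice — one motion-compensated reference and three
motion-encoded acquisitions (x, y, z) — and turns them into voxelwise
velocity maps, regional velocity time courses on the American Heart
Association (AHA) 16-segment model, left-ventricular twist and torsion,
and method-agreement statistics.  It is written for small-animal MR
physicists and cardiac phenotyping labs who want a tested, scriptable
replacement for ad-hoc reconstruction/analysis code, and it ships a
synthetic phantom with analytically known kinematics so every stage of
the chain can be validated end to end without scanner data.

## Method

Reconstruction. Each acquired k-space frame is apodized with a radial
Butterworth window, H(k) = 1 / (1 + (|k|/k_c)^(2n)) with order n = 3 and
cutoff k_c at the acquired Nyquist radius, isotropically zero-filled by a
factor of two (128 → 256, 200 µm → 100 µm voxels at 25.6 mm FOV) and
inverse Fourier transformed.  Velocity follows from phase subtraction
against the reference scan,

    v = venc · Δφ / π,   Δφ = arg(S_ref · conj(S_enc)) ∈ [−π, π),

with venc = 6 cm/s in-plane and 8 cm/s through-plane; the magnitude image
used for segmentation is the sum of the four scan magnitudes.  Residual
eddy-current phase offsets are removed per frame by fitting
v ≈ a + b·x + c·y over a static agarose reference region and subtracting
the plane from the whole map.

Kinematic analysis. Inside the epicardial/endocardial contours, bulk
motion is removed by subtracting the mask-mean of each component; the
in-plane velocities are then expressed in polar coordinates about the
per-frame centre of mass: radial velocity v_r (positive toward the
centre, i.e. contraction) and tangential velocity v_φ (positive =
clockwise viewed foot-to-head).  Slices are partitioned into 6 (basal,
mid) or 4 (apical) equiangular AHA segments, each split at its median
voxel radius into epicardial and endocardial compartments.

Twist and torsion. Per segment the angular velocity v_rot = v_φ / r
(rad/s) is integrated from end-diastole to end-systole,

    φ_twist = ∫_ED^ES v_rot dt   (reported in degrees),

and torsion per wall is apical minus basal twist.  Agreement between two
acquisitions is quantified by ordinary least-squares regression with a
t-test of slope = 1 and Bland–Altman bias with ±2 SD limits of
agreement; regional synchrony by correlating 24 angular sectors' mean
v_r series with the global time course.

The phantom is a contracting, twisting, base-to-apex-moving annulus plus
a static reference block, with smooth closed-form kinematics (peak
systolic mean radial velocity ≈ 0.8 cm/s, basal twist ≈ +2.5°, apical
≈ −2.6°), complex Gaussian noise, optional background phase planes and
an optional artifact-corrupted sector.

## Worked example

```python
from mtpm import PhantomSpec, ReconConfig, generate_cine, reconstruct_velocities
from mtpm.dataio import LVSegmentation
from mtpm.cli import analyze_slice

spec = PhantomSpec.default("basal", seed=42)          # noisy basal slice
cine, seg, truth = generate_cine(spec, domain="kspace")
matrix = cine.meta.matrix * 2                          # zero-filled grid
seg_hi = LVSegmentation.from_contours(seg.epi_contours, seg.endo_contours,
                                      matrix, cine.meta.fov_mm / matrix,
                                      reference_polygon=seg.reference_polygon)
vel = reconstruct_velocities(cine, ReconConfig(),
                             static_reference_mask=seg_hi.static_reference_mask)
res = analyze_slice(vel, seg_hi)
print(res.twist_df.query("compartment == 'full'")[["segment", "name", "twist_deg"]])
```

prints the per-segment basal twist

```
 segment          name  twist_deg
       1      anterior   2.529900
       2  anteroseptal   2.465225
       3  inferoseptal   2.507764
       4      inferior   2.587164
       5 inferolateral   2.388456
       6 anterolateral   2.496699
```

i.e. a clockwise basal rotation of ≈ 2.5° between end-diastole and
end-systole (frame 12 of 20, detected from the minimum cavity area),
which matches the phantom's closed-form value of 2.487° for this
transmural profile to well under 2%.  `res.peaks_df` holds the segmental
peak systolic/diastolic velocities (here ≈ +0.81 cm/s systolic radial),
and `torsion_table` on an apical and a basal twist table gives the
wall-wise torsion with the identity torsion = apical − basal twist.

The same pipeline is scriptable from the shell:

```sh
mtpm simulate --slice basal --seed 42 --out data/
mtpm recon    --in data/ --out recon/
mtpm analyze  --vel recon/ --contours recon/contours.json --out results/
mtpm pipeline --seed 7 --out study/       # all three slices + torsion
```

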