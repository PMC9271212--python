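# gerikit

Quantitative analysis of **live-brain Arc-mRNA transcription imaging**, for
labs that tag endogenous immediate-early-gene (IEG) transcripts with a
genetically encoded RNA indicator (GERI: PP7 stem-loops in the 3′ UTR bound
by a coat-protein–GFP fusion) and image transcription sites (TSs) in vivo by
two-photon microscopy, alongside calcium imaging and behavior.

The package covers the full analysis stack on which such experiments rest,
and ships synthetic-data generators with exact ground truth so that every
stage is testable without any raw imaging data:

| stage | module | what it does |
|---|---|---|
| image registration | `gerikit.registration` | phase-correlation motion correction against the red (autofluorescence) channel, cross-day rotation+translation alignment, max-normalized channel subtraction, 45-frame averaging, two-ROI stitching |
| segmentation | `gerikit.segmentation` | circular-Hough nucleus finding in XY/XZ, TS detection with the *two-consecutive-z-slices* rule (1–2 spots per nucleus), Arc+/Arc−/ND calling, two-Gaussian intensity thresholds, time-lapse TS linking |
| smFISH | `gerikit.smfish` | 3D Gaussian particle fitting, integrated intensity `I = A·σx·σy·σz`, single-mRNA/TS classification, 0.3-μm two-channel colocalization, nascent-copy counting |
| calcium | `gerikit.calcium` | ΔF/F with bleach correction, 3-SD/0.5-SD hysteresis events, sparse nonnegative AR(1) deconvolution, burst (2.5 per 33-ms bin) and theta-burst (100–167 ms interburst) scoring, walking filter (>0.5 cm/s, >0.5 cm runs) |
| spatial coding | `gerikit.spatial` | occupancy-normalized rate maps, Skaggs spatial information (bits/event), shuffle-test place cells, cross-session place-field correlation |
| engram ensembles | `gerikit.ensembles` | per-session Arc+ fractions, pairwise/consecutive overlap vs hypergeometric chance, reexpression trees, persistence counts |
| networks | `gerikit.networks` | circular-shift-null correlation graphs; degree, clustering, Newman modularity; subpopulation normalization |
| reporter physics | `gerikit.reporter_sim` | Monte Carlo comparison of direct RNA readout vs a delayed, decaying short-half-life GFP protein reporter |
| behavior | `gerikit.behavior` | freezing from mask-XOR motion energy (≥0.5-s sub-threshold runs), threshold calibration against manual scores |
| synthetic data | `gerikit.synthetic` | generators for all of the above, deterministic per seed |

## The core quantities

A single mRNA carrying 24 stem-loops, each bound by a tandem-dimer coat
protein with two GFPs, recruits up to **24 × 2 = 48 GFPs**; a TS holding
~15 nascent transcripts concentrates **~720 GFPs** at one locus — which is
why TSs are visible as diffraction-limited spots deep in tissue. Nascent
copy number is estimated as

```
copies = I_TS / median(I_single),     I = A · σx · σy · σz
```

Spatial information follows Skaggs: `SI = Σᵢ pᵢ (λᵢ/λ̄) log₂(λᵢ/λ̄)` in
bits/event. Chance ensemble overlap uses the hypergeometric law on the
universe of cells scoreable in both sessions. Theta-burst events are bursts
recurring at 6–10 Hz, i.e. interburst intervals in `[1000/10, 1000/6] ≈
[100, 167]` ms.

## Worked example

```python
import numpy as np
from gerikit import registration, segmentation, smfish, synthetic

cfg = synthetic.SceneConfig(
    volume_shape=(20, 160, 160), voxel_size=(1.0, 0.5, 0.5),
    n_nuclei=12, ts_fraction=0.23, autofluorescence_density=5,
    read_noise_sd=2.0, seed=0)
green, red, truth = synthetic.gen_twophoton_stack(cfg)
vol = registration.subtract_autofluorescence(green, red)
nuclei = segmentation.find_nuclei(vol, radius_range_um=(3.0, 5.0))
dets = segmentation.detect_ts(vol, nuclei)
calls = segmentation.classify_cells(nuclei, dets, gfp_bounds=(0, np.inf))
print(f"nuclei found: {len(nuclei)}  (planted: {cfg.n_nuclei})")
print(f"TS detections: {len(dets)}  (planted: {len(truth.ts_coordinates_um)})")
print(f"Arc+ cells: {sum(c.call == 'arc_pos' for c in calls)}/{len(calls)}")

_a, _b, t = synthetic.gen_smfish_field(
    300, 500, copy_dist=lambda rng, size: rng.poisson(14, size) + 1, seed=1)
counts, mean, sd = smfish.nascent_count(t["ts_intensity"], t["single_intensity"])
print(f"nascent mRNAs per TS: {mean:.1f} +/- {sd:.1f}")
print(f"GFPs per mRNA: {smfish.gfp_per_mrna()}  per locus at 15 copies: "
      f"{smfish.gfp_per_locus(15):.0f}")
```

prints

```
nuclei found: 12  (planted: 12)
TS detections: 2  (planted: 2)
Arc+ cells: 2/12
nascent mRNAs per TS: 14.9 +/- 3.7
GFPs per mRNA: 48  per locus at 15 copies: 720
```

All twelve planted nuclei are recovered by the Hough stage, both planted
TSs pass the two-consecutive-slices rule, the nascent-copy estimator lands
on the planted Poisson mean, and the labeling arithmetic gives the 48/720
GFP counts that make single-locus imaging feasible.

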