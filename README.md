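# epiwave

Non-invasive reconstruction of epicardial potentials, electrograms and
activation/recovery isochrones from body-surface potential maps
(electrocardiographic imaging, ECGI), using **wavelet-domain multitask
elastic-net regularization** with zeroth-order Tikhonov regularization as
the reference method. A synthetic torso–heart generator makes the whole
pipeline testable end to end without experimental recordings.

## The problem

Body-surface potentials Φ_B (r electrodes × m samples) relate to
heart-surface potentials Φ_H (q nodes × m samples) through a linear,
instantaneous transfer matrix A:

    Φ_B = A Φ_H + N,     N ~ i.i.d. Gaussian

Recovering Φ_H from Φ_B is severely ill-posed: A is badly conditioned, so
unregularized least squares amplifies measurement noise catastrophically.
Classical zeroth-order Tikhonov regularization solves

    min ‖A Φ_H − Φ_B‖_F² + λ ‖Φ_H‖_F²

which penalizes only solution energy. Because cardiac activation
propagates as wavefronts, electrograms are sparse in a wavelet basis over
*both* space and time. `epiwave` exploits this: each electrogram row is
transformed with a stationary (undecimated) Daubechies-2 wavelet
transform, P_B = SWT(Φ_B), and the epicardial coefficient matrix P_H is
estimated by a multitask elastic net

    min ‖A P_H − P_B‖_F² + λ [ (1−α) ½ ‖P_H‖_F² + α Σ_g ‖(P_H)_g‖₂ ]

where the groups g are either the rows of P_H (one group per heart node —
the default, matching standard multitask solvers) or its columns (one
group per wavelet coefficient, the literal mixed ℓ2/ℓ1 column norm; this
variant makes the problem separable). The time-domain estimate is the
inverse transform of the sparse solution. Post-processing derives
activation times (maximum negative d Φ/dt during depolarization) and
recovery times (maximum positive d Φ/dt during repolarization) from
smoothing-spline derivatives, plus the pacing origin as the node of
earliest activation.

Intended users: researchers in computational cardiac electrophysiology
who want a reproducible, oracle-tested reference implementation of
sparsity-promoting ECGI regularization, with a fully synthetic test bed.

## Worked example

```python
import numpy as np
import epiwave as ew

geom = ew.make_sphere_geometry(30, 40, heart_radius=30.0,
                               torso_radius=120.0, seed=0)
A = ew.monopole_transfer_matrix(geom)
print(f"transfer matrix: {A.shape}, condition number {A.condition_number:.3g}")

beat = ew.simulate_beat(geom, pacing_node=0, cv=1.0, apd_base=100.0,
                        apd_dispersion=10.0, duration=256.0, seed=0)
phi_b = ew.forward_project(A, beat, ew.NoiseModel(snr_db=20.0, seed=0))

tik = ew.tikhonov_reconstruct(A, phi_b, lam=0.01)
wen = ew.reconstruct_wavelet_en(
    A, phi_b, params=ew.RegularizationParams(lam=0.1, alpha=0.9, tol=1e-6))

for name, res in [("tikhonov", tik), ("wavelet-en", wen)]:
    cc, defined = ew.electrogram_cc(res.phi_h_hat, beat.phi_h_true)
    print(f"{name}: mean CC {np.where(defined, cc, 0).mean():.3f}, "
          f"data mismatch {res.data_mismatch_uv:.1f} uV")

split = 0.5 * (beat.activation_ms.max() + beat.recovery_ms.min())
iso = ew.compute_isochrones(wen.phi_h_hat, (0.0, split), (split, 255.0))
r_at, r_rt = ew.timing_correlation(
    iso, ew.IsochroneMap(beat.activation_ms, beat.recovery_ms))
node, xyz = ew.locate_pacing_origin(iso, geom)
err = ew.localization_error(node, geom.heart_nodes[beat.pacing_node], geom)
print(f"activation r {r_at:.3f}, recovery r {r_rt:.3f}, "
      f"pacing localization error {err:.1f} mm")
```

Output:

```
transfer matrix: (40, 30), condition number 1.22e+04
tikhonov: mean CC 0.886, data mismatch 53.1 uV
wavelet-en: mean CC 0.886, data mismatch 52.5 uV
activation r 0.897, recovery r 0.857, pacing localization error 19.5 mm
```

The mean CC is the Pearson correlation between true and reconstructed
electrograms averaged over heart nodes; the data mismatch is the RMS
difference between the recorded body-surface potentials and the forward
projection of the estimate, in microvolts. Timing correlations compare
detected activation/recovery maps to the simulated ground truth; the
localization error is the distance from the true pacing site to the node
of earliest reconstructed activation (here ≈ the internode spacing of the
coarse 30-node test mesh).

## Command line

```bash
epiwave simulate --q 99 --r 192 --snr-db 20 --seed 0 --out run/
epiwave reconstruct --transfer run/transfer.h5 --phib run/phi_b.h5 \
    --method wen --lam 0.1 --alpha 0.9 --out run/wen/
epiwave isochrones --recording run/wen/phi_h_hat.h5 \
    --geometry run/geometry.json --qrs-window 0 150 --t-window 150 511 \
    --out run/iso.csv
epiwave gridsearch --transfer run/transfer.h5 --phib run/phi_b.h5 \
    --out run/grid/
epiwave evaluate --transfer run/transfer.h5 --phib run/phi_b.h5 \
    --truth run/phi_h_true.h5 --reconstruction run/wen/phi_h_hat.h5 \
    --out run/report.json
```

Every command writes a JSON manifest (parameters, seeds, config hash,
version) so runs can be reproduced exactly.

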