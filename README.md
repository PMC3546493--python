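# cspat — compressed-sensing reconstruction for limited-view photoacoustic tomography

Photoacoustic tomography (PAT) maps the absorbed optical energy density
`A(r)` in tissue from the ultrasound it emits after pulsed laser
illumination.  When the detectors cover only an arc of the circle (here
90°) and the transducer responds only inside a frequency band, classical
backprojection leaves severe streak artifacts.  `cspat` implements the
compressed-sensing route: simulate band-limited, limited-view
frequency-domain measurements of sparse phantoms and reconstruct by
L1-penalised inversion with an alternating-direction method (ADM).

## Model

The temporal-frequency-domain forward operator on a pixel grid is

```
Φ[(m,n),(i,j)] = −i c k_n exp(i k_n |r_m − r_ij|) / |r_m − r_ij|,
```

with sensors `r_m` on a circular arc, wavenumbers `k_n = 2π f_n / c`,
and 64 frequencies per sensor drawn at random from a [0.2, 2.5] MHz
window; measurements are `y = Φx`.  Reconstruction solves the
unconstrained basis-pursuit-denoising problem in an orthonormal
Symmlet-4 wavelet basis Ψ,

```
min_θ ‖θ‖₁ + (1/2μ) ‖y − ΦΨ⁻¹θ‖₂²,
```

by the primal alternating-direction iteration (auxiliary residual `r`,
multiplier `λ`, penalty `β`, proximal step `τ`, relaxation `γ`):

```
r   ← μβ/(1+μβ) (λ/β − (Aθ − y))
θ   ← shrink(θ − τ A^T(Aθ + r − y − λ/β), τ/β)
λ   ← λ − γβ (Aθ + r − y)
```

stopping when the relative iterate change δ drops below 0.005.  The
default pipeline first row-whitens the system with
`(ΦΦ^H + εI)^{−1/2}`, which leaves the noiseless solution set unchanged
but cuts the iteration count from many thousands to a few tens.
A monotone FISTA solver and an exact linear-programming basis-pursuit
oracle provide independent cross-checks, and adjoint backprojection
serves as the classical baseline.

## Worked example

```python
import cspat

grid = cspat.ImageGrid(nx=48, ny=48, fov_mm=30.0)
phantom = cspat.make_disk_phantom(grid, seed=0)
op, y = cspat.simulate_measurements(phantom, n_positions=40, seed=1)
result = cspat.reconstruct_adm(op, y)
print(f"iterations: {result.iterations}")
print(f"RelErr: {cspat.rel_err(result.image, phantom.image):.2f}%")
print(f"recon SNR: {cspat.recon_snr_db(result.image, phantom.image):.1f} dB")
```

prints

```
iterations: 16
RelErr: 1.30%
recon SNR: 37.7 dB
```

— a five-disk phantom on a 30 mm field of view, recovered to about 1.3%
relative error from 40 sensor positions spanning a 90° arc, where
adjoint backprojection of the same data stays above 300% relative error.
The same pipeline is available from the shell:

```
cspat phantom  --n-disks 5 --seed 0 --out phantom.tiff
cspat simulate --phantom phantom.tiff --seed 1 --out meas.h5
cspat reconstruct --measurements meas.h5 --solver adm --out recon/
cspat evaluate --reconstruction recon/reconstruction.npy --reference phantom.tiff
cspat sweep-angles --phantom phantom.tiff --positions 16,40,80 --out sweep.csv
```

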