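# mospade

**Manifold-optimized spatial-mode demultiplexing (MO-SPADE) imaging.**

Conventional far-field imaging detects photons in the position basis
("direct imaging") and, for features below the Rayleigh scale, extracts far
less information than physics allows.  Sorting the image-plane field into a
set of orthonormal spatial modes before photon counting (SPADE) can reach
the quantum limit — but which modes?  `mospade` answers that by treating the
mode set itself as the optimization variable: it designs the J orthonormal
imaging modes that minimize the Cramér-Rao bound (CRB) for estimating an
arbitrary incoherent source distribution, benchmarks them against direct
imaging and against the quantum Cramér-Rao bound, and reconstructs sources
from simulated photon counts — including a fully adaptive protocol that
needs no prior knowledge of the scene.

The package is aimed at researchers in super-resolution and quantum-limited
imaging who want reproducible desk-scale benchmarks of modal imaging
strategies.

## Model in brief

A source F(R) = Σₖ cₖ fₖ(R) over K orthogonal source modes (point combs or
rectangle bins) is imaged through a Gaussian field PSF of width σ.  Photon
counts in imaging mode φⱼ are Poisson with per-photon probability
Pⱼ = Σₖ cₖ p_jk, p_jk = ∫_{fₖ} |⟨φⱼ|ψ_R⟩|² dR.  The per-photon Fisher
information matrix is

  I(c; Φ)_kl = Σⱼ p_jk p_jl / Pⱼ,

and the design objective L(Φ) = tr(W·I(c;Φ)⁻¹) (W = identity: K × mean CRB)
is minimized over the Stiefel manifold of orthonormal mode sets.  The
quantum benchmark is the SLD quantum Fisher information of the one-photon
mixed state ρ ∝ Σₖ cₖ ∫_{fₖ} |ψ_R⟩⟨ψ_R| dR, in the per-mean-photon
Poisson-channel convention so that CRB ≥ QCRB holds exactly.  Sources are
reconstructed by (variance-stabilized) non-negative least squares; the
adaptive loop alternates estimation with mode re-design using the
accumulated estimated information Σₘ Nₘ I(c_est; Φₘ).

## Worked example

Design five optimal modes for five equidistant point sources spaced
0.3σ apart (deep sub-Rayleigh) and compare against ideal direct imaging:

```python
import numpy as np
from mospade import (PSFModel, make_point_comb, design_modes, FisherBundle,
                     direct_imaging_factor, crb_from_factor)

psf = PSFModel(dimension=1, sigma=1.0)
scene = make_point_comb(5, 0.3)           # amplitudes 0.2 each
modes, trace = design_modes(scene, 5, psf)
mo = FisherBundle.from_source(scene, modes)
_, direct = crb_from_factor(direct_imaging_factor(scene, psf))

print(f"mean per-photon CRB, optimized modes: {mo.mean_crb:.1f}")
print(f"mean per-photon CRB, direct imaging:  {direct.mean():.1f}")
print(f"reduction factor: {direct.mean() / mo.mean_crb:.1f}")
```

Output:

```
mean per-photon CRB, optimized modes: 400.1
mean per-photon CRB, direct imaging:  15213.0
reduction factor: 38.0
```

Read: with a photon budget ⟨N⟩, an unbiased estimate of each source
amplitude (brightness 0.2) has variance at best ≈ 400/⟨N⟩ through the
optimized modes but ≈ 15200/⟨N⟩ through any pixel detector — the optimized
mode sorter extracts ~38× more information per photon at this spacing.  At
⟨N⟩ = 10⁶ the bound on the RMS amplitude error is 0.02 (10% of the
amplitude) for MO-SPADE versus 0.12 (62%) for direct imaging.

The same workflows are scriptable from the shell:

```
mospade crb-sweep --scene bump --sweep 0.6,0.8,1.2,2,3 --qcrb --out sweep.csv
mospade adaptive --scene bump --a 0.8 --photons 1e6 --trials 10 --out run/
```

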