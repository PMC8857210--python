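# Methods

## Model

An incoherent source with object-plane brightness F(R) is imaged through a
shift-invariant system with a Gaussian *field* point-spread function

    psi_R(x) = (2 pi sigma^2)^{-1/4} exp[-(x - R)^2 / (4 sigma^2)],

so the intensity PSF is a Gaussian of width sigma (sigma ≈ r_c/3 for an Airy
disk of radius r_c; all lengths in this package are in units of sigma).  The
source is decomposed over K orthogonal *source modes* f_k — Dirac deltas at
known locations, or unit-height rectangle bins tiling a finite interval
(squares in 2D) — with non-negative coefficients c, and the estimation task
is the coefficient vector.

At the image plane the field is sorted into J orthonormal *imaging modes*
phi_j and photon-counted per channel.  Detection is an independent Poisson
process: over a period with mean photon budget N, channel j records
n_j ~ Poisson(N P_j) with

    P_j = sum_k c_k p_jk,    p_jk = ∫_{f_k} |<phi_j | psi_R>|^2 dR.

P_j is used exactly as written (no renormalization over the J measured
modes); this is consistent with independent Poisson channel counts, whose
per-photon Fisher information matrix is

    I(c; Phi)_kl = sum_j p_jk p_jl / P_j.

The renormalized ("conditioned on detection") variant is not used anywhere
in the pipeline.

The mode-design objective is the weighted Cramér-Rao functional
L(Phi) = tr(W I(c; Phi)^{-1}) with W = identity by default, i.e. K times the
mean CRB over coefficients, minimized over the Stiefel manifold of M x J
orthonormal coefficient matrices.

## Representation

Modes and states live in a truncated Hermite-Gaussian (HG) basis matched to
the PSF width (tensor products in 2D).  Two facts make this basis exact
rather than approximate plumbing:

* `<HG_n | psi_R> = e^{-alpha^2/2} alpha^n / sqrt(n!)`, alpha = R/(2 sigma)
  — the shifted PSF is a coherent state of the HG ladder, so all field
  overlaps are closed-form; only the object-plane bin integrals need
  quadrature (per-bin Gauss-Legendre whose node count scales with the bin's
  phase span against the most oscillatory basis mode, which integrates the
  |<phi|psi_R>|^2 oscillations to ~1e-15; a uniform trapezoid grid at
  sigma/16 cannot reach the package's 1e-6 self-consistency requirement for
  high-order modes and is not used).
* Orthonormality of a mode set is exact matrix orthonormality of V, so the
  Stiefel constraint is algebraic.

The per-axis truncation M is chosen from the source extent (captured energy
of every shifted PSF over the support > 1 - 1e-6 requires roughly
M ≳ mu + 7 sqrt(mu), mu = (extent / 2 sigma)^2) and always exceeds the mode
count J.  A captured-energy diagnostic raises an error when a requested
scene does not fit the basis; density-matrix assembly additionally refuses
trace deficits above 1e-4.

Direct imaging is represented two ways, used for different purposes:

* **Continuum (fine-pixel) limit** for CRB curves:
  I_direct = ∫ d_k(x) d_l(x) / I(x) dx with erf-form bin intensity
  components.  This is the converged value of the pixel construction and has
  no pixel-width parameter.
* **Orthonormalized pixel modes** (indicator functions projected onto the HG
  basis, symmetrically orthonormalized) wherever an actual measurement is
  simulated — the Monte-Carlo baselines and the adaptive bootstrap.  A test
  verifies the pixel-mode CRB converges onto the continuum value within 1%
  as pixels shrink.  Note that a *single* pixel is one field mode: a huge
  bucket pixel captures only |∫ psi_0 / sqrt(w)|^2 of a central point's
  flux, not ~100% as an intensity bucket would.

## Numerical policy: square-root factors

Deep sub-Rayleigh information matrices are extremely ill-conditioned: the
information carried by spatial frequencies k through a Gaussian PSF falls
like exp(-sigma^2 k^2), so a rectangle discretization at width a produces
eigenvalue ratios of order exp(-sigma^2 pi^2 / a^2).  Forming the Gram
matrix I and inverting floors its small eigenvalues at ~eps * lambda_max and
turns mean CRBs into round-off noise below a ≈ 0.8 sigma.

Every bound in this package is therefore computed from a *square-root
factor* F with I = F^T F, via SVD:

* modal FIM: rows p_jk / sqrt(P_j);
* continuum direct imaging: rows d_k(x_i) sqrt(dx / I(x_i));
* quantum information: rows over retained eigen-pairs (q <= p) of rho,
  sqrt(w_qp) <e_q| drho_k |e_p> with w_qp = 4/(lam_q + lam_p) off-diagonal
  and 1/lam_q on the diagonal.

Factor entries are accurate to machine precision relative to their own
size, so singular-value ratios — and hence eigenvalue ratios of I — are
resolved far below the Gram matrix's eps * lambda_max floor.  This is what
makes the a = 0.6 sigma regime computable in double precision.  Below
a ≈ 0.5 sigma over ±12 sigma even the factored optimum is numerically
rank-deficient, so sweeps stop at 0.6 sigma; the asymptotic behaviour of
interest (quantum ratio near 2, order(s)-of-magnitude direct-imaging
penalty) is fully developed there.

Modes receiving probability below 1e-15 are dropped from the information
sum (their contribution scales as p^2/P).  Exact zeros in the evaluation
coefficients are floored at 1e-6 * max(c): a strictly empty Poisson channel
has vanishing variance, making any mode that only watches an empty bin
formally infinitely informative; the floor regularizes this boundary
artefact and is applied identically to classical and quantum bounds so
their ratio stays like-for-like.

## Mode optimization

`design_modes` minimizes L over the Stiefel manifold in two stages:

1. **Quasi-Newton stage.**  The manifold is parametrized by an unconstrained
   M x J matrix W through the polar retraction V = W (W^T W)^{-1/2}, and
   log L(V(W)) is minimized with L-BFGS.  The gradient is pulled back
   exactly through the matrix square root with the Daleckii-Krein
   divided-difference formula (verified against central differences to
   1e-9).  The log transform and quasi-Newton curvature model are what cope
   with the stiff landscape (curvature ratios ~1e12 deep sub-Rayleigh).
2. **Riemannian polish.**  Projection onto the tangent space, QR retraction,
   Barzilai-Borwein steps safeguarded by a monotone Armijo line search.
   Every accepted iterate is feasible to ~1e-15 and the recorded objective
   sequence is non-increasing by construction.

A fixed Tikhonov ridge (3e-14 times the largest information eigenvalue at a
reference start) is added to the information matrix *inside the optimizer
only*: transit iterates are legitimately rank-deficient (e.g. a mode set
that leaves some source direction dark), and the ridge keeps the objective
finite and smooth without biasing the optimum, whose smallest eigenvalue
sits orders of magnitude above it.  All reported CRBs are unridged.

Starting points: the low-order HG modes themselves, the top-J eigenvectors
of the one-photon density operator, orthonormalized shifted PSFs at the
source-mode centres, and seeded random orthonormal frames; the best final
point wins.  The deep sub-Rayleigh design problems are run with 4 random
restarts and a 6000-iteration cap (about a minute per problem); milder
problems converge in seconds with the defaults.  Returned mode sets are put
in a canonical gauge (sorted by decreasing P_j, sign fixed) — L is invariant
under signed column permutations, and only under those, since a general J x J
rotation changes the individual P_j.

Convergence: relative objective change below 1e-8 over 5 iterations, or
projected gradient norm below 1e-6, capped at 2000 iterations (defaults;
all overridable via `OptimizerConfig`).

## Quantum bound

The one-photon state of a scene is the incoherent mixture
rho = sum_k c_k T_k / S with T_k = ∫_{bin k} |psi_R><psi_R| dR and captured
flux S = sum_k c_k tr(T_k).  Symmetric logarithmic derivatives are built
from the eigendecomposition of rho, excluding eigen-pairs with
lam_q + lam_p < 1e-12 (the numerical form of the support restriction), and
the quantum Fisher information is K_kl = Re tr(L_k L_l rho).

Convention: the QFIM reported is the **per-mean-photon information of the
full Poisson detection model**, K_tot = S K(rho) + s s^T / S (equivalently,
the SLD construction applied to the unnormalized mixture).  The alternative
— differentiating the normalized state only — has *zero* information along
the overall-brightness direction (rho(t c) = rho(c)), so its QFIM is
singular and, worse, it is *not* an upper bound for the unconditioned
classical FIM used here, which does carry scale information
(c^T I c = sum_j P_j > 0).  With the Poisson-channel convention,
QFIM ⪰ FIM for every modal measurement and CRB ≥ QCRB are exact
data-processing theorems, and the MO-CRB/QCRB ratio is a clean
like-for-like per-photon comparison.  Everything is real (real PSF, real
rho), so weak commutativity tr(rho [L_i, L_j]) is the antisymmetry of
tr(rho L_i L_j), which the QFIM assembly yields for free; it vanishes to
round-off for these incoherent-source problems, meaning the quantum bound
is attainable in principle (possibly needing collective measurements, which
are bounded by a further factor of 2 and are out of scope here).

## Estimation

Sources are reconstructed by non-negative least squares on the stacked
linear model E[n_j^(m)] = N_m (p^(m) c)_j over all measurement records.
`nnls_reconstruct` defaults to plain NNLS; the adaptive pipeline and the
Monte-Carlo drivers default to the Poisson variance-stabilized weighting
(rows scaled by 1/sqrt(max(y,1))).  The reason is measured, not aesthetic:
with optimized mode sets the modal probabilities span decades, and
uniformly-weighted least squares is then grossly inefficient — on the
stacked adaptive data its MSE sits an order of magnitude above the
measurement's own CRB, while the weighted estimator tracks the bound.  NNLS
is biased at low photon numbers: its MSE falls below the CRB and saturates
at the scale of the source amplitudes, and at very high budgets the
rectangle approximation of a continuous scene imposes its own error floor.

## Adaptive protocol

The budget is split equally over one direct-imaging bootstrap period and
two adaptive periods (the reference schedule; any split is configurable).
Each adaptive iteration estimates c from all data so far, accumulates

    I_i^est = sum_{m <= i} N_m I(c_est; Phi_m)

with the budgets as weights (budgets, not realized counts: the FIM of a
period is its expected information, and budgets keep the weights
deterministic), and minimizes tr(W [I_i^est]^-1) over the current period's
mode set only — past terms are constants.  Estimated coefficients are
floored before FIM evaluation so a zero estimate cannot lock a bin out of
later iterations.  The schedule is fixed (no data-driven stopping); the
true source is used solely to draw photon counts.  Eight adaptive modes
suffice for 28 source bins because past-period information keeps the
accumulated FIM full-rank.

## Synthetic scenes

The 1D extended fixtures are parametrized stand-ins with the documented
qualitative properties (smooth, finite extent): a uniform plateau over
±8 sigma, a raised-cosine bump of half-width 8 sigma (which puts exactly 20
of 30 bins at nonzero amplitude when tiled at a = 0.8 sigma over
±12 sigma), and an asymmetric double bump (raised cosines at ∓4 sigma,
half-widths 3.5 sigma, heights 1 and 0.6), all normalized to unit flux.
2D scenes are a radial quadratic-phase chirp and an 8-spoke binary Siemens
star, bin-averaged and affinely rescaled so the *coefficient* Michelson
contrast equals the requested value exactly on top of a uniform background.
The generator emulates photon shot noise only: no detector noise, dead
time, crosstalk, aberrations or background counts, and sources are strictly
incoherent.  Passing tests therefore demonstrate the information-theoretic
mechanism, not robustness to laboratory imperfections.

## Problem sizes used in tests and the acceptance script

Sweeps use the three 1D fixtures over ±12 sigma at rectangle widths
0.6-3 sigma with J = K+1 modes (K up to 40, HG truncation up to ~64); the
point-comb analyses use 5 sources at spacings 0.2-1.5 sigma with J = 5; the
Monte-Carlo comparisons use 100 trials (point comb) and 10 trials
(adaptive, 28 bins, 8 adaptive modes, three equal periods) at a mean photon
number of 1e6; the 2D demonstration uses a 6x6-bin Siemens star with 12
adaptive modes.  These sizes were chosen so the full pipeline recomputes
every headline quantity in minutes on a single core while remaining inside
the regime where each claim is scale-free (ratios of bounds and of MSEs).

## Known limitations

* Below a ≈ 0.5 sigma (over ±12 sigma) double precision cannot represent
  the optimized information matrices even in factored form; sweeps stop at
  0.6 sigma.
* The optimizer certifies descent, not global optimality; reported MO CRBs
  are upper bounds on the true optima (the quantum ratio brackets how far
  they can be from optimal).
* QCRB evaluation uses dense eigendecompositions; 2D quantum bounds are
  restricted to small scenes, and the full 24x24-bin 2D scenes are treated
  with classical bounds and reconstructions only.
* Coherent or partially coherent sources and estimator-bias-aware design
  are out of scope.
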