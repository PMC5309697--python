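# Methods

## Model

Each atom's valence response is a single charged quantum harmonic
oscillator (Drude pseudoelectron) with unit charge q = 1, static
polarizability α₀, characteristic frequency ω and effective mass
m = q²/(α₀ω²). The dynamic polarizability is the single-pole Lorentzian
α(iω) = α₀/(1+(ω/ω_A)²) — the unique form consistent with a harmonic
oscillator, and the reason the plasmon-pole and RPA energy routes agree
identically (see below). The frequency closure ω = (4/3)C₆/α₀² follows
from the Casimir–Polder integral C₆ = (3/π)∫α(iω)²dω.

Pipeline: volume-ratio scaling → Dyson screening (short-range coupling) →
coupled Hamiltonian with the long-range coupling → exact diagonalization →
energies and fluctuation analysis. All internal units are Hartree atomic
units; conversions live in `units.py` only.

### Parameter scaling (`vdw_params`)

α₀ = v·α₀_free, C₆ = v²·C₆_free, R_vdw = v^{1/3}·R_free, with v the
per-atom Hirshfeld volume ratio supplied by the user (computed externally
by any DFT code; `--free-atom` sets v = 1). The free-atom reference table
(`data/free_atom_vdw.tsv`) ships the standard high-accuracy free-atom
α₀/C₆ set with the corresponding vdW radii for H, He, C–Ne, Si–Ar, Br, I;
it is data, not code, and can be overridden. Heteroatomic C₆ uses the
harmonic-mean combination rule, which is exactly the Casimir–Polder
integral of two Lorentzians (tested against independent quadrature).

### Dipole coupling (`coupling`)

Tensor convention: the pair block is T = (1 − 3R̂R̂ᵀ)/R³ (z-aligned pair →
diag(1, 1, −2)/R³), i.e. T = −∇∇(1/R). One consequence worth stating
because the literature uses both signs: with this convention the RPA
dielectric determinant is det(1 + A·T), not det(1 − A·T); the implementation
and its tests are consistent, and the plasmon/RPA equivalence test would
expose a sign slip on any cluster of ≥ 3 atoms (two-atom spectra are
symmetric and hide it).

Oscillators are not point dipoles: the short-range tensor is the
interaction of two spherical Gaussian charge clouds with the width
σ(iω) = (√(2/π)·α(iω)/3)^{1/3} (σ is the erf width parameter of
ρ ∝ exp(−r²/σ²), so the pair potential is erf(R/σ_AB)/R with
σ_AB = √(σ_A²+σ_B²)). It is finite at overlap and reduces to the bare
tensor beyond a few widths.

Range separation uses the Fermi switch f(R) = 1/(1+exp(−a(R/S_AB−1))),
S_AB = β(R_vdw_A + R_vdw_B): T_lr = f·T_bare enters the Hamiltonian,
T_sr = (1−f)·T_gauss enters the screening. Defaults a = 6, β = 0.83 (the
published range-separated self-consistent-screening value matched to the
PBE functional); both are config keys, and percent-level observables can
shift by ~1–2 points under plausible alternative β. Note f does not vanish
at contact — its floor is 1/(1+eᵃ) ≈ 0.0025 for a = 6.

### Screening (`screening`)

B(iω) = (A(iω)⁻¹ + T_sr(iω))⁻¹ solved by dense linear algebra per
frequency node, with frequency-dependent Gaussian widths. The
imaginary-frequency grid is 15-point Gauss–Legendre mapped to [0, ∞) via
ω = ω₀(1+u)/(1−u), ω₀ = 0.5 Ha, with a zero-weight ω = 0 node prepended
for static quantities; 15 nodes integrate the Lorentzian-squared
Casimir–Polder integrand to ≲1e-8 relative (grid-doubling stability is a
test). Contraction: ᾱ_A(iω) = ⅓·tr Σ_B B_AB (row sum over partners, tying
each atom to its molecular environment), C̄₆ by quadrature of ᾱ²,
ω̄ = (4/3)C̄₆/ᾱ₀², R̄_vdw = R_vdw(ᾱ₀/α₀)^{1/3}. The molecular
polarizability tensor is the sum of all blocks at ω = 0, and interfragment
atom-pair blocks of the static matrix are exported for heat maps (the
static limit is the default and is recorded in output metadata).

### Energies (`mbd_core`)

Hamiltonian blocks: ω_A²·1 on the diagonal, ω_Aω_B√(ᾱ_Aᾱ_B)·T_lr(A,B)
off-diagonal, built from screened parameters and screened radii in the
damping. Eigenvalues λᵢ must exceed 1e-12; below that the coupled
frequency would be imaginary (overlapping atoms / too-large β) and a hard
error reports min λ. Mode signs are fixed by making the largest-magnitude
component positive.

E_MBD = ½Σω̃ᵢ − (3/2)Σω_A. The RPA total (1/2π)∫Tr ln(1+A(iω)T_lr)dω is
mathematically identical for Lorentzian α and is used for the
order-by-order series (order n = −(1/2πn)∫Tr[(−A·T_lr)ⁿ]dω, starting at
the pairwise n = 2). If the spectral radius of A·T_lr reaches 1 the series
is flagged non-convergent; the log-det total is still returned unless an
eigenvalue reaches −1 (dielectric singularity → error).

Interaction energies subtract isolated-fragment MBD energies with each
fragment re-screened in isolation (the physically consistent reading of
"relaxed fragments"); freezing the complex-screened parameters is
available as a flag. The many-body reduction is quoted against the
second-order term of the same screened RPA series — attributing the
reduction to higher-order correlation within the model — and, separately,
against the unscreened pairwise baseline; both appear in reports because
the attribution convention is genuinely ambiguous.

The pairwise baseline is E = −Σ f(R)·C₆_AB/R⁶ over interfragment pairs
with unscreened volume-scaled parameters. A `damping="fermi2"` variant
squares the Fermi factor; that is the form which exactly equals the
second-order RPA term (second order in f·T gives f²), and the
corresponding test uses it.

### Fluctuation analysis (`fluct_analysis`)

Ground-state mass-weighted covariance ⟨ξξᵀ⟩ = ½Σᵢξ̃ᵢξ̃ᵢᵀ/ω̃ᵢ; atom A's
position covariance is its diagonal block divided by m_A. The charge
density is one normalized anisotropic Gaussian of unit charge per atom
(the nuclear +1 background cancels in differences and is omitted).

Density differences subtract fragment densities computed at the frozen
complex-screened parameters, so Δρ isolates the polarization induced by
the long-range interfragment correlation; re-screened fragments would fold
short-range dressing shifts into Δρ (roughly doubling the displaced charge
on benzene-dimer-scale systems) and are deliberately not the default here,
although they are for energies. The displaced charge integrates Δρ over
strictly positive voxels, with no isovalue cutoff. Default grids: 0.4 Bohr
spacing, 4 Å padding (converges the displaced charge to <1 % at
benzene-dimer scale). Strict 1e-6 charge-conservation checks use 6 Å
padding — with ~1.6 Bohr Gaussian widths, 4 Å of padding leaves ~1e-3 of
tail mass outside the box, which is immaterial for Δρ analyses but not for
a 1e-6 integral test.

Spectra are sums of unit-area Gaussians on an eV axis; the 0.06 eV default
"half-width" is interpreted as the half-width at half-maximum
(σ = HWHM/√(2 ln 2)). Mode dipole fields scale mode components by q/√m_A,
with a 5 %-of-maximum visibility threshold flag.

Mode projection embeds each fragment solution's modes (zero-padded) as an
orthonormal basis of the 3N displacement space; fragment solutions must
use frozen complex-screened parameters so the basis is exact and rows are
normalized by construction. Collectivity of a complex mode is
1/max_j c_ij² — the inverse participation of the dominant fragment mode —
chosen over the literal 1/max|c| because only the squared convention
assigns 3 to an equal three-component expansion (both are reported). The
per-mode binding contribution ½(ω̃ᵢ − Σ_j c_ij²ω_j^frag) is a defined
convention, fixed by the one hard constraint available: contributions must
sum exactly to the interfragment energy at fixed screened parameters
(tested to 1e-10 Ha).

Degeneracy caveat: for symmetric fragments (rings, chains) the fragment
spectrum is degenerate and any infinitesimal coupling mixes degenerate
modes arbitrarily; collectivity near 2 for a homodimer's paired modes is
physics, not noise. Zero-coupling identities (all collectivities 1) hold
exactly only for degeneracy-free fragments.

## Synthetic data

`fixtures.generate` produces seeded, bit-reproducible toy systems: dimers,
chains, regular rings, stacked ring pairs (a π–π surrogate: two parallel
N-rings at a stated separation) and random clusters with a 1.8 Bohr
minimum-distance floor. Volume ratios are constant or uniform-interval
draws. These emulate the geometry and parameter ranges of small conjugated
clusters but not real electronic structure: no chemistry fixes the ratios,
no relaxation, single-element rings. Tests passing on fixtures validate
the model's mathematics (identities, limits, equivariances) — statements
about real complexes additionally require real geometries and DFT-derived
Hirshfeld ratios.

The benzene-dimer checks use an idealized reconstruction of the two
standard conformers (D6h monomer r_CC = 1.3915 Å, r_CH = 1.080 Å;
parallel-displaced: 3.4 Å interplane / 1.6 Å offset; T-shaped: 4.96 Å
centre distance) with representative aromatic Hirshfeld ratios C 0.82,
H 0.60 — synthetic stand-ins, constructed in code, chosen once from
standard structural data and typical stockholder-partitioning values.

## Problem sizes and numerical choices

Dense linear algebra throughout: screening is 16 solves of a 3N×3N system,
diagonalization one symmetric eigensolve — desk-instant up to a few
hundred atoms. The test suite runs on ≤ 24-atom systems and finishes in
seconds; density grids reach ~10⁶ voxels (chunked Gaussian evaluation).
Eigenvalue positivity tolerance 1e-12; screening solves abort when the
condition number exceeds 1e14, naming the frequency. Cube files are
written with 13 significant digits so write→read round-trips preserve
values to 1e-10 (standard 6-digit cube readers still parse them).

## Known limitations

- No periodic boundary conditions / Ewald coupling.
- No DFT side: total binding energies of real complexes need an external
  semi-local functional contribution; this package reports the MBD part.
- Hirshfeld ratios are consumed, never computed.
- Free-atom table covers main-group elements listed above; others error out.
- Fully metallic (zero-gap) response is outside the model's single-pole
  ansatz.
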