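# Methods

`glioinvade` is a hybrid discrete–continuum, individual-cell-based model
of glioblastoma spheroid invasion in a homogeneous ECM-like substrate,
together with the morphometric analysis used to compare simulated
spheroids with bright-field measurements of the 3D invasion assay.

## Model

**Domain.** A 2D square lattice of physical side L = 5 mm at resolution
h = 20 µm (250 × 250 sites, roughly one cell diameter per site); each
site holds at most one cell.  The plane represents a central slice
through a 3D spheroid.  Coordinates are 0-based `(row, column)`; the
physical centre of site *(i, j)* is *((i+0.5)h, (j+0.5)h)*, and all
radii are measured from the centre of the seeding site *(n/2, n/2)*.

**Cells.** Every cell carries a single heritable trait, its *adhesion
preference* a ∈ {0,…,7}: the number of occupied Moore neighbours it
requires at a destination site before moving there.  Preferences 0–1
are classed *low* (single-cell migrators), 2–5 *middle*, 6–7 *high*
(core-forming).  All other traits — proliferation age T_p, oxygen
consumption, death threshold — are shared, unless a per-phenotype
proliferation table is configured.

**Scheduler.** Cell processes are updated asynchronously every
t_r = 0.8 h.  One macro-step executes: (1) a movement pass over all
live cells in a fresh uniform-random permutation; (2) an oxygen-field
advance of t_r; (3) a life-cycle pass over a second fresh permutation,
with hypoxic deaths applied at the end of the pass.  The fixed pass
order (movement → oxygen → lifecycle) lets death decisions see the
freshest oxygen field; applying deaths at pass end makes outcomes
independent of a cell's position in the permutation relative to dying
neighbours.  All randomness flows from a single `numpy` generator, so
`(config, seed)` determines every output bit.

**Movement.** Unbiased motility is Fickian, ∂c/∂t = D_c ∇²c.  The
standard 5-point discretisation yields a per-substep hop probability
p_move = 4 D_c k / h², with the substep k = min(t_r, h²/(4 D_c))
adjusted so an integer number of substeps tiles t_r and p_move ≤ 1.
During its movement turn a cell runs all its substeps: with probability
p_move it enumerates the empty Moore-adjacent sites whose occupied-
neighbour count (itself excluded, truncated at the lattice border)
equals its adhesion preference, and relocates to one chosen uniformly;
an empty admissible set forfeits that substep — there is no fallback to
non-matching sites.  Spreading the hop over the eight Moore directions
makes the realised free-space diffusivity 1.5 D_c (the four diagonal
steps have squared length 2h²); the package asserts the exact per-substep
second moment E[step²] = 1.5 p_move h² by simulation rather than hiding
it, and the admissibility gate is what produces the morphologies:
preference-0 cells detach and scatter, middle preferences crawl along
the tumour boundary as a cohesive sheet, preference-7 cells are
effectively immotile.

An alternative scheduling — interleaving single substeps across all
cells — was evaluated and rejected: it lets boundary cells ratchet off
cohesive fronts cooperatively, destroying the sheet-like primary
morphology (ensemble compactness drops from ≈0.81 to ≈0.52) and
roughly doubling front speeds.  The per-cell-consecutive scheme is the
one specified throughout.

**Proliferation.** A cell divides once its age reaches T_p (31 h for
the U87MG-like line, 25 h for the primary-like line, from doubling-time
assays), provided an empty site exists in its Moore neighbourhood of
radius r = 2 (24 sites); the daughter site is chosen uniformly among
all empty sites in that neighbourhood, and both cells restart at age 0.
With no free site the cell turns quiescent — its age frozen — and
divides the moment space appears.  Ages are initialised uniformly on
[0, T_p) to avoid synchronous division waves.

**Phenotype switch.** Optionally, at each mitosis the phenotype is
redrawn with probability p_mut (0.5 in the switch studies) uniformly
from the scenario's allowed set, self-transitions included, and applied
to both daughters.  The induced Markov chain P = (1−p) I + (p/k) J has
the uniform stationary law, so switching flattens the phenotype
composition.

**Oxygen and death.** Oxygen is the single limiting resource,

o_t = D_o ∇²o − γ_o o c_ij − α_o o,

with Dirichlet boundaries pinned at the medium concentration o_max
(normalised to 1) and c_ij ∈ {0,1} the live-cell indicator.  A cell on
a site with o < o_deadly dies and becomes empty space (no further
consumption; the site is immediately reusable).  Defaults:
D_o = 1e-5 cm²/s, α_o = 0, o_deadly = 0.1.

The per-cell consumption rate is the one free oxygen parameter once o
is normalised.  It was calibrated once, by a monotone scan, so that the
primary scenario's median first necrotic death lands near the observed
≈150 h; the frozen default is **γ_o = 0.012 s⁻¹**.  This is a
calibration, not a prediction, and is documented as such.

**Numerics of the oxygen solve.** Two integrators share the same
spatial discretisation (5-point Laplacian, boundary ring re-clamped
after every update):

* an explicit forward-Euler scheme with substep
  Δt_o = min(t_r, 0.9 h²/(4 D_o)), which satisfies the stability bound
  4 D_o Δt_o/h² ≤ 1 and the discrete maximum principle;
* an unconditionally stable backward-Euler step of the full macro-step,
  solved on the interior by conjugate gradients preconditioned with an
  exact DST (fast-Poisson) solve of the consumption-free operator and
  warm-started from the previous field; the consumption term is a
  localised diagonal perturbation, so a handful of iterations reach
  rtol 1e-8.

At the physical D_o the explicit bound is ≈0.09 s, i.e. ~3×10⁴ grid
sweeps per macro-step; since the local oxygen relaxation time (≈1/γ_o,
tens of seconds) is far below t_r = 0.8 h, the implicit step loses no
relevant transient.  `method="auto"` (the engine default) uses the
explicit scheme whenever ≤512 substeps suffice and the implicit one
otherwise.  Both schemes are verified against a direct sparse solve of
the discrete steady state and against the continuum closed form
o(x) = o_max cosh(x/ℓ)/cosh(X/ℓ), ℓ = √(D_o/α_o), on a quasi-1D strip;
they agree with each other to <1e-3 at steady state.

**Stopping rules.** A run ends at t_max (216 h = 9 days by default) or
as soon as any live cell comes within 5 sites of the lattice border
(the spheroid has outgrown the domain, as invasive cells outgrow the
well in vitro).

## Scenarios

| scenario | phenotypes | T_p (h) | initial disc | motility (cm²/s) |
|---|---|---|---|---|
| `u87mg` single-phase | {0,1,6,7} | 31 | 140 µm | 5e-9 |
| `u87mg` two-phase | {0,1,6,7} | 31 | 140 µm | 1.5e-8 on [0,24] h, 3e-9 after |
| `primary` single-phase | {2..7} | 25 | 200 µm | 2e-8 |
| `primary` two-phase | {2..7} | 25 | 200 µm | 4e-10 on [0,24] h, 4e-8 after |

The initial disc is completely filled; phenotypes are drawn i.i.d. from
the configured mixture.  The mixture proportions are not constrained by
the source data ("arbitrary" initialisation); the default is uniform
over the scenario's phenotype set and is exposed in the configuration.

## Morphometrics

Computed on live cells only (dead cells are empty space), mirroring the
image-analysis pipeline applied to bright-field micrographs:

* **invasive radius** — maximum distance from the seeding centre
  enclosing all cells;
* **core radius** — U87MG: maximum centre distance within the
  8-connected component containing the centre-most cell (the maternal
  spheroid); primary: reported missing, because the cohesive morphology
  admits no phenotype- or connectivity-based core/invasive separation;
* **invasive rim** — invasive minus core radius;
* **compactness** — mean fraction of occupied Moore neighbours per
  cell (∈[0,1]; border-truncated);
* **sparseness** — mean nearest-other-cell distance in units of h
  (1 for a packed block);
* **largest component fraction** — share of cells in the biggest
  8-connected component (≈1 for cohesive, <1 for starburst morphology);
* **expansion speed** — OLS slope of an ensemble-mean radius series
  over a stated time window (µm/h), windows [0,24] h and [24,96] h by
  default.

The exact compactness/sparseness statistics used on the original image
data are not part of the available text; the local-density and
nearest-neighbour definitions above are simple, exactly testable
statistics chosen to capture the same directional behaviour, and all
directional claims in the test-suite are made against these
definitions.

Replicate ensembles report per-timepoint means and standard deviations
over the replicates still running at each timepoint; replicates stopped
by the edge rule drop out of later timepoints, as spheroids whose cells
reach the well boundary leave the in vitro analysis.

## Problem sizes used in the shipped studies

Expansion speeds use 20 replicates of each two-phase scenario to 96 h;
the necrosis-onset study uses 10 replicates of the single-phase primary
scenario (each stopping at its first death); trend studies use 10
paired-seed replicates per arm with a ×2 rate perturbation, compared
at the final timepoint common to both arms within a 96 h horizon — the
window the whole in-vitro/in-silico comparison concentrates on, since
the fastest cells outgrow the domain (or well) soon after.  Directions,
not magnitudes, are the claims; the perturbation size is a package
choice.  Unit and property tests run on reduced domains
(0.4–2.4 mm) sized so that the edge-stopping rule stays inert unless it
is itself under test.

## What the synthetic phantoms do and do not show

The phantom generators (`make_disc`, `make_starburst`, `make_sprouted`)
build occupancy grids with construction-known radii, counts and
connectivity, so the morphometrics layer is validated independently of
the simulator — a disc must yield equal core and invasive radii, a
detached singleton must move the invasive radius but not the core, a
sprouted disc must stay one component with tips at core + sprout
length.  Phantoms are idealised: they contain no density gradients, no
mixed phenotypes within a component and no image noise, so passing them
validates the metric implementations, not the segmentation of real
micrographs (out of scope).

## Known limitations

* 2D lattice with single occupancy; no lattice-free motion, no 3D.
* The ECM is a passive homogeneous scaffold: no degradation,
  remodelling, haptotaxis or chemotaxis.
* Oxygen is the only microenvironmental field; phenotype is intrinsic
  (no environment-triggered switching or go-or-grow coupling, beyond
  the optional per-phenotype proliferation table).
* The Moore-direction walk realises an effective free-space diffusivity
  of 1.5 D_c; consequently the early, escape-dominated expansion of the
  low-adhesion scenario is faster than the bright-field regression
  values it is compared against, while cohesive front advance — which
  is gated by local adhesion geometry rather than by D_c — is somewhat
  slower.  Both behaviours follow from the movement rule as specified
  and are reported as measured.
* Necrosis onset is a calibrated quantity (γ_o), not an independent
  prediction.
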