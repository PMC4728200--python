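# Methods

## Scope and assumptions

`cytotension` estimates quasi-static intracellular tension in a single
adherent, fixed (hence mechanically equilibrated) cell from 2-D
fluorescence images. The central assumptions are:

- fluorescence intensity of phalloidin-stained actin is proportional to
  local actin density, and denser actin carries proportionally more
  tension;
- stress fibers behave as linear pre-strained elastic bands at a
  constant ~20% pre-strain (myosin-generated contraction); no
  hyperelasticity, viscosity or plasticity — adequate for statics, not
  for dynamic loading;
- traction at the substrate concentrates in vinculin-positive focal
  adhesions, with force proportional to adhesion area above 1 um^2;
- compression inside the cell is carried by a generic network of rigid
  sphere contacts (a stand-in for microtubules), or by the substrate
  alone when that network is disabled.

The three channels are assumed registered (same microscope frame); there
is no alignment, deconvolution or flat-field step.

## Coordinates and units

Images are `[row, col]`, origin top-left; the physical position of a pixel
centre is `((col + 0.5) p, (row + 0.5) p)` with pitch `p` in um. Mechanics
uses pg / um / us, under which `1 pg um / us^2 = 1 nN` exactly, so forces
are in nN with no conversion factors.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| pixel pitch | 0.29 | um | microscope sampling |
| block size | 2x2 | px | pixels per node; `d0 = block * pitch = 0.58 um` |
| `eps0` | 0.2 | – | interaction pre-strain (measured fiber pre-strain ~20%) |
| `g_v` | `1.1 g0` | um | interaction creation threshold; on the square grid this selects exactly the 4-neighbourhood (diagonals at `1.414 d0` are excluded) |
| node mass | 0.8 | pg | water-equivalent volume of the contactor envelope |
| contactor radius | `0.4 d0` | um | spheres touch after 20% mutual approach, i.e. exactly when a band slackens; keeps nodes from collapsing while staying "small" |
| FA force coefficient | 5.5 | nN/um^2 | area-to-force conversion |
| FA minimum area | 1.0 | um^2 | below this, area and force are uncorrelated; boundary inclusive |
| sub-micron FA force | 15 (off) | nN | optional flat force for the 0.5–1 um^2 class |
| `a` sweep | 1, 4, 8, 15 | nN | calibration grid spanning the physiological range |
| nucleus stiffness | `10 a` | nN | uniform, 10x the strongest actin interaction |
| relaxation horizon | 300 | us | `dt * steps` |

Node count is capped at 10 000; exceeding it is an error that suggests a
coarser binning.

## Solver

The target is the static equilibrium of the pre-stressed network, not its
transient. We integrate damped semi-implicit Euler:
`v <- damping (v + (F/m) dt)`, `x <- x + v dt`, with per-step velocity
retention 0.5 (strongly overdamped) and fixed anchors. Rigid frictionless
contact is regularized by a linear penalty `R_N = penalty * max(0, -g)`
with `penalty = 100 a / d0`; at equilibrium the resulting penetration
stays well below 1% of `d0` (asserted; a warning suggests a higher penalty
otherwise).

Explicit integration of the penalty contact bounds the stable step:
`damping * omega^2 * dt^2 < 3` with `omega^2 = penalty/m` up to
~3 200 us^-2 at the top of the sweep, hence the default `dt = 0.025 us`
with 12 000 steps covering the standard 300 us horizon. Convergence is
reported (max residual force on free nodes, and the free run length —
mean free-node displacement per step, a divided-medium stability
indicator) but not enforced: the run length is fixed and the residual is
surfaced. A run aborts with a diagnostic if the free run length grows for
50 consecutive steps (divergence) or any force turns non-finite.

`g_v` acts only at network creation; interactions persist under stretch
during relaxation (dynamic deletion is available behind a flag, off by
default). The solver contains no randomness: identical inputs give
bit-identical trajectories.

Contact candidate pairs are refreshed from a KD-tree every 100 steps with
a 0.3 um search cushion; node displacements per refresh interval are
orders of magnitude smaller than the cushion in all regimes the package
targets.

Anchor (focal adhesion) reactions are the net *tensile* force on each
fixed vinculin node — the pull the contractile network transmits to the
substrate; contact pushes against anchors are bookkept separately in the
compression summary.

## Calibration

For each `a` in the sweep the model is rebuilt and relaxed; the summed
anchor force is fitted by ordinary least squares as `F = alpha a - beta`
and inverted at the measured FA force sum. Least squares over all sweep
points is used rather than two-point interpolation because the relation
has mild curvature (the network rearranges slightly more at higher `a`);
R^2 below 0.9 triggers a warning, and a solution outside the swept range
warns about extrapolation.

Two cross-linear scale factors are reported: `T_cl_max = a eps0 / d0`
(tension per transverse length at gray value 1, the factor used by the
probes) and the cross-linear rigidity `a / d0`; they differ only by the
pre-strain factor and both appear in the calibration report. The mean
tension `T_mean` averages taut interactions only — slack bands carry no
force and would dilute the mean.

## Probes

Probes sample the 256-level normalized actin image, not the 10-label
quantization, with bilinear interpolation at half-pixel arc-length spacing
(sub-pixel sampling keeps measurements rotation invariant). The mean gray
value along a probe is the trapezoidal line average of the samples; a
plain sample mean overweights the two endpoints and biases Gaussian
profiles several percent low. Probes narrower than 0.6 um emit a warning:
below the model definition, resolution averaging underestimates tension.
Reported widths ignore diffraction.

The equivalent Young's modulus of a fiber is
`E = T / (pi (d/2)^2 eps)`; with tension in nN and diameter in um the
quotient is exactly kPa.

## Synthetic cells

The generator renders what the pipeline needs and nothing more: stress
fibers as straight segments with Gaussian cross profile (FWHM = nominal
width, imitating diffraction-limited imaging), an optional circumferential
belt with Gaussian radial profile, a uniform "dendritic" background inside
the cell body (the convex hull of all structures), vinculin disks of
prescribed areas, and a filled nucleus ellipse. Overlapping fibers are
max-composited so gray values stay in [0, 1] without renormalizing.
Gaussian noise (sd 0.01 by default) is added inside the cell body only,
emulating staining heterogeneity; background pixels stay exactly zero so
the `c > 0` footprint rule is well-posed, and Gaussian tails below 0.005
are truncated for the same reason.

The reference cell mirrors a typical well-spread fibroblast: 62 x 35 um at
0.29 um/px (~4 500 nodes after 2x2 binning), five fibers with widths
0.85–1.75 um spanning the range a user would probe, eight adhesion disks
of 1–2.5 um^2 at fiber termini, a 12 x 8 um nucleus and a belt of radius
14 um. Each fiber's ground-truth row includes a probe station placed where
no other structure crosses the profile, the closed-form Gaussian cross
mean (normalized by the rendered image maximum, i.e. exactly what a probe
on the normalized channel should read), and the per-unit-`T_cl_max`
tension. A smaller two-fiber "mini" cell serves fast end-to-end runs and
the node-spacing study.

What the synthetic images do *not* emulate: realistic point-spread
functions, curved or branching fibers, dendritic texture (the background
is flat), uneven illumination, and out-of-focus light. Tests passing on
them therefore validate the pipeline's bookkeeping, mechanics and
calibration — not robustness to real microscope artefacts.

Known resolution effect: probing a fiber whose FWHM is under ~4 pixels
dilutes the profile (trapezoidal integration of a bilinearly interpolated
Gaussian underestimates a concave peak by about `p^2/12 |f''|`), reaching
-4% at 0.85 um width on a 0.29 um grid. This is the imaging-resolution
averaging the probe width recommendation guards against, and the reason
sub-4-pixel fibers are checked against the closed form with a one-sided
5% band rather than 2%.

## Numerical choices and degenerate inputs

- Actin normalization subtracts the 1st-percentile intensity (robust to
  hot pixels; lower-interpolation quantile makes the operation exactly
  idempotent), clips negatives and rescales the maximum to 1; constant
  images are rejected.
- Label bins are right-closed with a 1e-12 boundary slack so values that
  are mathematically on a bin edge but perturbed by floating-point
  arithmetic land in the intended bin; `c = 0` produces no node.
- Block labels use the block's mean gray value (the standard binning
  reduction); anchor priority within a block is vinculin > nucleus >
  actin, because adhesions are the boundary condition and must never be
  silently demoted.
- FA detection uses 8-connectivity by default (the common particle
  analysis convention) and the area boundary is inclusive
  (`area >= 1 um^2`); both are configurable.
- Empty vinculin masks yield an empty adhesion list; calibration then
  fails explicitly since there is no force to match.
- The whole-cell tonus ratio is defined as 0 when no FA force is
  available rather than dividing by zero.

## Limitations

2-D only; single cell per image; no fiber tracing or segmentation (the
probe is user-drawn); no substrate deformation model (forces are inferred
from adhesion area, not measured); compression network is generic rather
than image-derived; population statistics are a concatenation of per-cell
reports, nothing more.
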