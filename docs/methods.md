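# Methods

`osteosim` simulates healing of a fixated rat-femur diaphyseal defect
on an idealized 2D longitudinal section, coupling a BMP-2
reaction–diffusion balance, a degrading alginate carrier, chemotactic
progenitor migration, plane-strain finite-element mechanics, and
strain-regulated tissue differentiation whose rates are modulated by
the local BMP-2 dose. This note records the model as implemented, the
parameters and their defaults, the numerical choices, the calibration
decisions that were genuinely open, and what the packaged tests do and
do not demonstrate.

## Geometry and scenarios

The section is the y ≥ 0 half of a longitudinal cut (symmetry axis at
y = 0), built from axis-aligned bands: medullary canal (0–1.1 mm),
endosteum strip (0.2 mm), cortical wall (0.7 mm), periosteum strip
(0.2 mm), and, for small-gap fractures only, a 1 mm outer callus band
over the central 12 mm. Modeled length 20 mm; the gap (2 or 8 mm) is
centered. These dimensions are reconstructions of an idealized rat
femur — only the 8 mm gap is a hard datum — and all are configurable.
The 2D fields carry unit (1 mm) out-of-plane thickness, so
concentrations stay volumetric (ng·cm⁻³, cells·cm⁻³).

Scenario initial states:

* **2 mm fracture (validation, 42 d):** gap and callus band filled with
  debris tissue (fracture hematoma); no carrier, no dose. The purpose
  is to show that at physiological BMP-2 every modulation fold is 1 and
  the model reduces to a purely mechanoregulated healing model.
* **8 mm defect (84 d):** the cortical window plus the adjacent
  endosteal/periosteal strips form the defect cross-section
  (8 × 1.1 mm). Empty: void (no substrate). Gel scenarios: normalized
  alginate a = 1 there; a dose D µg loads the encapsulated pool
  uniformly, g_gel(0) = 1000·D / V_gel with V_gel in cm³
  (≈ 5.7 × 10⁵ ng·cm⁻³ for 5 µg). The medullary canal under the defect
  is modeled as void — invasion is axial, from the intact tissue at the
  gap ends, matching the assumption that the periosteum (resected over
  the defect) and endosteum of the intact fragments are the progenitor
  sources.

MSC sources: the endosteal and periosteal strips over intact bone hold
the progenitor density at `source_density` (default 1 × 10⁵
cells·cm⁻³) every day.

## BMP-2 balance

Free BMP-2 g and encapsulated BMP-2 g_gel (both ng·cm⁻³):

* Encapsulated pool: dg_gel/dt = −(λ_gel + λ_rel(a)) g_gel with
  λ_gel = ln2/3.25 d⁻¹ (in-gel half-life loss, destroyed) and
  λ_rel(a) = λ_rel0 (1 − a), λ_rel0 = 0.027 d⁻¹ (transferred to g). An
  intact gel (a = 1) releases nothing; release accelerates as the
  carrier degrades and its contact surface grows.
* Free pool: release source; differentiation-event sink (each
  chondro-/osteogenic differentiation event consumes all local BMP-2
  above the physiological floor, g → g_min = 0.008 ng·cm⁻³);
  receptor-mediated uptake V_max g/(K_m + g) with
  V_max = (c_s + c_b) × 1.43 × 10⁻⁷ ng·cm⁻³·d⁻¹ per cell·cm⁻³ and
  K_m = 11.01 ng·cm⁻³; first-order decay λ = ln2/0.42 d⁻¹; production
  α (c_s + c_b)/(γ g + γ₀) with α = 2 × 10⁻⁹ ng·ml⁻¹·cell⁻¹·d⁻¹,
  γ = 15 (ng/ml)⁻¹, γ₀ = 0.01; Fickian diffusion with the linear blend
  D(a) = a·0.2 + (1 − a)·8.64 mm²·d⁻¹ between the in-gel and in-vivo
  diffusivities.

Two modeling clarifications were required:

* **Decay-rate form.** The degradation law is stated as exponential
  decay with a half-life; it is implemented as the autonomous rate
  dg/dt = −(ln2/t½) g, which reproduces that behavior exactly.
* **Perfusion floor.** The production constants are tuned such that
  cells keep g inside the physiological band, but production scales
  with the *local* (c_s + c_b) and, at realistic callus densities below
  ~9 × 10⁵ cells·cm⁻³, the local homeostat alone equilibrates slightly
  below g_min. In vascularized tissue the systemic circulation, not
  only local cells, maintains the baseline. The model therefore applies
  a physiological floor g ← max(g, g_min) in *host* tissue: everything
  that carried tissue at day 0, plus any volume whose non-alginate
  solid fraction exceeds 0.35 (newly formed, revascularized matrix).
  The defect interior — carrier or void — has no floor: there, g above
  g_min must come from the exogenous dose. This single mechanism makes
  the 2 mm fracture heal at physiological BMP-2 while an invaded but
  undosed carrier never reaches the differentiation threshold, which is
  exactly the union/non-union dichotomy the model exists to capture.

## Hydrogel

da/dt = −(λ_bulk + c_eff λ_cell) a, updated with the exact pointwise
exponential (unconditionally positive and monotone), with
λ_bulk = 5 × 10⁻⁴ d⁻¹ and λ_cell = 6.5 × 10⁻⁶ d⁻¹ per cell·cm⁻³. As
printed, the bulk term of the source balance would make an acellular
gel grow; the implemented sign gives decay, consistent with an aging
acellular gel retaining ≈ 95.9% at 12 weeks. The cell term represents
active invasion (ion exchange and water uptake around cells), so
c_eff is the total local cell density scaled by
clip(1 − mineralized/0.22, 0, 1): once mineralized matrix seals a
volume, water exchange and hence cell-driven hydrolysis stop, and the
alginate trapped in ossified tissue persists. That freeze threshold
(`erosion_freeze_frac`) is a calibration constant; it sets the
pointwise residual carrier left behind the ossification front.

Motility gating: D = D₀(1 − a) + ε_D a and χ = χ₀(1 − a). The random
floor ε_D keeps a weak migration channel through intact gel; the
library function defaults to ε_D = 10⁻² D₀, while the simulation
default is 3 × 10⁻⁵ D₀ — the calibrated value below which undosed gel
is not colonized on the 12-week horizon. Proliferation and
(indirectly) differentiation are gated by the adhesion factor (1 − a):
plain alginate presents no integrin ligands, so embedded cells neither
spread nor divide until the gel around them has degraded.

## Cell transport

Only MSCs migrate; differentiated cells are stationary matrix
producers. The Keller–Segel flux −D(a)∇c + c χ_eff ∇g uses
χ_eff = χ₀ (1 − a) × chemotaxis_fold(g): the mechanical/structural
sensitivity multiplied by the dose-dependent bell (the product form of
mechano-chemical coupling, applied to the chemical sensitivity).
Fluxes are closed where either neighbor is impassable: mineralized
fraction above 0.5 ("mineralized is the main tissue"), or total solid
below 0.05 (nothing to adhere to — this is why an empty defect is
never colonized). The chemotactic influx saturates as the receiving
volume approaches a packing density (3 × 10⁵ cells·cm⁻³ default,
volume-filling form), which bounds densities without clipping.

D₀ = 0.24 mm²·d⁻¹ (order of prior bone-healing models) and
χ₀ = 0.05 mm²·d⁻¹·(ng·cm⁻³)⁻¹ are not literature values; they are the
package's calibration knobs, chosen once so that the treated-defect
front crosses 10% bone fill near week 3–4 and covers the defect by
week 12, then frozen.

## Mechanics

Quasi-static drained linear elasticity in plane strain, solved daily
with bilinear quadrilateral elements (one per grid cell). Element
constants are the tissue-fraction-weighted (Voigt) averages of the
drained tissue table (debris 1.85 MPa … cortical bone 20 GPa, alginate
0.05 MPa), renormalized over the solid content; (near-)empty cells get
a 0.01 MPa floor so the system stays definite. Permeabilities are
homogenized and reported but the baseline solve is drained-elastic —
the stimulus is extracted once per day from a quasi-static state, so
transient poroelastic consolidation is deliberately out of the loop.

Boundary conditions: distal end plate fixed, symmetry (u_y = 0) on the
axis, the axial gait load applied as a traction on the proximal
cortical cross-section, and the external fixator as a linear spring on
the mean axial displacement of the loaded plate (distal plate
grounded). The half-section model halves the printed full-construct
load (14.4 N) and fixator stiffness (277 N·mm⁻¹) internally.

Stimulus: ψ = √J₂ of the small-strain deviator with ε_zz = 0 (raw J₂
selectable). √J₂ is first-order in strain, which makes the fate
thresholds strain-like quantities; it is zero for volumetric states
and rotation-invariant.

## Tissue rules

Where g ≥ g_min, MSC density above a 10³ cells·cm⁻³ event threshold
differentiates at r_diff toward the fate selected by ψ:
osteogenic (ψ ≤ 6 × 10⁻³), chondrogenic (≤ 3 × 10⁻²), fibrous above.
Chondro-/osteogenic conversions set the event mask that feeds the
BMP-2 sink; fibroblastic ones do not (BMP-2 does not act on that
pathway). Chondrocytes mature at r_mature × hypertrophy_fold(g), their
cartilage calcifies at the same rate, and calcified cartilage is
replaced by woven bone at r_endo (endochondral route). Bone cells
deposit woven bone at r_bone × bone_production_fold(g) × c_b
(intramembranous/appositional route). Produced matrix displaces
granulation, then debris, then free space; fractions are kept valid
with priority to the mineralized phases. Cortex-dominated volumes are
inert.

The ψ thresholds and base rates do not come from the modeled study —
they belong to the underlying mechanistic healing model — and are
calibration constants. They were tuned **once** so that the frozen
default configuration satisfies the qualitative contract (2 mm gap
unites by week 6; empty and gel-only 8 mm defects stay at ~0% bone;
gel + 5 µg reaches ~85% fill with ~10% residual carrier and a 10%
crossing near week 3–4), and then frozen:

| constant | default | units |
|---|---|---|
| r_prolif | 0.5 | d⁻¹ |
| r_diff | 0.2 | d⁻¹ |
| r_mature | 0.15 | d⁻¹ |
| r_endo | 0.2 | d⁻¹ |
| r_bone_matrix | 8 × 10⁻⁷ | fraction·d⁻¹ per cell·cm⁻³ |
| r_cart_matrix | 4 × 10⁻⁷ | fraction·d⁻¹ per cell·cm⁻³ |
| r_fib_matrix | 2 × 10⁻⁷ | fraction·d⁻¹ per cell·cm⁻³ |
| cell_capacity | 2.5 × 10⁵ | cells·cm⁻³ |
| source_density | 1 × 10⁵ | cells·cm⁻³ |

The carrying density is intentionally below the ~9 × 10⁵ cells·cm⁻³ at
which the local production homeostat alone would cross g_min: without
host perfusion or an exogenous dose, no cell population can talk
itself into differentiating. That choice is what makes the gel-only
non-union robust rather than a numerical coincidence.

## Numerics

* Boundary-snapped tensor-product rectilinear grid (default target
  cell 0.4 mm); every region boundary is a mesh line, so compositions
  are exact at day 0 and the FE patch test is trivial. An optional
  seeded jitter of interior mesh lines exists for robustness checks;
  the model itself is deterministic.
* Daily macro-step: (1) homogenize + FE solve + ψ; (2) MSC transport;
  (3) proliferation, differentiation, maturation/production; (4) BMP-2
  step with this day's event mask; (5) alginate decay; (6) record.
* Transport: cell-centered finite volumes, harmonic-mean face
  diffusivities (a zero on either side closes the face), first-order
  upwinding of the drift, explicit sub-steps under a positivity/CFL
  bound — exactly conservative, non-negative by construction.
* BMP-2: reactions advanced with Patankar-type positivity-preserving
  sub-steps (losses implicit, sources explicit, default 0.05 d);
  diffusion by one backward-Euler solve per day (sparse LU,
  refactorized daily as D(a) evolves). Faces into substrate-free void
  are closed: bare space holds no interstitial fluid continuum and
  must not act as a sink for tissue BMP-2.
* Gel pool and alginate: exact exponential updates; the released mass
  is the exact λ_rel/(λ_gel + λ_rel) share of the pool decrement.
* Degenerate inputs: negative concentrations, out-of-range a, invalid
  fractions and non-increasing mesh lines raise immediately; a step
  producing NaN or negative fields aborts with a diagnostic.

Problem sizes: the desk-scale defaults (0.4 mm cells → 350 cells for
the 8 mm defect; 84 daily steps) run a full scenario in ~2 s on one
core; halving the cell size changes day-84 bone fill by < 3 points.
These sizes are the package's default operating point; all are config.

## What the scenario tests show — and what they do not

The scenario suite runs the actual coupled model, not fixtures, so a
green suite shows: exact reproduction of the anchor folds and
closed-form kinetics; conservation and positivity of every field over
full 12-week runs; the union/non-union dichotomy; and week-12 outcomes
of the treated defect (~85% bone, ~10% carrier, burst-then-
physiological release) at the frozen defaults. It does **not** show
that the calibrated rates are biologically identified (several
(r, c)-combinations produce the same outcomes), nor that real defects
obey the idealized geometry, the deterministic sources, or the 2D
plane-strain reduction.

## Known limitations

* **Undosed carrier erosion.** Cells colonize an undosed gel slowly but
  do not differentiate in it (no bone — the robust prediction); over
  12 weeks they nevertheless erode much of the carrier, whereas the
  observed undosed gel stays nearly intact. The cell-driven
  degradation constant is large enough that any sustained contact
  destroys gel; reproducing "nearly intact" would require invading
  densities ~10² cells·cm⁻³, incompatible with the densities the other
  processes need. The acellular retention figure (95.9%) is exact.
* **Dose response is compressed.** Day-84 bone fill is monotone in dose
  only to within a few points on the coarse mesh (the chemotaxis bell
  peaks at 1 ng·cm⁻³, transiently favoring mid doses), and the low-dose
  (0.1 µg) fill is higher than observed in vivo: the in-gel half-life
  sets the differentiation-gate lifetime, which shrinks only ~11 days
  per decade of dose.
* The spatial mean BMP-2 over the defect can sit a few percent below
  g_min late in healing when un-vascularized carrier remnants are
  averaged in; the band check in the tests carries a 10% allowance at
  the floor for this reason.
* 2D plane strain; no torsional load case or failure testing; no bone
  remodeling, angiogenesis/oxygen, marrow or muscle progenitor
  sources, apoptosis, or callus-domain growth (the small-gap callus is
  a fixed band whose composition evolves).
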