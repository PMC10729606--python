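# Methods

## Scope and model class

`lungdosim` is a one-dimensional, whole-lung aerosol dosimetry model of the
typical-path / multiple-path family: the lung is a rooted tree of cylindrical
airway segments, aerosol transport is treated as serial filtration of a
tidal plug of air, and each airway removes particles with analytic
single-mechanism efficiencies.  The target quantity is the *deposited dose
per airway* over an acute exposure, and the derived statistic is the
obstruction ratio — the diameter of the sphere formed by an airway's total
deposited mass divided by the airway's own diameter.  Clearance is
deliberately excluded: over a 4-h acute exposure neither mucociliary nor
macrophage-mediated transport removes a decisive share of the deposit, so
total deposited mass is the appropriate dose metric; for repeated or
longer exposures this model would understate the differences that
clearance kinetics introduce.

## Aerosol representation

The exposure atmosphere is lognormal in aerodynamic diameter, parameterized
by MMAD (µm) and GSD.  The mass distribution is discretized into
`n_bins = 1000` geometric bins spanning MMAD·GSD^±4 with bin probabilities
from the lognormal CDF, renormalized to 1 (to 10⁻⁹); a bin is represented
by the geometric midpoint of its interval.  Quadrature error is negligible
at this resolution: refining 1000 → 10000 bins moves total deposition
fractions by < 0.1 percentage points (asserted in the test suite).
Monodisperse aerosols (GSD = 1) collapse to one bin.

Particle-side physics (CGS units, body conditions T = 310 K,
µ = 1.89×10⁻⁴ g cm⁻¹ s⁻¹, λ = 0.0712 µm, g = 981 cm s⁻²):

* Cunningham slip correction C(d) = 1 + (λ/d)(2.514 + 0.8 e^(−0.55 d/λ));
* settling velocity v_ts = ρ₀ d_ae² g C/(18 µ) with ρ₀ = 1 g/cm³
  (aerodynamic-diameter convention, so material density enters only via
  d_ae; the physical-diameter conversion d_p = d_ae/√(ρ/ρ₀) is provided
  for completeness);
* Stokes–Einstein diffusivity D = k_B T C/(3π µ d).

## Inhalability

Humans inhale essentially all particles below ~10 µm, and the study
aerosols carry no significant mass above that, so the human inhalable
fraction is 1.  Rats are obligate nose breathers whose aspiration
efficiency falls off above ~1 µm.  The rat curve is a logistic in
ln d_ae, IF(d) = 1 − 1/(1 + exp(a − b ln d)), with (a, b) =
(1.7795, 0.6117) fixed once so that the mass-weighted inhalable fractions
of the two study atmospheres (MMAD 2.74 µm/GSD 2.8 and 2.01 µm/GSD 3.0)
are 0.745 and 0.775, inside the 74–78% range established for resting rats
in this size regime.  The literature curve shape (e.g. Ménache et al.
1995) is steeper in d; only the mass-weighted outcomes for the study
aerosols are anchored here, and the shallow slope is a known consequence
of pinning exactly those two integrals (see Limitations).

## Extrathoracic (head) deposition

The nose/mouth-through-larynx region is modeled empirically, not airway by
airway: per species and route, η_ET = 1 − exp(−a (d_ae² Q)^b), with d_ae in
µm and Q the mean inspiratory flow in L/min — the classic
impaction-parameter form.  Exponents are fixed a priori at b = 1.17
(nasal) and 1.40 (oral), within the range of published airway-passage
correlations; the prefactors a are calibrated once, through the full
engine, so that the human nasal and oral study scenarios deposit 51.3% and
14.3% of inhaled mass in the head, and the rat nose-only scenario ~34.5%
of inhalable mass.  The expired stream passes the head filter a second
time on its way out.  All coefficients are frozen in
`lungdosim.config.EXTRATHORACIC` and echoed into every run manifest.

## Airway geometry

**Human.**  The builtin tree is the symmetric typical-path whole-lung
model after Yeh & Schum (1980): 24 generations, trachea = generation 1,
generations 1–17 conducting (TB), 18–24 alveolated (PUL), dichotomous
branching with 2^(g−1) airways per generation (16,777,215 in total).  The
symmetric tree is stored as one record per generation with a multiplicity;
per-airway quantities always refer to one physical airway, which makes
results invariant to expanding the representation.  A total alveolar
volume of 3000 cm³ at FRC is distributed over generations 18–24 in
proportion to airway count (alveoli are of roughly uniform size).  The
extrathoracic dead space is 50 cm³.

**Rat.**  The cast-based asymmetric rat geometries used by established
dosimetry tools are not published as tables, so the package generates a
*synthetic monopodial surrogate* and labels it as such: 28 TB generations
with a dominant trunk and lateral daughters (side-branch counts follow a
geometric growth schedule so the target TB airway count, default 6000, is
met rather than left to compounding chance), pulmonary offshoots budding
from TB generations 8–28, and eight pulmonary generations appended to each
complete TB path (depth 36).  Diameter and length ratios are lognormal
draws (major-daughter diameter ratio 0.90 ± 0.02, length/diameter
3.2 ± 0.5, trachea 0.34 cm × 2.3 cm), child diameters strictly below the
parent's, branching angles ~15° on the trunk and ~60° on laterals,
gravity angles ~N(45°, 15°), alveolar volume 3.5 cm³ on the terminal
ducts, ET dead space 0.42 cm³.  One seeded RNG stream per tree makes
generation byte-reproducible.

## Deposition engine

Breathing is a square wave: inspiration half the period, optional pause,
expiration the remainder (defaults: inspiratory fraction 0.5, pause 0 —
the simplest defensible resting cycle; both are configurable).  The root
flow is V_T/T_insp; at each branch point flow splits in proportion to the
subtended distal volumes.

Air is an incompressible plug.  Fresh aerosol enters the trachea only
after the head dead space is washed out; thereafter a parcel advances
until inspiration ends, filling each airway's lumen and attached alveolar
sleeve along the way.  The fraction of the breath that fully transits an
airway, the fraction that ends inside it, and the fraction that never
arrives follow in closed form from the cumulative filling times.  This
plug kinematics is what reproduces the characteristic zero deposition in
the terminal alveolar generations: their cumulative volume exceeds the
resting tidal breath, so the front never reaches them.

Per transit, the combined efficiency is η = 1 − (1−η_I)(1−η_S)(1−η_D):

* impaction (at the inlet bifurcation): arccos-form probability in
  ε = θ·Stk with Stk = v_ts U/(g d_airway) and θ the branching angle in
  radians — zero for a straight continuation;
* sedimentation: η_S = 1 − exp(−(4/π) v_ts L sin φ/(d U)) with φ the
  airway's angle from the gravity vector;
* diffusion: Ingham's series in x = D L/(4 U R²).

Air that ends inspiration inside an airway deposits over a half-length
pass; the share that ended in the alveolar sleeve is captured with
η_alv = 1 − exp(−(0.75 v_ts/r_alv + 5.784 D/r_alv²)·t_hold), the
well-mixed settling/diffusion rate in a sphere of alveolar radius
(r_alv = 105 µm human, 45 µm rat) over the mean wait t_hold = pause + half
the expiration.  On expiration every stream retraces its path with the
same efficiencies (flow magnitudes are symmetric for the default cycle)
and finally passes the head filter once more.  Mass balance —
head + TB + PUL + exhaled = 1 on the basis of inhaled mass — closes to
10⁻⁹ by construction and is asserted on every run.

Deposition is one-way coupled: deposited material never alters the
airflow, so a nominally plugged airway keeps filtering as if open.  At the
extreme concentrations studied here this understates proximal pile-up and
overstates distal penetration — a conservative direction for the
obstruction statistic.

Deposited mass per single airway is
m_j = C·V_T·f·t·IF · (per-airway fraction)/multiplicity, in µg.

## Obstruction analysis

For every TB and pulmonary airway (the head is excluded) the deposited
mass is converted at particle material density (1 g/cm³ for the study
material, so mass and volume coincide; the density is an explicit
parameter with no packing-porosity correction) into a coalesced-sphere
diameter (6V/π)^(1/3), and divided by the airway diameter.  Ratios are
binned half-open on the right with an unbounded last bin:
0/0.25/0.5/0.75/1.0 for rats and 0/0.1/0.2/0.3/0.4/0.5 for humans, with
counts and percentages reported for TB and PUL separately and jointly,
plus per-generation maxima and means.  Because the per-single-airway mass
is used, ratios are invariant to the symmetric-vs-expanded representation,
and at fixed deposition fractions they scale exactly as (C·t)^(1/3).

## What the synthetic data do and do not show

The generator reproduces the *structural* features the analysis depends on
— monopodial asymmetry, early pulmonary outgrowths, realistic airway
counts and calibres, strict diameter decrease — but it is not a rat cast:
per-airway results on the surrogate demonstrate the behaviour of the
method (mass balance, dose scaling, cross-concentration monotonicity,
rat-vs-human contrast in high-ratio airway counts), not anatomical
predictions for any real rat.  Passing tests on the surrogate therefore
validate the algorithms, and only the human results — computed on the
published typical-path geometry — carry quantitative weight.

## Numerical choices and degenerate inputs

Geometric bin edges and midpoints are computed in log space; GSD = 1 short
circuits to one bin.  Efficiencies are clipped to [0, 1]; the Ingham
series is exactly 0 at x = 0.  The half-pass sedimentation survival is the
square root of the full-pass survival.  Front fractions are clipped at 0
so airways beyond the tidal front contribute nothing.  Zero concentration
yields zero masses with unchanged fractions (the engine is linear in
concentration and duration).  Trees are validated before every run; a
violated invariant raises rather than producing silent nonsense.
Problem sizes: 1000 size bins × 24 generation records (human) or ~30,000
airway records (default rat surrogate); a human run takes ~10 ms and a
default rat run a few seconds on one core.

## Known limitations

* The rat head and inhalability curves are anchored only at the study
  aerosols' mass-weighted outcomes; their size dependence is shallower
  than cast-measured rodent data.  Together with the surrogate geometry
  this makes the surrogate's TB deposition fraction (~28–35% of inhalable)
  several-fold higher than cast-based reference values (~5%); rat-side
  results should be read as structural, not quantitative (see above).
* Plug flow without axial mixing: no aerosol is retained in the lung gas
  at end-expiration, which truncates the multi-breath accumulation real
  lungs show for sub-micron particles.  For the supra-micron study
  aerosols the error is small.
* The expiratory pass reuses inspiratory efficiencies (including
  impaction); expiratory secondary flows differ in reality.
* Upright posture enters only through per-airway gravity angles; where a
  source table lacks them, 38.24° (the random-orientation average) is
  substituted.
* No hygroscopic growth, charge, coagulation in transit, or
  deagglomeration.
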