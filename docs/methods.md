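# Model description and design notes

`daylily-fspm` is a functional–structural plant model (FSPM) of daylily
(*Hemerocallis citrina* Baroni) canopies. It couples, at a daily time step
over days 91–242 (1 April – 30 August), five components: sky radiation,
explicit 3-D plant architecture, canopy light interception, coupled C3 leaf
gas exchange, and source–sink carbon allocation. Its purpose is to compare
planting configurations (pattern, row spacing, plant spacing, density) by
the fresh-weight yield and length of the harvested flower buds.

## Daily loop

Each simulated day executes, in order: (1) the sky radiation update,
(2) per-leaf light interception and gas exchange, (3) per-plant source–sink
allocation and respiration, (4) morphology rules (organ initiation by
phenology, length advance, geometry refresh), (5) output recording. The
clock advances exactly one day per step; all stochastic draws (weather
noise, leaf azimuths, which shoots flower) derive from a single seed, so
replays are bit-identical.

## Sky radiation

Daily extraterrestrial radiation H_o (24-h mean, W m⁻²) comes from the
standard day-arc integral with solar constant 1367 W m⁻² and the usual
eccentricity and declination corrections. At-surface global radiation uses
a cloud-cover-based clearness regression,

    H / H_o = −0.08 + 0.21 (Tmax − Tmin)^0.5 − 0.012 N̄,

with N̄ the mean cloud fraction (0–1); the ratio is clamped to [0, 1] so
H ≤ H_o always. The sky is discretized into 72 diffuse directional sources
(6 elevation bands × 12 azimuth sectors, weights proportional to sector
solid angle × cos zenith) plus one direct sun source at the
irradiance-weighted daily-mean solar position. The diffuse fraction is
f_d = 0.23 + 0.77 × cloud (≈23 % diffuse under clear sky, all-diffuse under
overcast). Source weights are stated as contributions to horizontal
irradiance and close on H exactly.

Because the model runs one light pass per day, the dome carries the
*daylight-mean* intensity H × 86400 / daylength_s, and leaf assimilation is
integrated over the astronomical daylength. The season statistics the
synthetic weather reproduces (mean H 248.7 W m⁻², mean temperature 19.1 °C,
mean cloud 0.4, mean wind 2.4 m s⁻¹ at 40.13° N) are 24-h means.

The synthetic generator produces temperature as a seasonal sinusoid peaking
in late July plus seeded Gaussian noise, noisy cloud/wind/humidity around
their means, and solves one scalar (the diurnal temperature range) so that
the clearness-regression season mean matches the configured radiation to
well under 2 %. It emulates the first and second moments and the seasonal
trend of a Datong growing season; it does not emulate synoptic
autocorrelation (weather fronts), heat waves, or rain days, so passing
tests demonstrate behaviour under climatologically typical forcing, not
under weather extremes.

## Plant architecture and growth

A plant is a clump of 6 shoots. Each shoot carries 13 phytomers — an
opposite leaf pair per rank, azimuths advancing by the golden angle with
seeded jitter — and, on flowering shoots, a scape (leafless flowering stem)
bearing 40 flower buds. The flowering-scape emergence rate (default 50 %)
is realized as round(rate × shoots) scapes per plant with the bearing
shoots drawn at random, which honours the rate exactly while keeping
desk-scale plots representative.

Organ expansion follows the determinate sigmoid ("beta") growth law: rate
dw/dt = c_m ((t_e−t)/(t_e−t_m)) (t/t_m)^{t_m/(t_e−t_m)} with exact
cumulative w(t) = w_max (1 + (t_e−t)/(t_e−t_m)) (t/t_e)^{t_e/(t_e−t_m)};
c_m is derived from (w_max, t_m, t_e) so the curve reaches w_max exactly.
Lengths follow their growth curves in time (development), while dry-matter
gain is carbon-limited through the source–sink module; the daily sink
strength of an organ is the one-day increment of its cumulative curve, so
under unlimited assimilate the realized trajectory equals the potential
one exactly.

Default phenology calibration (all in the packaged schedule, replaceable by
CSV): leaf ranks are born every 6 days from day 65 — ranks 1–5 predate the
simulated window, representing March regrowth of the perennial rhizome, and
enter day 91 with their accrued size as initial state — each leaf grows for
50 days to a final length of 0.25 + 0.05 × rank m (0.30–0.90 m) at 1.0 g
dry matter per metre of leaf. The scape elongates from day 137 to 1.19 m
(t_e = 207) at 3 g DM; buds are born staggered over days 170–205, each
growing for 30 days to 0.128 m.

Leaf area is tied to dry mass by the specific leaf area constant
SLA = 0.0023 m² g⁻¹; at the default calibration a plant carries ≈93.6 g
leaf DM ≈ 0.215 m² leaf area (LAI ≈ 1.8 at 83,000 plants ha⁻¹). The SLA
constant makes leaves heavy per unit area, so the emergent leaf width
(area/length ≈ 2–3 mm) is narrower than field daylily leaves; geometry is
otherwise faithful (arching straps, base inclination 58° falling to −25° at
the tip, rendered as chains of parallelogram facets whose areas sum exactly
to the SLA area).

Planting layouts: ER places rows every `wide` m; NWR and DRBR place row
pairs `narrow` m apart repeating every (wide+narrow) m, DRBR with plants
staggered by half a spacing within each ridge pair. Realized density comes
from the per-plant allotment (wide × spacing for ER, (wide+narrow)/2 ×
spacing otherwise) and is exact; the catalogue's printed densities are
reproduced by round-to-nearest-thousand for 33 of 36 rows (the 71,428 →
"72,000" rows are a known rounding quirk of the catalogue). The outermost
row and row-end plants are guards excluded from all summaries.

## Canopy light interception

The default (projection) estimator is deterministic. For each dome source,
facets are projected onto the plane perpendicular to the beam and binned on
a 0.15 m grid; a facet's transmission is the product over shallower facets
in its cell of (1 − (1 − t) c_j), where c_j is the occluder's projected
area as a fraction of the cell and t the leaf transmittance. This is exact
for a full-cover occluder (transmission t) and tends to the turbid-medium
exponential for many small facets; reflected energy is counted as lost
(first-order scattering). The plot is virtually tiled 3 × 3 so edge plants
see realistic neighbours; incident, absorbed, reflected and escaped energy
close exactly by construction, and non-negative escape is asserted.
Sources carrying < 0.3 % of the dome flux are dropped with their energy
redistributed (configurable; set to 0 for exact audits).

A reverse Monte Carlo mode (exact ray–parallelogram intersections, Russian
roulette absorb/reflect/transmit) serves as the unbiased cross-check; on a
random 20-leaf scene the two modes agree to ~3 % in scene-total absorption.

Default leaf optics a/r/t = 0.85/0.10/0.05 (typical green-leaf PAR values);
the ground is a black absorber. Absorbed flux (W m⁻² leaf) converts to
PPFD with the factor 2.275 µmol J⁻¹.

## Leaf gas exchange

Per leaf and day the model solves the coupled steady state of
Farquhar–von Caemmerer–Berry biochemistry (A = min(Wc, Wj)(1 − Γ*/Ci) − Rd,
non-rectangular hyperbola for J), Ball–Woodrow–Berry stomatal conductance
(gs = g0 + m A h_s/Cs, floored at g0), CO₂ diffusion
(Ci = Ca − A(1.6/gs + 1.37/gb)), and a two-sided leaf energy balance
(shortwave load = longwave + sensible + latent), by damped successive
substitution (damping 0.5, tolerance 1e-4, cap 50; non-converged leaves are
flagged). Kc, Ko, Γ*, Vcmax, Rd follow Arrhenius temperature responses,
Jmax a peaked response.

The daylily gas-exchange constants behind the published simulator are not
available, so the packaged defaults are this package's own calibration:
Vcmax25 = 55, Jmax25 = 110 µmol m⁻² s⁻¹, α = 0.26 (incident basis),
θ = 0.7, Rd25 = 0.6, m = 9, g0 = 0.01 mol m⁻² s⁻¹. They were chosen, with
the organ schedule above, so that the optimal-density canopy realizes ≈95 %
of its growth potential — i.e. they are set by the reported organ and yield
endpoints, not by leaf-level gas-exchange measurements. A consequence worth
stating plainly: the canopy-mean net assimilation this produces (≈8–14
µmol m⁻² s⁻¹ for lit leaves) is higher than the low rates reported for
daylily leaves. Under the fixed constants above (SLA 0.0023 m² g⁻¹ —
i.e. 435 g DM per m² of leaf — and maintenance respiration 0.014 g glucose
g⁻¹ d⁻¹), a leaf assimilating ≤2.5 µmol m⁻² s⁻¹ cannot pay its own
maintenance (≈0.009 vs 0.014 g glucose per g leaf per day), so a
low-photosynthesis parameterization cannot grow these plants at all; the
calibration resolves the conflict in favour of the reproducible endpoints.

## Source–sink carbon allocation

Each plant has one shared assimilate pool (g glucose). Daily, in order:
leaf assimilation (converted at 180/6 g glucose per mol CO₂) tops up the
pool; organs receive gr_i = min(S_i/S_tot × ap, S_i Δt) (proportional to
sink strength, capped at potential; surplus stays in the pool); growth
respiration is charged at (1.39 − 1) g glucose per g new DM; maintenance at
0.014 g glucose per g structural DM; then the root draws 0.15 × the
remaining pool. If the pool cannot cover respiration the day's growth
shrinks proportionally — biomass is never catabolized and the pool never
goes negative. The daily ledger (assimilation, reserve, growth, both
respirations, root draw, pool) closes to 1e-9 g per plant per day and the
season audit to 1e-6 g.

Because the root draw removes 15 % of the *standing* pool every day, a
lump initial reserve decays like 0.85^t and cannot bootstrap the spring
canopy; the overwintered rhizome reserve (default 40 g glucose per plant)
is therefore released evenly over the first 50 days, recorded as an
explicit ledger column. This is an initial-condition delivery schedule,
not a dynamic remobilization model.

Fresh weights use per-organ fresh:dry ratios (leaf 6, scape 8, bud 12; the
bud value corresponds to ≈92 % water, within the range measured for tender
flower buds, and is jointly calibrated with the per-bud dry mass so a full
scape carries 171.42 g fresh buds).

## Yield accounting

The per-hectare yield multiplies the mean per-position bud fresh weight of
interior plants by the realized planting density. The per-"plant" yield
statistic is reported *per flowering shoot* (per scape): with 6 shoots per
clump and 50 % emergence, a planted position carries 3 scapes, and the
individual-plant figures reported for field daylilies are per flowering fan.
This convention is what makes the reported per-plant (≈171 g) and
per-hectare (≈43 t ha⁻¹ at 83,000 positions ha⁻¹) figures mutually
consistent; multiplying the per-scape figure by the position density alone
understates field yield threefold.

## Scenario sweep and statistics

The sweep runs all (or a subset of) the 36 catalogued configurations under
one shared seeded weather realization (a paired design), then applies the
dual quality thresholds: mean bud length ≥ 0.12 m and yield ≥ 35 t ha⁻¹.

Growth-curve calibration (`fit_beta`) least-squares fits (t_m, t_e, w_max)
of the cumulative sigmoid to organ time series; goodness of fit reports R²,
RMSE and the regression F of observed on predicted with (1, n−2) degrees of
freedom. On synthetic every-3-day series with 2 % noise (48 points) the
parameters are recovered within 5 % and R² > 0.95.

PLS path modeling is implemented natively (Lohmöller iteration, path
weighting scheme, mode-A outer estimation, tolerance 1e-7, cap 300):
standardized reflective blocks, per-endogenous OLS on construct scores,
Cronbach's α, Dijkstra–Henseler ρ_A, composite ρ_c, AVE, and specific
indirect effects as products along structural chains. The sweep's
measurement blocks are: the four configuration constructs (pattern code,
row distances wn/wide/narrow, plant spacing, realized density), growth-
stage-window means of canopy leaf PPFD, leaf temperature and net
assimilation as three-indicator physiological blocks, and final per-scape
bud dry mass as the single-indicator outcome.

One identifiability caveat: in the catalogue, row distance is an exact
function of density and plant spacing (wn = 2·10⁴/(density × spacing)), so
the partial path row distance → radiation is not statistically identifiable
from the sweep — its fitted value is design-dependent. The row-distance
benefit is therefore assessed within plant-spacing strata, where it is
identifiable and consistently positive; the density effect (negative on
radiation, photosynthesis and bud yield) is robust in both the PLS and the
rank correlations.

## Problem sizes and numerical choices

Default simulated plots are ~3.2 × 1.5 m (≈40 positions, ≈16 interior)
with periodic tiling; the test suite uses ~2 × 0.8 m plots, which change
per-plant outcomes by < 1 %. Leaves are rendered with 3 facets in the
standard configuration (1 in the test configuration); facet areas always
sum to the SLA area exactly. Projection-grid cell 0.15 m. The coupled
gas-exchange solver and the energy-balance Newton iteration are vectorized
over all leaves of the scene.

## Known limitations

* No soil water, nutrients, or temperature-dependent maintenance; the root
  is a pure carbon consumer.
* No leaf senescence: standing leaf biomass is maintained to season end,
  which makes late-season maintenance the dominant carbon cost.
* Organ lengths are developmental (not carbon-coupled), so bud length does
  not respond to planting configuration; configuration effects appear in
  bud mass and yield only.
* The density response of per-plant yield is damped by interception-
  fraction compensation (denser canopies intercept a larger share of the
  light they are offered); group-mean yield contrasts across the catalogue
  are correspondingly milder than the field-reported ones.
* Sub-daily light dynamics, spectral effects, and multi-year carryover are
  out of scope.
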