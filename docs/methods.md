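# Methods

## The control problem

Greenhouse crops need a minimum amount of photochemically useful light each
day, but supplemental LED light is expensive and sunlight is free and
uncertain. `greenlight` schedules LED output over a discretized photoperiod
(T steps of m seconds; defaults T = 64, m = 900 s for a 16-h window) so that
the crop's **daily photochemical integral** (DPI) requirement is met at
minimum electricity cost.

Light drives photosynthesis through the electron transport rate (ETR),
which saturates with photosynthetic photon flux density (PPFD):

    ETR(PPFD) = a · (1 − e^(−k·PPFD)),

a two-parameter exponential-saturation model. The shipped preset for
"Green Towers" lettuce uses a = 121 µmol m⁻² s⁻¹, k = 0.00277 per
µmol m⁻² s⁻¹ and a DPI requirement D̄ = 3 mol m⁻² d⁻¹. The saturating
shape is what makes optimization worthwhile: a photon added on a dark step
buys more ETR than the same photon added on a bright one, so *when* the
LEDs run matters even under a flat electricity tariff.

Writing x̄_t for the LED ETR contribution at step t, s_t for the sunlight
PPFD and s̄_t = ETR(s_t), the full-horizon program is

    minimize   Σ_t C_t · [ (1/k)·ln( a / (a − x̄_t − s̄_t) ) − s_t ]
    subject to Σ_t (x̄_t + s̄_t) ≥ D̄·10⁶ / m,
               0 ≤ x̄_t ≤ Ū_LED,

with C_t the electricity price (cents/kWh) and Ū_LED the maximum ETR the
fixture can add (default 86.21 µmol m⁻² s⁻¹, a PPFD of ≈450). The bracketed
term is exactly the supplemental PPFD needed to raise total ETR from s̄_t to
x̄_t + s̄_t, so the objective is the price-weighted supplemental light — the
electricity cost up to a constant conversion factor. The objective is
smooth and strictly convex on its domain wherever C_t > 0.

The units convention deserves one remark: rates are µmol m⁻² s⁻¹ and daily
integrals mol m⁻² d⁻¹; the 10⁻⁶ conversion appears exactly once in the
code (`integral_over_day`), and the DPI constraint is stated in rate units
as Σ(x̄+s̄) ≥ D̄·10⁶/m, which for the defaults demands a mean combined ETR
of 52.08 µmol m⁻² s⁻¹.

## Solver

The program's KKT conditions have a closed water-filling structure. With
multiplier λ on the DPI constraint, stationarity gives

    x̄_t(λ) = clip( a − s̄_t − C_t/(k·λ), 0, cap_t ),

a non-decreasing function of λ; bisection on λ (200 iterations) locates
the value at which the constraint binds, after which the non-clipped
coordinates are scaled so the constraint holds to machine precision.
Zero-price steps are free at the margin and are treated separately: they
are filled only as far as the requirement demands, so equal-price
instances bind the constraint exactly instead of overshooting. Per-step
caps are shrunk so that x̄_t + s̄_t ≤ a·(1 − 10⁻⁶), keeping the logarithm
away from its singularity on near-saturating steps. If even the all-cap
schedule cannot meet the requirement the all-cap plan is returned with a
`feasible=False` flag and the shortfall — a greenhouse loop must act every
step, so infeasibility is reported, never raised. Tests verify the
returned optimum against exhaustive grid search on 4-step instances and
against an independent SLSQP solve on larger ones.

## Receding-horizon (predictive) controller

The deployable controller cannot see the future. At each step i it:

1. observes the measured sunlight s_i for the current step;
2. banks the light already delivered, credit = Σ_{t<i} (x̄_t + s̄_t), using
   realized measurements, not old forecasts;
3. forecasts s_{i+1..T−1} with the Markov model (below);
4. re-solves the program over steps i..T−1 with the requirement net of the
   credit, and commits only x̄_i.

Before the first step no informative measurement exists (the photoperiod
starts pre-dawn), so the whole-day forecast is the per-step historical
mean. Because the full problem is strictly convex, feeding the controller
the *true* future makes every re-solve return the suffix of the unique
full-horizon optimum — the receding-horizon machinery then reproduces the
perfect-knowledge baseline exactly, a property the tests assert to 0.1%.
Any remaining gap between the predictive controller and the baseline is
therefore attributable to forecast error alone.

The final-step re-solve carries the constraint: whenever remaining LED
capacity permits, the day ends with DPI ≥ D̄. A deep enough sunlight
collapse late in the day can exhaust capacity; such days are flagged
infeasible with their shortfall and the simulation continues.

## Sunlight prediction

Within-day sunlight is modelled as a first-order Markov chain on 10
equal-width PPFD bins spanning [0, training maximum] (bin representative =
midpoint). Transition counts of consecutive-step pairs, never across a day
boundary, receive add-α smoothing (α = 1, Laplace) so unseen transitions
cannot become absorbing zeros, and are row-normalized. With ≥10 training
days one matrix is fitted per step of day (sunlight dynamics at 08:00 are
not those at noon); smaller training sets fall back to a single pooled
matrix. Forecasts are expectations — an indicator vector at the measured
bin propagated through the transition matrices, dotted with the bin values
— because the optimizer consumes expected sunlight, not scenarios.
Expectation propagation is tested against exhaustive path enumeration.
The bin count, smoothing and time-inhomogeneity rule are design choices of
this package; one fitted model per season is the intended usage.

## Pricing and cost conversion

Prices are cents/kWh per step; hourly profiles are held constant across
the four 15-min steps of each hour. Two kinds ship: a fixed tariff
(13.19 cents/kWh default) and a synthetic 24-h time-of-use fixture (low
overnight, midday plateau, evening peak) constructed for simulation — it
is representative in shape only, not market data.

Supplemental PPFD converts to electrical power through the fixture
efficacy (2.9 µmol J⁻¹, i.e. 2.9×10³ µmol kW⁻¹ s⁻¹), so

    step cost [cents/m²] = C_t · ppfd_t / (2.9×10³) · 0.25 h,

and the factor q = step_hours/(efficacy·10³) = 0.25/2900 satisfies
q·(optimizer objective) = Σ step costs as an exact algebraic identity,
which the tests check to 10⁻⁹ relative.

## Comparator controllers

The **baseline** solves the full-horizon program once with the day's
actual sunlight — an unattainable perfect-foresight optimum that lower
bounds every feasible schedule. The **heuristic** is the common
rule-based strategy: top sunlight up to a fixed PPFD threshold each step,
capped at the LED maximum, blind to prices and forecasts. Its default
threshold is the minimal constant PPFD whose sustained ETR meets the DPI
over the photoperiod (≈203.2 µmol m⁻² s⁻¹ for the defaults), the smallest
threshold that guarantees the requirement; because ETR(203.2) is exactly
the required mean, the heuristic always reaches DPI ≥ D̄ and typically
overshoots it on bright days. LED commands are expressed as PWM duty
cycles, linear in supplemental PPFD up to the fixture maximum.

## Synthetic weather

The generator replaces unavailable measured greenhouse irradiance. Each
day is a half-sine clear-sky PPFD arc over the daylight window, multiplied
by a three-state (clear / partly cloudy / overcast) first-order cloud
attenuation chain sampled at 3-min resolution and by a constant
greenhouse transmission (0.40, the shade-cloth regime). The 3-min samples
are averaged into 15-min control steps, mirroring a sensor polled every
three minutes; the 15-min value equals the mean of its five samples
exactly. Two presets are calibrated by Monte Carlo
(`scripts/calibrate_weather.py`) against seasonal daily-light-integral
statistics and then frozen:

| preset        | DLI mean target | DLI sd target | 1000-day empirical |
|---------------|-----------------|---------------|--------------------|
| winter_athens | 2.22            | 0.60          | ≈2.19 ± 0.59       |
| spring_athens | 7.45            | 3.11          | ≈7.53 ± 2.96       |

Cloud persistence controls the split between within-day (15-min) and
day-to-day variability; the spring preset is both brighter and far more
variable, which is the regime where optimization pays off. What the
generator does *not* emulate: solar-position astronomy (sunrise time and
day length are fixed per preset), within-day transmission changes from
shade-screen movement, spectral composition, and weather-front
autocorrelation across days (days are independent draws). Passing tests
therefore demonstrate the controllers' properties under a statistically
realistic but simplified sky; absolute cost levels on real greenhouse data
will differ, while the structural guarantees (constraint satisfaction,
baseline optimality, oracle equivalence) are data-independent.

## Simulation scale and numerical choices

Default study sizes keep a full season tractable on a laptop: seasons of
20 training + 30 evaluation days, 64 re-solves per predictive day, ~2 ms
per solve. Bisection runs 200 iterations (λ resolved far below any
meaningful tolerance); constraint satisfaction is reported to 10⁻⁶
relative; the log-domain guard is 10⁻⁶·a. Degenerate inputs: days whose
sunlight alone meets the requirement yield all-zero plans at zero cost;
requirement already covered by banked credit likewise; infeasible horizons
return capped plans with a shortfall; near-saturating sunlight shrinks the
per-step cap rather than failing.

## Known limitations

- Expectation forecasts ignore forecast uncertainty; a risk-aware
  (scenario or quantile) formulation could hedge late-day sunlight
  collapse instead of relying on end-of-day capacity.
- The dim early-morning start inherits the historical mean; on unusually
  dark days this overestimates sunlight until the first in-day updates
  arrive, the main source of the predictive controller's residual cost gap.
- Continuous dimming is assumed (LED hardware with 0–10 V dimming); on/off
  fixtures need a discrete formulation outside this package's scope.
- Heating interactions, spectral quality and canopy-level light gradients
  are not modelled.
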