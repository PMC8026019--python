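# Methods

## Scope

`metpbpk` implements a whole-body physiologically based pharmacokinetic
(PBPK) model of metformin for the mouse (20 compartments) and the human
(21 compartments; the extra pool is red blood cells). Metformin is not
metabolized: it is absorbed from the gut by saturable carriers and passive
paracellular transport, distributes into tissues, and is eliminated
unchanged in urine by glomerular filtration plus saturable tubular
secretion. The human model is derived from the mouse model by replacing
the physiology (volumes, plasma flows, filtration rate) and rescaling the
transporter capacities with two coefficients — this mouse-to-human
"scale-up" is the central scientific object of the package.

## Units and state

The ODE state is the **amount** of metformin free base in each compartment
(nmol); concentrations are amounts divided by compartment volume (mL), so
concentrations are nmol/mL (numerically equal to µM). Time is hours,
flows/clearances mL/h. Doses may be given as free base or as hydrochloride
salt; 1000 mg of the salt contains 778.4 mg of base (molar mass of the base:
129.16 g/mol).

## Model structure

Vascular wiring: venous plasma → lungs → arterial plasma; arterial plasma
perfuses heart, brain, muscle, adipose, stomach, kidneys, intestine, liver
(hepatic artery) and a lumped remainder. Stomach and intestine drain into
the portal vein, which perfuses the liver; liver, kidneys and the other
tissues return to venous plasma. The lungs carry the full cardiac (plasma)
output.

Tissue types:

- **Flow-limited tissues** (lungs, heart, brain, muscle, adipose, stomach,
  liver, remainder): uptake at the perfusing plasma flow `Q`, return flow
  `Q · C_tissue / K_t:p`, where `K_t:p` is the tissue:plasma partition
  coefficient. At steady state the tissue:plasma concentration ratio
  equals `K_t:p`.
- **Gut**: stomach lumen → intestine lumen (first-order gastric emptying)
  → feces (first-order transit). Absorption from the intestinal lumen uses
  five transport processes: saturable apical uptake into enterocytes
  (reaction 03.2), saturable basolateral efflux into intestinal capillary
  plasma (03.3), a saturable paracellular route directly to plasma (03.4),
  and two linear diffusion routes (03.6 lumen→enterocytes, 03.7
  lumen→plasma). A passive bidirectional exchange (03.8) links capillary
  plasma and enterocytes with partitioning `K_t:p(intestine)`.
- **Kidney**: arterial plasma perfuses a small kidney-plasma pool;
  glomerular filtration (12.1) moves drug from kidney plasma to the
  tubular lumen at `Q_GFR`; the tubular lumen empties into urine (12.2).
  Active secretion is a two-step saturable path: basolateral uptake from
  kidney plasma into kidney tissue (13.4, OCT2-like) and apical efflux
  into the tubular lumen (13.5, MATE-like), plus a passive exchange (13.6)
  with partitioning `K_t:p(kidney)`. Total renal clearance is therefore
  `CL_renal = Q_GFR + CL_active` at sub-saturating concentrations, capped
  by renal plasma flow (`CL_sys = Q·CL_i/(Q+CL_i)`).
- **Red blood cells** (human only): a slow bidirectional exchange with
  venous plasma (15.1) parameterized by uptake and release clearances;
  their ratio sets the equilibrium RBC:plasma ratio and their magnitude
  the multi-hour RBC time scale.

Every rate law except the five Michaelis–Menten carriers is linear in the
amounts, so the system is `dA/dt = M·A + (saturable terms)` with a constant
matrix `M` and an analytic Jacobian. Integration uses LSODA with tight
tolerances (`rtol 1e-8`, `atol 1e-10` nmol); dose events are handled as
integration restarts with the bolus added to the entry compartment
(oral → stomach lumen, intravenous → venous plasma). Mass balance —
amounts in all compartments plus excreta versus total administered base —
holds to ~1e-15 relative.

## In-vitro-to-organ translation and species scale-up

Intestinal carrier constants are expressed per mg of intestinal monolayer
protein (Caco-2 convention) and scaled to the whole organ by
`value × 0.2 mg protein/cm² × mucosal surface area` (0.2 mg/cm² is the
standard monolayer protein density). Reference areas: mouse 3·10⁴ cm²,
human 7.1·10⁵ cm² (71 m², villi and microvilli included).

The human model inherits all mouse kinetic constants and applies:

- **absorption coefficient 0.7** to the capacities of the five intestinal
  absorption processes (03.2, 03.3, 03.4, 03.6, 03.7), after the surface
  area substitution;
- **elimination coefficient 320** to the capacities of the two renal
  secretion steps (13.4, 13.5).

Affinities (Km) are conserved across species. Partition coefficients are
taken unchanged from the mouse. Human physiology (volumes, flows, GFR)
replaces mouse physiology; body weights other than the 70 kg reference
scale volumes and flows linearly.

## Reference parameterization

The packaged parameter files
(`src/metpbpk/parameters/{mouse,human}_synthetic.yaml`) are **synthetic
reference assemblies**, not a deposited parameter set: physiological
volumes and flows follow standard compendia for a 25 g mouse and a 70 kg
human; partition coefficients are fitted literature values (intestine 4.6,
stomach 3.2, liver 5.5, lungs 3.0, brain 0.8, muscle 4.1, adipose 0.7,
heart 2.5, remainder 0.8, kidney 4.5); carrier kinetics were calibrated
once, before the test suite was written, so that the closed model
reproduces headline in vivo behaviour in both species simultaneously:

| quantity | model | typical in vivo |
|---|---|---|
| mouse 50 mg/kg PO, urinary fraction (24 h) | 0.62 | ~0.6 |
| mouse 50 mg/kg PO, plasma Cmax (nmol/mL) | 27 | ~27 |
| mouse PO kidney Cmax (nmol/mL) | 505 | ~430 |
| mouse PO intestinal tissue Cmax (nmol/mL) | 1660 | ~1640 |
| human 500 mg, plasma Cmax (nmol/mL) | 5.5 | ~6 |
| human 500 mg, plasma AUC₀₋₂₄ (nmol·h/mL) | 44 | ~42 |
| human 500 mg, urinary fraction (24 h) | 0.44 | ~0.5 |
| human 500 mg BID ×8, plasma Cmax / Cmean | 6.9 / 3.9 | ~6.9 / 3.5 |
| human BID RBC Cmax (nmol/mL) | 3.3 | ~3.2 |

Key calibration insights, recorded because they constrain any
re-parameterization:

1. **Renal extraction is flow-limited.** The systemic renal clearance is
   `Q·CL_i/(Q+CL_i)`, so achieving a human clearance of ~30 L/h after the
   ×320 scale-up forces a high intrinsic basolateral capacity in the mouse
   (13.4 Vmax = 12 000 nmol/h at Km 18 nmol/mL).
2. **Linear absorption routes carry most of the flux in vivo.** Luminal
   concentrations after realistic doses are far above the carrier Km
   values, so the saturable routes clip and the diffusion constants
   (03.6/03.7) largely set the absorbed fraction.
3. The same area×coefficient scaling cannot make both species' absorbed
   fractions match observation with shared luminal transit parameters;
   gastric emptying, intestinal transit and effective lumen volumes are
   therefore species-specific physiology, not scaled kinetics.

## Non-compartmental analysis

AUC is the linear trapezoid; Cmax/Tmax on raw (sparse) curves is the
discrete maximum with ties resolved to the earliest time, while summaries
of dense simulated trajectories refine the peak by parabolic interpolation
through the discrete maximum (removing output-grid quantization of Tmax).
Terminal half-life is `ln 2 / λz` with λz from the log-linear regression
over the suffix of ≥3 strictly-post-Tmax points maximizing adjusted R²
(standard best-fit convention). Multi-dose summaries report the
course-wide Cmax/Tmax, the mean concentration over the final complete
dosing interval, and the steady-state time — the peak time of the first
interval whose Cmax changed by <1% from the previous interval, or the time
of the global maximum for monotonically accumulating pools such as red
blood cells.

## Estimation

Observations are tidy `(curve, time_h, value)` tables; curves are model
compartments (concentrations) or urine/feces (cumulative amounts).
Measured tissue homogenates can be corrected for trapped blood by dividing
by the inulin-space tissue fraction. After oral dosing the stomach-tissue
curve and a known outlier sampling occasion (the 2 h point in plasma,
portal vein and brain) are excluded.

The objective is least squares with each curve's residuals scaled by the
reciprocal of its observed mean (weight 1/mean² on squared residuals), so
curves of different magnitude contribute comparably. Optimization runs in
log-parameter space with `scipy.optimize.least_squares` (trust region
reflective, bounds), optionally multistarted from a seeded Latin hypercube
over the log-bounded box. Noiseless synthetic datasets are recovered
essentially exactly (partition coefficients to <1%, scale-up coefficients
to machine precision); synthetic noise is multiplicative lognormal with
`sigma² = ln(1+cv²)` and mean-preserving offset, default CV 10%.

Identifiability notes: the kidney partition coefficient is weakly
identified from oral data alone, because kidney-tissue kinetics are
dominated by the secretion carriers at low concentrations; joint fitting
of an oral plus an intravenous experiment (where concentrations transiently
saturate the carriers and the passive exchange becomes visible) restores
recovery to <1%. The stomach coefficient requires intravenous data for the
same exclusion reason as above.

## Limitations

- The parameter files are synthetic reference assemblies. They reproduce
  the headline behaviours above but are **not** a fitted, deposited
  parameter set; absolute tissue predictions inherit that uncertainty.
- The simulated mouse oral plasma terminal half-life is ~0.9 h, shorter
  than the 2–3 h apparent half-life often reported from sparse in vivo
  grids; the sparse-grid estimate mixes absorption and elimination phases.
- Human kidney-*tissue* accumulation is modest in this model
  (Cmax ≈ 17 nmol/mL at 500 mg). Symmetric ×320 scaling of both secretion
  steps cannot produce the very high human renal tissue concentrations
  sometimes reported, because at human plasma concentrations the
  influx:efflux capacity ratio is lower than in the mouse; matching such
  values would require asymmetric scaling of 13.4 vs 13.5.
- Transporter capacities do not scale with body weight in the
  `body_weight` option; only physiology does.
- No population variability, protein binding (metformin is essentially
  unbound), or metabolism (none known) is modelled. SBML export is not
  implemented.
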