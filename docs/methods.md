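# Methods

## Model structure and assumptions

The eye is reduced to three well-mixed fluid compartments: the tear film
(drug only — VEGF in tears is five to seven orders of magnitude below the
post-drop drug concentration and is neglected), the aqueous humor, and
the vitreous humor. Well-mixedness is the defining idealisation: tear and
aqueous volumes are small and actively circulated, and the aged, partly
liquefied vitreous mixes on a time scale of hours, which is fast relative
to the multi-week human simulations but *not* relative to a 3.5-hour
bench experiment — one reason the intravitreal fit is initialised from
measured 20-minute concentrations rather than from the nominal bolus.

VEGF has two identical, independent drug-binding sites. With binding rate
`k⁺` per site and unbinding `k⁻` per occupied site, the free ligand binds
at `2k⁺vr` (two open sites), the single complex VR binds a second drug at
`k⁺ru` and dissociates at `k⁻u`, and RVR dissociates at `2k⁻w` (either
drug may leave). These rates conserve total VEGF (`v+u+w`) and total drug
(`r+u+2w`) exactly; the test suite enforces both identities algebraically
and along trajectories.

Transport consists of: corneal influx of drug from the tear film (a
one-way flux — the peptide carrier assists only tear→aqueous passage, and
back-diffusion is negligible because the tear volume is an order of
magnitude smaller than the aqueous); bidirectional diffusive exchange of
all four species across the aqueous–vitreous interface; dilution of
aqueous solutes by aqueous turnover `ψ_Aq`; dilution of tear drug by tear
turnover `ψ_Tear`; constant retinal VEGF supply `φ_Vit,v`; and
vitreo-retinal interface terms for the drug species.

### Sign convention for the vitreo-retinal terms

The vitreo-retinal interface terms for R, VR and RVR enter the vitreal
equations with a **positive** sign, `+β_Vit-Ret,j·A_Vit-Ret/V_Vit·x_j`.
A loss interpretation (negative sign) was implemented and compared during
development: with the drug-eluting-lens submodel the steady state is
analytically `r_Aq = I/(ψ_Aq + bc/(b+c))` (negative sign) versus
`I/(ψ_Aq − bc/(c−b))` (positive sign), where `I` is the corneal influx,
`b = β_Vit-Ret,r·A_Vit-Ret` and `c = β_Aq-Vit,r·A_Aq-Vit`. Only the
positive convention permits `r_Vit > r_Aq` under topical delivery and
reproduces the reference predictions for all three human regimens to
better than 1%; the negative convention misses them by 9–15%. Physically
the positive term can be read as slow re-release from a retinal/choroidal
reservoir; numerically it is benign because `b` is ~2% of `c`, so the
system remains strongly dissipative. The coefficient is a parameter, so
users who prefer a strict-loss model can set `beta_vit_ret_* = 0` (the ex
vivo configuration does exactly that).

### Tear-volume law and dosing events

After a drop, the human tear volume jumps to the reservoir volume
(3.0e-2 mL; the excess of the 4.5e-2 mL drop runs off immediately after
mixing) and drains linearly back to the normal film volume (6.35e-3 mL)
over `τ_loss` = 0.05 h, with a Heaviside cutoff (H(0) = 1) holding it at
baseline thereafter. The enucleated porcine eye cannot maintain a film:
the volume is either the full drop (constant-volume variant, the default
for fitting — consistent with visual observation that the drop largely
stays put) or drains linearly to zero. In the draining variant the
`1/V(t)` loss rate is singular at `τ_loss`; since the exponent
`β·A·τ/V_Drop ≈ 1e-6` makes the drug lost in the final sliver negligible,
the implementation freezes the tear compartment once `V ≤ 1e-6·V_Drop`
(and keeps it frozen, with zero corneal flux, as the volume cannot
recover ex vivo).

Drops mix instantaneously (`r_new` is the volume-weighted average of film
and dose), injections add `r_Dose·V_Drop/V_Vit` to the vitreous (the
injected 45 µL is negligible against the 4.5 mL vitreous and quickly
drained), and lens insertion pins the tear concentration at
`r_Tear_init`, releasing it to free decay on removal. Consecutive drops
must be at least `τ_loss` apart so the film has returned to baseline. A
drop and an injection scheduled at the same instant are applied drop
first — a determinism convention only, as they reset disjoint variables.

## Parameters

Defaults (human and ex vivo porcine columns) are hard-coded factories
carrying literature-derived geometry (volumes, interface areas), binding
kinetics (`k⁺` = 0.576 pmol⁻¹ mL h⁻¹, `k⁻` = 2.63e-2 h⁻¹), turnover
rates, the fitted permeabilities, and dose concentration
(2.07e4 pmol mL⁻¹ ≈ 1 mg/mL of a 48 kDa fragment). Degradation rates
default to zero (a simplifying assumption) but are first-class parameters
because the sensitivity analysis sweeps them up to 0.77 h⁻¹. The ex vivo
switches (`ψ = φ = β_Vit-Ret = 0`) encode the absence of turnover, VEGF
production and choroidal clearance in a bench eye. All parameters
serialise to flat YAML/JSON key–value files, round-tripping bit-exactly.

Initial VEGF concentrations are the untreated steady state. With zero
degradation this is closed form: `v_Aq = φ/ψ_Aq` (everything supplied
must leave by aqueous washout) and `v_Vit = v_Aq + φ/(β_Aq-Vit,v·A_Aq-Vit)`
(the exchange flux must carry the supply); with degradation the 2×2
linear balance is solved. Sweeps over parameters entering this balance
re-derive the initial conditions per draw by default (`recompute_init`),
so each swept model starts at its own untreated equilibrium.

## Numerics

Default backend: a numba-compiled Dormand–Prince 5(4) stepper with
rtol 1e-8, atol 1e-12 pmol mL⁻¹, cubic-Hermite dense output on a ≤ 0.1 h
grid, and integration restarted at every dose event and at `τ_loss` after
each drop (adaptive steppers lose order across derivative kinks). The
post-injection binding collapse (free vitreal VEGF falls six orders of
magnitude in ~12 minutes) is fast but not stiff at these tolerances; a
scipy backend (`backend="scipy"`, `method="LSODA"`) provides a stiff
fallback and the cross-check oracle. Trajectory rows are duplicated
immediately before/after each event to capture discontinuities;
`summarize` means are trapezoid-rule time averages, not sample averages.
Accepted states with round-off negatives above −1e-12 are clamped to
zero; anything more negative raises (it signals a tolerance problem).
Interpolated output samples are clamped at −1e-9, reflecting the lower
order of the dense interpolant.

The drug-only bench submodels (VEGF disabled) are linear, so the fitting
and MCMC likelihoods evaluate concentrations exactly via the matrix
exponential of a 3×3 (topical: tear/aqueous/vitreous) or 2×2
(intravitreal) rate matrix — roughly three orders of magnitude faster
than time-stepping, and verified against the simulator to 1e-5 relative.

## Fitting

*Topical fit* (two free parameters: `β_Tear-Aq,r`, `β_Aq-Vit,r`):
constant tear volume equal to the drop volume, depleting tear
concentration, `r_Tear(0) = r_Dose`, drug-free aqueous and vitreous.
Objective: mean squared error against the topical-group aqueous drug
means. Points flagged below detection (mean and sd both exactly zero) are
excluded by a data-driven rule rather than a hard-coded time list — in
the bundled dataset this removes the anomalous 1 h point, leaving 20 min,
40 min and 3.5 h. *Intravitreal fit* (one parameter): no tear
compartment; the state at 20 min is set to the measured aqueous/vitreal
means and the later three aqueous means are fit.

Optimisation is Nelder–Mead on log10 parameters, multi-started from a 3×3
grid spanning ±2 decades around (1e-6, 1) cm h⁻¹ (the simplex can stall
from a single poor start), with the objective clamped to a large finite
penalty outside log10 ∈ [−14, 4] to keep the simplex in the numerically
representable range. A fit whose objective is flat under two-fold
parameter changes is flagged `degenerate` (unidentifiable data).
Including VEGF at measured bench concentrations shifts the fitted
permeabilities by ≲1.5% — VEGF is orders of magnitude below the drug, so
binding consumes a negligible drug fraction.

## Metropolis–Hastings identifiability

Random-walk MH in log10-parameter space, Gaussian proposals (default sd
0.025 dex, chosen so acceptance falls in the 0.1–0.6 band for both
chains), log-uniform priors on [1e-9, 1e-4] (corneal) and [1e-2, 10]
(aqueous–vitreous) cm h⁻¹, default 1e5 steps with 20% burn-in, fully
seeded.

The likelihood is an independent Gaussian on the fitted means. Its noise
scale is **fixed** by default at 1% of the largest fitted mean — an
instrument-precision scale for the group means. This choice sets only
the posterior *width*; the peak sits at the least-squares optimum
regardless. The superficially more principled alternative — treating the
scale as unknown with a Jeffreys-type prior and marginalising, giving a
`SSE^(−n/2)` marginal likelihood — is retained as
`error_model="marginal"`, but with only three fitted means and one or two
parameters that posterior is Student-like with at most two degrees of
freedom: essentially width-free, its mean dominated by the prior range.
It is kept as a conservative bound, not as the default, because an
identifiability statement needs a likelihood that actually constrains.
With the default model both posteriors are unimodal and sharp, with means
indistinguishable from the point estimates and relative sds of a few
percent.

## Synthetic data

`generate_measurements` emulates the bench sampling design — aqueous and
vitreal drug concentrations at 20 min, 40 min, 1 h and 3.5 h, three
replicate eyes per point — by simulating the corresponding ex vivo
submodel at known parameters and adding Gaussian noise with
sd = max(absolute floor, proportional·signal), truncated at zero to mimic
an immunoassay detection limit (real tables of this design contain exact
zeros). A single seed fans out to one stream per
(compartment, time, replicate), so growing the replicate count extends
rather than reshuffles earlier replicates. The generator reproduces the
*design* of the real experiment, not its biology: replicate scatter is
i.i.d. Gaussian, whereas real eyes contribute shared, between-eye
variability, assay nonlinearity near the floor and occasional gross
outliers (the real data contain an all-zero time point between two
detected ones). Parameter-recovery tests therefore validate the inference
machinery — estimator consistency, absence of coding bias — not the
field accuracy of the error model. Zero-noise recovery is exact to
<0.1%; at 20% proportional noise the recovery distribution over 200
datasets is centred on the truth (median bias <1%; the mean of the
aqueous–vitreous permeability is noise-skewed upward by a few percent,
as expected for a positively constrained parameter).

## Sensitivity analysis and regimen sweeps

One-at-a-time sweeps over tabulated biologically realistic ranges
(inclusive endpoints; 101 values by default, `step = range/100`), under
three fixed 12-week regimens: hourly drops (24/day), a continuously worn
lens, and injections at the start of weeks 1, 5 and 9. Outputs are the
max / time-mean / min of vitreal free VEGF and total vitreal drug
(`R_Tot = r + u + 2w`, two drug molecules per RVR) over weeks 9–12, where
the solution has settled (weeks 6–9 agree with weeks 9–12 to <0.5%). The
sensitivity factor is max-over-sweep / min-over-sweep of each output;
factors above 1.5 are deemed significant; a zero minimum reports an
infinite factor. Results are independent of evaluation order, and a sweep
pinned at the default value reproduces the unswept run bit-for-bit.

Regimen sweeps vary dosing intensity: 1–16 drops/day (first at 0 h,
spacing 16/n h across a 16-hour waking day) over 12 weeks; lenses worn
1–30 days with 1-day breaks over 124 days (window = final cycle);
injection intervals of 1–8 weeks over 32 weeks (window = the final
*complete* inter-injection cycle, which matters when the interval does
not divide the horizon); and the two dual modes (injections plus 4
drops/day at 4, 8, 12, 16 h, or plus lenses worn days 2–7 weekly).
Weekly "start of week k" maps to global hour (k−1)·168, and "start of
hour h" to hour (h−1) of the day, so "hours 1 to 16" yields 16 drops at
0…15 h.

## Problem sizes used in the shipped checks

The test suite and acceptance script run everything at full printed
scale except the sensitivity screen, which uses 11-point sweeps over the
six parameters significant under every regimen (the full 101-point ×
all-parameter × 3-regimen table is an overnight batch exposed through
`sensitivity_table` / the CLI). MCMC chains are 1e5 steps as in the
headline analysis; unit tests use shorter 2e4-step chains of the same
kernel.

## Known limitations

- No retinal or choroidal compartment: treatment efficacy is read from
  vitreal VEGF, one compartment removed from the disease site.
- No spatial resolution: post-injection gradients (clearly present in
  the bench data, where measured vitreal drug is far below the nominal
  bolus) are outside the model class; the fits work around this by
  initialising from measured concentrations.
- The peptide carrier is implicit — folded into the corneal permeability
  — so carrier dose, unbinding kinetics and carrier effects at inner
  barriers are not represented.
- Degradation defaults to zero; nonzero values are explored only in
  sensitivity sweeps.
- The topical submodel cannot reproduce vitreal drug measurements that
  exceed aqueous ones at early times (drug must flow down its gradient);
  such data are treated as unreliable rather than fit.
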