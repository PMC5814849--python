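# Methods

`walkerstep` models the leg-placing reaction of a DNA bipedal walker on an
origami track at two levels — a kinetic competition for the yield, and a
coarse polymer model for how the stepping rate depends on geometry — plus a
synthetic single-molecule FRET measurement used to exercise and validate the
analysis chain end to end.

## Kinetic competition

After the first fuel strand binds (to either the lifted leg or the next
foothold; the two intermediates are collapsed into one, assuming equal rates
from both), two first-order processes race: intramolecular stepping at
*k*<sub>s</sub> and binding of a second fuel at *k*<sub>FB</sub>[F1].
Trapping is treated as irreversible and absorbing — the fuel duplexes
(16 bp to the leg, 18 bp to the foothold) do not dissociate on experimental
timescales — so after long incubation every motor is either leg-placed or
trapped and the yield is the branching fraction
*Y* = *k*<sub>s</sub>/(*k*<sub>s</sub> + *k*<sub>FB</sub>[F1]).

The same competition is expressed through activation free energies with a
common kinetic prefactor, *Y* = softmax of −ΔG‡ terms, where the whole
concentration dependence sits in the fuel-binding barrier
ΔG‡<sub>FB</sub>([F1]) = ΔG‡<sub>FB,0</sub> − ln([F1]/c₀) with c₀ = 1 M by
convention. This makes the barrier picture exactly equivalent to the rate
picture under the mapping k = A·exp(−ΔG‡), which the tests assert to ten
significant digits. All energies are in units of k<sub>B</sub>T; temperature
never appears explicitly.

A stochastic first-passage oracle (`simulate_race`, exponential clocks, the
earlier clock wins) provides an independent check of the closed form at the
binomial 3σ level.

## Coarse mechanical model

The rate-limiting event of stepping is the formation of the first base pair
between the free leg terminus and the fuel overhang on the next foothold.
The construct is split into two independent tethered arms ("separate
molecules before contact"):

* **bound arm** — foothold anchor spacer (2 nt ss), the nicked
  foothold·fuel·leg duplex complex (18 + 16 bp) as **one coaxially stacked
  rigid rod**, the inter-leg hinge (3 nt ss), and the free 16-nt leg domain;
* **fuel arm** — anchor spacer (2 nt ss), the 18-bp foothold·fuel duplex
  rod, and the free 16-nt fuel overhang.

Duplexes are rigid rods at 0.34 nm/bp — all far below the ~50 nm dsDNA
persistence length. Single strands are freely-jointed chains with Kuhn
length 1.5 nm and contour 0.63 nm/nt; a partial terminal Kuhn link keeps its
true (shorter) length, and a segment shorter than one Kuhn length is one
rigid link. Joints, including the foothold anchors, are free pivots. The
only excluded-volume interaction is the track itself: a hard flat wall, or
the outside of a cylinder for the curled short axis (walker on the convex
side, tube circumference equal to the 60 nm origami width, R = 60/2π nm).
Wall rejection is exact at the *segment* level: on the flat track the
allowed half-space is convex so bead checks suffice, while on the cylinder
each rigid link is tested for closest approach to the axis so rods cannot
cut through the tube.

Treating the nicked duplex complex as one stacked rod (rather than rods
jointed at the nick) is a deliberate model choice: coaxial stacking across
nicks is the standard expectation for duplexes this short, and the jointed
variant makes the placement barrier rise several k<sub>B</sub>T across
5–20 nm steps, much steeper than the weak short-step dependence this system
exhibits.

### Contact probability and barriers

Both arm-end densities are sampled once at a canonical anchor
(10⁵ accepted conformations per arm by default) and transported rigidly to
any separation — translation on the plane, rotation about the axis on the
cylinder — so a single pair of clouds serves a whole step-size grid. Arc
separations beyond half the circumference are evaluated the shorter way
around (wrap-around).

The probability that the reactive ends approach within the capture radius
δ (default 1 nm, the scale of one base-pair bond; it cancels to first order
in barrier differences) is the overlap integral
p(d) ≈ (4π/3)δ³ ∫ρ<sub>A</sub>ρ<sub>B</sub>d**r**, evaluated on a 1 nm
voxel grid with Gaussian kernel smoothing. Numerical choices:

* **bandwidth 0.5 nm, kernel truncated at 16σ (8 nm reach).** The narrow
  bandwidth keeps the kernel-smoothing bias of the overlap below the
  Monte-Carlo error at the sample sizes used (verified against the exact
  pairwise-hit estimator, which agrees within 3σ wherever it registers
  hits); the long truncation keeps the smoothed densities strictly positive
  out to the geometric support, which is what resolves contacts rarer than
  10⁻⁶ near the reach limit.
* **support clipping.** Each density is zeroed beyond its arm's exact
  contour radius and one voxel below the wall, so p(d) is *exactly* zero
  beyond the reach limit (bound-arm contour + fuel-arm contour + δ).
* **boundary-kernel renormalization.** The smoothed histogram is divided by
  the smoothed support indicator, removing the first-order density
  underestimate next to the wall and support edges.
* **uncertainty.** The overlap is linear in each arm's histogram and the
  Gaussian filter is self-adjoint, so the integral equals a ratio of
  per-conformation voxel lookups; bootstrap resampling of those lookups
  (64 resamples, each side independently) gives the standard error.

Only barrier differences are physical:
ΔΔG‡(d) = −ln p(d)/p(d<sub>ref</sub>). They are anchored at the
d<sub>ref</sub> = 12 nm reference step with k<sub>s</sub><sup>ref</sup> =
3.5 s⁻¹ — the short-step stepping-rate scale implied by the measured
3.5 × 10⁻⁵ s⁻¹ at 35 nm lying five orders of magnitude below the short-step
rates — and k<sub>FB</sub> = 2.3 × 10⁵ M⁻¹s⁻¹. Cylinder-track predictions
are calibrated against the *flat* reference, since the reference rate is a
flat-origami measurement. The default model then places the 50% crossover
of the 10 nM yield curve near 28 nm, holds the 5–20 nm barrier span to
about 2 k<sub>B</sub>T, and puts the reach limit at 43.3 nm; all three are
recomputed by `scripts/acceptance.py`.

### Fuel hairpin

Transient secondary structure in the fuel overhang is modelled as a
two-state mixture: with probability p<sub>open</sub> = 1/(1+e^(−ΔG_hp)) the
full overhang is available, otherwise `sequestered_nt` nucleotides
(default 10) are removed from the overhang end. The folding free energy is
a config input (default −2 k<sub>B</sub>T), *not* computed from sequence.
The folded state cannot sag back down to the surface near the foothold
anchor, so it suppresses contact more strongly at 5 nm than at 10 nm steps
— the mechanism behind the short-step yield dip, asserted as a paired-run
test.

## Synthetic smFRET measurement

The generator emulates the diffusion-based two-population readout: each
burst is leg-placed with probability f<sub>LP</sub> (given by the kinetic
competition at that condition's true stepping rate and fuel concentration)
and its efficiency is drawn from a truncated normal on [0, 1]
(defaults: E<sub>LP</sub> = 0.2, E<sub>Trap</sub> = 0.8, widths 0.1 —
"clearly distinguishable" populations; the low/high assignment is a
labelling convention and can be swapped). Population widths stand in for
shot noise and heterogeneity; there is no photon-level simulation (no gamma
factor, background, bleed-through or burst search), so recovery tests
demonstrate the estimator under clean mixture conditions, not under
photon-budget artefacts of real data.

`estimate_fractions` fits the two-component truncated-normal mixture by EM.
The default fixes means and widths to control-characterized values (typical
smFRET practice) and estimates only the mixing weight; a free-means mode
uses weighted normal moments in the M-step (truncation corrections are
negligible for well-separated populations inside the unit interval). The
reported fraction is the weight of the component nearer E<sub>LP</sub>, so
the estimate is invariant to component relabelling. Confidence intervals
are percentile bootstrap over bursts (200 resamples). Fits are refused
below 50 bursts (EM instability) and for coinciding means
(unidentifiable); yields outside (0.01, 0.99) are flagged unreliable by the
rate-extraction stage rather than inverted, because 1−Y cancellation
destroys rate information there.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `k_FB` | 2.3e5 | M⁻¹s⁻¹ | fuel-binding rate constant |
| `k_s_ref` | 3.5 | s⁻¹ | stepping rate at the reference step |
| `d_ref_nm` | 12 | nm | calibration step size |
| `capture_radius_nm` | 1.0 | nm | first-base-pair capture distance δ |
| `ss_kuhn_nm` | 1.5 | nm | ssDNA Kuhn length |
| `ss_contour_nm_per_nt` | 0.63 | nm/nt | ssDNA contour per nucleotide |
| `ds_rise_nm_per_bp` | 0.34 | nm/bp | duplex rise per base pair |
| `cylinder_radius_nm` | 9.5493 | nm | 60 nm circumference / 2π |
| `bandwidth_nm` | 0.5 | nm | overlap-integral KDE bandwidth |
| `grid_spacing_nm` | 1.0 | nm | KDE voxel size |
| `n_conformations` | 100000 | — | accepted conformations per arm |
| `dG_hp_kBT` | −2.0 | k<sub>B</sub>T | hairpin folding free energy |
| `sequestered_nt` | 10 | nt | overhang nt unavailable when folded |
| `E_LP`, `E_Trap` | 0.2, 0.8 | — | FRET population means |
| `n_bursts` | 3000 | — | bursts per condition |

Segment lengths (anchor spacers 2 nt, hinge 3 nt, leg/overhang 16 nt,
duplexes 18 and 16 bp) are shipped in the default config and fully
overridable; the duplex lengths follow the walker's printed fuel-attachment
design, the spacer/hinge lengths are typical origami-walker values.

## Problem sizes and determinism

Default runs use 10⁵ accepted conformations per arm (seconds per arm;
a full yield-surface prediction completes in well under a minute on one
CPU) and 3000 bursts per FRET condition. The test suite uses 2 × 10⁴
conformations for property checks and the full 10⁵ for the headline
checks. All randomness flows from a single 64-bit seed through
`numpy.random.SeedSequence` substreams (per arm, per stage, per
condition); identical config + seed reproduce every CSV byte-for-byte, and
stochastic outputs carry their seed in metadata.

## Known limitations

* Barrier **differences** only: absolute stepping rates require the one
  experimental calibration point, and no base-pair-resolution free-energy
  profile (the downhill zipping after the first base pair) is modelled.
* The cylinder is a static, permanently closed, untwisted tube. It
  reproduces the earlier short-axis yield collapse (reduced overlap on the
  convex side) and the survival of yield beyond half-circumference
  separations via the wrap-around route, but it makes that route nearly as
  easy as a short forward step, so the predicted wrap-around yield at the
  largest short-axis steps (~100% at 1 nM) far exceeds the ~10% plateau a
  fluctuating, partially curled origami produces. Capturing the magnitude
  would need a model of tube closure statistics (seam gap, twist,
  curvature fluctuations), outside this package's scope.
* Intra- and inter-arm excluded volume is ignored (wall only); hairpin
  stability is an input, not computed from sequence; the origami is not
  simulated (curvature is an imposed parameter); the leg-lifting reaction
  and multi-step walking are out of scope except for the cumulative-yield
  helper.
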