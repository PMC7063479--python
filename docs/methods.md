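# Methods

## Pore-block model

Drug-channel interaction is modeled as memoryless pore block: at free
concentration `C` (nM), a channel with half-block concentration `IC50`
(nM) conducts the fraction `1 - beta` of its current, with

    beta = C^h / (C^h + IC50^h),    h = 1 by default.

This form is monotone increasing in `C`, equals 1/2 at `C = IC50`, and
saturates at full block — the standard IC50 semantics. (An equivalent
form sometimes typeset as `beta = [1 + C/IC50]^-1` inverts the
concentration dependence; the package documents and implements the
increasing form, which reproduces the reference block percentages from
the bundled table.) The Hill exponent is exposed per call for forward
compatibility with kinetic datasets but is fixed at 1 throughout the
pipeline; state-dependent (kinetic) binding models are out of scope.

A missing IC50 — printed as "–" in the source table for chlorpromazine,
cisapride, and tedisamil — means no measurable block at any tested
concentration and is mapped to `beta = 0`, giving those drugs vertical
trajectories in the block plane. All concentrations are nM; doses are
expressed as dimensionless multiples of the drug's effective free
therapeutic plasma concentration Cmax.

## EAD detection

An early afterdepolarization is a secondary depolarizing deflection
during repolarization. Detection operates on a uniformly sampled voltage
trace (detection grid 1 ms; finer internal solver steps are permitted
but the criterion is a finite difference, so the detection grid is fixed
and stated): an EAD is present when the forward slope `(V[k+1]-V[k])/dt`
exceeds 0.1 mV/ms at any sample whose offset from the cycle's stimulus
lies in [50, 1000] ms, in either of the last two recorded cycles of a
600-cycle, 1 Hz pacing run. Only *positive* slopes count: EADs are
upward deflections, and repolarization itself has a negative slope far
exceeding 0.1 mV/ms in magnitude, so an absolute-value reading would
fire on every normal beat. The window is clipped at the next stimulus so
a following upstroke can never satisfy the criterion; for the final
cycle the window ends with the trace.

Cell models are pluggable through a single contract —
`simulate(block, protocol, seed) -> VoltageTrace`, with each screened
current's conductance scaled by `(1 - beta)`. The package deliberately
re-derives no ionic gating equations; biophysical models (e.g. an
externally obtained O'Hara-Rudy implementation) can be registered
through the same interface.

## Synthetic cell model

The bundled cell model is explicitly *not* biophysical. It exists so
that every downstream component has an exact, analytically known ground
truth. Each cycle is a stylized action potential (rest −85 mV, 2 ms
upstroke to +30 mV, smooth cosine repolarization complete by 350 ms,
flat diastole after). A linear score over the seven screened channel
blocks,

    s = 4 b_Kr − 4 b_CaL + b_K1 + b_Ks + 0.5 b_NaL,

injects a triangular depolarizing bump at 400 ms post-stimulus whenever
`s > 2`, with rising slope `0.2 · sigmoid(s − 2)` mV/ms over 40 ms. The
slope crosses the 0.1 mV/ms detection threshold exactly at `s = 2`, and
the bump sits on the flat diastolic baseline so the measured finite
difference equals the nominal slope; the detected EAD region therefore
equals `{s > 2}` exactly, and passing the sigmoid makes near-threshold
behavior exercisable. The sign structure (I_Kr block promotes, I_CaL
block protects, smaller positive roles for I_K1/I_Ks/I_NaL) mirrors the
known physiology. What the fixture does *not* emulate: real AP
morphology and rate dependence, stochastic channel gating, calcium
dynamics, and any quantitative dose-response shape — so tests passing
against it demonstrate the pipeline's logic, not biophysical fidelity.

## Sensitivity analysis

500 pacing simulations are run at block vectors drawn from a Latin
hypercube over [0, 0.95]^7 (seeded; exactly one point per equal-width
stratum per dimension, via scipy's LHS engine). A logistic regression
`p = sigmoid(b + w·beta)` is fitted to the binary EAD labels with a tiny
ridge penalty (1e−6) that keeps the fit finite under the perfect
separation a deterministic EAD rule produces. The reported quantity is
the *average* marginal effect per channel — the mean over design rows of
`p(1−p) w_i` — rather than the effect at a reference point, because the
design spans the whole cube. Effects are normalized by the maximal
value (the largest, positive, effect), preserving signs, so the
strongest EAD-promoting channel reads exactly 1. Normalizing by the
largest *absolute* effect was considered and rejected: with the
synthetic model's symmetric ±4 weights, whether the fitted |w_Kr| or
|w_CaL| is fractionally larger is sampling noise, which would make the
sign of the anchor channel a coin flip; the signed maximum is stable and
matches the convention that the promoter bar is 1. Under it the
protective I_CaL effect may occasionally have magnitude slightly above
one.

## Gaussian-process boundary learning

The arrhythmia oracle over the (I_CaL, I_Kr) block square is treated as
expensive and binary. A Bernoulli-likelihood GP classifier — logistic
link, Laplace approximation, `amplitude² · RBF` kernel — is fitted by
marginal-likelihood maximization with bounds chosen against degeneracy:
length scale in [0.05, 2.0] (avoids needle or flat contours), amplitude
in [1, 1e3] (below unit logit scale ML-II collapses to a flat p = 0.5
solution; far above ~30 the Laplace approximation degrades on separable
labels). Two optimizer restarts escape the flat local optimum; for
fewer than 8 training points hyperparameter optimization is skipped
entirely (it is ill-posed there) and the default kernel `1 · RBF(0.3)`
is used. With a single observed class no latent GP is identifiable; the
predictive probability then shades from near-certainty at the data
toward 0.5 with the RBF proximity to the nearest training point, which
keeps predictions on the observed side of 0.5 everywhere and makes the
entropy acquisition explore the point farthest from the data.

Acquisition maximizes the Bernoulli predictive entropy
`−p ln p − (1−p) ln(1−p)` over a fixed 101×101 uniform candidate grid
(reproducible argmax, testable by exhaustive scan); ties are broken by
lowest index after a seeded shuffle. The loop queries 10 Latin-hypercube
points, then 30 rounds of fit → argmax-entropy → query, re-optimizing
hyperparameters after every query, and keeps a full audit log. The
0.5-probability contour is extracted by marching squares on a grid of
predictive probabilities. The kernel, link, and candidate construction
are package choices — the acquisition rule only needs a calibrated `p`.

## Surrogate boundary and critical concentrations

Learning the real classification boundary requires a whole-heart
arrhythmia oracle far beyond desk scale, so the package ships an
analytic stand-in with the boundary's two structural features — risk
onset near 70% I_Kr block for pure I_Kr blockers, and a safe wall at
60% I_CaL block beyond which no I_Kr block is arrhythmogenic — and
calibrated so that seven reference drugs cross it exactly at their known
critical multiples (thioridazine 0.1x, quinidine 0.3x, terfenadine 4.4x,
bepridil 4.9x, chlorpromazine 154.9x, amiodarone 282.6x, propranolol
474.6x). Each anchor is the drug's block point at its multiple; the
threshold curve B(x) is the piecewise-linear interpolant through the
anchors sorted by I_CaL block, extended linearly from the last anchor to
(0.60, 1.0); the region is arrhythmic iff `x < 0.60 and y ≥ B(x)`.

The critical concentration is the *first entry* into the arrhythmic
region along increasing multiple — well defined even when a trajectory
later exits near the safe wall. It is located by a coarse scan of 601
log-spaced multiples over [0.01x, 1000x] followed by geometric bisection
between the last safe and first arrhythmic grid point to 1e−3 relative
width; drugs with no arrhythmic point up to the 1000x cap are reported
as never crossing. The 1000x cap and the 350x high/low threshold are
exposed as configuration; any threshold between the top of the high
group (282.6x) and propranolol (474.6x) yields the same 14/9 split.

Two geometric consequences of the anchor construction are worth
stating. Because every anchor lies exactly *on* the curve, an anchor at
a local vertex can be a tangency rather than a transversal crossing.
Thioridazine's anchor is a local-minimum vertex: its trajectory touches
the region at exactly 0.1x, leaves, and re-enters near 0.124x; the
default scan recovers 0.1x because the 601-point grid contains the
decade multiples exactly. Propranolol's anchor is an isolated touch at
474.6x that no finite scan can see; it is reported as never crossing,
which places it in the same low-risk category as the 474.6x crossing
itself (474.6 > 350). Bepridil's anchor is a local-maximum vertex whose
trajectory penetrates the region by only ~1e−3 block units — resolvable
by the exact surrogate but below what a 40-sample GP boundary can see,
which is why GP-based stratifications are checked per drug (at least 22
of 23 category agreements) rather than on the exact 14/9 count.

## Leave-one-out validation

Risk labels are validated by leave-one-out GP classification on a single
feature, log10 of the critical multiple (never-crossing encoded as the
scan cap, log10 1000 = 3), affinely mapped onto [0, 1] from the scan
bounds. Each fold fits the 1-D GP classifier on the remaining drugs and
predicts the held-out one; folds whose training labels collapse to one
class are skipped with a warning. Because the full published label set
exists only as figure color coding, labels are caller-supplied rather
than bundled. A lone drug with a finite crossing far above the rest of
its class is characteristically misclassified — there is no similar
compound left in its training fold.

## Problem sizes and determinism

Default problem sizes are the study's own: 500 LHS runs over seven
channels for sensitivity, 10 + 30 oracle queries for boundary learning,
101×101 grids for candidates and evaluation, 601-point scans refined by
bisection for critical concentrations. Every stochastic component
(LHS, optimizer restarts, tie-breaking, simulated labels) flows from an
explicit integer seed, and identical seeds reproduce outputs
byte-for-byte, including the CLI's CSV/JSON reports, which embed the
full run configuration and its hash.

## Known limitations

- The pore-block model ignores binding kinetics, state dependence, and
  multi-channel cooperativity; IC50/Cmax inputs carry their own
  experimental uncertainty, which is not propagated.
- The surrogate boundary is a calibrated fixture, not a learned organ-
  scale result; conclusions tied to it demonstrate the pipeline, not new
  physiology. Anchor tangencies (above) are artifacts of exact
  interpolation.
- The synthetic cell model has a linear EAD score; real EAD genesis is
  nonlinear and rate dependent, so sensitivity magnitudes from the
  fixture are not biological estimates (only the sign structure is).
- GP classification assumes a stationary RBF kernel; strongly
  anisotropic or disconnected arrhythmic regions would need a richer
  kernel and more queries.
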