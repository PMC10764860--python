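# Methods

## The model

The package's core is a compartmental opinion-contagion model of vaccine
perception. Four non-overlapping behavioral compartments partition the
population: unwilling (U), hesitant (H), willing (W) and vaccinated (V),
with fractions u + h + w + v = 1. Transitions are of two kinds:

- **autonomous** — constant per-capita rates driven by global or internal
  factors: campaigns and access restrictions push U→H (rate k), self-driven
  confidence pushes H→W (e), relapse flows H→U (g) and W→H (d), and a
  smooth-supply channel vaccinates priority groups W→V (r);
- **induced** — mass-action contact terms: willing and vaccinated contacts
  move the unwilling toward hesitancy (βuw, ηuv), and vaccinated contacts
  confirm the hesitant into willingness (fhv).

Limited vaccine supply is modeled by a saturating (Michaelis–Menten-type)
flux Γ(w) = cw/(b+w): near-linear (slope c/b) when few are willing, capped
at the throughput c when many are. With b = 0.1 the queue saturates once a
few tenths of the population are willing simultaneously. A uniform
birth/death rate μ feeds newborns into U and removes everyone at equal
per-capita rate, which keeps the simplex invariant: the components of the
vector field sum to μ(1 − u − h − w − v) identically.

Assumptions worth keeping in mind: homogeneous mixing (no network
structure), constant rates (no time-dependent campaigns), vaccination
absorbing up to demography, and deterministic mean-field dynamics.

## Equilibria, stability, bifurcation

Equilibria are found by multi-start Newton root finding on the reduced
system (v eliminated through the conservation law; the fourth equation is
then automatically satisfied). The start set is a lattice over the
(u, h, w) simplex **plus logarithmically spaced small-w probes** — the
low-coverage branch lives at willing fractions of order 10⁻⁶ because the
supply term has slope c/b = 100 at the origin, and no coarse lattice lands
there. Roots are accepted by residual (‖rhs‖∞ ≤ 10⁻¹⁰; the hybrid Powell
solver occasionally reports failure at a fully converged point, so
acceptance is by residual with a Levenberg–Marquardt fallback), merged
within 10⁻⁶ in max-norm, and classified by the eigenvalues of the analytic
Jacobian (stable iff all real parts < −10⁻⁸; the conservation structure
makes every Jacobian column sum to −μ).

Branch continuation is natural-parameter continuation: each grid point is
seeded with the previous point's converged roots plus fresh lattice starts
to detect coexisting branches. The saddle-node (fold) of the low branch is
located by tracking it on a coarse grid until it ceases to exist and
bisecting the last bracket to 10⁻³ in the swept parameter. Regime labels
use the stable-equilibrium set with a high/low split at v = 0.5, which
separates the observed ~79% and sub-20% coverage states with a wide margin.

At the published parameter set (μ=0.2, e=0.01, r=0.2, g=0.5, d=0.05, b=0.1,
c=10, k=0.01, β=2) the package computes: a unique high-coverage stable
equilibrium v = 78.93% at (η=1.2, f=7.8); a fold of the low branch at
f = 7.785 for η = 1.2 (the stated operating point sits within 0.02 of the
fold, consistent with its description as the transition threshold); and a
single graded branch at η = 0.2 that rises through v = 14.3% (f=30) and
17.0% (f=50) toward an asymptote near 20%. Two printed claims of the source
analysis do not correspond to equilibria of these equations as printed: the
low branch at η = 1.2 carries v ≤ 0.4% everywhere up to the fold (not
≈19%), and the graded branch has no interior saturation at 13% (the value
13% is reached near f ≈ 27 and the curve keeps rising; the companion claim
of "15–20% at very large f" *is* reproduced). The acceptance checks report
the faithfully computed quantities; the corresponding two comparisons are
expected to disagree with the printed figures.

Numerical choices: stiff-capable LSODA integration (rtol 10⁻⁸, atol 10⁻¹⁰,
default horizon 1000 time units) for trajectories; simulation tolerance on
simplex drift 10⁻⁶; eigenvalue stability margin 10⁻⁸.

## Survey analysis

Closed answers are vectorized with one-hot categorical coding and 1–10
scales mapped to [0,1] via (value−1)/9, so one scale question contributes
at most as much squared distance as one option flip. Average-linkage
agglomeration is implemented with exact Lance–Williams updates
(d(a∪b, k) = (|a|d(a,k) + |b|d(b,k))/(|a|+|b|)), which reproduces the
brute-force mean of pairwise l₂ distances at every step; ties break toward
the lowest cluster ids for cross-platform determinism. Average linkage with
a metric distance is monotone, so merge heights never decrease. The
automatic threshold takes the widest gap between consecutive merge heights
among the last eight merges; on cleanly separated data this lands on the
dominant binary split (vaccine-reluctant vs enthusiast), and the
four-compartment structure is obtained with the k=4 override. Semantic
labels are assigned post hoc: the cluster with the highest
already-vaccinated share is V, the rest rank U < H < W by mean willingness.

Text preparation is deterministic and dependency-light: regex
sentence/token segmentation, URL and punctuation removal, lower-casing, and
a rule-and-lexicon lemmatizer whose suffix transformations are accepted
only when they land on a known base form. Participial and predicative
transition markers ("worried", "vaccinated", "confident", "available") are
base forms, so the graphs display them as-is; multiword driver terms fuse
to protected compound tokens ("SideEffects", "FamilyMembers"). A
suffix-stripping stemmer is available behind a flag. The stoplist is a
standard English list with the negator "no" deliberately retained, because
the association graphs use it as a hub ("no tours", "no industries"). The
POS tagger is a lexicon with suffix-heuristic fallback collapsed to
{noun, verb, other}; compounds are nouns, unknown words default to noun.
Sentiment polarity comes from compact positive/negative lexica restricted
to the survey domain, a peer-influence word list, and manual overrides for
neutral terms such as "health".

Transition rules are data: a YAML resource lists each arrow's source,
target, kind, inducers, rate symbol(s) and evidence co-locations (stored in
pipeline-normalized form — lemmas and fused compounds — and matched as
unordered sentence-co-occurrence edges). The default resource compiles to
eight rules binding each of {β, η, k, g, e, f, d, r, c, b} exactly once;
a symbolic reconstruction of the ODE right-hand side from the rules is
machine-checked against the hand-written equations in the test suite. The
smooth-supply arrow r carries no word evidence by design: it encodes the
priority-channel vaccination described in the survey narrative, not a
mined co-location.

## The synthetic-survey generator

The generator emulates the *structure* the analysis assumes, not the
descriptive statistics of any real population. Defaults: n = 400
respondents, four equal subpopulations, eight closed questions (four
categorical, four 1–10 scales) and three open questions, each targeted at
one compartment (as in the source survey, respondents answer the open
question aimed at their group). Closed answers use deterministic
categorical modes and peaked scale distributions (P(x) ∝ 0.15^|x−mode|),
which makes the default dataset cleanly separated — the regime the
clustering stage is expected to operate in; `p_mode` and `conc` are the
knobs that blur it. Open text mixes templated sentences (hub + associate
with stopword filler, expectation 2 per respondent, at least one when the
rate is ≥ 1) with noise sentences drawn from an unrelated vocabulary
(expectation 0.5 per respondent). One global seed fans out to per-stage
substreams, so label draws, closed answers and open text are independently
reproducible.

What the generator does **not** emulate: demographic covariates, realistic
vocabulary breadth, spelling noise, mixed-topic sentences, or respondents
whose answers straddle compartments. Passing tests on planted data
therefore demonstrate that the pipeline recovers structure it is designed
to see — exact cluster recovery (ARI = 1) and exact word-graph/template
correspondence at zero noise — not that it would segment noisy real survey
text at any particular accuracy.

## Design choices and limitations

- Scale problem sizes: surveys at n = 400 (n = 1196 only for a count
  contract), continuation at 400 grid points for the fold, coarse grids for
  regime maps. All stages run in seconds on one CPU.
- Evidence matching is exact pair matching after normalization; synonym or
  fuzzy matching is out of scope, as is inferring *new* transition rules
  from graphs (that mapping involves human interpretation).
- The word graphs are built per question with k = 6 hubs; hub-hub
  co-occurrences produce a single flagged edge; edges carry sentence
  co-occurrence counts even though weight-1 edges suffice to reproduce the
  qualitative structure.
- The dynamics module does no formal normal-form analysis; folds are
  located numerically. Stochastic and network-structured variants are out
  of scope.
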