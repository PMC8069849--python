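# Methods

## The model

`ecoqbn` treats the belief state of an ecological system as a wave function:
a unit-norm vector ψ of complex *probability amplitudes* √p·e^{iθ} over a
labelled basis of system states.  Squared magnitudes are classical
probabilities; measuring an outcome projects ψ onto that outcome's subspace
(probability = squared norm of the projection, Born's rule) and renormalizes
the remainder (collapse).  Every construct in the package reduces exactly to
ordinary probability when all phases are zero: a classical Bayesian network
file is a valid input and behaves classically.  Phases are extra degrees of
freedom a modeller assigns to encode non-classical uncertainty; there is no
published recipe for eliciting them from field observations, so they are
plain user inputs with default 0, never inferred.

Four layers build on the amplitude core:

1. **Networks** — DAGs of nodes with conditional amplitude tables (one
   unit-norm amplitude row per parent configuration).
2. **Ordered evidence** — projective conditioning in which the order of
   findings can matter.
3. **Path trajectories** — cyclic, disturbance-labelled state-transition
   graphs with amplitude-weighted edges, for intransitive systems a DAG
   cannot represent.
4. **Entrainment** — two sinusoidally coupled phase oscillators for
   signalling behaviour (duets, choruses).

## Coherent network inference

Inference is exact enumeration over joint assignments, capped at 2^20
joint states (the motivating examples have 3 nodes; the cap is
configurable).  Classical mode sums squared joint magnitudes — textbook
enumeration.

Coherent mode must reconcile two requirements: hidden-variable summation
has to happen at the amplitude level (otherwise phases can never matter),
yet a phase-free network has to reproduce classical Bayes exactly.  A raw
Feynman sum (add hidden-path amplitudes, then square) fails the second
requirement: with aligned phases it gives (Σ√p)² ≠ Σp.  We therefore
modulate rather than replace the classical mass.  For query state *q* with
hidden-assignment amplitude bundle {ψ_i}:

    visibility V(q) = |Σ ψ_i|² / (Σ |ψ_i|)²          ∈ [0, 1]
    mass(q)        = (Σ |ψ_i|²) · V(q)

followed by renormalization over query states.  V(q) is the standard
fringe-visibility ratio of the bundle: 1 when all pairwise phase
differences vanish (so phase-free models give exact Bayes), 0 under
complete destructive cancellation, intermediate otherwise.  The per-state
`InterferenceReport` records the classical mass, the modulated mass, and
their difference.

Evidence with zero classical probability is an error (conditioning on an
impossible event), never a silent renormalization; likewise a coherent
posterior in which interference extinguishes *every* query state.

## Order-sensitive evidence

Plain findings are diagonal projectors on the joint-assignment state
vector.  Operators acting on different nodes' tensor axes commute
identically — this is precisely why classical Bayesian conditioning is
commutative — so plain evidence is order-invariant by construction, and no
assignment of per-node operators on separate axes can ever break that.

Declaring a measurement rotation on a node therefore does something
stronger: it marks the node's question *incompatible* with the others, and
the engine switches to the standard quantum-cognition representation of
incompatible questions — rotated bases of one shared two-dimensional
system rather than orthogonal tensor factors.  The reference node (the
earliest measured node in topological order, stable under reordering of
the findings) supplies the basis and the initial state (the square-root
embedding of its prior marginal); each measured node's projectors are its
basis vectors rotated by the node's angle, `[cosφ, −sinφ; sinφ, cosφ]`.
Rotated projectors in a shared space genuinely fail to commute: in the
shipped 45° two-node example the two presentation orders of the same two
findings disagree about the first node by probability 0.5.  In the shared
regime every measured node must be binary, and the rotation replaces the
node's conditional table as the relationship between the questions — the
doctrine that incompatible questions admit no joint distribution.

`sequential_condition` returns a small result object recording which
regime ran and exposing `marginal(node)` uniformly in both.

## Path trajectories

A path's classical probability is the initial-state probability times the
product of squared edge magnitudes.  The per-path quantum value squares
each leg separately and is therefore *identical* for every phase
assignment — a single trajectory carries no interference.  Interference
lives entirely in `multipath_superposition`, which adds the path
amplitudes of every start→end route coherently: `coherent = |Σψ|²` against
`classical = Σ|ψ|²`, reaching 2× the classical sum for two equal aligned
paths and 0 for two opposed ones.

Edge amplitudes are possibility weights, not stochastic-matrix rows; when
a disturbance sequence is applied, mass branches over the label-matching
out-edges weighted by squared magnitudes normalized *among those matches*.
A state with no matching out-edge keeps its mass — a disturbance that
cannot transition a state leaves it unchanged — and only when no occupied
state matches is the sequence stranded (error carrying the reachable
prefix).  Permutation checking replays every distinct ordering (capped at
720) and flags any end-distribution difference, the noncommutativity
signature of disturbance regimes.

Enumeration may revisit states but not re-traverse a directed edge
(configurable), so each circuit is walked at most once and enumeration on
cyclic graphs terminates; `max_len` is a hard cap and ordering is
lexicographic in (target, label), hence deterministic.  Circuit finding
delegates to bounded simple-cycle enumeration and canonicalizes each
circuit to start at its lexicographically smallest state.

## Entrainment

dθ₁/dt = w₁ + A₂·sin(θ₂−θ₁), dθ₂/dt = w₂ + A₁·sin(θ₁−θ₂), with the
cross-indexed couplings (A₂ is the pull *on* oscillator 1).  The phase
difference obeys dΔ/dt = (w₁−w₂) − (A₁+A₂)·sinΔ, giving the locking law:
a stable fixed point Δ* = arcsin((w₁−w₂)/(A₁+A₂)) exists iff
|w₁−w₂| ≤ A₁+A₂.

The verdict object reports two vocabularies side by side and never
conflates them: the *parameter* conditions (entrainment ⇔ A₁=A₂, synchrony
⇔ w₁=w₂) and the *empirical* phase-locking test (range of the unwrapped Δ
over the final third of the trajectory below `tol`, default 1e-3 rad;
locked value = circular mean of that window, reported in (−π, π]).  They
disagree in general — unequal couplings still lock when the detuning is
small — and the tests assert that disagreement.

Integration is fixed-step RK4 (default dt = 0.01 time units), chosen for
bit-reproducibility over adaptive stepping; the system is smooth and
non-stiff, and halving dt moves final phases by < 1e-6 in the checked
cases.  `signal_train` converts a trajectory into emission-event times by
linear interpolation of the phase through each 2π branch crossing,
handling transient phase reversals under strong coupling.

## Example systems and the placeholder policy

Only a few numbers in the motivating examples are published: the riparian
prior 0.1 for the yellow-winged bat (magnitude √0.1 = 0.3162), the
deterministic rules of rock-paper-scissors over uniform moves, and the
boreal circuit black spruce → bog (thermokarst) → shrubland
(permafrost/peat aggradation) → black spruce (aggradation + tree
regeneration).  All remaining conditionals are fixed, documented
placeholders (bat: woodland prior 0.6; habitat-good rows 0.9 / 0.65 /
0.35 / 0.05; spruce edge probability 0.7) so every worked example is
reproducible; a seeded `randomize` path replaces the placeholders (never
the published prior) for property tests, and fixture emission is
byte-deterministic in (name, parameters, seed).

The random-network generator used by the property suite draws small
binary DAGs (≤4 nodes, ≤2 parents, row probabilities in [0.05, 0.95] so
all evidence is conditionable, optional uniform phases).  These networks
exercise the inference algebra, not ecological realism: passing tests
certify the probability calculus (classical reduction, oracle agreement,
normalization), and say nothing about whether any particular phase
assignment describes a real ecosystem — the package deliberately leaves
phase elicitation to the modeller.

## Numerical choices

- Unit-norm tolerance 1e-9 on state vectors and table rows; violating
  vectors are rejected, not silently rescaled (`StateVector.renormalized`
  is the explicit opt-in), so table-entry errors surface immediately.
- Phases canonicalized to [0, 2π); modular equality tolerance 1e-9.
- Amplitudes are stored as (magnitude, phase) and converted to rectangular
  form for sums, avoiding the sign ambiguity of real square roots.
- Events with Born probability ≤ 1e-12 count as impossible in collapse and
  conditioning.
- Observable eigenvalues default to state ordinals (no published numeric
  eigenvalues are used anywhere).
- Dominant-state reporting breaks exact ties toward the lowest ordinal.
- Test problem sizes: 500-network property sweeps for inference, 1000
  random path checks, and a 20×20 (detuning × coupling) locking sweep at
  t_end = 90, dt = 0.02 with a 5% exclusion margin around the analytic
  locking boundary, where critical slowing makes any finite-horizon
  verdict unreliable.

## Limitations

- Pure states only: no density matrices, no continuous-variable spaces,
  and no entanglement algebra beyond the joint-assignment vector.
- Exact enumeration only; no sampling or variational inference.
- The shared-space order-effect regime supports binary questions only.
- No structure or parameter learning, and no mapping from oscillator
  state to network probabilities beyond the shared interference
  formalism — none is defined in the source material.
- Phase elicitation from data is out of scope by design.
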