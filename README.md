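# ecoqbn — quantum-like Bayesian networks for ecological systems

Some ecological systems fit ordinary Bayesian networks badly: cyclic
(intransitive) successions that return to their starting state with no
climax condition, systems whose response depends on the *order* of
disturbances, and signalling behaviour that entrains and synchronizes.
`ecoqbn` is a small engine for modelling such systems with the probability
calculus of quantum theory, used as mathematics rather than physics: state
uncertainty is a unit-norm vector of complex amplitudes √p·e^{iθ}, outcome
probabilities come from Born's rule P = ‖Pψ‖², observation collapses the
state, and hidden alternatives can interfere through the cross term
2|ψᵢ||ψⱼ|cos(θᵢ−θⱼ).  With every phase at zero the whole engine reduces
exactly to classical probability, so any classical network file is a valid
input and a sanity baseline.

It is aimed at ecological modellers who want to experiment with
amplitude-valued conditional tables, interference-aware inference, cyclic
state-and-transition models, and two-oscillator entrainment, with small
networks and full reproducibility.

## What is inside

| Module | Contents |
| --- | --- |
| `ecoqbn.amplitude` | phases, amplitudes, state vectors, projectors, Born rule, collapse, interference reports |
| `ecoqbn.network` | amplitude-table networks, validation, exact classical/coherent inference, ordered (optionally noncommuting) evidence, information gain |
| `ecoqbn.paths` | cyclic disturbance-labelled transition graphs, path probabilities, multipath superposition, circuit detection, disturbance sequences |
| `ecoqbn.entrainment` | coupled phase oscillators dθ₁/dt = w₁ + A₂sin(θ₂−θ₁), dθ₂/dt = w₂ + A₁sin(θ₁−θ₂), locking analysis, event trains |
| `ecoqbn.io`, `ecoqbn.cli`, `ecoqbn.fixtures` | JSON/CSV dialects, the `ecoqbn` command, executable example systems |

See `docs/methods.md` for the model, the interference and evidence-order
constructions, numerical choices, and limitations.

## Worked example

The bat-habitat network has two root causes (riparian habitat, prior 0.1;
woodland/scrub/savanna habitat, placeholder prior 0.6) and a habitat node
conditioned on both:

```text
$ ecoqbn demo bat
bat habitat network (riparian prior 0.1000)
  P(habitat | no evidence): good=0.2870  poor=0.7130
  P(habitat | riparian=present, woodland_scrub_savanna=present): good=0.9000  poor=0.1000
```

With no evidence the habitat-good marginal is the table average
0.1·0.6·0.9 + … = 0.2870; observing both favourable habitats collapses it
to the 0.9000 table row.  The amplitude behind the riparian prior is
√0.1 = 0.3162.

Rock-paper-scissors shows *solution-incompleteness* in an intransitive
network — a single observed move carries exactly zero information about
the outcome, while both moves determine it:

```text
$ ecoqbn demo roshambo
roshambo: information gain about the outcome from single moves
  gain(player1=rock) = 0.0000
  ...
  P(outcome | rock vs scissors): p1_wins=1.0000  p2_wins=0.0000  draw=0.0000
```

The boreal example is a cyclic state-and-transition model — black spruce
→ bog (thermokarst) → shrubland (aggradation) → black spruce
(regeneration), each edge probability 0.7 — which the circuit finder
detects and the path engine superposes (one path, so the coherent and
classical totals agree at 0.7³ = 0.343):

```text
$ ecoqbn demo spruce
spruce transition graph: 1 circuit(s) (len<=3)
  black_spruce -> bog -> shrubland -> black_spruce   [thermokarst, aggradation, regeneration]
  spruce->spruce ensemble (classical):
    classical total: 0.3430
    coherent total:  0.3430
    interference:    0.0000
  after thermokarst , aggradation , regeneration: black_spruce=1.0000
```

Other subcommands: `infer` (posteriors from a network file, with
`--order given|reversed` for rotated-basis evidence), `paths`, `sequence`
(`--check-order` flags noncommuting disturbance orders), `entrain`
(oscillator integration, CSV trajectory, JSON verdict), and `validate`.

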