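# Default compartmental transition structure mined from the survey word
# graphs. Each rule names its source/target compartment, whether the
# transition is autonomous (constant per-capita rate) or induced (mass-action
# contact with an inducing compartment, or gated by vaccine availability),
# the rate symbol(s) it binds, and the word co-locations that evidence it.
# Evidence pairs are stored in pipeline-normalized form (lemmas, fused
# compounds) and matched as unordered sentence-co-occurrence edges.
#
# question: the open-ended question whose answer corpus evidences the rule
#   (O1 = reasons of the unwilling, O2 = reasons of the hesitant,
#    O3 = concerns of the willing).
rules:
  - source: U
    target: H
    kind: autonomous
    inducers: [self]
    rate_form: constant
    params: [k]
    question: O1
    evidence:
      - ["no", HerdImmunity]
      - ["no", tour]
      - ["no", industry]
  - source: U
    target: H
    kind: induced
    inducers: [W, V]
    rate_form: mass_action
    params: [beta, eta]
    question: O1
    evidence:
      - [FamilyMembers, take]
      - [friend, take]
      - [doctor, advice]
  - source: H
    target: W
    kind: autonomous
    inducers: [self]
    rate_form: constant
    params: [e]
    question: O2
    evidence:
      - [SideEffects, confident]
      - [feel, safe]
      - [seem, effective]
  - source: H
    target: W
    kind: induced
    inducers: [V]
    rate_form: mass_action
    params: [f]
    question: O2
    evidence:
      - [parent, take]
      - [people, effective]
      - [peer, vaccinated]
  - source: H
    target: U
    kind: autonomous
    inducers: [self]
    rate_form: constant
    params: [g]
    question: O2
    evidence:
      - [SideEffects, worried]
      - [SideEffects, health]
      - [SideEffects, harm]
  - source: W
    target: H
    kind: autonomous
    inducers: [self]
    rate_form: constant
    params: [d]
    question: O3
    evidence:
      - [prolonged, SideEffects]
      - [long, illness]
      - [NewStrain, affect]
  - source: W
    target: V
    kind: autonomous
    inducers: [self]
    rate_form: constant
    params: [r]
    question: O3
    evidence: []
  - source: W
    target: V
    kind: induced
    inducers: [availability]
    rate_form: saturating
    params: [c, b]
    question: O3
    evidence:
      - [available, slot]
      - [available, age]
      - [available, appointment]
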