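# Default synthetic-survey configuration: four latent subpopulations
# (U unwilling, H hesitant, W willing, V vaccinated) answering eight
# closed-ended questions (Yes/No/Maybe options or 1-10 scales) and three
# open-ended questions. Open text is seeded with the transition-driver word
# co-locations the association graphs are expected to recover, plus noise
# vocabulary.
#
# Closed-answer distributions: categorical questions give `mode` (the
# profile's modal option) and `p_mode` (its probability; the remainder is
# spread uniformly over the other options). Scale questions give `mode`
# (1-10) and `conc` in (0,1); P(value) is proportional to conc**|value-mode|.
# The default p_mode of 1.0 makes the compartments cleanly separated, the
# structure the dendrogram of the source survey shows; lower it to blur them.
n: 400
seed: 11
noise:
  rate: 0.5              # expected noise sentences per respondent
  vocab: [city, road, phone, shop, office, cricket, movie, song, festival, garden]
  min_words: 2
  max_words: 4
schema:
  Q1: {kind: categorical, options: ["Yes", "No"], text: "Would you take the vaccine when offered?"}
  Q2: {kind: categorical, options: ["Yes", "No"], text: "Have you already been vaccinated?"}
  Q3: {kind: scale, text: "Willingness to get vaccinated (1-10)"}
  Q4: {kind: scale, text: "Trust in vaccine safety (1-10)"}
  Q5: {kind: categorical, options: ["Yes", "No", "Maybe"], text: "Are you worried about side effects?"}
  Q6: {kind: scale, text: "Hesitation level (1-10)"}
  Q7: {kind: categorical, options: ["Yes", "No", "Maybe"], text: "Do you trust government vaccination campaigns?"}
  Q8: {kind: scale, text: "Openness to peer influence (1-10)"}
  O1: {kind: open, text: "What are some major reasons for you to not want to take the vaccine? What might change your decision?"}
  O2: {kind: open, text: "What are the reasons behind your hesitation? What might make you change your decision if most people take the vaccine?"}
  O3: {kind: open, text: "Is there any reason which might make you change your decision of taking the vaccine?"}
label_questions:
  willingness: Q3          # ranks clusters U < H < W on the willingness scale
  vaccinated: Q2           # splits V (already vaccinated) from W
profiles:
  - label: U
    proportion: 0.25
    emission_rate: 2.0
    open_question: O1
    closed:
      Q1: {mode: "No", p_mode: 1.0}
      Q2: {mode: "No", p_mode: 1.0}
      Q3: {mode: 2, conc: 0.15}
      Q4: {mode: 2, conc: 0.15}
      Q5: {mode: "Yes", p_mode: 1.0}
      Q6: {mode: 9, conc: 0.15}
      Q7: {mode: "No", p_mode: 1.0}
      Q8: {mode: 2, conc: 0.15}
    templates:
      - {hub: take, associate: FamilyMembers, pos: noun, tag: "U->H induced"}
      - {hub: take, associate: friend, pos: noun, tag: "U->H induced"}
      - {hub: doctor, associate: advice, pos: noun, tag: "U->H induced"}
      - {hub: "no", associate: HerdImmunity, pos: noun, tag: "U->H autonomous"}
      - {hub: "no", associate: tour, pos: noun, tag: "U->H autonomous"}
      - {hub: "no", associate: industry, pos: noun, tag: "U->H autonomous"}
  - label: H
    proportion: 0.25
    emission_rate: 2.0
    open_question: O2
    closed:
      Q1: {mode: "No", p_mode: 1.0}
      Q2: {mode: "No", p_mode: 1.0}
      Q3: {mode: 5, conc: 0.15}
      Q4: {mode: 4, conc: 0.15}
      Q5: {mode: "Yes", p_mode: 1.0}
      Q6: {mode: 6, conc: 0.15}
      Q7: {mode: "Maybe", p_mode: 1.0}
      Q8: {mode: 6, conc: 0.15}
    templates:
      - {hub: SideEffects, associate: confident, pos: verb, tag: "H->W autonomous"}
      - {hub: feel, associate: safe, pos: verb, tag: "H->W autonomous"}
      - {hub: effective, associate: seem, pos: verb, tag: "H->W autonomous"}
      - {hub: parent, associate: take, pos: verb, tag: "H->W induced"}
      - {hub: effective, associate: people, pos: noun, tag: "H->W induced"}
      - {hub: peer, associate: vaccinated, pos: verb, tag: "H->W induced"}
      - {hub: SideEffects, associate: worried, pos: verb, tag: "H->U autonomous"}
      - {hub: SideEffects, associate: health, pos: noun, tag: "H->U autonomous"}
      - {hub: SideEffects, associate: harm, pos: noun, tag: "H->U autonomous"}
  - label: W
    proportion: 0.25
    emission_rate: 2.0
    open_question: O3
    closed:
      Q1: {mode: "Yes", p_mode: 1.0}
      Q2: {mode: "No", p_mode: 1.0}
      Q3: {mode: 8, conc: 0.15}
      Q4: {mode: 8, conc: 0.15}
      Q5: {mode: "No", p_mode: 1.0}
      Q6: {mode: 3, conc: 0.15}
      Q7: {mode: "Yes", p_mode: 1.0}
      Q8: {mode: 7, conc: 0.15}
    templates:
      - {hub: available, associate: slot, pos: noun, tag: "W->V induced"}
      - {hub: available, associate: age, pos: noun, tag: "W->V induced"}
      - {hub: available, associate: appointment, pos: noun, tag: "W->V induced"}
      - {hub: SideEffects, associate: prolonged, pos: verb, tag: "W->H autonomous"}
      - {hub: long, associate: illness, pos: noun, tag: "W->H autonomous"}
      - {hub: NewStrain, associate: affect, pos: verb, tag: "W->H autonomous"}
  - label: V
    proportion: 0.25
    emission_rate: 0.0
    open_question: null
    closed:
      Q1: {mode: "Yes", p_mode: 1.0}
      Q2: {mode: "Yes", p_mode: 1.0}
      Q3: {mode: 10, conc: 0.15}
      Q4: {mode: 9, conc: 0.15}
      Q5: {mode: "No", p_mode: 1.0}
      Q6: {mode: 2, conc: 0.15}
      Q7: {mode: "Yes", p_mode: 1.0}
      Q8: {mode: 8, conc: 0.15}
    templates: []
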