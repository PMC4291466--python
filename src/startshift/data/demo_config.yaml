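# Demo scenario: a wild type, two Pol II active-site alleles (GOF shifts TSS
# usage upstream, LOF downstream), a family of TFIIF-like alleles with graded
# upstream shifts, a TFIIB-like downstream shifter, and three genetic
# interactors planted to realize the three canonical relationship classes:
#   tfg2-like-261 / tfg2-like-146 - own shift, additive doubles      (Class I)
#   sub1-like     - own shift, epistatic to GOF, exacerbates LOF     (Class II)
#   dst1-like     - no own shift, never modulates the Pol II profile (Class III)
seed: 42
replicates: 3

promoter:
  name: demo_multi_tss
  positions: [25, 34, 42, 49, 55, 62, 70, 81]
  base_weights: [0.05, 0.10, 0.20, 0.25, 0.18, 0.12, 0.07, 0.03]

noise:
  sigma: 0.1
  background: 0.0
  total_signal: 10000.0

bins:
  boundaries: [[20, 33], [33, 45], [45, 52], [52, 60], [60, 75], [75, 90]]

tss_strains:
  WT: 0.0
  pol2-GOF: -0.6
  pol2-LOF: 0.6
  tfg2-like-146: -1.5
  tfg2-like-261: -0.6
  tfg2-like-233: 0.0
  sua7-like-1: 1.5
  sub1-like: 0.8
  dst1-like: 0.0
  pol2-GOF tfg2-like-261: {additive_of: [pol2-GOF, tfg2-like-261]}
  pol2-LOF tfg2-like-261: {additive_of: [pol2-LOF, tfg2-like-261]}
  pol2-GOF tfg2-like-146: {additive_of: [pol2-GOF, tfg2-like-146]}  # inviable; no lanes
  pol2-LOF tfg2-like-146: {additive_of: [pol2-LOF, tfg2-like-146]}
  pol2-GOF sub1-like: {copy_of: pol2-GOF}
  pol2-LOF sub1-like: {additive_of: [pol2-LOF, sub1-like]}
  pol2-GOF dst1-like: {copy_of: pol2-GOF}
  pol2-LOF dst1-like: {copy_of: pol2-LOF}

growth:
  wt: WT
  permissive_medium: SC-Leu
  call_medium: YPD
  inviable_threshold: 0.05
  jitter_prob: 0.0
  media_panel:
    general: [YPD, YPD37, YPRaf, SC-Leu]
    mpa:
      SC-Leu+MPA: SC-Leu
    reporter:
      YPRafGal: YPD
      SC-Lys: SC-Leu
  fitness:
    WT: {default: 1.0, YPRafGal: 0.0, SC-Lys: 0.0}
    pol2-GOF: {default: 0.8, SC-Leu+MPA: 0.2, YPRafGal: 0.6, SC-Lys: 0.4}
    pol2-LOF: {default: 0.6, SC-Leu+MPA: 0.8, YPRafGal: 0.0, SC-Lys: 0.5}
    tfg2-like-146: {default: 0.8, SC-Leu+MPA: 0.0, YPRafGal: 0.2, SC-Lys: 0.2}
    tfg2-like-261: {default: 0.8, SC-Leu+MPA: 0.4, YPRafGal: 0.2, SC-Lys: 0.0}
    tfg2-like-233: {default: 1.0, YPRafGal: 0.0, SC-Lys: 0.0}
    sua7-like-1: {default: 0.7, YPD37: 0.2, SC-Leu+MPA: 0.9, YPRafGal: 0.4, SC-Lys: 0.6}
    sub1-like: {default: 0.6, YPRafGal: 0.0, SC-Lys: 0.4}
    dst1-like: {default: 0.8, YPRafGal: 0.0, SC-Lys: 0.3}
  epsilon:
    - pair: [pol2-GOF, tfg2-like-261]
      value: -1.5          # same-polarity exacerbation: synthetic sick
    - pair: [pol2-GOF, tfg2-like-146]
      value: -3.0          # strong same-polarity exacerbation: lethal
    - pair: [pol2-GOF, sub1-like]
      value: 0.5108        # double grows like the GOF single: epistasis
    - pair: [pol2-LOF, sub1-like]
      value: -1.5          # exacerbation of the LOF allele
    - pair: [pol2-GOF, dst1-like]
      value: -1.0          # growth interaction without TSS modulation

triples:
  - [pol2-GOF, tfg2-like-261, pol2-GOF tfg2-like-261]
  - [pol2-LOF, tfg2-like-261, pol2-LOF tfg2-like-261]
  - [pol2-GOF, tfg2-like-146, pol2-GOF tfg2-like-146]
  - [pol2-LOF, tfg2-like-146, pol2-LOF tfg2-like-146]
  - [pol2-GOF, sub1-like, pol2-GOF sub1-like]
  - [pol2-LOF, sub1-like, pol2-LOF sub1-like]
  - [pol2-GOF, dst1-like, pol2-GOF dst1-like]
  - [pol2-LOF, dst1-like, pol2-LOF dst1-like]

pol2_classes:
  pol2-GOF: gof
  pol2-LOF: lof

tolerances:
  tss_call: 0.15
  tau: 0.1
  direction: null
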