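# Hospital Anxiety and Depression Scale (HADS): 14 items, each scored 0-3,
# 7 anxiety + 7 depression items. Each item becomes one network node
# (node_granularity: per_item); `node` is the short node id used in outputs.
# Positively worded items are reverse-corrected (r -> 3 - r) before use.
instrument: HADS
node_granularity: per_item
items:
  - {id: hads01, node: Tns, label: "I feel tense or wound up", min: 0, max: 3}
  - {id: hads02, node: Enj, label: "I still enjoy the things I used to enjoy", min: 0, max: 3}
  - {id: hads03, node: Afr, label: "I get a sort of frightened feeling as if something awful is about to happen", min: 0, max: 3}
  - {id: hads04, node: Fnn, label: "I can laugh and see the funny side of things", min: 0, max: 3}
  - {id: hads05, node: Wrr, label: "Worrying thoughts go through my mind", min: 0, max: 3}
  - {id: hads06, node: Chr, label: "I feel cheerful", min: 0, max: 3}
  - {id: hads07, node: Rlx, label: "I can sit at ease and feel relaxed", min: 0, max: 3}
  - {id: hads08, node: Slw, label: "I feel as if I am slowed down", min: 0, max: 3}
  - {id: hads09, node: Btt, label: "I get a sort of frightened feeling like butterflies in the stomach", min: 0, max: 3}
  - {id: hads10, node: App, label: "I have lost interest in my appearance", min: 0, max: 3}
  - {id: hads11, node: Rst, label: "I feel restless as if I have to be on the move", min: 0, max: 3}
  - {id: hads12, node: Frw, label: "I look forward with enjoyment to things", min: 0, max: 3}
  - {id: hads13, node: Pnc, label: "I get sudden feelings of panic", min: 0, max: 3}
  - {id: hads14, node: Bok, label: "I can enjoy a good book or radio or TV program", min: 0, max: 3}
subscales:
  anxiety: [hads01, hads03, hads05, hads07, hads09, hads11, hads13]
  depression: [hads02, hads04, hads06, hads08, hads10, hads12, hads14]
reverse: [hads02, hads04, hads06, hads07, hads12, hads14]
communities:
  anxiety: anxiety
  depression: depression
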