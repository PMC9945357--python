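# Difficulties in Emotion Regulation Scale (DERS): 36 items scored 1-5,
# six subscales, each subscale summed into one network node
# (node_granularity: per_subscale). Item->subscale assignment and the
# reverse-coded list follow the standard published scoring; edit here if a
# translated form relabels items. `nodes` gives the short node id per subscale.
instrument: DERS
node_granularity: per_subscale
items:
  - {id: ders01, label: "I am clear about my feelings", min: 1, max: 5}
  - {id: ders02, label: "I pay attention to how I feel", min: 1, max: 5}
  - {id: ders03, label: "I experience my emotions as overwhelming and out of control", min: 1, max: 5}
  - {id: ders04, label: "I have no idea how I am feeling", min: 1, max: 5}
  - {id: ders05, label: "I have difficulty making sense out of my feelings", min: 1, max: 5}
  - {id: ders06, label: "I am attentive to my feelings", min: 1, max: 5}
  - {id: ders07, label: "I know exactly how I am feeling", min: 1, max: 5}
  - {id: ders08, label: "I care about what I am feeling", min: 1, max: 5}
  - {id: ders09, label: "I am confused about how I feel", min: 1, max: 5}
  - {id: ders10, label: "When I'm upset, I acknowledge my emotions", min: 1, max: 5}
  - {id: ders11, label: "When I'm upset, I become angry with myself for feeling that way", min: 1, max: 5}
  - {id: ders12, label: "When I'm upset, I become embarrassed for feeling that way", min: 1, max: 5}
  - {id: ders13, label: "When I'm upset, I have difficulty getting work done", min: 1, max: 5}
  - {id: ders14, label: "When I'm upset, I become out of control", min: 1, max: 5}
  - {id: ders15, label: "When I'm upset, I believe that I will remain that way for a long time", min: 1, max: 5}
  - {id: ders16, label: "When I'm upset, I believe that I'll end up feeling very depressed", min: 1, max: 5}
  - {id: ders17, label: "When I'm upset, I believe that my feelings are valid and important", min: 1, max: 5}
  - {id: ders18, label: "When I'm upset, I have difficulty focusing on other things", min: 1, max: 5}
  - {id: ders19, label: "When I'm upset, I feel out of control", min: 1, max: 5}
  - {id: ders20, label: "When I'm upset, I can still get things done", min: 1, max: 5}
  - {id: ders21, label: "When I'm upset, I feel ashamed with myself for feeling that way", min: 1, max: 5}
  - {id: ders22, label: "When I'm upset, I know that I can find a way to eventually feel better", min: 1, max: 5}
  - {id: ders23, label: "When I'm upset, I feel like I am weak", min: 1, max: 5}
  - {id: ders24, label: "When I'm upset, I feel like I can remain in control of my behaviors", min: 1, max: 5}
  - {id: ders25, label: "When I'm upset, I feel guilty for feeling that way", min: 1, max: 5}
  - {id: ders26, label: "When I'm upset, I have difficulty concentrating", min: 1, max: 5}
  - {id: ders27, label: "When I'm upset, I have difficulty controlling my behaviors", min: 1, max: 5}
  - {id: ders28, label: "When I'm upset, I believe there is nothing I can do to make myself feel better", min: 1, max: 5}
  - {id: ders29, label: "When I'm upset, I become irritated with myself for feeling that way", min: 1, max: 5}
  - {id: ders30, label: "When I'm upset, I start to feel very bad about myself", min: 1, max: 5}
  - {id: ders31, label: "When I'm upset, I believe that wallowing in it is all I can do", min: 1, max: 5}
  - {id: ders32, label: "When I'm upset, I lose control over my behaviors", min: 1, max: 5}
  - {id: ders33, label: "When I'm upset, I have difficulty thinking about anything else", min: 1, max: 5}
  - {id: ders34, label: "When I'm upset, I take time to figure out what I'm really feeling", min: 1, max: 5}
  - {id: ders35, label: "When I'm upset, it takes me a long time to feel better", min: 1, max: 5}
  - {id: ders36, label: "When I'm upset, my emotions feel overwhelming", min: 1, max: 5}
subscales:
  Nonacceptance: [ders11, ders12, ders21, ders23, ders25, ders29]
  Goals: [ders13, ders18, ders20, ders26, ders33]
  Impulse: [ders03, ders14, ders19, ders24, ders27, ders32]
  Awareness: [ders02, ders06, ders08, ders10, ders17, ders34]
  Strategies: [ders15, ders16, ders22, ders28, ders30, ders31, ders35, ders36]
  Clarity: [ders01, ders04, ders05, ders07, ders09]
reverse: [ders01, ders02, ders06, ders07, ders08, ders10, ders17, ders20, ders22, ders24, ders34]
nodes:
  Nonacceptance: NNC
  Goals: GOL
  Impulse: IMP
  Awareness: AWR
  Strategies: STR
  Clarity: CLR
communities:
  Nonacceptance: DER
  Goals: DER
  Impulse: DER
  Awareness: DER
  Strategies: DER
  Clarity: DER
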