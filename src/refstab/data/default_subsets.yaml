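# Default sample subsets of the 23-sample loquat tissue design:
# five developmental-series / tissue-type subsets, plus their union.
Fruits: [Fr1, Fr2, Fr3, Fr4, Fr5]
Floral tissues: [If, Fl, Pe, An, St, Fi, Ca]
Ovules and seeds: [Ov1, Ov2, Ov3, Sd1, Sd2, Sd3]
Vegetative tissues: [Rt, Yst, Mst, Yl, Ml]
All samples: [Fr1, Fr2, Fr3, Fr4, Fr5, If, Fl, Pe, An, St, Fi, Ca, Ov1, Ov2, Ov3, Sd1, Sd2, Sd3, Rt, Yst, Mst, Yl, Ml]
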