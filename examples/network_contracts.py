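"""The architecture facts that are checkable without training a network.

Shape contract of the 800x800 wrapper, the deep-supervision loss
combination, and the encoder-freeze partition used for transfer learning.
"""

from lvclust import (ParameterGroup, deep_supervision_loss, freeze_encoder,
                     wrapper_shape_check)

internal, output = wrapper_shape_check((800, 800))
print(f"wrapper: 800x800 input -> {internal} core -> {output} output")

loss = deep_supervision_loss(0.9, 0.8, 0.6, 0.5, 0.4)
print(f"deep-supervision loss for (0.9, 0.8, 0.6, 0.5, 0.4): {loss:.4f}")
print(f"unit losses combine to {deep_supervision_loss(1, 1, 1, 1, 1)} "
      "(the weight total 0.25+0.25+0.5+0.75+1)")

groups = [ParameterGroup(f"x{i}_0.block", "encoder", 1000) for i in range(5)] \
    + [ParameterGroup(f"up{i}.block", "decoder", 1200) for i in range(4)]
frozen = freeze_encoder(groups)
print(f"frozen encoder params   : {sum(g.n_params for g in frozen if not g.trainable)}")
print(f"trainable decoder params: {sum(g.n_params for g in frozen if g.trainable)}")
# Fine-tuning on a new hospital freezes the encoder backbone (X[i,0] column
# in the nested variant) and retrains only the decoder.
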